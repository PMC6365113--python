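import numpy as np
import pandas as pd
import pytest

from hotroutes import environment, simulate
from hotroutes.environment import (
    climate_velocity,
    correlation_screen,
    env_sar_contrast,
    tectonic_movement,
    terrain_ruggedness,
)
from hotroutes.sar import SpatialWeights


def test_tri_hand_value():
    z = np.array([[0.0, 1.0], [2.0, 3.0]])
    tri = terrain_ruggedness(z)
    # pixel (0,0): neighbours 1,2,3 -> mean |diff| = (1+2+3)/3
    assert tri[0, 0] == pytest.approx(2.0)
    assert tri[1, 1] == pytest.approx((1 + 2 + 3) / 3)


def test_tri_constant_offset_invariance():
    rng = np.random.default_rng(0)
    z = rng.normal(size=(8, 6))
    assert np.allclose(terrain_ruggedness(z), terrain_ruggedness(z + 100.0))
    assert np.all(terrain_ruggedness(np.full((5, 5), 7.0)) == 0.0)


def test_tri_block_average():
    z = np.tile(np.array([[0.0, 1.0], [1.0, 0.0]]), (3, 3))
    fine = terrain_ruggedness(z)
    coarse = terrain_ruggedness(z, cell_factor=2)
    assert coarse.shape == (3, 3)
    assert coarse[1, 1] == pytest.approx(fine[2:4, 2:4].mean())


def test_tri_rejects_bad_input():
    with pytest.raises(ValueError):
        terrain_ruggedness(np.ones(5))
    with pytest.raises(ValueError):
        terrain_ruggedness(np.ones((1, 5)))


def test_ccv_linear_ramp_exact():
    x = np.arange(10.0)
    present = np.tile(2.0 * x, (6, 1))          # gradient 2 per 1 km pixel
    past = present - 3.0
    v = climate_velocity(present, past, elapsed=1.5, pixel_km=1.0)
    # temporal = 3/1.5 = 2; spatial = 2 -> velocity 1 everywhere
    assert np.allclose(v, 1.0)


def test_ccv_flat_region_clamped():
    present = np.zeros((5, 5))
    present[:, 4] = 1.0
    past = present - 1.0
    v = climate_velocity(present, past, elapsed=1.0, pixel_km=1.0,
                         gradient_floor=0.1)
    assert np.isfinite(v).all()
    assert v[2, 0] == pytest.approx(1.0 / 0.1)
    with pytest.raises(ValueError):
        climate_velocity(present, past, elapsed=0.0)
    with pytest.raises(ValueError):
        climate_velocity(np.zeros((3, 3)), np.ones((3, 3)), 1.0)


def test_tectonic_rigid_motion_zero():
    # all points translate together: inter-neighbour distances constant
    base = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    shifts = np.array([[0, 0], [5, 2], [9, 9]], dtype=float)
    traj = base[:, None, :] + shifts[None, :, :]
    nbrs = [np.array([1, 2]), np.array([0, 2]), np.array([0, 1])]
    assert np.allclose(tectonic_movement(traj, nbrs), 0.0)


def test_tectonic_hand_value():
    # two cells moving apart: distances 1, 3 over two times
    traj = np.zeros((2, 2, 2))
    traj[1, 0, 0] = 1.0
    traj[1, 1, 0] = 3.0
    nbrs = [np.array([1]), np.array([0])]
    out = tectonic_movement(traj, nbrs)
    # centred deviations (-1, 1): sqrt(sum 2 / (1 * (2-1))) = sqrt(2)
    assert np.allclose(out, np.sqrt(2.0))
    out_iso = tectonic_movement(traj, [np.array([1]), np.array([], dtype=int)])
    assert np.isnan(out_iso[1])


def test_correlation_screen_drops_later():
    rng = np.random.default_rng(1)
    a = rng.normal(size=200)
    df = pd.DataFrame({"a": a, "b": a + rng.normal(scale=0.01, size=200),
                       "c": rng.normal(size=200)})
    kept = correlation_screen(df, rho_max=0.7)
    assert kept == ["a", "c"]
    assert correlation_screen(df[["b", "a", "c"]], 0.7) == ["b", "c"]


def _setup_env(seed, effects):
    cfg = simulate.SimConfig(seed=seed, grid_nx=15, grid_ny=10,
                             env_effects=effects)
    cells = simulate.make_cells(cfg)
    part = simulate.true_partition(cells)
    env, _ = simulate.simulate_env_layers(cells, part, cfg)
    weights = SpatialWeights.from_coords(
        cells.set_index("cell_id")[["x", "y"]], 150.0, 100.0)
    return env, part, weights


def test_env_contrast_detects_strong_effect():
    env, part, weights = _setup_env(3, {"strong": 4.0, "nil": 0.0})
    res = env_sar_contrast(env, part, weights)
    t = res.table.set_index("variable")
    assert t.loc["strong", "significant"]
    assert t.loc["strong", "beta"] > 0
    assert (t["p_bonferroni"] >= t["p_raw"] - 1e-15).all()


def test_env_contrast_zero_variance_skipped():
    env, part, weights = _setup_env(4, {"x": 1.0})
    flat = env[env["variable"] == "x"].copy()
    flat["variable"] = "flat"
    flat["value"] = 2.5
    env = pd.concat([env, flat], ignore_index=True)
    with pytest.warns(UserWarning, match="zero variance"):
        res = env_sar_contrast(env, part, weights)
    assert "flat" in res.dropped
    assert list(res.table["variable"]) == ["x"]


def test_env_contrast_standardization_recorded():
    env, part, weights = _setup_env(5, {"x": 2.0})
    res = env_sar_contrast(env, part, weights)
    srow = res.scaling.set_index("variable").loc["x"]
    raw = env[env["variable"] == "x"]["value"]
    assert srow["mean"] == pytest.approx(raw.mean())
    assert srow["sd"] == pytest.approx(raw.std(ddof=0))
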