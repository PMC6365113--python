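import json

import numpy as np
import pandas as pd
import pytest

from hotroutes import simulate
from hotroutes.simulate import (
    SimConfig,
    make_cells,
    simulate_dataset,
    simulate_env_layers,
    simulate_occurrence_grid,
    simulate_range_evolution,
    simulate_tree,
    true_partition,
)


def test_simconfig_validation():
    with pytest.raises(ValueError):
        SimConfig(hotspot_fraction=0.0)
    with pytest.raises(ValueError):
        SimConfig(birth=0.1, death=0.2)
    with pytest.raises(ValueError):
        SimConfig(sar_lambda=1.5)
    with pytest.raises(ValueError):
        SimConfig(focal_realm="nowhere")
    cfg = SimConfig()
    assert json.loads(cfg.to_json())["n_species"] == 200


def test_simulate_tree_basic():
    t = simulate_tree(0.15, 0.05, 50, seed=1)
    assert t.n_tips == 50
    assert t.is_ultrametric()
    assert len(set(t.tip_labels)) == 50
    assert t.root_age > 0
    # binary internal nodes
    internal = t.children[t.n_tips:]
    assert np.all(internal >= 0)


def test_simulate_tree_deterministic():
    a = simulate_tree(0.15, 0.05, 30, seed=9)
    b = simulate_tree(0.15, 0.05, 30, seed=9)
    assert a.to_newick() == b.to_newick()
    c = simulate_tree(0.15, 0.05, 30, seed=10)
    assert a.to_newick() != c.to_newick()


def test_simulate_tree_yule_root_age():
    # pure birth: E[crown age of an n-tip tree] = (1/b) sum_{k=2..n} 1/k
    n, b = 20, 0.3
    ages = [simulate_tree(b, 0.0, n, seed=s).root_age for s in range(300)]
    expect = sum(1.0 / k for k in range(2, n + 1)) / b
    se = np.std(ages) / np.sqrt(len(ages))
    assert abs(np.mean(ages) - expect) < 4 * se


def test_simulate_tree_invalid():
    with pytest.raises(ValueError):
        simulate_tree(0.1, 0.2, 10, seed=0)
    with pytest.raises(ValueError):
        simulate_tree(0.1, 0.0, 1, seed=0)


def test_range_evolution_states_and_determinism():
    cfg = SimConfig(seed=4, n_species=60)
    tree = simulate_tree(0.15, 0.05, 60, seed=3)
    tips, maps = simulate_range_evolution(tree, cfg)
    valid = set(cfg.model().space.labels)
    assert set(tips.values) <= valid
    assert len(tips) == 60
    assert maps.n_maps == 1
    assert getattr(maps, "n_resim") >= 0
    tips2, _ = simulate_range_evolution(tree, cfg)
    assert tips.equals(tips2)


def test_range_evolution_fixed_root():
    cfg = SimConfig(seed=4, n_species=40, d_true=0.0, e_true=0.0)
    tree = simulate_tree(0.15, 0.05, 40, seed=3)
    tips, maps = simulate_range_evolution(tree, cfg, root_range="H")
    # no anagenetic movement and sympatric copying: everything stays H
    assert set(tips.values) == {"H"}
    assert maps.histories[0].n_events() == 0


def test_make_cells_layout():
    cfg = SimConfig(grid_nx=30, grid_ny=20)
    cells = make_cells(cfg)
    assert len(cells) == 600
    assert list(cells["realm"].value_counts()) == [200, 200, 200]
    focal = cells[cells["realm"] == "focal"]
    n_hot = (focal["region"] == "H").sum()
    assert n_hot == round(0.2 * len(focal))
    # H occurs only in the focal realm
    assert set(cells.loc[cells["region"] == "H", "realm"]) == {"focal"}
    assert set(cells.loc[cells["realm"] != "focal", "region"]) == {"E"}
    # H patch is rook-contiguous
    hot = set(map(tuple, cells.loc[cells["region"] == "H", ["x", "y"]].to_numpy()))
    seen, frontier = set(), [next(iter(hot))]
    while frontier:
        x, y = frontier.pop()
        if (x, y) in seen:
            continue
        seen.add((x, y))
        frontier += [c for c in ((x+1, y), (x-1, y), (x, y+1), (x, y-1))
                     if c in hot and c not in seen]
    assert seen == hot


def test_occurrence_grid_respects_regions():
    cfg = SimConfig(seed=8, n_species=40, untreed_fraction=0.0)
    cells = make_cells(cfg)
    region_of = dict(zip(cells["cell_id"], cells["region"]))
    tips = pd.Series({"a": "H", "b": "NE", "c": "E", "d": "HN"})
    occ = simulate_occurrence_grid(tips, cfg, cells)
    for sp, state in tips.items():
        used = {region_of[c] for c in
                occ.occurrences.loc[occ.occurrences["species"] == sp, "cell_id"]}
        assert used <= set(state)
        assert used == set(state)  # every occupied area gets a patch


def test_occurrence_grid_untreed_extras():
    cfg = SimConfig(seed=8, n_species=40, untreed_fraction=0.5)
    tips = pd.Series({f"s{i}": "H" for i in range(10)})
    occ = simulate_occurrence_grid(tips, cfg)
    extras = [s for s in occ.species if s.startswith("ux")]
    assert len(extras) == 5


def test_env_layers_structure_and_effect():
    cfg = SimConfig(seed=2)
    cells = make_cells(cfg)
    part = true_partition(cells)
    env, effects = simulate_env_layers(cells, part, cfg)
    assert set(env["variable"]) == set(effects)
    assert len(env) == len(cells) * len(effects)
    wide = env.pivot(index="cell_id", columns="variable", values="value")
    hot = wide.index.isin(part.hotspot_cells)
    # npp has effect 1 on top of a unit-ish noise field: difference positive
    diff = wide.loc[hot, "npp"].mean() - wide.loc[~hot, "npp"].mean()
    assert diff > 0.2
    # zero-effect variable shows no comparable systematic shift
    diff0 = abs(wide.loc[hot, "ccv_temperature"].mean()
                - wide.loc[~hot, "ccv_temperature"].mean())
    assert diff0 < 1.5


def test_simulate_dataset_write(tmp_path):
    cfg = SimConfig(seed=1, n_species=25, grid_nx=12, grid_ny=8,
                    untreed_fraction=0.2)
    data = simulate_dataset(cfg)
    assert data.tree.n_tips == 25
    assert len(data.tip_ranges) == 25
    data.write(tmp_path)
    for name in ("tree.nwk", "occurrences.csv", "cells.csv", "env.csv", "truth.json"):
        assert (tmp_path / name).exists()
    truth = json.loads((tmp_path / "truth.json").read_text())
    assert truth["config"]["seed"] == 1
    assert set(truth["tip_ranges"]) == set(data.tree.tip_labels)
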