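import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from hotroutes import biogeo
from hotroutes.biogeo import (
    DEFAULT_SPACE,
    BiogeoModel,
    StateSpace,
    aicc,
    anagenetic_generator,
    branch_transition_matrices,
    cladogenetic_weights,
    code_tip_ranges,
    describe_model,
    fit_model,
    model_table,
    transition_matrices,
    tree_likelihood,
)
from hotroutes.hotspots import RegionPartition
from hotroutes.trees import IndexedTree

from conftest import make_grid


def test_state_space():
    sp = StateSpace()
    assert sp.labels == ["H", "N", "E", "HN", "HE", "NE"]
    assert sp.n_states == 6
    assert sp.index("NH") == sp.index("HN")
    with pytest.raises(KeyError):
        sp.index("X")


def test_generator_defective_and_conservative():
    m = BiogeoModel("DEC", False, 0.05, 0.02)
    Q = anagenetic_generator(m)
    # singles leak e into the (absent) null range; pairs are conservative
    rows = Q.sum(axis=1)
    assert np.allclose(rows[:3], -0.02)
    assert np.allclose(rows[3:], 0.0)
    Qn = anagenetic_generator(m, include_null=True)
    assert Qn.shape == (7, 7)
    assert np.allclose(Qn.sum(axis=1), 0.0)
    assert np.all(Qn[6, :] == 0.0)  # null is absorbing
    # off-diagonals non-negative
    off = Q - np.diag(np.diag(Q))
    assert np.all(off >= 0)


def test_generator_rates():
    m = BiogeoModel("DEC", False, 0.05, 0.02)
    sp = m.space
    Q = anagenetic_generator(m)
    assert Q[sp.index("H"), sp.index("HN")] == pytest.approx(0.05)
    assert Q[sp.index("HN"), sp.index("H")] == pytest.approx(0.02)
    assert Q[sp.index("H"), sp.index("NE")] == 0.0  # no two-step jumps


def test_generator_dispersal_mult():
    mult = np.ones((3, 3))
    mult[1, 0] = 3.0  # N -> H tripled
    m = BiogeoModel("DEC", False, 0.05, 0.02, dispersal_mult=mult)
    sp = m.space
    Q = anagenetic_generator(m)
    assert Q[sp.index("N"), sp.index("HN")] == pytest.approx(0.15)
    assert Q[sp.index("H"), sp.index("HN")] == pytest.approx(0.05)


def test_transition_matrices_rowsums():
    m = BiogeoModel("DEC", False, 0.05, 0.02)
    Qn = anagenetic_generator(m, include_null=True)
    P = transition_matrices(Qn, np.array([0.5, 2.0, 10.0]))
    assert np.allclose(P.sum(axis=2), 1.0, atol=1e-9)
    assert np.allclose(P[0], linalg.expm(Qn * 0.5), atol=1e-10)


def test_branch_conditioning_rows_sum_to_one():
    m = BiogeoModel("DEC", False, 0.05, 0.05)
    P = branch_transition_matrices(m, np.array([1.0, 5.0]), conditioning="branch")
    assert np.allclose(P.sum(axis=2), 1.0, atol=1e-12)
    P0 = branch_transition_matrices(m, np.array([1.0, 5.0]), conditioning="none")
    assert np.all(P0.sum(axis=2) < 1.0)  # defective
    with pytest.raises(ValueError):
        branch_transition_matrices(m, np.array([1.0]), conditioning="tree")


def test_dec_widespread_example():
    m = BiogeoModel("DEC", False, 0.01, 0.01)
    sp = m.space
    pairs, probs, types = cladogenetic_weights(m)[sp.index("HN")]
    assert len(probs) == 6
    assert np.allclose(probs, 1.0 / 6.0)
    assert sorted(types) == ["subset"] * 4 + ["vicariance"] * 2
    # vicariance outcomes are {H},{N} in both orders
    vic = {tuple(pairs[i]) for i, t in enumerate(types) if t == "vicariance"}
    h, n = sp.index("H"), sp.index("N")
    assert vic == {(h, n), (n, h)}


def test_single_area_parent_copies():
    for fam in biogeo.FAMILIES:
        m = BiogeoModel(fam, False, 0.01, 0.01)
        pairs, probs, types = cladogenetic_weights(m)[m.space.index("H")]
        assert len(probs) == 1 and probs[0] == 1.0
        assert types == ["sympatry"]
        assert tuple(pairs[0]) == (m.space.index("H"), m.space.index("H"))


def test_divalike_vicariance_only():
    m = BiogeoModel("DIVALIKE", False, 0.01, 0.01)
    _, probs, types = cladogenetic_weights(m)[m.space.index("HN")]
    assert set(types) == {"vicariance"}
    assert np.allclose(probs, 0.5)


def test_bayarealike_copy_only():
    m = BiogeoModel("BAYAREALIKE", False, 0.01, 0.01)
    pairs, probs, types = cladogenetic_weights(m)[m.space.index("HN")]
    assert types == ["copy"]
    assert tuple(pairs[0]) == (m.space.index("HN"), m.space.index("HN"))


def test_founder_weights():
    m = BiogeoModel("DEC", True, 0.01, 0.01, j=1.0)
    sp = m.space
    pairs, probs, types = cladogenetic_weights(m)[sp.index("H")]
    # sympatry (w=1) + 4 ordered founder pairs to N and E (w=1 each)
    assert len(probs) == 5
    assert np.allclose(probs, 0.2)
    assert types.count("founder") == 4
    # probabilities always normalize
    for i, (_, p, _) in cladogenetic_weights(m).items():
        assert p.sum() == pytest.approx(1.0)


def test_founder_flag_forces_j_zero():
    m = BiogeoModel("DEC", False, 0.01, 0.01, j=5.0)
    assert m.j == 0.0
    assert m.n_params == 2
    assert BiogeoModel("DEC", True, 0.01, 0.01, j=1.0).n_params == 3


def test_describe_model_probabilities():
    df = describe_model(BiogeoModel("DEC", True, 0.01, 0.01, j=2.0))
    assert np.allclose(df.groupby("parent")["prob"].sum(), 1.0)


def _tips(tree, states):
    return pd.Series(states, index=tree.tip_labels[: len(states)])


def test_likelihood_child_order_invariance():
    a = IndexedTree.from_newick("((A:1.0,B:1.0):1.0,C:2.0);")
    b = IndexedTree.from_newick("(C:2.0,(B:1.0,A:1.0):1.0);")
    st = pd.Series({"A": "H", "B": "HN", "C": "N"})
    for fam in biogeo.FAMILIES:
        m = BiogeoModel(fam, False, 0.07, 0.03)
        la = tree_likelihood(a, st, m)
        lb = tree_likelihood(b, st, m)
        assert la == pytest.approx(lb, rel=1e-12)


def test_likelihood_finite_and_negative(balanced4):
    st = pd.Series({"A": "H", "B": "N", "C": "HE", "D": "E"})
    ll = tree_likelihood(balanced4, st, BiogeoModel("DEC", False, 0.1, 0.05))
    assert np.isfinite(ll) and ll < 0


def test_likelihood_missing_tip_errors(balanced4):
    with pytest.raises(ValueError):
        tree_likelihood(balanced4, pd.Series({"A": "H"}), BiogeoModel())


def test_aicc():
    assert aicc(-10.0, 2, 50) == pytest.approx(20 + 4 + 2 * 2 * 3 / 47)
    with pytest.raises(ValueError):
        aicc(-10.0, 5, 6)


def test_model_table_guard(balanced4):
    st1 = pd.Series({"A": "H", "B": "N", "C": "HE", "D": "E"})
    st2 = pd.Series({"A": "N", "B": "N", "C": "HE", "D": "E"})
    f1 = fit_model(balanced4, st1, "DEC")
    f2 = fit_model(balanced4, st2, "DEC")
    with pytest.raises(ValueError, match="differing data"):
        model_table([f1, f2])
    tab = model_table([f1])
    assert tab.loc[0, "best"]
    assert tab["weight"].sum() == pytest.approx(1.0)


def test_code_tip_ranges():
    # focal realm: x >= 2; hotspot = c2_0
    grid = make_grid(
        [("sp1", 2, 0), ("sp1", 2, 1),            # 50% H, 50% N
         ("sp2", 0, 0), ("sp2", 0, 1), ("sp2", 1, 0),  # all E
         ("sp3", 2, 0), ("sp3", 0, 0), ("sp3", 2, 1)],  # H 1/3, E 1/3, N 1/3 -> coerced
        realms=lambda x, y: "focal" if x >= 2 else "west",
    )
    part = RegionPartition(pd.DataFrame({
        "cell_id": [c for c in grid.cells["cell_id"]],
        "klass": ["hotspot" if c in ("c2_0",) else "non-hotspot"
                  for c in grid.cells["cell_id"]],
        "realm": grid.cells["realm"].values,
    }))
    states, log = code_tip_ranges(grid, part, "focal", threshold=0.2)
    assert states["sp1"] == "HN"
    assert states["sp2"] == "E"
    assert len(states["sp3"]) == 2  # three qualify, largest two kept
    assert log["n_coerced"] == 1


def test_fit_recovers_on_moderate_tree():
    from hotroutes import simulate
    cfg = simulate.SimConfig(seed=11, n_species=150)
    tree = simulate.simulate_tree(0.15, 0.05, 150, seed=101)
    tips, _ = simulate.simulate_range_evolution(tree, cfg)
    fit = fit_model(tree, tips, "DEC", False)
    assert fit.converged
    assert 0.01 < fit.model.d < 0.25
    assert fit.model.e < 0.2
    assert fit.aicc == pytest.approx(aicc(fit.loglik, 2, 150))
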