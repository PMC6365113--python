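"""Synthetic inputs with known ground truth for the whole pipeline.

The generator produces, from one seed: a birth-death phylogeny
conditioned on its tip count; tip ranges from a forward simulation of
the configured three-area range-evolution model (with the full event
history retained as ground truth); a species x grid-cell occurrence
table in which each species occupies contiguous patches inside the
cells of its range, with heavy-tailed patch sizes; and per-cell
environmental layers with configurable hotspot effect sizes on top of a
simultaneous-autoregressive spatial error field.

Defaults emulate a desk-scale version of a global mammal/bird analysis:
a 30 x 20 grid of 100-km cells split into three vertical realm bands, a
200-tip tree with birth 0.15 and death 0.05 per lineage per Ma (crown
age around 40-60 Ma, so the 2-26 Ma analysis window is informative), and
a DEC forward process with d = 0.05, e = 0.02.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .biogeo import BiogeoModel, StateSpace, anagenetic_generator, cladogenetic_weights
from .bsm import History, StochasticMapSet
from .hotspots import OccurrenceGrid, RegionPartition
from .trees import IndexedTree

__all__ = [
    "SimConfig",
    "simulate_tree",
    "simulate_range_evolution",
    "simulate_occurrence_grid",
    "simulate_env_layers",
    "make_cells",
    "true_partition",
    "SimulatedDataset",
    "simulate_dataset",
]

DEFAULT_ENV_EFFECTS = {
    "npp": 1.0,
    "tri": 1.0,
    "habitat_count": 0.8,
    "ccv_temperature": 0.0,
    "ccv_precipitation": 0.0,
    "tectonic_movement": 0.0,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generator (one seed => one dataset)."""

    seed: int = 0
    n_species: int = 200
    grid_nx: int = 30
    grid_ny: int = 20
    cell_km: float = 100.0
    birth: float = 0.15
    death: float = 0.05
    d_true: float = 0.05
    e_true: float = 0.02
    j_true: float = 0.0
    family: str = "DEC"
    founder: bool = False
    realm_names: tuple[str, ...] = ("west", "focal", "east")
    focal_realm: str = "focal"
    hotspot_fraction: float = 0.20
    env_effects: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ENV_EFFECTS))
    sar_lambda: float = 0.5
    patch_shape: float = 1.3       # Lomax tail index of range patch sizes
    patch_scale: float = 4.0
    untreed_fraction: float = 0.15  # extra species with ranges but no tip
    root_range: str | None = None
    dispersal_mult: np.ndarray | None = None  # (3,3) directional multipliers

    def __post_init__(self) -> None:
        if not 0 < self.hotspot_fraction < 1:
            raise ValueError("hotspot_fraction must be in (0, 1)")
        if not self.birth > self.death >= 0:
            raise ValueError("need birth > death >= 0")
        if min(self.d_true, self.e_true, self.j_true) < 0:
            raise ValueError("range-evolution rates must be >= 0")
        if not -1 < self.sar_lambda < 1:
            raise ValueError("sar_lambda must be in (-1, 1)")
        if self.focal_realm not in self.realm_names:
            raise ValueError("focal_realm must be one of realm_names")

    def model(self) -> BiogeoModel:
        return BiogeoModel(self.family, self.founder or self.j_true > 0,
                           self.d_true, self.e_true, self.j_true,
                           dispersal_mult=self.dispersal_mult)

    def to_json(self) -> str:
        d = {k: (v if not isinstance(v, np.ndarray) else v.tolist())
             for k, v in self.__dict__.items()}
        d["env_effects"] = dict(self.env_effects)
        d["realm_names"] = list(self.realm_names)
        return json.dumps(d, indent=2)


# ----------------------------------------------------------------------
# tree
# ----------------------------------------------------------------------

def simulate_tree(birth: float, death: float, n_tips: int, seed: int,
                  max_retries: int = 1000) -> IndexedTree:
    """Birth-death tree conditioned on ``n_tips`` extant tips by retry.

    The simulation runs forward from a single lineage and stops at the
    moment the birth event that would create tip n+1 occurs; runs going
    extinct first are discarded.  Branch lengths are in Ma (tips at 0).
    """
    if not birth > death >= 0:
        raise ValueError("need birth > death >= 0")
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        tree = _simulate_bd_once(birth, death, n_tips, rng)
        if tree is not None:
            return tree
    raise RuntimeError(
        f"tree simulation failed to reach {n_tips} tips in {max_retries} tries "
        f"(birth={birth}, death={death})"
    )


def _simulate_bd_once(birth, death, n_tips, rng):
    # node records: [parent, t_start, t_end, child0, child1, extant]
    nodes = [[-1, 0.0, None, -1, -1, True]]
    extant = [0]
    t = 0.0
    total = birth + death
    while True:
        k = len(extant)
        if k == 0:
            return None
        t += rng.exponential(1.0 / (total * k))
        is_birth = rng.random() < birth / total
        if is_birth and k == n_tips:
            present = t
            break
        i = extant[rng.integers(k)]
        if is_birth:
            nodes[i][2] = t
            for slot in (3, 4):
                nodes.append([i, t, None, -1, -1, True])
                nodes[i][slot] = len(nodes) - 1
                extant.append(len(nodes) - 1)
            nodes[i][5] = False
            extant.remove(i)
        else:
            nodes[i][2] = t
            nodes[i][5] = False
            extant.remove(i)
    for i in extant:
        nodes[i][2] = present

    # prune extinct subtrees, suppress unifurcations
    alive = [False] * len(nodes)
    for i in extant:
        v = i
        while v >= 0 and not alive[v]:
            alive[v] = True
            v = nodes[v][0]

    def build(v):
        """Return (label_or_children, t_start, t_end) skeleton dicts."""
        c0, c1 = nodes[v][3], nodes[v][4]
        kids = [c for c in (c0, c1) if c >= 0 and alive[c]]
        if not kids:
            return {"tip": v, "t0": nodes[v][1], "t1": nodes[v][2]}
        if len(kids) == 1:
            sub = build(kids[0])
            sub = dict(sub)
            sub["t0"] = nodes[v][1]
            return sub
        return {"kids": [build(c) for c in kids], "t0": nodes[v][1], "t1": nodes[v][2]}

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(nodes) + 100))
    try:
        skel = build(0)
    finally:
        sys.setrecursionlimit(old)
    if "kids" not in skel:
        return None
    # flatten into IndexedTree arrays: tips first
    tips, internals = [], []

    def collect(nd):
        if "tip" in nd:
            tips.append(nd)
        else:
            internals.append(nd)
            for c in nd["kids"]:
                collect(c)

    collect(skel)
    order = tips + internals
    index = {id(nd): i for i, nd in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=int)
    children = np.full((n, 2), -1, dtype=int)
    blen = np.zeros(n)
    for nd in order:
        i = index[id(nd)]
        blen[i] = nd["t1"] - nd["t0"]
        if "kids" in nd:
            for s, c in enumerate(nd["kids"]):
                children[i, s] = index[id(c)]
                parent[index[id(c)]] = i
    # postorder via iterative DFS
    post, stack = [], [(index[id(skel)], False)]
    while stack:
        v, done = stack.pop()
        if done:
            post.append(v)
        else:
            stack.append((v, True))
            for c in children[v]:
                if c >= 0:
                    stack.append((c, False))
    blen[index[id(skel)]] = 0.0
    labels = [f"sp{i+1:04d}" for i in range(len(tips))]
    return IndexedTree(labels, parent, children, blen, np.asarray(post, dtype=int))


# ----------------------------------------------------------------------
# range evolution
# ----------------------------------------------------------------------

def simulate_range_evolution(
    tree: IndexedTree,
    config: SimConfig,
    root_range: str | None = None,
    max_branch_retries: int = 200,
) -> tuple[pd.Series, StochasticMapSet]:
    """Forward-simulate the range CTMC and cladogenesis along the tree.

    Returns coded tip ranges and the full true history wrapped as a
    single-map :class:`StochasticMapSet` so the event-counting code in
    the mapping module applies to it unchanged.  A branch whose range
    goes extinct (the null range) is resimulated; the count of
    resimulations is stored on the returned map set as ``n_resim``.
    """
    model = config.model()
    sp = model.space
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    Q = anagenetic_generator(model, include_null=True)
    null = sp.n_states
    clado = cladogenetic_weights(model)
    root_label = root_range or config.root_range
    if root_label is None:
        root_state = int(rng.integers(len(sp.areas)))  # uniform over singles
    else:
        root_state = sp.index(root_label)

    node_states = np.full(tree.n_nodes, -1, dtype=int)
    daughter_starts = np.full((tree.n_nodes, 2), -1, dtype=int)
    clado_types: list = [None] * tree.n_nodes
    branch_events: list = [[] for _ in range(tree.n_nodes)]
    n_resim = 0

    def sim_branch(start: int, t: float):
        events = []
        s, clock = start, 0.0
        while True:
            out = -Q[s, s]
            if out <= 0:
                break
            clock += rng.exponential(1.0 / out)
            if clock >= t:
                break
            p = Q[s].copy()
            p[s] = 0.0
            p /= p.sum()
            s2 = int(rng.choice(len(p), p=p))
            events.append((clock, s, s2))
            s = s2
            if s == null:
                return None, None
        return events, s

    root = tree.root
    node_states[root] = root_state
    stack = [root]
    while stack:
        v = stack.pop()
        if v < tree.n_tips:
            continue
        x = node_states[v]
        pairs, probs, types = clado[x]
        k = int(rng.choice(len(probs), p=probs))
        daughter_starts[v] = pairs[k]
        clado_types[v] = types[k]
        top_age = float(tree.ages[v])
        for slot, c in enumerate(tree.children[v]):
            y = int(pairs[k, slot])
            t = float(tree.blen[c])
            for attempt in range(max_branch_retries):
                events, end = sim_branch(y, t)
                if events is not None:
                    break
                n_resim += 1
            else:
                raise RuntimeError(
                    f"branch range went extinct {max_branch_retries} times "
                    f"(e={config.e_true}, d={config.d_true}, t={t:.2f})"
                )
            node_states[c] = end
            branch_events[c] = [(top_age - u, a, b) for u, a, b in events]
            stack.append(c)

    hist = History(node_states, daughter_starts, clado_types, branch_events)
    maps = StochasticMapSet(tree, model, [hist])
    maps.n_resim = n_resim
    tip_ranges = pd.Series(
        {tree.tip_labels[i]: sp.labels[node_states[i]] for i in range(tree.n_tips)},
        name="range_state",
    ).sort_index()
    return tip_ranges, maps


# ----------------------------------------------------------------------
# grid, occurrences, environment
# ----------------------------------------------------------------------

def make_cells(config: SimConfig) -> pd.DataFrame:
    """Cell table (cell_id, x, y, realm, region) with the true H patch.

    Realms are equal vertical bands; the true hotspot region is a single
    contiguous patch grown from the centre of the focal realm covering
    ``hotspot_fraction`` of its cells.  ``region`` is the H/N/E coding
    used by the forward range simulation (ground truth).
    """
    nx, ny = config.grid_nx, config.grid_ny
    n_realms = len(config.realm_names)
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xs, ys = xs.ravel(), ys.ravel()
    band = np.minimum((xs * n_realms) // nx, n_realms - 1)
    realm = np.asarray(config.realm_names)[band]
    cell_id = [f"c{x:03d}_{y:03d}" for x, y in zip(xs, ys)]
    df = pd.DataFrame({"cell_id": cell_id, "x": xs, "y": ys, "realm": realm})
    focal = df[df["realm"] == config.focal_realm]
    if focal.empty:
        raise ValueError(f"focal realm {config.focal_realm!r} has zero cells")
    n_hot = max(1, round(config.hotspot_fraction * len(focal)))
    # deterministic contiguous patch grown from the realm centre
    cx, cy = focal["x"].mean(), focal["y"].mean()
    focal = focal.assign(dist=(focal["x"] - cx) ** 2 + (focal["y"] - cy) ** 2)
    hot_ids = set(focal.sort_values(["dist", "cell_id"]).head(n_hot)["cell_id"])
    region = np.where(df["realm"] != config.focal_realm, "E",
                      np.where(df["cell_id"].isin(hot_ids), "H", "N"))
    return df.assign(region=region)


def true_partition(cells: pd.DataFrame, occupied: set | None = None) -> RegionPartition:
    """Ground-truth hotspot partition (region H vs rest) over given cells."""
    df = cells if occupied is None else cells[cells["cell_id"].isin(occupied)]
    table = pd.DataFrame({
        "cell_id": df["cell_id"].values,
        "klass": np.where(df["region"] == "H", "hotspot", "non-hotspot"),
        "realm": df["realm"].values,
    })
    return RegionPartition(table, clade="truth", metric="simulated")


def _grow_patch(allowed: set, seed_cell, size: int, rng) -> set:
    """Seeded breadth-first accretion of a contiguous patch on the grid."""
    patch = {seed_cell}
    frontier = [seed_cell]
    while len(patch) < size and frontier:
        i = int(rng.integers(len(frontier)))
        x, y = frontier[i]
        nbrs = [c for c in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1))
                if c in allowed and c not in patch]
        if not nbrs:
            frontier.pop(i)
            continue
        c = nbrs[int(rng.integers(len(nbrs)))]
        patch.add(c)
        frontier.append(c)
    return patch


def simulate_occurrence_grid(
    tip_ranges: pd.Series,
    config: SimConfig,
    cells: pd.DataFrame | None = None,
) -> OccurrenceGrid:
    """Occupancy patches for every species inside its true region(s).

    Patch sizes are heavy-tailed (Lomax); a species with a two-area
    range receives one contiguous patch per occupied area (seeded as
    close together as the geometry allows), so each area holds a
    substantial share of the range.  Optionally appends
    ``untreed_fraction`` extra species absent from the tree, emulating
    taxa with distribution data but no phylogenetic placement.
    """
    if cells is None:
        cells = make_cells(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    by_region: dict[str, set] = {
        r: set(map(tuple, cells.loc[cells["region"] == r, ["x", "y"]].to_numpy()))
        for r in ("H", "N", "E")
    }
    for r, cs in by_region.items():
        if not cs:
            raise ValueError(f"region {r!r} has zero cells in the layout")
    id_of = {(x, y): cid for cid, x, y in cells[["cell_id", "x", "y"]].itertuples(index=False)}

    species = list(tip_ranges.index)
    states = list(tip_ranges.values)
    n_extra = int(round(config.untreed_fraction * len(species)))
    for i in range(n_extra):
        species.append(f"ux{i+1:04d}")
        states.append(("H", "N", "E")[int(rng.integers(3))])

    rows = []
    for sp, state in zip(species, states):
        size = 1 + int(np.floor(rng.pareto(config.patch_shape) * config.patch_scale))
        areas = list(state)
        patches = []
        for ai, a in enumerate(areas):
            allowed = by_region[a]
            share = max(1, size // len(areas))
            if ai == 0 or not patches:
                seeds = sorted(allowed)
                seed_cell = seeds[int(rng.integers(len(seeds)))]
            else:
                ref = next(iter(patches[0]))
                seed_cell = min(sorted(allowed),
                                key=lambda c: (c[0] - ref[0]) ** 2 + (c[1] - ref[1]) ** 2)
            patches.append(_grow_patch(allowed, seed_cell, min(share, len(allowed)), rng))
        for patch in patches:
            rows.extend((sp, id_of[c]) for c in patch)
    occ = pd.DataFrame(rows, columns=["species", "cell_id"])
    return OccurrenceGrid(occ, cells[["cell_id", "x", "y", "realm"]].copy(), config.cell_km)


def _rook_adjacency(cells: pd.DataFrame) -> sparse.csr_matrix:
    pos = {(x, y): i for i, (x, y) in enumerate(cells[["x", "y"]].itertuples(index=False))}
    rows, cols = [], []
    for (x, y), i in pos.items():
        for nb in ((x + 1, y), (x, y + 1)):
            j = pos.get(nb)
            if j is not None:
                rows += [i, j]
                cols += [j, i]
    n = len(pos)
    return sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))


def simulate_env_layers(
    cells: pd.DataFrame,
    partition: RegionPartition,
    config: SimConfig,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Environmental variables = hotspot effect + SAR error field.

    Each variable v is effect_v * 1[hotspot] + u with
    u = (I - lambda W)^-1 eps, eps ~ N(0, 1), W the row-standardized
    rook-neighbour matrix of the full grid.  Returns a long table
    (cell_id, variable, value) and the true effects used.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    adj = _rook_adjacency(cells)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    W = sparse.diags(np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)) @ adj
    n = len(cells)
    A = sparse.identity(n, format="csc") - config.sar_lambda * W.tocsc()
    hot = cells["cell_id"].isin(partition.hotspot_cells).to_numpy(dtype=float)
    rows = []
    effects = dict(config.env_effects)
    for var, beta in effects.items():
        eps = rng.standard_normal(n)
        try:
            u = spsolve(A, eps)
        except Exception as exc:  # singular (I - lambda W)
            raise RuntimeError(
                f"(I - lambda W) singular at lambda={config.sar_lambda}; "
                f"|spectrum| bound 1"
            ) from exc
        vals = beta * hot + u
        rows.append(pd.DataFrame({
            "cell_id": cells["cell_id"].values, "variable": var, "value": vals,
        }))
    return pd.concat(rows, ignore_index=True), effects


# ----------------------------------------------------------------------
# one-call dataset
# ----------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    tree: IndexedTree
    tip_ranges: pd.Series
    true_history: StochasticMapSet
    cells: pd.DataFrame
    occurrences: OccurrenceGrid
    env: pd.DataFrame
    env_effects: dict[str, float]

    def write(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        self.occurrences.write_csv(out / "occurrences.csv", out / "cells.csv")
        self.env.to_csv(out / "env.csv", index=False)
        truth = {
            "config": json.loads(self.config.to_json()),
            "n_resim": getattr(self.true_history, "n_resim", 0),
            "tip_ranges": self.tip_ranges.to_dict(),
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate every pipeline input from one config (pure in the seed)."""
    tree = simulate_tree(config.birth, config.death, config.n_species,
                         seed=int(np.random.SeedSequence([config.seed, 3]).generate_state(1)[0] % (2**31)))
    tip_ranges, truth = simulate_range_evolution(tree, config)
    cells = make_cells(config)
    occ = simulate_occurrence_grid(tip_ranges, config, cells)
    part = true_partition(cells)
    env, effects = simulate_env_layers(cells, part, config)
    return SimulatedDataset(config, tree, tip_ranges, truth, cells, occ, env, effects)
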