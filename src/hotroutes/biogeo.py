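"""Three-area range-evolution models: likelihood, ML fit, AICc comparison.

Areas are H (hotspot cells of the focal realm), N (non-hotspot cells of
the focal realm) and E (everywhere else); ranges hold at most two areas,
giving six states H, N, E, HN, HE, NE plus an absorbing null range that
carries zero likelihood at the tips.

Anagenetic change along branches is a CTMC: a range gains an adjacent
area at rate d per (occupied, gained) pair and loses an occupied area at
rate e.  Cladogenetic change at nodes follows the family-specific outcome
table — DEC allows single-area sympatry, subset sympatry and narrow
vicariance; DIVALIKE allows single-area sympatry and vicariance;
BAYAREALIKE copies the parent range to both daughters.  The +J variants
add founder-event speciation: one daughter jumps to a single unoccupied
area with weight j (non-founder outcomes have weight 1; weights are
normalized within each parent range).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .hotspots import OccurrenceGrid, RegionPartition
from .trees import IndexedTree

__all__ = [
    "StateSpace",
    "BiogeoModel",
    "FitResult",
    "FAMILIES",
    "code_tip_ranges",
    "anagenetic_generator",
    "cladogenetic_weights",
    "transition_matrices",
    "branch_transition_matrices",
    "tree_likelihood",
    "fit_model",
    "aicc",
    "model_table",
]

FAMILIES = ("DEC", "DIVALIKE", "BAYAREALIKE")


@dataclass(frozen=True)
class StateSpace:
    """Ranges over a fixed area set with range size capped at two."""

    areas: tuple[str, ...] = ("H", "N", "E")
    max_range: int = 2

    @property
    def states(self) -> list[frozenset]:
        singles = [frozenset([a]) for a in self.areas]
        pairs = [frozenset(p) for p in itertools.combinations(self.areas, 2)]
        return singles + (pairs if self.max_range >= 2 else [])

    @property
    def labels(self) -> list[str]:
        return ["".join(sorted(s, key=self.areas.index)) for s in self.states]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        s = frozenset(label)
        for i, st in enumerate(self.states):
            if st == s:
                return i
        raise KeyError(f"unknown range state {label!r}")


DEFAULT_SPACE = StateSpace()


@dataclass
class BiogeoModel:
    """One member of the six-model family.

    d: anagenetic dispersal rate per (source, destination) area pair
       (events / lineage / Ma); e: per-area local extinction rate; j:
    founder-event weight, forced to 0 when ``founder`` is off.
    ``dispersal_mult`` optionally scales d per ordered area pair (used by
    the forward simulator to create directional dispersal; fitting uses
    the unconstrained default of all ones).
    """

    family: str = "DEC"
    founder: bool = False
    d: float = 0.01
    e: float = 0.01
    j: float = 0.0
    space: StateSpace = field(default_factory=StateSpace)
    dispersal_mult: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if min(self.d, self.e, self.j) < 0:
            raise ValueError("rates must be non-negative")
        if not self.founder:
            self.j = 0.0
        if self.dispersal_mult is None:
            k = len(self.space.areas)
            self.dispersal_mult = np.ones((k, k))

    @property
    def name(self) -> str:
        return self.family + ("+J" if self.founder else "")

    @property
    def n_params(self) -> int:
        return 3 if self.founder else 2


# ----------------------------------------------------------------------
# tip coding
# ----------------------------------------------------------------------

def code_tip_ranges(
    occ: OccurrenceGrid,
    partition: RegionPartition,
    realm: str,
    threshold: float = 0.20,
) -> tuple[pd.Series, dict]:
    """Code each species into H/N/E (max two areas) for one focal realm.

    A species is present in a region when >= ``threshold`` of its occupied
    cells fall there.  If more than two regions qualify the two largest
    fractions are kept (ties resolved H > N > E); if none qualifies the
    single largest region is used.  Returns the coding and a log with the
    count of >2-region coercions.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    klass = partition.klass_of()
    realms = partition.realm_of()
    region = {}
    for cid in klass.index:
        if realms[cid] == realm:
            region[cid] = "H" if klass[cid] == "hotspot" else "N"
        else:
            region[cid] = "E"
    priority = {"H": 0, "N": 1, "E": 2}
    states, coerced = {}, 0
    for sp, grp in occ.occurrences.groupby("species"):
        cells = grp["cell_id"]
        if len(cells) == 0:
            raise ValueError(f"species {sp!r} has no occupied cells")
        frac = cells.map(region).value_counts(normalize=True)
        qual = [r for r in ("H", "N", "E") if frac.get(r, 0.0) >= threshold]
        if len(qual) > 2:
            qual = sorted(qual, key=lambda r: (-frac[r], priority[r]))[:2]
            coerced += 1
        if not qual:
            qual = [max(("H", "N", "E"), key=lambda r: (frac.get(r, 0.0), -priority[r]))]
        states[sp] = "".join(sorted(qual, key=priority.get))
    log = {"realm": realm, "threshold": threshold, "n_coerced": coerced}
    return pd.Series(states, name="range_state").sort_index(), log


# ----------------------------------------------------------------------
# anagenetic process
# ----------------------------------------------------------------------

def anagenetic_generator(model: BiogeoModel, include_null: bool = False) -> np.ndarray:
    """CTMC rate matrix over ranges.

    Without the null state the matrix is defective: single-area ranges
    lose probability mass at rate e (flow into the absorbing null range,
    which contributes zero tip likelihood).  With ``include_null`` the
    null range is appended as a final absorbing row/column, making the
    generator conservative (used by the simulators).
    """
    sp = model.space
    states = sp.states
    n = sp.n_states
    m = n + 1 if include_null else n
    Q = np.zeros((m, m))
    area_idx = {a: i for i, a in enumerate(sp.areas)}
    null_leak = np.zeros(n)
    for i, s in enumerate(states):
        # gains: range acquires an unoccupied area, rate d per source area
        if len(s) < sp.max_range:
            for a in sp.areas:
                if a in s:
                    continue
                rate = model.d * sum(
                    model.dispersal_mult[area_idx[b], area_idx[a]] for b in s
                )
                Q[i, states.index(s | {a})] += rate
        # losses: each occupied area drops out at rate e
        for a in s:
            rest = s - {a}
            if rest:
                Q[i, states.index(rest)] += model.e
            elif include_null:
                Q[i, n] += model.e
            else:
                null_leak[i] += model.e
    for i in range(m):
        Q[i, i] = -Q[i].sum() - (null_leak[i] if i < n else 0.0)
    return Q


def transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """exp(Q t) for every t in ``lengths``, via one eigendecomposition.

    Falls back to scaling-and-squaring (scipy expm) per branch when the
    eigenvector matrix is ill-conditioned.
    """
    lengths = np.asarray(lengths, dtype=float)
    vals, vecs = np.linalg.eig(Q)
    cond = np.linalg.cond(vecs)
    if np.isfinite(cond) and cond < 1e8:
        vinv = np.linalg.inv(vecs)
        et = np.exp(np.outer(lengths, vals))
        P = np.einsum("ij,tj,jk->tik", vecs, et, vinv)
        P = np.real(P)
    else:
        P = np.stack([linalg.expm(Q * t) for t in lengths])
    np.clip(P, 0.0, None, out=P)
    return P


# ----------------------------------------------------------------------
# cladogenetic process
# ----------------------------------------------------------------------

def cladogenetic_weights(model: BiogeoModel) -> dict[int, tuple[np.ndarray, np.ndarray, list[str]]]:
    """Per parent state: allowed ordered daughter pairs and probabilities.

    Returns {parent index: (pairs (K,2) int, probs (K,), event types)}.
    Event types: 'sympatry' (single-area copy), 'subset', 'vicariance',
    'copy' (BAYAREALIKE widespread sympatry), 'founder'.
    """
    sp = model.space
    states = sp.states
    idx = {s: i for i, s in enumerate(states)}
    out = {}
    for i, parent in enumerate(states):
        entries: list[tuple[int, int, float, str]] = []
        if len(parent) == 1:
            entries.append((i, i, 1.0, "sympatry"))
        else:
            if model.family == "DEC":
                # sorted: frozenset iteration order varies across processes
                for a in sorted(parent, key=sp.areas.index):
                    sa = idx[frozenset([a])]
                    entries.append((sa, i, 1.0, "subset"))
                    entries.append((i, sa, 1.0, "subset"))
                (a, b) = sorted(parent, key=sp.areas.index)
                sa, sb = idx[frozenset([a])], idx[frozenset([b])]
                entries.append((sa, sb, 1.0, "vicariance"))
                entries.append((sb, sa, 1.0, "vicariance"))
            elif model.family == "DIVALIKE":
                (a, b) = sorted(parent, key=sp.areas.index)
                sa, sb = idx[frozenset([a])], idx[frozenset([b])]
                entries.append((sa, sb, 1.0, "vicariance"))
                entries.append((sb, sa, 1.0, "vicariance"))
            elif model.family == "BAYAREALIKE":
                entries.append((i, i, 1.0, "copy"))
        if model.founder and model.j > 0:
            for a in sp.areas:
                if a in parent:
                    continue
                sa = idx[frozenset([a])]
                entries.append((i, sa, model.j, "founder"))
                entries.append((sa, i, model.j, "founder"))
        pairs = np.array([(l, r) for l, r, _, _ in entries], dtype=int)
        w = np.array([w for _, _, w, _ in entries], dtype=float)
        types = [t for _, _, _, t in entries]
        out[i] = (pairs, w / w.sum(), types)
    return out


def describe_model(model: BiogeoModel) -> pd.DataFrame:
    """Tabulate the exact cladogenetic outcome distribution of a model."""
    sp = model.space
    rows = []
    for i, (pairs, probs, types) in cladogenetic_weights(model).items():
        for (l, r), p, t in zip(pairs, probs, types):
            rows.append({
                "parent": sp.labels[i], "left": sp.labels[l],
                "right": sp.labels[r], "type": t, "prob": p,
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# likelihood
# ----------------------------------------------------------------------

def _tip_state_indices(tree: IndexedTree, tip_states: pd.Series, space: StateSpace) -> np.ndarray:
    missing = [t for t in tree.tip_labels if t not in tip_states.index]
    if missing:
        raise ValueError(f"tips without a coded range: {missing[:5]}")
    return np.array([space.index(tip_states[t]) for t in tree.tip_labels])


def _flatten_clado(clado: dict, n_states: int):
    """Concatenate the per-parent outcome tables for vectorized mixing."""
    xs, ls, rs, ps = [], [], [], []
    for x, (pairs, probs, _) in clado.items():
        xs.extend([x] * len(probs))
        ls.extend(pairs[:, 0])
        rs.extend(pairs[:, 1])
        ps.extend(probs)
    return (np.asarray(xs), np.asarray(ls), np.asarray(rs),
            np.asarray(ps, dtype=float), n_states)


def _pruning_loglik(tree, tips, P, flat, prior):
    xs, ls, rs, ps, n_states = flat
    D = np.zeros((tree.n_nodes, n_states))
    log_scale = 0.0
    for v in tree.postorder:
        if v < tree.n_tips:
            D[v, tips[v]] = 1.0
            continue
        c0, c1 = tree.children[v]
        m0 = P[c0] @ D[c0]
        m1 = P[c1] @ D[c1]
        D[v] = np.bincount(xs, weights=ps * m0[ls] * m1[rs], minlength=n_states)
        mx = D[v].max()
        if mx <= 0:
            raise ValueError("likelihood is exactly zero: data impossible under model")
        D[v] /= mx
        log_scale += np.log(mx)
    lik = float(prior @ D[tree.root])
    if lik <= 0:
        raise ValueError("likelihood is exactly zero: data impossible under model")
    return float(np.log(lik) + log_scale)


def _root_prior_vector(root_prior, n_states: int) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior != "uniform":
            raise ValueError("root_prior must be 'uniform' or a probability vector")
        return np.full(n_states, 1.0 / n_states)
    prior = np.asarray(root_prior, dtype=float)
    return prior / prior.sum()


def branch_transition_matrices(
    model: BiogeoModel, lengths: np.ndarray, conditioning: str = "branch"
) -> np.ndarray:
    """Per-branch range transition probabilities.

    With ``conditioning='none'`` these are the rows of exp(Qt) of the
    defective generator: surviving single-area lineages pay a survival
    factor, which is the classic convention but pushes the ML extinction
    rate to zero.  With ``conditioning='branch'`` (default) each row is
    renormalized by its survival probability — every branch of a
    reconstructed tree has extant descendants, so its range cannot have
    gone extinct, and the renormalized rows are exactly the law of the
    simulated (resampled-on-extinction) forward process.
    """
    P = transition_matrices(anagenetic_generator(model), lengths)
    if conditioning == "branch":
        P = P / np.maximum(P.sum(axis=2, keepdims=True), 1e-300)
    elif conditioning != "none":
        raise ValueError("conditioning must be 'branch' or 'none'")
    return P


def tree_likelihood(
    tree: IndexedTree,
    tip_states: pd.Series,
    model: BiogeoModel,
    root_prior: np.ndarray | str = "uniform",
    conditioning: str = "branch",
) -> float:
    """Pruning log-likelihood of coded tip ranges under the model.

    Branch transitions use the matrix exponential of the anagenetic
    generator (survival-conditioned per branch by default, see
    :func:`branch_transition_matrices`); internal nodes mix over the
    cladogenetic outcome distribution.  Partial likelihoods are rescaled
    at every node.  The root prior defaults to uniform over the non-null
    ranges.
    """
    sp = model.space
    tips = _tip_state_indices(tree, tip_states, sp)
    P = branch_transition_matrices(model, tree.blen, conditioning)
    flat = _flatten_clado(cladogenetic_weights(model), sp.n_states)
    prior = _root_prior_vector(root_prior, sp.n_states)
    return _pruning_loglik(tree, tips, P, flat, prior)


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class FitResult:
    model: BiogeoModel
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    n_evals: int
    data_hash: int = 0

    @property
    def name(self) -> str:
        return self.model.name


D_BOUNDS = (1e-12, 5.0)
E_BOUNDS = (1e-12, 5.0)
J_BOUNDS = (0.0, 3.0)

_STARTS = [
    (0.01, 0.01, 0.05),
    (0.1, 0.02, 0.5),
    (0.4, 0.2, 1.5),
]


def fit_model(
    tree: IndexedTree,
    tip_states: pd.Series,
    family: str = "DEC",
    founder: bool = False,
    root_prior: np.ndarray | str = "uniform",
    conditioning: str = "branch",
    starts: list[tuple[float, float, float]] | None = None,
) -> FitResult:
    """Bounded maximum-likelihood fit of (d, e[, j]) by multi-start L-BFGS-B.

    d and e are optimized on a log scale within [1e-12, 5] events/Ma;
    j within [0, 3].  AICc uses n = number of tips.
    """
    n = tree.n_tips
    if n < 10:
        warnings.warn("fewer than 10 tips: parameter estimates will be poor")
    space = DEFAULT_SPACE
    tips_idx = _tip_state_indices(tree, tip_states, space)
    prior = _root_prior_vector(root_prior, space.n_states)
    evals = 0

    def nll(theta: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        d, e = np.exp(theta[0]), np.exp(theta[1])
        j = theta[2] if founder else 0.0
        model = BiogeoModel(family, founder, d, e, j, space)
        try:
            P = branch_transition_matrices(model, tree.blen, conditioning)
            flat = _flatten_clado(cladogenetic_weights(model), space.n_states)
            return -_pruning_loglik(tree, tips_idx, P, flat, prior)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12

    log_b = (np.log(D_BOUNDS[0]), np.log(D_BOUNDS[1]))
    bounds = [log_b, log_b] + ([J_BOUNDS] if founder else [])
    best = None
    for d0, e0, j0 in (starts or _STARTS):
        x0 = [np.log(d0), np.log(e0)] + ([j0] if founder else [])
        res = optimize.minimize(
            lambda th: nll(np.asarray(th)), x0, method="L-BFGS-B",
            bounds=bounds, options={"maxiter": 300, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(
            f"{family}{'+J' if founder else ''} fit failed from all starts "
            f"(best objective {None if best is None else best.fun})"
        )
    d_hat, e_hat = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    j_hat = float(best.x[2]) if founder else 0.0
    model = BiogeoModel(family, founder, d_hat, e_hat, j_hat, space)
    ll = -float(best.fun)
    k = model.n_params
    return FitResult(
        model, ll, k, n, aicc(ll, k, n), bool(best.success), evals,
        data_hash=hash((tuple(tree.tip_labels), tuple(tip_states.reindex(tree.tip_labels)))),
    )


def model_table(fits: list[FitResult]) -> pd.DataFrame:
    """AICc comparison table with delta-AICc and Akaike weights."""
    if not fits:
        raise ValueError("no fits supplied")
    if len({f.data_hash for f in fits}) > 1:
        raise ValueError("fits were computed on differing data")
    df = pd.DataFrame({
        "model": [f.name for f in fits],
        "d": [f.model.d for f in fits],
        "e": [f.model.e for f in fits],
        "j": [f.model.j for f in fits],
        "lnL": [f.loglik for f in fits],
        "k": [f.k for f in fits],
        "AICc": [f.aicc for f in fits],
    }).sort_values("AICc", kind="mergesort").reset_index(drop=True)
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    rel = np.exp(-0.5 * df["dAICc"])
    df["weight"] = rel / rel.sum()
    df["best"] = False
    df.loc[0, "best"] = True
    return df
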