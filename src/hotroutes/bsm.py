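"""Biogeographic stochastic mapping and time-binned event-rate series.

A stochastic map is one explicit range-evolution history consistent with
the coded tip ranges under a fitted model: joint node states are drawn
from their conditional distribution (backward pruning pass, forward
sampling pass including the cladogenetic outcome mixture), and each
branch history is then drawn conditional on its endpoints by
uniformization of the anagenetic CTMC.

Events are flattened into a typed table (dispersal, local extinction,
within-region cladogenesis, vicariance, founder), binned into 2-Ma
periods inside a 2-26 Ma window, and converted into per-region rates:
dispersal rate = median event count per bin across maps divided by the
lineage count of the normalizing region in the previous (older) bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biogeo import (
    BiogeoModel,
    FitResult,
    anagenetic_generator,
    branch_transition_matrices,
    cladogenetic_weights,
    transition_matrices,
)
from .trees import IndexedTree

__all__ = [
    "History",
    "StochasticMapSet",
    "RateSeries",
    "sample_maps",
    "extract_events",
    "lineage_counts",
    "dispersal_rate_series",
    "cladogenesis_rate_series",
    "standardized_difference",
    "colonization_age",
    "default_bins",
]

WITHIN_TYPES = {"sympatry", "subset", "copy"}


@dataclass
class History:
    """One sampled (or true) range-evolution history on a fixed tree.

    ``node_states[v]`` is the range index immediately before cladogenesis
    at internal node v (or the observed range at a tip).
    ``daughter_starts[v]`` are the post-cladogenesis start states of the
    two child branches.  ``branch_events[v]`` lists the anagenetic events
    on the branch above v as (age, from_state, to_state) in decreasing
    age order.
    """

    node_states: np.ndarray
    daughter_starts: np.ndarray
    clado_types: list
    branch_events: list

    def n_events(self) -> int:
        return sum(len(ev) for ev in self.branch_events)


@dataclass
class StochasticMapSet:
    tree: IndexedTree
    model: BiogeoModel
    histories: list[History]

    @property
    def n_maps(self) -> int:
        return len(self.histories)

    # ------------------------------------------------------------------
    def branch_segments(self, hist: History, v: int) -> list[tuple[float, float, int]]:
        """Piecewise-constant occupancy on the branch above v.

        Returns (age_hi, age_lo, state) segments from the branch top
        (parent's age) down to v's age.
        """
        tree = self.tree
        p = tree.parent[v]
        if p < 0:
            return []
        slot = 0 if tree.children[p][0] == v else 1
        state = int(hist.daughter_starts[p][slot])
        hi = float(tree.ages[p])
        lo = float(tree.ages[v])
        segs = []
        for age, _s_from, s_to in hist.branch_events[v]:
            segs.append((hi, float(age), state))
            state = int(s_to)
            hi = float(age)
        segs.append((hi, lo, state))
        return segs

    def state_at(self, hist: History, v: int, age: float) -> int | None:
        for hi, lo, s in self.branch_segments(hist, v):
            if hi >= age > lo or (lo == 0.0 and age == 0.0 and hi >= age):
                return s
        return None


def default_bins(start: float = 2.0, stop: float = 26.0, width: float = 2.0) -> np.ndarray:
    """Half-open [t, t+width) bin starts covering [start, stop)."""
    return np.arange(start, stop, width)


# ----------------------------------------------------------------------
# sampling
# ----------------------------------------------------------------------

def _pruning_tables(tree, tips_idx, model, root_prior, conditioning="branch"):
    n_states = model.space.n_states
    P = branch_transition_matrices(model, tree.blen, conditioning)
    clado = cladogenetic_weights(model)
    D = np.zeros((tree.n_nodes, n_states))
    M = np.zeros((tree.n_nodes, n_states))
    for v in tree.postorder:
        if v < tree.n_tips:
            D[v, tips_idx[v]] = 1.0
        else:
            c0, c1 = tree.children[v]
            for x, (pairs, probs, _) in clado.items():
                D[v, x] = float(np.sum(probs * M[c0][pairs[:, 0]] * M[c1][pairs[:, 1]]))
            mx = D[v].max()
            if mx <= 0:
                raise ValueError("tip data impossible under the model")
            D[v] /= mx
        M[v] = P[v] @ D[v]
    if isinstance(root_prior, str):
        prior = np.full(n_states, 1.0 / n_states)
    else:
        prior = np.asarray(root_prior, float)
        prior = prior / prior.sum()
    return P, clado, D, M, prior


class _Uniformizer:
    """Endpoint-conditioned CTMC path sampler by uniformization.

    Operates on the conservative generator including the absorbing null
    range; conditioning on a non-null endpoint automatically excludes
    null-visiting paths.
    """

    def __init__(self, model: BiogeoModel, max_jumps: int = 512, max_rejects: int = 10_000):
        self.Q = anagenetic_generator(model, include_null=True)
        self.m = self.Q.shape[0]
        self.rate = float(np.max(-np.diag(self.Q)))
        if self.rate > 0:
            self.R = np.eye(self.m) + self.Q / self.rate
        else:
            self.R = np.eye(self.m)
        self._pows = [np.eye(self.m), self.R.copy()]
        self.max_jumps = max_jumps
        self.max_rejects = max_rejects
        self._pt_cache: dict[float, np.ndarray] = {}

    def _rpow(self, k: int) -> np.ndarray:
        while len(self._pows) <= k:
            self._pows.append(self._pows[-1] @ self.R)
        return self._pows[k]

    def _pt(self, t: float) -> np.ndarray:
        if t not in self._pt_cache:
            self._pt_cache[t] = transition_matrices(self.Q, np.array([t]))[0]
        return self._pt_cache[t]

    def sample_path(self, a: int, b: int, t: float, rng) -> list[tuple[float, int, int]]:
        """Jump chain (time-from-top, from, to), excluding virtual jumps."""
        if self.rate == 0.0:
            if a != b:
                raise RuntimeError("no events possible but endpoints differ")
            return []
        p_ab = self._pt(t)[a, b]
        if p_ab <= 0:
            raise RuntimeError(
                f"endpoint pair ({a}->{b}) has zero probability over t={t}"
            )
        lam_t = self.rate * t
        # number of uniformized jumps
        u = rng.random()
        cum = 0.0
        n = -1
        log_pois = -lam_t
        pois = np.exp(log_pois)
        for k in range(self.max_jumps):
            term = pois * self._rpow(k)[a, b] / p_ab
            cum += term
            if u <= cum:
                n = k
                break
            pois *= lam_t / (k + 1)
        if n < 0:
            raise RuntimeError(
                f"uniformization jump count did not converge (branch t={t}, "
                f"rate={self.rate})"
            )
        if n == 0:
            return []
        # states at the n jump epochs
        states = [a]
        for i in range(1, n):
            prev = states[-1]
            w = self.R[prev, :] * self._rpow(n - i)[:, b]
            tot = w.sum()
            if tot <= 0:
                raise RuntimeError("degenerate intermediate-state weights")
            states.append(int(rng.choice(self.m, p=w / tot)))
        states.append(b)
        times = np.sort(rng.random(n)) * t
        events = []
        for i in range(n):
            if states[i] != states[i + 1]:
                events.append((float(times[i]), states[i], states[i + 1]))
        return events

    def sample_path_rejection(self, a: int, b: int, t: float, rng) -> list[tuple[float, int, int]]:
        for _ in range(self.max_rejects):
            events = []
            s, clock = a, 0.0
            ok = True
            while True:
                out = -self.Q[s, s]
                if out <= 0:
                    break
                clock += rng.exponential(1.0 / out)
                if clock >= t:
                    break
                probs = self.Q[s].copy()
                probs[s] = 0.0
                probs /= probs.sum()
                s2 = int(rng.choice(self.m, p=probs))
                events.append((clock, s, s2))
                s = s2
            if ok and s == b:
                return events
        raise RuntimeError(f"rejection sampling failed after {self.max_rejects} tries")


def sample_maps(
    tree: IndexedTree,
    tip_states: pd.Series,
    fit: FitResult | BiogeoModel,
    n_maps: int = 50,
    seed: int = 0,
    root_prior="uniform",
    conditioning: str = "branch",
) -> StochasticMapSet:
    """Draw ``n_maps`` stochastic range-evolution histories given the tips.

    Node states come from the backward-forward pass over the pruning
    tables (with the same survival conditioning used for fitting);
    branch histories are endpoint-conditioned CTMC paths drawn by
    uniformization, for which the per-branch conditioning cancels.
    """
    model = fit.model if isinstance(fit, FitResult) else fit
    sp = model.space
    tips_idx = np.array([sp.index(tip_states[t]) for t in tree.tip_labels])
    P, clado, D, M, prior = _pruning_tables(tree, tips_idx, model, root_prior, conditioning)
    uni = _Uniformizer(model)
    rng = np.random.default_rng(seed)
    n_states = sp.n_states
    histories = []
    for _ in range(n_maps):
        node_states = np.full(tree.n_nodes, -1, dtype=int)
        daughter_starts = np.full((tree.n_nodes, 2), -1, dtype=int)
        clado_types: list = [None] * tree.n_nodes
        branch_events: list = [[] for _ in range(tree.n_nodes)]
        root = tree.root
        w = prior * D[root]
        node_states[root] = int(rng.choice(n_states, p=w / w.sum()))
        stack = [root]
        while stack:
            v = stack.pop()
            if v < tree.n_tips:
                continue
            x = node_states[v]
            pairs, probs, types = clado[x]
            c0, c1 = tree.children[v]
            wk = probs * M[c0][pairs[:, 0]] * M[c1][pairs[:, 1]]
            k = int(rng.choice(len(wk), p=wk / wk.sum()))
            daughter_starts[v] = pairs[k]
            clado_types[v] = types[k]
            for slot, c in enumerate((c0, c1)):
                y = int(pairs[k, slot])
                if c < tree.n_tips:
                    xc = tips_idx[c]
                else:
                    wv = P[c][y, :] * D[c]
                    xc = int(rng.choice(n_states, p=wv / wv.sum()))
                node_states[c] = xc
                t = float(tree.blen[c])
                try:
                    path = uni.sample_path(y, xc, t, rng)
                except RuntimeError:
                    path = uni.sample_path_rejection(y, xc, t, rng)
                top_age = float(tree.ages[v])
                branch_events[c] = [(top_age - u, s0, s1) for u, s0, s1 in path]
                stack.append(c)
        histories.append(History(node_states, daughter_starts, clado_types, branch_events))
    return StochasticMapSet(tree, model, histories)


# ----------------------------------------------------------------------
# event extraction
# ----------------------------------------------------------------------

def extract_events(maps: StochasticMapSet) -> pd.DataFrame:
    """Typed event table: (map, event, age, source, dest, node).

    Dispersal rows carry the single source area and gained area; local
    extinctions the lost area; within-region cladogenesis one row per
    region shared by both daughters; founder rows the parent range and
    the jump area.
    """
    sp = maps.model.space
    labels = sp.labels
    states = sp.states
    rows = []
    for mi, hist in enumerate(maps.histories):
        for v in range(maps.tree.n_nodes):
            for age, s_from, s_to in hist.branch_events[v]:
                f, t = states[s_from], states[s_to]
                if len(t) > len(f):
                    (gained,) = t - f
                    (src,) = f
                    rows.append((mi, "dispersal", age, src, gained, v))
                elif len(t) < len(f):
                    (lost,) = f - t
                    rows.append((mi, "extinction", age, lost, lost, v))
        for v in range(maps.tree.n_tips, maps.tree.n_nodes):
            typ = hist.clado_types[v]
            if typ is None:
                continue
            age = float(maps.tree.ages[v])
            parent = states[hist.node_states[v]]
            dl = states[hist.daughter_starts[v][0]]
            dr = states[hist.daughter_starts[v][1]]
            if typ in WITHIN_TYPES:
                for region in sorted(dl & dr, key=sp.areas.index):
                    rows.append((mi, "cladogenesis", age, region, region, v))
            elif typ == "vicariance":
                rows.append((mi, "vicariance", age, labels[hist.node_states[v]], "", v))
            elif typ == "founder":
                jump = dl if (len(dl) == 1 and not dl <= parent) else dr
                (dest,) = jump
                rows.append((mi, "founder", age, labels[hist.node_states[v]], dest, v))
    return pd.DataFrame(rows, columns=["map", "event", "age", "source", "dest", "node"])


# ----------------------------------------------------------------------
# lineage counting and rate series
# ----------------------------------------------------------------------

def _region_mask(space, region: str) -> np.ndarray:
    return np.array([region in s for s in space.states])


def lineage_counts_per_map(maps: StochasticMapSet, region: str, ages: np.ndarray) -> np.ndarray:
    """(n_maps, n_ages) lineages whose range includes ``region`` at each age."""
    tree = maps.tree
    has = _region_mask(maps.model.space, region)
    out = np.zeros((maps.n_maps, len(ages)))
    for mi, hist in enumerate(maps.histories):
        for v in range(tree.n_nodes):
            if tree.parent[v] < 0:
                continue
            for hi, lo, s in maps.branch_segments(hist, v):
                if not has[s]:
                    continue
                sel = (ages <= hi) & (ages > lo)
                out[mi, sel] += 1
    return out


def lineage_counts(maps: StochasticMapSet, region: str, bin_starts: np.ndarray,
                   width: float = 2.0) -> np.ndarray:
    """Median (across maps) lineage count at each bin's older boundary."""
    ages = np.asarray(bin_starts, float) + width
    return np.median(lineage_counts_per_map(maps, region, ages), axis=0)


@dataclass
class RateSeries:
    """Per-bin rates with across-map spread.

    ``per_map`` is (n_maps, n_bins) with NaN in masked bins; ``point`` is
    the ratio-of-medians estimate (median event count over maps divided
    by the median lineage count of the normalizing region in the
    previous, older bin).
    """

    bin_starts: np.ndarray
    width: float
    per_map: np.ndarray
    point: np.ndarray
    region: str = ""
    label: str = ""

    @property
    def bin_ends(self) -> np.ndarray:
        return self.bin_starts + self.width

    @property
    def median(self) -> np.ndarray:
        return _nanquantile(self.per_map, 0.5)

    @property
    def q10(self) -> np.ndarray:
        return _nanquantile(self.per_map, 0.10)

    @property
    def q90(self) -> np.ndarray:
        return _nanquantile(self.per_map, 0.90)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "series": self.label, "region": self.region,
            "bin_start": self.bin_starts, "bin_end": self.bin_ends,
            "point": self.point, "median": self.median,
            "q10": self.q10, "q90": self.q90,
            "n_maps": self.per_map.shape[0],
        })


def _nanquantile(a: np.ndarray, q: float) -> np.ndarray:
    out = np.full(a.shape[1], np.nan)
    for j in range(a.shape[1]):
        col = a[:, j]
        col = col[~np.isnan(col)]
        if len(col):
            out[j] = np.quantile(col, q)
    return out


def _bin_counts(events: pd.DataFrame, n_maps: int, bin_starts: np.ndarray, width: float) -> np.ndarray:
    counts = np.zeros((n_maps, len(bin_starts)))
    if len(events):
        for mi, grp in events.groupby("map"):
            idx = np.floor((grp["age"].to_numpy() - bin_starts[0]) / width).astype(int)
            ok = (grp["age"].to_numpy() >= bin_starts[0]) & (idx < len(bin_starts))
            for i in idx[ok]:
                counts[mi, i] += 1
    return counts


def dispersal_rate_series(
    maps: StochasticMapSet,
    events: pd.DataFrame,
    source: str,
    dest: str,
    bin_starts: np.ndarray | None = None,
    width: float = 2.0,
    normalize_by: str = "destination",
    min_lineages: int = 10,
) -> RateSeries:
    """Directed dispersal rates per 2-Ma bin.

    Rate in bin [t, t+w) = event count divided by the lineage count of
    the normalizing region (destination by default) in the previous,
    older bin [t+w, t+2w).  Bins whose median denominator is below
    ``min_lineages`` are masked (NaN), not zero-filled.
    """
    if source == dest:
        raise ValueError("dispersal direction must have source != destination")
    if bin_starts is None:
        bin_starts = default_bins(width=width)
    bin_starts = np.asarray(bin_starts, float)
    norm_region = dest if normalize_by == "destination" else source
    sel = events[(events["event"] == "dispersal")
                 & (events["source"] == source) & (events["dest"] == dest)]
    counts = _bin_counts(sel, maps.n_maps, bin_starts, width)
    denom_ages = bin_starts + 2 * width  # older boundary of the previous bin
    denom = lineage_counts_per_map(maps, norm_region, denom_ages)
    denom_med = np.median(denom, axis=0)
    per_map = np.where(denom > 0, counts / np.maximum(denom, 1e-300), np.nan)
    med_counts = np.median(counts, axis=0)
    point = np.where(denom_med > 0, med_counts / np.maximum(denom_med, 1e-300), np.nan)
    mask = denom_med < min_lineages
    per_map[:, mask] = np.nan
    point[mask] = np.nan
    return RateSeries(bin_starts, width, per_map, point,
                      region=norm_region, label=f"dispersal {source}->{dest}")


def cladogenesis_rate_series(
    maps: StochasticMapSet,
    region: str,
    branch_rates: np.ndarray | None = None,
    bin_starts: np.ndarray | None = None,
    width: float = 2.0,
    estimator: str = "branch_rates",
    events: pd.DataFrame | None = None,
    min_lineages: int = 10,
) -> RateSeries:
    """In situ cladogenesis rates per bin for one region.

    ``estimator='branch_rates'`` (default): per bin and map, the
    time-weighted mean of per-branch speciation rates over branch
    segments occupying the region that overlap the bin (segments are
    split at bin boundaries).  ``estimator='event_counts'``: within-region
    cladogenetic event count divided by the lineage count in the
    previous older bin, mirroring the dispersal series.
    """
    if bin_starts is None:
        bin_starts = default_bins(width=width)
    bin_starts = np.asarray(bin_starts, float)
    tree = maps.tree
    has = _region_mask(maps.model.space, region)
    denom_ages = bin_starts + 2 * width
    denom = lineage_counts_per_map(maps, region, denom_ages)
    denom_med = np.median(denom, axis=0)

    if estimator == "event_counts":
        if events is None:
            events = extract_events(maps)
        sel = events[(events["event"] == "cladogenesis") & (events["source"] == region)]
        counts = _bin_counts(sel, maps.n_maps, bin_starts, width)
        per_map = np.where(denom > 0, counts / np.maximum(denom, 1e-300), np.nan)
        point = np.where(denom_med > 0,
                         np.median(counts, axis=0) / np.maximum(denom_med, 1e-300), np.nan)
    elif estimator == "branch_rates":
        if branch_rates is None:
            raise ValueError("branch_rates required for the branch-rate estimator")
        rates = np.asarray(branch_rates, float)
        wsum = np.zeros((maps.n_maps, len(bin_starts)))
        tsum = np.zeros((maps.n_maps, len(bin_starts)))
        for mi, hist in enumerate(maps.histories):
            for v in range(tree.n_nodes):
                if tree.parent[v] < 0:
                    continue
                for hi, lo, s in maps.branch_segments(hist, v):
                    if not has[s]:
                        continue
                    over_lo = np.maximum(lo, bin_starts)
                    over_hi = np.minimum(hi, bin_starts + width)
                    dt = np.clip(over_hi - over_lo, 0.0, None)
                    wsum[mi] += rates[v] * dt
                    tsum[mi] += dt
        per_map = np.where(tsum > 0, wsum / np.maximum(tsum, 1e-300), np.nan)
        med_w = np.median(wsum, axis=0)
        med_t = np.median(tsum, axis=0)
        point = np.where(med_t > 0, med_w / np.maximum(med_t, 1e-300), np.nan)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    mask = denom_med < min_lineages
    if np.all(np.isnan(per_map)):
        import warnings
        warnings.warn(f"no branches assigned to region {region!r} in any bin")
    per_map[:, mask] = np.nan
    point[mask] = np.nan
    return RateSeries(bin_starts, width, per_map, point,
                      region=region, label=f"cladogenesis {region} ({estimator})")


@dataclass
class StandardizedDifference:
    bin_starts: np.ndarray
    width: float
    per_map: np.ndarray          # (n_maps, n_bins), (a-b)/pooled SD
    median: np.ndarray
    q10: np.ndarray
    q90: np.ndarray
    aggregate: tuple[float, float, float]  # window-wide median, q10, q90
    pooled_sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start": self.bin_starts, "bin_end": self.bin_starts + self.width,
            "delta_median": self.median, "q10": self.q10, "q90": self.q90,
        })


def standardized_difference(a: RateSeries, b: RateSeries) -> StandardizedDifference:
    """Per-bin (a - b) / pooled SD with across-map 10-90% intervals.

    The pooled SD is taken over all non-masked per-map rate values of
    both series (all bins, both regions), so Δ is comparable across
    realms.  The aggregate Δ is each map's mean over defined bins,
    summarized across maps.
    """
    if not np.array_equal(a.bin_starts, b.bin_starts):
        raise ValueError("rate series have mismatched bins")
    pooled = np.concatenate([a.per_map.ravel(), b.per_map.ravel()])
    pooled = pooled[~np.isnan(pooled)]
    sd = float(np.std(pooled)) if len(pooled) else 0.0
    if sd == 0.0:
        raise ValueError("pooled SD is zero; standardized difference undefined")
    diff = (a.per_map - b.per_map) / sd
    agg_map = np.array([
        np.nanmean(row) if np.any(~np.isnan(row)) else np.nan for row in diff
    ])
    agg_map = agg_map[~np.isnan(agg_map)]
    if len(agg_map) == 0:
        agg = (np.nan, np.nan, np.nan)
    else:
        agg = tuple(float(np.quantile(agg_map, q)) for q in (0.5, 0.10, 0.90))
    return StandardizedDifference(
        a.bin_starts, a.width, diff,
        _nanquantile(diff, 0.5), _nanquantile(diff, 0.10), _nanquantile(diff, 0.90),
        agg, sd,
    )


def colonization_age(maps: StochasticMapSet, region: str) -> float:
    """Median (across maps) age of first occupancy of ``region`` in Ma.

    Per map: the root age when the root range includes the region,
    otherwise the oldest start of any branch segment occupying it.
    """
    tree = maps.tree
    has = _region_mask(maps.model.space, region)
    ages = []
    for hist in maps.histories:
        if has[hist.node_states[tree.root]]:
            ages.append(tree.root_age)
            continue
        oldest = None
        for v in range(tree.n_nodes):
            if tree.parent[v] < 0:
                continue
            for hi, lo, s in maps.branch_segments(hist, v):
                if has[s]:
                    oldest = hi if oldest is None else max(oldest, hi)
        if oldest is not None:
            ages.append(oldest)
    if not ages:
        raise ValueError(f"region {region!r} never occupied in any map")
    return float(np.median(ages))
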