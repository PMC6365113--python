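"""Tip-level diversification statistics and hotspot residual contrasts.

The DR statistic is the inverse of the equal-splits measure: walking from
a tip toward the root, the j-th edge on the path contributes its length
times 2^-(j-1).  High DR marks recently, rapidly diversifying lineages;
low DR marks phylogenetically isolated "ancient" lineages.  Species are
split into DR quartiles; per-cell quartile richness is regressed on total
richness, and the residuals contrast hotspot against non-hotspot cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .hotspots import OccurrenceGrid, RegionPartition, species_richness
from .sar import SARFit, SpatialWeights, fit_sar_error
from .trees import IndexedTree

__all__ = [
    "compute_dr",
    "assign_quartiles",
    "quartile_residuals",
    "branch_rates_from_dr",
    "hotspot_contrast",
    "HLContrast",
    "SpatialWeights",
    "fit_sar_error",
    "SARFit",
]


def compute_dr(tree: IndexedTree) -> pd.Series:
    """Inverse equal-splits diversification rate per tip (events / Ma).

    ES(tip) = sum_j l_j 2^-(j-1) along the tip-to-root path (edge 1 is the
    terminal edge); DR = 1 / ES.
    """
    dr = np.empty(tree.n_tips)
    for tip in range(tree.n_tips):
        es = 0.0
        w = 1.0
        v = tip
        while tree.parent[v] >= 0:
            es += tree.blen[v] * w
            w *= 0.5
            v = tree.parent[v]
        if es <= 0:
            raise ValueError(f"degenerate zero-length root path for tip {tree.tip_labels[tip]}")
        dr[tip] = 1.0 / es
    return pd.Series(dr, index=tree.tip_labels, name="DR")


def assign_quartiles(dr: pd.Series) -> pd.Series:
    """Quartile membership 1..4 by ascending DR (Q1 ancient, Q4 recent).

    Ties are broken by species name; group sizes differ by at most one,
    with remainders assigned to the lower quartiles first.
    """
    if len(dr) < 4:
        raise ValueError("need >= 4 species for quartiles")
    if dr.nunique() == 1:
        warnings.warn("all DR values equal; quartile split is by name only")
    order = dr.reset_index()
    order.columns = ["species", "dr"]
    order = order.sort_values(["dr", "species"], kind="mergesort")
    n = len(order)
    base, extra = divmod(n, 4)
    sizes = [base + (1 if q < extra else 0) for q in range(4)]
    labels = np.repeat([1, 2, 3, 4], sizes)
    return pd.Series(labels, index=order["species"].values, name="quartile").sort_index()


@dataclass
class QuartileResiduals:
    """Per-cell OLS residuals of Q1 and Q4 richness on total richness."""

    table: pd.DataFrame  # cell_id, realm, sr, q1_richness, q4_richness, q1_resid, q4_resid

    def residuals(self, quartile: int) -> pd.Series:
        col = {1: "q1_resid", 4: "q4_resid"}[quartile]
        return self.table.set_index("cell_id")[col]


def _quartile_sr(occ: OccurrenceGrid, quartiles: pd.Series, q: int) -> pd.Series:
    members = set(quartiles.index[quartiles == q])
    sub = occ.occurrences[occ.occurrences["species"].isin(members)]
    return sub.groupby("cell_id")["species"].nunique()


def quartile_residuals(
    occ: OccurrenceGrid,
    quartiles: pd.Series,
    per_realm: bool = True,
) -> QuartileResiduals:
    """OLS residuals of ancient (Q1) and recent (Q4) richness given total SR.

    A positive Q4 residual marks a cell with an excess of recently
    diversifying species relative to its total richness.  Fits are run
    within each realm by default (``per_realm=False`` fits globally).
    """
    occ_tree = occ.subset_species(set(quartiles.index))
    sr = species_richness(occ_tree)
    if sr.nunique() == 1:
        raise ValueError("total SR is constant across cells; regression undefined")
    q1 = _quartile_sr(occ_tree, quartiles, 1).reindex(sr.index, fill_value=0)
    q4 = _quartile_sr(occ_tree, quartiles, 4).reindex(sr.index, fill_value=0)
    realms = occ.cell_realms().reindex(sr.index)
    df = pd.DataFrame({
        "cell_id": sr.index, "realm": realms.values,
        "sr": sr.values, "q1_richness": q1.values, "q4_richness": q4.values,
    })
    groups = df.groupby("realm") if per_realm else [("all", df)]
    out = []
    for name, g in groups:
        g = g.copy()
        if g["sr"].nunique() == 1 or len(g) < 3:
            warnings.warn(f"realm {name!r}: SR constant or < 3 occupied cells; "
                          "residuals undefined, cells dropped")
            continue
        X = sm.add_constant(g["sr"].to_numpy(dtype=float))
        for col, res_col in (("q1_richness", "q1_resid"), ("q4_richness", "q4_resid")):
            fit = sm.OLS(g[col].to_numpy(dtype=float), X).fit()
            g[res_col] = fit.resid
        out.append(g)
    if not out:
        raise ValueError("SR is constant in every realm; regression undefined")
    return QuartileResiduals(pd.concat(out, ignore_index=True))


def branch_rates_from_dr(tree: IndexedTree, dr: pd.Series | None = None) -> np.ndarray:
    """Per-branch speciation-rate proxy: mean tip DR over descendant tips.

    This is the default branch-rate provider for the cladogenesis rate
    series; externally estimated per-branch rates (e.g. from a Bayesian
    rate-shift mixture model) can be substituted via a CSV keyed the same
    way (node index order of the tree).
    """
    if dr is None:
        dr = compute_dr(tree)
    tipvals = dr.reindex(tree.tip_labels).to_numpy()
    rates = np.empty(tree.n_nodes)
    for v, tips in enumerate(tree.tips_below()):
        rates[v] = tipvals[tips].mean()
    return rates


@dataclass
class HLContrast:
    """Hodges-Lehmann hotspot minus non-hotspot location contrast."""

    estimate: float
    ci_low: float
    ci_high: float
    statistic: float
    pvalue: float
    n_hot: int
    n_non: int


def hotspot_contrast(
    values: pd.Series,
    partition: RegionPartition,
    alpha: float = 0.05,
    max_pairs: int = 1_000_000,
    seed: int = 0,
) -> HLContrast:
    """Hodges-Lehmann shift estimate with a rank-sum confidence interval.

    The estimate is the median of all pairwise (hotspot - non-hotspot)
    differences; the CI inverts the Wilcoxon rank-sum test at level
    ``alpha`` using the normal approximation to the critical count.  When
    the pair count exceeds ``max_pairs`` the pair set is subsampled with a
    fixed seed.
    """
    klass = partition.klass_of()
    common = values.index.intersection(klass.index)
    hot = values.loc[[c for c in common if klass[c] == "hotspot"]].to_numpy(dtype=float)
    non = values.loc[[c for c in common if klass[c] == "non-hotspot"]].to_numpy(dtype=float)
    if len(hot) < 2 or len(non) < 2:
        raise ValueError("need >= 2 cells in each class")
    m, n = len(hot), len(non)
    if m * n <= max_pairs:
        diffs = np.sort((hot[:, None] - non[None, :]).ravel())
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, m, size=max_pairs)
        j = rng.integers(0, n, size=max_pairs)
        diffs = np.sort(hot[i] - non[j])
    hl = float(np.median(diffs))
    # critical count for the Mann-Whitney U at level alpha (normal approx.)
    z = stats.norm.ppf(1 - alpha / 2)
    mu = m * n / 2.0
    sd = np.sqrt(m * n * (m + n + 1) / 12.0)
    k = int(np.floor(mu - z * sd))
    k = max(k, 0)
    npairs = len(diffs)
    lo = diffs[min(k, npairs - 1)]
    hi = diffs[max(npairs - 1 - k, 0)]
    res = stats.mannwhitneyu(hot, non, alternative="two-sided")
    return HLContrast(hl, float(lo), float(hi), float(res.statistic), float(res.pvalue), m, n)
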