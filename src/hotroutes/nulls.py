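"""Size/shape controls for hotspots: cluster point-process nulls.

The observed hotspot cell centres in a realm are treated as a point
pattern; a Thomas cluster process (Poisson parents, Poisson offspring
counts, isotropic Gaussian offspring displacement) is fitted by minimum
contrast on Ripley's K, which has the closed form
K(r) = pi r^2 + (1/kappa)(1 - exp(-r^2 / (4 sigma^2))).
Simulating the fitted process, snapping to the grid and repairing the
cell count yields "control" hotspot sets of the same size and similar
spatial structure; any statistic computed on the real hotspots can then
be ranked inside its control distribution (two-sided 90% envelope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial import cKDTree

from .hotspots import RegionPartition

__all__ = [
    "ripley_k",
    "ClusterProcessFit",
    "fit_cluster_process",
    "simulate_thomas",
    "simulate_controls",
    "null_envelope",
    "contiguity",
]


def ripley_k(points: np.ndarray, window: tuple[float, float, float, float],
             r: np.ndarray) -> np.ndarray:
    """Ripley's K with translation edge correction on a rectangle.

    ``window`` is (x0, x1, y0, y1); ``points`` is (n, 2) in the same
    units as ``r``.
    """
    x0, x1, y0, y1 = window
    a, b = x1 - x0, y1 - y0
    area = a * b
    n = len(points)
    if n < 2:
        return np.zeros_like(r)
    dx = np.abs(points[:, 0][:, None] - points[:, 0][None, :])
    dy = np.abs(points[:, 1][:, None] - points[:, 1][None, :])
    d = np.hypot(dx, dy)
    iu = np.triu_indices(n, k=1)
    d, dx, dy = d[iu], dx[iu], dy[iu]
    w = area / ((a - dx) * (b - dy))  # translation correction, pairs counted twice
    lam = n / area
    out = np.empty_like(r, dtype=float)
    order = np.argsort(d)
    d_sorted = d[order]
    w_cum = np.concatenate([[0.0], np.cumsum(w[order])])
    idx = np.searchsorted(d_sorted, r, side="right")
    out = 2.0 * w_cum[idx] / (lam * lam * area)
    return out


def thomas_k(r: np.ndarray, kappa: float, sigma: float) -> np.ndarray:
    return np.pi * r ** 2 + (1.0 - np.exp(-(r ** 2) / (4.0 * sigma ** 2))) / kappa


@dataclass
class ClusterProcessFit:
    kappa: float              # parents per unit area
    sigma: float              # cluster scale (same units as coordinates)
    mu: float                 # mean offspring per parent
    window: tuple[float, float, float, float]
    n_points: int
    contrast: float
    weak_clustering: bool     # sigma ran to its upper bound (Poisson-like)


def fit_cluster_process(points: np.ndarray,
                        window: tuple[float, float, float, float],
                        r_max: float | None = None) -> ClusterProcessFit:
    """Minimum-contrast Thomas fit: min over (kappa, sigma) of
    integral of (K_hat^0.25 - K_model^0.25)^2, with mu set from the
    observed intensity.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 30:
        raise ValueError("need >= 30 points to fit a cluster process")
    x0, x1, y0, y1 = window
    side = min(x1 - x0, y1 - y0)
    if r_max is None:
        r_max = side / 4.0
    r = np.linspace(side / 200.0, r_max, 100)
    k_hat = ripley_k(points, window, r) ** 0.25
    area = (x1 - x0) * (y1 - y0)
    lam = len(points) / area
    sigma_hi = side  # beyond this clustering is indistinguishable from Poisson

    def contrast(theta):
        kappa, sigma = np.exp(theta)
        return float(np.sum((k_hat - thomas_k(r, kappa, sigma) ** 0.25) ** 2))

    # parents cannot be denser than the points themselves, nor arbitrarily
    # sparse; sigma beyond the window is unidentifiable from K
    bounds = [(np.log(lam / 1e4), np.log(5 * lam)),
              (np.log(side / 1000.0), np.log(sigma_hi))]
    best = None
    for k0, s0 in [(lam / 5, r_max / 8), (lam / 20, r_max / 3), (lam / 2, r_max / 20)]:
        res = optimize.minimize(
            contrast, np.log([k0, s0]), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("cluster-process minimum contrast did not converge; "
                           f"K curve: {list(zip(r[::20], k_hat[::20]**4))}")
    kappa, sigma = np.exp(best.x)
    weak = sigma >= sigma_hi * 0.99 or kappa >= 5 * lam * 0.99
    mu = lam / kappa
    return ClusterProcessFit(float(kappa), float(sigma), float(mu), window,
                             len(points), float(best.fun), bool(weak))


def simulate_thomas(fit: ClusterProcessFit, seed: int,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """One realization of the fitted Thomas process inside its window."""
    rng = rng or np.random.default_rng(seed)
    x0, x1, y0, y1 = fit.window
    pad = 4.0 * fit.sigma
    ex0, ex1, ey0, ey1 = x0 - pad, x1 + pad, y0 - pad, y1 + pad
    n_par = rng.poisson(fit.kappa * (ex1 - ex0) * (ey1 - ey0))
    pts = []
    for _ in range(n_par):
        px = rng.uniform(ex0, ex1)
        py = rng.uniform(ey0, ey1)
        n_off = rng.poisson(fit.mu)
        if n_off:
            off = rng.normal(0.0, fit.sigma, size=(n_off, 2)) + (px, py)
            pts.append(off)
    if not pts:
        return np.empty((0, 2))
    pts = np.concatenate(pts)
    keep = (pts[:, 0] >= x0) & (pts[:, 0] <= x1) & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
    return pts[keep]


def simulate_controls(
    fit: ClusterProcessFit,
    cells: pd.DataFrame,
    n_cells: int,
    n_sets: int = 50,
    seed: int = 0,
    realm: str | None = None,
) -> list[RegionPartition]:
    """Control hotspot sets with exactly ``n_cells`` hotspot cells each.

    Simulated points are snapped to the nearest grid cell and
    deduplicated; the set is then repaired to the exact count by
    nearest-neighbour accretion (add the unused cell closest to the
    current set) or farthest-point trimming (drop the cell farthest from
    the rest of the set).  Deterministic in the seed.
    """
    pool = cells if realm is None else cells[cells["realm"] == realm]
    if n_cells > len(pool):
        raise ValueError(f"window holds {len(pool)} cells < requested {n_cells}")
    xy = pool[["x", "y"]].to_numpy(dtype=float)
    ids = pool["cell_id"].to_numpy()
    tree = cKDTree(xy)
    rng = np.random.default_rng(seed)
    out = []
    for si in range(n_sets):
        pts = simulate_thomas(fit, seed=0, rng=rng)
        if len(pts):
            snapped = np.unique(tree.query(pts)[1])
        else:
            snapped = np.array([], dtype=int)
        chosen = set(snapped.tolist())
        if not chosen:
            chosen = {int(rng.integers(len(ids)))}
        while len(chosen) < n_cells:
            sel = np.fromiter(chosen, int)
            rest = np.setdiff1d(np.arange(len(ids)), sel)
            dmin = cKDTree(xy[sel]).query(xy[rest])[0]
            chosen.add(int(rest[np.argmin(dmin)]))
        while len(chosen) > n_cells:
            sel = np.fromiter(sorted(chosen), int)
            d2 = cKDTree(xy[sel]).query(xy[sel], k=2)[0][:, 1]
            chosen.discard(int(sel[np.argmax(d2)]))
        hot = set(ids[sorted(chosen)])
        table = pd.DataFrame({
            "cell_id": cells["cell_id"].values,
            "klass": np.where(cells["cell_id"].isin(hot), "hotspot", "non-hotspot"),
            "realm": cells["realm"].values if "realm" in cells else "all",
        })
        out.append(RegionPartition(table, clade="control", metric=f"thomas-{si}"))
    return out


def null_envelope(real_value: float, control_values) -> tuple[float, bool]:
    """Empirical quantile rank of the real statistic among the controls.

    Flagged (outside the two-sided 90% envelope) when the rank is below
    0.05 or above 0.95.  Ties get half weight.
    """
    ctl = np.asarray(list(control_values), dtype=float)
    if len(ctl) < 20:
        raise ValueError("need >= 20 control values")
    if np.ptp(ctl) == 0:
        raise ValueError("control distribution is constant")
    rank = (np.sum(ctl < real_value) + 0.5 * np.sum(ctl == real_value)) / len(ctl)
    return float(rank), bool(rank < 0.05 or rank > 0.95)


@dataclass
class ContiguityResult:
    mean_hotspot: float        # mean of per-cell median same-class distance, km
    mean_non_hotspot: float
    t_statistic: float
    pvalue: float
    n_isolated: int            # cells with no same-class neighbour in radius


def contiguity(partition: RegionPartition, coords: pd.DataFrame,
               cell_km: float = 100.0, radius_km: float = 1000.0) -> ContiguityResult:
    """Same-class spatial contiguity: per-cell median distance to
    same-class cells within ``radius_km``, class means compared by
    Welch's t test.  Isolated cells are excluded and counted.
    """
    klass = partition.klass_of()
    vals = {"hotspot": [], "non-hotspot": []}
    n_iso = 0
    xy_all = coords.loc[klass.index, ["x", "y"]].to_numpy(dtype=float) * cell_km
    karr = klass.to_numpy()
    for cls in vals:
        sel = karr == cls
        pts = xy_all[sel]
        if len(pts) < 2:
            raise ValueError(f"class {cls!r} has < 2 cells")
        tree = cKDTree(pts)
        for i, p in enumerate(pts):
            nbrs = [j for j in tree.query_ball_point(p, radius_km) if j != i]
            if not nbrs:
                n_iso += 1
                continue
            d = np.hypot(*(pts[nbrs] - p).T)
            vals[cls].append(np.median(d))
    hot, non = np.asarray(vals["hotspot"]), np.asarray(vals["non-hotspot"])
    t, p = stats.ttest_ind(hot, non, equal_var=False)
    return ContiguityResult(float(hot.mean()), float(non.mean()), float(t), float(p), n_iso)
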