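"""Environmental predictors and standardized hotspot contrasts.

Implements the raster-derived predictors used to compare hotspot and
non-hotspot cells — terrain ruggedness (TRI), climate-change velocity
(temporal change rate over local spatial gradient) and tectonic
movement (spread of inter-neighbour distances through time) — and the
per-variable spatially autoregressive contrast with Bonferroni-corrected
significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hotspots import RegionPartition
from .sar import SpatialWeights, fit_sar_error

__all__ = [
    "terrain_ruggedness",
    "climate_velocity",
    "tectonic_movement",
    "correlation_screen",
    "env_sar_contrast",
]


def terrain_ruggedness(elevation: np.ndarray, cell_factor: int = 1) -> np.ndarray:
    """TRI per cell from a (possibly finer) elevation grid.

    Per pixel: mean |elevation difference| to the up-to-8 neighbours
    (border pixels use the neighbours that exist).  With
    ``cell_factor`` > 1 the pixel grid is ``cell_factor`` times finer
    than the cell grid and pixel TRIs are averaged per cell block.
    Invariant to adding a constant to all elevations.
    """
    z = np.asarray(elevation, dtype=float)
    if z.ndim != 2 or min(z.shape) < 2:
        raise ValueError("elevation grid must be 2-D with at least 2 pixels per side")
    nx, ny = z.shape
    total = np.zeros_like(z)
    count = np.zeros_like(z)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            sx = slice(max(dx, 0), nx + min(dx, 0))
            sy = slice(max(dy, 0), ny + min(dy, 0))
            tx = slice(max(-dx, 0), nx + min(-dx, 0))
            ty = slice(max(-dy, 0), ny + min(-dy, 0))
            total[tx, ty] += np.abs(z[sx, sy] - z[tx, ty])
            count[tx, ty] += 1
    tri = total / count
    if cell_factor == 1:
        return tri
    cx, cy = nx // cell_factor, ny // cell_factor
    return tri[: cx * cell_factor, : cy * cell_factor].reshape(
        cx, cell_factor, cy, cell_factor
    ).mean(axis=(1, 3))


def climate_velocity(
    present: np.ndarray,
    past: np.ndarray,
    elapsed: float,
    pixel_km: float = 100.0,
    gradient_floor: float | None = None,
) -> np.ndarray:
    """Climate-change velocity: temporal gradient / spatial gradient.

    Temporal gradient = |present - past| / elapsed; spatial gradient =
    magnitude of the central-difference slope of the present layer (per
    km).  Gradients below ``gradient_floor`` (default: 1st percentile of
    positive gradients) are clamped, since velocity diverges over flat
    terrain.
    """
    p = np.asarray(present, dtype=float)
    q = np.asarray(past, dtype=float)
    if p.shape != q.shape:
        raise ValueError("present and past layers must have the same shape")
    if elapsed <= 0:
        raise ValueError("elapsed time must be positive")
    temporal = np.abs(p - q) / elapsed
    gx, gy = np.gradient(p, pixel_km)
    grad = np.hypot(gx, gy)
    pos = grad[grad > 0]
    if len(pos) == 0:
        raise ValueError("present layer has zero spatial gradient everywhere; "
                         "set gradient_floor explicitly")
    if gradient_floor is None:
        gradient_floor = float(np.percentile(pos, 1))
    return temporal / np.maximum(grad, gradient_floor)


def tectonic_movement(trajectories: np.ndarray, neighbors: list[np.ndarray]) -> np.ndarray:
    """Per-cell pooled SD of inter-neighbour distance series through time.

    ``trajectories`` is (n_cells, n_times, 2) positions (km);
    ``neighbors[i]`` lists neighbour indices of cell i.  For each
    neighbour the distance series over time is centred on its own mean;
    the cell value pools the squared deviations over all neighbours with
    an (n - 1)-per-series denominator.  Zero for rigid motion.
    """
    traj = np.asarray(trajectories, dtype=float)
    if traj.ndim != 3 or traj.shape[2] != 2:
        raise ValueError("trajectories must be (n_cells, n_times, 2)")
    n_cells, n_times, _ = traj.shape
    if n_times < 2:
        raise ValueError("need >= 2 time points")
    out = np.zeros(n_cells)
    for i in range(n_cells):
        nbrs = np.asarray(neighbors[i], dtype=int)
        if len(nbrs) == 0:
            out[i] = np.nan
            continue
        d = np.linalg.norm(traj[nbrs] - traj[i][None, :, :], axis=2)  # (k, n_times)
        dev = d - d.mean(axis=1, keepdims=True)
        out[i] = np.sqrt(np.sum(dev ** 2) / (len(nbrs) * (n_times - 1)))
    return out


def correlation_screen(env: pd.DataFrame, rho_max: float = 0.70) -> list[str]:
    """Drop later-listed variables Spearman-correlated above ``rho_max``.

    ``env`` is wide (cells x variables, in column order); returns the
    variables kept.
    """
    cols = list(env.columns)
    corr = env.corr(method="spearman").abs()
    kept: list[str] = []
    for c in cols:
        if all(corr.loc[c, k] <= rho_max for k in kept):
            kept.append(c)
    return kept


@dataclass
class EnvContrast:
    table: pd.DataFrame   # variable, beta, se, lambda, p_raw, p_bonferroni, significant
    dropped: list[str]
    scaling: pd.DataFrame  # variable, mean, sd used for standardization


def env_sar_contrast(
    env: pd.DataFrame,
    partition: RegionPartition,
    weights: SpatialWeights,
    alpha: float = 0.05,
    rho_max: float = 0.70,
    screen: bool = True,
) -> EnvContrast:
    """Standardized hotspot-vs-non-hotspot SAR contrast per variable.

    ``env`` is long (cell_id, variable, value).  Each variable is centred
    and scaled to unit SD, then regressed on the hotspot indicator under
    the SAR error model on ``weights``; p-values are Bonferroni-corrected
    over the variables tested.  Zero-variance variables are skipped with
    a warning; a correlation screen mirrors the practice of removing
    near-collinear variables before testing.
    """
    wide = env.pivot_table(index="cell_id", columns="variable", values="value", sort=False)
    wide = wide.loc[[c for c in weights.cell_ids if c in wide.index]]
    if list(wide.index) != list(weights.cell_ids):
        raise ValueError("environment table does not cover the weights' cells")
    klass = partition.klass_of().reindex(wide.index)
    hot = (klass == "hotspot").to_numpy(dtype=float)
    if hot.sum() < 2 or (1 - hot).sum() < 2:
        raise ValueError("need >= 2 cells per class")
    dropped = []
    import warnings as _warnings
    for col in list(wide.columns):
        if wide[col].std(ddof=0) == 0:
            _warnings.warn(f"variable {col!r} has zero variance; skipped")
            wide = wide.drop(columns=col)
            dropped.append(col)
    keep = correlation_screen(wide, rho_max) if screen else list(wide.columns)
    dropped += [c for c in wide.columns if c not in keep]
    m = len(keep)
    rows, scale_rows = [], []
    for var in keep:
        y = wide[var].to_numpy(dtype=float)
        mu, sd = y.mean(), y.std(ddof=0)
        fit = fit_sar_error((y - mu) / sd, hot, weights, names=["hotspot"])
        p_raw = float(fit.pvalues[1])
        p_bonf = min(1.0, p_raw * m)
        rows.append({
            "variable": var, "beta": float(fit.params[1]), "se": float(fit.bse[1]),
            "lambda": fit.lam, "p_raw": p_raw, "p_bonferroni": p_bonf,
            "significant": p_bonf < alpha,
        })
        scale_rows.append({"variable": var, "mean": mu, "sd": sd})
    return EnvContrast(pd.DataFrame(rows), dropped, pd.DataFrame(scale_rows))
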