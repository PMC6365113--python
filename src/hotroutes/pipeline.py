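"""End-to-end orchestration: simulate -> hotspots -> tip rates ->
biogeography -> stochastic maps -> rate series -> spatial null -> environment.

``run_all`` executes every stage for the focal realm of a simulated (or
loaded) dataset, writes each stage's tables to the run directory and a
manifest with the config hash, seeds and documented assumptions.  Stage
outputs are pure functions of (inputs, config, seed); per-stage seeds
are split deterministically from the master seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biogeo, bsm, environment, hotspots, nulls, simulate, tiprates
from .sar import SpatialWeights

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Thresholds and sizes for one full analysis run."""

    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    hotspot_fraction: float = 0.20
    coding_threshold: float = 0.20
    nrs_max_cells: int = 10
    neighbor_radius_km: float = 1000.0
    bin_width_ma: float = 2.0
    window_ma: tuple[float, float] = (2.0, 26.0)
    n_maps: int = 50
    n_controls: int = 50
    min_lineages: int = 10
    families: tuple[str, ...] = ("DEC", "DIVALIKE", "BAYAREALIKE")
    fit_founder_variants: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_ma[0] >= self.window_ma[1]:
            raise ValueError("window start must be < end")
        for name in ("hotspot_fraction", "coding_threshold", "bin_width_ma",
                     "neighbor_radius_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = json.loads(self.sim.to_json())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim_d = d.pop("sim", {})
        sim_d.pop("dispersal_mult", None)
        sim_d["realm_names"] = tuple(sim_d.get("realm_names", ("west", "focal", "east")))
        d["window_ma"] = tuple(d.get("window_ma", (2.0, 26.0)))
        d["families"] = tuple(d.get("families", ("DEC", "DIVALIKE", "BAYAREALIKE")))
        return cls(sim=simulate.SimConfig(**sim_d), **d)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_all(config: RunConfig, outdir) -> dict:
    """Run every stage; returns a summary dict (also written as manifest)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {"stages": {}}

    # --- simulate ------------------------------------------------------
    sim_cfg = simulate.SimConfig(**{**simulate.SimConfig(**{}).__dict__,
                                    **config.sim.__dict__,
                                    "seed": config.stage_seed("simulate")})
    data = simulate.simulate_dataset(sim_cfg)
    data.write(out / "data")
    summary["stages"]["simulate"] = {
        "n_tips": data.tree.n_tips, "root_age": data.tree.root_age,
        "n_cells": len(data.cells), "n_resim": getattr(data.true_history, "n_resim", 0),
    }

    # --- hotspots ------------------------------------------------------
    we = hotspots.weighted_endemicity(data.occurrences)
    sr = hotspots.species_richness(data.occurrences)
    realms = data.occurrences.cell_realms()
    part_we = hotspots.delineate_top_quantile(we, realms, config.hotspot_fraction, metric="WE")
    part_sr = hotspots.delineate_top_quantile(sr, realms, config.hotspot_fraction, metric="SR")
    part_nrs = hotspots.delineate_nrs(data.occurrences, config.nrs_max_cells)
    pd.DataFrame({"cell_id": we.index, "WE": we.values,
                  "SR": sr.reindex(we.index).values}).to_csv(out / "cell_metrics.csv", index=False)
    part_we.write_csv(out / "partition_we.csv")
    summary["stages"]["hotspots"] = {
        "n_hotspot_we": part_we.n_hotspot,
        "overlap_we_sr_pct": hotspots.partition_overlap(part_we, part_sr),
        "overlap_we_nrs_pct": hotspots.partition_overlap(part_we, part_nrs),
    }

    # --- tip rates -----------------------------------------------------
    dr = tiprates.compute_dr(data.tree)
    quart = tiprates.assign_quartiles(dr)
    resid = tiprates.quartile_residuals(data.occurrences, quart, per_realm=True)
    resid.table.to_csv(out / "quartile_residuals.csv", index=False)
    coords = data.occurrences.cell_coords().loc[resid.table["cell_id"]]
    weights = SpatialWeights.from_coords(coords, config.neighbor_radius_km,
                                         data.occurrences.cell_km)
    contrasts = []
    klass = part_we.klass_of().reindex(resid.table["cell_id"])
    hot_ind = (klass == "hotspot").to_numpy(dtype=float)
    for q, col in ((1, "q1_resid"), (4, "q4_resid")):
        sar_fit = tiprates.fit_sar_error(resid.table[col].to_numpy(), hot_ind,
                                         weights, names=["hotspot"])
        sar_resid = pd.Series(sar_fit.resid_spatial, index=resid.table["cell_id"].values)
        hl = tiprates.hotspot_contrast(resid.table.set_index("cell_id")[col], part_we)
        hl_sar = tiprates.hotspot_contrast(sar_resid, part_we)
        contrasts.append({
            "quartile": f"Q{q}", "sar_beta_hotspot": float(sar_fit.params[1]),
            "sar_lambda": sar_fit.lam,
            "hl_estimate": hl.estimate, "hl_ci_low": hl.ci_low, "hl_ci_high": hl.ci_high,
            "hl_estimate_sar_resid": hl_sar.estimate,
            "n_hot": hl.n_hot, "n_non": hl.n_non,
        })
    pd.DataFrame(contrasts).to_csv(out / "quartile_contrasts.csv", index=False)
    summary["stages"]["tiprates"] = {c["quartile"]: c["hl_estimate"] for c in contrasts}

    # --- biogeography --------------------------------------------------
    realm = sim_cfg.focal_realm
    tip_states, coding_log = biogeo.code_tip_ranges(
        data.occurrences, part_we, realm, config.coding_threshold)
    tree_species = set(data.tree.tip_labels)
    tip_states = tip_states[tip_states.index.isin(tree_species)]
    fits = []
    for fam in config.families:
        variants = (False, True) if config.fit_founder_variants else (False,)
        for founder in variants:
            fits.append(biogeo.fit_model(data.tree, tip_states, fam, founder))
    table = biogeo.model_table(fits)
    table.to_csv(out / "model_table.csv", index=False)
    best = fits[int(np.argmin([f.aicc for f in fits]))]
    summary["stages"]["biogeo"] = {
        "best_model": best.name, "d": best.model.d, "e": best.model.e,
        "j": best.model.j, "lnL": best.loglik, "coding_log": coding_log,
    }

    # --- stochastic maps and rate series ------------------------------
    maps = bsm.sample_maps(data.tree, tip_states, best, n_maps=config.n_maps,
                           seed=config.stage_seed("bsm"))
    events = bsm.extract_events(maps)
    events.to_csv(out / "event_table.csv", index=False)
    bins = np.arange(config.window_ma[0], config.window_ma[1], config.bin_width_ma)
    branch_rates = tiprates.branch_rates_from_dr(data.tree, dr)
    series = {}
    for src, dst in (("N", "H"), ("H", "N")):
        series[f"disp_{src}{dst}"] = bsm.dispersal_rate_series(
            maps, events, src, dst, bins, config.bin_width_ma,
            min_lineages=config.min_lineages)
    for region in ("H", "N"):
        series[f"clado_{region}"] = bsm.cladogenesis_rate_series(
            maps, region, branch_rates, bins, config.bin_width_ma,
            min_lineages=config.min_lineages)
    pd.concat([s.to_frame() for s in series.values()]).to_csv(
        out / "rate_series.csv", index=False)
    delta_clado = bsm.standardized_difference(series["clado_H"], series["clado_N"])
    delta_disp = bsm.standardized_difference(series["disp_NH"], series["disp_HN"])
    pd.concat([
        delta_clado.to_frame().assign(series="clado H-N"),
        delta_disp.to_frame().assign(series="disp NH-HN"),
    ]).to_csv(out / "standardized_differences.csv", index=False)
    col_ages = {r: bsm.colonization_age(maps, r) for r in ("H", "N")}
    summary["stages"]["bsm"] = {
        "n_events": int(len(events)),
        "delta_clado_aggregate": delta_clado.aggregate,
        "delta_disp_aggregate": delta_disp.aggregate,
        "colonization_age": col_ages,
    }

    # --- spatial null --------------------------------------------------
    cells_realm = data.cells[data.cells["realm"] == realm]
    hot_cells = part_we.hotspot_cells & set(cells_realm["cell_id"])
    hot_xy = cells_realm[cells_realm["cell_id"].isin(hot_cells)][["x", "y"]].to_numpy(float)
    null_summary: dict = {"skipped": False}
    if len(hot_xy) >= 30:
        window = (cells_realm["x"].min() - 0.5, cells_realm["x"].max() + 0.5,
                  cells_realm["y"].min() - 0.5, cells_realm["y"].max() + 0.5)
        cp = nulls.fit_cluster_process(hot_xy, window)
        controls = nulls.simulate_controls(cp, cells_realm, len(hot_cells),
                                           config.n_controls,
                                           seed=config.stage_seed("null"), realm=realm)
        ctrl_stats = [
            nulls.contiguity(c, data.cells.set_index("cell_id"),
                             data.occurrences.cell_km,
                             config.neighbor_radius_km).mean_hotspot
            for c in controls
        ]
        real_part = hotspots.RegionPartition(
            part_we.table[part_we.table["realm"] == realm].reset_index(drop=True))
        real_stat = nulls.contiguity(real_part, data.cells.set_index("cell_id"),
                                     data.occurrences.cell_km,
                                     config.neighbor_radius_km).mean_hotspot
        rank, flagged = nulls.null_envelope(real_stat, ctrl_stats)
        null_summary.update({"kappa": cp.kappa, "sigma": cp.sigma, "mu": cp.mu,
                             "real_contiguity_km": real_stat, "rank": rank,
                             "flagged": flagged})
    else:
        null_summary["skipped"] = True
        null_summary["reason"] = f"only {len(hot_xy)} hotspot cells (< 30)"
    summary["stages"]["null"] = null_summary

    # --- environment ---------------------------------------------------
    grid_weights = SpatialWeights.from_coords(
        data.cells.set_index("cell_id")[["x", "y"]],
        config.neighbor_radius_km, data.occurrences.cell_km)
    truth_part = simulate.true_partition(data.cells)
    env_res = environment.env_sar_contrast(data.env, truth_part, grid_weights)
    env_res.table.to_csv(out / "env_contrasts.csv", index=False)
    summary["stages"]["environment"] = {
        r["variable"]: {"beta": r["beta"], "significant": bool(r["significant"])}
        for _, r in env_res.table.iterrows()
    }

    summary["config_hash"] = config.config_hash()
    summary["seed"] = config.seed
    summary["package_version"] = __import__("hotroutes").__version__
    summary["stage_seeds"] = {s: config.stage_seed(s)
                              for s in ("simulate", "bsm", "null")}
    summary["assumptions"] = {
        "root_prior": "uniform over non-null ranges",
        "branch_conditioning": "survival-conditioned transition rows",
        "overlap_denominator": "smaller hotspot set",
        "quantile_universe": "occupied cells",
        "dispersal_normalizing_region": "destination",
        "interval_definition": "percentile across maps",
    }
    # the manifest must be a pure function of (config, seed): keep wall
    # time out of the file and only in the returned summary
    (out / "manifest.json").write_text(json.dumps(summary, indent=2, default=float))
    summary["runtime_s"] = round(time.time() - t0, 2)
    return summary
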