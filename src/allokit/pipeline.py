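"""End-to-end driver: CSV inputs (or a synthetic scenario) to final report.

Chains every stage in order -- melt fitting, Michaelis-Menten kinetics,
competition fitness, abundance normalization, double-mutant cycles, the
flux-fitness model and the phase-plane summary -- writing one tidy CSV
per stage plus a run log (seed, config hash, per-stage warnings).  For a
fixed configuration and seed the outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cycles as cyc
from . import io as aio
from . import kinetics as kin
from . import landscape as lsc
from . import synthetic as syn
from . import unfolding as unf
from .constants import DEFAULT_TEMPERATURE_K
from .errors import InvalidInputError
from .fitness import LN2, GrowthDataset, analyze_competition

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    outdir: str = "allokit_out"
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE_K
    bootstrap_B: int = 200
    i_baseline_slope: bool = False
    z_threshold: float = 1.96
    delta_floor: float = 0.1
    calib: float | None = None
    wt_doubling_time_hr: float = 4.5
    wt_id: str = "WT"
    # file-input mode: paths to stage CSVs (any subset; present stages run)
    inputs: dict = field(default_factory=dict)
    # synthetic mode: scenario description, used when inputs is empty
    scenario: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bootstrap_B < 0:
            raise InvalidInputError("bootstrap_B must be >= 0")
        if self.z_threshold <= 0 or self.delta_floor < 0:
            raise InvalidInputError("z_threshold must be > 0 and delta_floor >= 0")
        if self.wt_doubling_time_hr <= 0:
            raise InvalidInputError("WT doubling time must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _default_scenario() -> dict:
    """A one-cycle study: WT, two singles, their double, with a genuine
    interaction energy on the native-state stability."""
    return {
        "effect_M1": {"dG_NI": 0.8, "dGcat": -0.2},
        "effect_M2": {"dG_NI": 0.5, "dGcat": 0.1},
        "injected_delta": {"dG_NI": 0.0},
        "abundance_folds": {"M1": 1.3, "M2": 1.1, "DM": 1.8},
        "flux": {"a": 0.25, "b": 5.0},
        "noise": {
            "melt_sd_frac": 0.02,
            "kinetics_cv": 0.05,
            "competition_sd": 0.02,
            "abundance_cv": 0.15,
        },
    }


def _scenario_datasets(config: PipelineConfig) -> dict:
    sc = {**_default_scenario(), **config.scenario}
    noise = {**_default_scenario()["noise"], **sc.get("noise", {})}
    base = syn.GroundTruth(seed=config.seed)
    truths = syn.simulate_cycle_scenario(
        base,
        sc.get("effect_M1", {}),
        sc.get("effect_M2", {}),
        sc.get("injected_delta", {}),
        seed=config.seed,
    )

    folds = {"WT": 1.0, **sc.get("abundance_folds", {})}
    a_flux, b_flux = sc["flux"]["a"], sc["flux"]["b"]
    k_wt = base.growth_rate

    melts, kinetics_data = {}, {}
    growth_frames = []
    for i, (vid, truth) in enumerate(sorted(truths.items())):
        # noise SD scaled to each variant's own noiseless signal range
        span = np.ptp(
            np.concatenate(
                [truth.melt_signal(np.asarray(syn.DEFAULT_UREA_GRID), wl)
                 for wl in syn.DEFAULT_WAVELENGTHS]
            )
        )
        melts[vid] = syn.simulate_melt(
            truth,
            noise_sd=noise["melt_sd_frac"] * span,
            seed=config.seed + 101 + i,
            temperature=config.temperature,
        )
        kinetics_data[vid] = syn.simulate_kinetics(
            truth,
            noise_cv=noise["kinetics_cv"],
            seed=config.seed + 201 + i,
            temperature=config.temperature,
        )
        s_true = (
            0.0
            if vid == "WT"
            else cyc.flux_model(folds.get(vid, 1.0), truth.kcat, a_flux, b_flux)
            - cyc.flux_model(1.0, base.kcat, a_flux, b_flux)
        )
        k_mt = k_wt * 2.0 ** s_true
        comp = syn.simulate_competition(
            k_WT=k_wt,
            k_MT=k_mt,
            k_vector=0.0,
            noise_sd=noise["competition_sd"],
            seed=config.seed + 301 + i,
            mutant_id=vid,
        )
        sub = comp.data
        if vid != "WT":  # keep a single WT and vector track (from the WT sim)
            sub = sub[~sub["variant_id"].isin(["WT", "vector"])]
        growth_frames.append(sub)

    growth = GrowthDataset(data=pd.concat(growth_frames, ignore_index=True))
    abundance = syn.simulate_abundance(
        folds, noise_cv=noise["abundance_cv"], seed=config.seed + 401
    )
    cycle_defs = pd.DataFrame(
        [
            {"property": p, "single1": "M1", "single2": "M2", "double": "DM"}
            for p in ("ddG_NI", "ddG_IU", "ddG_cat", "ddG_eff")
        ]
    )
    return {
        "melts": melts,
        "kinetics": kinetics_data,
        "growth": growth,
        "abundance": abundance,
        "cycle_defs": cycle_defs,
        "truths": truths,
    }


def _file_datasets(config: PipelineConfig) -> dict:
    paths = config.inputs
    out: dict = {}
    if "melt" in paths:
        df = aio.read_table(paths["melt"], aio.MELT_SCHEMA)
        out["melts"] = {
            str(vid): unf.MeltDataset(str(vid), sub.reset_index(drop=True), config.temperature)
            for vid, sub in df.groupby("variant_id")
        }
    if "kinetics" in paths:
        df = aio.read_table(paths["kinetics"], aio.KINETICS_SCHEMA)
        e0 = df["E0_uM"].iloc[0] if "E0_uM" in df.columns else 1.0
        out["kinetics"] = {
            str(vid): kin.KineticsDataset(
                str(vid),
                float(sub["E0_uM"].iloc[0]) if "E0_uM" in sub.columns else float(e0),
                sub.reset_index(drop=True),
                calib=config.calib,
                temperature=config.temperature,
            )
            for vid, sub in df.groupby("variant_id")
        }
    if "growth" in paths:
        out["growth"] = GrowthDataset(aio.read_table(paths["growth"], aio.GROWTH_SCHEMA))
    if "abundance" in paths:
        out["abundance"] = aio.read_table(paths["abundance"], aio.ABUNDANCE_SCHEMA)
    if "cycles" in paths:
        out["cycle_defs"] = aio.read_table(paths["cycles"], aio.CYCLES_SCHEMA)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage present in the inputs (or the synthetic scenario).

    Returns a report dict with the per-stage tables and fit objects and
    writes CSV outputs plus ``run_log.yaml`` under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = _file_datasets(config) if config.inputs else _scenario_datasets(config)
    log: dict = {"seed": config.seed, "config_sha256": config.digest(), "stages": {}}
    report: dict = {}
    wt = config.wt_id

    # --- stability -------------------------------------------------------
    melt_fits: dict[str, unf.ThreeStateFit] = {}
    if "melts" in data:
        for i, (vid, ds) in enumerate(sorted(data["melts"].items())):
            melt_fits[vid] = unf.fit_three_state(
                ds,
                i_baseline_slope=config.i_baseline_slope,
                bootstrap=config.bootstrap_B,
                seed=config.seed + 1000 + i,
                temperature=config.temperature,
            )
        if wt not in melt_fits:
            raise InvalidInputError(f"melt data lacks the WT reference '{wt}'")
        rows, pert = [], {}
        for vid, f in melt_fits.items():
            p = unf.stability_perturbation(melt_fits[wt], f)
            pert[vid] = p
            rows.append(
                {
                    "variant_id": vid,
                    "dG_NI": f.dG_NI, "dG_NI_se": f.dG_NI_se,
                    "m_NI": f.m_NI, "m_NI_se": f.m_NI_se,
                    "dG_IU": f.dG_IU, "dG_IU_se": f.dG_IU_se,
                    "m_IU": f.m_IU, "m_IU_se": f.m_IU_se,
                    "ddG_NI": p.ddG_NI, "ddG_NI_se": p.ddG_NI_se,
                    "ddG_IU": p.ddG_IU, "ddG_IU_se": p.ddG_IU_se,
                    "rms": f.rms, "n_obs": f.n_obs,
                }
            )
        stability_table = pd.DataFrame(rows).sort_values("variant_id", kind="stable")
        aio.write_table(stability_table, outdir / "melt_fits.csv")
        report["stability"] = stability_table
        report["melt_fits"] = melt_fits
        log["stages"]["unfolding"] = {
            vid: f.warnings for vid, f in melt_fits.items() if f.warnings
        } or "ok"

    # --- kinetics --------------------------------------------------------
    if "kinetics" in data:
        kfits: dict[str, kin.KineticsFit] = {}
        for i, (vid, ds) in enumerate(sorted(data["kinetics"].items())):
            kfits[vid] = kin.fit_mm(ds, bootstrap=config.bootstrap_B, seed=config.seed + 2000 + i)
        if wt not in kfits:
            raise InvalidInputError(f"kinetics data lacks the WT reference '{wt}'")
        for vid, f in kfits.items():
            kin.compare_to_reference(f, kfits[wt])
        ktable = pd.DataFrame(
            [
                {
                    "variant_id": vid,
                    "kcat": f.kcat, "kcat_se": f.kcat_se,
                    "Km": f.Km, "Km_se": f.Km_se,
                    "Keff": f.Keff, "Keff_se": f.Keff_se,
                    "ddG_cat": f.ddG_cat, "ddG_cat_se": f.ddG_cat_se,
                    "ddG_eff": f.ddG_eff, "ddG_eff_se": f.ddG_eff_se,
                }
                for vid, f in kfits.items()
            ]
        ).sort_values("variant_id", kind="stable")
        aio.write_table(ktable, outdir / "kinetics_fits.csv")
        report["kinetics"] = ktable
        report["kinetics_fits"] = kfits
        log["stages"]["kinetics"] = {
            vid: f.warnings for vid, f in kfits.items() if f.warnings
        } or "ok"

    # --- fitness ---------------------------------------------------------
    if "growth" in data:
        fres = analyze_competition(data["growth"], wt_id=wt)
        ftable = pd.DataFrame(
            [
                {"variant_id": r.variant_id, "w": r.w, "w_se": r.w_se,
                 "s_norm": r.s_norm, "s_norm_se": r.s_norm_se}
                for r in fres
            ]
        ).sort_values("variant_id", kind="stable")
        aio.write_table(ftable, outdir / "fitness.csv")
        report["fitness"] = ftable
        log["stages"]["fitness"] = "ok"

    # --- abundance -------------------------------------------------------
    if "abundance" in data:
        arecs = cyc.abundance_fold(data["abundance"], wt_id=wt)
        atable = pd.DataFrame(
            [
                {"variant_id": r.variant_id, "fold_vs_wt": r.fold_vs_wt,
                 "fold_se": r.fold_se, "n_replicates": r.n_replicates}
                for r in arecs
            ]
        ).sort_values("variant_id", kind="stable")
        aio.write_table(atable, outdir / "abundance.csv")
        report["abundance"] = atable
        log["stages"]["abundance"] = "ok"

    # --- double-mutant cycles -------------------------------------------
    if "cycle_defs" in data and "stability" in report and "kinetics" in report:
        pert_tables: dict[str, dict[str, tuple[float, float]]] = {}
        st = report["stability"].set_index("variant_id")
        kt = report["kinetics"].set_index("variant_id")
        for prop, src, se_col in (
            ("ddG_NI", st, "ddG_NI_se"),
            ("ddG_IU", st, "ddG_IU_se"),
            ("ddG_cat", kt, "ddG_cat_se"),
            ("ddG_eff", kt, "ddG_eff_se"),
        ):
            pert_tables[prop] = {
                vid: (float(src.loc[vid, prop]), float(src.loc[vid, se_col]))
                for vid in src.index
            }
        crows = []
        for _, row in data["cycle_defs"].iterrows():
            res = cyc.mutant_cycle(
                row["property"],
                pert_tables[row["property"]],
                row["single1"], row["single2"], row["double"],
                z_threshold=config.z_threshold,
                floor=config.delta_floor,
            )
            crows.append(dataclasses.asdict(res))
        ctable = pd.DataFrame(crows)
        aio.write_table(ctable, outdir / "cycles.csv")
        report["cycles"] = ctable
        log["stages"]["cycles"] = "ok"

    # --- flux-fitness model ---------------------------------------------
    if {"kinetics", "fitness", "abundance"} <= set(report):
        panel = (
            report["fitness"][["variant_id", "s_norm"]]
            .merge(report["abundance"][["variant_id", "fold_vs_wt"]], on="variant_id")
            .merge(report["kinetics"][["variant_id", "kcat"]], on="variant_id")
        )
        if len(panel) >= 3:
            ff = cyc.fit_flux_model(
                panel["s_norm"], panel["fold_vs_wt"], panel["kcat"],
                variant_ids=panel["variant_id"],
            )
            aio.write_table(ff.predicted, outdir / "flux_fit.csv")
            report["flux"] = ff
            log["stages"]["flux"] = {
                "a": ff.a, "b": ff.b, "positive_trend": bool(ff.positive_trend)
            }

    # --- phase plane / per-variant summary ------------------------------
    if {"stability", "kinetics", "fitness"} <= set(report):
        plane = lsc.assemble_phase_plane(
            report["stability"], report["kinetics"], report["fitness"]
        )
        summary_cols = [
            c for c in (
                "variant_id", "s_norm", "s_norm_se", "ddG_NI", "ddG_NI_se",
                "ddG_IU", "ddG_IU_se", "kcat", "Km", "Keff", "ddG_cat",
                "ddG_cat_se", "ddG_eff", "ddG_eff_se", "quadrant",
            )
            if c in plane.columns
        ]
        summary = plane[summary_cols]
        aio.write_table(summary, outdir / "variant_summary.csv")
        report["summary"] = summary
        log["stages"]["landscape"] = "ok"

    with open(outdir / "run_log.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    report["log"] = log
    return report
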