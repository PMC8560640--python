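"""Top-level pipeline: simulate -> estimate -> derive -> analyze.

Ties the synthetic generators, PTT estimation, hemodynamic derivation and
cohort analysis into a single reproducible run.  Every stage writes its
outputs under the run directory and the run ends with a manifest recording
the seed, a hash of the configuration, and a SHA-256 digest of every output
file, so a rerun with the same seed is bitwise-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .hemodynamics import derive_record
from .io import (read_aif_csv, write_aif_csv, write_cohort_csv, write_json)
from .outcomes import fit_cox_per_sd, fit_log_ptt_model, km_dichotomized
from .synthetic import CohortConfig, TransitPhantomConfig, generate_aif_pair, generate_cohort
from .transit import PoorAIFSignalError, estimate_ptt, qc_report

ALL_STAGES = ("simulate_cohort", "simulate_curves", "estimate", "derive", "analyze")


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration detected before execution."""


@dataclass
class PipelineConfig:
    """Configuration of one synthetic end-to-end run."""

    outdir: str = "run"
    seed: int = 0
    n_subjects: int = 50
    stages: tuple = ALL_STAGES
    method: str = "fit"                  # PTT estimation method
    qc_floor: float = 0.5                # mmol/l
    low_dose_fraction: float = 0.0       # fraction of phantoms generated below the QC floor
    make_plots: bool = False
    cohort: dict = field(default_factory=dict)    # CohortConfig overrides
    phantom: dict = field(default_factory=dict)   # TransitPhantomConfig overrides

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise PipelineConfigError(f"unknown stage(s) {unknown}; valid: {ALL_STAGES}")
        if "estimate" in self.stages and "simulate_curves" not in self.stages:
            curve_dir = Path(self.outdir) / "curves"
            if not curve_dir.exists():
                raise PipelineConfigError(
                    "estimate stage enabled but no curve input: run simulate_curves "
                    f"or provide {curve_dir}")
        if not 0 <= self.low_dose_fraction <= 1:
            raise PipelineConfigError("low_dose_fraction must lie in [0, 1]")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    A stage failure still writes a manifest recording the failure point,
    then re-raises.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_root = np.random.SeedSequence(config.seed)

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": config.as_dict(),
        "stages": [],
        "outputs": {},
        "qc_summary": {},
        "status": "running",
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)

    cohort = None
    try:
        if "simulate_cohort" in config.stages:
            ccfg = CohortConfig(n_subjects=config.n_subjects,
                                seed=int(rng_root.generate_state(1)[0] % (2**31)),
                                **config.cohort)
            cohort = generate_cohort(ccfg)
            path = outdir / "cohort.csv"
            write_cohort_csv(cohort, path)
            record("simulate_cohort", path)

        curve_dir = outdir / "curves"
        subject_seeds = {}
        low_dose_ids: list = []
        if "simulate_curves" in config.stages:
            if cohort is None:
                raise PipelineConfigError("simulate_curves requires simulate_cohort")
            curve_dir.mkdir(exist_ok=True)
            child_seeds = rng_root.spawn(len(cohort))
            dose_rng = np.random.default_rng(rng_root.generate_state(1)[0] % (2**31) + 1)
            paths = []
            for (idx, row), childseq in zip(cohort.iterrows(), child_seeds):
                sid = int(row["id"])
                seed_i = int(childseq.generate_state(1)[0] % (2**31))
                subject_seeds[sid] = seed_i
                low_dose = bool(dose_rng.random() < config.low_dose_fraction)
                if low_dose:
                    low_dose_ids.append(sid)
                rr = 60.0 / float(row["heart_rate"])
                transit = float(np.clip(row["ptt"], 2.0, 20.0))
                n_frames = max(20, int(np.ceil((transit + 4.0 + 5.0 * 2.0 * 4.0) / rr)) + 5)
                pcfg = TransitPhantomConfig(
                    transit_mean=transit, rr_interval=rr, n_frames=n_frames,
                    seed=seed_i,
                    peak_conc=0.2 if low_dose else 5.0,
                    **config.phantom)
                pair, truth = generate_aif_pair(pcfg)
                p = curve_dir / f"subject_{sid:04d}.csv"
                write_aif_csv(pair, p, metadata={
                    "subject_id": sid, "seed": seed_i, "low_dose": low_dose,
                    "true_ptt_s": truth.true_ptt, "true_pttn": truth.true_pttn,
                })
                paths.append(p)
            record("simulate_curves", *paths)
            manifest["qc_summary"]["n_low_dose_generated"] = len(low_dose_ids)

        if "estimate" in config.stages:
            import pandas as pd
            rows = []
            n_excluded = 0
            for p in sorted(curve_dir.glob("subject_*.csv")):
                sid = int(p.stem.split("_")[1])
                pair = read_aif_csv(p)
                try:
                    result = estimate_ptt(pair, method=config.method,
                                          qc_floor=config.qc_floor)
                    report = qc_report(pair, result, qc_floor=config.qc_floor)
                except PoorAIFSignalError:
                    result = None
                    report = qc_report(pair, None, qc_floor=config.qc_floor)
                excluded = report.recommendation == "exclude"
                n_excluded += excluded
                rows.append({
                    "id": sid,
                    "ptt_est": result.ptt if result else np.nan,
                    "pttn_est": result.pttn if result else np.nan,
                    "included": int(not excluded),
                    "qc_flags": ";".join(report.flags),
                })
            est = pd.DataFrame(rows)
            path = outdir / "estimates.csv"
            est.to_csv(path, index=False, float_format="%.9g")
            record("estimate", path)
            manifest["qc_summary"].update({
                "n_processed": len(est),
                "n_included": int(est["included"].sum()),
                "n_excluded": int(n_excluded),
            })

        if "derive" in config.stages:
            import pandas as pd
            if cohort is None:
                raise PipelineConfigError("derive requires simulate_cohort")
            est = pd.read_csv(outdir / "estimates.csv")
            merged = cohort.merge(est, on="id", how="inner")
            merged = merged[merged["included"] == 1].copy()
            recs = [derive_record(r.stroke_volume, r.heart_rate, r.height,
                                  r.weight, r.ptt_est).as_dict()
                    for r in merged.itertuples()]
            merged["pbv_est"] = [d["pbv_ml"] for d in recs]
            merged["pbvi_est"] = [d["pbvi_ml_m2"] for d in recs]
            path = outdir / "cohort_with_estimates.csv"
            write_cohort_csv(merged, path)
            record("derive", path)

        if "analyze" in config.stages:
            import pandas as pd
            analysed = pd.read_csv(outdir / "cohort_with_estimates.csv")
            results: dict = {"n_analyzed": len(analysed)}
            try:
                lin = fit_log_ptt_model(analysed, outcome="ptt_est")
                results["log_ptt_regression"] = lin.as_dict()
            except ValueError as exc:
                results["log_ptt_regression"] = {"skipped": str(exc)}
            for pred in ("ptt_est", "pbvi_est"):
                try:
                    cox = fit_cox_per_sd(analysed, predictor=pred)
                    results[f"cox_{pred}"] = cox.as_dict()
                except ValueError as exc:
                    results[f"cox_{pred}"] = {"skipped": str(exc)}
            try:
                km = km_dichotomized(analysed, "ptt_est")
                results["km_ptt"] = {
                    "cutoff": km.cutoff, "logrank_p": km.logrank_p,
                    "n_low": km.n_low, "n_high": km.n_high,
                }
                if config.make_plots:
                    import matplotlib
                    matplotlib.use("Agg")
                    import matplotlib.pyplot as plt
                    ax = km.plot()
                    ax.figure.savefig(outdir / "km_ptt.png", dpi=100)
                    plt.close(ax.figure)
            except ValueError as exc:
                results["km_ptt"] = {"skipped": str(exc)}
            path = outdir / "analysis.json"
            write_json(results, path)
            record("analyze", path)

        manifest["status"] = "completed"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failure_stage"] = (manifest["stages"][-1] + "+1"
                                     if manifest["stages"] else config.stages[0])
        manifest["failure"] = f"{type(exc).__name__}: {exc}"
        write_json(manifest, outdir / "manifest.json")
        raise

    payload = json.dumps(manifest["outputs"], sort_keys=True).encode()
    manifest["manifest_hash"] = hashlib.sha256(payload).hexdigest()
    write_json(manifest, outdir / "manifest.json")
    return manifest
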