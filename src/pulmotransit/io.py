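"""File formats: AIF CSV, cohort CSV, NIfTI dynamic series, JSON, YAML.

Conventions: curves and cohorts are CSV, image stacks NIfTI (frames as the
last dimension), results JSON, configuration YAML.  Numeric output is
written at 9 significant digits so write -> read round-trips are lossless
to that precision.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .curves import AIFCurve, AIFCurvePair
from .extraction import DynamicSeries, SegmentationMasks

AIF_COLUMNS = ("time_s", "rv_conc_mmol_l", "lv_conc_mmol_l")
FLOAT_FMT = "%.9g"


class SchemaError(ValueError):
    """CSV does not match the documented schema."""


def write_aif_csv(pair: AIFCurvePair, path, metadata: dict | None = None) -> None:
    """Write a curve pair; optional metadata goes to a `.json` sidecar."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": pair.times,
        "rv_conc_mmol_l": pair.rv.conc,
        "lv_conc_mmol_l": pair.lv.conc,
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    side = {"rr_interval_s": pair.rr_interval, "qc_flags": list(pair.qc_flags)}
    if metadata:
        side.update(metadata)
    write_json(side, path.with_suffix(".json"))


def read_aif_csv(path, rr_interval: float | None = None) -> AIFCurvePair:
    """Read a curve pair, validating the schema.

    ``rr_interval`` is taken from the sidecar JSON when present, otherwise
    from the argument, otherwise from the median frame spacing.  Unknown
    extra columns are ignored with a warning; non-monotone times are a
    schema error reporting the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in AIF_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in AIF_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}", UserWarning,
                      stacklevel=2)
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise SchemaError(
            f"{path}: time_s not strictly increasing at line {bad[0] + 3} "
            f"(data row {bad[0] + 2})")

    sidecar = path.with_suffix(".json")
    qc_flags: list = []
    if sidecar.exists():
        meta = read_json(sidecar)
        rr_interval = meta.get("rr_interval_s", rr_interval)
        qc_flags = list(meta.get("qc_flags", []))
    if rr_interval is None:
        rr_interval = float(np.median(np.diff(t)))
    return AIFCurvePair(
        rv=AIFCurve(t, df["rv_conc_mmol_l"].to_numpy(dtype=float), "RV"),
        lv=AIFCurve(t, df["lv_conc_mmol_l"].to_numpy(dtype=float), "LV"),
        rr_interval=float(rr_interval), qc_flags=qc_flags,
    )


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_dynamic_series(series: DynamicSeries, path,
                         masks: SegmentationMasks | None = None) -> None:
    """NIfTI with frames as the last dimension, plus a JSON timing sidecar."""
    path = Path(path)
    arr = np.moveaxis(series.frames, 0, -1)
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))
    side = {
        "frame_times_s": [float(x) for x in series.frame_times],
        "rr_interval_s": series.rr_interval,
    }
    if masks is not None:
        side["arrival_frame_rv"] = int(masks.arrival_frame_rv)
        side["arrival_frame_lv"] = int(masks.arrival_frame_lv)
    write_json(side, Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json"))


def read_dynamic_series(path) -> DynamicSeries:
    path = Path(path)
    img = nib.load(str(path))
    arr = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"timing sidecar {sidecar} not found")
    meta = read_json(sidecar)
    return DynamicSeries(frames=arr,
                         frame_times=np.asarray(meta["frame_times_s"], dtype=float),
                         rr_interval=float(meta["rr_interval_s"]))


def write_masks(masks: SegmentationMasks, path) -> None:
    arr = np.zeros(masks.rv_mask.shape, dtype=np.int16)
    arr[masks.rv_mask] = 1
    arr[masks.lv_mask] = 2
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))


def _round_floats(obj, sig: int = 9):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    return obj


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_round_floats(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
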