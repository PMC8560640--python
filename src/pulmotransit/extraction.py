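"""Arterial input function extraction from dynamic perfusion image series.

The chain is: segment the RV and LV blood pools on the dynamic stack,
spatially average the signal inside each pool, subtract the pre-arrival
baseline, and convert normalized enhancement to gadolinium concentration
through a calibrated saturation model.

Blood-pool segmentation is a classical operator: per-pixel peak enhancement
(peak minus baseline) is thresholded at a configurable quantile, connected
components above a minimum area are kept, and the two largest are labeled
RV/LV by time-to-peak order (the bolus reaches the RV first).  Cases where
two pools cannot be found are rejected, mirroring the exclusion category of
incorrect automated blood-pool identification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from sklearn.base import BaseEstimator

from .curves import AIFCurve, AIFCurvePair
from .saturation import HyperbolicSaturation

MIN_FRAMES = 20


class BloodPoolIdentificationError(RuntimeError):
    """Fewer than two candidate blood pools found in the dynamic series."""


class QCWarning(UserWarning):
    """Non-fatal quality-control finding during extraction."""


@dataclass
class DynamicSeries:
    """Dynamic image stack: frame x row x col, one frame per heartbeat."""

    frames: np.ndarray
    frame_times: np.ndarray
    rr_interval: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3-D (frame, row, col)")
        if self.frames.shape[0] < MIN_FRAMES:
            raise ValueError(f"series needs at least {MIN_FRAMES} frames")
        if self.frame_times.size != self.frames.shape[0]:
            raise ValueError("frame_times length must equal the frame count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.rr_interval <= 0:
            raise ValueError("rr_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class SegmentationMasks:
    """Boolean cavity masks plus detected bolus-arrival frames."""

    rv_mask: np.ndarray
    lv_mask: np.ndarray
    arrival_frame_rv: int
    arrival_frame_lv: int

    def __post_init__(self) -> None:
        self.rv_mask = np.asarray(self.rv_mask, dtype=bool)
        self.lv_mask = np.asarray(self.lv_mask, dtype=bool)
        if not self.rv_mask.any() or not self.lv_mask.any():
            raise ValueError("masks must be non-empty")
        if np.any(self.rv_mask & self.lv_mask):
            raise ValueError("RV and LV masks must be disjoint")
        if self.arrival_frame_rv > self.arrival_frame_lv:
            raise ValueError("RV arrival cannot follow LV arrival")

    def dice(self, other: "SegmentationMasks") -> tuple:
        """Dice overlap of RV and LV masks against another mask set."""
        def _d(a, b):
            return 2.0 * np.sum(a & b) / (np.sum(a) + np.sum(b))
        return _d(self.rv_mask, other.rv_mask), _d(self.lv_mask, other.lv_mask)


def _detect_arrival(signal: np.ndarray, baseline_frames: int, k: float = 5.0) -> int:
    """First frame exceeding baseline + max(k*baseline SD, 5% of peak enhancement).

    Earliest qualifying frame wins (plateau tie-break).  Falls back to the
    5%-of-peak rule when the baseline is noiseless.
    """
    base = signal[:baseline_frames]
    mu, sd = float(np.mean(base)), float(np.std(base))
    peak_enh = float(signal.max() - mu)
    thr = mu + max(k * sd, 0.05 * peak_enh)
    above = np.nonzero(signal > thr)[0]
    return int(above[0]) if above.size else int(np.argmax(signal))


class BloodPoolSegmenter(BaseEstimator):
    """Segment RV and LV blood pools from peak contrast enhancement.

    Parameters
    ----------
    quantile : float
        Per-pixel peak-enhancement quantile used as the pool threshold.
    min_area : int
        Minimum connected-component area (pixels) for a candidate pool.
    baseline_frames : int
        Number of leading frames averaged as the pre-contrast baseline.
    fill_holes : bool
        Morphologically close and fill each retained component (noise can
        punch holes in an otherwise solid cavity).

    Fitted attributes
    -----------------
    rv_mask_, lv_mask_ : boolean arrays
    arrival_frame_rv_, arrival_frame_lv_ : int
    masks_ : SegmentationMasks
    """

    def __init__(self, quantile: float = 0.9, min_area: int = 20,
                 baseline_frames: int = 3, fill_holes: bool = True):
        self.quantile = quantile
        self.min_area = min_area
        self.baseline_frames = baseline_frames
        self.fill_holes = fill_holes

    def fit(self, series: DynamicSeries, y=None):
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must lie in (0, 1)")
        frames = series.frames
        baseline = frames[: self.baseline_frames].mean(axis=0)
        peak_enh = frames.max(axis=0) - baseline
        thr = np.quantile(peak_enh, self.quantile)
        candidate = peak_enh >= thr

        labels = measure.label(candidate, connectivity=2)
        props = [p for p in measure.regionprops(labels) if p.area >= self.min_area]
        if len(props) < 2:
            raise BloodPoolIdentificationError(
                f"blood pool identification failure: found {len(props)} candidate "
                f"pool(s), need 2 (threshold quantile {self.quantile})"
            )
        props.sort(key=lambda p: p.area, reverse=True)
        comp_masks = []
        for p in props[:2]:
            m = labels == p.label
            if self.fill_holes:
                m = ndimage.binary_closing(m, iterations=1)
                m = ndimage.binary_fill_holes(m)
            comp_masks.append(m)
        # closing can bridge the two components into overlap; keep disjoint
        overlap = comp_masks[0] & comp_masks[1]
        if overlap.any():
            comp_masks = [m & ~overlap for m in comp_masks]

        infos = []
        for m in comp_masks:
            sig = frames[:, m].mean(axis=1)
            infos.append({
                "mask": m,
                "ttp": int(np.argmax(sig)),
                "arrival": _detect_arrival(sig, self.baseline_frames),
            })
        infos.sort(key=lambda d: (d["ttp"], d["arrival"]))  # earlier peak = RV
        rv, lv = infos[0], infos[1]
        self.rv_mask_, self.lv_mask_ = rv["mask"], lv["mask"]
        self.arrival_frame_rv_ = min(rv["arrival"], lv["arrival"])
        self.arrival_frame_lv_ = max(rv["arrival"], lv["arrival"])
        self.masks_ = SegmentationMasks(
            rv_mask=self.rv_mask_, lv_mask=self.lv_mask_,
            arrival_frame_rv=self.arrival_frame_rv_,
            arrival_frame_lv=self.arrival_frame_lv_,
        )
        return self

    def predict(self, series: DynamicSeries = None) -> SegmentationMasks:
        if not hasattr(self, "masks_"):
            if series is None:
                raise RuntimeError("segmenter is not fitted")
            self.fit(series)
        return self.masks_


def segment_blood_pools(series: DynamicSeries, **params) -> SegmentationMasks:
    """Functional wrapper over :class:`BloodPoolSegmenter`."""
    return BloodPoolSegmenter(**params).fit(series).masks_


def signal_to_concentration(signal, calib) -> np.ndarray:
    """Convert a raw cavity signal series to concentration (mmol/l).

    Normalized enhancement ``(signal - s0)/s0`` (with ``s0`` from the
    calibration) is passed through the inverse of the forward saturation
    map.  Values below baseline clip to zero concentration; enhancement
    beyond the invertible range raises
    :class:`~pulmotransit.saturation.SaturationOverflowError` rather than
    clipping silently.
    """
    s = np.asarray(signal, dtype=float)
    enh = (s - calib.s0) / calib.s0
    return calib.inverse(enh)


def extract_aif(series: DynamicSeries, masks: SegmentationMasks,
                calib=None, baseline_frames: int | None = None) -> AIFCurvePair:
    """Spatially average, baseline-subtract, and convert both cavities.

    The baseline is the mean of the pre-arrival frames (default: all frames
    up to RV arrival minus 1).  Fewer than 3 baseline frames raises a
    :class:`QCWarning` (incorrect contrast-timing category) and the pair is
    flagged.  Returns an :class:`~pulmotransit.curves.AIFCurvePair` on the
    shared frame-time base.
    """
    calib = calib or HyperbolicSaturation()
    n_base = baseline_frames if baseline_frames is not None else max(masks.arrival_frame_rv - 1, 1)
    qc_flags = []
    if n_base < 3:
        warnings.warn(
            f"only {n_base} pre-arrival baseline frame(s); possible incorrect "
            "timing of contrast administration", QCWarning, stacklevel=2)
        qc_flags.append("incorrect_contrast_timing")

    curves = {}
    for label, mask in (("RV", masks.rv_mask), ("LV", masks.lv_mask)):
        sig = series.frames[:, mask].mean(axis=1)
        s0 = float(sig[:n_base].mean())
        if s0 <= 0:
            raise ValueError("non-positive baseline signal; cannot normalize enhancement")
        enh = (sig - s0) / s0
        conc = calib.inverse(enh)  # clips sub-baseline noise to 0
        curves[label] = AIFCurve(series.frame_times, conc, label)

    return AIFCurvePair(rv=curves["RV"], lv=curves["LV"],
                        rr_interval=series.rr_interval, qc_flags=qc_flags)
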