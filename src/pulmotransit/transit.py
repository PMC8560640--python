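"""Pulmonary transit time estimation from paired AIF curves.

PTT is the time between the centers of gravity (centroids) of the RV and LV
arterial input function curves after exclusion of the recirculation
component.  Recirculation exclusion follows standard indicator-dilution
practice: a gamma-variate ``A*(t-t0)^alpha*exp(-(t-t0)/beta)`` is fitted by
nonlinear least squares over the first-pass window (curve foot to the point
where the downslope falls below a configurable fraction of peak), and the
centroid is taken in closed form as ``t0 + beta*(alpha+1)``.  A
model-free fallback truncates the measured curve at the post-peak local
minimum preceding any secondary rise and computes the discrete trapezoidal
first moment.

PTTn normalizes PTT by the R-R interval, i.e. expresses the transit in
heartbeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .curves import AIFCurve, AIFCurvePair
from .synthetic import gamma_variate, gamma_variate_centroid

#: default QC floor on peak concentration, mmol/l (repository convention)
DEFAULT_QC_FLOOR = 0.5
#: default physiological plausibility window for PTT, seconds
PLAUSIBILITY_WINDOW = (2.0, 30.0)


class PoorAIFSignalError(RuntimeError):
    """No usable first-pass peak in the curve (poor AIF signal category)."""


@dataclass
class FirstPassModel:
    """Recirculation-excluded first pass for one cavity."""

    method: str                       # "fit" or "truncate"
    params: dict | None               # amplitude, t0, alpha, beta (fit only)
    fit_window: tuple                 # (start, stop) sample indices used
    converged: bool
    residual_rms: float
    centroid: float                   # s
    first_pass_conc: np.ndarray       # curve used for the centroid
    flags: list = field(default_factory=list)


@dataclass
class PTTResult:
    """Estimated transit for one curve pair."""

    centroid_rv: float
    centroid_lv: float
    ptt: float
    pttn: float
    method: str
    valid: bool
    qc_flags: list = field(default_factory=list)
    rv_model: FirstPassModel | None = None
    lv_model: FirstPassModel | None = None

    def as_dict(self) -> dict:
        return {
            "centroid_rv_s": self.centroid_rv,
            "centroid_lv_s": self.centroid_lv,
            "ptt_s": self.ptt,
            "pttn": self.pttn,
            "method": self.method,
            "valid": self.valid,
            "qc_flags": list(self.qc_flags),
        }


def curve_centroid(times, conc) -> float:
    """Discrete center of gravity: first moment with trapezoidal weights.

    Curves are used at their native one-sample-per-heartbeat resolution;
    no resampling or interpolation is applied.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 3:
        raise ValueError("centroid needs at least 3 samples")
    area = np.trapezoid(c, t)
    if area <= 0:
        raise ValueError("zero total area; centroid undefined")
    return float(np.trapezoid(t * c, t) / area)


def normalize_ptt(ptt: float, rr_interval: float) -> float:
    """PTTn = PTT (s) / R-R interval (s): transit time in heartbeats."""
    if rr_interval <= 0:
        raise ValueError("rr_interval must be positive")
    return ptt / rr_interval


# --------------------------------------------------------------------------
# first-pass isolation
# --------------------------------------------------------------------------

def _detect_foot(conc: np.ndarray) -> int:
    """Index of the curve foot: last quiet sample before sustained upslope.

    Arrival is the earliest frame exceeding baseline + max(5*baseline SD,
    5% of peak); the foot is the sample before it.
    """
    base = conc[:3]
    mu, sd = float(base.mean()), float(base.std())
    peak = float(conc.max())
    thr = mu + max(5.0 * sd, 0.05 * (peak - mu))
    above = np.nonzero(conc > thr)[0]
    arrival = int(above[0]) if above.size else int(np.argmax(conc))
    return max(arrival - 1, 0)


def _fit_window(conc: np.ndarray, foot: int, downslope_fraction: float) -> tuple:
    """(start, stop) indices: foot through the downslope at `fraction` of peak."""
    peak_idx = int(np.argmax(conc))
    peak = float(conc[peak_idx])
    stop = conc.size
    for i in range(peak_idx + 1, conc.size):
        if conc[i] < downslope_fraction * peak:
            stop = i
            break
    return max(foot - 1, 0), stop


def _truncate_at_recirc(conc: np.ndarray, rise_tol: float = 0.02) -> int:
    """Stop index for the model-free method: post-peak local minimum
    preceding a secondary rise (hysteresis of ``rise_tol`` * peak)."""
    peak_idx = int(np.argmax(conc))
    peak = float(conc[peak_idx])
    run_min, run_idx = np.inf, conc.size - 1
    for i in range(peak_idx, conc.size):
        if conc[i] < run_min:
            run_min, run_idx = conc[i], i
        elif conc[i] > run_min + rise_tol * peak:
            return run_idx + 1
    return conc.size


def fit_gamma_variate(times: np.ndarray, conc: np.ndarray, window: tuple,
                      max_nfev: int = 2000):
    """Bounded nonlinear least-squares fit of the gamma-variate on a window.

    Initialization: t0 from the foot, alpha = 3, beta from the time to peak,
    amplitude from the peak value.  Returns (params dict, converged flag,
    residual RMS relative to peak).
    """
    start, stop = window
    t_w, c_w = times[start:stop], conc[start:stop]
    peak_idx = int(np.argmax(conc))
    peak = float(conc[peak_idx])
    t_peak = float(times[peak_idx])
    t0_init = float(times[max(start, 0)])
    alpha_init = 3.0
    beta_init = max((t_peak - t0_init) / alpha_init, 1e-2)
    amp_init = peak / ((alpha_init * beta_init) ** alpha_init * np.exp(-alpha_init))

    def resid(x):
        log_amp, t0, log_alpha, log_beta = x
        model = gamma_variate(t_w, np.exp(log_amp), t0, np.exp(log_alpha), np.exp(log_beta))
        return model - c_w

    x0 = [np.log(amp_init), t0_init, np.log(alpha_init), np.log(beta_init)]
    lo = [-np.inf, float(times[0]) - 2.0, np.log(0.3), np.log(1e-3)]
    hi = [np.inf, t_peak, np.log(30.0), np.log(50.0)]
    x0 = np.clip(x0, lo, hi)
    res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=max_nfev)
    params = {
        "amplitude": float(np.exp(res.x[0])),
        "t0": float(res.x[1]),
        "alpha": float(np.exp(res.x[2])),
        "beta": float(np.exp(res.x[3])),
    }
    rms = float(np.sqrt(np.mean(res.fun**2))) / max(peak, 1e-12)
    converged = bool(res.status > 0) and rms < 0.25
    return params, converged, rms


def remove_recirculation(curve: AIFCurve, method: str = "fit",
                         downslope_fraction: float = 0.4,
                         qc_floor: float = DEFAULT_QC_FLOOR) -> FirstPassModel:
    """Isolate the first pass of one cavity curve.

    ``method='fit'`` (default) fits the gamma-variate and uses its
    closed-form centroid; a non-convergent fit falls back to truncation with
    a QC flag.  ``method='truncate'`` cuts the measured curve at the
    post-peak local minimum preceding any secondary rise and uses the
    discrete centroid.  A curve with no detectable peak (below ``qc_floor``)
    raises :class:`PoorAIFSignalError`.
    """
    t, c = curve.times, curve.conc
    peak = float(c.max())
    if peak < qc_floor:
        raise PoorAIFSignalError(
            f"poor AIF signal: peak {peak:.3g} mmol/l below QC floor {qc_floor:.3g}"
        )
    if method not in ("fit", "truncate"):
        raise ValueError("method must be 'fit' or 'truncate'")

    foot = _detect_foot(c)
    flags: list = []

    if method == "fit":
        window = _fit_window(c, foot, downslope_fraction)
        params, converged, rms = fit_gamma_variate(t, c, window)
        if converged:
            centroid = gamma_variate_centroid(params["t0"], params["alpha"], params["beta"])
            fp = gamma_variate(t, params["amplitude"], params["t0"],
                               params["alpha"], params["beta"])
            return FirstPassModel("fit", params, window, True, rms, centroid, fp, flags)
        flags.append("fit_nonconvergent_fallback_truncate")
        method = "truncate"
        rms_fit = rms
    else:
        rms_fit = np.nan

    stop = _truncate_at_recirc(c)
    fp = np.zeros_like(c)
    fp[:stop] = c[:stop]
    centroid = curve_centroid(t, fp)
    return FirstPassModel("truncate", None, (0, stop), True, rms_fit, centroid, fp, flags)


# --------------------------------------------------------------------------
# the estimator
# --------------------------------------------------------------------------

class PTTEstimator(BaseEstimator):
    """Centroid-based pulmonary transit time estimator.

    Applies recirculation exclusion to both cavities with the same method,
    takes the centroid difference (LV minus RV), and normalizes by the R-R
    interval.

    Parameters
    ----------
    method : {"fit", "truncate"}
        Recirculation-exclusion strategy (see :func:`remove_recirculation`).
    downslope_fraction : float
        Fit-window end: first post-peak sample below this fraction of peak.
    qc_floor : float
        Minimum acceptable peak concentration, mmol/l.
    plausibility_window : (float, float)
        Physiological PTT range in seconds; values outside are flagged.

    Fitted attributes
    -----------------
    ptt_, pttn_, centroid_rv_, centroid_lv_ : float
    qc_flags_ : list of str
    result_ : PTTResult
    """

    def __init__(self, method: str = "fit", downslope_fraction: float = 0.4,
                 qc_floor: float = DEFAULT_QC_FLOOR,
                 plausibility_window: tuple = PLAUSIBILITY_WINDOW):
        self.method = method
        self.downslope_fraction = downslope_fraction
        self.qc_floor = qc_floor
        self.plausibility_window = plausibility_window

    def fit(self, pair: AIFCurvePair, y=None):
        rv_model = remove_recirculation(pair.rv, self.method,
                                        self.downslope_fraction, self.qc_floor)
        lv_model = remove_recirculation(pair.lv, self.method,
                                        self.downslope_fraction, self.qc_floor)
        flags = list(pair.qc_flags) + [f"rv_{f}" for f in rv_model.flags] \
            + [f"lv_{f}" for f in lv_model.flags]

        ptt = lv_model.centroid - rv_model.centroid
        pttn = normalize_ptt(ptt, pair.rr_interval)
        valid = True
        if ptt <= 0:
            flags.append("invalid_nonpositive_ptt_labels_likely_swapped")
            valid = False
        else:
            lo, hi = self.plausibility_window
            if not lo <= ptt <= hi:
                flags.append("ptt_outside_plausible_range")

        self.result_ = PTTResult(
            centroid_rv=rv_model.centroid, centroid_lv=lv_model.centroid,
            ptt=ptt, pttn=pttn,
            method="centroid-of-fit" if self.method == "fit" else "centroid-of-truncated-curve",
            valid=valid, qc_flags=flags, rv_model=rv_model, lv_model=lv_model,
        )
        self.centroid_rv_ = rv_model.centroid
        self.centroid_lv_ = lv_model.centroid
        self.ptt_ = ptt
        self.pttn_ = pttn
        self.qc_flags_ = flags
        return self

    def predict(self, pair: AIFCurvePair = None) -> float:
        if not hasattr(self, "result_"):
            if pair is None:
                raise RuntimeError("estimator is not fitted")
            self.fit(pair)
        return self.ptt_


def estimate_ptt(pair: AIFCurvePair, **params) -> PTTResult:
    """Functional wrapper over :class:`PTTEstimator`."""
    return PTTEstimator(**params).fit(pair).result_


# --------------------------------------------------------------------------
# quality control
# --------------------------------------------------------------------------

@dataclass
class QCReport:
    """Structured exclusion-category report for one curve pair."""

    flags: list
    recommendation: str  # "include" or "exclude"

    def as_dict(self) -> dict:
        return {"flags": list(self.flags), "recommendation": self.recommendation}


#: flags that warrant exclusion (the erroneous-perfusion-data categories)
EXCLUSION_FLAGS = frozenset({
    "blood_pool_identification_failure",
    "incorrect_contrast_timing",
    "poor_aif_signal",
    "invalid_nonpositive_ptt_labels_likely_swapped",
})


def qc_report(pair: AIFCurvePair, result: PTTResult | None = None,
              qc_floor: float = DEFAULT_QC_FLOOR) -> QCReport:
    """Assess a curve pair against the exclusion categories.

    Categories: poor AIF signal (peak below the QC floor), incorrect
    contrast timing (enhancement already present at the first frame, so no
    baseline exists), non-positive PTT, implausible PTT, and fit
    non-convergence; plus any flags carried by the pair or result.
    """
    flags = list(pair.qc_flags)
    for curve in (pair.rv, pair.lv):
        if curve.peak < qc_floor and "poor_aif_signal" not in flags:
            flags.append("poor_aif_signal")
        if curve.conc[0] > 0.1 * max(curve.peak, qc_floor) and \
                "incorrect_contrast_timing" not in flags:
            flags.append("incorrect_contrast_timing")
    if result is not None:
        for f in result.qc_flags:
            if f not in flags:
                flags.append(f)
    recommendation = "exclude" if any(f in EXCLUSION_FLAGS for f in flags) else "include"
    return QCReport(flags=flags, recommendation=recommendation)
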