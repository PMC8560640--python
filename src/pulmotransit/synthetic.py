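"""Synthetic indicator-dilution and cohort data with known ground truth.

Three generators make every downstream stage testable without any download:

* :func:`generate_aif_pair` — paired RV/LV gadolinium concentration-time
  curves sampled once per heartbeat: a gamma-variate first pass, a delayed
  attenuated recirculation component, and additive noise.
* :func:`generate_dynamic_series` — a low-resolution dynamic short-axis
  image phantom with RV cavity, LV cavity, myocardial ring and background
  compartments, plus the true segmentation masks.
* :func:`generate_cohort` — a patient cohort table with covariates, a known
  log-PTT generating model, hemodynamic derivations, and right-censored
  time-to-MACE outcomes drawn from a Weibull proportional-hazards model.

Ground truth transit is defined on the noiseless, recirculation-free
components: the pulmonary transit time is the difference between the LV and
RV first-pass centroids, computed by trapezoidal quadrature on a fine grid
(``ORACLE_DT`` = 0.01 s).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .curves import AIFCurve, AIFCurvePair
from .hemodynamics import body_surface_area, cardiac_output, pulmonary_blood_volume, pbvi
from .saturation import HyperbolicSaturation

#: quadrature resolution of the ground-truth centroid oracle, seconds
ORACLE_DT = 0.01


# --------------------------------------------------------------------------
# curve phantom
# --------------------------------------------------------------------------

@dataclass
class TransitPhantomConfig:
    """Generating parameters of one paired-curve phantom.

    The first pass in the RV is a gamma-variate ``A*(t-t0)^alpha*exp(-(t-t0)/beta)``;
    the LV first pass is the RV curve convolved with a truncated-Gaussian
    transport kernel of mean ``transit_mean`` and SD ``transit_dispersion``.
    Each cavity additionally receives its own first pass delayed by
    ``recirc_delay`` and scaled by ``recirc_fraction`` (systemic
    recirculation), then Gaussian noise of SD ``noise_sd``.  Curves are
    sampled exactly once per ``rr_interval`` over ``n_frames`` heartbeats.
    """

    alpha: float = 3.0            # gamma-variate shape (dimensionless)
    beta: float = 2.0             # gamma-variate scale (s)
    t0_rv: float = 4.0            # RV bolus arrival (s)
    transit_mean: float = 7.7     # true pulmonary transit time (s)
    transit_dispersion: float = 1.0  # transport-kernel SD (s)
    recirc_delay: float = 15.0    # recirculation lag (s)
    recirc_fraction: float = 0.3  # recirculation amplitude / first-pass peak
    rr_interval: float = 0.9      # cardiac cycle length (s)
    n_frames: int = 90            # heartbeats imaged
    noise_sd: float = 0.05        # additive noise SD (mmol/l)
    peak_conc: float = 5.0        # first-pass peak concentration (mmol/l)
    seed: int = 0

    def validate(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("gamma-variate alpha and beta must be positive")
        if self.transit_mean <= 0:
            raise ValueError("transit_mean must be positive")
        if self.transit_dispersion < 0:
            raise ValueError("transit_dispersion must be non-negative")
        if self.rr_interval <= 0:
            raise ValueError("rr_interval must be positive")
        if not 0 <= self.recirc_fraction < 1:
            raise ValueError("recirc_fraction must lie in [0, 1)")
        if self.n_frames < 20:
            raise ValueError("n_frames must be at least 20")
        if self.noise_sd < 0 or self.peak_conc <= 0:
            raise ValueError("noise_sd must be >= 0 and peak_conc > 0")
        window = self.n_frames * self.rr_interval
        needed = self.t0_rv + self.transit_mean + 5.0 * self.beta * (self.alpha + 1.0)
        if needed > window:
            raise ValueError(
                f"first pass not captured: bolus needs {needed:.1f} s but the imaged "
                f"window is only {window:.1f} s; increase n_frames"
            )

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.rr_interval


@dataclass
class GroundTruthTransit:
    """True transit quantities of a phantom, from the quadrature oracle."""

    true_ptt: float
    true_centroid_rv: float
    true_centroid_lv: float
    true_pttn: float


def gamma_variate(t, amplitude: float, t0: float, alpha: float, beta: float):
    """Gamma-variate bolus model, zero before onset ``t0``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    m = t > t0
    x = t[m] - t0
    out[m] = amplitude * x**alpha * np.exp(-x / beta)
    return out


def gamma_variate_amplitude(peak: float, alpha: float, beta: float) -> float:
    """Amplitude giving the requested peak value (peak occurs at t0 + alpha*beta)."""
    return peak / ((alpha * beta) ** alpha * np.exp(-alpha))


def gamma_variate_centroid(t0: float, alpha: float, beta: float) -> float:
    """Closed-form first moment of the gamma-variate: t0 + beta*(alpha+1)."""
    return t0 + beta * (alpha + 1.0)


def _transport_kernel(mean: float, sd: float, dt: float) -> np.ndarray:
    """Truncated-Gaussian lag kernel on [0, inf), renormalized to unit area.

    Grid values are the Gaussian density at lag samples; truncation below
    zero lag is corrected by renormalization so the kernel mean stays close
    to ``mean`` (exact for mean >> sd).
    """
    upper = mean + 8.0 * sd
    lags = np.arange(0.0, upper + dt, dt)
    k = np.exp(-0.5 * ((lags - mean) / sd) ** 2)
    area = np.trapezoid(k, dx=dt)
    if area <= 0:
        raise ValueError("degenerate transport kernel")
    return k / area


def _first_pass_components(config: TransitPhantomConfig, t_end: float):
    """Noiseless recirculation-free RV/LV first passes on the oracle grid."""
    dt = ORACLE_DT
    t_fine = np.arange(0.0, t_end + dt, dt)
    amp = gamma_variate_amplitude(config.peak_conc, config.alpha, config.beta)
    rv_fine = gamma_variate(t_fine, amp, config.t0_rv, config.alpha, config.beta)
    if config.transit_dispersion < dt:
        # pure-delay limit: evaluate analytically, no discrete convolution
        lv_fine = gamma_variate(
            t_fine, amp, config.t0_rv + config.transit_mean, config.alpha, config.beta
        )
    else:
        kernel = _transport_kernel(config.transit_mean, config.transit_dispersion, dt)
        lv_fine = np.convolve(rv_fine, kernel)[: t_fine.size] * dt
    return t_fine, rv_fine, lv_fine, amp


def _quadrature_centroid(t: np.ndarray, c: np.ndarray) -> float:
    return float(np.trapezoid(t * c, t) / np.trapezoid(c, t))


def generate_aif_pair(config: TransitPhantomConfig):
    """Generate a paired RV/LV curve phantom.

    Returns
    -------
    pair : AIFCurvePair
        Noisy curves sampled once per heartbeat (concentrations clipped at 0).
    truth : GroundTruthTransit
        Centroids and PTT of the noiseless, recirculation-free first passes,
        computed by quadrature on the fine oracle grid.
    """
    config.validate()
    window = config.n_frames * config.rr_interval
    # extend the oracle grid far enough that tail truncation is negligible
    tail = config.beta * stats.gamma.ppf(1.0 - 1e-13, config.alpha + 1.0)
    t_end = max(window, config.t0_rv + config.transit_mean
                + 8.0 * config.transit_dispersion + tail)
    t_fine, rv_fine, lv_fine, amp = _first_pass_components(config, t_end)

    c_rv = _quadrature_centroid(t_fine, rv_fine)
    c_lv = _quadrature_centroid(t_fine, lv_fine)
    truth = GroundTruthTransit(
        true_ptt=c_lv - c_rv,
        true_centroid_rv=c_rv,
        true_centroid_lv=c_lv,
        true_pttn=(c_lv - c_rv) / config.rr_interval,
    )

    ft = config.frame_times
    # RV first pass is analytic at the sample times; LV interpolated off the
    # fine grid (exact in the pure-delay limit where it too is analytic)
    rv_fp = gamma_variate(ft, amp, config.t0_rv, config.alpha, config.beta)
    if config.transit_dispersion < ORACLE_DT:
        lv_fp = gamma_variate(ft, amp, config.t0_rv + config.transit_mean,
                              config.alpha, config.beta)
        lv_fp_delayed = gamma_variate(ft - config.recirc_delay, amp,
                                      config.t0_rv + config.transit_mean,
                                      config.alpha, config.beta)
    else:
        lv_fp = np.interp(ft, t_fine, lv_fine)
        lv_fp_delayed = np.interp(ft - config.recirc_delay, t_fine, lv_fine,
                                  left=0.0)
    rv_fp_delayed = gamma_variate(ft - config.recirc_delay, amp, config.t0_rv,
                                  config.alpha, config.beta)

    rv_total = rv_fp + config.recirc_fraction * rv_fp_delayed
    lv_total = lv_fp + config.recirc_fraction * lv_fp_delayed

    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        rv_total = rv_total + rng.normal(0.0, config.noise_sd, size=ft.size)
        lv_total = lv_total + rng.normal(0.0, config.noise_sd, size=ft.size)
    rv_total = np.clip(rv_total, 0.0, None)
    lv_total = np.clip(lv_total, 0.0, None)

    pair = AIFCurvePair(
        rv=AIFCurve(ft, rv_total, "RV"),
        lv=AIFCurve(ft, lv_total, "LV"),
        rr_interval=config.rr_interval,
    )
    return pair, truth


# --------------------------------------------------------------------------
# image phantom
# --------------------------------------------------------------------------

@dataclass
class PhantomGeometry:
    """Compartment layout of the dynamic short-axis phantom.

    Cavities are disks on a small grid; the myocardium is an annulus around
    the LV cavity; everything else is static background tissue.
    """

    shape: tuple = (64, 64)
    rv_center: tuple = (24, 17)
    rv_radius: float = 8.0
    lv_center: tuple = (38, 44)
    lv_radius: float = 10.0
    myo_outer_radius: float = 14.0

    def masks(self):
        rows, cols = np.ogrid[: self.shape[0], : self.shape[1]]
        d_rv = np.hypot(rows - self.rv_center[0], cols - self.rv_center[1])
        d_lv = np.hypot(rows - self.lv_center[0], cols - self.lv_center[1])
        rv = d_rv <= self.rv_radius
        lv = d_lv <= self.lv_radius
        myo = (d_lv > self.lv_radius) & (d_lv <= self.myo_outer_radius) & ~rv
        if np.any(rv & lv):
            raise ValueError("RV and LV cavity regions overlap")
        if not rv.any() or not lv.any():
            raise ValueError("cavity regions are empty on this grid")
        return rv, lv, myo


def generate_dynamic_series(
    config: TransitPhantomConfig,
    geometry: PhantomGeometry | None = None,
    calib: HyperbolicSaturation | None = None,
    pixel_snr: float | None = None,
    myo_fraction: float = 0.15,
    myo_delay: float = 3.0,
    background_level: float = 0.6,
):
    """Render the curve phantom into a dynamic image stack.

    Pixel intensities inside each cavity follow that cavity's noiseless
    concentration curve passed through the forward saturation model; the
    myocardium follows a delayed, attenuated copy of the LV curve; the
    background is static.  ``pixel_snr`` sets Gaussian pixel noise as
    (peak cavity enhancement signal)/SD; ``None`` means noiseless.

    Returns the series and the true segmentation masks.
    """
    from .extraction import DynamicSeries, SegmentationMasks  # local: avoid cycle

    config.validate()
    geometry = geometry or PhantomGeometry()
    calib = calib or HyperbolicSaturation()
    rv_mask, lv_mask, myo_mask = geometry.masks()

    noiseless = dataclasses.replace(config, noise_sd=0.0)
    pair, _ = generate_aif_pair(noiseless)
    ft = config.frame_times
    rv_conc = pair.rv.conc
    lv_conc = pair.lv.conc
    myo_conc = myo_fraction * np.interp(ft - myo_delay, ft, lv_conc, left=0.0)

    s0 = calib.s0
    rv_sig = s0 * (1.0 + calib.forward(rv_conc))
    lv_sig = s0 * (1.0 + calib.forward(lv_conc))
    myo_sig = s0 * (1.0 + calib.forward(myo_conc))
    bg_sig = background_level * s0

    frames = np.full((config.n_frames,) + tuple(geometry.shape), bg_sig)
    frames[:, rv_mask] = rv_sig[:, None]
    frames[:, lv_mask] = lv_sig[:, None]
    frames[:, myo_mask] = myo_sig[:, None]

    if pixel_snr is not None:
        if pixel_snr <= 0:
            raise ValueError("pixel_snr must be positive")
        amp = s0 * float(calib.forward(config.peak_conc))
        rng = np.random.default_rng(config.seed)
        frames = frames + rng.normal(0.0, amp / pixel_snr, size=frames.shape)

    series = DynamicSeries(frames=frames, frame_times=ft, rr_interval=config.rr_interval)

    def _arrival(conc):
        thr = 0.05 * conc.max()
        return int(np.argmax(conc > thr))

    masks = SegmentationMasks(
        rv_mask=rv_mask,
        lv_mask=lv_mask,
        arrival_frame_rv=_arrival(rv_conc),
        arrival_frame_lv=_arrival(lv_conc),
    )
    return series, masks


# --------------------------------------------------------------------------
# outcome cohort
# --------------------------------------------------------------------------

#: generating coefficients of the log_e PTT model (per covariate unit)
DEFAULT_LOG_PTT_BETAS: dict[str, float] = {
    "la_area_index": 0.019,
    "heart_rate": -0.008,
    "age": 0.003,
    "atrial_fibrillation": 0.118,
    "lvef": -0.007,
    "diabetes": -0.060,
    "hypertension": -0.038,
    "rest_mbf": -0.098,
    "male": 0.052,
}

#: MACE sub-type sampling weights (myocardial infarction, stroke,
#: heart-failure admission, VT / appropriate ICD therapy)
EVENT_TYPES = ("mi", "stroke", "hf_admission", "vt_icd")
EVENT_TYPE_WEIGHTS = (29 / 71, 10 / 71, 23 / 71, 9 / 71)


@dataclass
class CohortConfig:
    """Generating model of a synthetic outcome cohort.

    Covariates are drawn from independent marginals with clinically typical
    means/SDs and prevalences; ``log_e PTT`` is a linear predictor over them
    plus Gaussian noise; event times come from a Weibull proportional-hazards
    model whose log hazard is ``log_hr_per_sd_ptt * (PTT - ptt_ref)/hazard_ptt_sd``.
    ``baseline_hazard_scale`` is a hazard-rate multiplier (per month):
    ``H0(t) = (scale * t)^shape``, so a larger scale strictly increases the
    expected event count.
    """

    n_subjects: int = 1000
    # continuous covariates: (mean, sd)
    age: tuple = (62.0, 13.0)
    lvef: tuple = (61.0, 11.0)
    heart_rate: tuple = (68.0, 12.0)
    la_area_index: tuple = (12.0, 2.8)
    mpr: tuple = (2.4, 0.8)
    rest_mbf: tuple = (0.9, 0.25)
    stroke_volume: tuple = (87.0, 18.0)
    height: tuple = (170.0, 10.0)
    weight: tuple = (82.0, 16.0)
    # binary prevalences
    male_prev: float = 0.67
    diabetes_prev: float = 0.286
    hypertension_prev: float = 0.60
    dyslipidemia_prev: float = 0.487
    af_prev: float = 0.131
    lge_prev: float = 0.42
    prior_revasc_prev: float = 0.31
    # log PTT generating model
    log_ptt_betas: dict = field(default_factory=lambda: dict(DEFAULT_LOG_PTT_BETAS))
    log_ptt_intercept: float = 2.686
    log_ptt_noise_sd: float = 0.26
    # survival model
    baseline_hazard_scale: float = 0.0024  # per month
    baseline_hazard_shape: float = 1.0
    log_hr_per_sd_ptt: float = 0.0
    hazard_ptt_sd: float = 2.4   # s, the per-SD scale of the generating hazard
    hazard_ptt_ref: float = 8.0  # s, centering of the hazard linear predictor
    followup_min: float = 20.0   # months
    followup_max: float = 40.0   # months
    censor_rate: float = 0.0
    early_revasc_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        for name in ("age", "lvef", "heart_rate", "la_area_index", "mpr",
                     "rest_mbf", "stroke_volume", "height", "weight"):
            mean, sd = getattr(self, name)
            if sd <= 0:
                raise ValueError(f"{name} SD must be positive")
        for name in ("male_prev", "diabetes_prev", "hypertension_prev",
                     "dyslipidemia_prev", "af_prev", "lge_prev",
                     "prior_revasc_prev", "censor_rate", "early_revasc_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.baseline_hazard_scale <= 0 or self.baseline_hazard_shape <= 0:
            raise ValueError("baseline hazard parameters must be positive")
        if self.log_ptt_noise_sd < 0 or self.hazard_ptt_sd <= 0:
            raise ValueError("log_ptt_noise_sd must be >= 0 and hazard_ptt_sd > 0")
        if not 0 < self.followup_min <= self.followup_max:
            raise ValueError("follow-up window must satisfy 0 < min <= max")


# physiological clipping ranges applied before the log-PTT model is evaluated
_CLIP = {
    "age": (18.0, 95.0),
    "lvef": (10.0, 80.0),
    "heart_rate": (35.0, 140.0),
    "la_area_index": (4.0, 25.0),
    "mpr": (0.5, 5.0),
    "rest_mbf": (0.3, 2.0),
    "stroke_volume": (30.0, 160.0),
    "height": (140.0, 200.0),
    "weight": (40.0, 160.0),
}


def generate_cohort(config: CohortConfig):
    """Draw a synthetic cohort table (one row per subject).

    Covariates are clipped to physiological ranges *before* the log-PTT
    model is evaluated, so the generating linear model holds exactly on the
    delivered table.  PBVi is derived through the hemodynamics operations
    from the simulated stroke volume, heart rate, height and weight.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    def draw(name):
        mean, sd = getattr(config, name)
        lo, hi = _CLIP[name]
        return np.clip(rng.normal(mean, sd, n), lo, hi)

    df = pd.DataFrame({"id": np.arange(n)})
    for name in _CLIP:
        df[name] = draw(name)
    df["male"] = (rng.random(n) < config.male_prev).astype(int)
    df["diabetes"] = (rng.random(n) < config.diabetes_prev).astype(int)
    df["hypertension"] = (rng.random(n) < config.hypertension_prev).astype(int)
    df["dyslipidemia"] = (rng.random(n) < config.dyslipidemia_prev).astype(int)
    df["atrial_fibrillation"] = (rng.random(n) < config.af_prev).astype(int)
    df["lge_present"] = (rng.random(n) < config.lge_prev).astype(int)
    df["prior_mi_pci_cabg"] = (rng.random(n) < config.prior_revasc_prev).astype(int)

    lin = np.full(n, config.log_ptt_intercept)
    for cov, beta in config.log_ptt_betas.items():
        lin = lin + beta * df[cov].to_numpy(dtype=float)
    log_ptt = lin + rng.normal(0.0, config.log_ptt_noise_sd, n)
    df["ptt"] = np.exp(log_ptt)
    rr = 60.0 / df["heart_rate"].to_numpy()
    df["pttn"] = df["ptt"] / rr

    co = [cardiac_output(sv, hr) for sv, hr in zip(df["stroke_volume"], df["heart_rate"])]
    df["cardiac_output_l_min"] = [c.l_per_min for c in co]
    df["bsa"] = [body_surface_area(h, w) for h, w in zip(df["height"], df["weight"])]
    df["pbv"] = [pulmonary_blood_volume(p, c.ml_per_s)
                 for p, c in zip(df["ptt"], co)]
    df["pbvi"] = [pbvi(v, b) for v, b in zip(df["pbv"], df["bsa"])]

    # Weibull proportional hazards: H(t) = (scale*t)^shape * exp(eta)
    eta = config.log_hr_per_sd_ptt * (df["ptt"].to_numpy() - config.hazard_ptt_ref) / config.hazard_ptt_sd
    u = rng.random(n)
    t_event = (-np.log(u) * np.exp(-eta)) ** (1.0 / config.baseline_hazard_shape) / config.baseline_hazard_scale

    c_admin = rng.uniform(config.followup_min, config.followup_max, n)
    dropped = rng.random(n) < config.censor_rate
    c_extra = np.where(
        dropped,
        rng.uniform(0.0, (1.0 - config.censor_rate) * config.followup_max, n),
        np.inf,
    )
    c_total = np.minimum(c_admin, c_extra)
    event = t_event <= c_total
    df["followup_time"] = np.where(event, t_event, c_total)
    df["event"] = event.astype(int)
    types = rng.choice(EVENT_TYPES, size=n, p=EVENT_TYPE_WEIGHTS)
    df["event_type"] = np.where(event, types, "none")

    revasc = rng.random(n) < config.early_revasc_fraction
    df["early_revasc_days"] = np.where(revasc, rng.uniform(1.0, 90.0, n), np.nan)
    return df
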