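# pulmotransit

Automated estimation of **pulmonary transit time (PTT)** and **pulmonary
blood volume (PBV)** from first-pass perfusion arterial input function (AIF)
curves, with the cohort-level survival analyses used to evaluate them as
prognostic biomarkers.

## Who this is for

Researchers working with dynamic contrast-enhanced cardiac imaging who want
to derive cardiopulmonary biomarkers from paired right-ventricular (RV) and
left-ventricular (LV) blood-pool concentration curves, and to analyze their
association with clinical outcomes. Because individual-level clinical data
of this kind are rarely shareable, the package ships a synthetic-data module
that generates curve phantoms, dynamic image phantoms and outcome cohorts
with known ground truth, so every stage is testable end to end.

## The model

During first pass of a gadolinium bolus, the concentration-time curve in
each cavity is well described by a gamma-variate

    c(t) = A (t - t0)^alpha exp(-(t - t0)/beta),   t > t0,

whose center of gravity (first moment) is `t0 + beta (alpha + 1)`. The
pulmonary transit time is the time between the centroids of the LV and RV
AIF curves after excluding the systemic recirculation component:

    PTT   = centroid(LV) - centroid(RV)
    PTTn  = PTT / RR-interval            (transit expressed in heartbeats)
    PBV   = PTT x cardiac output         (indicator-dilution relation)
    PBVi  = PBV / BSA                    (indexed to body surface area)

Recirculation is excluded by fitting the gamma-variate over the first-pass
window (curve foot to the downslope at 40% of peak) and using its
closed-form centroid; a model-free fallback truncates the measured curve at
the post-peak minimum before any secondary rise. Curves are sampled once
per heartbeat, matching how perfusion imaging acquires one frame per
cardiac cycle.

Cohort analysis reports hazard ratios per one standard deviation of the
biomarker from Cox proportional-hazards models (Efron ties, Schoenfeld
residual diagnostics, optional penalized sensitivity refit), a multivariable
OLS of log PTT on clinical covariates, and mean-dichotomized Kaplan-Meier
curves with log-rank tests.

## Worked example

```bash
$ pulmotransit simulate --seed 1 --out demo --what curves
wrote demo/aif_pair.csv (true PTT 7.700 s)

$ pulmotransit estimate --aif demo/aif_pair.csv --out demo/result.json
PTT = 7.511 s, PTTn = 8.345 (include)

$ pulmotransit derive --sv 87 --hr 68 --height 172 --weight 80 --ptt 7.511
CO = 5.92 l/min, BSA = 1.955 m^2, PBV = 741 ml, PBVi = 379 ml/m^2
```

The simulated pair has a true transit of 7.700 s; the centroid estimator
recovers 7.511 s from noisy once-per-heartbeat samples (error about a fifth
of the 0.9-s frame interval), and QC recommends inclusion. `derive` then
turns a stroke volume of 87 ml at 68 beats/min into a cardiac output of
5.92 l/min, a Mosteller body surface area of 1.955 m^2, and a pulmonary
blood volume of 741 ml (379 ml/m^2 indexed) — values in the range typical
of clinical cohorts.

The same operations are available as a library:

```python
from pulmotransit import TransitPhantomConfig, generate_aif_pair, estimate_ptt

pair, truth = generate_aif_pair(TransitPhantomConfig(seed=1))
result = estimate_ptt(pair)          # PTTEstimator under the hood
print(result.ptt, truth.true_ptt)    # 7.511 vs 7.700 s
```

and the full synthetic pipeline (cohort -> curves -> estimation ->
hemodynamics -> outcome models) runs with `pulmotransit run --seed 1 --out
rundir`, writing per-stage CSV/JSON outputs and a manifest whose hashes are
bitwise-reproducible for a fixed seed.

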