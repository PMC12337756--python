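"""Validation experiments: each function recomputes, from scratch, one
quantitative check of the pipeline under the study's conditions —
closed-form sinuosity values, Monte-Carlo estimator consistency for
CRW tracks, a grid-search audit of the geometric median, exact
time-budget recovery, mixed-model coefficient recovery and null
calibration, residual-diagnostic calibration and power, and a
known-coefficient exercise of the reproduction harness.

Every function takes a ``seed`` and is deterministic given it.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .diagnostics import residual_diagnostics
from .glmm import MovementGLMM, MovementGLMMResults
from .metrics import SegmentGeometry, sinuosity, summarize_track
from .pipeline import default_roster, reproduce
from .simulate import (
    StudySimConfig,
    TrackSimConfig,
    kappa_for_mean_cos,
    simulate_study,
    simulate_track,
    theoretical_sinuosity,
)
from .stops import consolidate, geometric_median
from .stats import ModelSpec, fit_glmm, scale_predictors, transform_response


import contextlib


@contextlib.contextmanager
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def _seg(p: float, c: float, b: float) -> SegmentGeometry:
    return SegmentGeometry(np.array([p]), np.array([math.acos(max(min(c, 1.0), -1.0))]),
                           p=p, c=c, b=b)


def sinuosity_closed_forms() -> dict[str, float]:
    """Eq.-style spot values of the corrected sinuosity."""
    return {
        "sin_p1_c0_b0": sinuosity(_seg(1.0, 0.0, 0.0)),
        "sin_p4_c0_b0": sinuosity(_seg(4.0, 0.0, 0.0)),
        "sin_p1_c05_b0": sinuosity(_seg(1.0, 0.5, 0.0)),
        "sin_straight": sinuosity(_seg(1.0, 1.0, 0.0)),
    }


def crw_consistency(n_tracks: int = 500, n_steps: int = 200, p: float = 1.0,
                    c: float = 0.5, b: float = 0.3, seed: int = 0) -> dict[str, float]:
    """Mean pipeline-estimated sinuosity over CRW tracks vs. the
    generating closed form, with its Monte-Carlo standard error."""
    cfg = TrackSimConfig(n_steps=n_steps, step_mean_p=p, step_cv_b=b,
                         turn_kappa=kappa_for_mean_cos(c),
                         stop_rate=0.0, gap_prob=0.0)
    rng = np.random.default_rng(seed)
    est = []
    with _quiet():
        for _ in range(n_tracks):
            traj, events, _ = simulate_track(cfg, seed=int(rng.integers(2**31)))
            est.append(summarize_track(consolidate(traj, events)).sinuosity)
    est = np.asarray(est)
    theory = theoretical_sinuosity(p, c, b)
    se = float(est.std(ddof=1) / np.sqrt(n_tracks))
    return {
        "mean_estimate": float(est.mean()),
        "theory": theory,
        "mc_se": se,
        "z": float((est.mean() - theory) / se),
    }


def _grid_search_median(points: np.ndarray, resolution: float = 1e-3) -> np.ndarray:
    """Independent route: refined grid search of the (convex) distance
    sum over the bounding box, to ``resolution`` metres."""
    pts = np.asarray(points, float)
    lo = pts.min(axis=0) - 1.0
    hi = pts.max(axis=0) + 1.0
    center = (lo + hi) / 2.0
    span = float((hi - lo).max()) / 2.0
    while True:
        gx = np.linspace(center[0] - span, center[0] + span, 41)
        gy = np.linspace(center[1] - span, center[1] + span, 41)
        X, Y = np.meshgrid(gx, gy)
        obj = sum(np.hypot(X - px, Y - py) for px, py in pts)
        k = np.unravel_index(np.argmin(obj), obj.shape)
        center = np.array([X[k], Y[k]])
        step = gx[1] - gx[0]
        if step <= resolution:
            return center
        span = 2.0 * step


def geometric_median_audit(n_clouds: int = 50, seed: int = 0) -> dict[str, float]:
    """Worst disagreement between the Weiszfeld solver and the grid
    oracle over random 3-10 point clouds, metres."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_clouds):
        pts = rng.normal(0.0, 1.5, size=(int(rng.integers(3, 11)), 2))
        ours = np.asarray(geometric_median(pts, tol=1e-6))
        oracle = _grid_search_median(pts)
        worst = max(worst, float(np.hypot(*(ours - oracle))))
    return {"max_error_m": worst, "n_clouds": float(n_clouds)}


def time_budget_exactness(n_tracks: int = 100, seed: int = 0) -> dict[str, float]:
    """Worst deviation between pipeline time-budget shares and a
    per-second enumeration of the generating event log."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    with _quiet():
        for _ in range(n_tracks):
            cfg = TrackSimConfig(n_steps=int(rng.integers(60, 240)),
                                 stop_rate=float(rng.uniform(1.0, 6.0)),
                                 stop_duration_mean_s=float(rng.uniform(5.0, 30.0)),
                                 gap_prob=0.02)
            traj, events, _ = simulate_track(cfg, seed=int(rng.integers(2**31)))
            pt = consolidate(traj, events)
            summary = summarize_track(pt)
            stopping, nectaring, resting = summary.stopping, summary.nectaring, summary.resting
            t0, t1 = int(pt.t[0]), int(pt.t[-1])
            n_stop = n_nect = n_rest = 0
            for s in range(t0, t1):
                for ev in events:
                    if ev.start_s <= s < ev.end_s:
                        n_stop += 1
                        n_nect += ev.activity.value == "nectaring"
                        n_rest += ev.activity.value == "resting"
                        break
            dur = t1 - t0
            worst = max(worst,
                        abs(stopping - n_stop / dur),
                        abs(nectaring - n_nect / dur),
                        abs(resting - n_rest / dur))
    return {"max_share_error": worst, "n_tracks": float(n_tracks)}


def _fit_study_table(summaries, covariates, response="stopping",
                     family="beta_logit", fixed=None):
    drop = [c for c in ("habitat_area", "np_cov")
            if c in covariates.columns and c in summaries.columns]
    tab = summaries.merge(covariates.drop(columns=drop),
                          left_on="site", right_on="site_id")
    tab = tab.rename(columns={"urbanization_2000": "urbanization"})
    spec = ModelSpec(response=response, family=family, transformation="none",
                     fixed=fixed or ["np_cov", "urbanization"])
    tab = tab.copy()
    tab["__y"] = transform_response(tab[response], spec)
    scaled, _ = scale_predictors(tab, [c for c in spec.fixed if c != "sex"])
    return fit_glmm(spec, scaled, response_col="__y")


def glmm_recovery(n_reps: int = 200, n_sites: int = 30, n_per_site: int = 20,
                  effect: float = 0.15, seed: int = 0) -> dict[str, float]:
    """Mean coefficient estimates over replicated beta-GLMM studies
    with true logit-scale effects (+effect, -effect)."""
    rng = np.random.default_rng(seed)
    ests = []
    with _quiet():
        for _ in range(n_reps):
            cfg = StudySimConfig(n_sites=n_sites, n_per_site=n_per_site,
                                 true_coefs={"np_cov": effect, "urbanization": -effect})
            summ, cov, _ = simulate_study(cfg, seed=int(rng.integers(2**31)))
            fit = _fit_study_table(summ, cov)
            idx = {nme: i for i, nme in enumerate(fit.model.exog_names)}
            ests.append([fit.params[idx["np_cov"]], fit.params[idx["urbanization"]]])
    ests = np.asarray(ests)
    return {
        "true_np_cov": effect,
        "true_urbanization": -effect,
        "mean_np_cov": float(ests[:, 0].mean()),
        "mean_urbanization": float(ests[:, 1].mean()),
        "bias_np_cov": float(ests[:, 0].mean() - effect),
        "bias_urbanization": float(ests[:, 1].mean() + effect),
        "n_reps": float(n_reps),
    }


def glmm_null_type_i(n_reps: int = 200, n_sites: int = 30, n_per_site: int = 10,
                     alpha: float = 0.05, seed: int = 0) -> dict[str, float]:
    """Wald-test rejection rate when every true effect is zero."""
    rng = np.random.default_rng(seed)
    n_tests = n_rej = 0
    with _quiet():
        for _ in range(n_reps):
            cfg = StudySimConfig(n_sites=n_sites, n_per_site=n_per_site,
                                 true_coefs={"np_cov": 0.0, "urbanization": 0.0})
            summ, cov, _ = simulate_study(cfg, seed=int(rng.integers(2**31)))
            fit = _fit_study_table(summ, cov)
            idx = {nme: i for i, nme in enumerate(fit.model.exog_names)}
            for name in ("np_cov", "urbanization"):
                n_tests += 1
                n_rej += fit.pvalues[idx[name]] < alpha
    return {"type_i_rate": n_rej / n_tests, "n_tests": float(n_tests)}


def diagnostics_calibration(n_reps: int = 100, n_sites: int = 25, n_per_site: int = 6,
                            n_sim: int = 250, alpha: float = 0.05,
                            seed: int = 0) -> dict[str, float]:
    """KS-uniformity rejection rate when the fitted model is correct."""
    rng = np.random.default_rng(seed)
    rejections = 0
    with _quiet():
        for _ in range(n_reps):
            cfg = StudySimConfig(n_sites=n_sites, n_per_site=n_per_site)
            summ, cov, _ = simulate_study(cfg, seed=int(rng.integers(2**31)))
            fit = _fit_study_table(summ, cov)
            rep = residual_diagnostics(fit, n_sim=n_sim, seed=int(rng.integers(2**31)))
            rejections += rep.ks_uniformity_p < alpha
    return {"ks_rejection_rate": rejections / n_reps, "n_reps": float(n_reps)}


def diagnostics_dispersion_power(n_reps: int = 30, n_sites: int = 25,
                                 n_per_site: int = 6, n_sim: int = 250,
                                 inflation: float = 2.0, alpha: float = 0.05,
                                 seed: int = 0) -> dict[str, float]:
    """Fraction of replicates in which the dispersion test flags
    responses whose residual SD is ``inflation`` times (variance
    ``inflation**2`` times) what the fitted beta model expects."""
    rng = np.random.default_rng(seed)
    flagged = 0
    with _quiet():
        for _ in range(n_reps):
            cfg = StudySimConfig(n_sites=n_sites, n_per_site=n_per_site)
            summ, cov, _ = simulate_study(cfg, seed=int(rng.integers(2**31)))
            fit = _fit_study_table(summ, cov)
            mu = 1.0 / (1.0 + np.exp(-fit.fitted_linear(conditional=False)))
            y_infl = np.clip(mu + inflation * (fit.model.endog - mu), 1e-9, 1 - 1e-9)
            model2 = MovementGLMM(
                y_infl, fit.model.exog,
                dict(zip(fit.model.group_names, fit.model.group_codes)),
                family="beta_logit", exog_names=fit.model.exog_names)
            fit2 = MovementGLMMResults(
                model=model2, params=fit.params, cov_params=fit.cov_params,
                vc=fit.vc, dispersion=fit.dispersion,
                random_effects=fit.random_effects, llf=fit.llf, aic=fit.aic,
                converged=True)
            rep = residual_diagnostics(fit2, n_sim=n_sim, seed=int(rng.integers(2**31)))
            flagged += rep.dispersion_p < alpha
    return {"dispersion_flag_rate": flagged / n_reps, "n_reps": float(n_reps)}


def reproduction_harness_check(seed: int = 0) -> dict[str, float]:
    """Exercise `reproduce` on a synthetic stand-in for a deposited
    per-individual table (known coefficients at study-scale effect
    magnitudes) and report the worst coefficient error."""
    cfg = StudySimConfig(
        n_sites=29, n_per_site=12, response="flight_speed",
        family="beta_logit", transformation="divide_by_10",
        intercept=-2.3,  # ~1 m/s on the /10 scale
        true_coefs={"np_cov": -0.17, "urbanization": 0.14},
        sex_effect=0.35, species="PR", dispersion=60.0,
    )
    summaries, covariates, truth = simulate_study(cfg, seed=seed)
    table = summaries.merge(covariates.drop(columns=["habitat_area", "np_cov"]),
                            left_on="site", right_on="site_id").drop(columns="site_id")
    roster = [m for m in default_roster()
              if m.response == "flight_speed" and getattr(m, "species") == "PR"]
    with _quiet():
        models, _, fits = reproduce(table, roster=roster, seed=seed,
                                    radii=(2000.0,))
    (fit, radius, _aic) = next(iter(fits.values()))
    idx = {nme: i for i, nme in enumerate(fit.model.exog_names)}
    true = {"np_cov": truth["true_coefs"]["np_cov"],
            "urbanization": truth["true_coefs"]["urbanization"],
            "sex[male]": truth["sex_effect"]}
    errs = {k: fit.params[idx[k]] - v for k, v in true.items()}
    zs = {k: errs[k] / fit.bse[idx[k]] for k in true}
    return {
        "max_coef_error": float(max(abs(v) for v in errs.values())),
        "max_coef_error_se_units": float(max(abs(v) for v in zs.values())),
        "est_np_cov": float(fit.params[idx["np_cov"]]),
        "est_urbanization": float(fit.params[idx["urbanization"]]),
        "est_sex_male": float(fit.params[idx["sex[male]"]]),
        "n": float(fit.model.n_obs),
    }
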