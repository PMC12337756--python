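"""Synthetic data emulating the study's data-generating structure.

Four generators make every pipeline stage testable without field data:

* :func:`simulate_track` — a correlated random walk (CRW) observed at
  1-s resolution, with annotated stop bouts recorded as jittered point
  clouds and optional GPS dropout while flying. Turning increments are
  von Mises(0, kappa), whose mean cosine has the closed form
  c = I1(kappa)/I0(kappa); step lengths are gamma with mean ``p`` and
  CV ``b``. One CRW step spans one sampling second, so the generating
  (p, c, b) triple is exactly the quantity the estimators target and
  the theoretical sinuosity 2*[p((1+c)/(1-c) + b^2)]^(-1/2) is an
  analytic reference.
* :func:`simulate_transect` — i.i.d. per-segment nectar coverages.
* :func:`simulate_landscape` — a patchy biotope map with
  class-dependent sealing, partially masked, plus an optional
  monocentric city gradient.
* :func:`simulate_study` — per-individual response tables drawn from a
  beta or lognormal mixed model with known coefficients, in the same
  schema the pipeline writes, for parameter-recovery experiments.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0, i1
from shapely.geometry import Polygon

from .covariates import LandscapeInputs
from .raster import Raster
from .trajectory import Activity, Sex, Species, StopEvent, Trajectory, TransectRecord


def mean_cos_von_mises(kappa: float) -> float:
    """c = I1(kappa)/I0(kappa), the mean turning-angle cosine of a
    von Mises(0, kappa) increment."""
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    if kappa == 0.0:
        return 0.0
    if kappa > 500:  # asymptotic regime; avoids overflow in i0/i1
        return 1.0 - 1.0 / (2.0 * kappa)
    return float(i1(kappa) / i0(kappa))


def kappa_for_mean_cos(c: float) -> float:
    """Inverse of :func:`mean_cos_von_mises` by bracketing."""
    if not 0.0 <= c < 1.0:
        raise ValueError("target mean cosine must lie in [0, 1)")
    if c == 0.0:
        return 0.0
    return float(brentq(lambda k: mean_cos_von_mises(k) - c, 1e-8, 1e6))


def theoretical_sinuosity(p: float, c: float, b: float) -> float:
    return 2.0 * (p * ((1.0 + c) / (1.0 - c) + b**2)) ** -0.5


# ---------------------------------------------------------------------------
# track generator
# ---------------------------------------------------------------------------

@dataclass
class TrackSimConfig:
    """CRW-with-stops generator settings.

    Defaults emulate the field protocol: ~1 m/s flight in 1-s steps
    over roughly five and a half minutes, a couple of stops per minute
    with geometric bout lengths, an observer point-cloud jitter of a
    few decimetres while stopped, and occasional in-flight GPS loss.
    """

    n_steps: int = 336              # flight seconds (~ mean track duration)
    step_mean_p: float = 1.0        # m per 1-s step
    step_cv_b: float = 0.5
    turn_kappa: float = 1.1589      # mean turning cosine ~0.5
    stop_rate: float = 2.0          # landings per flight minute
    stop_duration_mean_s: float = 20.0  # geometric bout length
    activity_probs: dict[Activity, float] = field(default_factory=lambda: {
        Activity.NECTARING: 0.45,
        Activity.RESTING: 0.35,
        Activity.BASKING: 0.15,
        Activity.OVIPOSITION: 0.05,
    })
    jitter_sd: float = 0.3          # m, observer drift while the animal sits
    gap_prob: float = 0.01          # per flight fix dropout probability
    species: Species = Species.CP
    sex: Sex = Sex.UNKNOWN
    site_id: str = "S01"
    individual_id: str = "sim"
    seed: int | None = None

    def __post_init__(self):
        self.species = Species(self.species)
        self.sex = Sex(self.sex)
        self.activity_probs = {Activity(k): v for k, v in self.activity_probs.items()}
        if self.step_mean_p <= 0 or self.step_cv_b < 0 or self.turn_kappa < 0:
            raise ValueError("need p > 0, b >= 0, kappa >= 0")
        total = sum(self.activity_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"activity probabilities sum to {total}, not 1")

    @property
    def target_c(self) -> float:
        return mean_cos_von_mises(self.turn_kappa)


def simulate_track(cfg: TrackSimConfig, seed=None):
    """Generate (trajectory, stop events, ground truth).

    The ground-truth record carries the generating (p, c, b), the
    theoretical sinuosity, the realized mean flight speed and the
    realized time-budget shares implied by the event log.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    heading = rng.uniform(0.0, 2.0 * np.pi)
    pos = np.zeros(2)
    ts: list[int] = [0]
    xs: list[float] = [0.0]
    ys: list[float] = [0.0]
    is_stop_fix: list[bool] = [False]
    events: list[StopEvent] = []
    acts = list(cfg.activity_probs.keys())
    act_p = np.array([cfg.activity_probs[a] for a in acts])
    land_p = min(cfg.stop_rate / 60.0, 0.9)

    if cfg.step_cv_b > 0:
        shape = 1.0 / cfg.step_cv_b**2
        draw_step = lambda: rng.gamma(shape, cfg.step_mean_p / shape)
    else:
        draw_step = lambda: cfg.step_mean_p

    t = 0
    steps_left = cfg.n_steps
    just_stopped = False
    stop_seconds = {a: 0 for a in acts}
    flight_dist = 0.0
    while steps_left > 0:
        can_stop = (t >= 1) and (steps_left > 1) and not just_stopped
        if can_stop and rng.uniform() < land_p:
            d = int(rng.geometric(1.0 / cfg.stop_duration_mean_s))
            activity = acts[rng.choice(len(acts), p=act_p)]
            events.append(StopEvent(t, t + d, activity))
            stop_seconds[activity] += d
            # the landing fix at t is re-jittered together with the bout
            for k in range(d):
                ts.append(t + 1 + k)
                jx, jy = pos + rng.normal(0.0, cfg.jitter_sd, size=2)
                xs.append(jx)
                ys.append(jy)
                is_stop_fix.append(True)
            xs[-(d + 1)] = pos[0] + rng.normal(0.0, cfg.jitter_sd)
            ys[-(d + 1)] = pos[1] + rng.normal(0.0, cfg.jitter_sd)
            is_stop_fix[-(d + 1)] = True
            t += d
            just_stopped = True
            continue
        heading += rng.vonmises(0.0, cfg.turn_kappa) if cfg.turn_kappa > 0 else rng.uniform(-np.pi, np.pi)
        step = draw_step()
        pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        flight_dist += step
        t += 1
        ts.append(t)
        xs.append(pos[0])
        ys.append(pos[1])
        is_stop_fix.append(False)
        steps_left -= 1
        just_stopped = False

    # in-flight GPS dropout only; first/last fixes always survive
    keep = np.ones(len(ts), dtype=bool)
    if cfg.gap_prob > 0:
        drop = rng.uniform(size=len(ts)) < cfg.gap_prob
        drop &= ~np.asarray(is_stop_fix)
        drop[0] = drop[-1] = False
        keep = ~drop

    traj = Trajectory(
        individual_id=cfg.individual_id,
        species=cfg.species,
        sex=cfg.sex,
        site_id=cfg.site_id,
        t=np.asarray(ts)[keep],
        x=np.asarray(xs)[keep],
        y=np.asarray(ys)[keep],
    )
    duration = ts[-1]
    total_stop = sum(stop_seconds.values())
    truth = {
        "p": cfg.step_mean_p,
        "c": cfg.target_c,
        "b": cfg.step_cv_b,
        "sinuosity": theoretical_sinuosity(cfg.step_mean_p, cfg.target_c, cfg.step_cv_b),
        "speed": flight_dist / cfg.n_steps,
        "stopping_share": total_stop / duration,
        "nectaring_share": stop_seconds[Activity.NECTARING] / duration,
        "resting_share": stop_seconds[Activity.RESTING] / duration,
        "duration_s": duration,
        "n_stops": len(events),
    }
    return traj, events, truth


# ---------------------------------------------------------------------------
# transects and landscapes
# ---------------------------------------------------------------------------

def simulate_transect(n_segments: int, coverage, seed=None) -> list[TransectRecord]:
    """i.i.d. per-segment coverages clipped to [0, 100].

    ``coverage`` is a constant or a frozen scipy distribution (its
    ``rvs`` is used).
    """
    if n_segments < 1:
        raise ValueError("need at least one transect segment")
    rng = np.random.default_rng(seed)
    if np.isscalar(coverage):
        vals = np.full(n_segments, float(coverage))
    else:
        vals = np.asarray(coverage.rvs(size=n_segments, random_state=rng), dtype=float)
    vals = np.clip(vals, 0.0, 100.0)
    return [TransectRecord(i + 1, float(v)) for i, v in enumerate(vals)]


def simulate_landscape(
    n_classes: int = 4,
    coverage_fraction: float = 0.6,
    grid: tuple[int, int] = (120, 120),
    cellsize: float = 2.0,
    noise_sd: float = 3.0,
    monocentric: bool = False,
    seed=None,
):
    """(LandscapeInputs, truth) with known class sealing means.

    The biotope map is a nearest-seed (Voronoi) patchwork of
    ``n_classes`` classes; sealing is the class mean plus Gaussian
    noise, observed only on the western ``coverage_fraction`` of the
    domain (emulating a city map that stops at the administrative
    border). With ``monocentric`` the sealing instead decays smoothly
    with distance from the domain centre, so nested-buffer zonal means
    decrease with radius.
    """
    nrows, ncols = grid
    if nrows < 50 or ncols < 50:
        raise ValueError("grid must be at least 50 x 50")
    rng = np.random.default_rng(seed)
    template = Raster(np.zeros(grid), xll=0.0, yll=0.0, cellsize=cellsize)
    X, Y = template.cell_centers()

    seeds_xy = rng.uniform([0, 0], [ncols * cellsize, nrows * cellsize],
                           size=(max(n_classes * 3, n_classes), 2))
    seed_class = np.arange(len(seeds_xy)) % n_classes
    d2 = (X[..., None] - seeds_xy[:, 0]) ** 2 + (Y[..., None] - seeds_xy[:, 1]) ** 2
    classes = seed_class[np.argmin(d2, axis=-1)].astype(float)

    class_means = np.sort(rng.uniform(5.0, 90.0, size=n_classes))
    if monocentric:
        cx, cy = ncols * cellsize / 2.0, nrows * cellsize / 2.0
        dist = np.hypot(X - cx, Y - cy)
        base = 95.0 * np.exp(-dist / (0.25 * min(ncols, nrows) * cellsize))
    else:
        base = class_means[classes.astype(int)]
    sealing_full = np.clip(base + rng.normal(0.0, noise_sd, size=grid), 0.0, 100.0)

    sealing = sealing_full.copy()
    cut = template.xll + coverage_fraction * ncols * cellsize
    sealing[X >= cut] = np.nan

    extent_x, extent_y = ncols * cellsize, nrows * cellsize
    center = (extent_x / 2.0, extent_y / 2.0)
    half = 0.2 * min(extent_x, extent_y)
    habitat = Polygon([
        (center[0] - half, center[1] - half), (center[0] + half, center[1] - half),
        (center[0] + half, center[1] + half), (center[0] - half, center[1] + half),
    ])
    landscape = LandscapeInputs(
        sealing=Raster(sealing, 0.0, 0.0, cellsize),
        biotopes=Raster(classes, 0.0, 0.0, cellsize),
        site_centers={"S01": center},
        habitat_polygons={"S01": habitat},
    )
    truth = {
        "class_means": {int(k): float(v) for k, v in enumerate(class_means)},
        "sealing_full": sealing_full,
        "monocentric": monocentric,
        "noise_sd": noise_sd,
    }
    return landscape, truth


# ---------------------------------------------------------------------------
# study-level generator
# ---------------------------------------------------------------------------

@dataclass
class StudySimConfig:
    """Known-coefficient generator for GLMM recovery experiments.

    Defaults mirror the study's scale: ~29 sites along a gradient
    spanning roughly 1%-69% imperviousness, a handful of tracked
    individuals per site, nectar coverage averaging ~9% with a long
    right tail, and modest random-intercept spread.
    """

    n_sites: int = 29
    n_per_site: int = 5
    urbanization_range: tuple[float, float] = (1.4, 68.8)
    np_cov_mean: float = 9.2
    np_cov_sd: float = 8.3
    #: nectar coverage is measured per tracked individual (one transect
    #: through each butterfly's movement area); "site" collapses it to
    #: one value per site instead
    np_cov_level: str = "individual"
    habitat_area_range: tuple[float, float] = (1.0, 40.0)  # ha
    duration_mean_s: float = 336.0
    duration_sd_s: float = 158.0
    response: str = "stopping"
    family: str = "beta_logit"
    transformation: str = "none"
    intercept: float = 0.0
    true_coefs: dict[str, float] = field(default_factory=lambda: {
        "np_cov": 0.15, "urbanization": -0.15,
    })
    sex_effect: float | None = None  # logit/log-scale male effect; enables sex
    dispersion: float = 30.0  # beta precision phi, or lognormal sigma if that family
    random_sd: dict[str, float] = field(default_factory=lambda: {
        "habitat_area": 0.05, "duration_s": 0.05, "site": 0.15,
    })
    species: Species = Species.CP
    seed: int | None = None

    def __post_init__(self):
        self.species = Species(self.species)
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for k, v in self.true_coefs.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite effect for {k}")


def simulate_study(cfg: StudySimConfig, seed=None):
    """(summaries table, covariates table, truth record).

    Responses are drawn from the configured mixed model with the
    linear predictor built on *scaled* predictors, then mapped back to
    the raw scale the pipeline ingests (inverting the response
    transformation), so the tables match the pipeline's
    ``summaries.csv`` / ``covariates.csv`` schemas exactly.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_sites * cfg.n_per_site

    site_ids = [f"S{i + 1:02d}" for i in range(cfg.n_sites)]
    urb = np.linspace(*cfg.urbanization_range, cfg.n_sites)
    rng.shuffle(urb)
    area = rng.uniform(*cfg.habitat_area_range, size=cfg.n_sites)

    site = np.repeat(np.arange(cfg.n_sites), cfg.n_per_site)
    # gamma keeps nectar coverage positive and right-skewed
    k = (cfg.np_cov_mean / cfg.np_cov_sd) ** 2
    if cfg.np_cov_level == "individual":
        npc_i = np.clip(rng.gamma(k, cfg.np_cov_mean / k, size=n), 0.3, 100.0)
    elif cfg.np_cov_level == "site":
        npc_s = np.clip(rng.gamma(k, cfg.np_cov_mean / k, size=cfg.n_sites), 0.3, 100.0)
        npc_i = npc_s[site]
    else:
        raise ValueError("np_cov_level must be 'individual' or 'site'")
    dur_sigma = np.sqrt(np.log1p((cfg.duration_sd_s / cfg.duration_mean_s) ** 2))
    dur_mu = np.log(cfg.duration_mean_s) - dur_sigma**2 / 2.0
    duration = np.round(np.exp(rng.normal(dur_mu, dur_sigma, size=n))).astype(int)
    duration = np.clip(duration, 30, 720)
    sex = rng.choice(["female", "male"], size=n) if cfg.sex_effect is not None else \
        np.full(n, "unknown", dtype=object)

    def scaled(x):
        return (x - x.mean()) / x.std(ddof=1)

    # scale at the individual level (site values repeated), the same
    # convention the inference stage applies to its per-row table
    pred = {
        "np_cov": scaled(npc_i),
        "urbanization": scaled(urb[site]),
    }
    eta = np.full(n, cfg.intercept)
    for name, coef in cfg.true_coefs.items():
        eta = eta + coef * pred[name]
    if cfg.sex_effect is not None:
        eta = eta + cfg.sex_effect * (sex == "male")

    u: dict[str, np.ndarray] = {}
    for factor, sd in cfg.random_sd.items():
        if factor == "site":
            u_f = rng.normal(0.0, sd, size=cfg.n_sites)
            eta = eta + u_f[site]
        elif factor == "habitat_area":
            u_f = rng.normal(0.0, sd, size=cfg.n_sites)  # one area value per site
            eta = eta + u_f[site]
        elif factor == "duration_s":
            levels, inv = np.unique(duration, return_inverse=True)
            u_f = rng.normal(0.0, sd, size=len(levels))
            eta = eta + u_f[inv]
        else:
            raise ValueError(f"unknown random factor {factor!r}")
        u[factor] = u_f

    if cfg.family == "beta_logit":
        from scipy.special import expit
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        y = np.clip(rng.beta(mu * cfg.dispersion, (1 - mu) * cfg.dispersion),
                    1e-12, 1 - 1e-12)
    elif cfg.family == "lognormal_log":
        y = np.exp(rng.normal(eta, cfg.dispersion))
    else:
        raise ValueError(f"unknown family {cfg.family!r}")

    # invert the response transformation back to the raw reporting scale
    raw = y.copy()
    if cfg.transformation in ("add_epsilon", "both"):
        raw = np.maximum(raw - 1e-10, 0.0)
    if cfg.transformation in ("divide_by_10", "both"):
        raw = raw * 10.0

    summaries = pd.DataFrame({
        "individual_id": [f"ind{i + 1:03d}" for i in range(n)],
        "species": cfg.species.value,
        "sex": sex,
        "site": np.asarray(site_ids)[site],
        "duration_s": duration,
        "path_m": np.nan,
        "flight_speed": np.nan,
        "stopping": np.nan,
        "nectaring": np.nan,
        "resting": np.nan,
        "sinuosity": np.nan,
        "n_stops": 0,
        "n_segments": 1,
        "habitat_area": area[site],
        "np_cov": npc_i,  # per-individual transect coverage
    })
    summaries[cfg.response] = raw
    site_np = pd.Series(npc_i).groupby(site).mean().to_numpy()
    covariates = pd.DataFrame({
        "site_id": site_ids,
        "np_cov": site_np,
        "urbanization_500": urb,
        "urbanization_1000": urb,
        "urbanization_2000": urb,
        "habitat_area": area,
    })
    truth = {
        "intercept": cfg.intercept,
        "true_coefs": dict(cfg.true_coefs),
        "sex_effect": cfg.sex_effect,
        "dispersion": cfg.dispersion,
        "random_sd": dict(cfg.random_sd),
        "random_effects": u,
        "eta": eta,
        "response_support": y,
    }
    return summaries, covariates, truth
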