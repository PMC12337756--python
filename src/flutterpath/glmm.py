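"""Mixed-effect regression for movement responses.

Two response families cover the movement metrics: a beta family with
logit link for responses on the open unit interval (rescaled flight
speed, time-budget shares, rescaled tortuosity) and a lognormal family
with log link for positive skewed responses. Each model carries any
number of random-intercept factors; following the field workflow this
includes *continuous* grouping variables (habitat area, track
duration), every distinct value of which is a level of its factor —
a faithful-but-unusual structure that a configuration switch in the
pipeline can replace with fixed covariates.

Estimation is Laplace-approximate maximum likelihood: for candidate
variance/dispersion parameters, a penalised Fisher-scoring loop finds
the joint mode of fixed effects and random intercepts; the marginal
likelihood is the penalised likelihood at the mode corrected by the
log-determinant of the random-effect information; a derivative-free
outer optimiser moves the variance parameters. Wald standard errors of
the fixed effects come from the fixed-effect block of the inverse
joint information, conditional on the variance parameters — the
convention of the standard mixed-model packages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import digamma, expit, gammaln, polygamma
from scipy.stats import norm

_LOG_SD_MIN, _LOG_SD_MAX = -10.0, 5.0


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[str] | None = None):
        self.trace = trace or []
        super().__init__(message)


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

class BetaLogit:
    """Beta response, logit link: y ~ Beta(mu*phi, (1-mu)*phi),
    logit(mu) = eta. ``disp`` is the precision phi."""

    name = "beta_logit"
    disp_name = "phi"

    @staticmethod
    def check_support(y: np.ndarray) -> None:
        if np.any((y <= 0.0) | (y >= 1.0)):
            raise ValueError("beta responses must lie strictly inside (0, 1)")

    @staticmethod
    def _mu(eta):
        # keep shape parameters away from 0 for lgamma/digamma stability
        return np.clip(expit(eta), 1e-12, 1.0 - 1e-12)

    @staticmethod
    def loglik(y, eta, disp):
        mu = BetaLogit._mu(eta)
        a = mu * disp
        b = (1.0 - mu) * disp
        return float(np.sum(
            gammaln(disp) - gammaln(a) - gammaln(b)
            + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y)
        ))

    @staticmethod
    def score_weight(y, eta, disp):
        """Gradient and expected information of the log-likelihood with
        respect to eta, per observation."""
        mu = BetaLogit._mu(eta)
        v = mu * (1.0 - mu)
        a = mu * disp
        b = (1.0 - mu) * disp
        ystar = np.log(y) - np.log1p(-y)
        mustar = digamma(a) - digamma(b)
        g = disp * v * (ystar - mustar)
        w = disp**2 * v**2 * (polygamma(1, a) + polygamma(1, b))
        return g, w

    @staticmethod
    def init(y, X):
        z = np.log(y) - np.log1p(-y)
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        resid = z - X @ beta
        mu = expit(X @ beta)
        # method-of-moments precision from link-scale residual spread
        s2 = max(float(resid.var()), 1e-3)
        phi = max(1.0 / (s2 * np.mean(mu * (1 - mu))), 1.1)
        return beta, min(phi, 1e4)

    @staticmethod
    def simulate(rng, eta, disp):
        mu = BetaLogit._mu(eta)
        y = rng.beta(mu * disp, (1.0 - mu) * disp)
        return np.clip(y, 1e-12, 1.0 - 1e-12)

    @staticmethod
    def mean(eta):
        return expit(eta)


class LognormalLog:
    """Lognormal response, log link: log y ~ Normal(eta, disp**2).
    ``disp`` is the log-scale standard deviation sigma."""

    name = "lognormal_log"
    disp_name = "sigma"

    @staticmethod
    def check_support(y: np.ndarray) -> None:
        if np.any(y <= 0.0):
            raise ValueError("lognormal responses must be positive")

    @staticmethod
    def loglik(y, eta, disp):
        z = np.log(y)
        s2 = disp**2
        return float(np.sum(-0.5 * np.log(2.0 * np.pi * s2)
                            - (z - eta) ** 2 / (2.0 * s2) - z))

    @staticmethod
    def score_weight(y, eta, disp):
        s2 = disp**2
        g = (np.log(y) - eta) / s2
        w = np.full_like(eta, 1.0 / s2)
        return g, w

    @staticmethod
    def init(y, X):
        z = np.log(y)
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        sd = max(float((z - X @ beta).std()), 1e-3)
        return beta, sd

    @staticmethod
    def simulate(rng, eta, disp):
        return np.exp(rng.normal(eta, disp))

    @staticmethod
    def mean(eta):
        # median on the response scale; used only for residual work
        return np.exp(eta)


FAMILIES = {"beta_logit": BetaLogit, "lognormal_log": LognormalLog}


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class MovementGLMM:
    """Mixed model ``family(link) ~ X*beta + sum_g Z_g u_g``.

    Parameters
    ----------
    endog : (n,) response on the family's support.
    exog : (n, p) fixed-effect design, intercept included.
    groups : mapping factor name -> (n,) array; each distinct value is
        a random-intercept level.
    family : "beta_logit", "lognormal_log" or a family class.
    exog_names : column names for reporting.
    """

    def __init__(self, endog, exog, groups, family="beta_logit", exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        n, p = self.exog.shape
        if len(self.endog) != n:
            raise ValueError("endog and exog lengths differ")
        self.family = FAMILIES[family]() if isinstance(family, str) else family
        self.family.check_support(self.endog)
        self.exog_names = list(exog_names) if exog_names else [f"x{j}" for j in range(p)]

        self.group_names: list[str] = []
        self.group_codes: list[np.ndarray] = []
        self.group_sizes: list[int] = []
        for name, values in groups.items():
            codes, levels = pd.factorize(np.asarray(values), sort=True)
            if len(codes) != n:
                raise ValueError(f"grouping factor {name!r} length differs from endog")
            self.group_names.append(str(name))
            self.group_codes.append(codes.astype(np.int64))
            self.group_sizes.append(len(levels))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, fixed: list[str],
                       random: list[str], family="beta_logit", add_intercept=True):
        """Build from a tidy table. Non-numeric fixed-effect columns are
        dummy-coded (first level, alphabetically, is the reference —
        e.g. sex female reference, ``sex[male]`` reported)."""
        y = data[response].to_numpy(dtype=float)
        cols, names = [], []
        if add_intercept:
            cols.append(np.ones(len(data)))
            names.append("Intercept")
        for col in fixed:
            s = data[col]
            if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
                levels = sorted(pd.unique(s.astype(str)))
                for lev in levels[1:]:
                    cols.append((s.astype(str) == lev).to_numpy(dtype=float))
                    names.append(f"{col}[{lev}]")
            else:
                cols.append(s.to_numpy(dtype=float))
                names.append(col)
        X = np.column_stack(cols)
        groups = {g: data[g].to_numpy() for g in random}
        return cls(y, X, groups, family=family, exog_names=names)

    # -- internals ---------------------------------------------------------

    @property
    def n_obs(self) -> int:
        return len(self.endog)

    @property
    def k_fixed(self) -> int:
        return self.exog.shape[1]

    def _eta(self, beta, us):
        eta = self.exog @ beta
        for codes, u in zip(self.group_codes, us):
            eta = eta + u[codes]
        return eta

    # The joint information over (beta, u) has diagonal blocks for every
    # grouping factor; the largest factor (typically track duration, one
    # level per individual) is eliminated analytically by a Schur
    # complement onto the small dense remainder [beta | other factors],
    # making each scoring step O(n * m^2) with m a few dozen.

    def _ensure_design(self):
        if hasattr(self, "_C"):
            return
        n, p = self.exog.shape
        sizes = self.group_sizes
        self._big = int(np.argmax(sizes)) if sizes else None
        self._small = [g for g in range(len(sizes)) if g != self._big]
        cols = [self.exog]
        self._small_span: dict[int, tuple[int, int]] = {}
        off = p
        for g in self._small:
            q = sizes[g]
            z = np.zeros((n, q))
            z[np.arange(n), self.group_codes[g]] = 1.0
            cols.append(z)
            self._small_span[g] = (off, off + q)
            off += q
        self._C = np.column_stack(cols) if len(cols) > 1 else self.exog.astype(float)
        self._m = self._C.shape[1]

    def _schur(self, w: np.ndarray, variances: np.ndarray):
        """(S, Bq, delta): dense Schur complement of the joint
        information after eliminating the largest factor."""
        self._ensure_design()
        C = self._C
        wC = w[:, None] * C
        A = C.T @ wC
        for g, (lo, hi) in self._small_span.items():
            A[np.arange(lo, hi), np.arange(lo, hi)] += 1.0 / variances[g]
        if self._big is None:
            return A, None, None
        codes = self.group_codes[self._big]
        q = self.group_sizes[self._big]
        delta = np.bincount(codes, weights=w, minlength=q) + 1.0 / variances[self._big]
        Bq = np.zeros((q, self._m))
        np.add.at(Bq, codes, wC)
        S = A - Bq.T @ (Bq / delta[:, None])
        return S, Bq, delta

    def _grad_parts(self, g: np.ndarray, beta, us, variances):
        self._ensure_design()
        r_small = self._C.T @ g
        for gi, (lo, hi) in self._small_span.items():
            r_small[lo:hi] -= us[gi] / variances[gi]
        if self._big is None:
            return r_small, None
        codes = self.group_codes[self._big]
        q = self.group_sizes[self._big]
        r_big = np.bincount(codes, weights=g, minlength=q) - us[self._big] / variances[self._big]
        return r_small, r_big

    def _unpack(self, x_small, x_big):
        p = self.k_fixed
        beta = x_small[:p]
        us: list[np.ndarray | None] = [None] * len(self.group_sizes)
        for g, (lo, hi) in self._small_span.items():
            us[g] = x_small[lo:hi]
        if self._big is not None:
            us[self._big] = x_big
        return beta, us

    def _penalized_ll(self, beta, us, variances, disp):
        ll = self.family.loglik(self.endog, self._eta(beta, us), disp)
        pen = sum(float(u @ u) / (2.0 * v) for u, v in zip(us, variances))
        return ll - pen

    def _inner_mode(self, variances, disp, beta, us, maxiter=60, gtol=1e-7):
        """Penalised Fisher scoring for (beta, u) at fixed variances."""
        obj = self._penalized_ll(beta, us, variances, disp)
        for _ in range(maxiter):
            eta = self._eta(beta, us)
            g, w = self.family.score_weight(self.endog, eta, disp)
            r_small, r_big = self._grad_parts(g, beta, us, variances)
            gmax = float(np.abs(r_small).max())
            if r_big is not None and len(r_big):
                gmax = max(gmax, float(np.abs(r_big).max()))
            if gmax < gtol * (1.0 + abs(obj)):
                break
            S, Bq, delta = self._schur(w, variances)
            if Bq is not None:
                rr = r_small - Bq.T @ (r_big / delta)
                dx_small = np.linalg.solve(S, rr)
                dx_big = (r_big - Bq @ dx_small) / delta
            else:
                dx_small = np.linalg.solve(S, r_small)
                dx_big = None
            db, dus = self._unpack(dx_small, dx_big)
            step = 1.0
            for _ in range(30):
                nb = beta + step * db
                nus = [u + step * du for u, du in zip(us, dus)]
                nobj = self._penalized_ll(nb, nus, variances, disp)
                if np.isfinite(nobj) and nobj >= obj - 1e-10:
                    break
                step *= 0.5
            else:
                break  # no improving step; accept current mode
            moved = step * max(float(np.abs(db).max()),
                               max(float(np.abs(du).max()) for du in dus) if dus else 0.0)
            beta, us, obj = nb, nus, nobj
            if moved < 1e-10:
                break
        return beta, us, obj

    def _logdet_uu(self, w, variances):
        """log det of the random-effect information block, via the same
        Schur elimination restricted to the u rows."""
        S, _, delta = self._schur(w, variances)
        p = self.k_fixed
        out = 0.0
        if delta is not None:
            out += float(np.sum(np.log(delta)))
        if S.shape[0] > p:
            sign, ld = np.linalg.slogdet(S[p:, p:])
            if sign <= 0:
                raise np.linalg.LinAlgError("random-effect information not positive definite")
            out += float(ld)
        return out

    def _laplace_ll(self, theta, state):
        G = len(self.group_codes)
        log_sd = np.clip(theta[:G], _LOG_SD_MIN, _LOG_SD_MAX)
        variances = np.exp(2.0 * log_sd)
        disp = float(np.exp(np.clip(theta[G], -12.0, 12.0)))
        beta, us, pen = self._inner_mode(variances, disp, state["beta"], state["us"])
        state["beta"], state["us"] = beta, us
        eta = self._eta(beta, us)
        _, w = self.family.score_weight(self.endog, eta, disp)
        logdet = self._logdet_uu(w, variances)
        ll = pen - 0.5 * float(np.sum(2.0 * log_sd * np.asarray(self.group_sizes))) - 0.5 * logdet
        return ll, beta, us, variances, disp, w

    # -- fitting -----------------------------------------------------------

    def fit(self, start_variances=None, start_disp=None, maxfev=400,
            xatol=2e-3, fatol=1e-4) -> "MovementGLMMResults":
        """Maximise the Laplace-approximate marginal likelihood.

        Raises :class:`ConvergenceError` (with the optimiser trace)
        when neither the outer search nor the inner scoring settles.
        """
        G = len(self.group_codes)
        beta0, disp0 = self.family.init(self.endog, self.exog)
        if start_disp is not None:
            disp0 = float(start_disp)
        sd0 = np.full(G, 0.3) if start_variances is None else np.sqrt(np.asarray(start_variances, float))
        theta0 = np.concatenate([np.log(np.maximum(sd0, 1e-4)), [np.log(disp0)]])
        state = {"beta": beta0, "us": [np.zeros(q) for q in self.group_sizes]}
        trace: list[str] = []

        def nll(theta):
            try:
                ll, *_ = self._laplace_ll(theta, state)
            except (np.linalg.LinAlgError, RuntimeError, FloatingPointError) as exc:
                trace.append(f"theta={np.round(theta, 3)} failed: {exc}")
                return 1e12
            trace.append(f"theta={np.round(theta, 4)} ll={ll:.6f}")
            return -ll

        res = optimize.minimize(
            nll, theta0, method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": xatol, "fatol": fatol},
        )
        if not np.all(np.isfinite(res.x)) or res.fun >= 1e12:
            raise ConvergenceError("outer optimisation failed", trace)

        ll, beta, us, variances, disp, w = self._laplace_ll(res.x, state)
        # (H^-1)_[beta|small] = S^-1 by block inversion; beta block first
        S, _, _ = self._schur(w, variances)
        p = self.k_fixed
        cov_beta = np.linalg.inv(S)[:p, :p]

        singular = variances < 1e-6
        if singular.any():
            names = [n for n, s in zip(self.group_names, singular) if s]
            warnings.warn(f"random-intercept variance ~0 for {names}", stacklevel=2)

        k_params = p + G + 1
        return MovementGLMMResults(
            model=self,
            params=beta,
            cov_params=cov_beta,
            vc={n: float(v) for n, v in zip(self.group_names, variances)},
            dispersion=disp,
            random_effects={n: u for n, u in zip(self.group_names, us)},
            llf=float(ll),
            aic=float(-2.0 * ll + 2.0 * k_params),
            converged=bool(res.success or res.status == 2),
            n_outer_evals=int(res.nfev),
            singular_flags={n: bool(s) for n, s in zip(self.group_names, singular)},
        )


@dataclass
class MovementGLMMResults:
    """Estimates, Wald inference and simulation for a fitted model."""

    model: MovementGLMM
    params: np.ndarray
    cov_params: np.ndarray
    vc: dict[str, float]
    dispersion: float
    random_effects: dict[str, np.ndarray]
    llf: float
    aic: float
    converged: bool
    n_outer_evals: int = 0
    singular_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))

    @property
    def df_resid(self) -> int:
        return self.model.n_obs - self.model.k_fixed - len(self.vc)

    def fixed_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "std_error": self.bse,
             "z": self.zvalues, "p": self.pvalues},
            index=self.model.exog_names,
        )

    def fitted_linear(self, conditional: bool = True) -> np.ndarray:
        eta = self.model.exog @ self.params
        if conditional:
            for codes, name in zip(self.model.group_codes, self.model.group_names):
                eta = eta + self.random_effects[name][codes]
        return eta

    def simulate(self, n_sim: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
        """Unconditional simulation of ``n_sim`` response vectors:
        random intercepts are redrawn from their estimated variances,
        then responses from the family. Shape (n_sim, n_obs)."""
        rng = np.random.default_rng(rng)
        n = self.model.n_obs
        out = np.empty((n_sim, n))
        eta_fix = self.model.exog @ self.params
        for k in range(n_sim):
            eta = eta_fix.copy()
            for codes, q, name in zip(self.model.group_codes, self.model.group_sizes,
                                      self.model.group_names):
                u = rng.normal(0.0, np.sqrt(self.vc[name]), size=q)
                eta = eta + u[codes]
            out[k] = self.model.family.simulate(rng, eta, self.dispersion)
        return out

    def summary(self) -> str:
        fam = self.model.family
        lines = [
            "Movement mixed model (Laplace ML)",
            "=" * 64,
            f"family: {fam.name}    n: {self.model.n_obs}    "
            f"residual df: {self.df_resid}",
            f"logLik: {self.llf:.3f}    AIC: {self.aic:.3f}    "
            f"{fam.disp_name}: {self.dispersion:.4g}",
            "-" * 64,
            f"{'fixed effect':<22}{'estimate':>10}{'std.err':>10}{'z':>8}{'p':>10}",
        ]
        for name, est, se, z, p in zip(self.model.exog_names, self.params,
                                       self.bse, self.zvalues, self.pvalues):
            lines.append(f"{name:<22}{est:>10.4f}{se:>10.4f}{z:>8.3f}{p:>10.4g}")
        lines.append("-" * 64)
        lines.append("random intercept variances:")
        for name, v in self.vc.items():
            flag = "  (singular ~0)" if self.singular_flags.get(name) else ""
            lines.append(f"  {name:<20}{v:.5g}{flag}")
        return "\n".join(lines)
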