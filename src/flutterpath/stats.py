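"""Inference-stage helpers around :class:`~flutterpath.glmm.MovementGLMM`.

The analysis protocol: numeric predictors are centred and scaled to
unit (sample) standard deviation; predictor pairs with Spearman
|rs| >= 0.5 are screened for collinearity; responses are moved onto
their family's support (shares get a 1e-10 offset, speeds and
tortuosity are divided by 10 for the beta family); each response is
fitted with random intercepts for habitat area, track duration and
site; the urbanization buffer radius is chosen by AIC across
{500, 1000, 2000} m; species-level descriptive contrasts use the
Wilcoxon rank-sum test. No multiple-testing correction is applied —
per-coefficient Wald p-values are reported as-is.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glmm import MovementGLMM, MovementGLMMResults

EPSILON = 1e-10
BETA_CEILING = 1.0 - 1e-6


class Transformation(str, enum.Enum):
    NONE = "none"
    DIVIDE_BY_10 = "divide_by_10"
    ADD_EPSILON = "add_epsilon"
    BOTH = "both"


class Family(str, enum.Enum):
    BETA_LOGIT = "beta_logit"
    LOGNORMAL_LOG = "lognormal_log"


@dataclass
class ModelSpec:
    """One response x species model of the analysis roster."""

    response: str
    transformation: Transformation = Transformation.NONE
    family: Family = Family.BETA_LOGIT
    fixed: list[str] = field(default_factory=lambda: ["np_cov", "urbanization"])
    random_intercepts: list[str] = field(
        default_factory=lambda: ["habitat_area", "duration_s", "site"]
    )
    random_as_fixed: bool = False  # treat habitat area / duration as fixed covariates

    def __post_init__(self):
        self.transformation = Transformation(self.transformation)
        self.family = Family(self.family)


def scale_predictors(
    table: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Centre each column to mean 0 and scale to sample SD 1.

    Returns the transformed table and ``{column: (mean, sd)}`` for
    back-transformation. Constant columns are rejected.
    """
    out = table.copy()
    constants: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        mu = float(x.mean())
        sd = float(x.std(ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} is constant; cannot scale")
        out[col] = (x - mu) / sd
        constants[col] = (mu, sd)
    return out, constants


def collinearity_screen(
    table: pd.DataFrame, predictors: list[str], threshold: float = 0.5
) -> pd.DataFrame:
    """All pairwise Spearman rank correlations among ``predictors``.

    Pairs with |rs| >= ``threshold`` are flagged; the default pipeline
    drops the member with the larger mean absolute correlation.
    """
    if len(predictors) < 2:
        raise ValueError("need at least two predictors to screen")
    rows = []
    mean_abs = {
        p: np.mean([
            abs(sps.spearmanr(table[p], table[q]).statistic)
            for q in predictors if q != p
        ])
        for p in predictors
    }
    for i, a in enumerate(predictors):
        for b in predictors[i + 1:]:
            res = sps.spearmanr(table[a], table[b])
            rs = float(res.statistic)
            flagged = abs(rs) >= threshold
            drop = None
            if flagged:
                drop = a if mean_abs[a] >= mean_abs[b] else b
            rows.append({"a": a, "b": b, "rs": rs, "p": float(res.pvalue),
                         "flagged": flagged, "drop": drop})
    return pd.DataFrame(rows)


def transform_response(values, spec: ModelSpec) -> np.ndarray:
    """Move raw responses onto the model family's support.

    ``divide_by_10`` rescales speeds/tortuosity under 10 into (0, 1);
    ``add_epsilon`` lifts exact zeros off the boundary. Values at or
    above 1 after transformation are nudged to 1 - 1e-6 with a warning
    (the beta support is open).
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("responses must be finite")
    if spec.transformation in (Transformation.DIVIDE_BY_10, Transformation.BOTH):
        v = v / 10.0
    if spec.transformation in (Transformation.ADD_EPSILON, Transformation.BOTH):
        v = v + EPSILON
    if spec.family is Family.BETA_LOGIT:
        if np.any(v >= 1.0):
            warnings.warn(
                f"{int((v >= 1.0).sum())} response value(s) at or above 1 "
                f"nudged to {BETA_CEILING}", stacklevel=2,
            )
            v = np.where(v >= 1.0, BETA_CEILING, v)
        if np.any(v <= 0.0):
            raise ValueError("beta responses must be positive after transformation")
    if spec.family is Family.LOGNORMAL_LOG and np.any(v <= 0.0):
        raise ValueError("lognormal responses must be positive")
    return v


def fit_glmm(spec: ModelSpec, table: pd.DataFrame, response_col: str | None = None,
             **fit_kwargs) -> MovementGLMMResults:
    """Fit one roster model on a per-individual table.

    Expects predictors already scaled and the response already
    transformed (``response_col`` defaults to ``spec.response``).
    Unknown-sex rows must have been removed upstream where sex is a
    fixed effect.
    """
    response_col = response_col or spec.response
    if "sex" in spec.fixed and (table["sex"].astype(str) == "unknown").any():
        raise ValueError("unknown-sex rows must be dropped before fitting a sex model")
    if spec.random_as_fixed:
        fixed = spec.fixed + [r for r in spec.random_intercepts if r != "site"]
        random = [r for r in spec.random_intercepts if r == "site"]
    else:
        fixed, random = spec.fixed, spec.random_intercepts
    model = MovementGLMM.from_dataframe(
        table, response_col, fixed=fixed, random=random, family=spec.family.value
    )
    return model.fit(**fit_kwargs)


def select_radius(fits: dict[float, MovementGLMMResults]) -> tuple[float, pd.DataFrame]:
    """Choose the urbanization buffer radius by AIC (ties -> larger
    radius). All candidate fits must use the same observations."""
    ns = {r: f.model.n_obs for r, f in fits.items()}
    if len(set(ns.values())) != 1:
        raise ValueError(f"candidate fits use different row sets: {ns}")
    table = pd.DataFrame(
        {"radius_m": list(fits), "aic": [f.aic for f in fits.values()]}
    ).sort_values("radius_m", ignore_index=True)
    best = table.loc[table["aic"] <= table["aic"].min() + 1e-12, "radius_m"].max()
    return float(best), table


def wilcoxon_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison.

    Exact null distribution for samples of at most 10 without ties,
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    if np.all(np.concatenate([a, b]) == a[0]):
        return float(len(a) * len(b) / 2.0), 1.0  # no rank information at all
    small = len(a) <= 10 and len(b) <= 10
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
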