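"""End-to-end orchestration: tracks -> summaries -> covariates ->
mixed models -> report.

Inputs are declared in a :class:`RunConfig` (usually from YAML): a
track manifest (one row per individual with paths to the fix CSV and
the stop log), a site manifest (transect per site), and the landscape
layers. A *reproduction* entry point accepts a pre-derived
per-individual table in the shape archives deposit (responses and
predictors already computed) and runs only the inference stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariates import (
    LandscapeInputs,
    read_habitat_polygons,
    read_site_centers,
    site_covariates,
)
from .diagnostics import residual_diagnostics
from .metrics import summarize_track
from .raster import read_ascii_grid
from .stats import (
    Family,
    ModelSpec,
    Transformation,
    collinearity_screen,
    fit_glmm,
    scale_predictors,
    select_radius,
    transform_response,
    wilcoxon_compare,
)
from .stops import consolidate
from .trajectory import DEFAULT_GAP_THRESHOLD_S, read_events, read_track

log = logging.getLogger("flutterpath")


def default_roster() -> list[ModelSpec]:
    """The response x species models of the study's result tables.

    Per species: flight speed (beta, divided by 10), the three
    time-budget shares (beta, 1e-10 offset) and tortuosity (lognormal
    for CP, beta divided by 10 for PR); PR models add sex as a fixed
    effect.
    """
    roster = []
    for species in ("CP", "PR"):
        fixed = ["np_cov", "urbanization"] + (["sex"] if species == "PR" else [])
        for response, (family, tr) in {
            "flight_speed": (Family.BETA_LOGIT, Transformation.DIVIDE_BY_10),
            "stopping": (Family.BETA_LOGIT, Transformation.ADD_EPSILON),
            "nectaring": (Family.BETA_LOGIT, Transformation.ADD_EPSILON),
            "resting": (Family.BETA_LOGIT, Transformation.ADD_EPSILON),
        }.items():
            roster.append(ModelSpec(response=response, family=family,
                                    transformation=tr, fixed=list(fixed)))
            roster[-1].species = species  # type: ignore[attr-defined]
        tort = (ModelSpec("sinuosity", Transformation.NONE, Family.LOGNORMAL_LOG,
                          fixed=list(fixed))
                if species == "CP"
                else ModelSpec("sinuosity", Transformation.DIVIDE_BY_10,
                               Family.BETA_LOGIT, fixed=list(fixed)))
        tort.species = species  # type: ignore[attr-defined]
        roster.append(tort)
    return roster


@dataclass
class RunConfig:
    track_manifest: str  # CSV: individual_id,species,sex,site_id,track_path,events_path
    site_manifest: str   # CSV: site_id,transect_path
    sealing_raster: str
    biotope_raster: str
    site_centers: str    # GeoJSON points
    habitat_polygons: str  # GeoJSON polygons
    out_dir: str = "run_out"
    gap_threshold_s: int = DEFAULT_GAP_THRESHOLD_S
    gross_speed: bool = False
    sinuosity_weight: str = "length"
    radii: tuple[float, ...] = (500.0, 1000.0, 2000.0)
    seed: int = 0
    n_sim_diagnostics: int = 250

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, record: str, cause: Exception):
        self.stage, self.record = stage, record
        super().__init__(f"stage {stage!r} failed on {record!r}: {cause}")


def build_summaries(cfg: RunConfig) -> pd.DataFrame:
    manifest = pd.read_csv(cfg.track_manifest)
    rows = []
    for _, rec in manifest.iterrows():
        rid = str(rec["individual_id"])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                traj = read_track(rec["track_path"], individual_id=rid,
                                  species=rec["species"], sex=rec["sex"],
                                  site_id=str(rec["site_id"]))
                events = read_events(rec["events_path"])
                pt = consolidate(traj, events, gap_threshold_s=cfg.gap_threshold_s)
                summary = summarize_track(pt, weight=cfg.sinuosity_weight,
                                          gross_speed=cfg.gross_speed)
        except Exception as exc:
            raise PipelineError("summaries", rid, exc) from exc
        rows.append(asdict(summary) | {"site": summary.site_id})
    return pd.DataFrame(rows).drop(columns=["site_id"])


def build_covariates(cfg: RunConfig) -> pd.DataFrame:
    from .trajectory import read_transect

    sites = pd.read_csv(cfg.site_manifest)
    landscape = LandscapeInputs(
        sealing=read_ascii_grid(cfg.sealing_raster),
        biotopes=read_ascii_grid(cfg.biotope_raster),
        site_centers=read_site_centers(cfg.site_centers),
        habitat_polygons=read_habitat_polygons(cfg.habitat_polygons),
    )
    rows = []
    for _, rec in sites.iterrows():
        sid = str(rec["site_id"])
        try:
            cov = site_covariates(sid, read_transect(rec["transect_path"]), landscape,
                                  radii=cfg.radii)
        except Exception as exc:
            raise PipelineError("covariates", sid, exc) from exc
        row = {"site_id": sid, "np_cov": cov.np_cov, "habitat_area": cov.habitat_area}
        for r, u in cov.urbanization.items():
            row[f"urbanization_{int(r)}"] = u
        rows.append(row)
    return pd.DataFrame(rows)


def fit_roster(
    summaries: pd.DataFrame,
    covariates: pd.DataFrame,
    roster: list[ModelSpec] | None = None,
    radii: tuple[float, ...] = (500.0, 1000.0, 2000.0),
    seed: int = 0,
    n_sim_diagnostics: int = 250,
):
    """Fit every roster model at every buffer radius; select the
    radius by AIC per model; attach residual diagnostics.

    Returns (models table, diagnostics table, fits dict).
    """
    roster = default_roster() if roster is None else roster
    table_all = summaries.merge(covariates, left_on="site", right_on="site_id",
                                how="left", suffixes=("", "_cov"))
    model_rows, diag_rows, fits = [], [], {}
    rng = np.random.default_rng(seed)
    for mi, spec in enumerate(roster):
        species = getattr(spec, "species", None)
        tab = table_all if species is None else table_all[table_all["species"] == species]
        if "sex" in spec.fixed:
            tab = tab[tab["sex"] != "unknown"]
        tab = tab.dropna(subset=[spec.response]).copy()
        if len(tab) < 5:
            log.warning("skipping %s/%s: only %d rows", species, spec.response, len(tab))
            continue
        yname = f"__resp_{spec.response}"
        tab[yname] = transform_response(tab[spec.response], spec)

        per_radius = {}
        for radius in radii:
            urb_col = f"urbanization_{int(radius)}"
            if urb_col not in tab.columns:
                log.warning("no %s column; radius %gm skipped", urb_col, radius)
                continue
            try:
                sub = tab.rename(columns={urb_col: "urbanization"})
                scaled, _ = scale_predictors(sub, [c for c in spec.fixed if c != "sex"])
                per_radius[float(radius)] = fit_glmm(spec, scaled, response_col=yname)
            except Exception as exc:
                log.warning("fit failed (%s/%s, %gm): %s", species, spec.response, radius, exc)
        if not per_radius:
            continue
        best_radius, aic_table = select_radius(per_radius)
        fit = per_radius[best_radius]
        fits[(species, spec.response)] = (fit, best_radius, aic_table)

        diag = residual_diagnostics(fit, n_sim=n_sim_diagnostics,
                                    seed=rng.integers(2**31))
        for name, est, se, z, p in zip(fit.model.exog_names, fit.params, fit.bse,
                                       fit.zvalues, fit.pvalues):
            model_rows.append({
                "species": species, "response": spec.response,
                "family": spec.family.value, "transformation": spec.transformation.value,
                "radius_m": best_radius, "term": name,
                "estimate": est, "std_error": se, "z": z, "p": p,
                "ks_deviation": diag.flag.value != "ok",
            })
        diag_rows.append({
            "species": species, "response": spec.response,
            "ks_uniformity_p": diag.ks_uniformity_p,
            "dispersion_p": diag.dispersion_p, "n_sim": diag.n_sim,
            "flag": diag.flag.value,
        })
    return pd.DataFrame(model_rows), pd.DataFrame(diag_rows), fits


def species_descriptives(summaries: pd.DataFrame) -> pd.DataFrame:
    """Species means +- SD and Wilcoxon rank-sum contrasts for each
    response variable."""
    rows = []
    for response in ("flight_speed", "stopping", "nectaring", "resting", "sinuosity"):
        if response not in summaries:
            continue
        cp = summaries.loc[summaries["species"] == "CP", response].dropna()
        pr = summaries.loc[summaries["species"] == "PR", response].dropna()
        row = {"response": response,
               "cp_mean": cp.mean(), "cp_sd": cp.std(ddof=1),
               "pr_mean": pr.mean(), "pr_sd": pr.std(ddof=1)}
        if len(cp) and len(pr):
            stat, p = wilcoxon_compare(cp, pr)
            row |= {"wilcoxon_stat": stat, "wilcoxon_p": p}
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Full run; deterministic given (config, seed). Writes
    summaries.csv, covariates.csv, models.csv/json, diagnostics.csv,
    descriptives.csv, report.md and run.log into ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("flutterpath %s  config %s  seed %d", __version__,
                 cfg.config_hash(), cfg.seed)
        summaries = build_summaries(cfg)
        covariates = build_covariates(cfg)
        screen = collinearity_screen(
            summaries.merge(covariates, left_on="site", right_on="site_id"),
            ["np_cov", f"urbanization_{int(max(cfg.radii))}", "habitat_area"],
        )
        for _, r in screen[screen["flagged"]].iterrows():
            log.warning("collinear pair %s-%s rs=%.3f", r["a"], r["b"], r["rs"])
        models, diagnostics, fits = fit_roster(
            summaries, covariates, radii=cfg.radii, seed=cfg.seed,
            n_sim_diagnostics=cfg.n_sim_diagnostics,
        )
        descriptives = species_descriptives(summaries)

        paths = {}
        for name, df in {"summaries": summaries, "covariates": covariates,
                         "models": models, "diagnostics": diagnostics,
                         "descriptives": descriptives,
                         "collinearity": screen}.items():
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        (out / "models.json").write_text(
            json.dumps({"config_hash": cfg.config_hash(),
                        "models": models.to_dict(orient="records")},
                       indent=2, default=float))
        paths["models_json"] = out / "models.json"
        paths["report"] = out / "report.md"
        paths["report"].write_text(render_report(models, diagnostics, descriptives, fits,
                                                 cfg.config_hash()))
        log.info("run complete: %d individuals, %d models",
                 len(summaries), models[["species", "response"]].drop_duplicates().shape[0]
                 if len(models) else 0)
        return paths
    finally:
        log.removeHandler(handler)
        handler.close()


def reproduce(table: pd.DataFrame, roster: list[ModelSpec] | None = None,
              radii: tuple[float, ...] = (500.0, 1000.0, 2000.0), seed: int = 0,
              n_sim_diagnostics: int = 250):
    """Inference directly on a pre-derived per-individual table
    (the shape archives deposit): columns ``species, sex, site,
    duration_s, habitat_area, np_cov, urbanization_<r>...`` plus the
    response columns. Trajectory stages are skipped.
    """
    required = {"species", "sex", "site", "duration_s", "habitat_area", "np_cov"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"reproduction table lacks columns {sorted(missing)}")
    urb_cols = [c for c in table.columns if c.startswith("urbanization")]
    if not urb_cols:
        raise ValueError("reproduction table lacks urbanization columns")
    if "urbanization_2000" not in table.columns and len(urb_cols) == 1:
        table = table.rename(columns={urb_cols[0]: "urbanization_2000"})
        radii = (2000.0,)
    present = tuple(float(r) for r in radii
                    if f"urbanization_{int(r)}" in table.columns)
    # urbanization is a site property; nectar coverage and habitat area
    # stay on the per-individual rows (one transect per butterfly)
    covariates = (table[["site"] + [f"urbanization_{int(r)}" for r in present]]
                  .drop_duplicates("site").rename(columns={"site": "site_id"}))
    summaries = table.drop(columns=[c for c in table.columns
                                    if c.startswith("urbanization")])
    return fit_roster(summaries, covariates, roster=roster, radii=present,
                      seed=seed, n_sim_diagnostics=n_sim_diagnostics)


def render_report(models: pd.DataFrame, diagnostics: pd.DataFrame,
                  descriptives: pd.DataFrame, fits: dict, config_hash: str) -> str:
    """Markdown report: descriptive species block, one coefficient
    table per fitted model (KS deviations as footnote markers), and
    the per-model AIC radius-selection table."""
    lines = [f"# Movement analysis report", "",
             f"Config hash: `{config_hash}`", "", "## Species descriptives", ""]
    if len(descriptives):
        lines.append(descriptives.to_markdown(index=False, floatfmt=".3g"))
    lines.append("")
    for (species, response), (fit, radius, aic_table) in fits.items():
        mask = ((models["species"] == species) & (models["response"] == response)) \
            if len(models) else []
        block = models[mask] if len(models) else pd.DataFrame()
        ks_flag = bool(block["ks_deviation"].any()) if len(block) else False
        title = f"## {species} - {response}"
        if ks_flag:
            title += " [^ks]"
        lines += [title, "",
                  f"family `{block['family'].iloc[0] if len(block) else ''}`, "
                  f"urbanization radius {int(radius)} m", ""]
        if len(block):
            lines.append(block[["term", "estimate", "std_error", "z", "p"]]
                         .to_markdown(index=False, floatfmt=".4g"))
        lines += ["", "AIC by radius:",
                  aic_table.to_markdown(index=False, floatfmt=".2f"), ""]
    if len(models) and models["ks_deviation"].any():
        lines += ["[^ks]: Kolmogorov-Smirnov residual uniformity test: "
                  "deviation significant.", ""]
    return "\n".join(lines)
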