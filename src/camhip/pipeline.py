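"""Orchestration: outline measurement into hip tables, exposure/outcome
derivation (high bone mass, radiographic hip OA at baseline and follow-up),
and the Model 1-3 GEE association analyses with sex stratification and the
relaxed Croft >= 2 sensitivity definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .geometry import MeasureConfig, measure_hip
from .shape_io import FemurOutline, LandmarkScheme, read_points

__all__ = [
    "AnalysisSpec",
    "classify_hbm",
    "derive_outcomes",
    "derive_longitudinal",
    "measure_outlines",
    "measure_directory",
    "table_to_hips",
    "run_analysis",
    "validate_agreement",
]

log = logging.getLogger("camhip")

#: outcomes that are OA phenotypes (trigger the extra HBM adjustment in Model 3)
_OA_PHENOTYPES = {
    "oa",
    "any_osteophyte",
    "any_jsn",
    "any_sclerosis",
    "any_cyst",
    "incident",
    "progression",
    "croft_increase",
}


def classify_hbm(l1_z, th_z):
    """High bone mass: Z >= +3.2 at L1 or total hip with Z >= +1.2 at the
    other site.  Accepts scalars or arrays; boundaries inclusive."""
    l1 = np.asarray(l1_z, dtype=float)
    th = np.asarray(th_z, dtype=float)
    out = ((l1 >= 3.2) & (th >= 1.2)) | ((th >= 3.2) & (l1 >= 1.2))
    return bool(out) if out.ndim == 0 else out


def derive_outcomes(df: pd.DataFrame, croft_threshold: int = 3) -> pd.DataFrame:
    """Baseline outcome flags from radiographic grades (complete-case).

    ``oa`` is Croft grade >= ``croft_threshold`` (3 for the primary
    definition, 2 for the sensitivity analysis); ``any_*`` flags are grade
    >= 1.  Hips missing the Croft grade are dropped with a logged count,
    never imputed.
    """
    if croft_threshold not in (2, 3):
        raise ValueError("croft_threshold must be 2 or 3")
    n0 = len(df)
    out = df[df["croft_baseline"].notna()].copy()
    dropped = n0 - len(out)
    if dropped:
        log.info("derive_outcomes: excluded %d hips missing baseline Croft grade",
                 dropped)
    out["oa"] = (out["croft_baseline"] >= croft_threshold).astype(int)
    for grade, flag in (
        ("osteophyte", "any_osteophyte"),
        ("jsn", "any_jsn"),
        ("sclerosis", "any_sclerosis"),
        ("cyst", "any_cyst"),
    ):
        if grade in out.columns:
            out[flag] = (out[grade] >= 1).astype(int)
    return out


def derive_longitudinal(df: pd.DataFrame) -> pd.DataFrame:
    """Incident / progressive OA flags and grade change scores.

    Incident OA: free of OA at baseline (Croft < 3) and OA at follow-up
    (Croft >= 3).  Progressive OA: any increase in Croft score in a hip with
    OA (Croft >= 3) at baseline.  Hips without follow-up are excluded with a
    logged count.
    """
    n0 = len(df)
    out = df[df["croft_followup"].notna() & df["croft_baseline"].notna()].copy()
    dropped = n0 - len(out)
    if dropped:
        log.info("derive_longitudinal: excluded %d hips without follow-up", dropped)
    base = out["croft_baseline"].astype(float)
    fu = out["croft_followup"].astype(float)
    out["incident"] = ((base < 3) & (fu >= 3)).astype(int)
    out["progression"] = ((base >= 3) & (fu > base)).astype(int)
    out["croft_increase"] = (fu > base).astype(int)
    for grade in ("osteophyte", "jsn"):
        col = f"{grade}_followup"
        if col in out.columns:
            out[f"delta_{grade}"] = out[col].astype(float) - out[grade].astype(float)
    return out


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def measure_outlines(
    outlines: list[FemurOutline],
    scheme: LandmarkScheme | None = None,
    config: MeasureConfig | None = None,
) -> pd.DataFrame:
    """Measure a batch of outlines into a tidy per-hip results table."""
    rows = []
    for o in outlines:
        r = measure_hip(o, scheme, config)
        rows.append(
            {
                "subject_id": r.subject_id,
                "hip_id": r.hip_id,
                "side": o.side,
                "alpha_deg": np.nan if r.alpha_deg is None else round(r.alpha_deg, 1),
                "cam": r.cam,
                "neck_width": r.neck_width,
                "circle_x": r.circle.center[0],
                "circle_y": r.circle.center[1],
                "circle_r": r.circle.radius,
                "circle_rms": r.circle.rms_residual,
                "qc_flags": ";".join(sorted(r.qc_flags)),
            }
        )
    return pd.DataFrame(rows)


def measure_directory(
    points_dir: str | Path,
    scheme: LandmarkScheme | None = None,
    config: MeasureConfig | None = None,
    pattern: str = "*.pts",
) -> pd.DataFrame:
    paths = sorted(Path(points_dir).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no {pattern} files under {points_dir}")
    return measure_outlines([read_points(p) for p in paths], scheme, config)


# ---------------------------------------------------------------------------
# association analyses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisSpec:
    """One association analysis: exposure, outcome and adjustment level.

    Model 1 is unadjusted; Model 2 adds age and sex; Model 3 adds weight,
    height and adolescent activity (plus HBM status when a cam exposure is
    tested against an OA phenotype).  In sex-stratified mode sex leaves the
    covariate sets and the adjusted model uses age, weight, height and
    activity.
    """

    exposure: str
    outcome: str
    model: int = 3
    stratify_by_sex: bool = False
    croft_threshold: int = 3

    def __post_init__(self) -> None:
        if self.model not in (1, 2, 3):
            raise ValueError("model must be 1, 2 or 3")
        if self.croft_threshold not in (2, 3):
            raise ValueError("croft_threshold must be 2 or 3")

    def covariates(self, model: int) -> list[str]:
        if model == 1:
            return []
        if self.stratify_by_sex:
            # adjusted stratified model: age, weight, height, activity
            return ["age", "weight", "height", "activity"]
        if model == 2:
            return ["age", "sex"]
        cov = ["age", "sex", "weight", "height", "activity"]
        if self.exposure in ("cam", "alpha_sd") and self.outcome in _OA_PHENOTYPES:
            cov.append("hbm")
        return cov


_BMD_EXPOSURES = ("l1_bmd", "th_bmd_max")


def run_analysis(
    cohort: pd.DataFrame,
    spec: AnalysisSpec,
    working: str = "exchangeable",
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Fit the requested GEE models and return one tidy row per model/term.

    Clusters are individuals (``subject_id``); BMD exposures are
    standardized per SD on the analysis sample; complete-case filtering is
    logged.  Models that fail to converge or separate are reported in the
    output (``converged`` False / NaN estimates), never dropped.
    """
    df = cohort
    if "croft_baseline" in df.columns and (
        spec.outcome == "oa" or spec.outcome not in df.columns
    ):
        df = derive_outcomes(df, spec.croft_threshold)
    models = list(range(1, spec.model + 1))
    if spec.stratify_by_sex:
        models = [m for m in models if m != 3]  # stratified analyses use 2 models
    exposure = spec.exposure
    if exposure in _BMD_EXPOSURES:
        df = df.copy()
        df[exposure + "_sd"] = st.standardize(df[exposure])
        exposure = exposure + "_sd"

    strata = (
        [("all", df)]
        if not spec.stratify_by_sex
        else [(s, df[df["sex"] == s]) for s in ("male", "female")]
    )
    rows = []
    for stratum, sdf in strata:
        for model in models:
            needed = [exposure, spec.outcome, "subject_id"] + spec.covariates(model)
            sub = sdf.dropna(subset=[c for c in needed if c in sdf.columns])
            dropped = len(sdf) - len(sub)
            if dropped:
                log.info(
                    "run_analysis: model %d stratum %s excluded %d incomplete hips",
                    model, stratum, dropped,
                )
            covs = [exposure] + spec.covariates(model)
            try:
                fit = st.gee_logistic(
                    sub,
                    outcome=spec.outcome,
                    covariates=covs,
                    cluster="subject_id",
                    working=working,
                    conf_level=conf_level,
                    reference={"sex": "female", "activity": "0-1h"},
                )
            except (st.SeparationError, np.linalg.LinAlgError) as exc:
                log.warning("model %d stratum %s failed: %s", model, stratum, exc)
                rows.append(
                    {
                        "model": model, "stratum": stratum, "term": exposure,
                        "estimate": np.nan, "se": np.nan, "or": np.nan,
                        "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                        "n": len(sub), "n_clusters": sub["subject_id"].nunique(),
                        "working": working, "converged": False,
                    }
                )
                continue
            for _, t in fit.or_table.iterrows():
                rows.append(
                    {
                        "model": model, "stratum": stratum, "term": t["term"],
                        "estimate": t["estimate"], "se": t["se"], "or": t["or"],
                        "ci_low": t["ci_low"], "ci_high": t["ci_high"], "p": t["p"],
                        "n": fit.n_obs, "n_clusters": fit.n_clusters,
                        "working": working, "converged": fit.converged,
                    }
                )
    return pd.DataFrame(rows)


def table_to_hips(t: st.TwoByTwo, exposure: str = "exposure",
                  outcome: str = "outcome") -> pd.DataFrame:
    """Expand 2x2 counts into a hip-level table with arbitrary pairing.

    Consecutive hips share a subject (clusters of two), which exercises the
    clustered fit while leaving the crude odds ratio untouched — the GEE
    point estimate for an unadjusted binary exposure does not depend on the
    cluster assignment.
    """
    e = [1] * (t.a + t.b) + [0] * (t.c + t.d)
    y = [1] * t.a + [0] * t.b + [1] * t.c + [0] * t.d
    n = len(e)
    return pd.DataFrame(
        {
            "subject_id": [f"P{i // 2:04d}" for i in range(n)],
            exposure: e,
            outcome: y,
        }
    )


def validate_agreement(aa_manual, aa_auto, threshold: float = 60.0) -> dict:
    """Agreement between manual and semi-automatic alpha angles.

    Returns Cohen's kappa on the binary cam classifications at ``threshold``
    plus Lin's concordance correlation and Pearson's r on the angles.
    """
    aa_manual = np.asarray(aa_manual, dtype=float)
    aa_auto = np.asarray(aa_auto, dtype=float)
    if aa_manual.shape != aa_auto.shape:
        raise ValueError("paired vectors required")
    return {
        "kappa": st.cohens_kappa(
            (aa_manual >= threshold).astype(int), (aa_auto >= threshold).astype(int)
        ),
        "ccc": st.lins_ccc(aa_manual, aa_auto),
        "pearson_r": st.pearson_r(aa_manual, aa_auto),
    }
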