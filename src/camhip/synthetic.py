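"""Synthetic data generators: parametric femur outlines with known alpha
angles, and clustered two-hips-per-person cohorts with configurable effect
sizes.

The outline generator builds an analytic proximal-femur contour — a circular
head, a flaring neck channel symmetric about the neck axis, and an optional
cam bump that leaves the head circle at a prescribed angle — and samples it
at the 65 landmark indices of the annotation scheme.  Because the narrowest
neck section lies exactly on the neck axis by construction, the analytic
alpha angle equals the cam onset angle (or the tangent-departure angle of
the neck when there is no bump), which makes every geometric operation
testable against ground truth.

The cohort generator emulates the structure of a high-bone-mass family
cohort: individuals contribute two hips; covariates (age, sex, height,
weight, adolescent sport) follow configurable distributions; per-hip cam
status follows a logistic model; radiographic hip OA follows a logistic
model with a shared per-individual normal random intercept, which induces
the left-right correlation that the GEE analyses must absorb.  A numerical
oracle converts the conditional (random-intercept) odds ratio into the
population-averaged odds ratio that a GEE fit should recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .shape_io import N_POINTS, FemurOutline, LandmarkScheme, mirror_outline

__all__ = [
    "OutlineParams",
    "LogisticModel",
    "OaModel",
    "FollowupModel",
    "CohortParams",
    "ACTIVITY_LEVELS",
    "generate_outline",
    "generate_cohort",
    "marginal_or_oracle",
]

#: Adolescent sport categories (hours per week, ages 14-21), reference first.
ACTIVITY_LEVELS = ("0-1h", "2-3h", "4-7h", ">7h")


# ---------------------------------------------------------------------------
# outlines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlineParams:
    """Parameters of one synthetic proximal-femur outline.

    ``cam_onset_deg`` is the angle (at the head centre, measured from the
    neck axis toward the lateral side) at which the contour leaves the head
    circle; with ``cam_amplitude > 0`` it IS the analytic alpha angle.  With
    amplitude 0 the contour departs tangentially where the neck channel
    leaves the circle, at ``asin(neck_width / (2 * head_radius))``.
    """

    head_center: tuple[float, float] = (100.0, 100.0)
    head_radius: float = 30.0
    neck_width: float = 20.0
    neck_length: float = 30.0
    neck_axis_angle: float = 90.0
    cam_onset_deg: float = 75.0
    cam_amplitude: float = 3.0
    jitter_sd: float = 0.0
    side: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head_radius <= self.neck_width / 2:
            raise ValueError("head_radius must exceed neck_width/2")
        if not (0.0 < self.cam_onset_deg < 150.0):
            raise ValueError("cam_onset_deg must lie in (0, 150)")
        if self.cam_amplitude < 0 or self.jitter_sd < 0:
            raise ValueError("cam_amplitude and jitter_sd must be >= 0")
        if self.neck_length <= 0:
            raise ValueError("neck_length must be positive")
        if self.cam_amplitude > 0 and self.cam_onset_deg < self.tangent_deg + 5.0:
            raise ValueError(
                "cam_onset_deg must sit at least 5 deg lateral of the neck "
                f"tangent angle ({self.tangent_deg:.1f} deg)"
            )

    @property
    def tangent_deg(self) -> float:
        """Angle at which the unflared neck channel leaves the head circle."""
        return math.degrees(math.asin(self.neck_width / (2.0 * self.head_radius)))

    @property
    def alpha_truth_deg(self) -> float:
        """Analytic alpha angle implied by the construction."""
        return self.cam_onset_deg if self.cam_amplitude > 0 else self.tangent_deg


def generate_outline(
    params: OutlineParams, scheme: LandmarkScheme | None = None
) -> tuple[FemurOutline, float]:
    """Build one outline and return ``(outline, analytic_alpha_deg)``.

    Index layout (default scheme): 0-15 medial neck/shaft line, 16-18 and
    19-32 (head arc) on the head circle, 33-36 head/neck junction including
    the cam bump, 37-49 lateral neck line, 50-64 lateral shaft filler.
    The narrowest neck station (midpoint on the axis) is a vertex of both
    neck segments, so the analytic alpha is exact, not approximate.
    """
    scheme = scheme or LandmarkScheme()
    if scheme.head_arc != (19, 32) or scheme.neck_seg_a != (2, 15) or (
        scheme.neck_seg_b != (37, 49)
    ):
        raise ValueError("generate_outline supports the default landmark scheme")
    R = params.head_radius
    w0 = params.neck_width
    L = params.neck_length
    A = params.cam_amplitude
    onset = params.cam_onset_deg
    theta_t = params.tangent_deg

    a = math.radians(params.neck_axis_angle)
    u = np.array([math.cos(a), math.sin(a)])       # along the neck, away from head
    n = np.array([-math.sin(a), math.cos(a)])      # lateral (cam) side

    s0 = R + 0.55 * L                               # narrowest neck station
    step = L / 10.0
    flare = 0.1 / L                                 # offset o(s) = w0/2 + flare*(s-s0)^2

    def neck_point(k: float, lateral: bool) -> np.ndarray:
        s = s0 + k * step
        o = w0 / 2.0 + flare * (s - s0) ** 2
        return s * u + (o if lateral else -o) * n

    def circle_point(psi_deg: float, r: float = R) -> np.ndarray:
        psi = math.radians(psi_deg)
        return r * (math.cos(psi) * u + math.sin(psi) * n)

    pts = np.zeros((N_POINTS, 2))
    # medial line: indices 0..15 <-> stations k = 10 .. -5 (toward the head)
    for i in range(16):
        pts[i] = neck_point(10 - i, lateral=False)
    # medial junction -> head arc start, on the circle
    for i, psi in zip((16, 17, 18), (-45.0, -75.0, -105.0)):
        pts[i] = circle_point(psi)
    # head arc 19..32: sweep the dome (through 180 deg) to the lateral side
    theta_end = max(130.0, onset + 20.0) if A > 0 else 130.0
    for i, psi in enumerate(np.linspace(-130.0, theta_end - 360.0, 14)):
        pts[19 + i] = circle_point(psi)
    # junction region 33..36
    if A > 0:
        ramp = 10.0  # deg over which the bump reaches full amplitude
        junction = [
            (onset + 12.0, R),
            (onset + 5.0, R),
            (onset, R),
            (onset - 2.5, R + A * min(1.0, 2.5 / ramp)),
        ]
    else:
        hi = theta_end - 20.0
        junction = [
            (hi, R),
            ((hi + theta_t + 8.0) / 2.0, R),
            (theta_t + 8.0, R),
            (theta_t, R),  # exact tangency point of the w0 channel
        ]
    for i, (psi, r) in zip((33, 34, 35, 36), junction):
        pts[i] = circle_point(psi - 360.0, r)
    # lateral line: indices 37..49 <-> k = -5..7, then shaft filler 50..64
    for i in range(37, 50):
        pts[i] = neck_point(i - 42, lateral=True)
    for i in range(50, 65):
        pts[i] = neck_point(i - 42, lateral=True)

    pts = pts + np.asarray(params.head_center, dtype=float)
    rng = np.random.default_rng(params.seed)
    if params.jitter_sd > 0:
        pts = pts + rng.normal(0.0, params.jitter_sd, size=pts.shape)

    outline = FemurOutline(
        points=pts,
        side="left",
        subject_id="synthetic",
        hip_id=f"synthetic-{params.seed}",
        source="camhip.synthetic.generate_outline",
    )
    if params.side == "right":
        outline = mirror_outline(outline)
    return outline, params.alpha_truth_deg


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticModel:
    """Log-odds model: intercept + sum(coefs[col] * df[col])."""

    intercept: float = 0.0
    coefs: dict[str, float] = field(default_factory=dict)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(df), self.intercept, dtype=float)
        for col, beta in self.coefs.items():
            lp += beta * df[col].to_numpy(dtype=float)
        return lp


@dataclass(frozen=True)
class OaModel(LogisticModel):
    """Conditional (random-intercept) logistic model for radiographic hip OA.

    The default intercept gives ~20% marginal OA prevalence at the default
    conditional cam odds ratio of 3 and random-intercept sd of 1.
    """

    intercept: float = -1.95
    log_or_cam: float = math.log(3.0)
    random_intercept_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")


@dataclass(frozen=True)
class FollowupModel:
    p_retained: float = 0.33
    prog_intercept: float = -2.2
    prog_log_or_cam: float = 0.0


@dataclass(frozen=True)
class CohortParams:
    """Study-design parameters of a synthetic two-hips-per-person cohort.

    Defaults emulate the published cohort's demographics: two thirds female,
    two thirds high bone mass, age 61.6 (SD 11.8) years, sex-conditional
    height/weight, the four adolescent-sport categories at their observed
    frequencies, ~21% cam prevalence driven by male sex, and ~20% OA
    prevalence with a conditional cam odds ratio of 3.
    """

    n_individuals: int = 352
    p_female: float = 0.667
    p_hbm: float = 0.665
    age_mean: float = 61.6
    age_sd: float = 11.8
    height_by_sex: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"female": (163.0, 7.0), "male": (177.0, 7.0)}
    )
    weight_by_sex: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"female": (80.0, 15.0), "male": (90.0, 15.0)}
    )
    activity_probs: tuple[float, ...] = (0.110, 0.291, 0.240, 0.359)
    cam_model: LogisticModel = field(
        default_factory=lambda: LogisticModel(intercept=-2.05, coefs={"male": 1.55})
    )
    oa_model: OaModel = field(default_factory=OaModel)
    followup: FollowupModel = field(default_factory=FollowupModel)
    n_centres: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_female, self.p_hbm, self.followup.p_retained):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        probs = np.asarray(self.activity_probs, dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("activity_probs must be non-negative and sum to 1")
        if self.age_sd < 0:
            raise ValueError("sds must be >= 0")


# grade cutpoints on the OA linear predictor (proportional odds, 0-3 grades)
_GRADE_CUTPOINTS = {
    "osteophyte": -2.55,
    "jsn": -0.26,
    "sclerosis": 1.72,
    "cyst": 2.5,
}
_GRADE_STEP = 1.8


def _ordinal_grade(eta: np.ndarray, c1: float, rng: np.random.Generator) -> np.ndarray:
    """Draw 0-3 grades from a proportional-odds model with cutpoints c1+step*g."""
    v = rng.uniform(size=eta.shape)
    grade = np.zeros(eta.shape, dtype=int)
    for g in range(3):
        grade += (v < expit(eta - (c1 + _GRADE_STEP * g))).astype(int)
    return grade


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Simulate a hip-level cohort table (two rows per individual).

    Returns a DataFrame with one row per hip carrying identifiers,
    covariates, bone-density measures, cam status with an alpha angle,
    baseline OA/subphenotype grades and (for retained individuals)
    monotone follow-up grades.  Fully deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_individuals

    female = rng.uniform(size=n) < params.p_female
    sex = np.where(female, "female", "male")
    hbm = rng.uniform(size=n) < params.p_hbm
    age = rng.normal(params.age_mean, params.age_sd, size=n)
    height = np.empty(n)
    weight = np.empty(n)
    for s in ("female", "male"):
        m = sex == s
        hm, hs = params.height_by_sex[s]
        wm, ws = params.weight_by_sex[s]
        height[m] = rng.normal(hm, hs, size=m.sum())
        weight[m] = rng.normal(wm, ws, size=m.sum())
    activity = rng.choice(
        np.arange(len(ACTIVITY_LEVELS)), size=n, p=np.asarray(params.activity_probs)
    )
    centre = rng.integers(1, params.n_centres + 1, size=n)

    # BMD Z-scores consistent with the HBM classification rule
    l1_z = np.where(hbm, 3.4 + np.abs(rng.normal(0, 1, n)), rng.normal(0.8, 1.2, n))
    th_z = np.where(hbm, 1.4 + np.abs(rng.normal(0, 1, n)), rng.normal(0.8, 1.0, n))
    l1_z = np.where(~hbm, np.minimum(l1_z, 3.1), l1_z)
    th_z = np.where(~hbm, np.minimum(th_z, 3.1), th_z)
    l1_bmd = 1.05 + 0.14 * l1_z + rng.normal(0, 0.04, n)
    th_bmd_max = 1.00 + 0.12 * th_z + rng.normal(0, 0.03, n)

    # per-individual random intercept shared by both hips
    u_i = rng.normal(0.0, params.oa_model.random_intercept_sd, size=n)
    followed = rng.uniform(size=n) < params.followup.p_retained

    # expand to hips
    idx = np.repeat(np.arange(n), 2)
    side = np.tile(["left", "right"], n)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in idx],
            "hip_id": [f"S{i:04d}-{s[0].upper()}" for i, s in zip(idx, side)],
            "side": side,
            "sex": sex[idx],
            "male": (~female[idx]).astype(int),
            "age": age[idx],
            "height": height[idx],
            "weight": weight[idx],
            "activity": pd.Categorical.from_codes(
                activity[idx], categories=list(ACTIVITY_LEVELS), ordered=True
            ),
            "hbm": hbm[idx].astype(int),
            "l1_z": l1_z[idx],
            "th_z": th_z[idx],
            "l1_bmd": l1_bmd[idx],
            "th_bmd_max": th_bmd_max[idx],
            "centre": [f"centre{c}" for c in centre[idx]],
        }
    )
    m = len(df)

    cam = (rng.uniform(size=m) < expit(params.cam_model.linear_predictor(df))).astype(int)
    df["cam"] = cam
    # alpha angles consistent with cam status (threshold 60 deg)
    alpha = np.where(
        cam == 1,
        62.0 + np.abs(rng.normal(0, 8.0, m)),
        56.0 - np.abs(rng.normal(0, 7.0, m)),
    )
    df["alpha_deg"] = np.clip(alpha, 10.0, 130.0)

    eta = params.oa_model.linear_predictor(df)
    eta = eta + params.oa_model.log_or_cam * cam + u_i[idx]
    oa = (rng.uniform(size=m) < expit(eta)).astype(int)
    df["oa"] = oa

    grades = {
        name: _ordinal_grade(eta, c1, rng) for name, c1 in _GRADE_CUTPOINTS.items()
    }
    # keep grades consistent with the Croft rule (OA <=> two of four features)
    feat = np.stack([grades[k] >= 1 for k in _GRADE_CUTPOINTS], axis=0)
    n_feat = feat.sum(axis=0)
    need = (oa == 1) & (n_feat < 2)
    grades["osteophyte"] = np.where(need, np.maximum(grades["osteophyte"], 1),
                                    grades["osteophyte"])
    grades["jsn"] = np.where(need, np.maximum(grades["jsn"], 1), grades["jsn"])
    drop = oa == 0
    order = ["osteophyte", "jsn", "sclerosis", "cyst"]
    stacked = np.stack([grades[k] for k in order], axis=0)
    keep = np.argmax(stacked, axis=0)
    for j, name in enumerate(order):
        grades[name] = np.where(drop & (keep != j), 0, grades[name])
    for name in order:
        df[name] = grades[name]
    max_grade = np.max(np.stack([grades[k] for k in order], axis=0), axis=0)
    df["croft_baseline"] = np.where(
        oa == 1, 3 + (grades["osteophyte"] >= 2).astype(int), np.minimum(max_grade, 2)
    )

    # follow-up: monotone non-decreasing grades under a progression model
    df["followed"] = followed[idx]
    prog_lp = (
        params.followup.prog_intercept
        + params.followup.prog_log_or_cam * cam
        + u_i[idx]
    )
    inc_croft = (rng.uniform(size=m) < expit(prog_lp)).astype(int)
    inc_ost = (rng.uniform(size=m) < expit(prog_lp)).astype(int)
    inc_jsn = (rng.uniform(size=m) < expit(prog_lp)).astype(int)
    fu = np.where(followed[idx], np.minimum(df["croft_baseline"] + inc_croft, 5), np.nan)
    df["croft_followup"] = fu
    df["osteophyte_followup"] = np.where(
        followed[idx], np.minimum(df["osteophyte"] + inc_ost, 3), np.nan
    )
    df["jsn_followup"] = np.where(
        followed[idx], np.minimum(df["jsn"] + inc_jsn, 3), np.nan
    )
    return df


def marginal_or_oracle(
    params: CohortParams, x_ref: dict[str, float] | None = None, n_nodes: int = 96
) -> float:
    """Population-averaged OR for cam implied by the conditional OA model.

    Integrates the random intercept out of the conditional logistic model by
    Gauss-Hermite quadrature at fixed covariate values (defaults: all model
    covariates at zero), and forms the odds ratio of the two marginal
    probabilities.  This is the estimand a population-averaged (GEE) fit of
    OA on cam recovers, and is strictly attenuated toward 1 relative to the
    conditional OR whenever the random-intercept sd is positive.
    """
    model = params.oa_model
    eta0 = model.intercept
    for col, beta in model.coefs.items():
        eta0 += beta * (x_ref or {}).get(col, 0.0)
    sd = model.random_intercept_sd
    if sd == 0:
        p1 = expit(eta0 + model.log_or_cam)
        p0 = expit(eta0)
    else:
        t, w = np.polynomial.hermite.hermgauss(n_nodes)
        w = w / math.sqrt(math.pi)
        shift = math.sqrt(2.0) * sd * t
        p1 = float(w @ expit(eta0 + model.log_or_cam + shift))
        p0 = float(w @ expit(eta0 + shift))
    if not (np.isfinite(p1) and np.isfinite(p0)):
        raise ValueError("non-finite integrand in marginal OR oracle")
    return float((p1 / (1.0 - p1)) / (p0 / (1.0 - p0)))
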