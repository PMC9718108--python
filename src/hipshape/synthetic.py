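"""Synthetic hip-landmark cohorts with known ground truth.

Real pipelines of this kind start from anteroposterior pelvic radiographs
annotated with 82 landmark points along the bony contours of the hip joint.
No such data ships with this package, so this module generates cohorts with
the statistical structure the analysis assumes:

* a parametric per-sex template hip contour (femoral head arc, head-neck
  junction, lateral/medial neck, acetabular rim);
* a low-rank smooth orthonormal deformation basis, orthogonal to the
  similarity directions (translation, rotation, scaling) at the template, so
  true shape variation survives Procrustes alignment;
* per-hip mode scores z ~ N(0, 1), landmark noise, and nuisance similarity
  transforms; left hips are mirrored copies of the right-hip convention;
* participant covariates (sex, age, BMI, symptomatic status) matching the
  young-football-cohort marginals the analysis targets;
* binary cartilage/labral outcomes from a logistic model with mode effects,
  covariate effects and a participant-level random intercept shared by both
  hips, then SHOMRI subregion grades that round-trip exactly through the
  dichotomization rules.

Everything is driven by a single integer seed and is fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .io import (
    CARTILAGE_COLS,
    LABRAL_COLS,
    LandmarkConfiguration,
    write_hip_table,
    write_points_file,
)
from .procrustes import flatten_points, unflatten_points

N_POINTS = 82
#: points per anatomical segment, in polyline order
SEGMENT_SIZES = {
    "head_arc": 30,
    "headneck_junction": 7,
    "lateral_neck": 15,
    "medial_neck": 8,
    "acetabular_rim": 22,
}

HEAD_RADIUS = {"male": 25.0, "female": 22.0}
RIM_RADIUS = 28.0
HEAD_ARC_DEG = (200.0, -20.0)
RIM_ARC_DEG = (30.0, 150.0)


@dataclass
class TemplateShape:
    """82-point parametric hip contour, centroid at the origin (mm, y-up)."""

    points: np.ndarray
    segment_labels: tuple[str, ...]
    sex: str

    def segment(self, label: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.segment_labels) if s == label]
        return self.points[idx]


def _bezier(p0, p1, p2, p3, n: int) -> np.ndarray:
    """Sample a cubic Bezier curve at n evenly spaced parameter values."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    return ((1 - t) ** 3 * p0 + 3 * (1 - t) ** 2 * t * p1
            + 3 * (1 - t) * t**2 * p2 + t**3 * p3)


def make_template(sex: str) -> TemplateShape:
    """Parametric hip template for one sex (head radius 25 mm male, 22 female).

    Segments, in polyline order: 30 points on the femoral-head circular arc
    (200 deg -> -20 deg); 7 head-neck-junction points on a blending arc of
    radius 10 mm centred radially outside the lateral end of the head arc;
    15 lateral-neck / greater-trochanter points on a cubic Bezier; 8
    medial-neck points on a cubic Bezier; 22 acetabular-rim points on an arc
    of radius 28 mm concentric with the head (30 deg -> 150 deg).  The
    centroid is translated to the origin.
    """
    if sex not in HEAD_RADIUS:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    r = HEAD_RADIUS[sex]

    th = np.deg2rad(np.linspace(*HEAD_ARC_DEG, SEGMENT_SIZES["head_arc"]))
    head = r * np.column_stack([np.cos(th), np.sin(th)])

    # Blending arc: radius 10 mm, centred 10 mm radially beyond the lateral
    # head-arc endpoint, swept from 150 deg to 60 deg (7 points).
    c_jn = (r + 10.0) * np.array([np.cos(np.deg2rad(-20)), np.sin(np.deg2rad(-20))])
    phi = np.deg2rad(np.linspace(150.0, 60.0, SEGMENT_SIZES["headneck_junction"]))
    junction = c_jn + 10.0 * np.column_stack([np.cos(phi), np.sin(phi)])

    # Lateral neck and greater trochanter: bulge outwards then run down.
    lateral = _bezier(
        junction[-1],
        (r + 18.0, 5.0),
        (r + 22.0, -16.0),
        (r + 16.0, -36.0),
        SEGMENT_SIZES["lateral_neck"],
    )

    # Medial neck: gentle concave curve from the medial head-arc end downward.
    medial = _bezier(
        head[0],
        (-r + 2.0, -18.0),
        (-r + 5.0, -27.0),
        (-r + 7.0, -36.0),
        SEGMENT_SIZES["medial_neck"],
    )

    rho = np.deg2rad(np.linspace(*RIM_ARC_DEG, SEGMENT_SIZES["acetabular_rim"]))
    rim = RIM_RADIUS * np.column_stack([np.cos(rho), np.sin(rho)])

    pts = np.vstack([head, junction, lateral, medial, rim])
    pts = pts - pts.mean(axis=0)
    labels = tuple(
        label for label, size in SEGMENT_SIZES.items() for _ in range(size)
    )
    return TemplateShape(points=pts, segment_labels=labels, sex=sex)


def similarity_basis(template_points: np.ndarray) -> np.ndarray:
    """Orthonormal basis (4, 2k) of the similarity directions at a centered
    template: x/y translation, scaling, and infinitesimal rotation."""
    pts = np.asarray(template_points, float)
    k = pts.shape[0]
    flat = flatten_points(pts)
    tx = np.concatenate([np.ones(k), np.zeros(k)]) / np.sqrt(k)
    ty = np.concatenate([np.zeros(k), np.ones(k)]) / np.sqrt(k)
    scale = flat / np.linalg.norm(flat)
    rot = np.concatenate([-pts[:, 1], pts[:, 0]])
    rot = rot / np.linalg.norm(rot)
    # For a centered template these four are exactly mutually orthogonal.
    return np.stack([tx, ty, scale, rot])


def make_mode_basis(
    template: TemplateShape,
    n_modes: int,
    smooth_window: int = 7,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Smooth random orthonormal deformation modes (n_modes, 164).

    Standard-normal draws in R^164 are smoothed along the point index with a
    centered moving average (width ``smooth_window``) per coordinate channel,
    then Gram-Schmidt-orthogonalised against the four similarity directions
    and previously accepted modes, and normalised.  Deterministic given the
    seed.
    """
    if n_modes > 2 * N_POINTS - 4:
        raise ValueError(f"at most {2 * N_POINTS - 4} modes exist, requested {n_modes}")
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    sim = similarity_basis(template.points)
    kernel = np.ones(smooth_window) / smooth_window

    basis: list[np.ndarray] = []
    for j in range(n_modes):
        v = rng.standard_normal(2 * N_POINTS)
        x = np.convolve(v[:N_POINTS], kernel, mode="same")
        y = np.convolve(v[N_POINTS:], kernel, mode="same")
        v = np.concatenate([x, y])
        for _ in range(2):  # double Gram-Schmidt pass for numerical hygiene
            for b in list(sim) + basis:
                v = v - (v @ b) * b
        nrm = np.linalg.norm(v)
        if nrm < 1e-8:
            raise ValueError(
                f"degenerate random draw for mode {j}: Gram-Schmidt residual "
                f"norm {nrm:.3g} < 1e-8; use a different seed"
            )
        basis.append(v / nrm)
    return np.stack(basis)


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the cohort the analysis targets: 229 participants, 77.7%
    male, age ~ truncated Normal(26, 4) on [18, 50] years, BMI ~
    Normal(24.5, 2.5) kg/m^2, hip-level symptomatic-status marginals
    (0.629, 0.157, 0.214), ~4% of hips with KL > 0, 15 true shape modes with
    a power-law eigenspectrum (mode-1 RMS landmark displacement 2 mm), and
    cartilage-outcome log-odds of log 0.75, log 1.34 and log 0.61 per SD on
    modes 1, 12 and 15 (labral: log 1.30 on mode 12).
    """

    n_participants: int = 229
    male_fraction: float = 0.777
    n_true_modes: int = 15
    eigen_decay: float = 1.2           # gamma in lambda_j ~ j^-gamma
    mode1_rms_mm: float = 2.0          # sets the eigenspectrum scale c
    landmark_noise_sd: float = 0.5     # mm, iid per coordinate
    max_rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    max_translation_mm: float = 20.0
    smooth_window: int = 7
    # 1-based mode index -> log-OR per SD of true score
    effect_spec: tuple[tuple[int, float], ...] = (
        (1, float(np.log(0.75))),
        (12, float(np.log(1.34))),
        (15, float(np.log(0.61))),
    )
    labral_effect_spec: tuple[tuple[int, float], ...] = ((12, float(np.log(1.30))),)
    covariate_effects: dict = field(
        default_factory=lambda: {
            "age": 0.03,          # per year, centered at 26
            "bmi": 0.04,          # per kg/m^2, centered at 24.5
            "symptomatic": 0.6,   # vs asymptomatic
            "other": 0.2,         # vs asymptomatic
        }
    )
    random_effect_sd: float = 0.5      # sigma_u, logit scale, shared per participant
    baseline_logit: float = -0.33      # cartilage; ~52% marginal prevalence
    labral_baseline_logit: float = 0.46  # ~70% marginal prevalence
    status_probs: tuple[float, float, float] = (0.629, 0.157, 0.214)
    kl_positive_prob: float = 0.041
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must lie in [0, 1]")
        if not 1 <= self.n_true_modes <= 2 * N_POINTS - 4:
            raise ValueError(f"n_true_modes must lie in 1..{2 * N_POINTS - 4}")
        if self.eigen_decay <= 0:
            raise ValueError("eigen_decay must be > 0")
        if self.random_effect_sd < 0:
            raise ValueError("random_effect_sd must be >= 0")
        for p in (self.kl_positive_prob, *self.status_probs):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.status_probs) - 1.0) > 1e-9:
            raise ValueError("status_probs must sum to 1")
        for idx, _ in (*self.effect_spec, *self.labral_effect_spec):
            if not 1 <= idx <= self.n_true_modes:
                raise ValueError(f"effect on mode {idx} outside 1..{self.n_true_modes}")

    def eigenvalues(self) -> np.ndarray:
        """Power-law spectrum lambda_j = c * j^-gamma with the scale c fixed
        so mode-1 RMS landmark displacement is ``mode1_rms_mm``."""
        c = self.mode1_rms_mm**2 * N_POINTS
        j = np.arange(1, self.n_true_modes + 1, dtype=float)
        return c * j**-self.eigen_decay


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    mode_basis: dict            # sex -> (J, 164) orthonormal rows
    eigenvalues: np.ndarray     # (J,)
    true_scores: pd.DataFrame   # index hip_id, columns mode_1..mode_J
    random_effects: dict        # participant_id -> u
    effect_spec: tuple
    labral_effect_spec: tuple
    seed: int


def simulate_shomri(
    outcome_cartilage: bool,
    outcome_labral: bool,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """SHOMRI subregion grades consistent with the two binary outcomes.

    Cartilage-positive hips get 1 + Binomial(3, 0.3) affected subregions with
    grades uniform in {1, 2}; negative hips are all-zero.  Labral-positive
    hips get 1 + Binomial(3, 0.25) subregions with tear grades uniform in
    {2..5} and the rest uniform in {0, 1}; negative hips are uniform {0, 1}
    throughout.  The grades round-trip exactly through the dichotomization
    rules.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cart = np.zeros(10, dtype=int)
    if outcome_cartilage:
        n_affected = 1 + rng.binomial(3, 0.3)
        which = rng.choice(10, size=n_affected, replace=False)
        cart[which] = rng.integers(1, 3, size=n_affected)
    if outcome_labral:
        lab = rng.integers(0, 2, size=4)
        n_torn = 1 + rng.binomial(3, 0.25)
        which = rng.choice(4, size=n_torn, replace=False)
        lab[which] = rng.integers(2, 6, size=n_torn)
    else:
        lab = rng.integers(0, 2, size=4)
    return tuple(int(g) for g in cart), tuple(int(g) for g in lab)


def _rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _draw_hip_statuses(p_sym_hip_given_sym: float, rng) -> tuple[str, str]:
    """Statuses for the two hips of a symptomatic participant, hitting the
    target per-hip symptomatic fraction exactly (both symptomatic with
    probability 2q - 1, else one symptomatic and one 'other')."""
    q = min(max(p_sym_hip_given_sym, 0.5), 1.0)
    if rng.random() < 2 * q - 1:
        return "symptomatic", "symptomatic"
    if rng.random() < 0.5:
        return "symptomatic", "other"
    return "other", "symptomatic"


def simulate_cohort(
    cfg: GeneratorConfig,
) -> tuple[list[LandmarkConfiguration], pd.DataFrame, SyntheticTruth]:
    """Generate landmark configurations, the clinical table and ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    templates = {s: make_template(s) for s in ("male", "female")}
    basis_seeds = {s: int(rng.integers(2**31)) for s in ("male", "female")}
    bases = {
        s: make_mode_basis(templates[s], cfg.n_true_modes, cfg.smooth_window,
                           seed=basis_seeds[s])
        for s in ("male", "female")
    }
    lam = cfg.eigenvalues()
    sqrt_lam = np.sqrt(lam)
    eff = dict(cfg.effect_spec)
    lab_eff = dict(cfg.labral_effect_spec)
    cov = cfg.covariate_effects

    p_sym, p_other, _ = cfg.status_probs
    p_participant_sym = p_sym + p_other
    q = p_sym / p_participant_sym if p_participant_sym > 0 else 0.0

    configs: list[LandmarkConfiguration] = []
    rows: list[dict] = []
    score_rows: dict[str, np.ndarray] = {}
    random_effects: dict[str, float] = {}

    for i in range(cfg.n_participants):
        pid = f"P{i + 1:04d}"
        sex = "male" if rng.random() < cfg.male_fraction else "female"
        age = float(truncnorm.rvs(-2.0, 6.0, loc=26.0, scale=4.0, random_state=rng))
        bmi = float(rng.normal(24.5, 2.5))
        u = float(rng.normal(0.0, cfg.random_effect_sd))
        random_effects[pid] = u

        if rng.random() < p_participant_sym:
            statuses = _draw_hip_statuses(q, rng)
        else:
            statuses = ("asymptomatic", "asymptomatic")

        template = templates[sex]
        basis = bases[sex]
        for side, status in zip(("right", "left"), statuses):
            hip_id = f"{pid}_{side}"
            z = rng.standard_normal(cfg.n_true_modes)
            score_rows[hip_id] = z

            deformation = unflatten_points((sqrt_lam * z) @ basis)
            pts = template.points + deformation
            pts = pts + rng.normal(0.0, cfg.landmark_noise_sd, size=pts.shape)
            if side == "left":
                pts = pts * np.array([-1.0, 1.0])
            theta = np.deg2rad(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
            scale = rng.uniform(*cfg.scale_range)
            shift = rng.uniform(-cfg.max_translation_mm, cfg.max_translation_mm, size=2)
            pts = scale * pts @ _rotation(theta).T + shift

            configs.append(
                LandmarkConfiguration(
                    hip_id=hip_id, participant_id=pid, side=side, sex=sex, points=pts
                )
            )

            lp = cfg.baseline_logit + u
            lp += cov.get("age", 0.0) * (age - 26.0) + cov.get("bmi", 0.0) * (bmi - 24.5)
            lp_lab = cfg.labral_baseline_logit + u
            lp_lab += cov.get("age", 0.0) * (age - 26.0) + cov.get("bmi", 0.0) * (bmi - 24.5)
            if status == "symptomatic":
                lp += cov.get("symptomatic", 0.0)
                lp_lab += cov.get("symptomatic", 0.0)
            elif status == "other":
                lp += cov.get("other", 0.0)
                lp_lab += cov.get("other", 0.0)
            for m, beta in eff.items():
                lp += beta * z[m - 1]
            for m, beta in lab_eff.items():
                lp_lab += beta * z[m - 1]

            y_cart = bool(rng.random() < expit(lp))
            y_lab = bool(rng.random() < expit(lp_lab))
            cart_grades, lab_grades = simulate_shomri(y_cart, y_lab, rng=rng)

            kl = 0
            if rng.random() < cfg.kl_positive_prob:
                kl = int(rng.choice([1, 2], p=[0.7, 0.3]))

            row = {
                "participant_id": pid,
                "side": side,
                "sex": sex,
                "age": age,
                "bmi": bmi,
                "symptomatic_status": status,
                "kl_grade": kl,
            }
            row.update(dict(zip(CARTILAGE_COLS, cart_grades)))
            row.update(dict(zip(LABRAL_COLS, lab_grades)))
            rows.append(row)

    table = pd.DataFrame(rows)
    scores = pd.DataFrame.from_dict(
        score_rows, orient="index",
        columns=[f"mode_{j}" for j in range(1, cfg.n_true_modes + 1)],
    )
    scores.index.name = "hip_id"
    truth = SyntheticTruth(
        mode_basis=bases,
        eigenvalues=lam,
        true_scores=scores,
        random_effects=random_effects,
        effect_spec=cfg.effect_spec,
        labral_effect_spec=cfg.labral_effect_spec,
        seed=cfg.seed,
    )
    return configs, table, truth


def write_cohort(
    configs: list[LandmarkConfiguration],
    table: pd.DataFrame,
    truth: SyntheticTruth,
    cfg: GeneratorConfig,
    out_dir: str | Path,
) -> Path:
    """Write a cohort to disk: per-hip .pts files (with metadata sidecars),
    the clinical CSV, ground-truth CSVs and the generator config as JSON."""
    out = Path(out_dir)
    landmarks = out / "landmarks"
    landmarks.mkdir(parents=True, exist_ok=True)
    for config in configs:
        write_points_file(config, landmarks / f"{config.hip_id}.pts")
    write_hip_table(table, out / "clinical.csv")

    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    truth.true_scores.to_csv(truth_dir / "true_scores.csv")
    pd.DataFrame({"eigenvalue": truth.eigenvalues}).to_csv(
        truth_dir / "eigenvalues.csv", index=False
    )
    for sex, basis in truth.mode_basis.items():
        pd.DataFrame(basis).to_csv(truth_dir / f"mode_basis_{sex}.csv", index=False)
    pd.Series(truth.random_effects, name="u").rename_axis("participant_id").to_csv(
        truth_dir / "random_effects.csv"
    )

    cfg_dict = asdict(cfg)
    cfg_dict["effect_spec"] = [list(e) for e in cfg.effect_spec]
    cfg_dict["labral_effect_spec"] = [list(e) for e in cfg.labral_effect_spec]
    cfg_dict["scale_range"] = list(cfg.scale_range)
    cfg_dict["status_probs"] = list(cfg.status_probs)
    (out / "generator_config.json").write_text(
        json.dumps(cfg_dict, sort_keys=True, indent=1) + "\n"
    )
    return out


__all__ = [
    "TemplateShape",
    "GeneratorConfig",
    "SyntheticTruth",
    "make_template",
    "make_mode_basis",
    "similarity_basis",
    "simulate_shomri",
    "simulate_cohort",
    "write_cohort",
    "SEGMENT_SIZES",
    "HEAD_RADIUS",
]
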