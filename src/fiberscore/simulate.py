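"""Synthetic SHG-like collagen images and survival cohorts with ground truth.

Image side
----------
Fibers are circular arcs (straight lines when the turn angle is zero)
rendered as Gaussian-profile strokes onto a dark background, with optional
Poisson shot noise and additive Gaussian read noise. Each rendered fiber
keeps its generating :class:`FiberSpec`, so fiber count, length, width,
straightness and orientation have exact ground truth. Fiber orientations
are axial (undirected): they are drawn from a von Mises distribution on the
doubled angle and folded to [0, 180). The curvature parameter is the total
turning angle of the arc in radians, so ground-truth straightness
(endpoint chord / arc length) is the closed form sin(phi/2) / (phi/2).

Eight archetype presets mimic the canonical tumor-associated collagen
arrangements: curved wrapping fibers (1), fibers parallel (2) versus
perpendicular (3) to a declared boundary axis, a reticular crosslinked
network (4), strongly aligned (5) versus chaotic (6) orientation, and
dense (7) versus sparse (8) fiber packing.

Cohort side
-----------
Disease-free survival is drawn from a Weibull proportional-hazards model:
S(t | x) = exp(-(t/scale)^shape * exp(eta)) with linear predictor
eta = beta . x over named features. Censoring combines an administrative
follow-up horizon with an independent exponential time whose rate is
calibrated by numeric integration to hit a target overall censored
fraction. Each simulated patient carries the true eta so downstream fits
can be checked against the generating model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .cohort import CLINICAL_LEVELS, COHORT_LABELS, CohortTable
from .image import FIELD_OF_VIEW_UM, SHGImage

log = logging.getLogger("fiberscore")


# --------------------------------------------------------------------------
# fiber image simulation
# --------------------------------------------------------------------------

@dataclass
class FiberSpec:
    """Ground truth for one rendered fiber."""

    centerline: np.ndarray  # (N, 2) points in um, (x, y)
    width_um: float
    intensity: float
    id: int

    def arc_length_um(self) -> float:
        d = np.diff(self.centerline, axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def chord_um(self) -> float:
        v = self.centerline[-1] - self.centerline[0]
        return float(np.hypot(v[0], v[1]))

    def straightness(self) -> float:
        arc = self.arc_length_um()
        return self.chord_um() / arc if arc > 0 else 1.0

    def orientation_deg(self) -> float:
        """Axial chord orientation, counter-clockwise from +x, in [0, 180)."""
        v = self.centerline[-1] - self.centerline[0]
        return float(np.degrees(np.arctan2(v[1], v[0])) % 180.0)


@dataclass
class ImageSimParams:
    n_fibers: int = 30
    image_size_px: int = 512
    field_um: float = FIELD_OF_VIEW_UM
    length_mean_um: float = 50.0
    length_sd_um: float = 12.0
    width_mean_um: float = 1.6
    width_sd_um: float = 0.3
    curvature: float = 0.0            # total arc turning angle, radians; 0 = straight
    orientation_mu_deg: float = 0.0   # mean axial orientation
    orientation_kappa: float = 0.0    # von Mises concentration; 0 = uniform
    crosslink_rate: float = 0.0       # expected branch points per primary fiber
    intensity_mean: float = 100.0
    intensity_sd: float = 15.0
    noise_sd: float = 3.0             # additive Gaussian read noise
    shot_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size_px <= 0 or self.field_um <= 0:
            raise ValueError("image must have positive size")
        if self.n_fibers < 0 or self.crosslink_rate < 0 or self.orientation_kappa < 0:
            raise ValueError("rates and concentrations must be >= 0")
        if self.length_mean_um > 2.0 * self.field_um:
            raise ValueError("fiber length infeasible for the field of view")

    @property
    def pixel_size_um(self) -> float:
        return self.field_um / self.image_size_px


def _sample_axial_angle_deg(rng: np.random.Generator, mu_deg: float, kappa: float) -> float:
    """Axial (undirected) orientation: von Mises on the doubled angle."""
    if kappa <= 0:
        return float(rng.uniform(0.0, 180.0))
    doubled = rng.vonmises(np.radians(2.0 * mu_deg), kappa)
    return float(np.degrees(doubled / 2.0) % 180.0)


def _arc_polyline(
    start: np.ndarray, start_angle: float, length: float, turn: float, spacing: float
) -> np.ndarray:
    """Polyline of an arc from `start` with initial tangent `start_angle`.

    `turn` is the signed total turning angle in radians; 0 gives a straight
    segment. Arc length is `length` regardless of curvature.
    """
    n = max(int(np.ceil(length / spacing)), 2)
    s = np.linspace(0.0, length, n + 1)
    if abs(turn) < 1e-9:
        direction = np.array([np.cos(start_angle), np.sin(start_angle)])
        return start[None, :] + s[:, None] * direction[None, :]
    radius = length / abs(turn)
    sign = np.sign(turn)
    # center sits at distance R along the normal to the initial tangent
    normal = np.array([-np.sin(start_angle), np.cos(start_angle)]) * sign
    center = start + radius * normal
    alpha0 = np.arctan2(start[1] - center[1], start[0] - center[0])
    alphas = alpha0 + sign * s / radius
    return center[None, :] + radius * np.stack([np.cos(alphas), np.sin(alphas)], axis=1)


def _clip_polyline(points: np.ndarray, field: float) -> np.ndarray | None:
    """Longest in-bounds run of polyline points; None if fewer than 2 remain."""
    inside = np.all((points >= 0.0) & (points < field), axis=1)
    if inside.all():
        return points
    best_start, best_len, run_start = 0, 0, None
    for i, ok in enumerate(list(inside) + [False]):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    if best_len < 2:
        return None
    return points[best_start : best_start + best_len]


def _render_fiber(
    canvas: np.ndarray, mask: np.ndarray, spec: FiberSpec, pixel_size: float
) -> None:
    """Accumulate one fiber's Gaussian-profile stroke and its mask footprint."""
    pts_px = spec.centerline / pixel_size
    half_px = 0.5 * spec.width_um / pixel_size
    # FWHM of the intensity profile equals the fiber width
    sigma_px = max(half_px / np.sqrt(2.0 * np.log(2.0)), 0.4)
    margin = int(np.ceil(half_px + 3.0 * sigma_px)) + 2
    r0 = max(int(np.floor(pts_px[:, 1].min())) - margin, 0)
    r1 = min(int(np.ceil(pts_px[:, 1].max())) + margin + 1, canvas.shape[0])
    c0 = max(int(np.floor(pts_px[:, 0].min())) - margin, 0)
    c1 = min(int(np.ceil(pts_px[:, 0].max())) + margin + 1, canvas.shape[1])
    if r1 <= r0 or c1 <= c0:
        return
    patch = np.ones((r1 - r0, c1 - c0), dtype=bool)
    rows = np.clip(np.round(pts_px[:, 1]).astype(int) - r0, 0, patch.shape[0] - 1)
    cols = np.clip(np.round(pts_px[:, 0]).astype(int) - c0, 0, patch.shape[1] - 1)
    patch[rows, cols] = False
    dist = ndimage.distance_transform_edt(patch)
    canvas[r0:r1, c0:c1] += spec.intensity * np.exp(-0.5 * (dist / sigma_px) ** 2)
    mask[r0:r1, c0:c1] |= dist <= max(half_px, 0.5)


def simulate_image(
    params: ImageSimParams,
) -> tuple[SHGImage, list[FiberSpec], np.ndarray]:
    """Render a synthetic SHG ROI.

    Returns the image, the list of ground-truth fiber specs (branches
    included), and the boolean collagen mask (union of all fiber
    footprints). Identical parameters and seed give bitwise-identical
    output.
    """
    rng = np.random.default_rng(params.seed)
    size = params.image_size_px
    field = params.field_um
    px = params.pixel_size_um
    spacing = 0.7 * px

    canvas = np.zeros((size, size), dtype=np.float64)
    mask = np.zeros((size, size), dtype=bool)
    specs: list[FiberSpec] = []
    fid = 0

    def finish(points: np.ndarray | None, width: float, intensity: float) -> FiberSpec | None:
        nonlocal fid
        if points is None:
            return None
        spec = FiberSpec(centerline=points, width_um=width, intensity=intensity, id=fid)
        fid += 1
        specs.append(spec)
        _render_fiber(canvas, mask, spec, px)
        return spec

    for _ in range(params.n_fibers):
        length = float(np.clip(rng.normal(params.length_mean_um, params.length_sd_um),
                               5.0, 1.4 * field))
        width = float(np.clip(rng.normal(params.width_mean_um, params.width_sd_um), 0.4, None))
        intensity = float(np.clip(rng.normal(params.intensity_mean, params.intensity_sd), 10.0, None))
        theta = np.radians(_sample_axial_angle_deg(rng, params.orientation_mu_deg,
                                                   params.orientation_kappa))
        if rng.random() < 0.5:  # axial: either sense along the orientation
            theta += np.pi
        turn = params.curvature * (1.0 if rng.random() < 0.5 else -1.0)
        start = rng.uniform(2.0, field - 2.0, size=2)
        pts = _clip_polyline(_arc_polyline(start, theta, length, turn, spacing), field)
        parent = finish(pts, width, intensity)
        if parent is None:
            continue
        # crosslinks realized as branches off the parent fiber
        for _ in range(rng.poisson(params.crosslink_rate)):
            j = int(rng.integers(1, len(parent.centerline) - 1))
            tangent = parent.centerline[min(j + 1, len(parent.centerline) - 1)] - \
                parent.centerline[max(j - 1, 0)]
            t_angle = np.arctan2(tangent[1], tangent[0])
            branch_angle = t_angle + np.radians(rng.uniform(30.0, 150.0)) * \
                (1.0 if rng.random() < 0.5 else -1.0)
            b_len = float(np.clip(rng.normal(0.5 * params.length_mean_um,
                                             0.5 * params.length_sd_um), 5.0, field))
            b_pts = _clip_polyline(
                _arc_polyline(parent.centerline[j], branch_angle, b_len,
                              0.3 * turn, spacing), field)
            finish(b_pts, width, intensity)

    if params.shot_noise:
        canvas = rng.poisson(np.clip(canvas, 0.0, None)).astype(np.float64)
    if params.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, params.noise_sd, canvas.shape)
    canvas = np.clip(canvas, 0.0, 65535.0)

    image = SHGImage(pixels=canvas, pixel_size_um=px, id=f"sim_seed{params.seed}")
    return image, specs, mask


def analytic_straightness(curvature: float) -> float:
    """Closed-form straightness of an arc with total turning angle `curvature`."""
    if abs(curvature) < 1e-12:
        return 1.0
    half = curvature / 2.0
    return float(np.sin(half) / half)


# --------------------------------------------------------------------------
# archetype presets
# --------------------------------------------------------------------------

#: Declared tumor-boundary axis for the parallel/perpendicular archetypes.
BOUNDARY_AXIS_DEG = 0.0

_BASE = dict(n_fibers=30, curvature=0.25, orientation_kappa=0.0, crosslink_rate=0.2)

#: Preset parameter overrides per archetype id.
TACS_PRESETS: dict[int, dict] = {
    1: dict(_BASE, curvature=2.5),                                   # curved, wrapping
    2: dict(_BASE, orientation_mu_deg=BOUNDARY_AXIS_DEG,             # parallel to boundary
            orientation_kappa=8.0),
    3: dict(_BASE, orientation_mu_deg=BOUNDARY_AXIS_DEG + 90.0,      # perpendicular
            orientation_kappa=8.0),
    4: dict(_BASE, crosslink_rate=3.0, n_fibers=22),                 # reticular network
    5: dict(_BASE, orientation_mu_deg=45.0, orientation_kappa=12.0), # aligned
    6: dict(_BASE, orientation_kappa=0.0),                           # chaotic
    7: dict(_BASE, n_fibers=70),                                     # dense
    8: dict(_BASE, n_fibers=8),                                      # sparse
}


def simulate_tacs_archetype(
    pattern_id: int, seed: int = 0, image_size_px: int = 256, **overrides
) -> tuple[SHGImage, list[FiberSpec], np.ndarray]:
    """Render one of the eight archetypal collagen arrangements."""
    if pattern_id not in TACS_PRESETS:
        raise ValueError(f"archetype id must be in 1..8, got {pattern_id}")
    kwargs = dict(TACS_PRESETS[pattern_id])
    kwargs.update(overrides)
    params = ImageSimParams(image_size_px=image_size_px, seed=seed, **kwargs)
    img, specs, mask = simulate_image(params)
    img.id = f"tacs{pattern_id}_seed{seed}"
    return img, specs, mask


# --------------------------------------------------------------------------
# survival cohort simulation
# --------------------------------------------------------------------------

#: Marginal frequencies of the categorical clinical covariates used by the
#: cohort simulator (levels in the order of cohort.CLINICAL_LEVELS).
CLINICAL_FREQS: dict[str, tuple[float, ...]] = {
    "age_group": (0.561, 0.439),
    "subtype": (0.211, 0.454, 0.180, 0.155),
    "tumor_size": (0.414, 0.527, 0.059),
    "nodal_status": (0.507, 0.208, 0.285),
    "stage": (0.270, 0.439, 0.291),
    "grade": (0.158, 0.546, 0.296),
    "er": (0.335, 0.665),
    "pr": (0.428, 0.572),
    "her2": (0.685, 0.315),
    "chemotherapy": (0.079, 0.921),
    "endocrine_therapy": (0.380, 0.620),
    "radiation_therapy": (0.659, 0.341),
    "targeted_therapy": (0.932, 0.068),
}

#: Default cohort split proportions (training / internal / external).
COHORT_SPLIT = (355, 334, 253)


@dataclass
class CohortSimParams:
    """Parameters of the Weibull proportional-hazards cohort generator.

    ``beta`` maps feature names to true log-hazard coefficients. Names
    matching ``tacs_1``..``tacs_8`` generate Bernoulli indicators; names of
    the form ``column:level`` over the clinical covariates generate the
    corresponding indicator contrast; any other name generates an
    independent standard-normal latent feature. ``features`` may list extra
    (zero-coefficient) columns to generate alongside.
    """

    n_patients: int = 942
    beta: dict[str, float] = field(default_factory=dict)
    baseline_shape: float = 1.5
    baseline_scale_months: float = 91.0
    censoring_target: float | None = 0.70
    admin_horizon_months: float | None = 120.0
    tacs_prevalence: float = 0.30
    features: tuple[str, ...] | None = None
    include_clinical: bool = True
    include_tacs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 20:
            raise ValueError("n_patients must be >= 20")
        if self.censoring_target is not None and not (0.0 < self.censoring_target < 1.0):
            raise ValueError("censoring target must be in (0, 1)")
        if self.baseline_shape <= 0 or self.baseline_scale_months <= 0:
            raise ValueError("Weibull parameters must be positive")


def weibull_ph_survival(t: np.ndarray, eta: float, shape: float, scale: float) -> np.ndarray:
    """S(t | eta) of the generating proportional-hazards model."""
    return np.exp(-np.exp(eta) * (np.asarray(t, float) / scale) ** shape)


def weibull_ph_median(eta: float, shape: float, scale: float) -> float:
    """Median event time at linear predictor `eta` (closed form)."""
    return float(scale * (np.log(2.0) * np.exp(-eta)) ** (1.0 / shape))


def _calibrate_censoring_rate(
    etas: np.ndarray, shape: float, scale: float, horizon: float | None, target: float
) -> float:
    """Exponential censoring rate hitting the target overall censored fraction.

    The event fraction under rate rho is the average over patients of
    integral_0^tau f_i(t) exp(-rho t) dt, evaluated by trapezoid quadrature;
    rho is found with brentq. Deterministic given the drawn etas.
    """
    tau = horizon if horizon is not None else scale * 6.0
    t = np.linspace(1e-6, tau, 4096)
    rel = np.exp(etas)[:, None]
    base = (shape / scale) * (t / scale) ** (shape - 1.0)
    dens = rel * base[None, :] * np.exp(-rel * (t / scale) ** shape)  # f_i(t)

    def event_fraction(rho: float) -> float:
        w = np.exp(-rho * t)[None, :]
        return float(np.mean(np.trapezoid(dens * w, t, axis=1)))

    want = 1.0 - target
    if event_fraction(0.0) <= want:
        if horizon is not None:
            warnings.warn(
                "administrative horizon alone censors more than the target; "
                "no extra exponential censoring applied"
            )
        return 0.0
    lo, hi = 0.0, 1.0
    while event_fraction(hi) > want and hi < 1e4:
        hi *= 4.0
    return float(brentq(lambda r: event_fraction(r) - want, lo, hi, xtol=1e-8))


def _draw_feature_column(
    name: str, n: int, rng: np.random.Generator, params: CohortSimParams
) -> tuple[str, np.ndarray] | None:
    if name.startswith("tacs_"):
        return name, rng.binomial(1, params.tacs_prevalence, n).astype(float)
    if ":" in name:
        return None  # clinical contrast, handled from the categorical draw
    return name, rng.standard_normal(n)


def simulate_cohort(params: CohortSimParams) -> CohortTable:
    """Simulate a per-patient cohort table with known hazard structure.

    The returned table carries the drawn covariates, DFS time and event
    indicator, cohort assignment, and the true linear predictor in column
    ``eta_true``. Identical parameters and seed give an identical table.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    if params.beta and not any(abs(v) > 0 for v in params.beta.values()):
        warnings.warn("all generating coefficients are zero; survival is pure noise")

    df = pd.DataFrame({"patient_id": [f"P{i + 1:05d}" for i in range(n)]})

    # cohort assignment by the default split proportions
    props = np.asarray(COHORT_SPLIT, float) / sum(COHORT_SPLIT)
    counts = np.floor(props * n).astype(int)
    counts[0] += n - counts.sum()
    labels = np.repeat(COHORT_LABELS, counts)
    df["cohort"] = rng.permutation(labels)

    if params.include_clinical:
        for col, levels in CLINICAL_LEVELS.items():
            freqs = np.asarray(CLINICAL_FREQS[col])
            df[col] = rng.choice(levels, size=n, p=freqs / freqs.sum())
    if params.include_tacs:
        for i in range(1, 9):
            df[f"tacs_{i}"] = rng.binomial(1, params.tacs_prevalence, n)

    wanted = list(params.beta)
    if params.features is not None:
        wanted += [f for f in params.features if f not in params.beta]
    for name in wanted:
        if name in df.columns:
            continue
        drawn = _draw_feature_column(name, n, rng, params)
        if drawn is not None:
            df[drawn[0]] = drawn[1]

    eta = np.zeros(n)
    for name, coef in params.beta.items():
        if ":" in name:
            col, _, level = name.partition(":")
            if col not in df.columns:
                raise ValueError(f"coefficient on unknown clinical covariate {name!r}")
            x = (df[col] == level).to_numpy(float)
        elif name in df.columns:
            x = df[name].to_numpy(float)
        else:
            raise ValueError(f"coefficient on unresolved feature {name!r}")
        eta = eta + coef * x
    df["eta_true"] = eta

    shape, scale = params.baseline_shape, params.baseline_scale_months
    event_time = scale * (rng.exponential(1.0, n) * np.exp(-eta)) ** (1.0 / shape)

    horizon = params.admin_horizon_months
    if params.censoring_target is None:
        cens_time = np.full(n, np.inf) if horizon is None else np.full(n, horizon)
    else:
        rho = _calibrate_censoring_rate(eta, shape, scale, horizon, params.censoring_target)
        cens_time = rng.exponential(1.0 / rho, n) if rho > 0 else np.full(n, np.inf)
        if horizon is not None:
            cens_time = np.minimum(cens_time, horizon)

    df["dfs_months"] = np.minimum(event_time, cens_time)
    df["event"] = (event_time <= cens_time).astype(int)
    if not params.include_tacs:
        for i in range(1, 9):  # schema requires the indicator columns
            if f"tacs_{i}" not in df.columns:
                df[f"tacs_{i}"] = 0
    return CohortTable(df)
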