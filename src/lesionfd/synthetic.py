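"""Synthetic cohort generator with known ground truth.

Emulates the study design of a treated-glioma fiber-density analysis: a
healthy-control cohort whose fiber-density (FD) maps share a smooth
tract-like template field, and a patient cohort whose FD is multiplicatively
suppressed inside lesions of four types (resection cavity, contrast-enhancing
lesion, FET-PET uptake region, T2/FLAIR hyperintensity). Every generated
quantity is tied to a :class:`CohortTruth` so downstream estimates can be
checked against a recoverable truth.

The template field is a superposition of oriented Gaussian-profile ridges
("tracts"), which makes within-mask means available in closed form at zero
noise and gives the spatially inhomogeneous reference FD needed to exercise
the homogeneity inclusion criterion. Subject-level noise is multiplicative
lognormal (FD stays nonnegative without truncation), mean-one so cohort
averages converge to the template. All randomness derives from a single
integer seed; each subject gets a stable sub-seed hashed from
``(seed, subject id)``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import LESION_TYPES, BinaryMask, DensityImage, GridSpec, StreamlineSet, TBRMap

DEFAULT_SUPPRESSION = {"cavity": 0.15, "ce": 0.45, "fet": 0.50, "flair": 0.55}
# log-odds of ECOG impairment per mm^3 of total fiber loss; CE and FLAIR carry
# the strongest effects, mirroring which lesion types drive performance status
DEFAULT_ECOG_BETAS = {"cavity": 0.0005, "ce": 0.004, "fet": 0.0010, "flair": 0.0025}


def derive_seed(*parts) -> int:
    """Stable sub-seed (< 2^31) from arbitrary hashable parts."""
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class CohortTruth:
    """Ground-truth generator parameters the pipeline must recover.

    suppression_ratio maps lesion type to the true patient/reference FD ratio
    inside the lesion (in [0, 1]). tbr_slope/tbr_intercept define the linear
    relative-FD-vs-TBR law inside FET lesions when ``fet_tbr_coupling`` is on;
    tbr_intercept_sd is the between-subject SD of the intercept. ecog_betas
    are log-odds of impaired performance status per unit (mm^3) of total fiber
    loss. noise_sd is the SD of log FD for the multiplicative subject noise.
    """

    suppression_ratio: dict = field(default_factory=lambda: dict(DEFAULT_SUPPRESSION))
    tbr_slope: float = -0.074
    tbr_intercept: float = 0.59
    tbr_intercept_sd: float = 0.05
    fet_tbr_coupling: bool = False
    ecog_alpha: float = -4.5
    ecog_betas: dict = field(default_factory=lambda: dict(DEFAULT_ECOG_BETAS))
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for lt, r in self.suppression_ratio.items():
            if lt not in LESION_TYPES:
                raise ValueError(f"unknown lesion type {lt!r}")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"suppression ratio for {lt!r} must be in [0, 1]; got {r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SubjectRecord:
    """Covariates and lesion inventory for one subject."""

    id: str
    group: str  # "patient" | "control"
    age: float
    gender: str  # "m" | "f"
    education: int  # ordinal 1 (lowest) .. 4 (highest)
    ecog: int = 0
    months_since_rt: float | None = None
    lesion_volumes_mL: dict = field(default_factory=dict)
    fiber_loss: dict | None = None  # per lesion type, mm^3-scaled

    def __post_init__(self) -> None:
        if self.ecog not in range(5):
            raise ValueError("ECOG score must be an integer 0-4")
        if any(v < 0 for v in self.lesion_volumes_mL.values()):
            raise ValueError("lesion volumes must be nonnegative")


@dataclass(frozen=True)
class LesionSpec:
    """Ellipsoidal lesion: center and semi-axes in world mm.

    ``two_component`` adds a small detached satellite ellipsoid (for
    mask-cleaning tests). ``hollow_core_frac`` > 0 carves out a central
    necrotic core (for hole-filling tests)."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    two_component: bool = False
    hollow_core_frac: float = 0.0


@dataclass
class LesionMaskSet:
    """Per-subject binary masks by lesion type plus the TBR map."""

    masks: dict  # lesion_type -> BinaryMask
    tbr: TBRMap


# ---------------------------------------------------------------- tract field


@dataclass(frozen=True)
class Ridge:
    point_mm: tuple[float, float, float]
    direction: tuple[float, float, float]  # unit vector
    amplitude: float  # fibers/mm^3 at the ridge core
    sigma_mm: float  # Gaussian cross-sectional width


def make_ridges(grid: GridSpec, seed: int, n_ridges: int | None = None) -> list[Ridge]:
    """Draw 3-8 oriented Gaussian ridges spanning the grid."""
    rng = np.random.default_rng(derive_seed(seed, "ridges"))
    if n_ridges is None:
        n_ridges = int(rng.integers(3, 9))
    lo, hi = grid.extent_mm()
    span = hi - lo
    ridges = []
    for _ in range(n_ridges):
        point = lo + rng.uniform(0.25, 0.75, size=3) * span
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        amp = float(rng.uniform(40.0, 120.0))
        sigma = float(rng.uniform(0.10, 0.22) * span.min())
        ridges.append(Ridge(tuple(point), tuple(u), amp, sigma))
    return ridges


def tract_field(grid: GridSpec, ridges: list[Ridge]) -> np.ndarray:
    """Analytic noiseless FD template: sum of Gaussian-profile ridges."""
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij"), axis=-1)
    centers = grid.voxel_centers_mm(idx.reshape(-1, 3)).reshape(*grid.shape, 3)
    out = np.zeros(grid.shape)
    for r in ridges:
        v = centers - np.asarray(r.point_mm)
        along = v @ np.asarray(r.direction)
        d2 = np.einsum("...i,...i->...", v, v) - along**2
        out += r.amplitude * np.exp(-d2 / (2.0 * r.sigma_mm**2))
    return out


def _lognormal_factor(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    """Mean-one multiplicative noise; sd is the SD of log FD. sd=0 -> ones."""
    if sd == 0.0:
        return np.ones(shape)
    return np.exp(rng.normal(-0.5 * sd**2, sd, size=shape))


# ------------------------------------------------------------------ cohorts


def _draw_covariates(rng: np.random.Generator, sid: str, group: str) -> SubjectRecord:
    age = float(np.clip(rng.normal(51.6, 11.6), 20.0, 85.0))
    gender = "m" if rng.random() < 0.60 else "f"
    education = int(rng.choice([1, 2, 3, 4], p=[0.2, 0.4, 0.3, 0.1]))
    months = float(np.exp(rng.normal(np.log(14.0), 1.0))) if group == "patient" else None
    return SubjectRecord(
        id=sid, group=group, age=age, gender=gender, education=education,
        months_since_rt=months,
    )


def generate_control_cohort(
    n: int, grid: GridSpec, truth: CohortTruth, ridges: list[Ridge] | None = None
) -> list[tuple[DensityImage, SubjectRecord]]:
    """Generate ``n`` healthy-control FD images sharing one template field.

    Each image is the noiseless tract field times subject-level mean-one
    lognormal noise. Deterministic given ``truth.seed``.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if ridges is None:
        ridges = make_ridges(grid, truth.seed)
    base = tract_field(grid, ridges)
    out = []
    for i in range(n):
        sid = f"C{i:04d}"
        rng = np.random.default_rng(derive_seed(truth.seed, sid))
        rec = _draw_covariates(rng, sid, "control")
        fd = base * _lognormal_factor(rng, truth.noise_sd, grid.shape)
        out.append((DensityImage(grid=grid, values=fd), rec))
    return out


def _ellipsoid_mask(grid: GridSpec, spec: LesionSpec) -> np.ndarray:
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij"), axis=-1)
    centers = grid.voxel_centers_mm(idx.reshape(-1, 3)).reshape(*grid.shape, 3)
    rel = (centers - np.asarray(spec.center_mm)) / np.asarray(spec.radii_mm)
    r2 = np.einsum("...i,...i->...", rel, rel)
    mask = r2 <= 1.0
    if spec.hollow_core_frac > 0:
        mask &= r2 > spec.hollow_core_frac**2
    if spec.two_component:
        sat_center = np.asarray(spec.center_mm) + 2.5 * np.asarray(spec.radii_mm)
        sat_radii = np.maximum(np.asarray(spec.radii_mm) * 0.25, np.asarray(grid.voxel_size_mm))
        rel = (centers - sat_center) / sat_radii
        mask |= np.einsum("...i,...i->...", rel, rel) <= 1.0
    return mask


def _ellipsoid_radial_fraction(grid: GridSpec, spec: LesionSpec) -> np.ndarray:
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij"), axis=-1)
    centers = grid.voxel_centers_mm(idx.reshape(-1, 3)).reshape(*grid.shape, 3)
    rel = (centers - np.asarray(spec.center_mm)) / np.asarray(spec.radii_mm)
    return np.sqrt(np.einsum("...i,...i->...", rel, rel))


def default_lesion_layout(grid: GridSpec, seed: int | None = None) -> dict[str, LesionSpec]:
    """Four non-overlapping ellipsoids in the grid's quadrants.

    With a seed, centers and radii are jittered per subject so lesion volumes
    vary across the cohort.
    """
    lo, hi = grid.extent_mm()
    span = hi - lo
    rng = np.random.default_rng(seed if seed is not None else 0)
    jitter = (lambda: rng.uniform(-0.03, 0.03, size=3) * span) if seed is not None else (lambda: 0.0)
    scale = (lambda: rng.uniform(0.75, 1.15)) if seed is not None else (lambda: 1.0)
    anchors = {
        "cavity": (0.28, 0.28, 0.30),
        "ce": (0.72, 0.28, 0.30),
        "fet": (0.28, 0.72, 0.68),
        "flair": (0.72, 0.72, 0.68),
    }
    base_r = 0.14 * span.min()
    layout = {}
    for lt, frac in anchors.items():
        center = lo + np.asarray(frac) * span + jitter()
        r = base_r * scale()
        layout[lt] = LesionSpec(tuple(center), (r, r, r))
    return layout


def generate_patient(
    grid: GridSpec,
    truth: CohortTruth,
    lesion_layout: dict[str, LesionSpec],
    subject_id: str = "P0000",
    ridges: list[Ridge] | None = None,
    tbr_range: tuple[float, float] = (1.7, 5.2),
) -> tuple[DensityImage, LesionMaskSet, SubjectRecord]:
    """Generate one patient: FD image, lesion masks, TBR map and record.

    Inside each lesion mask the template FD is multiplied by the lesion
    type's suppression ratio (factors compound where non-cavity masks
    overlap; a cavity overlapping any other lesion is an error). If
    ``truth.fet_tbr_coupling``, FET voxels instead use the per-voxel factor
    ``tbr_intercept + tbr_slope * TBR`` (floored at 0), so relative FD is
    linear in TBR before noise. TBR is 1 outside the FET lesion and ramps
    from ``tbr_range[1]`` at the center to ``tbr_range[0]`` at the rim.
    """
    if ridges is None:
        ridges = make_ridges(grid, truth.seed)
    for lt in lesion_layout:
        if lt not in LESION_TYPES:
            raise ValueError(f"unknown lesion type {lt!r}")
    base = tract_field(grid, ridges)
    rng = np.random.default_rng(derive_seed(truth.seed, subject_id))
    rec = _draw_covariates(rng, subject_id, "patient")

    masks = {lt: _ellipsoid_mask(grid, spec) for lt, spec in lesion_layout.items()}
    if "cavity" in masks:
        for lt, m in masks.items():
            if lt != "cavity" and np.any(masks["cavity"] & m):
                raise ValueError("cavity mask may not overlap other lesion types")

    tbr = np.ones(grid.shape)
    if "fet" in masks:
        frac = _ellipsoid_radial_fraction(grid, lesion_layout["fet"])
        lo_tbr, hi_tbr = tbr_range[0], tbr_range[1]
        ramp = hi_tbr - (hi_tbr - lo_tbr) * np.clip(frac, 0.0, 1.0)
        tbr = np.where(masks["fet"], ramp, tbr)

    factor = np.ones(grid.shape)
    for lt, m in masks.items():
        if lt == "fet" and truth.fet_tbr_coupling:
            fet_factor = np.maximum(truth.tbr_intercept + truth.tbr_slope * tbr, 0.0)
            factor = np.where(m, factor * fet_factor, factor)
        else:
            factor = np.where(m, factor * truth.suppression_ratio.get(lt, 1.0), factor)

    fd = base * factor * _lognormal_factor(rng, truth.noise_sd, grid.shape)

    mask_objs = {
        lt: BinaryMask(grid=grid, values=m, lesion_type=lt) for lt, m in masks.items()
    }
    rec.lesion_volumes_mL = {
        lt: (mask_objs[lt].volume_mL if lt in mask_objs else 0.0) for lt in LESION_TYPES
    }
    return (
        DensityImage(grid=grid, values=fd),
        LesionMaskSet(masks=mask_objs, tbr=TBRMap(grid=grid, values=tbr)),
        rec,
    )


def generate_patient_cohort(
    n: int, grid: GridSpec, truth: CohortTruth, ridges: list[Ridge] | None = None
) -> list[tuple[DensityImage, LesionMaskSet, SubjectRecord]]:
    """Generate ``n`` patients with per-subject jittered lesion layouts."""
    if n < 1:
        raise ValueError("n must be positive")
    if ridges is None:
        ridges = make_ridges(grid, truth.seed)
    out = []
    for i in range(n):
        sid = f"P{i:04d}"
        layout = default_lesion_layout(grid, seed=derive_seed(truth.seed, sid, "layout"))
        out.append(generate_patient(grid, truth, layout, subject_id=sid, ridges=ridges))
    return out


def generate_ecog(
    records: list[SubjectRecord], truth: CohortTruth
) -> list[SubjectRecord]:
    """Draw impaired-vs-normal performance status from total fiber loss.

    Impairment probability is ``logistic(alpha + sum_type beta_type *
    fiberloss_type)``; impaired subjects get an ECOG grade in 1-4 (skewed
    toward 1, as in typical treated-glioma cohorts), others ECOG 0.
    Deterministic given ``truth.seed``; input records need ``fiber_loss``
    populated (zeros allowed).
    """
    out = []
    for rec in records:
        if rec.fiber_loss is None:
            raise ValueError(f"subject {rec.id} has no fiber-loss values")
        eta = truth.ecog_alpha + sum(
            truth.ecog_betas.get(lt, 0.0) * fl for lt, fl in rec.fiber_loss.items()
        )
        p = 1.0 / (1.0 + np.exp(-eta))
        rng = np.random.default_rng(derive_seed(truth.seed, "ecog", rec.id))
        if rng.random() < p:
            ecog = int(rng.choice([1, 2, 3, 4], p=[0.85, 0.10, 0.03, 0.02]))
        else:
            ecog = 0
        out.append(replace(rec, ecog=ecog))
    return out


def generate_streamlines(n: int, grid: GridSpec, seed: int = 0) -> StreamlineSet:
    """Random piecewise-linear streamlines confined to the grid's bounding box."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(derive_seed(seed, "streamlines"))
    lo, hi = grid.extent_mm()
    span = hi - lo
    eps = 1e-9
    lines = []
    for _ in range(n):
        k = int(rng.integers(2, 7))
        start = lo + rng.uniform(0.1, 0.9, size=3) * span
        steps = rng.normal(scale=0.18 * span.min(), size=(k - 1, 3))
        pts = np.vstack([start, start + np.cumsum(steps, axis=0)])
        pts = np.clip(pts, lo, hi - eps)
        lines.append(pts)
    return StreamlineSet(streamlines=lines)


def generate_tbr_bin_cohort(
    n_subjects: int,
    truth: CohortTruth,
    seed: int | None = None,
    bin_centers: tuple[float, ...] = (2.1, 3.1, 4.1, 5.1),
    residual_sd: float = 0.05,
) -> pd.DataFrame:
    """Bin-level relative-FD observations under the random-intercept TBR law.

    Emits one row per subject x TBR bin with columns (subject, mean_tbr,
    relative_fd): relative_fd = (intercept + N(0, tbr_intercept_sd)) +
    tbr_slope * mean_tbr + N(0, residual_sd). This is the direct route for
    mixed-model parameter-recovery studies; the image-based route produces
    the same structure through segmentation and binning.
    """
    rng = np.random.default_rng(derive_seed(truth.seed if seed is None else seed, "tbrbins"))
    rows = []
    for i in range(n_subjects):
        b0 = truth.tbr_intercept + rng.normal(0.0, truth.tbr_intercept_sd)
        for c in bin_centers:
            tbr = c + rng.uniform(-0.3, 0.3)
            fd = b0 + truth.tbr_slope * tbr + rng.normal(0.0, residual_sd)
            rows.append({"subject": f"P{i:04d}", "mean_tbr": tbr, "relative_fd": max(fd, 0.0)})
    return pd.DataFrame(rows)
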