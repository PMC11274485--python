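"""Synthetic PET/CT phantoms and Cox-linked survival cohorts.

The phantom family emulates the data regime the pipeline assumes, so every
stage is testable without access-gated clinical data:

* a CT volume with "bone" structures in the hard-tissue Hounsfield window:
  a vertical head/spine column topped by a wider head block, plus a
  horizontal shoulder bar marking the shoulder-girdle level, embedded in
  soft tissue;
* a PET volume with a small number of solid ellipsoidal hot lesions inside
  the head-and-neck subregion over a low background, with additive
  Gaussian noise;
* right-censored survival times whose hazard follows a Cox model,
  ``h0 * exp(beta * s_std)``, driven by the standardized log of the
  summed lesion peak-times-volume burden, with uniform administrative
  censoring calibrated to a target censoring fraction.

Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .region_crop import BoundingBox3D
from .volume_io import ImageVolume
from .survival import SurvivalRecord

__all__ = ["PhantomSpec", "Lesion", "PhantomTruth", "Cohort", "make_phantom_pair", "make_cohort"]


@dataclass(frozen=True)
class Lesion:
    center: tuple[float, float, float]  # voxel indices
    radii_mm: tuple[float, float, float]
    peak: float

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.radii_mm))


@dataclass
class PhantomTruth:
    """Construction ground truth for one phantom pair."""

    box: BoundingBox3D  # true head-and-neck region
    lesions: list[Lesion]
    shoulder_row: int
    lesion_summary: float  # log(sum of peak * volume)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, lesion statistics and survival process of the phantom family.

    Spatial units are mm with the default 1 mm isotropic grid. HU levels
    place bone inside the 700-2000 window over soft tissue; lesion peaks
    are SUV-like values well above the PET background.
    """

    shape: tuple[int, int, int] = (48, 48, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # CT geometry
    bone_hu: float = 1200.0
    soft_tissue_hu: float = 40.0
    head_column_width: int = 12
    head_top_margin: int = 3
    shoulder_row_frac: float = 0.3
    shoulder_span_frac: float = 0.85
    shoulder_thickness: int = 4
    box_margin: int = 6
    # PET lesions
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_radii_range_mm: tuple[float, float] = (3.0, 8.0)
    lesion_peak_range: tuple[float, float] = (2.0, 10.0)
    background: float = 0.3
    noise_sd: float = 0.05
    # survival process
    beta: float = 1.5
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.2

    def __post_init__(self):
        if not (700.0 <= self.bone_hu <= 2000.0):
            raise ValueError(f"bone_hu must lie in the bone window, got {self.bone_hu}")
        if self.lesion_peak_range[0] <= self.background:
            raise ValueError("lesion peaks must exceed the PET background")
        if self.baseline_hazard <= 0 or not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("invalid survival process rates")


def _true_box(spec: PhantomSpec) -> tuple[BoundingBox3D, int, int, int]:
    nx, ny, nz = spec.shape
    cx, cy = nx // 2, ny // 2
    half = spec.head_column_width // 2
    shoulder_row = int(spec.shoulder_row_frac * nz)
    z_top = nz - spec.head_top_margin
    box = BoundingBox3D(
        max(cx - half - spec.box_margin, 0),
        min(cx + half + spec.box_margin, nx),
        max(cy - half - spec.box_margin, 0),
        min(cy + half + spec.box_margin, ny),
        shoulder_row,
        z_top,
    )
    return box, cx, cy, shoulder_row


def _make_ct(spec: PhantomSpec, cx: int, cy: int, shoulder_row: int) -> np.ndarray:
    nx, ny, nz = spec.shape
    ct = np.full(spec.shape, spec.soft_tissue_hu, dtype=np.float32)
    half = spec.head_column_width // 2
    z_top = nz - spec.head_top_margin
    # head/spine column from shoulder level to the top of the head
    ct[cx - half:cx + half, cy - half:cy + half, shoulder_row:z_top] = spec.bone_hu
    # wider "skull" block near the top so the uppermost bone marks the head
    skull_half = min(half + 2, cx)
    skull_lo = max(z_top - 8, shoulder_row)
    ct[cx - skull_half:cx + skull_half, cy - skull_half:cy + skull_half, skull_lo:z_top] = spec.bone_hu
    # shoulder girdle at the SC/AC level: clavicle-like bar along x plus a
    # scapula/sternum-like bar along y, so both the coronal and the sagittal
    # bone projections are widest at the shoulder row
    span_x = int(spec.shoulder_span_frac * nx) // 2
    span_y = int(spec.shoulder_span_frac * ny) // 2
    th = spec.shoulder_thickness
    z_lo = max(shoulder_row - th // 2, 0)
    z_hi = shoulder_row + (th + 1) // 2
    ct[cx - span_x:cx + span_x, cy - half:cy + half, z_lo:z_hi] = spec.bone_hu
    ct[cx - half:cx + half, cy - span_y:cy + span_y, z_lo:z_hi] = spec.bone_hu
    return ct


def _sample_lesions(spec: PhantomSpec, box: BoundingBox3D, rng: np.random.Generator) -> list[Lesion]:
    k = int(rng.integers(spec.lesion_count_range[0], spec.lesion_count_range[1] + 1))
    lo_r, hi_r = spec.lesion_radii_range_mm
    lesions = []
    for _ in range(k):
        radii = rng.uniform(lo_r, hi_r, size=3)
        # center placed so the whole ellipsoid stays inside the true box
        center = []
        for lo, hi, r, s in (
            (box.x_min, box.x_max, radii[0], spec.spacing_mm[0]),
            (box.y_min, box.y_max, radii[1], spec.spacing_mm[1]),
            (box.z_min, box.z_max, radii[2], spec.spacing_mm[2]),
        ):
            r_vox = r / s
            c_lo, c_hi = lo + r_vox, hi - 1 - r_vox
            if c_lo > c_hi:
                raise ValueError(
                    f"lesion radius {r} mm cannot fit the head-and-neck region"
                )
            center.append(float(rng.uniform(c_lo, c_hi)))
        peak = float(rng.uniform(*spec.lesion_peak_range))
        lesions.append(Lesion(tuple(center), tuple(float(r) for r in radii), peak))
    return lesions


def _make_pet(spec: PhantomSpec, lesions: list[Lesion], rng: np.random.Generator) -> np.ndarray:
    nx, ny, nz = spec.shape
    pet = np.full(spec.shape, spec.background, dtype=np.float32)
    xs = np.arange(nx)[:, None, None]
    ys = np.arange(ny)[None, :, None]
    zs = np.arange(nz)[None, None, :]
    for les in lesions:
        rx, ry, rz = (r / s for r, s in zip(les.radii_mm, spec.spacing_mm))
        d2 = (
            ((xs - les.center[0]) / rx) ** 2
            + ((ys - les.center[1]) / ry) ** 2
            + ((zs - les.center[2]) / rz) ** 2
        )
        inside = d2 <= 1.0
        pet[inside] = np.maximum(pet[inside], les.peak)
    if spec.noise_sd > 0:
        pet = pet + rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)
        pet = np.maximum(pet, 0.0)
    return pet


def make_phantom_pair(spec: PhantomSpec, seed: int) -> tuple[ImageVolume, ImageVolume, PhantomTruth]:
    """Generate one co-registered CT/PET phantom pair plus ground truth."""
    rng = np.random.default_rng(seed)
    box, cx, cy, shoulder_row = _true_box(spec)
    ct = _make_ct(spec, cx, cy, shoulder_row)
    lesions = _sample_lesions(spec, box, rng)
    pet = _make_pet(spec, lesions, rng)
    summary = float(np.log(sum(l.peak * l.volume_mm3 for l in lesions)))
    truth = PhantomTruth(box, lesions, shoulder_row, summary)
    ct_vol = ImageVolume(ct, spec.spacing_mm, (0.0, 0.0, 0.0), "CT")
    pet_vol = ImageVolume(pet, spec.spacing_mm, (0.0, 0.0, 0.0), "PET")
    return ct_vol, pet_vol, truth


@dataclass
class Cohort:
    """A generated patient cohort with its data-generating ground truth."""

    ct: list[ImageVolume]
    pet: list[ImageVolume]
    truths: list[PhantomTruth]
    records: list[SurvivalRecord]
    true_risk: np.ndarray  # beta * standardized lesion summary
    spec: PhantomSpec
    seed: int

    def __len__(self) -> int:
        return len(self.records)


def _calibrate_admin_censoring(lam: np.ndarray, target: float) -> float:
    """Upper bound tau of U(0, tau) censoring hitting the target fraction.

    With exponential event times and uniform censoring, the expected
    censored fraction is mean over patients of (1 - exp(-lam*tau)) /
    (lam*tau), which decreases monotonically in tau; solve by bisection.
    """

    def frac(tau: float) -> float:
        x = lam * tau
        return float(np.mean((1.0 - np.exp(-x)) / x))

    return float(brentq(lambda t: frac(t) - target, 1e-9, 1e9, maxiter=200))


def make_cohort(spec: PhantomSpec, n: int, seed: int) -> Cohort:
    """Generate ``n`` phantom pairs with Cox-linked survival endpoints.

    Each patient's lesion summary ``s = log(sum_j peak_j * volume_j)`` is
    standardized across the cohort; event times are exponential with
    hazard ``h0 * exp(beta * s_std)`` and censoring is uniform
    administrative, calibrated so the expected censored fraction matches
    ``spec.censoring_rate``.
    """
    if n < 2:
        raise ValueError("cohort needs at least 2 patients")
    ss = np.random.SeedSequence([seed, 0xC0])
    pair_seeds = ss.generate_state(n) % (2**31 - 1)
    ct, pet, truths = [], [], []
    for i in range(n):
        c, p, t = make_phantom_pair(spec, int(pair_seeds[i]))
        ct.append(c)
        pet.append(p)
        truths.append(t)
    s = np.asarray([t.lesion_summary for t in truths])
    if np.std(s) == 0:
        import warnings

        warnings.warn("degenerate cohort: lesion summary has zero variance")
        s_std = np.zeros_like(s)
    else:
        s_std = (s - s.mean()) / s.std()
    lam = spec.baseline_hazard * np.exp(spec.beta * s_std)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E]))
    t_event = rng.exponential(1.0 / lam)
    if spec.censoring_rate > 0:
        tau = _calibrate_admin_censoring(lam, spec.censoring_rate)
        t_cens = rng.uniform(0.0, tau, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    records = [
        SurvivalRecord(f"P{i:04d}", float(max(time[i], 1e-9)), bool(event[i]))
        for i in range(n)
    ]
    return Cohort(ct, pet, truths, records, spec.beta * s_std, spec, seed)
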