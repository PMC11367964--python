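"""Seeded digital thorax phantoms with known myocardial-to-rib uptake.

The phantom stands in for a patient referred for bone-tracer cardiac
scintigraphy.  Organs are axis-aligned analytic primitives (elliptic
cylinders and ellipsoids) painted onto an isotropic voxel grid in a fixed
precedence order; each organ carries an activity concentration and a linear
attenuation coefficient at 140 keV.  The single dial that matters for the
study is ``myo_to_rib_ratio``: the myocardial-shell concentration relative
to rib uptake, which maps onto Perugini-like visual classes 0-3.

Organ precedence (later wins where primitives overlap):
body soft tissue < lungs < spine < sternum < ribs < kidneys <
ventricular blood pool < myocardial shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ActivityVolume, GridGeometry, MuMap

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "classify_ratio",
    "ratio_for_class",
    "make_phantom",
    "make_cohort",
]

# Linear attenuation coefficients (1/mm) at 140 keV.  Water/soft tissue and
# inflated lung follow standard mass-attenuation tables; the bone value is a
# mixed trabecular/cortical surrogate appropriate for ribs and vertebrae
# (pure cortical bone would be ~0.030/mm).
MU_SOFT_TISSUE = 0.0154
MU_LUNG = 0.004
MU_BONE = 0.025

#: Class bands for the myocardial-to-rib concentration ratio.
_CLASS_BANDS = {0: (0.0, 0.0), 1: (0.3, 0.7), 2: (0.85, 1.25), 3: (1.5, 2.5)}


def classify_ratio(ratio: float) -> int:
    """Map a myocardial-to-rib uptake ratio onto a Perugini-like class.

    0: no myocardial uptake; 1: less than rib; 2: comparable to rib;
    3: greater than rib (imaged with suppressed rib uptake).
    """
    if ratio < 0:
        raise ValueError("ratio must be nonnegative")
    if ratio == 0:
        return 0
    if ratio < 0.8:
        return 1
    if ratio <= 1.3:
        return 2
    return 3


def ratio_for_class(cls: int, rng: np.random.Generator) -> float:
    """Draw a ratio from the band used when synthesising a given class."""
    lo, hi = _CLASS_BANDS[int(cls)]
    if lo == hi:
        return lo
    return float(rng.uniform(lo, hi))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one thorax phantom.

    Activity concentrations are in arbitrary units per voxel volume; only
    ratios matter downstream because count levels are calibrated at
    simulation time.  ``rib_suppression`` scales the painted bone uptake for
    class-3 phantoms (strong myocardial uptake with mild/absent rib uptake);
    the myocardial concentration is always ``myo_to_rib_ratio * rib_uptake``
    relative to the *unsuppressed* rib reference.
    """

    grid: GridGeometry = field(default_factory=lambda: GridGeometry((64, 64, 64), 4.92))
    myo_to_rib_ratio: float = 1.0
    rib_uptake: float = 4.0
    soft_tissue_activity: float = 1.0
    lung_activity: float = 0.2
    blood_activity: float = 1.0
    kidney_activity: float = 6.0
    rib_suppression: float = 0.5
    mu_soft: float = MU_SOFT_TISSUE
    mu_lung: float = MU_LUNG
    mu_bone: float = MU_BONE
    jitter: bool = False
    jitter_translation_mm: float = 10.0
    jitter_size_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.myo_to_rib_ratio < 0:
            raise ValueError("myo_to_rib_ratio must be >= 0")
        for name in ("rib_uptake", "soft_tissue_activity", "lung_activity",
                     "blood_activity", "kidney_activity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.rib_suppression <= 1:
            raise ValueError("rib_suppression must be in (0, 1]")
        if not (self.mu_lung < self.mu_soft < self.mu_bone):
            raise ValueError("expected mu_lung < mu_soft < mu_bone")

    @property
    def perugini_class_truth(self) -> int:
        return classify_ratio(self.myo_to_rib_ratio)

    @property
    def myocardial_activity(self) -> float:
        return self.myo_to_rib_ratio * self.rib_uptake

    @property
    def painted_rib_activity(self) -> float:
        """Bone concentration actually painted (suppressed for class 3)."""
        if self.perugini_class_truth == 3:
            return self.rib_uptake * self.rib_suppression
        return self.rib_uptake


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth record for one subject, replacing human visual scoring."""

    subject_id: str
    perugini_class_truth: int
    myo_to_rib_ratio: float
    heart_center_mm: tuple[float, float, float]  # (z, y, x)
    total_activity: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perugini_class_truth not in (0, 1, 2, 3):
            raise ValueError("class must be in {0,1,2,3}")


@dataclass(frozen=True)
class CohortSpec:
    """A seeded cohort of phantoms with a fixed Perugini-class mix."""

    n_subjects: int = 30
    class_mix: dict[int, int] = field(
        default_factory=lambda: {0: 10, 1: 5, 2: 5, 3: 10})
    count_level: float = 2.0e6
    master_seed: int = 0
    grid: GridGeometry = field(default_factory=lambda: GridGeometry((64, 64, 64), 4.92))
    jitter: bool = True

    def __post_init__(self) -> None:
        if sum(self.class_mix.values()) != self.n_subjects:
            raise ValueError(
                f"class mix {self.class_mix} sums to {sum(self.class_mix.values())},"
                f" expected n_subjects={self.n_subjects}")
        if any(c not in (0, 1, 2, 3) for c in self.class_mix):
            raise ValueError("class mix keys must be Perugini classes 0-3")


# --- geometry helpers -------------------------------------------------------

def _voxel_centers(grid: GridGeometry):
    d = grid.voxel_size_mm
    z = (np.arange(grid.nz) + 0.5) * d
    y = (np.arange(grid.ny) + 0.5) * d
    x = (np.arange(grid.nx) + 0.5) * d
    return np.meshgrid(z, y, x, indexing="ij")


def _ellipsoid(zz, yy, xx, center, semi):
    cz, cy, cx = center
    az, ay, ax = semi
    return (((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2
            + ((xx - cx) / ax) ** 2) <= 1.0


def _tube_z(zz, yy, xx, cy, cx, ry, rx, z_lo, z_hi):
    """Elliptic cylinder along z between fractional-independent mm bounds."""
    return ((((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2) <= 1.0) \
        & (zz >= z_lo) & (zz <= z_hi)


def _tube_x(zz, yy, xx, cz, cy, rz, ry, x_lo, x_hi):
    """Elliptic cylinder along x (rib bar)."""
    return ((((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2) <= 1.0) \
        & (xx >= x_lo) & (xx <= x_hi)


def make_phantom(spec: PhantomSpec, seed: int = 0):
    """Rasterise one phantom.

    Returns ``(ActivityVolume, MuMap, PhantomTruth)``.  Deterministic in
    ``(spec, seed)``; the seed drives anatomical jitter only and is ignored
    when ``spec.jitter`` is False.
    """
    grid = spec.grid
    ez, ey, ex = grid.extent_mm
    rng = np.random.default_rng(seed)

    # anatomical jitter: heart translation and size scale within bounds
    if spec.jitter:
        dz, dy, dx = rng.uniform(-spec.jitter_translation_mm,
                                 spec.jitter_translation_mm, size=3)
        size_scale = 1.0 + rng.uniform(-spec.jitter_size_frac,
                                       spec.jitter_size_frac)
    else:
        dz = dy = dx = 0.0
        size_scale = 1.0

    zz, yy, xx = _voxel_centers(grid)
    act = np.zeros(grid.shape)
    mu = np.zeros(grid.shape)

    def paint(mask, a, m):
        act[mask] = a
        mu[mask] = m

    # body: elliptic cylinder along z covering the full axial range
    body = _tube_z(zz, yy, xx, 0.50 * ey, 0.50 * ex,
                   0.42 * ey, 0.46 * ex, 0.0, ez)
    paint(body, spec.soft_tissue_activity, spec.mu_soft)

    # lungs: right lung slightly larger; both posterior of the heart level
    lung_semi = (0.28 * ez, 0.24 * ey, 0.15 * ex)
    paint(body & _ellipsoid(zz, yy, xx, (0.58 * ez, 0.50 * ey, 0.28 * ex), lung_semi),
          spec.lung_activity, spec.mu_lung)
    paint(body & _ellipsoid(zz, yy, xx, (0.58 * ez, 0.50 * ey, 0.74 * ex),
                            (0.26 * ez, 0.22 * ey, 0.13 * ex)),
          spec.lung_activity, spec.mu_lung)

    bone_act = spec.painted_rib_activity

    # spine: posterior midline column
    paint(_tube_z(zz, yy, xx, 0.80 * ey, 0.50 * ex, 0.07 * ey, 0.06 * ex, 0.0, ez),
          bone_act, spec.mu_bone)
    # sternum: anterior midline column over the chest
    paint(_tube_z(zz, yy, xx, 0.13 * ey, 0.50 * ex, 0.045 * ey, 0.035 * ex,
                  0.30 * ez, 0.95 * ez),
          bone_act, spec.mu_bone)
    # ribs: anterior bars at several cranio-caudal levels
    n_ribs = 5
    for k in range(n_ribs):
        cz = (0.22 + 0.15 * k) * ez
        paint(_tube_x(zz, yy, xx, cz, 0.14 * ey, 0.035 * ez, 0.030 * ey,
                      0.08 * ex, 0.92 * ex),
              bone_act, spec.mu_bone)

    # kidneys: paired, caudal, posterior
    kid_semi = (0.09 * ez, 0.07 * ey, 0.06 * ex)
    for cx in (0.33 * ex, 0.67 * ex):
        paint(_ellipsoid(zz, yy, xx, (0.10 * ez, 0.62 * ey, cx), kid_semi),
              spec.kidney_activity, spec.mu_soft)

    # heart: spherical myocardial shell around a blood pool, patient-left,
    # anterior; jitter clamped so the centre stays strictly patient-left.
    # Outer radius ~1/6 of thorax width; thickened wall (amyloidotic hearts)
    r_out = 0.165 * ex * size_scale
    r_in = 0.62 * r_out
    cz_h = float(np.clip(0.55 * ez + dz, 0.25 * ez, 0.80 * ez))
    cy_h = float(np.clip(0.38 * ey + dy, 0.25 * ey, 0.55 * ey))
    cx_h = float(np.clip(0.64 * ex + dx, 0.57 * ex, 0.75 * ex))
    outer = _ellipsoid(zz, yy, xx, (cz_h, cy_h, cx_h), (r_out, r_out, r_out))
    inner = _ellipsoid(zz, yy, xx, (cz_h, cy_h, cx_h), (r_in, r_in, r_in))
    paint(inner, spec.blood_activity, spec.mu_soft)
    paint(outer & ~inner, spec.myocardial_activity, spec.mu_soft)

    activity = ActivityVolume(act, grid)
    truth = PhantomTruth(
        subject_id="phantom",
        perugini_class_truth=spec.perugini_class_truth,
        myo_to_rib_ratio=spec.myo_to_rib_ratio,
        heart_center_mm=(cz_h, cy_h, cx_h),
        total_activity=activity.total_activity(),
        seed=int(seed),
    )
    return activity, MuMap(mu, grid), truth


def make_cohort(cohort: CohortSpec):
    """Generate the full seeded cohort.

    Returns a list of ``(ActivityVolume, MuMap, PhantomTruth)`` triples, one
    per subject, in a seeded shuffled class order.  A pure function of the
    CohortSpec: the master seed drives per-subject seeds, uptake-ratio draws
    within each class band and anatomical jitter.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cohort.master_seed))
    classes = np.repeat(
        sorted(cohort.class_mix), [cohort.class_mix[c] for c in sorted(cohort.class_mix)])
    rng.shuffle(classes)
    subject_seeds = np.random.SeedSequence(cohort.master_seed).generate_state(
        cohort.n_subjects) % (2 ** 31)

    out = []
    for i, (cls, s) in enumerate(zip(classes, subject_seeds)):
        ratio = ratio_for_class(int(cls), rng)
        spec = PhantomSpec(grid=cohort.grid, myo_to_rib_ratio=ratio,
                           jitter=cohort.jitter)
        activity, mu, truth = make_phantom(spec, seed=int(s))
        truth = replace(truth, subject_id=f"S{i + 1:03d}")
        out.append((activity, mu, truth))
    return out
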