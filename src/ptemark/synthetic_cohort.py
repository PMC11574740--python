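"""Seeded synthetic TBI cohort generator.

Emulates the statistical structure that the downstream marker analysis
assumes: skull-stripped, atlas-registered "FLAIR-like" anatomical volumes
with hyperintense lesions whose spatial *prevalence* differs between the
PTE and non-PTE groups (so that group differences show up as variance, not
mean shifts), and band-limited ROI-driven resting-state time series with
group-dependent ALFF variance and connectivity perturbations.

Everything is pure and deterministic given a :class:`CohortConfig`; per-subject
random streams are derived from ``(config.seed, subject_index, stream_tag)``
so single subjects can be regenerated in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import ndimage

__all__ = [
    "ROI_NAMES",
    "PTE",
    "NONPTE",
    "CohortConfig",
    "Parcellation",
    "SyntheticSubject",
    "Cohort",
    "null_config",
    "strong_config",
    "generate_parcellation",
    "generate_anatomy",
    "plant_lesions",
    "generate_fmri",
    "generate_cohort",
    "iter_subjects",
]

PTE = "PTE"
NONPTE = "nonPTE"

# Lobe-level parcellation: 15 regions (bilateral frontal, parietal, temporal,
# occipital, insula, cingulate; brainstem; cerebellum; corpus callosum).
ROI_NAMES: tuple[str, ...] = (
    "L Frontal",
    "R Frontal",
    "L Parietal",
    "R Parietal",
    "L Temporal",
    "R Temporal",
    "L Occipital",
    "R Occipital",
    "L Insula",
    "R Insula",
    "L Cingulate",
    "R Cingulate",
    "Brainstem",
    "Cerebellum",
    "Corpus Callosum",
)

# Fractional (x, y, z) seed coordinates of each region inside the unit cube:
# x = left->right, y = posterior->anterior, z = inferior->superior.  Regions
# are the Voronoi cells of these seeds intersected with an ellipsoidal brain
# mask, which keeps every region contiguous.
_ROI_SEEDS = np.array(
    [
        (0.32, 0.74, 0.62),  # L Frontal
        (0.68, 0.74, 0.62),  # R Frontal
        (0.32, 0.42, 0.80),  # L Parietal
        (0.68, 0.42, 0.80),  # R Parietal
        (0.15, 0.55, 0.34),  # L Temporal
        (0.85, 0.55, 0.34),  # R Temporal
        (0.34, 0.12, 0.58),  # L Occipital
        (0.66, 0.12, 0.58),  # R Occipital
        (0.38, 0.58, 0.48),  # L Insula
        (0.62, 0.58, 0.48),  # R Insula
        (0.44, 0.56, 0.72),  # L Cingulate
        (0.56, 0.56, 0.72),  # R Cingulate
        (0.50, 0.50, 0.10),  # Brainstem
        (0.50, 0.20, 0.16),  # Cerebellum
        (0.50, 0.52, 0.60),  # Corpus Callosum
    ]
)

_MIN_ROI_VOXELS = 27


def _default_lesion_prevalence() -> dict[str, tuple[float, float]]:
    """Per-ROI lesion probability as (nonPTE, PTE).

    Baseline 5% everywhere; elevated PTE prevalence in bilateral temporal
    lobes, right occipital lobe and cerebellum, the regions where the group
    variance differences are planted.
    """
    prev = {name: (0.05, 0.05) for name in ROI_NAMES}
    for name in ("L Temporal", "R Temporal", "R Occipital", "Cerebellum"):
        prev[name] = (0.05, 0.45)
    return prev


def _default_alff_ratio() -> dict[str, float]:
    """PTE/non-PTE ALFF variance ratio per ROI (1.0 = no planted effect)."""
    ratio = {name: 1.0 for name in ROI_NAMES}
    for name in ("R Temporal", "R Occipital", "L Occipital", "R Parietal"):
        ratio[name] = 3.0
    return ratio


def _default_connectivity_shift() -> dict[tuple[str, str], tuple[float, float]]:
    """Additive correlation perturbation per ROI pair as (nonPTE, PTE)."""
    return {
        ("L Temporal", "R Temporal"): (0.0, -0.35),
        ("R Temporal", "Cerebellum"): (0.0, 0.35),
        ("L Occipital", "R Occipital"): (0.0, -0.30),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Design parameters of a synthetic cohort.

    Defaults follow the study design this generator emulates: 36 subjects per
    group, 153 resting-state volumes at a 2 s repetition interval, and an
    ALFF band of 0.01-0.1 Hz.  The grid is a desk-scale 64x64x16 stand-in for
    a 1 mm atlas grid (isotropic unit spacing).
    """

    n_per_group: int = 36
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    n_volumes: int = 153
    repetition_interval: float = 2.0
    alff_band: tuple[float, float] = (0.01, 0.1)
    lesion_prevalence: dict[str, tuple[float, float]] = field(
        default_factory=_default_lesion_prevalence
    )
    lesion_intensity: float = 3.0  # lesion contrast as a multiple of noise_sd
    # blob semi-axes in voxels: wide in-plane, thin through-plane, mirroring
    # the thick-slice acquisitions this generator emulates (~2.5 cm contusion)
    lesion_radius: float = 5.0
    lesion_radius_z: float = 2.0
    alff_variance_ratio: dict[str, float] = field(default_factory=_default_alff_ratio)
    alff_amp_sd: float = 0.2  # baseline across-subject sd of the ROI amplitude
    connectivity_shift: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=_default_connectivity_shift
    )
    noise_sd: float = 0.05  # anatomical voxel noise, intensity units
    fmri_noise_sd: float = 1.0  # white voxel noise on top of the ROI latent
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be three positive integers")
        nyquist = 1.0 / (2.0 * self.repetition_interval)
        low, high = self.alff_band
        if not (0.0 < low < high < nyquist):
            raise ValueError(
                f"alff_band must satisfy 0 < low < high < Nyquist ({nyquist:g} Hz)"
            )
        for name, (p0, p1) in self.lesion_prevalence.items():
            if not (0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0):
                raise ValueError(f"lesion prevalence for {name!r} outside [0, 1]")
        for name, r in self.alff_variance_ratio.items():
            if r <= 0:
                raise ValueError(f"ALFF variance ratio for {name!r} must be > 0")


def null_config(**overrides) -> CohortConfig:
    """A :class:`CohortConfig` with every planted group effect switched off.

    Under this configuration the two groups are statistically exchangeable,
    which calibration tests rely on.
    """
    base = dict(
        lesion_prevalence={name: (0.0, 0.0) for name in ROI_NAMES},
        alff_variance_ratio={name: 1.0 for name in ROI_NAMES},
        connectivity_shift={},
    )
    base.update(overrides)
    return CohortConfig(**base)


def strong_config(**overrides) -> CohortConfig:
    """A :class:`CohortConfig` with strongly planted group effects.

    Used as the classifier-recovery condition: near-deterministic lesion
    prevalence differences, large connectivity shifts and a large ALFF
    variance ratio, so a working pipeline must separate the groups.
    """
    prev = {name: (0.05, 0.05) for name in ROI_NAMES}
    for name in ("L Temporal", "R Temporal", "R Occipital", "Cerebellum"):
        prev[name] = (0.05, 0.9)
    ratio = {name: 1.0 for name in ROI_NAMES}
    for name in ("R Temporal", "R Occipital", "L Occipital", "R Parietal"):
        ratio[name] = 6.0
    shift = {
        ("L Temporal", "R Temporal"): (0.0, -0.5),
        ("R Temporal", "Cerebellum"): (0.0, 0.5),
        ("L Occipital", "R Occipital"): (0.0, -0.45),
    }
    base = dict(
        lesion_prevalence=prev,
        alff_variance_ratio=ratio,
        connectivity_shift=shift,
    )
    base.update(overrides)
    return CohortConfig(**base)


@dataclass(frozen=True)
class Parcellation:
    """Integer label volume (0 = outside brain) plus the ordered ROI table."""

    label_volume: np.ndarray  # int16, shape = grid_shape
    roi_table: tuple[tuple[int, str], ...]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_volume > 0

    @property
    def roi_ids(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.roi_table)

    @property
    def roi_names(self) -> tuple[str, ...]:
        return tuple(n for _, n in self.roi_table)

    def roi_sizes(self) -> np.ndarray:
        counts = np.bincount(self.label_volume.ravel(), minlength=len(self.roi_table) + 1)
        return counts[1 : len(self.roi_table) + 1]


@dataclass
class SyntheticSubject:
    """One generated subject: anatomy, time series, label and ground truth."""

    subject_id: str
    group: str  # PTE or nonPTE
    anat: np.ndarray  # float32 in [0, 1], shape = grid_shape
    ts: np.ndarray  # float32, shape = grid_shape + (n_volumes,)
    true_lesion_mask: np.ndarray  # bool, shape = grid_shape


@dataclass
class Cohort:
    subjects: list[SyntheticSubject]
    parcellation: Parcellation
    config: CohortConfig

    def labels(self) -> list[str]:
        return [s.group for s in self.subjects]


# ---------------------------------------------------------------------------
# Parcellation and anatomy
# ---------------------------------------------------------------------------

def _brain_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(
        (np.arange(nx) + 0.5) / nx,
        (np.arange(ny) + 0.5) / ny,
        (np.arange(nz) + 0.5) / nz,
        indexing="ij",
    )
    # Ellipsoid with semi-axes 0.46 of each grid dimension.
    r2 = ((x - 0.5) / 0.46) ** 2 + ((y - 0.5) / 0.46) ** 2 + ((z - 0.5) / 0.46) ** 2
    return r2 <= 1.0


def generate_parcellation(grid_shape: tuple[int, int, int] = (64, 64, 16)) -> Parcellation:
    """Deterministically tile an ellipsoidal brain mask into 15 labeled regions.

    Regions are Voronoi cells (in fractional grid coordinates) of fixed lobe
    seed points, so the same grid always yields the same labels and every
    region is contiguous.  Voxels outside the brain mask are labeled 0.
    """
    mask = _brain_mask(grid_shape)
    nx, ny, nz = grid_shape
    idx = np.argwhere(mask)
    frac = (idx + 0.5) / np.array([nx, ny, nz])
    # nearest seed in fractional coordinates
    d2 = ((frac[:, None, :] - _ROI_SEEDS[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)

    labels = np.zeros(grid_shape, dtype=np.int16)
    labels[tuple(idx.T)] = nearest.astype(np.int16) + 1

    parc = Parcellation(
        label_volume=labels,
        roi_table=tuple((i + 1, name) for i, name in enumerate(ROI_NAMES)),
    )
    sizes = parc.roi_sizes()
    if sizes.min() < _MIN_ROI_VOXELS:
        smallest = ROI_NAMES[int(sizes.argmin())]
        raise ValueError(
            f"grid {grid_shape} too small: ROI {smallest!r} has "
            f"{int(sizes.min())} voxels (< {_MIN_ROI_VOXELS})"
        )
    return parc


def _subject_rng(config_seed: int, subject_index: int, stream: int) -> np.random.Generator:
    # Deterministic per-subject, per-stream stream derived from the cohort seed.
    return np.random.default_rng(
        np.random.SeedSequence([int(config_seed), int(subject_index), int(stream)])
    )


def generate_anatomy(config: CohortConfig, subject_seed: tuple[int, int]) -> np.ndarray:
    """Smooth brain-masked intensity field plus voxel noise, clipped to [0, 1].

    The smooth base field is identical for all subjects (the cohort is assumed
    registered to a common atlas); only the voxel noise varies with the seed.
    Background voxels are exactly 0.
    """
    nx, ny, nz = config.grid_shape
    mask = _brain_mask(config.grid_shape)
    x, y, z = np.meshgrid(
        (np.arange(nx) + 0.5) / nx,
        (np.arange(ny) + 0.5) / ny,
        (np.arange(nz) + 0.5) / nz,
        indexing="ij",
    )
    rho2 = (x - 0.5) ** 2 + (y - 0.5) ** 2 + (z - 0.5) ** 2
    base = 0.30 + 0.45 * np.exp(-rho2 / 0.12) + 0.08 * np.cos(3 * np.pi * x) * np.cos(
        2 * np.pi * y
    )
    vol = base.copy()
    if config.noise_sd > 0:
        rng = _subject_rng(config.seed, subject_seed[1], 0) if isinstance(
            subject_seed, tuple
        ) else np.random.default_rng(subject_seed)
        vol = vol + rng.normal(0.0, config.noise_sd, size=vol.shape)
    vol = np.clip(vol, 0.0, 1.0)
    vol[~mask] = 0.0
    return vol.astype(np.float32)


def plant_lesions(
    anat: np.ndarray,
    parcellation: Parcellation,
    group: str,
    config: CohortConfig,
    subject_seed: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Add ellipsoidal hyperintense blobs per ROI with group-dependent probability.

    For each ROI an independent Bernoulli draw with the group's prevalence
    decides whether a blob (in-plane semi-axis ``lesion_radius``, through-plane
    ``lesion_radius_z``, contrast ``lesion_intensity * noise_sd``) is placed,
    centered uniformly inside the ROI.  Blobs that would extend outside the
    brain are shrunk to fit (with a warning).  Returns the lesioned volume and
    the boolean ground-truth mask.
    """
    gi = 1 if group == PTE else 0
    rng = _subject_rng(config.seed, subject_seed[1], 1) if isinstance(
        subject_seed, tuple
    ) else np.random.default_rng(subject_seed)
    labels = parcellation.label_volume
    mask_brain = parcellation.brain_mask
    edt = ndimage.distance_transform_edt(mask_brain)

    out = anat.copy()
    lesion_mask = np.zeros(anat.shape, dtype=bool)
    contrast = config.lesion_intensity * config.noise_sd

    grid = np.indices(anat.shape)
    for roi_id, name in parcellation.roi_table:
        prev = config.lesion_prevalence.get(name, (0.0, 0.0))[gi]
        if rng.random() >= prev:
            continue
        roi_vox = np.argwhere(labels == roi_id)
        center = roi_vox[rng.integers(len(roi_vox))]
        r_xy = float(config.lesion_radius)
        r_z = float(config.lesion_radius_z)
        r_allowed = float(edt[tuple(center)])
        if r_allowed < r_z:
            scale = max(r_allowed, 1.0) / r_z
            warnings.warn(
                f"lesion extent exceeds brain at ROI {name!r}; shrunk by "
                f"factor {scale:.2f}",
                stacklevel=2,
            )
            r_xy, r_z = max(r_xy * scale, 1.0), max(r_z * scale, 1.0)
        d2 = (
            ((grid[0] - center[0]) ** 2 + (grid[1] - center[1]) ** 2) / r_xy**2
            + (grid[2] - center[2]) ** 2 / r_z**2
        )
        blob = (d2 <= 1.0) & mask_brain
        out[blob] = np.clip(out[blob] + contrast, 0.0, 1.0)
        lesion_mask |= blob
    return out.astype(np.float32), lesion_mask


# ---------------------------------------------------------------------------
# fMRI
# ---------------------------------------------------------------------------

def _base_correlation() -> np.ndarray:
    """Fixed 15x15 base ROI correlation (distance-decaying, PD by construction)."""
    d = np.sqrt(((_ROI_SEEDS[:, None, :] - _ROI_SEEDS[None, :, :]) ** 2).sum(axis=2))
    c = 0.15 + 0.75 * np.exp(-((d / 0.25) ** 2))
    np.fill_diagonal(c, 1.0)
    return c


def repair_correlation(c: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the nearest-ish PD correlation matrix.

    Eigenvalues are clipped at ``min_eig`` and the diagonal re-normalized to 1.
    Raises if the input is so indefinite that the repair moves entries by more
    than 0.5 in absolute correlation.
    """
    c = (c + c.T) / 2.0
    w, v = np.linalg.eigh(c)
    repaired = (v * np.clip(w, min_eig, None)) @ v.T
    dinv = 1.0 / np.sqrt(np.diag(repaired))
    repaired = repaired * dinv[:, None] * dinv[None, :]
    np.fill_diagonal(repaired, 1.0)
    if np.max(np.abs(repaired - c)) > 0.5:
        raise ValueError(
            "perturbed correlation matrix not repairable to positive definite "
            f"(minimum eigenvalue {w.min():.3g})"
        )
    return repaired


def _group_correlation(config: CohortConfig, parcellation: Parcellation, group: str) -> np.ndarray:
    gi = 1 if group == PTE else 0
    names = list(parcellation.roi_names)
    c = _base_correlation().copy()
    for (a, b), shifts in config.connectivity_shift.items():
        ia, ib = names.index(a), names.index(b)
        c[ia, ib] += shifts[gi]
        c[ib, ia] = c[ia, ib]
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -0.99, 0.99)
    np.fill_diagonal(c, 1.0)
    return repair_correlation(c)


def _bandpass_rows(x: np.ndarray, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Zero every Fourier bin outside [low, high] (inclusive), per row."""
    t = x.shape[-1]
    freqs = np.fft.rfftfreq(t, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spectrum = np.fft.rfft(x, axis=-1)
    spectrum[..., ~keep] = 0.0
    return np.fft.irfft(spectrum, n=t, axis=-1)


def generate_fmri(
    parcellation: Parcellation,
    group: str,
    config: CohortConfig,
    subject_seed: tuple[int, int],
) -> np.ndarray:
    """Band-limited ROI-driven 4-D time series for one subject.

    15 latent ROI signals are drawn from a multivariate normal whose target
    correlation matrix is the base matrix perturbed per group (repaired to a
    positive-definite correlation matrix), band-pass filtered to the ALFF band
    and standardized.  Each ROI latent is scaled by a per-subject amplitude
    whose across-subject variance is group-dependent (the planted ALFF
    effect); each in-brain voxel's series is its ROI latent plus white noise.
    """
    gi = 1 if group == PTE else 0
    rng = _subject_rng(config.seed, subject_seed[1], 2) if isinstance(
        subject_seed, tuple
    ) else np.random.default_rng(subject_seed)
    t = config.n_volumes
    corr = _group_correlation(config, parcellation, group)
    chol = np.linalg.cholesky(corr)

    latent = chol @ rng.standard_normal((len(parcellation.roi_table), t))
    latent = _bandpass_rows(latent, config.repetition_interval, config.alff_band)
    sd = latent.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    latent /= sd

    # Per-subject ROI band-power multiplier m (amplitude sqrt(m)): ALFF scales
    # linearly with m, so the across-subject ALFF variance ratio between the
    # groups equals alff_variance_ratio (up to truncation at 0.05).
    amps = np.empty(len(parcellation.roi_table))
    for k, (_, name) in enumerate(parcellation.roi_table):
        ratio = config.alff_variance_ratio.get(name, 1.0)
        s = config.alff_amp_sd * (np.sqrt(ratio) if gi == 1 else 1.0)
        m = max(1.0 + s * rng.standard_normal(), 0.05)
        amps[k] = np.sqrt(m)
    latent *= amps[:, None]

    labels = parcellation.label_volume
    ts = np.zeros(config.grid_shape + (t,), dtype=np.float32)
    inb = labels > 0
    roi_index = labels[inb] - 1
    noise = rng.normal(0.0, config.fmri_noise_sd, size=(int(inb.sum()), t))
    ts[inb] = (latent[roi_index] + noise).astype(np.float32)
    return ts


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _subject_plan(config: CohortConfig) -> list[tuple[int, str, str]]:
    plan = []
    for i in range(config.n_per_group):
        plan.append((i, PTE, f"sub-{i:03d}-PTE"))
    for i in range(config.n_per_group):
        j = config.n_per_group + i
        plan.append((j, NONPTE, f"sub-{j:03d}-nonPTE"))
    return plan


def iter_subjects(
    config: CohortConfig, parcellation: Parcellation | None = None
) -> Iterator[SyntheticSubject]:
    """Yield subjects one at a time (memory-friendly for the default cohort)."""
    parc = parcellation if parcellation is not None else generate_parcellation(config.grid_shape)
    for index, group, sid in _subject_plan(config):
        anat = generate_anatomy(config, (config.seed, index))
        anat, mask = plant_lesions(anat, parc, group, config, (config.seed, index))
        ts = generate_fmri(parc, group, config, (config.seed, index))
        yield SyntheticSubject(
            subject_id=sid, group=group, anat=anat, ts=ts, true_lesion_mask=mask
        )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort (``n_per_group`` subjects per label) in memory.

    Pure and bitwise-deterministic given the config.  For the default cohort
    size prefer :func:`iter_subjects`, which streams subjects.
    """
    parc = generate_parcellation(config.grid_shape)
    subjects = list(iter_subjects(config, parc))
    return Cohort(subjects=subjects, parcellation=parc, config=config)
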