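"""Synthetic textured abdominal phantom and CT acquisition emulation.

Generates the inputs the stability analysis consumes when no scanner data
are available: a noise-free 2-D patterned phantom slice replicated into a
thin volume, containing three tissue classes (normal liver parenchyma, a
metastatic core and its surrounding rim) with distinct mean attenuation
and frozen spatial texture; dose-dependent noisy acquisitions of that
ground truth; and four reconstruction emulators that reproduce the
qualitative noise behaviour of filtered back projection (FBP), hybrid
iterative (HIR), model-based iterative (MBIR) and deep-learning (DLR)
reconstruction.

The acquisition model is deliberately image-domain only: stationary,
spatially correlated, zero-mean Gaussian noise whose standard deviation
follows the quantum-noise scaling law

    sigma(dose) = sigma_ref * sqrt(dose_ref / dose),    dose_ref = 1 mGy.

Sinogram physics (beam hardening, scatter, helical geometry) are out of
scope: the downstream analysis consumes only image-domain statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "TissueClassSpec",
    "AcquisitionDesign",
    "EmulatorParams",
    "ImageVolume",
    "ROISet",
    "PhantomSizingError",
    "TABLE1_DOSES_MGY",
    "RECON_MODES",
    "default_class_specs",
    "generate_ground_truth",
    "simulate_acquisition",
    "apply_reconstruction_emulator",
    "acquisition_seed",
    "build_manifest",
    "generate_dataset",
    "iter_acquisitions",
]

#: The 18 CTDIvol levels (mGy) of the acquisition protocol, spanning
#: 0.2-4 mGy (tube current 10-200 mA at 0.02 mGy/mA).
TABLE1_DOSES_MGY: tuple[float, ...] = (
    0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8,
    2.0, 2.2, 2.4, 2.6, 2.8, 3.0, 3.2, 3.6, 4.0,
)

#: Reconstruction emulator modes, ordered from texture-faithful/noisy to
#: strongly denoising.
RECON_MODES: tuple[str, ...] = ("FBP", "HIR", "MBIR", "DLR")

TISSUE_CLASSES: tuple[str, ...] = ("liver", "metastatic_core", "metastatic_rim")

N_ROIS_PER_CLASS = 8

#: In-plane ROI radius in voxels (9-voxel diameter cylinders).
ROI_RADIUS_VOX = 4.5


class PhantomSizingError(ValueError):
    """Raised when the requested volume cannot hold 24 non-overlapping ROIs."""


@dataclass(frozen=True)
class TissueClassSpec:
    """Attenuation statistics of one tissue class.

    Parameters
    ----------
    name:
        One of ``liver``, ``metastatic_core``, ``metastatic_rim``.
    mean_hu:
        Mean attenuation in Hounsfield units.
    texture_amplitude:
        Standard deviation (HU) of the frozen ground-truth texture field.
    texture_correlation_length:
        Correlation length of that field, in voxels (>= 1).
    """

    name: str
    mean_hu: float
    texture_amplitude: float
    texture_correlation_length: float

    def __post_init__(self) -> None:
        if self.name not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.name!r}")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be >= 0")
        if self.texture_correlation_length < 1:
            raise ValueError("texture_correlation_length must be >= 1 voxel")


def default_class_specs() -> tuple[TissueClassSpec, ...]:
    """Default tissue classes: distinguishable at high dose, confusable at 0.2 mGy."""
    return (
        TissueClassSpec("liver", 100.0, 10.0, 2.0),
        TissueClassSpec("metastatic_core", 40.0, 6.0, 1.0),
        TissueClassSpec("metastatic_rim", 70.0, 12.0, 2.0),
    )


@dataclass(frozen=True)
class AcquisitionDesign:
    """Factorial acquisition design: doses x repeats x reconstruction modes."""

    doses: tuple[float, ...] = TABLE1_DOSES_MGY
    n_repeats: int = 20
    recon_modes: tuple[str, ...] = RECON_MODES
    master_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.doses) < 1 or any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        unknown = set(self.recon_modes) - set(RECON_MODES)
        if unknown:
            raise ValueError(f"unknown reconstruction modes: {sorted(unknown)}")
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        object.__setattr__(self, "recon_modes", tuple(self.recon_modes))

    @property
    def n_datasets(self) -> int:
        return len(self.doses) * self.n_repeats * len(self.recon_modes)

    def small(self) -> "AcquisitionDesign":
        """Reduced design for tests and quick runs: 4 doses x 5 repeats x 4 modes."""
        return dataclasses.replace(self, doses=(0.4, 1.2, 2.0, 4.0), n_repeats=5)


@dataclass(frozen=True)
class EmulatorParams:
    """Tunables of the four reconstruction emulators.

    ``sigma_ref`` is the FBP noise SD (HU) at the 1 mGy reference dose;
    ``noise_kernel_sigma`` the in-plane Gaussian correlation of the raw
    noise field shared by all modes. ``hir_sigma`` is the HIR linear
    smoothing kernel; ``mbir_passes`` 3x3 in-plane median passes for the
    edge-preserving MBIR emulator; ``dlr_alpha`` the convex weight of the
    prior-anchored estimate in the DLR emulator and ``dlr_smooth_sigma``
    the smoothing applied to the residual around the texture prior.
    """

    sigma_ref: float = 25.0
    dose_ref: float = 1.0
    noise_kernel_sigma: float = 0.6
    hir_sigma: float = 0.8
    mbir_passes: int = 2
    dlr_alpha: float = 0.9
    dlr_smooth_sigma: float = 2.0
    #: RMS tolerance (HU) by which any emulator may perturb a noise-free
    #: volume inside class interiors.
    clean_tolerance_hu: float = 10.0


@dataclass(frozen=True)
class ImageVolume:
    """3-D voxel grid of HU values, axis order (z, y, x)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {v.shape}")
        object.__setattr__(self, "voxels", v)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class ROISet:
    """Integer label volume (0 = background, 1..24 = ROI ids) + class table."""

    labels: np.ndarray
    class_of: dict[int, str]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("label volume must be 3-D")
        object.__setattr__(self, "labels", lab.astype(np.int16))

    @property
    def roi_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.class_of))

    def mask(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"roi_id": list(self.roi_ids),
             "tissue_class": [self.class_of[i] for i in self.roi_ids]}
        )


# ---------------------------------------------------------------------------
# Ground truth generation
# ---------------------------------------------------------------------------

def _correlated_field(shape_2d, correlation_length, rng) -> np.ndarray:
    """Band-limited unit-variance random field (2-D)."""
    white = rng.standard_normal(shape_2d)
    f = ndimage.gaussian_filter(white, sigma=correlation_length, mode="wrap")
    f -= f.mean()
    sd = f.std()
    if sd > 0:
        f /= sd
    return f


def _phantom_geometry(shape):
    """Concentric lesion-in-liver geometry scaled to the in-plane extent.

    Returns per-class boolean masks (2-D) and per-class ROI centre lists.
    Radii scale with min(ny, nx)/128; ROI size is fixed at a 9-voxel
    diameter, so below ~96 in-plane voxels the 24 ROIs no longer fit and
    a PhantomSizingError is raised.
    """
    nz, ny, nx = shape
    if ny < 32 or nx < 32 or nz < 4:
        raise PhantomSizingError(
            f"shape {shape} too small: need >= 32 in-plane voxels and >= 4 slices"
        )
    s = min(ny, nx) / 128.0
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    core_r, rim_r, liver_r = 20.0 * s, 32.0 * s, 58.0 * s
    ring_r = {"metastatic_core": 13.0 * s,
              "metastatic_rim": 26.0 * s,
              "liver": 45.0 * s}
    band = {"metastatic_core": (0.0, core_r),
            "metastatic_rim": (core_r, rim_r),
            "liver": (rim_r, liver_r)}
    # each ROI cylinder must fit radially inside its class band ...
    for cls, r in ring_r.items():
        lo, hi = band[cls]
        if r - ROI_RADIUS_VOX < lo or r + ROI_RADIUS_VOX > hi:
            raise PhantomSizingError(
                f"shape {shape} too small: ROI ring for {cls} "
                f"(radius {r:.1f} +/- {ROI_RADIUS_VOX}) exceeds its class band "
                f"[{lo:.1f}, {hi:.1f}]"
            )
        # ... and 8 ROIs must fit around the ring without overlapping
        min_sep = 2.0 * r * np.sin(np.pi / N_ROIS_PER_CLASS)
        if min_sep < 2.0 * ROI_RADIUS_VOX:
            raise PhantomSizingError(
                f"shape {shape} too small: 8 ROIs of diameter "
                f"{2 * ROI_RADIUS_VOX:.0f} voxels do not fit on the {cls} ring "
                f"(centre separation {min_sep:.1f})"
            )
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = np.hypot(yy - cy, xx - cx)
    masks = {
        "metastatic_core": rr <= core_r,
        "metastatic_rim": (rr > core_r) & (rr <= rim_r),
        "liver": (rr > rim_r) & (rr <= liver_r),
    }
    angle0 = {"metastatic_core": 0.0, "metastatic_rim": np.pi / 8, "liver": np.pi / 16}
    centres = {}
    for cls, r in ring_r.items():
        theta = angle0[cls] + 2 * np.pi * np.arange(N_ROIS_PER_CLASS) / N_ROIS_PER_CLASS
        centres[cls] = [(cy + r * np.sin(t), cx + r * np.cos(t)) for t in theta]
    return masks, centres


def generate_ground_truth(
    class_specs=None,
    shape: tuple[int, int, int] = (4, 128, 128),
    seed: int = 0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[ImageVolume, ROISet]:
    """Build the frozen, noise-free phantom volume and its fixed ROI layout.

    One 2-D template slice — liver disc containing a lesion (core disc +
    rim annulus), each class textured by a frozen band-limited random
    field — replicated into ``shape[0]`` identical slices, mirroring a
    phantom printed from repeated copies of one template image.

    Deterministic given ``seed``. Raises :class:`PhantomSizingError` when
    the 24 ROIs cannot be placed without overlap.
    """
    specs = tuple(class_specs) if class_specs is not None else default_class_specs()
    by_name = {sp.name: sp for sp in specs}
    if set(by_name) != set(TISSUE_CLASSES):
        raise ValueError(f"need exactly the classes {TISSUE_CLASSES}")
    nz, ny, nx = shape
    masks, centres = _phantom_geometry(shape)

    template = np.full((ny, nx), -1000.0)  # air background
    ss = np.random.SeedSequence(seed)
    for idx, cls in enumerate(TISSUE_CLASSES):
        sp = by_name[cls]
        template[masks[cls]] = sp.mean_hu
        if sp.texture_amplitude > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=ss.entropy, spawn_key=(idx,))
            )
            fld = _correlated_field((ny, nx), sp.texture_correlation_length, rng)
            template[masks[cls]] += sp.texture_amplitude * fld[masks[cls]]

    voxels = np.broadcast_to(template, (nz, ny, nx)).copy()
    volume = ImageVolume(voxels, spacing, {"kind": "ground_truth", "seed": seed})

    labels = np.zeros((nz, ny, nx), dtype=np.int16)
    class_of: dict[int, str] = {}
    yy, xx = np.mgrid[0:ny, 0:nx]
    roi_id = 0
    for cls in TISSUE_CLASSES:
        for (cy_r, cx_r) in centres[cls]:
            roi_id += 1
            disc = np.hypot(yy - cy_r, xx - cx_r) <= ROI_RADIUS_VOX
            if not disc.any() or not masks[cls][disc].all():
                raise PhantomSizingError(
                    f"ROI {roi_id} ({cls}) does not lie inside its tissue class"
                )
            if (labels[0][disc] != 0).any():
                raise PhantomSizingError(f"ROI {roi_id} ({cls}) overlaps another ROI")
            labels[:, disc] = roi_id
            class_of[roi_id] = cls
    return volume, ROISet(labels, class_of)


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------

def acquisition_seed(master_seed: int, dose_index: int, repeat_index: int):
    """Deterministic per-acquisition seed: stable across runs and platforms."""
    return np.random.SeedSequence(
        entropy=master_seed, spawn_key=(dose_index, repeat_index)
    )


def simulate_acquisition(
    ground_truth: ImageVolume,
    dose_mgy: float,
    seed,
    params: EmulatorParams | None = None,
) -> ImageVolume:
    """Add one fresh, spatially correlated noise realization at the given dose.

    Noise SD follows sigma(dose) = sigma_ref * sqrt(dose_ref / dose); the
    field is white Gaussian noise smoothed in-plane with the shared raw
    noise kernel, then renormalized to zero mean and exactly the target
    SD. Each slice receives independent noise (slices model independent
    prints of one template).
    """
    if dose_mgy <= 0:
        raise ValueError(f"dose must be positive, got {dose_mgy}")
    p = params or EmulatorParams()
    rng = np.random.default_rng(seed)
    sigma = p.sigma_ref * np.sqrt(p.dose_ref / dose_mgy)
    white = rng.standard_normal(ground_truth.shape)
    fld = ndimage.gaussian_filter(
        white, sigma=(0.0, p.noise_kernel_sigma, p.noise_kernel_sigma), mode="wrap"
    )
    fld -= fld.mean()
    fld *= sigma / fld.std()
    prov = dict(ground_truth.provenance)
    prov.update({"kind": "acquisition", "dose_mGy": float(dose_mgy)})
    return ImageVolume(ground_truth.voxels + fld, ground_truth.spacing, prov)


def apply_reconstruction_emulator(
    noisy: ImageVolume,
    mode: str,
    params: EmulatorParams | None = None,
    prior: ImageVolume | None = None,
) -> ImageVolume:
    """Emulate one reconstruction algorithm's effect on the noisy image.

    * ``FBP`` — identity: noise passed through, texture faithful.
    * ``HIR`` — moderate linear in-plane Gaussian smoothing.
    * ``MBIR`` — strong edge-preserving nonlinear smoothing (iterated
      3x3 in-plane median), which also alters the noise correlation
      structure.
    * ``DLR`` — convex blend toward a texture-prior-anchored estimate:
      ``alpha * (prior + smooth(noisy - prior)) + (1 - alpha) * noisy``.
      Removes noise strongly while preserving the ground-truth texture
      spectrum; requires ``prior`` (the frozen ground truth).

    All modes are deterministic given their input.
    """
    p = params or EmulatorParams()
    v = noisy.voxels
    if mode == "FBP":
        out = v.copy()
    elif mode == "HIR":
        out = ndimage.gaussian_filter(v, sigma=(0.0, p.hir_sigma, p.hir_sigma),
                                      mode="nearest")
    elif mode == "MBIR":
        out = v
        for _ in range(max(1, p.mbir_passes)):
            out = ndimage.median_filter(out, size=(1, 3, 3), mode="nearest")
    elif mode == "DLR":
        if prior is None:
            raise ValueError("DLR emulator requires the ground-truth texture prior")
        resid = v - prior.voxels
        est = prior.voxels + ndimage.gaussian_filter(
            resid, sigma=(0.0, p.dlr_smooth_sigma, p.dlr_smooth_sigma), mode="nearest"
        )
        out = p.dlr_alpha * est + (1.0 - p.dlr_alpha) * v
    else:
        raise ValueError(f"unknown reconstruction mode {mode!r}; "
                         f"expected one of {RECON_MODES}")
    prov = dict(noisy.provenance)
    prov["recon_mode"] = mode
    return ImageVolume(out, noisy.spacing, prov)


# ---------------------------------------------------------------------------
# Factorial dataset
# ---------------------------------------------------------------------------

def build_manifest(design: AcquisitionDesign) -> pd.DataFrame:
    """Enumerate the full factorial (dose, repeat, mode) grid, one row per dataset."""
    rows = [
        {"dose_mGy": dose, "repeat": rep, "recon_mode": mode}
        for dose in design.doses
        for rep in range(design.n_repeats)
        for mode in design.recon_modes
    ]
    return pd.DataFrame(rows)


def iter_acquisitions(design, class_specs=None, shape=(4, 128, 128),
                      params: EmulatorParams | None = None):
    """Yield ``(volume, manifest_row)`` for every cell of the design.

    The same noisy realization per (dose, repeat) is fed to all
    reconstruction emulators, mirroring reconstruction of the same raw
    data four ways. Per-acquisition seeds derive from the design's
    master seed, so the stream is fully reproducible.
    """
    p = params or EmulatorParams()
    gt, roi_set = generate_ground_truth(class_specs, shape, seed=design.master_seed)
    for d_idx, dose in enumerate(design.doses):
        for rep in range(design.n_repeats):
            noisy = simulate_acquisition(
                gt, dose, acquisition_seed(design.master_seed, d_idx, rep), p
            )
            for mode in design.recon_modes:
                vol = apply_reconstruction_emulator(noisy, mode, p, prior=gt)
                prov = dict(vol.provenance)
                prov["repeat"] = rep
                vol = ImageVolume(vol.voxels, vol.spacing, prov)
                yield vol, {"dose_mGy": dose, "repeat": rep, "recon_mode": mode}


def generate_dataset(design, class_specs=None, shape=(4, 128, 128),
                     params: EmulatorParams | None = None):
    """Materialize the full factorial dataset.

    Returns ``(volumes, roi_set, manifest)`` with one volume per
    (dose, repeat, mode) cell. For large designs prefer
    :func:`iter_acquisitions`, which streams volumes instead of holding
    all of them in memory.
    """
    gt, roi_set = generate_ground_truth(class_specs, shape, seed=design.master_seed)
    volumes = []
    rows = []
    for vol, row in iter_acquisitions(design, class_specs, shape, params):
        volumes.append(vol)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    expected = build_manifest(design)
    if not manifest[["dose_mGy", "repeat", "recon_mode"]].equals(expected):
        raise RuntimeError("factorial enumeration out of order")  # defensive
    return volumes, roi_set, manifest
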