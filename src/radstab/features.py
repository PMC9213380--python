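"""From-scratch radiomics feature extraction: 93 features in six families.

Computes, for an ROI of a CT volume, 18 first-order features and five
families of gray-level texture-matrix features — 24 co-occurrence (GLCM),
16 run length (GLRLM), 16 size zone (GLSZM), 14 dependence (GLDM) and
5 neighbouring gray-tone difference (NGTDM) — following the standard
feature definitions used across the radiomics literature.

Conventions (all configurable via :class:`ExtractionSettings`):

* Gray levels are discretized with a fixed bin width of 25 HU, anchored
  at the ROI minimum: ``level(x) = floor((x - min) / W) + 1``.
* Texture is computed in 3-D: GLCM and GLRLM use the 13 unique 3-D
  direction vectors at distance 1, each feature evaluated per direction
  and then averaged; GLSZM zones and GLDM/NGTDM neighbourhoods use
  26-connectivity.
* No prefiltering, resampling or resegmentation is applied.

Degenerate inputs (single gray level, single voxel) resolve to documented
finite guard values rather than NaN; see the per-family feature functions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractionSettings",
    "DiscretizedROI",
    "FIRSTORDER_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
    "ALL_FEATURE_NAMES",
    "FAMILY_COUNTS",
    "discretize_fixed_bin_width",
    "discretize_roi",
    "first_order_features",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "gldm_matrix",
    "gldm_features",
    "ngtdm_features",
    "feature_vector",
    "extract_all",
]

# ---------------------------------------------------------------------------
# Canonical feature names (frozen in feature_manifest.json)
# ---------------------------------------------------------------------------

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)
GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

_FAMILIES = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}
FAMILY_COUNTS = {fam: len(names) for fam, names in _FAMILIES.items()}
ALL_FEATURE_NAMES = tuple(
    f"{fam}.{name}" for fam, names in _FAMILIES.items() for name in names
)

#: Guard value for NGTDM Coarseness on a perfectly uniform region.
COARSENESS_MAX = 1e6


def _check_manifest() -> None:
    """The shipped JSON manifest is the frozen contract; code must match it."""
    with resources.files("radstab").joinpath("feature_manifest.json").open() as fh:
        manifest = json.load(fh)
    for fam, names in _FAMILIES.items():
        if list(names) != manifest[fam]:
            raise RuntimeError(f"feature name drift in family {fam!r}")


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtractionSettings:
    """Knobs of the extractor. Defaults follow the standard protocol."""

    bin_width: float = 25.0
    distance: int = 1
    gldm_alpha: float = 0.0


@dataclass(frozen=True)
class DiscretizedROI:
    """ROI gray levels on the bounding-box grid.

    ``grid`` holds integer levels 1..Ng at in-ROI voxels and 0 outside
    the mask; ``mask`` marks in-ROI voxels. Level coordinates are thereby
    retained for the spatial texture matrices.
    """

    grid: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_width: float

    @property
    def levels(self) -> np.ndarray:
        """Flat vector of the in-ROI levels."""
        return self.grid[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize_fixed_bin_width(values, bin_width: float) -> np.ndarray:
    """Min-anchored fixed-bin-width quantization of HU values.

    ``level(x) = floor((x - min) / W) + 1``, clamped into the top bin so
    floating-point edge effects cannot create a spurious extra level.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty ROI")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = values.min()
    levels = np.floor((values - lo) / bin_width).astype(np.int64) + 1
    ng = int(np.floor((values.max() - lo) / bin_width)) + 1
    return np.minimum(levels, ng)


def discretize_roi(volume_voxels, mask, bin_width: float = 25.0) -> DiscretizedROI:
    """Discretize the masked voxels of a volume onto their bounding-box grid."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.shape(volume_voxels):
        raise ValueError("mask and volume shapes differ")
    if not mask.any():
        raise ValueError("cannot discretize an empty ROI")
    bbox = ndimage.find_objects(mask.astype(np.int8))[0]
    sub_mask = mask[bbox]
    sub_vals = np.asarray(volume_voxels, dtype=float)[bbox]
    levels = discretize_fixed_bin_width(sub_vals[sub_mask], bin_width)
    grid = np.zeros(sub_mask.shape, dtype=np.int64)
    grid[sub_mask] = levels
    return DiscretizedROI(grid, sub_mask, int(levels.max()), float(bin_width))


# ---------------------------------------------------------------------------
# First-order features
# ---------------------------------------------------------------------------

def first_order_features(values, voxel_volume: float = 1.0,
                         bin_width: float = 25.0) -> dict[str, float]:
    """The 18 first-order intensity features.

    Entropy and Uniformity are computed on the fixed-bin-width discretized
    histogram; all moments use biased (1/n) estimators. Skewness and
    Kurtosis of a constant ROI are defined as 0 (Kurtosis is the plain
    Pearson kurtosis, not excess kurtosis).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = x.mean()
    m2 = ((x - mean) ** 2).mean()
    m3 = ((x - mean) ** 3).mean()
    m4 = ((x - mean) ** 4).mean()
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    sub = x[(x >= p10) & (x <= p90)]
    levels = discretize_fixed_bin_width(x, bin_width)
    p = np.bincount(levels)[1:] / n
    p = p[p > 0]
    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": float(voxel_volume) * energy,
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(sub - sub.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": float(m2),
        "Uniformity": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# Shared helpers for the texture matrices
# ---------------------------------------------------------------------------

def _unique_directions_3d() -> list[tuple[int, int, int]]:
    """The 13 unique 3-D direction vectors (one from each +/- pair)."""
    dirs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) > (0, 0, 0):
                    dirs.append((dz, dy, dx))
    return dirs


def _all_neighbor_offsets() -> list[tuple[int, int, int]]:
    """All 26 offsets of the Chebyshev-1 neighbourhood."""
    return [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]


def _offset_slices(shape, offset):
    """Slices (a, b) such that arr[a] and arr[b] are shifted by ``offset``."""
    sl_a, sl_b = [], []
    for n, d in zip(shape, offset):
        if abs(d) > n - 1:
            return None
        sl_a.append(slice(max(0, -d), n - max(0, d)))
        sl_b.append(slice(max(0, d), n - max(0, -d)))
    return tuple(sl_a), tuple(sl_b)


def _plogp(p: np.ndarray) -> float:
    """-sum p log2 p over the strictly positive entries (0 log 0 = 0)."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(disc: DiscretizedROI, distance: int = 1,
                directions=None) -> list[np.ndarray]:
    """Symmetrized, normalized co-occurrence matrices, one per direction.

    Directions with no valid voxel pair in the ROI are dropped. A single
    in-ROI voxel yields no pairs at all; the degenerate one-level matrix
    ``[[1.0]]`` is returned so the feature set stays defined.
    """
    ng = disc.n_levels
    dirs = directions if directions is not None else _unique_directions_3d()
    mats = []
    for d in dirs:
        off = tuple(distance * c for c in d)
        sl = _offset_slices(disc.grid.shape, off)
        if sl is None:
            continue
        sl_a, sl_b = sl
        both = disc.mask[sl_a] & disc.mask[sl_b]
        la = disc.grid[sl_a][both]
        lb = disc.grid[sl_b][both]
        if la.size == 0:
            continue
        counts = np.zeros((ng, ng))
        np.add.at(counts, (la - 1, lb - 1), 1.0)
        counts = counts + counts.T  # symmetrize
        mats.append(counts / counts.sum())
    if not mats:
        mats = [np.ones((1, 1))]
    return mats


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    ux = float((i * px).sum())
    sigx2 = float(((i - ux) ** 2 * px).sum())

    # diagonal (|i-j|) and cross-diagonal (i+j) marginals
    k_diff = np.abs(ii - jj)
    p_diff = np.bincount(k_diff.ravel(), weights=p.ravel(), minlength=ng)
    kd = np.arange(ng)
    k_sum = ii + jj
    p_sum = np.bincount(k_sum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    ks = np.arange(2, 2 * ng + 1)

    da = float((kd * p_diff).sum())
    hxy = _plogp(p)
    hx = _plogp(px)
    pxpy = np.outer(px, px)
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    hxy2 = _plogp(pxpy)

    if sigx2 > 0:
        correlation = float(((ii * jj * p).sum() - ux * ux) / sigx2)
    else:
        correlation = 0.0  # flat region guard: no gray-level variance
    imc1 = (hxy - hxy1) / max(hx, hx) if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # MCC: sqrt of the second-largest eigenvalue of
    # Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) py(k)); 1 for a flat region.
    present = px > 0
    if present.sum() < 2:
        mcc = 1.0
    else:
        psub = p[np.ix_(present, present)]
        pxs = px[present]
        q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
        ev = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, ev[-2])))

    off_diag = k_diff > 0
    inv_var = float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum()) if off_diag.any() else 0.0

    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": ux,
        "ClusterProminence": float(((ii + jj - 2 * ux) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * ux) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * ux) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": _plogp(p_diff),
        "DifferenceVariance": float(((kd - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((ks * p_sum).sum()),
        "SumEntropy": _plogp(p_sum),
        "SumSquares": sigx2,
        "MCC": mcc,
    }


def glcm_features(matrices: list[np.ndarray]) -> dict[str, float]:
    """The 24 GLCM features, each averaged over the direction matrices."""
    per_dir = [_glcm_features_single(p) for p in matrices]
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrix(disc: DiscretizedROI, directions=None) -> list[np.ndarray]:
    """Run-length matrices R[level, run_length] per direction.

    A run is a maximal sequence of consecutive in-ROI voxels of equal
    gray level along the direction; out-of-ROI voxels break runs.
    """
    dirs = directions if directions is not None else _unique_directions_3d()
    ng = disc.n_levels
    grid, mask = disc.grid, disc.mask
    shape = grid.shape
    coords = np.argwhere(mask)
    mats = []
    for d in dirs:
        runs: dict[tuple[int, int], int] = {}
        max_len = 1
        for z, y, x in coords:
            pz, py_, px_ = z - d[0], y - d[1], x - d[2]
            pred_in = (
                0 <= pz < shape[0] and 0 <= py_ < shape[1] and 0 <= px_ < shape[2]
                and mask[pz, py_, px_]
            )
            lvl = grid[z, y, x]
            if pred_in and grid[pz, py_, px_] == lvl:
                continue  # not a run start
            length = 1
            nz_, ny_, nx_ = z + d[0], y + d[1], x + d[2]
            while (
                0 <= nz_ < shape[0] and 0 <= ny_ < shape[1] and 0 <= nx_ < shape[2]
                and mask[nz_, ny_, nx_] and grid[nz_, ny_, nx_] == lvl
            ):
                length += 1
                nz_, ny_, nx_ = nz_ + d[0], ny_ + d[1], nx_ + d[2]
            runs[(lvl, length)] = runs.get((lvl, length), 0) + 1
            max_len = max(max_len, length)
        r = np.zeros((ng, max_len))
        for (lvl, length), c in runs.items():
            r[lvl - 1, length - 1] = c
        mats.append(r)
    return mats


def _rlm_style_features(r: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared feature formulas for run-length-style matrices (GLRLM/GLSZM).

    ``r[i-1, j-1]`` counts runs (or zones) of level i and length (size) j.
    """
    total = r.sum()
    i = np.arange(1, r.shape[0] + 1, dtype=float)
    j = np.arange(1, r.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = r / total
    ri = r.sum(axis=1)
    rj = r.sum(axis=0)
    mu_i = float((np.arange(1, r.shape[0] + 1) * ri / total).sum())
    mu_j = float((np.arange(1, r.shape[1] + 1) * rj / total).sum())
    short, long_ = ("ShortRun", "LongRun") if kind == "run" else ("SmallArea", "LargeArea")
    size_nu = "RunLengthNonUniformity" if kind == "run" else "SizeZoneNonUniformity"
    var_j = "RunVariance" if kind == "run" else "ZoneVariance"
    ent = "RunEntropy" if kind == "run" else "ZoneEntropy"
    pct = "RunPercentage" if kind == "run" else "ZonePercentage"
    gl = "Run" if kind == "run" else "Zone"
    out = {
        f"{short}Emphasis": float((r / jj**2).sum() / total),
        f"{long_}Emphasis": float((r * jj**2).sum() / total),
        "GrayLevelNonUniformity": float((ri**2).sum() / total),
        "GrayLevelNonUniformityNormalized": float((ri**2).sum() / total**2),
        size_nu: float((rj**2).sum() / total),
        size_nu + "Normalized": float((rj**2).sum() / total**2),
        pct: float(total / n_voxels),
        "GrayLevelVariance": float((p * (ii - mu_i) ** 2).sum()),
        var_j: float((p * (jj - mu_j) ** 2).sum()),
        ent: _plogp(p.ravel()),
        f"LowGrayLevel{gl}Emphasis": float((r / ii**2).sum() / total),
        f"HighGrayLevel{gl}Emphasis": float((r * ii**2).sum() / total),
        f"{short}LowGrayLevelEmphasis": float((r / (ii**2 * jj**2)).sum() / total),
        f"{short}HighGrayLevelEmphasis": float((r * ii**2 / jj**2).sum() / total),
        f"{long_}LowGrayLevelEmphasis": float((r * jj**2 / ii**2).sum() / total),
        f"{long_}HighGrayLevelEmphasis": float((r * ii**2 * jj**2).sum() / total),
    }
    return out


def glrlm_features(matrices: list[np.ndarray], n_voxels: int) -> dict[str, float]:
    """The 16 GLRLM features, averaged over directions."""
    per_dir = []
    for r in matrices:
        f = _rlm_style_features(r, n_voxels, "run")
        per_dir.append({k: f[k] for k in GLRLM_NAMES})
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_matrix(disc: DiscretizedROI) -> np.ndarray:
    """Size-zone matrix S[level, zone_size] under 26-connectivity (single matrix)."""
    ng = disc.n_levels
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: list[tuple[int, int]] = []
    max_size = 1
    for lvl in range(1, ng + 1):
        sel = (disc.grid == lvl) & disc.mask
        if not sel.any():
            continue
        lab, n_zone = ndimage.label(sel, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        for sz in sizes:
            zones.append((lvl, int(sz)))
            max_size = max(max_size, int(sz))
    s = np.zeros((ng, max_size))
    for lvl, sz in zones:
        s[lvl - 1, sz - 1] += 1
    return s


def glszm_features(matrix: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 GLSZM features (zone analogues of the run-length family)."""
    f = _rlm_style_features(matrix, n_voxels, "zone")
    return {name: f[name] for name in GLSZM_NAMES}


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix(disc: DiscretizedROI, alpha: float = 0.0,
                distance: int = 1) -> np.ndarray:
    """Dependence matrix D[level, dependence].

    The dependence of a voxel is the number of its in-ROI Chebyshev-1
    neighbours whose gray level differs by at most ``alpha`` (the centre
    voxel itself is not counted, so a fully isolated voxel has
    dependence 0 and the columns index dependence values 0..26).
    """
    if distance != 1:
        raise NotImplementedError("GLDM is defined here for distance 1")
    grid, mask = disc.grid, disc.mask
    dep = np.zeros(grid.shape, dtype=np.int64)
    for off in _all_neighbor_offsets():
        sl = _offset_slices(grid.shape, off)
        if sl is None:
            continue
        sl_a, sl_b = sl
        ok = (
            mask[sl_a] & mask[sl_b]
            & (np.abs(grid[sl_a] - grid[sl_b]) <= alpha)
        )
        dep[sl_a] += ok
    deps = dep[mask]
    levels = grid[mask]
    d = np.zeros((disc.n_levels, int(deps.max()) + 1))
    np.add.at(d, (levels - 1, deps), 1.0)
    return d


def gldm_features(matrix: np.ndarray) -> dict[str, float]:
    """The 14 GLDM features.

    Columns of ``matrix`` index dependence counts d = 0..max; the feature
    formulas weight by j = d + 1 (equivalent to counting the centre voxel
    as dependent on itself), which keeps the small-dependence emphases
    finite at zero dependence.
    """
    total = matrix.sum()
    ng, nd = matrix.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nd + 1, dtype=float)  # dependence + 1
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = matrix / total
    ri = matrix.sum(axis=1)
    rj = matrix.sum(axis=0)
    mu_i = float((i * ri / total).sum())
    mu_j = float((j * rj / total).sum())
    return {
        "SmallDependenceEmphasis": float((matrix / jj**2).sum() / total),
        "LargeDependenceEmphasis": float((matrix * jj**2).sum() / total),
        "GrayLevelNonUniformity": float((ri**2).sum() / total),
        "DependenceNonUniformity": float((rj**2).sum() / total),
        "DependenceNonUniformityNormalized": float((rj**2).sum() / total**2),
        "GrayLevelVariance": float((p * (ii - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (jj - mu_j) ** 2).sum()),
        "DependenceEntropy": _plogp(p.ravel()),
        "LowGrayLevelEmphasis": float((matrix / ii**2).sum() / total),
        "HighGrayLevelEmphasis": float((matrix * ii**2).sum() / total),
        "SmallDependenceLowGrayLevelEmphasis":
            float((matrix / (ii**2 * jj**2)).sum() / total),
        "SmallDependenceHighGrayLevelEmphasis":
            float((matrix * ii**2 / jj**2).sum() / total),
        "LargeDependenceLowGrayLevelEmphasis":
            float((matrix * jj**2 / ii**2).sum() / total),
        "LargeDependenceHighGrayLevelEmphasis":
            float((matrix * ii**2 * jj**2).sum() / total),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_table(disc: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-level (n_i, p_i, s_i) of the neighbouring gray-tone difference matrix.

    ``s_i`` sums, over in-ROI voxels of level i, the absolute difference
    between i and the mean level of the voxel's valid (in-ROI) Chebyshev-1
    neighbours. Voxels without any valid neighbour are excluded.
    """
    grid, mask = disc.grid, disc.mask
    nb_sum = np.zeros(grid.shape, dtype=float)
    nb_cnt = np.zeros(grid.shape, dtype=np.int64)
    for off in _all_neighbor_offsets():
        sl = _offset_slices(grid.shape, off)
        if sl is None:
            continue
        sl_a, sl_b = sl
        ok = mask[sl_a] & mask[sl_b]
        nb_sum[sl_a] += np.where(ok, grid[sl_b], 0)
        nb_cnt[sl_a] += ok
    valid = mask & (nb_cnt > 0)
    levels = grid[valid]
    diffs = np.abs(levels - nb_sum[valid] / nb_cnt[valid])
    ng = disc.n_levels
    n_i = np.bincount(levels - 1, minlength=ng).astype(float)
    s_i = np.bincount(levels - 1, weights=diffs, minlength=ng)
    n_tot = n_i.sum()
    p_i = n_i / n_tot if n_tot > 0 else n_i
    return n_i, p_i, s_i


def ngtdm_features(disc: DiscretizedROI) -> dict[str, float]:
    """The 5 NGTDM features with the documented numerical guards.

    Coarseness of a perfectly uniform region (all s_i = 0) is capped at
    1e6; Contrast and Strength of such a region are 0, Busyness is 0 when
    only one gray level is present.
    """
    n_i, p_i, s_i = ngtdm_table(disc)
    nv = n_i.sum()
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, len(p_i) + 1, dtype=float)
    ps = float((p_i * s_i).sum())

    coarseness = 1.0 / ps if ps > 0 else COARSENESS_MAX
    coarseness = min(coarseness, COARSENESS_MAX)

    if ngp > 1:
        ip, pp, sp = i[present], p_i[present], s_i[present]
        di = ip[:, None] - ip[None, :]
        contrast = (
            float((pp[:, None] * pp[None, :] * di**2).sum()) / (ngp * (ngp - 1))
            * float(s_i.sum()) / nv
        )
        busy_den = float(np.abs(ip[:, None] * pp[:, None]
                                - ip[None, :] * pp[None, :]).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        complexity = float(
            (np.abs(di) * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
             / (pp[:, None] + pp[None, :])).sum()
        ) / nv
        s_sum = float(s_i.sum())
        strength = (
            float(((pp[:, None] + pp[None, :]) * di**2).sum()) / s_sum
            if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# Per-ROI extraction
# ---------------------------------------------------------------------------

def feature_vector(volume_voxels, mask, voxel_volume: float = 1.0,
                   settings: ExtractionSettings | None = None) -> dict[str, float]:
    """All 93 features of one ROI, keyed ``family.Name``."""
    s = settings or ExtractionSettings()
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(volume_voxels, dtype=float)[mask]
    if values.size == 0:
        raise ValueError("empty ROI")
    disc = discretize_roi(volume_voxels, mask, s.bin_width)
    out: dict[str, float] = {}
    for name, val in first_order_features(values, voxel_volume, s.bin_width).items():
        out[f"firstorder.{name}"] = val
    for name, val in glcm_features(glcm_matrix(disc, s.distance)).items():
        out[f"glcm.{name}"] = val
    for name, val in glrlm_features(glrlm_matrix(disc), disc.n_voxels).items():
        out[f"glrlm.{name}"] = val
    for name, val in glszm_features(glszm_matrix(disc), disc.n_voxels).items():
        out[f"glszm.{name}"] = val
    for name, val in gldm_features(gldm_matrix(disc, s.gldm_alpha)).items():
        out[f"gldm.{name}"] = val
    for name, val in ngtdm_features(disc).items():
        out[f"ngtdm.{name}"] = val
    if tuple(out) != ALL_FEATURE_NAMES:
        raise RuntimeError("feature set drifted from the 93-name contract")
    return out


def extract_all(volume, roi_set, settings: ExtractionSettings | None = None,
                provenance: dict | None = None) -> pd.DataFrame:
    """Extract all 93 features from every ROI of a volume.

    Returns a long-format table with columns ``feature, roi_id,
    tissue_class, value`` plus any provenance columns supplied (dose,
    reconstruction mode, repeat index). A failing ROI (empty or outside
    the volume) is logged and skipped; the run continues.
    """
    voxels = volume.voxels
    prov = provenance or {
        k: volume.provenance[k]
        for k in ("dose_mGy", "recon_mode", "repeat")
        if k in volume.provenance
    }
    if roi_set.labels.shape != voxels.shape:
        raise ValueError(
            f"mask shape {roi_set.labels.shape} != volume shape {voxels.shape}"
        )
    rows = []
    for roi_id in roi_set.roi_ids:
        mask = roi_set.labels == roi_id
        try:
            fv = feature_vector(voxels, mask, volume.voxel_volume, settings)
        except ValueError as exc:
            logger.warning("ROI %d skipped: %s", roi_id, exc)
            continue
        for feat, val in fv.items():
            rows.append({"feature": feat, "roi_id": roi_id,
                         "tissue_class": roi_set.class_of[roi_id],
                         "value": val, **prov})
    return pd.DataFrame(rows)


_check_manifest()
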