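"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately use naive loops (exhaustive pair
enumeration, line walking, flood fill, explicit ANOVA sums) so they stay
independent of the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

import radstab as r


@pytest.fixture(scope="session")
def ground_truth():
    return r.generate_ground_truth(seed=42)


@pytest.fixture(scope="session")
def small_feature_table():
    """Features from a tiny low-noise design, reused across pipeline tests."""
    design = r.AcquisitionDesign(doses=(1.0, 4.0), n_repeats=3,
                                 recon_modes=("FBP", "DLR"), master_seed=11)
    params = r.EmulatorParams(sigma_ref=5.0)
    return r.simulate_and_extract(design, params=params)


# ---------------------------------------------------------------------------
# Brute-force texture-matrix oracles
# ---------------------------------------------------------------------------

def _inside(shape, z, y, x):
    return 0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]


def brute_glcm(grid, mask, offset, ng):
    """Pair counts by exhaustive enumeration of ordered voxel pairs."""
    counts = np.zeros((ng, ng))
    shape = grid.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                for sgn in (+1, -1):
                    z2, y2, x2 = (z + sgn * offset[0], y + sgn * offset[1],
                                  x + sgn * offset[2])
                    if _inside(shape, z2, y2, x2) and mask[z2, y2, x2]:
                        counts[grid[z, y, x] - 1, grid[z2, y2, x2] - 1] += 1
    return counts


def brute_runs(grid, mask, direction, ng):
    """Run-length counts by walking every line voxel by voxel."""
    runs = {}
    shape = grid.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                pz, py, px = z - direction[0], y - direction[1], x - direction[2]
                if (_inside(shape, pz, py, px) and mask[pz, py, px]
                        and grid[pz, py, px] == grid[z, y, x]):
                    continue  # interior of a run
                lvl, length = grid[z, y, x], 1
                nz, ny, nx = z + direction[0], y + direction[1], x + direction[2]
                while (_inside(shape, nz, ny, nx) and mask[nz, ny, nx]
                        and grid[nz, ny, nx] == lvl):
                    length += 1
                    nz, ny, nx = (nz + direction[0], ny + direction[1],
                                  nx + direction[2])
                runs[(lvl, length)] = runs.get((lvl, length), 0) + 1
    max_len = max((l for (_, l) in runs), default=1)
    out = np.zeros((ng, max_len))
    for (lvl, length), c in runs.items():
        out[lvl - 1, length - 1] = c
    return out


def brute_zones(grid, mask, ng):
    """Connected zones (26-connectivity) by breadth-first flood fill."""
    shape = grid.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
               for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                lvl = grid[z, y, x]
                queue = [(z, y, x)]
                seen[z, y, x] = True
                size = 0
                while queue:
                    cz, cy, cx = queue.pop()
                    size += 1
                    for dz, dy, dx in offsets:
                        nz, ny, nx = cz + dz, cy + dy, cx + dx
                        if (_inside(shape, nz, ny, nx) and mask[nz, ny, nx]
                                and not seen[nz, ny, nx]
                                and grid[nz, ny, nx] == lvl):
                            seen[nz, ny, nx] = True
                            queue.append((nz, ny, nx))
                zones.append((lvl, size))
    max_size = max((s for (_, s) in zones), default=1)
    out = np.zeros((ng, max_size))
    for lvl, size in zones:
        out[lvl - 1, size - 1] += 1
    return out


def brute_gldm(grid, mask, alpha, ng):
    """Dependence counts by explicit neighbour loops."""
    shape = grid.shape
    entries = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                dep = 0
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if (dz, dy, dx) == (0, 0, 0):
                                continue
                            nz, ny, nx = z + dz, y + dy, x + dx
                            if (_inside(shape, nz, ny, nx) and mask[nz, ny, nx]
                                    and abs(grid[nz, ny, nx] - grid[z, y, x])
                                    <= alpha):
                                dep += 1
                entries.append((grid[z, y, x], dep))
    max_dep = max(d for (_, d) in entries)
    out = np.zeros((ng, max_dep + 1))
    for lvl, dep in entries:
        out[lvl - 1, dep] += 1
    return out


def brute_ngtdm(grid, mask, ng):
    """Per-level (n_i, s_i) by explicit neighbour averaging."""
    shape = grid.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                nbs = []
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if (dz, dy, dx) == (0, 0, 0):
                                continue
                            nz, ny, nx = z + dz, y + dy, x + dx
                            if _inside(shape, nz, ny, nx) and mask[nz, ny, nx]:
                                nbs.append(grid[nz, ny, nx])
                if not nbs:
                    continue
                lvl = grid[z, y, x]
                n_i[lvl - 1] += 1
                s_i[lvl - 1] += abs(lvl - float(np.mean(nbs)))
    return n_i, s_i


def brute_icc_3_1(m):
    """ICC(3,1) from explicit sum-of-squares loops."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.sum() / m.size
    ss_rows = sum(k * (m[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    bms = ss_rows / (n - 1)
    ems = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (bms - ems) / (bms + (k - 1) * ems)


def brute_occc(m):
    """OCCC as the weighted average of all pairwise CCCs."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    num = den = 0.0
    for j in range(k):
        for l in range(j + 1, k):
            x, y = m[:, j], m[:, l]
            sxy = ((x - x.mean()) * (y - y.mean())).mean()
            d = x.var() + y.var() + (x.mean() - y.mean()) ** 2
            num += (2 * sxy / d) * d  # pairwise CCC times its weight
            den += d
    return num / den


def random_toy_roi(rng, max_shape=(2, 6, 6), max_levels=4):
    """Random small discretized ROI (grid of levels + non-trivial mask)."""
    shape = tuple(int(rng.integers(1, m + 1)) for m in max_shape)
    grid = rng.integers(1, max_levels + 1, size=shape)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask.flat[rng.integers(mask.size)] = True
    grid = np.where(mask, grid, 0)
    # re-index levels so Ng equals the maximum present level
    present = np.unique(grid[mask])
    remap = {lvl: i + 1 for i, lvl in enumerate(present)}
    grid = np.vectorize(lambda v: remap.get(v, 0))(grid)
    from radstab.features import DiscretizedROI
    return DiscretizedROI(grid.astype(np.int64), mask, len(present), 25.0)
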