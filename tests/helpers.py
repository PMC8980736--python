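"""Independent brute-force oracles used to cross-check the library.

These deliberately avoid the code paths (and vectorized routines) they
verify: explicit Python loops for moments, per-atom scatter loops for
voxelization, and explicit sum formulas for correlation.
"""

from __future__ import annotations

import math


def brute_force_stats(values):
    """(mean, median, std, min, max, skew, excess kurtosis) via Σ loops."""
    n = len(values)
    mean = sum(values) / n
    ordered = sorted(values)
    if n % 2:
        median = ordered[n // 2]
    else:
        median = 0.5 * (ordered[n // 2 - 1] + ordered[n // 2])
    m2 = sum((x - mean) ** 2 for x in values) / n
    m3 = sum((x - mean) ** 3 for x in values) / n
    m4 = sum((x - mean) ** 4 for x in values) / n
    if m2 < 1e-12:
        std = skew = kurt = 0.0
    else:
        std = math.sqrt(m2)
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2 - 3.0
    return (mean, median, std, min(values), max(values), skew, kurt)


def brute_force_pearson(xs, ys):
    """Pearson r from the explicit Σ formula."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / math.sqrt(sxx * syy)


def brute_force_voxelize(atoms_xyz_elements, center, channel_of):
    """Scatter atoms into a 10x10x10x8 nested-list grid, one at a time."""
    grid = [[[[0] * 8 for _ in range(10)] for _ in range(10)]
            for _ in range(10)]
    for (x, y, z), element in atoms_xyz_elements:
        ix = math.floor((x - (center[0] - 10.0)) / 2.0)
        iy = math.floor((y - (center[1] - 10.0)) / 2.0)
        iz = math.floor((z - (center[2] - 10.0)) / 2.0)
        grid[ix][iy][iz][channel_of(element)] = 1
    for ix in range(10):
        for iy in range(10):
            for iz in range(10):
                occupied = any(grid[ix][iy][iz][c] for c in range(1, 8))
                grid[ix][iy][iz][0] = 0 if occupied else 1
    return grid


def pdb_line(serial, name, resname, chain, resseq, x, y, z,
             occ=1.0, element="", altloc=" ", record="ATOM"):
    """One fixed-column PDB coordinate record."""
    return (f"{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} "
            f"{chain:1s}{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {element:>2s}")
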