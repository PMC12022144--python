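"""EHH decay, integrated haplotype homozygosity, and cross-population
XP-EHH with genome-wide standardization.

EHH here is population-level (not allele-partitioned): at extension
distance x from a core site, EHH(x) = sum_h C(n_h, 2) / C(n, 2) where the
n_h are the multiplicities of distinct haplotype strings spanning the core
through x inclusive, over all n haplotypes.  The curve starts at (0, 1) by
convention and is evaluated at each successive site position.

iHH is the trapezoidal integral of EHH over genetic distance, left plus
right, each side truncated at the first site where EHH drops below the
truncation level (partial trapezoid to the linear-interpolated crossing).

XP-EHH(site) = ln(iHH_target / iHH_reference), z-scored over all defined
test sites genome-wide (single bin), with two-sided normal p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import PhasedPanel, ScoreTrack, standardize_scores

__all__ = ["EHHCurve", "ehh", "ihh", "xpehh", "xpehh_raw", "xpehh_genome"]


@dataclass
class EHHCurve:
    core_site_index: int
    direction: str  # "left" | "right"
    distances_cM: np.ndarray
    ehh_values: np.ndarray


def ehh(panel: PhasedPanel, core: int, direction: str) -> EHHCurve:
    """EHH decay curve from a core site in one direction.

    A core at the chromosome edge in the given direction yields a curve of
    length 1 (EHH = 1 at distance 0).
    """
    if panel.n_hap < 2:
        raise ValueError("EHH needs at least 2 haplotypes")
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    step = 1 if direction == "right" else -1
    H = panel.haplotypes
    cm = panel.positions_cM
    n = panel.n_hap
    denom = n * (n - 1) / 2.0
    # partition by the core allele first (strings include the core site)
    cluster = H[:, core].astype(np.int64)
    distances = [0.0]
    values = [1.0]
    j = core + step
    while 0 <= j < panel.n_sites:
        cluster = 2 * cluster + H[:, j]
        _, cluster, counts = np.unique(cluster, return_inverse=True, return_counts=True)
        ehh_val = float((counts * (counts - 1) / 2.0).sum() / denom)
        distances.append(abs(cm[j] - cm[core]))
        values.append(ehh_val)
        if ehh_val == 0.0:
            break
        j += step
    return EHHCurve(core, direction, np.array(distances), np.array(values))


def _integrate_truncated(dist: np.ndarray, val: np.ndarray, truncation: float) -> float:
    """Trapezoidal integral of an EHH curve, cut at the first crossing
    below ``truncation`` (partial trapezoid to the crossing point)."""
    total = 0.0
    for i in range(1, len(dist)):
        d0, d1 = dist[i - 1], dist[i]
        v0, v1 = val[i - 1], val[i]
        if v1 < truncation:
            if v0 > v1:
                x = d0 + (v0 - truncation) / (v0 - v1) * (d1 - d0)
                total += 0.5 * (v0 + truncation) * (x - d0)
            return total
        total += 0.5 * (v0 + v1) * (d1 - d0)
    return total


def ihh(panel: PhasedPanel, core: int, truncation: float = 0.05) -> float:
    """Integrated EHH (cM units), left + right, truncated at ``truncation``."""
    left = ehh(panel, core, "left")
    right = ehh(panel, core, "right")
    return _integrate_truncated(left.distances_cM, left.ehh_values, truncation) + (
        _integrate_truncated(right.distances_cM, right.ehh_values, truncation)
    )


@njit(cache=False)
def _ihh_side(H, cm, core, step, trunc):  # pragma: no cover - numba
    n, m = H.shape
    denom = n * (n - 1) / 2.0
    cluster = np.zeros(n, dtype=np.int64)
    # refine by core allele (curve still starts at value 1, distance 0)
    nc = 0
    newid = np.full(2, -1, dtype=np.int64)
    for h in range(n):
        a = H[h, core]
        if newid[a] < 0:
            newid[a] = nc
            nc += 1
        cluster[h] = newid[a]
    ehh_prev = 1.0
    d_prev = 0.0
    total = 0.0
    j = core + step
    while 0 <= j < m:
        counts = np.zeros(2 * nc, dtype=np.int64)
        for h in range(n):
            counts[2 * cluster[h] + H[h, j]] += 1
        ids = np.full(2 * nc, -1, dtype=np.int64)
        nc_new = 0
        num = 0.0
        for k in range(2 * nc):
            c = counts[k]
            if c > 0:
                ids[k] = nc_new
                nc_new += 1
                num += c * (c - 1) / 2.0
        for h in range(n):
            cluster[h] = ids[2 * cluster[h] + H[h, j]]
        nc = nc_new
        val = num / denom
        d = abs(cm[j] - cm[core])
        if val < trunc:
            if ehh_prev > val:
                x = d_prev + (ehh_prev - trunc) / (ehh_prev - val) * (d - d_prev)
                total += 0.5 * (ehh_prev + trunc) * (x - d_prev)
            return total
        total += 0.5 * (ehh_prev + val) * (d - d_prev)
        if val == 0.0:
            return total
        ehh_prev = val
        d_prev = d
        j += step
    return total


@njit(cache=False)
def _ihh_many(H, cm, cores, trunc):  # pragma: no cover - numba
    out = np.empty(cores.size, dtype=np.float64)
    for i in range(cores.size):
        c = cores[i]
        out[i] = _ihh_side(H, cm, c, -1, trunc) + _ihh_side(H, cm, c, 1, trunc)
    return out


def ihh_many(panel: PhasedPanel, cores, truncation: float = 0.05) -> np.ndarray:
    """Vectorised iHH at many core sites (numba fast path)."""
    cores = np.asarray(cores, dtype=np.int64)
    return _ihh_many(panel.haplotypes, panel.positions_cM, cores, float(truncation))


def xpehh_raw(
    panelA: PhasedPanel,
    panelB: PhasedPanel,
    test_sites,
    truncation: float = 0.05,
) -> np.ndarray:
    """Raw ln(iHH_A / iHH_B) at the given sites; NaN where either iHH = 0.

    Panels must share site coordinates (intersect/union beforehand).
    """
    if panelA.n_sites != panelB.n_sites or np.any(
        panelA.positions_bp != panelB.positions_bp
    ):
        raise ValueError("panels must share site coordinates")
    test_sites = np.asarray(test_sites, dtype=np.int64)
    iA = ihh_many(panelA, test_sites, truncation)
    iB = ihh_many(panelB, test_sites, truncation)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where((iA > 0) & (iB > 0), np.log(iA / iB), np.nan)
    return raw


def xpehh(
    panelA: PhasedPanel,
    panelB: PhasedPanel,
    test_sites,
    truncation: float = 0.05,
) -> ScoreTrack:
    """XP-EHH track for one chromosome, standardized over its defined sites."""
    return xpehh_genome([(panelA, panelB, test_sites)], truncation)


def xpehh_genome(pairs, truncation: float = 0.05) -> ScoreTrack:
    """XP-EHH across chromosomes with genome-wide (single-bin) standardization.

    ``pairs`` is a list of ``(panelA, panelB, test_sites)`` triples, one per
    chromosome.
    """
    chroms, positions, raws = [], [], []
    for panelA, panelB, test_sites in pairs:
        test_sites = np.asarray(test_sites, dtype=np.int64)
        raw = xpehh_raw(panelA, panelB, test_sites, truncation)
        raws.append(raw)
        positions.append(panelA.positions_bp[test_sites])
        chroms.append(np.full(test_sites.size, panelA.chrom, dtype=object))
    raw = np.concatenate(raws) if raws else np.zeros(0)
    z, p = standardize_scores(raw)
    return ScoreTrack(
        np.concatenate(chroms) if chroms else np.zeros(0, dtype=object),
        np.concatenate(positions) if positions else np.zeros(0, dtype=np.int64),
        raw,
        z,
        p,
        method="XPEHH",
    )
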