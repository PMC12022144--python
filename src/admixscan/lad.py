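"""Local ancestry deviation (LAD) scan.

For an ancestry k, the per-site proportion track p_j is the fraction of
haplotypes assigned k at site j.  The genome-wide baseline (mean and SD of
p_j across all sites of all supplied chromosomes) defines z-scores; maximal
contiguous runs of sites beyond ``threshold_sd`` standard deviations are
reported as deviated regions, labelled by direction (excess/deficit).  A
deviated region coinciding with a selection peak is a post-admixture
selection candidate.

Named threshold presets: strict 4.42 SD (no false regions expected
genome-wide) and lenient 3 SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AncestryMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "STRICT_SD",
    "LENIENT_SD",
    "ancestry_proportion",
    "ProportionTrack",
    "lad_scan",
    "lad_peak_overlap",
]

STRICT_SD = 4.42
LENIENT_SD = 3.0


def ancestry_proportion(matrix: AncestryMatrix, ancestry) -> np.ndarray:
    """Per-site proportion of haplotypes carrying the given ancestry
    (an integer code or a label)."""
    if isinstance(ancestry, str):
        if ancestry not in matrix.labels:
            raise ValueError(f"unknown ancestry label {ancestry!r}")
        ancestry = matrix.labels.index(ancestry)
    if not (0 <= int(ancestry) < matrix.K):
        raise ValueError(f"unknown ancestry code {ancestry}")
    if matrix.n_hap < 1:
        raise ValueError("need at least one haplotype")
    return (matrix.codes == int(ancestry)).mean(axis=0)


@dataclass
class ProportionTrack:
    """One chromosome's ancestry-proportion track."""

    chrom: str
    positions_bp: np.ndarray
    proportion: np.ndarray
    ancestry: str = "ANC"


def lad_scan(
    tracks: list[ProportionTrack] | ProportionTrack,
    threshold_sd: float = STRICT_SD,
    gap_sites: int = 0,
    baseline: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Scan proportion tracks for local ancestry deviations.

    The baseline mean/SD is computed across the sites of *all* supplied
    tracks (the genome-wide mean LAD) unless given explicitly.  Runs
    separated by at most ``gap_sites`` sub-threshold sites are merged.

    Returns a DataFrame with columns ``chrom, start, end, ancestry,
    direction, peak_proportion, peak_z, n_sites`` (0-based half-open bp
    intervals; ``end`` is one past the last deviated site's position).
    """
    if isinstance(tracks, ProportionTrack):
        tracks = [tracks]
    allp = np.concatenate([t.proportion for t in tracks])
    if baseline is None:
        mean, sd = float(allp.mean()), float(allp.std())
    else:
        mean, sd = baseline
    cols = [
        "chrom", "start", "end", "ancestry", "direction",
        "peak_proportion", "peak_z", "n_sites",
    ]
    if sd == 0:
        logger.warning("lad_scan: constant track (zero SD); no regions")
        return pd.DataFrame(columns=cols)
    rows = []
    for t in tracks:
        z = (t.proportion - mean) / sd
        for direction, mask in (
            ("excess", z > threshold_sd),
            ("deficit", z < -threshold_sd),
        ):
            for a, b in _runs(mask, gap_sites):
                zz = z[a:b]
                j = a + int(np.argmax(np.abs(zz)))
                rows.append(
                    {
                        "chrom": t.chrom,
                        "start": int(t.positions_bp[a]),
                        "end": int(t.positions_bp[b - 1]) + 1,
                        "ancestry": t.ancestry,
                        "direction": direction,
                        "peak_proportion": float(t.proportion[j]),
                        "peak_z": float(z[j]),
                        "n_sites": int(b - a),
                    }
                )
    return pd.DataFrame(rows, columns=cols)


def _runs(mask: np.ndarray, gap_sites: int):
    """Maximal runs of True, merging runs separated by <= gap_sites False."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > gap_sites + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[a]), int(idx[b]) + 1) for a, b in zip(starts, ends)]


def lad_peak_overlap(lad_regions: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Intersect LAD regions with selection peaks: the post-admixture
    selection candidate table.

    One row per (LAD region, peak) pair with >= 1 bp overlap, carrying the
    ancestry label, deviation direction and the peak's method tag.
    """
    cols = [
        "chrom", "start", "end", "ancestry", "direction", "peak_z",
        "method", "peak_start", "peak_end", "summit_pos",
    ]
    rows = []
    for _, r in lad_regions.iterrows():
        for _, p in peaks.iterrows():
            if str(r["chrom"]) != str(p["chrom"]):
                continue
            lo = max(int(r["start"]), int(p["start"]))
            hi = min(int(r["end"]), int(p["end"]))
            if hi - lo >= 1:
                rows.append(
                    {
                        "chrom": r["chrom"],
                        "start": lo,
                        "end": hi,
                        "ancestry": r["ancestry"],
                        "direction": r["direction"],
                        "peak_z": r["peak_z"],
                        "method": p["method"],
                        "peak_start": int(p["start"]),
                        "peak_end": int(p["end"]),
                        "summit_pos": int(p["summit_pos"]),
                    }
                )
    return pd.DataFrame(rows, columns=cols)
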