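"""Quantile + support-count peak calling on standardized score tracks.

A candidate SNP lies at or above the primary empirical quantile of the
genome-wide standardized scores (99.99% by default).  It is confirmed when
the window of ``window_bp`` centred on it holds at least ``min_support``
*other* SNPs at or above the support quantile (99.995% by default — higher
than the primary threshold, as specified).  Confirmed candidates' windows
are merged by union into peaks; the summit is the max-scoring SNP of each
peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ScoreTrack

logger = logging.getLogger(__name__)

__all__ = ["PeakCallingConfig", "DESK_SCALE_PEAKS", "call_peaks", "overlap"]


@dataclass
class PeakCallingConfig:
    primary_quantile: float = 0.9999
    support_quantile: float = 0.99995
    window_bp: int = 1_000_000
    min_support: int = 10
    score_side: str = "upper"  # "upper" | "two-sided"
    count_candidate_as_support: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.primary_quantile < 1.0 and 0.0 < self.support_quantile < 1.0):
            raise ValueError("quantiles must lie in (0, 1)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.min_support < 0:
            raise ValueError("min_support must be >= 0")
        if self.score_side not in ("upper", "two-sided"):
            raise ValueError("score_side must be 'upper' or 'two-sided'")


# Preset for scaled-down synthetic genomes (10^3-10^4 test SNPs): the
# standard quantiles leave fewer supporting SNPs genome-wide than
# min_support, so no peak could ever be confirmed at that track size.
DESK_SCALE_PEAKS = PeakCallingConfig(
    primary_quantile=0.99, support_quantile=0.995, window_bp=1_000_000, min_support=5
)


def call_peaks(track: ScoreTrack, config: PeakCallingConfig | None = None) -> pd.DataFrame:
    """Call selection peaks from a standardized track.

    Returns a DataFrame with columns ``chrom, start, end, summit_pos,
    summit_score, n_support, method`` (intervals 0-based half-open,
    non-overlapping within a chromosome).
    """
    if config is None:
        config = PeakCallingConfig()
    defined = track.defined
    scores = track.standardized[defined]
    if scores.size == 0:
        return _empty_peaks(track.method)
    if config.score_side == "two-sided":
        scores = np.abs(scores)
    n_min = 1.0 / (1.0 - config.primary_quantile)
    if scores.size < n_min:
        logger.warning(
            "call_peaks: %d defined sites < 1/(1-primary_quantile) = %.0f; "
            "thresholds are unstable",
            scores.size,
            n_min,
        )
    thr_primary = np.quantile(scores, config.primary_quantile)  # type-7 linear
    thr_support = np.quantile(scores, config.support_quantile)
    chroms = track.chrom[defined]
    pos = track.position_bp[defined]
    rows = []
    half = config.window_bp // 2
    for chrom in pd.unique(chroms):
        csel = chroms == chrom
        cpos = pos[csel]
        cscore = scores[csel]
        order = np.argsort(cpos, kind="stable")
        cpos, cscore = cpos[order], cscore[order]
        cand = np.flatnonzero(cscore >= thr_primary)
        sup_mask = cscore >= thr_support
        sup_pos = cpos[sup_mask]
        confirmed = []
        for i in cand:
            lo, hi = cpos[i] - half, cpos[i] + half
            n_sup = int(
                np.searchsorted(sup_pos, hi, side="right")
                - np.searchsorted(sup_pos, lo, side="left")
            )
            if not config.count_candidate_as_support and sup_mask[i]:
                n_sup -= 1  # "additional" variants exclude the candidate itself
            if n_sup >= config.min_support:
                confirmed.append((i, n_sup))
        # merge windows of confirmed candidates
        merged: list[list] = []
        for i, n_sup in confirmed:
            lo, hi = int(cpos[i] - half), int(cpos[i] + half)
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
                merged[-1][2].append(i)
                merged[-1][3] = max(merged[-1][3], n_sup)
            else:
                merged.append([lo, hi, [i], n_sup])
        for lo, hi, members, _ in merged:
            inside = (cpos >= lo) & (cpos < hi)
            j = np.flatnonzero(inside)[np.argmax(cscore[inside])]
            n_sup_peak = int(
                np.searchsorted(sup_pos, hi, side="right")
                - np.searchsorted(sup_pos, lo, side="left")
            )
            rows.append(
                {
                    "chrom": chrom,
                    "start": max(lo, 0),
                    "end": hi,
                    "summit_pos": int(cpos[j]),
                    "summit_score": float(cscore[j]),
                    "n_support": n_sup_peak,
                    "method": track.method,
                }
            )
    if not rows:
        return _empty_peaks(track.method)
    return pd.DataFrame(rows)


def _empty_peaks(method: str) -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "summit_pos", "summit_score", "n_support", "method"]
    ).astype({"start": np.int64, "end": np.int64})


def overlap(peaks: pd.DataFrame, regions) -> pd.DataFrame:
    """Pairs of (peak, region) with >= 1 bp intersection (half-open).

    ``regions`` is a DataFrame with ``chrom, start, end`` columns or an
    iterable of ``(chrom, start, end)`` tuples.
    """
    if not isinstance(regions, pd.DataFrame):
        regions = pd.DataFrame(list(regions), columns=["chrom", "start", "end"])
    rows = []
    for pi, p in peaks.iterrows():
        for ri, r in regions.iterrows():
            if str(p["chrom"]) != str(r["chrom"]):
                continue
            lo = max(int(p["start"]), int(r["start"]))
            hi = min(int(p["end"]), int(r["end"]))
            if hi - lo >= 1:
                rows.append(
                    {
                        "chrom": p["chrom"],
                        "peak_start": int(p["start"]),
                        "peak_end": int(p["end"]),
                        "region_start": int(r["start"]),
                        "region_end": int(r["end"]),
                        "overlap_start": lo,
                        "overlap_end": hi,
                        "overlap_bp": hi - lo,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "peak_start",
            "peak_end",
            "region_start",
            "region_end",
            "overlap_start",
            "overlap_end",
            "overlap_bp",
        ],
    )


def peaks_to_bed(peaks: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, p in peaks.iterrows():
            fh.write(
                f"{p['chrom']}\t{int(p['start'])}\t{int(p['end'])}\t"
                f"{p['method']}_summit@{int(p['summit_pos'])}\t{p['summit_score']:.4f}\n"
            )
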