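"""Core in-memory containers shared across the scan modules.

Conventions
-----------
* Alleles are polarized: ``0`` = ancestral, ``1`` = derived.
* Coordinates are 0-based, half-open internally.  VCF (1-based) and BED
  (0-based half-open) are converted at the I/O boundary.
* Haplotypes ``2*i`` and ``2*i + 1`` belong to diploid individual ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhasedPanel",
    "build_site_table",
    "ScoreTrack",
    "AncestryMatrix",
]


@dataclass
class PhasedPanel:
    """Phased haplotype alleles for one chromosome.

    Parameters
    ----------
    haplotypes
        ``(n_hap, n_sites)`` matrix of 0/1 allele codes (0 = ancestral,
        1 = derived).  ``n_hap`` must be even: haplotype rows ``2i`` and
        ``2i+1`` form diploid individual ``i``.
    positions_bp
        Strictly increasing physical positions.
    positions_cM
        Genetic-map positions aligned 1:1 with ``positions_bp``
        (non-decreasing).
    """

    haplotypes: np.ndarray
    positions_bp: np.ndarray
    positions_cM: np.ndarray
    chrom: str = "1"
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.positions_cM = np.asarray(self.positions_cM, dtype=np.float64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D (n_hap, n_sites) matrix")
        n_hap, n_sites = self.haplotypes.shape
        if n_hap % 2 != 0:
            raise ValueError(f"n_hap must be even (diploid pairing); got {n_hap}")
        if self.positions_bp.shape != (n_sites,):
            raise ValueError("positions_bp length does not match site count")
        if self.positions_cM.shape != (n_sites,):
            raise ValueError("positions_cM length does not match site count")
        if n_sites > 1:
            if np.any(np.diff(self.positions_bp) <= 0):
                raise ValueError("positions_bp must be strictly increasing")
            if np.any(np.diff(self.positions_cM) < 0):
                raise ValueError("positions_cM must be non-decreasing")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("alleles must be 0/1")
        if self.sample_ids is None:
            self.sample_ids = [f"ind{i}" for i in range(n_hap // 2)]
        if len(self.sample_ids) != n_hap // 2:
            raise ValueError("sample_ids length must equal n_hap/2")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_diploids(self) -> int:
        return self.n_hap // 2

    def dosages(self) -> np.ndarray:
        """Per-individual derived-allele dosage matrix ``(n_diploids, n_sites)``."""
        h = self.haplotypes
        return h[0::2].astype(np.int16) + h[1::2].astype(np.int16)

    def derived_counts(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0, dtype=np.int64)


def build_site_table(
    panel: PhasedPanel,
    ancestral_alleles: np.ndarray | None = None,
    derived_alleles: np.ndarray | None = None,
) -> pd.DataFrame:
    """Build the per-site metadata table for a polarized panel.

    Columns: ``position_bp, ancestral, derived, derived_count, derived_freq,
    n_hom_anc, n_het, n_hom_der, is_singleton, singleton_owner,
    in_excluded_region``.

    ``singleton_owner`` is the diploid index of the (single) carrier for
    derived-count-1 sites, and ``-1`` elsewhere.
    """
    n_hap = panel.n_hap
    dc = panel.derived_counts()
    dos = panel.dosages()
    n_hom_anc = (dos == 0).sum(axis=0)
    n_het = (dos == 1).sum(axis=0)
    n_hom_der = (dos == 2).sum(axis=0)
    is_singleton = dc == 1
    owner = np.full(panel.n_sites, -1, dtype=np.int64)
    if is_singleton.any():
        cols = np.flatnonzero(is_singleton)
        hap_idx = np.argmax(panel.haplotypes[:, cols], axis=0)
        owner[cols] = hap_idx // 2
    if ancestral_alleles is None:
        ancestral_alleles = np.full(panel.n_sites, "A", dtype=object)
    if derived_alleles is None:
        derived_alleles = np.full(panel.n_sites, "G", dtype=object)
    return pd.DataFrame(
        {
            "position_bp": panel.positions_bp,
            "ancestral": ancestral_alleles,
            "derived": derived_alleles,
            "derived_count": dc,
            "derived_freq": dc / n_hap if n_hap else np.nan,
            "n_hom_anc": n_hom_anc,
            "n_het": n_het,
            "n_hom_der": n_hom_der,
            "is_singleton": is_singleton,
            "singleton_owner": owner,
            "in_excluded_region": np.zeros(panel.n_sites, dtype=bool),
        }
    )


@dataclass
class ScoreTrack:
    """Per-test-SNP statistic values for one scan method (SDS or XP-EHH).

    ``raw`` is NaN at undefined sites; ``standardized``/``pvalue`` are
    defined wherever ``raw`` is.
    """

    chrom: np.ndarray
    position_bp: np.ndarray
    raw: np.ndarray
    standardized: np.ndarray
    pvalue: np.ndarray
    method: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.raw = np.asarray(self.raw, dtype=np.float64)
        self.standardized = np.asarray(self.standardized, dtype=np.float64)
        self.pvalue = np.asarray(self.pvalue, dtype=np.float64)
        n = len(self.position_bp)
        for name in ("chrom", "raw", "standardized", "pvalue"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.raw)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.position_bp,
                "raw": self.raw,
                "standardized": self.standardized,
                "pvalue": self.pvalue,
            }
        )
        df["neglog10_p"] = -np.log10(df["pvalue"])
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")


def standardize_scores(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Genome-wide z-scores and two-sided normal p-values for a raw track.

    NaN entries stay NaN.  Raises if fewer than 2 defined values or if the
    defined values are degenerate (zero spread).
    """
    raw = np.asarray(raw, dtype=np.float64)
    ok = ~np.isnan(raw)
    if ok.sum() < 2:
        raise ValueError("standardization requires >= 2 defined sites")
    mu = raw[ok].mean()
    sd = raw[ok].std()
    if sd == 0:
        raise ValueError("degenerate track: zero standard deviation")
    z = (raw - mu) / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    # two-sided p lies in (0, 1]; clip the underflow end only
    p = np.where(ok, np.clip(p, np.finfo(float).tiny, 1.0), np.nan)
    return z, p


@dataclass
class AncestryMatrix:
    """Per-haplotype, per-site integer ancestry assignments.

    ``codes`` is ``(n_hap, n_sites)`` with values in ``0..K-1``; ``labels``
    names the K ancestries.
    """

    codes: np.ndarray
    labels: list[str]
    positions_bp: np.ndarray
    chrom: str = "1"
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.codes = np.ascontiguousarray(self.codes, dtype=np.int16)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (n_hap, n_sites)")
        if self.positions_bp.shape != (self.codes.shape[1],):
            raise ValueError("positions_bp length does not match site count")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= len(self.labels)):
            raise ValueError("ancestry codes must lie in 0..K-1")
        if self.sample_ids is None:
            self.sample_ids = [f"ind{i}" for i in range(self.codes.shape[0] // 2)]

    @property
    def n_hap(self) -> int:
        return self.codes.shape[0]

    @property
    def K(self) -> int:
        return len(self.labels)
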