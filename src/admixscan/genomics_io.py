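"""Readers/writers for the standard formats the pipeline touches, and the
site filters that produce analysis-ready panels.

Internally everything is 0-based half-open; VCF (1-based) and BED (0-based
half-open) are converted at this boundary.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import AncestryMatrix, PhasedPanel, build_site_table

logger = logging.getLogger(__name__)

__all__ = [
    "read_phased_vcf",
    "select_test_snps",
    "GeneticMap",
    "read_ancestry_table",
    "read_bed",
]


def read_phased_vcf(path, ancestral_source: str = "AA", genetic_map=None):
    """Read a phased diploid VCF into a polarized panel + site table.

    Parameters
    ----------
    ancestral_source
        ``"AA"`` to take the ancestral allele from the INFO/AA tag, or a
        path to an ancestral FASTA (the base at each site's position).
    genetic_map
        Optional :class:`GeneticMap`; without it positions_cM default to
        1 cM/Mb (logged).

    Only biallelic SNPs are kept (indels/multiallelics dropped); alleles
    are recoded so 1 = derived.  Sites whose ancestral state is unknown or
    matches neither allele are dropped and counted in the log.  Sites with
    any missing genotype are dropped (logged).  Unphased genotypes raise.
    """
    from cyvcf2 import VCF

    fasta = None
    if ancestral_source != "AA":
        from pyfaidx import Fasta

        fasta = Fasta(str(ancestral_source))

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, positions, anc_list, der_list = [], [], [], []
    n_drop_nonsnp = n_drop_aa = n_drop_missing = 0
    chrom = None
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            n_drop_nonsnp += 1
            continue
        chrom = var.CHROM
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if fasta is not None:
            aa = str(fasta[var.CHROM][var.POS - 1]).upper()
        else:
            aa = var.INFO.get("AA")
            aa = aa.upper() if isinstance(aa, str) else None
        if aa not in (ref, alt):
            n_drop_aa += 1
            continue
        gt = var.genotype.array()  # (n_samples, 3): a0, a1, phased flag
        alleles = gt[:, :2]
        if (alleles < 0).any():
            n_drop_missing += 1
            continue
        unphased = np.flatnonzero(gt[:, 2] == 0)
        if unphased.size:
            raise ValueError(
                f"unphased genotype at {var.CHROM}:{var.POS} "
                f"sample {samples[unphased[0]]}"
            )
        hap = alleles.reshape(-1).astype(np.uint8)
        if aa == alt:  # polarization flip: ALT is ancestral
            hap = 1 - hap
            anc_list.append(alt)
            der_list.append(ref)
        else:
            anc_list.append(ref)
            der_list.append(alt)
        rows.append(hap)
        positions.append(var.POS - 1)  # to 0-based
    vcf.close()
    if n_drop_nonsnp or n_drop_aa or n_drop_missing:
        logger.info(
            "read_phased_vcf: dropped %d non-biallelic-SNP, %d unknown-ancestral, "
            "%d missing-genotype sites",
            n_drop_nonsnp,
            n_drop_aa,
            n_drop_missing,
        )
    if not rows:
        raise ValueError(f"no usable biallelic phased SNPs in {path}")
    H = np.array(rows, dtype=np.uint8).T
    pos = np.array(positions, dtype=np.int64)
    if genetic_map is not None:
        cm = genetic_map(pos)
    else:
        logger.info("no genetic map supplied; assuming uniform 1 cM/Mb")
        cm = pos / 1e6
    panel = PhasedPanel(H, pos, cm, chrom=chrom or "1", sample_ids=samples)
    sites = build_site_table(
        panel, np.array(anc_list, dtype=object), np.array(der_list, dtype=object)
    )
    return panel, sites


def select_test_snps(
    site_table: pd.DataFrame,
    maf_min: float = 0.05,
    maf_max: float = 0.95,
    excluded=None,
) -> np.ndarray:
    """Indices of sites usable as test SNPs.

    Keeps sites with ``maf_min <= MAF <= maf_max`` (MAF = min(f, 1-f) of the
    derived frequency), all three diploid genotype classes present, and
    position outside ``excluded`` intervals (0-based half-open
    ``(start, end)`` pairs or a BED-derived list).  Singletons can never
    qualify (derived count 1 fails the genotype-class rule) but remain in
    the site table for the singleton-density scorer.
    """
    f = site_table["derived_freq"].to_numpy()
    maf = np.minimum(f, 1.0 - f)
    ok = (maf >= maf_min) & (maf <= maf_max)
    ok &= (
        (site_table["n_hom_anc"].to_numpy() > 0)
        & (site_table["n_het"].to_numpy() > 0)
        & (site_table["n_hom_der"].to_numpy() > 0)
    )
    if "in_excluded_region" in site_table:
        ok &= ~site_table["in_excluded_region"].to_numpy()
    if excluded:
        pos = site_table["position_bp"].to_numpy()
        inside = np.zeros(len(pos), dtype=bool)
        for iv in excluded:
            # accept (start, end) or (chrom, start, end)
            start, end = (int(iv[1]), int(iv[2])) if len(iv) > 2 else (int(iv[0]), int(iv[1]))
            inside |= (pos >= start) & (pos < end)
        ok &= ~inside
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        logger.warning("select_test_snps: no sites pass the filters")
    return idx


class GeneticMap:
    """Monotone bp -> cM interpolator.

    Linear between map points; beyond the ends, extrapolates with the
    terminal cM/Mb slope.
    """

    def __init__(self, positions_bp, positions_cM):
        self.bp = np.asarray(positions_bp, dtype=np.float64)
        self.cM = np.asarray(positions_cM, dtype=np.float64)
        if self.bp.size < 2:
            raise ValueError("genetic map needs at least two points")
        if np.any(np.diff(self.bp) <= 0) or np.any(np.diff(self.cM) < 0):
            raise ValueError("genetic map must be monotone in bp and cM")

    @classmethod
    def from_plink(cls, path) -> "GeneticMap":
        """Read a PLINK ``.map``-style file: chrom, id, cM, bp."""
        tab = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
        return cls(tab.iloc[:, 3].to_numpy(), tab.iloc[:, 2].to_numpy())

    @classmethod
    def uniform(cls, rate_cM_per_Mb: float = 1.0, length_bp: float = 1e9) -> "GeneticMap":
        return cls([0.0, length_bp], [0.0, rate_cM_per_Mb * length_bp / 1e6])

    def __call__(self, positions_bp) -> np.ndarray:
        x = np.asarray(positions_bp, dtype=np.float64)
        out = np.interp(x, self.bp, self.cM)
        lo_slope = (self.cM[1] - self.cM[0]) / (self.bp[1] - self.bp[0])
        hi_slope = (self.cM[-1] - self.cM[-2]) / (self.bp[-1] - self.bp[-2])
        below = x < self.bp[0]
        above = x > self.bp[-1]
        if np.any(below):
            out = np.where(below, self.cM[0] + (x - self.bp[0]) * lo_slope, out)
        if np.any(above):
            out = np.where(above, self.cM[-1] + (x - self.bp[-1]) * hi_slope, out)
        return out if out.ndim else float(out)


def read_ancestry_table(path, positions_bp: np.ndarray | None = None) -> AncestryMatrix:
    """Read an RFmix ``.msp.tsv``-style table into a per-site ancestry matrix.

    Windows must tile the covered span without gaps or overlaps (half-open
    bp bounds).  When ``positions_bp`` is given, assignments are expanded
    onto that site grid (each site takes its containing window's label);
    otherwise one pseudo-site per window start is emitted.
    """
    with open(path) as fh:
        header1 = fh.readline().strip()
        header2 = fh.readline().strip()
    if not header1.startswith("#Subpopulation order/codes:"):
        raise ValueError("missing '#Subpopulation order/codes' header")
    codes_part = header1.split(":", 1)[1].strip()
    labels_by_code: dict[int, str] = {}
    for tok in codes_part.replace("\t", " ").split():
        lab, code = tok.rsplit("=", 1)
        labels_by_code[int(code)] = lab
    K = max(labels_by_code) + 1
    labels = [labels_by_code.get(k, f"ANC{k}") for k in range(K)]
    cols = header2.lstrip("#").split("\t")
    tab = pd.read_csv(path, sep="\t", skiprows=2, header=None, names=cols)
    chrom = str(tab.iloc[0, 0])
    spos = tab["spos"].to_numpy(dtype=np.int64)
    epos = tab["epos"].to_numpy(dtype=np.int64)
    bad = np.flatnonzero(spos[1:] != epos[:-1])
    if bad.size:
        raise ValueError(
            f"ancestry windows have gaps/overlaps at rows {list(bad + 1)} "
            f"(spos != previous epos)"
        )
    hap_cols = cols[6:]
    codes = tab[hap_cols].to_numpy(dtype=np.int64).T  # (n_hap, n_windows)
    if codes.size and (codes.min() < 0 or codes.max() >= K):
        raise ValueError("unknown ancestry code in table body")
    sample_ids = []
    for name in hap_cols[0::2]:
        sample_ids.append(name.rsplit(".", 1)[0])
    if positions_bp is None:
        positions_bp = spos
        site_codes = codes
    else:
        positions_bp = np.asarray(positions_bp, dtype=np.int64)
        win = np.searchsorted(spos, positions_bp, side="right") - 1
        if (win < 0).any() or (positions_bp >= epos[win]).any():
            raise ValueError("site positions fall outside the windows")
        site_codes = codes[:, win]
    return AncestryMatrix(
        site_codes.astype(np.int16), labels, positions_bp, chrom=chrom,
        sample_ids=sample_ids,
    )


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read BED intervals as (chrom, start, end), 0-based half-open."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
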