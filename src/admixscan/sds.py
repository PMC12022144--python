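"""Singleton density score (SDS): a per-test-SNP statistic for very recent
positive selection.

A rapid rise of the derived allele shortens the genealogical "tips" of the
haplotypes carrying it; singleton variants accrue on tips, so derived
carriers show a locally depleted singleton density (longer distances to
their nearest own singleton).

Model
-----
For each diploid individual the nearest singleton *owned by that
individual* strictly left and strictly right of the test SNP gives two
distances.  Each haplotype carries a tip-length scale t (t_A for ancestral,
t_D for derived tips) and its singletons form a Poisson process with rate
``lambda * t`` per bp, so the per-side nearest distance for an individual
with tips (t1, t2) is Exponential with rate ``lambda * (t1 + t2)`` (the sum
of the two distances is then Gamma with shape 2, replaceable by a
configured gamma-shape table per DAF bin and genotype).  Sides without a
singleton before the analysis boundary contribute censored survival terms.

The likelihood is profiled over the log tip-length ratio
``r = log(t_A / t_D)`` under the frequency-anchoring constraint
``f * t_D + (1 - f) * t_A = 1``, with the baseline rate ``lambda``
calibrated from the genome-wide mean nearest-singleton distance in the
site's DAF bin.  r > 0 means shorter derived tips, i.e. a rising derived
allele.  Raw scores are standardized within DAF bins of 0.05-0.95 in 0.01
steps and two-sided normal p-values are attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import PhasedPanel, ScoreTrack

logger = logging.getLogger(__name__)

__all__ = [
    "SingletonDistances",
    "TipModel",
    "SDSNormalization",
    "collect_singleton_distances",
    "raw_sds",
    "sds_track",
    "normalize_sds",
]

SDS_BIN_LO = 0.05
SDS_BIN_HI = 0.95
SDS_BIN_STEP = 0.01


@dataclass
class SingletonDistances:
    """Per-individual nearest-own-singleton distances around one test SNP."""

    left_bp: np.ndarray
    right_bp: np.ndarray
    left_censored: np.ndarray
    right_censored: np.ndarray
    genotype: np.ndarray  # derived-allele dosage 0/1/2 at the test SNP

    def __post_init__(self) -> None:
        self.left_bp = np.asarray(self.left_bp, dtype=np.float64)
        self.right_bp = np.asarray(self.right_bp, dtype=np.float64)
        self.left_censored = np.asarray(self.left_censored, dtype=bool)
        self.right_censored = np.asarray(self.right_censored, dtype=bool)
        self.genotype = np.asarray(self.genotype, dtype=np.int64)
        if np.any(self.left_bp <= 0) or np.any(self.right_bp <= 0):
            raise ValueError("distances must be positive")

    def flipped(self) -> "SingletonDistances":
        """Polarization flip at the test SNP (genotype g -> 2 - g)."""
        return SingletonDistances(
            self.left_bp,
            self.right_bp,
            self.left_censored,
            self.right_censored,
            2 - self.genotype,
        )


@dataclass
class TipModel:
    """Optional gamma-shape table kappa(f, g); identity (kappa = 2) gives the
    exponential-tip model.

    ``gamma_shapes`` maps ``(daf_bin_index, genotype)`` to the Gamma shape of
    the summed left+right distance.  The observability hook is accepted for
    interface compatibility and is the identity (each variant equally
    observable).
    """

    gamma_shapes: dict = field(default_factory=dict)
    observability: None = None

    @classmethod
    def from_tsv(cls, path) -> "TipModel":
        tab = pd.read_csv(path, sep="\t")
        shapes = {}
        for _, row in tab.iterrows():
            b = int(round((float(row["f_bin"]) - SDS_BIN_LO) / SDS_BIN_STEP))
            shapes[(b, int(row["genotype"]))] = float(row["shape"])
        return cls(gamma_shapes=shapes)

    def shape(self, f: float, g: int) -> float:
        b = int(np.floor((f - SDS_BIN_LO) / SDS_BIN_STEP + 1e-9))
        return self.gamma_shapes.get((b, g), 2.0)


def _singleton_positions_by_owner(site_table: pd.DataFrame, n_diploids: int):
    owners = site_table["singleton_owner"].to_numpy()
    pos = site_table["position_bp"].to_numpy()
    sel = site_table["is_singleton"].to_numpy()
    per = [pos[sel & (owners == i)] for i in range(n_diploids)]
    return per  # each already sorted (site table is position-sorted)


def collect_singleton_distances(
    panel: PhasedPanel,
    site_table: pd.DataFrame,
    test_snp: int,
    window_bp: tuple[int, int] | None = None,
    _singletons_by_owner=None,
) -> SingletonDistances:
    """Nearest own singleton strictly left/right of the test SNP per diploid.

    A side with no singleton inside the analysis window is censored at the
    window boundary (default: one bp beyond the panel's terminal sites)
    and carries the boundary distance.
    """
    if bool(site_table["is_singleton"].iloc[test_snp]):
        raise ValueError("a singleton cannot be a test SNP")
    n_ind = panel.n_diploids
    p0 = int(panel.positions_bp[test_snp])
    if window_bp is None:
        window_bp = (int(panel.positions_bp[0]) - 1, int(panel.positions_bp[-1]) + 1)
    lo, hi = window_bp
    if not (lo < p0 < hi):
        raise ValueError("test SNP lies outside the analysis window")
    per = (
        _singletons_by_owner
        if _singletons_by_owner is not None
        else _singleton_positions_by_owner(site_table, n_ind)
    )
    left = np.empty(n_ind)
    right = np.empty(n_ind)
    lcen = np.zeros(n_ind, dtype=bool)
    rcen = np.zeros(n_ind, dtype=bool)
    for i in range(n_ind):
        s = per[i]
        k = np.searchsorted(s, p0)
        # strictly left
        j = k - 1
        if j >= 0 and s[j] > lo:
            left[i] = p0 - s[j]
        else:
            left[i] = p0 - lo
            lcen[i] = True
        # strictly right (skip an exact-position singleton, excluded anyway)
        j = k if (k >= s.size or s[k] != p0) else k + 1
        if j < s.size and s[j] < hi:
            right[i] = s[j] - p0
        else:
            right[i] = hi - p0
            rcen[i] = True
    dosage = (
        panel.haplotypes[0::2, test_snp].astype(np.int64)
        + panel.haplotypes[1::2, test_snp]
    )
    return SingletonDistances(left, right, lcen, rcen, dosage)


def _tip_scales(r: float, f: float) -> tuple[float, float]:
    """(t_A, t_D) with log(t_A/t_D) = r and f*t_D + (1-f)*t_A = 1."""
    t_d = 1.0 / (f + (1.0 - f) * np.exp(r))
    return t_d * np.exp(r), t_d


def _loglik(r, d: SingletonDistances, f, lam, shapes):
    t_a, t_d = _tip_scales(r, f)
    tip_sum = np.array([2 * t_a, t_a + t_d, 2 * t_d])[d.genotype]
    rate0 = lam * tip_sum  # exponential per-side rate
    k_half = shapes[d.genotype] / 2.0  # per-side gamma shape
    beta = k_half * rate0  # rate adjusted to preserve the side mean 1/rate0
    ll = 0.0
    for dist, cen in ((d.left_bp, d.left_censored), (d.right_bp, d.right_censored)):
        obs = ~cen
        if obs.any():
            k, b, x = k_half[obs], beta[obs], dist[obs]
            ll += np.sum(k * np.log(b) - special.gammaln(k) + (k - 1) * np.log(x) - b * x)
        if cen.any():
            k, b, x = k_half[cen], beta[cen], dist[cen]
            ll += np.sum(np.log(np.maximum(special.gammaincc(k, b * x), 1e-300)))
    return ll


def raw_sds(
    distances: SingletonDistances,
    f: float,
    tip_model: TipModel | None = None,
    baseline_rate: float | None = None,
    r_bound: float = 8.0,
) -> tuple[float, float]:
    """Raw SDS r_hat = log(t_A / t_D) and its curvature-based standard error.

    ``baseline_rate`` is the per-tip singleton rate per bp for a neutral
    (t = 1) tip; when None it is calibrated from these distances by the
    censoring-aware exponential MLE.  Requires individuals in at least two
    genotype classes.
    """
    g = distances.genotype
    classes = np.unique(g)
    if classes.size < 2:
        raise ValueError(
            "raw SDS is unidentifiable without at least two genotype classes"
        )
    if not (0.0 < f < 1.0):
        raise ValueError("derived allele frequency must lie in (0, 1)")
    if baseline_rate is None:
        n_events = (~distances.left_censored).sum() + (~distances.right_censored).sum()
        total = distances.left_bp.sum() + distances.right_bp.sum()
        if n_events == 0 or total <= 0:
            raise ValueError("all sides censored; cannot calibrate baseline rate")
        baseline_rate = n_events / (2.0 * total)
    shapes = np.array(
        [(tip_model.shape(f, gg) if tip_model else 2.0) for gg in (0, 1, 2)]
    )
    res = optimize.minimize_scalar(
        lambda r: -_loglik(r, distances, f, baseline_rate, shapes),
        bounds=(-r_bound, r_bound),
        method="bounded",
        options={"xatol": 1e-6},
    )
    r_hat = float(res.x)
    h = 1e-3
    curv = (
        _loglik(r_hat + h, distances, f, baseline_rate, shapes)
        - 2.0 * _loglik(r_hat, distances, f, baseline_rate, shapes)
        + _loglik(r_hat - h, distances, f, baseline_rate, shapes)
    ) / h**2
    se = float(1.0 / np.sqrt(-curv)) if curv < 0 else np.inf
    return r_hat, se


def _bin_index(f: np.ndarray) -> np.ndarray:
    """DAF bin index in 0..89 for f in [0.05, 0.95); -1 outside."""
    b = np.floor((f - SDS_BIN_LO) / SDS_BIN_STEP + 1e-9).astype(np.int64)
    n_bins = int(round((SDS_BIN_HI - SDS_BIN_LO) / SDS_BIN_STEP))
    b[(f < SDS_BIN_LO) | (f > SDS_BIN_HI)] = -1
    b[b == n_bins] = n_bins - 1  # f exactly at the upper edge
    return b


def fit_baseline_rates(dists: list, freqs: np.ndarray) -> dict[int, float]:
    """Per-DAF-bin baseline singleton rate (censoring-aware exponential MLE
    of the per-side rate, halved to the per-tip scale) pooled over sites."""
    bins = _bin_index(np.asarray(freqs, dtype=np.float64))
    lam_bin: dict[int, float] = {}
    for b in np.unique(bins):
        sel = bins == b
        ev = sum(
            (~d.left_censored).sum() + (~d.right_censored).sum()
            for d, s in zip(dists, sel)
            if s
        )
        tot = sum(d.left_bp.sum() + d.right_bp.sum() for d, s in zip(dists, sel) if s)
        lam_bin[int(b)] = ev / (2.0 * tot) if ev and tot > 0 else np.nan
    return lam_bin


def _fit_sites(dists, freqs, lam_bin, tip_model, label):
    bins = _bin_index(np.asarray(freqs, dtype=np.float64))
    fitted = sorted(b for b, v in lam_bin.items() if np.isfinite(v))
    raw = np.full(len(dists), np.nan)
    se = np.full(len(dists), np.nan)
    n_failed = 0
    for i, (d, f, b) in enumerate(zip(dists, freqs, bins)):
        if b < 0 or not fitted:
            n_failed += 1
            continue
        bb = int(b) if np.isfinite(lam_bin.get(int(b), np.nan)) else min(
            fitted, key=lambda x: abs(x - int(b))
        )
        try:
            raw[i], se[i] = raw_sds(d, float(f), tip_model, baseline_rate=lam_bin[bb])
        except ValueError:
            n_failed += 1
    if n_failed:
        logger.info("%s: %d of %d sites undefined", label, n_failed, len(dists))
    return raw, se


def sds_track(
    panel: PhasedPanel,
    site_table: pd.DataFrame,
    test_snps,
    tip_model: TipModel | None = None,
    window_bp: tuple[int, int] | None = None,
    baseline_rates: dict[int, float] | None = None,
):
    """Raw SDS over a set of test SNPs with per-DAF-bin rate anchoring.

    Returns ``(raw, se, freqs)`` arrays aligned to ``test_snps``; sites
    where the fit is unidentifiable are NaN (logged).  ``baseline_rates``
    (per-DAF-bin per-tip rates, e.g. from :func:`fit_baseline_rates` on a
    genome-wide background) default to rates fit on this track itself.
    """
    test_snps = np.asarray(test_snps, dtype=np.int64)
    per_owner = _singleton_positions_by_owner(site_table, panel.n_diploids)
    freqs = site_table["derived_freq"].to_numpy()[test_snps]
    dists = [
        collect_singleton_distances(
            panel, site_table, int(t), window_bp, _singletons_by_owner=per_owner
        )
        for t in test_snps
    ]
    if baseline_rates is None:
        baseline_rates = fit_baseline_rates(dists, freqs)
    raw, se = _fit_sites(dists, freqs, baseline_rates, tip_model, "sds_track")
    return raw, se, freqs


class SDSNormalization:
    """Per-DAF-bin mean/SD of raw SDS, fit on one track and applicable to
    another (e.g. fit on a neutral genome-wide background, applied at
    candidate sites)."""

    def __init__(self, min_bin_size: int = 2):
        self.min_bin_size = min_bin_size
        self.bin_stats: dict[int, tuple[float, float]] = {}

    def fit(self, raw: np.ndarray, freqs: np.ndarray) -> "SDSNormalization":
        raw = np.asarray(raw, dtype=np.float64)
        bins = _bin_index(np.asarray(freqs, dtype=np.float64))
        defined = ~np.isnan(raw) & (bins >= 0)
        stats_: dict[int, tuple[float, float]] = {}
        for b in np.unique(bins[defined]):
            sel = defined & (bins == b)
            if sel.sum() >= self.min_bin_size:
                sd = raw[sel].std()
                if sd > 0:
                    stats_[int(b)] = (float(raw[sel].mean()), float(sd))
        if not stats_:
            raise ValueError("no DAF bin has enough defined sites to fit")
        self.bin_stats = stats_
        return self

    def transform(self, raw: np.ndarray, freqs: np.ndarray) -> np.ndarray:
        """Standardize raw scores with the fitted bin stats (nearest
        populated bin for unfitted bins); NaN outside the binned range."""
        raw = np.asarray(raw, dtype=np.float64)
        bins = _bin_index(np.asarray(freqs, dtype=np.float64))
        z = np.full(raw.size, np.nan)
        fitted = sorted(self.bin_stats)
        for i, (r, b) in enumerate(zip(raw, bins)):
            if np.isnan(r) or b < 0:
                continue
            bb = int(b) if int(b) in self.bin_stats else min(
                fitted, key=lambda x: abs(x - int(b))
            )
            mu, sd = self.bin_stats[bb]
            z[i] = (r - mu) / sd
        return z


def sds_track_genome(per_chrom, tip_model: TipModel | None = None):
    """Raw SDS across chromosomes with genome-wide per-DAF-bin anchoring.

    ``per_chrom`` is a list of ``(panel, site_table, test_snps)`` triples.
    Returns ``(raw, se, freqs, chroms, positions_bp)`` concatenated in
    input order.  The baseline rate of each DAF bin pools the
    nearest-singleton distances of that bin's sites over all chromosomes.
    """
    all_dists, all_freqs, all_chrom, all_pos = [], [], [], []
    for panel, site_table, test_snps in per_chrom:
        test_snps = np.asarray(test_snps, dtype=np.int64)
        per_owner = _singleton_positions_by_owner(site_table, panel.n_diploids)
        for t in test_snps:
            all_dists.append(
                collect_singleton_distances(
                    panel, site_table, int(t), _singletons_by_owner=per_owner
                )
            )
        all_freqs.append(site_table["derived_freq"].to_numpy()[test_snps])
        all_chrom.append(np.full(test_snps.size, panel.chrom, dtype=object))
        all_pos.append(panel.positions_bp[test_snps])
    freqs = np.concatenate(all_freqs) if all_freqs else np.zeros(0)
    chroms = np.concatenate(all_chrom) if all_chrom else np.zeros(0, dtype=object)
    pos = np.concatenate(all_pos) if all_pos else np.zeros(0, dtype=np.int64)
    lam_bin = fit_baseline_rates(all_dists, freqs)
    raw, se = _fit_sites(all_dists, freqs, lam_bin, tip_model, "sds_track_genome")
    return raw, se, freqs, chroms, pos


def normalize_sds(
    raw: np.ndarray,
    freqs: np.ndarray,
    chrom=None,
    positions_bp=None,
    min_bin_size: int = 2,
) -> ScoreTrack:
    """Standardize raw SDS within DAF bins of 0.05-0.95 (0.01 steps).

    Bins with fewer than ``min_bin_size`` defined sites are merged with the
    nearest populated bin (logged).  standardized = (raw - bin mean)/bin SD;
    p-values are two-sided standard normal.  Sites with DAF outside the
    binned range are left undefined.
    """
    raw = np.asarray(raw, dtype=np.float64)
    freqs = np.asarray(freqs, dtype=np.float64)
    n = raw.size
    if chrom is None:
        chrom = np.full(n, "1", dtype=object)
    if positions_bp is None:
        positions_bp = np.arange(n, dtype=np.int64)
    bins = _bin_index(freqs)
    defined = ~np.isnan(raw) & (bins >= 0)
    eff_bin = bins.astype(np.float64)
    counts = {b: int(((bins == b) & defined).sum()) for b in np.unique(bins[defined])}
    big = sorted(b for b, c in counts.items() if c >= min_bin_size)
    if not big:
        if defined.sum() and np.nanstd(raw[defined]) == 0:
            raise ValueError("degenerate SDS track: single bin with zero SD")
        big = sorted(counts)
    n_merged = 0
    for b, c in counts.items():
        if c < min_bin_size and big:
            nearest = min(big, key=lambda x: abs(x - b))
            eff_bin[bins == b] = nearest
            n_merged += 1
    if n_merged:
        logger.info("normalize_sds: merged %d sparse DAF bins", n_merged)
    z = np.full(n, np.nan)
    for b in np.unique(eff_bin[defined]):
        sel = defined & (eff_bin == b)
        mu = raw[sel].mean()
        sd = raw[sel].std()
        if sd == 0:
            raise ValueError(f"degenerate DAF bin {b}: zero standard deviation")
        z[sel] = (raw[sel] - mu) / sd
    p = np.where(
        np.isnan(z), np.nan, np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    )
    return ScoreTrack(chrom, positions_bp, np.where(defined, raw, np.nan), z, p, method="SDS")
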