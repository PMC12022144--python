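"""End-to-end orchestration: simulate (or load) -> filter -> score ->
call peaks -> LAD -> overlap, with reproducible seeding and a JSON
manifest.

The synthetic genome is a set of chromosomes simulated as target/outgroup
panel pairs sharing site coordinates; at most one chromosome carries a
sweep, and an ancestry mosaic is laid over the same site grid, optionally
with a favoured-ancestry boost coincident with the sweep locus.  Scans are
standardized genome-wide across chromosomes, peaks and LAD regions are
intersected, and the joint table is the post-admixture selection candidate
output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ScoreTrack
from .genomics_io import select_test_snps
from .haplostats import xpehh_genome
from .lad import STRICT_SD, ProportionTrack, ancestry_proportion, lad_peak_overlap, lad_scan
from .peaks import PeakCallingConfig, call_peaks, peaks_to_bed
from .sds import normalize_sds, sds_track_genome
from .simdata import SweepSimConfig, TractSimConfig, simulate_pair, simulate_tracts

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run"]


@dataclass
class RunConfig:
    """Configuration of one synthetic end-to-end run.

    ``sweep`` parameterises every chromosome's panel pair; its ``s`` is
    applied only on ``sweep_chrom`` (1-based; ``None`` = fully neutral).
    ``tract`` parameterises the ancestry mosaic per chromosome; when
    ``ancestry_boost`` is set, the favoured-ancestry boost is planted at
    the sweep position of ``sweep_chrom``.  Peak-calling thresholds
    default to the scan's standard values (99.99%/99.995% quantiles,
    1 Mb window, 10 supporting variants).
    """

    seed: int = 0
    methods: tuple = ("sds", "xpehh", "lad")
    n_chroms: int = 4
    sweep_chrom: int | None = 1
    sweep: SweepSimConfig = field(
        default_factory=lambda: SweepSimConfig(mu=5e-8, n_diploids=100)
    )
    tract: TractSimConfig = field(
        default_factory=lambda: TractSimConfig(
            n_haplotypes=200, K=2, m=(0.9, 0.1), g=30, delta=0.4
        )
    )
    ancestry_boost: bool = False
    map_cM_per_Mb: float = 10.0
    peak: PeakCallingConfig = field(default_factory=PeakCallingConfig)
    lad_threshold_sd: float = STRICT_SD
    lad_ancestry: int = 1
    truncation: float = 0.05
    maf_min: float = 0.05
    maf_max: float = 0.95

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "sweep" in d:
            d["sweep"] = SweepSimConfig(**d["sweep"])
        if "tract" in d:
            d["tract"]["m"] = tuple(d["tract"].get("m", (0.9, 0.1)))
            d["tract"] = TractSimConfig(**d["tract"])
        if "peak" in d:
            d["peak"] = PeakCallingConfig(**d["peak"])
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["tract"]["m"] = list(self.tract.m)
        return d


@dataclass
class RunResult:
    tracks: dict
    peaks: pd.DataFrame
    lad_regions: pd.DataFrame
    joint: pd.DataFrame
    manifest: dict
    sel_sites: dict


def run(config: RunConfig, outdir=None) -> RunResult:
    """Execute one end-to-end run; deterministic given the config seed.

    When ``outdir`` is given, score tracks (TSV), peak BEDs, LAD regions,
    the joint candidate table and a JSON manifest are written there.
    """
    root = np.random.SeedSequence(config.seed)
    chrom_seeds = root.spawn(config.n_chroms)
    panels: list = []
    manifest: dict = {
        "package": "admixscan",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "filter_counts": {},
        "stages": [],
    }
    sel_sites: dict = {}
    for c in range(1, config.n_chroms + 1):
        s = config.sweep.s if (config.sweep_chrom == c) else 0.0
        sub = dataclasses.replace(
            config.sweep,
            s=s,
            seed=int(chrom_seeds[c - 1].generate_state(1)[0] % (2**31 - 1)),
            cM_per_Mb=config.map_cM_per_Mb,
        )
        try:
            panelA, panelB, sitesA, sel_idx = simulate_pair(sub, chrom=str(c))
        except Exception as err:  # pragma: no cover - stage context
            raise RuntimeError(f"stage simulate (chrom {c}) failed: {err}") from err
        test = select_test_snps(sitesA, config.maf_min, config.maf_max)
        manifest["filter_counts"][str(c)] = {
            "n_sites": int(panelA.n_sites),
            "n_test_snps": int(test.size),
            "n_singletons": int(sitesA["is_singleton"].sum()),
        }
        panels.append((panelA, panelB, sitesA, test, sel_idx))
        if sel_idx is not None:
            sel_sites[str(c)] = int(panelA.positions_bp[sel_idx])
    manifest["stages"].append("simulate")

    tracks: dict[str, ScoreTrack] = {}
    if "xpehh" in config.methods:
        tracks["XPEHH"] = xpehh_genome(
            [(pA, pB, t) for pA, pB, _, t, _ in panels], config.truncation
        )
        manifest["stages"].append("xpehh")
    if "sds" in config.methods:
        raw, se, freqs, chroms, pos = sds_track_genome(
            [(pA, sA, t) for pA, _, sA, t, _ in panels]
        )
        tracks["SDS"] = normalize_sds(raw, freqs, chroms, pos)
        manifest["stages"].append("sds")

    all_peaks = [p for p in (call_peaks(tr, config.peak) for tr in tracks.values()) if len(p)]
    peaks = (
        pd.concat(all_peaks, ignore_index=True)
        if all_peaks
        else call_peaks(ScoreTrack([], [], [], [], [], "NONE"), config.peak)
    )
    manifest["stages"].append("peaks")

    lad_regions = pd.DataFrame()
    joint = pd.DataFrame()
    if "lad" in config.methods:
        ptracks = []
        for c, (panelA, _, _, _, sel_idx) in enumerate(panels, start=1):
            chrom_len_cM = config.sweep.seq_len_bp * config.map_cM_per_Mb / 1e6
            boost = config.ancestry_boost and (config.sweep_chrom == c)
            tcfg = dataclasses.replace(
                config.tract,
                chrom_len_cM=chrom_len_cM,
                sel_locus_cM=(
                    config.sweep.sel_pos_bp * config.map_cM_per_Mb / 1e6 if boost else None
                ),
                delta=config.tract.delta if boost else 0.0,
                seed=int(chrom_seeds[c - 1].generate_state(2)[1] % (2**31 - 1)),
            )
            grid_cM = panelA.positions_bp * config.map_cM_per_Mb / 1e6
            am = simulate_tracts(
                tcfg, grid_cM, positions_bp=panelA.positions_bp, chrom=str(c)
            )
            ptracks.append(
                ProportionTrack(
                    chrom=str(c),
                    positions_bp=panelA.positions_bp,
                    proportion=ancestry_proportion(am, config.lad_ancestry),
                    ancestry=am.labels[config.lad_ancestry],
                )
            )
        lad_regions = lad_scan(ptracks, config.lad_threshold_sd)
        joint = lad_peak_overlap(lad_regions, peaks)
        manifest["stages"] += ["lad", "overlap"]

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, tr in tracks.items():
            tr.to_tsv(outdir / f"{name.lower()}_track.tsv")
        peaks.to_csv(outdir / "peaks.tsv", sep="\t", index=False)
        peaks_to_bed(peaks, outdir / "peaks.bed")
        lad_regions.to_csv(outdir / "lad_regions.tsv", sep="\t", index=False)
        joint.to_csv(outdir / "joint_candidates.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    return RunResult(tracks, peaks, lad_regions, joint, manifest, sel_sites)
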