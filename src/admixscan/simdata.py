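"""Synthetic inputs for the selection and local-ancestry scans.

Two generators:

* :func:`simulate_panel` / :func:`simulate_pair` — phased haplotype panels
  under neutrality or an ongoing additive sweep, with all variants
  (including singletons) retained and alleles polarized by the founding
  state.  The default backend seeds a neutral population with msprime
  (discrete-time Wright–Fisher into Hudson coalescent) and runs any
  selected phase with an explicit forward Wright–Fisher engine; a pure
  forward backend (``backend="wf"``, >= 8*Ne burn-in generations) is kept
  for cross-validation.

* :func:`simulate_tracts` — post-admixture ancestry mosaics: each
  haplotype is a continuous-position Markov mosaic whose switch points
  follow a Poisson process of rate ``g`` per Morgan (``g`` generations
  since the admixture pulse), with states drawn from the stationary
  proportions ``m``; an optional selected locus raises the favoured
  ancestry's draw probability by ``delta``, decaying linearly to zero at
  ``sel_halfwidth_cM``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

from .core import AncestryMatrix, PhasedPanel, build_site_table

__all__ = [
    "SweepSimConfig",
    "TractSimConfig",
    "simulate_panel",
    "simulate_pair",
    "simulate_tracts",
    "tract_lengths",
    "RejectionBudgetExceeded",
    "write_vcf",
    "write_plink_map",
    "write_msp",
    "write_bed",
]


class RejectionBudgetExceeded(RuntimeError):
    """Raised when no sweep replicate satisfies the frequency condition."""


@dataclass
class SweepSimConfig:
    """Wright–Fisher sweep/neutral simulation parameters.

    ``s`` is the per-copy selection coefficient of the derived allele at
    ``sel_pos_bp`` (diploid fitness ``(1+s)**dosage``); ``s = 0`` gives a
    neutral replicate.  ``freq_condition`` is the minimum present-day
    derived frequency, in the sampled panel, required to accept a sweep
    replicate (rejection sampling).
    """

    n_diploids: int = 50
    seq_len_bp: int = 2_000_000
    mu: float = 1e-8
    rho: float = 1e-8
    Ne: int = 500
    s: float = 0.0
    sel_pos_bp: int | None = None  # defaults to the chromosome midpoint
    freq_condition: float = 0.8
    seed: int = 0
    max_tries: int = 200
    sweep_duration: int = 250
    stop_at_condition: bool = True
    cM_per_Mb: float = 1.0

    def __post_init__(self) -> None:
        if self.n_diploids < 2:
            raise ValueError("n_diploids must be >= 2")
        if not (0.0 <= self.s <= 1.0):
            raise ValueError("s must lie in [0, 1]")
        if not (0.0 <= self.freq_condition <= 1.0):
            raise ValueError("freq_condition must lie in [0, 1]")
        if self.sel_pos_bp is None:
            self.sel_pos_bp = self.seq_len_bp // 2
        if not (0 <= self.sel_pos_bp < self.seq_len_bp):
            raise ValueError("sel_pos_bp must lie in [0, seq_len_bp)")
        if self.Ne < 2:
            raise ValueError("Ne must be >= 2")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "SweepSimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TractSimConfig:
    """Admixture ancestry-mosaic parameters (pulse ``g`` generations ago)."""

    n_haplotypes: int = 200
    chrom_len_cM: float = 100.0
    K: int = 2
    m: tuple = (0.9, 0.1)
    g: int = 30
    sel_locus_cM: float | None = None
    sel_ancestry: int = 1
    delta: float = 0.0
    sel_halfwidth_cM: float = 10.0
    boost_mode: str = "selection"  # "selection" | "window"
    seed: int = 0

    def __post_init__(self) -> None:
        self.m = tuple(float(x) for x in self.m)
        if len(self.m) != self.K:
            raise ValueError("m must have length K")
        if abs(sum(self.m) - 1.0) > 1e-12:
            raise ValueError("ancestry proportions m must sum to 1")
        if self.g < 1:
            raise ValueError("g must be >= 1")
        if self.sel_locus_cM is not None or self.delta > 0:
            if not (0 <= self.sel_ancestry < self.K):
                raise ValueError("sel_ancestry out of range")
            if not (0.0 <= self.delta <= 1.0 - self.m[self.sel_ancestry] + 1e-12):
                raise ValueError("delta must lie in [0, 1 - m[sel_ancestry]]")
        if self.sel_locus_cM is not None and not (
            0.0 <= self.sel_locus_cM <= self.chrom_len_cM
        ):
            raise ValueError("sel_locus_cM must lie within the chromosome")
        if self.boost_mode not in ("selection", "window"):
            raise ValueError("boost_mode must be 'selection' or 'window'")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["m"] = list(self.m)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "TractSimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["m"] = tuple(d["m"])
        return cls(**d)


# ---------------------------------------------------------------------------
# forward Wright–Fisher engine
# ---------------------------------------------------------------------------


class _Population:
    """Haplotype matrix state of one WF population.

    ``G`` is ``(2N, S)`` uint8 over segregating sites at unsorted integer
    positions ``pos``; ``sel`` is the column index of the selected site
    (-1 when absent).
    """

    def __init__(self, G: np.ndarray, pos: np.ndarray, sel: int = -1):
        self.G = np.ascontiguousarray(G, dtype=np.uint8)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.sel = sel

    def copy(self) -> "_Population":
        return _Population(self.G.copy(), self.pos.copy(), self.sel)

    @property
    def n_hap(self) -> int:
        return self.G.shape[0]

    def sel_count(self) -> int:
        if self.sel < 0:
            return 0
        return int(self.G[:, self.sel].sum())


def _advance(
    pop: _Population,
    generations: int,
    rng: np.random.Generator,
    mu: float,
    rho: float,
    L: int,
    s: float = 0.0,
    stop_pop_freq: float | None = None,
) -> int:
    """Evolve ``pop`` in place for up to ``generations`` WF generations.

    Returns the number of generations actually run (early exit when the
    selected allele is lost, or when its population frequency reaches
    ``stop_pop_freq``).
    """
    n_hap = pop.n_hap
    n_dip = n_hap // 2
    mut_rate = n_hap * mu * L
    xo_rate = rho * L
    for gen in range(generations):
        G, pos = pop.G, pop.pos
        # parent sampling (selection via per-individual fitness)
        if s > 0.0 and pop.sel >= 0:
            dose = G[0::2, pop.sel].astype(np.float64) + G[1::2, pop.sel]
            w = (1.0 + s) ** dose
            p = w / w.sum()
            parents = rng.choice(n_dip, size=n_hap, p=p)
        else:
            parents = rng.integers(0, n_dip, size=n_hap)
        start = rng.integers(0, 2, size=n_hap)
        n_xo = rng.poisson(xo_rate, size=n_hap)
        child = G[2 * parents + start]
        for i in np.flatnonzero(n_xo):
            bp = np.sort(rng.integers(0, L, size=n_xo[i]))
            parity = np.searchsorted(bp, pos, side="right") % 2
            a = G[2 * parents[i] + start[i]]
            b = G[2 * parents[i] + 1 - start[i]]
            child[i] = np.where(parity == 0, a, b)
        # new mutations (infinite-sites on an integer grid; collisions dropped)
        n_new = rng.poisson(mut_rate)
        if n_new:
            new_pos = rng.integers(0, L, size=n_new)
            new_hap = rng.integers(0, n_hap, size=n_new)
            fresh = ~np.isin(new_pos, pos)
            # drop duplicates among the new positions themselves
            _, first = np.unique(new_pos, return_index=True)
            keep = np.zeros(n_new, dtype=bool)
            keep[first] = True
            keep &= fresh
            if keep.any():
                cols = np.zeros((n_hap, int(keep.sum())), dtype=np.uint8)
                cols[new_hap[keep], np.arange(int(keep.sum()))] = 1
                child = np.concatenate([child, cols], axis=1)
                pos = np.concatenate([pos, new_pos[keep]])
        # prune fixed / lost columns, preserving the selected column
        counts = child.sum(axis=0, dtype=np.int64)
        seg = (counts > 0) & (counts < n_hap)
        if pop.sel >= 0:
            seg[pop.sel] = counts[pop.sel] > 0
        new_sel = -1
        if pop.sel >= 0 and seg[pop.sel]:
            new_sel = int(seg[: pop.sel].sum())
        pop.G = np.ascontiguousarray(child[:, seg])
        pop.pos = pos[seg]
        pop.sel = new_sel
        if pop.sel < 0 and s > 0.0:
            return gen + 1  # selected allele lost
        if stop_pop_freq is not None and pop.sel >= 0:
            if pop.sel_count() >= stop_pop_freq * n_hap:
                return gen + 1
    return generations


def _inject_selected(pop: _Population, rng: np.random.Generator, sel_pos_bp: int) -> None:
    """Add the selected mutation at frequency 1/(2Ne) on a random haplotype."""
    hit = np.flatnonzero(pop.pos == sel_pos_bp)
    if hit.size:  # recycle an existing column's position: overwrite as fresh
        keep = np.ones(pop.pos.size, dtype=bool)
        keep[hit] = False
        pop.G = np.ascontiguousarray(pop.G[:, keep])
        pop.pos = pop.pos[keep]
    col = np.zeros((pop.n_hap, 1), dtype=np.uint8)
    col[rng.integers(0, pop.n_hap), 0] = 1
    pop.G = np.concatenate([pop.G, col], axis=1)
    pop.pos = np.concatenate([pop.pos, [sel_pos_bp]])
    pop.sel = pop.pos.size - 1


def _msprime_population(
    n_diploids: int, L: int, mu: float, rho: float, Ne: int, seed_seq: np.random.SeedSequence
) -> _Population:
    """Neutral equilibrium sample of ``n_diploids`` individuals via msprime."""
    import msprime

    s1, s2 = (int(x % (2**31 - 1)) + 1 for x in seed_seq.generate_state(2))
    ts = msprime.sim_ancestry(
        samples=n_diploids,
        population_size=Ne,
        sequence_length=L,
        recombination_rate=rho,
        model=[
            msprime.DiscreteTimeWrightFisher(duration=min(1000, 8 * Ne)),
            msprime.StandardCoalescent(),
        ],
        random_seed=s1,
    )
    ts = msprime.sim_mutations(
        ts, rate=mu, random_seed=s2, model=msprime.BinaryMutationModel()
    )
    keep_pos, cols = [], []
    for var in ts.variants():
        if len(var.site.mutations) != 1:  # drop recurrent-mutation sites
            continue
        gt = var.genotypes.astype(np.uint8)
        if 0 < gt.sum() < gt.size:
            keep_pos.append(int(var.site.position))
            cols.append(gt)
    if cols:
        G = np.ascontiguousarray(np.array(cols, dtype=np.uint8).T)
        pos = np.array(keep_pos, dtype=np.int64)
        # integer-grid collisions from discrete positions: keep first
        _, first = np.unique(pos, return_index=True)
        G, pos = G[:, np.sort(first)], pos[np.sort(first)]
    else:
        G = np.zeros((2 * n_diploids, 0), dtype=np.uint8)
        pos = np.zeros(0, dtype=np.int64)
    return _Population(G, pos)


def _sample_panel(
    pop: _Population,
    rng: np.random.Generator,
    n_diploids: int,
    config: SweepSimConfig,
    chrom: str = "1",
) -> tuple[PhasedPanel, "np.ndarray | None"]:
    """Draw a diploid sample; keep sites segregating in the sample (plus the
    selected site).  Returns (panel, sample-site positions of selected site)."""
    n_dip_pop = pop.n_hap // 2
    if n_diploids < n_dip_pop:
        ind = np.sort(rng.choice(n_dip_pop, size=n_diploids, replace=False))
    else:
        ind = np.arange(n_dip_pop)
    rows = np.empty(2 * ind.size, dtype=np.int64)
    rows[0::2], rows[1::2] = 2 * ind, 2 * ind + 1
    H = pop.G[rows]
    counts = H.sum(axis=0, dtype=np.int64)
    seg = (counts > 0) & (counts < H.shape[0])
    if pop.sel >= 0:
        seg[pop.sel] = counts[pop.sel] > 0
    order = np.argsort(pop.pos[seg], kind="stable")
    H = H[:, seg][:, order]
    pos = pop.pos[seg][order]
    sel_idx = None
    if pop.sel >= 0 and seg[pop.sel]:
        sel_idx = int(np.searchsorted(pos, config.sel_pos_bp))
    cm = pos * (config.cM_per_Mb / 1e6)
    panel = PhasedPanel(H, pos, cm, chrom=chrom)
    return panel, sel_idx


def _run_sweep_phase(
    base: _Population,
    rng: np.random.Generator,
    config: SweepSimConfig,
) -> tuple[_Population, int]:
    """Rejection-sample the selected phase from a common base population.

    Injects the selected mutation at 1/(2Ne) and evolves forward for up to
    ``sweep_duration`` generations.  With ``stop_at_condition`` (default)
    the phase ends at the first generation the population frequency
    reaches ``freq_condition`` — an *ongoing* sweep sampled at the
    conditioning frequency; otherwise the full duration is run and the
    end-state frequency is checked.  A replicate that loses the allele or
    falls short restarts from the base state.  Returns the accepted
    population and the phase duration actually run.
    """
    for _ in range(config.max_tries):
        pop = base.copy()
        _inject_selected(pop, rng, config.sel_pos_bp)
        ran = _advance(
            pop,
            config.sweep_duration,
            rng,
            config.mu,
            config.rho,
            config.seq_len_bp,
            s=config.s,
            stop_pop_freq=config.freq_condition if config.stop_at_condition else None,
        )
        if pop.sel >= 0 and pop.sel_count() >= config.freq_condition * pop.n_hap:
            return pop, ran
    raise RejectionBudgetExceeded(
        f"no sweep replicate reached frequency {config.freq_condition} "
        f"within the budget of {config.max_tries} tries "
        f"({config.sweep_duration} generations each)"
    )


def simulate_panel(
    config: SweepSimConfig, backend: str = "hybrid", chrom: str = "1"
):
    """Simulate one phased panel (all variants retained, singletons included).

    Returns ``(panel, site_table, selected_site_index)`` where the index is
    ``None`` for neutral replicates.  Deterministic given ``config.seed``.

    Backends: ``"hybrid"`` (msprime neutral equilibrium + forward WF
    selected phase; msprime only when ``s == 0``) or ``"wf"`` (pure forward
    Wright–Fisher with an 8*Ne-generation burn-in).
    """
    if backend not in ("hybrid", "wf"):
        raise ValueError(f"unknown backend {backend!r}")
    ss = np.random.SeedSequence(config.seed)
    ss_ms, ss_fwd = ss.spawn(2)
    rng = np.random.default_rng(ss_fwd)

    if config.s == 0.0:
        if backend == "hybrid":
            pop = _msprime_population(
                config.n_diploids,
                config.seq_len_bp,
                config.mu,
                config.rho,
                config.Ne,
                ss_ms,
            )
            panel, _ = _sample_panel(pop, rng, config.n_diploids, config, chrom)
        else:
            pop = _Population(
                np.zeros((2 * config.Ne, 0), dtype=np.uint8), np.zeros(0, dtype=np.int64)
            )
            _advance(pop, 8 * config.Ne, rng, config.mu, config.rho, config.seq_len_bp)
            panel, _ = _sample_panel(pop, rng, config.n_diploids, config, chrom)
        return panel, build_site_table(panel), None

    # selected replicate: neutral base population, then forward sweep phase
    if backend == "hybrid":
        base = _msprime_population(
            config.Ne, config.seq_len_bp, config.mu, config.rho, config.Ne, ss_ms
        )
    else:
        base = _Population(
            np.zeros((2 * config.Ne, 0), dtype=np.uint8), np.zeros(0, dtype=np.int64)
        )
        _advance(base, 8 * config.Ne, rng, config.mu, config.rho, config.seq_len_bp)

    for _ in range(config.max_tries):
        pop, _ = _run_sweep_phase(base, rng, config)
        panel, sel_idx = _sample_panel(pop, rng, config.n_diploids, config, chrom)
        if sel_idx is not None:
            daf = panel.haplotypes[:, sel_idx].mean()
            if daf >= config.freq_condition:
                return panel, build_site_table(panel), sel_idx
    raise RejectionBudgetExceeded(
        f"no sampled panel reached frequency {config.freq_condition} at the "
        f"selected site within the budget of {config.max_tries} tries"
    )


def simulate_pair(
    config: SweepSimConfig,
    backend: str = "hybrid",
    chrom: str = "1",
    split_generations: int | None = None,
):
    """Simulate a target/outgroup panel pair on shared site coordinates.

    A common neutral population is duplicated at the split; population A
    carries the sweep (when ``config.s > 0``) injected at the split and run
    until the sample frequency condition holds, population B evolves
    neutrally for the same number of generations (``split_generations``,
    defaulting to ``config.sweep_duration``, when neutral).  Panels are emitted on the union of segregating sites so
    downstream statistics see identical coordinates.

    Returns ``(panel_A, panel_B, site_table_A, selected_site_index)``.

    ``backend="msprime"`` (neutral only) runs a coalescent two-population
    split model directly — the fast path for large neutral genomes.
    """
    ss = np.random.SeedSequence(config.seed)
    ss_ms, ss_fwd = ss.spawn(2)
    rng = np.random.default_rng(ss_fwd)
    if backend == "msprime":
        if config.s != 0.0:
            raise ValueError("the msprime pair backend is neutral-only")
        gens = split_generations if split_generations is not None else config.sweep_duration
        return _msprime_pair(config, gens, ss_ms, chrom)
    if backend == "hybrid":
        base = _msprime_population(
            config.Ne, config.seq_len_bp, config.mu, config.rho, config.Ne, ss_ms
        )
    elif backend == "wf":
        base = _Population(
            np.zeros((2 * config.Ne, 0), dtype=np.uint8), np.zeros(0, dtype=np.int64)
        )
        _advance(base, 8 * config.Ne, rng, config.mu, config.rho, config.seq_len_bp)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    sel_idx = None
    if config.s > 0.0:
        for _ in range(config.max_tries):
            popA, ran = _run_sweep_phase(base, rng, config)
            panelA, sel_idx = _sample_panel(popA, rng, config.n_diploids, config, chrom)
            if sel_idx is not None and (
                panelA.haplotypes[:, sel_idx].mean() >= config.freq_condition
            ):
                break
        else:
            raise RejectionBudgetExceeded(
                f"no sampled panel met the frequency condition within "
                f"{config.max_tries} tries"
            )
        gens_B = ran
    else:
        gens = split_generations if split_generations is not None else config.sweep_duration
        popA = base.copy()
        _advance(popA, gens, rng, config.mu, config.rho, config.seq_len_bp)
        panelA, _ = _sample_panel(popA, rng, config.n_diploids, config, chrom)
        gens_B = gens

    popB = base.copy()
    _advance(popB, gens_B, rng, config.mu, config.rho, config.seq_len_bp)
    panelB, _ = _sample_panel(popB, rng, config.n_diploids, config, chrom)

    panelA, panelB, sel_idx = _union_coordinates(panelA, panelB, sel_idx, config)
    return panelA, panelB, build_site_table(panelA), sel_idx


def _msprime_pair(config: SweepSimConfig, split_gens: int, seed_seq, chrom: str):
    """Coalescent two-population neutral pair on shared coordinates."""
    import msprime

    s1, s2 = (int(x % (2**31 - 1)) + 1 for x in seed_seq.generate_state(2))
    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=config.Ne)
    dem.add_population(name="B", initial_size=config.Ne)
    dem.add_population(name="ANC", initial_size=config.Ne)
    dem.add_population_split(time=split_gens, derived=["A", "B"], ancestral="ANC")
    ts = msprime.sim_ancestry(
        samples={"A": config.n_diploids, "B": config.n_diploids},
        demography=dem,
        sequence_length=config.seq_len_bp,
        recombination_rate=config.rho,
        random_seed=s1,
    )
    ts = msprime.sim_mutations(
        ts, rate=config.mu, random_seed=s2, model=msprime.BinaryMutationModel()
    )
    pos, cols = [], []
    for var in ts.variants():
        if len(var.site.mutations) != 1:
            continue
        gt = var.genotypes.astype(np.uint8)
        if 0 < gt.sum() < gt.size:
            pos.append(int(var.site.position))
            cols.append(gt)
    G = np.array(cols, dtype=np.uint8).T if cols else np.zeros((4 * config.n_diploids, 0), np.uint8)
    pos = np.array(pos, dtype=np.int64)
    _, first = np.unique(pos, return_index=True)
    first = np.sort(first)
    G, pos = G[:, first], pos[first]
    cm = pos * (config.cM_per_Mb / 1e6)
    nA = 2 * config.n_diploids
    panelA = PhasedPanel(G[:nA], pos, cm, chrom=chrom)
    panelB = PhasedPanel(G[nA:], pos, cm, chrom=chrom)
    return panelA, panelB, build_site_table(panelA), None


def _union_coordinates(panelA, panelB, sel_idx_A, config):
    """Re-emit both panels on the union of their site positions (absent
    sites become monomorphic-ancestral columns)."""
    posA, posB = panelA.positions_bp, panelB.positions_bp
    union = np.union1d(posA, posB)

    def expand(panel, pos):
        H = np.zeros((panel.n_hap, union.size), dtype=np.uint8)
        idx = np.searchsorted(union, pos)
        H[:, idx] = panel.haplotypes
        cm = union * (config.cM_per_Mb / 1e6)
        return PhasedPanel(H, union, cm, chrom=panel.chrom, sample_ids=panel.sample_ids)

    newA = expand(panelA, posA)
    newB = expand(panelB, posB)
    sel = None
    if sel_idx_A is not None:
        sel = int(np.searchsorted(union, posA[sel_idx_A]))
    return newA, newB, sel


# ---------------------------------------------------------------------------
# admixture tract mosaics
# ---------------------------------------------------------------------------


def _draw_probs(config: TractSimConfig, x_morgan: float) -> np.ndarray:
    m = np.array(config.m)
    if (
        config.sel_locus_cM is None
        or config.delta == 0.0
        or config.boost_mode != "window"
    ):
        return m
    hw = config.sel_halfwidth_cM / 100.0
    locus = config.sel_locus_cM / 100.0
    w = max(0.0, 1.0 - abs(x_morgan - locus) / hw) if hw > 0 else 0.0
    if w == 0.0:
        return m
    k = config.sel_ancestry
    p = m.copy()
    boost = config.delta * w
    p[k] = m[k] + boost
    other = 1.0 - m[k]
    if other > 0:
        scale = (1.0 - p[k]) / other
        for j in range(config.K):
            if j != k:
                p[j] = m[j] * scale
    return p


def _one_mosaic(config: TractSimConfig, rng: np.random.Generator):
    """Breakpoints (Morgans, incl. 0 and L) and states of one haplotype."""
    L = config.chrom_len_cM / 100.0
    g = config.g
    xs = [0.0]
    states = [int(rng.choice(config.K, p=_draw_probs(config, 0.0)))]
    x = 0.0
    while True:
        x += rng.exponential(1.0 / g)
        if x >= L:
            break
        xs.append(x)
        states.append(int(rng.choice(config.K, p=_draw_probs(config, x))))
    xs.append(L)
    return np.array(xs), np.array(states, dtype=np.int16)


def simulate_tracts(
    config: TractSimConfig,
    positions_cM: np.ndarray,
    positions_bp: np.ndarray | None = None,
    chrom: str = "1",
    labels: list[str] | None = None,
) -> AncestryMatrix:
    """Emit ancestry assignments at a grid of site positions.

    Deterministic given ``config.seed``.  ``positions_cM`` is the emission
    grid; ``positions_bp`` defaults to ``cM * 1e6 / 1`` (1 cM/Mb).

    When a selected locus is configured, the default ``boost_mode
    "selection"`` raises the favoured ancestry's marginal probability at
    the locus to exactly ``m[sel_ancestry] + delta`` by conditioning each
    haplotype's mosaic on its locus state (post-admixture selection on the
    locus; the excess decays away from it on the natural tract-correlation
    scale ``1/g`` Morgan).  ``boost_mode "window"`` instead raises the
    redraw probability at switch points inside ``sel_halfwidth_cM``,
    linearly decaying to zero at the window edge; the realised marginal
    excess at the locus is then attenuated by the Markov lag.
    """
    positions_cM = np.asarray(positions_cM, dtype=np.float64)
    if positions_cM.size and (
        positions_cM.min() < 0 or positions_cM.max() > config.chrom_len_cM
    ):
        raise ValueError("grid positions must lie within the chromosome")
    rng = np.random.default_rng(config.seed)
    grid_m = positions_cM / 100.0
    select = (
        config.sel_locus_cM is not None
        and config.delta > 0.0
        and config.boost_mode == "selection"
    )
    locus_m = (config.sel_locus_cM or 0.0) / 100.0
    p_target = (config.m[config.sel_ancestry] + config.delta) if select else 0.0
    codes = np.empty((config.n_haplotypes, positions_cM.size), dtype=np.int16)
    for h in range(config.n_haplotypes):
        if select:
            want = rng.random() < p_target
            while True:  # condition the mosaic on its locus ancestry
                xs, states = _one_mosaic(config, rng)
                at = states[np.searchsorted(xs[1:-1], locus_m, side="right")]
                if (at == config.sel_ancestry) == want:
                    break
        else:
            xs, states = _one_mosaic(config, rng)
        idx = np.searchsorted(xs[1:-1], grid_m, side="right")
        codes[h] = states[idx]
    if positions_bp is None:
        positions_bp = np.round(positions_cM * 1e6).astype(np.int64)
    if labels is None:
        labels = [f"ANC{k}" for k in range(config.K)]
    return AncestryMatrix(codes, labels, positions_bp, chrom=chrom)


def tract_lengths(config: TractSimConfig, min_tracts: int = 10_000) -> np.ndarray:
    """Interior (uncensored) tract lengths in cM from fresh mosaics.

    Tracts are segments between successive switch events (including
    ancestry-preserving redraws), so their lengths are exactly exponential
    with mean ``100/g`` cM; boundary-censored segments are excluded.  The
    mosaics are drawn on a long internal window (>= 500 expected switches)
    so that finite-chromosome conditioning on the interior segments is
    negligible.
    """
    cfg = dataclasses.replace(
        config,
        chrom_len_cM=max(config.chrom_len_cM, 500 * 100.0 / config.g),
        sel_locus_cM=None,
        delta=0.0,
    )
    rng = np.random.default_rng(config.seed)
    out: list[np.ndarray] = []
    total = 0
    while total < min_tracts:
        xs, _ = _one_mosaic(cfg, rng)
        if xs.size > 3:  # at least two interior switch points
            seg = np.diff(xs[1:-1]) * 100.0
            out.append(seg)
            total += seg.size
    return np.concatenate(out) if out else np.zeros(0)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_vcf(panel: PhasedPanel, site_table, path) -> None:
    """Write a phased VCF (GT with '|', INFO/AA = ancestral allele).

    REF is the ancestral allele, ALT the derived, matching the panel's
    polarization.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom},length={int(panel.positions_bp[-1]) + 1 if panel.n_sites else 1}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        anc = site_table["ancestral"].to_numpy()
        der = site_table["derived"].to_numpy()
        H = panel.haplotypes
        for j in range(panel.n_sites):
            gts = "\t".join(
                f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(panel.n_diploids)
            )
            fh.write(
                f"{panel.chrom}\t{panel.positions_bp[j] + 1}\t.\t{anc[j]}\t{der[j]}"
                f"\t.\tPASS\tAA={anc[j]}\tGT\t{gts}\n"
            )


def write_plink_map(panel: PhasedPanel, path) -> None:
    """PLINK-style genetic map text: chrom, id, cM, bp."""
    with open(path, "w") as fh:
        for j in range(panel.n_sites):
            fh.write(
                f"{panel.chrom}\tsnp{j}\t{panel.positions_cM[j]:.8g}"
                f"\t{panel.positions_bp[j]}\n"
            )


def write_msp(am: AncestryMatrix, path, positions_cM: np.ndarray | None = None) -> None:
    """Write an RFmix ``.msp.tsv``-style table (windows of constant ancestry).

    Consecutive sites with identical assignments across all haplotypes are
    collapsed into one window; window bounds are half-open in bp.
    """
    pos = am.positions_bp
    if positions_cM is None:
        positions_cM = pos / 1e6
    n_sites = am.codes.shape[1]
    # run-length encode columns
    starts = [0]
    for j in range(1, n_sites):
        if not np.array_equal(am.codes[:, j], am.codes[:, j - 1]):
            starts.append(j)
    starts.append(n_sites)
    hap_names = []
    for sid in am.sample_ids:
        hap_names += [f"{sid}.0", f"{sid}.1"]
    with open(path, "w") as fh:
        fh.write(
            "#Subpopulation order/codes: "
            + "\t".join(f"{lab}={k}" for k, lab in enumerate(am.labels))
            + "\n"
        )
        fh.write(
            "#chm\tspos\tepos\tsgpos\tegpos\tn snps\t" + "\t".join(hap_names) + "\n"
        )
        for a, b in zip(starts[:-1], starts[1:]):
            spos = int(pos[a])
            # windows tile the covered span: each ends where the next starts
            epos = int(pos[b]) if b < n_sites else int(pos[b - 1]) + 1
            row = "\t".join(str(int(c)) for c in am.codes[:, a])
            fh.write(
                f"{am.chrom}\t{spos}\t{epos}\t{positions_cM[a]:.6f}"
                f"\t{positions_cM[b - 1]:.6f}\t{b - a}\t{row}\n"
            )


def write_bed(intervals, path) -> None:
    """Write (chrom, start, end[, name]) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")
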