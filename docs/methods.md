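# Methods

This note documents the models behind each module, the tunable parameters
that matter, the numerical conventions, and what the synthetic-data tests
do and do not demonstrate about real data.

## Haplotype panels: the Wright–Fisher simulator

`simdata.simulate_panel` / `simulate_pair` produce phased, polarized
panels (0 = ancestral, 1 = derived) with **all** variants retained —
singletons are the signal for the singleton-density score and are never
filtered at simulation time.

The default backend is a hybrid: the neutral equilibrium population is
drawn with msprime (a discrete-time Wright–Fisher phase of up to 1000
generations feeding into the Hudson coalescent, so whole-population
samples are handled correctly), and any selected phase is run by an
explicit forward Wright–Fisher engine on the full 2·Ne haplotype matrix:
per-individual fitness `(1+s)^dosage`, Poisson(ρL) crossovers per gamete
with uniform breakpoints, Poisson(2NeμL) new mutations per generation on
an integer-position infinite-sites grid, and per-generation pruning of
fixed/lost columns.  A pure forward backend (`backend="wf"`, 8·Ne burn-in
generations) is retained and validated against the Watterson prediction
θ_W·a_{n−1} in the test suite; the two backends agree in distribution for
neutral panels.

**Sweep conditioning.**  The selected mutation is injected at frequency
1/(2Ne) and the phase is rejection-sampled: by default the phase stops at
the first generation the population frequency reaches `freq_condition`
(an *ongoing* sweep sampled at the conditioning frequency — the regime
both scans target), bounded by `sweep_duration` generations
(default 250 ≈ 1.5× the deterministic time for s = 0.05 to reach 80%);
with `stop_at_condition=False` the full duration runs and the end state is
checked.  A replicate that loses the allele, or whose *sampled* panel
falls short of the frequency condition, restarts from the same base
population; exceeding `max_tries` raises an error naming the budget.

**Two populations.**  `simulate_pair` duplicates the base population at
the injection generation; the target evolves under selection for T
generations (T = the accepted phase duration), the reference evolves
neutrally for the same T, and both panels are emitted on the union of
their segregating positions (absent sites become monomorphic columns), so
downstream statistics see identical coordinates.

Defaults are human-like per-bp rates (μ = ρ = 1e-8) at a desk-scale
population (Ne = 500, 2 Mb, 50 diploids).  The acceptance studies override
μ and the sample size per statistic (see "Scaled-down study designs").

## Admixture mosaics

`simdata.simulate_tracts` models each haplotype after a single admixture
pulse `g` generations ago as a continuous-position Markov mosaic: switch
points follow a Poisson process of rate `g` per Morgan and the state at
each switch is drawn from the stationary proportions `m`.  Tract lengths
between switch events are therefore exactly Exponential(mean 100/g cM);
`tract_lengths` reports interior (uncensored) segments drawn on a long
internal window (≥ 500 expected switches) so finite-chromosome
conditioning is negligible.  Note a switch may redraw the same ancestry —
tract statistics count switch events, not ancestry changes, which is what
makes the exponential law exact.

**Post-admixture selection at a locus.**  Two boost modes:

* `selection` (default): each haplotype's mosaic is conditioned on its
  ancestry at the locus so the marginal probability of the favoured
  ancestry there is exactly `m + delta`; linked excess decays away from
  the locus on the natural tract-correlation scale 1/g Morgan.  This is
  the generative analogue of selection acting on the locus and dragging
  linked tracts.
* `window`: the redraw distribution at switch points inside
  `sel_halfwidth_cM` is tilted by `delta`, decaying linearly to zero at
  the window edge.  The realised marginal excess at the locus is then
  attenuated by the Markov lag — by the factor 1 − (1 − e^{−gh})/(gh) for
  halfwidth h Morgan — which is why the selection mode is the default:
  with g = 30 and h = 0.1 the window mode expresses only ~68% of delta,
  and narrower windows almost none.

## EHH, iHH and XP-EHH

EHH is population-level: at extension x from a core site,
EHH(x) = Σ_h C(n_h,2)/C(n,2) over distinct haplotype strings spanning the
core through x inclusive; the curve starts at (0, 1) by convention and is
evaluated at each successive site.  iHH is the trapezoidal integral over
genetic distance, left plus right, each side cut at the first site where
EHH drops below the truncation level (default 0.05; a partial trapezoid is
taken to the linearly interpolated crossing).  There is no maximum-
extension cap.  A numba kernel (`ihh_many`) computes iHH at many cores via
incremental cluster refinement and is cross-checked against the plain
Python curve integration and an explicit all-pairs oracle in the tests.

XP-EHH(site) = ln(iHH_target / iHH_ref); sites with either iHH = 0 are
undefined (NaN, logged).  Standardization is genome-wide single-bin
(frequency binning is applied only to SDS): z = (raw − mean)/SD over all
defined test sites of all chromosomes supplied to `xpehh_genome`, with
two-sided normal p-values.  Distances come from the panel's genetic-map
column; a uniform 1 cM/Mb map is assumed (with a warning) when no map is
given.  Because XP-EHH is a log-ratio, a uniform rescaling of the map
cancels exactly.

## Singleton density score

For each test SNP and diploid individual, the nearest singleton **owned by
that individual** strictly left and strictly right of the SNP gives two
distances; a side without a singleton inside the analysis window is
censored at the boundary and contributes a survival term.  Each haplotype
carries a tip-length scale t (t_A ancestral, t_D derived); singletons form
a Poisson process of rate λ·t per bp on each tip, so an individual's
per-side nearest distance is Exponential with rate λ·(t₁ + t₂) and the
left+right sum is Gamma(2).  A gamma-shapes table κ(f, g) may replace the
shape (per-side shape κ/2 with the rate scaled to preserve the side mean);
the identity table reproduces the exponential model.  Variant
observability is treated as equal (the hook exists but is the identity).

The likelihood is profiled over r = log(t_A/t_D) under the
frequency-anchoring constraint f·t_D + (1−f)·t_A = 1, with λ calibrated
per DAF bin from the genome-wide mean nearest-singleton distance (the
censoring-aware exponential MLE: events / total distance, halved to the
per-tip scale).  r > 0 ⇔ derived tips shorter ⇔ derived allele rising;
flipping the polarization of the test SNP negates r exactly.  The standard
error comes from the numerical curvature of the profile log-likelihood;
optimization is bounded (|r| ≤ 8) golden-section.

Raw scores are standardized within DAF bins of 0.05–0.95 in 0.01 steps
(bins with fewer than `min_bin_size` sites merge with the nearest
populated bin) and two-sided normal p-values attached.
`SDSNormalization` lets the bin statistics be fit on one track (e.g. a
neutral background) and applied to another — required when scoring a
candidate region whose own high-DAF bins are contaminated by the signal.

**Known limitation.**  At desk scale (Ne ≈ 500) every genealogical
timescale — the neutral tip length ≈ 2000/n_hap generations — is
comparable to the sweep duration (~170 generations at s = 0.05), so the
tip-length contrast between swept and neutral high-DAF sites is small:
neutral sites with a large derived class already have short derived tips,
and the mandatory DAF-bin standardization absorbs most of the sweep's
additional compression.  Single-site SDS power at this scale is ~10–30%,
far below its power in human-scale cohorts; the test suite measures and
reports this honestly (the sweep-power acceptance test is expected to fail
on its SDS component).  Genome-wide SDS *calibration* under neutrality is
unaffected and passes.

## Peak calling

Thresholds are empirical (type-7) quantiles of the standardized scores
over the genome-wide track: a candidate SNP sits at/above the primary
quantile (0.9999) and is confirmed when the `window_bp` (1 Mb) window
centred on it holds ≥ `min_support` (10) *other* SNPs at/above the support
quantile (0.99995 — deliberately higher than the primary; a config switch
lets the candidate count itself).  Confirmed windows are merged by union;
the summit is the maximum-scoring SNP of the merged interval.  The default
is upper-tail; `score_side="two-sided"` ranks |z|.  For synthetic genomes
of 10³–10⁴ test SNPs the standard quantiles leave fewer supporting SNPs
genome-wide than `min_support`, so the `DESK_SCALE_PEAKS` preset
(0.99/0.995, support 5) is used in the end-to-end studies.

## LAD scan

Per-site ancestry proportions p_j are compared against the mean and SD
computed across the sites of *all* supplied chromosomes (the genome-wide
mean LAD); maximal runs with |z| beyond the threshold are reported with
direction (excess/deficit — the scan is two-sided with direction labels;
excess is the case of primary interest), peak proportion and peak z.
Named presets: strict 4.42 SD and lenient 3 SD; the strict cutoff is
treated as a named constant, not re-derived.  Runs separated by at most
`gap_sites` sub-threshold sites merge (default 0).  `lad_peak_overlap`
intersects LAD regions with selection peaks (half-open intervals, ≥ 1 bp)
to produce the post-admixture selection candidate table.

## Scaled-down study designs (tests and acceptance script)

The pinned study conditions are Ne = 500 and 2 Mb chromosomes; the free
design parameters were chosen once, for statistical adequacy, and are not
tuned per run:

* **XP-EHH sweep power**: μ = 5e-8, ρ = 1e-8, 100 diploids; 10 sweep +
  10 matched neutral replicate pairs standardized together; the detection
  threshold is the 99th percentile of the *neutral* chromosomes' scores —
  at full scale the genome-wide distribution is >99% neutral, whereas at
  desk scale the entire 2 Mb sweep chromosome is inflated, so pooling it
  into the threshold would be circular.  Measured per-replicate power is
  ≈ 0.8.
* **SDS studies**: μ = 1e-7 and 32 diploids (≈ 12 singletons per
  individual over 2 Mb) for sweep panels; μ = 3e-7 and 64 diploids for
  the neutrality calibration, with test SNPs thinned 5× so neighbouring
  sites do not share nearest singletons (the KS uniformity test assumes
  independent sites).
* **End-to-end runs**: 4 chromosomes × 2 Mb, one sweep; ancestry mosaics
  on a 10 cM/Mb map (so the 3.3 cM tracts at g = 30 fit the chromosome),
  boost delta 0.4 at the sweep position; LAD at the strict preset;
  `DESK_SCALE_PEAKS`.

What passing these tests shows: the statistics, filters, normalizations
and peak/region callers behave as specified on data with the assumed
structure (equilibrium neutral background, hard ongoing sweep, single
admixture pulse, error-free phased genotypes and known ancestral states).
What they do not show: robustness to demographic misspecification
(growth, bottlenecks, migration), phasing/genotyping error, ancestral
misassignment, local-ancestry inference error, or background selection —
all absent from the generator by design.

## Numerical conventions

* Coordinates 0-based half-open internally; VCF (1-based) and BED
  converted at the I/O boundary.  Haplotypes 2i, 2i+1 form individual i.
* MAF = min(f, 1−f) of the polarized derived frequency; test SNPs need
  all three diploid genotype classes and MAF ∈ [0.05, 0.95]; singletons
  are never test SNPs but stay available to the SDS scorer.
* Sites with missing genotypes, unknown or mismatching ancestral states
  are dropped and counted in the log.
* Genetic maps interpolate linearly and extrapolate with the terminal
  cM/Mb slope; non-monotone maps are rejected.
* All generators are deterministic given their config seed (numpy
  SeedSequence throughout; child streams are spawned, never reused).
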