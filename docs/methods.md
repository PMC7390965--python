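# Methods

## Experimental design being modeled

The package targets paired ribosome-profiling (ribo-seq) and RNA-seq
time courses: biological replicates of the same tissue sampled at
several times after a stress treatment, with each biological sample
sequenced twice — once as ribosome-protected fragments (RPFs) and once
as randomly fragmented total RNA.  The default configuration is the ER
stress design this package was built around: 2 replicates × 3 time
points (0/6/12 hr) × 2 assays, single-end reads in transcript
coordinates, ~30 nt footprints, a 13 nt distance from an RPF's 5′ end
to the ribosomal P-site, retention windows of 27–32 nt (RPF) and
25–40 nt (RNA).

Translation efficiency (TE) of a gene is the ratio of its RPF count to
its RNA count; the inferential target is the per-gene TE *fold change*
δ_g between the first and last time points.

## Generative / inference model

Counts: RNA-seq libraries are Poisson; ribo-seq libraries are
zero-inflated Poisson (ZIP) with a single global excess-zero
probability π, reflecting technical dropout of footprints over and
above Poisson sampling.  The rate for gene g in library j is

    λ_gj = s_j · μ_g · ρ_g(t_j) · δ_g^{I(rpf, contrast)} · exp(η_{t_j,r_j})

with s_j the known size factor, μ_g baseline abundance, ρ_g(t) the RNA
fold change (ρ = 1 at baseline), η a pairing random effect shared by
the two libraries of one biological sample (η ~ N(0, σ²_pair)), and δ_g
applied only to ribo-seq libraries at the contrast (last) time point.
Libraries at intermediate times inform μ, ρ and η but carry δ = 1; the
TE contrast is deliberately first-vs-last.

Level-2 prior on δ_g: spike-and-slab.  With probability p₀, z_g = 0 and
δ_g = 1 exactly; otherwise δ_g ~ Gamma(a, b).  Defaults a = b = 2 give
slab mean 1 and substantial mass on both up- and down-regulation —
the mixture is direction-agnostic on purpose.

Remaining priors are proper but diffuse: log μ_g ~ N(anchor_g, 10) with
the anchor at the log mean normalized count (location only — the same
anchor initializes the chain), log ρ_g ~ N(0, 5), π and p₀ ~ Beta(1,1),
σ_pair ~ half-normal(1).  Improper priors would break the mixture
update, so "non-informative" is realized as wide-proper.

Choices left genuinely open by the problem, decided here: π is global
rather than per-gene (a per-gene π is unidentifiable at 2 replicates);
(a, b) are fixed constants rather than hyperpriors (configurable in
`ModelSpec`); genes with all-zero RPF but positive RNA stay in the
model (the ZIP spike absorbs them), while genes all-zero everywhere
are removed before fitting.

## Sampler

Metropolis-within-Gibbs, one scan per iteration:

1. log μ_g — per-gene Gaussian random walk, vectorized accept/reject.
2. log ρ_g,t — per-gene random walk per non-baseline time, touching
   only that time's columns.
3. (z_g, δ_g) — joint proposal from the spike-and-slab prior
   (z′ ~ Bern(1−p₀); δ′ ~ Gamma(a,b) when z′ = 1).  Because the
   proposal equals the conditional prior, the Metropolis–Hastings ratio
   reduces to the likelihood ratio over the ribo-seq contrast columns;
   no trans-dimensional machinery is needed.
4. log δ_g — refinement random walk for genes currently in the slab
   (Gamma prior ratio plus log-scale Jacobian), which decouples mixing
   of δ's magnitude from the in/out jumps of move 3.
5. η_{t,r} — scalar random walks.  Because η is informed by every count
   in its sample, its posterior scale shrinks like the inverse root of
   the sample's total count; the initial step size is set to
   2/√(mean sample total) so adaptation starts near the right scale.
6. σ_pair — log-scale random walk against the half-normal prior.
7. π — random walk on the logit scale (Jacobian π(1−π)).
8. p₀ — exact conjugate draw from Beta(1 + #{z=0}, 1 + #{z=1}).

Step sizes adapt every 50 burn-in iterations toward ~30% acceptance and
are frozen afterwards.  Defaults: 2 chains, 6,000 iterations, 1,000
burn-in, thinning 5; seed mandatory, chains seeded by spawning.
Convergence is summarized by split-R̂ and effective sample size
(via arviz) for the globals and a spread of gene-level δ's; R̂ > 1.1 or
degenerate (constant-chain) parameters are flagged, as a warning rather
than a hard failure.

## Decision rule

q_g = posterior probability that z_g = 1 *and* δ_g lies outside
[1/θ, θ] (default θ = 2: an at-least-twofold TE change in either
direction).  Gene selection is direct posterior probability FDR
control: sort by q descending and take the largest prefix whose mean
(1 − q) is ≤ α.  This is the standard Bayesian analogue of
frequentist FDR for posterior error probabilities; ties keep input
order, and the achieved estimate is reported alongside the calls.

## Counting and normalization

A read is assigned to a gene iff its 5′ end shifted by the P-site
offset (estimated per length for RPFs; 0 for RNA) lands inside the CDS
(0-based, half-open, transcript coordinates; cds_start = utr5_len, so
"13 nt upstream of the start codon" means five_prime_pos =
cds_start − 13).  Size factors anchor to a housekeeping gene:
s_j = (reference count in j) / geometric mean over libraries, which
leaves the reference's normalized values equal everywhere and the
factors' product at 1.  The factors enter the Bayesian model as known
offsets — the model always sees raw counts.  Naive TE tables average
normalized counts over replicates before ratios; zero-RNA genes yield
flagged missing TE rather than pseudocount-inflated values (a
pseudocount is available behind an explicit argument).

## QC conventions

* Metagene profiles average raw 5′-end counts per position across
  transcripts with ≥ 1 read in the window — no per-transcript depth
  normalization, and transcripts with no local reads are excluded from
  the mean.  Whether to average over all or only locally covered
  transcripts is a genuine convention choice; the covered-only rule is
  used consistently and keeps sparse libraries comparable.
* P-site offset search runs over d ∈ [8, 18] nt (bracketing known
  eukaryotic offsets), maximizing the count of 5′ ends at
  cds_start − d; ties break toward smaller d.
* Frame fractions use P-sites strictly inside the CDS; the periodicity
  statistic is the 2-df chi-square against a uniform frame split.
* Replicate correlation is Pearson on log(count + 1); the log tames the
  heavy right tail of expression.
* The out-of-frame peak upstream of stop codons is reported as a
  diagnostic (position and frame of the stop-window maximum), not
  modeled mechanistically.

## Synthetic-data generator

The generator emulates: library depth variation (log-normal size
factors, SD 0.2), a shared pairing effect per biological sample
(log-normal, SD 0.1), a log-normal baseline abundance spectrum
(log-mean 4, log-SD 1.5 — a realistic dynamic range of ~4 orders of
magnitude), RNA fold changes for 30% of genes (log-SD 1, interpolated
geometrically across intermediate times to mimic gradual induction),
spike-and-slab TE changes (p₀ = 0.8, Gamma(2,2) slab), ZIP dropout
π = 0.1 (the observed zero excess in real footprint libraries is not
published for this design; 0.1 is a placeholder choice, not a measured
value), and positional reads with configurable frame preference
(default 0.7/0.2/0.1), P-site offset (13 nt) and a 4× initiation-pause
occupancy of the first codon.  The start-codon pause is what makes the
P-site offset identifiable from synthetic data — with perfectly uniform
codon occupancy the offset would only be known modulo 3 — and it
mirrors the elevated start peak real metagene profiles show.

A high-abundance housekeeping gene (2% of library depth, no fold
change, exempt from dropout) is included by default so reference
normalization works end to end on synthetic data; its dropout
exemption reflects its role as a stable anchor.

What the generator does *not* emulate — and what passing tests
therefore do not establish about real data: sequencing error, adapter
artefacts, rRNA/ncRNA contamination, multi-mapping and isoform
ambiguity, gene-specific dropout rates, overdispersion beyond Poisson
(real RNA-seq is usually negative-binomial-ish; the model inherits the
Poisson assumption deliberately), and biased codon-level pause
landscapes beyond the single initiation peak.

## Numerical choices

* ZIP log-pmf is computed in log space via `logaddexp`; λ = 0 and
  π ∈ {0, 1} are handled as exact limits.
* The one-gene validation posterior integrates over a
  161 × 161 × 241 (log μ, log ρ, log δ) grid with trapezoid weights and
  log-sum-exp accumulation; MCMC agreement is measured by total
  variation on the spike plus a 4×-coarsened δ partition (≈ 60 cells),
  fine enough to resolve the slab's shape while keeping per-cell
  Monte-Carlo noise well below the 0.05 agreement threshold.
* FDR prefix search is exact (cumulative means, stable sort).
* Degenerate inputs: empty read sets give empty histograms/zero
  profiles; an empty candidate window or absent reference gene raise
  errors naming the offender; single-chain runs refuse to produce
  convergence diagnostics.

## Problem sizes used in tests and the acceptance script

Chosen as desk-scale defaults adequate per the R̂/ESS diagnostics: the
1,000-gene recovery run uses 2 chains × 2,500 iterations (burn-in 600,
thin 4); calibration re-simulates 20 (test suite) or 10 (acceptance
script) 300-gene experiments with 1 chain × 1,500 iterations; one-gene
quadrature comparisons use 2 chains × 9,000 iterations.  QC recovery
uses 100,000 reads over 200 transcripts.

## Known limitations

Poisson/ZIP likelihoods understate biological overdispersion, so on
real data the model is anti-conservative relative to a
negative-binomial treatment; normalization to a single housekeeping
gene inherits that gene's measurement noise (a multi-gene or
median-of-ratios anchor would be more robust but changes the method);
the TE contrast is strictly two-point; and the sampler's independent
per-gene moves mix slowly if genes ever became coupled through shared
hyperparameters beyond (π, p₀, σ_pair).
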