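# Methods

`flowsplice` identifies candidate regulatory splicing factors from
differential cassette-exon (skipped exon, SE) usage. Starting from
MISO-style Psi/Bayes-factor comparison tables, it selects nested sets of
regulated exons, extracts the intronic sequence flanking each exon, scores
k-mer enrichment against expression- and Psi-matched backgrounds within GC
bins, and ranks RNA-binding-protein (RBP) motif "fingerprints" by a
GSEA-style Kolmogorov–Smirnov statistic with permutation significance.

## Event selection cascade

Inputs are per-event, per-comparison records of (Psi_a, Psi_b, Bayes
factor), with ΔΨ = Ψ_a − Ψ_b fixed as condition-of-interest minus
reference (low flow minus high flow). Five rules are applied, the first
four nested:

1. **Flow-regulated** — BF > 5 in both of two independent low-vs-high-flow
   comparisons, consistent ΔΨ sign, and min(|ΔΨ₁|, |ΔΨ₂|) > 2 × the
   replicate-control |ΔΨ| (high-flow vs high-flow). Using the *minimum* of
   the two flow effects for the ratio clause is the conservative choice of
   which comparison the ratio applies to.
2. **Endothelial** — the cultured-endothelial-cell comparison recapitulates
   at least 50 % of the mean in vivo flow ΔΨ (inclusive bound, signed).
3. **Platelet-regulated** — platelet depletion reverts the flow-induced
   change by more than 50 % (reversion fraction 1 − ΔΨ_depl/ΔΨ_IgG) in both
   of two independent comparison pairs (strict bound; over-reversion past
   the baseline counts as reverted).
4. **In-vitro-factor-regulated** — adding platelets, macrophages and plasma
   to cultured cells reproduces more than 50 % of the flow change (strict).
5. **Rbfox2-regulated** (reported separately, over the flow-regulated set)
   — knockout BF > 5 in ≥ 1 of three comparisons (in vivo low flow, in vivo
   high flow, in vitro) and a consistent ΔΨ sign across all in vivo
   low-flow knockout comparisons; events are labelled *reverted* when that
   sign opposes the flow-induced direction, else *same*.

Strictness follows the wording of each rule (">" strict, "at least"
inclusive) and is configurable. Events missing any required comparison are
excluded, never imputed; every event receives an audit row naming the
clause that decided it, so the selection funnel is reconstructable.

## Flanking regions

For each selected exon, up to 200 nt of intron adjacent to the 3'SS
(upstream flank) and 5'SS (downstream flank) are extracted strand-aware in
transcript orientation. Flanks never cross out of their intron: shorter
introns yield truncated, flagged flanks. No splice-site consensus or
polypyrimidine-tract masking is applied — the flank starts at the first
intronic base. Crossed with the direction of the inclusion change this
gives four analysis regions: (upstream | downstream) × (increased |
decreased).

## Matched backgrounds and GC bins

Regulated exons sit at more intermediate Ψ and in more highly expressed
genes than the bulk of annotated SEs, so naive backgrounds would confound
motif enrichment with covariates. The eligible pool is all annotated SEs
in expressed genes (FPKM ≥ 1) that are not flow-regulated. Six background
sets are drawn from this pool, each reproducing the foreground's joint
histogram over expression deciles × five |Ψ − 0.5| strata (stratum edges
are pool quantiles; sampling is without replacement within a set; starved
strata fall back to the nearest stratum with replacement, logged). Joint
matching is the default because it is stricter than matching each marginal
independently; marginal matching is available (`match_mode`). Sets may
overlap each other but never the foreground, and they are resampled across
iterations (below), which is where the across-set variability used by the
z-score comes from.

k-mer frequencies are compared within ten GC bins whose edges are
quantiles of the pooled background flank GC (quantile rather than
fixed-width bins, so no bin is empty at the GC extremes); ties at an edge
go to the lower bin.

## k-mer enrichment z-scores

For k-mer m, GC bin b, background set s:

    e(m,b,s) = log2((f_fg(m,b)+p) / (f_bg(m,b,s)+p)) − log2(E_fg(m,b) / E_bg(m,b,s))

where f are within-bin frequencies (overlapping occurrences; windows with
N skipped; frequencies rather than counts so set-size imbalance cancels),
p = 1/min(window totals) is a pseudo-frequency keeping ratios finite, and
E is the k-mer's expected frequency under an order-1 Markov background
model fitted, with add-one smoothing, to the same bin's own sequence.

The composition term matters. A finite foreground's realized base and
dinucleotide content fluctuates, and those fluctuations move *all*
compositionally similar k-mers coherently. Motif member sets are
compositionally clustered, so without the correction the fingerprint
stage's permutation null (random k-mer sets) is anticonservative.
Fitting the expectation to the very same windows removes the realized
fluctuation while leaving k-mer-specific (site-level) enrichment intact.
`composition_order` selects 1 (default), 0 (mononucleotide) or None
(plain ratio).

Per-set scores are pooled over bins with weights equal to the foreground
k-mer mass per bin, E(m,s) = Σ_b w_b·e(m,b,s), and

    z(m) = mean_s E(m,s) / sd_s E(m,s)   (sample sd over the six sets).

z is undefined (excluded from ranking) when the sets show no spread,
except in the exact identity case (mean 0, spread 0) where z = 0. Because
the matched sets are themselves one random draw, the computation is
iterated (default 100 rounds) over freshly resampled background sets and z
averaged across rounds. K-mers are ranked by descending z, ties broken
lexicographically.

## RBP fingerprints

A CisBP-RNA-like plain-text PWM catalogue is bridged to the ranking by
member k-mer sets: a k-mer belongs to a motif iff its best base-2 log-odds
score (vs. a uniform background) over all k-wide windows of the matrix
reaches 80 % of that window's maximum attainable score; matrices shorter
than k are padded with uniform columns on both sides, and U↔T are mapped
at the RNA/DNA boundary.

The enrichment score is the unweighted GSEA running sum (hits +1/Nh,
misses −1/(N−Nh); ES = the deviation of maximum magnitude, signed; first
such position on ties). Leading edge: members at or before the extremum
for positive ES, at or after it for negative ES.

Significance is by permutation: for each motif, 1,000 random member sets
of matched size are drawn from the ranked universe and p = (1 + #{ES_null ≥
ES_obs}) / 1001 — one-sided, because the scientific question is abundance
at the *leading edge*; a two-sided test also flags compositional clumping
among the never-observed k-mers at the bottom of the ranking, which is not
a binding signal. Two refinements keep this null honest:

* **Independent draws per motif.** Sharing one null across same-size motifs
  correlates their p-values exactly in the extreme tail, which breaks
  Benjamini–Hochberg behaviour.
* **Overlap-aware null sets.** Two k-mers that are offset copies of each
  other (suffix of one = prefix of the other) share every occurrence of
  the merged (k+d)-mer, giving count correlation ≈ 4⁻ᵈ — measured here as
  z-correlation 0.25 for d = 1 against 0.004 for random pairs. Member sets
  derived from one PWM are full of such pairs (windows of a common
  consensus), so independent null draws understate their ES spread. Null
  rank vectors are therefore drawn through a Gaussian copula whose
  correlation is 4⁻ᵈ for shift-d member pairs (marginally each rank stays
  uniform). With this null the planted-motif recovery and null-calibration
  checks pass simultaneously; with independence draws they do not.

Benjamini–Hochberg FDR is applied across motifs within each region. The
region summary adds, per motif, the mean z of its top-5 member k-mers —
the "average z-score enrichment" view of family-level motif support.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes,
with defaults at the study conditions: 300 regulated foreground SEs (half
increased, half decreased inclusion) and a 3,000-event unregulated pool on
a toy contig; intron lengths 400–800 nt; per-event mean GC ~ Beta(9, 11)
(mean 0.45, roughly intronic), bases i.i.d. given it; foreground Ψ ~
Beta(5, 5) (intermediate), pool Ψ ~ Beta(0.45, 0.45) (U-shaped); foreground
expression log-normal(1.8, 1.0) vs pool log-normal(1.0, 1.2), so matching
is actually exercised. Flow effects are ±0.3 ΔΨ observed through Gaussian
noise (sd 0.02); the Bayes factor is generated, not inferred, by the
monotone map BF = exp(0.5·|ΔΨ|/σ) — the cascade only thresholds BF, so any
strictly monotone map exercises it. Dependence structure is nested (90 %
endothelial, one third of those platelet-dependent, half of those
in-vitro-dependent; 25 % Rbfox2-dependent independently), with reversion
fraction 0.8 in the depletion/knockout arms and recapitulation 0.9 vs 0.1
for dependent vs independent events.

The Rbfox analogue plants the 6-mer TGCATG at rate 0.6 into the downstream
flanks of decreased-inclusion foreground exons, overwriting bases at a
uniform offset wholly inside the flank (reverse-complemented onto
minus-strand genomic sequence) so coordinates and GC are preserved.

The fixture motif catalogue has 85 motifs, the scale of a curated RBP
signature collection: five Rbfox-family variants that extend the (U)GCAUG
core to either side (so their member 6-mers are exactly the words a
planted UGCAUG element produces — the element itself and its junction
extensions), one poly-A point-mass decoy, and 79 random decoys of length
5–8 and varied sharpness whose member sets are kept disjoint from the
GCATG/TGCAT cores so that recovery is attributable.

What the generator does *not* emulate: real splice-site consensus and
branch-point sequence, higher-order (≥ 2) sequence composition,
conservation structure, intron-length correlations, multiple planted
motifs, or MISO's posterior uncertainty. Passing tests therefore
demonstrate that the pipeline recovers planted signal and stays calibrated
under this generative model, not that it would be calibrated on real
introns, whose composition structure is richer (the order-1 correction
would absorb less of it).

## Numerical and design notes

* Coordinates are 0-based half-open throughout; Ψ is stored as a fraction,
  with percent-scale input auto-detected and rescaled.
* One top-level seed derives all stage streams (`numpy` `SeedSequence`);
  identical inputs + seed give byte-identical outputs.
* Problem sizes in the test suite: full-scale checks run 20 seeds at the
  study conditions above; module oracles run exhaustively at small N
  (every member subset of rankings to N = 10; 4⁶ enumeration against 50
  random PWMs; 1,000 random events for flank extraction).
* Known limitations: the copula null matches second-order overlap
  structure only (higher-order clustering among member k-mers is not
  modelled); quantile GC bins collapse when flank GC is nearly constant;
  with-replacement fallback in starved matching strata slightly reduces
  background diversity; the k=7 path reuses the k=6 machinery but its
  member sets are sparser, so fingerprints are noisier at equal foreground
  size.
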