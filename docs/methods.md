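# Methods

## Model

A genomic *estimation region* containing N CpG sites carries a joint
distribution over methylation patterns x ∈ {0,1}^N of Boltzmann form

    P(x) = exp(−V(x)) / Z,
    V(x) = − Σₙ αₙ x̃ₙ − Σₙ βₙ x̃ₙ x̃ₙ₊₁,    x̃ = 2x − 1,

the one-dimensional nearest-neighbour Ising model. Each pattern is assigned
a potential V(x); deep narrow potential wells mean a few patterns dominate
(low stochasticity), flat landscapes mean many patterns are comparably
likely (high stochasticity). The per-site field and per-pair coupling are
tied to genomic covariates so a region has only three free parameters:

    αₙ = a + b·ρₙ,        βₙ = c / dₙ,

where ρₙ is the local CpG density ((count within ±500 bp)/500, in [0,1]),
and dₙ the distance in bp between adjacent CpGs, capped at 1,000 bp so
couplings vanish smoothly across long gaps. Sign convention: positive `a`
favours methylation (this is our declaration; nothing upstream forces a
choice), `b` modulates the field with CpG density, and positive `c` makes
neighbouring sites agree (cooperativity → ordered, low-entropy landscapes).
Box constraints |a|,|b| ≤ 10 and |c| ≤ 20 keep the landscape numerically
sane; a fit ending on a bound is reported as-is.

All exact quantities use 2×2 transfer-matrix dynamic programming in log
space: the partition function and the forward/backward messages in O(N);
the marginal probability of a read with unobserved sites by clamping
observed sites in the in-window propagation and closing with the boundary
messages; the *methylation-level distribution* P(L = k/K) of a K-CpG
analysis subregion by augmenting the transfer matrix with a methylated-site
counter restricted to the subregion's sites (O(N·K), linear space with
per-step rescaling). For N ≤ 10 everything is verified against full 2^N
enumeration to 1e-10 relative error.

## Summary statistics

Per analysis subregion, from the fitted model's level distribution (never
from the empirical read histogram, which is retained only as a diagnostic):

* **MML** = Σₖ (k/K) pₖ — mean methylation level, in [0,1].
* **NME** = H(p)/log₂(K+1) with H in bits — normalized methylation
  entropy; 0 = deterministic landscape, 1 = maximally stochastic.
* **JSD** — the Jensen-Shannon *distance* (square root of the divergence,
  base-2 logs) between the test and reference level distributions of the
  same subregion; a metric in [0,1], 0 for identical distributions, 1
  exactly for disjoint-support (maximally discordant) ones. Computed via
  `scipy.spatial.distance.jensenshannon`; tests check it against an
  independent direct-summation implementation to 1e-12. Zero-probability
  cells contribute 0 to their own KL term, and the mixture is positive
  wherever either argument is, so no division by zero arises.

All entropies and divergences use base-2 logarithms throughout, which is
what puts NME and JSD on exact [0,1] scales.

dMML and dNME are test-minus-reference differences per subregion. Paired
genome-wide comparisons use the two-sided Wilcoxon signed-rank test over
subregions shared by both samples; with fewer than 10 shared subregions the
p-value is reported undefined, and for identically zero differences it is
1 by convention.

## Estimation

Regions are genomic tiles of 3,000 bp (estimation) subdivided into 150 bp
analysis subregions (both configurable; the spans were fixed before any
data were simulated and 3,000 must be a multiple of 150). Reads spanning an
estimation-region boundary are split at the boundary and treated as
independent fragments, which keeps each region's likelihood self-contained
at the cost of discarding a handful of cross-boundary couplings.

(a,b,c) maximize the summed log marginal likelihood of the region's
fragments (unobserved sites integrated out exactly). The optimizer is
Nelder-Mead inside the box from a fixed 3×3×3 start grid
({−5,0,5}×{−5,0,5}×{−10,0,10}), function tolerance 1e-6, best objective
wins with ties broken by lowest start index — derivative-free, and
deterministic for a given fragment set. A region is fit only with ≥ 20
informative reads; a subregion is scored only with ≥ 5 reads observing at
least one of its CpGs in the sample (both configurable; chosen as ordinary
coverage hygiene, not tuned).

Identifiability caveat: when ρ is nearly constant across a region (uniform
spacing), `b` is unidentifiable — only a + b·ρ̄ is determined — and the
fitted `b` may sit on its bound while `a` compensates. This is harmless for
MML/NME/JSD (they depend on α only through its value) but means parameter
tables should not be read as per-parameter estimates in flat-density
regions. `fit_parameters(fix_b=0.0)` pins `b` for such regions. The
parameter-recovery tests use a region with a dense upstream CpG flank so
that ρ spans ≈ 0.24–0.53 and all three parameters are identified.

## Gene and feature ranking

Genes are ranked by the **maximum** subregion JSD within ±2 kb of any TSS
annotated to the gene symbol (the statistic is a max, not a mean, because
the ranking is by *highest* local discordance); alternatively by maximum
dNME in the same window, or by a CpG-count-weighted mean JSD over the gene
body. Ties are broken by genomic position, so the ranking is invariant to
gene-table input order. Multiple TSSs per symbol score the union of their
windows.

Significance is a read-label permutation test: pool both samples' fragments
in the region, reassign labels preserving group sizes, refit both models,
recompute the region-level JSD; p = (1 + #{null ≥ observed})/(1 + n_perm)
with 199 permutations by default and Benjamini-Hochberg adjustment across
genes. The observed statistic and every null replicate use the identical
fitting procedure, which is what makes the null exchangeable; for large
calibration suites the optimizer start grid may be reduced (e.g. a single
start) — applied identically to observed and null fits — trading
optimization thoroughness for speed without breaking validity.

Feature summaries assign each scored subregion to the annotation interval
covering its midpoint ("none" if uncovered) and report per-label medians
and IQRs of dMML/dNME/JSD. Meta-profiles average a track in signed,
strand-aware distance bins around anchors (TSSs, feature centers): positive
distance is always downstream of the anchor.

## Synthetic data

The generator emulates only the features the statistics are sensitive to:

* **CpG map** — islands with exponential lengths (mean 1 kb) covering a
  configurable fraction of each chromosome; geometric inter-CpG gaps with
  mean 20 bp inside islands and 120 bp in open sea (minimum 2 bp); shores =
  2 kb island flanks, shelves = the next 2 kb. Every ⌊1/f⌋-th island is
  relabeled a bivalent promoter (f = 0.1 by default) and the longest open
  sea gaps get central heterochromatin blocks — both deterministic given
  the island layout, so every feature class is present even in small
  genomes.
* **Reads** — exact draws from each region's Ising distribution by
  forward-filtering/backward-sampling of the window marginal; each read
  covers a fixed number of consecutive CpGs (10 by default, depth 10 reads
  per CpG), and each covered site is masked unobserved i.i.d. at the miss
  rate (5%). Ground truth records the generating (a,b,c) and the *exact*
  model MML/NME of every subregion.
* **Tumor/normal pair** — normal: open sea/heterochromatin a = +2.5,
  islands and bivalent promoters a = −3.0, shores +1.0, shelves +2.0
  (shores intermediate but majority-methylated, shelves sea-like), all
  with b = 0 and c = +4.0 (strongly bimodal, low-entropy landscapes).
  Tumor: fields multiplied by 0.4 and c reduced to +1.0 — global
  hypomethylation of the sea together with globally elevated entropy —
  except bivalent-promoter regions, whose field flips to +2.0 (focal
  hypermethylation). Profiles are assigned per estimation region by the
  majority feature label of its sites; a feature run straddling a region
  boundary can therefore leave a few edge subregions governed by the
  neighbour's profile, which blurs but does not reverse the planted
  medians.

What the generator does *not* emulate: bisulfite conversion errors,
sequencing quality, alignment artifacts, copy-number structure, real
genome coordinates, or biological replicate variability. Passing tests
therefore demonstrate that the estimator and statistics recover planted
model structure from model-generated reads — not that the model is
adequate for any particular real methylome.

## Problem sizes and numerical choices

Test and demonstration runs use single-chromosome genomes of 0.1–1.4 Mb,
chosen so the planted-contrast suite scores ≥ 5,000 subregions and the
parameter-recovery study runs 50 replicates of 2,000 reads on a 20-CpG
region; these sizes are the package's own desk-scale study conditions.
Null calibration of the permutation test uses 50 independent same-parameter
regions at 199 permutations with a single optimizer start (see above).
Degenerate inputs are handled explicitly: fully-unobserved reads are
dropped, CpG-free subregions are never emitted, K = 0 has no level
distribution, and log-space accumulation keeps 200-site regions at the box
bounds finite.

## Known limitations

* The three-parameter covariate tying is a modelling choice; it cannot
  express within-region heterogeneity beyond what ρ and d carry.
* Permutation refitting is expensive (two fits per permutation per
  region); genome-wide significance is practical only for top-ranked genes
  or with the reduced start grid.
* The empirical-histogram mode requires reads that span a whole subregion
  and is a diagnostic, not a substitute for the model-based statistics.
* Nelder-Mead with a fixed grid can in principle miss the global optimum
  in pathological likelihoods; the enumeration and recovery tests bound
  this risk only at the tested sizes.
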