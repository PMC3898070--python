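# Methods

## The problem

The three subfamilies of Spalacidae — zokors (Myospalacinae), bamboo rats
(Rhizomyinae) and blind mole rats (Spalacinae) — have been grouped in all
three possible ways by earlier single-gene and morphological studies. With
four taxa (the three spalacids plus mouse as outgroup) an unrooted gene
tree has exactly three topologies:

* **T1 = ZB|SO** — zokor + bamboo rat sisters,
* **T2 = ZS|BO** — zokor + blind mole rat sisters,
* **T3 = BS|ZO** — bamboo rat + blind mole rat sisters.

The analysis infers a maximum-likelihood tree per orthologous gene,
censuses which topology each well-supported gene tree favours, and tests
the three counts against a uniform 1/3–1/3–1/3 null with a chi-square
(df = 2). A significant excess of one topology over thousands of
independent loci resolves the subfamily trichotomy even when ~60 % of
individual genes disagree — the expected signature of a short internal
branch (rapid successive speciations), under which incomplete lineage
sorting and estimation noise distribute the minority genes over the two
alternative topologies.

## Model and likelihood

Gene trees are evaluated under the standard time-reversible nucleotide
model family. A model is a scheme of exchangeabilities r = (r_AC, r_AG,
r_AT, r_CG, r_CT, r_GT), base frequencies π, optionally a proportion of
invariant sites p_inv (+I) and discrete-gamma rate heterogeneity with
shape α over k = 4 equal-probability categories (+G). The generator is
q_ij = r_ij π_j (i ≠ j), scaled so −Σ π_i q_ii = 1, i.e. branch lengths
are expected substitutions per site at rate 1. Transition probabilities
P(t) = exp(Qt) are computed by symmetrizing Q with diag(√π) and taking a
real eigendecomposition.

Site likelihoods use Felsenstein pruning over the two internal nodes of
the quartet with site-pattern compression (at most 4^4 = 256 unambiguous
patterns, so genes of any length cost the same). Gaps and ambiguity codes
are treated as missing data (leaf partial likelihood 1 for all states).
The mixture is

    L_site = p_inv · L(rate 0) + (1 − p_inv) · (1/k) Σ_c L(rate r_c)

with the discrete-gamma rates r_c normalized to mean 1 (so under +I
branch lengths are substitutions per *variable* site; the two conventions
differ only by a reparameterization of branch lengths).

The discrete-gamma category rates are mean-of-quantile-bin values,
computed through the regularized incomplete gamma function with the
shape+1 identity and renormalized to mean exactly 1.

**Fitting.** For a given topology the five branch lengths and the family's
free continuous parameters are maximized by coordinate ascent: a bounded
Brent line search per branch (bounds [1e-8, 10]) alternating with
Nelder–Mead over log-exchangeabilities, logit-p_inv and log-α, until the
log-likelihood improves by < 1e-6 over a full round (max 50 rounds).
Starting values: branches 0.1, exchangeabilities 1, p_inv 0.01, α 1;
base frequencies for unequal-frequency families are empirical counts held
fixed (the jModelTest convention). +I+G is accepted despite its weak
identifiability at quartet scale; the selection criteria arbitrate.

**Model selection.** The catalog is the jModelTest-style set of 11
substitution schemes × {equal, empirical frequencies} × {plain, +I, +G,
+I+G} (88 models), selectable down to {JC, HKY85, GTR} × {+G} for
pipeline-scale runs (the reduced catalog is what the analysis scripts and
the scaled pipeline checks use). K counts free exchangeability classes
(minus the one fixed to 1), 3 frequency parameters when unequal, p_inv
and α when present, plus 5 branch lengths; AIC = −2lnL + 2K and
BIC = −2lnL + K ln(n_sites) follow definitionally. Ties go to fewer
parameters, then catalog order. Selection runs **once per gene**, on the
topology with the best preliminary JC likelihood; the selected family is
reused for all three topologies and all bootstrap replicates.

**Bootstrap.** Nonparametric support resamples nucleotide columns with
replacement — implemented as a multinomial redraw of site-pattern counts,
which is distributionally identical and orders of magnitude faster. Each
replicate re-optimizes branch lengths per topology starting from the
full-data optimum (one coordinate-ascent pass with a looser Brent
tolerance — branch lengths barely move between replicates, and only the
identity of the winning topology matters). In fast mode (the default in
the drivers) the continuous model parameters stay frozen at their
full-data estimates; full re-optimization is available and is the library
default. Exact likelihood ties (within 1e-9) split the replicate's credit
equally, so signal-free alignments report supports (1/3, 1/3, 1/3).

**Concatenated analysis.** The supermatrix analysis shares one topology
and one set of branch lengths across all gene partitions, with
per-partition GTR+G parameters (or a single pooled parameter set in
`single_partition` mode). Given the branches the total likelihood is
separable, so each partition's parameters are optimized independently
between rounds of shared branch-length optimization. The bootstrap
resamples sites within partitions.

## Fourfold-degenerate sites

A 4D-site is a third codon position where all four bases encode the same
amino acid (the 8 codon families TC, CT, CC, CG, AC, GT, GC, GG). A
third-position alignment column qualifies only when, in **all four taxa**,
the codon is free of gaps/ambiguity and the first two positions are
identical across taxa with the shared 2-mer in a fourfold family — the
strict reading under which every observable third-position difference is
guaranteed synonymous. Two deliberate choices, both isolated behind
`identify_4d_columns`:

* codons containing gaps or ambiguity in *any* taxon are disqualified
  (conservative, matching common codeml "cleandata" practice);
* cross-taxon prefix identity is required, not merely per-taxon fourfold
  status (the alternative is defensible but weaker).

Coordinates are 0-based half-open internally and 1-based inclusive in
partition files. Inputs are assumed in frame (`frame_offset` defaults
to 0); a trailing partial codon is ignored with a warning. Alignments
shorter than 100 bp are discarded before any analysis (strictly below:
99 bp drops, 100 bp stays).

## Saturation test

Substitution saturation is diagnosed by comparing the mean observed
per-site Shannon entropy H (base 2, gapped/ambiguous columns skipped) to
the expected entropy at full saturation H_fss, where each taxon's base is
an independent draw from the empirical base composition (exact 4^n-pattern
enumeration for n ≤ 6 taxa, seeded Monte Carlo beyond). The index
Iss = H / H_fss is compared against a critical value Iss.c with a
one-sample t statistic over per-site entropies (two-tailed p, df =
n_sites − 1); an alignment counts as *unsaturated* only when Iss is
significantly below Iss.c. The published regression constants for Iss.c
are not copied; Iss.c is either user-supplied or estimated operationally:
simulate symmetric quartets of matched length at increasing divergence and
interpolate the Iss at which the true topology is recovered in only 50 %
of replicates (200 by default; the saturation driver uses 60 per level,
which is stable to ~0.02). Because the source study reports only p-value
bands for this step, the checks here are property-based: the
mitochondrial-like 4D concatenation must show strictly higher Iss than a
rate-matched nuclear one, and Iss must grow with total tree length.

## Synthetic data

The generator produces the statistical structure the analysis consumes —
it makes no attempt at sequence-level realism beyond what the pipeline
reads:

* **Topology mixture** (default 0.39/0.34/0.27, the observed census
  proportions): each gene's generating topology is an iid draw. The
  mixture is phenomenological; no coalescent model is implied.
* **Tree shape**: external branches (0.05, 0.05, 0.05, 0.10) — the longer
  one for the mouse outgroup — and a short internal branch τ = 0.02
  substitutions/site, consistent with the "very short branch" the study
  highlights.
* **Lengths**: gamma-distributed codon counts (mean 361 codons = 1,083 bp,
  matching the reported 5,541,534 bp / 5,116 genes; shape 6, floored at
  34 codons so the 100-bp filter can pass). The mitochondrial preset uses
  13 fixed lengths summing to exactly 11,307 bp and scales all branches
  ×5, so saturation behaviour diverges between the presets.
* **Substitution process**: κ = 4 transition bias with uniform base
  frequencies by default; roots are drawn codon-wise from the stop-free
  product law of the base frequencies (uniform frequencies keep the
  fourfold families at ~52 % of root codons, which puts the realized
  nuclear 4D fraction near the reported 12.92 % — strongly skewed
  compositions push it well below). Coding constraint is approximated by
  per-codon-position rate multipliers (1.0, 0.5, 2.5) — position 3
  fastest — which is all that 4D extraction and saturation need. Stop
  codons are excluded at the root but not forbidden after substitution;
  nothing downstream translates.
* **Reproducibility**: one RNG per gene keyed by (seed, gene index), so a
  gene's sequences are invariant to how many genes are generated.

What passing simulated-data tests does **not** show: robustness to
alignment error, indels, paralogy, base-composition heterogeneity across
lineages, or within-gene rate variation beyond codon position — real
transcriptome data contain all of these.

## Problem sizes and numerical choices

Scaled-down sizes used by the test suite and drivers (chosen once, as the
package's own desk-scale study conditions): the end-to-end pipeline check
runs 200 genes at the observed mixture with the reduced catalog and fast
bootstrap; topology-recovery uses 20 genes of 1,000 codons at τ = 0.2;
model-selection consistency uses 20 replicates of 5,000 sites; census
calibration uses 100 replicate censuses of 300 genes; the analysis
drivers default to 100 nuclear genes. A power note: at 200 counted genes
the census chi-square has noncentrality ≈ 4.4 under the default mixture,
so its p-value sits near the 0.05 boundary by design of the mixture
itself; at the study's ~4,300 counted genes the same mixture gives
p < 0.001 essentially always (the calibration tests cover both regimes).
The concatenated bootstrap behaves the same way: the log-likelihood gap
between the two leading topologies grows with the T1–T2 gene-count
margin while its resampling spread grows only with √(total sites), so a
200-gene supermatrix can report intermediate support (0.7–0.99 depending
on the realized margin) where the full ~5,000-gene matrix saturates
at 1.00.

Degenerate inputs: an alignment with a single site pattern yields equal
likelihoods and (1/3, 1/3, 1/3) supports by the tie rule; empty censuses
and zero-length 4D concatenations raise informative errors; genes whose
4D mask is empty contribute no partition to the 4D supermatrix.

## Known limitations

Quartets only (exhaustive evaluation replaces tree search); no Bayesian
MCMC — externally computed posterior supports enter the census through
the same tally path as bootstrap values; no codon or amino-acid models;
no indel or alignment-error simulation; +I+G parameters are reported as
fitted even where weakly identified.
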