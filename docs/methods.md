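# Methods

## The comparison model

Every analysis in this package reduces to comparing amino-acid usage
frequencies between an oxidant-exposed protein set (the *numerator*
condition) and a reference set (the *denominator*). Within-species
paradigms compare two compartments of the same proteome (peroxisome vs
whole proteome; mitochondrion vs whole proteome; mitochondrially encoded
respiratory-chain subunits vs all mitochondrial proteins); these are
computed per species and averaged. Group paradigms compare mean
frequencies of two species groups (aerobic vs facultatively anaerobic
animals; aerobic vs anaerobic prokaryote groups). A usage ratio of 1
means unchanged usage; effect sizes are measured by the factorial
deviation `d = max(R, 1/R)`, which treats a halving and a doubling as
equally strong.

## TMD-content normalization

Membrane-spanning segments are strongly enriched in hydrophobic residues,
and the compared protein sets differ enormously in their share of
transmembrane residues (a few percent for mitochondrially imported
proteins, above half for mitochondrially encoded subunits). Comparing raw
frequencies would therefore read hydrophobicity as adaptation. The
normalization pools each set's residues into a TMD pool and a non-TMD
pool and blends them at a common TMD content `c`:

    f_a(c) = c · f_a^TMD + (1 − c) · f_a^nonTMD,   R_a = f_a^num(c) / f_a^den(c)

Properties: the blend always sums to 1; at `c = τ` (the set's own TMD
fraction) it reproduces the raw unsegmented frequencies; when both sets
share the same τ the ratio is independent of the policy that picks `c`
among τ-derived choices; and with the symmetric default policy
(`c` = mean of the two τ values) the ratio is antisymmetric under
swapping numerator and denominator. The combining order is configurable:
blend-frequencies-then-divide (default) or form TMD-to-TMD and
non-TMD-to-non-TMD ratios first and combine with weight `c`; both
coincide when the τ values match. Normalization applies to the
compartment paradigms only; group paradigms use raw frequencies.

Zero denominator frequencies yield an *undefined* marker rather than a
pseudocount — pseudocounts would bias exactly the rare amino acids (C, W)
the analysis cares about. TMD annotations come from TMHMM-2.0 output
(long or short format); where none exist, a Kyte–Doolittle sliding-window
predictor (window 19, threshold 1.6, runs of above-threshold centers
merged when closer than 5 and expanded by half a window) provides a
fallback. It is a deliberately simple hydropathy heuristic, not a
re-implementation of the TMHMM model.

## Statistics

* **Kruskal–Wallis.** Per amino acid, the per-species frequency values of
  the two protein sets (each blended at that species pair's common TMD
  content) are treated as two samples of n species. H is tie-corrected;
  p comes from the chi-square approximation (1 df) or, for small samples,
  from full permutation enumeration. The exact p is inclusive,
  P(H ≥ h); a mid-p variant (half weight on the atom at the observed H)
  is exposed because the discrete null carries large atoms at small H for
  tiny samples, and the continuous chi-square tail can only be expected
  to land within the interval [mid-p, inclusive-p].
* **Log–log Pearson.** Correlations of usage (ratios or frequencies) with
  lifespan use base-10 logs on both axes (the base is irrelevant to r and
  p); p values are two-sided t tests.
* **Partial correlation.** First-order formula
  r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) with t on n−3 df,
  used to control body mass — the dominant allometric predictor of
  lifespan — out of both variables.
* **Independent contrasts.** Felsenstein pruning: contrast
  (x_i − x_j)/√(b_i + b_j) at each internal node, ancestral values as
  branch-length-weighted means, parent branches extended by
  b_i·b_j/(b_i + b_j). Daughters are ordered by smallest descendant tip
  label to fix contrast signs; polytomies are resolved as zero-length
  ladders and flagged. The contrast correlation is computed through the
  origin (no intercept), with t on k−1 df for k contrasts — the standard
  convention for contrasts, on which the source analyses are silent.
* **Multilinear q.** Log lifespan is regressed on all 20 frequencies.
  The design is compositional (rows sum to 1), hence rank-deficient; the
  fit uses the Moore–Penrose pseudoinverse with a singular-value cutoff
  at 1e-8 of the largest, which removes the compositional null direction
  instead of inverting numerical noise. The default share is
  q_a = 100·|β_a|·sd_a / Σ|β|·sd; an LMG-style alternative (average
  sequential R² gain over Monte-Carlo-sampled predictor orderings) is
  selectable. The originating analyses used an unspecified proprietary
  procedure, so neither definition claims numerical equivalence to it;
  on simplex-constrained data the minimum-norm fit provably spreads a
  single-predictor signal across all coefficients (its share caps near
  50 %), so q is best read as a relative, not absolute, attribution.
* **Median split.** Species are divided into equal halves at the median
  longevity (stable sort; ties at the median broken by rank order), and
  per-amino-acid group ratios mean(long)/mean(short) are formed without
  log transformation.

## Factorial ranking and reporting

Amino acids are ranked 1–20 per paradigm by decreasing `d`; exact ties
break alphabetically and are tie-marked. When ranking *printed* (two-
decimal) ratios, deviations that differed below printing precision
collapse; `RankVector.tie_groups(tolerance)` exposes maximal groups of
chained distances within a tolerance (0.005 covers two-decimal rounding)
within which the original unrounded order is unrecoverable. Percent
changes are `100·(R − 1)` rounded half away from zero (with a 1e-9 guard
against binary-representation artifacts of decimal inputs). The report
layer flags the four largest deviations per paradigm, marks their p
values only below 0.001, and hash-flags amino acids that are top-4 in at
least two paradigms.

## Genetic codes

NCBI translation tables 1, 2, 4, 5, 9, 13 and 14 (standard plus the
mitochondrial codes of the studied taxa) are taken from Biopython's
codon-table data, in the RNA alphabet. A decoding delta records, for each
codon translated differently by two tables, a loss for the old amino acid
and a gain for the new one; stop reassignments are included. Species-
panel summaries count, per codon change, the species whose mitochondrial
code carries it. Accounting is symmetric: a codon reassigned from
arginine to serine counts as an arginine loss *and* a serine gain. (The
published decoding column instead credits the arginine loss only to the
13 vertebrates whose codes turn AGA/AGG into stops; that count is
available separately as the number of species with to-stop
reassignments.)

## The synthetic-data generator

The generator emulates the *study conditions*, not protein evolution:

* 20 species by default, lifespans log-uniform over 0.05–100 years;
  log body mass follows a + b·log L (b = 3.5) with Gaussian noise whose
  variance is solved from the target log–log correlation (default 0.933,
  the panel's published value; |r| = 1 means zero noise).
* Compartment compositions are baseline frequencies (a UniProt-style
  global average) times injected per-amino-acid multipliers — defaulting
  to the published compartment ratio vectors — times L^slope for
  lifespan-linked amino acids (default: slope −0.3 on cysteine in the
  respiratory-chain compartment), renormalized to sum 1. Slopes apply
  only to non-reference compartments; a slope present in both sides of a
  ratio would cancel, which is why the reference compartment is exempt.
  Renormalization makes realized ratios deviate slightly from the
  injected multipliers; `expected_ratio` provides the corrected closed
  form that recovery tests compare against.
* TMD segments are uniform 17–25 residues (a typical helix span), placed
  disjointly to hit a per-compartment target TMD fraction (defaults:
  10 % whole proteome, 5 % organellar imports, 55 % mitochondrially
  encoded sets), with a hydrophobically biased composition inside
  segments (weights exp(KD/2.5) on the Kyte–Doolittle scale).
* All randomness flows from one seeded generator; identical
  configurations produce byte-identical bundles.

Default set sizes (60 proteins of mean length 300 per species and
compartment) are chosen so a full 20-species bundle generates and
analyzes in seconds while keeping multinomial noise on a 2 % amino acid
near 3 % relative — recovery tests that need tighter error raise the
set size locally. Because residues are drawn independently, the bundles
carry *only* multinomial noise: no phylogenetic autocorrelation of
compositions, no codon-level structure, no annotation error. Passing
recovery tests therefore demonstrates correctness of the estimators
under the declared generative model, not robustness to the full noise
structure of real proteomes.

## Numerical choices and degenerate inputs

Ambiguity residues (B, J, O, U, X, Z) are kept in sequences but excluded
from all counts. Coordinates are 1-based inclusive everywhere. Readers
reject malformed input with typed errors rather than coercing. Empty
pools, zero-variance log-variables, collinear controls, and missing tip
values raise rather than returning NaN silently; undefined ratios
propagate as NaN and rank last. Pure-birth trees clamp branch lengths to
a 1e-3 minimum because a zero-length terminal pair would make a contrast
variance vanish.

## Known limitations

The published cross-species tables themselves are not reproducible here:
they require the original RefSeq/UniProt proteomes, TMHMM runs and the
literature phylogeny. What this package validates end-to-end is the
machinery — on printed-table derivations and on synthetic bundles with
known truth. Rank comparisons against printed tables are limited by the
two-decimal resolution of the published ratios; within tie groups the
original order is unrecoverable. The hydropathy fallback is a heuristic
and should not be used where real TMHMM output is available.
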