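# Methods

This note documents the models and procedures mmpkit implements, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical decisions that affect results.

## Hydropathy profiling

Per-residue hydrophobicity scores come from a pluggable scale. The default
is the Cowan–Whittaker (1990) HPLC-derived scale at pH 7.5, shipped as a
human-editable TSV (`src/mmpkit/data/cowan_whittaker_ph75.tsv`); the
Kyte–Doolittle index ships alongside for cross-checks. Scores are
dimensionless; only their sign structure and relative magnitudes matter
downstream.

**Smoothing.** The raw profile is smoothed by the iterated 3-site moving
average: one pass replaces site *n* by mean(*x*[*n*−1], *x*[*n*], *x*[*n*+1]),
with terminal sites averaging the two available values (truncation rather
than padding — padding would invent boundary scores). Iteration count
defaults to 10 passes and is configurable; a convergence mode stops when
the largest per-site change drops below a tolerance (default 0.01) and the
count actually applied is reported (`iterations_used`). Unbounded
repetition provably flattens any profile to a constant (the window mean is
a strict contraction on the non-constant component, at a rate ~1/L² for
profile length L), so "smooth" necessarily means finitely many passes; 10
passes suppress single-residue spikes while leaving the helix-scale
structure (~20-residue features) intact.

**Hydrophobic domain and HYD.** The mask is the set of sites with smoothed
score strictly > 0. HYD is the arithmetic mean of the smoothed score over
the mask; for a protein set it is the pooled mean over the concatenated
masked sites of all the set's proteins. A profile whose smoothed values are
all ≤ 0 has *no* hydrophobic domain: that is signalled as an explicit
error, never silently reported as 0.0. Transmembrane-helix prediction is
out of scope; the S(*n*) > 0 mask is the working proxy for the membrane
domain.

**Ambiguity codes.** X/B/Z/U have no scale values. Such sites are excluded
from scoring, bridged in smoothing (the window spans the remaining scored
neighbors), and excluded from both numerator and denominator of every
composition percentage.

## Composition statistics

TC/SC/STC/CC are percentages of canonical amino-acid sites, pooled across
the genes of a protein set by concatenation — matching the definition of
TSN as a pooled site count — rather than averaged per gene (per-gene values
are available through single-gene sets, as used by the per-gene correlation
table). STC = TC + SC holds exactly by construction. The composition
domain is the full sequence by default; a `hydrophobic_mask` domain
restricts counts to masked sites and is reported side by side, since the
source analyses are ambiguous about the denominator. Species lacking any
gene of a set are dropped from that set's statistics and logged — pooling a
partial set would bias the denominator.

Group-level values are unweighted arithmetic means over species, with
per-group sd and n reported. Group means are the default input to every
correlation and regression; a species-level raw mode exists as a flag.

## Allometric transforms and the F-sweep

msBMR = C·M^−(1−α) and mtBMR = C·M^−(1−α)/F, with the per-cell and
mitochondrial-density proportionality constants fixed at 1, so mtBMR
carries C's (relative) units; only logarithms enter correlations, via the
exact form ln(mtBMR) = ln C − (1−α)·ln M / F. F = 1 is msBMR; F = ∞ is
handled symbolically and returns C exactly. The mitochondrial-density
exponent that motivates the transform is folded into F and is not a
runtime parameter.

The sweep grid defaults to {1, 1.25, 1.5, 2, 2.5, 3, 4, 5, 7.5, 10, 20,
50, 100, ∞}; F = 3 (an earlier mammalian calibration) is a named preset.
R² is the squared Pearson correlation of the trait with ln(mtBMR) across
groups; a degenerate variable yields NaN for that grid point; argmax ties
break toward larger F (determinism). Body masses and maximum lifespans are
group means; no temperature adjustment of metabolic rates is attempted.

## Regression battery

* Squared Pearson correlations carry the sign of the raw correlation
  (P/N) and their n; no multiple-testing correction is applied (raw R²
  values are the convention in this comparative literature — every cell
  reports its n instead).
* TSN correlations are computed with deuterostome groups excluded: the
  deuterostome lineage splits from the common TSN trend, and including it
  mixes two regimes.
* The TC–HYD power law y = a·x^b is fitted twice: nonlinear least squares
  on the original scale (headline, initialized from the log–log OLS
  solution) and log–log OLS (reported alongside) — the two differ under
  noise and the source convention is unknowable. R² for the power fit is
  1 − SSres/SStot on the original scale and may be negative (flagged).
* The two-predictor fit ln(mtBMR) ~ STC + HYD is plain OLS; the nesting
  inequality (R² ≥ either single-predictor R²) is asserted in tests.
* Lineage-split fits partition groups exactly into deuterostome vs rest
  using clade labels carried by the metadata file — the clade assignment is
  data, not code, so it stays auditable.

## Trait-space neighbor joining

Distance: D(i,j) = Σ_v (v_i − v_j)²/σ_v² over the chosen variables
(default TC and TSN on the 5-protein set). σ_v is the population
(divide-by-n) standard deviation over the groups in the table; sample sd
is a flag. Note D is a squared-difference sum (no square root), as
specified for this trait distance.

NJ is implemented from scratch (Q-matrix criterion, standard branch-length
and reduction formulas). Tie-breaks in the Q minimization take the
lexicographically lowest index pair, making output deterministic. Negative
branch lengths — expected on strongly non-additive trait matrices — are
clamped to 0 with a warning and counted in the result. Trees are unrooted
(trifurcating root node, n−2 internal nodes for n leaves); an optional
outgroup flag reroots for display. scikit-bio's independent NJ serves as a
cross-check oracle in the test suite, never as the implementation.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, so
every stage is testable without downloads:

* 13 groups × 20 species × 13 genes, ~400 residues per gene (~1.4 M
  residues), matching the scale of a real multi-group mtDNA protein
  dataset while keeping a full pipeline run to a few seconds.
* Sequences are iid multinomial draws per group. T/S/C frequencies are the
  group targets; the rest of the probability mass is split between a
  hydrophobic pool (I, L, V, F, M, A, W) and a polar pool (G, N, Q, H, K,
  R, D, E, P, Y) so the expected raw hydropathy hits a calibrated value.
* **HYD calibration.** The group target is the *measured* HYD (positive-part
  mean of the smoothed profile), not the raw mean. Under the iid model the
  smoothed score at an interior site is approximately Normal(m, v·w₂),
  where v is the residue-score variance and w₂ the smoother's squared-weight
  norm; the positive-part mean is then m + s·φ(m/s)/Φ(m/s). The generator
  root-finds the raw mean m that makes this equal the target. The
  approximation ignores terminal sites and non-normality; realized
  group-mean HYD lands within ~0.01–0.03 of target at default sizes, which
  the test suite checks.
* Group targets follow TC = 0.429·HYD^−4.2045 with log-normal relation
  noise (sd 0.09, set so the group-level TC–HYD correlation lands near
  R² ≈ 0.9, the regime reported for real data); SC and CC are affine in TC
  (CC negatively, with enough noise to keep CC correlations moderate).
  Deuterostome groups get low HYD/high TC, basal and protostome groups the
  converse, and gene lengths rise with TC within each lineage with the
  deuterostome length range strictly above the rest — the two-pathway
  TSN gradient the tree and the TSN regressions are designed to detect.
* Metadata: masses span ~7 orders of magnitude; ln C and ln MLS are affine
  in STC plus noise, so the sweep's expected optimum is F = ∞, mirroring
  the finding the pipeline is built to reproduce.
* Determinism: one master seed; per-group streams are spawned from it in
  group order. The ground-truth JSON records every generator parameter and
  regenerates the cohort bit for bit.

What the cohorts do **not** emulate: phylogenetic autocorrelation among
species within groups (species are exchangeable), local hydrophobic
clustering along the chain (an iid model has no helix periodicity; an
optional block sampler was considered and rejected as unnecessary — no
consumer statistic depends on site order beyond the 3-site smoother),
codon-level mutation processes, and alignment issues. Passing tests
therefore demonstrate correctness of the *computations* and recoverability
of *imposed* relations at realistic sizes — not that real data satisfy
those relations.

**F-recovery study design.** The noise-free sweep recovery uses the
13-group default. The noisy localization study (best F within one grid
step of the truth in ≥90% of replicates) is run at 40 simulated groups
with relation noise at R² ≈ 0.9 and sd(ln C) matched to one third of the
mass-term sd: a delta-method power analysis gives SE(1/F̂) ≈
√((1−R²)/R² · g/n) with g ≈ 0.44 at matched variances, so 13 groups yield
only ~77% localization probability while 40 give ~96%. The study size was
fixed from that analysis.

## Numerical choices and edge cases

* Strict inequality S(n) > 0 for the mask; a tie at exactly 0 is outside
  the domain.
* "No hydrophobic domain", zero-variance correlations, collinear
  predictors, infeasible generator targets, F < 1, and non-positive
  masses all raise explicit errors rather than returning sentinel numbers.
* ln(mtBMR·MLS) is computed as ln(mtBMR) + ln(MLS).
* Result files are written with a fixed float format and no timestamps;
  two runs on identical inputs are byte-identical, and the manifest
  (config minus output location, input SHA-256s, package version) is the
  complete recipe for a run.

## Known limitations

* The human-reference quantities are computed from the documented lengths
  of the 13 human mitochondrial proteins (`mmpkit.reference`), not from
  downloaded sequences; any analysis needing actual human residues
  requires supplying the sequences as FASTA.
* The power-law and linear headline fits assume group means are
  exchangeable points; no phylogenetic regression (PGLS/independent
  contrasts) is offered.
* Helix-by-helix spatial composition profiles require an external topology
  predictor and are out of scope; the S(n) > 0 mask is the only membrane
  proxy.
* The composition-space NJ tree is a similarity summary, not a phylogeny:
  branch lengths inherit the squared, variance-scaled units of the trait
  distance.
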