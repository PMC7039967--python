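# Methods

This note documents the statistical procedures, the defaults and why
they were chosen, the synthetic-data model, and the numerical decisions.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing (exprmatrix)

Expression matrices are features × samples, log2 intensities or raw
counts per a declared scale flag. The preprocessing mirrors a standard
bead-array workflow:

* **Detection filter** — keep features whose detection p-value is
  *strictly* below `alpha` (default 0.05) in at least `min_samples`
  (default 3) samples. The strict inequality is deliberate: a feature at
  exactly p = 0.05 everywhere is dropped.
* **Quantile normalization** — every sample's sorted values are replaced
  by the across-sample mean of order statistics. Ties within a sample
  receive the mean of the reference values for their tied ranks
  (mid-rank convention, implemented as linear interpolation of the
  reference at average ranks). The transform is rank-preserving within
  samples and exactly idempotent on tie-free data; with ties the
  mid-rank values slightly perturb the second-pass reference, so
  idempotency is exact only up to that perturbation.
* **log2 transform** — elementwise log2(x + offset), erroring (and
  naming offenders) on non-positive arguments. Missing values are
  rejected throughout; nothing is imputed.
* **Background subtraction** (optional, off by default) — subtracting
  each sample's 5th percentile and flooring at a small positive
  constant. This is a deliberately simple surrogate for
  convolution-model background correction, intended for synthetic data
  that has no negative-control probes; it should not be mistaken for
  the latter on real arrays.

## Differential expression (diffexp)

**Two-group t tests.** Pooled variance by default, Welch and moderated
variants behind a flag. Effect is mean(A) − mean(B) on the log2 scale.
Zero-variance features do not error (noise-free synthetic runs must
complete): a zero difference gives t = 0, p = 1; a nonzero difference
gives the smallest representable positive p, with a `degenerate` flag
either way.

**Variance moderation.** Per-feature sample variances s² with d df are
shrunk toward a scaled inverse-chi-square prior (d0, s0²) fitted by
method of moments on log variances (digamma/trigamma identities, with
Newton inversion of the trigamma function). Posterior variance
(d0·s0² + d·s²)/(d0 + d); augmented df d + d0. When the observed spread
of log variances does not exceed its sampling expectation, d0 = ∞ and
every posterior equals s0² (flagged); literally identical variances
short-circuit to s0² = that common value.

**BH adjustment** is the standard step-up procedure (delegated to
statsmodels); the test suite checks it against an exhaustive step-up
oracle on small vectors.

**Spline time-course test.** Each feature's temporal trend is modelled
on a natural cubic spline basis of dimension 3 (boundary knots at the
observed min/max time, interior knots at the 1/3 and 2/3 quantiles —
the `ns(x, df=3)` convention). The null design is
[intercept, arm offset, basis] (shared curve shape, arm-specific
level); the full design adds arm × basis interaction columns. The F
statistic on the interaction block therefore has numerator df equal to
the basis dimension, i.e. **3**, matching the 3 degrees of freedom the
analysis reports. The basis was sized so that dimension and interaction
df coincide at 3; placing three *interior* knots instead would give a
4-dimensional basis and a 4-df test, breaking that identity. Residual
variances may optionally be moderated across features exactly as for
the t test (posterior variance in the denominator, augmented
denominator df). Degenerate cases: a feature fitted exactly by the null
model (e.g. constant, or any noise-free non-divergent gene) has
0/0 → p = 1 with a flag; zero residual variance with real interaction
signal gives the smallest positive p. Residual sums of squares are
computed from explicit residuals after a QR projection, and values
below 1e-22 × total sum of squares are snapped to zero — round-off from
the projection would otherwise turn noise-free fits into F ratios of
two rounding errors.

The toolkit models two-arm designs with at least 4 distinct time
points; rank-deficient designs are rejected with a description of the
deficiency rather than silently dropped columns.

## Trajectory classification and the range filter (trajectory)

With stage means m1, m2, m3 (6/12/24 months) and differences
d1 = m2 − m1, d2 = m3 − m2, values within `epsilon` of zero are ties:

| pattern | class |
|---|---|
| d1 > 0, d2 > 0 | LI |
| d1 < 0, d2 < 0 | LD |
| d1 > 0, d2 < 0 | CD (interior peak) |
| d1 < 0, d2 > 0 | CU (interior trough) |
| both tied | FLAT |
| one tied | linear class of the signed difference |

The one-tie rule is the weak-inequality reading of a monotone chain:
(2, 2, 3) is increasing-with-a-plateau, hence LI. A strictly monotone
but curved profile is classed linear — the coarsest reading consistent
with sign patterns. `epsilon` defaults to 0 (exact ties only), which is
right for noise-free data; on noisy data the pipeline default is
effect_size/4, chosen once as a value an order of magnitude above the
standard error of a group mean at the default noise level and half-way
below the planted effect. Whether concavity should instead be read off
a fitted quadratic is undecidable from sign patterns alone; the
difference-sign definition is the simplest one that reproduces all four
response codes.

The **interpolation-range filter** keeps a gene iff
min(m1,m2,m3) ≤ mp ≤ max(m1,m2,m3), bounds inclusive ("outside the
range" eliminates, so boundary equality stays). For a piecewise-linear
interpolant the range is exactly that min/max, which the test suite
verifies against a dense-evaluation oracle over all 24 strict
arrangements. The control mean m0 enters only the significance
contrasts, never the shape or range computation; an optional
control-centering flag subtracts m0 from the other means for display
without changing any decision.

Selection is the OR of the four contrast flags (q ≤ FDR level,
boundary inclusive), then the range filter. Both are monotone:
removing the propranolol group can only grow the significance-selected
set, and the basic list is always a subset of the input features.

## Cross-species harmonization (crossspecies)

Homolog mapping is a static many-to-many table; one-to-many sources
expand to all human homologs (the conservative choice — it cannot
silently drop signal), unmapped sources are dropped and counted. The
constitutive-expression filter compares arithmetic means of raw counts
(not means of logs) between the two panels, with a +1 pseudocount on
both means applied always, for continuity at zero; a gene is kept iff
|log2 ratio| is strictly below 2. Raising the pseudocount pulls every
ratio toward 1, so the kept set is monotone non-decreasing in it
(property-tested). The toxicological core is the triple intersection
(tox DE mapped to human) ∩ (comparable baseline) ∩ (basic IH list),
with the first filter that removed each excluded gene recorded.

## miRNA layer (mirnamap)

Target tables are TargetScan-dialect TSVs with configurable column
names; blank miRNA/gene rows are skipped and counted (retired database
entries), unknown species tags are kept but flagged. Backward mapping
retains a (miRNA, gene) link iff it appears for both species of the
declared pair, matching symbols case-insensitively (mouse Myo1b ↔ human
MYO1B); adding the consistency requirement can only shrink the mapping.
Coverage of a list is the fraction of its genes with ≥ 1 mapping miRNA
(numerator and denominator are both reported, so any list-size
convention is auditable); putative biomarkers are exactly the covered
core genes, so coverage equals |biomarkers| / |core| by construction.
A miRNA is sole-targeting list L iff it has ≥ 1 target in the union of
the lists and every such target belongs to L only — genes that are
members of two lists disqualify sole status. Forward mapping
(gene → miRNA) is provided only as a thresholded table lookup on
supplied scores, clearly labelled a surrogate: probabilistic target
scoring is out of scope.

## Integration (integrate)

Phase assignment is a strict mean comparison with ties reported, never
silently assigned. Core lists are (basic ∩ published phase list) minus
manual exclusions; exclusions come from a YAML file in which every
symbol must carry a free-text reason — nothing is hard-coded. The
linear/nonlinear partition takes LI/LD as linearly responsive (with
direction) and CD/CU as non-linearly responsive; FLAT genes are
reported separately. qPCR fold changes follow 2^(−ΔΔCt) with
ΔCt = mean Ct(target) − mean Ct(reference) per group (group-mean Ct
before differencing; a per-replicate paired mode is available) and the
calibrator group designated by a role column or argument. Swapping
sample and calibrator inverts the fold change exactly. `build_report`
enforces a conservation ledger — every logged filter must satisfy
|kept| + |excluded| = |input| — and the subset chain (cores ⊆ basic,
biomarkers ⊆ cores) before emitting the JSON/TSV bundle.

## Synthetic data (simdata)

The generators emulate the structure each stage assumes, not the
physics of any platform (no bead-level artifacts, probe sequences or
scanner effects). Noise is i.i.d. Gaussian on the log2 scale; baseline
counts are negative-binomial (dispersion 10) around planted means.
Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_genes | 1000 | desk-scale but large enough for rate estimates |
| samples_per_group | 5 | small-cohort microarray study |
| shape_fractions | 0.2 each of LD/LI/CD/CU/FLAT | all classes exercised |
| effect_size | 2 log2 units | a clear 4-fold stage effect |
| noise_sd | 0.1 log2 units | array-replicate scale noise |
| frac_prop_in_range | 0.7 | both filter branches well populated |
| time_points | days 1, 3, 7, 14 | a 14-day dosing window |
| frac_divergent | 0.1 | sparse treatment response |
| baseline_frac_constitutive | 0.3 | strong tissue bias is common |
| n_mirnas / targets_per_mirna | 30 / 5 | small miRNA panel |
| mirna_frac_de | 0.3 | matches a handful of significant miRNAs |

Planting rules (baseline b per gene, effect e): LD = (b+e, b, b−e),
LI mirrored, CD = (b, b+e, b), CU = (b, b−e, b), FLAT constant;
in-range genes get mp at the midpoint of [min, max] of the stage means,
out-of-range genes mp = max + e — both unambiguous under noise.
Constitutive baseline genes are planted at |log2 ratio| in [3, 5],
comparable genes in [0, 1], with means ≥ 50, so pseudocounts and
rounding cannot flip a decision. Divergent toxicology genes add
e·sin(πz) (z = normalized time) to the treated arm, giving a smooth
divergence that peaks at e mid-window. Each generator draws from its
own RNG stream derived from the master seed, so outputs are reproducible
and mutually independent.

What passing the synthetic tests does **not** show about real data:
real arrays have correlated probes, heteroskedastic and heavy-tailed
noise, batch structure, and annotation ambiguity, none of which is
modelled; homolog tables and target predictions are version-dependent
in reality but exact by construction here. The synthetic results
validate the *machinery* (selection logic, calibration of the tests,
set algebra, accounting), not biological effect sizes.

## Statistical reading of the recovery checks

BH selection controls the false discovery rate in expectation, so
recovery checks on noisy data assert full planted recall plus a
false-positive count within the BH budget, and the calibration check
averages false discoveries over independent replicates; demanding
exact equality of a BH-selected set with planted truth on a single
noisy realization would fail by design a sizeable fraction of the time.
Noise-free runs, where null p-values are exactly 1 and signal p-values
degenerate to the smallest positive value, are where exact recovery is
asserted.

## Known limitations

* Trajectory classification is specified for exactly three interior
  time points; more stages would need a generalized shape grammar.
* The spline test assumes Gaussian errors and a shared basis across
  features; its null calibration is verified empirically at the default
  design but not under heteroskedasticity.
* The constitutive filter's pseudocount (+1) is a continuity device,
  not an estimate of technical background.
* Real published gene lists are consumed as plain symbol lists;
  upstream probe cleaning reduces to deduplication and non-empty-symbol
  validation of the supplied files.
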