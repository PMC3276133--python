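# Methods

This note documents the models behind each module, the parameters that
matter, the numerical choices, what the synthetic-data generator does and
does not emulate, and known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Growth-curve fitness

**Model.** A well's OD600 trace is treated as logistic,
`OD(t) = OD₀K / (OD₀ + (K − OD₀)e^{−rt})`, with the exponential-phase rate
`r` carrying the biology. Fitness is defined on rates: a strain of fitness
`f` grows at `r = f·ln2/D_wt`, so `W = D_wt/D_mutant` recovers `f` from
doubling times.

**Doubling-time estimator.** Log-linear fits are slid over every window of
≥ 5 consecutive readings whose OD lies in the exponential band
`[2·blank, max(OD)/2]`; the blank defaults to the first reading. Among
windows whose R² is within 0.005 of the best, the longest wins (earliest
start on ties), and `D = ln2/slope`. The tolerance matters: a strict R²
maximum favours 5-point windows whose apparent straightness is measurement
noise — with OD noise SD 0.005 it leaves a fitness-ratio error SD of ~0.07,
versus ~0.013 with the tolerance. On a noiseless exponential every window
is colinear and the estimate is exact for any tolerance. Traces whose
longest in-band stretch has 3–4 points are fitted anyway and flagged
`low_quality`; fewer raises `NoGrowth`, and a flat trace (range ≤ 0.01 OD)
raises `BelowDetection`.

**Bias, and why ratios are safe.** On a logistic trace the whole eligible
band sits where growth is already rate-suppressed (`d ln OD/dt =
r(1 − OD/K)`), so the *absolute* D is overestimated — by roughly a third
at OD₀ = 0.05·K with the long-window rule. Because the band is defined by
OD, wild type and mutant are measured over the same suppression profile
and the bias cancels in `W = D_wt/D_mut`, which the tests show recovers
planted fitness within ~2–3%. Absolute doubling times from this estimator
should not be compared across instruments or media.

**AUGC.** The trapezoidal integral of `(OD − baseline)` clipped at zero
over exactly `[t₀, t₀ + 24 h]` (interpolating the endpoint), in OD·hours;
baseline defaults to the first reading, no smoothing. AUGC is preferred
when inhibition exceeds 50% — the `auto` policy in `relative_fitness`
switches at an AUGC ratio of 0.5. The two readouts agree within ~10% only
under mild inhibition (f ≳ 0.8 and D_wt ≳ 100 min for a 24 h window):
once a curve plateaus well inside the window, AUGC compresses toward 1
and is a *monotone but nonlinear* proxy for rate fitness. Consequently a
dose–response assembled from AUGC fitness inherits a structural upward
IC50 distortion of order 10–20%; the package's IC50 validation therefore
operates on fitness-level measurements, and the curve-level test asserts
the looser recovery the chain actually achieves.

**Hill fit.** `f(d) = floor + (1 − floor)/(1 + (d/IC50)^h)` by bounded
least squares (`scipy.optimize.curve_fit`), initialised from the dose
nearest the half-response; doses are internally rescaled by the top dose,
making the fit exactly equivariant under unit changes (mM → µM multiplies
IC50 by 1000). If the mean response never falls below half the zero-dose
level the result is flagged `undetermined` with no extrapolated IC50.
The recommended sweep is an 11-step 1.5-fold dilution from 8× the
expected IC50 plus vehicle: the vehicle anchors the top asymptote and the
high top dose anchors the floor, which is what pushes the IC50 error SD
to ~5% at measurement noise SD 0.05 with triplicates (a 2-fold scoping
sweep leaves ~8%).

## Pooled screen

Arrays are mean-normalized to the grand mean of per-array means (within-
array structure untouched; a global per-array scale factor provably
cancels). Tag score = `log2(mean control intensity / treatment
intensity)`; zero intensities are floored at half the smallest positive
value on that side and flagged. A strain's score is the mean of its up-
and down-tag scores (single-tag strains flagged, tagless strains dropped
with a log entry); tags are combined *before* ranking.

**Rank product.** Within each replicate, strains are ranked descending
(most depleted = rank 1, average ties); RP is the geometric mean of a
strain's ranks. Significance: the null permutes each replicate's rank
column independently; `pfp(g) = E[#null RP ≤ RP_g] / rank(RP_g)`. The
permutation space is enumerated exhaustively when `(n!)^k ≤ 10⁶`,
otherwise 10,000 seeded Monte-Carlo draws by default. Comparisons are done
on the rank *product* (exact in float64 up to the sizes involved) with a
10⁻¹² relative guard. Replicate count matters: with 400 strains and only
2 replicates the expected null count at the 20th-best product is ~7, so
even perfectly separated mid-rank hits cannot reach pfp < 0.05 — the
study design simulated here uses 4 replicates.

Sensitive calls require pfp below the FDR cutoff (default 0.05) *and* a
positive mean score. Resistant calls (from high-dose, 20-generation
selections) require mean score ≤ −1 (≥ 2-fold enrichment, configurable)
and mean treatment intensity above the array background floor — a tag at
background carries no abundance information.

## Suppressor loci

ORF probe log2 ratios are averaged per ORF, ordered by start coordinate
within chromosomes (the `GenomeLayout` container enforces sorted,
non-overlapping, 1-based coordinates). A gene *qualifies* at score ≥ 1.6
(boundary included). Loci are maximal runs of qualifying genes in which
off-array genes are bridged — they score 0.00, never break a run, never
count toward the ≥ 2-adjacent minimum, but do enter the locus average —
and sub-threshold on-array genes terminate runs. A qualifying gene with no
qualifying neighbour is a singleton. The locus average is the arithmetic
mean over all members including the 0.00 entries, reported to two decimals
for display with full precision retained. The bundled worked-example table
(`chemscreen.datasets`) pins all of these behaviours; the published table
it reproduces rounds exact halves inconsistently, so comparisons use
±0.01.

## Epistasis

`ε = W_xy − W_x·W_y` per marker orientation, with single-mutant W taken
from marker-matched single deletions supplied as input (not assumed from
the deletion-collection screen). Pairs whose orientations disagree
(`|W_xy − W_yx|/2 > 0.2`, boundary kept) are filtered; surviving pairs
average the two orientations' ε. Sign classes use a declared dead-zone:
|mean ε| < 0.08 is "none" (the boundary is classified), making interaction
counts reproducible. Reciprocal reproducibility is summarised as the
squared Pearson correlation between orientation fitness vectors.

**Clustering.** Gene ε-profiles (rows of the symmetric gene × gene matrix,
diagonal absent) are clustered with average linkage on `1 − Pearson r`
computed over pairwise-complete observations. Genes with < 2 finite
values, < 50% finite profile, or a constant profile are dropped with a log
entry — correlations are not fabricated for them; pairs without a usable
correlation get the maximum distance 2.0, logged. The dendrogram exports
to Newick with branch lengths from merge heights. Same-chromosome gene
pairs closer than 50 kb can be flagged via `linked_pairs` and excluded
(double mutants of linked genes cannot be constructed by recombination).

## Synthetic-data generator

The generator is the study-conditions contract for the tests: pooled
growth treats one "generation" as a wild-type doubling, so a strain of
fitness f multiplies by `2^(g·f)` over g generations — 20 generations with
dilution back to constant pool size every 5 (dilution leaves relative
abundances untouched, and the arithmetic `2^(0.2·20) = 16` is exact and
tested). Starting abundances are lognormal with CV 0.25. Array readout is
`max(floor, scale·abundance·lognormal)` per tag with unit-mean lognormal
noise (CV 0.3), floor 2⁶ on a 2¹⁶ scale, and a scale putting the median
strain at 2¹². Growth curves are logistic (K = 1, OD₀ = 0.05, wild-type
doubling 90 min, 15-min sampling over 24 h) with additive OD noise
SD 0.005 clipped at zero. Double-mutant cohorts draw
`W_xy = W_x·W_y + ε(pathway_x, pathway_y) + N(0, 0.05)` independently per
orientation (ε-recovery scenarios use SD 0.02), with the planted ε truth
retained. The noise magnitudes are package choices — plausible for the
instrument class, not estimates from any particular dataset.

Deliberately **not** modelled: PCR amplification bias, probe
cross-hybridization, plate edge and lag effects, saturation optics, batch
structure. Passing the recovery suites therefore shows the estimators are
correct and calibrated for data satisfying the stated generative
assumptions; it does not certify performance on real arrays, whose noise
is structured.

## Numerical and degenerate-input choices

Zero-intensity floors are deterministic (half the smallest positive
value). Rank-product comparisons carry a 10⁻¹² relative guard so float
ties cannot flip counts. The dose rescaling in the Hill fit guarantees
exact unit equivariance rather than relying on optimizer path
invariance. Empty loci, all-zero arrays, constant replicate columns,
zero-variance correlation inputs, hits outside the annotation universe,
unsorted or overlapping gene layouts all raise immediately with specific
messages rather than propagating NaNs.

## Limitations

Absolute doubling times are policy-dependent and biased on saturating
curves (use ratios). AUGC-derived fitness is a compressed proxy under
early saturation; IC50s from AUGC-assembled dose curves inherit that
distortion. The rank-product pfp is an FDR *estimate* with Monte-Carlo
error of order `1/√n_permutations` in the null counts. The hypergeometric
enrichment ignores annotation structure (no ontology propagation or
conditional testing) and treats genes as exchangeable. The epistasis model
is purely multiplicative with additive ε offsets; no error-surface
modelling of ε significance is attempted.
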