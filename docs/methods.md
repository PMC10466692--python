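# Methods

## Scope

`cfscreen` models the computational half of extended cfDNA prenatal
screening: everything from binned read counts to clinical concordance
tables. Wet-lab steps (library construction, sequencing chemistry, the CMA
chip protocol, orthogonal FISH/MLPA/karyotype verification) are outside its
scope; diagnostic results enter only as ISCN-like strings or transcribed
case counts.

## The plasma mixture model

A pregnancy involves three genomes. Plasma cfDNA is a mixture of the
*maternal* genome and the *placental* (trophoblast) genome — the cells that
actually shed the "fetal" fraction — while the diagnostic comparator (CMA on
amniocytes) reads the *fetal* genome proper. The simulator keeps the three
separate. The expected count of fine bin *i* is

    E[c_i] = depth · w_i / Σ w,     w_i = g(GC_i) · q_i,
    q_i = (1 − ff) · m_i/2 + ff · [(1 − π) · b_i + π · k_i] / 2,

where ff is the fetal (placental) fraction, m_i the maternal copy number,
b_i the baseline placental copy number (sex-dependent on X/Y), k_i the
event copy number, π the placental mosaic fraction and g(GC) = a + b·GC the
linear GC effect (floored at 0.05). Counts are Poisson or — by default —
negative binomial via a gamma-Poisson mixture with Var = μ + 0.01·μ²;
the 1% dispersion floor dominates at the default depth and is what makes
small CNVs genuinely hard, as in real data. chrY bins carry an additive
background rate (5% of the diploid rate) emulating female reads mismapping
to chrY; it gives the chrY fetal-fraction estimator a realistic baseline.

Fragment lengths are reduced to the probability that a fragment falls in
the short 100–150 bp window: maternal lengths ~ N(166, 18), fetal
~ N(143, 18), truncated to [50, 250] bp, giving short-fragment
probabilities of 0.187 and 0.643. Each bin's short-fragment count is
binomial with a mixture probability weighted by the locally fetal-derived
read share. Only these two constants matter downstream, so the full length
distribution is never materialized.

Diagnostic truth records the fetal genotype. Fetal mosaic fractions in
[0.1, 0.9] are rendered as copy-number ranges ("×2–3"), below 0.1 the
majority genotype wins (nothing is reported), above 0.9 the event is
reported plain; interval findings under the 100 kb reporting floor are
dropped. Confined placental mosaicism (placental event, fetal genotype
normal) therefore produces screening-positive/diagnostic-negative pairs by
construction, and low-fraction fetal mosaicism the converse — the two
clinically recognized discordance mechanisms.

### Scale

The default genome is GRCh37 scaled to 1/20 with 25 kb bins (≈6,190 bins),
which reproduces the windows-per-event geometry of the full-scale
300,000-window design: a 6 Mb CNV spans ~240 windows here versus ~580
there, at a per-window depth of ~70 reads (default total depth 425,000 =
the clinical ~8.5 M unique reads divided by the reduction factor).
Events keep their absolute sizes; only chromosome lengths shrink. Fragment
profiles are emitted on a 50 kb grid regardless of the simulation grid,
matching the seqFF convention.

Cohort draws take ff ~ Beta(2, 6.5) clipped to [4.2%, 88.3%]
(mean ≈ 23.5%, matching the clinical distribution), a per-sample GC slope
~ N(1, 0.15), and scenario mixes over euploid, common trisomy, RAT, SCA,
mosaic, confined-placental, and fetal/maternal CNV states.

## Normalization

Relative read numbers are window counts over the mean window count; the GC
effect is fitted by OLS and divided out (multiplicative correction
preserves positivity and scale invariance), then renormalized to mean 1.
In the pipeline both the fit and the renormalization are restricted to
autosomal windows: chrX/chrY window masses depend on fetal sex and are
nearly empty on chrY, and letting them into the fit drags the autosomal
baseline by several percent — enough to bury a fetal CNV. The correction
removes a *linear* GC effect exactly; under a deliberately quadratic
simulated bias, residual curvature remains (a documented limitation,
asserted by test).

Equal-read windowing allocates windows to chromosomes by expected read
mass (largest remainder, at least one each) and cuts within chromosomes at
mass quantiles. Starting from binned counts, equality is only achievable
up to one fine-bin quantum, so the default pipeline keeps each fine bin as
its own window; coarser equal-read aggregation is available and tested but
would inject quantization steps comparable to the window mass at this
scale.

## Aneuploidy calling

Per-chromosome corrected-mass fractions are standardized against a euploid
reference panel (≥20 samples; default studies use 50). Autosomal fractions
are renormalized over autosomes only, making them independent of fetal
sex. Because the panel is finite, (x − μ̂)/σ̂ is sqrt(1+1/n)·t_{n−1} under
the null — at n = 50 a naive |z| ≥ 3 rule runs a 0.46% tail instead of the
nominal 0.27% — so the caller maps the statistic through the matching
Student-t probability onto the standard-normal scale before thresholding.
The calibration is exact marginally over panels; conditional on one
realized panel, individual chromosomes still scatter (a σ̂ drawn ~1 sd low
roughly triples that chromosome's tail), which is inherent to any
finite-panel design.

Thresholding at |z| ≥ 3 calls trisomy/monosomy identically for common
trisomies and RATs. Before fractions are computed, windows inside called
CNVs are imputed to the diploid baseline 1.0, so a large (typically
maternal) CNV cannot masquerade as a whole-chromosome aneuploidy; baseline
imputation rather than median imputation avoids amplifying the remaining
windows' noise.

Sex-chromosome logic: chrY presence means a chrY mass fraction more than
4 female-panel SDs above the mismapping background. The expected chrX mass
for a male pregnancy is the female panel mean scaled by 1 − ff/2, using
the *fragment-based* (seqFF) ff — the chrY route doubles under 47,XYY and
would misroute XYY to XXY. Then: no Y and z_X ≤ −3 → 45,X; no Y and
z_X ≥ 3 → 47,XXX; Y and z_X ≥ 3 → 47,XXY; Y and chrY excess ≥ 1.5× the
single-Y expectation at the measured ff → 47,XYY. The 1.5 factor sits
midway between one and two Y copies. Samples below the 3.5% ff detection
limit are no-calls throughout.

## CNV segmentation and calling

Segmentation is recursive binary splitting under the quadratic
(sum-of-squared-error) cost, computed in O(L) per segment from cumulative
sums. A candidate split is retained when

    |mean_L − mean_R| > z_split · σ̂ · sqrt(1/L_L + 1/L_R),

with σ̂ = 1.4826·median|Δx|/√2 (robust to the piecewise-constant signal).
Retention is deliberately liberal (z_split = 2.576, two-sided 1%, the CBS
convention): a spurious split still has to clear the call gate, while a
missed boundary cannot be recovered. The call gate requires
|segment z| = |mean − 1|·√L/σ̂ to exceed a Bonferroni-adjusted threshold,
max(z_t, Φ⁻¹(1 − Φ(−z_t)/n_windows)) with z_t = 3 — the segmentation
selects the most deviant stretch among ~n candidate boundaries, so an
unadjusted gate passes roughly one spurious call per sample; adjusted, the
euploid false-call rate is ~0.1 per sample. Calls also need ≥3 windows,
|deviation| ≥ 0.01, and < 90% of the chromosome (whole-chromosome shifts
belong to the Z caller).

An exact dynamic-programming solver for the same objective
(`optimal_partition`, O(m·n²)) is the small-instance oracle: on instances
of ≤200 windows with ≤3 changepoints and 20–50σ jumps the recursive
breakpoints equal the DP optimum (0 mismatches in 2,000 instances). The
oracle study runs retention at 5σ so that max-selected noise splits —
which a global DP may legitimately place elsewhere — stay out of a
placement comparison.

Origin attribution compares |deviation| with ff/2 (fetal heterozygous)
versus (1−ff)/2 and 1/2 (maternal, not/inherited by the fetus), classifying
to the nearest; when the fetal and maternal expectations are closer than
two standard errors, or the deviation sits exactly midway, the origin is
indeterminate. Maternal events deviate by ~0.5 regardless of ff, which is
why small detected CNVs are predominantly maternal.

## Fetal-fraction estimation

*chrY route*: ff_y = (observed chrY mass fraction − background) /
(male-reference − background), clamped to [0, 1]; undefined without Y
signal. Both references are computed analytically from the simulator's own
genome (noise-free female and all-fetal-male expectations), keeping the
package self-calibrating. Recovery error on simulated male cohorts is
~0.007 absolute.

*seqFF route*: ridge regression (α = 10⁻³ on standardized features) of ff
on {autosomal short-fragment proportion, count-weighted mean GC, log total
fragments}. The intercept is unpenalized, so the model predicts the
training-mean ff at the training-mean features exactly. Constant nuisance
features trigger a flagged univariate fall-back; at prediction the
nuisance features are clamped to their calibration range (the log-count
feature is near-constant in calibration and would otherwise extrapolate
wildly), while the short-fragment proportion extrapolates linearly so
low-ff samples can fall below the detection limit. In the pipeline the
model is trained on the male panel members with their chrY estimates as
targets — no external truth enters — and applies to either fetal sex.

Combination: mean of the two when chrY evidence is present, seqFF alone
otherwise; combined ff < 3.5% flags the sample as a no-call.

## Concordance analysis

The ISCN parser accepts the dialect
`arr[GRCh37] <band>(<start>_<end>)×<cn>[–<cn>]` (thousands separators,
`×`/`x`, en-dash/hyphen/underscore ranges, an optional `hmz` suffix for
homozygous stretches) plus whole-karyotype tokens (45,X etc.). Printed
coordinates are 1-based inclusive; internally everything is 0-based
half-open (BED convention), and the reported fragment size is the printed
difference. An interval counts as whole-chromosome when it covers ≥70% of
the chromosome's *reportable span* — arrays cover only the q arms of
acrocentric chromosomes and often stop short of qter, so printed trisomy
intervals cover 62–100% of their chromosomes; the span table encodes the
acrocentric q-arm starts and the male-specific chrY region. Same-copy
adjacent findings are merged (gap ≤ 1 Mb) before classification, which is
how two abutting chrY ×2 segments become 47,XYY. The chrY copy baseline is
1, so ×2 chrY intervals are duplications. ROH findings are parsed but
never screenable; CMA findings below the selection floor (deletions
< 0.5 Mb, duplications < 1 Mb) are excluded from concordance.

Matching: aneuploidies by chromosome, SCAs by karyotype identity (a
discordant karyotype counts one FP and one FN), CNVs greedily by same sign
and reciprocal overlap ≥ 25% (configurable). Metrics: sensitivity =
100·detected/diagnostic-positives, PPV = 100·confirmed/screen-positives,
miss rate = 100 − sensitivity, with 95% CIs by Wilson score with
continuity correction by default (other methods delegate to statsmodels).
The CI procedure behind the clinically printed intervals is not specified
anywhere and is not reproduced bit-exactly.

## What the simulator does and does not show

The generator reproduces the features that drive screening performance —
GC bias, overdispersed counts, fetal-fraction dilution, compartment
(placenta/fetus) discordance, fragment-length enrichment — under a clean
linear GC model, exchangeable bins and a single background chrY rate. It
does not model mappability structure, recurrent-CNV hotspots, maternal
malignancy, twin pregnancies, read-level artifacts or platform batch
effects. Passing tests therefore demonstrate the correctness and internal
calibration of the algorithms under these conditions, not clinical
performance; the clinical rates themselves enter the package only as
transcribed count fixtures, which the metric machinery reproduces exactly.

## Study sizes and numerics

Validation studies run at: null calibration 5,000 euploid samples × 22
autosomes against a 50-sample panel; fetal-fraction recovery 100 male
samples (chrY) and 100/50 train/test (seqFF); segmentation oracle 100
instances; size–sensitivity 60 replicates per size at ff = 0.10 over
{0.75, 1.5, 2.5, 4, 7.5} Mb plus 30 maternal replicates at each of three
ff values; mechanism studies 30 replicates each. Degenerate inputs are
handled explicitly: all-zero counts, constant GC, zero-SD panels and
sub-minimum segments raise; non-positive fitted GC factors clamp to 10⁻⁶
and flag; ties in origin attribution resolve to indeterminate.
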