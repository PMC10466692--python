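# cfscreen

Extended non-invasive prenatal testing (NIPT-PLUS) screens maternal-plasma
cell-free DNA not only for the common trisomies but also for rare autosomal
trisomies (RATs), sex-chromosome aneuploidies (SCAs) and sub-chromosomal
copy-number variants (CNVs). `cfscreen` is a self-contained re-implementation
of that computational stack for methodologists and pipeline developers: a
synthetic maternal-plasma cohort generator with paired diagnostic
(amniocyte-equivalent) truth, the read-count normalization and calling
algorithms, dual fetal-fraction estimation, and the screening-vs-diagnostic
concordance analysis (sensitivity, PPV, miss rate) against chromosomal
microarray (CMA) findings parsed from ISCN-like result strings.

## The model

The unit of analysis is the binned read count. The genome is tiled into
windows; the *relative read number* of window *i* is
r_i = c_i / mean(c), and the linear GC effect is removed by ordinary least
squares: fit r = a + b·GC, then divide, renormalizing to mean 1.

**Aneuploidy.** For each chromosome *c* the GC-corrected read-mass fraction
x_c is standardized against a euploid reference panel,

    z_c = (x_c − μ_c) / σ_c,     |z_c| ≥ 3  →  screen positive,

with a finite-panel Student-t calibration so the threshold keeps its nominal
0.27% two-sided false-positive rate. Sex karyotypes (45,X; 47,XXX; 47,XXY;
47,XYY) come from a decision table over z_X, chrY presence and the chrY mass
excess expected for a single Y at the measured fetal fraction.

**CNVs.** Corrected ratios are segmented by recursive binary least-squares
(quadratic-cost) splitting under a dynamic threshold
|mean_L − mean_R| > z·σ̂·sqrt(1/L_L + 1/L_R), with σ̂ a robust per-window
noise estimate; deviating segments become dup/del calls, and the deviation
magnitude (≈ ff/2 for fetal, ≈ (1−ff)/2 or 1/2 for maternal heterozygous
events) attributes origin. An exact dynamic-programming minimal-SSE solver
is included as the oracle for the recursive heuristic.

**Fetal fraction (ff).** Two routes, combined: the chrY read excess over the
female background (male pregnancies), and a seqFF-style ridge regression on
the genome-wide proportion of short (100–150 bp) fragments plus GC and
read-count covariates. Samples with combined ff < 3.5% are no-calls.

**Simulation.** Plasma is a three-genome mixture — maternal, placental
(which sheds the "fetal" cfDNA) and fetal proper (what the diagnostic test
sees). Expected bin counts follow
depth · (a + b·GC_i) · [(1−ff)·m_i/2 + ff·((1−π)·b_i + π·k_i)/2] with
negative-binomial noise, so confined placental mosaicism and low-fraction
fetal mosaicism produce exactly the false-positive and false-negative
discordance seen clinically, without special-casing.

## Worked example

```python
import cfscreen as cf

genome = cf.SyntheticGenome()                      # 1/20-scale genome, 25 kb bins
panel = cf.simulate_cohort(50, {}, seed=42, genome=genome)
pipe = cf.ScreeningPipeline(genome).fit([(b, p) for b, p, _ in panel])

ev = cf.GenomicEvent("chr21", 3, label="trisomy")
spec = cf.SimSampleSpec(sample_id="case01", fetal_fraction=0.16,
                        fetal_sex="male", fetal_events=[ev],
                        placental_events=[ev], seed=7)
bins, profile, truth = cf.simulate_sample(spec, genome)
calls = pipe.screen(bins, profile, sample_id="case01")

print(f"fetal fraction: chrY {calls.ff.ff_y:.3f}, seqFF {calls.ff.ff_seqff:.3f}, "
      f"combined {calls.ff.ff_combined:.3f} (below LOD: {calls.ff.below_lod})")
for c in calls.autosome_calls:
    print(f"aneuploidy call: {c.chromosome} {c.call}, z = {c.z:.2f}")

diag = cf.truth_to_diagnostic(truth, genome)
pair = cf.match_calls(calls, diag, genome=genome.info)
print("T21 classification:", pair.counts["T21"])
```

prints

```
fetal fraction: chrY 0.165, seqFF 0.161, combined 0.163 (below LOD: False)
aneuploidy call: chr21 trisomy, z = 4.29
T21 classification: {'TP': 1, 'FP': 0, 'FN': 0, 'TN': 0}
```

The simulated male pregnancy carries a fetal+placental trisomy 21 at a true
fetal fraction of 16%; both fetal-fraction routes recover it, the chr21
Z score crosses the positivity threshold, and matching against the rendered
CMA finding classifies the case as a true positive.

A thin CLI binds the stages for shell use:

```bash
cfscreen --seed 3 simulate --n 100 --mix "t21=0.05,45x=0.03" --out data/
cfscreen --seed 3 call    --data data/ --out out/
cfscreen --seed 3 concord --data data/ --calls out/calls.json --out out/
cfscreen report                     # metric tables from packaged fixtures
cfscreen fixtures-verify
```

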