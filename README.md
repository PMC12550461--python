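# gmmdenoise

Statistically grounded abundance filtering of amplicon sequence variants
(ASVs), aimed at eDNA metabarcoding and intraspecific haplotype recovery.

## The problem

Amplicon sequencing of environmental DNA recovers unique sequence variants
whose low-abundance tail is contaminated by PCR and sequencing artefacts.
Discarding ASVs below an abundance cutoff is common practice, but the cutoff
is usually chosen by convention.  On the log10 read-count scale, however,
true variants and artefacts form distinct abundance modes: artefacts arise
late in PCR and are amplified for fewer cycles, so their read counts are
orders of magnitude smaller, with occasional early-cycle artefacts reaching
intermediate abundance.

`gmmdenoise` models the per-ASV log10 total read count *x* as a k-component
Gaussian mixture

    p(x) = Σ_j w_j · φ((x − μ_j) / σ_j) / σ_j ,

fitted by expectation–maximisation.  With components ordered by ascending
mean, the uppermost component describes true variants and the rest describe
artefacts.  The filtering threshold is the upper one-sided 95% confidence
limit of the **second-uppermost** component,

    t = μ_(k−1) + z_0.95 · σ_(k−1) ,

i.e. the upper tail of the error-abundance distribution; ASVs with
log10(reads) below *t* are removed (equality retains).  The number of
components k is chosen by two-fold cross-validation or by sequential
parametric bootstrap likelihood-ratio testing.

The package also ships the generative simulation that motivates this model:
a template pool of true variants goes through 35 PCR cycles with
Beta-distributed amplification efficiencies and a Beta-distributed
substitution rate (transitions only, one substitution per copy per cycle),
followed by a multinomial sequencing draw.  The simulator provides ground
truth for validating the filter end to end.

## Worked example

```python
import numpy as np
from gmmdenoise import (SimConfig, simulate, log_abundance,
                        GMMDenoiserCV, abundance_filter)

res = simulate(SimConfig(seed=3))          # one simulated sequencing run
x = log_abundance(res.table)               # log10 total reads per ASV
est = GMMDenoiserCV(k_grid=range(1, 6), method="cv", random_state=0).fit(x)
print(est.chosen_k_, round(est.threshold_, 3))
filtered, report = abundance_filter(res.table, est.threshold_)
err = ~res.is_true
print(round(float((x[err] < est.threshold_).mean()), 3),
      report.n_retained, report.n_input)
```

prints

```
5 0.779
0.964 194 2707
```

The simulated run observed 2707 ASVs (100 true templates plus 2607
artefacts).  Cross-validation selected k = 5; the confidence limit of the
second-uppermost component put the cutoff at 0.779 on the log10 scale
(about 6 reads), which removes 96.4% of the artefact ASVs (194 of 2707
input ASVs survive) while every true variant above the cutoff is retained.

The same workflow is available from the shell:

```sh
gmmdenoise simulate --seed 3 --out-table table.tsv --out-truth truth.tsv
gmmdenoise all --input table.tsv --k-max 5 --seed 0 --out run
gmmdenoise filter --input table.tsv --threshold 2.0 --truth truth.tsv --out manual
```

Each command writes JSON reports with a metadata block (seed, config hash,
version) and plot-ready tables (abundance histograms, fitted mixture
densities, CV curves) instead of rendered figures.

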