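# ienfa — area-based intraepidermal nerve fibre morphometry

Skin-biopsy assessment of small-fibre neuropathy rests on the
intraepidermal nerve fibre density (IENFd, fibres per mm of epidermal
length), counted manually on PGP9.5-stained sections. `ienfa` implements
an automated, area-based alternative and the statistics needed to validate
it: segment the nerve fibres inside a manually delineated epidermis, sum
the calibrated particle area

```
IENFa   = Σ area of retained nerve particles            [µm²]
IENFa/P = IENFa / epidermis perimeter                   [µm²/µm]
IENFa/A = 100 · IENFa / epidermis area                  [×100, dimensionless]
```

and compare the result against IENFd through reliability (two-way ICC with
a subject-level cluster bootstrap and Holm correction), association
(Pearson, OLS with standardized β, Steiger's Z for dependent
correlations) and diagnostic performance (empirical ROC, Youden-optimal
cut-point, DeLong's test for paired AUCs).

The package is aimed at neurophysiology/image-analysis groups who want a
scriptable, fully seeded re-implementation of this workflow: three
interchangeable segmentation backends — Sobel **e**dge **d**etection (ED),
**c**ustom convolution **f**iltering (CF) and a trainable random-forest
pixel classifier (**a**utomated **a**nnotation, AA) — plus particle gating
(0.40 µm² minimum area, periphery exclusion, 8-connectivity) and the full
statistics layer. Because the underlying patient data are not public,
seeded generators provide (a) two-channel biopsy-like images with
pixel-level ground truth and (b) subject-level case–control cohorts with
realistic group/age/sex structure, so every stage is testable end to end.

## Worked example

```python
import numpy as np, pandas as pd
from ienfa.synthetic_data import simulate_cohort
from ienfa.stats import linreg, pearson, roc
from ienfa.morphometry import classify_denervation

cohort = simulate_cohort(seed=1)                   # 48 neuropathy / 63 controls
ctrl = cohort[cohort.group == "control"]

x = pd.DataFrame({"age": ctrl.age, "male": (ctrl.sex == "M").astype(float)})
fit = linreg(ctrl.ienfd.to_numpy(), x, standardize=True)

r, (lo, hi), p = pearson(cohort.ienfd, cohort.ienfa_a_aa)
labels = np.array([classify_denervation(d, a)
                   for d, a in zip(cohort.ienfd, cohort.age)])
res = roc(cohort.ienfa_a_aa.to_numpy(), labels)
```

printing (via the obvious format strings):

```
control IENFd: 7.33 +/- 3.05 fibres/mm
age slope: -0.122 fibres/mm/yr (std beta -0.50)
pooled r(IENFd, IENFa/A-AA) = 0.91 (95% CI 0.87-0.93)
ROC: AUC 0.938, Youden J 0.78 at IENFa/A-AA <= 0.85
```

Reading: this simulated control arm has a mean IENFd of 7.33 fibres/mm
declining by about 0.12 fibres/mm per year of age; the area-based
IENFa/A-AA biomarker tracks IENFd strongly across the pooled cohort
(r = 0.91); and calling subjects "denervated" by the age-specific IENFd
cut-offs (5.88 fibres/mm below 60 years, 2.50 at/above), a single
IENFa/A-AA threshold of 0.85 separates them with AUC 0.94 and Youden
index 0.78. Single-cohort values fluctuate seed to seed around the
generator's configured targets.

## Command line

```bash
ienfa simulate --seed 1 --out runs/sim          # images + truth + cohort.csv
ienfa train    --scribbles labels.csv --out runs/clf img1.tif img2.tif
ienfa quantify --images sections/ --classifier runs/clf/classifier.joblib \
               --out runs/quant                 # sections.csv, subjects.csv
ienfa validate --cohort runs/sim/cohort.csv --seed 1 --out runs/stats
ienfa report   --out report.json runs/stats
```

Every run directory receives the resolved configuration, a log with tool
version, seed and thresholds used, and SHA-256 checksums of the inputs.
Exit codes: 0 success, 2 configuration error, 3 data error.

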