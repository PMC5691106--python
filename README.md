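# petdyntex

Dual-time-point ¹⁸F-FDG PET analysis of tumor heterogeneity: SUV
computation, threshold segmentation, SUV/volume metrics, 18
three-dimensional textural features, and paired cohort statistics —
with a synthetic phantom generator so every stage is testable without
patient data.

## Who this is for

Nuclear-medicine and radiomics researchers studying how metabolic tumor
characteristics evolve between a standard (~60 min post-injection,
"PET-1") and a delayed (~3 h, "PET-2") acquisition. Tumor FDG uptake
keeps rising for hours after injection, so SUV-based variables and
spatial heterogeneity measures are *dynamic*; this package provides the
full measurement chain and the paired statistics to quantify that
dynamics on a cohort.

## What it computes

**SUV.** Stored scanner values are converted with the decay-corrected
body-weight formula

    SUV = SV · RS · W / ((RTD · DF) · e^(−ln2 · Et / HF))

(`SV` stored value, `RS` rescale slope, `W` weight in g, `RTD` injected
dose in Bq, `DF` decay factor, `Et` elapsed time per slice in s, `HF`
half-life in s), which corrects activity back to injection time and
makes both timepoints directly comparable.

**Segmentation.** The lesion is located in a manual 3D box; the VOI is
every voxel with SUV ≥ 40% of the box SUVmax (inclusive). Enclosed
sub-threshold cavities are counted as necrosis and stay excluded; with
multifocal disease the component with the highest uptake is kept
(26-connectivity throughout).

**Metrics.** SUVmax, SUVmean, SUVpeak (max 3×3×3-cube mean), MTV (VOI
volume, cm³), TLG = SUVmean × MTV.

**Texture (18 features).** On a 16-level discretized VOI: co-occurrence
matrix features ENT, HOM, CON, DIS, UNI (pairs over all 26 neighbours,
i.e. 13 directions and their opposites, normalized to probabilities,
natural log, 0·ln 0 ≡ 0) and run-length matrix features SRE, LRE, LGRE,
HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLNU, RLNU, RPC (maximal equal-level
runs over the 13 directions, e.g. SRE = (1/n_r) Σ RLM(i,j)/j², RPC =
n_r / Σ RLM(i,j)·j). On the raw SUV field: the gradient energies

    SE = √(∫|∇u|² dV) / √(∫|u|² dV),   TE = √(∫|∇u|² dV) / max u

with central differences in mm and one-sided fallback at the VOI edge.

**Cohort statistics.** Per variable, PET-1 vs PET-2 with a paired *t*
test when the paired differences pass Shapiro–Wilk normality, Wilcoxon
signed-rank otherwise; negative statistic ⇔ PET-1 lower. Spearman
correlations of texture with MTV/TLG (|r| > 0.75 flagged strong) and
stratification at MTV = 10 cm³.

## Worked example

```python
from petdyntex import DualTimePointModel, make_cohort

cohort, truths = make_cohort(56, seed=7)   # 56 paired synthetic patients
results = DualTimePointModel(cohort).fit(alpha=0.05)
print(results.summary())
```

prints (abridged):

```
Dual-time-point paired comparison (n = 56 patients, alpha = 0.05, correction = none)
A negative statistic means the PET-1 value was lower than PET-2.
variable mean±SD PET1 mean±SD PET2     test statistic p_value  significant
 suv_max  8.12 ± 2.27  9.16 ± 2.66 paired-t    -13.10  0.0000         True
suv_mean  5.13 ± 1.44    5.8 ± 1.7 wilcoxon     -6.51  0.0000         True
suv_peak  6.66 ± 2.06  7.45 ± 2.47 wilcoxon     -6.51  0.0000         True
 mtv_cm3  19.7 ± 12.2  17.8 ± 11.1 wilcoxon      6.36  0.0000         True
     tlg  99.3 ± 67.3   102 ± 69.7 wilcoxon     -3.05  0.0023         True
...      (18 texture rows follow)
```

The SUV metrics are significantly *higher* at the delayed acquisition
(negative statistics) while the 40%-threshold volume is significantly
*smaller* (positive statistic) — exactly the dynamics the generator
programs: delayed uptake gain 1.18 and profile sharpening 1.12.
`results.texture_volume_correlations()` gives the Spearman table
against MTV and TLG; on this cohort the run-length non-uniformity
features correlate strongly with tumor volume (GLNU–MTV r = 0.977,
RLNU–MTV r = 0.999).

A command-line interface covers the same pipeline on files:

```bash
petdyntex simulate --n 56 --seed 7 --out-dir phantoms/
petdyntex extract --pet1 pet1.nii --pet2 pet2.nii --box 40,64,40,64,12,36 --out features.csv
petdyntex stats --features features.csv --alpha 0.05
```

## Documentation

`docs/methods.md` describes the model assumptions, numerical choices,
the synthetic generator's design and what it does and does not emulate.
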