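# tampol

Single-cell analysis of tumour-associated macrophage (TAM) polarisation in
multiplex-immunohistochemistry tissue-microarray (TMA) data, with a
synthetic-cohort simulator so the whole pipeline is testable without patient
data.

## The problem

Macrophages in the tumour microenvironment span a phenotype continuum from
anti-tumoural **M1** (CD86, HLA-DR high) to pro-tumoural **M2** (CD163, MRC1
high). Given per-cell marker intensities exported from an image-analysis
tool (e.g. QuPath) for 1-mm TMA cores — each segmented into tumour
epithelium and stroma, with cells phenotyped as macrophage / tumour cell /
other — this package:

1. scores each macrophage with a **polarisation index**

   `index = (s_CD86 + s_HLADR) − (s_CD163 + s_MRC1)`

   where `s_m` is the percentile score of marker `m` across the pooled
   macrophage population (rank-based, so invariant to monotone intensity
   transforms), and classifies the pooled index distribution by quartiles:
   one extreme quartile M1-like, the opposite extreme M2-like, the middle
   half "mixed" (excluded from density analyses);
2. computes per-case **densities** (cells/mm²) of M1- and M2-like
   macrophages per region (tumour centre / invasive margin) and compartment
   (epithelium / stroma), **M1:M2 density ratios**, a whole-tumour
   integrative polarisation score, and intratumoural **heterogeneity** as
   the SD of per-core densities;
3. measures **nearest-neighbour distances** (NND) from each macrophage to
   the closest tumour cell in the same core, summarised per class, plus
   penalized-spline curves of scaled marker intensity versus distance;
4. runs **survival analysis**: ROC/Youden dichotomisation of each exposure
   against 5-year all-cause mortality, Kaplan–Meier curves with log-rank
   tests, and crude plus multivariable Cox proportional-hazards models
   (adjusted for sex, age, comorbidity score, neoadjuvant therapy, number of
   metastases, former liver metastases, and synchronicity), after excluding
   R1 resections and 30-day post-operative deaths.

The `tampol.synthetic` module generates full cohorts — core geometry,
Poisson cell placement, class-conditional lognormal marker intensities,
class-specific macrophage–tumour attraction, and exponential
proportional-hazards outcomes — with every planted truth recorded, so
classifier recovery, effect-direction detection and hazard-ratio recovery
can all be verified.

## Worked example

```python
from tampol.synthetic import SimConfig, generate_cohort
from tampol.polarisation import score_macrophages
from tampol.density import build_density_profiles
from tampol.spatial import nnd_table, median_nnd_by_class, percent_closer
from tampol.cell_model import filter_cores

cohort = generate_cohort(SimConfig(n_patients=10, seed=1))
cores = filter_cores(cohort.cores)          # drop QC-failed cores
polar = score_macrophages(cores)            # percentile scores -> quartile classes
profiles = build_density_profiles(cores, polar)
mets = profiles[profiles["sample_id"].str.endswith("_MET")]
nnd = nnd_table(cores, polar)
m1, m2 = median_nnd_by_class(nnd, "M1"), median_nnd_by_class(nnd, "M2")
```

This prints (via the obvious `print` calls):

```
macrophages scored: 33923
{'mixed': 0.5, 'M1': 0.25, 'M2': 0.25}
median stromal M2 density, invasive margin (mets): 277.5 cells/mm^2
median M1:M2 ratio, invasive-margin stroma (mets): 0.43
median NND: M1 18.3 um, M2 33.1 um (45% closer)
```

The class fractions are 25/50/25 by construction of the quartile rule; the
metastasis samples show the planted M2-dominant polarisation (stromal M1:M2
ratio below 1), and M1-like macrophages sit closer to tumour cells than
M2-like ones, reflecting the class-specific attraction in the generator.

The same analysis is available from the shell:

```bash
tampol all --seed 1 --outdir out/       # simulate -> ... -> report.md
tampol simulate --seed 1 --outdir data/
tampol polarise --cells data/cells.csv --areas data/areas.csv --out polar.csv
```

`out/report.md` contains cohort descriptives, paired primary-versus-
metastasis comparisons (Wilcoxon signed-rank), NND summaries, heterogeneity
tables and the per-exposure survival table (ROC cutoff, 5-year OS low/high,
log-rank p, crude and adjusted HRs with 95% CIs).

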