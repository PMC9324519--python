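# paslab

Pathway activation scoring and correlation-screen analysis for bulk
transcriptomics, built for dependency studies of the kind that ask: *is a
receptor kinase such as KIT a real vulnerability of a tumor type, and what
signaling changes follow when it is knocked down?* The package implements
the full computational chain such a study needs — expression preprocessing,
pathway activation levels from case-to-normal ratios, pan-cancer
expression-distribution clustering, immune-signature correlation screens
under adaptive FDR, and drug-sensitivity vs gene-dependency deconvolution —
together with seeded synthetic-data generators that plant known effects, so
every stage is testable offline with closed-form expectations.

## The core statistic

For a molecular pathway *p* with member genes *n*, each carrying a signed
activator/repressor role ARR(n,p) ∈ {−1, −0.5, 0, 0.5, 1} (negative for
repressors of the pathway's output, positive for activators), the pathway
activation level for a case-vs-norm comparison is the role-weighted mean of
log case-to-normal ratios:

    PAL(p) = Σₙ ARR(n,p) · log CNR(n) / Σₙ |ARR(n,p)|

where CNR(n) is gene *n*'s mean expression in the case samples divided by
its mean in the control ("norm") samples. Positive PAL means the pathway's
output is up in the case condition; a repressor going down raises PAL. The
normalizing denominator makes scores comparable across pathways of different
sizes. Genes not measured on the platform are excluded from numerator and
denominator alike. The same score, computed per sample against a cohort-mean
norm, yields the per-sample pathway activation strength (PAS) used in
tumor-cohort correlation analyses.

Around it the package provides: geometric probe averaging and quantile
normalization (`expression_io`), role-annotated pathway collections in an
extended GMT dialect (`pathway_model`), cohort histogram clustering with
Ward.D2 linkage and the strict >5% high-expressor flag
(`cohort_distributions`), mean-square signature scores with Pearson
correlation and Benjamini–Krieger–Yekutieli two-stage FDR
(`association_screen`), and channel-averaged drug-target correlation over
RNAi/CRISPR dependency panels (`dependency_pharm`).

## Worked example

Generate a case/control experiment in which the `ERK_survival` pathway is
activated by 1.0 log10 unit (activators up ×10, repressors down ×10, log
noise SD 0.2), then score all pathways:

```python
from paslab import pas_table, count_regulated
from paslab.pipeline import demo_collection
from paslab.synthetic import gen_pathway_dataset

coll = demo_collection()
expr, design = gen_pathway_dataset(coll, "ERK_survival", delta=1.0,
                                   sigma=0.2, seed=7)
res = pas_table(expr, design, coll)
print(res.table.round(3))
print(count_regulated(res, threshold=0.3))
```

```
                    klass    pal  n_members_used
pathway
ERK_survival    signaling  1.050               5
ATM_G2M_arrest  signaling -0.005               4
EPO_signaling   signaling  0.038               4
glycolysis      metabolic  0.008               4
oxphos          metabolic -0.090               4

{'n_up': 1, 'n_down': 0, 'n_total': 5, 'frac_up': 0.2, 'frac_down': 0.0}
```

The planted pathway is recovered at PAL ≈ 1.05 (exactly 1.0 in the
noise-free case), the unperturbed pathways sit near 0, and the regulated-
pathway counter flags exactly the planted activation at threshold 0.3.

The same operations are exposed on the command line:

```
paslab run --config examples/demo_config.yaml --out out/
paslab --help        # normalize, pas, distributions, screen, pharm, simulate, run
```

`paslab run` executes the full synthetic workflow (simulate → PAS → screen →
pharm) and writes a manifest checksumming every output; reruns with the same
config are byte-identical.

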