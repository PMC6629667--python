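# tactome

Bulk tumour expression profiles are mixtures: malignant tumour cells (TC)
and everything else living next to them — fibroblasts, immune cells,
endothelium, fat — collectively the tumour-adjacent cells (TAC). `tactome`
separates the two computationally and re-runs the standard prognostic
toolbox on each compartment, for researchers who want to know whether a
signal seen in bulk expression comes from the cancer cells, from their
microenvironment, or from an interaction of the two.

Given a bulk expression matrix (genes × samples, microarray-style
intensities), a panel of non-cancerous reference profiles and clinical
annotation, the package:

1. **deconvolves** each sample in linear space under the convex mixing
   model `b = p·t + (1−p)·s` — estimating a per-subtype cancer reference
   profile `m`, per-sample purity `p` (the RNA-signal fraction from tumour
   cells) and TC profiles `t` by alternating constrained least squares,
   then extracting TAC profiles by the exact inversion
   `s = (b − p·t)/(1 − p)`;
2. derives the **unexpressed-intensity threshold** from chromosome-Y genes
   (all-female cohort) and applies the shared log2 floor;
3. screens every gene in every compartment with **dichotomized Cox
   models** of five-year overall survival (median split, or threshold
   split when ≥79 patients exceed the unexpressed threshold), with BH
   false-discovery control, a |log2 HR| > 0.4 effect-size cutoff and a
   calibrated Schoenfeld-residual proportional-hazards check;
4. models **TC–TAC interactions** per gene
   (`survival ~ TAC + TC + TC×TAC` over four high/low groups) and
   classifies each gene as tc_only, tac_only, additive, saturation,
   antagonistic or synergistic;
5. clusters samples by **divisive (DIANA)** and **consensus clustering**
   and classifies subtypes with a trained nearest-centroid model;
6. benchmarks **random 50-gene biomarkers** (random forests, three-fold CV
   tuning, withheld test split) per profile type;
7. tests driver-gene mutations for **compartment-specific differential
   expression** (moderated linear models, cis/trans annotation).

A first-class synthetic-cohort generator produces METABRIC-like data with
known ground truth (purities, compartment profiles, planted survival and
mutation effects), so every stage is testable without controlled-access
data.

## Worked example

```python
import numpy as np
from tactome import RunConfig, SimulatorConfig
from tactome.simulate import (_build_gene_plan, generate_normal_panel,
                              generate_cohort)
from tactome.deconvolution import run_deconvolution_by_subtype

config = SimulatorConfig(n_genes=1500, n_per_subtype=38, n_normal_refs=60,
                         n_program_genes=150, noise_cv=0.1)
plan = _build_gene_plan(config, seed=23)
panel = generate_normal_panel(config, seed=23, plan=plan)
bulk, clinical, mutations, truth = generate_cohort(config, panel, 23, plan)

result = run_deconvolution_by_subtype(bulk, panel, clinical, RunConfig())
p_true = truth.purity.loc[result.purity.index]
print(f"median purity: {result.purity.median():.2f}")
print(f"purity r vs truth: {np.corrcoef(result.purity, p_true)[0, 1]:.3f}")
```

prints

```
median purity: 0.46
purity r vs truth: 0.974
```

i.e. on a 152-sample synthetic cohort with measurement noise, the median
sample is estimated to be about half tumour signal, and the per-sample
purity estimates track the generating truth with r ≈ 0.97. The
`DeconvolutionResult` also carries the TC/TAC matrices (the mixing
identity is exact before flooring) and per-subtype reference profiles.

The same flow is available from the shell:

```bash
tactome all --config cfg.yaml --outdir out --seed 20
```

which writes one TSV per result table (purities, screens, interaction
classes, cluster labels, biomarker AUCs, mutation reports), a JSON run
metadata file and a log; reruns with the same seeds are byte-identical.

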