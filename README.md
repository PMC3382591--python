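# tfnet

Integrative identification of a **minimal connected network (MCN) of
transcription factors regulated in cancer** and screening of its central
TFs' target genes for **accessible, cancer-specific, survival-associated
biomarker candidates**.

`tfnet` is aimed at computational biologists who have (i) expression and
copy-number profiles for a panel of cancer cell lines, (ii) a catalogue of
experimentally established TF→target regulations, (iii) a curated
protein–protein interactome, and (iv) patient expression/survival cohorts,
and who want to run the whole integrative chain — or any single stage — as
a reproducible, tested pipeline. A synthetic-data module generates all of
these inputs with planted ground truth, so every stage can be validated
without any external download.

## The method

1. **TF regulation scoring.** For each cell line, genes differentially
   expressed versus the pool of all other lines are called with a
   two-sample Kolmogorov–Smirnov test on replicate values; a gene is kept
   when its e-value (p × number of genes tested) is ≤ 10. Each line's
   regulated gene list is scored against the catalogue: for every TF, the
   one-sided Fisher/hypergeometric enrichment of its known targets in the
   list gives a regulation score −log₁₀(e-value), floored at 0, so a
   positive score means e < 1. TFs never significant in any line are
   discarded.
2. **CNV normalization.** Significantly altered genomic regions
   (GISTIC-style table, q ≤ 0.25) are reduced to one median log₂-ratio per
   region and sample; every gene overlapping a significant region inherits
   that median, all other genes get 0.
3. **Correlation-profile regression.** Three TF × cell-line matrices —
   regulation scores *R*, TF-gene expression *E*, TF-locus CNV *C* — are
   turned into TF–TF Pearson correlation profiles, and for each TF the
   model **R = β₀ + β₁·E + β₂·C** is fitted by OLS across the other TFs.
   TFs with both slopes significant (p ≤ 0.05 each, no multiplicity
   correction) are *correlatively regulated*: their inferred regulation is
   explained by their own expression and copy number.
4. **Minimal connected network.** The selected TFs are connected over the
   evidence-filtered interactome (≥ 2 experimental evidences) keeping
   direct interactions and single tolerated intermediates (shortest paths
   of length ≤ 2); the largest connected component is the MCN. Its node
   betweenness, degree and clustering distributions are compared by KS
   tests against MCNs of 1,000 random node sets, and a negative control
   repeats the extraction on 100 random TF lists from the catalogue.
5. **Biomarker screen.** Targets of the top-10 most central MCN TFs
   (betweenness ranking) are restricted to secreted/transmembrane
   ("accessible") genes, tested on a mixed patient cohort for cancer
   specificity (differential in cancer vs rest, not differential in
   inflammation; Welch t-tests with Benjamini–Hochberg q ≤ 0.05), and
   finally screened per survival cohort by splitting patients into
   expression tertiles and comparing the three Kaplan–Meier curves with a
   log-rank test (pass = p ≤ 0.05 in at least one cohort).

## Worked example

Generate a synthetic study with planted ground truth and run the whole
workflow:

```bash
tfnet synth --seed 1 --out study/
tfnet run --config study/run.cfg   # or use the Python API below
```

Python API:

```python
from tfnet import SyntheticConfig, generate_all, write_synthetic_inputs, run_pipeline

bundle = generate_all(SyntheticConfig(rng_seed=1))
cfg = write_synthetic_inputs(bundle, "study/inputs", out_dir="study/run")
summary = run_pipeline(cfg)
print(len(summary["selected_tfs"]), summary["mcn"]["significance"])
print(summary["biomarkers"])
```

With seed 1 this prints 33 selected TFs; the MCN covers 56 proteins
(31/33 seeds mapped), with KS p-values ≈ 2.7×10⁻⁵ (betweenness),
4.7×10⁻¹⁰ (degree) and 3.3×10⁻¹⁵ (clustering) against 1,000 random
networks and a negative-control p ≈ 4.5×10⁻⁴ against 100 random TF lists
— the planted module is a significant, hub-centred subnetwork, not an
artifact of upstream false positives. The top-10 central nodes carry
68.5% of the total betweenness; their 137 catalogue targets reduce to 52
accessible genes, of which 12 are called cancer-specific (all 12 planted
cancer-only genes recovered, all 6 inflammation-shared decoys excluded)
and 10 pass the tertile survival screen, including all 8 planted
survival-associated biomarkers.

Every stage is also exposed on its own (`tfnet tf-scores`,
`tfnet cnv-matrix`, `tfnet select-tfs`, `tfnet mcn`, `tfnet biomarkers`,
`tfnet survival`) and as plain library functions.

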