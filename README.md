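# escapescreen

Tools for finding acquired immune-escape drivers in longitudinal tumor
whole-exome data from patients on checkpoint blockade, and for testing
whether loss of heterozygosity (LOH) in an antigen-presentation gene —
canonically *B2M*, the obligate subunit of every HLA class I complex —
predicts non-response and shorter survival in cross-sectional cohorts.

It is written for cancer-genomics analysts who already have per-sample
somatic variant calls (with alt/ref read counts), allele-specific
copy-number segments, and tumor purity/ploidy estimates, and who want a
tested, reproducible implementation of the downstream analysis:

- **Consensus voting and force-calling** — keep variants called by at
  least two of the callers in each sample, take the union across a
  patient's biopsies, and assemble a complete (variant × sample) alt/ref
  count matrix with explicit 0/*N* cells instead of gaps.
- **Cancer cell fractions (CCF)** — convert a variant allele fraction to
  the fraction of cancer cells carrying the variant via
  `E[VAF] = CCF·α·m / (α·c_t + 2(1−α))`, where α is purity, `c_t` the
  local total copy number and `m` the mutation multiplicity; 95% CIs are
  exact binomial intervals mapped through the linear inverse. Detection
  power is the binomial tail probability of seeing ≥3 variant reads for
  a clonal variant at the observed depth.
- **Gene-level LOH** — a gene has LOH in a sample when segments with
  minor-allele copy number 0 cover the gene interval; biallelic loss
  (total copy number 0) is flagged separately.
- **The resistance screen** — a gene is a candidate escape driver when
  it carries ≥2 distinct non-silent variants, adequately powered
  (detection power ≥0.9 in *every* biopsy), each dominant (CCF reaching
  0.5) in at least one progression biopsy while absent (CCF ≤0.05) in
  every baseline/regression biopsy, with LOH over the gene wherever a
  variant sweeps.
- **Neoantigen load** — strong/weak MHC-I binder classification from
  NetMHCpan-style percentile ranks (mutant <0.5 / <2, wild-type >2) and
  the count of mutated genes with at least one binder.
- **Cohort endpoints** — one-sided Fisher exact enrichment of LOH in
  non-responders (built from the hypergeometric pmf), Kaplan–Meier
  curves and the log-rank test for overall survival, gene-set expression
  scores (geometric mean of TPM+1), and the closed-form IHC-bin, ddPCR
  fractional-abundance and in vivo competition formulas.
- **A synthetic cohort generator** — multi-biopsy patients with planted
  escape lesions (two sibling frameshifts at CCF 0.74/0.55 in distinct
  progression biopsies plus an overlapping deletion), binomial read
  sampling at ~150×, and a 105-patient cross-sectional cohort with
  LOH prevalence ~29% vs ~11% by response group and survival coupled to
  LOH status — so every stage is testable without access-controlled
  patient data.

## Worked example

```python
from escapescreen import (
    SimConfig, simulate_longitudinal_patient, ResistanceScreenModel,
    simulate_validation_cohort, CohortEnrichmentModel, DEFAULT_ESCAPE_GENE,
)

cohort = simulate_longitudinal_patient(SimConfig(seed=42), patient_id="P1")
print(ResistanceScreenModel.from_cohort(cohort).fit().summary())
```

```
Longitudinal resistance screen
==============================
patients screened : 1
patients skipped  : 0
thresholds        : power>=0.9, CCF_prog>=0.5, CCF_reg<=0.05, non-silent>=2
hits              : 1

patient_id gene  n_nonsilent  loh_in_progression  max_ccf_progression  max_ccf_nonprogression                passing_variants
        P1  B2M            2                True             0.868157                     0.0 15:45003775CT>C;15:45003795CT>C
```

Out of 252 variant rows (250 background passengers plus the two planted
frameshifts) the screen reports a single hit: the escape gene, carrying
two non-silent frameshifts that are dominant only during progression
(estimated CCF up to 0.87 there, 0.0 in every pre-progression biopsy)
with LOH over the locus in the progression biopsies.

```python
val = simulate_validation_cohort(SimConfig(seed=8))
print(CohortEnrichmentModel.from_cohort(val, DEFAULT_ESCAPE_GENE).fit().summary())
```

```
Cohort LOH enrichment & survival
================================
patients                  : 105
LOH | non-responders      : 19/69 (27.5%)
LOH | responders + LTS    : 2/36 (5.6%)
one-sided Fisher exact p  : 0.0053
log-rank statistic        : 7.261
log-rank p (chi2, 1 df)   : 0.0070
```

Here LOH in the escape gene is enriched among non-responders (27.5% vs
5.6% in this replicate) and carriers have significantly shorter overall
survival.

The same stages are available from the shell:

```bash
escape-screen simulate --seed 5 --out-dir sim/
escape-screen screen --variants sim/variants.tsv --segments sim/segments.tsv \
    --samples sim/samples.tsv --out hits.tsv
escape-screen run-all --seed 5 --out-dir results/
```

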