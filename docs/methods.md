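# Methods

## The CCF model

A somatic variant observed at alt/ref counts in a bulk biopsy is related
to the fraction of cancer cells carrying it (CCF) through the standard
allelic model with diploid normal contamination:

    E[VAF] = CCF · α · m / (α · c_t + 2(1 − α))

with α the tumor purity, `c_t` the total copy number of the locus in
cancer cells (taken from the allele-specific segment containing the
variant; 2 where no segment covers it), and `m` the number of mutated
copies per mutated cell. Assumptions: the normal compartment is diploid
and unmutated at the locus, copy number is clonal within the biopsy,
and all mutated cells share one multiplicity. Purity and ploidy are
inputs (from upstream purity/ploidy inference), never estimated here.

`m` is not observable from one biopsy; we use the integer that best
explains the observed VAF for a clonal variant,
`round(VAF·(α·c_t + 2(1−α))/α)`, clamped to `[1, round(c_t)]`. This is
correct for clonal variants and biases subclonal ones toward `m = 1`,
which is the common case for passengers.

Because the VAF→CCF map is linear, the 95% CI is the exact
Clopper–Pearson binomial interval on the VAF pushed through the same
scale factor and clamped to [0, 1]. Clopper–Pearson is deterministic
and conservative; measured coverage at 150× across purities 0.3–0.9 is
~96% (the acceptance suite checks 95% ± 2% over 2 000 simulated
variants).

**Detection power** for a variant position is the probability that a
clonal variant (CCF = 1) would yield at least `k_min = 3` supporting
reads at the observed depth, i.e. a binomial tail at the clonal VAF.
Three reads is the conventional minimum-evidence threshold; the value is
configurable. Power is non-decreasing in depth, purity and multiplicity.

## Consensus, force-calling, LOH

Voting is per sample: a variant is kept where ≥2 of the available
callers report it. The union of kept variants across a patient's
biopsies is then force-called — alt/ref counts are required for every
(variant, sample) pair, so a variant private to one biopsy carries an
explicit 0/N observation elsewhere and "absent" is distinguishable from
"unassayed". A missing pair is an error, not a silent gap. The only
artifact filter retained is an optional minimum alt-count; caller-
internal and fixation-artifact heuristics are out of scope.

Gene-level LOH in a sample requires the union of minor-copy-number-0
segments to cover the full gene interval (`min_covered_fraction = 1.0`
by default — conservative, and appropriate because escape-gene
deletions are typically multi-megabase while the gene is ~7 kb; the
threshold is configurable and logged). Intervals are 1-based inclusive
on disk and converted to half-open arithmetic internally. Overlapping
segments are resolved first-wins in (start, end) order. Biallelic loss
(total CN 0 over the same fraction) is reported as a separate flag.
A chromosome absent from a sample's segmentation yields `loh = False`
with a warning: absence of evidence, not evidence of deletion.

## The resistance screen

For a patient with at least one progression and one non-progression
biopsy, a gene is a hit when:

1. it carries ≥2 distinct non-silent variants (missense, nonsense,
   frameshift, splice-site, other protein-altering) whose detection
   power is ≥0.9 in **every** biopsy;
2. each such variant is *dominant* in ≥1 progression biopsy and has a
   CCF point estimate ≤0.05 in every baseline/regression biopsy;
3. the gene is under LOH in every progression biopsy where one of those
   variants is dominant.

Exclusivity is evaluated per variant, not per gene-pooled CCF, because
sibling escape subclones can each carry their own lesion in different
biopsies. Hits are sorted by maximum progression CCF.

**Dominance uses the 95% CI upper bound** (`ci_high ≥ 0.5`) rather than
the point estimate. This was a deliberate design choice: with binomial
read noise at 150× and purity as low as 0.3, a truly dominant subclone
at CCF 0.55 has its *point* estimate below 0.5 in a quarter or more of
replicates, which would make recovery of a planted escape gene
unacceptably unreliable; classifying on the interval (the same interval
the CCF error bars display) restores ≥95% recovery while the
point-estimate condition on the regression side (≤0.05) keeps
state-independent passengers out. The measured patient-level false-hit
rate under the no-escape scenario is 0% over 100 replicates. Both
thresholds are the smallest values consistent with the observed escape
CCFs (0.74/0.55 dominant, ~1% leakage in non-carrier biopsies) and are
configurable; `min_nonsilent = 1` admits single-lesion evidence.

## Neoantigen classification

Percentile ranks (lower = stronger binding) are consumed as input. A
mutant peptide is a strong binder at rank < 0.5 and weak at rank in
[0.5, 2), in both cases only when the matched wild-type peptide is a
non-binder (rank strictly > 2). Boundaries are strict-< on the mutant
side and strict-> on the wild-type side; the three classes partition the
rank plane and strong/weak are mutually exclusive. Neoantigen load is
the number of distinct mutated genes per patient with ≥1 strong or weak
binder, invariant to duplicate peptide rows.

## Cohort endpoints

The 2×2 table rows are LOH yes/no and columns non-responders vs
responders pooled with long-term survivors. The Fisher test is one-sided
in the fixed direction "LOH enriched in non-responders", computed as the
exact hypergeometric upper-tail sum; it is validated against exhaustive
enumeration of all fixed-margin tables with margins ≤30. Degenerate
margins return p = 1 with a warning.

The survival comparison is the standard two-group log-rank test:
hypergeometric mean and variance of the group-1 event count at each
distinct event time, chi-square p on 1 df (two-sided), Kaplan–Meier
product-limit curves per group. The implementation is a direct
vectorized transcription of that definition and is cross-checked against
lifelines in the test suite; it is unstratified, and no multiple-testing
correction is applied across a gene panel (single-gene usage is the
primary case; this mirrors per-gene reporting and is a known
limitation).

Gene-set expression scores are geometric means of TPM + 1; the +1
pseudocount prevents a single zero from annihilating the score and the
result is reported on that shifted scale. IHC staining bins are
[0,10), [10,50), [50,80), [80,100] — the printed ranges share endpoints,
so half-open-with-closed-top is the convention that makes the function
total. The ddPCR fractional abundance and two-clone competition scores
are the stated closed forms, with explicit domain errors at zero
denominators.

## The synthetic cohorts

The longitudinal generator emulates a serial-biopsy patient: one
baseline, then regression, then progression biopsies (default 5 total),
purity uniform on [0.3, 0.9], ploidy 2, depth Poisson around 150× (the
study-grade tumor coverage), and read counts binomial at the model VAF.
Background passengers (default 250, matching the scale of an adequately
powered exome screen) have state-independent CCFs — 70% clonal, the
rest uniform on [0.1, 0.9], with per-biopsy Gaussian jitter of SD 0.05
(a knob, not a claim) — drawn over a 200-gene pool so that
multi-mutation genes occur under the null and the screen's
multiple-mutation criterion is exercised nontrivially. Under the escape
scenario, progression biopsies carry a deletion (total CN 1, minor CN 0)
extending 2 Mb on either side of the escape gene, and two frameshifts in
the gene whose true CCFs are 0.74 and 0.55 in distinct progression
biopsies, 0.01 in the other progression biopsies and 0 before
progression — the two-sibling escape pattern. Caller support is
evidence-driven: ≥3 alt reads earns two or three voting callers, 1–2
reads a single caller, so weak calls are exercised through the voting
rule.

The cross-sectional generator draws per-patient LOH status Bernoulli by
response group (29% in 69 non-responders vs 11% in 26 responders + 10
long-term survivors), writes the corresponding segment profiles, and
draws survival from an exponential proportional-hazards model (baseline
hazard 1/1000 per day, hazard ratio 2 for LOH carriers — chosen to give
endpoint p-values of the observed order at n = 105) with independent
exponential censoring whose rate yields an expected censored fraction
of `censoring_rate` (default 0.4) under the baseline hazard.

What the simulator does **not** model: trinucleotide mutation spectra,
sequencing error and strand artifacts beyond binomial sampling,
subclonal copy number, purity estimation error, phylogenetic structure
beyond the two planted siblings, and caller-specific error profiles.
Passing tests therefore demonstrate correctness of the analysis logic
under its stated statistical model, not robustness to every real-data
pathology.

## Numerical conventions and problem sizes

All randomness flows through `numpy.random.default_rng` from a single
integer seed; identical (config, seed) give byte-identical cohorts.
Ties in survival times are handled by the hypergeometric variance;
segment overlap resolution is first-wins; CCF estimates are clamped to
[0, 1] and CIs forced to bracket the point estimate. Validation runs
use 100 replicate patients per scenario for recovery/specificity,
2 000 simulated variants for CI coverage, 5 000 (test) / 2 000 (script)
label permutations for log-rank calibration, and 20 replicate
105-patient cohorts for the cross-sectional endpoint summaries — sizes
at which every Monte-Carlo band in the suite is stable across seeds.
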