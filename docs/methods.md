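# Methods

`sigprog` implements a somatic-mutation prognosis pipeline for cancer
cohorts: single-base-substitution (SBS) catalogs, de-novo mutational
signatures, gene-level signature-attribution scores, and a five-year-survival
classifier built on those scores. This note records the models, the
numerical choices, and what the synthetic cohorts do and do not establish.

## Substitution catalogs

Somatic substitutions are classified into the standard 96 trinucleotide
classes: six pyrimidine-strand substitution types (C>A, C>G, C>T, T>A, T>C,
T>G) crossed with the 4×4 flanking-base combinations. A call whose
reference base is a purine is reverse-complemented together with both
flanks before labeling, so classification is strand-symmetric by
construction (an involution-consistency property the tests enforce by
enumeration). Class order is fixed — substitution type major, then 5'
flank, then 3' flank, alphabetical — so catalog files are column-stable.

Indels are never classified but count toward each sample's total burden,
which drives hypermutation flagging. The default hypermutation threshold is
1000 total somatic mutations per sample, the common exome-scale convention;
it is a parameter because whole-genome catalogs need a larger cut. Records
with non-ACGT flanks or alleles are skipped and counted, not fatal.
Coordinates follow the MAF convention (1-based, `+` strand assumed;
strand handling lives entirely in the classifier).

## Signature extraction

The catalog transpose `V` (96 × N counts) is factorized as `V ≈ W·H` with
`W` the 96 × K signature profiles and `H` the K × N exposures. The
objective is the generalized Kullback–Leibler divergence under
multiplicative updates — the natural likelihood for Poisson-like counts —
with a Frobenius option behind a flag. Each fit starts from strictly
positive uniform random factors; the default schedule is 20 restarts,
2000 iterations, tolerance 1e-6, best restart by objective with ties to the
lowest restart index. Everything is driven by a single integer seed through
`numpy.random.SeedSequence`, so results are reproducible bit-for-bit.

After the best restart, `W` is column-normalized (each signature is a
probability distribution over the 96 classes) and `H` is refit with `W`
fixed by KL multiplicative updates. This refit is the KL analogue of
non-negative least squares and has a useful exact property: with
column-stochastic `W`, the converged activities of each sample sum to that
sample's mutation count, so exposures read directly as attributed counts.
Signatures are ordered by descending total activity and named `S1…SK`
until reference matching renames them.

Rank selection scans a K grid and reports, per K, the best-restart
objective and a stability score: the mean cosine between each restart's
profiles and the best restart's after Hungarian matching. The chosen K is
the smallest with stability ≥ 0.9 whose relative error improvement to K+1
falls below 0.05; if no K qualifies, the most stable K wins. This is the
package's own rule — rank selection for mutational signatures has no
canonical criterion — and the diagnostics table is always returned so the
scan can be judged directly.

## Reference matching

Extracted signatures are named by cosine similarity against a COSMIC-style
panel (96 rows, one column per reference signature). Each extracted
signature takes its argmax reference; matches at cosine ≥ 0.80 adopt the
reference name with a trailing asterisk (`SBS44*`) marking a re-extracted
signature, while weaker matches keep their provisional name and are
flagged novel. The 0.80 floor sits just below the weakest match the
source analyses accepted (0.82). Exact cosine ties break lexicographically
and are logged; two signatures hitting the same reference are both
reported and flagged as a collision rather than silently resolved.

The bundled six-profile panel (`make_fixture_panel`) contains synthetic
stand-ins shaped after well-known processes (CpG deamination, APOBEC, MMR
deficiency, ROS-driven C>A, 5'-CTT T>G, flat background), not the
published vectors; pairwise cosines are all below 0.5 so matching on
synthetic data is unambiguous. Real analyses should supply a downloaded
COSMIC TSV.

## Cumulative contribution abundance (CCA)

Given fitted `W` and `H`, the probability that signature k generated a
mutation of class c in sample n is

    P(k | c, n) ∝ W[c, k] · H[k, n],

normalized over k. CCA(sample, gene, signature) is the sum of these
posteriors over all of the sample's gene-annotated SBS calls in that gene:
the expected number of the gene's mutations caused by that signature.
The definition is unnormalized by design — "abundance" is a count — and
per-sample mass is exactly conserved: summing CCA over genes and
signatures returns the sample's gene-annotated SBS count (a test asserts
this to 1e-6, and a brute-force per-mutation loop reproduces the
vectorized computation on small cohorts). A normalized variant (divide by
the sample's attributed total) sits behind a flag; no per-gene-length
correction is applied, and gene symbols are taken verbatim from the input.
When a class has zero likelihood under every active signature the
posterior falls back to uniform over active signatures, with a warning.

## Survival grouping and stratification

Five-year outcome groups: G1 — survival strictly over 60 months (any
status); G2 — under 60 months, dead; G3 — under 60 months, alive
(right-censored); G4 — missing information. Exactly 60 months is not
"more than 5 years" and falls to G2/G3 by status. Exposure stratification
puts samples with relative exposure strictly above the threshold (default
20%) in the high arm, excludes G4, fits Kaplan–Meier curves per arm
(lifelines) and runs a two-sided log-rank test. Thresholding uses
fractional exposure to match the percentage framing of signature-activity
distributions; absolute-count thresholding is a flag away. An empty arm
yields a result flagged undefined rather than an exception.

## Five-year-survival model

Training cases are G1 (positive) vs G2 (negative); features are CCA scores
of the selected prognosis-related signatures, columns named `GENE|SIG`.
Each of `n_rounds` rounds draws 95% of cases without replacement,
stratified by class, and fits a random forest (500 trees, unlimited depth,
√p features per split). A round votes only if its **out-of-bag** AUC
exceeds the 0.9 gate. The gate is deliberately out-of-bag: a forest's
resubstitution AUC is ≈1 even on permuted labels, which would make any
gate vacuous; OOB AUC is an honest internal estimate and sends the
passing-round count to zero under the null, as the tests verify. A passing
round votes for features whose impurity importance exceeds the round's
mean importance (a top-k rule is available). Features voted in more than
50% of the *passing* rounds — only passing rounds vote, so they are the
denominator — form the biomarker panel, and a final forest is refit on all
cases with that panel. The whole procedure is reproducible from one seed.

Model accuracy is summarized as the empirical ROC with trapezoidal AUC and
a 95% CI from 2000 class-stratified bootstrap replicates (percentile
interval, clipped to [0, 1]); DeLong's asymptotic interval is available as
an option. The trapezoidal AUC equals the Mann–Whitney pair-counting
statistic exactly on tie-free scores, which a brute-force oracle test
checks.

## Synthetic cohorts

The generator draws, per sample: a Dirichlet exposure vector over K
ground-truth signatures; a Poisson mutation count (7% of samples are
hypermutators at 20× the rate); per mutation a signature from the
exposures, a 96-class from that signature's profile, a gene from a
mutability-weighted panel of recurrently mutated gastric-cancer genes, and
a random strand for the emitted record. Survival is exponential with
log-hazard linear in the relative exposures, censored by an independent
uniform follow-up horizon (120 months), with a configurable fraction of
samples losing their clinical record to populate G4. Defaults are
desk-scale: 100 samples, 300 substitutions plus 85 indels per sample
(indel/SBS ratio ≈ 0.28, in line with pooled gastric-cancer catalogs), and
15% missing clinical data.

For biomarker-selection experiments a planted mechanism is available: a
latent carrier subgroup receives extra Poisson mutations in chosen
(gene, signature) pairs — a localized hypermutability event — plus a
carrier-specific hazard shift. The additive construction keeps every
non-planted feature distributionally untouched, so decoy selection rates
measure false positives cleanly (a multiplicative gene-weight bias would
depress decoy counts in carriers through renormalization).
`planted_biomarker_config` freezes the study conditions used throughout
the tests: 11 genes × 3 signatures = 33 features of which 3 are planted
(TP53 and MUC16 under the MMR-deficiency-like signature, MUC16 under the
C>A signature), 200 samples, carrier fraction 0.5, ~25 extra mutations per
pair, carrier hazard ratio e^(−3.5), and a 15-month mean baseline survival
typical of advanced gastric cancer — conditions under which the five-year
label is essentially decided by the planted mechanism, which is the
premise of a planted-recovery experiment.

What the synthetic cohorts do **not** emulate: real genomic coordinates,
regional mutation-rate covariates (replication timing, expression),
gene length differences, non-exponential hazards, correlated censoring,
and signatures as similar to each other as real COSMIC neighbours
(e.g. SBS5/SBS40). Passing tests therefore establish the correctness of
the machinery — tallying, factorization, attribution arithmetic,
selection logic, calibration of the log-rank test — not performance on
real cohorts, where signature collinearity and label noise are harsher.

## Numerical conventions

Probability vectors are validated to 1e-6 (file round-trips) or 1e-9
(internal); zero-exposure samples get all-zero relative exposures and are
flagged rather than renormalized; KL terms guard zeros with the machine
epsilon; Hungarian matching resolves signature permutation wherever
extracted and true signatures are compared. Problem sizes in the tests
(100-sample extraction cohorts, 200-sample survival and selection cohorts,
1000 type-I replicates) are the package's chosen desk-scale study
conditions, stated in `tests/` and `scripts/acceptance.py` alongside their
seeds.
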