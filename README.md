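# sigprog

Mutational-signature analysis and five-year-survival prognosis for cancer
cohorts, built around the single-base-substitution (SBS) signatures of
gastric cancer.

Somatic point mutations carry the fingerprints of the processes that
caused them. `sigprog` takes a cohort's somatic mutation table (MAF-like
TSV) through the full prognostic pipeline:

1. **Catalog** — tally each sample's substitutions into the 96
   trinucleotide classes (pyrimidine-strand collapsed, `A[C>T]G`-style),
   with hypermutation flagging on total burden.
2. **Signatures** — factorize the catalog `V ≈ W·H` by non-negative matrix
   factorization under the generalized Kullback–Leibler objective, with
   random restarts and a stability-based rank scan; `W` holds the 96-class
   signature profiles, `H` the per-sample exposures (attributed mutation
   counts).
3. **Matching** — name each extracted signature by cosine similarity
   against a COSMIC-style reference panel (`SBS44*` marks a re-extracted
   match).
4. **CCA** — cumulative contribution abundance: for each mutation the
   posterior `P(k | class c, sample n) ∝ W[c,k]·H[k,n]` attributes it to
   signatures; summing over a gene's mutations gives CCA(sample, gene,
   signature), the expected number of that gene's mutations caused by that
   signature. These `GENE|SIG` scores are the prognostic features.
5. **Survival** — five-year outcome groups (G1: >60 months; G2: <60,
   dead; G3: <60, censored; G4: unknown) and Kaplan–Meier/log-rank
   stratification of a signature's relative exposure at a threshold
   (the headline cut is 20%).
6. **FYSR model** — random-forest classification of G1 vs G2 on CCA
   features with repeated 95% subsampling: rounds passing an out-of-bag
   AUC gate (0.9) vote for their high-importance features, features voted
   in >50% of passing rounds become the biomarker panel, and the final
   forest is evaluated by ROC/AUC with a bootstrap 95% CI.

A fully specified synthetic-cohort generator (known signature mixtures,
gene labels, exponential survival with exposure-dependent hazard, planted
prognostic features) makes every stage testable without any data download.

## Worked example

`examples/04_cca_and_fysr.py` simulates a 200-sample cohort in which three
of 33 `GENE|SIG` features are planted as prognostic, re-extracts the
signatures, computes CCA and runs the selection:

```
CCA feature matrix: 200 samples x 33 GENE|SIG features
training classes: {'G2': 79, 'G1': 41}
30/30 rounds passed the AUC gate
selected biomarkers (feature, vote frequency):
       TP53|S1 (SBS44*) freq 1.00
      MUC16|S1 (SBS44*) freq 1.00
      MUC16|S2 (SBS18*) freq 1.00
apparent AUC 1.0000 (95% CI 1.0000-1.0000)
```

The three selected features are exactly the planted ones — TP53 and MUC16
under the MMR-deficiency-like signature (matched to the reference as
`SBS44*`) and MUC16 under the C>A signature (`SBS18*`) — and all 30 decoys
are rejected. The apparent AUC is computed on the training cohort and is
optimistic by construction; held-out evaluation uses `predict_fysr` on an
unseen cohort. The other examples cover catalog building
(`01_build_catalog.py`), extraction, rank selection and matching
(`02_extract_and_match.py`, cosines ≥ 0.998 to the generating profiles),
and survival stratification (`03_survival_stratification.py`, log-rank
p = 6.4e-06 for a planted protective signature).

A thin CLI mirrors the library:

```sh
sigprog simulate --n-samples 100 --seed 1 --out-prefix cohort
sigprog catalog --maf cohort.maf.tsv --out catalog.tsv
sigprog extract --catalog catalog.tsv --k-range 2:6 --seed 0 --out-prefix run1
sigprog km --expo run1.exposures_relative.tsv --signature S1 \
           --clinical cohort.clinical.tsv --threshold 0.2
```

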