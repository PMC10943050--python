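"""Build samples x 96 substitution catalogs from somatic mutation tables.

The mutation table is a MAF-like record set: one row per somatic call with
sample, locus, alleles, gene symbol and (for single-base substitutions) the
two flanking bases.  Only SBS calls enter the 96-class matrix; indels count
toward per-sample totals used for hypermutation flagging.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._classes import (
    BASES,
    CLASS_INDEX,
    CLASS_LABELS,
    COMPLEMENT,
    SUBSTITUTION_TYPES,
)

logger = logging.getLogger(__name__)

#: canonical column names of a mutation-record table
RECORD_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "flank5",
    "flank3",
    "variant_class",
]

_CONTEXT_RE = re.compile(r"^([ACGT])\[([ACGT])>([ACGT])\]([ACGT])$")


@dataclass
class MutationCatalog:
    """Samples x 96 non-negative count matrix with per-sample totals.

    ``counts`` rows follow ``sample_ids`` (first-occurrence order of the
    input); ``totals`` holds the full mutation burden per sample (SBS and
    indel), which is what hypermutation flagging operates on.
    ``n_skipped`` counts SBS records dropped for invalid alleles or flanks.
    """

    sample_ids: list[str]
    counts: np.ndarray
    totals: dict[str, int]
    class_labels: tuple[str, ...] = CLASS_LABELS
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.class_labels)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.class_labels)} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=list(self.class_labels)
        )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def classify_substitution(ref: str, alt: str, flank5: str, flank3: str) -> str:
    """Map one substitution and its flanks to its 96-class label.

    Purine reference bases are reverse-complemented together with both
    flanks so the label is always reported on the pyrimidine strand, e.g.
    ``classify_substitution("G", "A", "T", "C") == "G[C>T]A"``.
    """
    for name, b in (("ref", ref), ("alt", alt), ("flank5", flank5), ("flank3", flank3)):
        if b not in BASES:
            raise ValueError(f"{name} must be one of A/C/G/T, got {b!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r}): not a substitution")
    if ref in ("A", "G"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        flank5, flank3 = COMPLEMENT[flank3], COMPLEMENT[flank5]
    return f"{flank5}[{ref}>{alt}]{flank3}"


def classify_substitutions(records: pd.DataFrame) -> pd.Series:
    """Vectorized 96-class labels for the SBS rows of a record table.

    Returns a Series aligned to ``records.index`` with the class label, or
    NaN where the row is not a classifiable SBS (bad base, missing flank,
    ref == alt, multi-base alleles).
    """
    ref = records["ref"].astype(str).str.upper()
    alt = records["alt"].astype(str).str.upper()
    f5 = records["flank5"].astype(str).str.upper()
    f3 = records["flank3"].astype(str).str.upper()

    valid = (
        ref.isin(BASES) & alt.isin(BASES) & f5.isin(BASES) & f3.isin(BASES)
        & (ref != alt)
    )
    comp = lambda s: s.map(COMPLEMENT)  # noqa: E731
    purine = ref.isin(("A", "G"))
    ref_c = ref.where(~purine, comp(ref))
    alt_c = alt.where(~purine, comp(alt))
    f5_c = f5.where(~purine, comp(f3))
    f3_c = f3.where(~purine, comp(f5))

    labels = f5_c + "[" + ref_c + ">" + alt_c + "]" + f3_c
    return labels.where(valid)


def split_context(context: pd.Series) -> pd.DataFrame:
    """Split an "A[C>T]G"-style context column into ref/alt/flank columns."""
    parts = context.astype(str).str.extract(_CONTEXT_RE)
    parts.columns = ["flank5", "ref", "alt", "flank3"]
    return parts


def build_catalog(records: pd.DataFrame) -> MutationCatalog:
    """Tally a record table into a samples x 96 catalog.

    Indel records contribute to per-sample totals but not to the 96-class
    matrix.  SBS records with unusable alleles or flanks (e.g. an ``N``
    flank) are skipped with a logged warning and counted in
    ``catalog.n_skipped``.  Samples appear in first-occurrence order.
    """
    if len(records) == 0:
        raise ValueError("no mutation records supplied")
    records = records.reset_index(drop=True)
    sample_ids = list(pd.unique(records["sample_id"].astype(str)))
    sample_pos = {s: i for i, s in enumerate(sample_ids)}

    vclass = records["variant_class"].astype(str).str.upper()
    is_sbs = vclass == "SBS"

    counts = np.zeros((len(sample_ids), len(CLASS_LABELS)), dtype=np.int64)
    n_skipped = 0
    if is_sbs.any():
        sbs = records.loc[is_sbs]
        labels = classify_substitutions(sbs)
        bad = labels.isna()
        n_skipped = int(bad.sum())
        if n_skipped:
            logger.warning(
                "skipped %d SBS record(s) with invalid alleles or flanks", n_skipped
            )
        ok = sbs.loc[~bad]
        if len(ok):
            rows = ok["sample_id"].astype(str).map(sample_pos).to_numpy()
            cols = labels.loc[~bad].map(CLASS_INDEX).to_numpy()
            np.add.at(counts, (rows, cols), 1)

    # totals include indels and skipped records: full somatic burden
    totals_series = records.groupby(
        records["sample_id"].astype(str), sort=False
    ).size()
    totals = {s: int(totals_series[s]) for s in sample_ids}

    return MutationCatalog(
        sample_ids=sample_ids, counts=counts, totals=totals, n_skipped=n_skipped
    )


@dataclass
class HypermutationFlag:
    sample_id: str
    total_mutations: int
    is_hypermutated: bool


def flag_hypermutated(
    catalog: MutationCatalog,
    threshold: int = 1000,
    totals: dict[str, int] | None = None,
) -> list[HypermutationFlag]:
    """Flag samples whose total somatic burden exceeds ``threshold``.

    The default of 1000 mutations per sample is the usual exome-scale
    convention for calling a tumor hypermutated; it is configurable because
    whole-genome catalogs need a larger cut.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    totals = catalog.totals if totals is None else totals
    return [
        HypermutationFlag(s, totals.get(s, 0), totals.get(s, 0) > threshold)
        for s in catalog.sample_ids
    ]


def category_proportions(catalog: MutationCatalog) -> dict[str, float]:
    """Fractions of the six substitution types over the whole catalog."""
    total = catalog.counts.sum()
    if total == 0:
        raise ValueError("all-zero catalog: category proportions undefined")
    per_class = catalog.counts.sum(axis=0)
    out = {}
    for i, sub in enumerate(SUBSTITUTION_TYPES):
        out[sub] = float(per_class[16 * i : 16 * (i + 1)].sum() / total)
    return out


# ---------------------------------------------------------------------------
# I/O: MAF-like TSV reader and COSMIC-layout catalog writer

_MAF_REQUIRED = [
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Hugo_Symbol",
    "Variant_Type",
]


def read_maf(path, fasta=None) -> pd.DataFrame:
    """Read a MAF-like TSV into the canonical record table.

    Flanking bases are taken from explicit ``flank5``/``flank3`` columns,
    from a ``ref_context`` column in "A[C>T]G" form, or — when ``fasta`` is
    a path to an indexed genome FASTA — looked up from the reference
    sequence (1-based MAF coordinates).  Variant_Type values of SNP/SNV/SBS
    are treated as SBS; INS/DEL/INDEL as indels; anything else (DNP, TNP,
    multi-allelic) is dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"MAF is missing required column(s): {missing}")

    vt = df["Variant_Type"].str.upper()
    vclass = pd.Series(pd.NA, index=df.index, dtype="object")
    vclass[vt.isin(("SNP", "SNV", "SBS"))] = "SBS"
    vclass[vt.isin(("INS", "DEL", "INDEL"))] = "INDEL"
    n_dropped = int(vclass.isna().sum())
    if n_dropped:
        logger.warning(
            "dropped %d record(s) with unsupported Variant_Type (MNV/other)",
            n_dropped,
        )

    rec = pd.DataFrame(
        {
            "sample_id": df["Tumor_Sample_Barcode"],
            "chrom": df["Chromosome"],
            "pos": pd.to_numeric(df["Start_Position"]).astype(int),
            "ref": df["Reference_Allele"].str.upper(),
            "alt": df["Tumor_Seq_Allele2"].str.upper(),
            "gene": df["Hugo_Symbol"].fillna(""),
            "variant_class": vclass,
        }
    )

    if "flank5" in df.columns and "flank3" in df.columns:
        rec["flank5"] = df["flank5"].str.upper()
        rec["flank3"] = df["flank3"].str.upper()
    elif "ref_context" in df.columns:
        ctx = split_context(df["ref_context"].str.upper())
        rec["flank5"] = ctx["flank5"]
        rec["flank3"] = ctx["flank3"]
    elif fasta is not None:
        rec["flank5"], rec["flank3"] = _flanks_from_fasta(rec, fasta)
    else:
        raise ValueError(
            "no flanking-base source: provide flank5/flank3 columns, a "
            "ref_context column, or a genome FASTA"
        )
    return rec[~vclass.isna()].reset_index(drop=True)[RECORD_COLUMNS]


def _flanks_from_fasta(rec: pd.DataFrame, fasta):
    from pyfaidx import Fasta

    genome = Fasta(str(fasta))
    f5, f3 = [], []
    for chrom, pos, vclass in zip(rec["chrom"], rec["pos"], rec["variant_class"]):
        if vclass != "SBS":
            f5.append("")
            f3.append("")
            continue
        seq = genome[str(chrom)][pos - 2 : pos + 1].seq.upper()
        f5.append(seq[0] if len(seq) == 3 else "N")
        f3.append(seq[2] if len(seq) == 3 else "N")
    return pd.Series(f5, index=rec.index), pd.Series(f3, index=rec.index)


def write_catalog(catalog: MutationCatalog, path, transpose: bool = False) -> None:
    """Write a catalog TSV in the COSMIC layout.

    Default layout: first column ``MutationType`` with the 96 class labels,
    one column per sample.  ``transpose=True`` writes samples as rows.
    """
    frame = catalog.to_frame()
    if transpose:
        frame.to_csv(path, sep="\t", index_label="Sample")
    else:
        out = frame.T
        out.index.name = "MutationType"
        out.to_csv(path, sep="\t")


def read_catalog(path) -> MutationCatalog:
    """Read a catalog TSV written by :func:`write_catalog` (either layout)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name == "MutationType" or set(df.index) >= set(CLASS_LABELS):
        df = df.T
    df = df[list(CLASS_LABELS)]  # enforce canonical column order
    counts = df.to_numpy()
    int_counts = np.rint(counts).astype(np.int64)
    totals = {str(s): int(t) for s, t in zip(df.index, int_counts.sum(axis=1))}
    return MutationCatalog(
        sample_ids=[str(s) for s in df.index], counts=int_counts, totals=totals
    )
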