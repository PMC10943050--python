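"""Cumulative contribution abundance: gene-level signature-attribution scores.

Every single-base substitution in a sample is probabilistically attributed
to the extracted signatures: the posterior that signature k generated a
mutation of class c in sample n is proportional to W[c, k] * H[k, n].
Summing those posteriors over all of a gene's mutations in a sample gives
the cumulative contribution abundance CCA(sample, gene, signature) — the
expected number of that gene's mutations caused by that signature.  These
per-(gene, signature) scores are the feature set of the five-year-survival
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._classes import CLASS_INDEX
from .catalog import classify_substitutions
from .nmf import ExposureMatrix, SignatureSet

logger = logging.getLogger(__name__)


@dataclass
class CCATable:
    """Long-format (sample, gene, signature) -> cumulative abundance table."""

    table: pd.DataFrame  # columns: sample_id, gene, signature, cca
    signature_ids: list[str]
    sample_ids: list[str]
    normalized: bool = False

    def pivot(self) -> pd.DataFrame:
        """Wide samples x "GENE|SIG" matrix of the stored values."""
        wide = self.table.pivot_table(
            index="sample_id",
            columns=["gene", "signature"],
            values="cca",
            aggfunc="sum",
            fill_value=0.0,
        )
        wide.columns = [f"{g}|{s}" for g, s in wide.columns]
        return wide.reindex(self.sample_ids, fill_value=0.0)


def attribute_mutation(
    class_label: str,
    sample_exposures: np.ndarray,
    signatures: SignatureSet,
) -> np.ndarray:
    """Posterior probability over signatures for one mutation.

    ``posterior_k ~ W[class, k] * H[k, sample]`` normalized over k.  When
    every product is zero (the class is outside all active signatures'
    support) the posterior falls back to uniform over the signatures with
    nonzero exposure, with a warning.
    """
    h = np.asarray(sample_exposures, dtype=float)
    if h.sum() <= 0:
        raise ValueError("sample has no positive exposure")
    w = signatures.profiles[CLASS_INDEX[class_label]]
    p = w * h
    total = p.sum()
    if total <= 0:
        logger.warning(
            "class %s has zero likelihood under all active signatures; "
            "using uniform fallback",
            class_label,
        )
        active = h > 0
        p = active / active.sum()
        return p
    return p / total


def _posterior_matrix(signatures: SignatureSet, exposures: ExposureMatrix):
    """96 x K x N posteriors, precomputed per (class, sample)."""
    W = signatures.profiles  # 96 x K
    H = exposures.activities  # K x N
    P = W[:, :, None] * H[None, :, :]  # 96 x K x N
    totals = P.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(totals > 0, P / np.maximum(totals, 1e-300), 0.0)
    # zero-likelihood (class, sample) cells: uniform over active signatures
    zero_cells = (totals[:, 0, :] == 0)
    if zero_cells.any():
        active = (H > 0).astype(float)
        colsum = active.sum(axis=0)
        colsum[colsum == 0] = 1.0
        fallback = active / colsum  # K x N
        P = np.where(zero_cells[:, None, :], fallback[None, :, :], P)
    return P


def compute_cca(
    records: pd.DataFrame,
    signatures: SignatureSet,
    exposures: ExposureMatrix,
    selected_signatures: list[str] | None = None,
    normalize: bool = False,
) -> CCATable:
    """Accumulate per-mutation signature posteriors into gene-level scores.

    Only gene-annotated SBS records contribute; ``selected_signatures``
    restricts the output columns (the survival model uses the two
    prognosis-related signatures).  With ``normalize=True`` each sample's
    scores are divided by its total attributed count.
    """
    sig_ids = list(signatures.signature_ids)
    if selected_signatures is None:
        selected_signatures = sig_ids
    unknown = [s for s in selected_signatures if s not in sig_ids]
    if unknown:
        raise ValueError(f"unknown signature(s) {unknown}; available: {sig_ids}")

    sbs = records[records["variant_class"].astype(str).str.upper() == "SBS"].copy()
    sbs["_label"] = classify_substitutions(sbs)
    sbs = sbs[sbs["_label"].notna() & (sbs["gene"].astype(str) != "")]

    sample_pos = {s: i for i, s in enumerate(exposures.sample_ids)}
    known = sbs["sample_id"].astype(str).isin(sample_pos)
    if not known.all():
        logger.warning(
            "%d record(s) from samples absent in the exposure matrix dropped",
            int((~known).sum()),
        )
        sbs = sbs[known]

    P = _posterior_matrix(signatures, exposures)  # 96 x K x N
    rows = []
    if len(sbs):
        ci = sbs["_label"].map(CLASS_INDEX).to_numpy()
        ni = sbs["sample_id"].astype(str).map(sample_pos).to_numpy()
        post = P[ci, :, ni]  # n_records x K
        rec = pd.DataFrame(post, columns=sig_ids)
        rec["sample_id"] = sbs["sample_id"].astype(str).to_numpy()
        rec["gene"] = sbs["gene"].astype(str).to_numpy()
        agg = rec.groupby(["sample_id", "gene"], sort=True)[sig_ids].sum()
        long = agg.reset_index().melt(
            id_vars=["sample_id", "gene"], var_name="signature", value_name="cca"
        )
        rows.append(long[long["signature"].isin(selected_signatures)])

    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["sample_id", "gene", "signature", "cca"])
    )
    if normalize and len(table):
        tot = table.groupby("sample_id")["cca"].transform("sum")
        table = table.assign(cca=np.where(tot > 0, table["cca"] / tot, 0.0))
    return CCATable(
        table=table.reset_index(drop=True),
        signature_ids=list(selected_signatures),
        sample_ids=list(exposures.sample_ids),
        normalized=normalize,
    )


def cca_feature_matrix(
    table: CCATable,
    genes: list[str],
    signatures: list[str] | None = None,
) -> pd.DataFrame:
    """Dense samples x features matrix with columns named "GENE|SIG".

    Column order follows the input gene and signature order; pairs absent
    from the table (a gene never mutated in a sample) are zero-filled, and
    an all-zero column is kept rather than dropped.
    """
    if signatures is None:
        signatures = table.signature_ids
    cols = [f"{g}|{s}" for g in genes for s in signatures]
    wide = table.pivot()
    out = pd.DataFrame(0.0, index=table.sample_ids, columns=cols)
    shared = [c for c in cols if c in wide.columns]
    out[shared] = wide[shared]
    return out


def write_cca(table: CCATable, path, wide_path=None) -> None:
    """Write the long-format table, and optionally the wide feature matrix."""
    table.table.to_csv(path, sep="\t", index=False)
    if wide_path is not None:
        table.pivot().to_csv(wide_path, sep="\t", index_label="sample_id")
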