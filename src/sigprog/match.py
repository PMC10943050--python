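"""Name extracted signatures against a COSMIC-style reference panel.

Each de-novo signature is assigned the reference profile with the highest
cosine similarity; matched signatures take the reference name with a
trailing asterisk (``SBS44*``) marking them as this analysis's re-extracted
version, and signatures below the similarity floor keep their provisional
name and are flagged novel.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from ._classes import CLASS_LABELS
from .nmf import SignatureSet

logger = logging.getLogger(__name__)


@dataclass
class ReferencePanel:
    """96 x M column-stochastic reference profiles with COSMIC-style names."""

    profiles: np.ndarray
    names: list[str]
    version: str = ""
    class_labels: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if (self.profiles < 0).any():
            raise ValueError("reference profiles must be non-negative")
        if not np.allclose(self.profiles.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("each reference profile must sum to 1")
        if len(self.names) != self.profiles.shape[1]:
            raise ValueError("one name per profile required")


@dataclass
class SignatureMatch:
    extracted_id: str
    reference_name: str
    cosine: float
    assigned_name: str
    novel: bool = False
    collision: bool = False


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two non-negative 96-vectors; in [0, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def match_panel(
    signatures: SignatureSet,
    panel: ReferencePanel,
    min_cosine: float = 0.80,
) -> list[SignatureMatch]:
    """Assign each extracted signature its best-cosine reference name.

    Cosine ties are broken by lexicographic reference name (logged).  Two
    extracted signatures may hit the same reference; both keep the
    assignment and are flagged as a collision.  Matches below
    ``min_cosine`` keep the provisional id and are flagged novel.
    """
    if tuple(signatures.class_labels) != tuple(panel.class_labels):
        raise ValueError("signature and panel class-label orders differ")

    W = signatures.profiles
    P = panel.profiles
    Wn = W / np.linalg.norm(W, axis=0)
    Pn = P / np.linalg.norm(P, axis=0)
    C = Wn.T @ Pn  # K x M cosines

    # argmax with lexicographic tie-break on reference names
    name_order = np.argsort(panel.names, kind="stable")
    matches: list[SignatureMatch] = []
    for i, sig_id in enumerate(signatures.signature_ids):
        row = C[i]
        best = max(row)
        cands = [j for j in name_order if row[j] >= best - 1e-12]
        if len(cands) > 1:
            logger.info(
                "cosine tie for %s broken lexicographically among %s",
                sig_id,
                [panel.names[j] for j in cands],
            )
        j = cands[0]
        cos = float(np.clip(row[j], 0.0, 1.0))
        novel = cos < min_cosine
        matches.append(
            SignatureMatch(
                extracted_id=sig_id,
                reference_name=panel.names[j],
                cosine=cos,
                assigned_name=sig_id if novel else panel.names[j] + "*",
                novel=novel,
            )
        )

    counts: dict[str, int] = {}
    for m in matches:
        if not m.novel:
            counts[m.reference_name] = counts.get(m.reference_name, 0) + 1
    for m in matches:
        m.collision = not m.novel and counts[m.reference_name] > 1
    return matches


def matches_to_frame(matches: list[SignatureMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "extracted_id": m.extracted_id,
                "assigned_name": m.assigned_name,
                "reference_name": m.reference_name,
                "cosine": m.cosine,
                "novel": m.novel,
                "collision": m.collision,
            }
            for m in matches
        ]
    )


def read_reference_panel(path, version: str = "") -> ReferencePanel:
    """Read a COSMIC v3 layout TSV: "Type" column plus one column per signature.

    Rows are re-indexed to the canonical 96-class order; profiles are
    renormalized to sum to 1 to absorb rounding in published tables.
    """
    df = pd.read_csv(path, sep="\t")
    type_col = "Type" if "Type" in df.columns else df.columns[0]
    df = df.set_index(type_col)
    missing = set(CLASS_LABELS) - set(df.index)
    if missing:
        raise ValueError(
            f"panel is missing {len(missing)} substitution classes, e.g. "
            f"{sorted(missing)[:3]}"
        )
    df = df.loc[list(CLASS_LABELS)]
    profiles = df.to_numpy(dtype=float)
    profiles = profiles / profiles.sum(axis=0)
    return ReferencePanel(
        profiles=profiles, names=[str(c) for c in df.columns], version=version
    )


def write_matches(matches: list[SignatureMatch], path) -> None:
    matches_to_frame(matches).to_csv(path, sep="\t", index=False)
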