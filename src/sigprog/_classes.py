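"""The 96-class single-base-substitution alphabet.

Substitutions are reported on the pyrimidine strand: a mutation whose
reference base is a purine (A or G) is reverse-complemented together with
its two flanking bases before classification, so every substitution falls
into one of six types (C>A, C>G, C>T, T>A, T>C, T>G) and, with the 4 x 4
flanking-base combinations, one of 96 trinucleotide classes such as
"A[C>T]G".  Class order is fixed: substitution type major, then 5' flank,
then 3' flank, each alphabetical.
"""

from __future__ import annotations

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

CLASS_LABELS: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}"
    for sub in SUBSTITUTION_TYPES
    for f5 in BASES
    for f3 in BASES
)

CLASS_INDEX = {label: i for i, label in enumerate(CLASS_LABELS)}

N_CLASSES = 96


def substitution_type_of(label: str) -> str:
    """Return the six-way substitution type ("C>A", ...) of a class label."""
    return label[2:5]


def parse_class_label(label: str) -> tuple[str, str, str, str]:
    """Split "A[C>T]G" into (ref, alt, flank5, flank3).

    Raises ValueError for anything not in the 96-class alphabet.
    """
    if label not in CLASS_INDEX:
        raise ValueError(f"not a 96-class SBS label: {label!r}")
    return label[2], label[4], label[0], label[6]
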