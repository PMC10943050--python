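"""96-class substitution classification and catalog tallying."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sigprog as sp
from sigprog._classes import COMPLEMENT, SUBSTITUTION_TYPES, substitution_type_of
from sigprog.catalog import build_catalog, read_catalog, read_maf, write_catalog
from sigprog.simulate import write_cohort

BASES = "ACGT"


@pytest.mark.parametrize(
    "ref,alt,f5,f3,expected",
    [
        ("C", "A", "A", "A", "A[C>A]A"),  # pyrimidine ref, no collapsing
        ("G", "A", "T", "C", "G[C>T]A"),  # revcomp of TGC is GCA
        ("T", "G", "C", "T", "C[T>G]T"),
        ("A", "C", "G", "G", "C[T>G]C"),
    ],
)
def test_classify_examples(ref, alt, f5, f3, expected):
    assert sp.classify_substitution(ref, alt, f5, f3) == expected


def test_classification_is_complete_and_balanced():
    """All 576 valid inputs collapse onto exactly 96 classes, 16 per type."""
    labels = [
        sp.classify_substitution(r, a, f5, f3)
        for r, a, f5, f3 in itertools.product(BASES, BASES, BASES, BASES)
        if r != a
    ]
    distinct = set(labels)
    assert distinct == set(sp.CLASS_LABELS)
    per_type = pd.Series([substitution_type_of(l) for l in distinct]).value_counts()
    assert len(per_type) == 6
    assert (per_type == 16).all()


@given(
    ref=st.sampled_from("AG"),
    alt=st.sampled_from(BASES),
    f5=st.sampled_from(BASES),
    f3=st.sampled_from(BASES),
)
@settings(deadline=None)
def test_purine_collapse_matches_reverse_complement(ref, alt, f5, f3):
    """Classifying a purine-strand call equals classifying its revcomp."""
    if ref == alt:
        return
    direct = sp.classify_substitution(ref, alt, f5, f3)
    rc = sp.classify_substitution(
        COMPLEMENT[ref], COMPLEMENT[alt], COMPLEMENT[f3], COMPLEMENT[f5]
    )
    assert direct == rc


@pytest.mark.parametrize(
    "args", [("N", "A", "C", "C"), ("C", "C", "A", "A"), ("C", "A", "x", "T")]
)
def test_classify_rejects_bad_input(args):
    with pytest.raises(ValueError):
        sp.classify_substitution(*args)


def _rec(sample, ref, alt, f5, f3, gene="TP53", vclass="SBS"):
    return {
        "sample_id": sample,
        "chrom": "1",
        "pos": 100,
        "ref": ref,
        "alt": alt,
        "gene": gene,
        "flank5": f5,
        "flank3": f3,
        "variant_class": vclass,
    }


def test_build_catalog_hand_tally():
    records = pd.DataFrame(
        [
            _rec("s1", "C", "T", "A", "T"),
            _rec("s1", "G", "A", "T", "C"),  # collapses to G[C>T]A
            _rec("s1", "C", "T", "A", "T"),
        ]
    )
    catalog = build_catalog(records)
    row = catalog.to_frame().loc["s1"]
    assert row["A[C>T]T"] == 2
    assert row["G[C>T]A"] == 1
    assert row.sum() == 3


def test_indel_only_sample_has_zero_row_but_counts_in_totals():
    records = pd.DataFrame(
        [
            _rec("s1", "A", "AT", "", "", vclass="INDEL"),
            _rec("s1", "AC", "A", "", "", vclass="INDEL"),
        ]
    )
    catalog = build_catalog(records)
    assert catalog.counts.sum() == 0
    assert catalog.totals["s1"] == 2


def test_invalid_flank_skipped_with_count():
    records = pd.DataFrame(
        [_rec("s1", "C", "T", "N", "T"), _rec("s1", "C", "T", "A", "T")]
    )
    catalog = build_catalog(records)
    assert catalog.n_skipped == 1
    assert catalog.counts.sum() == 1


def test_row_sums_match_independent_sbs_counter(default_cohort, default_catalog):
    """Catalog row sums equal an independent per-sample SBS tally."""
    _, records, _, _ = default_cohort
    expected = (
        records[records["variant_class"] == "SBS"].groupby("sample_id").size()
    )
    got = default_catalog.to_frame().sum(axis=1)
    pd.testing.assert_series_equal(
        got.sort_index(), expected.sort_index(), check_names=False
    )


def test_sample_order_is_first_occurrence():
    records = pd.DataFrame(
        [_rec("b", "C", "T", "A", "T"), _rec("a", "C", "T", "A", "T"),
         _rec("b", "C", "A", "A", "A")]
    )
    assert build_catalog(records).sample_ids == ["b", "a"]


def test_flag_hypermutated_threshold_and_monotonicity(default_catalog):
    flags = sp.flag_hypermutated(default_catalog, threshold=1000)
    flagged = {f.sample_id for f in flags if f.is_hypermutated}
    stricter = {
        f.sample_id
        for f in sp.flag_hypermutated(default_catalog, threshold=5000)
        if f.is_hypermutated
    }
    assert stricter <= flagged
    above_max = max(default_catalog.totals.values()) + 1
    none = sp.flag_hypermutated(default_catalog, threshold=above_max)
    assert not any(f.is_hypermutated for f in none)


def test_hypermutator_fraction_recovered_by_flagging():
    """7% of samples at 20x the baseline rate are the flagged set."""
    config = sp.SimulationConfig(seed=21, n_samples=300)
    records, _, truth = sp.simulate_cohort(config)
    catalog = sp.build_catalog(records)
    flags = sp.flag_hypermutated(catalog, threshold=1000)
    flagged = {f.sample_id for f in flags if f.is_hypermutated}
    assert flagged == set(truth.hypermutators[truth.hypermutators].index)
    frac = len(flagged) / config.n_samples
    assert 0.03 <= frac <= 0.12  # binomial spread around the 7% design rate


def test_category_proportions_pure_and_uniform():
    pure = pd.DataFrame([_rec("s1", "C", "T", "A", "T")] * 5)
    props = sp.category_proportions(build_catalog(pure))
    assert props["C>T"] == 1.0
    assert set(props) == set(SUBSTITUTION_TYPES)

    uniform = sp.MutationCatalog(
        sample_ids=["s1"],
        counts=np.ones((1, 96), dtype=int),
        totals={"s1": 96},
    )
    props = sp.category_proportions(uniform)
    assert all(abs(v - 1 / 6) < 1e-12 for v in props.values())
    assert abs(sum(props.values()) - 1.0) < 1e-9


def test_category_proportions_all_zero_errors():
    empty = sp.MutationCatalog(
        sample_ids=["s1"], counts=np.zeros((1, 96), dtype=int), totals={"s1": 0}
    )
    with pytest.raises(ValueError):
        sp.category_proportions(empty)


def test_maf_and_catalog_round_trip(tmp_path, default_cohort, default_catalog):
    """Simulated cohort -> MAF TSV -> reader -> identical catalog."""
    _, records, clinical, _ = default_cohort
    prefix = tmp_path / "cohort"
    write_cohort(records, clinical, prefix)
    reread = read_maf(f"{prefix}.maf.tsv")
    catalog2 = build_catalog(reread)
    assert catalog2.sample_ids == default_catalog.sample_ids
    np.testing.assert_array_equal(catalog2.counts, default_catalog.counts)

    out = tmp_path / "catalog.tsv"
    write_catalog(default_catalog, out)
    catalog3 = read_catalog(out)
    np.testing.assert_array_equal(catalog3.counts, default_catalog.counts)
    assert catalog3.sample_ids == default_catalog.sample_ids
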