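"""Gene-level cumulative contribution abundance: posteriors and conservation."""

import numpy as np
import pandas as pd
import pytest

import sigprog as sp
from sigprog._classes import CLASS_INDEX, CLASS_LABELS
from sigprog.catalog import classify_substitutions


def _two_sig_set(w_row_a, w_row_b):
    """SignatureSet whose first two class rows are as given, rest uniform."""
    W = np.zeros((96, 2))
    W[0] = w_row_a
    W[1] = w_row_b
    remainder = 1.0 - W.sum(axis=0)
    W[2:] = remainder / 94
    return sp.SignatureSet(profiles=W, signature_ids=["sigA", "sigB"])


def test_attribute_mutation_normalizes_elementwise_products():
    sigs = _two_sig_set([0.2, 0.1], [0.0, 0.0])
    post = sp.attribute_mutation(CLASS_LABELS[0], np.array([0.5, 0.5]), sigs)
    np.testing.assert_allclose(post, [2 / 3, 1 / 3])
    assert post.sum() == pytest.approx(1.0)


def test_attribute_mutation_single_active_signature():
    sigs = _two_sig_set([0.2, 0.1], [0.0, 0.0])
    post = sp.attribute_mutation(CLASS_LABELS[0], np.array([0.0, 5.0]), sigs)
    np.testing.assert_allclose(post, [0.0, 1.0])


def test_attribute_mutation_zero_likelihood_falls_back_uniform():
    sigs = _two_sig_set([0.0, 0.1], [0.0, 0.2])
    W = sigs.profiles.copy()
    W[0, :] = 0.0  # class 0 outside both supports
    W[1, :] += 1.0 - W.sum(axis=0)
    sigs = sp.SignatureSet(profiles=W, signature_ids=["sigA", "sigB"])
    post = sp.attribute_mutation(CLASS_LABELS[0], np.array([1.0, 1.0]), sigs)
    np.testing.assert_allclose(post, [0.5, 0.5])


def _record(sample, label, gene):
    f5, ref, alt, f3 = label[0], label[2], label[4], label[6]
    return {
        "sample_id": sample,
        "chrom": "1",
        "pos": 1,
        "ref": ref,
        "alt": alt,
        "gene": gene,
        "flank5": f5,
        "flank3": f3,
        "variant_class": "SBS",
    }


def test_compute_cca_hand_sum():
    """Two TP53 mutations with posteriors (0.6,0.4) and (0.2,0.8)."""
    W = np.zeros((96, 2))
    W[0] = [0.3, 0.2]  # proportional to posteriors (0.6, 0.4) at h=(1,1)
    W[1] = [0.1, 0.4]  # proportional to (0.2, 0.8)
    W[2:] = (1.0 - W.sum(axis=0)) / 94
    sigs = sp.SignatureSet(profiles=W, signature_ids=["sigA", "sigB"])
    expo = sp.ExposureMatrix(
        activities=np.array([[1.0], [1.0]]),
        signature_ids=["sigA", "sigB"],
        sample_ids=["s1"],
    )
    records = pd.DataFrame(
        [
            _record("s1", CLASS_LABELS[0], "TP53"),
            _record("s1", CLASS_LABELS[1], "TP53"),
            _record("s1", CLASS_LABELS[2], ""),  # no gene: excluded
        ]
    )
    table = sp.compute_cca(records, sigs, expo)
    wide = table.pivot()
    assert wide.loc["s1", "TP53|sigA"] == pytest.approx(0.8)
    assert wide.loc["s1", "TP53|sigB"] == pytest.approx(1.2)
    assert wide.shape[1] == 2  # ungened mutation contributed nothing


def test_cca_conservation_on_synthetic_cohort(planted_run):
    """Total CCA mass per sample equals its gene-annotated SBS count."""
    records, table = planted_run["records"], planted_run["table"]
    tot = table.table.groupby("sample_id")["cca"].sum()
    sbs = records[records["variant_class"] == "SBS"]
    expected = sbs[sbs["gene"] != ""].groupby("sample_id").size()
    diff = (tot - expected.reindex(tot.index)).abs().max()
    assert diff < 1e-6


def test_cca_matches_bruteforce_oracle_small_cohort():
    """compute_cca equals a per-mutation loop on a 5-sample cohort."""
    config = sp.SimulationConfig(
        seed=77, n_samples=5, mutation_mean=30, indel_mean=3,
        hypermutator_fraction=0.0,
    )
    records, _, _ = sp.simulate_cohort(config)
    catalog = sp.build_catalog(records)
    res = sp.factorize(catalog, rank=2, n_restarts=3, seed=1)
    table = sp.compute_cca(records, res.signatures, res.exposures)

    sample_pos = {s: i for i, s in enumerate(res.exposures.sample_ids)}
    brute: dict[tuple, float] = {}
    sbs = records[records["variant_class"] == "SBS"].copy()
    sbs["label"] = classify_substitutions(sbs)
    for _, r in sbs.iterrows():
        if r["gene"] == "":
            continue
        h = res.exposures.activities[:, sample_pos[r["sample_id"]]]
        post = sp.attribute_mutation(r["label"], h, res.signatures)
        for k, sig in enumerate(res.signatures.signature_ids):
            key = (r["sample_id"], r["gene"], sig)
            brute[key] = brute.get(key, 0.0) + post[k]

    got = table.table.set_index(["sample_id", "gene", "signature"])["cca"]
    assert len(got) == len(brute)
    for key, val in brute.items():
        assert got[key] == pytest.approx(val, abs=1e-9)


def test_adding_mutation_only_increases_gene_mass():
    sigs = _two_sig_set([0.2, 0.1], [0.1, 0.2])
    expo = sp.ExposureMatrix(
        activities=np.array([[1.0], [1.0]]),
        signature_ids=["sigA", "sigB"],
        sample_ids=["s1"],
    )
    base = pd.DataFrame([_record("s1", CLASS_LABELS[0], "APC")])
    more = pd.DataFrame(
        [_record("s1", CLASS_LABELS[0], "APC"), _record("s1", CLASS_LABELS[1], "APC")]
    )
    m_base = sp.compute_cca(base, sigs, expo).pivot().sum(axis=1)["s1"]
    m_more = sp.compute_cca(more, sigs, expo).pivot().sum(axis=1)["s1"]
    assert m_more > m_base


def test_unknown_signature_name_rejected(planted_run):
    with pytest.raises(ValueError, match="available"):
        sp.compute_cca(
            planted_run["records"],
            planted_run["result"].signatures,
            planted_run["result"].exposures,
            selected_signatures=["NOPE"],
        )


def test_feature_matrix_layout_and_zero_fill():
    sigs = _two_sig_set([0.2, 0.1], [0.1, 0.2])
    expo = sp.ExposureMatrix(
        activities=np.array([[1.0, 2.0], [1.0, 1.0]]),
        signature_ids=["sigA", "sigB"],
        sample_ids=["s1", "s2"],
    )
    records = pd.DataFrame([_record("s1", CLASS_LABELS[0], "A")])
    table = sp.compute_cca(records, sigs, expo)
    X = sp.cca_feature_matrix(table, genes=["A", "B"], signatures=["sigA", "sigB"])
    assert list(X.columns) == ["A|sigA", "A|sigB", "B|sigA", "B|sigB"]
    assert list(X.index) == ["s1", "s2"]
    assert (X["B|sigA"] == 0).all() and (X["B|sigB"] == 0).all()  # kept, zero
    assert (X.loc["s2"] == 0).all()


def test_feature_matrix_agrees_with_table_lookups(planted_run):
    table = planted_run["table"]
    genes = sorted(table.table["gene"].unique())
    X = sp.cca_feature_matrix(table, genes=genes)
    long = table.table.set_index(["sample_id", "gene", "signature"])["cca"]
    for (s, g, sig), val in long.sample(n=50, random_state=0).items():
        assert X.loc[s, f"{g}|{sig}"] == pytest.approx(val, abs=1e-12)


def test_normalized_variant_sums_to_one(planted_run):
    table = sp.compute_cca(
        planted_run["records"],
        planted_run["result"].signatures,
        planted_run["result"].exposures,
        normalize=True,
    )
    sums = table.table.groupby("sample_id")["cca"].sum()
    np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-9)
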