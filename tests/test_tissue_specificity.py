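"""Tissue-specificity (ratio and presence/absence), sex bias and age filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msci.tissue_specificity import (
    classify_specific,
    denominator_tissues,
    filter_by_age,
    min_tissue_ratio,
    presence_absence_specific,
    sex_bias,
    sex_bias_table,
    specific_set,
)

from conftest import make_annotation, make_panel


# ---------------------------------------------------------------------------
# minimal tissue-to-tissue ratio
# ---------------------------------------------------------------------------

def test_midgut_specific_but_testis_biased_pattern():
    """Signals 629 (midgut) vs 196/34: specific at >2, not at >5."""
    signals = pd.Series({"midgut": 629.0, "testis": 196.0, "ovary": 34.0})
    r = min_tissue_ratio(signals, "midgut", exclude_sex_tissues=False)
    assert r == pytest.approx(629 / 196, rel=1e-9)
    assert r > 2 and not r > 5


def test_uniform_signals_are_not_specific():
    signals = pd.Series({"a": 10.0, "b": 10.0, "c": 10.0})
    assert min_tissue_ratio(signals, "a") == pytest.approx(1.0)


def test_zero_denominator_floored():
    signals = pd.Series({"a": 100.0, "b": 0.0, "c": 50.0})
    assert min_tissue_ratio(signals, "a", floor=1.0) == pytest.approx(2.0)
    # a larger floor caps the specificity further
    assert min_tissue_ratio(signals, "a", floor=60.0) == pytest.approx(100 / 60)


def test_non_positive_focal_never_specific():
    signals = pd.Series({"a": 0.0, "b": 5.0})
    assert min_tissue_ratio(signals, "a") == 0.0


def test_sex_tissues_excluded_from_denominator_by_default():
    all_t = ["midgut", "head", "testis", "ovary"]
    assert denominator_tissues(all_t, "midgut") == ["head"]
    assert denominator_tissues(all_t, "testis") == ["midgut", "head"]
    assert denominator_tissues(all_t, "midgut", exclude_sex_tissues=False) == [
        "head",
        "testis",
        "ovary",
    ]


# ---------------------------------------------------------------------------
# ratio classification
# ---------------------------------------------------------------------------

def _random_panel(seed, n=40):
    rng = np.random.default_rng(seed)
    tissues = ["midgut", "head", "salivary_gland", "ovary", "testis"]
    return make_panel({t: rng.lognormal(4, 1, n) for t in tissues})


def test_planted_tenfold_gene_in_all_threshold_sets():
    panel = make_panel(
        {"head": [1000.0, 10.0], "midgut": [50.0, 10.0], "testis": [30.0, 10.0], "ovary": [20.0, 10.0]}
    )
    calls = classify_specific(panel)
    for thr in (2, 5, 10):
        assert "g001" in specific_set(calls, "head", thr)
        assert "g002" not in specific_set(calls, "head", thr)


def test_uniform_panel_has_empty_sets():
    panel = make_panel({t: [10.0] * 5 for t in ["a", "b", "c"]})
    calls = classify_specific(panel)
    assert (calls["threshold_class"] == "none").all()


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_classification_matches_brute_force(seed):
    """Set membership equals a double loop over genes x tissues."""
    panel = _random_panel(seed)
    calls = classify_specific(panel)
    for tissue in panel.tissues:
        for thr in (2, 5, 10):
            got = specific_set(calls, tissue, thr)
            expected = {
                g
                for g in panel.gene_ids
                if min_tissue_ratio(panel.signals.loc[g], tissue) > thr
            }
            assert got == expected


@pytest.mark.parametrize("seed", [3, 4, 5, 6])
def test_threshold_sets_are_nested(seed):
    panel = _random_panel(seed, n=120)
    calls = classify_specific(panel)
    for tissue in panel.tissues:
        s2, s5, s10 = (specific_set(calls, tissue, t) for t in (2, 5, 10))
        assert s10 <= s5 <= s2


# ---------------------------------------------------------------------------
# sex bias
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "t,o,bias",
    [
        (196.0, 34.0, "testis-biased"),
        (50.0, 50.0, "unbiased"),
        (10.0, 30.0, "ovary-biased"),
        (100.0, 0.0, "testis-biased"),
    ],
)
def test_sex_bias_classes(t, o, bias):
    call = sex_bias(t, o, threshold=2)
    assert call.bias == bias


def test_sex_bias_ratio_and_higher_thresholds():
    call = sex_bias(196.0, 34.0)
    assert call.testis_ovary_ratio == pytest.approx(196 / 34)
    assert sex_bias(196.0, 34.0, threshold=5).bias == "testis-biased"
    assert sex_bias(196.0, 34.0, threshold=10).bias == "unbiased"


def test_sex_bias_both_zero_is_unbiased_with_nan_ratio():
    call = sex_bias(0.0, 0.0)
    assert call.bias == "unbiased"
    assert np.isnan(call.testis_ovary_ratio)


@pytest.mark.parametrize("seed", [10, 11])
def test_sex_bias_table_matches_scalar_and_partitions(seed):
    panel = _random_panel(seed, n=200)
    table = sex_bias_table(panel, threshold=2)
    assert set(table["bias"].unique()) <= {"testis-biased", "ovary-biased", "unbiased"}
    for g in panel.gene_ids[:50]:
        scalar = sex_bias(panel.testis_signal[g], panel.ovary_signal[g], gene_id=g)
        assert table.loc[g, "bias"] == scalar.bias


# ---------------------------------------------------------------------------
# presence/absence definition
# ---------------------------------------------------------------------------

def test_single_tissue_presence_is_specific():
    panel = make_panel(
        {"testis": [100.0, 100.0], "head": [1.0, 1.0], "midgut": [1.0, 1.0]},
        calls={
            "testis": [True, True],
            "head": [False, True],
            "midgut": [False, False],
        },
    )
    pa = presence_absence_specific(panel)
    assert pa.to_dict() == {"g001": "testis"}  # g002 present 4/4 in head too


def test_partial_presence_elsewhere_disqualifies():
    panel = make_panel(
        {"testis": [100.0], "head": [1.0]},
        calls={"testis": [True], "head": [False]},
    )
    assert presence_absence_specific(panel).to_dict() == {"g001": "testis"}
    panel.calls.loc["g001", ("head", 1)] = True  # present 1/4 in head
    assert presence_absence_specific(panel).empty


@pytest.mark.parametrize("seed", [20, 21, 22])
def test_presence_absence_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    tissues = ["a", "b", "c", "d"]
    n = 60
    sig = {t: rng.lognormal(4, 1, n) for t in tissues}
    panel = make_panel(sig)
    # randomize calls independently of signals
    arr = rng.random(panel.calls.shape) < 0.35
    panel.calls.iloc[:, :] = arr
    pa = presence_absence_specific(panel)
    for gi, g in enumerate(panel.gene_ids):
        expected = None
        for t in tissues:
            focal = panel.calls.loc[g, t].all()
            others = all(
                not panel.calls.loc[g, u].any() for u in tissues if u != t
            )
            if focal and others:
                expected = t
        assert pa.get(g) == expected
    # at most one tissue per gene by construction
    assert pa.index.is_unique


# ---------------------------------------------------------------------------
# age filter
# ---------------------------------------------------------------------------

def test_age_filter_keeps_requested_class():
    annot = make_annotation(["X", "2L", "3R"], age=["old", "young", "old"])
    kept = filter_by_age({"g001", "g002", "g003"}, annot)
    assert kept == {"g001", "g003"}
    assert filter_by_age(set(), annot) == set()


def test_age_filter_excludes_unannotated(caplog):
    annot = make_annotation(["X", "2L"], age=["old", "old"])
    kept = filter_by_age({"g001", "zzz"}, annot)
    assert kept == {"g001"}
    assert "without age class" in caplog.text
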