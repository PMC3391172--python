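"""2x2 contingency tests, the test-selection rule and normalized X frequencies."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from msci.enrichment_stats import testis_bias_enrichment as tb_enrichment
from msci.enrichment_stats import (
    FISHER_MAX_N,
    chromosomal_enrichment,
    contingency_test,
    fisher_exact_p,
    normalized_x_frequency,
    significance_stars,
    yates_chi2,
)
from msci.synthetic_data import SimulationConfig, simulate_tissue_panel
from msci.tissue_specificity import classify_specific, sex_bias_table

from conftest import make_annotation


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def test_balanced_table_gives_p_one():
    res = contingency_test(1, 1, 1, 1)
    assert res.test_used == "fisher"
    assert res.p_value == pytest.approx(1.0)


def test_fisher_matches_hypergeometric_enumeration():
    """Two-sided p for (5,15,15,5): sum of all fixed-margin tables whose
    probability does not exceed the observed one."""
    r1 = r2 = 20
    c1 = 20
    from math import comb

    w_obs = comb(r1, 5) * comb(r2, 15)
    num = sum(
        comb(r1, a) * comb(r2, c1 - a)
        for a in range(0, 21)
        if comb(r1, a) * comb(r2, c1 - a) <= w_obs
    )
    expected = num / comb(40, 20)
    assert fisher_exact_p(5, 15, 15, 5) == pytest.approx(expected, abs=1e-14)
    assert contingency_test(5, 15, 15, 5).p_value == pytest.approx(expected, abs=1e-14)


@pytest.mark.parametrize("seed", [0, 1])
def test_fisher_matches_scipy_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    for _ in range(200):
        a, b, c, d = rng.integers(0, 30, 4)
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        assert fisher_exact_p(a, b, c, d) == pytest.approx(
            sps.fisher_exact([[a, b], [c, d]]).pvalue, abs=1e-10
        )


# ---------------------------------------------------------------------------
# Yates chi-square and the selection rule
# ---------------------------------------------------------------------------

def test_equal_proportions_yield_zero_yates_statistic():
    # (10,90,100,900) scaled x10: ad = bc, so the corrected statistic is 0
    res = contingency_test(100, 900, 1000, 9000)
    assert res.total_n >= FISHER_MAX_N
    assert res.test_used == "chisq_yates"
    assert res.p_value == pytest.approx(1.0)
    chi2, p = yates_chi2(100, 900, 1000, 9000)
    assert chi2 == 0.0


def test_yates_closed_form():
    a, b, c, d = 120, 2380, 300, 7200
    N = a + b + c + d
    num = N * max(0.0, abs(a * d - b * c) - N / 2.0) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    chi2, p = yates_chi2(a, b, c, d)
    assert chi2 == pytest.approx(num / den, rel=1e-12)
    res = sps.chi2_contingency(np.array([[a, b], [c, d]]), correction=True)
    assert p == pytest.approx(res.pvalue, rel=1e-10)


def test_selection_rule_boundary():
    """N = 4,999 uses Fisher; N = 5,000 switches to Yates chi-square."""
    assert contingency_test(400, 2099, 430, 2070).test_used == "fisher"
    assert contingency_test(400, 2100, 430, 2070).test_used == "chisq_yates"


def test_zero_margin_is_degenerate():
    res = contingency_test(0, 0, 10, 20)
    assert res.degenerate and res.p_value == 1.0


def test_odds_ratio_and_stars():
    res = contingency_test(30, 10, 10, 30)
    assert res.odds_ratio == pytest.approx(9.0)
    assert res.significance_stars == significance_stars(res.p_value)
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.02) == "*"
    assert significance_stars(0.2) == "ns"


# ---------------------------------------------------------------------------
# normalized X frequency
# ---------------------------------------------------------------------------

def _annot_x_fraction(n_x, n_a):
    return make_annotation(
        ["X"] * n_x + ["2L"] * n_a,
        gene_ids=[f"g{i:04d}" for i in range(1, n_x + n_a + 1)],
    )


def test_normalized_frequency_identity():
    annot = _annot_x_fraction(10, 60)
    subset = ["g0001"] + [f"g{i:04d}" for i in range(11, 17)]  # 1 X of 7 = genome rate
    nf = normalized_x_frequency(subset, annot)
    assert nf.genome_x_fraction == pytest.approx(1 / 7)
    assert nf.normalized_freq == pytest.approx(1.0)


def test_normalized_frequency_closed_form():
    """k=10, n=100, p0=1/7: f = 0.7 and SE = sqrt(.1*.9/100)/(1/7) = 0.21."""
    annot = _annot_x_fraction(100, 600)
    x_ids = [f"g{i:04d}" for i in range(1, 11)]
    a_ids = [f"g{i:04d}" for i in range(101, 191)]
    nf = normalized_x_frequency(x_ids + a_ids, annot)
    assert nf.n == 100 and nf.k == 10
    assert nf.normalized_freq == pytest.approx(0.7)
    assert nf.se_norm == pytest.approx(0.21)
    assert nf.band70 == pytest.approx((0.49, 0.91))
    assert nf.band95 == pytest.approx((0.28, 1.12))
    lo70, hi70 = nf.band70
    lo95, hi95 = nf.band95
    assert lo95 <= lo70 and hi70 <= hi95


def test_empty_set_errors():
    annot = _annot_x_fraction(5, 30)
    with pytest.raises(ValueError):
        normalized_x_frequency([], annot)


# ---------------------------------------------------------------------------
# enrichment tables
# ---------------------------------------------------------------------------

def test_uniform_random_set_is_null(small_panel_sim):
    """A set drawn uniformly from the genome has f ~ 1 and is ns."""
    _, panel, annot, _ = small_panel_sim
    rng = np.random.default_rng(0)
    genes = rng.choice(panel.gene_ids, 400, replace=False)
    nf = normalized_x_frequency(genes, annot)
    assert nf.band95[0] <= 1.0 <= nf.band95[1] or abs(nf.normalized_freq - 1) < 0.3


def test_delegation_identity(small_panel_sim):
    """Sex-bias enrichment rows equal the generic test on the same counts."""
    _, panel, annot, _ = small_panel_sim
    calls = classify_specific(panel)
    sex_calls = sex_bias_table(panel)
    table = tb_enrichment(calls, sex_calls, annot, thresholds=[2])
    universe = set(calls["gene_id"]) & set(sex_calls.index)
    bias = sex_calls["bias"].reindex(sorted(universe))
    for _, row in table.iterrows():
        if row["n"] == 0:
            continue
        from msci.tissue_specificity import specific_set

        genes = specific_set(calls, row["tissue"], 2) & universe
        a = int((bias.loc[sorted(genes)] == "testis-biased").sum())
        b = len(genes) - a
        rest = universe - genes
        c = int((bias.loc[sorted(rest)] == "testis-biased").sum())
        d = len(rest) - c
        res = contingency_test(a, b, c, d)
        assert row["p_value"] == pytest.approx(res.p_value, rel=1e-12)
        assert row["test_used"] == res.test_used


def test_exclude_sex_biased_noop_without_sex_biased_genes():
    """When no gene is sex-biased the filter leaves results bit-identical."""
    cfg = SimulationConfig(
        n_genes=800,
        sexbias_coupling=0.0,
        tissue_log_sd=0.1,  # tight scatter: no background gene crosses 2-fold
        pa_specific_counts={},
    )
    panel, annot, _ = simulate_tissue_panel(cfg, seed=13)
    sex_calls = sex_bias_table(panel)
    # drop the gonads from the panel-driven bias by marking everything unbiased
    unbiased = sex_calls[sex_calls["bias"] == "unbiased"].index
    calls = classify_specific(panel)
    calls = calls[calls["gene_id"].isin(unbiased)]
    plain = chromosomal_enrichment(calls, annot, thresholds=[2], sex_calls=sex_calls)
    filtered = chromosomal_enrichment(
        calls, annot, thresholds=[2], exclude_sex_biased=True, sex_calls=sex_calls
    )
    pd.testing.assert_frame_equal(plain, filtered)


def test_planted_x_depleted_testis_set_detected():
    cfg = SimulationConfig(
        n_genes=6000,
        specific_fraction=0.05,
        testis_x_multiplier=0.2,
        pa_specific_counts={},
    )
    panel, annot, truth = simulate_tissue_panel(cfg, seed=17)
    calls = classify_specific(panel)
    table = chromosomal_enrichment(calls, annot, thresholds=[5]).set_index("tissue")
    row = table.loc["testis"]
    assert row["normalized_freq"] < 0.75
    assert row["p_value"] < 0.01
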