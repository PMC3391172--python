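"""Contingency-table enrichment statistics and normalized X frequencies.

The 2x2 test follows a sample-size rule: Fisher's exact test (two-sided, the
sum of probabilities of all tables with fixed margins whose probability does
not exceed the observed table's — the convention of R's ``fisher.test``) is
used whenever the total count is below 5,000; larger tables use the 1-df
chi-square with Yates continuity correction,

    chi2 = N * (max(0, |ad - bc| - N/2))^2 / ((a+b)(c+d)(a+c)(b+d)).

A gene set's chromosomal representation is summarized as the normalized X
frequency f = p_hat / p0, the set's X-linked fraction over the genome-wide
X-linked fraction, with binomial standard-error bands: f +/- 1 SE covers
roughly 70% and f +/- 2 SE roughly 95% of the sampling distribution under a
random draw from the genome.  Enrichment tables use the rest of the genome
(genome minus the set) as background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Total sample size below which Fisher's exact test is used.
FISHER_MAX_N = 5000


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ContingencyResult:
    counts: np.ndarray  # 2x2, rows (a,b;c,d)
    total_n: int
    test_used: str  # "fisher" | "chisq_yates"
    p_value: float
    odds_ratio: float
    significance_stars: str
    degenerate: bool = False  # zero margin


@dataclass
class NormalizedFrequency:
    n: int  # set size
    k: int  # X-linked genes in the set
    genome_x_fraction: float  # p0
    set_x_fraction: float  # p_hat = k/n
    normalized_freq: float  # f = p_hat/p0
    se_norm: float  # SE(p_hat)/p0
    band70: tuple[float, float]  # f +/- 1 SE
    band95: tuple[float, float]  # f +/- 2 SE


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exact hypergeometric enumeration.

    Table probabilities are compared exactly (integer arithmetic on the
    binomial weights, which share a common denominator), so ties are included
    without a floating-point guard.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    w_obs = comb(r1, a) * comb(r2, c)
    num = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w <= w_obs:
            num += w
    return num / comb(r1 + r2, c1)


def yates_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-corrected chi-square statistic and two-sided p (1 df)."""
    N = a + b + c + d
    num = N * max(0.0, abs(a * d - b * c) - N / 2.0) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = num / den
    return chi2, float(stats.chi2.sf(chi2, df=1))


def contingency_test(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """2x2 association test with the Fisher-below-5000 selection rule.

    Counts must be non-negative integers.  A zero margin makes the test
    degenerate: p = 1 with a flag.  The odds ratio ad/bc is reported (inf
    when bc = 0 with ad > 0, NaN for 0/0).
    """
    counts = np.array([[a, b], [c, d]], dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    N = int(counts.sum())
    margins = [a + b, c + d, a + c, b + d]
    test_used = "fisher" if N < FISHER_MAX_N else "chisq_yates"

    if min(margins) == 0 or N == 0:
        logger.warning("degenerate 2x2 table (zero margin): p set to 1")
        return ContingencyResult(counts, N, test_used, 1.0, float("nan"), "ns", True)

    if test_used == "fisher":
        p = fisher_exact_p(a, b, c, d)
    else:
        _, p = yates_chi2(a, b, c, d)
    p = min(1.0, p)

    ad, bc = a * d, b * c
    odds = ad / bc if bc > 0 else (float("inf") if ad > 0 else float("nan"))
    return ContingencyResult(counts, N, test_used, p, odds, significance_stars(p))


def normalized_x_frequency(
    gene_set: Iterable[str], annot: pd.DataFrame, universe: Iterable[str] | None = None
) -> NormalizedFrequency:
    """X-chromosome representation of a gene set relative to the genome.

    The genome baseline p0 is the X-linked fraction of all annotated genes
    passing the linkage filter (optionally restricted to ``universe``); the
    set is restricted to that same universe.  ``n = 0`` raises.
    """
    link = annot["linkage_class"]
    valid = link[link.isin(["X", "autosome"])]
    if universe is not None:
        valid = valid.reindex(valid.index.intersection(pd.Index(set(universe))))
    if valid.empty:
        raise ValueError("empty genome universe after linkage filtering")
    p0 = float((valid == "X").mean())
    genes = set(gene_set) & set(valid.index)
    n = len(genes)
    if n == 0:
        raise ValueError("empty gene set (after linkage filtering)")
    k = int((valid.loc[list(genes)] == "X").sum())
    p_hat = k / n
    f = p_hat / p0
    se = float(np.sqrt(p_hat * (1 - p_hat) / n)) / p0
    return NormalizedFrequency(
        n=n,
        k=k,
        genome_x_fraction=p0,
        set_x_fraction=p_hat,
        normalized_freq=f,
        se_norm=se,
        band70=(f - se, f + se),
        band95=(f - 2 * se, f + 2 * se),
    )


def _linkage_universe(annot: pd.DataFrame, universe: Iterable[str] | None) -> pd.Series:
    link = annot["linkage_class"]
    valid = link[link.isin(["X", "autosome"])]
    if universe is not None:
        valid = valid.reindex(valid.index.intersection(pd.Index(set(universe))))
    return valid


def chromosomal_enrichment(
    specific_calls: pd.DataFrame,
    annot: pd.DataFrame,
    thresholds: Iterable[float] = (2, 5, 10),
    exclude_sex_biased: bool = False,
    sex_calls: pd.DataFrame | None = None,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """X-vs-autosome enrichment of tissue-specific sets, per tissue x threshold.

    Builds, for every focal tissue and fold threshold, the 2x2 table of
    (X, autosome) x (in set, rest of genome) and applies the selection-rule
    contingency test plus the normalized X frequency.  With
    ``exclude_sex_biased`` set, genes whose sex-bias class is not ``unbiased``
    are removed from both the set and the genome background before testing
    (``sex_calls`` from :func:`msci.tissue_specificity.sex_bias_table`).
    Rows with an empty post-filter set carry n = 0 and no test.
    """
    from .tissue_specificity import specific_set

    if universe is None:
        universe = set(specific_calls["gene_id"])
    valid = _linkage_universe(annot, universe)
    if exclude_sex_biased:
        if sex_calls is None:
            raise ValueError("exclude_sex_biased requires sex_calls")
        unbiased = set(sex_calls.index[(sex_calls["bias"] == "unbiased").to_numpy()])
        valid = valid.reindex(valid.index.intersection(pd.Index(unbiased)))

    genome = set(valid.index)
    is_x = valid == "X"
    rows = []
    for tissue in sorted(specific_calls["focal_tissue"].unique()):
        for thr in thresholds:
            genes = specific_set(specific_calls, tissue, thr) & genome
            n = len(genes)
            if n == 0:
                rows.append(
                    {"tissue": tissue, "threshold": thr, "n": 0, "x_in_set": 0,
                     "normalized_freq": float("nan"), "se_norm": float("nan"),
                     "test_used": None, "p_value": float("nan"), "stars": None}
                )
                continue
            rest = genome - genes
            a = int(is_x.loc[list(genes)].sum())
            b = n - a
            c = int(is_x.loc[list(rest)].sum())
            d = len(rest) - c
            res = contingency_test(a, b, c, d)
            nf = normalized_x_frequency(genes, annot, universe=genome)
            rows.append(
                {
                    "tissue": tissue,
                    "threshold": thr,
                    "n": n,
                    "x_in_set": a,
                    "normalized_freq": nf.normalized_freq,
                    "se_norm": nf.se_norm,
                    "band95_lo": nf.band95[0],
                    "band95_hi": nf.band95[1],
                    "test_used": res.test_used,
                    "p_value": res.p_value,
                    "odds_ratio": res.odds_ratio,
                    "stars": res.significance_stars,
                }
            )
    return pd.DataFrame(rows)


def testis_bias_enrichment(
    specific_calls: pd.DataFrame,
    sex_calls: pd.DataFrame,
    annot: pd.DataFrame,
    thresholds: Iterable[float] = (2, 5, 10),
    contrast: str = "testis-vs-nontestis",
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Testis-bias enrichment within tissue-specific sets.

    The default contrast compares testis-biased vs non-testis-biased counts in
    each tissue-specific set against the rest of the genome; the alternative
    ``testis-vs-ovary`` contrast restricts the second margin to ovary-biased
    genes.
    """
    from .tissue_specificity import specific_set

    if contrast not in {"testis-vs-nontestis", "testis-vs-ovary"}:
        raise ValueError(f"unknown contrast {contrast!r}")
    if universe is None:
        universe = set(specific_calls["gene_id"])
    bias = sex_calls["bias"].reindex(pd.Index(set(universe)).intersection(sex_calls.index))
    if contrast == "testis-vs-ovary":
        bias = bias[bias.isin(["testis-biased", "ovary-biased"])]
    genome = set(bias.index)
    is_tb = bias == "testis-biased"

    rows = []
    for tissue in sorted(specific_calls["focal_tissue"].unique()):
        for thr in thresholds:
            genes = specific_set(specific_calls, tissue, thr) & genome
            n = len(genes)
            if n == 0:
                rows.append({"tissue": tissue, "threshold": thr, "n": 0,
                             "testis_biased_in_set": 0, "test_used": None,
                             "p_value": float("nan"), "stars": None})
                continue
            rest = genome - genes
            a = int(is_tb.loc[list(genes)].sum())
            b = n - a
            c = int(is_tb.loc[list(rest)].sum())
            d = len(rest) - c
            res = contingency_test(a, b, c, d)
            rows.append(
                {
                    "tissue": tissue,
                    "threshold": thr,
                    "n": n,
                    "testis_biased_in_set": a,
                    "set_fraction": a / n,
                    "genome_fraction": c / max(1, len(rest)),
                    "test_used": res.test_used,
                    "p_value": res.p_value,
                    "odds_ratio": res.odds_ratio,
                    "stars": res.significance_stars,
                }
            )
    return pd.DataFrame(rows)
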