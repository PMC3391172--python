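"""Tissue-specificity and sex-bias classification over an expression atlas.

Two definitions of tissue specificity are implemented:

* **ratio** — a gene is specific to a focal tissue when the minimal
  tissue-to-tissue signal ratio (focal signal divided by each other panel
  tissue's signal) exceeds a fold threshold; thresholds of 2, 5 and 10 yield
  nested candidate sets.  Denominator signals are floored at a small positive
  value so that unexpressed tissues do not produce spurious infinite
  specificity.  By default the gonads (testis, ovary) are not part of the
  denominator panel when classifying other tissues, so a midgut-specific gene
  may still carry substantial testis signal — the pattern the sex-bias filter
  is designed to catch.
* **presence/absence** — a gene is specific to a tissue when it is called
  present in all four replicate arrays of that tissue and absent in every
  replicate of every other tissue; this assigns at most one tissue per gene.

Sex bias is a three-way partition at a fold threshold (default 2): a gene is
testis-biased when testis/ovary exceeds the threshold, ovary-biased when
ovary/testis does, unbiased otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import TissuePanel

logger = logging.getLogger(__name__)

SEX_TISSUES = ("testis", "ovary")


@dataclass(frozen=True)
class SexBiasCall:
    gene_id: str
    testis_ovary_ratio: float  # NaN when both signals are zero
    bias: str  # "testis-biased" | "ovary-biased" | "unbiased"
    threshold: float = 2.0


def denominator_tissues(
    all_tissues: Sequence[str],
    focal: str,
    exclude_sex_tissues: bool = True,
) -> list[str]:
    """Panel tissues used in the denominator of the specificity ratio."""
    excluded = set(SEX_TISSUES) - {focal} if exclude_sex_tissues else set()
    return [t for t in all_tissues if t != focal and t not in excluded]


def min_tissue_ratio(
    signals,
    focal: str,
    floor: float = 1.0,
    exclude_sex_tissues: bool = True,
    denominators: Iterable[str] | None = None,
) -> float:
    """Minimal focal-to-other signal ratio for one gene.

    ``signals`` maps tissue name to mean signal.  Denominators are floored at
    ``floor`` before division; a non-positive focal signal returns 0 (never
    specific).
    """
    focal_sig = float(signals[focal])
    if focal_sig <= 0:
        return 0.0
    if denominators is None:
        denominators = denominator_tissues(list(signals.keys() if isinstance(signals, dict) else signals.index), focal, exclude_sex_tissues)
    dens = [max(float(signals[t]), floor) for t in denominators]
    if not dens:
        raise ValueError("need at least one denominator tissue")
    return min(focal_sig / d for d in dens)


def min_ratio_table(
    panel: TissuePanel,
    floor: float = 1.0,
    exclude_sex_tissues: bool = True,
) -> pd.DataFrame:
    """Gene x tissue table of minimal tissue-to-tissue ratios (vectorized)."""
    sig = panel.signals
    out = {}
    for focal in panel.tissues:
        dens = denominator_tissues(panel.tissues, focal, exclude_sex_tissues)
        floored = np.maximum(sig[dens].to_numpy(dtype=float), floor)
        with np.errstate(divide="ignore"):
            ratios = sig[focal].to_numpy(dtype=float)[:, None] / floored
        r = ratios.min(axis=1)
        r[sig[focal].to_numpy(dtype=float) <= 0] = 0.0
        out[focal] = r
    return pd.DataFrame(out, index=sig.index)


def _threshold_class(r: float, thresholds: Sequence[float]) -> str:
    cls = "none"
    for t in sorted(thresholds):
        if r > t:
            cls = f">{t:g}"
    return cls


def classify_specific(
    panel: TissuePanel,
    thresholds: Sequence[float] = (2, 5, 10),
    floor: float = 1.0,
    exclude_sex_tissues: bool = True,
) -> pd.DataFrame:
    """Ratio-based tissue-specificity calls for every gene x tissue.

    Returns a long table with columns ``gene_id``, ``focal_tissue``,
    ``min_ratio`` and ``threshold_class`` (the largest threshold passed, or
    ``none``).  Candidate sets are nested by construction:
    specific(>10) is a subset of specific(>5) is a subset of specific(>2).
    """
    ratios = min_ratio_table(panel, floor=floor, exclude_sex_tissues=exclude_sex_tissues)
    ratios.index.name = "gene_id"
    long = ratios.reset_index().melt(
        id_vars="gene_id", var_name="focal_tissue", value_name="min_ratio"
    )
    long["threshold_class"] = [
        _threshold_class(r, thresholds) for r in long["min_ratio"]
    ]
    return long


def specific_set(calls: pd.DataFrame, tissue: str, threshold: float) -> set[str]:
    """Genes specific to ``tissue`` at ``threshold`` from a classify table."""
    sub = calls[(calls["focal_tissue"] == tissue) & (calls["min_ratio"] > threshold)]
    return set(sub["gene_id"])


def sex_bias(
    testis_signal: float,
    ovary_signal: float,
    threshold: float = 2.0,
    gene_id: str = "",
) -> SexBiasCall:
    """Classify one gene's sex bias from its testis and ovary signals.

    The three classes are mutually exclusive: testis-biased iff
    testis/ovary > threshold, ovary-biased iff ovary/testis > threshold,
    unbiased otherwise.  When both signals are zero the gene is unbiased with
    an undefined (NaN) ratio.
    """
    t = float(testis_signal)
    o = float(ovary_signal)
    if t < 0 or o < 0:
        raise ValueError("signals must be non-negative")
    if t == 0 and o == 0:
        logger.warning("gene %s: both testis and ovary signals are zero", gene_id)
        return SexBiasCall(gene_id, float("nan"), "unbiased", threshold)
    ratio = t / o if o > 0 else float("inf")
    if t > threshold * o:
        bias = "testis-biased"
    elif o > threshold * t:
        bias = "ovary-biased"
    else:
        bias = "unbiased"
    return SexBiasCall(gene_id, ratio, bias, threshold)


def sex_bias_table(panel: TissuePanel, threshold: float = 2.0) -> pd.DataFrame:
    """Vectorized sex-bias classification; index gene_id, columns ratio/bias."""
    t = panel.testis_signal.to_numpy(dtype=float)
    o = panel.ovary_signal.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(o > 0, t / o, np.where(t > 0, np.inf, np.nan))
    bias = np.where(
        t > threshold * o,
        "testis-biased",
        np.where(o > threshold * t, "ovary-biased", "unbiased"),
    )
    # both-zero genes fall through the strict inequalities -> unbiased
    return pd.DataFrame(
        {"testis_ovary_ratio": ratio, "bias": bias}, index=panel.signals.index
    )


def presence_absence_specific(panel: TissuePanel) -> pd.Series:
    """Call genes specific to the single tissue where all calls are present.

    A gene is specific to tissue T iff its four replicate calls are present in
    T and every call is absent in every other tissue; by construction each
    gene maps to at most one tissue.  Returns a Series gene_id -> tissue for
    the specific genes only.  Genes with missing calls are skipped with a
    warning.
    """
    calls = panel.calls
    complete = calls.notna().all(axis=1)
    if (~complete).any():
        logger.warning("%d gene(s) with missing calls skipped", int((~complete).sum()))
        calls = calls.loc[complete]
    tissues = panel.tissues
    all_present = pd.DataFrame(
        {t: calls[t].all(axis=1) for t in tissues}, index=calls.index
    )
    any_present = pd.DataFrame(
        {t: calls[t].any(axis=1) for t in tissues}, index=calls.index
    )
    n_any = any_present.sum(axis=1)
    out = {}
    for t in tissues:
        mask = all_present[t] & (n_any == 1)
        for g in calls.index[mask]:
            out[g] = t
    return pd.Series(out, dtype=object, name="tissue")


def filter_by_age(gene_set: Iterable[str], annot: pd.DataFrame, keep: str = "old") -> set[str]:
    """Keep only genes of the requested age class (default ``old``: origin
    predating the Sophophora/Drosophila subgenus split).

    Genes missing from the annotation or lacking an age class are excluded
    with a warning; counts are logged.
    """
    gene_set = set(gene_set)
    ages = annot["age_class"].reindex(list(gene_set))
    missing = int(ages.isna().sum())
    if missing:
        logger.warning("%d gene(s) without age class excluded by the age filter", missing)
    kept = set(ages.index[(ages == keep).to_numpy(dtype=bool)])
    logger.info("age filter (%s): kept %d/%d genes", keep, len(kept), len(gene_set))
    return kept
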