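"""Replicate reproducibility diagnostics for stage expression matrices.

For each developmental stage, the Pearson correlation is computed over genes
for every unordered pair of replicate arrays.  With 10 replicates that gives
45 correlations per stage.  Low within-stage correlations (quality arrays are
usually above 0.9) indicate large experimental error, which inflates the
within-replicate variance component and erodes the power of chromosome-level
expression contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import StageExpressionSet

logger = logging.getLogger(__name__)


@dataclass
class CorrelationSummary:
    stage_label: str
    correlations: np.ndarray  # length C(n_replicates, 2), NaN pairs removed
    quartiles: dict  # min / q1 / median / q3 / max

    @property
    def mean(self) -> float:
        return float(np.mean(self.correlations))


def pairwise_correlations(stage: StageExpressionSet) -> np.ndarray:
    """Pearson correlation over genes for every unordered replicate pair.

    Pairs involving a zero-variance (constant) replicate column are undefined;
    they are excluded with a warning rather than set to zero.
    """
    if stage.n_replicates < 2:
        raise ValueError(f"stage {stage.stage_label}: need >=2 replicates")
    if stage.n_genes < 3:
        raise ValueError(f"stage {stage.stage_label}: need >=3 genes")
    mat = stage.matrix.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    iu = np.triu_indices(stage.n_replicates, k=1)
    vals = corr[iu]
    n_bad = int(np.isnan(vals).sum())
    if n_bad:
        logger.warning(
            "stage %s: %d replicate pair(s) with undefined correlation excluded",
            stage.stage_label,
            n_bad,
        )
        vals = vals[~np.isnan(vals)]
    return vals


def _quartiles(v: np.ndarray) -> dict:
    q = np.percentile(v, [0, 25, 50, 75, 100])
    return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}


def correlation_summary(
    stages: Mapping[str, StageExpressionSet],
    quality_threshold: float = 0.9,
) -> tuple[dict[str, CorrelationSummary], dict]:
    """Per-stage correlation summaries plus pooled statistics.

    Returns ``(per_stage, pooled)`` where ``pooled`` carries the overall mean
    of all correlations pooled across stages, the global minimum, and a
    ``low_quality`` flag raised when the overall mean falls below
    ``quality_threshold`` (default 0.9, the conventional benchmark for a
    quality microarray experiment).
    """
    if not stages:
        raise ValueError("need at least one stage")
    per_stage: dict[str, CorrelationSummary] = {}
    pool: list[np.ndarray] = []
    for label, st in stages.items():
        v = pairwise_correlations(st)
        per_stage[label] = CorrelationSummary(label, v, _quartiles(v))
        pool.append(v)
    allv = np.concatenate(pool)
    overall_mean = float(allv.mean())
    pooled = {
        "overall_mean": overall_mean,
        "global_min": float(allv.min()),
        "n_correlations": int(allv.size),
        "low_quality": overall_mean < quality_threshold,
        "quality_threshold": quality_threshold,
    }
    if pooled["low_quality"]:
        logger.warning(
            "overall mean replicate correlation %.3f below quality threshold %.2f",
            overall_mean,
            quality_threshold,
        )
    return per_stage, pooled


def summary_table(per_stage: Mapping[str, CorrelationSummary]) -> pd.DataFrame:
    """Flatten per-stage summaries into a tidy table (one row per stage)."""
    rows = []
    for label, s in per_stage.items():
        rows.append({"stage": label, "mean": s.mean, "n_pairs": s.correlations.size, **s.quartiles})
    return pd.DataFrame(rows)
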