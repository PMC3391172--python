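"""X-vs-autosome expression contrasts per developmental stage.

Each gene's expression within a stage is the arithmetic mean of its replicate
A-values; the unit of inference is the chromosome class (X vs autosomes), not
the individual gene.  Class means are compared with a two-sample t-test —
Welch's unequal-variance form by default, with the pooled-variance (Student)
variant selectable.  Under meiotic sex chromosome inactivation the X class
mean is expected to fall below the autosomal mean in stages where meiotic
spermatocytes dominate the tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import StageExpressionSet

logger = logging.getLogger(__name__)


@dataclass
class ChromosomeComparison:
    stage_label: str
    mean_X: float
    mean_A: float
    n_X: int
    n_A: int
    t_statistic: float
    p_value: float
    direction: int  # sign of (mean_X - mean_A)
    flagged: bool = False  # degenerate variance situation


def gene_means(stage: StageExpressionSet) -> pd.Series:
    """Per-gene arithmetic mean of A-values across replicates."""
    return stage.matrix.mean(axis=1)


def x_autosome_test(
    means: pd.Series,
    annot: pd.DataFrame,
    equal_var: bool = False,
    alternative: str = "two-sided",
    stage_label: str = "",
) -> ChromosomeComparison:
    """Two-sample t-test of X-linked vs autosomal per-gene mean expression.

    ``means`` is indexed by gene id; linkage comes from ``annot['linkage_class']``
    (genes with class ``excluded`` or missing annotation are ignored).  Welch's
    test by default (``equal_var=False``); two-sided p-values by default.
    """
    link = annot["linkage_class"].reindex(means.index)
    x = means[(link == "X").to_numpy()].to_numpy(dtype=float)
    a = means[(link == "autosome").to_numpy()].to_numpy(dtype=float)
    if len(x) < 2 or len(a) < 2:
        raise ValueError("need >=2 genes in each linkage class")

    flagged = False
    if (len(x) == 2 and np.var(x) == 0) or (len(a) == 2 and np.var(a) == 0):
        flagged = True
        logger.warning("stage %s: a linkage class has zero variance at n=2", stage_label)

    res = stats.ttest_ind(x, a, equal_var=equal_var, alternative=alternative)
    mean_x = float(x.mean())
    mean_a = float(a.mean())
    return ChromosomeComparison(
        stage_label=stage_label,
        mean_X=mean_x,
        mean_A=mean_a,
        n_X=len(x),
        n_A=len(a),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=int(np.sign(mean_x - mean_a)),
        flagged=flagged,
    )


def stage_tests(
    stages,
    annot: pd.DataFrame,
    equal_var: bool = False,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Run the X-vs-autosome contrast for every stage; one row per stage."""
    rows = []
    for label, st in stages.items():
        cmp = x_autosome_test(
            gene_means(st), annot, equal_var=equal_var, alternative=alternative, stage_label=label
        )
        rows.append(
            {
                "stage": label,
                "mean_X": cmp.mean_X,
                "mean_A": cmp.mean_A,
                "n_X": cmp.n_X,
                "n_A": cmp.n_A,
                "t": cmp.t_statistic,
                "p_value": cmp.p_value,
                "direction": cmp.direction,
            }
        )
    return pd.DataFrame(rows)
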