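"""Sum-of-squares variance decomposition for replicate expression matrices.

Within each developmental stage, expression values y_gr (gene g, replicate r)
are decomposed by a one-way random-effects model with genes as groups —
replicates are nested in genes, which is the only nesting available within a
stage:

    ss_within = sum_g sum_r (y_gr - ybar_g)^2        (experimental error)
    ss_among  = sum_g n_g (ybar_g - ybar)^2          (among genes)
    ms_within = ss_within / (N - G)
    ms_among  = ss_among / (G - 1)
    var_within = ms_within
    var_among  = max(0, (ms_among - ms_within) / n0)

where n0 is the effective group size (equal to the replicate count for
balanced data; the Sokal-Rohlf correction n0 = (N - sum n_g^2 / N) / (G - 1)
otherwise).  The experimental-error fraction is reported in percent,
100 * var_within / (var_within + var_among).

The companion SD-ratio diagnostic contrasts the standard deviation among
genes of the per-gene replicate means with the mean over genes of the
within-gene replicate SD; a ratio near 1 means biological signal barely
exceeds measurement noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import StageExpressionSet

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    stage_label: str
    ss_among: float
    ss_within: float
    ms_among: float
    ms_within: float
    var_among: float
    var_within: float
    error_fraction: float  # percent
    n_genes: int
    n_replicates: int


@dataclass
class SDRatioResult:
    stage_label: str
    linkage_class: str  # "X" | "autosome" | "pooled"
    among_gene_sd: float
    mean_within_sd: float
    ratio: float  # NaN when mean_within_sd == 0
    degenerate: bool = False


def variance_components(stage: StageExpressionSet) -> VarianceComponents:
    """One-way random-effects decomposition (replicates nested in genes).

    Accepts NaN cells for dialects with per-gene missing replicates; the
    unbalanced case uses the Sokal-Rohlf effective group size.  Requires at
    least two genes and two replicate measurements per gene.
    """
    y = stage.matrix.to_numpy(dtype=float)
    G = y.shape[0]
    if G < 2:
        raise ValueError("variance decomposition needs >=2 genes")
    if y.shape[1] < 2:
        raise ValueError("within-gene sum of squares undefined with a single replicate")

    mask = np.isfinite(y)
    n_g = mask.sum(axis=1)
    if (n_g < 2).any():
        raise ValueError("every gene needs >=2 non-null replicate values")
    N = int(n_g.sum())

    row_means = np.nansum(np.where(mask, y, 0.0), axis=1) / n_g
    grand = float(np.nansum(np.where(mask, y, 0.0)) / N)

    resid = np.where(mask, y - row_means[:, None], 0.0)
    ss_within = float(np.sum(resid**2))
    ss_among = float(np.sum(n_g * (row_means - grand) ** 2))

    ms_within = ss_within / (N - G)
    ms_among = ss_among / (G - 1)

    if np.all(n_g == n_g[0]):
        n0 = float(n_g[0])
    else:
        n0 = (N - float(np.sum(n_g**2)) / N) / (G - 1)

    var_within = ms_within
    var_among = max(0.0, (ms_among - ms_within) / n0)
    total = var_within + var_among
    error_fraction = 100.0 * var_within / total if total > 0 else float("nan")

    return VarianceComponents(
        stage_label=stage.stage_label,
        ss_among=ss_among,
        ss_within=ss_within,
        ms_among=ms_among,
        ms_within=ms_within,
        var_among=var_among,
        var_within=var_within,
        error_fraction=error_fraction,
        n_genes=G,
        n_replicates=stage.n_replicates,
    )


def within_gene_sds(stage: StageExpressionSet) -> pd.Series:
    """Sample SD (denominator n-1) across replicates, per gene."""
    if stage.n_replicates < 2:
        raise ValueError("within-gene SD undefined with a single replicate")
    return stage.matrix.std(axis=1, ddof=1)


def sd_summary(stage: StageExpressionSet) -> dict:
    """Quartile summary of the within-gene SD distribution (for box plots)."""
    sds = within_gene_sds(stage).to_numpy()
    q = np.percentile(sds, [0, 25, 50, 75, 100])
    return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4], "mean": sds.mean()}


def _sd_ratio_for(label: str, cls: str, mat: pd.DataFrame) -> SDRatioResult:
    gene_means = mat.mean(axis=1)
    among = float(gene_means.std(ddof=1))
    within = float(mat.std(axis=1, ddof=1).mean())
    degenerate = within == 0.0
    ratio = float("nan") if degenerate else among / within
    if degenerate:
        logger.warning("stage %s (%s): mean within-replicate SD is 0; ratio undefined", label, cls)
    return SDRatioResult(label, cls, among, within, ratio, degenerate)


def sd_ratio(
    stage: StageExpressionSet, annot: pd.DataFrame | None = None
) -> dict[str, SDRatioResult]:
    """Among-gene vs within-replicate SD ratio, pooled and per linkage class.

    ``annot`` must carry a ``linkage_class`` column; classes with fewer than
    two genes in the stage are skipped with a warning.  The pooled ratio is
    always reported.
    """
    out = {"pooled": _sd_ratio_for(stage.stage_label, "pooled", stage.matrix)}
    if annot is not None:
        link = annot["linkage_class"].reindex(stage.matrix.index)
        for cls in ("X", "autosome"):
            sub = stage.matrix.loc[(link == cls).to_numpy()]
            if len(sub) < 2:
                logger.warning(
                    "stage %s: linkage class %s has <2 genes; skipped", stage.stage_label, cls
                )
                continue
            out[cls] = _sd_ratio_for(stage.stage_label, cls, sub)
    return out


def components_table(stages, annot: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per stage with variance components and pooled/X/A SD ratios."""
    rows = []
    for label, st in stages.items():
        vc = variance_components(st)
        row = {
            "stage": label,
            "n_genes": vc.n_genes,
            "n_replicates": vc.n_replicates,
            "ss_among": vc.ss_among,
            "ss_within": vc.ss_within,
            "var_among": vc.var_among,
            "var_within": vc.var_within,
            "error_fraction_pct": vc.error_fraction,
        }
        for cls, res in sd_ratio(st, annot).items():
            row[f"sd_ratio_{cls}"] = res.ratio
        rows.append(row)
    return pd.DataFrame(rows)
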