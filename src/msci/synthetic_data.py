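"""Synthetic developing-testis matrices and tissue panels with known truth.

Every pipeline stage can be exercised without downloads: the generator
emulates (i) gene x replicate log2-intensity matrices with separable
among-gene and within-replicate variance and an optional X-linked downshift
in late stages, and (ii) a FlyAtlas-style tissue panel with planted
tissue-specific genes, planted testis/ovary bias correlated with tissue
specificity, chromosome-arm assignments and present/absent calls.

Model for the stage matrices: each gene g draws a baseline mean
mu_g ~ Normal(gene_mean_location, sqrt(var_among)); in stage s the gene mean
is mu_g + x_shift_s for X-linked genes; replicate values add independent
Normal(0, sqrt(var_within_s)) noise.  The expected mean pairwise replicate
correlation is var_among / (var_among + var_within) and the expected
experimental-error fraction is 100 * var_within / (var_within + var_among),
so the decomposition and QC modules have closed-form recovery targets.

Default study conditions: ~14,000 transcripts, 10 replicates, seven stages
(4thF..Adult) with per-stage error-variance defaults spanning roughly 24-44%
experimental error, X fraction 1/6, and a -0.5 log2 X shift in the three
late stages (wandering larvae through adult) where meiotic spermatocytes
dominate.

The tissue panel draws a per-gene baseline signal (log-normal) with
per-tissue log-normal scatter; a planted tissue-specific gene has its focal
signal raised to ``specific_fold x (1 + specific_margin)`` times its largest
denominator-panel signal.  With probability ``sexbias_coupling`` a planted
gene in a somatic tissue is additionally made testis-biased (ovary signal
pushed down), and such coupled genes are drawn with a depleted X probability
— the confound that sex-bias filtering must remove.  Presence/absence calls
are thresholded from the per-gene baseline (so background genes are broadly
present or broadly absent) plus planted single-tissue presence, with optional
Bernoulli flip noise per replicate call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import STAGE_LABELS, ConfigError, StageExpressionSet, TissuePanel, annotate_linkage

DEFAULT_TISSUES = (
    "midgut",
    "malpighian_tubule",
    "accessory_gland",
    "salivary_gland",
    "head",
    "ovary",
    "testis",
)

#: Autosomal arm labels and their relative sizes used for assignment.
_AUTOSOME_ARMS = ("2L", "2R", "3L", "3R", "4")
_ARM_WEIGHTS = (0.24, 0.25, 0.25, 0.25, 0.01)


@dataclass
class SimulationConfig:
    """Ground-truth parameters for both generators.

    Identical config + seed gives bit-identical outputs.  ``var_within`` may
    be a scalar (shared by all stages) or one value per stage; the defaults
    span per-stage experimental-error fractions from ~24% to ~44%.
    """

    # stage matrices
    n_genes: int = 14000
    n_replicates: int = 10
    stage_labels: Sequence[str] = STAGE_LABELS
    gene_mean_location: float = 8.0
    var_among: float = 1.0
    var_within: float | Sequence[float] = (0.42, 0.50, 0.33, 0.31, 0.36, 0.47, 0.79)
    x_fraction: float = 1.0 / 6.0
    x_shift_per_stage: Sequence[float] = (0.0, 0.0, 0.0, 0.0, -0.5, -0.5, -0.5)
    young_fraction: float = 0.10

    # tissue panel
    tissues: Sequence[str] = DEFAULT_TISSUES
    specific_fraction: float = 0.02
    specific_fold: float = 10.0
    specific_margin: float = 0.25  # focal = fold * (1 + margin) * max(panel)
    sexbias_coupling: float = 0.3
    coupled_x_multiplier: float = 0.2  # X prob multiplier for coupled genes
    testis_x_multiplier: float = 0.3  # planted testis-specific genes
    ovary_x_multiplier: float = 2.5  # planted ovary-specific genes
    signal_log_mean: float = math.log(400.0)  # per-gene baseline, ln scale
    signal_log_sd: float = 0.8
    tissue_log_sd: float = 0.75  # per-tissue scatter around the baseline
    call_threshold: float = 50.0
    call_flip_prob: float = 0.01
    pa_high_log_mean: float = math.log(500.0)  # planted present-tissue signal
    pa_low_log_mean: float = math.log(2.0)  # planted absent-tissue signal
    pa_specific_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "testis": 150,
            "ovary": 17,
            "head": 37,
            "accessory_gland": 10,
            "midgut": 8,
            "salivary_gland": 5,
            "malpighian_tubule": 5,
        }
    )

    seed: int = 0

    def __post_init__(self) -> None:
        n_stages = len(self.stage_labels)
        if len(set(self.stage_labels)) != n_stages:
            raise ConfigError("stage labels must be unique")
        vw = self.var_within
        if np.isscalar(vw):
            vw = tuple([float(vw)] * n_stages)
        else:
            vw = tuple(float(v) for v in vw)
        if len(vw) != n_stages:
            raise ConfigError("var_within must be scalar or one value per stage")
        self.var_within = vw
        if any(v < 0 for v in vw) or self.var_among < 0:
            raise ConfigError("variances must be non-negative")
        if len(self.x_shift_per_stage) != n_stages:
            raise ConfigError("x_shift_per_stage must have one value per stage")
        for name in ("x_fraction", "young_fraction", "sexbias_coupling", "specific_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.specific_fold <= 1.0:
            raise ConfigError("specific_fold must exceed 1 for planted genes")

    @property
    def var_within_by_stage(self) -> dict[str, float]:
        return dict(zip(self.stage_labels, self.var_within))


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(1, n + 1)]


def _assign_arms(rng: np.random.Generator, x_prob: np.ndarray) -> np.ndarray:
    """Chromosome arm per gene given each gene's probability of being X-linked."""
    on_x = rng.random(len(x_prob)) < x_prob
    arms = rng.choice(_AUTOSOME_ARMS, size=len(x_prob), p=np.array(_ARM_WEIGHTS) / sum(_ARM_WEIGHTS))
    return np.where(on_x, "X", arms)


def _annotation(rng: np.random.Generator, ids: list[str], arms: np.ndarray, young_fraction: float) -> pd.DataFrame:
    age = np.where(rng.random(len(ids)) < young_fraction, "young", "old")
    annot = pd.DataFrame(
        {"gene_id": ids, "chromosome": arms, "age_class": age, "unique_alignment": True}
    )
    return annotate_linkage(annot).set_index("gene_id")


def simulate_stage_set(
    config: SimulationConfig, seed: int | None = None
) -> tuple[dict[str, StageExpressionSet], pd.DataFrame, dict]:
    """Generate per-stage replicate matrices, the annotation and a truth record."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ids = _gene_ids(config.n_genes)
    arms = _assign_arms(rng, np.full(config.n_genes, config.x_fraction))
    annot = _annotation(rng, ids, arms, config.young_fraction)
    on_x = (annot["chromosome"] == "X").to_numpy()

    mu = rng.normal(config.gene_mean_location, math.sqrt(config.var_among), config.n_genes)
    rep_cols = [f"rep{i:02d}" for i in range(1, config.n_replicates + 1)]
    stages: dict[str, StageExpressionSet] = {}
    for label, vw, shift in zip(config.stage_labels, config.var_within, config.x_shift_per_stage):
        stage_mu = mu + shift * on_x
        y = stage_mu[:, None] + rng.normal(
            0.0, math.sqrt(vw), (config.n_genes, config.n_replicates)
        )
        mat = pd.DataFrame(y, index=pd.Index(ids, name="gene_id"), columns=rep_cols)
        stages[label] = StageExpressionSet(stage_label=label, matrix=mat)

    truth = {
        "gene_means": mu,
        "on_x": on_x,
        "var_among": config.var_among,
        "var_within": config.var_within_by_stage,
        "x_shift": dict(zip(config.stage_labels, config.x_shift_per_stage)),
        "config": asdict(config),
    }
    return stages, annot, truth


def simulate_tissue_panel(
    config: SimulationConfig, seed: int | None = None
) -> tuple[TissuePanel, pd.DataFrame, dict]:
    """Generate a tissue panel, its annotation and the planted-truth record."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    G = config.n_genes
    tissues = list(config.tissues)
    somatic = [t for t in tissues if t not in ("testis", "ovary")]
    ids = _gene_ids(G)

    # -- plant tissue-specific genes (ratio definition), disjoint across tissues
    n_spec = int(round(config.specific_fraction * G))
    perm = rng.permutation(G)
    planted: dict[str, np.ndarray] = {}
    cursor = 0
    for t in tissues:
        planted[t] = perm[cursor : cursor + n_spec]
        cursor += n_spec

    # -- plant presence/absence-specific genes from the remaining pool
    pa_planted: dict[str, np.ndarray] = {}
    for t, cnt in config.pa_specific_counts.items():
        if t not in tissues:
            raise ConfigError(f"pa_specific_counts references unknown tissue {t!r}")
        pa_planted[t] = perm[cursor : cursor + cnt]
        cursor += cnt
    if cursor > G:
        raise ConfigError("planted gene counts exceed n_genes")

    # -- couple somatic planted genes to testis bias
    coupled = np.zeros(G, dtype=bool)
    for t in somatic:
        coupled[planted[t]] |= rng.random(len(planted[t])) < config.sexbias_coupling

    # -- chromosome assignment with planted skews
    x_prob = np.full(G, config.x_fraction)
    x_prob[coupled] = config.x_fraction * config.coupled_x_multiplier
    for t, mult in (("testis", config.testis_x_multiplier), ("ovary", config.ovary_x_multiplier)):
        idx = np.concatenate([planted.get(t, []), pa_planted.get(t, [])]).astype(int)
        if idx.size:
            x_prob[idx] = min(0.9, config.x_fraction * mult)
    arms = _assign_arms(rng, x_prob)
    annot = _annotation(rng, ids, arms, config.young_fraction)

    # -- continuous signals: per-gene baseline x per-tissue scatter
    baseline = np.exp(rng.normal(config.signal_log_mean, config.signal_log_sd, G))
    sig = baseline[:, None] * np.exp(rng.normal(0.0, config.tissue_log_sd, (G, len(tissues))))

    for ti, t in enumerate(tissues):
        idx = planted[t]
        if idx.size == 0:
            continue
        others = [j for j in range(len(tissues)) if j != ti]
        peak = sig[idx][:, others].max(axis=1)
        sig[idx, ti] = config.specific_fold * (1.0 + config.specific_margin) * peak

    # -- testis/ovary bias coupled to specificity: push the ovary signal down
    t_i, o_i = tissues.index("testis"), tissues.index("ovary")
    r = rng.uniform(2.5, 8.0, int(coupled.sum()))
    sig[coupled, o_i] = np.minimum(sig[coupled, o_i], sig[coupled, t_i] / r)

    # -- presence/absence calls from the per-gene baseline plus planted
    #    single-tissue patterns (ratio-planted genes keep their baseline calls:
    #    they are expressed genes whose focal signal is merely elevated)
    call_sig = np.repeat(baseline[:, None], len(tissues), axis=1)
    for t, idx in pa_planted.items():
        ti = tissues.index(t)
        low = np.exp(rng.normal(config.pa_low_log_mean, 0.5, (len(idx), len(tissues))))
        high = np.exp(rng.normal(config.pa_high_log_mean, 0.3, len(idx)))
        call_sig[idx] = low
        call_sig[idx, ti] = high
        sig[idx] = low
        sig[idx, ti] = high

    present = call_sig > config.call_threshold
    n_calls = 4
    calls_arr = np.repeat(present[:, :, None], n_calls, axis=2)
    if config.call_flip_prob > 0:
        flips = rng.random(calls_arr.shape) < config.call_flip_prob
        calls_arr = calls_arr ^ flips
    calls = pd.DataFrame(
        {
            (t, i + 1): calls_arr[:, ti, i]
            for ti, t in enumerate(tissues)
            for i in range(n_calls)
        },
        index=pd.Index(ids, name="gene_id"),
    )
    calls.columns = pd.MultiIndex.from_tuples(calls.columns)

    signals = pd.DataFrame(sig, index=pd.Index(ids, name="gene_id"), columns=tissues)
    panel = TissuePanel(signals=signals, calls=calls, n_calls=n_calls)

    id_arr = np.array(ids)
    truth = {
        "planted_specific": {t: set(id_arr[v]) for t, v in planted.items()},
        "planted_pa_specific": {t: set(id_arr[v]) for t, v in pa_planted.items()},
        "coupled_testis_biased": set(id_arr[coupled]),
        "x_prob": x_prob,
        "config": asdict(config),
    }
    return panel, annot, truth


def write_truth(truth: dict, path) -> None:
    """Serialize planted-set truth as a tidy TSV (label, gene_id)."""
    rows = []
    for t, genes in truth.get("planted_specific", {}).items():
        rows.extend({"label": f"specific:{t}", "gene_id": g} for g in sorted(genes))
    for t, genes in truth.get("planted_pa_specific", {}).items():
        rows.extend({"label": f"pa_specific:{t}", "gene_id": g} for g in sorted(genes))
    rows.extend(
        {"label": "testis_biased_coupled", "gene_id": g}
        for g in sorted(truth.get("coupled_testis_biased", set()))
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
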