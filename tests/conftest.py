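import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from msci.io_formats import StageExpressionSet, TissuePanel, annotate_linkage
from msci.synthetic_data import SimulationConfig, simulate_stage_set, simulate_tissue_panel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_stage(values, label="4thF", gene_ids=None) -> StageExpressionSet:
    """Small stage matrix from a list of per-gene replicate lists."""
    arr = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i:03d}" for i in range(1, arr.shape[0] + 1)]
    mat = pd.DataFrame(
        arr,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"rep{i:02d}" for i in range(1, arr.shape[1] + 1)],
    )
    return StageExpressionSet(stage_label=label, matrix=mat)


def make_annotation(chromosomes, gene_ids=None, age=None) -> pd.DataFrame:
    if gene_ids is None:
        gene_ids = [f"g{i:03d}" for i in range(1, len(chromosomes) + 1)]
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": chromosomes,
            "age_class": age if age is not None else ["old"] * len(gene_ids),
            "unique_alignment": True,
        }
    )
    return annotate_linkage(df).set_index("gene_id")


def make_panel(signals: dict, calls: dict | None = None, n_calls: int = 4) -> TissuePanel:
    """Panel from {tissue: [per-gene signals]}; calls default to signal > 50."""
    sig = pd.DataFrame(signals, dtype=float)
    sig.index = pd.Index([f"g{i:03d}" for i in range(1, len(sig) + 1)], name="gene_id")
    data = {}
    for t in sig.columns:
        for r in range(1, n_calls + 1):
            if calls is not None and t in calls:
                data[(t, r)] = np.asarray(calls[t], dtype=bool)
            else:
                data[(t, r)] = sig[t].to_numpy() > 50.0
    cal = pd.DataFrame(data, index=sig.index)
    cal.columns = pd.MultiIndex.from_tuples(cal.columns)
    return TissuePanel(signals=sig, calls=cal, n_calls=n_calls)


@pytest.fixture(scope="session")
def small_sim():
    """A modest full simulation shared across read-only tests."""
    cfg = SimulationConfig(n_genes=3000)
    stages, annot, truth = simulate_stage_set(cfg, seed=11)
    return cfg, stages, annot, truth


@pytest.fixture(scope="session")
def small_panel_sim():
    cfg = SimulationConfig(n_genes=4000)
    panel, annot, truth = simulate_tissue_panel(cfg, seed=7)
    return cfg, panel, annot, truth
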