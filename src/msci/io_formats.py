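"""Tabular I/O for two-channel microarray expression data and tissue panels.

The canonical on-disk dialect is UTF-8 delimited text (TSV by default).  Three
tables are understood:

* stage expression — long format with columns ``gene_id``, ``stage`` and
  ``rep01``..``repNN`` holding A-values (average log2 intensity) per replicate;
* gene annotation — ``gene_id``, ``chromosome`` (arm label), ``age_class``
  (``old``/``young``) and ``unique_alignment``;
* tissue panel — per-gene mean signals per tissue plus four present/absent
  calls per tissue, or the probe-level pair of tables (signals and calls keyed
  by probe id) that is cross-linked to genes through the annotation.

Two-channel records are reduced to M/A coordinates: M = R - G (log fold
change) and A = (R + G)/2 (average intensity).  Records whose A-value cannot
be formed (either channel missing) are flagged and excluded from the
statistical analyses downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Developmental-stage labels: feeding (F) or wandering (W) larvae grown for
#: 4, 5, 6, 7 or 10 days, plus adult flies.
STAGE_LABELS: tuple[str, ...] = ("4thF", "5thF", "6thF", "7thF", "7thW", "10thW", "Adult")

#: Chromosome arms counted as autosomal in X-vs-autosome contrasts.
AUTOSOME_ARMS = frozenset({"2L", "2R", "3L", "3R", "4"})


class FormatError(ValueError):
    """Raised when an input table violates the expected schema."""


class ConfigError(ValueError):
    """Raised for invalid configuration (unknown stage labels, bad options)."""


# ---------------------------------------------------------------------------
# M/A transformation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelIntensities:
    """One two-channel record in both channel and M/A coordinates.

    ``M = R - G`` and ``A = (R + G) / 2``; both are ``None`` whenever either
    channel is missing, in which case :attr:`excluded` is true and the record
    must not enter the statistical analyses.
    """

    R: float | None
    G: float | None
    M: float | None
    A: float | None

    @property
    def excluded(self) -> bool:
        return self.A is None


def _coerce_channel(value, name: str, row=None) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        where = f" at row {row!r}" if row is not None else ""
        raise FormatError(f"non-numeric {name} channel value {value!r}{where}")
    if math.isnan(v):
        return None
    return v


def parse_channel_record(R, G, row=None) -> ChannelIntensities:
    """Build :class:`ChannelIntensities` from normalized log2 channel values.

    ``None``/NaN in either channel yields a record with null M and A, flagged
    for exclusion.  Non-numeric input raises :class:`FormatError` naming the
    offending row.
    """
    r = _coerce_channel(R, "R", row)
    g = _coerce_channel(G, "G", row)
    if r is None or g is None:
        return ChannelIntensities(r, g, None, None)
    return ChannelIntensities(r, g, r - g, (r + g) / 2.0)


def ma_transform(R, G) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized M/A transform; NaN in either channel propagates to both."""
    R = np.asarray(R, dtype=float)
    G = np.asarray(G, dtype=float)
    return R - G, (R + G) / 2.0


def channels_from_ma(M, A) -> tuple[np.ndarray, np.ndarray]:
    """Invert the M/A transform: R = A + M/2, G = A - M/2."""
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    return A + M / 2.0, A - M / 2.0


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def linkage_class(chromosome: str) -> str:
    """Map a chromosome arm label to ``X`` / ``autosome`` / ``excluded``.

    Chromosome 4 counts as autosomal; anything outside the euchromatic arms
    (heterochromatin, Y, mitochondrial, unmapped scaffolds) is excluded from
    linkage contrasts.
    """
    if chromosome == "X":
        return "X"
    if chromosome in AUTOSOME_ARMS:
        return "autosome"
    return "excluded"


def annotate_linkage(annot: pd.DataFrame) -> pd.DataFrame:
    """Add/refresh the derived ``linkage_class`` column."""
    annot = annot.copy()
    annot["linkage_class"] = annot["chromosome"].astype(str).map(linkage_class)
    return annot


def load_annotation(path, sep: str = "\t") -> pd.DataFrame:
    """Load a gene annotation table indexed by ``gene_id``.

    Requires ``gene_id`` and ``chromosome`` columns; ``age_class`` and
    ``unique_alignment`` are optional (missing ``unique_alignment`` defaults
    to true).  A ``linkage_class`` column is derived from the chromosome arm.
    """
    df = pd.read_csv(path, sep=sep, dtype={"gene_id": str})
    for col in ("gene_id", "chromosome"):
        if col not in df.columns:
            raise FormatError(f"annotation table missing required column {col!r}")
    if "unique_alignment" not in df.columns:
        df["unique_alignment"] = True
    else:
        df["unique_alignment"] = df["unique_alignment"].map(_as_bool)
    if "age_class" not in df.columns:
        df["age_class"] = pd.NA
    df = annotate_linkage(df)
    return df.set_index("gene_id")


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"1", "true", "t", "yes", "y"}
    return bool(v)


def write_annotation(annot: pd.DataFrame, path, sep: str = "\t") -> None:
    annot.reset_index().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Stage expression
# ---------------------------------------------------------------------------

@dataclass
class StageExpressionSet:
    """Gene x replicate matrix of A-values (log2) for one developmental stage."""

    stage_label: str
    matrix: pd.DataFrame  # index: gene_id, columns: rep01..repNN

    def __post_init__(self) -> None:
        self.matrix = self.matrix.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.matrix.shape[1]

    def validate(self) -> None:
        if self.matrix.isna().any().any():
            raise FormatError(f"stage {self.stage_label}: null A-values present")


def replicate_columns(n: int) -> list[str]:
    return [f"rep{i:02d}" for i in range(1, n + 1)]


def load_stage_expression(
    path,
    annot: pd.DataFrame | None = None,
    sep: str = "\t",
    stage_labels: Sequence[str] = STAGE_LABELS,
) -> dict[str, StageExpressionSet]:
    """Load per-stage expression sets, dropping rows with any null A-value.

    The exclusion is applied per stage: a gene dropped in one stage may remain
    in another.  Dropped-row counts are logged.  Unknown stage labels raise
    :class:`ConfigError`; if an annotation is supplied and shares no keys with
    the expression table, an error is raised (unannotated genes are otherwise
    only logged).
    """
    df = pd.read_csv(path, sep=sep, dtype={"gene_id": str, "stage": str})
    for col in ("gene_id", "stage"):
        if col not in df.columns:
            raise FormatError(f"expression table missing required column {col!r}")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols:
        raise FormatError("expression table has no replicate columns (rep01..)")

    unknown = set(df["stage"]) - set(stage_labels)
    if unknown:
        raise ConfigError(f"unknown stage label(s): {sorted(unknown)}")

    if annot is not None:
        known = set(df["gene_id"]) & set(annot.index)
        if not known:
            raise FormatError("no overlap between expression gene ids and annotation keys")
        n_unannot = df["gene_id"].nunique() - len(known)
        if n_unannot:
            logger.info("%d expression gene ids lack annotation", n_unannot)

    stages: dict[str, StageExpressionSet] = {}
    for stage, sub in df.groupby("stage", sort=False):
        mat = sub.set_index("gene_id")[rep_cols].astype(float)
        keep = mat.notna().all(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("stage %s: dropped %d rows with null A-values", stage, dropped)
        mat = mat.loc[keep]
        if mat.empty:
            raise FormatError(f"stage {stage}: all rows have null A-values")
        stages[stage] = StageExpressionSet(stage_label=str(stage), matrix=mat)
    return stages


def write_stage_expression(
    stages: Mapping[str, StageExpressionSet], path, sep: str = "\t"
) -> None:
    """Serialize stage sets back to the long TSV dialect (round-trip safe)."""
    frames = []
    for label, st in stages.items():
        sub = st.matrix.copy()
        sub.insert(0, "stage", label)
        frames.append(sub.reset_index())
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def xlsx_to_tsv(xlsx_path, tsv_path, sheet=0) -> None:
    """Thin converter from spreadsheet deposits to the canonical TSV dialect."""
    pd.read_excel(xlsx_path, sheet_name=sheet).to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tissue panel
# ---------------------------------------------------------------------------

@dataclass
class TissuePanel:
    """Per-gene tissue signals and present/absent calls.

    ``signals`` is a gene x tissue table of mean microarray signals (>= 0);
    ``calls`` is a gene x (tissue, replicate) boolean table with exactly
    ``n_calls`` replicate calls per tissue (four in FlyAtlas-style panels).
    """

    signals: pd.DataFrame  # index: gene_id, columns: tissue names
    calls: pd.DataFrame  # index: gene_id, columns: MultiIndex (tissue, rep)
    n_calls: int = 4

    def __post_init__(self) -> None:
        self.signals = self.signals.astype(float)
        if (self.signals.to_numpy() < 0).any():
            raise FormatError("tissue panel signals must be non-negative")
        for t in self.tissues:
            reps = self.calls[t].shape[1] if t in self.calls.columns.get_level_values(0) else 0
            if reps != self.n_calls:
                raise FormatError(
                    f"tissue {t!r}: expected {self.n_calls} call columns, found {reps}"
                )

    @property
    def tissues(self) -> list[str]:
        return list(self.signals.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.signals.index)

    @property
    def testis_signal(self) -> pd.Series:
        return self.signals["testis"]

    @property
    def ovary_signal(self) -> pd.Series:
        return self.signals["ovary"]


def _call_to_bool(v) -> bool:
    if isinstance(v, str):
        s = v.strip().upper()
        if s in {"P", "PRESENT", "1", "TRUE"}:
            return True
        if s in {"A", "ABSENT", "0", "FALSE"}:
            return False
        raise FormatError(f"unrecognized present/absent call {v!r}")
    return bool(v)


def load_tissue_panel(
    signal_path,
    call_path,
    annot: pd.DataFrame,
    sep: str = "\t",
    unique_only: bool = True,
    n_calls: int = 4,
) -> TissuePanel:
    """Assemble a gene-level panel from probe-level signal and call tables.

    Both tables are keyed by ``probe_id``; the annotation maps probes to gene
    ids and carries the uniqueness flag.  Probes aligning to multiple genome
    locations are discarded unless ``unique_only`` is false.  When several
    unique probes map to one gene, signals are averaged and the calls of the
    probe with the highest overall mean signal are used.
    """
    sig = pd.read_csv(signal_path, sep=sep, dtype={"probe_id": str})
    cal = pd.read_csv(call_path, sep=sep, dtype={"probe_id": str})
    for df, name in ((sig, "signal"), (cal, "call")):
        if "probe_id" not in df.columns:
            raise FormatError(f"{name} table missing 'probe_id' column")
    sig = sig.set_index("probe_id")
    cal = cal.set_index("probe_id")
    tissues = list(sig.columns)

    # schema check: exactly n_calls call columns per tissue
    call_cols: dict[str, list[str]] = {}
    for t in tissues:
        cols = [c for c in cal.columns if c.startswith(f"{t}_call")]
        if len(cols) != n_calls:
            raise FormatError(
                f"tissue {t!r}: expected {n_calls} call columns, found {len(cols)}"
            )
        call_cols[t] = sorted(cols)

    if "gene_id" not in annot.columns:
        raise FormatError("probe annotation must carry a 'gene_id' column")
    probes = annot.loc[annot.index.intersection(sig.index)].copy()
    n_before = len(probes)
    if unique_only:
        probes = probes[probes["unique_alignment"].astype(bool)]
        logger.info(
            "uniqueness filter: retained %d/%d probes", len(probes), n_before
        )
    if probes.empty:
        raise FormatError("no probes retained after uniqueness filter")

    sig = sig.loc[probes.index].astype(float)
    sig["gene_id"] = probes["gene_id"]
    gene_sig = sig.groupby("gene_id")[tissues].mean()

    # calls from the most intense probe per gene
    mean_sig = sig[tissues].mean(axis=1)
    best = (
        pd.DataFrame({"gene_id": probes["gene_id"], "s": mean_sig})
        .sort_values("s")
        .groupby("gene_id")
        .tail(1)
    )
    cal = cal.loc[best.index]
    data = {}
    for t in tissues:
        for i, col in enumerate(call_cols[t], start=1):
            data[(t, i)] = cal[col].map(_call_to_bool).to_numpy()
    gene_calls = pd.DataFrame(
        data, index=pd.Index(best["gene_id"], name="gene_id")
    )
    gene_calls.columns = pd.MultiIndex.from_tuples(gene_calls.columns)
    gene_calls = gene_calls.loc[gene_sig.index]
    logger.info("tissue panel assembled: %d genes, %d tissues", len(gene_sig), len(tissues))
    return TissuePanel(signals=gene_sig, calls=gene_calls, n_calls=n_calls)


def write_tissue_panel(panel: TissuePanel, signal_path, call_path, sep: str = "\t") -> None:
    """Write a gene-level panel as two TSVs (signals; P/A calls)."""
    panel.signals.reset_index().rename(columns={"index": "gene_id"}).to_csv(
        signal_path, sep=sep, index=False
    )
    flat = pd.DataFrame(index=panel.calls.index)
    for t in panel.signals.columns:
        for i in range(1, panel.n_calls + 1):
            flat[f"{t}_call{i}"] = np.where(panel.calls[(t, i)], "P", "A")
    flat.reset_index().to_csv(call_path, sep=sep, index=False)


def read_gene_tissue_panel(signal_path, call_path, sep: str = "\t", n_calls: int = 4) -> TissuePanel:
    """Read back a gene-level panel written by :func:`write_tissue_panel`."""
    sig = pd.read_csv(signal_path, sep=sep, dtype={"gene_id": str}).set_index("gene_id")
    cal = pd.read_csv(call_path, sep=sep, dtype={"gene_id": str}).set_index("gene_id")
    data = {}
    for t in sig.columns:
        cols = [c for c in cal.columns if c.startswith(f"{t}_call")]
        if len(cols) != n_calls:
            raise FormatError(f"tissue {t!r}: expected {n_calls} call columns, found {len(cols)}")
        for i, col in enumerate(sorted(cols), start=1):
            data[(t, i)] = cal[col].map(_call_to_bool).to_numpy()
    calls = pd.DataFrame(data, index=cal.index)
    calls.columns = pd.MultiIndex.from_tuples(calls.columns)
    return TissuePanel(signals=sig, calls=calls.loc[sig.index], n_calls=n_calls)
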