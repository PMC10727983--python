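"""Unit-level quantification tables and feature-level count matrices.

Reads per-sample quantification output in the ``quant.sf`` TSV dialect
(Name/Length/EffectiveLength/TPM/NumReads) and aggregates estimated read
counts onto catalog features: transcripts sum to their gene, repeat
instances sum to their subfamily.  Fractional counts from EM-based
quantifiers are preserved through aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .annotation import FeatureCatalog
from .features import wilcoxon_rank_sum

logger = logging.getLogger(__name__)

QUANT_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]

#: normalization states a count matrix can carry
MATRIX_STATES = ("raw", "normalized", "zscore", "log")


@dataclass
class QuantTable:
    """One sample's unit-level quantification (quant.sf dialect)."""

    sample_id: str
    table: pd.DataFrame  # indexed by unit id, columns Length/EffectiveLength/TPM/NumReads
    total_input_reads: float | None = None

    @property
    def num_reads(self) -> pd.Series:
        return self.table["NumReads"]


@dataclass
class CountMatrix:
    """Features x samples matrix with an explicit normalization state."""

    data: pd.DataFrame  # rows = feature ids, columns = sample ids
    state: str = "raw"

    def __post_init__(self):
        if self.state not in MATRIX_STATES:
            raise ValueError(f"unknown matrix state {self.state!r}")
        if self.state in ("raw", "normalized") and (self.data.values < 0).any():
            raise ValueError(f"negative entries in {self.state} count matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.data.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def read_tsv(cls, path: Union[str, Path], state: str = "raw") -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        return cls(df, state=state)


def read_quant(
    stream: Union[str, Path, IO[str]],
    sample_id: str | None = None,
    total_input_reads: float | None = None,
) -> QuantTable:
    """Read one quant.sf-dialect TSV.

    Requires the header Name/Length/EffectiveLength/TPM/NumReads; duplicated
    unit names and negative NumReads are errors.
    """
    if sample_id is None:
        sample_id = Path(str(stream)).parent.name or "sample"
    df = pd.read_csv(stream, sep="\t")
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"quant table missing columns {missing}")
    if df["Name"].duplicated().any():
        dups = df["Name"][df["Name"].duplicated()].unique()[:5]
        raise ValueError(f"duplicated unit names in quant table: {list(dups)}")
    for col in ("Length", "EffectiveLength", "TPM", "NumReads"):
        df[col] = pd.to_numeric(df[col])
    if (df["NumReads"] < 0).any():
        raise ValueError("negative NumReads in quant table")
    df = df.set_index("Name")
    return QuantTable(sample_id=sample_id, table=df, total_input_reads=total_input_reads)


def aggregate(
    tables: Iterable[QuantTable],
    catalog: FeatureCatalog | Mapping[str, str],
) -> tuple[CountMatrix, dict[str, set[str]]]:
    """Sum unit-level NumReads onto catalog features.

    Returns the raw-state matrix (every catalog feature present, zero-filled
    where unobserved) and the per-sample set of unit ids that could not be
    resolved through the unit->feature map (dropped with a warning).
    """
    if isinstance(catalog, FeatureCatalog):
        u2f = catalog.unit_to_feature
        all_features = catalog.feature_ids
    else:
        u2f = dict(catalog)
        all_features = sorted(set(u2f.values()))

    columns: dict[str, pd.Series] = {}
    unresolved: dict[str, set[str]] = {}
    for qt in tables:
        if qt.sample_id in columns:
            raise ValueError(f"duplicate sample_id {qt.sample_id!r} in aggregation")
        units = qt.table.index
        feat = units.map(u2f)
        known = feat.notna()
        missing_units = set(units[~known])
        if missing_units:
            logger.warning(
                "sample %s: %d units absent from catalog, dropped", qt.sample_id, len(missing_units)
            )
        unresolved[qt.sample_id] = missing_units
        sums = qt.table.loc[known, "NumReads"].groupby(feat[known]).sum()
        columns[qt.sample_id] = sums
    mat = pd.DataFrame(columns).reindex(all_features).fillna(0.0)
    mat.index.name = "feature_id"
    return CountMatrix(mat, state="raw"), unresolved


def mapping_rate(assigned_reads: float, total_input_reads: float) -> float:
    """Fraction of input reads assigned by quantification."""
    if total_input_reads <= 0:
        raise ValueError("total_input_reads must be positive")
    # fractional multi-hit splitting can overshoot by float rounding only
    if assigned_reads > total_input_reads * (1 + 1e-9):
        raise ValueError(
            f"assigned reads ({assigned_reads}) exceed total input reads ({total_input_reads})"
        )
    return min(assigned_reads / total_input_reads, 1.0)


def mapping_rate_table(tables: Iterable[QuantTable]) -> pd.DataFrame:
    """Per-sample mapping rates from quant tables carrying total_input_reads."""
    rows = []
    for qt in tables:
        if qt.total_input_reads is None:
            raise ValueError(f"sample {qt.sample_id}: total_input_reads unknown")
        assigned = float(qt.num_reads.sum())
        rows.append(
            {
                "sample_id": qt.sample_id,
                "assigned": assigned,
                "total": qt.total_input_reads,
                "mapping_rate": mapping_rate(assigned, qt.total_input_reads),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def compare_mapping_rates(naive: pd.Series, aware: pd.Series) -> dict:
    """Paired two-sided signed-rank comparison of per-sample mapping rates.

    ``naive`` and ``aware`` are indexed by sample id; samples must match.
    """
    naive, aware = naive.align(aware, join="inner")
    if len(naive) == 0:
        raise ValueError("no shared samples between the two mapping-rate series")
    stat, p = wilcoxon_rank_sum(aware.values, naive.values, paired=True)
    return {
        "n": int(len(naive)),
        "median_naive": float(naive.median()),
        "median_aware": float(aware.median()),
        "median_gain": float((aware - naive).median()),
        "statistic": stat,
        "p_value": p,
    }
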