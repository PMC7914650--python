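"""Differential-expression candidate selection.

Classifies per-gene DE summaries (log2 fold change, BH-adjusted p, mean
abundance in reads per million) as up/down/not-significant and applies the
candidate-selection thresholds and expression floors used for network seeding.

Two named presets encode the selection criteria for the two biotypes:

* miRNA: ``|log2FC| > 1``, adjusted p < 0.05, mean abundance > 4 RPM
* mRNA:  ``|log2FC| > 1.5``, adjusted p < 0.01, mean abundance > 0.7 RPM

Abundance is compared against the floor in each condition separately; a gene
is removed only when it is below the floor in *both* conditions (``either``
mode, the default), since low expression in a single condition is compatible
with strong regulation.  A ``mean`` mode comparing the cross-condition mean
is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

logger = logging.getLogger(__name__)

Direction = Literal["up", "down", "not_significant"]

DE_TABLE_COLUMNS = [
    "gene_id",
    "biotype",
    "log2fc",
    "p_adj",
    "mean_rpm_untreated",
    "mean_rpm_treated",
]


@dataclass(frozen=True)
class DifferentialExpressionRecord:
    """One gene's DE summary (treated vs untreated, log2 scale)."""

    gene_id: str
    biotype: Literal["miRNA", "protein_coding"]
    log2fc: float
    p_adj: float | None
    mean_rpm_untreated: float
    mean_rpm_treated: float

    def __post_init__(self) -> None:
        if self.p_adj is not None and not math.isnan(self.p_adj):
            if not 0.0 <= self.p_adj <= 1.0:
                raise ValueError(f"p_adj out of [0,1]: {self.p_adj!r}")
        if self.mean_rpm_untreated < 0 or self.mean_rpm_treated < 0:
            raise ValueError("abundances must be non-negative")


@dataclass(frozen=True)
class SelectionThresholds:
    """Thresholds for DE candidate selection.

    boundary_mode="strict" uses strict inequalities on the fold-change cut
    (|log2FC| > cut); "inclusive" uses |log2FC| >= cut.  The adjusted-p cut
    and the abundance floor are always strict (< and > respectively).
    floor_mode decides whether the abundance floor must be exceeded in either
    condition ("either", default) or by the cross-condition mean ("mean").
    """

    log2fc_cut: float
    p_adj_cut: float
    rpm_floor: float
    boundary_mode: Literal["strict", "inclusive"] = "strict"
    floor_mode: Literal["either", "mean"] = "either"

    def __post_init__(self) -> None:
        if self.log2fc_cut <= 0:
            raise ValueError("log2fc_cut must be positive")
        if not 0.0 < self.p_adj_cut < 1.0:
            raise ValueError("p_adj_cut must be in (0,1)")
        if self.rpm_floor < 0:
            raise ValueError("rpm_floor must be non-negative")


#: Selection presets for the two biotypes.
PRESETS: dict[str, SelectionThresholds] = {
    "mirna": SelectionThresholds(log2fc_cut=1.0, p_adj_cut=0.05, rpm_floor=4.0),
    "mrna": SelectionThresholds(log2fc_cut=1.5, p_adj_cut=0.01, rpm_floor=0.7),
}


def classify_de(
    record: DifferentialExpressionRecord, thresholds: SelectionThresholds
) -> Direction:
    """Classify a DE record as up / down / not_significant.

    A record missing its adjusted p-value is never called significant.
    """
    p = record.p_adj
    if p is None or (isinstance(p, float) and math.isnan(p)):
        logger.warning("record %s lacks p_adj; treated as not significant", record.gene_id)
        return "not_significant"
    if p >= thresholds.p_adj_cut:
        return "not_significant"
    fc, cut = record.log2fc, thresholds.log2fc_cut
    if thresholds.boundary_mode == "inclusive":
        if fc >= cut:
            return "up"
        if fc <= -cut:
            return "down"
    else:
        if fc > cut:
            return "up"
        if fc < -cut:
            return "down"
    return "not_significant"


def passes_floor(
    record: DifferentialExpressionRecord, thresholds: SelectionThresholds
) -> bool:
    """True if the record's abundance clears the expression floor."""
    if thresholds.floor_mode == "mean":
        mean = 0.5 * (record.mean_rpm_untreated + record.mean_rpm_treated)
        return mean > thresholds.rpm_floor
    return (
        max(record.mean_rpm_untreated, record.mean_rpm_treated) > thresholds.rpm_floor
    )


def select_candidates(
    records: Iterable[DifferentialExpressionRecord],
    thresholds: SelectionThresholds,
) -> list[DifferentialExpressionRecord]:
    """Retain significantly regulated records above the expression floor.

    Input order is preserved; an empty input yields an empty output.
    """
    return [
        r
        for r in records
        if classify_de(r, thresholds) != "not_significant" and passes_floor(r, thresholds)
    ]


def direction_map(
    records: Iterable[DifferentialExpressionRecord],
    thresholds: SelectionThresholds,
) -> dict[str, Direction]:
    """gene_id -> direction for every record in the table."""
    return {r.gene_id: classify_de(r, thresholds) for r in records}


# ---------------------------------------------------------------------------
# TSV I/O


def records_to_frame(records: Iterable[DifferentialExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.gene_id,
                r.biotype,
                r.log2fc,
                r.p_adj if r.p_adj is not None else float("nan"),
                r.mean_rpm_untreated,
                r.mean_rpm_treated,
            )
            for r in records
        ],
        columns=DE_TABLE_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[DifferentialExpressionRecord]:
    missing = set(DE_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if frame["gene_id"].duplicated().any():
        dupes = frame.loc[frame["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in DE table: {dupes[:5]}")
    out = []
    for row in frame.itertuples(index=False):
        p = float(row.p_adj)
        out.append(
            DifferentialExpressionRecord(
                gene_id=str(row.gene_id),
                biotype=str(row.biotype),  # type: ignore[arg-type]
                log2fc=float(row.log2fc),
                p_adj=None if math.isnan(p) else p,
                mean_rpm_untreated=float(row.mean_rpm_untreated),
                mean_rpm_treated=float(row.mean_rpm_treated),
            )
        )
    return out


def read_de_table(path) -> list[DifferentialExpressionRecord]:
    """Read a DE result table from TSV."""
    return frame_to_records(pd.read_csv(path, sep="\t"))


def write_de_table(records: Iterable[DifferentialExpressionRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.10g")
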