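"""Consensus miRNA-target aggregation and anti-correlation filtering.

Per-source miRNA-target predictions are admitted under each source's native
score convention, then aggregated into consensus interactions supported by at
least two distinct sources.  Interactions are annotated with the DE direction
of both partners and filtered to those whose directions anti-correlate, the
expression pattern expected when a miRNA degrades its target.

Source score conventions and cut-offs:

========== ======================= ====================
source      score convention        passing rule
========== ======================= ====================
targetscan  total context++ score   score <= -0.3
mirdb       prediction score 0-100  score >= 85
microt_cds  miTG score 0-1          score >= 0.95
mirtarbase  validation tier         tier == strong_validated
mirecords   validation tier         tier == strong_validated
========== ======================= ====================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PREDICTION_SOURCES = ("targetscan", "mirdb", "microt_cds")
VALIDATION_SOURCES = ("mirtarbase", "mirecords")
ALL_SOURCES = PREDICTION_SOURCES + VALIDATION_SOURCES

PREDICTION_TABLE_COLUMNS = ["mirna_id", "gene_id", "source", "score", "evidence_tier"]


@dataclass(frozen=True)
class TargetPrediction:
    """A single-source miRNA -> gene prediction.

    miRNA ids are mature-arm resolved (-5p/-3p); arms are distinct
    identifiers and are never collapsed to precursor names.
    """

    mirna_id: str
    gene_id: str
    source: str
    score: float | None = None
    evidence_tier: Literal["predicted", "strong_validated"] = "predicted"

    def __post_init__(self) -> None:
        if self.source in PREDICTION_SOURCES and self.score is None:
            raise ValueError(f"{self.source} prediction requires a score")


@dataclass
class ConsensusInteraction:
    """A miRNA-target pair supported by >= 2 distinct sources."""

    mirna_id: str
    gene_id: str
    supporting_sources: frozenset[str]
    validated: bool
    mirna_direction: Literal["up", "down"]
    gene_direction: Literal["up", "down"]
    provenance: str = ""  # free-text annotation, e.g. literature validation

    @property
    def n_sources(self) -> int:
        return len(self.supporting_sources)

    @property
    def anti_correlated(self) -> bool:
        return self.mirna_direction != self.gene_direction


def apply_source_threshold(prediction: TargetPrediction) -> bool:
    """Whether a prediction clears its source's cut-off."""
    src = prediction.source
    if src == "targetscan":
        return prediction.score is not None and prediction.score <= -0.3
    if src == "mirdb":
        return prediction.score is not None and prediction.score >= 85
    if src == "microt_cds":
        return prediction.score is not None and prediction.score >= 0.95
    if src in VALIDATION_SOURCES:
        return prediction.evidence_tier == "strong_validated"
    raise ValueError(f"unknown prediction source: {src!r}")


def build_consensus(
    predictions: Iterable[TargetPrediction],
    de_mirna: dict[str, str],
    de_mrna: dict[str, str],
    min_sources: int = 2,
    prediction_sources_only: bool = False,
) -> list[ConsensusInteraction]:
    """Aggregate predictions into multi-source consensus interactions.

    Parameters
    ----------
    predictions
        Per-source predictions; duplicates from one source for one pair
        count once toward the source tally.
    de_mirna, de_mrna
        gene_id -> direction ("up"/"down"/"not_significant") lookup from the
        classified DE tables.  Pairs whose miRNA or gene is absent, or not
        significantly regulated, are dropped (logged).
    min_sources
        Minimum number of distinct supporting sources (default 2).
    prediction_sources_only
        If True, require ``min_sources`` among prediction programs alone;
        by default any two distinct sources (prediction or validation)
        satisfy the rule.
    """
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    by_pair: dict[tuple[str, str], set[str]] = {}
    for pred in predictions:
        if apply_source_threshold(pred):
            by_pair.setdefault((pred.mirna_id, pred.gene_id), set()).add(pred.source)
    out: list[ConsensusInteraction] = []
    n_dropped = 0
    for (mirna, gene), sources in sorted(by_pair.items()):
        counted = (
            {s for s in sources if s in PREDICTION_SOURCES}
            if prediction_sources_only
            else sources
        )
        if len(counted) < min_sources:
            continue
        mdir = de_mirna.get(mirna)
        gdir = de_mrna.get(gene)
        if mdir not in ("up", "down") or gdir not in ("up", "down"):
            n_dropped += 1
            continue
        out.append(
            ConsensusInteraction(
                mirna_id=mirna,
                gene_id=gene,
                supporting_sources=frozenset(sources),
                validated=any(s in VALIDATION_SOURCES for s in sources),
                mirna_direction=mdir,
                gene_direction=gdir,
            )
        )
    if n_dropped:
        logger.info("dropped %d consensus pairs lacking DE directions", n_dropped)
    return out


def anticorrelation_filter(
    interactions: Iterable[ConsensusInteraction],
) -> list[ConsensusInteraction]:
    """Retain interactions whose miRNA and gene DE directions are opposite."""
    return [ia for ia in interactions if ia.anti_correlated]


def restrict_to_gene_set(
    interactions: Iterable[ConsensusInteraction], gene_set: set[str]
) -> list[ConsensusInteraction]:
    """Retain interactions whose target gene belongs to ``gene_set``.

    An empty gene set is rejected so that "no annotation supplied" cannot be
    mistaken for "nothing passed".
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    return [ia for ia in interactions if ia.gene_id in gene_set]


# ---------------------------------------------------------------------------
# TSV I/O


def read_predictions(path) -> list[TargetPrediction]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(PREDICTION_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        score = float(row.score) if pd.notna(row.score) else None
        out.append(
            TargetPrediction(
                mirna_id=str(row.mirna_id),
                gene_id=str(row.gene_id),
                source=str(row.source),
                score=score,
                evidence_tier=str(row.evidence_tier),  # type: ignore[arg-type]
            )
        )
    return out


def write_predictions(predictions: Sequence[TargetPrediction], path) -> None:
    pd.DataFrame(
        [
            (p.mirna_id, p.gene_id, p.source, p.score, p.evidence_tier)
            for p in predictions
        ],
        columns=PREDICTION_TABLE_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def interactions_to_frame(interactions: Iterable[ConsensusInteraction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                ia.mirna_id,
                ia.mirna_direction,
                ia.gene_id,
                ia.gene_direction,
                ",".join(sorted(ia.supporting_sources)),
                ia.n_sources,
                ia.validated,
                ia.anti_correlated,
            )
            for ia in interactions
        ],
        columns=[
            "mirna_id",
            "mirna_direction",
            "gene_id",
            "gene_direction",
            "sources",
            "n_sources",
            "validated",
            "anti_correlated",
        ],
    )


def write_interactions(interactions: Sequence[ConsensusInteraction], path) -> None:
    interactions_to_frame(interactions).to_csv(path, sep="\t", index=False)
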