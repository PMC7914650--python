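"""Over-representation analysis and regulator-target direction concordance.

Enrichment is the upper-tail hypergeometric test of the overlap between a
query gene list and each annotated gene set, followed by Benjamini-Hochberg
correction across sets.  Regulator concordance summarizes how consistently a
transcription factor's targets move with (activator) or against (repressor)
the regulator's own DE direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_id: str
    set_name: str
    universe_size: int
    set_size: int
    query_size: int
    overlap: int
    p_value: float
    q_value: float | None
    overlapping_ids: list[str]


def hypergeometric_enrichment(
    query: set[str],
    gene_sets: Mapping[str, Sequence[str]] | Mapping[str, set[str]],
    universe: set[str],
    set_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric ORA of a query list against gene sets.

    ``p = P[overlap >= observed]`` under sampling ``|query|`` genes from the
    universe without replacement.  Query ids outside the universe are dropped
    with a warning; set members outside the universe are ignored.  Results
    are BH-corrected and sorted by p ascending (set id breaking ties).
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    stray = query - universe
    if stray:
        logger.warning("%d query ids outside universe dropped", len(stray))
    query_in = query & universe
    results: list[EnrichmentResult] = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & universe
        overlap_ids = sorted(query_in & members)
        k, m, n, big_n = len(overlap_ids), len(universe), len(members), len(query_in)
        # P[X >= k] for X ~ Hypergeom(M=m, n=n, N=big_n)
        p = float(hypergeom.sf(k - 1, m, n, big_n)) if k > 0 else 1.0
        results.append(
            EnrichmentResult(
                set_id=set_id,
                set_name=(set_names or {}).get(set_id, set_id),
                universe_size=m,
                set_size=n,
                query_size=big_n,
                overlap=k,
                p_value=min(p, 1.0),
                q_value=None,
                overlapping_ids=overlap_ids,
            )
        )
    qs = bh_adjust([r.p_value for r in results]) if results else []
    for r, q in zip(results, qs):
        r.q_value = q
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def regulator_concordance(
    regulator_direction: Literal["up", "down"],
    target_directions: Sequence[Literal["up", "down"]],
    mode: Literal["activator", "repressor"] = "activator",
) -> tuple[float, str]:
    """Fraction of targets moving as the regulator's direction predicts.

    An activator's targets are expected to share the regulator's direction;
    a repressor's targets are expected to oppose it.  Returns the fraction
    and the raw count as ``"k/n"``.
    """
    if not target_directions:
        raise ValueError("target_directions must be non-empty")
    if regulator_direction not in ("up", "down"):
        raise ValueError(f"bad regulator direction: {regulator_direction!r}")
    expected = (
        regulator_direction
        if mode == "activator"
        else ("down" if regulator_direction == "up" else "up")
    )
    k = sum(1 for d in target_directions if d == expected)
    n = len(target_directions)
    return k / n, f"{k}/{n}"


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Parse a GMT file -> (set_id -> members, set_id -> description)."""
    sets: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line needs id, description, >=1 member: {line!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
        names[parts[0]] = parts[1]
    return sets, names


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path, descriptions=None) -> None:
    lines = []
    for set_id in gene_sets:
        desc = (descriptions or {}).get(set_id, set_id)
        lines.append("\t".join([set_id, desc, *gene_sets[set_id]]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_enrichment_results(results: Iterable[EnrichmentResult], path) -> None:
    lines = [
        "set_id\tset_name\tuniverse_size\tset_size\tquery_size\toverlap"
        "\tp_value\tq_value\toverlapping_ids"
    ]
    for r in results:
        lines.append(
            f"{r.set_id}\t{r.set_name}\t{r.universe_size}\t{r.set_size}"
            f"\t{r.query_size}\t{r.overlap}\t{r.p_value:.6g}\t{r.q_value:.6g}"
            f"\t{','.join(r.overlapping_ids)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
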