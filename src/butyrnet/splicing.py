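"""Simplified differential-splicing summarizer.

Per-replicate percent-spliced-in (PSI = inclusion / (inclusion + skipping)),
between-condition delta-PSI, a two-proportion test on pooled counts with BH
correction across events, and an event-type breakdown of the flagged calls.

This is an explicit simplified stand-in for replicate-aware splicing models:
the significance test pools replicate counts per condition and applies a
chi-square test (Fisher's exact when an expected cell count is below 5).
Inclusion counts are assumed pre-normalized for junction form length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, fisher_exact

from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "RI", "MXE", "A5SS", "A3SS")


@dataclass
class SplicingEvent:
    """A typed splicing event with replicate counts in two conditions."""

    event_id: str
    gene_id: str
    event_type: Literal["SE", "RI", "MXE", "A5SS", "A3SS"]
    inclusion_untreated: list[int]
    skipping_untreated: list[int]
    inclusion_treated: list[int]
    skipping_treated: list[int]
    p_value: float | None = None
    fdr: float | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type: {self.event_type!r}")
        for counts in (
            self.inclusion_untreated,
            self.skipping_untreated,
            self.inclusion_treated,
            self.skipping_treated,
        ):
            if any(c < 0 for c in counts):
                raise ValueError("counts must be non-negative")

    def psi_replicates(self, condition: Literal["untreated", "treated"]) -> list[float]:
        """Per-replicate PSI; zero-coverage replicates yield NaN."""
        inc = getattr(self, f"inclusion_{condition}")
        skip = getattr(self, f"skipping_{condition}")
        return [
            compute_psi(i, s) if i + s > 0 else float("nan")
            for i, s in zip(inc, skip)
        ]

    def mean_psi(self, condition: Literal["untreated", "treated"]) -> float:
        vals = [v for v in self.psi_replicates(condition) if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def delta_psi(self) -> float:
        """Treated minus untreated mean PSI."""
        return self.mean_psi("treated") - self.mean_psi("untreated")


def compute_psi(inclusion: int, skipping: int) -> float:
    """PSI = inclusion / (inclusion + skipping); requires nonzero coverage."""
    total = inclusion + skipping
    if total <= 0:
        raise ValueError("PSI undefined at zero coverage")
    return inclusion / total


def _pooled_counts(event: SplicingEvent) -> tuple[int, int, int, int]:
    return (
        sum(event.inclusion_untreated),
        sum(event.skipping_untreated),
        sum(event.inclusion_treated),
        sum(event.skipping_treated),
    )


def two_proportion_p(i1: int, s1: int, i2: int, s2: int) -> float:
    """Two-sided p for differing inclusion proportions on pooled counts.

    Chi-square with Yates continuity correction; Fisher's exact test when
    any expected cell count is below 5.  Equivalent to
    ``scipy.stats.chi2_contingency`` on the 2x2 table in the chi-square
    regime (asserted in the test suite).
    """
    n1, n2 = i1 + s1, i2 + s2
    if n1 == 0 or n2 == 0:
        raise ValueError("both conditions need nonzero pooled coverage")
    total = n1 + n2
    inc, skip = i1 + i2, s1 + s2
    if inc == 0 or skip == 0:
        return 1.0
    expected = np.array(
        [[n1 * inc, n1 * skip], [n2 * inc, n2 * skip]], dtype=float
    ) / total
    if expected.min() < 5:
        return float(fisher_exact([[i1, s1], [i2, s2]])[1])
    observed = np.array([[i1, s1], [i2, s2]], dtype=float)
    stat = float(((np.abs(observed - expected) - 0.5) ** 2 / expected).sum())
    return float(chi2.sf(stat, df=1))


def test_differential_splicing(
    events: Sequence[SplicingEvent],
    alpha_fdr: float = 0.05,
    min_delta_psi: float = 0.1,
    criteria_mode: Literal["and", "or"] = "and",
) -> list[SplicingEvent]:
    """Flag differentially spliced events.

    Pools replicate counts per condition, tests the inclusion proportion,
    BH-corrects across events, and flags events with ``fdr < alpha_fdr``
    AND ``|delta_psi| >= min_delta_psi`` (OR mode available).  Events with
    zero pooled coverage in a condition are excluded and logged.  Events are
    mutated in place (p_value/fdr/flagged) and the testable subset returned.
    """
    if not 0.0 < alpha_fdr < 1.0:
        raise ValueError("alpha_fdr must be in (0,1)")
    testable: list[SplicingEvent] = []
    n_skipped = 0
    for ev in events:
        i1, s1, i2, s2 = _pooled_counts(ev)
        if i1 + s1 == 0 or i2 + s2 == 0:
            n_skipped += 1
            continue
        ev.p_value = two_proportion_p(i1, s1, i2, s2)
        testable.append(ev)
    if n_skipped:
        logger.info("%d events excluded for zero coverage in a condition", n_skipped)
    if not testable:
        return []
    fdrs = bh_adjust([ev.p_value for ev in testable])
    for ev, q in zip(testable, fdrs):
        ev.fdr = q
        sig = q < alpha_fdr
        big = abs(ev.delta_psi) >= min_delta_psi
        ev.flagged = (sig and big) if criteria_mode == "and" else (sig or big)
    return testable


def summarize_event_types(flagged_events: Iterable[SplicingEvent]) -> dict[str, float]:
    """Percentage of flagged events per type; sums to 100 for non-empty input."""
    counts = {t: 0 for t in EVENT_TYPES}
    total = 0
    for ev in flagged_events:
        counts[ev.event_type] += 1
        total += 1
    if total == 0:
        return {}
    return {t: 100.0 * c / total for t, c in counts.items()}


# ---------------------------------------------------------------------------
# TSV I/O  (wide table: inc/skip per condition per replicate)


def events_to_frame(events: Sequence[SplicingEvent]) -> pd.DataFrame:
    if not events:
        return pd.DataFrame()
    n_reps = len(events[0].inclusion_untreated)
    cols = ["event_id", "gene_id", "event_type"]
    for cond in ("c1", "c2"):
        for r in range(1, n_reps + 1):
            cols += [f"inc_{cond}_r{r}", f"skip_{cond}_r{r}"]
    rows = []
    for ev in events:
        row = [ev.event_id, ev.gene_id, ev.event_type]
        for r in range(n_reps):
            row += [ev.inclusion_untreated[r], ev.skipping_untreated[r]]
        for r in range(n_reps):
            row += [ev.inclusion_treated[r], ev.skipping_treated[r]]
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def frame_to_events(frame: pd.DataFrame) -> list[SplicingEvent]:
    inc_c1 = sorted(c for c in frame.columns if c.startswith("inc_c1_"))
    skip_c1 = sorted(c for c in frame.columns if c.startswith("skip_c1_"))
    inc_c2 = sorted(c for c in frame.columns if c.startswith("inc_c2_"))
    skip_c2 = sorted(c for c in frame.columns if c.startswith("skip_c2_"))
    if not inc_c1 or len(inc_c1) != len(skip_c1) or len(inc_c2) != len(skip_c2):
        raise ValueError("malformed splicing count table")
    out = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        out.append(
            SplicingEvent(
                event_id=str(d["event_id"]),
                gene_id=str(d["gene_id"]),
                event_type=str(d["event_type"]),  # type: ignore[arg-type]
                inclusion_untreated=[int(d[c]) for c in inc_c1],
                skipping_untreated=[int(d[c]) for c in skip_c1],
                inclusion_treated=[int(d[c]) for c in inc_c2],
                skipping_treated=[int(d[c]) for c in skip_c2],
            )
        )
    return out


def read_event_table(path) -> list[SplicingEvent]:
    return frame_to_events(pd.read_csv(path, sep="\t"))


def write_event_table(events: Sequence[SplicingEvent], path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def write_splicing_results(events: Sequence[SplicingEvent], path) -> None:
    frame = pd.DataFrame(
        [
            (
                ev.event_id,
                ev.gene_id,
                ev.event_type,
                ev.mean_psi("untreated"),
                ev.mean_psi("treated"),
                ev.delta_psi,
                ev.p_value,
                ev.fdr,
                ev.flagged,
            )
            for ev in events
        ],
        columns=[
            "event_id",
            "gene_id",
            "event_type",
            "psi_untreated",
            "psi_treated",
            "delta_psi",
            "p_value",
            "fdr",
            "flagged",
        ],
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
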