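"""Coefficient of drug interaction (CDI) for two-treatment combinations.

Replicate readouts for a negative control, each mono-treatment and the
combination are reduced to control-normalized effect ratios

    A  = mean(treatment A) / mean(control)
    B  = mean(treatment B) / mean(control)
    AB = mean(combination) / mean(control)

and the interaction statistic CDI = AB / (A x B).  CDI below 1 indicates
synergy (below 0.7, significant synergy), 1 additivity, above 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

CdiClass = Literal[
    "significantly_synergistic", "synergistic", "additive", "antagonistic"
]

SIGNIFICANT_SYNERGY_CUT = 0.7


def normalize_to_control(
    readouts: Sequence[float],
    control_readouts: Sequence[float],
    mean_type: Literal["arithmetic", "geometric"] = "arithmetic",
) -> float:
    """Mean readout as a ratio to the mean control readout."""
    if len(readouts) == 0 or len(control_readouts) == 0:
        raise ValueError("readout lists must be non-empty")
    if mean_type == "geometric":
        x = np.asarray(readouts, dtype=float)
        c = np.asarray(control_readouts, dtype=float)
        if np.any(x <= 0) or np.any(c <= 0):
            raise ValueError("geometric mean requires positive readouts")
        return float(np.exp(np.mean(np.log(x)) - np.mean(np.log(c))))
    control_mean = float(np.mean(control_readouts))
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return float(np.mean(readouts)) / control_mean


def compute_cdi(ratio_a: float, ratio_b: float, ratio_ab: float) -> float:
    """CDI = AB / (A x B)."""
    if ratio_a <= 0 or ratio_b <= 0 or ratio_ab <= 0:
        raise ValueError("effect ratios must be positive")
    return ratio_ab / (ratio_a * ratio_b)


def classify_cdi(cdi: float, additive_tol: float = 1e-9) -> CdiClass:
    """Band a CDI value into the interaction classes.

    Exact additivity at CDI = 1 is tested within ``additive_tol`` since
    float equality is meaningless on measured ratios.
    """
    if cdi <= 0:
        raise ValueError("CDI must be positive")
    if abs(cdi - 1.0) <= additive_tol:
        return "additive"
    if cdi < SIGNIFICANT_SYNERGY_CUT:
        return "significantly_synergistic"
    if cdi < 1.0:
        return "synergistic"
    return "antagonistic"


@dataclass
class SynergyMeasurement:
    """Replicate readouts for the four conditions, with derived ratios."""

    control_readouts: list[float]
    a_readouts: list[float]
    b_readouts: list[float]
    ab_readouts: list[float]
    mean_type: Literal["arithmetic", "geometric"] = "arithmetic"

    @property
    def ratio_a(self) -> float:
        return normalize_to_control(self.a_readouts, self.control_readouts, self.mean_type)

    @property
    def ratio_b(self) -> float:
        return normalize_to_control(self.b_readouts, self.control_readouts, self.mean_type)

    @property
    def ratio_ab(self) -> float:
        return normalize_to_control(self.ab_readouts, self.control_readouts, self.mean_type)

    @property
    def cdi(self) -> float:
        return compute_cdi(self.ratio_a, self.ratio_b, self.ratio_ab)

    @property
    def classification(self) -> CdiClass:
        return classify_cdi(self.cdi)

    def bootstrap_ci(
        self, n_draws: int = 2000, alpha: float = 0.05, seed: int | None = None
    ) -> tuple[float, float]:
        """Percentile bootstrap CI on the CDI by resampling replicates.

        An uncertainty extension beyond the point statistic itself.
        """
        rng = np.random.default_rng(seed)
        groups = [
            np.asarray(g, dtype=float)
            for g in (self.control_readouts, self.a_readouts, self.b_readouts, self.ab_readouts)
        ]
        draws = np.empty(n_draws)
        for i in range(n_draws):
            c, a, b, ab = (rng.choice(g, size=g.size, replace=True) for g in groups)
            cm = c.mean()
            draws[i] = (ab.mean() / cm) / ((a.mean() / cm) * (b.mean() / cm))
        lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)


def read_readout_table(path) -> SynergyMeasurement:
    """Read a long-format readout TSV: ``condition  replicate  value``."""
    frame = pd.read_csv(path, sep="\t")
    needed = {"condition", "replicate", "value"}
    if not needed <= set(frame.columns):
        raise ValueError(f"readout table needs columns {sorted(needed)}")
    groups = {
        cond: frame.loc[frame["condition"] == cond, "value"].astype(float).tolist()
        for cond in ("control", "a", "b", "ab")
    }
    empty = [c for c, v in groups.items() if not v]
    if empty:
        raise ValueError(f"no readouts for condition(s): {empty}")
    return SynergyMeasurement(
        control_readouts=groups["control"],
        a_readouts=groups["a"],
        b_readouts=groups["b"],
        ab_readouts=groups["ab"],
    )


def write_readout_table(measurement: SynergyMeasurement, path) -> None:
    rows = []
    for cond, vals in (
        ("control", measurement.control_readouts),
        ("a", measurement.a_readouts),
        ("b", measurement.b_readouts),
        ("ab", measurement.ab_readouts),
    ):
        rows.extend((cond, i + 1, v) for i, v in enumerate(vals))
    pd.DataFrame(rows, columns=["condition", "replicate", "value"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_synergy_summary(measurement: SynergyMeasurement, path) -> None:
    Path(path).write_text(
        "ratio_a\tratio_b\tratio_ab\tcdi\tclassification\n"
        f"{measurement.ratio_a:.6g}\t{measurement.ratio_b:.6g}"
        f"\t{measurement.ratio_ab:.6g}\t{measurement.cdi:.6g}"
        f"\t{measurement.classification}\n"
    )
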