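"""Synthetic-data generation with planted ground truth.

Generates every input the analysis pipeline consumes — DE result tables,
per-source miRNA-target prediction tables, a scale-free interactome, gene
sets, splicing-event count tables and combination-readout tables — from one
:class:`SimulationConfig`, together with a :class:`PlantedTruth` record of
what was planted.  All randomness flows from the config seed through named
substreams, so identical (config, seed) pairs are bit-identical and adding
one generator call never perturbs another.

The generative choices (uniform null p-values, truncated-normal source
scores straddling each cut-off, Poisson coverage with binomial inclusion
draws, mean-one lognormal readout noise) are stand-ins for distributions no
real dataset pins down; see docs/methods.md for what they do and do not
emulate.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np

from .consensus import (
    PREDICTION_SOURCES,
    VALIDATION_SOURCES,
    TargetPrediction,
)
from .de import PRESETS, DifferentialExpressionRecord, SelectionThresholds
from .splicing import EVENT_TYPES, SplicingEvent
from .synergy import SynergyMeasurement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the analysed system: a few hundred miRNAs and a couple
    of thousand protein-coding genes with ~10% regulated at strong effect
    sizes, 24 planted regulatory pairs, a skipped-exon-dominated (60.3%)
    splicing event mix, delta-PSI 0.4 at ~100x event coverage, and a
    significantly synergistic combination (true CDI 0.63, mono-treatment
    effects 0.5 and 0.7) read out in quadruplicate at 10% CV.
    """

    seed: int = 0
    n_mirna: int = 300
    n_mrna: int = 2000
    frac_regulated: float = 0.1
    effect_log2fc: float = 2.5
    n_planted_pairs: int = 24
    n_decoy_predictions: int = 200
    interactome_size: int = 500
    attachment_degree: int = 2
    n_gene_sets: int = 20
    set_size_range: tuple[int, int] = (10, 50)
    n_splicing_events: int = 2000
    event_type_mix: tuple[float, float, float, float, float] = (
        0.603,
        0.1,
        0.1,
        0.1,
        0.097,
    )
    planted_delta_psi: float = 0.4
    coverage_mean: float = 100.0
    true_cdi: float = 0.63
    readout_cv: float = 0.1
    n_replicates: int = 4
    # secondary knobs the generator posts require
    frac_subfloor: float = 0.1  # regulated genes planted below the RPM floor
    frac_validated_pairs: float = 0.3
    frac_splicing_regulated: float = 0.05
    effect_a: float = 0.5
    effect_b: float = 0.7
    strict_null: bool = False  # null p-values pinned to 1 for exact-zero tests

    def __post_init__(self) -> None:
        for name in ("frac_regulated", "frac_subfloor", "frac_validated_pairs",
                     "frac_splicing_regulated", "readout_cv"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if len(self.event_type_mix) != len(EVENT_TYPES):
            raise ValueError("event_type_mix needs one fraction per event type")
        if any(f < 0 for f in self.event_type_mix):
            raise ValueError("event_type_mix fractions must be non-negative")
        if abs(sum(self.event_type_mix) - 1.0) > 1e-9:
            raise ValueError("event_type_mix must sum to 1 within 1e-9")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be positive")
        if not -1.0 <= self.planted_delta_psi <= 1.0:
            raise ValueError("planted_delta_psi must be in [-1,1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.true_cdi <= 0 or self.effect_a <= 0 or self.effect_b <= 0:
            raise ValueError("true_cdi and mono-treatment effects must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.attachment_degree < 1:
            raise ValueError("attachment_degree must be >= 1")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise ValueError("set_size_range must satisfy 1 <= lo <= hi")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator."""

    regulated_mirnas: dict[str, str]  # id -> direction
    regulated_mrnas: dict[str, str]
    true_pairs: list[tuple[str, str]]
    validated_pairs: set[tuple[str, str]]
    true_synergy: float
    subfloor_mirnas: set[str] = field(default_factory=set)
    subfloor_mrnas: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for mirna, gene in self.true_pairs:
            if mirna not in self.regulated_mirnas or gene not in self.regulated_mrnas:
                raise ValueError(f"pair ({mirna}, {gene}) not in regulated sets")
            if self.regulated_mirnas[mirna] == self.regulated_mrnas[gene]:
                raise ValueError(f"pair ({mirna}, {gene}) is not anti-correlated")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent substream keyed by (seed, stream name)."""
    key = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


def mirna_ids(n: int) -> list[str]:
    return [f"hsa-miR-{i:04d}-{'5p' if i % 2 else '3p'}" for i in range(1, n + 1)]


def gene_ids(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# truth


def simulate_truth(config: SimulationConfig) -> PlantedTruth:
    """Draw the regulated gene/miRNA sets, their directions and true pairs."""
    rng = _rng(config, "truth")
    mirnas = mirna_ids(config.n_mirna)
    genes = gene_ids(config.n_mrna)
    n_reg_mi = round(config.n_mirna * config.frac_regulated)
    n_reg_g = round(config.n_mrna * config.frac_regulated)
    reg_mi = sorted(rng.choice(mirnas, size=n_reg_mi, replace=False).tolist())
    reg_g = sorted(rng.choice(genes, size=n_reg_g, replace=False).tolist())
    mi_dirs = {m: ("up" if rng.random() < 0.5 else "down") for m in reg_mi}
    g_dirs = {g: ("up" if rng.random() < 0.5 else "down") for g in reg_g}

    pairs: list[tuple[str, str]] = []
    if config.n_planted_pairs:
        seen: set[tuple[str, str]] = set()
        candidates_by_dir = {
            "up": [g for g in reg_g if g_dirs[g] == "up"],
            "down": [g for g in reg_g if g_dirs[g] == "down"],
        }
        attempts = 0
        while len(pairs) < config.n_planted_pairs:
            attempts += 1
            if attempts > 100 * config.n_planted_pairs:
                raise ValueError(
                    "cannot plant the requested pairs; too few regulated genes "
                    "of opposite direction"
                )
            mirna = reg_mi[int(rng.integers(len(reg_mi)))]
            opposite = "down" if mi_dirs[mirna] == "up" else "up"
            pool = candidates_by_dir[opposite]
            if not pool:
                continue
            gene = pool[int(rng.integers(len(pool)))]
            if (mirna, gene) in seen:
                continue
            seen.add((mirna, gene))
            pairs.append((mirna, gene))
    n_val = round(len(pairs) * config.frac_validated_pairs)
    validated = set(pairs[:n_val])

    # regulated ids not protecting a planted pair may be planted sub-floor
    pair_mis = {m for m, _ in pairs}
    pair_gs = {g for _, g in pairs}
    sub_mi = {
        m for m in reg_mi
        if m not in pair_mis and rng.random() < config.frac_subfloor
    }
    sub_g = {
        g for g in reg_g
        if g not in pair_gs and rng.random() < config.frac_subfloor
    }
    return PlantedTruth(
        regulated_mirnas=mi_dirs,
        regulated_mrnas=g_dirs,
        true_pairs=pairs,
        validated_pairs=validated,
        true_synergy=config.true_cdi,
        subfloor_mirnas=sub_mi,
        subfloor_mrnas=sub_g,
    )


# ---------------------------------------------------------------------------
# DE tables


def generate_de_table(
    config: SimulationConfig,
    biotype: Literal["miRNA", "protein_coding"],
    truth: PlantedTruth | None = None,
) -> tuple[list[DifferentialExpressionRecord], PlantedTruth]:
    """Generate a DE result table with planted up/down genes.

    Unregulated genes carry uniform(0,1) adjusted p-values (pinned to 1 in
    strict-null mode) and near-zero log2FC; regulated genes carry
    ``|log2FC| >= effect_log2fc`` and an adjusted p below the biotype's
    selection cut.  Abundances straddle the biotype's RPM floor; genes
    anchoring a planted pair are always above it.
    """
    if truth is None:
        truth = simulate_truth(config)
    if biotype == "miRNA":
        ids = mirna_ids(config.n_mirna)
        regulated = truth.regulated_mirnas
        subfloor = truth.subfloor_mirnas
        thresholds = PRESETS["mirna"]
    elif biotype == "protein_coding":
        ids = gene_ids(config.n_mrna)
        regulated = truth.regulated_mrnas
        subfloor = truth.subfloor_mrnas
        thresholds = PRESETS["mrna"]
    else:
        raise ValueError(f"unknown biotype: {biotype!r}")
    rng = _rng(config, f"de:{biotype}")
    floor = thresholds.rpm_floor
    records = []
    for gid in ids:
        direction = regulated.get(gid)
        if direction is not None:
            sign = 1.0 if direction == "up" else -1.0
            log2fc = sign * (config.effect_log2fc + abs(rng.normal(0.0, 0.3)))
            p_adj = float(rng.uniform(0.0, thresholds.p_adj_cut * (1 - 1e-9)))
            if gid in subfloor:
                lo = float(rng.uniform(0.0, floor * 0.9))
                rpm_u, rpm_t = lo, float(rng.uniform(0.0, floor * 0.9))
            else:
                rpm_u = floor * (1.5 + float(rng.lognormal(0.5, 0.8)))
                rpm_t = rpm_u * 2.0**log2fc if direction else rpm_u
                rpm_t = max(rpm_t, 0.0)
        else:
            log2fc = float(rng.normal(0.0, 0.3))
            p_adj = 1.0 if config.strict_null else float(rng.uniform(0.0, 1.0))
            # straddle the floor: roughly half of nulls below it
            base = floor * float(rng.lognormal(0.0, 1.0))
            rpm_u, rpm_t = base, base * 2.0**log2fc
        records.append(
            DifferentialExpressionRecord(
                gene_id=gid,
                biotype=biotype,
                log2fc=float(log2fc),
                p_adj=p_adj,
                mean_rpm_untreated=float(rpm_u),
                mean_rpm_treated=float(rpm_t),
            )
        )
    return records, truth


# ---------------------------------------------------------------------------
# target predictions


def _draw_score(source: str, passing: bool, rng: np.random.Generator) -> float:
    """Truncated-normal score on the requested side of the source cut-off."""
    if source == "targetscan":  # pass: <= -0.3
        spread = abs(rng.normal(0.0, 0.15))
        return -0.3 - spread if passing else min(-0.3 + 1e-3 + spread, 0.0)
    if source == "mirdb":  # pass: >= 85
        spread = abs(rng.normal(0.0, 6.0))
        return min(85.0 + spread, 100.0) if passing else max(85.0 - 1e-3 - spread, 0.0)
    if source == "microt_cds":  # pass: >= 0.95
        spread = abs(rng.normal(0.0, 0.02))
        return min(0.95 + spread, 1.0) if passing else max(0.95 - 1e-3 - spread, 0.0)
    raise ValueError(f"no score convention for source {source!r}")


def generate_target_predictions(
    truth: PlantedTruth, config: SimulationConfig
) -> list[TargetPrediction]:
    """Emit per-source predictions covering true pairs plus controlled decoys.

    Every true pair receives passing predictions from >= 2 distinct sources
    (validated pairs: one strong-evidence validation entry plus >= 1
    prediction source).  Decoys cycle through three failure modes: failing
    scores, single-source support, and same-direction (non-anti-correlated)
    pairs that pass every upstream filter.
    """
    if not truth.true_pairs:
        raise ValueError("planted truth contains no true pairs")
    rng = _rng(config, "predictions")
    predictions: list[TargetPrediction] = []
    used_pairs: set[tuple[str, str]] = set(truth.true_pairs)

    for pair in truth.true_pairs:
        mirna, gene = pair
        n_pred = int(rng.integers(1, len(PREDICTION_SOURCES) + 1))
        if pair not in truth.validated_pairs:
            n_pred = max(n_pred, 2)
        sources = rng.choice(PREDICTION_SOURCES, size=n_pred, replace=False)
        for src in sources:
            predictions.append(
                TargetPrediction(mirna, gene, str(src), _draw_score(str(src), True, rng))
            )
        if pair in truth.validated_pairs:
            vsrc = VALIDATION_SOURCES[int(rng.integers(len(VALIDATION_SOURCES)))]
            predictions.append(
                TargetPrediction(mirna, gene, vsrc, None, "strong_validated")
            )

    mirnas = sorted(truth.regulated_mirnas)
    genes = sorted(truth.regulated_mrnas)
    same_dir = [
        (m, g)
        for m in mirnas
        for g in genes
        if truth.regulated_mirnas[m] == truth.regulated_mrnas[g]
    ]
    rng.shuffle(same_dir)
    same_iter = iter([p for p in same_dir if p not in used_pairs])

    def fresh_pair() -> tuple[str, str]:
        while True:
            pair = (
                mirnas[int(rng.integers(len(mirnas)))],
                genes[int(rng.integers(len(genes)))],
            )
            if pair not in used_pairs:
                return pair

    for i in range(config.n_decoy_predictions):
        mode = i % 3
        if mode == 0:  # fails every source score
            pair = fresh_pair()
            used_pairs.add(pair)
            for src in rng.choice(PREDICTION_SOURCES, size=2, replace=False):
                predictions.append(
                    TargetPrediction(*pair, str(src), _draw_score(str(src), False, rng))
                )
        elif mode == 1:  # single passing source only
            pair = fresh_pair()
            used_pairs.add(pair)
            src = str(PREDICTION_SOURCES[int(rng.integers(len(PREDICTION_SOURCES)))])
            predictions.append(
                TargetPrediction(*pair, src, _draw_score(src, True, rng))
            )
        else:  # passes consensus, fails anti-correlation
            pair = next(same_iter, None)
            if pair is None:
                logger.warning("ran out of same-direction pairs for decoys")
                continue
            used_pairs.add(pair)
            for src in rng.choice(PREDICTION_SOURCES, size=2, replace=False):
                predictions.append(
                    TargetPrediction(*pair, str(src), _draw_score(str(src), True, rng))
                )
    return predictions


# ---------------------------------------------------------------------------
# interactome


def generate_ppi_edges(
    config: SimulationConfig, node_ids: Sequence[str]
) -> list[tuple[str, str]]:
    """Scale-free (preferential-attachment) interactome over given node ids."""
    n = config.interactome_size
    if n < config.attachment_degree + 1:
        raise ValueError("interactome_size must exceed attachment_degree")
    if len(node_ids) < n:
        raise ValueError(f"need at least {n} node ids, got {len(node_ids)}")
    rng = _rng(config, "ppi")
    chosen = sorted(rng.choice(node_ids, size=n, replace=False).tolist())
    g = nx.barabasi_albert_graph(n, config.attachment_degree, seed=int(rng.integers(2**31)))
    return sorted(
        tuple(sorted((chosen[a], chosen[b]))) for a, b in g.edges
    )


# ---------------------------------------------------------------------------
# gene sets


def generate_gene_sets(
    config: SimulationConfig,
    universe: Sequence[str],
    enriched_genes: Sequence[str] | None = None,
    odds_ratio: float = 1.0,
) -> dict[str, list[str]]:
    """Uniform random gene sets; one designated set may be enrichment-biased.

    When ``enriched_genes`` is given, the first set ("CELL_CYCLE") is drawn
    by weighted sampling without replacement with the enriched genes
    up-weighted by ``odds_ratio``; all other sets are uniform.
    """
    lo, hi = config.set_size_range
    if hi > len(universe):
        raise ValueError("set size exceeds universe size")
    rng = _rng(config, "gene_sets")
    universe = list(universe)
    sets: dict[str, list[str]] = {}
    for i in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        if i == 0 and enriched_genes is not None:
            enriched = set(enriched_genes)
            weights = np.array(
                [odds_ratio if g in enriched else 1.0 for g in universe]
            )
            members = rng.choice(
                universe, size=size, replace=False, p=weights / weights.sum()
            )
            sets["CELL_CYCLE"] = sorted(members.tolist())
        else:
            members = rng.choice(universe, size=size, replace=False)
            sets[f"SET{i:03d}"] = sorted(members.tolist())
    return sets


# ---------------------------------------------------------------------------
# splicing events


def generate_splicing_events(
    config: SimulationConfig, exact_counts: bool = False
) -> tuple[list[SplicingEvent], set[str]]:
    """Generate splicing-event count tables with planted delta-PSI.

    Null events share one true PSI across conditions; planted events shift
    by ``planted_delta_psi``.  Planted base PSI is drawn so the shifted PSI
    stays within [0,1] whenever the shift leaves room on the 1/100 grid;
    otherwise the shifted PSI is clipped with a logged warning.  Replicate
    coverage is Poisson(coverage_mean) with binomial inclusion draws; with
    ``exact_counts`` the counts equal their expectation (coverage 100, true
    PSI on a 1/100 grid), the noiseless limit.

    Returns the events and the set of planted event ids.
    """
    rng = _rng(config, "splicing")
    n = config.n_splicing_events
    types = rng.choice(EVENT_TYPES, size=n, p=np.asarray(config.event_type_mix))
    n_planted = round(n * config.frac_splicing_regulated)
    planted_idx = set(
        rng.choice(n, size=n_planted, replace=False).tolist()
    ) if n_planted else set()
    events: list[SplicingEvent] = []
    planted_ids: set[str] = set()
    n_clipped = 0
    delta_grid = round(config.planted_delta_psi * 100)
    # grid range for planted base PSI that keeps the shifted PSI in [0,100]
    plant_lo, plant_hi = max(5, -delta_grid), min(95, 100 - delta_grid)
    for i in range(n):
        if i in planted_idx and plant_lo <= plant_hi:
            psi_u = int(rng.integers(plant_lo, plant_hi + 1)) / 100.0
        else:
            psi_u = int(rng.integers(5, 96)) / 100.0
        if i in planted_idx:
            psi_t = psi_u + config.planted_delta_psi
            if not 0.0 <= psi_t <= 1.0:
                psi_t = min(max(psi_t, 0.0), 1.0)
                n_clipped += 1
            psi_t = round(psi_t * 100) / 100.0
        else:
            psi_t = psi_u

        def draw(psi: float) -> tuple[list[int], list[int]]:
            inc, skip = [], []
            for _ in range(config.n_replicates):
                if exact_counts:
                    cov = 100
                    k = round(cov * psi)
                else:
                    cov = max(int(rng.poisson(config.coverage_mean)), 1)
                    k = int(rng.binomial(cov, psi))
                inc.append(k)
                skip.append(cov - k)
            return inc, skip

        inc_u, skip_u = draw(psi_u)
        inc_t, skip_t = draw(psi_t)
        event_id = f"EV{i:05d}"
        if i in planted_idx:
            planted_ids.add(event_id)
        events.append(
            SplicingEvent(
                event_id=event_id,
                gene_id=f"GENE{(i % config.n_mrna) + 1:05d}",
                event_type=str(types[i]),
                inclusion_untreated=inc_u,
                skipping_untreated=skip_u,
                inclusion_treated=inc_t,
                skipping_treated=skip_t,
            )
        )
    if n_clipped:
        logger.warning("planted delta-PSI clipped to [0,1] for %d events", n_clipped)
    return events, planted_ids


# ---------------------------------------------------------------------------
# synergy readouts


def generate_synergy_readouts(config: SimulationConfig) -> SynergyMeasurement:
    """Multiplicative-model combination readouts with a configured true CDI.

    Condition means: control 1, A ``effect_a``, B ``effect_b``, combination
    ``true_cdi * effect_a * effect_b`` (so the statistic inverts the model
    exactly at zero noise).  Noise is mean-one lognormal with the configured
    coefficient of variation.
    """
    rng = _rng(config, "synergy")
    means = {
        "control": 1.0,
        "a": config.effect_a,
        "b": config.effect_b,
        "ab": config.true_cdi * config.effect_a * config.effect_b,
    }
    cv = config.readout_cv
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        mu = -0.5 * sigma * sigma

        def noise() -> float:
            return float(rng.lognormal(mu, sigma))
    else:
        def noise() -> float:
            return 1.0
    groups = {
        cond: [m * noise() for _ in range(config.n_replicates)]
        for cond, m in means.items()
    }
    return SynergyMeasurement(
        control_readouts=groups["control"],
        a_readouts=groups["a"],
        b_readouts=groups["b"],
        ab_readouts=groups["ab"],
    )


# ---------------------------------------------------------------------------
# truth sidecar


def write_truth_sidecar(truth: PlantedTruth, path) -> None:
    """Write planted labels as a TSV sidecar."""
    lines = ["kind\tid_1\tid_2\tlabel"]
    for m in sorted(truth.regulated_mirnas):
        lines.append(f"regulated_mirna\t{m}\t\t{truth.regulated_mirnas[m]}")
    for g in sorted(truth.regulated_mrnas):
        lines.append(f"regulated_mrna\t{g}\t\t{truth.regulated_mrnas[g]}")
    for mirna, gene in truth.true_pairs:
        label = "validated" if (mirna, gene) in truth.validated_pairs else "predicted"
        lines.append(f"true_pair\t{mirna}\t{gene}\t{label}")
    lines.append(f"true_synergy\t\t\t{truth.true_synergy:.10g}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
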