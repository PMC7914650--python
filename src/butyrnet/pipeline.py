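"""End-to-end pipeline orchestration and the packaged interaction fixture.

Runs simulate -> DE filtering -> consensus -> anti-correlation -> cell-cycle
refinement -> network -> enrichment -> splicing -> synergy from a single
config, logging per-stage input/output counts and writing a run report
(Markdown plus a machine-readable TSV) that mirrors the candidate funnel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from . import consensus as cns
from . import de, enrichment, network, simulate, splicing, synergy

logger = logging.getLogger(__name__)

TABLE1_SHA256 = "2b0ed2b38cd63e05967915af7f5521636b9ef539db0add61395a5614730dc276"

_INPUT_FILES = {
    "de_mirna": "de_mirna.tsv",
    "de_mrna": "de_mrna.tsv",
    "predictions": "predictions.tsv",
    "interactome": "interactome.sif",
    "gene_sets": "gene_sets.gmt",
    "splicing_events": "splicing_events.tsv",
    "synergy_readouts": "synergy_readouts.tsv",
}


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    With ``simulate_inputs`` the synthetic generator writes every input into
    ``out_dir/inputs`` first; otherwise ``input_dir`` must already contain
    the seven input files and is checked before any stage runs.
    """

    out_dir: Path
    seed: int = 0
    simulate_inputs: bool = True
    input_dir: Path | None = None
    simulation: simulate.SimulationConfig | None = None
    boundary_mode: str = "strict"
    min_sources: int = 2
    min_degree: int = 1
    top_k: int = 10
    alpha: float = 0.05
    criteria_mode: str = "and"
    min_delta_psi: float = 0.1

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.simulation is None:
            self.simulation = simulate.SimulationConfig(seed=self.seed)
        if self.input_dir is not None:
            self.input_dir = Path(self.input_dir)

    def serialize(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["input_dir"] = str(self.input_dir) if self.input_dir else None
        return d


def load_pipeline_config(path) -> PipelineConfig:
    """Load a pipeline config from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulation", None)
    cfg = PipelineConfig(**raw)
    if sim is not None:
        cfg.simulation = simulate.SimulationConfig(
            seed=raw.get("seed", 0), **{
                k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()
            }
        )
    return cfg


def _simulate_inputs(config: PipelineConfig, input_dir: Path) -> None:
    sim = config.simulation
    assert sim is not None
    input_dir.mkdir(parents=True, exist_ok=True)
    truth = simulate.simulate_truth(sim)
    mi_records, _ = simulate.generate_de_table(sim, "miRNA", truth)
    g_records, _ = simulate.generate_de_table(sim, "protein_coding", truth)
    de.write_de_table(mi_records, input_dir / _INPUT_FILES["de_mirna"])
    de.write_de_table(g_records, input_dir / _INPUT_FILES["de_mrna"])
    preds = simulate.generate_target_predictions(truth, sim)
    cns.write_predictions(preds, input_dir / _INPUT_FILES["predictions"])
    edges = simulate.generate_ppi_edges(sim, simulate.gene_ids(sim.n_mrna))
    (input_dir / _INPUT_FILES["interactome"]).write_text(
        "\n".join(f"{a}\tpp\t{b}" for a, b in edges) + "\n"
    )
    pair_genes = sorted({g for _, g in truth.true_pairs})
    sets = simulate.generate_gene_sets(
        sim,
        simulate.gene_ids(sim.n_mrna),
        enriched_genes=pair_genes or None,
        odds_ratio=50.0,
    )
    # the planted pair genes must be annotatable as cell-cycle for the
    # refinement stage to keep them
    if pair_genes and "CELL_CYCLE" in sets:
        sets["CELL_CYCLE"] = sorted(set(sets["CELL_CYCLE"]) | set(pair_genes))
    enrichment.write_gmt(sets, input_dir / _INPUT_FILES["gene_sets"])
    events, _ = simulate.generate_splicing_events(sim)
    splicing.write_event_table(events, input_dir / _INPUT_FILES["splicing_events"])
    readouts = simulate.generate_synergy_readouts(sim)
    synergy.write_readout_table(readouts, input_dir / _INPUT_FILES["synergy_readouts"])
    simulate.write_truth_sidecar(truth, input_dir / "truth.tsv")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages in dependency order; returns the run report dict.

    Any stage failure raises with the failing stage named; outputs written
    before the failure are retained.
    """
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": config.serialize(), "stages": {}}

    def stage(name):
        def deco(fn):
            def run(*a, **k):
                try:
                    return fn(*a, **k)
                except Exception as exc:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return run
        return deco

    if config.simulate_inputs:
        input_dir = out_dir / "inputs"
        stage("simulate")(_simulate_inputs)(config, input_dir)
    else:
        if config.input_dir is None:
            raise ValueError("input_dir required when simulate_inputs is false")
        input_dir = config.input_dir
        missing = [
            f for f in _INPUT_FILES.values() if not (input_dir / f).exists()
        ]
        if missing:
            raise FileNotFoundError(
                f"missing pipeline inputs in {input_dir}: {missing}"
            )

    paths = {k: input_dir / v for k, v in _INPUT_FILES.items()}

    # -- DE filtering ------------------------------------------------
    @stage("filter-de")
    def _filter():
        mi = de.read_de_table(paths["de_mirna"])
        g = de.read_de_table(paths["de_mrna"])
        mi_thr = dataclasses.replace(
            de.PRESETS["mirna"], boundary_mode=config.boundary_mode
        )
        g_thr = dataclasses.replace(
            de.PRESETS["mrna"], boundary_mode=config.boundary_mode
        )
        mi_sel = de.select_candidates(mi, mi_thr)
        g_sel = de.select_candidates(g, g_thr)
        de.write_de_table(mi_sel, out_dir / "selected_mirnas.tsv")
        de.write_de_table(g_sel, out_dir / "selected_mrnas.tsv")
        report["stages"]["filter_de"] = {
            "mirna_in": len(mi),
            "mirna_selected": len(mi_sel),
            "mrna_in": len(g),
            "mrna_selected": len(g_sel),
            "thresholds": {
                "mirna": dataclasses.asdict(mi_thr),
                "mrna": dataclasses.asdict(g_thr),
            },
        }
        return mi, g, mi_thr, g_thr, mi_sel, g_sel

    mi, g, mi_thr, g_thr, mi_sel, g_sel = _filter()

    # -- consensus + anti-correlation --------------------------------
    @stage("consensus")
    def _consensus():
        preds = cns.read_predictions(paths["predictions"])
        mi_dirs = de.direction_map(mi_sel, mi_thr)
        g_dirs = de.direction_map(g_sel, g_thr)
        cons = cns.build_consensus(
            preds, mi_dirs, g_dirs, min_sources=config.min_sources
        )
        anti = cns.anticorrelation_filter(cons)
        cns.write_interactions(cons, out_dir / "consensus_interactions.tsv")
        cns.write_interactions(anti, out_dir / "anticorrelated_interactions.tsv")
        report["stages"]["consensus"] = {
            "predictions_in": len(preds),
            "consensus_pairs": len(cons),
            "anticorrelated_pairs": len(anti),
            "min_sources": config.min_sources,
        }
        return anti

    anti = _consensus()

    # -- cell-cycle refinement ---------------------------------------
    @stage("refine")
    def _refine():
        sets, _ = enrichment.read_gmt(paths["gene_sets"])
        if "CELL_CYCLE" in sets:
            refined = cns.restrict_to_gene_set(anti, set(sets["CELL_CYCLE"]))
        else:
            refined = anti
        cns.write_interactions(refined, out_dir / "cell_cycle_interactions.tsv")
        report["stages"]["refine"] = {
            "in": len(anti),
            "cell_cycle_pairs": len(refined),
        }
        return sets, refined

    gene_sets, refined = _refine()

    # -- network -----------------------------------------------------
    @stage("network")
    def _network():
        interactome = network.read_edge_list(paths["interactome"])
        seeds = {r.gene_id for r in g_sel}
        net = network.zero_order_subnetwork(
            seeds, interactome, min_degree=config.min_degree
        )
        ppi_nodes = len(net.nodes)
        net = network.integrate_mirna_edges(net, refined, add_missing_genes=True)
        hubs = network.rank_hubs(net, config.top_k) if net.nodes else []
        if net.nodes:
            network.export_network(net, out_dir / "network.sif", "sif")
            network.export_network(net, out_dir / "network.graphml", "graphml")
        report["stages"]["network"] = {
            "interactome_edges": len(interactome),
            "seed_genes": len(seeds),
            "ppi_nodes": ppi_nodes,
            "nodes_with_mirna": len(net.nodes),
            "edges": len(net.edges()),
            "top_hubs": hubs,
        }
        return net

    _network()

    # -- enrichment --------------------------------------------------
    @stage("enrich")
    def _enrich():
        universe = {r.gene_id for r in g}
        query = {r.gene_id for r in g_sel}
        results = enrichment.hypergeometric_enrichment(query, gene_sets, universe)
        enrichment.write_enrichment_results(results, out_dir / "enrichment.tsv")
        n_sig = sum(1 for r in results if r.q_value < config.alpha)
        report["stages"]["enrich"] = {
            "gene_sets": len(gene_sets),
            "query_size": len(query & universe),
            "significant_at_alpha": n_sig,
            "alpha": config.alpha,
        }

    _enrich()

    # -- splicing ----------------------------------------------------
    @stage("splice")
    def _splice():
        events = splicing.read_event_table(paths["splicing_events"])
        tested = splicing.test_differential_splicing(
            events,
            alpha_fdr=config.alpha,
            min_delta_psi=config.min_delta_psi,
            criteria_mode=config.criteria_mode,
        )
        flagged = [ev for ev in tested if ev.flagged]
        splicing.write_splicing_results(tested, out_dir / "splicing_results.tsv")
        report["stages"]["splice"] = {
            "events_in": len(events),
            "events_tested": len(tested),
            "events_flagged": len(flagged),
            "event_type_percentages": splicing.summarize_event_types(flagged),
        }

    _splice()

    # -- synergy -----------------------------------------------------
    @stage("synergy")
    def _synergy():
        measurement = synergy.read_readout_table(paths["synergy_readouts"])
        synergy.write_synergy_summary(measurement, out_dir / "synergy_summary.tsv")
        report["stages"]["synergy"] = {
            "ratio_a": measurement.ratio_a,
            "ratio_b": measurement.ratio_b,
            "ratio_ab": measurement.ratio_ab,
            "cdi": measurement.cdi,
            "classification": measurement.classification,
        }

    _synergy()

    _write_report(report, out_dir)
    return report


def _write_report(report: dict[str, Any], out_dir: Path) -> None:
    lines = ["# Pipeline run report", "", "## Stage funnel", ""]
    rows = ["stage\tmetric\tvalue"]
    for stage_name, metrics in report["stages"].items():
        lines.append(f"### {stage_name}")
        for key, value in metrics.items():
            lines.append(f"- {key}: {value}")
            if isinstance(value, (int, float, str)):
                rows.append(f"{stage_name}\t{key}\t{value}")
        lines.append("")
    lines.append("## Config")
    lines.append("```yaml")
    lines.append(yaml.safe_dump(report["config"], sort_keys=True).rstrip())
    lines.append("```")
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")
    (out_dir / "report.tsv").write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# packaged fixture


def load_table1_fixture() -> list[cns.ConsensusInteraction]:
    """Load the packaged table of 24 curated miRNA-mRNA interactions.

    The fixture transcribes the published cell-cycle-related interaction
    table (miRNA and target DE directions, supporting sources, validation
    annotation); its checksum is verified on load.
    """
    ref = resources.files("butyrnet.data") / "table1_interactions.tsv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise ValueError(
            f"fixture checksum mismatch: {digest} != {TABLE1_SHA256}"
        )
    out: list[cns.ConsensusInteraction] = []
    lines = raw.decode().splitlines()
    for line in lines[1:]:
        mirna, mdir, gene, gdir, sources, validation = line.split("\t")
        source_set = frozenset(sources.split(","))
        out.append(
            cns.ConsensusInteraction(
                mirna_id=mirna,
                gene_id=gene,
                supporting_sources=source_set,
                validated=bool(source_set & set(cns.VALIDATION_SOURCES)),
                mirna_direction=mdir,  # type: ignore[arg-type]
                gene_direction=gdir,  # type: ignore[arg-type]
                provenance=validation,
            )
        )
    return out
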