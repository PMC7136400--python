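"""End-to-end pipeline: DE -> ceRNA network -> biomarkers -> enrichment.

A single declarative config drives the run; every stage writes its artifact
under the output directory and the manifest records the config echo, input
digests, and per-stage counts, so identical config + inputs reproduce an
identical manifest (modulo timestamp).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, biomarkers, diffexpr, enrichment, network, synthetic
from .io import (
    GROUP_LOW,
    ExpressionMatrix,
    ValidationError,
    collapse_probes,
    read_expression_matrix,
    read_group_labels,
    read_interaction_table,
    read_probe_map,
)

logger = logging.getLogger("cernet")


# ---------------------------------------------------------------------------
# Manifest arithmetic helpers (also used for printed-count verification)
# ---------------------------------------------------------------------------


def direction_total(per_class_counts: dict[str, int]) -> int:
    """Total DE genes in one direction from per-class counts."""
    return sum(int(v) for v in per_class_counts.values())


def panel_size_from_directions(n_up: int, n_down: int) -> int:
    """Panel size as the sum of its up- and down-regulated members."""
    return int(n_up) + int(n_down)


def percent_of(part: int, whole: int, ndigits: int = 1) -> float:
    """100 * part / whole, rounded (e.g. network lncRNAs over DE lncRNAs)."""
    if whole <= 0:
        raise ValidationError(f"whole must be positive, got {whole}")
    return round(100.0 * part / whole, ndigits)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    mrna_path: str
    lncrna_path: str
    mirna_path: str
    phenotype_path: str
    interactions_path: str
    probe_map_paths: dict[str, str] = field(default_factory=dict)
    gmt_path: str | None = None
    de_alpha: float = 0.05
    prior_df: float | None = None
    pcc_threshold: float = 0.5
    neg_threshold: float = 0.0
    rf: biomarkers.RFConfig = field(default_factory=biomarkers.RFConfig)
    roc_threshold: float = 0.5
    ci_method: str = "bootstrap"
    ci_level: float = 0.95
    positive_group: str = GROUP_LOW
    run_enrichment: bool = True
    seed: int = 0
    out_dir: str = "cernet_out"

    def validate(self) -> None:
        for name in ("mrna_path", "lncrna_path", "mirna_path", "phenotype_path", "interactions_path"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ValidationError(f"{name} does not exist: {path}")
        if not 0 < self.de_alpha <= 1:
            raise ValidationError(f"de_alpha must be in (0, 1], got {self.de_alpha}")
        if not -1 <= self.pcc_threshold <= 1:
            raise ValidationError(f"pcc_threshold must be in [-1, 1], got {self.pcc_threshold}")
        if not -1 <= self.neg_threshold <= 1:
            raise ValidationError(f"neg_threshold must be in [-1, 1], got {self.neg_threshold}")
        if not 0 <= self.roc_threshold <= 1:
            raise ValidationError(f"roc_threshold must be in [0, 1], got {self.roc_threshold}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        rf_raw = raw.pop("rf", {})
        rf = biomarkers.RFConfig(**rf_raw) if isinstance(rf_raw, dict) else rf_raw
        known = {f.name for f in dataclasses.fields(cls)} - {"rf"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(rf=rf, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    config: dict
    input_digest: str
    version: str
    timestamp: float
    de_counts: dict  # per class: {"total": .., "up": .., "down": ..}
    n_candidate_pairs: int
    n_triplets: int
    network_summary: dict
    network_lncrna_percent: float | None
    panel_size: int | None
    evaluation: dict | None
    n_enriched_terms: int | None
    warnings: list[str] = field(default_factory=list)

    def core(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("timestamp")
        return d

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _load_matrix(path: str, rna_class: str, probe_map_path: str | None) -> ExpressionMatrix:
    matrix = read_expression_matrix(path, rna_class)
    if probe_map_path:
        matrix = collapse_probes(matrix, read_probe_map(probe_map_path))
    return matrix


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages and write artifacts under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []

    def stage(name: str):
        logger.info("pipeline stage: %s", name)

    # ---- load ------------------------------------------------------------
    stage("load")
    try:
        matrices = {
            "mRNA": _load_matrix(config.mrna_path, "mRNA", config.probe_map_paths.get("mRNA")),
            "lncRNA": _load_matrix(config.lncrna_path, "lncRNA", config.probe_map_paths.get("lncRNA")),
            "miRNA": _load_matrix(config.mirna_path, "miRNA", config.probe_map_paths.get("miRNA")),
        }
        labels = read_group_labels(config.phenotype_path)
        interactions = read_interaction_table(config.interactions_path)
    except ValidationError as exc:
        raise ValidationError(f"stage 'load' failed: {exc}") from exc
    digest = network.input_digest(
        config.mrna_path,
        config.lncrna_path,
        config.mirna_path,
        config.phenotype_path,
        config.interactions_path,
    )

    # ---- differential expression ----------------------------------------
    stage("diffexpr")
    de_tables = {}
    de_sets = {}
    de_counts = {}
    for cls, matrix in matrices.items():
        table = diffexpr.moderated_t_test(matrix, labels, config.prior_df)
        de = diffexpr.filter_de(table, config.de_alpha)
        de_tables[cls] = table
        de_sets[cls] = set(de["gene_id"])
        up = int((de["direction"] == "up").sum())
        down = int((de["direction"] == "down").sum())
        de_counts[cls] = {"total": len(de), "up": up, "down": down}
        diffexpr.write_de_table(table, out / f"de_{cls}.tsv")

    # ---- ceRNA network ---------------------------------------------------
    stage("network")
    lnc_ids = sorted(de_sets["lncRNA"])
    mrna_ids = sorted(de_sets["mRNA"])
    mirna_ids = sorted(de_sets["miRNA"])
    triplets: list[network.CeRNATriplet] = []
    n_candidates = 0
    if lnc_ids and mrna_ids:
        corr_lm = network.pairwise_pcc(matrices["lncRNA"], matrices["mRNA"], lnc_ids, mrna_ids)
        candidates = network.candidate_pairs(corr_lm, config.pcc_threshold)
        candidates.to_csv(out / "candidate_pairs.tsv", sep="\t", index=False, float_format="%.17g")
        n_candidates = len(candidates)
        if n_candidates and mirna_ids:
            corr_im = network.pairwise_pcc(matrices["miRNA"], matrices["mRNA"], mirna_ids, mrna_ids)
            corr_il = network.pairwise_pcc(matrices["miRNA"], matrices["lncRNA"], mirna_ids, lnc_ids)
            triplets = network.mediation_filter(
                candidates, interactions, corr_im, corr_il, mirna_ids, config.neg_threshold
            )
    provenance = {
        "pcc_threshold": config.pcc_threshold,
        "neg_threshold": config.neg_threshold,
        "de_alpha": config.de_alpha,
        "input_digest": digest,
    }
    net = network.build_network(triplets, provenance)
    summary = network.network_summary(net)
    network.write_network(net, out / "network_edges.tsv", "edge_list")
    network.write_network(net, out / "network.sif", "sif")
    (out / "network_summary.json").write_text(json.dumps(summary.to_dict(), indent=2, sort_keys=True))
    if not triplets:
        notes.append("no ceRNA triplets passed the filters; network is empty")
        logger.warning("pipeline: empty ceRNA network")

    net_lnc_percent = None
    if de_counts["lncRNA"]["total"]:
        net_lnc_percent = percent_of(summary.n_lncrna, de_counts["lncRNA"]["total"])

    # ---- biomarker selection + evaluation --------------------------------
    stage("biomarkers")
    panel_size = None
    evaluation = None
    network_lncrnas = sorted(net.node_ids("lncRNA"))
    if network_lncrnas:
        rf = dataclasses.replace(config.rf, seed=config.seed)
        panel = biomarkers.select_biomarkers(
            matrices["lncRNA"], labels, rf, candidates=network_lncrnas
        )
        panel.to_frame().to_csv(out / "panel.tsv", sep="\t", index=False, float_format="%.17g")
        panel_size = panel.size
        predictions = biomarkers.loocv_evaluate(
            matrices["lncRNA"], labels, panel, rf, config.positive_group, config.roc_threshold
        )
        predictions.to_csv(out / "loocv_predictions.tsv", sep="\t", index=False, float_format="%.17g")
        report = biomarkers.evaluate(
            predictions,
            config.positive_group,
            config.roc_threshold,
            config.ci_method,
            config.ci_level,
            seed=config.seed,
        )
        evaluation = report.to_dict()
        (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2, sort_keys=True))
    else:
        notes.append("no network lncRNAs; biomarker selection skipped")

    # ---- enrichment (optional) -------------------------------------------
    stage("enrichment")
    n_enriched = None
    if config.run_enrichment and config.gmt_path:
        network_mrnas = sorted(net.node_ids("mRNA"))
        if network_mrnas:
            collection = enrichment.read_gmt(config.gmt_path)
            try:
                table = enrichment.hypergeom_ora(network_mrnas, collection, config.de_alpha)
            except ValidationError as exc:
                notes.append(f"enrichment skipped: {exc}")
            else:
                table.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.17g")
                n_enriched = int(table["enriched"].sum())
        else:
            notes.append("no network mRNAs; enrichment skipped")

    manifest = RunManifest(
        config=config.to_dict(),
        input_digest=digest,
        version=__version__,
        timestamp=time.time(),
        de_counts=de_counts,
        n_candidate_pairs=n_candidates,
        n_triplets=len(triplets),
        network_summary=summary.to_dict(),
        network_lncrna_percent=net_lnc_percent,
        panel_size=panel_size,
        evaluation=evaluation,
        n_enriched_terms=n_enriched,
        warnings=notes,
    )
    # internal consistency: direction totals add up per class
    for cls, counts in manifest.de_counts.items():
        assert counts["up"] + counts["down"] == counts["total"], cls
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def make_demo(seed: int = 1, directory: str | Path = "cernet_demo") -> RunManifest:
    """Generate a small synthetic dataset, run the full pipeline on it."""
    directory = Path(directory)
    data_dir = directory / "data"
    cfg = synthetic.SynthConfig(
        n_per_group=5,
        n_mrna=60,
        n_lncrna=60,
        n_mirna=15,
        n_de_per_class=12,
        de_effect=2.0,
        n_triplets=8,
        coupling=0.9,
        n_decoy_interactions=80,
        noise_sd=0.4,
        seed=seed,
    )
    dataset = synthetic.generate_dataset(cfg)
    paths = synthetic.write_dataset(dataset, data_dir)
    config = PipelineConfig(
        mrna_path=str(paths["mRNA"]),
        lncrna_path=str(paths["lncRNA"]),
        mirna_path=str(paths["miRNA"]),
        phenotype_path=str(paths["phenotype"]),
        interactions_path=str(paths["interactions"]),
        rf=biomarkers.RFConfig(n_trees=200, n_repeats=2, seed=seed),
        seed=seed,
        out_dir=str(directory / "out"),
    )
    return run_pipeline(config)
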