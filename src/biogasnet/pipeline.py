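"""End-to-end orchestration: preprocess -> classify -> per-pathway networks ->
topology -> environmental screens, with a reproducibility manifest.

Replicates are classified individually by factor F and partitioned into the
acetoclastic (AcMe), hydrogenotrophic (HyMe) and mixed (BoMe) replicate sets;
one co-occurrence network is inferred per set that has at least three
replicates (smaller sets are skipped with a warning).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .abundance import (
    aggregate,
    filter_replicate_presence,
    normalize_relative,
    read_abundance_table,
    read_metadata,
)
from .env import spearman_screen, abundance_floor, vif_screen
from .network import CooccurrenceNetwork
from .pathways import (
    LABEL_ACETO,
    LABEL_BOTH,
    LABEL_HYDRO,
    classify_units,
    calls_to_frame,
    load_pathway_ko_sets,
)
from .topology import role_table, summarize_network

logger = logging.getLogger(__name__)

NETWORK_CODES = {LABEL_ACETO: "AcMe", LABEL_HYDRO: "HyMe", LABEL_BOTH: "BoMe"}


@dataclass
class PipelineConfig:
    """All stage parameters with their published defaults, plus paths and seed."""

    abundance_path: str
    annotation_path: str
    metadata_path: str
    outdir: str
    min_present: int = 3
    min_prevalence: float = 0.6
    n_top: int = 2500
    n_bottom: int = 2500
    min_support: int = 3
    bootstrap_iterations: int = 100
    alpha: float = 0.05
    f_lo: float = 0.4
    f_hi: float = 2.5
    z_thresh: float = 2.5
    p_thresh: float = 0.62
    spearman_alpha: float = 0.01
    min_mean_abundance: float = 0.1
    vif_threshold: float = 10.0
    ko_sets_path: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full chain; returns the run directory containing all outputs
    and a ``manifest.json`` recording config, seed, versions and counts."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "biogasnet_version": __version__,
        "config": asdict(cfg),
        "stages": {},
        "outputs": {},
    }

    # --- preprocess ---------------------------------------------------------
    X, annotation = read_abundance_table(cfg.abundance_path, cfg.annotation_path)
    metadata = read_metadata(cfg.metadata_path)
    manifest["stages"]["input"] = {"features": X.shape[1], "samples": X.shape[0]}
    X = filter_replicate_presence(X, min_present=cfg.min_present)
    X = normalize_relative(X, total=100.0)
    manifest["stages"]["preprocess"] = {"features_kept": X.shape[1]}

    # --- per-replicate pathway classification ------------------------------
    ko_sets = load_pathway_ko_sets(cfg.ko_sets_path)
    X_ko = aggregate(X, annotation, level="ko")
    calls = classify_units(X_ko, sets=ko_sets, mode="per_replicate",
                           lo=cfg.f_lo, hi=cfg.f_hi)
    calls_frame = calls_to_frame(calls)
    calls_out = calls_frame.copy()
    calls_out.index = [f"{p}:{r}" for p, r in calls_frame.index]
    calls_out.to_csv(outdir / "pathway_calls.tsv", sep="\t")
    n_failed = int(calls_frame["label"].isna().sum())
    if n_failed:
        logger.warning("%d replicate(s) had no methanogenesis signal and were "
                       "excluded from the network partition", n_failed)
    manifest["stages"]["classify"] = {
        "replicates": len(calls_frame),
        "labels": calls_frame["label"].value_counts().to_dict(),
        "unclassified": n_failed,
    }

    # --- per-pathway networks ----------------------------------------------
    X_species = aggregate(X, annotation, level="species")
    networks: dict = {}
    for label, code in NETWORK_CODES.items():
        members = calls_frame.index[calls_frame["label"] == label]
        if len(members) < 3:
            if len(members):
                logger.warning("pathway class %s has %d replicate(s) (<3); "
                               "network skipped", code, len(members))
            continue
        sub = X_species.loc[list(members)]
        est = CooccurrenceNetwork(
            min_prevalence=cfg.min_prevalence, n_top=cfg.n_top,
            n_bottom=cfg.n_bottom, min_support=cfg.min_support,
            bootstrap_iterations=cfg.bootstrap_iterations, alpha=cfg.alpha,
            seed=cfg.seed,
        ).fit(sub)
        est.edges_.to_csv(outdir / f"edges_{code}.tsv", sep="\t", index=False)
        entry = {
            "replicates": len(members),
            "candidates_tested": est.n_candidates_tested_,
            "edges": est.graph_.number_of_edges(),
            "nodes": est.graph_.number_of_nodes(),
        }
        if est.graph_.number_of_nodes():
            roles = role_table(est.graph_, seed=cfg.seed,
                               z_thresh=cfg.z_thresh, p_thresh=cfg.p_thresh)
            roles.to_csv(outdir / f"roles_{code}.tsv", sep="\t")
            summary = summarize_network(est.graph_, roles)
            summary.to_series().to_csv(outdir / f"summary_{code}.tsv", sep="\t",
                                       header=["value"])
            import networkx as nx

            nx.write_graphml(est.graph_, outdir / f"network_{code}.graphml")
            entry["modules"] = summary.n_modules
        networks[code] = entry
    manifest["stages"]["networks"] = networks

    # --- environmental screens ----------------------------------------------
    try:
        kept_vars, vif_report = vif_screen(metadata, threshold=cfg.vif_threshold)
        vif_report.to_csv(outdir / "vif_report.tsv", sep="\t", index=False)
    except ValueError as exc:
        logger.warning("VIF screen skipped: %s", exc)
        kept_vars = list(metadata.columns)
    floored = abundance_floor(X_species, min_mean=cfg.min_mean_abundance)
    correlations = spearman_screen(floored, metadata, alpha=cfg.spearman_alpha)
    correlations.to_csv(outdir / "env_correlations.tsv", sep="\t", index=False)
    manifest["stages"]["environment"] = {
        "vif_kept_variables": kept_vars,
        "features_screened": floored.shape[1],
        "significant_correlations": int(correlations["significant"].sum()),
    }

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
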