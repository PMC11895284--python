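"""End-to-end run: blood/tissue classification plus optional demultiplexing.

``run`` wires the stages together, merges their calls into a single
annotation table, and writes the results TSV plus a manifest capturing the
configuration and seeds needed to reproduce the run exactly. Outputs are
deterministic: rerunning the same configuration yields byte-identical
files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from ._errors import ConfigError
from .blood_tissue import BloodTissueConfig, classify
from .demux import call_doublets, filter_snps, fit_mixture, label_origins
from .io import (
    read_10x_mtx,
    read_allele_counts,
    read_annotations,
    write_results,
)

logger = logging.getLogger("scorigin")


@dataclass
class RunConfig:
    """Paths, stage toggles and parameters for one pipeline run."""

    query_dir: str
    reference_dir: str
    annotations: str
    out_dir: str
    ref_annotations: str | None = None
    allele_counts: str | None = None
    run_demux: bool = False
    # blood/tissue parameters
    immune_types: tuple[str, ...] | None = None
    min_cells: int = 20
    n_hvg: int = 2000
    latent_dim: int = 10
    embed_method: str = "umap"
    k: int = 2
    # demux parameters
    n_origins: int = 2
    max_maf: float = 10.0
    error_rate: float = 0.01
    doublet_rate: float = 0.05
    confidence_threshold: float = 0.8
    anchor_type: str | None = None
    anchor_label: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.run_demux and not self.allele_counts:
            raise ConfigError("demux stage requested but no allele-count path given")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(d)
        if "immune_types" in cfg and cfg["immune_types"] is not None:
            cfg["immune_types"] = tuple(cfg["immune_types"])
        return cls(**cfg)


def run(config: RunConfig) -> pd.DataFrame:
    """Execute the configured stages and write results under out_dir.

    Writes ``results.tsv`` (one row per barcode with compartment and
    origin calls), ``demux_posteriors.tsv`` when the demux stage runs, and
    ``manifest.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("reading query matrix from %s", config.query_dir)
    query = read_10x_mtx(config.query_dir)
    reference = read_10x_mtx(config.reference_dir)
    ann = read_annotations(config.annotations)
    ref_ann = (
        read_annotations(config.ref_annotations) if config.ref_annotations else None
    )

    bt_config = BloodTissueConfig(
        min_cells=config.min_cells,
        n_hvg=config.n_hvg,
        latent_dim=config.latent_dim,
        embed_method=config.embed_method,
        k=config.k,
        seed=config.seed,
    )
    if config.immune_types is not None:
        bt_config.immune_types = tuple(config.immune_types)

    logger.info("blood/tissue classification (%d cells)", query.n_cells)
    ann = classify(query, ann, reference, bt_config, ref_ann=ref_ann)

    if config.run_demux:
        logger.info("genotype demultiplexing from %s", config.allele_counts)
        counts = read_allele_counts(config.allele_counts)
        counts = filter_snps(counts, max_maf=config.max_maf)
        model, _ = fit_mixture(
            counts,
            n_origins=config.n_origins,
            seed=config.seed,
            error_rate=config.error_rate,
            doublet_rate=config.doublet_rate,
        )
        results = call_doublets(counts, model, threshold=config.confidence_threshold)
        if config.anchor_type and config.anchor_label:
            results = label_origins(
                results, ann, config.anchor_type, config.anchor_label
            )
            call_col = "origin_label"
        else:
            call_col = "call"
        calls = results.set_index("barcode")[call_col]
        ann["origin"] = (
            ann["barcode"].map(calls).fillna("unassigned").astype(str)
        )
        ann["doublet_flag"] = ann["origin"] == "doublet"
        results.to_csv(out_dir / "demux_posteriors.tsv", sep="\t", index=False)
    else:
        if "origin" not in ann.columns:
            ann["origin"] = "unassigned"
        ann["doublet_flag"] = False

    write_results(ann, out_dir / "results.tsv")

    manifest = {
        "package": "scorigin",
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_query_cells": query.n_cells,
        "n_reference_cells": reference.n_cells,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    logger.info("results written to %s", out_dir)
    return ann
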