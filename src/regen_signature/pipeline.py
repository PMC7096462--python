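"""End-to-end pipeline: simulate/load -> DE -> classify -> cluster -> enrich.

Each stage writes plain-text outputs (TSV, GMT, Newick, JSON) into the
output directory and the run ends with a manifest recording the config,
package version, seed and a SHA-256 checksum of every artifact, so a rerun
with the same config and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import build_profile_matrix, cluster_contrasts, tree_to_newick
from .de import run_all_contrasts
from .enrichment import (
    EnrichmentLabelConfig,
    GeneSetCatalog,
    label_enriched_sets,
    per_pair_set_test,
)
from .signature import (
    ClassifierThresholds,
    PanelConfig,
    call_regeneration_associated,
    classify_table,
)
from .simulate import CountMatrix, SimConfig, simulate_counts, simulate_geneset_catalog

log = logging.getLogger("regen_signature")

__all__ = ["PipelineError", "ValidationError", "load_config", "validate_inputs", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


class ValidationError(ValueError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path) -> dict:
    """Load a YAML/JSON pipeline config document."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return cfg


def validate_inputs(counts_path, sheet_path, gmt_path=None) -> list[str]:
    """Validate on-disk inputs; returns a list of human-readable issues.

    Checks duplicated gene ids, negative or non-integer counts, samples
    present in only one of matrix/sheet, malformed condition labels and
    empty gene sets. An empty report means the inputs are usable.
    """
    issues: list[str] = []
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sheet_path, sep="\t", index_col=0)

    dup = counts.index[counts.index.duplicated()].unique()
    for g in dup:
        issues.append(f"{counts_path}: duplicate gene id {g!r}")
    num = counts.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() | (num < 0) | (num != num.round())
    if bad.to_numpy().any():
        for gene, sample in zip(*bad.to_numpy().nonzero()):
            issues.append(
                f"{counts_path}: invalid count for gene {counts.index[gene]!r} "
                f"sample {counts.columns[sample]!r} (value {counts.iat[gene, sample]!r})"
            )
            if len(issues) > 50:
                break
    orphans = set(sheet.index) - set(counts.columns)
    for s in sorted(orphans):
        issues.append(f"{sheet_path}: sample {s!r} not present in count matrix")
    unsheeted = set(counts.columns) - set(sheet.index)
    for s in sorted(unsheeted):
        issues.append(f"{counts_path}: sample {s!r} missing from sample sheet")
    if "pair_id" not in sheet.columns or "condition" not in sheet.columns:
        issues.append(f"{sheet_path}: needs 'pair_id' and 'condition' columns")
    else:
        bad_cond = sheet.index[~sheet["condition"].isin(["wt", "mut"])]
        for s in bad_cond:
            issues.append(f"{sheet_path}: sample {s!r} has condition {sheet.loc[s, 'condition']!r}")

    if gmt_path is not None:
        catalog = GeneSetCatalog.read_gmt(gmt_path)
        for name, members in catalog.sets.items():
            if len(members) == 0:
                issues.append(f"{gmt_path}: gene set {name!r} is empty")
    return issues


def _panel_from_config(cfg: dict) -> PanelConfig:
    block = cfg.get("panel", {})
    kwargs = {}
    if "regen_pairs" in block:
        kwargs["regen_pairs"] = tuple(block["regen_pairs"])
    if "nonregen_pairs" in block:
        kwargs["nonregen_pairs"] = tuple(block["nonregen_pairs"])
    return PanelConfig(**kwargs)


def run_pipeline(cfg: dict, outdir, seed: int | None = None) -> dict:
    """Run every stage and return the manifest (also written to disk).

    ``cfg`` carries either a ``simulate`` block (synthetic mode) or an
    ``inputs`` block with counts/sample-sheet/GMT paths, plus optional
    ``panel``, ``thresholds``, ``enrichment`` and ``clustering`` blocks.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if ("simulate" in cfg) == ("inputs" in cfg):
        raise ValidationError("config must contain exactly one of 'simulate' or 'inputs'")

    panel = _panel_from_config(cfg)
    thr = ClassifierThresholds(**cfg.get("thresholds", {}))
    ecfg = EnrichmentLabelConfig(**cfg.get("enrichment", {}))
    clus = cfg.get("clustering", {})
    agg_mode = cfg.get("aggregation_mode", "intersection")
    margin_mode = cfg.get("margin_mode", "mirrored")
    artifacts: list[Path] = []

    # -- stage 1: obtain counts and catalog -------------------------------
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"])
        cat_kwargs = sim_kwargs.pop("catalog", {})
        if seed is not None:
            sim_kwargs["seed"] = int(seed)
        sim = SimConfig(**sim_kwargs)
        log.info("simulate: %d genes, %d pairs, seed %d", sim.n_genes, len(sim.pair_ids), sim.seed)
        cm, truth = simulate_counts(sim)
        catalog, planted = simulate_geneset_catalog(truth, seed=sim.seed, **cat_kwargs)
        cm.to_tsv(outdir / "counts.tsv", outdir / "sample_sheet.tsv")
        truth.to_tsv(outdir / "sim_truth.tsv")
        catalog.write_gmt(outdir / "gene_sets.gmt")
        (outdir / "planted_sets.json").write_text(json.dumps(planted, indent=1))
        artifacts += [
            outdir / "counts.tsv",
            outdir / "sample_sheet.tsv",
            outdir / "sim_truth.tsv",
            outdir / "gene_sets.gmt",
            outdir / "planted_sets.json",
        ]
    else:
        paths = cfg["inputs"]
        issues = validate_inputs(paths["counts"], paths["sample_sheet"], paths.get("gene_sets"))
        if issues:
            raise ValidationError("input validation failed:\n" + "\n".join(issues))
        cm = CountMatrix.from_tsv(paths["counts"], paths["sample_sheet"])
        catalog = GeneSetCatalog.read_gmt(paths["gene_sets"]) if paths.get("gene_sets") else None

    # -- stage 2: per-pair differential expression ------------------------
    log.info("de: testing %d pairs", cm.sample_sheet["pair_id"].nunique())
    contrasts = run_all_contrasts(cm.counts, cm.sample_sheet)
    for pair_id, ct in contrasts.items():
        p = outdir / f"contrast_{pair_id}.tsv"
        ct.to_tsv(p)
        artifacts.append(p)

    # -- stage 3: signature classification --------------------------------
    calls = classify_table(contrasts, panel, thr, margin_mode=margin_mode)
    calls = call_regeneration_associated(calls, panel, mode=agg_mode)
    sig_path = outdir / "signature_calls.tsv"
    with open(sig_path, "w") as fh:
        fh.write(f"# aggregation_mode={agg_mode} margin_mode={margin_mode}\n")
        calls.to_csv(fh, sep="\t")
    (outdir / "thresholds.json").write_text(
        json.dumps({"classifier": asdict(thr), "enrichment": asdict(ecfg)}, indent=1)
    )
    artifacts += [sig_path, outdir / "thresholds.json"]
    n_up = int((calls["regeneration_associated"] == "up").sum())
    n_down = int((calls["regeneration_associated"] == "down").sum())
    log.info("classify: %d up, %d down regeneration-associated genes", n_up, n_down)

    # -- stage 4: clustering on fold-change profiles ----------------------
    pair_order = [p for p in panel.all_pairs if p in contrasts]
    pair_order += [p for p in contrasts if p not in pair_order]
    profiles = build_profile_matrix(contrasts, tuple(pair_order))
    tree = cluster_contrasts(
        profiles,
        metric=clus.get("metric", "correlation"),
        linkage=clus.get("linkage", "average"),
    )
    (outdir / "dendrogram.nwk").write_text(tree_to_newick(tree) + "\n")
    tree.merge_table().to_csv(outdir / "merges.tsv", sep="\t", index=False)
    artifacts += [outdir / "dendrogram.nwk", outdir / "merges.tsv"]

    # -- stage 5: gene-set enrichment -------------------------------------
    if catalog is not None:
        universe = frozenset(profiles.index)
        catalog = GeneSetCatalog(
            sets=catalog.sets, universe=universe, descriptions=catalog.descriptions
        )
        per_pair = per_pair_set_test(contrasts, catalog)
        per_pair.to_csv(outdir / "per_pair_enrichment.tsv", sep="\t")
        assoc = set(calls.index[calls["regeneration_associated"] != "none"])
        eff = catalog.effective_sets()
        assoc_counts = {name: len(assoc & members) for name, members in eff.items()}
        labeled = label_enriched_sets(
            per_pair, panel.regen_pairs, panel.nonregen_pairs, ecfg, assoc_counts,
            reading=cfg.get("enrichment_reading", "significance"),
        )
        labeled.to_csv(outdir / "enriched_sets.tsv", sep="\t")
        artifacts += [outdir / "per_pair_enrichment.tsv", outdir / "enriched_sets.tsv"]
        log.info("enrich: %d sets labeled enriched", int(labeled["enriched"].sum()))

    # -- manifest ----------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": int(seed) if seed is not None else cfg.get("simulate", {}).get("seed"),
        "config": cfg,
        "checksums": {p.name: _sha256(p) for p in artifacts},
        "elapsed_seconds": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
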