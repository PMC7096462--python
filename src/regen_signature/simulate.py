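"""Synthetic count matrices with planted cross-contrast DE structure.

The generator emulates the design of a seven-contrast SMN-complex mutant
panel: each contrast pairs wildtype against one homozygous mutant (S1 =
smn1, G2-G7 = gemin2..gemin7), with a block of genes up- or down-regulated
in the regeneration-essential mutants only (S1, G3, G5), smaller blocks of
genes perturbed in exactly one contrast, and a null majority. Counts are
negative-binomial with ``var = mu + alpha * mu**2``, log-normal baseline
means and log-uniform per-sample depth factors, so downstream normalization
and dispersion estimation are exercised nontrivially.

Every planted effect is recorded in a :class:`SimTruth` ledger, which makes
recovery, type-I-error and clustering properties directly testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSetCatalog

__all__ = ["SimConfig", "SimTruth", "CountMatrix", "simulate_counts", "simulate_geneset_catalog"]

DEFAULT_PAIR_IDS = ("S1", "G2", "G3", "G4", "G5", "G6", "G7")
DEFAULT_REGEN_PAIRS = ("S1", "G3", "G5")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic seven-contrast experiment.

    Defaults describe the study conditions used throughout the test suite:
    2000 genes, 3 replicates per condition, a shared block of 100 up- and
    100 down-regulated genes planted in the regeneration pairs only at
    |log2FC| = 1.5, 25 contrast-specific genes per pair, NB dispersion 0.1,
    log-normal baseline means centred at 100 counts, and per-sample depth
    factors log-uniform in [0.5, 2].
    """

    n_genes: int = 2000
    n_replicates: int = 3
    pair_ids: tuple[str, ...] = DEFAULT_PAIR_IDS
    regen_pairs: tuple[str, ...] = DEFAULT_REGEN_PAIRS
    n_shared_up: int = 100
    n_shared_down: int = 100
    n_specific_per_pair: int = 25
    effect_log2fc: float = 1.5
    mean_log_mu: float = math.log(100.0)
    sd_log_mu: float = 1.0
    dispersion: float = 0.1
    library_size_spread: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.regen_pairs) <= set(self.pair_ids):
            raise ValueError("regen_pairs must be a subset of pair_ids")
        if min(self.n_shared_up, self.n_shared_down, self.n_specific_per_pair) < 0:
            raise ValueError("planted gene counts must be non-negative")
        planted = self.n_shared_up + self.n_shared_down + self.n_specific_per_pair * len(self.pair_ids)
        if planted > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.n_replicates < 2:
            raise ValueError("need >=2 replicates per condition")
        lo, hi = self.library_size_spread
        if not (0 < lo <= hi):
            raise ValueError("library_size_spread must satisfy 0 < lo <= hi")


@dataclass
class SimTruth:
    """Ledger of planted effects.

    ``category`` assigns each gene to ``shared_up``, ``shared_down``,
    ``specific:<pair>`` or ``null``; ``log2fc`` holds the true signed effect
    per gene and pair (0 where null).
    """

    category: pd.Series = field(repr=False)
    log2fc: pd.DataFrame = field(repr=False)

    def genes_in_category(self, category: str) -> list[str]:
        return list(self.category.index[self.category == category])

    @property
    def shared_genes(self) -> list[str]:
        return list(self.category.index[self.category.isin(["shared_up", "shared_down"])])

    def to_tsv(self, path) -> None:
        out = self.log2fc.copy()
        out.insert(0, "category", self.category)
        out.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path) -> "SimTruth":
        # keep_default_na: the "null" category is a literal label, not NaN
        df = pd.read_csv(path, sep="\t", index_col="gene", keep_default_na=False)
        lfc = df.drop(columns="category").astype(float)
        return cls(category=df["category"], log2fc=lfc)


@dataclass
class CountMatrix:
    """Integer gene x sample counts with a sample sheet.

    ``sample_sheet`` is indexed by sample id with columns ``pair_id`` and
    ``condition`` (``wt`` or ``mut``).
    """

    counts: pd.DataFrame = field(repr=False)
    sample_sheet: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.sample_sheet.index):
            raise ValueError("count columns and sample sheet rows must match in order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def to_tsv(self, counts_path, sheet_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene")
        self.sample_sheet.to_csv(sheet_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path, sheet_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
        sheet = pd.read_csv(sheet_path, sep="\t", index_col="sample_id")
        counts.columns.name = sheet.index.name
        return cls(counts=counts, sample_sheet=sheet)


def _plant_truth(config: SimConfig, rng: np.random.Generator) -> SimTruth:
    genes = [f"gene_{i:05d}" for i in range(config.n_genes)]
    category = pd.Series("null", index=pd.Index(genes, name="gene"), name="category")
    lfc = pd.DataFrame(0.0, index=category.index, columns=list(config.pair_ids))

    if config.effect_log2fc > 0:
        cursor = 0
        up = genes[cursor : cursor + config.n_shared_up]
        cursor += config.n_shared_up
        down = genes[cursor : cursor + config.n_shared_down]
        cursor += config.n_shared_down
        category.loc[up] = "shared_up"
        category.loc[down] = "shared_down"
        for pair in config.regen_pairs:
            lfc.loc[up, pair] = config.effect_log2fc
            lfc.loc[down, pair] = -config.effect_log2fc
        for pair in config.pair_ids:
            block = genes[cursor : cursor + config.n_specific_per_pair]
            cursor += config.n_specific_per_pair
            category.loc[block] = f"specific:{pair}"
            signs = rng.choice([-1.0, 1.0], size=len(block))
            lfc.loc[block, pair] = signs * config.effect_log2fc
    return SimTruth(category=category, log2fc=lfc)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw a seeded NB count matrix for the full seven-contrast panel.

    The mutant-condition mean of gene ``g`` in pair ``j`` is
    ``baseline_mean(g) * depth(sample) * 2**true_log2fc(g, j)``; wildtype
    omits the fold-change term. A zero ``effect_log2fc`` yields an all-null
    truth ledger regardless of the requested block sizes.
    """
    rng = np.random.default_rng(config.seed)
    truth = _plant_truth(config, rng)

    sample_ids, pair_col, cond_col = [], [], []
    for pair in config.pair_ids:
        for cond in ("wt", "mut"):
            for r in range(1, config.n_replicates + 1):
                sample_ids.append(f"{pair}_{cond}{r}")
                pair_col.append(pair)
                cond_col.append(cond)
    sheet = pd.DataFrame(
        {"pair_id": pair_col, "condition": cond_col},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    mu0 = rng.lognormal(config.mean_log_mu, config.sd_log_mu, size=config.n_genes)
    lo, hi = config.library_size_spread
    depth = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(sample_ids)))

    fold = np.ones((config.n_genes, len(sample_ids)))
    for j, (pair, cond) in enumerate(zip(pair_col, cond_col)):
        if cond == "mut":
            fold[:, j] = 2.0 ** truth.log2fc[pair].to_numpy()
    mean = mu0[:, None] * depth[None, :] * fold

    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        counts = rng.negative_binomial(shape, shape / (shape + mean))
    else:
        counts = rng.poisson(mean)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=truth.category.index, columns=sheet.index),
        sample_sheet=sheet,
    )
    return cm, truth


def simulate_geneset_catalog(
    truth: SimTruth,
    n_sets: int = 100,
    set_size_range: tuple[int, int] = (20, 200),
    n_enriched_sets: int = 10,
    enrichment_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[GeneSetCatalog, list[str]]:
    """Build a GMT-serializable catalog with planted enriched sets.

    The first ``n_enriched_sets`` sets draw ``enrichment_fraction`` of their
    members from the shared (regeneration-signature) genes and the rest
    uniformly from the remaining universe; background sets are uniform
    draws. Returns the catalog and the names of the planted sets.
    """
    if not (0 <= enrichment_fraction <= 1):
        raise ValueError("enrichment_fraction must be in [0, 1]")
    if n_enriched_sets > n_sets:
        raise ValueError("n_enriched_sets cannot exceed n_sets")
    lo, hi = set_size_range
    universe = list(truth.category.index)
    if not (0 < lo <= hi <= len(universe)):
        raise ValueError("set sizes must fit within the universe")

    rng = np.random.default_rng(seed)
    shared = truth.shared_genes
    max_planted = round(enrichment_fraction * hi)
    if enrichment_fraction > 0 and max_planted > len(shared):
        raise ValueError(
            f"requested up to {max_planted} planted members per set but only "
            f"{len(shared)} shared genes are available"
        )

    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    planted_names = []
    width = len(str(n_sets))
    for i in range(n_sets):
        name = f"set_{i + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched_sets and enrichment_fraction > 0:
            k = min(round(enrichment_fraction * size), len(shared))
            core = list(rng.choice(shared, size=k, replace=False))
            rest_pool = [g for g in universe if g not in set(core)]
            rest = list(rng.choice(rest_pool, size=size - k, replace=False))
            members = sorted(core + rest)
            planted_names.append(name)
            descriptions[name] = "planted"
        else:
            members = sorted(rng.choice(universe, size=size, replace=False))
            descriptions[name] = "background"
        sets[name] = tuple(members)

    catalog = GeneSetCatalog(sets=sets, universe=frozenset(universe), descriptions=descriptions)
    return catalog, planted_names
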