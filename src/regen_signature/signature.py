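"""Cross-contrast signature classification of regeneration-associated genes.

A gene is labeled ``X-up`` for a regeneration pair X (S1, G3 or G5) when it
is significantly up-regulated in X (fdr < 0.05, positive log2FC), not
significant in any non-regeneration pair (p >= 0.1 and fdr >= 0.25), and
every non-regeneration log2FC sits at least a 0.2 log2-unit margin below
X's log2FC. ``X-down`` mirrors the rule with signs flipped: under the
default ``mirrored`` margin reading each non-regeneration log2FC must sit
at least the margin above X's (i.e. closer to zero), which is the reading
under which the margin enforces specificity; the ``literal`` reading keeps
the printed inequality direction for down genes and is retained for
comparison (docs/methods.md).

Genes labeled across the regeneration pairs are aggregated into the
regeneration-associated up/down lists, by intersection (default) or union.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .de import ContrastTable

__all__ = [
    "PanelConfig",
    "ClassifierThresholds",
    "ContrastRow",
    "classify_gene",
    "classify_table",
    "call_regeneration_associated",
]


@dataclass(frozen=True)
class PanelConfig:
    """Which contrasts are regeneration pairs and which are specificity controls."""

    regen_pairs: tuple[str, ...] = ("S1", "G3", "G5")
    nonregen_pairs: tuple[str, ...] = ("G2", "G4", "G6", "G7")

    def __post_init__(self) -> None:
        if not self.regen_pairs or not self.nonregen_pairs:
            raise ValueError("both pair groups must be non-empty")
        if set(self.regen_pairs) & set(self.nonregen_pairs):
            raise ValueError("regen and non-regen pairs must be disjoint")

    @property
    def all_pairs(self) -> tuple[str, ...]:
        return self.regen_pairs + self.nonregen_pairs


@dataclass(frozen=True)
class ClassifierThresholds:
    """Significance, non-significance and fold-change-margin thresholds.

    Significance is strict (``fdr < fdr_sig``); non-significance in the
    control pairs requires ``p >= p_nonsig`` and ``fdr >= fdr_nonsig``;
    ``margin_log2`` is the minimum log2 fold-change separation between the
    qualifying regeneration pair and every control pair.
    """

    fdr_sig: float = 0.05
    p_nonsig: float = 0.1
    fdr_nonsig: float = 0.25
    margin_log2: float = 0.2

    def __post_init__(self) -> None:
        if min(self.fdr_sig, self.p_nonsig, self.fdr_nonsig) <= 0:
            raise ValueError("thresholds must be positive")
        if self.margin_log2 < 0:
            raise ValueError("margin_log2 must be >= 0")
        if self.fdr_sig >= self.fdr_nonsig:
            raise ValueError("fdr_sig must be below fdr_nonsig")


class ContrastRow(NamedTuple):
    """One gene's statistics in one contrast."""

    log2fc: float
    p_value: float
    fdr: float


def classify_gene(
    rows: Mapping[str, ContrastRow],
    panel: PanelConfig = PanelConfig(),
    thr: ClassifierThresholds = ClassifierThresholds(),
    margin_mode: str = "mirrored",
) -> frozenset[str] | None:
    """Label one gene across the panel; None if untestable.

    ``rows`` maps pair id to that gene's (log2fc, p_value, fdr). A gene
    missing any pair of the panel, or carrying NaN statistics, is
    untestable and returns None rather than an empty label set.
    """
    if margin_mode not in ("mirrored", "literal"):
        raise ValueError("margin_mode must be 'mirrored' or 'literal'")
    needed = panel.all_pairs
    for pair in needed:
        r = rows.get(pair)
        if r is None or any(np.isnan(v) for v in r):
            return None

    nonsig = all(
        rows[j].p_value >= thr.p_nonsig and rows[j].fdr >= thr.fdr_nonsig
        for j in panel.nonregen_pairs
    )
    labels = set()
    for x in panel.regen_pairs:
        rx = rows[x]
        if rx.fdr < thr.fdr_sig and rx.log2fc > 0 and nonsig:
            if all(rows[j].log2fc <= rx.log2fc - thr.margin_log2 for j in panel.nonregen_pairs):
                labels.add(f"{x}-up")
        if rx.fdr < thr.fdr_sig and rx.log2fc < 0 and nonsig:
            if margin_mode == "mirrored":
                ok = all(
                    rows[j].log2fc >= rx.log2fc + thr.margin_log2
                    for j in panel.nonregen_pairs
                )
            else:
                ok = all(
                    rows[j].log2fc <= rx.log2fc + thr.margin_log2
                    for j in panel.nonregen_pairs
                )
            if ok:
                labels.add(f"{x}-down")
    return frozenset(labels)


def classify_table(
    contrasts: Mapping[str, ContrastTable],
    panel: PanelConfig = PanelConfig(),
    thr: ClassifierThresholds = ClassifierThresholds(),
    margin_mode: str = "mirrored",
) -> pd.DataFrame:
    """Vectorized classification of every gene shared across the panel.

    Returns a frame indexed by gene with one column per regeneration pair
    taking values ``up`` / ``down`` / ``none``, plus a boolean ``testable``
    column. Untestable genes (missing or NaN in any panel contrast) carry
    ``none`` everywhere and ``testable = False``.
    """
    if margin_mode not in ("mirrored", "literal"):
        raise ValueError("margin_mode must be 'mirrored' or 'literal'")
    missing = [p for p in panel.all_pairs if p not in contrasts]
    if missing:
        raise KeyError(f"contrasts missing for pairs: {missing}")

    genes = contrasts[panel.all_pairs[0]].table.index
    for p in panel.all_pairs[1:]:
        genes = genes.intersection(contrasts[p].table.index)
    genes = genes.sort_values()

    def stat(pair: str, col: str) -> np.ndarray:
        return contrasts[pair].table.loc[genes, col].to_numpy(dtype=float)

    lfc = {p: stat(p, "log2fc") for p in panel.all_pairs}
    pval = {p: stat(p, "p_value") for p in panel.all_pairs}
    fdr = {p: stat(p, "fdr") for p in panel.all_pairs}

    testable = np.ones(len(genes), dtype=bool)
    for p in panel.all_pairs:
        testable &= ~np.isnan(lfc[p]) & ~np.isnan(pval[p]) & ~np.isnan(fdr[p])

    with np.errstate(invalid="ignore"):
        nonsig = testable.copy()
        for j in panel.nonregen_pairs:
            nonsig &= (pval[j] >= thr.p_nonsig) & (fdr[j] >= thr.fdr_nonsig)

        out = pd.DataFrame(index=genes)
        for x in panel.regen_pairs:
            up = (fdr[x] < thr.fdr_sig) & (lfc[x] > 0) & nonsig
            down = (fdr[x] < thr.fdr_sig) & (lfc[x] < 0) & nonsig
            for j in panel.nonregen_pairs:
                up &= lfc[j] <= lfc[x] - thr.margin_log2
                if margin_mode == "mirrored":
                    down &= lfc[j] >= lfc[x] + thr.margin_log2
                else:
                    down &= lfc[j] <= lfc[x] + thr.margin_log2
            out[x] = np.select([up, down], ["up", "down"], default="none")
    out["testable"] = testable
    out.index.name = "gene"
    return out


def call_regeneration_associated(
    calls: pd.DataFrame,
    panel: PanelConfig = PanelConfig(),
    mode: str = "intersection",
) -> pd.DataFrame:
    """Aggregate per-pair labels into regeneration-associated up/down calls.

    ``intersection`` (default) requires the same direction in every
    regeneration pair; ``union`` accepts any. Adds a
    ``regeneration_associated`` column in {``up``, ``down``, ``none``}.
    """
    if mode not in ("intersection", "union"):
        raise ValueError("mode must be 'intersection' or 'union'")
    cols = [calls[p] for p in panel.regen_pairs]
    if mode == "intersection":
        up = np.logical_and.reduce([c == "up" for c in cols])
        down = np.logical_and.reduce([c == "down" for c in cols])
    else:
        up = np.logical_or.reduce([c == "up" for c in cols])
        down = np.logical_or.reduce([c == "down" for c in cols])
    out = calls.copy()
    out["regeneration_associated"] = np.select([up, down], ["up", "down"], default="none")
    out.attrs["aggregation_mode"] = mode
    return out
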