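"""Fisher-exact over-representation analysis and cross-contrast set labeling.

Gene sets come from any GMT catalog (KEGG, GO, InterPro exports, or the
synthetic catalog bundled with this package). The universe is the set of
genes tested in every contrast — the only genes for which the cross-contrast
signature rule is defined.

Beyond plain over-representation of the regeneration-associated gene list,
the module implements the study-specific labeling rule: a set is called
enriched when it is over-represented (odds ratio > 1 plus a significance
condition) among the differentially expressed genes of at least one
regeneration pair (S1, G3, G5), strictly less significant in every
non-regeneration pair (G2, G4, G6, G7), within size bounds, and backed by a
minimum number of regeneration-associated members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .de import ContrastTable, bh_adjust

__all__ = [
    "GeneSetCatalog",
    "EnrichmentLabelConfig",
    "fisher_ora",
    "per_pair_set_test",
    "label_enriched_sets",
]


@dataclass
class GeneSetCatalog:
    """Named gene sets plus the analysis universe.

    ``sets`` maps set name to an ordered tuple of member ids. Members
    outside ``universe`` are ignored during testing (``effective_sets``).
    """

    sets: dict[str, tuple[str, ...]]
    universe: frozenset[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sets) != len(set(self.sets)):
            raise ValueError("gene set names must be unique")

    def effective_sets(self) -> dict[str, frozenset[str]]:
        """Sets intersected with the universe."""
        return {name: frozenset(m) & self.universe for name, m in self.sets.items()}

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "na")
                fh.write("\t".join([name, desc, *members]) + "\n")

    @classmethod
    def read_gmt(cls, path, universe: Iterable[str] | None = None) -> "GeneSetCatalog":
        """Parse a GMT file (name, description, tab-separated members).

        If ``universe`` is None it defaults to the union of all members.
        """
        sets: dict[str, tuple[str, ...]] = {}
        descriptions: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
                name, desc, *members = parts
                if name in sets:
                    raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
                sets[name] = tuple(members)
                descriptions[name] = desc
        if universe is None:
            universe = frozenset(g for m in sets.values() for g in m)
        return cls(sets=sets, universe=frozenset(universe), descriptions=descriptions)


@dataclass(frozen=True)
class EnrichmentLabelConfig:
    """Thresholds and filters for the enriched-set labeling rule.

    ``sig_fdr`` / ``sig_p``: a regeneration pair qualifies when its odds
    ratio exceeds 1 and (fdr < sig_fdr or p < sig_p) under the default
    significance reading (see ``label_enriched_sets``). Sets with fewer than
    ``min_set`` or more than ``max_set`` members in the universe, or fewer
    than ``min_assoc`` regeneration-associated members, are removed.
    """

    sig_fdr: float = 0.1
    sig_p: float = 0.01
    min_set: int = 10
    max_set: int = 500
    min_assoc: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.sig_fdr <= 1 and 0 < self.sig_p <= 1):
            raise ValueError("sig_fdr and sig_p must be in (0, 1]")
        if not (0 < self.min_set < self.max_set):
            raise ValueError("need 0 < min_set < max_set")
        if self.min_assoc < 1:
            raise ValueError("min_assoc must be >= 1")


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio ad/bc; Haldane-Anscombe +0.5 per cell when any cell is 0."""
    if min(a, b, c, d) == 0:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return (a * d) / (b * c)


def fisher_ora(
    associated: Iterable[str],
    catalog: GeneSetCatalog,
    min_set: int | None = None,
    max_set: int | None = None,
) -> pd.DataFrame:
    """Two-sided Fisher exact over-representation of a gene list per set.

    For each set the 2x2 table is (a = associated in set, b = associated
    outside, c = set minus associated, d = neither); p-values come from the
    exact hypergeometric two-sided test on the unmodified table, and FDRs
    are BH-adjusted across tested sets. Sets outside ``[min_set, max_set]``
    (counted within the universe) are excluded before testing.

    Odds ratios use the Haldane-Anscombe 0.5 correction only when a cell is
    zero; inference never uses the corrected table.
    """
    universe = catalog.universe
    if not universe:
        raise ValueError("empty universe")
    assoc = frozenset(associated)
    stray = assoc - universe
    if stray:
        raise ValueError(
            f"{len(stray)} associated genes outside the universe (e.g. {sorted(stray)[:3]})"
        )
    n_universe = len(universe)
    n_assoc = len(assoc)

    rows = []
    for name, members in catalog.effective_sets().items():
        size = len(members)
        if min_set is not None and size < min_set:
            continue
        if max_set is not None and size > max_set:
            continue
        a = len(assoc & members)
        b = n_assoc - a
        c = size - a
        d = n_universe - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((name, size, a, b, c, d, _odds_ratio(a, b, c, d), p))

    df = pd.DataFrame(
        rows,
        columns=["set", "set_size", "a", "b", "c", "d", "odds_ratio", "p_value"],
    ).set_index("set")
    if len(df):
        df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    else:
        df["fdr"] = pd.Series(dtype=float)
    df.attrs["n_associated"] = n_assoc
    df.attrs["empty_foreground"] = n_assoc == 0
    return df


def per_pair_set_test(
    contrasts: Mapping[str, ContrastTable],
    catalog: GeneSetCatalog,
    de_fdr: float = 0.05,
    min_set: int | None = None,
    max_set: int | None = None,
) -> pd.DataFrame:
    """Fisher ORA of each pair's DE genes (fdr < de_fdr) against each set.

    Returns one row per (set, pair), indexed by set with a ``pair`` column.
    """
    frames = []
    for pair_id, ct in contrasts.items():
        de = [g for g in ct.de_genes(de_fdr) if g in catalog.universe]
        res = fisher_ora(de, catalog, min_set=min_set, max_set=max_set)
        res = res.assign(pair=pair_id)
        frames.append(res)
    return pd.concat(frames)


def label_enriched_sets(
    per_pair_results: pd.DataFrame,
    regen_pairs: Iterable[str],
    nonregen_pairs: Iterable[str],
    cfg: EnrichmentLabelConfig,
    assoc_counts: Mapping[str, int],
    reading: str = "significance",
) -> pd.DataFrame:
    """Label sets enriched specifically in regeneration pairs.

    A set is labeled enriched when all of the following hold:

    * in at least one regeneration pair its odds ratio exceeds 1 and the
      significance condition holds — under the default ``significance``
      reading that is ``fdr < sig_fdr or p < sig_p``; the ``literal``
      reading inverts both inequalities (``fdr > sig_fdr or p > sig_p``),
      which turns the clause into a non-significance condition and is kept
      only for comparison (see docs/methods.md);
    * every non-regeneration pair is strictly less significant, i.e. its
      p-value exceeds the smallest qualifying regeneration-pair p;
    * the set size in the universe lies in ``[min_set, max_set]`` and the
      set contains at least ``min_assoc`` regeneration-associated genes.

    Parameters
    ----------
    per_pair_results
        Output of :func:`per_pair_set_test` covering every pair.
    assoc_counts
        Per-set count of regeneration-associated members.
    """
    if reading not in ("significance", "literal"):
        raise ValueError("reading must be 'significance' or 'literal'")
    regen_pairs = list(regen_pairs)
    nonregen_pairs = list(nonregen_pairs)
    all_pairs = set(regen_pairs) | set(nonregen_pairs)
    present = set(per_pair_results["pair"].unique())
    missing = all_pairs - present
    if missing:
        raise ValueError(f"missing per-pair results for pairs: {sorted(missing)}")

    rows = []
    for set_name, sub in per_pair_results.groupby(level=0, sort=True):
        sub = sub.set_index("pair")
        if not all_pairs <= set(sub.index):
            raise ValueError(f"set {set_name!r} lacks results for some pairs")
        size = int(sub["set_size"].iloc[0])
        n_assoc = int(assoc_counts.get(set_name, 0))
        failing = None
        if size < cfg.min_set or size > cfg.max_set:
            failing = "set_size"
        elif n_assoc < cfg.min_assoc:
            failing = "min_assoc"

        qualifying = []
        for pr in regen_pairs:
            r = sub.loc[pr]
            if r["odds_ratio"] <= 1:
                continue
            if reading == "significance":
                sig = (r["fdr"] < cfg.sig_fdr) or (r["p_value"] < cfg.sig_p)
            else:
                sig = (r["fdr"] > cfg.sig_fdr) or (r["p_value"] > cfg.sig_p)
            if sig:
                qualifying.append(pr)

        enriched = False
        min_regen_p = np.nan
        if failing is None and qualifying:
            min_regen_p = float(sub.loc[qualifying, "p_value"].min())
            enriched = bool(
                all(sub.loc[pr, "p_value"] > min_regen_p for pr in nonregen_pairs)
            )
        rows.append(
            {
                "set": set_name,
                "set_size": size,
                "n_associated": n_assoc,
                "qualifying_pairs": ",".join(qualifying),
                "min_regen_p": min_regen_p,
                "failing_filter": failing or "",
                "enriched": enriched,
            }
        )
    return pd.DataFrame(rows).set_index("set")
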