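"""Per-contrast negative-binomial differential expression.

Implements the classic bulk RNA-seq workflow for a single wildtype-vs-mutant
contrast: median-of-ratios size-factor normalization, gene-wise
method-of-moments dispersion estimation under the NB variance model
``var = mu + alpha * mu**2``, a Wald test on the log2 fold change with a
delta-method standard error, and Benjamini-Hochberg FDR across all tested
genes of the contrast.

This is a deliberately transparent procedure: dispersions are gene-wise
moment estimates with no empirical-Bayes shrinkage, and fold changes are
not moderated. Recovery of planted effects, not numerical agreement with
any particular external tool, is the correctness contract (see
``docs/methods.md``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContrastTable",
    "NormalizationError",
    "estimate_size_factors",
    "estimate_dispersions",
    "wald_de_test",
    "run_all_contrasts",
    "bh_adjust",
    "DISPERSION_FLOOR",
    "LOG2FC_PSEUDOCOUNT",
]

#: Lower bound for gene-wise dispersion estimates. Avoids degenerate
#: zero-variance Wald statistics when the sample variance falls below the
#: Poisson expectation.
DISPERSION_FLOOR = 1e-8

#: Pseudocount added to normalized condition means before taking log2 ratios,
#: so fold changes stay finite when one condition has zero counts.
LOG2FC_PSEUDOCOUNT = 0.5

_LN2 = np.log(2.0)


class NormalizationError(ValueError):
    """Raised when size factors cannot be estimated from the count matrix."""


@dataclass
class ContrastTable:
    """Per-gene DE summary for one wildtype-mutant pair.

    ``table`` is indexed by gene id with columns ``base_mean``, ``log2fc``,
    ``se_log2fc``, ``wald_stat``, ``p_value`` and ``fdr``. Genes with zero
    counts in both conditions are kept in the index but carry NaN statistics;
    they are excluded from multiple-testing correction.
    """

    pair_id: str
    table: pd.DataFrame = field(repr=False)

    def tested(self) -> pd.DataFrame:
        """Rows with a defined test result."""
        return self.table[self.table["p_value"].notna()]

    def de_genes(self, fdr_threshold: float = 0.05) -> list[str]:
        """Genes significant at ``fdr < fdr_threshold`` (strict inequality)."""
        t = self.table
        return list(t.index[t["fdr"] < fdr_threshold])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", na_rep="NA", index_label="gene")

    @classmethod
    def from_tsv(cls, path, pair_id: str) -> "ContrastTable":
        df = pd.read_csv(path, sep="\t", index_col="gene", na_values=["NA"])
        return cls(pair_id=pair_id, table=df)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample (column).

    Each gene expressed in every sample contributes the ratio of its count
    to its across-sample geometric mean; the per-sample factor is the median
    of those ratios. Genes with a zero count in any sample are excluded from
    the reference.

    Raises
    ------
    NormalizationError
        If no gene has nonzero counts in all samples.
    """
    mat = counts.to_numpy(dtype=float)
    usable = (mat > 0).all(axis=1)
    if not usable.any():
        raise NormalizationError(
            "size-factor estimation failed: no gene has nonzero counts in "
            f"every sample (matrix {mat.shape[0]} genes x {mat.shape[1]} samples)"
        )
    logm = np.log(mat[usable])
    log_geo = logm.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logm - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _condition_columns(sample_sheet: pd.DataFrame, pair_id: str) -> tuple[list, list]:
    rows = sample_sheet[sample_sheet["pair_id"] == pair_id]
    if rows.empty:
        raise KeyError(f"pair {pair_id!r} not present in sample sheet")
    wt = list(rows.index[rows["condition"] == "wt"])
    mut = list(rows.index[rows["condition"] == "mut"])
    if len(wt) < 2 or len(mut) < 2:
        raise ValueError(
            f"pair {pair_id!r} needs >=2 samples per condition "
            f"(got {len(wt)} wt, {len(mut)} mut)"
        )
    return wt, mut


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    sample_sheet: pd.DataFrame,
    pair_id: str,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Gene-wise method-of-moments NB dispersion for one contrast.

    Within each condition the estimate is ``(s^2 - mean) / mean^2`` on
    size-factor-normalized counts; the two condition estimates are averaged
    and floored at ``floor``. Genes with zero mean in both conditions get
    the floor.
    """
    wt, mut = _condition_columns(sample_sheet, pair_id)
    total = np.zeros(counts.shape[0])
    n_used = np.zeros(counts.shape[0])
    for cols in (wt, mut):
        norm = counts[cols].to_numpy(dtype=float) / size_factors[cols].to_numpy()
        m = norm.mean(axis=1)
        v = norm.var(axis=1, ddof=1)
        ok = m > 0
        contrib = np.zeros_like(m)
        contrib[ok] = (v[ok] - m[ok]) / m[ok] ** 2
        total += contrib
        n_used += ok
    alpha = np.where(n_used > 0, total / np.maximum(n_used, 1.0), floor)
    alpha = np.maximum(alpha, floor)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def wald_de_test(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    pair_id: str,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    pseudocount: float = LOG2FC_PSEUDOCOUNT,
) -> ContrastTable:
    """Wald test of mutant-vs-wildtype log2 fold change for one pair.

    The log2 fold change is the log2 ratio of pseudocounted normalized
    condition means. Its standard error comes from the delta method under
    the NB model: the variance of a normalized count with mean ``q`` in
    sample ``i`` is ``q / s_i + alpha * q**2``, so the variance of the
    condition mean is the average of those terms divided by the replicate
    count. The two-sided p-value uses the standard normal reference, and
    BH-adjusted FDRs are computed over all tested genes of the contrast.

    Genes with zero counts in both conditions are reported with NaN
    statistics and excluded from the FDR computation.
    """
    wt, mut = _condition_columns(sample_sheet, pair_id)
    sub = counts[wt + mut]
    if size_factors is None:
        size_factors = estimate_size_factors(sub)
    if dispersions is None:
        dispersions = estimate_dispersions(sub, size_factors, sample_sheet, pair_id)

    alpha = dispersions.to_numpy(dtype=float)
    norm = sub.to_numpy(dtype=float) / size_factors[sub.columns].to_numpy()
    base_mean = norm.mean(axis=1)

    out = {}
    for name, cols in (("wt", wt), ("mut", mut)):
        s = size_factors[cols].to_numpy()
        q = (sub[cols].to_numpy(dtype=float) / s).mean(axis=1)
        n = len(cols)
        # Var of the condition mean of normalized counts under NB noise.
        var = (q * np.sum(1.0 / s) + n * alpha * q**2) / n**2
        out[name] = (q, var)

    q_wt, v_wt = out["wt"]
    q_mut, v_mut = out["mut"]
    qp_wt = q_wt + pseudocount
    qp_mut = q_mut + pseudocount
    log2fc = np.log2(qp_mut / qp_wt)
    se = np.sqrt(v_mut / qp_mut**2 + v_wt / qp_wt**2) / _LN2
    se = np.maximum(se, 1e-12)

    tested = sub.to_numpy().sum(axis=1) > 0
    wald = np.where(tested, log2fc / se, np.nan)
    p = np.where(tested, 2.0 * stats.norm.sf(np.abs(wald)), np.nan)

    fdr = np.full_like(p, np.nan)
    if tested.any():
        fdr[tested] = bh_adjust(p[tested])

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": np.where(tested, log2fc, np.nan),
            "se_log2fc": np.where(tested, se, np.nan),
            "wald_stat": wald,
            "p_value": p,
            "fdr": fdr,
        },
        index=counts.index,
    )
    return ContrastTable(pair_id=pair_id, table=table)


def run_all_contrasts(counts: pd.DataFrame, sample_sheet: pd.DataFrame) -> dict[str, ContrastTable]:
    """Run the Wald DE test independently for every pair in the sample sheet."""
    results: dict[str, ContrastTable] = {}
    for pair_id in sample_sheet["pair_id"].unique():
        results[pair_id] = wald_de_test(counts, sample_sheet, pair_id)
    return results


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Input order is preserved; values must lie in [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1] with no missing values")
    return multipletests(p, method="fdr_bh")[1]
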