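import numpy as np
import pytest

import regen_signature as rs


@pytest.fixture(scope="session")
def default_run():
    """One full simulate -> DE run under the default study conditions."""
    cfg = rs.SimConfig(seed=7)
    cm, truth = rs.simulate_counts(cfg)
    contrasts = rs.run_all_contrasts(cm.counts, cm.sample_sheet)
    return cfg, cm, truth, contrasts


@pytest.fixture(scope="session")
def planted_runs():
    """Ten seeded runs with planted shared effects, for recovery properties.

    Returns per-seed dicts with the truth ledger, contrasts and
    regeneration-associated calls (intersection mode).
    """
    runs = []
    for seed in range(1, 11):
        cfg = rs.SimConfig(seed=seed)
        cm, truth = rs.simulate_counts(cfg)
        contrasts = rs.run_all_contrasts(cm.counts, cm.sample_sheet)
        calls = rs.call_regeneration_associated(rs.classify_table(contrasts))
        runs.append({"cfg": cfg, "truth": truth, "contrasts": contrasts, "calls": calls})
    return runs


def brute_force_bh(p):
    """Textbook O(m^2) BH adjusted p-values: for each p_i the smallest
    step-up bound m*t/#{p<=t} over candidate thresholds t >= p_i."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    out = np.empty(m)
    for i in range(m):
        candidates = [p[j] for j in range(m) if p[j] >= p[i]]
        out[i] = min(
            min(m * t / np.sum(p <= t) for t in candidates),
            1.0,
        )
    return out


def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher p by direct enumeration of tables with fixed margins.

    Sums hypergeometric probabilities of every table whose probability does
    not exceed the observed table's (with a small relative tolerance for
    floating-point ties, as in the conventional definition).
    """
    from scipy.stats import hypergeom

    N = a + b + c + d
    if N == 0:
        return 1.0
    K = a + b
    n = a + c
    lo, hi = max(0, K + n - N), min(K, n)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    p_obs = hypergeom.pmf(a, N, K, n)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def straight_line_classify(rows, regen_pairs, nonregen_pairs, thr, margin_mode="mirrored"):
    """Independent plain-loop re-implementation of the signature rule."""
    for pair in list(regen_pairs) + list(nonregen_pairs):
        if pair not in rows:
            return None
        lfc, p, fdr = rows[pair]
        if np.isnan(lfc) or np.isnan(p) or np.isnan(fdr):
            return None
    labels = set()
    for x in regen_pairs:
        lfc_x, p_x, fdr_x = rows[x]
        # X-up
        ok = fdr_x < thr.fdr_sig and lfc_x > 0
        for j in nonregen_pairs:
            lfc_j, p_j, fdr_j = rows[j]
            if not (p_j >= thr.p_nonsig and fdr_j >= thr.fdr_nonsig):
                ok = False
            if not (lfc_j <= lfc_x - thr.margin_log2):
                ok = False
        if ok:
            labels.add(x + "-up")
        # X-down
        ok = fdr_x < thr.fdr_sig and lfc_x < 0
        for j in nonregen_pairs:
            lfc_j, p_j, fdr_j = rows[j]
            if not (p_j >= thr.p_nonsig and fdr_j >= thr.fdr_nonsig):
                ok = False
            if margin_mode == "mirrored":
                if not (lfc_j >= lfc_x + thr.margin_log2):
                    ok = False
            else:
                if not (lfc_j <= lfc_x + thr.margin_log2):
                    ok = False
        if ok:
            labels.add(x + "-down")
    return frozenset(labels)
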