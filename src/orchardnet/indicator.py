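"""Correlation-based indicator (association) analysis of taxa vs strata.

For each taxon, every nonempty proper subset of strata is scored with the
group-equalized point-biserial correlation r.g between the taxon's
abundance and the 0/1 combo-membership indicator; sites are reweighted so
each stratum contributes equal total weight N/K, which removes group-size
bias (with equal group sizes r.g reduces to the plain point-biserial
correlation). The best combination is the maximizer (ties toward the
smaller, then lexicographically earlier, combo). Significance comes from
whole-sample label permutation of the *maximized* statistic:
p = (1 + #{perm >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CountMatrix, SampleMetadata, warn

MAX_STRATA = 5  # 2^5 - 2 = 30 candidate combinations


def stratum_combinations(strata: list[str]) -> list[tuple[str, ...]]:
    """All nonempty proper subsets, ordered by (size, lexicographic)."""
    strata = sorted(set(strata))
    k = len(strata)
    if k < 2:
        raise ValueError("need at least 2 strata")
    if k > MAX_STRATA:
        raise ValueError(f"combination search capped at {MAX_STRATA} strata, got {k}")
    out: list[tuple[str, ...]] = []
    for size in range(1, k):
        out.extend(combinations(strata, size))
    return out


def _site_weights(site_strata: np.ndarray, strata: list[str], equalize: bool) -> np.ndarray:
    """Per-site weights; group-equalized weights give each stratum total N/K."""
    n = len(site_strata)
    if not equalize:
        return np.ones(n)
    k = len(strata)
    counts = {g: int((site_strata == g).sum()) for g in strata}
    empty = [g for g, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"strata with no sites: {empty}")
    per_site = {g: n / (k * counts[g]) for g in strata}
    return np.array([per_site[g] for g in site_strata])


def _combo_indicators(
    site_strata: np.ndarray, combos: list[tuple[str, ...]]
) -> np.ndarray:
    """0/1 membership matrix, shape (n_combos, n_sites)."""
    return np.array(
        [[1.0 if g in set(c) else 0.0 for g in site_strata] for c in combos]
    )


def _weighted_corr_stats(X: np.ndarray, Y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlations between rows of X and rows of Y.

    X: (m, n) abundance rows; Y: (c, n) indicator rows; w: (n,) site weights.
    Returns (m, c). Uses sum_i w_i (y - ybar_w) x = X @ (w * (y - ybar_w)).
    """
    W = w.sum()
    my = (Y * w).sum(axis=1) / W
    Yc = (Y - my[:, None]) * w  # (c, n)
    vy = ((Y - my[:, None]) ** 2 * w).sum(axis=1)
    mx = X @ w / W
    vx = (X**2) @ w - W * mx**2
    sxy = X @ Yc.T  # (m, c)
    denom = np.sqrt(np.outer(vx, vy))
    with np.errstate(invalid="ignore", divide="ignore"):
        return sxy / denom


def rg_statistic(
    abundance,
    combo: tuple[str, ...] | set[str],
    site_strata,
    equalize: bool = True,
) -> float:
    """Group-equalized point-biserial correlation of one taxon vs one combo."""
    x = np.asarray(abundance, dtype=float)
    labels = np.asarray(site_strata, dtype=object)
    if x.size != labels.size:
        raise ValueError("abundance and site_strata lengths differ")
    if x.size < 2:
        raise ValueError("need at least 2 sites")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance abundance: statistic undefined")
    strata = sorted(set(labels))
    w = _site_weights(labels, strata, equalize)
    y = np.array([[1.0 if g in set(combo) else 0.0 for g in labels]])
    return float(_weighted_corr_stats(x[None, :], y, w)[0, 0])


def best_combination(
    abundance, site_strata, equalize: bool = True
) -> tuple[tuple[str, ...], float]:
    """Maximizing stratum combination for one taxon and its r.g value.

    Ties break toward the smaller combo, then lexicographically (the
    candidate list is ordered that way and the first maximum wins).
    """
    x = np.asarray(abundance, dtype=float)
    labels = np.asarray(site_strata, dtype=object)
    if np.ptp(x) == 0:
        raise ValueError("zero-variance abundance: statistic undefined")
    strata = sorted(set(labels))
    combos = stratum_combinations(strata)
    w = _site_weights(labels, strata, equalize)
    Y = _combo_indicators(labels, combos)
    stats = _weighted_corr_stats(x[None, :], Y, w)[0]
    best = int(np.argmax(stats))
    return combos[best], float(stats[best])


def permutation_test(
    abundance,
    site_strata,
    n_perm: int = 999,
    seed: int = 0,
    equalize: bool = True,
) -> tuple[float, tuple[str, ...], float]:
    """Permutation p-value for one taxon's maximized association statistic.

    Site labels are permuted as whole samples; each permutation re-maximizes
    the statistic over all combos, so the p-value accounts for combo
    selection. Returns (p_value, best_combo, observed_stat).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = np.asarray(abundance, dtype=float)
    table = indicator_analysis_array(
        x[None, :], np.asarray(site_strata, dtype=object),
        taxon_ids=["taxon"], n_perm=n_perm, seed=seed, equalize=equalize,
    )
    row = table.iloc[0]
    return float(row["p_value"]), tuple(row["best_combo"].split("+")), float(row["stat"])


def indicator_analysis(
    matrix: CountMatrix,
    metadata: SampleMetadata,
    n_perm: int = 999,
    seed: int = 0,
    equalize: bool = True,
) -> pd.DataFrame:
    """Indicator table for every taxon of a count matrix.

    Strata come from the metadata (land-use x location classes). Returns a
    DataFrame with columns taxon_id, best_combo ('+'-joined strata), stat,
    p_value, n_perm; zero-variance taxa are skipped with a warning.
    """
    strata = metadata.strata()
    missing = [s for s in matrix.sample_ids if s not in strata.index]
    if missing:
        raise KeyError(f"samples without metadata: {missing[:10]}")
    labels = strata.loc[matrix.sample_ids].to_numpy(dtype=object)
    return indicator_analysis_array(
        matrix.counts.astype(float),
        labels,
        taxon_ids=matrix.taxon_ids,
        n_perm=n_perm,
        seed=seed,
        equalize=equalize,
    )


def indicator_analysis_array(
    X: np.ndarray,
    labels: np.ndarray,
    taxon_ids: list[str],
    n_perm: int = 999,
    seed: int = 0,
    equalize: bool = True,
    chunk: int = 32,
) -> pd.DataFrame:
    """Vectorized core of the indicator analysis on a raw (taxa x sites) array.

    Permutations are drawn independently per taxon from a generator seeded
    by ``seed``; abundances are permuted against fixed labels/weights, which
    is equivalent to permuting the site labels themselves.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    X = np.asarray(X, dtype=float)
    n_taxa, n_sites = X.shape
    strata = sorted(set(labels))
    combos = stratum_combinations(strata)
    combo_names = ["+".join(c) for c in combos]
    w = _site_weights(labels, strata, equalize)
    Y = _combo_indicators(labels, combos)

    variable = np.ptp(X, axis=1) > 0
    if (~variable).any():
        skipped = [t for t, v in zip(taxon_ids, variable) if not v]
        warn(f"skipping {len(skipped)} zero-variance taxa (first few: {skipped[:5]})")

    obs = np.full((n_taxa, len(combos)), -2.0)
    obs[variable] = _weighted_corr_stats(X[variable], Y, w)
    best_idx = np.argmax(obs, axis=1)  # first occurrence wins ties
    obs_max = np.where(
        variable, np.take_along_axis(obs, best_idx[:, None], axis=1)[:, 0], np.nan
    )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31)]))
    exceed = np.zeros(n_taxa, dtype=np.int64)
    var_rows = np.flatnonzero(variable)
    for start in range(0, var_rows.size, chunk):
        rows = var_rows[start : start + chunk]
        xc = X[rows]  # (m, n)
        m = len(rows)
        perm = np.broadcast_to(xc, (n_perm, m, n_sites)).copy()
        rng.permuted(perm, axis=2, out=perm)
        stats = _weighted_corr_stats(perm.reshape(n_perm * m, n_sites), Y, w)
        perm_max = stats.max(axis=1).reshape(n_perm, m)
        exceed[rows] = (perm_max >= obs_max[rows][None, :]).sum(axis=0)

    p = (1.0 + exceed) / (n_perm + 1.0)
    return pd.DataFrame(
        {
            "taxon_id": taxon_ids,
            "best_combo": [combo_names[i] if v else "" for i, v in zip(best_idx, variable)],
            "stat": obs_max,
            "p_value": np.where(variable, p, np.nan),
            "n_perm": n_perm,
        }
    )


def association_network(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[nx.Graph, dict]:
    """Bipartite strata <-> significant-taxa graph plus summary counts.

    Each taxon with p < alpha links to every stratum of its best combo.
    The summary reports taxon counts per combo cardinality (cardinality 1 =
    habitat specialists), the specialist fraction, and how many significant
    taxa each unordered pair of strata shares.
    """
    sig = table.dropna(subset=["p_value"])
    sig = sig[sig["p_value"] < alpha]
    g = nx.Graph()
    strata_nodes = set()
    by_cardinality: dict[int, int] = {}
    shared_pairs: dict[tuple[str, str], int] = {}
    for _, row in sig.iterrows():
        combo = tuple(row["best_combo"].split("+"))
        strata_nodes.update(combo)
        g.add_node(row["taxon_id"], bipartite="taxon")
        for s in combo:
            g.add_node(s, bipartite="stratum")
            g.add_edge(s, row["taxon_id"])
        by_cardinality[len(combo)] = by_cardinality.get(len(combo), 0) + 1
        for a, b in combinations(sorted(combo), 2):
            shared_pairs[(a, b)] = shared_pairs.get((a, b), 0) + 1
    n_sig = int(len(sig))
    summary = {
        "n_significant": n_sig,
        "by_cardinality": by_cardinality,
        "specialist_fraction": (by_cardinality.get(1, 0) / n_sig) if n_sig else np.nan,
        "shared_pairs": shared_pairs,
    }
    return g, summary
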