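"""Dual-criterion gene-set enrichment.

A gene set is called enriched for a DEG group only when two independent
criteria agree, each BH-adjusted within its (DEG group, criterion)
family:

* **over-representation** — the upper-tail hypergeometric probability of
  observing at least the seen overlap between the DEG group and the set,
  with the measured gene universe as the sampling frame; and
* **rank enrichment (GSEA)** — the weighted Kolmogorov–Smirnov-like
  running-sum enrichment score over the full moderated-t ranking, with a
  gene-label permutation null shared across sets of equal size.

Both adjusted p-values must be strictly below 0.05 (the default) for the
``enriched`` verdict.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from gradprog.diffexpr import benjamini_hochberg


class EnrichmentError(ValueError):
    pass


# ------------------------------------------------------- over-representation


def hypergeometric_enrichment(
    deg_group: set[str], gene_set: set[str], universe: set[str]
) -> tuple[int, float]:
    """Upper-tail (inclusive) hypergeometric overlap test.

    Returns ``(k, p)`` with ``k`` the overlap count and
    ``p = P(X >= k)`` for ``X ~ Hypergeom(N=|universe|,
    K=|gene_set ∩ universe|, n=|deg_group|)``.  The gene set is
    intersected with the universe first; the DEG group must already be a
    subset of it.
    """
    if not universe:
        raise EnrichmentError("empty universe")
    if not deg_group <= universe:
        raise EnrichmentError("DEG group not contained in the universe")
    N = len(universe)
    K = len(gene_set & universe)
    n = len(deg_group)
    k = len(deg_group & gene_set & universe)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, min(p, 1.0)


# ------------------------------------------------------------- running sum


def rank_genes(metric: pd.Series) -> tuple[list[str], np.ndarray]:
    """Order genes by metric descending, gene ID ascending on ties."""
    df = pd.DataFrame({"m": metric.astype(float)})
    df = df.sort_index().sort_values("m", ascending=False, kind="mergesort")
    return df.index.tolist(), df["m"].to_numpy()


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n_total: int
) -> float:
    """Enrichment score given sorted 0-based member positions.

    ``weights`` are the member weights |r|^p in position order; the
    running sum only attains its extrema at a hit (maximum candidates)
    or just before a hit (minimum candidates), so only 2m points are
    evaluated.
    """
    m = positions.size
    n_miss = n_total - m
    if m == 0:
        raise EnrichmentError("gene set does not intersect the ranked list")
    if n_miss == 0:
        raise EnrichmentError("gene set covers the entire ranked list")
    n_r = weights.sum()
    if n_r <= 0:  # all member weights zero: fall back to unweighted steps
        cum_hit = np.arange(1, m + 1) / m
    else:
        cum_hit = np.cumsum(weights) / n_r
    misses_before = positions - np.arange(m)  # non-members left of each hit
    p_miss = misses_before / n_miss
    at_hit = cum_hit - p_miss
    before_hit = np.concatenate(([0.0], cum_hit[:-1])) - p_miss
    hi = at_hit.max()
    lo = before_hit.min()
    return float(hi if hi >= -lo else lo)


def gsea_score(
    ranked_genes: list[str],
    metric: np.ndarray,
    gene_set: set[str],
    weight_exponent: float = 1.0,
) -> float:
    """Signed maximum deviation of the GSEA running sum, in [-1, 1].

    ``ranked_genes`` must be ordered by the ranking metric (descending);
    member increments are ``|r|^weight_exponent`` normalized to sum 1,
    non-member decrements are ``1/(N - N_H)``.
    """
    metric = np.asarray(metric, dtype=float)
    if metric.shape != (len(ranked_genes),):
        raise EnrichmentError("metric length must match ranked list")
    if not np.isfinite(metric).all():
        raise EnrichmentError("ranking metric must be finite")
    member = np.array([g in gene_set for g in ranked_genes])
    positions = np.flatnonzero(member)
    weights = np.abs(metric[positions]) ** weight_exponent
    return _es_from_positions(positions, weights, len(ranked_genes))


def gsea_running_sum(
    ranked_genes: list[str],
    metric: np.ndarray,
    gene_set: set[str],
    weight_exponent: float = 1.0,
) -> np.ndarray:
    """Full running-sum trajectory (for plots and the brute-force check)."""
    metric = np.asarray(metric, dtype=float)
    member = np.array([g in gene_set for g in ranked_genes])
    n = member.size
    n_hit = int(member.sum())
    if n_hit == 0 or n_hit == n:
        raise EnrichmentError("degenerate gene set for running sum")
    w = np.where(member, np.abs(metric) ** weight_exponent, 0.0)
    n_r = w.sum()
    if n_r <= 0:
        w = member.astype(float)
        n_r = w.sum()
    steps = np.where(member, w / n_r, -1.0 / (n - n_hit))
    return np.cumsum(steps)


# ------------------------------------------------------- permutation null


def gsea_permutation_test(
    ranked_genes: list[str],
    metric: np.ndarray,
    collection: dict[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Gene-label permutation GSEA for a collection of sets.

    The null distribution of the enrichment score is built once per
    distinct set size (random member positions, ``n_perm`` draws) and
    shared across all sets of that size.  Per set:

    * ``nes`` — es divided by the mean |null es| of matching sign;
    * ``gsea_p`` — add-one permutation p-value on the score magnitude,
      ``(1 + #{|null es| >= |es|}) / (1 + n_perm)``; under the null the
      observed set is exchangeable with the permutations, so this p is
      uniform while still attaining the ``1/(1 + n_perm)`` floor.

    Sets with no overlap with the ranked universe get NaN statistics.
    """
    if n_perm < 100:
        raise EnrichmentError("n_perm must be >= 100")
    metric = np.asarray(metric, dtype=float)
    if not np.isfinite(metric).all():
        raise EnrichmentError("ranking metric must be finite")
    if np.ptp(metric) == 0:
        raise EnrichmentError("degenerate ranking metric (all values equal)")
    n = len(ranked_genes)
    gene_pos = {g: i for i, g in enumerate(ranked_genes)}
    absw = np.abs(metric) ** weight_exponent

    set_positions: dict[str, np.ndarray] = {}
    for name, members in collection.items():
        pos = np.fromiter(
            sorted(gene_pos[g] for g in members if g in gene_pos), dtype=int
        )
        set_positions[name] = pos

    sizes = sorted(
        {p.size for p in set_positions.values() if 0 < p.size < n}
    )
    rng = np.random.default_rng(seed)
    null_es: dict[int, np.ndarray] = {}
    for m in sizes:
        es_null = np.empty(n_perm)
        for i in range(n_perm):
            pos = np.sort(rng.choice(n, size=m, replace=False))
            es_null[i] = _es_from_positions(pos, absw[pos], n)
        null_es[m] = es_null

    rows = []
    for name, pos in set_positions.items():
        if pos.size == 0 or pos.size == n:
            rows.append((name, pos.size, np.nan, np.nan, np.nan))
            continue
        es = _es_from_positions(pos, absw[pos], n)
        null = null_es[pos.size]
        same_sign = null >= 0 if es >= 0 else null < 0
        n_extreme = int(np.sum(np.abs(null) >= abs(es)))
        gsea_p = (1 + n_extreme) / (1 + n_perm)
        denom = np.abs(null[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        rows.append((name, pos.size, es, nes, gsea_p))
    return pd.DataFrame(
        rows, columns=["set", "set_size", "es", "nes", "gsea_p"]
    ).set_index("set")


# ------------------------------------------------------------ dual criterion


def dual_criterion(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust within each (deg_group, criterion) family and call verdicts.

    ``records`` needs columns ``deg_group, hyper_p, gsea_p``; rows with a
    NaN GSEA p (set missing from the ranked universe) can never be
    enriched.  Adds ``hyper_adj_p, gsea_adj_p, enriched``.
    """
    out = records.copy()
    out["hyper_adj_p"] = np.nan
    out["gsea_adj_p"] = np.nan
    for _, idx in out.groupby("deg_group").groups.items():
        out.loc[idx, "hyper_adj_p"] = benjamini_hochberg(
            out.loc[idx, "hyper_p"].to_numpy()
        )
        gp = out.loc[idx, "gsea_p"].to_numpy()
        ok = np.isfinite(gp)
        adj = np.full(gp.shape, np.nan)
        if ok.any():
            adj[ok] = benjamini_hochberg(gp[ok])
        out.loc[idx, "gsea_adj_p"] = adj
    out["enriched"] = (
        (out["hyper_adj_p"] < alpha) & (out["gsea_adj_p"] < alpha)
    ).fillna(False)
    return out


# ----------------------------------------------------------- orchestration


def enrich_all(
    comparisons: dict[str, pd.DataFrame],
    deg_groups: dict[str, set[str]],
    collection: dict[str, dict],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Full dual-criterion enrichment over the nine DEG groups.

    The GSEA ranking metric is the comparison's moderated t over all
    measured genes, so one permutation run per comparison serves its
    all/up/down groups; the hypergeometric universe is the full measured
    gene list of that comparison.
    """
    sets = {name: rec["genes"] for name, rec in collection.items()}
    gsea_by_comp = {}
    for offset, (comp, res) in enumerate(sorted(comparisons.items())):
        ranked, metric = rank_genes(res["moderated_t"])
        gsea_by_comp[comp] = gsea_permutation_test(
            ranked, metric, sets, n_perm=n_perm, seed=seed + offset,
            weight_exponent=weight_exponent,
        )

    rows = []
    for group, degs in deg_groups.items():
        comp = group.rsplit("_", 1)[0]
        if comp not in comparisons:
            raise EnrichmentError(f"group {group!r} has no comparison result")
        universe = set(comparisons[comp].index)
        gsea = gsea_by_comp[comp]
        for name, members in sets.items():
            k, hyper_p = hypergeometric_enrichment(
                degs & universe, members, universe
            )
            g = gsea.loc[name]
            rows.append(
                {
                    "set": name,
                    "deg_group": group,
                    "k": k,
                    "hyper_p": hyper_p,
                    "es": g["es"],
                    "nes": g["nes"],
                    "gsea_p": g["gsea_p"],
                }
            )
    records = pd.DataFrame(rows)
    return dual_criterion(records, alpha=alpha)
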