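"""Two-group moderated-t differential expression and the DEG Venn partition.

The moderated t is the empirical-Bayes statistic of microarray practice:
per-gene pooled variances :math:`s_g^2` with :math:`d_g` residual df are
shrunk toward a prior :math:`(d_0, s_0^2)` estimated by moment-matching
the log sample variances (digamma/trigamma equations), giving the
posterior variance

.. math::

    \\tilde s_g^2 = \\frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g},
    \\qquad
    \\tilde t_g = \\frac{\\bar x_{g,a} - \\bar x_{g,b}}
                       {\\tilde s_g \\sqrt{1/n_a + 1/n_b}},

with two-sided p-values from a t distribution on :math:`d_0 + d_g` df.
When the spread of the log variances is entirely explained by sampling
noise the prior df is infinite and every gene shares the common variance
:math:`s_0^2`.

Three comparisons are run unpaired over the tissue classes — cancer vs
normal (C/N), cancer vs pericancerous (C/P), pericancerous vs normal
(P/N) — and DEGs selected at |log2FC| > 2, BH-adjusted p < 0.001 are
split into up/down groups whose three-way Venn overlaps mirror the
gradual-progression structure: a gene may be up in one comparison and
down in another, so the up-diagram and down-diagram totals can exceed
the all-DEG total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats

COMPARISONS = ("C/N", "C/P", "P/N")
#: numerator/denominator tissue per comparison
COMPARISON_CLASSES = {
    "C/N": ("cancer", "normal"),
    "C/P": ("cancer", "peri"),
    "P/N": ("peri", "normal"),
}


class DiffExprError(ValueError):
    pass


# ------------------------------------------------------------------ BH


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DiffExprError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DiffExprError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# --------------------------------------------------- prior (d0, s0^2) fit


def _trigamma_bisect(target: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = target for x > 0 by bracketed bisection."""
    lo, hi = 1e-8, 1e8
    if target >= special.polygamma(1, lo):
        return lo
    if target <= special.polygamma(1, hi):
        return np.inf
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # trigamma ~ 1/x: geometric bisection
        if special.polygamma(1, mid) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, lo):
            break
    return 0.5 * (lo + hi)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to sample variances.

    Returns ``(d0, s0_sq)``; ``d0`` is ``inf`` (full shrinkage to a
    common variance) when the observed spread of ``log s2`` does not
    exceed the trigamma sampling floor.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if not pos.any():
        return np.inf, 0.0
    z = np.log(s2[pos])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    if z.size < 2:
        return np.inf, float(np.exp(emean))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_bisect(evar)
    if not np.isfinite(half_d0):
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


# ------------------------------------------------------------ moderated t


def moderated_t(
    expr: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    comparison: str = "",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated-t comparison of two sample groups.

    ``group_a`` is the numerator class (for C/N, the cancer samples):
    ``log2fc = mean(a) - mean(b)``.  Returns one row per gene with
    columns ``log2fc, moderated_t, raw_p, adj_p, df_total,
    posterior_sd``; the fitted prior is stored in ``result.attrs``.

    ``prior_df`` overrides the estimated prior df (0 disables moderation,
    recovering the ordinary pooled-variance Student t).
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise DiffExprError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise DiffExprError("each group needs at least 2 samples")
    missing = (set(group_a) | set(group_b)) - set(expr.columns)
    if missing:
        raise DiffExprError(f"unknown samples: {sorted(missing)[:5]}")

    a = expr[group_a].to_numpy(dtype=float)
    b = expr[group_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    dg = na + nb - 2

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = mean_a - mean_b
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / dg

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2, dg)
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(s2, dg)
        if d0 == 0:
            s0_sq = 0.0

    if np.isinf(d0):
        post_var = np.full_like(s2, s0_sq)
    elif d0 == 0:
        post_var = s2
    else:
        post_var = (d0 * s0_sq + dg * s2) / (d0 + dg)

    se_scale = np.sqrt(1.0 / na + 1.0 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = log2fc / (np.sqrt(post_var) * se_scale)
    tstat = np.where(post_var == 0, np.where(log2fc == 0, 0.0, np.inf) * np.sign(log2fc), tstat)

    df_total = d0 + dg  # inf-safe: stats.t with df=inf is the normal
    raw_p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    adj_p = benjamini_hochberg(np.clip(raw_p, 0.0, 1.0))

    res = pd.DataFrame(
        {
            "log2fc": log2fc,
            "moderated_t": tstat,
            "raw_p": raw_p,
            "adj_p": adj_p,
            "df_total": df_total,
            "posterior_sd": np.sqrt(post_var),
        },
        index=expr.index,
    )
    res.attrs.update({"comparison": comparison, "d0": d0, "s0_sq": s0_sq,
                      "n_a": na, "n_b": nb})
    return res


def run_comparisons(expr: pd.DataFrame, annot: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Run the three tissue comparisons (C/N, C/P, P/N) unpaired."""
    from gradprog.io import samples_of

    out = {}
    for comp, (num, den) in COMPARISON_CLASSES.items():
        cols = set(expr.columns)
        ga = [s for s in samples_of(annot, num) if s in cols]
        gb = [s for s in samples_of(annot, den) if s in cols]
        out[comp] = moderated_t(expr, ga, gb, comparison=comp)
    return out


# ----------------------------------------------------------- DEG selection


def select_degs(
    result: pd.DataFrame,
    lfc_threshold: float = 2.0,
    alpha: float = 0.001,
) -> tuple[set[str], set[str]]:
    """Strict-threshold DEG selection: |log2FC| > threshold and adj_p < alpha."""
    sig = result["adj_p"] < alpha
    up = set(result.index[sig & (result["log2fc"] > lfc_threshold)])
    down = set(result.index[sig & (result["log2fc"] < -lfc_threshold)])
    return up, down


# ----------------------------------------------------------- Venn partition


@dataclass
class DEGPartition:
    """Up/down/all DEG sets per comparison and their three-way Venn cells.

    ``venn[diagram][cell]`` maps a cell key (comparison names joined by
    ``"&"``, e.g. ``"C/N&C/P&P/N"`` for the center) to the genes exactly
    in that cell; the cells of one diagram are disjoint and cover the
    union of its three sets.
    """

    up: dict[str, set[str]] = field(default_factory=dict)
    down: dict[str, set[str]] = field(default_factory=dict)
    venn: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    @property
    def all(self) -> dict[str, set[str]]:
        return {c: self.up[c] | self.down[c] for c in self.up}

    def groups(self) -> dict[str, set[str]]:
        """The nine DEG groups: {comparison}_{all,up,down}."""
        out = {}
        for comp in self.up:
            out[f"{comp}_all"] = self.up[comp] | self.down[comp]
            out[f"{comp}_up"] = self.up[comp]
            out[f"{comp}_down"] = self.down[comp]
        return out

    def cell_counts(self, diagram: str) -> dict[str, int]:
        return {cell: len(g) for cell, g in self.venn[diagram].items()}


def _venn_cells(sets: dict[str, set[str]]) -> dict[str, set[str]]:
    names = list(sets)
    cells: dict[str, set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(
                set(), *(sets[n] for n in names if n not in combo)
            )
            cells["&".join(combo)] = inside - outside
    return cells


def venn_partition(
    up: dict[str, set[str]], down: dict[str, set[str]]
) -> DEGPartition:
    """Build the three 7-cell Venn decompositions (all / up / down diagrams)."""
    if set(up) != set(down):
        raise DiffExprError("up and down must cover the same comparisons")
    all_sets = {c: up[c] | down[c] for c in up}
    part = DEGPartition(up={c: set(v) for c, v in up.items()},
                        down={c: set(v) for c, v in down.items()})
    part.venn = {
        "all": _venn_cells(all_sets),
        "up": _venn_cells(up),
        "down": _venn_cells(down),
    }
    return part


def write_comparison(result: pd.DataFrame, path) -> None:
    out = result[["log2fc", "moderated_t", "raw_p", "adj_p"]].rename(
        columns={"moderated_t": "t", "raw_p": "p"}
    )
    out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
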