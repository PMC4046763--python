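"""Signature risk scores and their association with postoperative survival.

A classifier is a gene (or miRNA) feature list from one enriched set,
scored under a *profile mode*:

``C``
    absolute expression in the cancer sample;
``C/P``
    cancer minus the patient's paired pericancerous sample (log2 ratio);
``P/N``
    pericancerous minus the mean of the normal reference samples;
``C/N``
    cancer minus the mean of the normal reference samples.

The per-patient risk score is the mean of per-feature z-scores
(standardized across patients within the cohort), a scale-free and
direction-preserving aggregate.  Association with survival is tested on
the continuous score by a univariate Cox proportional-hazards fit
(Efron tie correction, damped Newton on the partial likelihood) and,
for display, by a median split with Kaplan-Meier curves and the
log-rank test.  Positive log hazard ratio means higher score, worse
prognosis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from gradprog import io

PROFILE_MODES = ("C", "C/P", "P/N", "C/N")


class SurvivalError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class Classifier:
    name: str
    features: list[str]
    kind: str = "gene"  # gene | mirna
    mode: str = "C"

    def __post_init__(self) -> None:
        if not self.features:
            raise SurvivalError("classifier needs at least one feature")
        if self.kind not in ("gene", "mirna"):
            raise SurvivalError(f"unknown feature kind {self.kind!r}")
        if self.mode not in PROFILE_MODES:
            raise SurvivalError(f"unknown profile mode {self.mode!r}")


@dataclass
class SurvivalAssociation:
    """Everything one classifier-on-one-cohort test produces."""

    classifier: Classifier
    n_patients: int
    scores: pd.Series
    beta: float
    se_beta: float
    wald_p: float
    logrank_chi2: float
    logrank_p: float
    km_high: pd.DataFrame
    km_low: pd.DataFrame
    n_features_used: int
    n_features_missing: int
    n_dropped_missing_survival: int = 0

    @property
    def hr_sign(self) -> int:
        return int(np.sign(self.beta))

    def validates(self, discovery: "SurvivalAssociation",
                  alpha: float = 0.05) -> bool:
        """Validation rule: significant Wald p with the discovery sign."""
        return bool(self.wald_p < alpha and
                    self.hr_sign == discovery.hr_sign and self.hr_sign != 0)


# ------------------------------------------------------------ risk scores


def signature_score(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    classifier: Classifier,
) -> tuple[pd.Series, dict]:
    """Per-patient risk score for one classifier.

    Features absent from the matrix are dropped and counted; patients
    without the samples the mode requires are dropped with a warning.
    Returns ``(scores indexed by patient_id, info dict)``.
    """
    feats = [f for f in classifier.features if f in expr.index]
    n_missing = len(classifier.features) - len(feats)
    if not feats:
        raise SurvivalError(
            f"classifier {classifier.name!r}: no feature measured in cohort"
        )

    mode = classifier.mode
    pairs = io.paired_samples(annot)
    cancer = annot[annot["tissue"] == "cancer"].set_index("patient_id")["sample_id"]
    peri = annot[annot["tissue"] == "peri"].set_index("patient_id")["sample_id"]
    normals = [s for s in io.samples_of(annot, "normal") if s in expr.columns]

    if mode in ("C", "C/N"):
        pts = [p for p in cancer.index if cancer[p] in expr.columns]
        values = expr.loc[feats, [cancer[p] for p in pts]].to_numpy().T
    elif mode == "C/P":
        pts = [
            p for p in pairs["patient_id"]
            if cancer.get(p) in expr.columns and peri.get(p) in expr.columns
        ]
        dropped = len(set(cancer.index)) - len(pts)
        if dropped:
            warnings.warn(
                f"{classifier.name}: {dropped} patient(s) without a complete "
                "cancer/pericancerous pair dropped", stacklevel=2,
            )
        values = (
            expr.loc[feats, [cancer[p] for p in pts]].to_numpy().T
            - expr.loc[feats, [peri[p] for p in pts]].to_numpy().T
        )
    elif mode == "P/N":
        pts = [p for p in peri.index if peri[p] in expr.columns]
        values = expr.loc[feats, [peri[p] for p in pts]].to_numpy().T
    else:  # pragma: no cover - guarded in Classifier
        raise SurvivalError(f"unknown mode {mode!r}")

    if mode in ("P/N", "C/N"):
        if not normals:
            raise SurvivalError(f"mode {mode} needs normal reference samples")
        ref = expr.loc[feats, normals].to_numpy().mean(axis=1)
        values = values - ref[None, :]

    if not pts:
        raise SurvivalError("no patients with the samples this mode requires")

    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    z = np.zeros_like(values)
    informative = sd > 0
    z[:, informative] = (values[:, informative] - mu[informative]) / sd[informative]
    scores = pd.Series(z.mean(axis=1), index=pd.Index(pts, name="patient_id"))
    info = {
        "n_features_used": len(feats),
        "n_features_missing": n_missing,
        "features_used": feats,
    }
    return scores, info


# ------------------------------------------------------------------- Cox


def _cox_efron_stats(beta: float, t, d, x):
    """Negative log partial likelihood, score and information (Efron ties)."""
    order = np.argsort(-t, kind="mergesort")  # descending time
    t, d, x = t[order], d[order], x[order]
    eta = beta * x
    w = np.exp(eta)
    # cumulative risk-set sums as we sweep descending times
    cs0 = np.cumsum(w)
    cs1 = np.cumsum(w * x)
    cs2 = np.cumsum(w * x * x)
    ll = 0.0
    score = 0.0
    info = 0.0
    i = 0
    n = t.size
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # block [i, j) shares this time; risk set = everything up to j-1
        dmask = d[i:j] == 1
        nd = int(dmask.sum())
        if nd > 0:
            xi = x[i:j][dmask]
            wi = w[i:j][dmask]
            s0_tie, s1_tie, s2_tie = wi.sum(), (wi * xi).sum(), (wi * xi * xi).sum()
            s0, s1, s2 = cs0[j - 1], cs1[j - 1], cs2[j - 1]
            ll += beta * xi.sum()
            score += xi.sum()
            for l in range(nd):
                f = l / nd
                a0 = s0 - f * s0_tie
                a1 = s1 - f * s1_tie
                a2 = s2 - f * s2_tie
                ll -= np.log(a0)
                score -= a1 / a0
                info += a2 / a0 - (a1 / a0) ** 2
        i = j
    return -ll, score, info


def cox_fit_univariate(
    scores: pd.Series | np.ndarray,
    survival: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[float, float, float]:
    """Univariate Cox PH fit of survival on a continuous score.

    Maximizes the Efron-tie-corrected partial likelihood by damped
    Newton iteration; returns ``(beta, se_beta, wald_p)`` with a
    two-sided normal Wald p-value.
    """
    if isinstance(scores, pd.Series):
        surv = survival.set_index("patient_id").loc[scores.index]
        x = scores.to_numpy(dtype=float)
    else:
        surv = survival
        x = np.asarray(scores, dtype=float)
    t = surv["time_months"].to_numpy(dtype=float)
    d = surv["event"].to_numpy(dtype=int)
    if t.size != x.size:
        raise SurvivalError("score/survival length mismatch")
    if d.sum() < 2:
        raise SurvivalError("need at least 2 events")
    if np.ptp(x) == 0:
        raise SurvivalError("zero score variance")

    beta = 0.0
    nll, score, info = _cox_efron_stats(beta, t, d, x)
    for it in range(max_iter):
        if info <= 0:
            raise ConvergenceError(f"non-positive information at iter {it}")
        step = score / info
        if abs(step) < tol and abs(score) < 1e-6:
            break
        new_beta = beta + step
        new = _cox_efron_stats(new_beta, t, d, x)
        halvings = 0
        while new[0] > nll + 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new = _cox_efron_stats(new_beta, t, d, x)
            halvings += 1
        beta, (nll, score, info) = new_beta, new
        if abs(step) < tol:
            break
    else:
        raise ConvergenceError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(beta={beta:.4g}, score={score:.3g})"
        )
    se = 1.0 / np.sqrt(info)
    wald_p = 2.0 * stats.norm.sf(abs(beta) / se)
    return float(beta), float(se), float(wald_p)


def cox_partial_loglik(beta: float, survival: pd.DataFrame,
                       scores: np.ndarray) -> float:
    """Efron partial log-likelihood at a fixed beta (for grid checks)."""
    t = survival["time_months"].to_numpy(dtype=float)
    d = survival["event"].to_numpy(dtype=int)
    nll, _, _ = _cox_efron_stats(beta, t, d, np.asarray(scores, float))
    return -nll


# ----------------------------------------------------------- Kaplan-Meier


def kaplan_meier(survival: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step function as a DataFrame with columns ``time``,
    ``survival``, ``at_risk``, ``events``; starts at (0, 1), defined at
    the distinct event times, censored subjects leave the risk set after
    their time.
    """
    if len(survival) == 0:
        raise SurvivalError("empty survival table")
    t = survival["time_months"].to_numpy(dtype=float)
    d = survival["event"].to_numpy(dtype=int)
    order = np.argsort(t, kind="mergesort")
    t, d = t[order], d[order]
    n = t.size
    rows = [(0.0, 1.0, n, 0)]
    s = 1.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        at_risk = n - i
        events = int(d[i:j].sum())
        if events > 0:
            s *= 1.0 - events / at_risk
            rows.append((float(t[i]), s, at_risk, events))
        i = j
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk", "events"])


# --------------------------------------------------------------- log-rank


def _logrank_two_group(t, d, in_high) -> tuple[float, float]:
    event_times = np.unique(t[d == 1])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n_j = int(at_risk.sum())
        n1 = int((at_risk & in_high).sum())
        dying = at_risk & (t == et) & (d == 1)
        d_j = int(dying.sum())
        d1 = int((dying & in_high).sum())
        frac = n1 / n_j
        o_minus_e += d1 - d_j * frac
        if n_j > 1:
            var += d_j * frac * (1 - frac) * (n_j - d_j) / (n_j - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def logrank_test(
    scores: pd.Series, survival: pd.DataFrame
) -> tuple[float, float, np.ndarray]:
    """Median-split two-group log-rank test.

    Patients with score above the median form the high-risk group.
    Returns ``(chi2, p, high_mask)``.
    """
    surv = survival.set_index("patient_id").loc[scores.index]
    x = scores.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise SurvivalError("degenerate split: all scores identical")
    med = np.median(x)
    high = x > med
    if not high.any() or high.all():
        # every score equals the median on one side; fall back to >=
        high = x >= med
        if not high.any() or high.all():
            raise SurvivalError("degenerate split: empty group")
    t = surv["time_months"].to_numpy(dtype=float)
    d = surv["event"].to_numpy(dtype=int)
    chi2, p = _logrank_two_group(t, d, high)
    return chi2, p, high


# ----------------------------------------------------------- orchestration


def evaluate_classifier(
    classifier: Classifier,
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    survival: pd.DataFrame,
) -> SurvivalAssociation:
    """Score a classifier on a cohort and test the survival association."""
    scores, info = signature_score(expr, annot, classifier)
    surv = io.validate_survival(survival)
    have = scores.index.intersection(surv["patient_id"])
    n_dropped = len(scores) - len(have)
    if n_dropped:
        warnings.warn(
            f"{classifier.name}: {n_dropped} scored patient(s) without "
            "survival data dropped", stacklevel=2,
        )
    scores = scores.loc[have]
    surv = surv.set_index("patient_id").loc[have].reset_index()

    beta, se, wald_p = cox_fit_univariate(scores, surv)
    chi2, lr_p, high = logrank_test(scores, surv)
    km_high = kaplan_meier(surv[high])
    km_low = kaplan_meier(surv[~high])
    return SurvivalAssociation(
        classifier=classifier,
        n_patients=len(scores),
        scores=scores,
        beta=beta,
        se_beta=se,
        wald_p=wald_p,
        logrank_chi2=chi2,
        logrank_p=lr_p,
        km_high=km_high,
        km_low=km_low,
        n_features_used=info["n_features_used"],
        n_features_missing=info["n_features_missing"],
        n_dropped_missing_survival=n_dropped,
    )
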