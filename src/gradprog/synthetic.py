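"""Synthetic three-tissue cohorts with planted, fully known ground truth.

The generator emulates the structure of a paired tumor study: a small
normal-liver reference group plus patients contributing one
pericancerous and one cancer sample each.  Planted *gradual* genes shift
by half the effect in pericancerous tissue and the full effect in
cancer (up or down); gene sets are either null draws from the universe
or enriched for gradual genes; six redundant target databases report a
miRNA→gene edge with per-database recall on true edges and a small
false-positive rate elsewhere; and survival follows an exponential
hazard tied to the standardized mean cancer expression of the first
planted prognostic set, with independent uniform censoring tuned to a
target censoring fraction.

Every stage draws from its own RNG stream spawned from the master seed,
so adding or re-running a later stage never perturbs earlier draws, and
identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gradprog import io
from gradprog.config import SyntheticConfig, ConfigError

N_DATABASES = 6
DATABASE_NAMES = ("db1", "db2", "db3", "db4", "db5", "db6")

#: anti-correlation of a miRNA with the mean expression of its targets
MIRNA_TARGET_COUPLING = -0.5


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    gradual_up_genes: list[str] = field(default_factory=list)
    gradual_down_genes: list[str] = field(default_factory=list)
    enriched_sets: list[str] = field(default_factory=list)
    prognostic_sets: list[str] = field(default_factory=list)
    true_target_edges: set = field(default_factory=set)
    latent_risk: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "gradual_up_genes": sorted(self.gradual_up_genes),
            "gradual_down_genes": sorted(self.gradual_down_genes),
            "enriched_sets": list(self.enriched_sets),
            "prognostic_sets": list(self.prognostic_sets),
            "true_target_edges": sorted(map(list, self.true_target_edges)),
            "latent_risk": self.latent_risk,
        }


@dataclass
class CohortBundle:
    """One cohort's matrices, annotation, survival and latent risk."""

    expr_mrna: pd.DataFrame
    expr_mirna: pd.DataFrame
    annot: pd.DataFrame
    survival: pd.DataFrame | None = None
    latent_risk: pd.Series | None = None


@dataclass
class StudyBundle:
    """A full simulated study: discovery + validation cohort, shared truth."""

    config: SyntheticConfig
    truth: GroundTruth
    gene_sets: dict
    target_tables: dict[str, set]
    discovery: CohortBundle
    validation: CohortBundle


# ------------------------------------------------------------------ cohort


def _ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(
    config: SyntheticConfig,
    rng: np.random.Generator,
    truth: GroundTruth | None = None,
    sample_prefix: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the mRNA and miRNA matrices plus sample annotation.

    Per gene *g* and sample *s*: ``x = mu_g + e_g(class) + N(0, noise_sd)``
    with class effect 0 / delta/2 / delta (normal / pericancerous /
    cancer) for gradual-up genes, negated for gradual-down, zero
    otherwise.  miRNA expression is coupled anti-correlated to the mean
    expression of the miRNA's true targets.  When ``truth`` is given
    (validation cohorts) the planted structure is reused; otherwise
    gradual genes and true target edges are drawn here.
    """
    genes = _ids("G", config.n_genes)
    mirnas = _ids("hsa-sim-miR-", config.n_mirnas)
    n_up = int(round(config.frac_gradual_up * config.n_genes))
    n_down = int(round(config.frac_gradual_down * config.n_genes))

    if truth is None:
        truth = GroundTruth()
        chosen = rng.choice(config.n_genes, size=n_up + n_down, replace=False)
        truth.gradual_up_genes = [genes[i] for i in chosen[:n_up]]
        truth.gradual_down_genes = [genes[i] for i in chosen[n_up:]]
        for mi in range(config.n_mirnas):
            targets = rng.choice(config.n_genes, size=min(
                config.targets_per_mirna, config.n_genes), replace=False)
            truth.true_target_edges.update(
                (mirnas[mi], genes[t]) for t in targets
            )

    normal_ids = _ids(f"{sample_prefix}N", config.n_normal)
    patient_ids = _ids(f"{sample_prefix}P", config.n_pairs)
    peri_ids = [f"{p}_peri" for p in patient_ids]
    cancer_ids = [f"{p}_cancer" for p in patient_ids]
    sample_ids = normal_ids + peri_ids + cancer_ids

    annot = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient_id": (
                [f"{sample_prefix}N_ref"] * config.n_normal
                + patient_ids + patient_ids
            ),
            "tissue": (["normal"] * config.n_normal
                       + ["peri"] * config.n_pairs
                       + ["cancer"] * config.n_pairs),
        }
    )

    mu = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    effect = np.zeros((config.n_genes, len(sample_ids)))
    gene_index = {g: i for i, g in enumerate(genes)}
    class_mult = np.array(
        [0.0] * config.n_normal
        + [0.5] * config.n_pairs
        + [1.0] * config.n_pairs
    )
    for g in truth.gradual_up_genes:
        effect[gene_index[g]] = config.delta * class_mult
    for g in truth.gradual_down_genes:
        effect[gene_index[g]] = -config.delta * class_mult

    noise = rng.normal(0.0, config.noise_sd or 0.0,
                       (config.n_genes, len(sample_ids)))
    if config.noise_sd == 0:
        noise[:] = 0.0
    expr_mrna = pd.DataFrame(
        mu[:, None] + effect + noise, index=pd.Index(genes, name="gene_id"),
        columns=sample_ids,
    )

    # miRNA matrix: baseline + coupling to centered mean target expression
    mu_m = rng.normal(config.baseline_mean - 1.0, 1.0, config.n_mirnas)
    values = np.tile(mu_m[:, None], (1, len(sample_ids)))
    X = expr_mrna.to_numpy()
    targets_by_mirna: dict[str, list[int]] = {}
    for mm, g in truth.true_target_edges:
        targets_by_mirna.setdefault(mm, []).append(gene_index[g])
    for mi, m in enumerate(mirnas):
        tgt = targets_by_mirna.get(m)
        if tgt:
            tbar = X[tgt].mean(axis=0)
            values[mi] += MIRNA_TARGET_COUPLING * (tbar - tbar.mean())
    values += rng.normal(0.0, config.noise_sd,
                         (config.n_mirnas, len(sample_ids)))
    expr_mirna = pd.DataFrame(
        values, index=pd.Index(mirnas, name="gene_id"), columns=sample_ids
    )
    return expr_mrna, expr_mirna, annot, truth


# ---------------------------------------------------------------- gene sets


def generate_gene_sets(
    config: SyntheticConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
    genes: list[str],
) -> dict[str, dict]:
    """Draw the gene-set collection and designate enriched/prognostic sets.

    Enriched sets draw ``enriched_member_frac`` of their members from
    the gradual genes (alternating up/down pools); the remaining sets
    are uniform draws from the universe.  The first ``n_prognostic_sets``
    up-type enriched sets are marked prognostic.
    """
    lo, hi = config.set_size_range
    if hi > len(genes):
        raise ConfigError(
            f"set size {hi} exceeds the {len(genes)}-gene universe"
        )
    universe = np.array(genes)
    up_pool = np.array(truth.gradual_up_genes)
    down_pool = np.array(truth.gradual_down_genes)
    sets: dict[str, dict] = {}
    width = max(3, len(str(config.n_sets)))
    up_type_enriched: list[str] = []
    for si in range(config.n_sets):
        name = f"SET{si + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if si < config.n_enriched_sets:
            pool = up_pool if si % 2 == 0 else down_pool
            n_grad = min(int(np.ceil(config.enriched_member_frac * size)),
                         pool.size)
            grad = rng.choice(pool, size=n_grad, replace=False) if n_grad else []
            rest_pool = np.array(sorted(set(genes) - set(grad)))
            rest = rng.choice(rest_pool, size=size - n_grad, replace=False)
            members = set(grad) | set(rest)
            category = "planted_up" if si % 2 == 0 else "planted_down"
            if si % 2 == 0:
                up_type_enriched.append(name)
        else:
            members = set(rng.choice(universe, size=size, replace=False))
            category = "null"
        sets[name] = {"description": category, "genes": members}
    if not truth.enriched_sets:
        truth.enriched_sets = list(sets)[: config.n_enriched_sets]
        truth.prognostic_sets = up_type_enriched[: config.n_prognostic_sets]
    return sets


# ---------------------------------------------------------- target databases


def generate_target_databases(
    config: SyntheticConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
    genes: list[str],
    mirnas: list[str],
) -> dict[str, set]:
    """Six noisy edge tables: true edges kept with probability
    ``db_recall``, each non-edge reported with probability ``db_fpr``,
    independently per database."""
    gene_index = {g: i for i, g in enumerate(genes)}
    mirna_index = {m: i for i, m in enumerate(mirnas)}
    n_pairs_total = len(genes) * len(mirnas)
    true_flat = np.array(
        sorted(mirna_index[m] * len(genes) + gene_index[g]
               for m, g in truth.true_target_edges),
        dtype=np.int64,
    )
    non_edge_mask = np.ones(n_pairs_total, dtype=bool)
    non_edge_mask[true_flat] = False
    non_edges = np.flatnonzero(non_edge_mask)

    def unflatten(idx: np.ndarray) -> set:
        return {
            (mirnas[i // len(genes)], genes[i % len(genes)]) for i in idx
        }

    tables: dict[str, set] = {}
    true_list = sorted(truth.true_target_edges)
    for db in DATABASE_NAMES:
        keep = rng.random(len(true_list)) < config.db_recall
        edges = {e for e, k in zip(true_list, keep) if k}
        n_false = rng.binomial(non_edges.size, config.db_fpr)
        if n_false:
            false_idx = rng.choice(non_edges, size=n_false, replace=False)
            edges |= unflatten(false_idx)
        tables[db] = edges
    return tables


# ------------------------------------------------------------------ survival


def _tune_censor_bound(hazards: np.ndarray, target: float) -> float:
    """Upper bound of U(0, c) censoring hitting the target censor fraction.

    For exponential event times, ``P(censored | h) =
    (1 - exp(-h c)) / (h c)``; solve the cohort mean for c by bisection.
    """

    def frac(c: float) -> float:
        hc = hazards * c
        return float(np.mean((1.0 - np.exp(-hc)) / hc))

    lo, hi = 1e-9, 1e9
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def latent_risk_score(
    truth: GroundTruth,
    gene_sets: dict[str, dict],
    expr_mrna: pd.DataFrame,
    annot: pd.DataFrame,
) -> pd.Series:
    """Standardized mean cancer expression of the first prognostic set."""
    cancer = annot[annot["tissue"] == "cancer"]
    pts = cancer["patient_id"].tolist()
    cols = cancer["sample_id"].tolist()
    if truth.prognostic_sets:
        members = sorted(gene_sets[truth.prognostic_sets[0]]["genes"])
        vals = expr_mrna.loc[members, cols].to_numpy().mean(axis=0)
        sd = vals.std()
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
    else:
        z = np.zeros(len(cols))
    return pd.Series(z, index=pd.Index(pts, name="patient_id"))


def generate_survival(
    config: SyntheticConfig,
    truth: GroundTruth,
    expr_mrna: pd.DataFrame,
    annot: pd.DataFrame,
    gene_sets: dict[str, dict],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """Exponential survival with hazard tied to the planted signature.

    Event time ~ Exp(h0 · exp(beta_surv · z)) with z the latent risk
    score; h0 fixes the baseline median at
    ``config.median_survival_months``.  Censoring is independent
    U(0, c) with c tuned so the expected censored fraction equals
    ``censor_frac``; times are reported in months to one decimal.
    """
    z = latent_risk_score(truth, gene_sets, expr_mrna, annot)
    h0 = np.log(2.0) / config.median_survival_months
    hazards = h0 * np.exp(config.beta_surv * z.to_numpy())
    t_event = rng.exponential(1.0 / hazards)
    if config.censor_frac > 0:
        cmax = _tune_censor_bound(hazards, config.censor_frac)
        t_cens = rng.uniform(0.0, cmax, size=hazards.size)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(hazards.size, dtype=int)
    time = np.maximum(np.round(time, 1), 0.1)
    surv = pd.DataFrame(
        {"patient_id": z.index, "time_months": time, "event": event}
    )
    return surv, z


# ------------------------------------------------------------------- study


def simulate_study(config: SyntheticConfig) -> StudyBundle:
    """Simulate a discovery and a validation cohort sharing one truth."""
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(6)]
    rng_cohort, rng_sets, rng_db, rng_surv, rng_vcohort, rng_vsurv = streams

    mrna, mirna, annot, truth = generate_cohort(config, rng_cohort)
    genes = mrna.index.tolist()
    mirnas = mirna.index.tolist()
    gene_sets = generate_gene_sets(config, truth, rng_sets, genes)
    tables = generate_target_databases(config, truth, rng_db, genes, mirnas)
    surv, z = generate_survival(config, truth, mrna, annot, gene_sets,
                                rng_surv)
    truth.latent_risk = {p: float(v) for p, v in z.items()}
    discovery = CohortBundle(mrna, mirna, annot, surv, z)

    vmrna, vmirna, vannot, _ = generate_cohort(
        config, rng_vcohort, truth=truth, sample_prefix="V"
    )
    vsurv, vz = generate_survival(config, truth, vmrna, vannot, gene_sets,
                                  rng_vsurv)
    validation = CohortBundle(vmrna, vmirna, vannot, vsurv, vz)
    return StudyBundle(config, truth, gene_sets, tables, discovery,
                       validation)


def write_study(bundle: StudyBundle, outdir: str | Path) -> None:
    """Write every simulated artifact as plain text under ``outdir``."""
    out = Path(outdir)
    for name, cohort in (("discovery", bundle.discovery),
                         ("validation", bundle.validation)):
        d = out / name
        d.mkdir(parents=True, exist_ok=True)
        io.write_expression(cohort.expr_mrna, d / "expression_mrna.tsv")
        io.write_expression(cohort.expr_mirna, d / "expression_mirna.tsv")
        io.write_annotation(cohort.annot, d / "annotation.tsv")
        io.write_survival(cohort.survival, d / "survival.tsv")
    io.write_gmt(bundle.gene_sets, out / "gene_sets.gmt")
    db = out / "target_databases"
    db.mkdir(parents=True, exist_ok=True)
    for name, edges in bundle.target_tables.items():
        io.write_target_table(edges, db / f"{name}.tsv")
    io.write_json(bundle.truth.to_dict(), out / "ground_truth.json")
    io.write_json(bundle.config.to_dict(), out / "config.json")
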