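"""Planted structure, determinism, and calibration of the simulator."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from gradprog.config import ConfigError, SyntheticConfig
from gradprog.diffexpr import moderated_t, select_degs
from gradprog.io import samples_of
from gradprog.synthetic import (
    generate_cohort,
    generate_gene_sets,
    generate_survival,
    simulate_study,
    write_study,
)


def class_means(expr, annot, gene):
    return {
        t: expr.loc[gene, samples_of(annot, t)].mean()
        for t in ("normal", "peri", "cancer")
    }


def test_noise_free_shifts_are_exact():
    cfg = SyntheticConfig(n_genes=100, n_mirnas=10, n_sets=5,
                          n_enriched_sets=2, set_size_range=(5, 10),
                          noise_sd=0.0, delta=4.0, seed=1)
    rng = np.random.default_rng(0)
    mrna, _, annot, truth = generate_cohort(cfg, rng)
    up = truth.gradual_up_genes[0]
    down = truth.gradual_down_genes[0]
    m_up, m_down = class_means(mrna, annot, up), class_means(mrna, annot, down)
    assert m_up["cancer"] - m_up["normal"] == pytest.approx(4.0, abs=1e-12)
    assert m_up["peri"] - m_up["normal"] == pytest.approx(2.0, abs=1e-12)
    assert m_down["cancer"] - m_down["normal"] == pytest.approx(-4.0, abs=1e-12)
    assert m_up["normal"] < m_up["peri"] < m_up["cancer"]
    # paired columns share the patient ID
    pairs = annot[annot["tissue"] != "normal"]
    assert pairs.groupby("patient_id").size().eq(2).all()


def test_planted_effect_recovered_on_average():
    """Mean cancer-normal difference of planted up genes near delta."""
    cfg = SyntheticConfig(seed=5)  # 100 up + 100 down planted genes
    rng = np.random.default_rng(5)
    mrna, _, annot, truth = generate_cohort(cfg, rng)
    cancer = samples_of(annot, "cancer")
    normal = samples_of(annot, "normal")
    diffs = (
        mrna.loc[truth.gradual_up_genes, cancer].mean(axis=1)
        - mrna.loc[truth.gradual_up_genes, normal].mean(axis=1)
    )
    per_gene_var = cfg.noise_sd**2 * (1 / len(cancer) + 1 / len(normal))
    se = np.sqrt(per_gene_var / len(diffs))
    assert abs(diffs.mean() - cfg.delta) < 3 * se


def test_null_simulation_yields_no_degs():
    """Without planted effects the DEG caller stays empty almost always."""
    hits = 0
    for seed in range(20):
        cfg = SyntheticConfig(n_genes=800, n_mirnas=5, n_sets=3,
                              n_enriched_sets=0, n_prognostic_sets=0,
                              frac_gradual_up=0.0, frac_gradual_down=0.0,
                              seed=seed)
        rng = np.random.default_rng(seed)
        mrna, _, annot, _ = generate_cohort(cfg, rng)
        res = moderated_t(mrna, samples_of(annot, "cancer"),
                          samples_of(annot, "normal"))
        up, down = select_degs(res)
        hits += bool(up or down)
    assert hits <= 1  # clean in >= 95% of 20 seeds


def test_identical_seed_is_bit_identical():
    a = simulate_study(SyntheticConfig(n_genes=300, n_mirnas=20, n_sets=8,
                                       n_enriched_sets=2, seed=42))
    b = simulate_study(SyntheticConfig(n_genes=300, n_mirnas=20, n_sets=8,
                                       n_enriched_sets=2, seed=42))
    pd.testing.assert_frame_equal(a.discovery.expr_mrna, b.discovery.expr_mrna)
    pd.testing.assert_frame_equal(a.discovery.expr_mirna,
                                  b.discovery.expr_mirna)
    pd.testing.assert_frame_equal(a.discovery.survival, b.discovery.survival)
    pd.testing.assert_frame_equal(a.validation.expr_mrna,
                                  b.validation.expr_mrna)
    assert a.truth.to_dict() == b.truth.to_dict()
    assert a.target_tables == b.target_tables
    assert {k: sorted(v["genes"]) for k, v in a.gene_sets.items()} == {
        k: sorted(v["genes"]) for k, v in b.gene_sets.items()
    }


def test_gene_sets_sizes_and_enriched_composition(small_config, small_study):
    lo, hi = small_config.set_size_range
    truth, sets = small_study.truth, small_study.gene_sets
    gradual = set(truth.gradual_up_genes) | set(truth.gradual_down_genes)
    for name, rec in sets.items():
        assert lo <= len(rec["genes"]) <= hi
    for name in truth.enriched_sets:
        members = sets[name]["genes"]
        frac = len(members & gradual) / len(members)
        assert frac >= 0.6
    for name in truth.prognostic_sets:
        assert sets[name]["genes"] & set(truth.gradual_up_genes)


def test_fixed_set_size_request():
    cfg = SyntheticConfig(n_genes=100, n_mirnas=5, n_sets=3,
                          n_enriched_sets=0, set_size_range=(5, 5), seed=0)
    rng = np.random.default_rng(0)
    _, _, _, truth = generate_cohort(cfg, rng)
    sets = generate_gene_sets(cfg, truth, rng, [f"G{i:04d}" for i in range(100)])
    assert all(len(rec["genes"]) == 5 for rec in sets.values())


def test_set_size_exceeding_universe_errors():
    cfg = SyntheticConfig(n_genes=100, n_mirnas=5, n_sets=3,
                          set_size_range=(5, 20), n_enriched_sets=0, seed=0)
    rng = np.random.default_rng(0)
    _, _, _, truth = generate_cohort(cfg, rng)
    with pytest.raises(ConfigError, match="universe"):
        generate_gene_sets(cfg, truth, rng, [f"G{i}" for i in range(10)])


def test_no_censoring_means_all_events(small_config, small_study):
    cfg = replace(small_config, censor_frac=0.0)
    rng = np.random.default_rng(9)
    d = small_study.discovery
    surv, _ = generate_survival(cfg, small_study.truth, d.expr_mrna,
                                d.annot, small_study.gene_sets, rng)
    assert (surv["event"] == 1).all()


def test_censoring_tuned_to_target():
    """Across seeds the censored fraction averages near censor_frac."""
    fracs = []
    cfg = SyntheticConfig(n_genes=200, n_mirnas=10, n_sets=4,
                          n_enriched_sets=2, censor_frac=0.3, seed=0)
    for seed in range(15):
        study = simulate_study(replace(cfg, seed=seed))
        fracs.append(1 - study.discovery.survival["event"].mean())
    se = np.sqrt(0.3 * 0.7 / (15 * cfg.n_pairs))
    assert abs(np.mean(fracs) - 0.3) < 3 * se


def test_mirna_anticorrelated_with_targets(small_study):
    """Planted coupling: miRNA expression moves against its targets."""
    d, truth = small_study.discovery, small_study.truth
    targets = {}
    for m, g in truth.true_target_edges:
        targets.setdefault(m, []).append(g)
    cors = []
    for m, genes in list(targets.items())[:30]:
        tbar = d.expr_mrna.loc[genes].mean(axis=0)
        cors.append(np.corrcoef(d.expr_mirna.loc[m], tbar)[0, 1])
    # coupling -0.5 diluted by residual noise: expect a clearly negative mean
    assert np.mean(cors) < -0.1


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        SyntheticConfig(n_genes=0)
    with pytest.raises(ConfigError):
        SyntheticConfig(delta=-1.0)
    with pytest.raises(ConfigError):
        SyntheticConfig(db_recall=1.5)
    with pytest.raises(ConfigError):
        SyntheticConfig(n_normal=1)
    with pytest.raises(ConfigError):
        SyntheticConfig(set_size_range=(1, 5))
    with pytest.raises(ConfigError):
        SyntheticConfig(beta_surv=float("nan"))


def test_written_study_round_trips(tmp_path, small_study):
    from gradprog import io

    write_study(small_study, tmp_path)
    mrna = io.read_expression(tmp_path / "discovery" / "expression_mrna.tsv")
    assert mrna.shape == small_study.discovery.expr_mrna.shape
    np.testing.assert_allclose(mrna, small_study.discovery.expr_mrna,
                               rtol=1e-4)
    annot = io.read_annotation(tmp_path / "discovery" / "annotation.tsv")
    assert len(annot) == len(small_study.discovery.annot)
    sets = io.read_gmt(tmp_path / "gene_sets.gmt")
    assert {k: v["genes"] for k, v in sets.items()} == {
        k: v["genes"] for k, v in small_study.gene_sets.items()
    }
    truth = io.read_json(tmp_path / "ground_truth.json")
    assert truth["prognostic_sets"] == small_study.truth.prognostic_sets
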