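"""End-to-end orchestration: simulate → DE → enrich → substitute → survive.

``run_pipeline`` chains the stages on a simulated study and returns a
manifest of per-stage counts: DEGs per comparison, enriched sets per DEG
group, classifiers tested, and classifiers passing discovery and
validation (validation = Wald p < 0.05 with the discovery hazard-ratio
sign, on an independent cohort sharing the planted truth).  Given the
same config and seed the manifest is byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import replace
from pathlib import Path

import pandas as pd

from gradprog import io
from gradprog.config import PipelineConfig
from gradprog.diffexpr import (
    run_comparisons,
    select_degs,
    venn_partition,
    write_comparison,
)
from gradprog.enrichment import enrich_all
from gradprog.mirna import build_consensus_map, substitute_mirnas
from gradprog.survival import Classifier, SurvivalError, evaluate_classifier
from gradprog.synthetic import simulate_study

log = logging.getLogger("gradprog")

#: profile mode used for a classifier discovered in a comparison's groups
MODE_BY_COMPARISON = {"C/N": "C", "C/P": "C/P", "P/N": "P/N"}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name: str):
    log.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full discovery procedure on a synthetic study."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    timers: dict[str, float] = {}

    def finish(name: str, t0: float) -> None:
        timers[name] = round(time.perf_counter() - t0, 3)

    # -- simulate ---------------------------------------------------------
    t0 = _stage("simulate")
    try:
        syn = replace(config.synthetic, seed=config.seed)
        study = simulate_study(syn)
    except Exception as exc:
        raise PipelineError(f"simulate: {exc}") from exc
    finish("simulate", t0)
    if out is not None:
        from gradprog.synthetic import write_study

        write_study(study, out / "data")

    # -- differential expression -----------------------------------------
    t0 = _stage("diffexpr")
    try:
        comparisons = run_comparisons(study.discovery.expr_mrna,
                                      study.discovery.annot)
        up, down = {}, {}
        for comp, res in comparisons.items():
            up[comp], down[comp] = select_degs(
                res, config.lfc_threshold, config.de_alpha
            )
        partition = venn_partition(up, down)
        deg_groups = partition.groups()
    except Exception as exc:
        raise PipelineError(f"diffexpr: {exc}") from exc
    finish("diffexpr", t0)
    if out is not None:
        for comp, res in comparisons.items():
            write_comparison(res, out / f"de_{comp.replace('/', '')}.tsv")

    # -- enrichment -------------------------------------------------------
    t0 = _stage("enrichment")
    try:
        records = enrich_all(
            comparisons,
            deg_groups,
            study.gene_sets,
            n_perm=config.n_perm,
            seed=config.seed,
            alpha=config.enrich_alpha,
            weight_exponent=config.gsea_weight,
        )
    except Exception as exc:
        raise PipelineError(f"enrichment: {exc}") from exc
    finish("enrichment", t0)
    if out is not None:
        records.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                       float_format="%.6g")

    enriched = records[records["enriched"]]

    # -- consensus target map --------------------------------------------
    t0 = _stage("consensus")
    try:
        tables = [study.target_tables[k] for k in sorted(study.target_tables)]
        cmap = build_consensus_map(tables, min_votes=config.min_votes)
    except Exception as exc:
        raise PipelineError(f"consensus: {exc}") from exc
    finish("consensus", t0)
    if out is not None:
        rows = sorted(
            (m, g, cmap.votes[k]) for k, (m, g) in cmap._display.items()
        )
        pd.DataFrame(rows, columns=["mirna_id", "gene_id", "votes"]).to_csv(
            out / "consensus_map.tsv", sep="\t", index=False
        )

    # -- classifiers ------------------------------------------------------
    t0 = _stage("classifiers")
    gene_classifiers: list[tuple[str, Classifier]] = []
    mirna_classifiers: list[tuple[str, Classifier]] = []
    for _, row in enriched.iterrows():
        set_name, group = row["set"], row["deg_group"]
        comp = group.rsplit("_", 1)[0]
        members = study.gene_sets[set_name]["genes"]
        degs = sorted(members & deg_groups[group])
        if not degs:
            continue
        mode = MODE_BY_COMPARISON[comp]
        gene_classifiers.append(
            (set_name, Classifier(name=f"{set_name}|{group}", features=degs,
                                  kind="gene", mode=mode))
        )
        mirnas = sorted(substitute_mirnas(set(degs), cmap))
        if mirnas:
            mirna_classifiers.append(
                (set_name, Classifier(name=f"{set_name}|{group}|miR",
                                      features=mirnas, kind="mirna", mode="C"))
            )
    finish("classifiers", t0)

    # -- survival ---------------------------------------------------------
    t0 = _stage("survival")
    results = []
    for source_set, clf in gene_classifiers + mirna_classifiers:
        expr_d = (study.discovery.expr_mrna if clf.kind == "gene"
                  else study.discovery.expr_mirna)
        expr_v = (study.validation.expr_mrna if clf.kind == "gene"
                  else study.validation.expr_mirna)
        try:
            disc = evaluate_classifier(clf, expr_d, study.discovery.annot,
                                       study.discovery.survival)
        except SurvivalError as exc:
            log.warning("classifier %s skipped: %s", clf.name, exc)
            results.append({"classifier": clf.name, "set": source_set,
                            "kind": clf.kind, "status": "skipped",
                            "reason": str(exc)})
            continue
        rec = {
            "classifier": clf.name, "set": source_set, "kind": clf.kind,
            "mode": clf.mode, "status": "tested",
            "n_features": len(clf.features),
            "n_missing": disc.n_features_missing,
            "beta": disc.beta, "se_beta": disc.se_beta,
            "wald_p": disc.wald_p, "logrank_chi2": disc.logrank_chi2,
            "logrank_p": disc.logrank_p,
            "discovery_significant": bool(disc.wald_p < 0.05),
            "validated": False,
        }
        if rec["discovery_significant"]:
            try:
                val = evaluate_classifier(clf, expr_v, study.validation.annot,
                                          study.validation.survival)
                rec["validation_beta"] = val.beta
                rec["validation_wald_p"] = val.wald_p
                rec["validation_logrank_p"] = val.logrank_p
                rec["validated"] = val.validates(disc)
            except SurvivalError as exc:
                log.warning("validation of %s failed: %s", clf.name, exc)
                rec["validation_error"] = str(exc)
        results.append(rec)
    finish("survival", t0)
    assoc = pd.DataFrame(results)
    if out is not None:
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False,
                     float_format="%.6g")

    # -- manifest ---------------------------------------------------------
    from gradprog import __version__

    tested = assoc[assoc.get("status", pd.Series(dtype=str)) == "tested"] \
        if len(assoc) else assoc
    validated_sets = sorted(
        set(tested.loc[tested.get("validated", False) == True, "set"])  # noqa: E712
    ) if len(tested) else []
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "counts": {
            "degs": {g: len(v) for g, v in sorted(deg_groups.items())},
            "venn_center_all": len(
                partition.venn["all"]["C/N&C/P&P/N"]
            ),
            "enriched_per_group": {
                g: int((enriched["deg_group"] == g).sum())
                for g in sorted(deg_groups)
            },
            "consensus_edges": len(cmap),
            "classifiers_tested": int(len(tested)),
            "discovery_significant": int(
                tested["discovery_significant"].sum()) if len(tested) else 0,
            "validated": int(tested["validated"].sum()) if len(tested) else 0,
        },
        "validated_sets": validated_sets,
        "planted_prognostic_sets": list(study.truth.prognostic_sets),
        "planted_set_validated": bool(
            set(study.truth.prognostic_sets) & set(validated_sets)
        ),
        "timings_s": timers,
    }
    if out is not None:
        io.write_json(manifest, out / "manifest.json")
    return manifest
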