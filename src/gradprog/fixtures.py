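"""Packaged example classifiers for hepatocellular carcinoma.

Two curated fixtures ship with the package:

* nine prognostic gene-set classifiers (set name, DEG members, the DEG
  group the set was enriched with, and the profile mode(s) used for
  scoring), e.g. the chr1q32 cytogenetic-band set scored on absolute
  cancer expression; and
* two miRNA substitution sets: for each source gene set, its DEG
  members and the consensus-supported miRNAs that target them (37 and
  22 miRNAs; the smaller gene list is a subset of the larger and so is
  its miRNA set).

``mirna_target_edges_synthetic.tsv`` is a synthetic per-edge
reconstruction of the consensus target map behind the second fixture:
only the set-level miRNA↔gene-list relations are curated, so individual
edges were wired minimally (every miRNA targets at least one gene of
the smallest list it belongs to).  Set-level substitution results are
exact; individual edges are not real predictions.
"""

from __future__ import annotations

from importlib import resources

from gradprog import io
from gradprog.mirna import ConsensusTargetMap, build_consensus_map
from gradprog.survival import Classifier


class FixtureError(ValueError):
    pass


def _data_path(name: str):
    return resources.files("gradprog.data").joinpath(name)


def load_gene_classifiers() -> list[dict]:
    """The nine gene-set classifiers, as recorded.

    Each record has ``name, deg_group, features, profiles`` (a record
    may carry several profile modes, e.g. both C and C/P).
    """
    with resources.as_file(_data_path("hcc_gene_classifiers.json")) as p:
        records = io.read_json(p)
    for rec in records:
        if not rec.get("features") or not rec.get("profiles"):
            raise FixtureError(f"malformed classifier record {rec.get('name')!r}")
    return records


def gene_classifier_objects() -> list[Classifier]:
    """One :class:`Classifier` per (record, profile mode)."""
    out = []
    for rec in load_gene_classifiers():
        for mode in rec["profiles"]:
            out.append(Classifier(name=rec["name"], features=rec["features"],
                                  kind="gene", mode=mode))
    return out


def load_mirna_sets() -> list[dict]:
    """The two miRNA substitution sets with their source DEG lists."""
    with resources.as_file(_data_path("hcc_mirna_sets.json")) as p:
        records = io.read_json(p)
    for rec in records:
        if not rec.get("mirnas") or not rec.get("deg_members"):
            raise FixtureError(f"malformed miRNA set record {rec.get('name')!r}")
    return records


def load_target_map() -> ConsensusTargetMap:
    """Synthetic consensus map reproducing the fixture substitutions.

    Built from the packaged single-table edge list with ``min_votes=1``
    (the table *is* the consensus; per-database provenance is not part
    of the fixture).
    """
    with resources.as_file(_data_path("mirna_target_edges_synthetic.tsv")) as p:
        edges = io.read_target_table(p)
    return build_consensus_map([edges], min_votes=1)


def load_fixtures() -> tuple[list[dict], list[dict], ConsensusTargetMap]:
    """All packaged fixtures: gene classifiers, miRNA sets, target map."""
    return load_gene_classifiers(), load_mirna_sets(), load_target_map()
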