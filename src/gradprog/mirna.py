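"""Consensus miRNA→gene target map and miRNA substitution of gene sets.

Target predictions disagree wildly between databases, so an edge is
trusted only when at least ``min_votes`` of the supplied tables (3 of 6
by default) report it.  Identifier matching is tolerant — miRNA IDs are
case-insensitive and species prefixes like ``hsa-`` are stripped for
matching only, gene symbols are upper-cased — while the first-seen
original spelling is preserved in the output.  Distinct mature arms
(-5p/-3p) stay distinct.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

SPECIES_PREFIXES = ("hsa-", "mmu-", "rno-")


class ConsensusError(ValueError):
    pass


def _norm_mirna(mirna_id: str) -> str:
    key = mirna_id.strip().lower()
    for prefix in SPECIES_PREFIXES:
        if key.startswith(prefix):
            key = key[len(prefix):]
            break
    return key


def _norm_gene(gene_id: str) -> str:
    return gene_id.strip().upper()


@dataclass
class ConsensusTargetMap:
    """miRNA→gene edges surviving the multi-database vote.

    ``votes`` maps a normalized ``(mirna, gene)`` key to its vote count
    (always >= the threshold used to build the map); ``by_gene`` and
    ``by_mirna`` are the two symmetric lookup indices, holding original
    identifier spellings.
    """

    min_votes: int
    votes: dict[tuple[str, str], int] = field(default_factory=dict)
    by_gene: dict[str, set[str]] = field(default_factory=dict)
    by_mirna: dict[str, set[str]] = field(default_factory=dict)
    _display: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.votes)

    def edges(self) -> set[tuple[str, str]]:
        """Edges with original spellings."""
        return {self._display[key] for key in self.votes}

    def mirnas_targeting(self, gene_id: str) -> set[str]:
        return set(self.by_gene.get(_norm_gene(gene_id), set()))

    def targets_of(self, mirna_id: str) -> set[str]:
        return set(self.by_mirna.get(_norm_mirna(mirna_id), set()))


def build_consensus_map(
    tables: list[set[tuple[str, str]]], min_votes: int = 3
) -> ConsensusTargetMap:
    """Keep the edges present in at least ``min_votes`` distinct tables.

    ``tables`` holds one ``{(mirna_id, gene_id), ...}`` edge set per
    database; duplicate edges within one table count once.
    """
    if not 1 <= len(tables) <= 6:
        raise ConsensusError("expected between 1 and 6 target tables")
    if min_votes < 1 or min_votes > len(tables):
        raise ConsensusError(
            f"min_votes={min_votes} incompatible with {len(tables)} tables"
        )
    counts: Counter[tuple[str, str]] = Counter()
    display: dict[tuple[str, str], tuple[str, str]] = {}
    for table in tables:
        seen = set()
        for mirna, gene in table:
            key = (_norm_mirna(mirna), _norm_gene(gene))
            if key in seen:
                continue
            seen.add(key)
            counts[key] += 1
            display.setdefault(key, (mirna, gene))

    cmap = ConsensusTargetMap(min_votes=min_votes)
    for key, n in counts.items():
        if n >= min_votes:
            cmap.votes[key] = n
            cmap._display[key] = display[key]
            mirna, gene = display[key]
            cmap.by_gene.setdefault(key[1], set()).add(mirna)
            cmap.by_mirna.setdefault(key[0], set()).add(gene)
    return cmap


def substitute_mirnas(
    gene_set_degs: set[str], cmap: ConsensusTargetMap
) -> set[str]:
    """Union of miRNAs targeting any gene of the set's DEG members.

    An empty result is a legitimate outcome (none of the members has a
    consensus-supported regulator).
    """
    mirnas: set[str] = set()
    for gene in gene_set_degs:
        mirnas |= cmap.mirnas_targeting(gene)
    return mirnas
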