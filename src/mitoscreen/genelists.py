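"""Organelle gene lists and protein-to-gene identifier mapping.

An organelle list starts from a proteome inventory (e.g. a mitochondrial
proteome catalogue); protein or alias identifiers are converted to canonical
gene symbols through a frozen alias table, and the list is then restricted
to the genes actually measured on the expression platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["GeneList", "AliasTable", "proteome_to_genelist", "restrict_to_measured"]


def canonical(gene_id: str) -> str:
    return gene_id.strip().upper()


@dataclass(frozen=True)
class GeneList:
    """Named, order-free set of canonical (uppercase) gene identifiers."""

    name: str
    members: frozenset[str]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(canonical(m) for m in self.members))

    @property
    def size(self) -> int:
        return len(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return canonical(gene_id) in self.members


@dataclass
class AliasTable:
    """Many-to-one, case-insensitive mapping alias -> canonical gene ID."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        norm: dict[str, str] = {}
        for alias, gene in self.mapping.items():
            key = canonical(alias)
            target = canonical(gene)
            if key in norm and norm[key] != target:
                raise ValueError(
                    f"alias {alias!r} maps to both {norm[key]!r} and {target!r}"
                )
            norm[key] = target
        self.mapping = norm

    def __len__(self) -> int:
        return len(self.mapping)

    def get(self, alias: str) -> str | None:
        return self.mapping.get(canonical(alias))


def proteome_to_genelist(
    proteins: Iterable[str], aliases: AliasTable, name: str, provenance: str = ""
) -> tuple[GeneList, list[str]]:
    """Convert a proteome inventory into a transcript (gene) list.

    Returns the GeneList plus the distinct protein IDs that could not be
    mapped; unmapped IDs are reported, never silently dropped.
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("protein list is empty")
    if len(aliases) == 0:
        raise ValueError("alias table is empty")
    seen: set[str] = set()
    members: set[str] = set()
    unmapped: list[str] = []
    for pid in proteins:
        key = canonical(pid)
        if key in seen:
            continue
        seen.add(key)
        gene = aliases.get(key)
        if gene is None:
            unmapped.append(pid)
        else:
            members.add(gene)
    if unmapped:
        logger.info("gene list %s: %d protein IDs unmapped", name, len(unmapped))
    return GeneList(name=name, members=frozenset(members), provenance=provenance), unmapped


def restrict_to_measured(gene_list: GeneList, matrix: "ExpressionMatrix") -> GeneList:
    """Intersect a gene list with the genes measured in the matrix.

    Raises if the intersection is empty — set statistics are undefined on an
    empty list.
    """
    measured = {canonical(g) for g in matrix.gene_ids}
    kept = gene_list.members & measured
    dropped = gene_list.size - len(kept)
    if dropped:
        logger.info(
            "gene list %s: %d members not measured on this platform", gene_list.name, dropped
        )
    if not kept:
        raise ValueError(f"gene list {gene_list.name!r} shares no genes with the matrix")
    return GeneList(
        name=gene_list.name,
        members=frozenset(kept),
        provenance=gene_list.provenance or f"{gene_list.name} restricted to measured genes",
    )
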