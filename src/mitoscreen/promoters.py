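"""Strand-aware promoter window extraction around annotated TSS.

The window spans positions -upstream..-1 and +1..+downstream with the TSS
at +1 (there is no position 0), so the default -500/+100 window is 600 bp.
Sequences are returned promoter-sense: minus-strand windows are
reverse-complemented.  Windows running off a contig edge are N-padded to
full length and flagged rather than dropped, so promoter counts stay equal
to gene counts.

Genomic intervals are BED-style 0-based half-open; error messages use
1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "TssRecord",
    "PromoterRecord",
    "PromoterSet",
    "extract_promoters",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TssRecord:
    gene_id: str
    chrom: str
    position: int  # 1-based TSS coordinate
    strand: str
    transcript_id: str | None = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"{self.gene_id}: TSS position must be >= 1 (1-based)")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    sequence: str  # promoter-sense
    chrom: str
    start: int  # 0-based half-open genomic interval
    end: int
    strand: str
    truncated: bool = False


class PromoterSet:
    """One promoter-sense sequence per gene, all the same length."""

    def __init__(self, records: Iterable[PromoterRecord]):
        self._records: dict[str, PromoterRecord] = {}
        for rec in records:
            if rec.gene_id in self._records:
                raise ValueError(f"duplicate promoter for gene {rec.gene_id}")
            self._records[rec.gene_id] = rec
        lengths = {len(r.sequence) for r in self._records.values()}
        if len(lengths) > 1:
            raise ValueError(f"promoter sequences have mixed lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._records

    def __getitem__(self, gene_id: str) -> PromoterRecord:
        return self._records[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._records)

    def sequences(self) -> dict[str, str]:
        return {g: r.sequence for g, r in self._records.items()}

    def reverse_complemented(self) -> "PromoterSet":
        """Same promoters read on the opposite strand (for symmetry checks)."""
        flipped = {"+": "-", "-": "+"}
        return PromoterSet(
            PromoterRecord(
                gene_id=r.gene_id,
                sequence=reverse_complement(r.sequence),
                chrom=r.chrom,
                start=r.start,
                end=r.end,
                strand=flipped[r.strand],
                truncated=r.truncated,
            )
            for r in self._records.values()
        )


def _designate(tss: Iterable[TssRecord]) -> list[TssRecord]:
    """Resolve one TSS per gene: a single record, or a single record carrying
    a transcript_id designation among several; anything else is an error."""
    by_gene: dict[str, list[TssRecord]] = {}
    for rec in tss:
        by_gene.setdefault(rec.gene_id, []).append(rec)
    chosen = []
    ambiguous = []
    for gene, recs in by_gene.items():
        if len(recs) == 1:
            chosen.append(recs[0])
            continue
        designated = [r for r in recs if r.transcript_id]
        if len(designated) == 1:
            chosen.append(designated[0])
        else:
            ambiguous.append(gene)
    if ambiguous:
        raise ValueError(
            "multiple undesignated TSS records for gene(s): " + ", ".join(sorted(ambiguous))
        )
    return chosen


def extract_promoters(
    genome: Mapping[str, str] | str | Path,
    tss: Iterable[TssRecord],
    upstream: int = 500,
    downstream: int = 100,
) -> PromoterSet:
    """Extract promoter-sense windows of `upstream + downstream` bp.

    `genome` is either a mapping chrom -> sequence or a FASTA path (read
    through pyfaidx).  Plus strand, TSS at 1-based g: genomic interval
    [g-1-upstream, g-1+downstream); minus strand: [g-downstream, g+upstream)
    reverse-complemented.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be >= 0")
    length = upstream + downstream
    if length == 0:
        raise ValueError("promoter window has zero length")

    if isinstance(genome, (str, Path)):
        import pyfaidx

        fasta = pyfaidx.Fasta(str(genome), sequence_always_upper=True)
        contigs: Mapping = fasta
        contig_len = {name: len(fasta[name]) for name in fasta.keys()}
    else:
        contigs = genome
        contig_len = {name: len(seq) for name, seq in genome.items()}

    records = []
    for rec in _designate(tss):
        if rec.chrom not in contig_len:
            raise ValueError(f"{rec.gene_id}: chromosome {rec.chrom!r} not in genome")
        clen = contig_len[rec.chrom]
        if rec.position > clen:
            raise ValueError(
                f"{rec.gene_id}: TSS position {rec.position} beyond contig "
                f"{rec.chrom} length {clen} (1-based)"
            )
        g = rec.position
        if rec.strand == "+":
            start, end = g - 1 - upstream, g - 1 + downstream
        else:
            start, end = g - downstream, g + upstream
        lo, hi = max(start, 0), min(end, clen)
        raw = str(contigs[rec.chrom][lo:hi]).upper()
        left_pad = lo - start
        right_pad = end - hi
        seq = "N" * left_pad + raw + "N" * right_pad
        if rec.strand == "-":
            seq = reverse_complement(seq)
        assert len(seq) == length
        records.append(
            PromoterRecord(
                gene_id=rec.gene_id,
                sequence=seq,
                chrom=rec.chrom,
                start=max(start, 0),
                end=min(end, clen),
                strand=rec.strand,
                truncated=bool(left_pad or right_pad),
            )
        )
    return PromoterSet(records)
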