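"""Readers and writers for the plain-text formats the screen consumes.

Expression matrices are delimited text with gene IDs in the first column;
gene lists are single-column files or GMT lines; binding-site matrices come
in JASPAR-style or TRANSFAC-style text blocks, with the TF family carried
in the record name using the FAMILY/NAME convention; TSS records are BED6
(name = gene id) or TSV; regulator networks and alias/name maps are small
TSV tables.  All parsing is locale-independent (decimal point only).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genelists import AliasTable, GeneList
from .motifs import BASES, PositionFrequencyMatrix
from .promoters import PromoterRecord, PromoterSet, TssRecord
from .regulators import RegulatorNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_group_map",
    "write_group_map",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_pfms",
    "write_pfms",
    "read_tss",
    "read_network",
    "write_network",
    "read_alias_table",
    "read_name_map",
    "write_name_map",
    "read_promoters_fasta",
    "write_promoters_fasta",
]


def _sniff_delimiter(path: str | Path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


# ---------------------------------------------------------------- expression


def read_expression_matrix(
    path: str | Path,
    group_map: Mapping[str, str],
    scale: str = "log2",
) -> ExpressionMatrix:
    """Read a genes x samples delimited table (first column gene IDs).

    Duplicate gene rows are collapsed by mean (logged); duplicate sample
    names, non-numeric cells and samples missing from `group_map` are
    errors.
    """
    sep = _sniff_delimiter(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    samples = header[1:]
    dupes = {s for s in samples if samples.count(s) > 1}
    if dupes:
        raise ValueError(f"duplicate sample names in {path}: {sorted(dupes)}")
    missing = [s for s in samples if s not in group_map]
    if missing:
        raise ValueError(f"samples absent from group map: {missing}")

    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value {df.loc[bad[0], col]!r} at gene {bad[0]!r}, "
                f"sample {col!r}"
            )
        numeric[col] = converted
    n_dup = int(numeric.index.duplicated().sum())
    if n_dup:
        logger.info("collapsed %d duplicate gene rows by mean", n_dup)
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(values=numeric, sample_groups=dict(group_map), scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample, group."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sample, group = line.split("\t")[:2]
            if sample in out:
                raise ValueError(f"duplicate sample {sample!r} in group map")
            out[sample] = group
    if not out:
        raise ValueError(f"group map {path} is empty")
    return out


def write_group_map(group_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, group in group_map.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------- gene lists


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Single-column gene list (one ID per line); duplicates removed with a
    logged count.  For GMT files use :func:`read_gmt`."""
    path = Path(path)
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    if not ids:
        raise ValueError(f"gene list file {path} is empty")
    members = frozenset(i.upper() for i in ids)
    n_dup = len(ids) - len(members)
    if n_dup:
        logger.info("gene list %s: removed %d duplicate IDs", path.name, n_dup)
    return GeneList(name=name or path.stem, members=members, provenance=str(path))


def write_gene_list(gene_list: GeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(gene_list.members):
            fh.write(gene + "\n")


def read_gmt(path: str | Path) -> list[GeneList]:
    """GMT: name <tab> description <tab> member1 <tab> member2 ..."""
    lists = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description, members")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{ln}: gene set {name!r} has no members")
            lists.append(
                GeneList(name=name, members=frozenset(m.upper() for m in members), provenance=desc)
            )
    if not lists:
        raise ValueError(f"GMT file {path} is empty")
    return lists


def write_gmt(lists: list[GeneList], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gl in lists:
            fh.write("\t".join([gl.name, gl.provenance or ".", *sorted(gl.members)]) + "\n")


# ----------------------------------------------------------------------- PFM


def _split_family(name: str) -> tuple[str, str]:
    """FAMILY/NAME convention; family defaults to the matrix name."""
    if "/" in name:
        family, _, rest = name.partition("/")
        if family and rest:
            return family, name
    return name, name


def _build_pfm(name: str, rows: list[list[float]], source: str) -> PositionFrequencyMatrix:
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{source}: ragged count rows for matrix {name!r}")
    counts = np.array(rows, dtype=float)
    family, full_name = _split_family(name)
    return PositionFrequencyMatrix(name=full_name, family=family, counts=counts)


def _read_pfms_jaspar(path: Path) -> list[PositionFrequencyMatrix]:
    pfms = []
    name = None
    rows: list[list[float]] = []

    def flush():
        if name is None:
            return
        if len(rows) != 4:
            raise ValueError(f"{path}: matrix {name!r} has {len(rows)} base rows, expected 4")
        pfms.append(_build_pfm(name, rows, str(path)))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                rows = []
            else:
                body = line
                if body[0] in BASES and len(body) > 1 and not body[1].isdigit():
                    body = body[1:]
                body = body.replace("[", " ").replace("]", " ")
                rows.append([float(tok) for tok in body.split()])
    flush()
    if not pfms:
        raise ValueError(f"no matrices found in {path}")
    return pfms


def _read_pfms_transfac(path: Path) -> list[PositionFrequencyMatrix]:
    pfms = []
    name = None
    order: list[int] | None = None
    rows: list[list[float]] = []

    def flush():
        nonlocal name, order, rows
        if name is None and not rows:
            return
        if name is None:
            raise ValueError(f"{path}: TRANSFAC block without ID line")
        if order is None:
            raise ValueError(f"{path}: matrix {name!r} has no P0 header")
        by_pos = rows  # rows are per-position [A C G T] in P0 order
        base_rows = [[], [], [], []]
        for r in by_pos:
            if len(r) != 4:
                raise ValueError(f"{path}: ragged count rows for matrix {name!r}")
            for col_idx, base_idx in enumerate(order):
                base_rows[base_idx].append(r[col_idx])
        pfms.append(_build_pfm(name, base_rows, str(path)))
        name, order, rows = None, None, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            tag, _, rest = line.partition(" ")
            rest = rest.strip()
            if tag == "//":
                flush()
            elif tag in ("ID", "NA") and name is None:
                name = rest.split()[0]
            elif tag == "P0" or tag == "PO":
                letters = rest.split()
                if sorted(letters) != sorted(BASES):
                    raise ValueError(f"{path}: P0 header must list A C G T, got {letters}")
                order = [BASES.index(b) for b in letters]
            elif tag[:2].isdigit():
                toks = rest.split()
                # trailing consensus letter is optional in TRANSFAC rows
                if toks and toks[-1].isalpha():
                    toks = toks[:-1]
                rows.append([float(t) for t in toks])
    if name is not None or rows:
        flush()
    if not pfms:
        raise ValueError(f"no matrices found in {path}")
    return pfms


def read_pfms(path: str | Path, dialect: str = "jaspar") -> list[PositionFrequencyMatrix]:
    """Read binding-site count matrices; family tag from the FAMILY/NAME
    record name (family defaults to the matrix name)."""
    path = Path(path)
    if dialect == "jaspar":
        return _read_pfms_jaspar(path)
    if dialect == "transfac":
        return _read_pfms_transfac(path)
    raise ValueError(f"unknown PFM dialect {dialect!r}")


def write_pfms(pfms: list[PositionFrequencyMatrix], path: str | Path) -> None:
    """Write matrices in the JASPAR-style dialect read by :func:`read_pfms`."""
    with open(path, "w") as fh:
        for pwm in pfms:
            if pwm.family == pwm.name or pwm.name.startswith(pwm.family + "/"):
                header = pwm.name
            else:
                header = f"{pwm.family}/{pwm.name}"
            fh.write(f">{header}\n")
            for i, base in enumerate(BASES):
                vals = " ".join(format(v, "g") for v in pwm.counts[i])
                fh.write(f"{base} [ {vals} ]\n")


# ----------------------------------------------------------------------- TSS


def read_tss(path: str | Path) -> list[TssRecord]:
    """BED6 (chrom, start, end, gene_id, score, strand; TSS = start for +,
    end for -) or 4+-column TSV (gene_id, chrom, position, strand
    [, transcript_id]) with a header line."""
    path = Path(path)
    records = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith(("#", "track"))]
    if not lines:
        raise ValueError(f"TSS file {path} is empty")
    first = lines[0].split("\t")
    is_bed = len(first) >= 6 and first[1].isdigit() and first[2].isdigit()
    if is_bed:
        for line in lines:
            chrom, start, end, gene_id, _score, strand = line.split("\t")[:6]
            # BED is 0-based half-open; TSS is the 5' end of the feature
            pos = int(start) + 1 if strand == "+" else int(end)
            records.append(TssRecord(gene_id=gene_id, chrom=chrom, position=pos, strand=strand))
    else:
        body = lines[1:] if first[0].lower() in ("gene", "gene_id") else lines
        for line in body:
            fields = line.split("\t")
            gene_id, chrom, pos, strand = fields[:4]
            transcript = fields[4] if len(fields) > 4 and fields[4] else None
            records.append(
                TssRecord(
                    gene_id=gene_id,
                    chrom=chrom,
                    position=int(pos),
                    strand=strand,
                    transcript_id=transcript,
                )
            )
    return records


# ------------------------------------------------------------------- network


def read_network(path: str | Path) -> RegulatorNetwork:
    """Three-column TSV: TF, target, sign (+1/-1/0); header optional."""
    edges = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: expected TF, target, sign")
            tf, target, sign = fields[:3]
            if ln == 1 and sign.lower() == "sign":
                continue
            edges.append((tf, target, int(sign)))
    return RegulatorNetwork(edges)


def write_network(network: RegulatorNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\ttarget\tsign\n")
        for e in network.edges():
            fh.write(f"{e.tf}\t{e.target}\t{e.sign:+d}\n")


# ------------------------------------------------------------------ mappings


def _read_two_column(path: str | Path, what: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, value = line.split("\t")[:2]
            out[key] = value
    if not out:
        raise ValueError(f"{what} file {path} is empty")
    return out


def read_alias_table(path: str | Path) -> AliasTable:
    """Two-column TSV: alias (protein ID), canonical gene symbol."""
    return AliasTable(_read_two_column(path, "alias table"))


def read_name_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: motif/matrix name, gene symbol."""
    return _read_two_column(path, "name map")


def write_name_map(name_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, value in name_map.items():
            fh.write(f"{key}\t{value}\n")


# ----------------------------------------------------------------- promoters


def write_promoters_fasta(promoters: PromoterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in promoters:
            flag = " truncated" if rec.truncated else ""
            fh.write(f">{rec.gene_id} {rec.chrom}:{rec.start}-{rec.end}({rec.strand}){flag}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def read_promoters_fasta(path: str | Path) -> PromoterSet:
    """Read promoters written by :func:`write_promoters_fasta` (or any FASTA;
    location metadata defaults to a dummy interval on chrom '.')."""
    records = []
    gene_id, meta, chunks = None, None, []

    def flush():
        if gene_id is None:
            return
        seq = "".join(chunks).upper()
        chrom, start, end, strand, truncated = ".", 0, len(seq), "+", False
        if meta:
            loc = meta[0]
            truncated = "truncated" in meta
            if ":" in loc and "(" in loc:
                chrom, _, rest = loc.partition(":")
                span, _, strand_part = rest.partition("(")
                start_s, _, end_s = span.partition("-")
                start, end = int(start_s), int(end_s)
                strand = strand_part.rstrip(")")
        records.append(
            PromoterRecord(
                gene_id=gene_id, sequence=seq, chrom=chrom, start=start, end=end,
                strand=strand, truncated=truncated,
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                gene_id, meta, chunks = parts[0], parts[1:], []
            elif line:
                chunks.append(line)
    flush()
    if not records:
        raise ValueError(f"no sequences in {path}")
    return PromoterSet(records)
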