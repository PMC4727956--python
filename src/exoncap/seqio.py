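"""Format layer: FASTA/FASTQ, relaxed PHYLIP, NEXUS, newick, TSV.

All readers are line-ending agnostic; writers emit LF. Alignments move
through the toolkit as ``(names, rows)`` pairs or ``{name: seq}`` dicts;
trees as dendropy objects; tables as pandas DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import pandas as pd
from Bio import AlignIO, SeqIO


class FormatError(ValueError):
    """Malformed record in an input file."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path) -> list[tuple[str, str]]:
    recs = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            recs.append((rec.description, str(rec.seq).upper()))
    return recs


def write_fasta(path, records, width: int = 70) -> None:
    """``records``: iterable of (header, sequence)."""
    with open(path, "w", newline="\n") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> list[tuple[str, str, list[int]]]:
    """Returns (id, sequence, phred qualities). Sanger encoding."""
    out = []
    try:
        with open(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                out.append((rec.id, str(rec.seq).upper(),
                            rec.letter_annotations["phred_quality"]))
    except ValueError as e:
        raise FormatError(f"{path}: malformed FASTQ record {len(out) + 1}: {e}") from e
    return out


def write_fastq(path, records) -> None:
    """``records``: iterable of (id, sequence, phred qualities)."""
    with open(path, "w", newline="\n") as fh:
        for rid, seq, quals in records:
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# Structured FASTA headers for reference exons

@dataclass
class ExonHeader:
    exon_id: str
    gene_id: str
    chromosome: str
    start: int
    end: int
    frame: int

    def format(self) -> str:
        return "|".join([self.exon_id, self.gene_id, self.chromosome,
                         str(self.start), str(self.end), str(self.frame)])


def parse_exon_header(header: str) -> ExonHeader:
    parts = header.split()[0].split("|")
    if len(parts) != 6:
        raise FormatError(
            f"exon header must have 6 '|'-separated fields "
            f"(exon_id|gene_id|chrom|start|end|frame): {header!r}")
    try:
        return ExonHeader(parts[0], parts[1], parts[2],
                          int(parts[3]), int(parts[4]), int(parts[5]))
    except ValueError as e:
        raise FormatError(f"bad exon header {header!r}: {e}") from e


# ---------------------------------------------------------------------------
# Relaxed PHYLIP

def write_phylip(path, names: list[str], rows: list[str]) -> None:
    """Relaxed PHYLIP: full names, single space separator, sequential."""
    if len({len(r) for r in rows}) > 1:
        raise FormatError("phylip rows must be equal length")
    pad = max(len(n) for n in names) + 2
    with open(path, "w", newline="\n") as fh:
        fh.write(f" {len(names)} {len(rows[0])}\n")
        for n, r in zip(names, rows):
            fh.write(n.ljust(pad) + r + "\n")


def read_phylip(path, strict: bool = False) -> tuple[list[str], list[str]]:
    fmt = "phylip" if strict else "phylip-relaxed"
    try:
        with open(path) as fh:
            aln = AlignIO.read(fh, fmt)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e
    return [r.id for r in aln], [str(r.seq).upper() for r in aln]


# ---------------------------------------------------------------------------
# NEXUS (DATA + SETS blocks, the dialect consumed by partitioned ML tools)

def write_nexus(path, names, rows, charsets: list[tuple[str, str]] | None = None,
                missing: str = "?") -> None:
    """``charsets``: (name, range-expression) pairs, e.g. ("g1_pos1", "1-300\\3")."""
    with open(path, "w", newline="\n") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(names)} NCHAR={len(rows[0])};\n")
        fh.write(f"  FORMAT DATATYPE=DNA MISSING={missing} GAP=-;\n  MATRIX\n")
        pad = max(len(n) for n in names) + 2
        for n, r in zip(names, rows):
            fh.write("    " + n.ljust(pad) + r + "\n")
        fh.write("  ;\nEND;\n")
        if charsets:
            fh.write("\nBEGIN SETS;\n")
            for name, expr in charsets:
                fh.write(f"  CHARSET {name} = {expr};\n")
            fh.write("END;\n")


def read_nexus(path) -> tuple[list[str], list[str], list[tuple[str, str]]]:
    """Minimal reader for the dialect written by :func:`write_nexus`."""
    names, rows, charsets = [], [], []
    in_matrix = False
    for lineno, raw in enumerate(open(path), 1):
        line = raw.strip()
        up = line.upper()
        if up == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if line.startswith(";"):
                in_matrix = False
                continue
            if line:
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(f"{path}:{lineno}: bad matrix row")
                names.append(parts[0])
                rows.append(parts[1].upper())
        elif up.startswith("CHARSET"):
            body = line[7:].strip().rstrip(";")
            name, expr = body.split("=", 1)
            charsets.append((name.strip(), expr.strip()))
    if not names:
        raise FormatError(f"{path}: no MATRIX block found")
    return names, rows, charsets


# ---------------------------------------------------------------------------
# Newick trees

def read_newick(source) -> dendropy.Tree:
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        return dendropy.Tree.get(path=str(source), schema="newick", preserve_underscores=True)
    return dendropy.Tree.get(data=str(source), schema="newick", preserve_underscores=True)


def write_newick(path, tree: dendropy.Tree) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


# ---------------------------------------------------------------------------
# TSV tables

def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(path, df: pd.DataFrame) -> None:
    with open(path, "w", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False)
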