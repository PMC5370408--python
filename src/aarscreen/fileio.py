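"""Readers/writers for the formats the pipeline touches.

FASTA goes through Bio.SeqIO (dialect-tolerant on read; 60-column wrap on
write). GFF3 uses a minimal round-trip-exact reader/writer for the simple
feature rows emitted here (version pragma, 1-based inclusive coordinates,
ordered ``key=value`` attributes). Newick goes through the package Tree
(dendropy tokenises on read). Malformed inputs raise with a line number.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tree import Tree

GFF3_PRAGMA = "##gff-version 3"


# ------------------------------------------------------------------ FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Sequence[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ------------------------------------------------------------------ GFF3

def _parse_attributes(text: str, lineno: int) -> dict:
    attrs: dict[str, str] = {}
    for chunk in text.rstrip(";").split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"line {lineno}: malformed attribute {chunk!r}")
        k, v = chunk.split("=", 1)
        attrs[k] = v
    return attrs


def read_gff3(path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"line {lineno}: expected 9 columns, got {len(parts)}")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates "
                                 f"{parts[3]!r}..{parts[4]!r}") from None
            if start > end:
                raise ValueError(f"line {lineno}: start {start} > end {end}")
            if parts[6] not in "+-.":
                raise ValueError(f"line {lineno}: bad strand {parts[6]!r}")
            rows.append({
                "seqid": parts[0], "source": parts[1], "type": parts[2],
                "start": start, "end": end, "score": parts[5],
                "strand": parts[6], "phase": parts[7],
                "attributes": _parse_attributes(parts[8], lineno),
                "line": lineno,
            })
    return rows


def write_gff3(path, rows: Sequence[dict]) -> None:
    with open(path, "w") as fh:
        fh.write(GFF3_PRAGMA + "\n")
        for row in rows:
            attrs = ";".join(f"{k}={v}" for k, v in row["attributes"].items())
            fh.write("\t".join([
                row["seqid"], row["source"], row["type"],
                str(row["start"]), str(row["end"]), row.get("score", "."),
                row["strand"], row.get("phase", "."), attrs]) + "\n")


# ------------------------------------------------------------------ Newick

def read_newick(path) -> Tree:
    with open(path) as fh:
        return Tree.from_newick(fh.read())


def write_newick(path, tree: Tree) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ------------------------------------------------------------------ tables

def write_tsv(path, rows: Sequence[dict], columns: Optional[list] = None) -> None:
    if columns is None:
        columns = sorted({k for r in rows for k in r})
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join(str(r.get(c, "")) for c in columns) + "\n")


def read_tsv(path) -> list[dict]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return []
    cols = lines[0].split("\t")
    return [dict(zip(cols, line.split("\t"))) for line in lines[1:]]


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


# ------------------------------------------------------------------ references

def read_reference_set(fasta_path, labels_path):
    """Reference proteins (FASTA) + 2-column-or-3 label TSV (id, family, lineage)."""
    from .aars import Reference

    seqs = dict(read_fasta(fasta_path))
    refs = []
    for lineno, row in enumerate(read_tsv(labels_path), start=2):
        rid = row.get("id")
        if rid is None or rid not in seqs:
            raise ValueError(f"{labels_path}: line {lineno}: id {rid!r} "
                             "missing from reference FASTA")
        refs.append(Reference(rid, row.get("family", "unknown"),
                              row.get("lineage", "unassigned"), seqs[rid]))
    return refs


def write_reference_set(fasta_path, labels_path, refs) -> None:
    write_fasta(fasta_path, [(r.id, r.sequence) for r in refs])
    write_tsv(labels_path,
              [{"id": r.id, "family": r.family, "lineage": r.lineage}
               for r in refs],
              columns=["id", "family", "lineage"])
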