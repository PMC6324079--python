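"""Readers and writers for the interchange formats.

All tables are tab-separated with a single commented header line (``#``).
Identifiers are opaque strings: species are attached only through the
explicit protein->species map, never parsed out of identifiers. Writers
emit rows in sorted order so outputs are diffable.
"""
from __future__ import annotations

import hashlib
import io as _io
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .cluster import OrthologousGroup
from .qc import GenomeRecord, QCResult
from .simgraph import ScoreTable, normalize_scores
from .taxonomy import Taxonomy

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_scores",
    "read_species_map",
    "write_species_map",
    "read_genomes_tsv",
    "read_marker_hits",
    "write_qc_report",
    "read_taxonomy",
    "write_taxonomy",
    "read_og_tsv",
    "write_og_tsv",
    "read_groups_tsv",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "file_sha256",
]

_SEQ_RE = re.compile(r"^[A-Za-z\-\.\*]+$")


# -- FASTA ------------------------------------------------------------------

def read_fasta(
    path: str | Path, strict: bool = False, with_descriptions: bool = False
):
    """Ordered map id -> sequence; descriptions kept separately on request.

    Duplicate ids are an error; in strict mode non-sequence characters are
    too.
    """
    seqs: dict[str, str] = {}
    descs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq)
        if strict and not _SEQ_RE.match(seq):
            raise ValueError(f"non-sequence characters in record {rec.id!r}")
        seqs[rec.id] = seq
        desc = rec.description[len(rec.id):].strip()
        descs[rec.id] = desc
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return (seqs, descs) if with_descriptions else seqs


def write_fasta(
    path: str | Path,
    seqs: Mapping[str, str],
    descriptions: Mapping[str, str] | None = None,
) -> None:
    records = []
    for name, seq in seqs.items():
        desc = descriptions.get(name, "") if descriptions else ""
        records.append(SeqRecord(Seq(seq), id=name, description=desc))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


# -- Newick -----------------------------------------------------------------

def read_newick(source: str | Path) -> TreeNode:
    """Parse a Newick tree (file path or literal string)."""
    text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in Newick input")
    tree = TreeNode.read(_io.StringIO(text), convert_underscores=False)
    for tip in tree.tips():
        if not tip.name:
            raise ValueError("empty leaf name in Newick input")
    return tree


def write_newick(path: str | Path, tree: TreeNode) -> None:
    tree.write(str(path))


# -- score tables -----------------------------------------------------------

def read_scores(
    path: str | Path,
    species_of: Mapping[str, str],
    dialect: str = "simple",
) -> ScoreTable:
    """Read an all-vs-all hit table and normalize it.

    ``simple`` dialect: query, subject, score in the first three columns
    (extra columns ignored). ``outfmt6``: BLAST tabular, bitscore in column
    12. Non-numeric scores are reported with their line number.
    """
    col = {"simple": 2, "outfmt6": 11}.get(dialect)
    if col is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    raw: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) <= col:
                raise ValueError(f"{path}:{lineno}: expected >={col + 1} columns")
            try:
                score = float(fields[col])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric score {fields[col]!r}"
                ) from None
            key = (fields[0], fields[1])
            if key not in raw or score > raw[key]:
                raw[key] = score
    return normalize_scores(raw, species_of)


# -- simple TSVs ------------------------------------------------------------

def _write_tsv(path: str | Path, header: list[str], rows: Iterable[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for row in sorted(rows):
            fh.write("\t".join(str(x) for x in row) + "\n")


def _read_tsv(path: str | Path, n_cols: int) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, dtype=str, skip_blank_lines=True
    )
    if df.shape[1] < n_cols:
        raise ValueError(f"{path}: expected >= {n_cols} columns")
    return df


def read_species_map(path: str | Path) -> dict[str, str]:
    df = _read_tsv(path, 2)
    out: dict[str, str] = {}
    for prot, sp in zip(df[0], df[1]):
        if prot in out and out[prot] != sp:
            raise ValueError(f"protein {prot!r} mapped to two species")
        out[prot] = sp
    return out


def write_species_map(path: str | Path, species_of: Mapping[str, str]) -> None:
    _write_tsv(path, ["protein_id", "species_id"], species_of.items())


def read_genomes_tsv(path: str | Path) -> list[GenomeRecord]:
    """genome_id, is_viral (0/1), comma-separated contig lengths, n_proteins."""
    df = _read_tsv(path, 4)
    records = []
    for gid, viral, contigs, n_prot in zip(df[0], df[1], df[2], df[3]):
        lengths = tuple(
            int(x) for x in str(contigs).split(",") if x and x != "nan"
        )
        records.append(
            GenomeRecord(
                genome_id=gid,
                contig_lengths=lengths,
                n_proteins=int(n_prot),
                is_viral=viral in ("1", "true", "True"),
            )
        )
    return records


def read_marker_hits(path: str | Path) -> dict[str, frozenset[str]]:
    df = _read_tsv(path, 2)
    out: dict[str, set[str]] = {}
    for gid, marker in zip(df[0], df[1]):
        out.setdefault(gid, set()).add(marker)
    return {g: frozenset(m) for g, m in out.items()}


def write_qc_report(path: str | Path, results: Iterable[QCResult]) -> None:
    _write_tsv(
        path,
        ["genome_id", "passed", "reasons"],
        (
            (r.genome_id, int(r.passed), ",".join(r.failure_reasons))
            for r in results
        ),
    )


def read_taxonomy(path: str | Path) -> Taxonomy:
    """Newick (internal nodes labeled) or parent-child TSV, by extension."""
    p = Path(path)
    if p.suffix in (".nwk", ".newick", ".tree"):
        return Taxonomy.from_tree(read_newick(p))
    df = _read_tsv(p, 2)
    edges = [
        (child, None if parent in ("", "-", "nan") else parent)
        for child, parent in zip(df[0], df[1].fillna(""))
    ]
    return Taxonomy.from_edges(edges)


def write_taxonomy(path: str | Path, taxonomy: Taxonomy) -> None:
    _write_tsv(
        path,
        ["child_id", "parent_id"],
        ((c, p if p is not None else "-") for c, p in taxonomy.to_edges()),
    )


def write_og_tsv(
    path: str | Path, ogs_by_level: Mapping[str, list[OrthologousGroup]]
) -> None:
    rows = []
    for level, ogs in ogs_by_level.items():
        for og in ogs:
            for p in sorted(og.members):
                rows.append((og.og_id, level, p))
    _write_tsv(path, ["og_id", "level_id", "protein_id"], rows)


def read_og_tsv(
    path: str | Path, species_of: Mapping[str, str]
) -> dict[str, list[OrthologousGroup]]:
    df = _read_tsv(path, 3)
    members: dict[tuple[str, str], set[str]] = {}
    for og_id, level, prot in zip(df[0], df[1], df[2]):
        members.setdefault((level, og_id), set()).add(prot)
    out: dict[str, list[OrthologousGroup]] = {}
    for (level, og_id), mem in sorted(members.items()):
        n_sp = len({species_of[p] for p in mem})
        out.setdefault(level, []).append(
            OrthologousGroup(og_id, level, frozenset(mem), n_sp)
        )
    return out


def read_groups_tsv(path: str | Path) -> list[frozenset[str]]:
    """Group rows -> list of protein sets.

    First column is the group id, last column the protein id, so both plain
    group tables (group_id, protein_id) and OG tables (og_id, level_id,
    protein_id) are accepted.
    """
    df = _read_tsv(path, 2)
    groups: dict[str, set[str]] = {}
    for gid, prot in zip(df[0], df[df.shape[1] - 1]):
        groups.setdefault(gid, set()).add(prot)
    return [frozenset(groups[g]) for g in sorted(groups)]


def read_pairs_tsv(path: str | Path) -> set[frozenset[str]]:
    df = _read_tsv(path, 2)
    return {frozenset((a, b)) for a, b in zip(df[0], df[1]) if a != b}


def write_pairs_tsv(
    path: str | Path, pairs: Iterable[tuple[str, str, str]] | Iterable[tuple]
) -> None:
    rows = list(pairs)
    width = max((len(r) for r in rows), default=2)
    header = ["protein_a", "protein_b"] + (["relation"] if width > 2 else [])
    _write_tsv(path, header, rows)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
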