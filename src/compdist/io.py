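"""File I/O for the formats the pipeline touches.

FASTA/FASTQ parsing goes through Biopython; sequences are sanitized on
the way in (uppercase, U->T, ambiguity codes -> N).  Distance matrices
are written either in PHYLIP square format (taxon-count line, then
10-character padded labels — interoperable with the classic PHYLIP
``neighbor``/``treedist`` tools) or in a relaxed tab-separated dialect
with full labels that round-trips losslessly.  Trees are Newick via
dendropy, written deterministically with children ordered by their
smallest descendant leaf label.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Union

import dendropy
import numpy as np
from Bio import SeqIO

from .compression import NucleotidePayload, sanitize
from .distances import DistanceMatrix, SampleSet, sample_from_reads

__all__ = [
    "read_fasta",
    "read_fasta_reads",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "read_sample_dir",
    "write_phylip_matrix",
    "read_phylip_matrix",
    "read_label_map",
    "read_newick",
    "write_newick",
    "newick_string",
]

PathLike = Union[str, os.PathLike]


def read_fasta(path: PathLike) -> SampleSet:
    """Read a multi-record FASTA file as a set of long-sequence samples.

    Record ids (first whitespace-separated token of the header) become
    sample labels; duplicate ids are an error.
    """
    labels: list[str] = []
    payloads: dict[str, NucleotidePayload] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in payloads:
            raise ValueError(f"duplicate FASTA header {record.id!r} in {path}")
        payload, _ = sanitize(str(record.seq))
        labels.append(record.id)
        payloads[record.id] = payload
    if not labels:
        raise ValueError(f"no FASTA records found in {path}")
    return SampleSet(labels=labels, payloads=payloads)


def read_fasta_reads(path: PathLike) -> list[str]:
    """Read a FASTA file of short reads as a list of sanitized strings."""
    reads = [
        sanitize(str(r.seq))[0].symbols for r in SeqIO.parse(str(path), "fasta")
    ]
    if not reads:
        raise ValueError(f"no FASTA records found in {path}")
    return reads


def read_fastq(path: PathLike) -> list[str]:
    """Read a FASTQ file as a list of sanitized read strings.

    Quality lines are parsed (so malformed records raise) and then
    discarded; only the nucleotide content takes part in compression.
    """
    reads = [
        sanitize(str(r.seq))[0].symbols for r in SeqIO.parse(str(path), "fastq")
    ]
    if not reads:
        raise ValueError(f"no FASTQ records found in {path}")
    return reads


def write_fasta(
    sequences: dict[str, NucleotidePayload], path: PathLike, width: int = 70
) -> None:
    """Write labeled payloads as FASTA."""
    with open(path, "w") as fh:
        for label, payload in sequences.items():
            fh.write(f">{label}\n")
            s = payload.symbols
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_fastq(reads: list[str], path: PathLike, quality_char: str = "I") -> None:
    """Write reads as FASTQ with a constant placeholder quality."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read{i + 1}\n{read}\n+\n{quality_char * len(read)}\n")


def read_sample_dir(path: PathLike) -> SampleSet:
    """A directory of read files (one file = one NGS sample) as a SampleSet.

    FASTA (``.fa``/``.fasta``/``.fna``) and FASTQ (``.fq``/``.fastq``)
    files are accepted; each sample's reads are concatenated in file
    order and the file stem becomes the sample label.
    """
    path = Path(path)
    files = sorted(
        p
        for p in path.iterdir()
        if p.suffix.lower() in (".fa", ".fasta", ".fna", ".fq", ".fastq")
    )
    if not files:
        raise ValueError(f"no FASTA/FASTQ files found in {path}")
    labels = []
    payloads = {}
    for p in files:
        if p.suffix.lower() in (".fq", ".fastq"):
            reads = read_fastq(p)
        else:
            reads = read_fasta_reads(p)
        labels.append(p.stem)
        payloads[p.stem] = sample_from_reads(reads)
    return SampleSet(labels=labels, payloads=payloads, source_kind="read_sample")


def write_phylip_matrix(
    d: DistanceMatrix, path: PathLike, dialect: str = "square"
) -> None:
    """Write a distance matrix in PHYLIP square or relaxed dialect.

    ``square``: first line is the taxon count; each row starts with the
    label padded/truncated to 10 characters (an error if truncation
    makes labels collide), followed by space-separated distances.
    ``relaxed``: full labels, tab-separated, lossless round trip.
    """
    if dialect not in ("square", "relaxed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write(f"{len(d.labels)}\n")
        if dialect == "square":
            short = [label[:10] for label in d.labels]
            if len(set(short)) != len(short):
                dupes = sorted({s for s in short if short.count(s) > 1})
                raise ValueError(
                    "labels collide after 10-character truncation: "
                    f"{dupes}"
                )
            for label, row in zip(short, d.values):
                cells = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{label:<10} {cells}\n")
        else:
            for label, row in zip(d.labels, d.values):
                cells = "\t".join(repr(float(v)) for v in row)
                fh.write(f"{label}\t{cells}\n")


def read_phylip_matrix(path: PathLike) -> DistanceMatrix:
    """Read a distance matrix written by :func:`write_phylip_matrix`.

    The dialect is detected from the first data row (tab-separated =
    relaxed, otherwise square with a 10-character label field).
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty matrix file {path}")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise ValueError(f"{path}: first line must be the taxon count") from exc
    rows = lines[1:]
    if len(rows) != n:
        raise ValueError(f"{path}: expected {n} rows, found {len(rows)}")
    labels = []
    values = []
    relaxed = "\t" in rows[0]
    for row in rows:
        if relaxed:
            parts = row.split("\t")
            label, cells = parts[0], parts[1:]
        else:
            label = row[:10].strip()
            cells = row[10:].split()
        labels.append(label)
        values.append([float(c) for c in cells])
    return DistanceMatrix(labels=labels, values=np.array(values))


def read_label_map(path: PathLike) -> dict[str, str]:
    """Read a leaf -> group TSV table (two columns, optional # comments)."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            leaf, group = parts
            if leaf in groups:
                raise ValueError(f"{path}:{lineno}: duplicate leaf {leaf!r}")
            groups[leaf] = group
    if not groups:
        raise ValueError(f"no label assignments found in {path}")
    return groups


def _sort_children(tree: dendropy.Tree) -> None:
    order: dict[dendropy.Node, str] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            order[node] = node.taxon.label
        else:
            children = sorted(node.child_nodes(), key=order.get)
            node.set_child_nodes(children)
            order[node] = order[children[0]]


def newick_string(tree: dendropy.Tree) -> str:
    """Deterministic Newick: children ordered by smallest descendant label."""
    clone = tree.clone(depth=1)
    _sort_children(clone)
    return clone.as_string(
        schema="newick",
        suppress_rooting=False,
        unquoted_underscores=True,
        real_value_format_specifier=".6g",
    ).strip()


def write_newick(tree: dendropy.Tree, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def read_newick(path: PathLike) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    # dendropy leaves is_rooted unset unless the file says [&R]/[&U]
    if tree.is_rooted is None:
        tree.is_rooted = len(tree.seed_node.child_nodes()) == 2
    return tree
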