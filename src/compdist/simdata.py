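"""Synthetic genomes, evolved genome sets, and NGS-style short reads.

Everything the test battery needs is generated here, with explicit
seeds so every dataset is reproducible:

* :func:`random_genome` — i.i.d. bases at a chosen GC fraction.
* :func:`random_tree` — a random rooted binary guide tree with
  branch lengths in expected substitutions per site.
* :func:`evolve_along_tree` — Jukes–Cantor site-independent
  substitution of a root genome down a guide tree; a branch of length
  d substitutes each site with probability p = (3/4)(1 - exp(-4d/3)),
  drawing uniformly among the three other bases.
* :func:`simulate_reads` — uniform shotgun read sampling at a chosen
  coverage depth (read length 100 by default, matching common short
  read protocols) with a parameterized uniform-substitution error
  model standing in for platform-specific error profiles.

The simulator emulates the study conditions of short-read comparison
experiments: depths of 1x, 5x, 10x and 30x, read length 100, and error
models ranging from exact substrings to ~1% substitution noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np

from .compression import NucleotidePayload

__all__ = [
    "ReadSimConfig",
    "EvolveConfig",
    "ERROR_MODEL_RATES",
    "random_genome",
    "random_tree",
    "evolve_along_tree",
    "simulate_reads",
    "synthetic_clade",
]

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

# uniform substitution rates standing in for platform error profiles
ERROR_MODEL_RATES = {
    "exact": 0.0,
    "illumina_like": 0.01,
    "sanger_like": 0.005,
    "ls454_like": 0.005,
}


def _codes_to_payload(codes: np.ndarray) -> NucleotidePayload:
    return NucleotidePayload(_DECODE[codes].tobytes().decode("ascii"))


@dataclass(frozen=True)
class ReadSimConfig:
    """Shotgun read simulation settings.

    ``depth`` is the expected x-coverage; the number of reads is
    round(depth * L / read_length).  ``substitution_rate`` overrides
    the error model's default rate when given; the exact model admits
    only rate 0.  ``random_strand`` samples reads from either strand
    (reverse complement with probability 1/2) instead of the default
    forward-only convention.
    """

    depth: float
    read_length: int = 100
    error_model: str = "exact"
    substitution_rate: Optional[float] = None
    seed: int = 0
    random_strand: bool = False

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if self.error_model not in ERROR_MODEL_RATES:
            raise ValueError(
                f"unknown error model {self.error_model!r}; "
                f"choose from {sorted(ERROR_MODEL_RATES)}"
            )
        rate = self.rate
        if not 0.0 <= rate <= 0.75:
            raise ValueError("substitution rate must be in [0, 0.75]")
        if self.error_model == "exact" and rate != 0.0:
            raise ValueError("the exact model requires substitution rate 0")

    @property
    def rate(self) -> float:
        if self.substitution_rate is not None:
            return self.substitution_rate
        return ERROR_MODEL_RATES[self.error_model]


@dataclass(frozen=True)
class EvolveConfig:
    """Guide tree + seed for evolving a root genome to the leaves."""

    guide_tree: dendropy.Tree
    root_length: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise ValueError("root_length must be positive")
        for edge in self.guide_tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("guide tree has a negative branch length")


def random_genome(
    length: int, gc_fraction: float = 0.5, seed: int = 0
) -> NucleotidePayload:
    """I.i.d. random genome with P(G) = P(C) = gc_fraction / 2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.uint8)
    return _codes_to_payload(codes)


def random_tree(
    labels: list[str],
    seed: int = 0,
    branch_length_range: tuple[float, float] = (0.05, 1.0),
) -> dendropy.Tree:
    """Random rooted binary tree over the given leaf labels.

    Topology by repeated random joins of available subtrees; branch
    lengths drawn uniformly from ``branch_length_range`` (expected
    substitutions per site).
    """
    if len(labels) < 2:
        raise ValueError("need at least 2 leaf labels")
    if len(set(labels)) != len(labels):
        raise ValueError("leaf labels must be unique")
    lo, hi = branch_length_range
    if lo < 0 or hi < lo:
        raise ValueError("invalid branch length range")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace(labels)
    subtrees = [dendropy.Node(taxon=tns.get_taxon(l)) for l in labels]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        parent = dendropy.Node()
        for child in (subtrees[i], subtrees[j]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(lo, hi))
        subtrees = (
            [s for k, s in enumerate(subtrees) if k not in (i, j)] + [parent]
        )
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = subtrees[0]
    tree.is_rooted = True
    return tree


def _jc_substitute(
    codes: np.ndarray, branch_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Jukes–Cantor substitution of one branch; N sites are left alone."""
    if branch_length < 0:
        raise ValueError("negative branch length")
    if branch_length == 0:
        return codes
    p = 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))
    out = codes.copy()
    hit = (rng.random(codes.shape[0]) < p) & (codes < 4)
    n_hit = int(hit.sum())
    if n_hit:
        # uniform among the three other bases
        shift = rng.integers(1, 4, size=n_hit).astype(np.uint8)
        out[hit] = (out[hit] + shift) % 4
    return out


def evolve_along_tree(
    root: NucleotidePayload, cfg: EvolveConfig
) -> dict[str, NucleotidePayload]:
    """Evolve a root genome down a guide tree; returns leaf payloads.

    Site-independent Jukes–Cantor substitution along every branch;
    leaves inherit the root's sequence length exactly (no indels).
    """
    if len(root) == 0:
        raise ValueError("root genome is empty")
    rng = np.random.default_rng(cfg.seed)
    tree = cfg.guide_tree
    seqs: dict[dendropy.Node, np.ndarray] = {tree.seed_node: root.codes()}
    leaves: dict[str, NucleotidePayload] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            length = node.edge.length or 0.0
            seqs[node] = _jc_substitute(seqs[node.parent_node], length, rng)
        if node.is_leaf():
            leaves[node.taxon.label] = _codes_to_payload(seqs[node])
    return leaves


def simulate_reads(
    genome: NucleotidePayload, cfg: ReadSimConfig
) -> list[str]:
    """Shotgun reads from a genome at the configured depth.

    round(depth * L / read_length) reads of fixed length, start
    positions uniform with replacement, per-base substitution noise at
    the configured rate.  Under the exact model every read is a
    verbatim substring of the genome (forward strand by default).
    """
    L = len(genome)
    if L < cfg.read_length:
        raise ValueError(
            f"genome length {L} shorter than read length {cfg.read_length}"
        )
    rng = np.random.default_rng(cfg.seed)
    n_reads = int(round(cfg.depth * L / cfg.read_length))
    if n_reads < 1:
        raise ValueError("configured depth yields zero reads")
    codes = genome.codes()
    starts = rng.integers(0, L - cfg.read_length + 1, size=n_reads)
    reads = codes[starts[:, None] + np.arange(cfg.read_length)]
    if cfg.random_strand:
        flip = rng.random(n_reads) < 0.5
        reads[flip] = _COMPLEMENT[reads[flip][:, ::-1]]
    rate = cfg.rate
    if rate > 0:
        hit = (rng.random(reads.shape) < rate) & (reads < 4)
        shift = rng.integers(1, 4, size=int(hit.sum())).astype(np.uint8)
        reads[hit] = (reads[hit] + shift) % 4
    decoded = _DECODE[reads]
    return [row.tobytes().decode("ascii") for row in decoded]


def synthetic_clade(
    n_leaves: int = 10,
    genome_length: int = 20_000,
    branch_length_range: tuple[float, float] = (0.02, 0.3),
    gc_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[dendropy.Tree, dict[str, NucleotidePayload]]:
    """A random guide tree plus genomes evolved along it.

    Convenience wrapper producing a complete benchmark clade: a random
    ancestor genome, a random rooted binary guide tree over
    ``taxon01..taxonNN``, and the Jukes–Cantor leaf genomes.  The
    defaults (10 leaves, 20 kb genomes, branch lengths 0.02–0.3) give a
    moderately diverged clade whose topology a good distance measure
    should recover.
    """
    labels = [f"taxon{i + 1:02d}" for i in range(n_leaves)]
    tree = random_tree(labels, seed=seed, branch_length_range=branch_length_range)
    root = random_genome(genome_length, gc_fraction=gc_fraction, seed=seed + 1)
    leaves = evolve_along_tree(
        root, EvolveConfig(guide_tree=tree, root_length=genome_length, seed=seed + 2)
    )
    return tree, leaves
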