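"""Compression-based distances and pairwise distance matrices.

Three scalar dissimilarities are computed from compressed sizes:

* ``dist_cdm``  — C(xy) / (C(x) + C(y)), the compression-based
  dissimilarity measure.  Ranges from 1/2 (identical inputs, since then
  C(xy) ~ C(x) = C(y)) to 1 (no shared information, C(xy) ~ C(x)+C(y)).
* ``dist_cond`` — (C(x|y) + C(y|x)) / C(xy), a conditional-compression
  distance in [0, 1].
* ``dist_ncd``  — max{C(x|y), C(y|x)} / max{C(x), C(y)}, the normalized
  compression distance, a proper metric under idealized compression.

``pairwise_distances`` assembles a labeled symmetric matrix over a
sample set, caching each unconditional size and building every joint
payload in canonical (sorted-label) order so the matrix is exactly
symmetric.  An NGS read sample enters the pipeline as the plain
concatenation of its reads (``sample_from_reads``); the distances are
empirically robust to the concatenation order.

``matrix_correlation`` compares two distance matrices the way the
accuracy assessment does: each matrix is flattened by concatenating its
rows (diagonal and both triangles included) and the Pearson correlation
of the two vectors is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .compression import (
    CompressorBackend,
    NucleotidePayload,
    get_backend,
)

__all__ = [
    "SampleSet",
    "DistanceMatrix",
    "dist_cdm",
    "dist_cond",
    "dist_ncd",
    "pairwise_distances",
    "sample_from_reads",
    "matrix_correlation",
]

Measure = Literal["cdm", "cond", "ncd"]


@dataclass
class SampleSet:
    """An ordered collection of labeled payloads to be compared.

    ``source_kind`` records whether each payload is a long genomic
    sequence or the concatenation of an NGS read sample; it does not
    change how distances are computed.
    """

    labels: list[str]
    payloads: dict[str, NucleotidePayload]
    source_kind: Literal["long_sequence", "read_sample"] = "long_sequence"

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate sample labels: {dupes}")
        if any(not l for l in self.labels):
            raise ValueError("sample labels must be non-empty")
        missing = [l for l in self.labels if l not in self.payloads]
        if missing:
            raise ValueError(f"labels without payloads: {missing}")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> NucleotidePayload:
        return self.payloads[label]


@dataclass
class DistanceMatrix:
    """A labeled symmetric distance matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(
            self.values[self.labels.index(a), self.labels.index(b)]
        )


def dist_cdm(c_x: int, c_y: int, c_xy: int) -> float:
    """Compression-based dissimilarity measure C(xy)/(C(x)+C(y))."""
    if c_x + c_y == 0:
        raise ValueError("C(x) + C(y) must be positive")
    return c_xy / (c_x + c_y)


def dist_cond(c_xy: int, c_x_given_y: int, c_y_given_x: int) -> float:
    """Conditional-compression distance (C(x|y)+C(y|x))/C(xy)."""
    if c_xy == 0:
        raise ValueError("C(xy) must be positive")
    return (c_x_given_y + c_y_given_x) / c_xy


def dist_ncd(
    c_x: int, c_y: int, c_x_given_y: int, c_y_given_x: int
) -> float:
    """Normalized compression distance max{C(x|y),C(y|x)}/max{C(x),C(y)}."""
    if max(c_x, c_y) == 0:
        raise ValueError("max(C(x), C(y)) must be positive")
    return max(c_x_given_y, c_y_given_x) / max(c_x, c_y)


def sample_from_reads(
    reads: Sequence[str], order_seed: Optional[int] = None
) -> NucleotidePayload:
    """Concatenate a read sample into a single payload.

    Reads are joined with no separator.  With ``order_seed`` set, a
    seeded uniform shuffle of the read order is applied first; the
    payload length is the sum of read lengths either way.
    """
    if len(reads) == 0:
        raise ValueError("read sample is empty")
    reads = list(reads)
    if order_seed is not None:
        rng = np.random.default_rng(order_seed)
        order = rng.permutation(len(reads))
        reads = [reads[i] for i in order]
    return NucleotidePayload("".join(reads))


def pairwise_distances(
    samples: SampleSet,
    measure: Measure = "ncd",
    backend: Optional[CompressorBackend] = None,
) -> DistanceMatrix:
    """All-pairs compression distance matrix over a sample set.

    Each unconditional size C(x) is computed exactly once and cached.
    The joint payload of a pair is always concatenated in sorted-label
    order, so the output is exactly symmetric regardless of backend.
    The diagonal is stored as 0 by convention (neighbor joining and the
    PHYLIP matrix format expect zero self-distance) even though the raw
    self-dissimilarity of e.g. the CDM measure is about 1/2.
    """
    if measure not in ("cdm", "cond", "ncd"):
        raise ValueError(f"unknown measure {measure!r}")
    if backend is None:
        backend = get_backend("builtin")
    labels = samples.labels
    if len(labels) < 2:
        raise ValueError("need at least 2 samples")
    for label in labels:
        if len(samples[label]) == 0:
            raise ValueError(f"sample {label!r} has an empty payload")
    if measure in ("cond", "ncd") and not backend.supports_conditional:
        warnings.warn(
            f"backend {backend.name!r} lacks native conditional "
            "compression; using the C(yx)-C(y) approximation",
            stacklevel=2,
        )

    need_cx = measure in ("cdm", "ncd")
    c_single: dict[str, int] = {}
    if need_cx:
        for label in labels:
            c_single[label] = backend.size_bytes(samples[label])

    n = len(labels)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((labels[i], labels[j]))
            pa, pb = samples[a], samples[b]
            if measure == "cdm":
                c_ab = backend.size_bytes(pa + pb)
                d = dist_cdm(c_single[a], c_single[b], c_ab)
            elif measure == "cond":
                c_ab = backend.size_bytes(pa + pb)
                c_a_b = backend.conditional_size_bytes(pa, pb)
                c_b_a = backend.conditional_size_bytes(pb, pa)
                d = dist_cond(c_ab, c_a_b, c_b_a)
            else:  # ncd
                c_a_b = backend.conditional_size_bytes(pa, pb)
                c_b_a = backend.conditional_size_bytes(pb, pa)
                d = dist_ncd(c_single[a], c_single[b], c_a_b, c_b_a)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=list(labels), values=values)


def matrix_correlation(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    include_diagonal: bool = True,
) -> float:
    """Pearson correlation between two distance matrices.

    Each matrix is converted to a vector by concatenating its rows side
    by side — diagonal and both triangles included, which is the
    default — and the Pearson correlation of the two vectors is
    returned.  ``include_diagonal=False`` restricts the vectors to the
    upper triangle instead.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices have different labels")
    if include_diagonal:
        v1 = d1.values.ravel()
        v2 = d2.values.ravel()
    else:
        iu = np.triu_indices(len(d1.labels), k=1)
        v1 = d1.values[iu]
        v2 = d2.values[iu]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("correlation undefined for a constant matrix")
    return float(stats.pearsonr(v1, v2).statistic)
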