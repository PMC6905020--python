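"""Increment of diversity (ID) over symbol-count sources.

For a count vector X = [n_1, ..., n_s] with total N, the diversity measure is
D(X) = N log N - sum_i n_i log n_i (0 log 0 := 0, natural log).  For two
sources over the same alphabet the mixed diversity is D of the element-wise
sum, and the increment of diversity

    ID(X, Y) = D(X + Y) - D(X) - D(Y)

is a nonnegative, symmetric dissimilarity that vanishes exactly when X and Y
have proportional compositions.  A class's "standard source" is the pooled
symbol count over all its training segments; a test segment contributes its
own raw length-L counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .errors import FormatError, ParameterError
from .properties import PROPERTIES, PropertyAlphabet, composition_matrix, encode_indices
from .records import Segment


@dataclass
class DiversitySource:
    """A count vector over a property alphabet."""

    property_name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ParameterError("counts must be a 1-D vector")
        if np.any(self.counts < 0):
            raise ParameterError("counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def size(self) -> int:
        return self.counts.size


def _diversity(counts: np.ndarray) -> float:
    total = counts.sum()
    return float(xlogy(total, total) - xlogy(counts, counts).sum())


def diversity_measure(source: DiversitySource) -> float:
    """D(X) = N log N - sum n_i log n_i  (>= 0)."""
    return _diversity(source.counts)


def mixed_diversity(x: DiversitySource, y: DiversitySource) -> float:
    """D(X, Y): diversity of the element-wise sum of the two sources."""
    if x.size != y.size:
        raise ParameterError(f"alphabet mismatch: {x.size} vs {y.size}")
    return _diversity(x.counts + y.counts)


def increment(x: DiversitySource, y: DiversitySource) -> float:
    """ID(X, Y) = D(X + Y) - D(X) - D(Y)."""
    return mixed_diversity(x, y) - diversity_measure(x) - diversity_measure(y)


def build_standard_source(encoded, alphabet: PropertyAlphabet) -> DiversitySource:
    """Pool symbol counts over all positions of all segments of one class."""
    if isinstance(encoded, np.ndarray):
        if encoded.size == 0:
            raise FormatError("empty segment list")
        counts = np.bincount(encoded.ravel(), minlength=alphabet.size).astype(float)
    else:
        encoded = list(encoded)
        if not encoded:
            raise FormatError("empty segment list")
        counts = np.zeros(alphabet.size)
        for s in encoded:
            for c in s:
                counts[alphabet.index(c)] += 1
    return DiversitySource(alphabet.name, counts)


def _increment_many(seg_counts: np.ndarray, source: DiversitySource) -> np.ndarray:
    """Vectorized ID(segment counts, source) for an (n, A) count matrix."""
    src = source.counts[None, :]
    mixed = seg_counts + src
    d_mixed = xlogy(mixed.sum(axis=1), mixed.sum(axis=1)) - xlogy(mixed, mixed).sum(axis=1)
    d_seg = xlogy(seg_counts.sum(axis=1), seg_counts.sum(axis=1)) - xlogy(seg_counts, seg_counts).sum(axis=1)
    return d_mixed - d_seg - _diversity(source.counts)


def id_features(
    sources: dict[str, tuple[DiversitySource, DiversitySource]],
    segments: list[Segment],
) -> np.ndarray:
    """10-dim ID block: (ID vs positive source, ID vs negative source) per property.

    Property order AA, HYD, CHG, SS, SA; returns an (n, 10) array.
    """
    blocks = []
    for alphabet in PROPERTIES:
        try:
            pos_src, neg_src = sources[alphabet.name]
        except KeyError:
            raise ParameterError(f"missing diversity source for property {alphabet.name}") from None
        idx = encode_indices(segments, alphabet)
        seg_counts = composition_matrix(idx, alphabet) * idx.shape[1]  # raw counts
        blocks.append(_increment_many(seg_counts, pos_src))
        blocks.append(_increment_many(seg_counts, neg_src))
    return np.stack(blocks, axis=1)
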