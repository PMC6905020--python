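"""Position matrix scoring: pseudocounted frequency matrices, log-ratio weight
matrices, conservation indices, and the min-max-normalized segment score S.

For a class of training segments of length L over an alphabet of size A, the
position frequency matrix is

    p[i, j] = (n[i, j] + sqrt(N[i]) / A) / (N[i] + sqrt(N[i]))

where n[i, j] counts symbol j at position i and N[i] is the number of
segments.  The square-root pseudocount guarantees strictly positive columns
that sum to one exactly.  The weight matrix is the log-ratio against a
background distribution, m = log(p / p0); the conservation index rescales
column negative entropy to [0, 100]:

    C[i] = 100 / log(A) * (sum_j p[i, j] log p[i, j] + log A)

and a segment scores

    S = sum_i C[i] (m[i, j(i)] - min_j m[i, j])
        / sum_i C[i] (max_j m[i, j] - min_j m[i, j])   in [0, 1],

with j(i) the symbol observed at position i.  C and S are invariant to the
logarithm base; natural logs are used throughout.

A :class:`PositionScoreModel` holds one (frequency, weight, conservation)
triple per class (binding / non-binding), sharing a pooled background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .errors import FormatError, ParameterError
from .properties import PropertyAlphabet, encode_indices
from .records import Segment

logger = logging.getLogger(__name__)


@dataclass
class FrequencyMatrix:
    property_name: str
    counts: np.ndarray      # (L, A) integer counts n[i, j]
    totals: np.ndarray      # (L,) N[i]
    probs: np.ndarray       # (L, A) pseudocounted p[i, j]

    @property
    def window_length(self) -> int:
        return self.counts.shape[0]

    @property
    def alphabet_size(self) -> int:
        return self.counts.shape[1]


@dataclass
class WeightMatrix:
    property_name: str
    m: np.ndarray           # (L, A) log(p / p0)
    background: np.ndarray  # (A,) p0
    m_min: np.ndarray       # (L,) per-row minimum
    m_max: np.ndarray       # (L,) per-row maximum


def _as_index_matrix(encoded, alphabet: PropertyAlphabet) -> np.ndarray:
    """Accept either an (n, L) index array or a list of encoded strings."""
    if isinstance(encoded, np.ndarray):
        mat = encoded
    else:
        encoded = list(encoded)
        if not encoded:
            raise FormatError("empty segment list")
        lengths = {len(s) for s in encoded}
        if len(lengths) != 1:
            raise FormatError(f"ragged segment lengths {sorted(lengths)}")
        mat = np.array([[alphabet.index(c) for c in s] for s in encoded], dtype=np.intp)
    if mat.ndim != 2 or mat.shape[0] == 0:
        raise FormatError("need at least one encoded segment")
    return mat


def build_frequency_matrix(encoded, alphabet: PropertyAlphabet) -> FrequencyMatrix:
    """Estimate the pseudocounted position frequency matrix from one class."""
    mat = _as_index_matrix(encoded, alphabet)
    n_seg, L = mat.shape
    A = alphabet.size
    counts = np.zeros((L, A))
    np.add.at(counts, (np.arange(L)[None, :], mat), 1.0)
    totals = np.full(L, float(n_seg))
    sqrt_n = np.sqrt(totals)
    probs = (counts + (sqrt_n / A)[:, None]) / (totals + sqrt_n)[:, None]
    return FrequencyMatrix(alphabet.name, counts, totals, probs)


def background_probabilities(encoded, alphabet: PropertyAlphabet, scheme: str = "pooled") -> np.ndarray:
    """Background distribution p0 over the alphabet.

    ``pooled`` (default): add-one smoothed symbol frequencies over every
    position of every training segment, both classes pooled.  ``uniform``:
    1/A for every symbol.
    """
    A = alphabet.size
    if scheme == "uniform":
        return np.full(A, 1.0 / A)
    if scheme != "pooled":
        raise ParameterError(f"unknown background scheme {scheme!r}")
    mat = _as_index_matrix(encoded, alphabet)
    counts = np.bincount(mat.ravel(), minlength=A).astype(float)
    return (counts + 1.0) / (counts.sum() + A)


def build_weight_matrix(freq: FrequencyMatrix, background: np.ndarray) -> WeightMatrix:
    """Element-wise log-ratio weight matrix m = log(p / p0)."""
    p0 = np.asarray(background, dtype=float)
    if p0.shape != (freq.alphabet_size,) or np.any(p0 <= 0):
        raise ParameterError("background must be strictly positive over the alphabet")
    m = np.log(freq.probs / p0[None, :])
    return WeightMatrix(freq.property_name, m, p0, m.min(axis=1), m.max(axis=1))


def conservation_index(freq: FrequencyMatrix) -> np.ndarray:
    """Per-position conservation in [0, 100]; 0 at uniform, 100 at degenerate columns."""
    A = freq.alphabet_size
    ent = xlogy(freq.probs, freq.probs).sum(axis=1)  # sum p log p, 0 log 0 := 0
    c = 100.0 / np.log(A) * (ent + np.log(A))
    return np.clip(c, 0.0, 100.0)


def _score_many(weight: WeightMatrix, conservation: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Vectorized S for an (n, L) index array."""
    L = weight.m.shape[0]
    if indices.shape[1] != L:
        raise ParameterError(f"segment length {indices.shape[1]} != matrix length {L}")
    sel = weight.m[np.arange(L)[None, :], indices]           # (n, L)
    denom = float((conservation * (weight.m_max - weight.m_min)).sum())
    if denom <= 0.0:
        logger.warning("degenerate weight matrix: S defined as 0")
        return np.zeros(indices.shape[0])
    num = (conservation[None, :] * (sel - weight.m_min[None, :])).sum(axis=1)
    return num / denom


@dataclass
class PositionScoreModel:
    """Positive- and negative-class scoring matrices for one property."""

    alphabet: PropertyAlphabet
    pos_freq: FrequencyMatrix
    neg_freq: FrequencyMatrix
    pos_weight: WeightMatrix
    neg_weight: WeightMatrix
    pos_cons: np.ndarray
    neg_cons: np.ndarray

    @property
    def window_length(self) -> int:
        return self.pos_freq.window_length

    def to_dict(self) -> dict:
        return {
            "property": self.alphabet.name,
            "L": self.window_length,
            "symbols": list(self.alphabet.symbols),
            "background": self.pos_weight.background.tolist(),
            "pos": {
                "counts": self.pos_freq.counts.tolist(),
                "probs": self.pos_freq.probs.tolist(),
                "m": self.pos_weight.m.tolist(),
                "conservation": self.pos_cons.tolist(),
            },
            "neg": {
                "counts": self.neg_freq.counts.tolist(),
                "probs": self.neg_freq.probs.tolist(),
                "m": self.neg_weight.m.tolist(),
                "conservation": self.neg_cons.tolist(),
            },
        }


def train_position_model(
    pos_encoded,
    neg_encoded,
    alphabet: PropertyAlphabet,
    background: str = "pooled",
) -> PositionScoreModel:
    """Fit the two class matrices and the shared background for one property."""
    pos_mat = _as_index_matrix(pos_encoded, alphabet)
    neg_mat = _as_index_matrix(neg_encoded, alphabet)
    pooled = np.vstack([pos_mat, neg_mat])
    p0 = background_probabilities(pooled, alphabet, scheme=background)
    pf = build_frequency_matrix(pos_mat, alphabet)
    nf = build_frequency_matrix(neg_mat, alphabet)
    pw = build_weight_matrix(pf, p0)
    nw = build_weight_matrix(nf, p0)
    return PositionScoreModel(alphabet, pf, nf, pw, nw, conservation_index(pf), conservation_index(nf))


def position_features(model: PositionScoreModel, encoded) -> np.ndarray:
    """2L weight-matrix lookups: positive-matrix values then negative-matrix values."""
    idx = _encoded_to_indices(encoded, model.alphabet)
    L = model.window_length
    if idx.shape[-1] != L:
        raise ParameterError(f"segment length {idx.shape[-1]} != model length {L}")
    pos = model.pos_weight.m[np.arange(L), idx]
    neg = model.neg_weight.m[np.arange(L), idx]
    return np.concatenate([pos, neg])


def _encoded_to_indices(encoded, alphabet: PropertyAlphabet) -> np.ndarray:
    if isinstance(encoded, str):
        return np.array([alphabet.index(c) for c in encoded], dtype=np.intp)
    return np.asarray(encoded, dtype=np.intp)


def score_segment(model_weight: WeightMatrix, conservation: np.ndarray, encoded, alphabet: PropertyAlphabet | None = None) -> float:
    """Conservation-weighted min-max score S of one encoded segment, in [0, 1]."""
    if isinstance(encoded, str):
        if alphabet is None:
            raise ParameterError("alphabet required to decode a string segment")
        idx = _encoded_to_indices(encoded, alphabet)
    else:
        idx = np.asarray(encoded, dtype=np.intp)
    return float(_score_many(model_weight, conservation, idx[None, :])[0])


def s_features(models: dict[str, PositionScoreModel], segments: list[Segment]) -> np.ndarray:
    """10-dim S block: (S vs positive matrix, S vs negative matrix) per property.

    Property order AA, HYD, CHG, SS, SA; returns an (n, 10) array.
    """
    from .properties import PROPERTIES

    blocks = []
    for alphabet in PROPERTIES:
        try:
            model = models[alphabet.name]
        except KeyError:
            raise ParameterError(f"missing position model for property {alphabet.name}") from None
        idx = encode_indices(segments, alphabet)
        blocks.append(_score_many(model.pos_weight, model.pos_cons, idx))
        blocks.append(_score_many(model.neg_weight, model.neg_cons, idx))
    return np.stack(blocks, axis=1)
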