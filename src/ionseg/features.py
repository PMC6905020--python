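"""Assemble per-segment feature vectors from the trained scoring models.

Four feature sets mirror the three experiments plus their union:

* ``component``  — 39-dim concatenated composition (21 AA + 7 HYD + 4 CHG
  + 4 SS + 3 SA symbol frequencies).
* ``position``   — 2L weight-matrix lookups per property (10L total), or
  one-hot position encodings (``position_encoding="onehot"``).
* ``refinement`` — 20-dim: the 10 ID values followed by the 10 S scores.
* ``all``        — concatenation of the three blocks above.

All matrices, background distributions and diversity sources are fitted on
the training segments only; :meth:`SegmentFeaturizer.state_hash` fingerprints
the fitted state so leakage can be ruled out by comparison.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np

from .diversity import DiversitySource, build_standard_source, id_features
from .errors import ParameterError
from .properties import COMPONENT_DIM, PROPERTIES, composition_matrix, encode_indices
from .pwm import PositionScoreModel, s_features, train_position_model
from .records import Segment

FEATURE_SETS = ("component", "position", "refinement", "all")


class SegmentFeaturizer:
    """Fit class-conditional scoring models and emit feature matrices."""

    def __init__(
        self,
        feature_set: str = "refinement",
        background: str = "pooled",
        position_encoding: str = "pwm",
    ):
        if feature_set not in FEATURE_SETS:
            raise ParameterError(f"feature_set must be one of {FEATURE_SETS}")
        if position_encoding not in ("pwm", "onehot"):
            raise ParameterError("position_encoding must be 'pwm' or 'onehot'")
        self.feature_set = feature_set
        self.background = background
        self.position_encoding = position_encoding
        self.models: dict[str, PositionScoreModel] = {}
        self.sources: dict[str, tuple[DiversitySource, DiversitySource]] = {}
        self.window_length: int | None = None

    def fit(self, segments: list[Segment], labels: np.ndarray) -> "SegmentFeaturizer":
        labels = np.asarray(labels, dtype=bool)
        if labels.shape != (len(segments),):
            raise ParameterError("labels must align with segments")
        if not labels.any() or labels.all():
            raise ParameterError("training segments must contain both classes")
        self.window_length = segments[0].window_length
        pos = [s for s, y in zip(segments, labels) if y]
        neg = [s for s, y in zip(segments, labels) if not y]
        for alphabet in PROPERTIES:
            pos_idx = encode_indices(pos, alphabet)
            neg_idx = encode_indices(neg, alphabet)
            self.models[alphabet.name] = train_position_model(
                pos_idx, neg_idx, alphabet, background=self.background
            )
            self.sources[alphabet.name] = (
                build_standard_source(pos_idx, alphabet),
                build_standard_source(neg_idx, alphabet),
            )
        return self

    def _check_fitted(self) -> None:
        if not self.models:
            raise ParameterError("featurizer is not fitted")

    def _component_block(self, segments: list[Segment]) -> np.ndarray:
        return np.hstack(
            [composition_matrix(encode_indices(segments, a), a) for a in PROPERTIES]
        )

    def _position_block(self, segments: list[Segment]) -> np.ndarray:
        self._check_fitted()
        blocks = []
        for alphabet in PROPERTIES:
            idx = encode_indices(segments, alphabet)
            if self.position_encoding == "onehot":
                n, L = idx.shape
                onehot = np.zeros((n, L * alphabet.size))
                onehot[np.arange(n)[:, None], idx + np.arange(L)[None, :] * alphabet.size] = 1.0
                blocks.append(onehot)
            else:
                model = self.models[alphabet.name]
                L = model.window_length
                rows = np.arange(L)[None, :]
                blocks.append(model.pos_weight.m[rows, idx])
                blocks.append(model.neg_weight.m[rows, idx])
        return np.hstack(blocks)

    def _refinement_block(self, segments: list[Segment]) -> np.ndarray:
        self._check_fitted()
        return np.hstack(
            [id_features(self.sources, segments), s_features(self.models, segments)]
        )

    def transform(self, segments: list[Segment]) -> np.ndarray:
        """Feature matrix (n_segments, dim) for the configured feature set."""
        if not segments:
            raise ParameterError("no segments to featurize")
        if self.feature_set == "component":
            return self._component_block(segments)
        if self.feature_set == "position":
            return self._position_block(segments)
        if self.feature_set == "refinement":
            return self._refinement_block(segments)
        return np.hstack(
            [
                self._component_block(segments),
                self._position_block(segments),
                self._refinement_block(segments),
            ]
        )

    def fit_transform(self, segments: list[Segment], labels: np.ndarray) -> np.ndarray:
        return self.fit(segments, labels).transform(segments)

    def layout(self) -> dict:
        """Block layout descriptor: ordered (name, dimension) pairs."""
        L = self.window_length
        dims: list[tuple[str, int]] = []
        if self.feature_set in ("component", "all"):
            dims.append(("component", COMPONENT_DIM))
        if self.feature_set in ("position", "all"):
            if self.position_encoding == "onehot":
                d = sum(L * a.size for a in PROPERTIES)
            else:
                d = sum(2 * L for _ in PROPERTIES)
            dims.append(("position", d))
        if self.feature_set in ("refinement", "all"):
            dims.append(("refinement", 20))
        return {"feature_set": self.feature_set, "blocks": dims, "window_length": L}

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "feature_set": self.feature_set,
            "background": self.background,
            "position_encoding": self.position_encoding,
            "window_length": self.window_length,
            "models": {name: m.to_dict() for name, m in self.models.items()},
            "sources": {
                name: {"pos": p.counts.tolist(), "neg": n.counts.tolist()}
                for name, (p, n) in self.sources.items()
            },
        }

    def state_hash(self) -> str:
        """SHA-256 fingerprint of every fitted artifact (leakage guard)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()
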