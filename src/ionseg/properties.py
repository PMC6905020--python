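"""The five residue-property alphabets and per-segment composition features.

Each window position is mapped under five properties:

* ``AA``  — the residue itself: 20 standard amino acids plus the pad ``X``
  (21 symbols).
* ``HYD`` — hydropathy class: strongly hydrophilic {R,D,E,N,Q,K,H}, strongly
  hydrophobic {L,I,V,A,M,F}, weakly hydrophilic {S,T,Y,W}, and the three
  singleton classes proline, glycine, cysteine (6 classes + pad = 7).
* ``CHG`` — polarization charge: positive {K,R,P}, negative {D,E}, uncharged
  (the remaining 15) (+ pad = 4).
* ``SS``  — predicted secondary structure: helix/strand/coil (+ pad = 4).
* ``SA``  — predicted relative solvent accessibility, thresholded at 0.25:
  exposed strictly above, buried otherwise (+ pad = 3).

Every alphabet carries an explicit pad class so that composition vectors of
padded windows stay normalized; symbol order is fixed and is part of the
feature layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import FormatError, TrackError
from .records import PAD, STANDARD_AA, Segment

#: relative solvent accessibility strictly above this is "exposed"
SA_EXPOSURE_THRESHOLD = 0.25

_HYD_CLASSES = {
    "h": "RDENQKH",  # strongly hydrophilic
    "b": "LIVAMF",   # strongly hydrophobic
    "w": "STYW",     # weakly hydrophilic
    "P": "P",
    "G": "G",
    "C": "C",
}
_CHG_CLASSES = {
    "+": "KRP",
    "-": "DE",
    "0": "NQHLIVAMFSTYWCG",
}


@dataclass(frozen=True)
class PropertyAlphabet:
    """A named finite symbol set with a position-wise residue mapping.

    ``mapper(residue, ss, sa)`` returns one symbol; the pad residue always
    maps to the pad symbol (the last symbol of ``symbols``).
    """

    name: str
    symbols: tuple[str, ...]
    mapper: Callable[[str, str | None, float | None], str]
    needs_ss: bool = False
    needs_sa: bool = False

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def pad_symbol(self) -> str:
        return self.symbols[-1]

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise FormatError(f"symbol {symbol!r} not in {self.name} alphabet") from None

    def to_config(self) -> dict:
        """Machine-readable description (name, ordered symbols, residue map)."""
        res_map = {}
        for aa in STANDARD_AA:
            if self.name == "SS":
                continue
            if self.name == "SA":
                continue
            res_map[aa] = self.mapper(aa, None, None)
        return {"name": self.name, "symbols": list(self.symbols), "residue_map": res_map}


def _aa_map(res: str, ss, sa) -> str:
    return res


def _class_map(classes: dict[str, str]):
    lookup = {aa: sym for sym, members in classes.items() for aa in members}

    def mapper(res: str, ss, sa) -> str:
        if res == PAD:
            return PAD
        try:
            return lookup[res]
        except KeyError:
            raise FormatError(f"residue {res!r} has no property class") from None

    return mapper


def _ss_map(res: str, ss, sa) -> str:
    if res == PAD:
        return PAD
    if ss is None:
        raise TrackError("secondary-structure track required")
    if ss not in "HEC":
        raise FormatError(f"SS letter {ss!r} not in H/E/C")
    return ss


def _sa_map(res: str, ss, sa) -> str:
    if res == PAD:
        return PAD
    if sa is None or (isinstance(sa, float) and np.isnan(sa)):
        raise TrackError("solvent-accessibility track required")
    return "e" if sa > SA_EXPOSURE_THRESHOLD else "b"


AA = PropertyAlphabet("AA", tuple(STANDARD_AA) + (PAD,), _aa_map)
HYD = PropertyAlphabet("HYD", ("h", "b", "w", "P", "G", "C", PAD), _class_map(_HYD_CLASSES))
CHG = PropertyAlphabet("CHG", ("+", "-", "0", PAD), _class_map(_CHG_CLASSES))
SS = PropertyAlphabet("SS", ("H", "E", "C", PAD), _ss_map, needs_ss=True)
SA = PropertyAlphabet("SA", ("e", "b", PAD), _sa_map, needs_sa=True)

#: the fixed property order used by every concatenated feature block
PROPERTIES: tuple[PropertyAlphabet, ...] = (AA, HYD, CHG, SS, SA)

#: total component-feature dimension: 21 + 7 + 4 + 4 + 3
COMPONENT_DIM = sum(a.size for a in PROPERTIES)


def encode_segment(segment: Segment, alphabet: PropertyAlphabet) -> str:
    """Map a segment position-wise into ``alphabet``; pads map to the pad symbol."""
    if alphabet.needs_ss and segment.ss_symbols is None:
        raise TrackError(
            f"protein {segment.protein_id!r}: {alphabet.name} encoding needs an SS track"
        )
    if alphabet.needs_sa and segment.sa_values is None:
        raise TrackError(
            f"protein {segment.protein_id!r}: {alphabet.name} encoding needs an SA track"
        )
    out = []
    for k, res in enumerate(segment.symbols):
        ss = segment.ss_symbols[k] if segment.ss_symbols is not None else None
        sa = segment.sa_values[k] if segment.sa_values is not None else None
        out.append(alphabet.mapper(res, ss, sa))
    return "".join(out)


def encode_indices(segments: list[Segment], alphabet: PropertyAlphabet) -> np.ndarray:
    """Encode many segments into an (n, L) array of symbol indices."""
    idx = {s: i for i, s in enumerate(alphabet.symbols)}
    return np.array(
        [[idx[c] for c in encode_segment(seg, alphabet)] for seg in segments], dtype=np.intp
    )


def composition_vector(encoded: str, alphabet: PropertyAlphabet) -> np.ndarray:
    """Symbol frequencies of an encoded segment, in fixed symbol order (sums to 1)."""
    if not encoded:
        raise FormatError("cannot compute composition of an empty segment")
    counts = np.zeros(alphabet.size)
    for c in encoded:
        counts[alphabet.index(c)] += 1
    return counts / counts.sum()


def component_features(segment: Segment) -> np.ndarray:
    """Concatenated composition over AA, HYD, CHG, SS, SA — dimension 39."""
    return np.concatenate(
        [composition_vector(encode_segment(segment, a), a) for a in PROPERTIES]
    )


def composition_matrix(indices: np.ndarray, alphabet: PropertyAlphabet) -> np.ndarray:
    """Vectorized per-row composition for an (n, L) index array."""
    n, L = indices.shape
    counts = np.zeros((n, alphabet.size))
    np.add.at(counts, (np.arange(n)[:, None], indices), 1.0)
    return counts / L
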