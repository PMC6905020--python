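"""Protein records, binding annotations, optional structure tracks, and window extraction.

A protein chain is cut into overlapping fixed-length segments by sliding an
odd-length window along the sequence.  ``(L-1)/2`` dummy residues ``X`` are
appended at both termini so that every residue appears once as a window
center; a segment is positive iff its center residue is annotated as binding
the ion ligand.  Coordinates are 1-based and inclusive throughout, matching
the residue numbering used in binding-site annotation tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

from .errors import FormatError, ParameterError, TrackError

logger = logging.getLogger(__name__)

PAD = "X"
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: ambiguous / non-standard one-letter codes folded into the pad symbol
NONSTANDARD_AA = "BZUOJ"


@dataclass
class ProteinRecord:
    """One protein chain with its binding annotation and optional tracks.

    ``ss_track`` is a per-residue H/E/C string; ``sa_track`` holds predicted
    relative solvent accessibility in [0, 1].  Both must match the sequence
    length exactly when present.
    """

    id: str
    sequence: str
    binding_positions: set[int] = field(default_factory=set)
    ss_track: str | None = None
    sa_track: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.sequence)
        for p in self.binding_positions:
            if not (1 <= p <= n):
                raise FormatError(
                    f"protein {self.id!r}: binding position {p} outside [1, {n}]"
                )
        if self.ss_track is not None:
            if len(self.ss_track) != n:
                raise TrackError(
                    f"protein {self.id!r}: SS track length {len(self.ss_track)} != sequence length {n}"
                )
            bad = set(self.ss_track) - set("HEC")
            if bad:
                raise TrackError(f"protein {self.id!r}: SS letters {sorted(bad)} not in H/E/C")
        if self.sa_track is not None:
            self.sa_track = np.asarray(self.sa_track, dtype=float)
            if self.sa_track.shape != (n,):
                raise TrackError(
                    f"protein {self.id!r}: SA track length {self.sa_track.size} != sequence length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Segment:
    """One odd-length window over the padded sequence, labeled at its center.

    ``symbols`` uses the 20 standard residues plus the pad ``X``, which can
    occur only as a contiguous prefix/suffix.  ``ss_symbols`` / ``sa_values``
    carry the window slice of the protein's tracks, pad positions holding the
    pad symbol / ``nan``.
    """

    protein_id: str
    center: int
    symbols: str
    label: bool
    ss_symbols: str | None = None
    sa_values: tuple[float, ...] | None = None

    @property
    def window_length(self) -> int:
        return len(self.symbols)


def _clean_sequence(pid: str, raw: str) -> str:
    seq = raw.upper()
    if any(c.isdigit() for c in seq):
        raise FormatError(f"protein {pid!r}: sequence contains digits")
    if any(c in NONSTANDARD_AA for c in seq):
        logger.warning("protein %r: non-standard residues mapped to %r", pid, PAD)
        seq = "".join(PAD if c in NONSTANDARD_AA else c for c in seq)
    bad = set(seq) - set(STANDARD_AA) - {PAD}
    if bad:
        raise FormatError(f"protein {pid!r}: invalid residue letters {sorted(bad)}")
    return seq


def read_fasta(path, min_length: int | None = None) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects (no annotations).

    The record id is the first whitespace-delimited header token; sequences
    are uppercased.  ``min_length`` optionally drops chains at or below that
    length (the dataset-construction filter for short chains).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise FormatError(f"duplicate FASTA id {pid!r}")
        seen.add(pid)
        seq = _clean_sequence(pid, str(entry.seq))
        if not seq:
            raise FormatError(f"protein {pid!r}: empty sequence")
        records.append(ProteinRecord(id=pid, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA entries in {path}")
    if min_length is not None:
        records = [r for r in records if len(r) > min_length]
    return records


def read_binding_annotations(path, records: list[ProteinRecord], ligand: str | None = None) -> list[ProteinRecord]:
    """Attach binding positions from a tab-separated annotation table.

    Rows are ``protein_id<TAB>ligand_id<TAB>positions`` with space-separated
    1-based positions.  Positions are unioned over rows per protein;
    ``ligand`` restricts to one ligand id (default: pool all rows).
    """
    by_id = {r.id: r for r in records}
    positions: dict[str, set[int]] = {r.id: set() for r in records}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            pid, lig, pos_field = parts
            if pid not in by_id:
                raise FormatError(f"{path}:{lineno}: unknown protein id {pid!r}")
            if ligand is not None and lig != ligand:
                continue
            for tok in pos_field.split():
                try:
                    p = int(tok)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: malformed position {tok!r}") from exc
                if not (1 <= p <= len(by_id[pid])):
                    raise FormatError(
                        f"{path}:{lineno}: protein {pid!r} position {p} out of range "
                        f"[1, {len(by_id[pid])}]"
                    )
                positions[pid].add(p)
    return [replace(r, binding_positions=positions[r.id]) for r in records]


def _read_track_table(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least 2 tab-separated fields")
            if parts[0] in out:
                raise FormatError(f"{path}:{lineno}: duplicate protein id {parts[0]!r}")
            out[parts[0]] = parts[1:]
    return out


def attach_tracks(records: list[ProteinRecord], ss_path=None, sa_path=None) -> list[ProteinRecord]:
    """Attach predicted secondary-structure and solvent-accessibility tracks.

    SS rows are ``protein_id<TAB>HEC-string``; SA rows are
    ``protein_id<TAB>v1 v2 ...``.  SA values outside [0, 1] by at most 1e-9
    are clamped with a warning; larger excursions are errors.
    """
    ss = _read_track_table(ss_path) if ss_path is not None else {}
    sa = _read_track_table(sa_path) if sa_path is not None else {}
    out = []
    for rec in records:
        new = rec
        if rec.id in ss:
            new = replace(new, ss_track=ss[rec.id][0])
        if rec.id in sa:
            try:
                vals = np.array([float(v) for v in " ".join(sa[rec.id]).split()])
            except ValueError as exc:
                raise FormatError(f"protein {rec.id!r}: malformed SA value") from exc
            if vals.min() < -1e-9 or vals.max() > 1 + 1e-9:
                raise FormatError(
                    f"protein {rec.id!r}: SA values outside [0,1] "
                    f"(min {vals.min():.3g}, max {vals.max():.3g})"
                )
            if vals.min() < 0 or vals.max() > 1:
                logger.warning("protein %r: SA values clamped to [0,1]", rec.id)
            new = replace(new, sa_track=np.clip(vals, 0.0, 1.0))
        out.append(new)
    return out


def extract_windows(record: ProteinRecord, window_length: int) -> list[Segment]:
    """Slide an odd window of length ``window_length`` over the padded sequence.

    Returns exactly ``len(record)`` segments, one per residue as center, in
    sequence order.  Track windows are carried along when the record has
    tracks (pad positions get the pad symbol / ``nan``).
    """
    L = window_length
    if L < 3 or L % 2 == 0:
        raise ParameterError(f"window length must be odd and >= 3, got {L}")
    half = (L - 1) // 2
    padded = PAD * half + record.sequence + PAD * half
    ss_padded = (PAD * half + record.ss_track + PAD * half) if record.ss_track is not None else None
    if record.sa_track is not None:
        sa_padded = np.concatenate([np.full(half, np.nan), record.sa_track, np.full(half, np.nan)])
    else:
        sa_padded = None
    segments = []
    for center in range(1, len(record) + 1):
        lo = center - 1  # 0-based start in padded string
        segments.append(
            Segment(
                protein_id=record.id,
                center=center,
                symbols=padded[lo : lo + L],
                label=center in record.binding_positions,
                ss_symbols=ss_padded[lo : lo + L] if ss_padded is not None else None,
                sa_values=tuple(sa_padded[lo : lo + L]) if sa_padded is not None else None,
            )
        )
    return segments


def extract_all_windows(records: list[ProteinRecord], window_length: int) -> list[Segment]:
    """Concatenate :func:`extract_windows` over all records, in input order."""
    out: list[Segment] = []
    for rec in records:
        out.extend(extract_windows(rec, window_length))
    return out


# ---------------------------------------------------------------------------
# writers (round-trip with the readers above; also used by the simulator)

def write_fasta(records: list[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def write_binding_annotations(records: list[ProteinRecord], path, ligand: str = "ION") -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.binding_positions:
                pos = " ".join(str(p) for p in sorted(rec.binding_positions))
                fh.write(f"{rec.id}\t{ligand}\t{pos}\n")


def write_tracks(records: list[ProteinRecord], ss_path=None, sa_path=None) -> None:
    if ss_path is not None:
        with open(ss_path, "w") as fh:
            for rec in records:
                if rec.ss_track is not None:
                    fh.write(f"{rec.id}\t{rec.ss_track}\n")
    if sa_path is not None:
        with open(sa_path, "w") as fh:
            for rec in records:
                if rec.sa_track is not None:
                    vals = " ".join(f"{v:.6f}" for v in rec.sa_track)
                    fh.write(f"{rec.id}\t{vals}\n")
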