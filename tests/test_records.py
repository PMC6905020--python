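"""Sequence/annotation IO and sliding-window extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionseg import (
    FormatError,
    ParameterError,
    ProteinRecord,
    TrackError,
    attach_tracks,
    extract_windows,
    read_binding_annotations,
    read_fasta,
)
from ionseg.records import write_binding_annotations, write_fasta, write_tracks


def fasta(tmp_path, text):
    p = tmp_path / "in.fasta"
    p.write_text(text)
    return p


class TestReadFasta:
    def test_single_entry(self, tmp_path):
        recs = read_fasta(fasta(tmp_path, ">p1\nACDEF\n"))
        assert len(recs) == 1
        assert recs[0].id == "p1" and recs[0].sequence == "ACDEF"

    def test_multiline_uppercased(self, tmp_path):
        recs = read_fasta(fasta(tmp_path, ">p1 some description\nac\ndef\n"))
        assert recs[0].id == "p1"
        assert recs[0].sequence == "ACDEF"

    def test_duplicate_ids_rejected(self, tmp_path):
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(fasta(tmp_path, ">p1\nAC\n>p1\nDE\n"))

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            read_fasta(fasta(tmp_path, ""))

    def test_digits_rejected(self, tmp_path):
        with pytest.raises(FormatError, match="digit"):
            read_fasta(fasta(tmp_path, ">p1\nAC1DE\n"))

    def test_nonstandard_residues_become_pad(self, tmp_path):
        recs = read_fasta(fasta(tmp_path, ">p1\nABZC\n"))
        assert recs[0].sequence == "AXXC"


class TestAnnotations:
    def test_positions_unioned_over_rows(self, tmp_path):
        recs = read_fasta(fasta(tmp_path, ">p1\nACDEF\n"))
        ann = tmp_path / "b.tsv"
        ann.write_text("p1\tZN\t2 4\np1\tZN\t3\n")
        recs = read_binding_annotations(ann, recs)
        assert recs[0].binding_positions == {2, 3, 4}

    def test_out_of_range_position(self, tmp_path):
        recs = read_fasta(fasta(tmp_path, ">p1\nACDEF\n"))
        ann = tmp_path / "b.tsv"
        ann.write_text("p1\tZN\t9\n")
        with pytest.raises(FormatError, match=r"p1.*9"):
            read_binding_annotations(ann, recs)

    def test_unknown_protein_and_malformed_int(self, tmp_path):
        recs = read_fasta(fasta(tmp_path, ">p1\nACDEF\n"))
        ann = tmp_path / "b.tsv"
        ann.write_text("p9\tZN\t1\n")
        with pytest.raises(FormatError, match="unknown"):
            read_binding_annotations(ann, recs)
        ann.write_text("p1\tZN\ttwo\n")
        with pytest.raises(FormatError, match="malformed"):
            read_binding_annotations(ann, recs)

    def test_ligand_selector(self, tmp_path):
        recs = read_fasta(fasta(tmp_path, ">p1\nACDEF\n"))
        ann = tmp_path / "b.tsv"
        ann.write_text("p1\tZN\t2\np1\tCA\t5\n")
        assert read_binding_annotations(ann, recs, ligand="ZN")[0].binding_positions == {2}
        assert read_binding_annotations(ann, recs)[0].binding_positions == {2, 5}


class TestTracks:
    def test_attach_and_length_check(self, tmp_path):
        recs = read_fasta(fasta(tmp_path, ">p1\nACDEF\n"))
        ss = tmp_path / "ss.tsv"
        sa = tmp_path / "sa.tsv"
        ss.write_text("p1\tHHECC\n")
        sa.write_text("p1\t0.1 0.3 0.5 0.0 1.0\n")
        recs = attach_tracks(recs, ss_path=ss, sa_path=sa)
        assert recs[0].ss_track == "HHECC"
        assert np.allclose(recs[0].sa_track, [0.1, 0.3, 0.5, 0.0, 1.0])

    def test_length_mismatch(self, tmp_path):
        recs = read_fasta(fasta(tmp_path, ">p1\nACDEF\n"))
        ss = tmp_path / "ss.tsv"
        ss.write_text("p1\tHHEC\n")
        with pytest.raises(TrackError, match="length"):
            attach_tracks(recs, ss_path=ss)

    def test_sa_clamping_and_rejection(self, tmp_path):
        recs = read_fasta(fasta(tmp_path, ">p1\nAC\n"))
        sa = tmp_path / "sa.tsv"
        sa.write_text("p1\t0.5 1.001\n")
        with pytest.raises(FormatError):
            attach_tracks(recs, sa_path=sa)
        sa.write_text(f"p1\t0.5 {1 + 1e-10:.12f}\n")
        out = attach_tracks(recs, sa_path=sa)
        assert out[0].sa_track[1] == 1.0


class TestWindows:
    def test_padded_enumeration(self):
        rec = ProteinRecord(id="p1", sequence="ACDEF", binding_positions={3})
        segs = extract_windows(rec, 5)
        assert len(segs) == 5
        assert segs[0].symbols == "XXACD"
        assert segs[2].symbols == "ACDEF" and segs[2].label
        assert segs[4].symbols == "DEFXX"
        assert sum(s.label for s in segs) == 1

    def test_pad_width_is_half_window(self):
        rec = ProteinRecord(id="p1", sequence="A" * 10)
        segs = extract_windows(rec, 17)
        assert segs[0].symbols == "X" * 8 + "A" * 9

    def test_single_residue_protein(self):
        rec = ProteinRecord(id="p1", sequence="W")
        segs = extract_windows(rec, 3)
        assert len(segs) == 1 and segs[0].symbols == "XWX"

    @pytest.mark.parametrize("bad_L", [4, 2, -3, 1])
    def test_invalid_window_length(self, bad_L):
        rec = ProteinRecord(id="p1", sequence="ACDEF")
        with pytest.raises(ParameterError):
            extract_windows(rec, bad_L)

    @settings(derandomize=True, max_examples=40)
    @given(
        seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40),
        L=st.sampled_from([3, 5, 7, 9, 11, 13, 15, 17]),
    )
    def test_window_invariants(self, seq, L):
        """One segment per residue; centers spell the sequence; pads only terminal."""
        rec = ProteinRecord(id="p", sequence=seq, binding_positions={1})
        segs = extract_windows(rec, L)
        assert len(segs) == len(seq)
        half = (L - 1) // 2
        assert "".join(s.symbols[half] for s in segs) == seq
        assert sum(s.label for s in segs) == 1
        for s in segs:
            assert len(s.symbols) == L
            assert "X" not in s.symbols.strip("X")

    def test_round_trip(self, tmp_path):
        from ionseg import SimConfig, simulate_dataset

        records = simulate_dataset(SimConfig(n_proteins=4, length_range=(30, 40), seed=5))
        write_fasta(records, tmp_path / "a.fasta")
        write_binding_annotations(records, tmp_path / "b.tsv")
        write_tracks(records, ss_path=tmp_path / "ss.tsv", sa_path=tmp_path / "sa.tsv")
        back = read_fasta(tmp_path / "a.fasta")
        back = read_binding_annotations(tmp_path / "b.tsv", back)
        back = attach_tracks(back, ss_path=tmp_path / "ss.tsv", sa_path=tmp_path / "sa.tsv")
        for orig, rt in zip(records, back):
            assert rt.id == orig.id
            assert rt.sequence == orig.sequence
            assert rt.binding_positions == orig.binding_positions
            assert rt.ss_track == orig.ss_track
            assert np.allclose(rt.sa_track, orig.sa_track, atol=1e-6)
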