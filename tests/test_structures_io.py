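import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chirsep.elements import UnsupportedElementError
from chirsep.structures_io import (ExperimentRecord, FrameSet, ParseError,
                                   StructuralError, ValidationError,
                                   filter_records, load_experiment_table,
                                   load_solvent_table, max_possible_ee,
                                   read_frames, read_structure,
                                   validate_record, write_experiment_table,
                                   write_frames, write_structure)

WATER_XYZ = """3
water
O 0.000 0.000 0.000
H 0.957 0.000 0.000
H -0.240 0.927 0.000
"""

METHANE_SDF = """methane
  chirsep

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0900    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
M  END
$$$$
"""


class TestReadStructure:
    def test_water_xyz(self, tmp_path):
        path = tmp_path / "water.xyz"
        path.write_text(WATER_XYZ)
        mol = read_structure(path)
        assert mol.n_atoms == 3
        assert mol.elements == ["O", "H", "H"]
        assert np.isclose(mol.coords[1, 0], 0.957, atol=1e-5)

    def test_sdf_coordinates_match_block(self, tmp_path):
        path = tmp_path / "methane.sdf"
        path.write_text(METHANE_SDF)
        mol = read_structure(path)
        assert mol.elements == ["C", "H"]
        assert mol.coords[1, 0] == pytest.approx(1.09, abs=1e-12)

    def test_unknown_element_rejected(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("1\n\nXz 0.0 0.0 0.0\n")
        with pytest.raises(UnsupportedElementError):
            read_structure(path)

    def test_malformed_header_names_line(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("not-a-count\nfoo\n")
        with pytest.raises(ParseError, match="line 1"):
            read_structure(path)

    def test_truncated_file(self, tmp_path):
        path = tmp_path / "short.xyz"
        path.write_text("5\nheader\nO 0 0 0\n")
        with pytest.raises(ParseError, match="truncated"):
            read_structure(path)

    def test_xyz_round_trip(self, tmp_path, water):
        path = tmp_path / "w.xyz"
        write_structure(water, path)
        back = read_structure(path)
        assert back.elements == water.elements
        np.testing.assert_allclose(back.coords, water.coords, atol=1e-5)


class TestFrames:
    def _frames(self, tiny_complex, n=3):
        rng = np.random.default_rng(0)
        return FrameSet(tiny_complex,
                        [tiny_complex.coords + rng.normal(scale=0.05,
                                                          size=(5, 3))
                         for _ in range(n)])

    def test_h5_round_trip_bitwise(self, tmp_path, tiny_complex):
        frames = self._frames(tiny_complex)
        path = tmp_path / "frames.h5"
        write_frames(frames, path)
        back = read_frames(path)
        assert back.frame_count == 3
        for a, b in zip(frames.frames, back.frames):
            assert np.array_equal(a, b)  # bitwise
        assert back.complex_template.elements == tiny_complex.elements

    def test_xyz_round_trip(self, tmp_path, tiny_complex):
        frames = self._frames(tiny_complex, n=4)
        path = tmp_path / "frames.xyz"
        write_frames(frames, path)
        back = read_frames(path, template=tiny_complex)
        assert back.frame_count == 4
        for a, b in zip(frames.frames, back.frames):
            np.testing.assert_allclose(a, b, atol=1e-6)

    def test_single_frame_rejected(self, tiny_complex):
        with pytest.raises(StructuralError, match="2 frames"):
            FrameSet(tiny_complex, [tiny_complex.coords])

    def test_frame_shape_mismatch(self, tiny_complex):
        with pytest.raises(StructuralError, match="frame 1"):
            FrameSet(tiny_complex, [tiny_complex.coords, np.zeros((4, 3))])


class TestExperimentTable:
    def test_round_trip(self, tmp_path):
        recs = [
            ExperimentRecord("rac1", "ag1", [("ethanol", 1.0)], 0.2, 0.5, True),
            ExperimentRecord("rac1", "ag2", [("ethanol", 0.5), ("water", 0.5)],
                             0.05, 0.1, False),
        ]
        path = tmp_path / "exp.csv"
        write_experiment_table(recs, path)
        back = load_experiment_table(path)
        assert len(back) == 2
        assert back[0].m_frac == 0.2 and back[0].ee == 0.5
        assert back[1].solvent_components == [("ethanol", 0.5), ("water", 0.5)]

    def test_bad_fraction_sum_names_row(self, tmp_path):
        path = tmp_path / "exp.csv"
        path.write_text(
            "racemate_id,agent_id,solvents,solvent_fractions,m_frac,ee\n"
            "r1,a1,ethanol|water,0.6|0.5,0.2,0.5\n")
        with pytest.raises(ValidationError, match="row 0"):
            load_experiment_table(path)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "exp.csv"
        path.write_text(
            "racemate_id,agent_id,solvents,solvent_fractions,m_frac,ee\n")
        assert load_experiment_table(path) == []

    def test_zero_m_frac_imputes_ee(self):
        rec = ExperimentRecord("r", "a", [("ethanol", 1.0)], 0.0, 0.7)
        assert rec.ee == 0.0 and rec.ee_imputed

    def test_solvent_table(self, tmp_path):
        path = tmp_path / "solv.csv"
        path.write_text("solvent_id,a,b\nethanol,1.0,2.0\nwater,3.0,4.0\n")
        df = load_solvent_table(path)
        assert list(df.loc["water"]) == [3.0, 4.0]


class TestPhysicalConsistencyFilter:
    @pytest.mark.parametrize("m_frac,ee,keep", [
        (0.3, 1.0, True),    # below half mass: any ee possible
        (0.6, 0.9, False),   # max_ee = 2/3, far above the 5% band
        (0.6, 0.70, True),   # within the 5% experimental-error band
    ])
    def test_max_ee_rule(self, m_frac, ee, keep):
        rec = ExperimentRecord("r", "a", [("e", 1.0)], m_frac, ee)
        assert validate_record(rec)[0] is keep

    def test_max_ee_closed_form(self):
        assert max_possible_ee(0.4) == 1.0
        assert max_possible_ee(0.8) == pytest.approx(0.25)

    @given(m_frac=st.floats(0.0, 1.0), ee1=st.floats(0.0, 1.0),
           ee2=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_ee(self, m_frac, ee1, ee2):
        """If the higher-ee record is kept, any lower-ee record is kept too."""
        lo, hi = sorted([ee1, ee2])
        rec_lo = ExperimentRecord("r", "a", [("e", 1.0)], m_frac, lo)
        rec_hi = ExperimentRecord("r", "a", [("e", 1.0)], m_frac, hi)
        if validate_record(rec_hi)[0]:
            assert validate_record(rec_lo)[0]

    def test_filter_records_partitions(self):
        recs = [ExperimentRecord("r", "a", [("e", 1.0)], m, e)
                for m, e in [(0.3, 1.0), (0.9, 0.9), (0.6, 0.7)]]
        kept, discarded = filter_records(recs)
        assert len(kept) == 2 and len(discarded) == 1
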