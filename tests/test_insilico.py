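"""In-silico peak analysis: overlap fractions, distance maps, step rules."""

import numpy as np
import pandas as pd
import pytest

from tomomatch import (
    AngleList,
    Orientation,
    PhantomSpec,
    generate_angle_list,
    make_phantom,
    overlap_fraction,
    recommend_step,
    self_peak_analysis,
)
from tomomatch.errors import DomainError, MaskError, ShapeError
from tomomatch.geometry import rotate_array
from tomomatch.insilico import angular_distance_maps, rotation_profile


class TestOverlapFraction:
    def test_identity_is_one(self, two_lobe_template):
        assert overlap_fraction(
            two_lobe_template.density_mask, Orientation.identity()
        ) == 1.0

    def test_ball_rotation_invariant(self):
        # large enough that the surface-voxel rebinarization loss is small
        ball = make_phantom(PhantomSpec(kind="ball", dims=32))
        f = overlap_fraction(
            ball.density_mask, Orientation(40.0, 30.0, 70.0)
        )
        assert f >= 0.98

    def test_rod_matches_enumeration_oracle(self):
        rod = make_phantom(PhantomSpec(kind="rod", dims=32, binary=True))
        o = Orientation(theta=20.0)
        got = overlap_fraction(rod.density_mask, o)
        ref = rod.density_mask.data > 0.5
        rot = rotate_array(rod.density_mask.data.astype(np.float32), o) >= 0.5
        oracle = np.logical_and(ref, rot).sum() / ref.sum()
        assert got == pytest.approx(oracle, abs=1.0 / ref.sum())

    def test_empty_mask_rejected(self, ball_template):
        empty = ball_template.density_mask.with_data(
            np.zeros_like(ball_template.density_mask.data)
        )
        with pytest.raises(MaskError):
            overlap_fraction(empty, Orientation.identity())


class TestRecommendStep:
    def _table(self, rows):
        return pd.DataFrame(rows,
                            columns=["rotation_type", "offset_deg", "cc"])

    def test_flat_response_recommends_max(self):
        t = self._table([("cone", 0.0, 1.0), ("cone", 10.0, 0.99),
                         ("cone", 20.0, 0.98), ("cone", 30.0, 0.97)])
        assert recommend_step(t)["cone"] == 30.0

    def test_forty_percent_rule(self):
        t = self._table([("cone", 0.0, 1.0), ("cone", 10.0, 0.61),
                         ("cone", 20.0, 0.55)])
        # 39% drop at 10 deg passes, 45% at 20 deg fails
        assert recommend_step(t)["cone"] == 10.0

    def test_none_when_all_fail(self):
        t = self._table([("inplane", 0.0, 1.0), ("inplane", 5.0, 0.1)])
        assert recommend_step(t)["inplane"] is None

    def test_missing_columns_rejected(self):
        with pytest.raises(DomainError):
            recommend_step(pd.DataFrame({"cc": [1.0]}))

    def test_rod_inplane_tolerates_more_than_cone(self):
        """A rod is symmetric about its long (z) axis: in-plane spins barely
        cost CC, while cone tilts lose overlap quickly."""
        rod = make_phantom(PhantomSpec(kind="rod", dims=32))
        prof = pd.concat(
            [rotation_profile(rod, "cone"), rotation_profile(rod, "inplane")],
            ignore_index=True,
        )
        rec = recommend_step(prof)
        assert rec["inplane"] == 30.0  # max probed: spin-invariant
        assert rec["cone"] is None or rec["cone"] <= rec["inplane"]


class TestRotationProfile:
    def test_self_cc_decreases_with_offset(self, two_lobe_template):
        prof = rotation_profile(two_lobe_template, "cone",
                                offsets=(5.0, 15.0, 30.0))
        cc = prof["cc"].to_numpy()
        assert cc[0] > cc[1] > cc[2]
        assert (cc <= 1.0 + 1e-9).all()

    def test_cc_near_linear_in_overlap_for_binary_phantom(self):
        rod = make_phantom(PhantomSpec(kind="rod", dims=48, binary=True))
        offs = (5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0)
        prof = rotation_profile(rod, "cone", offsets=offs)
        ofr = [overlap_fraction(rod.density_mask, Orientation(theta=d))
               for d in offs]
        r = np.corrcoef(ofr, prof["cc"])[0, 1]
        assert r >= 0.99

    def test_hollow_falls_faster_than_ball(self):
        """Hollow phantoms lose CC faster with misorientation than a compact
        ball — the shape-dependence that motivates per-template tuning."""
        barrel = make_phantom(PhantomSpec(kind="hollow_barrel", dims=32))
        ball = make_phantom(PhantomSpec(kind="ball", dims=32))
        p_barrel = rotation_profile(barrel, "cone", offsets=(20.0,))
        p_ball = rotation_profile(ball, "cone", offsets=(20.0,))
        assert p_barrel["cc"].iloc[0] < p_ball["cc"].iloc[0]


class TestAngularDistanceMaps:
    def test_all_reference_gives_zero_maps(self):
        al = generate_angle_list(90.0)
        maps = type("M", (), {"angle_index": np.zeros((6, 6, 6), np.int32)})
        out = angular_distance_maps(maps, al, al[0])
        for grid in out.values():
            np.testing.assert_allclose(grid, 0.0, atol=1e-9)

    def test_single_orientation_constant_maps(self):
        al = AngleList(np.array([[30.0, 60.0, 10.0]]), step=0.0)
        maps = type("M", (), {"angle_index": np.zeros((4, 4, 4), np.int32)})
        out = angular_distance_maps(maps, al, Orientation.identity())
        for grid in out.values():
            assert np.ptp(grid) == pytest.approx(0.0, abs=1e-12)

    def test_voxelwise_matches_pairwise_oracle(self, rng):
        from tomomatch import angular_distance_full, cone_inplane_distance

        al = generate_angle_list(45.0)
        idx = rng.integers(0, len(al), size=(5, 5, 5)).astype(np.int32)
        maps = type("M", (), {"angle_index": idx})
        ref = Orientation(10.0, 20.0, 30.0)
        out = angular_distance_maps(maps, al, ref)
        for pos in [(0, 0, 0), (2, 3, 4), (4, 4, 4)]:
            o = al[int(idx[pos])]
            assert out["full"][pos] == pytest.approx(
                angular_distance_full(o, ref), abs=1e-9
            )
            cone, inpl = cone_inplane_distance(o, ref)
            assert out["cone"][pos] == pytest.approx(cone, abs=1e-9)
            assert out["inplane"][pos] == pytest.approx(inpl, abs=1e-9)


class TestSelfPeakAnalysis:
    @pytest.fixture(scope="class")
    def coarse(self):
        return generate_angle_list(90.0)

    def test_self_match_peaks_at_one(self, two_lobe_template, coarse):
        rep = self_peak_analysis(two_lobe_template, coarse)
        assert rep.peak_value == pytest.approx(1.0, abs=1e-4)
        c = two_lobe_template.boxsize // 2
        assert rep.peak_location == (c, c, c)
        assert rep.peak_value == pytest.approx(
            rep.cc_vs_rotation["cc"].max(), abs=1e-9
        )

    def test_cross_structure_scores_below_self(self, coarse):
        ball = make_phantom(PhantomSpec(kind="ball", dims=24))
        barrel = make_phantom(PhantomSpec(kind="hollow_barrel", dims=24))
        self_rep = self_peak_analysis(ball, coarse)
        cross_rep = self_peak_analysis(ball, coarse, probe=barrel.map)
        assert cross_rep.peak_value < self_rep.peak_value - 0.05

    def test_angular_offset_penalizes_peak(self, two_lobe_template):
        al = generate_angle_list(30.0)
        aligned = self_peak_analysis(two_lobe_template, al)
        offset = self_peak_analysis(two_lobe_template, al,
                                    angular_offset=15.0)
        assert offset.peak_value < aligned.peak_value

    def test_probe_shape_mismatch_rejected(self, two_lobe_template, coarse):
        from tomomatch import Volume

        bad = Volume(np.zeros((8, 8, 8), np.float32), 1.0)
        with pytest.raises(ShapeError):
            self_peak_analysis(two_lobe_template, coarse, probe=bad)

    def test_report_artifacts(self, two_lobe_template, coarse, tmp_path):
        rep = self_peak_analysis(two_lobe_template, coarse)
        rep.to_json(tmp_path / "r.json")
        text = rep.to_markdown(tmp_path / "r.md")
        assert (tmp_path / "r.json").exists()
        assert "solidity" in text
        binned = rep.binned_cc_vs_angle(2.0)
        assert {"bin", "cc_mean", "n"}.issubset(binned.columns)
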