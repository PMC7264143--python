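"""DVH construction, coverage metrics and the equivalent uniform dose."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrtplan import (
    DoseVolumePairs,
    EUDConfig,
    TumorVolumeProfile,
    assign_doses,
    build_dvh,
    coverage_metrics,
    eud,
    oar_metrics,
)
from mrtplan.synthetic import generate_depth_dose


def brute_force_eud(doses, volumes, d_ref, sf_ref):
    """Independent direct evaluation of the EUD formula."""
    w = np.asarray(volumes) / np.sum(volumes)
    surv = sum(wi * sf_ref ** (di / d_ref) for wi, di in zip(w, doses))
    return d_ref * math.log(surv) / math.log(sf_ref)


@pytest.fixture()
def two_step_pairs():
    return DoseVolumePairs(dose_gy=[15.0, 13.0], volume_mm3=[1.0, 1.0])


class TestAssignDoses:
    def test_flat_curve_gives_uniform_dose(self):
        profile = TumorVolumeProfile(
            bin_edges_mm=np.array([4.0, 5.0, 6.0, 7.0]),
            volume_mm3=np.array([1.0, 2.0, 1.0]),
        )
        curve = generate_depth_dose([(0.0, 100.0, 15.0), (10.0, 100.0, 15.0)])
        pairs = assign_doses(profile, curve, component="valley")
        assert np.allclose(pairs.dose_gy, 15.0)
        assert pairs.total_volume_mm3 == 4.0

    def test_two_bin_exponential_construction(self):
        # valley halves over 10 mm; one bin centered at the entrance (15 Gy)
        # and one centered where the exponential passes exactly 13 Gy
        curve = generate_depth_dose([(0.0, 150.0, 15.0), (10.0, 75.0, 7.5)])
        d13 = 10 * math.log(15 / 13) / math.log(2)
        w = 0.2
        hot = TumorVolumeProfile(
            bin_edges_mm=np.array([0.0, w]), volume_mm3=np.array([1.0])
        )
        cold = TumorVolumeProfile(
            bin_edges_mm=np.array([d13 - w / 2, d13 + w / 2]),
            volume_mm3=np.array([1.0]),
        )
        expected_hot = 15.0 * 2 ** (-(w / 2) / 10)  # dose at the hot bin center
        assert assign_doses(hot, curve).dose_gy[0] == pytest.approx(
            expected_hot, rel=1e-12
        )
        assert assign_doses(cold, curve).dose_gy[0] == pytest.approx(13.0, rel=1e-12)

    def test_out_of_span_bin_rejected(self):
        curve = generate_depth_dose([(0.0, 100.0, 15.0), (10.0, 50.0, 7.5)])
        profile = TumorVolumeProfile(
            bin_edges_mm=np.array([9.5, 11.5]), volume_mm3=np.array([1.0])
        )
        with pytest.raises(ValueError, match="span"):
            assign_doses(profile, curve)


class TestBuildDVH:
    def test_single_pair_step_function(self):
        pairs = DoseVolumePairs(dose_gy=[10.0], volume_mm3=[2.0])
        dvh = build_dvh(pairs)
        assert dvh.fraction_at_least(0.0) == 1.0
        assert dvh.fraction_at_least(10.0) == 1.0
        assert dvh.fraction_at_least(10.01) == 0.0

    def test_two_step_construction(self, two_step_pairs):
        dvh = build_dvh(two_step_pairs)
        assert dvh.fraction_at_least(13.0) == pytest.approx(1.0)
        assert dvh.fraction_at_least(14.0) == pytest.approx(0.5)
        assert dvh.fraction_at_least(15.0) == pytest.approx(0.5)
        assert dvh.fraction_at_least(15.1) == 0.0

    def test_merging_identical_doses_is_invariant(self):
        merged = DoseVolumePairs(dose_gy=[10.0, 12.0], volume_mm3=[3.0, 1.0])
        split = DoseVolumePairs(dose_gy=[10.0, 10.0, 12.0], volume_mm3=[1.0, 2.0, 1.0])
        d1, d2 = build_dvh(merged), build_dvh(split)
        assert np.allclose(d1.dose_gy, d2.dose_gy)
        assert np.allclose(d1.cum_volume_fraction, d2.cum_volume_fraction)

    def test_curve_is_monotone_and_anchored(self, two_step_pairs):
        dvh = build_dvh(two_step_pairs)
        assert dvh.cum_volume_fraction[0] == 1.0
        assert np.all(np.diff(dvh.cum_volume_fraction) <= 1e-12)
        assert dvh.cum_volume_fraction[-1] == 0.0

    def test_zero_volume_rejected(self):
        pairs = DoseVolumePairs(dose_gy=[1.0], volume_mm3=[0.0])
        with pytest.raises(ValueError):
            build_dvh(pairs)


class TestCoverageMetrics:
    def test_uniform_dose_at_prescription(self):
        pairs = DoseVolumePairs(dose_gy=[15.0] * 4, volume_mm3=[0.5] * 4)
        m = coverage_metrics(build_dvh(pairs), 15.0, EUDConfig(8.0, 0.115), pairs)
        assert m.v_prescription_pct == 100.0
        assert m.underdosed_volume_mm3 == 0.0
        assert m.d90_gy == pytest.approx(15.0)
        assert m.eud_gy == pytest.approx(15.0, abs=1e-10)

    def test_two_step_hand_oracle(self, two_step_pairs):
        # hand interpolation between corners (13, 1.0) and (15, 0.5)
        m = coverage_metrics(
            build_dvh(two_step_pairs), 15.0, EUDConfig(8.0, 0.115), two_step_pairs
        )
        assert m.v_prescription_pct == pytest.approx(50.00)
        assert m.underdosed_volume_mm3 == pytest.approx(1.000)
        assert m.d90_gy == pytest.approx(13.4)

    def test_volume_partition_is_exact(self, two_step_pairs):
        m = coverage_metrics(
            build_dvh(two_step_pairs), 14.0, EUDConfig(8.0, 0.115), two_step_pairs
        )
        covered = m.total_volume_mm3 * m.v_prescription_pct / 100
        assert covered + m.underdosed_volume_mm3 == pytest.approx(
            m.total_volume_mm3, abs=1e-9
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        doses = rng.uniform(5, 20, 12)
        vols = rng.uniform(0.1, 2, 12)
        cfg = EUDConfig(8.0, 0.115)
        perm = rng.permutation(12)
        a = DoseVolumePairs(dose_gy=doses, volume_mm3=vols)
        b = DoseVolumePairs(dose_gy=doses[perm], volume_mm3=vols[perm])
        ma = coverage_metrics(build_dvh(a), 15.0, cfg, a)
        mb = coverage_metrics(build_dvh(b), 15.0, cfg, b)
        assert ma == mb


class TestEUD:
    @given(
        dose=st.floats(0.5, 40),
        d_ref=st.floats(1, 20),
        sf_ref=st.floats(0.01, 0.99),
        n=st.integers(1, 10),
    )
    @settings(derandomize=True, max_examples=100)
    def test_uniform_dose_identity(self, dose, d_ref, sf_ref, n):
        pairs = DoseVolumePairs(dose_gy=[dose] * n, volume_mm3=[1.0] * n)
        assert eud(pairs, EUDConfig(d_ref, sf_ref)) == pytest.approx(dose, abs=1e-10)

    def test_two_dose_closed_form(self):
        pairs = DoseVolumePairs(dose_gy=[8.0, 16.0], volume_mm3=[1.0, 1.0])
        expected = 8 * math.log((0.3 + 0.3**2) / 2) / math.log(0.3)
        got = eud(pairs, EUDConfig(8.0, 0.3))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(10.86, abs=5e-3)

    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_brute_force_oracle_and_bounds(self, data):
        n = data.draw(st.integers(2, 8))
        doses = data.draw(
            st.lists(st.floats(0.5, 30), min_size=n, max_size=n)
        )
        vols = data.draw(
            st.lists(st.floats(0.1, 5), min_size=n, max_size=n)
        )
        cfg = EUDConfig(8.0, 0.115)
        pairs = DoseVolumePairs(dose_gy=doses, volume_mm3=vols)
        got = eud(pairs, cfg)
        assert got == pytest.approx(
            brute_force_eud(doses, vols, cfg.d_ref_gy, cfg.sf_ref), abs=1e-10
        )
        assert min(doses) - 1e-9 <= got <= max(doses) + 1e-9
        mean = np.average(doses, weights=vols)
        assert got <= mean + 1e-9  # cold spots dominate

    def test_unequal_volumes_weighting(self):
        pairs = DoseVolumePairs(dose_gy=[10.0, 20.0], volume_mm3=[3.0, 1.0])
        cfg = EUDConfig(8.0, 0.2)
        assert eud(pairs, cfg) == pytest.approx(
            brute_force_eud([10, 20], [3, 1], 8.0, 0.2), abs=1e-12
        )

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            EUDConfig(8.0, 1.5)
        with pytest.raises(ValueError):
            EUDConfig(0.0, 0.5)


class TestOARMetrics:
    def test_zero_dose_oar(self):
        pairs = DoseVolumePairs(
            dose_gy=[0.0, 0.0], volume_mm3=[5.0, 5.0], structure="OAR-brain"
        )
        table = oar_metrics(pairs, [8.0, 15.0])
        assert (table["valley_pct"] == 0.0).all()

    def test_matches_gtv_dvh_when_identical(self, two_step_pairs):
        table = oar_metrics(two_step_pairs, [13.0, 14.0, 15.0])
        dvh = build_dvh(two_step_pairs)
        for _, row in table.iterrows():
            assert row["valley_pct"] == pytest.approx(
                100 * dvh.fraction_at_least(row["threshold_gy"])
            )

    def test_constructed_isodose_fraction(self):
        # 21% of the OAR volume inside the 8 Gy isodose by construction
        pairs = DoseVolumePairs(
            dose_gy=[9.0, 5.0], volume_mm3=[21.0, 79.0], structure="OAR-brain"
        )
        table = oar_metrics(pairs, [8.0])
        assert table.loc[0, "valley_pct"] == pytest.approx(21.0)

    def test_composite_weights_peak_by_area_fraction(self, two_step_pairs):
        peak = DoseVolumePairs(dose_gy=[120.0, 104.0], volume_mm3=[1.0, 1.0])
        table = oar_metrics(two_step_pairs, [50.0], peak_pairs=peak, f_peak=0.125)
        assert table.loc[0, "valley_pct"] == 0.0
        assert table.loc[0, "peak_pct"] == 100.0
        assert table.loc[0, "composite_pct"] == pytest.approx(12.5)
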