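"""AFM position mapping, ±40 bp classification, occupancy estimation and the
measurement simulator."""

import numpy as np
import pytest

from talocus.afm_occupancy import (
    AfmMeasurement,
    PromoterSpec,
    classify_complex,
    expected_classified_fractions,
    is_valid_measurement,
    occupancy,
    position_bp,
    position_histogram,
    read_afm_tsv,
    write_afm_tsv,
)
from talocus.synthetic_data import simulate_afm

TEMPLATE = 1065
PROMOTERS = [PromoterSpec("RNAII", 276), PromoterSpec("RNAI", 498)]


class TestPositionBp:
    def test_per_molecule_scaling(self):
        m = AfmMeasurement("m1", contour_nm=341.0, complex_pos_nm=88.37, template_bp=TEMPLATE)
        assert position_bp(m) == pytest.approx(276, abs=0.5)

    def test_end_bound_complex(self):
        m = AfmMeasurement("m2", contour_nm=341.0, complex_pos_nm=0.0, template_bp=TEMPLATE)
        assert position_bp(m) == 0.0

    def test_midpoint_is_reflection_fixed_point(self):
        m = AfmMeasurement("m3", contour_nm=341.0, complex_pos_nm=170.5, template_bp=TEMPLATE)
        p = position_bp(m)
        assert p == pytest.approx(TEMPLATE - p)

    def test_contour_plausibility_gate(self):
        nominal = TEMPLATE * 0.34
        ok = AfmMeasurement("a", nominal * 1.1, 10.0, TEMPLATE)
        bad = AfmMeasurement("b", nominal * 1.5, 10.0, TEMPLATE)
        assert is_valid_measurement(ok) and not is_valid_measurement(bad)


class TestClassify:
    @pytest.mark.parametrize(
        "p,label",
        [(300, "RNAII"), (400, "nonspecific"), (789, "RNAII"), (498, "RNAI"), (530, "RNAI")],
    )
    def test_examples(self, p, label):
        assert classify_complex(p, TEMPLATE, PROMOTERS, 40) == label

    def test_invariant_under_end_reflection(self):
        rng = np.random.default_rng(0)
        for p in rng.uniform(0, TEMPLATE, size=300):
            assert classify_complex(p, TEMPLATE, PROMOTERS) == classify_complex(
                TEMPLATE - p, TEMPLATE, PROMOTERS
            )


class TestOccupancy:
    def _measurements(self, positions):
        contour = TEMPLATE * 0.34
        return [
            AfmMeasurement(f"m{i}", contour, p * contour / TEMPLATE, TEMPLATE)
            for i, p in enumerate(positions)
        ]

    def test_reported_occupancy_scenario(self):
        """66 complexes at the antitoxin promoter, 17 at the toxin promoter
        and 17 nonspecific give the 66/17/17% split and a promoter strength
        ratio just under four."""
        positions = [276.0] * 66 + [498.0] * 17 + [400.0] * 17
        res = occupancy(self._measurements(positions), PROMOTERS, ratio_pair=("RNAII", "RNAI"))
        assert res.fractions["RNAII"] == pytest.approx(0.66)
        assert res.fractions["RNAI"] == pytest.approx(0.17)
        assert res.fractions["nonspecific"] == pytest.approx(0.17)
        assert res.strength_ratio == pytest.approx(66 / 17)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        res = occupancy(self._measurements(rng.uniform(0, TEMPLATE, 137)), PROMOTERS)
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(res.counts.values()) == res.n_classified

    def test_single_promoter_degenerate(self):
        res = occupancy(self._measurements([276.0] * 10), PROMOTERS)
        assert res.fractions["RNAII"] == 1.0
        assert res.ci95["RNAII"][1] == pytest.approx(1.0)

    def test_n_equals_one_has_wide_ci(self):
        res = occupancy(self._measurements([276.0]), PROMOTERS)
        lo, hi = res.ci95["RNAII"]
        assert res.fractions["RNAII"] == 1.0
        assert hi - lo > 0.5

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        pos = list(rng.uniform(0, TEMPLATE, 80))
        a = occupancy(self._measurements(pos), PROMOTERS)
        b = occupancy(self._measurements(pos[::-1]), PROMOTERS)
        assert a.fractions == b.fractions

    def test_invalid_measurements_excluded_and_tallied(self):
        ms = self._measurements([276.0] * 5)
        ms.append(AfmMeasurement("bad", TEMPLATE * 0.34 * 2, 10.0, TEMPLATE))
        res = occupancy(ms, PROMOTERS)
        assert res.n_excluded == 1 and res.n_classified == 5

    def test_all_invalid_is_error(self):
        ms = [AfmMeasurement("bad", TEMPLATE * 0.34 * 2, 10.0, TEMPLATE)]
        with pytest.raises(ValueError):
            occupancy(ms, PROMOTERS)


class TestTsvIo:
    def test_round_trip(self, tmp_path):
        ms, _ = simulate_afm(7, TEMPLATE, PROMOTERS, {"RNAII": 1.0}, seed=0)
        p = tmp_path / "m.tsv"
        write_afm_tsv(ms, p)
        back = read_afm_tsv(p)
        assert len(back) == 7
        assert back[0].contour_nm == pytest.approx(ms[0].contour_nm)

    def test_missing_column_is_error(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("molecule_id\tcontour_nm\n")
        with pytest.raises(ValueError, match="complex_pos_nm"):
            read_afm_tsv(p)

    def test_malformed_row_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "molecule_id\tcontour_nm\tcomplex_pos_nm\ttemplate_bp\n"
            "ok\t340\t10\t1065\n"
            "bad\t340\t999\t1065\n"
        )
        ms = read_afm_tsv(p)
        assert [m.molecule_id for m in ms] == ["ok"]

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("molecule_id\tcontour_nm\tcomplex_pos_nm\ttemplate_bp\n")
        assert read_afm_tsv(p) == []


class TestSimulator:
    def test_degenerate_noise_recovers_centre_exactly(self):
        ms, _ = simulate_afm(
            1000, TEMPLATE, PROMOTERS, {"RNAII": 1.0}, sigma_bp=0.0, contour_cv=0.0, seed=5
        )
        for m in ms:
            p = position_bp(m)
            assert min(p, TEMPLATE - p) == pytest.approx(276, abs=1e-6)

    def test_deterministic_for_fixed_seed(self):
        a, _ = simulate_afm(50, TEMPLATE, PROMOTERS, {"RNAII": 0.5, "nonspecific": 0.5}, seed=3)
        b, _ = simulate_afm(50, TEMPLATE, PROMOTERS, {"RNAII": 0.5, "nonspecific": 0.5}, seed=3)
        assert a == b

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            simulate_afm(10, TEMPLATE, PROMOTERS, {"RNAII": 0.7}, seed=0)

    def test_category_frequencies_converge(self):
        frac = {"RNAII": 0.66, "RNAI": 0.17, "nonspecific": 0.17}
        _, truth = simulate_afm(100_000, TEMPLATE, PROMOTERS, frac, seed=8)
        cats = truth.afm["categories"]
        for k, f in frac.items():
            emp = cats.count(k) / len(cats)
            sd = (f * (1 - f) / len(cats)) ** 0.5
            assert abs(emp - f) < 3 * sd

    def test_pure_uniform_false_specific_rate(self):
        """Uniform nonspecific complexes are scored as specific exactly at
        the rate implied by the classification windows (with end
        reflection), matching the closed-form expectation."""
        frac = {"nonspecific": 1.0}
        ms, _ = simulate_afm(4000, TEMPLATE, PROMOTERS, frac, seed=9)
        res = occupancy(ms, PROMOTERS)
        exp = expected_classified_fractions(TEMPLATE, PROMOTERS, frac, sigma_bp=15.0)
        for name in exp:
            sd = (exp[name] * (1 - exp[name]) / 4000) ** 0.5
            assert abs(res.fractions[name] - exp[name]) < 3 * sd + 1e-9


class TestHistogram:
    def test_bins_cover_template_and_counts_sum(self):
        ms, _ = simulate_afm(500, TEMPLATE, PROMOTERS,
                             {"RNAII": 0.66, "RNAI": 0.17, "nonspecific": 0.17}, seed=11)
        df = position_histogram(ms, bin_bp=25)
        assert df["count"].sum() == len(ms)
        assert df["bin_start_bp"].iloc[0] == 0
        assert df["bin_end_bp"].iloc[-1] >= TEMPLATE
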