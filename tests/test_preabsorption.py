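import math

import numpy as np
import pytest
from scipy import stats

from epimap.datasets import FNNI_SUBSTITUTION_CURVES, g530_panel
from epimap.preabsorption import (
    GroupSummary,
    PanelEntry,
    StainingMeasurement,
    SuffixPattern,
    area_fraction,
    fit_inhibition_curve,
    ic50_bound,
    infer_epitope,
    panel_from_measurements,
    percent_of_control,
    substitution_scan,
    summarize,
    unpaired_t,
)


def measurement(code, area, conc=10.0, image="img"):
    return StainingMeasurement(
        image_id=image, tissue="t", peptide_code=code, concentration=conc, area_labelled=area
    )


class TestAreaFraction:
    def test_blank_image_is_zero(self):
        assert area_fraction(np.zeros((16, 16), dtype=np.uint8), 0) == 0.0

    def test_half_above_threshold(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:5] = 200
        assert area_fraction(img, 128) == 0.5

    def test_threshold_is_strict(self):
        img = np.full((4, 4), 128, dtype=np.uint8)
        assert area_fraction(img, 128) == 0.0
        assert area_fraction(img, 127) == 1.0

    def test_png_round_trip(self, tmp_path):
        from PIL import Image

        img = np.zeros((8, 8), dtype=np.uint8)
        img[:2] = 255
        path = tmp_path / "img.png"
        Image.fromarray(img, mode="L").save(path)
        assert area_fraction(path, 128) == 0.25

    def test_colour_image_rejected(self):
        with pytest.raises(ValueError):
            area_fraction(np.zeros((4, 4, 3), dtype=np.uint8), 0)


class TestPercentOfControl:
    def test_control_mean_maps_to_100(self):
        ms = [measurement("NONE", 0.04, 0.0), measurement("NONE", 0.04, 0.0)]
        out = percent_of_control(ms, "NONE")
        assert all(m.percent_of_control == pytest.approx(100.0) for m in out)

    def test_half_and_zero_blockade(self):
        ms = [
            measurement("NONE", 0.04, 0.0),
            measurement("PEP", 0.02),
            measurement("BLOCKED", 0.0),
        ]
        out = percent_of_control(ms, "NONE")
        assert out[1].percent_of_control == pytest.approx(50.0)
        assert out[2].percent_of_control == 0.0

    def test_scaling_all_areas_leaves_percentages_unchanged(self):
        ms = [measurement("NONE", 0.05, 0.0), measurement("PEP", 0.013)]
        scaled = [measurement(m.peptide_code, m.area_labelled * 3, m.concentration) for m in ms]
        a = percent_of_control(ms, "NONE")
        b = percent_of_control(scaled, "NONE")
        for x, y in zip(a, b):
            assert x.percent_of_control == pytest.approx(y.percent_of_control)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_of_control([measurement("NONE", 0.0, 0.0)], "NONE")


class TestSummarize:
    def test_constant_group(self):
        s = summarize({"g": [10.0, 10.0, 10.0]})["g"]
        assert (s.n, s.mean, s.sem) == (3, 10.0, 0.0)

    def test_two_point_group_hand_computed(self):
        s = summarize({"g": [0.0, 2.0]})["g"]
        assert s.mean == pytest.approx(1.0)
        assert s.sem == pytest.approx(1.0)  # SD = sqrt(2), SEM = sqrt(2)/sqrt(2)

    def test_singleton_group_has_zero_sem(self):
        s = summarize({"g": [7.0]})["g"]
        assert s.n == 1 and s.sem == 0.0

    def test_mean_recovery_on_simulated_replicates(self):
        mu, sd, n_rep, n_seed = 40.0, 8.0, 6, 100
        devs = []
        for seed in range(n_seed):
            rng = np.random.default_rng(seed)
            s = summarize({"g": rng.normal(mu, sd, n_rep)})["g"]
            devs.append(s.mean - mu)
        grand_se = sd / math.sqrt(n_rep * n_seed)
        assert abs(np.mean(devs)) <= 3 * grand_se


class TestUnpairedT:
    def test_identical_groups(self):
        res = unpaired_t([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_pooled_matches_scipy_on_raw_values(self, rng):
        a, b = rng.normal(10, 2, 8), rng.normal(12, 3, 6)
        res = unpaired_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.dof == len(a) + len(b) - 2

    def test_welch_matches_scipy(self, rng):
        a, b = rng.normal(10, 2, 8), rng.normal(12, 6, 5)
        res = unpaired_t(a, b, variant="welch")
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_summary_input_equals_raw_input(self, rng):
        for variant in ("pooled", "welch"):
            a, b = rng.normal(30, 10, 8), rng.normal(45, 12, 3)
            raw = unpaired_t(a, b, variant=variant)
            summ = unpaired_t(
                summarize({"a": a})["a"], summarize({"b": b})["b"], variant=variant
            )
            assert summ.t == pytest.approx(raw.t, abs=1e-9)
            assert summ.p == pytest.approx(raw.p, abs=1e-9)
            assert summ.dof == pytest.approx(raw.dof, abs=1e-9)

    def test_published_summary_comparison_runs(self):
        # KEFNNI vs EPL001 preabsorption at 100 ng/ml, from printed summaries
        kefnni = GroupSummary(n=8, mean=29.53, sem=9.69)
        epl001 = GroupSummary(n=4, mean=0.09, sem=0.05)
        res = unpaired_t(kefnni, epl001)
        assert res.t > 0 and 0 < res.p < 1

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t([1.0, 1.0], [2.0, 2.0])

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            unpaired_t([1.0], [2.0, 3.0])

    def test_power_at_planted_separation_matches_noncentral_t(self):
        # delta/sigma = 3, n = 8 per arm, alpha = 0.05, 500 simulations
        n, delta, alpha, n_sim = 8, 3.0, 0.05, 500
        dof = 2 * n - 2
        ncp = delta / math.sqrt(2 / n)
        tcrit = stats.t.ppf(1 - alpha / 2, dof)
        power = stats.nct.sf(tcrit, dof, ncp) + stats.nct.cdf(-tcrit, dof, ncp)
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(n_sim):
            a = rng.normal(0.0, 1.0, n)
            b = rng.normal(delta, 1.0, n)
            rejections += unpaired_t(a, b).p < alpha
        se = math.sqrt(power * (1 - power) / n_sim)
        assert abs(rejections / n_sim - power) <= max(3 * se, 0.01)


class TestIc50Bound:
    def test_flat_curve_not_reached(self):
        assert str(ic50_bound([(0.1, 100.0), (10.0, 98.0)])) == "not reached"

    def test_first_dose_at_or_below_half(self):
        b = ic50_bound([(0.1, 80.0), (10.0, 40.0), (1000.0, 5.0)])
        assert b.kind == "le" and b.concentration == 10.0

    def test_below_half_at_lowest_dose(self):
        b = ic50_bound([(0.1, 0.56), (1.0, 0.30), (10.0, 0.0)])
        assert b.kind == "lt_min" and b.concentration == 0.1

    def test_bound_ordering_of_published_trend(self):
        epl001 = ic50_bound([(0.1, 0.56), (1.0, 0.30), (10.0, 0.0), (100.0, 0.09)])
        fnni = ic50_bound([(0.1, 90.0), (1.0, 70.0), (10.0, 30.0), (100.0, 2.7)])
        kefnni = ic50_bound([(0.1, 95.0), (1.0, 85.0), (10.0, 60.0), (100.0, 29.53)])
        assert epl001.sort_value < fnni.sort_value < kefnni.sort_value

    def test_bracket_recovery_on_simulated_curves(self):
        from epimap.synthetic import inhibition_percent

        concs = (0.1, 1.0, 10.0, 100.0, 1000.0)
        hits = 0
        n_seed = 200
        for seed in range(n_seed):
            rng = np.random.default_rng(seed)
            ic50 = 5.0
            curve = []
            for c in concs:
                reps = [
                    max(0.0, inhibition_percent(c, ic50, 1.0) + rng.normal(0, 5.0))
                    for _ in range(4)
                ]
                curve.append((c, float(np.mean(reps))))
            b = ic50_bound(curve)
            if b.kind == "le" and ic50 <= b.concentration:
                hits += 1
            elif b.kind == "lt_min" and ic50 < b.concentration:
                hits += 1
        assert hits / n_seed >= 0.95

    def test_curve_fit_recovers_parameters_noise_free(self):
        from epimap.synthetic import inhibition_percent

        concs = [0.1, 1.0, 3.0, 10.0, 30.0, 100.0, 1000.0]
        y = [inhibition_percent(c, 7.0, 1.3) for c in concs]
        ic50, slope = fit_inhibition_curve(concs, y)
        assert ic50 == pytest.approx(7.0, rel=1e-4)
        assert slope == pytest.approx(1.3, rel=1e-4)


class TestInferEpitope:
    def test_published_panel_recovers_c_terminal_nni(self, g530_panel_fixture):
        result = infer_epitope(g530_panel_fixture, max_len=6)
        best = result.best_score
        assert str(best.pattern) == "NNI"
        assert best.accuracy == 1.0
        assert best.sensitivity == 1.0 and best.specificity == 1.0

    def test_ranking_prefers_more_fixed_slots_at_equal_accuracy(self, g530_panel_fixture):
        result = infer_epitope(g530_panel_fixture, max_len=3, top_k=10)
        accs = [s.accuracy for s in result.ranked]
        assert accs == sorted(accs, reverse=True)
        perfect = [s for s in result.ranked if s.accuracy == 1.0]
        assert str(perfect[0].pattern) == "NNI"
        assert all(
            s.pattern.n_fixed <= perfect[0].pattern.n_fixed for s in perfect[1:]
        )

    def test_degenerate_panel_flagged(self):
        panel = [
            PanelEntry("A", "NNI", "yes"),
            PanelEntry("B", "KNNI", "yes"),
        ]
        result = infer_epitope(panel)
        assert result.degenerate and result.best is None

    def test_permutation_invariance(self, g530_panel_fixture, rng):
        base = infer_epitope(g530_panel_fixture, max_len=4)
        shuffled = list(g530_panel_fixture)
        rng.shuffle(shuffled)
        other = infer_epitope(shuffled, max_len=4)
        assert str(base.best) == str(other.best)
        assert [str(s.pattern) for s in base.ranked] == [str(s.pattern) for s in other.ranked]

    def test_adding_already_rejected_non_blocker_keeps_best(self, g530_panel_fixture):
        base = infer_epitope(g530_panel_fixture, max_len=4)
        extra = g530_panel_fixture + [PanelEntry("NEW", "MKPLTGKVKEFQQQ", "no")]
        assert not base.best.matches("MKPLTGKVKEFQQQ")
        assert str(infer_epitope(extra, max_len=4).best) == str(base.best)

    def test_highest_conc_only_excluded_by_default_included_in_sensitivity_mode(self, g530_panel_fixture):
        strict = infer_epitope(g530_panel_fixture, max_len=4)
        lax = infer_epitope(g530_panel_fixture, max_len=4, include_highest_conc_only=True)
        assert str(strict.best) == "NNI"
        # ANNI ends in NNI, so the lax reading reaches the same rule
        assert str(lax.best) == "NNI"

    def test_residue_classification_from_substitution_scan(self, g530_panel_fixture):
        result = infer_epitope(
            g530_panel_fixture, max_len=6, substitution_results=FNNI_SUBSTITUTION_CURVES
        )
        cls = result.residue_classification
        assert cls[1] == "contiguous-core"  # I
        assert cls[2] == "contiguous-core"  # N
        assert cls[3] == "contiguous-core"  # N
        assert cls[4] == "required-non-contiguous"  # F


class TestSubstitutionScan:
    def test_published_tetramer_variants(self):
        scan = substitution_scan(FNNI_SUBSTITUTION_CURVES)
        # position 1 = C-terminal I (required), 4 = F (required); Ns tolerant
        assert scan == {1: True, 2: False, 3: False, 4: True}

    def test_requires_single_substitutions(self):
        with pytest.raises(ValueError):
            substitution_scan({"FNNI": True, "FAAI": False})

    def test_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            substitution_scan({"FNNI": True, "NNI": False})


class TestPanelFromMeasurements:
    def test_calls_blockade_at_top_dose(self):
        rows = [
            {"peptide_code": "B", "concentration_ng_ml": 10.0, "percent_of_control": 20.0},
            {"peptide_code": "B", "concentration_ng_ml": 1.0, "percent_of_control": 80.0},
            {"peptide_code": "N", "concentration_ng_ml": 10.0, "percent_of_control": 95.0},
            {"peptide_code": "NONE", "concentration_ng_ml": 0.0, "percent_of_control": 100.0},
        ]
        panel = panel_from_measurements(rows, {"B": "KNNI", "N": "KKKK"})
        byc = {e.peptide_code: e.blocks for e in panel}
        assert byc == {"B": "yes", "N": "no"}


class TestSuffixPattern:
    def test_matching_semantics(self):
        pat = SuffixPattern.from_string("xNNI")
        assert pat.matches("KEFNNI")
        assert not pat.matches("NNI")  # too short for the 4-slot pattern
        assert not pat.matches("KEFNNA")

    def test_all_wildcard_rejected(self):
        with pytest.raises(ValueError):
            SuffixPattern.from_string("xxx")
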