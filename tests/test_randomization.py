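import numpy as np
import pytest

import topostats as ts
from topostats.designs import BetweenDesign, enumerate_effects
from topostats.randomization import (RandomizationOptions,
                                     averaged_window_tanova,
                                     exact_pointwise_p, pointwise_p,
                                     result_table, run_tancova, run_tanova)
from topostats.simulate import (GenerativeSpec, SourceEffect, boxcar,
                                condition_effect_spec, generate,
                                random_topography)


def _quiet_opts(**kw):
    kw.setdefault("n_runs", 200)
    kw.setdefault("normalization", "none")
    return RandomizationOptions(**kw)


quiet = pytest.mark.filterwarnings("ignore:.*randomization runs.*")


class TestPointwiseP:
    @pytest.mark.parametrize("observed, null, expected", [
        (999.5, list(range(999)), 1 / 1000),       # larger than every null
        (5.0, [5.0] * 99, 1.0),                    # >= rule: ties count
        (5.0, [1, 2, 3, 4, 5, 6, 7, 8, 9], 6 / 10),  # median of 9
    ])
    def test_counting_rule(self, observed, null, expected):
        assert pointwise_p(observed, null) == pytest.approx(expected)

    def test_never_zero(self, rng):
        assert pointwise_p(np.inf, rng.random(100)) > 0


@quiet
class TestRunTanova:
    def test_reproducibility_bit_identical(self, within_2x2,
                                           small_null_dataset):
        opts = _quiet_opts(n_runs=50, seed=11)
        r1 = run_tanova(small_null_dataset, within_2x2, None, opts)
        r2 = run_tanova(small_null_dataset, within_2x2, None, opts)
        for eid in r1.p:
            assert np.array_equal(r1.p[eid], r2.p[eid])
            assert np.array_equal(r1.null[eid], r2.null[eid])

    def test_warns_on_few_runs(self, within_2x2, small_null_dataset):
        with pytest.warns(UserWarning, match="1000 runs"):
            run_tanova(small_null_dataset, within_2x2, None,
                       RandomizationOptions(n_runs=100, seed=1))

    def test_l2_analysis_invariant_to_map_rescaling(self, within_2x2,
                                                    small_null_dataset):
        ds = small_null_dataset
        rng = np.random.default_rng(0)
        scale = rng.uniform(0.5, 3.0, size=ds.data.shape[:3])[..., None]
        scaled = ts.ErpDataset(ds.data * scale, average_referenced=True)
        o1 = _quiet_opts(n_runs=50, normalization="l2", seed=3)
        r1 = run_tanova(ds, within_2x2, None, o1)
        r2 = run_tanova(scaled, within_2x2, None, o1)
        for eid in r1.p:
            assert np.allclose(r1.observed[eid], r2.observed[eid])
            assert np.array_equal(r1.p[eid], r2.p[eid])

    def test_unnormalized_statistic_is_equivariant(self, within_2x2,
                                                   small_null_dataset):
        ds = small_null_dataset
        doubled = ts.ErpDataset(2.0 * ds.data, average_referenced=True)
        o = _quiet_opts(n_runs=30, seed=4)
        r1 = run_tanova(ds, within_2x2, None, o)
        r2 = run_tanova(doubled, within_2x2, None, o)
        for eid in r1.p:
            assert np.allclose(r2.observed[eid], 2.0 * r1.observed[eid])
            assert np.array_equal(r1.p[eid], r2.p[eid])

    def test_injected_effect_found_in_its_window(self, within_2x2):
        ds, _ = generate(condition_effect_spec(seed=5, effect_amplitude=1.0))
        res = run_tanova(ds, within_2x2, None, _quiet_opts(n_runs=500,
                                                           seed=6))
        assert np.min(res.p["A"][15:26]) < 0.01
        # the interaction carries no injected signal
        assert np.min(res.p["AxB"]) > 0.002

    def test_flat_map_under_l2_names_culprit(self, within_2x2):
        data = np.random.default_rng(0).standard_normal((4, 4, 6, 5))
        data[2, 1, 3] = 0.0
        ds = ts.ErpDataset(data)
        with pytest.raises(ValueError, match="S03.*C2.*sample 3"):
            run_tanova(ds, within_2x2, None,
                       _quiet_opts(normalization="l2"))

    def test_result_table_layout(self, within_2x2, small_null_dataset):
        res = run_tanova(small_null_dataset, within_2x2, None,
                         _quiet_opts(n_runs=20, seed=1))
        tab = result_table(res)
        assert list(tab.columns) == ["effect", "effect_name", "time_ms",
                                     "observed_s", "p"]
        assert len(tab) == 3 * small_null_dataset.n_time


@quiet
class TestExhaustiveOracleAgreement:
    def test_small_design_matches_enumeration(self, within_1f):
        spec = GenerativeSpec(n_subjects=5, design_shape=(2,), n_time=1,
                              n_sensors=8, seed=21)
        ds, _ = generate(spec)
        eff = enumerate_effects(within_1f)[0]
        exact = exact_pointwise_p(ds, within_1f, None, eff, 0)
        res = run_tanova(ds, within_1f, None,
                         _quiet_opts(n_runs=4000, seed=22))
        mc = res.p["A"][0]
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(mc - exact) < 3 * se + 2 / 4000

    def test_between_groups_matches_enumeration(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((6, 1, 1, 8))
        ds = ts.ErpDataset(data)
        groups = BetweenDesign("categorical", (0, 0, 0, 1, 1, 1))
        eff = enumerate_effects(None, groups)[0]
        exact = exact_pointwise_p(ds, None, groups, eff, 0)
        res = run_tanova(ds, None, groups, _quiet_opts(n_runs=4000, seed=9))
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(res.p["G"][0] - exact) < 3 * se + 2 / 4000


@quiet
class TestTancova:
    def test_requires_continuous_between(self, within_2x2,
                                         small_null_dataset, groups_2):
        with pytest.raises(ValueError, match="continuous"):
            run_tancova(small_null_dataset, within_2x2, groups_2,
                        _quiet_opts())

    def test_too_few_distinct_covariate_values(self, within_2x2,
                                               small_null_dataset):
        cov = BetweenDesign("continuous", (1.0,) * 11 + (2.0,))
        with pytest.raises(ValueError, match="3 distinct"):
            run_tancova(small_null_dataset, within_2x2, cov,
                        _quiet_opts(n_runs=10))

    def test_covariate_linked_source_detected(self, within_2x2):
        from topostats.simulate import covariate_effect_spec
        spec = covariate_effect_spec(seed=31, gain=1.0, effect_amplitude=3.0)
        ds, truth = generate(spec)
        cov = BetweenDesign("continuous", spec.covariate)
        res = run_tancova(ds, within_2x2, cov,
                          _quiet_opts(n_runs=500, seed=32))
        lo, hi = truth.sources[0]["active_window"]
        assert np.min(res.p["COV"][lo:hi]) < 0.01
        assert np.median(res.p["COV"][:lo]) > 0.2


@quiet
class TestAveragedWindow:
    def test_single_sample_window_matches_pointwise(self, within_2x2,
                                                    small_null_dataset):
        opts = _quiet_opts(n_runs=100, seed=13)
        point = run_tanova(small_null_dataset, within_2x2, None, opts)
        avg = averaged_window_tanova(small_null_dataset, within_2x2, None,
                                     opts, (7, 8))
        for eid in point.p:
            assert avg.p[eid][0] == point.p[eid][7]
            assert np.allclose(avg.null[eid][:, 0], point.null[eid][:, 7])

    def test_sustained_effect_sharpens_when_averaged(self, within_2x2):
        ds, _ = generate(condition_effect_spec(seed=41,
                                               effect_amplitude=0.5))
        opts = _quiet_opts(n_runs=500, seed=42)
        point = run_tanova(ds, within_2x2, None, opts)
        avg = averaged_window_tanova(ds, within_2x2, None, opts, (15, 26))
        assert avg.p["A"][0] <= np.median(point.p["A"][15:26])

    def test_polarity_reversal_cancels(self, within_2x2):
        rng = np.random.default_rng(51)
        topo = random_topography(16, rng)
        tc = boxcar(40, 10, 30)
        tc[20:30] *= -1  # effect flips sign mid-window
        spec = GenerativeSpec(seed=51, noise_sd=0.3, sources=(
            SourceEffect(topo, tc, amplitude=2.0,
                         condition_weights=np.array([1, 1, -1, -1.0])),))
        ds, _ = generate(spec)
        opts = _quiet_opts(n_runs=300, seed=52)
        point = run_tanova(ds, within_2x2, None, opts)
        avg = averaged_window_tanova(ds, within_2x2, None, opts, (10, 30))
        assert np.min(point.p["A"][10:30]) < 0.01   # strong pointwise
        assert avg.p["A"][0] > 0.2                  # cancels when averaged

    def test_empty_window_rejected(self, within_2x2, small_null_dataset):
        with pytest.raises(ValueError, match="window"):
            averaged_window_tanova(small_null_dataset, within_2x2, None,
                                   _quiet_opts(), (10, 10))
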