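import numpy as np
import pytest

import crosscell as cc
from crosscell.model_core import CANONICAL_KEYS, ValidationError


class TestTransportScaling:
    def test_identity_scaling_leaves_parameters_unchanged(self, fixture_models):
        adult, _ = fixture_models
        scaled = cc.apply_scaling(adult, cc.TransportScaling.identity())
        assert scaled.params == adult.params

    def test_halving_gkr_only_halves_kr_conductance(self, fixture_models):
        adult, _ = fixture_models
        scaled = cc.apply_scaling(adult, cc.TransportScaling.from_partial(GKr=0.5))
        for name, value in adult.params.items():
            if name == "GKr":
                assert scaled.params[name] == pytest.approx(0.5 * value)
            else:
                assert scaled.params[name] == value
        # input untouched
        assert adult.params["GKr"] == pytest.approx(0.045)

    def test_composition_equals_elementwise_product(self, fixture_models):
        adult, _ = fixture_models
        rng = np.random.default_rng(4)
        a = cc.TransportScaling(dict(zip(CANONICAL_KEYS, rng.uniform(0.5, 1.5, 13))))
        b = cc.TransportScaling(dict(zip(CANONICAL_KEYS, rng.uniform(0.5, 1.5, 13))))
        two_step = cc.apply_scaling(cc.apply_scaling(adult, a), b)
        one_step = cc.apply_scaling(adult, a.compose(b))
        for name in adult.params:
            assert two_step.params[name] == pytest.approx(one_step.params[name],
                                                          rel=1e-12)

    @pytest.mark.parametrize("bad", [
        {k: 1.0 for k in CANONICAL_KEYS[:-1]},                    # missing key
        {**{k: 1.0 for k in CANONICAL_KEYS}, "GKr": -0.5},        # nonpositive
        {**{k: 1.0 for k in CANONICAL_KEYS}, "GKr": 0.0},
    ])
    def test_invalid_scalings_rejected_with_key_name(self, bad):
        with pytest.raises(ValidationError):
            cc.TransportScaling(bad)


class TestVariants:
    def test_empty_table_is_identity(self, fixture_models):
        adult, _ = fixture_models
        assert cc.apply_variant(adult, cc.VariantTable(())).params == adult.params

    def test_factor_one_entries_bit_identical(self, fixture_models):
        adult, _ = fixture_models
        out = cc.apply_variant(adult, cc.VariantTable((("GKs", 1.0), ("KNCX", 1.0))))
        assert out.params == adult.params

    def test_apply_then_invert_returns_baseline(self, fixture_models):
        adult, _ = fixture_models
        table = cc.VariantTable((("KSERCA", 0.5), ("KNCX", 1.75), ("GKs", 0.5)))
        back = cc.apply_variant(cc.apply_variant(adult, table), table.inverted())
        for name in adult.params:
            assert back.params[name] == pytest.approx(adult.params[name], rel=1e-12)

    def test_unknown_parameter_lists_valid_names(self, fixture_models):
        adult, _ = fixture_models
        with pytest.raises(ValidationError, match="valid names"):
            cc.apply_variant(adult, cc.VariantTable((("GNonsense", 0.5),)))

    def test_failing_heart_variant_prolongs_ap_and_reduces_cat(self, fixture_models):
        """Reduced SR uptake + NCX upregulation + IKs downregulation should
        lengthen the AP and shrink the Ca transient at 1 Hz."""
        adult, _ = fixture_models
        hf = cc.apply_variant(adult, cc.VariantTable(
            (("KSERCA", 0.5), ("KNCX", 1.75), ("GKs", 0.5))))
        proto = cc.ProtocolSpec("pace1", "paced", 1.0, duration_s=30.0)
        _, beat_base = cc.run_protocol(adult, proto)
        _, beat_hf = cc.run_protocol(hf, proto)
        f0, _ = cc.extract_features(beat_base)
        f1, _ = cc.extract_features(beat_hf)
        assert f1["APD90"] > f0["APD90"]
        assert f1["CaTA"] < f0["CaTA"]


class TestIntegrate:
    def test_120s_paced_trace_has_120_stimuli(self, fixture_models):
        adult, _ = fixture_models
        proto = cc.ProtocolSpec("pace1", "paced", 1.0, duration_s=120.0)
        trace = cc.integrate(adult, proto)
        assert len(trace.stim_times) == 120
        assert trace.t[-1] == pytest.approx(120_000.0)

    def test_zeroed_stimulus_rests_with_no_beats(self, fixture_models):
        adult, _ = fixture_models
        proto = cc.ProtocolSpec("rest", "paced", 1.0, duration_s=10.0,
                                stim_amplitude=0.0)
        trace = cc.integrate(adult, proto)
        assert trace.v.max() - trace.v.min() < 5.0
        assert cc.segment_last_beat(trace, "paced") is None

    def test_repeat_integration_identical(self, fixture_models):
        adult, _ = fixture_models
        proto = cc.ProtocolSpec("pace1", "paced", 1.0, duration_s=20.0)
        a = cc.integrate(adult, proto)
        b = cc.integrate(adult, proto)
        assert np.max(np.abs(a.v - b.v)) == 0.0
        assert np.max(np.abs(a.cai - b.cai)) == 0.0

    def test_spontaneous_protocol_requires_capability(self, fixture_models):
        adult, _ = fixture_models
        with pytest.raises(ValidationError):
            cc.integrate(adult, cc.ProtocolSpec("s", "spontaneous", duration_s=5.0))

    def test_adaptive_integrator_matches_scipy_lsoda(self, fixture_models):
        """The compiled Dormand-Prince path agrees with scipy's LSODA."""
        adult, _ = fixture_models
        proto = cc.ProtocolSpec("pace1", "paced", 1.0, duration_s=3.0)
        fast = cc.integrate(adult, proto)
        ref = cc.integrate(adult, proto, method="scipy")
        # compare away from the upstroke where tiny timing shifts dominate
        mask = np.abs(np.gradient(ref.v, ref.t)) < 5.0
        assert np.max(np.abs(fast.v[mask] - ref.v[mask])) < 1.0
        assert np.max(np.abs(fast.cai - ref.cai)) < 0.02


class TestFixtureContracts:
    def test_both_fixtures_expose_identical_pathway_keys(self, fixture_models):
        adult, ipsc = fixture_models
        assert set(adult.transport_map) == set(ipsc.transport_map) == set(
            CANONICAL_KEYS)

    def test_adult_baseline_phenotype(self, fixture_models):
        adult, _ = fixture_models
        proto = cc.ProtocolSpec("pace1", "paced", 1.0, duration_s=30.0)
        _, beat = cc.run_protocol(adult, proto)
        f, flags = cc.extract_features(beat)
        assert not flags
        assert -88 <= f["Vrest"] <= -82
        assert 200 <= f["APD90"] <= 350

    def test_spontaneous_fixture_self_oscillates(self, fixture_models):
        _, ipsc = fixture_models
        trace = cc.integrate(ipsc, cc.ProtocolSpec("s", "spontaneous",
                                                   duration_s=10.0))
        from crosscell.protocols import detect_upstrokes
        assert len(detect_upstrokes(trace.t, trace.v)) >= 3

    def test_spontaneous_rate_and_diastolic_potential(self, fixture_models):
        adult, ipsc = fixture_models
        _, beat = cc.run_protocol(ipsc, cc.ProtocolSpec("s", "spontaneous",
                                                        duration_s=30.0))
        f, _ = cc.extract_features(beat)
        assert 0.5 <= f["rate"] <= 1.5
        assert f["Vrest"] > -82  # less negative than the adult fixture

    @pytest.mark.parametrize("which", ["adult", "ipsc"])
    def test_apd90_monotone_in_gkr_multiplier(self, fixture_models, which):
        adult, ipsc = fixture_models
        model = adult if which == "adult" else ipsc
        proto = (cc.ProtocolSpec("p", "paced", 1.0, duration_s=25.0)
                 if which == "adult"
                 else cc.ProtocolSpec("s", "spontaneous", duration_s=25.0))
        apds = []
        for mult in (0.5, 0.75, 1.0, 1.25, 1.5):
            cell = cc.apply_scaling(model,
                                    cc.TransportScaling.from_partial(GKr=mult))
            _, beat = cc.run_protocol(cell, proto)
            f, _ = cc.extract_features(beat)
            apds.append(f["APD90"])
        assert all(a >= b for a, b in zip(apds, apds[1:]))

    @pytest.mark.parametrize("which", ["adult", "ipsc"])
    def test_cata_decreases_with_gcal_block(self, fixture_models, which):
        adult, ipsc = fixture_models
        model = adult if which == "adult" else ipsc
        proto = (cc.ProtocolSpec("p", "paced", 1.0, duration_s=25.0)
                 if which == "adult"
                 else cc.ProtocolSpec("s", "spontaneous", duration_s=25.0))
        catas = []
        for mult in (0.5, 1.0, 1.5):
            cell = cc.apply_scaling(model,
                                    cc.TransportScaling.from_partial(GCaL=mult))
            _, beat = cc.run_protocol(cell, proto)
            f, _ = cc.extract_features(beat)
            catas.append(f["CaTA"])
        assert catas[0] < catas[1] < catas[2]
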