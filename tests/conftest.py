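import numpy as np
import pandas as pd
import pytest

import crosscell as cc

# problem sizes for the expensive end-to-end fixtures; the reduced fixture
# models reach steady state well before 30 s (verified by the steady-state
# diagnostic test), so population runs use shortened protocols
POP_DURATION_S = 30.0
FAST_KW = dict(rtol=1e-5, atol=1e-7, dt_out=1.0)


@pytest.fixture(scope="session")
def fixture_models():
    return cc.make_fixture_models()


@pytest.fixture(scope="session")
def small_table():
    return cc.draw_scale_factors(cc.PopulationConfig(n_cells=40, seed=7))


@pytest.fixture(scope="session")
def small_paired_runs(fixture_models, small_table):
    """40-cell paired feature runs over the 8 non-K conditions (fast)."""
    adult, ipsc = fixture_models
    sprotos = [p for p in cc.standard_protocol_set("ipsc-like", POP_DURATION_S)
               if p.protocol_id not in ("KHigh", "KLow")]
    tprotos = [p for p in cc.standard_protocol_set("adult-like", POP_DURATION_S)
               if p.protocol_id == "pace1"]
    src = cc.simulate_population_features(ipsc, small_table, sprotos, **FAST_KW)
    tgt = cc.simulate_population_features(adult, small_table, tprotos, **FAST_KW)
    return src, tgt


@pytest.fixture(scope="session")
def paired_600_runs(fixture_models):
    """600-cell paired populations over the full 10-condition standard set."""
    adult, ipsc = fixture_models
    table = cc.draw_scale_factors(cc.PopulationConfig(n_cells=600, seed=1))
    sprotos = cc.standard_protocol_set("ipsc-like", POP_DURATION_S)
    tprotos = [p for p in cc.standard_protocol_set("adult-like", POP_DURATION_S)
               if p.protocol_id == "pace1"]
    src = cc.simulate_population_features(ipsc, table, sprotos, **FAST_KW)
    tgt = cc.simulate_population_features(adult, table, tprotos, **FAST_KW)
    return table, src, tgt


@pytest.fixture(scope="session")
def cross_model_600(paired_600_runs):
    _, src, tgt = paired_600_runs
    return cc.build_cross_model(src, tgt, "pace1", seed=2)


def make_triangular_beat(vrest=-80.0, vpeak=40.0, apd_total=400.0,
                         tail=200.0, dt=1.0, t0=0.0):
    """Triangular AP: instant rise to the peak at t0, linear fall over
    apd_total ms, then flat at rest; paired with a resting Ca trace."""
    t = np.arange(t0, t0 + apd_total + tail + dt / 2, dt)
    v = np.where(t - t0 <= apd_total,
                 vpeak - (vpeak - vrest) * (t - t0) / apd_total, vrest)
    ca = np.full_like(t, 0.1)
    return cc.BeatSegment(t=t, v=v, cai=ca, upstroke_time=t0,
                          cycle_length_ms=apd_total + tail, mode="paced",
                          stim_onset=None)


def make_exponential_ca_beat(ca_rest=0.1, amp=0.5, tau=200.0,
                             pre=100.0, total=1500.0, dt=0.1):
    """Exponential Ca transient (instant rise at t=0) on a triangular AP."""
    t = np.arange(-round(pre / dt), round(total / dt) + 1) * dt  # hits t=0 exactly
    ca = np.where(t < 0, ca_rest, ca_rest + amp * np.exp(-np.maximum(t, 0) / tau))
    v = np.where((t >= 0) & (t <= 300), 30.0 - 110.0 * t / 300.0, -80.0)
    return cc.BeatSegment(t=t, v=v, cai=ca, upstroke_time=0.0,
                          cycle_length_ms=total + pre, mode="paced",
                          stim_onset=None)


def latent_factor_data(n_rows=500, n_latent=3, px=10, py=4, noise=0.05, seed=0):
    """X = T P' (exact factor structure), Y = T Q' + observation noise.

    Keeping X noise-free makes the latent dimension identifiable: with X
    noise, PLSR keeps gaining held-out accuracy beyond the true dimension
    by averaging out predictor noise (attenuation correction).
    """
    rng = np.random.default_rng(seed)
    t = rng.normal(size=(n_rows, n_latent))
    x = t @ rng.normal(size=(n_latent, px))
    y = t @ rng.normal(size=(n_latent, py)) + noise * rng.normal(size=(n_rows, py))
    xdf = pd.DataFrame(x, columns=[f"x{i}" for i in range(px)])
    ydf = pd.DataFrame(y, columns=[f"y{i}" for i in range(py)])
    return xdf, ydf


NO_LOG = staticmethod(lambda c: False)
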