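"""Unit and property tests for the generative network models."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tebench as tb
from tebench.models import BURN_IN, ModelSpec


def small_spec(model, **kw):
    defaults = dict(n_samples=600, n_trials=3, n_datasets=2, rng_seed=42)
    defaults.update(kw)
    return ModelSpec(model, **defaults)


class TestSurrogateInput:
    def test_seeded_determinism_and_normalization(self):
        a = tb.generate_surrogate_input(3000, 1250, seed=1)
        b = tb.generate_surrogate_input(3000, 1250, seed=1)
        np.testing.assert_array_equal(a, b)
        assert abs(a.mean()) < 1e-12
        assert abs(a.var() - 1.0) < 1e-6

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            tb.generate_surrogate_input(1, 1250, seed=0)
        with pytest.raises(ValueError):
            tb.generate_surrogate_input(100, -5, seed=0)

    def test_spectral_peak_near_10_hz(self):
        """The in-band (8-12 Hz) periodogram maximum sits at ~10 Hz in
        the median over seeds."""
        peaks = []
        for seed in range(100):
            x = tb.generate_surrogate_input(3000, 1250, seed=seed)
            spec = np.abs(np.fft.rfft(x)) ** 2
            freqs = np.fft.rfftfreq(3000, 1 / 1250)
            band = (freqs >= 8) & (freqs <= 12)
            peaks.append(freqs[band][np.argmax(spec[band])])
        assert abs(np.median(peaks) - 10.0) < 1.0


class TestKus:
    def test_impulse_response_follows_coupling(self):
        """With noise off, a unit impulse on the input appears on channel
        2 scaled by gamma exactly 4 samples later, and nowhere else."""
        spec = small_spec("kus", noise_fraction=0.0, n_trials=1, n_datasets=1)
        d = np.zeros(spec.n_samples + BURN_IN)
        j = 100
        d[BURN_IN + j] = 1.0
        ens, _ = tb.simulate_kus(spec, input_signal=d)
        ch1 = ens.values[0, 0, 0]
        ch2 = ens.values[0, 0, 1]
        assert ch1[j] == 1.0
        assert ch2[j + 4] == pytest.approx(0.4)
        mask = np.ones_like(ch2, dtype=bool)
        mask[j + 4] = False
        assert np.all(ch2[mask] == 0.0)

    def test_input_too_short_rejected(self):
        spec = small_spec("kus")
        with pytest.raises(ValueError, match="input_signal"):
            tb.simulate_kus(spec, input_signal=np.zeros(spec.n_samples))

    def test_zero_noise_unit_input_chain(self):
        """gamma scaling cascades: ch3 = gamma^2 * input lag 8."""
        spec = small_spec("kus", noise_fraction=0.0, n_trials=1, n_datasets=1)
        d = np.zeros(spec.n_samples + BURN_IN)
        d[BURN_IN + 50] = 1.0
        ens, _ = tb.simulate_kus(spec, input_signal=d)
        assert ens.values[0, 0, 2, 58] == pytest.approx(0.4**2)
        assert ens.values[0, 0, 3, 62] == pytest.approx(0.4**2)
        # channel 5 is pure noise, hence zero here
        assert np.all(ens.values[0, 0, 4] == 0.0)

    def test_lag4_cross_covariance_dominates(self):
        spec = ModelSpec("kus", n_samples=3000, n_trials=2, n_datasets=1,
                         rng_seed=7)
        ens, _ = tb.simulate_kus(spec)
        x1 = ens.values[0, 0, 0] - ens.values[0, 0, 0].mean()
        x2 = ens.values[0, 0, 1] - ens.values[0, 0, 1].mean()
        cc = [np.dot(x1[:-lag], x2[lag:]) for lag in range(1, 13)]
        assert np.argmax(cc) + 1 == 4

    def test_graph_structure(self):
        _, g = tb.simulate_kus(small_spec("kus", n_samples=10, n_trials=1,
                                          n_datasets=1))
        assert g.direct_pairs() == (("X1", "X2"), ("X2", "X3"), ("X2", "X4"))
        assert set(g.indirect_pairs()) == {("X1", "X3"), ("X1", "X4")}
        assert g.delay_of("X2", "X4") == 8


class TestLogisticMap:
    def test_fixed_point_zero(self):
        assert tb.logistic_map(0.0, 3.576, 5) == 0.0

    def test_single_and_double_iteration(self):
        assert tb.logistic_map(0.5, 3.576, 1) == pytest.approx(0.894)
        # composing once more: 3.576 * 0.894 * 0.106
        assert tb.logistic_map(0.5, 3.576, 2) == pytest.approx(
            3.576 * 0.894 * (1 - 0.894))

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            tb.logistic_map(1.2, 3.576, 1)
        with pytest.raises(ValueError):
            tb.logistic_map(0.5, 4.5, 1)

    @given(st.floats(0, 1), st.integers(1, 5))
    def test_stays_in_unit_interval(self, x, n):
        assert 0.0 <= tb.logistic_map(x, 3.576, n) <= 1.0


class TestSigmoid:
    def test_inflection_and_asymptotes(self):
        assert tb.sigmoid_transfer(0.0, 6) == 0.0
        assert tb.sigmoid_transfer(1e3, 6) == pytest.approx(1.0)
        assert tb.sigmoid_transfer(-1e3, 6) == pytest.approx(-1.0)

    def test_value_equals_tanh_form(self):
        assert tb.sigmoid_transfer(0.4, 6) == pytest.approx(np.tanh(1.2))


class TestClmm:
    def test_values_confined_to_unit_interval(self):
        ens, _ = tb.simulate_clmm(small_spec("clmm"))
        assert ens.values.min() >= 0.0
        assert ens.values.max() <= 1.0

    def test_branch_to_sink_delays(self):
        _, g = tb.simulate_clmm(small_spec("clmm", n_samples=10, n_trials=1,
                                           n_datasets=1))
        assert g.delay_of("X12", "Xi") == 2
        assert g.delay_of("X22", "Xi") == 6
        assert g.delay_of("X32", "Xi") == 8

    def test_constant_input_noise_free_fixed_value(self):
        """With V = 0 the rescaling cancels gamma and X12 settles at
        f(0.5) = 0.894."""
        spec = small_spec("clmm", noise_fraction=0.0, n_trials=1,
                          n_datasets=1)
        const = np.full(spec.n_samples + BURN_IN, 0.5)
        ens, _ = tb.simulate_clmm(spec, inputs={1: const, 2: const, 3: const})
        x12 = ens.values[0, 0, ens.channels.index("X12")]
        assert np.allclose(x12, 0.894)

    def test_thirteen_channels_partition(self):
        _, g = tb.simulate_clmm(small_spec("clmm", n_samples=10, n_trials=1,
                                           n_datasets=1))
        assert len(g.nodes) == 13
        assert len(g.direct_edges) == 15
        assert len(g.indirect_pairs()) == 9


class TestCsem:
    def test_noise_free_driven_channels_in_sigmoid_range(self):
        ens, _ = tb.simulate_csem(small_spec("csem", noise_fraction=0.0))
        driven = ens.values[:, :, 1:4, :]
        assert np.all(np.abs(driven) < 1.0)

    def test_vanishing_input_gives_zero_channels(self):
        """sigmoid(0) = 0, so without noise the whole cascade dies out
        when nothing is transmitted (gamma acts only on zero input)."""
        spec = small_spec("csem", noise_fraction=0.0, n_trials=1,
                          n_datasets=1)
        ens, _ = tb.simulate_csem(spec)
        # X2..X4 are deterministic functions of X1; replacing X1 by its
        # own dynamics with zero noise keeps them inside (-1, 1) and a
        # zero X1 would null them; verify via the transfer function
        assert tb.sigmoid_transfer(0.0, spec.a_sigmoid) == 0.0

    def test_lag6_crosscorrelation_maximal(self):
        spec = ModelSpec("csem", n_samples=3000, n_trials=2, n_datasets=1,
                         rng_seed=9)
        ens, _ = tb.simulate_csem(spec)
        x1 = ens.values[0, 0, 0] - ens.values[0, 0, 0].mean()
        x2 = ens.values[0, 0, 1] - ens.values[0, 0, 1].mean()
        cc = [np.dot(x1[:-lag], x2[lag:]) for lag in range(1, 21)]
        assert np.argmax(cc) + 1 == 6

    def test_graph_structure(self):
        _, g = tb.simulate_csem(small_spec("csem", n_samples=10, n_trials=1,
                                           n_datasets=1))
        assert set(g.direct_pairs()) == {("X1", "X2"), ("X2", "X3"),
                                         ("X2", "X4"), ("X3", "X4")}
        assert set(g.indirect_pairs()) == {("X1", "X3"), ("X1", "X4")}


@pytest.mark.parametrize("model", ["kus", "clmm", "csem"])
class TestEnsembleInvariants:
    def test_determinism(self, model):
        e1, _ = tb.simulate(small_spec(model))
        e2, _ = tb.simulate(small_spec(model))
        np.testing.assert_array_equal(e1.values, e2.values)

    def test_trials_are_independent_draws(self, model):
        ens, _ = tb.simulate(small_spec(model))
        # noise channel (kus/csem: X5; clmm: the branch-1 input)
        ch = 4 if model in ("kus", "csem") else 0
        t0 = ens.values[0, 0, ch]
        t1 = ens.values[0, 1, ch]
        r = np.corrcoef(t0, t1)[0, 1]
        assert abs(r) < 0.2

    def test_graph_partition_covers_all_ordered_pairs(self, model):
        _, g = tb.simulate(small_spec(model, n_samples=10, n_trials=1,
                                      n_datasets=1))
        n = len(g.nodes)
        direct = set(g.direct_pairs())
        indirect = set(g.indirect_pairs())
        unconnected = set(g.unconnected_pairs())
        assert not direct & indirect
        assert not direct & unconnected
        assert not indirect & unconnected
        assert len(direct | indirect | unconnected) == n * (n - 1)


@pytest.mark.parametrize("model", ["kus", "csem"])
def test_noise_variance_tracks_noise_fraction(model):
    """The pure-noise channel carries internal + external noise, each at
    noise_fraction of the reference variance."""
    spec = ModelSpec(model, n_samples=3000, n_trials=4, n_datasets=1,
                     rng_seed=3)
    ens, _ = tb.simulate(spec)
    # both models drive with a unit-variance input by construction
    ref_var = 1.0
    noise_var = ens.values[0, :, 4, :].var()
    expected = 2 * spec.noise_fraction * ref_var
    assert noise_var == pytest.approx(expected, rel=0.15)


def test_strict_literal_noise_mode_changes_scale():
    base = ModelSpec("csem", n_samples=500, n_trials=1, n_datasets=1,
                     rng_seed=1)
    literal = ModelSpec("csem", n_samples=500, n_trials=1, n_datasets=1,
                        rng_seed=1, strict_literal_noise=True)
    v1 = tb.simulate(base)[0].values[0, 0, 4].var()
    v2 = tb.simulate(literal)[0].values[0, 0, 4].var()
    assert not np.isclose(v1, v2)


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec("nope")
    with pytest.raises(ValueError):
        ModelSpec("kus", fs=-1)
    with pytest.raises(ValueError):
        ModelSpec("kus", noise_fraction=-0.1)
    with pytest.raises(ValueError):
        ModelSpec("kus", gamma=0.0)
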