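import numpy as np
import pytest

import nocieeg as ng
from nocieeg.amif import EntropySpec, QuantizedSeries


def brute_force_amif(symbols: np.ndarray, tau: int, q: float | None) -> float:
    """Literal nested-sum evaluation of the Shannon/Rényi AMIF definitions."""
    a, b = (symbols, symbols) if tau == 0 else (symbols[:-tau], symbols[tau:])
    P = np.zeros((32, 32))
    for i, j in zip(a, b):
        P[i, j] += 1
    P /= P.sum()
    px, py = P.sum(axis=1), P.sum(axis=0)
    if q is None:  # Shannon
        return sum(P[i, j] * np.log2(P[i, j] / (px[i] * py[j]))
                   for i in range(32) for j in range(32) if P[i, j] > 0)
    # each term P^q / (px^{q-1} py^{q-1}) evaluated via its logarithm so the
    # literal formula stays accurate at extreme orders (q = 100)
    s = sum(np.exp(q * np.log(P[i, j])
                   - (q - 1) * (np.log(px[i]) + np.log(py[j])))
            for i in range(32) for j in range(32) if P[i, j] > 0)
    return np.log2(s) / (q - 1)


def uniform_symbols(repeats: int = 8) -> QuantizedSeries:
    return QuantizedSeries(np.tile(np.arange(32), repeats),
                           np.linspace(0, 1, 33))


class TestQuantize:
    def test_ramp_equal_occupancy(self):
        sym = ng.quantize(np.arange(0.0, 32.0, 0.5))  # 2 samples per bin
        counts = np.bincount(sym.symbols, minlength=32)
        assert np.all(counts == 2)

    def test_constant_degenerate(self):
        sym = ng.quantize(np.full(100, 3.3))
        assert sym.degenerate and np.all(sym.symbols == 0)

    def test_max_maps_to_last_bin(self):
        sym = ng.quantize(np.linspace(0, 1, 50))
        assert sym.symbols[-1] == 31

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ng.quantize(np.array([0.0, np.nan, 1.0]))

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(500)
        s1 = ng.quantize(x)
        s2 = ng.quantize(3.7 * x - 11.0)
        np.testing.assert_array_equal(s1.symbols, s2.symbols)


class TestJointDistribution:
    def test_tau_zero_diagonal(self, rng):
        sym = ng.quantize(rng.standard_normal(200))
        joint, px, py = ng.joint_distribution(sym, 0)
        assert np.all(joint[~np.eye(32, dtype=bool)] == 0)
        np.testing.assert_allclose(np.diag(joint), px)

    def test_normalization(self, rng):
        sym = ng.quantize(rng.standard_normal(200))
        for tau in (0, 1, 17):
            joint, _, _ = ng.joint_distribution(sym, tau)
            assert joint.sum() == pytest.approx(1.0)

    def test_periodic_sequence(self):
        sym = QuantizedSeries(np.tile([0, 1], 50), np.linspace(0, 1, 33))
        joint, _, _ = ng.joint_distribution(sym, 1)
        mass = {(i, j): joint[i, j] for i in range(32) for j in range(32)
                if joint[i, j] > 0}
        assert set(mass) == {(0, 1), (1, 0)}

    def test_lag_too_large(self, rng):
        sym = ng.quantize(rng.standard_normal(10))
        with pytest.raises(ValueError):
            ng.joint_distribution(sym, 10)


class TestShannonAMIF:
    def test_uniform_ceiling_five_bits(self):
        curve = ng.amif_shannon(uniform_symbols(), tau_max=3)
        assert curve.values[0] == pytest.approx(5.0, abs=1e-12)

    def test_independent_symbols_low_mi(self, rng):
        sym = ng.quantize(rng.standard_normal(20000))
        curve = ng.amif_shannon(sym, tau_max=1)
        assert curve.values[1] < 0.2

    def test_period_two_repetition(self):
        sym = QuantizedSeries(np.tile([0, 1], 100), np.linspace(0, 1, 33))
        curve = ng.amif_shannon(sym, tau_max=2)
        assert curve.values[2] == pytest.approx(curve.values[0], abs=1e-9)

    def test_degenerate_series_warns_nan(self):
        sym = ng.quantize(np.full(100, 2.0))
        with pytest.warns(RuntimeWarning):
            curve = ng.amif_shannon(sym, tau_max=3)
        assert np.all(np.isnan(curve.values))

    def test_nonnegative_and_bounded_by_entropy(self, rng):
        sym = ng.quantize(rng.standard_normal(1000))
        curve = ng.amif_shannon(sym, tau_max=30)
        assert np.all(curve.values >= -1e-12)
        assert np.all(curve.values <= curve.values[0] + 1e-9)
        assert curve.values[0] <= 5.0 + 1e-12


class TestRenyiAMIF:
    def test_q_one_is_error(self, rng):
        sym = ng.quantize(rng.standard_normal(100))
        with pytest.raises(ValueError, match="Shannon"):
            ng.amif_renyi(sym, 1.0, 5)

    def test_uniform_ceiling_any_q(self):
        for q in (0.1, 0.5, 2.0, 30.0, 100.0):
            curve = ng.amif_renyi(uniform_symbols(), q, 2)
            assert curve.values[0] == pytest.approx(5.0, abs=1e-9), q

    def test_shannon_limit(self, rng):
        sym = ng.quantize(rng.standard_normal(3000))
        sh = ng.amif_shannon(sym, 50).values
        for q in (1.001, 0.999):
            re = ng.amif_renyi(sym, q, 50).values
            assert np.max(np.abs(re - sh)) <= 1e-2

    @pytest.mark.parametrize("q", [None, 0.1, 0.5, 2.0, 30.0, 100.0])
    def test_oracle_equivalence_small_toys(self, q, rng):
        for _ in range(5):
            n = int(rng.integers(20, 51))
            sym = ng.quantize(rng.standard_normal(n))
            taus = range(4)
            if q is None:
                vals = ng.amif_shannon(sym, 3).values
            else:
                vals = ng.amif_renyi(sym, q, 3).values
            for tau in taus:
                assert vals[tau] == pytest.approx(
                    brute_force_amif(sym.symbols, tau, q), abs=1e-12)


class TestInvariances:
    def test_time_reversal_symmetry(self, rng):
        sym = ng.quantize(rng.standard_normal(500))
        rev = QuantizedSeries(sym.symbols[::-1].copy(), sym.bin_edges)
        for q in (None, 0.5, 2.0):
            if q is None:
                a = ng.amif_shannon(sym, 10).values
                b = ng.amif_shannon(rev, 10).values
            else:
                a = ng.amif_renyi(sym, q, 10).values
                b = ng.amif_renyi(rev, q, 10).values
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_affine_amplitude_invariance(self, rng):
        x = rng.standard_normal(800)
        a = ng.amif_shannon(ng.quantize(x), 10).values
        b = ng.amif_shannon(ng.quantize(-2.5 * x + 4.0), 10).values
        # sign flip reverses bin order but AMIF depends only on co-occurrence
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestNormalize:
    def test_normalized_at_zero(self, rng):
        curve = ng.amif_shannon(ng.quantize(rng.standard_normal(500)), 10)
        ncurve = ng.normalize(curve)
        assert ncurve.values[0] == pytest.approx(1.0)
        assert ncurve.normalized

    def test_idempotent(self, rng):
        curve = ng.amif_shannon(ng.quantize(rng.standard_normal(500)), 10)
        n1 = ng.normalize(curve)
        n2 = ng.normalize(n1)
        np.testing.assert_array_equal(n1.values, n2.values)

    def test_uniform_normalized_is_one(self):
        curve = ng.amif_shannon(uniform_symbols(), 2)
        assert ng.normalize(curve).values[0] == pytest.approx(1.0)
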