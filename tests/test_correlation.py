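"""Transfer entropy and Gaussian-convolution correlation estimators."""

import numpy as np
import pytest

import spikeplex as sp
from spikeplex.correlation import CCParams, TEParams, _te_all_pairs


def brute_force_te(s_i, s_j, k, l, d):
    """Independent oracle: dictionary-based plug-in TE over explicit word
    tuples (no integer encoding, no histogram tricks)."""
    from collections import Counter
    from math import log2

    t_len = len(s_i)
    t_lo = max(k - 1, d + l - 2, 0)
    joint = Counter()
    for t in range(t_lo, t_len - 1):
        i_next = s_i[t + 1]
        i_word = tuple(s_i[t - m] for m in range(k))
        j_word = tuple(s_j[t + 1 - d - m] for m in range(l))
        joint[(i_next, i_word, j_word)] += 1
    n = sum(joint.values())
    c_b = Counter()
    c_bg = Counter()
    c_ab = Counter()
    for (a, b, g), c in joint.items():
        c_b[b] += c
        c_bg[(b, g)] += c
        c_ab[(a, b)] += c
    te = 0.0
    for (a, b, g), c in joint.items():
        te += c * log2(c * c_b[b] / (c_bg[(b, g)] * c_ab[(a, b)]))
    return te / n


class TestTransferEntropy:
    @pytest.mark.parametrize("k,l,d", [(1, 1, 0), (2, 3, 1), (5, 5, 0), (5, 5, 7)])
    def test_matches_brute_force_oracle(self, k, l, d):
        rng = np.random.default_rng(10 * k + l + d)
        s_i = (rng.random(2000) < 0.15).astype(np.uint8)
        s_j = (rng.random(2000) < 0.15).astype(np.uint8)
        fast = sp.transfer_entropy(s_i, s_j, k=k, l=l, d=d)
        slow = brute_force_te(s_i.tolist(), s_j.tolist(), k, l, d)
        assert fast == pytest.approx(slow, abs=1e-12)

    def test_constant_source_gives_zero(self):
        rng = np.random.default_rng(0)
        s_i = (rng.random(5000) < 0.1).astype(np.uint8)
        s_j = np.zeros(5000, dtype=np.uint8)
        assert sp.transfer_entropy(s_i, s_j, k=3, l=3, d=2) == 0.0

    def test_copy_channel_approaches_one_bit(self):
        """A Bernoulli(1/2) source copied into the target with delay d0 has
        channel capacity 1 bit; the plug-in estimate on 1e5 bins matches."""
        rng = np.random.default_rng(7)
        d0 = 4
        s_j = rng.integers(0, 2, 100_000).astype(np.uint8)
        s_i = np.zeros(100_000, dtype=np.uint8)
        s_i[d0:] = s_j[:-d0]  # s_i(t+1) = s_j(t+1-d0)
        te = sp.transfer_entropy(s_i, s_j, k=1, l=1, d=d0)
        assert te == pytest.approx(1.0, abs=0.05)

    def test_independent_trains_near_zero(self):
        rng = np.random.default_rng(3)
        a = (rng.random(100_000) < 0.1).astype(np.uint8)
        b = (rng.random(100_000) < 0.1).astype(np.uint8)
        assert sp.transfer_entropy(a, b, k=5, l=5, d=3) < 0.01

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            sp.transfer_entropy(np.zeros(10), np.zeros(11))

    def test_shuffling_destroys_dependence(self):
        """A seeded bin permutation of the source drives TE to a small
        fraction of the copy-channel value."""
        rng = np.random.default_rng(11)
        d0 = 3
        s_j = rng.integers(0, 2, 50_000).astype(np.uint8)
        s_i = np.zeros(50_000, dtype=np.uint8)
        s_i[d0:] = s_j[:-d0]
        true_te = sp.transfer_entropy(s_i, s_j, k=1, l=1, d=d0)
        shuffled = [
            sp.transfer_entropy(s_i, rng.permutation(s_j), k=1, l=1, d=d0)
            for _ in range(20)
        ]
        assert np.quantile(shuffled, 0.95) < 0.1 * true_te


class TestHoteMax:
    def test_recovers_embedded_delay(self):
        rng = np.random.default_rng(5)
        d0 = 7
        s_j = (rng.random(30_000) < 0.3).astype(np.uint8)
        s_i = np.zeros(30_000, dtype=np.uint8)
        s_i[d0:] = s_j[:-d0]
        val, best_d = sp.hote_max(s_i, s_j, k=1, l=1, d_max=15)
        assert best_d == d0
        assert val >= sp.transfer_entropy(s_i, s_j, k=1, l=1, d=3)

    def test_dmax_zero_equals_single_delay(self):
        rng = np.random.default_rng(6)
        s_i = (rng.random(3000) < 0.1).astype(np.uint8)
        s_j = (rng.random(3000) < 0.1).astype(np.uint8)
        val, best_d = sp.hote_max(s_i, s_j, k=2, l=2, d_max=0)
        assert best_d == 0
        assert val == sp.transfer_entropy(s_i, s_j, k=2, l=2, d=0)

    def test_max_dominates_every_delay(self):
        rng = np.random.default_rng(8)
        s_i = (rng.random(4000) < 0.2).astype(np.uint8)
        s_j = (rng.random(4000) < 0.2).astype(np.uint8)
        val, _ = sp.hote_max(s_i, s_j, k=2, l=2, d_max=10)
        for d in range(11):
            assert val >= sp.transfer_entropy(s_i, s_j, k=2, l=2, d=d) - 1e-15


class TestAllPairsKernel:
    def test_kernel_agrees_with_single_pair_path(self):
        """The sparse histogram kernel must reproduce the plain numpy
        estimator exactly, including arg-max delays."""
        rng = np.random.default_rng(2)
        binned = (rng.random((5, 2500)) < 0.08).astype(np.uint8)
        values, delays = _te_all_pairs(binned, 5, 5, 12)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                v, d = sp.hote_max(binned[i], binned[j], k=5, l=5, d_max=12)
                assert values[i, j] == pytest.approx(v, abs=1e-12)
                assert delays[i, j] == d


class TestGaussianConvolve:
    def test_single_spike_peak_at_spike_time(self):
        s = np.zeros(2000)
        s[700] = 1
        x = sp.gaussian_convolve(s, sigma=0.2)
        assert np.argmax(x) == 700
        assert x[700] == pytest.approx(1.0 / (0.2 * np.sqrt(2 * np.pi)), rel=1e-6)

    def test_zero_train_zero_signal(self):
        assert np.all(sp.gaussian_convolve(np.zeros(500)) == 0)

    def test_kernel_normalisation_preserves_spike_count(self):
        rng = np.random.default_rng(4)
        s = np.zeros(5000)
        s[rng.choice(np.arange(1800, 3200), 10, replace=False)] = 1
        x = sp.gaussian_convolve(s, sigma=0.2)
        assert x.sum() * 0.001 == pytest.approx(10.0, rel=1e-3)

    def test_output_length_matches_input(self):
        assert len(sp.gaussian_convolve(np.zeros(1234))) == 1234

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            sp.gaussian_convolve(np.zeros(10), sigma=0.0)


class TestDelayedPearson:
    def test_shifted_copy_perfect_correlation(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=600)
        x_j = base
        x_i = np.empty(600)
        x_i[5:] = base[:-5]
        x_i[:5] = rng.normal(size=5)
        assert sp.delayed_pearson(x_i, x_j, 5) == pytest.approx(1.0)
        assert sp.delayed_pearson(-x_i, x_j, 5) == pytest.approx(-1.0)

    def test_hand_computed_toy(self):
        # ranks reversed: exact -1
        assert sp.delayed_pearson([1, 2, 3, 4], [4, 3, 2, 1], 0) == pytest.approx(-1.0)

    def test_constant_overlap_undefined(self):
        assert np.isnan(sp.delayed_pearson(np.ones(50), np.arange(50.0), 3))


class TestCorrelationMatrix:
    def test_te_matrix_contract(self):
        rng = np.random.default_rng(1)
        binned = (rng.random((4, 2000)) < 0.1).astype(np.uint8)
        m = sp.correlation_matrix(binned, "te", TEParams(d_max=5))
        assert np.all(np.diag(m.values) == 0)
        assert np.all(m.values >= 0)
        assert np.count_nonzero(m.values) <= 4 * 3

    def test_cc_bounds_and_diag(self):
        rng = np.random.default_rng(2)
        binned = (rng.random((4, 4000)) < 0.05).astype(np.uint8)
        m = sp.correlation_matrix(binned, "cc", CCParams(d_max=10))
        off = ~np.eye(4, dtype=bool)
        vals = m.values[off]
        assert np.all(np.abs(vals[np.isfinite(vals)]) <= 1.0)
        assert np.all(np.diag(m.values) == 0)

    def test_lagged_copy_is_matrix_maximum(self):
        """A pair carrying a 3-bin lagged copy among independent neurons must
        hold the largest CC entry, at the embedded delay."""
        rng = np.random.default_rng(12)
        n, t_len, d0 = 5, 20_000, 3
        binned = (rng.random((n, t_len)) < 0.05).astype(np.uint8)
        binned[1, d0:] = binned[0, : t_len - d0]  # neuron 0 drives neuron 1
        # a 2 ms kernel resolves the 3 ms lag (the 200 ms default smooths it out)
        m = sp.correlation_matrix(binned, "cc", CCParams(sigma=0.002))
        off = ~np.eye(n, dtype=bool)
        assert m.values[1, 0] == np.nanmax(m.values[off])
        assert m.best_delay[1, 0] == d0

    def test_silent_neuron_yields_undefined_cc(self):
        rng = np.random.default_rng(13)
        binned = (rng.random((3, 3000)) < 0.1).astype(np.uint8)
        binned[2] = 0
        m = sp.correlation_matrix(binned, "cc", CCParams(d_max=5))
        assert np.isnan(m.values[0, 2]) and np.isnan(m.values[2, 0])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            sp.correlation_matrix(np.zeros((3, 100), dtype=np.uint8), "granger")
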