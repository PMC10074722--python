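import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wavehot.wavelet import (
    HAAR_HIGHPASS,
    HAAR_LOWPASS,
    dwt_coefficient_vector,
    dwt_energy_summary,
    dwt_multilevel,
    entropy_vector,
    haar_analysis_step,
    log_energy_entropy,
    shannon_entropy,
    threshold_sure_norm_entropies,
    wpt_coefficient_vector,
    wpt_energy_summary,
    wpt_level3,
)

SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# independent brute-force oracle: literal evaluation of the filter-bank sums
# a[n] = sum_k s[k] g[k - 2n], d[n] = sum_k s[k] h[k - 2n] with the
# repeat-last-sample extension, written with explicit python loops.
# ---------------------------------------------------------------------------

def oracle_step(signal):
    s = list(map(float, signal))
    if len(s) % 2 == 1:
        s = s + [s[-1]]
    g, h = HAAR_LOWPASS, HAAR_HIGHPASS
    approx, detail = [], []
    for n in range(len(s) // 2):
        a = d = 0.0
        for k, sk in enumerate(s):
            m = k - 2 * n
            if 0 <= m < 2:
                a += sk * g[m]
                d += sk * h[m]
        approx.append(a)
        detail.append(d)
    return approx, detail


def oracle_multilevel(signal, levels=3):
    approx_levels, detail_levels = [], []
    current = list(map(float, signal))
    for _ in range(levels):
        a, d = oracle_step(current)
        approx_levels.append(a)
        detail_levels.append(d)
        current = a
    return approx_levels, detail_levels


def oracle_wpt3(signal):
    nodes = [list(map(float, signal))]
    for _ in range(3):
        nxt = []
        for node in nodes:
            a, d = oracle_step(node)
            nxt.extend([a, d])
        nodes = nxt
    return nodes


class TestHaarStep:
    def test_constant_pair(self):
        a, d = haar_analysis_step([1, 1])
        np.testing.assert_allclose(a, [SQRT2])
        np.testing.assert_allclose(d, [0.0], atol=1e-15)

    def test_antisymmetric_pair(self):
        a, d = haar_analysis_step([1, -1])
        np.testing.assert_allclose(a, [0.0], atol=1e-15)
        np.testing.assert_allclose(d, [SQRT2])

    def test_four_sample_example(self):
        a, d = haar_analysis_step([3, 1, 2, 4])
        np.testing.assert_allclose(a, [4 / SQRT2, 6 / SQRT2])
        np.testing.assert_allclose(d, [2 / SQRT2, -2 / SQRT2])

    def test_odd_length_extends_last_sample(self):
        a, d = haar_analysis_step([1, 2, 3])
        a2, d2 = haar_analysis_step([1, 2, 3, 3])
        np.testing.assert_allclose(a, a2)
        np.testing.assert_allclose(d, d2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            haar_analysis_step([])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            haar_analysis_step([1.0, float("nan")])

    def test_matches_oracle(self, rng):
        for n in (2, 4, 5, 6, 7, 8):
            s = rng.normal(size=n)
            a, d = haar_analysis_step(s)
            oa, od = oracle_step(s)
            np.testing.assert_allclose(a, oa, atol=1e-12)
            np.testing.assert_allclose(d, od, atol=1e-12)


class TestDwtMultilevel:
    def test_constant_signal(self):
        c = 2.5
        dec = dwt_multilevel([c] * 8)
        np.testing.assert_allclose(dec.approx[2], [c * 2 * SQRT2])
        for d in dec.detail:
            np.testing.assert_allclose(d, np.zeros_like(d), atol=1e-12)

    def test_dyadic_lengths(self, rng):
        dec = dwt_multilevel(rng.normal(size=8))
        assert [len(a) for a in dec.approx] == [4, 2, 1]
        assert [len(d) for d in dec.detail] == [4, 2, 1]

    def test_length6_lengths(self, rng):
        dec = dwt_multilevel(rng.normal(size=6))
        assert [len(a) for a in dec.approx] == [3, 2, 1]

    def test_parseval_100_random_signals(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            s = rng.normal(size=8)
            dec = dwt_multilevel(s)
            total = np.sum(dec.approx[2] ** 2) + sum(np.sum(d**2) for d in dec.detail)
            assert abs(total - np.sum(s**2)) < 1e-9

    def test_coefficients_match_oracle_50_signals(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            s = rng.normal(size=8)
            dec = dwt_multilevel(s)
            oa, od = oracle_multilevel(s)
            for j in range(3):
                np.testing.assert_allclose(dec.approx[j], oa[j], atol=1e-12)
                np.testing.assert_allclose(dec.detail[j], od[j], atol=1e-12)

    def test_levels_below_one_rejected(self):
        with pytest.raises(ValueError):
            dwt_multilevel([1, 2], levels=0)

    def test_always_three_levels_even_for_short_signals(self, rng):
        dec = dwt_multilevel(rng.normal(size=2), levels=3)
        assert dec.levels == 3
        assert len(dec.approx[2]) == 1


class TestWpt:
    def test_eight_terminal_nodes(self, rng):
        nodes = wpt_level3(rng.normal(size=8))
        assert len(nodes.nodes) == 8

    def test_constant_signal_spike_in_node0(self):
        c = 1.5
        nodes = wpt_level3([c] * 8)
        np.testing.assert_allclose(nodes.nodes[0], [c * 2 * SQRT2])
        for node in nodes.nodes[1:]:
            np.testing.assert_allclose(node, np.zeros_like(node), atol=1e-12)

    def test_parseval_100_random_signals(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            s = rng.normal(size=8)
            nodes = wpt_level3(s)
            total = sum(np.sum(n**2) for n in nodes.nodes)
            assert abs(total - np.sum(s**2)) < 1e-9

    def test_matches_oracle(self, rng):
        for n in (6, 8):
            s = rng.normal(size=n)
            nodes = wpt_level3(s)
            oracle = oracle_wpt3(s)
            for got, want in zip(nodes.nodes, oracle):
                np.testing.assert_allclose(got, want, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wpt_level3([])


class TestDwtEnergySummary:
    def test_constant_signal(self):
        summary = dwt_energy_summary(dwt_multilevel([3.0] * 8))
        np.testing.assert_allclose(summary.ea, [100, 100, 100])
        assert summary.ea_mean == pytest.approx(100)
        assert summary.ea_std == pytest.approx(0)
        assert summary.ed == pytest.approx(0)

    def test_alternating_signal_pure_detail(self):
        summary = dwt_energy_summary(dwt_multilevel([1, -1] * 4))
        np.testing.assert_allclose(summary.ea, [0, 0, 0], atol=1e-12)
        assert summary.ed == pytest.approx(100)

    def test_ea3_plus_ed_identity(self, rng):
        for _ in range(20):
            summary = dwt_energy_summary(dwt_multilevel(rng.normal(size=8)))
            assert summary.ea[2] + summary.ed == pytest.approx(100, abs=1e-12)
            assert all(0 <= e <= 100 for e in summary.ea)

    def test_population_std(self, rng):
        summary = dwt_energy_summary(dwt_multilevel(rng.normal(size=8)))
        ea = np.array(summary.ea)
        assert summary.ea_std == pytest.approx(float(ea.std(ddof=0)))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            dwt_energy_summary(dwt_multilevel([0.0] * 8))


class TestWptEnergySummary:
    def test_constant_relative(self):
        absolute, relative, total = wpt_energy_summary(wpt_level3([2.0] * 8))
        np.testing.assert_allclose(relative, [100, 0, 0, 0, 0, 0, 0, 0], atol=1e-12)
        assert total == pytest.approx(8 * 4.0)

    def test_relative_sums_to_100(self, rng):
        for _ in range(20):
            _, relative, _ = wpt_energy_summary(wpt_level3(rng.normal(size=8)))
            assert np.sum(relative) == pytest.approx(100, abs=1e-9)

    def test_total_equals_signal_energy(self, rng):
        s = rng.normal(size=8)
        _, _, total = wpt_energy_summary(wpt_level3(s))
        assert total == pytest.approx(np.sum(s**2), abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wpt_energy_summary(wpt_level3([0.0] * 8))


# independent per-formula entropy oracles
def oracle_shannon(s):
    return -sum(x * x * math.log(x * x) for x in s if x * x != 0)


def oracle_log_energy(s):
    return sum(math.log(x * x) for x in s if x * x != 0)


def oracle_threshold(s):
    return sum(1 for x in s if abs(x) > 0.2)


def oracle_sure(s):
    return len(s) - sum(1 for x in s if abs(x) <= 3) + sum(min(x * x, 9.0) for x in s)


def oracle_norm(s):
    return sum(abs(x) ** 1.3 for x in s)


class TestEntropies:
    def test_shannon_singleton_one(self):
        assert shannon_entropy([1.0]) == 0.0

    def test_shannon_spike(self):
        value = shannon_entropy([2 * SQRT2, 0, 0, 0, 0, 0, 0, 0])
        assert value == pytest.approx(-8 * math.log(8))

    def test_log_energy_ones(self):
        assert log_energy_entropy([1.0, 1.0]) == 0.0

    def test_log_energy_spike(self):
        assert log_energy_entropy([2 * SQRT2]) == pytest.approx(math.log(8))

    def test_threshold_count(self):
        t, _, _ = threshold_sure_norm_entropies([0.1, 0.3, 0.25, 0.05])
        assert t == 2

    def test_sure_example(self):
        _, sure, _ = threshold_sure_norm_entropies([1.0, 2.0])
        assert sure == pytest.approx(5.0)

    def test_norm_unit_pair(self):
        _, _, norm = threshold_sure_norm_entropies([1.0, -1.0])
        assert norm == pytest.approx(2.0)

    def test_zero_vector_all_zero(self):
        assert entropy_vector(np.zeros(16)).as_tuple() == (0, 0, 0, 0, 0)

    def test_zero_padding_invariance(self, rng):
        for _ in range(20):
            s = rng.normal(size=8)
            padded = np.concatenate([s, np.zeros(5)])
            np.testing.assert_allclose(
                entropy_vector(s).as_tuple(), entropy_vector(padded).as_tuple(),
                rtol=1e-12,
            )

    @given(st.lists(st.floats(min_value=-10, max_value=10), min_size=1, max_size=16))
    @settings(max_examples=50)
    def test_zero_append_property(self, values):
        base = entropy_vector(values).as_tuple()
        padded = entropy_vector(list(values) + [0.0]).as_tuple()
        np.testing.assert_allclose(base, padded, rtol=1e-9, atol=1e-12)

    def test_match_oracles_100_random_vectors(self):
        rng = np.random.default_rng(314)
        for _ in range(100):
            s = rng.normal(size=rng.integers(1, 12)) * rng.uniform(0.1, 5)
            ev = entropy_vector(s)
            assert ev.shannon == pytest.approx(oracle_shannon(s), rel=1e-10)
            assert ev.log_energy == pytest.approx(oracle_log_energy(s), rel=1e-10)
            assert ev.threshold == oracle_threshold(s)
            assert ev.sure == pytest.approx(oracle_sure(s), rel=1e-10)
            assert ev.norm == pytest.approx(oracle_norm(s), rel=1e-10)

    def test_coefficient_vector_layout(self, rng):
        s = rng.normal(size=8)
        dec = dwt_multilevel(s)
        coeffs = dwt_coefficient_vector(dec)
        expected = np.concatenate([dec.approx[2], dec.detail[2], dec.detail[1], dec.detail[0]])
        np.testing.assert_array_equal(coeffs, expected)
        assert coeffs.size == 8
        nodes = wpt_level3(s)
        assert wpt_coefficient_vector(nodes).size == 8
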