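import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dmrscan import (
    PipelineConfig,
    SignalTrack,
    biweight_mean,
    replicate_concordance,
    scale_track,
    windowed_ks_pscore,
)
from conftest import make_layout, make_signal_track


def biweight_oracle(x, c=5.0):
    """Independently coded biweight iteration (loop form, fresh derivation)."""
    x = list(map(float, x))
    m = float(np.median(x))
    mad = float(np.median([abs(v - m) for v in x]))
    if mad == 0:
        return m
    for _ in range(200):
        num = den = 0.0
        for v in x:
            u = (v - m) / (c * mad)
            if abs(u) < 1:
                w = (1 - u * u) ** 2
                num += w * v
                den += w
        m_new = num / den
        if abs(m_new - m) < 1e-12:
            return m_new
        m = m_new
    return m


class TestBiweightMean:
    def test_constant_vector_hits_mad_zero_branch(self):
        assert biweight_mean([0.5, 0.5, 0.5]) == 0.5

    def test_symmetric_input(self):
        assert biweight_mean([-1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_outlier_resistance_vs_oracle(self):
        x = [0, 0.1, -0.1, 0.05, 8.0]
        got = biweight_mean(x)
        assert got == pytest.approx(biweight_oracle(x), abs=1e-8)
        assert abs(got - np.median(x)) < 0.15
        assert abs(got - np.mean(x)) > 1.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            biweight_mean([])

    @pytest.mark.parametrize("seed", range(5))
    def test_random_inputs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.2, 1.0, size=200)
        x[:5] += 10  # contaminate
        assert biweight_mean(x) == pytest.approx(biweight_oracle(x), abs=1e-8)


class TestScaleTrack:
    def test_already_centered_unchanged(self):
        layout = make_layout(n=7)
        tr = make_signal_track(layout, [-3, -2, -1, 0, 1, 2, 3], scaled=False)
        out = scale_track(tr)
        assert np.allclose(out.values, tr.values)
        assert out.scaled

    def test_shift_invariance(self):
        layout = make_layout(n=50)
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 50)
        a = scale_track(make_signal_track(layout, base, scaled=False))
        b = scale_track(make_signal_track(layout, base + 7.5, scaled=False))
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_postcondition_biweight_mean_zero(self):
        layout = make_layout(n=1000)
        rng = np.random.default_rng(42)
        tr = make_signal_track(layout, rng.normal(0.3, 1.0, 1000), scaled=False)
        out = scale_track(tr)
        assert abs(biweight_mean(out.values.to_numpy())) < 1e-9

    def test_double_scaling_rejected(self):
        layout = make_layout(n=5)
        tr = make_signal_track(layout, [0.0] * 5, scaled=True)
        with pytest.raises(ValueError):
            scale_track(tr)


def clustered_layout(n_window=3, n_total=100, spacing_far=5000):
    """Layout where n_window probes share a 750-bp window, the rest are isolated
    except probe pairs needed to satisfy the 2-probe window floor."""
    from dmrscan import GenomicInterval, Probe, ProbeLayout

    probes = []
    for i in range(n_window):
        probes.append(
            Probe(f"W{i}", GenomicInterval("chr1", 1_000_000 + i * 100,
                                           1_000_000 + i * 100 + 50))
        )
    for i in range(n_total - n_window):
        probes.append(
            Probe(f"B{i}", GenomicInterval("chr2", i * spacing_far, i * spacing_far + 50))
        )
    return ProbeLayout(probes)


class TestWindowedKS:
    def test_closed_form_worked_example(self):
        # 3-probe window at 2.0 vs 97 background probes at 0.0:
        # D+ = 1, p = exp(-2*3*97/100), P = -log10(p) ~ 2.53
        layout = clustered_layout(n_window=3, n_total=100)
        vals = pd.Series(0.0, index=layout.probe_ids)
        vals[["W0", "W1", "W2"]] = 2.0
        ps = windowed_ks_pscore(SignalTrack("s", vals, scaled=True), layout)
        expected = -math.log10(math.exp(-2.0 * 3 * 97 / 100))
        assert ps.pscores["W1"] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.5276, abs=1e-3)

    def test_anti_enriched_window_scores_zero(self):
        layout = clustered_layout(n_window=3, n_total=100)
        rng = np.random.default_rng(1)
        vals = pd.Series(rng.uniform(1, 2, len(layout)), index=layout.probe_ids)
        vals[["W0", "W1", "W2"]] = 0.0  # window at the background minimum
        ps = windowed_ks_pscore(SignalTrack("s", vals, scaled=True), layout)
        assert ps.pscores["W1"] == pytest.approx(0.0, abs=0.05)

    def test_single_probe_window_scores_zero(self):
        layout = clustered_layout(n_window=1, n_total=50)
        vals = pd.Series(0.0, index=layout.probe_ids)
        vals["W0"] = 10.0
        ps = windowed_ks_pscore(SignalTrack("s", vals, scaled=True), layout)
        assert ps.pscores["W0"] == 0.0

    def test_unscaled_track_rejected(self):
        layout = make_layout(n=5)
        tr = make_signal_track(layout, [0.0] * 5, scaled=False)
        with pytest.raises(ValueError):
            windowed_ks_pscore(tr, layout)

    def test_matches_scipy_one_sided_statistic(self):
        # same window/background split handed to scipy's two-sample KS:
        # the D+ statistic must agree exactly; scipy's asymptotic one-sided
        # p adds a small-sample continuity correction on top of
        # exp(-2 D^2 mn/(m+n)), so the p-values agree only approximately.
        layout = clustered_layout(n_window=5, n_total=60)
        rng = np.random.default_rng(3)
        vals = pd.Series(rng.normal(0, 1, len(layout)), index=layout.probe_ids)
        vals[[f"W{i}" for i in range(5)]] += 1.2
        ps = windowed_ks_pscore(SignalTrack("s", vals, scaled=True), layout)
        win = vals[[f"W{i}" for i in range(5)]].to_numpy()
        bg = vals[[pid for pid in layout.probe_ids if pid.startswith("B")]].to_numpy()
        ref = stats.ks_2samp(bg, win, alternative="greater", method="asymp")
        m, n = len(win), len(bg)
        d = ref.statistic
        closed_form_p = math.exp(-2 * d * d * m * n / (m + n))
        assert ps.pscores["W2"] == pytest.approx(-math.log10(closed_form_p), rel=1e-9)
        assert d == pytest.approx(d_plus_oracle(bg, win), abs=1e-12)
        assert closed_form_p == pytest.approx(ref.pvalue, rel=0.8)

    def test_monotone_in_window_offset(self):
        # raising all window probes by a positive constant never lowers P
        layout = clustered_layout(n_window=4, n_total=80)
        rng = np.random.default_rng(7)
        base = pd.Series(rng.normal(0, 1, len(layout)), index=layout.probe_ids)
        last = -1.0
        for offset in [0.0, 0.3, 0.8, 1.5, 3.0]:
            vals = base.copy()
            vals[[f"W{i}" for i in range(4)]] = (
                base[[f"W{i}" for i in range(4)]] + offset
            )
            ps = windowed_ks_pscore(SignalTrack("s", vals, scaled=True), layout)
            score = ps.pscores["W1"]
            assert score >= last - 1e-12
            last = score

    def test_null_calibration_few_high_scores(self):
        # pure noise: <= 5% of probes reach the peak-calling threshold
        fracs = []
        for seed in range(10):
            layout = make_layout(spacing=100, n=400)
            rng = np.random.default_rng(seed)
            tr = make_signal_track(layout, rng.normal(0, 0.4, 400))
            ps = windowed_ks_pscore(tr, layout)
            fracs.append((ps.pscores >= 2.0).mean())
        assert np.mean(fracs) <= 0.05

    def test_pvalue_floor_caps_pscore(self):
        layout = clustered_layout(n_window=3, n_total=100)
        vals = pd.Series(0.0, index=layout.probe_ids)
        vals[["W0", "W1", "W2"]] = 2.0
        cfg = PipelineConfig(ks_pvalue_floor=1e-2)
        ps = windowed_ks_pscore(SignalTrack("s", vals, scaled=True), layout, cfg)
        assert ps.pscores["W1"] == pytest.approx(2.0)


def d_plus_oracle(bg, win):
    """sup_x (F_bg - F_win) via dense evaluation at all pooled points."""
    xs = np.concatenate([bg, win])
    f_bg = (np.asarray(bg)[:, None] <= xs).mean(axis=0)
    f_win = (np.asarray(win)[:, None] <= xs).mean(axis=0)
    return max((f_bg - f_win).max(), 0.0)


class TestExactPermutationOracle:
    def test_asymptotic_p_ranks_like_exhaustive_permutation_p(self):
        """For pooled sizes <= 12, ordering instances by the asymptotic p
        must agree with the exhaustive permutation p of D+ (ranks, not
        values)."""
        rng = np.random.default_rng(11)
        m, n = 4, 8
        results = []
        for _ in range(8):
            pooled = rng.normal(0, 1, m + n)
            win_idx = set(rng.choice(m + n, size=m, replace=False))
            win = pooled[sorted(win_idx)]
            bg = pooled[[i for i in range(m + n) if i not in win_idx]]
            d_obs = d_plus_oracle(bg, win)
            p_asym = math.exp(-2 * d_obs**2 * m * n / (m + n))
            count = total = 0
            for combo in itertools.combinations(range(m + n), m):
                w = pooled[list(combo)]
                b = np.delete(pooled, list(combo))
                total += 1
                if d_plus_oracle(b, w) >= d_obs - 1e-12:
                    count += 1
            results.append((p_asym, count / total))
        results.sort()
        perm_ps = [p for _, p in results]
        # permutation p must be non-decreasing along the asymptotic order
        assert all(a <= b + 1e-12 for a, b in zip(perm_ps, perm_ps[1:]))


class TestReplicateConcordance:
    def test_identical_tracks(self):
        layout = make_layout(n=30)
        rng = np.random.default_rng(0)
        a = make_signal_track(layout, rng.normal(0, 1, 30))
        assert replicate_concordance(a, a) == pytest.approx(1.0)

    def test_negated_track(self):
        layout = make_layout(n=30)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        a = make_signal_track(layout, x)
        b = make_signal_track(layout, -x)
        assert replicate_concordance(a, b) == pytest.approx(-1.0)

    def test_zero_variance_gives_nan_with_warning(self):
        layout = make_layout(n=10)
        a = make_signal_track(layout, [1.0] * 10)
        b = make_signal_track(layout, list(range(10)))
        with pytest.warns(UserWarning):
            assert math.isnan(replicate_concordance(a, b))

    def test_matches_analytic_value_for_shared_plus_noise(self):
        # r = signal_var / (signal_var + noise_var), averaged over 10 seeds
        layout = make_layout(n=2000)
        sig_var, noise_var = 1.0, 0.5
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            shared = rng.normal(0, math.sqrt(sig_var), 2000)
            a = make_signal_track(layout, shared + rng.normal(0, math.sqrt(noise_var), 2000))
            b = make_signal_track(layout, shared + rng.normal(0, math.sqrt(noise_var), 2000))
            rs.append(replicate_concordance(a, b))
        assert np.mean(rs) == pytest.approx(sig_var / (sig_var + noise_var), abs=0.05)
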