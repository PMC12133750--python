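"""Shapley axioms on toy models, band perturbation, joint report."""

import itertools
import math

import numpy as np
import pytest

from mbeeg.bands import BandSpec
from mbeeg.connectivity import PLVMatrix
from mbeeg.interpret import (
    AttributionReport,
    attribute,
    band_attribution,
    joint_report,
    sampling_shapley,
)
from mbeeg.montage import standard_1020_montage
from mbeeg.preprocess import EpochSet

CH8 = ["Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4"]


def make_epochs(data, fs=64.0, channels=None):
    n, c, t = data.shape
    mont = standard_1020_montage(channels or CH8[:c])
    return EpochSet(data=data, labels=np.ones(n, dtype=int), fs=fs,
                    window=(0, t / fs), montage=mont)


class LinearToy:
    """f(x) = [w . x, -w . x]; Shapley value of channel i is
    sum_t w[i,t] * (x[i,t] - b[i,t]) in closed form."""

    def __init__(self, w):
        self.w = w

    def __call__(self, batch):
        s = np.einsum("nct,ct->n", batch, self.w)
        return np.stack([s, -s], axis=1)


def exact_shapley(f, x, baseline, target):
    """Brute-force Shapley values by full coalition enumeration."""
    C = x.shape[0]
    phi = np.zeros(C)
    idx = list(range(C))
    for i in idx:
        others = [j for j in idx if j != i]
        for r in range(C):
            for S in itertools.combinations(others, r):
                weight = math.factorial(r) * math.factorial(C - r - 1) / math.factorial(C)
                with_i = baseline.copy()
                for j in (*S, i):
                    with_i[j] = x[j]
                without_i = baseline.copy()
                for j in S:
                    without_i[j] = x[j]
                v1 = f(with_i[None])[0, target]
                v0 = f(without_i[None])[0, target]
                phi[i] += weight * (v1 - v0)
    return phi


class TestSamplingShapley:
    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(0)
        C, T = 8, 4
        w = rng.standard_normal((C, T))
        x = rng.standard_normal((C, T))
        b = rng.standard_normal((C, T))
        f = LinearToy(w)
        phi = sampling_shapley(f, x, b, target=0, n_permutations=2000,
                               rng=np.random.default_rng(1))
        expected = ((x - b) * w).sum(axis=1)
        np.testing.assert_allclose(phi, expected, rtol=0.05, atol=0.05 * np.abs(expected).max())

    def test_matches_exact_enumeration_on_nonlinear_toy(self):
        rng = np.random.default_rng(2)
        C, T = 6, 2
        a = rng.standard_normal((C, T))

        def f(batch):
            s = np.tanh(np.einsum("nct,ct->n", batch, a))
            q = np.einsum("nct,nct->n", batch, batch) * 0.01
            return np.stack([s + q, -s], axis=1)

        x = rng.standard_normal((C, T))
        b = np.zeros((C, T))
        expected = exact_shapley(f, x, b, target=0)
        phi = sampling_shapley(f, x, b, target=0, n_permutations=2000,
                               rng=np.random.default_rng(3))
        assert np.max(np.abs(phi - expected)) < 0.05

    def test_efficiency_is_exact_per_estimate(self):
        rng = np.random.default_rng(4)
        C, T = 6, 3
        a = rng.standard_normal((C, T))

        def f(batch):
            return np.tanh(np.einsum("nct,ct->n", batch, a))[:, None]

        x = rng.standard_normal((C, T))
        b = rng.standard_normal((C, T))
        phi = sampling_shapley(f, x, b, target=0, n_permutations=50,
                               rng=np.random.default_rng(5))
        gap = f(x[None])[0, 0] - f(b[None])[0, 0]
        assert phi.sum() == pytest.approx(gap, abs=1e-12)

    def test_null_player_gets_zero(self):
        rng = np.random.default_rng(6)
        C, T = 5, 3
        w = rng.standard_normal((C, T))
        w[2] = 0.0  # channel 2 is ignored by the model
        f = LinearToy(w)
        x = rng.standard_normal((C, T))
        b = np.zeros((C, T))
        phi = sampling_shapley(f, x, b, target=0, n_permutations=500,
                               rng=np.random.default_rng(7))
        assert abs(phi[2]) < 1e-3 * np.abs(phi).max()

    def test_symmetric_players_get_equal_values(self):
        C, T = 4, 2
        w = np.ones((C, T))

        def f(batch):  # symmetric and nonlinear in the channel sum
            return np.tanh(batch.sum(axis=(1, 2)))[:, None]

        x = np.ones((C, T))
        x[2:] = 0.3
        b = np.zeros((C, T))
        phi = sampling_shapley(f, x, b, target=0, n_permutations=2000,
                               rng=np.random.default_rng(8))
        assert abs(phi[0] - phi[1]) < 0.05
        assert abs(phi[2] - phi[3]) < 0.05


class TestAttribute:
    def test_report_structure_and_channel_ranking(self):
        rng = np.random.default_rng(9)
        n, C, T = 6, 4, 8
        w = np.zeros((C, T))
        w[2] = 1.0  # only channel C3-position matters
        f = LinearToy(w)
        trials = make_epochs(rng.standard_normal((n, C, T)))
        background = make_epochs(rng.standard_normal((10, C, T)))
        rep = attribute(f, trials, background, n_permutations=200, seed=0)
        assert rep.values.shape == (n, C, T)
        assert rep.top_channels(1) == [trials.montage.channel_names[2]]
        # efficiency: per-trial sums equal output minus baseline
        sums = rep.values.sum(axis=(1, 2))
        np.testing.assert_allclose(sums, rep.output - rep.baseline, atol=1e-9)

    def test_gradient_x_input_requires_trained_model(self):
        f = LinearToy(np.ones((4, 8)))
        ep = make_epochs(np.zeros((2, 4, 8)))
        with pytest.raises(TypeError, match="TrainedModel"):
            attribute(f, ep, ep, method="gradient-x-input")

    def test_unknown_method_and_empty_background(self):
        f = LinearToy(np.ones((4, 8)))
        ep = make_epochs(np.zeros((2, 4, 8)))
        with pytest.raises(ValueError, match="unknown attribution method"):
            attribute(f, ep, ep, method="lime")
        empty = make_epochs(np.zeros((0, 4, 8)))
        with pytest.raises(ValueError, match="non-empty"):
            attribute(f, ep, empty)


class TestBandAttribution:
    def test_band_carrying_signal_ranks_first(self):
        """A model reading Alpha-band energy loses output only when the
        Alpha content is swapped out."""
        fs, T, C = 64.0, 128, 4
        t = np.arange(T) / fs
        rng = np.random.default_rng(10)
        alpha = np.sin(2 * np.pi * 10 * t)
        data = 0.1 * rng.standard_normal((8, C, T))
        data[:, 1] += alpha  # channel 1 carries a 10 Hz tone

        freqs = np.fft.rfftfreq(T, 1 / fs)
        amask = (freqs >= 8) & (freqs <= 13)

        def f(batch):
            spec = np.fft.rfft(batch[:, 1], axis=-1)
            power = (np.abs(spec[:, amask]) ** 2).sum(axis=-1) / T
            return np.stack([power, 1 - power], axis=1)

        ep = make_epochs(data, fs=fs)
        bands = [BandSpec("Theta", 4, 8), BandSpec("Alpha", 8, 13), BandSpec("Beta", 13, 30)]
        imp = band_attribution(f, ep, bands)
        assert max(imp, key=imp.get) == "Alpha"
        assert imp["Theta"] < 0.05 * imp["Alpha"]  # empty band: near-zero importance

    def test_importances_bounded_for_probability_models(self):
        rng = np.random.default_rng(11)

        def f(batch):
            z = np.einsum("nct->n", batch)
            p = 1 / (1 + np.exp(-z))
            return np.stack([p, 1 - p], axis=1)

        ep = make_epochs(rng.standard_normal((5, 4, 64)))
        imp = band_attribution(f, ep, [BandSpec("Alpha", 8, 13)])
        assert all(-1 <= v <= 1 for v in imp.values())


class TestJointReport:
    def plv_stub(self, values, band="Beta"):
        return PLVMatrix(band=BandSpec(band, 13, 30), values=values, n_time=256, n_trials=10)

    def report_stub(self, summary, names):
        C = len(summary)
        return AttributionReport(
            values=np.zeros((1, C, 4)),
            channel_summary=np.asarray(summary, dtype=float),
            baseline=np.zeros(1),
            predicted_class=np.zeros(1, dtype=int),
            output=np.zeros(1),
            method="sampling-shapley",
            channel_names=tuple(names),
        )

    def test_full_k_top_returns_whole_matrix(self):
        rng = np.random.default_rng(12)
        v = rng.uniform(0.1, 0.9, (4, 4))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        attr = self.report_stub([0.4, 0.3, 0.2, 0.1], CH8[:4])
        jr = joint_report(attr, [self.plv_stub(v)], k_top=4)
        np.testing.assert_array_equal(jr.plv_submatrices["Beta"], v)
        assert jr.top_channels == CH8[:4]  # already rank-ordered

    def test_concordant_structure_gives_positive_rho(self):
        # attribution order matches mean-PLV order exactly
        v = np.eye(4)
        strengths = [0.9, 0.7, 0.5, 0.3]
        for i in range(4):
            for j in range(i + 1, 4):
                v[i, j] = v[j, i] = min(strengths[i], strengths[j])
        attr = self.report_stub([4.0, 3.0, 2.0, 1.0], CH8[:4])
        jr = joint_report(attr, [self.plv_stub(v)], k_top=4)
        assert jr.concordance["Beta"] > 0

    def test_degenerate_attribution_flagged_none(self):
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 0.5
        v[0, 2] = v[2, 0] = 0.3
        v[1, 2] = v[2, 1] = 0.2
        attr = self.report_stub([0.5, 0.5, 0.5], CH8[:3])
        jr = joint_report(attr, [self.plv_stub(v)], k_top=3)
        assert jr.concordance["Beta"] is None
        assert "undefined" in jr.summary()

    def test_k_top_exceeding_channels_rejected(self):
        attr = self.report_stub([0.1, 0.2], CH8[:2])
        with pytest.raises(ValueError, match="exceeds"):
            joint_report(attr, [self.plv_stub(np.eye(2))], k_top=3)

    def test_concordance_bounded(self):
        rng = np.random.default_rng(13)
        for seed in range(5):
            g = np.random.default_rng(seed)
            v = g.uniform(0, 1, (5, 5))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 1.0)
            attr = self.report_stub(g.uniform(0, 1, 5), CH8[:5])
            jr = joint_report(attr, [self.plv_stub(v)], k_top=5)
            rho = jr.concordance["Beta"]
            assert rho is None or -1.0 <= rho <= 1.0
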