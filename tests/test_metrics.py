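import numpy as np
import pandas as pd
import pytest

from alnbrain.metrics import (Partition, bandpass, functional_connectivity,
                              gbc, kuramoto, metrics_report, subnetwork_gbc,
                              YEO7)


def _narrow(rng, n, T, TR):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bandpass(rng.standard_normal((n, T)), TR)


class TestFunctionalConnectivity:
    def test_self_correlation_unity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 50))
        FC = functional_connectivity(x)
        np.testing.assert_allclose(np.diag(FC), 1.0, atol=1e-12)

    def test_anticorrelated_pair(self):
        x = np.vstack([np.sin(np.linspace(0, 7, 40))])
        FC = functional_connectivity(np.vstack([x, -x]))
        assert FC[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 50))
        FC = functional_connectivity(x)
        for i in range(5):
            for j in range(5):
                xi = x[i] - x[i].mean()
                xj = x[j] - x[j].mean()
                want = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert FC[i, j] == pytest.approx(want, abs=1e-12)

    def test_constant_row_names_region(self):
        x = np.random.default_rng(2).standard_normal((3, 30))
        x[1] = 4.2
        with pytest.raises(ValueError, match="region 1"):
            functional_connectivity(x)


class TestGBC:
    def test_uniform_offdiagonal(self):
        c = 0.37
        FC = np.full((6, 6), c)
        np.fill_diagonal(FC, 1.0)
        region, glob = gbc(FC)
        np.testing.assert_allclose(region, c, atol=1e-14)
        assert glob == pytest.approx(c)

    def test_two_regions(self):
        FC = np.array([[1.0, 0.55], [0.55, 1.0]])
        region, _ = gbc(FC)
        np.testing.assert_allclose(region, [0.55, 0.55])

    @pytest.mark.parametrize("include_self", [False, True])
    def test_double_loop_oracle(self, include_self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((7, 60))
        FC = functional_connectivity(x)
        region, glob = gbc(FC, include_self=include_self)
        n = 7
        for i in range(n):
            if include_self:
                want = sum(FC[i, j] for j in range(n)) / n
            else:
                want = sum(FC[i, j] for j in range(n) if j != i) / (n - 1)
            assert region[i] == pytest.approx(want, abs=1e-12)
        assert glob == pytest.approx(region.mean())

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        FC = functional_connectivity(rng.standard_normal((6, 40)))
        perm = rng.permutation(6)
        region, _ = gbc(FC)
        region_p, _ = gbc(FC[np.ix_(perm, perm)])
        np.testing.assert_allclose(region_p, region[perm], atol=1e-14)


class TestSubnetworkGBC:
    def test_single_network_equals_global(self):
        part = Partition(labels=["Vis"] * 5)
        vals = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        per_net, assoc, sens = subnetwork_gbc(vals, part)
        assert per_net["Vis"] == pytest.approx(vals.mean())
        assert sens == pytest.approx(vals.mean())

    def test_two_block_constant_values(self):
        part = Partition(labels=["Def"] * 3 + ["Vis"] * 2)
        vals = np.array([0.2, 0.2, 0.2, 0.6, 0.6])
        per_net, assoc, sens = subnetwork_gbc(vals, part)
        assert per_net["Def"] == pytest.approx(0.2)
        assert per_net["Vis"] == pytest.approx(0.6)
        assert assoc == pytest.approx(0.2)
        assert sens == pytest.approx(0.6)

    def test_groupby_oracle(self):
        rng = np.random.default_rng(5)
        labels = list(rng.choice(YEO7, 40))
        vals = rng.random(40)
        part = Partition(labels=labels)
        per_net, assoc, sens = subnetwork_gbc(vals, part)
        df = pd.DataFrame({"net": labels, "v": vals})
        want = df.groupby("net")["v"].mean()
        for net in set(labels):
            assert per_net[net] == pytest.approx(want[net], abs=1e-12)

    def test_supergroups_disjoint_and_exclude_limbic(self):
        part = Partition(labels=list(YEO7))
        assert not np.any(part.association_mask & part.sensory_mask)
        lim = part.mask("Lim")
        assert not np.any(lim & (part.association_mask | part.sensory_mask))


class TestBandpass:
    TR = 2.0

    def test_passband_center_retained(self):
        t = np.arange(0, 600, self.TR)
        x = np.sin(2 * np.pi * 0.055 * t)[None, :]
        y = bandpass(x, self.TR)
        # compare amplitudes away from the edges
        sl = slice(30, -30)
        assert np.abs(y[0, sl]).max() == pytest.approx(1.0, rel=0.1)

    def test_stopband_attenuated(self):
        t = np.arange(0, 600, self.TR)
        x = np.sin(2 * np.pi * 0.2 * t)[None, :]
        y = bandpass(x, self.TR)
        assert np.abs(y[0, 30:-30]).max() < 0.1

    def test_out_of_band_power_reduced_90pct(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((1, 1000))
        y = bandpass(x, self.TR)
        freqs = np.fft.rfftfreq(1000, d=self.TR)
        mask_out = (freqs < 0.03) | (freqs > 0.08)
        p_in = np.abs(np.fft.rfft(x[0]))[mask_out] ** 2
        p_out = np.abs(np.fft.rfft(y[0]))[mask_out] ** 2
        assert p_out.sum() < 0.1 * p_in.sum()

    def test_warns_on_short_series(self):
        with pytest.warns(UserWarning, match="passband cycles"):
            bandpass(np.random.default_rng(7).standard_normal((2, 30)), self.TR)


class TestKuramoto:
    def test_identical_signals_fully_synchronous(self):
        rng = np.random.default_rng(8)
        base = _narrow(rng, 1, 300, 2.0)
        x = np.repeat(base, 6, axis=0)
        R_t, mean_R, meta = kuramoto(x)
        np.testing.assert_allclose(R_t, 1.0, atol=1e-9)
        assert meta == pytest.approx(0.0, abs=1e-9)

    def test_balanced_phases_cancel(self):
        t = np.arange(0, 2000, 2.0)
        phases = [0, np.pi / 2, np.pi, 3 * np.pi / 2]
        x = np.vstack([np.sin(2 * np.pi * 0.05 * t + p) for p in phases])
        _, mean_R, _ = kuramoto(x)
        assert mean_R < 0.05

    def test_complex_sum_oracle(self):
        from scipy.signal import hilbert
        rng = np.random.default_rng(9)
        x = _narrow(rng, 6, 200, 2.0)
        R_t, mean_R, meta = kuramoto(x)
        phases = np.angle(hilbert(x, axis=-1))
        for t in range(0, 200, 17):
            acc = 0.0 + 0.0j
            for k in range(6):
                acc += np.exp(1j * phases[k, t])
            assert R_t[t] == pytest.approx(abs(acc) / 6, abs=1e-10)

    def test_order_parameter_bounded(self):
        rng = np.random.default_rng(10)
        x = _narrow(rng, 8, 400, 2.0)
        R_t, mean_R, meta = kuramoto(x)
        assert np.all((R_t >= 0) & (R_t <= 1 + 1e-12))
        assert 0 <= mean_R <= 1
        assert meta <= 0.5

    def test_global_phase_shift_invariance(self):
        from scipy.signal import hilbert
        rng = np.random.default_rng(11)
        x = _narrow(rng, 5, 400, 2.0)
        shifted = np.real(hilbert(x, axis=-1) * np.exp(1j * 0.8))
        R1, _, _ = kuramoto(x)
        R2, _, _ = kuramoto(shifted)
        sl = slice(20, -20)
        np.testing.assert_allclose(R1[sl], R2[sl], atol=0.05)


def test_metrics_report_end_to_end(partition16):
    rng = np.random.default_rng(12)
    common = _narrow(rng, 1, 200, 2.0)
    noise = _narrow(rng, 16, 200, 2.0)
    bold = 0.7 * common + 0.5 * noise
    rep = metrics_report(bold, 2.0, partition16)
    assert rep.FC.shape == (16, 16)
    assert 0 < rep.gbc_global < 1
    assert 0 <= rep.mean_R <= 1
    assert set(rep.gbc_per_network) == set(YEO7)
    flat = rep.flat()
    assert flat["gbc_global"] == rep.gbc_global
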