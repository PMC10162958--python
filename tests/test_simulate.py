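import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats as spstats

import assrlab as al
from assrlab.simulate import SimulationError, band_limited_noise


class TestErpTemplate:
    def test_trough_position_and_depth(self):
        w = al.erp_template(30, 0.04, 1000)
        assert w.min() == pytest.approx(-30.0)
        assert w.argmin() == 40

    def test_zero_amplitude(self):
        assert not al.erp_template(0, 0.04, 1000).any()

    def test_sampling_rate_scaling(self):
        w = al.erp_template(30, 0.04, 2000)
        assert w.min() == pytest.approx(-30.0)
        assert w.argmin() == 80

    def test_bounded_support(self):
        w = al.erp_template(30, 0.04, 1000, support_s=0.3)
        assert w.size == 300

    def test_positive_lobes_smaller_than_trough(self):
        w = al.erp_template(30, 0.04, 1000)
        assert 0 < w.max() < 30

    def test_nonpositive_latency_rejected(self):
        with pytest.raises(SimulationError):
            al.erp_template(30, 0.0, 1000)


class TestPinkNoise:
    def test_alpha_zero_is_white(self):
        x = al.pink_noise(10000, 0.0, 1.0, 0)
        # KS against the standard normal (noise is scaled to unit SD)
        p = spstats.kstest(x, "norm").pvalue
        assert p > 0.01
        # flat spectrum: low- and high-band power comparable
        f, P = sps.welch(x, fs=1000, nperseg=2048)
        lo = P[(f > 10) & (f < 100)].mean()
        hi = P[(f > 300) & (f < 490)].mean()
        assert 0.5 < lo / hi < 2.0

    def test_one_over_f_slope(self):
        x = al.pink_noise(40000, 1.0, 1.0, 1)
        f, P = sps.welch(x, fs=1000, nperseg=8192)
        m = (f >= 2) & (f <= 100)
        slope = np.polyfit(np.log(f[m]), np.log(P[m]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_zero_scale_is_silent(self):
        assert not al.pink_noise(2, 1.0, 0.0, 0).any()

    def test_unit_sd_and_zero_mean(self):
        x = al.pink_noise(5000, 1.0, 3.0, 2)
        assert x.std() == pytest.approx(3.0)
        assert abs(x.mean()) < 1e-9

    def test_seed_reproducibility(self):
        assert np.array_equal(al.pink_noise(1000, 1, 1, 7),
                              al.pink_noise(1000, 1, 1, 7))


def test_band_limited_noise_stays_in_band():
    x = band_limited_noise(20000, 1000, (30, 80), 1.0, 0)
    f, P = sps.welch(x, fs=1000, nperseg=4096)
    in_band = P[(f >= 35) & (f <= 75)].mean()
    out_band = P[(f >= 120) & (f <= 200)].mean()
    assert in_band / out_band > 100


class TestSynthContinuous:
    def test_identity_gating_noiseless(self):
        proto, ev = al.build_erp_protocol(5, 3.5, 0.5)
        params = al.ConditionParams(gating_g=1.0, noise_sd_uv=0.0,
                                    basal_gamma_sd_uv=0.0)
        rec = al.synth_continuous(proto, ev, params, channels=["AC"], seed=0)
        ep1 = al.extract_epochs(rec, ev, "click1", 0.1, 0.3)
        ep2 = al.extract_epochs(rec, ev, "click2", 0.1, 0.3)
        assert np.allclose(al.average_erp(ep1, False), al.average_erp(ep2, False))

    def test_perfect_locking_gives_unit_itc(self, assr_freqs):
        proto, ev = al.build_assr_protocol(8, 40, 2, 4)
        params = al.ConditionParams(noise_sd_uv=0.0, basal_gamma_sd_uv=0.0,
                                    n1_amp_uv=0.0, assr_kappa=np.inf)
        rec = al.synth_continuous(proto, ev, params, channels=["AC"], seed=0)
        ep = al.extract_epochs(rec, ev, "train_start", 2.0, 2.5)
        am = al.assr_metrics(al.morlet_tf(ep, assr_freqs))
        assert am.itc40_in == pytest.approx(1.0)
        assert am.itc40_mp == pytest.approx(1.0)

    def test_zero_assr_amp_equals_noise_only(self):
        proto, ev = al.build_assr_protocol(3, 40, 2, 4)
        base = al.ConditionParams(assr_amp_uv=0.0, n1_amp_uv=0.0)
        rec = al.synth_continuous(proto, ev, base, channels=["AC"], seed=5)
        rec2 = al.synth_continuous(proto, ev, base, channels=["AC"], seed=5)
        assert np.array_equal(rec.data, rec2.data)

    def test_bit_reproducibility_and_seed_sensitivity(self):
        proto, ev = al.build_erp_protocol(3, 3.5, 0.5)
        p = al.condition_params("vehicle")
        a = al.synth_continuous(proto, ev, p, channels=["AC", "mPFC"], seed=1)
        b = al.synth_continuous(proto, ev, p, channels=["AC", "mPFC"], seed=1)
        c = al.synth_continuous(proto, ev, p, channels=["AC", "mPFC"], seed=2)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_amp_scaling_quadruples_evoked_power(self, assr_freqs):
        proto, ev = al.build_assr_protocol(4, 40, 2, 4)
        out = {}
        for amp in (2.0, 4.0):
            params = al.ConditionParams(noise_sd_uv=0.0, basal_gamma_sd_uv=0.0,
                                        n1_amp_uv=0.0, assr_amp_uv=amp,
                                        assr_kappa=np.inf, initial_boost=1.0)
            rec = al.synth_continuous(proto, ev, params, channels=["AC"], seed=0)
            ep = al.extract_epochs(rec, ev, "train_start", 2.0, 2.5)
            out[amp] = al.assr_metrics(al.morlet_tf(ep, assr_freqs)).power40_mp
        assert out[4.0] / out[2.0] == pytest.approx(4.0, rel=1e-3)

    def test_kappa_monotonically_raises_itc(self, assr_freqs):
        proto, ev = al.build_assr_protocol(20, 40, 2, 4)
        means = []
        for kappa in (0.5, 2.0, 8.0):
            vals = []
            for seed in range(6):
                params = al.ConditionParams(assr_kappa=kappa, n1_amp_uv=0.0)
                rec = al.synth_continuous(proto, ev, params, channels=["AC"],
                                          seed=seed)
                ep = al.extract_epochs(rec, ev, "train_start", 2.0, 2.5)
                vals.append(al.assr_metrics(al.morlet_tf(ep, assr_freqs)).itc40_mp)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_negative_onset_rejected(self):
        proto, ev = al.build_erp_protocol(2, 3.5, 0.5)
        ev.loc[0, "onset_s"] = -1.0
        with pytest.raises(SimulationError):
            al.synth_continuous(proto, ev, al.condition_params("vehicle"),
                                channels=["AC"], seed=0)


class TestSynthSpikeTrains:
    def test_poisson_rate_recovery(self):
        # no stimulus / opto modulation: homogeneous Poisson at the base rate
        proto, ev = al.build_assr_protocol(1, 40, 2, 10)
        params = al.ConditionParams(n_units=1, rate_sigma=0.0,
                                    rate_median_hz=10.0, in_gain=1.0,
                                    mp_gain=1.0, mp_mod_depth=0.0,
                                    pv_fraction=0.0)
        spikes = al.synth_spike_trains(proto, ev, None, params, seed=0,
                                       pad_s=1000.0)
        u = spikes.units[0]
        span = 2 + 1000.0
        rate = len(u.spike_times_s) / span
        assert rate == pytest.approx(10.0, abs=3 * np.sqrt(10 / span))

    def test_full_pv_suppression_silences_trains(self):
        proto, ev = al.build_assr_protocol(10, 40, 2, 5)
        flags = np.ones(10, dtype=bool)
        params = al.ConditionParams(n_units=4, pv_fraction=1.0,
                                    opto_suppression=0.0, rate_median_hz=20.0)
        spikes = al.synth_spike_trains(proto, ev, flags, params, seed=1)
        onsets = np.sort(ev.loc[ev.event_type == "train_start",
                                "onset_s"].to_numpy())
        for u in spikes.units:
            for t0 in onsets:
                inside = (u.spike_times_s >= t0) & (u.spike_times_s < t0 + 2)
                assert not inside.any()

    def test_pv_fraction_count(self):
        proto, ev = al.build_assr_protocol(1, 40, 2, 10)
        params = al.ConditionParams(n_units=40, pv_fraction=0.15)
        spikes = al.synth_spike_trains(proto, ev, None, params, seed=2)
        assert sum(u.pv for u in spikes.units) == 6

    def test_ly_tightening_halves_rate_spread(self):
        proto, ev = al.build_assr_protocol(1, 40, 2, 10)
        base = al.ConditionParams(n_units=60, pv_fraction=0.0)
        tight = al.ConditionParams(n_units=60, pv_fraction=0.0,
                                   ly_tightening=0.5)
        r0 = [u.baseline_rate_hz
              for u in al.synth_spike_trains(proto, ev, None, base, seed=3).units]
        r1 = [u.baseline_rate_hz
              for u in al.synth_spike_trains(proto, ev, None, tight, seed=3).units]
        ratio = np.std(r1, ddof=1) / np.std(r0, ddof=1)
        assert ratio == pytest.approx(0.5, rel=0.15)

    def test_timestamps_sorted_unique_40khz(self):
        proto, ev = al.build_assr_protocol(5, 40, 2, 5)
        spikes = al.synth_spike_trains(proto, ev, None,
                                       al.condition_params("vehicle"), seed=4)
        for u in spikes.units:
            t = u.spike_times_s
            assert np.all(np.diff(t) > 0)
            assert np.allclose(np.round(t * 40000), t * 40000)

    def test_bit_reproducibility(self):
        proto, ev = al.build_assr_protocol(3, 40, 2, 5)
        p = al.condition_params("vehicle")
        a = al.synth_spike_trains(proto, ev, None, p, seed=5)
        b = al.synth_spike_trains(proto, ev, None, p, seed=5)
        for ua, ub in zip(a.units, b.units):
            assert np.array_equal(ua.spike_times_s, ub.spike_times_s)


class TestConditionPresets:
    def test_mk801_directions(self):
        v, mk = al.condition_params("vehicle"), al.condition_params("MK801")
        assert mk.n1_amp_uv < v.n1_amp_uv
        assert mk.gating_g > v.gating_g  # S2/S1 closer to 1: weaker gating
        assert mk.basal_gamma_sd_uv > v.basal_gamma_sd_uv
        assert mk.assr_amp_uv < v.assr_amp_uv
        assert mk.assr_kappa < v.assr_kappa

    def test_rescue_is_dose_monotone_except_power(self):
        mk = al.condition_params("MK801")
        lo = al.condition_params("MK801+LY@1")
        hi = al.condition_params("MK801+LY@3")
        v = al.condition_params("vehicle")
        for attr in ("n1_amp_uv", "assr_kappa"):
            assert getattr(mk, attr) < getattr(lo, attr) < getattr(hi, attr) \
                <= getattr(v, attr)
        assert mk.gating_g > lo.gating_g > hi.gating_g >= v.gating_g
        assert mk.basal_gamma_sd_uv > lo.basal_gamma_sd_uv \
            > hi.basal_gamma_sd_uv >= v.basal_gamma_sd_uv
        # 40 Hz power is *not* rescued by the agonist
        assert lo.assr_amp_uv == hi.assr_amp_uv == mk.assr_amp_uv

    def test_opto_overlay(self):
        p = al.condition_params("saline", opto_model=True)
        assert p.opto_gamma_factor > 1.0
        assert p.opto_kappa_factor < 1.0
        assert p.opto_suppression < 1.0 <= p.disinhibition

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            al.condition_params("placebo")
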