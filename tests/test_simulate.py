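import math

import numpy as np
import pytest
from scipy.stats import vonmises

from eegfc.bands import BAND_BY_NAME
from eegfc.connectivity import band_phase_epochs, instantaneous_phase, plv, subject_connectivity
from eegfc.recording import GROUP_A, GROUP_B
from eegfc.simulate import (ConfigurationError, CouplingSpec, SimulationConfig,
                            _vonmises_jitter, default_config, expected_plv,
                            generate_cohort, load_cohort, write_cohort)
from eegfc.spectral import band_power, welch_psd


def _pair_config(kappa, band="beta1", duration=120.0, noise=0.0, seed=7,
                 lag=np.pi / 4):
    amp = np.zeros((2, 4))
    amp[:, ["theta", "alpha", "beta1", "beta2"].index(band)] = 10.0
    return SimulationConfig(
        n_per_group=1, channel_labels=["F3", "P3"], duration_s=duration,
        noise_scale=noise, band_amplitudes={"A": amp, "B": amp},
        couplings=[CouplingSpec(("F3", "P3"), band, lag, kappa)], seed=seed)


def epoch_averaged_pair_plv(recording, epoch_len=500):
    """PLV of the two channels from clean-signal Hilbert phases, 2-s epochs."""
    phases = instantaneous_phase(recording.data)
    n = (phases.shape[1] // epoch_len) * epoch_len
    eps = phases[:, :n].reshape(2, -1, epoch_len)
    return float(np.mean([plv(eps[0, k], eps[1, k])
                          for k in range(eps.shape[1])]))


class TestConfigValidation:
    def test_unknown_coupling_channel_named(self):
        with pytest.raises(ConfigurationError, match="O1"):
            SimulationConfig(n_per_group=1, channel_labels=["F3", "P3"],
                            couplings=[CouplingSpec(("F3", "O1"), "alpha",
                                                    0.1, 1.0)])

    def test_negative_kappa(self):
        with pytest.raises(ConfigurationError, match="kappa"):
            CouplingSpec(("F3", "P3"), "alpha", 0.1, -1.0)

    def test_lag_out_of_range(self):
        with pytest.raises(ConfigurationError, match="lag"):
            CouplingSpec(("F3", "P3"), "alpha", 4.0, 1.0)

    def test_identical_pair_members(self):
        with pytest.raises(ConfigurationError, match="distinct"):
            CouplingSpec(("F3", "F3"), "alpha", 0.1, 1.0)

    def test_short_duration_rejected(self):
        with pytest.raises(ConfigurationError, match="duration"):
            SimulationConfig(duration_s=3.0)

    def test_bad_mixing_diagonal(self):
        with pytest.raises(ConfigurationError, match="diagonal"):
            SimulationConfig(n_per_group=1, channel_labels=["F3", "P3"],
                            mixing=np.array([[1.0, 0.0], [0.5, -1.0]]))

    def test_negative_amplitudes_rejected(self):
        amp = -np.ones((2, 4))
        with pytest.raises(ConfigurationError, match="amplitude"):
            SimulationConfig(n_per_group=1, channel_labels=["F3", "P3"],
                            band_amplitudes={"A": amp, "B": amp})


class TestGenerateCohort:
    def test_counts_groups_and_intervals(self):
        cfg = default_config(n_per_group=2, duration_s=8.0, seed=0)
        recs = generate_cohort(cfg)
        assert len(recs) == 4
        assert [r.group_label for r in recs] == [GROUP_A] * 2 + [GROUP_B] * 2
        for r in recs:
            assert r.data.shape == (19, 2000)
            assert r.eyes_closed_intervals == [(0.0, 8.0)]

    def test_determinism(self):
        cfg = default_config(n_per_group=1, duration_s=8.0, seed=11)
        a = generate_cohort(cfg)
        b = generate_cohort(default_config(n_per_group=1, duration_s=8.0, seed=11))
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.data, rb.data)

    def test_seed_changes_data(self):
        a = generate_cohort(default_config(n_per_group=1, duration_s=8.0, seed=1))
        b = generate_cohort(default_config(n_per_group=1, duration_s=8.0, seed=2))
        assert not np.allclose(a[0].data, b[0].data)

    def test_band_power_monotone_in_amplitude(self, rng):
        powers = []
        for amp_value in (2.0, 5.0, 10.0):
            amp = np.zeros((2, 4))
            amp[0, 1] = amp_value
            cfg = SimulationConfig(n_per_group=1, channel_labels=["F3", "P3"],
                                   duration_s=8.0, noise_scale=1.0,
                                   band_amplitudes={"A": amp, "B": amp}, seed=3)
            rec = generate_cohort(cfg)[0]
            freqs, psd = welch_psd(rec.data[:, :500], 250.0)
            powers.append(band_power(freqs, psd, BAND_BY_NAME["alpha"])[0])
        assert powers[0] < powers[1] < powers[2]

    def test_frontal_preset_amplitudes(self):
        cfg = default_config()
        labels = list(cfg.channel_labels)
        a, b = cfg.band_amplitudes[GROUP_A], cfg.band_amplitudes[GROUP_B]
        fp1 = labels.index("Fp1")
        o1 = labels.index("O1")
        assert np.allclose(a[fp1], 1.3 * b[fp1])
        assert np.allclose(a[o1], b[o1])


class TestJitterMarginal:
    @pytest.mark.parametrize("kappa", [0.5, 4.0])
    def test_mean_resultant_matches_vonmises(self, kappa):
        d = _vonmises_jitter(np.random.default_rng(0), 60000, 250.0, kappa)
        emp = abs(np.exp(1j * d).mean())
        assert emp == pytest.approx(expected_plv(kappa), abs=0.03)

    def test_quantiles_match_vonmises(self):
        d = _vonmises_jitter(np.random.default_rng(1), 60000, 250.0, 2.0)
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            assert np.quantile(d, q) == pytest.approx(
                vonmises.ppf(q, 2.0), abs=0.05)

    def test_expected_plv_monte_carlo_oracle(self):
        # direct i.i.d. von Mises sampling cross-checks the Bessel ratio
        rng = np.random.default_rng(2)
        for kappa in (0.5, 2.0, 8.0):
            draws = vonmises.rvs(kappa, size=200_000, random_state=rng)
            assert abs(np.exp(1j * draws).mean()) == pytest.approx(
                expected_plv(kappa), abs=0.01)

    def test_expected_plv_limits(self):
        assert expected_plv(0.0) == 0.0
        assert expected_plv(1e6) == pytest.approx(1.0, abs=1e-5)


class TestPlvRecovery:
    @pytest.mark.parametrize("kappa", [0.5, 8.0])
    def test_recovery_within_tolerance(self, kappa):
        recs = generate_cohort(_pair_config(kappa))
        emp = np.mean([epoch_averaged_pair_plv(r) for r in recs])
        assert abs(emp - expected_plv(kappa)) < 0.05

    def test_no_jitter_constant_lag_locks_fully(self):
        cfg = _pair_config(kappa=1e9, lag=np.pi / 2, duration=20.0)
        rec = generate_cohort(cfg)[0]
        phases = band_phase_epochs(rec)
        pv = subject_connectivity(phases, "plv")
        cv = subject_connectivity(phases, "ciplv")
        b = list(pv.band_names).index("beta1")
        assert pv.values[b][0] > 0.99
        assert cv.values[b][0] > 0.99


class TestIndependenceAndMixing:
    def test_uncoupled_pairs_near_null(self):
        amp = np.full((3, 4), 8.0)
        cfg = SimulationConfig(n_per_group=1, channel_labels=["F3", "C3", "P3"],
                               duration_s=60.0, noise_scale=1.0,
                               band_amplitudes={"A": amp, "B": amp}, seed=9)
        rec = generate_cohort(cfg)[0]
        feats = subject_connectivity(band_phase_epochs(rec), "plv")
        # Independent same-band narrowband oscillators cannot reach the
        # i.i.d.-uniform null (~1/sqrt(T)) inside a 2-s epoch; the phase
        # diffusion keeps uncoupled pairs well below coupled ones instead.
        assert feats.values.max() < 0.6

    def test_zero_lag_mixing_dissociation(self):
        amp = np.zeros((2, 4))
        amp[0, 1] = 10.0
        mix = np.array([[1.0, 0.0], [0.9, 1.0]])
        cfg = SimulationConfig(n_per_group=1, channel_labels=["F3", "P3"],
                               duration_s=60.0, noise_scale=0.5,
                               band_amplitudes={"A": amp, "B": amp},
                               mixing=mix, seed=3)
        rec = generate_cohort(cfg)[0]
        phases = band_phase_epochs(rec)
        pv = subject_connectivity(phases, "plv")
        cv = subject_connectivity(phases, "ciplv")
        b = list(pv.band_names).index("alpha")
        assert pv.values[b][0] > 0.8
        assert cv.values[b][0] < 0.1


class TestCohortIO:
    def test_write_load_roundtrip(self, tmp_path, small_cohort):
        write_cohort(small_cohort[:3], tmp_path)
        back = load_cohort(tmp_path)
        assert [r.subject_id for r in back] == [r.subject_id
                                               for r in small_cohort[:3]]
        assert [r.group_label for r in back] == [r.group_label
                                                 for r in small_cohort[:3]]
        for orig, rt in zip(small_cohort[:3], back):
            assert rt.eyes_closed_intervals == orig.eyes_closed_intervals
            step = (orig.data.max(axis=1) - orig.data.min(axis=1)) / 65535
            assert np.all(np.abs(rt.data - orig.data) <= step[:, None] + 1e-12)
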