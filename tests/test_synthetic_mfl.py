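"""Emulator composition, noise statistics, CSV round-trip, determinism."""

import numpy as np
import pytest

from fontanjet import (InjectionProtocol, SensorModel, baseline_rpa,
                       cycle_average, entrainment_rate, read_waveform_csv,
                       write_waveform_csv)
from fontanjet.errors import AliasingError, FormatError
from fontanjet.synthetic_mfl import (EntrainmentEmulation, add_sensor_noise,
                                     compose_noiseless, emulate_mfl,
                                     entrainment_envelope)
from fontanjet.waveform import WaveformRecord


class TestCsvRoundTrip:
    def test_lossless_round_trip(self, baseline_record, tmp_path):
        path = tmp_path / "rec.csv"
        write_waveform_csv(baseline_record, path)
        back = read_waveform_csv(path)
        np.testing.assert_array_equal(back.time, baseline_record.time)
        for name, x in baseline_record.channels.items():
            np.testing.assert_array_equal(back.channels[name], x)
        assert back.sampling_rate == baseline_record.sampling_rate
        assert back.metadata["provenance"] == "simulated"

    def test_shuffled_column_order_parses_identically(self, tmp_path):
        t = np.arange(0.0, 1.0, 0.01)
        rec = WaveformRecord(t, {"q_rpa": np.sin(t), "q_lpa": np.cos(t)}, 100.0)
        p1 = tmp_path / "a.csv"
        write_waveform_csv(rec, p1)
        lines = p1.read_text().splitlines()
        header = lines[-len(t) - 1].split(",")
        order = [0, 2, 1]  # time_s, q_lpa, q_rpa
        shuffled = [",".join(row.split(",")[i] for i in order)
                    for row in lines[-len(t) - 1:]]
        p2 = tmp_path / "b.csv"
        p2.write_text("\n".join(lines[:-len(t) - 1] + shuffled))
        back = read_waveform_csv(p2)
        np.testing.assert_allclose(back.channels["q_rpa"], rec.channels["q_rpa"])
        np.testing.assert_allclose(back.channels["q_lpa"], rec.channels["q_lpa"])

    def test_time_gap_rejected(self, tmp_path):
        t = np.concatenate([np.arange(0.0, 1.0, 0.01),
                            np.arange(2.0, 3.0, 0.01)])
        path = tmp_path / "gap.csv"
        path.write_text(
            "# fontanjet-waveform v1\n# sampling_rate=100.0\ntime_s,q_rpa\n"
            + "\n".join(f"{ti},1.0" for ti in t))
        with pytest.raises(FormatError):
            read_waveform_csv(path)

    def test_duplicate_channel_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "# fontanjet-waveform v1\n# sampling_rate=100.0\n"
            "time_s,q_rpa,q_rpa\n0.0,1.0,1.0\n0.01,1.0,1.0\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_waveform_csv(path)


class TestEnvelope:
    def test_plateau_and_decay_closed_form(self):
        emu = EntrainmentEmulation(magnitude=0.3, tau_rise=0.4, tau_fall=0.1)
        t = np.arange(0.0, 30.0, 0.001)
        env = entrainment_envelope(t, [(5.0, 15.0)], emu)
        assert env[t < 5.0].max() == 0.0
        # on-phase follows 0.3*(1-exp(-x/0.4))
        x = t[(t >= 5.0) & (t < 15.0)] - 5.0
        np.testing.assert_allclose(env[(t >= 5.0) & (t < 15.0)],
                                   0.3 * (1 - np.exp(-x / 0.4)), atol=1e-9)
        # off-phase decays with tau_fall from the level reached
        lvl = 0.3 * (1 - np.exp(-10.0 / 0.4))
        x2 = t[t >= 15.0] - 15.0
        np.testing.assert_allclose(env[t >= 15.0], lvl * np.exp(-x2 / 0.1),
                                   atol=1e-9)


class TestEmulator:
    def test_pure_superposition_when_entrainment_zero(self, params):
        """E0 = 0, no noise: plateau mean minus baseline mean = Q_inj <1%."""
        proto = InjectionProtocol(0, "continuous", 10.0, 1, 100.0,
                                  start_time=12.0)
        clean = compose_noiseless(params, proto,
                                  EntrainmentEmulation(magnitude=0.0))
        pre = cycle_average(clean, "q_rpa", (3.0, 12.0))
        plateau = cycle_average(clean, "q_rpa", (14.0, 21.5))
        assert plateau - pre == pytest.approx(proto.rate_l_min, rel=0.01)

    def test_noiseless_ground_truth_recovery(self, params):
        """Programmed E0=+0.2 on a 0.3 L/min jet is recovered +/-0.01."""
        proto = InjectionProtocol(0, "continuous", 5.0, 1, 100.0,
                                  start_time=12.0)  # 0.3 L/min, 20 s on
        clean = compose_noiseless(params, proto,
                                  EntrainmentEmulation(magnitude=0.2))
        q_s = (cycle_average(clean, "q_upper", (3.0, 12.0))
               + cycle_average(clean, "q_lower", (3.0, 12.0)))
        q_meas = cycle_average(clean, "q_rpa", (17.0, 31.25))
        res = entrainment_rate(q_meas, baseline_rpa(q_s, 0.5), proto.rate_l_min)
        assert res.q_ent == pytest.approx(0.2, abs=0.01)
        assert res.label == "entrainment"

    def test_same_seed_bitwise_identical(self, params, case12_protocol,
                                         case12_clean):
        a = add_sensor_noise(case12_clean, SensorModel(seed=99))
        b = add_sensor_noise(case12_clean, SensorModel(seed=99))
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name], b.channels[name])

    def test_seed_isolation(self, case12_clean):
        """Different seeds change only the additive noise component."""
        a = add_sensor_noise(case12_clean, SensorModel(seed=1))
        b = add_sensor_noise(case12_clean, SensorModel(seed=2))
        assert not np.array_equal(a.channels["q_rpa"], b.channels["q_rpa"])
        # both fluctuate around the same clean signal
        for rec in (a, b):
            resid = rec.channels["q_rpa"] - case12_clean.channels["q_rpa"]
            assert abs(np.mean(resid)) < 0.01

    def test_zero_noise_returns_clean_record(self, case12_clean):
        quiet = SensorModel(flow_noise_sd=0.0, pressure_noise_sd=0.0,
                            mains_amplitude_flow=0.0,
                            mains_amplitude_pressure=0.0, seed=5)
        rec = add_sensor_noise(case12_clean, quiet)
        np.testing.assert_array_equal(rec.channels["q_rpa"],
                                      case12_clean.channels["q_rpa"])

    def test_noise_sd_matches_model(self):
        """Residual SD within 10% of the configured SD at n >= 1e4."""
        t = np.arange(0.0, 120.0, 0.01)  # 12000 samples
        clean = WaveformRecord(t, {"q_rpa": np.full_like(t, 1.2),
                                   "p_rpa": np.full_like(t, 7.7)}, 100.0)
        sensor = SensorModel(flow_noise_sd=0.05, pressure_noise_sd=0.4,
                             mains_amplitude_flow=0.0,
                             mains_amplitude_pressure=0.0, seed=3)
        rec = add_sensor_noise(clean, sensor)
        assert rec.time.size >= 10_000
        for name, sd in (("q_rpa", 0.05), ("p_rpa", 0.4)):
            resid = rec.channels[name] - clean.channels[name]
            assert np.std(resid) == pytest.approx(sd, rel=0.10)

    def test_sub_cardiac_sampling_rejected(self, params, case12_protocol):
        with pytest.raises(AliasingError):
            emulate_mfl(params, case12_protocol,
                        SensorModel(sampling_rate=2.0))
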