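"""Synthetic cohort generator: shapes, determinism, spectral targets, artifacts."""

import numpy as np
import pytest
from scipy.signal import periodogram

from eegmarkers import (
    ArtifactSpec,
    CohortConfig,
    SubjectSpec,
    generate_cohort,
    generate_subject_trials,
    inject_artifacts,
    make_subject_specs,
)


def alpha_spec(cfg, peak_hz=10.0, gain=5.0, noise_sd=0.05, seed=7):
    """A subject whose channel 0 is dominated by the alpha oscillator."""
    gains = np.zeros((3, cfg.n_channels))
    gains[1, 0] = gain  # independent alpha oscillator on channel 0
    mixing = np.zeros((3, cfg.n_channels))
    mixing[1, :] = 0.2
    return SubjectSpec(subject_id="S0", group="young", alpha_peak_hz=peak_hz,
                       band_gains=gains, mixing=mixing, noise_sd=noise_sd, seed=seed)


def fitted_alpha_peak(trials, channel, fs, lo=6.0, hi=14.0):
    """Oracle: trial-averaged periodogram peak within the alpha search window."""
    f, p = periodogram(trials.data[:, channel, :], fs=fs, axis=-1)
    p = p.mean(axis=0)
    mask = (f >= lo) & (f <= hi)
    return f[mask][np.argmax(p[mask])]


def test_default_config_mirrors_study_dimensions():
    cfg = CohortConfig()
    assert cfg.n_young == 22 and cfg.n_elderly == 23
    assert cfg.n_channels == 64 and cfg.fs == 1000.0
    assert cfg.n_samples == 1500
    specs = make_subject_specs(cfg)
    assert len(specs) == 45
    assert sum(s.group == "young" for s in specs) == 22
    assert sum(s.group == "elderly" for s in specs) == 23
    # one cell of trials has the study's epoch shape
    cfg_small_trials = CohortConfig(n_trials_per_condition=2)
    ts = generate_subject_trials(make_subject_specs(cfg_small_trials)[0],
                                 cfg_small_trials, "car_high")
    assert ts.data.shape == (2, 64, 1500)


def test_generation_is_deterministic(small_cohort_cfg):
    spec = make_subject_specs(small_cohort_cfg)[0]
    a = generate_subject_trials(spec, small_cohort_cfg, "a")
    b = generate_subject_trials(spec, small_cohort_cfg, "a")
    assert np.array_equal(a.data, b.data)
    c = generate_subject_trials(spec, small_cohort_cfg, "b")
    assert not np.array_equal(a.data, c.data)


def test_cohort_is_pure_function_of_config(small_cohort_cfg, small_cohort):
    again = generate_cohort(small_cohort_cfg)
    for key in small_cohort.trialsets:
        assert np.array_equal(small_cohort.trialsets[key].data, again.trialsets[key].data)


def test_oscillator_psd_peak_at_alpha_frequency():
    cfg = CohortConfig(n_young=1, n_elderly=1, n_channels=4, trial_len_ms=4000.0,
                       n_trials_per_condition=8, conditions=("c",),
                       background_scale=0.05, seed=1)
    ts = generate_subject_trials(alpha_spec(cfg), cfg, "c")
    f, p = periodogram(ts.data[:, 0, :], fs=cfg.fs, axis=-1)
    p = p.mean(axis=0)
    df = f[1] - f[0]
    assert abs(f[np.argmax(p)] - 10.0) <= 2 * df + 1e-9


def test_group_alpha_peak_difference_recovered():
    cfg = CohortConfig(n_young=5, n_elderly=5, n_channels=8,
                       n_trials_per_condition=10, conditions=("c",),
                       alpha_peak_young_hz=10.0, alpha_peak_elderly_hz=9.0,
                       alpha_peak_sd_hz=0.5, seed=33)
    specs = make_subject_specs(cfg)
    occ = cfg.occipital_channels[-1]
    peaks = {"young": [], "elderly": []}
    for spec in specs:
        ts = generate_subject_trials(spec, cfg, "c")
        peaks[spec.group].append(fitted_alpha_peak(ts, occ, cfg.fs))
    diff = np.mean(peaks["young"]) - np.mean(peaks["elderly"])
    assert 0.4 < diff < 1.6  # 1 Hz shift within sampling error of 5+5 subjects


def test_elderly_occipital_alpha_attenuation():
    cfg = CohortConfig(n_young=6, n_elderly=6, n_channels=8,
                       alpha_peak_elderly_hz=10.0, alpha_peak_sd_hz=0.0,
                       occipital_attenuation=0.5, seed=4)
    specs = make_subject_specs(cfg)
    occ = cfg.occipital_channels
    a = 1  # alpha band row
    young = np.mean([s.band_gains[a, occ].mean() for s in specs if s.group == "young"])
    old = np.mean([s.band_gains[a, occ].mean() for s in specs if s.group == "elderly"])
    assert old < 0.75 * young


def test_null_cohort_groups_exchangeable_in_parameters():
    cfg = CohortConfig(n_young=20, n_elderly=20, n_channels=8,
                       alpha_peak_elderly_hz=10.0, occipital_attenuation=1.0, seed=2)
    specs = make_subject_specs(cfg)
    peaks = {"young": [], "elderly": []}
    gains = {"young": [], "elderly": []}
    for s in specs:
        peaks[s.group].append(s.alpha_peak_hz)
        gains[s.group].append(s.band_gains.mean())
    assert abs(np.mean(peaks["young"]) - np.mean(peaks["elderly"])) < 0.5
    assert abs(np.mean(gains["young"]) - np.mean(gains["elderly"])) < 0.1


def test_shared_source_induces_cross_channel_correlation(small_cohort_cfg):
    """Channels sharing the occipital alpha source co-vary more than others."""
    from eegmarkers import BandDefinition, coherence_matrix, trial_spectra

    cfg = small_cohort_cfg
    ts = generate_subject_trials(make_subject_specs(cfg)[0], cfg, "a")
    occ = cfg.occipital_channels  # strong shared alpha mixing
    adj = coherence_matrix(trial_spectra(ts), band=BandDefinition.named("alpha"))
    shared = adj.values[occ[0], occ[1]]
    frontal_pair = adj.values[0, 1]  # weak alpha mixing (0.3 vs 1.0)
    assert shared > frontal_pair


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError, match="whole positive"):
        CohortConfig(trial_len_ms=1000.3)
    with pytest.raises(ValueError, match="at least one subject"):
        CohortConfig(n_young=0)
    cfg = CohortConfig(n_young=1, n_elderly=1, n_channels=2,
                       n_trials_per_condition=1, conditions=("c",))
    bad = alpha_spec(cfg, peak_hz=600.0)
    with pytest.raises(ValueError, match="Nyquist"):
        generate_subject_trials(bad, cfg, "c")


# ------------------------------------------------------------------ artifacts


def test_zero_rates_are_a_no_op(one_subject_trials):
    art = ArtifactSpec(blink_rate=0, muscle_rate=0, jump_prob=0, clip_prob=0)
    out, log = inject_artifacts(one_subject_trials, art, seed=1)
    assert np.array_equal(out.data, one_subject_trials.data)
    assert log.empty


def test_single_jump_bookkeeping(one_subject_trials):
    art = ArtifactSpec(blink_rate=0, muscle_rate=0, jump_prob=1.0, clip_prob=0,
                       jump_amp_sd=50.0)
    out, log = inject_artifacts(one_subject_trials, art, seed=2)
    assert set(log.kind) == {"jump"}
    assert len(log) == one_subject_trials.n_trials  # probability 1: one per trial
    for _, ev in log.iterrows():
        step = (out.data[ev.trial, ev.channel, ev.start]
                - one_subject_trials.data[ev.trial, ev.channel, ev.start])
        sd = one_subject_trials.data[ev.trial, ev.channel].std()
        assert step == pytest.approx(50.0 * sd, rel=1e-9)


def test_muscle_bursts_raise_high_band_power(one_subject_trials):
    from scipy.signal import butter, sosfiltfilt

    art = ArtifactSpec(blink_rate=0, muscle_rate=0.5, jump_prob=0, clip_prob=0)
    out, log = inject_artifacts(one_subject_trials, art, seed=3)
    sos = butter(4, (120.0, 140.0), btype="bandpass", fs=1000.0, output="sos")
    band_clean = sosfiltfilt(sos, one_subject_trials.data, axis=2)
    band_dirty = sosfiltfilt(sos, out.data, axis=2)
    hit = log[log.kind == "muscle"]
    assert len(hit) > 0
    for _, ev in hit.iterrows():
        p_dirty = np.mean(band_dirty[ev.trial, ev.channel, ev.start:ev.end] ** 2)
        p_clean = np.mean(band_clean[ev.trial, ev.channel, ev.start:ev.end] ** 2)
        assert p_dirty > 10 * p_clean


def test_band_above_nyquist_rejected(one_subject_trials):
    art = ArtifactSpec(muscle_band=(480.0, 520.0))
    with pytest.raises(ValueError, match="Nyquist"):
        inject_artifacts(one_subject_trials, art, seed=0)
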