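"""M-MCRA noise tracker: SPP recursion, gated covariance update, convergence."""

import numpy as np
import pytest

from eegfuse.mcra import (McraParams, NoiseTrackerState, iter_tracker,
                          run_tracker, update_noise_covariance, update_spp)
from eegfuse.stft import MultichannelSpectrogram, StftConfig, stft
from eegfuse.synthetic import SceneConfig, generate_recording


def _spec_from_frames(frames, fs=200.0):
    """Wrap (M, K, T) complex data as a spectrogram (K must be nfft/2+1)."""
    cfg = StftConfig(sample_rate=fs)
    m, k, t = frames.shape
    assert k == cfg.n_bins
    return MultichannelSpectrogram(values=frames, config=cfg,
                                   original_length=t * cfg.hop_samples)


def _random_frames(rng, m, k, t, scale=1.0):
    return scale * (rng.standard_normal((m, k, t))
                    + 1j * rng.standard_normal((m, k, t))) / np.sqrt(2)


def test_spp_recursion_matches_definition(rng):
    """p_new = alpha_p * p_prev + (1 - alpha_p) * indicator, exactly."""
    params = McraParams(alpha_p=0.2)
    state = NoiseTrackerState.initialize(9, 2, params)
    y = rng.standard_normal((2, 9)) + 1j * rng.standard_normal((2, 9))
    # drive a few frames to populate history
    for _ in range(3):
        update_spp(state, y, params)
    p_prev = state.spp.copy()
    s_prev = state.smoothed_power.copy()
    energy = np.sum(np.abs(2 * y) ** 2, axis=0)
    s_new = params.alpha_s * s_prev + (1 - params.alpha_s) * energy
    update_spp(state, 2 * y, params)
    smin = state.min_power
    indicator = (s_new / smin > params.delta_ratio).astype(float)
    assert np.allclose(state.spp, 0.2 * p_prev + 0.8 * indicator)


def test_stationary_input_drives_spp_to_zero(rng):
    """Constant-power noise: ratio -> 1 < delta, so SPP decays to zero."""
    params = McraParams()
    frames = _random_frames(rng, 4, 9, 400)
    _, spp = run_tracker(_spec_from_frames(frames), params)
    assert spp[-50:].mean() < 0.05


def test_energy_jump_fires_spp(rng):
    """A 20x energy jump after a quiet stretch raises p within a few frames."""
    params = McraParams(alpha_p=0.2)
    quiet = _random_frames(rng, 3, 9, 150, scale=1.0)
    loud = _random_frames(rng, 3, 9, 10, scale=np.sqrt(20.0))
    frames = np.concatenate([quiet, loud], axis=2)
    _, spp = run_tracker(_spec_from_frames(frames), params)
    assert spp[149].mean() < 0.1
    assert spp[154].mean() > 0.9   # 1 - 0.2^5 > 0.999 of the way to 1


def test_spp_scalar_oracle_single_channel(rng):
    """M=1 tracker equals an independently coded scalar MCRA recursion."""
    params = McraParams(vmin_frames=16)
    t = 120
    y = (rng.standard_normal((1, 9, t)) + 1j * rng.standard_normal((1, 9, t)))
    y[:, :, 60:] *= 6.0
    _, spp = run_tracker(_spec_from_frames(y), params)

    # scalar oracle, bin by bin
    for k in range(9):
        s = None
        p = 0.0
        hist = []
        ps = []
        for l in range(t):
            e = abs(y[0, k, l]) ** 2
            s = e if s is None else params.alpha_s * s + (1 - params.alpha_s) * e
            hist.append(s)
            smin = min(hist[-params.vmin_frames:])
            ratio = s / smin if smin > 0 else (np.inf if s > 0 else 1.0)
            ind = 1.0 if ratio > params.delta_ratio else 0.0
            p = params.alpha_p * p + (1 - params.alpha_p) * ind
            ps.append(p)
        assert np.allclose(spp[:, k], ps, atol=1e-12)


def test_covariance_update_is_eq1(rng):
    """alpha_d = 0 gives R_nn = y y^H exactly; p = 1 freezes R_nn."""
    params = McraParams(alpha_floor=0.0, init_frames=0)
    state = NoiseTrackerState.initialize(9, 3, params)
    y = rng.standard_normal((3, 9)) + 1j * rng.standard_normal((3, 9))
    update_spp(state, y, params)
    state.spp[:] = 0.0
    update_noise_covariance(state, y, params)
    outer = y.T[:, :, None] * np.conj(y.T[:, None, :])
    assert np.allclose(state.r_nn, outer, atol=1e-12)

    r_prev = state.r_nn.copy()
    y2 = rng.standard_normal((3, 9)) + 1j * rng.standard_normal((3, 9))
    update_spp(state, y2, params)
    state.spp[:] = 1.0   # signal surely present -> freeze
    update_noise_covariance(state, y2, params)
    assert np.allclose(state.r_nn, r_prev, atol=1e-12)
    assert np.allclose(state.alpha_d, 1.0)


def test_alpha_d_mapping_monotone_in_p():
    params = McraParams(alpha_floor=0.85)
    ps = np.linspace(0, 1, 11)
    alphas = params.alpha_floor + ps * (1 - params.alpha_floor)
    assert np.all(np.diff(alphas) > 0)
    assert alphas[0] == pytest.approx(0.85) and alphas[-1] == pytest.approx(1.0)


def test_monotone_trust_larger_p_keeps_rnn_closer(rng):
    """For the same history/frame, higher SPP leaves R_nn nearer its previous value."""
    y = rng.standard_normal((4, 9)) + 1j * rng.standard_normal((4, 9))
    params = McraParams(init_frames=0)
    dists = []
    for p in (0.1, 0.5, 0.9):
        state = NoiseTrackerState.initialize(9, 4, params)
        state.r_nn[:] = np.eye(4)
        state.frame_index = 10
        state.spp[:] = p
        r_prev = state.r_nn.copy()
        state.frame_index += 1
        update_noise_covariance(state, y, params)
        dists.append(np.linalg.norm(state.r_nn - r_prev))
    assert dists[0] > dists[1] > dists[2]


def test_covariance_convergence_to_truth(rng):
    """2000 stationary frames, p pinned low: R_nn within 15% of sigma^2 I,
    and equal to a directly-summed exponentially weighted average.

    The smoothing floor is raised to 0.995 for this measurement: an
    exponentially weighted covariance has relative error ~sqrt(M/n_eff)
    with n_eff = (1+a)/(1-a), so meeting 15% at M=4 needs n_eff >~ 180.
    """
    m, t, sigma2 = 4, 2000, 2.0
    params = McraParams(alpha_floor=0.995, init_frames=5, min_bound_factor=0.0)
    y = np.sqrt(sigma2 / 2) * (rng.standard_normal((m, 1, t))
                               + 1j * rng.standard_normal((m, 1, t)))
    state = NoiseTrackerState.initialize(1, m, params)
    oracle = None
    for l in range(t):
        update_spp(state, y[:, :, l], params)
        state.spp[:] = 0.1   # pin p
        update_noise_covariance(state, y[:, :, l], params)
        # direct-recursion oracle (ignoring the 5-frame init window)
        outer = y[:, 0, l][:, None] * np.conj(y[:, 0, l][None, :])
        a = params.alpha_floor + 0.1 * (1 - params.alpha_floor)
        if l < params.init_frames:
            oracle = outer if oracle is None else (oracle * l + outer) / (l + 1)
        else:
            oracle = a * oracle + (1 - a) * outer
    truth = sigma2 * np.eye(m)
    rel = np.linalg.norm(state.r_nn[0] - truth) / np.linalg.norm(truth)
    assert rel < 0.15
    assert np.linalg.norm(state.r_nn[0] - oracle) / np.linalg.norm(oracle) < 1e-4


def test_causality_prefix_identical(rng):
    frames = _random_frames(rng, 3, 9, 80)
    spec = _spec_from_frames(frames)
    r_full, p_full = run_tracker(spec)
    trunc = _spec_from_frames(frames[:, :, :30])
    r_part, p_part = run_tracker(trunc)
    assert np.array_equal(r_full[:30], r_part)
    assert np.array_equal(p_full[:30], p_part)


def test_rnn_hermitian_psd_everywhere(rng):
    frames = _random_frames(rng, 3, 9, 60)
    r_all, _ = run_tracker(_spec_from_frames(frames))
    herm = np.conj(np.swapaxes(r_all, -1, -2))
    assert np.allclose(r_all, herm, atol=1e-12)
    eigs = np.linalg.eigvalsh(r_all.reshape(-1, 3, 3))
    assert eigs.min() > -1e-10


def test_zero_spectrogram_keeps_initialization():
    spec = _spec_from_frames(np.zeros((2, 9, 40), dtype=complex))
    r_all, spp = run_tracker(spec)
    assert np.allclose(r_all, 0.0)
    assert np.allclose(spp, 0.0)


def test_noise_only_scene_low_spp():
    """Pure stationary noise (no sources): mean SPP < 0.2 after warm-up."""
    cfg = SceneConfig(seed=5, n_channels=6, duration_s=20.0,
                      source_powers=(1e-6,) * 6, spike_rate=0.0,
                      target_snr_db=-40.0)
    _, noisy, _ = generate_recording(cfg)
    spec = stft(noisy, StftConfig(sample_rate=cfg.fs))
    _, spp = run_tracker(spec)
    assert spp[100:].mean() < 0.2


def test_bursty_scene_spp_higher_during_bursts(rng):
    """Bursts occupying ~10% of frames raise SPP relative to quiet frames."""
    params = McraParams()
    t = 400
    frames = _random_frames(rng, 4, 9, t)
    burst_mask = np.zeros(t, dtype=bool)
    for start in (100, 200, 300):
        burst_mask[start : start + 13] = True
    frames[:, :, burst_mask] *= 4.0
    _, spp = run_tracker(_spec_from_frames(frames), params)
    mean_burst = spp[burst_mask].mean()
    mean_quiet = spp[~burst_mask & (np.arange(t) > 64)].mean()
    assert mean_burst > mean_quiet


def test_nonfinite_frame_rejected():
    params = McraParams()
    state = NoiseTrackerState.initialize(9, 2, params)
    y = np.full((2, 9), np.nan, dtype=complex)
    with pytest.raises(ValueError):
        update_spp(state, y, params)


def test_param_validation():
    with pytest.raises(ValueError):
        McraParams(alpha_s=1.5)
    with pytest.raises(ValueError):
        McraParams(delta_ratio=0.5)
    with pytest.raises(ValueError):
        McraParams(pooling="median")
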