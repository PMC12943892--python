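"""GEVD joint diagonalization, gain law, mu schedule, and subspace filtering."""

import numpy as np
import pytest
import scipy.linalg

from eegfuse.gevd import (GainSchedule, SignalSubspaceRule, apply_filter,
                          component_gain, denoise, estimate_ryy, gevd,
                          mu_from_snr, select_n_sig)
from eegfuse.mcra import McraParams
from eegfuse.stft import StftConfig, istft, stft
from eegfuse.synthetic import SceneConfig, generate_recording, snr_db


def _random_spd(rng, m, complex_=True):
    x = rng.standard_normal((m, 2 * m))
    if complex_:
        x = x + 1j * rng.standard_normal((m, 2 * m))
    return x @ x.conj().T / (2 * m) + 0.1 * np.eye(m)


# ---------------------------------------------------------------- gevd core

@pytest.mark.parametrize("m", [2, 5, 16, 62])
def test_joint_diagonalization_residuals(m, rng):
    for _ in range(5):
        r_yy, r_nn = _random_spd(rng, m), _random_spd(rng, m)
        dec = gevd(r_yy, r_nn)
        v = dec.V
        i_res = np.linalg.norm(v.conj().T @ r_nn @ v - np.eye(m))
        d = v.conj().T @ r_yy @ v
        off = np.linalg.norm(d - np.diag(np.diag(d)))
        assert i_res < 1e-8 * max(1.0, np.linalg.norm(r_nn))
        assert off < 1e-8 * max(1.0, np.linalg.norm(r_yy))
        assert np.all(np.diff(dec.lambdas) <= 1e-12)
        assert np.all(dec.lambdas >= 0)


def test_identity_noise_reduces_to_plain_evd(rng):
    """r_nn = I: generalized eigenvalues equal the ordinary Hermitian EVD."""
    m = 6
    r_yy = _random_spd(rng, m)
    dec = gevd(r_yy, np.eye(m))
    w_ref = np.sort(scipy.linalg.eigh(r_yy, eigvals_only=True))[::-1]
    assert np.allclose(dec.lambdas, w_ref, rtol=1e-6)


def test_identity_pencil_all_eigenvalues_one(rng):
    r = _random_spd(rng, 5)
    dec = gevd(r, r)
    assert np.allclose(dec.lambdas, 1.0, atol=1e-6)


def test_rank_one_update_closed_form(rng):
    """r_yy = I + s u u^H, r_nn = I: lambda_1 = 1 + s, the rest 1."""
    m, s = 7, 3.7
    u = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    u /= np.linalg.norm(u)
    dec = gevd(np.eye(m) + s * np.outer(u, u.conj()), np.eye(m))
    assert dec.lambdas[0] == pytest.approx(1 + s, rel=1e-6)
    assert np.allclose(dec.lambdas[1:], 1.0, atol=1e-6)


def test_cholesky_whitening_oracle(rng):
    """Independent whitening-based solution agrees with the implementation."""
    m = 8
    r_yy, r_nn = _random_spd(rng, m), _random_spd(rng, m)
    dec = gevd(r_yy, r_nn)
    # oracle: L L^H = r_nn, EVD of L^{-1} r_yy L^{-H}
    ln = np.linalg.cholesky(r_nn)
    mid = np.linalg.solve(ln, r_yy)
    mid = np.linalg.solve(ln, mid.conj().T).conj().T
    w = np.sort(np.linalg.eigvalsh(mid))[::-1]
    assert np.allclose(dec.lambdas, w, rtol=1e-8, atol=1e-8)


# ----------------------------------------------------------- gain schedule

def test_mu_schedule_endpoints_and_midpoint():
    sched = GainSchedule()
    assert mu_from_snr(25.0, sched) == 1.0
    assert mu_from_snr(20.0, sched) == 1.0
    assert mu_from_snr(-10.0, sched) == 1201.0
    assert mu_from_snr(7.5, sched) == pytest.approx((1 + 1201) / 2)  # = 601


def test_mu_monotone_nonincreasing_in_snr():
    sched = GainSchedule()
    grid = np.linspace(-30, 40, 400)
    mus = np.array([mu_from_snr(s, sched) for s in grid])
    assert np.all(np.diff(mus) <= 1e-9)
    assert mus.max() == 1201.0 and mus.min() == 1.0


def test_component_gain_values():
    assert component_gain(2.0, 1.0) == pytest.approx(0.5)
    assert component_gain(1.0, 1.0) == 0.0
    assert component_gain(0.5, 7.0) == 0.0       # negative a priori SNR clipped
    assert component_gain(11.0, 1.0) == pytest.approx(10 / 11)
    assert component_gain(11.0, 100.0) == pytest.approx(10 / 110)


def test_gain_monotonicity_grids():
    lambdas = np.linspace(0.0, 50.0, 201)
    for mu in (1.0, 10.0, 100.0, 1201.0):
        g = component_gain(lambdas, mu)
        assert np.all(np.diff(g) >= 0)
        assert np.all((g >= 0) & (g < 1))
    mus = np.linspace(1.0, 1201.0, 301)
    for lam in (1.5, 5.0, 20.0):
        g = np.array([component_gain(lam, mu) for mu in mus])
        assert np.all(np.diff(g) <= 0)


def test_wiener_reduction_at_mu_one():
    """mu = 1 gives the classical Wiener form (lambda-1)/(lambda-1+1)."""
    for lam in (1.2, 2.0, 7.0, 31.0):
        assert component_gain(lam, 1.0) == pytest.approx((lam - 1) / lam)


# ------------------------------------------------------------ apply_filter

def test_identity_gains_full_subspace_is_identity(rng):
    m = 6
    dec = gevd(_random_spd(rng, m), _random_spd(rng, m))
    y = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    out = apply_filter(y, dec, np.ones(m), n_sig=m)
    assert np.allclose(out, y, atol=1e-8)


def test_zero_gains_give_zero(rng):
    m = 5
    dec = gevd(_random_spd(rng, m), _random_spd(rng, m))
    y = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    assert np.allclose(apply_filter(y, dec, np.zeros(m), n_sig=m), 0.0)


def test_filter_matches_evd_projection_for_white_noise(rng):
    """r_nn = I: filter equals U diag(g) U^H y with U the unitary EVD basis."""
    m = 6
    r_yy = _random_spd(rng, m)
    dec = gevd(r_yy, np.eye(m))
    y = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    gains = component_gain(dec.lambdas, 2.0)
    out = apply_filter(y, dec, gains, n_sig=m)

    w, u = scipy.linalg.eigh(r_yy)
    w, u = w[::-1], u[:, ::-1]
    g_or = component_gain(w, 2.0)
    oracle = u @ (g_or * (u.conj().T @ y))
    assert np.allclose(out, oracle, atol=1e-6)


def test_noise_subspace_zeroed(rng):
    m = 5
    dec = gevd(_random_spd(rng, m), _random_spd(rng, m))
    y = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    out = apply_filter(y, dec, np.ones(m), n_sig=2)
    # expansion in the eigenbasis must have no components beyond n_sig
    coeffs = dec.V.conj().T @ out
    assert np.allclose(coeffs[2:], 0.0, atol=1e-8)


def test_n_sig_bounds_and_policies():
    lams = np.array([5.0, 1.2, 1.01, 0.9])
    assert select_n_sig(lams, SignalSubspaceRule(threshold_eps=0.05)) == 2
    assert select_n_sig(np.ones(4) * 0.5, SignalSubspaceRule()) == 1  # floor
    assert select_n_sig(lams, SignalSubspaceRule(policy="fixed-count",
                                                 fixed_count=3)) == 3
    with pytest.raises(ValueError):
        apply_filter(np.zeros(4), gevd(np.eye(4), np.eye(4)), np.ones(4), 0)


# ------------------------------------------------------------ estimate_ryy

def test_ryy_alpha_zero_is_instantaneous(rng):
    from eegfuse.stft import MultichannelSpectrogram
    cfg = StftConfig(sample_rate=200.0)
    vals = (rng.standard_normal((3, cfg.n_bins, 6))
            + 1j * rng.standard_normal((3, cfg.n_bins, 6)))
    spec = MultichannelSpectrogram(vals, cfg, 36)
    r = estimate_ryy(spec, alpha_y=0.0)
    l, k = 4, 2
    y = vals[:, k, l]
    outer = np.outer(y, y.conj())
    assert np.allclose(r[l, k], outer, rtol=1e-6)


def test_ryy_scaling_is_quadratic(rng):
    from eegfuse.stft import MultichannelSpectrogram
    cfg = StftConfig(sample_rate=200.0)
    vals = (rng.standard_normal((2, cfg.n_bins, 10))
            + 1j * rng.standard_normal((2, cfg.n_bins, 10)))
    r1 = estimate_ryy(MultichannelSpectrogram(vals, cfg, 60), alpha_y=0.5)
    r3 = estimate_ryy(MultichannelSpectrogram(3.0 * vals, cfg, 60), alpha_y=0.5)
    assert np.allclose(r3, 9.0 * r1, rtol=1e-9)


def test_ryy_converges_to_true_covariance(rng):
    """Long stationary run: smoothed R_yy within 15% of the true covariance."""
    from eegfuse.stft import MultichannelSpectrogram
    cfg = StftConfig(sample_rate=200.0)
    m, t = 3, 3000
    a = np.linalg.cholesky(np.array([[2.0, 0.5, 0], [0.5, 1.0, 0.2],
                                     [0, 0.2, 0.5]], dtype=complex))
    z = (rng.standard_normal((m, cfg.n_bins, t))
         + 1j * rng.standard_normal((m, cfg.n_bins, t))) / np.sqrt(2)
    vals = np.einsum("ij,jkt->ikt", a, z)
    truth = a @ a.conj().T
    r = estimate_ryy(MultichannelSpectrogram(vals, cfg, t * 6), alpha_y=0.99)
    rel = np.linalg.norm(r[-1, 0] - truth) / np.linalg.norm(truth)
    assert rel < 0.15


# ------------------------------------------------------------ full denoise

def test_denoise_deterministic(small_scene):
    cfg, clean, noisy, _ = small_scene
    spec = stft(noisy[:, :2000], StftConfig(sample_rate=cfg.fs))
    out1 = denoise(spec)
    out2 = denoise(spec)
    assert np.array_equal(out1.values, out2.values)


def test_denoise_suppresses_noise_only_scene():
    cfg = SceneConfig(seed=9, n_channels=6, duration_s=15.0,
                      source_powers=(1e-6,) * 6, spike_rate=0.0,
                      target_snr_db=-40.0)
    _, noisy, _ = generate_recording(cfg)
    spec = stft(noisy, StftConfig(sample_rate=cfg.fs))
    out = istft(denoise(spec))
    assert np.sum(out**2) < np.sum(noisy**2)


def test_denoise_passes_clean_high_snr_signal():
    """Clean high-amplitude oscillation, negligible noise: mu -> 1, g -> 1,
    output within 1 dB of input power per channel.

    A single amplitude-modulated source: its envelope troughs expose the
    noise floor to the minimum tracker, which is what the contract needs
    (with many always-on sources the floor is unobservable; see methods).
    """
    cfg = SceneConfig(seed=10, n_channels=6, duration_s=15.0,
                      target_snr_db=40.0, spike_rate=0.0,
                      source_bands=(("alpha", 8.0, 14.0),))
    clean, noisy, _ = generate_recording(cfg)
    spec = stft(noisy, StftConfig(sample_rate=cfg.fs))
    out = istft(denoise(spec))
    p_in = np.sum(noisy**2, axis=1)
    p_out = np.sum(out**2, axis=1)
    ratio_db = 10 * np.log10(p_out / p_in)
    assert np.all(np.abs(ratio_db) < 1.0)


def test_denoise_improves_snr(small_scene):
    """0 dB bursty scene: positive SNR gain end to end.

    Only 8 channels against 6 sources leaves little noise-only subspace, so
    the attainable gain is far below the 62-channel configuration; the
    check here is that the gain is real and positive at small scale.
    """
    cfg, clean, noisy, _ = small_scene
    spec = stft(noisy, StftConfig(sample_rate=cfg.fs))
    out = istft(denoise(spec))
    gain = snr_db(clean, out) - snr_db(clean, noisy)
    assert gain > 0.3
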