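# eegfuse

MIMO subspace denoising and band-attention graph classification for
multichannel EEG.

Scalp EEG is weak (microvolts) and contaminated by physiological artifacts,
power-line interference and motion transients, while the information used
for emotion decoding is spread unevenly over the canonical frequency bands
(delta, theta, alpha, beta, gamma). `eegfuse` implements an end-to-end
pipeline addressing both problems and a seeded synthetic-data module that
makes every stage testable against known ground truth — something real
recordings cannot provide, since their clean signal is never observed.

## The method

**Noise tracking (M-MCRA).** In the STFT domain, a signal-presence
probability p(k,l) per frequency bin gates a recursive estimate of the
M x M noise covariance:

    R_nn(k,l) = a_d R_nn(k,l-1) + (1 - a_d) Y(k,l) Y(k,l)^H,
    a_d = a_floor + p (1 - a_floor),

with p driven by the ratio of smoothed pooled energy to its sliding
minimum (minima-controlled recursive averaging, extended to multichannel
data). High p freezes the estimate so bursts of brain activity are not
absorbed as noise; a minima bound on trace(R_nn) anchors the level.

**Subspace filtering (GEVD).** Per bin, the pencil (R_yy, R_nn) is jointly
diagonalized, R_yy V = R_nn V Λ with V^H R_nn V = I. Each generalized
eigenvalue λ_i is the signal-plus-noise-to-noise ratio along its
eigendirection; λ_i − 1 is the a priori SNR. Retained components receive
the parameterized Wiener gain

    g_i = (λ_i − 1) / (λ_i − 1 + μ),

where μ is scheduled linearly in the frame's log-SNR between μ=1 (≥ 20 dB,
Wiener-like, minimal distortion) and μ=1201 (< −5 dB, aggressive musical-
noise suppression). The noise subspace beyond N_sig is zeroed and the
spectrum is synthesized as X̂ = V^{-H} G V^H Y, then inverted by
overlap-add.

**Features.** The denoised signal is split into the five rhythms with
zero-phase band-pass filters; each 1-s window of each channel/band is
summarized by its Gaussian differential entropy, DE = ½ ln(2πe σ²), and
the DE series is smoothed by a scalar random-walk Kalman smoother (LDS),
giving a (trials, 62, T, 5) tensor.

**Classifier.** Per band, a hierarchical 1x5 convolution stack
(64→128→256 filters with max pooling) embeds each channel's time course; a
self-adaptive graph layer builds a learned channel adjacency
E = softmax(A + S) (encoder attention scores A plus the embedding
self-correlation S) with top-k sparsification, and a spectral graph
convolution H' = σ(D̂^{-1/2} Ê D̂^{-1/2} X Θ) mixes information across the
montage. The five band vectors are fused by a single-head query-key-value
attention over bands, A = softmax(QKᵀ/√d_k), flattened and mean-pooled
into Z_final ∈ R^{N_b·D + D}, and classified by a small dense head trained
with Adam (lr 0.001, batch 64, label smoothing 0.1, dropout 0.1). The
neural components run on a self-contained numpy autodiff engine — no GPU
framework required.

## A worked example

`examples/01_denoise_synthetic_scene.py` builds the default scene — 62
channels, 60 s at 200 Hz, amplitude-modulated band-limited sources mixed to
0 dB SNR against white + pink + 50 Hz line + spike noise — and denoises it:

```
scene: 62 channels, 60 s, 20 spike artifacts, realized input SNR 0.00 dB
STFT: 9 bins x 2001 frames (window 13 samples, hop 6)
input SNR  :   0.00 dB
output SNR :   4.68 dB
SNR gain   :   4.68 dB  (energy of residual error relative to the clean reference)
```

The gain means the residual error energy after filtering is ~3x smaller
than the injected noise energy. The other examples cover feature
extraction (`02`), classifier training (`03`), leave-one-subject-out
evaluation with accuracy/MCC/macro-F1 and a paired t-test (`04`), and the
orchestrated pipeline with config file and manifest (`05`). A thin CLI
(`eegfuse simulate|denoise|features|train|evaluate|run|export-adjacency`)
wraps the same flow for shell use.

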