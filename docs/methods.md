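# Methods

This note documents the models, the parameter choices that matter, the
synthetic data the package is validated on, and the numerical decisions a
maintainer should know about.

## Signal model and STFT conventions

All denoising operates on one-sided short-time spectra of the real
multichannel signal. The analysis window is specified as a duration
(default 64 ms); at the default 200 Hz sampling rate that is 13 samples
(rounded from 12.8), with 50% overlap (hop 6 samples) and a zero-padded
FFT of the next power of two (16), giving K = 9 one-sided bins. Analysis
and synthesis both use a periodic square-root Hann taper (WOLA), the
signal is reflect-padded by half a window at each edge, and synthesis
divides by the shifted squared-window sum, so identity processing
reconstructs to floating-point precision for any window/hop whose overlap
sum is positive — there is no reliance on an exact constant-overlap-add
identity. A 13-sample window is very short by spectral-analysis standards;
its heavy spectral leakage is a property of the prescribed configuration
and is discussed under Limitations.

## M-MCRA noise-covariance tracking

Per bin, the tracker maintains:

* smoothed pooled energy S(k,l) = a_s S + (1−a_s) Σ_m |Y_m|², a_s = 0.8;
* an exact sliding minimum S_min over the last V_min = 64 frames
  (rolling-buffer implementation; ~1.9 s at the default frame rate);
* SPP p(k,l) = a_p p + (1−a_p)·[S/S_min > δ], a_p = 0.2;
* the noise covariance of the model equation
  R_nn ← a_d R_nn + (1−a_d) y yᴴ, a_d = a_floor + p (1−a_floor),
  a_floor = 0.85, Hermitian-symmetrized each step.

Three choices here deserve explanation.

**Decision threshold δ = 2.** The classic single-channel MCRA threshold
(δ ≈ 5) is calibrated to the heavy fluctuation of a χ²₂ periodogram.
Pooling the energy over M = 62 channels and smoothing over ~5 frames gives
the test statistic hundreds of degrees of freedom, so its noise-only
fluctuation around 1 is a few percent; δ = 2 then cleanly separates
oscillatory bursts (ratio 3–4 at a few dB of per-bin SNR) from noise
(ratio ≈ 1.1). With δ = 5 the detector essentially never fires on
realistic EEG scenes and the tracker absorbs the signal.

**Trace pooling rather than noise-whitened pooling.** A whitened statistic
yᴴR_nn⁻¹y/M is available (`pooling="whitened"`) and is the classical
multichannel detector, but it couples detection to the quantity being
protected: once signal leaks into R_nn the statistic renormalizes and
detection dies permanently. The decoupled trace statistic has no such
feedback and is the default.

**Minima bound on the noise level.** The SPP gate controls the *shape* of
R_nn but cannot undo a signal-contaminated history: if the initialization
(average of the first 5 frames, plus 1e-6 relative diagonal loading)
happens during activity and p then stays high, the contaminated estimate
is frozen indefinitely. The tracker therefore rescales R_nn whenever
trace(R_nn) exceeds 1.5 × S_min — the covariance analogue of the
minimum-statistics anchor that gives MCRA its name (the factor 1.5 absorbs
the negative bias of a windowed minimum). Disable with
`min_bound_factor=0`.

The tracker is causal: outputs for the first L frames are bit-identical
under truncation of the input (the initialization is a running average,
not a lookahead).

For *measuring* covariance convergence (stationary noise, fixed seed) the
floor is raised to 0.995: an exponentially weighted covariance has
irreducible relative error ≈ √(M/n_eff) with n_eff = (1+a)/(1−a), so a
15%-scale error at M = 4 needs n_eff ≈ 400. At the tracking default
(0.85) the estimator is deliberately fast, not statistically efficient.

## GEVD subspace filter

Per (bin, frame): R_yy is an exponentially smoothed outer-product average
with α_y = 0.95. The choice is a sample-support trade-off: at M = 62 an
effective window of ~20 frames is the practical compromise between rank
deficiency (α_y = 0.7 gives a rank-3 "covariance" whose eigenvalues are
meaningless) and responsiveness to burst non-stationarity.

The pencil (R_yy, R_nn) is solved by `scipy.linalg.eigh(a, b)` (Cholesky
whitening of R_nn internally), giving V with Vᴴ R_nn V = I and eigenvalues
sorted descending, clipped at zero. Diagonal loading (1e-8 relative) is
applied only if the unloaded solve fails, so residuals on well-conditioned
pencils stay at solver precision.

The signal-subspace dimension defaults to N_sig = #{λ > 1.05} (floor 1);
a fixed-count policy exists for experiments. The frame SNR that drives the
μ schedule is 10·log₁₀(λ₁ − 1) — the dominant component's a priori SNR.
The mean over the signal subspace is available (`stat="mean"`) but the
trailing near-unity eigenvalues it includes drag clean frames below the
20 dB anchor and cause needless distortion. μ interpolates linearly in dB
from 1 (at ≥ 20 dB) to 1201 (at < −5 dB); gains follow
g = max(λ−1, 0)/(max(λ−1, 0) + μ) (negative a priori SNR estimates are
clipped). Any per-bin numerical failure passes that bin through unchanged
and is counted in the log.

## Band features

Band edges follow the common EEG-literature convention: δ 1–4, θ 4–8,
α 8–14, β 14–31, γ 31–50 Hz (configurable). Filters are zero-phase
(forward–backward) Chebyshev-II band-passes designed to a gain contract —
±0.5 dB passband, ≥ 40 dB one transition width beyond the edges after the
double pass — rather than to a fixed order. DE uses the unbiased sample
variance; a constant window raises (its entropy is −∞). The LDS smoother
is a scalar random-walk Kalman filter plus RTS backward pass; only the
ratio q/r matters and defaults to 0.1 (output initialized at the first
observation, prior variance r). Trials are cut into non-overlapping 1-s
windows and zero-padded to a common frame count; a trial longer than the
padding target is an error, never silently truncated.

## Backbone and band-attention classifier

Per band (five independent instances): three blocks of 1x5 convolution
along time with 64→128→256 filters, LeakyReLU and width-2 max pooling,
then global average pooling to one 256-vector per channel. Channels share
weights and are never mixed by the convolution, so the stack is
permutation-equivariant over channels. The graph layer computes encoder
attention scores with 4 heads on a 256-dimensional projection
(head-averaged, pre-softmax) plus the row-softmaxed cosine-similarity Gram
matrix of the embeddings; E = row-softmax(A + S) is sparsified to the
top-10 entries per row (ties broken toward lower column indices) and
renormalized. Spectral graph convolution with self-loops maps embeddings
through Θ ∈ R^{256×32}; a linear readout reduces each node to a scalar,
giving the D = 62 band feature vector.

The fusion head is deliberately single-head (one W_Q/W_K/W_V triple,
d_k = d_v = D): with only five band tokens, a multi-head structure adds
parameters without capacity that matters, and the parameter census is
asserted in tests. Fusion output is [flatten(X′); mean over bands], length
N_b·D + D = 372. The classifier is two dense layers (hidden 64) with
dropout 0.1 between.

Training: Adam, lr 0.001, batch 64, 200 epochs, cross-entropy with label
smoothing 0.1 (target = (1−ε)·onehot + ε/C), and global-norm gradient
clipping at 5.0 (without it, occasional loss spikes destabilize individual
runs at small batch sizes). One integer seed controls initialization,
batch order and dropout. Inputs are standardized by the
training set's global mean and standard deviation (stored on the model and
applied at prediction); without centering, DE-scale inputs (~1.4) make
Adam at lr 0.001 converge impractically slowly. The whole stack runs on a
small reverse-mode autodiff engine over numpy (`eegfuse.nn`); convolution
is im2col plus a single 2-D GEMM, which keeps the weight gradient a plain
matrix product.

## Synthetic data

`generate_recording` emulates the artifact taxonomy of scalp EEG:
band-limited Gaussian-noise carriers with slow half-sine amplitude
envelopes (0.3 Hz; EEG rhythms wax and wane rather than run continuously),
mixed through a random channel matrix; noise is per-channel white +
1/f-shaped pink + a 50 Hz line component with random per-channel amplitude
and phase + Poisson spike transients (0.5/s, Hann-windowed, single
channel). The combined noise is rescaled so the realized input SNR matches
the target exactly. The default scene (62 channels, 60 s, 0 dB) is sized
so the full denoising path runs in well under a minute.

What the generator does *not* model: volume conduction from a forward head
model, electrode-specific spectra, non-Gaussian muscle artifacts, or any
stimulus protocol. Passing the denoising tests therefore demonstrates the
algorithm's behavior under its own assumptions (spatially low-rank
sources, locally stationary noise, observable noise floor), not clinical
performance.

`generate_labeled_features` draws DE-like features as
baseline + class band shift + subject band offset + N(0, σ²) with built-in
arousal-style class patterns (alpha-dominant / neutral / beta-gamma-
dominant), subject offsets σ = 0.3 and noise σ = 0.3 at effect size 1.0 —
Bayes-separable by construction, with classes balanced within every
subject so LOSO folds always contain all classes. The LOSO demonstration
uses 9 subjects x 6 trials with a 30-epoch, batch-8 schedule — a scale at
which the full model trains on one CPU in a few minutes; it verifies that
the architecture can recover known class structure across held-out
subjects, not that it reaches any particular accuracy on real data.

## Numerical choices and degenerate inputs

* Non-finite inputs are rejected at stage boundaries with explicit errors.
* PSD is maintained by symmetrization each update; eigenvalue clipping at
  zero is a logged repair path for numerical breakdown.
* `apply_filter` raises (with the condition number) if the eigenvector
  matrix is numerically singular; `denoise` converts that into a logged
  pass-through for the affected bin.
* S_min = 0 with S > 0 counts as signal present, never a division error.
* snr_db caps at 300 dB instead of returning infinity.
* Softmax rows sum to 1 within 1e-6; saturated entries may round to
  exactly 1.0 in float64.

## Known limitations

* The 9-bin spectral grid (64 ms window at 200 Hz) has coarse resolution
  and heavy leakage; adjacent-band sources overlap in the same bins, which
  limits per-bin SNR and hence SPP detectability. The window length and
  FFT size are configurable if a different operating point is wanted.
* The noise floor must be observable — through envelope troughs (in time)
  or a noise-only subspace (in space). A scene whose sources are always on
  in every bin and span all channels leaves the noise unidentifiable, and
  the filter will distort; the high-SNR pass-through contract holds for a
  single amplitude-modulated source, not for saturated scenes.
* With few channels relative to sources (e.g. 8 channels / 6 sources) the
  noise-only subspace is small and gains are correspondingly modest; the
  62-channel configuration is where the method earns its keep.
* EDF files can be read (via mne, optional extra) but not written;
  denoised output goes to HDF5 with provenance attributes.
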