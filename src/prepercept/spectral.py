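"""Multitaper spectral estimation: cross-spectra and sliding-window power.

All spectra are two-sided power spectral densities per Hz computed with
unit-energy DPSS tapers: for a tapered segment x of length N at rate fs,
``S(f) = |sum_t v(t) x(t) exp(-2 pi i f t)|^2 / fs`` so that the integral of
the two-sided density over (-Nyquist, Nyquist] equals the windowed variance
(Parseval).  Per-window mean removal is the only detrending applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .simulate import TrialEpochs

__all__ = [
    "TaperSet",
    "CrossSpectralDensity",
    "TimeFrequencyMap",
    "dpss_tapers",
    "multitaper_csd",
    "tfr_power",
]


@dataclass(frozen=True)
class TaperSet:
    """Orthonormal DPSS tapers with their spectral concentrations."""

    tapers: np.ndarray  # (n_tapers, n_samples), unit norm rows
    concentrations: np.ndarray  # eigenvalues in (0, 1]
    time_bandwidth: float

    @property
    def n_tapers(self) -> int:
        return self.tapers.shape[0]


def dpss_tapers(n_samples: int, time_bandwidth: float, n_tapers: int | None = None) -> TaperSet:
    """The ``n_tapers`` most concentrated discrete prolate spheroidal sequences.

    The usable taper count is bounded by ``floor(2 * time_bandwidth) - 1``;
    requesting more raises with the bound named.
    """
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8 for a meaningful taper set")
    max_tapers = int(np.floor(2 * time_bandwidth)) - 1
    if max_tapers < 1:
        raise ValueError(f"time_bandwidth {time_bandwidth} admits no concentrated taper")
    if n_tapers is None:
        n_tapers = max_tapers
    if n_tapers > max_tapers:
        raise ValueError(
            f"n_tapers={n_tapers} exceeds the concentration bound "
            f"floor(2*{time_bandwidth})-1 = {max_tapers}"
        )
    tap, ratios = windows.dpss(n_samples, time_bandwidth, Kmax=n_tapers, return_ratios=True)
    tap = np.atleast_2d(tap)
    tap = tap / np.linalg.norm(tap, axis=1, keepdims=True)  # unit energy for density scaling
    return TaperSet(tap, np.atleast_1d(ratios), float(time_bandwidth))


@dataclass
class CrossSpectralDensity:
    """Estimate-resolved cross-spectral matrices S(f).

    Internally the tapered Fourier coefficients ``coeffs`` (n_estimates,
    n_channels, n_freqs; the estimate axis enumerates trial x taper
    combinations) are stored, each contributing one rank-one estimate
    ``X X^H / fs``; the resolved array ``S`` (n_estimates, n_freqs, n_ch,
    n_ch) is materialized on demand and ``mean()`` computes the trial/taper
    average directly, which is what every downstream measure consumes.
    """

    freqs_hz: np.ndarray
    coeffs: np.ndarray
    window_s: tuple[float, float]
    sample_rate: float

    def __post_init__(self) -> None:
        if self.coeffs.ndim != 3:
            raise ValueError("coeffs must be (n_est, n_ch, n_freqs)")
        if self.coeffs.shape[2] != self.freqs_hz.size:
            raise ValueError("coeffs frequency axis must match freqs_hz")

    @property
    def n_estimates(self) -> int:
        return self.coeffs.shape[0]

    @property
    def S(self) -> np.ndarray:
        X = np.transpose(self.coeffs, (0, 2, 1))  # (est, freq, ch)
        return X[..., :, None] * np.conj(X[..., None, :]) / self.sample_rate

    def mean(self) -> np.ndarray:
        X = np.transpose(self.coeffs, (2, 1, 0))  # (freq, ch, est)
        m = X @ np.conj(np.swapaxes(X, 1, 2)) / (self.n_estimates * self.sample_rate)
        return m

    def band(self, lo: float, hi: float) -> "CrossSpectralDensity":
        keep = (self.freqs_hz >= lo - 1e-9) & (self.freqs_hz <= hi + 1e-9)
        return CrossSpectralDensity(
            self.freqs_hz[keep], self.coeffs[:, :, keep], self.window_s, self.sample_rate
        )

    def check_hermitian(self, atol: float = 1e-10) -> None:
        m = self.mean()
        if not np.allclose(m, np.conj(np.swapaxes(m, -1, -2)), atol=atol):
            raise AssertionError("CSD is not Hermitian")
        d = np.diagonal(m, axis1=-2, axis2=-1)
        if np.any(d.real < -atol) or np.any(np.abs(d.imag) > atol):
            raise AssertionError("CSD diagonal must be real nonnegative")


def _segment(epochs: TrialEpochs, window_s: tuple[float, float]) -> np.ndarray:
    mask = epochs.mask(window_s)
    if not mask.any():
        raise ValueError(f"window {window_s} lies outside the epoch")
    lo, hi = epochs.time_s[0], epochs.time_s[-1] + 1.0 / epochs.sample_rate
    if window_s[0] < lo - 1e-9 or window_s[1] > hi + 1e-9:
        raise ValueError(f"window {window_s} extends beyond the epoch [{lo}, {hi})")
    return epochs.data[:, :, mask]


def multitaper_csd(
    epochs: TrialEpochs,
    window_s: tuple[float, float] | None = None,
    freq_range_hz: tuple[float, float] | None = None,
    time_bandwidth: float = 2.0,
    n_tapers: int | None = None,
    n_fft: int | None = None,
) -> CrossSpectralDensity:
    """Trial/taper-resolved CSD of one analysis window on the natural rfft grid.

    The frequency grid is the window's own rfft grid (spacing = 1/window
    length), optionally restricted to ``freq_range_hz``.  Each trial x taper
    combination contributes one rank-one estimate ``X X^H / fs``.  ``n_fft``
    larger than the window zero-pads the tapered segments onto a denser grid
    (no new information; needed by spectral-matrix factorization, whose
    causal factor must be representable within the grid's lag range).
    """
    if window_s is None:
        window_s = (float(epochs.time_s[0]), float(epochs.time_s[-1] + 1 / epochs.sample_rate))
    seg = _segment(epochs, window_s)
    n_trials, n_ch, n = seg.shape
    fs = epochs.sample_rate
    taps = dpss_tapers(n, time_bandwidth, n_tapers)
    if n_fft is None:
        n_fft = n
    elif n_fft < n:
        raise ValueError("n_fft must be >= the window length")
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    if freq_range_hz is not None:
        lo, hi = freq_range_hz
        if hi <= lo:
            raise ValueError("empty frequency range")
        if hi > fs / 2 + 1e-9:
            raise ValueError(f"frequency {hi} exceeds Nyquist {fs / 2}")
        fkeep = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
        if not fkeep.any():
            raise ValueError("empty frequency range on the window's grid")
    else:
        fkeep = np.ones_like(freqs, bool)
    seg = seg - seg.mean(axis=2, keepdims=True)
    # (trials, tapers, channels, freqs)
    tapered = seg[:, None, :, :] * taps.tapers[None, :, None, :]
    X = np.fft.rfft(tapered, n=n_fft, axis=3)[..., fkeep]
    X = X.reshape(n_trials * taps.n_tapers, n_ch, int(fkeep.sum()))
    return CrossSpectralDensity(freqs[fkeep], X, window_s, fs)


@dataclass
class TimeFrequencyMap:
    """Sliding-window multitaper power, (trials, channels, freqs, times)."""

    power: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray  # window centers
    window_width_s: float
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    def condition_mean(self, condition: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("map carries no labels")
        return self.power[self.labels == condition].mean(axis=0)


def tfr_power(
    epochs: TrialEpochs,
    window_width_s: float,
    step_s: float,
    freqs_hz: np.ndarray,
    time_bandwidth: float = 3.0,
    n_tapers: int | None = None,
) -> TimeFrequencyMap:
    """Sliding-window multitaper power at arbitrary frequencies.

    Window centers step by ``step_s`` and are clipped so every window lies
    inside the epoch (no zero padding).  Power at each requested frequency is
    computed by explicit complex-exponential projection of the tapered
    window, so the grid need not coincide with the window's rfft bins.
    Frequencies below ~2 cycles per window are resolution-limited; they are
    allowed but carry the window's full mainlobe smoothing.
    """
    fs = epochs.sample_rate
    freqs_hz = np.asarray(freqs_hz, float)
    n_win = int(round(window_width_s * fs))
    if n_win > epochs.data.shape[2]:
        raise ValueError("analysis window longer than the epoch")
    if np.any(freqs_hz > fs / 2):
        raise ValueError("requested frequency beyond Nyquist")
    taps = dpss_tapers(n_win, time_bandwidth, n_tapers)
    t0, t1 = epochs.time_s[0], epochs.time_s[-1]
    half = (n_win - 1) / 2.0 / fs
    centers = np.arange(t0 + half, t1 - half + 1e-9, step_s)
    starts = np.clip(
        np.round((centers - half - t0) * fs).astype(int), 0, epochs.data.shape[2] - n_win
    )
    tloc = np.arange(n_win) / fs
    # (n_win, n_freqs) projection kernel, shared across windows
    kernel = np.exp(-2j * np.pi * tloc[:, None] * freqs_hz[None, :])
    power = np.empty((epochs.n_trials, epochs.n_channels, freqs_hz.size, centers.size))
    for w, s0 in enumerate(starts):
        seg = epochs.data[:, :, s0 : s0 + n_win]
        seg = seg - seg.mean(axis=2, keepdims=True)
        tapered = seg[:, None, :, :] * taps.tapers[None, :, None, :]
        X = tapered @ kernel  # (trials, tapers, channels, freqs)
        power[:, :, :, w] = (np.abs(X) ** 2).mean(axis=1) / fs
    return TimeFrequencyMap(power, freqs_hz, centers, window_width_s, epochs.labels)
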