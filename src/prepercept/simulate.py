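"""Synthetic cohort generator with known ground-truth directed coupling.

The generator emulates a 20-subject bistable-perception study: two oscillatory
cortical sources (a V1-like and an FFA-like node) follow a bivariate
vector-autoregressive (VAR) process with a 10-Hz resonance per channel.  On
"face" trials the FFA->V1 lag coefficient is larger than on "vase" trials
during the prestimulus interval only, so directed feedback connectivity is the
sole prestimulus difference between conditions.  After stimulus onset face
trials additionally receive an amplitude-modulated gamma burst and smooth
evoked bumps in the sources (V1-like early, FFA-like later), emulating the
post-stimulus category-specific activity that a time-resolved decoder picks
up.  Sources are mixed linearly into a homogeneous sensor array with additive
Gaussian noise; trial labels are i.i.d. Bernoulli reports.

Channel order is fixed package-wide as ``(V1, FFA)``: index 0 is the V1-like
source, index 1 the FFA-like source.  "Feedback" always means FFA->V1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

__all__ = [
    "SimulationConfig",
    "TrialEpochs",
    "CohortDataset",
    "companion_spectral_radius",
    "default_var_coeffs",
    "default_mixing",
    "var_generate",
    "generate_reports",
    "simulate_subject",
    "project_to_sensors",
    "simulate_cohort",
]

#: package-wide channel order for the two-node network
CHANNELS = ("V1", "FFA")
V1, FFA = 0, 1

LABELS = ("face", "vase")


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the companion matrix of a VAR(p) coefficient stack.

    Parameters
    ----------
    coeffs : (p, k, k) array
        Lag-indexed coefficient matrices A_1..A_p of
        ``x_t = sum_k A_k x_{t-k} + e_t``.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    p, k, _ = coeffs.shape
    comp = np.zeros((p * k, p * k))
    comp[:k, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[k:, :-k] = np.eye((p - 1) * k)
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def default_var_coeffs(
    f0_hz: float = 10.0, pole_radius: float = 0.8, sample_rate: float = 250.0, order: int = 5
) -> np.ndarray:
    """VAR(order) stack with an AR(2) resonance peaking at ``f0_hz`` on each channel.

    Lags 1-2 carry the oscillator; ``a1`` is chosen so the spectral peak sits
    exactly at ``f0_hz`` (``cos(w_peak) = -a1 (1 - a2) / (4 a2)`` for AR(2)),
    not merely the pole angle.  Higher lags are zero and exist so that
    directed coupling can be injected at lags 2-3 without changing the model
    order.  The default pole radius 0.8 yields an alpha bump of a few Hz
    half-width over a broadband low-frequency background, the regime in which
    prestimulus spectra concentrate below ~25 Hz with a clear ~10 Hz peak.
    """
    w0 = 2.0 * np.pi * f0_hz / sample_rate
    coeffs = np.zeros((order, 2, 2))
    a2 = -(pole_radius**2)
    a1 = -4.0 * a2 * np.cos(w0) / (1.0 - a2)
    coeffs[0] = a1 * np.eye(2)
    coeffs[1] = a2 * np.eye(2)
    return coeffs


def default_mixing(
    n_sensors: int = 30, n_sources: int = 2, smooth: int = 4, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Smooth random unit-norm sensor topographies, one column per source.

    Columns are Gaussian vectors smoothed along the sensor index (moving
    average of width ``2*smooth+1``) and normalized, a stand-in for the smooth
    field patterns of cortical sources on a sensor array.
    """
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_sensors, n_sources))
    kernel = np.ones(2 * smooth + 1)
    cols = np.stack(
        [np.convolve(raw[:, j], kernel, mode="same") for j in range(n_sources)], axis=1
    )
    cols /= np.linalg.norm(cols, axis=0, keepdims=True)
    return cols


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Generated source series are normalized to unit stationary SD (per channel,
    using the base process), so ``gamma_burst`` / ``evoked_face`` amplitudes
    and ``sensor_noise_sd`` are all in units of the ongoing source activity's
    SD.  Defaults: evoked responses comparable to the ongoing activity, a
    gamma burst at half the ongoing SD (small next to alpha, but large
    relative to the near-zero 60-Hz baseline power), sensor noise comparable
    to the per-sensor projected signal.
    """

    n_subjects: int = 20
    n_trials: int = 400
    sample_rate: float = 250.0
    epoch_window: tuple[float, float] = (-1.0, 0.5)
    var_coeffs_base: np.ndarray = field(default_factory=default_var_coeffs)
    #: FFA->V1 coefficient added at coupling_lags during the prestimulus window
    coupling_face: float = 0.035
    coupling_vase: float = 0.02
    coupling_lags: tuple[int, ...] = (2, 3)
    #: (center_freq_hz, onset_s, offset_s, amplitude) burst on the FFA source, face trials
    gamma_burst: tuple[float, float, float, float] = (60.0, 0.0, 0.35, 0.5)
    #: (source_index, center_s, sigma_s, amplitude) Gaussian bumps, face trials.
    #: Gaussian envelopes keep the evoked energy below ~25 Hz so the category
    #: difference in the gamma range comes from the gamma burst alone.
    evoked_face: tuple[tuple[int, float, float, float], ...] = (
        (V1, 0.10, 0.020, 1.5),
        (FFA, 0.16, 0.025, 1.3),
    )
    mixing: np.ndarray | None = None
    n_sensors: int = 30
    sensor_noise_sd: float = 0.25
    p_face: float = 0.5
    between_subject_sd: float = 0.3
    #: "shared": one excitability factor scales coupling delta, gamma and evoked
    #: amplitudes; "independent": separate factors; "none": no jitter.
    subject_factor_mode: str = "shared"
    noise_cov: np.ndarray = field(default_factory=lambda: np.eye(2))
    seed: int = 0

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.var_coeffs_base, float)
        if coeffs.ndim != 3 or coeffs.shape[1:] != (2, 2):
            raise ValueError("var_coeffs_base must be a (p, 2, 2) stack")
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("var_coeffs_base contains non-finite values")
        for coupling, name in ((self.coupling_face, "face"), (self.coupling_vase, "vase")):
            if not np.isfinite(coupling):
                raise ValueError(f"coupling_{name} is non-finite")
            rho = companion_spectral_radius(self._coeffs_with_coupling(coupling))
            if rho >= 1.0:
                raise ValueError(
                    f"unstable VAR for coupling_{name}={coupling}: "
                    f"companion spectral radius {rho:.4f} >= 1"
                )
        start, end = self.epoch_window
        if not (start < 0.0 < end):
            raise ValueError("epoch_window must straddle stimulus onset (start < 0 < end)")
        if not 0.0 <= self.p_face <= 1.0:
            raise ValueError("p_face must be a probability")
        if self.subject_factor_mode not in ("shared", "independent", "none"):
            raise ValueError("subject_factor_mode must be shared|independent|none")
        for v in (self.sensor_noise_sd, self.between_subject_sd, self.sample_rate):
            if not np.isfinite(v):
                raise ValueError("non-finite scalar parameter")

    def _coeffs_with_coupling(self, coupling: float) -> np.ndarray:
        coeffs = np.array(self.var_coeffs_base, float, copy=True)
        for lag in self.coupling_lags:
            if lag < 1 or lag > coeffs.shape[0]:
                raise ValueError(f"coupling lag {lag} outside model order {coeffs.shape[0]}")
            coeffs[lag - 1, V1, FFA] += coupling
        return coeffs

    @property
    def n_samples(self) -> int:
        start, end = self.epoch_window
        return int(round((end - start) * self.sample_rate))

    @property
    def time_s(self) -> np.ndarray:
        start, _ = self.epoch_window
        return start + np.arange(self.n_samples) / self.sample_rate


@dataclass
class TrialEpochs:
    """Trial-epoched multichannel time series with per-trial labels.

    ``data`` has shape (trials, channels, samples); ``time_s`` maps sample
    index to seconds relative to stimulus onset (0 = onset).
    """

    data: np.ndarray
    time_s: np.ndarray
    labels: np.ndarray
    sample_rate: float
    channel_kind: str = "source"
    subject_id: str = "s00"
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.time_s = np.asarray(self.time_s, float)
        self.labels = np.asarray(self.labels, dtype=object).astype(str)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.time_s.shape != (self.data.shape[2],):
            raise ValueError("time_s length must match the sample axis")
        dt = np.diff(self.time_s)
        if self.time_s.size > 1:
            if np.any(dt <= 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sample_rate, rtol=1e-6, atol=1e-9):
                raise ValueError("time axis must be uniform with spacing 1/sample_rate")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels length must equal trial count")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"illegal labels {sorted(bad)}; allowed: {LABELS}")
        if self.channel_kind not in ("sensor", "source"):
            raise ValueError("channel_kind must be 'sensor' or 'source'")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def mask(self, window_s: tuple[float, float]) -> np.ndarray:
        """Boolean sample mask for ``window_s`` = [start, end)."""
        return (self.time_s >= window_s[0] - 1e-12) & (self.time_s < window_s[1] - 1e-12)

    def select_trials(self, condition: str) -> "TrialEpochs":
        keep = self.labels == condition
        return TrialEpochs(
            self.data[keep],
            self.time_s,
            self.labels[keep],
            self.sample_rate,
            self.channel_kind,
            self.subject_id,
            self.channel_names,
        )

    def time_reversed(self) -> "TrialEpochs":
        return TrialEpochs(
            self.data[:, :, ::-1].copy(),
            self.time_s,
            self.labels,
            self.sample_rate,
            self.channel_kind,
            self.subject_id,
            self.channel_names,
        )


@dataclass
class CohortDataset:
    """One epochs object per subject, plus the realized generative parameters."""

    subjects: list[TrialEpochs]
    ground_truth: dict
    mixing: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = [ep.subject_id for ep in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")

    @property
    def subject_ids(self) -> list[str]:
        return [ep.subject_id for ep in self.subjects]


def stationary_sd(coeffs: np.ndarray, noise_cov: np.ndarray) -> np.ndarray:
    """Per-channel stationary SD of a stable VAR, via the companion-form Lyapunov equation."""
    coeffs = np.asarray(coeffs, float)
    p, k, _ = coeffs.shape
    comp = np.zeros((p * k, p * k))
    comp[:k, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[k:, :-k] = np.eye((p - 1) * k)
    Q = np.zeros((p * k, p * k))
    Q[:k, :k] = np.asarray(noise_cov, float)
    cov = solve_discrete_lyapunov(comp, Q)
    return np.sqrt(np.diag(cov)[:k])


def _burn_in_samples(coeffs: np.ndarray) -> int:
    rho = companion_spectral_radius(coeffs)
    order = coeffs.shape[0]
    # ~12 time constants of the slowest mode, never less than 10 model orders
    return max(10 * order, int(math.ceil(12.0 / max(1e-6, 1.0 - rho))))


def var_generate(
    coeffs: np.ndarray,
    noise_cov: np.ndarray,
    n_samples: int,
    seed: int | np.random.Generator = 0,
    n_trials: int = 1,
    burn_in: int | None = None,
) -> np.ndarray:
    """Stationary realization(s) of a stable VAR(p), shape (n_trials, k, n_samples).

    A burn-in period sized from the companion spectral radius is discarded so
    the returned samples are draws from the stationary law.  Unstable
    coefficient stacks are rejected.
    """
    coeffs = np.asarray(coeffs, float)
    noise_cov = np.asarray(noise_cov, float)
    rho = companion_spectral_radius(coeffs)
    if rho >= 1.0:
        raise ValueError(f"unstable VAR: companion spectral radius {rho:.4f} >= 1")
    if not np.allclose(noise_cov, noise_cov.T) or np.any(np.linalg.eigvalsh(noise_cov) <= 0):
        raise ValueError("noise_cov must be symmetric positive definite")
    rng = np.random.default_rng(seed)
    if burn_in is None:
        burn_in = _burn_in_samples(coeffs)
    p, k, _ = coeffs.shape
    total = burn_in + n_samples
    chol = np.linalg.cholesky(noise_cov)
    noise = rng.standard_normal((n_trials, total, k)) @ chol.T
    x = np.zeros((n_trials, total, k))
    for t in range(total):
        acc = noise[:, t, :]
        for lag in range(1, min(p, t) + 1):
            acc = acc + x[:, t - lag, :] @ coeffs[lag - 1].T
        x[:, t, :] = acc
    return np.transpose(x[:, burn_in:, :], (0, 2, 1))


def generate_reports(
    n_trials: int, p_face: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """i.i.d. Bernoulli report sequence of 'face'/'vase' labels."""
    if not 0.0 <= p_face <= 1.0:
        raise ValueError("p_face must be a probability")
    rng = np.random.default_rng(seed)
    return np.where(rng.random(n_trials) < p_face, "face", "vase").astype(str)


def _hann_bump(time_s: np.ndarray, start: float, stop: float) -> np.ndarray:
    env = np.zeros_like(time_s)
    inside = (time_s >= start) & (time_s <= stop)
    if stop > start:
        env[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (time_s[inside] - start) / (stop - start)))
    return env


def _gauss_bump(time_s: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((time_s - center) / sigma) ** 2)


def _subject_factors(config: SimulationConfig, rng: np.random.Generator) -> dict:
    draw = lambda: max(0.1, 1.0 + config.between_subject_sd * rng.standard_normal())
    if config.subject_factor_mode == "none":
        g = {"coupling": 1.0, "gamma": 1.0, "evoked": 1.0}
    elif config.subject_factor_mode == "shared":
        shared = draw()
        g = {"coupling": shared, "gamma": shared, "evoked": shared}
    else:
        g = {"coupling": draw(), "gamma": draw(), "evoked": draw()}
    return g


def simulate_subject(
    config: SimulationConfig, subject_seed: int | np.random.SeedSequence, subject_id: str = "s00"
) -> tuple[TrialEpochs, dict]:
    """Source-level epochs for one subject, plus the realized ground truth.

    Per trial: draw the report label; run the VAR with the label's FFA->V1
    coupling for burn-in + prestimulus samples, then continue the same
    realization with the base (uncoupled-difference) coefficients for the
    post-stimulus samples; on face trials add the gamma burst and the evoked
    bumps.  The subject-level excitability factor jitters the coupling
    difference and post-stimulus amplitudes once per subject.
    """
    rng = np.random.default_rng(subject_seed)
    g = _subject_factors(config, rng)
    delta = config.coupling_face - config.coupling_vase
    coupling = {
        "face": config.coupling_vase + g["coupling"] * delta,
        "vase": config.coupling_vase,
    }
    for lab, c in coupling.items():
        if companion_spectral_radius(config._coeffs_with_coupling(c)) >= 1.0:
            raise ValueError(f"subject-level jitter produced an unstable VAR ({lab})")

    labels = generate_reports(config.n_trials, config.p_face, rng)
    time_s = config.time_s
    fs = config.sample_rate
    n_pre = int(np.sum(time_s < 0))
    n_post = config.n_samples - n_pre
    coeffs_base = np.asarray(config.var_coeffs_base, float)
    p = coeffs_base.shape[0]
    burn = _burn_in_samples(config._coeffs_with_coupling(max(coupling.values())))
    chol = np.linalg.cholesky(np.asarray(config.noise_cov, float))
    # unit convention: sources reported in units of the base process' stationary SD
    base_sd = stationary_sd(coeffs_base, config.noise_cov)

    gamma_f, gamma_on, gamma_off, gamma_amp = config.gamma_burst
    gamma_env = _hann_bump(time_s, gamma_on, gamma_off)
    evoked = np.zeros((2, config.n_samples))
    for src, center, sigma, amp in config.evoked_face:
        evoked[src] += g["evoked"] * amp * _gauss_bump(time_s, center, sigma)

    data = np.empty((config.n_trials, 2, config.n_samples))
    for cond in LABELS:
        idx = np.flatnonzero(labels == cond)
        if idx.size == 0:
            continue
        coeffs_pre = config._coeffs_with_coupling(coupling[cond])
        total = burn + n_pre + n_post
        noise = rng.standard_normal((idx.size, total, 2)) @ chol.T
        x = np.zeros((idx.size, total, 2))
        switch = burn + n_pre  # first post-stimulus sample
        for t in range(total):
            coeffs = coeffs_pre if t < switch else coeffs_base
            acc = noise[:, t, :]
            for lag in range(1, min(p, t) + 1):
                acc = acc + x[:, t - lag, :] @ coeffs[lag - 1].T
            x[:, t, :] = acc
        epochs = np.transpose(x[:, burn:, :], (0, 2, 1)) / base_sd[None, :, None]
        if cond == "face":
            phase = rng.uniform(0, 2 * np.pi, idx.size)
            burst = (
                g["gamma"]
                * gamma_amp
                * gamma_env[None, :]
                * np.cos(2 * np.pi * gamma_f * time_s[None, :] + phase[:, None])
            )
            epochs[:, FFA, :] += burst
            epochs += evoked[None, :, :]
        data[idx] = epochs

    truth = {
        "subject_id": subject_id,
        "coupling_face": coupling["face"],
        "coupling_vase": coupling["vase"],
        "gamma_amplitude": g["gamma"] * gamma_amp,
        "evoked_gain": g["evoked"],
        "factors": g,
        "burn_in_samples": burn,
    }
    ep = TrialEpochs(data, time_s, labels, fs, "source", subject_id, CHANNELS)
    return ep, truth


def project_to_sensors(
    source_epochs: TrialEpochs,
    mixing: np.ndarray,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
) -> TrialEpochs:
    """Linear instantaneous mixing into a sensor array with additive Gaussian noise."""
    mixing = np.asarray(mixing, float)
    if mixing.ndim != 2 or mixing.shape[1] != source_epochs.n_channels:
        raise ValueError(
            f"mixing must be (n_sensors, {source_epochs.n_channels}); got {mixing.shape}"
        )
    rng = np.random.default_rng(seed)
    sensors = np.einsum("ms,tsn->tmn", mixing, source_epochs.data)
    if noise_sd > 0:
        sensors = sensors + noise_sd * rng.standard_normal(sensors.shape)
    return TrialEpochs(
        sensors,
        source_epochs.time_s,
        source_epochs.labels,
        source_epochs.sample_rate,
        "sensor",
        source_epochs.subject_id,
        None,
    )


def simulate_cohort(config: SimulationConfig, sensor_level: bool = True) -> CohortDataset:
    """Full cohort: per-subject seeds are spawned from the cohort seed.

    Returns sensor-level epochs (with the mixing matrix retained as the
    ground-truth forward model) unless ``sensor_level=False``, in which case
    source-level epochs are returned directly.
    """
    root = np.random.SeedSequence(config.seed)
    mix_seed, noise_seed, *subject_seeds = root.spawn(2 + config.n_subjects)
    mixing = (
        np.asarray(config.mixing, float)
        if config.mixing is not None
        else default_mixing(config.n_sensors, 2, seed=np.random.default_rng(mix_seed))
    )
    noise_rng = np.random.default_rng(noise_seed)
    subjects, truths = [], []
    for i, sseed in enumerate(subject_seeds):
        sid = f"s{i:02d}"
        src, truth = simulate_subject(config, sseed, sid)
        if sensor_level:
            subjects.append(project_to_sensors(src, mixing, config.sensor_noise_sd, noise_rng))
        else:
            subjects.append(src)
        truths.append(truth)
    return CohortDataset(subjects, {"subjects": truths, "config_seed": config.seed}, mixing)
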