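"""End-to-end orchestration: simulate -> decode -> ROI -> time-frequency
contrasts -> prestimulus power/coherence/Granger contrasts -> time-reversal
control -> cross-subject maxima correlations.

Stage conventions
-----------------
- Source reconstruction on synthetic cohorts uses the pseudo-inverse of the
  known mixing matrix as the spatial filter (the declared stand-in for
  anatomical source reconstruction); ``PipelineConfig.spatial_filter``
  accepts a user-supplied (grid x sensors) filter for real data.
- Connectivity statistics are evaluated on the prestimulus window's natural
  (Rayleigh) frequency grid restricted to the declared band; the spectral
  factorization itself always uses the full 0-Nyquist spectrum.
- Group tests are random-effects across subjects (one value per subject and
  condition enters each paired cluster permutation test).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .connectivity import (
    ConnectivitySpectrum,
    connectivity_spectrum,
    time_reversed_granger,
)
from .decoding import DecodingResult, extract_roi, project_to_source, temporal_decode
from .simulate import FFA, V1, CohortDataset, SimulationConfig, simulate_cohort
from .spectral import multitaper_csd, tfr_power
from .stats import (
    ClusterTestResult,
    cluster_permutation_test,
    extract_maxima,
    pearson_corr,
    runs_binomial_fit,
)

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline", "correlate_maxima"]

logger = logging.getLogger(__name__)

CONDITIONS = ("face", "vase")
NODE_NAMES = {V1: "V1", FFA: "FFA"}


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings layered on top of the cohort generator's config."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    prestim_window_s: tuple[float, float] = (-1.0, 0.0)
    poststim_window_s: tuple[float, float] = (0.0, 0.35)
    stats_band_hz: tuple[float, float] = (5.0, 25.0)
    #: sliding-window widths for the time-frequency contrast; the first is the
    #: primary analysis, the second the narrow-window control
    tfr_window_widths_s: tuple[float, ...] = (0.3, 0.1)
    tfr_step_s: float = 0.05
    gamma_freqs_hz: tuple[float, float, float] = (40.0, 100.0, 2.5)  # lo, hi, step
    gamma_half_bandwidth_hz: float = 10.0
    prestim_time_bandwidth: float = 2.0
    decode_band_hz: tuple[float, float] = (1.0, 33.0)
    decode_test_window_s: tuple[float, float] = (0.0, 0.35)
    roi_windows_s: tuple[tuple[float, float], ...] = ((0.05, 0.12), (0.12, 0.20))
    #: contrast induced power (per-condition evoked mean removed before the
    #: TFR): large evoked transients otherwise splatter broadband power into
    #: windows that truncate them, masquerading as oscillatory effects
    tfr_induced: bool = True
    n_folds: int = 4
    run_decoding: bool = True
    n_perm: int = 1000
    n_perm_decoding: int = 10000
    cluster_alpha: float = 0.05
    stats_seed: int = 0
    spatial_filter: np.ndarray | None = None

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    """All per-subject and group-level artifacts of one pipeline run."""

    config: PipelineConfig
    cohort: CohortDataset
    decoding: dict[str, DecodingResult]
    roi_points: dict[str, list[np.ndarray]]
    decoding_test: ClusterTestResult | None
    connectivity: list[ConnectivitySpectrum]
    connectivity_reversed: list[ConnectivitySpectrum]
    tfr_tests: dict[str, ClusterTestResult]
    power_tests: dict[str, ClusterTestResult]
    coherence_test: ClusterTestResult | None
    imag_coherency_test: ClusterTestResult | None
    granger_tests: dict[str, ClusterTestResult]
    granger_reversed_tests: dict[str, ClusterTestResult]
    behavior: dict
    maxima: pd.DataFrame | None
    correlations: pd.DataFrame | None
    provenance: dict

    def summary(self) -> dict:
        def test_summary(t: ClusterTestResult | None) -> dict | None:
            if t is None:
                return None
            return {
                "min_p": t.min_p,
                "n_clusters": len(t.clusters),
                "tail": t.tail,
                "n_permutations": t.n_permutations,
                "settings": t.settings,
            }

        out = {
            "provenance": self.provenance,
            "behavior": self.behavior,
            "decoding_test": test_summary(self.decoding_test),
            "tfr_tests": {k: test_summary(v) for k, v in self.tfr_tests.items()},
            "power_tests": {k: test_summary(v) for k, v in self.power_tests.items()},
            "coherence_test": test_summary(self.coherence_test),
            "imag_coherency_test": test_summary(self.imag_coherency_test),
            "granger_tests": {k: test_summary(v) for k, v in self.granger_tests.items()},
            "granger_reversed_tests": {
                k: test_summary(v) for k, v in self.granger_reversed_tests.items()
            },
        }
        if self.correlations is not None:
            out["correlations"] = self.correlations.to_dict(orient="records")
        return out

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pio.write_json(out_dir / "summary.json", self.summary())
        if self.connectivity:
            pio.connectivity_to_frame(self.connectivity).to_csv(
                out_dir / "connectivity.csv", index=False
            )
        if self.maxima is not None:
            self.maxima.to_csv(out_dir / "maxima.csv", index=False)
        if self.correlations is not None:
            self.correlations.to_csv(out_dir / "correlations.csv", index=False)
        if self.decoding:
            dec_dir = out_dir / "decoding"
            dec_dir.mkdir(exist_ok=True)
            rows = []
            for sid, res in self.decoding.items():
                pio.write_decoding(dec_dir / f"{sid}.h5", res)
                rows.append(pd.DataFrame({"subject": sid, "time_s": res.times_s, "auc": res.auc}))
            pd.concat(rows).to_csv(dec_dir / "auc.csv", index=False)


def _stats_grid(freqs_hz: np.ndarray, band: tuple[float, float], rayleigh_hz: float) -> np.ndarray:
    """Indices of Rayleigh-grid frequencies inside the statistics band."""
    on_grid = np.isclose(np.mod(freqs_hz, rayleigh_hz), 0, atol=1e-6) | np.isclose(
        np.mod(freqs_hz, rayleigh_hz), rayleigh_hz, atol=1e-6
    )
    keep = on_grid & (freqs_hz >= band[0] - 1e-9) & (freqs_hz <= band[1] + 1e-9)
    return np.flatnonzero(keep)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> ResultsBundle:
    """Execute the full study on one synthetic cohort.

    Any stage failure aborts with the stage name; stages completed so far are
    kept on the partially filled bundle attached to the raised exception.
    """
    stage = "simulate"
    partial: dict = {}
    try:
        cohort = simulate_cohort(config.simulation)
        partial["cohort"] = cohort

        stage = "spatial_filter"
        if config.spatial_filter is not None:
            spatial_filter = np.asarray(config.spatial_filter, float)
        elif cohort.mixing is not None:
            spatial_filter = np.linalg.pinv(cohort.mixing)
        else:
            raise ValueError("no spatial filter available (no mixing and none supplied)")

        stage = "behavior"
        sequences = [ep.labels for ep in cohort.subjects]
        seq_fit = runs_binomial_fit(sequences)
        behavior = {
            "face_report_pct_mean": float(
                np.mean([(ep.labels == "face").mean() for ep in cohort.subjects]) * 100
            ),
            "run_length_bins": seq_fit.bin_counts,
            "binomial_fit_r2": seq_fit.r_squared,
            "binomial_p_hat": seq_fit.p_hat,
        }

        stage = "decoding"
        decoding: dict[str, DecodingResult] = {}
        roi_points: dict[str, list[np.ndarray]] = {}
        decoding_test = None
        if config.run_decoding:
            auc_maps = []
            for ep in cohort.subjects:
                res = temporal_decode(
                    ep,
                    n_folds=config.n_folds,
                    band_hz=config.decode_band_hz,
                    seed=config.stats_seed,
                )
                decoding[ep.subject_id] = res
                src_map = project_to_source(res.patterns, spatial_filter)
                roi_points[ep.subject_id] = [
                    extract_roi(src_map, 0.95, win, res.times_s)
                    for win in config.roi_windows_s
                ]
                mask = (res.times_s >= config.decode_test_window_s[0]) & (
                    res.times_s <= config.decode_test_window_s[1]
                )
                auc_maps.append(res.auc[mask])
            auc_maps = np.asarray(auc_maps)
            decoding_test = cluster_permutation_test(
                auc_maps,
                np.full_like(auc_maps, 0.5),
                tail="greater",
                cluster_alpha=config.cluster_alpha,
                n_perm=config.n_perm_decoding,
                seed=config.stats_seed,
            )

        stage = "source_reconstruction"
        sources = [
            type(ep)(
                np.einsum("gm,tmn->tgn", spatial_filter, ep.data),
                ep.time_s,
                ep.labels,
                ep.sample_rate,
                "source",
                ep.subject_id,
                ("V1", "FFA"),
            )
            if ep.channel_kind == "sensor"
            else ep
            for ep in cohort.subjects
        ]

        stage = "tfr_contrast"
        lo, hi, step = config.gamma_freqs_hz
        gamma_grid = np.arange(lo, hi + 1e-9, step)
        tfr_tests: dict[str, ClusterTestResult] = {}
        tfr_effect_curves: dict[str, np.ndarray] = {}
        for width in config.tfr_window_widths_s:
            nw = max(1.0, width * config.gamma_half_bandwidth_hz)
            maps = {cond: [] for cond in CONDITIONS}
            for ep in sources:
                data = ep.data
                if config.tfr_induced:
                    data = data.copy()
                    for cond in CONDITIONS:
                        sel = ep.labels == cond
                        data[sel] -= data[sel].mean(axis=0, keepdims=True)
                ep_tfr = type(ep)(
                    data, ep.time_s, ep.labels, ep.sample_rate, ep.channel_kind,
                    ep.subject_id, ep.channel_names,
                )
                tfr = tfr_power(ep_tfr, width, config.tfr_step_s, gamma_grid, time_bandwidth=nw)
                # statistics use only windows lying fully after stimulus
                # onset: windows straddling t=0 mix in prestimulus samples,
                # where the conditions differ by construction (the coupling),
                # and would contaminate the post-stimulus contrast
                tmask = (tfr.times_s >= config.poststim_window_s[0] + width / 2 - 1e-9) & (
                    tfr.times_s <= config.poststim_window_s[1] + 1e-9
                )
                for cond in CONDITIONS:
                    m = tfr.condition_mean(cond)[:, :, tmask]
                    if config.tfr_induced:
                        # subtracting a condition mean of n trials removes
                        # 1/n of the stochastic power; undo it so unequal
                        # trial counts cannot bias the contrast
                        n_c = int(np.sum(ep.labels == cond))
                        if n_c > 1:
                            m = m * (n_c / (n_c - 1))
                    maps[cond].append(m)
            for node in (V1, FFA):
                a = np.asarray([m[node] for m in maps["face"]])
                b = np.asarray([m[node] for m in maps["vase"]])
                key = f"{NODE_NAMES[node]}_{int(round(width * 1000))}ms"
                tfr_tests[key] = cluster_permutation_test(
                    a,
                    b,
                    tail="two",
                    cluster_alpha=config.cluster_alpha,
                    n_perm=config.n_perm,
                    seed=config.stats_seed,
                )
                if node == FFA:
                    # per-subject max face-vase gamma effect, used for Fig-3-style maxima
                    tfr_effect_curves[key] = (a - b).reshape(a.shape[0], -1)

        stage = "prestim_power"
        rayleigh = 1.0 / (config.prestim_window_s[1] - config.prestim_window_s[0])
        power_maps = {cond: {V1: [], FFA: []} for cond in CONDITIONS}
        for ep in sources:
            for cond in CONDITIONS:
                csd = multitaper_csd(
                    ep.select_trials(cond),
                    config.prestim_window_s,
                    freq_range_hz=config.stats_band_hz,
                    time_bandwidth=config.prestim_time_bandwidth,
                )
                m = csd.mean()
                for node in (V1, FFA):
                    power_maps[cond][node].append(m[:, node, node].real)
        power_tests = {
            NODE_NAMES[node]: cluster_permutation_test(
                np.asarray(power_maps["face"][node]),
                np.asarray(power_maps["vase"][node]),
                tail="two",
                cluster_alpha=config.cluster_alpha,
                n_perm=config.n_perm,
                seed=config.stats_seed,
            )
            for node in (V1, FFA)
        }

        stage = "connectivity"
        connectivity: list[ConnectivitySpectrum] = []
        connectivity_reversed: list[ConnectivitySpectrum] = []
        for ep in sources:
            for cond in CONDITIONS:
                connectivity.append(
                    connectivity_spectrum(
                        ep,
                        config.prestim_window_s,
                        cond,
                        time_bandwidth=config.prestim_time_bandwidth,
                    )
                )
                connectivity_reversed.append(
                    time_reversed_granger(
                        ep,
                        config.prestim_window_s,
                        cond,
                        time_bandwidth=config.prestim_time_bandwidth,
                    )
                )

        stage = "connectivity_stats"
        freqs = connectivity[0].freqs_hz
        sel = _stats_grid(freqs, config.stats_band_hz, rayleigh)
        stat_freqs = freqs[sel]

        def stack(spectra, measure, cond):
            return np.asarray(
                [getattr(cs, measure)[sel] for cs in spectra if cs.condition == cond]
            )

        def contrast(spectra, measure, tail):
            return cluster_permutation_test(
                stack(spectra, measure, "face"),
                stack(spectra, measure, "vase"),
                tail=tail,
                cluster_alpha=config.cluster_alpha,
                n_perm=config.n_perm,
                seed=config.stats_seed,
            )

        coherence_test = contrast(connectivity, "coherence", "greater")
        imag_raw_face = np.abs(stack(connectivity, "imag_coherency", "face"))
        imag_raw_vase = np.abs(stack(connectivity, "imag_coherency", "vase"))
        imag_coherency_test = cluster_permutation_test(
            imag_raw_face,
            imag_raw_vase,
            tail="greater",
            cluster_alpha=config.cluster_alpha,
            n_perm=config.n_perm,
            seed=config.stats_seed,
        )
        granger_tests = {
            "feedforward": contrast(connectivity, "granger_ff", "greater"),
            "feedback": contrast(connectivity, "granger_fb", "greater"),
        }
        granger_reversed_tests = {
            "feedforward": contrast(connectivity_reversed, "granger_ff", "greater"),
            "feedback": contrast(connectivity_reversed, "granger_fb", "greater"),
        }

        stage = "maxima"
        maxima = None
        correlations = None
        if config.run_decoding:
            ids = [ep.subject_id for ep in cohort.subjects]
            auc_max = extract_maxima(
                {
                    sid: (decoding[sid].times_s, decoding[sid].auc)
                    for sid in ids
                },
                config.decode_test_window_s,
            )
            key300 = f"FFA_{int(round(config.tfr_window_widths_s[0] * 1000))}ms"
            gamma_curves = tfr_effect_curves[key300]
            gamma_max = {sid: float(gamma_curves[i].max()) for i, sid in enumerate(ids)}
            fb_by_subject: dict[str, list[np.ndarray]] = {sid: [] for sid in ids}
            for cs in connectivity:
                fb_by_subject[cs.subject_id].append(cs.granger_fb[sel])
            fb_max = {
                sid: float(np.mean(fb_by_subject[sid], axis=0).max()) for sid in ids
            }
            maxima = pd.DataFrame(
                {
                    "subject": ids,
                    "max_auc": [auc_max[s] for s in ids],
                    "max_gamma_effect": [gamma_max[s] for s in ids],
                    "max_feedback_granger": [fb_max[s] for s in ids],
                }
            )
            correlations = correlate_maxima(maxima)

        provenance = {
            "config_hash": config.config_hash(),
            "cohort_seed": config.simulation.seed,
            "stats_seed": config.stats_seed,
            "n_subjects": config.simulation.n_subjects,
            "n_trials": config.simulation.n_trials,
            "stats_freqs_hz": stat_freqs,
            "subject_ids": cohort.subject_ids,
        }
        bundle = ResultsBundle(
            config,
            cohort,
            decoding,
            roi_points,
            decoding_test,
            connectivity,
            connectivity_reversed,
            tfr_tests,
            power_tests,
            coherence_test,
            imag_coherency_test,
            granger_tests,
            granger_reversed_tests,
            behavior,
            maxima,
            correlations,
            provenance,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def correlate_maxima(maxima: pd.DataFrame) -> pd.DataFrame:
    """Three cross-subject Pearson correlations between the per-subject maxima.

    Rows: feedback Granger vs gamma effect, feedback Granger vs peak AUC,
    gamma effect vs peak AUC; columns r, p and the 95% CI bounds.
    """
    required = {"max_auc", "max_gamma_effect", "max_feedback_granger"}
    missing = required - set(maxima.columns)
    if missing:
        raise ValueError(f"maxima table lacks columns {sorted(missing)}")
    if maxima[list(required)].isna().any().any():
        raise ValueError("missing per-subject maxima; refusing to drop subjects silently")
    pairs = [
        ("max_feedback_granger", "max_gamma_effect"),
        ("max_feedback_granger", "max_auc"),
        ("max_gamma_effect", "max_auc"),
    ]
    rows = []
    for a, b in pairs:
        r, p, ci = pearson_corr(maxima[a].to_numpy(), maxima[b].to_numpy())
        rows.append({"x": a, "y": b, "r": r, "p": p, "ci_lo": ci[0], "ci_hi": ci[1]})
    return pd.DataFrame(rows)
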