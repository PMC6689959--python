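"""Group-level inference: cluster permutation tests, within-subject error bars,
run-length binomial analysis of reports, and cross-subject correlations.

The cluster-based permutation test corrects for multiple comparisons over a
frequency (1-D) or time-frequency (2-D) grid: cell-wise paired t statistics
are thresholded at the quantile implied by the cluster-forming alpha,
connected supra-threshold cells are summed, and the summed statistics are
compared against a Monte-Carlo null built from random within-subject
condition swaps (sign flips of the paired differences) using the
maximum-cluster statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps

__all__ = [
    "Cluster",
    "ClusterTestResult",
    "SequenceFit",
    "cluster_permutation_test",
    "within_subject_sem",
    "run_length_bins",
    "runs_binomial_fit",
    "pearson_corr",
    "max_in_range",
    "extract_maxima",
]

_TAILS = ("two", "greater", "less")


@dataclass
class Cluster:
    """A connected set of supra-threshold grid cells with its summed statistic."""

    cells: np.ndarray  # indices into the flattened grid
    stat_sum: float
    p_value: float
    sign: int  # +1 positive cluster, -1 negative


@dataclass
class ClusterTestResult:
    stat_map: np.ndarray
    clusters: list[Cluster]
    n_permutations: int
    tail: str
    cluster_alpha: float
    threshold: float
    grid_shape: tuple[int, ...] = ()
    settings: dict = field(default_factory=dict)

    @property
    def min_p(self) -> float:
        """Smallest cluster p, or 1.0 if no cluster formed."""
        return min((c.p_value for c in self.clusters), default=1.0)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.min_p < alpha


def _cluster_sums(
    stat_map: np.ndarray, threshold: float, tail: str, structure: np.ndarray
) -> tuple[list[np.ndarray], list[float], list[int]]:
    cells: list[np.ndarray] = []
    sums: list[float] = []
    signs: list[int] = []
    masks = []
    if tail in ("two", "greater"):
        masks.append((stat_map > threshold, 1))
    if tail in ("two", "less"):
        masks.append((stat_map < -threshold, -1))
    for mask, sign in masks:
        labelled, n = ndimage.label(mask, structure=structure)
        for k in range(1, n + 1):
            idx = np.flatnonzero(labelled.ravel() == k)
            cells.append(idx)
            sums.append(float(stat_map.ravel()[idx].sum()))
            signs.append(sign)
    return cells, sums, signs


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    tail: str = "two",
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    paired: bool = True,
    diagonal_adjacency: bool = False,
) -> ClusterTestResult:
    """Paired cluster-based permutation test of two subject x grid maps.

    Parameters
    ----------
    cond_a, cond_b : (n_subjects, *grid) arrays
        Per-subject maps; the grid may be 1-D (frequencies) or 2-D
        (frequency x time).  Adjacency is neighboring bins in 1-D and
        4-connectivity in 2-D (``diagonal_adjacency=True`` switches to 8).
    tail : 'two' | 'greater' (a > b) | 'less'

    The null distribution uses the maximum |cluster sum| over each sign-flip
    relabeling; cluster ``p = (exceedances + 1) / (n_perm + 1)``, so the
    smallest attainable p is ``1/(n_perm+1)``.
    """
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives meaningless p resolution; refused")
    if not paired:
        raise NotImplementedError("only the paired (within-subject) design is implemented")
    cond_a = np.asarray(cond_a, float)
    cond_b = np.asarray(cond_b, float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("condition maps must have equal shapes (equal subject counts)")
    n_subj = cond_a.shape[0]
    if n_subj < 6:
        raise ValueError("need at least 6 subjects for a meaningful permutation test")
    grid_shape = cond_a.shape[1:]
    diffs = (cond_a - cond_b).reshape(n_subj, -1)
    sd = diffs.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("degenerate (zero-variance) paired differences")

    dof = n_subj - 1
    if tail == "two":
        threshold = float(sps.t.ppf(1 - cluster_alpha / 2, dof))
    else:
        threshold = float(sps.t.ppf(1 - cluster_alpha, dof))

    if len(grid_shape) == 1:
        structure = np.ones(3, int)
    elif len(grid_shape) == 2:
        structure = (
            np.ones((3, 3), int)
            if diagonal_adjacency
            else ndimage.generate_binary_structure(2, 1)
        )
    else:
        raise ValueError("only 1-D and 2-D grids are supported")

    def t_maps(flips: np.ndarray) -> np.ndarray:
        # sign flips leave sum(d_i^2) unchanged: var derives from the flipped mean
        mean = flips @ diffs / n_subj
        ssq = np.sum(diffs**2, axis=0)
        var = (ssq - n_subj * mean**2) / dof
        return mean / np.sqrt(np.maximum(var, 1e-300) / n_subj)

    obs_t = t_maps(np.ones((1, n_subj)))[0]
    obs_map = obs_t.reshape(grid_shape)
    cells, sums, signs = _cluster_sums(obs_map, threshold, tail, structure)

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    null_t = t_maps(flips)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        _, perm_sums, _ = _cluster_sums(null_t[i].reshape(grid_shape), threshold, tail, structure)
        if perm_sums:
            null_max[i] = np.max(np.abs(perm_sums))

    clusters = []
    for idx, s, sign in zip(cells, sums, signs):
        p = float((np.sum(null_max >= abs(s)) + 1) / (n_perm + 1))
        clusters.append(Cluster(idx, s, p, sign))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterTestResult(
        obs_map,
        clusters,
        n_perm,
        tail,
        cluster_alpha,
        threshold,
        grid_shape,
        settings={"seed": seed, "n_subjects": n_subj, "paired": True},
    )


def within_subject_sem(values: np.ndarray) -> np.ndarray:
    """Within-subject SEM (Cousineau normalization with Morey's correction).

    ``values`` is (n_subjects, n_conditions) or (n_subjects, n_conditions,
    n_points).  Each subject's mean across conditions is removed (and the
    grand mean restored) before the per-condition SEM is computed; the result
    is scaled by sqrt(C / (C - 1)) to unbias the C-condition normalization.
    """
    values = np.asarray(values, float)
    if values.ndim == 2:
        values = values[:, :, None]
        squeeze = True
    elif values.ndim == 3:
        squeeze = False
    else:
        raise ValueError("values must be (subjects, conditions[, points])")
    n_subj, n_cond = values.shape[:2]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if n_cond < 2:
        raise ValueError("the within-subject correction is undefined for a single condition")
    subj_mean = values.mean(axis=1, keepdims=True)
    grand_mean = values.mean(axis=(0, 1), keepdims=True)
    centered = values - subj_mean + grand_mean
    sem = centered.std(axis=0, ddof=1) / np.sqrt(n_subj)
    sem *= np.sqrt(n_cond / (n_cond - 1))
    return sem[:, 0] if squeeze else sem


def run_length_bins(labels: np.ndarray, max_repeats: int = 10) -> np.ndarray:
    """Histogram of same-report run lengths, binned as 0..max_repeats repetitions.

    A run of L identical consecutive reports contributes one count to bin
    ``min(L - 1, max_repeats)``: bin 0 is a report not repeated at all, the
    top bin collects runs of max_repeats or more repetitions.
    """
    labels = np.asarray(labels).astype(str)
    if labels.size == 0:
        raise ValueError("empty report sequence")
    change = np.flatnonzero(labels[1:] != labels[:-1])
    run_lengths = np.diff(np.concatenate([[-1], change, [labels.size - 1]]))
    repeats = np.minimum(run_lengths - 1, max_repeats)
    return np.bincount(repeats, minlength=max_repeats + 1).astype(float)


@dataclass
class SequenceFit:
    """Binomial-law fit to the subject-averaged run-length histogram."""

    bin_counts: np.ndarray  # (11,) mean counts per repetition bin
    fitted: np.ndarray  # (11,) fitted expected counts
    r_squared: float
    p_hat: float  # fitted per-bin success probability of the binomial law
    #: heuristic: the fit explains the data AND the fitted law implies short
    #: runs (p_hat small); a perseverating reporter piles mass into the
    #: capped top bin, which a p ~ 1 binomial also fits, so R^2 alone cannot
    #: distinguish it
    stochastic: bool

    def __post_init__(self) -> None:
        if self.bin_counts.shape != self.fitted.shape or self.bin_counts.size != 11:
            raise ValueError("run-length analysis uses exactly 11 bins (0-10 repetitions)")


def runs_binomial_fit(
    label_sequences: list[np.ndarray], max_repeats: int = 10, r2_threshold: float = 0.9
) -> SequenceFit:
    """Fit a binomial law to the cross-subject mean run-length histogram.

    Per subject the same-report run lengths are histogrammed into 11 bins
    (0-10 repetitions, top bin capped), averaged across subjects, and fitted
    by least squares with a scaled Binomial(n=10, p) probability mass over
    the bins; goodness of fit is R^2 = 1 - SS_res / SS_tot.  A reporter that
    is stochastic trial-to-trial yields a sharply decaying histogram that the
    small-p binomial law captures (R^2 near 1); systematic perseveration
    piles counts into the top bin and the fit degrades.
    """
    if not label_sequences:
        raise ValueError("no report sequences given")
    counts = np.mean([run_length_bins(seq, max_repeats) for seq in label_sequences], axis=0)
    k = np.arange(max_repeats + 1)

    def model(p: float) -> np.ndarray:
        pmf = sps.binom.pmf(k, max_repeats, p)
        # closed-form least-squares scale given p
        scale = float(counts @ pmf) / max(float(pmf @ pmf), 1e-300)
        return scale * pmf

    p_grid = np.linspace(1e-3, 1 - 1e-3, 999)
    sse = np.array([float(np.sum((counts - model(p)) ** 2)) for p in p_grid])
    p_hat = float(p_grid[int(np.argmin(sse))])
    fitted = model(p_hat)
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - float(sse.min()) / max(ss_tot, 1e-300)
    stochastic = bool(r2 > r2_threshold and p_hat < 0.5)
    return SequenceFit(counts, fitted, r2, p_hat, stochastic)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float, tuple[float, float]]:
    """Pearson r with two-sided p and the Fisher-z 95% confidence interval."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    res = sps.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.959963984540054 / np.sqrt(x.size - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return r, p, ci


def max_in_range(
    axis_values: np.ndarray, values: np.ndarray, search_range: tuple[float, float] | None = None
) -> float:
    """Maximum of ``values`` restricted to ``search_range`` on its leading axis."""
    values = np.asarray(values, float)
    if search_range is not None:
        axis_values = np.asarray(axis_values, float)
        keep = (axis_values >= search_range[0] - 1e-12) & (axis_values <= search_range[1] + 1e-12)
        if not keep.any():
            raise ValueError("search range selects nothing")
        values = values[keep]
    return float(values.max())


def extract_maxima(
    per_subject: dict[str, tuple[np.ndarray, np.ndarray]],
    search_range: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Per-subject maxima of (axis, curve) pairs over a declared search range.

    Every subject in the mapping must carry a curve (no silent dropping); an
    empty mapping is refused.
    """
    if not per_subject:
        raise ValueError("no subjects given")
    out = {}
    for sid, pair in per_subject.items():
        if pair is None or pair[1] is None:
            raise ValueError(f"missing result for subject {sid}")
        axis_values, values = pair
        out[sid] = max_in_range(np.asarray(axis_values), values, search_range)
    return out
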