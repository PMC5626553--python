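"""Track-level statistics: summaries, correlation mining, fluorescence /
movement cross-correlation, clustering, and two null models.

The central scientific question this layer answers is whether fluorescence
of a tip-localised protein and tip movement are genuinely coupled. Per
track, a cross-correlation function (CCF) between normalised tip
fluorescence and the smoothed direction-corrected tip movement is computed
over a symmetric lag window; tracks are grouped by hierarchical clustering
of their CCFs, and the subcluster with the highest zero-offset CCF (the
"responding" filopodia) is tested against two nulls:

* a block-randomisation test — movement series reshuffled in blocks of
  eight frames (preserving short-range autocorrelation), reclustered, and
  accepted only when the top subcluster size matches the real one to within
  15%; and
* a discrete-time Markov-chain test — each series binned into nine
  equal-width states, independent chains simulated from the fitted
  transition matrices, and the observed correlation compared with the
  simulated correlation distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .calibration import Calibration
from .errors import (DegenerateSeriesError, InvalidTransitionMatrixError,
                     ParameterError, RandomizationError)
from .morphodynamics import AnalysisParams, classify_states, tip_persistence


# --------------------------------------------------------------------------
# track summaries
# --------------------------------------------------------------------------

SUMMARY_FIELDS = [
    "max_length_um", "mean_length_um", "straightness_at_max",
    "median_tip_extension_rate", "median_tip_retraction_rate",
    "median_base_invasion_rate", "median_base_retraction_rate",
    "tip_persistence_s", "frac_extending", "frac_retracting", "frac_stalling",
    "frac_base_invading", "frac_base_retracting", "frac_base_stable",
    "initial_tip_movement", "initial_base_movement",
    "preformation_fluor", "mean_tip_fluor", "mean_body_fluor",
]


def summarize_track(
    metrics: pd.DataFrame,
    params: AnalysisParams,
    calib: Calibration,
    movie_start_frame: int = 0,
    preformation_fluor: float = float("nan"),
) -> dict:
    """Collapse one track's per-frame metrics table into summary statistics.

    ``metrics`` must be indexed by frame and contain ``length_um``,
    ``straightness``, preprocessed ``dctm_nm_s`` / ``dcbm_nm_s`` and
    (optionally) ``norm_tip`` / ``body_mean`` columns. Rates are medians of
    the movement values beyond the ±threshold (extension/invasion above,
    retraction below). A track is flagged as a *new* filopodium when it
    appears after the movie start and starts shorter than
    ``new_filo_max_start_length_um`` (late first detection of a long
    structure usually means it drifted into focus, not that it formed).
    Fields that cannot be computed are NaN.
    """
    thr = params.state_threshold_nm_s
    out: dict = {}
    lengths = metrics["length_um"]
    out["max_length_um"] = float(lengths.max(skipna=True))
    out["mean_length_um"] = float(lengths.mean(skipna=True))
    if lengths.notna().any():
        f_max = lengths.idxmax(skipna=True)
        out["straightness_at_max"] = float(metrics["straightness"].get(f_max, np.nan))
    else:
        out["straightness_at_max"] = float("nan")

    dctm = metrics["dctm_nm_s"]
    dcbm = metrics["dcbm_nm_s"]
    out["median_tip_extension_rate"] = float(dctm[dctm > thr].median())
    out["median_tip_retraction_rate"] = float(dctm[dctm < -thr].median())
    out["median_base_invasion_rate"] = float(dcbm[dcbm > thr].median())
    out["median_base_retraction_rate"] = float(dcbm[dcbm < -thr].median())

    try:
        pers = tip_persistence(dctm, params, calib)
        out["tip_persistence_s"] = pers.seconds
        out["tip_persistence_censored"] = pers.censored
    except DegenerateSeriesError:
        out["tip_persistence_s"] = float("nan")
        out["tip_persistence_censored"] = True
    try:
        cls = classify_states(dctm, dcbm, params, calib)
        out["frac_extending"] = cls.tip_fractions["extending"]
        out["frac_retracting"] = cls.tip_fractions["retracting"]
        out["frac_stalling"] = cls.tip_fractions["stalling"]
        out["frac_base_invading"] = cls.base_fractions["invading"]
        out["frac_base_retracting"] = cls.base_fractions["retracting"]
        out["frac_base_stable"] = cls.base_fractions["stable"]
    except DegenerateSeriesError:
        for k in ("frac_extending", "frac_retracting", "frac_stalling",
                  "frac_base_invading", "frac_base_retracting", "frac_base_stable"):
            out[k] = float("nan")

    head = metrics.head(params.initial_window_points)
    out["initial_tip_movement"] = float(head["dctm_nm_s"].median())
    out["initial_base_movement"] = float(head["dcbm_nm_s"].median())

    out["preformation_fluor"] = preformation_fluor
    out["mean_tip_fluor"] = float(metrics["norm_tip"].mean()) \
        if "norm_tip" in metrics else float("nan")
    out["mean_body_fluor"] = float(metrics["body_mean"].mean()) \
        if "body_mean" in metrics else float("nan")

    start = int(metrics.index.min())
    start_len = metrics["length_um"].dropna()
    out["is_new_filopodium"] = bool(
        start > movie_start_frame
        and len(start_len) > 0
        and start_len.iloc[0] < params.new_filo_max_start_length_um
    )
    out["start_frame"] = start
    out["n_frames"] = int(len(metrics))
    return out


def correlation_matrix(
    summaries: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank-correlation matrix with Holm-adjusted p-values.

    Correlations use pairwise-complete observations; the Holm step-down
    correction is applied across all unique off-diagonal tests. Columns with
    no variation yield NaN entries.
    """
    cols = [c for c in summaries.columns
            if pd.api.types.is_numeric_dtype(summaries[c])]
    if len(summaries) < 4:
        raise ParameterError("need at least 4 tracks for a correlation matrix")
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    praw = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    pairs, pvals = [], []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = summaries[cols[i]], summaries[cols[j]]
            ok = a.notna() & b.notna()
            if ok.sum() < 4 or a[ok].nunique() < 2 or b[ok].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(a[ok], b[ok])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            praw.iloc[i, j] = praw.iloc[j, i] = p
            if np.isfinite(p):
                pairs.append((i, j))
                pvals.append(p)
    padj = praw.copy()
    if pvals:
        adj = multipletests(pvals, alpha=alpha, method="holm")[1]
        for (i, j), p in zip(pairs, adj):
            padj.iloc[i, j] = padj.iloc[j, i] = p
    np.fill_diagonal(padj.values, 0.0)
    return rho, padj


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw)."""
    return multipletests(list(pvals), method="holm")[1]


# --------------------------------------------------------------------------
# cross-correlation
# --------------------------------------------------------------------------

@dataclass
class CCFProfile:
    """Per-track cross-correlation between fluorescence and movement.

    ``lags_s`` are offsets in seconds; a *negative* offset means
    fluorescence precedes movement. ``values`` are the sample CCF at each
    offset, normalised by the product of the two series' (population)
    standard deviations, so the zero-lag value of a series with itself is 1.
    """

    track_id: int
    lags_s: np.ndarray
    values: np.ndarray
    cluster_label: Optional[int] = None

    @property
    def value_at_zero(self) -> float:
        return float(self.values[np.argmin(np.abs(self.lags_s))])


def cross_correlation(x: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample CCF of ``x`` against ``y`` for lags ``-max_lag..max_lag``.

    ``value[k] = sum_t (x[t+k] - xbar)(y[t] - ybar) / (n * sx * sy)`` with
    means/SDs over each whole series and ``n`` the series length, matching
    the classical (biased) cross-correlation convention. NaN pairs are
    skipped.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ParameterError("series must have equal length")
    n = len(x)
    has_nan = bool(np.isnan(x).any() or np.isnan(y).any())
    if not has_nan:
        xc, yc = x - x.mean(), y - y.mean()
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            raise DegenerateSeriesError("zero-variance series: CCF undefined")
        full = np.correlate(xc, yc, mode="full")  # index n-1+k holds lag k
        return full[n - 1 - max_lag: n + max_lag] / (n * sx * sy)
    xb, yb = np.nanmean(x), np.nanmean(y)
    sx, sy = np.nanstd(x), np.nanstd(y)
    if sx == 0 or sy == 0:
        raise DegenerateSeriesError("zero-variance series: CCF undefined")
    xc, yc = x - xb, y - yb
    out = np.empty(2 * max_lag + 1)
    for idx, k in enumerate(range(-max_lag, max_lag + 1)):
        if k >= 0:
            prod = xc[k:] * yc[: n - k]
        else:
            prod = xc[: n + k] * yc[-k:]
        out[idx] = np.nansum(prod) / (n * sx * sy)
    return out


def ccf_fluorescence_movement(
    norm_tip_fluor: Sequence[float],
    dctm: Sequence[float],
    params: AnalysisParams,
    calib: Calibration,
    track_id: int = -1,
) -> CCFProfile:
    """CCF between normalised tip fluorescence and smoothed tip movement.

    Both series are expected preprocessed (percentile filter + rolling
    mean). Tracks with fewer than ``min_series_points_ccf`` paired valid
    points are rejected — too short for meaningful block randomisation.
    """
    f = np.asarray(norm_tip_fluor, float)
    m = np.asarray(dctm, float)
    n_valid = int(np.sum(np.isfinite(f) & np.isfinite(m)))
    if n_valid < params.min_series_points_ccf:
        raise DegenerateSeriesError(
            f"track {track_id}: only {n_valid} paired points "
            f"(< {params.min_series_points_ccf}); excluded from CCF analysis"
        )
    max_lag = max(1, round(params.ccf_max_lag_s / calib.frame_interval_s))
    values = cross_correlation(f, m, max_lag)
    lags_s = np.arange(-max_lag, max_lag + 1) * calib.frame_interval_s
    return CCFProfile(track_id=track_id, lags_s=lags_s, values=values)


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

@dataclass
class ClusterResult:
    labels: np.ndarray            # cluster label per profile
    linkage: np.ndarray           # scipy linkage matrix (dendrogram)
    responding_label: int         # cluster with max mean CCF at offset 0
    responding_indices: np.ndarray
    responding_mean_ccf0: float


def cluster_ccfs(
    profiles: Sequence[CCFProfile],
    offset_range_s: tuple[float, float] = (-6.0, 6.0),
    n_clusters: int = 2,
    cut_height: Optional[float] = None,
    linkage_method: str = "complete",
) -> ClusterResult:
    """Hierarchically cluster CCF profiles on a restricted lag window.

    Euclidean distances between the CCF vectors at offsets within
    ``offset_range_s`` feed agglomerative clustering (complete linkage by
    default). The tree is cut either at ``cut_height`` or into
    ``n_clusters`` groups — the cut is an explicit parameter because the
    responding/non-responding split is a judgement call, not an automatic
    one. The *responding* subcluster is the one with maximal mean CCF at
    offset 0. Profiles' ``cluster_label`` fields are set in place.
    """
    if len(profiles) < 2:
        raise ParameterError("need at least 2 profiles to cluster")
    lags = profiles[0].lags_s
    sel = (lags >= offset_range_s[0]) & (lags <= offset_range_s[1])
    X = np.stack([p.values[sel] for p in profiles])
    Z = hierarchy.linkage(X, method=linkage_method, metric="euclidean")
    if cut_height is not None:
        labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    else:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    zero = int(np.argmin(np.abs(lags)))
    best_label, best_mean = -1, -np.inf
    for lab in np.unique(labels):
        mean0 = float(np.mean([p.values[zero]
                               for p, l in zip(profiles, labels) if l == lab]))
        if mean0 > best_mean:
            best_label, best_mean = int(lab), mean0
    for p, l in zip(profiles, labels):
        p.cluster_label = int(l)
    idx = np.nonzero(labels == best_label)[0]
    return ClusterResult(labels=labels, linkage=Z, responding_label=best_label,
                         responding_indices=idx, responding_mean_ccf0=best_mean)


# --------------------------------------------------------------------------
# block-randomization null
# --------------------------------------------------------------------------

def block_shuffle(series: np.ndarray, block: int, rng: np.random.Generator) -> np.ndarray:
    """Shuffle a series in contiguous blocks, preserving within-block order
    (and hence short-range autocorrelation). A trailing partial block is
    permuted along with the others."""
    x = np.asarray(series)
    blocks = [x[i: i + block] for i in range(0, len(x), block)]
    order = rng.permutation(len(blocks))
    return np.concatenate([blocks[i] for i in order])


@dataclass
class BlockRandomizationResult:
    observed_mean_ccf0: float
    null_mean_ccf0: np.ndarray
    p_value: float
    p_resolution: float         # 1 / n_accepted; p = 0 means "< p_resolution"
    n_accepted: int
    n_attempts: int
    responding_size: int


def block_randomization_test(
    fluor_series: Sequence[np.ndarray],
    movement_series: Sequence[np.ndarray],
    params: AnalysisParams,
    calib: Calibration,
    n_clusters: int = 2,
    block: int = 8,
    n_accepted: int = 1000,
    size_tol: float = 0.15,
    seed: int = 0,
    min_attempts_check: int = 500,
    max_attempts: Optional[int] = None,
) -> BlockRandomizationResult:
    """Bootstrap p-value for the responding subcluster's mean zero-lag CCF.

    Each accepted randomisation block-shuffles every track's movement
    series, recomputes the CCFs against the unshuffled fluorescence,
    re-clusters, and — if the top subcluster's size matches the real one to
    within ``size_tol`` — records its mean zero-offset CCF. The p-value is
    the fraction of accepted randomisations at least as extreme as the
    observed value (one-sided; the alternative is positive coupling). When
    no randomisation exceeds it, the p-value is 0 and ``p_resolution``
    (``1/n_accepted``) is the reportable upper bound.
    """
    if len(fluor_series) != len(movement_series) or len(fluor_series) < 2:
        raise ParameterError("need matched fluorescence/movement series lists (>= 2)")
    rng = np.random.default_rng(seed)

    def _profiles(movements):
        return [ccf_fluorescence_movement(f, m, params, calib, track_id=i)
                for i, (f, m) in enumerate(zip(fluor_series, movements))]

    real = cluster_ccfs(_profiles(movement_series), n_clusters=n_clusters)
    s_real = len(real.responding_indices)
    observed = real.responding_mean_ccf0

    accepted: list[float] = []
    attempts = 0
    cap = max_attempts if max_attempts is not None else 200 * n_accepted
    while len(accepted) < n_accepted:
        attempts += 1
        if attempts > cap:
            raise RandomizationError(
                f"gave up after {attempts - 1} attempts with "
                f"{len(accepted)} accepted", attempts - 1, len(accepted))
        if attempts == min_attempts_check and len(accepted) < 0.01 * attempts:
            raise RandomizationError(
                f"acceptance rate {len(accepted)}/{attempts} < 1%; "
                f"top-subcluster size {s_real} may be unstable",
                attempts, len(accepted))
        shuffled = [block_shuffle(m, block, rng) for m in movement_series]
        res = cluster_ccfs(_profiles(shuffled), n_clusters=n_clusters)
        if abs(len(res.responding_indices) - s_real) <= size_tol * s_real:
            accepted.append(res.responding_mean_ccf0)
    null = np.asarray(accepted)
    p = float(np.mean(null >= observed))
    return BlockRandomizationResult(
        observed_mean_ccf0=observed, null_mean_ccf0=null, p_value=p,
        p_resolution=1.0 / n_accepted, n_accepted=n_accepted,
        n_attempts=attempts, responding_size=s_real)


# --------------------------------------------------------------------------
# Markov-chain null
# --------------------------------------------------------------------------

@dataclass
class MarkovModel:
    """Discrete-time Markov chain fitted to a binned series.

    The series range is split into ``n_bins`` equal-width intervals; the
    chain's state space is restricted to the bins actually visited. The
    model is invalid (and the track discarded) when fewer than two states
    are occupied or some visited state has no outgoing transition.
    """

    n_bins: int
    bin_edges: np.ndarray
    states: np.ndarray            # occupied bin indices (sorted)
    transition_matrix: np.ndarray  # row-stochastic, over occupied states
    initial_state: int            # index into ``states``
    state_values: np.ndarray      # bin midpoints for occupied states

    def simulate(self, n_steps: int, n_sim: int, rng: np.random.Generator) -> np.ndarray:
        """Simulate ``n_sim`` realisations of ``n_steps`` states (vectorised)."""
        cum = np.cumsum(self.transition_matrix, axis=1)
        out = np.empty((n_sim, n_steps), dtype=np.int64)
        out[:, 0] = self.initial_state
        for t in range(1, n_steps):
            u = rng.random(n_sim)
            out[:, t] = (u[:, None] > cum[out[:, t - 1]]).sum(axis=1)
        return out

    def stationary_distribution(self) -> np.ndarray:
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, i])
        v = np.abs(v)
        return v / v.sum()


def fit_markov_model(series: Sequence[float], n_bins: int = 9) -> MarkovModel:
    """Bin a series into equal-width states and fit transition probabilities.

    Raises :class:`InvalidTransitionMatrixError` for degenerate series
    (constant, or containing a visited state with no outgoing observation).
    """
    x = np.asarray(series, float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise InvalidTransitionMatrixError("series too short to fit transitions")
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise InvalidTransitionMatrixError(
            "constant series occupies a single state; transition matrix degenerate")
    edges = np.linspace(lo, hi, n_bins + 1)
    bins = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    states = np.unique(bins)
    if len(states) < 2:
        raise InvalidTransitionMatrixError("fewer than two occupied states")
    index = {s: i for i, s in enumerate(states)}
    k = len(states)
    counts = np.zeros((k, k))
    for a, b in zip(bins[:-1], bins[1:]):
        counts[index[a], index[b]] += 1
    row_sums = counts.sum(axis=1)
    if np.any(row_sums == 0):
        dead = states[row_sums == 0]
        raise InvalidTransitionMatrixError(
            f"state(s) {dead.tolist()} have no outgoing observations; "
            "transition matrix invalid")
    tm = counts / row_sums[:, None]
    mids = 0.5 * (edges[:-1] + edges[1:])
    return MarkovModel(n_bins=n_bins, bin_edges=edges, states=states,
                       transition_matrix=tm, initial_state=index[bins[0]],
                       state_values=mids[states])


@dataclass
class MarkovNullResult:
    observed_corr: float
    sim_corrs: np.ndarray
    p_value: float
    z_score: float
    n_sim: int


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a ** 2).sum(axis=1) * (b ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def markov_null_test(
    norm_tip_fluor: Sequence[float],
    dctm: Sequence[float],
    n_sim: int = 10_000,
    seed: int = 0,
    n_bins: int = 9,
) -> MarkovNullResult:
    """Compare an observed fluorescence/movement correlation with the
    distribution produced by independent Markov chains.

    Both series are binned into ``n_bins`` equal-width states and a
    transition matrix is fitted to each; ``n_sim`` chain pairs are simulated
    independently (each starting from its series' initial state) and the
    Pearson correlation of each simulated pair (on bin midpoints) forms the
    null distribution. ``p = fraction of simulated correlations >= observed``
    (one-sided) and ``z = (observed - mean_sim) / sd_sim``.
    """
    f = np.asarray(norm_tip_fluor, float)
    m = np.asarray(dctm, float)
    ok = np.isfinite(f) & np.isfinite(m)
    f, m = f[ok], m[ok]
    if len(f) < 10:
        raise DegenerateSeriesError("fewer than 10 paired points for Markov test")
    observed = float(stats.pearsonr(f, m)[0])
    model_f = fit_markov_model(f, n_bins=n_bins)
    model_m = fit_markov_model(m, n_bins=n_bins)
    rng = np.random.default_rng(seed)
    sim_f = model_f.state_values[model_f.simulate(len(f), n_sim, rng)]
    sim_m = model_m.state_values[model_m.simulate(len(m), n_sim, rng)]
    corrs = _rowwise_pearson(sim_f, sim_m)
    exceed = np.nansum(corrs >= observed)
    p = float(exceed) / n_sim
    finite = corrs[np.isfinite(corrs)]
    sd = float(finite.std())
    z = (observed - float(finite.mean())) / sd if sd > 0 else float("nan")
    return MarkovNullResult(observed_corr=observed, sim_corrs=corrs,
                            p_value=p, z_score=z, n_sim=n_sim)
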