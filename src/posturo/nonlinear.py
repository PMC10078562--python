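"""Local dynamic stability of COP signals.

The stability of quiet standing is quantified by the largest Lyapunov
exponent (LyE) of the reconstructed sway dynamics, estimated with the
Rosenstein nearest-neighbour divergence method:

1. the scalar COP series is embedded by the method of time delays,
   ``X(t) = [x(t), x(t+T), ..., x(t + (d_E - 1) T)]``;
2. the delay ``T`` is the first minimum of the average mutual information
   (AMI) of the series with its lagged copy, computed per trial and per
   sway direction;
3. the embedding dimension ``d_E`` comes from global false nearest
   neighbours (FNN), or is fixed by the caller;
4. each embedded point is paired with its nearest neighbour subject to a
   Theiler exclusion equal to the mean period of the signal, the pairwise
   distance ``d_j(i)`` is tracked ``i`` steps forward, and the LyE is the
   least-squares slope of ``<ln d_j(i)>`` versus time over a short fit
   window (default 0 to 0.75 s).

A larger exponent means faster divergence of neighbouring trajectories,
i.e. lower local dynamic stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram
from sklearn.neighbors import KDTree

from .core import (
    AP,
    CopTrial,
    DataError,
    DegenerateInputError,
    DivergenceCurve,
    EmbeddingSpec,
)

AUTO = "AUTO"


@dataclass(frozen=True)
class AmiResult:
    """AMI curve (nats) over lags 0..max_lag and the chosen delay."""

    lags: np.ndarray
    ami: np.ndarray
    first_minimum: int
    fallback_used: bool


@dataclass(frozen=True)
class FnnResult:
    """FNN fraction per candidate dimension and the chosen dimension."""

    dimensions: np.ndarray
    fractions: np.ndarray
    chosen_dimension: int
    saturated: bool


def average_mutual_information(
    series: np.ndarray, max_lag: int, n_bins: int = 64, min_tol: float = 0.05
) -> AmiResult:
    """AMI of a series with its lagged copy, and its first significant minimum.

    The AMI at lag tau is the mutual information (nats) of the joint
    histogram of ``(x_t, x_{t+tau})`` on an ``n_bins`` x ``n_bins``
    equal-width grid.  The embedding delay is the first interior minimum
    of the curve, located robustly: the AMI valley of real signals is
    flat to within the histogram-estimator jitter, so the delay is the
    centre of the first plateau of lags whose AMI lies within ``min_tol``
    nats of the curve minimum.  The plateau only counts as a minimum if
    the curve drops into it and rises out of it by more than ``min_tol``
    (pointwise local minima inside estimator noise are not structure).
    If no such minimum exists up to ``max_lag`` — monotone-decaying AMI
    of stochastic signals, or the flat curve of iid noise — the fallback
    is the first lag where AMI drops below ``AMI(1)/e``, else ``max_lag``
    (flagged).
    """
    x = np.asarray(series, dtype=float)
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2")
    if len(x) <= max_lag + 1:
        raise DataError("series too short for requested max_lag")
    if np.ptp(x) == 0:
        raise DegenerateInputError("AMI undefined for a constant series")

    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    ami = np.empty(max_lag + 1)
    for tau in range(max_lag + 1):
        a = idx[: len(x) - tau]
        b = idx[tau:]
        joint = np.bincount(a * n_bins + b, minlength=n_bins * n_bins).astype(float)
        joint /= joint.sum()
        joint = joint.reshape(n_bins, n_bins)
        px = joint.sum(axis=1)
        py = joint.sum(axis=0)
        nz = joint > 0
        ami[tau] = float(
            np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz]))
        )

    # valley detection on a lightly smoothed curve: confirm the first
    # valley once the curve has risen min_tol above its running minimum,
    # then report the centre of the near-minimal plateau
    w = 5
    kernel = np.ones(w)
    smooth = np.convolve(ami, kernel, mode="same") / np.convolve(
        np.ones_like(ami), kernel, mode="same"
    )
    first_min = 0
    run_min = smooth[1]
    run_argmin = 1
    for tau in range(2, max_lag + 1):
        if smooth[tau] < run_min:
            run_min = smooth[tau]
            run_argmin = tau
        elif smooth[tau] >= run_min + min_tol:
            lo = hi = run_argmin
            while lo > 1 and smooth[lo - 1] <= run_min + min_tol:
                lo -= 1
            while hi < tau and smooth[hi + 1] <= run_min + min_tol:
                hi += 1
            first_min = int(round(0.5 * (lo + hi)))
            break
    fallback = first_min == 0
    if fallback:
        below = np.nonzero(ami[1:] < ami[1] / np.e)[0]
        first_min = int(below[0]) + 1 if below.size else max_lag
    return AmiResult(np.arange(max_lag + 1), ami, first_min, fallback)


def delay_embed(series: np.ndarray, spec: EmbeddingSpec) -> np.ndarray:
    """Time-delay embedding: rows are ``[x(t), x(t+T), ..., x(t+(d_E-1)T)]``.

    Returns an ``(M, d_E)`` array with ``M = N - (d_E - 1) T`` points.
    """
    x = np.asarray(series, dtype=float)
    T, d = spec.delay, spec.dimension
    m = len(x) - (d - 1) * T
    if m < 1:
        raise DataError(
            f"series of length {len(x)} too short to embed with T={T}, d_E={d}"
        )
    return np.column_stack([x[k * T : k * T + m] for k in range(d)])


def false_nearest_neighbors(
    series: np.ndarray,
    delay: int,
    max_dim: int = 10,
    r_tol: float = 15.0,
    a_tol: float = 2.0,
    threshold: float = 0.01,
) -> FnnResult:
    """Global false-nearest-neighbour analysis (Kennel criterion).

    For each candidate dimension ``d`` the nearest neighbour of every
    embedded point is found; the neighbour is *false* if the extra
    ``(d+1)``-th coordinate inflates the pair distance by more than
    ``r_tol``, or pushes it beyond ``a_tol`` times the series scale
    (its standard deviation).  The chosen dimension is the smallest with a
    false fraction below ``threshold``; if none qualifies, ``max_dim`` is
    returned with ``saturated=True``.
    """
    x = np.asarray(series, dtype=float)
    scale = float(np.std(x))
    if scale == 0:
        raise DegenerateInputError("FNN undefined for a constant series")
    dims = np.arange(1, max_dim + 1)
    fractions = np.full(len(dims), np.nan)
    chosen = None
    for k, d in enumerate(dims):
        # points must also exist in dimension d+1
        m_next = len(x) - d * delay
        if m_next < 10:
            raise DataError("series too short for FNN at requested max_dim")
        emb = delay_embed(x, EmbeddingSpec(delay, d))[:m_next]
        tree = KDTree(emb)
        dist, ind = tree.query(emb, k=2)
        nn_dist = dist[:, 1]
        nn_ind = ind[:, 1]
        extra = np.abs(x[d * delay : d * delay + m_next] - x[nn_ind + d * delay])
        grown = np.sqrt(nn_dist**2 + extra**2)
        # near-duplicate pairs (periodic revisits) sit at the floating-point
        # noise floor; their distance ratio is meaningless, not "false"
        resolvable = grown > 1e-8 * scale
        ok = resolvable & (nn_dist > 0)
        ratio = np.zeros(m_next)
        ratio[ok] = extra[ok] / nn_dist[ok]
        ratio[resolvable & ~ (nn_dist > 0)] = np.inf
        false = (ratio > r_tol) | (resolvable & (grown / scale > a_tol))
        fractions[k] = float(np.mean(false))
        if chosen is None and fractions[k] < threshold:
            chosen = int(d)
    saturated = chosen is None
    if saturated:
        chosen = int(max_dim)
    return FnnResult(dims, fractions, chosen, saturated)


def mean_period(series: np.ndarray, sampling_rate: float) -> float:
    """Mean period (s): reciprocal of the power-weighted mean frequency.

    The mean frequency is the power-spectrum-weighted average of the
    positive frequencies (DC excluded).  Used as the Theiler window for
    neighbour searches.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 64:
        raise DataError("mean_period needs at least 64 samples")
    freqs, power = periodogram(x, fs=sampling_rate, detrend=False)
    freqs, power = freqs[1:], power[1:]  # drop DC
    total = power.sum()
    if total <= 0:
        raise DegenerateInputError("zero spectral power, mean period undefined")
    return float(total / np.sum(freqs * power))


def _nearest_neighbors_theiler(points: np.ndarray, window: int) -> np.ndarray:
    """Index of each point's nearest neighbour with |i - j| > window.

    Returns -1 where no admissible neighbour exists.
    """
    m = len(points)
    tree = KDTree(points)
    nn = np.full(m, -1, dtype=int)
    pending = np.arange(m)
    k = min(m, 2 * window + 8)
    while pending.size:
        dist, ind = tree.query(points[pending], k=k)
        sep = np.abs(ind - pending[:, None])
        valid = sep > window
        has = valid.any(axis=1)
        first = np.argmax(valid, axis=1)
        nn[pending[has]] = ind[has, first[has]]
        pending = pending[~has]
        if k == m:
            break
        k = min(m, k * 2)
    return nn


def rosenstein_lye(
    series: np.ndarray,
    spec: EmbeddingSpec,
    sampling_rate: float,
    track_time: float = 1.0,
    fit_window: tuple[float, float] = (0.0, 0.75),
    theiler_window: int | None = None,
) -> DivergenceCurve:
    """Largest Lyapunov exponent by the Rosenstein divergence-slope method.

    For every embedded point the nearest neighbour with temporal index
    separation greater than the Theiler window (default: the signal's mean
    period, in samples) is found.  ``d_j(i)`` is the Euclidean distance of
    the pair ``i`` steps later; the curve value at time ``i / fs`` is the
    mean of ``ln d_j(i)`` over all pairs still inside the series.  The LyE
    (1/s) is the OLS slope of the curve over ``fit_window`` (inclusive).
    Pairs with zero initial distance are excluded.
    """
    x = np.asarray(series, dtype=float)
    points = delay_embed(x, spec)
    m = len(points)
    if m < 100:
        raise DataError(f"only {m} embedded points; need >= 100")
    if theiler_window is None:
        theiler_window = int(round(mean_period(x, sampling_rate) * sampling_rate))
    # keep enough admissible neighbour pairs when the signal's mean period
    # is long relative to the record (short trials of slow signals)
    theiler_window = max(1, min(theiler_window, (m - 2) // 3))

    nn = _nearest_neighbors_theiler(points, theiler_window)
    ref = np.nonzero(nn >= 0)[0]
    if ref.size == 0:
        raise DegenerateInputError("no neighbour pairs admissible under Theiler window")
    d0 = np.linalg.norm(points[ref] - points[nn[ref]], axis=1)
    keep = d0 > 0
    ref, pair = ref[keep], nn[ref][keep]
    if ref.size == 0:
        raise DegenerateInputError("all neighbour pairs have zero initial distance")

    n_steps = int(round(track_time * sampling_rate))
    times = np.arange(n_steps + 1) / sampling_rate
    mean_log = np.full(n_steps + 1, np.nan)
    n_pairs = np.zeros(n_steps + 1, dtype=int)
    horizon = np.maximum(ref, pair)
    for i in range(n_steps + 1):
        alive = horizon + i <= m - 1
        if not alive.any():
            break
        d = np.linalg.norm(points[ref[alive] + i] - points[pair[alive] + i], axis=1)
        pos = d > 0
        if not pos.any():
            break
        mean_log[i] = float(np.mean(np.log(d[pos])))
        n_pairs[i] = int(np.sum(pos))

    lo, hi = fit_window
    mask = (times >= lo) & (times <= hi) & np.isfinite(mean_log)
    if mask.sum() < 2:
        raise DataError("fewer than 2 curve samples inside the fit window")
    slope, intercept = np.polyfit(times[mask], mean_log[mask], 1)
    ok = np.isfinite(mean_log)
    return DivergenceCurve(
        times=times[ok],
        mean_log_divergence=mean_log[ok],
        n_pairs=n_pairs[ok],
        fit_window=(lo, hi),
        slope=float(slope),
        intercept=float(intercept),
    )


def trial_lye(
    trial: CopTrial,
    direction: str = AP,
    dimension: int | str = 6,
    ami_max_lag: int = 150,
    ami_n_bins: int = 64,
    track_time: float = 1.0,
    fit_window: tuple[float, float] = (0.0, 0.75),
    fnn_max_dim: int = 10,
) -> tuple[EmbeddingSpec, DivergenceCurve]:
    """Per-trial local dynamic stability of one sway direction.

    The delay is the per-trial AMI first minimum for the requested
    coordinate; the dimension is ``dimension`` (default 6) or FNN-selected
    when ``dimension="AUTO"``.  The COP series is used unfiltered.
    """
    series = trial.coordinate(direction)
    # cap the delay search so the embedding keeps >= 100 points
    max_feasible = (len(series) - 100 - 1) // max(1, (int(dimension) if dimension != AUTO else fnn_max_dim) - 1)
    max_lag = max(2, min(ami_max_lag, max_feasible))
    ami = average_mutual_information(series, max_lag=max_lag, n_bins=ami_n_bins)
    delay = max(1, ami.first_minimum)
    if dimension == AUTO:
        fnn = false_nearest_neighbors(series, delay, max_dim=fnn_max_dim)
        dim = fnn.chosen_dimension
    else:
        dim = int(dimension)
    spec = EmbeddingSpec(delay=delay, dimension=dim, direction=direction)
    curve = rosenstein_lye(
        series,
        spec,
        sampling_rate=trial.sampling_rate,
        track_time=track_time,
        fit_window=fit_window,
    )
    return spec, curve
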