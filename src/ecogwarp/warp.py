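"""Dynamic time warping of velocity profiles and application of the
resulting time-registration paths to series, spectrograms and raw signals.

The DTW variant is the classic symmetric step pattern with no slope
constraint: steps {(1,0), (0,1), (1,1)} with weights (1, 2, 1) on the local
cost, absolute difference as the 1-D Euclidean local cost, and
``g(0,0) = 2*d(0,0)``.  The registration path maps each time point of a
query trial onto the time axis of a reference trial; applying it to a
spectrogram re-maps frames while leaving the frequency axis untouched,
which is the whole point — warping the raw time-domain signal instead
distorts its frequency content (that operation is provided only to
demonstrate the artifact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import SignalTrace
from .tfr import NormalizedSpectrogram, Spectrogram, band_power

__all__ = [
    "RegistrationPath",
    "dtw_path",
    "dtw_cost",
    "warp_series",
    "warp_spectrogram",
    "warp_signal_time_domain",
    "path_from_gamma",
]

# relative tolerance used when matching backtracking candidates; float
# associativity differences between the vectorized forward pass and the
# stepwise predecessor sums are at this scale
_BT_RTOL = 1e-9

try:  # optional compiled kernels; the numpy path below is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - environment dependent
    _HAVE_NUMBA = False

if _HAVE_NUMBA:

    @_njit(cache=False)
    def _dp_matrix_nb(ref, q):  # pragma: no cover - exercised via dtw_path
        n, m = ref.size, q.size
        g = np.empty((n, m))
        g[0, 0] = 2.0 * abs(ref[0] - q[0])
        for j in range(1, m):
            g[0, j] = g[0, j - 1] + abs(ref[0] - q[j])
        for i in range(1, n):
            g[i, 0] = g[i - 1, 0] + abs(ref[i] - q[0])
            for j in range(1, m):
                d = abs(ref[i] - q[j])
                v = g[i - 1, j - 1] + 2.0 * d
                a = g[i - 1, j] + d
                if a < v:
                    v = a
                c = g[i, j - 1] + d
                if c < v:
                    v = c
                g[i, j] = v
        return g

    @_njit(cache=False)
    def _dp_cost_nb(ref, q):  # pragma: no cover
        n, m = ref.size, q.size
        prev = np.empty(m)
        prev[0] = 2.0 * abs(ref[0] - q[0])
        for j in range(1, m):
            prev[j] = prev[j - 1] + abs(ref[0] - q[j])
        cur = np.empty(m)
        for i in range(1, n):
            cur[0] = prev[0] + abs(ref[i] - q[0])
            for j in range(1, m):
                d = abs(ref[i] - q[j])
                v = prev[j - 1] + 2.0 * d
                a = prev[j] + d
                if a < v:
                    v = a
                c = cur[j - 1] + d
                if c < v:
                    v = c
                cur[j] = v
            prev, cur = cur, prev
        return prev[m - 1]

    @_njit(cache=False)
    def _backtrack_nb(g, ref, q, rtol):  # pragma: no cover
        n, m = ref.size, q.size
        out = np.empty((n + m - 1, 2), np.int64)
        k = n + m - 2
        i, j = n - 1, m - 1
        out[k, 0], out[k, 1] = i, j
        while i > 0 or j > 0:
            d = abs(ref[i] - q[j])
            best = np.inf
            if i > 0 and j > 0:
                diag = g[i - 1, j - 1] + 2.0 * d
                if diag < best:
                    best = diag
            if i > 0:
                vert = g[i - 1, j] + d
                if vert < best:
                    best = vert
            if j > 0:
                horiz = g[i, j - 1] + d
                if horiz < best:
                    best = horiz
            tol = rtol * (1.0 + best)
            # preference order: diagonal, then reference-advance, then query
            if i > 0 and j > 0 and g[i - 1, j - 1] + 2.0 * d <= best + tol:
                i, j = i - 1, j - 1
            elif i > 0 and g[i - 1, j] + d <= best + tol:
                i = i - 1
            else:
                j = j - 1
            k -= 1
            out[k, 0], out[k, 1] = i, j
        return out[k:]


@dataclass
class RegistrationPath:
    """A monotone DTW alignment between a reference and a query time axis.

    ``pairs`` is an ordered (L, 2) int array of (ref_index, query_index)
    with first pair (0, 0), last pair (N-1, M-1), steps in
    {(1,0), (0,1), (1,1)}, and every index of both axes visited at least
    once (continuity).  ``normalized_cost`` is ``total_cost / (N + M)``,
    the symmetric-form per-sample normalization.
    """

    pairs: np.ndarray
    total_cost: float
    n_ref: int
    n_query: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.intp)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must be an (L, 2) index array")
        self.validate()

    @property
    def normalized_cost(self) -> float:
        return self.total_cost / (self.n_ref + self.n_query)

    @property
    def ref_index(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def query_index(self) -> np.ndarray:
        return self.pairs[:, 1]

    def validate(self) -> None:
        p = self.pairs
        if self.total_cost < 0:
            raise ValueError("total_cost must be non-negative")
        if tuple(p[0]) != (0, 0) or tuple(p[-1]) != (self.n_ref - 1, self.n_query - 1):
            raise ValueError("path must run corner to corner")
        steps = np.diff(p, axis=0)
        ok = (steps >= 0).all() and (steps <= 1).all() and (steps.sum(axis=1) >= 1).all()
        if not ok:
            raise ValueError("path steps must be in {(1,0),(0,1),(1,1)}")

    def transposed(self) -> "RegistrationPath":
        """The same alignment with reference and query roles swapped."""
        return RegistrationPath(
            pairs=self.pairs[:, ::-1].copy(),
            total_cost=self.total_cost,
            n_ref=self.n_query,
            n_query=self.n_ref,
            meta=dict(self.meta),
        )


def _as_1d(x) -> np.ndarray:
    a = np.asarray(getattr(x, "vx", x), dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty series")
    if not np.all(np.isfinite(a)):
        raise ValueError("series contains non-finite values")
    return a


def _forward(ref: np.ndarray, query: np.ndarray, keep_matrix: bool):
    """Vectorized DP forward pass for the symmetric (1,2,1) step pattern.

    Row i of the cumulative matrix satisfies
    ``g[i,j] = min(g[i-1,j]+d, g[i-1,j-1]+2d, g[i,j-1]+d)``; the horizontal
    chain within a row is resolved in closed form with a running minimum
    over ``a_k - cumsum(d)_k``, so the whole pass is O(N) numpy row ops.
    """
    n, m = ref.size, query.size
    d0 = np.abs(ref[0] - query)
    row = np.empty(m)
    row[0] = 2.0 * d0[0]
    row[1:] = d0[1:]
    np.cumsum(row, out=row)  # g[0,j] = 2 d(0,0) + sum d(0,1..j)
    g = np.empty((n, m)) if keep_matrix else None
    if keep_matrix:
        g[0] = row
    for i in range(1, n):
        d = np.abs(ref[i] - query)
        a = np.empty(m)
        a[0] = row[0] + d[0]
        np.minimum(row[1:] + d[1:], row[:-1] + 2.0 * d[1:], out=a[1:])
        c = np.cumsum(d)
        row = np.minimum.accumulate(a - c) + c
        if keep_matrix:
            g[i] = row
    return row[-1], g


def dtw_cost(reference, query) -> float:
    """Total DTW cost only (no path recovery); O(N*M) time, O(M) memory."""
    ref, q = _as_1d(reference), _as_1d(query)
    if _HAVE_NUMBA:
        return float(_dp_cost_nb(ref, q))
    total, _ = _forward(ref, q, keep_matrix=False)
    return float(total)


def dtw_path(reference, query) -> RegistrationPath:
    """Align ``query`` to ``reference`` by dynamic time warping.

    Local cost is the absolute velocity difference ``d(i,j) = |ref_i - q_j|``
    (1-D Euclidean); the recursion uses the symmetric step weights (1, 2, 1)
    with ``g(0,0) = 2*d(0,0)`` and no slope or band constraint.  The path is
    recovered by backtracking with ties broken preferring the diagonal step,
    then the reference-advancing step — this matters on near-zero velocity
    pauses, where many cells tie, and fixes the result deterministically.

    Accepts plain arrays or :class:`~ecogwarp.kinematics.VelocitySeries`
    (whose signed X velocity is used).
    """
    ref, q = _as_1d(reference), _as_1d(query)
    n, m = ref.size, q.size
    if _HAVE_NUMBA:
        g = _dp_matrix_nb(ref, q)
        pairs = _backtrack_nb(g, ref, q, _BT_RTOL).astype(np.intp)
        return RegistrationPath(
            pairs=pairs, total_cost=float(g[-1, -1]), n_ref=n, n_query=m
        )
    total, g = _forward(ref, q, keep_matrix=True)

    # backtrack; candidate order encodes the tie-break preference
    i, j = n - 1, m - 1
    rev = [(i, j)]
    while i > 0 or j > 0:
        d = abs(ref[i] - q[j])
        cands: list[tuple[float, int, int]] = []
        if i > 0 and j > 0:
            cands.append((g[i - 1, j - 1] + 2.0 * d, i - 1, j - 1))
        if i > 0:
            cands.append((g[i - 1, j] + d, i - 1, j))
        if j > 0:
            cands.append((g[i, j - 1] + d, i, j - 1))
        best = min(c[0] for c in cands)
        tol = _BT_RTOL * (1.0 + best)
        for val, pi, pj in cands:
            if val <= best + tol:
                i, j = pi, pj
                break
        rev.append((i, j))
    pairs = np.asarray(rev[::-1], dtype=np.intp)
    return RegistrationPath(pairs=pairs, total_cost=float(total), n_ref=n, n_query=m)


def warp_series(query, path: RegistrationPath, aggregate: str = "mean") -> np.ndarray:
    """Re-express a query-axis series on the reference time axis.

    Output sample ``i`` aggregates ``query[j]`` over all path pairs with
    ``ref_index == i`` (arithmetic mean by default), so the result has the
    reference length.  Because path ref indices are non-decreasing and
    contiguous, the aggregation reduces to segmented means.
    """
    if aggregate != "mean":
        raise ValueError("only mean aggregation is supported")
    q = np.asarray(getattr(query, "vx", query), dtype=float)
    if q.ndim not in (1, 2):
        raise ValueError("query must be 1-D or (time, feature) 2-D")
    ridx, qidx = path.ref_index, path.query_index
    if q.shape[0] < path.n_query or qidx.max() >= q.shape[0]:
        raise ValueError("path indices exceed query length")
    counts = np.bincount(ridx, minlength=path.n_ref).astype(float)
    starts = np.searchsorted(ridx, np.arange(path.n_ref))
    gathered = q[qidx]
    summed = np.add.reduceat(gathered, starts, axis=0)
    if gathered.ndim == 2:
        return summed / counts[:, None]
    return summed / counts


def warp_spectrogram(
    spec: NormalizedSpectrogram | Spectrogram, path: RegistrationPath
) -> NormalizedSpectrogram | Spectrogram:
    """Warp every frequency column of a spectrogram onto the reference grid.

    The frequency axis is untouched — only frames are re-mapped — so the
    spectral content of each time slice is preserved exactly, unlike
    :func:`warp_signal_time_domain`.
    """
    if spec.values.shape[0] != path.n_query:
        raise ValueError(
            f"path was built for {path.n_query} frames, spectrogram has "
            f"{spec.values.shape[0]}"
        )
    warped = warp_series(spec.values, path)
    frame_times = spec.frame_times
    if path.n_ref != frame_times.size:
        # reference grid has its own frame count; rebuild times from the hop
        hop = float(frame_times[1] - frame_times[0]) if frame_times.size > 1 else 0.01
        frame_times = frame_times[0] + hop * np.arange(path.n_ref)
    if isinstance(spec, NormalizedSpectrogram):
        return NormalizedSpectrogram(
            frame_times=frame_times.copy(),
            freqs=spec.freqs.copy(),
            values=warped,
            baseline=None if spec.baseline is None else spec.baseline.copy(),
            baseline_window=spec.baseline_window,
        )
    return Spectrogram(frame_times=frame_times.copy(), freqs=spec.freqs.copy(), power=warped)


def warp_signal_time_domain(
    signal: SignalTrace, path: RegistrationPath, samples_per_frame: int
) -> SignalTrace:
    """Warp a raw signal along a frame-level path (anti-pattern demo).

    The frame-level registration is expanded to sample resolution by linear
    interpolation: each reference frame maps to the mean query-frame index
    of its path pairs, the map is interpolated to the sample grid, and the
    signal is resampled along it.  Stretching or compressing the waveform in
    this way shifts instantaneous frequency, so harmonic content (e.g. line
    noise) is smeared — which is exactly why spectrograms, not signals,
    should be warped.
    """
    if samples_per_frame < 1:
        raise ValueError("samples_per_frame must be >= 1")
    # mean query frame per reference frame (non-decreasing by monotonicity)
    counts = np.bincount(path.ref_index, minlength=path.n_ref).astype(float)
    qmean = np.bincount(path.ref_index, weights=path.query_index, minlength=path.n_ref)
    qmean /= counts
    n_out = path.n_ref * samples_per_frame
    ref_frame_coord = np.arange(n_out) / samples_per_frame
    # extend the frame map by its final slope so the last partial frame is
    # not clamped (keeps the identity path an exact no-op)
    xp = np.arange(path.n_ref + 1, dtype=float)
    tail = qmean[-1] - qmean[-2] if path.n_ref > 1 else 1.0
    fp = np.append(qmean, qmean[-1] + max(tail, 0.0))
    query_frame_coord = np.interp(ref_frame_coord, xp, fp)
    query_sample = query_frame_coord * samples_per_frame
    data = np.interp(query_sample, np.arange(len(signal)), signal.data)
    return SignalTrace(data=data, rate=signal.rate, t0=signal.t0, name=signal.name)


def path_from_gamma(
    ref_spec: NormalizedSpectrogram,
    query_spec: NormalizedSpectrogram,
    band: tuple[float, float] = (65.0, 90.0),
) -> RegistrationPath:
    """Registration path derived from gamma-band power instead of kinematics.

    Band-limited gamma (65-90 Hz by default) tracks movement closely enough
    to serve as a kinematics-free alignment signal, e.g. for imagined
    movements; the path is simply DTW between the two band-power series.
    """
    if ref_spec.freqs.shape != query_spec.freqs.shape or not np.allclose(
        ref_spec.freqs, query_spec.freqs
    ):
        raise ValueError("spectrograms must share a frequency grid")
    return dtw_path(band_power(ref_spec, band), band_power(query_spec, band))
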