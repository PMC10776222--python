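"""Constrained dynamic frequency–time warping (DFTW) distances.

Two normalized unit spectrograms are compared by a two-level dynamic
program: an outer time alignment over frames whose local cost is an
inner frequency alignment between the two frame spectra over mel bins.
Both levels use the symmetric step pattern (match / insert / delete,
weight 1 each) and a Sakoe–Chiba band — a half-width fraction of the
longer sequence in time, a maximum bin displacement in frequency — and
both normalize the optimal cost by the warping-path length so distances
are comparable across unit durations. The optimal alignment cost is the
acoustic distance; it is nonnegative, symmetric and zero for identical
spectrograms, but (like all DTW-family measures) does not satisfy the
triangle inequality.

Ties between equal-cost alignments resolve to the shortest path, making
the path-length-normalized value well defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

_INF = 1e300


@dataclass
class DftwConfig:
    """Alignment constraints and cost conventions.

    ``time_band_frac`` is the Sakoe–Chiba half-width as a fraction of
    the longer sequence; ``freq_band_bins`` the maximum mel-bin
    displacement of the frequency alignment; ``local_cost`` the
    elementwise cost (absolute or squared difference); ``normalize_by``
    whether the outer optimum is divided by its path length.
    """

    time_band_frac: float = 0.1
    freq_band_bins: int = 8
    local_cost: str = "abs"
    normalize_by: str = "path_length"

    def __post_init__(self) -> None:
        if not 0.0 < self.time_band_frac <= 1.0:
            raise ValueError("time_band_frac must be in (0, 1]")
        if self.freq_band_bins < 0:
            raise ValueError("freq_band_bins must be >= 0")
        if self.local_cost not in ("abs", "squared"):
            raise ValueError("local_cost must be 'abs' or 'squared'")
        if self.normalize_by not in ("path_length", "none"):
            raise ValueError("normalize_by must be 'path_length' or 'none'")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise DFTW distances over an ordered unit list."""

    values: np.ndarray
    unit_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n = len(self.unit_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match unit count")
        if not np.allclose(self.values, self.values.T, atol=1e-5):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.values < 0) or np.any(np.diag(self.values) != 0):
            raise ValueError("distances must be nonnegative with a zero diagonal")

    def __len__(self) -> int:
        return len(self.unit_ids)


@njit(cache=True)
def _frame_cost_kernel(a, b, band, squared, D, L):  # pragma: no cover - numba
    """Banded DP over mel bins; lexicographic (total cost, path length).

    D and L are (n, n) workspaces reused across calls; cells outside the
    band are never read (predecessor validity is checked by band
    membership, not by sentinel values).
    """
    n = a.shape[0]
    for i in range(n):
        jlo = i - band
        if jlo < 0:
            jlo = 0
        jhi = i + band
        if jhi > n - 1:
            jhi = n - 1
        for j in range(jlo, jhi + 1):
            diff = a[i] - b[j]
            if diff < 0.0:
                diff = -diff
            d = diff * diff if squared else diff
            if i == 0 and j == 0:
                D[0, 0] = d
                L[0, 0] = 1
                continue
            best = _INF
            best_len = 0
            if i > 0 and j > 0 and -band <= (i - 1) - (j - 1) <= band:
                best = D[i - 1, j - 1]
                best_len = L[i - 1, j - 1]
            if i > 0 and -band <= (i - 1) - j <= band:
                c = D[i - 1, j]
                if c < best or (c == best and L[i - 1, j] < best_len):
                    best = c
                    best_len = L[i - 1, j]
            if j > 0 and -band <= i - (j - 1) <= band:
                c = D[i, j - 1]
                if c < best or (c == best and L[i, j - 1] < best_len):
                    best = c
                    best_len = L[i, j - 1]
            D[i, j] = best + d
            L[i, j] = best_len + 1
    return D[n - 1, n - 1], L[n - 1, n - 1]


@njit(cache=True)
def _dftw_kernel(A, B, w, fband, squared):  # pragma: no cover - numba
    """Outer banded time DP; local cost = normalized inner frequency DP.

    A and B are (n_frames, n_mels) row-contiguous. Returns (total cost,
    path length) of the lexicographically optimal alignment.
    """
    ta, tb = A.shape[0], B.shape[0]
    nm = A.shape[1]
    D = np.empty((ta, tb))
    L = np.zeros((ta, tb), np.int64)
    iD = np.empty((nm, nm))
    iL = np.zeros((nm, nm), np.int64)
    for i in range(ta):
        jlo = i - w
        if jlo < 0:
            jlo = 0
        jhi = i + w
        if jhi > tb - 1:
            jhi = tb - 1
        for j in range(jlo, jhi + 1):
            c_sum, c_len = _frame_cost_kernel(A[i], B[j], fband, squared, iD, iL)
            d = c_sum / c_len
            if i == 0 and j == 0:
                D[0, 0] = d
                L[0, 0] = 1
                continue
            best = _INF
            best_len = 0
            if i > 0 and j > 0 and -w <= (i - 1) - (j - 1) <= w:
                best = D[i - 1, j - 1]
                best_len = L[i - 1, j - 1]
            if i > 0 and -w <= (i - 1) - j <= w:
                c = D[i - 1, j]
                if c < best or (c == best and L[i - 1, j] < best_len):
                    best = c
                    best_len = L[i - 1, j]
            if j > 0 and -w <= i - (j - 1) <= w:
                c = D[i, j - 1]
                if c < best or (c == best and L[i, j - 1] < best_len):
                    best = c
                    best_len = L[i, j - 1]
            D[i, j] = best + d
            L[i, j] = best_len + 1
    return D[ta - 1, tb - 1], L[ta - 1, tb - 1]


def frame_cost(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    freq_band_bins: int = 8,
    local_cost: str = "abs",
) -> float:
    """Optimal monotone frequency alignment cost between two frame spectra.

    Bin displacement is constrained to ``|i − j| ≤ freq_band_bins``; the
    optimal total is divided by its path length. With a zero band this
    collapses to the mean elementwise difference (no frequency warping).
    """
    a = np.ascontiguousarray(frame_a, dtype=np.float64)
    b = np.ascontiguousarray(frame_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("frames must be 1-D and of equal length")
    n = a.size
    D = np.empty((n, n))
    L = np.zeros((n, n), np.int64)
    total, length = _frame_cost_kernel(a, b, freq_band_bins, local_cost == "squared", D, L)
    return float(total / length)


def _as_frames(spec) -> np.ndarray:
    values = spec.values if hasattr(spec, "values") else np.asarray(spec)
    return np.ascontiguousarray(np.asarray(values, dtype=np.float64).T)


def time_band_width(n_frames_a: int, n_frames_b: int, time_band_frac: float) -> int:
    """Sakoe–Chiba half-width; widened to the minimum feasible width."""
    w = max(1, round(time_band_frac * max(n_frames_a, n_frames_b)))
    gap = abs(n_frames_a - n_frames_b)
    if w < gap:
        warnings.warn(
            f"time band half-width {w} cannot connect endpoints of lengths "
            f"{n_frames_a} and {n_frames_b}; widened to {gap}",
            stacklevel=3,
        )
        w = gap
    return w


def dftw_distance(spec_a, spec_b, config: DftwConfig | None = None) -> float:
    """DFTW acoustic distance between two unit spectrograms.

    Accepts :class:`~rookvoc.preprocessing.UnitSpectrogram` objects or
    raw (n_mels, n_frames) arrays with matching band counts.
    """
    config = config or DftwConfig()
    A, B = _as_frames(spec_a), _as_frames(spec_b)
    if A.shape[0] < 1 or B.shape[0] < 1:
        raise ValueError("spectrograms must have at least one frame")
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"band counts differ: {A.shape[1]} vs {B.shape[1]}")
    w = time_band_width(A.shape[0], B.shape[0], config.time_band_frac)
    total, length = _dftw_kernel(A, B, w, config.freq_band_bins, config.local_cost == "squared")
    return float(total / length) if config.normalize_by == "path_length" else float(total)


def pairwise_distances(
    spectrograms: list,
    config: DftwConfig | None = None,
    unit_ids: list[str] | None = None,
    checkpoint_path=None,
    chunk_rows: int = 64,
    progress: bool = False,
) -> DistanceMatrix:
    """Full symmetric DFTW distance matrix over a list of spectrograms.

    Computed row-chunk by row-chunk; after each chunk the partial matrix
    is persisted to ``checkpoint_path`` (``.npy``) when given, so an
    interrupted computation restarts from the last complete chunk. The
    result is independent of chunking. Distances are stored as float32.
    """
    config = config or DftwConfig()
    if len(spectrograms) < 2:
        raise ValueError("need at least two spectrograms")
    if unit_ids is None:
        unit_ids = [
            getattr(s, "unit_id", "") or f"unit_{i:06d}" for i, s in enumerate(spectrograms)
        ]
    if len(set(unit_ids)) != len(unit_ids):
        raise ValueError("duplicate unit_ids")

    n = len(spectrograms)
    frames = [_as_frames(s) for s in spectrograms]
    values = np.zeros((n, n), dtype=np.float32)
    start_row = 0
    if checkpoint_path is not None:
        try:
            saved = np.load(str(checkpoint_path) + ".part.npy")
            rows_done = int(np.load(str(checkpoint_path) + ".rows.npy"))
            if saved.shape == (n, n):
                values = saved
                start_row = rows_done
                logger.info("resuming pairwise distances at row %d", start_row)
        except (FileNotFoundError, OSError):
            pass

    for chunk_start in range(start_row, n, chunk_rows):
        chunk_end = min(chunk_start + chunk_rows, n)
        for i in range(chunk_start, chunk_end):
            ai = frames[i]
            for j in range(i + 1, n):
                bj = frames[j]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # per-pair band widening is routine here
                    w = time_band_width(ai.shape[0], bj.shape[0], config.time_band_frac)
                    total, length = _dftw_kernel(
                        ai, bj, w, config.freq_band_bins, config.local_cost == "squared"
                    )
                d = total / length if config.normalize_by == "path_length" else total
                values[i, j] = values[j, i] = np.float32(d)
        if checkpoint_path is not None:
            np.save(str(checkpoint_path) + ".part.npy", values)
            np.save(str(checkpoint_path) + ".rows.npy", np.int64(chunk_end))
        if progress:
            logger.info("pairwise distances: %d/%d rows", chunk_end, n)

    return DistanceMatrix(values=values, unit_ids=list(unit_ids))
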