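"""Maximal information coefficient (MIC) with a chi-square-terminated grid search.

The MIC of two equal-length series ``x``, ``y`` is the maximum, over all
axis-aligned grids whose bin-count product ``n_x * n_y`` does not exceed
``B(n, alpha) = n**alpha``, of the grid mutual information normalised by
``log2(min(n_x, n_y))``.  It lies in ``[0, 1]``, is invariant under strictly
increasing transforms of either variable (all cuts are placed between order
statistics), and detects both linear and non-linear dependence.

The search implemented here equipartitions one axis, optimises the other axis
by dynamic programming over rank-midpoint cut candidates, and then revisits
the equipartitioned boundaries with a backward search (removal or
repositioning, never insertion).  Cut insertion on the optimised axis is
terminated by a Pearson chi-square independence test on the 2 x m sub-table
induced by each boundary: a partition whose boundaries are not all significant
at ``chi2_p_threshold`` stops the search at the previous bin count.  With the
chi-square test disabled the search is exhaustive over every examined grid
shape whose smaller side has two bins, which makes it directly comparable to
:func:`exhaustive_mic_oracle` on small inputs.

Everything here is deterministic; there is no randomness in the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import chdtrc as _chi2_sf

__all__ = [
    "MICParams",
    "GridPartition",
    "MICResult",
    "grid_mutual_information",
    "optimize_axis_partition",
    "backward_prune",
    "compute_mic",
    "exhaustive_mic_oracle",
]

# Candidate cuts are subsampled only above this length; below it the dynamic
# program sees every rank midpoint and the search is exact per grid shape.
_FULL_CANDIDATE_N = 128


@dataclass(frozen=True)
class MICParams:
    """Tuning constants of the grid search.

    Parameters
    ----------
    alpha : float
        Exponent of the grid bound ``B(n, alpha) = n**alpha`` (0 < alpha < 1).
    chi2_p_threshold : float or None
        A new cut on the optimised axis is accepted only while every boundary
        of the partition passes a chi-square independence test at this level.
        ``None`` disables the termination test (exhaustive per-shape search).
    min_bins : int
        Smallest bin count per axis considered (2: anything less cannot carry
        information).
    max_prune_iter : int
        Upper bound on alternating optimise/prune sweeps per grid family.
    prune_max_bins : int
        Backward pruning is applied to equipartitions of up to this many
        bins; finer equipartitions keep their rank-balanced boundaries (their
        larger normaliser makes them rarely decisive, and pruning there costs
        far more than it recovers).
    """

    alpha: float = 0.6
    chi2_p_threshold: Optional[float] = 0.01
    min_bins: int = 2
    max_prune_iter: int = 2
    prune_max_bins: int = 6

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.chi2_p_threshold is not None and not 0.0 < self.chi2_p_threshold < 1.0:
            raise ValueError("chi2_p_threshold must lie in (0, 1) or be None")
        if self.min_bins < 2:
            raise ValueError("min_bins must be at least 2")


@dataclass(frozen=True)
class GridPartition:
    """Axis-aligned grid given by interior cut values on each axis."""

    x_edges: np.ndarray
    y_edges: np.ndarray

    def __post_init__(self) -> None:
        for name, e in (("x_edges", self.x_edges), ("y_edges", self.y_edges)):
            e = np.asarray(e, dtype=float)
            object.__setattr__(self, name, e)
            if e.ndim != 1:
                raise ValueError(f"{name} must be one-dimensional")
            if e.size > 1 and not np.all(np.diff(e) > 0):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def n_x(self) -> int:
        return self.x_edges.size + 1

    @property
    def n_y(self) -> int:
        return self.y_edges.size + 1


@dataclass(frozen=True)
class MICResult:
    """Outcome of a MIC computation.

    ``mic`` is the maximum over examined grids of the normalised grid mutual
    information; ``characteristic_scores`` retains the per-shape maxima for
    diagnostics (they are not consumed by the coupling pipeline).
    """

    mic: float
    best_grid: Optional[GridPartition]
    i_g_bits: float
    normalizer: float
    characteristic_scores: Dict[Tuple[int, int], float] = field(default_factory=dict)
    degenerate: bool = False

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.mic


_TRIL_CACHE: Dict[int, np.ndarray] = {}


def _tril_neg(P: int) -> np.ndarray:
    """Lower-triangular (incl. diagonal) -inf mask, cached per size."""
    out = _TRIL_CACHE.get(P)
    if out is None:
        out = np.where(np.tri(P, dtype=bool), -np.inf, 0.0)
        _TRIL_CACHE[P] = out
    return out


def _xlog2x(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    out = np.zeros(a.shape)
    m = a > 0
    am = a[m]
    out[m] = am * np.log2(am)
    return out


def grid_mutual_information(x, y, partition: GridPartition) -> float:
    """Plug-in mutual information (bits) of the 2-D histogram under ``partition``.

    Empty rows and columns contribute nothing.  Raises on length mismatch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 points")
    ix = np.searchsorted(partition.x_edges, x, side="right")
    iy = np.searchsorted(partition.y_edges, y, side="right")
    counts = np.bincount(
        ix * partition.n_y + iy, minlength=partition.n_x * partition.n_y
    ).reshape(partition.n_x, partition.n_y)
    return _mi_bits_from_counts(counts)


def _mi_bits_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    v = (
        _xlog2x(counts).sum()
        - _xlog2x(counts.sum(axis=1)).sum()
        - _xlog2x(counts.sum(axis=0)).sum()
        + _xlog2x(np.array([n]))[0]
    )
    return float(v / n)


# ---------------------------------------------------------------------------
# internal machinery (rank space)
# ---------------------------------------------------------------------------


def _allowed_positions(v_sorted: np.ndarray) -> np.ndarray:
    """Cut positions p (split before sorted index p) separating distinct values."""
    return np.nonzero(np.diff(v_sorted) > 0)[0] + 1


def _subsample_positions(allowed: np.ndarray, cap: int) -> np.ndarray:
    if allowed.size <= cap:
        return allowed
    idx = np.unique(np.round(np.linspace(0, allowed.size - 1, cap)).astype(int))
    return allowed[idx]


def _equipartition_positions(allowed: np.ndarray, n: int, m: int) -> np.ndarray:
    """Rank-balanced m-bin cut positions, snapped to allowed (tie-free) cuts."""
    chosen: List[int] = []
    for t in np.round(np.arange(1, m) * n / m).astype(int):
        i = np.searchsorted(allowed, t)
        best = None
        for j in (i - 1, i):
            if 0 <= j < allowed.size and allowed[j] not in chosen:
                if best is None or abs(allowed[j] - t) < abs(best - t):
                    best = int(allowed[j])
        if best is not None:
            chosen.append(best)
    return np.array(sorted(chosen), dtype=int)


def _chi2_split_p(row_left: np.ndarray, row_right: np.ndarray) -> float:
    """Pearson chi-square p for the 2 x m table formed by splitting at a boundary.

    Columns whose expected count falls below 1 are merged with a neighbour for
    the test only (df shrinks accordingly).
    """
    obs = np.vstack([row_left, row_right]).astype(float)
    obs = obs[:, obs.sum(axis=0) > 0]
    while obs.shape[1] >= 2:
        colsum = obs.sum(axis=0)
        rowsum = obs.sum(axis=1)
        ntot = colsum.sum()
        if ntot <= 0 or rowsum.min() <= 0:
            return 1.0
        exp = np.outer(rowsum, colsum) / ntot
        if exp.min() >= 1.0:
            stat = ((obs - exp) ** 2 / exp).sum()
            return float(_chi2_sf(obs.shape[1] - 1, stat))
        j = int(np.argmin(colsum))
        k = j - 1 if j > 0 else j + 1
        obs[:, k] += obs[:, j]
        obs = np.delete(obs, j, axis=1)
    return 1.0


class _FreeAxisDP:
    """Exact dynamic program over candidate cuts of the free axis.

    Maximises, for every bin count ``k``, the additive objective
    ``sum_b [ sum_j n_jb log2 n_jb - n_b log2 n_b ]`` whose completion with the
    fixed-axis margins yields the grid mutual information.
    """

    def __init__(self, labs_sorted: np.ndarray, m: int, pos_grid: np.ndarray, n: int):
        self.n = n
        self.m = m
        self.pos_grid = pos_grid
        cum = np.zeros((m, n + 1))
        np.add.at(cum, (labs_sorted, np.arange(n) + 1), 1.0)
        cum = np.cumsum(cum, axis=1)
        self.C = cum[:, pos_grid]  # (m, P)
        tot = pos_grid.astype(float)
        D = self.C[:, None, :] - self.C[:, :, None]
        T = tot[None, :] - tot[:, None]
        self.S = _xlog2x(D).sum(axis=0) - _xlog2x(T)
        self.fixed_margin = _xlog2x(self.C[:, -1]).sum()
        self._nlog2n = n * np.log2(n)

    def solve(self, kmax: int):
        """Return {k: (I_G bits, interior grid indices)} for k = 1..kmax."""
        P = self.pos_grid.size
        kcap = min(kmax, P - 1)
        S = self.S + _tril_neg(P)
        F = self.S[0].copy()
        args: List[np.ndarray] = []
        vals = {1: F[-1]}
        for k in range(2, kcap + 1):
            M = F[:, None] + S
            A = M.argmax(axis=0)
            F = M[A, np.arange(P)]
            args.append(A)
            vals[k] = F[-1]
        out = {}
        for k in range(1, kcap + 1):
            if not np.isfinite(vals[k]):
                continue
            idxs = []
            b = P - 1
            for kk in range(k, 1, -1):
                a = int(args[kk - 2][b])
                idxs.append(a)
                b = a
            idxs = idxs[::-1]
            i_g = (vals[k] - self.fixed_margin + self._nlog2n) / self.n
            out[k] = (float(i_g), idxs)
        return out

    def boundary_rows(self, idxs_full: List[int], i: int):
        """Rows of the 2 x m sub-table around interior boundary ``i``."""
        left = self.C[:, idxs_full[i]] - self.C[:, idxs_full[i - 1]]
        right = self.C[:, idxs_full[i + 1]] - self.C[:, idxs_full[i]]
        return left, right

    def accepted_kmax(self, solutions, params: MICParams) -> int:
        """Largest k whose every boundary passes the chi-square validity test."""
        if params.chi2_p_threshold is None:
            return max(solutions)
        kacc = 1
        for k in sorted(solutions):
            if k == 1:
                continue
            idxs_full = np.array([0] + solutions[k][1] + [self.pos_grid.size - 1])
            cols = self.C[:, idxs_full]
            L = (cols[:, 1:-1] - cols[:, :-2]).T  # (nb, m)
            R = (cols[:, 2:] - cols[:, 1:-1]).T
            if not self._boundaries_pass(L, R, params.chi2_p_threshold):
                break
            kacc = k
        return kacc

    @staticmethod
    def _boundaries_pass(L: np.ndarray, R: np.ndarray, threshold: float) -> bool:
        """Vectorised Pearson chi-square over all boundaries; merge fallback."""
        tot = L + R
        ntot = tot.sum(axis=1, keepdims=True)
        rl = L.sum(axis=1, keepdims=True)
        expL = rl * tot / ntot
        expR = tot - expL
        needs_merge = (np.minimum(expL, np.where(tot > 0, expR, np.inf)) < 1.0) & (tot > 0)
        stats = np.zeros(L.shape[0])
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (L - expL) ** 2 / expL + (R - expR) ** 2 / expR
        term = np.where(tot > 0, term, 0.0)
        dfs = (tot > 0).sum(axis=1) - 1
        for i in range(L.shape[0]):
            if rl[i, 0] == 0 or rl[i, 0] == ntot[i, 0]:
                return False  # one side of the split is empty
            if needs_merge[i].any():
                if _chi2_split_p(L[i], R[i]) >= threshold:
                    return False
                continue
            if dfs[i] < 1:
                return False
            p = float(_chi2_sf(dfs[i], term[i].sum()))
            if p >= threshold:
                return False
        return True


def _labels_from_positions(rank: np.ndarray, positions: np.ndarray) -> np.ndarray:
    return np.searchsorted(positions, rank, side="right")


def _value_edges(v_sorted: np.ndarray, positions) -> np.ndarray:
    positions = np.asarray(positions, dtype=int)
    return (v_sorted[positions - 1] + v_sorted[positions]) / 2.0


def optimize_axis_partition(x, y, x_edges, max_bins: int, params: Optional[MICParams] = None):
    """Optimise cuts on ``y`` for each bin count, holding an ``x`` partition fixed.

    Returns a dict ``{k: (y_edge_values, I_G_bits)}`` for bin counts
    ``2 <= k <= max_bins`` that survive the chi-square termination rule (all of
    them when the test is disabled).  Candidate cuts are the midpoints between
    consecutive distinct order statistics of ``y``.
    """
    params = params or MICParams()
    if max_bins < 2:
        raise ValueError("max_bins must be at least 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    x_edges = np.asarray(x_edges, dtype=float)
    labx = np.searchsorted(x_edges, x, side="right")
    oy = np.argsort(y, kind="mergesort")
    ys = y[oy]
    allowed = _allowed_positions(ys)
    if allowed.size == 0:
        return {}
    cap = allowed.size if n <= _FULL_CANDIDATE_N else max(24, 3 * max_bins)
    pos_grid = np.concatenate(([0], _subsample_positions(allowed, cap), [n]))
    dp = _FreeAxisDP(labx[oy].astype(int), int(labx.max()) + 1, pos_grid, n)
    sols = dp.solve(max_bins)
    kacc = dp.accepted_kmax(sols, params)
    out = {}
    for k, (i_g, idxs) in sols.items():
        if 2 <= k <= kacc:
            out[k] = (_value_edges(ys, pos_grid[idxs]), i_g)
    return out


def _score_positions(Cx: np.ndarray, positions: List[int], n: int) -> Tuple[float, float]:
    """(I_G bits, normalised score) of an x-partition given fixed y labels.

    ``Cx`` is the (ky, n+1) cumulative count of y-bin labels along the x order.
    """
    ky = Cx.shape[0]
    pos_full = np.array([0] + list(positions) + [n], dtype=int)
    cells = np.diff(Cx[:, pos_full], axis=1)  # (ky, mx)
    i_g = _mi_bits_from_counts(cells.T)
    mx = len(positions) + 1
    denom = np.log2(min(mx, ky)) if min(mx, ky) > 1 else 0.0
    return i_g, (i_g / denom if denom > 0 else 0.0)


def backward_prune(x, y, equi_axis_edges, params: Optional[MICParams] = None, y_edges=None):
    """Backward search over the equipartitioned ``x`` boundaries.

    Boundaries are revisited in reverse order; each may be removed or shifted
    to another rank midpoint between its flanking boundaries whenever the
    normalised score does not decrease (and, with the chi-square test enabled,
    a shifted boundary itself remains significant).  Bins are never added.
    Returns the adjusted x edge values.
    """
    params = params or MICParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    ox = np.argsort(x, kind="mergesort")
    xs = x[ox]
    allowed = _allowed_positions(xs)
    positions = sorted(
        int(np.searchsorted(xs, e, side="right")) for e in np.asarray(equi_axis_edges, dtype=float)
    )
    if y_edges is None:
        kmax = max(2, int(np.floor(n ** params.alpha)) // max(2, len(positions) + 1))
        sols = optimize_axis_partition(x, y, np.asarray(equi_axis_edges, float), kmax, params)
        if not sols:
            return np.asarray(equi_axis_edges, dtype=float)
        best_k = max(sols, key=lambda k: sols[k][1] / np.log2(min(len(positions) + 1, k)))
        y_edges = sols[best_k][0]
    laby = np.searchsorted(np.asarray(y_edges, float), y, side="right")
    ky = int(laby.max()) + 1
    Cx = np.zeros((ky, n + 1))
    np.add.at(Cx, (laby[ox], np.arange(n) + 1), 1.0)
    Cx = np.cumsum(Cx, axis=1)
    new_pos = _prune_positions(Cx, positions, allowed, n, params)
    return _value_edges(xs, np.array(new_pos, dtype=int)) if new_pos else np.array([])


def _prune_positions(
    Cx: np.ndarray, positions: List[int], allowed: np.ndarray, n: int, params: MICParams
) -> List[int]:
    """One backward sweep of removal / repositioning over ``positions``."""
    pos = list(positions)
    ky = Cx.shape[0]
    base_i, score_now = _score_positions(Cx, pos, n)
    for i in reversed(range(len(pos))):
        a = pos[i - 1] if i > 0 else 0
        b = pos[i + 1] if i + 1 < len(pos) else n
        cL = Cx[:, pos[i]] - Cx[:, a]
        cR = Cx[:, b] - Cx[:, pos[i]]
        var_cur = (
            _xlog2x(cL).sum()
            - _xlog2x(np.array([pos[i] - a]))[0]
            + _xlog2x(cR).sum()
            - _xlog2x(np.array([b - pos[i]]))[0]
        )
        # removal = merging the two flanking columns (score must not decrease)
        if len(pos) > 1:
            var_rem = _xlog2x(cL + cR).sum() - _xlog2x(np.array([b - a]))[0]
            i_rem = base_i + (var_rem - var_cur) / n
            mlo = min(len(pos), ky)
            s_rem = i_rem / np.log2(mlo) if mlo > 1 else 0.0
        else:
            s_rem = -np.inf
        cand = allowed[(allowed > a) & (allowed < b)]
        best_shift, s_shift = pos[i], -np.inf
        if cand.size:
            colL = Cx[:, cand] - Cx[:, [a]]
            colR = Cx[:, [b]] - Cx[:, cand]
            var = (
                _xlog2x(colL).sum(axis=0)
                - _xlog2x(cand - a)
                + _xlog2x(colR).sum(axis=0)
                - _xlog2x(b - cand)
            )
            i_vals = base_i + (var - var_cur) / n
            denom = np.log2(min(len(pos) + 1, ky)) if min(len(pos) + 1, ky) > 1 else 0.0
            scores = i_vals / denom if denom > 0 else np.zeros_like(i_vals)
            j = int(np.argmax(scores))
            best_shift, s_shift = int(cand[j]), float(scores[j])
            i_shift = float(i_vals[j])
        # prefer the strongest strictly-improving shift, else removal at >=
        if s_shift > score_now + 1e-12 and best_shift != pos[i]:
            if params.chi2_p_threshold is not None:
                left = Cx[:, best_shift] - Cx[:, a]
                right = Cx[:, b] - Cx[:, best_shift]
                if _chi2_split_p(left, right) >= params.chi2_p_threshold:
                    best_shift = pos[i]
            if best_shift != pos[i]:
                pos[i] = best_shift
                score_now, base_i = s_shift, i_shift
                continue
        if s_rem >= score_now and len(pos) > 1:
            pos.pop(i)
            score_now, base_i = s_rem, i_rem
    return pos


class _Best:
    """Tracks the best grid and the per-shape characteristic scores."""

    def __init__(self) -> None:
        self.score = -np.inf
        self.info = None
        self.char: Dict[Tuple[int, int], float] = {}

    def record(self, shape: Tuple[int, int], score: float, i_g: float, grid_info) -> None:
        prev = self.char.get(shape, -np.inf)
        if score > prev:
            self.char[shape] = score
        if score > self.score:
            self.score = score
            self.info = (i_g, grid_info, shape)


def _search_family(vx, vy, m: int, kmax: int, params: MICParams, swap: bool, best: _Best) -> None:
    """Search all grids with ``m`` bins on the equipartitioned axis of ``vx``.

    ``swap`` marks that (vx, vy) are the caller's (y, x), so recorded shapes
    and grids are transposed back.
    """
    n = vx.size
    ox = np.argsort(vx, kind="mergesort")
    xs = vx[ox]
    allowed_x = _allowed_positions(xs)
    if allowed_x.size == 0:
        return
    oy = np.argsort(vy, kind="mergesort")
    ys = vy[oy]
    allowed_y = _allowed_positions(ys)
    if allowed_y.size == 0:
        return
    rank_x = np.empty(n, dtype=int)
    rank_x[ox] = np.arange(n)
    cap = allowed_y.size if n <= _FULL_CANDIDATE_N else max(24, 3 * kmax)
    pos_grid = np.concatenate(([0], _subsample_positions(allowed_y, cap), [n]))

    def run_dp(x_positions: np.ndarray):
        labx = _labels_from_positions(rank_x, x_positions)
        m_eff = int(labx.max()) + 1
        if m_eff < 2:
            return None, m_eff
        dp = _FreeAxisDP(labx[oy].astype(int), m_eff, pos_grid, n)
        sols = dp.solve(kmax)
        kacc = dp.accepted_kmax(sols, params)
        return (dp, sols, kacc, labx), m_eff

    def record_all(sols, kacc, m_eff, x_positions):
        out_best = None
        for k, (i_g, idxs) in sols.items():
            if k < 2 or k > kacc:
                continue
            denom = np.log2(min(m_eff, k))
            score = i_g / denom if denom > 0 else 0.0
            shape = (k, m_eff) if swap else (m_eff, k)
            y_pos = pos_grid[idxs]
            gx = _value_edges(xs, np.asarray(x_positions, int))
            gy = _value_edges(ys, np.asarray(y_pos, int))
            grid = (gy, gx) if swap else (gx, gy)
            best.record(shape, score, i_g, grid)
            if out_best is None or score > out_best[0]:
                out_best = (score, k, y_pos)
        return out_best

    if m == 2:
        # Single equi-axis boundary: the backward search degenerates to a full
        # scan, so every (2, k) grid is optimised exactly over the candidate set.
        scan = _subsample_positions(allowed_x, 24 if n > _FULL_CANDIDATE_N else allowed_x.size)
        equi = _equipartition_positions(allowed_x, n, 2)
        scan = np.unique(np.concatenate([scan, equi])) if equi.size else scan
        for p in scan:
            res, m_eff = run_dp(np.array([p], dtype=int))
            if res is None:
                continue
            _, sols, kacc, _ = res
            record_all(sols, kacc, m_eff, np.array([p], dtype=int))
        return

    x_positions = _equipartition_positions(allowed_x, n, m)
    if x_positions.size == 0:
        return
    for _ in range(params.max_prune_iter):
        res, m_eff = run_dp(x_positions)
        if res is None:
            return
        dp, sols, kacc, labx = res
        chosen = record_all(sols, kacc, m_eff, x_positions)
        if chosen is None:
            return
        if m > params.prune_max_bins:
            return
        _, k_star, y_pos = chosen
        # y labels of every point from the chosen free-axis partition
        rank_y = np.empty(n, dtype=int)
        rank_y[oy] = np.arange(n)
        laby = _labels_from_positions(rank_y, y_pos)
        ky = int(laby.max()) + 1
        if ky < 2:
            return
        Cx = np.zeros((ky, n + 1))
        np.add.at(Cx, (laby[ox], np.arange(n) + 1), 1.0)
        Cx = np.cumsum(Cx, axis=1)
        new_pos = _prune_positions(Cx, list(x_positions), allowed_x, n, params)
        i_g, score = _score_positions(Cx, new_pos, n)
        shape = (ky, len(new_pos) + 1) if swap else (len(new_pos) + 1, ky)
        gx = _value_edges(xs, np.asarray(new_pos, int)) if new_pos else np.array([])
        gy = _value_edges(ys, np.asarray(y_pos, int))
        best.record(shape, score, i_g, (gy, gx) if swap else (gx, gy))
        if list(new_pos) == list(x_positions):
            return
        x_positions = np.array(new_pos, dtype=int)


def compute_mic(x, y, params: Optional[MICParams] = None) -> MICResult:
    """MIC of two equal-length series via the chi-square-terminated grid search.

    Both orientations are examined (each axis in turn equipartitioned while the
    other is optimised), so the result is symmetric in ``x`` and ``y``.
    Constant input yields ``mic = 0`` with the ``degenerate`` flag set.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 8 samples, or non-finite values.
    """
    params = params or MICParams()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return MICResult(0.0, None, 0.0, 0.0, {}, degenerate=True)
    b_bound = max(4, int(np.floor(n ** params.alpha)))
    best = _Best()
    for swap, (vx, vy) in ((False, (x, y)), (True, (y, x))):
        m = params.min_bins
        while m * 2 <= b_bound:
            kmax = b_bound // m
            _search_family(vx, vy, m, kmax, params, swap, best)
            m += 1
    if best.info is None:
        return MICResult(0.0, None, 0.0, 0.0, {}, degenerate=True)
    i_g, (gx, gy), shape = best.info
    mic_val = float(min(1.0, max(0.0, best.score)))
    return MICResult(
        mic=mic_val,
        best_grid=GridPartition(np.asarray(gx, float), np.asarray(gy, float)),
        i_g_bits=float(i_g),
        normalizer=float(np.log2(min(shape))),
        characteristic_scores=dict(best.char),
    )


def exhaustive_mic_oracle(x, y, max_B: int) -> float:
    """True maximum of normalised grid MI by brute-force grid enumeration.

    Enumerates every grid on rank-midpoint cuts with ``n_x * n_y <= max_B``
    and both bin counts >= 2.  Guarded to ``n <= 40`` and ``max_B <= 9``; this
    is a test oracle, not an estimator.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n > 40 or max_B > 9:
        raise ValueError("oracle guard exceeded (n <= 40, max_B <= 9)")
    ox = np.argsort(x, kind="mergesort")
    oy = np.argsort(y, kind="mergesort")
    xs, ys = x[ox], y[oy]
    px = _allowed_positions(xs)
    py = _allowed_positions(ys)
    if px.size == 0 or py.size == 0:
        return 0.0
    rank_x = np.empty(n, dtype=int)
    rank_x[ox] = np.arange(n)
    rank_y = np.empty(n, dtype=int)
    rank_y[oy] = np.arange(n)
    best = 0.0
    shapes = [
        (a, b)
        for a in range(2, max_B // 2 + 1)
        for b in range(2, max_B // a + 1)
    ]
    lab_cache: Dict[Tuple[str, Tuple[int, ...]], np.ndarray] = {}

    def labels(rank: np.ndarray, cuts: Tuple[int, ...], axis: str) -> np.ndarray:
        key = (axis, cuts)
        out = lab_cache.get(key)
        if out is None:
            out = np.searchsorted(np.array(cuts), rank, side="right")
            lab_cache[key] = out
        return out

    for a, b in shapes:
        if px.size < a - 1 or py.size < b - 1:
            continue
        denom = np.log2(min(a, b))
        for xc in combinations(px.tolist(), a - 1):
            labx = labels(rank_x, xc, "x") * b
            for yc in combinations(py.tolist(), b - 1):
                laby = labels(rank_y, yc, "y")
                counts = np.bincount(labx + laby, minlength=a * b).reshape(a, b)
                score = _mi_bits_from_counts(counts) / denom
                if score > best:
                    best = score
    return float(min(1.0, best))
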