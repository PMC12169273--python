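"""Penalized segmented least squares via dynamic programming.

This is the engine behind the trend/seasonal decomposition: a series is
partitioned into contiguous segments, each fitted by ordinary least squares
on a fixed per-step design matrix (linear-in-time for the trend component,
second-order harmonics for the seasonal component).  The optimal placement
of up to ``max_breaks`` breakpoints is found exactly by dynamic programming
over a grid of admissible break dates, and the number of breaks is selected
by BIC.

Candidate break dates live on a regular grid (``stride`` steps, default set
by the caller).  Segment costs for *all* admissible (start, end) pairs are
computed at once from cumulative cross-product sums, so refits with a new
response vector (e.g. bootstrap replicates) reuse the precomputed design
inverses and are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# variance floor used in BIC: residual scatter below this standard deviation
# (in the series' units) is treated as measurement-precision noise, so model
# selection never chases numerically-zero residual improvements on noiseless
# (synthetic) inputs
SIGMA_FLOOR = 1e-3


def design_trend(n: int, steps_per_year: int = 36) -> np.ndarray:
    """Design matrix [1, t] with t in years since series start (midpoints)."""
    t = (np.arange(n) + 0.5) / steps_per_year
    return np.column_stack([np.ones(n), t])


def design_harmonic(n: int, steps_per_year: int = 36) -> np.ndarray:
    """Second-order harmonic design [sin ωt, cos ωt, sin 2ωt, cos 2ωt].

    ω = 2π / steps_per_year with the integer step index as argument; the
    phase origin is global (series start), so all seasonal segments share
    it.  No intercept: the seasonal component is mean-zero over any whole
    year by construction.
    """
    u = 2.0 * np.pi * np.arange(n) / steps_per_year
    return np.column_stack([np.sin(u), np.cos(u), np.sin(2 * u), np.cos(2 * u)])


@dataclass
class SegmentFit:
    """One component's fitted segmentation."""

    bounds: np.ndarray        # segment boundaries, including 0 and n
    betas: list               # OLS coefficients per segment
    values: np.ndarray        # fitted component at every step (model-defined)
    rss: float
    n_breaks: int
    bic: float

    @property
    def break_steps(self) -> np.ndarray:
        """Interior boundaries: first step of each new segment."""
        return self.bounds[1:-1]


class Segmenter:
    """Reusable segmented-least-squares solver for one design matrix.

    Parameters
    ----------
    X : ndarray, shape (n, p)
        Per-step design matrix.
    valid : ndarray of bool, shape (n,)
        True where the response is observed; missing steps contribute
        nothing to any segment cost.
    min_seg : int
        Minimum segment length in steps.
    stride : int
        Break dates are restricted to multiples of ``stride``.
    """

    def __init__(self, X: np.ndarray, valid: np.ndarray, min_seg: int, stride: int = 3):
        n, p = X.shape
        if min_seg < p + 2:
            raise ValueError("min_seg too small for the design rank")
        self.n, self.p = n, p
        self.X = X
        self.w = valid.astype(float)
        self.min_seg = int(min_seg)
        self.stride = int(stride)

        interior = np.arange(self.stride, n, self.stride)
        self.bounds = np.concatenate([[0], interior, [n]]).astype(int)
        nb = self.bounds.size

        # cumulative X'X and observation counts (missing steps zero-weighted)
        Xw = X * self.w[:, None]
        P = np.zeros((n + 1, p, p))
        P[1:] = np.cumsum(np.einsum("ti,tj->tij", Xw, X), axis=0)
        N = np.zeros(n + 1)
        N[1:] = np.cumsum(self.w)
        self._P, self._N = P, N

        ii, jj = np.triu_indices(nb, k=1)
        seg_len = self.bounds[jj] - self.bounds[ii]
        seg_pts = N[self.bounds[jj]] - N[self.bounds[ii]]
        keep = (seg_len >= self.min_seg) & (seg_pts >= p + 2)
        self._ii, self._jj = ii[keep], jj[keep]
        self._pair_index = np.full((nb, nb), -1, dtype=int)
        self._pair_index[self._ii, self._jj] = np.arange(self._ii.size)

        A = P[self.bounds[self._jj]] - P[self.bounds[self._ii]]
        # ridge only the (rare) rank-deficient segments under heavy
        # missingness; everything else is solved exactly
        scale = (np.trace(A, axis1=1, axis2=2) / p) ** p
        bad = np.abs(np.linalg.det(A)) < np.maximum(scale, 1e-30) * 1e-12
        if bad.any():
            ridge = 1e-10 * np.trace(A[bad], axis1=1, axis2=2) / p + 1e-30
            A[bad] += ridge[:, None, None] * np.eye(p)
        self._Ainv = np.linalg.inv(A)
        self.n_eff = N[-1]

    # ------------------------------------------------------------------
    def _costs(self, y: np.ndarray):
        """Segment costs and betas for every admissible (start, end) pair."""
        yz = np.where(self.w > 0, y, 0.0)
        V = np.zeros((self.n + 1, self.p))
        V[1:] = np.cumsum(self.X * (self.w * yz)[:, None], axis=0)
        Q = np.zeros(self.n + 1)
        Q[1:] = np.cumsum(self.w * yz * yz)
        b = V[self.bounds[self._jj]] - V[self.bounds[self._ii]]
        beta = np.einsum("npq,nq->np", self._Ainv, b)
        cost = Q[self.bounds[self._jj]] - Q[self.bounds[self._ii]]
        cost = np.maximum(cost - np.einsum("np,np->n", b, beta), 0.0)
        return cost, beta

    def fit(self, y: np.ndarray, max_breaks: int, n_breaks: int | None = None) -> SegmentFit:
        """Optimal segmentation of ``y``.

        ``n_breaks=None`` selects the break count in 0..max_breaks by BIC
        (near-ties resolved toward fewer breaks); an integer forces that
        exact count (used by the bootstrap).
        """
        nb = self.bounds.size
        cost, beta = self._costs(y)
        C = np.full((nb, nb), np.inf)
        C[self._ii, self._jj] = cost

        F = np.full((max_breaks + 1, nb), np.inf)
        Arg = np.zeros((max_breaks + 1, nb), dtype=int)
        F[0] = C[0]
        for k in range(1, max_breaks + 1):
            tot = F[k - 1][:, None] + C
            Arg[k] = np.argmin(tot, axis=0)   # earliest index on ties
            F[k] = tot[Arg[k], np.arange(nb)]

        rss_by_m = F[:, nb - 1]
        if n_breaks is None:
            m = self._select_bic(rss_by_m, max_breaks)
        else:
            m = int(n_breaks)
            if not np.isfinite(rss_by_m[m]):
                # infeasible under min-segment constraints: fall back
                feas = np.flatnonzero(np.isfinite(rss_by_m))
                m = int(feas[np.argmin(np.abs(feas - m))])
        bic = self._bic(rss_by_m[m], m)

        # backtrack boundary indices
        idx = [nb - 1]
        b = nb - 1
        for k in range(m, 0, -1):
            b = int(Arg[k, b])
            idx.append(b)
        idx.append(0)
        idx = idx[::-1]
        bounds = self.bounds[idx]

        betas, values = [], np.empty(self.n)
        for a, bdx in zip(idx[:-1], idx[1:]):
            pr = self._pair_index[a, bdx]
            bt = beta[pr]
            betas.append(bt)
            sl = slice(self.bounds[a], self.bounds[bdx])
            values[sl] = self.X[sl] @ bt
        return SegmentFit(bounds=bounds, betas=betas, values=values,
                          rss=float(rss_by_m[m]), n_breaks=m, bic=float(bic))

    def _bic(self, rss: float, m: int) -> float:
        k = (m + 1) * self.p + m
        n = max(self.n_eff, 1.0)
        sigma2 = max(rss / n, SIGMA_FLOOR**2)
        return n * np.log(sigma2) + k * np.log(n)

    def _select_bic(self, rss_by_m: np.ndarray, max_breaks: int) -> int:
        best_m, best_bic = 0, np.inf
        for m in range(max_breaks + 1):
            if not np.isfinite(rss_by_m[m]):
                continue
            bic = self._bic(rss_by_m[m], m)
            if bic < best_bic - 1e-9:
                best_m, best_bic = m, bic
        return best_m


def exhaustive_rss(X: np.ndarray, y: np.ndarray, valid: np.ndarray,
                   min_seg: int, stride: int, n_breaks: int) -> float:
    """Brute-force minimum RSS over all admissible break placements.

    Independent oracle for the dynamic program: enumerates every combination
    of break dates on the same candidate grid and fits each segment with
    ``numpy.linalg.lstsq``.  Exponential in ``n_breaks``; only for tiny
    problems.
    """
    from itertools import combinations

    n, p = X.shape
    w = valid.astype(bool)
    candidates = [b for b in range(stride, n, stride)]

    def seg_rss(i: int, j: int) -> float:
        if j - i < min_seg:
            return np.inf
        m = w[i:j]
        if m.sum() < p + 2:
            return np.inf
        Xs, ys = X[i:j][m], y[i:j][m]
        coef, _, _, _ = np.linalg.lstsq(Xs, ys, rcond=None)
        r = ys - Xs @ coef
        return float(r @ r)

    best = np.inf
    for combo in combinations(candidates, n_breaks):
        bounds = [0, *combo, n]
        rss = sum(seg_rss(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1))
        best = min(best, rss)
    return best
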