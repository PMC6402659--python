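"""Covariance matrix adaptation evolution strategy (CMA-ES).

A compact (mu/mu_w, lambda) CMA-ES for low-dimensional, derivative-free
minimization: weighted recombination, cumulative step-size adaptation and
rank-1 plus rank-mu covariance updates with the standard default strategy
parameters.  Box constraints are handled by reflecting sampled points into
the feasible box before evaluation (penalty-free mirroring), which keeps
the ranking identical to the evaluation of the reflected points.

Deterministic for a given seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CmaEs", "reflect_into_box"]


def reflect_into_box(x: np.ndarray, lower, upper) -> np.ndarray:
    """Mirror x into [lower, upper] component-wise (period-2 reflection)."""
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    span = hi - lo
    out = np.array(x, dtype=float)
    finite = np.isfinite(span) & (span > 0)
    # reflect only where both bounds are finite; otherwise clip at the
    # finite bound by single mirroring
    y = np.mod(out[finite] - lo[finite], 2 * span[finite])
    out[finite] = lo[finite] + np.where(y > span[finite],
                                        2 * span[finite] - y, y)
    lo_only = ~finite & np.isfinite(lo)
    out[lo_only] = lo[lo_only] + np.abs(out[lo_only] - lo[lo_only])
    hi_only = ~finite & np.isfinite(hi) & ~np.isfinite(lo)
    out[hi_only] = hi[hi_only] - np.abs(hi[hi_only] - out[hi_only])
    return out


class CmaEs:
    """Ask/tell CMA-ES minimizer.

    Parameters
    ----------
    x0 : initial mean.
    sigma0 : initial step size (same scale for all coordinates).
    popsize : offspring per generation (lambda >= 4).
    bounds : optional (lower, upper) arrays; sampled points are reflected
        into the box before evaluation.
    seed : RNG seed; runs are reproducible for a fixed seed.
    """

    def __init__(self, x0, sigma0: float, popsize: int = 18,
                 bounds=None, seed: int | None = None):
        self.mean = np.array(x0, dtype=float)
        self.n = self.mean.size
        if sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if popsize < 4:
            raise ValueError("popsize must be at least 4")
        self.sigma = float(sigma0)
        self.lam = int(popsize)
        self.bounds = bounds
        self.rng = np.random.default_rng(seed)

        self.mu = self.lam // 2
        w = np.log((self.lam + 1) / 2) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / np.sum(self.weights**2)
        n, mueff = self.n, self.mueff
        self.cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
        self.cs = (mueff + 2) / (n + mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + mueff)
        self.cmu = min(1 - self.c1,
                       2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
        self.damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + self.cs
        self.chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self.generation = 0
        self._z = None
        self._y = None

    def ask(self) -> np.ndarray:
        """Sample lambda candidates (already reflected into the box)."""
        d, Bm = np.linalg.eigh(self.C)
        d = np.sqrt(np.maximum(d, 1e-20))
        self._sqrtC = Bm * d @ Bm.T
        self._invsqrtC = Bm / d @ Bm.T
        self._z = self.rng.standard_normal((self.lam, self.n))
        self._y = self._z @ self._sqrtC.T
        X = self.mean + self.sigma * self._y
        if self.bounds is not None:
            X = np.array([reflect_into_box(x, *self.bounds) for x in X])
        return X

    def tell(self, X: np.ndarray, f: np.ndarray) -> None:
        """Rank candidates by f (lower is better) and update the state."""
        order = np.argsort(f, kind="stable")[: self.mu]
        # recombine in sampling coordinates (the reflected evaluation point
        # only affects the ranking)
        y_sel = self._y[order]
        y_w = self.weights @ y_sel
        self.mean = self.mean + self.sigma * y_w
        if self.bounds is not None:
            self.mean = reflect_into_box(self.mean, *self.bounds)

        self.ps = (1 - self.cs) * self.ps + np.sqrt(
            self.cs * (2 - self.cs) * self.mueff) * (self._invsqrtC @ y_w)
        hsig = (np.linalg.norm(self.ps)
                / np.sqrt(1 - (1 - self.cs) ** (2 * (self.generation + 1)))
                / self.chi_n) < 1.4 + 2 / (self.n + 1)
        self.pc = (1 - self.cc) * self.pc + hsig * np.sqrt(
            self.cc * (2 - self.cc) * self.mueff) * y_w

        rank_mu = (y_sel * self.weights[:, None]).T @ y_sel
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc)
                               + (not hsig) * self.cc * (2 - self.cc) * self.C)
                  + self.cmu * rank_mu)
        self.C = (self.C + self.C.T) / 2
        self.sigma *= np.exp(
            (self.cs / self.damps)
            * (np.linalg.norm(self.ps) / self.chi_n - 1))
        self.sigma = float(min(self.sigma, 1e8))
        self.generation += 1
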