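"""Constrained exponential-decay fitting, sklearn-estimator style.

Two estimators cover the decay models used throughout the package:

* :class:`ExponentialDecay` — ``A exp(-t/tau)`` with an optional
  additive offset ``y0``; used for the center-line-slope decay
  (spectral diffusion time) and the population relaxation of 2D IR
  peak volumes.
* :class:`TriExponentialDecay` — ``sum_n A_n exp(-t/tau_n)`` with the
  amplitudes constrained to the unit simplex (A_n >= 0, sum A_n = 1),
  used for the H-bond survival autocorrelation.  The amplitudes are
  parametrised by stick-breaking (A1 = s1, A2 = (1-s1) s2,
  A3 = (1-s1)(1-s2), s in [0,1]) so the constraint holds exactly by
  construction; time constants are optimised in log space with
  multistart initialisation, making the fit deterministic.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy.optimize import curve_fit, least_squares
from sklearn.base import BaseEstimator


class ExponentialDecay(BaseEstimator):
    """Least-squares fit of ``y = A exp(-t/tau) [+ y0]``.

    Parameters
    ----------
    offset : include an additive constant ``y0`` (population-relaxation
        convention) or not (center-line-slope convention).
    tau_max : upper bound on the time constant; a fit pinned at this
        bound signals a non-decaying series and raises a warning.

    Attributes
    ----------
    amplitude_, tau_, offset_ : fitted parameters.
    covariance_ : covariance matrix of the free parameters.
    stderr_ : standard errors from the covariance diagonal.
    """

    def __init__(self, offset: bool = False, tau_max: float = 1e8):
        self.offset = offset
        self.tau_max = tau_max

    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(t) != len(y):
            raise ValueError("t and y must have the same length")
        if len(t) < (3 if self.offset else 2):
            raise ValueError("not enough points for the decay fit")
        y0_guess = y[-1] if self.offset else 0.0
        a_guess = y[0] - y0_guess
        if a_guess == 0.0:
            a_guess = max(abs(y).max(), 1e-12)
        # crude half-life guess from where the decay crosses half amplitude
        resid = y - y0_guess
        below = np.flatnonzero(np.abs(resid) < 0.5 * abs(a_guess))
        tau_guess = t[below[0]] / np.log(2) if len(below) and t[below[0]] > 0 \
            else (t[-1] - t[0]) / 2 or 1.0

        if self.offset:
            model = lambda t, a, tau, y0: a * np.exp(-t / tau) + y0
            p0 = [a_guess, tau_guess, y0_guess]
            bounds = ([-np.inf, 1e-12, -np.inf], [np.inf, self.tau_max, np.inf])
        else:
            model = lambda t, a, tau: a * np.exp(-t / tau)
            p0 = [a_guess, tau_guess]
            bounds = ([-np.inf, 1e-12], [np.inf, self.tau_max])
        popt, pcov = curve_fit(model, t, y, p0=p0, bounds=bounds,
                               maxfev=20000, xtol=1e-14, ftol=1e-14)
        self.amplitude_ = float(popt[0])
        self.tau_ = float(popt[1])
        self.offset_ = float(popt[2]) if self.offset else 0.0
        self.covariance_ = pcov
        self.stderr_ = np.sqrt(np.clip(np.diag(pcov), 0, None))
        span = float(t.max() - t.min())
        if self.tau_ > 0.5 * self.tau_max or not np.isfinite(pcov).all() \
                or (np.isfinite(self.stderr_[1]) and self.stderr_[1] > self.tau_) \
                or span / self.tau_ < 0.01:
            warnings.warn(
                "series does not decay appreciably over the sampled window; "
                "the time constant is poorly determined",
                RuntimeWarning, stacklevel=2)
        return self

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.amplitude_ * np.exp(-t / self.tau_) + self.offset_


def _stick_break(s1: float, s2: float) -> np.ndarray:
    return np.array([s1, (1.0 - s1) * s2, (1.0 - s1) * (1.0 - s2)])


class TriExponentialDecay(BaseEstimator):
    """Simplex-constrained triple-exponential fit of a correlation decay.

    ``C(t) = A1 exp(-t/tau1) + A2 exp(-t/tau2) + A3 exp(-t/tau3)`` with
    ``A_n >= 0`` and ``A1 + A2 + A3 = 1`` enforced exactly.  The
    shortest time constant can be held fixed (``fix_tau3``), reflecting
    the common practice of pinning a sub-resolution librational
    component.  Components are reported sorted by descending time
    constant.  Residuals are unweighted on the given lag grid.

    Attributes
    ----------
    amplitudes_ : (3,) fitted amplitudes, summing to 1.
    taus_ : (3,) fitted time constants (ps), descending.
    mean_lifetime_ : amplitude-weighted mean, ``sum A_n tau_n`` (ps) —
        the integral of the unit-normalized fit.
    covariance_ : 6x6 covariance of (A1, A2, A3, tau1, tau2, tau3).
    residual_norm_ : 2-norm of the residual vector at the optimum.
    """

    def __init__(self, fix_tau3: float | None = None, n_grid: int = 4,
                 tau_bounds: tuple[float, float | None] = (1e-4, None)):
        self.fix_tau3 = fix_tau3
        self.n_grid = n_grid
        self.tau_bounds = tau_bounds

    # -- internal parameter packing ---------------------------------
    def _unpack(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        amps = _stick_break(x[0], x[1])
        if self.fix_tau3 is None:
            taus = 10.0 ** x[2:5]
        else:
            taus = np.array([10.0 ** x[2], 10.0 ** x[3], self.fix_tau3])
        return amps, taus

    def fit(self, t, y, init: tuple | None = None):
        """Fit the decay; ``init=(amplitudes, taus)`` seeds an extra start."""
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(t) < 12:
            raise ValueError("triple-exponential fit needs at least 12 lags")
        if len(t) != len(y):
            raise ValueError("t and y must have the same length")

        def residuals(x):
            amps, taus = self._unpack(x)
            return amps @ np.exp(-np.outer(1.0 / taus, t)) - y

        # time constants beyond the sampled window are not identifiable;
        # bound them at the window length unless the caller overrides
        tau_hi = self.tau_bounds[1] if self.tau_bounds[1] is not None \
            else float(t.max())
        lo_l = np.log10(self.tau_bounds[0])
        hi_l = np.log10(tau_hi)
        n_tau = 2 if self.fix_tau3 is not None else 3
        lower = np.concatenate([[0.0, 0.0], np.full(n_tau, lo_l)])
        upper = np.concatenate([[1.0, 1.0], np.full(n_tau, hi_l)])

        starts = self._starts(t)
        if init is not None:
            a, taus = np.asarray(init[0], float), np.asarray(init[1], float)
            s1 = a[0]
            s2 = a[1] / (1.0 - a[0]) if a[0] < 1.0 else 0.5
            starts.append(np.concatenate([[s1, s2], np.log10(taus)]))

        best = None
        for x0 in starts:
            x0 = np.clip(x0[: 2 + n_tau], lower + 1e-9, upper - 1e-9)
            try:
                sol = least_squares(residuals, x0, bounds=(lower, upper),
                                    xtol=2.3e-16, ftol=2.3e-16, gtol=1e-14,
                                    max_nfev=5000)
            except Exception:
                continue
            # a max_nfev-terminated solution is still the best point found
            if np.isfinite(sol.cost) and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise RuntimeError(
                "triple-exponential fit failed to converge from any start; "
                "inspect the correlation function for pathologies")
        if np.any(np.isclose(best.x[2:], lo_l)) or np.any(np.isclose(best.x[2:], hi_l)):
            warnings.warn("best fit has a time constant at a bound",
                          RuntimeWarning, stacklevel=2)

        amps, taus = self._unpack(best.x)
        order = np.argsort(taus)[::-1]
        self.amplitudes_ = amps[order]
        self.taus_ = taus[order]
        self.mean_lifetime_ = float(self.amplitudes_ @ self.taus_)
        self.residual_norm_ = float(np.linalg.norm(best.fun))
        self.covariance_ = self._covariance(best, t, order)
        return self

    def _starts(self, t):
        """Deterministic multistart: descending log-spaced tau triplets."""
        t_lo = max(t[t > 0].min() if np.any(t > 0) else 1e-3, self.tau_bounds[0])
        t_hi = t.max() if self.tau_bounds[1] is None \
            else min(t.max(), self.tau_bounds[1])
        grid = np.linspace(np.log10(t_lo), np.log10(t_hi), self.n_grid)
        starts = []
        for combo in itertools.combinations(range(self.n_grid), 3):
            taus_l = grid[list(combo)][::-1]          # descending
            starts.append(np.concatenate([[0.4, 0.5], taus_l]))
        mid = 0.5 * (grid[0] + grid[-1])
        starts.append(np.array([1 / 3, 0.5, mid + 1, mid, mid - 1]))
        return starts

    def _covariance(self, sol, t, order):
        """Covariance of (A1..A3, tau1..tau3) via the delta method."""
        m, k = len(t), len(sol.x)
        dof = max(m - k, 1)
        s2 = 2.0 * sol.cost / dof
        JTJ = sol.jac.T @ sol.jac
        cov_free = s2 * np.linalg.pinv(JTJ)
        # numeric jacobian of the (A, tau) transform w.r.t. free params
        def transform(x):
            a, tau = self._unpack(x)
            return np.concatenate([a[order], tau[order]])
        T = np.empty((6, k))
        h = 1e-7
        base = transform(sol.x)
        for j in range(k):
            xp = sol.x.copy()
            xp[j] += h
            T[:, j] = (transform(xp) - base) / h
        return T @ cov_free @ T.T

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.amplitudes_ @ np.exp(-np.outer(1.0 / self.taus_, t))
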