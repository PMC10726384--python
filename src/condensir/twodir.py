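"""Spectral-diffusion and population-relaxation analysis of 2D IR cubes.

The center line slope (CLS) is measured per waiting time Tw by locating,
for every pump frequency in the analysis window (default 1618-1685
cm^-1), the probe position of the ground-state-bleach minimum with
three-point parabolic interpolation, then fitting a straight line of
probe-minimum versus pump.  CLS is the slope of that line: 1 for
perfectly correlated excitation and detection frequencies, 0 when the
response is independent of the excitation frequency.  For a
joint-Gaussian band the CLS equals the normalized frequency-frequency
correlation, so CLS(Tw) is an unbiased FFCF estimator in the Gaussian
limit.  The decay is summarised by CLS(Tw) = CLS0 exp(-Tw/tau_specdiff).

The nodal line slope (NLS, zero-crossing between bleach and ESA) is an
alternative estimator of the same conditional-mean slope; population
relaxation is obtained from integrated bleach volumes fitted with
A0 exp(-Tw/tau_VER) + y0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .fitting import ExponentialDecay
from .spectra import Spectrum2D

__all__ = [
    "CLSPoint", "CLSResult", "PopulationFit",
    "diagonal_cut", "antidiagonal_cut", "center_line_slope",
    "nodal_line_slope", "cls_series", "fit_cls_decay",
    "fit_population_decay",
]

DEFAULT_PUMP_RANGE = (1618.0, 1685.0)


@dataclass
class CLSPoint:
    """CLS at one waiting time, with the center-line points behind it."""

    tw: float
    cls: float
    pump: np.ndarray            # pump frequencies of the usable columns
    probe_min: np.ndarray       # interpolated probe position of the bleach minimum


@dataclass
class CLSResult:
    """CLS(Tw) series and, once fitted, the single-exponential summary."""

    waiting_times: np.ndarray
    cls: np.ndarray
    points: list = field(default_factory=list)
    cls0: float | None = None
    tau_specdiff: float | None = None
    covariance: np.ndarray | None = None


@dataclass
class PopulationFit:
    """Offset single-exponential fit of integrated bleach volumes."""

    a0: float
    tau_ver: float
    y0: float
    covariance: np.ndarray | None = None
    volumes: np.ndarray | None = None
    waiting_times: np.ndarray | None = None


# --------------------------------------------------------------------------
# Cuts
# --------------------------------------------------------------------------

def diagonal_cut(spec: Spectrum2D, tw: float) -> tuple[np.ndarray, np.ndarray]:
    """Signal along nu_pump = nu_probe over the axes' overlap."""
    S = spec.at(tw)
    interp = RegularGridInterpolator((spec.pump, spec.probe), S)
    lo = max(spec.pump[0], spec.probe[0])
    hi = min(spec.pump[-1], spec.probe[-1])
    if hi <= lo:
        raise ValueError("pump and probe axes do not overlap")
    nu = spec.pump[(spec.pump >= lo) & (spec.pump <= hi)]
    return nu, interp(np.column_stack([nu, nu]))


def antidiagonal_cut(spec: Spectrum2D, tw: float,
                     center: float) -> tuple[np.ndarray, np.ndarray]:
    """Signal along nu_pump + nu_probe = 2*center.

    Returns (s, signal) with s the displacement along the pump axis,
    i.e. the cut samples (center + s, center - s).
    """
    if not (spec.pump[0] <= center <= spec.pump[-1]) or \
            not (spec.probe[0] <= center <= spec.probe[-1]):
        raise ValueError("center frequency outside the axes")
    S = spec.at(tw)
    interp = RegularGridInterpolator((spec.pump, spec.probe), S)
    s_lo = max(spec.pump[0] - center, center - spec.probe[-1])
    s_hi = min(spec.pump[-1] - center, center - spec.probe[0])
    step = np.diff(spec.pump).min()
    s = np.arange(s_lo, s_hi + 0.5 * step, step)
    return s, interp(np.column_stack([center + s, center - s]))


# --------------------------------------------------------------------------
# Center line slope
# --------------------------------------------------------------------------

def _parabolic_min(x: np.ndarray, y: np.ndarray, idx: int) -> float:
    """Sub-gridpoint minimum position via a 3-point parabola."""
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    step = 0.5 * (x[idx + 1] - x[idx - 1])
    return float(x[idx] + np.clip(delta, -1.0, 1.0) * step)


def center_line_slope(spec: Spectrum2D, tw: float,
                      pump_range: tuple[float, float] = DEFAULT_PUMP_RANGE,
                      contrast_fraction: float = 0.1) -> CLSPoint:
    """CLS at one waiting time from the bleach minima of the pump columns.

    Columns whose bleach minimum sits on the probe-axis border or whose
    depth falls below ``contrast_fraction`` of the deepest column
    (bleach eroded by the overlapping ESA lobe) are dropped with a
    warning.  At least 4 usable columns are required.
    """
    S = spec.at(tw)
    cols = np.flatnonzero((spec.pump >= pump_range[0]) &
                          (spec.pump <= pump_range[1]))
    if len(cols) < 4:
        raise ValueError("fewer than 4 pump columns in the analysis window")
    minima, depths, interior = [], [], []
    for ip in cols:
        col = S[ip]
        idx = int(np.argmin(col))
        minima.append(idx)
        depths.append(-col[idx])
        interior.append(0 < idx < len(col) - 1 and col[idx] < 0)
    depths = np.array(depths)
    max_depth = depths.max()
    if max_depth <= 0:
        raise ValueError("no ground-state bleach (negative lobe) in the window")
    usable = np.array(interior) & (depths >= contrast_fraction * max_depth)
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} pump columns with weak or "
                      "border bleach minima (ESA interference)",
                      RuntimeWarning, stacklevel=2)
    if usable.sum() < 4:
        raise ValueError("fewer than 4 usable pump columns for the CLS")
    pump_used = spec.pump[cols[usable]]
    probe_min = np.array([_parabolic_min(spec.probe, S[ip], minima[k])
                          for k, ip in enumerate(cols) if usable[k]])
    slope = np.polyfit(pump_used, probe_min, 1)[0]
    return CLSPoint(tw=tw, cls=float(slope), pump=pump_used,
                    probe_min=probe_min)


def nodal_line_slope(spec: Spectrum2D, tw: float,
                     pump_range: tuple[float, float] = DEFAULT_PUMP_RANGE) -> float:
    """Slope of the bleach/ESA zero-crossing line, same convention as CLS."""
    S = spec.at(tw)
    cols = np.flatnonzero((spec.pump >= pump_range[0]) &
                          (spec.pump <= pump_range[1]))
    pump_used, node = [], []
    for ip in cols:
        col = S[ip]
        i_min = int(np.argmin(col))
        i_max = int(np.argmax(col))
        if col[i_min] >= 0 or col[i_max] <= 0 or i_min == i_max:
            continue
        lo, hi = sorted((i_min, i_max))
        crossing = None
        for j in range(lo, hi):
            if col[j] == 0.0:
                crossing = spec.probe[j]
                break
            if col[j] * col[j + 1] < 0:
                f = col[j] / (col[j] - col[j + 1])
                crossing = spec.probe[j] + f * (spec.probe[j + 1] - spec.probe[j])
                break
        if crossing is None:
            continue
        pump_used.append(spec.pump[ip])
        node.append(crossing)
    if len(pump_used) < 4:
        raise ValueError("fewer than 4 columns with a bleach/ESA zero crossing")
    return float(np.polyfit(pump_used, node, 1)[0])


def cls_series(spec: Spectrum2D,
               pump_range: tuple[float, float] = DEFAULT_PUMP_RANGE,
               contrast_fraction: float = 0.1) -> CLSResult:
    """CLS at every waiting time of the cube."""
    points = [center_line_slope(spec, tw, pump_range, contrast_fraction)
              for tw in spec.waiting_times]
    return CLSResult(waiting_times=spec.waiting_times.copy(),
                     cls=np.array([p.cls for p in points]), points=points)


def fit_cls_decay(cls_result: CLSResult) -> tuple[float, float]:
    """Fit CLS(Tw) = CLS0 exp(-Tw/tau_specdiff); returns (CLS0, tau).

    The fitted values and covariance are also stored on the result.  A
    non-decaying series yields a very large, poorly determined time
    constant with a warning (from the underlying estimator).
    """
    if len(cls_result.waiting_times) < 3:
        raise ValueError("need at least 3 waiting times for the decay fit")
    est = ExponentialDecay(offset=False)
    est.fit(cls_result.waiting_times, cls_result.cls)
    cls_result.cls0 = est.amplitude_
    cls_result.tau_specdiff = est.tau_
    cls_result.covariance = est.covariance_
    return est.amplitude_, est.tau_


def fit_population_decay(spec: Spectrum2D,
                         region: tuple[float, float, float, float] | None = None
                         ) -> PopulationFit:
    """Vibrational relaxation from integrated bleach volumes.

    ``region`` is (pump_lo, pump_hi, probe_lo, probe_hi); default full
    cube.  The bleach volume is the integral of the negative signal
    magnitude over the region, fitted with A0 exp(-Tw/tau_VER) + y0.
    """
    if len(spec.waiting_times) < 3:
        raise ValueError("need at least 3 waiting times for the decay fit")
    if region is None:
        region = (spec.pump[0], spec.pump[-1], spec.probe[0], spec.probe[-1])
    pm = (spec.pump >= region[0]) & (spec.pump <= region[1])
    qm = (spec.probe >= region[2]) & (spec.probe <= region[3])
    volumes = np.array([
        np.trapezoid(np.trapezoid(np.clip(-S[np.ix_(pm, qm)], 0, None),
                                  spec.probe[qm], axis=1), spec.pump[pm])
        for S in spec.cube])
    est = ExponentialDecay(offset=True)
    est.fit(spec.waiting_times, volumes)
    return PopulationFit(a0=est.amplitude_, tau_ver=est.tau_, y0=est.offset_,
                         covariance=est.covariance_, volumes=volumes,
                         waiting_times=spec.waiting_times.copy())
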