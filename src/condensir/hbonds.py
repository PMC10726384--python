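"""Amide-oxygen / water hydrogen-bond detection, survival autocorrelation
and constrained multi-exponential lifetime analysis.

The survival autocorrelation of the boolean occupancy ``h_ij(t)`` (1 if
amide oxygen i accepts an H-bond from water j at time t) is

    C(t) = < sum_ij h_ij(t0) h_ij(t0 + t) > / < sum_ij h_ij(t0)^2 >

with the angle brackets averaging over time origins t0.  The default is
the *intermittent* convention: a bond that breaks and later reforms
still contributes at long lags.  A strict-continuous variant (the bond
must persist through every intermediate frame) is available via
``continuous=True``.

After removal of the baseline (equilibrium) H-bond population the decay
is fitted with a simplex-constrained triple exponential; the
amplitude-weighted mean ``tau = sum A_n tau_n`` — the integral of the
unit-normalized fit — is the reported H-bond lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .fitting import TriExponentialDecay
from .frames import Frame, minimum_image_displacement

__all__ = [
    "HBondCriteria", "HBondSeries", "ACFResult", "TriExpFit",
    "detect_hbonds", "hbond_series", "survival_acf", "remove_baseline",
    "fit_triexp", "mean_lifetime",
]


@dataclass
class HBondCriteria:
    """Geometric H-bond definition (acceptor = amide O, donor = water O).

    A pair is bonded iff O_amide...H_water <= ``ah_cutoff`` AND
    O_amide...O_water <= ``da_cutoff`` AND the O_water-H...O_amide angle
    at the hydrogen is >= ``min_angle``.
    """

    ah_cutoff: float = 2.45       # Angstrom
    da_cutoff: float = 3.5        # Angstrom
    min_angle: float = 130.0      # degrees

    def __post_init__(self) -> None:
        if self.ah_cutoff <= 0 or self.da_cutoff <= 0:
            raise ValueError("distance cutoffs must be positive")
        if not 0.0 < self.min_angle <= 180.0:
            raise ValueError("min_angle must lie in (0, 180] degrees")


@dataclass
class HBondSeries:
    """Boolean occupancy matrix h_ij(t), one row per (residue, water) pair."""

    occupancy: np.ndarray               # (n_pairs, n_steps) bool
    dt: float                           # frame spacing, ps
    pairs: list | None = None           # optional pair identities

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 2:
            raise ValueError("occupancy must be 2-D (pairs x time)")
        if self.dt <= 0:
            raise ValueError("frame spacing must be positive")

    @property
    def n_pairs(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_steps(self) -> int:
        return self.occupancy.shape[1]


@dataclass
class ACFResult:
    """Survival autocorrelation C(t) with per-lag origin counts."""

    lags: np.ndarray                    # ps, strictly increasing
    c: np.ndarray
    n_origins: np.ndarray
    baseline: float | None = None       # subtracted plateau, if any

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.n_origins = np.asarray(self.n_origins, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


@dataclass
class TriExpFit:
    """Result of the constrained triple-exponential fit.

    Amplitudes satisfy A1 + A2 + A3 = 1 with all A >= 0; time constants
    are in ps.  ``mean_lifetime`` is the amplitude-weighted average
    ``sum A_n tau_n``, i.e. the integral of the unit-normalized fit.
    """

    amplitudes: np.ndarray
    taus: np.ndarray
    covariance: np.ndarray | None = None
    residual_norm: float | None = None

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.taus = np.asarray(self.taus, dtype=float)
        if self.amplitudes.shape != (3,) or self.taus.shape != (3,):
            raise ValueError("need exactly three components")
        if abs(self.amplitudes.sum() - 1.0) > 1e-9:
            raise ValueError("amplitudes must sum to 1")
        if np.any(self.amplitudes < -1e-12) or np.any(self.taus <= 0):
            raise ValueError("amplitudes must be >= 0 and taus > 0")

    @property
    def mean_lifetime(self) -> float:
        return float(self.amplitudes @ self.taus)


def mean_lifetime(fit: TriExpFit) -> float:
    """Amplitude-weighted mean lifetime sum A_n tau_n, in ps."""
    return fit.mean_lifetime


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------

def detect_hbonds(frame: Frame, criteria: HBondCriteria | None = None) -> set:
    """Amide-O / water H-bonded pairs in one frame.

    Returns a set of ``((chain_id, resid), water_resid)`` tuples.  All
    distances and the donor-hydrogen-acceptor angle use minimum-image
    displacements if the frame is periodic.
    """
    criteria = criteria or HBondCriteria()
    amide_mask = frame.roles == "amide_O"
    if not np.any(amide_mask):
        raise ValueError("frame carries no amide_O role labels")
    wh_mask = frame.roles == "water_H"
    wo_mask = frame.roles == "water_O"
    if not np.any(wh_mask):
        return set()

    box = frame.box if frame.periodic else None
    acceptor_xyz = frame.coords[amide_mask]
    acceptor_chain = frame.chain_ids[amide_mask]
    acceptor_resid = frame.resids[amide_mask]
    wh_xyz = frame.coords[wh_mask]
    wh_resid = frame.resids[wh_mask]
    wo_xyz = frame.coords[wo_mask]
    wo_resid = frame.resids[wo_mask]
    o_of_water = {int(r): wo_xyz[i] for i, r in enumerate(wo_resid)}

    if box is not None:
        tree = cKDTree(np.mod(wh_xyz, box), boxsize=box)
        query = np.mod(acceptor_xyz, box)
    else:
        tree = cKDTree(wh_xyz)
        query = acceptor_xyz

    bonded = set()
    neighbours = tree.query_ball_point(query, r=criteria.ah_cutoff)
    for ia, hits in enumerate(neighbours):
        oa = acceptor_xyz[ia]
        for ih in hits:
            wres = int(wh_resid[ih])
            if wres not in o_of_water:
                raise ValueError(f"water residue {wres} has no water_O atom")
            h = wh_xyz[ih]
            ow = o_of_water[wres]
            d_oo = np.linalg.norm(minimum_image_displacement(oa - ow, box))
            if d_oo > criteria.da_cutoff:
                continue
            v_ow = minimum_image_displacement(ow - h, box)
            v_oa = minimum_image_displacement(oa - h, box)
            cosang = v_ow @ v_oa / (np.linalg.norm(v_ow) * np.linalg.norm(v_oa))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle >= criteria.min_angle:
                bonded.add(((int(acceptor_chain[ia]), int(acceptor_resid[ia])),
                            wres))
    return bonded


def hbond_series(frames: list[Frame], dt: float,
                 criteria: HBondCriteria | None = None,
                 chain_ids: set | None = None) -> HBondSeries:
    """Occupancy matrix over a trajectory of frames.

    ``chain_ids`` optionally restricts the amide acceptors to a subset
    of chains (e.g. one phase).  The pair universe is the union of all
    pairs ever bonded.
    """
    per_frame = []
    for f in frames:
        pairs = detect_hbonds(f, criteria)
        if chain_ids is not None:
            pairs = {p for p in pairs if p[0][0] in chain_ids}
        per_frame.append(pairs)
    universe = sorted(set().union(*per_frame)) if per_frame else []
    index = {p: i for i, p in enumerate(universe)}
    occ = np.zeros((len(universe), len(frames)), dtype=bool)
    for t, pairs in enumerate(per_frame):
        for p in pairs:
            occ[index[p], t] = True
    return HBondSeries(occupancy=occ, dt=dt, pairs=universe)


# --------------------------------------------------------------------------
# Survival autocorrelation
# --------------------------------------------------------------------------

def survival_acf(series: HBondSeries, max_lag: float,
                 origin_stride: int = 1, continuous: bool = False) -> ACFResult:
    """Survival autocorrelation of the occupancy matrix.

    Time origins are spaced ``origin_stride`` frames apart; for each lag
    the numerator and the normalisation are averaged over the origins
    for which the lagged frame exists, so C(0) = 1 exactly.  ``max_lag``
    (ps) may not exceed half the trajectory length.
    """
    occ = series.occupancy
    n_steps = series.n_steps
    if origin_stride < 1:
        raise ValueError("origin_stride must be >= 1")
    if max_lag > 0.5 * (n_steps - 1) * series.dt + 1e-12:
        raise ValueError("max_lag exceeds half the trajectory length")
    if not occ.any():
        raise ValueError("all-zero occupancy: normalization undefined")
    n_lags = int(round(max_lag / series.dt)) + 1

    if continuous:
        return _continuous_acf(series, n_lags, origin_stride)

    s = occ.sum(axis=0).astype(np.int64)            # per-frame bonded count
    num = np.empty(n_lags)
    den = np.empty(n_lags)
    n_origins = np.empty(n_lags, dtype=int)
    if origin_stride == 1:
        # FFT autocorrelation per pair gives sum_{t0 <= T-1-L} h(t0)h(t0+L)
        T = n_steps
        nfft = 1
        while nfft < 2 * T:
            nfft *= 2
        acc = np.zeros(n_lags)
        for start in range(0, occ.shape[0], 256):
            block = occ[start:start + 256].astype(np.float64)
            F = np.fft.rfft(block, n=nfft, axis=1)
            corr = np.fft.irfft(F * np.conj(F), n=nfft, axis=1)[:, :n_lags]
            acc += corr.sum(axis=0)
        cum = np.cumsum(s)
        for L in range(n_lags):
            num[L] = acc[L]
            den[L] = cum[T - 1 - L]
            n_origins[L] = T - L
    else:
        for L in range(n_lags):
            t0 = np.arange(0, n_steps - L, origin_stride)
            num[L] = np.count_nonzero(occ[:, t0] & occ[:, t0 + L])
            den[L] = s[t0].sum()
            n_origins[L] = len(t0)
    c = num / den
    lags = np.arange(n_lags) * series.dt
    return ACFResult(lags=lags, c=c, n_origins=n_origins)


def _continuous_acf(series: HBondSeries, n_lags: int,
                    origin_stride: int) -> ACFResult:
    """Strict-survival variant: the bond must persist through every frame."""
    occ = series.occupancy
    n_steps = series.n_steps
    num = np.zeros(n_lags)
    den = 0.0
    origins = np.arange(0, n_steps - n_lags + 1, origin_stride)
    if len(origins) == 0:
        raise ValueError("trajectory too short for the requested max_lag")
    for t0 in origins:
        surv = np.logical_and.accumulate(occ[:, t0:t0 + n_lags], axis=1)
        num += surv.sum(axis=0)
        den += occ[:, t0].sum()
    if den == 0:
        raise ValueError("all-zero occupancy at the chosen origins")
    lags = np.arange(n_lags) * series.dt
    return ACFResult(lags=lags, c=num / den,
                     n_origins=np.full(n_lags, len(origins)))


def remove_baseline(acf: ACFResult, tail_fraction: float = 0.1) -> ACFResult:
    """Subtract the plateau (equilibrium H-bond population) and renormalize.

    The baseline is the mean of C over the final ``tail_fraction`` of
    lags; the result is rescaled so C(0) = 1 again.
    """
    n_tail = int(round(tail_fraction * len(acf.lags)))
    if n_tail < 5:
        raise ValueError("tail window must contain at least 5 lags")
    b = float(acf.c[-n_tail:].mean())
    c0 = acf.c[0]
    if b >= c0:
        raise ValueError("baseline >= C(0): no decaying component")
    c_new = (acf.c - b) / (c0 - b)
    return ACFResult(lags=acf.lags.copy(), c=c_new,
                     n_origins=acf.n_origins.copy(), baseline=b)


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

def fit_triexp(acf: ACFResult, init: TriExpFit | None = None,
               fix_tau3: float | None = None) -> TriExpFit:
    """Constrained triple-exponential fit of a baseline-removed ACF."""
    est = TriExponentialDecay(fix_tau3=fix_tau3)
    seed = None if init is None else (init.amplitudes, init.taus)
    est.fit(acf.lags, acf.c, init=seed)
    return TriExpFit(amplitudes=est.amplitudes_, taus=est.taus_,
                     covariance=est.covariance_,
                     residual_norm=est.residual_norm_)
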