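"""Synthetic-data generators with exactly known ground truth.

Four generators feed the analysis stages:

* a two-state (telegraph) Markov chain for H-bond occupancy, whose
  survival autocorrelation is exactly ``p + (1-p) exp(-(k_on+k_off) t)``
  with ``p = k_on/(k_on+k_off)``;
* a Gaussian frequency-fluctuation (Kubo-style) 2D IR cube whose
  center line slope equals the normalized frequency correlation
  ``rho(Tw) = Delta^2 exp(-Tw/tau_c) / (Delta^2 + sigma_h^2)``;
* ideal-geometry peptide backbones with settable C=O lengths, dihedral
  angles and proline positions;
* toy droplet-plus-dispersed multi-chain configurations in a periodic
  box, with phase labels known by construction.

All generators take a mandatory integer seed; there is no global
random state, and output is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .frames import Frame, PeptideStructure, merge_frames, pairwise_min_distance
from .hbonds import HBondSeries
from .spectra import Spectrum2D

__all__ = [
    "TelegraphParams", "gen_telegraph_occupancy",
    "KuboParams", "gen_kubo_2dspectra",
    "PeptideSpec", "gen_peptide_chain",
    "gen_droplet_system",
    "measure_dihedral",
]


# --------------------------------------------------------------------------
# Telegraph (two-state Markov) H-bond occupancy
# --------------------------------------------------------------------------

@dataclass
class TelegraphParams:
    """Two-state H-bond kinetics: off -> on at ``k_on``, on -> off at ``k_off``.

    Rates are in 1/ps, the timestep ``dt`` in ps.
    """

    n_pairs: int
    k_on: float
    k_off: float
    dt: float
    n_steps: int
    seed: int

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("rates must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 2:
            raise ValueError("need at least 2 time steps")
        if self.n_pairs < 1:
            raise ValueError("need at least 1 pair")


def gen_telegraph_occupancy(params: TelegraphParams,
                            initial_bonded: bool | None = None) -> HBondSeries:
    """Sample boolean occupancy trajectories of a telegraph process.

    The chain is propagated with *exact* exponential transition
    probabilities over each step, so the process observed at the sampled
    times is the exact continuous-time two-state Markov chain (no Euler
    discretisation bias).  The initial state is drawn from the
    stationary distribution ``k_on/(k_on+k_off)`` unless
    ``initial_bonded`` overrides it for every pair.
    """
    p = params
    k = p.k_on + p.k_off
    if p.dt * k > 0.1:
        warnings.warn(
            "dt*(k_on+k_off) > 0.1: time resolution is coarse relative to "
            "the kinetics; fast events between samples are invisible",
            RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(p.seed)
    occ = np.empty((p.n_pairs, p.n_steps), dtype=bool)
    if k == 0.0:
        p_eq = 1.0 if initial_bonded else 0.0
        if initial_bonded is None:
            raise ValueError("k_on=k_off=0 requires an explicit initial state")
        occ[:] = initial_bonded
        return HBondSeries(occupancy=occ, dt=p.dt)
    p_eq = p.k_on / k
    decay = np.exp(-k * p.dt)
    p_on_given_on = p_eq + (1.0 - p_eq) * decay     # P(1 -> 1) over dt
    p_on_given_off = p_eq * (1.0 - decay)           # P(0 -> 1) over dt
    if initial_bonded is None:
        occ[:, 0] = rng.random(p.n_pairs) < p_eq
    else:
        occ[:, 0] = initial_bonded
    u = rng.random((p.n_pairs, p.n_steps - 1))
    for t in range(1, p.n_steps):
        prev = occ[:, t - 1]
        thresh = np.where(prev, p_on_given_on, p_on_given_off)
        occ[:, t] = u[:, t - 1] < thresh
    return HBondSeries(occupancy=occ, dt=p.dt)


# --------------------------------------------------------------------------
# Kubo-style 2D IR cubes
# --------------------------------------------------------------------------

@dataclass
class KuboParams:
    """Joint-Gaussian bleach/ESA 2D lineshape with exponential memory loss.

    The bleach at waiting time Tw is a negative bivariate Gaussian in
    (pump, probe) with marginal variance ``Delta^2 + sigma_h^2`` and
    correlation ``rho(Tw) = Delta^2 exp(-Tw/tau_c) / (Delta^2 + sigma_h^2)``;
    the excited-state absorption is its positive copy shifted down the
    probe axis by ``anharmonic_shift``.  Both decay with the population
    lifetime.  This is a phenomenological lineshape, not a third-order
    response-function calculation: it is the minimal model for which the
    center line slope has the closed form CLS(Tw) = rho(Tw).
    """

    center_frequency: float          # cm^-1
    inhomogeneous_width: float       # Delta, cm^-1 (std. dev.)
    correlation_time: float          # tau_c, ps
    homogeneous_width: float         # sigma_h, cm^-1 (Gaussian std. dev.)
    anharmonic_shift: float          # cm^-1, ESA red shift along probe
    population_lifetime: float       # ps
    waiting_times: np.ndarray        # ps
    pump_axis: np.ndarray            # cm^-1
    probe_axis: np.ndarray           # cm^-1
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.waiting_times = np.asarray(self.waiting_times, dtype=float)
        self.pump_axis = np.asarray(self.pump_axis, dtype=float)
        self.probe_axis = np.asarray(self.probe_axis, dtype=float)
        if self.inhomogeneous_width < 0:
            raise ValueError("inhomogeneous width must be >= 0")
        if self.correlation_time <= 0:
            raise ValueError("correlation time must be positive")
        if self.anharmonic_shift <= 0:
            raise ValueError("anharmonic shift must be positive")
        if self.population_lifetime <= 0:
            raise ValueError("population lifetime must be positive")
        if np.any(self.waiting_times < 0):
            raise ValueError("waiting times must be non-negative")
        for ax in (self.pump_axis, self.probe_axis):
            if np.any(np.diff(ax) <= 0):
                raise ValueError("axes must be strictly increasing")


def _gauss2d(x: np.ndarray, y: np.ndarray, sigma2: float, rho: float) -> np.ndarray:
    """Unit-volume bivariate Gaussian with equal marginal variances.

    Unit volume (not unit peak) so that the integrated lobe intensity
    tracks the population amplitude alone, independent of the
    correlation-induced narrowing of the lineshape.
    """
    rho = float(np.clip(rho, -1.0 + 1e-12, 1.0 - 1e-12))
    q = (x ** 2 - 2.0 * rho * x * y + y ** 2) / (sigma2 * (1.0 - rho ** 2))
    norm = 2.0 * np.pi * sigma2 * np.sqrt(1.0 - rho ** 2)
    return np.exp(-0.5 * q) / norm


def gen_kubo_2dspectra(params: KuboParams) -> Spectrum2D:
    """Generate a synthetic 2D IR cube from the joint-Gaussian model."""
    p = params
    rng = np.random.default_rng(p.seed)
    sigma2 = p.inhomogeneous_width ** 2 + p.homogeneous_width ** 2
    if sigma2 <= 0:
        raise ValueError("total linewidth must be positive")
    xp = p.pump_axis[:, None] - p.center_frequency
    yb = p.probe_axis[None, :] - p.center_frequency
    ye = p.probe_axis[None, :] - (p.center_frequency - p.anharmonic_shift)
    cube = np.empty((len(p.waiting_times), len(p.pump_axis), len(p.probe_axis)))
    for i, tw in enumerate(p.waiting_times):
        rho = (p.inhomogeneous_width ** 2 *
               np.exp(-tw / p.correlation_time)) / sigma2
        amp = np.exp(-tw / p.population_lifetime)
        bleach = -amp * _gauss2d(xp, yb, sigma2, rho)
        esa = amp * _gauss2d(xp, ye, sigma2, rho)
        cube[i] = bleach + esa
        if p.noise_sd > 0:
            cube[i] += rng.normal(0.0, p.noise_sd, cube[i].shape)
    return Spectrum2D(pump=p.pump_axis, probe=p.probe_axis,
                      waiting_times=p.waiting_times, cube=cube)


# --------------------------------------------------------------------------
# Ideal-geometry peptide backbones
# --------------------------------------------------------------------------

# ideal internal coordinates (Angstrom / degrees) for a trans peptide
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_N_H = 1.010
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8
_ANGLE_C_N_H = 119.0
_OMEGA = 180.0


@dataclass
class PeptideSpec:
    """Backbone geometry request: per-residue (phi, psi), C=O lengths, prolines."""

    n_residues: int
    dihedrals: np.ndarray | None = None    # (n, 2) degrees; phi of residue 0 unused
    co_lengths: np.ndarray | float = 1.229
    proline_flags: np.ndarray | None = None
    rotation: np.ndarray | None = None     # rigid-body placement
    translation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("need at least one residue")
        if self.dihedrals is None:
            self.dihedrals = np.tile([-120.0, 120.0], (self.n_residues, 1))
        self.dihedrals = np.asarray(self.dihedrals, dtype=float)
        if self.dihedrals.shape != (self.n_residues, 2):
            raise ValueError("dihedrals must have shape (n_residues, 2)")
        if np.any(self.dihedrals <= -180.0) or np.any(self.dihedrals > 180.0):
            raise ValueError("dihedrals must lie in (-180, 180] degrees")
        self.co_lengths = np.broadcast_to(
            np.asarray(self.co_lengths, dtype=float), (self.n_residues,)).copy()
        if np.any(self.co_lengths <= 0):
            raise ValueError("C=O lengths must be positive")
        if self.proline_flags is None:
            self.proline_flags = np.zeros(self.n_residues, dtype=bool)
        self.proline_flags = np.asarray(self.proline_flags, dtype=bool)
        if len(self.proline_flags) != self.n_residues:
            raise ValueError("proline_flags length mismatch")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d from atoms a, b, c."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    b2 = c - b
    b2 /= np.linalg.norm(b2)
    b1 = b - a
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)
    m = np.cross(n, b2)
    d = bond * (-np.cos(theta) * b2 +
                np.sin(theta) * np.cos(chi) * m -
                np.sin(theta) * np.sin(chi) * n)
    return c + d


def measure_dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                     d: np.ndarray) -> float:
    """Signed dihedral a-b-c-d in degrees, IUPAC convention."""
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))


def _wrap180(x: float) -> float:
    return ((x + 180.0) % 360.0) - 180.0


def gen_peptide_chain(spec: PeptideSpec) -> PeptideStructure:
    """Build a backbone (N, CA, C, O, amide H) from ideal internal coordinates.

    Bond lengths and angles are standard trans-peptide values except the
    C=O lengths, which are set per residue from the spec.  Amide
    hydrogens are attached anti to the preceding carbonyl oxygen; the
    N-terminal residue and prolines carry none (NaN rows).
    """
    n = spec.n_residues
    N = np.full((n, 3), np.nan)
    CA = np.full((n, 3), np.nan)
    C = np.full((n, 3), np.nan)
    O = np.full((n, 3), np.nan)
    H = np.full((n, 3), np.nan)

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_BOND_N_CA, 0.0, 0.0)
    # CA->N points along -x; put C in the xy-plane at the N-CA-C angle
    th = np.deg2rad(_ANGLE_N_CA_C)
    C[0] = CA[0] + _BOND_CA_C * np.array([np.cos(np.pi - th), np.sin(np.pi - th), 0.0])

    for i in range(n):
        phi, psi = spec.dihedrals[i]
        O[i] = _place_atom(N[i], CA[i], C[i], spec.co_lengths[i],
                           _ANGLE_CA_C_O, _wrap180(psi + 180.0))
        if i + 1 < n:
            N[i + 1] = _place_atom(N[i], CA[i], C[i], _BOND_C_N,
                                   _ANGLE_CA_C_N, psi)
            CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1], _BOND_N_CA,
                                    _ANGLE_C_N_CA, _OMEGA)
            if not spec.proline_flags[i + 1]:
                H[i + 1] = _place_atom(O[i], C[i], N[i + 1], _BOND_N_H,
                                       _ANGLE_C_N_H, 180.0)
            phi_next = spec.dihedrals[i + 1, 0]
            C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1], _BOND_CA_C,
                                   _ANGLE_N_CA_C, phi_next)

    structure = PeptideStructure(
        atoms={"N": N, "CA": CA, "C": C, "O": O, "H": H},
        proline_flags=spec.proline_flags)
    _check_no_overlap(structure)
    if spec.rotation is not None or spec.translation is not None:
        structure = structure.transformed(spec.rotation, spec.translation)
    return structure


def _check_no_overlap(s: PeptideStructure, min_sep: float = 0.5) -> None:
    xyz = np.concatenate([v for v in s.atoms.values()])
    xyz = xyz[~np.isnan(xyz).any(axis=1)]
    d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < min_sep:
        raise ValueError(
            f"impossible geometry: atoms overlap (min distance {d.min():.3f} A)")


def backbone_dihedrals(s: PeptideStructure) -> np.ndarray:
    """Recompute (phi, psi) per residue from coordinates (NaN where undefined)."""
    n = s.n_residues
    out = np.full((n, 2), np.nan)
    N, CA, C = s.atoms["N"], s.atoms["CA"], s.atoms["C"]
    for i in range(n):
        if i > 0:
            out[i, 0] = measure_dihedral(C[i - 1], N[i], CA[i], C[i])
        if i + 1 < n:
            out[i, 1] = measure_dihedral(N[i], CA[i], C[i], N[i + 1])
    return out


# --------------------------------------------------------------------------
# Droplet-plus-dispersed configurations
# --------------------------------------------------------------------------

def gen_droplet_system(n_condensed: int, n_dispersed: int, box: float | np.ndarray,
                       min_gap: float, seed: int,
                       contact_distance: float = 2.5,
                       n_residues: int = 4,
                       max_retries: int = 500) -> Frame:
    """Place peptide chains as one contact-connected droplet plus loners.

    Chains ``0 .. n_condensed-1`` form a single cluster in which each
    chain's minimum atom-atom distance to its predecessor equals
    ``contact_distance`` (Angstrom); chains ``n_condensed ..`` are each
    at least ``min_gap`` from every other chain under the minimum-image
    convention.  The chain-id ordering is the ground-truth phase label.
    """
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    rng = np.random.default_rng(seed)
    if min_gap <= contact_distance:
        raise ValueError("min_gap must exceed the intended contact distance")
    template = gen_peptide_chain(PeptideSpec(n_residues=n_residues))

    placed: list[PeptideStructure] = []
    chain_id = 0
    # condensed cluster: chains laid out sequentially along +x, each
    # placed by bisection so its min distance to the previous chain is
    # exactly contact_distance
    prev_coords = None
    offset = np.zeros(3)
    for _ in range(n_condensed):
        chain = template.transformed(translation=offset)
        chain.chain_id = chain_id
        if prev_coords is not None:
            coords = _chain_coords(chain)
            shift = _bisect_contact(prev_coords, coords, np.array([1.0, 0, 0]),
                                    contact_distance)
            chain = chain.transformed(translation=np.array([shift, 0, 0]))
            offset = offset + np.array([shift, 0, 0])
        placed.append(chain)
        prev_coords = _chain_coords(chain)
        chain_id += 1

    # recentre the cluster in the box and check it fits
    if placed:
        allc = np.concatenate([_chain_coords(c) for c in placed])
        lo, hi = allc.min(axis=0), allc.max(axis=0)
        if np.any(hi - lo >= box - 2 * min_gap):
            raise ValueError("condensed cluster does not fit in the box")
        centre_shift = box / 2 - (lo + hi) / 2
        placed = [c.transformed(translation=centre_shift) for c in placed]

    # dispersed chains: rejection sampling with a minimum-image gap check
    for _ in range(n_dispersed):
        ok = False
        for _attempt in range(max_retries):
            Rm = _random_rotation(rng)
            pos = rng.random(3) * box
            cand = template.transformed(rotation=Rm, translation=pos)
            cand_coords = _chain_coords(cand)
            if all(pairwise_min_distance(cand_coords, _chain_coords(c), box)
                   >= min_gap for c in placed):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"failed to place a dispersed chain after {max_retries} tries; "
                "box too crowded for the requested min_gap")
        cand.chain_id = chain_id
        placed.append(cand)
        chain_id += 1

    if not placed:
        raise ValueError("empty system requested")
    frames = [c.to_frame() for c in placed]
    return merge_frames(frames, box=box, periodic=True)


def _chain_coords(s: PeptideStructure) -> np.ndarray:
    xyz = np.concatenate([v for v in s.atoms.values()])
    return xyz[~np.isnan(xyz).any(axis=1)]


def _bisect_contact(ref: np.ndarray, moving: np.ndarray, direction: np.ndarray,
                    target: float, tol: float = 1e-9) -> float:
    """Shift along ``direction`` making min distance (ref, moving) == target."""
    extent = np.ptp(np.concatenate([ref, moving]) @ direction)
    lo, hi = 0.0, 2.0 * extent + 2.0 * target + 10.0
    f = lambda t: pairwise_min_distance(ref, moving + t * direction) - target
    if f(lo) > 0:       # already separated: pull closer instead
        lo, hi = -hi, lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return hi


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via QR of a Gaussian matrix)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q
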