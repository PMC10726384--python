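"""Amide I one-exciton Hamiltonian and linear IR spectra.

The amide I band (backbone C=O stretch, ~1620-1680 cm^-1) of a peptide
is modelled as N coupled local oscillators.  Diagonal (site) frequencies
come from a linear map on the C=O bond length,

    omega_i = Omega0 - S * (r_CO,i - r0),

with Omega0 = 1655 cm^-1, r0 = 1.229 A and S = 400 cm^-1/A by default;
bond elongation (stronger H-bonding) red-shifts the site.  Sites whose
amide nitrogen belongs to a proline (i.e. the residue *preceding* a
proline) are red-shifted by a further 19 cm^-1 for the heavier ring
substituent.  Nearest-neighbour couplings are dominated by through-bond
effects and are read from a (phi, psi) dihedral map with periodic
bilinear interpolation; all longer-range couplings use the through-space
transition dipole coupling (TDC) model,

    beta_ij = pref * mu_i mu_j * [e_i.e_j - 3 (e_i.n)(e_j.n)] / r^3.

Diagonalizing the Hamiltonian gives delocalized eigenmodes; the linear
spectrum is the stick spectrum |sum_i c_ik mu_i|^2 at the eigenvalues,
convolved with unit-area Lorentzians (HWHM 6 cm^-1 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import PeptideStructure
from .synthetic import measure_dihedral

__all__ = [
    "SpectralMapParams", "CouplingMap", "TransitionDipole",
    "ExcitonHamiltonian", "LinearSpectrum",
    "local_mode_frequencies", "nn_coupling", "tdc_coupling",
    "transition_dipoles", "build_hamiltonian", "linear_spectrum",
    "ensemble_linear_spectrum", "synthetic_coupling_map",
]


@dataclass
class SpectralMapParams:
    """Parameters of the site-frequency map and line shape.

    gas_phase_frequency : Omega0, cm^-1.
    co_reference_length : r0, Angstrom.
    length_scaling : S, cm^-1 per Angstrom of C=O elongation.
    proline_shift : red shift (cm^-1) for amides preceding a proline.
    lorentzian_hwhm : half width at half maximum of the line shape, cm^-1.
    """

    gas_phase_frequency: float = 1655.0
    co_reference_length: float = 1.229
    length_scaling: float = 400.0
    proline_shift: float = 19.0
    lorentzian_hwhm: float = 6.0

    def __post_init__(self) -> None:
        for name in ("gas_phase_frequency", "co_reference_length",
                     "length_scaling", "proline_shift", "lorentzian_hwhm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class CouplingMap:
    """Nearest-neighbour coupling map on a periodic (phi, psi) grid.

    The grid must tile the full torus: node angles are uniformly spaced
    and wrap at +-180 degrees.  Queries use periodic bilinear
    interpolation, exact at grid nodes.
    """

    def __init__(self, phi_nodes: np.ndarray, psi_nodes: np.ndarray,
                 values: np.ndarray):
        self.phi_nodes = np.asarray(phi_nodes, dtype=float)
        self.psi_nodes = np.asarray(psi_nodes, dtype=float)
        self.values = np.asarray(values, dtype=float)
        for nodes, n in ((self.phi_nodes, self.values.shape[0]),
                         (self.psi_nodes, self.values.shape[1])):
            d = np.diff(nodes)
            if len(nodes) < 3 or np.any(d <= 0) or not np.allclose(d, d[0]):
                raise ValueError("map nodes must be uniformly increasing")
            if not np.isclose(nodes[-1] - nodes[0] + d[0], 360.0):
                raise ValueError("map grid must cover the full 360-degree torus")
        if len(self.phi_nodes) != self.values.shape[0] or \
                len(self.psi_nodes) != self.values.shape[1]:
            raise ValueError("grid/value shape mismatch")

    def __call__(self, phi: float, psi: float) -> float:
        def locate(x, nodes):
            step = nodes[1] - nodes[0]
            u = (x - nodes[0]) / step
            i = int(np.floor(u)) % len(nodes)
            return i, u - np.floor(u)
        i, fx = locate(phi, self.phi_nodes)
        j, fy = locate(psi, self.psi_nodes)
        ip = (i + 1) % len(self.phi_nodes)
        jp = (j + 1) % len(self.psi_nodes)
        v = self.values
        return float((1 - fx) * (1 - fy) * v[i, j] + fx * (1 - fy) * v[ip, j]
                     + (1 - fx) * fy * v[i, jp] + fx * fy * v[ip, jp])

    # -- file I/O: whitespace-delimited "phi psi coupling" triples ----
    @classmethod
    def from_file(cls, path) -> "CouplingMap":
        try:
            data = np.loadtxt(path)
            if data.ndim != 2 or data.shape[1] != 3:
                raise ValueError("expected three columns: phi psi coupling")
        except Exception as exc:
            raise ValueError(f"malformed coupling-map file {path}: {exc}") from exc
        phi = np.unique(data[:, 0])
        psi = np.unique(data[:, 1])
        if len(phi) * len(psi) != len(data):
            raise ValueError(f"coupling map in {path} is not a complete grid")
        vals = np.full((len(phi), len(psi)), np.nan)
        pi = {v: i for i, v in enumerate(phi)}
        qi = {v: i for i, v in enumerate(psi)}
        for a, b, c in data:
            vals[pi[a], qi[b]] = c
        return cls(phi, psi, vals)

    def to_file(self, path) -> None:
        rows = [(a, b, self.values[i, j])
                for i, a in enumerate(self.phi_nodes)
                for j, b in enumerate(self.psi_nodes)]
        np.savetxt(path, rows, fmt="%.4f %.4f %.6f",
                   header="phi_deg psi_deg coupling_cm-1")


def synthetic_coupling_map(spacing: float = 15.0) -> CouplingMap:
    """A smooth synthetic placeholder nearest-neighbour map.

    Illustrative stand-in with the qualitative shape and few-cm^-1
    magnitude typical of published dihedral coupling maps; it is NOT a
    fit to any quantum-chemical dataset.  Supply a real map file for
    quantitative work.
    """
    nodes = np.arange(-180.0, 180.0, spacing)
    phi = np.deg2rad(nodes)[:, None]
    psi = np.deg2rad(nodes)[None, :]
    vals = (4.0 * np.cos(phi + psi) - 1.5 * np.cos(phi)
            + 1.0 * np.cos(psi) + 1.2 * np.sin(phi) * np.sin(psi))
    return CouplingMap(nodes, nodes.copy(), vals)


@dataclass
class TransitionDipole:
    """Point transition dipole: origin (A), unit direction, magnitude (rel. D)."""

    origin: np.ndarray
    direction: np.ndarray
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise ValueError("direction must be a unit vector")

    @property
    def vector(self) -> np.ndarray:
        return self.magnitude * self.direction


@dataclass
class ExcitonHamiltonian:
    """N x N symmetric one-exciton Hamiltonian (cm^-1) plus site dipoles."""

    matrix: np.ndarray
    dipoles: list
    proline_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("Hamiltonian must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("Hamiltonian must be symmetric")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]


@dataclass
class LinearSpectrum:
    """Absorbance on a frequency grid plus the underlying stick spectrum."""

    grid: np.ndarray
    absorbance: np.ndarray
    stick_frequencies: np.ndarray
    stick_intensities: np.ndarray

    def first_moment(self) -> float:
        w = self.absorbance / self.absorbance.sum()
        return float(w @ self.grid)

    def second_moment(self) -> float:
        w = self.absorbance / self.absorbance.sum()
        mu = w @ self.grid
        return float(w @ (self.grid - mu) ** 2)


# --------------------------------------------------------------------------
# Site frequencies and couplings
# --------------------------------------------------------------------------

def local_mode_frequencies(structure: PeptideStructure,
                           params: SpectralMapParams | None = None) -> np.ndarray:
    """Per-residue amide I site frequencies from the C=O length map."""
    params = params or SpectralMapParams()
    if "C" not in structure.atoms or "O" not in structure.atoms or \
            np.isnan(structure.atoms["O"]).any() or np.isnan(structure.atoms["C"]).any():
        raise ValueError("structure is missing C=O atoms")
    r = structure.co_lengths()
    omega = params.gas_phase_frequency - params.length_scaling * (
        r - params.co_reference_length)
    flags = structure.proline_flags
    upstream = np.zeros(structure.n_residues, dtype=bool)
    upstream[:-1] = flags[1:]          # amide i's N belongs to residue i+1
    omega[upstream] -= params.proline_shift
    return omega


def nn_coupling(phi: float, psi: float, coupling_map: CouplingMap) -> float:
    """Nearest-neighbour coupling (cm^-1) at the linking residue's dihedrals."""
    return coupling_map(phi, psi)


def tdc_coupling(d_i: TransitionDipole, d_j: TransitionDipole,
                 prefactor: float = 580.0,
                 min_separation: float = 0.5) -> float:
    """Transition dipole coupling in cm^-1 (prefactor in cm^-1 A^3 D^-2)."""
    rvec = d_j.origin - d_i.origin
    r = np.linalg.norm(rvec)
    if r < min_separation:
        raise ValueError(f"dipole separation {r:.3f} A below the guard "
                         f"({min_separation} A)")
    n = rvec / r
    kappa = d_i.direction @ d_j.direction \
        - 3.0 * (d_i.direction @ n) * (d_j.direction @ n)
    return float(prefactor * d_i.magnitude * d_j.magnitude * kappa / r ** 3)


def transition_dipoles(structure: PeptideStructure,
                       displacement: float = 0.868,
                       tilt_deg: float = 20.0,
                       magnitude: float = 1.0) -> list:
    """Per-residue amide I transition dipoles.

    The dipole sits ``displacement`` A from C along the C=O bond and is
    tilted ``tilt_deg`` degrees from the C=O axis towards the amide
    nitrogen of the following residue (the peptide-bond partner); the
    terminal carbonyl, which has no partner nitrogen, keeps the C=O
    direction.
    """
    C, O, N = structure.atoms["C"], structure.atoms["O"], structure.atoms["N"]
    n_res = structure.n_residues
    tilt = np.deg2rad(tilt_deg)
    dipoles = []
    for i in range(n_res):
        u = O[i] - C[i]
        u = u / np.linalg.norm(u)
        origin = C[i] + displacement * u
        if i + 1 < n_res:
            w = N[i + 1] - C[i]
            w = w - (w @ u) * u
            wn = np.linalg.norm(w)
            direction = np.cos(tilt) * u + np.sin(tilt) * (w / wn) \
                if wn > 1e-9 else u
        else:
            direction = u
        dipoles.append(TransitionDipole(origin=origin, direction=direction,
                                        magnitude=magnitude))
    return dipoles


def build_hamiltonian(structure: PeptideStructure,
                      params: SpectralMapParams | None = None,
                      coupling_map: CouplingMap | None = None,
                      tdc_prefactor: float = 580.0,
                      dipole_displacement: float = 0.868,
                      dipole_tilt_deg: float = 20.0,
                      dipole_magnitude: float = 1.0) -> ExcitonHamiltonian:
    """Assemble the one-exciton Hamiltonian for a peptide structure.

    Diagonal: C=O-length site map (with proline shift).  First
    off-diagonal: dihedral-map coupling evaluated at the (phi, psi) of
    the residue linking the two carbonyls (residue i+1 for the pair
    (i, i+1)); its psi is recovered from the carbonyl-oxygen dihedral so
    the last residue needs no successor.  All other elements: TDC.
    """
    params = params or SpectralMapParams()
    coupling_map = coupling_map or synthetic_coupling_map()
    n = structure.n_residues
    H = np.diag(local_mode_frequencies(structure, params))
    dipoles = transition_dipoles(structure, dipole_displacement,
                                 dipole_tilt_deg, dipole_magnitude)
    N, CA, C, O = (structure.atoms[k] for k in ("N", "CA", "C", "O"))
    for i in range(n - 1):
        s = i + 1                                  # linking residue
        phi = measure_dihedral(C[s - 1], N[s], CA[s], C[s])
        # O sits at dihedral psi + 180, so psi = wrap(dihedral(N,CA,C,O) - 180)
        psi_from_o = measure_dihedral(N[s], CA[s], C[s], O[s])
        psi = (psi_from_o % 360.0) - 180.0
        beta = nn_coupling(phi, psi, coupling_map)
        H[i, i + 1] = H[i + 1, i] = beta
    for i in range(n):
        for j in range(i + 2, n):
            beta = tdc_coupling(dipoles[i], dipoles[j], tdc_prefactor)
            H[i, j] = H[j, i] = beta
    return ExcitonHamiltonian(matrix=H, dipoles=dipoles,
                              proline_flags=structure.proline_flags.copy())


# --------------------------------------------------------------------------
# Spectra
# --------------------------------------------------------------------------

def linear_spectrum(hamiltonian: ExcitonHamiltonian, grid: np.ndarray,
                    params: SpectralMapParams | None = None) -> LinearSpectrum:
    """Diagonalize and convolve with unit-area Lorentzians.

    Mode k at eigenvalue omega_k carries intensity |sum_i c_ik mu_i|^2
    (vector sum of the site dipoles weighted by the eigenvector).  The
    sum of stick intensities equals sum_ij mu_i . mu_j independent of
    the couplings (eigenbasis completeness).
    """
    params = params or SpectralMapParams()
    grid = np.asarray(grid, dtype=float)
    H = hamiltonian.matrix
    if not np.allclose(H, H.T, atol=1e-10):
        raise ValueError("Hamiltonian must be symmetric")
    evals, evecs = np.linalg.eigh(H)
    M = np.stack([d.vector for d in hamiltonian.dipoles], axis=1)  # (3, N)
    D = M @ evecs                                                  # (3, K)
    intensities = (D ** 2).sum(axis=0)
    gamma = params.lorentzian_hwhm
    lor = (gamma / np.pi) / ((grid[:, None] - evals[None, :]) ** 2 + gamma ** 2)
    absorbance = lor @ intensities
    return LinearSpectrum(grid=grid, absorbance=absorbance,
                          stick_frequencies=evals,
                          stick_intensities=intensities)


def ensemble_linear_spectrum(structures: list, grid: np.ndarray,
                             params: SpectralMapParams | None = None,
                             **hamiltonian_kwargs) -> LinearSpectrum:
    """Snapshot-averaged linear spectrum over an ensemble of structures."""
    if not structures:
        raise ValueError("no structures supplied")
    spectra = [linear_spectrum(build_hamiltonian(s, params, **hamiltonian_kwargs),
                               grid, params) for s in structures]
    absorbance = np.mean([s.absorbance for s in spectra], axis=0)
    return LinearSpectrum(
        grid=np.asarray(grid, dtype=float), absorbance=absorbance,
        stick_frequencies=np.concatenate([s.stick_frequencies for s in spectra]),
        stick_intensities=np.concatenate([s.stick_intensities for s in spectra])
        / len(spectra))
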