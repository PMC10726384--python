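"""Exciton Hamiltonian assembly, couplings and linear spectra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import condensir as cn
from condensir.excitons import synthetic_coupling_map
from condensir.synthetic import measure_dihedral


class TestLocalModes:
    def test_reference_length_gives_gas_phase_frequency(self):
        s = cn.gen_peptide_chain(cn.PeptideSpec(n_residues=1, co_lengths=1.229))
        assert cn.local_mode_frequencies(s)[0] == pytest.approx(1655.0)

    def test_elongation_red_shifts_linearly(self):
        s = cn.gen_peptide_chain(cn.PeptideSpec(n_residues=1, co_lengths=1.239))
        assert cn.local_mode_frequencies(s)[0] == pytest.approx(1651.0, abs=1e-9)

    def test_residue_preceding_proline_shifted(self):
        s = cn.gen_peptide_chain(cn.PeptideSpec(
            n_residues=2, co_lengths=1.229, proline_flags=[False, True]))
        freqs = cn.local_mode_frequencies(s)
        assert freqs[0] == pytest.approx(1655.0 - 19.0)
        assert freqs[1] == pytest.approx(1655.0)


class TestCouplingMap:
    def test_exact_at_grid_nodes(self):
        m = synthetic_coupling_map()
        i, j = 5, 9
        assert m(m.phi_nodes[i], m.psi_nodes[j]) == pytest.approx(
            m.values[i, j], abs=1e-12)

    def test_cell_center_is_corner_mean(self):
        m = synthetic_coupling_map()
        phi = 0.5 * (m.phi_nodes[3] + m.phi_nodes[4])
        psi = 0.5 * (m.psi_nodes[7] + m.psi_nodes[8])
        corners = [m.values[3, 7], m.values[4, 7], m.values[3, 8], m.values[4, 8]]
        assert m(phi, psi) == pytest.approx(np.mean(corners), abs=1e-12)

    def test_periodic_at_180(self):
        m = synthetic_coupling_map()
        assert m(180.0, 30.0) == pytest.approx(m(-180.0, 30.0), abs=1e-12)
        assert m(10.0, 180.0) == pytest.approx(m(10.0, -180.0), abs=1e-12)

    def test_file_round_trip(self, tmp_path):
        m = synthetic_coupling_map()
        path = tmp_path / "map.dat"
        m.to_file(path)
        m2 = cn.CouplingMap.from_file(path)
        assert np.allclose(m.values, m2.values, atol=1e-6)

    def test_malformed_file_rejected(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("1 2\n3 4\n")
        with pytest.raises(ValueError, match="malformed|columns"):
            cn.CouplingMap.from_file(path)


class TestTDC:
    def make(self, origin, direction, mag=1.0):
        d = np.asarray(direction, float)
        return cn.TransitionDipole(origin=np.asarray(origin, float),
                                   direction=d / np.linalg.norm(d),
                                   magnitude=mag)

    def test_head_to_tail_orientation_factor(self):
        a = self.make([0, 0, 0], [1, 0, 0])
        b = self.make([5, 0, 0], [1, 0, 0])
        beta = cn.tdc_coupling(a, b, prefactor=580.0)
        assert beta == pytest.approx(580.0 * -2.0 / 125.0)

    def test_side_by_side_orientation_factor(self):
        a = self.make([0, 0, 0], [0, 0, 1])
        b = self.make([5, 0, 0], [0, 0, 1])
        beta = cn.tdc_coupling(a, b, prefactor=580.0)
        assert beta == pytest.approx(580.0 * 1.0 / 125.0)

    def test_inverse_cube_distance_scaling(self):
        a = self.make([0, 0, 0], [0, 1, 0])
        near = cn.tdc_coupling(a, self.make([4, 0, 0], [0, 1, 0]))
        far = cn.tdc_coupling(a, self.make([8, 0, 0], [0, 1, 0]))
        assert far == pytest.approx(near / 8.0)

    def test_separation_guard(self):
        a = self.make([0, 0, 0], [1, 0, 0])
        with pytest.raises(ValueError, match="separation"):
            cn.tdc_coupling(a, self.make([0.1, 0, 0], [1, 0, 0]))


class TestHamiltonian:
    def test_single_residue_is_scalar(self):
        s = cn.gen_peptide_chain(cn.PeptideSpec(n_residues=1))
        H = cn.build_hamiltonian(s)
        assert H.matrix.shape == (1, 1)
        assert H.matrix[0, 0] == pytest.approx(1655.0)

    def test_dimer_off_diagonal_is_map_coupling(self):
        dihedrals = np.array([[0.0, -60.0], [-75.0, 140.0]])
        s = cn.gen_peptide_chain(cn.PeptideSpec(n_residues=2,
                                                dihedrals=dihedrals))
        m = synthetic_coupling_map()
        H = cn.build_hamiltonian(s, coupling_map=m)
        # linking residue is residue 1: its phi/psi as constructed
        assert H.matrix[0, 1] == pytest.approx(m(-75.0, 140.0), abs=1e-6)

    def test_long_range_elements_match_independent_tdc(self):
        s = cn.gen_peptide_chain(cn.PeptideSpec(n_residues=4))
        H = cn.build_hamiltonian(s)
        dipoles = cn.transition_dipoles(s)
        for i, j in [(0, 2), (0, 3), (1, 3)]:
            assert H.matrix[i, j] == pytest.approx(
                cn.tdc_coupling(dipoles[i], dipoles[j]), abs=1e-12)

    def test_symmetry(self, helix):
        H = cn.build_hamiltonian(helix)
        assert np.allclose(H.matrix, H.matrix.T, atol=1e-12)


class TestLinearSpectrum:
    grid = np.arange(1500.0, 1800.0, 0.25)

    def test_single_oscillator_lorentzian_width(self):
        s = cn.gen_peptide_chain(cn.PeptideSpec(n_residues=1))
        spec = cn.linear_spectrum(cn.build_hamiltonian(s), self.grid)
        peak = spec.absorbance.max()
        centre = self.grid[spec.absorbance.argmax()]
        assert centre == pytest.approx(1655.0, abs=0.3)
        half = np.flatnonzero(spec.absorbance >= 0.5 * peak)
        fwhm = self.grid[half[-1]] - self.grid[half[0]]
        assert fwhm == pytest.approx(12.0, abs=0.5)   # HWHM 6 -> FWHM 12

    def test_degenerate_dimer_splitting_and_intensities(self):
        omega, beta = 1650.0, 8.0
        dip = cn.TransitionDipole(origin=np.zeros(3),
                                  direction=np.array([1.0, 0, 0]))
        dip2 = cn.TransitionDipole(origin=np.array([4.0, 0, 0]),
                                   direction=np.array([1.0, 0, 0]))
        H = cn.ExcitonHamiltonian(
            matrix=np.array([[omega, beta], [beta, omega]]),
            dipoles=[dip, dip2])
        spec = cn.linear_spectrum(H, self.grid)
        assert np.allclose(sorted(spec.stick_frequencies),
                           [omega - beta, omega + beta])
        # in-phase combination carries all the intensity for parallel dipoles
        intens = spec.stick_intensities[np.argsort(spec.stick_frequencies)]
        assert intens[1] == pytest.approx(2.0, abs=1e-10)
        assert intens[0] == pytest.approx(0.0, abs=1e-10)

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_intensity_sum_rule_and_gershgorin(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        A = rng.normal(0, 5, (n, n))
        H_mat = np.diag(1640 + rng.normal(0, 10, n)) + (A + A.T) / 2 \
            - np.diag(np.diag(A))
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        mags = rng.uniform(0.5, 1.5, n)
        dipoles = [cn.TransitionDipole(origin=rng.normal(size=3) * 10,
                                       direction=dirs[i], magnitude=mags[i])
                   for i in range(n)]
        spec = cn.linear_spectrum(
            cn.ExcitonHamiltonian(matrix=H_mat, dipoles=dipoles),
            np.arange(1500.0, 1800.0, 1.0))
        # completeness: total stick intensity equals sum_i |mu_i|^2
        assert spec.stick_intensities.sum() == pytest.approx(
            (mags ** 2).sum(), rel=1e-10)
        # Gershgorin: eigenvalues within diagonal range +- max row sum
        radius = np.abs(H_mat - np.diag(np.diag(H_mat))).sum(axis=1).max()
        diag = np.diag(H_mat)
        assert spec.stick_frequencies.min() >= diag.min() - radius - 1e-9
        assert spec.stick_frequencies.max() <= diag.max() + radius + 1e-9

    def test_non_symmetric_hamiltonian_rejected(self):
        with pytest.raises(ValueError):
            cn.ExcitonHamiltonian(matrix=np.array([[1.0, 2.0], [0.0, 1.0]]),
                                  dipoles=[])

    def test_co_elongation_red_shifts_and_broadens(self, helix):
        """Stronger H-bonding (longer C=O) shifts the band red and widens it."""
        grid = np.arange(1580.0, 1720.0, 0.25)
        base = cn.linear_spectrum(cn.build_hamiltonian(helix), grid)
        lengths = np.full(12, 1.229)
        lengths[::3] += 0.02                    # elongate a third of the bonds
        stretched_structure = cn.gen_peptide_chain(cn.PeptideSpec(
            n_residues=12, dihedrals=np.tile([-57.0, -47.0], (12, 1)),
            co_lengths=lengths))
        stretched = cn.linear_spectrum(
            cn.build_hamiltonian(stretched_structure), grid)
        assert stretched.first_moment() < base.first_moment()
        assert stretched.second_moment() > base.second_moment()
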