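"""H-bond detection geometry, survival ACF and constrained lifetime fits."""

import numpy as np
import pytest

import condensir as cn
from condensir.frames import Frame


def water_frame(amide_o, waters, box=None, periodic=False):
    """Frame with one amide O and a list of (O, H1, H2) water triples."""
    coords = [amide_o]
    chain_ids = [0]
    resids = [0]
    roles = ["amide_O"]
    for j, (ow, h1, h2) in enumerate(waters):
        coords += [ow, h1, h2]
        chain_ids += [-1, -1, -1]
        resids += [100 + j] * 3
        roles += ["water_O", "water_H", "water_H"]
    return Frame(coords=np.array(coords, dtype=float),
                 chain_ids=np.array(chain_ids), resids=np.array(resids),
                 roles=np.array(roles, dtype="U8"), box=box, periodic=periodic)


class TestDetection:
    def test_linear_geometry_is_bonded(self):
        # O_amide at origin, H at 2.0 A, water O collinear beyond it
        frame = water_frame([0, 0, 0],
                            [([2.95, 0, 0], [2.0, 0, 0], [3.5, 0.9, 0])])
        assert cn.detect_hbonds(frame) == {((0, 0), 100)}

    def test_strict_distance_boundary(self):
        frame = water_frame([0, 0, 0],
                            [([3.41, 0, 0], [2.46, 0, 0], [4.0, 0.9, 0])])
        assert cn.detect_hbonds(frame) == set()
        frame = water_frame([0, 0, 0],
                            [([3.40, 0, 0], [2.45, 0, 0], [4.0, 0.9, 0])])
        assert cn.detect_hbonds(frame) == {((0, 0), 100)}

    def test_bent_geometry_rejected_by_angle(self):
        # H equidistant but the O_w-H...O_amide angle is ~90 degrees
        frame = water_frame([0, 0, 0],
                            [([2.0, 0.96, 0], [2.0, 0, 0], [2.5, 1.5, 0])])
        assert cn.detect_hbonds(frame) == set()

    def test_no_water_returns_empty(self):
        frame = water_frame([0, 0, 0], [])
        assert cn.detect_hbonds(frame) == set()

    def test_missing_amide_roles_rejected(self):
        frame = Frame(coords=np.zeros((1, 3)), chain_ids=[0], resids=[0],
                      roles=np.array(["other"]))
        with pytest.raises(ValueError, match="amide_O"):
            cn.detect_hbonds(frame)

    def test_minimum_image_bond_across_boundary(self):
        box = np.array([20.0, 20.0, 20.0])
        frame = water_frame([0.5, 10, 10],
                            [([17.6, 10, 10], [18.6, 10, 10], [17.0, 10.9, 10])],
                            box=box, periodic=True)
        # O_amide...H = 1.9 A through the boundary, collinear
        assert cn.detect_hbonds(frame) == {((0, 0), 100)}


def brute_force_acf(occ, dt, max_lag, stride):
    n_lags = int(round(max_lag / dt)) + 1
    c = np.empty(n_lags)
    for L in range(n_lags):
        num = den = 0.0
        for t0 in range(0, occ.shape[1] - L, stride):
            num += float((occ[:, t0] & occ[:, t0 + L]).sum())
            den += float(occ[:, t0].sum())
        c[L] = num / den
    return c


class TestSurvivalACF:
    def test_constant_occupancy_gives_unity(self):
        series = cn.HBondSeries(occupancy=np.ones((4, 50), dtype=bool), dt=0.1)
        acf = cn.survival_acf(series, max_lag=2.0)
        assert np.allclose(acf.c, 1.0)

    def test_normalized_at_zero_lag(self):
        rng = np.random.default_rng(1)
        series = cn.HBondSeries(occupancy=rng.random((6, 80)) < 0.4, dt=0.05)
        acf = cn.survival_acf(series, max_lag=1.0)
        assert acf.c[0] == 1.0

    @pytest.mark.parametrize("stride", [1, 3])
    def test_matches_brute_force_double_loop(self, stride):
        rng = np.random.default_rng(5)
        occ = rng.random((7, 60)) < 0.5
        series = cn.HBondSeries(occupancy=occ, dt=0.2)
        acf = cn.survival_acf(series, max_lag=4.0, origin_stride=stride)
        expected = brute_force_acf(occ, 0.2, 4.0, stride)
        assert np.allclose(acf.c, expected, atol=1e-12)

    def test_telegraph_acf_analytic(self):
        params = cn.TelegraphParams(n_pairs=1500, k_on=1.0, k_off=1.0,
                                    dt=0.01, n_steps=10_000, seed=13)
        series = cn.gen_telegraph_occupancy(params)
        acf = cn.survival_acf(series, max_lag=2.0)
        expected = 0.5 + 0.5 * np.exp(-2.0 * acf.lags)
        assert np.allclose(acf.c, expected, rtol=0.05)

    def test_continuous_never_exceeds_intermittent(self):
        rng = np.random.default_rng(2)
        occ = rng.random((10, 120)) < 0.6
        series = cn.HBondSeries(occupancy=occ, dt=0.1)
        inter = cn.survival_acf(series, max_lag=3.0)
        cont = cn.survival_acf(series, max_lag=3.0, continuous=True)
        assert np.all(cont.c <= inter.c + 1e-12)

    def test_all_zero_occupancy_rejected(self):
        series = cn.HBondSeries(occupancy=np.zeros((3, 40), dtype=bool), dt=0.1)
        with pytest.raises(ValueError, match="zero"):
            cn.survival_acf(series, max_lag=1.0)

    def test_max_lag_bounded_by_half_length(self):
        series = cn.HBondSeries(occupancy=np.ones((2, 50), dtype=bool), dt=0.1)
        with pytest.raises(ValueError, match="half"):
            cn.survival_acf(series, max_lag=3.0)


class TestBaseline:
    def test_decaying_acf_unchanged(self):
        lags = np.arange(0, 10, 0.1)
        acf = cn.ACFResult(lags=lags, c=np.exp(-2 * lags),
                           n_origins=np.ones(len(lags), dtype=int))
        cleaned = cn.remove_baseline(acf)
        assert np.allclose(cleaned.c, acf.c, atol=1e-8)

    def test_telegraph_plateau_removed(self):
        lags = np.arange(0, 10, 0.05)
        acf = cn.ACFResult(lags=lags, c=0.5 + 0.5 * np.exp(-2 * lags),
                           n_origins=np.ones(len(lags), dtype=int))
        cleaned = cn.remove_baseline(acf)
        assert cleaned.baseline == pytest.approx(0.5, abs=1e-6)
        assert np.allclose(cleaned.c, np.exp(-2 * lags), atol=1e-5)

    def test_constant_acf_rejected(self):
        lags = np.arange(0, 5, 0.1)
        acf = cn.ACFResult(lags=lags, c=np.ones(len(lags)),
                           n_origins=np.ones(len(lags), dtype=int))
        with pytest.raises(ValueError, match="baseline"):
            cn.remove_baseline(acf)


def sample_triexp(amps, taus, t):
    return np.asarray(amps) @ np.exp(-np.outer(1.0 / np.asarray(taus), t))


class TestTriExpFit:
    lags = np.concatenate([np.arange(0.0, 1.0, 0.005),
                           np.arange(1.0, 30.0, 0.05)])

    def acf_of(self, amps, taus):
        return cn.ACFResult(lags=self.lags, c=sample_triexp(amps, taus, self.lags),
                            n_origins=np.ones(len(self.lags), dtype=int))

    def test_condensed_phase_parameters_recovered(self):
        amps = (0.41, 0.07, 0.52)
        taus = (7.5, 0.77, 0.05)
        fit = cn.fit_triexp(self.acf_of(amps, taus), fix_tau3=0.05)
        assert np.allclose(fit.amplitudes, amps, rtol=1e-4)
        assert np.allclose(fit.taus, taus, rtol=1e-4)

    def test_amplitudes_sum_to_one_exactly(self):
        fit = cn.fit_triexp(self.acf_of((0.5, 0.3, 0.2), (9.0, 1.1, 0.2)))
        assert fit.amplitudes.sum() == pytest.approx(1.0, abs=1e-15)
        assert np.all(fit.amplitudes >= 0)

    def test_noise_free_recovery_separated_components(self):
        amps = (0.5, 0.3, 0.2)
        taus = (10.0, 1.0, 0.1)
        fit = cn.fit_triexp(self.acf_of(amps, taus))
        assert np.allclose(fit.amplitudes, amps, rtol=0.02)
        assert np.allclose(fit.taus, taus, rtol=0.02)

    def test_single_exponential_mean_lifetime(self):
        acf = cn.ACFResult(lags=self.lags, c=np.exp(-self.lags / 2.0),
                           n_origins=np.ones(len(self.lags), dtype=int))
        fit = cn.fit_triexp(acf)
        # amplitude split among degenerate components is arbitrary, but
        # the integral of the fit must equal the integral of the input
        assert fit.mean_lifetime == pytest.approx(2.0, rel=0.01)

    def test_mean_lifetime_is_amplitude_weighted_sum(self):
        fit = cn.TriExpFit(amplitudes=(1.0, 0.0, 0.0), taus=(4.0, 1.0, 0.1))
        assert cn.mean_lifetime(fit) == pytest.approx(4.0)

    def test_invalid_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            cn.TriExpFit(amplitudes=(0.5, 0.2, 0.2), taus=(1.0, 1.0, 1.0))
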