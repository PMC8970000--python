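"""Forward models: couplings, RDCs, SAXS, chain dimensions, FRET, shifts."""
import numpy as np
import pytest
from scipy.integrate import quad

from rhcg import constants, growth, observables, synthetic
from rhcg.observables import (
    DistanceModel,
    alignment_tensor,
    dmax_hn,
    ensemble_rg,
    fit_saxs,
    fret_efficiency,
    hydrodynamic_radius,
    karplus_j3,
    radius_of_gyration,
    rdc_profile,
    rg_to_rh,
    rh_to_rg,
    saw_nu_distribution,
    saxs_debye,
    secondary_shifts,
)
from rhcg.struct import Structure


def _point_structure(coords, element="C"):
    n = len(coords)
    return Structure(
        np.arange(1, n + 1),
        np.full(n, "ALA"),
        np.array([f"C{i}" for i in range(n)], dtype="U4"),
        np.full(n, element),
        np.asarray(coords, dtype=float),
    )


class TestKarplus:
    def test_extrema_closed_forms(self):
        a, b, c = constants.KARPLUS_HNHA
        assert karplus_j3(60.0) == pytest.approx(a + b + c, abs=1e-12)
        assert karplus_j3(180.0) == pytest.approx(a / 4 - b / 2 + c, abs=1e-12)

    def test_pointwise_transcription_oracle(self):
        a, b, c = 7.0, -1.2, 0.5
        phis = np.linspace(-180, 180, 73)
        expected = [
            a * np.cos(np.radians(p - 60)) ** 2 + b * np.cos(np.radians(p - 60)) + c
            for p in phis
        ]
        assert np.allclose(karplus_j3(phis, (a, b, c)), expected, atol=1e-12)


class TestDmaxHN:
    def test_idealized_amide_bond_value(self):
        assert dmax_hn(1.04) == pytest.approx(21.7, rel=5e-3)

    def test_cubic_scaling(self):
        assert dmax_hn(2.08) == pytest.approx(dmax_hn(1.04) / 8, rel=1e-12)

    def test_r3_product_constant(self):
        rs = np.array([0.9, 1.04, 1.3, 2.0])
        prods = np.array([dmax_hn(r) * r**3 for r in rs])
        assert np.allclose(prods, prods[0], rtol=1e-12)

    def test_independent_constant_folding(self):
        # D = mu0 * gammaH * |gammaN| * h / (8 pi^3 r^3), folded from CODATA
        from scipy.constants import h, mu_0, physical_constants

        gamma_h = physical_constants["proton gyromag. ratio"][0]
        gamma_n = 2.71261804e7  # |gamma(15N)|, rad s^-1 T^-1
        r = 1.04e-10
        expected = mu_0 * gamma_h * gamma_n * h / (8 * np.pi**3 * r**3) / 1e3
        assert dmax_hn(1.04) == pytest.approx(expected, rel=2e-3)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            dmax_hn(0.0)


class TestAlignmentTensor:
    def test_spherical_shape_gives_zero(self):
        # octahedral vertices: isotropic gyration tensor
        pts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        s = alignment_tensor(_point_structure(pts))
        assert np.allclose(s, 0.0, atol=1e-12)

    def test_thin_rod_axial_symmetry(self):
        z = np.linspace(-10, 10, 30)
        eps = 1e-3
        pts = np.column_stack([eps * np.cos(13 * z), eps * np.sin(13 * z), z])
        s = alignment_tensor(_point_structure(pts), order_scale=1e-3)
        assert s[2, 2] == pytest.approx(1e-3, rel=1e-5)
        assert s[0, 0] == pytest.approx(-0.5e-3, rel=1e-4)
        assert s[1, 1] == pytest.approx(-0.5e-3, rel=1e-4)

    def test_traceless_symmetric_and_eigen_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(25, 3)) * np.array([3.0, 1.5, 0.5])
        st = _point_structure(pts)
        s = alignment_tensor(st, order_scale=2e-3)
        assert abs(np.trace(s)) < 1e-15
        assert np.allclose(s, s.T)
        centered = pts - pts.mean(0)
        t = centered.T @ centered / len(pts)
        expected_eigs = np.sort(
            2e-3 * 1.5 * (np.linalg.eigvalsh(t) - np.trace(t) / 3) / np.trace(t)
        )
        assert np.allclose(np.sort(np.linalg.eigvalsh(s)), expected_eigs, atol=1e-12)

    def test_collinear_geometry_rejected(self):
        pts = np.outer(np.arange(5), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            alignment_tensor(_point_structure(pts))


def _ensemble_from_structures(structs):
    coords = np.stack([s.coords for s in structs])
    return growth.Ensemble(
        template=structs[0],
        coords=coords,
        fragment_indices=np.zeros((len(structs), 1), dtype=int),
        log_p_bias=np.zeros(len(structs)),
    )


class TestRdcProfile:
    def _chain(self, seed, n=8):
        rng = np.random.default_rng(seed)
        dihs = [
            (rng.uniform(-150, -60), rng.uniform(100, 160), 180.0) for _ in range(n)
        ]
        return synthetic.build_backbone("AKVLSDKV"[:n], dihs)

    def test_isotropic_tensor_gives_zero(self):
        ens = _ensemble_from_structures([self._chain(0)])
        prof = rdc_profile(ens, [3, 4, 5], tensor_backend=lambda s: np.zeros((3, 3)))
        assert np.allclose(prof.values, 0.0)

    def test_parallel_vectors_reach_axial_order(self):
        ens = _ensemble_from_structures([self._chain(1)])
        scale = 1e-3
        tensor = np.diag([-0.5, -0.5, 1.0]) * scale

        class _AllZ:
            def __call__(self, s):
                return tensor

        prof = rdc_profile(ens, [3], tensor_backend=_AllZ())
        # oracle: D = Dmax * v^T S v for the actual amide vector
        from rhcg.observables import amide_h_vectors

        v = amide_h_vectors(ens.template, [3])[0]
        expected = dmax_hn() * 1e3 * v @ tensor @ v
        assert prof.values[0] == pytest.approx(expected, rel=1e-10)
        # a vector along z would reach the full axial order parameter
        vz = np.array([0.0, 0.0, 1.0])
        assert vz @ tensor @ vz == pytest.approx(scale)

    def test_weighted_two_chain_mean(self):
        chains = [self._chain(2), self._chain(3)]
        ens = _ensemble_from_structures(chains)
        w = np.array([0.3, 0.7])
        prof = rdc_profile(ens, [3, 4], weights=w)
        p0 = rdc_profile(_ensemble_from_structures(chains[:1]), [3, 4])
        p1 = rdc_profile(_ensemble_from_structures(chains[1:]), [3, 4])
        assert np.allclose(prof.values, 0.3 * p0.values + 0.7 * p1.values, atol=1e-12)

    def test_mirror_inversion_invariance(self):
        """P2 is even: inverting the ensemble through the origin leaves the
        RDC profile unchanged."""
        chain = self._chain(4)
        mirrored = chain.with_coords(-chain.coords)
        p = rdc_profile(_ensemble_from_structures([chain]), [3, 4, 5])
        pm = rdc_profile(_ensemble_from_structures([mirrored]), [3, 4, 5])
        assert np.allclose(p.values, pm.values, atol=1e-9)

    def test_proline_raises(self):
        fd_seq = "AKPLS"
        dihs = [(-70, 140, 180)] * 5
        s = synthetic.build_backbone(fd_seq, dihs)
        ens = _ensemble_from_structures([s])
        with pytest.raises(ValueError, match="residues \\[3\\]"):
            rdc_profile(ens, [3])


class TestSaxs:
    def test_single_scatterer_flat(self):
        prof = saxs_debye(_point_structure([[0, 0, 0]]), np.linspace(0, 0.5, 20),
                          form_factors={"C": 3.0})
        assert np.allclose(prof.intensity, 9.0)

    def test_two_scatterer_interference(self):
        d = 5.0
        q = np.linspace(0.01, 0.5, 40)
        prof = saxs_debye(
            _point_structure([[0, 0, 0], [0, 0, d]]), q, form_factors={"C": 1.0}
        )
        expected = 2 * (1 + np.sin(q * d) / (q * d))
        assert np.allclose(prof.intensity, expected, atol=1e-10)

    def test_forward_intensity_at_zero(self):
        rng = np.random.default_rng(0)
        st = _point_structure(rng.normal(size=(12, 3)) * 3)
        prof = saxs_debye(st, np.array([0.0]))
        f = 6.0 * 12
        assert prof.intensity[0] == pytest.approx(f**2, rel=1e-12)

    def test_guinier_rg_matches_geometric(self):
        rng = np.random.default_rng(5)
        st = _point_structure(rng.normal(size=(40, 3)) * np.array([4, 3, 2]))
        rg = radius_of_gyration(st)
        q = np.linspace(0.01, 0.9 / rg, 25)
        prof = saxs_debye(st, q, form_factors={"C": 1.0})
        slope = np.polyfit(q**2, np.log(prof.intensity), 1)[0]
        rg_guinier = np.sqrt(-3 * slope)
        assert rg_guinier == pytest.approx(rg, rel=0.02)

    def test_ensemble_profile_is_weighted_mean(self):
        rng = np.random.default_rng(6)
        structs = [_point_structure(rng.normal(size=(8, 3)) * 3) for _ in range(2)]
        ens = _ensemble_from_structures(structs)
        q = np.linspace(0.0, 0.4, 10)
        w = np.array([0.25, 0.75])
        prof = saxs_debye(ens, q, weights=w)
        p0 = saxs_debye(structs[0], q)
        p1 = saxs_debye(structs[1], q)
        assert np.allclose(prof.intensity, 0.25 * p0.intensity + 0.75 * p1.intensity)


class TestFitSaxs:
    def _profile(self):
        rng = np.random.default_rng(7)
        st = _point_structure(rng.normal(size=(30, 3)) * 8)
        q = np.linspace(0.002, 0.3, 120)
        return saxs_debye(st, q)

    def test_exact_scale_background_recovery(self):
        prof = self._profile()
        a, b = 2.5e-3, 7.0
        i_exp = a * prof.intensity + b
        fit = fit_saxs(prof, prof.q, i_exp)
        assert fit["a"] == pytest.approx(a, rel=1e-8)
        assert fit["b"] == pytest.approx(b, rel=1e-8)

    def test_zero_background_recovered(self):
        prof = self._profile()
        i_exp = 1.7 * prof.intensity
        fit = fit_saxs(prof, prof.q, i_exp)
        assert abs(fit["b"]) < 1e-8 * i_exp.max()

    def test_aggregate_recovery(self):
        prof = self._profile()
        a, b, c, ra = 1.0e-3, 2.0, 50.0, 234.0
        i_exp = a * prof.intensity + b + c * np.exp(-prof.q**2 * ra**2 / 3)
        # aggregate term is negligible above q_split = 0.012 with R_a = 234
        fit = fit_saxs(prof, prof.q, i_exp, q_split=0.012)
        assert fit["c"] == pytest.approx(c, rel=0.01)
        assert fit["R_a"] == pytest.approx(ra, rel=0.01)

    def test_too_few_points_raises(self):
        prof = self._profile()
        with pytest.raises(ValueError, match="q_split"):
            fit_saxs(prof, np.array([0.2, 0.3]), np.array([1.0, 1.0]), q_split=0.25)


class TestChainDimensions:
    def test_single_atom_zero(self):
        assert radius_of_gyration(_point_structure([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_point_closed_form(self):
        d = 6.0
        st = _point_structure([[0, 0, 0], [0, 0, d]])
        assert radius_of_gyration(st) == pytest.approx(d / 2, abs=1e-12)

    def test_direct_sum_oracle(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(17, 3)) * 4
        st = _point_structure(pts)
        com = pts.mean(0)
        expected = np.sqrt(np.mean(np.sum((pts - com) ** 2, axis=1)))
        assert radius_of_gyration(st) == pytest.approx(expected, abs=1e-10)

    def test_ensemble_rms_combination(self):
        structs = [
            _point_structure([[0, 0, 0], [0, 0, 4.0]]),
            _point_structure([[0, 0, 0], [0, 0, 8.0]]),
        ]
        ens = _ensemble_from_structures(structs)
        w = np.array([0.5, 0.5])
        assert ensemble_rg(ens, weights=w) == pytest.approx(
            np.sqrt(0.5 * 2.0**2 + 0.5 * 4.0**2), abs=1e-12
        )


class TestHydrodynamicRadius:
    def test_monotone_in_rg(self):
        rgs = np.linspace(15, 60, 20)
        rhs = [rg_to_rh(rg, 130) for rg in rgs]
        assert np.all(np.diff(rhs) > 0)

    def test_numerical_inverse_roundtrip(self):
        for rg in (20.0, 39.0, 55.0):
            rh = rg_to_rh(rg, 130)
            assert rh_to_rg(rh, 130) == pytest.approx(rg, abs=1e-6)

    def test_two_chain_harmonic_combination(self):
        structs = [
            _point_structure([[0, 0, 0], [0, 0, 30.0]]),
            _point_structure([[0, 0, 0], [0, 0, 50.0]]),
        ]
        ens = _ensemble_from_structures(structs)
        w = np.array([0.4, 0.6])
        rh = hydrodynamic_radius(ens, weights=w, n_residues=50)
        rh0 = hydrodynamic_radius(structs[0], n_residues=50)
        rh1 = hydrodynamic_radius(structs[1], n_residues=50)
        assert rh == pytest.approx(1.0 / (0.4 / rh0 + 0.6 / rh1), abs=1e-10)

    def test_kirkwood_double_sum(self):
        pts = np.array([[0, 0, 0], [3.0, 0, 0], [0, 4.0, 0]])
        st = _point_structure(pts)
        inv = np.mean([1 / 3.0, 1 / 5.0, 1 / 4.0])
        assert hydrodynamic_radius(st, parameterization="kirkwood") == pytest.approx(
            1.0 / inv, abs=1e-12
        )


class TestSawNu:
    def test_mean_matches_request(self):
        for nu in (0.4, 0.5, 0.56, 0.6):
            model = saw_nu_distribution(nu, mean_distance=55.0)
            val, _ = quad(lambda r: r * model.pdf(r), 0, np.inf, limit=200)
            assert val == pytest.approx(55.0, abs=1e-6)

    def test_density_normalized(self):
        model = saw_nu_distribution(0.56, 60.0)
        val, _ = quad(model.pdf, 0, np.inf, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_nu_sanity_band_enforced(self):
        with pytest.raises(ValueError):
            saw_nu_distribution(0.2, 50.0)

    def test_forster_midpoint_and_limits(self):
        assert fret_efficiency(np.array([54.0]), r0=54.0) == pytest.approx(0.5)
        assert fret_efficiency(np.array([1e-3]), r0=54.0) == pytest.approx(1.0, abs=1e-9)
        assert fret_efficiency(np.array([1e5]), r0=54.0) == pytest.approx(0.0, abs=1e-12)

    def test_model_efficiency_matches_quadrature(self):
        model = saw_nu_distribution(0.56, 60.0, r0_forster=54.0)
        e = fret_efficiency(model, r0=54.0)
        direct, _ = quad(
            lambda r: model.pdf(r) / (1 + (r / 54.0) ** 6), 0, np.inf, limit=200
        )
        assert e == pytest.approx(direct, abs=1e-9)
        assert 0.0 < e < 1.0


class TestSecondaryShifts:
    def test_predictor_equals_coil_gives_zero(self):
        coil = {1: 55.0, 2: 57.0}
        assert secondary_shifts(dict(coil), coil) == {1: 0.0, 2: 0.0}

    def test_constant_offset(self):
        coil = {1: 55.0, 2: 57.0}
        pred = {r: v + 1.0 for r, v in coil.items()}
        out = secondary_shifts(pred, coil)
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_residue_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            secondary_shifts({1: 55.0}, {2: 55.0})

    def test_weighted_ensemble_mean(self, toy_libraries):
        from rhcg.observables import ensemble_predicted_shifts

        ens = growth.grow(toy_libraries, n_chains=2, pool_size=10, seed=44)
        predictor = synthetic.SyntheticShiftPredictor()
        w = np.array([0.2, 0.8])
        out = ensemble_predicted_shifts(ens, [3, 5], predictor, weights=w)
        structs = list(ens.structures())
        for r in (3, 5):
            expected = 0.2 * predictor(structs[0], r) + 0.8 * predictor(structs[1], r)
            assert out[r] == pytest.approx(expected, abs=1e-12)


class TestLinearityInWeights:
    def test_doubling_one_weight_follows_weighted_sum(self):
        rng = np.random.default_rng(9)
        structs = [_point_structure(rng.normal(size=(6, 3)) * 3) for _ in range(3)]
        ens = _ensemble_from_structures(structs)
        q = np.linspace(0, 0.3, 5)
        per_chain = np.stack([saxs_debye(s, q).intensity for s in structs])
        w = np.array([0.2, 0.3, 0.5])
        w2 = np.array([0.4, 0.3, 0.5])
        w2 /= w2.sum()
        for weights in (w, w2):
            prof = saxs_debye(ens, q, weights=weights)
            assert np.allclose(prof.intensity, weights @ per_chain, atol=1e-10)
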