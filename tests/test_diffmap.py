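import gemmi
import numpy as np
import pytest

from photoxtal import diffmap
from photoxtal.structio import Atom, AtomicModel, DensityMap, ReflectionSet, UnitCell


def _model(cell, positions, element="C", b=0.0):
    atoms = [Atom(id=f"{element}{i + 1}", element=element, chain="A",
                  residue_name="LIG", residue_number=1,
                  frac=np.asarray(p, float), occupancy=1.0, b_iso=b)
             for i, p in enumerate(positions)]
    return AtomicModel(cell=cell, atoms=atoms)


class TestStructureFactors:
    def test_single_atom_at_origin_gives_form_factor_and_zero_phase(self, toy_cell):
        m = _model(toy_cell, [(0.0, 0.0, 0.0)])
        rs = diffmap.calc_structure_factors(m, 2.0)
        stol2 = 1.0 / (4.0 * rs.d**2)
        f_c = np.array([gemmi.Element("C").it92.calculate_sf(s) for s in stol2])
        assert np.allclose(rs.f, f_c, rtol=1e-10)
        # phases 0 mod 360
        ph = np.radians(rs.phase)
        assert np.abs(np.sin(ph)).max() < 1e-10
        assert np.cos(ph).min() > 0.99

    def test_halved_cell_systematic_absence(self, toy_cell):
        m = _model(toy_cell, [(0.0, 0.1, 0.2), (0.5, 0.1, 0.2)])
        rs = diffmap.calc_structure_factors(m, 2.0)
        odd_h = rs.hkl[:, 0] % 2 == 1
        axial = (rs.hkl[:, 1] == 0) & (rs.hkl[:, 2] == 0)
        assert np.abs(rs.f[odd_h & axial]).max() < 1e-10

    def test_fft_agrees_with_direct_summation(self, toy_cell, rng):
        m = _model(toy_cell, rng.random((30, 3)), b=12.0)
        direct = diffmap.calc_structure_factors(m, 1.3, method="direct")
        fft = diffmap.calc_structure_factors(m, 1.3, method="fft")
        assert np.array_equal(direct.hkl, fft.hkl)
        # 0.1% of the rms amplitude: gridding error is absolute, so a purely
        # relative bound is meaningless for near-extinct reflections
        num = np.abs(direct.complex_f - fft.complex_f)
        assert num.max() < 1e-3 * np.sqrt(np.mean(direct.f**2))

    def test_unknown_element_named_in_error(self, toy_cell):
        m = _model(toy_cell, [(0.0, 0.0, 0.0)])
        m.atoms[0].element = "Zz"  # bypass constructor validation
        with pytest.raises(ValueError, match="Zz"):
            diffmap.calc_structure_factors_at(m, np.array([[1, 0, 0]]))


class TestScaling:
    def test_identity_scaling(self, dark_fcalc):
        scaled, res = diffmap.scale_to_reference(dark_fcalc, dark_fcalc)
        assert res.k == pytest.approx(1.0, abs=1e-8)
        assert res.b == pytest.approx(0.0, abs=1e-6)
        assert res.residual < 1e-12

    def test_linear_case(self, dark_fcalc):
        doubled = ReflectionSet(cell=dark_fcalc.cell, hkl=dark_fcalc.hkl,
                                f=2.0 * dark_fcalc.f, label="x2")
        _, res = diffmap.scale_to_reference(dark_fcalc, doubled)
        assert res.k == pytest.approx(0.5, abs=1e-8)
        assert res.b == pytest.approx(0.0, abs=1e-6)

    def test_recovers_k_and_b_under_noise(self, dark_fcalc, rng):
        k_true, b_true = 0.8, 5.0
        stol2 = 1.0 / (4.0 * dark_fcalc.d**2)
        f = dark_fcalc.f / (k_true * np.exp(-b_true * stol2))
        f *= 1.0 + 0.01 * rng.standard_normal(len(f))
        other = ReflectionSet(cell=dark_fcalc.cell, hkl=dark_fcalc.hkl,
                              f=np.abs(f), label="distorted")
        _, res = diffmap.scale_to_reference(dark_fcalc, other)
        assert res.k == pytest.approx(k_true, rel=0.02)
        assert res.b == pytest.approx(b_true, abs=0.5)

    def test_too_few_common_reflections(self, toy_cell):
        small = ReflectionSet(cell=toy_cell, hkl=np.array([[1, 0, 0]]),
                              f=np.array([1.0]))
        with pytest.raises(ValueError, match="common"):
            diffmap.scale_to_reference(small, small)


def _diffset(cell, df, sig, n=None):
    n = n or len(df)
    hkl = np.column_stack([np.arange(1, n + 1), np.zeros(n, int), np.zeros(n, int)])
    return diffmap.DifferenceSet(cell=cell, hkl=hkl, df=np.asarray(df, float),
                                 sig_df=np.asarray(sig, float),
                                 phase_dark=np.zeros(n))


class TestQWeights:
    def test_at_bin_means_weight_is_one_third(self, toy_cell):
        d = _diffset(toy_cell, [2.0] * 20, [0.5] * 20)
        w = diffmap.q_weights(d, n_bins=1).w
        assert np.allclose(w, 1.0 / 3.0, atol=1e-12)

    def test_weight_vanishes_monotonically_with_sigma(self, toy_cell):
        sigmas = [1.0, 5.0, 25.0, 125.0]
        prev = 1.0
        for s in sigmas:
            d = _diffset(toy_cell, [2.0] * 10 + [2.0], [0.5] * 10 + [s])
            w_last = diffmap.q_weights(d, n_bins=1).w[-1]
            assert w_last < prev
            prev = w_last
        # the bin mean includes the outlier, so the limit is 1/(n+1), not 0
        assert prev < 0.1

    def test_matches_independent_reimplementation(self, toy_cell, rng):
        n = 1000
        hkl = np.array(sorted({tuple(h) for h in
                               rng.integers(-9, 10, (3000, 3))} - {(0, 0, 0)}))[:n]
        df = rng.standard_normal(len(hkl)) * 3.0
        sig = np.abs(rng.standard_normal(len(hkl))) + 0.1
        d = diffmap.DifferenceSet(cell=toy_cell, hkl=hkl, df=df, sig_df=sig,
                                  phase_dark=np.zeros(len(hkl)))
        out = diffmap.q_weights(d, n_bins=10)
        # independent one-line evaluation per resolution bin
        order = np.argsort(d.d)[::-1]
        bins = np.array_split(order, 10)
        expect = np.empty(len(hkl))
        for b in bins:
            expect[b] = 1.0 / (1.0 + sig[b]**2 / np.mean(sig[b]**2)
                               + df[b]**2 / np.mean(df[b]**2))
        assert np.abs(out.w - expect).max() < 1e-12


class TestSynthesis:
    def test_zero_amplitudes_give_zero_map(self, toy_cell):
        rs = ReflectionSet(cell=toy_cell, hkl=np.array([[1, 0, 0], [0, 1, 0]]),
                           f=np.zeros(2), phase=np.zeros(2))
        m = diffmap.synthesize_map(rs)
        assert np.abs(m.values).max() == 0.0

    def test_single_reflection_is_cosine_with_maximum_at_origin(self, toy_cell):
        rs = ReflectionSet(cell=toy_cell, hkl=np.array([[1, 0, 0]]),
                           f=np.array([5.0]), phase=np.array([0.0]))
        m = diffmap.synthesize_map(rs, grid_factor=3.0)
        na = m.grid[0]
        profile = m.values[:, 0, 0]
        expect = 2 * 5.0 / toy_cell.volume * np.cos(2 * np.pi * np.arange(na) / na)
        assert np.allclose(profile, expect, atol=1e-12)
        assert np.argmax(profile) == 0
        # constant along the other axes
        assert np.ptp(m.values, axis=1).max() < 1e-12

    def test_parseval_identity(self, toy_cell, rng):
        hkl = np.array(sorted({tuple(h) for h in rng.integers(-6, 7, (600, 3))}
                              - {(0, 0, 0)}))[:200]
        f = np.abs(rng.standard_normal(len(hkl))) * 10
        ph = rng.uniform(0, 360, len(hkl))
        rs = ReflectionSet(cell=toy_cell, hkl=hkl, f=f, phase=ph)
        m = diffmap.synthesize_map(rs)
        expect_var = 2.0 * np.sum(f**2) / toy_cell.volume**2
        got = np.mean(m.values**2) - np.mean(m.values) ** 2
        assert got == pytest.approx(expect_var, rel=1e-6)

    def test_map_peaks_at_atom_positions(self, toy_cell):
        m = _model(toy_cell, [(0.25, 0.5, 0.75)], b=8.0)
        rs = diffmap.calc_structure_factors(m, 1.3)
        dm = diffmap.synthesize_map(rs)
        idx = np.unravel_index(np.argmax(dm.values), dm.grid)
        frac = np.array(idx) / np.array(dm.grid)
        err = np.abs(frac - [0.25, 0.5, 0.75])
        assert (err <= 1.0 / np.array(dm.grid) + 1e-12).all()


class TestSigmaNormalize:
    def test_normalized_statistics(self, toy_cell, rng):
        m = DensityMap(cell=toy_cell, values=rng.standard_normal((20, 20, 20)) * 7 + 3)
        out = diffmap.sigma_normalize(m)
        assert abs(out.mean) < 1e-12
        assert out.sigma == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, toy_cell, rng):
        v = rng.standard_normal((16, 16, 16))
        a = diffmap.sigma_normalize(DensityMap(cell=toy_cell, values=v))
        b = diffmap.sigma_normalize(DensityMap(cell=toy_cell, values=7 * v))
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_constant_map_rejected(self, toy_cell):
        with pytest.raises(ValueError):
            diffmap.sigma_normalize(DensityMap(cell=toy_cell,
                                               values=np.ones((8, 8, 8))))


def _gaussian_map(cell, centers_heights, shape=(48, 52, 56), width=0.6):
    dims = np.array(shape)
    gi = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), -1)
    vals = np.zeros(shape)
    for frac0, h in centers_heights:
        d = gi / dims - np.asarray(frac0)
        d -= np.rint(d)
        cart = d @ np.diag([cell.a, cell.b, cell.c]).T
        r2 = (cart**2).sum(-1)
        vals += h * np.exp(-r2 / (2 * width**2))
    return DensityMap(cell=cell, values=vals)


class TestPeakDetect:
    def test_zero_map_no_peaks(self, toy_cell):
        m = DensityMap(cell=toy_cell, values=np.zeros((16, 16, 16)))
        assert diffmap.peak_detect(m, 3.0) == []

    def test_single_gaussian_found_at_position(self, toy_cell):
        center = (0.25, 0.5, 0.25)  # on grid nodes of the (48, 52, 56) grid
        m = _gaussian_map(toy_cell, [(center, 8.0)])
        peaks = diffmap.peak_detect(m, 6.0, min_separation=2.0)
        assert len(peaks) == 1
        err = np.abs(peaks[0]["frac"] - center)
        assert (err <= 0.6 / np.array(m.grid)).all()
        assert peaks[0]["sign"] == 1
        assert peaks[0]["height_sigma"] == pytest.approx(8.0, rel=0.01)

    def test_nearby_blobs_merged(self, toy_cell):
        # two maxima 1 A apart along a; min_separation 2 A merges them
        c1 = (0.30, 0.5, 0.5)
        c2 = (0.30 + 1.0 / toy_cell.a, 0.5, 0.5)
        m = _gaussian_map(toy_cell, [(c1, 8.0), (c2, 7.0)], width=0.35)
        peaks = diffmap.peak_detect(m, 3.0, min_separation=2.0)
        assert len(peaks) == 1
        assert diffmap.peak_detect(m, 3.0, min_separation=0.5)


class TestAtomDEDAmplitude:
    def test_zero_map_all_zero(self, toy_cell, crystal_bundle):
        dark = crystal_bundle[0]
        m = DensityMap(cell=dark.cell, values=np.zeros((32, 32, 32)))
        amp = diffmap.atom_ded_amplitude(m, dark)
        assert all(v == 0.0 for v in amp.values())

    def test_locality_and_brute_force_agreement(self, toy_cell):
        atoms = [Atom(id="A", element="C", chain="A", residue_name="LIG",
                      residue_number=1, frac=np.array([0.3, 0.3, 0.3])),
                 Atom(id="B", element="C", chain="A", residue_name="LIG",
                      residue_number=2, frac=np.array([0.8, 0.8, 0.8]))]
        model = AtomicModel(cell=toy_cell, atoms=atoms)
        m = _gaussian_map(toy_cell, [((0.3, 0.3, 0.3), 5.0)])
        amp = diffmap.atom_ded_amplitude(m, model, radius=2.0, grid_step=0.5,
                                         sigma_cut=3.0)
        assert amp[("A", 1, "A")] > 0
        assert amp[("A", 2, "B")] == 0.0
        # brute-force voxel loop for atom A
        vals = []
        r_steps = 4
        for i in range(-r_steps, r_steps + 1):
            for j in range(-r_steps, r_steps + 1):
                for k in range(-r_steps, r_steps + 1):
                    off = np.array([i, j, k]) * 0.5
                    if np.linalg.norm(off) > 2.0:
                        continue
                    frac = atoms[0].frac + toy_cell.fractionalize(off)
                    v = m.value_at_frac(frac)[0]
                    if abs(v) >= 3.0:
                        vals.append(abs(v))
        assert amp[("A", 1, "A")] == pytest.approx(np.mean(vals), abs=1e-10)

    def test_sign_flip_invariance(self, toy_cell):
        atoms = [Atom(id="A", element="C", chain="A", residue_name="LIG",
                      residue_number=1, frac=np.array([0.3, 0.3, 0.3]))]
        model = AtomicModel(cell=toy_cell, atoms=atoms)
        m = _gaussian_map(toy_cell, [((0.3, 0.3, 0.3), 5.0)])
        neg = DensityMap(cell=toy_cell, values=-m.values)
        a1 = diffmap.atom_ded_amplitude(m, model)
        a2 = diffmap.atom_ded_amplitude(neg, model)
        assert a1 == a2


class TestNegativeDensityIntegral:
    def test_all_positive_map_gives_zero(self, toy_cell):
        atoms = [Atom(id="A", element="C", chain="A", residue_name="LIG",
                      residue_number=1, frac=np.array([0.5, 0.5, 0.5]))]
        model = AtomicModel(cell=toy_cell, atoms=atoms)
        m = _gaussian_map(toy_cell, [((0.5, 0.5, 0.5), 4.0)])
        assert diffmap.negative_density_integral(m, model, model.atoms, 3.0) == 0.0

    def test_gaussian_blob_matches_analytic_integral(self, toy_cell):
        # -h * (2 pi w^2)^{3/2} / voxel_volume, blob well inside the mask
        h, w = 6.0, 0.6
        m = _gaussian_map(toy_cell, [((0.5, 0.5, 0.5), -h)], width=w)
        atoms = [Atom(id="A", element="C", chain="A", residue_name="LIG",
                      residue_number=1, frac=np.array([0.5, 0.5, 0.5]))]
        model = AtomicModel(cell=toy_cell, atoms=atoms)
        got = diffmap.negative_density_integral(m, model, model.atoms, 3.5)
        vox_vol = toy_cell.volume / np.prod(m.grid)
        expect = -h * (2 * np.pi * w**2) ** 1.5 / vox_vol
        assert got == pytest.approx(expect, rel=0.02)

    def test_mask_far_from_blob_gives_zero(self, toy_cell):
        m = _gaussian_map(toy_cell, [((0.1, 0.1, 0.1), -6.0)])
        atoms = [Atom(id="A", element="C", chain="A", residue_name="LIG",
                      residue_number=1, frac=np.array([0.6, 0.6, 0.6]))]
        model = AtomicModel(cell=toy_cell, atoms=atoms)
        assert abs(diffmap.negative_density_integral(m, model, model.atoms, 2.0)) < 1e-12

    def test_empty_selection_rejected(self, toy_cell):
        m = _gaussian_map(toy_cell, [((0.5, 0.5, 0.5), -1.0)])
        model = AtomicModel(cell=toy_cell, atoms=[])
        with pytest.raises(ValueError):
            diffmap.negative_density_integral(m, model, [], 2.0)


class TestFDoublePrime:
    def test_decreases_with_energy_far_above_edges(self):
        # Fe K edge at 7.1 keV; sample well above it
        energies = np.linspace(10.0, 30.0, 9)
        vals = [diffmap.f_double_prime("Fe", e) for e in energies]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_unknown_element(self):
        with pytest.raises(ValueError):
            diffmap.f_double_prime("Qq", 10.0)
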