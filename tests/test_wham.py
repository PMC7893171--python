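import numpy as np
import pytest

from dimerscope.constants import kt
from dimerscope.synthetic.umbrella import (
    AnalyticPMFSpec,
    default_restraints,
    generate_umbrella_windows,
)
from dimerscope.wham import (
    RestraintSpec,
    UmbrellaWindow,
    bias_energy,
    binned_wham_distance,
    bootstrap_pmf,
    convergence_blocks,
    dissociation_dG,
    pmf_profile,
    read_window_dir,
    unbiased_observable_profile,
    wham,
    write_window_dir,
)


class TestBiasEnergy:
    def test_zero_at_all_centers(self):
        r = RestraintSpec(d0=0.5, k_d=1000.0, phi1_0=10.0, k_phi1=0.5,
                          phi3_0=-20.0, k_phi3=0.5)
        assert bias_energy((0.5, 10.0, -20.0), r) == 0.0

    def test_distance_term_value(self):
        r = RestraintSpec(d0=0.5, k_d=1000.0)
        assert np.isclose(bias_energy((0.6, 0.0, 0.0), r), 5.0)

    def test_dihedral_wrap_before_squaring(self):
        r = RestraintSpec(phi1_0=-179.0, k_phi1=0.5)
        # +179 vs -179: wrapped difference is -2 degrees, not 358
        assert np.isclose(bias_energy((0.0, 179.0, 0.0), r),
                          0.5 * 0.5 * 2.0**2)

    def test_radian_unit_conversion(self):
        k_rad = 100.0  # kJ/mol/rad^2
        r = RestraintSpec(phi1_0=0.0, k_phi1=k_rad, angle_unit="rad")
        expected = 0.5 * k_rad * np.radians(10.0) ** 2
        assert np.isclose(bias_energy((0.0, 10.0, 0.0), r), expected)

    def test_negative_force_constant_rejected(self):
        with pytest.raises(ValueError):
            RestraintSpec(d0=0.1, k_d=-1.0)


class TestWhamBasics:
    def test_single_unbiased_window_uniform_weights(self, rng):
        w = UmbrellaWindow(restraint=RestraintSpec(),
                           d=rng.uniform(0, 1, size=500))
        res = wham([w])
        assert np.allclose(res.weights, 1.0 / 500, atol=1e-14)
        assert res.f.tolist() == [0.0]

    def test_zero_bias_pmf_equals_log_histogram(self, rng):
        d = rng.normal(0.8, 0.1, size=4000)
        w = UmbrellaWindow(restraint=RestraintSpec(), d=d)
        res = wham([w])
        prof = pmf_profile(res, bin_width=0.05, offset="none")
        hist, edges = np.histogram(d, bins=np.arange(d.min(),
                                                     d.max() + 0.05 * (1 - 1e-12),
                                                     0.05))
        expected = -kt() * np.log(hist / d.size / 0.05)
        good = hist > 0
        assert np.allclose(prof.free_energy[good], expected[good], rtol=1e-10)

    def test_duplicated_window_leaves_weights_invariant(self, rng):
        d = rng.normal(0.5, 0.05, size=300)
        r = RestraintSpec(d0=0.5, k_d=500.0)
        w = UmbrellaWindow(restraint=r, d=d)
        res1 = wham([w])
        res2 = wham([w, UmbrellaWindow(restraint=r, d=d.copy())])
        assert np.allclose(res2.weights[:300] * 2, res1.weights, rtol=1e-8)

    def test_gauge_invariance_under_constant_bias_shift(
            self, double_well_windows):
        from dataclasses import replace

        _, windows, _ = double_well_windows
        sub = windows[5:10]
        res = wham(sub, tol=1e-12)
        shifted = [sub[0].__class__(
            restraint=replace(sub[0].restraint, offset=37.5),
            d=sub[0].d, phi1=sub[0].phi1, phi3=sub[0].phi3,
            time=sub[0].time)] + list(sub[1:])
        res2 = wham(shifted, tol=1e-12)
        assert np.allclose(res.weights, res2.weights, rtol=1e-10, atol=1e-18)

    def test_solution_unique_with_f0_pinned(self, double_well_windows):
        _, windows, _ = double_well_windows
        res1 = wham(windows[:8], tol=1e-10)
        res2 = wham(windows[:8], tol=1e-10, f_init=np.arange(8.0))
        assert res1.f[0] == 0.0
        assert np.allclose(res1.f, res2.f, atol=1e-8)

    def test_invalid_discard_fraction_rejected(self):
        w = UmbrellaWindow(restraint=RestraintSpec(), d=np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            wham([w], discard=1.0)

    def test_disjoint_windows_warn(self):
        w1 = UmbrellaWindow(restraint=RestraintSpec(d0=0.2, k_d=1e4),
                            d=np.full(50, 0.2))
        w2 = UmbrellaWindow(restraint=RestraintSpec(d0=1.4, k_d=1e4),
                            d=np.full(50, 1.4))
        with pytest.warns(RuntimeWarning, match="no sampled d-range"):
            wham([w1, w2], tol=1e-6)


class TestBinnedVsBinless:
    def test_agreement_on_distance_only_bias(self):
        pmf = AnalyticPMFSpec.well_plus_plateau(depth=20.0, domain=(0.0, 2.0))
        restraints = [RestraintSpec(d0=0.1 + 0.1 * i, k_d=1000.0)
                      for i in range(19)]
        windows, _ = generate_umbrella_windows(
            pmf, restraints, n_samples_per_window=2000, seed=21)
        res = wham(windows, tol=1e-8)
        prof = pmf_profile(res, bin_width=0.05)
        centers, fe = binned_wham_distance(windows, bin_width=0.05, tol=1e-8)
        # compare over bins present in both and well-sampled
        both = {}
        for c, f in zip(centers, fe):
            both[round(float(c), 6)] = f
        devs = []
        for c, f, n in zip(prof.bin_centers, prof.free_energy, prof.counts):
            key = round(float(c), 6)
            if n > 200 and key in both and np.isfinite(f) \
                    and np.isfinite(both[key]):
                devs.append(abs(f - both[key]))
        assert devs and max(devs) < 0.5  # kJ/mol, discretization error


class TestPmfProfile:
    def test_gaussian_sampling_gives_quadratic_profile(self, rng):
        sigma = 0.1
        d = rng.normal(1.0, sigma, size=200_000)
        w = UmbrellaWindow(restraint=RestraintSpec(), d=d)
        res = wham([w])
        prof = pmf_profile(res, bin_width=0.02)
        sel = prof.counts > 3000
        expected = kt() * (prof.bin_centers - 1.0) ** 2 / (2 * sigma**2)
        expected -= expected[sel].min()
        assert np.allclose(prof.free_energy[sel], expected[sel], atol=0.15)

    def test_all_samples_one_bin_rejected(self):
        w = UmbrellaWindow(restraint=RestraintSpec(), d=np.full(50, 0.5))
        res = wham([w])
        with pytest.raises(ValueError, match="degenerate"):
            pmf_profile(res, bin_width=0.1)

    def test_empty_interior_bins_flagged_not_interpolated(self, rng):
        d = np.concatenate([rng.uniform(0, 0.3, 200),
                            rng.uniform(0.9, 1.2, 200)])
        w = UmbrellaWindow(restraint=RestraintSpec(), d=d)
        res = wham([w])
        with pytest.warns(RuntimeWarning, match="empty interior"):
            prof = pmf_profile(res, bin_width=0.1)
        assert prof.empty_interior_bins().size > 0
        assert np.isnan(prof.free_energy[prof.empty_interior_bins()]).all()

    def test_min_offset_convention(self, double_well_windows):
        _, windows, _ = double_well_windows
        prof = pmf_profile(wham(windows, tol=1e-8))
        assert np.isclose(np.nanmin(prof.free_energy), 0.0)


class TestRecovery:
    def test_double_well_minima_recovered(self, double_well_windows):
        pmf, windows, _ = double_well_windows
        res = wham(windows, tol=1e-8)
        prof = pmf_profile(res, bin_width=0.05)
        fe = prof.free_energy
        # local minima of the recovered profile
        finite = np.isfinite(fe)
        idx = [i for i in range(1, fe.size - 1)
               if finite[i - 1] and finite[i] and finite[i + 1]
               and fe[i] < fe[i - 1] and fe[i] <= fe[i + 1]]
        found = prof.bin_centers[idx]
        for m in pmf.minima:
            # resolution limit: 0.05 nm bins plus the ~0.065 nm thermal
            # width of the shallow outer well at this sample size
            assert np.min(np.abs(found - m)) < 0.1

    def test_equilibration_discard_reduces_transient_bias(self):
        # first 30% of each window drawn from a shifted potential
        pmf = AnalyticPMFSpec.harmonic(k=200.0, d0=0.6, domain=(0.0, 1.5))
        shifted = AnalyticPMFSpec.harmonic(k=200.0, d0=1.0, domain=(0.0, 1.5))
        restraints = [RestraintSpec(d0=0.2 + 0.1 * i, k_d=500.0)
                      for i in range(12)]
        w_eq, _ = generate_umbrella_windows(pmf, restraints, 700, seed=31)
        w_tr, _ = generate_umbrella_windows(shifted, restraints, 300, seed=32)
        mixed = []
        for a, b in zip(w_tr, w_eq):
            mixed.append(UmbrellaWindow(
                restraint=a.restraint,
                d=np.concatenate([a.d, b.d]),
                phi1=np.concatenate([a.phi1, b.phi1]),
                phi3=np.concatenate([a.phi3, b.phi3]),
                time=np.concatenate([a.time, a.time[-1] + b.time]),
            ))
        prof_raw = pmf_profile(wham(mixed, tol=1e-8), bin_width=0.05)
        prof_cut = pmf_profile(wham(mixed, tol=1e-8, discard=0.3),
                               bin_width=0.05)

        def dev(prof):
            u0 = pmf.u0(prof.bin_centers)
            sel = prof.n_eff > 100
            shift = np.mean(prof.free_energy[sel] - u0[sel])
            return np.sqrt(np.mean(
                (prof.free_energy[sel] - u0[sel] - shift) ** 2))

        assert dev(prof_cut) < dev(prof_raw)


class TestBootstrap:
    def test_zero_variability_gives_zero_se(self):
        d = np.full(200, 0.5)
        d[:100] = 0.4  # two values, but every resample draws from the same
        w1 = UmbrellaWindow(restraint=RestraintSpec(), d=np.full(150, 0.40))
        w2 = UmbrellaWindow(restraint=RestraintSpec(), d=np.full(150, 0.60))
        prof, reps = bootstrap_pmf([w1, w2], n_boot=5, seed=1)
        assert np.allclose(prof.se[np.isfinite(prof.se)], 0.0, atol=1e-12)

    def test_seed_determinism(self, double_well_windows):
        _, windows, _ = double_well_windows
        sub = windows[::4]
        p1, r1 = bootstrap_pmf(sub, n_boot=4, seed=7)
        p2, r2 = bootstrap_pmf(sub, n_boot=4, seed=7)
        assert np.allclose(r1, r2, equal_nan=True)


class TestConvergenceBlocks:
    def test_single_block_equals_plain_profile(self, double_well_windows):
        _, windows, _ = double_well_windows
        t_span = windows[0].time.max() - windows[0].time.min()
        profiles, max_dev, converged = convergence_blocks(
            windows, block_length=t_span + 1e-6, bin_width=0.1)
        assert len(profiles) == 1
        ref = pmf_profile(wham(windows, tol=1e-8), bin_width=0.1,
                          d_range=(min(w.d.min() for w in windows),
                                   max(w.d.max() for w in windows)))
        a, b = profiles[0].free_energy, ref.free_energy
        ok = np.isfinite(a) & np.isfinite(b)
        assert np.allclose(a[ok], b[ok], atol=1e-6)

    def test_stationary_data_converges(self, double_well_windows):
        _, windows, _ = double_well_windows
        t_span = windows[0].time.max()
        _, max_dev, converged = convergence_blocks(
            windows, block_length=t_span / 2, bin_width=0.1, threshold=3.0)
        assert converged

    def test_drifting_data_flags_non_convergence(self):
        pmf_a = AnalyticPMFSpec.harmonic(k=300.0, d0=0.4, domain=(0.0, 1.5))
        pmf_b = AnalyticPMFSpec.harmonic(k=300.0, d0=1.0, domain=(0.0, 1.5))
        restraints = [RestraintSpec(d0=0.15 + 0.1 * i, k_d=300.0)
                      for i in range(13)]
        w_a, _ = generate_umbrella_windows(pmf_a, restraints, 500, seed=41)
        w_b, _ = generate_umbrella_windows(pmf_b, restraints, 500, seed=42)
        merged = []
        for a, b in zip(w_a, w_b):
            merged.append(UmbrellaWindow(
                restraint=a.restraint,
                d=np.concatenate([a.d, b.d]),
                phi1=np.concatenate([a.phi1, b.phi1]),
                phi3=np.concatenate([a.phi3, b.phi3]),
                time=np.concatenate([a.time, a.time[-1] + b.time]),
            ))
        _, max_dev, converged = convergence_blocks(
            merged, block_length=merged[0].time.max() / 2,
            bin_width=0.1, threshold=2.0)
        assert not converged

    def test_block_longer_than_data_rejected(self, double_well_windows):
        _, windows, _ = double_well_windows
        with pytest.raises(ValueError):
            convergence_blocks(windows, block_length=1e9)

    def test_timestamps_required(self):
        w = UmbrellaWindow(restraint=RestraintSpec(),
                           d=np.random.default_rng(0).uniform(0, 1, 100))
        with pytest.raises(ValueError, match="timestamps"):
            convergence_blocks([w], block_length=1.0)


class TestDissociation:
    def test_exact_plateau_value(self):
        prof = pmf_profile.__wrapped__ if hasattr(pmf_profile, "__wrapped__") \
            else None
        from dimerscope.wham import PMFProfile

        centers = np.arange(0.05, 2.0, 0.1)
        fe = np.where(centers < 1.0, 0.0, 55.0)
        fe[0] = 0.0
        profile = PMFProfile(bin_centers=centers, free_energy=fe, se=None,
                             temperature=310.0, offset="min",
                             f_windows=np.zeros(1),
                             counts=np.full(centers.size, 100),
                             n_eff=np.full(centers.size, 100.0),
                             bin_width=0.1)
        dg, flat = dissociation_dG(profile, (1.5, 1.9))
        assert dg == 55.0
        assert flat == 0.0

    def test_rising_profile_warns_about_flatness(self):
        from dimerscope.wham import PMFProfile

        centers = np.arange(0.05, 2.0, 0.1)
        fe = 30.0 * centers  # no asymptote
        profile = PMFProfile(bin_centers=centers, free_energy=fe, se=None,
                             temperature=310.0, offset="min",
                             f_windows=np.zeros(1),
                             counts=np.full(centers.size, 100),
                             n_eff=np.full(centers.size, 100.0),
                             bin_width=0.1)
        with pytest.warns(RuntimeWarning, match="not flat"):
            dg, flat = dissociation_dG(profile, (1.0, 1.9))
        assert flat > 5.0

    def test_unsampled_plateau_rejected(self, double_well_windows):
        _, windows, _ = double_well_windows
        prof = pmf_profile(wham(windows, tol=1e-8))
        with pytest.raises(ValueError):
            dissociation_dG(prof, (90.0, 99.0))


class TestObservableProfile:
    def test_uniform_weights_give_plain_average(self, rng):
        d = rng.uniform(0, 1, size=2000)
        obs = rng.normal(size=2000)
        w = UmbrellaWindow(restraint=RestraintSpec(), d=d, observable=obs)
        res = wham([w])
        prof = unbiased_observable_profile(res, bin_width=0.2, reference=0.0)
        for c, m in zip(prof.bin_centers, prof.mean):
            sel = np.abs(d - c) <= 0.1
            if sel.sum():
                assert np.isclose(m, obs[sel].mean(), atol=1e-9)

    def test_constant_observable_recovered_everywhere(
            self, double_well_windows):
        _, windows, _ = double_well_windows
        from dataclasses import replace

        wobs = [replace(w, observable=np.ones_like(w.d)) for w in windows]
        res = wham(wobs, tol=1e-8)
        prof = unbiased_observable_profile(res, bin_width=0.1)
        finite = np.isfinite(prof.mean)
        assert np.allclose(prof.mean[finite], 1.0)

    def test_deterministic_function_of_d_recovered(self):
        pmf = AnalyticPMFSpec.well_plus_plateau(depth=30.0)
        fn = lambda d: 50.0 / (1 + np.exp((d - 0.6) / 0.1))  # noqa: E731
        windows, _ = generate_umbrella_windows(
            pmf, default_restraints(n_windows=15), 800, seed=51,
            observable_fn=fn)
        res = wham(windows, tol=1e-8)
        prof = unbiased_observable_profile(res, bin_width=0.1)
        # per bin, the weighted mean must equal the weighted mean of fn(d)
        rel = res.d - prof.d_min
        for c, m in zip(prof.bin_centers, prof.mean):
            sel = np.abs(rel - c) <= 0.05
            if sel.sum() and np.isfinite(m):
                expect = np.average(fn(res.d[sel]), weights=res.weights[sel])
                assert np.isclose(m, expect, rtol=1e-5)

    def test_missing_observable_rejected(self, double_well_windows):
        _, windows, _ = double_well_windows
        res = wham(windows[:3], tol=1e-6)
        if res.observable is None:
            with pytest.raises(ValueError):
                unbiased_observable_profile(res)


class TestWindowDirIO:
    def test_round_trip(self, double_well_windows, tmp_path):
        _, windows, _ = double_well_windows
        sub = windows[:4]
        write_window_dir(sub, tmp_path / "win", temperature=310.0)
        back, temperature = read_window_dir(tmp_path / "win")
        assert temperature == 310.0
        assert len(back) == 4
        for a, b in zip(sub, back):
            assert np.allclose(a.d, b.d, rtol=1e-7)
            assert np.allclose(a.phi1, b.phi1, rtol=1e-7)
            assert a.restraint.d0 == b.restraint.d0
            assert a.restraint.k_d == b.restraint.k_d

    def test_npz_container_round_trip(self, double_well_windows, tmp_path):
        _, windows, _ = double_well_windows
        sub = windows[:3]
        write_window_dir(sub, tmp_path / "win", fmt="npz")
        back, _ = read_window_dir(tmp_path / "win")
        for a, b in zip(sub, back):
            assert np.array_equal(a.d, b.d)
            assert np.array_equal(a.phi3, b.phi3)

    def test_missing_force_constant_rejected(self, double_well_windows,
                                             tmp_path):
        import yaml

        _, windows, _ = double_well_windows
        write_window_dir(windows[:2], tmp_path / "win")
        mpath = tmp_path / "win" / "manifest.yaml"
        manifest = yaml.safe_load(mpath.read_text())
        del manifest["windows"][0]["k_d"]
        mpath.write_text(yaml.safe_dump(manifest))
        with pytest.raises(ValueError, match="mandatory"):
            read_window_dir(tmp_path / "win")
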