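"""Organelle instantiations: flagella, centrosome, LLPS droplet, nucleus."""

import numpy as np
import pytest

from poolgrowth import (PoolConfig, SimulationSpec, gillespie_run)
from poolgrowth.organelles import (CentrosomeSpec, FlagellaSpec, LLPSParams,
                                   NucleusGrowthMode, NucleusSpec,
                                   centrosome_model, flagella_amputate,
                                   flagella_simulate, llps_reduce,
                                   nucleus_cell_scaling,
                                   nucleus_confinement_sweep,
                                   nucleus_simulate, subunit_count)


def steady_mean(tr, t_frac=0.5):
    m = tr.times >= t_frac * tr.times[-1]
    return tr.sizes[m].mean(axis=0)


class TestFlagella:
    def test_unit_conversion(self):
        # 1 uM in 1 um^3 is ~602 molecules
        assert subunit_count(1.0, 1.0, "uM") == 602
        assert subunit_count(8.0, 100.0, "per_um3") == 800

    def test_mean_length_decreases_with_flagella_number(self):
        means = []
        for M in (1, 2, 4):
            spec = FlagellaSpec(M=M)
            tr = flagella_simulate(spec, t_max=2000.0, seed=5)
            means.append(spec.lengths_um(steady_mean(tr)).mean())
        assert means[0] > means[1] > means[2]

    def test_identical_pair_equal_lengths_at_balance_point(self):
        spec = FlagellaSpec()
        tr = flagella_simulate(spec, t_max=2000.0, seed=8)
        m = steady_mean(tr)
        assert abs(m[0] - m[1]) / m.mean() < 0.05
        # symmetric root of k+ (N - 2n)/(V (1+n)) = k-
        n_star = spec.steady_length_um() / (spec.subunit_size_nm * 1e-3)
        assert m.mean() == pytest.approx(n_star, rel=0.05)

    def test_amputation_transient_shrinkage_and_recovery(self):
        spec = FlagellaSpec()
        rg = flagella_amputate(spec, t_post=4000.0, seed=7)
        L_post = rg.lengths_post()
        intact = 1 - rg.amputated_structure
        w = 50
        windowed = np.convolve(L_post[:, intact], np.ones(w) / w, "valid")
        at_cut = L_post[0, intact]
        assert windowed.min() < at_cut          # intact shrinks after the cut
        # both converge to a common length near the pre-cut steady state
        tail = L_post[rg.post.times >= 0.75 * rg.post.times[-1]]
        final = tail.mean(axis=0)
        assert abs(final[0] - final[1]) / final.mean() < 0.05
        pre_steady = rg.lengths_pre()[-200:].mean()
        assert abs(final.mean() - pre_steady) / pre_steady < 0.05

    def test_no_production_gives_smaller_common_length(self):
        spec = FlagellaSpec()
        rg = flagella_amputate(spec, t_post=3000.0, seed=7, production=False)
        tail = rg.lengths_post()[rg.post.times >= 0.75 * rg.post.times[-1]]
        final = tail.mean(axis=0)
        pre_steady = rg.lengths_pre()[-200:].mean()
        assert abs(final[0] - final[1]) / final.mean() < 0.05
        assert final.mean() < 0.95 * pre_steady


class TestCentrosome:
    def test_closed_forms_match_ssa(self):
        model = centrosome_model(CentrosomeSpec(n_c=1))
        tr = model.simulate(t_max=30 * model.relaxation_time, seed=2)
        mean = tr.weighted_mean_sizes()[0]
        assert mean == pytest.approx(model.steady_size_single, rel=0.05)

    def test_identical_pair_stays_equal(self):
        model = centrosome_model(CentrosomeSpec(n_c=2))
        half = int(round(model.steady_size_multi))
        tr = model.simulate(t_max=20 * model.relaxation_time, seed=3,
                            init_sizes=[half, half])
        m = tr.weighted_mean_sizes()
        assert abs(m[0] - m[1]) / m.mean() < 0.02
        assert m.mean() == pytest.approx(model.steady_size_multi, rel=0.05)

    def test_volume_scales_linearly_with_cell_volume(self):
        V_grid = np.linspace(1000.0, 5000.0, 5)
        vols = []
        for i, vc in enumerate(V_grid):
            s = CentrosomeSpec(n_c=2, V_cell_um3=float(vc))
            mo = centrosome_model(s)
            tr = mo.simulate(t_max=20 * mo.relaxation_time, seed=10 + i)
            vols.append(tr.weighted_mean_sizes().mean()
                        * s.subunit_volume_um3)
        vols = np.asarray(vols)
        coef = np.polyfit(V_grid, vols, 1)
        resid = vols - np.polyval(coef, V_grid)
        r2 = 1 - (resid ** 2).sum() / ((vols - vols.mean()) ** 2).sum()
        assert r2 > 0.99


class TestLLPS:
    def test_coefficients_from_definitions(self):
        red = llps_reduce(LLPSParams(Q=2.0, k=1.0, k_BA=3.0, psi_minus=0.5,
                                     delta_v=1.0, N_tot=100, V_cell=10.0))
        assert (red.C0, red.C1, red.C2) == (1.0, 0.5, 3.0)
        assert red.effective_regime.value == "robust_control"
        red2 = llps_reduce(LLPSParams(Q=0.1, k=1.0, k_BA=3.0, psi_minus=0.5,
                                      delta_v=1.0, N_tot=100, V_cell=10.0))
        assert red2.effective_regime.value == "limiting_pool_line"

    def test_c1_zero_is_exactly_the_kinetic_centrosome_model(self):
        """Identical rates => identical seeded trajectories."""
        red = llps_reduce(LLPSParams(Q=10.0, k=0.0, k_BA=0.2, psi_minus=0.5,
                                     delta_v=1.0, N_tot=200, V_cell=5.0))
        assert red.C1 == 0.0
        spec_llps = red.simulation_spec(t_max=50.0, seed=12)
        p = red.kinetic_model_params()
        assert (p.alpha, p.beta) == (0.0, 1.0)
        spec_core = SimulationSpec(
            cfg=PoolConfig(N_total=200, V=5.0, M=1), params=[p], seed=12,
            t_max=50.0, record_dt=spec_llps.record_dt)
        a, b = gillespie_run(spec_llps), gillespie_run(spec_core)
        assert np.array_equal(a.sizes, b.sizes)
        assert np.array_equal(a.times, b.times)

    def test_rhs_structure(self):
        red = llps_reduce(LLPSParams(Q=2.0, k=1.0, k_BA=3.0, psi_minus=0.5,
                                     delta_v=1.0, N_tot=100, V_cell=10.0))
        n = 20.0
        expect = (1.0 + 0.5 * n) * (80.0 / 10.0) - 3.0 * n
        assert red.rhs(n) == pytest.approx(expect)

    def test_psi_minus_validated(self):
        with pytest.raises(ValueError):
            LLPSParams(Q=1, k=1, k_BA=1, psi_minus=0.0, delta_v=1,
                       N_tot=10, V_cell=1.0)


class TestNucleus:
    def test_surface_growth_sqrt_scaling(self):
        spec = NucleusSpec()
        ns = []
        for i, conc in enumerate([2.0, 4.0, 8.0, 16.0, 32.0]):
            s = NucleusSpec(subunit_conc=conc)
            tr = nucleus_simulate(s, t_max=1200.0, seed=20 + i)
            ns.append(tr.steady_mean_n()[0])
        ns = np.asarray(ns)
        slope = np.polyfit(np.log(ns), np.log(spec.radius_um(ns)), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.02)

    def test_volume_growth_cuberoot_scaling(self):
        spec = NucleusSpec.np_defaults()
        ns = []
        for i, conc in enumerate([0.2, 0.4, 0.75, 1.5, 3.0]):
            s = NucleusSpec.np_defaults(subunit_conc=conc)
            tr = nucleus_simulate(s, t_max=2500.0, seed=30 + i)
            ns.append(tr.steady_mean_n()[0])
        ns = np.asarray(ns)
        slope = np.polyfit(np.log(ns), np.log(spec.radius_um(ns)), 1)[0]
        assert slope == pytest.approx(1.0 / 3.0, abs=0.02)

    def test_more_nuclei_smaller_radius(self):
        radii = []
        for i, k in enumerate([1, 2, 4]):
            s = NucleusSpec(n_nuclei=k)
            tr = nucleus_simulate(s, t_max=1500.0, seed=40 + i)
            radii.append(s.radius_um(tr.steady_mean_n()).mean())
        assert radii[0] > radii[1] > radii[2]

    def test_confinement_monotone_then_saturating(self):
        spec = NucleusSpec()
        grid = [5.0, 8.0, 12.0, 20.0, 40.0]
        Rn = nucleus_confinement_sweep(spec, grid, t_max=1200.0, seed=33)
        assert np.all(np.diff(Rn) > -0.05)          # monotone up to noise
        assert Rn[0] < 0.9 * Rn[-1]                 # confinement shrinks it
        # flat beyond saturation: unconfined Lbar + R_n < 20 um
        assert abs(Rn[-1] - Rn[-2]) / Rn[-1] < 0.05
        free = nucleus_simulate(spec, t_max=1200.0, seed=33)
        R_free = spec.radius_um(free.steady_mean_n())[0]
        assert Rn[-1] == pytest.approx(R_free, rel=0.05)

    def test_cell_scaling_exponents(self):
        slope_np, vols = nucleus_cell_scaling(
            NucleusSpec.np_defaults(), [50.0, 100.0, 200.0, 400.0],
            t_max=2500.0, seed=44)
        assert slope_np == pytest.approx(1.0, abs=0.05)
        assert np.all(np.diff(vols) > 0)
        slope_ne, vols_ne = nucleus_cell_scaling(
            NucleusSpec(), [50.0, 100.0, 200.0, 400.0],
            t_max=1500.0, seed=45)
        assert slope_ne > 1.3                        # strongly superlinear
        assert np.all(np.diff(vols_ne) > 0)

    def test_invalid_confinement_rejected(self):
        with pytest.raises(ValueError):
            nucleus_simulate(NucleusSpec(R_sys_um=-1.0), t_max=10.0, seed=0)
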