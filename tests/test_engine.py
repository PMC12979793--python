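"""Force-field correctness, integrator physics, and folding protocols."""
import numpy as np
import pytest

from nlchrom.chain import (
    ScaffoldPlacement,
    build_nl_chain,
    initialize_from_scaffold,
    map_nl_to_cg,
)
from nlchrom.core import GenomicRegion, NucleosomeAnnotation
from nlchrom.engine import (
    contact_satisfaction,
    energy_and_forces,
    fold_homopolymer,
    fold_nl,
    langevin_run,
    make_homopolymer_system,
    make_nl_system,
    self_avoiding_walk,
)
from nlchrom.forcefield import ForceField, SimulationParams, WCA_CUT
from nlchrom.synth import NucleosomeArraySpec, gen_nucleosomes


def _pair_system(diams, **ff_kw):
    """Minimal 2-bead system with WCA only (harmonic bond k -> irrelevant)."""
    ff = ForceField(**ff_kw)
    import nlchrom.engine as E

    return E.System(
        diam=np.asarray(diams, dtype=float),
        is_nuc=np.zeros(len(diams), dtype=np.int64),
        bond_i=np.empty(0, dtype=np.int64),
        bond_j=np.empty(0, dtype=np.int64),
        bond_kind=np.empty(0, dtype=np.int64),
        bond_r0=np.empty(0),
        bond_R0=np.empty(0),
        bond_k=np.empty(0),
        ff=ff,
    )


class TestClosedForms:
    def test_wca_at_sigma_and_cutoff(self):
        sys_ = _pair_system([1.0, 1.0])
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        e, f, bd = energy_and_forces(pos, sys_)
        assert bd["wca"] == pytest.approx(1.0)  # U(sigma) = eps exactly
        pos[1, 0] = WCA_CUT
        e, f, bd = energy_and_forces(pos, sys_)
        assert bd["wca"] == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f).max() == pytest.approx(0.0, abs=1e-9)

    def test_wca_lorentz_rule_for_mixed_sizes(self):
        sys_ = _pair_system([4.0, 1.0])  # contact distance 2.5
        pos = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        _, _, bd = energy_and_forces(pos, sys_)
        assert bd["wca"] == pytest.approx(1.0)

    def test_fene_zero_at_origin_limit(self):
        """FENE energy -> 0 as r -> 0 (the log term vanishes)."""
        k, r0 = 30.0, 1.0
        R0 = 1.5 * r0
        r = 1e-8
        u = -0.5 * k * R0**2 * np.log(1 - r**2 / R0**2)
        assert u == pytest.approx(0.0, abs=1e-12)

    def test_fene_overstretch_signals_blowup(self):
        region = GenomicRegion("chrT", 0, 1000)
        ann = NucleosomeAnnotation(region, [200, 600], [1, 1])
        chain = map_nl_to_cg(build_nl_chain(ann), 1000)
        sys_ = make_nl_system(chain, np.empty((0, 2), int))
        sc = ScaffoldPlacement(coords_nm=np.zeros((1, 3)))
        pos = initialize_from_scaffold(chain, sc, seed=0)
        pos[3:] += 100.0  # tear one bond far past R0
        with pytest.raises(FloatingPointError, match="FENE"):
            energy_and_forces(pos, sys_)


class TestForceGradientConsistency:
    """Analytic forces match central-difference gradients for every term."""

    def _numeric_forces(self, pos, system, h=2e-6):
        num = np.zeros_like(pos)
        for i in range(pos.shape[0]):
            for c in range(3):
                pp = pos.copy()
                pp[i, c] += h
                ep, _, _ = energy_and_forces(pp, system)
                pm = pos.copy()
                pm[i, c] -= h
                em, _, _ = energy_and_forces(pm, system)
                num[i, c] = -(ep - em) / (2 * h)
        return num

    def test_homopolymer_terms(self):
        """Harmonic bonds + WCA + capped flat-bottom restraints."""
        sys_ = make_homopolymer_system(8, [(0, 7), (1, 5)])
        rng = np.random.default_rng(0)
        pos = self_avoiding_walk(8, seed=1) + rng.normal(0, 0.02, (8, 3))
        _, analytic, bd = energy_and_forces(pos, sys_)
        assert bd["restraint"] > 0  # the term is actually exercised
        num = self._numeric_forces(pos, sys_)
        scale = max(np.abs(analytic).max(), 1.0)
        assert np.abs(analytic - num).max() / scale < 1e-6

    def test_nl_terms_including_com(self):
        """FENE + bending + WCA + nucleosome attraction + COM restraint
        and COM-WCA, on a small mixed chain across two domains."""
        region = GenomicRegion("chrT", 0, 2000)
        ann = NucleosomeAnnotation(region, [200, 400, 1400, 1600], [1] * 4)
        chain = map_nl_to_cg(build_nl_chain(ann), 1000)
        sys_ = make_nl_system(chain, [(0, 1)] if chain.n_domains == 2 else [])
        # shrink the COM well so the restraint term is active
        sys_.crest_rc[:] = 1.0
        sc = ScaffoldPlacement(coords_nm=np.array([[0, 0, 0], [60.0, 0, 0]]))
        pos = initialize_from_scaffold(chain, sc, seed=3)
        _, analytic, bd = energy_and_forces(pos, sys_)
        assert bd["fene"] > 0 and bd["bend"] > 0
        assert bd["com_restraint"] > 0
        num = self._numeric_forces(pos, sys_)
        scale = max(np.abs(analytic).max(), 1.0)
        assert np.abs(analytic - num).max() / scale < 1e-6

    def test_attraction_term_gradient(self):
        import nlchrom.engine as E

        ff = ForceField(eps_nn=0.5)
        sys_ = E.System(
            diam=np.array([4.0, 4.0]),
            is_nuc=np.ones(2, dtype=np.int64),
            bond_i=np.empty(0, dtype=np.int64),
            bond_j=np.empty(0, dtype=np.int64),
            bond_kind=np.empty(0, dtype=np.int64),
            bond_r0=np.empty(0),
            bond_R0=np.empty(0),
            bond_k=np.empty(0),
            ff=ff,
        )
        pos = np.array([[0.0, 0, 0], [5.1, 0.3, -0.2]])  # inside the LJ well
        _, analytic, bd = energy_and_forces(pos, sys_)
        assert bd["attraction"] < 0
        num = self._numeric_forces(pos, sys_)
        assert np.abs(analytic - num).max() / max(np.abs(analytic).max(), 1e-3) < 1e-6


class TestIntegrator:
    @staticmethod
    def _advance(sys_, pos, vel, n_steps, noise, dt, gamma, kT):
        import nlchrom._kernels as K

        ff = sys_.ff
        pi, pj, ps, pk = sys_._buffers()
        forces = np.zeros_like(pos)
        energies = np.zeros(K.N_TERMS)
        status = K.run_chunk(
            pos, vel, noise, dt, gamma, kT,
            sys_.diam, sys_.is_nuc, 1.0, 10, sys_.skip_nonbonded,
            pi, pj, ps, pk, ff.epsilon, ff.eps_nn, ff.rc_nn_factor,
            sys_.bond_i, sys_.bond_j, sys_.bond_kind, sys_.bond_r0,
            sys_.bond_R0, sys_.bond_k,
            sys_.ang_i, sys_.ang_j, sys_.ang_k, ff.k_bend,
            sys_.rest_i, sys_.rest_j, sys_.rest_rc, ff.k_contact, ff.f_cap,
            sys_.dom_id, sys_.n_dom, sys_.dom_count,
            sys_.crest_a, sys_.crest_b, sys_.crest_rc, ff.k_com,
            sys_.cwca_a, sys_.cwca_b, sys_.sigma_com,
            forces, energies,
        )
        assert status == 0

    def test_nve_energy_conservation(self):
        """gamma = 0 velocity Verlet is symplectic: total energy shows
        bounded oscillation but no secular drift over 10^4 steps."""
        sys_ = make_homopolymer_system(10, [])
        pos = self_avoiding_walk(10, seed=4)
        rng = np.random.default_rng(1)
        kT = 0.01  # low amplitude so the 1e-4 eps bound is resolvable
        vel = rng.normal(0, np.sqrt(kT), pos.shape)
        dt = SimulationParams().dt
        # thermostatted pre-equilibration at the same temperature, so the
        # NVE segment starts from a steady-state configuration
        noise = rng.standard_normal((5000,) + pos.shape)
        self._advance(sys_, pos, vel, 5000, noise, dt, 1.0, kT)
        e_tot = []
        zero_noise = np.zeros((100,) + pos.shape)
        for _ in range(100):
            self._advance(sys_, pos, vel, 100, zero_noise, dt, 0.0, 0.0)
            pe, _, _ = energy_and_forces(pos, sys_)
            e_tot.append(pe + 0.5 * (vel**2).sum())
        t = np.arange(len(e_tot), dtype=float)
        slope = np.polyfit(t, e_tot, 1)[0]
        secular_drift = abs(slope) * len(e_tot)
        assert secular_drift < 1e-4  # in units of eps

    def test_equipartition_free_chain(self):
        """Thermostatted free 50-bead chain over 10^5 steps samples
        <KE> = (3/2) N kT within 2% of the target temperature."""
        n = 50
        sys_ = make_homopolymer_system(n, [])
        pos = self_avoiding_walk(n, seed=2)
        rng = np.random.default_rng(3)
        vel = rng.normal(0, 1.0, pos.shape)
        dt = SimulationParams().dt
        ke_samples = []
        for b in range(200):  # 200 x 500 = 1e5 steps
            noise = rng.standard_normal((500,) + pos.shape)
            self._advance(sys_, pos, vel, 500, noise, dt, sys_.ff.gamma, 1.0)
            if b >= 40:  # discard equilibration
                ke_samples.append(0.5 * (vel**2).sum())
        mean_ke = np.mean(ke_samples)
        assert mean_ke == pytest.approx(1.5 * n, rel=0.02)

    def test_bitwise_determinism(self):
        sys_ = make_homopolymer_system(12, [(0, 11)])
        pos = self_avoiding_walk(12, seed=5)
        params = SimulationParams(n_steps=2_000, save_interval=500, seed=9)
        a = langevin_run(pos, sys_, params)
        b = langevin_run(pos, sys_, params)
        assert np.array_equal(a.frames, b.frames)

    def test_default_protocol_yields_130_frames(self):
        params = SimulationParams()  # 6,500,000 steps / 50,000
        assert params.n_frames == 130
        with pytest.raises(ValueError, match="divide"):
            SimulationParams(n_steps=100, save_interval=33)


class TestContactSatisfaction:
    def test_extremes_and_fraction(self):
        pos = np.zeros((5, 3))
        assert contact_satisfaction(pos, [(0, 4), (1, 3)], 1.0) == 1.0
        rod = np.zeros((5, 3))
        rod[:, 0] = np.arange(5) * 10.0
        assert contact_satisfaction(rod, [(0, 4)], 2.5) == 0.0
        # hand-built: pairs (0,1) d=10 (out), (0,2) d=20 (out), (3,4) d=10...
        pos = rod.copy()
        pos[1] = pos[0]  # (0,1) satisfied
        pos[3] = pos[4]  # (3,4) satisfied
        assert contact_satisfaction(pos, [(0, 1), (0, 2), (3, 4)], 2.5) == pytest.approx(2 / 3)

    def test_empty_restraints_warn_and_return_one(self):
        with pytest.warns(UserWarning, match="empty"):
            assert contact_satisfaction(np.zeros((3, 3)), [], 1.0) == 1.0


class TestSelfAvoidingWalk:
    def test_rg_scaling_exponent(self):
        """Pivot-equilibrated SAWs show Flory scaling R_g ~ N^0.59."""
        sizes = [20, 40, 80, 160]
        mean_rg = []
        for n in sizes:
            rgs = []
            for s in range(25):
                pos = self_avoiding_walk(n, seed=1000 * n + s)
                c = pos - pos.mean(axis=0)
                rgs.append(np.sqrt((c**2).sum(axis=1).mean()))
            mean_rg.append(np.mean(rgs))
        slope = np.polyfit(np.log(sizes), np.log(mean_rg), 1)[0]
        assert slope == pytest.approx(0.59, abs=0.05)


class TestFolding:
    def test_single_long_range_restraint_closes_the_chain(self):
        pos, sat, ok = fold_homopolymer(
            [(0, 19)], 20, params=SimulationParams(seed=1)
        )
        assert ok and sat == 1.0
        assert np.linalg.norm(pos[0] - pos[19]) <= 2.5

    def test_block_restraints_compact_blocks(self, block_map_40):
        from nlchrom.preprocess import decompose, significant_contacts

        sig = significant_contacts(block_map_40)
        ens = decompose(sig, 1, seed=4)
        pos, sat, ok = fold_homopolymer(
            ens.replicates[0], 40, params=SimulationParams(seed=2)
        )
        assert sat >= 0.95
        blocks = np.zeros(40, int)
        blocks[14:27] = 1
        blocks[27:] = 2
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pos))
        iu, ju = np.triu_indices(40, k=1)
        same = blocks[iu] == blocks[ju]
        assert d[iu[same], ju[same]].mean() < d[iu[~same], ju[~same]].mean()

    def test_unconverged_fold_flagged_not_silently_accepted(self):
        # an impossible restraint budget: tiny step allowance
        pos, sat, ok = fold_homopolymer(
            [(0, 30), (1, 29), (2, 28)], 32,
            params=SimulationParams(seed=0),
            max_steps=0,
        )
        assert not ok and sat < 0.95

    def test_fold_nl_produces_expected_frames_and_com_contacts(self, nl_chain):
        rng = np.random.default_rng(0)
        sc = ScaffoldPlacement(coords_nm=rng.normal(0, 40, (4, 3)))
        params = SimulationParams(n_steps=20_000, save_interval=2_000, seed=6)
        traj, sat, ok = fold_nl(
            nl_chain, sc, [(0, 2)], params=params, max_phase_a_steps=40_000
        )
        assert traj.n_frames == 10
        assert ok and sat >= 0.95
        # restrained domain pair stays in contact in most production frames
        hits = 0
        rc = 90.0 / nl_chain.nm_per_sigma
        for f in traj.frames:
            coms = np.stack([f[nl_chain.cg_bin == d].mean(axis=0) for d in range(4)])
            hits += np.linalg.norm(coms[0] - coms[2]) <= rc
        assert hits >= 0.8 * traj.n_frames
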