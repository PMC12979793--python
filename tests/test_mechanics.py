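"""Free-energy surfaces, entropy, WLC rigidity, window statistics, and
the omics-mechanics composite."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from nlchrom.core import GenomicRegion, NucleosomeAnnotation
from nlchrom.chain import build_nl_chain, map_nl_to_cg
from nlchrom.mechanics import (
    FESurface,
    KBT_PN_NM,
    boltzmann_entropy,
    composite_activity,
    count_basins,
    effective_bond_length,
    global_wlc,
    kabsch_align,
    lagwise_wlc,
    pca_fes,
    rg_windows,
    tss_distance_profile,
)
from nlchrom.synth import gen_wlc


def _analytic_fes(P):
    P = P / P.sum()
    F = np.where(P > 0, -np.log(np.where(P > 0, P, 1.0)), np.inf)
    n1, n2 = P.shape
    return FESurface(np.arange(n1 + 1.0), np.arange(n2 + 1.0), P, F, 1.0)


class TestFes:
    def test_paraboloid_shape_of_gaussian_ensemble(self):
        """F(r) - F(0) = r^2 / (2 sigma^2) for an isotropic Gaussian,
        verified on the well-sampled core (r <= 2 sigma)."""
        rng = np.random.default_rng(0)
        frames = rng.normal(0, 1.0, (200_000, 8, 3))
        fes = pca_fes(frames, grid_bins=30, align=False, grid_sd=3.0)
        xs = 0.5 * (fes.edges1[:-1] + fes.edges1[1:])
        ys = 0.5 * (fes.edges2[:-1] + fes.edges2[1:])
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        s1, s2 = fes.edges1[-1] / 3.0, fes.edges2[-1] / 3.0  # grid spans 3 SD
        r2 = (X / s1) ** 2 + (Y / s2) ** 2
        core = (r2 <= 4.0) & np.isfinite(fes.F)
        coef = np.polyfit(r2[core], fes.F[core] - fes.F[core].min(), 1)[0]
        assert coef == pytest.approx(0.5, rel=0.05)

    def test_embedded_2d_ensemble_explains_everything(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(0, 1, (5000, 2)) * [3.0, 1.5]
        frames = np.zeros((5000, 4, 3))
        frames[:, 0, 0] = scores[:, 0]
        frames[:, 1, 1] = scores[:, 1]
        frames[:, 2, 0] = -scores[:, 0]
        frames[:, 3, 1] = -scores[:, 1]
        fes = pca_fes(frames, grid_bins=40, align=False)
        assert fes.explained_variance >= 0.99

    def test_identical_frames_error(self):
        frames = np.ones((50, 5, 3))
        with pytest.raises(ValueError, match="identical"):
            pca_fes(frames, align=False)

    def test_alignment_makes_fes_rotation_invariant(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, (800, 6, 3))
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        rotated = base @ q.T + rng.normal(0, 0, 3)
        fa = pca_fes(base, grid_bins=25, align=True)
        fb = pca_fes(rotated, grid_bins=25, align=True)
        assert boltzmann_entropy(fa) == pytest.approx(boltzmann_entropy(fb), abs=1e-9)
        assert count_basins(fa) == count_basins(fb)


class TestBasins:
    def test_single_gaussian_surface_has_one_basin(self):
        x = np.linspace(-3, 3, 61)
        P = np.exp(-0.5 * (x[:, None] ** 2 + x[None, :] ** 2))
        assert count_basins(_analytic_fes(P)) == 1

    def test_four_well_mixture(self):
        x = np.linspace(-1, 1, 41)
        X, Y = np.meshgrid(x, x, indexing="ij")
        P = np.zeros_like(X)
        for cx, cy in [(-0.6, -0.6), (-0.6, 0.6), (0.6, -0.6), (0.6, 0.6)]:
            P += np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * 0.01))
        assert count_basins(_analytic_fes(P)) == 4

    def test_invariant_under_constant_shift(self):
        rng = np.random.default_rng(3)
        P = rng.random((20, 20))
        P[P < 0.3] = 0  # unoccupied bins
        fes = _analytic_fes(P)
        n0 = count_basins(fes)
        fes.F = fes.F + 7.5  # count must depend on shape only
        assert count_basins(fes) == n0

    def test_plateau_merges_to_one_basin(self):
        P = np.zeros((9, 9))
        P[4, 4] = P[4, 5] = 0.4  # two equal-P adjacent minima of F
        P[0, 0] = 0.2
        assert count_basins(_analytic_fes(P)) == 2  # plateau + the corner


class TestEntropy:
    def test_uniform_distribution(self):
        P = np.full((10, 10), 1 / 100)
        assert boltzmann_entropy(_analytic_fes(P)) == pytest.approx(np.log(100))

    def test_single_bin_zero(self):
        P = np.zeros((5, 5))
        P[2, 2] = 1.0
        assert boltzmann_entropy(_analytic_fes(P)) == 0.0

    def test_merging_bins_never_increases_entropy(self):
        rng = np.random.default_rng(4)
        P = rng.random((16, 16))
        P /= P.sum()
        s_fine = boltzmann_entropy(_analytic_fes(P))
        coarse = P.reshape(8, 2, 8, 2).sum(axis=(1, 3))
        s_coarse = boltzmann_entropy(_analytic_fes(coarse))
        assert s_coarse <= s_fine + 1e-12

    def test_f_minimum_is_minus_log_max_p(self):
        rng = np.random.default_rng(5)
        frames = rng.normal(0, 1, (2000, 5, 3))
        fes = pca_fes(frames, grid_bins=20, align=False)
        assert fes.F.min() == pytest.approx(-np.log(fes.P.max()))


class TestEffectiveBondLength:
    def test_alternating_distances_geometric_mean(self):
        pos = np.zeros((1, 3, 3))
        pos[0, 1, 0] = 10.0
        pos[0, 2, 0] = 50.0  # bonds 10 and 40
        assert effective_bond_length(pos) == pytest.approx(np.sqrt(400.0))

    def test_uniform_distance(self):
        pos = np.zeros((2, 5, 3))
        pos[:, :, 0] = np.arange(5) * 7.0
        assert effective_bond_length(pos) == pytest.approx(7.0)

    def test_zero_bond_errors(self):
        with pytest.raises(ValueError, match="zero"):
            effective_bond_length(np.zeros((1, 3, 3)))


class TestWlcEstimators:
    @pytest.mark.parametrize("lp", [10.0, 20.0, 50.0])
    def test_recovery_within_ten_percent(self, lp):
        traj = gen_wlc(500, 20.0, lp, 200, seed=int(lp))
        lw = lagwise_wlc(traj.frames, n_boot=300, seed=1)
        gl = global_wlc(traj.frames, n_boot=200, seed=2)
        assert lw.lp_nm == pytest.approx(lp, rel=0.10)
        assert gl.lp_nm == pytest.approx(lp, rel=0.10)
        # cross-estimator agreement within the wider of the two CIs
        assert (
            gl.ci_lp[0] - (lw.ci_lp[1] - lw.ci_lp[0])
            <= lw.lp_nm
            <= gl.ci_lp[1] + (lw.ci_lp[1] - lw.ci_lp[0])
        )

    def test_kb_identity_holds_exactly(self):
        traj = gen_wlc(200, 20.0, 20.0, 50, seed=3)
        for est in (lagwise_wlc(traj.frames, n_boot=50, seed=0),
                    global_wlc(traj.frames, n_boot=50, seed=0)):
            assert est.kb_pn_nm2 == KBT_PN_NM * est.lp_nm
            assert est.ci_lp[0] <= est.lp_nm <= est.ci_lp[1]

    def test_rigid_rods_capped_and_flagged(self):
        traj = gen_wlc(50, 10.0, np.inf, 20, seed=4)
        with pytest.warns(UserWarning, match="capped"):
            est = lagwise_wlc(traj.frames, n_boot=20, seed=0)
        assert est.capped and est.lp_nm >= 1e6

    def test_global_fit_robust_to_noisy_long_lags(self):
        """Adding long, variance-dominated lags leaves the estimate within
        the previous CI (the trimming removes them)."""
        traj = gen_wlc(500, 20.0, 20.0, 200, seed=5)
        short = global_wlc(traj.frames, max_lag=10, n_boot=100, seed=1)
        longer = global_wlc(traj.frames, max_lag=60, n_boot=100, seed=1)
        assert short.ci_lp[0] <= longer.lp_nm <= short.ci_lp[1]

    def test_ci_coverage_over_repeats(self):
        """95% bootstrap CIs cover the true persistence length in >= 90%
        of repeat experiments, for both estimators."""
        lp = 20.0
        cov_lw = cov_gl = 0
        n_rep = 25
        for rep in range(n_rep):
            traj = gen_wlc(500, 20.0, lp, 200, seed=20_000 + rep)
            lw = lagwise_wlc(traj.frames, n_boot=200, seed=rep)
            gl = global_wlc(traj.frames, n_boot=150, seed=rep)
            cov_lw += lw.ci_lp[0] <= lp <= lw.ci_lp[1]
            cov_gl += gl.ci_lp[0] <= lp <= gl.ci_lp[1]
        assert cov_lw >= 0.9 * n_rep
        assert cov_gl >= 0.9 * n_rep


@pytest.fixture(scope="module")
def rod_chain():
    region = GenomicRegion("chrT", 0, 20_000)
    dyads = np.arange(100, 20_000, 200)
    ann = NucleosomeAnnotation(region, dyads, np.ones(dyads.size))
    return map_nl_to_cg(build_nl_chain(ann), 5000)


class TestWindowsAndProfiles:
    def _rod_frames(self, chain, spacing=1.0):
        pos = np.zeros((1, chain.n_beads, 3))
        pos[0, :, 0] = np.arange(chain.n_beads) * spacing
        return pos

    def test_rod_rg_closed_form(self, rod_chain):
        """R_g^2 of an n-bead rod with spacing b is b^2 (n^2 - 1)/12."""
        frames = self._rod_frames(rod_chain, spacing=2.0)
        table = rg_windows(frames, rod_chain, window_bp=20_000, step_bp=20_000)
        n = rod_chain.n_beads
        expected = np.sqrt(4.0 * (n**2 - 1) / 12.0)
        assert table["rg_mean_nm"].iloc[0] == pytest.approx(expected)

    def test_rg_scales_linearly_with_coordinates(self, rod_chain):
        f1 = self._rod_frames(rod_chain)
        t1 = rg_windows(f1, rod_chain, window_bp=10_000, step_bp=1_000)
        t2 = rg_windows(2 * f1, rod_chain, window_bp=10_000, step_bp=1_000)
        assert np.allclose(t2["rg_mean_nm"], 2 * t1["rg_mean_nm"])

    def test_windowed_rg_matches_brute_force(self, rod_chain):
        rng = np.random.default_rng(6)
        frames = rng.normal(0, 10, (3, rod_chain.n_beads, 3))
        table = rg_windows(frames, rod_chain, window_bp=10_000, step_bp=5_000)
        mid = rod_chain.midpoints
        sel = (mid >= 5_000) & (mid < 15_000)
        rgs = []
        for f in frames:
            c = f[sel] - f[sel].mean(axis=0)
            rgs.append(np.sqrt((c**2).sum(axis=1).mean()))
        row = table[table["window_start"] == 5_000].iloc[0]
        assert row["rg_mean_nm"] == pytest.approx(np.mean(rgs))

    def test_tss_profile_zero_at_origin_linear_for_rod(self, rod_chain):
        frames = self._rod_frames(rod_chain, spacing=1.0)
        prof = tss_distance_profile(frames, rod_chain, tss_bp=100)
        assert prof.loc[prof["offset_bp"] == 0, "mean_distance_nm"].iloc[0] == 0.0
        pos_half = prof[prof["offset_bp"] >= 0]
        r = np.corrcoef(pos_half["offset_bp"], pos_half["mean_distance_nm"])[0, 1]
        assert r > 0.999  # straight rod: distance linear in genomic offset

    def test_ideal_chain_profile_scales_as_sqrt_offset(self, rod_chain):
        """Equilibrated ideal (random-walk) chain: mean distance from the
        TSS grows as the square root of genomic offset."""
        rng = np.random.default_rng(7)
        n = rod_chain.n_beads
        steps = rng.normal(0, 1.0, (400, n, 3))
        frames = np.cumsum(steps, axis=1)
        prof = tss_distance_profile(frames, rod_chain, tss_bp=100)
        sel = prof["offset_bp"] > 2_000
        x = np.sqrt(prof.loc[sel, "offset_bp"].to_numpy(float))
        y = prof.loc[sel, "mean_distance_nm"].to_numpy()
        ratio = y / x
        assert ratio.std() / ratio.mean() < 0.10

    def test_tss_outside_region_errors(self, rod_chain):
        with pytest.raises(ValueError, match="outside"):
            tss_distance_profile(self._rod_frames(rod_chain), rod_chain, 25_000)


class TestCompositeActivity:
    def test_two_locus_z_convention(self):
        omics = pd.DataFrame({"rna": [1.0, 3.0]}, index=["a", "b"])
        rig = pd.Series([70.0, 80.0], index=["a", "b"])
        with pytest.warns(UserWarning):
            score = composite_activity(omics, rig)
        assert np.allclose(np.sort(score.composite), [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_anti_ranked_gives_perfect_negative_rho(self):
        omics = pd.DataFrame(
            {"rna": [4.0, 3.0, 2.0, 1.0], "h3k27ac": [8.0, 6.0, 4.0, 2.0]},
            index=list("abcd"),
        )
        rig = pd.Series([60.0, 65.0, 70.0, 75.0], index=list("abcd"))
        score = composite_activity(omics, rig)
        assert score.spearman_vs_rigidity == pytest.approx(-1.0)

    def test_repressive_mark_sign_flip_and_direct_formula(self):
        omics = pd.DataFrame(
            {
                "rna": [5.0, 1.0, 3.0, 2.0],
                "h3k27me3": [0.5, 3.0, 1.0, 2.0],  # repressive: flipped
            },
            index=list("abcd"),
        )
        rig = pd.Series([62.0, 80.0, 71.0, 75.0], index=list("abcd"))
        score = composite_activity(omics, rig)
        z_rna = (omics["rna"] - omics["rna"].mean()) / omics["rna"].std(ddof=1)
        z_k27 = -(omics["h3k27me3"] - omics["h3k27me3"].mean()) / omics[
            "h3k27me3"
        ].std(ddof=1)
        expected = (z_rna + z_k27) / 2
        assert np.allclose(score.composite, expected)
        assert score.spearman_vs_rigidity == pytest.approx(
            spearmanr(expected, rig)[0]
        )

    def test_single_locus_errors(self):
        with pytest.raises(ValueError):
            composite_activity(
                pd.DataFrame({"rna": [1.0]}, index=["a"]),
                pd.Series([70.0], index=["a"]),
            )


class TestKabsch:
    def test_alignment_removes_global_rotation(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, (10, 7, 3))
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:  # proper rotation, not a reflection
            q[:, 0] *= -1
        frames = np.concatenate([base, base @ q.T + 5.0])
        aligned = kabsch_align(frames)
        assert np.allclose(aligned[:10], aligned[10:], atol=1e-8)
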