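import numpy as np
import pytest

from quadratdyn.crowding import AlphaMatrix
from quadratdyn.ibm import CommunityParams, SpeciesParams, YearDraw
from quadratdyn.ipm import (IPM, SizeMesh, boundary_factor, mean_crowding,
                            state_from_individuals)
from quadratdyn.vital_rates import (GrowthParams, RecruitParams,
                                    SurvivalParams)


class TestSizeMesh:
    def test_weights_sum_to_span(self):
        mesh = SizeMesh(-1.6, 7.0, 100)
        assert mesh.weights.sum() == pytest.approx(7.0 + 1.6)

    def test_invalid_mesh_rejected(self):
        with pytest.raises(ValueError):
            SizeMesh(2.0, 1.0, 50)
        with pytest.raises(ValueError):
            SizeMesh(0.0, 1.0, 1)

    def test_deposit_preserves_count_and_mean(self):
        mesh = SizeMesh.default()
        u = 1.2345
        n = mesh.deposit(u, 3.0)
        assert (n * mesh.h).sum() == pytest.approx(3.0)
        mean_u = (n * mesh.h * mesh.nodes).sum() / 3.0
        assert mean_u == pytest.approx(u, abs=1e-12)


def flat_community(**overrides):
    # growth SD must exceed the mesh step (~0.086 at the default mesh) for
    # the midpoint rule to integrate the growth density accurately
    sp = SpeciesParams(
        SurvivalParams(intercept=overrides.get("surv_logit", 1000.0),
                       crowding={"A": 0.0}, crowding_size={"A": 0.0}),
        GrowthParams(size=1.0, var_a=overrides.get("var_a", 0.02),
                     crowding={"A": 0.0}, crowding_size={"A": 0.0}),
        RecruitParams(intercept=overrides.get("rec_int", -1000.0),
                      dd={"A": 0.0}))
    return CommunityParams({"A": sp}, AlphaMatrix.uniform(["A"], 0.05))


class TestMeanCrowding:
    def _two_species_state(self, mesh, cover_A=0.0, cover_B=1000.0):
        state = {"A": np.zeros(mesh.n_nodes), "B": np.zeros(mesh.n_nodes)}
        i = mesh.n_nodes // 2
        for sp, cov in (("A", cover_A), ("B", cover_B)):
            if cov > 0:
                state[sp][i] = cov / np.exp(mesh.nodes[i]) / mesh.h
        return state

    def test_zero_heterospecific_cover_gives_zero(self):
        mesh = SizeMesh.default()
        state = self._two_species_state(mesh, cover_B=0.0)
        alphas = AlphaMatrix.uniform(["A", "B"], 0.05)
        w = mean_crowding(state, {"A": mesh, "B": mesh}, alphas, "A",
                          np.array([1.0]))
        assert w["B"][0] == 0.0

    def test_heterospecific_closed_form_matches_monte_carlo(self, rng):
        """π/α · cover-density (infinite-plane form) against a 10⁴-placement
        Monte-Carlo of the Gaussian crowding sum, focal at quadrat centre so
        boundary truncation is negligible at α = 0.05."""
        alpha, L = 0.05, 100.0
        mesh = SizeMesh.default()
        cover_B = 1500.0
        state = self._two_species_state(mesh, cover_B=cover_B)
        alphas = AlphaMatrix.uniform(["A", "B"], alpha)
        w = mean_crowding(state, {"A": mesh, "B": mesh}, alphas, "A",
                          np.array([1.0]), extent_cm=None)
        closed = w["B"][0]
        assert closed == pytest.approx(np.pi / alpha * cover_B / L ** 2)
        n_pl = 10_000
        n_per = 25  # neighbours per placement, each of cover_B/25
        u_nb = cover_B / n_per
        total = np.zeros(n_pl)
        for k in range(n_pl):
            x = rng.uniform(0, L, n_per)
            y = rng.uniform(0, L, n_per)
            d2 = (x - 50.0) ** 2 + (y - 50.0) ** 2
            total[k] = (u_nb * np.exp(-alpha * d2)).sum()
        mc, se = total.mean(), total.std(ddof=1) / np.sqrt(n_pl)
        assert abs(mc - closed) < 3 * se

    def test_conspecific_never_exceeds_random_value(self):
        mesh = SizeMesh.default()
        alphas = AlphaMatrix.uniform(["A"], 0.05)
        state = {"A": np.full(mesh.n_nodes, 0.5)}
        u = mesh.nodes[::10]
        w_excl = mean_crowding(state, {"A": mesh}, alphas, "A", u,
                               conspecific_exclusion=True)
        w_rand = mean_crowding(state, {"A": mesh}, alphas, "A", u,
                               conspecific_exclusion=False)
        assert np.all(w_excl["A"] <= w_rand["A"] + 1e-12)
        assert np.all(w_excl["A"] < w_rand["A"])  # radius > 0 always

    def test_boundary_factor_limits(self):
        # tight kernel in a big quadrat → infinite-plane limit
        assert boundary_factor(5.0, 10_000.0) == pytest.approx(1.0, abs=1e-3)
        assert boundary_factor(0.05, None) == 1.0
        # finite quadrat always reduces crowding
        assert boundary_factor(0.05, 100.0) < 1.0


class TestKernel:
    def test_identity_demography_conserves_numbers(self):
        """S ≡ 1, mean-identity growth, no recruits: genet numbers are
        conserved (growth noise only diffuses sizes)."""
        ipm = IPM(flat_community(), SizeMesh.default())
        mesh = ipm.meshes["A"]
        state = {"A": np.exp(-0.5 * (mesh.nodes - 2.0) ** 2)}
        new = ipm.step(state, None)
        n0 = (state["A"] * mesh.h).sum()
        n1 = (new["A"] * mesh.h).sum()
        assert n1 == pytest.approx(n0, rel=1e-3)

    def test_survivor_count_without_recruitment(self):
        from scipy.special import logit
        ipm = IPM(flat_community(surv_logit=float(logit(0.6)), var_a=0.05),
                  SizeMesh.default())
        mesh = ipm.meshes["A"]
        # interior bump, away from eviction at the mesh bounds
        state = {"A": np.exp(-0.5 * ((mesh.nodes - 2.0) / 0.8) ** 2)}
        n0 = (state["A"] * mesh.h).sum()
        new = ipm.step(state, None)
        n1 = (new["A"] * mesh.h).sum()
        assert n1 == pytest.approx(0.6 * n0, rel=5e-3)

    def test_kernel_survival_column_mass(self):
        """∫G(v,u)dv ≈ 1 on a fine mesh, so column mass ≈ S(u)."""
        from scipy.special import logit
        ipm = IPM(flat_community(surv_logit=float(logit(0.8)), var_a=0.05),
                  SizeMesh(-3.0, 9.0, 400))
        mesh = ipm.meshes["A"]
        Wbar = {"A": np.zeros(mesh.n_nodes)}
        K = ipm.build_kernel("A", None, YearDraw.zero(["A"]), Wbar,
                             lam=0.0, cover_j=0.0)
        col_mass = K.sum(axis=0) * mesh.h
        interior = slice(50, 350)  # away from eviction at the bounds
        assert np.allclose(col_mass[interior], 0.8, atol=1e-3)


class TestStep:
    def test_zero_state_is_absorbing(self):
        ipm = IPM(flat_community(rec_int=2.0), SizeMesh.default())
        state = ipm.zero_state()
        new = ipm.step(state, None)
        assert all(np.all(v == 0) for v in new.values())

    def test_geometric_regime_constant_cover_multiplier(self):
        """Size-independent survival, mean-identity growth, fecundity per
        cover: cover multiplies by s·e^{a/2} + 0.25·e^γ every step (the
        e^{a/2} is the lognormal mean of the growth noise)."""
        from scipy.special import logit
        s, g, a = 0.6, -1.0, 0.02
        # mesh extends far below the recruit size so growth noise around
        # the recruit node is not evicted at the lower bound
        ipm = IPM(flat_community(surv_logit=float(logit(s)), rec_int=g,
                                 var_a=a), SizeMesh(-4.0, 7.0, 300))
        state = {"A": ipm.point_mass("A", 50.0)}
        factor_expected = s * np.exp(a / 2) + 0.25 * np.exp(g)
        covs = [ipm.cover(state)["A"]]
        for _ in range(4):
            state = ipm.step(state, None)
            covs.append(ipm.cover(state)["A"])
        ratios = np.diff(np.log(covs))
        assert np.allclose(np.exp(ratios), factor_expected, rtol=2e-3)

    def test_mesh_doubling_changes_one_step_cover_below_tenth_percent(
            self, symmetric_setup):
        truth, community, climate, years = symmetric_setup
        C = climate.row(years[0])
        draw = YearDraw.from_year(community, years[0])
        covs = {}
        for n in (100, 200):
            ipm = IPM(community, SizeMesh.default(n_nodes=n))
            st = ipm.low_density_state(500.0)
            st = ipm.step(st, C, draw)
            covs[n] = ipm.cover(st)
        for sp in covs[100]:
            rel = abs(covs[200][sp] - covs[100][sp]) / covs[100][sp]
            assert rel < 1e-3

    def test_species_label_permutation_symmetry(self, symmetric_setup):
        truth, community, climate, years = symmetric_setup
        ipm = IPM(community, SizeMesh.default())
        C = climate.row(years[0])
        draw = YearDraw.from_year(community, years[0])
        state = {"A": ipm.point_mass("A", 100.0),
                 "B": ipm.point_mass("B", 700.0)}
        swapped = {"A": state["B"].copy(), "B": state["A"].copy()}
        out = ipm.step(state, C, draw)
        out_swapped = ipm.step(swapped, C, draw)
        assert np.allclose(out["A"], out_swapped["B"])
        assert np.allclose(out["B"], out_swapped["A"])


class TestStochasticRun:
    def test_zero_steps_returns_initial_state(self, symmetric_setup, rng):
        truth, community, climate, years = symmetric_setup
        ipm = IPM(community, SizeMesh.default())
        state = ipm.low_density_state()
        out = ipm.run_stochastic(state, 0, rng, climate, years)
        assert out is state

    def test_same_seed_identical_trajectories(self, symmetric_setup):
        truth, community, climate, years = symmetric_setup
        ipm = IPM(community, SizeMesh.default())
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            covs = []
            ipm.run_stochastic(ipm.low_density_state(), 20, rng, climate,
                               years,
                               record=lambda t, s: covs.append(
                                   ipm.cover(s)["A"]))
            outs.append(covs)
        assert outs[0] == outs[1]


class TestEquilibrium:
    def test_two_identical_species_equal_covers(self, symmetric_setup, rng):
        truth, community, climate, years = symmetric_setup
        ipm = IPM(community, SizeMesh.default())
        eq = ipm.equilibrium_cover(rng, climate, years, burn_in=200,
                                   window=400)
        assert eq.cover["A"] == pytest.approx(eq.cover["B"], rel=1e-9)
        assert not eq.extinct

    def test_deterministic_environment_window_variance_vanishes(
            self, symmetric_setup, rng):
        truth, community, climate, years = symmetric_setup
        from quadratdyn.data_io import ClimateTable
        one_year = ClimateTable(climate.site, climate.data.iloc[[0]])
        ipm = IPM(community, SizeMesh.default())
        eq = ipm.equilibrium_cover(rng, one_year, None, burn_in=300,
                                   window=200)
        traj = np.array(eq.trajectory["A"])
        assert traj.std() / traj.mean() < 1e-6

    def test_single_species_constant_environment_matches_fixed_point(
            self, rng):
        """Time-average equals the fixed point of the deterministic map."""
        from quadratdyn import synthetic_data as sd
        truth = sd.scenario("single-species")
        community = truth.community
        ipm = IPM(community, SizeMesh.default())
        C = {c: m for c, m in sd.DEFAULT_CLIMATE_MEANS.items()}
        C["ppt1T1"] = C["ppt1"] * C["T1"]
        C["ppt2T2"] = C["ppt2"] * C["T2"]
        # fixed-point iteration oracle: iterate the one-species map
        state = ipm.low_density_state()
        for _ in range(600):
            state = ipm.step(state, C)
        fp = ipm.cover(state)["SOLO"]
        state2 = ipm.step(state, C)
        assert ipm.cover(state2)["SOLO"] == pytest.approx(fp, rel=1e-6)
        # equilibrium_cover with a constant climate table reproduces it
        from quadratdyn.data_io import ClimateTable
        import pandas as pd
        clim = ClimateTable("S", pd.DataFrame(
            {c: [sd.DEFAULT_CLIMATE_MEANS[c]]
             for c in ("pptLag", "ppt1", "ppt2", "T1", "T2")},
            index=pd.Index([2000], name="year")))
        eq = ipm.equilibrium_cover(rng, clim, None, burn_in=600, window=50)
        assert eq.cover["SOLO"] == pytest.approx(fp, rel=1e-4)
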