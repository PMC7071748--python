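"""aSPU engine: statistics, null correlation, Monte-Carlo reference, oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aspugwas.aspu import (
    DEFAULT_GAMMAS,
    AspuConfig,
    ZPanel,
    aspu_test,
    build_reference,
    estimate_null_corr,
    nearest_psd_correlation,
    spu_stat,
    staged_aspu,
)
from aspugwas.simdata import default_trait_corr


# ---------------------------------------------------------------- oracle ---
def brute_force_aspu(z, null_draws, gammas=DEFAULT_GAMMAS):
    """O(b^2) reference implementation used to validate the fast path.

    Per-gamma observed p: (1 + #{null |SPU| >= observed |SPU|}) / (b + 1).
    Null draw i's leave-one-out per-gamma p: (1 + #{j != i: |SPU_j| >=
    |SPU_i|}) / b.  Adaptive p: (1 + #{i: min-p_i <= observed min-p}) / (b+1).
    """
    z = np.where(np.isnan(z), 0.0, np.asarray(z, dtype=float))
    b = null_draws.shape[0]

    def spu(v, g):
        if math.isinf(g):
            return max(abs(x) for x in v)
        return sum(x**g for x in v)

    A = np.array([[abs(spu(null_draws[i], g)) for g in gammas] for i in range(b)])
    obs = np.array([abs(spu(z, g)) for g in gammas])
    per_gamma = {}
    for gi, g in enumerate(gammas):
        count = int((A[:, gi] >= obs[gi]).sum())
        per_gamma[g] = (1 + count) / (b + 1)
    minp_obs = min(per_gamma.values())
    hits = 0
    for i in range(b):
        minp_i = math.inf
        for gi in range(len(gammas)):
            c = int(sum(1 for j in range(b) if j != i and A[j, gi] >= A[i, gi]))
            minp_i = min(minp_i, (1 + c) / b)
        if minp_i <= minp_obs:
            hits += 1
    return (1 + hits) / (b + 1), per_gamma


# ------------------------------------------------------------- spu_stat ---
class TestSpuStat:
    @pytest.mark.parametrize(
        "z,gamma,expected",
        [
            ((1, 0, 0, 0, 0, 0, 0), 1, 1.0),
            ((1, 0, 0, 0, 0, 0, 0), 2, 1.0),
            ((1, 0, 0, 0, 0, 0, 0), math.inf, 1.0),
            ((2, -2, 0, 0, 0, 0, 0), 1, 0.0),
            ((2, -2, 0, 0, 0, 0, 0), 2, 8.0),
            ((2, -2, 0, 0, 0, 0, 0), 3, 0.0),
            ((2, -2, 0, 0, 0, 0, 0), math.inf, 2.0),
            ((0,) * 7, 5, 0.0),
            ((0,) * 7, math.inf, 0.0),
        ],
    )
    def test_examples(self, z, gamma, expected):
        assert spu_stat(np.array(z, dtype=float), gamma) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        z=st.lists(st.floats(-5, 5), min_size=1, max_size=9),
        gamma=st.sampled_from([1, 2, 3, 4, 5, 6, 7, 8]),
    )
    def test_permutation_invariance_and_scaling(self, z, gamma):
        z = np.array(z)
        perm = z[::-1].copy()
        assert spu_stat(perm, gamma) == pytest.approx(spu_stat(z, gamma), rel=1e-9, abs=1e-9)
        assert spu_stat(2.0 * z, gamma) == pytest.approx(
            2.0**gamma * spu_stat(z, gamma), rel=1e-9, abs=1e-9
        )
        assert spu_stat(z, math.inf) == pytest.approx(np.abs(z).max())


# ----------------------------------------------------- null correlation ---
class TestNullCorr:
    def test_independent_traits_identity(self, rng):
        zp = ZPanel([f"v{i}" for i in range(10_000)], rng.standard_normal((10_000, 7)),
                    list("ABCDEFG"))
        nc = estimate_null_corr(zp)
        off = nc.sigma[~np.eye(7, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_duplicated_column_unit_correlation(self, rng):
        z = rng.standard_normal((2000, 2))
        z[:, 1] = z[:, 0]
        nc = estimate_null_corr(ZPanel([f"v{i}" for i in range(2000)], z, ["A", "B"]))
        assert nc.sigma[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_signal_trimming_matches_direct_correlation(self, rng):
        """Sigma-hat equals the plain correlation of the null z columns."""
        rho = 0.5
        n = 5000
        L = np.linalg.cholesky([[1, rho], [rho, 1]])
        z = rng.standard_normal((n, 2)) @ L.T
        nc = estimate_null_corr(ZPanel([f"v{i}" for i in range(n)], z, ["A", "B"]))
        kept = np.all(np.abs(z) < 2, axis=1)
        direct = np.corrcoef(z[kept], rowvar=False)[0, 1]
        assert nc.sigma[0, 1] == pytest.approx(direct, abs=1e-10)
        # and the trimmed estimate stays near the generating correlation
        # (attenuated slightly by truncation)
        assert abs(nc.sigma[0, 1] - rho) < 0.1

    def test_too_few_variants_error(self):
        with pytest.raises(ValueError):
            estimate_null_corr(ZPanel(["v1"], np.array([[0.1, 0.2]]), ["A", "B"]))

    def test_psd_repair(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = nearest_psd_correlation(bad)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        assert np.allclose(np.diag(fixed), 1.0)


# ------------------------------------------------------------ reference ---
class TestReference:
    def test_identity_spu2_is_chi_square(self):
        ref = build_reference(np.eye(7), 1_000_000, seed=3)
        gi = ref.gammas.index(2)
        mean = float(ref.sorted_abs[gi].mean())
        assert abs(mean - 7.0) / 7.0 < 0.01

    def test_fixed_seed_bit_identical(self):
        r1 = build_reference(np.eye(3), 5000, seed=7)
        r2 = build_reference(np.eye(3), 5000, seed=7)
        for a, b in zip(r1.sorted_abs, r2.sorted_abs):
            assert np.array_equal(a, b)
        assert np.array_equal(r1.sorted_null_minp, r2.sorted_null_minp)

    def test_reference_row_counts(self):
        ref = build_reference(np.eye(4), 100, seed=1)
        assert all(len(a) == 100 for a in ref.sorted_abs)
        assert len(ref.sorted_null_minp) == 100

    def test_memory_budget_enforced(self):
        with pytest.raises(MemoryError):
            build_reference(np.eye(7), 10**11, seed=0)


# ------------------------------------------------------------ aspu_test ---
class TestAspuTest:
    def test_zero_vector_p_near_one(self):
        ref = build_reference(np.eye(7), 2000, seed=5)
        res = aspu_test(np.zeros(7), ref)
        assert res.p_aspu > 0.99
        assert all(p > 0.99 for p in res.per_gamma_p.values())

    def test_floor_attained_for_extreme_z(self):
        ref = build_reference(np.eye(7), 1000, seed=9)
        z = np.array([8.0, 0, 0, 0, 0, 0, 0])
        res = aspu_test(z, ref)
        assert res.p_aspu == pytest.approx(1 / 1001, rel=1e-12)
        rng = np.random.default_rng(2)
        draws = rng.standard_normal((200, 7))
        ref_small = build_reference(np.eye(7), 200, draws=draws)
        p_fast = aspu_test(z, ref_small).p_aspu
        p_oracle, _ = brute_force_aspu(z, draws)
        assert p_fast == p_oracle == pytest.approx(1 / 201, rel=1e-12)

    def test_oracle_equivalence_random_vectors(self, rng):
        """Fast rank-based path == O(b^2) double loop, exactly (b = 200)."""
        b = 200
        sigma = default_trait_corr(7)
        L = np.linalg.cholesky(sigma)
        draws = rng.standard_normal((b, 7)) @ L.T
        ref = build_reference(sigma, b, draws=draws)
        for _ in range(50):
            z = rng.normal(0, 1.5, size=7)
            res = aspu_test(z, ref)
            p_oracle, per_gamma_oracle = brute_force_aspu(z, draws)
            assert res.p_aspu == p_oracle
            for g in DEFAULT_GAMMAS:
                assert res.per_gamma_p[g] == per_gamma_oracle[g]

    def test_missing_components_substituted_and_flagged(self):
        ref = build_reference(np.eye(7), 1000, seed=4)
        z = np.array([np.nan, 3.0, np.nan, 0.0, 0.0, 0.0, 0.0])
        res = aspu_test(z, ref)
        assert res.missing_traits == 2
        full = aspu_test(np.array([0.0, 3.0, 0, 0, 0, 0, 0]), ref)
        assert res.p_aspu == full.p_aspu

    def test_all_missing_errors(self):
        ref = build_reference(np.eye(2), 100, seed=1)
        with pytest.raises(ValueError, match="missing"):
            aspu_test(np.array([np.nan, np.nan]), ref)

    def test_lower_bound_and_adaptive_penalty_sweep(self, rng):
        """p_aspu >= 1/(1+b) and p_aspu >= min per-gamma p, over 10^4 inputs."""
        b = 1000
        ref = build_reference(np.eye(7), b, seed=13)
        for _ in range(10_000):
            z = rng.normal(0, rng.uniform(0.5, 3.0), size=7)
            res = aspu_test(z, ref)
            assert res.p_aspu >= 1 / (1 + b) - 1e-15
            assert res.p_aspu >= min(res.per_gamma_p.values()) - 1e-15

    def test_type_one_error_calibrated(self, rng):
        """Empirical alpha at 0.05 within 3 binomial SEs (5000 null variants)."""
        sigma = default_trait_corr(7)
        L = np.linalg.cholesky(sigma)
        ref = build_reference(sigma, 10_000, seed=17)
        z = rng.standard_normal((5000, 7)) @ L.T
        rejections = sum(aspu_test(z[i], ref).p_aspu <= 0.05 for i in range(5000))
        rate = rejections / 5000
        tol = 3 * np.sqrt(0.05 * 0.95 / 5000)
        assert abs(rate - 0.05) <= tol

    def test_power_dominates_bonferroni_best_trait(self, rng):
        """Equal effects on all 7 traits: aSPU rejects at least as often as
        the Bonferroni-corrected best single trait."""
        sigma = np.eye(7)
        ref = build_reference(sigma, 5000, seed=21)
        mu = 1.2
        n_sim = 400
        aspu_rej = bonf_rej = 0
        for _ in range(n_sim):
            z = mu + rng.standard_normal(7)
            if aspu_test(z, ref).p_aspu <= 0.05:
                aspu_rej += 1
            pmin = 2 * stats.norm.sf(np.abs(z)).min()
            if pmin * 7 <= 0.05:
                bonf_rej += 1
        se = np.sqrt(0.25 / n_sim)
        assert aspu_rej / n_sim >= bonf_rej / n_sim - 2 * se


# ---------------------------------------------------------------- staged ---
class TestStaged:
    def _panel(self, rng, m=500):
        z = rng.standard_normal((m, 7))
        z[0] = 8.0  # one strongly associated variant
        return ZPanel([f"v{i}" for i in range(m)], z, list("ABCDEFG"))

    def test_unpromising_variant_stays_at_first_stage(self, rng):
        zp = self._panel(rng)
        cfg = AspuConfig(b_max=10_000, b_schedule=(1000, 10_000), seed=3)
        out = staged_aspu(zp, np.eye(7), cfg)
        dull = out[out["Paspu"] > 0.3]
        assert (dull["Bused"] == 1000).all()

    def test_strong_variant_promoted_to_b_max(self, rng):
        zp = self._panel(rng)
        cfg = AspuConfig(b_max=10_000, b_schedule=(1000, 10_000), seed=3)
        out = staged_aspu(zp, np.eye(7), cfg)
        assert out.loc[out["MarkerName"] == "v0", "Bused"].iloc[0] == 10_000

    def test_promotion_superset_of_final_significant(self, rng):
        """Staged mode promotes every variant that full-b evaluation calls
        significant (two-mode comparison on 500 variants)."""
        zp = self._panel(rng)
        b_max = 10_000
        staged = staged_aspu(zp, np.eye(7), AspuConfig(b_max=b_max, b_schedule=(1000, b_max), seed=3))
        full = staged_aspu(zp, np.eye(7), AspuConfig(b_max=b_max, b_schedule=(b_max,), seed=3))
        alpha_final = 10.0 / b_max
        sig_full = set(full.loc[full["Paspu"] <= alpha_final, "MarkerName"])
        promoted = set(staged.loc[staged["Bused"] == b_max, "MarkerName"])
        assert sig_full <= promoted
        # and for promoted variants the two modes agree exactly
        merged = staged.merge(full, on="MarkerName", suffixes=("_s", "_f"))
        at_max = merged[merged["Bused_s"] == b_max]
        assert np.allclose(at_max["Paspu_s"], at_max["Paspu_f"])

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            AspuConfig(b_max=1000, b_schedule=(1000, 100))
        with pytest.raises(ValueError):
            AspuConfig(b_max=1000, b_schedule=(10, 100))

    def test_gamma_zero_optional_and_inert(self, rng):
        """Including gamma = 0 never changes the adaptive p (SPU(0) == K)."""
        z = rng.standard_normal(7) * 2
        with_zero = build_reference(np.eye(7), 2000, gamma_set=(0,) + DEFAULT_GAMMAS, seed=5)
        without = build_reference(np.eye(7), 2000, gamma_set=DEFAULT_GAMMAS, seed=5)
        r0 = aspu_test(z, with_zero)
        r1 = aspu_test(z, without)
        assert r0.per_gamma_p[0] == 1.0
        assert r0.p_aspu == r1.p_aspu
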