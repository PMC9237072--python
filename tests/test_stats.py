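import itertools
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats as sps

from phasic.containers import ValidationError
from phasic.stats import (bh_adjust, cpm, estimate_dispersion_mom,
                          hypergeom_enrich, ks_phase_preference,
                          moderated_t_test, nb_wald_test, tmm_factors)


def bh_stepup_reference(p):
    """Independent O(m^2) step-up: min over j>=rank(i) of m*p(j)/j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    for pos, i in enumerate(order):
        rank = pos + 1
        cands = [m * p[order[k]] / (k + 1) for k in range(pos, m)]
        out[i] = min(1.0, min(cands))
    return out


class TestBHAdjust:
    def test_single_value_identity(self):
        assert bh_adjust([0.05]).tolist() == [0.05]

    def test_equal_inputs_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 7), [0.2] * 7)

    def test_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_reference_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_reference(p),
                                       atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_permutation_invariance_and_dominance(self, p):
        p = np.asarray(p)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all((adj >= 0) & (adj <= 1))
        perm = np.random.default_rng(0).permutation(p.size)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-15)


def hypergeom_tail_enumeration(k, n, K, N):
    """Brute-force P(X >= k) by enumerating all C(N, n) draws."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


class TestHypergeomEnrich:
    def test_all_success_population(self):
        res = hypergeom_enrich(5, 5, 10, 10)
        assert res.p_value == 1.0
        assert res.fold_enrichment == 1.0

    def test_zero_overlap_tail_is_one(self):
        assert hypergeom_enrich(0, 5, 4, 10).p_value == 1.0

    def test_against_enumeration(self):
        res = hypergeom_enrich(3, 5, 4, 10)
        expect = hypergeom_tail_enumeration(3, 5, 4, 10)
        assert res.p_value == pytest.approx(expect, rel=1e-12)
        assert res.fold_enrichment == pytest.approx((3 / 5) / (4 / 10))

    def test_small_grid_exact(self):
        for N in (6, 9):
            for K in range(N + 1):
                for n in range(1, N + 1):
                    for k in range(min(n, K) + 1):
                        got = hypergeom_enrich(k, n, K, N).p_value
                        expect = hypergeom_tail_enumeration(k, n, K, N)
                        assert got == pytest.approx(expect, abs=1e-12)

    def test_log_space_survives_extreme_enrichment(self):
        res = hypergeom_enrich(81, 167, 500, 15000)
        assert 0 < res.p_value < 1e-50

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_enrich(6, 5, 10, 20)


def tmm_reference(Y, trim_m=0.3, trim_a=0.05):
    """Straightforward per-pair trimmed-mean re-implementation."""
    Y = np.asarray(Y, float)
    lib = Y.sum(0)
    uq = np.array([np.quantile(Y[:, j] / lib[j], 0.75) for j in range(Y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.ones(Y.shape[1])
    for j in range(Y.shape[1]):
        if j == ref:
            continue
        keep = (Y[:, j] > 0) & (Y[:, ref] > 0)
        pj = Y[keep, j] / lib[j]
        pr = Y[keep, ref] / lib[ref]
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        w = (lib[j] - Y[keep, j]) / (lib[j] * Y[keep, j]) \
            + (lib[ref] - Y[keep, ref]) / (lib[ref] * Y[keep, ref])
        lo_m, hi_m = np.quantile(M, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(A, [trim_a, 1 - trim_a])
        sel = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        f[j] = 2 ** (np.sum(M[sel] / w[sel]) / np.sum(1 / w[sel]))
    return f / np.exp(np.mean(np.log(f)))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        Y = np.tile(np.arange(1, 21)[:, None], (1, 4))
        np.testing.assert_allclose(tmm_factors(Y), np.ones(4), atol=1e-12)

    def test_invariant_to_column_rescaling(self, rng):
        # M-values are scale-free; the delta-method precision weights are
        # not exactly, so invariance to rescaling one column is approximate
        Y = rng.poisson(30.0, (200, 4)) + 1
        f1 = tmm_factors(Y)
        Y2 = Y.copy()
        Y2[:, 2] *= 5
        np.testing.assert_allclose(tmm_factors(Y2), f1, rtol=0.01)

    def test_spiked_column_matches_direct_formula(self, rng):
        Y = rng.poisson(50.0, (400, 3)) + 1
        spike = rng.choice(400, 20, replace=False)
        Y[spike, 0] *= 8
        np.testing.assert_allclose(tmm_factors(Y), tmm_reference(Y), rtol=1e-10)

    def test_product_is_one(self, rng):
        Y = rng.poisson(20.0, (300, 5)) + 1
        assert np.prod(tmm_factors(Y)) == pytest.approx(1.0, rel=1e-10)

    def test_all_zero_unit_rejected(self):
        Y = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValidationError, match="all-zero"):
            tmm_factors(Y)

    def test_matches_edger_on_spiked_instance(self, rng, tmp_path):
        """Independent cross-check against the canonical R implementation."""
        Y = rng.poisson(rng.lognormal(3, 1, 300)[:, None]
                        * np.ones((300, 5))).astype(int) + 1
        Y[rng.choice(300, 15, replace=False), 0] *= 8
        np.savetxt(tmp_path / "y.tsv", Y, fmt="%d", delimiter="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            y <- as.matrix(read.table('{tmp_path}/y.tsv'))
            cat(calcNormFactors(DGEList(counts=y))$samples$norm.factors, sep='\\n')
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        ref = np.array([float(x) for x in out.stdout.split()])
        np.testing.assert_allclose(tmm_factors(Y), ref, rtol=0.02)


class TestCPM:
    def test_forced_by_formula_single_unit(self):
        out = cpm(np.array([[1], [1], [2]]))
        np.testing.assert_allclose(out[:, 0], [250000, 250000, 500000])

    def test_random_matrix_matches_direct_formula(self, rng):
        Y = rng.poisson(5.0, (30, 6)) + 1
        f = rng.uniform(0.5, 2.0, 6)
        f = f / np.exp(np.mean(np.log(f)))
        expect = Y / (Y.sum(0) * f)[None, :] * 1e6
        np.testing.assert_allclose(cpm(Y, f), expect)


def moderated_t_reference(Y, design, coef):
    """Scalar step-by-step empirical-Bayes reference (brentq root-finding)."""
    from scipy.optimize import brentq
    n, p = design.shape
    df = n - p
    xtx_inv = np.linalg.inv(design.T @ design)
    betas, s2s = [], []
    for y in Y:
        b, *_ = np.linalg.lstsq(design, y, rcond=None)
        betas.append(b[coef])
        s2s.append(((y - design @ b) ** 2).sum() / df)
    s2s = np.array(s2s)
    z = np.log(s2s)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    d0 = 2 * brentq(lambda x: special.polygamma(1, x) - evar, 1e-6, 1e6)
    s0 = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
    post = (d0 * s0 + df * s2s) / (d0 + df)
    t = np.array(betas) / np.sqrt(post * xtx_inv[coef, coef])
    pv = 2 * sps.t.sf(np.abs(t), df + d0)
    return t, pv, d0, s0


class TestModeratedT:
    @staticmethod
    def _design(n_per_group):
        return np.column_stack([np.ones(2 * n_per_group),
                                np.repeat([0.0, 1.0], n_per_group)])

    def test_identical_groups_give_t_zero_p_one(self, rng):
        design = self._design(3)
        Y = rng.normal(size=(50, 6))
        Y[0] = np.tile([1.0, 2.0, 3.0], 2)   # same values in both groups
        res = moderated_t_test(Y, design, coef=1)
        assert res.table.loc[0, "t_moderated"] == pytest.approx(0.0, abs=1e-10)
        assert res.table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_matches_step_by_step_reference(self, rng):
        design = self._design(3)
        Y = rng.normal(5.0, 1.0, size=(200, 6)) \
            * rng.uniform(0.5, 2.0, 200)[:, None]
        res = moderated_t_test(Y, design, coef=1)
        t, pv, d0, s0 = moderated_t_reference(Y, design, 1)
        np.testing.assert_allclose(res.table["t_moderated"], t, rtol=1e-6)
        np.testing.assert_allclose(res.table["p_value"], pv, rtol=1e-6)
        assert res.prior_df == pytest.approx(d0, rel=1e-4)
        assert res.prior_var == pytest.approx(s0, rel=1e-4)

    def test_matches_limma_on_small_instance(self, rng, tmp_path):
        """Dual-route check against the canonical R implementation."""
        design = self._design(3)
        Y = rng.normal(4.0, 1.0, size=(150, 6))
        np.savetxt(tmp_path / "y.tsv", Y, delimiter="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            y <- as.matrix(read.table('{tmp_path}/y.tsv'))
            design <- cbind(1, rep(c(0, 1), each=3))
            fit <- eBayes(lmFit(y, design))
            write.table(cbind(fit$t[,2], fit$p.value[,2]),
                        '{tmp_path}/ref.tsv', row.names=FALSE, col.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        ref = np.loadtxt(tmp_path / "ref.tsv")
        res = moderated_t_test(Y, design, coef=1)
        np.testing.assert_allclose(res.table["t_moderated"], ref[:, 0],
                                   rtol=1e-6)
        np.testing.assert_allclose(res.table["p_value"], ref[:, 1], rtol=1e-6)

    def test_shared_variance_approaches_pooled_t(self, rng):
        # all genes share one true variance -> prior df large, moderated t
        # close to the ordinary t computed with the pooled variance
        design = self._design(4)
        Y = rng.normal(0.0, 1.0, size=(3000, 8))
        res = moderated_t_test(Y, design, coef=1)
        assert res.prior_df > 10
        pooled = ((Y - Y @ design @ np.linalg.inv(design.T @ design) @ design.T)
                  ** 2).sum() / (3000 * 6)
        b = (Y @ design @ np.linalg.inv(design.T @ design))[:, 1]
        t_pooled = b / np.sqrt(pooled * np.linalg.inv(design.T @ design)[1, 1])
        corr = np.corrcoef(res.table["t_moderated"], t_pooled)[0, 1]
        assert corr > 0.99

    def test_null_p_values_uniform(self, rng):
        design = self._design(3)
        Y = rng.normal(0.0, 1.0, size=(2000, 6)) \
            * rng.uniform(0.5, 2.0, 2000)[:, None]
        res = moderated_t_test(Y, design, coef=1)
        ks = sps.kstest(res.table["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_saturated_design_rejected(self, rng):
        with pytest.raises(ValidationError, match="saturated"):
            moderated_t_test(rng.normal(size=(5, 2)), np.eye(2), coef=1)


class TestNBWald:
    def test_poisson_limit_matches_glm_oracle(self, rng):
        import statsmodels.api as sm
        n = 16
        Y = rng.poisson(50.0, size=(20, n))
        phase = np.array(["G1"] * 8 + ["G2M"] * 8)
        res = nb_wald_test(Y, phase, dispersion=0.0)
        lib = Y.sum(0).astype(float)
        X = np.column_stack([np.ones(n), (phase == "G2M").astype(float)])
        for g in range(5):
            z = Y[g] / lib * 1e6
            fit = sm.GLM(z, X, family=sm.families.Poisson()).fit()
            assert res.loc[g, "log2fc"] == pytest.approx(
                fit.params[1] / np.log(2), abs=1e-5)

    def test_planted_fold_change_recovered(self, rng):
        # 200 genes at NB(100) in G1 vs NB(200) in G2M, n=20 per group,
        # plus a dominant stable ballast gene so library sizes stay
        # comparable and the planted ratio survives normalization
        n = 40
        G = 200
        phase = np.array(["G1"] * 20 + ["G2M"] * 20)
        mu = np.where(phase == "G2M", 200.0, 100.0)
        phi = 0.1
        lam = rng.gamma(1 / phi, phi * np.tile(mu, (G, 1)))
        Y = np.vstack([rng.poisson(lam),
                       rng.poisson(np.full(n, 1e6))])
        res = nb_wald_test(Y, phase)
        assert res["log2fc"][:G].mean() == pytest.approx(1.0, abs=0.1)

    def test_null_large_n_fold_changes_shrink(self, rng):
        G, n = 300, 200
        phi = 0.2
        lam = rng.gamma(1 / phi, phi * 50.0 * np.ones((G, n)))
        Y = rng.poisson(lam)
        phase = np.array(["G1"] * 100 + ["G2M"] * 100)
        res = nb_wald_test(Y, phase)
        assert np.abs(res["log2fc"]).mean() < 0.1
        pv = res["p_value"].dropna()
        assert sps.kstest(pv, "uniform").pvalue > 0.001

    def test_needs_two_units_per_phase(self, rng):
        with pytest.raises(ValidationError):
            nb_wald_test(rng.poisson(5, (10, 3)),
                         np.array(["G1", "G2M", "G2M"]))


class TestKSPhasePreference:
    def test_identical_scores_not_phase_specific(self):
        scores = np.tile(np.arange(10.0), 2)
        phases = np.repeat(["G1", "G2M"], 10)
        d, p, specific = ks_phase_preference(scores, phases)
        assert d == 0 and not specific

    def test_strong_shift_is_phase_specific(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 1000),
                                 rng.normal(1, 1, 1000)])
        phases = np.repeat(["G1", "G2M"], 1000)
        d, p, specific = ks_phase_preference(scores, phases)
        assert p < 1e-12 and specific

    def test_tiny_samples_cannot_reach_threshold(self, rng):
        scores = np.array([0.0, 0.1, 0.2, 100.0, 101.0, 102.0])
        phases = np.repeat(["G1", "G2M"], 3)
        d, p, specific = ks_phase_preference(scores, phases)
        assert not specific  # discrete p floor at n=3 per phase

    def test_single_unit_phase_rejected(self):
        with pytest.raises(ValidationError):
            ks_phase_preference([1.0, 2.0, 3.0], ["G1", "G2M", "G2M"])
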