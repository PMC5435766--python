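import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from hybridqg import genotype, gwas, kernels, phenostat, simdata
from hybridqg.core import (
    DataError,
    PhenotypeTable,
    STAGE_ACROSS,
    STAGE_WITHIN,
    default_map,
)
from hybridqg.mixedlm import spectral_reml


def _means_from_values(ids, values, env="E1", stage=STAGE_WITHIN):
    df = pd.DataFrame(
        {"genotype_id": ids, "environment": env, "replicate": 1, "value": values}
    )
    return PhenotypeTable(df, stage=stage)


def _stacked_means(ids, values_by_env):
    rows = []
    for env, vals in values_by_env.items():
        for g, v in zip(ids, vals):
            rows.append((g, env, 1, v))
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["genotype_id", "environment", "replicate", "value"]),
        stage=STAGE_WITHIN,
    )


@pytest.fixture(scope="module")
def scan_population():
    gmap = default_map(n_chromosomes=4, chrom_length_cm=80, markers_per_chrom=10)
    dh = simdata.simulate_dh_population(gmap, 60, seed=42)
    design = simdata.make_crossing_design(list(dh.individual_ids), 100, seed=42)
    hyb = genotype.infer_hybrid_genotypes(dh, design)
    pop = dh.concat(hyb)
    dm = genotype.f_infinity_design(pop)
    kin = kernels.rogers_kinship(pop)
    return pop, dm, kin


class TestHolm:
    def test_stepdown_example(self):
        p = [0.001, 0.01, 0.03, 0.04, 0.2]
        flags = gwas.holm_correct(p, alpha=0.1)
        assert flags.tolist() == [True, True, True, True, False]

    def test_all_ones(self):
        assert not gwas.holm_correct([1.0] * 5, alpha=0.1).any()

    def test_single_p(self):
        assert gwas.holm_correct([0.09], alpha=0.1).tolist() == [True]

    def test_subset_of_unadjusted(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        flags = gwas.holm_correct(p, alpha=0.1)
        assert np.all(p[flags] < 0.1)

    def test_nonfinite_rejected(self):
        with pytest.raises(DataError):
            gwas.holm_correct([0.1, np.nan])


class TestMainEffectScan:
    def test_exact_mode_matches_gls_oracle(self, scan_population):
        pop, dm, kin = scan_population
        idx = np.arange(25)
        sub = pop.subset_individuals(idx)
        dm_sub = genotype.f_infinity_design(sub)
        kin_sub = kernels.rogers_kinship(sub)
        rng = np.random.default_rng(1)
        y = 0.4 * dm_sub.A[:, 3] + rng.normal(0, 1, 25)
        means = _means_from_values(list(sub.individual_ids), y)
        res = gwas.main_effect_scan(means, dm_sub, kin_sub, mode="exact")
        # oracle: per marker, REML via spectral path, then explicit-V GLS by Cholesky
        K = kin_sub.values
        for j in [0, 3, 7, 19]:
            cols = []
            if np.std(dm_sub.A[:, j]) > 0:
                cols.append(dm_sub.A[:, j])
            if np.std(dm_sub.D[:, j]) > 0:
                cols.append(dm_sub.D[:, j])
            if not cols:
                continue
            X = np.column_stack([np.ones(25)] + cols)
            null = spectral_reml(y, X, K=K)
            V = null.sigma2_u * K + null.sigma2_e * np.eye(25)
            cf = linalg.cho_factor(V)
            ViX = linalg.cho_solve(cf, X)
            XtViX = X.T @ ViX
            beta = np.linalg.solve(XtViX, X.T @ linalg.cho_solve(cf, y))
            r = y - X @ beta
            df = 25 - X.shape[1]
            s2 = float(r @ linalg.cho_solve(cf, r)) / df
            cov = np.linalg.inv(XtViX) * s2
            t = beta / np.sqrt(np.diag(cov))
            p_orc = 2 * stats.t.sf(np.abs(t), df)
            row = res.table.iloc[j]
            assert row["p_a"] == pytest.approx(p_orc[1], abs=1e-8)
            if len(cols) == 2:
                assert row["p_d"] == pytest.approx(p_orc[2], abs=1e-8)

    def test_planted_qtl_found(self, scan_population):
        pop, dm, kin = scan_population
        rng = np.random.default_rng(7)
        qtl = 17
        y = 1.2 * dm.A[:, qtl] + rng.normal(0, 0.5, pop.n_individuals)
        means = _means_from_values(list(pop.individual_ids), y)
        res = gwas.main_effect_scan(means, dm, kin)
        best = int(np.argmin(res.table["p_a"].to_numpy()))
        r2 = np.corrcoef(dm.A[:, best], dm.A[:, qtl])[0, 1] ** 2
        assert best == qtl or r2 > 0.9

    def test_constant_marker_flagged(self, scan_population):
        pop, dm, kin = scan_population
        dm2 = genotype.f_infinity_design(pop)
        dm2.A[:, 5] = 1.0
        dm2.D[:, 5] = 0.0
        rng = np.random.default_rng(3)
        means = _means_from_values(list(pop.individual_ids), rng.normal(size=pop.n_individuals))
        res = gwas.main_effect_scan(means, dm2, kin)
        row = res.table.iloc[5]
        assert row["p_a"] == 1.0 and "constant" in row["flag"]

    def test_p3d_close_to_exact(self):
        # polygenic background, no major QTL, at the reference trial's size:
        # per-marker variance components stay near the null fit, so the
        # shortcut tracks the exact scan for 95% of markers
        gmap = default_map(n_chromosomes=19, chrom_length_cm=80, markers_per_chrom=10)
        dh = simdata.simulate_dh_population(gmap, 180, seed=42)
        design_cr = simdata.make_crossing_design(list(dh.individual_ids), 318, seed=42)
        pop = dh.concat(genotype.infer_hybrid_genotypes(dh, design_cr))
        dm = genotype.f_infinity_design(pop)
        kin = kernels.rogers_kinship(pop)
        rng = np.random.default_rng(11)
        u = dm.A @ rng.normal(0, 0.02, dm.n_markers)
        y = u + rng.normal(0, 0.5, pop.n_individuals)
        means = _means_from_values(list(pop.individual_ids), y)
        p3d = gwas.main_effect_scan(means, dm, kin, mode="p3d").table
        exact = gwas.main_effect_scan(means, dm, kin, mode="exact").table
        for term in ("p_a", "p_d"):
            lp3d = -np.log10(np.clip(p3d[term].to_numpy(), 1e-300, 1))
            lex = -np.log10(np.clip(exact[term].to_numpy(), 1e-300, 1))
            rel = np.abs(lp3d - lex) / np.maximum(lex, 0.05)
            assert np.mean(rel < 0.10) >= 0.95

    def test_environment_stacking(self, scan_population):
        pop, dm, kin = scan_population
        rng = np.random.default_rng(5)
        base = 0.8 * dm.A[:, 2]
        means = _stacked_means(
            list(pop.individual_ids),
            {
                "E1": base + rng.normal(0, 0.4, pop.n_individuals),
                "E2": 0.5 + base + rng.normal(0, 0.4, pop.n_individuals),
            },
        )
        res = gwas.main_effect_scan(means, dm, kin)
        assert int(np.argmin(res.table["p_a"].to_numpy())) == 2


class TestEpistasisScan:
    def test_pair_coefficients_match_weighted_regression(self, scan_population):
        pop, dm, kin = scan_population
        idx = np.arange(30)
        sub = pop.subset_individuals(idx)
        dm_sub = genotype.f_infinity_design(sub)
        kin_sub = kernels.rogers_kinship(sub)
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 30) + 0.5 * dm_sub.A[:, 0] * dm_sub.A[:, 25]
        means = _means_from_values(list(sub.individual_ids), y)
        res = gwas.epistasis_scan_2d(
            means, dm_sub, kin_sub, marker_idx=np.array([0, 25])
        )
        assert len(res.table) == 1
        # oracle: GLS via explicit V^{-1/2} weighting on the same null components
        K = kin_sub.values
        X0 = np.ones((30, 1))
        null = spectral_reml(y, X0, K=K)
        V = null.sigma2_u * K + null.sigma2_e * np.eye(30)
        W = np.linalg.cholesky(np.linalg.inv(V))
        M = gwas._pair_columns(dm_sub.A, dm_sub.D, 0, 25)
        keep = M.std(axis=0) > 0
        X = np.column_stack([X0, M[:, keep]])
        bw, *_ = np.linalg.lstsq(W.T @ X, W.T @ y, rcond=None)
        row = res.table.iloc[0]
        got = [row[f"beta_{t}"] for t in ("a1", "a2", "d1", "d2", "i11", "i12", "i21", "i22")]
        got = [g for g in got if np.isfinite(g)]
        assert np.allclose(got, bw[1:], atol=1e-8)

    def test_planted_dd_interaction_detected(self):
        gmap = default_map(n_chromosomes=3, chrom_length_cm=60, markers_per_chrom=5)
        hits = 0
        for seed in range(5):
            dh = simdata.simulate_dh_population(gmap, 80, seed=seed)
            design = simdata.make_crossing_design(list(dh.individual_ids), 150, seed=seed)
            hyb = genotype.infer_hybrid_genotypes(dh, design)
            pop = dh.concat(hyb)
            dm = genotype.f_infinity_design(pop)
            kin = kernels.rogers_kinship(pop)
            rng = np.random.default_rng(seed)
            i, j = 1, 8
            y = 1.5 * dm.D[:, i] * dm.D[:, j] + rng.normal(0, 0.4, pop.n_individuals)
            means = _means_from_values(list(pop.individual_ids), y)
            res = gwas.epistasis_scan_2d(means, dm, kin)
            t = res.table
            best = t.iloc[int(np.nanargmin(t["p_i22"].to_numpy()))]
            if {best["marker_1"], best["marker_2"]} == {
                dm.map.marker_id[i], dm.map.marker_id[j]
            }:
                hits += 1
        assert hits >= 4

    def test_linked_pairs_skipped(self, scan_population):
        pop, dm, kin = scan_population
        pairs, skipped = gwas.candidate_pairs(dm, min_cm=10.0)
        for (i, j) in pairs:
            same = dm.map.chromosome[i] == dm.map.chromosome[j]
            assert not (same and abs(dm.map.position_cm[i] - dm.map.position_cm[j]) < 10)
        assert any(reason == "linked" for *_, reason in skipped)


class TestPermutationThreshold:
    def test_quantile_definition_and_determinism(self, scan_population):
        pop, dm, kin = scan_population
        rng = np.random.default_rng(9)
        means = _means_from_values(list(pop.individual_ids), rng.normal(size=pop.n_individuals))
        groups = dict(zip(pop.individual_ids, pop.group))
        idx = np.array([0, 11, 22, 33])
        kw = dict(groups=groups, n_perm=60, alpha=0.05, marker_idx=idx)
        t1 = gwas.permutation_threshold(means, dm, kin, seed=4, **kw)
        t2 = gwas.permutation_threshold(means, dm, kin, seed=4, **kw)
        assert t1 == t2
        assert set(t1) == set(gwas.EPI_TERMS)
        assert all(0 < v <= 1 for v in t1.values())

    def test_nperm_too_small(self, scan_population):
        pop, dm, kin = scan_population
        rng = np.random.default_rng(9)
        means = _means_from_values(list(pop.individual_ids), rng.normal(size=pop.n_individuals))
        groups = dict(zip(pop.individual_ids, pop.group))
        with pytest.raises(DataError):
            gwas.permutation_threshold(means, dm, kin, groups, n_perm=20, alpha=0.05)

    def test_permutation_preserves_multienv_vectors(self, scan_population):
        pop, *_ = scan_population
        groups = dict(zip(pop.individual_ids, pop.group))
        rng = np.random.default_rng(0)
        mapping = gwas.permute_within_groups(pop.individual_ids, groups, rng)
        for src, dst in mapping.items():
            assert groups[src] == groups[dst]
        assert sorted(mapping.values()) == sorted(mapping.keys())


class TestExplainedVariance:
    def test_orthogonal_increments(self):
        rng = np.random.default_rng(1)
        n = 400
        x1 = np.repeat([1.0, -1.0], n // 2)
        x2 = np.tile([1.0, -1.0], n // 2)  # orthogonal to x1
        y = 0.5 * x1 + 0.3 * x2 + rng.normal(0, 0.3, n)
        means = _means_from_values([f"g{i}" for i in range(n)], y, stage=STAGE_ACROSS)
        ev = gwas.explained_variance(means, [x1, x2], [0.001, 0.01], h2=1.0)
        inc = ev.per_qtl["r2_increment"].to_numpy()
        r2_1 = gwas._adjusted_r2(y, x1.reshape(-1, 1))
        r2_2 = gwas._adjusted_r2(y, x2.reshape(-1, 1))
        assert inc[0] == pytest.approx(r2_1, abs=5e-3)
        assert inc[1] == pytest.approx(r2_2, abs=5e-3)

    def test_total_equals_direct_fit(self):
        rng = np.random.default_rng(2)
        n = 120
        cols = [rng.normal(size=n) for _ in range(4)]
        y = cols[0] + 0.5 * cols[1] + rng.normal(0, 1, n)
        means = _means_from_values([f"g{i}" for i in range(n)], y, stage=STAGE_ACROSS)
        ev = gwas.explained_variance(means, cols, [0.01, 0.02, 0.5, 0.9], h2=0.8)
        direct = gwas._adjusted_r2(y, np.column_stack(cols))
        assert ev.total_r2 == pytest.approx(direct, abs=1e-10)
        assert np.sum(ev.per_qtl["r2_increment"]) == pytest.approx(ev.total_r2, abs=1e-10)

    def test_collinear_dropped_and_pg_capped(self):
        rng = np.random.default_rng(3)
        n = 60
        x = rng.normal(size=n)
        y = x.copy()  # perfect fit: raw pG > 1 for small h2
        means = _means_from_values([f"g{i}" for i in range(n)], y, stage=STAGE_ACROSS)
        with pytest.warns(UserWarning):
            ev = gwas.explained_variance(means, [x, 2 * x], [0.001, 0.01], h2=0.5)
        assert ev.pg == 1.0 and ev.capped
        assert ev.per_qtl["r2_increment"].iloc[1] == 0.0

    def test_no_qtl_rejected(self):
        means = _means_from_values(["a", "b"], [1.0, 2.0], stage=STAGE_ACROSS)
        with pytest.raises(DataError):
            gwas.explained_variance(means, [], [], h2=0.5)


class TestCvMapping:
    def test_fold_determinism(self):
        rng = np.random.default_rng(0)
        ids = np.array([f"h{i}" for i in range(50)], dtype=object)
        f1 = gwas.hybrid_folds(ids, 5, np.random.default_rng(3))
        f2 = gwas.hybrid_folds(ids, 5, np.random.default_rng(3))
        assert f1 == f2
        assert sorted(x for f in f1 for x in f) == sorted(ids)

    def test_perfect_single_qtl_accuracy_one(self, scan_population):
        pop, dm, kin = scan_population
        qtl = 13
        y = dm.A[:, qtl].astype(float)  # fully marker-determined, H2 = 1
        stacked = _means_from_values(list(pop.individual_ids), y)
        across = _means_from_values(list(pop.individual_ids), y, env="ALL", stage=STAGE_ACROSS)
        groups = dict(zip(pop.individual_ids, pop.group))
        res = gwas.cv_mapping_accuracy(
            stacked, across, dm, pop, groups, h2=1.0, folds=5, seed=1
        )
        ok = res[res["flag"] == ""]
        assert len(ok) >= 4
        assert np.allclose(ok["accuracy"], 1.0, atol=1e-6)
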