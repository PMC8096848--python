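"""Synthetic cohort generator: planted structure, determinism, calibration."""
import numpy as np
import pytest
from scipy import stats
from sklearn.linear_model import LogisticRegression

from gcsex.simulate import (
    CohortConfig,
    generate_cohorts,
    generate_promoters,
    generate_survival,
    generate_utrs,
    plant_hormone_module,
)
from gcsex.survival import logrank
from gcsex.targets import MIR125B_5P, compile_seed_patterns, scan_promoter_halfsites, scan_utr


class TestGenerateCohorts:
    def test_sex_counts_forced_by_config(self):
        cfg = CohortConfig(n_samples=100, n_genes=50, male_fraction=0.5,
                           n_y_linked=2, n_xist_like=1, n_xci_escape=2)
        cohorts = generate_cohorts(cfg, n_cohorts=5, seed=0)
        assert len(cohorts) == 5
        for mat, table, ann in cohorts:
            assert sum(s == "male" for s in table.sex) == 50
            assert mat.values.shape == (50, 100)

    def test_y_linked_at_floor_in_every_female(self):
        cfg = CohortConfig(n_samples=60, n_genes=40, n_y_linked=4,
                           n_xist_like=2, n_xci_escape=3, floor_value=1.25)
        mat, table, _ = generate_cohorts(cfg, 1, seed=5)[0]
        females = ~table.is_male
        males = table.is_male
        for g in cfg.planted_sex_genes[:4]:
            assert np.all(mat.row(g)[females] == 1.25)
            assert np.all(mat.row(g)[males] != 1.25)
        for g in cfg.planted_sex_genes[4:6]:  # XIST-like: silent in males
            assert np.all(mat.row(g)[males] == 1.25)

    def test_xci_escape_shift(self):
        cfg = CohortConfig(n_samples=4000, n_genes=30, n_y_linked=1,
                           n_xist_like=1, n_xci_escape=5, sex_effect_size=1.0,
                           male_fraction=0.5)
        mat, table, _ = generate_cohorts(cfg, 1, seed=2)[0]
        g = cfg.planted_sex_genes[2]
        shift = mat.row(g)[~table.is_male].mean() - mat.row(g)[table.is_male].mean()
        assert shift == pytest.approx(1.0, abs=0.1)

    def test_deterministic_per_seed(self):
        cfg = CohortConfig(n_samples=30, n_genes=25, n_y_linked=2,
                           n_xist_like=1, n_xci_escape=2)
        a = generate_cohorts(cfg, 2, seed=9)
        b = generate_cohorts(cfg, 2, seed=9)
        c = generate_cohorts(cfg, 2, seed=10)
        for (m1, _, _), (m2, _, _) in zip(a, b):
            np.testing.assert_array_equal(m1.values, m2.values)
        assert not np.array_equal(a[0][0].values, c[0][0].values)

    def test_cohorts_share_genes_but_not_noise(self):
        cfg = CohortConfig(n_samples=30, n_genes=25, n_y_linked=2,
                           n_xist_like=1, n_xci_escape=2)
        cohorts = generate_cohorts(cfg, 3, seed=1)
        assert cohorts[0][0].gene_ids == cohorts[1][0].gene_ids
        assert not np.array_equal(cohorts[0][0].values, cohorts[1][0].values)

    def test_planted_counts_exceeding_genes_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            CohortConfig(n_samples=10, n_genes=5, n_y_linked=4,
                         n_xist_like=4, n_xci_escape=4)

    def test_planted_genes_separate_sexes_with_logistic_fit(self):
        cfg = CohortConfig(n_samples=200, n_genes=100, n_y_linked=5,
                           n_xist_like=3, n_xci_escape=7, seed=3)
        mat, table, _ = generate_cohorts(cfg, 1, seed=3)[0]
        idx = [mat.gene_index(g) for g in cfg.planted_sex_genes]
        X = mat.values[idx].T
        y = table.is_male.astype(int)
        acc = LogisticRegression(max_iter=2000).fit(X, y).score(X, y)
        assert acc >= 0.95


class TestHormoneModule:
    def test_rho_one_gives_perfect_correlation(self, small_cohort):
        _, mat, _, _ = small_cohort
        out = plant_hormone_module(mat, "G00000", "G00001", rho=1.0, seed=4)
        r = np.corrcoef(out.row("G00000"), out.row("G00001"))[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("rho", [0.0, 0.5])
    def test_empirical_r_within_fisher_interval(self, rho):
        # Fisher-z 99% interval at n=10000: atanh(r) ~ N(atanh(rho), 1/sqrt(n-3))
        n = 10000
        cfg = CohortConfig(n_samples=n, n_genes=10, n_y_linked=1,
                           n_xist_like=1, n_xci_escape=1)
        mat, _, _ = generate_cohorts(cfg, 1, seed=8)[0]
        out = plant_hormone_module(mat, "G00000", "G00001", rho=rho, seed=8)
        r = np.corrcoef(out.row("G00000"), out.row("G00001"))[0, 1]
        halfwidth = 2.576 / np.sqrt(n - 3)
        lo = np.tanh(np.arctanh(rho) - halfwidth)
        hi = np.tanh(np.arctanh(rho) + halfwidth)
        assert lo <= r <= hi
        assert abs(r - rho) <= 3.0 / np.sqrt(n)

    def test_host_genes_correlate_with_mirna(self, small_cohort):
        _, mat, _, _ = small_cohort
        out = plant_hormone_module(mat, "G00000", "G00001", ("G00002", "G00003"),
                                   rho=0.5, rho_host=0.9, seed=1)
        r = np.corrcoef(out.row("G00002"), out.row("G00001"))[0, 1]
        assert r > 0.7

    def test_unknown_gene_rejected(self, small_cohort):
        _, mat, _, _ = small_cohort
        with pytest.raises(KeyError):
            plant_hormone_module(mat, "NOPE", "G00001")


class TestGenerateSurvival:
    def _table(self, n, seed=0):
        cfg = CohortConfig(n_samples=n, n_genes=5, n_y_linked=1,
                           n_xist_like=1, n_xci_escape=1)
        return generate_cohorts(cfg, 1, seed=seed)[0][1]

    def test_zero_censoring_gives_all_events(self):
        table = self._table(100)
        x = np.zeros((1, 100))
        out = generate_survival(table, x, np.array([0.0]), censor_rate=0.0, seed=1)
        assert out.event.sum() == 100

    def test_censor_rate_calibrated(self):
        table = self._table(4000)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 4000))
        out = generate_survival(table, x, np.array([0.5]), censor_rate=0.3, seed=2)
        assert 1 - out.event.mean() == pytest.approx(0.3, abs=0.04)

    def test_null_betas_give_uniform_logrank_p(self):
        # under beta=0 the log-rank p across replicates is ~U(0,1)
        table = self._table(80)
        groups = np.array(["a"] * 40 + ["b"] * 40)
        ps = []
        for rep in range(200):
            out = generate_survival(table, np.zeros((1, 80)), np.array([0.0]),
                                    censor_rate=0.1, seed=1000 + rep)
            ps.append(logrank(out.time, out.event, groups)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_beta_recovered_by_cox(self):
        import pandas as pd

        from gcsex.survival import cox_fit

        table = self._table(2000)
        rng = np.random.default_rng(3)
        x = (rng.random(2000) < 0.5).astype(float)
        out = generate_survival(table, x[None, :], np.array([np.log(1.5)]),
                                censor_rate=0.2, seed=3)
        df = pd.DataFrame({"time": out.time, "event": out.event, "x": x})
        fit = cox_fit(df, ["x"])
        assert fit.beta[0] == pytest.approx(np.log(1.5), abs=0.1)

    def test_misaligned_covariates_rejected(self):
        table = self._table(10)
        with pytest.raises(ValueError):
            generate_survival(table, np.zeros((1, 7)), np.array([0.0]))


class TestGenerateUtrs:
    def test_planted_plan_recovered_exactly(self):
        plan = {"geneA": {"8mer": 1}, "geneB": {"7mer-m8": 2, "6mer": 1}}
        utrs = generate_utrs(["geneA", "geneB"], ["d1", "d2"], MIR125B_5P,
                             sites_per_target=plan, utr_length=400, seed=6)
        seed = compile_seed_patterns(MIR125B_5P)
        sites_a = scan_utr(utrs.sequences["geneA"], seed)
        assert [s.site_type for s in sites_a] == ["8mer"]
        types_b = sorted(s.site_type for s in scan_utr(utrs.sequences["geneB"], seed))
        assert types_b == ["6mer", "7mer-m8", "7mer-m8"]

    def test_decoys_have_no_sites(self):
        utrs = generate_utrs(["t"], ["d1", "d2", "d3"], MIR125B_5P,
                             utr_length=300, seed=7)
        seed = compile_seed_patterns(MIR125B_5P)
        for g in ("d1", "d2", "d3"):
            assert scan_utr(utrs.sequences[g], seed) == []

    def test_alphabet_and_determinism(self):
        a = generate_utrs(["t"], ["d"], MIR125B_5P, utr_length=200, seed=1)
        b = generate_utrs(["t"], ["d"], MIR125B_5P, utr_length=200, seed=1)
        assert a.sequences == b.sequences
        assert set("".join(a.sequences.values())) <= set("ACGT")

    def test_infeasible_plan_rejected(self):
        with pytest.raises(ValueError):
            generate_utrs(["t"], [], MIR125B_5P, utr_length=6, seed=0)


class TestGeneratePromoters:
    def test_exact_half_site_counts(self):
        proms = generate_promoters({"p1": 1, "p2": 3, "p0": 0},
                                   promoter_length=800, seed=2)
        assert len(scan_promoter_halfsites(proms["p1"], span=800)) == 1
        assert len(scan_promoter_halfsites(proms["p2"], span=800)) == 3
        assert scan_promoter_halfsites(proms["p0"], span=800) == []


class TestCountMode:
    def test_nb_counts_feed_cpm_and_keep_sex_signal(self):
        from gcsex.preprocess import cpm_log_normalize

        cfg = CohortConfig(n_samples=120, n_genes=80, n_y_linked=4,
                           n_xist_like=2, n_xci_escape=6, scale="counts")
        mat, table, _ = generate_cohorts(cfg, 1, seed=21)[0]
        assert mat.scale == "counts"
        assert (mat.values >= 0).all()
        assert np.allclose(mat.values, np.round(mat.values))
        logged = cpm_log_normalize(mat)
        idx = [logged.gene_index(g) for g in cfg.planted_sex_genes]
        X = logged.values[idx].T
        acc = LogisticRegression(max_iter=2000).fit(
            X, table.is_male.astype(int)).score(X, table.is_male.astype(int))
        assert acc >= 0.95
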