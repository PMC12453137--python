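"""NB interaction LRT: normalisation, dispersion, calibration, cross-checks."""

import numpy as np
import pandas as pd
import pytest

from amexpand.expression import (
    estimate_dispersion,
    family_context_proportion,
    median_ratio_size_factors,
    nb_interaction_lrt,
    run_interaction_tests,
)
from amexpand.models import ExpressionExperiment, GeneRecord, InteractionTestResult


def _design(reps=3):
    rows = []
    for m in (0, 1):
        for s in (0, 1):
            for r in range(reps):
                rows.append((f"m{m}s{s}_r{r}", m, s))
    return pd.DataFrame(rows, columns=["sample", "myc", "stress"]).set_index("sample")


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile([[10], [40], [100]], (1, 4))
        assert np.allclose(median_ratio_size_factors(counts), 1.0)

    def test_doubled_column_gives_factor_ratio_two(self):
        base = np.array([[10.0], [40.0], [100.0]])
        counts = np.hstack([base, 2 * base])
        f = median_ratio_size_factors(counts)
        assert f[1] / f[0] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_single_gene_matrix(self):
        f = median_ratio_size_factors(np.array([[10.0, 20.0]]))
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_no_all_positive_gene_rejected(self):
        with pytest.raises(ValueError, match="pseudo-reference"):
            median_ratio_size_factors(np.array([[0, 5], [5, 0]]))


class TestEstimateDispersion:
    def test_poisson_counts_hit_floor_with_many_reps(self, rng):
        design = _design(reps=50)
        counts = rng.poisson(200.0, size=(300, len(design)))
        alpha = estimate_dispersion(counts, design, np.ones(len(design)))
        assert np.median(alpha) < 0.01

    def test_variance_equal_mean_exactly_floors(self):
        design = _design(reps=2)
        # cells [10, 12]: var 2, mean 11 -> (2-11)/121 < 0 -> floor
        counts = np.tile([10, 12], (1, 4))
        alpha = estimate_dispersion(counts, design, np.ones(8))
        assert alpha[0] == pytest.approx(1e-8)

    def test_nb_dispersion_recovered_within_band(self, rng):
        design = _design(reps=50)
        r = 1 / 0.2
        mu = 100.0
        counts = rng.negative_binomial(r, r / (r + mu), size=(400, len(design)))
        alpha = estimate_dispersion(counts, design, np.ones(len(design)))
        inside = np.mean((alpha >= 0.1) & (alpha <= 0.4))
        assert inside >= 0.9


class TestNbInteractionLrt:
    def test_type_one_error_calibrated(self, rng):
        design = _design(reps=3)
        myc = design["myc"].to_numpy()
        stress = design["stress"].to_numpy()
        n = 500
        b0 = np.log(100) + rng.normal(0, 0.3, n)
        mu = np.exp(
            b0[:, None] + 0.3 * myc[None, :] - 0.2 * stress[None, :]
        )
        r = 1 / 0.1
        counts = rng.negative_binomial(r, r / (r + mu))
        hits = 0
        tested = 0
        for i in range(n):
            res = nb_interaction_lrt(counts[i], design, np.ones(12), 0.1)
            if res.p is not None:
                tested += 1
                hits += res.p < 0.05
        assert 0.03 <= hits / tested <= 0.08

    def test_strong_interaction_detected(self, rng):
        design = _design(reps=3)
        myc = design["myc"].to_numpy()
        stress = design["stress"].to_numpy()
        # myc+stress cell mean is 8x the additive expectation
        mu = 100 * np.exp(
            0.2 * myc + 0.1 * stress + np.log(8.0) * myc * stress
        )
        r = 1 / 0.05
        counts = rng.negative_binomial(r, r / (r + mu[None, :]))[0]
        res = nb_interaction_lrt(counts, design, np.ones(12), 0.05)
        assert res.p < 0.01

    def test_exactly_additive_counts_give_zero_llr(self):
        design = _design(reps=2)
        myc = design["myc"].to_numpy()
        stress = design["stress"].to_numpy()
        counts = (10 * 2.0**myc * 3.0**stress).astype(int)  # 10,30,20,60: additive
        res = nb_interaction_lrt(counts, design, np.ones(8), 0.1)
        assert res.llr <= 1e-6

    def test_llr_invariant_to_size_factor_scaling(self, rng):
        design = _design(reps=3)
        counts = rng.poisson(80, size=12)
        sf = np.exp(rng.normal(0, 0.2, 12))
        a = nb_interaction_lrt(counts, design, sf, 0.1)
        b = nb_interaction_lrt(counts, design, 7.3 * sf, 0.1)
        assert a.llr == pytest.approx(b.llr, abs=1e-8)

    def test_incomplete_factorial_rejected(self, rng):
        design = _design(reps=3).iloc[:9]  # drops the m1s1 cell
        with pytest.raises(ValueError, match="incomplete factorial"):
            nb_interaction_lrt(rng.poisson(50, 9), design, np.ones(9), 0.1)

    def test_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        design = _design(reps=3)
        myc = design["myc"].to_numpy(float)
        stress = design["stress"].to_numpy(float)
        X_full = np.column_stack([np.ones(12), myc, stress, myc * stress])
        X_red = X_full[:, :3]
        for _ in range(5):
            counts = rng.poisson(rng.uniform(30, 300), size=12).astype(float)
            alpha = float(rng.uniform(0.02, 0.3))
            sf = np.exp(rng.normal(0, 0.15, 12))
            sf = sf / np.exp(np.mean(np.log(sf)))
            mine = nb_interaction_lrt(counts, design, sf, alpha)
            fam = sm.families.NegativeBinomial(alpha=alpha)
            llf_full = sm.GLM(counts, X_full, family=fam, offset=np.log(sf)).fit().llf
            llf_red = sm.GLM(counts, X_red, family=fam, offset=np.log(sf)).fit().llf
            ref = max(0.0, 2 * (llf_full - llf_red))
            assert mine.llr == pytest.approx(ref, abs=1e-4)


class TestTestInteractions:
    def test_low_count_genes_excluded_and_bh_over_tested(self, rng):
        design = _design(reps=3)
        counts = rng.poisson(100, size=(50, 12))
        counts[0] = 0  # all-zero gene
        counts[1] = np.where(np.arange(12) == 0, 5, 0)  # total < 10
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(50)],
                          columns=design.index)
        exp = ExpressionExperiment(counts=df, design=design.copy())
        res = run_interaction_tests(exp)
        by_id = {r.gene_id: r for r in res}
        assert "g0" not in by_id and "g1" not in by_id
        tested = [r for r in res if r.p is not None]
        assert all(r.q is not None for r in tested)


class TestFamilyContextProportion:
    def _genes(self, fam_sizes):
        genes = []
        i = 0
        for fam, n in fam_sizes.items():
            for _ in range(n):
                genes.append(
                    GeneRecord(f"g{i}", "sp", "chr1", 1 + 2000 * i, 1000 + 2000 * i,
                               family_id=fam)
                )
                i += 1
        return genes

    @staticmethod
    def _res(gene_id, sig, tested=True):
        return InteractionTestResult(
            gene_id=gene_id, llr=1.0 if tested else None,
            p=0.01 if tested else None, q=0.01 if tested else None,
            significant=sig, dispersion=0.1, converged=tested,
        )

    def test_half_significant(self):
        genes = self._genes({"F1": 4})
        g2f = {g.gene_id: "F1" for g in genes}
        results = [self._res("g0", True), self._res("g1", False)]
        (m,) = family_context_proportion(results, g2f, genes)
        assert (m.size, m.n_tested, m.metric) == (4, 2, 0.5)

    def test_none_and_all_significant(self):
        genes = self._genes({"F1": 2, "F2": 2})
        g2f = {g.gene_id: g.family_id for g in genes}
        results = [self._res("g0", False), self._res("g1", False),
                   self._res("g2", True), self._res("g3", True)]
        m = {x.family_id: x for x in family_context_proportion(results, g2f, genes)}
        assert m["F1"].metric == 0.0 and m["F2"].metric == 1.0

    def test_untested_families_omitted(self):
        genes = self._genes({"F1": 2, "F2": 1})
        g2f = {g.gene_id: g.family_id for g in genes}
        results = [self._res("g0", True)]
        out = family_context_proportion(results, g2f, genes)
        assert [m.family_id for m in out] == ["F1"]

    def test_conflicting_family_assignment_rejected(self):
        genes = self._genes({"F1": 1})
        g2f = {"g0": "F2"}
        with pytest.raises(ValueError, match="two families"):
            family_context_proportion([self._res("g0", False)], g2f, genes)
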