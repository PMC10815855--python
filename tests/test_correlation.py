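import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from sysgen.correlation import (
    correlate_focal_gene,
    correlate_genes_with_traits,
    fold_difference,
    pearson_with_p,
)
from sysgen.simulate import (
    CorrelatedBlock,
    ExtraGene,
    SimConfig,
    simulate_expression,
    simulate_ri_genotypes,
)
from sysgen.types import ExpressionMatrix, TraitTable, ValidationError


class TestPearsonWithP:
    def test_self_correlation_is_one_with_clamped_p(self):
        r, p, n = pearson_with_p([1.0, 2, 4, 7], [1.0, 2, 4, 7])
        assert r == 1.0 and n == 4
        assert 0 < p <= 5e-324

    def test_orthogonal_deviations_give_zero(self):
        r, p, n = pearson_with_p([1, 2, 3], [1, 0, 1])
        assert r == pytest.approx(0.0, abs=1e-15)
        assert p == pytest.approx(1.0)

    def test_matches_closed_formula_and_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x, y = rng.standard_normal(10), rng.standard_normal(10)
            r, p, n = pearson_with_p(x, y)
            # direct product-moment formula + t-distribution tail
            rr = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            t = rr * np.sqrt((10 - 2) / (1 - rr**2))
            pp = 2 * stats.t.sf(abs(t), 8)
            assert r == pytest.approx(rr, abs=1e-12)
            assert p == pytest.approx(pp, abs=1e-12)
            sr, sp = stats.pearsonr(x, y)
            assert r == pytest.approx(sr, abs=1e-12)
            assert p == pytest.approx(sp, rel=1e-9)

    def test_pairwise_complete_handling(self):
        x = [1.0, np.nan, 3.0, 4.0, 5.0]
        y = [2.0, 2.0, 6.0, 8.0, np.nan]
        r, p, n = pearson_with_p(x, y)
        assert n == 3
        assert r == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="undefined correlation"):
            pearson_with_p([1, 1, 1], [1, 2, 3])

    @given(
        st.lists(st.floats(-50, 50), min_size=5, max_size=12, unique=True),
        st.floats(0.1, 4.0),
        st.floats(-10.0, 10.0),
    )
    def test_affine_invariance_and_symmetry(self, xs, a, b):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        y = rng.standard_normal(len(xs))
        if np.std(y) == 0:
            return
        r1, p1, _ = pearson_with_p(xs, y)
        r2, p2, _ = pearson_with_p(y, xs)  # symmetric
        assert r1 == pytest.approx(r2, abs=1e-12) and p1 == pytest.approx(p2, abs=1e-12)
        r3, p3, _ = pearson_with_p(a * np.asarray(xs) + b, y)  # positive-slope affine
        assert r3 == pytest.approx(r1, abs=1e-9) and p3 == pytest.approx(p1, abs=1e-9)
        r4, _, _ = pearson_with_p(-a * np.asarray(xs) + b, y)  # negative slope flips sign
        assert r4 == pytest.approx(-r1, abs=1e-9)


class TestFocalScreen:
    def _matrix(self):
        rng = np.random.default_rng(8)
        vals = pd.DataFrame(
            rng.normal(8, 1, size=(5, 40)),
            index=["focal", "copy", "dim", "null1", "null2"],
            columns=[f"s{i}" for i in range(40)],
        )
        vals.loc["copy"] = vals.loc["focal"]
        vals.loc["dim"] = 6.5 + 0.1 * (vals.loc["focal"] - 8)  # correlated but dim
        return ExpressionMatrix(vals)

    def test_exact_copy_passes(self):
        out = correlate_focal_gene(self._matrix(), "focal").set_index("partner")
        assert out.loc["copy", "r"] == pytest.approx(1.0)
        assert bool(out.loc["copy", "passes_filter"])
        assert "focal" not in out.index

    def test_mean_gate_blocks_dim_gene(self):
        out = correlate_focal_gene(self._matrix(), "focal").set_index("partner")
        assert out.loc["dim", "p"] < 0.05
        assert not bool(out.loc["dim", "passes_filter"])

    def test_human_mode_r_threshold(self):
        out = correlate_focal_gene(self._matrix(), "focal", r_threshold=0.5)
        passed = set(out.loc[out["passes_filter"], "partner"])
        assert passed == {"copy"}

    def test_missing_focal_rejected(self):
        with pytest.raises(ValidationError, match="ghost"):
            correlate_focal_gene(self._matrix(), "ghost")

    def test_filter_counts_monotone_in_thresholds(self):
        m = self._matrix()
        loose = correlate_focal_gene(m, "focal", p_threshold=0.2, min_mean=5.0)
        tight_p = correlate_focal_gene(m, "focal", p_threshold=0.01, min_mean=5.0)
        tight_mean = correlate_focal_gene(m, "focal", p_threshold=0.2, min_mean=7.5)
        assert tight_p["passes_filter"].sum() <= loose["passes_filter"].sum()
        assert tight_mean["passes_filter"].sum() <= loose["passes_filter"].sum()

    def test_planted_block_recovery_power(self):
        # 50 partners at rho 0.6 with the focal gene + 500 null genes, 40 strains:
        # on average nearly all partners clear nominal p < 0.05
        counts = []
        for rep in range(100):
            cfg = SimConfig(
                seed=900 + rep, n_strains=40, n_background_genes=500, block_size=10,
                extra_genes=[ExtraGene("focal", "1", 40.0)],
                correlated_blocks=[CorrelatedBlock("focal", n_partners=50, rho=0.6)],
            )
            gm = simulate_ri_genotypes(cfg)
            em = simulate_expression(gm, cfg)
            out = correlate_focal_gene(em, "focal")
            planted = out["partner"].str.startswith("partner")
            counts.append(int((out.loc[planted, "p"] < 0.05).sum()))
        assert np.mean(counts) >= 45


class TestTraitCorrelation:
    def _pair(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(
            rng.normal(8, 1, size=(2, 12)),
            index=["g1", "g2"], columns=[f"RI{i}" for i in range(12)],
        )
        em = ExpressionMatrix(expr)
        traits = pd.DataFrame(index=expr.columns)
        traits["loaded"] = expr.loc["g1"]
        traits["sparse"] = expr.loc["g2"] + rng.standard_normal(12)
        traits.loc["RI3", "sparse"] = np.nan
        return em, TraitTable(traits)

    def test_perfect_loading(self):
        em, tt = self._pair()
        out = correlate_genes_with_traits(em, tt, ["g1"]).set_index("trait")
        assert out.loc["loaded", "r"] == pytest.approx(1.0)
        assert bool(out.loc["loaded", "significant"])

    def test_missing_value_reduces_n_by_one(self):
        em, tt = self._pair()
        out = correlate_genes_with_traits(em, tt, ["g2"]).set_index("trait")
        assert out.loc["sparse", "n"] == 11
        assert out.loc["loaded", "n"] == 12

    def test_null_trait_correlations_stay_small(self):
        rng = np.random.default_rng(10)
        n = 1000
        em = ExpressionMatrix(pd.DataFrame(
            rng.normal(8, 1, size=(1, n)), index=["g"], columns=[f"s{i}" for i in range(n)]
        ))
        small = 0
        for rep in range(40):
            tt = TraitTable(pd.DataFrame(
                {"t": rng.standard_normal(n)}, index=em.values.columns))
            r = correlate_genes_with_traits(em, tt, ["g"])["r"].iloc[0]
            small += abs(r) < 0.1
        assert small >= 38  # |r| < 0.1 in >= 95% of null replicates

    def test_no_overlap_rejected(self):
        em, _ = self._pair()
        tt = TraitTable(pd.DataFrame({"t": [1.0]}, index=["other"]))
        with pytest.raises(ValidationError, match="overlap"):
            correlate_genes_with_traits(em, tt, ["g1"])


class TestFoldDifference:
    def test_published_strain_extremes(self):
        # log2 means 11.31 and 12.16 across the RI panel -> ~1.8-fold range
        fd = fold_difference(pd.Series({"BXD49": 11.31, "BXD44": 12.16}))
        assert round(fd.fold, 2) == 1.80
        assert fd.min_id == "BXD49" and fd.max_id == "BXD44"

    def test_flat_panel_is_onefold(self):
        assert fold_difference(pd.Series({"a": 3.3, "b": 3.3})).fold == 1.0

    def test_unit_log2_step_doubles(self):
        assert fold_difference(pd.Series({"a": 0.0, "b": 1.0})).fold == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            fold_difference(pd.Series(dtype=float))
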