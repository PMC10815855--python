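import numpy as np
import pandas as pd
import pytest

from sysgen.infiltration import (
    InfiltrationScores,
    correlate_genes_with_infiltration,
    differential_infiltration,
    infiltration_matrix,
    ssgsea_score,
)
from sysgen.simulate import CohortConfig, SimConfig, simulate_cohort
from sysgen.types import ConfigError, ExpressionMatrix, GeneSetCollection, ValidationError


def _oracle_es(values: pd.Series, members, alpha):
    """Step-by-step running-sum oracle, written independently of the
    implementation: walk the descending ranking one gene at a time."""
    from scipy.stats import rankdata

    genes = list(values.index)
    ranks = dict(zip(genes, rankdata(values.to_numpy(), method="average")))
    ordering = sorted(genes, key=lambda g: (-values[g], g))
    in_w = {g: abs(ranks[g]) ** alpha for g in ordering if g in members}
    total_in = sum(in_w.values())
    n_out = len(genes) - len(in_w)
    es, p_in, p_out = 0.0, 0.0, 0.0
    for g in ordering:
        if g in members:
            p_in += in_w[g] / total_in
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


def _sample(values, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return pd.Series(np.asarray(values, dtype=float), index=genes)


class TestSsgseaScore:
    def test_five_gene_toy_matches_oracle(self):
        s = _sample([5.0, 4.0, 3.0, 2.0, 1.0])
        members = {"g0", "g1"}  # set = top-2 expressed genes
        for alpha in (0.0, 0.25):
            assert ssgsea_score(s, members, alpha=alpha) == pytest.approx(
                _oracle_es(s, members, alpha), abs=1e-12
            )

    def test_random_samples_match_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(25):
            n = int(rng.integers(5, 40))
            s = _sample(rng.normal(8, 2, size=n))
            k = int(rng.integers(1, n - 1))
            members = set(rng.choice(s.index, size=k, replace=False))
            assert ssgsea_score(s, members) == pytest.approx(
                _oracle_es(s, members, 0.25), abs=1e-10
            )

    def test_rank_invariance_under_monotone_transforms(self):
        rng = np.random.default_rng(16)
        s = _sample(rng.normal(8, 2, size=30))
        members = set(s.index[:6])
        base = ssgsea_score(s, members)
        assert ssgsea_score(np.exp(s), members) == pytest.approx(base, abs=1e-12)
        assert ssgsea_score(3.0 * s + 11.0, members) == pytest.approx(base, abs=1e-12)

    def test_gene_order_irrelevant(self):
        rng = np.random.default_rng(17)
        s = _sample(rng.normal(size=20))
        members = set(s.index[:4])
        shuffled = s.sample(frac=1.0, random_state=1)
        assert ssgsea_score(shuffled, members) == pytest.approx(
            ssgsea_score(s, members), abs=1e-12
        )

    def test_unmeasured_set_rejected(self):
        with pytest.raises(ValidationError, match="no member"):
            ssgsea_score(_sample([1.0, 2.0, 3.0]), {"alien"})
        with pytest.raises(ValidationError, match="every measured gene"):
            ssgsea_score(_sample([1.0, 2.0]), {"g0", "g1"})


class TestInfiltrationMatrix:
    def _cohort_config(self, **kw):
        sigs = {
            "A": [f"a{i}" for i in range(6)],
            "B": [f"b{i}" for i in range(6)],
        }
        defaults = dict(
            n_case=5, n_control=5, signatures=sigs,
            case_props={"A": 0.7, "B": 0.3}, control_props={"A": 0.3, "B": 0.7},
            concentration=None, noise_sd=0.0, n_background_genes=20,
        )
        defaults.update(kw)
        return SimConfig(seed=18, cohort=CohortConfig(**defaults))

    def test_identical_samples_get_identical_scores(self):
        em, _ = simulate_cohort(self._cohort_config())
        sigs = GeneSetCollection.from_dict(self._cohort_config().cohort.signatures)
        scores = infiltration_matrix(em, sigs)
        case_scores = scores.scores.loc[scores.sample_group == "case"]
        assert np.allclose(case_scores.to_numpy(), case_scores.to_numpy()[0], atol=1e-12)

    def test_one_hot_sample_maximizes_its_own_cell_type(self):
        cfg = self._cohort_config(
            case_props={"A": 1.0, "B": 0.0}, control_props={"A": 0.0, "B": 1.0}
        )
        em, _ = simulate_cohort(cfg)
        sigs = GeneSetCollection.from_dict(cfg.cohort.signatures)
        scores = infiltration_matrix(em, sigs)
        a_scores = scores.scores["A"]
        assert a_scores.idxmax().startswith("case")
        assert scores.scores["B"].idxmax().startswith("control")

    def test_per_sample_shift_leaves_scores_unchanged(self):
        em, _ = simulate_cohort(self._cohort_config(noise_sd=0.2))
        sigs = GeneSetCollection.from_dict(self._cohort_config().cohort.signatures)
        base = infiltration_matrix(em, sigs).scores
        shifted_vals = em.values.copy()
        shifted_vals.iloc[:, 0] += 7.5
        shifted = infiltration_matrix(
            ExpressionMatrix(shifted_vals, None, em.sample_group), sigs
        ).scores
        assert np.allclose(base.to_numpy(), shifted.to_numpy(), atol=1e-12)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ConfigError, match="sum"):
            self._cohort_config(case_props={"A": 0.7, "B": 0.7})


class TestDifferentialInfiltration:
    def _scores(self, a, b):
        vals = pd.DataFrame({"cell": np.r_[a, b]},
                            index=[f"s{i}" for i in range(len(a) + len(b))])
        groups = pd.Series(["x"] * len(a) + ["y"] * len(b), index=vals.index)
        return InfiltrationScores(vals, groups)

    def test_identical_distributions_give_p_one(self):
        out = differential_infiltration(self._scores([1.0] * 5, [1.0] * 5))
        assert out["p"].iloc[0] == 1.0

    def test_complete_separation_exact_p(self):
        # 5 vs 5, no ties, complete separation: exact two-sided p = 2/252
        out = differential_infiltration(
            self._scores([1.0, 2, 3, 4, 5], [6.0, 7, 8, 9, 10])
        )
        assert out["p"].iloc[0] == pytest.approx(2 / 252, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError, match="at least 3"):
            differential_infiltration(self._scores([1.0, 2], [3.0, 4, 5]))

    @pytest.mark.parametrize("n_per_group", [8, 12])
    def test_type_one_error_calibration(self, n_per_group):
        # exchangeable null: flag rate should sit near the nominal 0.05
        rng = np.random.default_rng(19)
        flags = 0
        reps = 400
        for _ in range(reps):
            out = differential_infiltration(
                self._scores(rng.standard_normal(n_per_group),
                             rng.standard_normal(n_per_group))
            )
            flags += bool(out["significant"].iloc[0])
        assert 0.02 <= flags / reps <= 0.08

    def test_planted_proportion_shift_power(self):
        # case vs control shift of 0.2 in cell A's mixing proportion, 15/15
        sigs = {"A": [f"a{i}" for i in range(8)], "B": [f"b{i}" for i in range(8)]}
        hits = 0
        for rep in range(100):
            cfg = SimConfig(
                seed=3000 + rep,
                cohort=CohortConfig(
                    n_case=15, n_control=15, signatures=sigs,
                    case_props={"A": 0.5, "B": 0.5},
                    control_props={"A": 0.3, "B": 0.7},
                ),
            )
            em, _ = simulate_cohort(cfg)
            scores = infiltration_matrix(em, GeneSetCollection.from_dict(sigs))
            out = differential_infiltration(scores).set_index("cell_type")
            hits += bool(out.loc["A", "significant"])
        assert hits >= 90


class TestGeneInfiltrationCorrelation:
    def test_affine_gene_of_score_is_perfectly_correlated(self):
        rng = np.random.default_rng(20)
        scores = pd.DataFrame({"A": rng.normal(size=12)},
                              index=[f"s{i}" for i in range(12)])
        infl = InfiltrationScores(scores)
        vals = pd.DataFrame({s: [2.0 * scores.loc[s, "A"] + 5.0, rng.normal()]
                             for s in scores.index}, index=["tracked", "noise"])
        em = ExpressionMatrix(vals)
        out = correlate_genes_with_infiltration(em, infl, ["tracked", "noise"])
        assert out.shape[0] == 2  # genes x cell types
        tracked = out.set_index("gene").loc["tracked"]
        assert tracked["r"] == pytest.approx(1.0)

    def test_null_gene_correlations_stay_moderate(self):
        # |r| < 0.37 in >= 95% of null replicates at n = 30
        rng = np.random.default_rng(21)
        small = 0
        reps = 200
        for _ in range(reps):
            scores = pd.DataFrame({"A": rng.normal(size=30)},
                                  index=[f"s{i}" for i in range(30)])
            em = ExpressionMatrix(pd.DataFrame(
                rng.normal(size=(1, 30)), index=["g"], columns=scores.index))
            out = correlate_genes_with_infiltration(em, InfiltrationScores(scores), ["g"])
            small += abs(out["r"].iloc[0]) < 0.37
        assert small / reps >= 0.95

    def test_absent_gene_rejected(self):
        scores = InfiltrationScores(pd.DataFrame({"A": [0.1, 0.2, 0.3]},
                                                 index=["s0", "s1", "s2"]))
        em = ExpressionMatrix(pd.DataFrame(np.zeros((1, 3)) + [[1, 2, 3]],
                                           index=["g"], columns=["s0", "s1", "s2"]))
        with pytest.raises(ValidationError):
            correlate_genes_with_infiltration(em, scores, ["ghost"])
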