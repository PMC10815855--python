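import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sysgen.eqtl import (
    LOD_DIVISOR,
    QtlPeak,
    QtlScan,
    classify_cis_trans,
    genome_scan,
    lrs_to_lod,
    marker_lrs,
    permutation_thresholds,
    support_interval,
)
from sysgen.simulate import PlantedEqtl, SimConfig, simulate_expression, simulate_ri_genotypes
from sysgen.types import ValidationError


def _gaussian_loglik_lrs(y, g):
    """Independent oracle: -2 * delta log-likelihood of Gaussian mean models
    (MLE variance), computed from the full likelihood expressions."""
    y = np.asarray(y, dtype=float)
    n = y.size

    def loglik(resid):
        s2 = (resid**2).mean()
        return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)

    r0 = y - y.mean()
    r1 = y.copy()
    for cls in (0, 1):
        r1[g == cls] = y[g == cls] - y[g == cls].mean()
    return 2.0 * (loglik(r1) - loglik(r0))


class TestMarkerLrs:
    def test_worked_example(self):
        # SS0 = 5, SS1 = 1 -> LRS = 4 ln 5; additive = 3.5 - 1.5 = 2
        lrs, add = marker_lrs([1, 2, 3, 4], np.array([0, 0, 1, 1]))
        assert lrs == pytest.approx(4 * np.log(5), abs=1e-12)
        assert add == pytest.approx(2.0)

    def test_constant_trait_scores_zero(self):
        lrs, _ = marker_lrs([2.0, 2, 2, 2], np.array([0, 1, 0, 1]))
        assert lrs == 0.0

    def test_monomorphic_marker_rejected(self):
        with pytest.raises(ValidationError, match="monomorphic"):
            marker_lrs([1, 2, 3, 4], np.array([1, 1, 1, 1]))

    def test_perfect_fit_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            lrs, _ = marker_lrs([1, 1, 5, 5], np.array([0, 0, 1, 1]))
        assert lrs == 1e6

    def test_matches_likelihood_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(6, 30)
            g = np.zeros(n, dtype=int)
            g[: rng.integers(1, n - 1)] = 1
            rng.shuffle(g)
            y = rng.standard_normal(n)
            lrs, _ = marker_lrs(y, g)
            assert lrs == pytest.approx(_gaussian_loglik_lrs(y, g), abs=1e-9)

    @given(st.floats(-5, 5), st.floats(0.1, 10))
    def test_affine_invariance(self, shift, scale):
        y = np.array([0.3, -1.2, 0.8, 2.0, -0.5, 1.1])
        g = np.array([0, 1, 0, 1, 1, 0])
        base, _ = marker_lrs(y, g)
        moved, _ = marker_lrs(scale * y + shift, g)
        assert moved == pytest.approx(base, abs=1e-8)


class TestGenomeScan:
    def test_single_marker_scan_equals_marker_lrs(self):
        from sysgen.types import GenotypeMatrix

        markers = pd.DataFrame(
            {"chrom": ["1", "1", "2"], "pos_mb": [5.0, 15.0, 8.0]},
            index=pd.Index(["m1", "m2", "m3"], name="marker"),
        )
        codes = pd.DataFrame(
            [[0, 1, 1], [1, 0, 1], [0, 1, 0], [1, 0, 0]],
            index=pd.Index(list("abcd"), name="strain"), columns=markers.index,
        )
        gm = GenotypeMatrix(codes, markers)
        y = pd.Series([1.0, 2.0, 3.0, 2.5], index=gm.strain_ids)
        scan = genome_scan(y, gm)
        for mid in gm.marker_ids:
            expected, _ = marker_lrs(y.to_numpy(), gm.codes[mid].to_numpy())
            row = scan.table.set_index("marker").loc[mid]
            assert row["lrs"] == pytest.approx(expected, abs=1e-9)

    def test_monomorphic_markers_flagged_not_fatal(self):
        markers = pd.DataFrame(
            {"chrom": ["1", "1"], "pos_mb": [1.0, 2.0]},
            index=pd.Index(["a", "b"], name="marker"),
        )
        codes = pd.DataFrame(
            [[0, 0], [1, 0], [0, 0], [1, 0]],
            index=pd.Index(list("wxyz"), name="strain"), columns=markers.index,
        )
        from sysgen.types import GenotypeMatrix

        scan = genome_scan([1.0, 2, 3, 4], GenotypeMatrix(codes, markers))
        tbl = scan.table.set_index("marker")
        assert bool(tbl.loc["a", "polymorphic"]) and not bool(tbl.loc["b", "polymorphic"])
        assert np.isnan(tbl.loc["b", "lrs"])

    def test_strong_planted_effect_is_localized(self):
        # machinery check at a strong effect (beta=2, sd=0.5): the argmax
        # should sit at or next to the planted marker essentially always
        hits = 0
        for rep in range(30):
            cfg = SimConfig(seed=1200 + rep, n_strains=40, residual_sd=0.5,
                            n_background_genes=0,
                            planted_eqtls=[PlantedEqtl("g", "m3_010", beta=2.0)])
            gm = simulate_ri_genotypes(cfg)
            em = simulate_expression(gm, cfg)
            scan = genome_scan(em.values.loc["g"], gm)
            ids = list(gm.codes.columns)
            dist = abs(ids.index(scan.top_marker()["marker"]) - ids.index("m3_010"))
            hits += dist <= 1
        assert hits >= 29


class TestPermutationThresholds:
    def test_significant_at_least_suggestive_and_deterministic(self, tiny_genotypes):
        y = [0.5, -1.0, 1.5]
        with pytest.warns(UserWarning, match="noisy"):
            a = permutation_thresholds(y, tiny_genotypes, n_perm=99, seed=3)
        sig, sug = a
        assert sig >= sug
        with pytest.warns(UserWarning):
            b = permutation_thresholds(y, tiny_genotypes, n_perm=99, seed=3)
        assert a == b

    def test_seed_required(self, tiny_genotypes):
        with pytest.raises(ValidationError, match="seed"):
            permutation_thresholds([1.0, 2, 3], tiny_genotypes, n_perm=100)


class TestSupportInterval:
    def _scan(self, lods, positions, chrom="1"):
        table = pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(len(lods))],
                "chrom": [chrom] * len(lods),
                "pos_mb": positions,
                "lrs": np.asarray(lods) * LOD_DIVISOR,
                "additive": 0.0,
                "polymorphic": True,
            }
        )
        return QtlScan(table)

    def test_drop_interval_includes_first_failing_flank(self):
        # peak LOD 4.0, cutoff 2.5: only the peak stays contiguous, the
        # flanking markers (the first to fail the drop) are included
        scan = self._scan([0.5, 2.0, 4.0, 2.0, 0.5], [10, 20, 30, 40, 50])
        peak = support_interval(scan, "1")
        assert peak.pos_mb == 30
        assert (peak.interval_start_mb, peak.interval_end_mb) == (20, 40)

    def test_flat_profile_spans_chromosome(self):
        scan = self._scan([2.0] * 5, [10, 20, 30, 40, 50])
        peak = support_interval(scan, "1")
        assert (peak.interval_start_mb, peak.interval_end_mb) == (10, 50)

    def test_peak_tie_breaks_to_smaller_position(self):
        scan = self._scan([1.0, 3.0, 3.0, 1.0], [10, 20, 30, 40])
        assert support_interval(scan, "1").pos_mb == 20

    def test_lod_definition(self):
        assert lrs_to_lod(4.60517) == pytest.approx(1.0, abs=1e-5)
        assert LOD_DIVISOR == pytest.approx(2 * np.log(10))

    def test_absent_chromosome_rejected(self):
        scan = self._scan([1.0, 2.0, 1.0], [1, 2, 3])
        with pytest.raises(ValidationError):
            support_interval(scan, "7")


class TestCisTransClassification:
    def _peak(self, chrom, pos):
        return QtlPeak(chrom=chrom, pos_mb=pos, lrs=10.0,
                       interval_start_mb=pos - 5, interval_end_mb=pos + 5)

    def test_distant_chromosome_is_trans(self):
        # focal-gene case: gene on Chr 17 at 24.728 Mb, peak on Chr 11 at 104.768 Mb
        assert classify_cis_trans(self._peak("11", 104.768), "17", 24.728) == "trans"

    def test_local_peak_is_cis(self):
        assert classify_cis_trans(self._peak("17", 24.7), "17", 24.728) == "cis"

    def test_same_chromosome_outside_window_is_trans(self):
        assert classify_cis_trans(self._peak("5", 50.0), "5", 65.0) == "trans"

    def test_window_is_inclusive(self):
        assert classify_cis_trans(self._peak("5", 50.0), "5", 60.0) == "cis"

    def test_missing_annotation_rejected(self):
        with pytest.raises(ValidationError):
            classify_cis_trans(self._peak("1", 1.0), None, None)
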