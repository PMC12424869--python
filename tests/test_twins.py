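"""Twin identification, heritability estimation, confound diagnostics."""

import numpy as np
import pandas as pd
import pytest

from ribovar.simulate import simulate_twin_frequency_study
from ribovar.twins import (
    KinshipRecord,
    copy_number_correlation,
    depth_confound,
    heritable_linkage,
    identify_parent_offspring_and_trios,
    identify_twins,
    twin_variant_correlation,
)


class TestIdentifyTwins:
    def test_kinship_threshold_strict(self):
        records = [
            KinshipRecord("a", "b", 0.45),
            KinshipRecord("c", "d", 0.40),  # exactly at the boundary: not MZ
        ]
        assert identify_twins(records) == [("a", "b")]

    def test_greedy_deduplication_prefers_higher_kinship(self):
        records = [
            KinshipRecord("a", "b", 0.44),
            KinshipRecord("a", "c", 0.49),
        ]
        assert identify_twins(records) == [("a", "c")]

    def test_recovery_from_simulated_kinship(self):
        rng = np.random.default_rng(0)
        truth = [(f"t{i}a", f"t{i}b") for i in range(30)]
        records = [
            KinshipRecord(a, b, float(rng.normal(0.5, 0.02))) for a, b in truth
        ]
        others = [f"u{i}" for i in range(40)]
        for _ in range(100):
            x, y = rng.choice(others, 2, replace=False)
            records.append(KinshipRecord(str(x), str(y),
                                         float(rng.uniform(0, 0.2))))
        found = set(identify_twins(records))
        assert found == set(truth)


class TestParentOffspring:
    def test_po_pair_criteria(self):
        records = [
            KinshipRecord("mum", "kid", 0.25, 1950, 1980),
            KinshipRecord("sib1", "sib2", 0.25, 1950, 1952),  # gap too small
            KinshipRecord("x", "y", 0.40, 1950, 1990),  # kinship too high
        ]
        pairs, _ = identify_parent_offspring_and_trios(records)
        assert pairs == [("mum", "kid")]

    def test_kinship_bounds_inclusive(self):
        records = [
            KinshipRecord("a", "b", 0.17, 1950, 1980),
            KinshipRecord("c", "d", 0.35, 1950, 1980),
        ]
        pairs, _ = identify_parent_offspring_and_trios(records)
        assert len(pairs) == 2

    def test_missing_birth_year_skipped(self):
        records = [KinshipRecord("a", "b", 0.25, None, 1980)]
        pairs, trios = identify_parent_offspring_and_trios(records)
        assert pairs == [] and trios == []

    def test_trio_assembly_from_simulated_pedigree(self):
        # two parents (not PO with each other) + one child each way
        records = [
            KinshipRecord("dad", "kid", 0.25, 1950, 1980),
            KinshipRecord("mum", "kid", 0.26, 1952, 1980),
            KinshipRecord("dad", "mum", 0.02, 1950, 1952),
            # grandparent chain: gran-dad are PO, so (gran, mum) can't parent kid2
            KinshipRecord("gran", "dad", 0.25, 1920, 1950),
        ]
        _, trios = identify_parent_offspring_and_trios(records)
        assert trios == [("kid", "dad", "mum")]


class TestTwinCorrelation:
    def test_identical_twin_frequencies_give_r_one(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, size=20)
        rows = {}
        pairs = []
        for i, v in enumerate(vals):
            a, b = f"t{i}a", f"t{i}b"
            rows[a] = {"v": v}
            rows[b] = {"v": v}
            pairs.append((a, b))
        freq = pd.DataFrame.from_dict(rows, orient="index")
        rec = twin_variant_correlation(freq, pairs)
        assert rec.loc["v", "twin_spearman"] == pytest.approx(1.0)
        assert bool(rec.loc["v", "heritable"]) is True

    def test_threshold_is_strict(self):
        # rank-correlation exactly at the threshold must not be heritable
        rows = {}
        pairs = []
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        for i, v in enumerate(x):
            rows[f"a{i}"] = {"v": v}
            rows[f"b{i}"] = {"v": v}
            pairs.append((f"a{i}", f"b{i}"))
        freq = pd.DataFrame.from_dict(rows, orient="index")
        rec = twin_variant_correlation(freq, pairs, heritable_threshold=1.0)
        assert rec.loc["v", "twin_spearman"] == pytest.approx(1.0)
        assert bool(rec.loc["v", "heritable"]) is False  # R > 1.0 impossible

    def test_somatic_null_gives_small_r(self):
        freq, pairs, labels, _ = simulate_twin_frequency_study(
            n_pairs=177, n_germline=0, n_somatic=30, depth=5000, seed=3
        )
        rec = twin_variant_correlation(freq, pairs)
        assert rec["twin_spearman"].abs().median() < 0.15
        assert not rec["heritable"].any()

    def test_orientation_symmetry(self):
        freq, pairs, _, _ = simulate_twin_frequency_study(
            n_pairs=40, n_germline=5, n_somatic=5, depth=2000, seed=4
        )
        r1 = twin_variant_correlation(freq, pairs, seed=0)["twin_spearman"]
        swapped = [(b, a) for a, b in pairs]
        r2 = twin_variant_correlation(freq, swapped, seed=0)["twin_spearman"]
        # Spearman is symmetric under (x, y) exchange: orientation irrelevant
        pd.testing.assert_series_equal(r1, r2)

    def test_too_few_pairs_gives_missing_r(self):
        freq = pd.DataFrame({"v": [0.1, 0.1, 0.2, np.nan]},
                            index=["a1", "b1", "a2", "b2"])
        rec = twin_variant_correlation(freq, [("a1", "b1"), ("a2", "b2")])
        assert np.isnan(rec.loc["v", "twin_spearman"])


class TestDepthConfound:
    def test_depth_noise_coupling_reproduces_ordering(self):
        # germline variants measured at variant-specific depth: low depth
        # adds binomial noise, deflating the twin correlation
        rng = np.random.default_rng(5)
        n_var = 60
        depths = np.where(
            rng.random(n_var) < 0.5,
            rng.uniform(80, 300, n_var),
            rng.uniform(6000, 10000, n_var),
        )
        freq, pairs, _, depth_per_variant = simulate_twin_frequency_study(
            n_pairs=120, n_germline=n_var, n_somatic=0, depth=depths, seed=6,
            germline_beta=(0.8, 8.0),
        )
        rec = twin_variant_correlation(
            freq, pairs, mean_depth=depth_per_variant
        )
        out = depth_confound(rec, depth_threshold=5000)
        assert out["n_all"] == n_var
        assert out["n_filtered"] == int((depths >= 5000).sum())
        assert out["r_all"] > out["r_filtered"] > -0.2
        assert out["r_all"] > 0.3

    def test_all_variants_above_threshold_identical_strata(self):
        rec = pd.DataFrame(
            {
                "twin_spearman": [0.9, 0.5, 0.2, 0.7],
                "mean_depth": [6000.0, 7000.0, 8000.0, 9000.0],
            }
        )
        out = depth_confound(rec)
        assert out["r_all"] == pytest.approx(out["r_filtered"])

    def test_small_stratum_gives_nan(self):
        rec = pd.DataFrame(
            {"twin_spearman": [0.9, 0.5], "mean_depth": [100.0, 200.0]}
        )
        out = depth_confound(rec)
        assert np.isnan(out["r_filtered"]) and np.isnan(out["r_all"])


class TestLinkage:
    def test_cosegregating_variants_correlate(self):
        # two variants carried by the same haplotype: frequencies move together
        rng = np.random.default_rng(7)
        hap = rng.uniform(0.1, 0.9, size=60)
        other = rng.uniform(0.1, 0.9, size=60)
        freq = pd.DataFrame(
            {
                "10:A:T": hap + rng.normal(0, 0.01, 60),
                "40:C:G": hap + rng.normal(0, 0.01, 60),
                "99:G:A": other,
            }
        )
        corr, order = heritable_linkage(freq, list(freq.columns))
        assert corr.loc["10:A:T", "40:C:G"] > 0.95
        assert abs(corr.loc["10:A:T", "99:G:A"]) < 0.35
        assert set(order) == set(freq.columns)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(8)
        freq = pd.DataFrame(rng.uniform(size=(30, 4)),
                            columns=list("abcd"))
        corr, _ = heritable_linkage(freq, list("abcd"))
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)

    def test_constant_column_gives_nan_entries(self):
        freq = pd.DataFrame(
            {"a": [0.5, 0.5, 0.5, 0.5], "b": [0.1, 0.2, 0.3, 0.4]}
        )
        corr, _ = heritable_linkage(freq, ["a", "b"])
        assert np.isnan(corr.loc["a", "b"])


class TestCopyNumberCorrelation:
    def test_independent_frequency_uncorrelated(self):
        rng = np.random.default_rng(9)
        n = 300
        freq = pd.DataFrame({"v": rng.uniform(size=n)},
                            index=[f"p{i}" for i in range(n)])
        cn = pd.Series(rng.normal(400, 40, n), index=freq.index)
        out = copy_number_correlation(freq, cn)
        assert abs(out.loc["v", "cn_pearson"]) < 0.15

    def test_perfect_coupling_gives_r_one(self):
        cn = pd.Series([300.0, 350, 400, 450, 500],
                       index=[f"p{i}" for i in range(5)])
        freq = pd.DataFrame({"v": cn / 1000.0})
        out = copy_number_correlation(freq, cn)
        assert out.loc["v", "cn_pearson"] == pytest.approx(1.0)

    def test_coupled_somatic_variant_recovered(self):
        # somatic injection rate rises with copy-number expansion
        rng = np.random.default_rng(10)
        n = 400
        cn = pd.Series(rng.normal(400, 40, n), index=[f"p{i}" for i in range(n)])
        z = (cn - 400) / 40
        freq = pd.DataFrame(
            {"som": np.clip(0.01 * (1 + 0.5 * z) + rng.normal(0, 0.002, n),
                            0, 1)},
            index=cn.index,
        )
        out = copy_number_correlation(freq, cn)
        assert out.loc["som", "cn_pearson"] > 0.5

    def test_constant_input_gives_nan(self):
        freq = pd.DataFrame({"v": [0.5, 0.5, 0.5]},
                            index=["p1", "p2", "p3"])
        cn = pd.Series([300.0, 400, 500], index=freq.index)
        assert np.isnan(copy_number_correlation(freq, cn).loc["v", "cn_pearson"])
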