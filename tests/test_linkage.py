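import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nilqtl import simulate
from nilqtl.linkage import (
    design_sequential_cross,
    permutation_thresholds,
    qc_genotypes,
    scan_with_thresholds,
    select_extremes,
    variance_explained,
    wilcoxon_scan,
)

from conftest import make_matrix, make_phenotype_table


def matrix_from_masks(mask_by_marker: dict, n: int):
    calls = {
        f"s{i:02d}": {mk: ("B" if i in idx else "G") for mk, idx in mask_by_marker.items()}
        for i in range(n)
    }
    return make_matrix(calls)


class TestQcGenotypes:
    def test_chi2_closed_form_40_37(self):
        """40 B / 37 G of 77: chi2 = 9/77 ~ 0.1169, p ~ 0.73, passes."""
        matrix = matrix_from_masks({"m1": set(range(40))}, 77)
        report = qc_genotypes(matrix)
        assert report.per_marker.at["m1", "chi2"] == pytest.approx(9 / 77, abs=1e-9)
        assert report.per_marker.at["m1", "p"] == pytest.approx(
            stats.chi2.sf(9 / 77, 1), abs=1e-12
        )
        assert report.per_marker.at["m1", "p"] == pytest.approx(0.7325, abs=1e-3)
        assert bool(report.per_marker.at["m1", "passed"])

    def test_total_distortion_fails(self):
        matrix = matrix_from_masks({"m1": set(range(77))}, 77)
        report = qc_genotypes(matrix)
        assert not report.per_marker.at["m1", "passed"]

    def test_uncallable_marker_flagged(self):
        calls = {f"s{i}": {"m1": "B" if i < 6 else "G", "m2": None} for i in range(12)}
        matrix = make_matrix(calls)
        report = qc_genotypes(matrix)
        assert not report.per_marker.at["m2", "callable"]

    def test_segregant_call_rate(self):
        calls = {
            f"s{i}": {f"m{j}": (None if (i == 0 and j < 50) else "B") for j in range(100)}
            for i in range(12)
        }
        report = qc_genotypes(make_matrix(calls))
        assert report.per_segregant.at["s0", "call_rate"] == pytest.approx(0.5)
        assert not report.per_segregant.at["s0", "passed"]
        assert bool(report.per_segregant.at["s1", "passed"])

    def test_too_few_segregants(self):
        with pytest.raises(ValueError):
            qc_genotypes(matrix_from_masks({"m1": {0, 1}}, 5))


class TestWilcoxonScan:
    @staticmethod
    def enumeration_p(x, y):
        """Exhaustive two-sided rank-sum p over all group assignments."""
        values = np.concatenate([x, y])
        n1 = len(x)
        ranks = stats.rankdata(values)
        mean = n1 * len(y) / 2
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        count = total = 0
        for comb in itertools.combinations(range(len(values)), n1):
            u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
            total += 1
            if abs(u - mean) >= abs(u_obs - mean) - 1e-9:
                count += 1
        return count / total

    def test_separated_groups_exact_p(self):
        """B {1,2,3} vs G {4,5,6}: U=0, exact two-sided p = 2/20 = 0.1."""
        matrix = matrix_from_masks({"m1": {0, 1, 2}}, 6)
        pheno = make_phenotype_table({f"s{i:02d}": float(i + 1) for i in range(6)})
        out = wilcoxon_scan(matrix, pheno, "RS")
        assert out.loc[0, "p"] == pytest.approx(0.1, abs=1e-12)
        assert out.loc[0, "direction"] == "B"

    def test_identical_multisets_p_one(self):
        matrix = matrix_from_masks({"m1": {0, 1, 2}}, 6)
        pheno = make_phenotype_table(
            {"s00": 1.0, "s01": 2.0, "s02": 3.0, "s03": 1.0, "s04": 2.0, "s05": 3.0}
        )
        out = wilcoxon_scan(matrix, pheno, "RS")
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_constant_phenotype_p_one(self):
        matrix = matrix_from_masks({"m1": {0, 1, 2}}, 8)
        pheno = make_phenotype_table({f"s{i:02d}": 4.2 for i in range(8)})
        out = wilcoxon_scan(matrix, pheno, "RS")
        assert out.loc[0, "p"] == 1.0

    def test_matches_enumeration_all_small_instances(self):
        """Scan equals exhaustive enumeration on every split with n <= 8."""
        rng = np.random.default_rng(3)
        for n in range(4, 9):
            for n1 in range(2, n - 1):
                values = rng.permutation(np.arange(n)).astype(float)
                matrix = matrix_from_masks({"m1": set(range(n1))}, n)
                pheno = make_phenotype_table(
                    {f"s{i:02d}": values[i] for i in range(n)}
                )
                out = wilcoxon_scan(matrix, pheno, "RS")
                expected = self.enumeration_p(values[:n1], values[n1:])
                assert out.loc[0, "p"] == pytest.approx(expected, abs=1e-9), (n, n1)

    def test_normal_approx_close_to_permutation_estimate(self):
        """n=77 split 40/37 with a 1-SD shift: asymptotic p within 10% relative
        of a large Monte-Carlo permutation estimate (sampled enumeration)."""
        rng = np.random.default_rng(17)
        rel_errors = []
        for _ in range(20):
            y = rng.normal(10, 1, 77)
            y[:40] -= 1.0
            matrix = matrix_from_masks({"m1": set(range(40))}, 77)
            pheno = make_phenotype_table({f"s{i:02d}": y[i] for i in range(77)})
            p_scan = wilcoxon_scan(matrix, pheno, "RS").loc[0, "p"]
            ranks = stats.rankdata(y)
            u_obs = ranks[:40].sum() - 40 * 41 / 2
            mean = 40 * 37 / 2
            count = 0
            n_mc = 20_000
            for _ in range(n_mc):
                perm = rng.permutation(77)
                u = ranks[perm[:40]].sum() - 40 * 41 / 2
                if abs(u - mean) >= abs(u_obs - mean) - 1e-9:
                    count += 1
            p_mc = count / n_mc
            if p_mc > 5e-3:  # MC resolution floor
                rel_errors.append(abs(p_scan - p_mc) / p_mc)
        assert np.median(rel_errors) < 0.10

    def test_skips_marker_with_tiny_class(self):
        matrix = matrix_from_masks({"m1": {0}, "m2": {0, 1, 2}}, 8)
        pheno = make_phenotype_table({f"s{i:02d}": float(i) for i in range(8)})
        out = wilcoxon_scan(matrix, pheno, "RS")
        assert list(out["marker"]) == ["m2"]

    def test_invariance_monotone_transform_and_relabeling(self):
        """Rank statistics: p is unchanged by monotone trait transforms and by
        relabeling segregant ids."""
        rng = np.random.default_rng(23)
        y = rng.normal(10, 3, 30)
        matrix = matrix_from_masks({"m1": set(range(0, 30, 2))}, 30)
        pheno1 = make_phenotype_table({f"s{i:02d}": float(y[i]) for i in range(30)})
        pheno2 = make_phenotype_table(
            {f"s{i:02d}": float(np.exp(y[i] / 5)) for i in range(30)}
        )
        p1 = wilcoxon_scan(matrix, pheno1, "RS").loc[0, "p"]
        p2 = wilcoxon_scan(matrix, pheno2, "RS").loc[0, "p"]
        assert p1 == pytest.approx(p2, abs=1e-12)
        # relabeling: swap ids consistently in both tables
        relabel = {f"s{i:02d}": f"x{99 - i:02d}" for i in range(30)}
        matrix2 = make_matrix(
            {
                relabel[seg]: {"m1": matrix.frame.at[seg, "m1"]}
                for seg in matrix.segregants
            }
        )
        pheno3 = make_phenotype_table(
            {relabel[f"s{i:02d}"]: float(y[i]) for i in range(30)}
        )
        p3 = wilcoxon_scan(matrix2, pheno3, "RS").loc[0, "p"]
        assert p1 == pytest.approx(p3, abs=1e-12)


class TestPermutationThresholds:
    def test_single_marker_threshold_near_nominal(self):
        """With one marker the 5% genome-wide threshold is the single-test
        null quantile, -log10(0.05), within Monte-Carlo error."""
        rng = np.random.default_rng(4)
        y = rng.normal(10, 1, 60)
        matrix = matrix_from_masks({"m1": set(range(30))}, 60)
        pheno = make_phenotype_table({f"s{i:02d}": float(y[i]) for i in range(60)})
        thresholds = permutation_thresholds(
            matrix, pheno, "RS", n_perm=4000, seed=11
        )
        assert thresholds[0.05] == pytest.approx(-math.log10(0.05), abs=0.12)
        assert thresholds[0.10] == pytest.approx(-math.log10(0.10), abs=0.12)

    def test_level_monotonicity(self, h4_population):
        _, matrix, pheno = h4_population
        thresholds = permutation_thresholds(matrix, pheno, "RS", n_perm=200, seed=0)
        assert thresholds[0.05] >= thresholds[0.10]

    def test_reproducible_under_seed(self, h4_population):
        _, matrix, pheno = h4_population
        a = permutation_thresholds(matrix, pheno, "RS", n_perm=150, seed=5)
        b = permutation_thresholds(matrix, pheno, "RS", n_perm=150, seed=5)
        assert a == b

    def test_minimum_permutations_enforced(self, h4_population):
        _, matrix, pheno = h4_population
        with pytest.raises(ValueError):
            permutation_thresholds(matrix, pheno, "RS", n_perm=50, seed=0)

    def test_fwer_calibration(self):
        """Under a no-QTL null, the rate of any marker exceeding the 5%
        threshold is 5% +/- 2% across simulated datasets."""
        rng = np.random.default_rng(31)
        n, m = 50, 10
        false_positives = 0
        n_sim = 400
        for sim in range(n_sim):
            masks = {
                f"m{j}": set(np.flatnonzero(rng.random(n) < 0.5).tolist())
                for j in range(m)
            }
            # guard against degenerate classes
            masks = {
                k: (v if 2 <= len(v) <= n - 2 else set(range(n // 2)))
                for k, v in masks.items()
            }
            matrix = matrix_from_masks(masks, n)
            y = rng.normal(10, 1, n)
            pheno = make_phenotype_table({f"s{i:02d}": float(y[i]) for i in range(n)})
            thresholds = permutation_thresholds(
                matrix, pheno, "RS", n_perm=300, seed=1000 + sim
            )
            scan = wilcoxon_scan(matrix, pheno, "RS")
            if (scan["neglog10_p"] >= thresholds[0.05]).any():
                false_positives += 1
        rate = false_positives / n_sim
        assert abs(rate - 0.05) <= 0.02


class TestVarianceExplained:
    def test_balanced_80_20_split_exact(self):
        """y = 2*x1 + 1*x2 on a balanced noiseless design: shares are exactly
        80% and 20%, interaction 0."""
        calls = {}
        values = {}
        i = 0
        for a in ("B", "G"):
            for b in ("B", "G"):
                for _ in range(5):
                    seg = f"s{i:02d}"
                    calls[seg] = {"L1": a, "L2": b}
                    values[seg] = 2.0 * (a == "B") + 1.0 * (b == "B")
                    i += 1
        matrix = make_matrix(calls)
        pheno = make_phenotype_table(values, trait="T70")
        decomp = variance_explained(matrix, pheno, "T70", ["L1", "L2"])
        assert decomp.model == "two_locus_interaction"
        assert decomp.percent("L1") == pytest.approx(80.0, abs=1e-8)
        assert decomp.percent("L2") == pytest.approx(20.0, abs=1e-8)
        assert decomp.percent("L1:L2") == pytest.approx(0.0, abs=1e-8)

    def test_null_phenotype_small_shares(self):
        rng = np.random.default_rng(9)
        pvals = []
        for sim in range(200):
            masks = {
                "L1": set(np.flatnonzero(rng.random(60) < 0.5).tolist()),
                "L2": set(np.flatnonzero(rng.random(60) < 0.5).tolist()),
            }
            masks = {k: (v if 2 <= len(v) <= 58 else set(range(30))) for k, v in masks.items()}
            matrix = matrix_from_masks(masks, 60)
            y = rng.normal(10, 1, size=60)
            pheno = make_phenotype_table({f"s{i:02d}": float(y[i]) for i in range(60)})
            decomp = variance_explained(matrix, pheno, "RS", ["L1", "L2"])
            pvals.append(decomp.terms.set_index("term").at["L1", "p"])
            assert decomp.percent("L1") < 25.0
        # p-values approximately uniform: mean near 0.5
        assert np.mean(pvals) == pytest.approx(0.5, abs=0.08)

    def test_one_way_model(self):
        calls = {f"s{i:02d}": {"L1": "B" if i < 10 else "G"} for i in range(20)}
        values = {f"s{i:02d}": (5.0 if i < 10 else 9.0) for i in range(20)}
        matrix = make_matrix(calls)
        pheno = make_phenotype_table(values)
        decomp = variance_explained(matrix, pheno, "RS", ["L1"])
        assert decomp.model == "one_way"
        assert decomp.percent("L1") == pytest.approx(100.0, abs=1e-8)

    def test_empty_cell_drops_interaction(self, caplog):
        calls = {}
        values = {}
        combos = [("B", "B"), ("B", "G"), ("G", "B")]  # missing (G, G)
        i = 0
        for a, b in combos:
            for _ in range(6):
                seg = f"s{i:02d}"
                calls[seg] = {"L1": a, "L2": b}
                values[seg] = float(i % 5)
                i += 1
        decomp = variance_explained(
            make_matrix(calls), make_phenotype_table(values), "RS", ["L1", "L2"]
        )
        assert decomp.model == "two_locus"

    def test_h4_like_share_recovery(self):
        """Shares configured at the reported 15.6-25.8% band are recovered on
        average across simulated populations."""
        target1, target2 = 25.8, 15.6
        a1 = math.sqrt(4 * target1)
        a2 = math.sqrt(4 * target2)
        sd = math.sqrt(100 - target1 - target2)
        rng = np.random.default_rng(55)
        shares1, shares2 = [], []
        for sim in range(300):
            masks = {
                "L1": set(np.flatnonzero(rng.random(77) < 0.5).tolist()),
                "L2": set(np.flatnonzero(rng.random(77) < 0.5).tolist()),
            }
            masks = {k: (v if 2 <= len(v) <= 75 else set(range(38))) for k, v in masks.items()}
            matrix = matrix_from_masks(masks, 77)
            calls = matrix.frame.to_numpy(object)
            y = (
                50.0
                + a1 * (calls[:, list(matrix.marker_ids).index("L1")] == "B")
                + a2 * (calls[:, list(matrix.marker_ids).index("L2")] == "B")
                + rng.normal(0, sd, 77)
            )
            pheno = make_phenotype_table(
                {f"s{i:02d}": float(y[i]) for i in range(77)}, trait="T70"
            )
            decomp = variance_explained(matrix, pheno, "T70", ["L1", "L2"])
            shares1.append(decomp.percent("L1"))
            shares2.append(decomp.percent("L2"))
        assert np.mean(shares1) == pytest.approx(target1, abs=2.0)
        assert np.mean(shares2) == pytest.approx(target2, abs=2.0)


class TestSelectExtremes:
    def test_best_decile_of_77_is_7(self):
        rng = np.random.default_rng(1)
        pheno = make_phenotype_table(
            {f"s{i:02d}": float(v) for i, v in enumerate(rng.uniform(0, 50, 77))}
        )
        assert len(select_extremes(pheno, "RS", fraction=0.1)) == 7

    def test_fraction_one_returns_all(self):
        pheno = make_phenotype_table({f"s{i}": float(i) for i in range(10)})
        assert len(select_extremes(pheno, "RS", fraction=1.0)) == 10

    def test_manual_sort_oracle(self):
        values = {
            "s3": 4.0, "s1": 2.0, "s7": 9.0, "s2": 2.0, "s5": 1.0,
            "s9": 8.0, "s4": 6.0, "s0": 3.0, "s8": 7.0, "s6": 5.0,
        }
        pheno = make_phenotype_table(values)
        got = select_extremes(pheno, "RS", fraction=0.4, direction="lowest")
        assert got == ["s5", "s1", "s2", "s0"]  # ties s1/s2 broken by id
        top = select_extremes(pheno, "RS", fraction=0.2, direction="highest")
        assert top == ["s7", "s9"]


class TestDesignSequentialCross:
    def _population(self, rng, n=20, fixed=("Q1", "Q2")):
        calls, values = {}, {}
        for i in range(n):
            seg = f"s{i:02d}"
            calls[seg] = {
                "Q1": rng.choice(["B", "G"]),
                "Q2": rng.choice(["B", "G"]),
                "M1": rng.choice(["B", "G"]),
                "M2": rng.choice(["B", "G"]),
            }
            values[seg] = float(rng.uniform(0, 40))
        return make_matrix(calls), make_phenotype_table(values)

    def test_two_qualifying_returns_that_pair(self):
        calls = {
            "s1": {"Q1": "B", "M1": "B"},
            "s2": {"Q1": "B", "M1": "G"},
            "s3": {"Q1": "G", "M1": "B"},
        }
        pheno = make_phenotype_table({"s1": 1.0, "s2": 30.0, "s3": 15.0})
        pair, het = design_sequential_cross(
            make_matrix(calls), pheno, "RS", ["Q1"], "B"
        )
        assert pair == ("s1", "s2")
        assert het == ["M1"]

    def test_too_few_qualifying_rejected(self):
        calls = {"s1": {"Q1": "B"}, "s2": {"Q1": "G"}}
        pheno = make_phenotype_table({"s1": 1.0, "s2": 2.0})
        with pytest.raises(ValueError):
            design_sequential_cross(make_matrix(calls), pheno, "RS", ["Q1"], "B")

    def test_exhaustive_pair_oracle(self):
        """Returned pair maximizes |trait difference| over all qualifying
        pairs (checked by brute force on random 20-segregant tables)."""
        rng = np.random.default_rng(41)
        for _ in range(50):
            matrix, pheno = self._population(rng)
            means = pheno.trait_means("RS")
            qualifying = [
                s
                for s in matrix.segregants
                if matrix.frame.at[s, "Q1"] == "B" and matrix.frame.at[s, "Q2"] == "B"
            ]
            if len(qualifying) < 2:
                continue
            best = max(
                itertools.combinations(sorted(qualifying), 2),
                key=lambda pr: (abs(means[pr[0]] - means[pr[1]]), pr),
            )
            pair, het = design_sequential_cross(
                matrix, pheno, "RS", ["Q1", "Q2"], "B"
            )
            assert pair == best
            assert "Q1" not in het and "Q2" not in het

    def test_virtual_hybrid_excludes_fixed_loci(self, h4_population, h4_config):
        panel, matrix, pheno = h4_population
        fixed = [q.marker_id for q in h4_config.qtls]
        pair, het = design_sequential_cross(matrix, pheno, "RS", fixed, "B")
        assert not set(fixed) & set(het)


class TestSequentialMappingLogic:
    def test_conditioning_increases_minor_qtl_power(self):
        """Fixing the two major QTLs (H5-style cross) raises detection power
        for a minor ~7%-variance QTL at n=84."""
        minor_share = 7.0
        a_minor = math.sqrt(4 * minor_share)  # ~5.3 against residual below
        major1, major2 = simulate.QtlSpec("IV_766", -12.0, "B"), simulate.QtlSpec(
            "VIII_281", -10.0, "B"
        )
        minor = simulate.QtlSpec("XV_545", a_minor, "G")  # G improves, like XV_1051
        sd = math.sqrt(100 - 4 * minor_share)
        hits_h4 = hits_h5 = 0
        n_rep = 25
        for rep in range(n_rep):
            cfg = simulate.SimulationConfig(
                seed=9000 + rep,
                n_segregants=84,
                qtls=[major1, major2, minor],
                trait_mean=40.0,
                residual_sd=sd,
            )
            rng = np.random.default_rng(cfg.seed)
            panel, matrix, pheno = simulate.simulate_population(cfg)

            def minor_significant(mat, ph):
                scan = wilcoxon_scan(mat, ph, "RS")
                row = scan[scan["marker"] == minor.marker_id]
                return (not row.empty) and row["p"].iloc[0] < 0.05

            if minor_significant(matrix, pheno):
                hits_h4 += 1

            # H5: both majors fixed to B, minor still segregating
            hybrid = (
                np.array(
                    [
                        "B" if mid in (major1.marker_id, major2.marker_id) else "B"
                        for mid in panel.ids
                    ],
                    dtype=object,
                ),
                np.array(
                    [
                        "B" if mid in (major1.marker_id, major2.marker_id) else "G"
                        for mid in panel.ids
                    ],
                    dtype=object,
                ),
            )
            matrix5 = simulate.simulate_segregant_matrix(
                hybrid, panel, 84, rng=rng, id_prefix="h5_"
            )
            pheno5 = simulate.simulate_phenotypes(
                matrix5, cfg.qtls, cfg.trait_mean, cfg.residual_sd, rng=rng,
                n_replicates=1,
            )
            if minor_significant(matrix5, pheno5):
                hits_h5 += 1
        assert hits_h5 > hits_h4


class TestScanWithThresholds:
    def test_linkage_result_round_trip(self, h4_population, tmp_path):
        from nilqtl import core_io

        panel, matrix, pheno = h4_population
        result = scan_with_thresholds(
            matrix, pheno, "RS", n_perm=150, seed=2, panel=panel
        )
        path = tmp_path / "scan.tsv"
        core_io.write_linkage_table(result, path)
        back = core_io.read_linkage_table(path)
        assert len(back) == len(result.table)
        merged = back.set_index("marker")["neglog10_p"]
        for _, row in result.table.iterrows():
            assert merged[row["marker"]] == pytest.approx(row["neglog10_p"], abs=5e-7)
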