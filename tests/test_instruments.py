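"""Instrument selection, clumping, harmonization, strength and power."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import summr
from summr.errors import DomainError, LDMismatchError
from summr.instruments import (PowerSpec, clump, f_statistic, harmonize,
                               instrument_strength, power_at_n,
                               required_sample_size, select_significant,
                               variant_r2)
from summr.sumstats import LDMatrix

from conftest import make_table


class TestSelectSignificant:
    def test_boundary_is_strict(self):
        table = make_table([{"pvalue": 5.0e-8}, {"pvalue": 4.9e-8}])
        kept = select_significant(table)
        assert list(kept.variants["snp_id"]) == ["rs2"]

    def test_threshold_one_keeps_all(self):
        table = make_table([{"pvalue": 0.5}, {"pvalue": 0.999}])
        assert select_significant(table, 1.1).n_variants == 2


def brute_force_clump(table, ld, r2_threshold, window_kb):
    """Independent oracle: literal greedy definition over explicit pair checks."""
    rows = {r.snp_id: r for r in table.variants.itertuples(index=False)}
    unassigned = sorted(rows, key=lambda s: (rows[s].pvalue, s))
    kept = []
    while unassigned:
        index = unassigned.pop(0)
        kept.append(index)
        survivors = []
        for other in unassigned:
            same_chrom = rows[other].chrom == rows[index].chrom
            close = abs(rows[other].pos - rows[index].pos) <= window_kb * 1000
            linked = ld is None or ld.lookup(index, other) >= r2_threshold
            if not (same_chrom and close and linked):
                survivors.append(other)
        unassigned = survivors
    return sorted(kept)


def random_clump_instance(seed, n=60):
    rng = np.random.default_rng(seed)
    rows = [{"snp_id": f"rs{i}", "chrom": str(rng.integers(1, 4)),
             "pos": int(rng.integers(1, 50_000_000)),
             "pvalue": float(rng.uniform(1e-30, 1e-4))} for i in range(n)]
    table = make_table(rows)
    m = rng.uniform(0, 1, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    ld = LDMatrix([f"rs{i}" for i in range(n)], m)
    return table, ld


class TestClump:
    def test_linked_pair_keeps_most_significant(self):
        table = make_table([
            {"snp_id": "rsA", "chrom": "1", "pos": 1_000_000, "pvalue": 1e-20},
            {"snp_id": "rsB", "chrom": "1", "pos": 1_100_000, "pvalue": 1e-9},
        ])
        ld = LDMatrix(["rsA", "rsB"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert list(clump(table, ld).variants["snp_id"]) == ["rsA"]

    def test_below_r2_threshold_keeps_both(self):
        table = make_table([
            {"snp_id": "rsA", "chrom": "1", "pos": 1_000_000, "pvalue": 1e-20},
            {"snp_id": "rsB", "chrom": "1", "pos": 1_100_000, "pvalue": 1e-9},
        ])
        ld = LDMatrix(["rsA", "rsB"], np.array([[1.0, 0.0005], [0.0005, 1.0]]))
        assert clump(table, ld).n_variants == 2

    def test_cross_chromosome_never_clumped(self):
        table = make_table([
            {"snp_id": "rsA", "chrom": "1", "pos": 1_000_000, "pvalue": 1e-20},
            {"snp_id": "rsB", "chrom": "2", "pos": 1_000_000, "pvalue": 1e-9},
        ])
        ld = LDMatrix(["rsA", "rsB"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert clump(table, ld).n_variants == 2

    def test_missing_variant_in_ld_is_error(self):
        table = make_table([{"snp_id": "rsA"}, {"snp_id": "rsB"}])
        ld = LDMatrix(["rsA"], np.array([[1.0]]))
        with pytest.raises(LDMismatchError, match="rsB"):
            clump(table, ld)

    def test_distance_only_fallback_warns(self):
        table = make_table([
            {"snp_id": "rsA", "chrom": "1", "pos": 1_000_000, "pvalue": 1e-20},
            {"snp_id": "rsB", "chrom": "1", "pos": 1_100_000, "pvalue": 1e-9},
        ])
        with pytest.warns(UserWarning, match="distance-only"):
            kept = clump(table, None)
        assert list(kept.variants["snp_id"]) == ["rsA"]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        table, ld = random_clump_instance(seed)
        r2_t, window = 0.3, 1000
        kept = clump(table, ld, r2_t, window)
        assert sorted(kept.variants["snp_id"]) == brute_force_clump(
            table, ld, r2_t, window)


class TestHarmonize:
    def _pair(self, exp_row, out_row):
        exposure = make_table([exp_row])
        outcome = make_table([out_row], trait_name="out")
        return harmonize(exposure, outcome)

    def test_allele_swap_negates_and_reflects(self):
        hset = self._pair(
            {"effect_allele": "A", "other_allele": "G", "beta": 0.02, "eaf": 0.3},
            {"effect_allele": "G", "other_allele": "A", "beta": 0.05, "eaf": 0.7},
        )
        rec = hset.records.iloc[0]
        assert rec.beta_out == -0.05 and rec.eaf_out == pytest.approx(0.3)
        assert rec.sign_flipped and not rec.strand_complemented

    def test_intermediate_palindrome_excluded(self):
        hset = self._pair(
            {"effect_allele": "A", "other_allele": "T", "eaf": 0.50},
            {"effect_allele": "A", "other_allele": "T", "eaf": 0.50},
        )
        assert hset.nsnp == 0
        assert list(hset.excluded["reason"]) == ["palindromic_intermediate_eaf"]

    def test_strand_complement_recognized(self):
        hset = self._pair(
            {"effect_allele": "A", "other_allele": "G", "beta": 0.02, "eaf": 0.3},
            {"effect_allele": "T", "other_allele": "C", "beta": 0.05, "eaf": 0.3},
        )
        rec = hset.records.iloc[0]
        assert rec.beta_out == 0.05 and rec.strand_complemented and not rec.sign_flipped

    def test_complement_and_swap(self):
        hset = self._pair(
            {"effect_allele": "A", "other_allele": "G", "beta": 0.02, "eaf": 0.3},
            {"effect_allele": "C", "other_allele": "T", "beta": 0.05, "eaf": 0.7},
        )
        rec = hset.records.iloc[0]
        assert rec.beta_out == -0.05 and rec.sign_flipped and rec.strand_complemented

    def test_unresolvable_alleles_excluded(self):
        hset = self._pair(
            {"effect_allele": "A", "other_allele": "G"},
            {"effect_allele": "A", "other_allele": "C"},
        )
        assert list(hset.excluded["reason"]) == ["allele_mismatch"]

    def test_missing_in_outcome(self):
        exposure = make_table([{"snp_id": "rs1"}, {"snp_id": "rs2"}])
        outcome = make_table([{"snp_id": "rs1"}], trait_name="out")
        outcome.variants.loc[0, "snp_id"] = "rs1"
        hset = harmonize(exposure, outcome)
        assert ("rs2", "missing_in_outcome") in hset.excluded.itertuples(index=False)

    def test_exposure_reoriented_positive(self):
        hset = self._pair(
            {"effect_allele": "A", "other_allele": "G", "beta": -0.02, "eaf": 0.3},
            {"effect_allele": "A", "other_allele": "G", "beta": 0.05, "eaf": 0.3},
        )
        rec = hset.records.iloc[0]
        assert rec.beta_exp == 0.02 and rec.beta_out == -0.05
        assert rec.eaf_exp == pytest.approx(0.7)

    def test_palindrome_outside_window_oriented_by_eaf(self):
        hset = self._pair(
            {"effect_allele": "A", "other_allele": "T", "beta": 0.02, "eaf": 0.2},
            {"effect_allele": "A", "other_allele": "T", "beta": 0.05, "eaf": 0.8},
        )
        rec = hset.records.iloc[0]  # opposite frequency sides: strand flip inferred
        assert rec.beta_out == -0.05 and rec.eaf_out == pytest.approx(0.2)

    def test_partition_into_records_and_excluded(self):
        exposure, outcome, _, _ = summr.simulate_two_sample(
            summr.SimulationModel(n_snps=40, seed=5))
        exposure2, outcome2, _ = summr.inject_harmonization_noise(
            exposure, outcome, 0.3, 0.2, 0.1, seed=6)
        hset = harmonize(exposure2, outcome2)
        all_ids = sorted(exposure2.variants["snp_id"])
        assert sorted(list(hset.records["snp_id"]) + list(hset.excluded["snp_id"])) == all_ids


class TestStrengthFormulas:
    def test_zero_beta_gives_zero_r2(self):
        assert variant_r2(0.0, 0.3, 0.01, 1000) == 0.0

    @given(st.floats(-0.5, 0.5), st.floats(0.01, 0.99), st.floats(1e-4, 0.1),
           st.integers(100, 2_000_000))
    @settings(max_examples=200, deadline=None)
    def test_printed_form_equals_simplified(self, beta, eaf, se, n):
        printed = variant_r2(beta, eaf, se, n)
        simplified = beta ** 2 / (beta ** 2 + se ** 2 * n)
        assert printed == pytest.approx(simplified, abs=1e-12)

    def test_half_variance_closed_form(self):
        n, se = 10_000, 0.01
        assert variant_r2(se * math.sqrt(n), 0.25, se, n) == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_eaf_rejected(self):
        with pytest.raises(DomainError):
            variant_r2(0.1, 0.0, 0.01, 1000)

    def test_f_statistic_values(self):
        assert f_statistic(0.0, 100) == 0.0
        assert f_statistic(0.01, 1002) == pytest.approx(0.01 * 1000 / 0.99)
        with pytest.raises(DomainError):
            f_statistic(1.0, 100)

    def test_weak_flag_below_ten(self):
        table = make_table([{"beta": 0.001, "se": 0.005, "n": 10000},
                            {"beta": 0.05, "se": 0.005, "n": 10000}])
        df, total = instrument_strength(table)
        assert list(df["weak"]) == [True, False]
        assert df["f"].iloc[0] < 10 < df["f"].iloc[1]
        assert total == pytest.approx(df["r2"].sum())


class TestPower:
    K = 12906 / 121885

    def test_null_or_rejected(self):
        with pytest.raises(DomainError):
            required_sample_size(PowerSpec(1.0, self.K, 0.01))

    def test_inverse_square_scaling_in_effect(self):
        n1 = required_sample_size(PowerSpec(math.exp(-0.4), self.K, 0.01))
        n2 = required_sample_size(PowerSpec(math.exp(-0.2), self.K, 0.01))
        assert n2 == pytest.approx(4 * n1, rel=1e-6)

    def test_self_inverse_at_published_scale(self):
        # back-compute the r2 that makes N = 74,894 the exact requirement
        b = math.log(0.72)
        z = 1.959963984540054 + 0.8416212335729143
        r2 = z ** 2 / (74_894 * b ** 2 * self.K * (1 - self.K))
        assert required_sample_size(PowerSpec(0.72, self.K, r2)) == 74_894

    def test_power_and_sample_size_mutually_inverse(self):
        spec = PowerSpec(0.72, self.K, 0.01)
        n = required_sample_size(spec)
        assert power_at_n(PowerSpec(0.72, self.K, 0.01, n=n)) >= 0.80
        assert power_at_n(PowerSpec(0.72, self.K, 0.01, n=max(2, n - 1))) < 0.80
        # power is monotone in N
        assert power_at_n(PowerSpec(0.72, self.K, 0.01, n=2 * n)) > \
            power_at_n(PowerSpec(0.72, self.K, 0.01, n=n))
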