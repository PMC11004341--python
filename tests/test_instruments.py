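"""Instrument selection: p filter, LD clumping, F statistic, variance explained."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrchain.instruments import (
    LDTable,
    SelectionConfig,
    clump,
    f_statistic,
    filter_by_pvalue,
    read_ld_table,
    select_instruments,
    variance_explained,
    write_ld_table,
)
from mrchain.exceptions import ConfigError

from conftest import make_sumstats


def brute_force_clump(frame: pd.DataFrame, ld: LDTable, config: SelectionConfig):
    """Independent reimplementation of greedy clumping for oracle checks."""
    candidates = {row["rsid"]: row for row in frame.to_dict("records")}
    kept = []
    while candidates:
        best = min(candidates.values(), key=lambda r: (r["pvalue"], r["rsid"]))
        kept.append(best["rsid"])
        del candidates[best["rsid"]]
        for rsid in list(candidates):
            other = candidates[rsid]
            in_window = (
                other["chrom"] == best["chrom"]
                and abs(other["pos"] - best["pos"]) <= config.clump_window_kb * 1000
            )
            if in_window and ld.r2(best["rsid"], rsid) >= config.clump_r2:
                del candidates[rsid]
    return sorted(kept)


class TestSelectionConfig:
    def test_defaults_match_study_thresholds(self):
        cfg = SelectionConfig()
        assert cfg.p_threshold == 5e-5
        assert cfg.clump_r2 == 0.001
        assert cfg.clump_window_kb == 10_000
        assert cfg.f_min == 10

    @pytest.mark.parametrize(
        "kw", [{"p_threshold": 0}, {"clump_r2": 1.5}, {"clump_window_kb": -1}, {"f_min": -2}]
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ConfigError):
            SelectionConfig(**kw)


class TestPvalueFilter:
    def test_retains_exactly_sub_threshold(self):
        stats = make_sumstats(
            [{"pvalue": 1e-6}, {"pvalue": 4e-5}, {"pvalue": 6e-5}]
        )
        kept = filter_by_pvalue(stats, 5e-5)
        assert list(kept.frame["pvalue"]) == [1e-6, 4e-5]

    def test_all_null_input_gives_empty_output(self):
        stats = make_sumstats([{"pvalue": 1.0}, {"pvalue": 1.0}])
        assert len(filter_by_pvalue(stats, 5e-5)) == 0

    def test_empty_input_gives_empty_output(self):
        stats = make_sumstats([{"pvalue": 1.0}])
        empty = filter_by_pvalue(stats, 5e-5)
        assert len(filter_by_pvalue(empty, 5e-5)) == 0

    def test_idempotent(self):
        stats = make_sumstats([{"pvalue": p} for p in (1e-8, 1e-4, 0.2)])
        once = filter_by_pvalue(stats, 1e-3)
        twice = filter_by_pvalue(once, 1e-3)
        pd.testing.assert_frame_equal(once.frame, twice.frame)


class TestFStatistic:
    @pytest.mark.parametrize(
        "beta,se,expected", [(0.02, 0.004, 25.0), (0.01, 0.005, 4.0), (0.0, 0.01, 0.0)]
    )
    def test_arithmetic(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)


class TestVarianceExplained:
    def test_stated_formula(self):
        # z = 10, n = 1000 -> 100/1100
        assert variance_explained(0.1, 0.01, 1000) == pytest.approx(100 / 1100)

    def test_zero_effect(self):
        assert variance_explained(0.0, 0.01, 1000) == 0.0

    def test_monotone_decreasing_in_n(self):
        values = [variance_explained(0.1, 0.01, n) for n in (100, 1000, 10_000, 1e7)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] < 1e-4

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(0.1, 0.01, 2)


class TestClump:
    def test_worked_example_keeps_s1_s3(self):
        stats = make_sumstats(
            [
                {"rsid": "S1", "pvalue": 1e-8, "pos": 1000},
                {"rsid": "S2", "pvalue": 1e-6, "pos": 2000},
                {"rsid": "S3", "pvalue": 1e-7, "pos": 3000},
            ]
        )
        ld = LDTable({("S1", "S2"): 0.5})
        kept, report = clump(stats, ld, SelectionConfig())
        assert sorted(kept.frame["rsid"]) == ["S1", "S3"]
        rep = report.set_index("rsid")["disposition"]
        assert rep["S2"] == "clumped_to:S1"

    def test_outside_window_retained_despite_ld(self):
        stats = make_sumstats(
            [
                {"rsid": "far1", "pos": 1_000},
                {"rsid": "far2", "pos": 20_001_000, "pvalue": 1e-6},
            ]
        )
        ld = LDTable({("far1", "far2"): 0.9})
        kept, _ = clump(stats, ld, SelectionConfig())
        assert len(kept) == 2

    def test_other_chromosome_never_discarded(self):
        stats = make_sumstats(
            [{"rsid": "a", "chrom": "1"}, {"rsid": "b", "chrom": "2", "pvalue": 1e-6}]
        )
        ld = LDTable({("a", "b"): 0.99})
        kept, _ = clump(stats, ld, SelectionConfig())
        assert len(kept) == 2

    def test_single_snp_retained(self):
        kept, _ = clump(make_sumstats([{}]), LDTable(), SelectionConfig())
        assert len(kept) == 1

    def test_output_sorted_and_order_independent(self):
        rng = np.random.default_rng(1)
        rows = [
            {"rsid": f"r{i}", "chrom": str(1 + i % 2), "pos": 1000 * (1 + i),
             "pvalue": float(rng.uniform(1e-9, 1e-5))}
            for i in range(12)
        ]
        ld = LDTable(
            {(f"r{i}", f"r{j}"): float(rng.uniform(0, 0.4))
             for i in range(12) for j in range(i + 1, 12) if rng.random() < 0.4}
        )
        base = make_sumstats(rows)
        shuffled = make_sumstats([rows[i] for i in rng.permutation(12)])
        kept_a, _ = clump(base, ld, SelectionConfig())
        kept_b, _ = clump(shuffled, ld, SelectionConfig())
        assert list(kept_a.frame["rsid"]) == list(kept_b.frame["rsid"])
        # sorted by (chrom, pos)
        frame = kept_a.frame
        assert list(frame.sort_values(["chrom", "pos"]).index) == list(frame.index)

    def test_retained_pairs_below_r2_within_window(self):
        rng = np.random.default_rng(7)
        rows = [
            {"rsid": f"w{i}", "chrom": "3", "pos": 10_000 * i,
             "pvalue": float(rng.uniform(1e-9, 1e-5))}
            for i in range(15)
        ]
        ld = LDTable(
            {(f"w{i}", f"w{j}"): float(rng.uniform(0, 0.01))
             for i in range(15) for j in range(i + 1, 15)}
        )
        kept, _ = clump(make_sumstats(rows), ld, SelectionConfig())
        ids = list(kept.frame["rsid"])
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                assert ld.r2(a, b) < 0.001

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 21))
        rows = [
            {"rsid": f"x{i}", "chrom": str(1 + int(rng.integers(2))),
             "pos": int(rng.integers(1, 3_000) * 10_000),
             "pvalue": float(rng.uniform(1e-10, 1e-4))}
            for i in range(m)
        ]
        ld = LDTable(
            {(f"x{i}", f"x{j}"): float(rng.uniform(0, 1))
             for i in range(m) for j in range(i + 1, m) if rng.random() < 0.5}
        )
        config = SelectionConfig(clump_r2=0.1)
        kept, _ = clump(make_sumstats(rows), ld, config)
        oracle = brute_force_clump(make_sumstats(rows).frame, ld, config)
        assert sorted(kept.frame["rsid"]) == oracle


class TestLDTable:
    def test_symmetric_lookup_and_default_zero(self):
        table = LDTable({("a", "b"): 0.7})
        assert table.r2("b", "a") == 0.7
        assert table.r2("a", "c") == 0.0

    def test_round_trip(self, tmp_path):
        table = LDTable({("a", "b"): 0.7, ("c", "d"): 0.001})
        path = tmp_path / "ld.tsv"
        write_ld_table(table, path)
        back = read_ld_table(path)
        assert back.r2("b", "a") == 0.7 and back.r2("c", "d") == 0.001

    def test_invalid_r2_rejected(self):
        with pytest.raises(ValueError):
            LDTable({("a", "b"): 1.2})


class TestSelectInstruments:
    def test_dispositions_cover_every_snp(self):
        exposure = make_sumstats(
            [
                {"rsid": "keep", "pvalue": 1e-8, "beta": 0.05, "se": 0.005},
                {"rsid": "weak", "pvalue": 1e-6, "beta": 0.005, "se": 0.005, "pos": 5_000_000},
                {"rsid": "pfail", "pvalue": 0.1},
                {"rsid": "palin", "pvalue": 1e-8, "effect_allele": "A",
                 "other_allele": "T", "pos": 9_000_000},
                {"rsid": "missing", "pvalue": 1e-8, "beta": 0.08, "se": 0.005,
                 "pos": 12_000_000},
            ]
        )
        outcome = make_sumstats(
            [{"rsid": "keep"}, {"rsid": "weak"}, {"rsid": "pfail"}, {"rsid": "palin"}]
        )
        instr, report = select_instruments(exposure, outcome)
        rep = report.set_index("rsid")["disposition"]
        assert rep["keep"] == "retained"
        assert rep["weak"] == "weak_F"
        assert rep["pfail"] == "p_fail"
        assert rep["palin"] == "palindromic"
        assert rep["missing"] == "absent_in_outcome"
        assert list(instr["rsid"]) == ["keep"]
        assert instr.loc[0, "f_stat"] == pytest.approx(100.0)
        assert 0 <= instr.loc[0, "r2_exp"] <= 1

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(threshold=st.floats(1e-8, 0.9))
    def test_p_filter_monotone_in_threshold(self, threshold):
        stats = make_sumstats([{"pvalue": p} for p in np.geomspace(1e-9, 0.5, 12)])
        small = set(filter_by_pvalue(stats, threshold).frame["rsid"])
        large = set(filter_by_pvalue(stats, min(0.95, threshold * 10)).frame["rsid"])
        assert small <= large
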