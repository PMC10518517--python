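import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bidirmr.instruments import (LDReference, choose_p_threshold, clump,
                                 compute_f_statistic, compute_r_squared,
                                 diagnostics_for, filter_weak, find_proxies,
                                 screen_confounders_and_outcome)
from bidirmr.instruments import InstrumentDiagnostics
from tests.conftest import make_dataset


class TestThresholdChoice:
    def test_enough_gs_snps_keeps_strict(self):
        ds = make_dataset([{"p_value": 1e-9}] * 5)
        assert choose_p_threshold(ds) == 5e-8

    def test_too_few_gs_snps_relaxes(self):
        ds = make_dataset([{"p_value": 1e-9}] * 2 + [{"p_value": 1e-6}] * 10)
        assert choose_p_threshold(ds) == 1e-5

    def test_relaxed_returned_even_when_selection_will_be_empty(self):
        ds = make_dataset([{"p_value": 0.5}] * 3)
        assert choose_p_threshold(ds) == 1e-5
        assert clump(ds, 1e-5, LDReference()) == []


class TestClump:
    def test_independent_candidates_all_kept(self):
        ds = make_dataset([{"p_value": 1e-9}, {"p_value": 1e-8}, {"p_value": 1e-7}])
        kept = clump(ds, 5e-8, LDReference(), r2_max=0.001)
        assert set(kept) == {"rs1", "rs2"}  # rs3 above threshold

    def test_one_ld_block_keeps_best_p(self):
        ds = make_dataset([
            {"variant_id": "rs1", "p_value": 1e-9, "position": 1000},
            {"variant_id": "rs2", "p_value": 1e-8, "position": 2000},
            {"variant_id": "rs3", "p_value": 1e-7, "position": 3000}])
        ld = LDReference({("rs1", "rs2"): 0.5, ("rs1", "rs3"): 0.5,
                          ("rs2", "rs3"): 0.5})
        assert clump(ds, 5e-7, ld) == ["rs1"]

    def test_window_rule_spares_distant_pairs(self):
        ds = make_dataset([
            {"variant_id": "rs1", "p_value": 1e-9, "position": 1000},
            {"variant_id": "rs2", "p_value": 1e-8, "position": 20_000_000 + 1000}])
        ld = LDReference({("rs1", "rs2"): 0.5})
        assert clump(ds, 5e-8, ld, window_bp=10_000_000) == ["rs1", "rs2"]

    def test_output_invariant_to_row_order(self):
        rows = [{"variant_id": f"rs{i}", "p_value": p, "position": 1000 + i * 500}
                for i, p in enumerate([1e-9, 1e-8, 1e-7, 1e-10, 1e-6], 1)]
        ld = LDReference({("rs4", "rs1"): 0.8, ("rs2", "rs3"): 0.9})
        a = clump(make_dataset(rows), 1e-5, ld)
        b = clump(make_dataset(rows[::-1]), 1e-5, ld)
        assert a == b

    def test_survivor_pairs_satisfy_rule(self):
        rng = np.random.default_rng(5)
        rows = [{"variant_id": f"rs{i}", "p_value": float(rng.uniform(1e-10, 1e-6)),
                 "position": int(rng.integers(1, 3_000_000))} for i in range(1, 13)]
        pairs = {(f"rs{i}", f"rs{j}"): float(rng.uniform(0, 1))
                 for i in range(1, 13) for j in range(i + 1, 13) if rng.random() < 0.4}
        ld = LDReference(pairs)
        ds = make_dataset(rows)
        kept = clump(ds, 1e-5, ld, r2_max=0.1, window_bp=1_000_000)
        pos = {v: int(ds.table.loc[v, "position"]) for v in kept}
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert ld.r2(a, b) < 0.1 or abs(pos[a] - pos[b]) > 1_000_000

    def test_missing_ld_reference_is_error(self):
        ds = make_dataset([{"p_value": 1e-9}])
        with pytest.raises(ValueError, match="pre-clumped"):
            clump(ds, 5e-8, None)
        assert clump(ds, 5e-8, None, pre_clumped=True) == ["rs1"]


class TestStrengthStatistics:
    @pytest.mark.parametrize("eaf,beta,expected", [
        (0.5, 0.1, 0.005),
        (0.1, 0.2, 0.0072),
        (0.3, 0.0, 0.0),
    ])
    def test_r_squared_formula(self, eaf, beta, expected):
        assert compute_r_squared(eaf, beta) == pytest.approx(expected, rel=1e-12)

    def test_r_squared_domain_and_clipping(self):
        with pytest.raises(ValueError):
            compute_r_squared(0.0, 0.1)
        assert compute_r_squared(0.5, 3.0) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("r2,n,expected", [
        (0.0, 100, 0.0),
        (0.005, 1000, 0.005 * 998 / 0.995),        # ~5.0151
        (0.01, 8293, 0.01 * 8291 / 0.99),          # ~83.747, cytokine-GWAS n
    ])
    def test_f_statistic_formula(self, r2, n, expected):
        assert compute_f_statistic(r2, n) == pytest.approx(expected, rel=1e-12)

    def test_f_statistic_rejects_tiny_n(self):
        with pytest.raises(ValueError):
            compute_f_statistic(0.01, 2)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(r2=st.floats(1e-6, 0.5), n=st.integers(10, 10**6),
           dr=st.floats(1e-6, 0.4), dn=st.integers(1, 10**5))
    def test_f_statistic_monotone(self, r2, n, dr, dn):
        f = compute_f_statistic(r2, n)
        assert compute_f_statistic(min(r2 + dr, 0.95), n) > f
        assert compute_f_statistic(r2, n + dn) > f

    def test_weak_filter_boundary(self):
        diags = [InstrumentDiagnostics("rs1", 0.001, 9.99),
                 InstrumentDiagnostics("rs2", 0.001, 10.0),
                 InstrumentDiagnostics("rs3", 0.001, 50.0)]
        kept = filter_weak(diags, f_min=10.0)
        assert [d.variant_id for d in kept] == ["rs2", "rs3"]
        assert diags[0].excluded_reason == "weak"
        assert filter_weak([], 10.0) == []

    def test_diagnostics_consistent_with_formulas(self, dataset_factory):
        ds = dataset_factory([{"eaf": 0.5, "beta": 0.1, "n": 1000}])
        (d,) = diagnostics_for(ds, ["rs1"])
        assert d.r_squared == pytest.approx(0.005)
        assert d.f_statistic == pytest.approx(0.005 * 998 / 0.995)


class TestScreens:
    def screen(self, pmap):
        return make_dataset([{"variant_id": v, "p_value": p} for v, p in pmap.items()],
                            trait_id="BMI")

    def test_bonferroni_threshold_excludes(self):
        ids = [f"rs{i}" for i in range(1, 11)]
        scr = self.screen({v: 0.5 for v in ids} | {"rs1": 0.001})
        kept, log = screen_confounders_and_outcome(ids, {"BMI": scr})
        assert "rs1" not in kept and len(kept) == 9
        assert ("rs1", "confounder:BMI") in log

    def test_above_threshold_retained(self):
        ids = [f"rs{i}" for i in range(1, 11)]
        scr = self.screen({v: 0.5 for v in ids} | {"rs1": 0.01})  # 0.01 > 0.05/10
        kept, _ = screen_confounders_and_outcome(ids, {"BMI": scr})
        assert len(kept) == 10

    def test_untestable_instrument_retained(self):
        scr = self.screen({"rs1": 0.5})
        kept, log = screen_confounders_and_outcome(["rs1", "rs99"], {"BMI": scr})
        assert "rs99" in kept
        assert ("rs99", "not testable in BMI") in log

    def test_threshold_counts_only_testable(self):
        # 2 of 10 instruments testable -> threshold 0.025, p=0.02 excluded
        ids = [f"rs{i}" for i in range(1, 11)]
        scr = self.screen({"rs1": 0.02, "rs2": 0.5})
        kept, _ = screen_confounders_and_outcome(ids, {"BMI": scr})
        assert "rs1" not in kept and len(kept) == 9


class TestProxies:
    def outcome_with(self, pmap):
        return make_dataset([{"variant_id": v, "p_value": p} for v, p in pmap.items()],
                            trait_id="out")

    def test_good_proxy_substituted(self):
        ld = LDReference({("rs1", "px1"): 0.95})
        out = self.outcome_with({"px1": 0.3})
        subs, dropped = find_proxies(["rs1"], ld, out)
        assert subs == {"rs1": "px1"} and dropped == []

    def test_weak_proxy_dropped(self):
        ld = LDReference({("rs1", "px1"): 0.85})
        subs, dropped = find_proxies(["rs1"], ld, self.outcome_with({"px1": 0.3}))
        assert subs == {} and dropped[0][0] == "rs1"

    def test_r2_tie_broken_by_outcome_p(self):
        ld = LDReference({("rs1", "pxA"): 0.95, ("rs1", "pxB"): 0.95})
        out = self.outcome_with({"pxA": 0.3, "pxB": 0.01})
        subs, _ = find_proxies(["rs1"], ld, out)
        assert subs == {"rs1": "pxB"}

    def test_proxy_must_be_present_in_outcome(self):
        ld = LDReference({("rs1", "px1"): 0.99})
        subs, dropped = find_proxies(["rs1"], ld, self.outcome_with({"other": 0.5}))
        assert subs == {} and len(dropped) == 1


class TestLDReference:
    def test_symmetry_identity_and_absent_pairs(self):
        ld = LDReference({("a", "b"): 0.4})
        assert ld.r2("a", "b") == ld.r2("b", "a") == 0.4
        assert ld.r2("a", "a") == 1.0
        assert ld.r2("a", "zzz") == 0.0

    def test_table_round_trip(self, tmp_path):
        ld = LDReference({("rs1", "rs2"): 0.42, ("rs2", "rs3"): 0.9})
        path = tmp_path / "ld.tsv"
        ld.to_table(path)
        back = LDReference.from_table(path)
        assert back.r2("rs2", "rs1") == pytest.approx(0.42)
        assert back.r2("rs3", "rs2") == pytest.approx(0.9)
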