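import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from lik.calling import (
    CallConfig, CandidateSet, Evidence, THREEFOLD_LOG2, bh_adjust,
    call_fold_change, call_presence_absence, combine_candidates,
    compute_log2_ratios, qc_filter,
)
from lik.errors import DesignError, InsufficientReplicationError
from lik.synthetic import ChirpSimParams, gen_chirp_experiment

from conftest import make_table


CFG = CallConfig()


def test_threefold_threshold_value():
    assert THREEFOLD_LOG2 == pytest.approx(1.584963, abs=5e-7)


class TestQcFilter:
    def test_single_peptide_and_flagged_rows_removed(self, small_design):
        inten = {s: [10.0] * 6 for s in small_design.sample_ids}
        t = make_table(small_design, inten,
                       unique_peptides=[1, 2, 5, 5, 5, 5],
                       contaminant=[False, False, True, False, False, False])
        out = qc_filter(t, CFG)
        # one single-peptide row and one contaminant row drop
        assert len(out) == 4
        assert list(out.meta.index) == ["PG001", "PG003", "PG004", "PG005"]

    def test_empty_table_passes_through(self, small_design):
        t = make_table(small_design, {s: [] for s in small_design.sample_ids})
        assert len(qc_filter(t, CFG)) == 0

    def test_removed_count_matches_direct_enumeration(self, small_design):
        rng = np.random.default_rng(0)
        n = 60
        up = rng.integers(1, 5, n).tolist()
        cont = (rng.random(n) < 0.2).tolist()
        t = make_table(small_design, {s: [10.0] * n for s in small_design.sample_ids},
                       unique_peptides=up, contaminant=cont)
        expected = sum(1 for u, c in zip(up, cont) if u >= 2 and not c)
        assert len(qc_filter(t, CFG)) == expected


class TestPresenceAbsence:
    def test_single_uv_pulldown_suffices(self, small_design):
        inten = {s: [0.0] for s in small_design.sample_ids}
        inten["uv_p"] = [100.0]
        t = make_table(small_design, inten)
        called = call_presence_absence(t, small_design, CFG)
        assert "PG000" in called
        assert called.records["PG000"][0].modes == ("uv",)

    def test_detection_only_in_controls_never_calls(self, small_design):
        inten = {s: [0.0] for s in small_design.sample_ids}
        for s in small_design.controls():
            inten[s.sample_id] = [100.0]
        t = make_table(small_design, inten)
        assert len(call_presence_absence(t, small_design, CFG)) == 0

    def test_one_native_pulldown_not_enough(self, small_design):
        inten = {s: [0.0] for s in small_design.sample_ids}
        inten["n_P1"] = [100.0]
        t = make_table(small_design, inten)
        assert len(call_presence_absence(t, small_design, CFG)) == 0

    def test_matches_brute_force_on_random_detection_matrix(self, small_design):
        rng = np.random.default_rng(1)
        n = 50
        det = rng.random((n, len(small_design.sample_ids))) < 0.4
        inten = {s: det[:, j] * 100.0
                 for j, s in enumerate(small_design.sample_ids)}
        t = make_table(small_design, inten)
        called = call_presence_absence(t, small_design, CFG).proteins

        native = [small_design.sample_ids.index(s.sample_id)
                  for s in small_design.pulldowns("native")]
        uv = [small_design.sample_ids.index(s.sample_id)
              for s in small_design.pulldowns("uv")]
        fa = [small_design.sample_ids.index(s.sample_id)
              for s in small_design.pulldowns("formaldehyde")]
        expected = {
            t.meta.index[i] for i in range(n)
            if det[i, native].sum() >= 2 or det[i, uv].sum() >= 1
            or det[i, fa].sum() >= 1
        }
        assert called == expected

    def test_no_pulldowns_is_design_error(self, small_design):
        from lik.design import ExperimentDesign, Sample
        ctrl_only = ExperimentDesign(
            [Sample("c", "native", "", "control", "no_probe", "")])
        t = make_table(ctrl_only, {"c": [1.0]})
        with pytest.raises(DesignError):
            call_presence_absence(t, ctrl_only, CFG)


class TestLog2Ratios:
    def test_exact_arithmetic(self, small_design):
        inten = {s: [1000.0] for s in small_design.sample_ids}
        inten["uv_p"] = [8000.0]
        inten["uv_c"] = [1000.0]
        t = make_table(small_design, inten)
        r = compute_log2_ratios(t, small_design)
        assert r.loc["PG000", "uv"] == pytest.approx(3.0)
        assert r.loc["PG000", "formaldehyde"] == pytest.approx(0.0)

    def test_undetected_pulldown_gives_no_ratio(self, small_design):
        inten = {s: [100.0] for s in small_design.sample_ids}
        inten["uv_p"] = [0.0]
        t = make_table(small_design, inten)
        assert np.isnan(compute_log2_ratios(t, small_design).loc["PG000", "uv"])

    def test_matches_independent_recomputation(self, small_design):
        rng = np.random.default_rng(5)
        n = 40
        inten = {s: np.exp2(rng.uniform(10, 20, n)) for s in small_design.sample_ids}
        t = make_table(small_design, inten)
        r = compute_log2_ratios(t, small_design)
        # independent recomputation straight from raw cells
        for i, pid in enumerate(t.protein_ids):
            expected = np.log2(inten["uv_p"][i]) - np.log2(inten["uv_c"][i])
            assert r.loc[pid, "uv"] == pytest.approx(expected)
            nat_p = np.mean([np.log2(inten[f"n_{p}"][i])
                             for p in ("P1", "P2", "P3")])
            nat_c = np.mean([np.log2(inten[f"n_{p}_c"][i])
                             for p in ("P1", "P2", "P3")])
            assert r.loc[pid, "native"] == pytest.approx(nat_p - nat_c)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 7), [0.2] * 7)

    def test_matches_step_up_formula_and_statsmodels(self):
        rng = np.random.default_rng(2)
        p = rng.random(100)
        adj = bh_adjust(p)
        # direct step-up formula oracle
        order = np.argsort(p)
        m = len(p)
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expected[i] = running
        np.testing.assert_allclose(adj, expected)
        np.testing.assert_allclose(
            adj, multipletests(p, method="fdr_bh")[1])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_capped(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestFoldChange:
    def _uniform_table(self, design, n=6, uv_ratio=1.0):
        inten = {s: [1000.0] * n for s in design.sample_ids}
        return make_table(design, inten)

    def test_exact_threshold_not_called(self, small_design):
        # log2 ratio exactly 1.584963... (threefold) must fail the strict test
        inten = {s: [1000.0] for s in small_design.sample_ids}
        inten["uv_p"] = [3000.0]
        t = make_table(small_design, inten)
        r = compute_log2_ratios(t, small_design)
        called = call_fold_change(r, t, small_design,
                                  CallConfig(log2fc_threshold=np.log2(3.0)))
        assert "PG000" not in called
        inten["uv_p"] = [3000.1]
        t2 = make_table(small_design, inten)
        r2 = compute_log2_ratios(t2, small_design)
        assert "PG000" in call_fold_change(
            r2, t2, small_design, CallConfig(log2fc_threshold=np.log2(3.0)))

    def test_native_needs_replicates(self, small_design):
        # small_design has 3 single-probe native pulldowns and no pooled
        # replicates -> the native contrast has 3 pulldowns / 3 controls, OK;
        # dropping to 1 control must raise
        from lik.design import ExperimentDesign, Sample
        d = ExperimentDesign([
            Sample("c1", "native", "P1", "control", "nonhomologous_probe", ""),
            Sample("p1", "native", "P1", "pulldown", "not_applicable", "c1"),
        ])
        t = make_table(d, {"c1": [10.0], "p1": [100.0]})
        r = compute_log2_ratios(t, d)
        with pytest.raises(InsufficientReplicationError):
            call_fold_change(r, t, d, CFG)

    def test_probe_vote_boundary(self, full_design):
        # planted signal in only 4 of 6 native probe combinations -> fails
        # the >4-of-6 vote even with an extreme ratio
        pulls = full_design.pulldowns("native")
        combos = full_design.probe_combos("native")
        n = 1
        inten = {s.sample_id: [1000.0] for s in full_design.samples}
        detected_combos = combos[:4]
        for s in pulls:
            if s.probe_combo in detected_combos:
                inten[s.sample_id] = [64000.0]
            else:
                inten[s.sample_id] = [0.0]
        t = make_table(full_design, inten)
        r = compute_log2_ratios(t, full_design)
        assert "PG000" not in call_fold_change(r, t, full_design, CFG)

    def test_zero_noise_recovery_is_exact(self, full_design):
        p = ChirpSimParams(n_proteins=200, n_true=20, effect_log2fc=3.0,
                           noise_sd=0.0, dropout_p=0.0, design=full_design,
                           seed=13, n_contaminants=0, n_single_peptide=0)
        table, truth = gen_chirp_experiment(p)
        r = compute_log2_ratios(table, full_design)
        called = call_fold_change(r, table, full_design, CFG).proteins
        assert called == truth.planted_interactors

    def test_calls_invariant_to_global_rescaling(self, full_design):
        p = ChirpSimParams(n_proteins=80, n_true=10, noise_sd=0.4,
                           design=full_design, seed=21,
                           n_contaminants=0, n_single_peptide=0)
        table, _ = gen_chirp_experiment(p)
        r1 = compute_log2_ratios(table, full_design)
        c1 = call_fold_change(r1, table, full_design, CFG).proteins

        from lik.io import ProteinGroupTable
        scaled = ProteinGroupTable(table.meta, table.intensities * 37.0)
        r2 = compute_log2_ratios(scaled, full_design)
        c2 = call_fold_change(r2, scaled, full_design, CFG).proteins
        assert c1 == c2
        pd.testing.assert_frame_equal(r1, r2, check_exact=False)

    def test_control_dropout_inflates_single_replicate_calls(self, full_design):
        # Under the global-pseudocount policy, a random control dropout in a
        # single-control crosslinked arm masquerades as strong enrichment:
        # uniform dropout must therefore inflate the false-call rate.
        def fdr_at(dropout):
            p = ChirpSimParams(seed=0, dropout_p=dropout)
            table, truth = gen_chirp_experiment(p)
            cfg = CFG
            filt = qc_filter(table, cfg)
            r = compute_log2_ratios(filt, p.design)
            called = call_fold_change(r, filt, p.design, cfg).proteins
            tp = len(called & truth.planted_interactors)
            return (len(called) - tp) / max(len(called), 1)

        assert fdr_at(0.0) <= 0.05
        assert fdr_at(0.05) > 0.2

    def test_calls_invariant_to_row_order(self, full_design):
        p = ChirpSimParams(n_proteins=60, n_true=8, design=full_design, seed=3,
                           n_contaminants=0, n_single_peptide=0)
        table, _ = gen_chirp_experiment(p)
        r = compute_log2_ratios(table, full_design)
        c1 = call_fold_change(r, table, full_design, CFG).proteins

        perm = np.random.default_rng(0).permutation(len(table))
        shuffled = table.subset(table.protein_ids[perm])
        r2 = compute_log2_ratios(shuffled, full_design)
        c2 = call_fold_change(r2, shuffled, full_design, CFG).proteins
        assert c1 == c2


class TestCombine:
    def test_published_scale_union(self):
        chirp = CandidateSet({f"P{i}": [Evidence("fold_change", ("native",))]
                              for i in range(131)})
        extras = [f"R{i}" for i in range(4)]
        merged = combine_candidates([chirp], extras)
        assert len(merged) == 135
        assert all(e.criterion == "rip_validated"
                   for x in extras for e in merged.evidence[x])

    def test_empty_extras_identity(self):
        cs = CandidateSet({"A": [Evidence("presence_absence", ("uv",))]})
        assert combine_candidates([cs]).proteins == {"A"}

    def test_overlap_matches_set_union(self):
        rng = np.random.default_rng(7)
        ids = [f"P{i}" for i in range(40)]
        s1 = set(rng.choice(ids, 20, replace=False))
        s2 = set(rng.choice(ids, 25, replace=False))
        extras = list(rng.choice(ids, 10, replace=False))
        cs1 = CandidateSet({p: [Evidence("presence_absence")] for p in s1})
        cs2 = CandidateSet({p: [Evidence("fold_change")] for p in s2})
        merged = combine_candidates([cs1, cs2], extras)
        assert merged.proteins == s1 | s2 | set(extras)

    def test_every_candidate_has_evidence(self, full_design):
        p = ChirpSimParams(n_proteins=100, n_true=15, design=full_design, seed=9)
        table, _ = gen_chirp_experiment(p)
        cfg = CFG
        filt = qc_filter(table, cfg)
        pa = call_presence_absence(filt, full_design, cfg)
        r = compute_log2_ratios(filt, full_design)
        fc = call_fold_change(r, filt, full_design, cfg)
        merged = combine_candidates([pa, fc])
        assert all(len(evs) >= 1 for evs in merged.evidence.values())
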