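"""Recombination scans, consensus, and event summaries."""

import math

import numpy as np
import pytest
from scipy.stats import binom

from microdiv._util import decode
from microdiv.io import AlignmentBlock, BlockRow
from microdiv.recombination import (CandidateEvent,
                                    chimera_scan, ensemble_consensus,
                                    extract_variable_sites, maxchi_scan, rdp_scan,
                                    scan_all, summarize_events, RecombinationEvent)
from microdiv.simulate import SimParams, simulate_population


def blocks_from_arrays(seqs: dict) -> list[AlignmentBlock]:
    L = len(next(iter(seqs.values())))
    rows = [BlockRow(n, f"{n}_chr", 0, L, "+", decode(s)) for n, s in sorted(seqs.items())]
    return [AlignmentBlock(0, rows)]


def mutated(seq, rate, rng):
    s = seq.copy()
    k = rng.binomial(len(s), rate)
    pos = rng.choice(len(s), k, replace=False)
    s[pos] = (s[pos] + rng.integers(1, 4, k)) % 4
    return s


class TestVariableSites:
    def test_identical_rows_no_sites(self):
        seq = np.zeros(1000, dtype=np.uint8)
        cols = extract_variable_sites(blocks_from_arrays({"a": seq, "b": seq}),
                                      ["a", "b"])
        assert cols.var_cols.size == 0 and cols.n_columns == 1000

    def test_single_substitution_located(self):
        a = np.zeros(1000, dtype=np.uint8)
        b = a.copy()
        b[7] = 2
        cols = extract_variable_sites(blocks_from_arrays({"a": a, "b": b}), ["a", "b"])
        assert cols.var_cols.tolist() == [7]

    def test_gapped_and_short_blocks_excluded(self):
        rows = [BlockRow("a", "a_chr", 0, 4, "+", "AC-GT"),
                BlockRow("b", "b_chr", 0, 5, "+", "ACAGT")]
        short = AlignmentBlock(0, rows)
        cols = extract_variable_sites([short], ["a", "b"], min_block_length=1)
        assert cols.n_columns == 4  # gapped column dropped

    def test_site_count_equals_truth_changed_positions(self, small_pop):
        _, genomes, truth, _, blocks = small_pop
        cols = extract_variable_sites(blocks, sorted(g.strain_id for g in genomes))
        changed = {m.position for m in truth.mutation_sites}
        for t in truth.recomb_tracts:
            changed |= set(t.imported_positions)
        assert cols.var_cols.size == len(changed)
        assert set(cols.var_cols.tolist()) == changed


class TestMaxChi:
    def test_identical_pair_empty(self):
        seq = np.zeros(5000, dtype=np.uint8)
        rng = np.random.default_rng(0)
        other = mutated(seq, 0.02, rng)
        cols = extract_variable_sites(
            blocks_from_arrays({"a": seq, "b": seq, "c": other}), ["a", "b", "c"])
        assert maxchi_scan(cols, ("a", "b")) == []

    def test_mosaic_breakpoint_localized(self):
        # recipient = parent1 left half + parent2 right half, 2% divergences
        rng = np.random.default_rng(1)
        anc = rng.integers(0, 4, 60_000).astype(np.uint8)
        p1 = mutated(anc, 0.02, rng)
        p2 = mutated(anc, 0.02, rng)
        rec = np.concatenate([p1[:30_000], p2[30_000:]])
        cols = extract_variable_sites(
            blocks_from_arrays({"p1": p1, "p2": p2, "rec": rec}), ["p1", "p2", "rec"])
        cands = maxchi_scan(cols, ("rec", "p2"), seed=3)
        assert cands, "no candidate found at the mosaic junction"
        best = min(cands, key=lambda c: abs(c.breakpoint_col - 30_000))
        window_bp = 210 * 60_000 / cols.var_cols.size
        assert abs(best.breakpoint_col - 30_000) < window_bp

    def test_uniform_divergence_type_i(self):
        # plain diverged pairs: no candidate at p < 0.001 across seeds
        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(seed + 100)
            anc = rng.integers(0, 4, 40_000).astype(np.uint8)
            a = mutated(anc, 0.01, rng)
            b = mutated(anc, 0.01, rng)
            c = mutated(anc, 0.01, rng)
            cols = extract_variable_sites(
                blocks_from_arrays({"a": a, "b": b, "c": c}), ["a", "b", "c"])
            cands = maxchi_scan(cols, ("a", "b"), seed=seed)
            hits += any(x.p_value < 0.001 for x in cands)
        assert hits <= 1

    def test_window_must_be_even(self):
        seq = np.zeros(100, dtype=np.uint8)
        cols = extract_variable_sites(blocks_from_arrays({"a": seq, "b": seq}),
                                      ["a", "b"], min_block_length=1)
        with pytest.raises(ValueError, match="even"):
            from microdiv.recombination import _scan_peaks
            _scan_peaks(np.ones(500, dtype=np.float32), 211, 100,
                        np.random.default_rng(0))

    def test_fewer_sites_than_window_warns_empty(self):
        a = np.zeros(2000, dtype=np.uint8)
        b = a.copy()
        b[::100] = 1
        cols = extract_variable_sites(blocks_from_arrays({"a": a, "b": b}), ["a", "b"])
        with pytest.warns(UserWarning):
            assert maxchi_scan(cols, ("a", "b")) == []


class TestChimera:
    def test_two_identical_strains_empty(self):
        rng = np.random.default_rng(2)
        anc = rng.integers(0, 4, 20_000).astype(np.uint8)
        a = mutated(anc, 0.01, rng)
        cols = extract_variable_sites(
            blocks_from_arrays({"a": a, "b": a.copy(), "c": mutated(anc, 0.01, rng)}),
            ["a", "b", "c"])
        # a/b identical: no informative sites for the (a,b parents) orientation,
        # and the others hold no recombination signal
        cands = [c for c in chimera_scan(cols, ("a", "b", "c"), seed=1)
                 if c.p_value < 0.001]
        assert cands == []

    def test_external_import_recipient_inferred(self):
        rng = np.random.default_rng(3)
        anc = rng.integers(0, 4, 60_000).astype(np.uint8)
        a = mutated(anc, 0.01, rng)
        b = mutated(anc, 0.01, rng)
        c = mutated(anc, 0.01, rng)
        donor = mutated(a, 0.03, rng)       # donor related to A
        c[25_000:33_000] = donor[25_000:33_000]
        cols = extract_variable_sites(blocks_from_arrays({"a": a, "b": b, "c": c}),
                                      ["a", "b", "c"])
        cands = [x for x in chimera_scan(cols, ("a", "b", "c"), seed=2)
                 if x.p_value < 0.001]
        assert cands
        best = max(cands, key=lambda x: x.statistic)
        assert best.recipient == "c"
        assert best.col_interval[0] < 33_000 and 25_000 < best.col_interval[1]

    def test_distinct_strains_required(self, small_pop):
        _, genomes, _, _, blocks = small_pop
        cols = extract_variable_sites(blocks, sorted(g.strain_id for g in genomes))
        with pytest.raises(ValueError, match="distinct"):
            chimera_scan(cols, ("S01", "S01", "S02"))


class TestRdp:
    def test_homogeneous_triplet_empty(self):
        rng = np.random.default_rng(4)
        anc = rng.integers(0, 4, 30_000).astype(np.uint8)
        seqs = {n: mutated(anc, 0.005, rng) for n in "abc"}
        cols = extract_variable_sites(blocks_from_arrays(seqs), ["a", "b", "c"])
        assert [c for c in rdp_scan(cols, ("a", "b", "c")) if c.p_value < 0.001] == []

    def test_import_covered_by_merged_candidate(self):
        # 5 kb import at 2% divergence into a 0.2%-divergent background
        rng = np.random.default_rng(7)
        anc = rng.integers(0, 4, 60_000).astype(np.uint8)
        a = mutated(anc, 0.001, rng)
        b = mutated(anc, 0.001, rng)
        c = mutated(anc, 0.001, rng)
        donor = mutated(c, 0.02, rng)
        c[30_000:35_000] = donor[30_000:35_000]
        cols = extract_variable_sites(blocks_from_arrays({"a": a, "b": b, "c": c}),
                                      ["a", "b", "c"])
        sig = [x for x in rdp_scan(cols, ("a", "b", "c")) if x.p_value < 0.001]
        assert sig
        cov = max((min(x.col_interval[1], 35_000) - max(x.col_interval[0], 30_000))
                  / 5_000 for x in sig)
        assert cov >= 0.8

    def test_binomial_tail_matches_enumeration(self):
        # the exact tail used for window significance vs direct enumeration
        for n, x, p in [(10, 3, 0.2), (25, 20, 0.6), (30, 1, 0.05), (17, 17, 0.5)]:
            direct = sum(math.comb(n, k) * p ** k * (1 - p) ** (n - k)
                         for k in range(x, n + 1))
            assert binom.sf(x - 1, n, p) == pytest.approx(direct, abs=1e-12)

    def test_oversized_window_rejected(self):
        seq = np.zeros(50, dtype=np.uint8)
        cols = extract_variable_sites(blocks_from_arrays({"a": seq, "b": seq,
                                                          "c": seq}),
                                      ["a", "b", "c"], min_block_length=1)
        with pytest.raises(ValueError, match="window"):
            rdp_scan(cols, ("a", "b", "c"), window_nt=100)


class TestConsensus:
    def _mini_columns(self):
        rng = np.random.default_rng(5)
        anc = rng.integers(0, 4, 40_000).astype(np.uint8)
        seqs = {n: mutated(anc, 0.003, rng) for n in ("s1", "s2", "s3", "s4")}
        donor = mutated(seqs["s1"], 0.03, rng)
        seqs["s1"][15_000:21_000] = donor[15_000:21_000]
        return extract_variable_sites(blocks_from_arrays(seqs),
                                      ["s1", "s2", "s3", "s4"])

    def test_single_method_below_k_yields_nothing(self):
        cols = self._mini_columns()
        cands = [CandidateEvent("maxchi", "s1", ("s1", "s2"), (15_000, 21_000),
                                50.0, 1e-5)]
        assert ensemble_consensus(cols, cands, k=2) == []

    def test_three_methods_one_event(self):
        cols = self._mini_columns()
        cands = [CandidateEvent(m, "s1", ("s1", "s2"), iv, 50.0, 1e-5)
                 for m, iv in [("maxchi", (14_500, 20_500)),
                               ("chimera", (15_200, 21_300)),
                               ("rdp", (15_100, 20_900))]]
        events = ensemble_consensus(cols, cands, k=3)
        assert len(events) == 1
        (e,) = events
        assert e.supporting_methods == {"maxchi", "chimera", "rdp"}
        assert e.recipients == ("s1",)
        assert e.col_interval[0] < 21_000 and 15_000 < e.col_interval[1]
        assert e.breakpoints[0] <= e.breakpoints[1]
        assert e.inferred_donor == "external"

    def test_k_above_method_count_rejected(self):
        cols = self._mini_columns()
        with pytest.raises(ValueError):
            ensemble_consensus(cols, [], k=4)

    def test_detection_deterministic(self):
        p = SimParams(seed=31, core_length=60_000, theta_site=2e-3, rho_rel=0.3,
                      mean_tract=3_000, n_core_genes=30, n_accessory_families=10)
        genomes, _, _, blocks = simulate_population(p)
        strains = sorted(g.strain_id for g in genomes)
        cols = extract_variable_sites(blocks, strains)
        e1 = ensemble_consensus(cols, scan_all(cols, seed=9))
        e2 = ensemble_consensus(cols, scan_all(cols, seed=9))
        assert e1 == e2


class TestSummaries:
    def _event(self, strain, lo, hi):
        return RecombinationEvent((strain,), (lo, hi), (lo, hi), frozenset({"rdp"}),
                                  {}, (lo, hi), "external")

    def test_no_events_zero_fractions(self):
        s = summarize_events([], {"a": 1000})
        assert s["overall_recombined_fraction"] == 0.0
        assert s["per_strain"]["recombined_fraction"].tolist() == [0.0]

    def test_overlapping_union_arithmetic(self):
        evs = [self._event("a", 0, 100), self._event("a", 50, 150)]
        s = summarize_events(evs, {"a": 1000})
        assert s["per_strain"]["recombined_fraction"].iloc[0] == pytest.approx(0.15)
        assert s["size_histogram"]["total"] == 2

    def test_detected_fraction_bounded_by_truth_plus_fp(self, small_pop):
        _, genomes, truth, _, blocks = small_pop
        from microdiv._util import total_span
        strains = sorted(g.strain_id for g in genomes)
        cols = extract_variable_sites(blocks, strains)
        events = ensemble_consensus(cols, scan_all(cols, seed=13))
        summary = summarize_events(events, {s: cols.n_columns for s in strains})
        truth_frac = total_span((t.start, t.end) for t in truth.recomb_tracts) \
            / cols.n_columns
        assert summary["overall_recombined_fraction"] <= truth_frac + 0.05
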