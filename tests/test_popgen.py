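"""Clonal frames, masked genealogy, rate estimation and dN/dS.

The dN/dS oracle below enumerates mutational pathways directly from the
genetic code and is written against the stated counting conventions, not
against the implementation: per-position synonymous fractions exclude
changes to stop codons, multi-hit codons average over all orderings of the
differing positions that avoid stop codons, and Jukes-Cantor corrects the
proportions.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from microdiv._util import encode
from microdiv.popgen import (assign_clonal_frames, build_clonal_tree,
                             core_gene_sequences, estimate_rates, pairwise_dnds)
from microdiv.recombination import RecombinationEvent, extract_variable_sites
from microdiv.simulate import SimParams, simulate_population

GENETIC_CODE = {}
for b1 in "TCAG":
    for b2 in "TCAG":
        for b3 in "TCAG":
            GENETIC_CODE[b1 + b2 + b3] = None
_BASES = "TCAG"
_AAS = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for i, codon in enumerate(GENETIC_CODE):
    GENETIC_CODE[codon] = _AAS[i]
STOPS = {c for c, a in GENETIC_CODE.items() if a == "*"}


def oracle_codon_sites(codon):
    syn = 0.0
    for pos in range(3):
        s = n = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOPS:
                continue
            if GENETIC_CODE[alt] == GENETIC_CODE[codon]:
                s += 1
            else:
                n += 1
        if s + n:
            syn += s / (s + n)
    return syn, 3.0 - syn


def oracle_codon_diffs(c1, c2):
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    all_paths, ok_paths = [], []
    for order in itertools.permutations(pos):
        cur, steps, blocked = c1, [], False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in STOPS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        all_paths.append(steps)
        if not blocked:
            ok_paths.append(steps)
    paths = ok_paths or all_paths
    sd = nd = 0.0
    for steps in paths:
        for a, b in steps:
            if GENETIC_CODE[a] == GENETIC_CODE[b]:
                sd += 1
            else:
                nd += 1
    return sd / len(paths), nd / len(paths)


def oracle_dnds(a, b):
    S = N = Sd = Nd = 0.0
    for i in range(len(a) // 3):
        ca, cb = a[3 * i:3 * i + 3], b[3 * i:3 * i + 3]
        s1, n1 = oracle_codon_sites(ca)
        s2, n2 = oracle_codon_sites(cb)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        s, n = oracle_codon_diffs(ca, cb)
        Sd += s
        Nd += n
    pS, pN = Sd / S, Nd / N
    jc = lambda p: -0.75 * math.log1p(-4 * p / 3)
    return dict(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
                dS=jc(pS) if pS < 0.75 else float("nan"),
                dN=jc(pN) if pN < 0.75 else float("nan"))


def random_cds(rng, n_codons):
    codons = [c for c in GENETIC_CODE if c not in STOPS]
    return "".join(rng.choice(codons) for _ in range(n_codons))


def diverge_cds(cds, rate, rng):
    out = list(cds)
    n_cod = len(cds) // 3
    for i in range(n_cod):
        for j in range(3):
            if rng.random() < rate:
                pos = 3 * i + j
                alt = rng.choice([b for b in "ACGT" if b != out[pos]])
                trial = out.copy()
                trial[pos] = alt
                if "".join(trial[3 * i:3 * i + 3]) not in STOPS:
                    out = trial
    return "".join(out)


class TestDnDs:
    def test_identical_flagged_ds_zero(self):
        r = pairwise_dnds("ATGGCT", "ATGGCT")
        assert not r.defined and r.flag == "dS_zero"
        assert r.Nd == r.Sd == 0

    def test_single_synonymous_change(self):
        base = random_cds(np.random.default_rng(1), 99) + "TTT"
        other = base[:-3] + "TTC"  # Phe -> Phe, third position
        r = pairwise_dnds(base, other)
        assert r.Sd == pytest.approx(1.0) and r.Nd == pytest.approx(0.0)
        assert r.ratio == pytest.approx(0.0)
        assert r.N_sites + r.S_sites == pytest.approx(len(base))

    def test_matches_enumeration_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a = random_cds(rng, 300)
            b = diverge_cds(a, 0.05, rng)
            r = pairwise_dnds(a, b)
            o = oracle_dnds(a, b)
            for got, exp in [(r.S_sites, o["S"]), (r.N_sites, o["N"]),
                             (r.Sd, o["Sd"]), (r.Nd, o["Nd"]),
                             (r.dS, o["dS"]), (r.dN, o["dN"])]:
                assert got == pytest.approx(exp, abs=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        a = random_cds(rng, 150)
        b = diverge_cds(a, 0.08, rng)
        r1, r2 = pairwise_dnds(a, b), pairwise_dnds(b, a)
        assert r1.Sd == pytest.approx(r2.Sd) and r1.Nd == pytest.approx(r2.Nd)
        assert r1.ratio == pytest.approx(r2.ratio, nan_ok=True)

    def test_gapped_codons_dropped(self):
        r = pairwise_dnds("ATG---AAA", "ATGGGGAAA")
        assert r.N_sites + r.S_sites == pytest.approx(6.0)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            pairwise_dnds("ATGTAAAAA", "ATGTAAAAA")

    def test_length_validation(self):
        with pytest.raises(ValueError):
            pairwise_dnds("ATGA", "ATGA")
        with pytest.raises(ValueError):
            pairwise_dnds("ATG", "ATGATG")

    def test_core_gene_dnds_low_under_neutral_counting(self, small_pop):
        _, genomes, _, matrix, _ = small_pop
        seqs = core_gene_sequences(genomes, matrix)
        ratios = []
        for fam, per_strain in list(seqs.items())[:20]:
            vals = list(per_strain.values())
            try:
                r = pairwise_dnds(vals[0], vals[-1])
            except ValueError:
                continue
            if r.defined:
                ratios.append(r.ratio)
        # neutral simulation: no systematic excess of nonsynonymous change
        assert all(np.isfinite(v) for v in ratios)


class TestClonalFrames:
    def test_uniform_matrix_single_frame(self):
        ids = ["a", "b", "c"]
        ani = pd.DataFrame(100.0, index=ids, columns=ids)
        cfa = assign_clonal_frames(ani, threshold=99.5)
        assert cfa.n_frames == 1

    def test_block_diagonal_recovered(self):
        ids = ["a", "b", "c", "d"]
        ani = pd.DataFrame(98.2, index=ids, columns=ids)
        for x, y in [("a", "b"), ("c", "d")]:
            ani.loc[x, y] = ani.loc[y, x] = 99.9
        np.fill_diagonal(ani.values, 100.0)
        cfa = assign_clonal_frames(ani, threshold=99.5)
        g = cfa.groups()
        assert sorted(map(tuple, g.values())) == [("a", "b"), ("c", "d")]

    def test_simulated_frames_recovered(self, clonal_pop):
        _, genomes, truth, _, blocks = clonal_pop
        strains = sorted(g.strain_id for g in genomes)
        core = {s: np.concatenate([encode(b.row(s).seq) for b in blocks])
                for s in strains}
        L = len(next(iter(core.values())))
        ani = pd.DataFrame(100.0, index=strains, columns=strains)
        for i, a in enumerate(strains):
            for b in strains[i + 1:]:
                ident = 100.0 * (1 - (core[a] != core[b]).mean())
                ani.loc[a, b] = ani.loc[b, a] = ident
        within = [ani.loc[a, b] for a in strains for b in strains if a < b
                  and truth.cf_assignment[a] == truth.cf_assignment[b]]
        between = [ani.loc[a, b] for a in strains for b in strains if a < b
                   and truth.cf_assignment[a] != truth.cf_assignment[b]]
        thr = (min(within) + max(between)) / 2
        cfa = assign_clonal_frames(ani, threshold=thr)
        want = {}
        for s, cf in truth.cf_assignment.items():
            want.setdefault(cf, []).append(s)
        assert sorted(sorted(v) for v in cfa.groups().values()) == \
               sorted(sorted(v) for v in want.values())

    def test_missing_pairs_rejected(self):
        ani = pd.DataFrame([[100.0, np.nan], [np.nan, 100.0]],
                           index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            assign_clonal_frames(ani)


def truth_events(truth):
    return [RecombinationEvent(
        recipients=tuple(sorted(t.recipients)), interval=(t.start, t.end),
        col_interval=(t.start, t.end), supporting_methods=frozenset({"truth"}),
        min_p={}, breakpoints=(t.start, t.end), inferred_donor="external",
        imported_substitution_count=t.imported_substitutions)
        for t in truth.recomb_tracts]


class TestClonalTree:
    def test_clonal_simulation_topology_recovered(self, clonal_pop):
        _, genomes, truth, _, blocks = clonal_pop
        strains = sorted(g.strain_id for g in genomes)
        cols = extract_variable_sites(blocks, strains)
        tree = build_clonal_tree(cols, [])
        rf = truth.tree().compare_rfd(tree)
        assert rf == 0.0

    def test_masking_never_hurts_topology(self):
        for seed in (41, 42, 43):
            p = SimParams(seed=seed, core_length=80_000, theta_site=2e-3,
                          rho_rel=0.4, mean_tract=4_000, donor_divergence=0.05,
                          n_core_genes=40, n_accessory_families=10)
            genomes, truth, _, blocks = simulate_population(p)
            strains = sorted(g.strain_id for g in genomes)
            cols = extract_variable_sites(blocks, strains)
            masked = build_clonal_tree(cols, truth_events(truth), mask_pad=0)
            unmasked = build_clonal_tree(cols, [])
            rf_masked = truth.tree().compare_rfd(masked)
            rf_unmasked = truth.tree().compare_rfd(unmasked)
            assert rf_masked <= rf_unmasked

    def test_identical_strains_zero_length_cherry(self):
        p = SimParams(seed=50, n_strains=4, n_clonal_frames=2, theta_site=1e-3,
                      rho_rel=0.0, core_length=40_000, n_core_genes=20,
                      n_accessory_families=0)
        genomes, truth, _, blocks = simulate_population(p)
        strains = sorted(g.strain_id for g in genomes)
        cols = extract_variable_sites(blocks, strains)
        # duplicate one strain by copying its row
        from microdiv.io import AlignmentBlock, BlockRow
        rows = []
        for b in blocks:
            rr = list(b.rows)
            src = b.row(strains[0])
            rr.append(BlockRow("DUP", "DUP_chr", src.start, src.end, "+", src.seq))
            rows.append(AlignmentBlock(b.block_id, rr))
        cols2 = extract_variable_sites(rows, strains + ["DUP"])
        tree = build_clonal_tree(cols2, [])
        d = tree.tip_tip_distances()[strains[0], "DUP"]
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_overmasking_rejected(self, small_pop):
        _, genomes, _, _, blocks = small_pop
        strains = sorted(g.strain_id for g in genomes)
        cols = extract_variable_sites(blocks, strains)
        huge = [RecombinationEvent(tuple(strains), (0, cols.n_columns),
                                   (0, cols.n_columns), frozenset({"truth"}), {},
                                   (0, cols.n_columns), "external", 0)]
        with pytest.raises(ValueError, match="mask"):
            build_clonal_tree(cols, huge)


class TestRateEstimation:
    def test_no_events_zero_ratios(self, clonal_pop):
        _, genomes, truth, _, blocks = clonal_pop
        strains = sorted(g.strain_id for g in genomes)
        cols = extract_variable_sites(blocks, strains)
        est = estimate_rates(cols, [], truth.tree())
        assert est.r_over_m == 0.0 and est.rho_over_theta == 0.0
        assert est.n_clonal_mutations == len(truth.mutation_sites)

    def test_truth_bypass_is_exact(self, small_pop):
        _, genomes, truth, _, blocks = small_pop
        strains = sorted(g.strain_id for g in genomes)
        cols = extract_variable_sites(blocks, strains)
        est = estimate_rates(cols, truth_events(truth), truth.tree(), mask_pad=0)
        assert est.n_clonal_mutations == len(truth.mutation_sites)
        assert est.n_events == len(truth.recomb_tracts)
        assert est.r_over_m == pytest.approx(truth.realized_r_over_m)
        assert est.rho_over_theta == pytest.approx(truth.realized_rho_over_theta)

    def test_zero_mutations_flagged(self):
        p = SimParams(seed=60, theta_site=0.0, rho_rel=0.0, core_length=30_000,
                      n_core_genes=20, n_accessory_families=4)
        genomes, truth, _, blocks = simulate_population(p)
        strains = sorted(g.strain_id for g in genomes)
        cols = extract_variable_sites(blocks, strains)
        est = estimate_rates(cols, [], truth.tree())
        assert not est.defined
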