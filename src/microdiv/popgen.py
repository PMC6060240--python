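"""Clonal-frame clustering, clonal genealogy, r/m and rho/theta, dN/dS.

The recombination-aware genealogy follows the masking recipe: every
detected (or true) import is masked for its recipient lineage, pairwise
Jukes-Cantor distances are computed on the co-unmasked columns, and the
tree is neighbor-joined and midpoint-rooted. The impact ratios are then
direct counts on that tree:

* ``n_clonal_mutations`` — substitutions implied by the masked alignment
  under Fitch parsimony,
* ``n_imported_subs`` — substitutions carried by imports (taken from the
  event table when it provides exact counts, otherwise counted as
  recipient-vs-sibling differences inside each event),
* ``r/m = n_imported_subs / n_clonal_mutations`` and
  ``rho/theta = n_events / n_clonal_mutations``.

Masks are padded (``mask_pad``) so breakpoint uncertainty of the detector
does not leak imported substitutions into the mutation count; with exact
event intervals (e.g. simulator truth) a pad of 0 reproduces the realized
ratios exactly.

dN/dS is the Nei-Gojobori counting method with Jukes-Cantor correction, a
stand-in for likelihood codon models that preserves the comparative use of
the ratio (<1 purifying, >1 diversifying).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._util import merge_intervals, total_span
from .recombination import AlignedColumnSet, RecombinationEvent

STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODON_AA: dict[str, str] = {}


def _aa(codon: str) -> str:
    if not _CODON_AA:
        from Bio.Data.CodonTable import standard_dna_table
        _CODON_AA.update(standard_dna_table.forward_table)
        for c in standard_dna_table.stop_codons:
            _CODON_AA[c] = "*"
    return _CODON_AA[codon]


# ---------------------------------------------------------------------------
# clonal frames
# ---------------------------------------------------------------------------

@dataclass
class ClonalFrameAssignment:
    assignment: dict[str, str]      # strain -> CF label
    threshold: float                # ANIb linkage threshold used
    n_frames: int

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, cf in self.assignment.items():
            out.setdefault(cf, []).append(s)
        return {cf: sorted(m) for cf, m in out.items()}


def assign_clonal_frames(ani, threshold: float = 99.5) -> ClonalFrameAssignment:
    """Single-linkage clusters of strains at ANIb >= threshold.

    ``ani`` is a complete symmetric DataFrame of pairwise ANIb values
    (percent). Clusters are labelled CF1.. in order of their most similar
    internal pair, ties broken by strain name; deterministic."""
    import pandas as pd

    if not isinstance(ani, pd.DataFrame):
        raise TypeError("ani must be a strains x strains DataFrame")
    strains = list(ani.index)
    if list(ani.columns) != strains:
        raise ValueError("ANI matrix rows and columns disagree")
    vals = ani.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("ANI matrix has missing pairs")
    dist = 100.0 - vals
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, dist.T)  # enforce symmetry for squareform
    if len(strains) == 1:
        labels = np.array([1])
    else:
        z = linkage(squareform(dist, checks=False), method="single")
        labels = fcluster(z, t=100.0 - threshold, criterion="distance")
    # stable CF numbering: order clusters by their first strain name
    order: dict[int, int] = {}
    for s, lab in sorted(zip(strains, labels)):
        if lab not in order:
            order[lab] = len(order) + 1
    assignment = {s: f"CF{order[lab]}" for s, lab in zip(strains, labels)}
    return ClonalFrameAssignment(assignment, threshold, len(order))


# ---------------------------------------------------------------------------
# masking and distances
# ---------------------------------------------------------------------------

def _padded_intervals(events: list[RecombinationEvent], strain: str,
                      pad: int, n_cols: int) -> list[tuple[int, int]]:
    ivals = [(max(e.col_interval[0] - pad, 0), min(e.col_interval[1] + pad, n_cols))
             for e in events if strain in e.recipients]
    return merge_intervals(ivals)


def _mask_sites(columns: AlignedColumnSet, events, pad: int):
    """Per-strain interval masks plus a boolean mask over the variable sites."""
    n = len(columns.strains)
    ivals = {s: _padded_intervals(events, s, pad, columns.n_columns)
             for s in columns.strains}
    site_mask = np.zeros((n, columns.var_cols.size), dtype=bool)
    for i, s in enumerate(columns.strains):
        for lo, hi in ivals[s]:
            a, b = np.searchsorted(columns.var_cols, (lo, hi))
            site_mask[i, a:b] = True
    return ivals, site_mask


def _jc(p: float) -> float:
    if p >= 0.75:
        return float("inf")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def build_clonal_tree(columns: AlignedColumnSet, events: list[RecombinationEvent],
                      mask_pad: int = 1000):
    """Recombination-masked neighbor-joining genealogy, midpoint-rooted.

    Event intervals (padded by ``mask_pad`` columns) are masked per
    recipient; pairwise Jukes-Cantor distances use only co-unmasked
    columns. Raises when masking removes more than 90% of the columns."""
    from skbio import DistanceMatrix, TreeNode
    from skbio.tree import nj

    strains = columns.strains
    ivals, site_mask = _mask_sites(columns, events, mask_pad)
    masked_frac = np.mean([total_span(ivals[s]) / columns.n_columns for s in strains])
    if masked_frac > 0.9:
        raise ValueError(
            f"masking removes {100 * masked_frac:.0f}% of alignment columns; "
            "review detector settings before estimating a genealogy")
    n = len(strains)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = merge_intervals(ivals[strains[i]] + ivals[strains[j]])
            denom = columns.n_columns - sum(e - s for s, e in both)
            ok = ~site_mask[i] & ~site_mask[j]
            diffs = int(((columns.var_chars[i] != columns.var_chars[j]) & ok).sum())
            p = diffs / denom if denom > 0 else 0.75
            d = _jc(min(p, 0.7499))
            dist[i, j] = dist[j, i] = d
    if n == 2:
        tree = TreeNode.read([f"({strains[0]}:{dist[0, 1] / 2},{strains[1]}:{dist[0, 1] / 2});"])
        return tree
    tree = nj(DistanceMatrix(dist, ids=strains))
    try:
        tree = tree.root_at_midpoint()
    except Exception:  # zero-length star trees cannot be midpoint-rooted
        pass
    return tree


# ---------------------------------------------------------------------------
# rate estimation
# ---------------------------------------------------------------------------

@dataclass
class PopGenEstimates:
    r_over_m: float
    rho_over_theta: float
    n_events: int
    n_imported_subs: int
    n_clonal_mutations: int
    defined: bool = True


def _fitch_changes(columns: AlignedColumnSet, tree, site_mask: np.ndarray) -> int:
    """Total parsimony substitutions over the variable sites, vectorized.

    Masked tips contribute a wildcard state; columns reduced to one visible
    state count zero changes."""
    idx = {s: i for i, s in enumerate(columns.strains)}
    n_var = columns.var_cols.size
    changes = np.zeros(n_var, dtype=np.int64)
    states: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            i = idx[node.name]
            st = (1 << columns.var_chars[i].astype(np.int64)).astype(np.int8)
            st = np.where(site_mask[i], np.int8(15), st)
            states[id(node)] = st
        else:
            st = None
            for child in node.children:
                cst = states.pop(id(child))
                if st is None:
                    st = cst
                else:
                    inter = st & cst
                    empty = inter == 0
                    changes += empty
                    st = np.where(empty, st | cst, inter)
            states[id(node)] = st
    return int(changes.sum())


def _nearest_sibling(tree, recipient: str) -> dict[str, float]:
    dm = tree.tip_tip_distances()
    row = {t: dm[recipient, t] for t in dm.ids if t != recipient}
    return dict(sorted(row.items(), key=lambda kv: (kv[1], kv[0])))


def estimate_rates(columns: AlignedColumnSet, events: list[RecombinationEvent],
                   tree=None, mask_pad: int = 1000) -> PopGenEstimates:
    """Direct-count r/m and rho/theta from events and the masked alignment.

    ``n_imported_subs`` uses each event's exact count when present (truth
    tables) and otherwise counts sites inside the event where the recipient
    differs from its closest tree sibling. Events without exact counts are
    deduplicated into regions (intervals overlapping by at least half of
    the shorter) before counting ``n_events``, since the per-recipient event
    table reports one row per recipient for a shared import. Zero observed
    mutations flags the ratios undefined."""
    if tree is None:
        tree = build_clonal_tree(columns, events, mask_pad=mask_pad)
    _, site_mask = _mask_sites(columns, events, mask_pad)
    n_mut = _fitch_changes(columns, tree, site_mask)

    n_imported = 0
    exact = all(e.imported_substitution_count is not None for e in events) and bool(events)
    sib_cache: dict[str, dict[str, float]] = {}
    for e in events:
        if e.imported_substitution_count is not None:
            n_imported += int(e.imported_substitution_count)
            continue
        recip = e.recipient
        if recip not in sib_cache:
            sib_cache[recip] = _nearest_sibling(tree, recip)
        a, b = np.searchsorted(columns.var_cols, e.col_interval)
        ri = columns.index(recip)
        count = 0
        for sib in sib_cache[recip]:
            si = columns.index(sib)
            ok = ~site_mask[si, a:b]
            if ok.any() or b == a:
                count = int((columns.var_chars[ri, a:b][ok]
                             != columns.var_chars[si, a:b][ok]).sum())
                break
        n_imported += count

    n_events = len(events) if exact else _count_regions(events)
    if n_mut == 0:
        nan = float("nan")
        return PopGenEstimates(nan if n_imported else 0.0, nan if n_events else 0.0,
                               n_events, n_imported, 0, defined=False)
    return PopGenEstimates(n_imported / n_mut, n_events / n_mut,
                           n_events, n_imported, n_mut)


def _count_regions(events: list[RecombinationEvent]) -> int:
    """Events from different recipients merged when their column intervals
    overlap by at least half of the shorter interval."""
    ivals = sorted(e.col_interval for e in events)
    regions: list[tuple[int, int]] = []
    for lo, hi in ivals:
        if regions:
            plo, phi = regions[-1]
            ov = min(phi, hi) - max(plo, lo)
            if ov >= 0.5 * min(hi - lo, phi - plo):
                regions[-1] = (plo, max(phi, hi))
                continue
        regions.append((lo, hi))
    return len(regions)


# ---------------------------------------------------------------------------
# dN/dS (Nei-Gojobori with Jukes-Cantor correction)
# ---------------------------------------------------------------------------

@dataclass
class DnDsResult:
    pair: tuple[str, str]
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float
    dS: float
    ratio: float
    defined: bool
    flag: str = ""


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Changes to stop codons are excluded from the possible changes at a
    position; each position still contributes one site, so S+N = 3."""
    s = 0.0
    aa0 = _aa(codon)
    for pos in range(3):
        syn = non = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            if _aa(alt) == aa0:
                syn += 1
            else:
                non += 1
        tot = syn + non
        s += syn / tot if tot else 0.0
    return s, 3.0 - s


def _codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, averaged over the minimal
    mutational pathways between two codons; pathways passing through a stop
    codon are excluded (all-blocked pairs fall back to every pathway)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    valid = [steps for blocked, steps in paths if not blocked]
    if not valid:
        valid = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in valid:
        for a, b in steps:
            if _aa(a) == _aa(b):
                sd += 1
            else:
                nd += 1
    k = len(valid)
    return sd / k, nd / k


def pairwise_dnds(cds_a: str, cds_b: str, pair: tuple[str, str] = ("a", "b")) -> DnDsResult:
    """Nei-Gojobori pairwise dN/dS of two aligned coding sequences.

    Sequences must be equal-length multiples of 3; codon pairs containing a
    gap are dropped; internal stop codons raise. Proportions are
    Jukes-Cantor corrected; saturation (p >= 0.75) or dS = 0 flag the
    result undefined rather than returning a number."""
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("length not a multiple of 3")
    codons = []
    n_codons = len(a) // 3
    for i in range(n_codons):
        ca, cb = a[3 * i:3 * i + 3], b[3 * i:3 * i + 3]
        if "-" in ca or "-" in cb:
            continue
        internal = i < n_codons - 1
        if (ca in STOP_CODONS or cb in STOP_CODONS) and internal:
            raise ValueError(f"internal stop codon at codon {i}")
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue  # trailing stop codons are not scored
        codons.append((ca, cb))
    if not codons:
        raise ValueError("no comparable codons")
    S = N = Sd = Nd = 0.0
    for ca, cb in codons:
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        s, n = _codon_diffs(ca, cb)
        Sd += s
        Nd += n
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    flag = ""
    if pS >= 0.75 or pN >= 0.75:
        flag = "saturated"
        dN = dS = ratio = float("nan")
    else:
        dS, dN = _jc(pS), _jc(pN)
        if dS == 0.0:
            flag = "dS_zero"
            ratio = float("nan")
        else:
            ratio = dN / dS
    return DnDsResult(pair, N, S, Nd, Sd, pN, pS,
                      dN if not flag == "saturated" else float("nan"),
                      dS if not flag == "saturated" else float("nan"),
                      ratio, defined=(flag == ""), flag=flag)


def core_gene_sequences(genomes, matrix) -> dict[str, dict[str, str]]:
    """Per-strain sequences of every core family, ready for dN/dS.

    Uses each strain's own gene coordinates; with a gap-free core the
    sequences of one family are mutually aligned. Minus-strand genes are
    reverse-complemented to coding orientation."""
    from ._util import revcomp
    from .pangenome import partition_pangenome

    core, _ = partition_pangenome(matrix)
    by_strain = {g.strain_id: g for g in genomes}
    gene_of = {(s, gid): None for fam in core for s, gid in matrix.gene_members[fam]}
    for g in genomes:
        for gm in g.genes:
            if (g.strain_id, gm.gene_id) in gene_of:
                gene_of[(g.strain_id, gm.gene_id)] = gm
    out: dict[str, dict[str, str]] = {}
    for fam in sorted(core):
        seqs = {}
        for s, gid in matrix.gene_members[fam]:
            gm = gene_of[(s, gid)]
            seq = by_strain[s].sequence(gm.replicon_id)[gm.start:gm.end]
            seqs[s] = revcomp(seq) if gm.strand == "-" else seq
        out[fam] = seqs
    return out
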