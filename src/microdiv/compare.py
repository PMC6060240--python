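"""Pairwise genome identity: fragment matching, ANIb post-processing, TETRA.

ANIb here follows the fragment-table recipe: pairwise local matches (from the
built-in anchored matcher or a parsed MUMmer ``show-coords`` table) are
post-processed — matches contained in a larger match are dropped, matches
overlapping by more than 10% of the shorter match's length are joined — and
the identity is the length-weighted mean over the kept fragments.

TETRA is the correlation of strand-symmetrized tetranucleotide z-score
profiles, with expected counts from the maximal-order Markov model
``E[n(abcd)] = n(abc) * n(bcd) / n(bc)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._util import encode, revcomp
from .io import GenomeRecord


@dataclass(frozen=True)
class FragmentMatch:
    """One aligned pairwise match; intervals 0-based half-open, ref-forward."""

    ref_id: str
    qry_id: str
    ref_interval: tuple[int, int]
    qry_interval: tuple[int, int]
    orientation: str
    identity: float

    def __post_init__(self):
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0,100]")
        if self.ref_interval[1] <= self.ref_interval[0]:
            raise ValueError(f"empty reference interval {self.ref_interval}")

    @property
    def length(self) -> int:
        """Reference span of the match."""
        return self.ref_interval[1] - self.ref_interval[0]


@dataclass(frozen=True)
class AniResult:
    pair: tuple[str, str]
    anib: float
    aligned_fraction: float
    n_fragments_kept: int
    defined: bool = True


@dataclass(frozen=True)
class TetraProfile:
    strain_id: str
    z: np.ndarray  # 256 z-scores, strand-symmetrized


# ---------------------------------------------------------------------------
# fragment matching (built-in Nucmer stand-in)
# ---------------------------------------------------------------------------

def match_fragments(ref, qry, min_anchor: int = 15, max_gap: int = 1000,
                    min_length: int = 100, min_identity: float = 70.0,
                    xdrop: int = 30) -> list[FragmentMatch]:
    """Exact-k-mer-anchored, ungap-extended local matches between two genomes.

    Accepts :class:`GenomeRecord` (chromosome only) or raw strings. Anchors on
    shared ``min_anchor``-mers, chains anchors on the same diagonal within
    ``max_gap`` bp, extends both ends ungapped under an X-drop rule, and
    recomputes each fragment's identity by direct substring comparison.
    Deterministic; empty sequences yield an empty list.
    """
    if min_anchor < 11:
        raise ValueError("min_anchor must be >= 11")
    ref_id, rseq = _seq_of(ref)
    qry_id, qseq = _seq_of(qry)
    if not rseq or not qseq:
        return []
    k = min_anchor
    index: dict[str, list[int]] = {}
    for i in range(len(rseq) - k + 1):
        kmer = rseq[i:i + k]
        if "N" in kmer:
            continue
        hits = index.setdefault(kmer, [])
        if len(hits) < 8:  # cap repeats
            hits.append(i)

    out: list[FragmentMatch] = []
    for orientation in "+-":
        q = qseq if orientation == "+" else revcomp(qseq)
        diags: dict[int, list[int]] = {}
        for j in range(len(q) - k + 1):
            for i in index.get(q[j:j + k], ()):
                diags.setdefault(j - i, []).append(i)
        for diag, rposs in diags.items():
            rposs = sorted(set(rposs))
            run_start = prev = rposs[0]
            runs = []
            for i in rposs[1:]:
                if i - prev > max_gap:
                    runs.append((run_start, prev + k))
                    run_start = i
                prev = i
            runs.append((run_start, prev + k))
            for rs, re_ in runs:
                frag = _extend(rseq, q, rs, re_, diag, xdrop)
                if frag is None:
                    continue
                rs, re_ = frag
                qs, qe = rs + diag, re_ + diag
                n = re_ - rs
                if n < min_length:
                    continue
                ident = 100.0 * sum(a == b for a, b in zip(rseq[rs:re_], q[qs:qe])) / n
                if ident < min_identity:
                    continue
                if orientation == "-":
                    qs, qe = len(q) - qe, len(q) - qs
                out.append(FragmentMatch(ref_id, qry_id, (rs, re_), (qs, qe),
                                         orientation, round(ident, 4)))
    # deduplicate fragments discovered from several anchors
    out = sorted(set(out), key=lambda f: (f.ref_interval, f.qry_interval, f.orientation))
    return out


def _seq_of(g) -> tuple[str, str]:
    if isinstance(g, GenomeRecord):
        return g.strain_id, g.chromosome
    return "seq", str(g)


def _extend(rseq: str, q: str, rs: int, re_: int, diag: int, xdrop: int):
    """Ungapped X-drop extension of [rs,re_) along the given diagonal."""
    # left
    score = best = 0
    best_i = rs
    i = rs - 1
    while i >= 0 and i + diag >= 0 and best - score <= xdrop:
        score += 1 if rseq[i] == q[i + diag] else -3
        if score > best:
            best, best_i = score, i
        i -= 1
    rs = best_i
    # right
    score = best = 0
    best_j = re_
    j = re_
    while j < len(rseq) and j + diag < len(q) and best - score <= xdrop:
        score += 1 if rseq[j] == q[j + diag] else -3
        if score > best:
            best, best_j = score, j + 1
        j += 1
    re_ = best_j
    if re_ <= rs:
        return None
    return rs, re_


# ---------------------------------------------------------------------------
# ANIb post-processing
# ---------------------------------------------------------------------------

def merge_and_filter_fragments(frags: list[FragmentMatch],
                               overlap_basis: str = "shorter") -> list[FragmentMatch]:
    """Post-process a fragment table the way the ANIb recipe prescribes.

    Fragments contained within a larger fragment (on the reference) are
    filtered out; fragments overlapping by more than 10% of their length are
    joined. ``overlap_basis`` selects which length the 10% refers to:
    ``shorter`` (default), ``longer``, or ``either`` (each fragment's own
    length — join if the overlap exceeds 10% of either). Joined fragments
    take the interval union and a length-weighted identity computed over
    disjoint reference coverage (the overlap is counted once, with the longer
    fragment's identity). Idempotent.
    """
    if not frags:
        return []
    pairs = {(f.ref_id, f.qry_id) for f in frags}
    if len(pairs) > 1:
        raise ValueError(f"fragments from mixed genome pairs: {sorted(pairs)}")
    if overlap_basis not in ("shorter", "longer", "either"):
        raise ValueError(f"unknown overlap_basis {overlap_basis!r}")

    kept = list(frags)
    while True:
        kept = _drop_contained(kept)
        joined = _join_pass(kept, overlap_basis)
        if joined == kept:
            return sorted(joined, key=lambda f: f.ref_interval)
        kept = joined


def _drop_contained(frags: list[FragmentMatch]) -> list[FragmentMatch]:
    # longest first; identity breaks ties so duplicates collapse deterministically
    frags = sorted(frags, key=lambda f: (-f.length, -f.identity, f.ref_interval))
    kept: list[FragmentMatch] = []
    for f in frags:
        s, e = f.ref_interval
        if any(g.ref_interval[0] <= s and e <= g.ref_interval[1] for g in kept):
            continue
        kept.append(f)
    return sorted(kept, key=lambda f: f.ref_interval)


def _join_threshold(a: FragmentMatch, b: FragmentMatch, basis: str) -> float:
    if basis == "shorter":
        return 0.10 * min(a.length, b.length)
    if basis == "longer":
        return 0.10 * max(a.length, b.length)
    return 0.10 * min(a.length, b.length)  # "either": exceeds 10% of either


def _join_pass(frags: list[FragmentMatch], basis: str) -> list[FragmentMatch]:
    frags = sorted(frags, key=lambda f: f.ref_interval)
    out: list[FragmentMatch] = []
    cur = frags[0]
    for nxt in frags[1:]:
        if nxt.ref_interval[1] <= cur.ref_interval[1]:
            continue  # swallowed by an earlier join; containment rule drops it
        ov = cur.ref_interval[1] - nxt.ref_interval[0]
        if ov > _join_threshold(cur, nxt, basis):
            cur = _join(cur, nxt, ov)
        else:
            out.append(cur)
            cur = nxt
    out.append(cur)
    return out


def _join(a: FragmentMatch, b: FragmentMatch, ov: int) -> FragmentMatch:
    """Join two reference-overlapping fragments; overlap weighted once."""
    ov = max(ov, 0)
    long_f = a if a.length >= b.length else b
    pieces = [
        (a.length - ov, a.identity),           # a-exclusive
        (ov, long_f.identity),                 # shared, counted once
        (max(b.ref_interval[1] - a.ref_interval[1], 0), b.identity),  # b-exclusive
    ]
    w = sum(p for p, _ in pieces)
    ident = sum(p * i for p, i in pieces) / w if w else long_f.identity
    return replace(
        long_f,
        ref_interval=(a.ref_interval[0], max(a.ref_interval[1], b.ref_interval[1])),
        qry_interval=(min(a.qry_interval[0], b.qry_interval[0]),
                      max(a.qry_interval[1], b.qry_interval[1])),
        identity=ident,
    )


def compute_anib(frags_kept: list[FragmentMatch], ref_length: int | None = None) -> AniResult:
    """Length-weighted mean identity over post-processed fragments."""
    if not frags_kept:
        return AniResult(("", ""), float("nan"), 0.0, 0, defined=False)
    pair = (frags_kept[0].ref_id, frags_kept[0].qry_id)
    w = sum(f.length for f in frags_kept)
    anib = sum(f.identity * f.length for f in frags_kept) / w
    if ref_length:
        from ._util import total_span
        frac = total_span(f.ref_interval for f in frags_kept) / ref_length
    else:
        frac = float("nan")
    return AniResult(pair, anib, frac, len(frags_kept))


def ani_pair(ref: GenomeRecord, qry: GenomeRecord, **match_kw) -> AniResult:
    frags = match_fragments(ref, qry, **match_kw)
    kept = merge_and_filter_fragments(frags) if frags else []
    res = compute_anib(kept, ref_length=len(ref.chromosome))
    return replace(res, pair=(ref.strain_id, qry.strain_id))


def ani_matrix(genomes: list[GenomeRecord], **match_kw):
    """All-vs-all ANIb. Returns (symmetric-mean DataFrame, per-direction dict).

    The symmetric mean of the two directed values is the headline number;
    both directions are kept in the returned dict.
    """
    import pandas as pd

    ids = [g.strain_id for g in genomes]
    directed: dict[tuple[str, str], AniResult] = {}
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for i, a in enumerate(genomes):
        for b in genomes[i + 1:]:
            r_ab = ani_pair(a, b, **match_kw)
            r_ba = ani_pair(b, a, **match_kw)
            directed[(a.strain_id, b.strain_id)] = r_ab
            directed[(b.strain_id, a.strain_id)] = r_ba
            vals = [r.anib for r in (r_ab, r_ba) if r.defined]
            mean = float(np.mean(vals)) if vals else float("nan")
            mat.loc[a.strain_id, b.strain_id] = mean
            mat.loc[b.strain_id, a.strain_id] = mean
    return mat, directed


# ---------------------------------------------------------------------------
# TETRA
# ---------------------------------------------------------------------------

def _kmer_counts(seq: str, k: int) -> np.ndarray:
    codes = encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(4 ** k, dtype=np.int64)
    idx = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for off in range(k):
        c = codes[off:off + n]
        ok &= c < 4
        idx = idx * 4 + np.where(c < 4, c, 0)
    return np.bincount(idx[ok], minlength=4 ** k)


def tetra_zscores(g, min_length: int = 50_000) -> TetraProfile:
    """Strand-symmetrized tetranucleotide z-score profile of a genome.

    Counts are accumulated over every replicon and its reverse complement;
    expected counts come from the maximal-order Markov model and the z-score
    uses that model's variance. Sequences shorter than ``min_length`` in
    total trigger a warning (z-scores become unstable).
    """
    if isinstance(g, GenomeRecord):
        sid = g.strain_id
        seqs = [seq for _, seq, _ in g.replicons]
    else:
        sid, seqs = "seq", [str(g)]
    total = sum(len(s) for s in seqs)
    if total < 4:
        raise ValueError("sequence shorter than 4")
    if total < min_length:
        warnings.warn(f"{sid}: only {total} bp; tetranucleotide z-scores are unstable")
    n4 = np.zeros(256, dtype=np.int64)
    n3 = np.zeros(64, dtype=np.int64)
    n2 = np.zeros(16, dtype=np.int64)
    for s in seqs:
        for t in (s, revcomp(s)):
            n4 += _kmer_counts(t, 4)
            n3 += _kmer_counts(t, 3)
            n2 += _kmer_counts(t, 2)
    i = np.arange(256)
    abc, bcd, bc = i >> 2, i & 63, (i >> 2) & 15
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = np.where(n2[bc] > 0, n3[abc] * n3[bcd] / np.maximum(n2[bc], 1), 0.0)
        var = np.where(
            (n3[abc] > 0) & (n3[bcd] > 0),
            exp * ((n3[abc] - exp) * (n3[bcd] - exp)) / (n3[abc] * n3[bcd] + 1e-300),
            0.0,
        )
        z = np.where(var > 0, (n4 - exp) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    return TetraProfile(sid, z)


def tetra_correlation(a: TetraProfile, b: TetraProfile) -> float:
    """Pearson correlation of two TETRA profiles, in percent."""
    r = float(np.corrcoef(a.z, b.z)[0, 1])
    return 100.0 * r
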