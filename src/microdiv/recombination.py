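"""Ensemble homologous-recombination detection on a core multiple alignment.

Three scanning statistics are implemented — MaxChi (pairwise match/mismatch
chi-square contrast), a Chimaera-style triplet variant (parental-affinity
series of a putative recombinant), and an RDP-style triplet window scan
(local over-representation of a pairing, binomial tail) — and combined by a
k-of-m consensus: regions supported by at least ``k`` distinct methods at
``p < p_cutoff`` are certified, the tracts and their recipient strains are
delineated inside each certified region from the per-strain
divergence-from-consensus profile, per-strain calls are reassembled into
one event per import, breakpoints are refined by the MaxChi statistic at
the region edges, and a donor is inferred from within-event distances.

Significance for the chi-square scans comes from the permutation null of the
maximum statistic over candidate breakpoints (seeded; family-wise valid by
construction). The permutation loop exits early once the observed maximum is
clearly unexceptional, which keeps genome-wide scans fast without touching
the attainable p resolution near the cutoff. RDP windows use the exact
binomial tail with a Bonferroni correction over windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import binom

from ._util import merge_intervals, spawn_rng
from .io import AlignmentBlock

_GAPCODE = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _GAPCODE[ord(_b)] = _i
_GAPCODE[ord("N")] = 4
_GAPCODE[ord("-")] = 5


# ---------------------------------------------------------------------------
# aligned column set
# ---------------------------------------------------------------------------

@dataclass
class AlignedColumnSet:
    """Gap-free columns of the blocks containing every considered strain.

    ``var_cols`` indexes the polymorphic columns in the concatenated
    gap-free column space; ``var_chars`` holds their per-strain states;
    ``positions`` maps every column to a genome coordinate per strain.
    """

    strains: list[str]
    n_columns: int
    var_cols: np.ndarray    # (n_var,) int64, ascending
    var_chars: np.ndarray   # (n_strains, n_var) uint8
    positions: np.ndarray   # (n_strains, n_columns) int32

    def index(self, strain: str) -> int:
        return self.strains.index(strain)

    def genome_interval(self, strain: str, col_start: int, col_end: int) -> tuple[int, int]:
        i = self.index(strain)
        return int(self.positions[i, col_start]), int(self.positions[i, col_end - 1]) + 1

    def pair_mismatch(self, a: str, b: str) -> np.ndarray:
        return self.var_chars[self.index(a)] != self.var_chars[self.index(b)]


def extract_variable_sites(blocks: list[AlignmentBlock], strains: list[str],
                           min_block_length: int = 500) -> AlignedColumnSet:
    """Concatenate gap-free columns of blocks containing all *strains*.

    Blocks missing a strain or shorter than ``min_block_length`` are
    skipped; columns with a gap or N in any considered strain are dropped;
    the polymorphic columns among the rest become the variable sites.
    """
    chunks, pos_chunks = [], []
    for b in blocks:
        if not set(strains) <= b.strains() or b.length < min_block_length:
            continue
        mat = np.empty((len(strains), b.length), dtype=np.uint8)
        pos = np.empty((len(strains), b.length), dtype=np.int32)
        for i, s in enumerate(strains):
            row = b.row(s)
            codes = _GAPCODE[np.frombuffer(row.seq.upper().encode(), dtype=np.uint8)]
            mat[i] = codes
            ungapped = codes != 5
            offs = np.cumsum(ungapped) - 1
            if row.strand == "+":
                pos[i] = row.start + offs
            else:
                pos[i] = row.end - 1 - offs
        keep = (mat < 4).all(axis=0)
        chunks.append(mat[:, keep])
        pos_chunks.append(pos[:, keep])
    if not chunks:
        raise ValueError("no alignment blocks contain all requested strains")
    mat = np.concatenate(chunks, axis=1)
    pos = np.concatenate(pos_chunks, axis=1)
    var = (mat != mat[0]).any(axis=0)
    return AlignedColumnSet(
        strains=list(strains), n_columns=mat.shape[1],
        var_cols=np.flatnonzero(var).astype(np.int64),
        var_chars=np.ascontiguousarray(mat[:, var]),
        positions=pos,
    )


# ---------------------------------------------------------------------------
# candidate and accepted events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateEvent:
    method: str                       # maxchi | chimera | rdp
    recipient: str | None
    parents: tuple[str, ...] | None
    col_interval: tuple[int, int]
    statistic: float
    p_value: float
    breakpoint_col: int | None = None

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside (0,1]")
        if self.col_interval[1] <= self.col_interval[0]:
            raise ValueError("empty candidate interval")


@dataclass(frozen=True)
class RecombinationEvent:
    recipients: tuple[str, ...]
    interval: tuple[int, int]          # genome bp, first recipient's coordinates
    col_interval: tuple[int, int]      # alignment columns
    supporting_methods: frozenset[str]
    min_p: dict
    breakpoints: tuple[int, int]       # refined columns
    inferred_donor: str
    imported_substitution_count: int | None = None

    @property
    def recipient(self) -> str:
        return self.recipients[0]

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


# ---------------------------------------------------------------------------
# shared scan machinery
# ---------------------------------------------------------------------------

def _chi2_profile(cum: np.ndarray, centers: np.ndarray, half: int) -> np.ndarray:
    """2x2 chi-square of mismatch counts left/right of each center.

    ``cum`` is the zero-prefixed cumulative mismatch count (…, n+1)."""
    left = cum[..., centers] - cum[..., centers - half]
    right = cum[..., centers + half] - cum[..., centers]
    tot = left + right
    w = float(half)
    denom = w * w * tot * (2 * w - tot)
    num = 2 * w * (left * (w - right) - right * (w - left)) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(denom > 0, num / denom, 0.0)
    return chi


def _perm_max_null(vec: np.ndarray, centers: np.ndarray, half: int, obs_max: float,
                   rng, n_perm: int, chunk: int = 127) -> np.ndarray:
    """Sample the permutation null of the max chi-square; early exit when null.

    Under a permutation of site order the chi-square at each candidate
    center depends only on how the mismatches fall into the bins cut by the
    window boundaries, so the null is drawn exactly (and cheaply) as
    multivariate-hypergeometric bin counts instead of explicit shuffles.
    The observed maximum must beat every draw to reach the smallest
    attainable p, so once two draws match or exceed it the final p can no
    longer clear a small cutoff and sampling stops.
    """
    n = vec.size
    m_ones = int(vec.sum())
    bounds = np.unique(np.concatenate([centers - half, centers, centers + half]))
    bounds = bounds[(bounds > 0) & (bounds < n)]
    sizes = np.diff(np.concatenate([[0], bounds, [n]])).astype(np.int64)
    # cum index of each needed boundary position
    pos_index = {int(b): i + 1 for i, b in enumerate(bounds)}
    pos_index[0] = 0
    pos_index[n] = len(bounds) + 1
    c_lo = np.array([pos_index[int(c - half)] for c in centers])
    c_mid = np.array([pos_index[int(c)] for c in centers])
    c_hi = np.array([pos_index[int(c + half)] for c in centers])

    exceed = 0
    done = 0
    null_max = []
    remaining = n_perm
    while remaining > 0:
        m = min(chunk, remaining)
        counts = rng.multivariate_hypergeometric(sizes, m_ones, size=m,
                                                 method="marginals")
        cum = np.zeros((m, sizes.size + 1), dtype=np.float32)
        np.cumsum(counts, axis=1, dtype=np.float32, out=cum[:, 1:])
        left = cum[:, c_mid] - cum[:, c_lo]
        right = cum[:, c_hi] - cum[:, c_mid]
        mx = _chi2_pair(left, right, half).max(axis=1)
        null_max.append(mx)
        exceed += int((mx >= obs_max).sum())
        done += m
        remaining -= m
        if exceed >= 2:
            break
        chunk = min(chunk * 4, 1024)
    return np.concatenate(null_max)


def _chi2_pair(left: np.ndarray, right: np.ndarray, half: int) -> np.ndarray:
    tot = left + right
    w = float(half)
    denom = w * w * tot * (2 * w - tot)
    num = 2 * w * (left * (w - right) - right * (w - left)) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, num / denom, 0.0)


def _scan_peaks(vec: np.ndarray, window_sites: int, n_perm: int, rng,
                stat_stride: int = 10, p_report: float = 0.05, max_peaks: int = 40):
    """Find significant local maxima of the MaxChi statistic along ``vec``.

    Returns a list of ``(center_index, statistic, p)``. The candidate-center
    grid (every ``stat_stride`` sites) is shared between the observed scan
    and the permutation null, so the test stays exact on that grid; the
    grid is much finer than the window, which bounds how much of a peak it
    can miss."""
    if window_sites % 2:
        raise ValueError("window_sites must be even")
    half = window_sites // 2
    n = vec.size
    if n < window_sites:
        return None  # caller warns
    centers = np.arange(half, n - half + 1, stat_stride)
    cum = np.zeros(n + 1, dtype=np.float32)
    np.cumsum(vec, dtype=np.float32, out=cum[1:])
    obs = _chi2_profile(cum, centers, half)
    order = np.argsort(obs)[::-1]
    peaks = []
    blocked = np.zeros(centers.size, dtype=bool)
    null_max = _perm_max_null(vec, centers, half, float(obs.max()), rng, n_perm)
    for oi in order:
        if blocked[oi] or len(peaks) >= max_peaks:
            continue
        stat = float(obs[oi])
        if stat <= 0:
            break
        p = (1 + int((null_max >= stat).sum())) / (null_max.size + 1)
        if p > p_report:
            break
        peaks.append((int(centers[oi]), stat, float(p)))
        # block only half a window: the entry and exit breakpoints of one
        # tract can sit closer than a full window apart
        lo, hi = centers[oi] - half, centers[oi] + half
        blocked |= (centers >= lo) & (centers <= hi)
    return peaks


def _site_interval_to_cols(columns: AlignedColumnSet, lo_site: int, hi_site: int):
    lo = int(columns.var_cols[max(lo_site, 0)])
    hi = int(columns.var_cols[min(hi_site, columns.var_cols.size - 1)]) + 1
    return lo, hi


# ---------------------------------------------------------------------------
# MaxChi (pairwise)
# ---------------------------------------------------------------------------

def maxchi_scan(columns: AlignedColumnSet, pair: tuple[str, str],
                window_sites: int = 210, n_perm: int = 1023,
                seed: int = 0, p_report: float = 0.05) -> list[CandidateEvent]:
    """MaxChi scan of one strain pair over the variable sites.

    Slides a ``window_sites``-site window (half left, half right of each
    candidate breakpoint) over the pair's match/mismatch series and tests
    the maximum chi-square against the permutation null of shuffled site
    order. Each significant local maximum becomes a candidate with the
    maximizing column as its provisional breakpoint; the putative recipient
    is the member whose affinity to the consensus of the remaining strains
    flips across the breakpoint (near-ties yield a candidate for each)."""
    a, b = pair
    mism = columns.pair_mismatch(a, b).astype(np.float32)
    rng = spawn_rng(seed, "maxchi", a, b)
    peaks = _scan_peaks(mism, window_sites, n_perm, rng)
    if peaks is None:
        warnings.warn(f"maxchi {a}/{b}: fewer variable sites than window")
        return []
    others = [s for s in columns.strains if s not in pair]
    cons = _consensus(columns, others) if others else None
    out = []
    for lo_s, hi_s, center, stat, p in _segments_from_peaks(mism, peaks):
        lo, hi = _site_interval_to_cols(columns, lo_s, hi_s - 1)
        bp = int(columns.var_cols[center])
        for recip in _flip_recipients(columns, pair, cons, (lo_s, hi_s)):
            out.append(CandidateEvent("maxchi", recip, tuple(pair), (lo, hi),
                                      stat, p, breakpoint_col=bp))
    return out


def _segments_from_peaks(vec: np.ndarray, peaks):
    """Turn significant breakpoints into candidate segments.

    Peaks partition the site series; each peak claims the flanking segment
    whose mean deviates more from the series-wide mean (for a mismatch
    series that is the locally divergent side, i.e. the imported tract).
    Two breakpoints delimiting one tract both claim the tract, so segments
    are deduplicated. Returns ``(lo_site, hi_site, peak_center, stat, p)``."""
    gmean = float(vec.mean())
    bnds = sorted(c for c, _, _ in peaks)
    reach = 840  # a claimed segment extends at most this many sites past its peak
    best: dict[tuple[int, int], tuple[int, float, float]] = {}
    for c, stat, p in peaks:
        i = bnds.index(c)
        prev_b = bnds[i - 1] if i > 0 else max(c - reach, 0)
        next_b = bnds[i + 1] if i + 1 < len(bnds) else min(c + reach, vec.size)
        prev_b, next_b = max(prev_b, c - reach), min(next_b, c + reach)
        left, right = vec[prev_b:c], vec[c:next_b]
        lm = float(left.mean()) if left.size else gmean
        rm = float(right.mean()) if right.size else gmean
        lo, hi = (prev_b, c) if abs(lm - gmean) >= abs(rm - gmean) else (c, next_b)
        if hi - lo <= 0:
            continue
        # trim to the divergent core: score each site against the midpoint
        # of the two flank densities at the peak (the local contrast), and
        # keep the maximum-sum subarray — this localizes the tract without
        # bridging across background-level gaps
        t0 = (lm + rm) / 2.0
        sign = 1.0 if float(vec[lo:hi].mean()) >= t0 else -1.0
        lo, hi = _dense_core(sign * (vec[lo:hi] - t0), lo)
        if hi - lo <= 0:
            continue
        key = (lo, hi)
        if key not in best or stat > best[key][1]:
            best[key] = (c, stat, p)
    return [(lo, hi, c, stat, p) for (lo, hi), (c, stat, p) in sorted(best.items())]


def _dense_core(dev: np.ndarray, offset: int) -> tuple[int, int]:
    """Maximum-sum subarray (Kadane), returned as site indices + offset."""
    best_sum = cur = -np.inf
    best = (offset, offset + 1)
    start = 0
    for i, x in enumerate(dev):
        if cur <= 0:
            cur, start = float(x), i
        else:
            cur += float(x)
        if cur > best_sum:
            best_sum = cur
            best = (offset + start, offset + i + 1)
    return best


def _consensus(columns: AlignedColumnSet, strains: list[str]) -> np.ndarray:
    idx = [columns.index(s) for s in strains]
    chars = columns.var_chars[idx]
    cons = np.empty(chars.shape[1], dtype=np.uint8)
    counts = np.stack([(chars == c).sum(axis=0) for c in range(4)])
    cons = np.argmax(counts, axis=0).astype(np.uint8)
    return cons


def _flip_recipients(columns, pair, cons, seg) -> list[str]:
    """The pair member whose divergence from the outgroup consensus rises
    inside the candidate segment (near-ties flag both members)."""
    if cons is None:
        return list(pair)
    lo, hi = seg
    scores = {}
    for s in pair:
        mx = columns.var_chars[columns.index(s)] != cons
        local = float(mx[lo:hi].mean()) if hi > lo else 0.0
        scores[s] = local - float(mx.mean())
    a, b = pair
    hi_s, lo_s = max(scores[a], scores[b]), min(scores[a], scores[b])
    if hi_s > 0 and (lo_s <= 0 or lo_s / hi_s < 0.75):
        return [a if scores[a] >= scores[b] else b]
    return [a, b]  # ambiguous: flag both, resolved at consensus stage


# ---------------------------------------------------------------------------
# Chimaera-style (triplet)
# ---------------------------------------------------------------------------

def chimera_scan(columns: AlignedColumnSet, triplet: tuple[str, str, str],
                 window_sites: int = 210, n_perm: int = 1023,
                 seed: int = 0, p_report: float = 0.05) -> list[CandidateEvent]:
    """Chimaera-style scan: MaxChi on the parental-affinity series.

    For each member as putative recombinant, the informative sites are the
    columns where the two parents differ and the recombinant matches one of
    them; the binary series records which parent it matches. A recombinant
    region flips the series, which the MaxChi contrast detects. Overlapping
    peaks across the three orientations keep only the strongest."""
    if len(set(triplet)) != 3:
        raise ValueError("triplet must contain three distinct strains")
    raw = []
    warned = False
    for r in triplet:
        p1, p2 = [s for s in triplet if s != r]
        cr = columns.var_chars[columns.index(r)]
        c1 = columns.var_chars[columns.index(p1)]
        c2 = columns.var_chars[columns.index(p2)]
        informative = (c1 != c2) & ((cr == c1) | (cr == c2))
        sites = np.flatnonzero(informative)
        if sites.size < window_sites:
            warned = warned or sites.size > 0
            continue
        v = (cr[sites] == c1[sites]).astype(np.float32)
        rng = spawn_rng(seed, "chimera", r, p1, p2)
        peaks = _scan_peaks(v, window_sites, n_perm, rng)
        for lo_s, hi_s, center, stat, p in _segments_from_peaks(v, peaks or []):
            site_lo = int(sites[lo_s])
            site_hi = int(sites[hi_s - 1])
            lo, hi = _site_interval_to_cols(columns, site_lo, site_hi)
            raw.append(CandidateEvent("chimera", r, (p1, p2), (lo, hi), stat, p,
                                      breakpoint_col=int(columns.var_cols[sites[center]])))
    if not raw and warned:
        warnings.warn(f"chimera {triplet}: fewer informative sites than window")
    # keep the strongest orientation where peaks overlap; the recipient is
    # then re-read from the pairwise-distance shift inside the candidate
    # region (the member whose distances to the other two move the most),
    # which resolves external-donor imports the orientation alone cannot
    raw.sort(key=lambda c: -c.statistic)
    kept: list[CandidateEvent] = []
    for c in raw:
        if any(_overlap(c.col_interval, k.col_interval) for k in kept):
            continue
        recip = _rdp_recipient(columns, triplet, c.col_interval)
        kept.append(CandidateEvent(c.method, recip, c.parents, c.col_interval,
                                   c.statistic, c.p_value, c.breakpoint_col))
    return kept


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


# ---------------------------------------------------------------------------
# RDP-style (triplet)
# ---------------------------------------------------------------------------

def rdp_scan(columns: AlignedColumnSet, triplet: tuple[str, str, str],
             window_nt: int = 90, step: int | None = None,
             p_report: float = 0.05, min_sites: int = 4,
             gap_windows: int = 8) -> list[CandidateEvent]:
    """RDP-style window scan of one triplet.

    Informative sites are columns where exactly two of the three agree; each
    supports one pairing. Windows (``window_nt`` alignment columns) where a
    pairing is over-represented relative to its genome-wide proportion are
    chained (tolerating short gaps), and each chained region is tested with
    the exact binomial tail of its supporting-site count at the genome-wide
    proportion, Bonferroni-corrected over the number of tested regions.
    Testing every pairing, not only the genome-wide minority, keeps power
    against imports from outside the sample: an external import makes the
    two *non-recipients* agree locally, and that pairing may well be the
    genome-wide majority."""
    if len(set(triplet)) != 3:
        raise ValueError("triplet must contain three distinct strains")
    if window_nt > columns.n_columns:
        raise ValueError("window larger than the alignment")
    step = step or max(window_nt // 3, 1)
    ia, ib, ic = (columns.index(s) for s in triplet)
    ca, cb, cc = columns.var_chars[ia], columns.var_chars[ib], columns.var_chars[ic]
    eq = np.stack([(ca == cb) & (cb != cc), (ca == cc) & (ca != cb), (cb == cc) & (cb != ca)])
    informative = eq.sum(axis=0) == 1
    if not informative.any():
        return []
    labels = np.argmax(eq[:, informative], axis=0)
    info_cols = columns.var_cols[informative]
    g = np.bincount(labels, minlength=3)
    total = int(g.sum())
    cum = np.zeros((3, labels.size + 1), dtype=np.int64)
    for lab in range(3):
        np.cumsum(labels == lab, out=cum[lab, 1:])
    starts = np.arange(0, columns.n_columns - window_nt + 1, step)
    lo = np.searchsorted(info_cols, starts)
    hi = np.searchsorted(info_cols, starts + window_nt)
    counts = cum[:, hi] - cum[:, lo]  # (3, n_windows)
    m = counts.sum(axis=0)

    regions: list[tuple[int, int, int]] = []  # (label, w_start, w_end)
    for lab in range(3):
        if g[lab] == 0 or g[lab] == total:
            continue
        p0 = g[lab] / total
        dom = (counts[lab] > m * p0) & (counts[lab] > 0)
        idx = np.flatnonzero(dom)
        if idx.size == 0:
            continue
        run_s = prev = int(idx[0])
        for i in list(idx[1:]) + [None]:
            if i is not None and i - prev <= gap_windows:
                prev = int(i)
                continue
            regions.append((lab, run_s, prev))
            if i is not None:
                run_s = prev = int(i)
    if not regions:
        return []
    out = []
    n_regions = len(regions)
    for lab, ws, we in regions:
        c_lo, c_hi = int(starts[ws]), int(starts[we] + window_nt)
        a, b = np.searchsorted(info_cols, (c_lo, c_hi))
        mm = int(b - a)
        if mm < min_sites:
            continue
        xx = int((labels[a:b] == lab).sum())
        p0 = g[lab] / total
        p_raw = float(binom.sf(xx - 1, mm, p0))
        p_adj = min(p_raw * n_regions, 1.0)
        if p_adj >= p_report:
            continue
        recip = _rdp_recipient(columns, triplet, (c_lo, c_hi))
        out.append(CandidateEvent("rdp", recip, tuple(triplet), (c_lo, c_hi),
                                  float(xx), max(p_adj, 1e-300)))
    return out


def _rdp_recipient(columns: AlignedColumnSet, triplet, col_iv) -> str:
    """The member whose pairwise divergence rates shift most in the window.

    Rates are per alignment column (not per variable site): inside an
    import the variable-site density itself rises, which distorts
    site-fraction distances for every pair, import or not."""
    sl = slice(*np.searchsorted(columns.var_cols, col_iv))
    span = max(col_iv[1] - col_iv[0], 1)
    best, best_score = triplet[0], -1.0
    for s in triplet:
        score = 0.0
        for t in triplet:
            if t == s:
                continue
            mism = columns.pair_mismatch(s, t)
            gw = float(mism.sum()) / columns.n_columns
            local = float(mism[sl].sum()) / span
            score += abs(local - gw)
        if score > best_score:
            best, best_score = s, score
    return best


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

def scan_all(columns: AlignedColumnSet, window_sites: int = 210, window_nt: int = 90,
             n_perm: int = 1023, seed: int = 0, max_triplets: int = 200) -> list[CandidateEvent]:
    """Run every method over all pairs and triplets of strains.

    Triplets are enumerated exhaustively for up to 10 strains and seeded
    subsampling is used beyond that."""
    strains = columns.strains
    cands: list[CandidateEvent] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pair in combinations(strains, 2):
            cands += maxchi_scan(columns, pair, window_sites, n_perm, seed)
        triplets = list(combinations(strains, 3))
        if len(strains) > 10 and len(triplets) > max_triplets:
            rng = spawn_rng(seed, "triplets")
            idx = rng.choice(len(triplets), size=max_triplets, replace=False)
            triplets = [triplets[i] for i in sorted(idx)]
        for tri in triplets:
            cands += chimera_scan(columns, tri, window_sites, n_perm, seed)
            cands += rdp_scan(columns, tri, window_nt)
    return cands


def ensemble_consensus(columns: AlignedColumnSet, cands: list[CandidateEvent],
                       k: int = 2, p_cutoff: float = 0.001,
                       window_sites: int = 210) -> list[RecombinationEvent]:
    """k-of-m consensus over candidate events.

    Candidates below ``p_cutoff`` are grouped per recipient by column
    overlap; groups supported by at least ``k`` distinct methods become
    events whose interval is the union, with breakpoints refined by a local
    MaxChi contrast around the union's edges and the donor chosen as the
    non-recipient strain closest to the recipient within the event (or
    "external" when every strain is farther inside the event than its
    genome-wide background, the signature of an import from outside the
    sample).

    The scanning statistics certify *where* recombination is supported;
    which strains carry the import and the tract's exact extent are read
    off the per-strain divergence-from-consensus profile inside each
    certified region (window-scale scans smear intervals and can attribute
    the recipient to either side of a pairing, so profile-based
    delineation is used for the final calls)."""
    if k > 3:
        raise ValueError(f"consensus k={k} exceeds the number of implemented methods")
    sig = [c for c in cands if c.p_value < p_cutoff]

    # maximal column runs covered by >= k distinct methods (any recipient)
    per_method = {m: merge_intervals([c.col_interval for c in sig if c.method == m])
                  for m in {c.method for c in sig}}
    pts: list[tuple[int, int]] = []
    for ivs in per_method.values():
        for lo, hi in ivs:
            pts.append((lo, +1))
            pts.append((hi, -1))
    pts.sort()
    regions: list[tuple[int, int, str, frozenset, dict]] = []
    active = 0
    run_start = None
    for pos, delta in pts:
        prev = active
        active += delta
        if prev < k <= active:
            run_start = pos
        elif prev >= k > active and run_start is not None:
            for s in columns.strains:
                regions.extend(_trimmed_regions(columns, sig, s, run_start, pos))
            run_start = None

    # merge regions across recipients: one biological import shows up once
    # per carrying strain and must become a single event whose recipients
    # all get masked downstream
    regions.sort()
    events: list[RecombinationEvent] = []
    cluster: list[tuple] = []
    for reg in regions + [(None,)]:
        if reg[0] is not None and cluster and reg[0] < max(r[1] for r in cluster):
            cluster.append(reg)
            continue
        if cluster:
            lo = min(r[0] for r in cluster)
            hi = max(r[1] for r in cluster)
            recips = tuple(sorted({r[2] for r in cluster}))
            methods = frozenset().union(*(r[3] for r in cluster))
            min_p: dict = {}
            for r in cluster:
                for m, p in r[4].items():
                    min_p[m] = min(min_p.get(m, 1.0), p)
            bp = _refine_breakpoints(columns, recips, (lo, hi), window_sites)
            donor = _infer_donor(columns, recips[0], (lo, hi))
            events.append(RecombinationEvent(
                recipients=recips,
                interval=columns.genome_interval(recips[0], lo, hi),
                col_interval=(lo, hi),
                supporting_methods=methods, min_p=min_p,
                breakpoints=bp, inferred_donor=donor,
            ))
        cluster = [reg] if reg[0] is not None else []
    return sorted(_assemble_imports(columns, events, window_sites),
                  key=lambda e: (e.col_interval, e.recipients))


def _assemble_imports(columns, events: list[RecombinationEvent], window_sites: int,
                      gap: int = 200, mutual: float = 0.7) -> list[RecombinationEvent]:
    """Reassemble fragmented per-strain calls into one event per import.

    Overlapping imports into different strains fragment the profile-based
    calls into alternating recipient subsets. Per strain, nearby calls
    (column gap <= ``gap``) are merged into that strain's tract runs;
    runs of different strains are then joined into a single event only
    when they are mutually concordant (reciprocal overlap >= ``mutual`` of
    the shorter and half of the longer) — the signature of one shared
    import rather than two stacked ones."""
    runs: list[tuple[int, int, str, frozenset, dict]] = []
    for s in columns.strains:
        evs = sorted((e.col_interval for e in events if s in e.recipients))
        if not evs:
            continue
        cur_lo, cur_hi = evs[0]
        merged: list[tuple[int, int]] = []
        for lo, hi in evs[1:]:
            if lo - cur_hi <= gap:
                cur_hi = max(cur_hi, hi)
            else:
                merged.append((cur_lo, cur_hi))
                cur_lo, cur_hi = lo, hi
        merged.append((cur_lo, cur_hi))
        for lo, hi in merged:
            over = [e for e in events if s in e.recipients
                    and _overlap(e.col_interval, (lo, hi))]
            methods = frozenset().union(*(e.supporting_methods for e in over))
            min_p: dict = {}
            for e in over:
                for m, p in e.min_p.items():
                    min_p[m] = min(min_p.get(m, 1.0), p)
            runs.append((lo, hi, s, methods, min_p))

    imports: list[dict] = []
    for lo, hi, s, methods, min_p in sorted(runs):
        joined = False
        for imp in imports:
            ov = min(imp["hi"], hi) - max(imp["lo"], lo)
            shorter = min(hi - lo, imp["hi"] - imp["lo"])
            longer = max(hi - lo, imp["hi"] - imp["lo"])
            if ov >= mutual * shorter and ov >= 0.5 * longer:
                imp["lo"], imp["hi"] = min(imp["lo"], lo), max(imp["hi"], hi)
                imp["strains"].add(s)
                imp["methods"] |= methods
                for m, p in min_p.items():
                    imp["min_p"][m] = min(imp["min_p"].get(m, 1.0), p)
                joined = True
                break
        if not joined:
            imports.append({"lo": lo, "hi": hi, "strains": {s},
                            "methods": set(methods), "min_p": dict(min_p)})

    out = []
    for imp in imports:
        recips = tuple(sorted(imp["strains"]))
        lo, hi = imp["lo"], imp["hi"]
        out.append(RecombinationEvent(
            recipients=recips,
            interval=columns.genome_interval(recips[0], lo, hi),
            col_interval=(lo, hi),
            supporting_methods=frozenset(imp["methods"]),
            min_p=imp["min_p"],
            breakpoints=_refine_breakpoints(columns, recips, (lo, hi), window_sites),
            inferred_donor=_infer_donor(columns, recips[0], (lo, hi)),
        ))
    return out


def _trimmed_regions(columns, cands: list[CandidateEvent], recipient: str,
                     lo: int, hi: int, smooth: int = 9, max_gap_cols: int = 1500,
                     min_sites: int = 5) -> list[tuple[int, int, str, frozenset, dict]]:
    """Localize imports inside a method-certified coverage run.

    The scans certify that recombination involving ``recipient`` is
    supported somewhere in [lo, hi); the tract itself is where the
    recipient diverges from the majority consensus of the other strains.
    Runs of the smoothed divergence profile above 1/2 (majority divergence)
    become the reported regions — one region per import even when a
    coverage run spans several."""
    region_cands = [c for c in cands if _overlap(c.col_interval, (lo, hi))]
    region_methods = frozenset(c.method for c in region_cands)
    ri = columns.index(recipient)
    cons = _consensus(columns, [s for s in columns.strains if s != recipient])
    a, b = np.searchsorted(columns.var_cols, (lo, hi))
    prof = (columns.var_chars[ri, a:b] != cons[a:b]).astype(np.float32)
    if prof.size < min_sites:
        return []
    w = min(smooth, prof.size)
    kern = np.ones(w) / w
    sm = np.convolve(prof, kern, mode="same")
    above = np.flatnonzero(sm > 0.5)
    if above.size == 0:
        return []
    out = []
    run_s = prev = int(above[0])
    for i in list(above[1:]) + [None]:
        # gap measured in alignment columns: a clean stretch between two
        # imports holds few variable sites, so a site-count gap would
        # silently bridge distinct tracts
        if i is not None and (columns.var_cols[a + int(i)]
                              - columns.var_cols[a + prev]) <= max_gap_cols:
            prev = int(i)
            continue
        if prev - run_s + 1 >= min_sites:
            c_lo = int(columns.var_cols[a + run_s])
            c_hi = int(columns.var_cols[a + prev]) + 1
            over = [c for c in region_cands if _overlap(c.col_interval, (c_lo, c_hi))]
            methods = frozenset(c.method for c in over) or region_methods
            min_p = {m: min(c.p_value for c in over if c.method == m) for m in methods}
            if not min_p:
                min_p = {m: min(c.p_value for c in region_cands if c.method == m)
                         for m in region_methods}
            out.append((c_lo, c_hi, recipient, methods, min_p))
        if i is not None:
            run_s = prev = int(i)
    return out


def _best_partner(columns: AlignedColumnSet, recip: str) -> str:
    best, bd = None, np.inf
    for s in columns.strains:
        if s == recip:
            continue
        d = float(columns.pair_mismatch(recip, s).mean())
        if d < bd:
            best, bd = s, d
    return best


def _refine_breakpoints(columns: AlignedColumnSet, recipients: tuple[str, ...],
                        col_iv: tuple[int, int], window_sites: int) -> tuple[int, int]:
    """MaxChi refinement of the two edges of a consensus interval.

    The chi-square contrast of the recipient-vs-nonrecipient-consensus
    mismatch series is maximized near each edge. Contrasting against the
    consensus (rather than the closest strain, which may itself carry the
    import) keeps the junction sharp."""
    recip = recipients[0]
    others = [s for s in columns.strains if s not in recipients]
    if others:
        cons = _consensus(columns, others)
        mism = (columns.var_chars[columns.index(recip)] != cons).astype(np.float32)
    else:
        mism = columns.pair_mismatch(recip, _best_partner(columns, recip)).astype(np.float32)
    half = window_sites // 2
    lo_site, hi_site = np.searchsorted(columns.var_cols, col_iv)
    cum = np.zeros(mism.size + 1, dtype=np.float32)
    np.cumsum(mism, out=cum[1:])

    def edge(site: int) -> int:
        a = max(site - half, half)
        b = min(site + half, mism.size - half)
        if b <= a:
            return int(np.clip(site, 0, columns.var_cols.size - 1))
        centers = np.arange(a, b)
        chi = _chi2_profile(cum, centers, half)
        return int(centers[np.argmax(chi)])

    left = edge(int(lo_site))
    right = edge(int(max(hi_site - 1, lo_site)))
    if right < left:
        left, right = right, left
    return int(columns.var_cols[left]), int(columns.var_cols[right])


def _infer_donor(columns: AlignedColumnSet, recip: str, col_iv: tuple[int, int]) -> str:
    sl = slice(*np.searchsorted(columns.var_cols, col_iv))
    best, best_d, best_bg = "external", np.inf, np.inf
    for s in columns.strains:
        if s == recip:
            continue
        mism = columns.pair_mismatch(recip, s)
        if mism[sl].size == 0:
            continue
        d = float(mism[sl].mean())
        if d < best_d:
            best, best_d, best_bg = s, d, float(mism.mean())
    if best != "external" and best_d >= best_bg:
        return "external"
    return best


def detect_recombination(blocks: list[AlignmentBlock], strains: list[str] | None = None,
                         k: int = 2, p_cutoff: float = 0.001, window_sites: int = 210,
                         window_nt: int = 90, n_perm: int = 1023, seed: int = 0,
                         min_block_length: int = 500):
    """Full pipeline: variable sites -> three scans -> consensus events.

    Returns ``(events, columns)``."""
    if strains is None:
        strains = sorted(set.union(*(b.strains() for b in blocks)))
    columns = extract_variable_sites(blocks, strains, min_block_length)
    cands = scan_all(columns, window_sites, window_nt, n_perm, seed)
    events = ensemble_consensus(columns, cands, k=k, p_cutoff=p_cutoff,
                                window_sites=window_sites)
    return events, columns


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_events(events: list[RecombinationEvent], genome_lengths: dict[str, int],
                     size_thresholds: tuple[int, ...] = (10_000, 50_000)):
    """Per-strain event counts, recombined fractions and a size histogram.

    ``genome_lengths`` maps strain id -> genome length (bp). The recombined
    fraction is the union of event intervals over the genome length; the
    overall fraction pools spans and lengths over all strains."""
    import pandas as pd

    rows = []
    union_total = 0
    for s, L in sorted(genome_lengths.items()):
        evs = [e for e in events if s in e.recipients]
        span = sum(e - s0 for s0, e in merge_intervals([e.interval for e in evs]))
        union_total += span
        rows.append({"strain": s, "n_events": len(evs), "recombined_bp": span,
                     "recombined_fraction": span / L if L else 0.0})
    per_strain = pd.DataFrame(rows)
    total_len = sum(genome_lengths.values())
    sizes = np.array([e.length for e in events]) if events else np.array([], dtype=int)
    hist = {f">{t}bp": int((sizes > t).sum()) for t in size_thresholds}
    hist["total"] = len(events)
    return {
        "per_strain": per_strain,
        "overall_recombined_fraction": union_total / total_len if total_len else 0.0,
        "size_histogram": hist,
    }
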