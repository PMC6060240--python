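"""Fisher-exact COG-category enrichment with Benjamini-Hochberg FDR.

Compares the functional composition of a foreground gene set (genes in
recombined regions, or in islands) against a background set; each category
gets an exact two-sided test of its 2x2 table, a BH-adjusted q-value, and a
direction (over/under) from the odds ratio. Significance uses the dual
threshold p < 0.05 and q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .io import GeneModel
from .recombination import RecombinationEvent


@dataclass(frozen=True)
class EnrichmentRow:
    category: str
    fg_in: int
    fg_out: int
    bg_in: int
    bg_out: int
    odds_ratio: float
    p: float
    q: float
    direction: str
    significant: bool


def fisher_enrichment(foreground: set, background: set,
                      categories: dict, alpha: float = 0.05) -> list[EnrichmentRow]:
    """Per-category Fisher exact tests of foreground vs background genes.

    ``categories`` maps gene id -> single-letter COG category (genes
    missing from the map are kept in the totals but belong to no tested
    category). The background must contain the foreground; the 2x2 table
    for category c is (fg in c, fg not in c) x (bg-only in c, bg-only not
    in c). Rows are sorted by q then category."""
    if not foreground:
        raise ValueError("empty foreground gene set")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    rest = background - foreground
    cats = sorted({c for g, c in categories.items() if g in background and c})
    rows = []
    for c in cats:
        fg_in = sum(1 for g in foreground if categories.get(g) == c)
        fg_out = len(foreground) - fg_in
        bg_in = sum(1 for g in rest if categories.get(g) == c)
        bg_out = len(rest) - bg_in
        odds, p = fisher_exact([[fg_in, fg_out], [bg_in, bg_out]], alternative="two-sided")
        rows.append((c, fg_in, fg_out, bg_in, bg_out, float(odds), float(p)))
    if not rows:
        return []
    qs = multipletests([r[6] for r in rows], method="fdr_bh")[1]
    out = []
    for (c, a, b, d, e, odds, p), q in zip(rows, qs):
        fg_rate = a / (a + b)
        bg_rate = d / (d + e) if d + e else 0.0
        direction = "over" if fg_rate > bg_rate else "under"
        out.append(EnrichmentRow(c, a, b, d, e, odds, p, float(q), direction,
                                 significant=(p < alpha and q < alpha)))
    return sorted(out, key=lambda r: (r.q, r.category))


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def genes_in_events(events: list[RecombinationEvent], genes: list[GeneModel],
                    min_overlap: float = 0.0) -> set[str]:
    """Gene ids overlapping any event interval.

    ``min_overlap`` is the fraction of the gene's length that must fall
    inside an event (0 keeps any >= 1 bp overlap). Coordinates of genes and
    events must share a coordinate system (the recipient genome)."""
    out = set()
    for g in genes:
        need = max(min_overlap * g.length, 1)
        for e in events:
            lo, hi = e.interval
            ov = min(g.end, hi) - max(g.start, lo)
            if ov >= need:
                out.add(g.gene_id)
                break
    return out
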