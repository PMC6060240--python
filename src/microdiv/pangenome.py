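"""Core/accessory pangenome partition, accumulation curves, island scan."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import gc_percent
from .io import GeneModel, GenomeRecord


@dataclass
class OrthologMatrix:
    """Gene-family x strain presence/absence with positional anchors.

    ``presence`` is a boolean DataFrame (families x strains). ``anchors``
    maps a family to one representative ``(strain_id, GeneModel)``;
    ``gene_members`` maps a family to every ``(strain_id, gene_id)`` carrying
    it. Families absent from every strain are rejected.
    """

    presence: pd.DataFrame
    anchors: dict[str, tuple[str, GeneModel]] = field(default_factory=dict)
    gene_members: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self):
        if self.presence.size == 0:
            raise ValueError("empty ortholog matrix")
        if not self.presence.any(axis=1).all():
            missing = self.presence.index[~self.presence.any(axis=1)].tolist()
            raise ValueError(f"families present in no strain: {missing[:5]}")

    @property
    def families(self) -> list[str]:
        return list(self.presence.index)

    @property
    def strains(self) -> list[str]:
        return list(self.presence.columns)

    def gene_to_family(self) -> dict[tuple[str, str], str]:
        return {(s, gid): fam for fam, mem in self.gene_members.items() for s, gid in mem}

    def to_tsv(self, path) -> None:
        self.presence.astype(int).to_csv(path, sep="\t", index_label="family")

    @classmethod
    def from_tsv(cls, path) -> "OrthologMatrix":
        df = pd.read_csv(path, sep="\t", index_col="family").astype(bool)
        return cls(df)


@dataclass
class AccumulationCurve:
    order_count: int
    k: np.ndarray                    # 1..n strains
    pangenome_mean: np.ndarray
    pangenome_sd: np.ndarray
    core_mean: np.ndarray
    core_sd: np.ndarray
    per_order_pangenome: np.ndarray  # (order_count, n)
    per_order_core: np.ndarray
    new_genes_per_strain: pd.DataFrame  # per-permutation new-family counts, by strain

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k,
            "pangenome_mean": self.pangenome_mean, "pangenome_sd": self.pangenome_sd,
            "core_mean": self.core_mean, "core_sd": self.core_sd,
        })


@dataclass(frozen=True)
class IslandCall:
    strain_id: str
    replicon_id: str
    interval: tuple[int, int]
    n_genes: int
    gc_percent: float
    accessory_fraction: float
    pct_genome: float


def partition_pangenome(m: OrthologMatrix) -> tuple[set[str], set[str]]:
    """Core = families present in every strain; accessory = the rest."""
    if len(m.strains) < 2:
        raise ValueError("need at least 2 strains to partition a pangenome")
    allp = m.presence.all(axis=1)
    core = set(m.presence.index[allp])
    accessory = set(m.presence.index[~allp])
    return core, accessory


def accumulation_curves(m: OrthologMatrix, n_orders: int = 100, seed: int = 0) -> AccumulationCurve:
    """Pangenome/core gene counts as strains are added in random orders.

    For each seeded permutation the pangenome at k is the union of the first
    k strains' families and the core their intersection; the difference
    between consecutive pangenome sizes is the number of new families the
    k-th strain contributes (the black bars of a gene-accumulation plot).
    """
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    rng = np.random.default_rng(seed)
    pres = m.presence.to_numpy()  # families x strains
    strains = m.strains
    n = len(strains)
    pan = np.zeros((n_orders, n), dtype=int)
    core = np.zeros((n_orders, n), dtype=int)
    new_counts: dict[str, list[int]] = {s: [] for s in strains}
    for o in range(n_orders):
        order = rng.permutation(n)
        union = np.zeros(pres.shape[0], dtype=bool)
        inter = np.ones(pres.shape[0], dtype=bool)
        prev = 0
        for k, idx in enumerate(order):
            union |= pres[:, idx]
            inter &= pres[:, idx]
            pan[o, k] = union.sum()
            core[o, k] = inter.sum()
            new_counts[strains[idx]].append(pan[o, k] - prev)
            prev = pan[o, k]
    return AccumulationCurve(
        order_count=n_orders,
        k=np.arange(1, n + 1),
        pangenome_mean=pan.mean(axis=0), pangenome_sd=pan.std(axis=0),
        core_mean=core.mean(axis=0), core_sd=core.std(axis=0),
        per_order_pangenome=pan, per_order_core=core,
        new_genes_per_strain=pd.DataFrame(new_counts),
    )


def island_scan(g: GenomeRecord, m: OrthologMatrix, window: int = 10_000,
                step: int | None = None, min_accessory_fraction: float = 0.5,
                min_genes: int = 3, max_gc_delta: float | None = None) -> list[IslandCall]:
    """Flag accessory-dense windows as genomic islands.

    Slides a window along each replicon; windows whose genes are at least
    ``min_accessory_fraction`` accessory (families absent from some strain)
    are flagged and adjacent flagged windows merged. If ``max_gc_delta`` is
    given (e.g. -2.0), merged calls must additionally deviate from the
    genome-average GC by at most that signed amount (islands run AT-richer
    than the backbone). Calls are sorted by position.
    """
    if g.strain_id not in m.strains:
        raise ValueError(f"strain {g.strain_id} absent from ortholog matrix")
    step = step or window // 2
    core, _ = partition_pangenome(m)
    fam_of = m.gene_to_family()
    calls: list[IslandCall] = []
    genome_gc = gc_percent("".join(seq for _, seq, _ in g.replicons))
    for rid, seq, _kind in g.replicons:
        genes = [x for x in g.genes if x.replicon_id == rid]
        if not genes:
            continue
        starts = np.array([x.start for x in genes])
        ends = np.array([x.end for x in genes])
        acc = np.array([fam_of.get((g.strain_id, x.gene_id)) not in core for x in genes])
        flagged: list[tuple[int, int]] = []
        for ws in range(0, max(len(seq) - window + 1, 1), step):
            we = min(ws + window, len(seq))
            in_w = (starts < we) & (ends > ws)
            if in_w.sum() >= min_genes and acc[in_w].mean() >= min_accessory_fraction:
                if flagged and ws <= flagged[-1][1]:
                    flagged[-1] = (flagged[-1][0], we)
                else:
                    flagged.append((ws, we))
        for s, e in flagged:
            in_c = (starts < e) & (ends > s)
            gc = gc_percent(seq[s:e])
            if max_gc_delta is not None and not (gc - genome_gc) <= max_gc_delta:
                continue
            calls.append(IslandCall(
                g.strain_id, rid, (s, e), int(in_c.sum()), gc,
                float(acc[in_c].mean()) if in_c.any() else 0.0,
                100.0 * (e - s) / len(seq),
            ))
    return sorted(calls, key=lambda c: (c.replicon_id, c.interval))
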