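"""Forward simulator for a recombining bacterial population.

Generates a small population of near-identical strains (a species at
within-species ANI >= 98%) structured into clonal frames, with

* clonal mutations placed as Poisson draws on the branches of a random
  clonal genealogy (Jukes-Cantor single-hit, no indels in the core),
* homologous-recombination imports: geometric-length tracts replaced by a
  donor haplotype drawn at divergence ``donor_divergence`` from the
  recipient's current sequence, with the imported substitutions counted
  exactly,
* accessory gene families gained at a small number of island hotspots
  (plus optional strain-specific plasmids), producing an open pangenome.

Every stochastic choice flows from ``SimParams.seed``, so identical
parameters give byte-identical output. The emitted XMFA is the true core
alignment: gap-free blocks split at the island hotspots.

Identifiability guarantee
-------------------------
The generator is built so its realized recombination/mutation ratios are
exactly recoverable from the emitted data: donors copy the recipient's
pre-event haplotype (imports never erase unrelated variation wholesale), and
clonal mutations are only placed at positions where, after masking every
tract for its recipient lineage, at least one carrier and one non-carrier
strain remain visible. Without this constraint a mutation falling inside an
earlier import of an ancestral lineage would be masked away for every
carrier and the truth ratios would be systematically unrecoverable.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass

import numpy as np

from ._util import decode, spawn_rng
from .io import AlignmentBlock, BlockRow, GeneModel, GenomeRecord

COG_LETTERS = "JKLDVTMNUOCGEFHIPQRS"


# ---------------------------------------------------------------------------
# parameters and truth tables
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Study-condition defaults: 8 strains in 5 clonal frames on a 500 kb
    core, rho/theta 0.3 with ~31% of the core covered by imports, donor pool
    at 2% divergence, and an open accessory genome at two island hotspots."""

    n_strains: int = 8
    n_clonal_frames: int = 5
    core_length: int = 500_000
    theta_site: float = 2.5e-4     # expected substitutions/site over the whole tree
    rho_rel: float = 0.3           # recombination events per mutation (target rho/theta)
    mean_tract: int = 5_000        # geometric tract length, bp
    donor_divergence: float = 0.02  # nu: substitutions/site carried by an import
    n_core_genes: int = 250
    n_accessory_families: int = 120
    island_hotspots: int = 2
    plasmid_rate: float = 0.6
    seed: int = 0
    gc_core: float = 0.62
    gc_accessory: float = 0.45
    min_gene_length: int = 300

    def __post_init__(self):
        for name in ("theta_site", "rho_rel", "donor_divergence", "plasmid_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 1 <= self.n_clonal_frames <= self.n_strains:
            raise ValueError("need 1 <= n_clonal_frames <= n_strains")
        if self.core_length < self.n_core_genes * self.min_gene_length:
            raise ValueError("core_length too small for n_core_genes")
        if self.mean_tract >= self.core_length:
            raise ValueError("mean tract length must be < core_length")
        if self.island_hotspots < 1:
            raise ValueError("need at least one island hotspot")


@dataclass(frozen=True)
class RecombTract:
    """One true import: the recipient branch's tip set and the core interval."""

    recipients: frozenset[str]
    start: int
    end: int
    imported_substitutions: int
    imported_positions: tuple[int, ...] = ()


@dataclass(frozen=True)
class MutationSite:
    strains: frozenset[str]  # carriers of the derived state
    position: int


@dataclass
class SimTruth:
    clonal_tree_newick: str
    cf_assignment: dict[str, str]
    mutation_sites: list[MutationSite]
    recomb_tracts: list[RecombTract]
    accessory_gains: list[tuple[str, str, int]]
    hotspot_loci: list[int]

    @property
    def realized_r_over_m(self) -> float:
        m = len(self.mutation_sites)
        r = sum(t.imported_substitutions for t in self.recomb_tracts)
        return r / m if m else (0.0 if r == 0 else float("nan"))

    @property
    def realized_rho_over_theta(self) -> float:
        m = len(self.mutation_sites)
        n = len(self.recomb_tracts)
        return n / m if m else (0.0 if n == 0 else float("nan"))

    def tree(self):
        """The clonal genealogy as a scikit-bio TreeNode."""
        from skbio import TreeNode
        return TreeNode.read(_stdio.StringIO(self.clonal_tree_newick))


# ---------------------------------------------------------------------------
# clonal genealogy
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("name", "children", "height", "length", "tips", "mutations", "events")

    def __init__(self, name, children=(), height=0.0):
        self.name = name
        self.children = list(children)
        self.height = height
        self.length = 0.0  # set once the parent is known
        self.tips = frozenset([name]) if not children else frozenset().union(*(c.tips for c in children))
        self.mutations: list[int] = []
        self.events: list[tuple[int, int]] = []

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def newick(self) -> str:
        def fmt(n):
            if not n.children:
                return f"{n.name}:{n.length:.10f}"
            inner = ",".join(fmt(c) for c in n.children)
            return f"({inner}):{n.length:.10f}"
        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


def _coalesce(nodes: list[_Node], heights, rng, prefix: str) -> list[_Node]:
    nodes = list(nodes)
    for k, h in enumerate(heights):
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(_Node(f"{prefix}{k}", [a, b], height=float(h)))
    return nodes


def sample_clonal_tree(params: SimParams, rng=None) -> tuple[_Node, dict[str, str]]:
    """Random clonal genealogy with the requested clonal-frame structure.

    Strains in the same frame coalesce at low heights, frames at high
    heights, so within-frame identity exceeds between-frame identity in
    expectation. Branch lengths are normalized to sum to 1: ``theta_site``
    is then the expected substitutions/site over the whole tree.
    """
    if rng is None:
        rng = spawn_rng(params.seed, "tree")
    strains = [f"S{i + 1:02d}" for i in range(params.n_strains)]
    order = list(rng.permutation(params.n_strains))
    # sizes: every frame gets one strain, remainder distributed at random
    sizes = np.ones(params.n_clonal_frames, dtype=int)
    for _ in range(params.n_strains - params.n_clonal_frames):
        sizes[rng.integers(params.n_clonal_frames)] += 1
    cf_assignment: dict[str, str] = {}
    roots: list[_Node] = []
    pos = 0
    for cf in range(params.n_clonal_frames):
        members = [strains[order[pos + k]] for k in range(sizes[cf])]
        pos += sizes[cf]
        for m in members:
            cf_assignment[m] = f"CF{cf + 1}"
        tips = [_Node(m) for m in sorted(members)]
        heights = np.sort(rng.uniform(0.02, 0.12, size=len(tips) - 1))
        roots.extend(_coalesce(tips, heights, rng, prefix=f"cf{cf}_"))
    heights = np.sort(rng.uniform(0.40, 1.00, size=len(roots) - 1))
    root = _coalesce(roots, heights, rng, prefix="anc")[0]

    total = 0.0
    for n in root.walk():
        if n is root:
            continue
        parent = _parent_of(root, n)
        n.length = parent.height - n.height
        total += n.length
    for n in root.walk():
        if n is not root:
            n.length /= total
    return root, cf_assignment


def _parent_of(root: _Node, node: _Node) -> _Node:
    for n in root.walk():
        if node in n.children:
            return n
    raise ValueError("node not in tree")


# ---------------------------------------------------------------------------
# core evolution
# ---------------------------------------------------------------------------

def simulate_core_evolution(root: _Node, params: SimParams, rng=None,
                            forced_tracts=None):
    """Evolve core sequences down the clonal tree.

    Returns ``(seqs, mutation_sites, recomb_tracts)`` where ``seqs`` maps
    strain id -> uint8 array. ``forced_tracts`` is an optional list of
    ``(tip_strain, start, end)`` imports added deterministically on top of
    the Poisson events (used by benchmarks that need controlled tracts).
    """
    if rng is None:
        rng = spawn_rng(params.seed, "core")
    L = params.core_length
    branches = [n for n in root.walk() if n is not root]
    all_strains = root.tips

    # pass 1: recombination events on branches
    for n in branches:
        n.events = []
        k = rng.poisson(params.rho_rel * params.theta_site * L * n.length)
        for _ in range(k):
            start = int(rng.integers(L))
            tlen = int(rng.geometric(1.0 / params.mean_tract))
            n.events.append((start, min(start + tlen, L)))
    if forced_tracts:
        by_tip = {n.name: n for n in branches if not n.children}
        for tip, s, e in forced_tracts:
            by_tip[tip].events.append((int(s), int(e)))

    events_flat = [(n.tips, s, e) for n in branches for s, e in n.events]

    # pass 2: clonal mutations, kept identifiable under tract masking
    used: set[int] = set()
    for n in branches:
        n.mutations = []
        k = rng.poisson(params.theta_site * L * n.length)
        for _ in range(k):
            for _try in range(10_000):
                pos = int(rng.integers(L))
                if pos in used:
                    continue
                masked = frozenset()
                for tips, s, e in events_flat:
                    if s <= pos < e:
                        masked = masked | tips
                if n.tips <= masked or (all_strains - n.tips) <= masked:
                    continue
                break
            else:
                raise RuntimeError("could not place an identifiable mutation; "
                                   "recombination coverage too dense")
            used.add(pos)
            n.mutations.append(pos)

    # pass 3: apply down the tree
    nu = params.donor_divergence
    root_seq = _random_seq(L, params.gc_core, rng)
    seqs: dict[str, np.ndarray] = {}
    mutation_sites: list[MutationSite] = []
    recomb_tracts: list[RecombTract] = []

    def descend(node: _Node, seq: np.ndarray):
        if node is not root:
            seq = seq.copy()
            for pos in node.mutations:
                seq[pos] = (seq[pos] + rng.integers(1, 4)) % 4
                mutation_sites.append(MutationSite(node.tips, pos))
            for s, e in node.events:
                tlen = e - s
                k = int(rng.binomial(tlen, nu)) if nu > 0 else 0
                sub_pos = []
                if k:
                    sub_pos = sorted(int(x) for x in rng.choice(tlen, size=k, replace=False) + s)
                    for p in sub_pos:
                        seq[p] = (seq[p] + rng.integers(1, 4)) % 4
                recomb_tracts.append(RecombTract(node.tips, s, e, k, tuple(sub_pos)))
        if node.children:
            for c in node.children:
                descend(c, seq)
        else:
            seqs[node.name] = seq
    descend(root, root_seq)
    return seqs, mutation_sites, recomb_tracts


def _random_seq(length: int, gc: float, rng) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


# ---------------------------------------------------------------------------
# accessory content
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Family:
    family_id: str
    hotspot: int            # index into hotspot loci; -1 for plasmid families
    length: int
    strains: frozenset[str]
    cog: str
    strand: str


def simulate_accessory_content(params: SimParams, root: _Node, rng=None):
    """Assign accessory families to strains at island hotspots.

    Families are gained on random tree lineages (biased toward tips, giving
    many strain-specific genes and an open pangenome) and concentrated at
    ``island_hotspots`` core loci.
    """
    if rng is None:
        rng = spawn_rng(params.seed, "accessory")
    L = params.core_length
    lo, hi = int(0.1 * L), int(0.9 * L)
    loci = np.sort(rng.choice(np.arange(lo, hi, 1000), size=params.island_hotspots,
                              replace=False)).astype(int)
    branches = [n for n in root.walk() if n is not root]
    tips = [n for n in branches if not n.children]
    families: list[_Family] = []
    for i in range(params.n_accessory_families):
        node = tips[rng.integers(len(tips))] if rng.random() < 0.6 \
            else branches[rng.integers(len(branches))]
        strains = node.tips
        if strains == root.tips:  # accessory must be a proper subset
            strains = strains - {sorted(strains)[rng.integers(len(strains))]}
        families.append(_Family(
            family_id=f"ACC{i + 1:04d}",
            hotspot=int(rng.integers(params.island_hotspots)),
            length=int(rng.integers(150, 500)) * 3,
            strains=frozenset(strains),
            cog=COG_LETTERS[rng.integers(len(COG_LETTERS))],
            strand="+" if rng.random() < 0.5 else "-",
        ))
    return list(map(int, loci)), families


# ---------------------------------------------------------------------------
# full population
# ---------------------------------------------------------------------------

def simulate_population(params: SimParams, forced_tracts=None):
    """Run the full generator.

    Returns ``(genomes, truth, ortholog_matrix, alignment_blocks)``:
    per-strain :class:`GenomeRecord` objects, the ground-truth tables, the
    gene-family presence/absence matrix, and the true core alignment.
    """
    from .pangenome import OrthologMatrix

    tree_rng = spawn_rng(params.seed, "tree")
    root, cf_assignment = sample_clonal_tree(params, tree_rng)
    core_rng = spawn_rng(params.seed, "core")
    seqs, mutation_sites, recomb_tracts = simulate_core_evolution(
        root, params, core_rng, forced_tracts=forced_tracts)
    acc_rng = spawn_rng(params.seed, "accessory")
    loci, families = simulate_accessory_content(params, root, acc_rng)
    gene_rng = spawn_rng(params.seed, "genes")
    strains = sorted(seqs)
    L = params.core_length

    # core genes on the core coordinate system, avoiding hotspot cut points
    spacing = L // params.n_core_genes
    core_genes: list[tuple[str, int, int, str, str]] = []
    for i in range(params.n_core_genes):
        glen = 3 * int(gene_rng.integers(params.min_gene_length // 3,
                                         max(spacing - 60, params.min_gene_length + 3) // 3))
        start = i * spacing + int(gene_rng.integers(0, max(spacing - glen, 1)))
        end = min(start + glen, L)
        strand = "+" if gene_rng.random() < 0.5 else "-"
        cog = COG_LETTERS[int(gene_rng.integers(len(COG_LETTERS)))]
        if any(start < h < end for h in loci):
            continue  # a gene may not straddle an island insertion point
        core_genes.append((f"CORE{i + 1:04d}", start, end, strand, cog))

    fam_seqs = {f.family_id: _random_seq(f.length, params.gc_accessory, gene_rng)
                for f in families}

    genomes: list[GenomeRecord] = []
    accessory_gains: list[tuple[str, str, int]] = []
    presence: dict[str, dict[str, bool]] = {}
    members: dict[str, list[tuple[str, str]]] = {}
    plasmid_families: list[_Family] = []

    for s in strains:
        chrom_parts: list[np.ndarray] = []
        genes: list[GeneModel] = []
        offset = 0  # accumulated island length inserted before the cursor
        prev = 0
        island_content = {
            h: [f for f in families if f.hotspot == h and s in f.strains]
            for h in range(len(loci))
        }
        for h, locus in enumerate(loci):
            chrom_parts.append(seqs[s][prev:locus])
            isl_start = locus + offset
            cursor = isl_start
            for f in island_content[h]:
                chrom_parts.append(fam_seqs[f.family_id])
                genes.append(GeneModel(f"{s}_{f.family_id}", f"{s}_chr", cursor,
                                       cursor + f.length, f.strand, f.cog,
                                       "accessory island protein"))
                accessory_gains.append((s, f.family_id, int(locus)))
                cursor += f.length
            offset = cursor - locus
            prev = locus
        chrom_parts.append(seqs[s][prev:])
        chrom = decode(np.concatenate(chrom_parts))

        shift = np.zeros(len(loci) + 1, dtype=int)
        acc = 0
        for h, locus in enumerate(loci):
            acc += sum(f.length for f in island_content[h])
            shift[h + 1] = acc

        def genome_coord(c: int) -> int:
            return c + int(shift[np.searchsorted(loci, c, side="right")])

        for fam, start, end, strand, cog in core_genes:
            genes.append(GeneModel(f"{s}_{fam}", f"{s}_chr", genome_coord(start),
                                   genome_coord(start) + (end - start), strand, cog,
                                   "core protein"))
        replicons = [(f"{s}_chr", chrom, "chromosome")]

        plasmid_draw = spawn_rng(params.seed, "plasmid", s)
        if plasmid_draw.random() < params.plasmid_rate:
            plen = int(plasmid_draw.integers(15_000, 40_000))
            pseq = decode(_random_seq(plen, 0.50, plasmid_draw))
            n_pg = int(plasmid_draw.integers(5, 15))
            for j in range(n_pg):
                gl = 3 * int(plasmid_draw.integers(100, 400))
                gs = int(j * plen / n_pg)
                ge = min(gs + gl, plen)
                if ge - gs < 3:
                    continue
                fam = _Family(f"PLS_{s}_{j + 1:02d}", -1, ge - gs, frozenset([s]),
                              COG_LETTERS[int(plasmid_draw.integers(len(COG_LETTERS)))],
                              "+")
                plasmid_families.append(fam)
                genes.append(GeneModel(f"{s}_{fam.family_id}", f"{s}_pls1", gs, ge,
                                       "+", fam.cog, "plasmid protein"))
                accessory_gains.append((s, fam.family_id, -1))
            replicons.append((f"{s}_pls1", pseq, "plasmid"))

        genes.sort(key=lambda g: (g.replicon_id, g.start))
        genomes.append(GenomeRecord(s, replicons, genes))

    # ortholog matrix
    fam_ids, pres_rows, anchors = [], [], {}
    gene_index = {(g.strain_id, gm.gene_id): gm for g in genomes for gm in g.genes}
    for fam, *_ in core_genes:
        fam_ids.append(fam)
        pres_rows.append({s: True for s in strains})
        members[fam] = [(s, f"{s}_{fam}") for s in strains]
    for f in families + plasmid_families:
        fam_ids.append(f.family_id)
        pres_rows.append({s: s in f.strains for s in strains})
        members[f.family_id] = [(s, f"{s}_{f.family_id}") for s in sorted(f.strains)]
    import pandas as pd
    pres = pd.DataFrame(pres_rows, index=fam_ids).astype(bool)[strains]
    for fam in fam_ids:
        s0, gid0 = members[fam][0]
        anchors[fam] = (s0, gene_index[(s0, gid0)])
    matrix = OrthologMatrix(pres, anchors=anchors, gene_members=members)

    # true alignment blocks: core segments between hotspots, gap-free
    blocks: list[AlignmentBlock] = []
    bounds = [0] + list(loci) + [L]
    island_len = {s: {} for s in strains}
    for s in strains:
        for h in range(len(loci)):
            island_len[s][h] = sum(f.length for f in families
                                   if f.hotspot == h and s in f.strains)
    for b in range(len(bounds) - 1):
        seg_s, seg_e = bounds[b], bounds[b + 1]
        rows = []
        for s in strains:
            off = sum(island_len[s][h] for h in range(b))
            rows.append(BlockRow(s, f"{s}_chr", seg_s + off, seg_e + off, "+",
                                 decode(seqs[s][seg_s:seg_e])))
        blocks.append(AlignmentBlock(b, rows))

    truth = SimTruth(
        clonal_tree_newick=root.newick(),
        cf_assignment=cf_assignment,
        mutation_sites=mutation_sites,
        recomb_tracts=recomb_tracts,
        accessory_gains=accessory_gains,
        hotspot_loci=list(map(int, loci)),
    )
    return genomes, truth, matrix, blocks
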