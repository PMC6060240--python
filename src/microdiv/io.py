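"""Readers and writers for the external formats the pipeline touches.

Internal convention: every coordinate is 0-based half-open on the forward
strand. XMFA and GFF3 are 1-based inclusive on disk; the readers and writers
convert. Readers reject malformed input instead of silently repairing it.

Formats
-------
FASTA             genome and gene sequences (via Biopython's parser)
XMFA (Mauve)      whole-genome multiple alignments in locally collinear blocks
show-coords table MUMmer pairwise match coordinates (``show-coords -rcl`` style)
GFF3 / TSV        gene models with an optional single-letter COG category
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

IUPAC = set("ACGTUNRYSWKMBDHV")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene on a replicon; ``start``/``end`` are 0-based half-open."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    cog_category: str | None = None
    product: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A strain's replicons (chromosome plus optional plasmids) and genes."""

    strain_id: str
    replicons: list[tuple[str, str, str]]  # (replicon_id, sequence, kind)
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self):
        ids = [r[0] for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.strain_id}: duplicate replicon ids")
        lens = {r[0]: len(r[1]) for r in self.replicons}
        for rid, seq, kind in self.replicons:
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"{self.strain_id}/{rid}: non-ACGTN characters {sorted(bad)}")
            if kind not in ("chromosome", "plasmid"):
                raise ValueError(f"{self.strain_id}/{rid}: unknown replicon kind {kind!r}")
        for g in self.genes:
            if g.replicon_id not in lens:
                raise ValueError(f"gene {g.gene_id}: unknown replicon {g.replicon_id}")
            if g.end > lens[g.replicon_id]:
                raise ValueError(f"gene {g.gene_id}: extends past replicon end")

    def sequence(self, replicon_id: str) -> str:
        for rid, seq, _ in self.replicons:
            if rid == replicon_id:
                return seq
        raise KeyError(replicon_id)

    @property
    def chromosome(self) -> str:
        for rid, seq, kind in self.replicons:
            if kind == "chromosome":
                return seq
        raise ValueError(f"{self.strain_id}: no chromosome")

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq, _ in self.replicons)


@dataclass(frozen=True)
class BlockRow:
    strain_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    seq: str  # gapped

    @property
    def ungapped_length(self) -> int:
        return len(self.seq) - self.seq.count("-")


@dataclass
class AlignmentBlock:
    """One locally collinear block; all rows share the gapped length."""

    block_id: int
    rows: list[BlockRow]

    def __post_init__(self):
        lens = {len(r.seq) for r in self.rows}
        if len(lens) > 1:
            raise ValueError(f"block {self.block_id}: ragged rows (gapped lengths {sorted(lens)})")
        for r in self.rows:
            if r.ungapped_length != r.end - r.start:
                raise ValueError(
                    f"block {self.block_id}, {r.strain_id}: ungapped length "
                    f"{r.ungapped_length} != interval span {r.end - r.start}"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0].seq) if self.rows else 0

    def strains(self) -> set[str]:
        return {r.strain_id for r in self.rows}

    def row(self, strain_id: str) -> BlockRow:
        for r in self.rows:
            if r.strain_id == strain_id:
                return r
        raise KeyError(strain_id)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)``; uppercases and maps U->T.

    Raises on an empty file and on any character outside the IUPAC
    nucleotide alphabet, naming the offending position.
    """
    records = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            seq = seq.upper().replace("U", "T")
            bad = set(seq) - IUPAC
            if bad:
                pos = min(seq.index(b) for b in bad)
                raise ValueError(
                    f"{path}: record {title.split()[0]!r} has non-IUPAC "
                    f"character {seq[pos]!r} at position {pos}"
                )
            records.append((title.split()[0], seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# XMFA (Mauve dialect)
# ---------------------------------------------------------------------------

_XMFA_HEADER = re.compile(r"^>\s*(\d+):(\d+)-(\d+)\s+([+-])(?:\s+(.*))?$")


def read_xmfa(path, strain_names: Sequence[str] | None = None) -> list[AlignmentBlock]:
    """Parse a Mauve-dialect XMFA file into :class:`AlignmentBlock` objects.

    Record headers are ``>seqnum:start-end ± comment`` with 1-based inclusive
    coordinates; ``=`` ends a block. ``#Sequence<n>File`` comments map seqnum
    to strain names unless *strain_names* overrides them. The optional header
    comment carries ``strain_id/replicon_id`` when written by this package.
    """
    seq_files: dict[int, str] = {}
    blocks: list[AlignmentBlock] = []
    rows: list[BlockRow] = []
    cur: tuple | None = None
    chunks: list[str] = []

    def name_for(num: int) -> str:
        if strain_names is not None:
            return strain_names[num - 1]
        if num in seq_files:
            return Path(seq_files[num]).name.rsplit(".", 1)[0]
        return str(num)

    def flush_record():
        nonlocal cur, chunks
        if cur is None:
            return
        num, start, end, strand, comment = cur
        seq = "".join(chunks).upper()
        if comment and "/" in comment:
            sid, rid = comment.split("/", 1)
        else:
            sid, rid = name_for(num), comment or name_for(num)
        # XMFA is 1-based inclusive -> 0-based half-open
        rows.append(BlockRow(sid, rid, start - 1, end, strand, seq))
        cur, chunks = None, []

    def flush_block():
        nonlocal rows
        flush_record()
        if rows:
            try:
                blocks.append(AlignmentBlock(len(blocks), rows))
            except ValueError as exc:
                raise ValueError(f"{path}: {exc}") from None
            rows = []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#Sequence(\d+)File\s+(.*)", line)
                if m:
                    seq_files[int(m.group(1))] = m.group(2).strip()
                continue
            if line.startswith("="):
                flush_block()
            elif line.startswith(">"):
                flush_record()
                m = _XMFA_HEADER.match(line)
                if not m:
                    raise ValueError(f"{path}: unparseable XMFA header {line!r}")
                num, start, end = int(m.group(1)), int(m.group(2)), int(m.group(3))
                cur = (num, start, end, m.group(4), (m.group(5) or "").strip())
            else:
                if cur is None:
                    raise ValueError(f"{path}: sequence data outside a record: {line!r}")
                chunks.append(line)
    flush_block()
    if not blocks:
        raise ValueError(f"{path}: no alignment blocks")
    return blocks


def write_xmfa(blocks: Sequence[AlignmentBlock], path, strain_order: Sequence[str] | None = None) -> None:
    """Write blocks in the Mauve XMFA dialect (1-based inclusive on disk)."""
    if strain_order is None:
        strain_order = sorted({r.strain_id for b in blocks for r in b.rows})
    index = {s: i + 1 for i, s in enumerate(strain_order)}
    with open(path, "w") as fh:
        fh.write("#FormatVersion Mauve1\n")
        for s in strain_order:
            fh.write(f"#Sequence{index[s]}File\t{s}.fa\n")
        for b in blocks:
            for r in b.rows:
                fh.write(f"> {index[r.strain_id]}:{r.start + 1}-{r.end} {r.strand} "
                         f"{r.strain_id}/{r.replicon_id}\n")
                for i in range(0, len(r.seq), 80):
                    fh.write(r.seq[i:i + 80] + "\n")
            fh.write("=\n")


# ---------------------------------------------------------------------------
# MUMmer show-coords tables
# ---------------------------------------------------------------------------

def read_coords(path) -> list["FragmentMatch"]:
    """Parse a ``show-coords -rcl``-style table into FragmentMatch objects.

    Columns: S1 E1 S2 E2 LEN1 LEN2 %IDY ... ref_tag qry_tag (1-based
    inclusive; S2>E2 marks a reverse-orientation match). Header/separator
    lines (``=``, ``/``, ``NUCMER``, column captions, ``|`` separators) are
    skipped.
    """
    from .compare import FragmentMatch  # deferred: avoids an import cycle

    out = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.replace("|", " ").strip()
            if not line or line[0] in "=/[" or line[0].isalpha():
                continue
            parts = line.split()
            if len(parts) < 9:
                raise ValueError(f"{path}:{ln}: expected >=9 columns, got {len(parts)}")
            s1, e1, s2, e2 = (int(x) for x in parts[:4])
            idy = float(parts[6])
            ref_tag, qry_tag = parts[-2], parts[-1]
            if s1 > e1:
                raise ValueError(f"{path}:{ln}: reversed reference interval {s1}>{e1}")
            orientation = "+"
            if s2 > e2:
                orientation = "-"
                s2, e2 = e2, s2
            out.append(FragmentMatch(
                ref_id=ref_tag, qry_id=qry_tag,
                ref_interval=(s1 - 1, e1), qry_interval=(s2 - 1, e2),
                orientation=orientation, identity=idy,
            ))
    if not out:
        raise ValueError(f"{path}: no coordinate rows")
    return out


def write_coords(frags, path) -> None:
    """Write FragmentMatch objects back to a show-coords-style table."""
    with open(path, "w") as fh:
        fh.write("NUCMER\n\n    [S1]     [E1]  |     [S2]     [E2]  |  [LEN 1]  [LEN 2]  |  [% IDY]  | [TAGS]\n")
        fh.write("=" * 90 + "\n")
        for f in frags:
            (rs, re_), (qs, qe) = f.ref_interval, f.qry_interval
            if f.orientation == "-":
                s2, e2 = qe, qs + 1
            else:
                s2, e2 = qs + 1, qe
            fh.write(f"{rs + 1:8d} {re_:8d}  | {s2:8d} {e2:8d}  | "
                     f"{re_ - rs:8d} {qe - qs:8d}  | {f.identity:8.2f}  | "
                     f"{f.ref_id}\t{f.qry_id}\n")


# ---------------------------------------------------------------------------
# gene tables (GFF3 subset and TSV dialect)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["gene_id", "replicon_id", "start", "end", "strand", "cog_category", "product"]


def read_gene_table(path) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive) or this package's TSV.

    The TSV dialect has a header line with columns
    ``gene_id replicon_id start end strand cog_category product`` and is
    already 0-based half-open. GFF3 attributes ``ID``, ``cog_category`` and
    ``product`` are honoured.
    """
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("gene_id\t"):
        return _read_gene_tsv(path)
    return _read_gff3(path)


def _read_gene_tsv(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected TSV columns {header}")
        for ln, line in enumerate(fh, 2):
            if not line.strip():
                continue
            vals = line.rstrip("\n").split("\t")
            gid, rid, start, end, strand, cog, product = vals
            try:
                genes.append(GeneModel(gid, rid, int(start), int(end), strand,
                                       cog or None, product))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    if not genes:
        raise ValueError(f"{path}: no gene rows")
    return genes


def _read_gff3(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns")
            seqid, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype not in ("gene", "CDS"):
                continue
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            s, e = int(start), int(end)
            if e < s:
                raise ValueError(f"{path}:{ln}: end < start")
            try:
                genes.append(GeneModel(
                    attr.get("ID", f"{seqid}_{ln}"), seqid, s - 1, e, strand,
                    attr.get("cog_category") or None, attr.get("product", ""),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    if not genes:
        raise ValueError(f"{path}: no gene features")
    return genes


def write_gene_table(genes: Sequence[GeneModel], path, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_TSV_COLUMNS) + "\n")
            for g in genes:
                fh.write(f"{g.gene_id}\t{g.replicon_id}\t{g.start}\t{g.end}\t"
                         f"{g.strand}\t{g.cog_category or ''}\t{g.product}\n")
    elif fmt == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in genes:
                attrs = f"ID={g.gene_id}"
                if g.cog_category:
                    attrs += f";cog_category={g.cog_category}"
                if g.product:
                    attrs += f";product={g.product}"
                fh.write(f"{g.replicon_id}\tmicrodiv\tgene\t{g.start + 1}\t{g.end}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")
    else:
        raise ValueError(f"unknown gene-table format {fmt!r}")
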