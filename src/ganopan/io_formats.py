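"""Readers and writers for the external file formats the pipeline consumes.

All genomic coordinates are converted at the boundary to a single internal
convention: 0-based, half-open intervals.  GFF3 (1-based inclusive) and VCF
(1-based, padding-base anchored) exist only inside this module; everything
downstream operates on the in-memory domain types defined here.

Formats handled
---------------
* OrthoFinder ``Orthogroups.tsv`` dialect (tab-separated; comma-space
  separated gene lists per genome column).
* GFF3 gene models (gene/mRNA/exon/CDS), via :mod:`gffutils`.
* VCF 4.x structural-variant calls with ``SVTYPE``/``END``/``SVLEN`` info
  keys (SyRI-export style), via :mod:`pysam`.
* Expression count matrix TSV plus a sample sheet TSV.
* Flat gene-to-GO association TSV.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
import pysam

__all__ = [
    "FormatError",
    "OrthogroupTable",
    "Transcript",
    "GeneModel",
    "SvRecord",
    "read_orthogroups",
    "write_orthogroups",
    "read_gff3",
    "write_gff3",
    "read_sv_vcf",
    "write_sv_vcf",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_counts",
    "write_counts",
    "read_go_associations",
    "write_go_associations",
]

logger = logging.getLogger("ganopan")

_TOOL_TAG = "ganopan 0.1.0"
TISSUES = ("mycelium", "fruiting_body")

SV_TYPES = ("INS", "DEL", "DUP", "INV", "TRA")
_GO_RE = re.compile(r"^GO:\d{7}$")


class FormatError(ValueError):
    """A file violated the expected dialect or an input invariant."""


# ---------------------------------------------------------------------------
# Orthogroups
# ---------------------------------------------------------------------------

@dataclass
class OrthogroupTable:
    """One orthogroup: a family of genes keyed by genome.

    ``members`` maps every genome in the table (identically across families)
    to a possibly-empty list of gene identifiers.
    """

    family_id: str
    members: dict[str, list[str]]

    @property
    def occupancy(self) -> int:
        return sum(1 for genes in self.members.values() if genes)

    @property
    def genes(self) -> list[str]:
        return [g for genes in self.members.values() for g in genes]


def read_orthogroups(path: str | Path) -> list[OrthogroupTable]:
    """Parse an OrthoFinder-style ``Orthogroups.tsv``.

    The first non-comment line is the header (family-ID column followed by
    genome names); each subsequent row is one family with comma-separated
    gene lists per genome cell.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty orthogroup table")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header needs a family column plus >=1 genome")
    genomes = header[1:]
    if len(set(genomes)) != len(genomes):
        raise FormatError(f"{path}: duplicate genome column")

    tables: list[OrthogroupTable] = []
    seen_families: set[str] = set()
    gene_owner: dict[str, str] = {}
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(header):
            cells += [""] * (len(header) - len(cells))
        fam = cells[0].strip()
        if fam in seen_families:
            raise FormatError(f"{path}: duplicate family ID {fam!r}")
        seen_families.add(fam)
        members: dict[str, list[str]] = {}
        for genome, cell in zip(genomes, cells[1:]):
            genes = [g.strip() for g in cell.split(",") if g.strip()]
            for g in genes:
                if g in gene_owner:
                    raise FormatError(
                        f"{path}: gene {g!r} appears in families "
                        f"{gene_owner[g]!r} and {fam!r}"
                    )
                gene_owner[g] = fam
            members[genome] = genes
        tables.append(OrthogroupTable(fam, members))
    return tables


def write_orthogroups(tables: Sequence[OrthogroupTable], path: str | Path) -> None:
    path = Path(path)
    if not tables:
        raise FormatError("nothing to write: empty orthogroup collection")
    genomes = list(tables[0].members)
    with path.open("w") as fh:
        fh.write(f"# {_TOOL_TAG} orthogroups genomes={len(genomes)}\n")
        fh.write("Orthogroup\t" + "\t".join(genomes) + "\n")
        for t in tables:
            cells = [", ".join(t.members.get(g, [])) for g in genomes]
            fh.write(t.family_id + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]        # 0-based half-open, sorted
    cds: list[tuple[int, int]]          # 0-based half-open, sorted

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class GeneModel:
    """A gene with its transcript structure on internal coordinates.

    ``start``/``end`` span the whole gene body (0-based half-open).  The
    promoter and downstream windows are derived, strand-aware intervals
    immediately outside the gene span.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def promoter(self, length: int) -> tuple[int, int]:
        """Window of ``length`` bp upstream of the transcription start."""
        if self.strand == "+":
            return (max(0, self.start - length), self.start)
        return (self.end, self.end + length)

    def downstream(self, length: int) -> tuple[int, int]:
        """Window of ``length`` bp past the transcription end."""
        if self.strand == "+":
            return (self.end, self.end + length)
        return (max(0, self.start - length), self.start)


def _validate_gene(gene: GeneModel) -> None:
    if gene.strand not in ("+", "-"):
        raise FormatError(f"gene {gene.gene_id}: unknown strand {gene.strand!r}")
    if not (0 <= gene.start < gene.end):
        raise FormatError(f"gene {gene.gene_id}: invalid span {gene.span}")
    for tr in gene.transcripts:
        for name, ivals in (("exon", tr.exons), ("CDS", tr.cds)):
            prev_end = None
            for s, e in ivals:
                if not (gene.start <= s < e <= gene.end):
                    raise FormatError(
                        f"gene {gene.gene_id}: {name} [{s},{e}) outside gene span"
                    )
                if prev_end is not None and s < prev_end:
                    raise FormatError(
                        f"gene {gene.gene_id}: overlapping/unsorted {name} intervals"
                    )
                prev_end = e
        # every CDS base must fall inside an exon
        for cs, ce in tr.cds:
            if not any(es <= cs and ce <= ee for es, ee in tr.exons):
                raise FormatError(
                    f"gene {gene.gene_id}: CDS [{cs},{ce}) not contained in an exon"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 (gene/mRNA/exon/CDS features)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        gene = GeneModel(
            gene_id=gf.id,
            chrom=gf.seqid,
            strand=gf.strand,
            start=gf.start - 1,
            end=gf.end,
        )
        for mf in db.children(gf, featuretype="mRNA", order_by="start"):
            exons = sorted(
                (f.start - 1, f.end)
                for f in db.children(mf, featuretype="exon", order_by="start")
            )
            cds = sorted(
                (f.start - 1, f.end)
                for f in db.children(mf, featuretype="CDS", order_by="start")
            )
            if not exons and cds:
                exons = list(cds)
            gene.transcripts.append(Transcript(mf.id, exons, cds))
        _validate_gene(gene)
        genes.append(gene)
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"# {_TOOL_TAG} gene-models\n")
        for gene in genes:
            row = [gene.chrom, "ganopan", "gene", str(gene.start + 1),
                   str(gene.end), ".", gene.strand, ".", f"ID={gene.gene_id}"]
            fh.write("\t".join(row) + "\n")
            for tr in gene.transcripts:
                fh.write("\t".join([
                    gene.chrom, "ganopan", "mRNA", str(gene.start + 1),
                    str(gene.end), ".", gene.strand, ".",
                    f"ID={tr.transcript_id};Parent={gene.gene_id}",
                ]) + "\n")
                for s, e in tr.exons:
                    fh.write("\t".join([
                        gene.chrom, "ganopan", "exon", str(s + 1), str(e),
                        ".", gene.strand, ".", f"Parent={tr.transcript_id}",
                    ]) + "\n")
                # phase tracks the running coding length in transcription order
                cds_order = tr.cds if gene.strand == "+" else tr.cds[::-1]
                cum = 0
                phases = {}
                for s, e in cds_order:
                    phases[(s, e)] = (3 - cum % 3) % 3
                    cum += e - s
                for s, e in tr.cds:
                    fh.write("\t".join([
                        gene.chrom, "ganopan", "CDS", str(s + 1), str(e),
                        ".", gene.strand, str(phases[(s, e)]),
                        f"Parent={tr.transcript_id}",
                    ]) + "\n")


# ---------------------------------------------------------------------------
# Structural variants (VCF)
# ---------------------------------------------------------------------------

@dataclass
class SvRecord:
    """A structural variant on internal coordinates.

    DEL/DUP/INV occupy ``[start, end)``; INS and TRA breakends are
    zero-length anchors (``start == end``) at the affected base.
    ``length`` is the event size (inserted/deleted/spanned bases).
    """

    sv_id: str
    chrom: str
    svtype: str
    start: int
    end: int
    length: int

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise FormatError(f"SV {self.sv_id}: unsupported SVTYPE {self.svtype!r}")
        if self.length <= 0:
            raise FormatError(f"SV {self.sv_id}: non-positive length {self.length}")
        if self.svtype in ("INS", "TRA"):
            if self.start != self.end:
                raise FormatError(f"SV {self.sv_id}: {self.svtype} must be a point anchor")
        elif self.end <= self.start:
            raise FormatError(f"SV {self.sv_id}: empty span [{self.start},{self.end})")

    @property
    def is_point(self) -> bool:
        return self.start == self.end


def read_sv_vcf(path: str | Path) -> list[SvRecord]:
    """Read SV calls from a VCF with SVTYPE/END/SVLEN info keys.

    Records without a recognizable SVTYPE are skipped with a warning (SyRI
    exports carry heterogeneous annotation records); ``END < POS`` is a
    hard format error.
    """
    records: list[SvRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for i, rec in enumerate(vf):
            svtype = rec.info.get("SVTYPE")
            if isinstance(svtype, tuple):
                svtype = svtype[0]
            if svtype == "BND":
                svtype = "TRA"
            if svtype not in SV_TYPES:
                skipped += 1
                logger.warning("skipping record %s at %s:%s (SVTYPE=%r)",
                               rec.id, rec.chrom, rec.pos, svtype)
                continue
            svid = rec.id or f"sv{i}"
            try:
                svlen = rec.info.get("SVLEN")
            except ValueError:  # SVLEN absent from the header
                svlen = None
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            if svtype in ("INS", "TRA"):
                anchor = rec.pos - 1
                length = abs(int(svlen)) if svlen is not None else 1
                records.append(SvRecord(svid, rec.chrom, svtype, anchor, anchor, length))
            else:
                # rec.stop carries INFO/END (1-based inclusive == half-open end)
                start, end = rec.pos, rec.stop
                if end < start:
                    raise FormatError(f"{path}: SV {svid}: END < POS")
                records.append(SvRecord(svid, rec.chrom, svtype, start, end, end - start))
    if skipped:
        logger.warning("%d VCF records skipped (missing/unsupported SVTYPE)", skipped)
    return records


def write_sv_vcf(records: Sequence[SvRecord], path: str | Path,
                 contigs: Sequence[str] | None = None) -> None:
    path = Path(path)
    if contigs is None:
        contigs = sorted({r.chrom for r in records})
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={_TOOL_TAG} sv-writer\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            if r.is_point:
                pos = r.start + 1
                info = f"SVTYPE={r.svtype};SVLEN={r.length}"
            else:
                pos = r.start
                info = f"SVTYPE={r.svtype};END={r.end};SVLEN={r.length}"
            alt = f"<{r.svtype}>"
            fh.write(f"{r.chrom}\t{pos}\t{r.sv_id}\tN\t{alt}\t.\tPASS\t{info}\n")


# ---------------------------------------------------------------------------
# Sample sheet & counts
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, genome_id, tissue, replicate."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["sample_id", "genome_id", "tissue", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    bad = sorted(set(df["tissue"]) - set(TISSUES))
    if bad:
        raise FormatError(f"{path}: unknown tissue values {bad}")
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise FormatError(f"{path}: replicate numbers must be positive")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id")
    if df.duplicated(subset=["genome_id", "tissue", "replicate"]).any():
        raise FormatError(f"{path}: duplicate (genome, tissue, replicate) triple")
    return df.set_index("sample_id", drop=False)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# {_TOOL_TAG} sample-sheet\n")
        sheet.to_csv(fh, sep="\t", index=False)


def read_counts(path: str | Path, sheet: pd.DataFrame) -> pd.DataFrame:
    """Gene x sample raw count matrix, validated against the sample sheet.

    Genes with all-zero rows are retained; their IDs are listed in
    ``df.attrs["all_zero_genes"]``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    unknown = [c for c in df.columns if c not in set(sheet["sample_id"])]
    if unknown:
        raise FormatError(f"{path}: samples not in sheet: {unknown}")
    absent = [s for s in sheet["sample_id"] if s not in df.columns]
    if absent:
        raise FormatError(f"{path}: sheet samples missing from matrix: {absent}")
    vals = df.to_numpy()
    if (vals < 0).any():
        raise FormatError(f"{path}: negative counts")
    if (vals != vals.astype(int)).any():
        raise FormatError(f"{path}: non-integer counts")
    df = df.astype(int)
    zero_rows = df.index[(df == 0).all(axis=1)].tolist()
    if zero_rows:
        logger.warning("%d genes unexpressed everywhere", len(zero_rows))
    df.attrs["all_zero_genes"] = zero_rows
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# {_TOOL_TAG} counts genes={counts.shape[0]} samples={counts.shape[1]}\n")
        counts.to_csv(fh, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# GO associations
# ---------------------------------------------------------------------------

def read_go_associations(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV: gene_id <tab> semicolon-separated GO IDs."""
    out: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, ln in enumerate(fh, 1):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            gene = parts[0].strip()
            raw = parts[1] if len(parts) > 1 else ""
            terms = set()
            for t in raw.split(";"):
                t = t.strip()
                if not t:
                    continue
                if not _GO_RE.match(t):
                    raise FormatError(f"{path}:{lineno}: malformed GO ID {t!r}")
                terms.add(t)
            out.setdefault(gene, set()).update(terms)
    return out


def write_go_associations(assoc: dict[str, set[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# {_TOOL_TAG} go-associations\n")
        for gene in sorted(assoc):
            fh.write(f"{gene}\t{';'.join(sorted(assoc[gene]))}\n")
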