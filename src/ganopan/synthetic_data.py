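"""Synthetic study generator with planted ground truth.

Generates an internally consistent set of inputs emulating a 15-genome
fungal pan-genome study built around five expression-profiled cultivars:

* an orthogroup table over all genomes, with families planted in the four
  occupancy categories at configurable (study-scaled) proportions;
* GFF3 gene models for the five cultivar genomes, laid out non-overlapping
  with intronless and two-exon structures;
* a VCF of structural variants planted on the anchor cultivar so that the
  intended (region, impact) class of each is known;
* a negative-binomial count matrix (two tissues, four replicates each per
  genome) with category-graded means and, optionally, expression effects
  coupled to the planted SVs — including one mandatory 440 bp promoter
  insertion on a highly-expressed anchor gene, mirroring the kind of
  regulatory variant such studies are designed to surface;
* a flat gene-to-GO association table with annotation coverage decreasing
  from core to private genes.

Every emitted record is traceable to the :class:`GroundTruth`, and a fixed
seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .io_formats import GeneModel, OrthogroupTable, SvRecord, Transcript, TISSUES
from .pangenome import CATEGORIES, CategoryScheme

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_pangenome",
    "simulate_genome_annotation",
    "simulate_counts",
    "simulate_go_associations",
    "simulate_study",
    "write_study",
]

# Full-study family composition (core, softcore, dispensable, private) and
# singleton-gene tally; scaled by `scale` for desk-sized runs.
BASE_CATEGORY_COUNTS = {"core": 5917, "softcore": 1937, "dispensable": 5058,
                        "private": 575}
BASE_SINGLETONS = 368


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults mirror the emulated study design."""

    n_genomes: int = 15
    xzl_genomes: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S6")
    anchor_genome: str = "S3"
    scale: float = 0.05
    category_counts: dict[str, int] | None = None
    n_singletons: int | None = None
    multi_copy_fraction: float = 0.05
    # expression
    base_mean: float = 25.0
    category_multipliers: tuple[float, float, float, float] = (8.0, 4.0, 2.0, 1.0)
    gene_mean_sigma: float = 0.5          # log-normal spread of family means
    dispersion: float = 0.05              # NB: var = m + dispersion * m^2
    n_replicates: int = 4
    library_jitter: float = 0.2
    # structural variants
    sv_rate: float = 0.2
    effect_fraction: float = 0.5
    planted_log2fc: float = 2.0
    couple_sv_effects: bool = True
    promoter_len: int = 1000
    downstream_len: int = 500
    n_chromosomes: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < len(self.xzl_genomes):
            raise ValueError("n_genomes smaller than the cultivar panel")
        if self.anchor_genome not in self.xzl_genomes:
            raise ValueError("anchor genome must be one of the cultivars")
        m = self.category_multipliers
        if not all(a > b for a, b in zip(m, m[1:])):
            raise ValueError("category multipliers must be strictly decreasing")
        if self.dispersion < 0 or self.sv_rate < 0 or self.scale <= 0:
            raise ValueError("negative rate/scale parameter")

    def resolved_category_counts(self) -> dict[str, int]:
        if self.category_counts is not None:
            return dict(self.category_counts)
        return {c: max(1, round(v * self.scale))
                for c, v in BASE_CATEGORY_COUNTS.items()}

    def resolved_singletons(self) -> int:
        if self.n_singletons is not None:
            return self.n_singletons
        return round(BASE_SINGLETONS * self.scale)

    @property
    def genomes(self) -> list[str]:
        extra = [f"G{i:02d}" for i in range(6, 6 + self.n_genomes - len(self.xzl_genomes))]
        return list(self.xzl_genomes) + extra


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage."""

    seed: int
    family_category: dict[str, str] = field(default_factory=dict)
    family_occupancy: dict[str, int] = field(default_factory=dict)
    family_mean: dict[str, float] = field(default_factory=dict)
    gene_family: dict[str, str] = field(default_factory=dict)
    gene_genome: dict[str, str] = field(default_factory=dict)
    gene_mean: dict[str, float] = field(default_factory=dict)
    singleton_genes: list[str] = field(default_factory=list)
    homolog_groups: dict[str, dict[str, str]] = field(default_factory=dict)
    sv_affected_groups: set[str] = field(default_factory=set)
    effect_groups: set[str] = field(default_factory=set)
    planted_impacts: list[dict[str, str]] = field(default_factory=list)

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for c in self.family_category.values():
            out[c] += 1
        return out

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["sv_affected_groups"] = sorted(self.sv_affected_groups)
        d["effect_groups"] = sorted(self.effect_groups)
        return json.dumps(d, indent=1, sort_keys=True)


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    truth: GroundTruth
    tables: list[OrthogroupTable]
    gene_models: dict[str, list[GeneModel]]     # cultivar genome -> genes
    svs: list[SvRecord]                         # on the anchor genome
    counts: pd.DataFrame
    sheet: pd.DataFrame
    go_associations: dict[str, set[str]]


# ---------------------------------------------------------------------------
# Stage 1: orthogroup table
# ---------------------------------------------------------------------------

def _category_bands(scheme: CategoryScheme) -> dict[str, tuple[int, int]]:
    n = scheme.n_genomes
    return {
        "core": (n, n),
        "softcore": (scheme.softcore_min, n - 1),
        "dispensable": (scheme.dispensable_min, scheme.softcore_min - 1),
        "private": (1, 1),
    }


def simulate_pangenome(config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[list[OrthogroupTable], GroundTruth]:
    """Plant families with occupancies drawn uniformly from category bands."""
    rng = rng or np.random.default_rng(config.seed)
    truth = GroundTruth(seed=config.seed)
    genomes = config.genomes
    scheme = CategoryScheme.default(config.n_genomes)
    bands = _category_bands(scheme)
    counts = config.resolved_category_counts()
    for cat, n_fam in counts.items():
        lo, hi = bands[cat]
        if n_fam > 0 and lo > hi:
            raise ValueError(f"category {cat!r} band empty for N={config.n_genomes}")

    gene_counter = {g: 0 for g in genomes}

    def new_gene(genome: str) -> str:
        gene_counter[genome] += 1
        return f"{genome}_g{gene_counter[genome]:05d}"

    mult = dict(zip(CATEGORIES, config.category_multipliers))
    tables: list[OrthogroupTable] = []
    fam_idx = 0
    for cat in CATEGORIES:
        lo, hi = bands[cat]
        for _ in range(counts[cat]):
            fam_idx += 1
            fam = f"OG{fam_idx:06d}"
            occ = int(rng.integers(lo, hi + 1))
            subset = [genomes[i] for i in sorted(rng.choice(len(genomes), occ,
                                                            replace=False))]
            members = {g: [] for g in genomes}
            for g in subset:
                members[g].append(new_gene(g))
            if occ > 1 and rng.random() < config.multi_copy_fraction:
                extra = subset[int(rng.integers(len(subset)))]
                members[extra].append(new_gene(extra))
            mean = config.base_mean * mult[cat] * float(
                rng.lognormal(0.0, config.gene_mean_sigma))
            truth.family_category[fam] = cat
            truth.family_occupancy[fam] = occ
            truth.family_mean[fam] = mean
            for g, genes in members.items():
                for gid in genes:
                    truth.gene_family[gid] = fam
                    truth.gene_genome[gid] = g
                    truth.gene_mean[gid] = mean
            tables.append(OrthogroupTable(fam, members))

    for _ in range(config.resolved_singletons()):
        genome = config.xzl_genomes[int(rng.integers(len(config.xzl_genomes)))]
        gid = new_gene(genome)
        truth.singleton_genes.append(gid)
        truth.gene_genome[gid] = genome
        truth.gene_mean[gid] = config.base_mean * mult["private"] * float(
            rng.lognormal(0.0, config.gene_mean_sigma))

    truth.homolog_groups = {
        t.family_id: {g: t.members[g][0] for g in config.xzl_genomes}
        for t in tables
        if all(len(t.members[g]) == 1 for g in config.xzl_genomes)
    }
    return tables, truth


# ---------------------------------------------------------------------------
# Stage 2: gene models and structural variants
# ---------------------------------------------------------------------------

# planted SV kinds: (svtype, target region, intended impact)
_SV_MENU = (
    ("del_inframe", "DEL", "cds", "moderate"),
    ("del_frameshift", "DEL", "cds", "high"),
    ("ins_inframe", "INS", "cds", "moderate"),
    ("ins_frameshift", "INS", "cds", "high"),
    ("del_intron", "DEL", "intron", "modifier"),
    ("ins_promoter", "INS", "promoter_upstream", "modifier"),
    ("del_promoter", "DEL", "promoter_upstream", "modifier"),
    ("dup_frameshift", "DUP", "cds", "high"),
    ("inv_span", "INV", "cds", "moderate"),
    ("tra_cds", "TRA", "cds", "high"),
)


def _make_gene(gene_id: str, chrom: str, start: int, strand: str,
               rng: np.random.Generator) -> GeneModel:
    utr = 60
    cds_len = 3 * int(rng.integers(150, 500))
    two_exon = rng.random() < 0.5
    if two_exon:
        intron_len = int(rng.integers(80, 300))
        split = 3 * int(rng.integers(30, cds_len // 3 - 30))
        e1 = (start, start + utr + split)
        c1 = (start + utr, start + utr + split)
        i0 = e1[1]
        e2 = (i0 + intron_len, i0 + intron_len + (cds_len - split) + utr)
        c2 = (i0 + intron_len, i0 + intron_len + (cds_len - split))
        exons, cds = [e1, e2], [c1, c2]
        end = e2[1]
    else:
        end = start + utr + cds_len + utr
        exons = [(start, end)]
        cds = [(start + utr, start + utr + cds_len)]
    return GeneModel(gene_id, chrom, strand, start, end,
                     [Transcript(f"{gene_id}.t1", exons, cds)])


def _plant_sv(kind: str, sv_id: str, gene: GeneModel,
              config: SimulationConfig,
              rng: np.random.Generator) -> SvRecord | None:
    """Place an SV of the given kind relative to one gene; None if the gene
    structure cannot host it."""
    tr = gene.transcripts[0]
    cs, ce = tr.cds[0]
    interior = (cs + 6, ce - 6)         # avoid terminal codons
    if interior[1] - interior[0] < 30:
        return None
    chrom = gene.chrom
    prom = gene.promoter(config.promoter_len)
    if kind == "del_inframe":
        s = interior[0] + 3
        return SvRecord(sv_id, chrom, "DEL", s, s + 9, 9)
    if kind == "del_frameshift":
        s = interior[0] + 3
        return SvRecord(sv_id, chrom, "DEL", s, s + 7, 7)
    if kind == "ins_inframe":
        p = interior[0] + 9
        return SvRecord(sv_id, chrom, "INS", p, p, 6)
    if kind == "ins_frameshift":
        p = interior[0] + 9
        return SvRecord(sv_id, chrom, "INS", p, p, 5)
    if kind == "del_intron":
        if len(tr.exons) < 2:
            return None
        i0, i1 = tr.exons[0][1], tr.exons[1][0]
        if i1 - i0 < 20:
            return None
        return SvRecord(sv_id, chrom, "DEL", i0 + 5, i1 - 5, (i1 - 5) - (i0 + 5))
    if kind == "ins_promoter":
        p = prom[0] + int(rng.integers(50, config.promoter_len - 50))
        return SvRecord(sv_id, chrom, "INS", p, p, 440)
    if kind == "del_promoter":
        s = prom[0] + 100
        return SvRecord(sv_id, chrom, "DEL", s, s + 150, 150)
    if kind == "dup_frameshift":
        s = interior[0] + 3
        return SvRecord(sv_id, chrom, "DUP", s, s + 8, 8)
    if kind == "inv_span":
        return SvRecord(sv_id, chrom, "INV", gene.start - 50, gene.end + 50,
                        gene.end - gene.start + 100)
    if kind == "tra_cds":
        p = interior[0] + 12
        return SvRecord(sv_id, chrom, "TRA", p, p, 1)
    raise ValueError(f"unknown SV kind {kind!r}")


def simulate_genome_annotation(config: SimulationConfig, truth: GroundTruth,
                               rng: np.random.Generator | None = None,
                               ) -> tuple[dict[str, list[GeneModel]], list[SvRecord]]:
    """Lay out cultivar gene models and plant SVs on the anchor genome."""
    rng = rng or np.random.default_rng(config.seed + 1)
    gap = config.promoter_len + config.downstream_len + 700
    gene_models: dict[str, list[GeneModel]] = {}
    for genome in config.xzl_genomes:
        genes = sorted(g for g, gn in truth.gene_genome.items() if gn == genome)
        if len(genes) < 10:
            raise ValueError("need at least 10 genes per genome")
        chroms = [f"chr{i + 1:02d}" for i in range(config.n_chromosomes)]
        cursors = {c: config.promoter_len + 500 for c in chroms}
        models = []
        for i, gid in enumerate(genes):
            chrom = chroms[i % len(chroms)]
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _make_gene(gid, chrom, cursors[chrom], strand, rng)
            cursors[chrom] = gene.end + gap
            models.append(gene)
        gene_models[genome] = models

    svs: list[SvRecord] = []
    anchor_models = {g.gene_id: g for g in gene_models[config.anchor_genome]}
    # the flagship planted variant: a 440 bp promoter insertion on a
    # single-copy homolog of the anchor genome, with an expression effect
    msh4_gene = None
    for fam in sorted(truth.homolog_groups):
        cand = truth.homolog_groups[fam][config.anchor_genome]
        if cand in anchor_models:
            msh4_gene = cand
            break
    sv_idx = 0
    if msh4_gene is not None:
        sv = _plant_sv("ins_promoter", "sv_msh4_ins", anchor_models[msh4_gene],
                       config, rng)
        if sv is not None:
            svs.append(sv)
            truth.planted_impacts.append({
                "sv_id": sv.sv_id, "gene_id": msh4_gene,
                "region": "promoter_upstream", "impact": "modifier",
                "kind": "ins_promoter",
            })
            fam = truth.gene_family[msh4_gene]
            truth.sv_affected_groups.add(fam)
            truth.effect_groups.add(fam)

    for gid in sorted(anchor_models):
        if gid == msh4_gene:
            continue
        if rng.random() >= config.sv_rate:
            continue
        kind, svtype, region, impact = _SV_MENU[int(rng.integers(len(_SV_MENU)))]
        sv_idx += 1
        sv = _plant_sv(kind, f"sv{sv_idx:05d}", anchor_models[gid], config, rng)
        if sv is None:
            continue
        svs.append(sv)
        truth.planted_impacts.append({
            "sv_id": sv.sv_id, "gene_id": gid,
            "region": region, "impact": impact, "kind": kind,
        })
        fam = truth.gene_family.get(gid)
        if fam is not None and fam in truth.homolog_groups:
            truth.sv_affected_groups.add(fam)

    # plant expression effects, coupled to SVs or not
    pool = sorted(truth.sv_affected_groups - truth.effect_groups)
    n_effects = round(config.effect_fraction * len(pool))
    if config.couple_sv_effects:
        chosen = [pool[i] for i in sorted(rng.choice(len(pool), n_effects,
                                                     replace=False))] if pool else []
    else:
        allg = sorted(set(truth.homolog_groups) - truth.effect_groups)
        chosen = [allg[i] for i in sorted(rng.choice(len(allg), n_effects,
                                                     replace=False))] if allg else []
    truth.effect_groups.update(chosen)
    for fam in truth.effect_groups:
        gid = truth.homolog_groups[fam][config.anchor_genome]
        truth.gene_mean[gid] = truth.gene_mean[gid] * 2.0 ** config.planted_log2fc
    return gene_models, svs


# ---------------------------------------------------------------------------
# Stage 3: counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(config: SimulationConfig, truth: GroundTruth,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB-distributed counts for every cultivar gene across 2 tissues x
    n_replicates per genome; genes score 0 in samples of other genomes."""
    rng = rng or np.random.default_rng(config.seed + 2)
    xzl = config.xzl_genomes
    genes = sorted(g for g, gn in truth.gene_genome.items() if gn in xzl)
    rows_by_genome = {g: np.array([truth.gene_genome[x] == g for x in genes])
                      for g in xzl}
    means = np.array([truth.gene_mean[g] for g in genes])

    sheet_rows, columns, data = [], [], []
    for genome in xzl:
        for tissue in TISSUES:
            for rep in range(1, config.n_replicates + 1):
                sample = f"{genome}_{tissue}_{rep}"
                lib = 1.0 + config.library_jitter * (2 * rng.random() - 1)
                col = np.zeros(len(genes), dtype=int)
                mask = rows_by_genome[genome]
                col[mask] = _nb_draw(rng, means[mask] * lib, config.dispersion)
                data.append(col)
                columns.append(sample)
                sheet_rows.append({"sample_id": sample, "genome_id": genome,
                                   "tissue": tissue, "replicate": rep})
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    sheet = pd.DataFrame(sheet_rows).set_index("sample_id", drop=False)
    return counts, sheet


# ---------------------------------------------------------------------------
# Stage 4: GO associations
# ---------------------------------------------------------------------------

_ANNOT_PROB = {"core": 0.9, "softcore": 0.8, "dispensable": 0.6,
               "private": 0.4, None: 0.4}


def simulate_go_associations(config: SimulationConfig, truth: GroundTruth,
                             rng: np.random.Generator | None = None,
                             n_terms: int = 60) -> dict[str, set[str]]:
    """Flat gene->GO sets with coverage graded by pan-genome category."""
    rng = rng or np.random.default_rng(config.seed + 3)
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    out: dict[str, set[str]] = {}
    for gid in sorted(g for g, gn in truth.gene_genome.items()
                      if gn in config.xzl_genomes):
        fam = truth.gene_family.get(gid)
        cat = truth.family_category.get(fam) if fam else None
        if rng.random() >= _ANNOT_PROB[cat]:
            continue
        k = 1 + int(rng.poisson(1.5))
        chosen = rng.choice(n_terms, min(k, n_terms), replace=False)
        out[gid] = {terms[i] for i in chosen}
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Run all generator stages off a single seeded random stream."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    tables, truth = simulate_pangenome(config, rng)
    gene_models, svs = simulate_genome_annotation(config, truth, rng)
    counts, sheet = simulate_counts(config, truth, rng)
    go = simulate_go_associations(config, truth, rng)
    return SimulatedStudy(config, truth, tables, gene_models, svs,
                          counts, sheet, go)


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Emit every input file in the dialect the readers expect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["orthogroups"] = outdir / "orthogroups.tsv"
    io_formats.write_orthogroups(study.tables, paths["orthogroups"])
    for genome, models in study.gene_models.items():
        p = outdir / f"{genome}.gff3"
        io_formats.write_gff3(models, p)
        paths[f"gff3_{genome}"] = p
    contigs = [f"chr{i + 1:02d}" for i in range(study.config.n_chromosomes)]
    paths["svs"] = outdir / "svs.vcf"
    io_formats.write_sv_vcf(study.svs, paths["svs"], contigs=contigs)
    paths["counts"] = outdir / "counts.tsv"
    io_formats.write_counts(study.counts, paths["counts"])
    paths["samples"] = outdir / "samples.tsv"
    io_formats.write_sample_sheet(study.sheet, paths["samples"])
    paths["go"] = outdir / "go_associations.tsv"
    io_formats.write_go_associations(study.go_associations, paths["go"])
    paths["truth"] = outdir / "ground_truth.json"
    paths["truth"].write_text(study.truth.to_json())
    return paths
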