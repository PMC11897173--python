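"""End-to-end orchestration of the analysis stages from one config.

Stages communicate through files in the run directory, so a re-run can
skip any stage whose inputs (config, seed and upstream outputs) are
byte-identical to what the manifest records.  Stage order:

    simulate? -> classify -> rarefy -> shared -> sv-annotate
              -> de -> profile -> associate -> enrich -> report
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Callable

import pandas as pd
import yaml

from . import enrichment, expression, io_formats, pangenome, sv_impact
from .synthetic_data import SimulationConfig, simulate_study, write_study

__all__ = ["DEFAULT_CONFIG", "load_config", "run_all", "render_report"]

logger = logging.getLogger("ganopan")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": True,
    "simulation": {},                 # SimulationConfig overrides
    "inputs": {},                     # used when simulate is false
    "xzl_genomes": ["S1", "S2", "S3", "S4", "S6"],
    "anchor_genome": "S3",
    "rarefy": {"n_perm": 100},
    "impact": {"promoter_len": 1000, "downstream_len": 500},
    "de": {"tissues": ["mycelium", "fruiting_body"], "pseudo_count": 0.5},
    "profile": {"tissue": "mycelium", "breadth_threshold": 1.0},
    "enrich": {"alpha": 0.05},
}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    for k, v in (overrides or {}).items():
        if v is not None:
            cfg[k] = v
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()


class _Run:
    """Mutable run state: directory, manifest, skip bookkeeping."""

    def __init__(self, cfg: dict, outdir: Path):
        self.cfg = cfg
        self.outdir = outdir
        self.manifest_path = outdir / "manifest.json"
        self.prev = {}
        if self.manifest_path.exists():
            self.prev = json.loads(self.manifest_path.read_text()).get("stages", {})
        self.manifest = {
            "tool": "ganopan 0.1.0",
            "config_hash": _config_hash(cfg),
            "seed": cfg["seed"],
            "stages": {},
        }

    def path(self, rel: str) -> Path:
        p = self.outdir / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    def stage(self, name: str, inputs: list[str],
              fn: Callable[[], list[str]]) -> list[str]:
        """Run (or skip) one stage; returns the stage's output rel-paths."""
        in_hash = hashlib.sha256(json.dumps({
            "config": self.manifest["config_hash"],
            "seed": self.cfg["seed"],
            "inputs": {r: _sha256(self.outdir / r) for r in sorted(inputs)},
        }, sort_keys=True).encode()).hexdigest()
        prev = self.prev.get(name)
        if prev and prev.get("inputs_hash") == in_hash:
            ok = all((self.outdir / r).exists()
                     and _sha256(self.outdir / r) == h
                     for r, h in prev["outputs"].items())
            if ok:
                logger.info("stage %s: up to date, skipped", name)
                self.manifest["stages"][name] = dict(prev, skipped=True)
                return list(prev["outputs"])
        t0 = time.perf_counter()
        try:
            outputs = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        self.manifest["stages"][name] = {
            "inputs_hash": in_hash,
            "outputs": {r: _sha256(self.outdir / r) for r in outputs},
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "skipped": False,
        }
        logger.info("stage %s: done (%d outputs)", name, len(outputs))
        return outputs

    def finish(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1,
                                                 sort_keys=True))


def _input_files(cfg: dict, run: _Run) -> dict[str, str]:
    """Relative paths of the pipeline inputs inside the run directory."""
    if cfg["simulate"]:
        base = "inputs"
        rel = {
            "orthogroups": f"{base}/orthogroups.tsv",
            "svs": f"{base}/svs.vcf",
            "counts": f"{base}/counts.tsv",
            "samples": f"{base}/samples.tsv",
            "go": f"{base}/go_associations.tsv",
        }
        for g in cfg["xzl_genomes"]:
            rel[f"gff3_{g}"] = f"{base}/{g}.gff3"
        return rel
    rel = {}
    for key, value in cfg["inputs"].items():
        if key == "gff3":
            for g, p in value.items():
                rel[f"gff3_{g}"] = p
        else:
            rel[key] = value
    return rel


def run_all(cfg: dict, outdir: str | Path) -> Path:
    """Execute every stage in dependency order; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(cfg, outdir)
    seed = int(cfg["seed"])
    anchor = cfg["anchor_genome"]
    xzl = list(cfg["xzl_genomes"])

    # -- inputs ------------------------------------------------------------
    if cfg["simulate"]:
        def do_simulate() -> list[str]:
            sim_cfg = SimulationConfig(seed=seed, **cfg["simulation"])
            study = simulate_study(sim_cfg)
            paths = write_study(study, outdir / "inputs")
            return [str(p.relative_to(outdir)) for p in paths.values()]
        run.stage("simulate", [], do_simulate)
    files = _input_files(cfg, run)
    for key, rel in files.items():
        if not (outdir / rel).exists():
            stage = "sv-annotate" if key.startswith(("gff3", "svs")) else key
            raise FileNotFoundError(
                f"stage {stage!r}: required input {rel!r} missing")

    tables = io_formats.read_orthogroups(outdir / files["orthogroups"])
    matrix = pangenome.build_matrix(tables)

    # -- pan-genome --------------------------------------------------------
    def do_classify() -> list[str]:
        cls = pangenome.classify(matrix)
        frame = cls.to_frame(matrix)
        with run.path("classification.tsv").open("w") as fh:
            fh.write(f"# ganopan 0.1.0 classify n_genomes={matrix.n_genomes}\n")
            frame.to_csv(fh, sep="\t", index=False)
        comp = {"counts": cls.counts,
                "percentages": {k: round(v, 2) for k, v in cls.percentages.items()},
                "n_families": cls.n_families}
        run.path("composition.json").write_text(json.dumps(comp, indent=1))
        return ["classification.tsv", "composition.json"]
    run.stage("classify", [files["orthogroups"]], do_classify)

    def do_rarefy() -> list[str]:
        res = pangenome.rarefy(matrix, n_perm=int(cfg["rarefy"]["n_perm"]),
                               seed=seed)
        with run.path("rarefaction.tsv").open("w") as fh:
            fh.write(f"# ganopan 0.1.0 rarefy n_perm={res.n_permutations} seed={seed}\n")
            res.to_frame().to_csv(fh, sep="\t", index=False)
        return ["rarefaction.tsv"]
    run.stage("rarefy", [files["orthogroups"]], do_rarefy)

    def do_shared() -> list[str]:
        subset = [g for g in xzl if g in matrix.genomes][:6]
        counts = pangenome.shared_counts(matrix, subset)
        with run.path("shared_patterns.tsv").open("w") as fh:
            fh.write(f"# ganopan 0.1.0 shared subset={','.join(subset)}\n")
            fh.write("pattern\tcount\n")
            for pat in sorted(counts):
                fh.write(f"{pat}\t{counts[pat]}\n")
        return ["shared_patterns.tsv"]
    run.stage("shared", [files["orthogroups"]], do_shared)

    # -- SV impact ---------------------------------------------------------
    impact_cfg = sv_impact.ImpactConfig(
        promoter_len=int(cfg["impact"]["promoter_len"]),
        downstream_len=int(cfg["impact"]["downstream_len"]))

    def do_annotate() -> list[str]:
        genes = io_formats.read_gff3(outdir / files[f"gff3_{anchor}"])
        svs = io_formats.read_sv_vcf(outdir / files["svs"])
        anns = sv_impact.annotate(genes, svs, impact_cfg)
        sv_impact.write_impact_annotations(anns, run.path("sv_impacts.tsv"),
                                           impact_cfg)
        sv_counts, gene_counts = sv_impact.summarize_impacts(anns)
        run.path("sv_summary.json").write_text(json.dumps(
            {"sv_counts": sv_counts, "gene_counts": gene_counts}, indent=1))
        return ["sv_impacts.tsv", "sv_summary.json"]
    run.stage("sv-annotate",
              [files[f"gff3_{anchor}"], files["svs"]], do_annotate)

    # -- expression --------------------------------------------------------
    sheet = io_formats.read_sample_sheet(outdir / files["samples"])
    counts = io_formats.read_counts(outdir / files["counts"], sheet)
    study = expression.ExpressionStudy(counts, sheet)
    homologs = expression.single_copy_homologs(tables, xzl)
    hom_counts = expression.homolog_counts(counts, homologs, sheet)
    hom_study = expression.ExpressionStudy(hom_counts, sheet)

    def do_de() -> list[str]:
        outputs = []
        flags = pd.Series(False, index=hom_counts.index)
        for other in (g for g in xzl if g != anchor):
            for tissue in cfg["de"]["tissues"]:
                a = hom_study.samples_for(genome=anchor, tissue=tissue)
                b = hom_study.samples_for(genome=other, tissue=tissue)
                res = expression.call_de(hom_study, a, b,
                                         pseudo_count=cfg["de"]["pseudo_count"])
                rel = f"de/{anchor}_vs_{other}_{tissue}.tsv"
                with run.path(rel).open("w") as fh:
                    fh.write(f"# ganopan 0.1.0 de {anchor} vs {other} {tissue}\n")
                    res.to_csv(fh, sep="\t", index_label="group_id")
                outputs.append(rel)
                flags |= res["is_deg"]
        with run.path("deg_flags.tsv").open("w") as fh:
            fh.write(f"# ganopan 0.1.0 deg-flags anchor={anchor}\n")
            flags.rename("is_deg").to_csv(fh, sep="\t", index_label="group_id")
        return outputs + ["deg_flags.tsv"]
    run.stage("de", [files["counts"], files["samples"], files["orthogroups"]],
              do_de)

    def do_profile() -> list[str]:
        cls = pangenome.classify(matrix)
        gene_cat = {}
        for t in tables:
            cat = cls.categories[t.family_id]
            for g in t.genes:
                gene_cat[g] = cat
        tissue = cfg["profile"]["tissue"]
        prof, kw_stat, kw_p = expression.category_expression_profile(
            study, gene_cat, tissue)
        with run.path("category_profile.tsv").open("w") as fh:
            fh.write(f"# ganopan 0.1.0 profile tissue={tissue} "
                     f"kw_stat={kw_stat:.4g} kw_p={kw_p:.4g}\n")
            prof.to_csv(fh, sep="\t", index=False)
        breadth = expression.expression_breadth(
            study, homologs, tissue,
            threshold=float(cfg["profile"]["breadth_threshold"]))
        fam_cat = {f: cls.categories[f] for f in breadth.index}
        bf = pd.DataFrame({"breadth": breadth,
                           "category": pd.Series(fam_cat)})
        with run.path("expression_breadth.tsv").open("w") as fh:
            fh.write(f"# ganopan 0.1.0 breadth tissue={tissue}\n")
            bf.to_csv(fh, sep="\t", index_label="group_id")
        run.path("profile_stats.json").write_text(json.dumps(
            {"kw_statistic": kw_stat, "kw_p_value": kw_p, "tissue": tissue},
            indent=1))
        return ["category_profile.tsv", "expression_breadth.tsv",
                "profile_stats.json"]
    run.stage("profile", [files["counts"], files["samples"],
                          files["orthogroups"]], do_profile)

    def do_associate() -> list[str]:
        impacts = pd.read_csv(outdir / "sv_impacts.tsv", sep="\t", comment="#")
        genic = impacts[impacts["region"].isin(
            ["cds", "exon_noncoding", "intron", "promoter_upstream"])]
        affected_genes = set(genic["gene_id"])
        sv_flags = {fam: members[anchor] in affected_genes
                    for fam, members in homologs.items()}
        deg = pd.read_csv(outdir / "deg_flags.tsv", sep="\t", comment="#",
                          index_col=0)["is_deg"]
        deg_flags = {fam: bool(deg.get(fam, False)) for fam in homologs}
        res = expression.sv_deg_association(deg_flags, sv_flags)
        run.path("association.json").write_text(json.dumps({
            "table": res.table.tolist(),
            "n_groups": res.n,
            "deg_proportion_sv": res.deg_proportion_sv,
            "deg_proportion_no_sv": res.deg_proportion_no_sv,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "method": res.method,
        }, indent=1))
        return ["association.json"]
    run.stage("associate", ["sv_impacts.tsv", "deg_flags.tsv",
                            files["orthogroups"]], do_associate)

    def do_enrich() -> list[str]:
        assoc = io_formats.read_go_associations(outdir / files["go"])
        impacts = pd.read_csv(outdir / "sv_impacts.tsv", sep="\t", comment="#")
        anchor_genes = {g.gene_id for g in
                        io_formats.read_gff3(outdir / files[f"gff3_{anchor}"])}
        best: dict[str, int] = {}
        sev = {"modifier": 0, "low": 1, "moderate": 2, "high": 3}
        for _, row in impacts.iterrows():
            best[row["gene_id"]] = max(best.get(row["gene_id"], 0),
                                       sev[row["impact"]])
        high_genes = {g for g, s in best.items() if s == 3} & anchor_genes
        rel = "enrichment.tsv"
        if not high_genes or not any(g in assoc for g in high_genes):
            with run.path(rel).open("w") as fh:
                fh.write("# ganopan 0.1.0 enrich: no annotated high-impact genes\n")
            return [rel]
        df = enrichment.enrich(high_genes, anchor_genes, assoc,
                               alpha=float(cfg["enrich"]["alpha"]))
        with run.path(rel).open("w") as fh:
            fh.write(f"# ganopan 0.1.0 enrich alpha={cfg['enrich']['alpha']}\n")
            df.to_csv(fh, sep="\t", index=False)
        return [rel]
    run.stage("enrich", ["sv_impacts.tsv", files["go"],
                         files[f"gff3_{anchor}"]], do_enrich)

    def do_report() -> list[str]:
        summary = build_summary(outdir)
        run.path("report.json").write_text(json.dumps(summary, indent=1,
                                                      sort_keys=True))
        run.path("report.md").write_text(render_report(summary))
        return ["report.json", "report.md"]
    run.stage("report", ["composition.json", "rarefaction.tsv",
                         "sv_summary.json", "deg_flags.tsv",
                         "association.json", "enrichment.tsv"], do_report)

    run.finish()
    return outdir


def build_summary(outdir: Path) -> dict:
    """Collect stage outputs into one machine-readable summary."""
    comp = json.loads((outdir / "composition.json").read_text())
    rare = pd.read_csv(outdir / "rarefaction.tsv", sep="\t", comment="#")
    kmax = rare["k"].max()
    at_end = rare[rare["k"] == kmax]
    sv = json.loads((outdir / "sv_summary.json").read_text())
    deg = pd.read_csv(outdir / "deg_flags.tsv", sep="\t", comment="#",
                      index_col=0)["is_deg"]
    assoc = json.loads((outdir / "association.json").read_text())
    enr_rows = []
    enr_path = outdir / "enrichment.tsv"
    try:
        enr = pd.read_csv(enr_path, sep="\t", comment="#")
        enr_rows = enr.head(10).to_dict(orient="records")
    except pd.errors.EmptyDataError:
        pass
    return {
        "composition": comp,
        "rarefaction": {
            "n_genomes": int(kmax),
            "pan_final": float(at_end["pan"].mean()),
            "core_final": float(at_end["core"].mean()),
            "n_permutations": int(rare["permutation"].nunique()),
        },
        "sv_summary": sv,
        "de": {"n_groups": int(deg.size), "n_deg_groups": int(deg.sum())},
        "association": assoc,
        "enrichment_top": enr_rows,
    }


def render_report(summary: dict) -> str:
    """Markdown view of the JSON summary (every number comes from it)."""
    c = summary["composition"]
    lines = ["# Pan-genome run report", "", "## Family composition", "",
             "| category | families | % |", "|---|---|---|"]
    for cat in ("core", "softcore", "dispensable", "private"):
        lines.append(f"| {cat} | {c['counts'][cat]} | {c['percentages'][cat]} |")
    lines += ["", f"Total families: {c['n_families']}", ""]
    r = summary["rarefaction"]
    lines += ["## Rarefaction", "",
              f"At N={r['n_genomes']} genomes ({r['n_permutations']} orderings): "
              f"pan={r['pan_final']:g}, core={r['core_final']:g}", ""]
    s = summary["sv_summary"]
    lines += ["## SV impact", "", "| impact | SVs | genes |", "|---|---|---|"]
    for cat in ("high", "moderate", "low", "modifier"):
        lines.append(f"| {cat} | {s['sv_counts'][cat]} | {s['gene_counts'][cat]} |")
    d = summary["de"]
    lines += ["", "## Differential expression", "",
              f"{d['n_deg_groups']} of {d['n_groups']} homolog groups are DEGs "
              f"in at least one anchor-vs-other comparison.", ""]
    a = summary["association"]
    if a:
        lines += ["## SV-DEG association", "",
                  f"DEG proportion among SV-affected groups: "
                  f"{a['deg_proportion_sv']:.4g}; among others: "
                  f"{a['deg_proportion_no_sv']:.4g} "
                  f"({a['method']} p={a['p_value']:.3g}, "
                  f"statistic={a['statistic']:.4g}, n={a['n_groups']})", ""]
    else:
        lines += ["## SV-DEG association", "", "no DE analysis configured", ""]
    lines += ["## Top enrichment rows", ""]
    if summary["enrichment_top"]:
        lines += ["| term | k | K | p |", "|---|---|---|---|"]
        for row in summary["enrichment_top"]:
            lines.append(f"| {row['term_id']} | {row['study_hits']} | "
                         f"{row['population_hits']} | {row['p_value']:.3g} |")
    else:
        lines.append("no enrichment rows")
    lines.append("")
    return "\n".join(lines)
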