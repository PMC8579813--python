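"""End-to-end orchestration: simulate -> discover -> scan -> filter -> annotate -> overlay.

Every stage is a pure function of (inputs, config, seed); the run directory
collects each stage's outputs plus a machine-readable summary and an audit
log of the parameter values used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .expression_overlay import concordance_tsv, de_crosstab, load_expression, regulon_concordance
from .genome_io import (
    extract_upstream,
    read_genome,
    read_ortholog_table,
    training_regions,
    write_fasta,
    write_features_tsv,
    write_ortholog_table,
)
from .motif_discovery import Geometry, MotifSpec, discover
from .pwm_regulon import (
    build_pwm,
    consistency_filter,
    hits_to_tsv,
    logo_matrix_tsv,
    regulon_summary_tsv,
    scan_genomes,
    write_meme,
)
from .regulatory_annotation import (
    classify_mode,
    find_promoter,
    footprint_report,
    read_tss_table,
    utr_stats,
    write_tss_table,
)
from .synthetic_data import GeneratorConfig, gen_expression, gen_toy_genomes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All run parameters; file inputs or a simulate block."""

    outdir: str = "regufoot_run"
    seed: int = 0
    # inputs (either simulate=... or explicit paths)
    simulate: dict | None = None
    genomes: dict[str, dict[str, str]] = field(default_factory=dict)  # species -> {fasta, features}
    orthologs: str | None = None
    tss: str | None = None
    expression: str | None = None
    # analysis parameters
    motif_mode: str = "palindrome"
    width_range: tuple[int, int] = (20, 24)
    unit_range: tuple[int, int] = (7, 11)
    periods: tuple[int, ...] = (21, 32)
    spacer_range: tuple[int, int] = (20, 30)
    restarts: int = 20
    scan_window: int = 300
    min_intergenic: int = 50
    quorum_fraction: float = 0.5
    quorum_min: int = 2
    de_threshold: float = 2.0
    moderate_band: tuple[float, float] = (1.5, 2.0)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("width_range", "unit_range", "spacer_range", "moderate_band"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.periods = tuple(cfg.periods)
        return cfg

    def motif_spec(self) -> MotifSpec:
        return MotifSpec(
            mode=self.motif_mode,
            width_range=self.width_range,
            unit_range=self.unit_range,
            periods=self.periods,
            spacer_range=self.spacer_range,
        )


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the machine-readable summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setLevel(logging.INFO)
    logging.getLogger("regufoot").addHandler(fh)
    summary: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    try:
        _run_stages(config, out, summary)
    except Exception as exc:
        summary["error"] = str(exc)
        _write_summary(summary, out)
        raise
    finally:
        logging.getLogger("regufoot").removeHandler(fh)
    _write_summary(summary, out)
    return summary


def _write_summary(summary: dict, out: Path) -> None:
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True, default=str)


def _run_stages(config: RunConfig, out: Path, summary: dict) -> None:
    audit = {"parameters": {k: v for k, v in asdict(config).items()}}
    with open(out / "audit.json", "w") as f:
        json.dump(audit, f, indent=2, default=str)

    truth = None
    expression_df = None
    induction = None

    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        geometry = sim_kwargs.pop("geometry", None)
        if geometry is not None:
            geometry = Geometry(**geometry)
        gcfg = GeneratorConfig(
            seed=config.seed, motif=config.motif_spec(), geometry=geometry, **sim_kwargs
        )
        genomes, groups, tss_records, truth = gen_toy_genomes(gcfg)
        simdir = out / "simulated"
        simdir.mkdir(exist_ok=True)
        for sp, genome in genomes.items():
            write_fasta(genome, simdir / f"{sp}.fna")
            write_features_tsv(genome, simdir / f"{sp}.features.tsv")
        write_ortholog_table(groups, simdir / "orthologs.tsv")
        write_tss_table(tss_records, simdir / "tss.tsv")
        truth.sites_tsv(simdir / "truth_sites.tsv")
        truth.membership_tsv(simdir / "truth_membership.tsv")
        ref = sorted(genomes)[0]
        member_genes = {
            g.members[ref] for g in groups if g.group_id in truth.regulon_members and ref in g.members
        }
        all_genes = [g.members[ref] for g in groups if ref in g.members]
        expression_df, expr_truth = gen_expression(gcfg, {"TF": member_genes}, all_genes)
        expression_df.to_csv(simdir / "expression.tsv", sep="\t")
        induction = expr_truth.induction
        tss_map = {t.locus_tag: t for t in tss_records}
        summary["stages"]["simulate"] = {
            "n_species": len(genomes),
            "n_groups": len(groups),
            "n_target_operons": len(truth.regulon_members),
        }
    else:
        genomes = {
            sp: read_genome(paths["fasta"], paths["features"], species_id=sp)
            for sp, paths in config.genomes.items()
        }
        if config.orthologs is None:
            raise ValueError("config must provide an ortholog table or a simulate block")
        groups = read_ortholog_table(config.orthologs)
        tss_map = {t.locus_tag: t for t in read_tss_table(config.tss)} if config.tss else {}
        if config.expression:
            expression_df = load_expression(config.expression)
        summary["stages"]["load"] = {"n_species": len(genomes), "n_groups": len(groups)}

    # training set: target-operon upstream regions across species
    if truth is not None:
        target_groups = [g for g in groups if g.group_id in truth.regulon_members]
    else:
        target_groups = groups
    regions = training_regions(
        target_groups, genomes, min_len=config.min_intergenic, max_len=config.scan_window
    )
    summary["stages"]["training_set"] = {"n_regions": len(regions)}

    result = discover(regions, config.motif_spec(), restarts=config.restarts, seed=config.seed)
    summary["stages"]["discover"] = {
        "geometry": result.geometry.describe(),
        "consensus": result.consensus,
        "mean_information": result.mean_information,
        "low_confidence": result.low_confidence,
        "n_sites": len(result.sites),
    }

    site_seqs = [s.site_seq for s in result.sites]
    motif = build_pwm(site_seqs, geometry=result.geometry, tf_id="TF")
    write_meme(motif, out / "motif.meme")
    logo_matrix_tsv(motif, out / "motif_logo.tsv")
    summary["stages"]["pwm"] = {"threshold": motif.threshold, "n_training_sites": len(site_seqs)}

    hits = scan_genomes(motif, genomes, window=config.scan_window)
    hits_to_tsv(hits, out / "hits.tsv")
    regulon = consistency_filter(
        hits, groups, tf_id="TF", quorum_fraction=config.quorum_fraction, quorum_min=config.quorum_min
    )
    summary["stages"]["regulon"] = {
        "n_members": len(regulon.members),
        "unverified": regulon.unverified,
    }

    # mode classification + footprints for members with TSS
    ref = sorted(genomes)[0]
    group_by_id = {g.group_id: g for g in groups}
    mode_calls = []
    for m in regulon.members:
        locus = group_by_id[m.group_id].members.get(ref)
        if locus is None or locus not in tss_map or ref not in m.hits:
            continue
        try:
            region = extract_upstream(genomes[ref], locus, max_len=config.scan_window)
        except KeyError:
            continue
        promoter = find_promoter(region, tss_map[locus]) if region else None
        mode_calls.append((m.group_id, classify_mode(m.hits[ref], tss_map[locus], promoter)))
    regulon.mode = _aggregate_mode([c.call for _, c in mode_calls])
    regulon_summary_tsv(regulon, out / "regulon.tsv")
    with open(out / "mode_calls.tsv", "w") as f:
        f.write("group_id\tcall\tevidence\n")
        for gid, c in mode_calls:
            f.write(f"{gid}\t{c.call}\t{c.evidence}\n")
    summary["stages"]["annotate"] = {
        "n_mode_calls": len(mode_calls),
        "calls": {gid: c.call for gid, c in mode_calls},
        "regulon_mode": regulon.mode,
    }
    if tss_map:
        summary["stages"]["utr"] = utr_stats(list(tss_map.values()))

    # footprint report for the first regulon member
    if regulon.members:
        m = regulon.members[0]
        g = group_by_id[m.group_id]
        member_regions = {
            sp: extract_upstream(genomes[sp], locus, max_len=config.scan_window)
            for sp, locus in g.members.items()
            if sp in genomes and locus in genomes[sp]
        }
        member_hits = {sp: [h] for sp, h in m.hits.items()}
        with open(out / "footprint.txt", "w") as f:
            f.write(footprint_report(g, member_regions, hits=member_hits))

    # expression overlay
    if expression_df is not None:
        member_genes = set()
        for m in regulon.members:
            locus = group_by_id[m.group_id].members.get(ref)
            if locus:
                member_genes.add(locus)
        table = de_crosstab(
            expression_df,
            threshold=config.de_threshold,
            regulon_members=member_genes,
            moderate_band=config.moderate_band,
        )
        table.to_tsv(out / "de_crosstab.tsv")
        if induction is None:
            induction = {"TF": {expression_df.columns[0]}}
        reports = regulon_concordance(table, {"TF": member_genes}, induction)
        concordance_tsv(reports, out / "concordance.tsv")
        summary["stages"]["expression"] = {
            "union_upregulated": len(table.union_up),
            "concordance": {k: v.concordance for k, v in reports.items()},
        }
    else:
        logger.info("no expression matrix supplied; DE stage skipped")
        summary["stages"]["expression"] = "skipped (no expression input)"

    # recovery metrics against planted truth
    if truth is not None:
        predicted = regulon.member_ids()
        tp = len(predicted & truth.regulon_members)
        fp = len(predicted - truth.regulon_members)
        fn = len(truth.regulon_members - predicted)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        summary["stages"]["benchmark"] = {
            "precision": precision,
            "recall": recall,
            "tp": tp,
            "fp": fp,
            "fn": fn,
        }


def _aggregate_mode(calls: list[str]) -> str:
    informative = [c for c in calls if c in ("repressor", "activator")]
    if not informative:
        return "unknown"
    if all(c == informative[0] for c in informative):
        return informative[0]
    return "ambiguous"
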