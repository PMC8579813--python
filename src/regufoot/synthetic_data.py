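"""Ground-truthed synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a comparative study design over a clade of closely
related thermophilic genomes: orthologous upstream regions across k
pseudo-species descend from an ancestral region by independent per-base
resampling (no indels, so offsets stay comparable across species), with
planted regulator binding sites mutating at a lower rate than the
background -- the conservation signal phylogenetic footprinting exploits.
Toy genomes embed those regions upstream of placeholder ORFs; TSSs are
placed so planted sites realize prescribed repressor or activator
geometries; and expression matrices co-induce regulon members on their
cognate substrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (
    GeneFeature,
    GenomeRecord,
    OrthologGroup,
    UpstreamRegion,
    reverse_complement,
)
from .motif_discovery import BASES, Geometry, MotifSpec
from .regulatory_annotation import MINUS10_CONSENSUS, MINUS35_CONSENSUS, TSSRecord

STUDY_CONDITIONS = ("cellulose", "cellobiose", "glucose", "xylan", "xylose")


@dataclass
class GeneratorConfig:
    """Defaults mirror the emulated study design (clade of AT-rich genomes,
    five growth substrates, strong induction of regulon members)."""

    n_species: int = 8
    n_target_operons: int = 10
    n_decoy_genes: int = 200
    region_len: int = 300
    gc: float = 0.35  # thermophile-like AT-rich background
    divergence: float = 0.3  # per-base background resampling rate between species
    site_mutation_rate: float = 0.1  # per-base site mutation rate per species
    motif: MotifSpec = field(default_factory=MotifSpec)
    geometry: Geometry | None = None  # concrete planted geometry; default from motif spec
    consensus: str | None = None  # planted consensus (full span, spacer as background)
    effect_size: float = 3.0  # log2 induction of regulon members
    noise_sd: float = 0.3
    conditions: tuple[str, ...] = STUDY_CONDITIONS
    tss_median: int = 50
    repressor_fraction: float = 0.5
    orf_len: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must be in [0, 1]")
        for name in ("divergence", "site_mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")


@dataclass
class PlantedSite:
    species_id: str
    locus_tag: str
    position: int  # 0-based start within the region
    offset: int  # relative to translation start
    strand: str
    site_seq: str


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery without re-running the generator."""

    consensus: str
    geometry: Geometry
    sites: list[PlantedSite]
    regulon_members: set[str]  # target ortholog-group ids
    decoy_groups: set[str]
    induction: dict[str, set[str]] = field(default_factory=dict)  # regulon -> conditions
    expected_de: set[str] = field(default_factory=set)  # reference-species genes
    tss_geometry: dict[str, str] = field(default_factory=dict)  # group -> repressor|activator
    seed: int = 0

    def sites_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("species_id\tlocus_tag\tposition\toffset\tstrand\tsite_seq\n")
            for s in self.sites:
                fh.write(f"{s.species_id}\t{s.locus_tag}\t{s.position}\t{s.offset}\t{s.strand}\t{s.site_seq}\n")

    def membership_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("group_id\tis_target\ttss_geometry\n")
            for gid in sorted(self.regulon_members):
                fh.write(f"{gid}\ttrue\t{self.tss_geometry.get(gid, '')}\n")
            for gid in sorted(self.decoy_groups):
                fh.write(f"{gid}\tfalse\t\n")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def gen_background(length: int, gc: float, rng: np.random.Generator | int) -> str:
    """i.i.d. background sequence with P(G) = P(C) = gc/2."""
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    if length < 0:
        raise ValueError("length must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if length == 0:
        return ""
    codes = rng.choice(4, size=length, p=_base_probs(gc))
    return "".join(BASES[c] for c in codes)


def random_consensus(geometry: Geometry, gc: float, rng: np.random.Generator) -> str:
    """Random full-span consensus honoring the geometry's internal symmetry.

    Spacer positions are written as N and drawn fresh from background at
    planting time (a nonconserved linker).
    """
    probs = _base_probs(gc)

    def draw(n: int) -> str:
        return "".join(BASES[c] for c in rng.choice(4, size=n, p=probs))

    if geometry.mode == "palindrome":
        w = geometry.width
        half = draw(w // 2)
        mid = draw(1) if w % 2 else ""
        return half + mid + reverse_complement(half)
    if geometry.mode == "direct_repeat":
        unit = draw(geometry.unit)
        return unit + "N" * (geometry.period - geometry.unit) + unit
    unit = draw(geometry.unit)
    return unit + "N" * geometry.spacer + reverse_complement(unit)


def default_geometry(spec: MotifSpec) -> Geometry:
    """Midpoint-of-grid geometry used when none is pinned in the config."""
    if spec.mode == "palindrome":
        return Geometry("palindrome", width=spec.width_range[0])
    if spec.mode == "direct_repeat":
        return Geometry("direct_repeat", unit=spec.unit_range[0] + 1, period=spec.periods[0])
    return Geometry(
        "inverted_repeat_spaced",
        unit=spec.unit_range[0],
        spacer=(spec.spacer_range[0] + spec.spacer_range[1]) // 2,
    )


def _instantiate(consensus: str, gc: float, rng: np.random.Generator) -> str:
    """Replace spacer Ns with fresh background bases."""
    if "N" not in consensus:
        return consensus
    probs = _base_probs(gc)
    return "".join(
        BASES[rng.choice(4, p=probs)] if b == "N" else b for b in consensus
    )


def _mutate(seq: str, rate: float, gc: float, rng: np.random.Generator, resample: bool) -> str:
    """Per-base mutation: resample from background, or substitute to another base."""
    if rate <= 0.0:
        return seq
    probs = _base_probs(gc)
    out = list(seq)
    hit = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hit):
        if resample:
            out[i] = BASES[rng.choice(4, p=probs)]
        else:
            choices = [b for b in BASES if b != seq[i]]
            out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def gen_ortholog_regions(
    config: GeneratorConfig,
    site_positions: dict[str, tuple[int, str]] | None = None,
) -> tuple[dict[str, list[UpstreamRegion]], list[OrthologGroup], SyntheticTruth]:
    """Orthologous upstream regions with one conserved planted site per target.

    Each target operon gets an ancestral region carrying one instance of the
    consensus (spacer bases drawn fresh); per-species copies resample
    background bases at the divergence rate and mutate site bases at the
    (lower) site mutation rate, so sites are more conserved than background.
    Decoy genes get independent background in every species (orthologous in
    the table, but without a conserved site).

    ``site_positions`` optionally pins {group_id: (position, strand)}.
    """
    rng = np.random.default_rng(config.seed)
    geometry = config.geometry or default_geometry(config.motif)
    if geometry.span > config.region_len:
        raise ValueError("motif span exceeds region length")
    consensus = config.consensus or random_consensus(geometry, config.gc, rng)
    if len(consensus) != geometry.span:
        raise ValueError("consensus length does not match geometry span")
    span = geometry.span
    R = config.region_len
    species = [f"sp{k:02d}" for k in range(config.n_species)]

    regions: dict[str, list[UpstreamRegion]] = {sp: [] for sp in species}
    groups: list[OrthologGroup] = []
    sites: list[PlantedSite] = []
    targets: set[str] = set()
    decoys: set[str] = set()

    for j in range(config.n_target_operons):
        gid = f"og_target_{j:03d}"
        targets.add(gid)
        ancestral_bg = gen_background(R, config.gc, rng)
        if site_positions and gid in site_positions:
            pos, strand = site_positions[gid]
        else:
            pos = int(rng.integers(0, R - span + 1))
            strand = "+" if rng.random() < 0.5 else "-"
        inst = _instantiate(consensus, config.gc, rng)
        planted = inst if strand == "+" else reverse_complement(inst)
        members: dict[str, str] = {}
        for sp in species:
            locus = f"{sp}_t{j:03d}"
            members[sp] = locus
            bg = _mutate(ancestral_bg, config.divergence, config.gc, rng, resample=True)
            site = _mutate(planted, config.site_mutation_rate, config.gc, rng, resample=False)
            seq = bg[:pos] + site + bg[pos + span :]
            regions[sp].append(
                UpstreamRegion(locus_tag=locus, seq=seq, offset_start=-R, species_id=sp)
            )
            sites.append(
                PlantedSite(
                    species_id=sp,
                    locus_tag=locus,
                    position=pos,
                    offset=pos - R,
                    strand=strand,
                    site_seq=site if strand == "+" else reverse_complement(site),
                )
            )
        groups.append(OrthologGroup(group_id=gid, members=members))

    for j in range(config.n_decoy_genes):
        gid = f"og_decoy_{j:04d}"
        decoys.add(gid)
        members = {}
        for sp in species:
            locus = f"{sp}_d{j:04d}"
            members[sp] = locus
            regions[sp].append(
                UpstreamRegion(
                    locus_tag=locus,
                    seq=gen_background(R, config.gc, rng),
                    offset_start=-R,
                    species_id=sp,
                )
            )
        groups.append(OrthologGroup(group_id=gid, members=members))

    truth = SyntheticTruth(
        consensus=consensus,
        geometry=geometry,
        sites=sites,
        regulon_members=targets,
        decoy_groups=decoys,
        seed=config.seed,
    )
    return regions, groups, truth


def _plant_promoter(seq: list[str], region_start: int, tss_offset: int) -> tuple[int, int]:
    """Write canonical -35/-10 hexamers at gap 7, spacer 17; return their start offsets."""
    m10_start = tss_offset - 7 - 6
    m35_start = m10_start - 17 - 6
    for off, hexamer in ((m35_start, MINUS35_CONSENSUS), (m10_start, MINUS10_CONSENSUS)):
        i = off - region_start
        seq[i : i + 6] = list(hexamer)
    return m35_start, m10_start


def gen_toy_genomes(
    config: GeneratorConfig,
) -> tuple[dict[str, GenomeRecord], list[OrthologGroup], list[TSSRecord], SyntheticTruth]:
    """Toy genomes whose upstream regions round-trip through genome I/O.

    Each gene unit is [upstream region][placeholder ORF] on alternating
    strands, separated so upstream extraction recovers the planted region
    exactly.  TSSs (reference species, shared offsets across species) are
    drawn with a configurable median UTR length and placed so each target's
    planted site realizes a repressor geometry (site within the 5'UTR) or an
    activator geometry (site wholly upstream of a planted canonical -35/-10
    promoter), in the configured proportions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    geometry = config.geometry or default_geometry(config.motif)
    span = geometry.span
    R = config.region_len

    # choose per-target mechanism, TSS and compatible site placement
    site_positions: dict[str, tuple[int, str]] = {}
    tss_offsets: dict[str, int] = {}
    mechanisms: dict[str, str] = {}
    promoter_targets: dict[str, int] = {}
    for j in range(config.n_target_operons):
        gid = f"og_target_{j:03d}"
        mech = "repressor" if rng.random() < config.repressor_fraction else "activator"
        utr = int(np.clip(round(config.tss_median * rng.lognormal(0.0, 0.4)), 15, 250))
        t = -utr
        if mech == "repressor":
            # site inside the 5'UTR [t, 0)
            if -t < span + 2:
                t = -(span + 10)
            lo, hi = t, -span
            pos_off = int(rng.integers(lo, hi + 1))
        else:
            # site wholly upstream of the -35 element (which we plant)
            m35_start = t - 7 - 6 - 17 - 6
            hi = m35_start - span - 2
            lo = max(-R, hi - 60)
            if lo > hi:
                t = -config.tss_median
                m35_start = t - 36
                hi = m35_start - span - 2
                lo = max(-R, hi - 60)
            pos_off = int(rng.integers(lo, hi + 1))
            promoter_targets[gid] = t
        strand = "+" if rng.random() < 0.5 else "-"
        site_positions[gid] = (pos_off + R, strand)
        tss_offsets[gid] = t
        mechanisms[gid] = mech

    sub_cfg = GeneratorConfig(**{**config.__dict__})
    regions, groups, truth = gen_ortholog_regions(sub_cfg, site_positions=site_positions)
    truth.tss_geometry = mechanisms

    # plant canonical promoters for activator targets (all species, same offsets)
    by_group = {g.group_id: g for g in groups}
    for gid, t in promoter_targets.items():
        for sp, locus in by_group[gid].members.items():
            for region in regions[sp]:
                if region.locus_tag == locus:
                    chars = list(region.seq)
                    _plant_promoter(chars, region.offset_start, t)
                    region.seq = "".join(chars)

    # assemble contigs: [region][ORF] alternating strands, 10 bp separators
    genomes: dict[str, GenomeRecord] = {}
    for sp in sorted(regions):
        parts: list[str] = []
        genes: list[GeneFeature] = []
        cursor = 0
        for i, region in enumerate(regions[sp]):
            orf = "ATG" + gen_background(config.orf_len - 6, config.gc, rng) + "TAA"
            strand = "+" if i % 2 == 0 else "-"
            if strand == "+":
                parts.append(region.seq)
                parts.append(orf)
                genes.append(
                    GeneFeature(
                        locus_tag=region.locus_tag,
                        contig="chr",
                        start=cursor + len(region),
                        end=cursor + len(region) + len(orf),
                        strand="+",
                    )
                )
            else:
                parts.append(reverse_complement(orf))
                parts.append(reverse_complement(region.seq))
                genes.append(
                    GeneFeature(
                        locus_tag=region.locus_tag,
                        contig="chr",
                        start=cursor,
                        end=cursor + len(orf),
                        strand="-",
                    )
                )
            cursor += len(region) + len(orf)
            sep = gen_background(10, config.gc, rng)
            parts.append(sep)
            cursor += len(sep)
        genomes[sp] = GenomeRecord(species_id=sp, contigs={"chr": "".join(parts)}, genes=genes)

    ref = sorted(regions)[0]
    tss_records = [
        TSSRecord(locus_tag=by_group[gid].members[ref], tss_offset=tss_offsets[gid])
        for gid in sorted(tss_offsets)
    ]
    return genomes, groups, tss_records, truth


def gen_expression(
    config: GeneratorConfig,
    regulons: dict[str, set[str]],
    all_genes: list[str],
    induction_map: dict[str, set[str]] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Regulon-structured expression matrix with known DE truth.

    Baseline log2 expression ~ Normal(8, 1) per gene; regulon members gain
    ``effect_size`` on their inducing conditions; Normal(0, noise_sd) noise
    is added everywhere.  Inducing conditions default to a round-robin
    assignment over the configured substrate panel.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    conds = list(config.conditions)
    if induction_map is None:
        induction_map = {
            rid: {conds[i % len(conds)]} for i, rid in enumerate(sorted(regulons))
        }
    baseline = rng.normal(8.0, 1.0, size=len(all_genes))
    values = np.tile(baseline[:, None], (1, len(conds)))
    gene_index = {g: i for i, g in enumerate(all_genes)}
    expected_de: set[str] = set()
    for rid in sorted(regulons):
        for g in sorted(regulons[rid]):
            if g not in gene_index:
                continue
            for c in induction_map[rid]:
                values[gene_index[g], conds.index(c)] += config.effect_size
            if config.effect_size > 0:
                expected_de.add(g)
    values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    df = pd.DataFrame(values, index=all_genes, columns=conds)
    truth = SyntheticTruth(
        consensus="",
        geometry=config.geometry or default_geometry(config.motif),
        sites=[],
        regulon_members=set().union(*regulons.values()) if regulons else set(),
        decoy_groups=set(),
        induction=induction_map,
        expected_de=expected_de,
        seed=config.seed,
    )
    return df, truth
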