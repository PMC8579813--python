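"""Genome and feature I/O, upstream-region extraction and training-set assembly.

Coordinates are 0-based half-open internally; files are read and written
1-based inclusive (GFF convention).  Upstream regions are reported on the
gene's coding strand with positions relative to the translation start
(negative = upstream, half-open), so a region spanning ``[-120, 0)`` is the
120 bp immediately 5' of the start codon.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """A protein-coding gene on a contig (0-based half-open coordinates)."""

    locus_tag: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.locus_tag}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def translation_start(self) -> int:
        """Genomic coordinate of the translation start (strand-aware)."""
        return self.start if self.strand == "+" else self.end


@dataclass
class GenomeRecord:
    """One annotated genome: contig sequences plus gene features."""

    species_id: str
    contigs: dict[str, str]
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.contig not in self.contigs:
                raise ValueError(
                    f"gene {g.locus_tag} references unknown contig {g.contig!r}"
                )
            if g.end > len(self.contigs[g.contig]):
                raise ValueError(
                    f"gene {g.locus_tag} extends past end of contig {g.contig}"
                )
            if g.locus_tag in seen:
                raise ValueError(f"duplicate locus_tag {g.locus_tag}")
            seen.add(g.locus_tag)
        self._by_tag = {g.locus_tag: g for g in self.genes}

    def gene(self, locus_tag: str) -> GeneFeature:
        try:
            return self._by_tag[locus_tag]
        except KeyError:
            raise KeyError(f"no gene {locus_tag!r} in genome {self.species_id}") from None

    def __contains__(self, locus_tag: str) -> bool:
        return locus_tag in self._by_tag


@dataclass
class UpstreamRegion:
    """A gene's upstream window on its coding strand.

    ``offset_start``/``offset_end`` are relative to the translation start
    (half-open; ``offset_end <= 0``).  ``truncated_by`` records why the
    window is shorter than requested: an upstream coding region, the contig
    edge, or ``"none"`` for a full-length window.
    """

    locus_tag: str
    seq: str
    offset_start: int
    offset_end: int = 0
    truncated_by: str = "none"
    species_id: str = ""

    def __post_init__(self) -> None:
        if self.offset_end > 0:
            raise ValueError("offset_end must be <= 0 (upstream of translation start)")
        if len(self.seq) != self.offset_end - self.offset_start:
            raise ValueError("sequence length does not match offsets")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class OrthologGroup:
    """One ortholog group: at most one member locus per species."""

    group_id: str
    members: dict[str, str]


def _parse_gff3_features(path) -> list[GeneFeature]:
    feats = []
    # prefer locus_tag over ID over Name when naming the gene
    attr_res = [re.compile(rf"(?:^|;){key}=([^;]+)") for key in ("locus_tag", "ID", "Name")]
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            contig, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in ("gene", "CDS"):
                continue
            m = next((mm for rx in attr_res if (mm := rx.search(attrs))), None)
            if m is None:
                raise ValueError(f"{path}:{lineno}: no locus_tag/ID in attributes")
            prod = re.search(r"product=([^;]+)", attrs)
            feats.append(
                GeneFeature(
                    locus_tag=m.group(1),
                    contig=contig,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    product=prod.group(1) if prod else "",
                )
            )
    # a gene and its CDS share a locus tag in many GFF3 files; keep one
    uniq: dict[str, GeneFeature] = {}
    for f in feats:
        uniq.setdefault(f.locus_tag, f)
    return list(uniq.values())


def _parse_tsv_features(path) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns (contig, start, end, strand, locus_tag)")
            contig, start, end, strand, locus_tag = cols[:5]
            if lineno == 1 and not start.isdigit():
                continue  # header row
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
            feats.append(
                GeneFeature(
                    locus_tag=locus_tag,
                    contig=contig,
                    start=s - 1,
                    end=e,
                    strand=strand,
                    product=cols[5] if len(cols) > 5 else "",
                )
            )
    return feats


def read_genome(fasta_path, features_path, species_id: str | None = None) -> GenomeRecord:
    """Read a genome FASTA plus a GFF3 or 5-column TSV feature table.

    File coordinates are 1-based inclusive and converted to the internal
    0-based half-open convention on read.  Sequences are uppercased and must
    be over {A,C,G,T,N}.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"contig {rec.id}: non-ACGTN characters {sorted(bad)}")
        contigs[rec.id] = seq
    if species_id is None:
        species_id = str(fasta_path)
    path = str(features_path)
    if path.endswith((".gff", ".gff3")):
        genes = _parse_gff3_features(path)
    else:
        genes = _parse_tsv_features(path)
    if not genes:
        logger.warning("feature file %s contains no gene rows", path)
    return GenomeRecord(species_id=species_id, contigs=contigs, genes=genes)


def write_features_tsv(genome: GenomeRecord, path) -> None:
    """Write the feature table as TSV with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tlocus_tag\tproduct\n")
        for g in genome.genes:
            fh.write(f"{g.contig}\t{g.start + 1}\t{g.end}\t{g.strand}\t{g.locus_tag}\t{g.product}\n")


def write_fasta(genome: GenomeRecord, path) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def extract_upstream(
    genome: GenomeRecord,
    locus_tag: str,
    max_len: int = 300,
    stop_at_coding: bool = True,
) -> UpstreamRegion:
    """Coding-strand upstream window ``[-L, 0)`` of a gene's translation start.

    ``L = min(max_len, distance to the nearest upstream coding region if
    stop_at_coding, distance to the contig edge)``.  For minus-strand genes
    the genomic window downstream of ``gene.end`` is reverse-complemented so
    offsets are always relative to the translation start on the coding strand.
    """
    if max_len <= 0:
        raise ValueError("max_len must be > 0")
    gene = genome.gene(locus_tag)
    contig_seq = genome.contigs[gene.contig]
    others = [g for g in genome.genes if g.contig == gene.contig and g.locus_tag != locus_tag]

    if gene.strand == "+":
        anchor = gene.start
        edge_limit = anchor  # bases available to the contig start
        gene_limit = edge_limit
        if stop_at_coding:
            for g in others:
                if g.start < anchor:
                    gene_limit = min(gene_limit, anchor - min(g.end, anchor))
        L = min(max_len, edge_limit, gene_limit)
        seq = contig_seq[anchor - L : anchor]
    else:
        anchor = gene.end
        edge_limit = len(contig_seq) - anchor
        gene_limit = edge_limit
        if stop_at_coding:
            for g in others:
                if g.end > anchor:
                    gene_limit = min(gene_limit, max(g.start, anchor) - anchor)
        L = min(max_len, edge_limit, gene_limit)
        seq = reverse_complement(contig_seq[anchor : anchor + L])

    if L == max_len:
        truncated = "none"
    elif gene_limit < edge_limit:
        truncated = "upstream_gene"
    elif edge_limit < max_len and edge_limit <= gene_limit:
        truncated = "contig_edge"
    else:
        truncated = "upstream_gene"
    return UpstreamRegion(
        locus_tag=locus_tag,
        seq=seq,
        offset_start=-L,
        offset_end=0,
        truncated_by=truncated,
        species_id=genome.species_id,
    )


def training_regions(
    groups: list[OrthologGroup],
    genomes: dict[str, GenomeRecord],
    min_len: int = 50,
    max_len: int = 300,
    stop_at_coding: bool = True,
) -> list[UpstreamRegion]:
    """Assemble the motif-discovery training set from ortholog groups.

    One upstream region per resolvable member; regions of length <= min_len
    are dropped (intergenic regions must exceed 50 bp by default).  Raises if
    a group resolves in no genome or if every region is filtered out.
    """
    regions: list[UpstreamRegion] = []
    n_dropped = 0
    for group in sorted(groups, key=lambda g: g.group_id):
        resolved = 0
        for species_id in sorted(group.members):
            locus = group.members[species_id]
            genome = genomes.get(species_id)
            if genome is None or locus not in genome:
                continue
            resolved += 1
            region = extract_upstream(genome, locus, max_len=max_len, stop_at_coding=stop_at_coding)
            if len(region) <= min_len:
                n_dropped += 1
                continue
            regions.append(region)
        if resolved == 0:
            raise ValueError(f"ortholog group {group.group_id} resolves in no genome")
    if n_dropped:
        logger.warning("training_regions: dropped %d region(s) of length <= %d bp", n_dropped, min_len)
    if not regions:
        raise ValueError("training set empty: all regions filtered out")
    return regions


def read_ortholog_table(path) -> list[OrthologGroup]:
    """Read a TSV ortholog table (header required: group_id, species_id, locus_tag)."""
    groups: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["group_id", "species_id", "locus_tag"]:
            raise ValueError(f"{path}: expected header 'group_id\\tspecies_id\\tlocus_tag'")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            gid, sp, locus = cols[:3]
            members = groups.setdefault(gid, {})
            if sp in members:
                raise ValueError(f"{path}:{lineno}: duplicate species {sp} in group {gid}")
            members[sp] = locus
    return [OrthologGroup(gid, members) for gid, members in groups.items()]


def write_ortholog_table(groups: list[OrthologGroup], path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tspecies_id\tlocus_tag\n")
        for g in groups:
            for sp in sorted(g.members):
                fh.write(f"{g.group_id}\t{sp}\t{g.members[sp]}\n")


@dataclass
class Operon:
    """A run of adjacent same-strand genes treated as one transcription unit."""

    operon_id: str
    locus_tags: list[str]
    lead_gene: str  # first gene in transcription order (5' end)
    strand: str


def assign_operons(genome: GenomeRecord, max_gap: int = 100) -> list[Operon]:
    """Group adjacent same-strand genes with intergenic gap < max_gap into operons.

    The lead gene is the 5'-most gene in transcription order: lowest start on
    the plus strand, highest end on the minus strand.
    """
    operons: list[Operon] = []
    by_contig: dict[str, list[GeneFeature]] = {}
    for g in genome.genes:
        by_contig.setdefault(g.contig, []).append(g)
    for contig in sorted(by_contig):
        genes = sorted(by_contig[contig], key=lambda g: g.start)
        run: list[GeneFeature] = []
        for g in genes:
            if run and g.strand == run[-1].strand and g.start - run[-1].end < max_gap:
                run.append(g)
            else:
                if run:
                    operons.append(_make_operon(run, len(operons)))
                run = [g]
        if run:
            operons.append(_make_operon(run, len(operons)))
    return operons


def _make_operon(run: list[GeneFeature], idx: int) -> Operon:
    strand = run[0].strand
    lead = run[0] if strand == "+" else run[-1]
    return Operon(
        operon_id=f"operon_{idx:04d}",
        locus_tags=[g.locus_tag for g in run],
        lead_gene=lead.locus_tag,
        strand=strand,
    )
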