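"""Positional weight matrices, genome scanning and cross-genome regulon assembly.

A PWM is built from an aligned set of training sites with a
background-distributed pseudocount; scores are log2 odds (bits) summed over
the modeled columns (spacer columns of spaced geometries are skipped).  The
scan threshold is the minimum score observed over the training sites, so
training-set recall is 100% by construction.  Predicted sites are filtered
by a cross-genome consistency check: an operon joins the regulon only when
sites recur upstream of its orthologs in enough of the genomes that carry
both the regulator and the operon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .genome_io import (
    GenomeRecord,
    OrthologGroup,
    UpstreamRegion,
    assign_operons,
    extract_upstream,
    reverse_complement,
)
from .motif_discovery import BASES, COMPLEMENT_INDEX, Geometry, _BASE_INDEX

logger = logging.getLogger(__name__)


@dataclass
class SiteHit:
    """A scored motif occurrence relative to a gene's translation start."""

    species_id: str
    locus_tag: str
    offset: int  # site start relative to translation start (negative upstream)
    strand: str
    score: float  # bits
    site_seq: str

    @property
    def end_offset(self) -> int:
        return self.offset + len(self.site_seq)


@dataclass
class MotifModel:
    """A PWM with its geometry, training sites and learned score threshold."""

    tf_id: str
    geometry: Geometry
    counts: np.ndarray  # (n_modeled, 4)
    weights: np.ndarray  # (n_modeled, 4) log2 odds
    background: np.ndarray  # (4,)
    alpha: float
    training_sites: list[SiteHit] = field(default_factory=list)
    threshold: float = -math.inf

    @property
    def span(self) -> int:
        return self.geometry.span

    def information_content(self) -> np.ndarray:
        """Per modeled column information content in bits."""
        n = self.counts
        p = (n + 1e-9) / (n + 1e-9).sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = p * np.log2(p / self.background[None, :])
        return np.nansum(terms, axis=1)


def build_pwm(
    sites: list[str],
    background: np.ndarray | None = None,
    alpha: float = 1.0,
    geometry: Geometry | None = None,
    tf_id: str = "TF",
    site_meta: list[SiteHit] | None = None,
) -> MotifModel:
    """Build a log-odds PWM from aligned full-span site sequences.

    weights(b, i) = log2((n(b,i) + alpha*q(b)) / ((N + alpha) * q(b))); the
    threshold is the minimum training-site score.  ``geometry`` defaults to a
    contiguous palindrome-mode span covering the whole site; for spaced
    geometries only the unit columns are counted and scored.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 training sites")
    span = len(sites[0])
    if any(len(s) != span for s in sites):
        raise ValueError("ragged site lengths in training set")
    if geometry is None:
        geometry = Geometry("palindrome", width=span)
    if geometry.span != span:
        raise ValueError(f"site length {span} does not match geometry span {geometry.span}")
    if background is None:
        background = np.full(4, 0.25)
    q = np.asarray(background, dtype=float)

    offsets = geometry.modeled_offsets
    counts = np.zeros((len(offsets), 4))
    N = len(sites)
    for s in sites:
        for k, off in enumerate(offsets):
            b = _BASE_INDEX.get(s[off])
            if b is None:
                raise ValueError(f"invalid base {s[off]!r} in training site")
            if b < 4:
                counts[k, b] += 1.0
            else:  # N counted as background mass
                counts[k] += q
    weights = np.log2((counts + alpha * q[None, :]) / ((N + alpha) * q[None, :]))

    motif = MotifModel(
        tf_id=tf_id,
        geometry=geometry,
        counts=counts,
        weights=weights,
        background=q,
        alpha=alpha,
    )
    hits = site_meta or [
        SiteHit(species_id="", locus_tag=f"train_{i}", offset=0, strand="+", score=0.0, site_seq=s)
        for i, s in enumerate(sites)
    ]
    for h, s in zip(hits, sites):
        h.score = score_site(motif, s)
    motif.training_sites = hits
    motif.threshold = min(h.score for h in hits)
    return motif


def score_site(motif: MotifModel, site_seq: str) -> float:
    """Score one full-span site sequence (bits); N columns score 0 (background)."""
    if len(site_seq) != motif.span:
        raise ValueError("site length does not match motif span")
    total = 0.0
    for k, off in enumerate(motif.geometry.modeled_offsets):
        b = _BASE_INDEX[site_seq[off]]
        if b < 4:
            total += motif.weights[k, b]
    return float(total)


def _weights5(motif: MotifModel) -> np.ndarray:
    w5 = np.zeros((motif.weights.shape[0], 5))
    w5[:, :4] = motif.weights
    return w5


def score_region(
    motif: MotifModel,
    region: UpstreamRegion,
    both_strands: bool = True,
    threshold: float | None = None,
) -> list[SiteHit]:
    """All above-threshold motif occurrences in one upstream region.

    Hits are reported with offsets relative to the translation start and
    sorted by offset.  For palindrome-mode motifs the tied columns make the
    two strands score identically at every position, so only the canonical
    plus-strand hit is reported.
    """
    theta = motif.threshold if threshold is None else threshold
    span = motif.span
    L = len(region)
    if L < span:
        return []
    seq = np.fromiter((_BASE_INDEX[b] for b in region.seq), dtype=np.int8, count=L)
    P = L - span + 1
    w5 = _weights5(motif)
    offsets = motif.geometry.modeled_offsets

    fwd = np.zeros(P)
    for k, off in enumerate(offsets):
        fwd += w5[k, seq[off : off + P]]

    strands: list[tuple[np.ndarray, str]] = [(fwd, "+")]
    palindrome = motif.geometry.mode == "palindrome"
    if both_strands and not palindrome:
        w5_rc = np.zeros_like(w5)
        w5_rc[:, :4] = motif.weights[:, COMPLEMENT_INDEX]
        rev = np.zeros(P)
        for k, off in enumerate(offsets):
            off_rc = span - 1 - off
            rev += w5_rc[k, seq[off_rc : off_rc + P]]
        strands.append((rev, "-"))

    hits: list[SiteHit] = []
    for scores, strand in strands:
        for p in np.flatnonzero(scores >= theta):
            window = region.seq[p : p + span]
            hits.append(
                SiteHit(
                    species_id=region.species_id,
                    locus_tag=region.locus_tag,
                    offset=region.offset_start + int(p),
                    strand=strand,
                    score=float(scores[p]),
                    site_seq=window if strand == "+" else reverse_complement(window),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_genomes(
    motif: MotifModel,
    genomes: dict[str, GenomeRecord],
    tf_species: set[str] | None = None,
    window: int = 300,
    operon_max_gap: int = 100,
    stop_at_coding: bool = True,
) -> dict[str, list[SiteHit]]:
    """Scan every first-in-operon upstream region of each genome at threshold.

    Genomes lacking an ortholog of the regulator (``tf_species`` given and
    species absent) are skipped, mirroring the practice of scanning only
    genomes that possess the TF gene.
    """
    results: dict[str, list[SiteHit]] = {}
    for species_id in sorted(genomes):
        if tf_species is not None and species_id not in tf_species:
            logger.info("scan_genomes: %s lacks the TF ortholog; skipped", species_id)
            continue
        genome = genomes[species_id]
        hits: list[SiteHit] = []
        if window > 0:
            for operon in assign_operons(genome, max_gap=operon_max_gap):
                region = extract_upstream(genome, operon.lead_gene, max_len=window, stop_at_coding=stop_at_coding)
                hits.extend(score_region(motif, region))
        results[species_id] = hits
    return results


@dataclass
class RegulonMember:
    group_id: str
    hits: dict[str, SiteHit]  # species -> best hit
    conservation: int  # number of species with a hit
    n_eligible: int


@dataclass
class Regulon:
    """A regulator with its consistency-filtered target operons."""

    tf_id: str
    members: list[RegulonMember]
    mode: str = "unknown"
    unverified: bool = False

    def member_ids(self) -> set[str]:
        return {m.group_id for m in self.members}


def consistency_filter(
    hits_by_species: dict[str, list[SiteHit]],
    groups: list[OrthologGroup],
    tf_id: str = "TF",
    tf_species: set[str] | None = None,
    quorum_fraction: float = 0.5,
    quorum_min: int = 2,
) -> Regulon:
    """Cross-genome consistency check removing false-positive scan hits.

    An operon (ortholog group of lead genes) is retained iff hits occur
    upstream of its orthologs in at least
    ``max(quorum_min, ceil(quorum_fraction * n_eligible))`` species, where
    the eligible species are those carrying both the TF ortholog and the
    operon ortholog.  With a single scanned species no cross-genome evidence
    exists: all hits are kept and the regulon flagged unverified.
    """
    scanned = set(hits_by_species)
    eligible_tf = scanned if tf_species is None else (scanned & tf_species)

    locus_to_group: dict[tuple[str, str], str] = {}
    group_by_id = {g.group_id: g for g in groups}
    for g in groups:
        for sp, locus in g.members.items():
            locus_to_group[(sp, locus)] = g.group_id

    per_group: dict[str, dict[str, SiteHit]] = {}
    for sp, hits in hits_by_species.items():
        for h in hits:
            gid = locus_to_group.get((sp, h.locus_tag))
            if gid is None:
                continue
            best = per_group.setdefault(gid, {})
            if sp not in best or h.score > best[sp].score:
                best[sp] = h

    single_species = len(scanned) < 2
    members: list[RegulonMember] = []
    for gid in sorted(per_group):
        species_hits = per_group[gid]
        n_eligible = len(set(group_by_id[gid].members) & eligible_tf)
        conservation = len(species_hits)
        quorum = max(quorum_min, math.ceil(quorum_fraction * n_eligible))
        if single_species or conservation >= quorum:
            members.append(
                RegulonMember(
                    group_id=gid,
                    hits=dict(sorted(species_hits.items())),
                    conservation=conservation,
                    n_eligible=n_eligible,
                )
            )
    return Regulon(tf_id=tf_id, members=members, unverified=single_species)


# ---------------------------------------------------------------------------
# MEME minimal motif format and tabular output


def write_meme(motif: MotifModel, path) -> None:
    """Write the motif in MEME minimal format (modeled columns only).

    Geometry, pseudocount and threshold are carried in trailing comment
    lines so a round-trip through read_meme reproduces the weights exactly.
    """
    n = motif.counts
    nsites = float(n[0].sum()) if len(n) else 0.0
    p = n / n.sum(axis=1, keepdims=True)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            + " ".join(f"{b} {motif.background[i]:.17g}" for i, b in enumerate(BASES))
            + "\n\n"
        )
        fh.write(f"MOTIF {motif.tf_id}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {len(n)} nsites= {nsites:.17g} E= 0\n"
        )
        for row in p:
            fh.write(" ".join(f"{x:.17g}" for x in row) + "\n")
        g = motif.geometry
        fh.write(
            f"# regufoot-geometry mode={g.mode} width={g.width} unit={g.unit} "
            f"period={g.period} spacer={g.spacer}\n"
        )
        fh.write(f"# regufoot-alpha {motif.alpha:.17g}\n")
        fh.write(f"# regufoot-threshold {motif.threshold:.17g}\n")


def read_meme(path) -> MotifModel:
    """Read a motif written by write_meme (MEME minimal format + metadata)."""
    tf_id = "TF"
    background = np.full(4, 0.25)
    rows: list[list[float]] = []
    nsites = 0.0
    alpha = 1.0
    threshold = -math.inf
    geometry: Geometry | None = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[j * 2 + 1]) for j in range(4)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            tf_id = line.split()[1]
        elif line.startswith("letter-probability matrix"):
            fields = dict(zip(line.split()[2::2], line.split()[3::2]))
            w = int(fields["w="])
            nsites = float(fields["nsites="])
            for j in range(w):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            i += w
        elif line.startswith("# regufoot-geometry"):
            kv = dict(part.split("=") for part in line.split()[2:])
            geometry = Geometry(
                mode=kv["mode"],
                width=int(kv["width"]),
                unit=int(kv["unit"]),
                period=int(kv["period"]),
                spacer=int(kv["spacer"]),
            )
        elif line.startswith("# regufoot-alpha"):
            alpha = float(line.split()[2])
        elif line.startswith("# regufoot-threshold"):
            threshold = float(line.split()[2])
        i += 1
    p = np.array(rows)
    counts = p * nsites
    if geometry is None:
        geometry = Geometry("palindrome", width=len(rows))
    q = background
    weights = np.log2((counts + alpha * q[None, :]) / ((nsites + alpha) * q[None, :]))
    return MotifModel(
        tf_id=tf_id,
        geometry=geometry,
        counts=counts,
        weights=weights,
        background=q,
        alpha=alpha,
        threshold=threshold,
    )


def hits_to_tsv(hits_by_species: dict[str, list[SiteHit]], path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\tlocus_tag\toffset\tstrand\tscore\tsite_seq\n")
        for sp in sorted(hits_by_species):
            for h in hits_by_species[sp]:
                fh.write(f"{sp}\t{h.locus_tag}\t{h.offset}\t{h.strand}\t{h.score:.4f}\t{h.site_seq}\n")


def hits_to_gff3(
    hits_by_species: dict[str, list[SiteHit]],
    genomes: dict[str, GenomeRecord],
    path,
    tf_id: str = "TF",
) -> None:
    """Write hits as GFF3 intervals in genomic coordinates (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for sp in sorted(hits_by_species):
            genome = genomes.get(sp)
            if genome is None:
                continue
            for h in hits_by_species[sp]:
                gene = genome.gene(h.locus_tag)
                span = len(h.site_seq)
                if gene.strand == "+":
                    start = gene.start + h.offset
                    strand = h.strand
                else:
                    start = gene.end - h.offset - span
                    strand = "-" if h.strand == "+" else "+"
                fh.write(
                    f"{gene.contig}\tregufoot\tTF_binding_site\t{start + 1}\t{start + span}\t"
                    f"{h.score:.4f}\t{strand}\t.\tID={tf_id}_{h.locus_tag};locus={h.locus_tag};score={h.score:.4f}\n"
                )


def regulon_summary_tsv(regulon: Regulon, path) -> None:
    with open(path, "w") as fh:
        fh.write("tf_id\tgroup_id\tconservation\tn_eligible\tbest_score\tmode\n")
        for m in regulon.members:
            best = max(h.score for h in m.hits.values())
            fh.write(
                f"{regulon.tf_id}\t{m.group_id}\t{m.conservation}\t{m.n_eligible}\t{best:.4f}\t{regulon.mode}\n"
            )


def logo_matrix_tsv(motif: MotifModel, path) -> None:
    """Position x base probability matrix for logo plotting."""
    n = motif.counts
    p = n / n.sum(axis=1, keepdims=True)
    with open(path, "w") as fh:
        fh.write("position\t" + "\t".join(BASES) + "\n")
        for i, row in enumerate(p):
            fh.write(f"{i}\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")
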