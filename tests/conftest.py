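import numpy as np
import pytest

from regufoot.genome_io import GeneFeature, GenomeRecord, UpstreamRegion, reverse_complement
from regufoot.synthetic_data import gen_background


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_region(seq: str, locus_tag: str = "g1", species_id: str = "") -> UpstreamRegion:
    return UpstreamRegion(
        locus_tag=locus_tag, seq=seq, offset_start=-len(seq), species_id=species_id
    )


def planted_regions(
    consensus: str,
    n_regions: int,
    rng: np.random.Generator,
    region_len: int = 300,
    gc: float = 0.5,
    both_strands: bool = True,
):
    """Background regions each carrying one exact planted instance; returns
    (regions, positions, strands)."""
    span = len(consensus)
    regions, positions, strands = [], [], []
    for i in range(n_regions):
        bg = gen_background(region_len, gc, rng)
        inst, strand = consensus, "+"
        if both_strands and rng.random() < 0.5:
            inst, strand = reverse_complement(consensus), "-"
        p = int(rng.integers(0, region_len - span + 1))
        regions.append(make_region(bg[:p] + inst + bg[p + span :], locus_tag=f"r{i:03d}"))
        positions.append(p)
        strands.append(strand)
    return regions, positions, strands


def toy_genome(seqs_and_genes, species_id="spX") -> GenomeRecord:
    """Build a GenomeRecord from {contig: (sequence, [(locus, start, end, strand)])}."""
    contigs = {c: s for c, (s, _) in seqs_and_genes.items()}
    genes = [
        GeneFeature(locus_tag=t, contig=c, start=a, end=b, strand=st)
        for c, (_, glist) in seqs_and_genes.items()
        for (t, a, b, st) in glist
    ]
    return GenomeRecord(species_id=species_id, contigs=contigs, genes=genes)
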