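"""Promoter location, repressor/activator classification and UTR statistics."""

import numpy as np
import pytest

from regufoot.genome_io import OrthologGroup
from regufoot.pwm_regulon import SiteHit
from regufoot.regulatory_annotation import (
    MINUS10_CONSENSUS,
    MINUS35_CONSENSUS,
    PromoterCall,
    TSSRecord,
    classify_mode,
    find_promoter,
    footprint_report,
    read_tss_table,
    utr_stats,
    write_tss_table,
)
from regufoot.synthetic_data import gen_background

from conftest import make_region


def region_with_promoter(tss_offset: int, gap: int = 7, spacer: int = 17, L: int = 200, rng=None):
    """Background region with canonical hexamers planted at the given geometry."""
    rng = rng or np.random.default_rng(5)
    seq = list("".join("CG"[i % 2] for i in range(L)))  # promoter-free background
    m10 = tss_offset - gap - 6
    m35 = m10 - spacer - 6
    for off, hexamer in ((m35, MINUS35_CONSENSUS), (m10, MINUS10_CONSENSUS)):
        i = off + L
        seq[i : i + 6] = list(hexamer)
    return make_region("".join(seq))


class TestFindPromoter:
    def test_exact_consensus_found(self):
        region = region_with_promoter(-60, gap=7, spacer=17)
        call = find_promoter(region, TSSRecord("g", -60))
        assert call is not None
        assert call.total_mismatches == 0
        assert call.spacer == 17
        assert call.minus10_hexamer == MINUS10_CONSENSUS
        assert call.minus35_hexamer == MINUS35_CONSENSUS
        assert call.minus10_offset == -60 - 7 - 6

    def test_tie_breaks_toward_canonical_gap(self):
        # two zero-mismatch promoters at gaps 5 and 8: 8 is closer to 7
        L = 240
        seq = list("".join("CG"[i % 2] for i in range(L)))
        t = -80
        for gap in (5, 8):
            m10 = t - gap - 6
            m35 = m10 - 17 - 6
            seq[m10 + L : m10 + L + 6] = list(MINUS10_CONSENSUS)
            seq[m35 + L : m35 + L + 6] = list(MINUS35_CONSENSUS)
        call = find_promoter(make_region("".join(seq)), TSSRecord("g", t))
        assert call is not None and call.minus10_offset == t - 8 - 6

    def test_no_call_on_promoter_free_background(self):
        region = make_region("C" * 150)
        assert find_promoter(region, TSSRecord("g", -60)) is None

    def test_mismatch_cut_rejects_weak_candidates(self):
        # hexamers degraded to 3 mismatches each exceed the per-hexamer cut
        region = region_with_promoter(-60)
        seq = list(region.seq)
        i10 = -60 - 7 - 6 + len(seq)
        seq[i10 : i10 + 3] = list("GGG")  # TATAAT -> GGGAAT: 3 mismatches
        degraded = make_region("".join(seq))
        assert find_promoter(degraded, TSSRecord("g", -60)) is None

    def test_truncated_window_flagged_partial(self):
        # promoter planted at a compact geometry that fits a short region,
        # while part of the search grid extends past the region edge
        region = region_with_promoter(-60, gap=5, spacer=15, L=93)
        call = find_promoter(region, TSSRecord("g", -60))
        assert call is not None and call.partial
        assert call.total_mismatches == 0

    def test_minus_strand_gene_equivalent(self):
        # upstream regions are always on the coding strand, so a minus-strand
        # gene's promoter is found identically after extraction
        from regufoot.genome_io import extract_upstream, reverse_complement
        from conftest import toy_genome

        region = region_with_promoter(-60, L=200)
        # minus-strand gene: its upstream window follows the ORF in genomic coords
        genomic = reverse_complement("ATGAAATAA") + reverse_complement(region.seq)
        genome = toy_genome({"c": (genomic, [("g", 0, 9, "-")])})
        extracted = extract_upstream(genome, "g", max_len=200)
        assert extracted.seq == region.seq
        call = find_promoter(extracted, TSSRecord("g", -60))
        assert call is not None and call.total_mismatches == 0


def hit(offset: int, span: int = 20) -> SiteHit:
    return SiteHit("sp", "g", offset=offset, strand="+", score=10.0, site_seq="A" * span)


class TestClassifyMode:
    def test_site_inside_utr_is_repressor(self):
        call = classify_mode(hit(-40), TSSRecord("g", -70))
        assert call.call == "repressor"

    def test_rex_mbh_geometry_is_activator(self):
        # operator ending 45 bp upstream of the TSS, promoter at canonical
        # spacing: site lies wholly upstream of the -35 element -> activation
        t = -60
        promoter = PromoterCall(
            minus35_offset=t - 36, minus35_hexamer=MINUS35_CONSENSUS, minus35_mismatches=0,
            minus10_offset=t - 13, minus10_hexamer=MINUS10_CONSENSUS, minus10_mismatches=0,
            spacer=17,
        )
        site = hit(t - 45 - 20)  # ends exactly 45 bp upstream of the TSS
        call = classify_mode(site, TSSRecord("g", t), promoter)
        assert call.call == "activator"

    def test_straddling_minus35_boundary_is_ambiguous(self):
        t = -60
        promoter = PromoterCall(
            minus35_offset=t - 36, minus35_hexamer=MINUS35_CONSENSUS, minus35_mismatches=0,
            minus10_offset=t - 13, minus10_hexamer=MINUS10_CONSENSUS, minus10_mismatches=0,
            spacer=17,
        )
        # ends 1 bp past the upstream edge of -35 but before the hexamer: ambiguous
        site = hit(t - 36 - 20 + 1)
        assert site.end_offset == promoter.minus35_offset + 1
        call = classify_mode(site, TSSRecord("g", t), promoter)
        assert call.call == "repressor"  # overlaps the -35 hexamer itself

        # a short site wholly inside the -35/-10 spacer touches no landmark
        # but is not upstream of -35 either -> ambiguous
        gap_site = hit(-89, span=8)  # [-89, -81) inside spacer (-90, -73)
        call2 = classify_mode(gap_site, TSSRecord("g", t), promoter)
        assert call2.call == "ambiguous"

    def test_missing_tss_is_unknown(self):
        assert classify_mode(hit(-40), None).call == "unknown"

    def test_truth_table_exhaustive(self):
        """Exhaustive sweep of site positions against an independent interval oracle."""
        t = -100
        promoter = PromoterCall(
            minus35_offset=t - 36, minus35_hexamer=MINUS35_CONSENSUS, minus35_mismatches=0,
            minus10_offset=t - 13, minus10_hexamer=MINUS10_CONSENSUS, minus10_mismatches=0,
            spacer=17,
        )
        span = 20
        for for_promoter in (promoter, None):
            for a in range(-250, -span + 1):
                b = a + span
                # oracle: written directly from the positional rule
                if b > t and a < 0:
                    expect = "repressor"
                elif for_promoter is not None and (
                    (a < t - 7 and b > t - 13) or (a < t - 30 and b > t - 36)
                ):
                    expect = "repressor"
                else:
                    boundary = t - 36 if for_promoter is not None else t - 35
                    expect = "activator" if b <= boundary else "ambiguous"
                got = classify_mode(hit(a), TSSRecord("g", t), for_promoter).call
                assert got == expect, (a, b, for_promoter is not None, got, expect)


class TestUtrStats:
    def test_median(self):
        s = utr_stats([TSSRecord("a", -10), TSSRecord("b", -50), TSSRecord("c", -300)])
        assert s["median_utr"] == 50
        assert s["fraction_within_cutoff"] == pytest.approx(2 / 3)

    def test_single_long_utr(self):
        # the longest observed 5'UTR case: a single 329 bp leader
        s = utr_stats([TSSRecord("fucI", -329)])
        assert s["median_utr"] == 329

    def test_all_zero(self):
        s = utr_stats([TSSRecord("a", 0), TSSRecord("b", 0)])
        assert s["median_utr"] == 0 and s["fraction_within_cutoff"] == 1.0

    def test_permutation_invariant(self, rng):
        records = [TSSRecord(f"g{i}", -int(v)) for i, v in enumerate(rng.integers(0, 300, 20))]
        a = utr_stats(records)
        b = utr_stats(list(reversed(records)))
        assert a == b

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            utr_stats([])

    def test_table_roundtrip(self, tmp_path):
        records = [TSSRecord("a", -50), TSSRecord("b", -120)]
        write_tss_table(records, tmp_path / "t.tsv")
        assert read_tss_table(tmp_path / "t.tsv") == records


class TestFootprintReport:
    def test_conserved_site_forms_column_band(self, rng):
        group = OrthologGroup("og1", {f"sp{k}": f"g{k}" for k in range(3)})
        regions, hits = {}, {}
        for k in range(3):
            sp = f"sp{k}"
            seq = gen_background(100, 0.4, rng)
            regions[sp] = make_region(seq, locus_tag=f"g{k}", species_id=sp)
            hits[sp] = [SiteHit(sp, f"g{k}", offset=-60, strand="+", score=9.0, site_seq="A" * 10)]
        text = footprint_report(group, regions, hits=hits)
        mark_lines = [l for l in text.splitlines() if set(l.strip()) == {"="}]
        assert len(mark_lines) == 3
        assert len({(l.index("="), l.rindex("=")) for l in mark_lines}) == 1  # one column band

    def test_species_without_hit_has_no_marker(self, rng):
        group = OrthologGroup("og1", {"sp0": "a", "sp1": "b"})
        regions = {
            "sp0": make_region(gen_background(80, 0.4, rng), locus_tag="a"),
            "sp1": make_region(gen_background(80, 0.4, rng), locus_tag="b"),
        }
        hits = {"sp0": [SiteHit("sp0", "a", -40, "+", 9.0, "A" * 8)]}
        text = footprint_report(group, regions, hits=hits)
        lines = text.splitlines()
        sp1_idx = next(i for i, l in enumerate(lines) if l.startswith("sp1"))
        assert "=" not in lines[sp1_idx + 1]

    def test_single_species_warns_but_renders(self, rng, caplog):
        group = OrthologGroup("og1", {"sp0": "a"})
        regions = {"sp0": make_region(gen_background(60, 0.4, rng), locus_tag="a")}
        with caplog.at_level("WARNING"):
            text = footprint_report(group, regions)
        assert "sp0" in text
        assert any("only 1 species" in r.message for r in caplog.records)

    def test_html_escapes(self, rng):
        group = OrthologGroup("og1", {"sp0": "a", "sp1": "b"})
        regions = {
            "sp0": make_region("ACGT" * 10, locus_tag="a"),
            "sp1": make_region("ACGT" * 10, locus_tag="b"),
        }
        html = footprint_report(group, regions, html=True)
        assert html.startswith("<pre>")
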