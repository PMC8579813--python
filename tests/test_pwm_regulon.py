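"""PWM construction, threshold rule, scanning oracle and consistency filter."""

import math

import numpy as np
import pytest

from regufoot.genome_io import GenomeRecord, OrthologGroup, reverse_complement
from regufoot.motif_discovery import Geometry
from regufoot.pwm_regulon import (
    SiteHit,
    build_pwm,
    consistency_filter,
    read_meme,
    scan_genomes,
    score_region,
    score_site,
    write_meme,
)
from regufoot.synthetic_data import gen_background

from conftest import make_region, toy_genome


def brute_force_scan(motif, region, theta=None):
    """Independent oracle: explicit loop over positions, strands, columns."""
    theta = motif.threshold if theta is None else theta
    span = motif.span
    out = []
    for p in range(len(region.seq) - span + 1):
        window = region.seq[p : p + span]
        for strand, site in (("+", window), ("-", reverse_complement(window))):
            if motif.geometry.mode == "palindrome" and strand == "-":
                continue  # canonical-strand reporting for palindromes
            s = 0.0
            for k, off in enumerate(motif.geometry.modeled_offsets):
                b = site[off]
                if b != "N":
                    s += motif.weights[k, "ACGT".index(b)]
            if s >= theta:
                out.append((region.offset_start + p, strand, s))
    return sorted(out)


class TestBuildPwm:
    def test_identical_sites_closed_form(self):
        # 2 identical sites, alpha=1, uniform q: consensus-base weight is
        # log2((2 + 0.25) / ((2 + 1) * 0.25)) = log2(3) per column (hand arithmetic)
        motif = build_pwm(["ACGTT", "ACGTT"], alpha=1.0, geometry=Geometry("palindrome", width=5))
        expected = math.log2((2 + 0.25) / (3 * 0.25))
        for k, b in enumerate("ACGTT"):
            assert motif.weights[k, "ACGT".index(b)] == pytest.approx(expected, abs=1e-12)
        # non-consensus base: log2((0 + 0.25) / (3 * 0.25)) = log2(1/3)
        assert motif.weights[0, 1] == pytest.approx(math.log2(0.25 / 0.75), abs=1e-12)

    def test_balanced_column_weight_zero(self):
        motif = build_pwm(["A", "C", "G", "T"], alpha=1.0, geometry=Geometry("palindrome", width=1))
        np.testing.assert_allclose(motif.weights, 0.0, atol=1e-12)

    def test_threshold_is_min_training_score(self):
        sites = ["AAAA", "AAAT", "TTTT"]
        motif = build_pwm(sites, geometry=Geometry("palindrome", width=4))
        scores = [score_site(motif, s) for s in sites]
        assert motif.threshold == min(scores)

    def test_ragged_sites_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_pwm(["AAAA", "AAA"])

    def test_needs_two_sites(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_pwm(["AAAA"])


class TestScoreRegion:
    def _random_motif(self, rng, span=8, n_sites=6):
        sites = [gen_background(span, 0.5, rng) for _ in range(n_sites)]
        return build_pwm(sites, geometry=Geometry("palindrome", width=span))

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            motif = self._random_motif(rng)
            region = make_region(gen_background(120, 0.4, rng))
            theta = float(rng.normal(0, 3))
            hits = score_region(motif, region, threshold=theta)
            got = sorted((h.offset, h.strand, h.score) for h in hits)
            expected = brute_force_scan(motif, region, theta=theta)
            assert [(o, s) for o, s, _ in got] == [(o, s) for o, s, _ in expected]
            for (_, _, a), (_, _, b) in zip(got, expected):
                assert abs(a - b) <= 1e-9

    def test_embedded_training_site_found(self, rng):
        sites = [gen_background(10, 0.5, rng) for _ in range(5)]
        motif = build_pwm(sites, geometry=Geometry("palindrome", width=10))
        bg = "".join("AC"[i % 2] for i in range(100))  # low-scoring periodic background
        seq = bg[:40] + sites[0] + bg[50:]
        hits = score_region(motif, make_region(seq))
        offsets = [h.offset for h in hits]
        assert -60 in offsets  # position 40 in a 100 bp window

    def test_spaced_mode_skips_spacer_columns(self, rng):
        geometry = Geometry("inverted_repeat_spaced", unit=5, spacer=10)
        core = "GGGAC" + "A" * 10 + "GTCCC"
        motif = build_pwm([core, core], geometry=geometry)
        variant = "GGGAC" + "T" * 10 + "GTCCC"  # different spacer, same units
        assert score_site(motif, variant) == score_site(motif, core)

    def test_palindrome_reports_canonical_strand_once(self, rng):
        pal = "AACGTT"
        motif = build_pwm([pal, pal], geometry=Geometry("palindrome", width=6))
        region = make_region(gen_background(30, 0.5, rng)[:12] + pal + gen_background(12, 0.5, rng))
        hits = [h for h in score_region(motif, region) if h.offset == -18]
        assert len(hits) == 1 and hits[0].strand == "+"

    def test_infinite_threshold_empty(self, rng):
        motif = self._random_motif(rng)
        region = make_region(gen_background(50, 0.5, rng))
        assert score_region(motif, region, threshold=math.inf) == []

    def test_raising_threshold_never_adds_hits(self, rng):
        motif = self._random_motif(rng)
        region = make_region(gen_background(200, 0.5, rng))
        low = {(h.offset, h.strand) for h in score_region(motif, region, threshold=-5.0)}
        high = {(h.offset, h.strand) for h in score_region(motif, region, threshold=0.0)}
        assert high <= low

    def test_short_region_empty(self, rng):
        motif = self._random_motif(rng, span=10)
        assert score_region(motif, make_region("ACGT")) == []


class TestScanGenomes:
    def _setup(self, rng):
        site = "TTAACGTTAA"  # palindromic planted operator
        genomes = {}
        groups = [OrthologGroup("og1", {}), OrthologGroup("og_bg", {})]
        for k in range(3):
            sp = f"sp{k}"
            bg = gen_background(400, 0.3, rng)
            upstream = bg[:100] + site + bg[110:200]  # 200 bp upstream, site at 100
            seq = upstream + "ATG" + gen_background(94, 0.3, rng) + "TAA" + gen_background(400, 0.3, rng)
            genes = [("target", 200, 300, "+"), ("other", 550, 650, "+")]
            genomes[sp] = toy_genome({"c": (seq, genes)}, species_id=sp)
            groups[0].members[sp] = "target"
            groups[1].members[sp] = "other"
        motif = build_pwm([site] * 2, geometry=Geometry("palindrome", width=10))
        return motif, genomes, groups, site

    def test_planted_sites_found_in_all_species(self, rng):
        motif, genomes, groups, site = self._setup(rng)
        hits = scan_genomes(motif, genomes, window=300)
        for sp in genomes:
            target_hits = [h for h in hits[sp] if h.locus_tag == "target" and h.site_seq == site]
            assert any(h.offset == -100 for h in target_hits)

    def test_species_without_tf_skipped(self, rng):
        motif, genomes, groups, _ = self._setup(rng)
        hits = scan_genomes(motif, genomes, tf_species={"sp0", "sp1"}, window=300)
        assert set(hits) == {"sp0", "sp1"}

    def test_zero_window_empty(self, rng):
        motif, genomes, _, _ = self._setup(rng)
        hits = scan_genomes(motif, genomes, window=0)
        assert all(h == [] for h in hits.values())

    def test_revcomp_genome_mirrors_hits(self, rng):
        # flipping the contig (and gene strand) leaves coding-strand hits identical
        motif, genomes, _, _ = self._setup(rng)
        g = genomes["sp0"]
        L = len(g.contigs["c"])
        flipped = GenomeRecord(
            species_id="sp0f",
            contigs={"c": reverse_complement(g.contigs["c"])},
            genes=[
                type(f)(f.locus_tag, f.contig, L - f.end, L - f.start, "-" if f.strand == "+" else "+")
                for f in g.genes
            ],
        )
        a = scan_genomes(motif, {"sp0": g}, window=300)["sp0"]
        b = scan_genomes(motif, {"sp0f": flipped}, window=300)["sp0f"]
        assert sorted((h.locus_tag, h.offset, h.score) for h in a) == sorted(
            (h.locus_tag, h.offset, h.score) for h in b
        )


class TestConsistencyFilter:
    def _hits(self, spec):
        """spec: {group: n_species_with_hit}; 8 species, groups in all species."""
        groups = [OrthologGroup(g, {f"sp{k}": f"sp{k}_{g}" for k in range(8)}) for g in spec]
        hits = {f"sp{k}": [] for k in range(8)}
        for g, n in spec.items():
            for k in range(n):
                hits[f"sp{k}"].append(
                    SiteHit(f"sp{k}", f"sp{k}_{g}", offset=-50, strand="+", score=10.0, site_seq="A" * 10)
                )
        return hits, groups

    def test_quorum_arithmetic(self):
        hits, groups = self._hits({"og_a": 5, "og_b": 1})
        reg = consistency_filter(hits, groups)
        # 5 of 8 eligible >= max(2, ceil(0.5*8)) = 4 -> retained; 1 of 8 -> removed
        assert reg.member_ids() == {"og_a"}
        assert reg.members[0].conservation == 5

    def test_full_quorum_requires_all(self):
        hits, groups = self._hits({"og_a": 7})
        reg = consistency_filter(hits, groups, quorum_fraction=1.0)
        assert reg.member_ids() == set()

    def test_lowering_quorum_never_removes_members(self):
        hits, groups = self._hits({"og_a": 5, "og_b": 3, "og_c": 2})
        strict = consistency_filter(hits, groups, quorum_fraction=0.6)
        loose = consistency_filter(hits, groups, quorum_fraction=0.3)
        assert strict.member_ids() <= loose.member_ids()

    def test_single_species_flagged_unverified(self):
        groups = [OrthologGroup("og_a", {"sp0": "x"})]
        hits = {"sp0": [SiteHit("sp0", "x", -40, "+", 8.0, "A" * 10)]}
        reg = consistency_filter(hits, groups)
        assert reg.unverified
        assert reg.member_ids() == {"og_a"}


class TestMemeRoundTrip:
    def test_weights_identical(self, tmp_path, rng):
        sites = [gen_background(12, 0.4, rng) for _ in range(7)]
        motif = build_pwm(sites, geometry=Geometry("palindrome", width=12), tf_id="RexLike")
        write_meme(motif, tmp_path / "m.meme")
        back = read_meme(tmp_path / "m.meme")
        assert back.tf_id == "RexLike"
        assert back.geometry == motif.geometry
        np.testing.assert_allclose(back.weights, motif.weights, atol=1e-9)
        assert back.threshold == pytest.approx(motif.threshold, abs=1e-9)

    def test_spaced_geometry_round_trips(self, tmp_path):
        geometry = Geometry("inverted_repeat_spaced", unit=5, spacer=27)
        core = "GGGAC" + "A" * 27 + "GTCCC"
        motif = build_pwm([core, core], geometry=geometry)
        write_meme(motif, tmp_path / "m.meme")
        back = read_meme(tmp_path / "m.meme")
        assert back.geometry == geometry
        np.testing.assert_allclose(back.weights, motif.weights, atol=1e-9)
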