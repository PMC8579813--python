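"""Repressor-vs-activator classification from site position alone.

Builds an upstream region with a mapped TSS at -60 and canonical -35/-10
promoter hexamers, then classifies two binding sites: one inside the 5'UTR
(blocks polymerase -> repressor) and one ending 45 bp upstream of the TSS
(recruits polymerase -> activator, the classic dual-mode redox-regulator
geometry).
"""

from regufoot import TSSRecord, classify_mode, find_promoter
from regufoot.genome_io import UpstreamRegion
from regufoot.pwm_regulon import SiteHit
from regufoot.regulatory_annotation import MINUS10_CONSENSUS, MINUS35_CONSENSUS
from regufoot.synthetic_data import gen_background

tss = TSSRecord("mbh", tss_offset=-60)
seq = list(gen_background(200, 0.35, 3))
m10_start = -60 - 7 - 6  # -10 hexamer ends 7 bp before the TSS
m35_start = m10_start - 17 - 6  # 17 bp spacer
seq[m10_start + 200 : m10_start + 206] = list(MINUS10_CONSENSUS)
seq[m35_start + 200 : m35_start + 206] = list(MINUS35_CONSENSUS)
region = UpstreamRegion(locus_tag="mbh", seq="".join(seq), offset_start=-200)

promoter = find_promoter(region, tss)
print(f"promoter: -35 at {promoter.minus35_offset}, -10 at {promoter.minus10_offset}, "
      f"spacer {promoter.spacer} bp, {promoter.total_mismatches} mismatches")

utr_site = SiteHit("sp", "mbh", offset=-45, strand="+", score=12.0, site_seq="A" * 20)
upstream_site = SiteHit("sp", "mbh", offset=-60 - 45 - 20, strand="+", score=12.0, site_seq="A" * 20)

for name, site in (("site inside 5'UTR", utr_site), ("site 45 bp upstream of TSS", upstream_site)):
    call = classify_mode(site, tss, promoter)
    print(f"{name}: {call.call}  ({call.evidence})")
# sites overlapping the UTR or promoter block transcription (repressor);
# sites wholly upstream of the -35 element suggest activation
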