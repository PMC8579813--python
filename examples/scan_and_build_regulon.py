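"""Scan toy genomes with a trained PWM and apply the consistency filter.

Generates 4 toy genomes with 6 target operons (conserved planted operator
upstream of each ortholog) plus 40 decoy genes, builds a PWM from the
planted sites with the minimum-training-score threshold, scans every
first-in-operon upstream region, and keeps operons whose sites recur in
enough genomes.  The retained members should be exactly the 6 targets.
"""

from regufoot import GeneratorConfig, build_pwm, consistency_filter, scan_genomes
from regufoot.synthetic_data import gen_toy_genomes

cfg = GeneratorConfig(n_species=4, n_target_operons=6, n_decoy_genes=40, seed=11)
genomes, groups, tss, truth = gen_toy_genomes(cfg)

motif = build_pwm(
    [s.site_seq for s in truth.sites], geometry=truth.geometry, tf_id="TF"
)
print(f"PWM threshold (min training-site score): {motif.threshold:.2f} bits")

hits = scan_genomes(motif, genomes, window=300)
print("raw hits per species:", {sp: len(h) for sp, h in hits.items()})

regulon = consistency_filter(hits, groups, tf_id="TF")
print(f"regulon members after consistency check: {len(regulon.members)}")
for m in regulon.members:
    print(f"  {m.group_id}: conserved in {m.conservation}/{m.n_eligible} species")

predicted = regulon.member_ids()
tp = len(predicted & truth.regulon_members)
print(f"precision {tp / len(predicted):.2f}  recall {tp / len(truth.regulon_members):.2f}")
# the consistency quorum removes decoy hits that appear in only one genome
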