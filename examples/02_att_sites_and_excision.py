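"""Find att cores, reconstruct attB/attP, and excise a prophage in silico.

Recovers each prophage's att core as the longest exact direct repeat
flanking the region, then applies the single-crossover recombination model
to the published impaired 26-bp site: the crossover position k splits the
sites into attB = attL[:k] + attR[k:] on the chromosome and
attP = attR[:k] + attL[k:] on the excised circle.
"""

from prophagekit import synth
from prophagekit.att import AttSiteSet, excise, find_att_core, infer_crossover_interval, recombine, region_length

truth = synth.generate_host_genome(seed=1)
for region in truth.regions:
    att = find_att_core(truth.genome, region)
    print(f"{region.name}: att core {att.core_length} bp {att.attL}")

# Published interval lengths depend on the printed coordinate convention:
print("36,053 bp (1-based inclusive):", region_length(935757, 971809, "inclusive"))
print("39,183 bp (end - start):      ", region_length(1496626, 1535809, "end_minus_start"))

# The impaired att site: attL and attR differ at three positions, so the
# observed attP pins the crossover to a contiguous interval of positions.
attL = "CAGCCCACTTTTTTCTTCTTTGATTA"
attR = "CAGCCGACATTCTTCTTCTTTGACTA"
attP_observed = "CAGCCGACATTCTTCTTCTTTGATTA"
_, attP = recombine(attL, attR, k=23)
print("attP from crossover k=23:", attP, "(matches observed:", attP == attP_observed, ")")
print("crossovers consistent with observed attP:", infer_crossover_interval(attL, attR, attP_observed))

# Excise the first prophage: the host keeps one attB copy, the circle attP.
region = truth.regions[0]
att = find_att_core(truth.genome, region)
host, circle = excise(truth.genome, region, att, k=0)
print(
    f"excised {region.name}: host {len(host):,} bp (+circle {len(circle):,} bp "
    f"= genome {len(truth.genome):,} bp), host carries "
    f"{host.sequence.count(att.attB)} att core copy"
)
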