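"""Compare phage genomes by Mash sketch distance, ANI and clustering.

Builds a small family of related phage sequences (a parent, two drifted
relatives and an unrelated genome), sketches them (k=21, s=1000), clusters
the pairwise Mash distances, and checks species boundaries with fragment
ANI (same species at >= 85%).
"""

import numpy as np

from prophagekit import synth
from prophagekit.compare import ani, classify_species, cluster, is_hit, pairwise_mash, similarity_percent

rng = np.random.default_rng(1)
parent = synth.random_dna(20_000, 0.45, rng)
phages = {
    "vnp_like_A": parent,
    "vnp_like_B": synth.mutate_sequence(parent, 0.01, rng),
    "vnp_like_C": synth.mutate_sequence(parent, 0.08, rng),
    "unrelated": synth.random_dna(20_000, 0.45, rng),
}

matrix = pairwise_mash(list(phages), list(phages.values()))
print("pairwise Mash similarity (%):")
for i, a in enumerate(matrix.labels):
    for b in matrix.labels[i + 1 :]:
        sim = similarity_percent(matrix.get(a, b))
        print(f"  {a} vs {b}: {sim:5.1f}% {'(hit at >=70%)' if is_hit(sim) else ''}")

root = cluster(matrix)
print("dendrogram:", root.to_nested())

for other in ("vnp_like_B", "vnp_like_C", "unrelated"):
    value = ani(parent, phages[other])
    shown = "undefined" if value is None else f"{value:.1f}%"
    print(f"ANI parent vs {other}: {shown} -> {classify_species(value)} species")
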