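"""Generate a synthetic induction dataset and write it to standard formats.

Builds a 200-kb host chromosome carrying two prophages flanked by att
direct repeats, simulates supernatant-sequencing coverage after induction,
and writes FASTA (genome), BED (truth regions) and bedGraph (coverage).
The printed numbers are the ground truth later examples try to recover.
"""

from pathlib import Path

from prophagekit import io, synth

out = Path("scratch/example_data")
out.mkdir(parents=True, exist_ok=True)

truth = synth.generate_host_genome(seed=1)
coverage = synth.simulate_supernatant_coverage(truth, seed=1)

io.write_fasta([truth.genome], out / "host.fasta")
io.write_regions(truth.regions, out / "prophages.bed")
io.write_coverage(coverage, out / "supernatant.bedgraph")

print(f"chromosome: {len(truth.genome):,} bp with {len(truth.regions)} prophages")
for region in truth.regions:
    f = truth.induced_fraction[region.name]
    b = truth.burst_size[region.name]
    print(
        f"  {region.name}: {region.start:,}-{region.end:,} "
        f"({len(region):,} bp), att core {len(region.att_core)} bp, "
        f"induced fraction {f}, burst size {b:g} -> expected fold {1 + f * b:g}x"
    )
print(f"background depth {truth.background_depth:g}x; files in {out}/")
# The expected fold is 1 + induced_fraction * burst_size: phage DNA released
# by induced cells adds on top of the residual host-DNA background.
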