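"""Quantify spontaneous prophage induction (SPI) from a simulated qPCR plate.

The attB-junction assay only amplifies genomes that have excised the
prophage. Amounts are read off a standard curve (five 1:10 dilutions from
1 ng/ul), normalised to the thymidine-kinase reference gene, and expressed
relative to the prophage-free control, which carries the attB junction on
every genome and therefore defines 100%.
"""

from prophagekit import qpcr, synth

truth = synth.generate_host_genome(seed=1)
plate = synth.simulate_qpcr_plate(truth, seed=1)  # 0.15 cycles of Ct noise

curve = qpcr.fit_plate_curve(plate)
print(
    f"standard curve: slope {curve.slope:.4f} cycles/decade, "
    f"efficiency {100 * curve.efficiency:.1f}%, r2 {curve.r2:.4f}"
)

for region in truth.regions:
    target = f"{region.name.lower()}_attB"
    est = qpcr.spi_from_plate(plate, "wt_exp", "dvnp12_ctrl", target)
    print(
        f"{region.name}: SPI fraction {est:.3f}% "
        f"(truth {100 * truth.spi_fraction[region.name]:.2f}%)"
    )

control = qpcr.spi_from_plate(plate, "dvnp12_ctrl", "dvnp12_ctrl", "vnp1_attB")
print(f"fully induced control vs itself: {control:.1f}% (identity check)")
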