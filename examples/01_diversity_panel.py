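"""Per-locus diversity panel of the bundled 164-accession core collection.

The package ships the one genotype table the Akebia trifoliata survey
prints in full: the core collection's 11-marker identity cards.  Decoding
them gives a real 164 x 11 codominant matrix, whose diversity panel
(allele counts, effective alleles, observed/expected heterozygosity, Nei's
gene diversity, Shannon index, PIC) we compute here.
"""

from ssrcore import load_core164, locus_stats_table

matrix = load_core164()
print(matrix)

panel = locus_stats_table(matrix).round(4)
print(panel.to_string())

print(
    "\nThe 'Mean' row summarises the panel: mean PIC "
    f"{panel.loc['Mean', 'PIC']:.4f} is high (PIC > 0.5), as expected — "
    "these 11 markers were picked for discriminating power.  The gap "
    f"between Ho ({panel.loc['Mean', 'Ho']:.4f}) and He "
    f"({panel.loc['Mean', 'He']:.4f}) is the heterozygote deficit typical "
    "of a partially selfing collection."
)
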