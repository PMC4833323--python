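"""Composition and codon-usage statistics of a simulated genome.

Prints whole-genome base percentages, the A-T share of third codon
positions (the hallmark of these AT-rich mitogenomes), and the most and
least used codons.
"""

import mitopair as mp
from mitopair.composition import codon_usage, composition_table, round2
from mitopair.genome import extract_gene

genome, _ = mp.simulate_genome(mp.SimConfig(seed=1))
table = composition_table(genome).set_index("label")

whole = table.loc["Complete genome"]
print(f"complete genome: {int(whole['length'])} bp, "
      f"A-T {round2(whole['A-T'])}%")
pcgs = table.loc["All PCGs"]
print(f"all PCGs: {int(pcgs['length'])} bp, A-T3 {round2(pcgs['A-T3'])}% "
      "(third codon positions are strongly A-T biased)")

usage = codon_usage([extract_gene(genome, f) for f in genome.genes("PCG")])
frame = usage.to_frame().sort_values("count", ascending=False)
top, bottom = frame.iloc[0], frame.iloc[-1]
print(f"{usage.total} codons in total; most used {top['codon']} "
      f"({top['count']} hits, {top['percent']:.2f}%), least used "
      f"{bottom['codon']} ({bottom['count']} hits)")
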