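"""Genetic-code lookups built on the NCBI translation tables.

The invertebrate mitochondrial code (translation table 5) is the default
throughout: AGA/AGG encode serine, TGA encodes tryptophan, and a broad set of
alternative start codons is in use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable

__all__ = ["GeneticCode", "INVERTEBRATE_MITO", "STOP"]

STOP = "*"
BASES = "ACGT"

#: Alternative start codons observed in bivalve mitogenome annotations
#: (the union of the ATN/GTG/TTG set).
ALT_STARTS = frozenset({"ATG", "ATA", "ATT", "ATC", "GTG", "TTG"})


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino acid map with its start-codon set.

    ``table[codon]`` maps every one of the 64 codons to a one-letter amino
    acid, stop codons to ``'*'``.
    """

    id: int
    table: dict[str, str] = field(repr=False)
    start_codons: frozenset[str]

    @classmethod
    def from_ncbi(cls, table_id: int = 5) -> "GeneticCode":
        ncbi = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(ncbi.forward_table)
        for codon in ncbi.stop_codons:
            table[codon] = STOP
        assert len(table) == 64
        starts = frozenset(ncbi.start_codons)
        if table_id == 5:
            starts = starts | ALT_STARTS
        return cls(id=table_id, table=table, start_codons=starts)

    def translate(self, cds: str) -> str:
        if len(cds) % 3:
            raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
        cds = cds.upper()
        return "".join(
            self.table.get(cds[i : i + 3], "X") for i in range(0, len(cds), 3)
        )

    def is_stop(self, codon: str) -> bool:
        return self.table.get(codon.upper()) == STOP

    def fourfold_prefixes(self) -> frozenset[str]:
        """Dinucleotide prefixes whose codon family is four-fold degenerate.

        A prefix qualifies when all four third bases give one and the same
        amino acid; stop-containing families are excluded by construction.
        """
        out = set()
        for p1, p2 in product(BASES, repeat=2):
            aas = {self.table[p1 + p2 + b] for b in BASES}
            if len(aas) == 1 and STOP not in aas:
                out.add(p1 + p2)
        return frozenset(out)


INVERTEBRATE_MITO = GeneticCode.from_ncbi(5)
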