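"""Nucleotide composition, codon usage and simple ORF extraction.

Percentages are kept at full precision in memory; the two-decimal, half-up
rounding of published composition tables is applied only when formatting
(:func:`round2`).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .codes import BASES, GeneticCode, INVERTEBRATE_MITO
from .genome import AnnotatedGenome, GeneFeature, extract_gene, reverse_complement

__all__ = [
    "CompositionRow",
    "CodonUsageTable",
    "nucleotide_composition",
    "third_position_composition",
    "codon_usage",
    "start_stop_table",
    "find_orfs",
    "round2",
]


def round2(x: float) -> float:
    """Two-decimal half-up rounding (the convention of printed tables)."""
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class CompositionRow:
    """Base percentages of a sequence, over unambiguous bases only."""

    label: str
    length: int
    pct_T: float
    pct_C: float
    pct_A: float
    pct_G: float

    @property
    def pct_AT(self) -> float:
        return self.pct_A + self.pct_T

    def as_dict(self) -> dict[str, float]:
        return {
            "label": self.label,
            "length": self.length,
            "T": self.pct_T,
            "C": self.pct_C,
            "A": self.pct_A,
            "G": self.pct_G,
            "A-T": self.pct_AT,
        }


def nucleotide_composition(seq: str, label: str = "") -> CompositionRow:
    """Percent A/C/G/T of a sequence; ambiguity codes are excluded from counts."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in BASES}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    pct = {b: 100.0 * counts[b] / total for b in BASES}
    return CompositionRow(label, len(seq), pct["T"], pct["C"], pct["A"], pct["G"])


def third_position_composition(cds: str, label: str = "") -> CompositionRow:
    """Composition over third codon positions of an in-frame CDS."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    row = nucleotide_composition(cds.upper()[2::3], label)
    return CompositionRow(label, len(cds), row.pct_T, row.pct_C, row.pct_A, row.pct_G)


@dataclass
class CodonUsageTable:
    """Counts and usage percentages over all 64 codons (stop codons included)."""

    counts: dict[str, int]
    code: GeneticCode

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percent(self, codon: str) -> float:
        return 100.0 * self.counts[codon.upper().replace("U", "T")] / self.total

    def count(self, codon: str) -> int:
        return self.counts[codon.upper().replace("U", "T")]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for codon, n in self.counts.items():
            rows.append(
                {
                    "aa": self.code.table[codon],
                    "codon": codon.replace("T", "U"),
                    "count": n,
                    "percent": 100.0 * n / self.total,
                }
            )
        return pd.DataFrame(rows).sort_values(["aa", "codon"]).reset_index(drop=True)


def codon_usage(
    cds_set: list[str] | str, code: GeneticCode = INVERTEBRATE_MITO
) -> CodonUsageTable:
    if isinstance(cds_set, str):
        cds_set = [cds_set]
    counts = {a + b + c: 0 for a in BASES for b in BASES for c in BASES}
    for cds in cds_set:
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if codon in counts:  # skip codons with ambiguity codes
                counts[codon] += 1
    return CodonUsageTable(counts, code)


def start_stop_table(
    genome: AnnotatedGenome, code: GeneticCode = INVERTEBRATE_MITO
) -> pd.DataFrame:
    """First and last codon of every protein-coding gene."""
    rows = []
    for f in genome.genes("PCG"):
        seq = extract_gene(genome, f)
        rows.append(
            {
                "gene": f.name,
                "start_codon": seq[:3],
                "stop_codon": seq[-3:],
                "start_is_canonical": seq[:3] in code.start_codons,
                "stop_is_valid": code.is_stop(seq[-3:]),
            }
        )
    return pd.DataFrame(rows)


def find_orfs(
    seq: str,
    code: GeneticCode = INVERTEBRATE_MITO,
    min_codons: int = 30,
    strands: str = "both",
) -> list[GeneFeature]:
    """Maximal start-to-stop open reading frames on one or both strands.

    For every stop codon the longest upstream in-frame start (i.e. the
    earliest one after the previous stop) is reported, so each stop yields at
    most one ORF per strand. Lengths are counted in sense codons, the stop
    excluded; coordinates are 1-based on the forward strand. Only
    stop-terminated ORFs qualify.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    seq = seq.upper()
    n = len(seq)
    out: list[GeneFeature] = []
    todo = {"+": seq}
    if strands == "both":
        todo["-"] = reverse_complement(seq)
    elif strands == "-":
        todo = {"-": reverse_complement(seq)}
    for strand, s in todo.items():
        for frame in range(3):
            prev_stop_end = frame  # exclusive left bound of the current segment
            for i in range(frame, n - 2, 3):
                codon = s[i : i + 3]
                if not code.is_stop(codon):
                    continue
                start = _first_start(s, prev_stop_end, i, code)
                prev_stop_end = i + 3
                if start is None:
                    continue
                ncod = (i - start) // 3
                if ncod < min_codons:
                    continue
                lo, hi = start, i + 3  # 0-based half-open on this strand
                if strand == "-":
                    lo, hi = n - hi, n - lo
                out.append(
                    GeneFeature(
                        name=f"ORF{ncod}",
                        kind="ORF",
                        start=lo + 1,
                        end=hi,
                        strand=strand,
                        start_codon=s[start : start + 3],
                        stop_codon=codon,
                    )
                )
    return sorted(out, key=lambda f: (f.start, f.end, f.strand))


def _first_start(s: str, lo: int, hi: int, code: GeneticCode) -> int | None:
    for i in range(lo, hi, 3):
        if s[i : i + 3] in code.start_codons:
            return i
    return None


def composition_table(
    genome: AnnotatedGenome, code: GeneticCode = INVERTEBRATE_MITO
) -> pd.DataFrame:
    """Per-gene and aggregate composition rows, third positions for PCGs.

    Mirrors the layout of published mitogenome composition tables: one row
    per gene, then concatenation rows for all PCGs / rRNAs / tRNAs / coding
    DNA / unassigned regions / the complete genome.
    """
    from .genome import unassigned_regions

    def row(label: str, seq: str, third: bool) -> dict:
        d = nucleotide_composition(seq, label).as_dict()
        if third:
            t = third_position_composition(seq, label)
            d.update(
                {"T3": t.pct_T, "C3": t.pct_C, "A3": t.pct_A, "G3": t.pct_G, "A-T3": t.pct_AT}
            )
        d["length"] = len(seq)
        return d

    rows = []
    groups: dict[str, list[str]] = {"PCG": [], "rRNA": [], "tRNA": []}
    for f in genome.features:
        seq = extract_gene(genome, f)
        if f.kind in groups:
            groups[f.kind].append(seq)
        if f.kind == "ORF":
            continue
        rows.append(row(f.name, seq, third=f.kind == "PCG"))
    rows.append(row("All PCGs", "".join(groups["PCG"]), third=True))
    if groups["rRNA"]:
        rows.append(row("All rRNAs", "".join(groups["rRNA"]), third=False))
    if groups["tRNA"]:
        rows.append(row("All tRNAs", "".join(groups["tRNA"]), third=False))
    coding = "".join(groups["PCG"] + groups["rRNA"] + groups["tRNA"])
    rows.append(row("All coding DNA", coding, third=False))
    urs = [
        genome.sequence[u.start - 1 : u.end] if u.end >= u.start
        else genome.sequence[u.start - 1 :] + genome.sequence[: u.end]
        for u in unassigned_regions(genome)
        if u.length > 0
    ]
    if urs:
        rows.append(row("All URs", "".join(urs), third=False))
    rows.append(row("Complete genome", genome.sequence, third=False))
    return pd.DataFrame(rows)
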