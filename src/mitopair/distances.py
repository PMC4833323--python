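"""Pairwise corrected distances between homologous genes.

Two corrections of the raw proportion of differing sites are implemented:

* the Jin–Nei gamma nucleotide distance, a two-parameter
  (transition/transversion) distance with gamma-distributed rate variation
  across sites (shape ``a``),

      d = (a/2) * [ (1-2P-Q)^(-1/a) + (1/2)(1-2Q)^(-1/a) - 3/2 ]

  where P and Q are the transition and transversion proportions, and

* the Kimura amino-acid distance,

      d = -ln(1 - p - 0.2 p^2),

  a closed-form correction of the amino-acid p-distance, undefined (the pair
  is "too divergent") once the log argument reaches zero, at p ~ 0.8541.

Gap and ambiguity columns are removed pairwise (a column is dropped when
either sequence carries one). Distances are reported multiplied by 100, the
scale on which comparative mitogenome tables print them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .codes import GeneticCode, INVERTEBRATE_MITO
from .genome import AnnotatedGenome, extract_gene

__all__ = [
    "AlignedPair",
    "PairCounts",
    "DistanceResult",
    "align_pair",
    "pair_counts",
    "jin_nei_gamma",
    "kimura_protein",
    "gene_distance_table",
    "group_averages",
    "KIMURA_MAX_P",
]

_NT = set("ACGT")
_AA = set("ACDEFGHIKLMNPQRSTVWY")
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}

#: Largest amino-acid p-distance for which the Kimura correction is defined
#: (positive root of 0.2 p^2 + p - 1 = 0).
KIMURA_MAX_P = (math.sqrt(1 + 4 * 0.2) - 1) / (2 * 0.2)


@dataclass(frozen=True)
class AlignedPair:
    """Two equal-length gapped sequences plus their alphabet ('nt' or 'aa')."""

    a: str
    b: str
    alphabet: str = "nt"

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("aligned sequences must have equal length")
        if self.alphabet not in ("nt", "aa"):
            raise ValueError("alphabet must be 'nt' or 'aa'")

    def __add__(self, other: "AlignedPair") -> "AlignedPair":
        if self.alphabet != other.alphabet:
            raise ValueError("cannot concatenate alignments over different alphabets")
        return AlignedPair(self.a + other.a, self.b + other.b, self.alphabet)


@dataclass(frozen=True)
class PairCounts:
    """Comparable-site count with difference / transition / transversion rates."""

    n: int
    p: float  # proportion of differing comparable sites
    P: float  # transition proportion (nucleotide alphabets only)
    Q: float  # transversion proportion


def align_pair(
    a: str,
    b: str,
    alphabet: str = "nt",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> AlignedPair:
    """Global affine-gap alignment of two unaligned sequences.

    Nucleotide scoring is match/mismatch; amino-acid scoring uses BLOSUM62.
    This is a stand-in for curated multi-aligner consensus alignments: for
    published-table reproduction, feed pre-aligned sequences straight to
    :func:`pair_counts` instead. The first optimal traceback is returned,
    which is deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "nt":
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    else:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        gap_open, gap_extend = -10.0, -1.0
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a.upper(), b.upper())[0]
    ga, gb = aln[0], aln[1]
    return AlignedPair(ga, gb, alphabet)


def pair_counts(pair: AlignedPair) -> PairCounts:
    """Site counts under pairwise deletion of gap/ambiguity columns."""
    valid = _NT if pair.alphabet == "nt" else _AA
    n = diff = ts = 0
    for x, y in zip(pair.a, pair.b):
        if x not in valid or y not in valid:
            continue
        n += 1
        if x != y:
            diff += 1
            if frozenset((x, y)) in _TRANSITIONS:
                ts += 1
    if n == 0:
        raise ValueError("no comparable columns after pairwise deletion")
    if pair.alphabet == "aa":
        return PairCounts(n, diff / n, 0.0, 0.0)
    return PairCounts(n, diff / n, ts / n, (diff - ts) / n)


def jin_nei_gamma(counts: PairCounts, a: float = 1.0) -> float:
    """Jin–Nei gamma-corrected nucleotide distance, times 100.

    Returns NaN when the correction is undefined (1-2P-Q <= 0 or
    1-2Q <= 0), i.e. the sequences are too divergent.
    """
    if a <= 0:
        raise ValueError("gamma shape must be positive")
    u = 1.0 - 2.0 * counts.P - counts.Q
    v = 1.0 - 2.0 * counts.Q
    if u <= 0.0 or v <= 0.0:
        return math.nan
    d = (a / 2.0) * (u ** (-1.0 / a) + 0.5 * v ** (-1.0 / a) - 1.5)
    return 100.0 * d


def kimura_protein(counts: PairCounts) -> float:
    """Kimura-corrected amino-acid distance, times 100; NaN when too divergent."""
    p = counts.p
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0:
        return math.nan
    return -100.0 * math.log(arg)


@dataclass(frozen=True)
class DistanceResult:
    label: str
    n_sites: int
    p_distance: float  # percent
    jn_distance: float  # x100; NaN if too divergent
    kimura_aa: float | None = None  # x100; NaN if too divergent; None if not a PCG

    @property
    def too_divergent(self) -> bool:
        return math.isnan(self.jn_distance) or (
            self.kimura_aa is not None and math.isnan(self.kimura_aa)
        )


CONCATENATIONS = ("All coding DNA", "PCGs", "rRNAs", "tRNAs")


def gene_distance_table(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    gene_sets: dict[str, list[str]] | None = None,
    code: GeneticCode = INVERTEBRATE_MITO,
    gamma_a: float = 1.0,
    aligned_pairs: dict[str, AlignedPair] | None = None,
) -> pd.DataFrame:
    """Per-gene and concatenation distances between two annotated genomes.

    Genes are matched by name; a gene absent from either genome yields an
    absent (NaN) column, mirroring unannotated genes in published tables.
    Protein-coding genes additionally carry a translated Kimura amino-acid
    distance. Concatenations ("All coding DNA", "PCGs", "rRNAs", "tRNAs")
    concatenate the per-gene alignments before counting. Pre-computed
    alignments may be supplied per gene via ``aligned_pairs``.

    Returns a tidy DataFrame with one row per label and columns
    ``label, kind, n_sites, p_distance, jn_distance, kimura_aa, too_divergent``.
    """
    names_a = {f.name: f for f in genome_a.features if f.kind != "ORF"}
    names_b = {f.name: f for f in genome_b.features if f.kind != "ORF"}
    if gene_sets is None:
        gene_sets = {}
        for kind in ("PCG", "rRNA", "tRNA"):
            gene_sets[kind] = [
                n for n, f in names_a.items() if f.kind == kind and n in names_b
            ]
    rows = []
    nt_by_kind: dict[str, list[AlignedPair]] = {"PCG": [], "rRNA": [], "tRNA": []}
    aa_parts: list[AlignedPair] = []
    all_names = [n for kind in ("PCG", "rRNA", "tRNA") for n in gene_sets.get(kind, [])]
    absent = sorted(
        (set(names_a) | set(names_b)) - set(all_names), key=lambda n: n
    )
    for kind in ("PCG", "rRNA", "tRNA"):
        for name in gene_sets.get(kind, []):
            sa = extract_gene(genome_a, names_a[name])
            sb = extract_gene(genome_b, names_b[name])
            if aligned_pairs and name in aligned_pairs:
                pair = aligned_pairs[name]
            else:
                pair = align_pair(sa, sb, "nt")
            nt_by_kind[kind].append(pair)
            counts = pair_counts(pair)
            kim = None
            if kind == "PCG":
                aa_pair = align_pair(
                    code.translate(sa).rstrip("*"), code.translate(sb).rstrip("*"), "aa"
                )
                aa_parts.append(aa_pair)
                kim = kimura_protein(pair_counts(aa_pair))
            rows.append(
                _result_row(name, kind, counts, jin_nei_gamma(counts, gamma_a), kim)
            )
    for name in absent:
        rows.append(
            {
                "label": name,
                "kind": (names_a.get(name) or names_b.get(name)).kind,
                "n_sites": 0,
                "p_distance": math.nan,
                "jn_distance": math.nan,
                "kimura_aa": math.nan,
                "too_divergent": False,
            }
        )
    # concatenations of the per-gene alignments
    coding = nt_by_kind["PCG"] + nt_by_kind["rRNA"] + nt_by_kind["tRNA"]
    concat_specs = [
        ("All coding DNA", coding, None),
        ("PCGs", nt_by_kind["PCG"], aa_parts),
        ("rRNAs", nt_by_kind["rRNA"], None),
        ("tRNAs", nt_by_kind["tRNA"], None),
    ]
    for label, parts, aa in concat_specs:
        if not parts:
            continue
        whole = parts[0]
        for p in parts[1:]:
            whole = whole + p
        counts = pair_counts(whole)
        kim = None
        if aa:
            whole_aa = aa[0]
            for p in aa[1:]:
                whole_aa = whole_aa + p
            kim = kimura_protein(pair_counts(whole_aa))
        rows.append(
            _result_row(label, "concat", counts, jin_nei_gamma(counts, gamma_a), kim)
        )
    return pd.DataFrame(rows)


def _result_row(label, kind, counts, jn, kim):
    return {
        "label": label,
        "kind": kind,
        "n_sites": counts.n,
        "p_distance": 100.0 * counts.p,
        "jn_distance": jn,
        "kimura_aa": math.nan if kim is None else kim,
        "too_divergent": math.isnan(jn) or (kim is not None and math.isnan(kim)),
    }


def group_averages(
    table: pd.DataFrame, groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Unweighted arithmetic mean of distance columns per species group.

    ``table`` is indexed by species (rows) with numeric distance columns;
    missing cells are skipped, so a group mean over k present values divides
    by k. Raises on an empty group.
    """
    out = {}
    for label, members in groups.items():
        if not members:
            raise ValueError(f"group {label!r} is empty")
        sub = table.loc[members]
        out[f"{label} (N = {len(members)})"] = sub.mean(axis=0, skipna=True)
    return pd.DataFrame(out).T
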