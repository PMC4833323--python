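"""Data model and I/O for annotated circular mitochondrial genomes.

Coordinates follow the convention of mitogenome annotation tables: 1-based,
inclusive on both ends. A feature whose ``end`` is smaller than its ``start``
wraps past the origin of the circle (such features arise from rotation and
simulation; deposited annotations are usually rotated so that none exist).
All coordinate arithmetic is funnelled through :func:`_span_length` and the
``start0`` helpers so that the 1-based shift happens in exactly one place.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "AnnotatedGenome",
    "UnassignedRegion",
    "GenomeValidationError",
    "ParseError",
    "parse_genome",
    "write_genome",
    "extract_gene",
    "unassigned_regions",
    "rotate_genome",
]

FEATURE_KINDS = ("PCG", "tRNA", "rRNA", "ORF")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeValidationError(ValueError):
    """An annotation is inconsistent with the sequence or the topology."""


class ParseError(ValueError):
    """A record could not be parsed."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a (possibly circular) mitogenome.

    ``start``/``end`` are 1-based inclusive; ``end < start`` means the span
    wraps past the origin. ``partial`` relaxes the in-frame length check for
    protein-coding genes.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None
    partial: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise GenomeValidationError(
                f"feature {self.name!r}: kind {self.kind!r} not in {FEATURE_KINDS}"
            )
        if self.strand not in "+-":
            raise GenomeValidationError(
                f"feature {self.name!r}: strand must be '+' or '-'"
            )
        if self.start < 1 or self.end < 1:
            raise GenomeValidationError(
                f"feature {self.name!r}: coordinates are 1-based and positive"
            )

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def span_length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    @property
    def start0(self) -> int:
        """0-based index of the first base (the only 1-based -> 0-based shift)."""
        return self.start - 1


@dataclass(frozen=True)
class UnassignedRegion:
    """Intergenic bases after a gene; negative length counts an overlap."""

    after_gene: str
    start: int
    end: int
    length: int


@dataclass
class AnnotatedGenome:
    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    topology: str = "circular"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.topology not in ("circular", "linear"):
            raise GenomeValidationError(f"unknown topology {self.topology!r}")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        self._validate()

    def _validate(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            if f.start > n or f.end > n:
                raise GenomeValidationError(
                    f"feature {f.name!r} ({f.start}..{f.end}) lies beyond the "
                    f"{n} bp sequence"
                )
            if f.wraps and self.topology == "linear":
                raise GenomeValidationError(
                    f"feature {f.name!r} has end < start on a linear sequence"
                )
            if f.kind == "PCG" and not f.partial and f.span_length(n) % 3:
                raise GenomeValidationError(
                    f"PCG {f.name!r} span ({f.span_length(n)} bp) is not a "
                    "multiple of 3"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"gene {name!r} not annotated on genome {self.id!r}")

    def genes(self, kind: str | None = None) -> list[GeneFeature]:
        if kind is None:
            return list(self.features)
        return [f for f in self.features if f.kind == kind]


def extract_gene(genome: AnnotatedGenome, feature: GeneFeature | str) -> str:
    """Return the gene sequence; '-' strand features are reverse-complemented.

    Wrap-around spans concatenate the tail of the sequence with its head.
    """
    if isinstance(feature, str):
        feature = genome.feature(feature)
    span = feature.span_length(genome.length)
    doubled = genome.sequence + genome.sequence
    sub = doubled[feature.start0 : feature.start0 + span]
    if feature.strand == "-":
        sub = reverse_complement(sub)
    return sub


def unassigned_regions(genome: AnnotatedGenome) -> list[UnassignedRegion]:
    """Gaps (or overlaps, as negative lengths) after each gene, around the circle.

    Between consecutive features the gap is ``next.start - this.end - 1``; at
    the wrap the next start is carried once around the circle. The positive
    gaps, feature coverage and overlaps together tile the genome exactly.
    """
    if not genome.features:
        raise GenomeValidationError("genome has no features")
    n = genome.length
    feats = genome.features
    out: list[UnassignedRegion] = []
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        unwrapped_end = f.start + f.span_length(n) - 1  # may exceed n
        next_start = nxt.start if i + 1 < len(feats) else nxt.start + n
        gap = next_start - unwrapped_end - 1
        ur_start = unwrapped_end % n + 1
        ur_end = (next_start - 2) % n + 1
        out.append(UnassignedRegion(f.name, ur_start, ur_end, gap))
    return out


def rotate_genome(genome: AnnotatedGenome, anchor_gene: str) -> AnnotatedGenome:
    """Rotate the circle so that ``anchor_gene`` starts at position 1."""
    if genome.topology != "circular":
        raise GenomeValidationError("only circular genomes can be rotated")
    anchor = genome.feature(anchor_gene)  # KeyError if absent
    off = anchor.start0
    n = genome.length
    seq = genome.sequence[off:] + genome.sequence[:off]
    feats = [
        replace(
            f,
            start=(f.start0 - off) % n + 1,
            end=(f.end - 1 - off) % n + 1,
        )
        for f in genome.features
    ]
    return AnnotatedGenome(genome.id, seq, feats, topology="circular")


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = (
    "name",
    "kind",
    "start",
    "end",
    "strand",
    "anticodon",
    "start_codon",
    "stop_codon",
)

_GB_KIND = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "ORF": "misc_feature"}
_GB_KIND_INV = {v: k for k, v in _GB_KIND.items()}


def parse_genome(
    path: str | Path,
    features_path: str | Path | None = None,
    id: str | None = None,
) -> AnnotatedGenome:
    """Read an annotated genome from GenBank, or from FASTA plus a feature TSV.

    With a single argument the file is parsed as a GenBank flat file; with
    ``features_path`` the first argument is a FASTA file and the second a
    tab-separated feature table (columns: name, kind, start, end, strand,
    anticodon, start_codon, stop_codon).
    """
    path = Path(path)
    if features_path is not None:
        return _parse_fasta_tsv(path, Path(features_path), id=id)
    return _parse_genbank(path, id=id)


def _parse_genbank(path: Path, id: str | None = None) -> AnnotatedGenome:
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError) as exc:
        raise ParseError(f"{path}: not a readable GenBank record ({exc})") from exc
    topology = record.annotations.get("topology", "circular")
    n = len(record.seq)
    feats = []
    for sf in record.features:
        if sf.type not in _GB_KIND_INV:
            continue
        q = sf.qualifiers
        name = (q.get("gene") or q.get("product") or q.get("note") or ["?"])[0]
        start, end = _location_to_coords(sf, n, path)
        feats.append(
            GeneFeature(
                name=name,
                kind=_GB_KIND_INV[sf.type],
                start=start,
                end=end,
                strand="-" if sf.location.strand == -1 else "+",
                anticodon=(q.get("anticodon") or [None])[0],
                start_codon=(q.get("start_codon") or [None])[0],
                stop_codon=(q.get("stop_codon") or [None])[0],
                partial=bool(q.get("partial")),
            )
        )
    return AnnotatedGenome(id or record.id, str(record.seq), feats, topology)


def _location_to_coords(sf: SeqFeature, n: int, path: Path) -> tuple[int, int]:
    loc = sf.location
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) == 2 and int(parts[-1].end) == n and int(parts[0].start) == 0:
            # join(x..n, 1..y): a span wrapping the origin
            return int(parts[1].start) + 1, int(parts[0].end)
        raise ParseError(f"{path}: unsupported compound location {loc}")
    return int(loc.start) + 1, int(loc.end)


def _parse_fasta_tsv(path: Path, features_path: Path, id: str | None) -> AnnotatedGenome:
    try:
        record = next(SeqIO.parse(str(path), "fasta"))
    except (StopIteration, ValueError) as exc:
        raise ParseError(f"{path}: not a readable FASTA record ({exc})") from exc
    feats = read_feature_table(features_path)
    return AnnotatedGenome(id or record.id, str(record.seq), feats)


def read_feature_table(path: str | Path) -> list[GeneFeature]:
    feats = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(("name", "kind", "start", "end")) - set(reader.fieldnames or ())
        if missing:
            raise ParseError(f"{path}: feature table lacks columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                feats.append(
                    GeneFeature(
                        name=row["name"],
                        kind=row["kind"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        strand=row.get("strand") or "+",
                        anticodon=row.get("anticodon") or None,
                        start_codon=row.get("start_codon") or None,
                        stop_codon=row.get("stop_codon") or None,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    return feats


def write_genome(
    genome: AnnotatedGenome,
    path: str | Path,
    features_path: str | Path | None = None,
) -> None:
    """Write GenBank (default) or, with ``features_path``, FASTA + feature TSV."""
    path = Path(path)
    if features_path is not None:
        with open(path, "w") as fh:
            fh.write(f">{genome.id}\n")
            for i in range(0, genome.length, 70):
                fh.write(genome.sequence[i : i + 70] + "\n")
        write_feature_table(genome.features, features_path)
        return
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16],
        description="",
        annotations={"molecule_type": "DNA", "topology": genome.topology},
    )
    n = genome.length
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start0, n, strand),
                    SimpleLocation(0, f.end, strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start0, f.end, strand)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        for key in ("anticodon", "start_codon", "stop_codon"):
            val = getattr(f, key)
            if val:
                quals[key] = [val]
        if f.partial:
            quals["partial"] = ["true"]
        record.features.append(SeqFeature(loc, type=_GB_KIND[f.kind], qualifiers=quals))
    SeqIO.write(record, str(path), "genbank")


def write_feature_table(features: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TSV_COLUMNS)
        for f in features:
            writer.writerow(
                [
                    f.name,
                    f.kind,
                    f.start,
                    f.end,
                    f.strand,
                    f.anticodon or "",
                    f.start_codon or "",
                    f.stop_codon or "",
                ]
            )
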