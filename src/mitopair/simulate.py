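"""Synthetic annotated mitogenome pairs with known ground truth.

The generator emulates the statistical structure of a venerid-style doubly
uniparental inheritance (DUI) mitogenome pair: a ~20 kb circular molecule
with 13 protein-coding genes, 2 rRNAs and 22 tRNAs all on the "+" strand
(the default roster transcribes a published venerid F annotation), A-T-rich
third codon positions, a long unassigned region (LUR) with tandem repeats
and an optional planted reverse-strand ORF, an optional linear composition
trend at third codon positions (the replication-origin signature the
sliding-window method is designed to detect), and an F/M pair diverged under
a two-parameter (transition/transversion) substitution process with
gamma-distributed rate variation, amino-acid-preserving rejection at a
configurable fraction of codons, an in-frame insertion in the M copy of
cox2, and an M-only supernumerary tRNA whose decayed homolog is left in the
F LUR.

Everything emitted is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .codes import BASES, GeneticCode, INVERTEBRATE_MITO
from .distances import AlignedPair, PairCounts
from .genome import AnnotatedGenome, GeneFeature, read_feature_table

__all__ = [
    "TrendSpec",
    "RepeatSpec",
    "DivergenceSpec",
    "SimConfig",
    "SimTruth",
    "default_roster",
    "simulate_genome",
    "evolve_pair",
    "make_aligned_pair",
]


@dataclass(frozen=True)
class TrendSpec:
    """Linear composition trend injected at third codon positions.

    ``slope`` is in percent per bp of distance from the start of ``anchor``
    (measured forward around the circle), the same units in which the
    sliding-window regression reports its slopes.
    """

    nucleotide: str = "C"
    slope: float = 0.0005
    anchor: str = "cox3"


@dataclass(frozen=True)
class RepeatSpec:
    """A tandem repeat planted in the long unassigned region."""

    motif_length: int = 109
    copies: int = 2
    at: str = "end"  # 'start' or 'end' of the LUR


@dataclass(frozen=True)
class DivergenceSpec:
    """Two-parameter substitution regime between the F and M copies."""

    expected_distance: float = 0.50  # expected substitutions/site (pre-rejection)
    kappa: float = 2.0  # transition/transversion rate ratio
    gamma_shape: float | None = 1.0  # None = uniform rates
    constrained_fraction: float = 0.7  # codons restricted to synonymous change


@dataclass
class SimConfig:
    seed: int = 0
    roster: list[GeneFeature] | None = None
    genome_length: int = 20025
    # base sampling profiles, order A,C,G,T
    third_pos_profile: tuple = (0.21, 0.05, 0.21, 0.53)
    codon_pos1_profile: tuple = (0.22, 0.11, 0.24, 0.43)
    codon_pos2_profile: tuple = (0.20, 0.15, 0.20, 0.45)
    noncoding_profile: tuple = (0.26, 0.08, 0.26, 0.40)
    structural_rna_profile: tuple = (0.29, 0.10, 0.22, 0.39)
    trend: TrendSpec | None = None
    lur_repeats: tuple = (RepeatSpec(15, 2, "start"), RepeatSpec(109, 2, "end"))
    planted_orf_codons: int | None = None
    divergence: DivergenceSpec = field(default_factory=DivergenceSpec)
    cox2_insertion_codons: int = 100
    extra_trna: bool = True
    code: GeneticCode = field(default_factory=lambda: INVERTEBRATE_MITO)


@dataclass
class SimTruth:
    """Ground truth for everything the generator planted."""

    trend: TrendSpec | None = None
    repeats: list[tuple[int, int, str]] = field(default_factory=list)
    planted_orf: tuple[int, int, str] | None = None
    cox2_insertion: tuple[int, int] | None = None
    extra_trna: tuple[int, int] | None = None
    divergence: DivergenceSpec | None = None


def default_roster() -> list[GeneFeature]:
    ref = resources.files("mitopair.data").joinpath("venerid_f_roster.tsv")
    with resources.as_file(ref) as p:
        return read_feature_table(p)


def _sample(rng: np.random.Generator, profile, n: int) -> np.ndarray:
    return rng.choice(4, size=n, p=np.asarray(profile) / np.sum(profile))


_IDX = {b: i for i, b in enumerate(BASES)}


def _decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def simulate_genome(cfg: SimConfig) -> tuple[AnnotatedGenome, SimTruth]:
    """Generate one annotated circular genome according to the config."""
    rng = np.random.default_rng(cfg.seed)
    return _simulate_genome(cfg, rng)


def _simulate_genome(cfg: SimConfig, rng: np.random.Generator):
    roster = cfg.roster or default_roster()
    L = cfg.genome_length
    if max(f.end for f in roster) > L:
        raise ValueError("roster extends beyond the configured genome length")
    seq = _sample(rng, cfg.noncoding_profile, L)
    truth = SimTruth(trend=cfg.trend, divergence=cfg.divergence)

    # structural RNAs first, protein-coding genes last so overlapping
    # annotations never corrupt a reading frame
    for f in roster:
        if f.kind in ("tRNA", "rRNA"):
            seq[f.start0 : f.end] = _sample(rng, cfg.structural_rna_profile, f.end - f.start0)
    trend_anchor0 = None
    if cfg.trend is not None:
        trend_anchor0 = next(f for f in roster if f.name == cfg.trend.anchor).start0
    for f in roster:
        if f.kind == "PCG":
            seq[f.start0 : f.end] = _pcg_codons(cfg, rng, f, L, trend_anchor0)

    # long unassigned region = largest gap between consecutive roster genes
    lur_start0, lur_end0 = _largest_gap(roster, L)
    _plant_lur(cfg, rng, seq, lur_start0, lur_end0, truth)

    genome = AnnotatedGenome("sim", _decode(seq), list(roster))
    return genome, truth


def _pcg_codons(cfg, rng, f: GeneFeature, L: int, trend_anchor0):
    span = f.end - f.start0
    ncod = span // 3
    b1 = _sample(rng, cfg.codon_pos1_profile, ncod)
    b2 = _sample(rng, cfg.codon_pos2_profile, ncod)
    if cfg.trend is None:
        b3 = _sample(rng, cfg.third_pos_profile, ncod)
    else:
        x = (f.start0 + 3 * np.arange(ncod) + 2 - trend_anchor0) % L
        p = np.tile(np.asarray(cfg.third_pos_profile, dtype=float), (ncod, 1))
        t = _IDX[cfg.trend.nucleotide.upper()]
        delta = (cfg.trend.slope / 100.0) * x
        others = p[:, [j for j in range(4) if j != t]].sum(axis=1)
        newp = np.clip(p[:, t] + delta, 0.005, 0.95)
        scale = (1.0 - newp) / others
        for j in range(4):
            p[:, j] = newp if j == t else p[:, j] * scale
        u = rng.random(ncod)
        b3 = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    # never emit an in-frame stop (TAA/TAG): resample offending third bases
    stop = (b1 == _IDX["T"]) & (b2 == _IDX["A"]) & ((b3 == _IDX["A"]) | (b3 == _IDX["G"]))
    if stop.any():
        b3[stop] = np.where(rng.random(int(stop.sum())) < 0.5, _IDX["T"], _IDX["C"])
    codons = np.empty(span, dtype=np.int64)
    codons[0::3], codons[1::3], codons[2::3] = b1, b2, b3
    start = f.start_codon or "ATG"
    stop_codon = f.stop_codon or "TAA"
    codons[:3] = [_IDX[c] for c in start]
    codons[-3:] = [_IDX[c] for c in stop_codon]
    return codons


def _largest_gap(roster: list[GeneFeature], L: int) -> tuple[int, int]:
    feats = sorted(roster, key=lambda f: f.start)
    best = (0, 0)
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        nxt_start = nxt.start if i + 1 < len(feats) else nxt.start + L
        gap = nxt_start - f.end - 1
        if gap > best[1] - best[0]:
            best = (f.end, f.end + gap)  # 0-based half-open
    return best


def _plant_lur(cfg, rng, seq, lo: int, hi: int, truth: SimTruth) -> None:
    cursor_start, cursor_end = lo, hi
    for spec in cfg.lur_repeats:
        motif = _sample(rng, cfg.noncoding_profile, spec.motif_length)
        block = np.tile(motif, spec.copies)
        if spec.at == "start":
            a = cursor_start
            cursor_start += len(block) + 5
        else:
            a = cursor_end - len(block)
            cursor_end = a - 5
        seq[a : a + len(block)] = block
        truth.repeats.append((a + 1, a + len(block), _decode(motif)))
    if cfg.planted_orf_codons:
        n = cfg.planted_orf_codons
        length = 3 * (n + 1)  # sense codons + stop
        if cursor_end - cursor_start < length:
            raise ValueError("LUR too small for the requested planted ORF")
        body1 = _sample(rng, cfg.codon_pos1_profile, n - 1)
        body2 = _sample(rng, cfg.codon_pos2_profile, n - 1)
        body3 = _sample(rng, cfg.third_pos_profile, n - 1)
        stop = (body1 == _IDX["T"]) & (body2 == _IDX["A"]) & (
            (body3 == _IDX["A"]) | (body3 == _IDX["G"])
        )
        body3[stop] = _IDX["C"]
        # guard stop immediately upstream so the reported span starts exactly
        # at the planted start codon
        full = np.empty(length + 3, dtype=np.int64)
        full[:3] = [_IDX[c] for c in "TAA"]
        full[3:6] = [_IDX[c] for c in "ATG"]
        full[6:-3:3], full[7:-3:3], full[8:-3:3] = body1, body2, body3
        full[-3:] = [_IDX[c] for c in "TAA"]
        rc = 3 - full[::-1]  # reverse complement in the A,C,G,T encoding
        a = (cursor_start + cursor_end - len(full)) // 2
        seq[a : a + len(full)] = rc
        truth.planted_orf = (a + 1, a + length, "-")


# ---------------------------------------------------------------------------
# divergence


def _k2p_mutate(
    rng: np.random.Generator,
    codes: np.ndarray,
    d: float,
    kappa: float,
    gamma_shape: float | None,
) -> np.ndarray:
    """One-pass Kimura two-parameter substitution at expected distance d.

    Gamma rate variation multiplies the per-site distance; transversions are
    split evenly between the two possible target bases. Encoding is
    A,C,G,T = 0..3, so the transition partner is the complement within the
    purine/pyrimidine pair and transversions flip the chemical class.
    """
    n = len(codes)
    rates = (
        np.ones(n)
        if gamma_shape is None
        else rng.gamma(gamma_shape, 1.0 / gamma_shape, size=n)
    )
    ds = d * rates
    bt = ds / (kappa + 2.0)
    at = kappa * bt
    e_ab = np.exp(-2.0 * (at + bt))
    e_b = np.exp(-4.0 * bt)
    P = 0.25 + 0.25 * e_b - 0.5 * e_ab  # transition probability
    Q = 0.5 - 0.5 * e_b  # total transversion probability
    u = rng.random(n)
    out = codes.copy()
    ts_partner = np.array([2, 3, 0, 1])  # A<->G, C<->T
    tv1 = np.array([1, 0, 1, 0])  # one transversion target per base
    tv2 = np.array([3, 2, 3, 2])  # the other
    m_ts = u < P
    m_tv1 = (u >= P) & (u < P + Q / 2)
    m_tv2 = (u >= P + Q / 2) & (u < P + Q)
    out[m_ts] = ts_partner[codes[m_ts]]
    out[m_tv1] = tv1[codes[m_tv1]]
    out[m_tv2] = tv2[codes[m_tv2]]
    return out


def evolve_pair(
    genome: AnnotatedGenome,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[AnnotatedGenome, AnnotatedGenome, SimTruth]:
    """Derive an F-like and an M-like copy from an ancestral genome.

    The F copy is the input itself; the M copy accumulates the whole expected
    divergence (placing both branches' substitutions on one lineage is
    equivalent for pairwise distances). At the configured fraction of
    protein-coding codons, substitutions that would change the amino acid are
    rejected (the codon reverts), so synonymous third positions carry most of
    the divergence. Afterwards the M copy optionally receives an in-frame
    cox2 insertion and a supernumerary tRNA in its LUR whose decayed homolog
    overwrites the corresponding stretch of the F LUR.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    div = cfg.divergence
    truth = SimTruth(divergence=div)
    f_genome = AnnotatedGenome(
        genome.id + "_F", genome.sequence, list(genome.features), genome.topology
    )
    codes = np.array([_IDX.get(b, 0) for b in genome.sequence], dtype=np.int64)
    if div.expected_distance <= 0:
        m_codes = codes.copy()
    else:
        m_codes = _k2p_mutate(rng, codes, div.expected_distance, div.kappa, div.gamma_shape)
        m_codes = _reject_nonsynonymous(cfg, rng, genome, codes, m_codes)
    m_seq = _decode(m_codes)
    m_feats = list(genome.features)

    if cfg.cox2_insertion_codons and any(f.name == "cox2" for f in m_feats):
        m_seq, m_feats, ins = _insert_in_gene(
            cfg, rng, m_seq, m_feats, "cox2", cfg.cox2_insertion_codons
        )
        truth.cox2_insertion = ins
    if cfg.extra_trna and any(f.name == "trnF" for f in m_feats):
        m_seq, m_feats, placed, f_genome = _plant_extra_trna(
            cfg, rng, m_seq, m_feats, f_genome
        )
        truth.extra_trna = placed
    m_genome = AnnotatedGenome(genome.id + "_M", m_seq, m_feats, genome.topology)
    return f_genome, m_genome, truth


def _reject_nonsynonymous(cfg, rng, genome, old: np.ndarray, new: np.ndarray) -> np.ndarray:
    aa = np.zeros(64, dtype=np.int64)
    for i, b1 in enumerate(BASES):
        for j, b2 in enumerate(BASES):
            for k, b3 in enumerate(BASES):
                aa[16 * i + 4 * j + k] = ord(cfg.code.table[b1 + b2 + b3])
    out = new.copy()
    L = genome.length
    for f in genome.genes("PCG"):
        span = f.span_length(L)
        idx = (f.start0 + np.arange(span)) % L
        if f.strand == "-":
            idx = idx[::-1]
        ncod = span // 3
        tri = idx[: 3 * ncod].reshape(ncod, 3)
        o = old[tri] if f.strand == "+" else 3 - old[tri]
        m = out[tri] if f.strand == "+" else 3 - out[tri]
        aa_old = aa[16 * o[:, 0] + 4 * o[:, 1] + o[:, 2]]
        aa_new = aa[16 * m[:, 0] + 4 * m[:, 1] + m[:, 2]]
        constrained = rng.random(ncod) < cfg.divergence.constrained_fraction
        constrained[0] = constrained[-1] = True  # keep start and stop intact
        revert = constrained & (aa_new != aa_old)
        # also revert any codon mutated into a stop mid-gene
        revert |= (aa_new == ord("*")) & (np.arange(ncod) < ncod - 1)
        for row in tri[revert]:
            out[row] = old[row]
    return out


def _insert_in_gene(cfg, rng, seq: str, feats, gene: str, n_codons: int):
    f = next(x for x in feats if x.name == gene)
    ncod = (f.end - f.start0) // 3
    at0 = f.start0 + 3 * (ncod // 2)  # in-frame, mid-gene
    b1 = _sample(rng, cfg.codon_pos1_profile, n_codons)
    b2 = _sample(rng, cfg.codon_pos2_profile, n_codons)
    b3 = _sample(rng, cfg.third_pos_profile, n_codons)
    stop = (b1 == _IDX["T"]) & (b2 == _IDX["A"]) & ((b3 == _IDX["A"]) | (b3 == _IDX["G"]))
    b3[stop] = _IDX["C"]
    block = np.empty(3 * n_codons, dtype=np.int64)
    block[0::3], block[1::3], block[2::3] = b1, b2, b3
    segment = _decode(block)
    new_seq, new_feats = _splice(seq, feats, at0, segment)
    return new_seq, new_feats, (at0 + 1, at0 + len(segment))


def _plant_extra_trna(cfg, rng, m_seq: str, m_feats, f_genome: AnnotatedGenome):
    src = next(x for x in m_feats if x.name == "trnF")
    trna = m_seq[src.start0 : src.end]
    lo, hi = _largest_gap(m_feats, len(m_seq))
    at0 = (lo + hi) // 2
    m_seq, m_feats = _splice(m_seq, m_feats, at0, trna)
    new = GeneFeature(
        name="trnF(sup)", kind="tRNA", start=at0 + 1, end=at0 + len(trna),
        strand="+", anticodon=src.anticodon,
    )
    m_feats = sorted(m_feats + [new], key=lambda x: x.start)
    # decayed homolog in the F LUR: same spot, heavily mutated, unannotated
    decayed = _decode(
        _k2p_mutate(
            rng,
            np.array([_IDX.get(b, 0) for b in trna]),
            0.3,
            cfg.divergence.kappa,
            None,
        )
    )
    flo, fhi = _largest_gap(list(f_genome.features), f_genome.length)
    fat0 = (flo + fhi) // 2
    fseq = f_genome.sequence[:fat0] + decayed + f_genome.sequence[fat0 + len(decayed):]
    f_genome = AnnotatedGenome(
        f_genome.id, fseq, list(f_genome.features), f_genome.topology
    )
    return m_seq, m_feats, (at0 + 1, at0 + len(trna)), f_genome


def _splice(seq: str, feats, at0: int, segment: str):
    """Insert ``segment`` at 0-based position ``at0``; features after the
    point shift, a feature containing the point extends to absorb it."""
    n = len(segment)
    new_seq = seq[:at0] + segment + seq[at0:]
    new_feats = []
    for f in feats:
        start, end = f.start, f.end
        if f.start0 >= at0:
            start, end = start + n, end + n
        elif at0 < end:
            end += n
        new_feats.append(replace(f, start=start, end=end))
    return new_seq, new_feats


def make_aligned_pair(
    cfg: SimConfig, n: int = 1000, rng: np.random.Generator | None = None
) -> tuple[AlignedPair, PairCounts]:
    """Gap-free evolved pair with its exactly realized P, Q and p.

    The realized counts feed the distance formulas directly in unit tests;
    no alignment step intervenes.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    div = cfg.divergence
    a = _sample(rng, cfg.third_pos_profile, n)
    b = _k2p_mutate(rng, a, div.expected_distance, div.kappa, div.gamma_shape)
    ts_partner = np.array([2, 3, 0, 1])
    diff = a != b
    ts = diff & (b == ts_partner[a])
    counts = PairCounts(
        n=n,
        p=float(diff.mean()),
        P=float(ts.mean()),
        Q=float((diff & ~ts).mean()),
    )
    return AlignedPair(_decode(a), _decode(b), "nt"), counts
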