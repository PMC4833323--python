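"""Replication-origin signal at four-fold degenerate sites.

Third codon positions whose codon family encodes one amino acid for all four
bases evolve nearly neutrally, so their composition records the asymmetric,
replication-associated mutation pressure along the molecule. The genome is
rotated to a chosen anchor gene (conventionally the first protein-coding gene
downstream of the long unassigned region), the four-fold sites are collected
in rotated coordinates, and composition plus A-T skew are computed over a
sliding window. A least-squares linear trend per nucleotide, with its
two-sided significance test, and per-nucleotide autocorrelograms (with
Bartlett large-lag 95% bands, which diagnose how far overlapping windows
violate the independence the regression assumes) summarise the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .codes import BASES, GeneticCode, INVERTEBRATE_MITO
from .genome import AnnotatedGenome, rotate_genome, unassigned_regions

__all__ = [
    "FourfoldTrack",
    "WindowConfig",
    "WindowSeries",
    "TrendFit",
    "Autocorrelogram",
    "OriginReport",
    "fourfold_sites",
    "window_series",
    "at_skew_series",
    "fit_trend",
    "autocorrelogram",
    "origin_report",
]

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i


@dataclass(frozen=True)
class FourfoldTrack:
    """Four-fold degenerate third-position sites, in rotated coordinates."""

    genome_id: str
    anchor: str | None
    positions: np.ndarray  # 1-based, strictly increasing
    bases: np.ndarray  # uint8 codes 0..3 = A,C,G,T
    genome_length: int
    pcg_site_total: int

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def base_fraction(self, base: str) -> float:
        return float(np.mean(self.bases == BASES.index(base.upper())))


@dataclass(frozen=True)
class WindowConfig:
    window: int = 700
    step: int = 300
    anchor: str | None = "cox3"
    min_sites_per_window: int = 10

    def __post_init__(self) -> None:
        if not (self.window >= self.step > 0):
            raise ValueError("require window >= step > 0")


@dataclass
class WindowSeries:
    """Per-window site counts and base counts over a circular coordinate.

    Windows with fewer than ``min_sites`` sites report missing (NaN)
    percentages and skew.
    """

    starts: np.ndarray  # 1-based window start coordinates
    window: int
    counts: dict[str, np.ndarray] = field(repr=False)
    min_sites: int = 10

    @property
    def n_sites(self) -> np.ndarray:
        return sum(self.counts.values())

    @property
    def valid(self) -> np.ndarray:
        return self.n_sites >= self.min_sites

    def pct(self, base: str) -> np.ndarray:
        n = self.n_sites.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = 100.0 * self.counts[base.upper()] / n
        p[~self.valid] = np.nan
        return p

    @property
    def at_skew(self) -> np.ndarray:
        a = self.counts["A"].astype(float)
        t = self.counts["T"].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            skew = (a - t) / (a + t)
        skew[(a + t) == 0] = np.nan
        skew[~self.valid] = np.nan
        return skew

    def to_frame(self):
        import pandas as pd

        d = {"start": self.starts, "n_sites": self.n_sites}
        for b in BASES:
            d[f"pct_{b}"] = self.pct(b)
        d["at_skew"] = self.at_skew
        return pd.DataFrame(d)


@dataclass(frozen=True)
class TrendFit:
    nucleotide: str
    slope: float  # percent per bp
    intercept: float  # percent
    r_squared: float
    p_value: float
    n_windows: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    @property
    def direction(self) -> str:
        if self.slope > 0:
            return "increasing"
        if self.slope < 0:
            return "decreasing"
        return "flat"


@dataclass(frozen=True)
class Autocorrelogram:
    nucleotide: str
    acf: np.ndarray  # lags 0..max_lag
    band: np.ndarray  # large-lag 95% band per lag
    n: int

    @property
    def significant_lags(self) -> list[int]:
        return [k for k in range(1, len(self.acf)) if abs(self.acf[k]) > self.band[k]]


def fourfold_sites(
    genome: AnnotatedGenome,
    code: GeneticCode = INVERTEBRATE_MITO,
    anchor: str | None = "cox3",
) -> FourfoldTrack:
    """Collect four-fold degenerate third positions of all protein-coding genes.

    Positions are 1-based genomic coordinates after rotating the circle so
    that ``anchor`` starts at 1 (pass ``anchor=None`` to keep coordinates as
    annotated). A position annotated by more than one gene counts once.
    """
    if anchor is not None:
        genome = rotate_genome(genome, anchor)
    pcgs = genome.genes("PCG")
    if not pcgs:
        raise ValueError(f"genome {genome.id!r} has no protein-coding genes")
    prefixes = code.fourfold_prefixes()
    fourfold = np.zeros(16, dtype=bool)
    for p in prefixes:
        fourfold[4 * _ENC[ord(p[0])] + _ENC[ord(p[1])]] = True

    L = genome.length
    pos_all: list[np.ndarray] = []
    base_all: list[np.ndarray] = []
    total = 0
    doubled = genome.sequence + genome.sequence
    for f in pcgs:
        span = f.span_length(L)
        total += span
        raw = _ENC[np.frombuffer(doubled[f.start0 : f.start0 + span].encode(), np.uint8)]
        gene = raw if f.strand == "+" else _revcomp_codes(raw)[::-1]
        ncod = span // 3
        b1 = gene[0 : 3 * ncod : 3]
        b2 = gene[1 : 3 * ncod : 3]
        b3 = gene[2 : 3 * ncod : 3]
        ok = (b1 < 4) & (b2 < 4) & (b3 < 4)
        ok &= fourfold[(4 * b1 + b2).clip(max=15)]
        k = np.nonzero(ok)[0]
        gene_index = 3 * k + 2  # index of the third base within the gene
        if f.strand == "+":
            gpos = (f.start0 + gene_index) % L
        else:
            gpos = (f.start0 + span - 1 - gene_index) % L
        pos_all.append(gpos + 1)
        base_all.append(b3[k])

    pos = np.concatenate(pos_all)
    bas = np.concatenate(base_all)
    order = np.argsort(pos, kind="stable")
    pos, bas = pos[order], bas[order]
    keep = np.ones(len(pos), dtype=bool)
    keep[1:] = pos[1:] != pos[:-1]  # position-keyed: duplicates count once
    return FourfoldTrack(
        genome_id=genome.id,
        anchor=anchor,
        positions=pos[keep],
        bases=bas[keep],
        genome_length=L,
        pcg_site_total=total,
    )


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes.copy()
    valid = codes < 4
    out[valid] = 3 - codes[valid]  # A<->T, C<->G in the ACGT encoding
    return out


def window_series(track: FourfoldTrack, cfg: WindowConfig | None = None) -> WindowSeries:
    """Sliding-window base counts over the rotated genomic coordinate.

    Window *w* covers positions ``[start, start + window)``; starts advance
    by ``step`` from 1 until they exceed the genome length, and windows
    reaching past the end wrap around the circle.
    """
    cfg = cfg or WindowConfig()
    if track.n_sites == 0:
        raise ValueError("empty four-fold track")
    L = track.genome_length
    starts = np.arange(1, L + 1, cfg.step)
    counts: dict[str, np.ndarray] = {}
    for i, b in enumerate(BASES):
        p = track.positions[track.bases == i]  # sorted
        lo = starts
        hi = starts + cfg.window - 1
        inside = np.searchsorted(p, np.minimum(hi, L), side="right") - np.searchsorted(
            p, lo, side="left"
        )
        # wrapped tail, capped so a window longer than the circle counts
        # every site exactly once
        wrap_hi = np.clip(np.minimum(hi - L, lo - 1), 0, None)
        inside = inside + np.searchsorted(p, wrap_hi, side="right")
        counts[b] = inside
    return WindowSeries(
        starts=starts, window=cfg.window, counts=counts, min_sites=cfg.min_sites_per_window
    )


def at_skew_series(track: FourfoldTrack, cfg: WindowConfig | None = None) -> WindowSeries:
    """Windowed series whose ``at_skew`` channel is (A-T)/(A+T) per window."""
    return window_series(track, cfg)


def fit_trend(series: WindowSeries, nucleotide: str) -> TrendFit:
    """Ordinary least squares of windowed percentage against window start (bp).

    The p-value is the plain two-sided t-test on the slope, uncorrected for
    the autocorrelation that overlapping windows induce; the autocorrelogram
    is the diagnostic for that.
    """
    y = series.pct(nucleotide)
    x = series.starts.astype(float)
    m = ~np.isnan(y)
    x, y = x[m], y[m]
    if len(y) < 3:
        raise ValueError(f"only {len(y)} valid windows; need at least 3")
    if np.ptp(y) == 0.0:
        return TrendFit(nucleotide.upper(), 0.0, float(y[0]), 0.0, 1.0, len(y))
    fit = stats.linregress(x, y)
    return TrendFit(
        nucleotide=nucleotide.upper(),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n_windows=len(y),
    )


def autocorrelogram(
    series: WindowSeries | np.ndarray, nucleotide: str = "", max_lag: int = 17
) -> Autocorrelogram:
    """Sample autocorrelation (biased denominator) with Bartlett 95% bands.

    ``band[k] = 1.96 * sqrt((1 + 2 * sum_{0<j<k} acf(j)^2) / n)`` — the
    large-lag standard error under the hypothesis that the series is white
    beyond lag *k*.
    """
    if isinstance(series, WindowSeries):
        y = series.pct(nucleotide)
        y = y[~np.isnan(y)]
    else:
        y = np.asarray(series, dtype=float)
    n = len(y)
    if n <= max_lag:
        raise ValueError(f"series of {n} windows is too short for max_lag={max_lag}")
    y = y - y.mean()
    c0 = float(np.dot(y, y)) / n
    if c0 == 0.0:
        raise ValueError("zero-variance series has no autocorrelation")
    acf = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        acf[k] = (np.dot(y[: n - k], y[k:]) / n) / c0
    cum = np.concatenate(([0.0], np.cumsum(acf[1:] ** 2)))
    z = stats.norm.ppf(0.975)
    band = z * np.sqrt((1.0 + 2.0 * np.concatenate(([0.0], cum[:-1]))) / n)
    return Autocorrelogram(nucleotide.upper(), acf, band, n)


@dataclass(frozen=True)
class OriginReport:
    """Descriptive evidence for control-region / origin placement.

    Lists each nucleotide's trend (direction and significance), the windows
    at local minima of the A-T skew, and the unassigned regions overlapping
    those windows — the candidate control region / origin neighbourhoods. No
    single-point origin call is made.
    """

    genome_id: str
    anchor: str | None
    trends: dict[str, TrendFit]
    skew_minima: list[dict]
    alpha: float = 0.05

    def to_text(self) -> str:
        lines = [f"Origin-of-replication report for {self.genome_id}"]
        if self.anchor:
            lines.append(f"coordinates rotated to start at {self.anchor}")
        lines.append("")
        lines.append("Nucleotide trends at four-fold degenerate sites:")
        for b, t in self.trends.items():
            sig = "significant" if t.p_value < self.alpha else "not significant"
            lines.append(
                f"  {b}: {t.direction} (slope {t.slope:+.4g} %/bp, "
                f"R^2 {t.r_squared:.4f}, p {t.p_value:.4g}; {sig} at alpha={self.alpha})"
            )
        lines.append("")
        lines.append("A-T skew local minima (candidate origin neighbourhoods):")
        for m in self.skew_minima:
            urs = ", ".join(m["unassigned_after"]) or "none"
            lines.append(
                f"  window {m['start']}..{m['end']}: skew {m['skew']:+.3f}; "
                f"overlapping unassigned regions after: {urs}"
            )
        lines.append("")
        lines.append(
            "Caveat: overlapping windows are autocorrelated; p-values are "
            "uncorrected — consult the autocorrelograms."
        )
        return "\n".join(lines)


def origin_report(
    trends: dict[str, TrendFit],
    skew: WindowSeries,
    genome: AnnotatedGenome,
    anchor: str | None = "cox3",
    alpha: float = 0.05,
) -> OriginReport:
    """Assemble the descriptive origin report from fitted trends and skew.

    ``genome`` is rotated to ``anchor`` internally so that unassigned-region
    coordinates match the windowed series.
    """
    g = rotate_genome(genome, anchor) if anchor is not None else genome
    urs = [u for u in unassigned_regions(g) if u.length > 0]
    s = skew.at_skew
    minima = []
    for i in range(len(s)):
        if np.isnan(s[i]):
            continue
        left = s[i - 1] if i > 0 and not np.isnan(s[i - 1]) else np.inf
        right = s[i + 1] if i + 1 < len(s) and not np.isnan(s[i + 1]) else np.inf
        if s[i] <= left and s[i] <= right:
            w_start = int(skew.starts[i])
            w_end = w_start + skew.window - 1
            overlapping = [
                u.after_gene for u in urs if _overlaps_circular(u, w_start, w_end, g.length)
            ]
            minima.append(
                {
                    "start": w_start,
                    "end": min(w_end, g.length),
                    "skew": float(s[i]),
                    "unassigned_after": overlapping,
                }
            )
    minima.sort(key=lambda m: m["skew"])
    return OriginReport(genome.id, anchor, dict(trends), minima, alpha)


def _overlaps_circular(u, w_start: int, w_end: int, L: int) -> bool:
    def spans(a, b):
        if b >= a:
            return [(a, b)]
        return [(a, L), (1, b)]

    for ua, ub in spans(u.start, u.end):
        for wa, wb in spans(w_start, (w_end - 1) % L + 1):
            if ua <= wb and wa <= ub:
                return True
    return False
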