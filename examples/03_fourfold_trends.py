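"""Locate the replication-origin signal at four-fold degenerate sites.

A composition gradient is injected into the simulated genome (C rising with
distance from cox3); the sliding-window analysis recovers it, and the origin
report lists the A-T-skew minima with the unassigned regions they overlap —
the candidate control-region neighbourhoods.
"""

import mitopair as mp
from mitopair.fourfold import autocorrelogram, fit_trend, fourfold_sites, origin_report, window_series

cfg = mp.SimConfig(seed=11, trend=mp.TrendSpec(nucleotide="C", slope=0.001))
genome, _ = mp.simulate_genome(cfg)

track = fourfold_sites(genome, anchor="cox3")
print(f"{track.n_sites} four-fold degenerate sites "
      f"({100 * track.n_sites / track.pcg_site_total:.2f}% of PCG sites), "
      f"T share {100 * track.base_fraction('T'):.2f}%")

series = window_series(track, mp.WindowConfig(window=700, step=300))
trends = {b: fit_trend(series, b) for b in "ACGT"}
for b, t in trends.items():
    print(f"  {b}: slope {t.slope:+.2e} %/bp, R^2 {t.r_squared:.4f}, "
          f"p {t.p_value:.4g}")

acf = autocorrelogram(series, "C", max_lag=17)
print(f"C-series acf: significant lags {acf.significant_lags} "
      "(overlapping windows induce short-range autocorrelation)")

report = origin_report(trends, series, genome)
print(report.to_text())
# The injected positive C trend is recovered as significant; a real genome
# analysed the same way points at the long unassigned region as the likely
# control region / origin of replication.
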