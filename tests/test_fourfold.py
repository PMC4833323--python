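"""Four-fold degenerate sites, sliding windows, trends, autocorrelograms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mitopair as mp
from mitopair.codes import INVERTEBRATE_MITO
from mitopair.fourfold import (
    FourfoldTrack,
    WindowConfig,
    autocorrelogram,
    fit_trend,
    fourfold_sites,
    origin_report,
    window_series,
)
from mitopair.genome import AnnotatedGenome, GeneFeature

# four-fold families of the invertebrate mitochondrial code, enumerated by
# hand from the table: Leu CTN, Val GTN, Ser TCN + AGN, Pro CCN, Thr ACN,
# Ala GCN, Arg CGN, Gly GGN
EXPECTED_PREFIXES = {"CT", "GT", "TC", "AG", "CC", "AC", "GC", "CG", "GG"}


def one_gene_genome(cds, name="g1"):
    pad = "C" * ((3 - len(cds) % 3) % 3)
    return AnnotatedGenome(
        "t", cds + pad + "CCC", [GeneFeature(name, "PCG", 1, len(cds))]
    )


class TestFourfoldSites:
    def test_code_families(self):
        assert INVERTEBRATE_MITO.fourfold_prefixes() == frozenset(EXPECTED_PREFIXES)

    def test_single_degenerate_codon(self):
        g = one_gene_genome("ATGCTTTAA")
        track = fourfold_sites(g, anchor="g1")
        assert track.n_sites == 1
        assert list(track.positions) == [6]  # third base of CTT
        assert track.bases[0] == 3  # T

    def test_no_degenerate_sites(self):
        g = one_gene_genome("ATG" * 10)
        assert fourfold_sites(g, anchor="g1").n_sites == 0

    def test_no_pcgs_raises(self):
        g = AnnotatedGenome("t", "ACGTACGTAC", [GeneFeature("t1", "tRNA", 1, 6)])
        with pytest.raises(ValueError):
            fourfold_sites(g, anchor="t1")

    def test_minus_strand_gene_maps_back_to_genomic_coordinates(self):
        from mitopair.genome import reverse_complement

        cds = "ATGCTTTAA"
        seq = reverse_complement(cds) + "CCC"
        g = AnnotatedGenome("t", seq, [GeneFeature("g1", "PCG", 1, 9, "-")])
        track = fourfold_sites(g, anchor="g1")
        assert track.n_sites == 1
        # gene position 6 (third base of CTT) -> genomic position 9 - 6 + 1
        assert list(track.positions) == [4]

    def test_counts_on_simulated_genome(self, sim_genome):
        g, _ = sim_genome
        track = fourfold_sites(g)
        assert 0 < track.n_sites < track.pcg_site_total / 3
        assert np.all(np.diff(track.positions) > 0)
        # T-rich thirds by construction
        assert track.base_fraction("T") > 0.4

    def test_rotation_invariance_of_site_count(self, sim_genome):
        g, _ = sim_genome
        a = fourfold_sites(g, anchor="cox3")
        b = fourfold_sites(mp.rotate_genome(g, "nad5"), anchor="cox3")
        assert a.n_sites == b.n_sites
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.bases, b.bases)


def make_track(positions, bases, L):
    pos = np.asarray(positions)
    order = np.argsort(pos)
    return FourfoldTrack("t", None, pos[order],
                         np.asarray(bases)[order], L, 3 * len(positions))


class TestWindowSeries:
    def test_single_window_equals_whole_track(self):
        track = make_track([1, 5, 10, 20], [0, 3, 3, 1], L=20)
        ws = window_series(track, WindowConfig(window=20, step=20, anchor=None,
                                               min_sites_per_window=1))
        assert len(ws.starts) == 1
        assert ws.n_sites[0] == 4
        assert ws.pct("T")[0] == 50.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_interval_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(50, 400))
        n = int(rng.integers(1, 60))
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=min(n, L), replace=False))
        bases = rng.integers(0, 4, size=len(pos))
        track = make_track(pos, bases, L)
        w = int(rng.integers(5, L + 10))
        s = int(rng.integers(1, w + 1))
        ws = window_series(track, WindowConfig(window=w, step=s, anchor=None,
                                               min_sites_per_window=0))
        for i, start in enumerate(ws.starts):
            covered = {(start - 1 + k) % L + 1 for k in range(min(w, L))}
            for bi, b in enumerate("ACGT"):
                expect = sum(1 for p, c in zip(pos, bases) if p in covered and c == bi)
                assert ws.counts[b][i] == expect

    def test_site_count_conserved_with_non_overlapping_windows(self, sim_genome):
        g, _ = sim_genome
        track = fourfold_sites(g)
        ws = window_series(track, WindowConfig(window=700, step=700))
        # every position is in exactly one window except double-counting by the
        # final wrap-around window; subtract its wrapped part
        total = int(ws.n_sites.sum())
        last_start = ws.starts[-1]
        wrapped = last_start + 700 - 1 - track.genome_length
        overcount = int(np.sum(track.positions <= wrapped)) if wrapped > 0 else 0
        assert total - overcount == track.n_sites

    def test_low_count_windows_flagged_missing(self):
        track = make_track([1, 2, 3], [0, 1, 2], L=100)
        ws = window_series(track, WindowConfig(window=10, step=10, anchor=None,
                                               min_sites_per_window=2))
        assert np.isnan(ws.pct("A")[1:]).all()
        assert not np.isnan(ws.pct("A")[0])


class TestAtSkew:
    def test_all_t_window_is_minus_one(self):
        track = make_track([1, 2, 3], [3, 3, 3], L=10)
        ws = window_series(track, WindowConfig(window=10, step=10, anchor=None,
                                               min_sites_per_window=1))
        assert ws.at_skew[0] == -1.0

    def test_balanced_window_is_zero(self):
        track = make_track([1, 2], [0, 3], L=10)
        ws = window_series(track, WindowConfig(window=10, step=10, anchor=None,
                                               min_sites_per_window=1))
        assert ws.at_skew[0] == 0.0

    def test_no_at_flagged_missing(self):
        track = make_track([1, 2], [1, 2], L=10)
        ws = window_series(track, WindowConfig(window=10, step=10, anchor=None,
                                               min_sites_per_window=1))
        assert np.isnan(ws.at_skew[0])

    def test_matches_direct_formula(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 500), size=80, replace=False))
        track = make_track(pos, rng.integers(0, 4, size=80), L=500)
        ws = window_series(track, WindowConfig(window=100, step=50, anchor=None,
                                               min_sites_per_window=1))
        a, t = ws.counts["A"].astype(float), ws.counts["T"].astype(float)
        for i in range(len(ws.starts)):
            if a[i] + t[i] == 0 or a[i] + t[i] + ws.counts["C"][i] + ws.counts["G"][i] < 1:
                continue
            assert ws.at_skew[i] == pytest.approx((a[i] - t[i]) / (a[i] + t[i]))


def series_from(y, starts=None):
    """WindowSeries stand-in built directly from a percentage series."""
    y = np.asarray(y, dtype=float)

    class _S:
        def __init__(self):
            self.starts = np.asarray(starts if starts is not None else
                                     np.arange(1, len(y) + 1), dtype=float)

        def pct(self, _):
            return y.copy()

    return _S()


class TestTrendFit:
    def test_flat_series(self):
        fit = fit_trend(series_from([5.0] * 10), "C")
        assert (fit.slope, fit.r_squared, fit.p_value) == (0.0, 0.0, 1.0)

    def test_exact_line_recovered(self):
        x = np.arange(1, 11, dtype=float)
        fit = fit_trend(series_from(2 * x, starts=x), "C")
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_too_few_windows_raises(self):
        with pytest.raises(ValueError):
            fit_trend(series_from([1.0, 2.0]), "C")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        x = np.sort(rng.uniform(0, 1000, size=n))
        y = rng.uniform(0, 100, size=n)
        fit = fit_trend(series_from(y, starts=x), "A")
        # brute-force normal equations + t test
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        from scipy import stats as sps

        t = beta[1] / se
        p = 2 * sps.t.sf(abs(t), n - 2)
        r2 = 1 - (resid @ resid) / np.sum((y - y.mean()) ** 2)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)
        assert fit.p_value == pytest.approx(p, abs=1e-10)


class TestAutocorrelogram:
    def test_lag_zero_is_one(self, rng):
        a = autocorrelogram(rng.normal(size=100), "A", max_lag=10)
        assert a.acf[0] == pytest.approx(1.0)
        assert np.all(np.abs(a.acf) <= 1 + 1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            autocorrelogram(np.arange(10.0), "A", max_lag=17)

    def test_ar1_acf_near_phi(self):
        rng = np.random.default_rng(7)
        n, phi = 500, 0.8
        y = np.zeros(n)
        for t in range(1, n):
            y[t] = phi * y[t - 1] + rng.normal()
        a = autocorrelogram(y, "A", max_lag=5)
        assert a.acf[1] == pytest.approx(phi, abs=0.1)

    def test_matches_brute_force_and_statsmodels(self, rng):
        y = rng.normal(size=120)
        a = autocorrelogram(y, "A", max_lag=17)
        yc = y - y.mean()
        c0 = np.sum(yc * yc) / len(y)
        for k in range(18):
            ck = np.sum(yc[: len(y) - k] * yc[k:]) / len(y)
            assert a.acf[k] == pytest.approx(ck / c0, abs=1e-10)
        from statsmodels.tsa.stattools import acf as sm_acf

        ref, conf = sm_acf(y, nlags=17, fft=False, alpha=0.05, bartlett_confint=True)
        assert np.allclose(a.acf, ref, atol=1e-10)
        # Bartlett band: statsmodels returns acf +/- band
        band_ref = conf[1:, 1] - ref[1:]
        assert np.allclose(a.band[1:], band_ref, atol=1e-10)


class TestOriginReport:
    def test_injected_trend_flagged(self):
        cfg = mp.SimConfig(seed=5, trend=mp.TrendSpec(nucleotide="C", slope=0.01))
        g, _ = mp.simulate_genome(cfg)
        track = fourfold_sites(g)
        ws = window_series(track)
        trends = {b: fit_trend(ws, b) for b in "ACGT"}
        rep = origin_report(trends, ws, g)
        assert trends["C"].slope > 0
        assert trends["C"].p_value < 0.05
        assert "increasing" in rep.to_text()

    def test_skew_minima_report_overlapping_urs(self, sim_genome):
        g, _ = sim_genome
        track = fourfold_sites(g)
        ws = window_series(track)
        trends = {b: fit_trend(ws, b) for b in "ACGT"}
        rep = origin_report(trends, ws, g)
        assert len(rep.skew_minima) >= 1
        for m in rep.skew_minima:
            assert -1.0 <= m["skew"] <= 1.0
        text = rep.to_text()
        assert "Caveat" in text
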