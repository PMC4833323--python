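"""End-to-end orchestration: composition, fourfold trends, distances, PCA.

Writes TSV tables (two-decimal rounding applied at this presentation layer
only) plus a machine-readable JSON summary carrying full precision.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import comparative, composition, distances, fourfold
from .genome import AnnotatedGenome, unassigned_regions

log = logging.getLogger("mitopair")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    out_dir: Path
    genome_a: AnnotatedGenome | None = None
    genome_b: AnnotatedGenome | None = None
    stages: tuple = ("compose", "fourfold", "distance", "compare")
    window: int = 700
    step: int = 300
    anchor: str = "cox3"
    max_lag: int = 17
    gamma_a: float = 1.0
    distance_table_path: Path | None = None  # defaults to the packaged table
    pca_standardize: bool = False
    extra: dict = field(default_factory=dict)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the requested stages; returns the JSON-ready summary dict."""
    if cfg.genome_a is None and set(cfg.stages) & {"compose", "fourfold", "distance"}:
        raise ValueError("at least one genome is required for the requested stages")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": list(cfg.stages)}
    genomes = [g for g in (cfg.genome_a, cfg.genome_b) if g is not None]

    if "compose" in cfg.stages:
        for g in genomes:
            log.info("compose: %s", g.id)
            tab = composition.composition_table(g)
            _write_rounded(tab, out / f"composition_{g.id}.tsv")
            whole = composition.nucleotide_composition(g.sequence, g.id)
            summary.setdefault("composition", {})[g.id] = {
                "length": g.length,
                "pct_AT": whole.pct_AT,
                "n_unassigned_regions": sum(
                    1 for u in unassigned_regions(g) if u.length > 0
                ),
            }

    if "fourfold" in cfg.stages:
        wcfg = fourfold.WindowConfig(cfg.window, cfg.step, cfg.anchor)
        for g in genomes:
            log.info("fourfold: %s window=%d step=%d anchor=%s",
                     g.id, cfg.window, cfg.step, cfg.anchor)
            track = fourfold.fourfold_sites(g, anchor=cfg.anchor)
            series = fourfold.window_series(track, wcfg)
            _write_rounded(series.to_frame(), out / f"fourfold_series_{g.id}.tsv")
            fits = {b: fourfold.fit_trend(series, b) for b in "ACGT"}
            rows = [
                {"nucleotide": b, "slope": t.slope, "intercept": t.intercept,
                 "r_squared": t.r_squared, "p_value": t.p_value}
                for b, t in fits.items()
            ]
            import pandas as pd

            pd.DataFrame(rows).to_csv(out / f"fourfold_fits_{g.id}.tsv", sep="\t", index=False)
            acfs = {}
            if series.valid.sum() > cfg.max_lag:
                for b in "ACGT":
                    a = fourfold.autocorrelogram(series, b, cfg.max_lag)
                    acfs[b] = {"acf": a.acf.tolist(), "band": a.band.tolist(),
                               "significant_lags": a.significant_lags}
                pd.DataFrame(
                    {f"acf_{b}": acfs[b]["acf"] for b in "ACGT"}
                ).to_csv(out / f"fourfold_acf_{g.id}.tsv", sep="\t", index=False)
            report = fourfold.origin_report(fits, series, g, cfg.anchor)
            (out / f"origin_report_{g.id}.txt").write_text(report.to_text())
            summary.setdefault("fourfold", {})[g.id] = {
                "n_sites": track.n_sites,
                "pct_T": 100 * track.base_fraction("T"),
                "trends": {b: {"slope": t.slope, "r_squared": t.r_squared,
                               "p_value": t.p_value} for b, t in fits.items()},
                "acf": acfs,
                "skew_minima": report.skew_minima,
            }

    if "distance" in cfg.stages:
        if cfg.genome_b is None:
            raise ValueError("the distance stage needs a second genome (an F/M pair)")
        log.info("distance: %s vs %s (gamma a=%.3g)",
                 cfg.genome_a.id, cfg.genome_b.id, cfg.gamma_a)
        table = distances.gene_distance_table(
            cfg.genome_a, cfg.genome_b, gamma_a=cfg.gamma_a
        )
        _write_rounded(table, out / "distances.tsv")
        summary["distance"] = {
            row["label"]: {k: row[k] for k in ("p_distance", "jn_distance", "kimura_aa")}
            for row in table.to_dict("records")
        }

    if "compare" in cfg.stages:
        log.info("compare: PCA and rank concordance")
        table = comparative.load_distance_table(cfg.distance_table_path)
        matrix = comparative.build_feature_matrix(table, missing_policy="mean")
        res = comparative.pca(matrix, standardize=cfg.pca_standardize)
        _write_rounded(res.scores, out / "pca_scores.tsv", index=True)
        _write_rounded(res.loadings, out / "pca_loadings.tsv", index=True)
        groups = {
            g: list(table.index[table["group"] == g])
            for g in ("Unionoidea", "Amarsipobranchia")
        }
        ranks = None
        if all(len(m) > 0 for m in groups.values()):
            means = {
                g: [table.loc[m, f"nt_{gene}"].mean()
                    for gene in comparative.GENES_AA]
                for g, m in groups.items()
            }
            rc = comparative.rank_concordance(*means.values())
            ranks = {"spearman_rho": rc.spearman_rho, "spearman_p": rc.spearman_p,
                     "kendall_tau": rc.kendall_tau, "kendall_p": rc.kendall_p}
        summary["compare"] = {
            "variance_pct": res.variance_pct.tolist(),
            "pc1_pct": float(res.variance_pct[0]),
            "rank_concordance": ranks,
        }

    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2))
    return summary


def _write_rounded(df, path, index=False) -> None:
    df = df.copy()
    for c in df.columns:
        if df[c].dtype.kind == "f":
            df[c] = df[c].map(lambda x: x if isinstance(x, str) else composition.round2(x)
                              if not (isinstance(x, float) and math.isnan(x)) else x)
    df.to_csv(path, sep="\t", index=index)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj
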