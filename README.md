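# mitopair

Comparative analysis of paired sex-linked mitochondrial genomes in bivalves
with **doubly uniparental inheritance (DUI)** — species that transmit two
independent mitochondrial lineages, an egg-transmitted F genome and a
sperm-transmitted M genome. `mitopair` implements, as a tested library, the
computational battery used to characterise such a pair:

* **Genome model** — annotated circular mitogenomes (GenBank flat file or
  FASTA + feature TSV), unassigned-region (UR) accounting with gene overlaps
  as negative gaps, and rotation to any anchor gene.
* **Composition** — per-gene and aggregate base percentages, third-codon
  position composition, codon usage under the invertebrate mitochondrial
  code (translation table 5), start/stop tabulation, and simple maximal ORF
  extraction on both strands.
* **Fourfold-trend analysis** — the replication-origin localisation method:
  collect third positions of four-fold degenerate codon families (those
  where all four third bases encode the same amino acid), slide a window
  (default 700 bp, step 300 bp) over the rotated genome, and fit a linear
  trend per nucleotide,

  `pct_b(x) = α + β·x`,  with the two-sided t-test on β and `R²`,

  plus the A-T skew `(A−T)/(A+T)` per window and per-nucleotide
  autocorrelograms with Bartlett large-lag 95% bands. Deamination pressure
  on the strand left single-stranded during replication makes T accumulate
  toward the origin of the heavy strand while A and C do the opposite, so
  the trends and the skew minima point at the control region.
* **Divergence** — per-gene and concatenated distances from pairwise
  alignments with pairwise deletion: p-distance, the Jin–Nei gamma
  nucleotide distance

  `d = (a/2) [ (1−2P−Q)^(−1/a) + ½ (1−2Q)^(−1/a) − 3/2 ]`

  (P transitions, Q transversions, gamma shape `a = 1` by default), and the
  Kimura amino-acid distance `d = −ln(1 − p − 0.2 p²)` (undefined, "too
  divergent", for `p ≳ 0.854`). All reported ×100.
* **Comparative synthesis** — species × per-gene feature matrices, PCA
  (covariance by default, correlation optional), and Spearman/Kendall rank
  concordance of gene-divergence orderings between taxon groups. A
  transcription of the published 15-species DUI distance table ships with
  the package.
* **Synthetic data** — a deterministic generator of annotated F/M pairs
  with known ground truth: venerid-style gene roster, A-T-rich third codon
  positions, LUR with tandem repeats and plantable reverse-strand ORFs,
  injectable composition trends, K2P+gamma divergence with
  amino-acid-preserving rejection, the 100-codon M-`cox2` insertion, and an
  M-only supernumerary tRNA.

## Worked example

```python
import mitopair as mp

cfg = mp.SimConfig(seed=1)
ancestor, truth = mp.simulate_genome(cfg)
f, m, pair_truth = mp.evolve_pair(ancestor, cfg)

track = mp.fourfold_sites(f, anchor="cox3")
series = mp.window_series(track, mp.WindowConfig(window=700, step=300))
fit = mp.fit_trend(series, "C")

table = mp.gene_distance_table(f, m).set_index("label")
print(table.loc["All coding DNA", ["p_distance", "jn_distance"]])
```

Running the narrative scripts in `examples/` prints, among other things:

```
sim_F: 20025 bp, 13 PCGs, 2 rRNAs, 22 tRNAs, 27 unassigned regions
sim_M: 20399 bp, 13 PCGs, 2 rRNAs, 23 tRNAs, 28 unassigned regions
cox2: F 1386 bp, M 1686 bp (insertion at M positions 5398..5697)
All coding DNA       p 16.12   Jin-Nei 20.65
PCA: PC1 73.27% + PC2 10.66% = 83.93% of variance
all-coding Jin-Nei group average, Unionoidea (N = 6): 100.64
all-coding Jin-Nei group average, Amarsipobranchia (N = 7): 66.97
```

The simulated pair diverges ~16% per coding site (the regime observed in
venerid DUI pairs); the Jin–Nei correction exceeds the raw p-distance
because it undoes multiple hits. The PCA on the packaged cross-species
table separates unionids (group average ≈ 101) from mussels+clams (≈ 67)
along the first component.

A thin CLI mirrors the stages: `mitopair simulate|compose|fourfold|
distance|compare|run-all` (see `mitopair --help`).

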