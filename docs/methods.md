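# Methods

## Scope and data model

`mitopair` operates on annotated circular mitochondrial genomes. External
coordinates are 1-based and inclusive on both ends, matching the convention
of published annotation tables; a feature with `end < start` wraps past the
origin of the circle. Internally every coordinate computation goes through a
single 0-based accessor (`GeneFeature.start0`) so the off-by-one shift
happens in exactly one place. Unassigned regions (URs) are defined between
consecutive annotated genes as `next.start − this.end − 1`, carried once
around the circle at the wrap; negative values count overlapping
nucleotides. The tiling identity

```
feature coverage + positive gaps − overlaps = genome length
```

is asserted on every simulated genome and holds for any annotation without
triple overlaps. Rotation to an anchor gene shifts all coordinates modulo
the length and leaves every extracted gene sequence unchanged — a property
the test suite checks on random genomes, since all downstream per-gene
statistics must be rotation-invariant.

Ambiguity codes are accepted in sequences but excluded from all composition
and degenerate-site counts; exclusion is the conservative choice when the
handling is otherwise unspecified. Genes on the "−" strand are supported
throughout (some bivalve families encode on both strands) even though the
default roster is single-strand.

## Composition and ORFs

Percentages are computed over unambiguous bases and kept at full precision;
the two-decimal half-up rounding of printed tables is applied only at the
presentation layer. Codon usage counts stop codons as codons — the
concatenated PCG length of the default roster (12,681 bp = 3 × 4,227
codons) is only consistent with stops included. Incomplete terminal codons
are rejected rather than patched: the genomes this package models are
annotated without truncated stops, and the simulator never emits them.

ORF extraction reports, per strand and per stop codon, the maximal
start-to-stop span whose start is the earliest in-frame start after the
previous stop; length is counted in sense codons (stop excluded). The
alternative start set is {ATG, ATA, ATT, ATC, GTG, TTG}, the union observed
in bivalve mitogenome annotations. Only stop-terminated ORFs are reported.
No expression scoring is attempted — extraction here is purely positional.

## Four-fold degenerate-site trend analysis

A site is four-fold degenerate when the first two bases of its codon
determine the amino acid for all four third bases under the invertebrate
mitochondrial code; the nine qualifying families (CTN, GTN, TCN, AGN, CCN,
ACN, GCN, CGN, GGN) are derived programmatically from the code table, so a
different translation table changes the families automatically.
Stop-containing families are excluded by construction; codons containing
ambiguity codes are skipped; a position annotated by two genes counts once
(the track is position-keyed).

The genome is rotated so the anchor gene (default `cox3`, the first
protein-coding gene downstream of the long unassigned region) starts at
position 1. Windows cover `[start, start + window)` in rotated genomic
coordinates — not positions along the concatenated site string — starting
at 1 and advancing by `step` until the start exceeds the genome length;
windows reaching past the end wrap around the circle, and a window longer
than the circle counts each site once. Defaults are 700/300 bp. Windows
with fewer than `min_sites_per_window` (default 10) sites report missing
values; intergenic stretches thus appear as empty windows rather than being
skipped over.

The per-nucleotide trend is an ordinary least-squares regression of the
windowed percentage on the window start coordinate in bp (slopes are
therefore in %/bp, the scale on which origin-proximity effects of order
10⁻⁴ %/bp are visible over a 20 kb molecule). The p-value is the plain
two-sided t-test on the slope, uncorrected for multiplicity or for the
autocorrelation that overlapping windows induce — that correction is
deliberately left to the diagnostic: the autocorrelogram uses the biased
(1/n) autocovariance estimator on the mean-centred series with Bartlett
large-lag bands `z₀.₉₇₅ · sqrt((1 + 2 Σ_{j<k} r_j²)/n)`. With step <
window, lag-1 autocorrelation is expected by construction and the origin
report prints that caveat. The type-I calibration test in the suite
therefore runs with `step == window` (non-overlapping windows), where the
independence assumption holds and the empirical false-positive rate of the
slope test on trend-free genomes must sit in 0.05 ± 0.03.

The origin report is descriptive by design: it lists each nucleotide's
trend direction and significance, the local minima of the windowed A-T skew
`(A−T)/(A+T)`, and the unassigned regions overlapping those windows. It
makes no single-point origin call — skew minima plus trend directions
bracket candidate control-region neighbourhoods, and resolving them further
(secondary structure, repeats) is outside this package's scope.

## Distances

Pairwise alignment uses a global affine-gap aligner (match 1 / mismatch −1
/ open −5 / extend −1 for nucleotides; BLOSUM62 with −10/−1 for amino
acids), the first optimal traceback taken deterministically. This is a
stand-in for curated multi-aligner consensus alignments; pre-aligned pairs
can be supplied and bypass it, which is the route to reproduce
published-table values exactly. Columns with a gap or ambiguity in either
sequence are deleted pairwise before counting; transitions are A↔G and
C↔T. The Jin–Nei gamma distance defaults to shape `a = 1` (the default of
the distance tools this analysis style is built on; the parameter is
exposed). Both corrections return NaN with a `too_divergent` status when
their bracket/log argument is non-positive; for the Kimura correction that
threshold is `p = (√1.8 − 1)/0.4 ≈ 0.8541`. Corrected distances are
reported ×100. Concatenation rows ("All coding DNA", "PCGs", "rRNAs",
"tRNAs") concatenate the per-gene alignments before counting, so a gene's
gap structure is preserved.

## Cross-species synthesis

The packaged table `data/bivalve_distances.tsv` transcribes the published
15-species F-versus-M distance matrix (per-gene Jin–Nei nucleotide
distances, 13 PCGs + 2 rRNAs, and per-PCG Kimura amino-acid distances, all
×100), with blanks where a gene is unannotated in a species and where one
amino-acid pair is too divergent to correct. The feature matrix is species
× 28 columns; missing cells are mean-imputed by default (column dropping is
available for sensitivity analysis, and entirely-missing columns are always
dropped).

PCA is an eigendecomposition of the column-centred covariance matrix;
`standardize=True` switches to the correlation matrix. Covariance PCA is
the default because it is the configuration under which the packaged table
reproduces the published first-component variance share (73.3% vs the
printed 73.20%); correlation PCA on the same matrix yields ~80%, and
column dropping shifts it further (the `atp8` columns carry one extreme
unionid value that dominates the covariance), so the missing-value policy
is genuinely load-bearing and is surfaced as an explicit argument rather
than hidden. Component signs are fixed by making each component's
largest-magnitude loading positive.

Rank concordance between two gene orderings uses Spearman's ρ (t
approximation) and Kendall's τ (exact for n ≤ 10 without ties, otherwise
the normal approximation), average ranks for ties. On the packaged table,
comparing the 13 per-PCG group-mean nucleotide distances of Unionoidea
against Amarsipobranchia gives ρ = +0.352 (p = 0.2387) and τ = +0.282
(p = 0.2044) — the gene-divergence rankings of the two DUI clades cannot
be shown to be related. The 13-PCG column set is the default for this
comparison; including the two rRNA columns is exposed as an option.

## Synthetic-data generator

The generator's defaults are the study conditions the rest of the package
assumes, not tuning knobs:

* **Roster** — the packaged venerid-style F annotation: 20,025 bp, 13
  PCGs, 2 rRNAs, 22 tRNAs, all "+" strand, with the observed alternative
  start codons and TAA/TAG stops, and a 1,855 bp long unassigned region
  (LUR).
* **Composition** — third codon positions drawn from (A,C,G,T) =
  (0.21, 0.05, 0.21, 0.53), giving A-T3 ≈ 74%, with in-frame stops
  resampled away; non-coding and structural-RNA tracts use correspondingly
  A-T-rich profiles. These match the composition regime of AT-rich venerid
  mitogenomes.
* **LUR structure** — a 15 bp × 2 tandem repeat at the 5′ side and a
  109 bp × 2 repeat at the 3′ side, plus an optional planted reverse-strand
  ORF. A stop codon is planted immediately upstream of the ORF's start on
  its own strand so that extraction recovers exactly the planted span.
* **Trend injection** — an optional linear shift of the third-position
  probability of one nucleotide with distance from the anchor gene, in
  %/bp. The default effect size, 0.0005 %/bp (10 percentage points across
  the molecule), is a mid-scale origin signature: stronger than the
  ~0.0003 %/bp trends reported for real venerid genomes (already
  significant there) but far from saturating a window's sampling noise.
* **Divergence** — the M copy accumulates the whole pairwise distance
  under a Kimura two-parameter process (default κ = 2) with gamma rate
  variation (shape 1) at an expected 0.5 substitutions/site before
  selection; a rejection step then reverts non-synonymous changes at 70% of
  protein-coding codons (start and stop always). The realised coding
  divergence lands near 16% per site — the average F/M divergence observed
  in the venerid DUI pair this emulates — with divergence concentrated at
  third positions, which is what makes the fourfold-site analysis
  meaningful on simulated data.
* **Structural differences** — an in-frame 100-codon insertion mid-`cox2`
  in the M copy and one supernumerary tRNA inserted into the M LUR, whose
  heavily mutated (d ≈ 0.3) homolog overwrites the corresponding stretch of
  the F LUR unannotated, emulating the decayed F-side counterparts of
  M-only tRNAs.

One random stream keyed by the config seed drives everything; identical
seed and config give byte-identical genomes, annotations and truths.

What the generator does **not** emulate: secondary structure and its
constraints on tRNA/rRNA evolution, indels outside the two planted
structural events, recombination, selection beyond the
synonymous/non-synonymous dial, and base-composition heterogeneity along
the molecule beyond the injected linear trend. Passing tests on synthetic
data therefore demonstrate the correctness and calibration of the
estimators under the stated model, not the biological fidelity of any
particular inference on real genomes.

## Numerical choices and scale of the checks

* OLS fits, autocorrelations and PCA variance fractions are checked
  against brute-force reimplementations (normal equations, direct
  autocovariance sums, explicit eigendecomposition) to 1e-10 on random
  instances; independent library implementations (statsmodels acf,
  scikit-learn PCA) serve as cross-checks in tests only.
* A zero-variance trend series returns slope 0, R² 0, p 1 rather than an
  error; fewer than 3 valid windows is an error.
* Estimator recovery runs 200 replicates of 2,000-site gap-free pairs at
  expected distance 0.20, asserting the mean Jin–Nei estimate within 3
  Monte-Carlo standard errors; trend-sign recovery uses 40 simulated
  genomes at the default injected effect size; type-I calibration uses 200
  trend-free genomes with non-overlapping windows. These sizes keep the
  whole suite under ~10 s while leaving the assertions statistically
  meaningful.
* Alignment scores are verified against exhaustive affine-gap enumeration
  for inputs up to 8 residues; the same gap convention (first gap base
  pays the opening cost) is implemented independently in the oracle.

## Known limitations

* The built-in pairwise aligner is not a substitute for consensus
  multi-aligner pipelines; distances on real, highly diverged pairs depend
  on alignment quality, and exact reproduction of published per-gene values
  requires supplying the original alignments.
* The trend test inherits every caveat of OLS on compositional,
  window-sampled data: bounded responses, heteroscedastic window counts,
  and autocorrelation under overlapping windows. The autocorrelogram is a
  diagnostic, not a correction.
* The origin report localises candidate regions; it does not (and cannot,
  from composition alone) pin a replication origin to a nucleotide.
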