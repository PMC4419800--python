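# Methods

This note records the statistical model behind `chromstab`, the choices
made where the design was genuinely open, and what the synthetic world does
and does not establish.

## The comparison

All analyses reduce per-gene measurements to a two-compartment contrast:
the X chromosome versus the pooled autosomes. The pooled "A" statistic
weights every autosomal gene equally; it is **not** a mean of chromosome
means. (A chromosome-weighted variant can be computed from the per-
chromosome rows of the same summary table; with autosome gene counts
spanning ~230–2,000 the two differ, and the gene-weighted form is the
primary one.) The X:AA ratio is mean_X / mean_A of the value column under
study.

Confidence intervals on per-chromosome means are Student-t (95%) on the
untransformed values; a bootstrap-percentile alternative is available via
`ci_method="bootstrap"`. For a single observation, or a degenerate
all-equal group, the interval collapses to the mean rather than being
reported as undefined.

## Tests

Group comparisons use Kruskal–Wallis H with average-rank tie correction and
the χ² approximation at k−1 degrees of freedom (via scipy). The statistic
is rank-based, hence invariant under any strictly monotone transform of the
data — appropriate for strongly right-skewed half-lives. When every
observation is identical the test is reported as H = 0, p = 1 (perfect
exchangeability), not as an error. "Two-tailed" labels in the source
literature are retained at face value; the χ²-based p is inherently an
upper-tail probability and that is what is reported.

Pairwise chromosome tests run every unordered pair and correct over the
full pair count (253 for 22 autosomes + X); Bonferroni is the default,
Holm selectable. The single X-vs-pooled-A test can be reported corrected by
the same pair count so it sits on the same footing as the pairwise family.

## Resampling null

The null asks whether the X mean could arise from an arbitrary subset of
autosomal genes: B samples of n_draw autosomal values are drawn without
replacement *within* a sample and independently *across* samples (the
sampler is a vectorised Floyd algorithm, numba-accelerated, driven by
pre-drawn uniforms so the Python fallback produces the identical stream).
The empirical p uses the add-one convention (count_ge + 1)/(B + 1), never
exactly zero, and ties at the observed value count as exceedances
(conservative). The raw exceedance count is reported alongside because
"0 of B samplings reached the observed mean" is itself the result of
interest. Histograms for persistence use Freedman–Diaconis binning.

## Sliding windows

Genes with the value present are ordered by start coordinate within each
arm (p arm: start < centromere coordinate, which is a required input — no
genome build is packaged; the simulator provides a two-arm layout in its
truth block). A window of 30 genes advances one gene per step, giving
n − 29 windows per arm; arms shorter than one window yield an empty
profile. `locate_gene_window` returns the window whose ⌈w/2⌉-th member (in
coordinate order) is the query gene; near an arm end it returns the nearest
window flagged `at_edge`.

## Ribosome density

RPKM = count / (length/10³) / (total/10⁶). Library totals default to the
column sums of the input count tables (the original mapping totals are
generally unavailable); this scales both RPKM columns by constants and
cancels in cross-chromosome comparisons of the density ratio. Filters are
strict inequalities in a fixed order (ribo count > 10, RNA count > 50,
ribo RPKM > 2, RNA RPKM > 5, then the exclusion list), and removal counts
attribute each record to its first failing rule so the tally is
reproducible. Density = ribo RPKM / RNA RPKM, defined only after
filtering guarantees a positive denominator.

## Sequence composition

CDS validation keeps sequences ≥ 60 nt starting with ATG ("shorter than 60"
read strictly, so exactly 60 nt is kept; no alternative start codons). GC
excludes N from numerator and denominator; GC3 takes codon third positions
with N positions excluded and a trailing partial codon ignored with a
warning.

The word matrix counts all DNA words of lengths 1–6 (5,460 columns,
lexicographic within each length) with overlapping windows that never span
sequence boundaries — a chromosome's UTRs are not concatenated, which would
create chimeric words — and windows containing N are skipped. Each count is
divided by the chromosome's total UTR length (a literal "divided by the
sequence length"; dividing by the window count L−k+1 is available behind
`denominator="windows"` and differs negligibly for L ≫ k). PCA operates on
unit-variance-scaled columns (centered, divided by sd; zero-variance
columns dropped with a logged count) via SVD, with component signs fixed so
the leading loading is positive. Explained variance is reported both as a
share of the total and as a share of the variance remaining after the
preceding components — the "x% of total, y% of remaining" convention used
when quoting PC1/PC2 pairs.

## Synthetic world

The generator's defaults state the world the analyses assume: 353 X-linked
genes and 11,326 autosomal genes (autosome counts proportional to real
human per-chromosome gene counts, largest-remainder renormalised);
half-lives log-normal with log-sd 0.75 and log-mean set so the autosomal
mean is ≈ 7 h (the source data's dispersion is unpublished, so the log-sd
is a package choice giving a realistic long right tail — no distributional
fidelity is claimed); a 1.46× multiplicative X-stability effect applied
before the optional 24 h assay ceiling (truncation, flagged per gene, not
resampling — mirroring a pulse-labeling assay that cannot resolve
half-lives beyond ~24 h); Spearman targets of +0.30 (RPKM vs half-life)
and −0.25 (length vs half-life) induced through a Gaussian copula
(r = 2·sin(πρ_s/6)), which hits rank correlations exactly in distribution
while leaving all marginals log-normal — the X multiplier, being monotone,
leaves within-compartment ranks untouched; Poisson ribo/RNA counts with a
per-gene log-normal density (log-sd 0.25, unit mean) elevated 1.3-fold on
X, with library sizes 2×10⁷ (ribo) and 5×10⁷ (RNA); condition pairs with a
global destabilisation factor (default 5.3/8.1 ≈ 0.654, the ratio of
published global means under NMD-factor depletion) and an extra X factor
(default 0.9); and uniform-composition sequences with per-chromosome GC3
targets (default 0.55) plus an optional planted fraction of invalid CDS for
filter testing.

What a green test establishes: that the estimators recover the parameters
of *this* generating process and that the tests are calibrated under *its*
null. The world deliberately omits features of real data — gene-family
clustering, GC isochores, expression-dependent measurement error,
overdispersed counts, UTR motif structure — so green tests do not certify
behaviour under those violations.

## Numerical and I/O choices

- Interval files are BED (0-based half-open) on disk; internal gene
  coordinates are 1-based inclusive; the two converters in
  `chromstab.tables` are the only place the shift occurs.
- Chromosome names are normalised by stripping a `chr` prefix and
  uppercasing X/Y; mitochondrial and unplaced contigs are rejected with a
  logged count (the analysis universe is autosomes + X).
- Genes are mapped to chromosomes only via the user-supplied table — no
  live annotation-database queries, for reproducibility.
- Missing half-lives stay missing (never zero) and such genes are excluded
  from stability statistics but retained in the table. Capped genes are
  included by default; `exclude_capped=True` is a sensitivity switch.
- Table writers emit full-precision floats (`%.17g`), and the reader
  converts through numpy's correctly-rounded parser, so write→read round
  trips are bit-exact and pipeline reruns are byte-identical.
- All randomness flows through numpy Generators seeded from explicit
  seeds; bundle sub-generators use fixed spawn keys so stand-alone calls
  reproduce the bundle exactly.

## Known limitations

- The resampling engine targets B ≤ ~10⁶ on one core; no analytic
  (normal-theory) approximation of the null is provided.
- Pseudoautosomal regions are not modelled or analysed.
- The paired-condition module summarises per-chromosome deltas only; no
  per-gene differential testing.
- `intersect_tables` matches on exact gene identifiers; no cross-dataset
  identifier mapping is attempted.
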