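# Methods

## Coordinate model

All intervals are 0-based half-open, the BED/BEDPE convention; GTF input
(1-based inclusive) is converted on read, so a `gene` line at 1001..2000 on
the + strand yields a TSS at 1000 and a gene body of [1000, 2000). Overlap
means ≥ 1 bp shared under half-open semantics; no minimum-fraction rule is
applied anywhere. Interval queries go through a per-chromosome interval
tree whose answers are, by construction and by test, identical to an
exhaustive scan.

## Anchor and loop classification

A promoter is a strand-symmetric window of ±`promoter_flank_bp` (default
2,000 bp) around a TSS. The symmetric window is a deliberate choice: loop
anchors are themselves wide (kilobases), so the asymmetry of real core
promoters is immaterial at this resolution, and a symmetric window keeps
the definition strand-free. An anchor overlapping any promoter window is
classed *promoter* even if it also overlaps a peak — promoter precedence
makes the promoter/enhancer partition well defined, since H3K27ac peaks
frequently sit on active promoters. Otherwise an overlap with any H3K27ac
peak makes it *enhancer*; otherwise *other*.

Loop categories follow from the unordered anchor-class pair (EEI, EPI,
PPI); a loop touching an *other* anchor goes to a fourth category that is
reported but excluded from the EEI/EPI/PPI percentage denominator, because
those percentages describe the enhancer/promoter interaction network only.
Loop distance is the absolute difference of floor anchor midpoints — the
least anchor-width-sensitive choice — and "long-range" means strictly
greater than `long_range_bp` (default 20,000 bp). Medians of distances use
the lower median so reported values stay integral base pairs; at these
scales the difference from an interpolated median is immaterial.

## Differential loop calling

Per condition, loops are kept when `fdr < fdr_max` (strict, default 0.05)
and `pet_count >= min_pets` (inclusive, default 5), then scaled to PETs per
million valid read pairs. The library-size denominator (`total_valid_pairs`)
comes from upstream processing and is supplied in the run configuration —
it cannot be inferred from a loop file.

Cross-condition matching assigns every loop the key (chrom,
⌊mid₁/`match_bin_bp`⌋, ⌊mid₂/`match_bin_bp`⌋) and pairs keys across
conditions; the default bin of 5,000 bp is the finest resolution at which
such maps are usually visualized, and bin matching — unlike greedy overlap
pairing — is deterministic, order-independent and total (every loop lands
in exactly one pair). Same-condition loops sharing a key are aggregated by
summing counts; the highest-PET member is the representative that supplies
coordinates for category and distance reporting.

A one-sided pair is gained (treated-only) or lost (control-only) *in
number*. A two-sided pair is gained/lost *in strength* when the
treated/control normalized ratio is ≥ `strength_fold` or ≤ 1/`strength_fold`
(inclusive, default 1.5); otherwise unchanged. The fold threshold is a
stated, configurable choice — no significance test is attached to strength
changes, since loop-level FDR control already happened per condition and
there are no replicates to estimate a dispersion from. Gained loops take
their category and distance from the treated side, lost loops from the
control side: the side where the loop exists.

## DEG–loop integration

DEG selection uses the printed inequality forms exactly: up is
log₂FC > 1 (strict) with padj < 0.05 (strict); down is log₂FC ≤ −1
(inclusive) with padj < 0.05. A gene locus is the single-interval union of
the promoter window and the gene body, so both promoter-anchored and
gene-body loops can link. A link requires a direction-consistent
differential loop (up↔gained, down↔lost; unchanged never links) whose
existing-side PET count is ≥ `min_link_pets` (default 5, interpreted as the
raw PET support of the individual linking loop, mirroring the per-loop
filter) and whose representative anchor overlaps the locus. Ranking is by
padj ascending; padj values of exactly 0 are preserved as written (never
floored to machine epsilon), which forces a tie-break — |log₂FC| descending,
then gene id — to keep the order deterministic.

## Synthetic data generator

The generator emulates the statistical structure of a two-condition
H3K27ac HiChIP comparison on a small genome: by default 3 chromosomes of
10 Mb carrying 200 genes and 300 enhancer peaks (placed clear of promoter
windows so planted anchor classes are unambiguous), a backbone of 500
stable loops, 50 gained and 50 lost loops in number, 30 gained and 30 lost
in strength at a true fold of 2, and 25 + 25 decoy loops per condition that
fail the FDR or PET filter. Planted EPI loops sit on (peak, promoter)
pairs, EEI on (peak, peak), PPI on (promoter, promoter); anchors are
feature centre ± 1 kb and anchor-bin keys are kept globally unique so every
planted loop maps to exactly one matched pair. A configurable fraction
(default 0.6) of planted loop changes is coupled to planted DEGs whose
promoter anchors the loop; coupled DEGs get |log₂FC| ≥ 2 and tiny padj,
null genes get zero-centred log₂FC noise and padj ≥ 0.1, and two genes
carry a literal `NA` padj to exercise the parser's drop path.

PET counts: each loop draws a baseline strength from a negative binomial
(mean 15, size 8), capturing the over-dispersion of contact counts across
loops; condition-level raw counts are the baseline scaled by that
condition's sequencing depth (1.2 M and 1.0 M valid pairs by default, so
depth normalization is actually exercised) with multiplicative log-normal
jitter of 0.1 in log₂ units, floored at `min_pets` so a stable loop never
drops below the count filter in just one condition. The jitter models
technical, not biological, variation and is deliberately small relative to
`strength_fold`: a replicate-free fold-change caller is only valid in that
regime, and the generator states the assumption rather than hiding it.
What passing recovery tests therefore show is that the pipeline's
arithmetic and matching are correct under the model's assumptions — not
that a 1.5-fold cutoff without replicates would be well-powered on noisy
real libraries, where between-library variation can exceed this jitter.
FDR fields are assigned (planted < 0.05, decoys ≥ 0.05), not computed:
upstream loop calling is out of scope and the pipeline only consumes FDR.

The worked fixture is a fully hand-specified six-gene bundle whose four
focal genes reproduce published ferroptosis expression values (HDM2 2.44 /
2.91e-239, TXNRD1 2.04 / 1.26e-216, MKI67 −3.89 / 0, TOP2A −3.31 / 0)
coupled to gained/strengthened/lost promoter loops; its golden outputs are
regenerated by the pipeline itself and used as a byte-level regression
anchor.

## Numerical and determinism choices

Thresholds live in one `RunConfig` and are echoed into every run report.
All outputs are deterministically sorted (natural chromosome order, then
anchor starts); repeated runs on identical inputs are byte-identical, and
the generator is byte-reproducible from its seed. Degenerate inputs are
defined rather than special-cased: empty loop sets yield header-only
tables, percentage denominators of zero are reported as absent rather than
NaN, a normalized ratio against a zero control count is treated as
infinite (gained in strength), and identical anchors give distance 0.
Problem sizes in the test suite (bundles of tens to hundreds of loops,
oracle instances ≤ 10³ elements) were chosen as the smallest scales at
which every code path and invariant is exercised.

## Known limitations

Replicate-aware differential testing (dispersion estimation, count-model
p-values) is out of scope by design, as are loop calling, peak calling and
the DE fit itself — all consumed as inputs. Matching by fixed bins can
split a true match across a bin boundary when two anchors straddle it;
at 5 kb bins with 2 kb anchors this affects boundary cases only, and the
generator avoids planting them. One merged loop list per condition is
assumed; replicate merging happens upstream.
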