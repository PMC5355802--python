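# Methods

This note documents the models and numerical choices behind `brickseq`: how
reads are assigned to strands, how presence and incorporation are
quantified, what the simulator does and does not emulate, and where the
design was genuinely open.

## Read model and strand assignment

Sequencing libraries for brick/origami quantification are built by ligating
adaptors onto each single strand; the insert therefore starts with 4–7
random nucleotides (added for cluster diversity on the sequencer) followed
by the 5' end of the strand. Assignment (`matching.assign_read`) scans read
offsets 4, 5, 6 and 7 in increasing order and looks the 20-mer at each
offset up in a hash of strand prefixes; the first hit wins. Only read 1 of
a paired-end run is used — the assignment rule needs only the 5' end.

Choices and edge cases:

* **Exact matching, case-insensitive; `N` never matches.** No
  error-tolerant matching is attempted: with ≥20-nt anchors the false-match
  probability is negligible and mismatch tolerance would need a model of
  sequencer errors the pipeline otherwise avoids.
* **Collisions.** A 20-mer shared by several strands maps to an AMBIGUOUS
  bin rather than an arbitrary winner; `design.validate_prefix_uniqueness`
  reports such pairs up front. Ambiguous and unassigned reads are tallied,
  so read counts are conserved exactly through demultiplexing and
  assignment (asserted by tests at every stage).
* **Short reads.** Reads under 24 nt (shortest leader + anchor) are
  unassignable; reads of 24–26 nt are scanned at the offsets that fit.
* Index-barcode demultiplexing is exact by default with an optional Hamming
  tolerance (default 0); the barcode comes from a separate index FASTQ or
  from the last colon-field of the read header.

## Read fractions and presence thresholding

A strand's read fraction is its count divided by the total *assigned*
count of its sample (unassigned reads carry no strand identity, so
including them would only rescale every fraction by the same factor).

Whether a canvas strand is part of an assembled shape is decided from
v<sub>i</sub> = log2(RF<sub>product,i</sub> / RF<sub>canvas,i</sub>). For a
shape built from a subset of a canvas this distribution is bimodal: a right
mode of incorporated strands and a left mode of strands only present at
trace level in the product band. The procedure
(`incorporation.presence_threshold`):

1. add a pseudocount (default 1 read) to the raw counts of this step only,
   so absent strands give finite ratios — the raw ratio is undefined at
   zero counts;
2. histogram the values into exactly 20 evenly spaced bins spanning their
   range;
3. least-squares fit one- and two-component Gaussian curves to the binned
   counts. The two-component fit is started from several deterministic
   initializations (means at the 25th/75th percentiles with sds of half the
   IQR, and at the two most populated well-separated histogram bins with
   sds of one and two bin widths); the converged start with the lowest
   residual sum of squares is kept. Multi-starting matters because a mode
   concentrated in a single bin needs a near-delta component that a single
   broad start cannot reach;
4. adopt the two-component model only if (a) it wins on AIC computed from
   the binned residuals, (b) the fitted means are at least one bin width
   apart, and (c) the fitted density dips, between the means, to at most
   half the smaller of the two fitted peaks. Criterion (c) rejects the
   common failure mode where a second Gaussian merely absorbs histogram
   jitter in a unimodal sample;
5. with two components, the threshold is the argmin of the fitted density
   strictly between the means, rounded **up** to the next bin edge — the
   conservative direction, erring toward excluding marginal strands. With
   one component the threshold is `None` and every strand is present
   (the usual outcome for origami, where all staples incorporate).

Degenerate inputs: fewer than 20 strands cannot populate a 20-bin histogram
meaningfully, so the fit is refused and all strands are kept, with a
warning. If no least-squares start converges at all, the threshold falls
back to the midpoint of the two most populated histogram modes and the
fallback is logged.

## SRI

`compute_sri` implements

SRI<sub>i</sub> = (P<sub>i</sub>/P<sub>tot</sub>) /
(P<sub>i</sub>/P<sub>tot</sub> + M<sub>i</sub>/M<sub>tot</sub>)

on **raw** counts — no pseudocount, so the formula is exact; a strand with
no reads in either band has undefined SRI. The statistic depends on the
counts only through P<sub>i</sub>/M<sub>i</sub> and
P<sub>tot</sub>/M<sub>tot</sub>, which is why one multiplicative bias per
strand, shared between the bands, cancels exactly (property-tested). SRI
is relative: a ratio of ratios, monotone in incorporation but not linear in
it, and not an absolute structure yield.

Filters, in order of precedence: strands with excluded roles (half-bricks,
edge protectors, scaffold) never receive an SRI; strands below the presence
threshold are flagged `below_threshold`; strands with fewer than 25 product
reads (default `min_product_reads`) are flagged `low_reads` — below that
depth the ratio is too noisy to interpret. Flagged strands render grey.

As a QC, `qc_sequence_correlates` reports the Pearson correlation of SRI
against strand GC fraction: a well-behaved library shows |r| near 0 because
composition bias is shared between bands and cancels. Nearest-neighbour
free-energy correlates are out of scope.

## Mixing experiments

The quantitative accuracy of pooled sequencing is validated by mixing five
pools of six oligos at known ratios across six mixes (a uniform reference
mix A and five cyclic permutations of 1:2:3:4:0, so each pool appears at
0/10/20/30/40% of a mix). Analysis (`mixing`): per-pool mean reads per
member oligo, normalized across pools; each pool's fraction divided by its
fraction in the reference mix; and the resulting values renormalized to sum
to 1 per mix (the normalized read fraction, NRF). The reference division
cancels any per-oligo bias shared across mixes — exactly, which is
property-tested — and the renormalization puts NRF on the same scale as the
expected fractions. Agreement is summarized as the squared Pearson
correlation over all non-reference (expected, observed) pairs, plus the
mean and s.d. of NRF at each expected level (five pools per level). The
reference mix is excluded from R²: its expected values are constant and it
defines the normalization. Pooled points rather than level means are used
for R²; with five observations per level the two differ negligibly.

## Simulator

The simulator generates the statistical structure the pipeline assumes,
not sequencer realism. One assembly is parameterized by:

| parameter | default | meaning |
|---|---|---|
| `true_p` | — | per-strand incorporation probability in [0,1] |
| `stoich_cv` | 0.10 | lognormal cv of input stoichiometry (the ~10% scale expected from spectrophotometric oligo quantification) |
| `bias_sd_log` | 1.0 | sd of log of the per-strand ligation/amplification bias, shared between the bands of one assembly (directly measured single-strand ligation efficiencies span roughly 20–70%, i.e. several-fold — a lognormal with sd(log)=1 covers that spread) |
| `per_sample_bias_sd` | 0 | extra lognormal noise drawn independently per sample; models ligation-step variability that the SRI/NRF normalizations cannot cancel |
| `depth` | 5×10⁵ | multinomial reads per band |
| `read_length` | 50 | emitted read length |

Product-band sampling weights are stoich × bias × p; monomer weights use
(1 − p); the canvas-input sample uses stoich × bias. Reads are drawn
multinomially, formatted as a random 4–7-nt leader, the strand sequence,
and random filler to the read length, and written as FASTQ (R1 plus a
paired index FASTQ) in shuffled order. Re-counting an emitted file
reproduces the input counts exactly, which anchors the round-trip tests.
All randomness flows from one integer seed through named substreams
(band, sample), so every output is byte-reproducible.

Deliberately not modelled: sequencing errors and quality scores, chimeric
reads, strand-specific aggregation, gel cross-contamination, and any
separation of ligation from PCR bias (they are not separately identifiable
from band counts). Passing tests therefore show that the *analysis* is
correct and unbiased under the stated statistical assumptions — consistent
per-strand bias, stoichiometry variation smaller than incorporation
variation — not that those assumptions hold for a particular wet-lab run.

`spatial_incorporation_field` produces incorporation probabilities with a
penalty on lattice-boundary strands, mirroring the empirical pattern that
poor incorporation concentrates at structure edges and thin features; it
exists to make rendered maps show realistic spatial structure in demos and
tests.

## Geometry and rendering

Designs live on a square lattice with inter-helix spacing 2 nm, 10.67 bp
per helical turn and 0.34 nm axial rise per base; base coordinates are
0-based half-open. (The per-turn constant is interpreted as bp/turn, the
square-lattice convention; only relative geometry matters for rendering.)
A strand segment on helix (row, col) spanning bases [b0, b1) becomes a box
with x ∈ [0.34·b0, 0.34·b1) nm and a 2 nm cross-section at
(y, z) = 2·(col, row) nm — so the scene is affine in design coordinates.

SRI maps use linear RGB interpolation from blue (0,0,1) at 0 to yellow
(1,1,0) at 1; flagged strands are grey and excluded from every aggregate.
3D structures are summarized by projections along each major axis — the
per-cell **mean** of contributing box values (max-intensity is available as
an option; the aggregation is a free choice and mean keeps holes visible) —
and by ordered, contiguous slices of configurable thickness (default
8.1 nm, the axial extent of a 24-bp brick layer). Cells no unflagged box
touches are transparent, so tunnels and undetected regions appear as holes.
PNG/SVG output is byte-deterministic for fixed input (fixed dpi, no
timestamps, fixed SVG hash salt).

caDNAno v2 square-lattice JSON is supported by walking each staple's
per-base neighbour arrays 5'→3' and collapsing maximal same-helix runs into
segments; sequences are supplied through a separate id→sequence table since
caDNAno files usually omit them. Honeycomb files are rejected;
insertion/deletion (loop/skip) annotations are ignored with a warning; the
scaffold is carried as a role of its own and excluded from counting and
SRI, as are half-bricks and edge protectors.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data at
sizes chosen to make the statistics stable while staying desk-scale: a
100-strand structure at 5×10⁵ reads per band for replicate concordance, a
400-strand canvas with a 200-strand shape (full FASTQ round trip, 1.5×10⁶
reads total) for detection completeness, 10⁶ reads per mix for the mixing
R², and 20 independent simulations for threshold-classification accuracy.

## Known limitations

* SRI is relative; comparing absolute values across structures with
  different overall assembly yields is not meaningful.
* The presence threshold needs enough strands (≥ 20) and a genuinely
  bimodal ratio distribution; shallow canvas sampling can blur the modes.
* Prefix assignment requires unique 20-mers; designs with repeated 5' ends
  must be flagged via the collision report before sequencing.
* caDNAno support covers plain square-lattice designs without
  insertions/deletions.
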