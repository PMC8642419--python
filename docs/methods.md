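# Methods

This note documents the models, conventions and numerical choices behind
`itrmap`, in the order data flows through the pipeline.

## Coordinate and evidence conventions

All coordinates are 0-based, half-open; BED output follows the BED
standard natively. Insertion positions are between-base coordinates of
the payload-genome boundary at the 3' ITR junction. UMIs — not raw
reads — are the unit of integration evidence everywhere (peak support,
Poisson counts, dilution); raw-read support is carried along for QC only.
One UMI is treated as one captured junction molecule.

## The synthetic library generator

The generator emulates a junction-capture (single-tail adapter/tag PCR)
library: genomic DNA sheared to fragments of Normal(500, 60) bp
(truncated at the read length), nested PCR anchored in the payload 3'
ITR, sequenced as 2 x 250 bp paired ends. Read 1 is
`UMI (10 nt) + terminal ITR segment + genomic flank`; read 2 is the
reverse-complement read from the far fragment end and is not used by the
junction logic (the nested-PCR design anchors the junction on the R1
side).

Planted truth on a random genome (GC fraction 0.41, human-like):

* one protospacer+PAM cassette, padded so no TTAA falls within +/-4 bp of
  the blunt cut site; the planted spacer is guaranteed to be the unique
  exact occurrence (any chance duplicate is point-mutated away);
* `n_off_target_sites` TTAA motifs, non-overlapping, at least 2 kb from
  the cut and 1.5 kb from each other so their background windows stay
  clean;
* a recorded 300 bp decoy (prefix of a 1.2 kb "vector" sequence) verified
  absent from the genome. Background molecules — residual episomal
  payload — read ITR followed by vector sequence and therefore never map;
  they supply the negative UMIs for the LOD procedure.

Default molecule counts (one on-target event with 50 UMIs, nine
off-target events with 20 UMIs each, 50 background UMIs, 0.1% per-base
substitution error) are the standard study conditions used throughout the
tests and the acceptance script.

Per-molecule junction features are drawn independently: with probability
`itr_deletion_prob` (default 0.3) the ITR terminus loses 1-6 bp
(uniform; a fixed length is expressed as min = max), and on-target
molecules additionally carry a 1-3 bp genomic insertion or deletion at
the cut with probability `junction_indel_prob` (default 0.1). Off-target
junctions carry no genomic indels: native transposition into TTAA is
seamless. Background molecules keep intact ITRs, since ITR disruption is
a product of the integration reaction. Sequencing error is
substitution-only with constant Q30 qualities; junction indels, where the
signal of interest lives, are injected explicitly instead.

The on-target event's orientation defaults to "+" (configurable). This
is an identifiability choice, not a shortcut: when the genomic base that
follows a truncated ITR happens to equal the first deleted ITR base, the
split point is intrinsically ambiguous (the same left/right-alignment
ambiguity familiar from VCF indel normalization), and a fraction of
terminal deletions would be recorded one base short. With the default
ITR terminal segment and spacer, the "+" on-target junction has no such
homology, so planted deletion fractions are exactly recoverable; at TTAA
junctions (which begin with T, matching the default ITR's first terminal
base) the ambiguity is real and users should expect a one-base blur
there.

Determinism: every stochastic step derives its generator from
`(seed, stream)` pairs, so a config+seed reproduces FASTQ/BED/TSV output
byte for byte.

## Junction extraction

Reads sharing a UMI are greedily clustered at 0.97 identity (edit
distance over the longer read) so that UMI collisions between unrelated
molecules stay separate — the conventional usearch-style identity
threshold — and each cluster collapses to a column-wise majority-vote
consensus (ties break to the lexicographically smaller base for
determinism). Dedup of already-deduplicated output is the identity.

The ITR terminal segment is then located by *local* alignment (match +2,
mismatch -3, gap open -5, extend -2) against the read prefix. Local
mode matters: the read continues into genomic sequence and the ITR tail
may be truncated, so both right ends must be trimmable simultaneously —
under these scores a chance continuation must begin with a matching base
to extend, so the aligned span ends at the junction. The split point is
the read position where the aligned ITR ends; ITR bases beyond the
aligned span are recorded as a terminal deletion at ITR coordinates, and
internal substitutions/indels are kept as edit operations for profiling.
Acceptance requires >= 20 aligned ITR bases at >= 0.9 identity (tolerant
of the reported ITR-end disruption, strict enough to reject ITR-free
reads); rejection reason is recorded, not raised. Background molecules
are accepted here by design — they carry an ITR — and are separated at
the mapping stage.

## Mapping and peak calling

Genomic segments (>= 25 bp) are placed with edlib (infix mode) in both
orientations with an edit budget of 10% of the segment length. A
placement is unique only if no alternative exists within 4 extra edits
once the winning locus is masked out, and if the best-distance locations
do not spread beyond half a segment length; otherwise the molecule is
`ambiguous`. The junction coordinate is the ITR-proximal end of the
placement: interval start on "+", interval end on "-".

Junction positions within `window_bp` of each other merge into one
candidate. The window is derived from the data as
`max(20, round(SD(read_start) + SD(read_end)))`, with SDs pooled
(size-weighted, population SD) over preliminary 20 bp clusters — the
concrete reading of calibrating the peak model to the spread of read
start and end positions; it is overridable by config. Candidates need
>= 2 UMIs to be tested. The local lambda follows the macs2 convention
(max of genome-wide and 1 kb / 10 kb flank rates, candidate span
excluded, flank windows clipped to the genome); p is the exact Poisson
upper tail, and fold enrichment floors lambda at 0.1 UMIs/window so it
stays finite on clean backgrounds. Benjamini-Hochberg correction runs
over all tested candidates via statsmodels; the default retention cutoff
is q <= 0.001.

Classification: a peak is on-target iff its apex (modal junction
position) lies within 50 bp of the blunt cut site — in practice recovered
peaks sit at distance 0, and the window only absorbs junction indels —
and the TTAA flag is set iff a TTAA motif starts within +/-4 bp of the
apex, which is where a target-site duplication would place it. The
on-target signature is therefore `on_target & !ttaa`; off-target
transposition shows `off_target & ttaa`.

## Indel profiling

Two axes. `itr_relative` consumes the ITR edit operations from junction
splitting; offsets are 0-based from the first ITR base. A deletion
increments the count at every offset it spans; an insertion is attributed
to the offset of the base preceding it (left-anchored). Molecules (UMI
consensuses) are counted, consistent with the rest of the pipeline.
`cut_relative` consumes the genomic alignments: cigar-level indels at
their genome offsets from the cut, plus junction-level shifts — a
molecule whose junction maps past the cut counts as a deletion of the
skipped cut-proximal bases, which is the only way a junction library can
express a deletion that consumed the boundary itself.

## Limit of detection

Positives are UMIs whose junction maps within the on-target window;
negatives are all other UMIs (off-target, unmapped, background).
For each fraction in {0.01, 0.10, 0.25, 0.50, 0.99} and each of 100
replicates, `round(fraction * n_pos)` positives are drawn without
replacement, all negatives are kept, peaks are re-called on the diluted
set, and the on-target peak's fold enrichment and q-value are recorded
(FE = 0 when no peak is called). The extrapolation regresses log10
fraction on the per-fraction replicate mean of log10 FE (log-FE is the
predictor), excluding FE = 0 replicates from the mean and undetected
fractions from the fit; the LOD is the fitted fraction at FE = 1, the
background level — FE = 0 is unreachable under a floored lambda, so the
log-scale crossing is the meaningful detection boundary. The estimate is
censored (reported as the smallest tested fraction, an upper bound) when
that fraction is still significant in >= 95% of replicates and the
extrapolation falls below it, or when FE never declines across the grid
and no line can be fitted. Fixed seeds make the whole table reproducible.

On the default simulation the procedure lands at ~0.2% — logged as a
sanity observation, not asserted, since it depends on the simulated
background depth.

## Guide utilities

The cut model is a blunt cut 3 bp 5' of the PAM (SpCas9); SaCas9, CjCas9
and LbCpf1 are available as (PAM, offset) presets only — staggered-cut
geometry is out of scope. Off-target enumeration is an exhaustive
numpy-vectorized scan of both strands for IUPAC-PAM-matching windows
within a Hamming budget (<= 6) of the spacer; mismatch count is the only
score. Reporter arithmetic takes %GFP (on-target) and %RFP (overall)
and reports off-target as `max(0, overall - on)`, warning when clipping
occurs.

## Problem sizes and limitations

The bundled simulations (100 kb genome, a few hundred molecules; 1000
molecules for deletion-fraction recovery) are sized so the full test
suite and the acceptance script each run in seconds on one CPU while
every recovery statistic is measured on enough molecules to be stable.

What passing tests on synthetic data do *not* show: robustness to PCR
duplicates and chimeras, quality-dependent error profiles, repetitive or
diploid genomes, multi-chromosome references, or adapter contamination —
none of which the generator models. The uniqueness margin makes the
mapper conservative in repeats (molecules become `ambiguous` rather than
mis-placed), and the LOD band obtained here reflects the simulated
background depth, not any real library's.
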