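"""Mapping of junction genomic segments and insertion-site peak calling.

Each junction read's genomic segment is placed on the reference (either
orientation) with a uniqueness margin; junction coordinates are aggregated
into candidate insertion sites, tested against a local Poisson background
(macs2-style local lambda: the maximum of the genome-wide UMI rate and
flank rates at 1 kb and 10 kb around the candidate), Benjamini-Hochberg
corrected, and classified on-/off-target against the Cas9 cut site.  UMIs,
not raw reads, are the unit of evidence throughout.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import edlib
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import ReferenceGenome, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class AlignedJunction:
    umi: str
    chrom: str
    junction_pos: int
    strand: str
    mapq_unique: bool
    read_start: int
    read_end: int
    edits: list[tuple[str, int, int]] = field(default_factory=list)
    side: str = "3prime"


@dataclass(frozen=True)
class Unmapped:
    umi: str
    reason: str  # {"too_short", "none", "ambiguous"}


@dataclass(frozen=True)
class PeakParams:
    window_bp: int | None = None  # None = derive from read start/end SDs
    background_flanks_bp: tuple[int, ...] = (1000, 10000)
    q_threshold: float = 0.001
    min_umis: int = 2
    pseudo_lambda: float = 0.1
    max_edit_frac: float = 0.1
    min_segment_len: int = 25
    unique_margin: int = 5

    def __post_init__(self) -> None:
        if self.window_bp is not None and self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")


@dataclass
class InsertionPeak:
    chrom: str
    start: int
    end: int
    apex: int
    n_umis: int
    n_reads: int
    expected: float
    fold_enrichment: float
    p_value: float
    q_value: float = float("nan")
    label: str = "unclassified"
    distance_to_cut: int | None = None
    ttaa: bool = False
    strand: str = "."


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def align_junction(
    jr, genome: ReferenceGenome, params: PeakParams = PeakParams()
) -> AlignedJunction | Unmapped:
    """Place a junction read's genomic segment uniquely on the reference.

    Both orientations are searched (edlib, infix mode).  The placement is
    unique only if no alternative placement exists within
    ``unique_margin`` - 1 extra edits once the best locus is masked.  The
    junction coordinate is the ITR-proximal end of the placement: the
    interval start on the + strand, the interval end on the - strand.
    """
    seg = jr.genomic_seq.upper()
    if len(seg) < params.min_segment_len:
        return Unmapped(jr.umi, "too_short")
    k = int(params.max_edit_frac * len(seg))
    best = None  # (dist, strand, start, end, cigar)
    ambiguous = False
    for strand, query in (("+", seg), ("-", reverse_complement(seg))):
        res = edlib.align(query, genome.sequence, mode="HW", task="path", k=k)
        d = res["editDistance"]
        if d < 0:
            continue
        locs = res["locations"]
        starts = sorted({s for s, _ in locs if s is not None})
        multi = starts and (starts[-1] - starts[0] > len(seg) // 2)
        if best is None or d < best[0]:
            s, e = locs[0]
            best = (d, strand, s, e + 1, res["cigar"])
            ambiguous = multi
        elif d == best[0]:
            ambiguous = True
    if best is None:
        return Unmapped(jr.umi, "none")
    if ambiguous:
        return Unmapped(jr.umi, "ambiguous")

    d, strand, start, end, cigar = best
    # second-best check: mask the winning locus and re-search both strands
    masked = genome.sequence[:start] + "#" * (end - start) + genome.sequence[end:]
    k2 = d + params.unique_margin - 1
    for query in (seg, reverse_complement(seg)):
        res = edlib.align(query, masked, mode="HW", task="distance", k=k2)
        if res["editDistance"] >= 0:
            return Unmapped(jr.umi, "ambiguous")

    junction_pos = start if strand == "+" else end
    edits = _genomic_edits(cigar, start, end, strand)
    return AlignedJunction(
        umi=jr.umi,
        chrom=genome.name,
        junction_pos=junction_pos,
        strand=strand,
        mapq_unique=True,
        read_start=start,
        read_end=end,
        edits=edits,
        side=getattr(jr, "side", "3prime"),
    )


def _genomic_edits(cigar: str, start: int, end: int, strand: str):
    """Convert an edlib cigar into (kind, genome_pos, length) operations."""
    edits = []
    gpos = start
    for op, n in _parse_cigar(cigar):
        if op == "=":
            gpos += n
        elif op == "X":
            edits.append(("X", gpos, n))
            gpos += n
        elif op == "D":  # gap in query = genomic bases absent from the read
            edits.append(("D", gpos, n))
            gpos += n
        elif op == "I":  # read bases absent from the genome
            edits.append(("I", max(start, gpos - 1), n))
    return edits


def align_all(junction_reads, genome, params: PeakParams = PeakParams()):
    """Map a batch of junction reads; returns (aligned, unmapped)."""
    aligned, unmapped = [], []
    for jr in junction_reads:
        res = align_junction(jr, genome, params)
        (aligned if isinstance(res, AlignedJunction) else unmapped).append(res)
    logger.info("aligned %d junctions, %d unmapped", len(aligned), len(unmapped))
    return aligned, unmapped


def derive_window(alignments, prelim_window: int = 20) -> int:
    """Aggregation window from the spread of read start/end positions.

    Junctions are pre-clustered at ``prelim_window`` bp; the window is
    max(20, round(SD(read_start) + SD(read_end))) with SDs pooled over
    clusters (size-weighted, population SD).
    """
    clusters = _cluster_positions(alignments, prelim_window)
    sds, weights = [], []
    for members in clusters:
        if len(members) < 2:
            continue
        starts = np.array([a.read_start for a in members], dtype=float)
        ends = np.array([a.read_end for a in members], dtype=float)
        sds.append(starts.std() + ends.std())
        weights.append(len(members))
    if not sds:
        return prelim_window
    pooled = float(np.average(sds, weights=weights))
    return max(20, int(round(pooled)))


def _cluster_positions(alignments, window: int):
    """Group alignments whose junction positions are within ``window`` bp."""
    ordered = sorted(alignments, key=lambda a: a.junction_pos)
    clusters, current = [], []
    for a in ordered:
        if current and a.junction_pos - current[-1].junction_pos > window:
            clusters.append(current)
            current = []
        current.append(a)
    if current:
        clusters.append(current)
    return clusters


def call_peaks(
    alignments: list[AlignedJunction],
    genome: ReferenceGenome,
    params: PeakParams = PeakParams(),
) -> list[InsertionPeak]:
    """Aggregate junctions into candidate sites and Poisson-test each one.

    For a candidate with n distinct UMIs the expectation is
    lambda = window_bp * max(genome-wide UMI rate, flank rates over
    ``background_flanks_bp`` excluding the candidate's own span), and
    p = P(X >= n | lambda) for X ~ Poisson(lambda).  Fold enrichment is
    n / max(lambda, pseudo_lambda).  Candidates with fewer than
    ``min_umis`` UMIs are dropped before testing.
    """
    if not alignments:
        raise ValueError("no mapped junctions")
    window = params.window_bp if params.window_bp is not None else derive_window(alignments)
    clusters = _cluster_positions(alignments, window)

    total_umis = len({a.umi for a in alignments})
    genome_rate = total_umis / len(genome.sequence)

    peaks = []
    for members in clusters:
        umis = {a.umi for a in members}
        if len(umis) < params.min_umis:
            continue
        positions = [a.junction_pos for a in members]
        apex = _modal_position(positions)
        start, end = min(positions), max(positions) + 1
        rate = genome_rate
        for flank in params.background_flanks_bp:
            lo = max(0, apex - flank)
            hi = min(len(genome.sequence), apex + flank)
            n_bg = len(
                {
                    a.umi
                    for a in alignments
                    if lo <= a.junction_pos < hi
                    and not (start <= a.junction_pos < end)
                }
            )
            span = (hi - lo) - (min(hi, end) - max(lo, start))
            if span > 0:
                rate = max(rate, n_bg / span)
        lam = rate * window
        n = len(umis)
        p = float(stats.poisson.sf(n - 1, lam))
        strand_votes = Counter(a.strand for a in members)
        peaks.append(
            InsertionPeak(
                chrom=members[0].chrom,
                start=start,
                end=end,
                apex=apex,
                n_umis=n,
                n_reads=sum(getattr(a, "support", 1) for a in members),
                expected=lam,
                fold_enrichment=n / max(lam, params.pseudo_lambda),
                p_value=p,
                strand=strand_votes.most_common(1)[0][0],
            )
        )
    peaks.sort(key=lambda pk: (pk.chrom, pk.start))
    return peaks


def _modal_position(positions: list[int]) -> int:
    counts = Counter(positions)
    return min(sorted(counts), key=lambda pos: (-counts[pos], pos))


def correct_fdr(
    peaks: list[InsertionPeak], q_threshold: float = 0.001
) -> list[InsertionPeak]:
    """Benjamini-Hochberg across all tested candidates; keep q <= threshold.

    q-values are written onto every input peak; the returned list contains
    the retained peaks ordered by genome coordinate.
    """
    if not peaks:
        return []
    pvals = np.array([pk.p_value for pk in peaks])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for pk, q in zip(peaks, qvals):
        pk.q_value = float(q)
    kept = [pk for pk in peaks if pk.q_value <= q_threshold]
    kept.sort(key=lambda pk: (pk.chrom, pk.start))
    return kept


def classify_peaks(
    peaks: list[InsertionPeak],
    genome: ReferenceGenome,
    cut_site: int | None,
    on_target_window: int = 50,
) -> list[InsertionPeak]:
    """Label peaks on-/off-target and flag the piggyBac TTAA signature.

    A peak is on-target iff |apex - cut_site| <= ``on_target_window``;
    ``ttaa`` is true iff a TTAA motif starts within +/-4 bp of the apex.
    With ``cut_site=None`` peaks stay labeled "unclassified" (TTAA still
    flagged).
    """
    if cut_site is not None and not 0 <= cut_site <= len(genome.sequence):
        raise ValueError("cut site outside genome")
    for pk in peaks:
        lo = max(0, pk.apex - 4)
        window_seq = genome.sequence[lo : pk.apex + 8]
        pk.ttaa = "TTAA" in window_seq
        if cut_site is None:
            pk.label = "unclassified"
            pk.distance_to_cut = None
        else:
            pk.distance_to_cut = pk.apex - cut_site
            pk.label = (
                "on_target" if abs(pk.distance_to_cut) <= on_target_window else "off_target"
            )
    return peaks
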