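"""UMI consensus collapsing and ITR/genome junction splitting.

Reads sharing a UMI (and sufficient sequence identity, to keep UMI
collisions apart) collapse to a majority-vote consensus molecule.  Each
consensus is then split at the end of its terminal ITR segment by
semi-global alignment: the ITR must align from the read start (after the
UMI) but may stop early, which is how transposition-induced ITR-terminal
truncations are detected and recorded for indel profiling.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import edlib
from Bio import SeqIO
from Bio.Align import PairwiseAligner

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ItrSpec:
    """The ITR terminal segment to anchor on, with acceptance thresholds."""

    sequence: str
    side: str = "3prime"
    min_match_len: int = 20
    min_identity: float = 0.9

    def __post_init__(self) -> None:
        if self.side not in ("5prime", "3prime"):
            raise ValueError("side must be 5prime or 3prime")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_match_len > len(self.sequence):
            raise ValueError("min_match_len exceeds ITR length")


@dataclass
class ConsensusRead:
    """A UMI-collapsed molecule; ``seq`` excludes the UMI prefix."""

    umi: str
    seq: str
    support: int = 1


@dataclass
class JunctionRead:
    """A consensus molecule split into ITR and genomic segments.

    ``itr_alignment`` is ``((itr_start, itr_end), ops)`` where ops are
    ``(kind, itr_offset, length)`` tuples with kind in {"X", "D", "I"}
    (substitution, ITR bases deleted in the read, read bases inserted).
    Offsets are 0-based from the first ITR base; a terminal truncation is
    recorded as a deletion spanning the missing ITR tail.
    """

    umi: str
    side: str
    itr_end_in_read: int
    genomic_seq: str
    itr_alignment: tuple[tuple[int, int], list[tuple[str, int, int]]]
    support: int = 1
    identity: float = 1.0


@dataclass(frozen=True)
class Rejection:
    umi: str
    reason: str


def _extract_umi(record) -> tuple[str, str]:
    """UMI from the read name tag ``UMI:<seq>`` (simulator convention)."""
    name = record.id if hasattr(record, "id") else record[0]
    for token in name.split("|"):
        if token.startswith("UMI:"):
            return token[4:], name
    return "", name


def dedup_umis(
    reads: Iterable,
    umi_length: int = 10,
    cluster_identity: float = 0.97,
    min_length: int = 30,
) -> list[ConsensusRead]:
    """Collapse reads to per-UMI majority-vote consensus molecules.

    ``reads`` are Bio.SeqRecord objects (or ``(name, seq)`` tuples) whose
    sequence starts with the UMI.  Within a UMI, reads are greedily
    clustered at ``cluster_identity`` so that UMI collisions between
    unrelated molecules stay separate; each cluster yields one consensus
    with its raw-read support.  Reads shorter than ``min_length`` + UMI are
    skipped (count logged).
    """
    groups: dict[str, list[str]] = defaultdict(list)
    n_skipped = 0
    for rec in reads:
        seq = str(rec.seq) if hasattr(rec, "seq") else rec[1]
        umi_tag, _ = _extract_umi(rec)
        if len(seq) < umi_length + min_length:
            n_skipped += 1
            continue
        umi = umi_tag or seq[:umi_length]
        groups[umi].append(seq[umi_length:])
    if n_skipped:
        logger.info("dedup: skipped %d reads shorter than %d bp", n_skipped, umi_length + min_length)

    out: list[ConsensusRead] = []
    for umi in sorted(groups):
        clusters: list[list[str]] = []
        for seq in groups[umi]:
            placed = False
            for cl in clusters:
                rep = cl[0]
                d = edlib.align(seq, rep, mode="NW", task="distance")["editDistance"]
                if 1.0 - d / max(len(seq), len(rep)) >= cluster_identity:
                    cl.append(seq)
                    placed = True
                    break
            if not placed:
                clusters.append([seq])
        for cl in clusters:
            out.append(ConsensusRead(umi=umi, seq=_majority_consensus(cl), support=len(cl)))
    return out


def _majority_consensus(seqs: list[str]) -> str:
    if len(seqs) == 1:
        return seqs[0]
    lengths = Counter(len(s) for s in seqs)
    target_len = max(lengths, key=lambda L: (lengths[L], L))
    cols = []
    for i in range(target_len):
        votes = Counter(s[i] for s in seqs if len(s) > i)
        top = max(votes.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        cols.append(top[0])
    return "".join(cols)


def consensus_to_records(consensuses: list[ConsensusRead]) -> list[tuple[str, str]]:
    """Round-trip helper: re-emit consensuses in the raw-read convention."""
    return [(f"cons|UMI:{c.umi}", c.umi + c.seq) for c in consensuses]


def _make_aligner() -> PairwiseAligner:
    # Local alignment: the read runs on into genomic sequence and the ITR
    # tail may be truncated at the junction, so both right ends must be
    # trimmable at once.  With these scores a chance continuation needs a
    # matching base to extend, so the aligned span ends at the junction.
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


def split_junction(read: ConsensusRead, itr: ItrSpec) -> JunctionRead | Rejection:
    """Split a consensus read at the end of its aligned ITR segment.

    The ITR is aligned semi-globally to the read prefix: anchored at the
    left (both sequences start together), free at the right.  The split
    point is the read position where the aligned ITR ends; ITR bases beyond
    the aligned span are recorded as a terminal deletion.  Accepts iff the
    aligned ITR length is >= ``min_match_len`` and identity over the aligned
    span is >= ``min_identity``; otherwise rejects with reason ``no_itr``.
    """
    window = read.seq[: len(itr.sequence) + 40]
    if not window:
        return Rejection(read.umi, "no_itr")
    aln = _ALIGNER.align(window, itr.sequence.upper())[0]
    t_blocks, q_blocks = aln.aligned
    if len(q_blocks) == 0:
        return Rejection(read.umi, "no_itr")
    q_start = int(q_blocks[0][0])
    q_end = int(q_blocks[-1][1])
    t_start = int(t_blocks[0][0])
    t_end = int(t_blocks[-1][1])

    ops: list[tuple[str, int, int]] = []
    matches = 0
    columns = 0
    # leading context outside the local alignment
    if q_start > 0 and t_start == 0:
        ops.append(("D", 0, q_start))  # ITR start missing from the read
    elif t_start > 0 and q_start == 0:
        ops.append(("I", 0, t_start))  # read starts with non-ITR bases
    prev_t, prev_q = t_start, q_start
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if qs > prev_q:  # ITR bases absent from the read
            ops.append(("D", prev_q, qs - prev_q))
            columns += qs - prev_q
        if ts > prev_t:  # read bases inserted relative to the ITR
            ops.append(("I", max(0, prev_q - 1), ts - prev_t))
            columns += ts - prev_t
        for k in range(te - ts):
            columns += 1
            if window[ts + k] == itr.sequence[qs + k].upper():
                matches += 1
            else:
                ops.append(("X", qs + k, 1))
        prev_t, prev_q = te, qe
    identity = matches / columns if columns else 0.0

    if q_end - q_start < itr.min_match_len or identity < itr.min_identity:
        return Rejection(read.umi, "no_itr")
    if q_end < len(itr.sequence):  # terminal truncation
        ops.append(("D", q_end, len(itr.sequence) - q_end))
    return JunctionRead(
        umi=read.umi,
        side=itr.side,
        itr_end_in_read=t_end,
        genomic_seq=read.seq[t_end:],
        itr_alignment=((q_start, q_end), ops),
        support=read.support,
        identity=identity,
    )


def extract_junctions(
    r1_path: str | Path,
    itr: ItrSpec,
    umi_length: int = 10,
    cluster_identity: float = 0.97,
) -> tuple[list[JunctionRead], list[Rejection]]:
    """FASTQ -> deduplicated, ITR-split junction reads (plus rejections)."""
    records = SeqIO.parse(str(r1_path), "fastq")
    consensuses = dedup_umis(records, umi_length=umi_length, cluster_identity=cluster_identity)
    accepted: list[JunctionRead] = []
    rejected: list[Rejection] = []
    for cons in consensuses:
        res = split_junction(cons, itr)
        if isinstance(res, JunctionRead):
            accepted.append(res)
        else:
            rejected.append(res)
    logger.info(
        "extract: %d consensus molecules, %d junctions, %d rejected",
        len(consensuses), len(accepted), len(rejected),
    )
    return accepted, rejected
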