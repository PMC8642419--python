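"""Guide-RNA utilities: cut-site arithmetic, exhaustive off-target scanning,
and fluorescent-reporter efficiency arithmetic.

The off-target scan enumerates every genomic window whose PAM matches the
guide's IUPAC PAM pattern and whose protospacer is within a Hamming-distance
budget of the spacer, on both strands.  Mismatch count is the only score;
activity weighting (CFD-style) is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import ReferenceGenome, reverse_complement

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


#: Default 20-nt spacer used by the self-contained simulation configs.
DEFAULT_SPACER = "GAGTCCGAGCAGAAGAAGAA"


@dataclass(frozen=True)
class GuideSpec:
    """A CRISPR guide: spacer, IUPAC PAM pattern and blunt-cut offset.

    ``cut_offset`` counts from the PAM-proximal end of the spacer; the SpCas9
    default (3) places a blunt cut between positions -3 and -4 of the
    protospacer.
    """

    spacer: str = DEFAULT_SPACER
    pam: str = "NGG"
    cut_offset: int = 3

    def __post_init__(self) -> None:
        if not 17 <= len(self.spacer) <= 24:
            raise ValueError("spacer must be 17-24 nt")
        if set(self.spacer.upper()) - set("ACGT"):
            raise ValueError("spacer must be over {A,C,G,T}")
        if set(self.pam.upper()) - set(IUPAC):
            raise ValueError("pam must be an IUPAC pattern")
        object.__setattr__(self, "spacer", self.spacer.upper())
        object.__setattr__(self, "pam", self.pam.upper())


#: (pam, cut_offset) presets for the nucleases supported as find modules.
NUCLEASE_PRESETS = {
    "SpCas9": ("NGG", 3),
    "SaCas9": ("NNGRRT", 3),
    "CjCas9": ("NNNNRYAC", 3),
    "LbCpf1": ("TTTV", 18),
}


@dataclass(frozen=True)
class OffTargetHit:
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int
    site_seq: str


@dataclass(frozen=True)
class EfficiencySummary:
    pct_on_target: float
    pct_overall: float
    pct_off_target: float


def _scan(guide: GuideSpec, genome_seq: str, max_mismatches: int):
    """Vectorized both-strand scan; yields (start, end, strand, mm)."""
    g = np.frombuffer(genome_seq.upper().encode(), dtype=np.uint8)
    lsp, lpam = len(guide.spacer), len(guide.pam)
    L = lsp + lpam
    n = len(g) - L + 1
    if n <= 0:
        return
    # plus strand: spacer then PAM
    mm = np.zeros(n, dtype=np.int16)
    for j, base in enumerate(guide.spacer):
        mm += g[j : j + n] != ord(base)
    ok = mm <= max_mismatches
    for j, code in enumerate(guide.pam):
        allowed = np.frombuffer(IUPAC[code].encode(), dtype=np.uint8)
        ok &= np.isin(g[lsp + j : lsp + j + n], allowed)
    for i in np.nonzero(ok)[0]:
        yield int(i), int(i) + L, "+", int(mm[i])
    # minus strand: plus-strand sequence is revcomp(pam) + revcomp(spacer)
    rc_spacer = reverse_complement(guide.spacer)
    rc_pam = guide.pam.translate(_IUPAC_COMP)[::-1]
    mm = np.zeros(n, dtype=np.int16)
    for j, base in enumerate(rc_spacer):
        mm += g[lpam + j : lpam + j + n] != ord(base)
    ok = mm <= max_mismatches
    for j, code in enumerate(rc_pam):
        allowed = np.frombuffer(IUPAC[code].encode(), dtype=np.uint8)
        ok &= np.isin(g[j : j + n], allowed)
    for i in np.nonzero(ok)[0]:
        yield int(i), int(i) + L, "-", int(mm[i])


def find_cut_site(guide: GuideSpec, genome: ReferenceGenome) -> tuple[int, str]:
    """Locate the unique protospacer+PAM and return the blunt-cut coordinate.

    The cut is a 0-based between-base coordinate ``cut_offset`` bp 5' of the
    PAM on the protospacer strand.
    """
    hits = [h for h in _scan(guide, genome.sequence, 0)]
    if not hits:
        raise ValueError("protospacer not found")
    if len(hits) > 1:
        raise ValueError("ambiguous protospacer")
    start, end, strand, _ = hits[0]
    if strand == "+":
        cut = start + len(guide.spacer) - guide.cut_offset
    else:
        cut = start + len(guide.pam) + guide.cut_offset
    return cut, strand


def enumerate_offtargets(
    guide: GuideSpec, genome: ReferenceGenome, max_mismatches: int
) -> list[OffTargetHit]:
    """Exhaustive mismatch scan of both strands, sorted by (mismatches, coord)."""
    if max_mismatches > 6:
        raise ValueError("max_mismatches must be <= 6")
    hits = []
    for start, end, strand, mm in _scan(guide, genome.sequence, max_mismatches):
        site = genome.sequence[start:end]
        if strand == "-":
            site = reverse_complement(site)
        hits.append(OffTargetHit(genome.name, start, end, strand, mm, site))
    hits.sort(key=lambda h: (h.mismatches, h.start, h.strand))
    return hits


def reporter_efficiencies(pct_gfp: float, pct_rfp: float) -> EfficiencySummary:
    """Split reporter fluorescence into on-/overall/off-target percentages.

    GFP reports on-target insertion (ORF reconstitution), RFP overall
    insertion; off-target is the clipped difference overall - on.
    """
    for name, v in (("pct_gfp", pct_gfp), ("pct_rfp", pct_rfp)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    if pct_gfp > pct_rfp:
        logger.warning(
            "on-target %% (%.3g) exceeds overall %% (%.3g); off-target clipped to 0",
            pct_gfp, pct_rfp,
        )
    return EfficiencySummary(
        pct_on_target=pct_gfp,
        pct_overall=pct_rfp,
        pct_off_target=max(0.0, pct_rfp - pct_gfp),
    )
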