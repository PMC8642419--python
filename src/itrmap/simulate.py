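"""Synthetic junction-capture (STAT-PCR style) library generator.

Emulates the library structure of single-tail adapter/tag PCR anchored in the
3' inverted terminal repeat (ITR) of a piggyBac-class transposon payload:
genomic DNA sheared to ~500 bp fragments, nested PCR from the ITR, sequenced
as 2 x 250 bp paired-end reads.  Every captured molecule carries a unique
molecular identifier (UMI); read 1 is UMI + terminal ITR segment + genomic
flank read off the insertion point.

The generator plants, on a random reference genome:

* one protospacer + PAM locus (the programmed Cas9 target; the on-target
  insertion sits at the blunt cut site, *not* at a TTAA motif),
* a configurable number of TTAA motifs hosting off-target insertions
  (piggyBac's native preference, with target-site duplication),
* a recorded decoy sequence guaranteed absent from the genome, used as the
  "vector" body of background (non-integrated episomal payload) molecules.

Truth is emitted as BED6 plus a per-molecule manifest so downstream recovery
can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Terminal 60 bp of the payload 3' ITR used by default.  The junction-facing
#: end deliberately does not terminate in TTAA (the TTAA duplication is a
#: property of the genomic target site, not of the ITR itself).
DEFAULT_ITR = "TTAACCCTAGAAAGATAGTCTGCGTAAAATTGACGCATGATTATCTTTAACGTACGTCAC"

#: Constant PHRED quality written for every base (Q30).
_QUAL_CHAR = "?"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic junction-capture library.

    Counts are molecules (UMIs); probabilities are per molecule except
    ``substitution_error_rate`` which is per sequenced base.
    """

    genome_length: int = 100_000
    gc_fraction: float = 0.41
    seed: int = 1
    n_on_target_umis: int = 50
    n_off_target_sites: int = 9
    umis_per_off_site: int = 20
    n_background_umis: int = 50
    fragment_mean: int = 500
    fragment_sd: float = 60.0
    read_length: int = 250
    substitution_error_rate: float = 0.001
    itr_deletion_prob: float = 0.3
    itr_deletion_minlen: int = 1
    itr_deletion_maxlen: int = 6
    junction_indel_prob: float = 0.1
    umi_length: int = 10
    on_target_strand: str = "+"

    def __post_init__(self) -> None:
        counts = dict(
            genome_length=self.genome_length,
            n_on_target_umis=self.n_on_target_umis,
            n_off_target_sites=self.n_off_target_sites,
            umis_per_off_site=self.umis_per_off_site,
            n_background_umis=self.n_background_umis,
            fragment_mean=self.fragment_mean,
            read_length=self.read_length,
            itr_deletion_minlen=self.itr_deletion_minlen,
            itr_deletion_maxlen=self.itr_deletion_maxlen,
            umi_length=self.umi_length,
        )
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        probs = dict(
            gc_fraction=self.gc_fraction,
            substitution_error_rate=self.substitution_error_rate,
            itr_deletion_prob=self.itr_deletion_prob,
            junction_indel_prob=self.junction_indel_prob,
        )
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must be <= fragment_mean")
        if self.genome_length < 10 * self.fragment_mean:
            raise ValueError("genome_length must be >= 10 * fragment_mean")
        if self.itr_deletion_minlen > self.itr_deletion_maxlen:
            raise ValueError("itr_deletion_minlen > itr_deletion_maxlen")
        if self.on_target_strand not in ("+", "-"):
            raise ValueError("on_target_strand must be '+' or '-'")

    @classmethod
    def from_json(cls, payload: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class ReferenceGenome:
    """A synthetic reference with its planted features and decoy sequence."""

    name: str
    sequence: str
    planted_features: list[tuple[str, int, int, str]]
    decoy: str = ""
    vector: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    def features(self, label: str) -> list[tuple[str, int, int, str]]:
        return [f for f in self.planted_features if f[0] == label]

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.sequence), width):
                fh.write(self.sequence[i : i + width] + "\n")


@dataclass
class IntegrationEvent:
    """Ground-truth payload insertion.

    ``position`` is the 0-based between-base coordinate of the payload-genome
    boundary at the 3' ITR junction.  Per-molecule ITR truncations and
    junction indels are drawn at read-simulation time and recorded in the
    manifest; the event-level ``itr_deletion``/``genomic_indel`` describe the
    planted (nominal) junction.
    """

    event_id: str
    position: int
    strand: str
    klass: str  # {"on_target", "off_target"}
    ttaa_site: bool
    itr_deletion: int = 0
    genomic_indel: int = 0
    n_umis: int = 0


@dataclass
class ReadSet:
    r1_path: Path
    r2_path: Path
    truth_path: Path
    manifest_path: Path
    manifest: pd.DataFrame


class SizingError(ValueError):
    """Genome too short to host the requested planted features."""


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _concrete_pam(pam: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_IUPAC[c])) for c in pam.upper())


def make_reference(config: SimConfig, guide) -> ReferenceGenome:
    """Build a random genome with the guide locus, TTAA motifs and a decoy.

    The protospacer + PAM is planted once, padded so that no TTAA falls
    within +/-4 bp of the cut site (the on-target signature is TTAA-free).
    ``n_off_target_sites`` non-overlapping TTAA motifs are planted at least
    2 kb from the cut site.  Deterministic given ``config.seed``.
    """
    if not 17 <= len(guide.spacer) <= 24:
        raise ValueError("guide spacer must be 17-24 nt")
    rng = np.random.default_rng([config.seed, 0])
    margin = int(config.fragment_mean + 10 * config.fragment_sd)
    pad = "GCGCG"
    site_len = len(guide.spacer) + len(guide.pam) + 2 * len(pad)
    # quick capacity check: each feature needs ~1.5 kb of clearance
    needed = 2 * margin + site_len + config.n_off_target_sites * 1500 + 4000
    if config.genome_length < needed:
        raise SizingError(
            f"genome_length {config.genome_length} too short for "
            f"{config.n_off_target_sites} off-target sites (need >= {needed})"
        )

    seq = list(_random_dna(rng, config.genome_length, config.gc_fraction))
    pam_concrete = _concrete_pam(guide.pam, rng)
    cassette = pad + guide.spacer + pam_concrete + pad
    s = int(rng.integers(margin, config.genome_length - margin - len(cassette)))
    seq[s : s + len(cassette)] = list(cassette)
    proto_start = s + len(pad)
    proto_end = proto_start + len(guide.spacer) + len(guide.pam)
    cut = proto_start + len(guide.spacer) - guide.cut_offset

    # plant TTAA motifs: non-overlapping, >= 2 kb from the cut, >= 1.5 kb apart
    ttaa_starts: list[int] = []
    attempts = 0
    while len(ttaa_starts) < config.n_off_target_sites:
        attempts += 1
        if attempts > 200 * max(1, config.n_off_target_sites):
            raise SizingError("could not place requested TTAA motifs")
        t = int(rng.integers(margin, config.genome_length - margin - 4))
        if abs(t - cut) < 2000:
            continue
        if any(abs(t - u) < 1500 for u in ttaa_starts):
            continue
        if not (proto_start - 50 <= t <= proto_end + 50):
            ttaa_starts.append(t)
    ttaa_starts.sort()
    for t in ttaa_starts:
        seq[t : t + 4] = list("TTAA")

    genome_seq = "".join(seq)

    # the planted protospacer must be the unique exact spacer occurrence
    genome_seq = _scrub_extra_occurrences(genome_seq, guide.spacer, proto_start, rng)

    # decoy / vector body: guaranteed absent from the genome
    decoy_rng = np.random.default_rng([config.seed, 99])
    while True:
        vector = _random_dna(decoy_rng, 1200, 0.5)
        if vector[:300] not in genome_seq:
            break

    features = [("protospacer", proto_start, proto_end, "+")]
    features += [("ttaa", t, t + 4, "+") for t in ttaa_starts]
    return ReferenceGenome(
        name="chrS",
        sequence=genome_seq,
        planted_features=features,
        decoy=vector[:300],
        vector=vector,
    )


def _scrub_extra_occurrences(
    genome: str, spacer: str, keep_at: int, rng: np.random.Generator
) -> str:
    """Mutate one base of any exact spacer occurrence other than the plant."""
    for query in (spacer, reverse_complement(spacer)):
        start = 0
        while True:
            i = genome.find(query, start)
            if i == -1:
                break
            if i != keep_at or query != spacer:
                mid = i + len(query) // 2
                old = genome[mid]
                new = {"A": "C", "C": "A", "G": "T", "T": "G"}[old]
                genome = genome[:mid] + new + genome[mid + 1 :]
            start = i + 1
    return genome


def plan_events(config: SimConfig, genome: ReferenceGenome, guide) -> list[IntegrationEvent]:
    """Lay out the ground-truth insertion events on a built reference.

    One on-target event at the Cas9 cut site (no TTAA, no target-site
    duplication) and one off-target event per planted TTAA motif, on a
    random strand, with piggyBac-style insertion at the motif.
    """
    from .guides import find_cut_site  # local import to avoid cycle

    rng = np.random.default_rng([config.seed, 1])
    events: list[IntegrationEvent] = []
    if config.n_on_target_umis > 0:
        cut, _ = find_cut_site(guide, genome)
        events.append(
            IntegrationEvent(
                event_id="on_0",
                position=cut,
                strand=config.on_target_strand,
                klass="on_target",
                ttaa_site=False,
                n_umis=config.n_on_target_umis,
            )
        )
    ttaa = genome.features("ttaa")
    if config.n_off_target_sites > len(ttaa):
        raise ValueError("more off-target events requested than planted TTAA motifs")
    for k in range(config.n_off_target_sites):
        _, t, _, _ = ttaa[k]
        if config.umis_per_off_site == 0:
            continue
        events.append(
            IntegrationEvent(
                event_id=f"off_{k}",
                position=t,
                strand=str(rng.choice(["+", "-"])),
                klass="off_target",
                ttaa_site=True,
                n_umis=config.umis_per_off_site,
            )
        )
    for ev in events:
        if ev.klass == "off_target":
            assert genome.sequence[ev.position : ev.position + 4] == "TTAA"
    return events


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _fragment_length(config: SimConfig, rng: np.random.Generator) -> int:
    hi = config.fragment_mean + 10 * config.fragment_sd
    f = int(round(rng.normal(config.fragment_mean, config.fragment_sd)))
    return int(min(max(f, config.read_length), hi))


def simulate_reads(
    genome: ReferenceGenome,
    events: list[IntegrationEvent],
    itr: str,
    config: SimConfig,
    outdir: str | Path,
) -> ReadSet:
    """Write R1/R2 FASTQ, a truth BED6 and a per-molecule manifest TSV.

    R1 = UMI + (terminal ITR segment, truncated by a per-molecule ITR
    deletion) + genomic flank read off the event position on the event
    strand.  R2 is the reverse-complement read from the far fragment end.
    Background molecules carry the full ITR followed by vector (decoy)
    sequence that never maps to the genome.
    """
    if len(itr) < 35:
        raise ValueError("ITR terminal segment must be >= 35 nt")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 2])

    seen_umis: set[str] = set()

    def new_umi() -> str:
        while True:
            u = "".join(rng.choice(list("ACGT"), size=config.umi_length))
            if u not in seen_umis:
                seen_umis.add(u)
                return u

    r1_path = outdir / "reads_R1.fastq"
    r2_path = outdir / "reads_R2.fastq"
    truth_path = outdir / "truth.bed"
    manifest_path = outdir / "manifest.tsv"

    rows = []
    ridx = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        molecule_plan = [(ev, i) for ev in events for i in range(ev.n_umis)]
        molecule_plan += [(None, i) for i in range(config.n_background_umis)]
        for ev, _ in molecule_plan:
            umi = new_umi()
            frag = _fragment_length(config, rng)
            # ITR disruption is created by the integration reaction, so
            # background (episomal) molecules keep intact ITR ends.
            itr_del = 0
            if ev is not None and rng.random() < config.itr_deletion_prob:
                itr_del = int(
                    rng.integers(config.itr_deletion_minlen, config.itr_deletion_maxlen + 1)
                )
            itr_part = itr[: len(itr) - itr_del]
            g_indel = 0
            if ev is not None:
                if ev.klass == "on_target" and rng.random() < config.junction_indel_prob:
                    size = int(rng.integers(1, 4))
                    g_indel = size if rng.random() < 0.5 else -size
                gl = max(0, frag - len(itr_part))
                template = itr_part + _genomic_flank(genome, ev, g_indel, gl, rng)
            else:
                gl = max(0, frag - len(itr_part))
                template = itr_part + genome.vector[:gl]

            r1 = umi + template[: config.read_length - config.umi_length]
            r2 = reverse_complement(template)[: config.read_length]
            r1 = _apply_substitutions(r1, config.substitution_error_rate, rng)
            r2 = _apply_substitutions(r2, config.substitution_error_rate, rng)
            event_id = ev.event_id if ev is not None else "background"
            name = f"mol{ridx}|UMI:{umi}|{event_id}"
            f1.write(f"@{name}/1\n{r1}\n+\n{_QUAL_CHAR * len(r1)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{_QUAL_CHAR * len(r2)}\n")
            rows.append(
                dict(
                    read_id=name,
                    umi=umi,
                    event_id=event_id,
                    itr_deletion=itr_del,
                    genomic_indel=g_indel,
                    strand=(ev.strand if ev is not None else "."),
                    fragment_length=frag,
                )
            )
            ridx += 1

    with open(truth_path, "w") as fh:
        for ev in events:
            fh.write(
                f"{genome.name}\t{ev.position}\t{ev.position + 1}\t"
                f"{ev.event_id}\t{ev.n_umis}\t{ev.strand}\n"
            )

    manifest = pd.DataFrame(
        rows,
        columns=[
            "read_id", "umi", "event_id", "itr_deletion",
            "genomic_indel", "strand", "fragment_length",
        ],
    )
    manifest.to_csv(manifest_path, sep="\t", index=False)
    logger.info("simulated %d molecules (%d events)", len(manifest), len(events))
    return ReadSet(r1_path, r2_path, truth_path, manifest_path, manifest)


def _genomic_flank(
    genome: ReferenceGenome,
    ev: IntegrationEvent,
    g_indel: int,
    length: int,
    rng: np.random.Generator,
) -> str:
    """Genomic sequence downstream of the junction on the event strand.

    A negative junction indel deletes |g_indel| genomic bases at the cut; a
    positive one inserts random bases between the ITR and the genome.
    """
    ins = ""
    if g_indel > 0:
        ins = "".join(rng.choice(list("ACGT"), size=g_indel))
        length = max(0, length - g_indel)
    k = -g_indel if g_indel < 0 else 0
    if ev.strand == "+":
        start = ev.position + k
        flank = genome.sequence[start : start + length]
    else:
        end = ev.position - k
        flank = reverse_complement(genome.sequence[max(0, end - length) : end])
    return ins + flank


def simulate_library(
    config: SimConfig, guide, itr: str = DEFAULT_ITR, outdir: str | Path = "."
) -> tuple[ReferenceGenome, list[IntegrationEvent], ReadSet]:
    """Convenience wrapper: reference + events + reads in one call."""
    genome = make_reference(config, guide)
    events = plan_events(config, genome, guide)
    readset = simulate_reads(genome, events, itr, config, outdir)
    return genome, events, readset
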