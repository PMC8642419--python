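"""End-to-end orchestration: simulate (optional) -> extract -> align ->
call -> classify -> profile indels -> LOD (optional), with a reproducible
on-disk report bundle (BED, TSVs, JSON summary).

All outputs are plain text, written deterministically: two runs with the
same configuration and seed produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .calling import PeakParams, align_all, call_peaks, classify_peaks, correct_fdr
from .extract import ItrSpec, extract_junctions
from .guides import GuideSpec, find_cut_site
from .indels import profile_junction_indels
from .lod import LODConfig, estimate_lod, make_peak_closure, partition_umis
from .simulate import DEFAULT_ITR, SimConfig, simulate_library

logger = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    outdir: Path
    peaks: list
    n_junctions: int
    n_unmapped: int
    lod: object | None
    summary_path: Path
    peaks_path: Path


def run_pipeline(config: dict, outdir: str | Path) -> ReportBundle:
    """Execute the full analysis described by a JSON-style config dict.

    Recognized keys: ``sim`` (SimConfig fields; triggers a self-contained
    simulated run), ``guide`` (GuideSpec fields or null to skip
    classification), ``itr`` (terminal ITR sequence), ``peaks`` (PeakParams
    fields), ``lod`` (LODConfig fields or null to skip LOD),
    ``on_target_window`` (bp, default 50).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if "sim" not in config:
        raise ValueError("self-contained runs require a 'sim' section")
    sim_cfg = SimConfig.from_json(config.get("sim", {}))
    guide_cfg = config.get("guide", "default")
    guide = None
    if guide_cfg is not None:
        guide = GuideSpec(**guide_cfg) if isinstance(guide_cfg, dict) else GuideSpec()
    itr_seq = config.get("itr", DEFAULT_ITR)
    peak_params = PeakParams(**config.get("peaks", {}))
    on_target_window = int(config.get("on_target_window", 50))

    sim_guide = guide if guide is not None else GuideSpec()
    genome, events, readset = simulate_library(sim_cfg, sim_guide, itr_seq, outdir)
    genome.write_fasta(outdir / "genome.fa")
    if readset.manifest.empty:
        raise ValueError("no reads")

    itr = ItrSpec(sequence=itr_seq)
    junctions, rejected = extract_junctions(
        readset.r1_path, itr, umi_length=sim_cfg.umi_length
    )
    _write_junctions_tsv(junctions, outdir / "junctions.tsv")

    aligned, unmapped = align_all(junctions, genome, peak_params)
    if not aligned:
        raise ValueError("no mapped junctions")

    peaks = call_peaks(aligned, genome, peak_params)
    kept = correct_fdr(peaks, q_threshold=peak_params.q_threshold)
    cut_site = None
    if guide is not None:
        cut_site, _ = find_cut_site(guide, genome)
    classify_peaks(kept, genome, cut_site, on_target_window)
    _write_peaks_bed(kept, outdir / "peaks.bed")

    profile = profile_junction_indels(
        junction_reads=junctions, axis="itr_relative", itr_length=len(itr_seq)
    )
    profile.to_dataframe().to_csv(outdir / "indel_profile_itr.tsv", sep="\t", index=False)

    lod_est = None
    lod_cfg_raw = config.get("lod")
    if lod_cfg_raw is not None and cut_site is not None:
        lod_payload = dict(lod_cfg_raw)
        if "fractions" in lod_payload:
            lod_payload["fractions"] = tuple(lod_payload["fractions"])
        lod_cfg = LODConfig(**lod_payload)
        all_umis = set(readset.manifest.umi)
        pos, neg = partition_umis(aligned, all_umis, cut_site, on_target_window)
        closure = make_peak_closure(aligned, genome, peak_params, cut_site, on_target_window)
        lod_est = estimate_lod(pos, neg, closure, lod_cfg)
        lod_est.table.to_csv(outdir / "lod_table.tsv", sep="\t", index=False)
        fit = lod_est.fit
        with open(outdir / "lod.json", "w") as fh:
            json.dump(
                {
                    "lod_fraction": lod_est.lod_fraction,
                    "censored": lod_est.censored,
                    "fit": None if fit is None else dataclasses.asdict(fit),
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")

    summary = {
        "version": __version__,
        "seed": sim_cfg.seed,
        "config": _jsonable(config),
        "n_molecules": int(len(readset.manifest)),
        "n_consensus_junctions": len(junctions),
        "n_rejected": len(rejected),
        "n_unmapped": len(unmapped),
        "n_peaks": len(kept),
        "n_on_target": sum(pk.label == "on_target" for pk in kept),
        "n_off_target": sum(pk.label == "off_target" for pk in kept),
        "cut_site": cut_site,
    }
    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline done: %d peaks (%d on-target)", len(kept), summary["n_on_target"])
    return ReportBundle(
        outdir=outdir,
        peaks=kept,
        n_junctions=len(junctions),
        n_unmapped=len(unmapped),
        lod=lod_est,
        summary_path=summary_path,
        peaks_path=outdir / "peaks.bed",
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_junctions_tsv(junctions, path: Path) -> None:
    rows = [
        dict(
            umi=j.umi,
            side=j.side,
            itr_end_in_read=j.itr_end_in_read,
            identity=round(j.identity, 6),
            support=j.support,
            genomic_seq=j.genomic_seq,
        )
        for j in sorted(junctions, key=lambda j: j.umi)
    ]
    pd.DataFrame(
        rows, columns=["umi", "side", "itr_end_in_read", "identity", "support", "genomic_seq"]
    ).to_csv(path, sep="\t", index=False)


def _write_peaks_bed(peaks, path: Path) -> None:
    """BED6 + fold_enrichment, p, q, ttaa, distance_to_cut extra columns."""
    with open(path, "w") as fh:
        for pk in sorted(peaks, key=lambda p: (p.chrom, p.start)):
            dist = "" if pk.distance_to_cut is None else pk.distance_to_cut
            fh.write(
                f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.label}\t{pk.n_umis}\t{pk.strand}\t"
                f"{pk.fold_enrichment:.6g}\t{pk.p_value:.6g}\t{pk.q_value:.6g}\t"
                f"{int(pk.ttaa)}\t{dist}\n"
            )
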