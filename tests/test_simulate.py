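"""Synthetic library generator: determinism, truth bookkeeping, geometry."""

from __future__ import annotations

import pytest

import itrmap as im
from itrmap.simulate import DEFAULT_ITR


def test_reference_geometry_and_planted_guide(small_sim, guide):
    genome = small_sim["genome"]
    cfg = small_sim["config"]
    assert len(genome.sequence) == cfg.genome_length
    (label, start, end, strand) = genome.features("protospacer")[0]
    planted = genome.sequence[start:end]
    assert planted.startswith(guide.spacer)
    # exact search finds the protospacer only at its recorded coordinate
    assert genome.sequence.find(guide.spacer) == start
    assert genome.sequence.find(guide.spacer, start + 1) == -1


def test_decoy_absent_from_genome(small_sim):
    genome = small_sim["genome"]
    assert len(genome.decoy) == 300
    assert genome.decoy not in genome.sequence


def test_make_reference_deterministic(tmp_path, guide):
    cfg = im.SimConfig(seed=11)
    g1 = im.make_reference(cfg, guide)
    g2 = im.make_reference(cfg, guide)
    assert g1.sequence == g2.sequence
    assert g1.planted_features == g2.planted_features


def test_full_simulation_deterministic(tmp_path, guide):
    cfg = im.SimConfig(seed=5, n_on_target_umis=5, n_off_target_sites=2,
                       umis_per_off_site=3, n_background_umis=2)
    out = []
    for sub in ("a", "b"):
        d = tmp_path / sub
        _, _, rs = im.simulate_library(cfg, guide, outdir=d)
        out.append((rs.r1_path.read_bytes(), rs.r2_path.read_bytes(),
                    rs.truth_path.read_bytes()))
    assert out[0] == out[1]


def test_sizing_error_when_genome_cannot_host_features(guide):
    with pytest.raises(ValueError):
        # violates the genome_length >= 10 * fragment_mean invariant
        im.SimConfig(genome_length=500, n_off_target_sites=100)
    cfg = im.SimConfig(genome_length=10_000, n_off_target_sites=100)
    with pytest.raises(im.SizingError):
        im.make_reference(cfg, guide)


def test_plan_events_layout(small_sim, guide):
    genome, events = small_sim["genome"], small_sim["events"]
    cfg = small_sim["config"]
    on = [e for e in events if e.klass == "on_target"]
    off = [e for e in events if e.klass == "off_target"]
    assert len(on) == 1 and len(off) == cfg.n_off_target_sites
    cut, _ = im.find_cut_site(guide, genome)
    assert on[0].position == cut
    for e in off:
        assert genome.sequence[e.position : e.position + 4] == "TTAA"
        assert e.ttaa_site
        assert abs(e.position - cut) >= 2000


def test_plan_events_empty_and_single(guide):
    cfg = im.SimConfig(n_on_target_umis=0, n_off_target_sites=0)
    genome = im.make_reference(cfg, guide)
    assert im.plan_events(cfg, genome, guide) == []
    cfg2 = im.SimConfig(n_off_target_sites=0)
    genome2 = im.make_reference(cfg2, guide)
    events = im.plan_events(cfg2, genome2, guide)
    assert len(events) == 1 and events[0].klass == "on_target"


def test_umi_conservation_and_manifest(small_sim):
    cfg, rs = small_sim["config"], small_sim["readset"]
    expected = (
        cfg.n_on_target_umis
        + cfg.n_off_target_sites * cfg.umis_per_off_site
        + cfg.n_background_umis
    )
    assert len(rs.manifest) == expected
    assert rs.manifest.umi.is_unique
    assert (rs.manifest.event_id == "background").sum() == cfg.n_background_umis


def test_truth_bed_one_record_per_event(small_sim):
    rs, events = small_sim["readset"], small_sim["events"]
    lines = rs.truth_path.read_text().strip().splitlines()
    assert len(lines) == len(events)
    chrom, start, end, name, score, strand = lines[0].split("\t")
    assert int(end) == int(start) + 1
    assert strand in "+-"


def test_error_free_reads_start_with_itr_and_match_reference(small_sim):
    genome, rs = small_sim["genome"], small_sim["readset"]
    cfg = small_sim["config"]
    events = {e.event_id: e for e in small_sim["events"]}
    for rec, (_, row) in zip(_fastq(rs.r1_path), rs.manifest.iterrows()):
        name, seq = rec
        assert seq[: cfg.umi_length] == row.umi
        body = seq[cfg.umi_length :]
        assert body.startswith(DEFAULT_ITR)
        genomic = body[len(DEFAULT_ITR) :]
        if row.event_id == "background":
            assert genome.vector.startswith(genomic)
        else:
            ev = events[row.event_id]
            if ev.strand == "+":
                ref = genome.sequence[ev.position : ev.position + len(genomic)]
            else:
                ref = im.reverse_complement(
                    genome.sequence[ev.position - len(genomic) : ev.position]
                )
            assert genomic == ref


def test_itr_too_short_rejected(small_sim, guide, tmp_path):
    cfg, genome = small_sim["config"], small_sim["genome"]
    events = small_sim["events"]
    with pytest.raises(ValueError, match="35"):
        im.simulate_reads(genome, events, "ACGT" * 5, cfg, tmp_path)


def _fastq(path):
    lines = path.read_text().splitlines()
    for i in range(0, len(lines), 4):
        yield lines[i][1:], lines[i + 1]
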