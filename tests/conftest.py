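from __future__ import annotations

import pytest

import itrmap as im


@pytest.fixture(scope="session")
def guide() -> im.GuideSpec:
    return im.GuideSpec()


@pytest.fixture(scope="session")
def default_run(tmp_path_factory, guide):
    """The standard study simulation processed through the whole pipeline:
    100 kb genome, 1 on-target event (50 UMIs) + 9 off-target TTAA events
    (20 UMIs each), background molecules, 0.1% substitution error."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = im.SimConfig(seed=1)
    genome, events, readset = im.simulate_library(cfg, guide, outdir=outdir)
    itr = im.ItrSpec(sequence=im.DEFAULT_ITR)
    junctions, rejected = im.extract_junctions(readset.r1_path, itr)
    aligned, unmapped = im.align_all(junctions, genome)
    peaks = im.call_peaks(aligned, genome)
    kept = im.correct_fdr(peaks, q_threshold=0.001)
    cut, _ = im.find_cut_site(guide, genome)
    im.classify_peaks(kept, genome, cut)
    return dict(
        config=cfg,
        genome=genome,
        events=events,
        readset=readset,
        junctions=junctions,
        rejected=rejected,
        aligned=aligned,
        unmapped=unmapped,
        peaks=kept,
        cut=cut,
    )


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory, guide):
    """A small error-free library for exact-sequence assertions."""
    outdir = tmp_path_factory.mktemp("small_sim")
    cfg = im.SimConfig(
        seed=3,
        n_on_target_umis=10,
        n_off_target_sites=2,
        umis_per_off_site=5,
        n_background_umis=5,
        substitution_error_rate=0.0,
        itr_deletion_prob=0.0,
        junction_indel_prob=0.0,
    )
    genome, events, readset = im.simulate_library(cfg, guide, outdir=outdir)
    return dict(config=cfg, genome=genome, events=events, readset=readset)
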