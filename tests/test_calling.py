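"""Genomic placement of junction segments, Poisson peak test, FDR, labels."""

from __future__ import annotations

import numpy as np
import pytest
from _oracles import bh_qvalues, local_lambda, poisson_tail

import itrmap as im
from itrmap.calling import AlignedJunction, Unmapped


class _Seg:
    def __init__(self, umi, seq):
        self.umi, self.genomic_seq, self.side = umi, seq, "3prime"


def _aj(umi, pos, chrom="chrS", start=None, end=None, strand="+"):
    start = pos if start is None else start
    end = start + 180 if end is None else end
    return AlignedJunction(umi, chrom, pos, strand, True, start, end)


def test_align_verbatim_segment(small_sim):
    genome = small_sim["genome"]
    seg = genome.sequence[4213 : 4213 + 180]
    res = im.align_junction(_Seg("U1", seg), genome)
    assert isinstance(res, AlignedJunction)
    assert (res.junction_pos, res.strand) == (4213, "+")
    assert (res.read_start, res.read_end) == (4213, 4393)


def test_align_reverse_complement_coordinates(small_sim):
    """Coordinate oracle: a read whose ITR-proximal end is the right edge of
    the slice must report the slice end as the junction, on the - strand."""
    genome = small_sim["genome"]
    seg = im.reverse_complement(genome.sequence[7000:7180])
    res = im.align_junction(_Seg("U1", seg), genome)
    assert isinstance(res, AlignedJunction)
    assert res.strand == "-"
    assert res.junction_pos == 7180
    assert (res.read_start, res.read_end) == (7000, 7180)
    # replay both conventions: + placement of the same bases must not exist
    assert genome.sequence.find(seg) == -1


def test_align_decoy_unmapped(small_sim):
    genome = small_sim["genome"]
    res = im.align_junction(_Seg("U1", genome.decoy[:180]), genome)
    assert res == Unmapped("U1", "none")


def test_align_too_short(small_sim):
    res = im.align_junction(_Seg("U1", "ACGTACGT"), small_sim["genome"])
    assert res == Unmapped("U1", "too_short")


def test_align_repeated_segment_is_ambiguous(small_sim):
    genome = small_sim["genome"]
    seg = genome.sequence[5000:5180]
    doctored = im.ReferenceGenome(
        name="dup",
        sequence=genome.sequence + seg + genome.sequence[-500:],
        planted_features=[],
    )
    res = im.align_junction(_Seg("U1", seg), doctored)
    assert res == Unmapped("U1", "ambiguous")


def test_call_peaks_single_pileup(small_sim):
    genome = small_sim["genome"]
    alns = [_aj(f"U{i}", 5000) for i in range(20)]
    peaks = im.call_peaks(alns, genome, im.PeakParams(window_bp=20))
    assert len(peaks) == 1
    pk = peaks[0]
    assert (pk.apex, pk.n_umis) == (5000, 20)
    assert pk.p_value < 1e-10


def test_call_peaks_empty_errors(small_sim):
    with pytest.raises(ValueError, match="no mapped junctions"):
        im.call_peaks([], small_sim["genome"])


def test_poisson_pvalue_matches_tail_sum_at_lambda_one():
    """Designed dataset with lambda exactly 1.0: p = 1 - e^-1 * sum_{i<5} 1/i!"""
    L, window = 2000, 20
    genome = im.ReferenceGenome("toy", "A" * L, [])
    singles = [k for k in range(0, L, 21) if abs(k - 1001) > 25] + [1999]
    assert len(singles) == 95
    alns = [_aj(f"B{i}", pos) for i, pos in enumerate(singles)]
    alns += [_aj(f"S{i}", 1001) for i in range(5)]
    peaks = im.call_peaks(alns, genome, im.PeakParams(window_bp=window, min_umis=5))
    pk = [p for p in peaks if p.apex == 1001][0]
    assert pk.expected == pytest.approx(1.0, abs=1e-12)
    expected_p = poisson_tail(5, 1.0)
    assert expected_p == pytest.approx(0.003660, abs=5e-7)
    assert pk.p_value == pytest.approx(expected_p, abs=1e-10)


def test_fold_enrichment_uses_floored_lambda():
    L = 2000
    genome = im.ReferenceGenome("toy", "A" * L, [])
    alns = [_aj(f"S{i}", 500) for i in range(10)]
    peaks = im.call_peaks(alns, genome, im.PeakParams(window_bp=20))
    pk = peaks[0]
    lam = pk.expected
    assert pk.fold_enrichment == pytest.approx(10 / max(lam, 0.1))


@pytest.mark.parametrize("seed", range(10))
def test_call_peaks_matches_sliding_window_oracle(seed):
    """Randomized small genomes: lambda and p recomputed by brute force."""
    rng = np.random.default_rng(seed)
    L = int(rng.integers(1000, 5001))
    genome = im.ReferenceGenome("toy", "A" * L, [])
    alns = []
    for c in range(int(rng.integers(1, 4))):
        center = int(rng.integers(100, L - 100))
        for i in range(int(rng.integers(2, 30))):
            alns.append(_aj(f"C{c}.{i}", center))
    for i in range(int(rng.integers(0, 60))):
        alns.append(_aj(f"N{i}", int(rng.integers(0, L))))
    params = im.PeakParams(window_bp=20)
    peaks = im.call_peaks(alns, genome, params)
    positions_by_umi = {a.umi: a.junction_pos for a in alns}
    for pk in peaks:
        lam = local_lambda(
            positions_by_umi, L, pk.apex, pk.start, pk.end, 20,
            flanks=params.background_flanks_bp,
        )
        assert pk.expected == pytest.approx(lam, abs=1e-12)
        assert pk.p_value == pytest.approx(poisson_tail(pk.n_umis, lam), abs=1e-10)


def test_adding_umis_never_increases_pvalue():
    L = 5000
    genome = im.ReferenceGenome("toy", "A" * L, [])
    background = [_aj(f"B{i}", 37 * i % L) for i in range(40)]
    last_p = 1.0
    for n in range(2, 30, 3):
        alns = background + [_aj(f"S{i}", 2500) for i in range(n)]
        peaks = im.call_peaks(alns, genome, im.PeakParams(window_bp=20))
        pk = [p for p in peaks if p.apex == 2500][0]
        assert pk.p_value <= last_p + 1e-15
        last_p = pk.p_value


def _peak(p):
    return im.InsertionPeak(
        chrom="toy", start=0, end=1, apex=0, n_umis=2, n_reads=2,
        expected=0.1, fold_enrichment=1.0, p_value=p,
    )


def test_bh_stepup_examples():
    peaks = [_peak(p) for p in (0.01, 0.02, 0.03, 0.04)]
    im.correct_fdr(peaks, q_threshold=0.05)
    assert [pk.q_value for pk in peaks] == pytest.approx([0.04] * 4)

    single = [_peak(0.0005)]
    kept = im.correct_fdr(single, q_threshold=0.001)
    assert kept == single and single[0].q_value == pytest.approx(0.0005)

    removed = [_peak(0.5)]
    assert im.correct_fdr(removed, q_threshold=0.001) == []
    assert removed[0].q_value == pytest.approx(0.5)


@pytest.mark.parametrize("seed", range(20))
def test_bh_matches_independent_stepup(seed):
    rng = np.random.default_rng(seed)
    m = int(rng.integers(1, 201))
    pvals = rng.random(m)
    peaks = [_peak(p) for p in pvals]
    im.correct_fdr(peaks, q_threshold=1e-9)
    expected = bh_qvalues(list(pvals))
    assert [pk.q_value for pk in peaks] == pytest.approx(expected, abs=1e-12)


def test_classify_on_off_and_ttaa(small_sim):
    genome = small_sim["genome"]
    cut = small_sim["events"][0].position
    ttaa_pos = [e.position for e in small_sim["events"] if e.klass == "off_target"][0]
    peaks = [_peak(0.001) for _ in range(2)]
    peaks[0].apex = cut
    peaks[1].apex = ttaa_pos
    im.classify_peaks(peaks, genome, cut)
    assert peaks[0].label == "on_target"
    assert peaks[0].distance_to_cut == 0
    assert not peaks[0].ttaa  # insertion at the programmed break, not a TTAA
    assert peaks[1].label == "off_target"
    assert peaks[1].ttaa


def test_classify_cut_outside_genome_errors(small_sim):
    with pytest.raises(ValueError, match="outside"):
        im.classify_peaks([_peak(0.5)], small_sim["genome"], cut_site=10**9)
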