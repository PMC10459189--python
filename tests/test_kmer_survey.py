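import numpy as np
import pytest

from plantsurvey import seqcodes, simdata
from plantsurvey.kmer_survey import (
    KmerHistogram,
    assess_heterozygosity,
    count_kmers,
    detect_peaks,
    estimate_genome_size,
    estimate_repeat_fraction,
    fit_spectrum,
)
from scipy import stats as sps

from .oracles import canonical_kmer_counts_bruteforce


def _hist_from_counts(counts: dict[str, int], k: int) -> dict[int, int]:
    bins: dict[int, int] = {}
    for depth in counts.values():
        bins[depth] = bins.get(depth, 0) + 1
    return bins


def test_hand_enumerated_canonical_counting():
    # ACGTACGT, k=3: windows ACG CGT GTA TAC ACG CGT
    # canonical(ACG)=canonical(CGT)=ACG (x4), canonical(GTA)=canonical(TAC)=GTA (x2)
    hist = count_kmers(["ACGTACGT"], k=3)
    assert hist.bins == {4: 1, 2: 1}
    assert hist.total_volume == 6
    assert hist.total_species == 2


def test_counting_matches_bruteforce_string_path(rng):
    seqs = ["".join("ACGTN"[i] for i in rng.integers(0, 5, size=60)) for _ in range(30)]
    hist = count_kmers(seqs, k=5)
    expect = _hist_from_counts(canonical_kmer_counts_bruteforce(seqs, 5), 5)
    assert hist.bins == expect


def test_counting_matches_bruteforce_matrix_path(rng):
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, size=40)) for _ in range(50)]
    seqs[3] = seqs[3][:10] + "N" + seqs[3][11:]
    mat = seqcodes.encode_matrix(seqs)
    hist = count_kmers(mat, k=7)
    expect = _hist_from_counts(canonical_kmer_counts_bruteforce(seqs, 7), 7)
    assert hist.bins == expect


def test_matrix_and_string_paths_agree(rng):
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, size=80)) for _ in range(40)]
    assert count_kmers(seqs, k=17).bins == count_kmers(seqcodes.encode_matrix(seqs), k=17).bins


def test_strand_invariance(rng):
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, size=70)) for _ in range(20)]
    rc = [seqcodes.revcomp(s) for s in seqs]
    assert count_kmers(seqs, k=9).bins == count_kmers(rc, k=9).bins


def test_even_or_out_of_range_k_rejected():
    with pytest.raises(ValueError):
        count_kmers(["ACGTACGT"], k=4)
    with pytest.raises(ValueError):
        count_kmers(["ACGTACGT"], k=33)


def test_depth_cap_accumulates_tail():
    hist = count_kmers(["ACGTA" * 100], k=5, cap=10)
    assert max(hist.bins) <= 10


def test_histogram_tsv_round_trip(tmp_path):
    hist = KmerHistogram(17, {1: 500, 2: 30, 83: 1000})
    path = tmp_path / "hist.tsv"
    hist.to_tsv(path)
    assert KmerHistogram.from_tsv(path, k=17).bins == hist.bins


def test_genome_size_from_single_peak():
    hist = KmerHistogram(17, {20: 1000})
    assert estimate_genome_size(hist, 1, 20) == 1000


def test_genome_size_excludes_error_bins():
    hist = KmerHistogram(17, {1: 10_000, 20: 1000})
    assert estimate_genome_size(hist, 2, 20) == 1000
    with pytest.raises(ValueError):
        estimate_genome_size(hist, 21, 20)
    with pytest.raises(ValueError):
        estimate_genome_size(KmerHistogram(17, {1: 5}), 2, 3)


def test_peak_detection_on_constructed_spectrum():
    # geometric error blob + Poisson coverage bump at depth 30
    bins = {}
    for d in range(1, 8):
        bins[d] = int(1e6 * 0.4 ** (d - 1))
    for d in range(8, 61):
        bins[d] = bins.get(d, 0) + int(2e5 * sps.poisson.pmf(d, 30))
    hist = KmerHistogram(17, bins)
    d_min, c_peak, repeat_peak = detect_peaks(hist)
    assert 2 <= d_min <= 15
    assert abs(c_peak - 30) <= 1


def test_duplicated_half_genome_shows_repeat_peak_and_fraction():
    unique = simdata.make_organelle_genome(200_000, seed=11)
    dup = simdata.make_organelle_genome(100_000, seed=12)
    full = unique + dup + dup  # half the content present in two copies
    cfg = simdata.SimConfig(
        nuclear_size=len(full), repeat_fraction=0.0, organelle_sizes=(),
        organelle_read_fraction=0.0, depth_nuclear=30.0, error_rate=0.0, seed=13,
    )
    src = [simdata.ReadSource("g", full, False, 1.0)]
    r1, r2, _ = simdata.simulate_reads(src, cfg)
    mat = np.concatenate([r1.codes, r2.codes])
    hist = count_kmers(mat, k=17)
    d_min, c_peak, repeat_peak = detect_peaks(hist)
    # read-edge losses shift the k-mer peak to c * (L-k+1)/L
    c_expected = 30 * (150 - 17 + 1) / 150
    assert abs(c_peak - c_expected) <= 1.5
    assert repeat_peak is not None and abs(repeat_peak - 2 * c_peak) <= 4
    size = estimate_genome_size(hist, d_min, c_peak)
    # integer peak depth discretization costs a few percent at c ~ 27
    assert abs(size - 400_000) / 400_000 < 0.06
    rep = estimate_repeat_fraction(hist, d_min, c_peak)
    assert abs(rep - 0.5) < 0.05


def test_poisson_unique_spectrum_has_no_repeats():
    c = 40
    bins = {d: int(round(5e5 * sps.poisson.pmf(d, c))) for d in range(10, 90)}
    bins = {d: v for d, v in bins.items() if v > 0}
    hist = KmerHistogram(17, bins)
    assert estimate_repeat_fraction(hist, 10, c) <= 0.02


def test_heterozygosity_from_constructed_half_peak():
    c, a, e = 60, 1_000_000, 200_000
    bins = {}
    for d in range(1, 130):
        v = a * sps.poisson.pmf(d, c) + e * sps.poisson.pmf(d, c // 2)
        if v >= 1:
            bins[d] = int(v)
    present, rate = assess_heterozygosity(KmerHistogram(17, bins), 5, c)
    assert present
    # f = (E/2)/(E/2 + A) with E=2e5, A=1e6 -> ~0.0909; rate = 1-(1-f)^(1/17)
    assert rate == pytest.approx(1 - (1 - 0.1 / 1.1) ** (1 / 17), rel=0.15)

    bins_hom = {d: int(a * sps.poisson.pmf(d, c)) for d in range(1, 130)}
    bins_hom = {d: v for d, v in bins_hom.items() if v > 0}
    present2, rate2 = assess_heterozygosity(KmerHistogram(17, bins_hom), 5, c)
    assert not present2 and rate2 == 0.0


def test_fit_spectrum_bundles_all_estimates():
    bins = {1: 50_000}
    for d in range(5, 70):
        bins[d] = bins.get(d, 0) + int(3e5 * sps.poisson.pmf(d, 35))
    fit = fit_spectrum(KmerHistogram(17, bins))
    assert fit.k == 17
    assert abs(fit.c_peak - 35) <= 1
    assert fit.genome_size > 0
    assert 0.0 <= fit.repeat_fraction < 0.1
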