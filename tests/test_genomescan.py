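import numpy as np
import pandas as pd
import pytest

from eprr.coalsim import SimContext, drop_mutations_fixed_S, simulate_trees
from eprr.estimator import ModelCache
from eprr.genomescan import (
    GeneticMap,
    ScanConfig,
    WindowResult,
    calibrate_Ne,
    concentration_curve,
    map_correlation,
    read_window_vcf,
    rho_to_cM_per_Mb,
    scan,
    write_vcf,
)
from eprr.haplotype import MISSING, HaplotypeMatrix


# ---------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------

_TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1
1\t100\t.\tA\tC\t50\t.\t.\tGT\t0|1\t0|0
1\t200\t.\tG\tT\t50\t.\t.\tGT\t1|1\t0|0
1\t300\t.\tA\tAT\t90\t.\t.\tGT\t0|1\t0|0
1\t400\t.\tC\tG\t10\t.\t.\tGT\t0|1\t0|0
1\t500\t.\tT\tA\t50\t.\t.\tGT\t0|1\t1|0
"""


def test_read_window_vcf_filters(tmp_path):
    path = str(tmp_path / "toy.vcf")
    with open(path, "w") as fh:
        fh.write(_TOY_VCF)
    m = read_window_vcf(path, ("1", 0, 1000))
    # indel (POS 300) and QUAL 10 site (POS 400) are dropped
    assert m.S == 3
    assert m.n == 4  # two diploids -> four haplotype rows
    assert list(m.positions) == [99, 199, 499]
    # sample s0 is 0|1 at the first site: haplotype rows 0 and 1 differ
    assert m.alleles[0, 0] != m.alleles[1, 0]


def test_read_window_vcf_unphased_and_missing(tmp_path):
    vcf = _TOY_VCF.replace("GT\t0|1\t1|0\n", "GT\t0/1\t1|0\n", 1)
    path = str(tmp_path / "toy2.vcf")
    with open(path, "w") as fh:
        fh.write(vcf)
    m = read_window_vcf(path, ("1", 0, 1000))
    # only the unphased cells (sample s0 at POS 500) become '?'
    j = list(m.positions).index(499)
    assert m.alleles[0, j] == MISSING and m.alleles[1, j] == MISSING
    assert m.alleles[2, j] != MISSING and m.alleles[3, j] != MISSING


def test_read_window_vcf_empty_region(tmp_path):
    path = str(tmp_path / "toy3.vcf")
    with open(path, "w") as fh:
        fh.write(_TOY_VCF)
    m = read_window_vcf(path, ("1", 600, 900))
    assert m.S == 0


def _window_matrix(n, S, rho, seed, window):
    ts = simulate_trees(SimContext(n=n, rho=rho, seed=seed))
    m = drop_mutations_fixed_S(ts, S, seed=seed)
    chrom, start, end = window
    pos = np.sort(
        np.unique((m.positions * (end - start)).astype(int))
    )
    # re-space duplicate bp collisions deterministically
    while len(pos) < m.S:
        pos = np.unique(np.concatenate([pos, [pos.max() + 1]]))
    return HaplotypeMatrix(m.alleles, pos.astype(float), window=window)


def test_write_then_read_vcf_round_trip(tmp_path):
    m = _window_matrix(20, 15, 10, seed=3, window=("1", 0, 10_000))
    path = str(tmp_path / "sim.vcf")
    write_vcf(path, [m], chrom="1", chrom_length=10_000)
    back = read_window_vcf(path, ("1", 0, 10_000))
    assert back.n == m.n and back.S == m.S
    # A/C coding preserves the 0/1 split pattern of every column
    for j in range(m.S):
        orig = m.alleles[:, j]
        got = back.alleles[:, j]
        assert len(np.unique(got)) == 2
        split_orig = orig == orig[0]
        split_got = got == got[0]
        assert np.array_equal(split_orig, split_got)


# ---------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------

def test_scan_statuses_and_cache_reuse(tmp_path):
    # 4 windows of 10 kb: [0) normal, [1) gap, [2) duplicate of window 0
    # (same spectrum -> cache hit), [3) too few sites
    # write_vcf offsets each matrix's window-relative positions itself
    w0 = _window_matrix(20, 15, 10, seed=3, window=("1", 0, 10_000))
    w2 = HaplotypeMatrix(w0.alleles, w0.positions, window=("1", 20_000, 30_000))
    w3 = _window_matrix(20, 3, 10, seed=5, window=("1", 30_000, 40_000))
    path = str(tmp_path / "scan.vcf")
    write_vcf(path, [w0, w2, w3], chrom="1", chrom_length=40_000)
    cfg = ScanConfig(window_len=10_000, min_sites=5,
                     gaps=[("1", 12_000, 13_000)])
    cache = ModelCache(seed=4, training_reps=10)
    gmap = scan(path, cfg, cache, seed=9, correction_reps=5)
    statuses = [w.status for w in gmap.windows]
    assert statuses == ["estimated", "skipped_gap", "estimated", "skipped_few_sites"]
    assert cache.builds == 1  # identical (xi2', xix') reused the model
    assert gmap.windows[0].rho >= 0
    df = gmap.to_dataframe()
    assert list(df.columns[:5]) == ["chrom", "start", "end", "rho", "status"]


def test_scan_recovers_constant_rate(tmp_path):
    """End-to-end synthetic recovery: a chromosome simulated at constant
    rho per window yields a mean window estimate near the truth."""
    true_rho, n_windows, window = 25.0, 10, 50_000
    mats = []
    for k in range(n_windows):
        m = _window_matrix(50, 30, true_rho, seed=200 + k,
                           window=("1", k * window, (k + 1) * window))
        mats.append(m)
    path = str(tmp_path / "chrom.vcf")
    write_vcf(path, mats, chrom="1", chrom_length=n_windows * window)
    cfg = ScanConfig(window_len=window, min_sites=10)
    cache = ModelCache(seed=18, training_reps=30)
    gmap = scan(path, cfg, cache, seed=18, correction_reps=30)
    est = gmap.estimated()
    assert len(est) == n_windows
    rhos = np.array([w.rho for w in est])
    se = rhos.std(ddof=1) / np.sqrt(len(rhos))
    assert abs(rhos.mean() - true_rho) < max(3 * se, 2.0)


def test_scan_is_deterministic(tmp_path):
    w0 = _window_matrix(20, 15, 10, seed=3, window=("1", 0, 10_000))
    path = str(tmp_path / "det.vcf")
    write_vcf(path, [w0], chrom="1", chrom_length=10_000)
    cfg = ScanConfig(window_len=10_000, min_sites=5)
    g1 = scan(path, cfg, ModelCache(seed=4, training_reps=10), seed=9,
              correction_reps=5)
    g2 = scan(path, cfg, ModelCache(seed=4, training_reps=10), seed=9,
              correction_reps=5)
    assert g1.windows[0].rho == g2.windows[0].rho


# ---------------------------------------------------------------------
# calibration, conversion, comparison
# ---------------------------------------------------------------------

def _uniform_map(rhos, window_len=50_000, chrom="1"):
    wins = [
        WindowResult(chrom, k * window_len, (k + 1) * window_len, float(r), "estimated")
        for k, r in enumerate(rhos)
    ]
    return GeneticMap(windows=wins, window_len=window_len)


def test_calibrate_ne_arithmetic():
    # total rho 400 over intervals of total genetic length 1 cM -> Ne = 10000
    gmap = _uniform_map([100, 100, 100, 100])
    ref = pd.DataFrame({"chrom": ["1", "1"], "pos": [0, 200_000], "cM": [0.0, 1.0]})
    assert calibrate_Ne(gmap, ref) == pytest.approx(10_000.0)
    ref2 = ref.assign(cM=[0.0, 2.0])
    assert calibrate_Ne(gmap, ref2) == pytest.approx(5_000.0)


def test_calibrate_ne_round_trip():
    # a map built as rho = 4 Ne r from the reference recovers Ne exactly
    ne_true = 12_345.0
    window = 50_000
    cm_per_window = np.array([0.02, 0.05, 0.01, 0.07, 0.03])
    rhos = 4 * ne_true * cm_per_window / 100.0
    gmap = _uniform_map(list(rhos), window_len=window)
    pos = np.arange(len(rhos) + 1) * window
    ref = pd.DataFrame({
        "chrom": "1",
        "pos": pos,
        "cM": np.concatenate([[0.0], np.cumsum(cm_per_window)]),
    })
    assert calibrate_Ne(gmap, ref) == pytest.approx(ne_true, rel=1e-9)
    # and converting back reproduces the reference mean cM/Mb
    mean_rho_per_mb = rhos.sum() / (len(rhos) * window / 1e6)
    mean_cm_per_mb = cm_per_window.sum() / (len(rhos) * window / 1e6)
    assert rho_to_cM_per_Mb(mean_rho_per_mb, ne_true) == pytest.approx(
        mean_cm_per_mb, rel=1e-9
    )


def test_rho_to_cm_per_mb_printed_conversions():
    assert rho_to_cM_per_Mb(939.66, 20_073) == pytest.approx(1.1703, abs=5e-5)
    assert rho_to_cM_per_Mb(474.31, 10_133) == pytest.approx(1.1702, abs=5e-5)
    assert rho_to_cM_per_Mb(0.0, 10_000) == 0.0


def test_map_correlation_identities():
    rng = np.random.default_rng(8)
    rhos = rng.uniform(0, 10, size=40)
    a = _uniform_map(list(rhos))
    assert map_correlation(a, a, 100_000) == pytest.approx(1.0)
    b = _uniform_map(list(12.0 - rhos))
    assert map_correlation(a, b, 100_000) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        map_correlation(_uniform_map([1, 2]), _uniform_map([1, 2]), 50_000)


def test_map_correlation_constructed_value():
    # shared + independent components with a known analytic correlation
    rng = np.random.default_rng(15)
    shared = rng.normal(0, 1, size=200)
    a = _uniform_map(list(10 + 2 * shared + rng.normal(0, 1, 200)))
    b = _uniform_map(list(10 + 2 * shared + rng.normal(0, 1, 200)))
    expect = 4 / 5  # cov = 4, var = 4 + 1
    assert abs(map_correlation(a, b, 50_000) - expect) < 0.05


def test_concentration_curve_shapes():
    seq, rec = concentration_curve(_uniform_map([3.0] * 10))
    assert np.allclose(rec, seq)  # uniform map -> diagonal
    seq2, rec2 = concentration_curve(_uniform_map([10.0] + [0.0] * 9))
    assert rec2[1] == pytest.approx(1.0)  # one hot window carries everything
    # 70% of recombination in 30% of the sequence
    rhos = [7.0 / 3] * 3 + [3.0 / 7] * 7
    seq3, rec3 = concentration_curve(_uniform_map(rhos))
    k = int(np.flatnonzero(np.isclose(seq3, 0.3))[0])
    assert rec3[k] == pytest.approx(0.7)
    assert np.all(np.diff(rec3) >= -1e-12)
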