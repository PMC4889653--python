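"""Genome-scale recombination maps from phased VCF.

The scanner tiles each chromosome with fixed-length windows, applies the
site and window filters (SNPs only, site quality >= 20, no assembly-gap
overlap, at least 10 non-singleton segregating sites), batches windows by
their folded-spectrum combination so each unique (xi2', xix') trains one
regression model, and emits a window-level rho map.  Utilities convert
rho to cM/Mb via an Ne calibrated against a pedigree-based genetic map,
correlate maps at a chosen scale, and summarize how concentrated
recombination is along the sequence.

Coordinates are 0-based half-open throughout; VCF input positions are
converted on read, and gap BED intervals are taken as 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from ._rng import derive_seed
from .estimator import (
    EstimateOptions,
    ModelCache,
    WindowSkipped,
    estimate_window,
)
from .haplotype import MISSING, HaplotypeMatrix, encode_alleles
from .sumstats import fold_spectrum

__all__ = [
    "ScanConfig",
    "WindowResult",
    "GeneticMap",
    "read_window_vcf",
    "scan",
    "calibrate_Ne",
    "rho_to_cM_per_Mb",
    "map_correlation",
    "concentration_curve",
    "write_vcf",
]

_NT_CODE = {"A": 2, "C": 3, "G": 4, "T": 5}
_CODE_NT = {v: k for k, v in _NT_CODE.items()}


@dataclass
class ScanConfig:
    """Window and filter settings for a genome scan."""

    window_len: int = 50_000
    step: int | None = None  # defaults to window_len (nonoverlapping)
    min_sites: int = 10
    min_qual: float = 20.0
    gaps: list[tuple[str, int, int]] = field(default_factory=list)
    samples: list[str] | None = None

    def __post_init__(self) -> None:
        if self.window_len <= 0:
            raise ValueError("window_len must be > 0")
        if self.step is None:
            self.step = self.window_len
        if self.step not in (self.window_len, self.window_len // 2):
            raise ValueError("step must be window_len or window_len/2")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")


@dataclass
class WindowResult:
    chrom: str
    start: int
    end: int
    rho: float
    status: str  # estimated | skipped_gap | skipped_few_sites | skipped_undefined
    xi2p: int = 0
    xixp: int = 0
    H: int = 0


@dataclass
class GeneticMap:
    """An ordered collection of window results, optionally Ne-calibrated."""

    windows: list[WindowResult]
    window_len: int
    Ne: float | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (w.chrom, w.start, w.end, w.rho, w.status, w.xi2p, w.xixp, w.H)
                for w in self.windows
            ],
            columns=["chrom", "start", "end", "rho", "status", "xi2p", "xixp", "H"],
        )

    def estimated(self) -> list[WindowResult]:
        return [w for w in self.windows if w.status == "estimated"]


def _fetch_records(vcf: pysam.VariantFile, chrom: str, start: int, end: int):
    try:
        yield from vcf.fetch(chrom, start, end)
    except ValueError:
        # no index: linear scan
        for rec in vcf:
            if rec.chrom == chrom and start <= rec.start < end:
                yield rec


def read_window_vcf(
    vcf_path: str,
    region: tuple[str, int, int],
    cfg: ScanConfig | None = None,
) -> HaplotypeMatrix:
    """Phased haplotypes for one genomic window.

    Keeps biallelic and multi-allelic SNPs with QUAL >= cfg.min_qual;
    indels and low-quality sites are dropped.  Each diploid sample
    contributes two haplotype rows; unphased or missing genotypes become
    '?' cells.  Non-segregating columns are removed.
    """
    cfg = cfg or ScanConfig()
    chrom, start, end = region
    with pysam.VariantFile(vcf_path) as vcf:
        sample_names = list(cfg.samples or vcf.header.samples)
        rows_per_sample = None
        columns: list[np.ndarray] = []
        positions: list[int] = []
        for rec in _fetch_records(vcf, chrom, start, end):
            alleles = [rec.ref] + list(rec.alts or ())
            if any(a is None or len(a) != 1 or a.upper() not in _NT_CODE for a in alleles):
                continue  # indel or symbolic allele
            if rec.qual is not None and rec.qual < cfg.min_qual:
                continue
            col = []
            for s in sample_names:
                call = rec.samples[s]
                gt = call["GT"]
                phased = call.phased or len(gt) == 1
                for a in gt:
                    if a is None or not phased:
                        col.append(MISSING)
                    else:
                        col.append(_NT_CODE[alleles[a].upper()])
            if rows_per_sample is None:
                rows_per_sample = len(col)
            columns.append(np.array(col, dtype=np.uint8))
            positions.append(rec.start)
    if not columns:
        n_rows = 0 if rows_per_sample is None else rows_per_sample
        return HaplotypeMatrix(
            np.zeros((n_rows, 0), dtype=np.uint8), np.zeros(0), window=region
        )
    m = HaplotypeMatrix(
        np.stack(columns, axis=1), np.array(positions, dtype=float), window=region
    )
    return m.drop_nonsegregating()


def _overlaps_gap(cfg: ScanConfig, chrom: str, start: int, end: int) -> bool:
    for gc, gs, ge in cfg.gaps:
        if gc == chrom and start < ge and gs < end:
            return True
    return False


def _chrom_lengths(vcf_path: str) -> dict[str, int]:
    with pysam.VariantFile(vcf_path) as vcf:
        out = {c.name: c.length for c in vcf.header.contigs.values() if c.length}
        if out:
            return out
        # fall back to the last variant position per chromosome
        lengths: dict[str, int] = {}
        for rec in vcf:
            lengths[rec.chrom] = max(lengths.get(rec.chrom, 0), rec.stop)
        return lengths


def scan(
    vcf_path: str,
    cfg: ScanConfig | None = None,
    cache: ModelCache | None = None,
    seed: int = 1,
    correction_reps: int = 100,
) -> GeneticMap:
    """Estimate rho in sliding windows over every chromosome of a VCF.

    Windows are anchored at multiples of the step from position 0; the
    final partial window is dropped.  Windows overlapping a gap or with
    fewer than cfg.min_sites non-singleton segregating sites are marked
    skipped.  Per-window seeds derive from (seed, chrom, start) so a
    re-run of one window reproduces the full scan.
    """
    cfg = cfg or ScanConfig()
    cache = cache or ModelCache(seed=derive_seed(seed, "scan-cache"))
    results: list[WindowResult] = []
    for chrom, length in sorted(_chrom_lengths(vcf_path).items()):
        for start in range(0, length - cfg.window_len + 1, cfg.step):
            end = start + cfg.window_len
            if _overlaps_gap(cfg, chrom, start, end):
                results.append(WindowResult(chrom, start, end, float("nan"), "skipped_gap"))
                continue
            m = read_window_vcf(vcf_path, (chrom, start, end), cfg)
            if m.S == 0:
                results.append(
                    WindowResult(chrom, start, end, float("nan"), "skipped_few_sites")
                )
                continue
            spec = fold_spectrum(m)
            if spec.xi2p + spec.xixp < cfg.min_sites:
                results.append(
                    WindowResult(
                        chrom, start, end, float("nan"), "skipped_few_sites",
                        spec.xi2p, spec.xixp,
                    )
                )
                continue
            opts = EstimateOptions(
                training_reps=cache.training_reps,
                correction_reps=correction_reps,
                seed=derive_seed(seed, chrom, start),
                cache=cache,
                min_sites=cfg.min_sites,
            )
            try:
                est = estimate_window(m, opts)
            except WindowSkipped:
                results.append(
                    WindowResult(
                        chrom, start, end, float("nan"), "skipped_undefined",
                        spec.xi2p, spec.xixp,
                    )
                )
                continue
            results.append(
                WindowResult(
                    chrom, start, end, est.rho, "estimated",
                    spec.xi2p, spec.xixp, est.h_obs,
                )
            )
    return GeneticMap(windows=results, window_len=cfg.window_len)


# ---------------------------------------------------------------------
# calibration, conversion and comparison
# ---------------------------------------------------------------------

def _reference_cM(reference: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    """Genetic length in cM of [start, end) under a (chrom, pos, cM) map."""
    sub = reference[reference["chrom"] == chrom]
    if len(sub) < 2:
        return 0.0
    pos = sub["pos"].to_numpy(dtype=float)
    cm = sub["cM"].to_numpy(dtype=float)
    lo = max(start, pos.min())
    hi = min(end, pos.max())
    if hi <= lo:
        return 0.0
    return float(np.interp(hi, pos, cm) - np.interp(lo, pos, cm))


def calibrate_Ne(gmap: GeneticMap, reference: pd.DataFrame) -> float:
    """Ne from comparing total map length with a pedigree-based map.

    Ne = sum(rho over overlapping estimated windows) divided by 4 times
    the reference genetic length (in Morgans) of the same intervals.
    """
    total_rho = 0.0
    total_morgans = 0.0
    for w in gmap.estimated():
        cm = _reference_cM(reference, w.chrom, w.start, w.end)
        if cm > 0:
            total_rho += w.rho
            total_morgans += cm / 100.0
    if total_morgans <= 0 or total_rho <= 0:
        raise ValueError("no overlap between the map and the reference")
    ne = total_rho / (4.0 * total_morgans)
    gmap.Ne = ne
    return ne


def rho_to_cM_per_Mb(rho_per_Mb: float, Ne: float) -> float:
    """Convert a per-Mb rho into cM/Mb: r = 100 * rho / (4 Ne)."""
    if Ne <= 0:
        raise ValueError("Ne must be > 0")
    return 100.0 * rho_per_Mb / (4.0 * Ne)


def _rebin(gmap: GeneticMap, scale_bp: int) -> dict[tuple[str, int], float]:
    """Per-bin summed rho (length-weighted for partial overlap); bins
    touching any skipped window are undefined."""
    bins: dict[tuple[str, int], float] = {}
    bad: set[tuple[str, int]] = set()
    for w in gmap.windows:
        b0 = w.start // scale_bp
        b1 = (w.end - 1) // scale_bp
        for b in range(b0, b1 + 1):
            key = (w.chrom, b)
            lo = max(w.start, b * scale_bp)
            hi = min(w.end, (b + 1) * scale_bp)
            frac = (hi - lo) / (w.end - w.start)
            if w.status != "estimated":
                bad.add(key)
                continue
            bins[key] = bins.get(key, 0.0) + w.rho * frac
    return {k: v for k, v in bins.items() if k not in bad}


def map_correlation(map_a: GeneticMap, map_b: GeneticMap, scale_bp: int) -> float:
    """Pearson correlation of two maps rebinned to scale_bp."""
    ra = _rebin(map_a, scale_bp)
    rb = _rebin(map_b, scale_bp)
    shared = sorted(set(ra) & set(rb))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared bins")
    va = np.array([ra[k] for k in shared])
    vb = np.array([rb[k] for k in shared])
    return float(np.corrcoef(va, vb)[0, 1])


def concentration_curve(gmap: GeneticMap) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative recombination share versus sequence share.

    Windows sorted by rho descending; returns step-curve vertices from
    (0, 0) to (1, 1).  The curve is concave: the busiest windows carry a
    disproportionate share of recombination.
    """
    est = gmap.estimated()
    if not est:
        raise ValueError("no estimated windows")
    rho = np.sort(np.array([w.rho for w in est]))[::-1]
    total = rho.sum()
    seq = np.arange(len(rho) + 1) / len(rho)
    rec = np.concatenate([[0.0], np.cumsum(rho)]) / (total if total > 0 else 1.0)
    return seq, rec


# ---------------------------------------------------------------------
# synthetic VCF export (testing and examples)
# ---------------------------------------------------------------------

def write_vcf(
    path: str,
    matrices: list[HaplotypeMatrix],
    chrom: str = "1",
    chrom_length: int | None = None,
    qual: float = 100.0,
) -> None:
    """Write synthetic haplotype windows as a phased diploid VCF.

    Rows 2i and 2i+1 become sample i's two phased alleles.  Binary
    matrices are encoded as A (0) / C (1); positions must be base pairs
    within each matrix's window.
    """
    n = matrices[0].n
    if n % 2:
        raise ValueError("need an even number of haplotypes to form diploids")
    samples = [f"s{i}" for i in range(n // 2)]
    length = chrom_length or max(int(m.window[2]) for m in matrices if m.window)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for m in matrices:
            offset = m.window[1] if m.window else 0
            for j in range(m.S):
                col = m.alleles[:, j]
                obs = col[col != MISSING]
                vals = np.unique(obs)
                if np.all(vals < 2):  # binary coding -> A/C
                    ref, alts = "A", ["C"]
                    idx = {0: 0, 1: 1}
                else:
                    ref = _CODE_NT[int(vals[0])]
                    alts = [_CODE_NT[int(v)] for v in vals[1:]]
                    idx = {int(v): k for k, v in enumerate(vals)}
                gts = []
                for i in range(0, n, 2):
                    a, b = col[i], col[i + 1]
                    fa = "." if a == MISSING else str(idx[int(a)])
                    fb = "." if b == MISSING else str(idx[int(b)])
                    gts.append(f"{fa}|{fb}")
                pos1 = int(offset + m.positions[j]) + 1  # VCF is 1-based
                fh.write(
                    f"{chrom}\t{pos1}\t.\t{ref}\t{','.join(alts)}\t{qual:g}\t.\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )
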