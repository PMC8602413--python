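"""Genotype, population-map and window-grid handling.

This module owns the substrate of every downstream statistic: a matrix of
biallelic diploid genotype codes with genomic coordinates, the sample ->
population assignment, the standard SNP site filters (missingness, minor
allele frequency, heterozygote-excess HWE), outgroup polarization into
per-population derived-allele frequencies, and the sliding window grid.

Coordinates are 0-based half-open internally (BED convention); VCF input
and output convert from/to the 1-based VCF convention at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeTable",
    "PopulationMap",
    "FrequencyTable",
    "WindowGrid",
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "filter_variants",
    "polarize_by_outgroup",
    "make_windows",
]

log = logging.getLogger(__name__)

MISSING = -1  # genotype code for an uncalled diploid genotype


@dataclass
class GenotypeTable:
    """Biallelic SNP sites x samples with diploid alt-allele-count codes.

    ``genotypes[i, j]`` is 0/1/2 (count of alt alleles) or ``MISSING`` (-1).
    ``pos`` is 0-based; positions are strictly increasing within a contig.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (self.pos.size, len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        ok = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not ok.all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take_sites(self, index: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            self.chrom[index], self.pos[index], self.ref[index],
            self.alt[index], self.genotypes[index], list(self.samples),
        )

    def subset_samples(self, samples: list[str]) -> "GenotypeTable":
        missing = [s for s in samples if s not in self.samples]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        idx = [self.samples.index(s) for s in samples]
        return GenotypeTable(
            self.chrom, self.pos, self.ref, self.alt,
            self.genotypes[:, idx], list(samples),
        )


@dataclass
class PopulationMap:
    """Sample -> population labels, with an optional designated outgroup."""

    assignments: dict[str, str]
    outgroup: str | None = None

    def __post_init__(self) -> None:
        if self.outgroup is not None and self.outgroup not in self.populations:
            raise ValueError(f"outgroup {self.outgroup!r} has no samples")

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.assignments.values()))

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]


@dataclass
class FrequencyTable:
    """Per-site, per-population derived-allele frequencies after polarization.

    ``derived_freq[k, i]`` is the derived-allele frequency of population
    ``populations[k]`` at site ``i`` (NaN when no calls); ``n_called`` the
    number of non-missing haploid calls. ``usable`` marks sites where the
    outgroup was fixed, i.e. where the ancestral state is known; only those
    sites enter the D/fd machinery. At unusable sites frequencies refer to
    the alt allele (polarity is arbitrary but consistent, which suffices
    for the polarity-invariant statistics pi, dxy and FST).
    """

    chrom: np.ndarray
    pos: np.ndarray
    populations: list[str]
    derived_freq: np.ndarray  # (n_pops, n_sites) float64
    n_called: np.ndarray      # (n_pops, n_sites) int32, haploid calls
    usable: np.ndarray        # (n_sites,) bool
    ancestral_is_ref: np.ndarray  # (n_sites,) bool; meaningful where usable

    def __post_init__(self) -> None:
        self.derived_freq = np.asarray(self.derived_freq, dtype=np.float64)
        self.n_called = np.asarray(self.n_called, dtype=np.int32)
        with np.errstate(invalid="ignore"):
            bad = (self.derived_freq < 0) | (self.derived_freq > 1)
        if bad.any():
            raise ValueError("derived frequencies outside [0, 1]")
        if (self.n_called % 2).any():
            raise ValueError("haploid call counts must be even (diploids)")

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def _k(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None

    def freq(self, population: str) -> np.ndarray:
        return self.derived_freq[self._k(population)]

    def n(self, population: str) -> np.ndarray:
        return self.n_called[self._k(population)]

    def pooled(self, labels) -> tuple[np.ndarray, np.ndarray]:
        """Derived freq and call count of several populations pooled."""
        ks = [self._k(p) for p in (labels if not isinstance(labels, str) else [labels])]
        n = self.n_called[ks].astype(np.float64)
        f = np.nan_to_num(self.derived_freq[ks])
        ntot = n.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ntot > 0, (f * n).sum(axis=0) / ntot, np.nan)
        return p, ntot.astype(np.int64)


@dataclass
class WindowGrid:
    """Sliding windows in 0-based half-open coordinates."""

    window_size: int
    step: int
    chrom: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    start: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    end: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    partial: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    @property
    def n_windows(self) -> int:
        return int(self.start.size)

    def lengths(self) -> np.ndarray:
        return self.end - self.start


# ---------------------------------------------------------------------------
# I/O


def read_vcf(path: str, samples: list[str] | None = None) -> GenotypeTable:
    """Read biallelic SNPs from a (possibly gzipped) VCF into a GenotypeTable.

    Multiallelic records and non-SNP records are dropped (counts logged).
    Positions are converted from 1-based VCF to 0-based internal coordinates.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF reading") from e

    try:
        vcf = VCF(str(path), samples=samples, gts012=True)
    except OSError as e:
        raise FileNotFoundError(f"cannot open VCF {path!r}: {e}") from e
    if samples is not None:
        got = list(vcf.samples)
        absent = [s for s in samples if s not in got]
        if absent:
            raise KeyError(f"requested samples absent from VCF: {absent}")
    chrom, pos, ref, alt, gts = [], [], [], [], []
    n_multi = n_nonsnp = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_nonsnp += 1
            continue
        chrom.append(rec.CHROM)
        pos.append(rec.POS - 1)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        g = rec.gt_types.astype(np.int8)  # gts012: 0/1/2, 3 = unknown
        g[g == 3] = MISSING
        gts.append(g)
    if n_multi or n_nonsnp:
        log.info("read_vcf: dropped %d multiallelic and %d non-SNP records",
                 n_multi, n_nonsnp)
    sample_list = list(vcf.samples)
    vcf.close()
    if not pos:
        return GenotypeTable(
            np.empty(0, object), np.empty(0, np.int64), np.empty(0, object),
            np.empty(0, object), np.empty((0, len(sample_list)), np.int8),
            sample_list)
    return GenotypeTable(np.array(chrom, object), np.array(pos, np.int64),
                         np.array(ref, object), np.array(alt, object),
                         np.vstack(gts), sample_list)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gt: GenotypeTable, path: str,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeTable as a minimal VCF v4.2 (GT field only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introscan\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in dict.fromkeys(gt.chrom):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gt.samples) + "\n")
        for i in range(gt.n_sites):
            row = "\t".join(_GT_STR[int(g)] for g in gt.genotypes[i])
            fh.write(f"{gt.chrom[i]}\t{gt.pos[i] + 1}\t.\t{gt.ref[i]}\t"
                     f"{gt.alt[i]}\t.\tPASS\t.\tGT\t{row}\n")


def read_popmap(path: str, outgroup: str | None = None) -> PopulationMap:
    """Read a two-column TSV ``sample<TAB>population`` (header optional)."""
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str)
    cols = [c.lstrip("#") for c in df.columns]
    if cols[:2] != ["sample", "population"]:
        # headerless file: first row was data
        df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                         names=["sample", "population"])
    else:
        df.columns = cols
    if df["sample"].duplicated().any():
        raise ValueError("sample assigned to more than one population")
    return PopulationMap(dict(zip(df["sample"], df["population"])), outgroup)


# ---------------------------------------------------------------------------
# Site filters


@lru_cache(maxsize=200_000)
def _hwe_het_excess_midp(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-sided mid-p exact HWE test for heterozygote *excess*.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts (Levene/Haldane distribution) and returns the upper
    tail P(het >= observed) with the mid-p correction.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_alt = n_het + 2 * n_hom_alt
    n_alt = min(n_alt, 2 * n - n_alt)  # work with the minor allele
    hets = np.arange(n_alt % 2, n_alt + 1, 2)
    homa = (n_alt - hets) // 2
    homr = n - hets - homa
    logw = (hets * np.log(2.0) - gammaln(homr + 1.0)
            - gammaln(hets + 1.0) - gammaln(homa + 1.0))
    w = np.exp(logw - logw.max())
    w /= w.sum()
    i = np.searchsorted(hets, n_het)
    return float(w[i + 1:].sum() + 0.5 * w[i])


def filter_variants(gt: GenotypeTable, max_missing: float = 0.1,
                    min_maf: float = 0.05,
                    het_excess_alpha: float = 0.001,
                    report: dict | None = None) -> GenotypeTable:
    """Apply the standard SNP site filters and return the surviving sites.

    A site is removed when its genotype missingness exceeds ``max_missing``,
    its pooled minor-allele frequency (over non-missing calls) is below
    ``min_maf``, or a one-sided exact HWE test shows heterozygote excess at
    mid-p < ``het_excess_alpha``. Criteria are evaluated on the input table
    (not sequentially), which makes the filter idempotent. Removal counts
    per criterion are written into ``report`` if given.
    """
    if gt.n_sites == 0:
        raise ValueError("empty genotype table")
    g = gt.genotypes
    miss = (g == MISSING).mean(axis=1)
    called = (g != MISSING).sum(axis=1)
    alt = np.where(g == MISSING, 0, g).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(called > 0, alt / (2.0 * called), np.nan)
    maf = np.fmin(af, 1.0 - af)
    fail_miss = miss > max_missing
    fail_maf = ~(maf >= min_maf)  # NaN (no calls) also fails
    n_het = (g == 1).sum(axis=1)
    n_hom_alt = (g == 2).sum(axis=1)
    n_hom_ref = called - n_het - n_hom_alt
    hwe_p = np.fromiter(
        (_hwe_het_excess_midp(int(a), int(b), int(c))
         for a, b, c in zip(n_hom_ref, n_het, n_hom_alt)),
        dtype=np.float64, count=gt.n_sites)
    fail_hwe = hwe_p < het_excess_alpha
    keep = ~(fail_miss | fail_maf | fail_hwe)
    if report is not None:
        report.update(n_input=gt.n_sites, n_kept=int(keep.sum()),
                      n_fail_missing=int(fail_miss.sum()),
                      n_fail_maf=int(fail_maf.sum()),
                      n_fail_het_excess=int(fail_hwe.sum()))
    if not keep.any():
        log.warning("filter_variants removed every site")
    return gt.take_sites(keep)


# ---------------------------------------------------------------------------
# Polarization


def polarize_by_outgroup(gt: GenotypeTable, pm: PopulationMap) -> FrequencyTable:
    """Polarize alleles against a fixed outgroup and tabulate frequencies.

    The ancestral allele at a site is the allele for which every called
    outgroup genotype is homozygous. Sites where the outgroup is
    polymorphic (any het, or mixed homozygotes) or entirely missing are
    flagged unusable; their reported frequency falls back to the alt
    allele. Derived frequencies are computed per population from observed
    (non-missing) calls only.
    """
    if pm.outgroup is None:
        raise ValueError("population map declares no outgroup")
    unknown = [s for s in pm.assignments if s not in gt.samples]
    if unknown:
        raise KeyError(f"popmap samples absent from genotypes: {unknown}")
    pops = pm.populations
    col = {s: j for j, s in enumerate(gt.samples)}
    og_idx = [col[s] for s in pm.samples_of(pm.outgroup)]
    og = gt.genotypes[:, og_idx]
    og_called = og != MISSING
    any_call = og_called.any(axis=1)
    all_ref = np.where(og_called, og == 0, True).all(axis=1)
    all_alt = np.where(og_called, og == 2, True).all(axis=1)
    usable = any_call & (all_ref | all_alt)
    ancestral_is_ref = np.where(usable, all_ref, True)

    n_pops, n_sites = len(pops), gt.n_sites
    freq = np.full((n_pops, n_sites), np.nan)
    n_called = np.zeros((n_pops, n_sites), dtype=np.int32)
    for k, p in enumerate(pops):
        idx = [col[s] for s in pm.samples_of(p)]
        sub = gt.genotypes[:, idx]
        called = sub != MISSING
        n = 2 * called.sum(axis=1)
        alt_count = np.where(called, sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(n > 0, alt_count / n, np.nan)
        derived = np.where(ancestral_is_ref, p_alt, 1.0 - p_alt)
        freq[k] = derived
        n_called[k] = n
    return FrequencyTable(gt.chrom, gt.pos, pops, freq, n_called,
                          usable, ancestral_is_ref)


# ---------------------------------------------------------------------------
# Window grid


def make_windows(contig_lengths: dict[str, int], window_size: int = 100_000,
                 step: int = 20_000) -> WindowGrid:
    """Build the sliding window grid (0-based half-open) over each contig.

    Window starts advance by ``step``; the last window on a contig may be
    shorter than ``window_size`` and is flagged partial. The union of the
    windows covers each contig exactly.
    """
    if step <= 0 or window_size <= 0:
        raise ValueError("window_size and step must be positive")
    if window_size < step:
        raise ValueError("window_size must be >= step")
    chroms, starts, ends, partial = [], [], [], []
    for c, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for contig {c!r}")
        s = 0
        while s < length:
            e = min(s + window_size, length)
            chroms.append(c)
            starts.append(s)
            ends.append(e)
            partial.append(e - s < window_size)
            if e == length:
                break
            s += step
    return WindowGrid(window_size, step, np.array(chroms, object),
                      np.array(starts, np.int64), np.array(ends, np.int64),
                      np.array(partial, bool))


def window_sums(grid: WindowGrid, chrom: np.ndarray, pos: np.ndarray,
                values: np.ndarray) -> np.ndarray:
    """Sum per-site values over every grid window.

    ``values`` has sites along its last axis; sites must be coordinate
    sorted within each contig (the GenotypeTable invariant). Returns an
    array shaped like ``values`` with the site axis replaced by windows.
    NaNs in ``values`` are treated as zero.
    """
    vals = np.nan_to_num(np.asarray(values, dtype=np.float64))
    out = np.zeros(vals.shape[:-1] + (grid.n_windows,))
    csum = np.zeros(vals.shape[:-1] + (vals.shape[-1] + 1,))
    np.cumsum(vals, axis=-1, out=csum[..., 1:])
    for c in dict.fromkeys(grid.chrom):
        site_sel = np.flatnonzero(chrom == c)
        win_sel = np.flatnonzero(grid.chrom == c)
        if site_sel.size == 0:
            continue
        p = pos[site_sel]
        lo = site_sel[0] + np.searchsorted(p, grid.start[win_sel], "left")
        hi = site_sel[0] + np.searchsorted(p, grid.end[win_sel], "left")
        out[..., win_sel] = csum[..., hi] - csum[..., lo]
    return out
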