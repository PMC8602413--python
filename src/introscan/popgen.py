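"""Windowed diversity and differentiation statistics.

Nucleotide diversity (pi), absolute divergence (dxy) and Hudson's FST are
computed from per-population allele frequencies in sliding windows, plus a
genotype-correlation LD decay curve (r-squared vs. physical distance).

All per-bp statistics are normalised by the window length in bp, which
assumes sites absent from the table are invariant (as after joint
genotyping with a fixed site set).

Estimators
----------
pi (per window)  : sum_sites [n/(n-1) * 2 p (1-p)] / L
dxy (per window) : sum_sites [pA (1-pB) + pB (1-pA)] / L
FST (Hudson, ratio of averages over the window's sites):
    num_site = (pA-pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)
    den_site = pA(1-pB) + pB(1-pA)
    FST = sum(num) / sum(den)

Negative window FST values are preserved; windows with no usable data
report NaN rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import (MISSING, FrequencyTable, GenotypeTable,
                          PopulationMap, WindowGrid, window_sums)

__all__ = ["window_pi", "window_dxy", "window_fst", "diversity_table",
           "ld_decay", "LDDecayCurve"]


def _site_pi(freqs: FrequencyTable, population) -> np.ndarray:
    """Per-site pi terms n/(n-1) * 2p(1-p); NaN where < 2 called alleles."""
    if isinstance(population, str):
        p, n = freqs.freq(population), freqs.n(population).astype(float)
    else:
        p, n = freqs.pooled(population)
        n = n.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 1, n / (n - 1.0) * 2.0 * p * (1.0 - p), np.nan)


def window_pi(freqs: FrequencyTable, grid: WindowGrid, population) -> np.ndarray:
    """Per-bp nucleotide diversity of one population (or pooled label set)
    in each grid window. Windows with zero called sites report NaN."""
    site = _site_pi(freqs, population)
    called = ~np.isnan(site)
    sums = window_sums(grid, freqs.chrom, freqs.pos, np.where(called, site, 0.0))
    n_called = window_sums(grid, freqs.chrom, freqs.pos, called.astype(float))
    with np.errstate(invalid="ignore"):
        return np.where(n_called > 0, sums / grid.lengths(), np.nan)


def _pair_freqs(freqs: FrequencyTable, pop_a, pop_b):
    pa = freqs.freq(pop_a) if isinstance(pop_a, str) else freqs.pooled(pop_a)[0]
    pb = freqs.freq(pop_b) if isinstance(pop_b, str) else freqs.pooled(pop_b)[0]
    na = freqs.n(pop_a) if isinstance(pop_a, str) else freqs.pooled(pop_a)[1]
    nb = freqs.n(pop_b) if isinstance(pop_b, str) else freqs.pooled(pop_b)[1]
    return pa, pb, na.astype(float), nb.astype(float)


def window_dxy(freqs: FrequencyTable, grid: WindowGrid, pop_a, pop_b) -> np.ndarray:
    """Per-bp absolute divergence between two populations per window."""
    pa, pb, na, nb = _pair_freqs(freqs, pop_a, pop_b)
    site = pa * (1.0 - pb) + pb * (1.0 - pa)
    ok = (na > 0) & (nb > 0) & ~np.isnan(site)
    sums = window_sums(grid, freqs.chrom, freqs.pos, np.where(ok, site, 0.0))
    n_ok = window_sums(grid, freqs.chrom, freqs.pos, ok.astype(float))
    with np.errstate(invalid="ignore"):
        return np.where(n_ok > 0, sums / grid.lengths(), np.nan)


def hudson_fst_components(pa, pb, na, nb):
    """Per-site Hudson numerator and denominator (Bhatia et al. form)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((pa - pb) ** 2
               - pa * (1.0 - pa) / (na - 1.0)
               - pb * (1.0 - pb) / (nb - 1.0))
        den = pa * (1.0 - pb) + pb * (1.0 - pa)
    ok = (na > 1) & (nb > 1) & ~np.isnan(num)
    return np.where(ok, num, 0.0), np.where(ok, den, 0.0), ok


def window_fst(freqs: FrequencyTable, grid: WindowGrid, pop_a, pop_b) -> np.ndarray:
    """Hudson FST (ratio of averages) between two populations per window.

    Sites need >= 2 called alleles in each population. Windows whose
    summed denominator is zero (no variation) report NaN.
    """
    pa, pb, na, nb = _pair_freqs(freqs, pop_a, pop_b)
    num, den, _ = hudson_fst_components(pa, pb, na, nb)
    num_w = window_sums(grid, freqs.chrom, freqs.pos, num)
    den_w = window_sums(grid, freqs.chrom, freqs.pos, den)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den_w > 0, num_w / den_w, np.nan)


def diversity_table(freqs: FrequencyTable, grid: WindowGrid,
                    populations: list[str] | None = None) -> pd.DataFrame:
    """Tidy per-window table of pi for every population and dxy/FST for
    every population pair, with BED-compatible leading columns."""
    pops = populations or freqs.populations
    base = pd.DataFrame({"chrom": grid.chrom, "start": grid.start,
                         "end": grid.end, "partial": grid.partial})
    n_sites = window_sums(grid, freqs.chrom, freqs.pos,
                          np.ones(freqs.n_sites))
    base["n_sites"] = n_sites.astype(int)
    rows = []
    for p in pops:
        d = base.copy()
        d["stat"], d["populations"], d["value"] = "pi", p, window_pi(freqs, grid, p)
        rows.append(d)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            for stat, fn in (("dxy", window_dxy), ("fst", window_fst)):
                d = base.copy()
                d["stat"], d["populations"] = stat, f"{a},{b}"
                d["value"] = fn(freqs, grid, a, b)
                rows.append(d)
    return pd.concat(rows, ignore_index=True)


@dataclass
class LDDecayCurve:
    """Mean genotype-correlation r^2 binned by pairwise distance."""

    bin_left: np.ndarray   # bp, inclusive
    bin_right: np.ndarray  # bp, exclusive
    mean_r2: np.ndarray
    n_pairs: np.ndarray


def ld_decay(gt: GenotypeTable, pm: PopulationMap, population: str,
             max_dist: int = 500_000, bin_width: int = 10_000) -> LDDecayCurve:
    """Unphased-genotype LD decay (Rogers-Huff style r^2) for one population.

    For every intra-contig pair of segregating sites within ``max_dist``,
    r^2 is the squared Pearson correlation of the 0/1/2 genotype codes over
    samples called at both sites; pairs are binned by physical distance.
    """
    cols = [gt.samples.index(s) for s in pm.samples_of(population)]
    if not cols:
        raise KeyError(f"no samples for population {population!r}")
    g = gt.genotypes[:, cols].astype(np.float64)
    g[gt.genotypes[:, cols] == MISSING] = np.nan
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for c in dict.fromkeys(gt.chrom):
        idx = np.flatnonzero(gt.chrom == c)
        pos = gt.pos[idx]
        sub = g[idx]
        for ii in range(idx.size):
            jj = ii + 1 + np.searchsorted(pos[ii + 1:], pos[ii] + max_dist, "right")
            for kk in range(ii + 1, jj):
                x, y = sub[ii], sub[kk]
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 2:
                    continue
                vx, vy = x[ok], y[ok]
                if vx.std() == 0 or vy.std() == 0:
                    continue
                r = np.corrcoef(vx, vy)[0, 1]
                b = int((pos[kk] - pos[ii] - 1) // bin_width)
                if 0 <= b < n_bins:
                    sums[b] += r * r
                    counts[b] += 1
    left = np.arange(n_bins, dtype=np.int64) * bin_width
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(left, left + bin_width, mean, counts)
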