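"""Four-taxon introgression statistics: Patterson's D, f3, and the windowed
fd scan with FDR-controlled tract calling.

All statistics are frequency-based, computed on outgroup-polarized derived
allele frequencies p1, p2, p3 (p4 = 0 at usable sites by construction when
the outgroup population itself defines the polarization).

Per site:
    abba = (1-p1) p2 p3 (1-p4)
    baba = p1 (1-p2) p3 (1-p4)
    D = (sum abba - sum baba) / (sum abba + sum baba)

fd (per window, following the dynamic-donor estimator): the D numerator
divided by the same numerator with the per-site donor frequency
pd = max(p2, p3) substituted for both P2 and P3, which bounds fd in [0, 1]
when the window D is positive. Window fd values are Z-standardized genome
wide; one-sided upper-tail normal p-values are Benjamini-Hochberg adjusted;
windows with positive D and q < alpha are merged into introgressed tracts.

Significance of genome-wide D and f3 uses a delete-one weighted block
jackknife over fixed-size genomic blocks (default 1 Mb), with per-block
usable-site counts as weights; |Z| > 3 is the conventional cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .genotype_io import FrequencyTable, WindowGrid, window_sums

__all__ = ["SitePatternSums", "DStatResult", "site_patterns",
           "genome_wide_d", "f3_statistic", "window_fd_scan", "fdr_bh",
           "call_introgressed_tracts", "merge_intervals"]


@dataclass
class SitePatternSums:
    """Per-site ABBA/BABA terms (and donor-maximized variants) on the
    usable-site subset, with coordinates for block/window aggregation."""

    chrom: np.ndarray
    pos: np.ndarray
    abba: np.ndarray
    baba: np.ndarray
    abba_donor: np.ndarray   # with pd = max(p2, p3) substituted
    baba_donor: np.ndarray
    taxa: tuple[str, str, str, str]

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)


@dataclass
class DStatResult:
    statistic: float
    se: float
    z: float
    n_blocks: int
    n_sites: int
    taxa: tuple
    name: str = "D"

    @property
    def significant(self) -> bool:
        return np.isfinite(self.z) and abs(self.z) > 3.0


def site_patterns(freqs: FrequencyTable,
                  taxa: tuple[str, str, str, str]) -> SitePatternSums:
    """ABBA/BABA terms per usable site for the quartet (P1, P2, P3, O).

    Sites unusable for polarization or lacking calls in any taxon are
    skipped. The outgroup frequency p4 enters as-is; it is 0 whenever O is
    the polarizing outgroup population.
    """
    p1_l, p2_l, p3_l, p4_l = taxa
    p1, p2, p3, p4 = (freqs.freq(t) for t in taxa)
    ok = freqs.usable.copy()
    for t in taxa:
        ok &= freqs.n(t) > 0
    sel = np.flatnonzero(ok)
    p1, p2, p3, p4 = p1[sel], p2[sel], p3[sel], p4[sel]
    pd_ = np.maximum(p2, p3)
    return SitePatternSums(
        chrom=freqs.chrom[sel], pos=freqs.pos[sel],
        abba=(1 - p1) * p2 * p3 * (1 - p4),
        baba=p1 * (1 - p2) * p3 * (1 - p4),
        abba_donor=(1 - p1) * pd_ * pd_ * (1 - p4),
        baba_donor=p1 * (1 - pd_) * pd_ * (1 - p4),
        taxa=tuple(taxa))


def _block_ids(chrom: np.ndarray, pos: np.ndarray, block_size: int) -> np.ndarray:
    """Assign each site a consecutive integer block id (contig x block)."""
    ids = np.zeros(pos.size, dtype=np.int64)
    offset = 0
    for c in dict.fromkeys(chrom):
        sel = chrom == c
        b = pos[sel] // block_size
        # re-index blocks of this contig consecutively
        uniq, inv = np.unique(b, return_inverse=True)
        ids[sel] = offset + inv
        offset += uniq.size
    return ids


def weighted_block_jackknife(num_blocks: np.ndarray, den_blocks: np.ndarray,
                             weights: np.ndarray) -> tuple[float, float]:
    """Delete-one weighted block jackknife for a ratio estimator.

    ``num_blocks``/``den_blocks`` are per-block sums whose grand totals form
    the estimate theta = sum(num)/sum(den); ``weights`` are per-block
    weights (site counts). Returns (theta, SE) using the Busing et al.
    weighted jackknife variance. Blocks with zero weight are dropped
    (removing an empty block cannot change the estimate).
    """
    keep = weights > 0
    num_blocks, den_blocks, weights = (a[keep] for a in
                                       (num_blocks, den_blocks, weights))
    B = num_blocks.size
    tot_num, tot_den = num_blocks.sum(), den_blocks.sum()
    theta = tot_num / tot_den
    if B < 2:
        return float(theta), float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (tot_num - num_blocks) / (tot_den - den_blocks)
    if not np.isfinite(loo).all():  # a block carries all the signal
        return float(theta), float("nan")
    n = weights.sum()
    tau = n / weights
    theta_j = B * theta - ((1.0 - weights / n) * loo).sum()
    pseudo = tau * theta - (tau - 1.0) * loo
    var = float(np.sum((pseudo - theta_j) ** 2 / (tau - 1.0)) / B)
    return float(theta), float(np.sqrt(var))


def genome_wide_d(sums: SitePatternSums,
                  block_size: int = 1_000_000) -> DStatResult:
    """Genome-wide D with delete-one weighted block-jackknife significance.

    D = (sum abba - sum baba)/(sum abba + sum baba); SE over genomic blocks
    of ``block_size`` bp weighted by usable-site counts; Z = D/SE.
    """
    if sums.n_sites == 0:
        raise ValueError("no usable sites")
    ids = _block_ids(sums.chrom, sums.pos, block_size)
    nb = int(ids.max()) + 1
    num = np.bincount(ids, sums.abba - sums.baba, minlength=nb)
    den = np.bincount(ids, sums.abba + sums.baba, minlength=nb)
    w = np.bincount(ids, minlength=nb).astype(np.float64)
    d, se = weighted_block_jackknife(num, den, w)
    z = d / se if se and np.isfinite(se) and se > 0 else float("nan")
    return DStatResult(d, se, z, int((w > 0).sum()), sums.n_sites,
                       sums.taxa, name="D")


def f3_statistic(freqs: FrequencyTable, target: str, source_a: str,
                 source_b: str, block_size: int = 1_000_000) -> DStatResult:
    """Three-population f3(target; A, B) with block-jackknife significance.

    Per site: (pC-pA)(pC-pB) - pC(1-pC)/(nC-1), averaged over usable
    sites; the correction removes the sampling-noise bias of the target's
    frequency estimate. Significantly negative f3 (Z < -3) indicates the
    target is admixed between populations related to the two sources.
    """
    pc, pa, pb = (freqs.freq(t) for t in (target, source_a, source_b))
    nc = freqs.n(target).astype(np.float64)
    ok = (freqs.usable & (freqs.n(source_a) > 0) & (freqs.n(source_b) > 0)
          & (nc > 1))
    if not ok.any():
        raise ValueError("no usable sites with >= 2 target alleles")
    sel = np.flatnonzero(ok)
    term = ((pc - pa) * (pc - pb) - pc * (1 - pc) / (nc - 1.0))[sel]
    ids = _block_ids(freqs.chrom[sel], freqs.pos[sel], block_size)
    nb = int(ids.max()) + 1
    num = np.bincount(ids, term, minlength=nb)
    w = np.bincount(ids, minlength=nb).astype(np.float64)
    f3, se = weighted_block_jackknife(num, w.copy(), w)
    z = f3 / se if se and np.isfinite(se) and se > 0 else float("nan")
    return DStatResult(f3, se, z, int((w > 0).sum()), sel.size,
                       (target, source_a, source_b), name="f3")


def fdr_bh(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: q-values and discovery flags at alpha."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def window_fd_scan(freqs: FrequencyTable, grid: WindowGrid,
                   taxa: tuple[str, str, str, str], min_sites: int = 10,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Windowed D and fd scan for the quartet (P1, P2, P3, O).

    Per window: D from the window's ABBA/BABA sums; fd = numerator /
    donor-maximized numerator. fd is left undefined (NaN) when the window
    has D <= 0, a non-positive denominator, or fewer than ``min_sites``
    informative sites (abba + baba > 0). Defined fd values are
    Z-standardized genome-wide, converted to one-sided upper-tail normal
    p-values, and BH-adjusted; ``significant`` flags q < alpha with D > 0.
    """
    sums = site_patterns(freqs, taxa)
    stack = np.vstack([sums.abba, sums.baba, sums.abba_donor,
                       sums.baba_donor,
                       (sums.abba + sums.baba > 0).astype(np.float64)])
    w = window_sums(grid, sums.chrom, sums.pos, stack)
    abba, baba, abba_d, baba_d, n_inf = w
    with np.errstate(invalid="ignore", divide="ignore"):
        d_win = np.where(abba + baba > 0, (abba - baba) / (abba + baba), np.nan)
        denom = abba_d - baba_d
        fd = (abba - baba) / denom
    defined = ((d_win > 0) & (denom > 0) & (n_inf >= min_sites)
               & ~grid.partial)
    fd = np.where(defined, fd, np.nan)
    out = pd.DataFrame({
        "chrom": grid.chrom, "start": grid.start, "end": grid.end,
        "D": d_win, "fd": fd, "n_sites": n_inf.astype(int),
    })
    z = np.full(grid.n_windows, np.nan)
    p = np.full(grid.n_windows, np.nan)
    q = np.full(grid.n_windows, np.nan)
    sig = np.zeros(grid.n_windows, dtype=bool)
    if defined.any():
        vals = fd[defined]
        sd = vals.std(ddof=1) if vals.size > 1 else np.nan
        if np.isfinite(sd) and sd > 0:
            z[defined] = (vals - vals.mean()) / sd
            p[defined] = norm.sf(z[defined])
            q[defined], sig_d = fdr_bh(p[defined], alpha)
            sig[np.flatnonzero(defined)] = sig_d
    out["Z"], out["p"], out["q"], out["significant"] = z, p, q, sig
    return out


def merge_intervals(chrom: np.ndarray, start: np.ndarray,
                    end: np.ndarray) -> list[tuple[str, int, int, list[int]]]:
    """Union of half-open intervals; merges overlapping or book-ended ones.

    Returns (chrom, start, end, member_indices) sorted by coordinate, with
    member indices referring to the input order.
    """
    order = np.lexsort((start, np.asarray(chrom, dtype=object)))
    merged: list[tuple[str, int, int, list[int]]] = []
    for i in order:
        c, s, e = chrom[i], int(start[i]), int(end[i])
        if merged and merged[-1][0] == c and s <= merged[-1][2]:
            pc, ps, pe, members = merged.pop()
            merged.append((pc, ps, max(pe, e), members + [int(i)]))
        else:
            merged.append((c, s, e, [int(i)]))
    return merged


def call_introgressed_tracts(scan: pd.DataFrame, alpha: float = 0.05,
                             donor: str | None = None,
                             recipient: str | None = None) -> pd.DataFrame:
    """Merge significant fd windows (D > 0, q < alpha) into tracts.

    Adjacent means overlapping or book-ended on the same contig, which on
    a sliding grid merges consecutive significant steps. Returns a
    BED-like frame with member window count, mean/max fd and the total
    introgressed bp; disjoint and coordinate-sorted by construction.
    """
    sig = scan[(scan["D"] > 0) & (scan["q"] < alpha)].reset_index(drop=True)
    cols = ["chrom", "start", "end", "n_windows", "mean_fd", "max_fd",
            "donor", "recipient"]
    if sig.empty:
        return pd.DataFrame(columns=cols)
    merged = merge_intervals(sig["chrom"].to_numpy(), sig["start"].to_numpy(),
                             sig["end"].to_numpy())
    rows = []
    for c, s, e, members in merged:
        fd = sig.loc[members, "fd"]
        rows.append((c, s, e, len(members), fd.mean(), fd.max(),
                     donor, recipient))
    return pd.DataFrame(rows, columns=cols)
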