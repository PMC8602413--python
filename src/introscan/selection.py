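"""Domestication-selection scan: joint top-decile pi-ratio x FST outliers.

A window is a selection candidate when the diversity ratio of a wild over
a domestic cohort (pi_w / pi_d) and the Hudson FST between the cohorts
both fall at or above their empirical upper quantile (default the 90th
percentile, i.e. the overlap of the top 10% outliers of each statistic).
Candidate windows are merged into regions and intersected with a gene
annotation; overlap enrichment between gene lists is assessed with a
hypergeometric / Fisher exact test.

Both cohorts are pooled across their member populations; rank-based
thresholding makes the selected set invariant to monotone rescaling of
either statistic. Windows where either statistic is undefined (or that are
partial end-of-contig windows) are excluded from quantile estimation and
from selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .abba_baba import merge_intervals
from .genotype_io import FrequencyTable, WindowGrid
from .popgen import window_fst, window_pi

__all__ = ["selection_scan", "merge_selection_regions", "annotate_regions",
           "read_bed", "gene_overlap_test"]


def selection_scan(freqs: FrequencyTable, grid: WindowGrid,
                   wild, domestic, quantile: float = 0.9,
                   pi_ratio_threshold: float | None = None,
                   fst_threshold: float | None = None) -> pd.DataFrame:
    """Per-window pi_w, pi_d, pi_w/pi_d and FST with joint-decile selection.

    ``wild`` and ``domestic`` are population labels or label lists (pooled).
    Thresholds default to the empirical ``quantile`` of each statistic over
    defined, non-partial windows; fixed thresholds may be supplied instead
    (e.g. a published cutoff). Ties at the threshold are selected (>=).
    """
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must be in [0, 1]")
    pi_w = window_pi(freqs, grid, wild)
    pi_d = window_pi(freqs, grid, domestic)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(pi_d > 0, pi_w / pi_d, np.nan)
    fst = window_fst(freqs, grid, wild, domestic)
    defined = ~np.isnan(ratio) & ~np.isnan(fst) & ~grid.partial
    ratio_cut = (pi_ratio_threshold if pi_ratio_threshold is not None
                 else np.quantile(ratio[defined], quantile) if defined.any()
                 else np.nan)
    fst_cut = (fst_threshold if fst_threshold is not None
               else np.quantile(fst[defined], quantile) if defined.any()
               else np.nan)
    top_ratio = defined & (ratio >= ratio_cut)
    top_fst = defined & (fst >= fst_cut)
    out = pd.DataFrame({
        "chrom": grid.chrom, "start": grid.start, "end": grid.end,
        "pi_wild": pi_w, "pi_domestic": pi_d, "pi_ratio": ratio, "fst": fst,
        "top_pi_ratio": top_ratio, "top_fst": top_fst,
        "selected": top_ratio & top_fst,
    })
    out.attrs["pi_ratio_threshold"] = float(ratio_cut)
    out.attrs["fst_threshold"] = float(fst_cut)
    return out


def merge_selection_regions(records: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/book-ended selected windows into disjoint regions.

    The summed member-window counts equal the number of selected windows.
    """
    sel = records[records["selected"]].reset_index(drop=True)
    cols = ["chrom", "start", "end", "n_windows"]
    if sel.empty:
        return pd.DataFrame(columns=cols)
    merged = merge_intervals(sel["chrom"].to_numpy(), sel["start"].to_numpy(),
                             sel["end"].to_numpy())
    return pd.DataFrame([(c, s, e, len(m)) for c, s, e, m in merged],
                        columns=cols)


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED4+ file (0-based half-open; name in column 4)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"malformed BED (need >= 3 columns): {path}")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(name=".")
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if "name" not in df:
        df["name"] = "."
    if not (df["end"] > df["start"]).all():
        raise ValueError(f"malformed BED intervals in {path}")
    return df


def annotate_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach the genes whose half-open interval intersects each region."""
    out = regions.copy()
    lists = []
    for _, r in regions.iterrows():
        hit = genes[(genes["chrom"] == r["chrom"])
                    & (genes["start"] < r["end"])
                    & (genes["end"] > r["start"])]
        lists.append(sorted(dict.fromkeys(hit["name"])))
    out["genes"] = lists
    return out


def gene_overlap_test(universe: int, n_list_a: int, n_list_b: int,
                      n_overlap: int) -> float:
    """Two-sided Fisher exact p for the overlap of two gene lists drawn
    from a universe of ``universe`` genes (hypergeometric 2x2 table)."""
    if n_overlap > min(n_list_a, n_list_b) or max(n_list_a, n_list_b) > universe:
        raise ValueError("inconsistent overlap counts")
    rv = hypergeom(universe, n_list_a, n_list_b)
    # two-sided by summation of outcomes no more probable than observed
    k = np.arange(max(0, n_list_a + n_list_b - universe),
                  min(n_list_a, n_list_b) + 1)
    pmf = rv.pmf(k)
    return float(pmf[pmf <= rv.pmf(n_overlap) * (1 + 1e-12)].sum())
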