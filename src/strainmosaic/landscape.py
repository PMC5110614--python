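"""Variant-density landscape and ancestry-composition summaries.

Sliding-window variant counts (default 500 kb windows, 100 kb step;
every variant is counted in each overlapping window), QTL vs non-QTL
density comparison (window assignment by midpoint, rank-based test),
and per-chromosome ancestry composition of decoded haploblocks with the
equal-representation chance baseline.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import mannwhitneyu

__all__ = ["window_density", "qtl_density_split", "ancestry_composition",
           "chance_baseline", "plot_density_histogram"]

log = logging.getLogger(__name__)


def window_density(positions, chrom_length: int, window_size: int = 500_000,
                   step: int = 100_000, chrom: str = "chr1") -> pd.DataFrame:
    """Sliding-window variant counts and densities (variants/kb).

    Windows start every ``step`` bp from 0; the terminal windows are
    truncated at the chromosome end and keep their true length in the
    density denominator. Overlapping windows each count every variant
    they contain.
    """
    if step > window_size:
        log.warning("step %d > window size %d leaves gaps between windows",
                    step, window_size)
    pos = np.sort(np.asarray(positions))
    starts = np.arange(0, max(chrom_length, 1), step)
    ends = np.minimum(starts + window_size, chrom_length)
    counts = np.searchsorted(pos, ends, side="left") - \
        np.searchsorted(pos, starts, side="left")
    lengths = np.maximum(ends - starts, 1)
    return pd.DataFrame({
        "chrom": chrom,
        "start": starts,
        "end": ends,
        "count": counts,
        "density": counts / (lengths / 1000.0),
    })


def qtl_density_split(track: pd.DataFrame, qtl_intervals,
                      assignment: str = "midpoint") -> dict:
    """Partition window densities by QTL overlap and compare the groups.

    With ``assignment="midpoint"`` a window belongs to the QTL partition
    when its midpoint falls inside a QTL interval; with ``"contained"``
    only windows fully inside (QTL) or fully outside (non-QTL) an
    interval are kept — boundary-straddling windows, whose density mixes
    both regimes, are excluded, giving an unbiased enrichment estimate.
    Reports group means, medians, the mean ratio (QTL/non-QTL) and a
    Mann-Whitney rank test.
    """
    tree = IntervalTree()
    for s, e in qtl_intervals:
        if e > s:
            tree.addi(s, e)
    starts = track["start"].to_numpy()
    ends = track["end"].to_numpy()
    if assignment == "midpoint":
        mid = (starts + ends) // 2
        in_qtl = np.array([bool(tree.overlap(m, m + 1)) for m in mid])
        keep = np.ones_like(in_qtl, dtype=bool)
    elif assignment == "contained":
        in_qtl = np.array([any(iv.begin <= s and e <= iv.end
                               for iv in tree.overlap(s, e))
                           for s, e in zip(starts, ends)])
        touches = np.array([bool(tree.overlap(s, e))
                            for s, e in zip(starts, ends)])
        keep = in_qtl | ~touches
    else:
        raise ValueError(f"unknown assignment {assignment!r}")

    dens = track["density"].to_numpy()
    qd, nd = dens[in_qtl & keep], dens[~in_qtl & keep]
    out = {
        "qtl_densities": qd,
        "nonqtl_densities": nd,
        "n_qtl_windows": int(in_qtl.sum()),
        "n_nonqtl_windows": int((~in_qtl).sum()),
        "mean_qtl": float(qd.mean()) if qd.size else float("nan"),
        "mean_nonqtl": float(nd.mean()) if nd.size else float("nan"),
        "median_qtl": float(np.median(qd)) if qd.size else float("nan"),
        "median_nonqtl": float(np.median(nd)) if nd.size else float("nan"),
    }
    out["mean_ratio"] = (out["mean_qtl"] / out["mean_nonqtl"]
                         if nd.size and out["mean_nonqtl"] > 0 else float("nan"))
    if qd.size and nd.size:
        stat, p = mannwhitneyu(qd, nd, alternative="two-sided")
        out["mannwhitney_u"], out["mannwhitney_p"] = float(stat), float(p)
    else:
        out["mannwhitney_u"] = out["mannwhitney_p"] = float("nan")
    return out


def chance_baseline(group_size: int, n_founders: int = 8) -> float:
    """Genome fraction a founder group would contribute by chance when
    all founders are equally represented."""
    if not 0 < group_size <= n_founders:
        raise ValueError("group size must be in (0, n_founders]")
    return group_size / n_founders


def ancestry_composition(haploblocks, chrom_lengths: dict | None = None) -> pd.DataFrame:
    """bp-weighted fraction of each ancestry label per chromosome and
    genome-wide (row ``"genome"``); fractions sum to 1 per row."""
    by_chrom: dict = {}
    last_end: dict = {}
    for blk in sorted(haploblocks, key=lambda b: (b.chrom, b.start)):
        if blk.chrom in last_end and blk.start < last_end[blk.chrom]:
            raise ValueError(
                f"overlapping haploblocks on {blk.chrom} at {blk.start}")
        last_end[blk.chrom] = blk.end
        by_chrom.setdefault(blk.chrom, {})
        lab = blk.label_str
        by_chrom[blk.chrom][lab] = by_chrom[blk.chrom].get(lab, 0) + blk.length

    rows = {}
    genome: dict = {}
    for chrom, labels in by_chrom.items():
        total = chrom_lengths.get(chrom) if chrom_lengths else sum(labels.values())
        rows[chrom] = {lab: ln / total for lab, ln in labels.items()}
        for lab, ln in labels.items():
            genome[lab] = genome.get(lab, 0) + ln
    gtotal = sum(genome.values())
    if gtotal:
        rows["genome"] = {lab: ln / gtotal for lab, ln in genome.items()}
    return pd.DataFrame(rows).T.fillna(0.0)


def plot_density_histogram(split: dict, ax=None, bins: int = 30):
    """Histogram of window densities, QTL vs non-QTL partitions."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(split["nonqtl_densities"], bins=bins, alpha=0.6, density=True,
            label="non-QTL", color="red")
    ax.hist(split["qtl_densities"], bins=bins, alpha=0.6, density=True,
            label="QTL", color="blue")
    ax.set_xlabel("variants / kb")
    ax.set_ylabel("window frequency")
    ax.legend()
    return ax
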