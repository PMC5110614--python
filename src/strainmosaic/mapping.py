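"""Reference-bias impact of the mapping genome on RNA-seq results.

Mapping RNA-seq reads to a strain-specific (variant-applied) genome
instead of the reference changes the fate of a small fraction of reads,
which can flip differential-expression (DE) calls. This module
quantifies both effects:

* a per-read fate taxonomy comparing placements under the two genomes
  (locus equivalence judged through the strain->reference liftover);
* a DE-set comparison at the adjusted-p <= alpha rule (default 0.1),
  with *lost* / *gained* / *common* classes, a *borderline* flag for
  genes whose significance flips while the adjusted p stays within a
  factor of the cutoff, read-count direction, and a pseudogene flag
  (pseudogenes are notorious sources of reference-mapping artifacts).

DE p-values are inputs from any count-based test; no DE model is fitted
here.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

__all__ = ["classify_read_fates", "compare_de_sets", "READ_FATES"]

READ_FATES = (
    "unique_both_same_locus", "unique_both_moved", "gained_unique",
    "lost_unique", "multi_both", "unmapped_both", "mixed",
)


def _fate(ref_row, strain_row, inv_by_chrom, tol):
    ref_status = ref_row["status"] if ref_row is not None else "unmapped"
    strain_status = strain_row["status"] if strain_row is not None else "unmapped"

    if ref_status == "unique" and strain_status == "unique":
        chrom = strain_row["chrom"]
        table = inv_by_chrom.get(chrom)
        lifted = table.lift(int(strain_row["pos"]), side="left") \
            if table is not None else int(strain_row["pos"])
        same = (chrom == ref_row["chrom"] and lifted is not None
                and abs(lifted - int(ref_row["pos"])) <= tol)
        return "unique_both_same_locus" if same else "unique_both_moved"
    if strain_status == "unique":
        return "gained_unique"
    if ref_status == "unique":
        return "lost_unique"
    if ref_status == "multi" and strain_status == "multi":
        return "multi_both"
    if ref_status == "unmapped" and strain_status == "unmapped":
        return "unmapped_both"
    return "mixed"


def classify_read_fates(placements_ref: pd.DataFrame,
                        placements_strain: pd.DataFrame,
                        liftover_by_chrom: dict | None = None,
                        tol: int = 0):
    """Per-read mapping-fate table and summary fractions.

    Placement frames carry ``read_id``, ``status`` (unique / multi /
    unmapped) and, for unique reads, ``chrom`` and ``pos`` (0-based, in
    that genome's coordinates). Reads absent from a frame count as
    unmapped there. Two unique placements are the same locus when the
    strain position lifted back to reference coordinates agrees within
    ``tol`` bp. Returns ``(fates DataFrame, summary fractions dict)``.
    """
    liftover_by_chrom = liftover_by_chrom or {}
    ref = placements_ref.set_index("read_id")
    strain = placements_strain.set_index("read_id")
    inv = {c: t.invert() for c, t in liftover_by_chrom.items()}

    all_reads = sorted(set(ref.index) | set(strain.index))
    records = []
    for rid in all_reads:
        r = ref.loc[rid] if rid in ref.index else None
        s = strain.loc[rid] if rid in strain.index else None
        records.append((rid, _fate(r, s, inv, tol)))
    fates = pd.DataFrame(records, columns=["read_id", "fate"])

    counts = Counter(fates["fate"])
    n = len(fates)
    summary = {f: counts.get(f, 0) / n if n else 0.0 for f in READ_FATES}
    return fates, summary


def compare_de_sets(results_ref: pd.DataFrame, results_strain: pd.DataFrame,
                    counts_ref: pd.DataFrame | None = None,
                    counts_strain: pd.DataFrame | None = None,
                    alpha: float = 0.1, borderline_factor: float = 2.0,
                    biotypes: pd.DataFrame | None = None):
    """Compare DE results between reference and strain-genome mappings.

    Result frames carry ``gene`` and ``p_adj``; optional count frames
    carry ``gene`` and ``count`` (summed mapped reads); optional
    ``biotypes`` carries ``gene`` and ``biotype``. A gene is significant
    at adjusted p <= ``alpha``. Classes: *common* (significant under
    both mappings), *lost* (reference only), *gained* (strain only),
    *neither*. A lost/gained gene is *borderline* when its
    non-significant adjusted p is within ``alpha * borderline_factor``.
    Genes present in only one result set are excluded from the Venn
    partition and reported separately.

    Returns ``(comparison DataFrame, venn counts dict)``.
    """
    merged = results_ref.rename(columns={"p_adj": "p_adj_ref"}).merge(
        results_strain.rename(columns={"p_adj": "p_adj_strain"}),
        on="gene", how="outer", validate="one_to_one")
    missing = merged[merged[["p_adj_ref", "p_adj_strain"]].isna().any(axis=1)]
    both = merged.dropna(subset=["p_adj_ref", "p_adj_strain"]).copy()

    sig_ref = both["p_adj_ref"] <= alpha
    sig_strain = both["p_adj_strain"] <= alpha
    both["de_status"] = np.select(
        [sig_ref & sig_strain, sig_ref & ~sig_strain, ~sig_ref & sig_strain],
        ["common", "lost", "gained"], default="neither")

    nonsig_p = np.where(sig_ref, both["p_adj_strain"], both["p_adj_ref"])
    both["borderline"] = (sig_ref ^ sig_strain) & \
        (nonsig_p <= alpha * borderline_factor)

    if counts_ref is not None and counts_strain is not None:
        cnt = counts_ref.rename(columns={"count": "count_ref"}).merge(
            counts_strain.rename(columns={"count": "count_strain"}),
            on="gene", how="outer")
        both = both.merge(cnt, on="gene", how="left")
        both["count_change"] = np.select(
            [both["count_strain"] > both["count_ref"],
             both["count_strain"] < both["count_ref"]],
            ["increased", "decreased"], default="unchanged")
    else:
        both["count_change"] = "unchanged"

    if biotypes is not None:
        both = both.merge(biotypes, on="gene", how="left")
        both["pseudogene"] = both["biotype"].fillna("").str.contains("pseudogene")
    else:
        both["pseudogene"] = False

    venn = {k: int((both["de_status"] == k).sum())
            for k in ("common", "lost", "gained", "neither")}
    venn["tested_both"] = len(both)
    venn["missing"] = len(missing)
    return both, venn
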