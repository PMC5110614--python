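"""Rule-based variant classification for a pair of inbred strains.

Each biallelic site carries read depth and alt-supporting read counts in
both strains. A strain's call is retained only when it has depth >= 5
with >= 90% of reads supporting the variant allele and lies more than
5 bp from a repeat element; sites failing these are rejected with the
reason recorded. Retained calls are classified as *common* (both strains
carry the same alt, both passing filters) or *strain-distinct*; a
candidate strain-distinct call is demoted when the other strain's raw,
unfiltered call shows >= 3 reads with >= 50% carrying the same alt —
ambiguous evidence that the variant may not distinguish the strains.

Coding effects follow the standard taxonomy: SNPs are translated through
the affected codon (synonymous / non-synonymous / premature stop) and
CDS indels are frameshifts whenever the length change is not divisible
by three, otherwise in-frame insertions or deletions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .config import Thresholds

__all__ = [
    "VariantSite", "ClassifiedVariant", "GeneModel",
    "FilterDecision", "DataError", "AnnotationError",
    "filter_site", "classify_site", "classify_sites",
    "annotate_coding_effect", "summarize_classes", "summary_table",
]

MAX_INDEL_LEN = 50  # events this large or larger belong to SV handling

CLASSES = (
    "common", "distinct_strainA", "distinct_strainB", "demoted",
    "filtered_depth", "filtered_het", "filtered_repeat",
)

CODING_EFFECTS = (
    "none", "synonymous", "nonsynonymous", "stop",
    "inframe_insertion", "inframe_deletion", "frameshift",
)


class DataError(ValueError):
    """Inconsistent per-site read evidence."""


class AnnotationError(ValueError):
    """Gene model unusable for coding-effect annotation."""


@dataclass
class VariantSite:
    """One biallelic site with per-strain read evidence.

    ``pos`` is 1-based (VCF convention); ``repeat_distance`` is the bp
    distance from the variant span to the nearest repeat element
    (``math.inf`` when no repeat is annotated), 0 when overlapping.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: dict            # strain -> total reads
    alt_support: dict      # strain -> reads supporting alt
    repeat_distance: float = math.inf
    in_catalog: bool = False

    def __post_init__(self):
        for strain, d in self.depth.items():
            a = self.alt_support.get(strain, 0)
            if not 0 <= a <= d and d > 0:
                raise DataError(
                    f"{self.chrom}:{self.pos} strain {strain}: alt support {a} "
                    f"outside [0, depth={d}]")
            if d == 0 and a > 0:
                raise DataError(
                    f"{self.chrom}:{self.pos} strain {strain}: zero depth with "
                    f"{a} supporting reads")
        if self.is_indel and abs(len(self.ref) - len(self.alt)) >= MAX_INDEL_LEN:
            raise DataError(
                f"{self.chrom}:{self.pos}: indel of {abs(len(self.ref) - len(self.alt))} bp "
                f"exceeds small-variant limit ({MAX_INDEL_LEN} bp)")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def alt_fraction(self, strain: str) -> float:
        d = self.depth.get(strain, 0)
        return self.alt_support.get(strain, 0) / d if d > 0 else 0.0

    def calls_alt(self, strain: str) -> bool:
        """Whether this strain's raw call asserts the alt allele."""
        return self.alt_support.get(strain, 0) >= 1 and self.alt_fraction(strain) >= 0.5


@dataclass
class FilterDecision:
    retained: bool
    reason: str | None = None  # a filtered_* class when rejected


@dataclass
class ClassifiedVariant:
    site: VariantSite
    vclass: str
    coding_effect: str = "none"
    genes: tuple = ()

    def __post_init__(self):
        if self.vclass not in CLASSES:
            raise ValueError(f"unknown class {self.vclass!r}")


@dataclass
class GeneModel:
    """Minimal gene model: strand-aware CDS intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    cds: list = field(default_factory=list)  # sorted (start, end) genomic intervals
    biotype: str = "protein_coding"

    @property
    def start(self) -> int:
        return min(s for s, _ in self.cds)

    @property
    def end(self) -> int:
        return max(e for _, e in self.cds)

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


def filter_site(site: VariantSite, strain: str,
                params: Thresholds | None = None) -> FilterDecision:
    """Depth, allele-support and repeat-proximity filters for one strain's call."""
    params = params or Thresholds()
    if site.depth.get(strain, 0) < params.min_depth:
        return FilterDecision(False, "filtered_depth")
    if site.alt_fraction(strain) < params.min_support:
        return FilterDecision(False, "filtered_het")
    if site.repeat_distance <= params.repeat_margin:
        return FilterDecision(False, "filtered_repeat")
    return FilterDecision(True)


def classify_site(site: VariantSite, strains: tuple[str, str] | None = None,
                  params: Thresholds | None = None) -> ClassifiedVariant:
    """Assign exactly one class to a site.

    The site object carries both strains' evidence, including the raw
    (unfiltered) counts of the non-asserting strain used by the
    cross-check demotion rule.
    """
    params = params or Thresholds()
    if strains is None:
        strains = tuple(site.depth.keys())
    a, b = strains

    decisions = {}
    for s in strains:
        if site.calls_alt(s):
            decisions[s] = filter_site(site, s, params)
        else:
            decisions[s] = FilterDecision(False, None)  # no call, nothing to filter

    retained = [s for s in strains if decisions[s].retained]

    if len(retained) == 2:
        return ClassifiedVariant(site, "common")

    if len(retained) == 1:
        asserting = retained[0]
        other = b if asserting == a else a
        if (site.depth.get(other, 0) >= params.cross_min_depth
                and site.alt_fraction(other) >= params.cross_min_support):
            return ClassifiedVariant(site, "demoted")
        which = "distinct_strainA" if asserting == a else "distinct_strainB"
        return ClassifiedVariant(site, which)

    # no strain retained: report the failure reason of the strain with the
    # strongest alt evidence (ties go to the first strain)
    best = max(strains, key=lambda s: (site.alt_fraction(s), s == a))
    reason = decisions[best].reason
    if reason is None:
        # neither strain asserts the alt at >=50%: heterozygous-looking noise
        reason = "filtered_het"
    return ClassifiedVariant(site, reason)


def classify_sites(sites, strains=None, params=None,
                   gene_models=None, ref_seqs=None) -> list[ClassifiedVariant]:
    """Classify a list of sites, optionally annotating coding effects."""
    out = []
    for site in sites:
        cv = classify_site(site, strains, params)
        if gene_models is not None and cv.vclass in (
                "common", "distinct_strainA", "distinct_strainB"):
            try:
                cv.coding_effect, cv.genes = annotate_coding_effect(
                    site, gene_models, ref_seqs)
            except AnnotationError:
                cv.coding_effect, cv.genes = "none", ()
        out.append(cv)
    return out


def _codon_effect(site: VariantSite, gene: GeneModel, ref_seqs: dict) -> str:
    """Translate the affected codon before/after a SNP (strand-aware)."""
    if gene.cds_length() % 3 != 0:
        raise AnnotationError(
            f"gene {gene.gene_id}: CDS length {gene.cds_length()} not divisible by 3")
    seq = ref_seqs[site.chrom]
    pos0 = site.pos - 1
    cds_seq = []
    cds_index = None
    offset = 0
    for s, e in sorted(gene.cds):
        cds_seq.append(seq[s:e])
        if s <= pos0 < e:
            cds_index = offset + (pos0 - s)
        offset += e - s
    if cds_index is None:
        return "none"
    cds = "".join(cds_seq)
    if cds[cds_index].upper() != site.ref.upper():
        raise AnnotationError(
            f"{site.chrom}:{site.pos}: reference base {cds[cds_index]!r} does not "
            f"match variant ref allele {site.ref!r}")
    mut = cds[:cds_index] + site.alt + cds[cds_index + 1:]
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
        mut = str(Seq(mut).reverse_complement())
        cds_index = len(cds) - 1 - cds_index
    codon_i = cds_index // 3
    old = str(Seq(cds[3 * codon_i:3 * codon_i + 3]).translate())
    new = str(Seq(mut[3 * codon_i:3 * codon_i + 3]).translate())
    if new == old:
        return "synonymous"
    if new == "*":
        return "stop"
    return "nonsynonymous"


def annotate_coding_effect(site: VariantSite, gene_models,
                           ref_seqs: dict | None = None) -> tuple[str, tuple]:
    """Coding effect of a variant against a set of gene models.

    Returns ``(effect, gene_ids)``; ``effect`` is ``"none"`` outside any
    CDS. For a variant hitting several genes the most severe effect is
    reported (stop/frameshift > nonsynonymous/in-frame > synonymous).
    """
    pos0 = site.pos - 1
    span_end = pos0 + max(len(site.ref), 1)
    severity = {"none": 0, "synonymous": 1, "inframe_insertion": 2,
                "inframe_deletion": 2, "nonsynonymous": 3, "frameshift": 4,
                "stop": 5}
    best, hit_genes = "none", []
    for gene in gene_models:
        if gene.chrom != site.chrom:
            continue
        in_cds = any(s < span_end and pos0 < e for s, e in gene.cds)
        if not in_cds:
            continue
        hit_genes.append(gene.gene_id)
        if site.is_indel:
            delta = abs(len(site.ref) - len(site.alt))
            if delta % 3 != 0:
                effect = "frameshift"
            elif len(site.alt) > len(site.ref):
                effect = "inframe_insertion"
            else:
                effect = "inframe_deletion"
        else:
            if ref_seqs is None:
                raise AnnotationError("reference sequences required for SNP effects")
            effect = _codon_effect(site, gene, ref_seqs)
        if severity[effect] > severity[best]:
            best = effect
    return best, tuple(hit_genes)


def summarize_classes(classified) -> dict:
    """Per-class counts; always a full partition of the input."""
    classified = list(classified)
    counts = Counter(cv.vclass for cv in classified)
    summary = {c: counts.get(c, 0) for c in CLASSES}
    summary["total"] = len(classified)
    return summary


def summary_table(classified) -> pd.DataFrame:
    """Per-strain-class variant-type breakdown (rows mirror a variant
    summary table: totals, SNP/indel split, coding categories, catalog
    membership)."""
    cols = {"distinct_strainA": [], "distinct_strainB": [], "common": []}
    for cv in classified:
        if cv.vclass in cols:
            cols[cv.vclass].append(cv)

    def tally(items):
        snps = [c for c in items if not c.site.is_indel]
        dels = [c for c in items
                if len(c.site.ref) > len(c.site.alt)]
        ins = [c for c in items
               if len(c.site.ref) < len(c.site.alt)]
        eff = Counter(c.coding_effect for c in items)
        in_cat = sum(c.site.in_catalog for c in items)
        return {
            "total": len(items),
            "snps": len(snps),
            "deletions": len(dels),
            "insertions": len(ins),
            "coding_total": sum(v for k, v in eff.items() if k != "none"),
            "synonymous": eff.get("synonymous", 0),
            "nonsynonymous": eff.get("nonsynonymous", 0),
            "inframe_deletion": eff.get("inframe_deletion", 0),
            "inframe_insertion": eff.get("inframe_insertion", 0),
            "frameshift": eff.get("frameshift", 0),
            "stop": eff.get("stop", 0),
            "in_catalog": in_cat,
            "private": len(items) - in_cat,
        }

    return pd.DataFrame({k: tally(v) for k, v in cols.items()})
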