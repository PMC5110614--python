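"""Strain-specific genome construction with coordinate liftover.

Applies a high-confidence variant set (SNPs and small indels) to a
reference sequence, producing the strain sequence together with an
invertible coordinate map, and shifts gene annotation through that map.
SNPs substitute in place; indels shift all downstream coordinates.
Variants follow the VCF convention: 1-based, left-aligned, with the
anchor base shared between ref and alt alleles for indels.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass

__all__ = ["LiftoverTable", "LiftoverError", "apply_variants", "lift_annotation"]

log = logging.getLogger(__name__)


class LiftoverError(ValueError):
    """Variant set inconsistent with the reference."""


@dataclass(frozen=True)
class Segment:
    """Matched block: equal-length, colinear in both coordinate systems."""

    ref_start: int
    ref_end: int
    strain_start: int
    strain_end: int

    @property
    def offset(self) -> int:
        return self.strain_start - self.ref_start


class LiftoverTable:
    """Monotone map between reference and strain coordinates.

    Built from ordered, non-overlapping matched segments. Positions
    inside deleted reference spans (or inserted strain spans) have no
    exact image; ``side`` selects the behaviour there: ``"strict"``
    returns ``None``, ``"left"``/``"right"`` snap to the nearest mapped
    coordinate's image on that side.
    """

    def __init__(self, segments):
        self.segments = list(segments)
        prev = None
        for seg in self.segments:
            if seg.ref_end - seg.ref_start != seg.strain_end - seg.strain_start:
                raise LiftoverError("segment lengths differ between coordinates")
            if prev is not None and (seg.ref_start < prev.ref_end
                                     or seg.strain_start < prev.strain_end):
                raise LiftoverError("segments overlap or are unordered")
            prev = seg
        self._ref_starts = [s.ref_start for s in self.segments]

    def lift(self, ref_pos: int, side: str = "strict"):
        """Map a 0-based reference position to the strain coordinate."""
        i = bisect.bisect_right(self._ref_starts, ref_pos) - 1
        if i >= 0:
            seg = self.segments[i]
            if ref_pos < seg.ref_end:
                return ref_pos + seg.offset
        if side == "strict":
            return None
        if side == "left":
            # image of the last mapped reference base at or before ref_pos
            if i < 0:
                return None
            return self.segments[i].strain_end - 1
        if side == "right":
            if i + 1 >= len(self.segments):
                return None
            return self.segments[i + 1].strain_start
        raise ValueError(f"unknown side {side!r}")

    def invert(self) -> "LiftoverTable":
        return LiftoverTable([
            Segment(s.strain_start, s.strain_end, s.ref_start, s.ref_end)
            for s in self.segments])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [(s.ref_start, s.ref_end, s.strain_start, s.strain_end, s.offset)
             for s in self.segments],
            columns=["ref_start", "ref_end", "strain_start", "strain_end",
                     "offset"])

    @classmethod
    def from_frame(cls, df) -> "LiftoverTable":
        return cls(Segment(int(r.ref_start), int(r.ref_end),
                           int(r.strain_start), int(r.strain_end))
                   for r in df.itertuples())


def _as_tuples(variants):
    """Accept (pos1, ref, alt) tuples or objects with .site/.pos/.ref/.alt."""
    out = []
    for v in variants:
        if isinstance(v, tuple):
            out.append(v)
        else:
            site = getattr(v, "site", v)
            out.append((site.pos, site.ref, site.alt))
    return sorted(out)


def apply_variants(reference: str, variants, allowed_classes=None):
    """Apply sorted, non-overlapping variants to a reference sequence.

    Returns ``(strain_sequence, LiftoverTable)``. Raises
    ``LiftoverError`` on overlapping variants (all offenders listed) or
    when a variant's ref allele does not match the reference sequence.
    ``allowed_classes`` restricts which classified variants are applied
    (others raise, since the caller should have selected them).
    """
    if allowed_classes is not None:
        bad = [v for v in variants
               if getattr(v, "vclass", None) not in allowed_classes]
        if bad:
            raise LiftoverError(
                f"{len(bad)} variants outside allowed classes {allowed_classes}")
    recs = _as_tuples(variants)

    overlaps = []
    prev_end = -1
    for pos1, ref, _alt in recs:
        start = pos1 - 1
        if start < prev_end:
            overlaps.append(f"{pos1}:{ref}")
        prev_end = max(prev_end, start + len(ref))
    if overlaps:
        raise LiftoverError(f"overlapping variants at {overlaps}")

    parts = []
    segments = []
    ref_cursor = 0      # next unconsumed reference base
    strain_cursor = 0
    seg_ref_start = 0   # start of the open matched segment

    def close_segment(ref_end):
        nonlocal seg_ref_start, strain_cursor
        if ref_end > seg_ref_start:
            length = ref_end - seg_ref_start
            segments.append(Segment(seg_ref_start, ref_end,
                                    strain_cursor, strain_cursor + length))
            strain_cursor += length

    for pos1, ref, alt in recs:
        start = pos1 - 1
        if reference[start:start + len(ref)].upper() != ref.upper():
            raise LiftoverError(
                f"ref allele {ref!r} at position {pos1} does not match "
                f"reference {reference[start:start + len(ref)]!r}")
        m = min(len(ref), len(alt))  # matched (anchor) prefix length
        parts.append(reference[ref_cursor:start])
        parts.append(alt)
        close_segment(start + m)     # unchanged run + anchor/SNP span map 1:1
        strain_cursor += len(alt) - m   # inserted strain-only bases
        seg_ref_start = start + len(ref)  # deleted ref bases have no image
        ref_cursor = start + len(ref)

    parts.append(reference[ref_cursor:])
    close_segment(len(reference))
    strain_seq = "".join(parts)

    delta = sum(len(a) - len(r) for _, r, a in recs)
    assert len(strain_seq) == len(reference) + delta
    return strain_seq, LiftoverTable(segments)


def lift_annotation(genes, table: LiftoverTable):
    """Map gene models through a liftover table.

    Features whose boundary falls inside a deleted span snap outward to
    the nearest retained coordinate and are flagged; features entirely
    deleted are dropped (logged). Returns
    ``(lifted_genes, flags, dropped_ids)`` where ``flags`` maps gene_id
    to True when any boundary was adjusted.
    """
    from .classify import GeneModel

    lifted, flags, dropped = [], {}, []
    for gene in genes:
        new_cds = []
        adjusted = False
        for s, e in gene.cds:
            ns = table.lift(s)
            if ns is None:
                ns = table.lift(s, side="right")
                adjusted = True
            ne_last = table.lift(e - 1)
            if ne_last is None:
                ne_last = table.lift(e - 1, side="left")
                adjusted = True
            if ns is None or ne_last is None or ns > ne_last:
                continue  # exon entirely within a deletion
            new_cds.append((ns, ne_last + 1))
        if not new_cds:
            dropped.append(gene.gene_id)
            log.info("feature %s entirely deleted in strain genome", gene.gene_id)
            continue
        lifted.append(GeneModel(gene.gene_id, gene.chrom, gene.strand,
                                new_cds, gene.biotype))
        flags[gene.gene_id] = adjusted
    return lifted, flags, dropped
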