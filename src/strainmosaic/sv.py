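"""Structural-variant merging and strain-specificity selection.

SV calls from two strain backgrounds are merged across redundant
(overlapping) calls, scored by the read support each event receives in
the *other* strain, and split into strain-unique vs shared events at
the score cutoff that keeps the estimated false discovery rate of
unique calls at or below a target.

The FDR is estimated from a shared-truth proxy: events independently
called in both strains' call sets are taken as known-shared, and the
estimate at cutoff ``c`` is the fraction of proxy-shared events among
all events called unique at ``c``. A running maximum over the cutoff
sweep makes the estimate monotone, so the largest admissible cutoff is
well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["SvEvent", "CutoffResult", "merge_redundant", "score_events",
           "select_cutoff", "sv_summary_table"]

log = logging.getLogger(__name__)

SV_TYPES = ("deletion", "insertion", "gain", "loss", "inversion", "translocation")


@dataclass
class SvEvent:
    """One structural variant with per-strain supporting-read counts."""

    chrom: str
    start: int                      # 0-based half-open
    end: int
    svtype: str
    support: dict                   # strain -> supporting reads
    source_strain: str | None = None
    chrom2: str | None = None       # translocation partner breakpoint
    pos2: int | None = None
    event_id: int | None = None
    sources: frozenset = field(default_factory=frozenset)
    score: float | None = None

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if not self.sources and self.source_strain is not None:
            self.sources = frozenset([self.source_strain])

    @property
    def span(self) -> int:
        return self.end - self.start


def _reciprocal_overlap(a: SvEvent, b: SvEvent) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.span, ov / b.span)


def _overlaps_any(ev: SvEvent, intervals) -> bool:
    return any(ev.start < e and s < ev.end for s, e in intervals)


def merge_redundant(calls, reciprocal: float = 0.5, breakpoint_tol: int = 600,
                    telomeres=None):
    """Merge redundant overlapping calls into single events.

    Same-type events with reciprocal overlap >= ``reciprocal`` merge to
    the union span with per-strain supports summed and source-strain
    sets united. Translocations are matched by both breakpoint pairs
    within ``breakpoint_tol`` bp instead of overlap fraction. Events
    overlapping telomeric intervals are excluded. Malformed records are
    reported and skipped.

    Returns ``(merged_events, errors)``.
    """
    telomeres = telomeres or []
    errors = []
    keep = []
    for ev in calls:
        if ev.svtype != "translocation" and ev.start >= ev.end:
            errors.append(f"{ev.chrom}:{ev.start}-{ev.end} {ev.svtype}: "
                          f"empty or inverted interval")
            continue
        if _overlaps_any(ev, telomeres):
            continue
        keep.append(ev)

    merged = []
    by_group: dict = {}
    for ev in keep:
        by_group.setdefault((ev.chrom, ev.svtype), []).append(ev)

    for (chrom, svtype), group in sorted(by_group.items()):
        group.sort(key=lambda e: (e.start, e.end))
        clusters: list[list[SvEvent]] = []
        for ev in group:
            placed = False
            for cl in clusters:
                rep = cl[-1]
                if svtype == "translocation":
                    match = (abs(ev.start - rep.start) <= breakpoint_tol
                             and ev.chrom2 == rep.chrom2
                             and ev.pos2 is not None and rep.pos2 is not None
                             and abs(ev.pos2 - rep.pos2) <= breakpoint_tol)
                else:
                    match = _reciprocal_overlap(ev, rep) >= reciprocal
                if match:
                    cl.append(ev)
                    placed = True
                    break
            if not placed:
                clusters.append([ev])
        for cl in clusters:
            strains = set()
            for ev in cl:
                strains.update(ev.support)
            support = {s: sum(ev.support.get(s, 0) for ev in cl) for s in strains}
            sources = frozenset().union(*(ev.sources for ev in cl))
            eids = {ev.event_id for ev in cl if ev.event_id is not None}
            merged.append(SvEvent(
                chrom, min(ev.start for ev in cl), max(ev.end for ev in cl),
                svtype, support=support,
                source_strain=cl[0].source_strain,
                chrom2=cl[0].chrom2, pos2=cl[0].pos2,
                event_id=min(eids) if eids else None,
                sources=sources))
    merged.sort(key=lambda e: (e.chrom, e.start, e.end, e.svtype))
    return merged, errors


def score_events(events):
    """Strain-specificity score per event.

    ``score = other / (own + other)`` where *own* is the larger and
    *other* the smaller of the two strain supports: 0 means no
    cross-strain evidence (strongly strain-unique), 0.5 means balanced
    support (shared). Events with zero total support are flagged and
    excluded.

    Returns ``(scored_events, unsupported_events)``.
    """
    scored, unsupported = [], []
    for ev in events:
        vals = sorted(ev.support.values(), reverse=True)
        own = vals[0] if vals else 0
        other = vals[1] if len(vals) > 1 else 0
        if own + other == 0:
            unsupported.append(ev)
            continue
        ev.score = other / (own + other)
        scored.append(ev)
    if unsupported:
        log.warning("%d events with zero support in both strains excluded",
                    len(unsupported))
    return scored, unsupported


@dataclass
class CutoffResult:
    cutoff: float
    estimated_fdr: float
    unique_events: list
    sweep: pd.DataFrame
    target_met: bool


def select_cutoff(scored_events, target_fdr: float = 0.05,
                  shared_proxy=None) -> CutoffResult:
    """Sweep all distinct score values and pick the largest cutoff whose
    (monotone) estimated FDR stays at or below ``target_fdr``.

    ``shared_proxy`` is a predicate marking known-shared events; by
    default an event is proxy-shared when it was independently called in
    both strains' call sets (``len(ev.sources) == 2``). Proxy-shared
    events drive the FDR estimate but are excluded from the returned
    unique set — an event detected in both strains is by definition not
    strain-unique; the estimate calibrates how many *undetected* shared
    events slip below the same cutoff.
    """
    if shared_proxy is None:
        shared_proxy = lambda ev: len(ev.sources) >= 2
    events = sorted(scored_events, key=lambda e: e.score)
    if not events:
        return CutoffResult(0.0, 0.0, [], pd.DataFrame(), True)

    rows = []
    n_called = n_proxy = 0
    fdr_mono = 0.0
    i = 0
    n = len(events)
    while i < n:
        c = events[i].score
        while i < n and events[i].score == c:
            n_called += 1
            n_proxy += bool(shared_proxy(events[i]))
            i += 1
        raw = n_proxy / n_called
        fdr_mono = max(fdr_mono, raw)
        rows.append({"cutoff": c, "n_unique": n_called, "n_proxy_shared": n_proxy,
                     "fdr_raw": raw, "fdr": fdr_mono})
    sweep = pd.DataFrame(rows)

    ok = sweep[sweep["fdr"] <= target_fdr]
    if len(ok):
        row = ok.iloc[-1]
        target_met = True
    else:
        row = sweep.loc[sweep["fdr"].idxmin()]
        target_met = False
        log.warning("no cutoff reaches target FDR %.3g; falling back to the "
                    "FDR-minimizing cutoff %.3g (FDR %.3g)",
                    target_fdr, row["cutoff"], row["fdr"])
    cutoff = float(row["cutoff"])
    unique = [ev for ev in events
              if ev.score <= cutoff and not shared_proxy(ev)]
    return CutoffResult(cutoff, float(row["fdr"]), unique, sweep, target_met)


def sv_summary_table(events, unique_events) -> pd.DataFrame:
    """Per-type counts of strain-unique events, split by source strain."""
    unique_ids = {id(ev) for ev in unique_events}
    rows = {}
    for ev in events:
        if id(ev) not in unique_ids:
            continue
        src = ev.source_strain or "unknown"
        rows.setdefault(src, {t: 0 for t in SV_TYPES})
        rows[src][ev.svtype] += 1
    df = pd.DataFrame(rows).fillna(0).astype(int)
    if not df.empty:
        df.loc["total"] = df.sum()
    return df
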