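"""Synthetic two-strain study generator.

Emulates the statistical structure the analysis assumes, for a pair of
highly inbred strains derived from a heterogeneous founder pool:

* a founder SNP panel for the five sequenced founders plus one latent
  "unknown" haplotype (standing in for the unsequenced founders and the
  reference-like strain, which together form the combined unknown/
  reference ancestry state);
* mosaic strain genomes whose ancestry path is a Markov chain with
  per-interval switch probability ``1 - exp(-switch_scale * d_Morgan)``,
  modulated by a cM/Mb recombination map;
* per-site read depths (negative binomial) and alt-supporting read
  counts (binomial with the per-read error rate), plus a repeat mask,
  gene models, QTL intervals and a toy reference sequence;
* structural-variant call sets per strain with shared and strain-unique
  events, cross-strain noise support and redundant overlapping calls.

Every simulated observable gets exactly one truth label, returned in a
``TruthSet`` that is kept separate from the fixture files the pipeline
consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .classify import GeneModel, VariantSite
from .config import ConfigError, SimConfig
from .recomb import interval_cM
from .sv import SvEvent

__all__ = [
    "FounderPanel", "MosaicStrain", "TruthSet", "StudyData", "IndelPanel",
    "simulate_founder_panel", "simulate_mosaic_strain", "simulate_read_support",
    "simulate_sv_callsets", "simulate_indels", "simulate_reference",
    "simulate_genes", "simulate_intervals", "simulate_study",
    "ambiguous_sites",
]

UNKNOWN_LABEL = "Unk/Ref"
DEFAULT_FOUNDERS = ("A", "AK", "BALBc", "C3H", "DBA2")

_BASES = np.array(list("ACGT"))


@dataclass
class FounderPanel:
    """Biallelic founder alleles per site (0 = ref, 1 = alt)."""

    chrom: str
    positions: np.ndarray          # 0-based bp, strictly increasing
    ref: np.ndarray                # ref allele strings
    alt: np.ndarray                # alt allele strings
    alleles: np.ndarray            # (n_founders, n_sites) in {0, 1}
    founder_names: tuple
    unknown_alleles: np.ndarray | None = None  # latent haplotype (truth side)
    ibd_runs: list = field(default_factory=list)  # (start_site, end_site, i, j)

    @property
    def n_sites(self) -> int:
        return self.positions.size

    @property
    def n_founders(self) -> int:
        return self.alleles.shape[0]


@dataclass
class MosaicStrain:
    """One inbred strain: allele dosages plus the true ancestry path."""

    name: str
    dosage: np.ndarray             # per site in {0.0, 0.5, 1.0}
    truth_states: np.ndarray       # per site: founder index, n_founders = unknown
    het_mask: np.ndarray

    @property
    def called_alleles(self) -> np.ndarray:
        """Hard genotype calls (het rounds to ref)."""
        return (self.dosage > 0.5).astype(int)


@dataclass
class IndelPanel:
    """Held-out indel markers used to validate ancestry blocks."""

    positions: np.ndarray                  # 0-based bp
    founder_carrier: np.ndarray            # (n_founders, n_indels) bool
    unknown_carrier: np.ndarray            # (n_indels,) bool
    strain_carrier: dict                   # strain -> (n_indels,) bool


@dataclass
class TruthSet:
    """Truth labels for every simulated observable (oracle side only)."""

    true_ancestry: dict = field(default_factory=dict)   # strain -> state array
    true_class: np.ndarray | None = None                # per emitted site
    true_sv_labels: dict = field(default_factory=dict)  # event_id -> label
    site_index: np.ndarray | None = None                # emitted site -> panel index


@dataclass
class StudyData:
    """Everything one synthetic study produces."""

    cfg: SimConfig
    panel: FounderPanel
    strains: dict                   # name -> MosaicStrain
    sites: list                     # list[VariantSite] (emitted call set)
    truth: TruthSet
    repeats: list                   # (start, end) intervals
    qtl: list                       # (start, end) intervals
    genes: list                     # list[GeneModel]
    indels: IndelPanel | None = None
    sv_calls: dict | None = None    # strain -> list[SvEvent]


# ---------------------------------------------------------------------------
# founder panel


def _sample_positions(rng, n, length, intervals=None, boost=1.0, min_gap=16):
    """Distinct positions with minimum spacing; density inside ``intervals``
    is ``boost`` times the outside density."""
    n_slots = length // min_gap
    if n > n_slots:
        raise ConfigError(f"cannot place {n} sites with {min_gap} bp spacing "
                          f"on a {length} bp chromosome")
    if intervals and boost != 1.0:
        slot_pos = np.arange(n_slots) * min_gap
        inside = np.zeros(n_slots, dtype=bool)
        for s, e in intervals:
            inside |= (slot_pos >= s) & (slot_pos < e)
        n_in = inside.sum()
        w_in = boost * n_in
        w_out = n_slots - n_in
        k_in = rng.binomial(n, w_in / (w_in + w_out))
        k_in = min(k_in, n_in)
        sel_in = rng.choice(np.flatnonzero(inside), size=k_in, replace=False)
        sel_out = rng.choice(np.flatnonzero(~inside), size=n - k_in, replace=False)
        slots = np.concatenate([sel_in, sel_out])
    else:
        slots = rng.choice(n_slots, size=n, replace=False)
    pos = np.sort(slots * min_gap + rng.integers(0, min_gap // 2, size=n))
    return pos


def _draw_alleles(rng, n, indel_fraction):
    """Random ref/alt allele pairs; a fraction are small indels (< 50 bp)."""
    ref = rng.choice(_BASES, size=n)
    shift = rng.integers(1, 4, size=n)
    alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]
    ref, alt = ref.astype(object), alt.astype(object)
    is_indel = rng.random(n) < indel_fraction
    for i in np.flatnonzero(is_indel):
        extra = "".join(rng.choice(_BASES, size=rng.integers(1, 6)))
        if rng.random() < 0.5:
            alt[i] = ref[i] + extra        # insertion
        else:
            ref[i], alt[i] = ref[i] + extra, ref[i]  # deletion
    return ref, alt


def simulate_founder_panel(cfg: SimConfig, rng=None) -> FounderPanel:
    """Founder allele panel with IBD runs and unknown-founder-only sites."""
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    pos = _sample_positions(rng, cfg.n_sites, cfg.chrom_length)
    ref, alt = _draw_alleles(rng, cfg.n_sites, cfg.indel_fraction)
    alleles = (rng.random((cfg.n_founders, cfg.n_sites))
               < cfg.founder_alt_freq).astype(np.int8)
    unknown = (rng.random(cfg.n_sites) < cfg.founder_alt_freq).astype(np.int8)

    # sites where only the (latent) unknown founder carries the alt; by
    # construction these occur at exactly the configured rate — chance
    # all-founder-reference sites elsewhere keep the unknown on reference
    only_unknown = rng.random(cfg.n_sites) < cfg.unknown_fraction
    alleles[:, only_unknown] = 0
    unknown[only_unknown] = 1
    chance_no_match = ~only_unknown & (alleles.sum(axis=0) == 0) & (unknown == 1)
    unknown[chance_no_match] = 0

    # contiguous founder-pair IBD runs (shared haplotype: SNPs identical,
    # and held-out indels inherit the same sharing, see simulate_indels)
    ibd_runs = []
    if cfg.ibd_run_fraction > 0 and cfg.n_founders >= 2:
        n_runs = max(1, int(round(cfg.ibd_run_fraction * cfg.n_sites
                                  / cfg.ibd_run_length)))
        for _ in range(n_runs):
            start = int(rng.integers(0, max(1, cfg.n_sites - cfg.ibd_run_length)))
            i, j = (int(v) for v in rng.choice(cfg.n_founders, size=2,
                                               replace=False))
            alleles[j, start:start + cfg.ibd_run_length] = \
                alleles[i, start:start + cfg.ibd_run_length]
            ibd_runs.append((start, start + cfg.ibd_run_length, i, j))

    names = tuple(DEFAULT_FOUNDERS[:cfg.n_founders]) if cfg.n_founders <= 5 \
        else tuple(f"F{i}" for i in range(cfg.n_founders))
    return FounderPanel(cfg.chrom, pos, ref, alt, alleles, names, unknown,
                        ibd_runs)


# ---------------------------------------------------------------------------
# mosaic strain


def simulate_mosaic_strain(panel: FounderPanel, cfg: SimConfig, rng=None,
                           name: str | None = None) -> MosaicStrain:
    """Stitch a mosaic genome from the founder pool.

    The ancestry path is a Markov chain over the sequenced founders plus
    the unknown state; per-interval switch probability is
    ``1 - exp(-switch_scale * d)`` with ``d`` the interval's genetic
    length in Morgans from the recombination map.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n = panel.n_sites
    k = panel.n_founders + 1  # + unknown state
    d_morgan = interval_cM(panel.positions, cfg.recomb_map) / 100.0
    q = 1.0 - np.exp(-cfg.switch_scale * d_morgan)

    states = np.empty(n, dtype=np.int64)
    states[0] = rng.integers(k)
    switches = rng.random(n - 1) < q
    cur = states[0]
    for t in range(1, n):
        if switches[t - 1]:
            cur = (cur + 1 + rng.integers(k - 1)) % k
        states[t] = cur

    true_allele = np.where(
        states < panel.n_founders,
        panel.alleles[np.minimum(states, panel.n_founders - 1),
                      np.arange(n)],
        panel.unknown_alleles,
    ).astype(np.int8)

    flip = rng.random(n) < cfg.seq_error
    allele = np.where(flip, 1 - true_allele, true_allele)
    het = rng.random(n) < (1.0 - cfg.homozygosity)
    dosage = np.where(het, 0.5, allele.astype(float))
    return MosaicStrain(name or "strain", dosage, states, het)


# ---------------------------------------------------------------------------
# read support


def _repeat_intervals(cfg: SimConfig, rng) -> list:
    if cfg.repeat_fraction <= 0 or cfg.n_repeats <= 0:
        return []
    return simulate_intervals(rng, cfg.n_repeats, cfg.chrom_length,
                              cfg.repeat_fraction)


def simulate_intervals(rng, n, length, fraction) -> list:
    """Non-overlapping intervals covering ~``fraction`` of the chromosome."""
    mean_len = max(1, int(fraction * length / n))
    lens = np.maximum(1, rng.exponential(mean_len, size=n).astype(int))
    starts = np.sort(rng.choice(length, size=n, replace=False))
    out, last_end = [], -1
    for s, ln in zip(starts, lens):
        s = max(s, last_end + 1)
        e = min(s + ln, length)
        if e > s:
            out.append((int(s), int(e)))
            last_end = e
    return out


def _distance_to_intervals(positions, intervals) -> np.ndarray:
    """bp distance from each position to the nearest interval (0 inside)."""
    if not intervals:
        return np.full(len(positions), math.inf)
    starts = np.array([s for s, _ in intervals])
    ends = np.array([e for _, e in intervals])
    pos = np.asarray(positions)
    i = np.searchsorted(starts, pos, side="right") - 1
    d_prev = np.where(i >= 0,
                      np.maximum(0, pos - ends[np.maximum(i, 0)] + 1),
                      math.inf)
    inside = (i >= 0) & (pos < ends[np.maximum(i, 0)])
    j = np.minimum(i + 1, len(starts) - 1)
    d_next = np.where(i + 1 < len(starts), starts[j] - pos, math.inf)
    d = np.minimum(d_prev, d_next)
    d[inside] = 0
    return d.astype(float)


def simulate_read_support(strains: dict, panel: FounderPanel, cfg: SimConfig,
                          rng=None, repeats=None):
    """Per-site depth and alt-support counts for both strains.

    Depth is negative binomial around ``mean_depth`` (clipped below at
    ``min_depth``); alt support is binomial with success probability
    ``1 - seq_error`` at homozygous-alt sites, ``seq_error`` at ref sites
    and 0.5 at heterozygous sites. Emits a ``VariantSite`` for every
    panel site where at least one strain shows alt-supporting reads,
    along with the emitted-site -> panel-site index map.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed + 2)
    if repeats is None:
        repeats = _repeat_intervals(cfg, rng)
    n = panel.n_sites
    rep_dist = _distance_to_intervals(panel.positions, repeats)
    in_catalog = rng.random(n) < cfg.catalog_fraction

    depth, support = {}, {}
    for name, strain in strains.items():
        p_nb = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.mean_depth)
        d = rng.negative_binomial(cfg.depth_dispersion, p_nb, size=n)
        if cfg.min_depth > 0:
            d = np.maximum(d, cfg.min_depth)
        p_alt = np.where(strain.dosage == 1.0, 1.0 - cfg.seq_error,
                         np.where(strain.dosage == 0.5, 0.5, cfg.seq_error))
        depth[name] = d
        support[name] = rng.binomial(d, p_alt)

    names = list(strains)
    any_alt = np.zeros(n, dtype=bool)
    for name in names:
        any_alt |= support[name] > 0
    idx = np.flatnonzero(any_alt)

    sites = [
        VariantSite(
            chrom=panel.chrom,
            pos=int(panel.positions[i]) + 1,
            ref=str(panel.ref[i]),
            alt=str(panel.alt[i]),
            depth={name: int(depth[name][i]) for name in names},
            alt_support={name: int(support[name][i]) for name in names},
            repeat_distance=float(rep_dist[i]),
            in_catalog=bool(in_catalog[i]),
        )
        for i in idx
    ]
    return sites, idx, repeats


def _true_classes(strains: dict, idx: np.ndarray) -> np.ndarray:
    """Truth label per emitted site from the strains' true dosages."""
    names = list(strains)
    a, b = strains[names[0]], strains[names[1]]
    out = np.empty(idx.size, dtype=object)
    for j, i in enumerate(idx):
        da, db = a.dosage[i], b.dosage[i]
        if da == 0.5 or db == 0.5:
            out[j] = "het"
        elif da == 1.0 and db == 1.0:
            out[j] = "common"
        elif da == 1.0:
            out[j] = "distinct_strainA"
        elif db == 1.0:
            out[j] = "distinct_strainB"
        else:
            out[j] = "absent"
    return out


# ---------------------------------------------------------------------------
# held-out indels


def simulate_indels(panel: FounderPanel, strains: dict, cfg: SimConfig,
                    rng=None, n_indels: int = 500) -> IndelPanel:
    """Held-out indel markers inherited through the true ancestry path.

    Each indel is carried by a random subset of founders; a strain
    carries it exactly when its true ancestor at that position does, so
    at zero noise the per-block consistency of a correct decoding is 1.
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    pos = np.sort(rng.choice(cfg.chrom_length, size=n_indels, replace=False))
    carrier = rng.random((panel.n_founders, n_indels)) < 0.3
    # guarantee each indel is carried by someone so strains can inherit it
    none = ~carrier.any(axis=0)
    carrier[rng.integers(panel.n_founders, size=none.sum()), np.flatnonzero(none)] = True
    unknown_carrier = rng.random(n_indels) < 0.3

    # ancestry is defined per site; between sites it is taken constant up
    # to the inter-site midpoint (matching haploblock boundary semantics),
    # so each indel inherits from its *nearest* site's ancestor
    right = np.clip(np.searchsorted(panel.positions, pos), 0,
                    panel.n_sites - 1)
    left = np.maximum(right - 1, 0)
    use_left = (np.abs(pos - panel.positions[left])
                <= np.abs(panel.positions[right] - pos))
    site_of = np.where(use_left, left, right)

    # founders IBD over a run share the whole haplotype, indels included
    for s, e, i, j in panel.ibd_runs:
        in_run = (site_of >= s) & (site_of < e)
        carrier[j, in_run] = carrier[i, in_run]
    strain_carrier = {}
    for name, strain in strains.items():
        st = strain.truth_states[site_of]
        strain_carrier[name] = np.where(
            st < panel.n_founders,
            carrier[np.minimum(st, panel.n_founders - 1), np.arange(n_indels)],
            unknown_carrier,
        ).astype(bool)
    return IndelPanel(pos, carrier, unknown_carrier, strain_carrier)


# ---------------------------------------------------------------------------
# structural variants


def simulate_sv_callsets(cfg: SimConfig, rng=None):
    """Two per-strain SV call lists plus shared/unique truth labels.

    Shared events are called (with breakpoint jitter) in both strains
    and carry high support in both backgrounds; unique events are called
    only in their source strain, with Poisson background noise as
    cross-strain support. Redundant overlapping duplicates are injected
    at ``sv_duplicate_rate``.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed + 4)
    a, b = cfg.strain_names
    n = cfg.n_sv
    n_unique = int(round(n * cfg.sv_unique_fraction))
    n_ua = n_unique // 2
    n_ub = n_unique - n_ua

    spans = simulate_intervals(rng, n, cfg.chrom_length, 0.02)
    while len(spans) < n:  # rare collision shrinkage; top up deterministically
        extra = simulate_intervals(rng, n - len(spans), cfg.chrom_length, 0.005)
        spans.extend(extra)
    spans = spans[:n]
    types = list(rng.choice(["deletion", "insertion", "gain", "loss", "inversion"],
                            size=n))
    n_tr = int(round(cfg.sv_translocation_fraction * n))
    for i in rng.choice(n, size=n_tr, replace=False):
        types[i] = "translocation"

    labels = np.array(["shared"] * (n - n_unique)
                      + [f"unique_{a}"] * n_ua + [f"unique_{b}"] * n_ub)
    rng.shuffle(labels)

    calls = {a: [], b: []}
    truth = {}

    def support_pair(label):
        hi = lambda: max(1, int(rng.poisson(cfg.sv_mean_support)))
        lo = lambda: int(rng.poisson(cfg.sv_noise_support))
        if label == "shared":
            return {a: hi(), b: hi()}
        if label == f"unique_{a}":
            return {a: hi(), b: lo()}
        return {a: lo(), b: hi()}

    def jitter(x):
        return max(0, int(x + rng.integers(-cfg.sv_breakpoint_jitter,
                                           cfg.sv_breakpoint_jitter + 1)))

    for eid, ((s, e), t, label) in enumerate(zip(spans, types, labels)):
        sup = support_pair(label)
        truth[eid] = "shared" if label == "shared" else "unique"
        chrom2 = cfg.chrom if t == "translocation" else None
        pos2 = int(rng.integers(cfg.chrom_length)) if t == "translocation" else None
        sources = [a, b] if label == "shared" else [label.split("_", 1)[1]]
        for src in sources:
            ev = SvEvent(cfg.chrom, jitter(s), max(jitter(s) + 1, jitter(e)), t,
                         support=dict(sup), source_strain=src,
                         chrom2=chrom2,
                         pos2=None if pos2 is None else jitter(pos2),
                         event_id=eid)
            calls[src].append(ev)
            if rng.random() < cfg.sv_duplicate_rate:
                calls[src].append(SvEvent(
                    cfg.chrom, jitter(s), max(jitter(s) + 1, jitter(e)), t,
                    support=dict(sup), source_strain=src, chrom2=chrom2,
                    pos2=None if pos2 is None else jitter(pos2), event_id=eid))
    return calls, truth


# ---------------------------------------------------------------------------
# reference sequence, genes, QTLs


def simulate_reference(panel: FounderPanel, length: int | None = None,
                       rng=None, seed: int = 0) -> dict:
    """Toy reference sequence with the panel's ref alleles embedded.

    Intended for small (<= a few Mb) chromosomes; the variant-applied
    genome builder and coding-effect annotation read from it.
    """
    rng = rng or np.random.default_rng(seed)
    length = length or int(panel.positions[-1]) + 100
    seq = rng.choice(_BASES, size=length)
    for i in range(panel.n_sites):
        p = int(panel.positions[i])
        ref = str(panel.ref[i])
        if p + len(ref) <= length:
            seq[p:p + len(ref)] = list(ref)
    return {panel.chrom: "".join(seq)}


def simulate_genes(cfg: SimConfig, rng=None, avoid=None) -> list:
    """Non-overlapping toy gene models with in-frame CDS exons."""
    rng = rng or np.random.default_rng(cfg.seed + 5)
    genes = []
    n = cfg.n_genes
    if n <= 0:
        return genes
    spacing = cfg.chrom_length // (n + 1)
    for g in range(n):
        anchor = spacing * (g + 1)
        n_ex = int(rng.integers(1, 4))
        cds, cur = [], anchor
        for _ in range(n_ex):
            ln = 3 * int(rng.integers(10, 60))
            cds.append((cur, cur + ln))
            cur += ln + int(rng.integers(50, 500))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "pseudogene" if rng.random() < 0.1 else "protein_coding"
        genes.append(GeneModel(f"gene{g:04d}", cfg.chrom, strand, cds, biotype))
    return genes


# ---------------------------------------------------------------------------
# full study


def simulate_study(cfg: SimConfig, with_svs: bool = True,
                   with_indels: bool = True) -> StudyData:
    """Generate one complete synthetic study, deterministically from
    ``cfg.seed``."""
    cfg.validate()
    root = np.random.default_rng(cfg.seed)
    streams = root.spawn(8)

    qtl = simulate_intervals(streams[0], cfg.n_qtl, cfg.chrom_length,
                             cfg.qtl_fraction) if cfg.n_qtl > 0 else []

    rng_panel = streams[1]
    panel = simulate_founder_panel(cfg, rng_panel)
    if cfg.qtl_density_boost != 1.0 and qtl:
        # re-place sites with boosted density inside QTLs (alleles unchanged)
        panel.positions = _sample_positions(
            rng_panel, cfg.n_sites, cfg.chrom_length,
            intervals=qtl, boost=cfg.qtl_density_boost)

    a, b = cfg.strain_names
    strains = {
        a: simulate_mosaic_strain(panel, cfg, streams[2], name=a),
        b: simulate_mosaic_strain(panel, cfg, streams[3], name=b),
    }
    sites, idx, repeats = simulate_read_support(strains, panel, cfg, streams[4])

    truth = TruthSet(
        true_ancestry={s.name: s.truth_states for s in strains.values()},
        true_class=_true_classes(strains, idx),
        site_index=idx,
    )

    sv_calls = None
    if with_svs:
        sv_calls, sv_truth = simulate_sv_callsets(cfg, streams[5])
        truth.true_sv_labels = sv_truth

    indels = simulate_indels(panel, strains, cfg, streams[6]) if with_indels else None
    genes = simulate_genes(cfg, streams[7])
    return StudyData(cfg, panel, strains, sites, truth, repeats, qtl, genes,
                     indels, sv_calls)


# ---------------------------------------------------------------------------
# truth-side utilities


def ambiguous_sites(panel: FounderPanel, truth_states: np.ndarray) -> np.ndarray:
    """Mask of sites whose true ancestor is indistinguishable, within its
    true ancestry block, from at least one other founder (IBD-ambiguous).

    For unknown-ancestry blocks the latent haplotype is compared with
    each sequenced founder the same way.
    """
    n = panel.n_sites
    mask = np.zeros(n, dtype=bool)
    block_start = 0
    for t in range(1, n + 1):
        if t == n or truth_states[t] != truth_states[block_start]:
            s = int(truth_states[block_start])
            sl = slice(block_start, t)
            if s < panel.n_founders:
                own = panel.alleles[s, sl]
                others = [f for f in range(panel.n_founders) if f != s]
                rows = panel.alleles[others, sl]
            else:
                own = panel.unknown_alleles[sl]
                rows = panel.alleles[:, sl]
            if rows.size and np.any(np.all(rows == own[None, :], axis=1)):
                mask[sl] = True
            block_start = t
    return mask
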