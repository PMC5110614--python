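"""Founder-ancestry hidden Markov model.

Infers the ancestral origin of each segment of an inbred strain's
genome from a panel of sequenced founder strains. The model has one
state per sequenced founder plus one combined unknown/reference state
(covering the unsequenced founders together with the reference-like
founder, which is underrepresented in SNP panels).

Observations are per-site founder-match patterns: the subset of
{sequenced founders, reference} whose allele equals the target strain's
allele. Emissions are per-state Bernoulli match probabilities over
those indicators — flexible enough to absorb founder-specific biases,
sequencing error and de novo mutation. During fitting each founder
state is parameterized by a self-match, a pooled cross-founder-match
and a reference-match probability (the unknown state by a pooled
founder match and a reference match): tying the cross-founder
indicators keeps state labels identified with their founders. Transitions correspond to recombination
events: the per-interval switch probability is
``1 - exp(-switch_scale * d)`` with ``d`` the genetic interval length
in Morgans from a recombination map, the switch mass divided uniformly
among the other states.

Emission parameters and the global switch scale are fitted by
Expectation-Maximization (log-space forward-backward); the Viterbi path
yields maximum-likelihood haploblocks, which are relabeled as identical
by descent (IBD) when several founders are indistinguishable across the
block. Decodings are validated against held-out indels: the fraction of
strain indels inside each block that the labeled ancestor also carries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .recomb import cumulative_cM

__all__ = [
    "ObservationTrack", "HmmModel", "Haploblock",
    "build_observation_track", "transition_matrix", "default_model",
    "forward_backward", "em_fit", "viterbi_decode",
    "collapse_to_haploblocks", "validate_with_indels",
]

log = logging.getLogger(__name__)

UNKNOWN_LABEL = "Unk/Ref"


@dataclass
class ObservationTrack:
    """Per-site founder-match patterns on a genetic map."""

    chrom: str
    positions: np.ndarray       # 0-based bp, strictly increasing
    cM: np.ndarray              # genetic positions
    X: np.ndarray               # (n_sites, n_indicators) match indicators
    indicator_names: tuple      # founders + "Ref"
    site_index: np.ndarray      # indices into the source panel

    def __post_init__(self):
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("observation positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return self.positions.size


@dataclass
class HmmModel:
    """Six-state (founders + unknown/reference) ancestry HMM."""

    state_names: tuple
    indicator_names: tuple
    emission: np.ndarray        # (K, F) per-state indicator match probabilities
    switch_scale: float         # expected switches per Morgan
    init: np.ndarray            # (K,) initial distribution
    error_floor: float = 0.01
    self_floor: float = 0.0     # lower bound on founder-state self match

    def __post_init__(self):
        self.emission = np.asarray(self.emission, dtype=float)
        self.init = np.asarray(self.init, dtype=float)
        if np.any(self.emission < 0) or np.any(self.emission > 1):
            raise ValueError("emission probabilities must lie in [0, 1]")
        if self.switch_scale < 0:
            raise ValueError("switch_scale must be non-negative")

    @property
    def n_states(self) -> int:
        return self.emission.shape[0]

    @property
    def unknown_state(self) -> int:
        return self.n_states - 1


@dataclass
class Haploblock:
    """Maximal run of one decoded state, possibly IBD-relabeled."""

    chrom: str
    start: int                  # half-open bp
    end: int
    state: int
    label: frozenset            # founder-name set (>= 2 members when IBD)
    mean_posterior: float
    n_sites: int

    @property
    def label_str(self) -> str:
        return "+".join(sorted(self.label))

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# observations


def build_observation_track(panel, strain_alleles, recomb_map,
                            keep_uninformative: float = 1.0,
                            rng=None, chrom: str | None = None) -> ObservationTrack:
    """Founder-match patterns for a strain's genotype calls.

    ``strain_alleles`` holds 0 (reference allele), 1 (alt) or NaN
    (missing; skipped with a logged count) per panel site. Sites where
    the strain matches the reference *and* every sequenced founder carry
    no founder-discriminating signal and can be thinned: a fraction
    ``keep_uninformative`` of them is retained.
    """
    alleles = np.asarray(strain_alleles, dtype=float)
    if alleles.shape[0] != panel.n_sites:
        raise ValueError("strain alleles and panel cover different site sets")
    missing = np.isnan(alleles)
    if missing.any():
        log.info("%d sites missing in strain; skipped", int(missing.sum()))
    keep = ~missing

    g = np.nan_to_num(alleles, nan=0.0).astype(int)
    match_f = (panel.alleles == g[None, :]).T          # (n, n_founders)
    match_ref = (g == 0)[:, None]
    X = np.concatenate([match_f, match_ref], axis=1)

    uninformative = keep & (g == 0) & match_f.all(axis=1)
    if keep_uninformative < 1.0:
        rng = rng or np.random.default_rng(0)
        drop = uninformative & (rng.random(panel.n_sites) >= keep_uninformative)
        keep &= ~drop

    idx = np.flatnonzero(keep)
    pos = panel.positions[idx]
    return ObservationTrack(
        chrom or panel.chrom, pos, cumulative_cM(pos, recomb_map),
        X[idx].astype(bool), tuple(panel.founder_names) + ("Ref",), idx)


# ---------------------------------------------------------------------------
# model pieces


def default_model(founder_names, switch_scale: float = 10.0,
                  self_match: float = 0.9, off_match: float = 0.5,
                  error_floor: float = 0.01,
                  self_floor: float = 0.8) -> HmmModel:
    """Symmetric starting model for EM.

    Founder states match their own founder with probability
    ``self_match`` and everything else at the uninformative
    ``off_match``; the unknown/reference state is exchangeable over the
    sequenced-founder indicators. ``self_floor`` keeps each founder
    state's self-match probability high during fitting: a segment
    assigned to a founder must actually match that founder except for
    error and de novo mutation, which prevents founder states absent
    from the mosaic from drifting into chance-level matching and
    impersonating the unknown/reference state.
    """
    founders = tuple(founder_names)
    nf = len(founders)
    k, f = nf + 1, nf + 1
    emission = np.full((k, f), off_match)
    for i in range(nf):
        emission[i, i] = self_match
    init = np.full(k, 1.0 / k)
    return HmmModel(founders + (UNKNOWN_LABEL,), founders + ("Ref",),
                    emission, switch_scale, init, error_floor, self_floor)


def interval_switch_probs(cM: np.ndarray, switch_scale: float) -> np.ndarray:
    d = np.diff(np.asarray(cM, dtype=float)) / 100.0  # Morgans
    if np.any(d < 0):
        raise ValueError("genetic positions must be non-decreasing")
    return 1.0 - np.exp(-switch_scale * d)


def transition_matrix(interval_cM: float, switch_scale: float,
                      n_states: int) -> np.ndarray:
    """State-to-state transition probabilities for one interval.

    ``P(switch) = 1 - exp(-switch_scale * interval_cM / 100)``, divided
    uniformly among the other states; rows sum to 1.
    """
    if interval_cM < 0:
        raise ValueError("negative genetic distance")
    q = 1.0 - math.exp(-switch_scale * interval_cM / 100.0)
    a = np.full((n_states, n_states), q / (n_states - 1))
    np.fill_diagonal(a, 1.0 - q)
    return a


def _log_emissions(track: ObservationTrack, model: HmmModel) -> np.ndarray:
    """(n_sites, K) log-likelihood of each site's pattern per state."""
    p = np.clip(model.emission, 1e-12, 1 - 1e-12)
    x = track.X.astype(float)
    return x @ np.log(p).T + (1.0 - x) @ np.log1p(-p).T


# ---------------------------------------------------------------------------
# inference


def forward_backward(track: ObservationTrack, model: HmmModel):
    """Log-space forward-backward pass.

    Returns ``(loglik, gamma, stay_post, q)`` where ``gamma`` are the
    posterior state marginals (rows sum to 1), ``stay_post[t]`` is the
    posterior probability of *not* switching over interval ``t`` and
    ``q`` the prior per-interval switch probabilities.
    """
    logb = _log_emissions(track, model)
    n, k = logb.shape
    q = interval_switch_probs(track.cM, model.switch_scale)

    alpha = np.empty((n, k))
    with np.errstate(divide="ignore"):
        alpha[0] = np.log(model.init) + logb[0]
    c = np.empty(n)  # per-step log normalizers (scaled log-space)
    c[0] = _logsumexp(alpha[0])
    alpha[0] -= c[0]
    for t in range(1, n):
        w = np.exp(alpha[t - 1])
        qt = q[t - 1]
        trans = (1.0 - qt) * w + (qt / (k - 1)) * (w.sum() - w)
        with np.errstate(divide="ignore"):
            alpha[t] = np.log(trans) + logb[t]
        c[t] = _logsumexp(alpha[t])
        alpha[t] -= c[t]
    loglik = float(c.sum())

    beta = np.zeros((n, k))
    for t in range(n - 2, -1, -1):
        w = np.exp(beta[t + 1] + logb[t + 1] - c[t + 1])
        qt = q[t]
        with np.errstate(divide="ignore"):
            beta[t] = np.log((1.0 - qt) * w + (qt / (k - 1)) * (w.sum() - w))

    loggamma = alpha + beta
    loggamma -= _logsumexp(loggamma, axis=1)[:, None]
    gamma = np.exp(loggamma)

    # posterior stay probability per interval: sum_i xi_t(i, i)
    stay = np.empty(n - 1)
    for t in range(n - 1):
        qt = q[t]
        joint_diag = np.exp(alpha[t]) * (1.0 - qt) * \
            np.exp(logb[t + 1] + beta[t + 1] - c[t + 1])
        stay[t] = joint_diag.sum()
    if n == 1:
        gamma[0] /= gamma[0].sum()
    return loglik, gamma, np.clip(stay, 0.0, 1.0), q


def _logsumexp(a, axis=None):
    from scipy.special import logsumexp

    return logsumexp(a, axis=axis)


def em_fit(track: ObservationTrack, model0: HmmModel, max_iter: int = 50,
           tol: float = 1e-6, fit_switch_scale: bool = True):
    """Baum-Welch fit of emissions and the global switch scale.

    The per-iteration log-likelihood is non-decreasing up to numerical
    tolerance; iteration stops when the gain drops below ``tol`` or at
    ``max_iter``. Returns ``(fitted_model, loglik_trace)``.
    """
    if track.n_sites == 0:
        raise ValueError("empty observation track")
    model = HmmModel(model0.state_names, model0.indicator_names,
                     model0.emission.copy(), model0.switch_scale,
                     model0.init.copy(), model0.error_floor,
                     model0.self_floor)
    nf = len(model.state_names) - 1
    trace = []
    d_morgan = np.diff(track.cM) / 100.0
    x = track.X.astype(float)

    for it in range(max_iter):
        loglik, gamma, stay, _ = forward_backward(track, model)
        if not np.isfinite(loglik):
            bad = int(np.argmax(~np.isfinite(
                _log_emissions(track, model).max(axis=1))))
            raise FloatingPointError(
                f"non-finite likelihood; first offending site index {bad} "
                f"(bp {track.positions[min(bad, track.n_sites - 1)]})")
        trace.append(loglik)

        # M-step: emissions. Each founder state carries three parameters
        # (match-self, pooled match-other-founders, match-reference); the
        # unknown/reference state carries two (pooled founders, reference).
        # Tying the cross-founder indicators anchors state identity: a
        # state can only fit a segment well by matching *its own* founder,
        # which prevents label switching and spare-state specialization.
        weights = gamma.sum(axis=0)                      # (K,)
        num = gamma.T @ x                                # (K, F)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = num / weights[:, None]
            for i in range(nf):
                cross = [j for j in range(nf) if j != i]
                if cross:
                    p[i, cross] = num[i, cross].sum() / (len(cross) * weights[i])
            p[-1, :nf] = num[-1, :nf].sum() / (nf * weights[-1])
        p[~np.isfinite(p)] = 0.5
        p = np.clip(p, model.error_floor, 1.0 - model.error_floor)
        for i in range(nf):
            p[i, i] = max(p[i, i], model.self_floor)
        model.emission = p

        # M-step: switch scale (1-D maximization of the expected
        # complete-data transition log-likelihood)
        if fit_switch_scale and track.n_sites > 1:
            sw = np.clip(1.0 - stay, 0.0, 1.0)
            pos_d = d_morgan > 0

            def neg_obj(s):
                qq = 1.0 - np.exp(-s * d_morgan[pos_d])
                qq = np.clip(qq, 1e-12, 1 - 1e-12)
                return -(sw[pos_d] * np.log(qq)
                         + (1.0 - sw[pos_d]) * np.log1p(-qq)).sum()

            if pos_d.any() and sw[pos_d].sum() > 0:
                res = minimize_scalar(neg_obj, bounds=(1e-8, 1e4),
                                      method="bounded")
                model.switch_scale = float(res.x)

        if it > 0 and trace[-1] - trace[-2] < tol:
            break

    loglik, _, _, _ = forward_backward(track, model)
    trace.append(loglik)
    return model, trace


def viterbi_decode(track: ObservationTrack, model: HmmModel):
    """Single highest-probability state path (log-probability returned).

    Ties break deterministically toward the lower-indexed state.
    """
    logb = _log_emissions(track, model)
    n, k = logb.shape
    q = interval_switch_probs(track.cM, model.switch_scale)
    with np.errstate(divide="ignore"):
        delta = np.log(model.init) + logb[0]
        back = np.zeros((n, k), dtype=np.int64)
        for t in range(1, n):
            qt = q[t - 1]
            loga = np.full((k, k), -np.inf if qt == 0 else
                           math.log(qt / (k - 1)))
            np.fill_diagonal(loga, math.log1p(-qt) if qt < 1 else -np.inf)
            cand = delta[:, None] + loga
            back[t] = np.argmax(cand, axis=0)   # first max = lowest index
            delta = cand[back[t], np.arange(k)] + logb[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    logprob = float(delta[path[-1]])
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path, logprob


# ---------------------------------------------------------------------------
# haploblocks


def collapse_to_haploblocks(path, gamma, track: ObservationTrack, panel,
                            chrom_length: int | None = None) -> list:
    """Collapse a decoded path into chromosome-tiling haploblocks.

    Block boundaries fall midway between adjacent sites of different
    states; the first block starts at 0 and the last ends at
    ``chrom_length`` (defaulting just past the final site). A block
    decoded as founder *f* is relabeled with the full set of founders
    whose panel alleles are identical to *f*'s across the block's sites
    (identical by descent).
    """
    n = len(path)
    if n == 0:
        return []
    if chrom_length is None:
        chrom_length = int(track.positions[-1]) + 1
    state_names = tuple(panel.founder_names) + (UNKNOWN_LABEL,)
    nf = panel.n_founders

    blocks = []
    run_start = 0
    for t in range(1, n + 1):
        if t == n or path[t] != path[run_start]:
            s = int(path[run_start])
            start = 0 if run_start == 0 else \
                int((track.positions[run_start - 1] + track.positions[run_start]) // 2)
            end = chrom_length if t == n else \
                int((track.positions[t - 1] + track.positions[t]) // 2)
            sites = track.site_index[run_start:t]
            if s < nf:
                own = panel.alleles[s, sites]
                members = {panel.founder_names[f]
                           for f in range(nf)
                           if np.array_equal(panel.alleles[f, sites], own)}
            else:
                members = {UNKNOWN_LABEL}
            blocks.append(Haploblock(
                track.chrom, start, end, s, frozenset(members),
                float(gamma[run_start:t, s].mean()) if gamma is not None else float("nan"),
                t - run_start))
            run_start = t
    return blocks


def validate_with_indels(haploblocks, indel_positions, strain_carrier,
                         founder_carrier, founder_names, unknown_carrier=None):
    """Per-block indel-consistency fractions.

    For each block, the fraction of held-out strain indels inside the
    block that the labeled ancestor (any member of an IBD label set)
    also carries. Blocks with no strain indels get ``None`` (undefined,
    not zero). Returns ``(per_block, weighted_mean)`` where the mean is
    weighted by per-block indel counts; ``weighted_mean`` is ``None``
    when no block is informative.
    """
    indel_positions = np.asarray(indel_positions)
    strain_carrier = np.asarray(strain_carrier, dtype=bool)
    name_to_idx = {nm: i for i, nm in enumerate(founder_names)}

    per_block = []
    tot_consistent = tot_indels = 0
    for blk in haploblocks:
        inside = (indel_positions >= blk.start) & (indel_positions < blk.end)
        carried = inside & strain_carrier
        m = int(carried.sum())
        if m == 0:
            per_block.append(None)
            continue
        idx = np.flatnonzero(carried)
        if blk.label == frozenset({UNKNOWN_LABEL}):
            if unknown_carrier is None:
                per_block.append(None)
                continue
            anc = np.asarray(unknown_carrier, dtype=bool)[idx]
        else:
            members = [name_to_idx[nm] for nm in blk.label if nm in name_to_idx]
            anc = np.asarray(founder_carrier, dtype=bool)[members][:, idx].any(axis=0)
        frac = float(anc.mean())
        per_block.append(frac)
        tot_consistent += int(anc.sum())
        tot_indels += m
    mean = tot_consistent / tot_indels if tot_indels else None
    return per_block, mean
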