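"""Content-specific activity in listeners: ANOVA-style variance decomposition.

Both listener groups receive identical sensory input; only the attended
speaker differs.  The *content component* of a group is therefore the group
mean minus the grand mean over all listeners -- any stimulus-driven
activity common to everyone cancels, leaving the signal specific to the
attended story.  The proportion of the listeners' total EEG variance
carried by this component,

    R2_L = SS_between / SS_total,
    SS_between = sum_g n_g * sum_{t,c} (mean_g - grand)^2,
    SS_total   = sum_l  sum_{t,c} (x_l - grand)^2,

pooled over time samples and channels, is the effect of attentive focus.
It is reported bias-corrected (Delta R2_L = observed minus the mean of its
group-exchange permutation distribution) because the sample R2 of even
unrelated groups is positive.

Because every permutation only relabels listeners, all statistics are
bilinear in the listener-pair Gram matrices; these are precomputed once per
ensemble so the exhaustive 924-assignment distribution costs microseconds
per assignment.  The frequency decomposition applies Parseval's theorem to
the same sums of squares, so per-bin contributions add up exactly to the
global R2_L.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .containers import StimulusEnsemble
from .exceptions import DegenerateInputError
from .permutation import (Assignment, PermutationDistribution, bias_correct,
                          build_distribution, enumerate_group_exchanges,
                          maxstat_correct, permutation_pvalue)
from .results import EffectEstimate

__all__ = [
    "content_component", "r2_listener", "r2_listener_stat",
    "decompose_by_channel", "decompose_by_frequency", "ListenerAnova",
]


def _centered_listeners(ensemble: StimulusEnsemble,
                        center: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Stacked listener data, optionally mean-centered per listener/channel.

    Centering removes DC offsets that are acquisition artifacts; it is the
    default for every analysis entry point.  Hand-worked textbook examples
    are defined on raw voltages, so it can be disabled.
    """
    x = ensemble.listener_array()
    if center:
        x = x - x.mean(axis=1, keepdims=True)
    return x, ensemble.group_labels()


def _group_weight(n: int, members: np.ndarray) -> np.ndarray:
    """Coefficients expressing (group mean - grand mean) as a listener combo."""
    w = np.full(n, -1.0 / n)
    w[members] += 1.0 / len(members)
    return w


def content_component(ensemble: StimulusEnsemble,
                      center: bool = True) -> dict[str, np.ndarray]:
    """Per-group content component: group mean minus grand mean (time x channels).

    The group-size-weighted sum of the returned components is identically
    zero, since the grand mean is the size-weighted mean of group means.
    """
    x, labels = _centered_listeners(ensemble, center)
    groups = ensemble.group_members()
    if any(len(m) == 0 for m in groups.values()):
        raise ValueError("every group needs at least one listener")
    grand = x.mean(axis=0)
    return {
        sid: x[labels == sid].mean(axis=0) - grand
        for sid in ensemble.speaker_ids
    }


class ListenerAnova:
    """Fast evaluation of listener-ANOVA statistics under group relabeling.

    Precomputes, per ensemble, the Gram matrix of centered listener signals
    (globally, per channel, and per frequency bin when requested).  Any
    group assignment's between-group sum of squares is then a quadratic
    form in the group-contrast weights, so exhaustive permutation runs in
    O(n_listeners^2) per assignment.

    All ensembles must have the same number of listeners and equal observed
    group sizes; a single group exchange relabels the listeners jointly in
    every ensemble (the listeners are the same people in each stimulus).
    """

    def __init__(self, ensembles: Sequence[StimulusEnsemble] | StimulusEnsemble,
                 center: bool = True):
        self.center = center
        if isinstance(ensembles, StimulusEnsemble):
            ensembles = [ensembles]
        if not ensembles:
            raise ValueError("need at least one ensemble")
        self.ensembles = list(ensembles)
        ns = {len(e.listeners) for e in self.ensembles}
        if len(ns) != 1:
            raise ValueError("ensembles must share the listener count")
        self.n_listeners = ns.pop()
        first = self.ensembles[0]
        sizes = sorted(len(m) for m in first.group_members().values())
        if any(sorted(len(m) for m in e.group_members().values()) != sizes
               for e in self.ensembles):
            raise ValueError("ensembles must share the observed group sizes")
        # observed group = listeners attending the first (sorted) speaker
        self._observed: list[Assignment] = []
        self._grams: list[np.ndarray] = []
        self._ss_total: list[float] = []
        self._grams_channel: list[np.ndarray] = []
        self._ss_total_channel: list[np.ndarray] = []
        for e in self.ensembles:
            x, labels = _centered_listeners(e, center)
            obs = tuple(np.flatnonzero(labels == e.speaker_ids[0]))
            self._observed.append(obs)
            n = x.shape[0]
            flat = x.reshape(n, -1)
            gram = flat @ flat.T
            grand = flat.mean(axis=0)
            ss_total = float(np.sum((flat - grand) ** 2))
            if ss_total <= 0:
                raise DegenerateInputError("listeners carry zero total variance")
            self._grams.append(gram)
            self._ss_total.append(ss_total)
            gram_c = np.einsum("itc,jtc->ijc", x, x, optimize=True)
            grand_c = x.mean(axis=0)
            self._grams_channel.append(gram_c)
            self._ss_total_channel.append(np.sum((x - grand_c) ** 2, axis=(0, 1)))
        if len(set(self._observed)) != 1:
            raise ValueError(
                "ensembles must share the observed grouping (the same listener "
                "positions attend the first speaker in every stimulus), so a "
                "single group exchange relabels all stimuli jointly")
        self.group_size = len(self._observed[0])
        self._freq_cache: dict[float, tuple] = {}

    # -- assignments ----------------------------------------------------------

    @property
    def observed(self) -> Assignment:
        """Observed assignment: listener indices attending the first speaker."""
        return self._observed[0]

    def assignments(self) -> list[Assignment]:
        """Exhaustive group exchanges, the observed assignment first.

        Assignments are index subsets into each ensemble's sorted listener
        list; a subset relabels all ensembles jointly.
        """
        return enumerate_group_exchanges(self.n_listeners, self.group_size,
                                         observed=self._observed[0])

    def _weights(self, assignment: Assignment) -> tuple[np.ndarray, np.ndarray]:
        a = np.asarray(assignment, dtype=int)
        b = np.setdiff1d(np.arange(self.n_listeners), a)
        return _group_weight(self.n_listeners, a), _group_weight(self.n_listeners, b)

    # -- statistics -----------------------------------------------------------

    def r2(self, assignment: Assignment) -> float:
        """Cross-stimulus mean of SS_between / SS_total under an assignment."""
        wa_, wb_ = self._weights(assignment)
        na, nb = len(assignment), self.n_listeners - len(assignment)
        vals = []
        for gram, ss_tot in zip(self._grams, self._ss_total):
            ss_b = na * wa_ @ gram @ wa_ + nb * wb_ @ gram @ wb_
            vals.append(ss_b / ss_tot)
        # quadratic forms can dip epsilon-below zero in floating point
        return float(np.clip(np.mean(vals), 0.0, 1.0))

    def r2_per_channel(self, assignment: Assignment) -> np.ndarray:
        """Local per-channel ratio SS_between(c) / SS_total(c), stimulus-averaged."""
        wa_, wb_ = self._weights(assignment)
        na, nb = len(assignment), self.n_listeners - len(assignment)
        out = []
        for gram_c, ss_tot_c in zip(self._grams_channel, self._ss_total_channel):
            ss_b = (na * np.einsum("i,ijc,j->c", wa_, gram_c, wa_)
                    + nb * np.einsum("i,ijc,j->c", wb_, gram_c, wb_))
            with np.errstate(invalid="ignore", divide="ignore"):
                out.append(np.where(ss_tot_c > 0, ss_b / ss_tot_c, np.nan))
        stacked = np.asarray(out)
        dead = np.isnan(stacked).all(axis=0)
        merged = np.full(stacked.shape[1], np.nan)
        if (~dead).any():
            merged[~dead] = np.nanmean(stacked[:, ~dead], axis=0)
        return merged

    def _freq_grams(self, bin_hz: float):
        """Per-frequency-bin Gram matrices via Parseval-weighted rFFT products."""
        if bin_hz in self._freq_cache:
            return self._freq_cache[bin_hz]
        grams_b, edges = [], None
        for e in self.ensembles:
            x, _ = _centered_listeners(e, self.center)
            n_l, n_t, _ = x.shape
            if bin_hz > e.fs / 2:
                raise ValueError("bin width exceeds the Nyquist frequency")
            freqs = np.fft.rfftfreq(n_t, d=1.0 / e.fs)
            coef = np.full(len(freqs), 2.0 / n_t)
            coef[0] = 1.0 / n_t
            if n_t % 2 == 0:
                coef[-1] = 1.0 / n_t
            bins = np.minimum((freqs / bin_hz).astype(int),
                              int(np.ceil(freqs[-1] / bin_hz)) - 1)
            n_bins = bins.max() + 1
            f = np.fft.rfft(x, axis=1)
            g = np.zeros((n_l, n_l, n_bins))
            for b in range(n_bins):
                sel = f[:, bins == b, :] * np.sqrt(coef[bins == b])[None, :, None]
                g[:, :, b] = np.einsum("ikc,jkc->ij", sel, sel.conj(),
                                       optimize=True).real
            grams_b.append(g)
            edges = np.arange(n_bins + 1) * bin_hz
        self._freq_cache[bin_hz] = (grams_b, edges)
        return grams_b, edges

    def r2_per_frequency(self, assignment: Assignment,
                         bin_hz: float) -> np.ndarray:
        """Global per-bin contributions SS_between(b) / SS_total; sum equals r2."""
        grams_b, _ = self._freq_grams(bin_hz)
        wa_, wb_ = self._weights(assignment)
        na, nb = len(assignment), self.n_listeners - len(assignment)
        out = []
        for g, ss_tot in zip(grams_b, self._ss_total):
            ss_b = (na * np.einsum("i,ijb,j->b", wa_, g, wa_)
                    + nb * np.einsum("i,ijb,j->b", wb_, g, wb_))
            out.append(ss_b / ss_tot)
        return np.mean(np.asarray(out), axis=0)


def r2_listener_stat(listeners: np.ndarray, labels: np.ndarray,
                     center: bool = True) -> float:
    """Direct (slow) R2_L on a stacked listener array -- reference route.

    ``listeners`` is (n_listeners, n_times, n_channels); ``labels`` the
    attended-speaker id per listener.  Listeners are mean-centered per
    channel before pooling.
    """
    x = np.asarray(listeners, dtype=float)
    if center:
        x = x - x.mean(axis=1, keepdims=True)
    grand = x.mean(axis=0)
    ss_total = float(np.sum((x - grand) ** 2))
    if ss_total <= 0:
        raise DegenerateInputError("zero total variance")
    ss_between = 0.0
    for g in np.unique(labels):
        sel = x[np.asarray(labels) == g]
        ss_between += len(sel) * np.sum((sel.mean(axis=0) - grand) ** 2)
    return float(np.clip(ss_between / ss_total, 0.0, 1.0))


def r2_listener(ensembles: Sequence[StimulusEnsemble] | StimulusEnsemble,
                inference: bool = True,
                include_identity: bool = True) -> EffectEstimate:
    """Proportion of listener variance explained by attentive focus.

    Computed per stimulus and averaged across stimuli; with
    ``inference=True`` the exhaustive group-exchange distribution supplies
    the exact p-value and the bias-corrected Delta R2_L.
    """
    engine = ListenerAnova(ensembles)
    observed = engine.r2(engine.assignments()[0])
    if not inference:
        return EffectEstimate(r2=observed)
    dist = build_distribution(engine.r2, engine.assignments())
    return EffectEstimate(
        r2=observed,
        delta_r2=float(bias_correct(dist, include_identity=include_identity)),
        p_uncorrected=permutation_pvalue(dist),
        p_corrected=permutation_pvalue(dist),
        extra={"n_permutations": dist.n},
    )


def decompose_by_channel(ensembles: Sequence[StimulusEnsemble] | StimulusEnsemble,
                         alpha: float = 0.05) -> dict:
    """Per-channel local effect ratios with max-statistic corrected significance.

    Channels with zero variance are flagged dead and excluded from the
    significance mask.  Returns channel names, local ratios, bias-corrected
    ratios, corrected p-values and the significance mask at ``alpha``.
    """
    engine = ListenerAnova(ensembles)
    dist = build_distribution(engine.r2_per_channel, engine.assignments(),
                              family="channels")
    dead = ~np.isfinite(dist.values).all(axis=0)
    values = np.where(np.isfinite(dist.values), dist.values, -np.inf)
    dist = PermutationDistribution(values=values, assignments=dist.assignments,
                                   family="channels")
    with np.errstate(invalid="ignore"):  # dead channels carry -inf sentinels
        p_unc, p_cor = maxstat_correct(dist)
        delta = bias_correct(dist)
    observed = dist.observed
    first = engine.ensembles[0]
    return {
        "channels": next(iter(first.listeners.values())).channel_names,
        "r2": np.where(dead, np.nan, observed),
        "delta_r2": np.where(dead, np.nan, delta),
        "p_uncorrected": np.where(dead, np.nan, p_unc),
        "p_corrected": np.where(dead, np.nan, p_cor),
        "significant": (p_cor <= alpha) & ~dead,
        "dead": dead,
    }


def decompose_by_frequency(ensembles: Sequence[StimulusEnsemble] | StimulusEnsemble,
                           bin_hz: float = 1.0,
                           alpha: float = 0.05) -> dict:
    """Frequency-resolved contributions to R2_L (Parseval decomposition).

    Per-bin contributions are global (share of the total variance), so
    they sum exactly to the pooled R2_L; significance per bin is
    max-statistic corrected across bins.
    """
    engine = ListenerAnova(ensembles)
    stat = lambda a: engine.r2_per_frequency(a, bin_hz)
    dist = build_distribution(stat, engine.assignments(), family="frequency")
    p_unc, p_cor = maxstat_correct(dist)
    delta = bias_correct(dist)
    _, edges = engine._freq_grams(bin_hz)
    return {
        "bin_edges_hz": edges,
        "bin_centers_hz": 0.5 * (edges[:-1] + edges[1:]),
        "contribution": dist.observed,
        "delta_contribution": delta,
        "p_uncorrected": p_unc,
        "p_corrected": p_cor,
        "significant": p_cor <= alpha,
        "global_r2": float(np.sum(dist.observed)),
    }
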