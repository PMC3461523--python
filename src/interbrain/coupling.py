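"""Speaker-listener coupling: lagged set correlation via CCA.

Whether speaker and listener brains engage homologous channels or entirely
different ones is unknown a priori, so the shared variance between the
speaker's multichannel EEG and the listeners' content component is
measured with canonical correlation analysis.  Cohen's *set correlation*
summarizes the canonical spectrum as the proportion of generalized
variance shared between the two sets,

    R2_SL = 1 - prod_i (1 - r_i^2)        (the complement of Wilks' Lambda),

which reduces to the squared Pearson correlation when both sets are
univariate.  A *one-to-one* variant applies the same product formula to
the channelwise correlations between identically labeled channels only
(Cz with Cz, ...); it can only detect coupling through homologous scalp
patterns, so the contrast between the two statistics is diagnostic of
non-homologous coordination.

The scan repeats the analysis over a grid of time lags (positive lag =
listener sample paired with an *earlier* speaker sample, i.e. the listener
follows).  Because the exhaustive group-exchange permutation test must
recompute the statistic for every relabeling, the scan engine precomputes
all listener-pair and speaker-listener cross-product matrices per lag;
each relabeled statistic is then a cheap quadratic form plus a small SVD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml
from scipy import linalg as sla
from scipy import stats as sstats

from .containers import Recording, StimulusEnsemble
from .exceptions import RankDeficiencyError
from .permutation import (Assignment, PermutationDistribution, bias_correct,
                          enumerate_group_exchanges, maxstat_correct,
                          permutation_pvalue)
from .results import EffectCurve, EffectEstimate

__all__ = [
    "CanonicalSpectrum", "ROISpec", "set_correlation", "r2_one_to_one",
    "count_significant_variates", "make_lag_grid", "lag_scan",
    "LaggedCouplingEngine", "lag_scan_ensemble", "roi_scan", "default_rois",
]

_JITTER = 1e-12  # relative diagonal jitter keeping Cholesky well-posed


@dataclass
class CanonicalSpectrum:
    """Canonical correlations (descending) with weights and sample size."""

    correlations: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.correlations = np.asarray(self.correlations, dtype=float)
        if np.any(np.diff(self.correlations) > 1e-10):
            raise ValueError("canonical correlations must be non-increasing")
        if np.any(self.correlations < -1e-12) or np.any(self.correlations > 1 + 1e-9):
            raise ValueError("canonical correlations must lie in [0, 1]")

    @property
    def r2_set(self) -> float:
        """Cohen's set correlation: 1 - prod (1 - r_i^2)."""
        return _set_r2(self.correlations)


def _set_r2(r: np.ndarray) -> float:
    r = np.clip(np.asarray(r, dtype=float), 0.0, 1.0)
    return float(-np.expm1(np.sum(np.log1p(-np.minimum(r, 1.0 - 1e-15) ** 2))))


def set_correlation(X: np.ndarray, Y: np.ndarray,
                    reg: float | None = None
                    ) -> tuple[float, CanonicalSpectrum]:
    """Set correlation between two multivariate time series.

    Parameters
    ----------
    X, Y : ndarray, shape (n_times, p) and (n_times, q)
        Column-centered internally.
    reg : float or None
        Ridge added to the within-set covariances, relative to their mean
        diagonal.  ``None`` (default) means no ridge, but a small one
        (1e-3) is auto-enabled with a warning when ``n < 5 * (p + q)``.
        An explicit ``0.0`` disables regularization entirely, in which
        case rank-deficient input raises :class:`RankDeficiencyError`.

    Returns
    -------
    (r2, spectrum) :
        ``r2 = 1 - prod(1 - r_i^2)`` and the full canonical spectrum.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of time samples")
    n, p = X.shape
    q = Y.shape[1]
    if reg is None:
        reg = 0.0
        if n < 5 * (p + q):
            warnings.warn(
                f"only {n} samples for p+q={p + q} variables; enabling ridge "
                "regularization (1e-3) of the within-set covariances",
                RuntimeWarning, stacklevel=2)
            reg = 1e-3
    if reg == 0.0 and n <= p + q:
        raise ValueError("need more time samples than p + q (or regularization)")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    if reg == 0.0:
        qx, rx = np.linalg.qr(Xc)
        qy, ry = np.linalg.qr(Yc)
        for rr, name in ((rx, "X"), (ry, "Y")):
            d = np.abs(np.diag(rr))
            if d.min() <= 1e-10 * max(d.max(), 1e-300):
                raise RankDeficiencyError(
                    f"{name} is rank deficient; enable ridge regularization")
        u, s, vt = np.linalg.svd(qx.T @ qy)
        r = np.clip(s, 0.0, 1.0)
        a = sla.solve_triangular(rx, u, lower=False)
        b = sla.solve_triangular(ry, vt.T, lower=False)
    else:
        cxx = Xc.T @ Xc
        cyy = Yc.T @ Yc
        cxy = Xc.T @ Yc
        cxx[np.diag_indices_from(cxx)] += reg * np.trace(cxx) / p
        cyy[np.diag_indices_from(cyy)] += reg * np.trace(cyy) / q
        lx = np.linalg.cholesky(cxx)
        ly = np.linalg.cholesky(cyy)
        m = sla.solve_triangular(lx, cxy, lower=True)
        m = sla.solve_triangular(ly, m.T, lower=True).T
        u, s, vt = np.linalg.svd(m)
        r = np.clip(s, 0.0, 1.0)
        a = sla.solve_triangular(lx.T, u, lower=False)
        b = sla.solve_triangular(ly.T, vt.T, lower=False)
    k = min(p, q)
    spectrum = CanonicalSpectrum(correlations=r[:k], x_weights=a[:, :k],
                                 y_weights=b[:, :k], n_samples=n)
    return spectrum.r2_set, spectrum


def r2_one_to_one(X: np.ndarray, Y: np.ndarray,
                  pairing: Sequence[tuple[int, int]] | None = None) -> float:
    """One-to-one variant of the set correlation.

    Applies ``1 - prod(1 - r_c^2)`` to the Pearson correlations between
    identically paired channels only.  ``pairing`` defaults to positional
    (channel c of X with channel c of Y), which requires identical channel
    counts.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of time samples")
    if pairing is None:
        if X.shape[1] != Y.shape[1]:
            raise ValueError("positional pairing needs equal channel counts")
        pairing = [(c, c) for c in range(X.shape[1])]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    rs = []
    for i, j in pairing:
        if not (0 <= i < X.shape[1] and 0 <= j < Y.shape[1]):
            raise ValueError(f"unpaired channel in pairing entry ({i}, {j})")
        denom = np.linalg.norm(Xc[:, i]) * np.linalg.norm(Yc[:, j])
        rs.append(0.0 if denom == 0 else float(Xc[:, i] @ Yc[:, j] / denom))
    return _set_r2(np.abs(np.asarray(rs)))


def count_significant_variates(spectrum: CanonicalSpectrum,
                               alpha: float = 0.05) -> int:
    """Number of leading canonical variates with significant correlation.

    Bartlett's sequential chi-square approximation: for k = 0, 1, ... the
    hypothesis that all correlations beyond the first k are zero is tested
    with the statistic

        -(n - (p + q + 3) / 2) * ln prod_{i > k} (1 - r_i^2)

    on (p - k)(q - k) degrees of freedom.  Testing stops at the first
    non-rejection; the count of consecutive rejections is returned.
    """
    r = np.clip(spectrum.correlations, 0.0, 1.0 - 1e-15)
    p = spectrum.x_weights.shape[0]
    q = spectrum.y_weights.shape[0]
    n = spectrum.n_samples
    if n <= p + q:
        raise ValueError("sample size too small for Bartlett's approximation")
    log_terms = np.log1p(-r ** 2)
    factor = n - (p + q + 3) / 2.0
    count = 0
    for k in range(len(r)):
        stat = -factor * log_terms[k:].sum()
        df = (p - k) * (q - k)
        if sstats.chi2.sf(stat, df) > alpha:
            break
        count = k + 1
    return count


# -- lag machinery ------------------------------------------------------------

def make_lag_grid(start_s: float = -2.0, stop_s: float = 20.0,
                  step_s: float = 0.5) -> np.ndarray:
    """Inclusive lag grid; the default spans -2 s (listener anticipates)
    to +20 s (listener follows) in 0.5 s steps, 45 points."""
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    if start_s >= stop_s:
        raise ValueError("start_s must be below stop_s")
    n = int(round((stop_s - start_s) / step_s))
    return np.round(start_s + step_s * np.arange(n + 1), 10)


def _lag_slices(lag_n: int, n_times: int) -> tuple[slice, slice]:
    """(listener rows, speaker rows) pairing listener t with speaker t - lag."""
    if abs(lag_n) >= n_times:
        raise ValueError("lag exceeds the recording length")
    if lag_n >= 0:
        return slice(lag_n, n_times), slice(0, n_times - lag_n)
    return slice(0, n_times + lag_n), slice(-lag_n, n_times)


def lag_scan(speaker: Recording | np.ndarray, listener_component: np.ndarray,
             lags_s: np.ndarray, fs: float | None = None,
             reg: float | None = None) -> EffectCurve:
    """Raw set-correlation curve between one speaker and one content component.

    For each lag the listener component at time t is correlated with the
    speaker at t - lag on the trimmed overlap.  No permutation inference is
    attached; see :func:`lag_scan_ensemble` for the full ensemble-level
    statistic with exact p-values and bias correction.
    """
    if isinstance(speaker, Recording):
        s_data, fs = speaker.data, speaker.fs
    else:
        s_data = np.asarray(speaker, dtype=float)
        if fs is None:
            raise ValueError("fs is required when speaker is a bare array")
    comp = np.asarray(listener_component, dtype=float)
    if comp.shape[0] != s_data.shape[0]:
        raise ValueError("speaker and component must share a time base")
    lags_s = np.asarray(lags_s, dtype=float)
    n = s_data.shape[0]
    if np.max(np.abs(lags_s)) * fs >= n:
        raise ValueError("lag grid exceeds the recording length")
    r2s = []
    for lag in lags_s:
        rows_l, rows_s = _lag_slices(int(round(lag * fs)), n)
        r2, _ = set_correlation(s_data[rows_s], comp[rows_l], reg=reg)
        r2s.append(r2)
    return EffectCurve(lags_s=lags_s, r2=np.asarray(r2s))


class LaggedCouplingEngine:
    """Precomputed cross-products for fast lagged set correlation under
    group relabeling.

    For every (ensemble, lag) the centered listener segments and both
    speaker segments are assembled once and their full cross-product matrix
    is stored in blocks.  Under a relabeling, the content component of the
    group attending speaker ``s`` is a fixed linear combination of the
    listeners (weights ``1/n_g`` in-group minus ``1/n`` overall), so its
    covariance with itself and with the speaker are quadratic/linear forms
    in the stored blocks; canonical correlations then need only a pair of
    triangular solves and a channels-square SVD per evaluation.
    """

    def __init__(self, ensembles: Sequence[StimulusEnsemble] | StimulusEnsemble,
                 lags_s: np.ndarray | None = None,
                 ridge: float | None = None):
        if isinstance(ensembles, StimulusEnsemble):
            ensembles = [ensembles]
        self.ensembles = list(ensembles)
        if not self.ensembles:
            raise ValueError("need at least one ensemble")
        self.lags_s = (make_lag_grid() if lags_s is None
                       else np.asarray(lags_s, dtype=float))
        first = self.ensembles[0]
        self.n_listeners = len(first.listeners)
        self.n_channels = first.n_channels
        self.speaker_ids = first.speaker_ids
        observed = set()
        for e in self.ensembles:
            if len(e.listeners) != self.n_listeners or e.n_channels != self.n_channels:
                raise ValueError("ensembles must share listener and channel counts")
            labels = e.group_labels()
            observed.add(tuple(np.flatnonzero(labels == e.speaker_ids[0])))
        if len(observed) != 1:
            raise ValueError("ensembles must share the observed grouping")
        self.observed: Assignment = observed.pop()
        self.group_size = len(self.observed)

        n_t = first.n_times
        max_lag_n = int(np.max(np.abs(np.round(self.lags_s * first.fs))))
        if max_lag_n >= n_t:
            raise ValueError("lag grid exceeds the recording length")
        min_seg = n_t - max_lag_n
        dim = 2 * self.n_channels  # speaker + component per evaluation
        if ridge is None:
            ridge = 0.0
            if min_seg < 5 * dim:
                warnings.warn(
                    f"shortest lagged segment has {min_seg} samples for "
                    f"{dim} variables; enabling ridge regularization (1e-3)",
                    RuntimeWarning, stacklevel=2)
                ridge = 1e-3
        self.ridge = ridge
        self._blocks: list[list[dict]] = []
        for e in self.ensembles:
            self._blocks.append([self._precompute(e, lag) for lag in self.lags_s])

    def _precompute(self, e: StimulusEnsemble, lag_s: float) -> dict:
        n_t = e.n_times
        lag_n = int(round(lag_s * e.fs))
        rows_l, rows_s = _lag_slices(lag_n, n_t)
        listeners = e.listener_array()[:, rows_l, :]
        listeners = listeners - listeners.mean(axis=1, keepdims=True)
        n, t_seg, c = listeners.shape
        speakers = {}
        for sid in e.speaker_ids:
            s = e.speakers[sid].data[rows_s]
            speakers[sid] = s - s.mean(axis=0)
        stack = np.concatenate([speakers[sid] for sid in e.speaker_ids]
                               + [listeners.transpose(1, 0, 2).reshape(t_seg, n * c)],
                               axis=1)
        g = stack.T @ stack
        n_sp = len(e.speaker_ids)
        blocks = {"t_seg": t_seg}
        p_block = g[n_sp * c:, n_sp * c:].reshape(n, c, n, c)
        blocks["P2"] = np.ascontiguousarray(
            p_block.transpose(0, 2, 1, 3).reshape(n * n, c * c))
        for i, sid in enumerate(e.speaker_ids):
            sxx = g[i * c:(i + 1) * c, i * c:(i + 1) * c].copy()
            sxx[np.diag_indices_from(sxx)] += (
                (self.ridge + _JITTER) * np.trace(sxx) / c)
            sx = g[i * c:(i + 1) * c, n_sp * c:].reshape(c, n, c)
            blocks[sid] = {
                "lx": np.linalg.cholesky(sxx),
                "diag_x": np.diag(sxx).copy(),
                "SX": np.ascontiguousarray(sx.transpose(1, 0, 2).reshape(n, c * c)),
            }
        return blocks

    # -- weights --------------------------------------------------------------

    def _weight_rows(self, assignments: Sequence[Assignment]
                     ) -> dict[str, np.ndarray]:
        """Group-contrast weight matrix (n_assignments x n_listeners) per speaker."""
        n, k = self.n_listeners, self.group_size
        u = np.zeros((len(assignments), n))
        for row, a in enumerate(assignments):
            u[row, list(a)] = 1.0
        w = {self.speaker_ids[0]: u / k - 1.0 / n,
             self.speaker_ids[1]: (1.0 - u) / (n - k) - 1.0 / n}
        return w

    # -- evaluation -----------------------------------------------------------

    def scan(self, assignments: Sequence[Assignment] | None = None
             ) -> tuple[PermutationDistribution, PermutationDistribution]:
        """Evaluate both statistics for every assignment and lag.

        Returns permutation distributions (assignments x lags) for the set
        correlation and for the one-to-one variant, each already averaged
        across stimuli and speakers inside every assignment.
        """
        if assignments is None:
            assignments = self.assignments()
        w_all = self._weight_rows(assignments)
        n_a, n_lags = len(assignments), len(self.lags_s)
        c = self.n_channels
        acc_set = np.zeros((n_a, n_lags))
        acc_one = np.zeros((n_a, n_lags))
        n_terms = 0
        for blocks_e in self._blocks:
            n_terms += len(self.speaker_ids)
            for li, blocks in enumerate(blocks_e):
                p2 = blocks["P2"]
                for sid in self.speaker_ids:
                    w = w_all[sid]
                    pair_w = (w[:, :, None] * w[:, None, :]).reshape(n_a, -1)
                    cyy_all = pair_w @ p2
                    cxy_all = w @ blocks[sid]["SX"]
                    lx = blocks[sid]["lx"]
                    dx = blocks[sid]["diag_x"]
                    tr_scale = (self.ridge + _JITTER)
                    for a in range(n_a):
                        cyy = cyy_all[a].reshape(c, c).copy()
                        cyy[np.diag_indices_from(cyy)] += (
                            tr_scale * np.trace(cyy) / c)
                        cxy = cxy_all[a].reshape(c, c)
                        ly = np.linalg.cholesky(cyy)
                        m = sla.solve_triangular(lx, cxy, lower=True,
                                                 check_finite=False)
                        m = sla.solve_triangular(ly, m.T, lower=True,
                                                 check_finite=False).T
                        r = np.linalg.svd(m, compute_uv=False)
                        acc_set[a, li] += _set_r2(r)
                        dy = np.diag(cyy)
                        rc = np.abs(np.diag(cxy)) / np.sqrt(dx * dy)
                        acc_one[a, li] += _set_r2(rc)
        acc_set /= n_terms
        acc_one /= n_terms
        mk = lambda v: PermutationDistribution(values=v,
                                               assignments=list(assignments),
                                               family="lags")
        return mk(acc_set), mk(acc_one)

    def assignments(self) -> list[Assignment]:
        return enumerate_group_exchanges(self.n_listeners, self.group_size,
                                         observed=self.observed)


def lag_scan_ensemble(ensembles: Sequence[StimulusEnsemble] | StimulusEnsemble,
                      lags_s: np.ndarray | None = None,
                      inference: bool = True,
                      ridge: float | None = None,
                      assignments: Sequence[Assignment] | None = None,
                      ) -> dict[str, EffectCurve]:
    """Full lag scan with exhaustive permutation inference.

    Returns effect curves (averaged across stimuli and speakers) for the
    set correlation (``"set"``) and the one-to-one variant
    (``"one_to_one"``); with inference, each carries bias-corrected
    Delta R2, exact per-lag p-values and max-statistic corrected p-values
    over the lag family.
    """
    engine = LaggedCouplingEngine(ensembles, lags_s=lags_s, ridge=ridge)
    if assignments is None:
        assignments = (engine.assignments() if inference
                       else [engine.observed])
    dist_set, dist_one = engine.scan(assignments)
    out = {}
    for name, dist in (("set", dist_set), ("one_to_one", dist_one)):
        observed = dist.values[0]
        if inference:
            p_unc, p_cor = maxstat_correct(dist)
            out[name] = EffectCurve(lags_s=engine.lags_s, r2=observed,
                                    delta_r2=bias_correct(dist),
                                    p_uncorrected=p_unc, p_corrected=p_cor)
        else:
            out[name] = EffectCurve(lags_s=engine.lags_s, r2=observed)
    return out


# -- regions of interest ------------------------------------------------------

@dataclass
class ROISpec:
    """Named channel subsets for spatially restricted coupling analysis."""

    rois: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.rois:
            raise ValueError("at least one ROI is required")
        for name, chans in self.rois.items():
            if not chans:
                raise ValueError(f"ROI {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.rois)

    def indices(self, channel_names: Sequence[str]) -> dict[str, np.ndarray]:
        idx = {}
        lookup = {name: i for i, name in enumerate(channel_names)}
        for name, chans in self.rois.items():
            missing = [ch for ch in chans if ch not in lookup]
            if missing:
                raise ValueError(f"ROI {name!r} channels missing from data: "
                                 f"{missing}")
            idx[name] = np.asarray([lookup[ch] for ch in chans])
        return idx

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"rois": self.rois}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ROISpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(rois={k: list(v) for k, v in payload["rois"].items()})


#: Default 7 x 9 scalp division over a 63-channel 10/20-style montage:
#: frontal (left/medial/right), central/temporal (left, right), medial
#: central, and occipito-parietal regions of nine electrodes each.
DEFAULT_ROI_NAMES = [
    "frontal_left", "frontal_medial", "frontal_right",
    "temporal_left", "central_medial", "temporal_right",
    "occipito_parietal",
]


def default_rois(channel_names: Sequence[str]) -> ROISpec:
    """Seven ROIs of nine electrodes each over the given montage.

    For arbitrary (e.g. synthetic) channel names the first 63 channels are
    divided into seven consecutive blocks of nine; a documented stand-in
    for a scalp-anatomical division, adequate for planted-structure
    recovery where the ground-truth mixing is known.
    """
    if len(channel_names) < 63:
        raise ValueError("the default 7x9 ROI layout needs >= 63 channels")
    rois = {
        name: list(channel_names[9 * i: 9 * (i + 1)])
        for i, name in enumerate(DEFAULT_ROI_NAMES)
    }
    return ROISpec(rois=rois)


def roi_scan(ensembles: Sequence[StimulusEnsemble] | StimulusEnsemble,
             rois: ROISpec, lag_s: float,
             inference: bool = True,
             ridge: float | None = None,
             assignments: Sequence[Assignment] | None = None) -> dict:
    """Set correlation for every (speaker ROI, listener ROI) pair at one lag.

    Returns matrices (speaker ROI x listener ROI) of raw R2, bias-corrected
    Delta R2 and corrected p-values (max-statistic over all pairs).
    Averaged across stimuli and speakers, like the full-scalp scan.
    """
    if isinstance(ensembles, StimulusEnsemble):
        ensembles = [ensembles]
    engine = LaggedCouplingEngine(ensembles, lags_s=np.asarray([lag_s]),
                                  ridge=ridge)
    channel_names = next(iter(ensembles[0].listeners.values())).channel_names
    idx = rois.indices(channel_names)
    names = rois.names
    n_r = len(names)
    if assignments is None:
        assignments = (engine.assignments() if inference
                       else [engine.observed])
    w_all = engine._weight_rows(assignments)
    n_a = len(assignments)
    c = engine.n_channels
    values = np.zeros((n_a, n_r * n_r))
    n_terms = 0
    for blocks_e in engine._blocks:
        blocks = blocks_e[0]
        p2 = blocks["P2"]
        n_terms += len(engine.speaker_ids)
        for sid in engine.speaker_ids:
            w = w_all[sid]
            pair_w = (w[:, :, None] * w[:, None, :]).reshape(n_a, -1)
            cyy_all = pair_w @ p2
            cxy_all = w @ blocks[sid]["SX"]
            lx_full = blocks[sid]["lx"]
            sxx = lx_full @ lx_full.T
            for a in range(n_a):
                cyy = cyy_all[a].reshape(c, c)
                cxy = cxy_all[a].reshape(c, c)
                cell = 0
                for ri in names:
                    ix = idx[ri]
                    sxx_i = sxx[np.ix_(ix, ix)].copy()
                    sxx_i[np.diag_indices_from(sxx_i)] += (
                        _JITTER * np.trace(sxx_i) / len(ix))
                    lx = np.linalg.cholesky(sxx_i)
                    for rj in names:
                        jx = idx[rj]
                        cyy_j = cyy[np.ix_(jx, jx)].copy()
                        cyy_j[np.diag_indices_from(cyy_j)] += (
                            (engine.ridge + _JITTER) * np.trace(cyy_j) / len(jx))
                        ly = np.linalg.cholesky(cyy_j)
                        m = sla.solve_triangular(lx, cxy[np.ix_(ix, jx)],
                                                 lower=True, check_finite=False)
                        m = sla.solve_triangular(ly, m.T, lower=True,
                                                 check_finite=False).T
                        r = np.linalg.svd(m, compute_uv=False)
                        values[a, cell] += _set_r2(r)
                        cell += 1
    values /= n_terms
    dist = PermutationDistribution(values=values, assignments=list(assignments),
                                   family="roi_pairs")
    out = {
        "speaker_rois": names,
        "listener_rois": names,
        "r2": dist.values[0].reshape(n_r, n_r),
    }
    if inference and n_a > 1:
        p_unc, p_cor = maxstat_correct(dist)
        out["delta_r2"] = np.asarray(bias_correct(dist)).reshape(n_r, n_r)
        out["p_uncorrected"] = p_unc.reshape(n_r, n_r)
        out["p_corrected"] = p_cor.reshape(n_r, n_r)
    return out


def coupling_spectrum(ensemble: StimulusEnsemble, lag_s: float,
                      speaker_id: str | None = None,
                      reg: float | None = None) -> CanonicalSpectrum:
    """Canonical spectrum between one speaker and its group's content
    component at a given lag (for canonical-variate assessment)."""
    from .listener import content_component

    sid = speaker_id or ensemble.speaker_ids[0]
    comp = content_component(ensemble)[sid]
    rows_l, rows_s = _lag_slices(int(round(lag_s * ensemble.fs)),
                                 ensemble.n_times)
    _, spectrum = set_correlation(ensemble.speakers[sid].data[rows_s],
                                  comp[rows_l], reg=reg)
    return spectrum
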