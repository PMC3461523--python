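"""End-to-end orchestration: simulate / load, analyse, report.

One :class:`AnalysisConfig` governs a run.  ``run_analysis`` produces a
machine-readable bundle containing the listener effect (global, by channel
and by frequency), the lagged coupling curves (set correlation and
one-to-one variant), the ROI pair matrix at the peak lag, and the
canonical-variate assessment -- all with exact group-exchange permutation
inference and bias correction.  Identical config and seed give an
identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import comb
from typing import Any, Sequence

import numpy as np
import yaml

from .containers import StimulusEnsemble
from .coupling import (LaggedCouplingEngine, ROISpec, coupling_spectrum,
                       count_significant_variates, default_rois,
                       lag_scan_ensemble, make_lag_grid, roi_scan)
from .exceptions import ConfigError
from .listener import ListenerAnova, decompose_by_channel, decompose_by_frequency
from .permutation import (bias_correct, build_distribution,
                          enumerate_group_exchanges, permutation_pvalue,
                          sample_group_exchanges)
from .synthetic import PlantManifest, generate_ensemble

__all__ = ["AnalysisConfig", "run_analysis", "make_report", "save_results"]


@dataclass
class AnalysisConfig:
    """Settings for a full analysis run.

    Defaults follow the reference design: lags from -2 s to +20 s in 0.5 s
    steps, 0.05 significance level, exhaustive group-exchange permutations
    (Monte-Carlo fallback above ``permutation_cap`` assignments).
    """

    lag_start_s: float = -2.0
    lag_stop_s: float = 20.0
    lag_step_s: float = 0.5
    analysis_rate_hz: float = 100.0
    freq_bin_hz: float = 1.0
    roi_spec_path: str | None = None
    permutation_mode: str = "exhaustive"
    permutation_cap: int = 100_000
    permutation_seed: int = 0
    include_identity: bool = True
    alpha: float = 0.05
    ridge: float | None = None
    do_channels: bool = True
    do_frequency: bool = True
    do_roi: bool = True
    do_variates: bool = True

    def __post_init__(self) -> None:
        if self.lag_step_s <= 0:
            raise ConfigError("lag_step_s must be positive")
        if self.lag_start_s >= self.lag_stop_s:
            raise ConfigError("lag_start_s must be below lag_stop_s")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.permutation_mode not in ("exhaustive", "monte-carlo"):
            raise ConfigError("permutation_mode must be 'exhaustive' or 'monte-carlo'")
        if self.permutation_cap < 2:
            raise ConfigError("permutation_cap must be at least 2")
        if self.analysis_rate_hz <= 0:
            raise ConfigError("analysis_rate_hz must be positive")
        if self.freq_bin_hz <= 0:
            raise ConfigError("freq_bin_hz must be positive")

    def lag_grid(self) -> np.ndarray:
        return make_lag_grid(self.lag_start_s, self.lag_stop_s, self.lag_step_s)

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


def _ensembles_from_source(source: Any, config: AnalysisConfig
                           ) -> list[StimulusEnsemble]:
    """Accept ensembles, HDF5 paths, or a simulation manifest dict."""
    if isinstance(source, StimulusEnsemble):
        return [source]
    if isinstance(source, (list, tuple)):
        if all(isinstance(s, StimulusEnsemble) for s in source):
            return list(source)
        return [StimulusEnsemble.from_hdf5(str(p)) for p in source]
    if isinstance(source, str):
        return [StimulusEnsemble.from_hdf5(source)]
    if isinstance(source, dict):
        sim = dict(source)
        manifest_keys = set(PlantManifest.__dataclass_fields__)
        manifest = PlantManifest(**{k: sim.pop(k) for k in list(sim)
                                    if k in manifest_keys})
        sim.setdefault("fs", config.analysis_rate_hz)
        return [generate_ensemble(manifest, **sim)]
    raise ConfigError("input must be ensembles, HDF5 path(s), or a manifest dict")


def _assignments_for(n: int, k: int, observed, config: AnalysisConfig):
    exhaustive = (config.permutation_mode == "exhaustive"
                  and comb(n, k) <= config.permutation_cap)
    if exhaustive:
        return enumerate_group_exchanges(n, k, observed=observed)
    return sample_group_exchanges(n, k, config.permutation_cap,
                                  config.permutation_seed, observed=observed)


def run_analysis(config: AnalysisConfig, source: Any) -> dict[str, Any]:
    """Run the full pipeline on an ensemble container or simulation manifest."""
    ensembles = _ensembles_from_source(source, config)
    anova = ListenerAnova(ensembles)
    assignments = _assignments_for(anova.n_listeners, anova.group_size,
                                   anova.observed, config)
    results: dict[str, Any] = {"config": config.to_dict(),
                               "n_permutations": len(assignments)}

    dist_l = build_distribution(anova.r2, assignments)
    results["listener"] = {
        "r2": float(dist_l.observed),
        "delta_r2": float(bias_correct(dist_l,
                                       include_identity=config.include_identity)),
        "p": permutation_pvalue(dist_l),
    }
    if config.do_channels:
        ch = decompose_by_channel(ensembles, alpha=config.alpha)
        results["listener_channels"] = ch
    if config.do_frequency:
        fr = decompose_by_frequency(ensembles, bin_hz=config.freq_bin_hz,
                                    alpha=config.alpha)
        results["listener_frequency"] = fr

    curves = lag_scan_ensemble(ensembles, lags_s=config.lag_grid(),
                               ridge=config.ridge, assignments=assignments)
    results["coupling"] = {name: curve.to_dict()
                           for name, curve in curves.items()}
    peak_lag = curves["set"].peak_lag
    results["coupling"]["peak_lag_s"] = peak_lag
    sig = curves["set"].p_corrected <= config.alpha
    results["coupling"]["significant_lags_s"] = (
        curves["set"].lags_s[sig].tolist())

    if config.do_roi:
        rois = (ROISpec.from_yaml(config.roi_spec_path)
                if config.roi_spec_path else
                default_rois(next(iter(ensembles[0].listeners.values()))
                             .channel_names))
        results["roi"] = roi_scan(ensembles, rois, lag_s=peak_lag,
                                  ridge=config.ridge, assignments=assignments)
    if config.do_variates:
        variates = {}
        for ei, e in enumerate(ensembles):
            for sid in e.speaker_ids:
                spectrum = coupling_spectrum(e, peak_lag, speaker_id=sid,
                                             reg=config.ridge)
                variates[f"stimulus{ei}/{sid}"] = {
                    "count": count_significant_variates(spectrum,
                                                        alpha=config.alpha),
                    "r2_first": float(spectrum.correlations[0] ** 2),
                }
        results["variates"] = variates
    return results


_SECTIONS = ("listener", "coupling")


def make_report(results: dict[str, Any]) -> str:
    """Human-readable summary of a result bundle.

    Raises if required sections are missing, listing all of them.
    """
    missing = [s for s in _SECTIONS if s not in results]
    if missing:
        raise ValueError(f"incomplete results bundle; missing sections: {missing}")
    lines = ["Speaker-listener EEG coupling report",
             "=" * 38]
    li = results["listener"]
    lines.append(f"Listener content effect: delta R2_L = {li['delta_r2']:.4f} "
                 f"(raw R2 = {li['r2']:.4f}, p = {li['p']:.5g}, "
                 f"{results.get('n_permutations', '?')} permutations)")
    cp = results["coupling"]
    peak = cp["peak_lag_s"]
    set_curve = cp["set"]
    one_curve = cp.get("one_to_one")
    lines.append(f"Coupling peak: lag {peak:+.1f} s, "
                 f"delta R2_SL = {set_curve['peak_delta_r2']:.4f}")
    sig = cp.get("significant_lags_s") or []
    if sig:
        lines.append(f"Significant lags (corrected): "
                     + ", ".join(f"{s:+.1f}" for s in sig))
    else:
        lines.append("No lag reaches corrected significance.")
    lines.append("lag [s]   R2_SL     dR2_SL    p_corr" +
                 ("    dR2_1:1" if one_curve else ""))
    for i, lag in enumerate(set_curve["lags_s"]):
        mark = " <- peak" if lag == peak else ""
        row = (f"{lag:+7.1f}  {set_curve['r2'][i]:.5f}  "
               f"{(set_curve['delta_r2'] or set_curve['r2'])[i]:+.5f}  "
               f"{(set_curve['p_corrected'] or [float('nan')] * (i + 1))[i]:.4f}")
        if one_curve is not None and one_curve.get("delta_r2") is not None:
            row += f"  {one_curve['delta_r2'][i]:+.5f}"
        lines.append(row + mark)
    if "variates" in results:
        for key, v in results["variates"].items():
            lines.append(f"Canonical variates [{key}]: {v['count']} significant, "
                         f"r2_1 = {v['r2_first']:.4f}")
    if "roi" in results and "p_corrected" in results["roi"]:
        p = np.asarray(results["roi"]["p_corrected"])
        i, j = np.unravel_index(np.argmin(p), p.shape)
        lines.append(
            f"Strongest ROI pair: speaker {results['roi']['speaker_rois'][i]} "
            f"-> listener {results['roi']['listener_rois'][j]} "
            f"(p_corr = {p[i, j]:.4f})")
    return "\n".join(lines)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def save_results(results: dict[str, Any], path: str) -> None:
    """Serialize a result bundle to deterministic JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=1, sort_keys=True)
        fh.write("\n")
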