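"""End-to-end orchestration: events -> transitions -> mixtures -> report.

The full analysis mirrors the experimental workflow: restrict to calls,
build within-phase transitions, decompose log intervals into short/long
mixture components per condition, compare short components across
conditions by Monte-Carlo percentile intervals, rebuild everything on
the session-shuffled pseudo pairing, and model phase-wise call counts.
All randomness flows from one root seed through per-stage derived
seeds, so a report is reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import interval_mixture, mixture_compare, phase_counts, pseudo_pairing, transitions
from .events_io import Phase, SessionRecord, VocalType, filter_events, group_sessions, read_call_table
from .interval_mixture import GmmFit
from .mixture_compare import PercentileInterval
from .simulate import SimulationParams, simulate_experiment


class ConfigError(ValueError):
    pass


@dataclass
class PipelineReport:
    """Everything the analysis produced, with provenance."""

    seed: int
    config_hash: str
    input_digests: dict[str, str]
    n_sessions: int
    transition_counts: dict[str, int]
    overlap_count: int
    fraction_within: dict[str, float]
    gmm_fits: dict[str, GmmFit | None]
    comparisons: dict[str, PercentileInterval | None]
    pseudo_transition_counts: dict[str, int]
    pseudo_overlap_count: int
    pseudo_fraction_within: dict[str, float]
    pseudo_gmm: GmmFit | None
    count_table: list[dict[str, Any]]
    aic_table: list[dict[str, Any]]
    best_count_model: str
    fixed_effects: dict[str, float]
    random_intercept_variances: dict[str, float]
    excluded_intervals: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        def conv(obj):
            if obj is None or isinstance(obj, (int, float, str, bool)):
                return obj
            if dataclasses.is_dataclass(obj):
                d = dataclasses.asdict(obj)
                if isinstance(obj, PercentileInterval):
                    d["contains_zero"] = obj.contains_zero
                return {k: conv(v) for k, v in d.items()}
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            return str(obj)

        return {k: conv(v) for k, v in self.__dict__.items()}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _load_config(config_path: str | Path) -> tuple[dict, str]:
    path = Path(config_path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = path.read_bytes()
    cfg = yaml.safe_load(raw) or {}
    return cfg, hashlib.sha256(raw).hexdigest()


def _load_sessions(cfg: dict, seed: int) -> tuple[list[SessionRecord], dict[str, str]]:
    digests: dict[str, str] = {}
    if "simulation" in cfg:
        sim = cfg["simulation"] or {}
        params = SimulationParams(**sim.get("params", {}))
        phase_mult = {}
        if "f2f_rate_multiplier" in sim:
            phase_mult[Phase.F2F] = float(sim["f2f_rate_multiplier"])
        sessions = simulate_experiment(
            params,
            n_subjects=int(sim.get("n_subjects", 6)),
            sessions_per_pair=int(sim.get("sessions_per_pair", 4)),
            phase_rate_multipliers=phase_mult or None,
            subject_rate_sd=float(sim.get("subject_rate_sd", 0.0)),
            seed=seed,
        )
    elif "inputs" in cfg:
        path = Path(cfg["inputs"]["events_csv"])
        if not path.exists():
            raise ConfigError(f"input events table not found: {path}")
        digests[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()
        sessions = group_sessions(read_call_table(path, dialect="csv"))
    else:
        raise ConfigError("config must contain a 'simulation' or an 'inputs' block")
    return sessions, digests


def _pooled_intervals(
    sessions: list[SessionRecord], phase: Phase
) -> tuple[np.ndarray, np.ndarray, int]:
    """(exchange intervals, repeated intervals, overlaps) pooled over sessions."""
    blocks = [
        filter_events(rec.events_in(phase), vocal_type=VocalType.CALL)
        for rec in sessions
    ]
    trans = transitions.pooled_transitions(blocks)
    exchange, repeated = transitions.split_by_kind(trans)
    return (
        transitions.intervals(exchange),
        transitions.intervals(repeated),
        transitions.count_overlaps(trans),
    )


def _maybe_fit(values, seed: int) -> GmmFit | None:
    try:
        return interval_mixture.fit_intervals(values, seed=seed)
    except ValueError:
        return None


def _maybe_compare(fit_a, fit_b, seed, n_reps, level, label_a, label_b):
    if fit_a is None or fit_b is None:
        return None
    try:
        return mixture_compare.compare_conditions(
            fit_a, fit_b, "short", n_reps=n_reps, level=level, seed=seed,
            label_a=label_a, label_b=label_b,
        )
    except ValueError:
        # an unconverged fit refuses comparison; report the gap, not a guess
        return None


def run_full_analysis(
    config_path: str | Path,
    seed: int | None = None,
) -> PipelineReport:
    """Execute every stage on the configured inputs and collect a report."""
    cfg, cfg_hash = _load_config(config_path)
    root_seed = int(cfg.get("seed", 0) if seed is None else seed)
    stage_seed = {
        name: int(np.random.SeedSequence([root_seed, i]).generate_state(1)[0] % (2**31))
        for i, name in enumerate(["simulate", "gmm", "compare", "pseudo"])
    }
    analysis = cfg.get("analysis", {}) or {}
    n_reps = int(analysis.get("n_permutations", 10_000))
    level = float(analysis.get("percentile_level", 95.0))
    threshold = float(analysis.get("interval_threshold", 10.0))

    sessions, digests = _load_sessions(cfg, stage_seed["simulate"])

    # --- real-pairing transitions, per phase ---
    exch_f2f, rep_f2f, overlaps = _pooled_intervals(sessions, Phase.F2F)
    _, rep_pre, _ = _pooled_intervals(sessions, Phase.PRE)
    _, rep_post, _ = _pooled_intervals(sessions, Phase.POST)
    rep_solo = np.concatenate([rep_pre, rep_post])

    fits: dict[str, GmmFit | None] = {
        "exchange_f2f": _maybe_fit(exch_f2f, stage_seed["gmm"]),
        "repeated_f2f": _maybe_fit(rep_f2f, stage_seed["gmm"] + 1),
        "repeated_pre": _maybe_fit(rep_pre, stage_seed["gmm"] + 2),
        "repeated_post": _maybe_fit(rep_post, stage_seed["gmm"] + 3),
        "repeated_solo": _maybe_fit(rep_solo, stage_seed["gmm"] + 4),
    }
    comparisons = {
        "exchange_vs_repeated_f2f": _maybe_compare(
            fits["exchange_f2f"], fits["repeated_f2f"],
            stage_seed["compare"], n_reps, level, "exchange", "repeated",
        ),
        "f2f_vs_solo_repeated": _maybe_compare(
            fits["repeated_f2f"], fits["repeated_solo"],
            stage_seed["compare"] + 1, n_reps, level, "F2F", "solo",
        ),
        "pre_vs_post_repeated": _maybe_compare(
            fits["repeated_pre"], fits["repeated_post"],
            stage_seed["compare"] + 2, n_reps, level, "PRE", "POST",
        ),
    }

    # --- pseudo pairing null ---
    pseudo_sessions = pseudo_pairing.make_pseudo_sessions(sessions, seed=stage_seed["pseudo"])
    ps_exch, ps_rep, ps_overlaps = pseudo_pairing.pseudo_transition_analysis(pseudo_sessions)
    pseudo_fit = _maybe_fit(ps_exch, stage_seed["gmm"] + 5)

    # --- phase-wise call counts ---
    rows = phase_counts.count_calls_by_phase(sessions)
    fit_phase = phase_counts.fit_count_model(rows, include_phase=True)
    fit_null = phase_counts.fit_count_model(rows, include_phase=False)
    best, aic_table = phase_counts.select_model_aic([fit_phase, fit_null])

    return PipelineReport(
        seed=root_seed,
        config_hash=cfg_hash,
        input_digests=digests,
        n_sessions=len(sessions),
        transition_counts={"exchange": len(exch_f2f), "repeated": len(rep_f2f)},
        overlap_count=overlaps,
        fraction_within={
            f"exchange_f2f_within_{threshold:g}s": (
                transitions.fraction_within(exch_f2f, threshold) if exch_f2f.size else float("nan")
            ),
            f"repeated_f2f_within_{threshold:g}s": (
                transitions.fraction_within(rep_f2f, threshold) if rep_f2f.size else float("nan")
            ),
        },
        gmm_fits=fits,
        comparisons=comparisons,
        pseudo_transition_counts={"exchange": len(ps_exch), "repeated": len(ps_rep)},
        pseudo_overlap_count=ps_overlaps,
        pseudo_fraction_within={
            f"pseudo_exchange_within_{threshold:g}s": (
                transitions.fraction_within(ps_exch, threshold) if ps_exch.size else float("nan")
            ),
        },
        pseudo_gmm=pseudo_fit,
        count_table=phase_counts.counts_to_frame(rows).to_dict("records"),
        aic_table=aic_table.to_dict("records"),
        best_count_model="phase" if best.include_phase else "null",
        fixed_effects=fit_phase.fixed_effects,
        random_intercept_variances=fit_phase.random_intercept_variances,
        excluded_intervals={
            name: fit.n_excluded_nonpositive
            for name, fit in fits.items()
            if fit is not None
        },
    )


def write_report(report: PipelineReport, out_dir: str | Path, fmt: str = "json") -> Path:
    """Write the report and its tables under ``out_dir``; returns the report path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fits = {k: v for k, v in report.gmm_fits.items() if v is not None}
    if fits:
        interval_mixture.fits_to_table(fits).to_csv(out / "gmm_table.csv", index=False)
    import pandas as pd

    pd.DataFrame(report.count_table).to_csv(out / "counts.csv", index=False)
    pd.DataFrame(report.aic_table).to_csv(out / "aic_table.csv", index=False)
    if fmt == "json":
        path = out / "report.json"
        path.write_text(report.to_json() + "\n")
    else:
        path = out / "report.csv"
        flat = pd.json_normalize(report.to_dict(), sep=".")
        flat.T.to_csv(path, header=False)
    return path
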