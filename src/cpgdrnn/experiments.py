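"""End-to-end experiment orchestration on synthetic gait data.

Experiment 1 (proof of concept): train single-pattern networks at one walking
speed from pure sine inputs at the extracted harmonic frequencies (SEA) and
from detuned variants shifted +/- 0.25 Hz (SEB / SEC), and compare the best
similarity indices.  Experiment 2 (multi-pattern): train one network per
hidden-unit count on amplitude-modulated sine inputs at several learned
velocities, test prediction at unlearned intermediate velocities, and record
the emergent connectivity (inhibitory-weight fraction) and time-constant
statistics.  Synthetic generator seeds play the role the individual subjects
played in the original recordings.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import drnn_core, evaluation, synthetic_gait
from .drnn_core import DRNNParams, TrainingConfig, TrainingPattern
from .errors import EmptyReportError, InvalidConfigError
from .harmonic_features import (
    CycleSegment,
    HarmonicSpec,
    NormalizationRecord,
    build_sine_inputs,
    extract_trial_spec,
    normalize_targets,
    select_representative_cycles,
)
from .synthetic_gait import GaitGenConfig, generate_trial


def _derived_seed(*parts: int) -> int:
    """Deterministic sub-seed (< 2**31) from a tuple of integer tags."""
    return int(np.random.SeedSequence([int(p) for p in parts]).generate_state(1)[0] % (2**31))


@dataclass
class PreparedPattern:
    """A two-cycle training pattern with its provenance."""

    pattern: TrainingPattern
    segment: CycleSegment
    spec: HarmonicSpec
    record: NormalizationRecord
    velocity_kmh: float


def prepare_pattern(
    series: synthetic_gait.ElevationSeries,
    variant: str = "AM",
    input_gain: float = 1.0,
    washout_s: float = 1.0,
) -> PreparedPattern:
    """Reduce a trial to a representative two-cycle training pattern.

    The two-gait-cycle segment is chosen to preserve the full recording's FFT
    characteristics; its pooled harmonic spec defines the oscillator inputs
    (scaled by ``input_gain``), and the segment waveforms normalized onto
    [-1, 1] are the targets.  The oscillator drive starts ``washout_s``
    seconds before the scored window so the network is evaluated on its
    oscillatory regime rather than the cold-start transient.
    """
    segment = select_representative_cycles(series)
    spec = extract_trial_spec(segment)
    targets, record = normalize_targets(segment)
    washout_steps = int(round(washout_s * segment.sample_rate))
    grid = np.arange(-washout_steps, segment.data.shape[0]) / segment.sample_rate
    inputs = build_sine_inputs(spec, variant, grid)
    pattern = TrainingPattern(
        inputs=inputs.data * input_gain,
        targets=targets,
        Tc=segment.Tc,
        label=f"v={series.velocity_kmh:g}kmh/{variant}",
        washout_steps=washout_steps,
    )
    return PreparedPattern(
        pattern=pattern, segment=segment, spec=spec, record=record,
        velocity_kmh=series.velocity_kmh,
    )


@dataclass(frozen=True)
class Experiment1Config:
    """Single-pattern proof of concept at one walking speed."""

    velocity_kmh: float = 3.0
    n_hidden: int = 30
    n_iterations: int = 10_000
    n_restarts: int = 10
    variants: tuple[str, ...] = ("SEA", "SEB", "SEC")
    seeds: tuple[int, ...] = (0, 1, 2)
    sample_rate_hz: float = 100.0
    duration_s: float = 40.0
    noise_sd: float = 0.0
    cycle_jitter: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.variants or not set(self.variants) <= {"SEA", "SEB", "SEC"}:
            raise InvalidConfigError("variants must be a nonempty subset of SEA/SEB/SEC")


@dataclass(frozen=True)
class Experiment2Config:
    """Multi-pattern learning across velocities with a hidden-unit sweep."""

    learn_velocities: tuple[float, ...] = (1.5, 2.5, 3.5, 4.5, 5.5)
    predict_velocities: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
    hidden_sweep: tuple[int, ...] = (80,)
    n_iterations: int = 5_000
    n_restarts: int = 5
    seeds: tuple[int, ...] = (0,)
    sample_rate_hz: float = 100.0
    duration_s: float = 40.0
    noise_sd: float = 0.5
    cycle_jitter: float = 0.02
    master_seed: int = 0

    def __post_init__(self) -> None:
        if set(self.predict_velocities) & set(self.learn_velocities):
            raise InvalidConfigError("predict velocities must be disjoint from learned ones")
        if not self.hidden_sweep:
            raise InvalidConfigError("hidden_sweep must be nonempty")


@dataclass
class ExperimentResult:
    """Result tables plus the selected models and full config echo."""

    table: pd.DataFrame
    per_velocity: pd.DataFrame
    models: dict
    predictions: dict
    config: dict
    failures: list = field(default_factory=list)


def _gen_config(cfg, velocity: float, seed: int) -> GaitGenConfig:
    return GaitGenConfig(
        velocity_kmh=velocity,
        duration_s=cfg.duration_s,
        sample_rate_hz=cfg.sample_rate_hz,
        noise_sd=cfg.noise_sd,
        cycle_jitter=cfg.cycle_jitter,
        seed=seed,
    )


def _config_echo(cfg) -> dict:
    doc = dataclasses.asdict(cfg)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in doc.items()}


def run_experiment1(config: Experiment1Config | None = None) -> ExperimentResult:
    """Train best-of-restart networks per input variant and generator seed.

    A failure in one (seed, variant) cell is recorded and the remaining cells
    proceed.
    """
    cfg = config if config is not None else Experiment1Config()
    dt = 1.0 / cfg.sample_rate_hz
    rows = []
    models: dict = {}
    predictions: dict = {}
    failures: list = []
    for gen_seed in cfg.seeds:
        trial = generate_trial(_gen_config(cfg, cfg.velocity_kmh, gen_seed))
        for variant in cfg.variants:
            try:
                prep = prepare_pattern(trial, variant=variant)
                tc = TrainingConfig(
                    n_iterations=cfg.n_iterations,
                    n_restarts=cfg.n_restarts,
                    dt=dt,
                    seed=_derived_seed(cfg.master_seed, gen_seed, cfg.variants.index(variant)),
                )
                best, table = drnn_core.train_restarts(
                    [prep.pattern], cfg.n_hidden, tc
                )
                pred = drnn_core.predict(best, prep.pattern.inputs, dt=dt)[
                    prep.pattern.washout_steps :
                ]
                plane = evaluation.fit_covariation_plane(
                    pred[:, 0], pred[:, 1], pred[:, 2]
                )
                sel = table[table.selected].iloc[0]
                rows.append(
                    {
                        "seed": gen_seed,
                        "variant": variant,
                        "mean_si": float(sel.mean_si),
                        "loss": float(sel.loss),
                        "planarity": plane.planarity,
                        "f1_hz": prep.spec.f1,
                        "train_seed": tc.seed,
                    }
                )
                models[(gen_seed, variant)] = best
                predictions[(gen_seed, variant)] = {
                    "predicted": pred,
                    "target": prep.pattern.targets,
                    "Tc": prep.pattern.Tc,
                }
            except Exception as exc:  # per-cell isolation, sweep continues
                failures.append({"seed": gen_seed, "variant": variant, "error": repr(exc)})
    return ExperimentResult(
        table=pd.DataFrame(rows),
        per_velocity=pd.DataFrame(),
        models=models,
        predictions=predictions,
        config=_config_echo(cfg),
        failures=failures,
    )


def run_experiment2(config: Experiment2Config | None = None) -> ExperimentResult:
    """Multi-pattern training per hidden-unit count with velocity prediction.

    Per (seed, hidden) cell the table reports the best restart's mean learning
    SI, the mean prediction SI at the unlearned velocities, the inhibitory
    weight fraction and the median time constant.  Per-velocity SIs go into
    ``per_velocity``.
    """
    cfg = config if config is not None else Experiment2Config()
    dt = 1.0 / cfg.sample_rate_hz
    rows = []
    vel_rows = []
    models: dict = {}
    predictions: dict = {}
    failures: list = []
    for gen_seed in cfg.seeds:
        learn_preps = [
            prepare_pattern_for(cfg, v, gen_seed, gain=1.0) for v in cfg.learn_velocities
        ]
        # one global gain keeps the oscillator drive O(1) while preserving the
        # amplitude ratios across velocities that carry the speed information
        gain = 1.0 / max(max(p.spec.amplitudes) for p in learn_preps)
        for p in learn_preps:
            p.pattern.inputs = p.pattern.inputs * gain
        pred_preps = [
            prepare_pattern_for(cfg, v, gen_seed, gain=gain) for v in cfg.predict_velocities
        ]
        for hi, n_hidden in enumerate(cfg.hidden_sweep):
            try:
                tc = TrainingConfig(
                    n_iterations=cfg.n_iterations,
                    n_restarts=cfg.n_restarts,
                    dt=dt,
                    seed=_derived_seed(cfg.master_seed, gen_seed, hi),
                )
                best, table = drnn_core.train_restarts(
                    [p.pattern for p in learn_preps], n_hidden, tc
                )
                sel = table[table.selected].iloc[0]
                learn_sis = _per_pattern_si(best, learn_preps, dt)
                pred_sis = _per_pattern_si(best, pred_preps, dt)
                structure = evaluation.weight_sign_distribution(best)
                rows.append(
                    {
                        "seed": gen_seed,
                        "n_hidden": n_hidden,
                        "si_learn": float(np.mean([s for _, s in learn_sis])),
                        "si_predict": float(np.mean([s for _, s in pred_sis])),
                        "loss": float(sel.loss),
                        "frac_negative": structure.frac_negative,
                        "frac_positive": structure.frac_positive,
                        "T_median": structure.T_median,
                        "input_gain": gain,
                        "train_seed": tc.seed,
                    }
                )
                for phase, sis in (("learn", learn_sis), ("predict", pred_sis)):
                    for v, s in sis:
                        vel_rows.append(
                            {
                                "seed": gen_seed,
                                "n_hidden": n_hidden,
                                "velocity_kmh": v,
                                "phase": phase,
                                "si": s,
                            }
                        )
                models[(gen_seed, n_hidden)] = best
                predictions[(gen_seed, n_hidden)] = {
                    v: drnn_core.predict(best, p.pattern.inputs, dt=dt)[
                        p.pattern.washout_steps :
                    ]
                    for v, p in zip(cfg.predict_velocities, pred_preps)
                }
            except Exception as exc:
                failures.append({"seed": gen_seed, "n_hidden": n_hidden, "error": repr(exc)})
    return ExperimentResult(
        table=pd.DataFrame(rows),
        per_velocity=pd.DataFrame(vel_rows),
        models=models,
        predictions=predictions,
        config=_config_echo(cfg),
        failures=failures,
    )


def prepare_pattern_for(
    cfg: Experiment2Config | Experiment1Config, velocity: float, gen_seed: int, gain: float
) -> PreparedPattern:
    """Generate a trial at one velocity and reduce it to an AM pattern."""
    trial = generate_trial(_gen_config(cfg, velocity, gen_seed))
    return prepare_pattern(trial, variant="AM", input_gain=gain)


def _per_pattern_si(
    params: DRNNParams, preps: Sequence[PreparedPattern], dt: float
) -> list[tuple[float, float]]:
    out = []
    for prep in preps:
        pred = drnn_core.predict(params, prep.pattern.inputs, dt=dt)[
            prep.pattern.washout_steps :
        ]
        sis = [
            evaluation.similarity_index(
                prep.pattern.targets[:, c], pred[:, c], prep.pattern.Tc, dt
            )
            for c in range(6)
        ]
        out.append((prep.velocity_kmh, float(np.mean(sis))))
    return out


def make_report(
    results: ExperimentResult | Sequence[ExperimentResult],
    outdir: str | Path,
    figures: bool = True,
) -> Path:
    """Write a markdown summary (plus optional PNG figures) of one or more
    experiment results.  Regenerating from the same results is byte-stable."""
    if isinstance(results, ExperimentResult):
        results = [results]
    results = list(results)
    if not results or all(r.table.empty for r in results):
        raise EmptyReportError("no experiment results to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["# CPG-DRNN experiment report", ""]
    for k, res in enumerate(results):
        lines += [f"## Result set {k + 1}", "", "### Configuration", "",
                  "```json", json.dumps(res.config, indent=1, sort_keys=True), "```", ""]
        lines += ["### Summary table", "", "```", res.table.to_string(index=False), "```", ""]
        if not res.per_velocity.empty:
            lines += ["### Per-velocity similarity", "", "```",
                      res.per_velocity.to_string(index=False), "```", ""]
        if res.failures:
            lines += ["### Failures", "", "```", json.dumps(res.failures, indent=1), "```", ""]
        if figures:
            lines += _figures(res, outdir, k)
    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path


def _figures(res: ExperimentResult, outdir: Path, k: int) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lines = []
    if {"n_hidden", "si_learn"} <= set(res.table.columns) and len(res.table) > 0:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        agg = res.table.groupby("n_hidden")[["si_learn", "si_predict"]].median()
        ax.plot(agg.index, agg.si_learn, "o-", label="learning")
        ax.plot(agg.index, agg.si_predict, "s--", label="prediction")
        ax.set_xlabel("hidden units")
        ax.set_ylabel("mean SI")
        ax.legend()
        fig.tight_layout()
        name = f"si_vs_hidden_{k + 1}.png"
        fig.savefig(outdir / name, dpi=110)
        plt.close(fig)
        lines += [f"![SI vs hidden units]({name})", ""]
    if {"variant", "mean_si"} <= set(res.table.columns) and len(res.table) > 0:
        fig, ax = plt.subplots(figsize=(4.2, 3.2))
        agg = res.table.groupby("variant")["mean_si"].mean()
        ax.bar(agg.index, agg.values)
        ax.set_ylabel("best mean SI")
        fig.tight_layout()
        name = f"si_by_variant_{k + 1}.png"
        fig.savefig(outdir / name, dpi=110)
        plt.close(fig)
        lines += [f"![SI by input variant]({name})", ""]
    if "frac_negative" in res.table.columns and len(res.table) > 0:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        agg = res.table.groupby("n_hidden")[["frac_negative", "frac_positive"]].mean()
        ax.bar(np.arange(len(agg)) - 0.2, 100 * agg.frac_negative, 0.4, label="inhibitory")
        ax.bar(np.arange(len(agg)) + 0.2, 100 * agg.frac_positive, 0.4, label="excitatory")
        ax.set_xticks(np.arange(len(agg)), [str(i) for i in agg.index])
        ax.set_xlabel("hidden units")
        ax.set_ylabel("% of connections")
        ax.legend()
        fig.tight_layout()
        name = f"weight_signs_{k + 1}.png"
        fig.savefig(outdir / name, dpi=110)
        plt.close(fig)
        lines += [f"![Weight sign distribution]({name})", ""]
    return lines
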