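"""Synthetic listeners, threshold datasets, and full simulated experiments.

Two generator tiers:

* ``generate_threshold_dataset`` draws gain-reduction estimates directly
  from the hierarchical linear model the analysis fits (fixed effects +
  by-participant Gaussian random effects + residual noise).  It isolates
  the statistics: fitting its output should recover the generative
  coefficients.
* ``generate_full_experiment`` chains mechanistic listeners through the
  detection model and the adaptive staircase for every condition of the
  three experimental designs, producing run-level tables the whole
  pipeline can consume.

Defaults are the study conditions: 7 participants and 2 runs per condition
for the tonal design, 4 participants for the broadband-noise design;
fixed effects and variance components default to the fitted tonal-model
values; precursor level grids 20-90 dB SPL (on-frequency, 10-dB steps),
60-95 dB SPL (off-frequency, 5-dB steps) and 24-64 dB overall (broadband
noise, 10-dB steps, capped at 64 dB to stay below the middle-ear-muscle
reflex).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cochlea import (
    GainReductionRule,
    IOFunction,
    ListenerProfile,
    StimulusSpec,
    erb_bandwidth,
    level_per_erb,
    spectrum_level,
)
from .detection import TrialCondition, equally_effective_masker_level
from .staircase import EXP12_CONFIG, EXP3_CONFIG, StaircaseConfig, run_staircase
from .analysis import GainReductionPoint

__all__ = [
    "CohortParams",
    "TONAL_PARAMS",
    "BBN_PARAMS",
    "generate_cohort",
    "generate_threshold_dataset",
    "generate_full_experiment",
    "bbn_overall_to_db_per_erb",
]

SIGNAL_FREQ_KHZ = 4.0
OFF_FREQ_KHZ = 2.4
BBN_BAND = (80.0, 10_000.0)
BBN_LEVEL_CAP_DB = 64.0  # middle-ear-muscle-reflex guard

ON_TONE_GRID = tuple(np.arange(20.0, 91.0, 10.0))
OFF_TONE_GRID = tuple(np.arange(60.0, 96.0, 5.0))
BBN_OVERALL_GRID = tuple(np.arange(24.0, 65.0, 10.0))


def bbn_overall_to_db_per_erb(overall_dB: float,
                              signal_freq_kHz: float = SIGNAL_FREQ_KHZ) -> float:
    """Convert broadband-noise overall RMS level to the dB/ERB level at the
    signal place (spectrum level + 10 log10(ERB))."""
    sl = spectrum_level(overall_dB, *BBN_BAND)
    return level_per_erb(sl, erb_bandwidth(signal_freq_kHz))


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters for a synthetic cohort.

    Fixed effects and variance components parameterise the hierarchical
    model of gain reduction vs precursor level: per-class linear predictors
    with by-participant Gaussian intercepts (and optionally class offsets),
    plus residual run-to-run noise.
    """

    n_participants: int = 7
    runs_per_condition: int = 2
    intercept: float = -4.32
    level_slope: float = 0.33
    class_offsets: dict = field(default_factory=lambda: {"off_tone": -49.47})
    class_level_slopes: dict = field(default_factory=lambda: {"off_tone": 0.47})
    sd_participant_intercept: float = float(np.sqrt(31.23))
    sd_participant_class_offset: float = float(np.sqrt(16.18))
    intercept_class_corr: float = -0.02
    sd_residual: float = float(np.sqrt(11.98))
    on_tone_grid: tuple = ON_TONE_GRID
    off_tone_grid: tuple = OFF_TONE_GRID
    bbn_overall_grid: tuple = ()  # empty -> tonal design only

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("cohort must contain at least one participant")
        for sd in (self.sd_participant_intercept,
                   self.sd_participant_class_offset, self.sd_residual):
            if sd < 0:
                raise ValueError("SDs must be >= 0")
        if abs(self.intercept_class_corr) > 1:
            raise ValueError("|correlation| must be <= 1")
        if any(l > BBN_LEVEL_CAP_DB for l in self.bbn_overall_grid):
            raise ValueError(
                f"BBN overall levels must not exceed {BBN_LEVEL_CAP_DB} dB"
            )


# Tonal (two-class) design with the fitted tonal-model parameterisation.
TONAL_PARAMS = CohortParams()

# Broadband-noise (three-class) design: 4 participants, random intercepts
# only, with the fitted three-class parameterisation.
BBN_PARAMS = CohortParams(
    n_participants=4,
    intercept=-3.40,
    level_slope=0.29,
    class_offsets={"off_tone": -47.50, "bbn": 1.52},
    class_level_slopes={"off_tone": 0.46, "bbn": 0.11},
    sd_participant_intercept=float(np.sqrt(48.90)),
    sd_participant_class_offset=0.0,
    intercept_class_corr=0.0,
    sd_residual=float(np.sqrt(15.62)),
    bbn_overall_grid=BBN_OVERALL_GRID,
)


def generate_cohort(params: CohortParams, seed: Optional[int] = None
                    ) -> list[ListenerProfile]:
    """Sample mechanistic listeners: per-listener I/O function (gain
    35-50 dB, compression 0.2-0.5, breakpoint 30-45 dB SPL), quiet
    threshold 5-20 dB SPL, off-frequency attenuation, and a mechanistic
    gain-reduction rule.  The rule's implied level slopes are ``s`` for an
    off-frequency precursor and ``s * c`` on-frequency (above breakpoint).
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    listeners = []
    for i in range(params.n_participants):
        g = rng.uniform(35.0, 50.0)
        c = rng.uniform(0.2, 0.5)
        bp = rng.uniform(30.0, 45.0)
        io = IOFunction(gain_dB=g, compression_exponent=c, breakpoint_dB=bp)
        quiet = rng.uniform(5.0, 20.0)
        s = rng.uniform(0.7, 0.9)
        # elicitation floor set near the quiet-threshold place output so
        # moderate precursors elicit reduction without instant saturation
        e0 = io.output(quiet) + rng.uniform(5.0, 15.0)
        rule = GainReductionRule(mode="mechanistic", elicitation_slope_s=s,
                                 elicitation_floor_E0=e0,
                                 cap_dB=min(30.0, g))
        listeners.append(ListenerProfile.calibrated(
            id=f"S{i + 1:02d}", quiet_threshold_dB_SPL=quiet, io=io,
            off_freq_attenuation_dB=rng.uniform(7.0, 12.0),
            psychometric_spread_dB=4.0,
            run_noise_sd_dB=rng.uniform(0.8, 2.0),
            gain_rule=rule,
        ))
    return listeners


def _class_grids(params: CohortParams) -> list[tuple[str, np.ndarray]]:
    grids = [("on_tone", np.asarray(params.on_tone_grid, dtype=float)),
             ("off_tone", np.asarray(params.off_tone_grid, dtype=float))]
    if len(params.bbn_overall_grid):
        per_erb = np.array([bbn_overall_to_db_per_erb(l)
                            for l in params.bbn_overall_grid])
        grids.append(("bbn", per_erb))
    return grids


def generate_threshold_dataset(params: CohortParams, seed: Optional[int] = None
                               ) -> list[GainReductionPoint]:
    """Draw gain-reduction estimates directly from the hierarchical model.

    One point per (participant, class, level, run).  BBN levels are emitted
    in dB/ERB, tonal levels in dB SPL.  Negative estimates are kept (floor
    filtering belongs to the analysis stage).
    """
    rng = np.random.default_rng(seed)
    cov = np.array([
        [params.sd_participant_intercept ** 2,
         params.intercept_class_corr * params.sd_participant_intercept
         * params.sd_participant_class_offset],
        [params.intercept_class_corr * params.sd_participant_intercept
         * params.sd_participant_class_offset,
         params.sd_participant_class_offset ** 2],
    ])
    points = []
    for i in range(params.n_participants):
        u_int, u_cls = rng.multivariate_normal([0.0, 0.0], cov)
        for cls, grid in _class_grids(params):
            for level in grid:
                mu = params.intercept + params.level_slope * level + u_int
                if cls != "on_tone":
                    mu += (params.class_offsets.get(cls, 0.0)
                           + params.class_level_slopes.get(cls, 0.0) * level)
                    if cls == "off_tone":
                        mu += u_cls
                for _ in range(params.runs_per_condition):
                    est = mu + rng.normal(0.0, params.sd_residual)
                    points.append(GainReductionPoint(
                        participant=f"S{i + 1:02d}", precursor_class=cls,
                        level_dB=float(level), estimate_dB=float(est)))
    return points


@dataclass(frozen=True)
class ExperimentDesign:
    """Condition lists for a full simulated study."""

    gom_masker_levels: tuple = tuple(np.arange(30.0, 96.0, 10.0))
    matched_off_levels: tuple = (65.0, 75.0)
    precursor_level_grids: dict = field(default_factory=lambda: {
        "on_tone": ON_TONE_GRID,
        "off_tone": OFF_TONE_GRID,
        "bbn": BBN_OVERALL_GRID,
    })
    gom_precursor_level_dB: float = 40.0
    runs_per_condition: int = 2


def _signal(level: float = 0.0) -> StimulusSpec:
    return StimulusSpec.tone("signal", SIGNAL_FREQ_KHZ, max(level, 0.001),
                             duration_ms=6.0)


def _precursor(cls: str, level: float) -> StimulusSpec:
    if cls == "on_tone":
        return StimulusSpec.tone("precursor", SIGNAL_FREQ_KHZ, level)
    if cls == "off_tone":
        return StimulusSpec.tone("precursor", OFF_FREQ_KHZ, level)
    if cls == "bbn":
        return StimulusSpec.noise("precursor", level, *BBN_BAND)
    raise ValueError(f"unknown precursor class {cls!r}")


def generate_full_experiment(cohort: Iterable[ListenerProfile],
                             design: ExperimentDesign = ExperimentDesign(),
                             seed: int = 0,
                             staircase_cfgs: Optional[dict] = None,
                             ) -> dict[str, pd.DataFrame]:
    """Simulate the three designs end to end for every listener.

    Chains the listener model, detection model and staircase for each
    condition and run.  Returns run-level (``runs``), trial-level
    (``trials``) and derived gain-reduction (``gain_reduction_points``)
    tables.  QC failures are recorded, never dropped silently.
    Deterministic given ``seed``.
    """
    cfgs = {"exp1": EXP12_CONFIG, "exp2": EXP12_CONFIG, "exp3": EXP3_CONFIG}
    if staircase_cfgs:
        cfgs.update(staircase_cfgs)
    root = np.random.SeedSequence(seed)
    run_rows, trial_rows, gr_rows = [], [], []

    def do_run(listener: ListenerProfile, cond: TrialCondition,
               cfg: StaircaseConfig, run_seed: int, experiment: str) -> float:
        run = run_staircase(cond, listener, cfg, seed=run_seed)
        run_rows.append({
            "experiment": experiment, "participant": listener.id,
            "condition": cond.label, "estimate_dB": run.threshold_estimate_dB,
            "reversal_sd_dB": run.reversal_sd_dB, "qc_pass": run.qc_pass,
            "qc_reason": run.qc_reason, "seed": run_seed,
        })
        t = run.trials.copy()
        t.insert(0, "condition", cond.label)
        t.insert(0, "participant", listener.id)
        t.insert(0, "experiment", experiment)
        trial_rows.append(t)
        return run.threshold_estimate_dB

    for listener, child in zip(list(cohort), root.spawn(10_000)):
        seeds = iter(child.generate_state(100_000) % (2 ** 31))

        # --- Experiment 1: GOM with/without precursor + matched maskers
        gom_precursor = _precursor("on_tone", design.gom_precursor_level_dB)
        for lv in design.gom_masker_levels:
            masker = StimulusSpec.tone("masker", OFF_FREQ_KHZ, lv,
                                       duration_ms=20.0)
            for prec, tag in ((None, "masker_alone"), (gom_precursor, "with_precursor")):
                cond = TrialCondition(signal=_signal(), masker=masker,
                                      precursor=prec,
                                      label=f"gom_{lv:.0f}_{tag}")
                for _ in range(design.runs_per_condition):
                    do_run(listener, cond, cfgs["exp1"], int(next(seeds)), "exp1")
        for off_lv in design.matched_off_levels:
            off = StimulusSpec.tone("masker", OFF_FREQ_KHZ, off_lv,
                                    duration_ms=20.0)
            on_lv = equally_effective_masker_level(off, listener)
            on = StimulusSpec.tone("masker", SIGNAL_FREQ_KHZ, on_lv,
                                   duration_ms=20.0)
            for masker, mtag in ((off, "off"), (on, "on")):
                for prec, ptag in ((None, "alone"), (gom_precursor, "precursor")):
                    cond = TrialCondition(
                        signal=_signal(), masker=masker, precursor=prec,
                        label=f"matched_{off_lv:.0f}_{mtag}_{ptag}")
                    for _ in range(design.runs_per_condition):
                        do_run(listener, cond, cfgs["exp1"], int(next(seeds)), "exp1")

        # --- Experiments 2-3: precursor alone, signal threshold tracked
        quiet_cond = TrialCondition(signal=_signal(), label="quiet")
        quiet_runs = [do_run(listener, quiet_cond, cfgs["exp2"],
                             int(next(seeds)), "exp2")
                      for _ in range(design.runs_per_condition)]
        quiet = float(np.nanmean(quiet_runs))
        for cls, grid in design.precursor_level_grids.items():
            experiment = "exp3" if cls == "bbn" else "exp2"
            for lv in grid:
                prec = _precursor(cls, lv)
                cond = TrialCondition(signal=_signal(), precursor=prec,
                                      label=f"{cls}_{lv:.0f}")
                for _ in range(design.runs_per_condition):
                    est = do_run(listener, cond, cfgs[experiment],
                                 int(next(seeds)), experiment)
                    level_out = (bbn_overall_to_db_per_erb(lv)
                                 if cls == "bbn" else float(lv))
                    gr_rows.append({
                        "participant": listener.id, "precursor_class": cls,
                        "level_dB": level_out,
                        "level_overall_dB": float(lv),
                        "estimate_dB": est - quiet,
                    })

    return {
        "runs": pd.DataFrame(run_rows),
        "trials": pd.concat(trial_rows, ignore_index=True),
        "gain_reduction_points": pd.DataFrame(gr_rows),
    }
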