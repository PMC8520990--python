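"""High-level experiments composed from the library primitives.

These are the computations the analysis drivers, the command-line interface
and the reproduction script share: the summary-table t statistics, the
staircase convergence study, the hypothesis-discrimination contrast, and
the mixed-model parameter-recovery study.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .analysis import (
    fit_gain_reduction_lmm,
    floor_filter,
    holm_bonferroni,
    points_to_frame,
    pooled_t_from_summary,
    term_name,
)
from .cochlea import IOFunction, ListenerProfile, StimulusSpec
from .detection import (
    TrialCondition,
    equally_effective_masker_level,
    percent_correct_3ifc,
    predicted_threshold,
)
from .staircase import EXP12_CONFIG, run_staircase, staircase_asymptote
from .synthetic import (
    CohortParams,
    SIGNAL_FREQ_KHZ,
    OFF_FREQ_KHZ,
    generate_cohort,
    generate_threshold_dataset,
)
from .io import load_table1

__all__ = [
    "table1_statistics",
    "staircase_convergence",
    "hypothesis_discrimination",
    "lmm_recovery",
]


def table1_statistics(table: Optional[pd.DataFrame] = None,
                      alpha: float = 0.05) -> dict:
    """Recompute the equally-effective-masker t statistics from the summary
    table.

    Per participant and matched masker level: a one-tailed pooled-variance t
    comparing the off-frequency-with-precursor threshold against the
    on-frequency-with-precursor threshold, Holm-corrected within the family
    of per-participant tests.  Group test: one-tailed pooled t comparing
    per-participant mean precursor-induced shifts (averaged over the two
    matched levels) for off- vs on-frequency maskers.
    """
    df = table if table is not None else load_table1()
    rows = []
    for (part, pair), cell in df.groupby(["participant", "matched_pair"]):
        def grab(freq_on: bool, with_prec: bool) -> pd.Series:
            sel = cell[((cell["masker_freq_kHz"] == SIGNAL_FREQ_KHZ) == freq_on)
                       & ((cell["precursor_class"] != "none") == with_prec)]
            if len(sel) != 1:
                raise ValueError(f"expected one cell for {part}/{pair}, got {len(sel)}")
            return sel.iloc[0]

        off_p, on_p = grab(False, True), grab(True, True)
        t, dof, p = pooled_t_from_summary(
            off_p["mean_threshold_dB"], off_p["sd_dB"], int(off_p["n_runs"]),
            on_p["mean_threshold_dB"], on_p["sd_dB"], int(on_p["n_runs"]),
            tail="one")
        off_a, on_a = grab(False, False), grab(True, False)
        rows.append({
            "participant": part, "matched_level_dB": pair,
            "t": t, "df": dof, "p": p,
            "shift_off_dB": off_p["mean_threshold_dB"] - off_a["mean_threshold_dB"],
            "shift_on_dB": on_p["mean_threshold_dB"] - on_a["mean_threshold_dB"],
        })
    per = pd.DataFrame(rows).sort_values(["participant", "matched_level_dB"],
                                         ignore_index=True)
    reject, adj = holm_bonferroni(per["p"].to_numpy(), alpha=alpha)
    per["p_holm"] = adj
    per["significant"] = reject

    by_part = per.groupby("participant")[["shift_off_dB", "shift_on_dB"]].mean()
    off_sh, on_sh = by_part["shift_off_dB"], by_part["shift_on_dB"]
    t_g, df_g, p_g = pooled_t_from_summary(
        off_sh.mean(), off_sh.std(ddof=1), len(off_sh),
        on_sh.mean(), on_sh.std(ddof=1), len(on_sh), tail="one")
    return {
        "per_participant": per,
        "group": {"t": t_g, "df": df_g, "p": p_g,
                  "mean_shift_off_dB": float(off_sh.mean()),
                  "mean_shift_on_dB": float(on_sh.mean())},
    }


def staircase_convergence(n_runs: int = 200, seed: int = 0,
                          quiet_threshold: float = 12.0,
                          spread_dB: float = 4.0) -> dict:
    """Simulate many 50-trial 2-down/1-up signal tracks in quiet on a
    listener with a known Gaussian psychometric function and evaluate that
    function's percent correct at the mean threshold estimate; compare the
    simulator mean with the exact Markov-chain asymptote."""
    io = IOFunction(gain_dB=40.0, compression_exponent=0.3, breakpoint_dB=40.0)
    listener = ListenerProfile.calibrated(
        "conv", quiet_threshold, io, psychometric_spread_dB=spread_dB,
        run_noise_sd_dB=0.0)
    cond = TrialCondition(signal=StimulusSpec.tone("signal", SIGNAL_FREQ_KHZ,
                                                   30.0, duration_ms=6.0),
                          label="quiet")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2 ** 31, size=n_runs)
    ests = []
    for s in run_seeds:
        run = run_staircase(cond, listener, EXP12_CONFIG, seed=int(s))
        if np.isfinite(run.threshold_estimate_dB):
            ests.append(run.threshold_estimate_dB)
    mean_est = float(np.mean(ests))
    pc = percent_correct_3ifc(mean_est, quiet_threshold, spread_dB)
    oracle = staircase_asymptote(
        lambda l: percent_correct_3ifc(l, quiet_threshold, spread_dB),
        quiet_threshold - 20.0, quiet_threshold + 20.0, step_dB=2.0)
    return {"mean_estimate_dB": mean_est, "percent_correct": 100.0 * pc,
            "oracle_mean_dB": oracle, "n_runs": len(ests),
            "true_threshold_dB": quiet_threshold}


def hypothesis_discrimination(n_listeners: int = 7, seed: int = 0,
                              off_masker_level: float = 65.0,
                              precursor_level: float = 40.0) -> pd.DataFrame:
    """Predicted threshold shifts for equally effective on-/off-frequency
    maskers when an on-frequency precursor is added, under both hypotheses.

    Under gain reduction the off-frequency shift exceeds the on-frequency
    shift for every listener with nonzero elicited gain reduction; under
    additivity the shifts are identical by construction.
    """
    cohort = generate_cohort(CohortParams(n_participants=n_listeners), seed=seed)
    signal = StimulusSpec.tone("signal", SIGNAL_FREQ_KHZ, 30.0, duration_ms=6.0)
    prec = StimulusSpec.tone("precursor", SIGNAL_FREQ_KHZ, precursor_level)
    rows = []
    for listener in cohort:
        off = StimulusSpec.tone("masker", OFF_FREQ_KHZ, off_masker_level,
                                duration_ms=20.0)
        on_lv = equally_effective_masker_level(off, listener)
        on = StimulusSpec.tone("masker", SIGNAL_FREQ_KHZ, on_lv, duration_ms=20.0)
        rec = {"participant": listener.id, "on_masker_level_dB": on_lv}
        from .cochlea import elicited_gain_reduction
        rec["delta_g_dB"] = elicited_gain_reduction(prec, listener)
        for hyp in ("gain_reduction", "additivity"):
            for masker, tag in ((off, "off"), (on, "on")):
                base = predicted_threshold(
                    TrialCondition(signal=signal, masker=masker), listener, hyp)
                shifted = predicted_threshold(
                    TrialCondition(signal=signal, masker=masker, precursor=prec),
                    listener, hyp)
                rec[f"{hyp}_shift_{tag}_dB"] = shifted - base
        rows.append(rec)
    return pd.DataFrame(rows)


def lmm_recovery(params: CohortParams, n_cohorts: int = 50, seed: int = 0,
                 random_structure: str = "slopes") -> dict:
    """Repeatedly generate cohorts from the hierarchical model, floor-filter
    (> 4 dB), fit the mixed model and average the fixed effects."""
    rng = np.random.default_rng(seed)
    coef_rows = []
    for _ in range(n_cohorts):
        pts = generate_threshold_dataset(params, seed=int(rng.integers(2 ** 31)))
        kept = floor_filter(pts, 4.0)
        res = fit_gain_reduction_lmm(points_to_frame(kept),
                                     random_structure=random_structure)
        coef_rows.append({t: res.coef(t) for t in res.fixed_effects["term"]})
    coefs = pd.DataFrame(coef_rows)
    out = {"mean_coefficients": coefs.mean().to_dict(),
           "sd_coefficients": coefs.std(ddof=1).to_dict(),
           "n_cohorts": n_cohorts}
    out["level_slope"] = float(coefs[term_name()].mean())
    off_int = term_name("off_tone", with_level=True)
    if off_int in coefs:
        out["level_x_off_tone"] = float(coefs[off_int].mean())
    bbn_int = term_name("bbn", with_level=True)
    if bbn_int in coefs:
        out["level_x_bbn"] = float(coefs[bbn_int].mean())
    return out
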