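"""Estimation pipeline for behavioural gain-reduction data.

Covers the full analysis chain: growth-of-masking (GOM) table assembly,
gain-reduction estimates (threshold with precursor minus quiet threshold),
precursor-induced threshold shifts for equally effective maskers,
summary-statistic t-tests with Holm-Bonferroni correction, floor filtering,
and linear mixed-effects models of gain reduction versus precursor level
and frequency class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "SummaryCondition",
    "GainReductionPoint",
    "LMMResult",
    "gain_reduction_estimate",
    "precursor_shift",
    "pooled_t_from_summary",
    "holm_bonferroni",
    "floor_filter",
    "assemble_gom",
    "fit_gain_reduction_lmm",
]

PRECURSOR_CLASSES = ("none", "on_tone", "off_tone", "bbn")


@dataclass(frozen=True)
class SummaryCondition:
    """Per-condition summary: mean threshold, SD, and run count."""

    participant: str
    mean_threshold_dB: float
    sd_dB: float
    n_runs: int
    masker_freq_kHz: Optional[float] = None
    masker_level_dB: Optional[float] = None
    precursor_class: str = "none"
    precursor_level_dB: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sd_dB < 0:
            raise ValueError("SD must be >= 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.precursor_class not in PRECURSOR_CLASSES:
            raise ValueError(f"unknown precursor class {self.precursor_class!r}")


@dataclass(frozen=True)
class GainReductionPoint:
    """One gain-reduction estimate: (participant, precursor class, level).

    ``level_dB`` is dB SPL for tonal precursors and dB/ERB for broadband
    noise."""

    participant: str
    precursor_class: str
    level_dB: float
    estimate_dB: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.level_dB):
            raise ValueError("precursor level must be finite")


@dataclass
class LMMResult:
    """Fitted mixed-model summary: fixed effects and variance components."""

    fixed_effects: pd.DataFrame  # term, estimate, se, t, df, p
    variance_components: dict[str, float]
    method: str = "REML"
    df_method: str = "residual"  # Satterthwaite unavailable in the backend
    converged: bool = True
    singular: bool = False

    def coef(self, term: str) -> float:
        row = self.fixed_effects.loc[self.fixed_effects["term"] == term]
        if row.empty:
            raise KeyError(f"no fixed effect named {term!r}; "
                           f"have {list(self.fixed_effects['term'])}")
        return float(row["estimate"].iloc[0])


def gain_reduction_estimate(threshold_with_precursor_dB: float,
                            quiet_threshold_dB: float) -> float:
    """Estimated gain reduction: signal threshold with precursor (no masker)
    minus quiet threshold.  Not clamped; floor filtering is done later."""
    if not (np.isfinite(threshold_with_precursor_dB)
            and np.isfinite(quiet_threshold_dB)):
        raise ValueError("thresholds must be finite")
    return float(threshold_with_precursor_dB - quiet_threshold_dB)


def precursor_shift(with_precursor: SummaryCondition,
                    masker_alone: SummaryCondition) -> float:
    """Mean threshold shift caused by adding a precursor to a fixed masker
    condition (same participant, masker frequency and level)."""
    same = (with_precursor.participant == masker_alone.participant
            and with_precursor.masker_freq_kHz == masker_alone.masker_freq_kHz
            and with_precursor.masker_level_dB == masker_alone.masker_level_dB)
    if not same:
        raise ValueError(
            "conditions do not describe the same participant/masker: "
            f"{with_precursor} vs {masker_alone}"
        )
    return float(with_precursor.mean_threshold_dB - masker_alone.mean_threshold_dB)


def pooled_t_from_summary(m1: float, s1: float, n1: int,
                          m2: float, s2: float, n2: int,
                          tail: Literal["one", "two"] = "one"
                          ) -> tuple[float, int, float]:
    """Student's pooled-variance two-sample t-test from summary statistics.

    Returns ``(t, df, p)`` with ``df = n1 + n2 - 2``.  The one-tailed p is
    the upper-tail probability of ``t`` (testing mean1 > mean2).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    if sp2 == 0:
        if m1 == m2:
            raise ZeroDivisionError("pooled variance 0 with equal means: t undefined")
        t = np.inf if m1 > m2 else -np.inf
    else:
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if tail == "one":
        p = float(sps.t.sf(t, df))
    else:
        p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), df, p


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Holm's step-down multiple-comparison procedure.

    Returns ``(reject, adjusted_p)`` aligned with the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        adj = min((m - rank) * p[idx], 1.0)
        running_max = max(running_max, adj)
        adjusted[idx] = running_max
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] < alpha / (m - rank):
            reject[idx] = True
        else:
            break  # step-down procedure stops at the first failure
    return reject, adjusted


def floor_filter(points: Iterable[GainReductionPoint], min_dB: float = 4.0
                 ) -> list[GainReductionPoint]:
    """Keep points whose estimated gain reduction strictly exceeds
    ``min_dB`` (removes floor effects that would flatten level slopes)."""
    return [p for p in points if p.estimate_dB > min_dB]


def points_to_frame(points: Iterable[GainReductionPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.participant, p.precursor_class, p.level_dB, p.estimate_dB)
         for p in points],
        columns=["participant", "precursor_class", "level_dB", "estimate_dB"],
    )


def assemble_gom(conditions: Iterable[SummaryCondition]) -> pd.DataFrame:
    """Growth-of-masking table per participant.

    Rows sorted by masker level; no-precursor and with-precursor means
    paired side by side; masker-absent rows (``masker_level_dB`` None)
    carried with a null masker level as the quiet/precursor-alone anchors.
    """
    conds = list(conditions)
    freqs = {c.masker_freq_kHz for c in conds if c.masker_freq_kHz is not None}
    if len(freqs) > 1:
        raise ValueError(f"conditions mix masker frequencies: {sorted(freqs)}")
    seen = set()
    for c in conds:
        key = (c.participant, c.masker_level_dB, c.precursor_class)
        if key in seen:
            raise ValueError(f"duplicate GOM cell: {key}")
        seen.add(key)
    rows = []
    participants = sorted({c.participant for c in conds})
    for part in participants:
        mine = [c for c in conds if c.participant == part]
        levels = sorted({c.masker_level_dB for c in mine},
                        key=lambda x: (x is not None, x))
        for lv in levels:
            without = next((c for c in mine if c.masker_level_dB == lv
                            and c.precursor_class == "none"), None)
            withp = next((c for c in mine if c.masker_level_dB == lv
                          and c.precursor_class != "none"), None)
            rows.append({
                "participant": part,
                "masker_level_dB": lv,
                "threshold_no_precursor_dB":
                    without.mean_threshold_dB if without else np.nan,
                "threshold_with_precursor_dB":
                    withp.mean_threshold_dB if withp else np.nan,
            })
    df = pd.DataFrame(rows)
    df["shift_dB"] = (df["threshold_with_precursor_dB"]
                      - df["threshold_no_precursor_dB"])
    return df


_REFERENCE = "on_tone"
_CLS = f"C(precursor_class, Treatment('{_REFERENCE}'))"


def term_name(cls: Optional[str] = None, with_level: bool = False) -> str:
    """statsmodels term name for a class offset or level x class
    interaction in the fitted gain-reduction model."""
    if cls is None:
        return "level_dB"
    base = f"{_CLS}[T.{cls}]"
    return f"level_dB:{base}" if with_level else base


def fit_gain_reduction_lmm(points: Iterable[GainReductionPoint],
                           random_structure: Literal["slopes", "intercepts"] = "slopes",
                           ) -> LMMResult:
    """Fit estimated gain reduction ~ level * precursor class, with
    by-participant random effects, by REML.

    ``random_structure='slopes'`` adds by-participant random offsets for the
    precursor class (the two-class tonal model); ``'intercepts'`` fits
    random intercepts only (the three-class model including broadband
    noise).  The reference class is the on-frequency tone; the level
    covariate is uncentred dB.  Degrees of freedom use a residual
    approximation (flagged in the result).
    """
    df = points if isinstance(points, pd.DataFrame) else points_to_frame(points)
    if df["participant"].nunique() < 2:
        raise ValueError("need at least two participants for a mixed model")
    if _REFERENCE not in set(df["precursor_class"]):
        raise ValueError(f"reference class {_REFERENCE!r} absent from data")

    formula = f"estimate_dB ~ level_dB * {_CLS}"
    re_formula = f"1 + {_CLS}" if random_structure == "slopes" else "1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["participant"],
                            re_formula=re_formula)
        fit = model.fit(reml=True)
        bse_fe = fit.bse_fe  # may warn on degenerate (zero-variance) fits

    k_fixed = len(fit.fe_params)
    resid_df = max(len(df) - k_fixed - df["participant"].nunique(), 1)
    terms = list(fit.fe_params.index)
    rows = []
    for t in terms:
        est = float(fit.fe_params[t])
        se = float(bse_fe[t])
        tval = est / se if se > 0 else np.nan
        p = float(2.0 * sps.t.sf(abs(tval), resid_df))
        rows.append((t, est, se, tval, resid_df, p))
    fixed = pd.DataFrame(rows, columns=["term", "estimate", "se", "t", "df", "p"])

    vc: dict[str, float] = {"residual_var": float(fit.scale)}
    cov_re = np.asarray(fit.cov_re)
    re_names = list(fit.cov_re.index)
    for i, name in enumerate(re_names):
        vc[f"var({name})"] = float(cov_re[i, i])
    if len(re_names) == 2:
        denom = np.sqrt(cov_re[0, 0] * cov_re[1, 1])
        vc["corr"] = float(cov_re[0, 1] / denom) if denom > 0 else np.nan

    singular = bool(np.any(np.diag(cov_re) < 1e-8))
    return LMMResult(fixed_effects=fixed, variance_components=vc,
                     method="REML", df_method="residual",
                     converged=bool(fit.converged), singular=singular)
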