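"""Power-spectrum-model detection stage.

Detection of a brief on-frequency signal in forward masking is modelled as a
criterion signal-to-masker ratio (SMR, ``K`` dB) at the output of the
auditory filter at the signal place.  Two competing accounts of what a
precursor does are implemented:

* ``gain_reduction`` — the precursor reduces the low-level gain of the
  cochlear I/O function; the signal (and an on-frequency masker) pass
  through the reduced curve, while an off-frequency masker, processed
  linearly at the signal place, is untouched.  Equally effective on- and
  off-frequency maskers therefore diverge when a precursor is added.
* ``additivity`` — the I/O function is static and the compressed intensities
  of masker and precursor add; the predicted shift is identical for equally
  effective maskers regardless of frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

from scipy.stats import norm

from .cochlea import (
    IOFunction,
    ListenerProfile,
    StimulusSpec,
    elicited_gain_reduction,
    io_output,
    is_on_frequency,
    place_excitation,
)

__all__ = [
    "TrialCondition",
    "predicted_threshold",
    "equally_effective_masker_level",
    "percent_correct_3ifc",
    "LEVEL_FLOOR_DB",
    "LEVEL_CEIL_DB",
]

LEVEL_FLOOR_DB = -20.0
LEVEL_CEIL_DB = 120.0
_BISECT_TOL_DB = 0.01

# Anchors the Gaussian psychometric so that p(true threshold) = 0.707
# exactly: 1/3 + (2/3) * Phi(z0) = 0.707.
_Z0 = float(norm.ppf((0.707 - 1.0 / 3.0) / (2.0 / 3.0)))

Hypothesis = Literal["gain_reduction", "additivity"]


@dataclass(frozen=True)
class TrialCondition:
    """Stimulus configuration of one forward-masking trial."""

    signal: StimulusSpec
    masker: Optional[StimulusSpec] = None
    precursor: Optional[StimulusSpec] = None
    background_noise: bool = True  # high-pass noise flag, metadata only
    label: str = ""

    def __post_init__(self) -> None:
        if self.signal.role != "signal":
            raise ValueError("signal stimulus must have role 'signal'")
        if self.masker is not None and self.masker.role != "masker":
            raise ValueError("masker stimulus must have role 'masker'")
        if self.precursor is not None and self.precursor.role != "precursor":
            raise ValueError("precursor stimulus must have role 'precursor'")


def _power_sum(*levels_dB: float) -> float:
    return 10.0 * math.log10(sum(10.0 ** (l / 10.0) for l in levels_dB))


def predicted_threshold(cond: TrialCondition, listener: ListenerProfile,
                        hypothesis: Hypothesis = "gain_reduction") -> float:
    """Signal level (dB SPL) at the criterion SMR under the given hypothesis.

    The threshold is the lowest signal level whose place output reaches
    ``K`` dB above the intensity sum of the effective masker excitation and
    the internal noise floor.  Saturates at the search bounds
    ``[-20, 120]`` dB SPL if the criterion is unreachable.
    """
    f_sig = cond.signal.frequency_kHz
    io_full = listener.io
    n0 = listener.internal_noise_dB
    k = listener.criterion_smr_dB

    if hypothesis == "gain_reduction":
        dg = (elicited_gain_reduction(cond.precursor, listener, f_sig)
              if cond.precursor is not None else 0.0)
        io_sig = io_full.reduced(dg)
        if cond.masker is None:
            em = None
        else:
            # on-frequency maskers ride the reduced curve; off-frequency
            # maskers take the linear path and keep their effectiveness
            em = place_excitation(cond.masker, f_sig, listener,
                                  gain_reduced_io=io_sig)
        target = _power_sum(em, n0) + k if em is not None else n0 + k
    elif hypothesis == "additivity":
        io_sig = io_full
        parts = []
        if cond.masker is not None:
            parts.append(place_excitation(cond.masker, f_sig, listener))
        if cond.precursor is not None and cond.precursor.kind != "silence":
            parts.append(place_excitation(cond.precursor, f_sig, listener))
        em_eff = _power_sum(*parts) if parts else None
        target = _power_sum(em_eff, n0) + k if em_eff is not None else n0 + k
    else:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")

    # io_sig is strictly increasing: bisect for io_sig(L) = target
    lo, hi = LEVEL_FLOOR_DB, LEVEL_CEIL_DB
    if io_output(hi, io_sig) < target:
        return hi
    if io_output(lo, io_sig) >= target:
        threshold = lo
    else:
        while hi - lo > _BISECT_TOL_DB:
            mid = 0.5 * (lo + hi)
            if io_output(mid, io_sig) >= target:
                hi = mid
            else:
                lo = mid
        threshold = hi
    # never below the (possibly gain-reduced) quiet threshold
    quiet_target = n0 + k
    if io_output(threshold, io_sig) < quiet_target:
        threshold = io_sig.inverse(quiet_target)
    return float(threshold)


def equally_effective_masker_level(off_masker: StimulusSpec,
                                   listener: ListenerProfile,
                                   signal_freq_kHz: float = 4.0) -> float:
    """On-frequency masker level matching the off-frequency masker's place
    excitation, so both produce the same signal threshold without a precursor.

    Solves ``io(L_on) = L_off - A`` by bisection to 0.01 dB.
    """
    if is_on_frequency(off_masker.frequency_kHz, signal_freq_kHz):
        raise ValueError("masker to match must be off-frequency")
    target = off_masker.level_dB_SPL - listener.off_freq_attenuation_dB
    io = listener.io
    lo, hi = LEVEL_FLOOR_DB, LEVEL_CEIL_DB
    if io_output(lo, io) > target or io_output(hi, io) < target:
        raise ValueError(
            f"no on-frequency level in [{lo}, {hi}] dB SPL matches place "
            f"excitation {target:.2f} dB"
        )
    while hi - lo > _BISECT_TOL_DB:
        mid = 0.5 * (lo + hi)
        if io_output(mid, io) >= target:
            hi = mid
        else:
            lo = mid
    return float(0.5 * (lo + hi))


def percent_correct_3ifc(signal_level_dB: float, true_threshold_dB: float,
                         spread_dB: float) -> float:
    """Probability correct in a 3-interval forced-choice detection task.

    Gaussian-CDF psychometric with guessing rate 1/3, anchored so that the
    probability at the true threshold is exactly 0.707 (the level the
    2-down/1-up rule tracks).
    """
    if spread_dB <= 0:
        raise ValueError(f"psychometric spread must be positive, got {spread_dB}")
    z = (signal_level_dB - true_threshold_dB) / spread_dB + _Z0
    return float(1.0 / 3.0 + (2.0 / 3.0) * norm.cdf(z))
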