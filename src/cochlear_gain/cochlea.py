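"""Cochlear-place computations.

The model of the cochlear response at the signal place is a two-segment
("broken-stick") input-output (I/O) function: linear with gain ``G`` below a
breakpoint ``BP``, compressive with slope ``c`` above it.  Preceding sound
(a *precursor*) elicits the medial olivocochlear reflex, which reduces the
low-level gain by an amount ``delta_g`` (dB).  The reduction pivots the
breakpoint so that the high-level, compressive segment is unchanged — the
curves converge at high levels.

Stimuli reaching the signal place are mapped to a place output level:

* an on-frequency tone (within one equivalent rectangular bandwidth of the
  signal frequency) passes through the I/O function;
* an off-frequency tone is processed linearly, attenuated by a fixed
  per-listener amount ``A`` and untouched by gain reduction;
* a broadband noise contributes the level falling within one ERB at the
  signal place (spectrum level + 10 log10(ERB)), passed through the I/O
  function.

All levels are dB SPL unless explicitly labelled spectrum level or dB/ERB;
all logarithms are base 10.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Optional

__all__ = [
    "IOFunction",
    "StimulusSpec",
    "GainReductionRule",
    "ListenerProfile",
    "erb_bandwidth",
    "spectrum_level",
    "level_per_erb",
    "io_output",
    "apply_gain_reduction",
    "place_excitation",
    "elicited_gain_reduction",
]


def erb_bandwidth(frequency_kHz: float) -> float:
    """Equivalent rectangular bandwidth (Hz) of the auditory filter at
    ``frequency_kHz`` (kHz): ``24.7 * (4.37 * F + 1)``."""
    if frequency_kHz <= 0:
        raise ValueError(f"frequency must be positive, got {frequency_kHz}")
    return 24.7 * (4.37 * frequency_kHz + 1.0)


def spectrum_level(overall_dB: float, band_low_Hz: float, band_high_Hz: float) -> float:
    """Spectrum level (dB/Hz) of a flat-spectrum noise with the given overall
    RMS level and band edges."""
    width = band_high_Hz - band_low_Hz
    if width <= 0:
        raise ValueError(f"empty noise band: [{band_low_Hz}, {band_high_Hz}] Hz")
    return overall_dB - 10.0 * math.log10(width)


def level_per_erb(spectrum_level_dB: float, erb_Hz: float) -> float:
    """Level of noise falling within one ERB: ``SL + 10 log10(ERB)``."""
    if erb_Hz <= 0:
        raise ValueError(f"bandwidth must be positive, got {erb_Hz}")
    return spectrum_level_dB + 10.0 * math.log10(erb_Hz)


@dataclass(frozen=True)
class IOFunction:
    """Two-segment cochlear input-output function.

    Parameters
    ----------
    gain_dB : float
        Low-level gain ``G`` (dB), applied below the breakpoint.
    compression_exponent : float
        Slope ``c`` of the compressive segment, ``0 < c <= 1``.
    breakpoint_dB : float
        Input level ``BP`` (dB SPL) where compression begins.
    """

    gain_dB: float
    compression_exponent: float
    breakpoint_dB: float

    def __post_init__(self) -> None:
        if self.gain_dB < 0:
            raise ValueError(f"gain must be >= 0, got {self.gain_dB}")
        if not (0.0 < self.compression_exponent <= 1.0):
            raise ValueError(
                f"compression exponent must be in (0, 1], got {self.compression_exponent}"
            )
        if not math.isfinite(self.breakpoint_dB):
            raise ValueError("breakpoint must be finite")

    def output(self, input_dB: float) -> float:
        return io_output(input_dB, self)

    def inverse(self, output_dB: float) -> float:
        """Input level producing ``output_dB`` (exact piecewise inversion)."""
        knee_out = self.breakpoint_dB + self.gain_dB
        if output_dB <= knee_out:
            return output_dB - self.gain_dB
        return self.breakpoint_dB + (output_dB - knee_out) / self.compression_exponent

    def reduced(self, delta_g: float) -> "IOFunction":
        return apply_gain_reduction(self, delta_g)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "IOFunction":
        return cls(**json.loads(payload))


def io_output(input_dB: float, io: IOFunction) -> float:
    """Place output (dB) of the two-segment I/O function at ``input_dB``."""
    if input_dB < io.breakpoint_dB:
        return input_dB + io.gain_dB
    return (
        io.breakpoint_dB
        + io.gain_dB
        + io.compression_exponent * (input_dB - io.breakpoint_dB)
    )


def apply_gain_reduction(io: IOFunction, delta_g: float) -> IOFunction:
    """Return the I/O function with low-level gain reduced by ``delta_g`` dB.

    The breakpoint moves up to ``BP + delta_g / (1 - c)`` so the compressive
    segment is unchanged: outputs above the new breakpoint are identical to
    the full-gain curve, outputs below the original breakpoint drop by
    exactly ``delta_g``.  For ``c == 1`` the two segments are parallel and
    the curve simply loses ``delta_g`` of gain everywhere below ``BP``.
    """
    if delta_g < 0 or delta_g > io.gain_dB:
        raise ValueError(
            f"delta_g must be in [0, {io.gain_dB}] dB, got {delta_g}"
        )
    if delta_g == 0:
        return io
    c = io.compression_exponent
    if c == 1.0:
        new_bp = io.breakpoint_dB
    else:
        new_bp = io.breakpoint_dB + delta_g / (1.0 - c)
    return IOFunction(
        gain_dB=io.gain_dB - delta_g,
        compression_exponent=c,
        breakpoint_dB=new_bp,
    )


StimulusRole = Literal["precursor", "masker", "signal", "none"]
StimulusKind = Literal["tone", "broadband_noise", "silence"]


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus component: a tone, a broadband noise, or silence."""

    role: StimulusRole
    kind: StimulusKind
    level_dB_SPL: float = 0.0
    duration_ms: float = 0.0
    frequency_kHz: Optional[float] = None
    band_low_Hz: Optional[float] = None
    band_high_Hz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "tone":
            if self.frequency_kHz is None or self.frequency_kHz <= 0:
                raise ValueError("tone requires a positive frequency_kHz")
        elif self.kind == "broadband_noise":
            if (
                self.band_low_Hz is None
                or self.band_high_Hz is None
                or not self.band_low_Hz < self.band_high_Hz
            ):
                raise ValueError("noise requires band_low_Hz < band_high_Hz")
        if self.kind != "silence":
            if not math.isfinite(self.level_dB_SPL):
                raise ValueError("stimulus level must be finite")
            if self.duration_ms <= 0:
                raise ValueError("stimulus duration must be positive")

    @staticmethod
    def silence(role: StimulusRole = "none") -> "StimulusSpec":
        return StimulusSpec(role=role, kind="silence")

    @staticmethod
    def tone(role: StimulusRole, frequency_kHz: float, level_dB_SPL: float,
             duration_ms: float = 50.0) -> "StimulusSpec":
        return StimulusSpec(role=role, kind="tone", frequency_kHz=frequency_kHz,
                            level_dB_SPL=level_dB_SPL, duration_ms=duration_ms)

    @staticmethod
    def noise(role: StimulusRole, level_dB_SPL: float,
              band_low_Hz: float = 80.0, band_high_Hz: float = 10_000.0,
              duration_ms: float = 50.0) -> "StimulusSpec":
        return StimulusSpec(role=role, kind="broadband_noise",
                            band_low_Hz=band_low_Hz, band_high_Hz=band_high_Hz,
                            level_dB_SPL=level_dB_SPL, duration_ms=duration_ms)


@dataclass(frozen=True)
class GainReductionRule:
    """How a precursor's level maps to elicited gain reduction (dB).

    ``mechanistic`` mode drives gain reduction from the precursor's place
    excitation through the full-gain I/O curve:
    ``delta_g = clamp(s * (E - E0), 0, cap)``.  An on-frequency precursor is
    itself compressed, so its elicited gain reduction grows at slope
    ``s * c`` per dB above the breakpoint, while an off-frequency precursor
    (linear path) grows at slope ``s`` — the asymmetry the level-slope
    analysis quantifies.

    ``empirical`` mode maps the physical level directly through per-class
    linear coefficients (dB SPL for tones, dB/ERB for noise).
    """

    mode: Literal["mechanistic", "empirical"] = "mechanistic"
    elicitation_slope_s: float = 0.8
    elicitation_floor_E0: float = 55.0
    cap_dB: float = 40.0
    empirical_intercepts: dict[str, float] = field(default_factory=dict)
    empirical_slopes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.elicitation_slope_s < 0:
            raise ValueError("elicitation slope s must be >= 0")
        if self.cap_dB < 0:
            raise ValueError("cap must be >= 0")
        if any(v < 0 for v in self.empirical_slopes.values()):
            raise ValueError("empirical slopes must be >= 0")


@dataclass(frozen=True)
class ListenerProfile:
    """One simulated ear.

    ``internal_noise_dB`` (N0) is the place-output floor; ``calibrated``
    constructs it so the model's quiet threshold equals
    ``quiet_threshold_dB_SPL``.  ``off_freq_attenuation_dB`` (A) is the level
    an off-frequency tone loses reaching the signal place.
    ``criterion_smr_dB`` (K) is the signal-to-masker ratio at the place
    output required for detection; ``psychometric_spread_dB`` is the Gaussian
    spread of the psychometric function; ``run_noise_sd_dB`` is between-run
    threshold jitter.
    """

    id: str
    quiet_threshold_dB_SPL: float
    io: IOFunction
    internal_noise_dB: float
    off_freq_attenuation_dB: float = 9.0
    criterion_smr_dB: float = 0.0
    psychometric_spread_dB: float = 4.0
    run_noise_sd_dB: float = 1.5
    gain_rule: GainReductionRule = field(default_factory=GainReductionRule)

    def __post_init__(self) -> None:
        if self.psychometric_spread_dB <= 0:
            raise ValueError("psychometric spread must be positive")
        if self.run_noise_sd_dB < 0:
            raise ValueError("run noise SD must be >= 0")
        if self.off_freq_attenuation_dB < 0:
            raise ValueError("off-frequency attenuation must be >= 0")
        if self.gain_rule.cap_dB > self.io.gain_dB:
            raise ValueError("gain-reduction cap cannot exceed the I/O gain")

    @classmethod
    def calibrated(cls, id: str, quiet_threshold_dB_SPL: float, io: IOFunction,
                   criterion_smr_dB: float = 0.0, **kwargs) -> "ListenerProfile":
        """Build a listener whose internal noise floor reproduces the given
        quiet threshold: N0 = io(quiet_threshold) - K."""
        n0 = io_output(quiet_threshold_dB_SPL, io) - criterion_smr_dB
        return cls(id=id, quiet_threshold_dB_SPL=quiet_threshold_dB_SPL, io=io,
                   internal_noise_dB=n0, criterion_smr_dB=criterion_smr_dB,
                   **kwargs)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, payload: str) -> "ListenerProfile":
        d = json.loads(payload)
        d["io"] = IOFunction(**d["io"])
        d["gain_rule"] = GainReductionRule(**d["gain_rule"])
        return cls(**d)


def is_on_frequency(tone_freq_kHz: float, signal_freq_kHz: float) -> bool:
    """A tone counts as on-frequency when within one ERB of the signal."""
    return abs(tone_freq_kHz - signal_freq_kHz) * 1000.0 <= erb_bandwidth(signal_freq_kHz)


def place_excitation(stim: StimulusSpec, signal_freq_kHz: float,
                     listener: ListenerProfile, gain_reduced_io: Optional[IOFunction] = None
                     ) -> float:
    """Place-output level (dB) of ``stim`` at the signal-frequency place.

    ``gain_reduced_io`` selects the curve on-frequency energy passes through
    (defaults to the listener's full-gain curve).  Off-frequency tones take
    the linear path (level − A) and are unaffected by gain reduction.
    """
    io = gain_reduced_io if gain_reduced_io is not None else listener.io
    if stim.kind == "silence":
        return listener.internal_noise_dB
    if stim.kind == "tone":
        if is_on_frequency(stim.frequency_kHz, signal_freq_kHz):
            return io_output(stim.level_dB_SPL, io)
        return stim.level_dB_SPL - listener.off_freq_attenuation_dB
    # broadband noise: level in one ERB at the signal place, compressed
    f_hz = signal_freq_kHz * 1000.0
    if not (stim.band_low_Hz <= f_hz <= stim.band_high_Hz):
        raise ValueError(
            f"noise band [{stim.band_low_Hz}, {stim.band_high_Hz}] Hz does not "
            f"cover the signal frequency {f_hz} Hz"
        )
    sl = spectrum_level(stim.level_dB_SPL, stim.band_low_Hz, stim.band_high_Hz)
    in_band = level_per_erb(sl, erb_bandwidth(signal_freq_kHz))
    return io_output(in_band, io)


def precursor_class(stim: StimulusSpec, signal_freq_kHz: float) -> str:
    if stim.kind == "silence":
        return "none"
    if stim.kind == "broadband_noise":
        return "bbn"
    return "on_tone" if is_on_frequency(stim.frequency_kHz, signal_freq_kHz) else "off_tone"


def elicited_gain_reduction(precursor: StimulusSpec, listener: ListenerProfile,
                            signal_freq_kHz: float = 4.0) -> float:
    """Gain reduction (dB) elicited by ``precursor`` at the signal place."""
    if precursor.kind == "silence":
        return 0.0
    rule = listener.gain_rule
    cap = min(rule.cap_dB, listener.io.gain_dB)
    if rule.mode == "mechanistic":
        excitation = place_excitation(precursor, signal_freq_kHz, listener)
        dg = rule.elicitation_slope_s * (excitation - rule.elicitation_floor_E0)
    else:
        cls = precursor_class(precursor, signal_freq_kHz)
        if cls not in rule.empirical_slopes or cls not in rule.empirical_intercepts:
            raise ValueError(f"no empirical coefficients for precursor class {cls!r}")
        if precursor.kind == "broadband_noise":
            sl = spectrum_level(precursor.level_dB_SPL, precursor.band_low_Hz,
                                precursor.band_high_Hz)
            level = level_per_erb(sl, erb_bandwidth(signal_freq_kHz))
        else:
            level = precursor.level_dB_SPL
        dg = rule.empirical_intercepts[cls] + rule.empirical_slopes[cls] * level
    return float(min(max(dg, 0.0), cap))
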