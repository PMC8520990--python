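#!/usr/bin/env python
"""Contrast the two accounts of precursor-induced forward masking.

For a mechanistic synthetic cohort, find on-frequency maskers equally
effective to a 65-dB SPL off-frequency masker, add an identical 40-dB SPL
on-frequency precursor to both, and predict the signal-threshold shift
under (a) cochlear gain reduction and (b) additivity of masking.  Gain
reduction predicts a larger off-frequency shift; additivity predicts equal
shifts.  Writes results/hypothesis_shifts.csv.
"""

from pathlib import Path

from cochlear_gain.pipeline import hypothesis_discrimination

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    hd = hypothesis_discrimination(n_listeners=7, seed=1)
    OUT.mkdir(exist_ok=True)
    hd.to_csv(OUT / "hypothesis_shifts.csv", index=False)
    cols = ["participant", "delta_g_dB", "gain_reduction_shift_off_dB",
            "gain_reduction_shift_on_dB", "additivity_shift_off_dB",
            "additivity_shift_on_dB"]
    print(hd[cols].to_string(index=False,
                             float_format=lambda v: f"{v:.2f}"))
    n_sig = int((hd["gain_reduction_shift_off_dB"]
                 > hd["gain_reduction_shift_on_dB"]).sum())
    print(f"\ngain reduction: off-frequency shift > on-frequency shift for "
          f"{n_sig}/{len(hd)} listeners")
    max_add = float((hd["additivity_shift_off_dB"]
                     - hd["additivity_shift_on_dB"]).abs().max())
    print(f"additivity: max |off - on| shift difference {max_add:.3f} dB "
          f"(equal by construction)")
    print(f"wrote {OUT / 'hypothesis_shifts.csv'}")


if __name__ == "__main__":
    main()
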