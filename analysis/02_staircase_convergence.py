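#!/usr/bin/env python
"""Check that the simulated 2-down/1-up procedure tracks the 70.7% point.

Simulates 250 fifty-trial signal tracks on a listener with a known
Gaussian 3IFC psychometric function, evaluates the generative percent
correct at the mean threshold estimate, and compares the simulator mean
with the exact Markov-chain stationary asymptote.  Writes
results/staircase_convergence.json.
"""

import json
from pathlib import Path

from cochlear_gain.pipeline import staircase_convergence

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    conv = staircase_convergence(n_runs=250, seed=1)
    OUT.mkdir(exist_ok=True)
    (OUT / "staircase_convergence.json").write_text(
        json.dumps(conv, indent=2) + "\n")
    print(f"true threshold        {conv['true_threshold_dB']:.2f} dB SPL")
    print(f"mean estimate (n={conv['n_runs']})  {conv['mean_estimate_dB']:.2f} dB SPL")
    print(f"tracked percent correct  {conv['percent_correct']:.1f}%  (rule target 70.7%)")
    print(f"Markov-chain asymptote   {conv['oracle_mean_dB']:.2f} dB SPL")
    print(f"wrote {OUT / 'staircase_convergence.json'}")


if __name__ == "__main__":
    main()
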