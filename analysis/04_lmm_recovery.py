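#!/usr/bin/env python
"""Parameter-recovery study for the gain-reduction mixed models.

Generates 50 synthetic cohorts from each generative parameterisation
(tonal two-class model with random frequency offsets; three-class model
including broadband noise with random intercepts only), floor-filters at
4 dB, refits the corresponding mixed model, and reports the mean recovered
fixed effects next to the generative values.  Writes
results/lmm_recovery.json.
"""

import json
from pathlib import Path

from cochlear_gain.pipeline import lmm_recovery
from cochlear_gain.synthetic import BBN_PARAMS, TONAL_PARAMS

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tonal = lmm_recovery(TONAL_PARAMS, n_cohorts=50, seed=2,
                         random_structure="slopes")
    bbn = lmm_recovery(BBN_PARAMS, n_cohorts=50, seed=3,
                       random_structure="intercepts")
    OUT.mkdir(exist_ok=True)
    payload = {"tonal": tonal, "bbn": bbn}
    (OUT / "lmm_recovery.json").write_text(json.dumps(payload, indent=2) + "\n")
    print("tonal model (50 cohorts, 7 participants each):")
    print(f"  level slope       {tonal['level_slope']:.3f}   (generative 0.33)")
    print(f"  level x frequency {tonal['level_x_off_tone']:.3f}   (generative 0.47)")
    print("three-class model (50 cohorts, 4 participants each):")
    print(f"  level slope       {bbn['level_slope']:.3f}   (generative 0.29)")
    print(f"  level x frequency {bbn['level_x_off_tone']:.3f}   (generative 0.46)")
    print(f"  level x noise     {bbn['level_x_bbn']:.3f}   (generative 0.11)")
    print("small downward offsets reflect truncation by the 4-dB floor filter")
    print(f"wrote {OUT / 'lmm_recovery.json'}")


if __name__ == "__main__":
    main()
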