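#!/usr/bin/env python
"""SPB landmark-pair separation recovery from simulated two-spot channels.

Each replicate renders the 180 nm mother/daughter pair with the default
PSF/camera model and refits it with the joint two-3D-Gaussian model seeded
near the truth. The mean fitted separation is an unbiasedness check of the
fit that anchors all SPA realignment.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from npcquant.experiments import spb_separation_recovery
from npcquant.pipeline import write_csv_with_header

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 0
N_REPLICATES = 50


def main() -> None:
    seps = spb_separation_recovery(n_replicates=N_REPLICATES, seed=SEED)
    OUT.mkdir(exist_ok=True)
    write_csv_with_header(pd.DataFrame({"replicate": np.arange(len(seps)),
                                        "fitted_separation_nm": seps}),
                          OUT / "spb_separations.csv",
                          {"n": N_REPLICATES, "seed": SEED, "truth_nm": 180.0})
    se = seps.std(ddof=1) / np.sqrt(len(seps))
    summary = {"truth_nm": 180.0, "mean_nm": round(float(seps.mean()), 2),
               "sd_nm": round(float(seps.std(ddof=1)), 2),
               "se_nm": round(float(se), 3), "n": len(seps)}
    (OUT / "spb_separation_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"fitted separation {seps.mean():.2f} +- {se:.2f} nm (SE, n={len(seps)}); "
          f"truth 180 nm -> bias {seps.mean() - 180:+.2f} nm "
          f"({abs(seps.mean() - 180) / (3 * se):.2f} of the 3 SE budget)")


if __name__ == "__main__":
    main()
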