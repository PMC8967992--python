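#!/usr/bin/env python
"""Recovery of a constructed NPC exclusion zone around the SPB.

Nuclei are simulated with NPCs forbidden within 150 nm of the SPB midpoint
and run through the same SPA chain as the null. The averaged axis profile now
dips well below the 0.8 threshold at the SPB, and the inverted-Gaussian fit
sizes the zone (FWHM = 2.355 x SD, 95% CI from the fit covariance). Note the
measured FWHM is narrower than the constructed ball's 300 nm diameter: the
12-pixel-wide profile band averages across the dip and the projected zone
shrinks with the cap's tilt — exactly what the protocol would report for a
hard zone of this size (see docs/methods.md).
"""

import json
from pathlib import Path

import pandas as pd

from npcquant.experiments import spa_study
from npcquant.pipeline import write_csv_with_header

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 0
ZONE_RADIUS_NM = 150.0


def main() -> None:
    res = spa_study(n_nuclei=100, seed=SEED, exclusion_radius_nm=ZONE_RADIUS_NM)
    OUT.mkdir(exist_ok=True)
    write_csv_with_header(
        pd.DataFrame({"position_nm": res.profile.positions_nm,
                      "normalized_intensity": res.profile.intensities}),
        OUT / "exclusion_zone_profile.csv",
        {"n_nuclei": 100, "seed": SEED, "zone_radius_nm": ZONE_RADIUS_NM})
    fit = res.exclusion.fit
    summary = {
        "constructed_zone_diameter_nm": 2 * ZONE_RADIUS_NM,
        "n_aligned": res.n_aligned,
        "profile_min": round(float(res.profile.intensities.min()), 4),
        "exclusion_called": res.exclusion.excluded,
        "fwhm_nm": round(fit.fwhm_nm, 1) if fit and fit.converged else None,
        "fwhm_ci95_nm": [round(v, 1) for v in fit.fwhm_ci95_nm]
        if fit and fit.converged else None,
        "dip_center_nm": round(fit.center_nm, 1) if fit and fit.converged else None,
    }
    (OUT / "exclusion_zone_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"averaged {res.n_aligned} nuclei; profile min "
          f"{summary['profile_min']:.3f} -> exclusion called: "
          f"{res.exclusion.excluded}")
    if fit and fit.converged:
        lo, hi = fit.fwhm_ci95_nm
        print(f"exclusion zone FWHM {fit.fwhm_nm:.1f} nm "
              f"(95% CI {lo:.1f}-{hi:.1f}), dip centered at "
              f"{fit.center_nm:+.0f} nm from the SPB midpoint")


if __name__ == "__main__":
    main()
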