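#!/usr/bin/env python
"""Recovery of constructed nucleolar Nup reductions from NE line profiles.

Synthetic two-channel NE profiles are built with the Nup signal reduced by a
known fraction over the nucleolar arc, rotated randomly and degraded with
noise. The marker-anchored alignment/averaging pipeline must recover the mean
normalised Nup value at position 0 (the nucleolar centre) for reductions of
0, 20 and 50%.
"""

import json
from pathlib import Path

from npcquant.experiments import nucleolar_recovery

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 0
REDUCTIONS = (0.0, 0.2, 0.5)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = {}
    for r in REDUCTIONS:
        out = nucleolar_recovery(r, n_scenes=50, noise_sd=0.10, seed=SEED)
        rows[f"reduction_{r:g}"] = {k: round(v, 4) if isinstance(v, float) else v
                                    for k, v in out.items()}
        print(f"constructed reduction {r:.0%}: recovered value at position 0 = "
              f"{out['mean']:.3f} +- {out['se']:.3f} (SE, n={out['n']}; "
              f"truth {1 - r:.2f})")
    (OUT / "nucleolar_reduction_summary.json").write_text(
        json.dumps(rows, indent=2))


if __name__ == "__main__":
    main()
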