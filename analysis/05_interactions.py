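#!/usr/bin/env python
"""Interactive effects: PWS sensitivity vs sac diameter.

Crosses the maximum-diameter grid with secondary levels of wall thickness,
axial extent, and fiber stiffness k1, and reports, per diameter, the PWS
spread across the secondary levels — the widening of these spreads with
diameter is the interaction effect.
"""

import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
import aawall as aw
from aawall.study import StudyRunner

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    runner = StudyRunner(bc=aw.BoundaryConditions(pressure=0.016, increments=5),
                         resolution=(36, 20, 2), verbose=True)
    t0 = time.perf_counter()
    df = runner.run_interaction_sweeps()
    df.to_csv(RESULTS / "interactions.csv", index=False)
    spreads = (df.groupby(["secondary", "diameter"])["PWS_spread"]
               .first().unstack("diameter"))
    print(spreads.round(3).to_string())
    print(f"[{time.perf_counter()-t0:.0f}s] spread growth from smallest to "
          "largest diameter, per secondary parameter:")
    print((spreads.iloc[:, -1] / spreads.iloc[:, 0]).round(2).to_string())


if __name__ == "__main__":
    main()
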