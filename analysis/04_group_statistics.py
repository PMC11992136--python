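#!/usr/bin/env python
"""Group inference on the normative z-scores.

One-way ANOVA + Tukey/Cohen's d per feature and the status/dosage
interaction GLMs, written as stats_*.csv.  Prints the features with the
strongest group effects -- on a cohort simulated with carrier deficits
in the aperiodic exponent and alpha peak, those features should surface.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from run_config import RUN_DIR, analysis_config

from restingnorm.pipeline import stats_stage


def main() -> None:
    config = analysis_config()
    stats_stage(config, RUN_DIR)
    anova = pd.read_csv(RUN_DIR / "stats_anova.csv").sort_values("p")
    print("top features by omnibus ANOVA on z-scores:")
    print(anova.head(8)[["feature", "F", "p", "eta_p_sq"]].round(4).to_string(index=False))
    tukey = pd.read_csv(RUN_DIR / "stats_tukey.csv")
    hits = tukey[tukey["p"] < 0.05].sort_values("p")
    print(f"\n{len(hits)} significant Tukey pairs (p < 0.05):")
    if len(hits):
        print(hits[["feature", "pair", "mean_diff", "p", "cohens_d"]]
              .round(4).to_string(index=False))


if __name__ == "__main__":
    main()
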