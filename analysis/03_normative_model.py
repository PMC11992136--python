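#!/usr/bin/env python
"""Fit GP normative models on controls and z-score every subject.

Applies the percentile-IQR outlier rule per feature, trains the
Gaussian-process trajectory (age/sex/site/quality covariates) on the
control group, and writes zscores.csv plus per-feature SMSE reports.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from run_config import RUN_DIR, analysis_config

from restingnorm.pipeline import normative_stage


def main() -> None:
    config = analysis_config()
    z = normative_stage(config, RUN_DIR)
    report = json.loads((RUN_DIR / "normative_report.json").read_text())
    print(f"z-scored {z['subject_id'].nunique()} subjects x "
          f"{z['feature'].nunique()} features")
    print("\nper-feature SMSE (cross-validated on controls; 1 = mean predictor):")
    for feat, rep in sorted(report.items()):
        print(f"  {feat:22s} smse={rep['smse']:.3f} excluded={rep['n_excluded']}")


if __name__ == "__main__":
    main()
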