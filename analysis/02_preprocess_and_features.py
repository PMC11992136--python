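#!/usr/bin/env python
"""Preprocess every recording and extract spectral/connectivity features.

Runs the eight-step cleaning chain, the surface-Laplacian transform,
Welch + aperiodic/periodic parameterization and per-band wPLI, writing
features.csv and per-subject preprocessing reports.  Prints the
retention summary (channels/seconds kept per group).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from run_config import RUN_DIR, analysis_config

from restingnorm.pipeline import features_stage, stage_report


def main() -> None:
    config = analysis_config()
    features = features_stage(config, RUN_DIR)
    print(f"extracted {features['feature'].nunique()} features x "
          f"{features['subject_id'].nunique()} subjects")
    print("\nretention:")
    print(stage_report(RUN_DIR))


if __name__ == "__main__":
    main()
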