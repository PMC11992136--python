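"""Shared configuration for the numbered analysis scripts.

A reduced-scale rendition of the study conditions (fewer channels,
shorter recordings, smaller cohort) so the full chain runs on a laptop
in a few minutes; every stage otherwise uses the pipeline defaults.
"""

from pathlib import Path

from restingnorm.config import RunConfig
from restingnorm.synthetic import ArtifactSpec, EffectConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "analysis_run"


def analysis_config(seed: int = 1) -> RunConfig:
    return RunConfig(
        out_dir=str(RUN_DIR),
        seed=seed,
        n_ctrl=30,
        n_del=10,
        n_dup=8,
        n_channels=24,
        n_excluded=4,
        duration_s=60.0,
        rate=250.0,
        min_train=15,
        effects=EffectConfig(artifacts=ArtifactSpec(1, 8.0, 0.15),
                             n_coupled_pairs=3),
    )
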