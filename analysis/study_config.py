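"""Shared study conditions for the analysis scripts.

The cohort mirrors the paired lung-subtype setting this project emulates:
505 vs 483 samples, 2000 genes per modality (HDLSS at desk scale), a
stronger expression signal than copy-number signal, and per-modality sample
dropout so the modalities overlap in 988 common samples.
"""

from omicsfuse.synthetic import SimConfig

STUDY = SimConfig()  # generator defaults ARE the study conditions
CV_SEEDS = (1, 2, 3, 4, 5)
K_FOLDS = 5
K_SCALE = 10.0
TOP_N = 500
MODEL_NAME = "gradient_boosting"
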