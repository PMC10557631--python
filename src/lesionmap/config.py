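"""Analysis configuration shared across the pipeline.

All thresholds used by the spatial and MRI stages live in one dataclass so a
run can be reproduced from its config snapshot alone.  The defaults are the
study conditions: module-score cutoffs for the gray-matter and lesion masks,
the ligand-receptor detection threshold on unit-rescaled expression, the
differential-expression filter chain, the cluster-proportion test cutoffs,
the 1250 ms T1 partition, and the rim / dilation geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml


@dataclass
class AnalysisConfig:
    # module-score masks (strict > comparisons)
    gm_score_threshold: float = 0.01
    lesion_score_threshold: float = 0.1
    # ligand-receptor colocalization on unit-rescaled expression
    coloc_expression_threshold: float = 0.15
    # DEG filter chain (rank-sum test)
    deg_adj_p_cutoff: float = 0.05
    deg_logfc_cutoff: float = 0.25
    deg_pct2_cutoff: float = 0.1
    # cluster-proportion permutation test
    proportion_fdr_cutoff: float = 0.05
    proportion_log2fc_cutoff: float = 0.25
    # MRI
    t1_cutoff_ms: float = 1250.0
    lesion_delta: float = 0.2          # normalized PD units, terminal - baseline
    n_mri_rims: int = 5
    # spot-level rim geometry
    n_outward_rims: int = 10
    dilation_rounds: int = 5
    # module scoring
    module_score_bins: int = 24
    module_score_ctrl: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outward_rims < 1 or self.n_mri_rims < 1:
            raise ValueError("rim counts must be >= 1")
        for name, value in asdict(self).items():
            if isinstance(value, float) and not (value == value and abs(value) < float("inf")):
                raise ValueError(f"threshold {name!r} must be finite")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


DEFAULT_CONFIG = AnalysisConfig()
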