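"""Pipeline configuration shared by the CLI subcommands.

Every output table carries the config fingerprint in a ``# config:`` header
so that downstream steps can refuse to combine tables produced under
different settings (e.g. a target and a decoy rule database mined with
different thresholds).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from .spectra_io import MASS_DECIMALS


@dataclass
class PipelineConfig:
    rounding_decimals: int = MASS_DECIMALS
    ppm: float = 20.0
    min_supp_x: int = 5
    min_tp: int = 5
    max_body: int = 3
    fdr_alpha: float = 0.01
    sim_threshold: float = 0.5
    aggregation: str = "exhaustive"
    max_cuts: int = 2
    cleavage_policy: str = "all_acyclic"
    decoy_fraction: float = 0.2
    fingerprint_bits: int = 1024
    fingerprint_max_path: int = 7
    small_filter: int = 5

    def __post_init__(self):
        if self.max_body not in (1, 2, 3):
            raise ValueError("max_body must be 1, 2 or 3")
        if self.max_cuts not in (0, 1, 2):
            raise ValueError("max_cuts must be 0, 1 or 2")
        if not 0 < self.fdr_alpha <= 1:
            raise ValueError("fdr_alpha must be in (0, 1]")
        if not 0 <= self.sim_threshold <= 1:
            raise ValueError("sim_threshold must be in [0, 1]")
        if not 0 < self.decoy_fraction <= 1:
            raise ValueError("decoy_fraction must be in (0, 1]")

    def fingerprint(self) -> str:
        """Canonical one-line rendering of the configuration."""
        d = asdict(self)
        return " ".join(f"{k}={d[k]}" for k in sorted(d))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            return cls(**json.load(handle))
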