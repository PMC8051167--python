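"""Run configuration: paths, thresholds and reproducibility knobs.

Threshold defaults are the method's published operating point: consensus
fraction 0.7, minimum pattern length 15 nt, PWM log-odds threshold 10 bits
with a minimum motif width of 10 nt, splice consensus value 75 and
maximum-entropy score 3 bits.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

DEFAULT_ALIGNER = "mafft --auto {input}"


@dataclass
class RunConfig:
    # paths
    input_dir: str = ""
    library_info: str = ""
    pwm_dir: str = ""
    output_dir: str = "consreg_out"
    donor_matrix: str | None = None
    acceptor_matrix: str | None = None
    maxent_dir: str | None = None
    # thresholds (defaults = the method's published operating point)
    consensus_threshold: float = 0.7
    min_pattern_len: int = 15
    logodds_threshold: float = 10.0
    min_motif_width: int = 10
    cv_threshold: float = 75.0
    maxent_threshold: float = 3.0
    pseudocount: float = 0.01
    # behaviour
    strands: str = "both"
    ss_rule: str = "any"
    seed: int = 0
    n_controls: int | None = None  # None: one control per conserved pattern
    aligner: str = DEFAULT_ALIGNER

    def __post_init__(self) -> None:
        positive = {
            "consensus_threshold": self.consensus_threshold,
            "min_pattern_len": self.min_pattern_len,
            "logodds_threshold": self.logodds_threshold,
            "min_motif_width": self.min_motif_width,
            "cv_threshold": self.cv_threshold,
            "maxent_threshold": self.maxent_threshold,
            "pseudocount": self.pseudocount,
        }
        for name, val in positive.items():
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if not 0 < self.consensus_threshold <= 1:
            raise ValueError("consensus_threshold must be in (0, 1]")
        if self.strands not in ("+", "-", "both"):
            raise ValueError("strands must be '+', '-' or 'both'")
        if self.ss_rule not in ("any", "all"):
            raise ValueError("ss_rule must be 'any' or 'all'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
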