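"""Run configuration: tolerances, thresholds, seeds, provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path


@dataclass
class RunConfig:
    """Tunable numerics shared across analyses.

    All tolerances are in flux units (mmol·gDW⁻¹·h⁻¹) unless noted.
    ``epsilon`` is the gapfilling feasibility target, deliberately larger
    than the ``growth_threshold`` used for growth calls so gapfill
    solutions cannot rest on numerically marginal trickle fluxes.
    """

    lp_tolerance: float = 1e-9
    milp_gap: float = 0.0
    epsilon: float = 0.01            # gapfill / flux-fitting biomass floor
    delta: float = 1e-3              # flux-vs-activity classification cutoff
    growth_threshold: float = 1e-6   # growth/no-growth call
    interaction_tolerance: float = 1e-6
    percentile: float = 10.0         # universal-role on/off percentile
    seed: int = 42
    output_dir: str = "."
    verbosity: int = 1

    def __post_init__(self):
        for name in ("lp_tolerance", "epsilon", "delta", "growth_threshold",
                     "interaction_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.milp_gap < 0:
            raise ValueError("milp_gap must be >= 0")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def write_provenance(self, path: str | Path, inputs: dict[str, str] | None = None):
        """Record parameters and input-file hashes next to an analysis output."""
        record = {"config": asdict(self), "config_hash": self.config_hash(),
                  "inputs": {}}
        for label, fname in (inputs or {}).items():
            digest = hashlib.sha256(Path(fname).read_bytes()).hexdigest()[:16]
            record["inputs"][label] = {"path": str(fname), "sha256_16": digest}
        Path(path).write_text(json.dumps(record, indent=1))
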