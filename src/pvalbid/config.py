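"""Run configuration: defaults, YAML loading, reproducibility echo."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

log = logging.getLogger("pvalbid")


@dataclass
class RunConfig:
    """All tunables of a pipeline run; every default is usable as-is."""

    panel: str = "bundled"            # "bundled" or path prefix to FASTA+TSV
    gap_open: float = 10.0
    gap_extend: float = 1.0
    lineage_margin: float = 2.0       # identity points
    majority_threshold: float = 0.8   # rule discovery
    hybrid_window: int = 20
    hybrid_step: int = 1
    hybrid_margin: float = 5.0        # identity points per window
    out_dir: str = "pvalbid_out"
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
            unknown = set(data) - set(cls().__dict__)
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def echo(self, panel_checksum: str) -> None:
        """Write the reproducibility block to the run log (stderr)."""
        log.info("run configuration:")
        for key, value in asdict(self).items():
            log.info("  %s = %r", key, value)
        log.info("  panel_checksum = %s", panel_checksum)


def setup_logging(verbosity: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, verbosity.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
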