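"""Run configuration, run reports and logging.

Every tunable constant of the pipeline lives in :class:`RunConfig` so that a
whole analysis is reproducible from one YAML file plus one seed.  The
:class:`RunReport` collects what a run actually did (input digests, per-stage
timings, emitted files) and serialises to JSON next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from contextlib import contextmanager
from pathlib import Path
from typing import Any, Iterator

import yaml

logger = logging.getLogger("ciliagraph")

#: Equal weights for the three prioritization components
#: (impact similarity, connection strength, key-regulator index).
DEFAULT_WEIGHTS: tuple[float, float, float] = (1.0 / 3, 1.0 / 3, 1.0 / 3)


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger for CLI use (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper()))


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters.

    Parameters
    ----------
    alpha_deg:
        Adjusted-p cutoff for retaining differentially expressed genes;
        a gene is significant iff ``p_adj < alpha_deg`` (strict).
    combined_threshold:
        A pathway is listed when its combined coefficient is strictly
        greater than this value.
    anchor_name:
        Name of the reference pathway (autophagy) all others are scored
        against.
    scan_window:
        Window length (in ranks) for the sustained-slope zone detector.
    scan_slope:
        Minimum absolute windowed slope for a rank to belong to a zone.
    seed:
        Seed for every stochastic stage.
    weights:
        Non-negative weights (summing to 1) for the combined coefficient:
        (impact similarity, connection strength, key-regulator index).
    overlap_weight:
        Blend between gene-overlap (Ochiai) and inverse hop distance in the
        anchor connection strength; 1 = overlap only, 0 = distance only.
    """

    alpha_deg: float = 0.05
    combined_threshold: float = 0.35
    anchor_name: str | None = None
    scan_window: int = 10
    scan_slope: float = 0.6
    seed: int = 0
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    overlap_weight: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_deg < 1.0:
            raise ValueError(f"alpha_deg must lie in (0,1), got {self.alpha_deg}")
        if not 0.0 <= self.combined_threshold <= 1.0:
            raise ValueError(
                f"combined_threshold must lie in [0,1], got {self.combined_threshold}"
            )
        if self.scan_window < 1:
            raise ValueError(f"scan_window must be positive, got {self.scan_window}")
        if not 0.0 < self.scan_slope <= 1.0:
            raise ValueError(f"scan_slope must lie in (0,1], got {self.scan_slope}")
        if self.seed < 0:
            raise ValueError(f"seed must be non-negative, got {self.seed}")
        self.weights = tuple(float(w) for w in self.weights)  # type: ignore[assignment]
        if len(self.weights) != 3 or any(w < 0 for w in self.weights):
            raise ValueError(f"weights must be three non-negative reals, got {self.weights}")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {self.weights}")
        if not 0.0 <= self.overlap_weight <= 1.0:
            raise ValueError(
                f"overlap_weight must lie in [0,1], got {self.overlap_weight}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a configuration from a YAML mapping; missing keys keep defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["weights"] = list(self.weights)
        return d


@dataclasses.dataclass
class RunReport:
    """What a run did: config echo, input digests, timings, outputs."""

    config: dict[str, Any] = dataclasses.field(default_factory=dict)
    digests: dict[str, int] = dataclasses.field(default_factory=dict)
    seed: int | None = None
    timings: dict[str, float] = dataclasses.field(default_factory=dict)
    outputs: list[str] = dataclasses.field(default_factory=list)

    @contextmanager
    def stage(self, name: str) -> Iterator[None]:
        """Time a pipeline stage and record it under ``name``."""
        t0 = time.perf_counter()
        try:
            yield
        finally:
            self.timings[name] = round(time.perf_counter() - t0, 6)

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path
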