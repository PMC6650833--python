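"""Pipeline configuration and logging.

All timing constants default to the values the method was designed around:
15 s analysis windows moved in 1 s steps (93.33% overlap), a 45 s warm-up
discarded from every calibration recording, 5 s sampling of evaluation
levels, and a 95% confidence level for the chance-level calibration.
Every value can be overridden from a YAML/JSON config file or from CLI
flags; flags win over file values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .exceptions import InvalidInputError

log = logging.getLogger("playaffect")


def setup_logging(level: int = logging.INFO) -> None:
    """Configure the package logger once, with a terse structured format."""
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(level)


@dataclass
class PipelineConfig:
    """Run-wide constants of the detection pipeline.

    Parameters
    ----------
    window_length_s, window_step_s
        Geometry of the moving analysis window (seconds).
    warmup_s
        Initial seconds of each calibration recording discarded before the
        boredom/stress thirds are cut.
    sampling_interval_s
        Spacing of test samples drawn from evaluation levels.
    band_hz
        Physiological pass-band for pulse search (0.75-4 Hz = 45-240 bpm).
    hr_history_max_jump_bpm
        Maximal accepted change between consecutive heart-rate estimates.
    alpha
        Significance level for the binomial chance-level threshold.
    seed
        Master RNG seed; every stochastic step derives its stream from it.
    """

    window_length_s: float = 15.0
    window_step_s: float = 1.0
    warmup_s: float = 45.0
    sampling_interval_s: float = 5.0
    band_hz: tuple[float, float] = (0.75, 4.0)
    hr_history_max_jump_bpm: float = 12.0
    min_peak_ratio: float = 0.05
    search_iterations: int = 30
    cv_folds: int = 10
    cv_repeats: int = 3
    alpha: float = 0.05
    seed: int = 0

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["band_hz"] = list(self.band_hz)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        d = dict(data)
        if "band_hz" in d:
            band = tuple(float(x) for x in d["band_hz"])
            if len(band) != 2 or not band[0] < band[1]:
                raise InvalidInputError(f"band_hz must be (low, high): {band}")
            d["band_hz"] = band
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        """Read a YAML (or JSON — YAML is a superset) config file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, Mapping):
            raise InvalidInputError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
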