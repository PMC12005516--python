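"""Model parameter file handling.

Every uncertain model input is expressed as a :class:`Param`: either a point
estimate with a 95% confidence interval (``mean``/``lo``/``hi``), a bare
interval with no stated central value (``lo``/``hi``), or a fixed constant.
The packaged default file (``data/therapy_params.yaml``) encodes the full
input set: baseline event rates, disability weights with durations, and the
per-therapy effect estimates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["Param", "ModelParams", "load_params"]


@dataclass(frozen=True)
class Param:
    """A scalar model input with optional uncertainty.

    Exactly one of three shapes is valid:

    * CI parameter: ``mean`` with ``lo <= mean <= hi`` (95% interval);
    * range parameter: ``lo < hi`` with no ``mean`` (uniform interval);
    * fixed parameter: ``fixed`` only, never sampled.
    """

    mean: float | None = None
    lo: float | None = None
    hi: float | None = None
    fixed: float | None = None

    def __post_init__(self) -> None:
        if self.fixed is not None:
            return
        if self.lo is None or self.hi is None:
            raise ValueError(f"interval parameter needs lo and hi: {self}")
        if self.hi < self.lo:
            raise ValueError(f"hi < lo in {self}")
        if self.mean is not None and not (self.lo <= self.mean <= self.hi):
            raise ValueError(f"mean outside [lo, hi] in {self}")

    @property
    def kind(self) -> str:
        if self.fixed is not None:
            return "fixed"
        return "ci" if self.mean is not None else "range"

    @property
    def point(self) -> float:
        """Point estimate: the mean, the fixed value, or the interval midpoint."""
        if self.fixed is not None:
            return self.fixed
        if self.mean is not None:
            return self.mean
        return 0.5 * (self.lo + self.hi)

    @classmethod
    def from_config(cls, spec: Any) -> "Param":
        if isinstance(spec, (int, float)):
            return cls(fixed=float(spec))
        if not isinstance(spec, Mapping):
            raise TypeError(f"cannot parse parameter spec {spec!r}")
        if "point" in spec:
            return cls(fixed=float(spec["point"]))
        return cls(
            mean=None if "mean" not in spec else float(spec["mean"]),
            lo=None if "lo" not in spec else float(spec["lo"]),
            hi=None if "hi" not in spec else float(spec["hi"]),
        )


class ModelParams:
    """Parsed model parameter set (baseline rates, disutilities, therapies)."""

    def __init__(self, config: Mapping[str, Any]):
        self.config = dict(config)
        base = config["baseline"]
        self.severe_hypo_rate = Param.from_config(base["severe_hypo_rate"])
        self.kidney_failure_rate = Param.from_config(base["kidney_failure_rate"])
        self.mortality_coeff_per_1000 = float(base["mortality"]["coeff_per_1000"])
        self.mortality_slope = float(base["mortality"]["slope_per_year"])

        self.disutility: dict[str, dict[str, Param | None]] = {}
        for cause, entry in config["disutility"].items():
            self.disutility[cause] = {
                "value": Param.from_config(entry["value"]),
                "duration_days": (
                    Param.from_config(entry["duration_days"])
                    if "duration_days" in entry
                    else None
                ),
            }

        self.therapies: dict[str, Any] = dict(config["therapies"])

    def therapy_names(self) -> list[str]:
        return list(self.therapies)


def _default_path() -> Path:
    return Path(
        importlib.resources.files("insulinshift").joinpath("data/therapy_params.yaml")  # type: ignore[arg-type]
    )


def load_params(path: str | Path | None = None) -> ModelParams:
    """Load a parameter file (YAML); ``None`` loads the packaged default set."""
    p = Path(path) if path is not None else _default_path()
    with open(p) as fh:
        config = yaml.safe_load(fh)
    return ModelParams(config)
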