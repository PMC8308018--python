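"""Synthetic data generators, fixtures and plain-text I/O.

The generators reproduce the three sampling models of the validation
studies — a zero-mean normal with unknown scale, a log-normal with unknown
location and unit log-scale, and finite Gaussian mixtures — plus the
printed eight-schools table.  All draws flow through seeded
``numpy.random.Generator`` objects; there is no global RNG state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
import numpy as np
import pandas as pd

from .samplers import MixtureSpec, SchoolsData

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorSpec",
    "generate",
    "generate_normal_scale",
    "generate_lognormal_location",
    "generate_mixture",
    "MIX_THREE_COMPONENT",
    "REPEATED_SAMPLING_MODELS",
    "schools_fixture",
    "read_velocities",
    "write_study",
    "write_manifest",
]


#: The 3-component benchmark truth 0.25 N(0, 1.2^2) + 0.65 N(-10, 1) + 0.10 N(7, 0.8^2).
MIX_THREE_COMPONENT = MixtureSpec(
    weights=(0.25, 0.65, 0.10), means=(0.0, -10.0, 7.0), sds=(1.2, 1.0, 0.8)
)

#: Equal-weight k = 3, 4, 5 truths used in the repeated-sampling study.
REPEATED_SAMPLING_MODELS = (
    MixtureSpec(
        weights=(1 / 3, 1 / 3, 1 / 3),
        means=(-10.0, 0.0, 7.0),
        sds=(1.0, 0.8, 1.2),
    ),
    MixtureSpec(
        weights=(0.25, 0.25, 0.25, 0.25),
        means=(-10.0, -3.0, 0.0, 7.0),
        sds=(1.0, 0.9, 0.8, 1.2),
    ),
    MixtureSpec(
        weights=(0.2, 0.2, 0.2, 0.2, 0.2),
        means=(-10.0, -3.0, 0.0, 3.0, 7.0),
        sds=(1.0, 0.9, 0.8, 1.0, 1.2),
    ),
)


@dataclass(frozen=True)
class GeneratorSpec:
    """One sampling model: family, its parameters, sample size, seed."""

    family: str                      # normal_scale | lognormal_location | mixture
    n: int
    seed: int = 0
    sigma: float = 1.0               # normal_scale
    mu: float = 0.0                  # lognormal_location (log-scale sd fixed at 1)
    mixture: MixtureSpec | None = None

    def __post_init__(self) -> None:
        if self.family not in ("normal_scale", "lognormal_location", "mixture"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.family == "normal_scale" and not (self.sigma > 0):
            raise ValueError("sigma must be positive")
        if self.family == "mixture" and self.mixture is None:
            raise ValueError("mixture family requires a MixtureSpec")


def generate_normal_scale(sigma: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return rng.normal(0.0, sigma, size=n)


def generate_lognormal_location(mu: float, n: int, rng: np.random.Generator) -> np.ndarray:
    return np.exp(rng.normal(mu, 1.0, size=n))


def generate_mixture(spec: MixtureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Component indicator first, then the component normal."""
    z = rng.choice(spec.k, size=n, p=np.asarray(spec.weights))
    return rng.normal(np.asarray(spec.means)[z], np.asarray(spec.sds)[z])


def generate(spec: GeneratorSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    if spec.family == "normal_scale":
        return generate_normal_scale(spec.sigma, spec.n, rng)
    if spec.family == "lognormal_location":
        return generate_lognormal_location(spec.mu, spec.n, rng)
    return generate_mixture(spec.mixture, spec.n, rng)


def schools_fixture() -> SchoolsData:
    """The printed eight-schools table: SAT coaching effects and their
    known standard errors."""
    return SchoolsData(
        labels=("A", "B", "C", "D", "E", "F", "G", "H"),
        y=(28.0, 8.0, -3.0, 7.0, -1.0, 1.0, 18.0, 12.0),
        se=(15.0, 10.0, 16.0, 11.0, 9.0, 11.0, 10.0, 18.0),
    )


def read_velocities(path) -> np.ndarray:
    """Read a plain-text vector (one value per line, '#' comments and
    blank lines skipped).  The galaxy benchmark has 82 rows; the count is
    logged but not enforced."""
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if not values:
        raise ValueError(f"{path}: no numeric rows found")
    if len(values) != 82:
        logger.info("%s: read %d velocities (the benchmark set has 82)", path, len(values))
    return np.asarray(values)


def write_study(table: pd.DataFrame, path) -> None:
    """Tidy CSV, one row per cell: comma-separated, UTF-8, '.' decimal."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def write_manifest(meta: dict, path) -> None:
    """JSON run manifest (seeds, settings, timestamp)."""
    payload = dict(meta)
    payload.setdefault("written_at", datetime.now(timezone.utc).isoformat())
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
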