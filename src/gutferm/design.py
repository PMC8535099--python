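"""Experimental-design registry and case enumeration.

A batch colonic fermentation experiment is a full factorial of
treatments x time points x experimental replicas, with each biological
case measured several times by qPCR and by GC-MS (technical replicas).
The registry records that factorial; :func:`build_design` enumerates it
at the three granularities the downstream statistics need.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError

#: Treatment label conventionally used for the pre-fermentation baseline.
BASELINE_LABEL = "BL"


@dataclass(frozen=True)
class DesignRegistry:
    """The factorial layout of a fermentation experiment.

    Parameters
    ----------
    treatments
        Fermentation substrates / vessels (e.g. a reference prebiotic, the
        test substrate, and a blank control).
    time_points_h
        Sampling times in hours, strictly increasing; 0 is the baseline
        (labelled ``BL``) and must be present exactly once.
    experimental_replicas
        Independent fermentation runs.
    technical_replicas_qpcr, technical_replicas_gcms
        Repeated measurements per biological case on each instrument.
    """

    treatments: tuple[str, ...] = ("FOS", "FLS", "BC")
    time_points_h: tuple[float, ...] = (0.0, 6.0, 18.0, 24.0)
    experimental_replicas: int = 2
    technical_replicas_qpcr: int = 3
    technical_replicas_gcms: int = 2

    def __post_init__(self) -> None:
        if not self.treatments:
            raise ValidationError("registry needs at least one treatment")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValidationError("treatment labels must be unique")
        tps = tuple(float(t) for t in self.time_points_h)
        object.__setattr__(self, "time_points_h", tps)
        object.__setattr__(self, "treatments", tuple(self.treatments))
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValidationError("time points must be strictly increasing")
        if sum(1 for t in tps if t == 0.0) != 1:
            raise ValidationError("baseline (time 0) must be present exactly once")
        for name in ("experimental_replicas", "technical_replicas_qpcr",
                     "technical_replicas_gcms"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    # -- serialisation -----------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignRegistry":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            treatments=tuple(raw["treatments"]),
            time_points_h=tuple(raw["time_points_h"]),
            experimental_replicas=int(raw["experimental_replicas"]),
            technical_replicas_qpcr=int(raw["technical_replicas_qpcr"]),
            technical_replicas_gcms=int(raw["technical_replicas_gcms"]),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({**asdict(self),
                            "treatments": list(self.treatments),
                            "time_points_h": list(self.time_points_h)}, fh)


@dataclass
class DesignCounts:
    """Enumerated measurement cases at three granularities."""

    cases: pd.DataFrame          # treatment, time_h, experiment
    gcms: pd.DataFrame           # cases x technical GC-MS replicas
    qpcr: pd.DataFrame           # cases x technical qPCR replicas

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_gcms(self) -> int:
        return len(self.gcms)

    @property
    def n_qpcr(self) -> int:
        return len(self.qpcr)


def build_design(registry: DesignRegistry) -> DesignCounts:
    """Enumerate biological cases and per-instrument measurements.

    Biological cases are treatments x time points x experimental replicas;
    each case yields ``technical_replicas_gcms`` GC-MS measurements and
    ``technical_replicas_qpcr`` qPCR measurements, so the counts factorize
    exactly.
    """
    cases = pd.DataFrame(
        itertools.product(registry.treatments, registry.time_points_h,
                          range(1, registry.experimental_replicas + 1)),
        columns=["treatment", "time_h", "experiment"],
    )

    def _with_tech(n: int) -> pd.DataFrame:
        reps = pd.DataFrame({"replicate": range(1, n + 1)})
        return cases.merge(reps, how="cross")

    return DesignCounts(
        cases=cases,
        gcms=_with_tech(registry.technical_replicas_gcms),
        qpcr=_with_tech(registry.technical_replicas_qpcr),
    )


def interaction_count(n_vocs: int, n_samples: int) -> int:
    """Dataset-shape audit: number of variable x sample interactions.

    With 197 compounds measured over 48 samples this is 9456, the size of
    the volatilome screening problem.
    """
    if n_vocs < 0 or n_samples < 0:
        raise ValidationError("counts must be non-negative")
    return int(n_vocs) * int(n_samples)
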