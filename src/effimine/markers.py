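"""Laboratory-marker reference specifications.

A :class:`MarkerSpec` describes one coagulation or immune-inflammatory
marker: its reference (normal) range, the pre-treatment distribution
summary used by the cohort simulator (median and quartiles, as clinical
tables report them), and the direction of clinical benefit.

A default table of eight markers routinely tracked in active rheumatoid
arthritis (fibrinogen, platelets, ESR, Hs-CRP, IgA, IgG, IgM, rheumatoid
factor) ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

HIGH_IS_BAD = "high-is-bad"
LOW_IS_BAD = "low-is-bad"
_DIRECTIONS = (HIGH_IS_BAD, LOW_IS_BAD)


@dataclass(frozen=True)
class MarkerSpec:
    """One marker's reference range, pre-treatment summary and direction.

    Parameters
    ----------
    name : str
        Marker identifier, e.g. ``"Hs-CRP"``.
    normal_low, normal_high : float
        Reference-range bounds in marker units.
    pre_median, pre_q1, pre_q3 : float
        Median and quartiles of the pre-treatment distribution.
    direction : str
        ``"high-is-bad"`` (a decrease is improvement) or ``"low-is-bad"``.
    units : str
        Free-text unit label, informational only.
    """

    name: str
    normal_low: float
    normal_high: float
    pre_median: float
    pre_q1: float
    pre_q3: float
    direction: str = HIGH_IS_BAD
    units: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("marker name must be non-empty")
        if not self.normal_low < self.normal_high:
            raise ValueError(
                f"marker {self.name!r}: normal_low must be < normal_high"
            )
        if not (self.pre_q1 <= self.pre_median <= self.pre_q3):
            raise ValueError(
                f"marker {self.name!r}: require pre_q1 <= pre_median <= pre_q3"
            )
        if self.direction not in _DIRECTIONS:
            raise ValueError(
                f"marker {self.name!r}: direction must be one of {_DIRECTIONS}"
            )

    @property
    def improves_downward(self) -> bool:
        """True when a post-treatment decrease counts as improvement."""
        return self.direction == HIGH_IS_BAD


def specs_from_frame(frame: pd.DataFrame) -> list[MarkerSpec]:
    """Build MarkerSpec objects from a table with the packaged CSV's columns."""
    required = {
        "name", "normal_low", "normal_high",
        "pre_median", "pre_q1", "pre_q3",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    specs = []
    for row in frame.to_dict("records"):
        specs.append(
            MarkerSpec(
                name=str(row["name"]),
                normal_low=float(row["normal_low"]),
                normal_high=float(row["normal_high"]),
                pre_median=float(row["pre_median"]),
                pre_q1=float(row["pre_q1"]),
                pre_q3=float(row["pre_q3"]),
                direction=str(row.get("direction", HIGH_IS_BAD)),
                units=str(row.get("units", "")),
            )
        )
    return specs


def load_marker_specs(path) -> list[MarkerSpec]:
    """Read marker specifications from a CSV file."""
    return specs_from_frame(pd.read_csv(path))


def default_marker_specs() -> list[MarkerSpec]:
    """The packaged eight-marker reference table."""
    with resources.files("effimine.data").joinpath("markers.csv").open() as fh:
        return specs_from_frame(pd.read_csv(fh))
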