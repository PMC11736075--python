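"""Marker panel definitions.

The default panel is the 17-marker ECPGR *Malus/Pyrus* set (CH01h01 ... GD147)
shipped as a YAML fixture.  Most markers amplify a single locus; Hi02c07 and
CH04e05 are presumed multi-locus (three-allele diploid calls there are
genuine, not artefacts) and GD12's locus type is unknown.  CH02g09 carries a
shift rule describing the 2 bp inter-cohort sizing offset observed between
the 2009-2014 and 2017-2021 project blocks at AFLs 122-140 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Optional

import yaml

from .model import Cohort


class LocusType(str, Enum):
    SINGLE = "single"
    MULTI = "multi"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ShiftRule:
    """Inter-cohort sizing offset: AFLs of the affected cohort falling in
    [window_low_bp, window_high_bp] may need +shift_bp to align with the
    other cohort."""

    window_low_bp: int
    window_high_bp: int
    shift_bp: int
    affected_cohort: Cohort

    def __post_init__(self):
        if self.window_low_bp >= self.window_high_bp:
            raise ValueError(
                "shift rule window must satisfy window_low_bp < window_high_bp"
            )


@dataclass(frozen=True)
class MarkerDef:
    name: str
    locus_type: LocusType = LocusType.SINGLE
    forward_primer: Optional[str] = None
    reverse_primer: Optional[str] = None
    shift_rule: Optional[ShiftRule] = None

    def __post_init__(self):
        if not self.name:
            raise ValueError("marker name must be non-empty")


@dataclass
class MarkerPanel:
    """Ordered list of marker definitions; order defines output column order."""

    markers: list

    def __post_init__(self):
        names = [m.name for m in self.markers]
        if len(names) != len(set(names)):
            raise ValueError("marker names must be unique within a panel")

    @property
    def names(self):
        return [m.name for m in self.markers]

    def __len__(self):
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def get(self, name) -> MarkerDef:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"marker {name!r} not in panel")


def _marker_from_dict(d) -> MarkerDef:
    rule = d.get("shift_rule")
    shift = None
    if rule is not None:
        shift = ShiftRule(
            window_low_bp=int(rule["window_low_bp"]),
            window_high_bp=int(rule["window_high_bp"]),
            shift_bp=int(rule["shift_bp"]),
            affected_cohort=Cohort(rule["affected_cohort"]),
        )
    return MarkerDef(
        name=str(d["name"]),
        locus_type=LocusType(d.get("locus_type", "single")),
        forward_primer=d.get("forward_primer"),
        reverse_primer=d.get("reverse_primer"),
        shift_rule=shift,
    )


def load_panel(path) -> MarkerPanel:
    """Load a marker panel from a YAML (or JSON; YAML is a superset) file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return MarkerPanel([_marker_from_dict(d) for d in data["markers"]])


def default_panel() -> MarkerPanel:
    """The standard 17-marker Malus panel shipped with the package."""
    ref = resources.files("ssrcurate").joinpath("data/panel_malus17.yaml")
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return MarkerPanel([_marker_from_dict(d) for d in data["markers"]])
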