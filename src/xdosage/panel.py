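"""Marker panel definitions.

Copy-number sexing compares the dosage of X-linked loci against an autosomal
normalizer: XX individuals carry two copies of each X marker, single-X
individuals one, while autosomal copy number is two in everyone.  A panel
therefore needs at least one marker of each role, plus a per-primer
amplification factor ``A`` (template multiplication per cycle; 2 = perfect
doubling) used to efficiency-correct the 2^-ddCt fold change.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

X_LINKED = "x_linked"
AUTOSOMAL = "autosomal"
ROLES = (X_LINKED, AUTOSOMAL)


@dataclass(frozen=True)
class Marker:
    """A qPCR marker: name, chromosomal role and primer amplification factor.

    ``amplification_factor`` must lie in (1, 2]: 1 would mean no
    amplification, values above 2 are physically impossible for PCR.
    """

    name: str
    role: str
    amplification_factor: float = 2.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("marker name must be non-empty")
        if self.role not in ROLES:
            raise ValueError(
                f"marker {self.name!r}: role must be one of {ROLES}, got {self.role!r}"
            )
        if not 1.0 < self.amplification_factor <= 2.0:
            raise ValueError(
                f"marker {self.name!r}: amplification factor must be in (1, 2], "
                f"got {self.amplification_factor}"
            )


@dataclass(frozen=True)
class MarkerPanel:
    """An immutable collection of markers with at least one of each role."""

    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names in panel")
        if not self.x_markers:
            raise ValueError("panel needs at least one x_linked marker")
        if not self.autosomal_markers:
            raise ValueError("panel needs at least one autosomal marker")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    @property
    def x_markers(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers if m.role == X_LINKED)

    @property
    def autosomal_markers(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers if m.role == AUTOSOMAL)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def marker(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"marker {name!r} not in panel")

    def role(self, name: str) -> str:
        return self.marker(name).role

    def factor(self, name: str) -> float:
        return self.marker(name).amplification_factor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "role": [m.role for m in self.markers],
                "amplification_factor": [m.amplification_factor for m in self.markers],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MarkerPanel":
        required = {"name", "role", "amplification_factor"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        return cls(
            tuple(
                Marker(str(r.name), str(r.role), float(r.amplification_factor))
                for r in frame.itertuples(index=False)
            )
        )

    @classmethod
    def from_tsv(cls, path: str | Path | io.IOBase) -> "MarkerPanel":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def default_panel() -> MarkerPanel:
    """The three X-linked + one autosomal marker panel used for validation.

    Amplification factors are panel constants measured once per primer from
    standard curves (values here correspond to 91%-98% efficiency, typical
    for validated primers); override them with measured values.
    """
    return MarkerPanel(
        (
            Marker("VSSC", X_LINKED, 1.96),
            Marker("SL4108", X_LINKED, 1.91),
            Marker("SL3442", X_LINKED, 1.94),
            Marker("AL40057", AUTOSOMAL, 1.98),
        )
    )
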