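"""Reading, validating and writing qPCR plate exports and sample annotations.

The canonical plate schema is long format, one well per row, with columns
``plate_id, well, sample_id, target, replicate, ct``.  A well's ``ct`` may be
missing ("Undetermined" on most instruments); missing values are preserved as
NaN, never dropped silently.  Every row excluded or flagged during loading is
reported in an audit list with its source line number.

The female reference sample of each plate is declared explicitly (the export
itself does not mark it), either as a single sample id shared by all plates or
as a mapping ``plate_id -> sample_id``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panel import MarkerPanel

PLATE_COLUMNS = ("plate_id", "well", "sample_id", "target", "replicate", "ct")

#: strings treated as a missing Ct on import (case-insensitive)
MISSING_CT_TOKENS = {"", "undetermined", "undet", "na", "nan", "none", "null"}

HAPLOTYPES = ("HT1", "HT1*", "HT2", "HT3", "unknown")
STAGES = ("adult", "larva", "unknown")
SEXES = ("female", "male", "unknown")


@dataclass(frozen=True)
class Well:
    """One Ct measurement: a (sample, target, replicate) well on a plate."""

    plate_id: str
    well: str
    sample_id: str
    target: str
    replicate: int
    ct: float | None = None

    def __post_init__(self) -> None:
        if self.ct is not None and not np.isnan(self.ct) and self.ct <= 0:
            raise ValueError(
                f"well {self.plate_id}/{self.well}: ct must be positive, got {self.ct}"
            )


@dataclass
class PlateData:
    """A validated plate: long-format well table plus its reference sample."""

    plate_id: str
    wells: pd.DataFrame
    reference_sample: str

    def __post_init__(self) -> None:
        missing = set(PLATE_COLUMNS) - set(self.wells.columns)
        if missing:
            raise ValueError(
                f"plate {self.plate_id!r}: well table missing columns {sorted(missing)}"
            )
        dup = self.wells.duplicated(subset=["plate_id", "well"])
        if dup.any():
            dupes = self.wells.loc[dup, "well"].tolist()
            raise ValueError(f"plate {self.plate_id!r}: duplicate wells {dupes}")
        if self.reference_sample not in set(self.wells["sample_id"]):
            raise ValueError(
                f"plate {self.plate_id!r}: reference sample "
                f"{self.reference_sample!r} has no wells on the plate"
            )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.wells["sample_id"]))

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.wells["target"]))


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample metadata: mitochondrial haplotype, stage, phenotypic sex."""

    sample_id: str
    haplotype: str = "unknown"
    stage: str = "unknown"
    phenotypic_sex: str = "unknown"
    family_id: str | None = None


def _parse_ct(raw: object, line: int, audit: list[dict]) -> float:
    """Parse one ct cell; malformed or non-positive values become NaN + audit."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    text = str(raw).strip()
    if text.lower() in MISSING_CT_TOKENS:
        return np.nan
    try:
        value = float(text)
    except ValueError:
        audit.append(
            {"line": line, "issue": "malformed_ct", "detail": f"unparseable ct {text!r}"}
        )
        return np.nan
    if value <= 0:
        audit.append(
            {"line": line, "issue": "nonpositive_ct", "detail": f"ct {value} <= 0"}
        )
        return np.nan
    return value


def read_plates(
    path: str | Path,
    references: str | Mapping[str, str],
    sep: str | None = None,
    panel: MarkerPanel | None = None,
) -> tuple[list[PlateData], list[dict]]:
    """Read a long-format plate export into validated :class:`PlateData`.

    Parameters
    ----------
    path
        Delimited text file with the canonical columns.  Comma or tab is
        auto-detected unless ``sep`` is forced.
    references
        The female reference sample: one id used for every plate, or a
        mapping ``plate_id -> sample_id``.
    panel
        Optional; when given, samples lacking any well for an autosomal
        panel target are flagged in the audit (they cannot be normalized
        downstream), and unknown targets are flagged.

    Returns
    -------
    (plates, audit)
        Plates in file order and an audit list of dicts (one per flagged
        row/sample, with 1-based file line numbers where applicable).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if "\t" in first else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = set(PLATE_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")

    audit: list[dict] = []
    frame = raw.loc[:, list(PLATE_COLUMNS)].copy()
    # header is line 1, first data row line 2
    frame["ct"] = [
        _parse_ct(v, i + 2, audit) for i, v in enumerate(raw["ct"].tolist())
    ]
    frame["replicate"] = pd.to_numeric(frame["replicate"], errors="raise").astype(int)
    for col in ("plate_id", "well", "sample_id", "target"):
        frame[col] = frame[col].astype(str).str.strip()

    plates: list[PlateData] = []
    for plate_id, wells in frame.groupby("plate_id", sort=False):
        if isinstance(references, str):
            ref = references
        else:
            if plate_id not in references:
                raise ValueError(f"no reference sample declared for plate {plate_id!r}")
            ref = references[plate_id]
        wells = wells.reset_index(drop=True)
        plate = PlateData(str(plate_id), wells, ref)  # validates dupes + reference
        if panel is not None:
            unknown = set(plate.targets) - set(panel.names)
            for t in sorted(unknown):
                audit.append(
                    {
                        "plate_id": plate_id,
                        "issue": "unknown_target",
                        "detail": f"target {t!r} not in panel",
                    }
                )
            auto = set(panel.autosomal_markers)
            for sample_id, sub in wells.groupby("sample_id"):
                if not (set(sub["target"]) & auto):
                    audit.append(
                        {
                            "plate_id": plate_id,
                            "sample_id": sample_id,
                            "issue": "no_autosomal_wells",
                            "detail": "sample has no wells for any autosomal target",
                        }
                    )
        plates.append(plate)
    return plates, audit


def write_plates(plates: Iterable[PlateData], path: str | Path, sep: str = "\t") -> None:
    """Write plates back to one canonical long-format delimited file."""
    frames = [p.wells.loc[:, list(PLATE_COLUMNS)] for p in plates]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def _norm_category(value: object, allowed: tuple[str, ...], column: str,
                   row: str) -> str:
    text = "" if value is None or (isinstance(value, float) and np.isnan(value)) else str(value).strip()
    if not text:
        return "unknown"
    if text in allowed:
        return text
    # case-insensitive match before declaring unknown
    for cand in allowed:
        if text.lower() == cand.lower():
            return cand
    warnings.warn(
        f"sample {row!r}: unrecognized {column} {text!r} recorded as 'unknown'",
        stacklevel=3,
    )
    return "unknown"


def read_annotations(path: str | Path, sep: str | None = None) -> list[SampleAnnotation]:
    """Read a sample annotation table (sample_id, haplotype, stage, sex, family).

    Unknown category levels are preserved as ``"unknown"`` with a warning;
    rows are never dropped.  Duplicate sample ids raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if "\t" in first else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    if "sample_id" not in frame.columns:
        raise ValueError(f"{path}: missing mandatory column 'sample_id'")
    ids = frame["sample_id"].astype(str).str.strip()
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"{path}: duplicate sample ids {dupes}")

    annotations = []
    for i, row in frame.iterrows():
        sid = str(row["sample_id"]).strip()
        fam = row.get("family_id")
        fam = None if fam is None or (isinstance(fam, float) and np.isnan(fam)) or str(fam).strip() == "" else str(fam).strip()
        annotations.append(
            SampleAnnotation(
                sample_id=sid,
                haplotype=_norm_category(row.get("haplotype"), HAPLOTYPES, "haplotype", sid),
                stage=_norm_category(row.get("stage"), STAGES, "stage", sid),
                phenotypic_sex=_norm_category(
                    row.get("phenotypic_sex"), SEXES, "phenotypic_sex", sid
                ),
                family_id=fam,
            )
        )
    return annotations


def annotations_frame(annotations: Iterable[SampleAnnotation] | pd.DataFrame) -> pd.DataFrame:
    """Coerce annotations (dataclasses or an existing frame) to a DataFrame."""
    if isinstance(annotations, pd.DataFrame):
        return annotations
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "haplotype": [a.haplotype for a in annotations],
            "stage": [a.stage for a in annotations],
            "phenotypic_sex": [a.phenotypic_sex for a in annotations],
            "family_id": [a.family_id for a in annotations],
        }
    )


def unused_annotations(
    annotations: Iterable[SampleAnnotation], plates: Iterable[PlateData]
) -> list[str]:
    """Annotated sample ids that appear on no plate (retained, just flagged)."""
    on_plates: set[str] = set()
    for p in plates:
        on_plates.update(p.sample_ids)
    return [a.sample_id for a in annotations if a.sample_id not in on_plates]
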