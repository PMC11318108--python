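"""Replicate-level quality control of qPCR Ct values.

Four criteria are applied sequentially to each plate, in this fixed order:

1. individual wells with a missing Ct or Ct above the cutoff (default 26.5
   cycles, strict ``>``) are discarded as late-amplification outliers;
2. per sample x target, if the standard deviation of the surviving
   replicates exceeds the maximum (default 0.5 cycles, sample SD with n-1
   denominator, compared with ``<=``), the whole sample x target is
   discarded as unreliable;
3. per sample x target, fewer than the minimum number of surviving
   replicates (default 2 of the triplicate) discards the sample x target;
4. a sample whose autosomal normalizer failed (1)-(3) is discarded entirely,
   since no dCt can be computed for it.

The order matters: the SD in (2) is computed only over replicates that
survived (1).  Every discarded well, target or sample is recorded in an
audit table with the criterion that removed it; no data point vanishes
silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MarkerPanel
from .plate_io import PlateData

SUMMARY_COLUMNS = (
    "plate_id",
    "sample_id",
    "target",
    "role",
    "mean_ct",
    "n_passing",
    "replicate_sd",
    "status",
    "discard_reason",
)

AUDIT_COLUMNS = ("plate_id", "sample_id", "target", "well", "criterion", "detail")

STATUS_OK = "ok"
STATUS_DISCARDED = "discarded"

REASON_SD = "criterion_2_replicate_sd"
REASON_TOO_FEW = "criterion_3_too_few_replicates"
REASON_AUTOSOMAL = "criterion_4_autosomal_failed"
REASON_ABSENT = "absent"


@dataclass(frozen=True)
class QcParams:
    """Filter thresholds.  Defaults are the published criteria."""

    ct_cutoff: float = 26.5       # cycles; wells strictly above are outliers
    replicate_sd_max: float = 0.5  # cycles; SD of surviving replicates, <=
    min_replicates: int = 2        # surviving replicates needed per target

    def __post_init__(self) -> None:
        if self.ct_cutoff <= 0:
            raise ValueError("ct_cutoff must be positive")
        if self.replicate_sd_max < 0:
            raise ValueError("replicate_sd_max must be >= 0")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")


def filter_replicates(
    plate: PlateData,
    panel: MarkerPanel,
    params: QcParams = QcParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the four filter criteria to one plate.

    Returns ``(summaries, audit)``: one summary row per sample x panel
    marker (status ok or discarded, with mean Ct and replicate SD of the
    surviving wells), and an audit table listing every discarded well,
    target and sample with the criterion responsible.
    """
    unknown = set(plate.targets) - set(panel.names)
    if unknown:
        raise ValueError(
            f"plate {plate.plate_id!r} contains targets not in the panel: "
            f"{sorted(unknown)}"
        )

    audit_rows: list[dict] = []
    summary_rows: list[dict] = []

    wells = plate.wells
    for sample_id in plate.sample_ids:
        sample_wells = wells[wells["sample_id"] == sample_id]
        sample_summaries: dict[str, dict] = {}
        for marker in panel.markers:
            sub = sample_wells[sample_wells["target"] == marker.name]
            if sub.empty:
                sample_summaries[marker.name] = {
                    "plate_id": plate.plate_id,
                    "sample_id": sample_id,
                    "target": marker.name,
                    "role": marker.role,
                    "mean_ct": np.nan,
                    "n_passing": 0,
                    "replicate_sd": np.nan,
                    "status": STATUS_DISCARDED,
                    "discard_reason": REASON_ABSENT,
                }
                audit_rows.append(
                    {
                        "plate_id": plate.plate_id,
                        "sample_id": sample_id,
                        "target": marker.name,
                        "well": None,
                        "criterion": REASON_ABSENT,
                        "detail": "no wells for this panel marker",
                    }
                )
                continue

            # criterion 1: drop missing or late (> cutoff) wells
            ct = sub["ct"].astype(float)
            fail1 = ct.isna() | (ct > params.ct_cutoff)
            for _, row in sub[fail1].iterrows():
                detail = (
                    "missing ct"
                    if pd.isna(row["ct"])
                    else f"ct {float(row['ct']):.3f} > cutoff {params.ct_cutoff}"
                )
                audit_rows.append(
                    {
                        "plate_id": plate.plate_id,
                        "sample_id": sample_id,
                        "target": marker.name,
                        "well": row["well"],
                        "criterion": 1,
                        "detail": detail,
                    }
                )
            surviving = ct[~fail1]

            n = int(surviving.size)
            mean_ct = float(surviving.mean()) if n else np.nan
            sd = float(surviving.std(ddof=1)) if n >= 2 else np.nan

            status, reason = STATUS_OK, None
            # criterion 2: replicate scatter of survivors (needs >= 2 values)
            if n >= 2 and sd > params.replicate_sd_max:
                status, reason = STATUS_DISCARDED, REASON_SD
                audit_rows.append(
                    {
                        "plate_id": plate.plate_id,
                        "sample_id": sample_id,
                        "target": marker.name,
                        "well": None,
                        "criterion": 2,
                        "detail": f"replicate sd {sd:.3f} > {params.replicate_sd_max}",
                    }
                )
            # criterion 3: enough surviving replicates
            elif n < params.min_replicates:
                status, reason = STATUS_DISCARDED, REASON_TOO_FEW
                audit_rows.append(
                    {
                        "plate_id": plate.plate_id,
                        "sample_id": sample_id,
                        "target": marker.name,
                        "well": None,
                        "criterion": 3,
                        "detail": f"{n} surviving replicates < {params.min_replicates}",
                    }
                )

            sample_summaries[marker.name] = {
                "plate_id": plate.plate_id,
                "sample_id": sample_id,
                "target": marker.name,
                "role": marker.role,
                "mean_ct": mean_ct if status == STATUS_OK else np.nan,
                "n_passing": n,
                "replicate_sd": sd,
                "status": status,
                "discard_reason": reason,
            }

        # criterion 4: no usable autosomal normalizer -> drop whole sample
        autosomal_ok = any(
            sample_summaries[name]["status"] == STATUS_OK
            for name in panel.autosomal_markers
        )
        if not autosomal_ok:
            for name, summ in sample_summaries.items():
                if summ["status"] == STATUS_OK:
                    summ["status"] = STATUS_DISCARDED
                    summ["discard_reason"] = REASON_AUTOSOMAL
                    summ["mean_ct"] = np.nan
            audit_rows.append(
                {
                    "plate_id": plate.plate_id,
                    "sample_id": sample_id,
                    "target": None,
                    "well": None,
                    "criterion": 4,
                    "detail": "no Ct computable for the autosomal marker; "
                    "sample discarded",
                }
            )
        summary_rows.extend(sample_summaries.values())

    summaries = pd.DataFrame(summary_rows, columns=list(SUMMARY_COLUMNS))
    audit = pd.DataFrame(audit_rows, columns=list(AUDIT_COLUMNS))
    return summaries, audit


def surviving_wells(plate: PlateData, audit: pd.DataFrame) -> pd.DataFrame:
    """Wells of ``plate`` not individually discarded by criterion 1.

    Criterion 2-4 discards act on whole targets/samples; the well-level
    conservation property (every well is either here or in the audit) holds
    against criterion-1 rows.
    """
    dropped = set(audit.loc[audit["criterion"] == 1, "well"].dropna())
    return plate.wells[~plate.wells["well"].isin(dropped)]
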