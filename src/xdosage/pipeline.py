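"""End-to-end driver: plates -> QC -> fold changes -> consensus sex calls."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .panel import MarkerPanel
from .plate_io import PlateData
from .qc import QcParams, STATUS_OK, filter_replicates
from .quantify import fold_change
from .sexcall import CallParams, SexAssignment, assign_sex


@dataclass
class SexingResult:
    """Everything the pipeline produced, stage by stage."""

    summaries: pd.DataFrame        # QC per sample x marker
    qc_audit: pd.DataFrame         # per-discard audit rows
    folds: pd.DataFrame            # per sample x X marker fold changes
    fold_log: pd.DataFrame         # sample x marker combinations skipped
    assignments: list[SexAssignment]
    assignment_table: pd.DataFrame

    def assignment(self, sample_id: str) -> SexAssignment:
        for a in self.assignments:
            if a.sample_id == sample_id:
                return a
        raise KeyError(sample_id)


def run_sexing(
    plates: PlateData | Sequence[PlateData],
    panel: MarkerPanel,
    qc_params: QcParams = QcParams(),
    call_params: CallParams = CallParams(),
    mode: str = "single_factor",
) -> SexingResult:
    """Run QC, quantification and sex calling over one or more plates.

    Each plate is filtered and quantified against its own declared female
    reference; fold tables are concatenated and consensus calls made per
    sample.  Samples present on the plates but lacking any computable fold
    change (QC failures) are reported as removed with reason ``qc_failed``.
    """
    if isinstance(plates, PlateData):
        plates = [plates]
    if not plates:
        raise ValueError("no plates given")

    summaries_parts, audit_parts = [], []
    references: dict[str, str] = {}
    all_samples: list[str] = []
    for plate in plates:
        s, a = filter_replicates(plate, panel, qc_params)
        summaries_parts.append(s)
        audit_parts.append(a)
        references[plate.plate_id] = plate.reference_sample
        all_samples.extend(plate.sample_ids)

    summaries = pd.concat(summaries_parts, ignore_index=True)
    qc_audit = pd.concat(audit_parts, ignore_index=True)

    folds, fold_log = fold_change(summaries, panel, references, mode=mode)

    with_folds = set(folds["sample_id"])
    qc_failed = [s for s in dict.fromkeys(all_samples) if s not in with_folds]
    assignments, table = assign_sex(folds, call_params, qc_failed=qc_failed)
    return SexingResult(summaries, qc_audit, folds, fold_log, assignments, table)
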