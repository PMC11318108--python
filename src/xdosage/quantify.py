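"""Efficiency-corrected relative quantification (2^-ddCt).

Standard curves
---------------
Primer efficiency is estimated by ordinary least squares of Ct on
log10(template concentration) over a serial dilution.  A perfect primer
doubles template each cycle, giving slope -log2(10) = -3.3219 cycles per
decade; the amplification factor is recovered as ``A = 10^(-1/slope)`` and
the efficiency as ``(A - 1) * 100`` percent.

Fold changes
------------
For each sample the within-sample dCt is the X-marker Ct minus the
autosomal-marker Ct (this sign makes a one-copy X come out at fold 0.5, the
dosage expectation); the ddCt subtracts the same quantity for the plate's
female reference, and the fold change is ``A^(-ddCt)`` with ``A`` the
X-primer's amplification factor (``single_factor`` mode, the default).  The
``efficiency_ratio`` mode applies each primer's own factor to its Ct
difference (Pfaffl-style ratio); the two agree when the factors are equal or
the sample's autosomal Ct matches the reference's.  Computation is strictly
per plate — each plate carries its own reference — and tables are
concatenated afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MarkerPanel
from .qc import STATUS_OK

FOLD_COLUMNS = (
    "plate_id",
    "sample_id",
    "target",
    "dct",
    "ddct",
    "fold",
    "reference_sample",
)

MODES = ("single_factor", "efficiency_ratio")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution series for one primer pair."""

    target: str
    points: tuple[tuple[float, float], ...]  # (concentration, mean ct)
    slope: float                             # cycles per log10(concentration)
    intercept: float
    r_squared: float
    amplification_factor: float              # 10^(-1/slope)
    efficiency_pct: float                    # (A - 1) * 100
    valid: bool                              # slope < 0


def fit_standard_curve(
    points: Iterable[tuple[float, float]] | pd.DataFrame,
    target: str = "",
) -> StandardCurve:
    """OLS fit of Ct on log10(concentration).

    ``points`` is an iterable of (concentration, ct) pairs or a DataFrame
    with ``concentration`` and ``ct`` columns (replicate rows allowed).
    Non-positive concentrations raise; a non-negative slope yields a curve
    flagged invalid (no meaningful amplification factor).
    """
    if isinstance(points, pd.DataFrame):
        conc = points["concentration"].to_numpy(dtype=float)
        ct = points["ct"].to_numpy(dtype=float)
    else:
        pts = [(float(c), float(v)) for c, v in points]
        conc = np.array([c for c, _ in pts])
        ct = np.array([v for _, v in pts])
    if conc.size < 2 or np.unique(conc).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")

    fit = stats.linregress(np.log10(conc), ct)
    slope = float(fit.slope)
    valid = slope < 0
    if valid:
        amplification_factor = float(10.0 ** (-1.0 / slope))
        efficiency_pct = (amplification_factor - 1.0) * 100.0
    else:
        amplification_factor = float("nan")
        efficiency_pct = float("nan")

    mean_by_conc = (
        pd.DataFrame({"concentration": conc, "ct": ct})
        .groupby("concentration", sort=False)["ct"]
        .mean()
    )
    return StandardCurve(
        target=target,
        points=tuple(
            (float(c), float(v)) for c, v in mean_by_conc.items()
        ),
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        amplification_factor=amplification_factor,
        efficiency_pct=efficiency_pct,
        valid=valid,
    )


def _plate_reference(references: str | Mapping[str, str], plate_id: str) -> str:
    if isinstance(references, str):
        return references
    if plate_id not in references:
        raise ValueError(f"no reference sample declared for plate {plate_id!r}")
    return references[plate_id]


def fold_change(
    summaries: pd.DataFrame,
    panel: MarkerPanel,
    reference_sample: str | Mapping[str, str],
    mode: str = "single_factor",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plate efficiency-corrected fold changes of X markers.

    Parameters
    ----------
    summaries
        QC summary table (from :func:`xdosage.qc.filter_replicates`,
        possibly concatenated over plates).
    reference_sample
        The female reference: one id for all plates or ``plate_id -> id``.
    mode
        ``single_factor`` (default): fold = A_x^(-ddct).
        ``efficiency_ratio``: per-primer factors applied separately.

    Returns
    -------
    (folds, skipped)
        ``folds`` has one row per sample x X marker that passed QC;
        ``skipped`` logs sample x marker combinations for which no fold
        could be computed (QC-discarded or marker missing).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    unknown = set(summaries["target"]) - set(panel.names)
    if unknown:
        raise ValueError(f"summaries contain unknown markers: {sorted(unknown)}")

    fold_rows: list[dict] = []
    skip_rows: list[dict] = []
    for plate_id, plate_sum in summaries.groupby("plate_id", sort=False):
        ref = _plate_reference(reference_sample, str(plate_id))
        ok = plate_sum[plate_sum["status"] == STATUS_OK]
        ok_ct = {
            (r.sample_id, r.target): float(r.mean_ct)
            for r in ok.itertuples(index=False)
        }

        def autosomal_ct(sample_id: str) -> float | None:
            values = [
                ok_ct[(sample_id, name)]
                for name in panel.autosomal_markers
                if (sample_id, name) in ok_ct
            ]
            return float(np.mean(values)) if values else None

        ref_auto = autosomal_ct(ref)
        ref_x = {
            name: ok_ct.get((ref, name)) for name in panel.x_markers
        }
        if ref_auto is None or not any(v is not None for v in ref_x.values()):
            raise ValueError(
                f"plate {plate_id!r}: reference sample {ref!r} has no usable "
                "autosomal or X-marker Ct after QC; nothing computable"
            )

        for sample_id in pd.unique(plate_sum["sample_id"]):
            auto = autosomal_ct(str(sample_id))
            for name in panel.x_markers:
                ct_x = ok_ct.get((sample_id, name))
                ct_x_ref = ref_x.get(name)
                if auto is None or ct_x is None or ct_x_ref is None:
                    skip_rows.append(
                        {
                            "plate_id": plate_id,
                            "sample_id": sample_id,
                            "target": name,
                            "detail": "autosomal Ct unavailable"
                            if auto is None
                            else (
                                "marker failed QC or absent"
                                if ct_x is None
                                else "reference marker failed QC"
                            ),
                        }
                    )
                    continue
                dct = ct_x - auto
                dct_ref = ct_x_ref - ref_auto
                ddct = dct - dct_ref
                a_x = panel.factor(name)
                if mode == "single_factor":
                    fold = a_x ** (-ddct)
                else:
                    # mean autosomal factor when the panel has several
                    a_auto = float(
                        np.mean([panel.factor(n) for n in panel.autosomal_markers])
                    )
                    fold = (a_x ** (-(ct_x - ct_x_ref))) / (
                        a_auto ** (-(auto - ref_auto))
                    )
                fold_rows.append(
                    {
                        "plate_id": plate_id,
                        "sample_id": sample_id,
                        "target": name,
                        "dct": dct,
                        "ddct": ddct,
                        "fold": fold,
                        "reference_sample": ref,
                    }
                )

    folds = pd.DataFrame(fold_rows, columns=list(FOLD_COLUMNS))
    skipped = pd.DataFrame(
        skip_rows, columns=["plate_id", "sample_id", "target", "detail"]
    )
    return folds, skipped
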