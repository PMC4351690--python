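"""Comparative-CT (2^-ddCT) relative quantification.

Per sample, dCT = mean CT(target) - mean CT(endogenous control);
ddCT = dCT(sample) - dCT(calibrator sample); fold = 2^-ddCT. Amplification
efficiency is assumed exact (base 2, no correction). Replicate dispersion is
summarized as the standard deviation over replicate-wise folds (replicate i
of the target paired with replicate i of the control); a delta-method
propagation from the ddCT scale is available behind ``sd_mode="propagated"``
and is the automatic fallback when replicate counts differ.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

_LN2 = math.log(2.0)


@dataclass
class CTMeasurement:
    """Replicate threshold-cycle values for one (sample, assay)."""

    sample_id: str
    assay_id: str
    cts: np.ndarray

    def __post_init__(self) -> None:
        self.cts = np.asarray(self.cts, dtype=float)
        if self.cts.ndim != 1 or len(self.cts) == 0:
            raise ValueError("need >= 1 replicate CT value")
        if not np.all(np.isfinite(self.cts)):
            raise ValueError(
                f"non-finite CT for {self.sample_id}/{self.assay_id}"
            )

    @property
    def mean(self) -> float:
        return float(self.cts.mean())


@dataclass
class RelativeQuant:
    sample_id: str
    assay_id: str
    fold: float
    sd: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def _propagated_sd(target: CTMeasurement, control: CTMeasurement, fold: float) -> float:
    var_t = target.cts.var(ddof=1) if len(target.cts) > 1 else 0.0
    var_c = control.cts.var(ddof=1) if len(control.cts) > 1 else 0.0
    sd_ddct = math.sqrt(var_t + var_c)
    return fold * _LN2 * sd_ddct


def delta_delta_ct(
    target: CTMeasurement,
    control: CTMeasurement,
    calibrator_target: CTMeasurement,
    calibrator_control: CTMeasurement,
    sd_mode: str = "replicate",
) -> RelativeQuant:
    """Relative quantity of one sample/assay versus the calibrator sample.

    The calibrator evaluated against itself yields fold exactly 1. With
    ``sd_mode="replicate"`` (default) the SD comes from replicate-wise folds;
    mismatched replicate counts fall back to the propagated SD with a
    warning. ``sd_mode="propagated"`` always uses the ddCT-scale propagation.
    """
    if sd_mode not in ("replicate", "propagated"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    if control.assay_id != calibrator_control.assay_id:
        raise ValueError("endogenous control assay differs between samples")
    dct_cal = calibrator_target.mean - calibrator_control.mean
    ddct = (target.mean - control.mean) - dct_cal
    fold = 2.0 ** (-ddct)
    if sd_mode == "replicate" and len(target.cts) == len(control.cts):
        rep_folds = 2.0 ** (-((target.cts - control.cts) - dct_cal))
        sd = float(rep_folds.std(ddof=1)) if len(rep_folds) > 1 else 0.0
    else:
        if sd_mode == "replicate":
            warnings.warn(
                f"replicate count mismatch for {target.sample_id}/"
                f"{target.assay_id}; falling back to propagated SD",
                stacklevel=2,
            )
        sd = _propagated_sd(target, control, fold)
    return RelativeQuant(target.sample_id, target.assay_id, float(fold), sd)


def read_ct_table(path: str | Path) -> list[CTMeasurement]:
    """CSV with columns sample_id, assay_id, ct (one row per replicate)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "assay_id": str})
    needed = {"sample_id", "assay_id", "ct"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (sample, assay), grp in df.groupby(
        ["sample_id", "assay_id"], sort=True
    ):
        out.append(CTMeasurement(sample, assay, grp["ct"].to_numpy(float)))
    return out


def batch_relative_quant(
    measurements: list[CTMeasurement],
    control_assay: str,
    calibrator_sample: str,
    sd_mode: str = "replicate",
) -> list[RelativeQuant]:
    """One :class:`RelativeQuant` per (sample, target assay).

    Every sample must carry the endogenous control assay, and the calibrator
    sample must carry the control plus every target assay it is used for.
    Output is ordered by sample id then assay id.
    """
    table: dict[tuple[str, str], CTMeasurement] = {}
    for m in measurements:
        key = (m.sample_id, m.assay_id)
        if key in table:
            raise ValueError(f"duplicate measurement for {key}")
        table[key] = m
    samples = sorted({m.sample_id for m in measurements})
    assays = sorted(
        {m.assay_id for m in measurements if m.assay_id != control_assay}
    )
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not present")
    for s in samples:
        if (s, control_assay) not in table:
            raise ValueError(f"sample {s!r} lacks control assay {control_assay!r}")
    results = []
    cal_control = table[(calibrator_sample, control_assay)]
    for s in samples:
        for a in assays:
            if (s, a) not in table:
                continue
            if (calibrator_sample, a) not in table:
                raise ValueError(
                    f"calibrator sample {calibrator_sample!r} lacks assay {a!r}"
                )
            results.append(
                delta_delta_ct(
                    table[(s, a)],
                    table[(s, control_assay)],
                    table[(calibrator_sample, a)],
                    cal_control,
                    sd_mode=sd_mode,
                )
            )
    return results


def write_quant_table(quants: list[RelativeQuant], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sample_id": q.sample_id, "assay_id": q.assay_id,
             "fold": q.fold, "sd": q.sd}
            for q in quants
        ]
    ).to_csv(path, index=False)
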