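"""Normalization arithmetic for qPCR, knockdown efficiency, insulin
secretion (GSIS) and 3C chromatin-contact assays.

All four operations are small, exactly specified ratio computations:

* qPCR: the 2^-dCt model with an internal reference gene (e.g. TBP),
  expressed as fold over a baseline — either the control-amiRNA group or,
  for decay time courses, the t = 0 measurement (percentage mode).
* amiRNA efficiency: percent knockdown from the fraction of transcript
  remaining; an amiRNA counts as efficient only above 50% knockdown
  (strict inequality).
* GSIS: secreted insulin normalized per cell, fold over the control group
  at basal (2.8 mM) glucose; the secretion index (secreted / content)
  corrects for changes in cellular insulin content.
* 3C: qPCR contact signal relative to an intronic control region, then
  expressed as a fraction of the non-targeting control sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "qpcr_relative_expression",
    "amirna_efficiency",
    "gsis_summary",
    "contact_normalization",
    "two_reference_ratio",
]


def qpcr_relative_expression(
    measurements: pd.DataFrame,
    baseline: str = "control_group",
    percent: bool = False,
) -> pd.Series:
    """Fold expression per sample from Ct values.

    ``measurements`` needs columns ``ct_target``, ``ct_reference`` and
    ``group``; baseline "time_zero" additionally needs ``timepoint``.
    rel = 2^-(ct_target - ct_reference); fold = rel / mean(rel of the
    baseline rows).  ``percent`` multiplies by 100 (decay-curve
    convention, with the t = 0 mean at 100%).
    """
    rel = 2.0 ** -(measurements["ct_target"] - measurements["ct_reference"])
    if baseline == "control_group":
        base = rel[measurements["group"] == "control"]
    elif baseline == "time_zero":
        base = rel[measurements["timepoint"] == 0]
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    if base.empty:
        raise ValueError("baseline group is empty")
    fold = rel / base.mean()
    if percent:
        fold = fold * 100.0
    return fold.rename("fold")


def two_reference_ratio(signal, ref_a, ref_b) -> np.ndarray:
    """Quantification against the mean of two reference signals
    (e.g. a protein band normalized to the average of TBP and H3)."""
    signal = np.asarray(signal, dtype=float)
    denom = (np.asarray(ref_a, dtype=float) + np.asarray(ref_b, dtype=float)) / 2.0
    if (denom <= 0).any():
        raise ValueError("reference signals must be positive")
    return signal / denom


def amirna_efficiency(fold_remaining: float) -> tuple[float, bool]:
    """Percent knockdown and the efficiency gate (> 50%, strict)."""
    if fold_remaining < 0:
        raise ValueError("fold_remaining must be >= 0")
    knockdown_pct = 100.0 * (1.0 - fold_remaining)
    return knockdown_pct, knockdown_pct > 50.0


def gsis_summary(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-well normalized secretion, fold over basal control, and the
    content-corrected secretion index.

    Columns required: ``secreted_insulin``, ``insulin_content``,
    ``cells_per_well``, ``glucose_mM``, ``group``.  Fold is relative to
    the mean of control wells at 2.8 mM glucose.
    """
    df = measurements.copy()
    if (df["cells_per_well"] <= 0).any() or (df["insulin_content"] <= 0).any():
        raise ValueError("cells_per_well and insulin_content must be positive")
    df["normalized"] = df["secreted_insulin"] / df["cells_per_well"]
    basal_control = df[(df["group"] == "control") & (df["glucose_mM"] == 2.8)]
    if basal_control.empty:
        raise ValueError("no control wells at 2.8 mM glucose")
    df["fold"] = df["normalized"] / basal_control["normalized"].mean()
    df["secretion_index"] = df["secreted_insulin"] / df["insulin_content"]
    return df


def contact_normalization(measurements: pd.DataFrame) -> pd.DataFrame:
    """3C contact signal per region, normalized twice.

    Columns required: ``region``, ``signal``, ``control_signal`` (the
    intronic control region's signal in the same sample) and ``group``.
    interaction = signal / control_signal; the reported value divides by
    the mean interaction of the control-group sample(s) for that region.
    """
    df = measurements.copy()
    if (df["control_signal"] <= 0).any():
        raise ValueError("control-region signal must be positive")
    df["interaction"] = df["signal"] / df["control_signal"]
    out_rows = []
    for region, sub in df.groupby("region", sort=False):
        ctrl = sub[sub["group"] == "control"]
        if ctrl.empty:
            raise ValueError(f"region {region!r} has no control sample")
        denom = ctrl["interaction"].mean()
        sub = sub.copy()
        sub["normalized"] = sub["interaction"] / denom
        out_rows.append(sub)
    return pd.concat(out_rows)
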