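"""Closed-form wet-lab quantifications.

qPCR-based CRISPR deletion efficiency, 2^-ddCt relative expression,
glucose-stimulated insulin secretion (GSIS) normalization, dual
luciferase normalization and growth-curve normalization.  Operations
act on single measurements; :func:`average_replicates` collapses
technical duplicates beforehand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class CtQuartet:
    """Cycle thresholds for target and copy-number reference in edited vs WT cells."""

    ct_target_edited: float
    ct_ref_edited: float
    ct_target_wt: float
    ct_ref_wt: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not math.isfinite(v):
                raise ValidationError(f"non-finite Ct value for {name}")


@dataclass(frozen=True)
class SecretionPair:
    """Secreted insulin and total cellular insulin content, same assay units."""

    secreted: float
    content: float

    def __post_init__(self) -> None:
        if self.content <= 0:
            raise ValidationError("insulin content must be positive")
        if self.secreted < 0:
            raise ValidationError("secreted insulin cannot be negative")


def editing_efficiency(q: CtQuartet) -> float:
    """CRISPR deletion efficiency (%) from wild-type-allele qPCR.

    With dCt = Ct(target) - Ct(reference) in each condition,

        efficiency = (1 - 2^-(dCt_edited - dCt_wt)) * 100.

    One extra cycle to detect the intact allele in edited cells means
    half the template survived, i.e. 50% efficiency.  A negative value
    (edited template amplifying earlier than wild type) is reported
    unclamped with a warning.
    """
    ddct = (q.ct_target_edited - q.ct_ref_edited) - (q.ct_target_wt - q.ct_ref_wt)
    eff = (1.0 - 2.0 ** (-ddct)) * 100.0
    if eff < 0:
        warnings.warn(f"negative editing efficiency ({eff:.1f}%)", stacklevel=2)
    return eff


def relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Fold expression by the 2^-ddCt method (control vs itself = 1.0)."""
    for v in (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control):
        if not math.isfinite(v):
            raise ValidationError("non-finite Ct value")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


def secretion_percent(p: SecretionPair) -> float:
    """Secreted insulin as a percentage of total cellular content."""
    return 100.0 * p.secreted / p.content


def fold_over_basal(stim_percent: float, basal_percent: float) -> float:
    """Stimulated secretion as a fold of low-glucose basal secretion."""
    if basal_percent <= 0:
        raise ValidationError("basal secretion must be positive")
    return stim_percent / basal_percent


def luciferase_activity(
    firefly: float, renilla: float, firefly_ctrl: float, renilla_ctrl: float
) -> float:
    """Renilla-normalized firefly activity relative to the empty-vector control."""
    if renilla <= 0 or renilla_ctrl <= 0 or firefly_ctrl <= 0:
        raise ValidationError("normalization denominators must be positive")
    return (firefly / renilla) / (firefly_ctrl / renilla_ctrl)


def growth_normalize(od_series: Sequence[float], od_day0: float) -> np.ndarray:
    """Normalize an optical-density time course to its day-0 value."""
    if od_day0 <= 0:
        raise ValidationError("day-0 optical density must be positive")
    return np.asarray(od_series, dtype=float) / od_day0


def average_replicates(
    df: pd.DataFrame, group_cols: Sequence[str], value_cols: Sequence[str]
) -> pd.DataFrame:
    """Mean of technical replicates per condition, keeping group columns."""
    return df.groupby(list(group_cols), as_index=False, sort=False)[list(value_cols)].mean()
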