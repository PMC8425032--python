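"""Relative qPCR expression by the ddCp (Livak) method with multi-reference averaging.

For each sample, dCp = Cp_target - mean(Cp_references); the expression
level is 2**-dCp, and the fold-change between conditions a and b is
2**-dCp_a / 2**-dCp_b, whose log2 is simply dCp_b - dCp_a.  Reference
genes are combined by the arithmetic mean of their Cp values.  Replicate
pairs are analyzed individually and summarized as mean +/- SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trace_model import CpRecord, ValidationError

__all__ = ["ExpressionResult", "expression_level", "log2_fold_change", "replicate_log2_fc"]


@dataclass(frozen=True)
class ExpressionResult:
    """dCp and the derived expression level 2**-dCp for one record."""

    delta_cp: float
    expression_level: float
    condition: str
    strain: str


def expression_level(record: CpRecord) -> ExpressionResult:
    """dCp = Cp_target - mean(Cp_refs); expression level = 2**-dCp."""
    if not record.reference_cps:
        raise ValidationError("at least one reference Cp is required")
    delta = record.target_cp - float(np.mean(record.reference_cps))
    return ExpressionResult(
        delta_cp=delta,
        expression_level=2.0**-delta,
        condition=record.condition,
        strain=record.strain,
    )


def log2_fold_change(condition_a: ExpressionResult, condition_b: ExpressionResult) -> float:
    """log2 of level_a/level_b, computed exactly as dCp_b - dCp_a."""
    return condition_b.delta_cp - condition_a.delta_cp


def replicate_log2_fc(
    records_a: Sequence[CpRecord], records_b: Sequence[CpRecord]
) -> tuple[float, float]:
    """Per-replicate log2 fold-changes (a over b), summarized as (mean, SD).

    Replicates are paired in order; the two lists must have equal length.
    SD is reported as 0 for a single pair.
    """
    if len(records_a) != len(records_b) or not records_a:
        raise ValidationError("need equal, non-zero numbers of replicate records")
    fcs = [
        log2_fold_change(expression_level(a), expression_level(b))
        for a, b in zip(records_a, records_b)
    ]
    sd = float(np.std(fcs, ddof=1)) if len(fcs) > 1 else 0.0
    return float(np.mean(fcs)), sd
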