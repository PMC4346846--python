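"""Relative qPCR quantification by 2^-ΔΔCt with multi-reference normalization.

For each unit (tissue) and biological subject, technical-replicate Ct
values are averaged on the Ct scale, then

    ΔCt  = Ct_target − mean(Ct_ref1, ..., Ct_refk)
    ΔΔCt = ΔCt_unit − ΔCt_calibrator
    RQ   = 2^−ΔΔCt

The arithmetic mean of reference Cts equals the log2 of the geometric mean
of their linear quantities, so this is normalization to the geometric mean
of the reference genes.  Amplification efficiency is fixed at 2.0 (100%).
With a single reference gene the computation reduces to the textbook
two-gene 2^-ΔΔCt.  The calibrator unit's point estimate is exactly 1.

Across-tissue comparison runs a one-way ANOVA on log2(RQ) over biological
subjects followed by pairwise t-tests in the protected (Fisher's LSD)
fashion — pairwise testing happens only when the ANOVA rejects — with
letter groups from the same compact-letter-display routine the
association module uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import letter_grouping
from .datamodel import CtTable, DataError


@dataclass
class ExpressionResult:
    """Relative quantities per unit, with per-subject replicate values."""

    target: str
    refs: list[str]
    calibrator: str
    rq: pd.Series                 # point estimate per unit (calibrator = 1)
    log2_rq_subjects: pd.DataFrame  # rows (unit, subject), column 'log2_rq'
    delta_ct: pd.Series           # mean ΔCt per unit

    def spread(self) -> pd.Series:
        """SD of log2 RQ across biological subjects, per unit."""
        return self.log2_rq_subjects.groupby("unit")["log2_rq"].std()


def delta_delta_ct(
    ct: CtTable, target: str, refs: Sequence[str], calibrator: str
) -> ExpressionResult:
    """Relative expression of *target* against *refs*, scaled to *calibrator*.

    Raises if the target or any reference gene is unmeasured in some unit,
    or if the calibrator unit is absent.
    """
    refs = list(refs)
    mean_ct = ct.mean_ct()  # (unit, subject) x gene
    genes_needed = [target, *refs]
    for g in genes_needed:
        if g not in mean_ct.columns:
            raise DataError(f"gene {g!r} not present in Ct table")
        missing = mean_ct.index[mean_ct[g].isna()].tolist()
        if missing:
            raise DataError(f"gene {g!r} unmeasured in unit(s) {missing}")
    units = mean_ct.index.get_level_values("unit")
    if calibrator not in set(units):
        raise DataError(f"calibrator unit {calibrator!r} not in Ct table")
    dct = mean_ct[target] - mean_ct[refs].mean(axis=1)
    dct_by_unit = dct.groupby("unit").mean()
    ddct_subj = dct - dct_by_unit.loc[calibrator]
    log2_rq = (-ddct_subj).rename("log2_rq").reset_index()
    rq_unit = np.exp2(-(dct_by_unit - dct_by_unit.loc[calibrator]))
    return ExpressionResult(
        target=target,
        refs=refs,
        calibrator=calibrator,
        rq=rq_unit,
        log2_rq_subjects=log2_rq,
        delta_ct=dct_by_unit,
    )


def tissue_comparison(
    res: ExpressionResult, alpha: float = 0.05
) -> tuple[dict[str, str], float]:
    """Letter groups across units from log2(RQ) of biological subjects.

    Units with fewer than two subjects are excluded with a warning.
    Returns ``(letters per unit, overall ANOVA p)``.
    """
    groups = {
        unit: sub["log2_rq"].to_numpy(float)
        for unit, sub in res.log2_rq_subjects.groupby("unit")
    }
    excluded = [u for u, v in groups.items() if len(v) < 2]
    if excluded:
        warnings.warn(f"unit(s) with <2 biological replicates excluded: {excluded}")
        groups = {u: v for u, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise DataError("need >=2 units with >=2 biological replicates")
    units = sorted(groups)
    overall_p = float(stats.f_oneway(*(groups[u] for u in units)).pvalue)
    order = sorted(units, key=lambda u: -float(np.mean(groups[u])))
    if not overall_p < alpha:
        # protected (Fisher's LSD) comparison: no pairwise testing unless
        # the overall ANOVA rejects
        return {u: "a" for u in units}, overall_p
    pw = pd.DataFrame(np.nan, index=units, columns=units)
    for i, g in enumerate(units):
        for h in units[i + 1 :]:
            a, b = groups[g], groups[h]
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                # degenerate zero-variance groups: identical -> p 1, else 0
                p = 1.0 if a.mean() == b.mean() else 0.0
            else:
                p = float(stats.ttest_ind(a, b).pvalue)
            pw.loc[g, h] = pw.loc[h, g] = p
    return letter_grouping(pw, alpha, order), overall_p


def expression_table(res: ExpressionResult, letters: dict[str, str] | None = None) -> pd.DataFrame:
    """Tidy per-unit output: RQ, spread, optional letters."""
    out = pd.DataFrame({"rq": res.rq, "sd_log2_rq": res.spread()})
    if letters is not None:
        out["letters"] = pd.Series(letters)
    return out.rename_axis("unit").reset_index()
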