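"""Relative-quantification arithmetic for qPCR and ChIP-qPCR.

The comparative-Ct method assumes a doubling per cycle (efficiency 2,
configurable): DeltaCt = target Ct - reference Ct, DeltaDeltaCt =
DeltaCt - mean DeltaCt of the reference condition, fold =
efficiency^(-DeltaDeltaCt). ChIP enrichment divides the
antibody-over-IgG enrichment of the induced condition by that of the
uninduced condition, so the uninduced baseline is 1 by construction.
Fold changes are tested against the null value 1 with a one-sample t.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    DomainError,
    SampleSizeError,
)

DOX = "dox"
NO_DOX = "no_dox"


def _check_ct(values) -> None:
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all() or (v <= 0).any():
        raise DomainError("cycle thresholds must be positive and finite")


def delta_delta_ct(
    records: pd.DataFrame,
    reference_condition: str = NO_DOX,
    efficiency: float = 2.0,
) -> pd.Series:
    """Per-sample fold change by the comparative-Ct method.

    ``records`` columns: sample_id, condition, target_ct, reference_ct.
    The reference condition's mean DeltaCt anchors the scale, so its mean
    fold is 1 by construction. Invariant to adding a constant to every
    Ct value.
    """
    required = {"sample_id", "condition", "target_ct", "reference_ct"}
    missing = required - set(records.columns)
    if missing:
        raise ConfigurationError(f"missing columns: {sorted(missing)}")
    _check_ct(records["target_ct"])
    _check_ct(records["reference_ct"])
    delta = records["target_ct"].astype(float) - records["reference_ct"].astype(float)
    ref_mask = records["condition"] == reference_condition
    if not ref_mask.any():
        raise ConfigurationError(
            f"reference condition {reference_condition!r} absent"
        )
    ddct = delta - delta[ref_mask].mean()
    fold = pd.Series(np.power(efficiency, -ddct.to_numpy()),
                     index=records["sample_id"], name="fold_change")
    return fold


def chip_fold_enrichment(
    records: pd.DataFrame, efficiency: float = 2.0
) -> pd.Series:
    """Per-region ChIP enrichment of the induced over uninduced condition.

    ``records`` columns: region, condition (dox / no_dox), antibody
    ('target' or 'IgG'), ct. Per condition,
    enrichment = efficiency^-(Ct_target - Ct_IgG); the reported value is
    enrichment_dox / enrichment_no_dox (uninduced baseline = 1). Several
    replicate rows per (region, condition, antibody) are averaged on the
    Ct scale. The result is unchanged by adding one constant to all four
    Ct values of a region.
    """
    required = {"region", "condition", "antibody", "ct"}
    missing = required - set(records.columns)
    if missing:
        raise ConfigurationError(f"missing columns: {sorted(missing)}")
    _check_ct(records["ct"])
    out = {}
    for region, sub in records.groupby("region"):
        ct = {}
        for cond in (DOX, NO_DOX):
            for ab in ("target", "IgG"):
                sel = (sub["condition"] == cond) & (sub["antibody"] == ab)
                if not sel.any():
                    raise ConfigurationError(
                        f"region {region!r}: missing {ab} Ct for condition {cond!r}"
                    )
                ct[cond, ab] = float(sub.loc[sel, "ct"].astype(float).mean())
        enr_dox = efficiency ** (-(ct[DOX, "target"] - ct[DOX, "IgG"]))
        enr_no = efficiency ** (-(ct[NO_DOX, "target"] - ct[NO_DOX, "IgG"]))
        out[region] = enr_dox / enr_no
    return pd.Series(out, name="normalized_enrichment")


def one_sample_t(
    values: Sequence[float],
    hypothesized_mean: float = 1.0,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """One-sample t test of fold changes against a hypothesized mean
    (default 1, the no-change null). ``alternative`` is 'two-sided',
    'greater' or 'less'; n >= 3 and nonzero variance required."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise SampleSizeError(f"one-sample t needs >= 3 values, got {v.size}")
    if np.ptp(v) == 0:
        raise DegenerateDataError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(v, hypothesized_mean, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
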