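"""Per-cohort preprocessing to the analysis (log2) scale.

Array cohorts go through background correction, log2 transformation and
quantile normalization; probes are then filtered on array detection
p-values (a probe is "expressed" when its detection p is below the cutoff
in at least ``min_detected_samples`` samples — by default one sample, the
permissive convention for two-class tissue panels). RNA-seq cohorts
distributed as upper-quartile-normalized counts are only log2-transformed
with a pseudocount; no quantile normalization is applied to them.

Background correction is a minimum-shift rule: if the cohort's minimum is
<= 0, the whole matrix is shifted so its minimum becomes 1. Model-based
array background adjustment needs bead-level data that public matrices do
not carry; the shift rule is deterministic and preserves all contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import SCALE_LOG2, SCALE_RAW, ExpressionDataset
from .errors import DomainError, MissingDataError, ScaleError

log = logging.getLogger(__name__)


@dataclass
class NormalizationConfig:
    """Knobs for cohort preprocessing.

    background_mode : 'shift_to_positive' or 'none'
    detection_p_max : strict upper bound for a probe to count as detected
        in a sample (default 0.01)
    min_detected_samples : number of samples that must detect a probe for
        it to be kept (default 1)
    rnaseq_pseudocount : added before log2 on count-scale data (default 1)
    """

    background_mode: str = "shift_to_positive"
    detection_p_max: float = 0.01
    min_detected_samples: int = 1
    rnaseq_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.detection_p_max < 1:
            raise DomainError("detection_p_max must be in (0, 1)")
        if self.min_detected_samples < 1:
            raise DomainError("min_detected_samples must be >= 1")
        if self.rnaseq_pseudocount <= 0:
            raise DomainError("rnaseq_pseudocount must be positive")
        if self.background_mode not in ("shift_to_positive", "none"):
            raise DomainError(f"unknown background_mode {self.background_mode!r}")


def background_correct(
    ds: ExpressionDataset, cfg: NormalizationConfig = NormalizationConfig()
) -> ExpressionDataset:
    """Minimum-shift background correction on raw intensities.

    In 'shift_to_positive' mode, when min(matrix) <= 0 every value is
    shifted by (1 - min) so the new minimum is exactly 1; already-positive
    matrices pass through unchanged. Mode 'none' is the identity.
    """
    if ds.scale != SCALE_RAW:
        raise ScaleError(
            f"{ds.dataset_id}: background correction applies to raw intensities"
        )
    if cfg.background_mode == "none":
        return ds
    lo = np.nanmin(ds.matrix.to_numpy(dtype=float))
    if lo > 0:
        return ds
    shift = 1.0 - lo
    log.info("%s: background shift +%g (min was %g)", ds.dataset_id, shift, lo)
    return ds.with_matrix(ds.matrix + shift)


def log2_transform(ds: ExpressionDataset) -> ExpressionDataset:
    """Elementwise log2; requires strictly positive values."""
    if ds.scale != SCALE_RAW:
        raise ScaleError(f"{ds.dataset_id}: data already on log2 scale")
    vals = ds.matrix.to_numpy(dtype=float)
    nonpos = np.nansum(vals <= 0, axis=1) > 0
    if nonpos.any():
        offenders = ds.matrix.index[nonpos].tolist()
        raise DomainError(
            f"{ds.dataset_id}: nonpositive values in features {offenders[:5]} "
            f"({int(nonpos.sum())} total); background-correct first"
        )
    return ds.with_matrix(np.log2(ds.matrix), scale=SCALE_LOG2)


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Force every sample (column) onto the common reference distribution.

    The reference is the row-wise mean of the column-sorted matrix. Each
    value is replaced by the reference value at its within-column rank;
    ties receive the mean of the reference values across their rank span,
    which makes the operation deterministic and stable under sample
    permutation. Idempotent. A single-sample dataset is returned unchanged
    with a warning (there is nothing to equalize).
    """
    m = ds.matrix.to_numpy(dtype=float)
    if np.isnan(m).any():
        raise DomainError(f"{ds.dataset_id}: quantile normalization requires complete data")
    n_features, n_samples = m.shape
    if n_samples < 2:
        warnings.warn(f"{ds.dataset_id}: single sample; quantile normalization skipped")
        return ds
    order = np.argsort(m, axis=0, kind="stable")
    sorted_m = np.take_along_axis(m, order, axis=0)
    reference = sorted_m.mean(axis=1)

    out = np.empty_like(m)
    # cumulative reference sums let a tie span be averaged in O(1)
    ref_cum = np.concatenate([[0.0], np.cumsum(reference)])
    for j in range(n_samples):
        col = m[:, j]
        idx = order[:, j]
        col_sorted = col[idx]
        # boundaries of runs of equal values in the sorted column
        starts = np.flatnonzero(np.r_[True, col_sorted[1:] != col_sorted[:-1]])
        ends = np.r_[starts[1:], n_features]
        span_means = (ref_cum[ends] - ref_cum[starts]) / (ends - starts)
        run_id = np.repeat(np.arange(starts.size), ends - starts)
        out[idx, j] = span_means[run_id]
    return ds.with_matrix(pd.DataFrame(out, index=ds.matrix.index,
                                       columns=ds.matrix.columns))


def detection_filter(
    ds: ExpressionDataset, cfg: NormalizationConfig = NormalizationConfig()
) -> ExpressionDataset:
    """Keep probes detected (detection p strictly below ``detection_p_max``)
    in at least ``min_detected_samples`` samples; feature order preserved."""
    if ds.detection_p is None:
        raise MissingDataError(f"{ds.dataset_id}: no detection p-values to filter on")
    detected = (ds.detection_p < cfg.detection_p_max).sum(axis=1)
    keep = detected >= cfg.min_detected_samples
    dropped = int((~keep).sum())
    if dropped:
        log.info("%s: detection filter removed %d/%d probes",
                 ds.dataset_id, dropped, ds.n_features)
    return ds.with_matrix(ds.matrix.loc[keep])


def preprocess_rnaseq(
    ds: ExpressionDataset, cfg: NormalizationConfig = NormalizationConfig()
) -> ExpressionDataset:
    """log2(count + pseudocount) for count-scale RNA-seq matrices already
    normalized upstream (e.g. upper-quartile RSEM); no quantile step."""
    if ds.scale != SCALE_RAW:
        raise ScaleError(f"{ds.dataset_id}: data already transformed")
    vals = ds.matrix.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise DomainError(f"{ds.dataset_id}: negative values are not counts")
    return ds.with_matrix(np.log2(ds.matrix + cfg.rnaseq_pseudocount), scale=SCALE_LOG2)


def preprocess_array_cohort(
    ds: ExpressionDataset, cfg: NormalizationConfig = NormalizationConfig()
) -> ExpressionDataset:
    """Full array pipeline: background correct -> log2 -> quantile
    normalize -> detection filter (skipped when the cohort carries no
    detection p-values)."""
    out = background_correct(ds, cfg)
    out = log2_transform(out)
    out = quantile_normalize(out)
    if out.detection_p is not None:
        out = detection_filter(out, cfg)
    return out
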