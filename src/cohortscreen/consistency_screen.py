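"""Cross-cohort candidate screen.

A candidate gene survives the screen when, in more than a configurable
fraction (default strictly more than 50%) of the cohorts in which it is
measured, it (i) correlates with an anchor gene (Spearman rho >= rho_min
and p <= p_max, computed on primary-tumor samples) and (ii) is altered
between tumor and normal tissue (Mann-Whitney p <= p_max in the required
direction). Cohorts that do not measure a gene shrink that gene's
denominator instead of counting as failures.

Statistical primitives follow small-sample-exact conventions: Spearman p
is computed by full rank-permutation enumeration for n <= 8 and by the
t approximation otherwise; the Mann-Whitney test is exact for small
tie-free groups and normal-approximated with tie and continuity
corrections otherwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import collapse_isoforms_to_gene_signal
from .datatypes import ClinicalTable, ExpressionDataset, ProbeMap
from .errors import (
    ConfigurationError,
    DegenerateDataError,
    MissingGeneError,
    SampleSizeError,
)

log = logging.getLogger(__name__)

EXACT_SPEARMAN_MAX_N = 8
EXACT_MWU_MAX_N = 8


@dataclass
class ScreenCriteria:
    """Thresholds of the consistency screen.

    rho_min / p_max : per-cohort correlation criterion (boundary inclusive:
        rho >= rho_min, p <= p_max).
    consistency_fraction : a criterion is consistent when it holds in
        strictly more than this fraction of evaluable cohorts.
    require_positive_rho : when False, |rho| >= rho_min passes.
    alteration_direction : 'down', 'up', or 'any'; with 'any', only the
        majority direction across passing cohorts counts.
    tumor_only : restrict correlations to primary-tumor samples.
    """

    rho_min: float = 0.2
    p_max: float = 0.05
    consistency_fraction: float = 0.5
    require_positive_rho: bool = True
    alteration_direction: str = "down"
    tumor_only: bool = True
    min_normal: int = 3
    min_tumor: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.rho_min <= 1:
            raise ConfigurationError("rho_min must be in (0, 1]")
        if not 0 < self.p_max < 1:
            raise ConfigurationError("p_max must be in (0, 1)")
        if not 0 < self.consistency_fraction <= 1:
            raise ConfigurationError("consistency_fraction must be in (0, 1]")
        if self.alteration_direction not in ("down", "up", "any"):
            raise ConfigurationError("alteration_direction must be down/up/any")


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SampleSizeError("paired vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a small-sample exact p-value.

    rho is the Pearson correlation of mid-ranks. The two-sided p-value is
    exact — P(|rho*| >= |rho|) over all n! permutations of one rank
    vector — for n <= 8, and uses the t approximation
    t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df otherwise. Pairs with a
    missing value are removed first; n >= 3 is required and either vector
    being constant is an error.
    """
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 3:
        raise SampleSizeError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant vector: Spearman correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Enumerate all permutations of one mid-rank vector."""
    n = rx.size
    cx = rx - rx.mean()
    denom_x = math.sqrt(float(cx @ cx))
    ry_c = ry - ry.mean()
    denom_y = math.sqrt(float(ry_c @ ry_c))
    thresh = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    for perm in itertools.permutations(ry_c):
        r = float(cx @ np.asarray(perm)) / (denom_x * denom_y)
        if abs(r) >= thresh:
            count += 1
        total += 1
    return count / total


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney test of group ``a`` vs group ``b``.

    Returns (U statistic of group a, two-sided p, median(a) - median(b)).
    Exact enumeration when the smaller group has <= 8 values and there are
    no cross-group ties; otherwise the normal approximation with tie and
    continuity corrections. Fully tied data (zero tie-corrected variance)
    yields p = 1 with a log message.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 3 or b.size < 3:
        raise SampleSizeError(
            f"each group needs >= 3 values (got {a.size} and {b.size})"
        )
    median_shift = float(np.median(a) - np.median(b))
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        log.info("all values tied; Mann-Whitney p set to 1")
        u = a.size * b.size / 2.0
        return u, 1.0, median_shift
    if min(a.size, b.size) <= EXACT_MWU_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if math.isnan(p):  # degenerate variance under heavy ties
        p = 1.0
    return float(res.statistic), min(1.0, p), median_shift


def _cohort_gene_signal(
    ds: ExpressionDataset, probe_map: ProbeMap, gene: str
) -> Optional[pd.Series]:
    try:
        return collapse_isoforms_to_gene_signal(ds, probe_map, gene)
    except MissingGeneError:
        return None


def _tumor_samples(ds: ExpressionDataset) -> list[str]:
    if ds.samples is None:
        return ds.sample_ids
    tumors = set(ds.samples.samples_of_class("primary_tumor"))
    return [s for s in ds.sample_ids if s in tumors]


def correlate_with_anchor(
    cohorts: Sequence[ExpressionDataset],
    probe_map: ProbeMap,
    anchor: str,
    candidates: Iterable[str],
    crit: ScreenCriteria = ScreenCriteria(),
) -> pd.DataFrame:
    """Per (cohort, candidate) Spearman correlation with the anchor gene.

    Correlations use primary-tumor samples (all samples when
    ``crit.tumor_only`` is off or no clinical table is linked). Cohorts in
    which either gene is unmeasured, or with < 4 complete pairs, produce
    no record. Raises when the anchor is measured nowhere.
    """
    candidates = list(candidates)
    anchor_found = False
    rows = []
    for ds in cohorts:
        anchor_sig = _cohort_gene_signal(ds, probe_map, anchor)
        if anchor_sig is None:
            continue
        anchor_found = True
        samples = _tumor_samples(ds) if crit.tumor_only else ds.sample_ids
        if not samples:
            log.warning("%s: no eligible samples for correlation", ds.dataset_id)
            continue
        av = anchor_sig[samples]
        for gene in candidates:
            sig = _cohort_gene_signal(ds, probe_map, gene)
            if sig is None:
                continue
            gv = sig[samples]
            x, y = _pairwise_complete(av.to_numpy(), gv.to_numpy())
            if x.size < 4:
                log.info("%s/%s: only %d complete pairs; skipped",
                         ds.dataset_id, gene, x.size)
                continue
            try:
                rho, p = spearman(x, y)
            except DegenerateDataError:
                log.info("%s/%s: constant signal; skipped", ds.dataset_id, gene)
                continue
            rho_ok = rho >= crit.rho_min if crit.require_positive_rho \
                else abs(rho) >= crit.rho_min
            rows.append({
                "dataset_id": ds.dataset_id,
                "gene": gene,
                "rho": rho,
                "p_value": p,
                "n_samples": int(x.size),
                "passes": bool(rho_ok and p <= crit.p_max),
            })
    if not anchor_found:
        raise ConfigurationError(f"anchor gene {anchor!r} measured in no cohort")
    return pd.DataFrame(rows, columns=["dataset_id", "gene", "rho", "p_value",
                                       "n_samples", "passes"])


def tumor_vs_normal(
    cohorts: Sequence[ExpressionDataset],
    probe_map: ProbeMap,
    candidates: Iterable[str],
    crit: ScreenCriteria = ScreenCriteria(),
) -> pd.DataFrame:
    """Per (cohort, candidate) tumor-vs-normal Mann-Whitney alteration test.

    A cohort contributes only when it has at least ``crit.min_tumor``
    primary-tumor and ``crit.min_normal`` normal samples with the gene
    measured. ``median_shift`` is tumor median minus normal median (log2
    units); direction 'down'/'up' requires p <= p_max with the matching
    sign, else 'none'.
    """
    rows = []
    for ds in cohorts:
        if ds.samples is None:
            continue
        tumors = [s for s in ds.samples.samples_of_class("primary_tumor")
                  if s in ds.matrix.columns]
        normals = [s for s in ds.samples.samples_of_class("normal")
                   if s in ds.matrix.columns]
        if len(tumors) < crit.min_tumor or len(normals) < crit.min_normal:
            continue
        for gene in candidates:
            sig = _cohort_gene_signal(ds, probe_map, gene)
            if sig is None:
                continue
            a = sig[tumors].dropna().to_numpy()
            b = sig[normals].dropna().to_numpy()
            if a.size < crit.min_tumor or b.size < crit.min_normal:
                continue
            _, p, shift = mann_whitney_u(a, b)
            if p <= crit.p_max and shift < 0:
                direction = "down"
            elif p <= crit.p_max and shift > 0:
                direction = "up"
            else:
                direction = "none"
            if crit.alteration_direction == "any":
                passes = direction != "none"
            else:
                passes = direction == crit.alteration_direction
            rows.append({
                "dataset_id": ds.dataset_id,
                "gene": gene,
                "median_shift": shift,
                "p_value": p,
                "direction": direction,
                "passes": bool(passes),
            })
    return pd.DataFrame(rows, columns=["dataset_id", "gene", "median_shift",
                                       "p_value", "direction", "passes"])


def aggregate_screen(
    corr: pd.DataFrame,
    alt: pd.DataFrame,
    crit: ScreenCriteria = ScreenCriteria(),
) -> pd.DataFrame:
    """Strict-majority verdict per gene.

    selected <=> n_pass_corr > f * n_evaluable_corr AND
                 n_pass_alt  > f * n_evaluable_alt,
    with f = crit.consistency_fraction and denominators counting only the
    cohorts in which the gene was evaluable. With
    alteration_direction='any', only the majority direction among passing
    cohorts counts (ties broken toward 'down', the direction of interest
    for a loss-of-expression screen). Genes with no evaluable alteration
    cohort are excluded. Output sorted by correlation pass fraction
    (descending), then gene label.
    """
    if corr.empty or alt.empty:
        raise ConfigurationError("both correlation and alteration records required")
    rows = []
    genes = sorted(set(corr["gene"]) | set(alt["gene"]))
    f = crit.consistency_fraction
    for gene in genes:
        c = corr[corr["gene"] == gene]
        a = alt[alt["gene"] == gene]
        if c.empty or a.empty:
            log.info("gene %s not evaluable in both criteria; excluded", gene)
            continue
        n_corr, k_corr = len(c), int(c["passes"].sum())
        if crit.alteration_direction == "any":
            passing = a[a["passes"]]
            n_down = int((passing["direction"] == "down").sum())
            n_up = int((passing["direction"] == "up").sum())
            k_alt = n_down if n_down >= n_up else n_up
        else:
            k_alt = int(a["passes"].sum())
        n_alt = len(a)
        selected = (k_corr > f * n_corr) and (k_alt > f * n_alt)
        rows.append({
            "gene": gene,
            "n_evaluable_corr": n_corr,
            "n_pass_corr": k_corr,
            "n_evaluable_alt": n_alt,
            "n_pass_alt": k_alt,
            "corr_fraction": k_corr / n_corr,
            "selected": bool(selected),
        })
    out = pd.DataFrame(rows, columns=["gene", "n_evaluable_corr", "n_pass_corr",
                                      "n_evaluable_alt", "n_pass_alt",
                                      "corr_fraction", "selected"])
    if out.empty:
        return out
    return (out.sort_values(["corr_fraction", "gene"], ascending=[False, True])
               .reset_index(drop=True))
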