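"""Quartile-based disease-free-survival stratification.

Patients are ranked by a per-sample signal — a single gene's
isoform-collapsed expression or the mean of several genes' signals — and
the lowest quartile (Q1) is compared against the pooled upper three
quartiles. The comparison uses the Kaplan-Meier product-limit estimator
and the log-rank (Mantel-Cox) test; the hazard ratio is reported in the
observed/expected form HR = (O1/E1)/(O2/E2) with Q1 as group 1, so
HR > 1 means the low-expression group recurs faster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import collapse_isoforms_to_gene_signal
from .datatypes import ClinicalTable, ExpressionDataset, ProbeMap
from .errors import (
    ConfigurationError,
    DegenerateDataError,
    DomainError,
    SampleSizeError,
)

log = logging.getLogger(__name__)

Q1 = "Q1"
REST = "rest"


@dataclass
class StratificationConfig:
    """quartile_fraction: quantile cut for the low group (default 0.25,
    must stay below 0.5 so Q1 is a minority); signature_combine:
    'mean_signal' (raw mean of log2 signals) or 'zscore_mean'
    (per-gene standardization first)."""

    quartile_fraction: float = 0.25
    signature_combine: str = "mean_signal"

    def __post_init__(self) -> None:
        if not 0 < self.quartile_fraction < 0.5:
            raise DomainError("quartile_fraction must be in (0, 0.5)")
        if self.signature_combine not in ("mean_signal", "zscore_mean"):
            raise DomainError("signature_combine must be mean_signal or zscore_mean")


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_samples: int = 0

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S = 1 before the first
        event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi_sq: float
    p_value: float
    observed: tuple      # (O_a, O_b)
    expected: tuple      # (E_a, E_b)
    hazard_ratio: float  # (O_a/E_a)/(O_b/E_b), group a = Q1
    hr_diverged: bool = False


def composite_signal(
    ds: ExpressionDataset,
    probe_map: ProbeMap,
    genes: Sequence[str],
    cfg: StratificationConfig = StratificationConfig(),
) -> pd.Series:
    """Per-sample signature signal across ``genes``.

    'mean_signal' is the unweighted mean of the per-gene (isoform-
    collapsed) log2 signals; 'zscore_mean' standardizes each gene across
    samples first. A single gene returns its own signal. Any listed gene
    that is unmeasured raises MissingGeneError naming it.
    """
    if not genes:
        raise ConfigurationError("empty gene list")
    signals = pd.DataFrame(
        {g: collapse_isoforms_to_gene_signal(ds, probe_map, g) for g in genes}
    )
    if cfg.signature_combine == "zscore_mean":
        sd = signals.std(ddof=1)
        if (sd == 0).any():
            raise DegenerateDataError(
                f"constant signal for genes {signals.columns[sd == 0].tolist()}"
            )
        signals = (signals - signals.mean()) / sd
    out = signals.mean(axis=1)
    out.name = "+".join(genes)
    return out


def quartile_groups(
    signal: pd.Series, cfg: StratificationConfig = StratificationConfig()
) -> pd.Series:
    """Label each sample Q1 (signal <= the linear-interpolation
    ``quartile_fraction`` quantile) or rest; boundary ties all go to Q1
    so the low group is never empty."""
    signal = signal.dropna()
    if signal.size < 8:
        raise SampleSizeError(f"need >= 8 samples to form quartiles, got {signal.size}")
    if signal.nunique() == 1:
        raise DegenerateDataError("constant signal: quartiles undefined")
    cut = float(np.quantile(signal.to_numpy(), cfg.quartile_fraction))
    groups = pd.Series(np.where(signal <= cut, Q1, REST), index=signal.index)
    log.info("quartile split: |Q1|=%d, |rest|=%d (cut=%.4g)",
             int((groups == Q1).sum()), int((groups == REST).sum()), cut)
    return groups


def km_curve(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i), where n_i
    counts everyone still at risk at t_i (censoring tied with an event at
    the same time is handled events-first: the censored subject is still
    at risk at that time). With no events the curve is S = 1 with a
    warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size != events.size or times.size == 0:
        raise DomainError("times and events must be nonempty, equal-length")
    if (times < 0).any():
        raise DomainError("negative survival time")
    if events.sum() == 0:
        warnings.warn("no events: survival curve is identically 1")
        return KMCurve(np.array([]), np.array([]), np.array([]), np.array([]),
                       n_samples=int(times.size))
    event_times = np.unique(times[events == 1])
    at_risk = np.empty(event_times.size)
    n_events = np.empty(event_times.size)
    for i, t in enumerate(event_times):
        at_risk[i] = int((times >= t).sum())
        n_events[i] = int(((times == t) & (events == 1)).sum())
    survival = np.cumprod(1.0 - n_events / at_risk)
    return KMCurve(event_times, survival, at_risk.astype(int),
                   n_events.astype(int), n_samples=int(times.size))


def logrank_hr(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> LogRankResult:
    """Log-rank (Mantel-Cox) test of group a vs group b with the O/E
    hazard ratio.

    At each distinct event time the expected number of events in group a
    is d * n_a / n; the variance term is the hypergeometric
    d (n_a/n)(1 - n_a/n)(n - d)/(n - 1). chi^2 = (O_a - E_a)^2 / V on
    1 df. HR = (O_a/E_a)/(O_b/E_b); when one group has expected but no
    observed events the ratio diverges and is reported as +inf (or 0)
    with ``hr_diverged`` set.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise DegenerateDataError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise DegenerateDataError("no events in either group")
    all_event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    O_a = float(ea.sum())
    O_b = float(eb.sum())
    E_a = 0.0
    V = 0.0
    for t in all_event_times:
        n_a = float((ta >= t).sum())
        n_b = float((tb >= t).sum())
        n = n_a + n_b
        d = float(((ta == t) & (ea == 1)).sum() + ((tb == t) & (eb == 1)).sum())
        E_a += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1.0 - n_a / n) * (n - d) / (n - 1.0)
    E_b = (O_a + O_b) - E_a
    chi_sq = 0.0 if V == 0 else (O_a - E_a) ** 2 / V
    p = float(stats.chi2.sf(chi_sq, df=1))
    diverged = False
    if E_a == 0 or E_b == 0:
        raise DegenerateDataError("a group accrues no expected events")
    rate_a = O_a / E_a
    rate_b = O_b / E_b
    if rate_b == 0:
        hr = float("inf") if rate_a > 0 else float("nan")
        diverged = True
    else:
        hr = rate_a / rate_b
        if rate_a == 0:
            diverged = True
    return LogRankResult(chi_sq=float(chi_sq), p_value=p,
                         observed=(O_a, O_b), expected=(E_a, E_b),
                         hazard_ratio=hr, hr_diverged=diverged)


@dataclass
class StratificationResult:
    genes: list
    group_sizes: dict
    curve_q1: KMCurve
    curve_rest: KMCurve
    logrank: Optional[LogRankResult]
    groups: pd.Series = field(repr=False)

    def curves_table(self) -> pd.DataFrame:
        """Plot-ready long table of both KM curves."""
        frames = []
        for label, curve in ((Q1, self.curve_q1), (REST, self.curve_rest)):
            frames.append(pd.DataFrame({
                "group": label,
                "time": curve.event_times,
                "survival": curve.survival,
                "at_risk": curve.at_risk,
                "n_events": curve.n_events,
            }))
        return pd.concat(frames, ignore_index=True)


def stratify_dfs(
    ds: ExpressionDataset,
    clin: ClinicalTable,
    probe_map: ProbeMap,
    genes: Sequence[str],
    cfg: StratificationConfig = StratificationConfig(),
) -> StratificationResult:
    """Q1-vs-rest disease-free-survival analysis of a gene signature.

    Composes composite_signal -> quartile_groups -> per-group KM curves
    -> log-rank. Only primary-tumor samples with DFS annotation enter;
    fewer than 8 eligible samples is an error. A cohort without any
    recurrence event returns curves with a warning and no test.
    """
    surv = clin.survival_frame()
    tumors = set(clin.samples_of_class("primary_tumor"))
    eligible = [s for s in ds.sample_ids if s in tumors and s in surv.index]
    if len(eligible) < 8:
        raise SampleSizeError(
            f"{ds.dataset_id}: only {len(eligible)} eligible samples"
        )
    signal = composite_signal(ds, probe_map, genes, cfg)[eligible]
    groups = quartile_groups(signal, cfg)
    surv = surv.loc[groups.index]
    in_q1 = groups == Q1
    t_q1 = surv.loc[in_q1, "dfs_time"].to_numpy()
    e_q1 = surv.loc[in_q1, "dfs_event"].to_numpy()
    t_rest = surv.loc[~in_q1, "dfs_time"].to_numpy()
    e_rest = surv.loc[~in_q1, "dfs_event"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve_q1 = km_curve(t_q1, e_q1)
        curve_rest = km_curve(t_rest, e_rest)
    if e_q1.sum() + e_rest.sum() == 0:
        warnings.warn(f"{ds.dataset_id}: no recurrence events; log-rank skipped")
        lr = None
    else:
        lr = logrank_hr(t_q1, e_q1, t_rest, e_rest)
    return StratificationResult(
        genes=list(genes),
        group_sizes={Q1: int(in_q1.sum()), REST: int((~in_q1).sum())},
        curve_q1=curve_q1,
        curve_rest=curve_rest,
        logrank=lr,
        groups=groups,
    )
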