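"""Two-group differential expression with empirical-Bayes variance
moderation.

For each probe a two-group linear model gives the log2 fold change, the
pooled within-group variance s^2 and its residual degrees of freedom d.
The per-probe variances are then shrunk toward a prior: assuming
s^2 | sigma^2 ~ sigma^2 * chi^2_d / d and an inverse-chi-square prior
sigma^2 ~ s0^2 * d0 / chi^2_{d0}, the posterior variance is

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and the moderated t statistic t = log2FC / sqrt(s~^2 * (1/n1 + 1/n2)) is
referred to a t distribution on d0 + d degrees of freedom. The prior
(d0, s0^2) is estimated from the marginal distribution of log s^2 by a
moment match on the digamma/trigamma identities of the log scaled-F
distribution. d0 = 0 recovers the ordinary pooled t exactly; d0 = +inf
fixes every variance at s0^2 (normal-limit reference distribution).

P-values are adjusted by the Benjamini-Hochberg step-up, and candidates
are selected by adjusted p and a signed linear fold-change cutoff
(fold changes below 1 are reported as -1/ratio).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import SCALE_LOG2, ExpressionDataset, ProbeMap
from .errors import DegenerateDataError, DesignError, DomainError, ScaleError

log = logging.getLogger(__name__)

TREATED = "treated"
CONTROL = "control"


@dataclass
class ModeratedTParams:
    """Variance prior: d0 prior degrees of freedom (0 <= d0 <= inf) and
    s0_sq prior variance (> 0 whenever d0 > 0)."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise DomainError("d0 must be >= 0")
        if self.d0 > 0 and not self.s0_sq > 0:
            raise DomainError("s0_sq must be positive when d0 > 0")


@dataclass
class DESelectionCriteria:
    """adj_p_max: BH-adjusted p cutoff (strict); fc_min: linear
    fold-change magnitude cutoff (inclusive), must exceed 1."""

    adj_p_max: float = 0.05
    fc_min: float = 1.5

    def __post_init__(self) -> None:
        if not self.fc_min > 1:
            raise DomainError("fc_min must be > 1")
        if not 0 < self.adj_p_max <= 1:
            raise DomainError("adj_p_max must be in (0, 1]")


class DESelection(NamedTuple):
    significant: list[str]       # probes with adj_p < adj_p_max
    fc_filtered: list[str]       # significant AND |linear_fc| >= fc_min
    candidate_genes: list[str]   # unique annotated genes of fc_filtered
    n_up: int                    # significant probes with positive fold change
    n_down: int


def _group_indices(
    ds: ExpressionDataset, group_labels: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    treated = [s for s in ds.sample_ids if group_labels.get(s) == TREATED]
    control = [s for s in ds.sample_ids if group_labels.get(s) == CONTROL]
    unknown = {v for v in group_labels.values()} - {TREATED, CONTROL}
    if unknown:
        raise DesignError(f"unknown group labels: {sorted(unknown)}")
    if len(treated) < 2 or len(control) < 2:
        raise DesignError(
            f"need >= 2 samples per group (treated={len(treated)}, "
            f"control={len(control)})"
        )
    return treated, control


def fit_two_group(
    ds: ExpressionDataset, group_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per-probe two-group fit on log2 data.

    Returns a DataFrame indexed by probe with columns ``log2_fc``
    (treated mean - control mean), ``s_sq`` (pooled within-group
    variance), ``residual_df``, ``n_treated``, ``n_control``.
    """
    if ds.scale != SCALE_LOG2:
        raise ScaleError("differential expression requires log2-scale data")
    treated, control = _group_indices(ds, group_labels)
    mt = ds.matrix[treated].to_numpy(dtype=float)
    mc = ds.matrix[control].to_numpy(dtype=float)
    n_t, n_c = mt.shape[1], mc.shape[1]
    lfc = mt.mean(axis=1) - mc.mean(axis=1)
    ss_t = ((mt - mt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss_c = ((mc - mc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n_t + n_c - 2
    s_sq = (ss_t + ss_c) / df
    return pd.DataFrame(
        {"log2_fc": lfc, "s_sq": s_sq, "residual_df": df,
         "n_treated": n_t, "n_control": n_c},
        index=ds.matrix.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the strictly decreasing
    trigamma; the standard series start 1/y + 0.5 converges in a few
    steps for any y > 0)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_variance_prior(
    s_sq: Sequence[float], residual_df: int
) -> ModeratedTParams:
    """Moment-match the variance prior on z = log(s^2).

    Under the hierarchical model, e = z - digamma(d/2) + log(d/2) has
    mean log(s0^2) - digamma(d0/2) + log(d0/2) and excess variance
    trigamma(d0/2) beyond the sampling term trigamma(d/2); inverting the
    trigamma gives d0, and the mean relation then gives s0^2. When the
    observed variance of e does not exceed the sampling term, there is no
    evidence of variance heterogeneity and d0 = +inf with s0^2 =
    exp(mean(e)). Zero variances are excluded from the moment fit with a
    warning; all-zero variances are an error.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    if s_sq.size == 0 or (s_sq <= 0).all():
        raise DegenerateDataError("all residual variances are zero")
    if (s_sq <= 0).any():
        warnings.warn(f"{int((s_sq <= 0).sum())} zero variances excluded "
                      "from prior estimation")
        s_sq = s_sq[s_sq > 0]
    if s_sq.size < 50:
        warnings.warn(f"only {s_sq.size} probes: variance-prior estimate "
                      "will be unstable")
    d = float(residual_df)
    z = np.log(s_sq)
    e = z - float(special.digamma(d / 2.0)) + math.log(d / 2.0)
    e_mean = float(e.mean())
    if s_sq.size > 1:
        e_var = float(e.var(ddof=1))
    else:
        e_var = 0.0
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return ModeratedTParams(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - math.log(half_d0)))
    return ModeratedTParams(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    fit: pd.DataFrame, params: ModeratedTParams
) -> pd.DataFrame:
    """Moderated t and two-sided p per probe from a ``fit_two_group``
    frame. d0 = 0 reduces exactly to the ordinary pooled two-sample t;
    d0 = +inf uses s0^2 with the normal reference distribution."""
    d = fit["residual_df"].to_numpy(dtype=float)
    s_sq = fit["s_sq"].to_numpy(dtype=float)
    lfc = fit["log2_fc"].to_numpy(dtype=float)
    inv_n = 1.0 / fit["n_treated"].to_numpy() + 1.0 / fit["n_control"].to_numpy()
    if math.isinf(params.d0):
        s_tilde = np.full_like(s_sq, params.s0_sq)
        df_total = np.full_like(s_sq, np.inf)
    else:
        s_tilde = (params.d0 * params.s0_sq + d * s_sq) / (params.d0 + d)
        df_total = params.d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s_tilde * inv_n)
    t = np.where(np.isnan(t) & (lfc == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return pd.DataFrame({"t_mod": t, "p_value": p, "df_total": df_total},
                        index=fit.index)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_p[i] = min over j with p[j] >= p[i] of m * p[j] / rank(j),
    clipped to 1; the input order is preserved in the output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m, dtype=float)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def _linear_fc(log2_fc: np.ndarray) -> np.ndarray:
    """Signed fold change: 2^lfc when lfc >= 0, else -2^(-lfc); magnitude
    always >= 1 and the sign matches the log fold change (0 -> +1)."""
    ratio = np.power(2.0, np.abs(log2_fc))
    return np.where(log2_fc < 0, -ratio, ratio)


def run_de(
    ds: ExpressionDataset,
    group_labels: Mapping[str, str],
    probe_map: Optional[ProbeMap] = None,
    params: Optional[ModeratedTParams] = None,
) -> pd.DataFrame:
    """Full per-probe DE table: fit, estimate the variance prior (unless
    given), moderate, BH-adjust, annotate. Columns: probe_id (index),
    gene_symbol, log2_fc, linear_fc, s_sq, t_mod, p_value, adj_p."""
    fit = fit_two_group(ds, group_labels)
    if params is None:
        params = estimate_variance_prior(
            fit["s_sq"].to_numpy(), int(fit["residual_df"].iloc[0])
        )
    mod = moderated_t_test(fit, params)
    lfc = fit["log2_fc"].to_numpy()
    out = pd.DataFrame(
        {
            "gene_symbol": [probe_map.gene_of(p) if probe_map else None
                            for p in fit.index],
            "log2_fc": lfc,
            "linear_fc": _linear_fc(lfc),
            "s_sq": fit["s_sq"].to_numpy(),
            "t_mod": mod["t_mod"].to_numpy(),
            "p_value": mod["p_value"].to_numpy(),
            "adj_p": bh_adjust(mod["p_value"].to_numpy()),
        },
        index=fit.index,
    )
    out.index.name = "probe_id"
    out.attrs["d0"] = params.d0
    out.attrs["s0_sq"] = params.s0_sq
    return out


def select_de_candidates(
    results: pd.DataFrame,
    crit: DESelectionCriteria = DESelectionCriteria(),
    probe_map: Optional[ProbeMap] = None,
) -> DESelection:
    """Two-stage selection: significance by adjusted p, then the linear
    fold-change cut; candidate genes are the unique annotated symbols of
    the fold-change-filtered probes (unannotated probes stay in the probe
    lists but not the gene list)."""
    if results.empty:
        raise DegenerateDataError("empty DE result table")
    sig_mask = results["adj_p"] < crit.adj_p_max
    fc_mask = sig_mask & (results["linear_fc"].abs() >= crit.fc_min)
    significant = results.index[sig_mask].tolist()
    fc_filtered = results.index[fc_mask].tolist()
    n_up = int((sig_mask & (results["log2_fc"] > 0)).sum())
    n_down = int((sig_mask & (results["log2_fc"] < 0)).sum())

    def annotate(probe: str) -> Optional[str]:
        if "gene_symbol" in results.columns and results.loc[probe, "gene_symbol"]:
            return results.loc[probe, "gene_symbol"]
        if probe_map is not None:
            return probe_map.gene_of(probe)
        return None

    genes: list[str] = []
    for probe in fc_filtered:
        g = annotate(probe)
        if g and g not in genes:
            genes.append(g)
    return DESelection(significant, fc_filtered, genes, n_up, n_down)
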