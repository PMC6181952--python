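"""Seeded generator of multi-cohort expression + survival worlds.

The generator emulates the statistical structure the screen assumes:

* several cohorts of normal and primary-tumor samples, each measuring a
  shared gene panel through 1-4 isoform-level probes per gene;
* an anchor gene and planted candidate genes whose *population* Spearman
  correlation with the anchor hits a target value — latent bivariate
  Gaussians are calibrated through the exact Gaussian identity
  rho_S = (6/pi) * arcsin(rho_P / 2), inverted as
  rho_P = 2 * sin(pi * rho_S / 6);
* tumor-vs-normal log2 shifts for planted genes, array detection
  p-values with a configurable fraction of never-detected noise probes,
  and raw intensities equal to 2^(log2 signal) so the standard
  preprocessing chain (background correct, log2, quantile normalize,
  detection filter) applies;
* disease-free-survival times from an exponential proportional-hazards
  model on standardized gene signals, with independent uniform censoring
  calibrated to a target censoring rate.

Every quantity is drawn from a per-(cohort, gene) random stream derived
from the master seed, so adding a gene never perturbs other genes' draws
and identical seeds give identical worlds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import SCALE_LOG2, SCALE_RAW, ClinicalTable, ExpressionDataset, ProbeMap
from .errors import ConfigurationError

DETECTED_P_MAX = 0.0099   # detected probes draw detection p below this
UNDETECTED_P_MIN = 0.0101  # noise probes draw detection p above this


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson latent correlation giving a target population Spearman
    correlation for bivariate Gaussians: rho_P = 2 sin(pi rho_S / 6)."""
    if not -1 < rho_s < 1:
        raise ConfigurationError("target Spearman rho must be in (-1, 1)")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass
class PlantedCandidate:
    """A gene planted to satisfy (or probe) the screen criteria.

    target_rho : population Spearman correlation with the anchor.
    present_in : cohort indices measuring the gene (None = all cohorts).
    tumor_shift : log2 shift added to tumor samples (negative = loss).
    """

    gene: str
    target_rho: float
    present_in: Optional[Sequence[int]] = None
    tumor_shift: float = 0.0


@dataclass
class SurvivalParams:
    """Exponential proportional-hazards generator.

    baseline_hazard : events per month for a patient at the gene-signal
        mean (default 0.02 ~ median DFS of about 3 years).
    coefficients : gene -> log-hazard per SD of that gene's signal
        (negative = protective: high expression, fewer recurrences).
    censoring_rate : target fraction censored by the independent uniform
        censoring mechanism (calibrated in expectation).
    max_follow_up : administrative truncation, months (truncation counts
        as censoring).
    """

    baseline_hazard: float = 0.02
    coefficients: dict = field(default_factory=dict)
    censoring_rate: float = 0.5
    max_follow_up: float = 180.0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigurationError("censoring_rate must be in [0, 1)")
        if self.max_follow_up <= 0:
            raise ConfigurationError("max_follow_up must be positive")


@dataclass
class SyntheticConfig:
    """Parameterization of the simulated multi-cohort world.

    Defaults emulate a seven-cohort screen: 12 normal + 50 tumor samples
    per cohort, 200 genes with 1-4 isoform probes each, unit log2 noise,
    and 5% of probes never detected on the array.
    """

    n_cohorts: int = 7
    samples_per_cohort: tuple = (12, 50)  # (n_normal, n_tumor) or list of pairs
    n_genes: int = 200
    isoforms_per_gene: tuple = (1, 4)
    anchor_gene: str = "ANCHOR"
    planted_candidates: list = field(default_factory=list)
    noise_sd: float = 1.0
    isoform_noise_sd: float = 0.25
    detection_noise: float = 0.05
    baseline_range: tuple = (6.0, 10.0)
    survival: Optional[SurvivalParams] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts < 1 or self.n_genes < 1:
            raise ConfigurationError("need at least one cohort and one gene")
        pairs = self.cohort_sizes()
        for n_normal, n_tumor in pairs:
            if n_normal < 3 or n_tumor < 3:
                raise ConfigurationError("all sample counts must be >= 3")
        if not 0 <= self.detection_noise < 1:
            raise ConfigurationError("detection_noise must be in [0, 1)")
        lo, hi = self.isoforms_per_gene
        if not 1 <= lo <= hi:
            raise ConfigurationError("isoforms_per_gene bounds must satisfy 1 <= lo <= hi")
        for cand in self.planted_candidates:
            spearman_to_pearson(cand.target_rho)  # validates range
            if cand.present_in is not None:
                if any(not 0 <= c < self.n_cohorts for c in cand.present_in):
                    raise ConfigurationError(
                        f"{cand.gene}: presence mask outside cohort range"
                    )

    def cohort_sizes(self) -> list[tuple[int, int]]:
        if isinstance(self.samples_per_cohort[0], (tuple, list)):
            sizes = [tuple(p) for p in self.samples_per_cohort]
            if len(sizes) != self.n_cohorts:
                raise ConfigurationError("one (n_normal, n_tumor) pair per cohort")
            return sizes
        return [tuple(self.samples_per_cohort)] * self.n_cohorts

    def gene_names(self) -> list[str]:
        """Anchor, planted candidates, then null filler genes."""
        names = [self.anchor_gene] + [c.gene for c in self.planted_candidates]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate gene names in configuration")
        i = 0
        while len(names) < self.n_genes:
            candidate = f"NULL{i:04d}"
            if candidate not in names:
                names.append(candidate)
            i += 1
        return names[: max(self.n_genes, len(names))]


@dataclass
class GroundTruth:
    """Planted truths, derived analytically from the configuration —
    never from generated data."""

    gene_truth: pd.DataFrame     # gene, target_rho, tumor_shift, n_present
    expected_selected: list      # genes satisfying the screen by construction
    probe_map: ProbeMap = None


def _expected_selected(cfg: SyntheticConfig, rho_min: float = 0.2,
                       consistency_fraction: float = 0.5,
                       alteration_direction: str = "down") -> list[str]:
    """Which planted genes satisfy the screen criteria *by construction*:
    target rho at/above threshold and an alteration in the required
    direction, in strictly more than the consistency fraction of the
    cohorts measuring the gene. Statistical power is not modeled; this is
    the population-level answer."""
    out = []
    for cand in cfg.planted_candidates:
        n_present = (cfg.n_cohorts if cand.present_in is None
                     else len(set(cand.present_in)))
        if n_present == 0:
            continue
        corr_ok = cand.target_rho >= rho_min
        if alteration_direction == "down":
            alt_ok = cand.tumor_shift < 0
        elif alteration_direction == "up":
            alt_ok = cand.tumor_shift > 0
        else:
            alt_ok = cand.tumor_shift != 0
        # criteria hold in every cohort measuring the gene, so the
        # consistency rule reduces to n_present > f * n_present, i.e.
        # simply corr_ok and alt_ok (denominators shrink with presence)
        if corr_ok and alt_ok:
            out.append(cand.gene)
    return out


def _gene_rng(seed: int, cohort: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, cohort, gene_index + 1]))


def _cohort_rng(seed: int, cohort: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, cohort, 0]))


def simulate_cohorts(
    cfg: SyntheticConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate the multi-cohort world.

    Returns raw-intensity datasets (detection p-values populated, clinical
    tables linked) plus the shared probe map and planted truths. Probe ids
    are ``<GENE>_iso<j>``; raw intensity is 2^(log2 signal) so the full
    preprocessing chain applies. When ``cfg.survival`` is set, tumor
    samples carry DFS annotation from the proportional-hazards model.
    """
    genes = cfg.gene_names()
    by_gene = {c.gene: c for c in cfg.planted_candidates}
    sizes = cfg.cohort_sizes()

    # isoform counts and probe-level noise flags are cohort-independent
    # platform properties: drawn from the gene stream of cohort index -1
    # equivalent (use cohort slot n_cohorts to keep streams disjoint)
    probe_rows = []
    iso_counts = {}
    probe_noise = {}
    lo, hi = cfg.isoforms_per_gene
    # the anchor and planted candidates are measurable by construction
    # (their cohort presence is the config's ground truth); detection
    # noise only ever silences filler probes
    exempt = {cfg.anchor_gene} | set(by_gene)
    for gi, gene in enumerate(genes):
        rng = _gene_rng(cfg.seed, cfg.n_cohorts, gi)
        k = int(rng.integers(lo, hi + 1))
        iso_counts[gene] = k
        for j in range(k):
            probe = f"{gene}_iso{j + 1}"
            probe_rows.append({"probe_id": probe, "gene_symbol": gene,
                               "isoform_label": f"iso{j + 1}"})
            noisy = rng.random() < cfg.detection_noise
            probe_noise[probe] = bool(noisy and gene not in exempt)
    probe_map = ProbeMap(pd.DataFrame(probe_rows))

    cohorts = []
    for ci in range(cfg.n_cohorts):
        n_normal, n_tumor = sizes[ci]
        n = n_normal + n_tumor
        cohort_id = f"cohort{ci + 1}"
        sample_ids = ([f"{cohort_id}_N{i + 1}" for i in range(n_normal)]
                      + [f"{cohort_id}_T{i + 1}" for i in range(n_tumor)])
        tumor_mask = np.array([False] * n_normal + [True] * n_tumor)

        anchor_latent = _cohort_rng(cfg.seed, ci).standard_normal(n)

        def attenuation(gene: str) -> float:
            """Correlation damping from isoform measurement noise: the
            collapsed signal is gene + noise with variance tau^2 / k."""
            tau_sq = cfg.isoform_noise_sd ** 2 / iso_counts[gene]
            return cfg.noise_sd / math.sqrt(cfg.noise_sd ** 2 + tau_sq)

        gene_log2 = {}
        for gi, gene in enumerate(genes):
            cand = by_gene.get(gene)
            if cand is not None and cand.present_in is not None \
                    and ci not in cand.present_in:
                continue
            rng = _gene_rng(cfg.seed, ci, gi)
            baseline = rng.uniform(*cfg.baseline_range)
            if gene == cfg.anchor_gene:
                latent = anchor_latent
            elif cand is not None and cand.target_rho != 0:
                # calibrate the latent correlation so the *measured*
                # (isoform-averaged) signal attains the target Spearman
                # rho: measured Pearson = rho_latent * a_anchor * a_cand
                rho_p = spearman_to_pearson(cand.target_rho)
                rho_p /= attenuation(cfg.anchor_gene) * attenuation(gene)
                if abs(rho_p) >= 1:
                    raise ConfigurationError(
                        f"{gene}: target rho {cand.target_rho} infeasible "
                        f"under isoform noise {cfg.isoform_noise_sd}"
                    )
                latent = (rho_p * anchor_latent
                          + math.sqrt(1.0 - rho_p ** 2) * rng.standard_normal(n))
            else:
                latent = rng.standard_normal(n)
            values = baseline + cfg.noise_sd * latent
            if cand is not None and cand.tumor_shift != 0:
                values = values + cand.tumor_shift * tumor_mask
            gene_log2[gene] = values

        rows, index = [], []
        det_rows = []
        for gi, gene in enumerate(genes):
            if gene not in gene_log2:
                continue
            rng = _gene_rng(cfg.seed, ci, gi)
            # independent probe-level stream: jump ahead of the draws above
            probe_stream = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, ci, gi + 1, 7])
            )
            for j in range(iso_counts[gene]):
                probe = f"{gene}_iso{j + 1}"
                vals = gene_log2[gene] + probe_stream.normal(
                    0.0, cfg.isoform_noise_sd, size=n
                )
                if probe_noise[probe]:
                    det = probe_stream.uniform(UNDETECTED_P_MIN, 1.0, size=n)
                else:
                    det = probe_stream.uniform(0.0, DETECTED_P_MAX, size=n)
                rows.append(np.power(2.0, vals))
                det_rows.append(det)
                index.append(probe)
        matrix = pd.DataFrame(np.vstack(rows), index=index, columns=sample_ids)
        detection = pd.DataFrame(np.vstack(det_rows), index=index,
                                 columns=sample_ids)

        clin = pd.DataFrame({
            "sample_id": sample_ids,
            "tissue_class": ["normal"] * n_normal + ["primary_tumor"] * n_tumor,
        })
        clinical = ClinicalTable(clin)
        if cfg.survival is not None:
            gene_frame = pd.DataFrame(gene_log2, index=sample_ids).T
            tumor_ids = [s for s, t in zip(sample_ids, tumor_mask) if t]
            dfs = _survival_times(
                gene_frame[tumor_ids], cfg.survival,
                np.random.default_rng(np.random.SeedSequence([cfg.seed, ci, 0, 11])),
            )
            clin = clin.merge(dfs, on="sample_id", how="left")
            clinical = ClinicalTable(clin)

        cohorts.append(ExpressionDataset(
            dataset_id=cohort_id, matrix=matrix, scale=SCALE_RAW,
            detection_p=detection, samples=clinical,
        ))

    truth_rows = []
    for cand in cfg.planted_candidates:
        n_present = (cfg.n_cohorts if cand.present_in is None
                     else len(set(cand.present_in)))
        truth_rows.append({"gene": cand.gene, "target_rho": cand.target_rho,
                           "tumor_shift": cand.tumor_shift,
                           "n_present": n_present})
    truth = GroundTruth(
        gene_truth=pd.DataFrame(truth_rows,
                                columns=["gene", "target_rho", "tumor_shift",
                                         "n_present"]),
        expected_selected=_expected_selected(cfg),
        probe_map=probe_map,
    )
    return cohorts, truth


def _calibrate_censoring_bound(hazards: np.ndarray, target: float) -> float:
    """Upper bound c of the uniform censoring time such that the expected
    censored fraction mean_i (1 - e^{-h_i c}) / (h_i c) equals the target.
    Monotone decreasing in c, solved by bisection on log c."""

    def censored_fraction(c: float) -> float:
        x = hazards * c
        return float(np.mean(-np.expm1(-x) / x))

    lo, hi = 1e-9, 1e9
    f = lambda c: censored_fraction(c) - target
    # censored_fraction -> 1 as c -> 0 and -> 0 as c -> inf
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-10))


def _survival_times(
    gene_signals: pd.DataFrame, params: SurvivalParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Exponential PH times for the samples (columns of gene_signals).

    hazard_i = baseline * exp(sum_g beta_g * z_{g,i}) with z the per-gene
    standardized signal; censoring C ~ U(0, c) with c calibrated to the
    target rate, plus truncation at max_follow_up (also censoring)."""
    samples = gene_signals.columns
    lp = np.zeros(len(samples))
    for gene, beta in params.coefficients.items():
        if gene not in gene_signals.index:
            raise ConfigurationError(f"survival coefficient for unmeasured gene {gene!r}")
        sig = gene_signals.loc[gene].to_numpy(dtype=float)
        sd = sig.std(ddof=1)
        z = (sig - sig.mean()) / sd if sd > 0 else np.zeros_like(sig)
        lp += beta * z
    hazards = params.baseline_hazard * np.exp(lp)
    event_t = rng.exponential(1.0 / hazards)
    if params.censoring_rate > 0:
        c = _calibrate_censoring_bound(hazards, params.censoring_rate)
        censor_t = rng.uniform(0.0, c, size=len(samples))
    else:
        censor_t = np.full(len(samples), np.inf)
    censor_t = np.minimum(censor_t, params.max_follow_up)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return pd.DataFrame({"sample_id": samples, "dfs_time": time,
                         "dfs_event": event})


def simulate_survival_cohort(
    expr: ExpressionDataset,
    probe_map: ProbeMap,
    params: SurvivalParams,
    seed: int,
) -> ClinicalTable:
    """DFS annotation for an existing (log2-scale) expression dataset.

    All samples are treated as primary tumors; the linear predictor uses
    the isoform-collapsed, standardized signal of each coefficient-bearing
    gene. With all coefficients zero the baseline hazard applies to
    everyone (valid: a pure-noise cohort)."""
    from .cohort_io import gene_signal_matrix

    genes = list(params.coefficients)
    signals = gene_signal_matrix(expr, probe_map, genes) if genes else \
        pd.DataFrame(columns=expr.sample_ids)
    missing = set(genes) - set(signals.index)
    if missing:
        raise ConfigurationError(f"genes unmeasured in cohort: {sorted(missing)}")
    dfs = _survival_times(signals if genes else
                          pd.DataFrame(np.zeros((0, expr.n_samples)),
                                       columns=expr.sample_ids),
                          params, np.random.default_rng(seed))
    dfs["tissue_class"] = "primary_tumor"
    return ClinicalTable(dfs[["sample_id", "tissue_class", "dfs_time", "dfs_event"]])


def simulate_perturbation_arrays(
    n_probes: int = 2000,
    n_de: int = 50,
    lfc: float = 2.0,
    groups: tuple = (3, 3),
    d0: float = 4.0,
    s0_sq: float = 0.05,
    detection_noise: float = 0.0,
    seed: int = 0,
    baseline_range: tuple = (6.0, 10.0),
) -> tuple[ExpressionDataset, dict, pd.DataFrame]:
    """Two-group perturbation experiment with a scaled-inverse-chi-square
    variance prior.

    Per-probe true variances are drawn as sigma^2 = d0 * s0_sq / chi2_d0
    (all equal to s0_sq when d0 is infinite); the first ``n_de`` probes
    receive a mean shift ``lfc`` in the treated group. Returns the log2
    dataset (detection p-values included), the sample -> group mapping,
    and the per-probe truth table.
    """
    if n_de > n_probes:
        raise ConfigurationError("n_de cannot exceed n_probes")
    n_t, n_c = groups
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2 ** 20]))
    if math.isinf(d0):
        sigma_sq = np.full(n_probes, s0_sq)
    else:
        sigma_sq = d0 * s0_sq / rng.chisquare(d0, size=n_probes)
    mu = rng.uniform(*baseline_range, size=n_probes)
    n = n_t + n_c
    data = mu[:, None] + np.sqrt(sigma_sq)[:, None] * rng.standard_normal((n_probes, n))
    is_de = np.zeros(n_probes, dtype=bool)
    is_de[:n_de] = True
    data[is_de, :n_t] += lfc

    probe_ids = [f"P{i + 1:05d}" for i in range(n_probes)]
    sample_ids = [f"T{i + 1}" for i in range(n_t)] + [f"C{i + 1}" for i in range(n_c)]
    noise = rng.random(n_probes) < detection_noise
    det = np.where(noise[:, None],
                   rng.uniform(UNDETECTED_P_MIN, 1.0, size=(n_probes, n)),
                   rng.uniform(0.0, DETECTED_P_MAX, size=(n_probes, n)))
    ds = ExpressionDataset(
        dataset_id=f"perturbation_seed{seed}",
        matrix=pd.DataFrame(data, index=probe_ids, columns=sample_ids),
        scale=SCALE_LOG2,
        detection_p=pd.DataFrame(det, index=probe_ids, columns=sample_ids),
    )
    labels = {s: ("treated" if i < n_t else "control")
              for i, s in enumerate(sample_ids)}
    truth = pd.DataFrame({"probe_id": probe_ids, "is_de": is_de,
                          "true_lfc": np.where(is_de, lfc, 0.0),
                          "true_sigma_sq": sigma_sq,
                          "detection_noise": noise}).set_index("probe_id")
    return ds, labels, truth
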