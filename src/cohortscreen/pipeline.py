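"""Orchestration of the full screening workflow from a single config.

Stage 1 (candidate screen): normalize each cohort, then test every
candidate gene for anchor correlation and tumor-vs-normal alteration,
aggregated by the strict-majority consistency rule.

Stage 2 (perturbation follow-up): moderated-t differential expression of
a two-group perturbation experiment, fold-change selection, then a
correlation-consistency re-screen of the selected genes against a new
anchor (typically the stage-1 winner).

Signature evaluation: per cohort, Q1-vs-rest disease-free-survival
stratification for each single gene and for the mean-signal composite.

Every threshold used is echoed into the report together with input file
digests, so any report can be reproduced from its own config echo.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import (
    read_clinical_table,
    read_expression_table,
    read_probe_map,
)
from .consistency_screen import (
    ScreenCriteria,
    aggregate_screen,
    correlate_with_anchor,
    tumor_vs_normal,
)
from .datatypes import ClinicalTable, ExpressionDataset, ProbeMap
from .errors import ConfigurationError
from .normalize import NormalizationConfig, preprocess_array_cohort, preprocess_rnaseq
from .perturbation_de import DESelectionCriteria, run_de, select_de_candidates
from .survival_strat import StratificationConfig, stratify_dfs

log = logging.getLogger(__name__)


@dataclass
class ScreenReport:
    """Config echo + per-stage tables + provenance."""

    config_echo: dict
    tables: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                         float_format="%.10g")
        meta = {"config": self.config_echo, "provenance": self.provenance}
        (out / "report.json").write_text(json.dumps(meta, indent=2, default=str))


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_config(config) -> tuple[dict, dict]:
    """Accept a mapping or a YAML/JSON path; returns (config, digests)."""
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        cfg = yaml.safe_load(path.read_text())
        return cfg, {str(path): _digest(path)}
    return dict(config), {}


def _check_inputs_exist(paths: Sequence) -> None:
    missing = [str(p) for p in paths if p and not Path(p).exists()]
    if missing:
        raise ConfigurationError(f"missing input files: {missing}")


def _load_cohorts(cfg: dict, digests: dict) -> list[ExpressionDataset]:
    entries = cfg.get("cohorts")
    if not entries:
        raise ConfigurationError("config names no cohorts")
    paths = []
    for e in entries:
        paths.append(e.get("expression"))
        paths.append(e.get("clinical"))
    _check_inputs_exist([p for p in paths if p])
    cohorts = []
    for e in entries:
        ds = read_expression_table(e["expression"],
                                   dialect=e.get("dialect", "plain_tsv"),
                                   dataset_id=e.get("id"))
        digests[e["expression"]] = _digest(e["expression"])
        if e.get("clinical"):
            ds = dataclasses.replace(ds, samples=read_clinical_table(e["clinical"]))
            digests[e["clinical"]] = _digest(e["clinical"])
        cohorts.append(ds)
    return cohorts


def normalize_cohorts(
    cohorts: Sequence[ExpressionDataset],
    norm_cfg: NormalizationConfig,
    kinds: Optional[Sequence[str]] = None,
) -> list[ExpressionDataset]:
    """Array cohorts take the full chain; 'rnaseq' cohorts take the
    log2(x + pseudocount) passthrough."""
    kinds = kinds or ["array"] * len(cohorts)
    out = []
    for ds, kind in zip(cohorts, kinds):
        if kind == "rnaseq":
            out.append(preprocess_rnaseq(ds, norm_cfg))
        else:
            out.append(preprocess_array_cohort(ds, norm_cfg))
    return out


def screen_cohorts(
    cohorts: Sequence[ExpressionDataset],
    probe_map: ProbeMap,
    anchor: str,
    candidates: Sequence[str],
    crit: ScreenCriteria = ScreenCriteria(),
) -> dict:
    """Library-level stage 1 on already-normalized cohorts; returns the
    three screen tables."""
    corr = correlate_with_anchor(cohorts, probe_map, anchor, candidates, crit)
    alt = tumor_vs_normal(cohorts, probe_map, candidates, crit)
    if corr.empty or alt.empty:
        verdicts = pd.DataFrame(columns=["gene", "n_evaluable_corr", "n_pass_corr",
                                         "n_evaluable_alt", "n_pass_alt",
                                         "corr_fraction", "selected"])
    else:
        verdicts = aggregate_screen(corr, alt, crit)
    return {"correlations": corr, "alterations": alt, "verdicts": verdicts}


def run_candidate_screen(config) -> ScreenReport:
    """Full stage-1 (and optional stage-2) screen from a config mapping
    or YAML path; fails before any computation if referenced files are
    missing."""
    cfg, digests = _load_config(config)
    cohorts = _load_cohorts(cfg, digests)
    if cfg.get("probe_map"):
        _check_inputs_exist([cfg["probe_map"]])
        probe_map = read_probe_map(cfg["probe_map"])
        digests[cfg["probe_map"]] = _digest(cfg["probe_map"])
    else:
        all_features = {f for ds in cohorts for f in ds.feature_ids}
        probe_map = ProbeMap.identity(sorted(all_features))

    candidates = cfg.get("candidates")
    if isinstance(candidates, str):
        _check_inputs_exist([candidates])
        digests[candidates] = _digest(candidates)
        candidates = [line.strip() for line in Path(candidates).read_text().splitlines()
                      if line.strip()]
    if not candidates:
        raise ConfigurationError("config names no candidate genes")
    anchor = cfg.get("anchor")
    if not anchor:
        raise ConfigurationError("config names no anchor gene")

    norm_cfg = NormalizationConfig(**cfg.get("normalize", {}))
    crit = ScreenCriteria(**cfg.get("screen", {}))
    kinds = [e.get("kind", "array") for e in cfg["cohorts"]]
    normalized = normalize_cohorts(cohorts, norm_cfg, kinds)
    tables = screen_cohorts(normalized, probe_map, anchor, candidates, crit)

    echo = {
        "anchor": anchor,
        "candidates": list(candidates),
        "screen": dataclasses.asdict(crit),
        "normalize": dataclasses.asdict(norm_cfg),
        "cohorts": [{"id": ds.dataset_id, "n_features": ds.n_features,
                     "n_samples": ds.n_samples} for ds in normalized],
    }

    if cfg.get("stage2"):
        s2 = cfg["stage2"]
        _check_inputs_exist([s2.get("expression"), s2.get("groups"),
                             s2.get("probe_map")])
        expr = read_expression_table(s2["expression"],
                                     dialect=s2.get("dialect", "probe_profile"))
        digests[s2["expression"]] = _digest(s2["expression"])
        groups_tab = pd.read_csv(s2["groups"], sep="\t")
        digests[s2["groups"]] = _digest(s2["groups"])
        group_labels = dict(zip(groups_tab["sample_id"], groups_tab["group"]))
        s2_map = read_probe_map(s2["probe_map"]) if s2.get("probe_map") else probe_map
        if s2.get("probe_map"):
            digests[s2["probe_map"]] = _digest(s2["probe_map"])
        de_crit = DESelectionCriteria(**s2.get("de", {}))
        de_norm = preprocess_array_cohort(expr, norm_cfg)
        de = run_de(de_norm, group_labels, probe_map=s2_map)
        selection = select_de_candidates(de, de_crit, s2_map)
        de_out = de.reset_index()
        tables["de_results"] = de_out
        tables["de_selection"] = pd.DataFrame({
            "probe_id": selection.significant,
            "fc_filtered": [p in set(selection.fc_filtered)
                            for p in selection.significant],
        })
        stage2_anchor = s2.get("anchor")
        if stage2_anchor is None:
            winners = tables["verdicts"].query("selected")["gene"]
            if winners.empty:
                raise ConfigurationError("stage 2 needs an anchor: no stage-1 winner")
            stage2_anchor = winners.iloc[0]
        confirm = screen_cohorts(normalized, probe_map, stage2_anchor,
                                 selection.candidate_genes, crit)
        tables["stage2_correlations"] = confirm["correlations"]
        tables["stage2_verdicts"] = confirm["verdicts"]
        echo["stage2"] = {"anchor": stage2_anchor,
                          "de": dataclasses.asdict(de_crit),
                          "candidate_genes": selection.candidate_genes,
                          "n_significant": len(selection.significant),
                          "n_up": selection.n_up, "n_down": selection.n_down}

    report = ScreenReport(
        config_echo=echo,
        tables=tables,
        provenance={"tool_version": __version__, "inputs_sha256": digests},
    )
    if cfg.get("out"):
        report.write(cfg["out"])
    return report


def evaluate_signature(
    ds: ExpressionDataset,
    clin: ClinicalTable,
    probe_map: ProbeMap,
    genes: Sequence[str],
    strat_cfg: StratificationConfig = StratificationConfig(),
) -> pd.DataFrame:
    """Side-by-side Q1-vs-rest results for each single gene and for the
    composite signature in one cohort."""
    rows = []
    combos = [[g] for g in genes]
    if len(genes) > 1:
        combos.append(list(genes))
    for combo in combos:
        res = stratify_dfs(ds, clin, probe_map, combo, strat_cfg)
        lr = res.logrank
        rows.append({
            "dataset_id": ds.dataset_id,
            "signature": "+".join(combo),
            "n_q1": res.group_sizes["Q1"],
            "n_rest": res.group_sizes["rest"],
            "chi_sq": lr.chi_sq if lr else np.nan,
            "p_value": lr.p_value if lr else np.nan,
            "hazard_ratio": lr.hazard_ratio if lr else np.nan,
        })
    return pd.DataFrame(rows)


def run_signature_evaluation(config) -> ScreenReport:
    """Per-cohort single-gene and composite survival stratification from
    a config mapping or YAML path. Cohorts without survival annotation
    are skipped with a warning; the others are processed."""
    cfg, digests = _load_config(config)
    cohorts = _load_cohorts(cfg, digests)
    genes = cfg.get("genes")
    if not genes:
        raise ConfigurationError("config names no signature genes")
    if cfg.get("probe_map"):
        _check_inputs_exist([cfg["probe_map"]])
        probe_map = read_probe_map(cfg["probe_map"])
        digests[cfg["probe_map"]] = _digest(cfg["probe_map"])
    else:
        all_features = {f for ds in cohorts for f in ds.feature_ids}
        probe_map = ProbeMap.identity(sorted(all_features))
    norm_cfg = NormalizationConfig(**cfg.get("normalize", {}))
    strat_cfg = StratificationConfig(**cfg.get("stratify", {}))
    kinds = [e.get("kind", "array") for e in cfg["cohorts"]]
    normalized = normalize_cohorts(cohorts, norm_cfg, kinds)

    frames = []
    for ds in normalized:
        if ds.samples is None or ds.samples.survival_frame().empty:
            log.warning("%s: no survival annotation; skipped", ds.dataset_id)
            continue
        frames.append(evaluate_signature(ds, ds.samples, probe_map, genes,
                                         strat_cfg))
    if not frames:
        raise ConfigurationError("no cohort carries survival annotation")
    table = pd.concat(frames, ignore_index=True)
    report = ScreenReport(
        config_echo={"genes": list(genes),
                     "stratify": dataclasses.asdict(strat_cfg),
                     "normalize": dataclasses.asdict(norm_cfg)},
        tables={"signature_evaluation": table},
        provenance={"tool_version": __version__, "inputs_sha256": digests},
    )
    if cfg.get("out"):
        report.write(cfg["out"])
    return report
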