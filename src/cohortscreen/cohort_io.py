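"""Readers and writers for cohort tables.

Two expression dialects are supported:

``plain_tsv``
    features x samples, first column = feature id, header row = sample ids.
    Missing values are encoded as ``NA``.

``probe_profile``
    GenomeStudio "Final Report (sample probe profile)"-style export: one
    probe-id column (``ProbeID``), then per-sample ``<sample>.AVG_Signal``
    and ``<sample>.Detection Pval`` columns.

Clinical tables and probe maps are plain TSV with a header. Isoform
collapse averages all probes mapped to a gene into one per-sample signal
(the mean-signal convention for multi-isoform platforms).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .datatypes import SCALE_LOG2, SCALE_RAW, ClinicalTable, ExpressionDataset, ProbeMap
from .errors import FormatError, ScaleError, TableParseError

log = logging.getLogger(__name__)

SIGNAL_SUFFIX = ".AVG_Signal"
DETECTION_SUFFIX = ".Detection Pval"
NA_TOKEN = "NA"


def _to_numeric(frame: pd.DataFrame, path: str) -> pd.DataFrame:
    """Parse all cells to float; name the first offending row/column.

    Uses Python's correctly-rounded float parser so that values written
    at full precision round-trip bit-identically."""
    probe = frame.apply(pd.to_numeric, errors="coerce")
    bad = probe.isna() & frame.notna() & (frame != NA_TOKEN)
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise TableParseError(
            f"{path}: non-numeric value {frame.loc[row, col]!r} "
            f"at feature {row!r}, column {col!r}"
        )
    out = frame.map(lambda v: np.nan if v is None else float(v))
    return out.astype(float)


def read_expression_table(
    path, dialect: str = "plain_tsv", dataset_id: Optional[str] = None
) -> ExpressionDataset:
    """Read an expression matrix; returns data on the raw-intensity scale.

    ``probe_profile`` populates ``detection_p``; ``plain_tsv`` leaves it
    absent. Column (sample) order is preserved as found in the file.
    """
    path = Path(path)
    dataset_id = dataset_id or path.stem
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected a feature-id column plus data columns")
    raw = raw.replace({NA_TOKEN: None, "": None})
    feature_col = raw.columns[0]
    features = raw[feature_col]
    if features.isna().any():
        raise FormatError(f"{path}: missing feature id")
    if features.duplicated().any():
        dups = features[features.duplicated()].tolist()
        raise FormatError(f"{path}: duplicated feature ids: {dups[:5]}")
    body = raw.drop(columns=[feature_col])
    body.index = pd.Index(features, name=feature_col)

    if dialect == "plain_tsv":
        matrix = _to_numeric(body, str(path))
        return ExpressionDataset(dataset_id, matrix, SCALE_RAW)

    if dialect == "probe_profile":
        signal_cols = [c for c in body.columns if c.endswith(SIGNAL_SUFFIX)]
        detect_cols = [c for c in body.columns if c.endswith(DETECTION_SUFFIX)]
        if not signal_cols or not detect_cols:
            raise FormatError(
                f"{path}: probe_profile dialect requires per-sample "
                f"'{SIGNAL_SUFFIX}' and '{DETECTION_SUFFIX}' columns"
            )
        samples = [c[: -len(SIGNAL_SUFFIX)] for c in signal_cols]
        missing = [s for s in samples if s + DETECTION_SUFFIX not in detect_cols]
        if missing:
            raise FormatError(f"{path}: no detection column for samples {missing}")
        matrix = _to_numeric(body[signal_cols], str(path))
        matrix.columns = samples
        detection = _to_numeric(body[[s + DETECTION_SUFFIX for s in samples]], str(path))
        detection.columns = samples
        return ExpressionDataset(dataset_id, matrix, SCALE_RAW, detection_p=detection)

    raise FormatError(f"unknown dialect {dialect!r}")


def write_expression_table(ds: ExpressionDataset, path) -> None:
    """Write an ExpressionDataset; probe-profile layout when detection
    p-values are present, plain TSV otherwise. Full float precision so a
    read round-trips bit-identically."""
    path = Path(path)
    if ds.detection_p is None:
        out = ds.matrix.copy()
        out.insert(0, "feature_id", out.index)
        out.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.17g")
        return
    cols: dict[str, object] = {"ProbeID": ds.matrix.index}
    for s in ds.sample_ids:
        cols[s + SIGNAL_SUFFIX] = ds.matrix[s].to_numpy()
        cols[s + DETECTION_SUFFIX] = ds.detection_p[s].to_numpy()
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN,
                              float_format="%.17g")


def read_clinical_table(path) -> ClinicalTable:
    """Read a clinical TSV (sample_id, tissue_class, optional dfs_time /
    dfs_event); all consistency checks happen in ClinicalTable."""
    raw = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    raw = raw.replace({NA_TOKEN: None, "": None})
    for col in ("dfs_time", "dfs_event"):
        if col in raw.columns:
            raw[col] = pd.to_numeric(raw[col], errors="raise")
    return ClinicalTable(raw)


def write_clinical_table(clin: ClinicalTable, path) -> None:
    clin.table.to_csv(Path(path), sep="\t", index=False, na_rep=NA_TOKEN)


def read_probe_map(path) -> ProbeMap:
    raw = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    raw = raw.replace({"": None})
    return ProbeMap(raw)


def write_probe_map(pmap: ProbeMap, path) -> None:
    pmap.table.to_csv(Path(path), sep="\t", index=False, na_rep="")


def collapse_isoforms_to_gene_signal(
    ds: ExpressionDataset, probe_map: ProbeMap, gene: str
) -> pd.Series:
    """Per-sample gene signal: the unweighted arithmetic mean of all
    probes mapped to ``gene`` that are measured in ``ds``.

    With a single mapped probe the probe's row is returned unchanged.
    Requires log2-scale data (averaging raw intensities would weight
    bright probes disproportionately). Raises MissingGeneError when no
    mapped probe is measured, so a caller can skip the cohort.
    """
    if ds.scale != SCALE_LOG2:
        raise ScaleError(
            f"{ds.dataset_id}: isoform collapse requires log2 scale, got {ds.scale!r}"
        )
    probes = [p for p in probe_map.probes_for(gene) if p in ds.matrix.index]
    if not probes:
        from .errors import MissingGeneError

        raise MissingGeneError(
            f"{ds.dataset_id}: no probe for gene {gene!r} is measured"
        )
    sub = ds.matrix.loc[probes]
    if sub.isna().any().any():
        log.debug("%s: gene %s has missing probe values; mean over observed",
                  ds.dataset_id, gene)
    signal = sub.mean(axis=0, skipna=True)
    signal.name = gene
    return signal


def gene_signal_matrix(
    ds: ExpressionDataset, probe_map: ProbeMap, genes: Iterable[str]
) -> pd.DataFrame:
    """Collapse several genes at once; genes with no measured probe are
    silently omitted (callers inspect the index)."""
    from .errors import MissingGeneError

    rows = {}
    for g in genes:
        try:
            rows[g] = collapse_isoforms_to_gene_signal(ds, probe_map, g)
        except MissingGeneError:
            continue
    if not rows:
        return pd.DataFrame(columns=ds.sample_ids)
    return pd.DataFrame(rows).T
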