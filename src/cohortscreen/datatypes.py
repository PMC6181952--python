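"""Core in-memory containers for cohort-level analysis.

An :class:`ExpressionDataset` holds one cohort's probe/gene x sample matrix
(as a pandas DataFrame) together with its measurement scale, optional
per-cell array detection p-values, and a link to the cohort's clinical
annotation. A :class:`ClinicalTable` carries tissue class and optional
disease-free-survival (DFS) columns per sample. A :class:`ProbeMap` relates
probe/isoform-level features to gene symbols; gene symbols are matched
case-insensitively after trimming because public cohort tables are
inconsistent about casing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, MissingGeneError, VocabularyError

SCALE_RAW = "raw_intensity"
SCALE_LOG2 = "log2"
VALID_SCALES = (SCALE_RAW, SCALE_LOG2)

TISSUE_CLASSES = ("normal", "primary_tumor", "cell_line", "other")


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation.

    ``table`` columns: ``sample_id`` (unique), ``tissue_class`` (closed
    vocabulary), optional ``dfs_time`` (months, >= 0) and ``dfs_event``
    (1 = recurrence, 0 = censored). A row may have neither DFS column,
    but an event always requires a time.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "tissue_class"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"clinical table missing columns: {sorted(missing)}")
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicated sample ids in clinical table: {dups}")
        bad = set(t["tissue_class"].dropna()) - set(TISSUE_CLASSES)
        if bad:
            raise VocabularyError(
                f"unknown tissue_class tokens {sorted(bad)}; "
                f"allowed: {list(TISSUE_CLASSES)}"
            )
        if "dfs_event" in t.columns:
            ev = t["dfs_event"].dropna()
            if not ev.isin([0, 1]).all():
                raise DomainError("dfs_event must be 0 or 1")
            if "dfs_time" not in t.columns:
                raise FormatError("dfs_event present without dfs_time column")
            has_event = t["dfs_event"].notna()
            if (has_event & t["dfs_time"].isna()).any():
                bad_ids = t.loc[has_event & t["dfs_time"].isna(), "sample_id"]
                raise FormatError(
                    f"dfs_event recorded without dfs_time for samples: {list(bad_ids)}"
                )
        if "dfs_time" in t.columns:
            times = t["dfs_time"].dropna()
            if (times < 0).any():
                raise DomainError("dfs_time must be nonnegative")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def samples_of_class(self, tissue_class: str) -> list[str]:
        sel = self.table["tissue_class"] == tissue_class
        return self.table.loc[sel, "sample_id"].tolist()

    def survival_frame(self) -> pd.DataFrame:
        """Rows with both DFS time and event, indexed by sample id."""
        t = self.table
        if "dfs_time" not in t.columns or "dfs_event" not in t.columns:
            return pd.DataFrame(columns=["dfs_time", "dfs_event"])
        keep = t["dfs_time"].notna() & t["dfs_event"].notna()
        out = t.loc[keep, ["sample_id", "dfs_time", "dfs_event"]].set_index("sample_id")
        return out.astype({"dfs_time": float, "dfs_event": int})


@dataclass
class ExpressionDataset:
    """One cohort's expression matrix (features x samples).

    ``matrix`` is a DataFrame with unique feature ids as the index and
    unique sample ids as the columns. ``scale`` is ``raw_intensity`` for
    untransformed array signal / RNA-seq counts and ``log2`` after
    transformation. ``detection_p``, when present, is a same-shaped matrix
    of per-cell array detection p-values in [0, 1].
    """

    dataset_id: str
    matrix: pd.DataFrame
    scale: str
    detection_p: Optional[pd.DataFrame] = None
    samples: Optional[ClinicalTable] = None

    def __post_init__(self) -> None:
        m = self.matrix
        if self.scale not in VALID_SCALES:
            raise FormatError(f"unknown scale {self.scale!r}; allowed {VALID_SCALES}")
        if m.index.duplicated().any():
            dups = m.index[m.index.duplicated()].tolist()
            raise FormatError(f"{self.dataset_id}: duplicated feature ids: {dups[:5]}")
        if m.columns.duplicated().any():
            dups = m.columns[m.columns.duplicated()].tolist()
            raise FormatError(f"{self.dataset_id}: duplicated sample ids: {dups[:5]}")
        if self.scale == SCALE_LOG2:
            vals = m.to_numpy(dtype=float)
            if not np.isfinite(vals[~np.isnan(vals)]).all():
                raise DomainError(f"{self.dataset_id}: non-finite values on log2 scale")
        if self.detection_p is not None:
            d = self.detection_p
            if d.shape != m.shape:
                raise FormatError(
                    f"{self.dataset_id}: detection_p shape {d.shape} != matrix {m.shape}"
                )
            if not d.index.equals(m.index) or not d.columns.equals(m.columns):
                raise FormatError(f"{self.dataset_id}: detection_p labels differ from matrix")
            dv = d.to_numpy(dtype=float)
            dv = dv[~np.isnan(dv)]
            if dv.size and (dv.min() < 0 or dv.max() > 1):
                raise DomainError(f"{self.dataset_id}: detection p-values outside [0, 1]")

    @property
    def feature_ids(self) -> list[str]:
        return self.matrix.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.columns.tolist()

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def with_matrix(
        self,
        matrix: pd.DataFrame,
        scale: Optional[str] = None,
        detection_p: Optional[pd.DataFrame] = "keep",  # type: ignore[assignment]
    ) -> "ExpressionDataset":
        """Copy with a replaced matrix; detection_p is subset to the new
        features unless explicitly replaced."""
        dp = self.detection_p
        if isinstance(detection_p, pd.DataFrame) or detection_p is None:
            dp = detection_p
        elif dp is not None:
            dp = dp.loc[matrix.index, matrix.columns]
        return replace(
            self,
            matrix=matrix,
            scale=scale if scale is not None else self.scale,
            detection_p=dp,
        )


@dataclass
class ProbeMap:
    """Probe/isoform -> gene symbol map.

    Each probe id maps to at most one gene symbol. Gene symbols are matched
    case-insensitively after whitespace trimming; probe ids are
    case-sensitive.
    """

    table: pd.DataFrame
    _by_gene: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"probe_id", "gene_symbol"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"probe map missing columns: {sorted(missing)}")
        if t["probe_id"].duplicated().any():
            dups = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()
            raise FormatError(f"probe ids map to more than one gene: {dups[:5]}")
        if "isoform_label" not in t.columns:
            t = t.assign(isoform_label=None)
        self.table = t.reset_index(drop=True)
        by_gene: dict[str, list[str]] = {}
        for probe, gene in zip(self.table["probe_id"], self.table["gene_symbol"]):
            key = str(gene).strip().upper()
            by_gene.setdefault(key, []).append(str(probe))
        self._by_gene = by_gene

    @classmethod
    def identity(cls, feature_ids) -> "ProbeMap":
        """Map where every feature is its own gene (gene-level matrices)."""
        return cls(pd.DataFrame({"probe_id": list(feature_ids),
                                 "gene_symbol": list(feature_ids)}))

    def probes_for(self, gene: str) -> list[str]:
        key = gene.strip().upper()
        if key not in self._by_gene:
            raise MissingGeneError(f"no probe maps to gene {gene!r}")
        return list(self._by_gene[key])

    def genes(self) -> list[str]:
        return sorted({str(g).strip() for g in self.table["gene_symbol"]})

    def gene_of(self, probe_id: str) -> Optional[str]:
        hit = self.table.loc[self.table["probe_id"] == probe_id, "gene_symbol"]
        return None if hit.empty else str(hit.iloc[0]).strip()
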