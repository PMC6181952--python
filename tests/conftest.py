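import numpy as np
import pandas as pd
import pytest

from cohortscreen.datatypes import ClinicalTable, ExpressionDataset, ProbeMap


@pytest.fixture
def small_log2_dataset():
    """4 probes (2 genes x 2 isoforms) x 4 samples on the log2 scale."""
    matrix = pd.DataFrame(
        {
            "s1": [2.0, 4.0, 5.0, 6.0],
            "s2": [4.0, 6.0, 5.5, 7.0],
            "s3": [3.0, 5.0, 6.0, 8.0],
            "s4": [5.0, 7.0, 6.5, 9.0],
        },
        index=["GA_iso1", "GA_iso2", "GB_iso1", "GB_iso2"],
    )
    return ExpressionDataset("toy", matrix, "log2")


@pytest.fixture
def two_gene_map():
    return ProbeMap(pd.DataFrame({
        "probe_id": ["GA_iso1", "GA_iso2", "GB_iso1", "GB_iso2"],
        "gene_symbol": ["GA", "GA", "GB", "GB"],
        "isoform_label": ["iso1", "iso2", "iso1", "iso2"],
    }))


@pytest.fixture
def clinical_four():
    return ClinicalTable(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "tissue_class": ["normal", "normal", "primary_tumor", "primary_tumor"],
    }))


def make_survival_clinical(sample_ids, times, events, tissue="primary_tumor"):
    return ClinicalTable(pd.DataFrame({
        "sample_id": list(sample_ids),
        "tissue_class": [tissue] * len(sample_ids),
        "dfs_time": list(times),
        "dfs_event": list(events),
    }))
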