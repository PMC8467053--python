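"""Bundled reference tables from a published FFPE xenograft MALDI-MSI
lipidomics study, used as worked examples for the filter and significance
rules: the 26-mass master peak list with whole-dataset CVs and accurate
masses, the tumor-vs-necrosis mixed-model summary, and the
treated-vs-control marker summary."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("lipidmsi").joinpath(f"data/{name}")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def master_list() -> pd.DataFrame:
    """Published master peak list (m/z, CV%, accurate m/z, ID, tier flags)."""
    return _load("reference_master_list.tsv")


def tumor_necrosis_stats() -> pd.DataFrame:
    """Published tumor-vs-necrosis log2FC and LMM p-value summary."""
    return _load("reference_tumor_necrosis.tsv")


def treatment_stats() -> pd.DataFrame:
    """Published treated-vs-control Wilcoxon/AUC marker summary."""
    return _load("reference_treatment.tsv")
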