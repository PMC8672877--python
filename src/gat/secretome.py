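"""Secreted-protein and effector-candidate filters.

Effector candidates follow the standard fungal definition: a predicted
secreted protein — signal peptide present, no transmembrane domain, no
GPI anchor — shorter than 300 amino acids (strict bound).  The SP/TM/GPI
verdicts come from upstream predictors (SignalP, TMHMM, big-PI) consumed as
feature-table columns, so the filter is testable without those tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class EffectorRules:
    require_sp: bool = True
    max_tm: int = 0
    allow_gpi: bool = False
    max_length: int = 300  # exclusive: candidates are < max_length aa

    def __post_init__(self) -> None:
        if self.max_length <= 0:
            raise ValueError("max_length must be positive")
        if self.max_tm < 0:
            raise ValueError("max_tm must be >= 0")


def secreted_set(features: pd.DataFrame) -> list[str]:
    """Gene ids with a predicted signal peptide, in input order."""
    if "has_sp" not in features.columns:
        raise ValueError("feature table lacks a has_sp column")
    return features.loc[features["has_sp"].astype(bool), "gene_id"].tolist()


def effector_candidates(
    features: pd.DataFrame, rules: EffectorRules = EffectorRules()
) -> list[str]:
    """Gene ids passing the effector filter, in input order.

    Keeps rows with (SP if required) and tm_count <= max_tm and (no GPI
    unless allowed) and protein_length < max_length.
    """
    needed = {"has_sp", "tm_count", "has_gpi", "protein_length"}
    missing = needed - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks columns: {sorted(missing)}")
    if (features["protein_length"] < 0).any():
        raise ValueError("negative protein_length in feature table")
    mask = (
        (features["tm_count"].astype(int) <= rules.max_tm)
        & (features["protein_length"].astype(int) < rules.max_length)
    )
    if rules.require_sp:
        mask &= features["has_sp"].astype(bool)
    if not rules.allow_gpi:
        mask &= ~features["has_gpi"].astype(bool)
    return features.loc[mask, "gene_id"].tolist()
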