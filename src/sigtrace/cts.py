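"""Cancer-type-specific signature (CTS-MS) and mutation-marker selection.

A signature is specific to a cancer type when, over a labeled cohort of
refitted exposures, (1) it is observed (contribution > 0.06) in at least
20% of that type's samples, (2) its mean contribution exceeds that of the
pooled remaining types by a fold change > 1.5, and (3) the absolute mean
difference exceeds 0.1.  Tumor-specific mutation markers are genes mutated
in more than 5% of a type's samples whose frequency differs from the pooled
rest by more than 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    pass


@dataclass
class CohortExposures:
    """Refitted exposures plus cancer-type labels for a cohort."""

    exposures: pd.DataFrame  # samples x signatures
    types: pd.Series  # sample -> type label

    def __post_init__(self) -> None:
        self.types = pd.Series(self.types).reindex(self.exposures.index)
        if self.types.isna().any():
            missing = self.types.index[self.types.isna()][:3].tolist()
            raise ConfigurationError(f"samples without a type label: {missing}")

    @property
    def type_names(self) -> list[str]:
        return sorted(self.types.unique())


@dataclass(frozen=True)
class CTSEntry:
    signature: str
    fraction_in_type: float
    mean_in_type: float
    mean_in_rest: float
    fold_change: float
    abs_diff: float


@dataclass
class CTSMSPattern:
    type_name: str
    entries: list[CTSEntry]

    @property
    def signatures(self) -> list[str]:
        return [e.signature for e in self.entries]


def signature_prevalence(
    cohort: CohortExposures, presence_cutoff: float = 0.06
) -> pd.DataFrame:
    """Fraction of each type's samples with exposure strictly above the cutoff.

    Returns a types x signatures DataFrame.  "Observed" means a contribution
    > 0.06, the presence rule used for exposure heatmaps.
    """
    present = cohort.exposures > presence_cutoff
    return present.groupby(cohort.types).mean()


def _means_by_membership(
    cohort: CohortExposures, type_name: str
) -> tuple[pd.Series, pd.Series]:
    mask = cohort.types == type_name
    return cohort.exposures[mask].mean(), cohort.exposures[~mask].mean()


def select_cts_ms(
    cohort: CohortExposures,
    type_name: str,
    min_fraction: float = 0.20,
    min_fc: float = 1.5,
    min_diff: float = 0.1,
    presence_cutoff: float = 0.06,
    epsilon: float = 1e-3,
    center: str = "mean",
) -> CTSMSPattern:
    """Select the signatures specific to ``type_name`` versus the pooled rest.

    Fold change is computed on mean (or median, ``center="median"``)
    exposures with a symmetric pseudo-count ``epsilon`` guarding zero rest
    means.  Entries are sorted by absolute difference, descending.
    """
    if type_name not in set(cohort.types):
        raise ConfigurationError(f"type {type_name!r} not in cohort")
    if cohort.types.nunique() < 2:
        raise ConfigurationError("CTS-MS selection needs at least 2 cancer types")
    mask = cohort.types == type_name
    if center == "mean":
        m_t = cohort.exposures[mask].mean()
        m_r = cohort.exposures[~mask].mean()
    elif center == "median":
        m_t = cohort.exposures[mask].median()
        m_r = cohort.exposures[~mask].median()
    else:
        raise ConfigurationError(f"unknown center {center!r}")
    frac = (cohort.exposures[mask] > presence_cutoff).mean()
    entries = []
    for sig in cohort.exposures.columns:
        fc = (m_t[sig] + epsilon) / (m_r[sig] + epsilon)
        diff = abs(m_t[sig] - m_r[sig])
        if frac[sig] >= min_fraction and fc > min_fc and diff > min_diff:
            entries.append(
                CTSEntry(
                    signature=sig,
                    fraction_in_type=float(frac[sig]),
                    mean_in_type=float(m_t[sig]),
                    mean_in_rest=float(m_r[sig]),
                    fold_change=float(fc),
                    abs_diff=float(diff),
                )
            )
    entries.sort(key=lambda e: (-e.abs_diff, e.signature))
    return CTSMSPattern(type_name, entries)


def select_specific_mutations(
    gene_matrix: pd.DataFrame,
    types: Mapping[str, str] | pd.Series,
    type_name: str,
    min_freq: float = 0.05,
    min_diff: float = 0.1,
) -> list[tuple[str, float, float]]:
    """Tumor-specific mutation markers for one type versus the pooled rest.

    Candidate genes are mutated in strictly more than ``min_freq`` of the
    type's samples; candidates are kept when the absolute frequency
    difference against the rest exceeds ``min_diff``.  Sorted by absolute
    difference, descending.
    """
    types = pd.Series(types).reindex(gene_matrix.index)
    if type_name not in set(types):
        raise ConfigurationError(f"type {type_name!r} not in cohort")
    if types.nunique() < 2:
        raise ConfigurationError("marker selection needs at least 2 cancer types")
    mask = types == type_name
    f_t = gene_matrix[mask].mean()
    f_r = gene_matrix[~mask].mean()
    out = [
        (gene, float(f_t[gene]), float(f_r[gene]))
        for gene in gene_matrix.columns
        if f_t[gene] > min_freq and abs(f_t[gene] - f_r[gene]) > min_diff
    ]
    out.sort(key=lambda t: (-abs(t[1] - t[2]), t[0]))
    return out


def pattern_to_dict(pattern: CTSMSPattern) -> dict:
    return {
        "type_name": pattern.type_name,
        "entries": [vars(e) for e in pattern.entries],
    }


def pattern_from_dict(d: dict) -> CTSMSPattern:
    return CTSMSPattern(d["type_name"], [CTSEntry(**e) for e in d["entries"]])
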