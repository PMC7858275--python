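"""Taxon-to-function projection of community composition.

Community profiles are projected onto pathway space through a taxon-by-
pathway reference matrix: reads from taxa present in the reference are
renormalized and multiplied through the reference rows; the fraction of
reads assignable to the reference is reported per sample.  Pathway profiles
can then be aggregated to a coarser hierarchy level (e.g. level-2 functional
categories).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hermetia.community import AbundanceTable

log = logging.getLogger(__name__)

__all__ = ["FunctionalProfile", "project_functions", "aggregate_hierarchy"]


@dataclass
class FunctionalProfile:
    """Pathway x sample relative abundances plus per-sample assignability."""

    values: pd.DataFrame          # pathways x samples, columns sum to 1 (or NaN)
    fraction_assigned: pd.Series  # per sample, in [0, 1]
    level: str = "pathway"


def project_functions(table: AbundanceTable, reference: pd.DataFrame,
                      covered_taxa: set[str] | None = None) -> FunctionalProfile:
    """Project sample compositions onto pathway profiles.

    ``reference`` is indexed by taxon id with one column per pathway; rows of
    covered taxa sum to 1.  Per sample: reads of taxa outside the reference
    (or outside ``covered_taxa``) are unassigned; the rest are renormalized
    and pushed through the reference.  A sample with zero covered reads gets
    an all-NaN profile and fraction 0, with a warning.
    """
    if covered_taxa is None:
        # all-zero reference rows are placeholders for taxa absent from the
        # reference, not genuine coverage
        nonzero = reference.index[(reference != 0).any(axis=1)]
        covered = set(nonzero)
    else:
        covered = set(covered_taxa) & set(reference.index)
    covered_ids = [t for t in table.taxon_ids if t in covered]

    counts = table.counts
    totals = counts.sum(axis=1)
    cov_counts = counts[covered_ids]
    cov_totals = cov_counts.sum(axis=1)
    frac = (cov_totals / totals).astype(float)

    ref = reference.loc[covered_ids]
    profiles = {}
    for sid in table.sample_ids:
        if cov_totals[sid] == 0:
            log.warning("project_functions: sample %s has no covered reads", sid)
            profiles[sid] = pd.Series(np.nan, index=reference.columns)
            continue
        rel = cov_counts.loc[sid] / cov_totals[sid]
        prof = ref.T @ rel
        total = prof.sum()
        profiles[sid] = prof / total if total > 0 else prof
    values = pd.DataFrame(profiles)
    values.index.name = "pathway"
    return FunctionalProfile(values=values, fraction_assigned=frac, level="pathway")


def aggregate_hierarchy(profile: FunctionalProfile,
                        pathway_map: "pd.Series | dict[str, str]",
                        level: str = "category") -> FunctionalProfile:
    """Sum pathway values into their parent categories; totals are preserved."""
    mapping = pd.Series(pathway_map)
    unmapped = profile.values.index.difference(mapping.index)
    if len(unmapped):
        raise ValueError(f"unmapped pathways: {list(unmapped)[:5]}")
    grouped = profile.values.groupby(mapping.loc[profile.values.index]).sum(min_count=1)
    grouped.index.name = level
    return FunctionalProfile(values=grouped,
                             fraction_assigned=profile.fraction_assigned,
                             level=level)
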