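"""Four-way quantification classes for differential taxa.

A taxon that differs between two groups is only as trustworthy as the
measurements behind it.  Comparing each group's detection status (enough
samples with at least one read) and quantification status (group mean
relative abundance above the CV-derived threshold) yields four classes:

* ``quant`` - above the quantitative limit in both groups; both the
  direction and the magnitude of the difference are credible.
* ``semi_quant`` - detected in both, quantifiable in one; the direction is
  credible, the magnitude is not.
* ``no_quant`` - detected in both but quantifiable in neither.
* ``presence_absence`` - detected in only one group; only the existence of
  the taxon there is credible.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .anchoring import AbsoluteAbundanceTable
from .tables_io import TaxonCountTable

__all__ = ["QuantClass", "GroupQuantSummary", "group_summary", "assign_class",
           "classify_taxa"]

#: default fraction of a group's samples that must carry the taxon for the
#: group to count as "detected" (2 of 3, mirroring a 4-of-6 prevalence rule)
DEFAULT_MIN_PREVALENCE = 2.0 / 3.0


class QuantClass(str, Enum):
    QUANT = "quant"
    SEMI_QUANT = "semi_quant"
    NO_QUANT = "no_quant"
    PRESENCE_ABSENCE = "presence_absence"


@dataclass(frozen=True)
class GroupQuantSummary:
    """Detection/quantification status of one taxon within one group."""

    group: str
    prevalence: float  # fraction of samples with >= 1 read
    mean_rel_abundance: float
    mean_abs_load: float  # copies/g
    above_lod: bool
    above_loq: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.above_loq and not self.above_lod:
            raise ValueError("above_loq implies above_lod")


def group_summary(
    table: TaxonCountTable,
    abs_table: AbsoluteAbundanceTable,
    taxon_id: str,
    group_samples: Sequence[str],
    loq_threshold_percent: float,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    group: str = "",
) -> GroupQuantSummary:
    """Summarise one taxon's detection and quantification status in a group.

    Detection (LOD) asks whether the taxon shows up at all: prevalence of
    samples with >= 1 read must reach ``min_prevalence``.  Quantification
    (LOQ) additionally asks whether the group's mean relative abundance
    clears ``loq_threshold_percent`` - the CV-curve threshold at the
    cohort's analysis depth.
    """
    samples = list(group_samples)
    if not samples:
        raise ValueError(f"empty group {group!r}")
    counts = table.counts.loc[samples, taxon_id]
    rel = table.relative_abundance().loc[samples, taxon_id]
    loads = abs_table.loads.loc[samples, taxon_id]
    prevalence = float((counts >= 1).mean())
    mean_rel = float(rel.mean())
    above_lod = prevalence >= min_prevalence
    above_loq = above_lod and mean_rel >= loq_threshold_percent / 100.0
    return GroupQuantSummary(
        group=group,
        prevalence=prevalence,
        mean_rel_abundance=mean_rel,
        mean_abs_load=float(loads.mean()),
        above_lod=above_lod,
        above_loq=above_loq,
    )


def assign_class(
    summary_a: GroupQuantSummary, summary_b: GroupQuantSummary
) -> QuantClass:
    """Map a pair of group summaries (same taxon) to its quantification class.

    The mapping is total over the detection/quantification lattice except
    when neither group detects the taxon, which is an error - such taxa
    should have been filtered before classification.
    """
    if not summary_a.above_lod and not summary_b.above_lod:
        raise ValueError("taxon not present in either group")
    if summary_a.above_lod != summary_b.above_lod:
        return QuantClass.PRESENCE_ABSENCE
    if summary_a.above_loq and summary_b.above_loq:
        return QuantClass.QUANT
    if summary_a.above_loq or summary_b.above_loq:
        return QuantClass.SEMI_QUANT
    return QuantClass.NO_QUANT


def classify_taxa(
    table: TaxonCountTable,
    abs_table: AbsoluteAbundanceTable,
    groups: Mapping[str, Sequence[str]],
    loq_threshold_percent: float,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
) -> pd.DataFrame:
    """Classify every taxon detected in at least one of two groups.

    ``groups`` maps exactly two group labels to their sample ids.  Returns a
    DataFrame indexed by taxon with per-group prevalence, mean relative
    abundance, mean load, and the assigned ``quant_class``; taxa detected in
    neither group are omitted.
    """
    if len(groups) != 2:
        raise ValueError("classification compares exactly two groups")
    (label_a, samples_a), (label_b, samples_b) = groups.items()
    rows = {}
    for taxon in table.taxon_ids:
        sa = group_summary(table, abs_table, taxon, samples_a,
                           loq_threshold_percent, min_prevalence, group=label_a)
        sb = group_summary(table, abs_table, taxon, samples_b,
                           loq_threshold_percent, min_prevalence, group=label_b)
        if not sa.above_lod and not sb.above_lod:
            continue
        rows[taxon] = {
            f"prevalence_{label_a}": sa.prevalence,
            f"prevalence_{label_b}": sb.prevalence,
            f"mean_rel_{label_a}": sa.mean_rel_abundance,
            f"mean_rel_{label_b}": sb.mean_rel_abundance,
            f"mean_load_{label_a}": sa.mean_abs_load,
            f"mean_load_{label_b}": sb.mean_abs_load,
            "quant_class": assign_class(sa, sb).value,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "taxon_id"
    return out
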