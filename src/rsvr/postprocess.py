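"""Postprocessing of significant associations and plausibility scoring.

Associations with posterior probability of association (PPA) above 0.95
pass through three re-run filters:

1. ``with_relatives`` -- re-run including relatives; drop if the PPA falls
   below 0.9 (conflicting evidence within families);
2. ``affected_relative_variants`` -- re-run after removing variants absent
   from affected relatives of cases; drop below 0.25;
3. ``relatedness_pruned`` -- re-run after pruning cases so that no more
   than one case from any set of potentially related cases sharing a
   variant remains (pairs above the 99th percentile of per-ancestry
   rare-variant sharing counts); drop below 0.25.

Surviving associations are deduplicated to the strongest disease class per
(gene, disease group), matched against gene panels, and candidates without
a panel are scored 0-3 on purifying selection or recessive inheritance,
cosegregation (three or more additional relatives, with a two-alt-read
mosaicism rescue) and a curated biological-support flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "EvidenceRow",
    "PanelRecord",
    "RelativeObservation",
    "REFILTER_THRESHOLDS",
    "refilter_association",
    "relatedness_prune",
    "dedup_disease_group",
    "match_panel",
    "count_cosegregation",
    "plausibility_score",
    "fdr_upper_bound",
    "percentage",
]

#: PPA drop thresholds per re-run mode
REFILTER_THRESHOLDS = {
    "with_relatives": 0.9,
    "affected_relative_variants": 0.25,
    "relatedness_pruned": 0.25,
}

#: number of alternate-allele reads that rescues a homozygous-reference
#: genotype call as mosaic
MOSAIC_MIN_ALT_READS = 2

_EVIDENCE_RANK = {"green": 2, "amber": 1, "red": 0}


@dataclass(frozen=True)
class EvidenceRow:
    """Evidence columns feeding the 0-3 plausibility score."""

    gene: str
    case_set: str
    level: str  # specific_disease | sub_group
    moi: str  # dominant | recessive
    variant_class: str  # high | moderate | utr5
    pli: float | None
    z: float | None
    coseg_relatives: int
    coseg_consistent: bool
    biology_support: bool


@dataclass(frozen=True)
class PanelRecord:
    panel: str
    panel_type: str
    sub_group: str
    gene: str
    evidence: str  # green | amber | red
    gene_count: int

    def __post_init__(self) -> None:
        if self.evidence not in _EVIDENCE_RANK:
            raise ValueError(f"unknown evidence level {self.evidence!r}")


@dataclass(frozen=True)
class RelativeObservation:
    """One relative not included in the association analysis."""

    sample_id: str
    affected: bool
    carrier: bool
    alt_reads: int = 0


def refilter_association(
    initial_ppa: float, rerun_ppa: float, mode: str
) -> bool:
    """Keep/drop decision for one re-run filter; True means keep."""
    if mode not in REFILTER_THRESHOLDS:
        raise ValueError(f"unknown re-run mode {mode!r}")
    if initial_ppa <= 0.95:
        raise ValueError("re-run filters apply to associations with PPA > 0.95")
    return rerun_ppa >= REFILTER_THRESHOLDS[mode]


def relatedness_prune(
    sharing: pd.DataFrame, cases: Iterable[str]
) -> list[str]:
    """Prune potentially related cases to one per variant-sharing cluster.

    ``sharing`` has columns sample_a, sample_b, ancestry, shared_count: the
    number of rare variants shared by each pair of individuals.  Pairs at
    or above the 99th percentile of their ancestry's sharing distribution
    are flagged; flagged case pairs form clusters (connected components) of
    which only the lexicographically first member is kept.
    """
    cases = sorted(cases)
    if sharing.empty:
        return cases
    flagged = nx.Graph()
    flagged.add_nodes_from(cases)
    for ancestry, group in sharing.groupby("ancestry"):
        cutoff = np.percentile(group["shared_count"], 99)
        hot = group[group["shared_count"] >= cutoff]
        for row in hot.itertuples(index=False):
            if row.sample_a in flagged and row.sample_b in flagged:
                flagged.add_edge(row.sample_a, row.sample_b)
    keep = []
    for component in nx.connected_components(flagged):
        keep.append(min(component))
    return sorted(keep)


def dedup_disease_group(results: pd.DataFrame) -> pd.DataFrame:
    """Keep only the most strongly associated disease class per
    (gene, disease_group); PPA ties break by case-set name."""
    required = {"gene", "disease_group", "case_set", "ppa"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    ordered = results.sort_values(
        ["gene", "disease_group", "ppa", "case_set"],
        ascending=[True, True, False, True],
    )
    return (
        ordered.groupby(["gene", "disease_group"], as_index=False)
        .first()
        .reset_index(drop=True)
    )


def match_panel(
    gene: str,
    case_set: str,
    case_set_sub_group: str | None,
    panels: Sequence[PanelRecord],
) -> PanelRecord | None:
    """Staged panel matching.

    First panels containing the gene whose name equals the case set
    (ignoring case); failing that, panels containing the gene whose disease
    sub-group equals the case set's sub-group.  Multiple matches reduce to
    the highest evidence level, then the smallest panel, then panel name.
    Returns ``None`` for a candidate previously unidentified association.
    """
    containing = [p for p in panels if p.gene == gene]
    stage1 = [p for p in containing if p.panel.casefold() == case_set.casefold()]
    if stage1:
        candidates = stage1
    elif case_set_sub_group is not None:
        candidates = [
            p
            for p in containing
            if p.sub_group.casefold() == case_set_sub_group.casefold()
        ]
    else:
        candidates = []
    if not candidates:
        return None
    best_evidence = max(_EVIDENCE_RANK[p.evidence] for p in candidates)
    candidates = [p for p in candidates if _EVIDENCE_RANK[p.evidence] == best_evidence]
    smallest = min(p.gene_count for p in candidates)
    candidates = [p for p in candidates if p.gene_count == smallest]
    return min(candidates, key=lambda p: p.panel)


def count_cosegregation(
    relatives: Sequence[RelativeObservation],
) -> tuple[int, bool]:
    """(number of cosegregating relatives, consistency flag).

    A relative cosegregates when affected and carrying the pertinent
    variants, or unaffected and not carrying them.  An affected relative
    called homozygous reference counts as a mosaic carrier when two or
    more reads support the alternate allele.  The flag is False when any
    affected relative lacks the variants (and is not mosaic).
    """
    count = 0
    consistent = True
    for rel in relatives:
        is_carrier = rel.carrier or rel.alt_reads >= MOSAIC_MIN_ALT_READS
        if rel.affected:
            if is_carrier:
                count += 1
            else:
                consistent = False
        elif not rel.carrier:
            count += 1
    return count, consistent


def plausibility_score(row: EvidenceRow) -> int:
    """Sum of three evidence points.

    Selection/MOI point: recessive inheritance, or a dominant high-impact
    association in a loss-of-function intolerant gene (pLI > 0.9), or a
    dominant moderate-impact association in a missense-depleted gene
    (Z > 2).  Cosegregation point: three or more cosegregating relatives
    with no inconsistency.  Biology point: curated support flag.
    """
    selection = False
    if row.moi == "recessive":
        selection = True
    elif row.moi == "dominant":
        if row.variant_class == "high" and row.pli is not None and row.pli > 0.9:
            selection = True
        if row.variant_class == "moderate" and row.z is not None and row.z > 2:
            selection = True
    coseg = row.coseg_relatives >= 3 and row.coseg_consistent
    return int(selection) + int(coseg) + int(row.biology_support)


def fdr_upper_bound(n_significant: int, n_documented: int, ndigits: int = 1) -> float:
    """Percentage of significant associations lacking prior documentation."""
    if n_significant <= 0:
        raise ValueError("need a positive number of significant associations")
    return round(100 * (n_significant - n_documented) / n_significant, ndigits)


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> float:
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    value = 100 * numerator / denominator
    return round(value) if ndigits == 0 else round(value, ndigits)
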