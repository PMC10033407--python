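"""Rarity scoring against population allele-count references and prefilters.

The probabilistic minor allele frequency (PMAF) score is an ordinal 0-3
summary of how confidently a variant can be called rare given reference
allele counts (gnomAD-like).  One-sided binomial tests are evaluated per
population against target frequencies t = 0.001 and t = 0.0001 at a 0.05
significance level:

* score 0 -- null rejected at t = 0.001 in any population, total allele
  count at least two (almost surely not rare);
* score 1 -- null rejected at t = 0.0001 in any population;
* score 2 -- neither null rejected;
* score 3 -- absent from the reference altogether.

On the non-pseudoautosomal region of chromosome X only male allele counts
are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import binom

__all__ = [
    "PopulationCounts",
    "rarity_test",
    "pmaf_score",
    "depth_pass_rate",
    "tabulate_common",
    "internal_af_filter",
    "load_population_counts",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05
PMAF_THRESHOLDS = (0.001, 0.0001)


@dataclass(frozen=True)
class PopulationCounts:
    """Reference allele counts for one population.

    ``ac_male``/``an_male`` are only consulted for non-PAR chromosome X
    variants, where female counts would dilute the hemizygous signal.
    """

    population: str
    ac: int
    an: int
    ac_male: int | None = None
    an_male: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.ac <= self.an:
            raise ValueError(f"ac={self.ac} outside [0, an={self.an}]")
        if self.ac_male is not None and self.an_male is not None:
            if self.ac_male > self.ac or self.an_male > self.an:
                raise ValueError("male counts exceed totals")


def rarity_test(ac: int, an: int, t: float) -> float:
    """Upper-tail binomial p-value P(X >= ac | n=an, p=t).

    ``ac = 0`` or ``an = 0`` carry no evidence against rarity and return 1.
    """
    if not 0 <= ac <= an:
        raise ValueError(f"ac={ac} outside [0, an={an}]")
    if ac == 0:
        return 1.0
    if an == 0:
        logger.warning("rarity test with an=0: returning p=1")
        return 1.0
    return float(binom.sf(ac - 1, an, t))


def pmaf_score(counts: Sequence[PopulationCounts], chrx_nonpar: bool = False) -> int:
    """Ordinal rarity score in {0, 1, 2, 3}; see module docstring."""
    pairs = []
    for c in counts:
        if chrx_nonpar:
            if c.ac_male is None or c.an_male is None:
                logger.warning(
                    "no male counts for population %s on non-PAR chrX; skipping",
                    c.population,
                )
                continue
            pairs.append((c.ac_male, c.an_male))
        else:
            pairs.append((c.ac, c.an))
    total_ac = sum(ac for ac, _ in pairs)
    if not pairs or total_ac == 0:
        return 3
    rejected_common = any(
        rarity_test(ac, an, PMAF_THRESHOLDS[0]) < ALPHA for ac, an in pairs
    )
    if rejected_common and total_ac >= 2:
        return 0
    if any(rarity_test(ac, an, PMAF_THRESHOLDS[1]) < ALPHA for ac, an in pairs):
        return 1
    return 2


def depth_pass_rate(
    gvcf_records: Sequence[Sequence[tuple[int, int, bool]]],
    positions: Iterable[int],
) -> dict[int, float]:
    """Per-position fraction of sampled gVCFs whose covering record passes.

    Each sample contributes a list of ``(start, end, passes)`` records with
    1-based inclusive spans.  Positions with no covering record in a sample
    count as failing for that sample.
    """
    samples = list(gvcf_records)
    if not samples:
        raise ValueError("empty gVCF subsample")
    out: dict[int, float] = {}
    for pos in positions:
        n_pass = 0
        for records in samples:
            covering = [ok for start, end, ok in records if start <= pos <= end]
            if covering and all(covering):
                n_pass += 1
        out[pos] = n_pass / len(samples)
    return out


def tabulate_common(
    subsample_counts: Mapping[int, tuple[int, int]],
    maf: float = 0.01,
    alpha: float = 1e-6,
) -> set[int]:
    """Variant ids statistically almost certain to be common.

    Flags ids where a one-sided binomial test of the subsample allele count
    against MAF ``maf`` is rejected at level ``alpha``.
    """
    return {
        vid
        for vid, (ac, an) in subsample_counts.items()
        if rarity_test(ac, an, maf) < alpha
    }


def internal_af_filter(
    genotypes: pd.DataFrame,
    n_samples: int,
    threshold: float = 0.002,
    ploidy: int = 2,
) -> set[int]:
    """Variant ids whose within-cohort MAF is >= ``threshold``.

    ``genotypes`` needs columns ``rsvr_id`` and ``allele_count`` (one row
    per non-reference call).  Variants strictly below the threshold are
    retained; the returned set is to be deleted.
    """
    if genotypes.empty:
        return set()
    total_alleles = n_samples * ploidy
    acs = genotypes.groupby("rsvr_id")["allele_count"].sum()
    return set(acs.index[acs / total_alleles >= threshold].astype(int))


def load_population_counts(path: str) -> dict[int, list[PopulationCounts]]:
    """Read a tab-delimited allele-count reference keyed by RSVR ID.

    Expected columns: rsvr_id, population, ac, an and optionally ac_male,
    an_male.
    """
    df = pd.read_csv(path, sep="\t")
    out: dict[int, list[PopulationCounts]] = {}
    has_male = "ac_male" in df.columns and "an_male" in df.columns
    for row in df.itertuples(index=False):
        out.setdefault(int(row.rsvr_id), []).append(
            PopulationCounts(
                population=str(row.population),
                ac=int(row.ac),
                an=int(row.an),
                ac_male=int(row.ac_male) if has_male and pd.notna(row.ac_male) else None,
                an_male=int(row.an_male) if has_male and pd.notna(row.an_male) else None,
            )
        )
    return out
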