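"""Bayesian gene x case-set association with latent variant pathogenicity.

Seven models are compared: a baseline model of no association (prior 0.99)
and six association models crossing a mode of inheritance (dominant or
recessive) with a class of etiological variant (high impact, moderate
impact or 5' UTR).  Under an association model each qualifying rare variant
carries a latent pathogenicity indicator z_j with an exchangeable
beta-Bernoulli prior; an individual has a *pathogenic configuration* when
their pathogenic allele count reaches 1 (dominant) or their ploidy
(recessive).  Case status is modelled with two conjugate beta-binomial
strata -- probability of being a case tau0 without a pathogenic
configuration and tau1 with one -- so the marginal likelihood given z is
available in closed form and the model evidence is a sum over z.

The sum is exact for J <= ``max_enumeration`` variants and otherwise
estimated by Monte Carlo sampling of z from its prior (with a recorded
seed and standard error).  The posterior probability of association (PPA)
is the total posterior mass on the six association models; the modal
association model fixes the inferred MOI and variant class, and per-variant
pathogenicity posteriors are reported conditional on it.

The tau0 ~ Beta(1, 9), tau1 ~ Beta(4, 2) defaults are documented package
substitutes for the reference implementation's hyperparameters and are
configurable through :class:`RiskPrior`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, logsumexp

from rsvr.codec import meets_impact

__all__ = [
    "ModelSpec",
    "RiskPrior",
    "AssociationInput",
    "Estimator",
    "AssociationResult",
    "default_model_specs",
    "select_analysis_cohort",
    "qualifying_variants",
    "model_evidence",
    "variant_pathogenicity",
    "compute_ppa",
    "run_association",
]

#: prior probabilities of the seven default models; association mass 0.01
BASELINE_PRIOR = 0.99
MAIN_CLASS_PRIOR = 0.002475
UTR5_PRIOR = 0.00005

#: latent pathogenicity priors: Beta(3,1) for high impact (prior mean 75%),
#: Beta(2,8) for moderate impact and 5' UTR (prior mean 20%)
HIGH_PATHOGENICITY_PRIOR = (3.0, 1.0)
OTHER_PATHOGENICITY_PRIOR = (2.0, 8.0)

MIN_MEDIAN_GQ = 35
MIN_SNV_CADD = 10.0


@dataclass(frozen=True)
class ModelSpec:
    """One of the prior-weighted models under comparison."""

    kind: str  # "baseline" | "association"
    prior_prob: float
    moi: str | None = None  # "dominant" | "recessive"
    variant_class: str | None = None  # "high" | "moderate" | "utr5"
    pmaf_min: int = 0
    pathogenicity_prior: tuple[float, float] = OTHER_PATHOGENICITY_PRIOR

    def __post_init__(self) -> None:
        if self.kind not in {"baseline", "association"}:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "association":
            if self.moi not in {"dominant", "recessive"}:
                raise ValueError(f"unknown MOI {self.moi!r}")
            if self.variant_class not in {"high", "moderate", "utr5"}:
                raise ValueError(f"unknown variant class {self.variant_class!r}")

    @property
    def label(self) -> str:
        if self.kind == "baseline":
            return "baseline"
        return f"{self.moi}_{self.variant_class}"


def default_model_specs() -> tuple[ModelSpec, ...]:
    """The seven default models.

    Dominant models require PMAF >= 2 (target MAF < 0.01%) because dominant
    variants are under stronger negative selection; recessive models use
    PMAF >= 1 (target MAF < 0.1%).  The order below is also the
    deterministic tie-break order for the modal model.
    """
    specs = [ModelSpec(kind="baseline", prior_prob=BASELINE_PRIOR)]
    for moi, pmaf_min in (("dominant", 2), ("recessive", 1)):
        for vclass in ("high", "moderate", "utr5"):
            specs.append(
                ModelSpec(
                    kind="association",
                    prior_prob=UTR5_PRIOR if vclass == "utr5" else MAIN_CLASS_PRIOR,
                    moi=moi,
                    variant_class=vclass,
                    pmaf_min=pmaf_min,
                    pathogenicity_prior=(
                        HIGH_PATHOGENICITY_PRIOR
                        if vclass == "high"
                        else OTHER_PATHOGENICITY_PRIOR
                    ),
                )
            )
    return tuple(specs)


@dataclass(frozen=True)
class RiskPrior:
    """Beta priors on case probability without (tau0) and with (tau1) a
    pathogenic configuration of alleles."""

    tau0: tuple[float, float] = (1.0, 9.0)
    tau1: tuple[float, float] = (4.0, 2.0)

    def __post_init__(self) -> None:
        for pair in (self.tau0, self.tau1):
            if min(pair) <= 0:
                raise ValueError("Beta parameters must be positive")


@dataclass
class AssociationInput:
    """Genotypes of qualifying variants for a selected unrelated cohort.

    ``G`` is an individuals x variants allele-count matrix with entries
    0/1/2 (1 for hemizygous carriers), ``y`` the case indicator and
    ``ploidy`` per-individual (2, or 1 for male non-PAR chrX).
    """

    G: np.ndarray
    y: np.ndarray
    ploidy: np.ndarray | None = None
    variant_ids: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G)
        self.y = np.asarray(self.y, dtype=bool)
        if self.G.ndim != 2 or self.G.shape[0] != self.y.shape[0]:
            raise ValueError("G rows must align with y")
        if self.ploidy is None:
            self.ploidy = np.full(self.y.shape[0], 2, dtype=int)
        else:
            self.ploidy = np.asarray(self.ploidy, dtype=int)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def J(self) -> int:
        return self.G.shape[1]


@dataclass(frozen=True)
class Estimator:
    method: str  # "exact_enumeration" | "monte_carlo"
    draws: int = 0
    seed: int | None = None
    std_error: float = 0.0


@dataclass
class AssociationResult:
    ppa: float
    posteriors: dict[str, float]
    modal_model: ModelSpec | None
    variant_pathogenicity: dict[int, float] = field(default_factory=dict)
    log_evidence: dict[str, float] = field(default_factory=dict)
    estimator: Estimator | None = None


# ---------------------------------------------------------------------------
# cohort and variant selection


def select_analysis_cohort(
    case_set: set[str],
    family_of: Mapping[str, str],
    unrelated: set[str],
    explained_gene: Mapping[str, str] | None = None,
    gene: str | None = None,
) -> tuple[list[str], list[str]]:
    """One case per case-set pedigree; unrelated controls from other pedigrees.

    Cases explained by variants in a different gene are reassigned to the
    control group to boost power.
    """
    if not case_set:
        raise ValueError("empty case set")
    explained_gene = explained_gene or {}
    reassigned = {
        s
        for s in case_set
        if s in explained_gene and gene is not None and explained_gene[s] != gene
    }
    eligible = case_set - reassigned
    by_family: dict[str, list[str]] = {}
    for s in sorted(eligible):
        by_family.setdefault(family_of[s], []).append(s)
    cases = [members[0] for members in by_family.values()]
    case_families = {family_of[s] for s in eligible}
    controls = sorted(
        s
        for s in family_of
        if s not in case_set and family_of[s] not in case_families and s in unrelated
    )
    controls += sorted(reassigned)
    return sorted(cases), controls


def qualifying_variants(variants: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Filter a gene's variant table down to the columns a model uses.

    Expected columns: rsvr_id, csq (bitmask), pmaf, median_gq, is_snv,
    cadd (nullable), loftee (nullable).  Rules: impact-class membership,
    PMAF >= spec.pmaf_min, median GQ >= 35, SNVs need CADD >= 10 when a
    score is available, and low-confidence LOFTEE calls are excluded from
    the high-impact class.
    """
    if spec.kind == "baseline":
        return variants.iloc[0:0]
    keep = variants["csq"].map(lambda m: meets_impact(int(m), spec.variant_class))
    keep &= variants["pmaf"] >= spec.pmaf_min
    if "median_gq" in variants.columns:
        keep &= variants["median_gq"] >= MIN_MEDIAN_GQ
    if "cadd" in variants.columns:
        cadd = pd.to_numeric(variants["cadd"], errors="coerce")
        keep &= ~(variants.get("is_snv", False) & cadd.notna() & (cadd < MIN_SNV_CADD))
    if spec.variant_class == "high" and "loftee" in variants.columns:
        keep &= variants["loftee"].fillna("") != "low_confidence"
    return variants.loc[keep].sort_values("rsvr_id")


# ---------------------------------------------------------------------------
# evidence computation


def _log_ml_y(k1: np.ndarray, n1: np.ndarray, k: int, n: int, risk: RiskPrior):
    """Log marginal likelihood of y given pathogenic-configuration strata.

    ``n1``/``k1`` are the sizes and case counts of the x=1 stratum (may be
    vectors over z-configurations); the x=0 stratum holds the rest.
    """
    a0, b0 = risk.tau0
    a1, b1 = risk.tau1
    k0 = k - k1
    n0 = n - n1
    return (
        betaln(a0 + k0, b0 + (n0 - k0))
        - betaln(a0, b0)
        + betaln(a1 + k1, b1 + (n1 - k1))
        - betaln(a1, b1)
    )


def _pathogenic_config(G: np.ndarray, ploidy: np.ndarray, Z: np.ndarray, moi: str):
    """Boolean matrix X[i, m]: does individual i have a pathogenic
    configuration under z-vector m?"""
    if moi == "dominant":
        return (G > 0) @ Z.T >= 1
    return G @ Z.T >= ploidy[:, None]


def baseline_log_evidence(y: np.ndarray, risk: RiskPrior) -> float:
    """Evidence with no pathogenic configurations (x identically 0)."""
    k, n = int(np.sum(y)), int(y.shape[0])
    return float(_log_ml_y(np.array(0), np.array(0), k, n, risk))


def model_evidence(
    inp: AssociationInput,
    spec: ModelSpec,
    risk: RiskPrior = RiskPrior(),
    max_enumeration: int = 12,
    mc_draws: int = 20_000,
    seed: int = 0,
) -> tuple[float, Estimator, dict[int, float]]:
    """Log evidence of one model, estimator metadata and per-variant
    pathogenicity posteriors under that model.

    Exact enumeration over all 2^J latent pathogenicity vectors when
    J <= ``max_enumeration``; Monte-Carlo sampling of z from its
    beta-Bernoulli prior beyond.
    """
    y = inp.y
    k, n = int(np.sum(y)), inp.n
    if spec.kind == "baseline" or inp.J == 0:
        return baseline_log_evidence(y, risk), Estimator("exact_enumeration"), {}

    a, b = spec.pathogenicity_prior
    J = inp.J
    # individuals with no qualifying alleles never reach a pathogenic
    # configuration; collapse them into fixed stratum counts
    carrier = np.asarray(inp.G).sum(axis=1) > 0
    Gc = np.asarray(inp.G)[carrier]
    yc = y[carrier]
    pc = inp.ploidy[carrier]

    if J <= max_enumeration:
        m = 1 << J
        Z = (np.arange(m)[:, None] >> np.arange(J)) & 1
        X = _pathogenic_config(Gc, pc, Z, spec.moi)
        n1 = X.sum(axis=0)
        k1 = (X & yc[:, None]).sum(axis=0)
        log_ml = _log_ml_y(k1, n1, k, n, risk)
        sizes = Z.sum(axis=1)
        log_pz = betaln(a + sizes, b + J - sizes) - betaln(a, b)
        log_terms = log_pz + log_ml
        log_evidence = float(logsumexp(log_terms))
        w = np.exp(log_terms - log_evidence)
        post = w @ Z
        est = Estimator("exact_enumeration")
    else:
        rng = np.random.default_rng(seed)
        p = rng.beta(a, b, size=mc_draws)
        Z = (rng.random((mc_draws, J)) < p[:, None]).astype(np.int8)
        X = _pathogenic_config(Gc, pc, Z, spec.moi)
        n1 = X.sum(axis=0)
        k1 = (X & yc[:, None]).sum(axis=0)
        log_ml = _log_ml_y(k1, n1, k, n, risk)
        log_evidence = float(logsumexp(log_ml) - np.log(mc_draws))
        ml = np.exp(log_ml - log_ml.max())
        se = float(np.std(ml, ddof=1) / np.sqrt(mc_draws) / np.mean(ml))
        w = ml / ml.sum()
        post = w @ Z
        est = Estimator("monte_carlo", draws=mc_draws, seed=seed, std_error=se)
    if not np.isfinite(log_evidence):
        raise FloatingPointError(
            f"non-finite evidence for model {spec.label} (n={n}, J={J})"
        )
    ids = inp.variant_ids if inp.variant_ids is not None else range(J)
    return log_evidence, est, {int(i): float(q) for i, q in zip(ids, post)}


def variant_pathogenicity(
    inp: AssociationInput,
    spec: ModelSpec,
    risk: RiskPrior = RiskPrior(),
    **kwargs,
) -> dict[int, float]:
    """P(z_j = 1 | data, model) for each qualifying variant."""
    _, _, post = model_evidence(inp, spec, risk, **kwargs)
    return post


def compute_ppa(
    log_evidence: Mapping[str, float], specs: Sequence[ModelSpec]
) -> tuple[float, dict[str, float], ModelSpec | None]:
    """Posterior model probabilities from log evidences and model priors.

    Returns (PPA, per-model posteriors, modal association model).  Ties in
    the modal-model argmax break by the fixed order of ``specs``.
    """
    labels = [s.label for s in specs]
    missing = set(labels) - set(log_evidence)
    if missing:
        raise ValueError(f"missing evidences for models: {sorted(missing)}")
    log_post = np.array(
        [np.log(s.prior_prob) + log_evidence[s.label] for s in specs]
    )
    log_post -= logsumexp(log_post)
    post = np.exp(log_post)
    posteriors = dict(zip(labels, map(float, post)))
    assoc = [(i, s) for i, s in enumerate(specs) if s.kind == "association"]
    ppa = float(sum(post[i] for i, _ in assoc))
    modal = max(assoc, key=lambda t: (post[t[0]], -t[0]))[1] if assoc else None
    return ppa, posteriors, modal


def run_association(
    variant_table: pd.DataFrame,
    genotypes: Mapping[int, Mapping[str, int]],
    cases: Sequence[str],
    controls: Sequence[str],
    specs: Sequence[ModelSpec] | None = None,
    risk: RiskPrior = RiskPrior(),
    ploidy: Mapping[str, int] | None = None,
    max_enumeration: int = 12,
    mc_draws: int = 20_000,
    seed: int = 0,
) -> AssociationResult:
    """Full model comparison for one gene x case-set pair.

    ``genotypes`` maps rsvr_id -> {sample_id: allele_count} for the gene's
    variants; samples absent from a mapping are homozygous reference.
    """
    specs = tuple(specs) if specs is not None else default_model_specs()
    samples = list(cases) + list(controls)
    y = np.zeros(len(samples), dtype=bool)
    y[: len(cases)] = True
    pl = np.array([2 if ploidy is None else ploidy.get(s, 2) for s in samples])

    log_evidence: dict[str, float] = {}
    per_model_paths: dict[str, dict[int, float]] = {}
    estimator = None
    sample_pos = {s: i for i, s in enumerate(samples)}
    for spec in specs:
        qv = qualifying_variants(variant_table, spec)
        ids = [int(v) for v in qv["rsvr_id"]]
        G = np.zeros((len(samples), len(ids)), dtype=np.int8)
        for j, vid in enumerate(ids):
            for s, c in genotypes.get(vid, {}).items():
                i = sample_pos.get(s)
                if i is not None:
                    G[i, j] = min(int(c), 2)
        inp = AssociationInput(G=G, y=y, ploidy=pl, variant_ids=ids)
        ev, est, post = model_evidence(
            inp, spec, risk, max_enumeration=max_enumeration, mc_draws=mc_draws, seed=seed
        )
        log_evidence[spec.label] = ev
        per_model_paths[spec.label] = post
        if spec.kind == "association" and estimator is None:
            estimator = est

    ppa, posteriors, modal = compute_ppa(log_evidence, specs)
    return AssociationResult(
        ppa=ppa,
        posteriors=posteriors,
        modal_model=modal,
        variant_pathogenicity=per_model_paths.get(modal.label, {}) if modal else {},
        log_evidence=log_evidence,
        estimator=estimator,
    )


def associate_matrix(
    G: np.ndarray,
    y: np.ndarray,
    variant_classes: Sequence[str],
    specs: Sequence[ModelSpec] | None = None,
    risk: RiskPrior = RiskPrior(),
    seed: int = 0,
    mc_draws: int = 20_000,
) -> AssociationResult:
    """Model comparison straight from a genotype matrix.

    ``variant_classes`` gives the impact class ("high", "moderate" or
    "utr5") of each column; columns are assumed to have already passed the
    rarity and quality filters (PMAF 3, adequate GQ).
    """
    from rsvr.codec import encode_csq

    class_terms = {
        "high": {"stop_gained"},
        "moderate": {"missense_variant"},
        "utr5": {"5_prime_UTR_variant"},
    }
    G = np.asarray(G)
    if G.shape[1] != len(variant_classes):
        raise ValueError("one class per variant column required")
    table = pd.DataFrame(
        {
            "rsvr_id": range(G.shape[1]),
            "csq": [encode_csq(class_terms[c]) for c in variant_classes],
            "pmaf": 3,
            "median_gq": 99.0,
            "is_snv": False,
            "cadd": None,
            "loftee": None,
        }
    )
    samples = [f"s{i}" for i in range(G.shape[0])]
    genotypes = {
        j: {samples[i]: int(G[i, j]) for i in np.flatnonzero(G[:, j])}
        for j in range(G.shape[1])
    }
    y = np.asarray(y, dtype=bool)
    cases = [samples[i] for i in np.flatnonzero(y)]
    controls = [samples[i] for i in np.flatnonzero(~y)]
    return run_association(
        table, genotypes, cases, controls, specs, risk, seed=seed, mc_draws=mc_draws
    )


def gene_variant_table(conn, gene: str) -> pd.DataFrame:
    """Per-variant table for a gene, collapsing transcripts.

    Consequence masks are OR-ed over the gene's transcripts and a
    low-confidence LOFTEE call on any transcript marks the variant.
    """
    from rsvr.reservoir import query_gene_variants

    rows = query_gene_variants(conn, gene)
    if rows.empty:
        return pd.DataFrame(
            columns=["rsvr_id", "csq", "pmaf", "median_gq", "is_snv", "cadd", "loftee"]
        )
    agg = (
        rows.groupby("rsvr_id")
        .agg(
            csq=("csq", lambda s: int(np.bitwise_or.reduce(s.astype(np.int64)))),
            pmaf=("pmaf", "first"),
            median_gq=("median_gq", "first"),
            is_snv=("is_snv", "first"),
            cadd=("cadd", "first"),
            loftee=(
                "loftee",
                lambda s: "low_confidence" if (s == "low_confidence").any() else None,
            ),
        )
        .reset_index()
    )
    agg["median_gq"] = agg["median_gq"].fillna(99.0)
    agg["is_snv"] = agg["is_snv"].astype(bool)
    return agg


def associate_gene_db(
    conn,
    gene: str,
    case_set: str,
    specs: Sequence[ModelSpec] | None = None,
    risk: RiskPrior = RiskPrior(),
    seed: int = 0,
    mc_draws: int = 20_000,
    explained_gene: Mapping[str, str] | None = None,
) -> AssociationResult:
    """Run the full model comparison for one gene against a stored case set."""
    from rsvr.reservoir import gene_genotypes

    members = {
        row[0]
        for row in conn.execute(
            "SELECT sample_id FROM CASE_SET WHERE name = ?", (case_set,)
        )
    }
    if not members:
        raise KeyError(f"unknown or empty case set {case_set!r}")
    family_of = {}
    unrelated = set()
    for sample, family, flag in conn.execute(
        "SELECT sample_id, family_id, unrelated FROM SAMPLE"
    ):
        family_of[sample] = family
        if flag:
            unrelated.add(sample)
    cases, controls = select_analysis_cohort(
        members & set(family_of), family_of, unrelated, explained_gene, gene
    )
    table = gene_variant_table(conn, gene)
    genotypes = gene_genotypes(conn, [int(v) for v in table["rsvr_id"]])
    return run_association(
        table, genotypes, cases, controls, specs, risk, seed=seed, mc_draws=mc_draws
    )
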