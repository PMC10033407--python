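"""Association engine tests, anchored on an independent brute-force oracle.

The oracle integrates tau0 and tau1 numerically (adaptive quadrature over
the Beta priors) and enumerates latent pathogenicity vectors explicitly
with itertools, sharing no code with the closed-form beta-binomial path it
checks.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from rsvr.association import (
    AssociationInput,
    Estimator,
    ModelSpec,
    RiskPrior,
    baseline_log_evidence,
    compute_ppa,
    default_model_specs,
    model_evidence,
    qualifying_variants,
    run_association,
    select_analysis_cohort,
    variant_pathogenicity,
)
from rsvr.codec import encode_csq


def beta_pdf(x, a, b):
    return x ** (a - 1) * (1 - x) ** (b - 1) / (math.gamma(a) * math.gamma(b) / math.gamma(a + b))


def ml_stratum_oracle(k, n, a, b):
    """Integrate t^k (1-t)^(n-k) against the Beta(a,b) prior numerically."""
    val, _ = quad(lambda t: t**k * (1 - t) ** (n - k) * beta_pdf(t, a, b), 0, 1)
    return val


def pz_oracle(size, J, a, b):
    val, _ = quad(lambda p: p**size * (1 - p) ** (J - size) * beta_pdf(p, a, b), 0, 1)
    return val


def evidence_oracle(G, y, ploidy, moi, path_prior, risk):
    """Brute-force model evidence: explicit z-enumeration + quadrature."""
    n, J = G.shape
    k = int(sum(y))
    total = 0.0
    for z in itertools.product([0, 1], repeat=J):
        if moi == "dominant":
            x = [any(z[j] and G[i, j] > 0 for j in range(J)) for i in range(n)]
        else:
            x = [
                sum(z[j] * G[i, j] for j in range(J)) >= ploidy[i] for i in range(n)
            ]
        n1 = sum(x)
        k1 = sum(1 for i in range(n) if x[i] and y[i])
        ml = ml_stratum_oracle(k - k1, n - n1, *risk.tau0) * ml_stratum_oracle(
            k1, n1, *risk.tau1
        )
        total += pz_oracle(sum(z), J, *path_prior) * ml
    return math.log(total)


def random_instance(rng, n_max=20, j_max=10):
    n = int(rng.integers(4, n_max + 1))
    J = int(rng.integers(1, j_max + 1))
    G = rng.choice([0, 0, 0, 1, 2], size=(n, J)).astype(np.int8)
    y = rng.random(n) < 0.4
    ploidy = rng.choice([1, 2], size=n, p=[0.1, 0.9])
    return G, y, ploidy


class TestDefaultSpecs:
    def test_prior_mass(self):
        specs = default_model_specs()
        assert len(specs) == 7
        total = sum(s.prior_prob for s in specs)
        assoc = sum(s.prior_prob for s in specs if s.kind == "association")
        assert total == pytest.approx(1.0, abs=1e-12)
        assert assoc == pytest.approx(0.01, abs=1e-12)

    def test_pmaf_thresholds(self):
        for s in default_model_specs():
            if s.kind == "association":
                assert s.pmaf_min == (2 if s.moi == "dominant" else 1)

    def test_pathogenicity_priors(self):
        for s in default_model_specs():
            if s.kind != "association":
                continue
            expected = (3.0, 1.0) if s.variant_class == "high" else (2.0, 8.0)
            assert s.pathogenicity_prior == expected

    def test_equal_dominant_recessive_mass(self):
        specs = default_model_specs()
        dom = sum(s.prior_prob for s in specs if s.moi == "dominant")
        rec = sum(s.prior_prob for s in specs if s.moi == "recessive")
        assert dom == pytest.approx(rec)


class TestModelEvidence:
    def spec(self, moi="dominant", vclass="moderate"):
        return ModelSpec(
            kind="association",
            prior_prob=0.002475,
            moi=moi,
            variant_class=vclass,
            pmaf_min=1,
            pathogenicity_prior=(3.0, 1.0) if vclass == "high" else (2.0, 8.0),
        )

    def test_j_zero_equals_baseline(self):
        y = np.array([1, 1, 0, 0, 0], dtype=bool)
        inp = AssociationInput(G=np.zeros((5, 0)), y=y)
        risk = RiskPrior()
        ev, est, post = model_evidence(inp, self.spec(), risk)
        assert ev == pytest.approx(baseline_log_evidence(y, risk))
        assert est.method == "exact_enumeration"
        assert post == {}

    def test_toy_matches_oracle(self):
        G = np.array([[1, 0], [0, 1], [0, 0], [1, 0], [0, 0], [0, 0]], dtype=np.int8)
        y = np.array([1, 1, 0, 1, 0, 0], dtype=bool)
        ploidy = np.full(6, 2)
        risk = RiskPrior()
        spec = self.spec()
        inp = AssociationInput(G=G, y=y, ploidy=ploidy)
        ev, _, _ = model_evidence(inp, spec, risk)
        expected = evidence_oracle(G, y, ploidy, "dominant", spec.pathogenicity_prior, risk)
        assert ev == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("moi", ["dominant", "recessive"])
    def test_random_instances_match_oracle(self, moi, rng):
        risk = RiskPrior()
        spec = self.spec(moi=moi)
        for _ in range(10):
            G, y, ploidy = random_instance(rng, n_max=12, j_max=6)
            inp = AssociationInput(G=G, y=y, ploidy=ploidy)
            ev, _, _ = model_evidence(inp, spec, risk)
            expected = evidence_oracle(G, y, ploidy, moi, spec.pathogenicity_prior, risk)
            assert abs(ev - expected) / abs(expected) < 1e-4

    def test_monte_carlo_close_to_exact(self, rng):
        G, y, ploidy = random_instance(rng, n_max=20, j_max=8)
        while G.shape[1] < 8:
            G, y, ploidy = random_instance(rng, n_max=20, j_max=8)
        risk = RiskPrior()
        spec = self.spec()
        inp = AssociationInput(G=G, y=y, ploidy=ploidy)
        exact, _, _ = model_evidence(inp, spec, risk, max_enumeration=12)
        mc, est, _ = model_evidence(
            inp, spec, risk, max_enumeration=4, mc_draws=40_000, seed=7
        )
        assert est.method == "monte_carlo"
        assert est.seed == 7 and est.std_error > 0
        assert abs(math.exp(mc - exact) - 1) < 3 * est.std_error

    def test_hemizygous_recessive(self):
        # single pathogenic allele suffices at ploidy 1
        G = np.array([[1], [1], [0], [0]], dtype=np.int8)
        y = np.array([1, 0, 1, 0], dtype=bool)
        risk = RiskPrior()
        spec = self.spec(moi="recessive")
        hemi = model_evidence(
            AssociationInput(G=G, y=y, ploidy=np.array([1, 1, 2, 2])), spec, risk
        )[0]
        expected = evidence_oracle(G, y, [1, 1, 2, 2], "recessive", spec.pathogenicity_prior, risk)
        assert hemi == pytest.approx(expected, abs=1e-6)


class TestVariantPathogenicity:
    def spec(self):
        return ModelSpec(
            kind="association",
            prior_prob=0.002475,
            moi="dominant",
            variant_class="high",
            pmaf_min=2,
            pathogenicity_prior=(3.0, 1.0),
        )

    def test_case_only_variant_above_prior_mean(self):
        G = np.array([[1], [1], [0], [0], [0], [0]], dtype=np.int8)
        y = np.array([1, 1, 0, 0, 0, 0], dtype=bool)
        post = variant_pathogenicity(AssociationInput(G=G, y=y), self.spec())
        assert post[0] > 3 / 4

    def test_uncarried_variant_returns_prior_mean(self):
        G = np.zeros((6, 1), dtype=np.int8)
        y = np.array([1, 1, 0, 0, 0, 0], dtype=bool)
        post = variant_pathogenicity(AssociationInput(G=G, y=y), self.spec())
        assert post[0] == pytest.approx(3 / 4, abs=1e-12)

    def test_bounded(self, rng):
        for _ in range(5):
            G, y, ploidy = random_instance(rng, n_max=15, j_max=5)
            post = variant_pathogenicity(
                AssociationInput(G=G, y=y, ploidy=ploidy), self.spec()
            )
            assert all(0.0 <= p <= 1.0 for p in post.values())


class TestComputePpa:
    def test_equal_evidence_returns_prior(self):
        specs = default_model_specs()
        ev = {s.label: -5.0 for s in specs}
        ppa, posteriors, modal = compute_ppa(ev, specs)
        assert ppa == pytest.approx(0.01, abs=1e-12)
        assert sum(posteriors.values()) == pytest.approx(1.0, abs=1e-12)

    def test_dominated_baseline(self):
        specs = default_model_specs()
        ev = {s.label: -1e6 for s in specs}
        ev["dominant_high"] = 0.0
        ppa, _, modal = compute_ppa(ev, specs)
        assert ppa == pytest.approx(1.0)
        assert modal.label == "dominant_high"

    def test_tie_breaks_by_model_order(self):
        specs = default_model_specs()
        ev = {s.label: 0.0 for s in specs}
        _, _, modal = compute_ppa(ev, specs)
        # equal posteriors among same-prior models: dominant_high comes first
        assert modal.label == "dominant_high"

    def test_missing_evidence_raises(self):
        specs = default_model_specs()
        with pytest.raises(ValueError):
            compute_ppa({"baseline": 0.0}, specs)

    def test_posterior_normalization_random(self, rng):
        specs = default_model_specs()
        for _ in range(20):
            ev = {s.label: float(rng.normal(scale=50)) for s in specs}
            _, posteriors, _ = compute_ppa(ev, specs)
            assert sum(posteriors.values()) == pytest.approx(1.0, abs=1e-12)


class TestCohortSelection:
    def test_one_case_per_pedigree(self):
        family_of = {"a1": "f1", "a2": "f1", "b1": "f2", "c1": "f3", "d1": "f4"}
        cases, controls = select_analysis_cohort(
            {"a1", "a2", "b1", "c1"}, family_of, unrelated=set(family_of)
        )
        assert len(cases) == 3
        assert controls == ["d1"]

    def test_explained_case_moved_to_controls(self):
        family_of = {"a1": "f1", "b1": "f2", "d1": "f4"}
        cases, controls = select_analysis_cohort(
            {"a1", "b1"},
            family_of,
            unrelated=set(family_of),
            explained_gene={"b1": "GENE_B"},
            gene="GENE_A",
        )
        assert cases == ["a1"]
        assert "b1" in controls

    def test_relative_of_control_excluded(self):
        family_of = {"a1": "f1", "d1": "f4", "d2": "f4"}
        cases, controls = select_analysis_cohort(
            {"a1"}, family_of, unrelated={"a1", "d1"}
        )
        assert controls == ["d1"]

    def test_empty_case_set_raises(self):
        with pytest.raises(ValueError):
            select_analysis_cohort(set(), {}, set())


class TestQualifyingVariants:
    def table(self):
        return pd.DataFrame(
            {
                "rsvr_id": [1, 2, 3, 4, 5, 6],
                "csq": [
                    encode_csq({"stop_gained"}),
                    encode_csq({"stop_gained"}),
                    encode_csq({"missense_variant"}),
                    encode_csq({"missense_variant"}),
                    encode_csq({"frameshift_variant"}),
                    encode_csq({"5_prime_UTR_variant"}),
                ],
                "pmaf": [3, 3, 3, 1, 3, 3],
                "median_gq": [90, 90, 90, 90, 20, 90],
                "is_snv": [True, True, True, True, False, True],
                "cadd": [25.0, 25.0, 5.0, 25.0, None, None],
                "loftee": [None, "low_confidence", None, None, None, None],
            }
        )

    def spec(self, vclass, pmaf_min=2, moi="dominant"):
        return ModelSpec(
            kind="association",
            prior_prob=0.002475,
            moi=moi,
            variant_class=vclass,
            pmaf_min=pmaf_min,
        )

    def test_loftee_low_confidence_excluded_from_high(self):
        ids = set(qualifying_variants(self.table(), self.spec("high"))["rsvr_id"])
        assert 2 not in ids and 1 in ids

    def test_low_cadd_snv_excluded(self):
        ids = set(qualifying_variants(self.table(), self.spec("moderate"))["rsvr_id"])
        assert 3 not in ids

    def test_indel_without_cadd_retained(self):
        # variant 5 is an indel with no CADD but fails median GQ
        table = self.table()
        table.loc[table.rsvr_id == 5, "median_gq"] = 90
        ids = set(qualifying_variants(table, self.spec("moderate"))["rsvr_id"])
        assert 5 in ids

    def test_median_gq_filter(self):
        ids = set(qualifying_variants(self.table(), self.spec("high"))["rsvr_id"])
        assert 5 not in ids

    def test_pmaf_threshold_by_moi(self):
        dom = set(qualifying_variants(self.table(), self.spec("moderate", 2))["rsvr_id"])
        rec = set(qualifying_variants(self.table(), self.spec("moderate", 1, "recessive"))["rsvr_id"])
        assert 4 not in dom and 4 in rec

    def test_baseline_spec_empty(self):
        spec = ModelSpec(kind="baseline", prior_prob=0.99)
        assert qualifying_variants(self.table(), spec).empty


class TestRunAssociation:
    def test_planted_dominant_signal(self, rng):
        # 200 cases / 1800 controls, 3 pathogenic high-impact variants carried
        # by 24 cases and 2 controls
        cases = [f"case{i}" for i in range(200)]
        controls = [f"ctl{i}" for i in range(1800)]
        table = pd.DataFrame(
            {
                "rsvr_id": [101, 102, 103],
                "csq": [encode_csq({"stop_gained"})] * 3,
                "pmaf": [3, 3, 3],
                "median_gq": [90, 90, 90],
                "is_snv": [False, False, False],
                "cadd": [None, None, None],
                "loftee": [None, None, None],
            }
        )
        genotypes = {
            101: {f"case{i}": 1 for i in range(8)},
            102: {f"case{i}": 1 for i in range(8, 16)},
            103: {f"case{i}": 1 for i in range(16, 24)} | {"ctl0": 1, "ctl1": 1},
        }
        result = run_association(table, genotypes, cases, controls, seed=1)
        assert result.ppa > 0.95
        assert result.modal_model.moi == "dominant"
        assert result.modal_model.variant_class == "high"
        assert sum(result.posteriors.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(p > 0.5 for p in result.variant_pathogenicity.values())

    def test_null_returns_near_prior(self, rng):
        cases = [f"case{i}" for i in range(50)]
        controls = [f"ctl{i}" for i in range(500)]
        table = pd.DataFrame(
            {
                "rsvr_id": [7],
                "csq": [encode_csq({"missense_variant"})],
                "pmaf": [3],
                "median_gq": [90],
                "is_snv": [False],
                "cadd": [None],
                "loftee": [None],
            }
        )
        # variant load proportional between cases and controls
        genotypes = {7: {"case0": 1} | {f"ctl{i}": 1 for i in range(10)}}
        result = run_association(table, genotypes, cases, controls, seed=1)
        assert result.ppa < 0.5
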