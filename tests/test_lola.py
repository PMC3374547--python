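import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from claimsdeid import adversary
from claimsdeid.claims_model import Dataset, LEVEL1_QIS, LEVEL2_QIS
from claimsdeid.hierarchy import Hierarchy, apply_node, build_lattice
from claimsdeid.lola import (
    BackgroundKnowledge,
    MatchIndex,
    evaluate_node,
    info_loss_entropy,
    match_count,
    sample_background_knowledge,
    search,
)
from claimsdeid.risk_metrics import RiskParams, equivalence_classes
from claimsdeid.synthetic_data import SynthConfig, generate_population


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _norm(v):
    return None if (v is None or v is pd.NA or (isinstance(v, float) and math.isnan(v))) else v


def brute_force_match(bk: BackgroundKnowledge, ds: Dataset) -> int:
    """Naive reference matcher: nested loops, no shared code paths."""
    count = 0
    for _, prow in ds.patients.iterrows():
        if tuple(_norm(prow[c]) for c in LEVEL1_QIS) != bk.level1:
            continue
        claims = ds.claims[ds.claims["member_id"] == prow["member_id"]]
        ok = True
        for qi, known in bk.level2.items():
            pool = [_norm(v) for v in claims[qi] if _norm(v) is not None]
            for v in known:
                if _norm(v) in pool:
                    pool.remove(_norm(v))
                else:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            count += 1
    return count


def _blueprint_population():
    """120 patients in two big demographic blocks, one constant claim each;
    risk behaviour is exactly the level-1 class structure."""
    rows = []
    crows = []
    i = 0
    for base_age, size in ((20, 60), (30, 60)):
        for j in range(size):
            i += 1
            m = f"B{i:03d}"
            rows.append((m, base_age + j % 5, "M", 0, 0))
            crows.append({
                "member_id": m, "provider_id": "P1", "vendor": "V1", "pcp": "C1",
                "year": "Y1", "specialty": "Internal", "place_of_service": "Office",
                "cpt_code": "99213", "los": 0, "dsfc": 0, "pay_delay": 10,
                "diagnosis": "250.00",
            })
    patients = pd.DataFrame(rows, columns=["member_id", "age", "sex", "dih_y2", "dih_y3"])
    return Dataset(patients, pd.DataFrame(crows), 1.0)


@pytest.fixture(scope="module")
def blueprint_pop():
    return _blueprint_population()


# --------------------------------------------------------------------------
# background knowledge
# --------------------------------------------------------------------------

class TestSampleBackgroundKnowledge:
    def test_single_claim_patient_gets_singletons(self, population):
        prof = adversary.profile(population)
        m = population.claims.groupby("member_id").size().idxmin()
        row = population.patients.set_index("member_id", drop=False).loc[m]
        claims = population.claims_of(m)
        bk = sample_background_knowledge(row, claims, prof, np.random.default_rng(0))
        for qi in LEVEL2_QIS:
            vals = [v for v in claims[qi] if _norm(v) is not None]
            assert len(bk.level2[qi]) == min(prof.power_of(m, qi), len(vals))

    def test_full_knowledge_when_power_covers_claims(self, population):
        prof = adversary.profile(population, p_m=1000)
        # with an unbounded cap, a chronic (single-valued) QI is fully known
        m = population.patients["member_id"].iloc[0]
        row = population.patients.iloc[0]
        claims = population.claims_of(m)
        bk = sample_background_knowledge(row, claims, prof, np.random.default_rng(1))
        for qi in LEVEL2_QIS:
            vals = [v for v in claims[qi] if _norm(v) is not None]
            if len(set(vals)) == 1:
                assert Counter(bk.level2[qi]) == Counter(vals)

    def test_deterministic_under_seed(self, population):
        prof = adversary.profile(population)
        row = population.patients.iloc[3]
        claims = population.claims_of(row["member_id"])
        bk1 = sample_background_knowledge(row, claims, prof, np.random.default_rng(5))
        bk2 = sample_background_knowledge(row, claims, prof, np.random.default_rng(5))
        assert bk1 == bk2


# --------------------------------------------------------------------------
# matching
# --------------------------------------------------------------------------

class TestMatchCount:
    def test_self_match(self, population):
        prof = adversary.profile(population)
        rng = np.random.default_rng(2)
        index = MatchIndex(population)
        for i in range(10):
            row = population.patients.iloc[i]
            claims = population.claims_of(row["member_id"])
            bk = sample_background_knowledge(row, claims, prof, rng)
            assert match_count(bk, index) >= 1

    def test_level1_only_matching(self):
        patients = pd.DataFrame({
            "member_id": ["a", "b", "c", "d"],
            "age": [30, 30, 30, 40], "sex": ["F"] * 4,
            "dih_y2": [0] * 4, "dih_y3": [0] * 4,
        })
        claims = pd.DataFrame(columns=[
            "member_id", "provider_id", "vendor", "pcp", "year", "specialty",
            "place_of_service", "cpt_code", "los", "dsfc", "pay_delay", "diagnosis",
        ])
        ds = Dataset(patients, claims)
        bk = BackgroundKnowledge(level1=(30, "F", 0, 0), level2={})
        assert match_count(bk, ds) == 3

    def test_equals_bruteforce_on_random_draws(self, hierarchies):
        """1,000 random background-knowledge draws against a 50-patient
        dataset: the indexed matcher agrees with naive enumeration."""
        ds = generate_population(SynthConfig(n_patients=50, seed=21, chronic_fraction=0.5))
        lat = build_lattice(hierarchies, ["age", "days_in_hospital", "los", "dsfc"])
        gds = apply_node(ds, lat.node((1, 1, 1, 2)), hierarchies)
        prof = adversary.profile(gds)
        index = MatchIndex(gds)
        rng = np.random.default_rng(3)
        rows = gds.patients.reset_index(drop=True)
        for _ in range(1000):
            row = rows.iloc[int(rng.integers(len(rows)))]
            claims = gds.claims_of(row["member_id"])
            bk = sample_background_knowledge(row, claims, prof, rng)
            assert match_count(bk, index) == brute_force_match(bk, gds)


# --------------------------------------------------------------------------
# node evaluation
# --------------------------------------------------------------------------

class TestEvaluateNode:
    def test_identical_patients_never_high_risk(self, hierarchies, blueprint_pop):
        # at the 5-year age level both blocks collapse to classes of 60 >= k
        lat = build_lattice(hierarchies, ["age", "days_in_hospital"])
        params = RiskParams(alpha=1.0)
        ev = evaluate_node(
            blueprint_pop, lat.node((1, 0)), hierarchies, params,
            iterations=5, patients_per_iteration=None, seed=0,
        )
        assert ev.prop_high_risk == 0.0
        assert ev.acceptable

    def test_unique_patients_all_high_risk(self, hierarchies):
        patients = pd.DataFrame({
            "member_id": [f"u{i}" for i in range(10)],
            "age": range(20, 30), "sex": ["F"] * 10,
            "dih_y2": [0] * 10, "dih_y3": [0] * 10,
        })
        claims = pd.DataFrame(columns=[
            "member_id", "provider_id", "vendor", "pcp", "year", "specialty",
            "place_of_service", "cpt_code", "los", "dsfc", "pay_delay", "diagnosis",
        ])
        ds = Dataset(patients, claims)
        lat = build_lattice(hierarchies, ["age"])
        ev = evaluate_node(
            ds, lat.bottom, hierarchies, RiskParams(alpha=1.0),
            iterations=5, patients_per_iteration=None, seed=0,
        )
        assert ev.prop_high_risk == 1.0

    def test_bootstrap_mean_matches_exact_expectation(self, hierarchies):
        """On a fixture with deterministic background knowledge the exact
        high-risk proportion is enumerable; the bootstrap must agree to
        within 3 standard errors."""
        rows, crows = [], []
        # 8 classes of 5 on level 1; half the patients carry a rarer diagnosis
        i = 0
        for cls in range(8):
            for j in range(5):
                i += 1
                m = f"E{i:02d}"
                rows.append((m, 20 + cls, "M", 0, 0))
                diag = "250.00" if j < 3 else "428.0"
                for _ in range(3):  # 3 claims, single-valued per QI => BK is full
                    crows.append({
                        "member_id": m, "provider_id": "P1", "vendor": "V1",
                        "pcp": "C1", "year": "Y1", "specialty": "Internal",
                        "place_of_service": "Office", "cpt_code": "99213",
                        "los": 0, "dsfc": 0, "pay_delay": 1, "diagnosis": diag,
                    })
        ds = Dataset(
            pd.DataFrame(rows, columns=["member_id", "age", "sex", "dih_y2", "dih_y3"]),
            pd.DataFrame(crows), 1.0,
        )
        params = RiskParams(theta=0.25, f_min=4, alpha=1.0, maxsup=0.5)
        assert params.k == 4
        lat = build_lattice(hierarchies, ["age"])
        # exact: every patient's BK matches exactly its (level1, diagnosis)
        # companions: 3 or 2 < k=4 -> everyone is high risk
        index = MatchIndex(ds)
        prof = adversary.profile(ds)
        exact = 0
        for _, row in ds.patients.iterrows():
            bk = sample_background_knowledge(
                row, ds.claims_of(row["member_id"]), prof, np.random.default_rng(0)
            )
            exact += match_count(bk, index) < params.k
        exact_prop = exact / ds.n_patients
        assert exact_prop == 1.0
        ev = evaluate_node(
            ds, lat.bottom, hierarchies, params,
            iterations=50, patients_per_iteration=40, seed=1,
        )
        se = max(ev.se, 1e-9)
        assert abs(ev.prop_high_risk - exact_prop) <= 3 * se

    def test_partial_high_risk_expectation(self, hierarchies):
        """Mixed fixture: some classes comfortably large, some small; the
        bootstrap mean sits within 3 SE of the enumerated expectation."""
        rows, crows = [], []
        i = 0
        for cls, size in enumerate([6, 6, 2, 2]):  # k=4: only sizes 2 are risky
            for _ in range(size):
                i += 1
                m = f"P{i:02d}"
                rows.append((m, 30 + cls, "F", 0, 0))
                crows.append({
                    "member_id": m, "provider_id": "P1", "vendor": "V1",
                    "pcp": "C1", "year": "Y1", "specialty": "Internal",
                    "place_of_service": "Office", "cpt_code": "99213",
                    "los": 0, "dsfc": 0, "pay_delay": 1, "diagnosis": "250.00",
                })
        ds = Dataset(
            pd.DataFrame(rows, columns=["member_id", "age", "sex", "dih_y2", "dih_y3"]),
            pd.DataFrame(crows), 1.0,
        )
        params = RiskParams(theta=0.25, f_min=4, alpha=1.0, maxsup=0.1)
        lat = build_lattice(hierarchies, ["age"])
        exact_prop = 4 / 16  # the four patients in classes of 2
        ev = evaluate_node(
            ds, lat.bottom, hierarchies, params,
            iterations=60, patients_per_iteration=32, seed=2,
        )
        mc_se = math.sqrt(exact_prop * (1 - exact_prop) / (60 * 32))
        assert abs(ev.prop_high_risk - exact_prop) <= 3 * max(ev.se, mc_se)


# --------------------------------------------------------------------------
# information loss
# --------------------------------------------------------------------------

def _toy_hierarchy(name, col, table="patients"):
    ident = lambda v: v  # noqa: E731
    return Hierarchy(name, (ident, lambda v: "any"), (col,), table)


class TestInfoLoss:
    def _dataset(self, ages):
        patients = pd.DataFrame({
            "member_id": [f"m{i}" for i in range(len(ages))],
            "age": ages, "sex": ["F"] * len(ages),
            "dih_y2": [0] * len(ages), "dih_y3": [0] * len(ages),
        })
        claims = pd.DataFrame(columns=[
            "member_id", "provider_id", "vendor", "pcp", "year", "specialty",
            "place_of_service", "cpt_code", "los", "dsfc", "pay_delay", "diagnosis",
        ])
        return Dataset(patients, claims)

    def test_bottom_node_zero_bits(self, population, hierarchies):
        lat = build_lattice(hierarchies, ["age", "days_in_hospital", "los", "dsfc"])
        out = apply_node(population, lat.bottom, hierarchies)
        assert info_loss_entropy(population, out) == 0.0

    def test_two_pairs_merged_is_four_bits(self):
        ds = self._dataset([20, 20, 30, 30])
        h = {"age": _toy_hierarchy("age", "age")}
        gds = apply_node(ds, build_lattice(h).top, h)
        loss = info_loss_entropy(ds, gds, {"patients": ["age"]})
        assert loss == pytest.approx(4.0)  # 4 records x -log2(2/4)

    def test_constant_column_costs_nothing(self):
        ds = self._dataset([25, 25, 25, 25])
        h = {"age": _toy_hierarchy("age", "age")}
        gds = apply_node(ds, build_lattice(h).top, h)
        assert info_loss_entropy(ds, gds, {"patients": ["age"]}) == 0.0

    def test_monotone_up_the_lattice(self, population, hierarchies):
        lat = build_lattice(hierarchies, ["age", "days_in_hospital"])
        losses = [
            info_loss_entropy(population, apply_node(population, lat.node(l), hierarchies))
            for l in [(0, 0), (1, 0), (2, 0), (3, 0), (3, 1), (3, 2)]
        ]
        assert losses == sorted(losses)


# --------------------------------------------------------------------------
# lattice search
# --------------------------------------------------------------------------

class TestSearch:
    def _search_args(self, hierarchies):
        lat = build_lattice(hierarchies, ["age", "days_in_hospital"])
        params = RiskParams(theta=0.05, f_min=20, alpha=1.0, maxsup=0.008)
        return lat, params

    def test_acceptable_bottom_is_optimal(self, hierarchies):
        # one big class: already releasable untouched
        rows = [(f"m{i}", 30, "F", 0, 0) for i in range(40)]
        patients = pd.DataFrame(rows, columns=["member_id", "age", "sex", "dih_y2", "dih_y3"])
        claims = pd.DataFrame(columns=[
            "member_id", "provider_id", "vendor", "pcp", "year", "specialty",
            "place_of_service", "cpt_code", "los", "dsfc", "pay_delay", "diagnosis",
        ])
        ds = Dataset(patients, claims)
        lat, params = self._search_args(hierarchies)
        res = search(ds, lat, hierarchies, params,
                     iterations=3, patients_per_iteration=None, seed=0)
        assert res.releasable
        assert res.optimal == lat.bottom
        assert res.info_loss[res.optimal] == 0.0

    def test_search_matches_exhaustive_evaluation(self, hierarchies, blueprint_pop):
        """Candidate set and optimum equal brute-force evaluation of every
        node of a 12-node lattice under a common seed."""
        lat, params = self._search_args(hierarchies)
        res = search(blueprint_pop, lat, hierarchies, params,
                     iterations=30, patients_per_iteration=120, seed=7)
        exhaustive = {}
        for node in lat.nodes():
            ev = evaluate_node(blueprint_pop, node, hierarchies, params,
                               iterations=30, patients_per_iteration=120, seed=7)
            exhaustive[node] = ev.acceptable
        expected_candidates = {n for n, ok in exhaustive.items() if ok}
        assert set(res.candidates) == expected_candidates
        losses = {
            n: info_loss_entropy(
                blueprint_pop, apply_node(blueprint_pop, n, hierarchies)
            )
            for n in expected_candidates
        }
        brute_opt = min(expected_candidates, key=lambda n: (losses[n], n.height, n.levels))
        assert res.optimal == brute_opt
        assert res.optimal.level_of("age") == 1  # 5-year bins suffice here

    def test_invariant_to_node_enumeration_order(self, hierarchies, blueprint_pop):
        lat, params = self._search_args(hierarchies)
        kw = dict(iterations=20, patients_per_iteration=120, seed=7)
        res1 = search(blueprint_pop, lat, hierarchies, params, **kw)
        rng = np.random.default_rng(9)
        nodes = lat.nodes()
        rng.shuffle(nodes)
        res2 = search(blueprint_pop, lat, hierarchies, params, node_order=nodes, **kw)
        assert res1.optimal == res2.optimal
        assert set(res1.candidates) == set(res2.candidates)

    def test_estimates_monotone_along_ascending_path_with_common_seed(
        self, hierarchies, blueprint_pop
    ):
        lat, params = self._search_args(hierarchies)
        path = [(0, 0), (1, 0), (2, 0), (3, 0), (3, 1), (3, 2)]
        props = [
            evaluate_node(blueprint_pop, lat.node(l), hierarchies, params,
                          iterations=10, patients_per_iteration=120, seed=3).prop_high_risk
            for l in path
        ]
        assert all(a >= b - 1e-12 for a, b in zip(props, props[1:]))

    def test_no_acceptable_node_reports_cannot_release(self, hierarchies):
        rows = [(f"m{i}", 20 + i, "F", 0, 0) for i in range(8)]
        patients = pd.DataFrame(rows, columns=["member_id", "age", "sex", "dih_y2", "dih_y3"])
        claims = pd.DataFrame(columns=[
            "member_id", "provider_id", "vendor", "pcp", "year", "specialty",
            "place_of_service", "cpt_code", "los", "dsfc", "pay_delay", "diagnosis",
        ])
        ds = Dataset(patients, claims)
        lat, params = self._search_args(hierarchies)  # k=20 > 8 patients
        res = search(ds, lat, hierarchies, params,
                     iterations=2, patients_per_iteration=None, seed=0)
        assert not res.releasable
        assert res.optimal is None
        assert res.candidates == []

    def test_reduces_to_classical_k_anonymity(self, hierarchies):
        """alpha=1 and no claim-level knowledge: the accepted nodes are
        exactly those whose generalized table is (k, maxsup)-anonymous by an
        independent checker."""
        pop = generate_population(SynthConfig(n_patients=150, seed=31))
        params = RiskParams(theta=0.2, f_min=5, alpha=1.0, maxsup=0.05)
        lat = build_lattice(hierarchies, ["age", "days_in_hospital"])
        qi = ["age", "sex", "dih_y2", "dih_y3"]
        res = search(pop, lat, hierarchies, params, qis=(),
                     iterations=1, patients_per_iteration=None, seed=0)
        for node in lat.nodes():
            gds = apply_node(pop, node, hierarchies)
            key = gds.patients[qi].astype("string").agg("|".join, axis=1)
            sizes = key.map(key.value_counts())
            # brute-force k-anonymity-with-suppression-budget check
            frac_below = float((sizes < params.k).mean())
            anonymous = frac_below <= params.maxsup
            assert (node in res.candidates) == anonymous
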