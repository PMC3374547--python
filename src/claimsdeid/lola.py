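"""Longitudinal generalization-lattice search under bootstrap-evaluated
re-identification risk (LOLA: longitudinal optimal lattice anonymization).

A release candidate is one node of the generalization lattice.  A node is
*acceptable* when the proportion of patients an adversary could single out
— patients whose background knowledge matches fewer than k records — is at
most MaxSup.  Because the adversary knows only p_ih of each patient's claim
values per quasi-identifier, exact evaluation would enumerate every
combination of known values; instead a hierarchical bootstrap samples
patients with replacement and, for each, one random draw of background
knowledge, averaging the high-risk proportion over iterations.

The search walks the lattice bottom-up with predictive tagging: once a node
is clearly acceptable every generalization of it must be too (class sizes
only grow upward), so its ancestors are tagged without evaluation.  Among
acceptable nodes the one with the least non-uniform-entropy information
loss wins.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import adversary
from .adversary import AdversaryProfile
from .claims_model import Dataset, LEVEL1_QIS, LEVEL2_QIS
from .exceptions import DomainError
from .hierarchy import Hierarchy, Lattice, LatticeNode, apply_node
from .risk_metrics import RiskParams

__all__ = [
    "BackgroundKnowledge",
    "NodeEvaluation",
    "SearchResult",
    "MatchIndex",
    "build_match_index",
    "sample_background_knowledge",
    "match_count",
    "evaluate_node",
    "info_loss_entropy",
    "search",
]


def _norm(v):
    """Missing values compare equal; everything else by value."""
    return None if (v is None or v is pd.NA or (isinstance(v, float) and math.isnan(v))) else v


_BLOCK_RE = re.compile(r"^(?:wk|2wk|mo)\s+(-?\d+)$")


def _dsfc_order(v) -> float:
    """Temporal order key for a raw or generalized DSFC value."""
    if isinstance(v, str):
        m = _BLOCK_RE.match(v)
        if m:
            return float(m.group(1))
        try:
            return float(v)
        except ValueError:
            return math.nan
    try:
        return float(v)
    except (TypeError, ValueError):
        return math.nan


@dataclass
class BackgroundKnowledge:
    """One sampled attack instance: what the adversary knows about a patient.

    ``level1`` is the patient's demographic tuple (age, sex, DIH Y2/Y3 in
    released vocabulary); ``level2`` maps each claim QI to the multiset of
    known values.  The optional payloads model the sensitivity-analysis
    relaxations: ``same_claim_tuple`` asserts one full claim's QI tuple,
    ``ordered_pairs`` asserts the temporal order of one value pair per QI.
    """

    level1: tuple
    level2: dict[str, tuple]
    same_claim_tuple: dict | None = None
    ordered_pairs: dict[str, tuple] | None = None


@dataclass
class NodeEvaluation:
    """Bootstrap estimate of the high-risk proportion at one lattice node."""

    node: LatticeNode
    prop_high_risk: float
    se: float
    iterations: int
    patients_per_iteration: int | None
    seed: int | None
    acceptable: bool


@dataclass
class SearchResult:
    """Outcome of a lattice search.

    ``releasable`` is False when no node — not even the top — met the
    criterion; ``optimal`` is then None.
    """

    optimal: LatticeNode | None
    candidates: list[LatticeNode]
    info_loss: dict[LatticeNode, float]
    evaluations: list[NodeEvaluation]
    releasable: bool


class MatchIndex:
    """Per-patient matching structures over a (generalized) dataset."""

    def __init__(self, ds: Dataset, qis: Sequence[str] = LEVEL2_QIS):
        self.qis = tuple(qis)
        self.level1: dict = {}
        self.by_level1: dict[tuple, list] = {}
        self.counters: dict = {}
        self.claims: dict = {}
        for row in ds.patients.itertuples(index=False):
            t = tuple(_norm(getattr(row, c)) for c in LEVEL1_QIS)
            m = row.member_id
            self.level1[m] = t
            self.by_level1.setdefault(t, []).append(m)
            self.counters[m] = {qi: Counter() for qi in self.qis}
            self.claims[m] = []
        for row in ds.claims.itertuples(index=False):
            m = row.member_id
            rec = {qi: _norm(getattr(row, qi)) for qi in self.qis}
            rec["_dsfc_order"] = _dsfc_order(getattr(row, "dsfc"))
            self.claims[m].append(rec)
            for qi in self.qis:
                if rec[qi] is not None:
                    self.counters[m][qi][rec[qi]] += 1


def build_match_index(ds: Dataset, qis: Sequence[str] = LEVEL2_QIS) -> MatchIndex:
    return MatchIndex(ds, qis)


def sample_background_knowledge(
    patient_row: Mapping,
    patient_claims: pd.DataFrame,
    prof: AdversaryProfile,
    rng: np.random.Generator,
    qis: Sequence[str] | None = None,
) -> BackgroundKnowledge:
    """Draw one instance of adversary knowledge about a patient.

    Per QI, a simple random sample of min(p_ih, n_i) values is taken across
    the patient's claims without replacement; level-1 values are copied
    exactly.
    """
    qis = tuple(qis) if qis is not None else prof.qis
    member = patient_row["member_id"]
    level1 = tuple(_norm(patient_row[c]) for c in LEVEL1_QIS)
    level2 = {}
    for qi in qis:
        vals = [v for v in patient_claims[qi].tolist() if _norm(v) is not None]
        p = min(prof.power_of(member, qi), len(vals))
        if p == 0:
            level2[qi] = ()
            continue
        idx = rng.choice(len(vals), size=p, replace=False)
        level2[qi] = tuple(vals[i] for i in sorted(idx))
    return BackgroundKnowledge(level1=level1, level2=level2)


def _patient_matches(index: MatchIndex, member, bk: BackgroundKnowledge) -> bool:
    counters = index.counters[member]
    for qi, known in bk.level2.items():
        if not known:
            continue
        need = Counter(_norm(v) for v in known)
        have = counters[qi]
        if any(have[v] < c for v, c in need.items()):
            return False
    if bk.same_claim_tuple is not None:
        sct = {qi: _norm(v) for qi, v in bk.same_claim_tuple.items()}
        if not any(
            all(rec[qi] == v for qi, v in sct.items())
            for rec in index.claims[member]
        ):
            return False
    if bk.ordered_pairs is not None:
        for qi, (first, second) in bk.ordered_pairs.items():
            a, b = _norm(first), _norm(second)
            ok = False
            recs = index.claims[member]
            for i, r1 in enumerate(recs):
                if r1[qi] != a:
                    continue
                for j, r2 in enumerate(recs):
                    if i == j or r2[qi] != b:
                        continue
                    # ties in DSFC are consistent with either order
                    if not (r1["_dsfc_order"] > r2["_dsfc_order"]):
                        ok = True
                        break
                if ok:
                    break
            if not ok:
                return False
    return True


def match_count(bk: BackgroundKnowledge, ds_or_index) -> int:
    """Number of released patients consistent with the background knowledge:
    equal level-1 tuple and, per QI, the known values a sub-multiset of the
    patient's claim values (plus any variant payload conditions)."""
    index = ds_or_index if isinstance(ds_or_index, MatchIndex) else MatchIndex(ds_or_index)
    members = index.by_level1.get(bk.level1, [])
    return sum(1 for m in members if _patient_matches(index, m, bk))


def evaluate_node(
    ds: Dataset,
    node: LatticeNode,
    hierarchies: Mapping[str, Hierarchy],
    params: RiskParams,
    p_m: int = 5,
    qis: Sequence[str] = LEVEL2_QIS,
    iterations: int = 1000,
    patients_per_iteration: int | None = 10000,
    seed: int | None = None,
) -> NodeEvaluation:
    """Hierarchical-bootstrap estimate of the high-risk proportion at a node.

    Per iteration, ``patients_per_iteration`` patients are sampled with
    replacement (None sweeps every patient exactly once); each sampled
    patient contributes one background-knowledge draw, and is high-risk when
    the draw matches fewer than k records.  The node statistic is the mean
    high-risk fraction over iterations.
    """
    if ds.n_patients == 0:
        raise DomainError("cannot evaluate a node on an empty dataset")
    if iterations < 1 or (
        patients_per_iteration is not None and patients_per_iteration < 1
    ):
        raise DomainError("bootstrap parameters must be positive")
    rng = np.random.default_rng(seed)
    gds = apply_node(ds, node, hierarchies)
    prof = adversary.profile(gds, qis=qis, p_m=p_m)
    index = MatchIndex(gds, qis=qis)
    members = gds.patients["member_id"].tolist()
    rows = {
        r["member_id"]: r
        for r in gds.patients.to_dict("records")
    }
    claims_by_member: dict = {m: g for m, g in gds.claims.groupby("member_id", sort=False)}
    empty_claims = gds.claims.iloc[0:0]
    k = params.k
    stats = np.empty(iterations)
    for b in range(iterations):
        if patients_per_iteration is None:
            sampled = members
        else:
            sampled = [
                members[i]
                for i in rng.integers(0, len(members), size=patients_per_iteration)
            ]
        high = 0
        for m in sampled:
            bk = sample_background_knowledge(
                rows[m], claims_by_member.get(m, empty_claims), prof, rng, qis=qis
            )
            if match_count(bk, index) < k:
                high += 1
        stats[b] = high / len(sampled)
    prop = float(stats.mean())
    se = float(stats.std(ddof=1) / math.sqrt(iterations)) if iterations > 1 else 0.0
    return NodeEvaluation(
        node=node,
        prop_high_risk=prop,
        se=se,
        iterations=iterations,
        patients_per_iteration=patients_per_iteration,
        seed=seed,
        acceptable=prop <= params.maxsup,
    )


def _column_entropy(orig: pd.Series, gen: pd.Series) -> float:
    df = pd.DataFrame({"o": orig.astype("string"), "g": gen.astype("string")})
    df = df.fillna("<NA>")
    total = 0.0
    for _, grp in df.groupby("g", sort=False):
        counts = grp["o"].value_counts()
        size = len(grp)
        total += float(-(counts * np.log2(counts.to_numpy() / size)).sum())
    return total


def info_loss_entropy(
    original: Dataset,
    generalized: Dataset,
    qi_columns: Mapping[str, Sequence[str]] | None = None,
) -> float:
    """Non-uniform entropy information loss, in bits.

    For every record and QI column, the loss is −log2 of the empirical
    probability of the record's original value within its generalized group;
    an ungeneralized column contributes 0.
    """
    if qi_columns is None:
        qi_columns = {"patients": list(LEVEL1_QIS), "claims": list(LEVEL2_QIS)}
    total = 0.0
    for table, cols in qi_columns.items():
        odf = getattr(original, table)
        gdf = getattr(generalized, table)
        if len(odf) != len(gdf):
            raise DomainError(
                f"{table} tables are not row-aligned ({len(odf)} vs {len(gdf)})"
            )
        for col in cols:
            total += _column_entropy(
                odf[col].reset_index(drop=True), gdf[col].reset_index(drop=True)
            )
    return total


def search(
    ds: Dataset,
    lattice: Lattice,
    hierarchies: Mapping[str, Hierarchy],
    params: RiskParams,
    p_m: int = 5,
    qis: Sequence[str] = LEVEL2_QIS,
    iterations: int = 200,
    patients_per_iteration: int | None = 2000,
    seed: int | None = None,
    node_order: Sequence[LatticeNode] | None = None,
) -> SearchResult:
    """Find the least-information-loss acceptable node of the lattice.

    Nodes are processed bottom-up (by height, then level tuple) and every
    evaluation reuses the same seed, so estimates across nodes share their
    random draws (common random numbers).  A node whose estimate clears the
    MaxSup boundary by at least two Monte-Carlo standard errors tags all of
    its generalizations acceptable without further evaluation; borderline
    nodes never tag, preserving pruning soundness under noise.  Ties on
    information loss break toward the lower total level sum, then the
    lexicographically smallest level tuple.
    """
    if node_order is None:
        node_order = sorted(lattice.nodes(), key=lambda n: (n.height, n.levels))
    status: dict[LatticeNode, str] = {}
    evaluations: list[NodeEvaluation] = []
    for node in node_order:
        if node in status:
            continue
        ev = evaluate_node(
            ds, node, hierarchies, params,
            p_m=p_m, qis=qis, iterations=iterations,
            patients_per_iteration=patients_per_iteration, seed=seed,
        )
        evaluations.append(ev)
        status[node] = "acceptable" if ev.acceptable else "unacceptable"
        clear = abs(ev.prop_high_risk - params.maxsup) >= 2 * ev.se
        if clear:
            if ev.acceptable:
                for anc in lattice.ancestors(node):
                    status.setdefault(anc, "acceptable")
            else:
                for desc in lattice.descendants(node):
                    status.setdefault(desc, "unacceptable")
    candidates = sorted(
        (n for n, s in status.items() if s == "acceptable"),
        key=lambda n: (n.height, n.levels),
    )
    if not candidates:
        return SearchResult(None, [], {}, evaluations, releasable=False)
    info_loss = {
        n: info_loss_entropy(ds, apply_node(ds, n, hierarchies)) for n in candidates
    }
    optimal = min(candidates, key=lambda n: (info_loss[n], n.height, n.levels))
    return SearchResult(optimal, candidates, info_loss, evaluations, releasable=True)
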