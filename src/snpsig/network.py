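"""Disease-architecture networks and Random-Forest scoring of critical SNPs.

Validated signatures are merged into a weighted graph over SNP-genotype
features: every signature induces a clique over its features (edge weight
= number of cases carrying a signature containing both endpoints), and
features of different signatures are linked when their signatures share
case members (weight = shared case count).  SNPs recurring across many
signatures form hubs of this architecture; they are scored by how well a
Random Forest trained on their genotype states (optionally together with
their signature partners' states) predicts the case/control split under
stratified 5-fold cross-validation, and by a permutation test on the
number of signatures that survive label shuffling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .errors import ValidationError
from .matrix import MISSING, GenotypeMatrix
from .mining import MEMBER, DiseaseSignature, MiningConfig, match_signature
from .phenotype import CohortAssignment
from .stats import FisherExactCache, mean_odds_ratio

logger = logging.getLogger(__name__)


def case_memberships(
    matrix: GenotypeMatrix, cohort: CohortAssignment, signatures: list[DiseaseSignature]
) -> list[set[str]]:
    """Per-signature set of case sample ids carrying the signature."""
    cases = set(cohort.cases)
    out = []
    for sig in signatures:
        memb = match_signature(matrix, sig.features)
        carriers = {s for s, m in zip(matrix.sample_ids, memb) if m == MEMBER}
        out.append(carriers & cases)
    return out


def build_architecture(
    signatures: list[DiseaseSignature], case_members: list[set[str]]
) -> nx.Graph:
    """Merge signatures into the disease-architecture graph.

    Nodes are (snp_id, state) features.  Node attributes: ``n_signatures``.
    Edge attributes: ``weight`` (cases sharing both features through
    signature co-membership) and ``kind`` ("clique" within a signature,
    "shared_cases" across signatures).  Community labels from greedy
    modularity maximization are stored as the ``community`` node attribute.
    """
    if not signatures:
        raise ValidationError("need at least one validated signature")
    if len(case_members) != len(signatures):
        raise ValidationError("case_members must align with signatures")
    graph = nx.Graph()
    feat_sigs: dict[tuple, list[int]] = {}
    for i, sig in enumerate(signatures):
        for feat in sig.sorted_features():
            feat_sigs.setdefault(feat, []).append(i)
    for feat in sorted(feat_sigs):
        graph.add_node(feat, n_signatures=len(feat_sigs[feat]))
    feat_cases = {
        feat: set().union(*(case_members[i] for i in sigs)) for feat, sigs in feat_sigs.items()
    }
    for f, g in itertools.combinations(sorted(feat_sigs), 2):
        common_sigs = set(feat_sigs[f]) & set(feat_sigs[g])
        if common_sigs:
            weight = len(set().union(*(case_members[i] for i in common_sigs)))
            graph.add_edge(f, g, weight=max(weight, 1), kind="clique")
        else:
            shared = len(feat_cases[f] & feat_cases[g])
            if shared:
                graph.add_edge(f, g, weight=shared, kind="shared_cases")
    communities = nx.algorithms.community.greedy_modularity_communities(graph, weight="weight")
    for label, nodes in enumerate(sorted(communities, key=lambda c: sorted(c)[0])):
        for node in nodes:
            graph.nodes[node]["community"] = label
    return graph


def write_architecture(graph: nx.Graph, edge_path, graphml_path=None) -> None:
    """Plain weighted edge list (TSV) and optionally GraphML."""
    rows = [
        {
            "feature_a": f"{u[0]}:{u[1]}",
            "feature_b": f"{v[0]}:{v[1]}",
            "weight": d["weight"],
            "kind": d["kind"],
        }
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(edge_path, sep="\t", index=False)
    if graphml_path is not None:
        relabel = {n: f"{n[0]}:{n[1]}" for n in graph.nodes}
        nx.write_graphml(nx.relabel_nodes(graph, relabel), graphml_path)


# ----------------------------------------------------------------------
# Random-Forest critical-SNP scoring
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CriticalSnpReport:
    snp_id: str
    n_signatures: int
    rf_accuracy: float
    permutation_p: float = float("nan")

    def is_critical(self, alpha: float = 0.05, baseline: float | None = None) -> bool:
        """Critical = permutation p below alpha and RF beats the majority class."""
        ok = self.permutation_p <= alpha
        if baseline is not None:
            ok = ok and self.rf_accuracy > baseline
        return bool(ok)


def _one_hot_states(col: np.ndarray) -> np.ndarray:
    """3-column one-hot encoding; a missing genotype is all-zero."""
    out = np.zeros((col.shape[0], 3), dtype=np.float64)
    for st in (0, 1, 2):
        out[col == st, st] = 1.0
    return out


def rf_score_snp(
    matrix: GenotypeMatrix,
    cohort: CohortAssignment,
    snp_id: str,
    partner_snps: list[str] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean stratified k-fold CV accuracy of a Random Forest on one SNP.

    Predictors are the SNP's one-hot genotype states plus, when given, the
    one-hot states of its signature partners.  100 trees, default depth;
    deterministic given ``seed``.
    """
    cc = sorted(cohort.cases + cohort.controls)
    row_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    rows = [row_index[s] for s in cc]
    y = (cohort.labels.reindex(cc) == "case").to_numpy()
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < folds:
        raise ValidationError(
            f"cannot stratify {folds} folds with class counts {counts.tolist()}"
        )
    blocks = [_one_hot_states(matrix.states[rows, matrix.snp_index(snp_id)])]
    for p in partner_snps or []:
        blocks.append(_one_hot_states(matrix.states[rows, matrix.snp_index(p)]))
    X = np.hstack(blocks)
    clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy")
    return float(scores.mean())


def rf_score_critical_snps(
    matrix: GenotypeMatrix,
    cohort: CohortAssignment,
    signatures: list[DiseaseSignature],
    candidate_snps: list[str] | None = None,
    include_partners: bool = True,
    folds: int = 5,
    seed: int = 0,
) -> list[CriticalSnpReport]:
    """RF-score every candidate SNP appearing in at least one signature."""
    snp_sigs: dict[str, list[DiseaseSignature]] = {}
    for sig in signatures:
        for snp in sig.snps:
            snp_sigs.setdefault(snp, []).append(sig)
    if candidate_snps is None:
        candidate_snps = sorted(snp_sigs)
    out = []
    for snp in candidate_snps:
        sigs = snp_sigs.get(snp)
        if not sigs:
            raise ValidationError(f"candidate SNP {snp!r} appears in no signature")
        partners = sorted({s for sig in sigs for s in sig.snps if s != snp}) if include_partners else None
        acc = rf_score_snp(matrix, cohort, snp, partner_snps=partners, folds=folds, seed=seed)
        out.append(CriticalSnpReport(snp_id=snp, n_signatures=len(sigs), rf_accuracy=acc))
    return out


def critical_permutation_test(
    matrix: GenotypeMatrix,
    cohort: CohortAssignment,
    snp_id: str,
    signatures: list[DiseaseSignature],
    config: MiningConfig | None = None,
    n_permutations: int = 199,
    seed: int = 0,
) -> float:
    """Permutation p for the number of signatures retained around one SNP.

    The statistic is how many of the SNP's observed signatures still pass
    the mining filters (case prevalence, odds ratio > 1, Fisher p < alpha)
    after the case/control labels are shuffled -- i.e. the permutation is
    restricted to the SNP's observed partner space for tractability.
    Empirical p = (1 + #{perm stat >= observed}) / (1 + n_permutations).
    """
    if n_permutations < 19:
        raise ValueError("n_permutations < 19 cannot resolve an alpha of 0.05")
    cfg = config or MiningConfig()
    own = [sig for sig in signatures if snp_id in sig.snps]
    if not own:
        raise ValidationError(f"SNP {snp_id!r} appears in no signature")
    cc = sorted(cohort.cases + cohort.controls)
    row_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    rows = [row_index[s] for s in cc]
    case_mask = (cohort.labels.reindex(cc) == "case").to_numpy()
    A, B = int(case_mask.sum()), int((~case_mask).sum())
    fisher = FisherExactCache(A, B)

    memb = np.array(
        [match_signature(matrix, sig.features)[rows] == MEMBER for sig in own],
        dtype=np.float32,
    )
    m_counts = memb.sum(axis=1).astype(np.int64)

    def stat(case_vec: np.ndarray) -> int:
        a = (memb @ case_vec.astype(np.float32)).astype(np.int64)
        prev_ok = a / A >= cfg.min_case_prevalence
        orr = np.array(
            [mean_odds_ratio(ai, mi - ai, A, B) for ai, mi in zip(a, m_counts)]
        )
        p = fisher.pvalues(a, m_counts)
        return int((prev_ok & (orr > 1.0) & (p < cfg.alpha)).sum())

    observed = stat(case_mask)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        exceed += stat(rng.permutation(case_mask)) >= observed
    return (1.0 + exceed) / (1.0 + n_permutations)


def write_critical_report(reports: list[CriticalSnpReport], path) -> None:
    pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "n_signatures": r.n_signatures,
                "rf_accuracy": r.rf_accuracy,
                "permutation_p": r.permutation_p,
            }
            for r in reports
        ]
    ).to_csv(path, sep="\t", index=False)
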