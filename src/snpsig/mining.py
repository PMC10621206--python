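"""Combinatorial disease-signature mining and permutation-based validation.

A *feature* is a (SNP, genotype-state) pair; a *disease signature* is a
set of 1-5 features at distinct SNPs whose conjunction (a sample carries
every component state exactly) is enriched in cases.  Signatures are
discovered in layers of increasing combinatorial order: all single
features with sufficient case prevalence form layer 1; each subsequent
layer extends a beam of the most promising lower-order combinations by
one feature.  Candidates are reported when they satisfy all three filter
criteria -- case prevalence above ``min_case_prevalence``, two-sided
Fisher p below ``alpha`` and odds ratio (relative to the cohort's mean
odds) above 1.

Validation randomizes whole datasets: the case/control labels are
shuffled and the *entire layered search* is re-run on each permuted
dataset, giving the null distribution of discovery p-values under the
same selection procedure.  The estimated false-discovery rate at
threshold ``t`` is the (add-one smoothed) mean number of null discoveries
with p <= t divided by the observed number; per-candidate q-values are
the monotonized minima of that ratio.  Re-running the selection on every
permutation is essential: the observed candidates are the extremes of a
very large search space, so comparing them against per-candidate label
permutations alone would ignore the selection effect entirely.

:func:`permutation_fdr` additionally provides the classic per-candidate
empirical p-value + Benjamini-Hochberg route for externally supplied
candidate lists that were *not* chosen by a data-driven search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .errors import ValidationError
from .matrix import MISSING, GenotypeMatrix
from .phenotype import CohortAssignment
from .stats import FisherExactCache, bh_adjust, mean_odds_ratio

logger = logging.getLogger(__name__)

STATES = (0, 1, 2)

Feature = tuple[str, int]  # (snp_id, genotype state)


@dataclass(frozen=True)
class DiseaseSignature:
    """A validated (or candidate) combination of SNP-genotype features."""

    features: frozenset[Feature]
    case_count: int
    control_count: int
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")
    validated: bool = False

    @property
    def order(self) -> int:
        return len(self.features)

    @property
    def snps(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.features)

    def sorted_features(self) -> tuple[Feature, ...]:
        return tuple(sorted(self.features))


@dataclass
class MiningConfig:
    """Search and validation parameters.

    ``min_case_prevalence`` is the fraction of cases a candidate must
    cover; ``alpha`` the per-candidate Fisher threshold; ``fdr_q`` the
    q-value cut for validation; ``beam_width`` the number of combinations
    per layer kept for extension (``None`` = unlimited, exhaustive within
    prevalence-eligible space).
    """

    max_order: int = 5
    min_case_prevalence: float = 0.05
    alpha: float = 0.05
    fdr_q: float = 0.05
    n_permutations: int = 99
    beam_width: int | None = 150
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")
        for name in ("min_case_prevalence", "alpha", "fdr_q"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


# ----------------------------------------------------------------------
# Membership and per-signature statistics
# ----------------------------------------------------------------------

MEMBER, NON_MEMBER, INCOMPLETE = 1, 0, -1


def match_signature(matrix: GenotypeMatrix, features) -> np.ndarray:
    """Per-sample membership of a feature conjunction.

    Returns an int vector over ``matrix.sample_ids``: ``MEMBER`` when every
    feature's SNP carries exactly the feature's state, ``INCOMPLETE`` when
    any component genotype is missing, ``NON_MEMBER`` otherwise.  An empty
    feature set is the vacuous conjunction: everyone is a member.
    """
    features = list(features)
    snps = [s for s, _ in features]
    if len(set(snps)) != len(snps):
        raise ValidationError("duplicate SNP across signature features")
    member = np.ones(matrix.n_samples, dtype=bool)
    incomplete = np.zeros(matrix.n_samples, dtype=bool)
    for snp_id, state in features:
        if state not in STATES:
            raise ValidationError(f"invalid feature state {state}")
        col = matrix.column(snp_id)
        incomplete |= col == MISSING
        member &= col == state
    out = np.where(member, MEMBER, NON_MEMBER)
    out[incomplete] = INCOMPLETE
    return out


def signature_stats(
    membership: np.ndarray,
    cohort: CohortAssignment,
    sample_ids: list[str],
) -> tuple[int, int, float, float]:
    """Counts, mean-odds odds ratio and Fisher p for one signature.

    Members with incomplete genotypes are excluded from the counts; the
    denominator odds are the full cohort's total cases / total controls.
    Returns ``(case_count, control_count, odds_ratio, p_value)``.
    """
    labels = cohort.labels.reindex(sample_ids).to_numpy()
    member = membership == MEMBER
    if (membership == INCOMPLETE).all():
        raise ValidationError("membership is incomplete for every sample")
    case_count = int((member & (labels == "case")).sum())
    control_count = int((member & (labels == "control")).sum())
    return signature_stats_from_counts(
        case_count, control_count, cohort.n_cases, cohort.n_controls
    )


def signature_stats_from_counts(
    case_count: int,
    control_count: int,
    total_cases: int,
    total_controls: int,
) -> tuple[int, int, float, float]:
    """Statistics from explicit counts (e.g. a published signature table).

    The odds ratio is relative to the cohort mean odds,
    ``(case_count/control_count) / (total_cases/total_controls)``; the
    p-value is a two-sided Fisher exact test of membership vs case status.
    """
    if total_cases < 1 or total_controls < 1:
        raise ValidationError("cohort must contain at least one case and one control")
    orr = mean_odds_ratio(case_count, control_count, total_cases, total_controls)
    table = [
        [case_count, total_cases - case_count],
        [control_count, total_controls - control_count],
    ]
    p = float(fisher_exact(table, alternative="two-sided")[1])
    return case_count, control_count, float(orr), p


# ----------------------------------------------------------------------
# Layered beam search (array-based hot path)
# ----------------------------------------------------------------------


class _SearchSpace:
    """Precomputed feature membership structures for one dataset.

    Features are ordered canonically by (snp_id, state) so that results do
    not depend on the column order of the input matrix; samples are the
    cohort's case/control samples ordered by sample id so that permutation
    streams are reproducible regardless of input row order.
    """

    def __init__(self, matrix: GenotypeMatrix, cohort: CohortAssignment,
                 snp_whitelist_first: set[str] | None = None):
        cc_samples = sorted(cohort.cases + cohort.controls)
        if not cohort.n_cases or not cohort.n_controls:
            raise ValidationError("cohort must contain both cases and controls")
        row_index = {s: i for i, s in enumerate(matrix.sample_ids)}
        try:
            rows = [row_index[s] for s in cc_samples]
        except KeyError as exc:
            raise ValidationError(f"cohort sample {exc} absent from genotype matrix") from None
        states = matrix.states[rows, :]
        labels = cohort.labels.reindex(cc_samples).to_numpy()
        self.sample_ids = cc_samples
        self.case_mask = labels == "case"
        self.n = len(cc_samples)
        self.A = int(self.case_mask.sum())
        self.B = self.n - self.A

        snp_order = sorted(range(matrix.n_snps), key=lambda j: matrix.snp_ids[j])
        self.feat_snp_id: list[str] = []
        self.feat_state: list[int] = []
        feat_cols = []
        feat_snp_idx = []
        for rank, j in enumerate(snp_order):
            col = states[:, j]
            for st in STATES:
                self.feat_snp_id.append(matrix.snp_ids[j])
                self.feat_state.append(st)
                feat_cols.append(col == st)  # missing -> non-member
                feat_snp_idx.append(rank)
        self.nfeat = len(feat_cols)
        self.F = np.ascontiguousarray(np.array(feat_cols, dtype=bool))
        self.Ff = self.F.astype(np.float32)
        self.feat_snp = np.asarray(feat_snp_idx, dtype=np.int64)
        self.fisher = FisherExactCache(self.A, self.B)
        # candidates at layer 1 may be restricted (seeded search)
        if snp_whitelist_first is None:
            self.first_layer = np.arange(self.nfeat)
        else:
            mask = np.isin(np.asarray(self.feat_snp_id), sorted(snp_whitelist_first))
            self.first_layer = np.flatnonzero(mask)

    def feature(self, idx: int) -> Feature:
        return (self.feat_snp_id[idx], self.feat_state[idx])

    def encode(self, idx_sets: np.ndarray) -> np.ndarray:
        """Pack sorted feature-index tuples (rows) into int64 keys."""
        base = np.int64(self.nfeat)
        keys = np.zeros(idx_sets.shape[0], dtype=np.int64)
        for c in range(idx_sets.shape[1]):
            keys = keys * base + idx_sets[:, c]
        return keys

    def decode(self, key: int, order: int) -> tuple[int, ...]:
        out = []
        for _ in range(order):
            out.append(int(key % self.nfeat))
            key //= self.nfeat
        return tuple(reversed(out))


@dataclass
class _LayerResult:
    keys: np.ndarray
    order: int
    a: np.ndarray
    m: np.ndarray
    p: np.ndarray
    orr: np.ndarray


def _odds_vec(a: np.ndarray, m: np.ndarray, A: int, B: int) -> np.ndarray:
    b = m - a
    num = np.where(b == 0, (a + 0.5) / 0.5, np.divide(a, np.maximum(b, 1)))
    return num / (A / B)


def _run_search(space: _SearchSpace, case_mask: np.ndarray, cfg: MiningConfig) -> list[_LayerResult]:
    """One full layered search; returns the filtered candidates per layer."""
    A = int(case_mask.sum())
    B = space.n - A
    case_f = case_mask.astype(np.float32)
    reported: list[_LayerResult] = []

    # ---- layer 1
    f_idx = space.first_layer
    m1 = space.F[f_idx].sum(axis=1).astype(np.int64)
    a1 = (space.Ff[f_idx] @ case_f).astype(np.int64)
    elig = a1 / A >= cfg.min_case_prevalence
    elig &= m1 < space.n  # a feature carried by everyone is uninformative
    p1 = np.ones(f_idx.shape[0])
    p1[elig] = space.fisher.pvalues(a1[elig], m1[elig])
    orr1 = _odds_vec(a1, m1, A, B)
    rep = elig & (p1 < cfg.alpha) & (orr1 > 1.0)
    if rep.any():
        reported.append(
            _LayerResult(f_idx[rep].astype(np.int64), 1, a1[rep], m1[rep], p1[rep], orr1[rep])
        )

    # beam = prevalence-eligible features ranked by (p, -OR, canonical idx)
    cand = np.flatnonzero(elig)
    if cand.size == 0 or cfg.max_order == 1:
        return reported
    rank = np.lexsort((f_idx[cand], -orr1[cand], p1[cand]))
    beam = cand[rank[: cfg.beam_width]] if cfg.beam_width else cand[rank]
    beam_feats = f_idx[beam][:, None]  # (w, 1) feature indices
    beam_memb = space.F[f_idx[beam]].copy()  # (w, n)

    for order in range(2, cfg.max_order + 1):
        w = beam_feats.shape[0]
        if w == 0:
            break
        Bm = beam_memb.astype(np.float32)
        m_mat = (Bm @ space.Ff.T).astype(np.int64)  # (w, nfeat) joint member counts
        a_mat = (Bm[:, case_mask] @ space.Ff[:, case_mask].T).astype(np.int64)
        # disallow reusing a SNP already in the combination
        snp_clash = np.zeros((w, space.nfeat), dtype=bool)
        for c in range(beam_feats.shape[1]):
            snp_clash |= space.feat_snp[beam_feats[:, c]][:, None] == space.feat_snp[None, :]
        elig2 = (a_mat / A >= cfg.min_case_prevalence) & ~snp_clash
        bi, fj = np.nonzero(elig2)
        if bi.size == 0:
            break
        idx_sets = np.sort(np.column_stack([beam_feats[bi], fj[:, None]]), axis=1)
        keys = space.encode(idx_sets)
        keys, first = np.unique(keys, return_index=True)
        bi, fj, idx_sets = bi[first], fj[first], idx_sets[first]
        a_v = a_mat[bi, fj]
        m_v = m_mat[bi, fj]
        p_v = space.fisher.pvalues(a_v, m_v)
        orr_v = _odds_vec(a_v, m_v, A, B)
        rep = (p_v < cfg.alpha) & (orr_v > 1.0)
        if rep.any():
            reported.append(_LayerResult(keys[rep], order, a_v[rep], m_v[rep], p_v[rep], orr_v[rep]))
        if order == cfg.max_order:
            break
        rank = np.lexsort((keys, -orr_v, p_v))
        sel = rank[: cfg.beam_width] if cfg.beam_width else rank
        beam_feats = idx_sets[sel]
        beam_memb = beam_memb[bi[sel]] & space.F[fj[sel]]
    return reported


def _dedup(space: _SearchSpace, layers: list[_LayerResult]) -> list[tuple[tuple[int, ...], int, int, float, float]]:
    """Collapse nested candidates with identical membership onto the smaller set.

    Returns tuples ``(feature_idx_tuple, case_count, member_count, p, odds_ratio)``.
    A superset is redundant exactly when some reported proper subset has the
    same member count (conjunction can only shrink membership).
    """
    items: list[tuple[tuple[int, ...], int, int, float, float]] = []
    for layer in layers:
        for k, a, m, p, orr in zip(layer.keys, layer.a, layer.m, layer.p, layer.orr):
            feats = space.decode(int(k), layer.order) if layer.order > 1 else (int(k),)
            items.append((feats, int(a), int(m), float(p), float(orr)))
    items.sort(key=lambda t: (len(t[0]), t[0]))
    kept_by_m: dict[int, list[frozenset[int]]] = {}
    out = []
    for feats, a, m, p, orr in items:
        fset = frozenset(feats)
        redundant = any(sub < fset for sub in kept_by_m.get(m, ()))
        if not redundant:
            kept_by_m.setdefault(m, []).append(fset)
            out.append((feats, a, m, p, orr))
    return out


# ----------------------------------------------------------------------
# Public mining API
# ----------------------------------------------------------------------

def mine_candidates(
    matrix: GenotypeMatrix,
    cohort: CohortAssignment,
    config: MiningConfig,
    seed_snps: set[str] | None = None,
    dedup: bool = True,
) -> list[DiseaseSignature]:
    """Layered search only: candidates passing the prevalence/p/OR filters.

    No permutation validation is applied (q-values are NaN).  With
    ``seed_snps`` the search is restricted to combinations containing at
    least one feature at a seed SNP.
    """
    space = _SearchSpace(matrix, cohort, snp_whitelist_first=seed_snps)
    layers = _run_search(space, space.case_mask, config)
    if dedup:
        rows = _dedup(space, layers)
    else:
        rows = []
        for layer in layers:
            for k, a, m, p, orr in zip(layer.keys, layer.a, layer.m, layer.p, layer.orr):
                feats = space.decode(int(k), layer.order) if layer.order > 1 else (int(k),)
                rows.append((feats, int(a), int(m), float(p), float(orr)))
    out = [
        DiseaseSignature(
            features=frozenset(space.feature(i) for i in feats),
            case_count=a,
            control_count=m - a,
            odds_ratio=orr,
            p_value=p,
        )
        for feats, a, m, p, orr in rows
    ]
    out.sort(key=lambda s: (s.p_value, -s.odds_ratio, s.sorted_features()))
    return out


def mine_signatures(
    matrix: GenotypeMatrix,
    cohort: CohortAssignment,
    config: MiningConfig,
    seed_snps: set[str] | None = None,
) -> list[DiseaseSignature]:
    """Full pipeline: layered search plus dataset-randomization FDR.

    The search is re-run on ``config.n_permutations`` label-shuffled copies
    of the dataset; each observed candidate's q-value estimates the false
    discovery rate at its p-value threshold (see module docstring).
    Candidates with ``q <= config.fdr_q`` are marked validated.  Fully
    deterministic given ``config.random_seed``.
    """
    if config.n_permutations < 19:
        raise ValueError("n_permutations < 19 cannot resolve an alpha of 0.05")
    space = _SearchSpace(matrix, cohort, snp_whitelist_first=seed_snps)
    layers = _run_search(space, space.case_mask, config)
    rows = _dedup(space, layers)
    for layer in layers:
        logger.info("layer order=%d: %d candidates pass filters", layer.order, layer.keys.size)
    if not rows:
        return []

    rng = np.random.default_rng(config.random_seed)
    null_p: list[np.ndarray] = []
    for _ in range(config.n_permutations):
        perm_case = rng.permutation(space.case_mask)
        perm_layers = _run_search(space, perm_case, config)
        if perm_layers:
            null_p.append(np.concatenate([lay.p for lay in perm_layers]))
    null_sorted = np.sort(np.concatenate(null_p)) if null_p else np.empty(0)

    obs_p = np.array([r[3] for r in rows])
    order = np.argsort(obs_p, kind="stable")
    sorted_p = obs_p[order]
    n_obs_le = np.arange(1, sorted_p.size + 1)
    n_null_le = np.searchsorted(null_sorted, sorted_p, side="right")
    fdr_hat = ((1.0 + n_null_le) / (1.0 + config.n_permutations)) / n_obs_le
    q_sorted = np.minimum(np.minimum.accumulate(fdr_hat[::-1])[::-1], 1.0)
    q = np.empty_like(obs_p)
    q[order] = q_sorted

    out = []
    for (feats, a, m, p, orr), qv in zip(rows, q):
        out.append(
            DiseaseSignature(
                features=frozenset(space.feature(i) for i in feats),
                case_count=a,
                control_count=m - a,
                odds_ratio=orr,
                p_value=p,
                q_value=float(qv),
                validated=bool(qv <= config.fdr_q),
            )
        )
    out.sort(key=lambda s: (s.q_value, -s.odds_ratio, s.sorted_features()))
    n_val = sum(s.validated for s in out)
    logger.info("validated %d/%d candidates at q<=%s (seed=%d)",
                n_val, len(out), config.fdr_q, config.random_seed)
    return out


def permutation_fdr(
    matrix: GenotypeMatrix,
    cohort: CohortAssignment,
    candidates: list[frozenset | set | tuple],
    n_permutations: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-candidate permutation p-values with Benjamini-Hochberg adjustment.

    For each label permutation every candidate's Fisher p is recomputed;
    the empirical p is ``(1 + #{perm p <= observed p}) / (1 + n_permutations)``
    and BH across candidates yields q.  Appropriate for externally fixed
    candidate lists; for candidates chosen by a data-driven search use
    :func:`mine_signatures`, whose validation repeats the selection on
    each permuted dataset.
    """
    if n_permutations < 19:
        raise ValueError("n_permutations < 19 cannot resolve an alpha of 0.05")
    cc_samples = sorted(cohort.cases + cohort.controls)
    case_mask = (cohort.labels.reindex(cc_samples) == "case").to_numpy()
    A, B = int(case_mask.sum()), int((~case_mask).sum())
    fisher = FisherExactCache(A, B)
    row_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    rows = [row_index[s] for s in cc_samples]

    memb = []
    for feats in candidates:
        mvec = match_signature(matrix, feats)[rows]
        memb.append(mvec == MEMBER)
    M = np.array(memb, dtype=np.float32)
    m_counts = M.sum(axis=1).astype(np.int64)
    obs_a = (M @ case_mask.astype(np.float32)).astype(np.int64)
    obs_p = fisher.pvalues(obs_a, m_counts)

    rng = np.random.default_rng(seed)
    n_le = np.zeros(len(candidates), dtype=np.int64)
    for _ in range(n_permutations):
        perm = rng.permutation(case_mask).astype(np.float32)
        a = (M @ perm).astype(np.int64)
        p = fisher.pvalues(a, m_counts)
        n_le += p <= obs_p
    emp_p = (1.0 + n_le) / (1.0 + n_permutations)
    q = bh_adjust(emp_p)
    return pd.DataFrame(
        {
            "features": [tuple(sorted(f)) for f in candidates],
            "observed_p": obs_p,
            "empirical_p": emp_p,
            "q_value": q,
        }
    )


def single_snp_association(matrix: GenotypeMatrix, cohort: CohortAssignment) -> pd.DataFrame:
    """Allelic single-SNP association table (the GWAS baseline).

    Per SNP, minor-allele counts in cases vs controls are tested with a
    two-sided Fisher exact test on the 2x2 allele table.  Monomorphic SNPs
    report p = 1.  The ``genome_wide_significant`` flag marks p < 5e-8.
    """
    cc_samples = sorted(cohort.cases + cohort.controls)
    row_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    rows = [row_index[s] for s in cc_samples]
    states = matrix.states[rows, :]
    case = (cohort.labels.reindex(cc_samples) == "case").to_numpy()
    out = []
    for j, snp_id in enumerate(matrix.snp_ids):
        col = states[:, j]
        ok = col != MISSING
        ca, co = ok & case, ok & ~case
        minor_ca = int(col[ca].sum())
        minor_co = int(col[co].sum())
        tot_ca, tot_co = 2 * int(ca.sum()), 2 * int(co.sum())
        if minor_ca + minor_co == 0 or minor_ca + minor_co == tot_ca + tot_co:
            p = 1.0
        else:
            p = float(
                fisher_exact(
                    [[minor_ca, tot_ca - minor_ca], [minor_co, tot_co - minor_co]]
                )[1]
            )
        out.append((snp_id, minor_ca, minor_co, p))
    df = pd.DataFrame(out, columns=["snp_id", "minor_cases", "minor_controls", "p"]).set_index("snp_id")
    df["genome_wide_significant"] = df["p"] < 5e-8
    return df


def write_signature_table(signatures: list[DiseaseSignature], path) -> None:
    """Tab-separated signature report (order, features, counts, OR, p, q)."""
    rows = []
    for s in signatures:
        rows.append(
            {
                "order": s.order,
                "features": ";".join(f"{snp}:{st}" for snp, st in s.sorted_features()),
                "case_count": s.case_count,
                "control_count": s.control_count,
                "odds_ratio": s.odds_ratio,
                "p": s.p_value,
                "q": s.q_value,
                "validated": s.validated,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
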