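"""Ancestry-confounder screening, phenotype enrichment and seeded mining.

Population structure can manufacture spurious genotype-disease
associations: if a signature's carriers concentrate in one ancestry
stratum and disease risk also differs by ancestry, the signature is
associated with disease without any genetic effect.  The confounder
screen refits each signature in a logistic regression
``case ~ membership + ancestry`` and discards signatures whose
membership coefficient loses significance (Bonferroni-adjusted Wald
p >= 0.05) once the binary ancestry covariate is present.

Phenotype enrichment compares signature carriers against the *rest of
the case population* (not against controls): a pooled two-proportion
Z-test for categorical phenotypes and a two-sided Mann-Whitney U with
normal approximation and tie correction for continuous ones, BH-adjusted
across all phenotypes tested.

Seeded mining restricts the combinatorial search to combinations
containing at least one pre-specified seed SNP, shrinking the search
space so that associations found in one cohort can be looked for
directly in another.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm
from statsmodels.stats.proportion import proportions_ztest
import statsmodels.api as sm

from .errors import ValidationError
from .matrix import GenotypeMatrix
from .mining import DiseaseSignature, MiningConfig, mine_signatures
from .phenotype import CohortAssignment
from .stats import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfounderCheckResult:
    signature_id: str
    membership_p: float
    adjusted_p: float
    verdict: str  # "pass" or "fail"
    fit_note: str = ""


def _ridge_logit(X: np.ndarray, y: np.ndarray, lam: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-penalized logistic fit by Newton iterations; returns (beta, se).

    Fallback for (quasi-)separated data where plain maximum likelihood
    diverges; the small L2 penalty keeps the Hessian invertible.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(50):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu) - lam * beta
        hess = (X.T * w) @ X + lam * np.eye(k)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    cov = np.linalg.inv(hess)
    return beta, np.sqrt(np.diag(cov))


def ancestry_confounder_check(
    memberships: dict[str, np.ndarray],
    cohort: CohortAssignment,
    ancestry: pd.Series,
    sample_ids: list[str],
    alpha: float = 0.05,
    method: str = "bonferroni",
) -> list[ConfounderCheckResult]:
    """Screen signatures for ancestry confounding by logistic regression.

    ``memberships`` maps a signature id to a boolean carrier vector over
    ``sample_ids``; ``ancestry`` is a binary (0/1) series indexed by sample
    id, defined for every cohort sample.  Each signature is fitted
    separately: ``case ~ intercept + membership + ancestry``; the Wald p of
    the membership coefficient is Bonferroni-adjusted (``method='bh'``
    switches to Benjamini-Hochberg).  ``fail`` iff adjusted p >= alpha.
    """
    cc = sorted(cohort.cases + cohort.controls)
    anc = ancestry.reindex(cc)
    if anc.isna().any():
        raise ValidationError("ancestry undefined for some cohort samples")
    pos = {s: i for i, s in enumerate(sample_ids)}
    rows = [pos[s] for s in cc]
    y = (cohort.labels.reindex(cc) == "case").to_numpy(dtype=float)
    anc_v = anc.to_numpy(dtype=float)

    raw_p = []
    notes = []
    ids = sorted(memberships)
    for sig_id in ids:
        memb = np.asarray(memberships[sig_id], dtype=float)[rows]
        X = np.column_stack([np.ones_like(y), memb, anc_v])
        note = ""
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", True) or not np.isfinite(fit.bse[1]):
                raise np.linalg.LinAlgError("non-convergence")
            p = float(fit.pvalues[1])
        except Exception:
            beta, se = _ridge_logit(X, y)
            z = beta[1] / se[1]
            p = float(2 * norm.sf(abs(z)))
            note = "penalized fallback (separation or non-convergence)"
            logger.warning("signature %s: %s", sig_id, note)
        raw_p.append(p)
        notes.append(note)

    raw = np.asarray(raw_p)
    if method == "bonferroni":
        adj = np.minimum(raw * len(raw), 1.0)
    elif method == "bh":
        adj = bh_adjust(raw)
    else:
        raise ValueError(f"unknown correction method {method!r}")
    return [
        ConfounderCheckResult(
            signature_id=sig_id,
            membership_p=float(p),
            adjusted_p=float(a),
            verdict="pass" if a < alpha else "fail",
            fit_note=note,
        )
        for sig_id, p, a, note in zip(ids, raw, adj, notes)
    ]


def genes_surviving_check(
    results: list[ConfounderCheckResult], signature_genes: dict[str, set[str]]
) -> dict[str, bool]:
    """Per gene, whether any signature mapped to it passed the screen."""
    survives: dict[str, bool] = {}
    for res in results:
        for gene in signature_genes.get(res.signature_id, ()):
            survives[gene] = survives.get(gene, False) or res.verdict == "pass"
    return survives


@dataclass(frozen=True)
class EnrichmentResult:
    phenotype: str
    test: str
    statistic: float
    raw_p: float
    adjusted_p: float
    direction: str  # "up" when carriers exceed other cases
    underpowered: bool = False


def phenotype_enrichment(
    carrier_mask: np.ndarray,
    phenotypes: pd.DataFrame,
    variable_types: dict[str, str],
) -> list[EnrichmentResult]:
    """Compare signature-carrier cases against the remaining cases.

    ``carrier_mask`` is boolean over the rows of ``phenotypes``, which must
    contain cases only.  ``variable_types`` maps column -> "categorical"
    (0/1 indicator; pooled two-proportion Z) or "continuous" (two-sided
    Mann-Whitney U, asymptotic with tie correction).  BH across all
    phenotypes tested; groups smaller than 5 are flagged underpowered but
    still reported.
    """
    carrier_mask = np.asarray(carrier_mask, dtype=bool)
    if carrier_mask.shape[0] != len(phenotypes):
        raise ValidationError("carrier mask must align with phenotype rows")
    results = []
    for col, kind in variable_types.items():
        x = phenotypes[col].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        g1 = x[ok & carrier_mask]
        g2 = x[ok & ~carrier_mask]
        under = min(len(g1), len(g2)) < 5
        if len(g1) == 0 or len(g2) == 0:
            results.append(EnrichmentResult(col, kind, float("nan"), 1.0, 1.0, "none", True))
            continue
        if kind == "categorical":
            counts = np.array([g1.sum(), g2.sum()])
            nobs = np.array([len(g1), len(g2)])
            if counts.sum() == 0 or counts.sum() == nobs.sum():
                stat, p = 0.0, 1.0
            else:
                stat, p = proportions_ztest(counts, nobs)
            direction = "up" if g1.mean() > g2.mean() else ("down" if g1.mean() < g2.mean() else "none")
        elif kind == "continuous":
            if np.unique(x[ok]).size == 1:
                stat, p = float(len(g1) * len(g2) / 2.0), 1.0
            else:
                res = mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
                stat, p = float(res.statistic), float(res.pvalue)
            direction = "up" if np.median(g1) > np.median(g2) else ("down" if np.median(g1) < np.median(g2) else "none")
        else:
            raise ValueError(f"unknown variable type {kind!r} for {col!r}")
        results.append(EnrichmentResult(col, kind, float(stat), float(p), float("nan"), direction, under))
    adj = bh_adjust(np.array([r.raw_p for r in results]))
    return [
        EnrichmentResult(r.phenotype, r.test, r.statistic, r.raw_p, float(a), r.direction, r.underpowered)
        for r, a in zip(results, adj)
    ]


def seeded_mine(
    matrix: GenotypeMatrix,
    cohort: CohortAssignment,
    seed_snps: list[str],
    config: MiningConfig,
) -> list[DiseaseSignature]:
    """Hypothesis-driven mining restricted to combinations with >= 1 seed SNP.

    Seed SNPs absent from the matrix are logged and dropped.  Criteria and
    validation are identical to :func:`snpsig.mining.mine_signatures`; the
    FDR is computed within the reduced (seeded) candidate space.
    """
    present = [s for s in seed_snps if s in set(matrix.snp_ids)]
    missing = sorted(set(seed_snps) - set(present))
    if missing:
        logger.warning("dropping %d seed SNPs absent from matrix: %s%s",
                       len(missing), missing[:5], "..." if len(missing) > 5 else "")
    if not present:
        return []
    return mine_signatures(matrix, cohort, config, seed_snps=set(present))
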