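"""Expanded Genotypes Analysis (EGA): stratified causality assessment.

A validated k-SNP disease signature names one exact genotype state per
SNP, but its carriers are only one cell of the full 3^k grid of genotype
assignments over those SNPs (the *expanded genotype signatures*).  EGA
asks whether a *critical SNP*'s minor allele shifts disease odds
consistently once the genotypes of the interacting SNPs are held fixed.

For every assignment of the interacting SNPs (a *block*), the EGA odds
ratio divides the disease odds of patients carrying one (or two) copies
of the critical minor allele by the odds of patients homozygous wild
type at the critical SNP.  Expanded signatures seen in fewer than 15
patients are excluded, no continuity correction is applied (a zero cell
makes the block incomplete), and signatures of more than 3 SNPs are
rejected outright: at 81 or 243 cells a cohort of ~1,300 leaves too few
patients per cell for directionality to be interpretable.

The per-critical-SNP pattern over all complete blocks is classified into
seven categories (universally / SNP-specific / combination-specific,
each causative or protective, plus ambiguous).  The original category
definitions are descriptive prose; the decision rules implemented here
are this package's formalization of them, documented in the methods note.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact

from .errors import UnsupportedOrderError, ValidationError
from .matrix import MISSING, GenotypeMatrix
from .phenotype import CohortAssignment
from .stats import odds_ratio_2x2, woolf_ci

logger = logging.getLogger(__name__)

CATEGORIES = (
    "universally_causative",
    "universally_protective",
    "snp_specific_causative",
    "snp_specific_protective",
    "combination_specific_causative",
    "combination_specific_protective",
    "ambiguous",
)


@dataclass(frozen=True)
class ExpandedGenotype:
    """One full genotype assignment over a signature's SNPs, with counts."""

    assignment: tuple[tuple[str, int], ...]  # ((snp_id, state), ...) in input SNP order
    case_count: int
    control_count: int
    included: bool  # False when case+control < min_patients

    @property
    def total(self) -> int:
        return self.case_count + self.control_count

    @property
    def odds(self) -> float:
        if self.control_count == 0:
            return math.inf if self.case_count else math.nan
        return self.case_count / self.control_count

    def state_of(self, snp_id: str) -> int:
        for s, st in self.assignment:
            if s == snp_id:
                return st
        raise KeyError(snp_id)


@dataclass(frozen=True)
class EgaBlock:
    """One matched comparison: critical minor-allele state vs wild type.

    ``interacting`` fixes the genotype of every non-critical SNP;
    ``critical_state`` is 1 (heterozygous) or 2 (homozygous minor).
    """

    critical_snp: str
    critical_state: int
    interacting: tuple[tuple[str, int], ...]
    variant_cases: int
    variant_controls: int
    wt_cases: int
    wt_controls: int
    complete: bool
    reason: str = ""

    @property
    def wt_odds(self) -> float:
        return self.wt_cases / self.wt_controls if self.wt_controls else math.nan

    @property
    def variant_odds(self) -> float:
        return self.variant_cases / self.variant_controls if self.variant_controls else math.nan

    @property
    def ega_odds_ratio(self) -> float:
        return ega_odds_ratio(
            self.variant_cases, self.variant_controls, self.wt_cases, self.wt_controls
        )[0]

    @property
    def ci95(self) -> tuple[float, float]:
        return woolf_ci(
            self.variant_cases, self.variant_controls, self.wt_cases, self.wt_controls
        )

    @property
    def direction(self) -> int:
        """+1 causative (OR > 1), -1 protective (OR < 1), 0 neutral/undefined."""
        if not self.complete:
            return 0
        orr = self.ega_odds_ratio
        if math.isnan(orr) or orr == 1.0:
            return 0
        return 1 if orr > 1.0 else -1


def ega_odds_ratio(
    variant_cases: int, variant_controls: int, wt_cases: int, wt_controls: int
) -> tuple[float, tuple[float, float]]:
    """EGA odds ratio (variant odds / wild-type odds) with Woolf 95% CI.

    No continuity correction: any zero cell yields NaN.
    """
    if min(variant_cases, variant_controls, wt_cases, wt_controls) <= 0:
        return float("nan"), (float("nan"), float("nan"))
    orr = odds_ratio_2x2(variant_cases, variant_controls, wt_cases, wt_controls)
    return float(orr), woolf_ci(variant_cases, variant_controls, wt_cases, wt_controls)


def n_expanded(k: int) -> int:
    """Number of expanded genotype signatures for a k-SNP signature (3^k)."""
    if k < 1:
        raise ValueError("signature order must be >= 1")
    return 3**k


def enumerate_expanded(
    matrix: GenotypeMatrix,
    cohort: CohortAssignment,
    signature_snps: list[str],
    min_patients: int = 15,
) -> list[ExpandedGenotype]:
    """All 3^k genotype assignments over the signature's SNPs, with counts.

    Counts use complete-genotype case/control samples only (any missing
    component genotype drops the sample).  Assignments carried by fewer
    than ``min_patients`` samples are flagged ``included=False`` but still
    returned, so that counts always partition the complete-genotype cohort.
    """
    k = len(signature_snps)
    if k == 0 or len(set(signature_snps)) != k:
        raise ValidationError("signature SNPs must be non-empty and distinct")
    if k > 3:
        raise UnsupportedOrderError(
            f"expanded-genotype enumeration limited to 3 SNPs (got {k}): with 3^{k} "
            "cells the per-cell sample counts are too small for stable odds"
        )
    cc = sorted(cohort.cases + cohort.controls)
    row_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    rows = [row_index[s] for s in cc]
    cols = [matrix.snp_index(s) for s in signature_snps]
    states = matrix.states[np.ix_(rows, cols)]
    complete = (states != MISSING).all(axis=1)
    states = states[complete]
    case = (cohort.labels.reindex(cc).to_numpy() == "case")[complete]

    code = np.zeros(states.shape[0], dtype=np.int64)
    for c in range(k):
        code = code * 3 + states[:, c]
    n_cells = 3**k
    case_counts = np.bincount(code[case], minlength=n_cells)
    ctrl_counts = np.bincount(code[~case], minlength=n_cells)

    out = []
    for cell, assignment in enumerate(itertools.product((0, 1, 2), repeat=k)):
        ca, co = int(case_counts[cell]), int(ctrl_counts[cell])
        out.append(
            ExpandedGenotype(
                assignment=tuple(zip(signature_snps, assignment)),
                case_count=ca,
                control_count=co,
                included=(ca + co) >= min_patients,
            )
        )
    return out


def ega_blocks(expanded: list[ExpandedGenotype], critical_snp: str) -> list[EgaBlock]:
    """Group expanded signatures by interacting assignment and form EGA blocks.

    Within each interacting assignment the homozygous-wild-type (state 0)
    expanded signature is the denominator; the heterozygous and homozygous
    minor expanded signatures give one block each.  A block is complete
    only when both sides are included (>= the patient floor) and all four
    cells are positive.
    """
    snps = [s for s, _ in expanded[0].assignment]
    if critical_snp not in snps:
        raise ValidationError(f"critical SNP {critical_snp!r} not in signature")
    groups: dict[tuple[tuple[str, int], ...], dict[int, ExpandedGenotype]] = {}
    for eg in expanded:
        inter = tuple((s, st) for s, st in eg.assignment if s != critical_snp)
        groups.setdefault(inter, {})[eg.state_of(critical_snp)] = eg
    blocks = []
    for inter in sorted(groups, key=lambda t: tuple(st for _, st in t)):
        cells = groups[inter]
        wt = cells.get(0)
        for crit_state in (1, 2):
            var = cells.get(crit_state)
            if wt is None or var is None:
                continue
            complete = True
            reason = ""
            if not (wt.included and var.included):
                complete, reason = False, "below patient floor"
            elif min(var.case_count, var.control_count, wt.case_count, wt.control_count) == 0:
                complete, reason = False, "zero cell"
            blocks.append(
                EgaBlock(
                    critical_snp=critical_snp,
                    critical_state=crit_state,
                    interacting=inter,
                    variant_cases=var.case_count,
                    variant_controls=var.control_count,
                    wt_cases=wt.case_count,
                    wt_controls=wt.control_count,
                    complete=complete,
                    reason=reason,
                )
            )
    return blocks


@dataclass(frozen=True)
class EgaClassification:
    category: str
    n_complete_blocks: int
    insufficient_data: bool = False
    detail: str = ""


def _consistent(directions: list[int]) -> int:
    """Shared direction of a block list; 0 if mixed, all-neutral or empty."""
    nonzero = [d for d in directions if d != 0]
    if not nonzero:
        return 0
    return nonzero[0] if len(set(nonzero)) == 1 else 0


def classify_ega(blocks: list[EgaBlock]) -> EgaClassification:
    """Assign the causality category for one critical SNP.

    Decision rules, applied in order over the complete blocks (an OR of
    exactly 1 counts as consistent with either direction):

    1. fewer than 2 complete blocks -> ambiguous (insufficient data);
    2. every block shares one direction -> universally causative/protective;
    3. blocks where an interacting SNP (or any interacting SNP) carries a
       minor allele share direction D and all remaining blocks are opposite
       or neutral -> SNP-specific, labelled by D (the direction the critical
       minor allele shows when it co-occurs with the interacting minor allele);
    4. exactly one block carries direction D and more than one block is
       opposite -> combination-specific, labelled by D;
    5. otherwise ambiguous.
    """
    complete = [b for b in blocks if b.complete]
    if len(complete) < 2:
        return EgaClassification("ambiguous", len(complete), insufficient_data=True,
                                 detail="fewer than 2 complete blocks")
    dirs = [b.direction for b in complete]

    uni = _consistent(dirs)
    if uni != 0 and all(d in (0, uni) for d in dirs):
        cat = "universally_causative" if uni > 0 else "universally_protective"
        return EgaClassification(cat, len(complete))

    # SNP-specific: stratify by minor-allele presence at one interacting SNP,
    # then by presence at any interacting SNP.
    inter_snps = [s for s, _ in complete[0].interacting]

    def strata(pred) -> tuple[list[int], list[int]]:
        present = [b.direction for b in complete if pred(b)]
        absent = [b.direction for b in complete if not pred(b)]
        return present, absent

    conditions = [(s, (lambda b, s=s: dict(b.interacting)[s] >= 1)) for s in inter_snps]
    if len(inter_snps) > 1:
        conditions.append(
            ("any", lambda b: any(st >= 1 for _, st in b.interacting))
        )
    for name, pred in conditions:
        present, absent = strata(pred)
        d = _consistent(present)
        if d != 0 and present and all(x in (0, -d) for x in absent):
            cat = "snp_specific_causative" if d > 0 else "snp_specific_protective"
            return EgaClassification(cat, len(complete), detail=f"stratified on {name}")

    # combination-specific needs a *set* of genotypes at multiple interacting
    # SNPs; with a single interactor any one-cell effect is just noise
    if len(inter_snps) >= 2:
        pos = sum(1 for d in dirs if d > 0)
        neg = sum(1 for d in dirs if d < 0)
        if pos == 1 and neg > 1:
            return EgaClassification("combination_specific_causative", len(complete))
        if neg == 1 and pos > 1:
            return EgaClassification("combination_specific_protective", len(complete))
    return EgaClassification("ambiguous", len(complete))


def pooled_allele_test(
    matrix: GenotypeMatrix,
    cohort: CohortAssignment,
    critical_snp: str,
    stratum: dict[str, tuple[int, ...]] | None = None,
    carrier_states: tuple[int, ...] = (1, 2),
) -> tuple[float, float]:
    """Carrier vs wild-type odds ratio within a stratum of interacting genotypes.

    ``stratum`` maps interacting SNP ids to the tuple of states a sample may
    carry there (``None`` = whole cohort).  Returns ``(odds_ratio, fisher_p)``
    for carriers of the critical minor allele (states in ``carrier_states``)
    against homozygous wild type, two-sided.
    """
    cc = sorted(cohort.cases + cohort.controls)
    row_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    rows = [row_index[s] for s in cc]
    case = cohort.labels.reindex(cc).to_numpy() == "case"
    crit = matrix.states[rows, matrix.snp_index(critical_snp)]
    keep = crit != MISSING
    if stratum:
        for snp_id, allowed in stratum.items():
            col = matrix.states[rows, matrix.snp_index(snp_id)]
            keep &= np.isin(col, allowed)
    if not keep.any():
        raise ValidationError("empty stratum")
    carrier = np.isin(crit, carrier_states) & keep
    wt = (crit == 0) & keep
    a = int((carrier & case).sum())
    b = int((carrier & ~case).sum())
    c = int((wt & case).sum())
    d = int((wt & ~case).sum())
    orr = odds_ratio_2x2(a, b, c, d)
    p = float(fisher_exact([[a, b], [c, d]])[1])
    return float(orr), p


def write_ega_report(blocks: list[EgaBlock], classification: EgaClassification, path) -> None:
    """Tab-separated block table plus a JSON classification footer sidecar."""
    import json

    import pandas as pd

    rows = []
    for b in blocks:
        lo, hi = b.ci95
        rows.append(
            {
                "interacting": ";".join(f"{s}:{st}" for s, st in b.interacting),
                "critical_state": b.critical_state,
                "variant_cases": b.variant_cases,
                "variant_controls": b.variant_controls,
                "wt_cases": b.wt_cases,
                "wt_controls": b.wt_controls,
                "ega_odds_ratio": b.ega_odds_ratio,
                "ci95_low": lo,
                "ci95_high": hi,
                "complete": b.complete,
                "reason": b.reason,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    with open(str(path) + ".json", "w") as fh:
        json.dump(
            {
                "category": classification.category,
                "n_complete_blocks": classification.n_complete_blocks,
                "insufficient_data": classification.insufficient_data,
                "detail": classification.detail,
            },
            fh,
            indent=1,
        )
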