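"""Synthetic genotype/phenotype cohorts with planted combinatorial signatures.

The generator emulates the structure of a genotyped post-viral cohort at
desk scale so the whole pipeline is testable end to end: biallelic SNPs
with Hardy-Weinberg genotypes at minor-allele frequencies drawn from a
configurable range, optional multi-population structure via the
Balding-Nichols model (per-population allele frequencies drawn from a
Beta distribution around the ancestral frequency with a single
divergence parameter), uniform genotype missingness, disease status from
a multiplicative odds model in which *planted signatures* -- exact 2-3
SNP genotype combinations -- multiply a sample's disease odds, and
pre/post symptom scores whose summed change separates diseased from
healthy samples.

The planted effects are interaction-only by default: the odds multiplier
applies to carriers of the full genotype combination, so the component
SNPs are individually near-null and the signal is genuinely
combinatorial.  The returned truth set (planted features, target
multipliers, realized carrier odds ratios) is sufficient to score
recovery by any mining run.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix
from .phenotype import SymptomTable

logger = logging.getLogger(__name__)

#: Symptom inventory: 7 symptoms in 3 groups, each scored 0-10.
DEFAULT_SYMPTOMS: dict[str, str] = {
    "breathlessness": "respiratory",
    "cough": "respiratory",
    "fatigue": "fatigue",
    "muscle_pain": "fatigue",
    "post_exertional_malaise": "fatigue",
    "anxiety": "mental_health",
    "low_mood": "mental_health",
}

SCALE_MAX = 10


@dataclass(frozen=True)
class PlantedSignature:
    """An exact genotype combination that multiplies carriers' disease odds."""

    features: tuple[tuple[int, int], ...]  # (snp index, genotype state)
    odds_multiplier: float = 5.0
    #: allele frequency forced at the component SNPs; ~0.4 puts a
    #: 3-heterozygote combination near 10% carrier prevalence (0.48^3).
    forced_freq: float | None = 0.4

    def __post_init__(self) -> None:
        snps = [i for i, _ in self.features]
        if len(set(snps)) != len(snps):
            raise ValueError("planted feature SNPs must be distinct")
        if self.odds_multiplier <= 0:
            raise ValueError("odds_multiplier must be positive")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``populations`` lists (fraction, divergence) pairs; divergence is the
    Balding-Nichols Fst-like parameter in [0, 1).  ``population_odds``
    optionally multiplies baseline disease odds per population, which
    makes ancestry a genuine confounder for the screening tests.
    """

    n_samples: int = 2000
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    populations: tuple[tuple[float, float], ...] = ((1.0, 0.0),)
    planted: tuple[PlantedSignature, ...] = (
        PlantedSignature(features=((0, 1), (1, 1), (2, 1)), odds_multiplier=5.0),
    )
    baseline_odds: float = 0.2
    population_odds: tuple[float, ...] | None = None
    #: per-SNP allele-frequency overrides, one frequency per population
    forced_freqs: dict[int, tuple[float, ...]] = field(default_factory=dict)
    case_change_mean: float = 10.0
    control_change_mean: float = 1.0
    change_sd: float = 2.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        fr = sum(f for f, _ in self.populations)
        if abs(fr - 1.0) > 1e-9:
            raise ValueError("population fractions must sum to 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for _, fst in self.populations:
            if not 0.0 <= fst < 1.0:
                raise ValueError("divergence parameter must lie in [0, 1)")
        if self.population_odds is not None and len(self.population_odds) != len(self.populations):
            raise ValueError("population_odds must match populations")


@dataclass
class SyntheticDataset:
    """Bundle of everything one simulation run produced."""

    matrix: GenotypeMatrix
    ancestry: pd.Series  # population index per sample
    disease: pd.Series  # boolean per sample
    truth: dict
    symptoms: SymptomTable | None = None


# ----------------------------------------------------------------------

def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, pd.Series]:
    """Draw genotypes under Hardy-Weinberg with optional population structure.

    Per SNP an ancestral frequency is uniform on ``maf_range``; each
    population's frequency is a Balding-Nichols draw
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` (the ancestral frequency itself when
    F = 0), and genotypes are Binomial(2, p).  Missing calls are sprinkled
    uniformly at ``missing_rate``.  Returns the matrix and the per-sample
    population index.
    """
    rng = rng or np.random.default_rng(config.random_seed)
    n, m = config.n_samples, config.n_snps
    n_pops = len(config.populations)
    fractions = np.array([f for f, _ in config.populations])
    pop = rng.choice(n_pops, size=n, p=fractions)

    ancestral = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    for sig in config.planted:
        if sig.forced_freq is not None:
            for j, _ in sig.features:
                ancestral[j] = sig.forced_freq
    freqs = np.empty((n_pops, m))
    for k, (_, fst) in enumerate(config.populations):
        if fst == 0.0:
            freqs[k] = ancestral
        else:
            shape = (1.0 - fst) / fst
            freqs[k] = rng.beta(ancestral * shape, (1.0 - ancestral) * shape)
    for j, per_pop in config.forced_freqs.items():
        freqs[:, j] = np.asarray(per_pop, dtype=float)

    states = rng.binomial(2, freqs[pop, :]).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        states[mask] = MISSING

    sample_ids = [f"s{i:05d}" for i in range(n)]
    snp_ids = [f"snp{j:05d}" for j in range(m)]
    snp_map = pd.DataFrame(
        {
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1, dtype=np.int64) * 10_000,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "minor_is_alt": [True] * m,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    matrix = GenotypeMatrix(sample_ids, snp_ids, states, snp_map)
    return matrix, pd.Series(pop, index=sample_ids, name="population")


def assign_disease(
    matrix: GenotypeMatrix,
    config: SimulationConfig,
    ancestry: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, dict]:
    """Draw disease labels from the multiplicative odds model.

    Per sample ``odds = baseline * (population multiplier) * product of
    matched planted multipliers``; disease ~ Bernoulli(odds / (1 + odds)).
    The report records, per planted signature, the carrier count and the
    realized carrier-vs-non-carrier odds ratio next to its target.
    """
    rng = rng or np.random.default_rng(config.random_seed + 1)
    n = matrix.n_samples
    odds = np.full(n, config.baseline_odds, dtype=float)
    if config.population_odds is not None:
        if ancestry is None:
            raise ValueError("population_odds requires the ancestry series")
        odds *= np.asarray(config.population_odds, dtype=float)[ancestry.to_numpy()]
    carrier_masks = []
    for sig in config.planted:
        carrier = np.ones(n, dtype=bool)
        for j, state in sig.features:
            carrier &= matrix.states[:, j] == state
        carrier_masks.append(carrier)
        odds[carrier] *= sig.odds_multiplier
    prob = odds / (1.0 + odds)
    disease = rng.random(n) < prob

    report = {"baseline_odds": config.baseline_odds, "planted": []}
    for sig, carrier in zip(config.planted, carrier_masks):
        a = int((disease & carrier).sum())
        b = int((~disease & carrier).sum())
        c = int((disease & ~carrier).sum())
        d = int((~disease & ~carrier).sum())
        realized = (a / b) / (c / d) if min(b, c, d) > 0 else math.nan
        report["planted"].append(
            {
                "features": [
                    [matrix.snp_ids[j], int(state)] for j, state in sig.features
                ],
                "target_multiplier": sig.odds_multiplier,
                "carriers": int(carrier.sum()),
                "realized_carrier_or": realized,
            }
        )
    return pd.Series(disease, index=matrix.sample_ids, name="disease"), report


def synthesize_symptoms(
    disease: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    ancestry: pd.Series | None = None,
) -> SymptomTable:
    """Draw pre/post symptom scores whose summed change tracks disease.

    Pre scores are Binomial(10, 0.15) integers per symptom.  A per-sample
    total deterioration (normal with disease-dependent mean) is spread over
    the symptoms, rounded, added to the pre scores and clipped to the 0-10
    scale.  Healthy samples get a small mean change so both cohort rules
    (upper-quartile cases, sub-median non-negative controls) are exercised.
    """
    rng = rng or np.random.default_rng(config.random_seed + 2)
    symptoms = list(DEFAULT_SYMPTOMS)
    n = len(disease)
    k = len(symptoms)
    is_case = disease.to_numpy(dtype=bool)
    pre = rng.binomial(SCALE_MAX, 0.15, size=(n, k))
    mean = np.where(is_case, config.case_change_mean, config.control_change_mean)
    total = np.rint(rng.normal(mean, config.change_sd)).astype(int)
    weights = rng.dirichlet(np.full(k, 4.0), size=n)
    # spread the integer total over symptoms without rounding it away
    per_symptom = np.zeros((n, k), dtype=int)
    for i in range(n):
        if total[i] != 0:
            alloc = rng.multinomial(abs(total[i]), weights[i])
            per_symptom[i] = np.sign(total[i]) * alloc
    post = np.clip(pre + per_symptom, 0, SCALE_MAX)

    data = {}
    for c, sym in enumerate(symptoms):
        data[f"{sym}_pre"] = pre[:, c]
        data[f"{sym}_post"] = post[:, c]
    frame = pd.DataFrame(data, index=disease.index)
    if ancestry is not None:
        frame["ancestry"] = ancestry.reindex(disease.index).to_numpy()
    return SymptomTable(frame, dict(DEFAULT_SYMPTOMS))


def simulate_dataset(config: SimulationConfig, with_symptoms: bool = True) -> SyntheticDataset:
    """Genotypes, ancestry, disease labels, truth set and (optional) symptoms."""
    rng = np.random.default_rng(config.random_seed)
    matrix, ancestry = simulate_genotypes(config, rng)
    disease, report = assign_disease(matrix, config, ancestry, rng)
    truth = {
        "random_seed": config.random_seed,
        "n_samples": config.n_samples,
        "n_snps": config.n_snps,
        **report,
    }
    symptoms = synthesize_symptoms(disease, config, rng, ancestry) if with_symptoms else None
    return SyntheticDataset(matrix, ancestry, disease, truth, symptoms)


def recovery_fraction(truth: dict, signatures) -> float:
    """Fraction of planted signatures matched by a mined signature.

    A planted signature counts as recovered when some mined signature's
    features contain every planted (snp, state) feature.
    """
    planted = truth.get("planted", [])
    if not planted:
        return float("nan")
    mined = [set(sig.features) for sig in signatures]
    hit = 0
    for entry in planted:
        want = {(snp, int(state)) for snp, state in entry["features"]}
        if any(want <= feats for feats in mined):
            hit += 1
    return hit / len(planted)


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
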