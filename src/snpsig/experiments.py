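"""Reference simulation experiments at desk scale.

Each function runs one self-contained synthetic experiment under the
package's standard study conditions and returns plain numbers, so that
the validation suite and the reproduction script exercise exactly the
same pipeline with exactly the same generator settings.  Problem sizes
(samples, SNPs, permutations, beam width) are fixed here once; they are
chosen so a single desk CPU completes each experiment in seconds while
keeping the planted effects at the odds-ratio scale the method is meant
to detect.
"""

from __future__ import annotations

import numpy as np

from .ega import classify_ega, ega_blocks, enumerate_expanded
from .mining import MEMBER, MiningConfig, match_signature, mine_signatures
from .phenotype import CohortAssignment
from .secondary import ancestry_confounder_check
from .simulate import PlantedSignature, SimulationConfig, recovery_fraction, simulate_dataset


def _cohort(ds) -> CohortAssignment:
    return CohortAssignment.from_labels(ds.disease.to_numpy(), ds.matrix.sample_ids)


def null_mining_fdp(seed: int) -> dict:
    """Mine a null cohort (no planted effects): every validation is false.

    1,000 samples x 500 SNPs, pair search (beam 30), 199 permutations.
    Returns the number of candidates, validations and the realized
    false-discovery proportion (V / max(R, 1); here R == V).
    """
    cfg = SimulationConfig(
        n_samples=1000, n_snps=500, planted=(), baseline_odds=0.5,
        missing_rate=0.01, random_seed=seed,
    )
    ds = simulate_dataset(cfg, with_symptoms=False)
    mcfg = MiningConfig(max_order=2, beam_width=30, n_permutations=199, random_seed=seed)
    sigs = mine_signatures(ds.matrix, _cohort(ds), mcfg)
    n_validated = sum(s.validated for s in sigs)
    return {
        "n_candidates": len(sigs),
        "n_validated": n_validated,
        "fdp": n_validated / max(n_validated, 1),
    }


def planted_recovery(seed: int) -> dict:
    """Mine a cohort with one planted 3-SNP heterozygote signature.

    2,000 samples x 500 SNPs; the component SNPs sit at allele frequency
    0.4 so the full combination covers ~10% of samples (0.48^3), with a
    5-fold odds multiplier on top of baseline odds 0.2.  Triplet search
    (beam 150), 49 validation permutations.
    """
    planted = PlantedSignature(features=((0, 1), (1, 1), (2, 1)), odds_multiplier=5.0)
    cfg = SimulationConfig(
        n_samples=2000, n_snps=500, planted=(planted,), baseline_odds=0.2,
        missing_rate=0.01, random_seed=seed,
    )
    ds = simulate_dataset(cfg, with_symptoms=False)
    mcfg = MiningConfig(max_order=3, beam_width=150, n_permutations=49, random_seed=seed)
    validated = [s for s in mine_signatures(ds.matrix, _cohort(ds), mcfg) if s.validated]
    return {
        "recovered": recovery_fraction(ds.truth, validated) == 1.0,
        "realized_carrier_or": ds.truth["planted"][0]["realized_carrier_or"],
        "n_validated": len(validated),
    }


def ega_scenario(kind: str, seed: int, n_samples: int = 5000) -> str:
    """Plant a known causality pattern for a 2-SNP signature and classify it.

    ``kind='universal_protective'``: the critical SNP's minor allele
    multiplies odds by 0.4 regardless of the interacting genotype.
    ``kind='snp_specific_protective'``: the minor allele multiplies odds
    by 0.3 when the interacting SNP carries a minor allele but by 2.0
    when the interacting SNP is wild type.  Returns the assigned category.
    """
    planted = []
    for crit_state in (1, 2):
        for inter_state in (0, 1, 2):
            if kind == "universal_protective":
                mult = 0.4
            elif kind == "snp_specific_protective":
                mult = 0.3 if inter_state >= 1 else 2.0
            else:
                raise ValueError(f"unknown scenario {kind!r}")
            planted.append(
                PlantedSignature(
                    features=((0, crit_state), (1, inter_state)),
                    odds_multiplier=mult,
                    forced_freq=0.45,
                )
            )
    cfg = SimulationConfig(
        n_samples=n_samples, n_snps=10, planted=tuple(planted), baseline_odds=0.5,
        missing_rate=0.0, random_seed=seed,
    )
    ds = simulate_dataset(cfg, with_symptoms=False)
    cohort = _cohort(ds)
    expanded = enumerate_expanded(ds.matrix, cohort, ["snp00000", "snp00001"])
    return classify_ega(ega_blocks(expanded, "snp00000")).category


def confounder_scenario(kind: str, seed: int) -> str:
    """Run the ancestry screen on a confounded or a genuine signature.

    ``kind='confounded'``: two diverged populations, disease risk driven by
    population (odds 0.15 vs 0.6) and a single-SNP signature whose carrier
    frequency differs sharply between populations (0.05 vs 0.5) -- the
    membership association is pure ancestry.  ``kind='balanced'``: equal
    population risk and a genuinely causal planted pair (odds x4).
    Returns the screen's verdict, "pass" or "fail".
    """
    if kind == "confounded":
        cfg = SimulationConfig(
            n_samples=2000, n_snps=30, planted=(), missing_rate=0.0,
            populations=((0.5, 0.05), (0.5, 0.05)),
            population_odds=(0.15, 0.6),
            forced_freqs={0: (0.05, 0.5)},
            random_seed=seed,
        )
        features = [("snp00000", 1)]
    elif kind == "balanced":
        cfg = SimulationConfig(
            n_samples=2000, n_snps=30, missing_rate=0.0,
            planted=(PlantedSignature(features=((2, 1), (3, 1)), odds_multiplier=4.0),),
            populations=((0.5, 0.05), (0.5, 0.05)),
            population_odds=(0.2, 0.2),
            random_seed=seed,
        )
        features = [("snp00002", 1), ("snp00003", 1)]
    else:
        raise ValueError(f"unknown scenario {kind!r}")
    ds = simulate_dataset(cfg, with_symptoms=False)
    membership = match_signature(ds.matrix, features) == MEMBER
    (result,) = ancestry_confounder_check(
        {"sig": membership}, _cohort(ds), ds.ancestry, ds.matrix.sample_ids
    )
    return result.verdict
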