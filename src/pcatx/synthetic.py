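"""Synthetic two-group expression cohorts with planted, known-truth effects.

The generator emulates the statistical structure of a radical-prostatectomy
cohort of 1152 patients (596 African-American men, 556 European-American men)
compared at the clinical and transcriptomic level.  Clinical covariates are
drawn per group from the published marginal distributions of the study's
baseline table; expression is Gaussian on the log scale with optional planted
per-gene group shifts, planted gene-set activity shifts, and covariate-linked
confounding shifts, so downstream estimators can be validated against known
ground truth.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GROUP1_LABEL = "AAM"
GROUP0_LABEL = "EAM"

# Baseline-table category counts per group.  Keys are covariate column names;
# missing values (pT, CAPRA-S availability differs from the cohort total) are
# tracked separately so generated tables reproduce per-variable analyzed n.
TABLE1_COUNTS: dict[str, dict[str, dict[str, int]]] = {
    "grade_group": {
        GROUP1_LABEL: {"1": 35, "2": 333, "3": 131, "4": 49, "5": 48},
        GROUP0_LABEL: {"1": 18, "2": 306, "3": 150, "4": 30, "5": 52},
    },
    "pt_stage": {
        GROUP1_LABEL: {"T2": 322, "T3a": 130, "T3b": 88, "T4": 16},
        GROUP0_LABEL: {"T2": 323, "T3a": 144, "T3b": 61, "T4": 2},
    },
    "pn_stage": {
        GROUP1_LABEL: {"N1": 21, "N0": 27, "NX": 548},
        GROUP0_LABEL: {"N1": 20, "N0": 24, "NX": 512},
    },
    "capra_s": {
        GROUP1_LABEL: {"Low": 62, "Intermediate": 126, "High": 89},
        GROUP0_LABEL: {"Low": 146, "Intermediate": 161, "High": 54},
    },
}

GROUP_SIZES = {GROUP1_LABEL: 596, GROUP0_LABEL: 556}

# Log-normal PSA parameters back-solved from the published median and IQR
# (median 7.9, IQR 5.6-12 ng/ml in group 1; 6.5, 4.8-10 in group 0).
PSA_LOGNORMAL = {
    GROUP1_LABEL: (math.log(7.9), math.log(12.0 / 5.6) / (2 * 0.674489750196)),
    GROUP0_LABEL: (math.log(6.5), math.log(10.0 / 4.8) / (2 * 0.674489750196)),
}


def table1_marginals() -> dict[str, dict[str, dict[str, float]]]:
    """Per-covariate, per-group category proportions from the baseline table.

    Proportions are over the non-missing samples of each covariate, so they
    sum to 1 per covariate and group.  Missing-data rates (pT and CAPRA-S are
    unavailable for a subset of each group) are returned under the pseudo-level
    ``__missing_rate__`` keyed dict of the same structure via
    :func:`table1_missing_rates`.
    """
    out: dict[str, dict[str, dict[str, float]]] = {}
    for cov, groups in TABLE1_COUNTS.items():
        out[cov] = {}
        for grp, counts in groups.items():
            total = sum(counts.values())
            out[cov][grp] = {level: c / total for level, c in counts.items()}
    return out


def table1_missing_rates() -> dict[str, dict[str, float]]:
    """Fraction of each group missing each covariate in the baseline table."""
    rates: dict[str, dict[str, float]] = {}
    for cov, groups in TABLE1_COUNTS.items():
        rates[cov] = {}
        for grp, counts in groups.items():
            observed = sum(counts.values())
            rates[cov][grp] = 1.0 - observed / GROUP_SIZES[grp]
    return rates


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Parameters
    ----------
    n_group1, n_group0
        Sample counts for the two groups (defaults: the study's 596 / 556).
    covariate_marginals
        ``{covariate: {group_label: {level: probability}}}``.  Defaults to the
        published baseline-table proportions.
    n_genes
        Number of genes simulated.
    planted_effects
        ``{gene_id: delta}`` mean shifts (log-expression units) added to
        group-1 samples for those genes.
    planted_sets
        ``[(set_name, [gene_ids], shift)]`` activity shifts added to every
        listed gene in group-1 samples.
    noise_sd
        Standard deviation of the Gaussian noise on log expression.
    confounding
        ``{covariate: {level: shift}}`` expression shifts applied to all genes
        of samples carrying that covariate level, used to exercise covariate
        adjustment.
    missing_rates
        ``{covariate: {group_label: rate}}`` probability that a covariate is
        missing; defaults to the baseline-table missingness.
    seed
        Integer seed for the single PRNG stream.
    """

    n_group1: int = 596
    n_group0: int = 556
    covariate_marginals: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=table1_marginals
    )
    n_genes: int = 2000
    planted_effects: Mapping[str, float] = field(default_factory=dict)
    planted_sets: Sequence[tuple[str, Sequence[str], float]] = field(default_factory=tuple)
    noise_sd: float = 1.0
    confounding: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    missing_rates: Mapping[str, Mapping[str, float]] = field(default_factory=table1_missing_rates)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 <= 0 or self.n_group0 <= 0:
            raise ValueError("group sizes must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for cov, groups in self.covariate_marginals.items():
            for grp, probs in groups.items():
                vals = list(probs.values())
                if any(p < 0 for p in vals):
                    raise ValueError(f"negative probability in {cov}/{grp}")
                if abs(sum(vals) - 1.0) > 1e-9:
                    raise ValueError(
                        f"probabilities for covariate {cov!r} group {grp!r} "
                        f"sum to {sum(vals):.6g}, not 1"
                    )


@dataclass
class SyntheticCohort:
    """A generated cohort: expression, clinical table, and planted truth."""

    expression: pd.DataFrame  # genes x samples, log scale
    clinical: pd.DataFrame  # one row per sample
    truth: dict

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.clinical["sample_id"]):
            raise ValueError("expression columns and clinical sample_id disagree")


def _sample_covariate(
    rng: np.random.Generator,
    n: int,
    probs: Mapping[str, float],
    missing_rate: float,
) -> np.ndarray:
    levels = list(probs)
    draws = rng.choice(levels, size=n, p=[probs[l] for l in levels])
    out = draws.astype(object)
    if missing_rate > 0:
        out[rng.random(n) < missing_rate] = None
    return out


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort deterministically from ``spec`` (seed included).

    Genes without planted effects are identically distributed in both groups
    conditional on covariates; a gene with planted effect ``delta`` has its
    group-1 mean shifted by ``delta`` on the log-expression scale.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_group1 + spec.n_group0
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    groups = np.array([GROUP1_LABEL] * spec.n_group1 + [GROUP0_LABEL] * spec.n_group0)

    clinical = pd.DataFrame({"sample_id": sample_ids, "group": groups})
    for cov, by_group in spec.covariate_marginals.items():
        col = np.empty(n, dtype=object)
        for grp in (GROUP1_LABEL, GROUP0_LABEL):
            mask = groups == grp
            miss = spec.missing_rates.get(cov, {}).get(grp, 0.0)
            col[mask] = _sample_covariate(rng, int(mask.sum()), by_group[grp], miss)
        clinical[cov] = col

    # PSA: log-normal per group, parameters matched to the published
    # median/IQR; age: Gaussian from the published mean and IQR width.
    psa = np.empty(n)
    age = np.empty(n)
    for grp, (mu, sigma) in PSA_LOGNORMAL.items():
        mask = groups == grp
        psa[mask] = np.exp(rng.normal(mu, sigma, int(mask.sum())))
    for grp, mean in ((GROUP1_LABEL, 63.3), (GROUP0_LABEL, 64.0)):
        mask = groups == grp
        age[mask] = rng.normal(mean, 7.2, int(mask.sum()))
    clinical["psa"] = np.round(psa, 2)
    clinical["age"] = np.round(age, 1)

    genes = [f"G{i:05d}" for i in range(1, spec.n_genes + 1)]
    gene_index = {g: i for i, g in enumerate(genes)}
    expr = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))

    is_group1 = groups == GROUP1_LABEL
    for gene, delta in spec.planted_effects.items():
        if gene not in gene_index:
            raise ValueError(f"planted effect names unknown gene {gene!r}")
        expr[gene_index[gene], is_group1] += delta
    for set_name, set_genes, shift in spec.planted_sets:
        for gene in set_genes:
            if gene not in gene_index:
                raise ValueError(f"planted set {set_name!r} names unknown gene {gene!r}")
            expr[gene_index[gene], is_group1] += shift

    for cov, shifts in spec.confounding.items():
        values = clinical[cov].to_numpy()
        for level, shift in shifts.items():
            expr[:, values == str(level)] += shift

    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=sample_ids)
    truth = {
        "planted_effects": dict(spec.planted_effects),
        "planted_sets": [
            (name, list(gs), float(shift)) for name, gs, shift in spec.planted_sets
        ],
        "confounding": copy.deepcopy({k: dict(v) for k, v in spec.confounding.items()}),
        "seed": spec.seed,
    }
    return SyntheticCohort(expression=expression, clinical=clinical, truth=truth)


# ---------------------------------------------------------------------------
# Synthetic model fixtures: plausible gene sets, weighted signatures, drug
# models and immune panels drawn from a cohort's gene universe, for exercising
# the scoring stages with known inputs.


def synthetic_gene_sets(
    genes: Sequence[str], n_sets: int, set_size: int, seed: int = 0
) -> list:
    """Random disjoint-ish gene sets sampled from ``genes``."""
    from pcatx.pathway import GeneSet

    rng = np.random.default_rng(seed)
    return [
        GeneSet(
            name=f"SET_{i + 1:02d}",
            genes=tuple(rng.choice(genes, size=set_size, replace=False)),
            description="synthetic gene set",
        )
        for i in range(n_sets)
    ]


def synthetic_signatures(
    genes: Sequence[str], n_signatures: int = 19, sig_size: int = 15, seed: int = 0
) -> list:
    """Random weighted prognostic-signature stand-ins (weights in [-1, 1])."""
    from pcatx.pathway import SignatureModel

    rng = np.random.default_rng(seed)
    sigs = []
    for i in range(n_signatures):
        chosen = rng.choice(genes, size=sig_size, replace=False)
        weights = {g: float(w) for g, w in zip(chosen, rng.uniform(-1, 1, sig_size))}
        sigs.append(SignatureModel(name=f"SIG_{i + 1:02d}", weights=weights, scale=True))
    return sigs


def synthetic_drug_models(
    genes: Sequence[str], n_drugs: int = 89, genes_per_drug: int = 20, seed: int = 0
) -> list:
    """Random correlation-weighted drug response models.

    Correlations are drawn uniformly from [0.3, 0.9] with random sign but a
    dominant-sign majority so the signed-sum denominator stays well away from
    zero, as real most-correlated-gene panels do.
    """
    from pcatx.drug_response import DrugResponseModel

    rng = np.random.default_rng(seed)
    models = []
    for i in range(n_drugs):
        chosen = rng.choice(genes, size=genes_per_drug, replace=False)
        mags = rng.uniform(0.3, 0.9, genes_per_drug)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        flip = rng.random(genes_per_drug) < 0.15  # minority opposite-sign genes
        cors = sign * np.where(flip, -mags, mags)
        models.append(
            DrugResponseModel(
                drug=f"DRUG_{i + 1:03d}",
                gene_correlations={g: float(c) for g, c in zip(chosen, cors)},
            )
        )
    return models


def synthetic_immune_panel(genes: Sequence[str], size: int = 124, seed: int = 0) -> list[str]:
    """A synthetic immune/microenvironment panel of the study's size (124)."""
    rng = np.random.default_rng(seed)
    return [str(g) for g in rng.choice(genes, size=size, replace=False)]
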