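"""Synthetic genotype, trait and Ct data with the structure the pipeline assumes.

Genotypes arise as random unions of two gametes drawn independently from a
specified haplotype-frequency vector (random mating, so Hardy-Weinberg
holds at the haplotype level); the true phase of every individual is kept
in :class:`SimTruth` for estimator-recovery tests.  Traits follow the
fixed-effects linear model the association stage fits:

    Y = baseline + effect(class) + age + dam_age + season + sire + N(0, σ)

with covariates assigned uniformly at random and independent of genotype
(a separable design; confounding can be injected for negative tests by
passing per-level covariate effects).  Ct tables emulate a multi-tissue
qPCR panel: reference genes flat across tissues in expectation, target
shifted by −log2(relative expression).

Defaults reproduce the study conditions of the bovine SIRT2 panel this
pipeline was built around: n = 468 cows, two-locus haplotype frequencies
(0.621, 0.279, 0.095, 0.005), nine body-size traits with baselines equal
to the published CC-class LS means and residual SDs chosen so the LS-mean
standard errors at the published class sizes match the published order of
magnitude (plausible, not published, values), 3 age classes, 3 dam-age
classes, 2 seasons, 10 sires, and a 13-tissue × 3-bull expression design.

The packaged in-study genotype counts (the ``paper_fixture``) are also
defined here: per-locus classes 374/94/0 and 192/202/74 (n = 468), the
five diplotype classes 188/168/34/18/56 (464 individuals), and the joint
two-locus table they imply, in which the 4 remaining individuals are
forced into the (CT, CC) class by the single-locus marginals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    BODY_TRAITS,
    CtTable,
    GenotypeTable,
    LocusDef,
    TraitTable,
    canonical_call,
    genotype_label,
)
from .haplotypes import Haplotype, JointGenotypeCounts

LOCI = (LocusDef("g.19501C>T", ("C", "T")), LocusDef("g.19518C>T", ("C", "T")))

#: Two-locus haplotype frequencies of the study population (C-C, C-T, T-T, T-C).
STUDY_HAP_FREQS: dict[Haplotype, float] = {
    ("C", "C"): 0.621,
    ("C", "T"): 0.279,
    ("T", "T"): 0.095,
    ("T", "C"): 0.005,
}

#: Published CC-class LS means, used as trait baselines (cm; BF cm; ULA cm²).
TRAIT_BASELINES = {
    "BL": 132.608, "WH": 119.222, "RL": 41.664, "HW": 38.286, "CD": 58.345,
    "CC": 161.993, "PBW": 18.409, "BF": 0.873, "ULA": 45.188,
}

#: Published CC-class standard errors; residual SDs are back-calculated as
#: SE·sqrt(374) so simulated SEs land at the published magnitude.
_CC_CLASS_SES = {
    "BL": 0.478, "WH": 0.481, "RL": 0.201, "HW": 0.258, "CD": 0.315,
    "CC": 0.734, "PBW": 0.142, "BF": 0.014, "ULA": 0.673,
}
TRAIT_RESIDUAL_SD = {
    t: se * math.sqrt(374) for t, se in _CC_CLASS_SES.items()
}

#: The 13 sampled tissue types of the expression panel.
TISSUES = (
    "heart", "liver", "spleen", "lung", "kidney", "muscle",
    "subcutaneous_fat", "rumen", "reticulum", "omasum", "abomasum",
    "small_intestine", "large_intestine",
)


@dataclass
class SimConfig:
    """All knobs of the generator, with study-condition defaults."""

    n: int = 468
    loci: tuple[LocusDef, ...] = LOCI
    hap_freqs: Mapping[Haplotype, float] = field(
        default_factory=lambda: dict(STUDY_HAP_FREQS)
    )
    #: trait -> {class label -> additive effect in trait units}; class labels
    #: are genotype classes at ``effect_locus`` ("CC", "CT", ...) or
    #: diplotype strings ("CC|CT" = sorted joined haplotypes) depending on
    #: ``effect_on``.
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    effect_on: str = "genotype"      # or "diplotype"
    effect_locus: str = "g.19501C>T"
    n_age_classes: int = 3
    n_dam_age_classes: int = 3
    n_sires: int = 10
    season_p_spring: float = 0.5
    baselines: Mapping[str, float] = field(
        default_factory=lambda: dict(TRAIT_BASELINES)
    )
    residual_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(TRAIT_RESIDUAL_SD)
    )
    #: per-level covariate shifts, e.g. {"age": {"age1": -0.5}}; default null
    covariate_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.hap_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if any(sd <= 0 for sd in self.residual_sd.values()):
            raise ValueError("residual SDs must be positive")


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset."""

    hap_pairs: list[tuple[Haplotype, Haplotype]]
    covariates: Optional[pd.DataFrame] = None
    effects: Optional[Mapping[str, Mapping[str, float]]] = None
    covariate_effects: Optional[Mapping[str, Mapping[str, float]]] = None

    def diplotype_label(self, i: int) -> str:
        a, b = sorted("".join(h) for h in self.hap_pairs[i])
        return f"{a}|{b}"


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeTable, SimTruth]:
    """Draw unphased genotypes as unions of two gametes (random mating)."""
    rng = np.random.default_rng([cfg.seed, 0])
    haps = list(cfg.hap_freqs)
    probs = np.array([cfg.hap_freqs[h] for h in haps], dtype=float)
    if np.any(probs < 0):
        raise ValueError("haplotype frequencies must be non-negative")
    gametes = rng.choice(len(haps), size=(cfg.n, 2), p=probs)
    sample_ids = [f"s{i + 1:04d}" for i in range(cfg.n)]
    calls = np.empty((cfg.n, len(cfg.loci)), dtype=object)
    pairs = []
    for i in range(cfg.n):
        h1, h2 = haps[gametes[i, 0]], haps[gametes[i, 1]]
        pairs.append((h1, h2))
        for j in range(len(cfg.loci)):
            calls[i, j] = canonical_call(h1[j], h2[j])
    return GenotypeTable(sample_ids, list(cfg.loci), calls), SimTruth(pairs)


def simulate_traits(cfg: SimConfig, truth: SimTruth) -> TraitTable:
    """Generate the trait/covariate table from the fixed-effects model."""
    rng = np.random.default_rng([cfg.seed, 1])
    n = len(truth.hap_pairs)
    sample_ids = [f"s{i + 1:04d}" for i in range(n)]
    cov = pd.DataFrame(
        {
            "age": rng.choice(
                [f"age{k + 1}" for k in range(cfg.n_age_classes)], size=n
            ),
            "dam_age": rng.choice(
                [f"dam{k + 1}" for k in range(cfg.n_dam_age_classes)], size=n
            ),
            "season": rng.choice(
                ["spring", "fall"],
                size=n,
                p=[cfg.season_p_spring, 1 - cfg.season_p_spring],
            ),
            "sire": rng.choice(
                [f"sire{k + 1:02d}" for k in range(cfg.n_sires)], size=n
            ),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    locus_j = [l.name for l in cfg.loci].index(cfg.effect_locus)
    labels = []
    for i in range(n):
        if cfg.effect_on == "diplotype":
            labels.append(truth.diplotype_label(i))
        else:
            h1, h2 = truth.hap_pairs[i]
            labels.append(
                genotype_label(canonical_call(h1[locus_j], h2[locus_j]))
            )
    data = cov.copy()
    traits = list(cfg.baselines)
    for trait in traits:
        eff = cfg.effects.get(trait, {})
        y = np.full(n, float(cfg.baselines[trait]))
        for i, lab in enumerate(labels):
            y[i] += eff.get(lab, 0.0)
        for cname, level_effects in cfg.covariate_effects.items():
            for lvl, e in level_effects.items():
                y += np.where(cov[cname] == lvl, e, 0.0)
        y += rng.normal(0.0, cfg.residual_sd[trait], size=n)
        data[trait] = y
    truth.covariates = cov
    truth.effects = {t: dict(cfg.effects.get(t, {})) for t in traits}
    truth.covariate_effects = {
        c: dict(v) for c, v in cfg.covariate_effects.items()
    }
    return TraitTable(
        data, trait_cols=traits, covariate_cols=["age", "dam_age", "season", "sire"]
    )


def simulate_ct(
    n_tissues: int = 13,
    n_subjects: int = 3,
    profile: Optional[Mapping[str, float]] = None,
    noise_sd: float = 0.15,
    seed: int = 0,
    target: str = "SIRT2",
    refs: Sequence[str] = ("ACTB", "RPS9", "GAPDH"),
    n_tech_reps: int = 3,
) -> CtTable:
    """Simulate a tissue-panel qPCR experiment in triplicate.

    *profile* maps tissue -> relative expression (linear scale); reference
    genes are flat across tissues in expectation.  Default tissues are the
    13-tissue bovine panel; extra tissues get generic names.
    """
    rng = np.random.default_rng([seed, 2])
    tissues = list(TISSUES[:n_tissues]) + [
        f"tissue{k + 1}" for k in range(max(0, n_tissues - len(TISSUES)))
    ]
    if profile is None:
        profile = {t: 1.0 for t in tissues}
    ref_base = {g: 20.0 + 2.0 * k for k, g in enumerate(refs)}
    target_base = 26.0
    rows = []
    for t in tissues:
        rel = profile.get(t, 1.0)
        if rel <= 0:
            raise ValueError(f"relative expression must be positive ({t})")
        for s in range(n_subjects):
            subj = f"b{s + 1}"
            shift = rng.normal(0.0, noise_sd)  # per-run additive shift
            for g in refs:
                mu = ref_base[g] + shift
                for r in range(n_tech_reps):
                    rows.append(
                        (t, subj, g, str(r + 1), mu + rng.normal(0, noise_sd))
                    )
            mu = target_base - math.log2(rel) + shift
            for r in range(n_tech_reps):
                rows.append(
                    (t, subj, target, str(r + 1), mu + rng.normal(0, noise_sd))
                )
    return CtTable(
        pd.DataFrame(rows, columns=["unit", "subject", "gene", "rep", "ct"])
    )


# ---------------------------------------------------------------------------
# packaged in-study counts

#: Per-locus genotype-class counts of the study population (n = 468).
STUDY_GENOTYPE_COUNTS = {
    "g.19501C>T": {"CC": 374, "CT": 94, "TT": 0},
    "g.19518C>T": {"CC": 192, "CT": 202, "TT": 74},
}

#: Published diplotype class sizes (464 of the 468 individuals).
STUDY_DIPLOTYPE_SIZES = {
    "Hap1/Hap1": 188,
    "Hap1/Hap2": 168,
    "Hap1/Hap3": 34,
    "Hap2/Hap2": 18,
    "Hap2/Hap3": 56,
}


def paper_fixture() -> tuple[
    JointGenotypeCounts, dict[str, dict[str, int]], dict[str, int]
]:
    """The packaged in-study counts.

    Returns the two-locus joint genotype table, the per-locus genotype
    counts, and the diplotype class sizes.  The joint table is a
    derivation: the five published diplotype classes pin down six of the
    joint cells, and the single-locus marginals force the remaining 4
    individuals into the (CT, CC) class.
    """
    C, T = "C", "T"
    joint = {
        ((C, C), (C, C)): 188,   # Hap1/Hap1
        ((C, C), (C, T)): 168,   # Hap1/Hap2
        ((C, C), (T, T)): 18,    # Hap2/Hap2
        ((C, T), (C, C)): 4,     # Hap1/Hap4 (forced by marginals)
        ((C, T), (C, T)): 34,    # Hap1/Hap3 (dominant phase)
        ((C, T), (T, T)): 56,    # Hap2/Hap3
    }
    jg = JointGenotypeCounts(list(LOCI), joint)
    return jg, {k: dict(v) for k, v in STUDY_GENOTYPE_COUNTS.items()}, dict(
        STUDY_DIPLOTYPE_SIZES
    )


def genotype_table_from_joint(jg: JointGenotypeCounts) -> GenotypeTable:
    """Expand joint genotype-class counts into an individual-level table."""
    rows = []
    ids = []
    i = 0
    for cls, count in sorted(jg.counts.items()):
        for _ in range(count):
            i += 1
            ids.append(f"s{i:04d}")
            rows.append(cls)
    arr = np.empty((len(ids), len(jg.loci)), dtype=object)
    for i, row in enumerate(rows):
        for j, pair in enumerate(row):
            arr[i, j] = pair
    return GenotypeTable(ids, list(jg.loci), arr)
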