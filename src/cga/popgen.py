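"""Per-locus descriptive population genetics for biallelic SNPs.

Implements the classical single-locus summary used in livestock
candidate-gene studies: allele frequencies from allele counts, Nei's gene
diversity (expected heterozygosity) ``He = 1 - Σ p_i²``, the effective
allele number ``Ne = 1/Σ p_i²``, Botstein's polymorphism information
content ``PIC = 1 - Σ p_i² - Σ_{i<j} 2 p_i² p_j²`` (for two alleles,
``He - 2p²q²``), and the Hardy-Weinberg χ² goodness-of-fit test with the
fixed critical values 5.991 (α = 0.05) and 9.21 (α = 0.01).

Conventions: unobserved genotype classes stay in the χ² sum with O = 0, no
continuity correction is applied, and significance is judged against the
fixed critical values above rather than a recomputed degrees-of-freedom
quantile — the convention under which published genotype-count tables of
this kind reproduce exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import GenotypeTable

#: Fixed χ² critical values (df = 2 convention).
CHI2_CRIT_05 = 5.991
CHI2_CRIT_01 = 9.21

#: PIC classification cutoffs; boundary values go to the higher class.
PIC_LOW = 0.25
PIC_HIGH = 0.50


@dataclass
class LocusSummary:
    """All per-locus statistics for one biallelic SNP."""

    locus: str
    genotype_counts: dict[str, int]
    n: int
    allele_freqs: dict[str, float]
    He: float
    Ne: float
    PIC: float
    pic_class: str
    chi2: float
    expected_counts: dict[str, float]
    hwe_verdict: str


def allele_frequencies(genotype_counts: Mapping[str, int]) -> dict[str, float]:
    """Allele frequencies from genotype-class counts via allele counting.

    ``freq(a) = (2·hom_a + het_a) / 2n``; classes are two-character labels
    like ``"CC"``/``"CT"``.
    """
    total = sum(genotype_counts.values())
    if total <= 0:
        raise ValueError("total genotype count must be positive")
    if any(c < 0 for c in genotype_counts.values()):
        raise ValueError("genotype counts must be non-negative")
    counts: dict[str, float] = {}
    for label, n in genotype_counts.items():
        a, b = label[0], label[1]
        counts[a] = counts.get(a, 0) + n
        counts[b] = counts.get(b, 0) + n
    return {a: c / (2 * total) for a, c in sorted(counts.items())}


def gene_heterozygosity(freqs: Mapping[str, float]) -> float:
    """Nei's gene diversity He = 1 − Σ p_i²."""
    p = np.asarray(list(freqs.values()), dtype=float)
    _check_simplex(p)
    return float(1.0 - np.sum(p**2))


def effective_allele_number(freqs: Mapping[str, float]) -> float:
    """Effective allele number Ne = 1 / Σ p_i²."""
    p = np.asarray(list(freqs.values()), dtype=float)
    _check_simplex(p)
    return float(1.0 / np.sum(p**2))


def pic(freqs: Mapping[str, float]) -> tuple[float, str]:
    """Botstein's polymorphism information content and its class.

    Returns ``(PIC, class)`` where class is ``low`` (< 0.25),
    ``intermediate`` (0.25–0.50) or ``high`` (> 0.50); boundary values are
    assigned to the higher class.
    """
    p = np.asarray(list(freqs.values()), dtype=float)
    _check_simplex(p)
    sum_sq = np.sum(p**2)
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * p[i] ** 2 * p[j] ** 2
    value = float(1.0 - sum_sq - cross)
    if value < PIC_LOW:
        klass = "low"
    elif value < PIC_HIGH:
        klass = "intermediate"
    else:
        klass = "high"
    return value, klass


def hwe_chisq(
    genotype_counts: Mapping[str, int],
) -> tuple[float, dict[str, float], str]:
    """Hardy-Weinberg χ² goodness-of-fit test at one biallelic locus.

    Expected counts are ``(p²n, 2pqn, q²n)``; the sum runs over all three
    genotype classes including unobserved ones.  The verdict compares the
    statistic to the fixed critical values 5.991 and 9.21.
    """
    freqs = allele_frequencies(genotype_counts)
    alleles = sorted(freqs)
    if len(alleles) > 2:
        raise ValueError("hwe_chisq supports biallelic loci only")
    n = sum(genotype_counts.values())
    if len(alleles) == 1:
        a = alleles[0]
        warnings.warn(f"monomorphic locus ({a}); chi2 defined as 0")
        return 0.0, {a + a: float(n)}, "not_rejected_0.05"
    a, b = alleles
    p, q = freqs[a], freqs[b]
    expected = {a + a: p * p * n, a + b: 2 * p * q * n, b + b: q * q * n}
    chi2 = 0.0
    for label, e in expected.items():
        o = genotype_counts.get(label, 0)
        if e > 0:
            chi2 += (o - e) ** 2 / e
    if chi2 >= CHI2_CRIT_01:
        verdict = "rejected_0.01"
    elif chi2 >= CHI2_CRIT_05:
        verdict = "rejected_0.05"
    else:
        verdict = "not_rejected_0.05"
    return float(chi2), expected, verdict


def locus_summary(table: GenotypeTable, locus: str) -> LocusSummary:
    """Full per-locus summary; missing calls are excluded from n."""
    counts = table.genotype_counts(locus)
    n = sum(counts.values())
    if n == 0:
        raise ValueError(f"locus {locus!r} has no non-missing calls")
    freqs = allele_frequencies(counts)
    he = gene_heterozygosity(freqs)
    ne = effective_allele_number(freqs)
    pic_val, pic_class = pic(freqs)
    chi2, expected, verdict = hwe_chisq(counts)
    return LocusSummary(
        locus=locus,
        genotype_counts=dict(counts),
        n=n,
        allele_freqs=freqs,
        He=he,
        Ne=ne,
        PIC=pic_val,
        pic_class=pic_class,
        chi2=chi2,
        expected_counts=expected,
        hwe_verdict=verdict,
    )


def summary_table(table: GenotypeTable) -> pd.DataFrame:
    """Per-locus summaries for every locus, as a tidy frame."""
    rows = []
    for loc in table.loci:
        s = locus_summary(table, loc.name)
        row: dict[str, object] = {"locus": s.locus, "n": s.n}
        for label, c in s.genotype_counts.items():
            row[f"n_{label}"] = c
            row[f"freq_{label}"] = c / s.n
        for allele, f in s.allele_freqs.items():
            row[f"p_{allele}"] = f
        row.update(
            chi2=s.chi2, PIC=s.PIC, pic_class=s.pic_class,
            He=s.He, Ne=s.Ne, hwe_verdict=s.hwe_verdict,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _check_simplex(p: np.ndarray) -> None:
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies must sum to 1, got {p}")
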