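"""EM haplotype-frequency inference, linkage disequilibrium, diplotypes.

Unphased multi-locus genotypes are phase-ambiguous whenever an individual
is heterozygous at two or more loci.  The classical expectation-
maximization estimator apportions each ambiguous genotype among its
compatible ordered haplotype pairs with weight proportional to the product
of current haplotype frequencies, then re-estimates frequencies from the
expected gamete counts; the observed-data multinomial log-likelihood is
non-decreasing at every step.

From the fitted two-locus haplotype frequencies the pairwise LD measures
are::

    D   = f_AB − pA·pB
    D'  = |D| / Dmax,  Dmax = min(pA(1−pB), (1−pA)pB)      if D > 0
                       Dmax = min(pA·pB, (1−pA)(1−pB))      if D < 0
    r²  = D² / (pA(1−pA)·pB(1−pB))

with A, B the designated (reference) alleles.  Rare haplotypes may be
dropped at a frequency cutoff (0.05 in the source study), and each sample
receives a most-probable haplotype pair (diplotype) with its posterior.

With ``h`` heterozygous loci a genotype has ``2^(h−1)`` unordered phase
configurations; enumeration is practical up to roughly 12 heterozygous
loci per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Optional, Sequence

import numpy as np

from .datamodel import MISSING, GenotypeTable, LocusDef, canonical_call

Haplotype = tuple[str, ...]
GenotypeClass = tuple[tuple[str, str], ...]


@dataclass
class JointGenotypeCounts:
    """Counts of multi-locus genotype classes (one unordered pair per locus)."""

    loci: list[LocusDef]
    counts: dict[GenotypeClass, int]

    def __post_init__(self) -> None:
        canon: dict[GenotypeClass, int] = {}
        for cls, n in self.counts.items():
            if n < 0:
                raise ValueError("genotype counts must be non-negative")
            if len(cls) != len(self.loci):
                raise ValueError(
                    f"class {cls} has {len(cls)} loci, expected {len(self.loci)}"
                )
            key = tuple(canonical_call(*pair) for pair in cls)
            for pair, loc in zip(key, self.loci):
                if not set(pair) <= loc.allele_set:
                    raise ValueError(
                        f"alleles {pair} not valid for locus {loc.name}"
                    )
            canon[key] = canon.get(key, 0) + n
        self.counts = canon

    @property
    def n_individuals(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_table(
        cls, table: GenotypeTable, loci: Optional[Sequence[str]] = None
    ) -> tuple["JointGenotypeCounts", int]:
        """Tally joint classes from a genotype table.

        Samples with a missing call at any involved locus are excluded;
        the number excluded is returned alongside the counts.
        """
        names = [l.name for l in table.loci] if loci is None else list(loci)
        idx = [table.locus_index(n) for n in names]
        defs = [table.loci[j] for j in idx]
        counts: dict[GenotypeClass, int] = {}
        skipped = 0
        for i in range(table.n_samples):
            calls = tuple(table.calls[i, j] for j in idx)
            if any(c is MISSING for c in calls):
                skipped += 1
                continue
            counts[calls] = counts.get(calls, 0) + 1
        return cls(defs, counts), skipped


@dataclass
class EMResult:
    """Fitted haplotype frequencies with the optimisation trace.

    ``haplotypes`` covers all 2^L possible allele strings (zero-frequency
    ones included); ``hap_names`` labels them Hap1, Hap2, ... in order of
    descending fitted frequency.
    """

    loci: list[LocusDef]
    haplotypes: list[Haplotype]
    frequencies: np.ndarray
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    hap_names: dict[Haplotype, str] = field(init=False)

    def __post_init__(self) -> None:
        order = np.argsort(-self.frequencies, kind="stable")
        self.hap_names = {
            self.haplotypes[k]: f"Hap{r + 1}" for r, k in enumerate(order)
        }

    def freq_map(self) -> dict[Haplotype, float]:
        return {h: float(f) for h, f in zip(self.haplotypes, self.frequencies)}

    def freq_of(self, hap: str | Haplotype) -> float:
        hap = tuple(hap)
        return float(self.frequencies[self.haplotypes.index(hap)])


@dataclass
class LDResult:
    """Pairwise linkage disequilibrium between two biallelic loci."""

    D: float
    Dprime: float
    r2: float
    pA: float
    pB: float


@dataclass
class DiplotypeCall:
    """Most-probable haplotype pair for one sample."""

    sample_id: str
    pair: tuple[Haplotype, Haplotype]
    posterior: float
    all_pairs: dict[tuple[Haplotype, Haplotype], float]
    label: str


def _enumerate_haplotypes(loci: Sequence[LocusDef]) -> list[Haplotype]:
    return [tuple(h) for h in product(*(sorted(l.alleles) for l in loci))]


def _ordered_resolutions(cls: GenotypeClass) -> list[tuple[Haplotype, Haplotype]]:
    """All ordered (gamete-1, gamete-2) phasings of a genotype class."""
    per_locus = []
    for a, b in cls:
        per_locus.append([(a, b)] if a == b else [(a, b), (b, a)])
    out = []
    for combo in product(*per_locus):
        hap1 = tuple(x[0] for x in combo)
        hap2 = tuple(x[1] for x in combo)
        out.append((hap1, hap2))
    return out


def em_haplotype_frequencies(
    jg: JointGenotypeCounts,
    tol: float = 1e-8,
    max_iter: int = 1000,
    init: str = "marginal",
) -> EMResult:
    """Estimate population haplotype frequencies by EM.

    Parameters
    ----------
    jg
        Multi-locus genotype-class counts (≥ 1 individual, ≥ 2 loci).
    tol
        Convergence tolerance: stop when the largest absolute frequency
        change and the log-likelihood change both fall below it.
    max_iter
        Iteration cap; exceeding it flags the result not-converged.
    init
        ``"marginal"`` (product of single-locus allele frequencies, the
        default) or ``"uniform"``.
    """
    if len(jg.loci) < 2:
        raise ValueError("EM requires at least two loci")
    n = jg.n_individuals
    if n == 0:
        raise ValueError("EM requires at least one individual")
    haps = _enumerate_haplotypes(jg.loci)
    index = {h: k for k, h in enumerate(haps)}
    # resolutions per class, as index pairs
    classes = list(jg.counts.items())
    resolutions = [
        [(index[a], index[b]) for a, b in _ordered_resolutions(cls)]
        for cls, _ in classes
    ]
    weights = np.array([c for _, c in classes], dtype=float)

    if init == "uniform":
        f = np.full(len(haps), 1.0 / len(haps))
    elif init == "marginal":
        marg: list[dict[str, float]] = []
        for j, loc in enumerate(jg.loci):
            cnt: dict[str, float] = {a: 0.0 for a in loc.alleles}
            for cls, c in classes:
                cnt[cls[j][0]] += c
                cnt[cls[j][1]] += c
            tot = sum(cnt.values())
            marg.append({a: v / tot for a, v in cnt.items()})
        f = np.array(
            [np.prod([marg[j][h[j]] for j in range(len(jg.loci))]) for h in haps]
        )
        # guard against a zero start locking haplotypes out
        f = np.maximum(f, 1e-12)
        f /= f.sum()
    else:
        raise ValueError(f"unknown init {init!r}")

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expected = np.zeros_like(f)
        ll = 0.0
        for (cls, count), res in zip(classes, resolutions):
            probs = np.array([f[i] * f[j] for i, j in res])
            norm = probs.sum()
            ll += count * np.log(norm)
            w = count * probs / norm
            for (i, j), wk in zip(res, w):
                expected[i] += wk
                expected[j] += wk
        new_f = expected / (2.0 * n)
        trace.append(float(ll))
        delta_f = float(np.max(np.abs(new_f - f)))
        delta_ll = abs(trace[-1] - trace[-2]) if len(trace) > 1 else np.inf
        f = new_f
        if delta_f < tol or delta_ll < tol:
            converged = True
            break
    return EMResult(
        loci=list(jg.loci),
        haplotypes=haps,
        frequencies=f,
        loglik_trace=trace,
        n_iter=it,
        converged=converged,
    )


def ld_measures(
    hap_freqs: Mapping[Haplotype | str, float],
    designated: Optional[tuple[str, str]] = None,
) -> LDResult:
    """Pairwise D, |D'| and r² from two-locus haplotype frequencies.

    *designated* names the allele at each locus whose haplotype defines the
    sign of D (default: the lexicographically first allele at each locus,
    i.e. the reference in C/T-style SNPs).  A monomorphic margin makes D'
    and r² undefined (NaN).
    """
    freqs = {tuple(h): float(v) for h, v in hap_freqs.items()}
    if any(len(h) != 2 for h in freqs):
        raise ValueError("ld_measures requires two-locus haplotypes")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"haplotype frequencies sum to {total}, not 1")
    alleles1 = sorted({h[0] for h in freqs})
    alleles2 = sorted({h[1] for h in freqs})
    if designated is None:
        designated = (alleles1[0], alleles2[0])
    A, B = designated
    pA = sum(v for h, v in freqs.items() if h[0] == A)
    pB = sum(v for h, v in freqs.items() if h[1] == B)
    fAB = freqs.get((A, B), 0.0)
    D = fAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        return LDResult(D=D, Dprime=float("nan"), r2=float("nan"), pA=pA, pB=pB)
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        dmax = np.nan
    dprime = 0.0 if D == 0 else abs(D) / dmax
    r2 = D * D / denom
    return LDResult(D=D, Dprime=float(dprime), r2=float(r2), pA=pA, pB=pB)


def filter_haplotypes(
    freqs: Mapping[Haplotype | str, float], cutoff: float
) -> tuple[dict[Haplotype, float], float]:
    """Drop haplotypes below a frequency cutoff.

    Returns the retained map and its summed probability; raises if nothing
    survives.
    """
    retained = {tuple(h): float(v) for h, v in freqs.items() if v >= cutoff}
    if not retained:
        raise ValueError(f"no haplotype reaches frequency cutoff {cutoff}")
    return retained, float(sum(retained.values()))


def assign_diplotypes(
    table: GenotypeTable,
    em: EMResult,
    loci: Optional[Sequence[str]] = None,
) -> tuple[list[DiplotypeCall], list[str]]:
    """Most-probable haplotype pair per sample under EM frequencies.

    Posterior over compatible unordered pairs is proportional to
    ``f_a·f_b`` (doubled when a ≠ b).  Ties break by lexicographic
    haplotype order.  Samples with a missing call at any involved locus are
    skipped; their ids are returned separately.
    """
    names = [l.name for l in em.loci] if loci is None else list(loci)
    idx = [table.locus_index(n) for n in names]
    fmap = em.freq_map()
    calls: list[DiplotypeCall] = []
    skipped: list[str] = []
    for i, sid in enumerate(table.sample_ids):
        geno = tuple(table.calls[i, j] for j in idx)
        if any(c is MISSING for c in geno):
            skipped.append(sid)
            continue
        pair_w: dict[tuple[Haplotype, Haplotype], float] = {}
        for a, b in _ordered_resolutions(geno):
            key = (a, b) if a <= b else (b, a)
            pair_w[key] = pair_w.get(key, 0.0) + fmap[a] * fmap[b]
        total = sum(pair_w.values())
        if total <= 0:
            # all compatible pairs have zero fitted frequency: fall back to
            # a uniform posterior over compatible pairs
            pair_w = {k: 1.0 for k in pair_w}
            total = float(len(pair_w))
        post = {k: w / total for k, w in pair_w.items()}
        best_p = max(post.values())
        # tie-break: among equal posteriors take the lexicographically
        # smallest pair
        pair = min(k for k, v in post.items() if v == best_p)
        names_pair = sorted(
            (em.hap_names[pair[0]], em.hap_names[pair[1]]),
            key=lambda s: int(s[3:]),
        )
        calls.append(
            DiplotypeCall(
                sample_id=sid,
                pair=pair,
                posterior=best_p,
                all_pairs=post,
                label="/".join(names_pair),
            )
        )
    return calls, skipped


def diplotype_class_counts(calls: Sequence[DiplotypeCall]) -> dict[str, int]:
    """Tally assigned diplotype labels (e.g. ``Hap1/Hap2``)."""
    out: dict[str, int] = {}
    for c in calls:
        out[c.label] = out.get(c.label, 0) + 1
    return dict(sorted(out.items()))
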