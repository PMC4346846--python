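"""Core containers for the candidate-gene pipeline.

A study consists of three tables keyed by sample identifier:

* :class:`GenotypeTable` — unordered diploid allele pairs at a handful of
  biallelic SNPs (e.g. the two 3'UTR variants g.19501C>T and g.19518C>T in
  bovine *SIRT2*).  Calls are unphased; phase is inferred downstream.
* :class:`TraitTable` — quantitative body-size traits (cm or cm²) plus
  categorical covariates (age class, dam-age class, season, sire).
* :class:`CtTable` — long-format qPCR threshold cycles per
  (unit, subject, gene, technical replicate).

Allele pairs are stored canonically (lexicographically sorted), so the
genotype class label of a call ("CC", "CT", ...) is unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid call.
MISSING: None = None

#: Canonical trait columns of the bovine body-size panel: body length,
#: withers height, rump length, hip width, chest depth, chest circumference,
#: pin bone width, backfat thickness, ultrasound loin muscle area.
BODY_TRAITS = ("BL", "WH", "RL", "HW", "CD", "CC", "PBW", "BF", "ULA")

#: Optional extra trait (hip height) accepted but not required.
OPTIONAL_TRAITS = ("HH",)

#: Default covariate columns of the fixed-effects model.
COVARIATES = ("age", "dam_age", "season", "sire")

SEASON_LEVELS = ("spring", "fall")


class DataError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass(frozen=True)
class LocusDef:
    """A biallelic locus: a name and exactly two allele symbols.

    The first allele is treated as the reference/designated allele when a
    direction is needed (e.g. signed LD).  Coordinates embedded in names
    such as ``g.19501C>T`` are opaque labels; no coordinate arithmetic is
    ever performed on them.
    """

    name: str
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]:
            raise DataError(
                f"locus {self.name!r} must have exactly two distinct alleles, "
                f"got {self.alleles!r}"
            )

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset(self.alleles)


def canonical_call(a: str, b: str) -> tuple[str, str]:
    """Return the unordered allele pair in canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)


def genotype_label(call: Optional[tuple[str, str]]) -> str:
    """Compact class label for a canonical call, '..' if missing."""
    return ".." if call is None else call[0] + call[1]


@dataclass
class GenotypeTable:
    """Samples × loci matrix of unordered diploid calls.

    ``calls`` is an object array of shape (n_samples, n_loci); each entry is
    a canonical 2-tuple of allele symbols or :data:`MISSING`.
    """

    sample_ids: list[str]
    loci: list[LocusDef]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=object)
        if self.calls.shape != (len(self.sample_ids), len(self.loci)):
            raise DataError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted(
                s for s in set(self.sample_ids) if self.sample_ids.count(s) > 1
            )
            raise DataError(f"duplicate sample ids: {dupes}")
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise DataError(f"duplicate locus names: {names}")
        for j, loc in enumerate(self.loci):
            for i, sid in enumerate(self.sample_ids):
                call = self.calls[i, j]
                if call is MISSING:
                    continue
                a, b = call
                if canonical_call(a, b) != call:
                    self.calls[i, j] = canonical_call(a, b)
                    a, b = self.calls[i, j]
                bad = {a, b} - loc.allele_set
                if bad:
                    raise DataError(
                        f"sample {sid!r}, locus {loc.name!r}: allele(s) "
                        f"{sorted(bad)} not in allele set {loc.alleles}"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def locus_index(self, name: str) -> int:
        for j, loc in enumerate(self.loci):
            if loc.name == name:
                return j
        raise KeyError(f"locus {name!r} not in table")

    def column(self, name: str) -> list[Optional[tuple[str, str]]]:
        return list(self.calls[:, self.locus_index(name)])

    def genotype_counts(self, name: str) -> dict[str, int]:
        """Observed genotype-class counts at one locus (missing excluded).

        All three biallelic classes are reported, including unobserved ones.
        """
        j = self.locus_index(name)
        loc = self.loci[j]
        a, b = sorted(loc.alleles)
        counts = {a + a: 0, a + b: 0, b + b: 0}
        for call in self.calls[:, j]:
            if call is not MISSING:
                counts[genotype_label(call)] += 1
        return counts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.loci == other.loci
            and self.calls.shape == other.calls.shape
            and all(
                x == y for x, y in zip(self.calls.ravel(), other.calls.ravel())
            )
        )


@dataclass
class TraitTable:
    """Quantitative traits and categorical covariates, indexed by sample id."""

    data: pd.DataFrame
    trait_cols: list[str]
    covariate_cols: list[str]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise DataError("duplicate sample ids in trait table")
        for col in self.trait_cols:
            if col not in self.data.columns:
                raise DataError(f"declared trait column {col!r} missing")
            vals = pd.to_numeric(self.data[col], errors="coerce")
            bad = self.data[col].notna() & vals.isna()
            if bad.any():
                raise DataError(
                    f"non-numeric value in trait column {col!r}, "
                    f"sample {self.data.index[bad][0]!r}"
                )
            if np.isinf(vals.dropna()).any():
                raise DataError(f"non-finite value in trait column {col!r}")
            self.data[col] = vals
        for col in self.covariate_cols:
            if col not in self.data.columns:
                raise DataError(f"declared covariate column {col!r} missing")
            self.data[col] = self.data[col].astype("string")
        if "season" in self.covariate_cols:
            seen = set(self.data["season"].dropna())
            bad = seen - set(SEASON_LEVELS)
            if bad:
                raise DataError(
                    f"unknown season level(s) {sorted(bad)}; "
                    f"expected one of {SEASON_LEVELS}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class CtTable:
    """Long-format qPCR threshold cycles.

    Columns: ``unit`` (tissue), ``subject`` (biological replicate),
    ``gene``, ``rep`` (technical replicate index), ``ct`` (cycles > 0).
    """

    data: pd.DataFrame

    REQUIRED = ("unit", "subject", "gene", "rep", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise DataError(f"Ct table missing column(s) {missing}")
        ct = pd.to_numeric(self.data["ct"], errors="coerce")
        if ct.isna().any():
            raise DataError("non-numeric Ct value")
        if (ct <= 0).any():
            raise DataError("Ct values must be positive cycle counts")
        self.data = self.data.assign(ct=ct)

    @property
    def units(self) -> list[str]:
        return sorted(self.data["unit"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def mean_ct(self) -> pd.DataFrame:
        """Technical replicates averaged on the Ct scale.

        Returns a frame indexed by (unit, subject) with one column per gene.
        """
        return (
            self.data.groupby(["unit", "subject", "gene"])["ct"]
            .mean()
            .unstack("gene")
        )
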