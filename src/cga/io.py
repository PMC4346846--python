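"""Readers and writers for the pipeline's tab-separated formats.

All files are UTF-8 TSV; lines starting with ``#`` are comments.  The
genotype dialect accepts ``X/Y`` or ``XY`` cells (case-sensitive allele
symbols) and the missing markers ``./.`` or ``NA``; the writer always emits
``X/Y`` and ``./.``.  An optional VCF importer accepts biallelic SNP
records, reading GT fields and discarding phase (the pipeline treats all
input as unphased).
"""

from __future__ import annotations

import re
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    CtTable,
    DataError,
    GenotypeTable,
    LocusDef,
    TraitTable,
    canonical_call,
)

_MISSING_CELLS = {"./.", ".", "NA", ""}
_CELL_RE = re.compile(r"^([^/\s])/([^/\s])$|^([^/\s])([^/\s])$")


def _parse_cell(cell: str, row: str, col: str) -> Optional[tuple[str, str]]:
    cell = cell.strip()
    if cell in _MISSING_CELLS:
        return MISSING
    m = _CELL_RE.match(cell)
    if not m:
        raise DataError(
            f"malformed genotype cell {cell!r} at sample {row!r}, locus {col!r}"
        )
    a, b = (m.group(1), m.group(2)) if m.group(1) else (m.group(3), m.group(4))
    return canonical_call(a, b)


def read_genotype_table(
    path, loci: Optional[Iterable[LocusDef]] = None
) -> GenotypeTable:
    """Read a sample × locus genotype TSV.

    Header is ``sample`` followed by one column per locus.  Allele sets are
    taken from *loci* when given (order defines the reference allele) and
    inferred from the observed alleles otherwise (sorted, so the
    lexicographically first allele acts as reference).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.columns[0] != "sample":
        raise DataError(
            f"first column must be 'sample', got {df.columns[0]!r}"
        )
    sample_ids = df["sample"].tolist()
    locus_names = list(df.columns[1:])
    calls = np.empty((len(sample_ids), len(locus_names)), dtype=object)
    for j, name in enumerate(locus_names):
        for i, sid in enumerate(sample_ids):
            calls[i, j] = _parse_cell(df.iloc[i, j + 1], sid, name)
    if loci is not None:
        defs = {d.name: d for d in loci}
        missing = [n for n in locus_names if n not in defs]
        if missing:
            raise DataError(f"no allele definition for locus column(s) {missing}")
        locus_defs = [defs[n] for n in locus_names]
    else:
        locus_defs = []
        for j, name in enumerate(locus_names):
            seen: set[str] = set()
            for call in calls[:, j]:
                if call is not MISSING:
                    seen.update(call)
            if len(seen) > 2:
                raise DataError(
                    f">2 distinct alleles {sorted(seen)} at locus {name!r}"
                )
            if len(seen) < 2:
                # monomorphic column: pad with a placeholder alternate so the
                # biallelic invariant holds
                seen.update("N")
            locus_defs.append(LocusDef(name, tuple(sorted(seen))))
    return GenotypeTable(sample_ids, locus_defs, calls)


def write_genotype_table(table: GenotypeTable, path) -> None:
    """Write a genotype table; round-trips bit-identically."""
    rows = []
    for i, sid in enumerate(table.sample_ids):
        row = {"sample": sid}
        for j, loc in enumerate(table.loci):
            call = table.calls[i, j]
            row[loc.name] = "./." if call is MISSING else f"{call[0]}/{call[1]}"
        rows.append(row)
    cols = ["sample"] + [loc.name for loc in table.loci]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_vcf_genotypes(path) -> GenotypeTable:
    """Import biallelic SNP genotypes from a VCF (requires cyvcf2).

    Phase separators are accepted but phase is discarded.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    loci: list[LocusDef] = []
    columns: list[list] = []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue  # biallelic SNPs only
        name = var.ID or f"{var.CHROM}:{var.POS}{var.REF}>{var.ALT[0]}"
        alleles = (var.REF, var.ALT[0])
        col = []
        for gt in var.genotypes:  # [a0, a1, phased]
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                col.append(MISSING)
            else:
                col.append(canonical_call(alleles[a0], alleles[a1]))
        loci.append(LocusDef(name, alleles))
        columns.append(col)
    calls = np.empty((len(sample_ids), len(loci)), dtype=object)
    for j, col in enumerate(columns):
        calls[:, j] = col
    return GenotypeTable(sample_ids, loci, calls)


def read_trait_table(
    path, trait_cols: Iterable[str], covariate_cols: Iterable[str]
) -> TraitTable:
    """Read a trait/covariate TSV with a leading ``sample`` column."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str,
        keep_default_na=False, na_values=["NA", ""],
    )
    if df.columns[0] != "sample":
        raise DataError(f"first column must be 'sample', got {df.columns[0]!r}")
    df = df.set_index("sample")
    return TraitTable(df, list(trait_cols), list(covariate_cols))


def write_trait_table(table: TraitTable, path) -> None:
    table.data.rename_axis("sample").to_csv(path, sep="\t", na_rep="NA")


def read_ct_table(path) -> CtTable:
    """Read a long-format Ct TSV (unit, subject, gene, rep, ct)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"rep": str})
    return CtTable(df)


def write_ct_table(table: CtTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def join_genotype_traits(
    genotypes: GenotypeTable,
    traits: TraitTable,
    extra: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Inner-join genotype calls with traits on sample id.

    Returns the joined frame (one genotype-class column per locus, label
    ``..`` → NaN) and a report of samples dropped from each side.  *extra*
    may carry additional per-sample columns (e.g. diplotype classes) indexed
    by sample id; samples absent from it survive with NaN.
    """
    from .datamodel import genotype_label

    gdf = pd.DataFrame(
        {
            loc.name: [
                genotype_label(c) if c is not MISSING else np.nan
                for c in genotypes.column(loc.name)
            ]
            for loc in genotypes.loci
        },
        index=pd.Index(genotypes.sample_ids, name="sample"),
    )
    common = gdf.index.intersection(traits.data.index)
    if len(common) == 0:
        raise DataError("no overlapping sample ids between genotypes and traits")
    joined = gdf.loc[common].join(traits.data.loc[common])
    if extra is not None:
        joined = joined.join(extra)
    report = {
        "genotypes_dropped": genotypes.n_samples - len(common),
        "traits_dropped": len(traits.data) - len(common),
        "joined": len(common),
    }
    return joined, report
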