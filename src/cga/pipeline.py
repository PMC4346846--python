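"""End-to-end orchestration: popgen → EM/LD → diplotypes → association.

One config object drives the whole run; every output is TSV plus a single
machine-readable JSON summary.  Stage order is fixed, a fixed seed gives a
byte-identical report bundle, and each dropped sample is accounted for in
the summary.  Any stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .association import (
    ModelSpec,
    bonferroni_threshold,
    diplotype_association,
    fit_marker_model,
)
from .datamodel import BODY_TRAITS, COVARIATES
from .expression import delta_delta_ct, expression_table, tissue_comparison
from .haplotypes import (
    JointGenotypeCounts,
    assign_diplotypes,
    diplotype_class_counts,
    em_haplotype_frequencies,
    filter_haplotypes,
    ld_measures,
)
from .io import (
    join_genotype_traits,
    read_ct_table,
    read_genotype_table,
    read_trait_table,
)
from .popgen import summary_table


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Paths, column roles and thresholds for one pipeline run."""

    genotypes: str
    traits: Optional[str] = None
    ct: Optional[str] = None
    loci: Optional[Sequence[str]] = None
    trait_cols: Sequence[str] = BODY_TRAITS
    covariate_cols: Sequence[str] = COVARIATES
    alpha: float = 0.05
    hap_cutoff: float = 0.05
    min_class_size: int = 10
    expr_target: str = "SIRT2"
    expr_refs: Sequence[str] = ("ACTB", "RPS9", "GAPDH")
    expr_calibrator: Optional[str] = None
    outdir: str = "cga_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; return the JSON-serializable summary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"tool": "cga", "version": __version__, "seed": cfg.seed}

    genotypes = _stage("read_genotypes")(_read_genotypes)(cfg)
    summary["n_samples"] = genotypes.n_samples

    pop = _stage("popgen")(summary_table)(genotypes)
    pop.to_csv(outdir / "popgen.tsv", sep="\t", index=False)

    em, ld, retained, retained_sum, dip_counts, dip_extra = _stage("haplotypes")(
        _haplotype_stage
    )(genotypes, cfg, outdir)
    summary["haplotypes"] = {
        "".join(h): float(f) for h, f in zip(em.haplotypes, em.frequencies)
    }
    summary["em_iterations"] = em.n_iter
    summary["em_converged"] = em.converged
    if ld is not None:
        summary["ld"] = {"D": ld.D, "Dprime": ld.Dprime, "r2": ld.r2}
    summary["retained_haplotype_probability"] = retained_sum
    summary["diplotype_counts"] = dip_counts
    summary["diplotype_skipped_missing"] = dip_extra

    if cfg.traits is not None:
        assoc_summary = _stage("association")(_association_stage)(
            genotypes, em, cfg, outdir
        )
        summary.update(assoc_summary)

    if cfg.ct is not None:
        expr_summary = _stage("expression")(_expression_stage)(cfg, outdir)
        summary["expression"] = expr_summary

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _read_genotypes(cfg: PipelineConfig):
    path = Path(cfg.genotypes)
    if not path.exists():
        raise FileNotFoundError(f"genotype file not found: {path}")
    return read_genotype_table(path)


def _haplotype_stage(genotypes, cfg: PipelineConfig, outdir: Path):
    jg, skipped = JointGenotypeCounts.from_table(genotypes, cfg.loci)
    em = em_haplotype_frequencies(jg)
    with open(outdir / "em_loglik.log", "w") as fh:
        for k, ll in enumerate(em.loglik_trace):
            fh.write(f"{k + 1}\t{ll:.10f}\n")
    rows = [
        {
            "haplotype": "".join(h),
            "name": em.hap_names[h],
            "frequency": float(f),
        }
        for h, f in sorted(
            zip(em.haplotypes, em.frequencies), key=lambda x: -x[1]
        )
    ]
    pd.DataFrame(rows).to_csv(outdir / "haplotypes.tsv", sep="\t", index=False)
    ld = None
    if len(em.loci) == 2:
        ld = ld_measures(em.freq_map())
        pd.DataFrame(
            [{"D": ld.D, "Dprime": ld.Dprime, "r2": ld.r2}]
        ).to_csv(outdir / "ld.tsv", sep="\t", index=False)
    retained, retained_sum = filter_haplotypes(em.freq_map(), cfg.hap_cutoff)
    calls, skipped_ids = assign_diplotypes(genotypes, em)
    pd.DataFrame(
        [
            {
                "sample": c.sample_id,
                "diplotype": c.label,
                "hap1": "".join(c.pair[0]),
                "hap2": "".join(c.pair[1]),
                "posterior": c.posterior,
            }
            for c in calls
        ]
    ).to_csv(outdir / "diplotypes.tsv", sep="\t", index=False)
    return (
        em,
        ld,
        retained,
        retained_sum,
        diplotype_class_counts(calls),
        len(skipped_ids) + skipped,
    )


def _association_stage(genotypes, em, cfg: PipelineConfig, outdir: Path):
    traits = read_trait_table(cfg.traits, cfg.trait_cols, cfg.covariate_cols)
    calls, _ = assign_diplotypes(genotypes, em)
    dip = pd.DataFrame(
        {"diplotype": {c.sample_id: c.label for c in calls}}
    ).rename_axis("sample")
    joined, join_report = join_genotype_traits(genotypes, traits, extra=dip)
    n_markers = len(genotypes.loci)
    thr = bonferroni_threshold(cfg.alpha, len(cfg.trait_cols), n_markers)
    single_rows = []
    for loc in genotypes.loci:
        for trait in cfg.trait_cols:
            res = fit_marker_model(
                joined,
                ModelSpec(trait, loc.name, tuple(cfg.covariate_cols)),
                threshold=thr,
            )
            t = res.table()
            t.insert(0, "locus", loc.name)
            t.insert(1, "trait", trait)
            single_rows.append(t)
    pd.concat(single_rows).to_csv(
        outdir / "assoc_single.tsv", sep="\t", index=False
    )
    diplo_rows = []
    dropped_classes: dict[str, int] = {}
    for trait in cfg.trait_cols:
        res, dropped_classes = diplotype_association(
            joined,
            ModelSpec(trait, "diplotype", tuple(cfg.covariate_cols)),
            min_class_size=cfg.min_class_size,
            threshold=thr,
        )
        t = res.table()
        t.insert(0, "trait", trait)
        diplo_rows.append(t)
    pd.concat(diplo_rows).to_csv(
        outdir / "assoc_diplotype.tsv", sep="\t", index=False
    )
    return {
        "join": join_report,
        "bonferroni_threshold": thr,
        "diplotype_classes_dropped": dropped_classes,
    }


def _expression_stage(cfg: PipelineConfig, outdir: Path):
    ct = read_ct_table(cfg.ct)
    calibrator = cfg.expr_calibrator
    if calibrator is None:
        raise ValueError("expr_calibrator must be set when a Ct file is given")
    res = delta_delta_ct(ct, cfg.expr_target, cfg.expr_refs, calibrator)
    try:
        letters, overall_p = tissue_comparison(res, alpha=cfg.alpha)
    except Exception:
        letters, overall_p = None, float("nan")
    expression_table(res, letters).to_csv(
        outdir / "expression.tsv", sep="\t", index=False
    )
    return {
        "calibrator": calibrator,
        "overall_p": overall_p,
        "rq": {u: float(v) for u, v in res.rq.items()},
    }
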