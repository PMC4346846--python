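"""Fixed-effects association of marker classes with quantitative traits.

The model is the classical livestock candidate-gene GLM

    Y = µ + G + age + dam_age + season + sire + e

with every term a fixed categorical effect and G either a single-marker
genotype class or a combined-genotype (diplotype) class.  For each level of
G the module reports the least-squares mean — the model prediction averaged
with *equal weight* over the levels of every other factor ("population
marginal means", the GLM-procedure convention) — with its standard error
from the coefficient covariance, an overall partial (Type III) F-test for
G, unadjusted pairwise t-tests on LS-mean contrasts, and a compact letter
display judged at a familywise Bonferroni threshold α/(n_traits·n_markers).

Sire enters as a fixed effect (matching the source model); samples with a
missing trait, factor level or covariate are dropped casewise and counted.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


class DesignError(ValueError):
    """Raised for unusable designs (aliasing, single-level factors)."""


@dataclass
class ModelSpec:
    """What to fit: one trait, one factor of interest, fixed covariates."""

    trait: str
    factor: str
    covariates: tuple[str, ...] = ("age", "dam_age", "season", "sire")


@dataclass
class AssociationResult:
    """Per-level LS means ± SE, tests, and letter groups for one model."""

    trait: str
    factor: str
    levels: list[str]                  # descending LS-mean order
    n_per_level: dict[str, int]
    lsmeans: dict[str, float]
    ses: dict[str, float]
    overall_p: float
    pairwise_p: pd.DataFrame           # symmetric, NaN diagonal
    letters: dict[str, str]
    threshold: float
    significant: bool                  # any pairwise p < threshold
    df_resid: int
    n_used: int
    n_dropped: int

    def table(self) -> pd.DataFrame:
        """Publication-style frame: level, n, LS mean, SE, letters."""
        return pd.DataFrame(
            {
                "level": self.levels,
                "n": [self.n_per_level[l] for l in self.levels],
                "lsmean": [self.lsmeans[l] for l in self.levels],
                "se": [self.ses[l] for l in self.levels],
                "letters": [self.letters[l] for l in self.levels],
                "overall_p": self.overall_p,
            }
        )


def bonferroni_threshold(alpha: float, n_traits: int, n_markers: int) -> float:
    """Familywise significance threshold α / (n_traits · n_markers)."""
    if alpha <= 0 or n_traits <= 0 or n_markers <= 0:
        raise ValueError("alpha and test counts must be positive")
    return alpha / (n_traits * n_markers)


def _build_design(
    data: pd.DataFrame, factor: str, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str], list[str], dict[str, list[str]], dict[str, np.ndarray]]:
    """Reference-coded design matrix plus LS-mean contrast rows.

    Returns (X, column names, factor levels, covariate levels, contrast row
    per factor level).  The contrast for level g sets the factor dummies to
    indicate g and every covariate dummy to 1/k for a k-level covariate —
    the equal-weight average over covariate levels.
    """
    f_levels = sorted(data[factor].dropna().unique())
    if len(f_levels) < 2:
        raise DesignError(f"factor {factor!r} has <2 observed levels: {f_levels}")
    cov_levels = {c: sorted(data[c].dropna().unique()) for c in covariates}
    cols: list[str] = ["Intercept"]
    blocks = [np.ones((len(data), 1))]
    for lvl in f_levels[1:]:
        cols.append(f"{factor}[{lvl}]")
        blocks.append((data[factor] == lvl).to_numpy(float)[:, None])
    for c in covariates:
        for lvl in cov_levels[c][1:]:
            cols.append(f"{c}[{lvl}]")
            blocks.append((data[c] == lvl).to_numpy(float)[:, None])
    X = np.hstack(blocks)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True, mode="economic")
        aliased = sorted(cols[k] for k in piv[rank:])
        raise DesignError(f"rank-deficient design; aliased column(s): {aliased}")

    contrasts: dict[str, np.ndarray] = {}
    for g in f_levels:
        c = np.zeros(X.shape[1])
        c[0] = 1.0
        for k, name in enumerate(cols):
            for lvl in f_levels[1:]:
                if name == f"{factor}[{lvl}]" and g == lvl:
                    c[k] = 1.0
        pos = 1 + len(f_levels) - 1
        for cv in covariates:
            kcv = len(cov_levels[cv])
            for _ in cov_levels[cv][1:]:
                c[pos] = 1.0 / kcv
                pos += 1
        contrasts[g] = c
    return X, cols, f_levels, cov_levels, contrasts


def _fit_one(
    X: np.ndarray,
    y: np.ndarray,
    f_levels: list[str],
    contrasts: dict[str, np.ndarray],
    n_factor_dummies: int,
) -> tuple[dict[str, float], dict[str, float], float, pd.DataFrame, int]:
    """OLS fit + LS means, SEs, overall Type III F, pairwise t p-values."""
    res = sm.OLS(y, X).fit()
    lsmeans = {g: float(contrasts[g] @ res.params) for g in f_levels}
    ses = {
        g: float(np.sqrt(contrasts[g] @ res.cov_params() @ contrasts[g]))
        for g in f_levels
    }
    # Type III partial test for the factor: with reference coding and no
    # interactions this is the joint test that its dummy coefficients vanish,
    # equivalently that all LS means are equal.
    R = np.zeros((n_factor_dummies, X.shape[1]))
    for k in range(n_factor_dummies):
        R[k, 1 + k] = 1.0
    overall_p = float(res.f_test(R).pvalue)
    pw = pd.DataFrame(np.nan, index=f_levels, columns=f_levels)
    for i, g in enumerate(f_levels):
        for h in f_levels[i + 1 :]:
            d = contrasts[g] - contrasts[h]
            p = float(res.t_test(d).pvalue)
            pw.loc[g, h] = pw.loc[h, g] = p
    return lsmeans, ses, overall_p, pw, int(res.df_resid)


def fit_marker_model(
    data: pd.DataFrame, spec: ModelSpec, threshold: float = 0.05
) -> AssociationResult:
    """Fit the fixed-effects model for one trait and one factor.

    *data* holds one row per sample with the trait, the factor and all
    covariate columns; rows with any of these missing are dropped casewise.
    *threshold* is the (possibly Bonferroni-adjusted) familywise p cutoff
    used for the letter display and the significance flag.
    """
    needed = [spec.trait, spec.factor, *spec.covariates]
    sub = data[needed].dropna()
    n_dropped = len(data) - len(sub)
    X, cols, f_levels, _, contrasts = _build_design(
        sub, spec.factor, spec.covariates
    )
    if X.shape[0] <= X.shape[1]:
        raise DesignError("no residual degrees of freedom")
    y = sub[spec.trait].to_numpy(float)
    lsmeans, ses, overall_p, pw, df_resid = _fit_one(
        X, y, f_levels, contrasts, len(f_levels) - 1
    )
    order = sorted(f_levels, key=lambda g: -lsmeans[g])
    letters = letter_grouping(pw, threshold, order)
    n_per = sub[spec.factor].value_counts().to_dict()
    sig = bool(np.nanmin(pw.to_numpy()) < threshold) if len(f_levels) > 1 else False
    return AssociationResult(
        trait=spec.trait,
        factor=spec.factor,
        levels=order,
        n_per_level={g: int(n_per.get(g, 0)) for g in order},
        lsmeans=lsmeans,
        ses=ses,
        overall_p=overall_p,
        pairwise_p=pw,
        letters=letters,
        threshold=threshold,
        significant=sig,
        df_resid=df_resid,
        n_used=len(sub),
        n_dropped=n_dropped,
    )


def fit_many_traits(
    data: pd.DataFrame,
    factor: str,
    traits: Sequence[str],
    covariates: Sequence[str] = ("age", "dam_age", "season", "sire"),
    threshold: float = 0.05,
) -> dict[str, AssociationResult]:
    """Fit one model per trait sharing a single design matrix.

    Rows missing the factor or any covariate are dropped once; rows missing
    an individual trait are dropped per trait.  Equivalent to calling
    :func:`fit_marker_model` trait by trait, but builds the design once.
    """
    base = data[[factor, *covariates]].dropna()
    results: dict[str, AssociationResult] = {}
    X_full, cols, f_levels, _, contrasts = _build_design(base, factor, covariates)
    for trait in traits:
        tv = data.loc[base.index, trait]
        mask = tv.notna().to_numpy()
        X = X_full[mask]
        y = tv.to_numpy(float)[mask]
        lsmeans, ses, overall_p, pw, df_resid = _fit_one(
            X, y, f_levels, contrasts, len(f_levels) - 1
        )
        order = sorted(f_levels, key=lambda g: -lsmeans[g])
        n_per = base.loc[mask, factor].value_counts().to_dict()
        results[trait] = AssociationResult(
            trait=trait,
            factor=factor,
            levels=order,
            n_per_level={g: int(n_per.get(g, 0)) for g in order},
            lsmeans=lsmeans,
            ses=ses,
            overall_p=overall_p,
            pairwise_p=pw,
            letters=letter_grouping(pw, threshold, order),
            threshold=threshold,
            significant=bool(np.nanmin(pw.to_numpy()) < threshold),
            df_resid=df_resid,
            n_used=int(mask.sum()),
            n_dropped=len(data) - int(mask.sum()),
        )
    return results


def diplotype_association(
    data: pd.DataFrame,
    spec: ModelSpec,
    min_class_size: int = 10,
    threshold: float = 0.05,
) -> tuple[AssociationResult, dict[str, int]]:
    """Association with combined-genotype (diplotype) classes.

    Classes smaller than *min_class_size* are dropped and reported; at
    least two classes must survive.
    """
    counts = data[spec.factor].value_counts()
    dropped = {c: int(n) for c, n in counts.items() if n < min_class_size}
    keep = data[~data[spec.factor].isin(dropped)].copy()
    surviving = keep[spec.factor].dropna().unique()
    if len(surviving) < 2:
        raise DesignError(
            f"<2 diplotype classes of size >= {min_class_size} "
            f"(dropped {dropped})"
        )
    return fit_marker_model(keep, spec, threshold=threshold), dropped


def letter_grouping(
    pairwise_p: pd.DataFrame,
    threshold: float,
    order: Optional[Sequence[str]] = None,
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Two levels share no letter iff their pairwise p is below *threshold*.
    *order* lists levels in descending-mean order (default: frame order);
    letters are assigned 'a', 'b', ... so the top-mean group gets 'a'.
    """
    levels = list(order) if order is not None else list(pairwise_p.index)
    groups: list[set[str]] = [set(levels)]
    for i, g in enumerate(levels):
        for h in levels[i + 1 :]:
            p = pairwise_p.loc[g, h]
            if pd.isna(p) or p >= threshold:
                continue
            new_groups: list[set[str]] = []
            for grp in groups:
                if g in grp and h in grp:
                    new_groups.append(grp - {g})
                    new_groups.append(grp - {h})
                else:
                    new_groups.append(grp)
            # absorb groups contained in another
            groups = [
                grp
                for k, grp in enumerate(new_groups)
                if grp
                and not any(
                    grp < other or (grp == other and k2 < k)
                    for k2, other in enumerate(new_groups)
                    if k2 != k
                )
            ]
    pos = {lvl: k for k, lvl in enumerate(levels)}
    groups.sort(key=lambda grp: tuple(sorted(pos[l] for l in grp)))
    letters = {lvl: "" for lvl in levels}
    for letter, grp in zip(string.ascii_lowercase, groups):
        for lvl in grp:
            letters[lvl] += letter
    return letters
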