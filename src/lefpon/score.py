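"""Composite genetic protective score and the multifactor logistic models.

Each significant CpG contributes 0 (hypermethylated, above the 75th
percentile), 1 (intermediate) or 2 (hypomethylated, below the 25th
percentile); the rs705379 genotype contributes 0 (TT), 1 (CT) or 2 (CC).
The sum is the composite genetic protective score (0..2k+2; with the
nine significant sites, 0..20), which is further categorised into
cohort quartiles. Model 1 regresses response on the score term alone;
Model 2 adds the covariates retained by a univariate P < 0.2 screen,
with variance inflation factors reported as the collinearity check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .stats import LogisticFit, SeparationError, fit_logistic

METHYLATION_CODE = {"high": 0, "medium": 1, "low": 2}
GENOTYPE_CODE = {"TT": 0, "CT": 1, "CC": 2}

#: the nine CpG sites significantly associated with response
SIGNIFICANT_CPGS = tuple(
    f"cg17330251_{i}" for i in (2, 3, 4, 6, 7, 8, 9, 10, 12)
)

VIF_FLAG_THRESHOLD = 5.0


@dataclass
class CompositeScore:
    patient_index: np.ndarray
    methylation_codes: pd.DataFrame  # patients x scored CpGs, values 0/1/2
    genotype_codes: np.ndarray
    score: np.ndarray  # integer sum
    quartile_category: np.ndarray  # ordinal 1..4
    quartile_cutoffs: tuple[float, float, float]


@dataclass
class MultifactorModel:
    model_id: str  # "model1" | "model2"
    fit: LogisticFit
    screened_covariates: dict[str, float]  # name -> univariate Wald P
    vif: dict[str, float]
    vif_flagged: tuple[str, ...]


def methylation_code(category: str) -> int:
    """0 for hypermethylation, 1 for intermediate, 2 for hypomethylation."""
    try:
        return METHYLATION_CODE[category]
    except KeyError:
        raise ValueError(f"unknown methylation category: {category!r}") from None


def genotype_code(genotype: str) -> int:
    """0 for TT, 1 for CT, 2 for CC (C is the protective allele)."""
    try:
        return GENOTYPE_CODE[genotype]
    except KeyError:
        raise ValueError(f"unknown genotype: {genotype!r}") from None


def composite_score(
    categories: pd.DataFrame,
    genotypes: Sequence[str],
    scored_cpgs: Sequence[str] = SIGNIFICANT_CPGS,
) -> CompositeScore:
    """Sum methylation and genotype codes into the protective score.

    Quartile categories (1..4) come from the cohort score distribution
    at its 25/50/75 percentiles (linear interpolation, same rule as the
    methylation cutoffs); a score exactly at a cutoff stays in the lower
    category.
    """
    missing = [c for c in scored_cpgs if c not in categories.columns]
    if missing:
        raise ValueError(f"missing scored CpG column(s): {missing}")
    genotypes = np.asarray(genotypes)
    if len(genotypes) != len(categories):
        raise ValueError("genotypes and categories must align")
    codes = categories[list(scored_cpgs)].apply(
        lambda col: col.map(methylation_code)
    )
    if codes.isna().any().any():
        raise ValueError("unknown methylation category among scored CpGs")
    geno_codes = np.array([genotype_code(g) for g in genotypes])
    score = codes.sum(axis=1).to_numpy() + geno_codes
    p25, p50, p75 = np.percentile(score, [25, 50, 75])
    quartile = 1 + (score > p25).astype(int) + (score > p50) + (score > p75)
    return CompositeScore(
        patient_index=np.arange(len(score)),
        methylation_codes=codes,
        genotype_codes=geno_codes,
        score=score.astype(int),
        quartile_category=quartile,
        quartile_cutoffs=(float(p25), float(p50), float(p75)),
    )


def screen_covariates(
    candidates: dict[str, Sequence[float]],
    responder_flags: Sequence[int],
    threshold: float = 0.2,
) -> dict[str, float]:
    """Univariate logistic screen: keep candidates with Wald P < threshold.

    Each candidate is fit alone against the outcome (no covariates); a
    constant or non-converging candidate is excluded with a warning.
    Returns the retained names mapped to their univariate P values.
    """
    responder = np.asarray(responder_flags, dtype=int)
    n = len(responder)
    retained: dict[str, float] = {}
    for name, values in candidates.items():
        x = np.asarray(values, dtype=float)
        if x.shape != (n,):
            raise ValueError(f"candidate {name!r} misaligned with outcome")
        if np.ptp(x) == 0:
            warnings.warn(f"candidate {name!r} is constant; excluded from screen")
            continue
        design = np.column_stack([np.ones(n), x])
        try:
            fit = fit_logistic(design, responder, names=["const", name])
        except SeparationError:
            warnings.warn(f"candidate {name!r}: separation in univariate fit; excluded")
            continue
        if not fit.converged:
            warnings.warn(f"candidate {name!r}: univariate fit did not converge; excluded")
            continue
        p = fit[name]["p"]
        if p < threshold:
            retained[name] = p
    return retained


def _vifs(design: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    out: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, name in enumerate(names):
            if name == "const":
                continue
            try:
                v = float(variance_inflation_factor(design, i))
            except Exception:
                v = float("inf")
            out[name] = v if np.isfinite(v) else float("inf")
    return out


def fit_multifactor(
    score_term: Sequence[float],
    screened: dict[str, Sequence[float]],
    responder_flags: Sequence[int],
    screened_p: Optional[dict[str, float]] = None,
    alpha: float = 0.05,
) -> tuple[MultifactorModel, MultifactorModel]:
    """Fit Model 1 (score only) and Model 2 (score + screened covariates).

    ``score_term`` is the quartile-coded (or raw) protective score.
    Variance inflation factors are computed for Model 2's predictors;
    values above 5 (or unbounded, under perfect collinearity) are
    flagged. Separation or non-convergence surfaces with the model id.
    """
    responder = np.asarray(responder_flags, dtype=int)
    score = np.asarray(score_term, dtype=float)
    n = len(responder)
    if score.shape != (n,):
        raise ValueError("score term misaligned with outcome")

    def _fit(design: np.ndarray, names: list[str], model_id: str) -> LogisticFit:
        try:
            fit = fit_logistic(design, responder, names=names, alpha=alpha)
        except SeparationError as exc:
            raise SeparationError(f"{model_id}: {exc}") from exc
        if not fit.converged:
            warnings.warn(f"{model_id}: logistic fit did not converge; "
                          "results must not be reported")
        return fit

    design1 = np.column_stack([np.ones(n), score])
    model1 = MultifactorModel(
        model_id="model1",
        fit=_fit(design1, ["const", "score"], "model1"),
        screened_covariates={},
        vif={},
        vif_flagged=(),
    )

    cov_names = list(screened)
    design2 = np.column_stack(
        [np.ones(n), score] + [np.asarray(screened[c], dtype=float) for c in cov_names]
    )
    names2 = ["const", "score"] + cov_names
    vifs = _vifs(design2, names2)
    flagged = tuple(k for k, v in vifs.items() if v > VIF_FLAG_THRESHOLD)
    if flagged:
        warnings.warn(f"model2: high collinearity (VIF > {VIF_FLAG_THRESHOLD:g}) "
                      f"for {flagged}")
    model2 = MultifactorModel(
        model_id="model2",
        fit=_fit(design2, names2, "model2"),
        screened_covariates=dict(screened_p or {}),
        vif=vifs,
        vif_flagged=flagged,
    )
    return model1, model2
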