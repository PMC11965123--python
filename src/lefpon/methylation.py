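"""Quartile-based CpG methylation analysis.

Each CpG is split at its cohort 25th/75th percentiles into low / medium /
high methylation; per-CpG association with responder status uses an
ordinal hypomethylation coding (high = 0, medium = 1, low = 2) in an
age- and sex-adjusted logistic model, plus pairwise indicator contrasts
against the low category and a chi-square on the 3x2 category-by-outcome
table. Patient-level average methylation over the 12 sites is compared
across rs705379 genotypes (median/IQR + Kruskal-Wallis) and correlated
with the DAS28 improvement (Spearman).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stats import (
    Chi2Result,
    ContingencyTable,
    LogisticFit,
    SeparationError,
    fit_logistic,
    kruskal_wallis,
    pearson_chi2,
    spearman_corr,
)

CATEGORIES = ("low", "medium", "high")
ORDINAL_CODE = {"high": 0, "medium": 1, "low": 2}  # hypomethylation coding
GENOTYPES = ("CC", "CT", "TT")


@dataclass
class CpgAssociationResult:
    cpg_id: str
    ordinal_fit: LogisticFit  # outcome ~ ordinal code + age + sex
    contrast_fit: Optional[LogisticFit]  # outcome ~ medium/high vs low + age + sex
    chi2: Optional[Chi2Result]  # None when fewer than two categories occur
    category_counts: pd.DataFrame  # categories x (responder, non_responder)
    cutoffs: tuple[float, float]

    @property
    def ordinal_or(self) -> float:
        return self.ordinal_fit["meth_code"]["or"]


@dataclass
class GenotypeMethylationSummary:
    per_genotype: dict[str, dict[str, float]]  # genotype -> n/median/q25/q75
    kruskal_h: float
    kruskal_p: float


def categorize_cpg(
    values: Sequence[float],
    q25: Optional[float] = None,
    q75: Optional[float] = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Three-level quartile categorisation of one CpG.

    low iff value < q25, high iff value > q75, medium otherwise (values
    exactly at a cutoff are medium). Percentiles use linear interpolation
    between closest order statistics. A constant vector yields all-medium
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 values to form quartiles")
    if q25 is None:
        q25 = float(np.percentile(values, 25))
    if q75 is None:
        q75 = float(np.percentile(values, 75))
    if q25 > q75:
        raise ValueError("q25 must not exceed q75")
    if np.ptp(values) == 0:
        warnings.warn("constant CpG values: all categories set to medium")
        return np.full(len(values), "medium", dtype=object), (q25, q75)
    cats = np.full(len(values), "medium", dtype=object)
    cats[values < q25] = "low"
    cats[values > q75] = "high"
    return cats, (q25, q75)


def _category_table(categories: np.ndarray, responder: np.ndarray) -> pd.DataFrame:
    counts = pd.DataFrame(
        0, index=list(CATEGORIES), columns=["responder", "non_responder"], dtype=int
    )
    for cat in CATEGORIES:
        mask = categories == cat
        counts.loc[cat, "responder"] = int(np.sum(mask & (responder == 1)))
        counts.loc[cat, "non_responder"] = int(np.sum(mask & (responder == 0)))
    return counts


def per_cpg_association(
    categories: pd.DataFrame,
    responder_flags: Sequence[int],
    age: Sequence[float],
    sex_female: Sequence[int],
    cutoffs: Optional[dict[str, tuple[float, float]]] = None,
    alpha: float = 0.05,
) -> list[CpgAssociationResult]:
    """Age/sex-adjusted association of each CpG's category with response.

    ``categories`` holds one column of low/medium/high labels per CpG.
    An empty category is collapsed into medium (with a warning) before
    the contrasts; separation errors propagate with the CpG id attached.
    """
    responder = np.asarray(responder_flags, dtype=int)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex_female, dtype=float)
    n = len(responder)
    results: list[CpgAssociationResult] = []
    for cpg in categories.columns:
        cats = np.asarray(categories[cpg], dtype=object)
        present = {c for c in CATEGORIES if np.any(cats == c)}
        missing = set(CATEGORIES) - present
        if missing and present != {"medium"}:
            warnings.warn(
                f"{cpg}: empty categor{'y' if len(missing) == 1 else 'ies'} "
                f"{sorted(missing)} collapsed into medium"
            )
        codes = np.array([ORDINAL_CODE[c] for c in cats], dtype=float)
        design = np.column_stack([np.ones(n), codes, age, sex])
        try:
            ordinal_fit = fit_logistic(
                design, responder, names=["const", "meth_code", "age", "sex_female"],
                alpha=alpha,
            )
        except SeparationError as exc:
            raise SeparationError(f"{cpg}: {exc}") from exc
        contrast_fit: Optional[LogisticFit] = None
        if {"low", "medium"} <= present or {"low", "high"} <= present:
            cols = [np.ones(n)]
            names = ["const"]
            for level in ("medium", "high"):
                if level in present:
                    cols.append((cats == level).astype(float))
                    names.append(f"{level}_vs_low")
            cols.extend([age, sex])
            names.extend(["age", "sex_female"])
            try:
                contrast_fit = fit_logistic(
                    np.column_stack(cols), responder, names=names, alpha=alpha
                )
            except SeparationError as exc:
                raise SeparationError(f"{cpg}: {exc}") from exc
        table_df = _category_table(cats, responder)
        nonempty = table_df.loc[table_df.sum(axis=1) > 0]
        if len(nonempty) >= 2:
            chi2 = pearson_chi2(
                ContingencyTable(
                    nonempty.to_numpy().T,
                    ("responder", "non_responder"),
                    tuple(nonempty.index),
                )
            )
        else:
            chi2 = None
        q = (cutoffs or {}).get(cpg, (np.nan, np.nan))
        results.append(
            CpgAssociationResult(
                cpg_id=str(cpg), ordinal_fit=ordinal_fit, contrast_fit=contrast_fit,
                chi2=chi2, category_counts=table_df, cutoffs=q,
            )
        )
    return results


def average_methylation(matrix: np.ndarray) -> np.ndarray:
    """Per-patient arithmetic mean over the 12 CpG sites.

    Missing entries are skipped (mean over observed sites) with the
    affected row count reported via a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != 12:
        raise ValueError("expected an n x 12 methylation matrix")
    finite = np.isfinite(matrix)
    if np.any((matrix[finite] < 0) | (matrix[finite] > 1)):
        raise ValueError("methylation values must lie in [0, 1]")
    n_missing_rows = int(np.sum(~finite.all(axis=1)))
    if n_missing_rows:
        warnings.warn(
            f"{n_missing_rows} patients with missing CpG values: "
            "row means taken over observed sites"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(matrix, axis=1)
    return matrix.mean(axis=1)


def methylation_by_genotype(
    avg: Sequence[float], genotypes: Sequence[str]
) -> GenotypeMethylationSummary:
    """Median/IQR of average methylation per genotype plus Kruskal-Wallis."""
    avg = np.asarray(avg, dtype=float)
    genotypes = np.asarray(genotypes)
    if avg.shape != genotypes.shape:
        raise ValueError("avg and genotypes must align")
    per: dict[str, dict[str, float]] = {}
    groups = []
    for g in GENOTYPES:
        vals = avg[genotypes == g]
        if len(vals) == 0:
            warnings.warn(f"genotype group {g} is empty; omitted from the comparison")
            continue
        per[g] = {
            "n": int(len(vals)),
            "median": float(np.median(vals)),
            "q25": float(np.percentile(vals, 25)),
            "q75": float(np.percentile(vals, 75)),
        }
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("fewer than two genotype groups present")
    h, p = kruskal_wallis(groups)
    return GenotypeMethylationSummary(per_genotype=per, kruskal_h=h, kruskal_p=p)


def correlate_with_ddas28(
    avg: Sequence[float], delta_das28: Sequence[float]
) -> tuple[float, float]:
    """Spearman correlation between average methylation and dDAS28."""
    return spearman_corr(avg, delta_das28)
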