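"""Genetic-model association at rs705379.

Builds the codominant / dominant / recessive / allele cross-tabulations
of genotype against responder status and computes, per model, the
Pearson chi-square, crude Woolf odds ratios per non-reference level, and
an age- and sex-adjusted logistic fit with indicator coding against the
reference (CC for genotype models, C for the allele model).

The allele model reports the crude odds ratio only: per-allele rows
duplicate subjects, so covariate adjustment on 2N pseudo-observations
would misstate the information and is deliberately omitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .stats import (
    Chi2Result,
    ContingencyTable,
    LogisticFit,
    OddsRatioResult,
    SeparationError,
    fit_logistic,
    odds_ratio_woolf,
    pearson_chi2,
)

MODELS = ("codominant", "dominant", "recessive", "allele")
GENOTYPES = ("CC", "CT", "TT")


@dataclass
class GeneticModelResult:
    model: str
    table: ContingencyTable
    chi2: Chi2Result
    crude_or: dict[str, OddsRatioResult]  # keyed by non-reference level
    adjusted_fit: Optional[LogisticFit] = None


def _genotype_counts(genotypes: np.ndarray, responder: np.ndarray) -> np.ndarray:
    counts = np.zeros((2, 3), dtype=np.int64)
    for j, g in enumerate(GENOTYPES):
        mask = genotypes == g
        counts[0, j] = int(np.sum(mask & (responder == 1)))
        counts[1, j] = int(np.sum(mask & (responder == 0)))
    return counts


def build_model_table(
    genotypes: Sequence[str], responder_flags: Sequence[int], model: str
) -> ContingencyTable:
    """Cross-tabulate genotype against response under one genetic model.

    Rows are (responder, non_responder); the reference level is the first
    column. The allele model counts two alleles per subject.
    """
    genotypes = np.asarray(genotypes)
    responder = np.asarray(responder_flags, dtype=int)
    if len(genotypes) == 0:
        raise ValueError("empty cohort")
    if genotypes.shape != responder.shape:
        raise ValueError("genotypes and responder flags must align")
    if not set(np.unique(genotypes)) <= set(GENOTYPES):
        raise ValueError("genotypes must be CC/CT/TT")
    g = _genotype_counts(genotypes, responder)
    rows = ("responder", "non_responder")
    if model == "codominant":
        return ContingencyTable(g, rows, GENOTYPES)
    if model == "dominant":
        counts = np.column_stack([g[:, 0], g[:, 1] + g[:, 2]])
        return ContingencyTable(counts, rows, ("CC", "CT+TT"))
    if model == "recessive":
        counts = np.column_stack([g[:, 0] + g[:, 1], g[:, 2]])
        return ContingencyTable(counts, rows, ("CC+CT", "TT"))
    if model == "allele":
        c = 2 * g[:, 0] + g[:, 1]
        t = 2 * g[:, 2] + g[:, 1]
        return ContingencyTable(np.column_stack([c, t]), rows, ("C", "T"))
    raise ValueError(f"unknown genetic model: {model!r}")


def _crude_ors(table: ContingencyTable, alpha: float) -> dict[str, OddsRatioResult]:
    """Woolf OR per non-reference column against the reference column.

    Layout per level L: a = responders at L, b = responders at reference,
    c = non-responders at L, d = non-responders at reference, so OR < 1
    means level L is depleted among responders relative to the reference.
    """
    counts = table.counts
    out: dict[str, OddsRatioResult] = {}
    for j in range(1, counts.shape[1]):
        out[table.col_labels[j]] = odds_ratio_woolf(
            int(counts[0, j]), int(counts[0, 0]),
            int(counts[1, j]), int(counts[1, 0]),
            alpha=alpha, haldane=True,
        )
    return out


def _indicator_design(
    genotypes: np.ndarray, model: str, age: np.ndarray, sex_female: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    n = len(genotypes)
    cols = [np.ones(n)]
    names = ["const"]
    if model == "codominant":
        for g in ("CT", "TT"):
            cols.append((genotypes == g).astype(float))
            names.append(g)
    elif model == "dominant":
        cols.append(np.isin(genotypes, ("CT", "TT")).astype(float))
        names.append("CT+TT")
    elif model == "recessive":
        cols.append((genotypes == "TT").astype(float))
        names.append("TT")
    cols.extend([age, sex_female])
    names.extend(["age", "sex_female"])
    return np.column_stack(cols), names


def associate_all_models(
    genotypes: Sequence[str],
    responder_flags: Sequence[int],
    age: Optional[Sequence[float]] = None,
    sex_female: Optional[Sequence[int]] = None,
    alpha: float = 0.05,
    models: Sequence[str] = MODELS,
) -> list[GeneticModelResult]:
    """Genotype-association summary for the requested genetic models.

    Adjusted logistic fits (outcome ~ genotype indicators + age + sex,
    female = 1) are produced for the genotype models when covariates are
    supplied; separation or non-convergence is re-raised with the model
    name attached.
    """
    genotypes = np.asarray(genotypes)
    responder = np.asarray(responder_flags, dtype=int)
    results: list[GeneticModelResult] = []
    for model in models:
        table = build_model_table(genotypes, responder, model)
        chi2 = pearson_chi2(table)
        crude = _crude_ors(table, alpha)
        adjusted: Optional[LogisticFit] = None
        if model != "allele" and age is not None and sex_female is not None:
            design, names = _indicator_design(
                genotypes, model,
                np.asarray(age, dtype=float),
                np.asarray(sex_female, dtype=float),
            )
            try:
                adjusted = fit_logistic(design, responder, names=names, alpha=alpha)
            except SeparationError as exc:
                raise SeparationError(f"{model} model: {exc}") from exc
        results.append(
            GeneticModelResult(
                model=model, table=table, chi2=chi2,
                crude_or=crude, adjusted_fit=adjusted,
            )
        )
    return results
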