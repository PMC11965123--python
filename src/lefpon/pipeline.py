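"""End-to-end orchestration: simulate/load, score, associate, report.

Stages run in a fixed order — clinical scoring, univariate covariate
screen, genetic-model association (plus HWE), CpG categorisation and
per-CpG association, genotype/methylation/dDAS28 analyses, composite
protective score and the two multifactor models — and write one
delimited report table each. A fixed seed makes every artifact
byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import association as assoc
from . import clinical, methylation as meth, score as score_mod
from .clinical import ClinicalVisit
from .io import cohort_to_frame, read_cohort, write_cohort
from .simulate import CPG_IDS, CohortConfig, PatientRecord, generate_cohort
from .stats import hwe_test

logger = logging.getLogger(__name__)

#: published genotype-by-response counts (responders, non-responders)
TABLE1_COUNTS = {"CC": (50, 20), "CT": (63, 49), "TT": (34, 24)}

SCREEN_CANDIDATES = ("pct", "mono", "plt", "siri", "nlr", "plr", "sii", "neut", "lymph")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Run configuration for :func:`run_pipeline`."""

    input_path: Optional[str] = None  # cohort file; None -> simulate
    cohort_config: Optional[CohortConfig] = None
    scored_cpgs: tuple[str, ...] = score_mod.SIGNIFICANT_CPGS
    alpha: float = 0.05
    screen_threshold: float = 0.2
    score_coding: str = "quartile"  # "quartile" | "raw"
    missing_policy: str = "complete-case"  # "complete-case" | "impute"
    outdir: str = "lefpon_out"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.screen_threshold < 1.0:
            raise ValueError("screen_threshold must lie in (0, 1)")
        if self.score_coding not in ("quartile", "raw"):
            raise ValueError("score_coding must be 'quartile' or 'raw'")
        if self.missing_policy not in ("complete-case", "impute"):
            raise ValueError("missing_policy must be 'complete-case' or 'impute'")
        unknown = [c for c in self.scored_cpgs if c not in CPG_IDS]
        if unknown:
            raise ValueError(f"scored CpG id(s) not in schema: {unknown}")
        if self.input_path is None and self.cohort_config is None:
            object.__setattr__(self, "cohort_config", CohortConfig(seed=self.seed))
        if self.cohort_config is not None:
            self.cohort_config.validate()


@dataclass
class RunReport:
    config: dict
    stages: list[dict] = field(default_factory=list)
    files: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def log_stage(self, name: str, n_in: int, n_out: int, **extra) -> None:
        self.stages.append({"stage": name, "n_in": n_in, "n_out": n_out, **extra})


# ---------------------------------------------------------------------------
# per-patient clinical frame
# ---------------------------------------------------------------------------


def clinical_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-patient DAS28 scores, EULAR category, responder flag, indices.

    Raw visit components win over precomputed DAS28; a mismatch above
    0.01 between the two is logged.
    """
    rows = []
    mismatches = 0
    for r in records:
        scores = {}
        for name, visit, pre in (
            ("baseline", r.baseline, r.das28_baseline),
            ("month6", r.month6, r.das28_month6),
        ):
            if visit is not None:
                val = clinical.das28(visit)
                if pre is not None and abs(val - pre) > 0.01:
                    mismatches += 1
            else:
                val = pre
            scores[name] = val
        resp = clinical.classify_response(scores["baseline"], scores["month6"])
        idx = clinical.inflammation_indices(r.neut, r.lymph, r.mono, r.plt)
        rows.append(
            {
                "id": r.id, "age": r.age,
                "sex_female": int(r.sex == "female"),
                "genotype": r.genotype,
                "das28_baseline": resp.das28_baseline,
                "das28_month6": resp.das28_month6,
                "delta_das28": resp.delta_das28,
                "category": resp.category,
                "responder": resp.responder,
                "neut": r.neut, "lymph": r.lymph, "mono": r.mono,
                "plt": r.plt, "pct": r.pct,
                "nlr": idx.nlr, "plr": idx.plr, "sii": idx.sii, "siri": idx.siri,
            }
        )
    if mismatches:
        logger.warning(
            "%d patients: supplied DAS28 disagrees with raw components by > 0.01 "
            "(raw components used)", mismatches,
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published-counts reconstruction fixture
# ---------------------------------------------------------------------------


def reconstruct_table1_fixture() -> list[PatientRecord]:
    """240-patient cohort matching the published genotype-by-response counts.

    Response status is fixed through precomputed DAS28 pairs (5.0 -> 3.0
    is a good response; 5.5 -> 5.2 is non-response). Methylation is a
    deterministic synthetic gradient and age/sex cycle deterministically,
    so downstream stages run but carry no genetic signal of their own.
    """
    records: list[PatientRecord] = []
    i = 0
    for genotype, (n_resp, n_nonresp) in TABLE1_COUNTS.items():
        for responder, count in ((1, n_resp), (0, n_nonresp)):
            for _ in range(count):
                m = 0.2 + 0.6 * (i / 239.0)
                records.append(
                    PatientRecord(
                        id=f"T{i + 1:03d}",
                        age=45.0 + (i % 21),
                        sex="female" if i % 5 else "male",
                        genotype=genotype,
                        methylation=np.full(len(CPG_IDS), m),
                        baseline=None,
                        month6=None,
                        das28_baseline=5.0 if responder else 5.5,
                        das28_month6=3.0 if responder else 5.2,
                        neut=4.0, lymph=1.8, mono=0.45, plt=260.0, pct=0.0026,
                    )
                )
                i += 1
    return records


# ---------------------------------------------------------------------------
# report emission helpers
# ---------------------------------------------------------------------------


def _genetic_report(results, hwe) -> pd.DataFrame:
    rows = []
    for res in results:
        counts = res.table.counts
        n_resp, n_nonresp = counts[0].sum(), counts[1].sum()
        for j, level in enumerate(res.table.col_labels):
            row = {
                "model": res.model,
                "level": level,
                "responders": int(counts[0, j]),
                "responders_pct": round(100.0 * counts[0, j] / n_resp, 2),
                "non_responders": int(counts[1, j]),
                "non_responders_pct": round(100.0 * counts[1, j] / n_nonresp, 2),
                "chi2": res.chi2.statistic if j == 0 else np.nan,
                "chi2_p": res.chi2.p if j == 0 else np.nan,
            }
            if j == 0:
                row.update(or_value=np.nan, or_ci_low=np.nan, or_ci_high=np.nan,
                           or_p=np.nan, note="Ref")
            else:
                crude = res.crude_or[level]
                row.update(or_value=crude.or_value, or_ci_low=crude.ci_low,
                           or_ci_high=crude.ci_high, note="crude")
                if res.adjusted_fit is not None and res.adjusted_fit.converged:
                    adj = res.adjusted_fit[level]
                    row.update(adj_or=adj["or"], adj_or_ci_low=adj["ci_low"],
                               adj_or_ci_high=adj["ci_high"], or_p=adj["p"])
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["hwe"] = {"statistic": hwe.statistic, "df": hwe.df, "p": hwe.p}
    return df


def _cpg_report(results) -> pd.DataFrame:
    rows = []
    for r in results:
        counts = r.category_counts
        term = r.ordinal_fit["meth_code"]
        row = {
            "cpg_id": r.cpg_id,
            "q25": r.cutoffs[0], "q75": r.cutoffs[1],
            "ordinal_or": term["or"],
            "ordinal_ci_low": term["ci_low"], "ordinal_ci_high": term["ci_high"],
            "ordinal_p": term["p"],
            "chi2": r.chi2.statistic if r.chi2 else np.nan,
            "chi2_p": r.chi2.p if r.chi2 else np.nan,
        }
        for cat in ("low", "medium", "high"):
            row[f"{cat}_responder"] = int(counts.loc[cat, "responder"])
            row[f"{cat}_non_responder"] = int(counts.loc[cat, "non_responder"])
        if r.contrast_fit is not None:
            for name in r.contrast_fit.names:
                if name.endswith("_vs_low"):
                    c = r.contrast_fit[name]
                    row[f"{name}_or"] = c["or"]
                    row[f"{name}_p"] = c["p"]
        rows.append(row)
    return pd.DataFrame(rows)


def _model_report(models) -> pd.DataFrame:
    rows = []
    for m in models:
        fit = m.fit
        for i, name in enumerate(fit.names):
            rows.append(
                {
                    "model": m.model_id,
                    "term": "constant" if name == "const" else name,
                    "beta": fit.coefficients[i],
                    "se": fit.standard_errors[i],
                    "wald": fit.wald_z[i] ** 2,
                    "df": 1,
                    "or_value": fit.odds_ratios[i],
                    "or_ci_low": fit.or_ci_low[i],
                    "or_ci_high": fit.or_ci_high[i],
                    "p": fit.p_values[i],
                    "vif": m.vif.get(name, np.nan),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_pipeline(config: AnalysisConfig) -> RunReport:
    """Execute the full analysis; returns the run report.

    Emits, under ``config.outdir``: the cohort table (when simulated),
    ``clinical_scores.csv``, ``univariate_screen.csv``,
    ``genetic_association.csv``, ``cpg_association.csv``,
    ``methylation_by_genotype.csv``, ``multifactor_models.csv`` and
    ``run_report.json``. Any stage failure removes partial outputs and
    raises :class:`PipelineError` naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=_config_dict(config))
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
        report.files.append(str(path))

    stage = "load_cohort"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if config.input_path is not None:
                records = read_cohort(config.input_path)
            else:
                records = generate_cohort(config.cohort_config)
                write_cohort(records, outdir / "cohort.csv")
                written.append(outdir / "cohort.csv")
                report.files.append(str(outdir / "cohort.csv"))
            report.log_stage(stage, n_in=len(records), n_out=len(records))

            stage = "clinical_scores"
            frame = clinical_frame(records)
            frame = _apply_missing_policy(frame, config, report)
            emit(frame, "clinical_scores.csv")
            report.log_stage(stage, n_in=len(records), n_out=len(frame),
                             responders=int(frame["responder"].sum()))

            stage = "univariate_screen"
            candidates = {c: frame[c].to_numpy() for c in SCREEN_CANDIDATES
                          if c in frame.columns}
            retained = score_mod.screen_covariates(
                candidates, frame["responder"].to_numpy(),
                threshold=config.screen_threshold,
            )
            emit(
                pd.DataFrame(
                    [{"candidate": k, "univariate_p": v, "retained": True}
                     for k, v in retained.items()]
                    + [{"candidate": k, "univariate_p": np.nan, "retained": False}
                       for k in candidates if k not in retained]
                ),
                "univariate_screen.csv",
            )
            report.log_stage(stage, n_in=len(candidates), n_out=len(retained),
                             retained=sorted(retained))

            stage = "genetic_association"
            genotypes = frame["genotype"].to_numpy()
            responder = frame["responder"].to_numpy()
            results = assoc.associate_all_models(
                genotypes, responder,
                age=frame["age"].to_numpy(),
                sex_female=frame["sex_female"].to_numpy(),
                alpha=config.alpha,
            )
            counts = {g: int(np.sum(genotypes == g)) for g in ("CC", "CT", "TT")}
            hwe = hwe_test(counts["CC"], counts["CT"], counts["TT"])
            emit(_genetic_report(results, hwe), "genetic_association.csv")
            report.log_stage(stage, n_in=len(frame), n_out=len(results),
                             hwe_p=hwe.p)

            stage = "cpg_association"
            meth_matrix = np.vstack([r.methylation for r in records])
            meth_matrix = meth_matrix[frame.index.to_numpy()]
            categories = {}
            cutoffs = {}
            for j, cpg in enumerate(CPG_IDS):
                cats, q = meth.categorize_cpg(meth_matrix[:, j])
                categories[cpg] = cats
                cutoffs[cpg] = q
            cat_df = pd.DataFrame(categories)
            cpg_results = meth.per_cpg_association(
                cat_df, responder, frame["age"], frame["sex_female"],
                cutoffs=cutoffs, alpha=config.alpha,
            )
            emit(_cpg_report(cpg_results), "cpg_association.csv")
            report.log_stage(stage, n_in=len(frame), n_out=len(cpg_results))

            stage = "methylation_genotype"
            avg = meth.average_methylation(meth_matrix)
            summary = meth.methylation_by_genotype(avg, genotypes)
            rho, rho_p = meth.correlate_with_ddas28(
                avg, frame["delta_das28"].to_numpy()
            )
            geno_rows = [
                {"genotype": g, **vals} for g, vals in summary.per_genotype.items()
            ]
            geno_df = pd.DataFrame(geno_rows)
            geno_df["kruskal_h"] = summary.kruskal_h
            geno_df["kruskal_p"] = summary.kruskal_p
            geno_df["spearman_r_ddas28"] = rho
            geno_df["spearman_p_ddas28"] = rho_p
            emit(geno_df, "methylation_by_genotype.csv")
            report.log_stage(stage, n_in=len(frame), n_out=len(geno_rows),
                             spearman_r=rho)

            stage = "multifactor_models"
            comp = score_mod.composite_score(
                cat_df, genotypes, scored_cpgs=config.scored_cpgs
            )
            score_term = (
                comp.quartile_category if config.score_coding == "quartile"
                else comp.score
            )
            screened_vals = {k: frame[k].to_numpy() for k in retained}
            model1, model2 = score_mod.fit_multifactor(
                score_term, screened_vals, responder,
                screened_p=retained, alpha=config.alpha,
            )
            emit(_model_report([model1, model2]), "multifactor_models.csv")
            report.log_stage(stage, n_in=len(frame), n_out=2,
                             score_coding=config.score_coding)

        report.warnings = sorted({str(w.message) for w in caught})
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc

    report_path = outdir / "run_report.json"
    with open(report_path, "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2, sort_keys=True)
    report.files.append(str(report_path))
    return report


def _config_dict(config: AnalysisConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("cohort_config") is not None:
        for k, v in list(d["cohort_config"].items()):
            if isinstance(v, tuple):
                d["cohort_config"][k] = list(v)
    return d


def _apply_missing_policy(
    frame: pd.DataFrame, config: AnalysisConfig, report: RunReport
) -> pd.DataFrame:
    numeric = frame.select_dtypes(include=[np.number]).columns
    n_missing = int(frame[numeric].isna().any(axis=1).sum())
    if n_missing == 0:
        return frame
    if config.missing_policy == "complete-case":
        logger.info("dropping %d incomplete rows (complete-case policy)", n_missing)
        return frame.dropna(subset=numeric)  # original positions kept in the index
    for col in numeric:
        frame[col] = frame[col].fillna(frame[col].median())
    logger.info("imputed medians for %d incomplete rows", n_missing)
    return frame
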