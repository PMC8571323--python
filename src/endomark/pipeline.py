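"""End-to-end orchestration: simulate/ingest → analyze → JSON report.

The pipeline chains the analysis stages in the order the biomarker study
runs them: cohort simulation or ingestion, in-vitro dose–response and
sensitivity regression, per-arm qualifying-biomarker and interaction tests,
Monte-Carlo CV threshold selection, mosaic/balance checks at the selected
threshold, Bayesian subgroup pCR estimation, ROC/optimal-cutoff analysis, and
the Allred/PFS comparison.  Output is a machine-readable report validated
against the pydantic schema below (published as ``docs/report.schema.json``),
plus CSV tables.  Everything is deterministic given the config and seed; the
report deliberately contains no timestamps so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import allred as allred_mod
from . import bayes as bayes_mod
from . import dose_response, roc, threshold_cv
from .association import (
    ContingencyTable2x2,
    association_table,
    fisher_exact_2x2,
    mann_whitney,
)
from .simulate import (
    CohortSimConfig,
    generate_cellline_panel,
    generate_ihc_cohort,
    generate_trial_cohort,
    panel_to_frames,
    read_cohort,
    write_cohort,
)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "mosaic_counts"]

logger = logging.getLogger("endomark.pipeline")

ALL_STAGES = ("simulate", "invitro", "qualify", "threshold_cv", "bayes", "roc", "allred")


class PipelineConfig(BaseModel):
    """Configuration for one pipeline run (YAML/JSON loadable)."""

    seed: int = 0
    stages: list[str] = Field(default_factory=lambda: list(ALL_STAGES))
    outdir: Optional[str] = None
    cohort_csv: Optional[str] = None
    cohort_sim: dict = Field(default_factory=dict)
    marker: str = "RAB5A"
    markers: list[str] = Field(default_factory=lambda: ["RAB4A", "RAB5A", "RAB11A"])
    arms: tuple[str, str] = ("TDM1P", "TH")
    threshold_override: Optional[float] = None
    cv_iterations: int = 100
    panel: dict = Field(default_factory=dict)
    ihc: dict = Field(default_factory=dict)
    bayes_chain: dict = Field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**data)


class AssociationRow(BaseModel):
    marker: str
    model: str
    coef: float
    coef_sign: int
    odds_ratio_per_sd: float
    lr_stat: float
    p: float
    neg_log10_p: float
    adjusted_for_hr: bool


class SimulateSection(BaseModel):
    arm_sizes: dict[str, int]
    pcr_counts: dict[str, int]
    n_total: int


class InvitroMarkerFit(BaseModel):
    marker: str
    slope: float
    intercept: float
    r2: float
    n: int


class InvitroSection(BaseModel):
    fits: list[InvitroMarkerFit]
    ic50_by_line: dict[str, float]


class ThresholdCVSection(BaseModel):
    selected_threshold: float
    overall_combined_p: float
    n_iterations: int
    combined_p_by_threshold: dict[str, float]


class MosaicCell(BaseModel):
    arm: str
    group: str
    pcr: bool
    count: int


class BalanceSection(BaseModel):
    threshold: float
    mosaic: list[MosaicCell]
    fisher_hr_p: float
    erbb2_ranksum_p: float


class BayesEstimate(BaseModel):
    arm: str
    subset: str
    mean_prob: float
    pi_low: float
    pi_high: float


class ArmROC(BaseModel):
    arm: str
    auc: float
    optimal_cutoff: float


class AllredSection(BaseModel):
    U: float
    p: float
    median_high: float
    median_low: float
    n_high: int
    n_low: int


class PipelineReport(BaseModel):
    seed: int
    stages: list[str]
    simulate: Optional[SimulateSection] = None
    invitro: Optional[InvitroSection] = None
    qualify: Optional[list[AssociationRow]] = None
    threshold_cv: Optional[ThresholdCVSection] = None
    balance: Optional[BalanceSection] = None
    bayes: Optional[list[BayesEstimate]] = None
    roc: Optional[list[ArmROC]] = None
    allred: Optional[AllredSection] = None


def mosaic_counts(
    cohort: pd.DataFrame, threshold: float, marker: str = "RAB5A"
) -> pd.DataFrame:
    """Arm × biomarker-group × pCR counts at a dichotomizing threshold.

    Low means expression < threshold.  The counts partition the cohort.
    """
    group = np.where(cohort[marker].to_numpy(dtype=float) >= threshold, "High", "Low")
    tab = (
        cohort.assign(group=group)
        .groupby(["arm", "group", "pcr"], observed=False)
        .size()
        .rename("count")
        .reset_index()
    )
    return tab


def _balance_checks(cohort, threshold, marker, experimental_arm) -> BalanceSection:
    mos = mosaic_counts(cohort, threshold, marker)
    sub = cohort[cohort["arm"] == experimental_arm]
    high = sub[marker].to_numpy(dtype=float) >= threshold
    hr_neg = (sub["hr_status"] == "HRneg").to_numpy()
    table = ContingencyTable2x2(
        a=int(np.sum(high & hr_neg)),
        b=int(np.sum(high & ~hr_neg)),
        c=int(np.sum(~high & hr_neg)),
        d=int(np.sum(~high & ~hr_neg)),
    )
    fisher_p = fisher_exact_2x2(table)
    erbb2 = sub["ERBB2"].to_numpy(dtype=float)
    if high.all() or not high.any():
        erbb2_p = float("nan")
    else:
        _, erbb2_p = mann_whitney(erbb2[high], erbb2[~high])
    return BalanceSection(
        threshold=float(threshold),
        mosaic=[MosaicCell(**row) for row in mos.to_dict("records")],
        fisher_hr_p=fisher_p,
        erbb2_ranksum_p=erbb2_p,
    )


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the requested stages and return the validated report.

    When ``config.outdir`` is set, writes ``report.json`` plus per-stage CSV
    tables there.
    """
    report = PipelineReport(seed=config.seed, stages=list(config.stages))
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    cohort = None
    needs_cohort = {"simulate", "qualify", "threshold_cv", "bayes", "roc"} & set(
        config.stages
    )
    if needs_cohort:
        if config.cohort_csv:
            cohort = read_cohort(config.cohort_csv)
            logger.info("loaded cohort from %s (n=%d)", config.cohort_csv, len(cohort))
        else:
            sim_cfg = CohortSimConfig(**{"seed": config.seed, **config.cohort_sim})
            cohort = generate_trial_cohort(sim_cfg)
            logger.info("simulated cohort (seed=%d, n=%d)", sim_cfg.seed, len(cohort))
        sizes = cohort.groupby("arm").size().to_dict()
        pcr = cohort.groupby("arm")["pcr"].sum().astype(int).to_dict()
        report.simulate = SimulateSection(
            arm_sizes={k: int(v) for k, v in sizes.items()},
            pcr_counts=pcr,
            n_total=len(cohort),
        )
        if outdir:
            write_cohort(cohort, outdir / "cohort.csv")

    if "invitro" in config.stages:
        panel_kwargs = {"seed": config.seed + 1, **config.panel}
        panel = generate_cellline_panel(marker=config.marker, **panel_kwargs)
        via, expr = panel_to_frames(panel, marker=config.marker)
        ic50s = {}
        for rec in panel:
            line = via[via["cell_line"] == rec.name]
            fit = dose_response.fit_sigmoid(
                line["concentration"].to_numpy(), line["viability"].to_numpy()
            )
            ic50s[rec.name] = fit.ic50 if fit.ic50 is not None else float("nan")
        x = expr.set_index("cell_line").loc[list(ic50s), config.marker].to_numpy()
        lin = dose_response.sensitivity_regression(x, list(ic50s.values()))
        report.invitro = InvitroSection(
            fits=[
                InvitroMarkerFit(
                    marker=config.marker,
                    slope=lin.slope,
                    intercept=lin.intercept,
                    r2=lin.r2,
                    n=lin.n,
                )
            ],
            ic50_by_line=ic50s,
        )
        if outdir:
            via.to_csv(outdir / "viability.csv", index=False)
            pd.DataFrame(
                [{"cell_line": k, "ic50": v} for k, v in ic50s.items()]
            ).to_csv(outdir / "ic50_summary.csv", index=False)

    if "qualify" in config.stages:
        tab = association_table(cohort, config.markers, config.arms)
        tab_adj = association_table(cohort, config.markers, config.arms, adjust_hr=True)
        both = pd.concat([tab, tab_adj], ignore_index=True)
        report.qualify = [AssociationRow(**row) for row in both.to_dict("records")]
        if outdir:
            both.to_csv(outdir / "association_table.csv", index=False)

    threshold = config.threshold_override
    if "threshold_cv" in config.stages:
        cv_cfg = threshold_cv.CVConfig(
            n_iterations=config.cv_iterations, seed=config.seed + 2
        )
        result = threshold_cv.run_cv(cohort, config.marker, config.arms, cv_cfg)
        report.threshold_cv = ThresholdCVSection(
            selected_threshold=result.selected_threshold,
            overall_combined_p=result.overall_p.p,
            n_iterations=cv_cfg.n_iterations,
            combined_p_by_threshold={
                f"{t:.6g}": c.p for t, c in result.combined_p_by_threshold.items()
            },
        )
        if threshold is None:
            threshold = result.selected_threshold
        if outdir:
            (outdir / "threshold_cv.json").write_text(
                json.dumps(result.to_dict(), indent=2)
            )

    if threshold is not None and cohort is not None:
        report.balance = _balance_checks(cohort, threshold, config.marker, config.arms[0])
        if outdir:
            mosaic_counts(cohort, threshold, config.marker).to_csv(
                outdir / "mosaic_counts.csv", index=False
            )

    if "bayes" in config.stages:
        if threshold is None:
            raise ValueError("bayes stage needs a threshold (run threshold_cv or override)")
        spec = bayes_mod.BayesModelSpec(seed=config.seed + 3, **config.bayes_chain)
        design = bayes_mod.build_subtype_design(
            cohort, threshold, experimental_arm=config.arms[0], arms=config.arms,
            marker=config.marker,
        )
        draws = bayes_mod.sample_posterior(spec, design.X, design.y)
        estimates = []
        for is_exp, arm in ((True, config.arms[0]), (False, config.arms[1])):
            for subset in (None, "high", "low"):
                try:
                    s = bayes_mod.estimate_pcr(draws, design, is_exp, subset, arm_label=arm)
                except ValueError:
                    continue
                estimates.append(
                    BayesEstimate(
                        arm=arm,
                        subset=s.subset_label,
                        mean_prob=s.mean_prob,
                        pi_low=s.pi95[0],
                        pi_high=s.pi95[1],
                    )
                )
        report.bayes = estimates
        if outdir:
            pd.DataFrame([e.model_dump() for e in estimates]).to_csv(
                outdir / "bayes_estimates.csv", index=False
            )

    if "roc" in config.stages:
        rows = []
        for arm in config.arms:
            sub = cohort[cohort["arm"] == arm]
            curve = roc.roc_curve(
                sub[config.marker].to_numpy(dtype=float), sub["pcr"].to_numpy(bool)
            )
            rows.append(
                ArmROC(arm=arm, auc=curve.auc, optimal_cutoff=roc.optimal_cutoff(curve))
            )
            if outdir:
                curve.points.to_csv(outdir / f"roc_{arm}.csv", index=False)
        report.roc = rows

    if "allred" in config.stages:
        ihc_kwargs = {"seed": config.seed + 4, **config.ihc}
        ihc = generate_ihc_cohort(**ihc_kwargs)
        totals = [
            allred_mod.allred_total(i, p).total
            for i, p in zip(ihc["intensity"], ihc["proportion"])
        ]
        groups = allred_mod.dichotomize_allred(totals)
        res = allred_mod.compare_pfs(groups, ihc["pfs_weeks"].to_numpy())
        report.allred = AllredSection(**res)
        if outdir:
            ihc.assign(total=totals, group=groups).to_csv(
                outdir / "ihc_cohort.csv", index=False
            )

    if outdir:
        (outdir / "report.json").write_text(report.model_dump_json(indent=2))
        logger.info("report written to %s", outdir / "report.json")
    return report
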