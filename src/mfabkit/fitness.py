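"""INSeq stage: within-species depth normalization, pseudocount-8 log2
transform, fitness scores relative to the control diet, and moderated
differential-fitness tests.

The fitness score of gene g in a treated mouse is

    score(g, mouse) = [log2 n(g, dpg6) - log2 n(g, dpg2)]
                      - mean over control mice of the same ratio

on depth-normalized, pseudocount-8 counts. A negative score means the
insertion mutant loses abundance under the supplement: the gene matters for
fitness in that diet context. Differential tests fit a per-gene linear
model of the day-6/day-2 contrast on diet arm and moderate the gene-wise
variances with an empirical-Bayes prior before BH correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fit_variance_prior, moderated_t
from .design import ExperimentDesign

logger = logging.getLogger(__name__)

__all__ = ["FitnessParams", "normalize_log2", "fitness_score", "differential_fitness"]


class FitnessError(ValueError):
    pass


@dataclass(frozen=True)
class FitnessParams:
    pseudocount: float = 8.0
    alpha: float = 0.05
    baseline_day: int = 2
    comparison_day: int = 6
    library_size_target: str = "median"  # or "cpm"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise FitnessError("pseudocount must be > 0")


def normalize_log2(counts: pd.DataFrame, params: FitnessParams | None = None) -> pd.DataFrame:
    """Scale counts to a common library size within each species, then
    log2(scaled + pseudocount).

    ``counts`` needs columns species, gene, sample, count. The target
    library size is the median of that species' per-sample totals (or 1e6
    when ``library_size_target == "cpm"``). Samples with zero total for a
    species are excluded with a log record.
    """
    params = params or FitnessParams()
    df = counts.copy()
    if (df["count"] < 0).any():
        raise FitnessError("insertion counts must be >= 0")
    out = []
    for sp, sub in df.groupby("species", sort=False):
        totals = sub.groupby("sample")["count"].sum()
        dead = totals[totals <= 0]
        if len(dead):
            logger.warning(
                "species %s: excluding %d zero-total sample(s): %s",
                sp, len(dead), list(dead.index),
            )
            sub = sub[~sub["sample"].isin(dead.index)]
            totals = totals[totals > 0]
        if totals.empty:
            raise FitnessError(f"species {sp!r}: no sample with positive library size")
        target = 1e6 if params.library_size_target == "cpm" else float(totals.median())
        scale = target / totals
        sub = sub.assign(
            normalized=sub["count"].to_numpy() * scale.loc[sub["sample"]].to_numpy()
        )
        sub = sub.assign(log2_value=np.log2(sub["normalized"] + params.pseudocount))
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def fitness_score(
    log2table: pd.DataFrame,
    design: ExperimentDesign,
    params: FitnessParams | None = None,
) -> pd.DataFrame:
    """Per-gene, per-mouse fitness scores referenced to control-diet mice.

    ``log2table`` needs species, gene, mouse, day, arm, log2_value. Mice
    missing the baseline or comparison day are excluded with a warning.
    Control (unsupplemented) mice's scores average exactly 0 per gene by
    construction.
    """
    params = params or FitnessParams()
    df = log2table
    wide = df.pivot_table(
        index=["species", "gene", "mouse", "arm"],
        columns="day",
        values="log2_value",
        aggfunc="mean",
    )
    for day in (params.baseline_day, params.comparison_day):
        if day not in wide.columns:
            raise FitnessError(f"no samples at dpg {day}")
    complete = wide[[params.baseline_day, params.comparison_day]].dropna()
    lost = wide.index.get_level_values("mouse").nunique() - complete.index.get_level_values("mouse").nunique()
    if lost:
        logger.warning("excluded %d mouse/mice missing a baseline or comparison sample", lost)
    delta = (
        complete[params.comparison_day] - complete[params.baseline_day]
    ).rename("delta").reset_index()
    ctrl = delta[delta["arm"] == "unsupplemented"]
    if ctrl.empty:
        raise FitnessError("no control (unsupplemented) mice with both sampling days")
    ctrl_mean = ctrl.groupby(["species", "gene"])["delta"].mean().rename("control_delta")
    delta = delta.merge(ctrl_mean, on=["species", "gene"], how="left")
    missing_ctrl = delta["control_delta"].isna()
    if missing_ctrl.any():
        raise FitnessError("genes lack a control comparator; arms without controls are untestable")
    delta["fitness_score"] = delta["delta"] - delta["control_delta"]
    return delta[["species", "gene", "mouse", "arm", "delta", "fitness_score"]]


def differential_fitness(
    log2table: pd.DataFrame,
    design: ExperimentDesign,
    params: FitnessParams | None = None,
    min_genes_for_moderation: int = 10,
) -> pd.DataFrame:
    """Per-gene moderated tests of diet-arm effects on fitness.

    Per species: the day-6 minus day-2 log2 contrast per mouse is regressed
    on diet arm (unsupplemented as reference, shared design matrix across
    genes); gene-wise residual variances are shrunk toward a moment-
    estimated prior; moderated t p-values are BH-adjusted per arm across
    genes. ``significant_decrease`` marks adjusted p < alpha with a
    negative coefficient.
    """
    params = params or FitnessParams()
    scores = fitness_score(log2table, design, params)
    results = []
    for sp, sub in scores.groupby("species", sort=False):
        mat = sub.pivot_table(index="gene", columns="mouse", values="delta")
        mice = list(mat.columns)
        arms = pd.Series({m: design.arms[m] for m in mice})
        arm_levels = [a for a in design.arms_present if a != "unsupplemented"]
        for a in arm_levels:
            if (arms == a).sum() < 3 or (arms == "unsupplemented").sum() < 3:
                raise FitnessError(f"need >= 3 mice in arm {a!r} and in the control arm")
        X = np.column_stack(
            [np.ones(len(mice))] + [(arms == a).astype(float).to_numpy() for a in arm_levels]
        )
        Y = mat.to_numpy()  # genes x mice
        finite = np.isfinite(Y).all(axis=1)
        if not finite.all():
            logger.warning("species %s: %d gene(s) with missing contrasts flagged untestable",
                           sp, int((~finite).sum()))
        XtX_inv = np.linalg.pinv(X.T @ X)
        beta = Y[finite] @ X @ XtX_inv.T          # genes x coeffs
        fitted = beta @ X.T
        resid = Y[finite] - fitted
        df_resid = len(mice) - np.linalg.matrix_rank(X)
        if df_resid <= 0:
            raise FitnessError("zero residual degrees of freedom: add mice or drop arms")
        s2 = (resid**2).sum(axis=1) / df_resid
        n_genes = finite.sum()
        prior = (
            fit_variance_prior(s2, df_resid)
            if n_genes >= min_genes_for_moderation
            else None
        )
        if prior is None:
            from ._stats import VariancePrior
            prior = VariancePrior(0.0, float(np.median(s2)) if n_genes else 1.0)
        genes = mat.index[finite]
        for j, a in enumerate(arm_levels, start=1):
            unscaled = float(np.sqrt(XtX_inv[j, j]))
            t, p, df_total, _ = moderated_t(beta[:, j], unscaled, s2, df_resid, prior)
            res = pd.DataFrame(
                {
                    "species": sp,
                    "gene": genes,
                    "arm": a,
                    "mean_score": beta[:, j],
                    "moderated_t": t,
                    "p_value": p,
                }
            )
            res["p_adjusted"] = bh_adjust(res["p_value"])
            res["significant_decrease"] = (
                (res["p_adjusted"] < params.alpha) & (res["mean_score"] < 0)
            )
            res["testable"] = True
            results.append(res)
        if not finite.all():
            for a in arm_levels:
                results.append(
                    pd.DataFrame(
                        {
                            "species": sp,
                            "gene": mat.index[~finite],
                            "arm": a,
                            "mean_score": np.nan,
                            "moderated_t": np.nan,
                            "p_value": np.nan,
                            "p_adjusted": np.nan,
                            "significant_decrease": False,
                            "testable": False,
                        }
                    )
                )
    return pd.concat(results, ignore_index=True)
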