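"""Metaproteomic stage: unique-peptide protein summarization, detection-limit
imputation, cyclic loess normalization, moderated differential expression,
and PUL-level set tests.

Missing protein intensities in label-free metaproteomics are dominated by
the instrument's limit of detection, so missing values are imputed from a
down-shifted narrow Gaussian: per sample, N(mean - 2.2*sd, (0.3*sd)^2),
where mean and sd come from that sample's observed distribution restricted
to proteins detected in more than three mice of at least one treatment
group.

The PUL set test asks whether the proteins of one polysaccharide
utilization locus moved together: Z compares the mean log2 fold change of
PUL members against the species-wide background distribution,

    Z = (mean_members - mean_all) / (sd_all / sqrt(n_members)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._stats import bh_adjust, fit_variance_prior, moderated_t, VariancePrior
from .design import ExperimentDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationParams",
    "summarize_proteins",
    "impute_lod",
    "cyclic_loess",
    "differential_expression",
    "pul_set_test",
]


class ProteomicsError(ValueError):
    pass


@dataclass(frozen=True)
class ImputationParams:
    shift: float = 2.2        # downshift, in observed-sd units
    width: float = 0.3        # imputation sd, in observed-sd units
    min_detection_mice: int = 3  # protein must be detected in MORE than this many mice in a group
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift <= 0 or self.width <= 0:
            raise ProteomicsError("imputation multipliers must be > 0")


def summarize_proteins(peptides: pd.DataFrame) -> pd.DataFrame:
    """Sum unique-peptide abundances per protein and log2-transform.

    ``peptides`` needs columns peptide, proteins (';'-separated accessions
    for shared peptides), sample, abundance. Peptides mapping to more than
    one protein are discarded; proteins left with no unique peptide are
    absent from the output.
    """
    df = peptides.copy()
    n_map = df["proteins"].astype(str).str.split(";").str.len()
    unique = df[n_map == 1].copy()
    dropped = int((n_map > 1).sum())
    if dropped:
        logger.info("discarded %d shared peptide record(s)", dropped)
    unique["protein"] = unique["proteins"].astype(str)
    summed = (
        unique.groupby(["protein", "sample"], sort=True)["abundance"].sum().reset_index()
    )
    if (summed["abundance"] <= 0).any():
        raise ProteomicsError("summed peptide abundance must be > 0 before log2")
    summed["log2_abundance"] = np.log2(summed["abundance"])
    return summed


def _detection_filter(table: pd.DataFrame, params: ImputationParams) -> set[str]:
    """Proteins detected in more than ``min_detection_mice`` mice within at
    least one treatment group (per species implicitly via protein IDs)."""
    det = table[table["detected"]]
    counts = det.groupby(["protein", "arm"])["mouse"].nunique()
    ok = counts[counts > params.min_detection_mice]
    return set(ok.index.get_level_values("protein"))


def impute_lod(table: pd.DataFrame, params: ImputationParams | None = None) -> pd.DataFrame:
    """Impute missing log2 abundances from a down-shifted Gaussian.

    ``table`` is tidy: species, protein, sample, mouse, arm, log2_abundance,
    detected. Observed values are never overwritten; imputed rows get
    ``imputed = True``. Draws are seeded via ``params.seed``.
    """
    params = params or ImputationParams()
    rng = np.random.default_rng(params.seed)
    df = table.copy()
    df["imputed"] = False
    if df["detected"].all():
        return df
    keep = _detection_filter(df, params)
    for sample, idx in df.groupby("sample").groups.items():
        sub = df.loc[idx]
        obs = sub[sub["detected"] & sub["protein"].isin(keep)]["log2_abundance"]
        if len(obs) < 10:
            raise ProteomicsError(
                f"sample {sample!r}: only {len(obs)} observed proteins pass the "
                "detection filter; distribution unestimable"
            )
        mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        miss = sub.index[~sub["detected"]]
        if len(miss):
            draws = rng.normal(mu - params.shift * sd, params.width * sd, len(miss))
            df.loc[miss, "log2_abundance"] = draws
            df.loc[miss, "imputed"] = True
    return df


def cyclic_loess(
    matrix: pd.DataFrame,
    span: float = 0.7,
    n_cycles: int = 3,
    min_proteins: int = 100,
) -> pd.DataFrame:
    """Cyclic loess normalization of a proteins-by-samples log2 matrix.

    For every sample pair (a, b): fit a loess of M = x_a - x_b against
    A = (x_a + x_b)/2 and move each sample half the fitted trend toward the
    other; repeat for ``n_cycles``. Matrices with ``min_proteins`` or fewer
    rows are passed through untouched (too few proteins to estimate the
    trend). The pairwise half-shifts cancel, so the grand mean is preserved.
    """
    if matrix.shape[0] <= min_proteins:
        return matrix
    if not np.isfinite(matrix.to_numpy()).all():
        raise ProteomicsError("non-finite values: impute before normalizing")
    X = matrix.to_numpy(dtype=float).copy()
    n = X.shape[1]
    if n < 2:
        raise ProteomicsError("need >= 2 samples")
    for _ in range(n_cycles):
        for i in range(n - 1):
            for j in range(i + 1, n):
                A = (X[:, i] + X[:, j]) / 2.0
                M = X[:, i] - X[:, j]
                fit = lowess(M, A, frac=span, it=3, return_sorted=False)
                X[:, i] -= fit / 2.0
                X[:, j] += fit / 2.0
    return pd.DataFrame(X, index=matrix.index, columns=matrix.columns)


def differential_expression(
    table: pd.DataFrame,
    design: ExperimentDesign,
    alpha: float = 0.05,
    min_genes_for_moderation: int = 10,
) -> pd.DataFrame:
    """Per-protein arm-vs-unsupplemented moderated tests at the comparison day.

    ``table`` is tidy (species, protein, mouse, arm, log2_abundance) with
    one value per mouse (dpg 6). Returns per species/protein/arm: lfc,
    moderated t, p, BH-adjusted p.
    """
    arm_levels = [a for a in design.arms_present if a != "unsupplemented"]
    if not arm_levels:
        raise ProteomicsError("need at least one supplemented arm beside the control")
    if "unsupplemented" not in design.arms_present:
        raise ProteomicsError("no unsupplemented control arm in the design")
    results = []
    for sp, sub in table.groupby("species", sort=False):
        mat = sub.pivot_table(index="protein", columns="mouse", values="log2_abundance")
        mat = mat.dropna(axis=0)
        mice = list(mat.columns)
        arms = pd.Series({m: design.arms[m] for m in mice})
        for a in arm_levels + ["unsupplemented"]:
            if (arms == a).sum() < 3:
                raise ProteomicsError(f"need >= 3 mice in arm {a!r} at the comparison day")
        X = np.column_stack(
            [np.ones(len(mice))] + [(arms == a).astype(float).to_numpy() for a in arm_levels]
        )
        Y = mat.to_numpy()
        XtX_inv = np.linalg.pinv(X.T @ X)
        beta = Y @ X @ XtX_inv.T
        resid = Y - beta @ X.T
        df_resid = len(mice) - np.linalg.matrix_rank(X)
        if df_resid <= 0:
            raise ProteomicsError("zero residual degrees of freedom")
        s2 = (resid**2).sum(axis=1) / df_resid
        prior = (
            fit_variance_prior(s2, df_resid)
            if mat.shape[0] >= min_genes_for_moderation
            else VariancePrior(0.0, float(np.median(s2)) if len(s2) else 1.0)
        )
        for j, a in enumerate(arm_levels, start=1):
            unscaled = float(np.sqrt(XtX_inv[j, j]))
            t, p, _, _ = moderated_t(beta[:, j], unscaled, s2, df_resid, prior)
            res = pd.DataFrame(
                {
                    "species": sp,
                    "protein": mat.index,
                    "arm": a,
                    "lfc": beta[:, j],
                    "moderated_t": t,
                    "p_value": p,
                }
            )
            res["p_adjusted"] = bh_adjust(res["p_value"])
            results.append(res)
    return pd.concat(results, ignore_index=True)


def pul_set_test(
    lfc_table: pd.DataFrame,
    pul_annotation: pd.DataFrame,
    alpha: float = 0.05,
    variant: str = "background",
) -> pd.DataFrame:
    """One-sample Z test per PUL against the species background.

    ``lfc_table`` has species, protein, arm, lfc; ``pul_annotation`` has
    species, pul_id, gene (gene == protein ID). ``variant`` is
    ``"background"`` (Z of the member mean against the species-wide mean,
    default) or ``"zero"`` (member mean against 0 with the background sd).
    BH adjustment across PULs within species x arm. PULs with fewer than
    two quantified members are flagged untestable.
    """
    if variant not in ("background", "zero"):
        raise ProteomicsError(f"unknown Z-test variant {variant!r}")
    ann = pul_annotation.rename(columns={"gene": "protein"})
    dup = ann.duplicated(subset=["species", "protein"], keep=False)
    if dup.any():
        multi = ann.loc[dup].sort_values(["species", "protein"])
        raise ProteomicsError(
            "gene(s) assigned to more than one PUL within a species: "
            f"{multi['protein'].unique()[:5].tolist()}"
        )
    rows = []
    for (sp, arm), sub in lfc_table.groupby(["species", "arm"], sort=True):
        lfcs = sub.set_index("protein")["lfc"]
        g_mean, g_sd = float(lfcs.mean()), float(lfcs.std(ddof=1))
        for pul_id, members in ann[ann["species"] == sp].groupby("pul_id"):
            mem = lfcs.reindex(members["protein"]).dropna()
            n = len(mem)
            if n < 2:
                rows.append(
                    {
                        "species": sp, "arm": arm, "pul_id": pul_id, "n_members": n,
                        "mean_lfc": float(mem.mean()) if n else np.nan,
                        "z": np.nan, "p_value": np.nan, "testable": False,
                    }
                )
                continue
            center = 0.0 if variant == "zero" else g_mean
            z = (float(mem.mean()) - center) / (g_sd / np.sqrt(n))
            rows.append(
                {
                    "species": sp, "arm": arm, "pul_id": pul_id, "n_members": n,
                    "mean_lfc": float(mem.mean()),
                    "z": float(z),
                    "p_value": float(2.0 * stats.norm.sf(abs(z))),
                    "testable": True,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    for (sp, arm), idx in out.groupby(["species", "arm"]).groups.items():
        out.loc[idx, "p_adjusted"] = bh_adjust(out.loc[idx, "p_value"])
    out["responsive"] = out["p_adjusted"] < alpha
    out.loc[~out["testable"], "responsive"] = False
    return out
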