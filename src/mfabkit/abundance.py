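"""COPRO-Seq stage: genome-size-normalized relative abundance, spike-in
absolute abundance, diet-responsiveness classification, and the
specific-activity metric.

Relative abundance divides each strain's read count by its informative
genome size before renormalizing, so that a strain's share reflects genome
copies rather than sequenced bases. Absolute abundance anchors those shares
to the known number of spike-in cells added per sample:

    abs_{i,j} = (relab_{i,j} / relab_{spike,j}) * cells_added_j / mass_j

in genome equivalents per gram of feces.

A strain is called diet-responsive when, in a Gaussian linear mixed model of
absolute abundance on diet arm x day with a random intercept per animal,
at least ``min_significant_comparisons`` of the six pairwise arm
comparisons are significant after Tukey-HSD (within strain) and BH (across
strains) adjustment, and the estimated marginal mean of at least one
supplemented arm exceeds ``emm_ratio_threshold`` times the pooled
pre-switch (dpg 2) mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from ._stats import bh_adjust, tukey_pvalue
from .design import PRIMARY_SPIKEIN, SUPPLEMENTED_ARMS, ExperimentDesign, spikein_cells_added

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeInSpec",
    "ResponsivenessCriteria",
    "relative_abundance",
    "absolute_abundance",
    "classify_responsive",
    "specific_activity",
]


class AbundanceError(ValueError):
    pass


@dataclass(frozen=True)
class SpikeInSpec:
    """A known quantity of non-gut bacterial cells added to each sample."""

    strain: str = PRIMARY_SPIKEIN
    density_cells_per_ml: float = 2.22e8
    volume_ul: float = 30.0

    @property
    def cells_added(self) -> float:
        cells = self.density_cells_per_ml * self.volume_ul * 1e-3
        if cells <= 0:
            raise AbundanceError("spike-in cells_added must be > 0")
        return cells


@dataclass(frozen=True)
class ResponsivenessCriteria:
    """Thresholds defining a diet-responsive strain."""

    alpha: float = 0.01
    min_significant_comparisons: int = 3
    emm_ratio_threshold: float = 1.5
    baseline_day: int = 2
    log10_transform: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise AbundanceError("alpha must be in (0, 1)")
        if not 1 <= self.min_significant_comparisons <= 6:
            raise AbundanceError("min_significant_comparisons must be in [1, 6]")


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Genome-size-normalized relative abundance per sample.

    ``counts`` needs columns sample, strain, count, genome_size_bp (other
    columns pass through). Adds a ``relabundance`` column; within each
    sample the values sum to 1.
    """
    df = counts.copy()
    if (df["genome_size_bp"] <= 0).any():
        raise AbundanceError("informative genome sizes must be > 0")
    if (df["count"] < 0).any():
        raise AbundanceError("read counts must be >= 0")
    df["_density"] = df["count"] / df["genome_size_bp"]
    totals = df.groupby("sample")["_density"].transform("sum")
    zero = df.loc[totals == 0, "sample"].unique()
    if len(zero):
        raise AbundanceError(f"zero total genome-normalized density in sample(s): {list(zero)}")
    df["relabundance"] = df["_density"] / totals
    return df.drop(columns="_density")


def absolute_abundance(
    relab: pd.DataFrame,
    spikein: SpikeInSpec | None = None,
    mass_g: float | None = None,
) -> pd.DataFrame:
    """Convert relative to absolute abundance via the spike-in strain.

    ``relab`` needs columns sample, strain, relabundance and either a
    ``mass_g`` column or an explicit ``mass_g`` argument. Adds
    ``abs_abundance`` (genome equivalents per gram of feces).
    """
    spikein = spikein or SpikeInSpec()
    df = relab.copy()
    if mass_g is not None:
        df["mass_g"] = mass_g
    if "mass_g" not in df.columns:
        raise AbundanceError("feces mass: pass mass_g column or argument")
    spike = df[df["strain"] == spikein.strain].set_index("sample")["relabundance"]
    missing = sorted(set(df["sample"]) - set(spike.index))
    if missing:
        raise AbundanceError(f"spike-in {spikein.strain!r} absent from sample(s): {missing}")
    dropout = spike[spike <= 0]
    if len(dropout):
        raise AbundanceError(
            f"spike-in dropout (relabundance 0) in sample(s): {list(dropout.index)}"
        )
    df["abs_abundance"] = (
        df["relabundance"].to_numpy()
        / spike.loc[df["sample"]].to_numpy()
        * spikein.cells_added
        / df["mass_g"].to_numpy()
    )
    return df


_COMPARISONS = list(combinations(("unsupplemented", "pea_fiber", "PFABN", "SBABN"), 2))


def _fit_strain_mixed(sub: pd.DataFrame, arms: list[str]):
    """Mixed model abundance ~ arm*day (random intercept per mouse) on
    post-switch samples; returns (emm per arm, pairwise contrasts)."""
    sub = sub.copy()
    sub["arm"] = pd.Categorical(sub["arm"], categories=arms)
    # fit on a unit-scale response: contrasts/p-values are scale-invariant,
    # and raw genome-equivalent magnitudes (~1e10) break the optimizer
    scale = float(sub["abs_abundance"].abs().mean()) or 1.0
    sub["abs_abundance"] = sub["abs_abundance"] / scale
    days = sorted(sub["day"].unique())
    formula = "abs_abundance ~ C(arm) * C(day)" if len(days) > 1 else "abs_abundance ~ C(arm)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, sub, groups=sub["mouse"])
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=True, method="powell")
    fe = fit.fe_params
    cov = fit.cov_params().loc[fe.index, fe.index]
    exog_names = list(fe.index)

    def cell_row(arm, day):
        row = pd.Series(0.0, index=exog_names)
        row["Intercept"] = 1.0
        for name in exog_names:
            if name == f"C(arm)[T.{arm}]":
                row[name] = 1.0
            if name == f"C(day)[T.{day}]":
                row[name] = 1.0
            if name == f"C(arm)[T.{arm}]:C(day)[T.{day}]":
                row[name] = 1.0
        return row

    # EMM per arm: average of cell means over post-switch days
    emm_rows = {a: np.mean([cell_row(a, d) for d in days], axis=0) for a in arms}
    emm = {a: float(np.dot(emm_rows[a], fe.to_numpy())) * scale for a in arms}
    n_obs = len(sub)
    rank = np.linalg.matrix_rank(model.exog)
    df_resid = max(n_obs - rank - 1, 1)
    contrasts = []
    for a1, a2 in combinations(arms, 2):
        L = emm_rows[a1] - emm_rows[a2]
        est = float(np.dot(L, fe.to_numpy())) * scale
        se = float(np.sqrt(L @ cov.to_numpy() @ L)) * scale
        p = tukey_pvalue(est, se, n_groups=len(arms), df=df_resid)
        contrasts.append({"comparison": f"{a1}_vs_{a2}", "estimate": est, "se": se, "p_tukey": p})
    return emm, contrasts


def classify_responsive(
    abund: pd.DataFrame,
    design: ExperimentDesign,
    criteria: ResponsivenessCriteria | None = None,
) -> pd.DataFrame:
    """Per-strain diet-responsiveness calls.

    ``abund`` is the absolute-abundance table (sample, mouse, day, arm,
    strain, abs_abundance); spike-in rows should be excluded by the caller
    or are ignored if an ``is_spikein`` column is present.

    Returns one row per strain with the responsive call, the number of
    significant comparisons, the maximum supplemented-arm EMM ratio, and a
    ``testable`` flag (False for singular fits — never silently dropped).
    """
    criteria = criteria or ResponsivenessCriteria()
    df = abund.copy()
    if "is_spikein" in df.columns:
        df = df[~df["is_spikein"]]
    if criteria.log10_transform:
        df = df.assign(abs_abundance=np.log10(df["abs_abundance"].clip(lower=1.0)))
    arms = design.arms_present
    if len([a for a in arms if a != "unsupplemented"]) < 1 or len(arms) < 2:
        raise AbundanceError("need post-supplementation samples from >= 2 arms")
    for arm in arms:
        if len(design.mice_in_arm(arm)) < 3:
            raise AbundanceError(f"need >= 3 mice per arm (arm {arm!r})")

    post = df[df["day"] > criteria.baseline_day]
    baseline = df[df["day"] == criteria.baseline_day]
    if baseline.empty:
        raise AbundanceError(f"no baseline (dpg {criteria.baseline_day}) samples present")

    records, contrast_rows = [], []
    for strain, sub in post.groupby("strain", sort=True):
        base_mean = baseline.loc[baseline["strain"] == strain, "abs_abundance"].mean()
        try:
            emm, contrasts = _fit_strain_mixed(sub, arms)
            testable = all(np.isfinite(c["p_tukey"]) for c in contrasts)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("strain %s untestable: %s", strain, exc)
            emm, contrasts, testable = {}, [], False
        ratios = {
            a: (emm[a] / base_mean if emm and base_mean > 0 else np.nan) for a in emm
        }
        max_ratio = max(
            (r for a, r in ratios.items() if a in SUPPLEMENTED_ARMS and np.isfinite(r)),
            default=np.nan,
        )
        for c in contrasts:
            contrast_rows.append({"strain": strain, **c})
        records.append(
            {
                "strain": strain,
                "testable": testable,
                "baseline_mean": base_mean,
                "max_emm_ratio": max_ratio,
                **{f"emm_ratio_{a}": ratios.get(a, np.nan) for a in arms},
            }
        )
    calls = pd.DataFrame(records).set_index("strain")
    cdf = pd.DataFrame(contrast_rows)
    if not cdf.empty:
        # BH across strains, separately within each pairwise comparison
        cdf["p_adj"] = np.nan
        for comp, idx in cdf.groupby("comparison").groups.items():
            cdf.loc[idx, "p_adj"] = bh_adjust(cdf.loc[idx, "p_tukey"])
        n_sig = (
            cdf[cdf["p_adj"] < criteria.alpha].groupby("strain").size().reindex(calls.index).fillna(0)
        )
    else:
        n_sig = pd.Series(0, index=calls.index)
    calls["n_significant"] = n_sig.astype(int)
    calls["responsive"] = (
        calls["testable"]
        & (calls["n_significant"] >= criteria.min_significant_comparisons)
        & (calls["max_emm_ratio"] > criteria.emm_ratio_threshold)
    )
    calls.attrs["contrasts"] = cdf
    return calls.reset_index()


def specific_activity(
    abund: pd.DataFrame,
    responsive_strains: list[str],
    design: ExperimentDesign,
    post_day: int = 6,
    arms: list[str] | None = None,
) -> pd.DataFrame:
    """Supplement-specific activity per diet arm.

    For each supplemented arm (default: all supplemented arms present): the
    summed increase in responsive strains' absolute abundance between the
    pre-switch baseline and ``post_day``, averaged over mice, divided by
    the arm's supplement dose. Units: genome equivalents per gram feces per
    (gram supplement per day). Requesting the unsupplemented arm is an
    error (division by zero dose).
    """
    rows = []
    sub = abund[abund["strain"].isin(responsive_strains)]
    if arms is None:
        arms = [a for a in design.arms_present if a in SUPPLEMENTED_ARMS]
    for arm in arms:
        dose = design.dose_g_per_day.get(arm, 0.0)
        if dose <= 0:
            raise AbundanceError(
                f"specific activity undefined for arm {arm!r} with dose 0 "
                "(restrict to supplemented arms)"
            )
        deltas = []
        for mouse in design.mice_in_arm(arm):
            m = sub[sub["mouse"] == mouse]
            pre = m.loc[m["day"] == design.baseline_day, "abs_abundance"].sum()
            post = m.loc[m["day"] == post_day, "abs_abundance"].sum()
            deltas.append(post - pre)
        rows.append(
            {
                "arm": arm,
                "dose_g_per_day": dose,
                "mean_delta_abundance": float(np.mean(deltas)),
                "specific_activity": float(np.mean(deltas) / dose),
                "n_mice": len(deltas),
            }
        )
    return pd.DataFrame(rows)
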