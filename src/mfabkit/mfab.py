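"""MFAB stage: bead accounting, internal-standard GC-MS calibration,
per-bead monosaccharide mass, percent-remaining degradation, molecule and
amine-occupancy conversions, and group/synergy statistics.

Beads recovered from the gut carry whatever glycan the microbiota did not
remove. Quantification chain: counting beads give the absolute number of
sample beads per vial; internal-standard-corrected GC-MS peak areas on a
twofold dilution standard curve give monosaccharide mass per vial; dividing
by beads and referencing to never-gavaged input beads gives percent
remaining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "BeadChemistryParams",
    "StandardCurve",
    "count_beads",
    "correct_areas",
    "fit_standard_curve",
    "mass_per_bead",
    "percent_remaining",
    "molecules_per_bead",
    "amine_occupancy",
    "mann_whitney",
    "synergy_interaction",
]

AVOGADRO = 6.02214076e23


class MfabError(ValueError):
    pass


@dataclass(frozen=True)
class BeadChemistryParams:
    """Bead-surface chemistry constants for molecule/occupancy conversions.

    Defaults describe maltodextrin-coated amine+phosphonate beads: polymer
    number-average molar mass Mn ~= 1300 Da (dextrose equivalent 13-17),
    2.18e10 reactive amines and, for the streptavidin comparison, 9.21e8
    biotin sites per bead.
    """

    mn_da: float = 1300.0
    amines_per_bead: float = 2.18e10
    biotin_sites_per_bead: float = 9.21e8

    def __post_init__(self) -> None:
        if self.mn_da <= 0:
            raise MfabError("Mn must be > 0")


@dataclass(frozen=True)
class StandardCurve:
    analyte: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def quantify(self, corrected_area: float) -> float:
        """Invert the fitted line: mass (ng) for a corrected peak area."""
        if self.slope <= 0:
            raise MfabError(f"invalid standard curve for {self.analyte}: slope <= 0")
        return (corrected_area - self.intercept) / self.slope


def count_beads(events: pd.DataFrame) -> pd.Series:
    """Absolute sample beads per tube from counting-bead ratios.

    beads = sample_events * counting_beads_added / counting_events.
    ``events`` needs columns tube, sample_events, counting_events,
    counting_beads_added.
    """
    if (events["counting_events"] <= 0).any():
        bad = events.loc[events["counting_events"] <= 0, "tube"].tolist()
        raise MfabError(f"zero counting-bead events (no reference) in tube(s): {bad}")
    if (events["counting_beads_added"] <= 0).any():
        raise MfabError("counting beads added must be > 0")
    beads = (
        events["sample_events"]
        * events["counting_beads_added"]
        / events["counting_events"]
    )
    return pd.Series(beads.to_numpy(), index=events["tube"].to_numpy(), name="n_beads")


def correct_areas(peaks: pd.DataFrame) -> pd.DataFrame:
    """Internal-standard correction of raw peak areas.

    Each vial's areas are scaled by (reference IS area / vial IS area),
    where the reference is the median IS response of the series: a vial
    whose IS response drifted low has all its analyte areas scaled up
    proportionally, and a single drifted vial is restored exactly. Mass
    quantification through a standard curve corrected the same way is
    invariant to a global multiplicative drift shared by analyte and IS
    areas.
    """
    df = peaks.copy()
    if (df["is_area"] <= 0).any():
        bad = df.loc[df["is_area"] <= 0, "vial"].tolist()
        raise MfabError(f"non-positive internal-standard area in vial(s): {bad}")
    if (df["peak_area"] < 0).any():
        raise MfabError("peak areas must be >= 0")
    ref = df["is_area"].median()
    df["corrected_area"] = df["peak_area"] * ref / df["is_area"]
    return df


def fit_standard_curve(standards: pd.DataFrame, analyte: str) -> StandardCurve:
    """OLS line of IS-corrected area on nominal mass for one analyte.

    ``standards`` is the peak table restricted to (or containing) rows with
    role == "standard"; needs >= 3 dilution points with varying mass.
    """
    sub = standards[(standards["analyte"] == analyte)]
    if "role" in sub.columns:
        sub = sub[sub["role"] == "standard"]
    sub = sub.dropna(subset=["standard_mass_ng"])
    if len(sub) < 3:
        raise MfabError(f"{analyte}: need >= 3 dilution points, got {len(sub)}")
    if sub["standard_mass_ng"].nunique() < 2:
        raise MfabError(f"{analyte}: zero variance in standard masses")
    if "corrected_area" not in sub.columns:
        sub = correct_areas(sub)
    x = sub["standard_mass_ng"].to_numpy(dtype=float)
    y = sub["corrected_area"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(analyte, float(slope), float(intercept), r2, len(sub))


def mass_per_bead(
    peaks: pd.DataFrame,
    curves: dict[str, StandardCurve],
    n_beads: pd.Series,
) -> pd.DataFrame:
    """Monosaccharide mass per 1000 beads for input/recovered vials.

    Negative mass estimates (area below the intercept) are clipped to 0 and
    flagged. ``n_beads`` is indexed by vial/tube ID.
    """
    sub = peaks[peaks["role"].isin(["input", "recovered"])].copy()
    if "corrected_area" not in sub.columns:
        corrected = correct_areas(peaks)
        sub = corrected[corrected["role"].isin(["input", "recovered"])].copy()
    rows = []
    for _, r in sub.iterrows():
        curve = curves[r["analyte"]]
        beads = float(n_beads.get(r["vial"], np.nan))
        if not np.isfinite(beads) or beads <= 0:
            raise MfabError(f"vial {r['vial']!r}: no positive bead count available")
        mass = curve.quantify(r["corrected_area"])
        clipped = mass < 0
        if clipped:
            logger.warning("vial %s: negative mass estimate clipped to 0", r["vial"])
            mass = 0.0
        rows.append(
            {
                "vial": r["vial"],
                "animal": r.get("animal"),
                "bead_type": r.get("bead_type"),
                "analyte": r["analyte"],
                "role": r["role"],
                "n_beads": beads,
                "ng_per_1000_beads": mass / beads * 1000.0,
                "clipped": clipped,
            }
        )
    return pd.DataFrame(rows)


def percent_remaining(recovered: pd.DataFrame, input_beads: pd.DataFrame) -> pd.DataFrame:
    """Percent of input per-bead monosaccharide mass still on recovered beads.

    Rows are matched on (bead_type, analyte). Values above 100% are
    permitted but flagged.
    """
    inp = input_beads.set_index(["bead_type", "analyte"])["ng_per_1000_beads"]
    if (inp <= 0).any():
        bad = inp[inp <= 0].index.tolist()
        raise MfabError(f"input per-bead mass must be > 0; offending bead/analyte: {bad}")
    out = recovered.copy()
    keys = list(zip(out["bead_type"], out["analyte"]))
    missing = [k for k in keys if k not in inp.index]
    if missing:
        raise MfabError(f"no input-bead reference for {sorted(set(missing))}")
    ref = np.array([inp.loc[k] for k in keys], dtype=float)
    out["percent_remaining"] = 100.0 * out["ng_per_1000_beads"].to_numpy() / ref
    out["over_100"] = out["percent_remaining"] > 100.0
    return out


def molecules_per_bead(ng_per_1000_beads: float, chem: BeadChemistryParams | None = None) -> float:
    """Polymer molecules per bead from monosaccharide mass per 1000 beads.

    molecules = mass_per_bead(g) * N_A / Mn. The released-monosaccharide
    mass stands in for polymer mass (4.43 ng glucose/1000 beads at
    Mn = 1300 Da gives 2.05e9 molecules/bead).
    """
    chem = chem or BeadChemistryParams()
    grams_per_bead = ng_per_1000_beads * 1e-9 / 1000.0
    return grams_per_bead * AVOGADRO / chem.mn_da


def amine_occupancy(molecules: float, chem: BeadChemistryParams | None = None) -> float:
    """Percent of surface reactive amines occupied by polymer molecules."""
    chem = chem or BeadChemistryParams()
    return 100.0 * molecules / chem.amines_per_bead


# ---------------------------------------------------------------------------
# Statistics

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for group a (ties count 1/2)."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(a, b, exact_max_n: int = 16) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    For combined n <= ``exact_max_n`` the p-value is exact: all
    C(n, n_a) assignments of the pooled values are enumerated and the
    two-sided p is P(U' <= U_low) + P(U' >= n_a n_b - U_low) with
    U_low = min(U, n_a n_b - U). Larger samples use the tie-corrected
    normal approximation (no continuity correction). All values tied
    across both groups gives p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise MfabError("each group needs n >= 3")
    u = _u_statistic(a, b)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return u, 1.0
    n = n1 + n2
    u_low = min(u, n1 * n2 - u)
    u_high = n1 * n2 - u_low
    if n <= exact_max_n:
        total = comb(n, n1)
        count = 0
        idx_all = frozenset(range(n))
        for picks in combinations(range(n), n1):
            ga = pooled[list(picks)]
            gb = pooled[list(idx_all - set(picks))]
            up = _u_statistic(ga, gb)
            if up <= u_low + 1e-12 or up >= u_high - 1e-12:
                count += 1
        return u, min(1.0, count / total)
    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (u - n1 * n2 / 2.0) / np.sqrt(sigma2)
    return u, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def synergy_interaction(
    table: pd.DataFrame,
    response: str = "percent_remaining",
    diet: str = "arm",
    bead: str = "bead_type",
) -> pd.DataFrame:
    """Diet x bead-type interaction test on percent remaining.

    Ordinary least squares ``response ~ diet + bead + diet:bead``; reports
    each interaction coefficient with its 95% CI and t-test p-value. A
    negative interaction for a colocalized bead type means the supplement
    enhanced degradation of that bead beyond the additive expectation.
    Every diet x bead cell must be populated (>= 1 animal), with >= 2 diet
    arms and >= 2 bead types.
    """
    diets = table[diet].unique()
    beads = table[bead].unique()
    if len(diets) < 2 or len(beads) < 2:
        raise MfabError("need >= 2 diet arms and >= 2 bead types")
    cells = table.groupby([diet, bead]).size()
    for d in diets:
        for b in beads:
            if (d, b) not in cells.index:
                raise MfabError(f"empty design cell: diet {d!r} x bead {b!r}")
    ref_diet = "unsupplemented" if "unsupplemented" in diets else sorted(diets)[0]
    formula = f"{response} ~ C({diet}, Treatment('{ref_diet}')) * C({bead})"
    fit = smf.ols(formula, data=table).fit()
    conf = fit.conf_int()
    rows = []
    for name in fit.params.index:
        if ":" not in name:
            continue
        rows.append(
            {
                "term": name,
                "estimate": float(fit.params[name]),
                "ci_low": float(conf.loc[name, 0]),
                "ci_high": float(conf.loc[name, 1]),
                "p_value": float(fit.pvalues[name]),
            }
        )
    return pd.DataFrame(rows)
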