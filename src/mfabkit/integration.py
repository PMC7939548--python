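"""Fitness-vs-expression quadrant analysis.

Each gene with both a proteomic log2 fold change (x) and an INSeq fitness
score (y) is a point. Genes inside an ellipse of the interquartile range —
centered at the medians with semi-axes IQR_x/2 and IQR_y/2 — are treated
as unremarkable and excluded. Among the remaining genes, a 2x2 chi-square
asks whether a PUL's members are overrepresented in the lower-right
quadrant (x > 0, y < 0: highly expressed, costly to disrupt), using all
other genes with both measurements as the null.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import bh_adjust, chisq_2x2

logger = logging.getLogger(__name__)

__all__ = ["iqr_ellipse_mask", "quadrant_chisq"]


class IntegrationError(ValueError):
    pass


def iqr_ellipse_mask(
    points: pd.DataFrame,
    x: str = "lfc",
    y: str = "fitness_score",
    semi_axis_iqr_factor: float = 0.5,
) -> pd.Series:
    """Boolean mask: True for points inside (or on) the IQR ellipse.

    The ellipse is centered at (median x, median y) with semi-axes
    ``semi_axis_iqr_factor * IQR`` per axis (0.5 reads "ellipse of the
    interquartile range" as full width = IQR). A zero IQR on either axis is
    degenerate: every point is treated as outside, with a warning.
    """
    if len(points) < 4:
        raise IntegrationError("need >= 4 points for quartiles")
    xv = points[x].to_numpy(dtype=float)
    yv = points[y].to_numpy(dtype=float)
    med_x, med_y = np.median(xv), np.median(yv)
    iqr_x = np.subtract(*np.percentile(xv, [75, 25]))
    iqr_y = np.subtract(*np.percentile(yv, [75, 25]))
    if iqr_x <= 0 or iqr_y <= 0:
        logger.warning("degenerate IQR ellipse (zero IQR); treating all points as outside")
        return pd.Series(False, index=points.index, name="inside_ellipse")
    ax, ay = semi_axis_iqr_factor * iqr_x, semi_axis_iqr_factor * iqr_y
    q = ((xv - med_x) / ax) ** 2 + ((yv - med_y) / ay) ** 2
    return pd.Series(q <= 1.0, index=points.index, name="inside_ellipse")


def quadrant_chisq(
    points: pd.DataFrame,
    pul_annotation: pd.DataFrame,
    x: str = "lfc",
    y: str = "fitness_score",
    x_boundary: float = 0.0,
    y_boundary: float = 0.0,
    semi_axis_iqr_factor: float = 0.5,
) -> pd.DataFrame:
    """Per-PUL chi-square for lower-right-quadrant overrepresentation.

    ``points`` needs species, gene, x and y columns; ``pul_annotation``
    needs species, pul_id, gene. The IQR ellipse is computed per species
    and its genes excluded from every table. Pearson chi-square without
    continuity correction; BH across PULs within species. A PUL with an
    empty margin gets statistic 0 and p 1, flagged.
    """
    rows = []
    for sp, sub in points.groupby("species", sort=True):
        inside = iqr_ellipse_mask(sub, x=x, y=y, semi_axis_iqr_factor=semi_axis_iqr_factor)
        outside = sub[~inside]
        in_quad = (outside[x] > x_boundary) & (outside[y] < y_boundary)
        ann = pul_annotation[pul_annotation["species"] == sp]
        for pul_id, members in ann.groupby("pul_id"):
            is_pul = outside["gene"].isin(set(members["gene"]))
            if not is_pul.any():
                rows.append(
                    {
                        "species": sp, "pul_id": pul_id,
                        "pul_in_quadrant": 0, "pul_outside_quadrant": 0,
                        "other_in_quadrant": int(in_quad[~is_pul].sum()),
                        "other_outside_quadrant": int((~in_quad[~is_pul]).sum()),
                        "chi2": 0.0, "p_value": 1.0, "degenerate": True,
                    }
                )
                continue
            table = np.array(
                [
                    [int(in_quad[is_pul].sum()), int((~in_quad[is_pul]).sum())],
                    [int(in_quad[~is_pul].sum()), int((~in_quad[~is_pul]).sum())],
                ]
            )
            chi2, p = chisq_2x2(table)
            degenerate = bool(
                table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0
            )
            rows.append(
                {
                    "species": sp, "pul_id": pul_id,
                    "pul_in_quadrant": int(table[0, 0]),
                    "pul_outside_quadrant": int(table[0, 1]),
                    "other_in_quadrant": int(table[1, 0]),
                    "other_outside_quadrant": int(table[1, 1]),
                    "chi2": chi2, "p_value": p, "degenerate": degenerate,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    for sp, idx in out.groupby("species").groups.items():
        out.loc[idx, "p_adjusted"] = bh_adjust(out.loc[idx, "p_value"])
    return out
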