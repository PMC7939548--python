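"""Experiment-design containers shared by the generators and analyses.

The modeled experiment: gnotobiotic mice colonized with a defined 14-strain
human gut consortium, fed a HiSF-LoFV base diet, and switched two days
post-gavage (dpg 2) to the same diet supplemented with pea fiber, pea-fiber
arabinan (PFABN), sugar-beet arabinan (SBABN), or left unsupplemented.
Fecal samples carry two non-gut spike-in strains for absolute-abundance
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ARMS = ("unsupplemented", "pea_fiber", "PFABN", "SBABN")
SUPPLEMENTED_ARMS = ("pea_fiber", "PFABN", "SBABN")

#: Spike-in cell suspensions added to every fecal sample before DNA
#: extraction: 30 uL each of 2.22e8 cells/mL (A. acidiphilus, used for the
#: absolute-abundance equation) and 9.93e8 cells/mL (A. radiobacter, QC).
SPIKEIN_DENSITIES = {
    "A_acidiphilus": 2.22e8,
    "A_radiobacter": 9.93e8,
}
SPIKEIN_VOLUME_UL = 30.0
PRIMARY_SPIKEIN = "A_acidiphilus"

DEFAULT_STRAINS = {
    # strain id -> informative genome size (bp): the uniquely mappable
    # portion of each genome, used to normalize read counts
    "B_thetaiotaomicron_VPI5482": 6.0e6,
    "B_thetaiotaomicron_7330": 6.2e6,
    "B_vulgatus_ATCC8482": 4.8e6,
    "B_cellulosilyticus_WH2": 6.8e6,
    "B_ovatus_ATCC8483": 6.3e6,
    "B_caccae": 4.3e6,
    "B_finegoldii": 4.9e6,
    "B_massiliensis": 4.2e6,
    "P_distasonis": 4.6e6,
    "E_rectale": 3.4e6,
    "C_aerofaciens": 2.4e6,
    "R_obeum": 3.6e6,
    "D_longicatena": 2.9e6,
    "F_prausnitzii_distractor": 3.1e6,
}
DEFAULT_SPIKEIN_SIZES = {
    "A_acidiphilus": 3.0e6,
    "A_radiobacter": 5.7e6,
}


class DesignError(ValueError):
    """Raised when an experiment design violates its invariants."""


@dataclass
class ExperimentDesign:
    """Mice, diet arms, sampling days and strain panel for one experiment.

    Parameters
    ----------
    mice : list of animal IDs
    arms : diet arm per mouse, aligned with ``mice``
    days : sampling days (dpg); must include the pre-switch baseline (dpg 2)
    dose_g_per_day : supplement mass consumed per day for each arm (g/day)
    strains : strain ID -> informative genome size (bp)
    spikeins : spike-in strain ID -> informative genome size (bp)
    baseline_day : the pre-switch sampling day
    """

    mice: list[str]
    arms: dict[str, str]
    days: list[int] = field(default_factory=lambda: [2, 6, 10])
    dose_g_per_day: dict[str, float] = field(
        default_factory=lambda: {
            "unsupplemented": 0.0,
            "pea_fiber": 0.5,
            "PFABN": 0.5,
            "SBABN": 0.5,
        }
    )
    strains: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STRAINS))
    spikeins: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPIKEIN_SIZES))
    baseline_day: int = 2

    def __post_init__(self) -> None:
        missing = [m for m in self.mice if m not in self.arms]
        if missing:
            raise DesignError(f"mice without a diet arm: {missing}")
        bad = sorted(set(self.arms.values()) - set(ARMS))
        if bad:
            raise DesignError(f"unknown diet arms: {bad} (expected one of {ARMS})")
        if self.baseline_day not in self.days:
            raise DesignError(
                f"baseline day dpg {self.baseline_day} missing from days {self.days}"
            )
        if 6 not in self.days:
            raise DesignError("dpg 6 must be among the sampling days")
        for arm, dose in self.dose_g_per_day.items():
            if arm == "unsupplemented" and dose != 0:
                raise DesignError("unsupplemented arm must have dose 0")
            if arm != "unsupplemented" and dose <= 0:
                raise DesignError(f"supplemented arm {arm!r} needs dose > 0")

    @property
    def arms_present(self) -> list[str]:
        return [a for a in ARMS if a in set(self.arms.values())]

    def mice_in_arm(self, arm: str) -> list[str]:
        return [m for m in self.mice if self.arms[m] == arm]

    def post_days(self) -> list[int]:
        return [d for d in self.days if d > self.baseline_day]


def default_design(n_per_arm: int = 4, days: list[int] | None = None) -> ExperimentDesign:
    """Balanced design: ``n_per_arm`` mice in each of the four diet arms."""
    mice, arms = [], {}
    for arm in ARMS:
        for k in range(n_per_arm):
            mid = f"{arm}_m{k + 1}"
            mice.append(mid)
            arms[mid] = arm
    return ExperimentDesign(mice=mice, arms=arms, days=days or [2, 6, 10])


def spikein_cells_added(strain: str = PRIMARY_SPIKEIN) -> float:
    """Absolute spike-in cells added per sample (volume x density)."""
    return SPIKEIN_VOLUME_UL * 1e-3 * SPIKEIN_DENSITIES[strain]
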