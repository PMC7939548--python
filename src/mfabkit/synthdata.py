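"""Seeded generators for every input table the pipeline consumes.

Each generator emulates the statistical structure of one assay:

* ``simulate_coproseq`` — shotgun community profiling (COPRO-Seq): reads per
  strain are multinomial with probabilities proportional to true cell count
  times informative genome size; two spike-in strains are added at a fixed,
  known cell number per sample.
* ``simulate_inseq`` — transposon-insertion sequencing: per-gene mutant
  counts at the pre-switch baseline (dpg 2) and dpg 6, with planted log2
  fitness effects acting multiplicatively on the dpg-6 expectation and
  lognormal mouse-level noise.
* ``simulate_proteomics`` — label-free protein abundances on the log2
  scale, left-censored at an instrument detection limit, with planted diet
  effects on designated PUL member proteins.
* ``simulate_gcms`` — internal-standard GC-MS peak areas for twofold
  dilution standards, input beads and recovered beads, plus a
  counting-bead flow-cytometry table; true degradation is specified per
  bead type and arm.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .design import (
    ARMS,
    PRIMARY_SPIKEIN,
    SUPPLEMENTED_ARMS,
    ExperimentDesign,
    default_design,
    spikein_cells_added,
)

__all__ = [
    "SimulationParams",
    "BeadDesign",
    "default_bead_design",
    "simulate_coproseq",
    "simulate_inseq",
    "simulate_proteomics",
    "simulate_gcms",
]


class ConfigurationError(ValueError):
    """A simulation parameter block is incomplete or inconsistent."""


@dataclass
class SimulationParams:
    """Knobs for all generators. Defaults define the study conditions.

    ``fold_changes`` maps (strain, arm) to the multiplicative change in true
    cell density after the diet switch; ``fitness_effects`` maps
    (species, gene, arm) to a planted log2 fitness effect;
    ``protein_effects`` maps (species, protein, arm) to a planted log2
    abundance effect; ``degradation_truth`` maps (bead_type, arm) to the
    true fraction of bead-bound monosaccharide removed in vivo.
    """

    seed: int = 0
    read_depth: int = 1_000_000
    true_load: float = 1e11            # total cells per gram of feces
    sample_mass_g: float = 0.05
    fold_changes: dict[tuple[str, str], float] = field(default_factory=dict)
    fitness_effects: dict[tuple[str, str, str], float] = field(default_factory=dict)
    protein_effects: dict[tuple[str, str, str], float] = field(default_factory=dict)
    lod_log2: float = 14.0
    coproseq_noise_sd: float = 0.15    # lognormal sigma on true cells (natural log)
    inseq_noise_sd: float = 0.2        # lognormal sigma on per-gene counts (log2)
    proteomics_noise_sd: float = 0.5   # additive sd on log2 abundance
    gcms_noise_sd: float = 0.05        # multiplicative lognormal sigma on peak areas
    degradation_truth: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.read_depth < 1e5:
            raise ConfigurationError("read_depth must be >= 1e5")
        for key, f in self.degradation_truth.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"degradation fraction for {key} not in [0,1]: {f}")
        for name in ("coproseq_noise_sd", "inseq_noise_sd", "proteomics_noise_sd", "gcms_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


# stable per-stream offsets so generators draw from independent streams
_STREAMS = {"coproseq": 11, "inseq": 23, "proteomics": 37, "gcms": 53}


def _stream_rng(params: SimulationParams, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, _STREAMS[stream]]))


# ---------------------------------------------------------------------------
# COPRO-Seq

def simulate_coproseq(design: ExperimentDesign, params: SimulationParams) -> pd.DataFrame:
    """Simulate a strain-by-sample read-count table.

    Returns a tidy frame with columns sample, mouse, day, arm, mass_g,
    strain, count, genome_size_bp, is_spikein. Counts per sample sum exactly
    to ``params.read_depth``.
    """
    rng = _stream_rng(params, "coproseq")
    strains = list(design.strains)
    for strain, arm in product(strains, design.arms_present):
        if (strain, arm) not in params.fold_changes:
            raise ConfigurationError(
                f"fold_changes missing entry for strain/arm pair ({strain!r}, {arm!r})"
            )
    # fixed uneven baseline composition, drawn once per seed
    base = rng.dirichlet(np.full(len(strains), 6.0))
    spike_cells = {s: spikein_cells_added(s) for s in design.spikeins}

    rows = []
    for mouse in design.mice:
        arm = design.arms[mouse]
        for day in design.days:
            sample = f"{mouse}_d{day}"
            cells = base * params.true_load * params.sample_mass_g
            if day > design.baseline_day:
                fc = np.array([params.fold_changes[(s, arm)] for s in strains])
                cells = cells * fc
            if params.coproseq_noise_sd > 0:
                cells = cells * rng.lognormal(0.0, params.coproseq_noise_sd, len(strains))
            all_ids = strains + list(design.spikeins)
            sizes = np.array(
                [design.strains[s] for s in strains]
                + [design.spikeins[s] for s in design.spikeins]
            )
            all_cells = np.concatenate([cells, [spike_cells[s] for s in design.spikeins]])
            probs = all_cells * sizes
            probs = probs / probs.sum()
            counts = rng.multinomial(params.read_depth, probs)
            for sid, size, n, spike in zip(
                all_ids, sizes, counts, [False] * len(strains) + [True] * len(design.spikeins)
            ):
                rows.append(
                    {
                        "sample": sample,
                        "mouse": mouse,
                        "day": day,
                        "arm": arm,
                        "mass_g": params.sample_mass_g,
                        "strain": sid,
                        "count": int(n),
                        "genome_size_bp": size,
                        "is_spikein": spike,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# INSeq

def simulate_inseq(
    design: ExperimentDesign,
    params: SimulationParams,
    species: list[str] | None = None,
    n_genes: int = 200,
) -> pd.DataFrame:
    """Simulate per-gene insertion-mutant counts at dpg 2 and dpg 6.

    A gene with planted effect ``e`` in arm ``a`` has its expected dpg-6
    count scaled by ``2**e`` relative to control mice. Counts are
    expected-scale values with multiplicative lognormal mouse noise; with
    ``inseq_noise_sd = 0`` they equal their expectations exactly, so planted
    effects propagate through the fitness score in closed form.

    Returns columns species, gene, sample, mouse, day, arm, count.
    """
    if "unsupplemented" not in design.arms_present:
        raise ConfigurationError("INSeq simulation needs an unsupplemented control arm")
    rng = _stream_rng(params, "inseq")
    species = species or ["B_thetaiotaomicron_VPI5482"]
    rows = []
    for sp in species:
        genes = [f"{sp}_g{i:04d}" for i in range(n_genes)]
        base = rng.lognormal(np.log(2000.0), 0.8, n_genes)  # per-gene library abundance
        for mouse in design.mice:
            arm = design.arms[mouse]
            for day in (design.baseline_day, 6):
                mu = base.copy()
                if day > design.baseline_day:
                    eff = np.array(
                        [params.fitness_effects.get((sp, g, arm), 0.0) for g in genes]
                    )
                    mu = mu * np.power(2.0, eff)
                if params.inseq_noise_sd > 0:
                    mu = mu * np.power(
                        2.0, rng.normal(0.0, params.inseq_noise_sd, n_genes)
                    )
                sample = f"{mouse}_d{day}"
                rows.extend(
                    {
                        "species": sp,
                        "gene": g,
                        "sample": sample,
                        "mouse": mouse,
                        "day": day,
                        "arm": arm,
                        "count": c,
                    }
                    for g, c in zip(genes, mu)
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Metaproteomics

def simulate_proteomics(
    design: ExperimentDesign,
    params: SimulationParams,
    pul_annotation: pd.DataFrame | None = None,
    species: list[str] | None = None,
    n_proteins: int = 300,
    day: int = 6,
    feature_prefix: str = "p",
) -> pd.DataFrame:
    """Simulate a log2 protein-abundance table at the comparison day.

    Baseline abundances are log-normal (normal on the log2 scale); planted
    ``protein_effects`` shift designated proteins in supplemented arms;
    values below ``lod_log2`` are recorded as missing (NaN, detected=False).

    Returns columns species, protein, sample, mouse, day, arm,
    log2_abundance, detected.
    """
    rng = _stream_rng(params, "proteomics")
    species = species or ["B_thetaiotaomicron_VPI5482"]
    rows = []
    for sp in species:
        proteins = [f"{sp}_{feature_prefix}{i:04d}" for i in range(n_proteins)]
        base = rng.normal(20.0, 3.0, n_proteins)
        for mouse in design.mice:
            arm = design.arms[mouse]
            eff = np.array(
                [params.protein_effects.get((sp, p, arm), 0.0) for p in proteins]
            )
            vals = base + eff
            if params.proteomics_noise_sd > 0:
                vals = vals + rng.normal(0.0, params.proteomics_noise_sd, n_proteins)
            detected = vals >= params.lod_log2
            sample = f"{mouse}_d{day}"
            rows.extend(
                {
                    "species": sp,
                    "protein": p,
                    "sample": sample,
                    "mouse": mouse,
                    "day": day,
                    "arm": arm,
                    "log2_abundance": v if ok else np.nan,
                    "detected": bool(ok),
                }
                for p, v, ok in zip(proteins, vals, detected)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GC-MS + flow cytometry (MFAB)

ANALYTES = ("arabinose", "galactose", "xylose", "glucose", "mannose", "rhamnose")


@dataclass
class BeadDesign:
    """Which bead types went into which animals, and their glycan loads.

    ``load_ng_per_1000`` is the true input loading of the reporter
    monosaccharide per 1000 beads (the observed conjugation range is roughly
    2-20 ng arabinose per 1000 beads).
    """

    animals: list[str]
    arms: dict[str, str]
    bead_types: list[str] = field(default_factory=lambda: ["PFABN", "SBABN", "acetylated"])
    analyte: dict[str, str] = field(
        default_factory=lambda: {
            "PFABN": "arabinose",
            "SBABN": "arabinose",
            "acetylated": "arabinose",
        }
    )
    load_ng_per_1000: dict[str, float] = field(
        default_factory=lambda: {"PFABN": 10.0, "SBABN": 10.0, "acetylated": 2.0}
    )
    n_beads_hydrolyzed: float = 3000.0
    counting_beads_added: float = 50_000.0


def default_bead_design(n_per_arm: int = 6, arms: tuple[str, ...] = ("unsupplemented", "pea_fiber")) -> BeadDesign:
    animals, amap = [], {}
    for arm in arms:
        for k in range(n_per_arm):
            a = f"{arm}_a{k + 1}"
            animals.append(a)
            amap[a] = arm
    return BeadDesign(animals=animals, arms=amap)


def simulate_gcms(
    bead_design: BeadDesign, params: SimulationParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate GC-MS peak areas and a flow-cytometry counting-bead table.

    Emits, per analyte, a seven-point twofold dilution standard series; per
    bead type, one input-bead vial; per animal x bead type, one
    recovered-bead vial whose true per-bead mass is the input load times
    (1 - true degradation). Every vial carries a D6-myo-inositol internal
    standard (15 ng nominal) whose area shares the vial's multiplicative
    instrument drift, so IS correction cancels it.

    Returns (peaks, flow_events).
    """
    rng = _stream_rng(params, "gcms")
    slope_true = {an: 120.0 * (1 + 0.1 * i) for i, an in enumerate(ANALYTES)}
    is_mass_ng = 15.0
    is_area_base = 1800.0
    sigma = params.gcms_noise_sd

    def drift() -> float:
        return float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0

    peaks = []

    def vial(vial_id, analyte, role, true_mass_ng, std_mass=np.nan, animal=None, bead_type=None):
        d = drift()
        extra = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
        peaks.append(
            {
                "vial": vial_id,
                "analyte": analyte,
                "role": role,
                "peak_area": slope_true[analyte] * true_mass_ng * d * extra,
                "is_area": is_area_base * d,
                "is_mass_ng": is_mass_ng,
                "standard_mass_ng": std_mass,
                "animal": animal,
                "bead_type": bead_type,
            }
        )

    for an in ANALYTES:
        mass = 200.0
        for i in range(7):
            vial(f"std_{an}_{i}", an, "standard", mass, std_mass=mass)
            mass /= 2.0

    used_analytes = set(bead_design.analyte.values())
    for bt in bead_design.bead_types:
        an = bead_design.analyte[bt]
        if an not in used_analytes:
            continue
        mass = bead_design.load_ng_per_1000[bt] * bead_design.n_beads_hydrolyzed / 1000.0
        vial(f"input_{bt}", an, "input", mass, bead_type=bt)

    flow = []
    for animal in bead_design.animals:
        arm = bead_design.arms[animal]
        for bt in bead_design.bead_types:
            frac = params.degradation_truth.get((bt, arm), 0.0)
            an = bead_design.analyte[bt]
            mass = (
                bead_design.load_ng_per_1000[bt]
                * (1.0 - frac)
                * bead_design.n_beads_hydrolyzed
                / 1000.0
            )
            vial(f"rec_{animal}_{bt}", an, "recovered", mass, animal=animal, bead_type=bt)
            # counting-bead reference: sample events scale with beads present
            count_events = 1000.0
            sample_events = (
                bead_design.n_beads_hydrolyzed
                * count_events
                / bead_design.counting_beads_added
            )
            flow.append(
                {
                    "tube": f"rec_{animal}_{bt}",
                    "animal": animal,
                    "arm": arm,
                    "bead_type": bt,
                    "sample_events": sample_events,
                    "counting_events": count_events,
                    "counting_beads_added": bead_design.counting_beads_added,
                }
            )
    for bt in bead_design.bead_types:
        flow.append(
            {
                "tube": f"input_{bt}",
                "animal": "input",
                "arm": "input",
                "bead_type": bt,
                "sample_events": bead_design.n_beads_hydrolyzed
                * 1000.0
                / bead_design.counting_beads_added,
                "counting_events": 1000.0,
                "counting_beads_added": bead_design.counting_beads_added,
            }
        )
    return pd.DataFrame(peaks), pd.DataFrame(flow)
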