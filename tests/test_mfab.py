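"""Bead quantification: counting-bead arithmetic, IS-corrected standard
curves, per-bead mass and percent remaining, molecule conversions, and the
Mann-Whitney / synergy statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mfabkit as mk
from mfabkit.mfab import (
    AVOGADRO,
    BeadChemistryParams,
    MfabError,
    StandardCurve,
    correct_areas,
)
from mfabkit.synthdata import SimulationParams, default_bead_design


class TestCountBeads:
    def test_ratio_arithmetic(self):
        ev = pd.DataFrame(
            {
                "tube": ["t1"],
                "sample_events": [5000],
                "counting_events": [1000],
                "counting_beads_added": [50_000],
            }
        )
        assert mk.count_beads(ev)["t1"] == pytest.approx(250_000)

    def test_zero_sample_events_zero_beads(self):
        ev = pd.DataFrame(
            {
                "tube": ["t1"],
                "sample_events": [0],
                "counting_events": [1000],
                "counting_beads_added": [50_000],
            }
        )
        assert mk.count_beads(ev)["t1"] == 0

    def test_ratio_invariance(self):
        ev = pd.DataFrame(
            {
                "tube": ["a", "b"],
                "sample_events": [5000, 10000],
                "counting_events": [1000, 2000],
                "counting_beads_added": [50_000, 50_000],
            }
        )
        beads = mk.count_beads(ev)
        assert beads["a"] == pytest.approx(beads["b"])

    def test_zero_counting_events_is_error(self):
        ev = pd.DataFrame(
            {
                "tube": ["t1"],
                "sample_events": [10],
                "counting_events": [0],
                "counting_beads_added": [50_000],
            }
        )
        with pytest.raises(MfabError, match="t1"):
            mk.count_beads(ev)


def _standards(masses, slope=2.0, is_area=100.0, is_scale=None):
    n = len(masses)
    is_areas = np.full(n, is_area) if is_scale is None else is_area * np.asarray(is_scale)
    return pd.DataFrame(
        {
            "vial": [f"v{i}" for i in range(n)],
            "analyte": "arabinose",
            "role": "standard",
            "peak_area": slope * np.asarray(masses) * (is_areas / is_area),
            "is_area": is_areas,
            "is_mass_ng": 15.0,
            "standard_mass_ng": masses,
        }
    )


class TestStandardCurve:
    def test_perfect_line(self):
        curve = mk.fit_standard_curve(_standards([1, 2, 4, 8, 16]), "arabinose")
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)

    def test_is_correction_cancels_vial_drift(self):
        # one vial's IS response halved: raw areas halve too, correction
        # restores the identical curve
        clean = mk.fit_standard_curve(_standards([1, 2, 4, 8]), "arabinose")
        drifted = mk.fit_standard_curve(
            _standards([1, 2, 4, 8], is_scale=[1, 0.5, 1, 1]), "arabinose"
        )
        assert drifted.slope == pytest.approx(clean.slope)
        assert drifted.intercept == pytest.approx(clean.intercept, abs=1e-9)

    def test_quantify_inverts_line(self):
        curve = mk.fit_standard_curve(_standards([1, 2, 4, 8]), "arabinose")
        assert curve.quantify(10.0) == pytest.approx(5.0)

    def test_global_instrument_drift_cancels_in_quantification(self):
        # a shared multiplicative drift on analyte AND IS areas (standards
        # and sample alike) leaves the estimated mass invariant
        base = _standards([1, 2, 4, 8])
        sample = pd.DataFrame(
            {
                "vial": ["s"],
                "analyte": "arabinose",
                "role": "recovered",
                "peak_area": [10.0],
                "is_area": [100.0],
                "is_mass_ng": 15.0,
                "standard_mass_ng": [np.nan],
            }
        )
        def quantify(table):
            corrected = correct_areas(table)
            curve = mk.fit_standard_curve(corrected, "arabinose")
            return curve.quantify(
                corrected.loc[corrected["role"] == "recovered", "corrected_area"].item()
            )
        table = pd.concat([base, sample], ignore_index=True)
        drifted = table.assign(
            peak_area=table["peak_area"] * 1.7, is_area=table["is_area"] * 1.7
        )
        assert quantify(drifted) == pytest.approx(quantify(table))
        assert quantify(table) == pytest.approx(5.0)

    def test_too_few_points_is_error(self):
        with pytest.raises(MfabError, match="3 dilution points"):
            mk.fit_standard_curve(_standards([1, 2]), "arabinose")


class TestMassAndPercentRemaining:
    def _record(self, ng, bead_type="PFABN"):
        return pd.DataFrame(
            {
                "bead_type": [bead_type],
                "analyte": ["arabinose"],
                "ng_per_1000_beads": [ng],
            }
        )

    def test_mass_per_bead_division(self):
        curve = StandardCurve("arabinose", 1.0, 0.0, 1.0, 4)
        peaks = pd.DataFrame(
            {
                "vial": ["v1"],
                "analyte": ["arabinose"],
                "role": ["recovered"],
                "corrected_area": [30.0],
                "animal": ["a1"],
                "bead_type": ["PFABN"],
            }
        )
        out = mk.mass_per_bead(peaks, {"arabinose": curve}, pd.Series({"v1": 3000.0}))
        assert out["ng_per_1000_beads"].item() == pytest.approx(10.0)

    def test_negative_mass_clipped_and_flagged(self):
        curve = StandardCurve("arabinose", 1.0, 50.0, 1.0, 4)
        peaks = pd.DataFrame(
            {
                "vial": ["v1"],
                "analyte": ["arabinose"],
                "role": ["recovered"],
                "corrected_area": [10.0],
            }
        )
        out = mk.mass_per_bead(peaks, {"arabinose": curve}, pd.Series({"v1": 1000.0}))
        assert out["ng_per_1000_beads"].item() == 0.0
        assert out["clipped"].item()

    def test_percent_remaining_arithmetic(self):
        out = mk.percent_remaining(self._record(2.5), self._record(10.0))
        assert out["percent_remaining"].item() == pytest.approx(25.0)

    def test_recovered_equals_input_is_100(self):
        out = mk.percent_remaining(self._record(7.3), self._record(7.3))
        assert out["percent_remaining"].item() == pytest.approx(100.0)

    def test_zero_input_mass_is_error(self):
        with pytest.raises(MfabError, match="> 0"):
            mk.percent_remaining(self._record(1.0), self._record(0.0))


class TestMoleculeConversions:
    def test_printed_maltodextrin_pair(self):
        # 4.43 ng glucose per 1000 beads at Mn 1300 Da -> 2.05e9
        # molecules/bead -> 9.4% of 2.18e10 surface amines
        mols = mk.molecules_per_bead(4.43)
        assert mols == pytest.approx(2.05e9, rel=0.01)
        assert mk.amine_occupancy(mols) == pytest.approx(9.4, abs=0.1)

    def test_unit_conversion_oracle(self):
        # 1.3 ng/1000 beads at Mn 1300: 1.3e-12 g * N_A / 1300 = 6.022e8
        mols = mk.molecules_per_bead(1.3)
        assert mols == pytest.approx(1.3e-12 * AVOGADRO / 1300.0, rel=1e-12)
        assert mols == pytest.approx(6.022e8, rel=1e-3)

    def test_amine_vs_biotin_capacity(self):
        chem = BeadChemistryParams()
        assert chem.amines_per_bead / chem.biotin_sites_per_bead >= 23.0

    def test_invalid_mn_rejected(self):
        with pytest.raises(MfabError):
            BeadChemistryParams(mn_da=-1.0)


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        u, p = mk.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 arrangements

    def test_identical_groups_p_one(self):
        _, p = mk.mann_whitney([5, 5, 5], [5, 5, 5])
        assert p == 1.0

    def test_matches_scipy_enumeration_on_random_small_instances(self, rng):
        for _ in range(100):
            a = rng.normal(0, 1, 4) + rng.normal(0, 1)
            b = rng.normal(0, 1, 4)
            u, p = mk.mann_whitney(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 12)
        _, p = mk.mann_whitney(a, b)
        ref = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_small_groups_rejected(self):
        with pytest.raises(MfabError):
            mk.mann_whitney([1, 2], [3, 4, 5])


class TestSynergyInteraction:
    def _table(self, rng, interaction=0.0, noise=3.0, n=6):
        rows = []
        base = {"unsupplemented": 80.0, "pea_fiber": 60.0}
        bead_eff = {"GM": 0.0, "GM_PFABN": -10.0}
        for arm, mu_a in base.items():
            for bead, mu_b in bead_eff.items():
                inter = interaction if (arm == "pea_fiber" and bead == "GM_PFABN") else 0.0
                for i in range(n):
                    rows.append(
                        {
                            "arm": arm,
                            "bead_type": bead,
                            "animal": f"{arm}_{bead}_{i}",
                            "percent_remaining": mu_a + mu_b + inter + rng.normal(0, noise),
                        }
                    )
        return pd.DataFrame(rows)

    def test_planted_interaction_recovered(self, rng):
        tab = self._table(rng, interaction=-20.0)
        out = mk.synergy_interaction(tab)
        assert len(out) == 1
        assert out["estimate"].item() == pytest.approx(-20.0, abs=5.0)
        assert out["p_value"].item() < 0.05

    def test_additive_data_null_calibrated(self, rng):
        pvals = []
        for _ in range(100):
            out = mk.synergy_interaction(self._table(rng, interaction=0.0))
            pvals.append(out["p_value"].item())
        assert np.mean(np.array(pvals) < 0.05) <= 0.12
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_bead_type_is_error(self, rng):
        tab = self._table(rng)
        with pytest.raises(MfabError):
            mk.synergy_interaction(tab[tab["bead_type"] == "GM"])

    def test_empty_cell_named(self, rng):
        tab = self._table(rng)
        tab = tab[~((tab["arm"] == "pea_fiber") & (tab["bead_type"] == "GM"))]
        with pytest.raises(MfabError, match="pea_fiber.*GM"):
            mk.synergy_interaction(tab)


class TestRecoveryAtNoise:
    def test_degradation_truth_recovered_within_tolerance(self):
        """Truth f in {0, .25, .5, .9} at 5% multiplicative GC-MS noise:
        mean recovered percent remaining within +-3 points of 100(1-f)
        over 20 replicates per level."""
        from mfabkit.mfab import count_beads, fit_standard_curve, mass_per_bead, percent_remaining

        bead_design = default_bead_design(n_per_arm=1, arms=("pea_fiber",))
        for level, f in enumerate([0.0, 0.25, 0.5, 0.9]):
            truth = {(bt, "pea_fiber"): f for bt in bead_design.bead_types}
            vals = []
            for rep in range(20):
                params = SimulationParams(
                    seed=1000 + 37 * level + rep,
                    gcms_noise_sd=0.05,
                    degradation_truth=truth,
                )
                peaks, flow = mk.simulate_gcms(bead_design, params)
                corrected = correct_areas(peaks)
                n_beads = count_beads(flow)
                curves = {
                    an: fit_standard_curve(corrected, an)
                    for an in corrected["analyte"].unique()
                }
                quant = mass_per_bead(corrected, curves, n_beads)
                pr = percent_remaining(
                    quant[quant["role"] == "recovered"],
                    quant[quant["role"] == "input"],
                )
                vals.append(
                    pr.loc[pr["bead_type"] == "PFABN", "percent_remaining"].mean()
                )
            assert np.mean(vals) == pytest.approx(100.0 * (1 - f), abs=3.0)
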