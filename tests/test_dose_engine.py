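"""MIRD dose contraction, sphere self-dose, effective dose and cohort report."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_doses, exhaustive_effective_dose
from petdosim import (
    Phantom,
    SValueTable,
    absorbed_doses,
    build_report,
    effective_dose,
    sphere_self_dose,
    synthetic_svalue_table,
)
from petdosim.constants import (
    ADULT_PHANTOM_MASSES_G,
    DELTA_NP_MGY_G_PER_MBQ_H,
    ICRP60_REMAINDER_ORGANS,
    ICRP60_WEIGHTS,
)
from petdosim.dose_engine import load_weights
from petdosim import reference


# ---------------------------------------------------------------------------
# absorbed_doses
# ---------------------------------------------------------------------------


class TestAbsorbedDoses:
    def test_single_unit_source(self):
        frame = pd.DataFrame([[1.0], [0.5]], index=["a", "b"], columns=["a"])
        d = absorbed_doses({"a": 1.0}, SValueTable(frame))
        assert d == {"a": 1.0, "b": 0.5}

    def test_zero_taus_give_zero_doses(self, svalues):
        d = absorbed_doses({o: 0.0 for o in svalues.sources}, svalues)
        assert all(v == 0.0 for v in d.values())

    def test_matches_brute_force_double_loop(self, rng):
        organs = [f"o{i}" for i in range(5)]
        frame = pd.DataFrame(rng.uniform(0.1, 1.0, (5, 5)), index=organs, columns=organs)
        frame.values[np.diag_indices(5)] += 2.0  # self-dose row maximum
        s = SValueTable(frame)
        taus = {o: float(rng.uniform(0, 0.5)) for o in organs}
        expected = brute_force_doses(taus, frame)
        got = absorbed_doses(taus, s)
        for o in organs:
            assert got[o] == pytest.approx(expected[o], rel=1e-12)

    def test_linearity_by_superposition(self, svalues, rng):
        t1 = {o: float(rng.uniform(0, 0.2)) for o in svalues.sources}
        t2 = {o: float(rng.uniform(0, 0.2)) for o in svalues.sources}
        combined = absorbed_doses({o: t1[o] + 2 * t2[o] for o in t1}, svalues)
        d1, d2 = absorbed_doses(t1, svalues), absorbed_doses(t2, svalues)
        for o in combined:
            assert combined[o] == pytest.approx(d1[o] + 2 * d2[o], rel=1e-10)

    def test_unmatched_source_routes_to_remainder(self, svalues):
        with pytest.warns(UserWarning, match="remainder"):
            d = absorbed_doses({"pineal_gland": 0.1}, svalues)
        ref = absorbed_doses({"remainder": 0.1}, svalues)
        assert d == ref


# ---------------------------------------------------------------------------
# sphere self-dose
# ---------------------------------------------------------------------------


class TestSphereSelfDose:
    def test_zero_tau_gives_zero(self):
        assert sphere_self_dose(25.0, 0.0) == 0.0

    def test_inverse_mass_scaling(self):
        assert sphere_self_dose(50.0, 0.01) == pytest.approx(sphere_self_dose(25.0, 0.01) / 2)

    def test_hand_computation(self):
        tau, mass = 0.0102, 25.0
        assert sphere_self_dose(mass, tau) == pytest.approx(tau * DELTA_NP_MGY_G_PER_MBQ_H / mass)

    def test_rejects_non_positive_mass(self):
        with pytest.raises(ValueError):
            sphere_self_dose(0.0, 0.01)


# ---------------------------------------------------------------------------
# effective dose
# ---------------------------------------------------------------------------


def _dose_vector(base: float) -> dict[str, float]:
    return {o: base for o in reference.ORGAN_DOSES_35H_MGY_PER_MBQ}


class TestEffectiveDose:
    def test_uniform_dose_returns_itself(self, phantom, weights):
        for method in ("olinda", "icrp60"):
            e = effective_dose(_dose_vector(0.02), weights, phantom, method)
            assert e == pytest.approx(0.02, rel=1e-12)

    def test_weights_sum_to_one(self, weights):
        assert sum(weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_bounded_by_max_organ_dose_and_order_invariant(self, phantom, weights, rng):
        doses = {o: float(rng.uniform(0.001, 0.2)) for o in reference.ORGAN_DOSES_35H_MGY_PER_MBQ}
        for method in ("olinda", "icrp60"):
            e = effective_dose(doses, weights, phantom, method)
            assert e <= max(doses.values())
            shuffled = dict(sorted(doses.items(), key=lambda kv: kv[1]))
            assert effective_dose(shuffled, weights, phantom, method) == pytest.approx(e)

    def test_splitting_rule_matches_exhaustive_case_analysis(self, phantom, weights, rng):
        """Random dose vectors exercise both branches of the ICRP-60 rule."""
        from petdosim.dose_engine import _surrogate_doses

        fired = {True: 0, False: 0}
        for _ in range(50):
            doses = {o: float(rng.uniform(0.001, 0.1)) for o in reference.ORGAN_DOSES_35H_MGY_PER_MBQ}
            if rng.uniform() < 0.5:  # force the splitting branch half the time
                doses["adrenals"] = 0.5
            h = _surrogate_doses(doses, phantom)
            rem = {o: (doses[o], phantom.mass(o)) for o in ICRP60_REMAINDER_ORGANS}
            expected = exhaustive_effective_dose(h, weights, rem)
            got = effective_dose(doses, weights, phantom, "icrp60")
            assert got == pytest.approx(expected, rel=1e-12)
            fired[max(rem.values())[0] > max(h.values())] += 1
        assert fired[True] > 0 and fired[False] > 0

    def test_splitting_does_not_fire_when_remainder_is_low(self, phantom, weights):
        doses = _dose_vector(0.01)
        doses["liver"] = 0.05  # weighted organ dominates
        e_split = effective_dose(doses, weights, phantom, "icrp60")
        # manual mass-weighted remainder, no splitting
        rd = np.array([doses[o] for o in ICRP60_REMAINDER_ORGANS])
        rm = np.array([phantom.mass(o) for o in ICRP60_REMAINDER_ORGANS])
        manual = sum(
            w * (doses["liver"] if t == "liver" else 0.01)
            for t, w in ICRP60_WEIGHTS.items()
            if t not in ("remainder",)
        ) + 0.05 * float((rd * rm).sum() / rm.sum())
        assert e_split == pytest.approx(manual, rel=1e-12)

    def test_missing_weighted_tissue_raises(self, phantom, weights):
        doses = _dose_vector(0.01)
        doses.pop("thymus")  # esophagus surrogate disappears
        with pytest.raises(KeyError):
            effective_dose(doses, weights, phantom)


# ---------------------------------------------------------------------------
# phantom / fixtures I/O
# ---------------------------------------------------------------------------


class TestFixturesIO:
    def test_phantom_roundtrip(self, phantom, tmp_path):
        path = tmp_path / "phantom.csv"
        phantom.to_csv(path)
        again = Phantom.from_csv(path)
        assert again.masses_g == pytest.approx(phantom.masses_g)

    def test_phantom_requires_added_glands(self):
        masses = dict(ADULT_PHANTOM_MASSES_G)
        masses.pop("lacrimal_glands")
        with pytest.raises(ValueError, match="lacrimal"):
            Phantom("broken", masses)

    def test_svalue_roundtrip_and_unit_conversion(self, svalues, tmp_path):
        path = tmp_path / "svalues.csv"
        svalues.to_csv(path)
        again = SValueTable.from_csv(path)
        pd.testing.assert_frame_equal(again.frame, svalues.frame, rtol=1e-9)
        # per-second table converts on load
        per_s = tmp_path / "svalues_s.csv"
        with open(per_s, "w") as fh:
            fh.write("# units: mGy/(MBq.s)\n")
            (svalues.frame / 3600.0).rename_axis("target").to_csv(fh)
        converted = SValueTable.from_csv(per_s)
        np.testing.assert_allclose(converted.frame, svalues.frame, rtol=1e-9)

    def test_self_dose_row_maximum_enforced(self):
        frame = pd.DataFrame([[0.1, 0.5], [0.2, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="row maximum"):
            SValueTable(frame)

    def test_weights_csv_roundtrip(self, weights, tmp_path):
        path = tmp_path / "weights.csv"
        pd.DataFrame(sorted(weights.items()), columns=["tissue", "w_t"]).to_csv(path, index=False)
        assert load_weights(path) == pytest.approx(weights)


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------


class TestBuildReport:
    def _taus(self, svalues, scale=1.0):
        return {o: 0.01 * scale for o in svalues.sources if o != "remainder"} | {
            "remainder": 0.5 * scale,
            "parotid_glands": 0.01 * scale,
        }

    def test_single_subject_has_zero_sd(self, svalues, phantom, weights):
        rep = build_report([self._taus(svalues)], svalues, weights, phantom)
        assert (rep.organ_doses["sd"] == 0).all()
        assert rep.effective_dose_sd == 0.0

    def test_two_identical_subjects(self, svalues, phantom, weights):
        taus = self._taus(svalues)
        one = build_report([taus], svalues, weights, phantom)
        two = build_report([taus, dict(taus)], svalues, weights, phantom)
        assert (two.organ_doses["sd"] == 0).all()
        pd.testing.assert_series_equal(
            one.organ_doses["mean_mgy_per_mbq"], two.organ_doses["mean_mgy_per_mbq"]
        )

    def test_sorted_by_descending_mean_dose(self, svalues, phantom, weights):
        rep = build_report([self._taus(svalues)], svalues, weights, phantom)
        means = rep.organ_doses["mean_mgy_per_mbq"].to_numpy()
        assert (np.diff(means) <= 1e-15).all()

    def test_gland_rows_use_sphere_model(self, svalues, phantom, weights):
        taus = self._taus(svalues)
        rep = build_report([taus], svalues, weights, phantom)
        expected = sphere_self_dose(phantom.mass("parotid_glands"), taus["parotid_glands"])
        assert rep.organ_doses.loc["parotid_glands", "mean_mgy_per_mbq"] == pytest.approx(expected)

    def test_report_regeneration_is_bit_stable(self, cohort6, svalues, phantom, weights, tmp_path):
        from petdosim import subject_residence_times

        outs = []
        for run in range(2):
            taus = [
                subject_residence_times(s.organ_tacs, s.urine_collections, 3.5)
                for s in cohort6
            ]
            rep = build_report(taus, svalues, weights, phantom)
            path = tmp_path / f"report_{run}.csv"
            rep.to_csv(path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]
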