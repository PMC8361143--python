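"""Signal matching, de-isotoping cascade and normalization."""
import numpy as np
import pandas as pd
import pytest

from lipidmrm.chem import Transition, make_species, transition_for
from lipidmrm.quant import (
    MissingStandardError,
    Series,
    build_series,
    deisotope_series,
    deisotope_table,
    match_signals,
    quantify,
    to_molpercent,
)


def _signal(sample, polarity, q1, q3, intensity):
    return {
        "sample": sample,
        "polarity": polarity,
        "q1_mz": q1,
        "q3_mz": q3,
        "intensity": intensity,
    }


@pytest.fixture()
def pc_transition():
    return transition_for(make_species("PC", 34, 1))


class TestMatchSignals:
    def test_exact_and_boundary_signals_assigned(self, pc_transition):
        t = pc_transition
        sig = pd.DataFrame(
            [
                _signal("s1", "+", t.q1_mz, t.q3_mz, 100.0),
                _signal("s1", "+", t.q1_mz + 0.5, t.q3_mz, 50.0),  # inclusive edge
                _signal("s1", "+", t.q1_mz + 0.6, t.q3_mz, 10.0),  # outside
            ]
        )
        res = match_signals(sig, [t])
        assert len(res.intensities) == 1
        assert res.intensities.loc[0, "intensity"] == pytest.approx(75.0)  # mean
        assert len(res.unassigned) == 1
        assert res.unassigned.loc[0, "intensity"] == 10.0

    def test_polarity_must_agree(self, pc_transition):
        t = pc_transition
        sig = pd.DataFrame([_signal("s1", "-", t.q1_mz, t.q3_mz, 5.0)])
        res = match_signals(sig, [t])
        assert res.intensities.empty
        assert len(res.unassigned) == 1

    def test_median_reducer(self, pc_transition):
        t = pc_transition
        sig = pd.DataFrame(
            [_signal("s1", "+", t.q1_mz, t.q3_mz, v) for v in (1.0, 2.0, 100.0)]
        )
        res = match_signals(sig, [t], reducer="median")
        assert res.intensities.loc[0, "intensity"] == 2.0

    def test_ambiguous_signal_goes_to_nearest(self):
        near = Transition("X 30:0", "X", 30, 0, "+", 1, 700.0, 184.0)
        far = Transition("X 30:1", "X", 30, 1, "+", 1, 700.4, 184.0)
        sig = pd.DataFrame([_signal("s1", "+", 700.1, 184.0, 10.0)])
        res = match_signals(sig, [near, far])
        assert list(res.intensities["species_id"]) == ["X 30:0"]
        assert len(res.ambiguous) == 1

    def test_cl_alternative_q3_accepted(self):
        t = transition_for(make_species("CL", 72, 4))
        alt = t.q3_alternatives[0]
        sig = pd.DataFrame([_signal("s1", "-", t.q1_mz, alt, 42.0)])
        res = match_signals(sig, [t])
        assert list(res.intensities["species_id"]) == ["CL 72:4"]


class TestBuildSeries:
    def test_partition_and_order(self):
        tbl = pd.DataFrame(
            {
                "class": ["PC"] * 4 + ["PC", "PE"],
                "c": [34, 34, 34, 34, 36, 34],
                "d": [1, 3, 0, 2, 1, 1],
            }
        )
        series = build_series(tbl)
        by_key = {(s.class_name, s.c): s.ds for s in series}
        assert by_key[("PC", 34)] == (3, 2, 1, 0)
        assert by_key[("PC", 36)] == (1,)
        assert by_key[("PE", 34)] == (1,)

    def test_unordered_series_rejected(self):
        with pytest.raises(ValueError):
            Series("PC", 34, (0, 1, 2))


class TestDeisotopeSeries:
    def test_two_member_toy(self):
        ser = Series("PC", 34, (1, 0))
        corrected, clipped = deisotope_series(
            ser, {"PC 34:1": 100.0, "PC 34:0": 10.0}, {"PC 34:1": 0.05}
        )
        assert corrected == {"PC 34:1": 100.0, "PC 34:0": 5.0}
        assert not any(clipped.values())

    def test_zero_factors_identity(self):
        ser = Series("PC", 34, (2, 1, 0))
        vals = {"PC 34:2": 7.0, "PC 34:1": 5.0, "PC 34:0": 3.0}
        corrected, _ = deisotope_series(ser, vals, dict.fromkeys(vals, 0.0))
        assert corrected == vals

    def test_oversubtraction_clips_and_flags(self):
        ser = Series("PC", 34, (1, 0))
        corrected, clipped = deisotope_series(
            ser, {"PC 34:1": 100.0, "PC 34:0": 1.0}, {"PC 34:1": 0.5}
        )
        assert corrected["PC 34:0"] == 0.0
        assert clipped["PC 34:0"]

    def test_gap_blocks_subtraction(self):
        # 34:1 missing: 34:0 must not be corrected against 34:2
        ser = Series("PC", 34, (2, 0))
        corrected, _ = deisotope_series(
            ser, {"PC 34:2": 100.0, "PC 34:0": 10.0}, {"PC 34:2": 0.1, "PC 34:0": 0.1}
        )
        assert corrected["PC 34:0"] == 10.0

    def test_gap_handling_matches_forward_model(self):
        # forward model where the missing species truly has zero abundance:
        # contamination only crosses adjacent d, so the gap receives none
        true = {"PC 34:2": 50.0, "PC 34:0": 20.0}
        f = {"PC 34:2": 0.1, "PC 34:1": 0.08, "PC 34:0": 0.05}
        measured = {
            "PC 34:2": true["PC 34:2"],
            # contaminant of 34:1 would be f(34:2)*true(34:2) but 34:1 is unmeasured
            "PC 34:0": true["PC 34:0"] + f["PC 34:1"] * 0.0,
        }
        ser = Series("PC", 34, (2, 0))
        corrected, _ = deisotope_series(ser, measured, f)
        assert corrected == pytest.approx(true)

    def test_inverse_of_forward_contamination(self, rng):
        """Forward contamination then the cascade is the identity (noise-free)."""
        for _ in range(300):
            length = int(rng.integers(2, 9))
            ds = tuple(range(length - 1, -1, -1))
            ser = Series("PC", 36, ds)
            ids = ser.species_ids
            true = {sid: float(rng.uniform(0, 100)) for sid in ids}
            f = {sid: float(rng.uniform(0, 0.2)) for sid in ids}
            measured = {}
            for i, sid in enumerate(ids):
                upstream = ids[i - 1] if i > 0 else None
                measured[sid] = true[sid] + (
                    f[upstream] * true[upstream] if upstream else 0.0
                )
            corrected, clipped = deisotope_series(ser, measured, f)
            assert not any(clipped.values())
            for sid in ids:
                assert corrected[sid] == pytest.approx(true[sid], abs=1e-9)

    def test_raising_a_factor_lowers_the_member_it_corrects(self, rng):
        """Raising f(d) weakly lowers J(d-1); corrected stays non-negative.

        Only the immediately corrected member is monotone: a lowered J(d-1)
        subtracts less from J(d-2), so further-downstream members can rise
        — the cascade alternates signs.
        """
        ds = (3, 2, 1, 0)
        ser = Series("PC", 36, ds)
        ids = ser.species_ids
        for _ in range(50):
            vals = {sid: float(rng.uniform(0, 100)) for sid in ids}
            f = {sid: float(rng.uniform(0, 0.3)) for sid in ids}
            base, _ = deisotope_series(ser, vals, f)
            assert all(v >= 0 for v in base.values())
            for i, bump in enumerate(ids[:-1]):
                f2 = dict(f)
                f2[bump] = f[bump] + 0.1
                more, _ = deisotope_series(ser, vals, f2)
                corrected_member = ids[i + 1]
                assert more[corrected_member] <= base[corrected_member] + 1e-12


@pytest.fixture()
def small_corrected():
    rows = []
    for sample in ("s1", "s2"):
        for sid, cls, c, d, inten in [
            ("PC 34:1", "PC", 34, 1, 200.0),
            ("PC 34:0", "PC", 34, 0, 100.0),
            ("PC 24:0", "PC", 24, 0, 50.0),  # internal standard
            ("PE 34:1", "PE", 34, 1, 80.0),
            ("PE 24:0", "PE", 24, 0, 40.0),  # internal standard
        ]:
            rows.append(
                {
                    "sample": sample,
                    "species_id": sid,
                    "class": cls,
                    "c": c,
                    "d": d,
                    "raw": inten,
                    "corrected": inten,
                    "clipped": False,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def standards():
    return pd.DataFrame(
        {
            "class": ["PC", "PE"],
            "species_id": ["PC 24:0", "PE 24:0"],
            "spiked_pmol": [100.0, 100.0],
        }
    )


@pytest.fixture()
def phosphate():
    return pd.DataFrame({"sample": ["s1", "s2"], "phosphate_nmol": [20.0, 40.0]})


class TestQuantify:
    def test_is_ratio_and_exclusion(self, small_corrected, standards, phosphate):
        q = quantify(small_corrected, standards, phosphate)
        assert "PC 24:0" not in set(q["species_id"])
        row = q[(q["sample"] == "s1") & (q["species_id"] == "PC 34:1")].iloc[0]
        assert row["pmol"] == pytest.approx(200.0 / 50.0 * 100.0)
        assert row["pmol_per_phosphate"] == pytest.approx(row["pmol"] / 20.0)

    def test_intensity_equal_to_is_gives_spiked_amount(
        self, small_corrected, standards, phosphate
    ):
        df = small_corrected.copy()
        df.loc[df["species_id"] == "PE 34:1", ["raw", "corrected"]] = 40.0
        q = quantify(df, standards, phosphate)
        row = q[(q["sample"] == "s1") & (q["species_id"] == "PE 34:1")].iloc[0]
        assert row["pmol"] == pytest.approx(100.0)

    def test_zero_intensity_gives_zero_amount(
        self, small_corrected, standards, phosphate
    ):
        df = small_corrected.copy()
        df.loc[df["species_id"] == "PC 34:0", ["raw", "corrected"]] = 0.0
        q = quantify(df, standards, phosphate)
        assert (q[q["species_id"] == "PC 34:0"]["pmol"] == 0).all()

    def test_missing_standard_is_hard_error(self, small_corrected, phosphate):
        only_pc = pd.DataFrame(
            {"class": ["PC"], "species_id": ["PC 24:0"], "spiked_pmol": [100.0]}
        )
        with pytest.raises(MissingStandardError, match="PE"):
            quantify(small_corrected, only_pc, phosphate)

    def test_zero_intensity_standard_is_hard_error(
        self, small_corrected, standards, phosphate
    ):
        df = small_corrected.copy()
        df.loc[df["species_id"] == "PE 24:0", "corrected"] = 0.0
        with pytest.raises(MissingStandardError, match="s1"):
            quantify(df, standards, phosphate)

    def test_scale_invariance(self, small_corrected, standards, phosphate):
        q1 = quantify(small_corrected, standards, phosphate)
        scaled = small_corrected.copy()
        scaled.loc[scaled["sample"] == "s1", ["raw", "corrected"]] *= 7.3
        q2 = quantify(scaled, standards, phosphate)
        assert np.allclose(q1["pmol"], q2["pmol"])


class TestMolPercent:
    def test_sums_to_100_overall_and_per_class(
        self, small_corrected, standards, phosphate
    ):
        q = quantify(small_corrected, standards, phosphate)
        overall = to_molpercent(q, "all")
        assert overall.groupby("sample")["molpct"].sum().to_numpy() == pytest.approx(
            [100.0, 100.0], abs=1e-6
        )
        per_class = to_molpercent(q, "class")
        sums = per_class.groupby(["sample", "class"])["molpct"].sum()
        assert np.allclose(sums, 100.0, atol=1e-6)

    def test_phosphate_cancels(self, small_corrected, standards, phosphate):
        q1 = to_molpercent(quantify(small_corrected, standards, phosphate))
        other = phosphate.copy()
        other["phosphate_nmol"] *= 13.0
        q2 = to_molpercent(quantify(small_corrected, standards, other))
        assert np.allclose(q1["molpct"], q2["molpct"])

    def test_single_species_is_100(self, standards, phosphate):
        df = pd.DataFrame(
            [
                {
                    "sample": "s1",
                    "species_id": sid,
                    "class": "PC",
                    "c": c,
                    "d": d,
                    "raw": v,
                    "corrected": v,
                    "clipped": False,
                }
                for sid, c, d, v in [("PC 34:1", 34, 1, 5.0), ("PC 24:0", 24, 0, 2.0)]
            ]
        )
        q = to_molpercent(
            quantify(df, standards.iloc[:1], phosphate.iloc[:1])
        )
        assert q["molpct"].to_numpy() == pytest.approx([100.0])


def test_deisotope_table_runs_per_sample_series(rng):
    factors = {"PC 34:1": 0.1, "PC 34:0": 0.08}
    rows = []
    for sample in ("a", "b"):
        rows += [
            {"sample": sample, "species_id": "PC 34:1", "class": "PC", "c": 34, "d": 1,
             "intensity": 100.0},
            {"sample": sample, "species_id": "PC 34:0", "class": "PC", "c": 34, "d": 0,
             "intensity": 20.0},
        ]
    out = deisotope_table(pd.DataFrame(rows), factors)
    sat = out[out["species_id"] == "PC 34:0"]
    assert np.allclose(sat["corrected"], 20.0 - 0.1 * 100.0)
    assert (out[out["species_id"] == "PC 34:1"]["corrected"] == 100.0).all()
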