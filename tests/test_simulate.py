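import dataclasses
import json

import numpy as np
import pytest

from conftest import random_truth
from lipidquant.model import GlycerideSpecies as S
from lipidquant.nmr import integrate_window, normalize_to_tms, quantify
from lipidquant.simulate import (
    GroundTruthComposition,
    SimulationParams,
    generate_batch_fixture,
    simulate_fame_table,
    simulate_spectrum,
)

NOISELESS = SimulationParams(noise_sd_rel=0.0)


def canonical_truth(**kwargs):
    return GroundTruthComposition(
        moles={
            S.TAG: 0.70, S.DAG_12: 0.10, S.DAG_13: 0.15,
            S.MAG_1: 0.01, S.MAG_2: 0.01, S.FFA: 0.03,
        },
        **kwargs,
    )


class TestGroundTruth:
    def test_rejects_all_zero_and_negative_moles(self):
        with pytest.raises(ValueError):
            GroundTruthComposition(moles={S.TAG: 0.0})
        with pytest.raises(ValueError):
            GroundTruthComposition(moles={S.TAG: 1.0, S.FFA: -0.1})

    def test_rejects_nonpositive_gain(self):
        with pytest.raises(ValueError):
            canonical_truth(gain=0.0)

    def test_chain_count(self):
        t = canonical_truth()
        assert t.total_chains == pytest.approx(
            3 * 0.70 + 2 * 0.25 + 1 * 0.02 + 1 * 0.03
        )


class TestSimulateSpectrum:
    def test_same_seed_is_bitwise_identical(self):
        t = canonical_truth()
        s1, _ = simulate_spectrum(t, seed=99)
        s2, _ = simulate_spectrum(t, seed=99)
        assert np.array_equal(s1.intensity, s2.intensity)
        s3, _ = simulate_spectrum(t, seed=100)
        assert not np.array_equal(s1.intensity, s3.intensity)

    def test_window_area_bookkeeping_noiseless(self, table):
        # each quantification window's raw integral must equal
        # gain x sum(moles x protons) up to the Lorentzian tail leakage the
        # neighbouring windows deposit into it (~1 % relative for the small
        # 1,3-DAG window sitting next to the 12x larger ester envelope;
        # equal moles keep every window at a comparable scale)
        t = GroundTruthComposition(moles={sp: 1.0 for sp in S}, gain=3.7)
        spec, _ = simulate_spectrum(t, NOISELESS)
        counts = table.proton_counts()
        for key, (lo, hi) in table.quant_windows().items():
            expected = t.gain * sum(
                t.mole(sp) * p for sp, p in counts[key].items()
            )
            got = integrate_window(spec, lo, hi)
            assert got == pytest.approx(expected, rel=0.015), key

    def test_pure_tag_ester_window_counts_four_protons(self, table):
        t = GroundTruthComposition(moles={S.TAG: 1.0})
        spec, _ = simulate_spectrum(t, NOISELESS)
        normed, _ = normalize_to_tms(spec)
        area = integrate_window(normed, 4.11, 4.38)
        # TMS integral 1 corresponds to 12 x tms_moles protons
        protons = area * 12.0 * NOISELESS.tms_moles
        assert protons == pytest.approx(4.0, rel=0.01)

    def test_gain_invariance_of_quantification(self):
        base = canonical_truth(gain=1.0)
        scaled = canonical_truth(gain=10.0)
        r1 = quantify(simulate_spectrum(base, NOISELESS, seed=1)[0])
        r2 = quantify(simulate_spectrum(scaled, NOISELESS, seed=1)[0])
        for k in r1.mole_percent:
            assert r1.mole_percent[k] == pytest.approx(r2.mole_percent[k], abs=1e-9)

    def test_too_coarse_grid_rejected(self):
        params = dataclasses.replace(NOISELESS, n_points=1024)
        with pytest.raises(ValueError, match="grid points"):
            simulate_spectrum(canonical_truth(), params)

    def test_truth_record_reports_composition(self):
        _, rec = simulate_spectrum(canonical_truth(), NOISELESS)
        assert rec["mole_percent"]["TAG"] == pytest.approx(70.0)
        assert rec["mole_percent"]["DAG"] == pytest.approx(25.0)


class TestSimulateFameTable:
    def test_noiseless_round_trip(self):
        from lipidquant.fame import normalize_areas

        prof = normalize_areas(
            simulate_fame_table({"C16:0": 0.3, "C18:1": 0.7}, noise_cv=0.0, seed=0)
        )
        assert prof.get("C16:0") == pytest.approx(30.0)
        assert prof.get("C18:1") == pytest.approx(70.0)

    def test_mean_recovery_over_many_tables(self):
        # lognormal noise has unit mean, so averaging 200 tables recovers
        # the true fractions within 1 % relative
        from lipidquant.fame import normalize_areas

        truth = {"C16:0": 0.25, "C18:0": 0.10, "C18:1": 0.40, "C18:2": 0.25}
        rng = np.random.default_rng(77)
        acc = {k: [] for k in truth}
        for _ in range(200):
            prof = normalize_areas(
                simulate_fame_table(truth, noise_cv=0.05,
                                    seed=int(rng.integers(2**31)))
            )
            for k in truth:
                acc[k].append(prof.get(k))
        for k, frac in truth.items():
            assert np.mean(acc[k]) == pytest.approx(100 * frac, rel=0.01)

    def test_detection_floor_marks_nd(self):
        recs = simulate_fame_table(
            {"C16:0": 0.99, "C22:0": 0.01}, total_area=100.0, noise_cv=0.0,
            seed=0, detection_floor=5.0,
        )
        flags = {r.fa.label: r.detected for r in recs}
        assert flags == {"C16:0": True, "C22:0": False}

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            simulate_fame_table({"C16:0": 0.5, "C18:1": 0.4})
        with pytest.raises(ValueError):
            simulate_fame_table({"C16:0": 1.5, "C18:1": -0.5})


class TestBatchFixture:
    def test_same_seed_gives_identical_manifest(self, tmp_path):
        m1 = generate_batch_fixture(tmp_path / "a", seed=5)
        m2 = generate_batch_fixture(tmp_path / "b", seed=5)
        assert json.dumps(m1, sort_keys=True) == json.dumps(m2, sort_keys=True)
        f1 = (tmp_path / "a" / "spectra" / "S1.txt").read_bytes()
        f2 = (tmp_path / "b" / "spectra" / "S1.txt").read_bytes()
        assert f1 == f2

    def test_layout_and_truth_content(self, tmp_path):
        man = generate_batch_fixture(tmp_path / "fix", seed=3)
        assert set(man["strains"]) == {"S1", "S2", "S3", "S4", "S5"}
        for strain, info in man["strains"].items():
            assert (tmp_path / "fix" / "spectra" / f"{strain}.txt").exists()
            assert (tmp_path / "fix" / "fame" / f"{strain}.csv").exists()
            assert info["dag_total_yield_mg_per_L"] == pytest.approx(
                info["dag12_yield_mg_per_L"] + info["dag13_yield_mg_per_L"]
            )
        assert (tmp_path / "fix" / "fermentation.csv").exists()
        assert json.loads((tmp_path / "fix" / "truth.json").read_text()) == man


class TestParameterRecovery:
    def test_noiseless_recovery_within_half_point(self):
        spec, rec = simulate_spectrum(canonical_truth(), NOISELESS, seed=2)
        rep = quantify(spec)
        errs = [
            abs(rep.mole_percent[k] - rec["mole_percent"][k])
            for k in ("MAG", "1,2-DAG", "1,3-DAG", "TAG", "FA")
        ]
        assert np.mean(errs) <= 0.5

    def test_random_compositions_recover_at_default_noise(self):
        rng = np.random.default_rng(2024)
        maes = []
        for _ in range(20):
            t = random_truth(rng)
            spec, rec = simulate_spectrum(t, seed=int(rng.integers(2**31)))
            rep = quantify(spec)
            maes.append(
                np.mean([
                    abs(rep.mole_percent[k] - rec["mole_percent"][k])
                    for k in ("MAG", "1,2-DAG", "1,3-DAG", "TAG", "FA")
                ])
            )
        assert np.mean(maes) <= 1.0
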