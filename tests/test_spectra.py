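"""MGF/mzML round trips, discovery pre-filters, candidate-table ingest."""

import numpy as np
import pytest

from xlinkprm import (
    CrosslinkPair,
    Ms2Spectrum,
    PrmRun,
    PrmScan,
    CandidateRecord,
    filter_candidates,
    filter_precursor_mass,
    group_unique_spectra,
    load_candidates,
    read_mgf,
    read_prm_run,
    write_mgf,
    write_mzml,
)
from xlinkprm.spectra import MgfFormatError, read_prm_table, write_prm_table


def _random_spectra(n, rng):
    out = []
    for i in range(n):
        k = rng.integers(3, 30)
        out.append(
            Ms2Spectrum(
                precursor_mz=float(rng.uniform(400, 1600)),
                precursor_charge=int(rng.integers(4, 9)),
                rt=float(rng.uniform(5, 180)),
                mz=rng.uniform(100, 1800, size=k),
                intensity=rng.uniform(0, 1e6, size=k),
                title=f"s{i}",
            )
        )
    return out


class TestMgf:
    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.mgf"
        p.write_text("")
        assert read_mgf(p) == []

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(7)
        spectra = _random_spectra(100, rng)
        p = tmp_path / "run.mgf"
        write_mgf(spectra, p)
        back = read_mgf(p)
        assert len(back) == 100
        for a, b in zip(spectra, back):
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-6)
            assert b.precursor_charge == a.precursor_charge
            assert b.rt == pytest.approx(a.rt, abs=1e-6)
            np.testing.assert_allclose(b.mz, a.mz, atol=1e-6)
            np.testing.assert_allclose(b.intensity, a.intensity, atol=1e-4)

    def test_unbalanced_blocks_reported_with_line_number(self, tmp_path):
        p = tmp_path / "bad.mgf"
        p.write_text("BEGIN IONS\nPEPMASS=500\n100 200\n")
        with pytest.raises(MgfFormatError, match="line 1"):
            read_mgf(p)
        p.write_text("END IONS\n")
        with pytest.raises(MgfFormatError, match="line 1"):
            read_mgf(p)


class TestPrecursorMassFilter:
    def _spec(self, mz, z):
        return Ms2Spectrum(
            precursor_mz=mz, precursor_charge=z, rt=10.0, mz=[200.0], intensity=[1.0]
        )

    def test_light_kept_heavy_removed(self):
        light = self._spec(536.043, 4)  # neutral ~2140 Da
        heavy = self._spec(1601.0, 6)  # neutral ~9600 Da
        assert filter_precursor_mass([light, heavy]) == [light]

    def test_empty_input(self):
        assert filter_precursor_mass([]) == []

    def test_idempotent(self):
        spectra = [self._spec(536.043, 4), self._spec(1601.0, 6), self._spec(900.0, 8)]
        once = filter_precursor_mass(spectra)
        assert filter_precursor_mass(once) == once


class TestGroupUnique:
    def _spec(self, mz, z=4, rt=10.0):
        return Ms2Spectrum(
            precursor_mz=mz, precursor_charge=z, rt=rt, mz=[200.0], intensity=[1.0]
        )

    def test_disjoint_sets_all_retained(self):
        by_group = {"S": [self._spec(500.0)], "E": [self._spec(800.0)]}
        out = group_unique_spectra(by_group)
        assert len(out["S"]) == 1 and len(out["E"]) == 1

    def test_shared_spectrum_removed_from_both(self):
        by_group = {"S": [self._spec(500.0)], "E": [self._spec(500.0)]}
        out = group_unique_spectra(by_group)
        assert out["S"] == [] and out["E"] == []

    def test_charge_mismatch_is_not_a_match(self):
        by_group = {"S": [self._spec(500.0, z=4)], "E": [self._spec(500.0, z=5)]}
        out = group_unique_spectra(by_group)
        assert len(out["S"]) == 1 and len(out["E"]) == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        groups = ["S", "F", "E", "A"]
        by_group = {}
        # draw precursors from a small grid so cross-group collisions occur
        for g in groups:
            specs = []
            for _ in range(25):
                mz = float(rng.choice([500.0, 600.0, 700.0]) + rng.uniform(0, 0.03))
                specs.append(self._spec(mz, z=int(rng.integers(4, 6)),
                                        rt=float(rng.choice([10.0, 30.0]))))
            by_group[g] = specs
        out = group_unique_spectra(by_group, mz_tol=0.01, rt_tol=2.0)
        # oracle: all-pairs scan, written independently of the implementation
        for g, specs in by_group.items():
            expected = []
            for s in specs:
                shared = False
                for g2, specs2 in by_group.items():
                    if g2 == g:
                        continue
                    for s2 in specs2:
                        if (
                            s.precursor_charge == s2.precursor_charge
                            and abs(s.precursor_mz - s2.precursor_mz) <= 0.01
                            and abs(s.rt - s2.rt) <= 2.0
                        ):
                            shared = True
                if not shared:
                    expected.append(s)
            assert out[g] == expected

    def test_never_increases_counts_and_idempotent(self):
        rng = np.random.default_rng(3)
        by_group = {g: _random_spectra(10, rng) for g in ("S", "F", "E")}
        out = group_unique_spectra(by_group)
        for g in by_group:
            assert len(out[g]) <= len(by_group[g])
        again = group_unique_spectra(out)
        assert {g: len(v) for g, v in again.items()} == {
            g: len(v) for g, v in out.items()
        }

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_unique_spectra({"S": []})


class TestCandidates:
    def _rec(self, n_frag, seq_a="AGYLEKR", seq_b="RIYQFTAASPK"):
        return CandidateRecord(
            pair=CrosslinkPair.from_sequences(seq_a, seq_b, 24),
            z=4,
            n_fragments_matched=n_frag,
            rt=40.0,
        )

    def test_ratio_above_threshold_kept(self):
        rec = self._rec(34)  # 34/18 = 1.889
        assert rec.score_ratio == pytest.approx(34 / 18)
        assert filter_candidates([rec]) == [rec]

    def test_ratio_exactly_threshold_removed(self):
        rec = self._rec(27)  # 27/18 = 1.5 exactly: strict inequality
        assert filter_candidates([rec]) == []

    def test_partition_and_oracle(self):
        rng = np.random.default_rng(5)
        records = [self._rec(int(n)) for n in rng.integers(10, 60, size=10)]
        kept = filter_candidates(records)
        assert kept == [r for r in records if r.n_fragments_matched / 18 > 1.5]
        rejected = [r for r in records if r.score_ratio <= 1.5]
        assert len(kept) + len(rejected) == len(records)  # partition, nothing lost

    def test_load_candidates_round_trip(self, tmp_path):
        p = tmp_path / "cands.tsv"
        p.write_text(
            "peptide_a\tpeptide_b\tcm\tz\tn_fragments_matched\trt\n"
            "AGYLEKR\tRIYQFTAASPK\t24\t4\t34\t40.2\n"
        )
        (rec,) = load_candidates(p)
        assert rec.total_length == 18
        assert rec.z == 4

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "cands.tsv"
        p.write_text("peptide_a\tpeptide_b\tz\tn_fragments_matched\trt\n")
        with pytest.raises(ValueError, match="cm"):
            load_candidates(p)


class TestPrmRunIo:
    def _run(self, rng, n_targets=2, n_scans=5):
        run = PrmRun(sample_id="S1", group="S")
        for t in range(n_targets):
            target = 500.0 + 100.0 * t
            scans = []
            for s in range(n_scans):
                k = rng.integers(2, 12)
                scans.append(
                    PrmScan(
                        rt=10.0 + 0.05 * s,
                        mz=rng.uniform(100, 1500, size=k),
                        intensity=rng.uniform(1, 1e5, size=k),
                    )
                )
            run.scans_by_target[target] = scans
        return run

    def test_mzml_round_trip(self, tmp_path):
        rng = np.random.default_rng(13)
        run = self._run(rng)
        p = tmp_path / "run.mzML"
        write_mzml(run, p)
        back = read_prm_run(p, sample_id="S1", group="S")
        assert sorted(back.scans_by_target) == sorted(run.scans_by_target)
        for target, scans in run.scans_by_target.items():
            bscans = back.scans_by_target[round(target, 4)]
            assert len(bscans) == len(scans)
            for a, b in zip(scans, bscans):
                assert b.rt == pytest.approx(a.rt, abs=1e-6)
                np.testing.assert_allclose(b.mz, a.mz, rtol=1e-12)
                np.testing.assert_allclose(b.intensity, a.intensity, rtol=1e-12)

    def test_table_round_trip(self, tmp_path):
        rng = np.random.default_rng(17)
        run = self._run(rng)
        p = tmp_path / "run.tsv"
        write_prm_table(run, p)
        back = read_prm_table(p, sample_id="S1", group="S")
        for target, scans in run.scans_by_target.items():
            bscans = back.scans_by_target[round(target, 4)]
            assert len(bscans) == len(scans)
            for a, b in zip(scans, bscans):
                np.testing.assert_allclose(b.mz, a.mz, atol=1e-5)

    def test_interleaved_targets_keep_scan_counts(self, tmp_path):
        rng = np.random.default_rng(19)
        run = self._run(rng, n_targets=2, n_scans=7)
        p = tmp_path / "run.mzML"
        write_mzml(run, p)
        back = read_prm_run(p)
        assert [len(v) for v in back.scans_by_target.values()] == [7, 7]

    def test_file_without_ms2_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("target_mz\tscan\trt\tmz\tintensity\n")
        with pytest.raises(ValueError):
            read_prm_run(p)
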