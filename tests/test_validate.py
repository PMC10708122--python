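"""XIC extraction and the validation filter cascade."""

import numpy as np
import pytest

from xlinkprm import (
    ChromatogramTrace,
    CrosslinkPair,
    FilterConfig,
    FragmentIon,
    MergedResult,
    PrecursorIon,
    PrmRun,
    PrmScan,
    SampleDesign,
    ValidationResult,
    accept_cohort,
    apply_filter_cascade,
    average_donors,
    extract_xic,
    generate_transitions,
    merge_charge_states,
)

PAIR = CrosslinkPair.from_sequences("AGYLEKR", "RIYQFTAASPK", 24)
PRECURSOR = PrecursorIon(pair=PAIR, charge=4, mz_calc=536.043, rt_center=40.2)
SHORT_PAIR = CrosslinkPair.from_sequences("AGYLEK", "RIYQFTAASPK", 24)


def _trace(index=6, apex=10_000.0, ppm=0.5, mz=800.0, n=30):
    """A triangular trace peaking mid-window with a controlled apex ppm error."""
    frag = FragmentIon(source="a", series="y", index=index, charge=1,
                       carries_shift=False, mz=mz)
    rt = 37.2 + 0.2 * np.arange(n)
    inten = apex * (1.0 - np.abs(np.arange(n) - n // 2) / (n // 2))
    measured = np.full(n, mz * (1.0 + ppm * 1e-6))
    return ChromatogramTrace(
        transition=frag, sample_id="S1", group="S",
        rt=rt, intensity=inten, measured_mz=measured,
    )


class TestExtractXic:
    def _run_with_peak(self, frag_mz, apex=50_000.0, rt_true=40.2, ppm_err=0.0,
                       extra_mz=None):
        run = PrmRun(sample_id="S1", group="S")
        rts = 37.2 + (2.0 / 60.0) * np.arange(181)
        scans = []
        for rt in rts:
            inten = apex * np.exp(-0.5 * ((rt - rt_true) / 0.1) ** 2)
            mzs, ints = [], []
            if inten > 1.0:
                mzs.append(frag_mz * (1.0 + ppm_err * 1e-6))
                ints.append(inten)
            if extra_mz is not None and inten > 1.0:
                mzs.append(extra_mz)
                ints.append(inten * 2)
            scans.append(PrmScan(rt=rt, mz=np.array(mzs), intensity=np.array(ints)))
        run.scans_by_target[round(536.043, 4)] = scans
        return run

    def test_no_signal_gives_all_zero_traces(self):
        run = PrmRun(sample_id="S1", group="S")
        rts = 37.2 + 0.1 * np.arange(61)
        run.scans_by_target[536.043] = [
            PrmScan(rt=rt, mz=np.array([]), intensity=np.array([])) for rt in rts
        ]
        target = generate_transitions(PAIR, 4, 40.2)
        traces = extract_xic(run, target)
        assert len(traces) == len(target.transitions)
        assert all(t.apex_intensity == 0.0 for t in traces)

    def test_gaussian_peak_apex_recovered(self):
        target = generate_transitions(PAIR, 4, 40.2)
        frag = target.transitions[0]
        run = self._run_with_peak(frag.mz, rt_true=40.45)
        traces = extract_xic(run, target)
        trace = next(t for t in traces if t.transition is frag)
        assert trace.apex_rt == pytest.approx(40.45, abs=2.0 / 60.0 + 1e-9)
        other = [t for t in traces if t.transition is not frag]
        assert all(t.apex_intensity == 0.0 for t in other)

    def test_interference_stays_on_its_own_mz(self):
        """A co-isolating peptide's peaks must not leak into the target's XIC."""
        target = generate_transitions(PAIR, 4, 40.2)
        frag = target.transitions[0]
        # interference 50 ppm away: inside the isolation window, outside the XIC
        run = self._run_with_peak(frag.mz, extra_mz=frag.mz * (1 + 50e-6))
        traces = extract_xic(run, target)
        trace = next(t for t in traces if t.transition is frag)
        assert trace.apex_intensity == pytest.approx(50_000.0, rel=1e-3)
        assert trace.apex_ppm_deviation < 0.01

    def test_measured_mz_is_weighted_mean_and_ppm_detected(self):
        target = generate_transitions(PAIR, 4, 40.2)
        frag = target.transitions[0]
        run = self._run_with_peak(frag.mz, ppm_err=2.0)
        traces = extract_xic(run, target)
        trace = next(t for t in traces if t.transition is frag)
        assert trace.apex_ppm_deviation == pytest.approx(2.0, abs=1e-6)


class TestFilterCascade:
    def test_counting_example_below_acceptance(self):
        traces = (
            [_trace(apex=10_000, ppm=0.5) for _ in range(4)]
            + [_trace(apex=2_000, ppm=0.5) for _ in range(3)]  # below noise floor
            + [_trace(apex=10_000, ppm=2.0)]  # fails mass accuracy
        )
        result = apply_filter_cascade(PRECURSOR, traces)
        assert result.n_surviving == 4

    def test_all_clean_traces_survive(self):
        traces = [_trace(apex=10_000, ppm=0.5, index=5 + i) for i in range(8)]
        result = apply_filter_cascade(PRECURSOR, traces)
        assert result.n_surviving == 8

    def test_low_index_transitions_dropped(self):
        traces = [_trace(index=i) for i in (3, 4, 5)]
        result = apply_filter_cascade(PRECURSOR, traces)
        assert [t.transition.index for t in result.surviving_transitions] == [5]

    def test_short_peptide_excludes_whole_precursor(self):
        precursor = PrecursorIon(pair=SHORT_PAIR, charge=4, mz_calc=500.0,
                                 rt_center=40.0)
        result = apply_filter_cascade(precursor, [_trace() for _ in range(8)])
        assert result.excluded and result.n_surviving == 0

    def test_apex_exactly_at_noise_floor_rejected(self):
        result = apply_filter_cascade(PRECURSOR, [_trace(apex=3000.0)])
        assert result.n_surviving == 0

    def test_matches_brute_force_oracle_on_random_traces(self):
        rng = np.random.default_rng(29)
        cfg = FilterConfig()
        for _ in range(50):
            traces = [
                _trace(
                    index=int(rng.integers(3, 10)),
                    apex=float(rng.uniform(0, 10_000)),
                    ppm=float(rng.uniform(0, 2.5)),
                    mz=float(rng.uniform(200, 1500)),
                )
                for _ in range(int(rng.integers(1, 15)))
            ]
            result = apply_filter_cascade(PRECURSOR, traces, cfg)
            # independent re-statement of the rules
            expected = [
                t
                for t in traces
                if t.transition.index >= 5
                and max(t.intensity) > 3000.0
                and abs(t.measured_mz[np.argmax(t.intensity)] - t.transition.mz)
                / t.transition.mz
                * 1e6
                <= 1.0
            ]
            assert result.surviving_transitions == expected

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(31)
        traces = [
            _trace(
                index=int(rng.integers(3, 10)),
                apex=float(rng.uniform(0, 10_000)),
                ppm=float(rng.uniform(0, 2.5)),
            )
            for _ in range(30)
        ]
        strict = apply_filter_cascade(PRECURSOR, traces, FilterConfig())
        relaxed = apply_filter_cascade(
            PRECURSOR,
            traces,
            FilterConfig(noise_floor=1000.0, accept_ppm=3.0, min_fragment_index=3),
        )
        assert relaxed.n_surviving >= strict.n_surviving
        assert set(id(t) for t in strict.surviving_transitions) <= set(
            id(t) for t in relaxed.surviving_transitions
        )


def _result(sample_id, group, n_surviving, area=100.0, precursor=PRECURSOR):
    return ValidationResult(
        precursor=precursor,
        sample_id=sample_id,
        group=group,
        surviving_transitions=[_trace(apex=area) for _ in range(n_surviving)],
    )


class TestAcceptCohort:
    def test_max_four_everywhere_rejected(self):
        results = [_result(f"S{i}", "S", 4) for i in range(3)]
        accept_cohort(results)
        assert not any(r.accepted for r in results)

    def test_one_sample_reaching_five_retains_all(self):
        results = [_result("S1", "S", 5), _result("E1", "E", 0)]
        accept_cohort(results)
        assert all(r.accepted for r in results)

    def test_exactly_five_is_accepted(self):
        (r,) = accept_cohort([_result("S1", "S", 5)])
        assert r.accepted

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            accept_cohort([])


class TestMergeAndAverage:
    def _design(self):
        return SampleDesign(
            samples=tuple(
                (f"{g}{d}", g, d) for g in ("S", "E") for d in (1, 2, 3)
            )
        )

    def test_single_charge_identity(self):
        r = _result("S1", "S", 6)
        r.accepted = True
        (m,) = merge_charge_states([r])
        assert m.total_area == pytest.approx(r.total_area)

    def test_two_charges_areas_add(self):
        p5 = PrecursorIon(pair=PAIR, charge=5, mz_calc=429.0, rt_center=40.2)
        r4 = _result("S1", "S", 6)
        r5 = _result("S1", "S", 6, precursor=p5)
        r4.accepted = r5.accepted = True
        (m,) = merge_charge_states([r4, r5])
        assert m.total_area == pytest.approx(r4.total_area + r5.total_area)
        assert m.n_precursors == 2

    def test_unaccepted_results_not_merged(self):
        assert merge_charge_states([_result("S1", "S", 6)]) == []

    def test_average_donors_mean_and_zero_fill(self):
        design = self._design()
        merged = [
            MergedResult(pair=PAIR, sample_id=f"S{d}", group="S",
                         total_area=a, n_precursors=1)
            for d, a in zip((1, 2, 3), (3.0, 6.0, 9.0))
        ]
        means = average_donors(merged, design)
        assert means.loc[PAIR.label, "S"] == pytest.approx(6.0)
        assert means.loc[PAIR.label, "E"] == 0.0  # missing donors count as zero

    def test_all_zero_group(self):
        design = self._design()
        merged = [
            MergedResult(pair=PAIR, sample_id="E1", group="E",
                         total_area=0.0, n_precursors=1)
        ]
        assert average_donors(merged, design).loc[PAIR.label, "E"] == 0.0

    def test_group_without_samples_rejected(self):
        design = SampleDesign(samples=(("S1", "S", 1), ("S2", "S", 2)))
        merged = [MergedResult(pair=PAIR, sample_id="S1", group="S",
                               total_area=1.0, n_precursors=1)]
        means = average_donors(merged, design)  # single complete group is fine
        assert means.loc[PAIR.label, "S"] == pytest.approx(0.5)

    def test_merge_then_average_commutes_when_all_donors_present(self):
        design = self._design()
        p5 = PrecursorIon(pair=PAIR, charge=5, mz_calc=429.0, rt_center=40.2)
        results = []
        for d in (1, 2, 3):
            for g in ("S", "E"):
                for prec in (PRECURSOR, p5):
                    r = _result(f"{g}{d}", g, 6, area=float(100 * d), precursor=prec)
                    r.accepted = True
                    results.append(r)
        merged_first = average_donors(merge_charge_states(results), design)
        # average per (charge, group) then sum over charges
        by_charge = {}
        for prec in (PRECURSOR, p5):
            sub = [r for r in results if r.precursor is prec]
            fake_merged = [
                MergedResult(pair=r.precursor.pair, sample_id=r.sample_id,
                             group=r.group, total_area=r.total_area, n_precursors=1)
                for r in sub
            ]
            by_charge[prec.charge] = average_donors(fake_merged, design)
        summed = sum(by_charge.values())
        assert np.allclose(merged_first.to_numpy(), summed.to_numpy())
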