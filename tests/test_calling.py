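"""The positivity rule, QC interpretation and the species call."""

import dataclasses

import numpy as np
import pytest

from psocidchip.calling import (
    AMPLIFICATION_OR_HYB_FAIL,
    ANCHOR_COUPLING_FAIL,
    CONTAMINATION_OR_NONSPECIFIC,
    CallingParams,
    ChipQC,
    ProbeCall,
    call_species,
    control_means,
    corrected_signal,
    evaluate_qc,
    probe_call,
    report_to_tsv,
    run_pipeline,
    site_positive,
)
from psocidchip.chip_io import ChipScan, SpotSignal, write_gal, write_gpr
from psocidchip.simulator import SignalSimConfig, simulate_scan


def spot(f635, b635, flag=0, probe="Lpa", lattice=1, row=2, col=3):
    return SpotSignal(lattice=lattice, row=row, col=col, probe_code=probe,
                      f635_mean=f635, b635=b635, flag=flag)


class TestCorrectedSignal:
    @pytest.mark.parametrize("f,b,expected", [
        (1000, 1000, 0), (1800, 200, 1600), (50, 120, -70)])
    def test_background_subtraction_unclamped(self, f, b, expected):
        assert corrected_signal(spot(f, b)) == expected


class TestControlMeans:
    def _scan(self, blanks, negatives):
        spots = []
        for i, (v, fl) in enumerate(blanks):
            spots.append(spot(v, 0, flag=fl, probe="B", col=3 + i))
        for i, (v, fl) in enumerate(negatives):
            spots.append(spot(v, 0, flag=fl, probe="N", row=3, col=3 + i))
        return ChipScan(chip_id="t", spots=spots)

    def test_plain_means(self):
        scan = self._scan([(10, 0)] * 4, [(0, 0)] * 4)
        assert control_means(scan, 1) == (10, 0)

    def test_flagged_spot_excluded(self):
        scan = self._scan([(100, -100)] + [(30, 0)] * 3, [(0, 0)] * 4)
        assert control_means(scan, 1) == (30, 0)

    def test_no_valid_control_spots_is_an_error(self):
        scan = self._scan([(10, -50)] * 4, [(0, 0)] * 4)
        with pytest.raises(ValueError, match="control"):
            control_means(scan, 1)


class TestSitePositive:
    def test_boundary_exactly_500_is_negative(self):
        assert not site_positive(500, 0, 0)
        assert site_positive(501, 0, 0)

    def test_ten_times_negative_vetoes(self):
        # d = 600 fails because 600 <= 10 * 70
        assert not site_positive(600, 0, 70)
        assert site_positive(701, 0, 70)

    def test_blank_subtraction_enters_d(self):
        assert not site_positive(600, 100, 0)
        assert site_positive(601, 100, 0)

    def test_oracle_equivalence_random_spots(self):
        # direct transcription of the published sentence, evaluated
        # independently of the implementation
        def oracle(signal, blank_mean, negative_mean):
            d = signal - blank_mean
            return (d > 10 * negative_mean) and (d > 500)

        rng = np.random.default_rng(123)
        signals = rng.uniform(-200, 3000, size=10_000)
        blanks = rng.uniform(0, 300, size=10_000)
        negatives = rng.uniform(0, 120, size=10_000)
        for s, b, n in zip(signals, blanks, negatives):
            assert site_positive(s, b, n) == oracle(s, b, n)


class TestProbeCall:
    def test_mean_mode_positive(self):
        spots = [spot(v, 0, col=c)
                 for c, v in zip(range(3, 7), (2000, 2100, 1900, 2000))]
        call = probe_call("Lpa", spots, 0, 0)
        assert call.positive and call.mean_corrected == 2000

    def test_mean_mode_single_bright_replicate_not_enough(self):
        spots = [spot(v, 0, col=c)
                 for c, v in zip(range(3, 7), (800, 100, 100, 100))]
        call = probe_call("Lpa", spots, 0, 0)
        assert not call.positive and call.mean_corrected == 275

    def test_all_sites_mode_requires_every_replicate(self):
        spots = [spot(v, 0, col=c)
                 for c, v in zip(range(3, 7), (800, 100, 100, 100))]
        params = CallingParams(aggregate_mode="all_sites")
        assert not probe_call("Lpa", spots, 0, 0, params).positive
        bright = [spot(900, 0, col=c) for c in range(3, 7)]
        assert probe_call("Lpa", bright, 0, 0, params).positive

    def test_too_few_valid_replicates_indeterminate(self):
        spots = [spot(2000, 0, col=3), spot(2000, 0, flag=-50, col=4),
                 spot(2000, 0, flag=-50, col=5)]
        call = probe_call("Lpa", spots, 0, 0)
        assert call.indeterminate and not call.positive and call.n_valid == 1

    def test_monotone_in_signal(self):
        base = (600, 550, 620, 580)
        for bump in (0, 100, 500, 5000):
            spots = [spot(v + bump, 0, col=c)
                     for c, v in zip(range(3, 7), base)]
            low = probe_call("Lpa", spots, 0, 0).positive
            spots_hi = [spot(v + bump + 1, 0, col=c)
                        for c, v in zip(range(3, 7), base)]
            high = probe_call("Lpa", spots_hi, 0, 0).positive
            assert high >= low

    def test_constant_offset_cancels(self):
        # adding c to both foreground and background changes nothing
        spots = [spot(v, 100, col=c)
                 for c, v in zip(range(3, 7), (900, 950, 1000, 1050))]
        shifted = [dataclasses.replace(s, f635_mean=s.f635_mean + 777,
                                       b635=s.b635 + 777) for s in spots]
        assert (probe_call("Lpa", spots, 10, 5).positive
                == probe_call("Lpa", shifted, 10, 5).positive)


class TestQcAndSpeciesCall:
    def _call(self, positive=True, code="P"):
        return ProbeCall(code, (1000.0,) * 4, 1000.0, positive, 4)

    def test_clean_chip(self):
        anchors = [spot(30000, 100, probe="A", col=c) for c in range(1, 5)]
        qc = evaluate_qc(anchors, self._call(True), self._call(False, "N"))
        assert qc.ok and qc.codes == ()

    def test_dark_anchors(self):
        anchors = [spot(100, 90, probe="A", col=c) for c in range(1, 5)]
        qc = evaluate_qc(anchors, self._call(True), self._call(False, "N"))
        assert not qc.anchors_ok and ANCHOR_COUPLING_FAIL in qc.codes

    def test_hot_negative_control(self):
        anchors = [spot(30000, 100, probe="A", col=c) for c in range(1, 5)]
        qc = evaluate_qc(anchors, self._call(True), self._call(True, "N"))
        assert not qc.negative_ok
        assert CONTAMINATION_OR_NONSPECIFIC in qc.codes

    def test_dark_positive_control(self):
        anchors = [spot(30000, 100, probe="A", col=c) for c in range(1, 5)]
        qc = evaluate_qc(anchors, self._call(False), self._call(False, "N"))
        assert not qc.positive_ok
        assert AMPLIFICATION_OR_HYB_FAIL in qc.codes

    def _species_calls(self, positives):
        return {code: ProbeCall(code, (1.0,) * 4,
                                5000.0 if code in positives else 10.0,
                                code in positives, 4)
                for code in ("Lpa", "Lbo", "Lbr")}

    def test_unique_positive_identifies(self):
        qc = ChipQC(True, True, True)
        targets = {"Lpa": "Liposcelis paeta", "Lbo": "Liposcelis bostrychophila",
                   "Lbr": "Liposcelis brunnea"}
        res = call_species("s", self._species_calls({"Lpa"}), targets, qc)
        assert res.status == "identified"
        assert res.species == "Liposcelis paeta"

    def test_two_positives_ambiguous(self):
        qc = ChipQC(True, True, True)
        res = call_species("s", self._species_calls({"Lpa", "Lbo"}), {}, qc)
        assert res.status == "ambiguous"

    def test_no_positive_is_no_call(self):
        qc = ChipQC(True, True, True)
        res = call_species("s", self._species_calls(set()), {}, qc)
        assert res.status == "no_call"

    def test_qc_failure_voids_call(self):
        qc = ChipQC(False, True, True, codes=(ANCHOR_COUPLING_FAIL,))
        res = call_species("s", self._species_calls({"Lpa"}), {}, qc)
        assert res.status == "invalid"

    def test_indeterminate_deciding_probe_demotes_to_ambiguous(self):
        qc = ChipQC(True, True, True)
        calls = self._species_calls({"Lpa"})
        calls["Lbo"] = ProbeCall("Lbo", (2000.0,), 2000.0, False, 1,
                                 indeterminate=True)
        res = call_species("s", calls, {"Lpa": "Liposcelis paeta"}, qc)
        assert res.status == "ambiguous"


class TestPipeline:
    def _run(self, panel, layout, tmp_path, truth, failure_modes=None,
             seed=0, **config_kw):
        config = SignalSimConfig(true_species_per_lattice=truth,
                                 failure_modes=failure_modes or {},
                                 seed=seed, **config_kw)
        scan, truths = simulate_scan(layout, panel, config)
        gpr = tmp_path / "scan.gpr"
        gal = tmp_path / "layout.gal"
        write_gpr(scan, gpr)
        write_gal(layout, gal)
        return run_pipeline(gpr, panel, gal_path=gal), truths

    def test_low_noise_scan_identifies_truth(self, panel, layout, tmp_path):
        results, _ = self._run(panel, layout, tmp_path,
                               {1: "Liposcelis entomophila"})
        assert results[0].status == "identified"
        assert results[0].species == "Liposcelis entomophila"
        assert results[0].positive_probes == ["Len"]

    def test_anchor_failure_mode_flagged(self, panel, layout, tmp_path):
        results, _ = self._run(panel, layout, tmp_path,
                               {1: "Liposcelis rufa"},
                               failure_modes={1: frozenset({"anchor_fail"})})
        assert results[0].status == "invalid"
        assert results[0].qc.codes == (ANCHOR_COUPLING_FAIL,)

    def test_contamination_mode_flagged(self, panel, layout, tmp_path):
        results, _ = self._run(panel, layout, tmp_path,
                               {1: "Liposcelis rufa"},
                               failure_modes={1: frozenset({"contamination"})})
        assert results[0].status == "invalid"
        assert CONTAMINATION_OR_NONSPECIFIC in results[0].qc.codes

    def test_hyb_failure_mode_flagged(self, panel, layout, tmp_path):
        results, _ = self._run(panel, layout, tmp_path,
                               {1: "Liposcelis rufa"},
                               failure_modes={1: frozenset({"hyb_fail"})})
        assert results[0].status == "invalid"
        assert results[0].qc.codes == (AMPLIFICATION_OR_HYB_FAIL,)

    def test_twelve_lattices_ten_species_two_blank(self, panel, layout,
                                                   tmp_path):
        species = [p.target_species for p in panel.species_probes]
        truth = {i + 1: species[i] for i in range(10)}
        truth[11] = None
        truth[12] = None
        results, truths = self._run(panel, layout, tmp_path, truth)
        assert len(results) == 12
        for res, t in zip(results, truths):
            assert res.status == t.expected_status
            if t.expected_status == "identified":
                assert res.species == t.true_species

    def test_weak_signal_below_threshold_gives_no_call(self, panel, layout,
                                                       tmp_path):
        results, _ = self._run(panel, layout, tmp_path,
                               {1: "Liposcelis paeta"},
                               positive_signal_mean=300.0,
                               positive_signal_sd=30.0)
        # species probe cannot clear the 500 rule; positive control fails
        # too, so the chip reports a hybridization problem rather than a
        # species
        assert results[0].status in {"invalid", "no_call"}
        assert results[0].positive_probes == []

    def test_report_deterministic(self, panel, layout, tmp_path):
        results1, _ = self._run(panel, layout, tmp_path,
                                {1: "Liposcelis mendax"}, seed=9)
        results2, _ = self._run(panel, layout, tmp_path,
                                {1: "Liposcelis mendax"}, seed=9)
        assert report_to_tsv(results1) == report_to_tsv(results2)
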