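"""Candidate enumeration against brute force, and panel verification."""

import random

import pytest

from psocidchip.panel import load_default_panel
from psocidchip.probe_design import (
    DesignParams,
    DesignWarning,
    enumerate_candidates,
    verify_panel_specificity,
)
from psocidchip.seq import gc_fraction, reverse_complement
from psocidchip.simulator import SequenceSimConfig, simulate_sequences

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(s):
    return "".join(COMP[b] for b in reversed(s))


def brute_force_candidates(records, params):
    """Exhaustive enumeration oracle: all windows, all lengths, both strands.

    Returns, per species, the set of qualifying window sequences taken
    from the first conspecific record (independent reimplementation of
    the design rule with plain string operations).
    """
    by_species = {}
    for rid, species, s in records:
        by_species.setdefault(species, []).append(s)
    out = {}
    for species, seqs in by_species.items():
        ref = seqs[0]
        others = [s for sp, group in by_species.items() if sp != species
                  for s in group]
        wins = set()
        for k in range(params.length_range[0], params.length_range[1] + 1):
            for i in range(len(ref) - k + 1):
                w = ref[i:i + k]
                if not (params.gc_range[0] <= gc_fraction(w)
                        <= params.gc_range[1]):
                    continue
                if any(w not in s for s in seqs):
                    continue
                best = k + 1
                for s in others:
                    for strand_w in (w, rc(w)):
                        for j in range(len(s) - k + 1):
                            mm = sum(a != b
                                     for a, b in zip(strand_w, s[j:j + k]))
                            best = min(best, mm)
                if best >= params.min_cross_species_mismatches:
                    wins.add(w)
        out[species] = wins
    return out


def mutate(seq, positions, rng):
    chars = list(seq)
    for i in positions:
        chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
    return "".join(chars)


class TestEnumerateCandidates:
    def test_matches_brute_force_on_small_panel(self):
        rng = random.Random(42)
        params = DesignParams(length_range=(22, 24))
        a = "".join(rng.choice("ACGT") for _ in range(150))
        b = mutate(a, rng.sample(range(150), 12), rng)
        c = "".join(rng.choice("ACGT") for _ in range(150))
        records = [("a1", "sp A", a), ("b1", "sp B", b), ("c1", "sp C", c)]
        got = enumerate_candidates(records, params)
        expected = brute_force_candidates(records, params)
        for species in expected:
            assert {cand.sequence for cand in got[species]} == expected[species]

    def test_divergent_block_localizes_candidates(self):
        # two species identical except a 25-nt block differing at 5
        # positions: candidates exist only inside that block
        rng = random.Random(7)
        a = "".join(rng.choice("ACGT") for _ in range(200))
        block = range(100, 125)
        b = mutate(a, [100, 106, 112, 118, 124], rng)
        params = DesignParams(min_cross_species_mismatches=3,
                              gc_range=(0.0, 1.0))
        records = [("a1", "sp A", a), ("b1", "sp B", b)]
        got = enumerate_candidates(records, params)
        expected = brute_force_candidates(records, params)
        for species in ("sp A", "sp B"):
            assert {c.sequence for c in got[species]} == expected[species]
        for species in ("sp A", "sp B"):
            for cand in got[species]:
                # 1-based window must overlap >=3 divergent sites, so it
                # must lie across the block
                assert cand.start <= 125 and cand.end >= 101

    def test_identical_species_yield_no_candidates(self):
        rng = random.Random(3)
        a = "".join(rng.choice("ACGT") for _ in range(120))
        records = [("a1", "sp A", a), ("b1", "sp B", a)]
        with pytest.warns(DesignWarning):
            got = enumerate_candidates(records, DesignParams())
        assert got == {"sp A": [], "sp B": []}

    def test_single_species_input_is_an_error(self):
        with pytest.raises(ValueError, match="2 species"):
            enumerate_candidates([("a1", "sp A", "ACGT" * 30)],
                                 DesignParams())

    def test_candidates_sorted_by_distance_then_tm(self):
        panel = simulate_sequences(SequenceSimConfig(
            n_species=3, n_populations_per_species=(1, 1), seq_length=250,
            seed=11))
        got = enumerate_candidates(panel.records, DesignParams())
        for cands in got.values():
            keys = [(-c.min_nontarget_mismatches, -c.tm_C) for c in cands]
            assert keys == sorted(keys)

    def test_planted_tags_recovered(self):
        config = SequenceSimConfig(n_species=6,
                                   n_populations_per_species=(1, 3),
                                   seq_length=300, seed=5)
        panel = simulate_sequences(config)
        got = enumerate_candidates(panel.records, DesignParams())
        for species, tag in panel.tags.items():
            seqs = {c.sequence for c in got[species]}
            assert tag.sequence in seqs
            hits = [c for c in got[species] if c.sequence == tag.sequence]
            assert (hits[0].start, hits[0].end) == (tag.start, tag.end)
            assert hits[0].within_species_coverage == 1.0


class TestVerifyPanel:
    def _records_with_planted_probes(self, panel, seed=0):
        """Synthetic conspecific sequences carrying each real probe at its
        declared coordinates."""
        rng = random.Random(seed)
        records = []
        for p in panel.species_probes:
            backbone = "".join(rng.choice("ACGT") for _ in range(450))
            s0 = p.declared_start - 1
            seq = (backbone[:s0] + p.core_sequence
                   + backbone[s0 + len(p.core_sequence):])
            records.append((p.code + "_ref", p.target_species, seq))
        return records

    def test_all_probes_pass_on_planted_panel(self):
        panel = load_default_panel()
        records = self._records_with_planted_probes(panel)
        reports = verify_panel_specificity(panel, records)
        assert len(reports) == 10
        for rep in reports:
            assert rep.passes(3), rep.probe_code
            assert len(rep.rows) == len(records)

    def test_coordinate_check_passes_at_declared_span(self):
        panel = load_default_panel()
        records = self._records_with_planted_probes(panel)
        reports = verify_panel_specificity(panel, records)
        lpa = next(r for r in reports if r.probe_code == "Lpa")
        assert lpa.coordinate_ok is True
        row = next(r for r in lpa.rows if r.species == "Liposcelis paeta")
        assert row.best_match_mismatches == 0
        assert row.best_match_start == 98

    def test_probe_copied_into_nontarget_fails(self):
        panel = load_default_panel()
        records = self._records_with_planted_probes(panel)
        lpa = panel.probe("Lpa")
        rid, species, seq = records[0]
        assert species != lpa.target_species
        records[0] = (rid, species, seq[:10] + lpa.core_sequence + seq[10:])
        reports = verify_panel_specificity(panel, records)
        rep = next(r for r in reports if r.probe_code == "Lpa")
        assert not rep.passes(3)
        bad = next(r for r in rep.rows if r.sequence_id == rid)
        assert bad.best_match_mismatches == 0

    def test_reverse_complement_closure(self):
        panel = load_default_panel()
        records = self._records_with_planted_probes(panel)
        flipped = [(rid, sp, reverse_complement(s)) for rid, sp, s in records]
        direct = {r.probe_code: r.passes(3)
                  for r in verify_panel_specificity(panel, records)}
        mirrored = {r.probe_code: r.passes(3)
                    for r in verify_panel_specificity(panel, flipped)}
        assert direct == mirrored

    def test_absent_species_warns_per_probe(self):
        panel = load_default_panel()
        records = self._records_with_planted_probes(panel)[:3]
        reports = verify_panel_specificity(panel, records)
        missing = [r for r in reports if r.warnings]
        assert len(missing) == 7
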