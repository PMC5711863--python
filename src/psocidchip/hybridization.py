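"""Predict the chip hybridization pattern expected for an amplicon.

Given a sample's labeled amplicon (the asymmetric-PCR product, with the
Cy5 fluor on the reverse-primer strand) and the probe panel, this module
produces the truth table the signal caller should recover: which species
probes should light up, whether the positive control should, and that the
negative and blank controls never should.

Hybridization is modeled purely by sequence identity: a species probe is
expected positive iff its core matches the amplicon on either strand with
at most ``max_mismatches`` mismatches (default 0 — at the 66 °C assay
stringency the panel behaves as an exact-match detector).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import seq as sq
from .panel import ProbePanel

__all__ = ["AmpliconRecord", "PatternRow", "ExpectedPattern", "predict_pattern"]


@dataclass(frozen=True)
class AmpliconRecord:
    """One sample's amplicon, stored in sense orientation.

    ``labeled_strand`` records which strand carries the Cy5 label; with
    the standard 20:1 asymmetric PCR it is the antisense (reverse-primer
    extension) strand.  Pattern prediction searches both strands, so the
    label bookkeeping does not change calls.
    """

    sample_id: str
    sequence: str
    labeled_strand: str = "antisense"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"amplicon {self.sample_id!r}: empty sequence")
        sq.encode(self.sequence)  # raises on non-IUPAC
        if self.labeled_strand not in {"sense", "antisense"}:
            raise ValueError("labeled_strand must be 'sense' or 'antisense'")


@dataclass(frozen=True)
class PatternRow:
    probe_code: str
    expected_positive: bool
    best_mismatches: int


@dataclass
class ExpectedPattern:
    sample_id: str
    rows: list[PatternRow] = field(default_factory=list)

    def positive_codes(self) -> list[str]:
        return [r.probe_code for r in self.rows if r.expected_positive]

    def row(self, code: str) -> PatternRow:
        for r in self.rows:
            if r.probe_code == code:
                return r
        raise KeyError(code)


def predict_pattern(
    panel: ProbePanel,
    amplicon: AmpliconRecord,
    max_mismatches: int = 0,
    positive_template: AmpliconRecord | None = None,
) -> ExpectedPattern:
    """Expected per-probe outcome for one sample.

    Species probes are matched against the amplicon on both strands;
    the positive probe is expected positive iff the positive-control
    template (spiked into every hybridization mix) is supplied and
    contains the probe; negative and blank controls are always expected
    negative.
    """
    pattern = ExpectedPattern(sample_id=amplicon.sample_id)
    for probe in panel.probes:
        if probe.role == "species":
            if len(probe.core_sequence) > len(amplicon.sequence):
                mm = len(probe.core_sequence)
            else:
                mm, _, _ = sq.hamming_min_over_windows(
                    probe.core_sequence, amplicon.sequence, both_strands=True)
            pattern.rows.append(
                PatternRow(probe.code, mm <= max_mismatches, mm))
        elif probe.role == "positive":
            if positive_template is None:
                pattern.rows.append(
                    PatternRow(probe.code, False, len(probe.core_sequence)))
            else:
                mm, _, _ = sq.hamming_min_over_windows(
                    probe.core_sequence, positive_template.sequence,
                    both_strands=True)
                pattern.rows.append(
                    PatternRow(probe.code, mm <= max_mismatches, mm))
        elif probe.role in {"negative", "blank"}:
            pattern.rows.append(PatternRow(probe.code, False, -1))
        # anchor spots are pre-labeled, not hybridization outcomes
    return pattern


def pattern_to_tsv(pattern: ExpectedPattern) -> str:
    lines = ["probe_code\texpected_positive\tbest_mismatches"]
    for r in pattern.rows:
        lines.append(f"{r.probe_code}\t{int(r.expected_positive)}\t{r.best_mismatches}")
    return "\n".join(lines) + "\n"
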