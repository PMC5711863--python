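"""The chip decision procedure: spot positivity, QC, and the species call.

The scanner reports a foreground mean and a local background per spot at
635 nm; the working signal is F635 Mean - B635, retained unclamped so
that control means reflect the scanner noise floor.  Per lattice:

* the blank and negative control levels are the means of the corrected
  signals over their (unflagged) replicate spots;
* a detecting site is positive iff d = corrected - blank_mean is
  strictly greater than 10 x the negative-control mean AND strictly
  greater than 500 fluorescence units;
* a probe is positive when the mean of its replicate corrected signals
  passes the same site rule (default), or, in ``all_sites`` mode, when
  every valid replicate passes individually;
* anchor spots are judged on raw foreground (they carry their own Cy5
  and do not depend on hybridization);
* QC: dark anchors mean the probes never coupled to the slide; a
  positive negative-control means contamination or non-specific
  hybridization; a dark positive-control means amplification or
  hybridization failed.  Any QC failure voids the lattice.
* A valid lattice is "identified" iff exactly one species probe is
  positive; more are "ambiguous", none is "no_call".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import fmean
from typing import Sequence

from .chip_io import ChipLayout, ChipScan, SpotSignal, build_default_layout, read_gal, read_gpr
from .panel import ProbePanel

__all__ = [
    "CallingParams",
    "ProbeCall",
    "ChipQC",
    "SpeciesCall",
    "corrected_signal",
    "control_means",
    "site_positive",
    "probe_call",
    "evaluate_qc",
    "call_species",
    "call_lattice",
    "run_pipeline",
    "report_to_tsv",
]

ANCHOR_COUPLING_FAIL = "ANCHOR_COUPLING_FAIL"
CONTAMINATION_OR_NONSPECIFIC = "CONTAMINATION_OR_NONSPECIFIC"
AMPLIFICATION_OR_HYB_FAIL = "AMPLIFICATION_OR_HYB_FAIL"


@dataclass(frozen=True)
class CallingParams:
    """Thresholds of the positivity rule.

    ``absolute_threshold`` is the 500-unit floor and
    ``negative_multiplier`` the 10x negative-control factor; both
    comparisons are strict.  ``anchor_threshold`` (on raw foreground)
    defaults to ``absolute_threshold``.
    """

    absolute_threshold: float = 500.0
    negative_multiplier: float = 10.0
    min_valid_replicates: int = 2
    aggregate_mode: str = "mean_then_threshold"  # or "all_sites"
    anchor_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.absolute_threshold <= 0 or self.negative_multiplier <= 0:
            raise ValueError("thresholds must be positive")
        if self.aggregate_mode not in {"mean_then_threshold", "all_sites"}:
            raise ValueError("aggregate_mode must be mean_then_threshold/all_sites")

    @property
    def anchor_cut(self) -> float:
        return (self.anchor_threshold if self.anchor_threshold is not None
                else self.absolute_threshold)


@dataclass(frozen=True)
class ProbeCall:
    probe_code: str
    replicate_corrected_signals: tuple[float, ...]
    mean_corrected: float
    positive: bool
    n_valid: int
    indeterminate: bool = False


@dataclass(frozen=True)
class ChipQC:
    anchors_ok: bool
    positive_ok: bool
    negative_ok: bool
    codes: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return self.anchors_ok and self.positive_ok and self.negative_ok


@dataclass
class SpeciesCall:
    sample_id: str
    status: str  # identified | ambiguous | no_call | invalid
    species: str = ""
    positive_probes: list[str] = field(default_factory=list)
    qc: ChipQC | None = None
    probe_calls: dict[str, ProbeCall] = field(default_factory=dict)
    lattice: int | None = None


def corrected_signal(spot: SpotSignal) -> float:
    """F635 Mean - B635; may be negative, never clamped."""
    return spot.f635_mean - spot.b635


def control_means(
    scan: ChipScan,
    lattice: int,
    blank_code: str = "B",
    negative_code: str = "N",
) -> tuple[float, float]:
    """(blank_mean, negative_mean) over valid control spots of one lattice.

    Raises if either control has zero valid spots — without a noise floor
    and a non-specific baseline the lattice is uninterpretable.
    """
    means = []
    for code_role in (blank_code, negative_code):
        spots = [s for s in scan.lattice_spots(lattice)
                 if s.probe_code == code_role and s.valid]
        if not spots:
            raise ValueError(
                f"lattice {lattice}: no valid {code_role!r} control spots")
        means.append(fmean(corrected_signal(s) for s in spots))
    return means[0], means[1]


def site_positive(
    corrected: float,
    blank_mean: float,
    negative_mean: float,
    params: CallingParams = CallingParams(),
) -> bool:
    """One detecting site's positivity.

    d = corrected - blank_mean must strictly exceed both
    ``negative_multiplier * negative_mean`` and ``absolute_threshold``.
    """
    d = corrected - blank_mean
    return (d > params.negative_multiplier * negative_mean
            and d > params.absolute_threshold)


def probe_call(
    probe_code: str,
    spots: Sequence[SpotSignal],
    blank_mean: float,
    negative_mean: float,
    params: CallingParams = CallingParams(),
) -> ProbeCall:
    """Aggregate replicate spots of one probe into a single call.

    With fewer than ``min_valid_replicates`` unflagged spots the probe is
    indeterminate: treated as negative for species calling but surfaced.
    """
    valid = [s for s in spots if s.valid]
    signals = tuple(corrected_signal(s) for s in valid)
    if len(valid) < params.min_valid_replicates:
        return ProbeCall(probe_code, signals,
                         fmean(signals) if signals else 0.0,
                         positive=False, n_valid=len(valid),
                         indeterminate=True)
    mean = fmean(signals)
    if params.aggregate_mode == "mean_then_threshold":
        pos = site_positive(mean, blank_mean, negative_mean, params)
    else:  # all_sites
        pos = all(site_positive(x, blank_mean, negative_mean, params)
                  for x in signals)
    return ProbeCall(probe_code, signals, mean, positive=pos,
                     n_valid=len(valid))


def evaluate_qc(
    anchor_spots: Sequence[SpotSignal],
    positive_call: ProbeCall,
    negative_call: ProbeCall,
    params: CallingParams = CallingParams(),
) -> ChipQC:
    """Interpret the three control outcomes.

    Anchors are judged on raw F635 Mean against ``anchor_cut`` (their Cy5
    is attached at synthesis, so brightness only reflects coupling).

    The positive and negative control calls passed in must be judged
    against the blank and absolute threshold only (negative_mean = 0):
    the 10x-negative veto presupposes a trustworthy negative control,
    which is precisely what QC is testing — a contaminated chip would
    otherwise veto its own detection.
    """
    valid_anchors = [s for s in anchor_spots if s.valid]
    anchors_ok = bool(valid_anchors) and all(
        s.f635_mean > params.anchor_cut for s in valid_anchors)
    positive_ok = positive_call.positive
    negative_ok = not negative_call.positive
    codes: list[str] = []
    if not anchors_ok:
        codes.append(ANCHOR_COUPLING_FAIL)
    if not negative_ok:
        codes.append(CONTAMINATION_OR_NONSPECIFIC)
    if not positive_ok:
        codes.append(AMPLIFICATION_OR_HYB_FAIL)
    return ChipQC(anchors_ok=anchors_ok, positive_ok=positive_ok,
                  negative_ok=negative_ok, codes=tuple(codes))


def call_species(
    sample_id: str,
    species_calls: dict[str, ProbeCall],
    probe_targets: dict[str, str],
    qc: ChipQC,
) -> SpeciesCall:
    """Fold per-probe calls and QC into the final per-sample verdict.

    Invalid if any QC flag is down.  Otherwise identified iff exactly one
    species probe is positive; an indeterminate probe that could have
    changed a unique-positive verdict demotes it to ambiguous.
    """
    positives = [c for c, call in species_calls.items() if call.positive]
    indeterminate = [c for c, call in species_calls.items()
                     if call.indeterminate]
    result = SpeciesCall(sample_id=sample_id, status="", qc=qc,
                         positive_probes=positives)
    if not qc.ok:
        result.status = "invalid"
    elif len(positives) == 1:
        if indeterminate:
            # the unreadable probe might have been a second positive
            result.status = "ambiguous"
        else:
            result.status = "identified"
            result.species = probe_targets[positives[0]]
    elif len(positives) > 1:
        result.status = "ambiguous"
    else:
        result.status = "no_call"
    return result


def call_lattice(
    scan: ChipScan,
    layout: ChipLayout,
    panel: ProbePanel,
    lattice: int,
    params: CallingParams = CallingParams(),
) -> SpeciesCall:
    anchor_code = panel.probes_by_role("anchor")[0].code
    positive_code = panel.probes_by_role("positive")[0].code
    negative_code = panel.probes_by_role("negative")[0].code
    blank_code = panel.probes_by_role("blank")[0].code
    blank_mean, negative_mean = control_means(
        scan, lattice, blank_code=blank_code, negative_code=negative_code)
    calls: dict[str, ProbeCall] = {}
    for probe in panel.probes:
        if probe.role == "anchor":
            continue
        calls[probe.code] = probe_call(
            probe.code, scan.probe_spots(lattice, probe.code),
            blank_mean, negative_mean, params)
    # QC self-judgment of the control probes: blank + absolute threshold
    # only (see evaluate_qc docstring)
    positive_qc = probe_call(positive_code,
                             scan.probe_spots(lattice, positive_code),
                             blank_mean, 0.0, params)
    negative_qc = probe_call(negative_code,
                             scan.probe_spots(lattice, negative_code),
                             blank_mean, 0.0, params)
    qc = evaluate_qc(scan.probe_spots(lattice, anchor_code),
                     positive_qc, negative_qc, params)
    species_calls = {p.code: calls[p.code] for p in panel.species_probes}
    targets = {p.code: p.target_species for p in panel.species_probes}
    sample_id = scan.sample_ids.get(lattice, f"{scan.chip_id}:lattice{lattice}")
    result = call_species(sample_id, species_calls, targets, qc)
    result.probe_calls = calls
    result.lattice = lattice
    return result


def run_pipeline(
    gpr_path: str | Path,
    panel: ProbePanel,
    gal_path: str | Path | None = None,
    params: CallingParams = CallingParams(),
    background_column: str = "B635",
) -> list[SpeciesCall]:
    """Read a scan, join it to a layout, and call every lattice.

    Deterministic: identical inputs yield identical reports.
    """
    layout = read_gal(gal_path) if gal_path else build_default_layout(panel)
    scan = read_gpr(gpr_path, layout, background_column=background_column)
    return [call_lattice(scan, layout, panel, lattice, params)
            for lattice in scan.lattices()]


def report_to_tsv(results: Sequence[SpeciesCall]) -> str:
    lines = ["lattice\tsample_id\tstatus\tspecies\tpositive_probes\t"
             "qc_codes\tprobe_means"]
    for r in results:
        means = ";".join(
            f"{code}={call.mean_corrected:.1f}"
            for code, call in sorted(r.probe_calls.items()))
        codes = ",".join(r.qc.codes) if r.qc else ""
        lines.append("\t".join([
            str(r.lattice if r.lattice is not None else ""),
            r.sample_id, r.status, r.species or ".",
            ",".join(r.positive_probes) or ".", codes or ".", means]))
    return "\n".join(lines) + "\n"
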