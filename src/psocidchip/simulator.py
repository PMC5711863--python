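"""Synthetic data for end-to-end testing of the whole pipeline.

Two generators:

* :func:`simulate_sequences` builds ITS2-like labeled sequence panels in
  which each species carries a planted, species-unique tag (the region a
  designer should find) at recorded coordinates, with within-species SNP
  variation that never touches the tag.
* :func:`simulate_scan` writes a noisy GPR scan for a chip whose lattices
  each hybridized one sample.  Corrected signals are drawn log-normally
  above an additive Gaussian background — a standard fluorescence noise
  shape — and failure modes (anchor coupling failure, contamination,
  amplification/hybridization failure, cross-hybridization leakage) can
  be injected per lattice.

Both generators take a mandatory seed and are fully deterministic; the
truth they used is returned alongside the files so tests can grade the
pipeline's answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import seq as sq
from .chip_io import ChipLayout, ChipScan, SpotSignal
from .panel import ProbePanel

__all__ = [
    "SequenceSimConfig",
    "PlantedTag",
    "SequencePanel",
    "SignalSimConfig",
    "LatticeTruth",
    "simulate_sequences",
    "simulate_scan",
    "write_fasta",
]

_BASES = np.array(list("ACGT"))

DEFAULT_SPECIES_NAMES = tuple(f"Simulospecies sp{i + 1:02d}" for i in range(10))


@dataclass(frozen=True)
class SequenceSimConfig:
    """Shape of the synthetic ITS2 panel.

    Defaults mirror the real study: 10 species, 1-5 populations each,
    ~450 nt ITS2-like sequences, 24 nt unique tags kept at pairwise
    Hamming distance >= 5 (comfortably above the design threshold of 3),
    and a 1% within-species SNP rate outside the tag.
    """

    n_species: int = 10
    n_populations_per_species: tuple[int, int] = (1, 5)
    seq_length: int = 450
    tag_length: int = 24
    min_tag_distance: int = 5
    tag_gc_range: tuple[float, float] = (0.35, 0.65)
    within_species_snp_rate: float = 0.01
    species_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_tag_distance < 1:
            raise ValueError("min_tag_distance must be >= 1")
        if not (15 <= self.tag_length <= 40):
            raise ValueError("tag_length must be a plausible probe length (15-40)")
        if self.min_tag_distance > self.tag_length:
            raise ValueError(
                "min_tag_distance cannot exceed tag_length: no tag pair "
                "can be that far apart")
        if self.seq_length < 2 * self.tag_length:
            raise ValueError("seq_length too short to host a tag")
        if not (0 <= self.within_species_snp_rate < 0.2):
            raise ValueError("within_species_snp_rate must be in [0, 0.2)")


@dataclass(frozen=True)
class PlantedTag:
    species: str
    sequence: str
    start: int  # 1-based inclusive on every conspecific sequence
    end: int


@dataclass
class SequencePanel:
    """records: (sequence_id, species, sequence); truth: planted tags."""

    records: list[tuple[str, str, str]] = field(default_factory=list)
    tags: dict[str, PlantedTag] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _pairwise_ok(tag: str, others: list[str], min_dist: int) -> bool:
    """Tag must keep the distance to every existing tag on both strands."""
    t = np.frombuffer(tag.encode(), dtype=np.uint8)
    rc = np.frombuffer(sq.reverse_complement(tag).encode(), dtype=np.uint8)
    for other in others:
        o = np.frombuffer(other.encode(), dtype=np.uint8)
        if int((t != o).sum()) < min_dist or int((rc != o).sum()) < min_dist:
            return False
    return True


def simulate_sequences(config: SequenceSimConfig) -> SequencePanel:
    """Generate a labeled multi-species panel with planted unique tags.

    Every conspecific sequence carries the species tag verbatim at the
    same recorded coordinates; SNP noise is applied only outside the tag.
    Raises when the requested tag spacing cannot be sampled (tag space
    too small for the pairwise-distance constraint).
    """
    rng = np.random.default_rng(config.seed)
    names = (config.species_names
             or DEFAULT_SPECIES_NAMES[:config.n_species]
             or tuple(f"Simulospecies sp{i + 1:02d}"
                      for i in range(config.n_species)))
    if len(names) < config.n_species:
        names = tuple(f"Simulospecies sp{i + 1:02d}"
                      for i in range(config.n_species))
    tags: list[str] = []
    for _ in range(config.n_species):
        for _attempt in range(2000):
            tag = _random_seq(rng, config.tag_length)
            # planted tags must themselves be valid probes: moderate GC
            # keeps them inside any sensible designer's GC filter
            gc = (tag.count("G") + tag.count("C")) / len(tag)
            if not (config.tag_gc_range[0] <= gc <= config.tag_gc_range[1]):
                continue
            if _pairwise_ok(tag, tags, config.min_tag_distance):
                tags.append(tag)
                break
        else:
            raise ValueError(
                "could not sample mutually distant tags: tag space too "
                f"small for tag_length={config.tag_length}, "
                f"min_tag_distance={config.min_tag_distance}")
    panel = SequencePanel()
    lo, hi = config.n_populations_per_species
    for species, tag in zip(names[:config.n_species], tags):
        backbone = _random_seq(rng, config.seq_length)
        start0 = int(rng.integers(0, config.seq_length - config.tag_length + 1))
        base = backbone[:start0] + tag + backbone[start0 + config.tag_length:]
        panel.tags[species] = PlantedTag(
            species, tag, start0 + 1, start0 + config.tag_length)
        n_pops = int(rng.integers(lo, hi + 1))
        for p in range(n_pops):
            chars = np.array(list(base))
            if config.within_species_snp_rate > 0 and p > 0:
                mask = rng.random(config.seq_length) < config.within_species_snp_rate
                mask[start0:start0 + config.tag_length] = False
                for i in np.flatnonzero(mask):
                    choices = [b for b in "ACGT" if b != chars[i]]
                    chars[i] = choices[int(rng.integers(0, 3))]
            rid = f"{species.replace(' ', '_')}_pop{p + 1}"
            panel.records.append((rid, species, "".join(chars)))
    return panel


def write_fasta(panel: SequencePanel, path: str | Path) -> None:
    lines = []
    for rid, species, s in panel.records:
        lines.append(f">{rid} species={species.replace(' ', '_')}")
        for i in range(0, len(s), 70):
            lines.append(s[i:i + 70])
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Scan simulation

VALID_FAILURE_MODES = frozenset(
    {"anchor_fail", "contamination", "hyb_fail"})


@dataclass(frozen=True)
class SignalSimConfig:
    """Noise model and truth for one simulated chip scan.

    ``true_species_per_lattice`` maps lattice number -> species name (or
    None for a no-template lattice: the spiked positive control still
    lights up, the species probes do not).  Corrected signals for truly
    hybridized spots are log-normal with the given natural-scale mean/sd;
    everything sits on an additive Gaussian background.  Failure modes
    per lattice: ``anchor_fail``, ``contamination``, ``hyb_fail``;
    cross-hybridization leakage is configured via ``cross_hyb`` as
    (probe_code, level) with level the leaked fraction of the positive
    signal.
    """

    true_species_per_lattice: dict[int, str | None] = field(default_factory=dict)
    positive_signal_mean: float = 10000.0
    positive_signal_sd: float = 1000.0
    background_mean: float = 100.0
    background_sd: float = 30.0
    blank_mean: float = 20.0
    negative_mean: float = 30.0
    control_sd: float = 15.0
    anchor_signal_mean: float = 40000.0
    failure_modes: dict[int, frozenset[str]] = field(default_factory=dict)
    cross_hyb: dict[int, tuple[str, float]] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        for v in (self.positive_signal_mean, self.background_mean,
                  self.blank_mean, self.negative_mean):
            if v < 0:
                raise ValueError("signal means must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        for lattice, modes in self.failure_modes.items():
            bad = set(modes) - VALID_FAILURE_MODES
            if bad:
                raise ValueError(f"unknown failure mode(s) {sorted(bad)}")


@dataclass(frozen=True)
class LatticeTruth:
    lattice: int
    true_species: str | None
    expected_status: str
    expected_qc_codes: tuple[str, ...]


def _lognormal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Log-normal draws parameterized by natural-scale mean and sd."""
    if mean <= 0:
        return np.zeros(n)
    var = sd ** 2
    mu = np.log(mean ** 2 / np.sqrt(var + mean ** 2))
    sigma = np.sqrt(np.log(1 + var / mean ** 2))
    return rng.lognormal(mu, sigma, size=n)


def simulate_scan(
    layout: ChipLayout,
    panel: ProbePanel,
    config: SignalSimConfig,
) -> tuple[ChipScan, list[LatticeTruth]]:
    """Draw a full noisy scan plus the truth table grading it.

    Spots of the true species' probe and of the positive control draw
    from the positive log-normal; other species probes and controls draw
    from their background/control levels; anchors are bright unless
    ``anchor_fail``.  ``contamination`` lifts the negative control to the
    positive level; ``hyb_fail`` kills all hybridization-driven signal
    (positive control included) while anchors stay bright.
    """
    from .calling import (AMPLIFICATION_OR_HYB_FAIL, ANCHOR_COUPLING_FAIL,
                          CONTAMINATION_OR_NONSPECIFIC)

    rng = np.random.default_rng(config.seed)
    known = {p.target_species for p in panel.species_probes}
    for lattice, species in config.true_species_per_lattice.items():
        if species is not None and species not in known:
            raise ValueError(
                f"lattice {lattice}: unknown species {species!r} "
                "(not targeted by any panel probe)")
    code_by_species = {p.target_species: p.code for p in panel.species_probes}
    anchor = panel.probes_by_role("anchor")[0].code
    positive = panel.probes_by_role("positive")[0].code
    negative = panel.probes_by_role("negative")[0].code
    blank = panel.probes_by_role("blank")[0].code

    scan = ChipScan(chip_id=f"simchip-seed{config.seed}")
    truths: list[LatticeTruth] = []
    for lattice in sorted(config.true_species_per_lattice):
        species = config.true_species_per_lattice[lattice]
        modes = config.failure_modes.get(lattice, frozenset())
        true_code = code_by_species.get(species) if species else None
        scan.sample_ids[lattice] = (
            f"sample-{lattice:02d}-"
            + (species.replace(" ", "_") if species else "no_template"))
        for (row, col) in sorted(layout.spot_map):
            probe_code = layout.spot_map[(row, col)]
            bg = max(0.0, float(rng.normal(config.background_mean,
                                           config.background_sd)))
            if probe_code == anchor:
                level = 0.0 if "anchor_fail" in modes else float(
                    _lognormal(rng, config.anchor_signal_mean,
                               0.1 * config.anchor_signal_mean, 1)[0])
            elif probe_code == blank:
                level = float(rng.normal(config.blank_mean, config.control_sd))
            elif probe_code == negative:
                if "contamination" in modes:
                    level = float(_lognormal(rng, config.positive_signal_mean,
                                             config.positive_signal_sd, 1)[0])
                else:
                    level = float(rng.normal(config.negative_mean,
                                             config.control_sd))
            elif probe_code == positive:
                if "hyb_fail" in modes:
                    level = float(rng.normal(config.negative_mean,
                                             config.control_sd))
                else:
                    level = float(_lognormal(rng, config.positive_signal_mean,
                                             config.positive_signal_sd, 1)[0])
            else:  # species probe spot
                hybridized = (probe_code == true_code
                              and "hyb_fail" not in modes)
                if hybridized:
                    level = float(_lognormal(rng, config.positive_signal_mean,
                                             config.positive_signal_sd, 1)[0])
                else:
                    level = float(rng.normal(config.negative_mean,
                                             config.control_sd))
                xh = config.cross_hyb.get(lattice)
                if xh and probe_code == xh[0] and not hybridized:
                    level += float(
                        _lognormal(rng, xh[1] * config.positive_signal_mean,
                                   xh[1] * config.positive_signal_sd, 1)[0])
            scan.spots.append(SpotSignal(
                lattice=lattice, row=row, col=col, probe_code=probe_code,
                f635_mean=max(0.0, level) + bg, b635=bg, flag=0))
        codes = []
        if "anchor_fail" in modes:
            codes.append(ANCHOR_COUPLING_FAIL)
        if "contamination" in modes:
            codes.append(CONTAMINATION_OR_NONSPECIFIC)
        if "hyb_fail" in modes:
            codes.append(AMPLIFICATION_OR_HYB_FAIL)
        if codes:
            status = "invalid"
        elif species is None:
            status = "no_call"
        else:
            status = "identified"
        truths.append(LatticeTruth(lattice, species, status, tuple(codes)))
    return scan, truths


def truth_to_tsv(truths: list[LatticeTruth], path: str | Path) -> None:
    lines = ["lattice\ttrue_species\texpected_status\texpected_qc_codes"]
    for t in truths:
        lines.append("\t".join([
            str(t.lattice), t.true_species or ".", t.expected_status,
            ",".join(t.expected_qc_codes) or "."]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
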