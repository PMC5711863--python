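"""Species-specific probe discovery and panel specificity verification.

A candidate probe is a window of a species' ITS2 sequence that

* is exactly present (IUPAC-compatible, 0 mismatches) in the required
  fraction of conspecific sequences (all of them by default),
* sits at Hamming distance >= ``min_cross_species_mismatches`` from every
  same-length window, on either strand, of every non-target sequence, and
* passes GC-content and (optionally) melting-temperature filters.

The same machinery verifies an existing probe panel: for each species
probe the best match in every input sequence is reported, and the probe
passes when its only perfect hits are conspecific and all non-target
sequences keep the required distance.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from . import seq as sq
from .panel import ProbePanel

__all__ = [
    "DesignParams",
    "ProbeCandidate",
    "SpecificityRow",
    "SpecificityReport",
    "DesignWarning",
    "read_labeled_fasta",
    "enumerate_candidates",
    "verify_panel_specificity",
]

DEFAULT_SPECIES_REGEX = r"species=([^;,\s]+(?:[_ ][^;,\s]+)?)"


class DesignWarning(UserWarning):
    """Non-fatal design issue (e.g. a species with no specific window)."""


@dataclass(frozen=True)
class DesignParams:
    """Filters applied during candidate enumeration.

    Defaults mirror the published panel: probe lengths 22–26 nt and a
    minimum cross-species Hamming distance of 3 mismatches.
    """

    length_range: tuple[int, int] = (22, 26)
    min_cross_species_mismatches: int = 3
    require_perfect_within_species: bool = True
    within_species_min_coverage: float = 1.0
    gc_range: tuple[float, float] = (0.30, 0.70)
    tm_range_C: tuple[float, float] | None = None
    max_candidates_per_species: int = 0  # 0 = no cap
    distance_mode: str = "hamming"  # or "edit"

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (15 <= lo <= hi <= 40):
            raise ValueError("length_range must lie within [15, 40]")
        if self.min_cross_species_mismatches < 1:
            raise ValueError("min_cross_species_mismatches must be >= 1")
        if self.distance_mode not in {"hamming", "edit"}:
            raise ValueError("distance_mode must be 'hamming' or 'edit'")


@dataclass(frozen=True)
class ProbeCandidate:
    target_species: str
    sequence: str
    start: int  # 1-based inclusive on the named reference
    end: int
    reference_id: str
    within_species_coverage: float
    min_nontarget_mismatches: int
    gc: float
    tm_C: float


@dataclass(frozen=True)
class SpecificityRow:
    sequence_id: str
    species: str
    best_match_mismatches: int
    best_match_start: int  # 1-based
    strand: str


@dataclass
class SpecificityReport:
    probe_code: str
    target_species: str
    rows: list[SpecificityRow] = field(default_factory=list)
    coordinate_ok: bool | None = None
    warnings: list[str] = field(default_factory=list)

    def passes(self, min_nontarget_mismatches: int) -> bool:
        """Specific iff perfect hits are conspecific-only and every
        non-target keeps the required distance."""
        ok = True
        for row in self.rows:
            if row.species == self.target_species:
                continue
            if row.best_match_mismatches < min_nontarget_mismatches:
                ok = False
        return ok


def read_labeled_fasta(
    path: str | Path, species_regex: str = DEFAULT_SPECIES_REGEX
) -> list[tuple[str, str, str]]:
    """Read a multi-FASTA of labeled sequences -> [(id, species, sequence)].

    The species label is taken from the first regex group matched against
    the full header; failing that, the first two whitespace-separated
    words of the description after the id.
    """
    pat = re.compile(species_regex)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        m = pat.search(header)
        if m:
            label = m.group(1).replace("_", " ")
        else:
            words = header.split()
            rest = words[1:] if len(words) > 1 else words
            label = " ".join(rest[:2]) if rest else rec.id
        out.append((rec.id, label, str(rec.seq).upper()))
    return out


def _group_by_species(
    records: Sequence[tuple[str, str, str]]
) -> dict[str, list[tuple[str, str]]]:
    groups: dict[str, list[tuple[str, str]]] = {}
    for rid, species, s in records:
        groups.setdefault(species, []).append((rid, s))
    return groups


def _min_distance_to_sequences(
    window: str, seqs: Iterable[str], mode: str
) -> int:
    fn = sq.hamming_min_over_windows if mode == "hamming" else sq.edit_min_over_windows
    best = len(window) + 1
    for s in seqs:
        if len(s) < len(window):
            continue
        mm, _, _ = fn(window, s, both_strands=True)
        if mm < best:
            best = mm
            if best == 0:
                break
    return best


def enumerate_candidates(
    records: Sequence[tuple[str, str, str]],
    params: DesignParams = DesignParams(),
) -> dict[str, list[ProbeCandidate]]:
    """Enumerate species-specific probe candidates for every species.

    ``records`` are (sequence_id, species, sequence) triples, e.g. from
    :func:`read_labeled_fasta`.  Returns a dict mapping species to its
    candidates, sorted by descending cross-species distance then
    descending Tm.  A species with no qualifying window gets an empty
    list plus a :class:`DesignWarning`; a single-species input is an
    error, since specificity is undefined without a non-target.
    """
    groups = _group_by_species(records)
    if len(groups) < 2:
        raise ValueError(
            "candidate enumeration needs at least 2 species; "
            f"got {sorted(groups)}"
        )
    min_cov = (
        1.0 if params.require_perfect_within_species
        else params.within_species_min_coverage
    )
    out: dict[str, list[ProbeCandidate]] = {}
    enc_fwd = {rid: sq.encode(s) for rid, _, s in records}
    enc_rev = {rid: sq.encode(sq.reverse_complement(s)) for rid, _, s in records}
    for species, members in groups.items():
        ref_id, ref_seq = members[0]
        conspecific_ids = [rid for rid, _ in members]
        nontarget_ids = [rid for rid2, sp2, _ in records if sp2 != species
                         for rid in [rid2]]
        found: list[ProbeCandidate] = []
        seen_windows: set[str] = set()
        ref_enc = enc_fwd[ref_id]
        for length in range(params.length_range[0], params.length_range[1] + 1):
            if len(ref_seq) < length:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref_enc, length)
            m = windows.shape[0]
            if params.distance_mode == "hamming":
                # vectorized: min Hamming distance of every reference
                # window to every window of every non-target, both strands
                min_mm = np.full(m, length + 1, dtype=np.int64)
                for rid in nontarget_ids:
                    for enc in (enc_fwd[rid], enc_rev[rid]):
                        if len(enc) < length:
                            continue
                        subj = np.lib.stride_tricks.sliding_window_view(
                            enc, length)
                        d = ((windows[:, None, :] & subj[None, :, :]) == 0
                             ).sum(axis=2).min(axis=1)
                        np.minimum(min_mm, d, out=min_mm)
            else:
                min_mm = np.array([
                    _min_distance_to_sequences(
                        ref_seq[i:i + length],
                        [s for rid2, sp2, s in records if sp2 != species],
                        "edit")
                    for i in range(m)])
            cov_hits = np.zeros(m, dtype=np.int64)
            for rid in conspecific_ids:
                enc = enc_fwd[rid]
                if len(enc) < length:
                    continue
                subj = np.lib.stride_tricks.sliding_window_view(enc, length)
                exact = (((windows[:, None, :] & subj[None, :, :]) == 0
                          ).sum(axis=2) == 0).any(axis=1)
                cov_hits += exact
            coverage = cov_hits / len(conspecific_ids)
            for start0 in range(m):
                if min_mm[start0] < params.min_cross_species_mismatches:
                    continue
                if coverage[start0] < min_cov:
                    continue
                window = ref_seq[start0:start0 + length]
                if window in seen_windows:
                    continue
                if not all(c in "ACGT" for c in window):
                    continue
                gc = sq.gc_fraction(window)
                if not (params.gc_range[0] <= gc <= params.gc_range[1]):
                    continue
                tm = sq.tm_nearest_neighbor(window)
                if params.tm_range_C is not None and not (
                    params.tm_range_C[0] <= tm <= params.tm_range_C[1]
                ):
                    continue
                seen_windows.add(window)
                found.append(ProbeCandidate(
                    target_species=species,
                    sequence=window,
                    start=start0 + 1,
                    end=start0 + length,
                    reference_id=ref_id,
                    within_species_coverage=float(coverage[start0]),
                    min_nontarget_mismatches=int(min_mm[start0]),
                    gc=gc,
                    tm_C=tm,
                ))
        found.sort(key=lambda c: (-c.min_nontarget_mismatches, -c.tm_C,
                                  c.start, c.end))
        if not found:
            warnings.warn(
                f"no species-specific window found for {species}",
                DesignWarning, stacklevel=2,
            )
        cap = params.max_candidates_per_species
        out[species] = found[:cap] if cap else found
    return out


def verify_panel_specificity(
    panel: ProbePanel,
    records: Sequence[tuple[str, str, str]],
    params: DesignParams = DesignParams(),
) -> list[SpecificityReport]:
    """Check every species probe of a panel against labeled sequences.

    For each probe, the best (lowest-mismatch) ungapped match in every
    sequence is recorded on either strand.  When the probe has declared
    coordinates and a conspecific sequence carries a perfect forward hit,
    the hit position is compared with the declared span and
    ``coordinate_ok`` set accordingly.
    """
    fn = (sq.hamming_min_over_windows if params.distance_mode == "hamming"
          else sq.edit_min_over_windows)
    species_present = {species for _, species, _ in records}
    reports = []
    for probe in panel.species_probes:
        rep = SpecificityReport(probe_code=probe.code,
                                target_species=probe.target_species)
        if probe.target_species not in species_present:
            rep.warnings.append(
                f"target species {probe.target_species!r} absent from input"
            )
        for rid, species, s in records:
            if len(s) < len(probe.core_sequence):
                rep.rows.append(SpecificityRow(rid, species,
                                               len(probe.core_sequence), 0, "+"))
                continue
            mm, pos0, strand = fn(probe.core_sequence, s, both_strands=True)
            rep.rows.append(SpecificityRow(rid, species, mm, pos0 + 1, strand))
            if (
                mm == 0
                and species == probe.target_species
                and probe.declared_start is not None
                and probe.declared_end is not None
            ):
                hit = (pos0 + 1, pos0 + len(probe.core_sequence))
                ok = hit == (probe.declared_start, probe.declared_end)
                # any conspecific perfect hit at the declared span validates
                rep.coordinate_ok = ok if rep.coordinate_ok is not True else True
        reports.append(rep)
    return reports


def candidates_to_tsv(
    candidates: Mapping[str, Sequence[ProbeCandidate]], path: str | Path
) -> None:
    cols = ["target_species", "sequence", "start", "end", "reference_id",
            "within_species_coverage", "min_nontarget_mismatches", "gc", "tm_C"]
    lines = ["\t".join(cols)]
    for species in sorted(candidates):
        for c in candidates[species]:
            lines.append("\t".join([
                c.target_species, c.sequence, str(c.start), str(c.end),
                c.reference_id, f"{c.within_species_coverage:.4f}",
                str(c.min_nontarget_mismatches), f"{c.gc:.4f}", f"{c.tm_C:.2f}",
            ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def reports_to_tsv(reports: Sequence[SpecificityReport], path: str | Path,
                   params: DesignParams = DesignParams()) -> None:
    cols = ["probe_code", "target_species", "sequence_id", "species",
            "best_match_mismatches", "best_match_start", "strand", "probe_passes"]
    lines = ["\t".join(cols)]
    for rep in reports:
        passes = rep.passes(params.min_cross_species_mismatches)
        for row in rep.rows:
            lines.append("\t".join([
                rep.probe_code, rep.target_species, row.sequence_id, row.species,
                str(row.best_match_mismatches), str(row.best_match_start),
                row.strand, "yes" if passes else "no",
            ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
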