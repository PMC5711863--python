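"""Domain model for the diagnostic probe panel.

The panel bundles everything printed on the chip and in the reaction mix:
the ten *Liposcelis* species and their source populations, the ten
species-specific ITS2 probes, the four quality-control probes (anchor,
positive, negative, blank) and the PCR primers.  Probe tables, species
rosters and primer tables travel as plain UTF-8 TSV files; parsers
validate every structural invariant and raise instead of silently fixing.

Coordinates are 1-based inclusive on the target species' ITS2 sense
strand.  Linker chemistry (5' amino modifier + poly-T15 spacer) and fluor
labels are kept as metadata so that sequence algorithms only ever see the
hybridizing core.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

__all__ = [
    "SpeciesRecord",
    "PopulationRecord",
    "Probe",
    "PrimerRecord",
    "ProbePanel",
    "PanelValidationError",
    "ValidationCheck",
    "ValidationReport",
    "parse_probe_table",
    "write_probe_table",
    "parse_species_table",
    "parse_primer_table",
    "load_default_panel",
    "validate_panel",
]

GROUP_CODES = frozenset({"IA", "IB", "IIC", "IID"})
PROBE_ROLES = frozenset({"species", "anchor", "positive", "negative", "blank"})
QC_ROLES = ("anchor", "positive", "negative", "blank")
DNA_RE = re.compile(r"^[ACGT]*$")

DEFAULT_HYBRIDIZATION_TEMP_C = 66.0
DEFAULT_PRIMER_RATIO = 20.0  # labeled reverse : forward

_MISSING = {"", "."}


class PanelValidationError(ValueError):
    """A probe/primer/roster table violated a structural invariant."""


@dataclass(frozen=True)
class SpeciesRecord:
    species_name: str
    group_code: str

    def __post_init__(self) -> None:
        if self.group_code not in GROUP_CODES:
            raise PanelValidationError(
                f"species {self.species_name!r}: unknown group code "
                f"{self.group_code!r} (expected one of {sorted(GROUP_CODES)})"
            )


@dataclass(frozen=True)
class PopulationRecord:
    species_name: str
    population_id: str
    region: str = ""


@dataclass(frozen=True)
class Probe:
    """One spotted oligo.

    ``core_sequence`` is the hybridizing part only; the 5' linker
    (``linker_5prime``) and any fluor (``label_5prime``) are metadata.
    ``declared_start``/``declared_end`` are 1-based inclusive positions on
    the target ITS2 sense sequence and are absent (``None``) for QC probes.
    """

    code: str
    role: str
    target_species: str = ""
    core_sequence: str = ""
    linker_5prime: str = ""
    label_5prime: str = ""
    declared_length: int | None = None
    declared_start: int | None = None
    declared_end: int | None = None

    def __post_init__(self) -> None:
        if self.role not in PROBE_ROLES:
            raise PanelValidationError(
                f"probe {self.code!r}: unknown role {self.role!r}"
            )
        if not DNA_RE.match(self.core_sequence):
            raise PanelValidationError(
                f"probe {self.code!r}: core sequence contains non-ACGT characters"
            )
        if self.role == "species" and not self.target_species:
            raise PanelValidationError(
                f"probe {self.code!r}: species probe needs a target species"
            )
        if self.role != "species" and self.target_species:
            raise PanelValidationError(
                f"probe {self.code!r}: QC probe must not name a target species"
            )
        if (
            self.declared_start is not None
            and self.declared_end is not None
            and self.declared_end < self.declared_start
        ):
            raise PanelValidationError(
                f"probe {self.code!r}: end {self.declared_end} < "
                f"start {self.declared_start}"
            )

    def check_consistency(self) -> None:
        """Enforce the strict span/length invariants (used at parse time).

        Kept out of ``__post_init__`` so that an inconsistent panel can be
        constructed in memory and audited by :func:`validate_panel`.
        """
        if self.role == "blank":
            if self.core_sequence:
                raise PanelValidationError(
                    f"probe {self.code!r}: blank control carries no sequence"
                )
            return
        if not self.core_sequence:
            raise PanelValidationError(
                f"probe {self.code!r}: role {self.role!r} requires a sequence"
            )
        if (
            self.declared_length is not None
            and self.declared_length != len(self.core_sequence)
        ):
            raise PanelValidationError(
                f"probe {self.code!r}: declared length {self.declared_length} "
                f"!= sequence length {len(self.core_sequence)}"
            )
        if (
            self.role == "species"
            and self.declared_start is not None
            and self.declared_end is not None
        ):
            span = self.declared_end - self.declared_start + 1
            if span != len(self.core_sequence):
                raise PanelValidationError(
                    f"probe {self.code!r}: coordinate span {span} != sequence "
                    f"length {len(self.core_sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.core_sequence)


@dataclass(frozen=True)
class PrimerRecord:
    name: str
    sequence: str
    label_5prime: str = ""
    direction: str = "forward"
    molar_ratio_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in {"forward", "reverse"}:
            raise PanelValidationError(
                f"primer {self.name!r}: direction must be forward/reverse"
            )
        if not DNA_RE.match(self.sequence) or not self.sequence:
            raise PanelValidationError(
                f"primer {self.name!r}: sequence must be non-empty ACGT"
            )
        if self.molar_ratio_weight <= 0:
            raise PanelValidationError(
                f"primer {self.name!r}: molar ratio weight must be positive"
            )


@dataclass
class ProbePanel:
    """A full chip panel: roster + probes + primers + assay metadata."""

    species: list[SpeciesRecord] = field(default_factory=list)
    populations: list[PopulationRecord] = field(default_factory=list)
    probes: list[Probe] = field(default_factory=list)
    primers: list[PrimerRecord] = field(default_factory=list)
    hybridization_temp_C: float = DEFAULT_HYBRIDIZATION_TEMP_C

    @property
    def species_probes(self) -> list[Probe]:
        return [p for p in self.probes if p.role == "species"]

    def probes_by_role(self, role: str) -> list[Probe]:
        return [p for p in self.probes if p.role == role]

    def probe(self, code: str) -> Probe:
        for p in self.probes:
            if p.code == code:
                return p
        raise KeyError(code)

    @property
    def probe_codes(self) -> list[str]:
        return [p.code for p in self.probes]


# ---------------------------------------------------------------------------
# TSV parsing

def _split_rows(path: str | Path) -> tuple[list[str], list[list[str]]]:
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise PanelValidationError(f"{path}: empty table")
    header = lines[0].rstrip("\n").split("\t")
    rows = [ln.split("\t") for ln in lines[1:]]
    return header, rows


def _cell(row: dict[str, str], key: str) -> str:
    v = row.get(key, "").strip()
    return "" if v in _MISSING else v


_COORD_RANGE_RE = re.compile(r"^(\d+)\s*[-–—]\s*(\d+)$")  # accepts en/em dash


def _parse_coord(row: dict[str, str], code: str) -> tuple[int | None, int | None]:
    """Start/end either as two columns or a single 'position' range."""
    s, e = _cell(row, "start"), _cell(row, "end")
    if s and e:
        return int(s), int(e)
    pos = _cell(row, "position")
    if pos:
        m = _COORD_RANGE_RE.match(pos)
        if not m:
            raise PanelValidationError(
                f"probe {code!r}: malformed position range {pos!r}"
            )
        return int(m.group(1)), int(m.group(2))
    return None, None


_LINKER_PREFIX_RE = re.compile(r"^(?:(Cy\d+)-)?(?:NH2-)?(?:\(T\)15-)?", re.I)


def _strip_linker(seq: str) -> tuple[str, str, str]:
    """Split decorated sequence text into (core, linker, label).

    Accepts bare cores as well as decorated forms like
    ``NH2-(T)15-AGGA...`` or ``Cy5-GTCT...-NH2``.
    """
    label = ""
    linker_parts: list[str] = []
    s = seq.strip()
    m = re.match(r"^(Cy\d+)-", s, re.I)
    if m:
        label = m.group(1)
        s = s[m.end():]
    m = re.match(r"^NH2-\(T\)15-", s, re.I)
    if m:
        linker_parts.append("NH2-(T)15")
        s = s[m.end():]
    if s.upper().endswith("-NH2"):
        linker_parts.append("NH2-3prime")
        s = s[:-4]
    return s, "+".join(linker_parts), label


def parse_probe_table(path: str | Path) -> ProbePanel:
    """Read a probe TSV into a :class:`ProbePanel` (probes only).

    Columns: code, role, target_species, sequence, linker, label, length,
    start, end (or a single ``position`` range column).  The sequence cell
    may still carry linker decoration text, which is stripped into the
    linker/label fields.  Raises :class:`PanelValidationError` on any
    invariant violation.
    """
    header, rows = _split_rows(path)
    probes: list[Probe] = []
    seen: set[str] = set()
    for raw in rows:
        row = dict(zip(header, raw))
        code = _cell(row, "code")
        if not code:
            raise PanelValidationError(f"{path}: row without a probe code")
        if code in seen:
            raise PanelValidationError(f"duplicate probe code {code!r}")
        seen.add(code)
        core, linker_from_seq, label_from_seq = _strip_linker(_cell(row, "sequence"))
        start, end = _parse_coord(row, code)
        length = _cell(row, "length")
        probe = Probe(
                code=code,
                role=_cell(row, "role"),
                target_species=_cell(row, "target_species"),
                core_sequence=core.upper(),
                linker_5prime=_cell(row, "linker") or linker_from_seq,
                label_5prime=_cell(row, "label") or label_from_seq,
                declared_length=int(length) if length else None,
                declared_start=start,
                declared_end=end,
            )
        probe.check_consistency()
        probes.append(probe)
    return ProbePanel(probes=probes)


def write_probe_table(panel: ProbePanel, path: str | Path) -> None:
    """Write probes back to TSV; inverse of :func:`parse_probe_table`."""
    cols = ["code", "role", "target_species", "sequence", "linker", "label",
            "length", "start", "end"]
    lines = ["\t".join(cols)]
    for p in panel.probes:
        lines.append("\t".join([
            p.code,
            p.role,
            p.target_species or ".",
            p.core_sequence or ".",
            p.linker_5prime or ".",
            p.label_5prime or ".",
            str(p.declared_length) if p.declared_length is not None else ".",
            str(p.declared_start) if p.declared_start is not None else ".",
            str(p.declared_end) if p.declared_end is not None else ".",
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def parse_species_table(path: str | Path) -> tuple[list[SpeciesRecord], list[PopulationRecord]]:
    """Read the species/population roster TSV (species, group, population, region)."""
    header, rows = _split_rows(path)
    species: dict[str, SpeciesRecord] = {}
    populations: list[PopulationRecord] = []
    pop_ids: set[str] = set()
    for raw in rows:
        row = dict(zip(header, raw))
        name = _cell(row, "species")
        group = _cell(row, "group")
        if name not in species:
            species[name] = SpeciesRecord(name, group)
        elif species[name].group_code != group:
            raise PanelValidationError(
                f"species {name!r} listed with conflicting groups"
            )
        pop = _cell(row, "population")
        if pop:
            if pop in pop_ids:
                raise PanelValidationError(f"duplicate population id {pop!r}")
            pop_ids.add(pop)
            populations.append(PopulationRecord(name, pop, _cell(row, "region")))
    return list(species.values()), populations


def parse_primer_table(path: str | Path) -> list[PrimerRecord]:
    header, rows = _split_rows(path)
    primers = []
    for raw in rows:
        row = dict(zip(header, raw))
        core, _, label_from_seq = _strip_linker(_cell(row, "sequence"))
        weight = _cell(row, "molar_ratio_weight")
        primers.append(
            PrimerRecord(
                name=_cell(row, "name"),
                sequence=core.upper(),
                label_5prime=_cell(row, "label") or label_from_seq,
                direction=_cell(row, "direction") or "forward",
                molar_ratio_weight=float(weight) if weight else 1.0,
            )
        )
    return primers


def _data_path(name: str) -> Path:
    return Path(str(resources.files("psocidchip").joinpath("data", name)))


def load_default_panel() -> ProbePanel:
    """Load the packaged ten-species panel (probe, roster and primer tables)."""
    panel = parse_probe_table(_data_path("probes.tsv"))
    species, populations = parse_species_table(_data_path("species.tsv"))
    primers = parse_primer_table(_data_path("primers.tsv"))
    return replace(
        panel,
        species=species,
        populations=populations,
        primers=primers,
        hybridization_temp_C=DEFAULT_HYBRIDIZATION_TEMP_C,
    )


# ---------------------------------------------------------------------------
# Validation report

@dataclass(frozen=True)
class ValidationCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list[ValidationCheck] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[ValidationCheck]:
        return [c for c in self.checks if not c.passed]

    def add(self, name: str, passed: bool, detail: str = "") -> None:
        self.checks.append(ValidationCheck(name, passed, detail))


def validate_panel(panel: ProbePanel) -> ValidationReport:
    """Run consistency checks over a parsed panel.

    Failures land in the report rather than raising, so a panel can be
    audited as a whole: one span-consistency check per species probe,
    role-cardinality checks (exactly one anchor/positive/negative/blank,
    one species probe per listed species), and alphabet checks.
    """
    report = ValidationReport()
    for role in QC_ROLES:
        n = len(panel.probes_by_role(role))
        report.add(
            f"role_cardinality[{role}]", n == 1,
            f"expected exactly 1 {role} probe, found {n}",
        )
    sp_probes = panel.species_probes
    targets = [p.target_species for p in sp_probes]
    report.add(
        "one_probe_per_target_species",
        len(targets) == len(set(targets)),
        "duplicate target species among species probes" if
        len(targets) != len(set(targets)) else "",
    )
    if panel.species:
        roster = {s.species_name for s in panel.species}
        missing = roster - set(targets)
        report.add(
            "probe_for_every_listed_species", not missing,
            f"species without a probe: {sorted(missing)}" if missing else "",
        )
        orphans = {p.species_name for p in panel.populations} - roster
        report.add(
            "populations_reference_roster", not orphans,
            f"populations of unlisted species: {sorted(orphans)}" if orphans else "",
        )
    for p in sp_probes:
        if p.declared_start is None or p.declared_end is None:
            report.add(f"span[{p.code}]", False, "missing coordinates")
            continue
        span = p.declared_end - p.declared_start + 1
        ok = span == len(p.core_sequence) == (p.declared_length or span)
        report.add(
            f"span[{p.code}]", ok,
            f"span {span}, sequence {len(p.core_sequence)} nt, "
            f"declared {p.declared_length}",
        )
    for p in panel.probes:
        report.add(
            f"alphabet[{p.code}]",
            bool(DNA_RE.match(p.core_sequence)),
            "non-ACGT characters" if not DNA_RE.match(p.core_sequence) else "",
        )
    return report
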