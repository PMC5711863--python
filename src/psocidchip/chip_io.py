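"""Chip geometry and the GAL / GPR file dialects.

A chip carries 12 identical probe lattices arranged 6 x 2; each lattice
is an 8 x 10 spot grid hybridized with one sample.  Row 1 and columns
1-2 of every lattice hold directly Cy5-labeled anchor spots (24 per
lattice) used for orientation and for verifying probe-slide coupling;
the 56 interior spots carry 4 replicate spots of each non-anchor probe.
Column pitch is 0.4 mm and row pitch 0.8 mm.

Layouts travel as GAL (GenePix Array List) files and quantified scans as
GPR (GenePix Results) files: tab-delimited bodies under an ATF-style
header.  Both round-trip losslessly.  Coordinates are 1-based (Block,
Row, Column) following the GPR convention; spot flags < 0 mark spots to
exclude from downstream statistics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .panel import ProbePanel, QC_ROLES

__all__ = [
    "ChipLayout",
    "SpotSignal",
    "ChipScan",
    "AtfParseError",
    "build_default_layout",
    "write_gal",
    "read_gal",
    "write_gpr",
    "read_gpr",
    "layout_to_tsv",
    "layout_from_tsv",
]

DEFAULT_LATTICES = 12
DEFAULT_LATTICE_GRID = (6, 2)
DEFAULT_SPOT_GRID = (8, 10)
DEFAULT_COLUMN_PITCH_MM = 0.4
DEFAULT_ROW_PITCH_MM = 0.8
DEFAULT_REPLICATES = 4


class AtfParseError(ValueError):
    """Malformed ATF-style file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass
class ChipLayout:
    """Spot-to-probe map shared by all lattices of a chip."""

    lattices_per_chip: int = DEFAULT_LATTICES
    lattice_grid: tuple[int, int] = DEFAULT_LATTICE_GRID
    spot_grid: tuple[int, int] = DEFAULT_SPOT_GRID
    column_pitch_mm: float = DEFAULT_COLUMN_PITCH_MM
    row_pitch_mm: float = DEFAULT_ROW_PITCH_MM
    spot_map: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rows, cols = self.spot_grid
        for (r, c) in self.spot_map:
            if not (1 <= r <= rows and 1 <= c <= cols):
                raise ValueError(
                    f"spot ({r},{c}) outside the {rows}x{cols} grid")

    def probe_at(self, row: int, col: int) -> str:
        return self.spot_map[(row, col)]

    def spots_of(self, probe_code: str) -> list[tuple[int, int]]:
        return sorted(rc for rc, code in self.spot_map.items()
                      if code == probe_code)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for code in self.spot_map.values():
            out[code] = out.get(code, 0) + 1
        return out

    @property
    def spots_per_lattice(self) -> int:
        return self.spot_grid[0] * self.spot_grid[1]


@dataclass(frozen=True)
class SpotSignal:
    lattice: int
    row: int
    col: int
    probe_code: str
    f635_mean: float
    b635: float
    flag: int = 0

    @property
    def valid(self) -> bool:
        return self.flag >= 0

    @property
    def corrected(self) -> float:
        return self.f635_mean - self.b635


@dataclass
class ChipScan:
    chip_id: str
    sample_ids: dict[int, str] = field(default_factory=dict)
    spots: list[SpotSignal] = field(default_factory=list)
    missing: list[tuple[int, int, int]] = field(default_factory=list)

    def lattices(self) -> list[int]:
        return sorted({s.lattice for s in self.spots})

    def lattice_spots(self, lattice: int) -> list[SpotSignal]:
        return [s for s in self.spots if s.lattice == lattice]

    def probe_spots(self, lattice: int, probe_code: str) -> list[SpotSignal]:
        return [s for s in self.spots
                if s.lattice == lattice and s.probe_code == probe_code]


def build_default_layout(panel: ProbePanel) -> ChipLayout:
    """Deterministic default placement for a 10-species + 4-QC panel.

    Anchors fill row 1 and columns 1-2 of the remaining rows (24 spots).
    The 56 interior spots take 4 consecutive replicates of each non-anchor
    probe in panel order (species probes, then positive, negative, blank)
    walking the grid row-major; the 4 surplus spots fall to blank.
    """
    for role in QC_ROLES:
        if len(panel.probes_by_role(role)) != 1:
            raise ValueError(f"panel needs exactly one {role} probe")
    species = panel.species_probes
    if len(species) != 10:
        raise ValueError(
            f"default layout expects 10 species probes, got {len(species)}")
    anchor = panel.probes_by_role("anchor")[0]
    blank = panel.probes_by_role("blank")[0]
    ordered = species + [panel.probes_by_role(r)[0]
                         for r in ("positive", "negative", "blank")]
    rows, cols = DEFAULT_SPOT_GRID
    spot_map: dict[tuple[int, int], str] = {}
    for c in range(1, cols + 1):
        spot_map[(1, c)] = anchor.code
    for r in range(2, rows + 1):
        spot_map[(r, 1)] = anchor.code
        spot_map[(r, 2)] = anchor.code
    interior = [(r, c) for r in range(2, rows + 1) for c in range(3, cols + 1)]
    codes = [p.code for p in ordered for _ in range(DEFAULT_REPLICATES)]
    codes += [blank.code] * (len(interior) - len(codes))
    for rc, code in zip(interior, codes):
        spot_map[rc] = code
    return ChipLayout(spot_map=spot_map)


# ---------------------------------------------------------------------------
# ATF helpers

def _write_atf(path: str | Path, file_type: str, records: list[str],
               columns: list[str], rows: list[list[str]]) -> None:
    buf = io.StringIO()
    all_records = [f"Type={file_type}"] + records
    buf.write("ATF\t1.0\n")
    buf.write(f"{len(all_records)}\t{len(columns)}\n")
    for rec in all_records:
        buf.write(f'"{rec}"\n')
    buf.write("\t".join(columns) + "\n")
    for row in rows:
        buf.write("\t".join(row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _read_atf(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise AtfParseError("missing 'ATF' magic", line=1)
    if len(lines) < 2:
        raise AtfParseError("truncated file: no record-count line", line=2)
    try:
        n_records = int(lines[1].split("\t")[0])
    except ValueError as exc:
        raise AtfParseError(f"bad record count {lines[1]!r}", line=2) from exc
    header: dict[str, str] = {}
    for i in range(2, 2 + n_records):
        if i >= len(lines):
            raise AtfParseError("fewer header records than declared", line=i + 1)
        rec = lines[i].strip().strip('"')
        if "=" not in rec:
            raise AtfParseError(f"header record without '=': {rec!r}", line=i + 1)
        key, _, value = rec.partition("=")
        header[key] = value
    body = "\n".join(lines[2 + n_records:])
    if not body.strip():
        raise AtfParseError("no data table after header", line=2 + n_records + 1)
    df = pd.read_csv(io.StringIO(body), sep="\t", float_precision="round_trip")
    return header, df


# ---------------------------------------------------------------------------
# GAL

def write_gal(layout: ChipLayout, path: str | Path) -> None:
    records = [
        f"BlockCount={layout.lattices_per_chip}",
        f"BlockGrid={layout.lattice_grid[0]}x{layout.lattice_grid[1]}",
        f"SpotRows={layout.spot_grid[0]}",
        f"SpotCols={layout.spot_grid[1]}",
        f"ColumnPitchMM={layout.column_pitch_mm!r}",
        f"RowPitchMM={layout.row_pitch_mm!r}",
    ]
    rows = []
    for block in range(1, layout.lattices_per_chip + 1):
        for (r, c) in sorted(layout.spot_map):
            code = layout.spot_map[(r, c)]
            rows.append([str(block), str(r), str(c), code, code])
    _write_atf(path, "GenePix ArrayList V1.0", records,
               ["Block", "Row", "Column", "Name", "ID"], rows)


def read_gal(path: str | Path) -> ChipLayout:
    header, df = _read_atf(path)
    for col in ("Block", "Row", "Column", "Name"):
        if col not in df.columns:
            raise AtfParseError(f"GAL missing required column {col!r}")
    n_blocks = int(header.get("BlockCount", df["Block"].nunique()))
    if df["Block"].nunique() != n_blocks:
        raise AtfParseError(
            f"BlockCount={n_blocks} but body has {df['Block'].nunique()} blocks")
    grid = header.get("BlockGrid", "")
    lattice_grid = (
        tuple(int(x) for x in grid.split("x")) if "x" in grid
        else DEFAULT_LATTICE_GRID
    )
    maps: dict[int, dict[tuple[int, int], str]] = {}
    for _, rec in df.iterrows():
        maps.setdefault(int(rec["Block"]), {})[
            (int(rec["Row"]), int(rec["Column"]))] = str(rec["Name"])
    first = maps[min(maps)]
    for block, m in maps.items():
        if m != first:
            raise AtfParseError(
                f"block {block} spot map differs from block {min(maps)}; "
                "all lattices must share one layout")
    spot_rows = int(header.get("SpotRows", max(r for r, _ in first)))
    spot_cols = int(header.get("SpotCols", max(c for _, c in first)))
    return ChipLayout(
        lattices_per_chip=n_blocks,
        lattice_grid=lattice_grid,  # type: ignore[arg-type]
        spot_grid=(spot_rows, spot_cols),
        column_pitch_mm=float(header.get("ColumnPitchMM",
                                         DEFAULT_COLUMN_PITCH_MM)),
        row_pitch_mm=float(header.get("RowPitchMM", DEFAULT_ROW_PITCH_MM)),
        spot_map=first,
    )


# ---------------------------------------------------------------------------
# GPR

def write_gpr(scan: ChipScan, path: str | Path) -> None:
    records = [f"ChipID={scan.chip_id}"]
    for lattice in sorted(scan.sample_ids):
        records.append(f"Sample{lattice}={scan.sample_ids[lattice]}")
    rows = []
    for s in sorted(scan.spots, key=lambda s: (s.lattice, s.row, s.col)):
        rows.append([str(s.lattice), str(s.row), str(s.col), s.probe_code,
                     str(s.flag), repr(float(s.f635_mean)),
                     repr(float(s.b635))])
    _write_atf(path, "GenePix Results 3", records,
               ["Block", "Row", "Column", "Name", "Flags", "F635 Mean", "B635"],
               rows)


def read_gpr(
    path: str | Path,
    layout: ChipLayout,
    background_column: str = "B635",
) -> ChipScan:
    """Parse a quantified scan and join it to a layout.

    Requires columns Block, Row, Column, "F635 Mean" and the configured
    background column ("B635" by default, "B635 Mean" for scanners that
    emit the mean local background).  Every spot must exist in the layout;
    layout spots absent from the file are recorded in ``scan.missing``.
    """
    header, df = _read_atf(path)
    required = ["Block", "Row", "Column", "F635 Mean"]
    for col in required:
        if col not in df.columns:
            raise AtfParseError(f"GPR missing required column {col!r}")
    bg = background_column
    if bg not in df.columns:
        if bg == "B635" and "B635 Mean" in df.columns:
            bg = "B635 Mean"
        else:
            raise AtfParseError(f"GPR missing background column {bg!r}")
    sample_ids = {
        int(k[len("Sample"):]): v for k, v in header.items()
        if k.startswith("Sample") and k[len("Sample"):].isdigit()
    }
    scan = ChipScan(chip_id=header.get("ChipID", Path(path).stem),
                    sample_ids=sample_ids)
    seen: set[tuple[int, int, int]] = set()
    for _, rec in df.iterrows():
        lattice, row, col = int(rec["Block"]), int(rec["Row"]), int(rec["Column"])
        if (row, col) not in layout.spot_map:
            raise AtfParseError(
                f"spot (block {lattice}, row {row}, col {col}) not in layout")
        name = str(rec["Name"]) if "Name" in df.columns else \
            layout.spot_map[(row, col)]
        flag = int(rec["Flags"]) if "Flags" in df.columns else 0
        scan.spots.append(SpotSignal(
            lattice=lattice, row=row, col=col, probe_code=name,
            f635_mean=float(rec["F635 Mean"]), b635=float(rec[bg]), flag=flag))
        seen.add((lattice, row, col))
    for lattice in scan.lattices():
        for (r, c) in layout.spot_map:
            if (lattice, r, c) not in seen:
                scan.missing.append((lattice, r, c))
    return scan


# ---------------------------------------------------------------------------
# Simple TSV layout (for tests and hand-authored fixtures)

def layout_to_tsv(layout: ChipLayout, path: str | Path) -> None:
    lines = ["lattice\trow\tcol\tprobe_code"]
    for block in range(1, layout.lattices_per_chip + 1):
        for (r, c) in sorted(layout.spot_map):
            lines.append(f"{block}\t{r}\t{c}\t{layout.spot_map[(r, c)]}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def layout_from_tsv(path: str | Path, **kwargs) -> ChipLayout:
    df = pd.read_csv(path, sep="\t")
    spot_map = {(int(r.row), int(r.col)): str(r.probe_code)
                for r in df.itertuples() if int(r.lattice) == int(df["lattice"].min())}
    n_blocks = df["lattice"].nunique()
    rows = int(df["row"].max())
    cols = int(df["col"].max())
    return ChipLayout(lattices_per_chip=n_blocks, spot_grid=(rows, cols),
                      spot_map=spot_map, **kwargs)
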