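"""Reading and writing melt-fluorescence datasets in plain-text dialects.

A melt dataset is a shared temperature grid plus one relative-fluorescence
(RFU) series per well.  Two delimited-text dialects are supported:

* ``wide`` — first column ``temperature``, one column per well::

      temperature,A1,A2
      65.0,1000.0,998.2
      65.1,999.1,997.5

* ``long`` — three columns ``sample_id``, ``temperature``, ``rfu``, one row
  per (well, temperature) observation.

The delimiter (comma or tab) is auto-detected from the header line; the
decimal separator is always ``"."``.  Spreadsheet instrument exports are
supported through an "export to delimited text first" contract: any export
whose first sheet matches one of these dialects can be saved as CSV/TSV and
read directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SampleSeries",
    "MeltDataset",
    "MeltParseError",
    "SampleSheetError",
    "read_melt_table",
    "read_sample_sheet",
    "apply_sample_sheet",
    "write_melt_table",
]

ROLES = ("reference", "unknown")

#: Significant digits used when writing numbers; round-trips are exact to
#: this precision.
WRITE_PRECISION = 6


class MeltParseError(ValueError):
    """A melt table violated the dialect contract (bad cell, bad grid...)."""


class SampleSheetError(ValueError):
    """A sample sheet was malformed or inconsistent with its dataset."""


@dataclass
class SampleSeries:
    """One well: its RFU series plus identifying metadata."""

    sample_id: str
    rfu: np.ndarray
    label: str | None = None
    replicate_group: str | None = None
    role: str = "unknown"

    def __post_init__(self) -> None:
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


@dataclass
class MeltDataset:
    """A temperature grid plus per-well RFU series.

    Invariants (checked in ``validate``): temperatures strictly increasing
    with at least 2 points; every series has one finite RFU value per
    temperature; sample ids unique.
    """

    temperatures: np.ndarray
    samples: list[SampleSeries]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.validate()

    def validate(self) -> None:
        t = self.temperatures
        if t.size < 2:
            raise ValueError("a melt dataset needs at least 2 temperature points")
        if not np.all(np.isfinite(t)):
            raise ValueError("temperatures must be finite")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValueError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)
            if s.rfu.shape != t.shape:
                raise ValueError(
                    f"sample {s.sample_id!r} has {s.rfu.size} RFU values for "
                    f"{t.size} temperatures"
                )
            if not np.all(np.isfinite(s.rfu)):
                raise ValueError(f"sample {s.sample_id!r} has non-finite RFU values")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample(self, sample_id: str) -> SampleSeries:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        """Wide-dialect DataFrame: temperature column + one column per well."""
        data = {"temperature": self.temperatures}
        for s in self.samples:
            data[s.sample_id] = s.rfu
        return pd.DataFrame(data)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _parse_float(cell: str, row: int, col: str) -> float:
    try:
        value = float(cell)
    except (TypeError, ValueError):
        raise MeltParseError(
            f"non-numeric cell {cell!r} at data row {row}, column {col!r}"
        ) from None
    if not math.isfinite(value):
        raise MeltParseError(f"non-finite value at data row {row}, column {col!r}")
    return value


def read_melt_table(path: str | Path, dialect: str = "wide") -> MeltDataset:
    """Read a delimited melt table into a :class:`MeltDataset`.

    ``dialect`` is ``"wide"`` or ``"long"`` (see module docstring).  Column
    order in the file is preserved as sample order.  Duplicate or
    non-increasing temperature rows raise :class:`MeltParseError` naming the
    offending row rather than being silently fixed.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [
        ln for ln in text.splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise MeltParseError(f"{path}: empty file")
    sep = _sniff_delimiter(lines[0])
    header = [h.strip() for h in lines[0].split(sep)]

    if dialect == "wide":
        return _read_wide(path, lines, sep, header)
    if dialect == "long":
        return _read_long(path, lines, sep, header)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")


def _read_wide(path: Path, lines: list[str], sep: str, header: list[str]) -> MeltDataset:
    if len(header) < 2:
        raise MeltParseError(f"{path}: wide table needs a temperature column and at least one well")
    well_ids = header[1:]
    temps: list[float] = []
    columns: list[list[float]] = [[] for _ in well_ids]
    for i, line in enumerate(lines[1:], start=1):
        cells = [c.strip() for c in line.split(sep)]
        if len(cells) != len(header):
            raise MeltParseError(
                f"{path}: data row {i} has {len(cells)} cells, expected {len(header)}"
            )
        temps.append(_parse_float(cells[0], i, header[0]))
        for series, cell, col in zip(columns, cells[1:], well_ids):
            series.append(_parse_float(cell, i, col))
    _check_grid(path, temps)
    samples = [SampleSeries(sample_id=w, rfu=np.array(col)) for w, col in zip(well_ids, columns)]
    return MeltDataset(np.array(temps), samples, meta={"source": str(path), "dialect": "wide"})


def _read_long(path: Path, lines: list[str], sep: str, header: list[str]) -> MeltDataset:
    required = ["sample_id", "temperature", "rfu"]
    if [h.lower() for h in header[:3]] != required:
        raise MeltParseError(f"{path}: long table header must be {required}, got {header}")
    per_sample: dict[str, list[tuple[float, float]]] = {}
    for i, line in enumerate(lines[1:], start=1):
        cells = [c.strip() for c in line.split(sep)]
        if len(cells) != 3:
            raise MeltParseError(f"{path}: data row {i} has {len(cells)} cells, expected 3")
        sid = cells[0]
        t = _parse_float(cells[1], i, "temperature")
        r = _parse_float(cells[2], i, "rfu")
        per_sample.setdefault(sid, []).append((t, r))
    if not per_sample:
        raise MeltParseError(f"{path}: long table has no data rows")
    first_sid = next(iter(per_sample))
    temps = [t for t, _ in per_sample[first_sid]]
    _check_grid(path, temps)
    grid = np.array(temps)
    samples = []
    for sid, pairs in per_sample.items():
        t_s = np.array([t for t, _ in pairs])
        if t_s.shape != grid.shape or not np.allclose(t_s, grid):
            raise MeltParseError(
                f"{path}: sample {sid!r} temperature grid differs from sample {first_sid!r}"
            )
        samples.append(SampleSeries(sample_id=sid, rfu=np.array([r for _, r in pairs])))
    return MeltDataset(grid, samples, meta={"source": str(path), "dialect": "long"})


def _check_grid(path: Path, temps: list[float]) -> None:
    if len(temps) < 2:
        raise MeltParseError(f"{path}: fewer than 2 temperature rows")
    for i in range(1, len(temps)):
        if temps[i] == temps[i - 1]:
            raise MeltParseError(f"{path}: duplicate temperature {temps[i]} at data row {i + 1}")
        if temps[i] < temps[i - 1]:
            raise MeltParseError(
                f"{path}: temperature decreases at data row {i + 1} ({temps[i]} after {temps[i - 1]})"
            )


def read_sample_sheet(path: str | Path) -> dict[str, dict]:
    """Read a sample sheet mapping sample_id -> metadata.

    Required columns: ``sample_id``, ``label``, ``replicate_group``, ``role``
    (role one of ``reference``/``unknown``).  Returns a dict keyed by
    sample_id; apply it to a dataset with :func:`apply_sample_sheet`.
    """
    path = Path(path)
    first = path.read_text(encoding="utf-8").splitlines()
    if not first:
        raise SampleSheetError(f"{path}: empty file")
    sep = _sniff_delimiter(first[0])
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"sample_id", "label", "replicate_group", "role"}
    missing = required - set(df.columns)
    if missing:
        raise SampleSheetError(f"{path}: missing required column(s) {sorted(missing)}")
    updates: dict[str, dict] = {}
    for i, row in df.iterrows():
        role = row["role"]
        if role not in ROLES:
            raise SampleSheetError(
                f"{path}: row {i + 1}: role {role!r} not in {ROLES}"
            )
        sid = row["sample_id"]
        if sid in updates:
            raise SampleSheetError(f"{path}: duplicate sample_id {sid!r}")
        updates[sid] = {
            "label": row["label"] or None,
            "replicate_group": row["replicate_group"] or None,
            "role": role,
        }
    return updates


def apply_sample_sheet(dataset: MeltDataset, updates: Mapping[str, dict]) -> MeltDataset:
    """Attach sample-sheet metadata to a dataset, in place.

    Fails loudly on sheet entries whose sample_id is not in the dataset.
    """
    known = set(dataset.sample_ids)
    orphans = sorted(set(updates) - known)
    if orphans:
        raise SampleSheetError(f"sample sheet ids not present in dataset: {orphans}")
    for s in dataset.samples:
        if s.sample_id in updates:
            u = updates[s.sample_id]
            s.label = u["label"]
            s.replicate_group = u["replicate_group"]
            s.role = u["role"]
    return dataset


def write_melt_table(dataset: MeltDataset, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Write a dataset (or derived curve set) in the canonical wide dialect.

    Numbers are written with ``WRITE_PRECISION`` significant digits, so a
    read-back dataset equals the original to that precision.  ``header_lines``
    are emitted as ``#``-prefixed comment lines recording parameters.
    Refuses to write a dataset with no samples.
    """
    if not dataset.samples:
        raise ValueError("refusing to write a dataset with no samples")
    path = Path(path)
    fmt = f"{{:.{WRITE_PRECISION}g}}"
    with path.open("w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(",".join(["temperature"] + dataset.sample_ids) + "\n")
        for i, t in enumerate(dataset.temperatures):
            cells = [fmt.format(t)] + [fmt.format(s.rfu[i]) for s in dataset.samples]
            fh.write(",".join(cells) + "\n")


def write_sample_sheet(dataset: MeltDataset, path: str | Path) -> None:
    """Write the dataset's metadata as a sample sheet (CSV)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("sample_id,label,replicate_group,role\n")
        for s in dataset.samples:
            fh.write(f"{s.sample_id},{s.label or ''},{s.replicate_group or ''},{s.role}\n")
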