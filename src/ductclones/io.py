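"""Domain types and file I/O for confetti clone tables, ductal trees and 1D point patterns.

A *clone* is a cohesive patch of cells sharing one stochastically recombined
confetti fluorophore; its size is the number of labelled cells counted in the
patch. Tables are tidy: one row per clone, with stratification keys (mouse,
gland, genotype, lineage, days post-induction, duct location, branch level).

Clone tables are TSV (default) or CSV, UTF-8, header mandatory, with columns
named exactly after the :class:`CloneRecord` fields. Ductal trees are TSV edge
lists ``segment_id, parent_id, n_cell_slots`` (empty ``parent_id`` marks the
root). Point patterns are positions in micrometres along a duct of known length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import CloneTableFormatError, TreeStructureError

GENOTYPES = ("WT", "BRCA1_TRP53")
LINEAGES = ("luminal", "basal")
LOCATIONS = ("main_duct", "side_branch", "unknown")
COLORS = ("GFP", "YFP", "RFP", "CFP")

#: Canonical column order of a clone-table file (deterministic on write).
CLONE_COLUMNS = (
    "mouse_id",
    "gland_id",
    "genotype",
    "lineage",
    "time_days",
    "size_cells",
    "location",
    "branch_level",
    "transformed",
    "color",
)

_MANDATORY_COLUMNS = (
    "mouse_id",
    "gland_id",
    "genotype",
    "lineage",
    "time_days",
    "size_cells",
)


@dataclass(frozen=True)
class CloneRecord:
    """One confetti clone: a cohesive single-colour patch of labelled cells."""

    mouse_id: str
    gland_id: str
    genotype: str
    lineage: str
    time_days: int
    size_cells: int
    location: str = "unknown"
    branch_level: Optional[int] = None
    transformed: bool = False
    color: Optional[str] = None

    def validate(self) -> list[str]:
        """Return all invariant violations of this record (empty when valid)."""
        problems = []
        if self.genotype not in GENOTYPES:
            problems.append(f"genotype {self.genotype!r} not in {GENOTYPES}")
        if self.lineage not in LINEAGES:
            problems.append(f"lineage {self.lineage!r} not in {LINEAGES}")
        if self.location not in LOCATIONS:
            problems.append(f"location {self.location!r} not in {LOCATIONS}")
        if self.color is not None and self.color not in COLORS:
            problems.append(f"color {self.color!r} not in {COLORS}")
        if self.size_cells < 1:
            problems.append(f"size_cells must be >= 1, got {self.size_cells}")
        if self.time_days < 0:
            problems.append(f"time_days must be >= 0, got {self.time_days}")
        if self.branch_level is not None and self.branch_level < 0:
            problems.append(f"branch_level must be missing or >= 0, got {self.branch_level}")
        return problems


@dataclass
class CloneTable:
    """Ordered collection of :class:`CloneRecord` with free-text provenance."""

    records: list[CloneRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CloneRecord]:
        return iter(self.records)

    def validate(self) -> None:
        """Raise :class:`CloneTableFormatError` listing every invalid record."""
        errors = []
        for i, rec in enumerate(self.records):
            for msg in rec.validate():
                errors.append((i, msg))
        if errors:
            raise CloneTableFormatError(
                f"{len(errors)} invalid record(s)", row_errors=errors
            )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [[getattr(r, c) for c in CLONE_COLUMNS] for r in self.records],
            columns=list(CLONE_COLUMNS),
        )
        if df.empty:
            df = pd.DataFrame(columns=list(CLONE_COLUMNS))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "CloneTable":
        records = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            records.append(
                CloneRecord(
                    mouse_id=str(d["mouse_id"]),
                    gland_id=str(d["gland_id"]),
                    genotype=str(d["genotype"]),
                    lineage=str(d["lineage"]),
                    time_days=int(d["time_days"]),
                    size_cells=int(d["size_cells"]),
                    location=str(d.get("location", "unknown")),
                    branch_level=(
                        None
                        if d.get("branch_level") is None or _is_missing(d.get("branch_level"))
                        else int(d["branch_level"])
                    ),
                    transformed=bool(d.get("transformed", False)),
                    color=(None if _is_missing(d.get("color")) else str(d["color"])),
                )
            )
        table = cls(records=records, provenance=provenance)
        table.validate()
        return table

    def subset(self, **criteria) -> "CloneTable":
        """Records matching all ``field=value`` criteria, order preserved."""
        recs = [
            r
            for r in self.records
            if all(getattr(r, k) == v for k, v in criteria.items())
        ]
        return CloneTable(records=recs, provenance=self.provenance)

    def sizes(self) -> np.ndarray:
        return np.array([r.size_cells for r in self.records], dtype=np.int64)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", ""):
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def read_clone_table(path, dialect: str = "tsv") -> CloneTable:
    """Read and validate a clone table.

    Unknown columns are preserved in the provenance string; row order is kept.
    All malformed rows are reported together (line numbers refer to the file,
    header = line 1).
    """
    sep = _sep(dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CloneTableFormatError(
            f"missing mandatory column(s): {', '.join(missing)}"
        )
    extra = [c for c in df.columns if c not in CLONE_COLUMNS]

    records: list[CloneRecord] = []
    row_errors: list[tuple[int, str]] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header occupies line 1
        d = dict(zip(df.columns, row))
        try:
            rec = CloneRecord(
                mouse_id=d["mouse_id"],
                gland_id=d["gland_id"],
                genotype=d["genotype"],
                lineage=d["lineage"],
                time_days=int(d["time_days"]),
                size_cells=int(d["size_cells"]),
                location=d.get("location") or "unknown",
                branch_level=(
                    None if _is_missing(d.get("branch_level")) else int(d["branch_level"])
                ),
                transformed=_parse_bool(d.get("transformed", "false")),
                color=(None if _is_missing(d.get("color")) else d["color"]),
            )
        except (ValueError, KeyError) as exc:
            row_errors.append((line, f"unparseable row: {exc}"))
            continue
        problems = rec.validate()
        if problems:
            row_errors.extend((line, p) for p in problems)
        else:
            records.append(rec)
    if row_errors:
        raise CloneTableFormatError(
            f"{len(row_errors)} invalid row(s) in {path}", row_errors=row_errors
        )
    provenance = f"read from {path}"
    if extra:
        provenance += f"; extra columns: {', '.join(extra)}"
    return CloneTable(records=records, provenance=provenance)


def write_clone_table(table: CloneTable, path, dialect: str = "tsv") -> None:
    """Write a clone table with deterministic column order and '.' decimals.

    The output is bit-stable for a fixed table and round-trips through
    :func:`read_clone_table` field-for-field.
    """
    table.validate()
    sep = _sep(dialect)
    rows = []
    for r in table.records:
        rows.append(
            [
                r.mouse_id,
                r.gland_id,
                r.genotype,
                r.lineage,
                str(r.time_days),
                str(r.size_cells),
                r.location,
                "" if r.branch_level is None else str(r.branch_level),
                "true" if r.transformed else "false",
                "" if r.color is None else r.color,
            ]
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(sep.join(CLONE_COLUMNS) + "\n")
        for row in rows:
            fh.write(sep.join(row) + "\n")


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")


# ---------------------------------------------------------------------------
# Ductal trees
# ---------------------------------------------------------------------------


@dataclass
class DuctalTree:
    """Ductal network topology as parent-linked segments.

    ``segments`` maps ``segment_id -> (parent_id or None, n_cell_slots)``.
    Exactly one segment (the main duct) has no parent.
    """

    segments: dict[str, tuple[Optional[str], int]]

    def __post_init__(self):
        self._validate()
        self._children: dict[str, list[str]] = {sid: [] for sid in self.segments}
        for sid, (parent, _) in self.segments.items():
            if parent is not None:
                self._children[parent].append(sid)

    @property
    def root(self) -> str:
        return self._root

    def children(self, segment_id: str) -> list[str]:
        return self._children[segment_id]

    def n_cell_slots(self, segment_id: str) -> int:
        return self.segments[segment_id][1]

    def _validate(self) -> None:
        roots = [sid for sid, (parent, _) in self.segments.items() if parent is None]
        if len(roots) != 1:
            raise TreeStructureError(
                f"tree must have exactly one root, found {len(roots)}"
            )
        self._root = roots[0]
        for sid, (parent, slots) in self.segments.items():
            if parent is not None and parent not in self.segments:
                raise TreeStructureError(f"segment {sid!r} has unknown parent {parent!r}")
            if slots < 1:
                raise TreeStructureError(f"segment {sid!r} has n_cell_slots < 1")
        # acyclicity + reachability: every segment must reach the root
        for sid in self.segments:
            seen = set()
            cur: Optional[str] = sid
            while cur is not None:
                if cur in seen:
                    raise TreeStructureError(f"cycle detected through segment {cur!r}")
                seen.add(cur)
                cur = self.segments[cur][0]
            if self._root not in seen:
                raise TreeStructureError(f"segment {sid!r} not reachable from root")

    def path_to_root(self, segment_id: str) -> list[str]:
        if segment_id not in self.segments:
            raise KeyError(f"unknown segment {segment_id!r}")
        path = [segment_id]
        cur = self.segments[segment_id][0]
        while cur is not None:
            path.append(cur)
            cur = self.segments[cur][0]
        return path


def read_ductal_tree(path) -> DuctalTree:
    """Read a TSV edge list (segment_id, parent_id, n_cell_slots)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("segment_id", "parent_id", "n_cell_slots"):
        if col not in df.columns:
            raise TreeStructureError(f"missing column {col!r} in {path}")
    segments: dict[str, tuple[Optional[str], int]] = {}
    for row in df.itertuples(index=False):
        sid = row.segment_id
        if sid in segments:
            raise TreeStructureError(f"duplicate segment id {sid!r}")
        parent = None if row.parent_id.strip() == "" else row.parent_id
        segments[sid] = (parent, int(row.n_cell_slots))
    return DuctalTree(segments=segments)


def write_ductal_tree(tree: DuctalTree, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("segment_id\tparent_id\tn_cell_slots\n")
        for sid, (parent, slots) in tree.segments.items():
            fh.write(f"{sid}\t{'' if parent is None else parent}\t{slots}\n")


def branch_level(tree: DuctalTree, segment_id: str) -> int:
    """Number of branch points separating a segment from the main duct.

    Counts ancestors (the root included) that bifurcate, i.e. have two or more
    children; unbranched elongations do not increment the level. The root
    segment is level 0.
    """
    path = tree.path_to_root(segment_id)
    return sum(1 for ancestor in path[1:] if len(tree.children(ancestor)) >= 2)


def to_newick(tree: DuctalTree) -> str:
    """Export the tree topology as a Newick string with segment-id labels."""

    def fmt(sid: str) -> str:
        kids = tree.children(sid)
        if not kids:
            return sid
        return "(" + ",".join(fmt(k) for k in sorted(kids)) + ")" + sid

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# 1D point patterns
# ---------------------------------------------------------------------------


@dataclass
class PointPattern1D:
    """Positions (µm) of marked cells along a duct of length ``domain_length``."""

    positions: np.ndarray
    domain_length: float

    def __post_init__(self):
        self.positions = np.sort(np.asarray(self.positions, dtype=float))
        if self.domain_length <= 0:
            raise ValueError("domain_length must be > 0")
        if self.positions.size and (
            self.positions[0] < 0 or self.positions[-1] > self.domain_length
        ):
            raise ValueError("positions must lie within [0, domain_length]")

    @property
    def n_points(self) -> int:
        return int(self.positions.size)


def read_point_pattern(path) -> PointPattern1D:
    """Read a point pattern TSV with columns ``position_um`` and ``domain_length_um``."""
    df = pd.read_csv(path, sep="\t")
    if "domain_length_um" not in df.columns or "position_um" not in df.columns:
        raise ValueError(f"expected columns position_um, domain_length_um in {path}")
    domain = float(df["domain_length_um"].iloc[0]) if len(df) else 0.0
    if len(df) == 0:
        raise ValueError("cannot infer domain length from an empty pattern file")
    positions = df["position_um"].to_numpy(dtype=float)
    positions = positions[~np.isnan(positions)]
    return PointPattern1D(positions=positions, domain_length=domain)


def write_point_pattern(pattern: PointPattern1D, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("position_um\tdomain_length_um\n")
        if pattern.n_points == 0:
            fh.write(f"\t{pattern.domain_length:.6f}\n")
        for x in pattern.positions:
            fh.write(f"{x:.6f}\t{pattern.domain_length:.6f}\n")
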