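"""Data model and I/O for DNA nanostructure designs.

A :class:`Design` holds the strands of a DNA brick canvas, a brick shape, or a
DNA origami structure, together with square-lattice geometry.  Each
:class:`Strand` carries its sequence (5'→3'), a role, the lattice segments it
occupies, and the shapes it belongs to.  Two loaders are provided: a simple
tabular (TSV) design format, and a subset of the caDNAno v2 JSON format for
square-lattice origami designs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ROLES = frozenset(
    {"brick", "half_brick", "edge_protector", "staple", "scaffold"}
)
#: roles excluded from incorporation statistics (rendered grey)
EXCLUDED_ROLES = frozenset({"half_brick", "edge_protector", "scaffold"})

_DNA = frozenset("ACGT")

DESIGN_COLUMNS = [
    "strand_id",
    "sequence",
    "role",
    "helix_row",
    "helix_col",
    "base_start",
    "base_end",
    "shapes",
]


class DesignError(ValueError):
    """Raised for malformed or inconsistent design inputs."""


@dataclass(frozen=True)
class Segment:
    """A contiguous run of bases on one helix, half-open [base_start, base_end)."""

    helix_row: int
    helix_col: int
    base_start: int
    base_end: int

    def __post_init__(self) -> None:
        if self.base_start >= self.base_end:
            raise DesignError(
                f"segment base_start must be < base_end, got "
                f"[{self.base_start}, {self.base_end})"
            )

    @property
    def length(self) -> int:
        return self.base_end - self.base_start


@dataclass
class Strand:
    """One oligonucleotide of a design: a DNA brick, staple, or scaffold."""

    strand_id: str
    sequence: str
    role: str = "brick"
    segments: tuple[Segment, ...] = ()
    shapes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.role not in VALID_ROLES:
            raise DesignError(
                f"strand {self.strand_id!r}: unknown role {self.role!r} "
                f"(valid: {sorted(VALID_ROLES)})"
            )
        bad = set(self.sequence) - _DNA
        if bad:
            raise DesignError(
                f"strand {self.strand_id!r}: non-ACGT characters {sorted(bad)} "
                "in sequence"
            )
        if self.role != "scaffold" and len(self.sequence) < 20:
            raise DesignError(
                f"strand {self.strand_id!r}: sequence length {len(self.sequence)} "
                "< 20; prefix-based read assignment needs a 20-nt prefix"
            )
        self.segments = tuple(self.segments)
        self.shapes = frozenset(self.shapes)

    def prefix(self, k: int = 20) -> str:
        return self.sequence[:k]

    @property
    def gc_fraction(self) -> float:
        if not self.sequence:
            return float("nan")
        gc = sum(1 for b in self.sequence if b in "GC")
        return gc / len(self.sequence)


@dataclass(frozen=True)
class Geometry:
    """Square-lattice geometry constants (nm)."""

    inter_helix_nm: float = 2.0
    bp_per_turn: float = 10.67
    axial_rise_nm: float = 0.34

    def __post_init__(self) -> None:
        if min(self.inter_helix_nm, self.bp_per_turn, self.axial_rise_nm) <= 0:
            raise DesignError("geometry constants must be positive")


@dataclass
class Design:
    """A named collection of strands on a square lattice."""

    name: str
    strands: dict[str, Strand] = field(default_factory=dict)
    lattice: str = "square"
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        if self.lattice != "square":
            raise DesignError(f"unsupported lattice {self.lattice!r}")
        if not isinstance(self.strands, dict):
            strands = {}
            for s in self.strands:
                if s.strand_id in strands:
                    raise DesignError(f"duplicate strand_id {s.strand_id!r}")
                strands[s.strand_id] = s
            self.strands = strands

    def __len__(self) -> int:
        return len(self.strands)

    def __iter__(self):
        return iter(self.strands.values())

    def __contains__(self, strand_id: str) -> bool:
        return strand_id in self.strands

    def __getitem__(self, strand_id: str) -> Strand:
        return self.strands[strand_id]

    @property
    def shape_registry(self) -> frozenset[str]:
        """All shape identifiers referenced by any strand."""
        shapes: set[str] = set()
        for s in self:
            shapes |= s.shapes
        return frozenset(shapes)

    def countable_strands(self) -> list[Strand]:
        """Strands that participate in read counting (scaffold excluded)."""
        return [s for s in self if s.role != "scaffold"]


# ---------------------------------------------------------------------------
# Tabular design format
# ---------------------------------------------------------------------------

def load_design_table(path, name: str | None = None) -> Design:
    """Load a design from the tabular (TSV) strand format.

    The file is tab-separated with header columns ``strand_id``, ``sequence``,
    ``role``, ``helix_row``, ``helix_col``, ``base_start``, ``base_end``,
    ``shapes`` (semicolon-separated shape ids; may be empty).  A strand with
    several lattice segments repeats its id on multiple rows; the rows must
    agree on sequence, role and shapes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise DesignError(f"design table {path}: missing columns {missing}")

    strands: dict[str, Strand] = {}
    seen_segments: set[tuple] = set()
    for strand_id, grp in df.groupby("strand_id", sort=False):
        seqs = set(grp["sequence"].str.upper())
        if len(seqs) > 1:
            raise DesignError(
                f"strand {strand_id!r}: conflicting sequences across rows"
            )
        roles = set(grp["role"])
        if len(roles) > 1:
            raise DesignError(f"strand {strand_id!r}: conflicting roles")
        shape_sets = set(grp["shapes"])
        if len(shape_sets) > 1:
            raise DesignError(f"strand {strand_id!r}: conflicting shape lists")
        shapes = frozenset(s for s in next(iter(shape_sets)).split(";") if s)

        segments = []
        for _, row in grp.iterrows():
            seg = Segment(
                int(row["helix_row"]),
                int(row["helix_col"]),
                int(row["base_start"]),
                int(row["base_end"]),
            )
            key = (strand_id, seg.helix_row, seg.helix_col, seg.base_start, seg.base_end)
            if key in seen_segments:
                raise DesignError(
                    f"duplicate (strand_id, segment) row for {strand_id!r}: {seg}"
                )
            seen_segments.add(key)
            segments.append(seg)

        strands[strand_id] = Strand(
            strand_id=strand_id,
            sequence=next(iter(seqs)),
            role=next(iter(roles)),
            segments=tuple(segments),
            shapes=shapes,
        )

    if name is None:
        name = str(path)
    return Design(name=name, strands=strands)


def write_design_table(design: Design, path) -> None:
    """Serialize a design to the tabular format (inverse of load_design_table)."""
    rows = []
    for s in design:
        shapes = ";".join(sorted(s.shapes))
        for seg in s.segments:
            rows.append(
                (s.strand_id, s.sequence, s.role, seg.helix_row, seg.helix_col,
                 seg.base_start, seg.base_end, shapes)
            )
    pd.DataFrame(rows, columns=DESIGN_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# caDNAno v2 (square lattice subset)
# ---------------------------------------------------------------------------

def load_cadnano(path, sequence_map: dict[str, str] | None = None,
                 name: str | None = None) -> Design:
    """Load staple paths from a caDNAno v2 square-lattice JSON file.

    caDNAno files store, per helix (``vstrands`` entry), per base position, the
    5' and 3' neighbours of the scaffold and staple strands as
    ``[helix_num, base]`` pairs (``[-1, -1]`` marks an end).  Each staple path
    is recovered by walking 5'→3' from its 5' end; maximal same-helix runs
    become :class:`Segment` s.  Sequences are supplied through
    ``sequence_map`` (staple id → sequence) because caDNAno files usually omit
    them; staples absent from the map get a placeholder poly-A sequence of the
    path length.

    Staple ids are ``st_{helix}_{base}`` from the 5'-end position.  The
    scaffold, if present, is recorded as a single role="scaffold" strand
    without segments.  Insertion/deletion (loop/skip) annotations are ignored
    with a warning.
    """
    with open(path) as fh:
        doc = json.load(fh)
    vstrands = doc.get("vstrands")
    if not vstrands:
        raise DesignError(f"{path}: no vstrands; not a caDNAno v2 file")

    by_num: dict[int, dict] = {}
    for vs in vstrands:
        by_num[vs["num"]] = vs
        # Square-lattice caDNAno files have an even number of base columns
        # divisible by 32/21 distinction; honeycomb uses 21-multiples with
        # col/row parity constraints.  The robust discriminator is the length
        # of the per-base arrays: honeycomb files are multiples of 21 and not
        # of 32.
        n = len(vs["stap"])
        if n % 21 == 0 and n % 32 != 0:
            raise DesignError(
                f"{path}: helix {vs['num']} has {n} positions (multiple of 21): "
                "honeycomb-lattice files are not supported"
            )
        if any(vs.get("loop", [])) or any(vs.get("skip", [])):
            logger.warning(
                "%s: helix %d has loop/skip annotations; ignored", path, vs["num"]
            )

    sequence_map = sequence_map or {}

    # 5' staple ends: positions whose 5' neighbour is [-1,-1] but 3' is not.
    strands: dict[str, Strand] = {}
    visited: set[tuple[int, int]] = set()
    for num, vs in by_num.items():
        for base, entry in enumerate(vs["stap"]):
            p5h, p5b, p3h, p3b = entry
            if (p5h, p5b) != (-1, -1) or (p3h, p3b) == (-1, -1):
                continue
            path_cells = _walk(by_num, num, base, kind="stap")
            for cell in path_cells:
                if cell in visited:
                    raise DesignError(f"{path}: staple paths overlap at {cell}")
                visited.add(cell)
            sid = f"st_{num}_{base}"
            seq = sequence_map.get(sid, "A" * len(path_cells))
            strands[sid] = Strand(
                strand_id=sid,
                sequence=seq,
                role="staple",
                segments=_segments_from_path(by_num, path_cells),
            )

    # Scaffold: record presence as a single strand, no geometry needed.
    has_scaffold = any(
        entry != [-1, -1, -1, -1] for vs in by_num.values() for entry in vs["scaf"]
    )
    if has_scaffold:
        seq = sequence_map.get("scaffold", "")
        strands["scaffold"] = Strand(
            strand_id="scaffold", sequence=seq, role="scaffold"
        )

    if name is None:
        name = str(path)
    return Design(name=name, strands=strands)


def _walk(by_num: dict[int, dict], helix: int, base: int, kind: str
          ) -> list[tuple[int, int]]:
    """Walk a strand path 5'→3' through the per-base neighbour arrays."""
    cells = []
    seen = set()
    cur = (helix, base)
    while cur != (-1, -1):
        if cur in seen:
            raise DesignError(f"strand path contains a cycle at {cur}")
        seen.add(cur)
        cells.append(cur)
        entry = by_num[cur[0]][kind][cur[1]]
        cur = (entry[2], entry[3])
    return cells


def _segments_from_path(by_num: dict[int, dict], cells: list[tuple[int, int]]
                        ) -> tuple[Segment, ...]:
    """Collapse a 5'→3' cell path into maximal same-helix segments."""
    segments = []
    run = [cells[0]]
    for cell in cells[1:]:
        if cell[0] == run[-1][0] and abs(cell[1] - run[-1][1]) == 1:
            run.append(cell)
        else:
            segments.append(_run_to_segment(by_num, run))
            run = [cell]
    segments.append(_run_to_segment(by_num, run))
    return tuple(segments)


def _run_to_segment(by_num: dict[int, dict], run: list[tuple[int, int]]) -> Segment:
    helix = run[0][0]
    vs = by_num[helix]
    bases = [b for _, b in run]
    return Segment(
        helix_row=vs["row"],
        helix_col=vs["col"],
        base_start=min(bases),
        base_end=max(bases) + 1,
    )


# ---------------------------------------------------------------------------
# Validation and subsetting
# ---------------------------------------------------------------------------

def validate_prefix_uniqueness(design: Design, k: int = 20
                               ) -> list[tuple[str, str]]:
    """Report pairs of countable strands sharing the same k-nt 5' prefix.

    Returns a lexicographically ordered list of (strand_id, strand_id) pairs;
    an empty list means every k-prefix is unique, so prefix-anchored read
    assignment is unambiguous.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_prefix: dict[str, list[str]] = {}
    for s in design.countable_strands():
        by_prefix.setdefault(s.prefix(k), []).append(s.strand_id)
    pairs = []
    for ids in by_prefix.values():
        if len(ids) > 1:
            ids = sorted(ids)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    pairs.append((ids[i], ids[j]))
    return sorted(pairs)


def subset_shape(design: Design, shape_id: str) -> Design:
    """Return the sub-design of strands belonging to ``shape_id``."""
    known = design.shape_registry
    if shape_id not in known:
        raise DesignError(
            f"unknown shape {shape_id!r}; known shapes: {sorted(known)}"
        )
    strands = {s.strand_id: s for s in design if shape_id in s.shapes}
    return Design(
        name=f"{design.name}:{shape_id}",
        strands=strands,
        lattice=design.lattice,
        geometry=design.geometry,
    )
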