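"""FASTQ demultiplexing and prefix-anchored read-to-strand assignment.

Sequencing libraries are prepared by ligating adaptors onto each brick or
staple; the insert therefore begins with 4–7 random nucleotides (added for
cluster diversity) followed by the 5' end of the strand itself.  A read is
assigned to a strand by an exact, case-insensitive match of a 20-nt strand
prefix at read offsets 4, 5, 6 or 7, smallest offset winning.  Reads whose
20-mer matches more than one strand are tallied as ambiguous; reads matching
no strand are tallied as unassigned.  Read conservation holds at every stage.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import Design

logger = logging.getLogger(__name__)

PREFIX_LEN = 20
#: allowed lengths of the random 5' leader, scanned in increasing order
LEADER_OFFSETS = (4, 5, 6, 7)
MIN_READ_LEN = LEADER_OFFSETS[0] + PREFIX_LEN  # 24 nt

UNASSIGNED = "__unassigned__"
AMBIGUOUS = "__ambiguous__"
UNDETERMINED = "__undetermined__"

VALID_BANDS = frozenset({"product", "monomer", "canvas_input"})


class MatchingError(ValueError):
    pass


@dataclass(frozen=True)
class SampleSheetEntry:
    """One sequenced sample: a gel band of one structure design."""

    sample_id: str
    band: str
    index_barcode: str
    design_ref: str
    shape_id: str | None = None
    replicate: str | None = None

    def __post_init__(self) -> None:
        if self.band not in VALID_BANDS:
            raise MatchingError(
                f"sample {self.sample_id!r}: band {self.band!r} not in "
                f"{sorted(VALID_BANDS)}"
            )


def load_sample_sheet(path) -> list[SampleSheetEntry]:
    """Read the sample sheet TSV (sample_id, band, index_barcode, design_ref,
    shape_id, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = []
    for _, row in df.iterrows():
        entries.append(
            SampleSheetEntry(
                sample_id=row["sample_id"],
                band=row["band"],
                index_barcode=row["index_barcode"].upper(),
                design_ref=row["design_ref"],
                shape_id=row.get("shape_id") or None,
                replicate=row.get("replicate") or None,
            )
        )
    _check_sheet(entries)
    return entries


def write_sample_sheet(entries: Iterable[SampleSheetEntry], path) -> None:
    rows = [
        (e.sample_id, e.band, e.index_barcode, e.design_ref,
         e.shape_id or "", e.replicate or "")
        for e in entries
    ]
    pd.DataFrame(
        rows,
        columns=["sample_id", "band", "index_barcode", "design_ref",
                 "shape_id", "replicate"],
    ).to_csv(path, sep="\t", index=False)


def _check_sheet(entries: list[SampleSheetEntry]) -> None:
    barcodes = [e.index_barcode for e in entries]
    if len(set(barcodes)) != len(barcodes):
        dupes = sorted({b for b in barcodes if barcodes.count(b) > 1})
        raise MatchingError(f"duplicate index barcodes in sample sheet: {dupes}")
    if len({len(b) for b in barcodes}) > 1:
        raise MatchingError("sample-sheet index barcodes differ in length")


@dataclass
class CountTable:
    """Per-sample assigned read counts with unassigned/ambiguous tallies."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    n_unassigned: int = 0
    n_ambiguous: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def n_total(self) -> int:
        return self.n_assigned + self.n_unassigned + self.n_ambiguous

    def validate(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise MatchingError(f"sample {self.sample_id!r}: negative count")
        if self.n_unassigned < 0 or self.n_ambiguous < 0:
            raise MatchingError(f"sample {self.sample_id!r}: negative tally")

    def write(self, path) -> None:
        rows = sorted(self.counts.items())
        pd.DataFrame(rows, columns=["strand_id", "count"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read(cls, path, sample_id: str, n_unassigned: int = 0,
             n_ambiguous: int = 0) -> "CountTable":
        df = pd.read_csv(path, sep="\t", dtype={"strand_id": str, "count": int})
        return cls(
            sample_id=sample_id,
            counts=dict(zip(df["strand_id"], df["count"])),
            n_unassigned=n_unassigned,
            n_ambiguous=n_ambiguous,
        )


def write_count_summary(tables: Iterable[CountTable], path) -> None:
    rows = [
        (t.sample_id, t.n_total, t.n_assigned, t.n_unassigned, t.n_ambiguous)
        for t in tables
    ]
    pd.DataFrame(
        rows,
        columns=["sample_id", "n_total", "n_assigned", "n_unassigned",
                 "n_ambiguous"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def open_text(path, mode: str = "rt") -> TextIO:
    """Open a plain or gzipped text file."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) records from a FASTQ file (.gz ok)."""
    with open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[tuple[str, str, str]],
    index_reads: Iterable[tuple[str, str, str]] | None,
    sheet: list[SampleSheetEntry],
    max_mismatches: int = 0,
) -> dict[str, list[str]]:
    """Route reads to samples by index barcode.

    The index sequence comes from ``index_reads`` (a separate index FASTQ,
    paired record-by-record with ``reads``) or, if ``index_reads`` is None,
    from the last colon-separated field of each read title.  Returns a map
    sample_id → list of read sequences, with unmatched reads under
    :data:`UNDETERMINED`.  Every input read is routed exactly once.
    """
    _check_sheet(sheet)
    by_barcode = {e.index_barcode: e.sample_id for e in sheet}
    bc_len = len(next(iter(by_barcode)))
    out: dict[str, list[str]] = {e.sample_id: [] for e in sheet}
    out[UNDETERMINED] = []

    if index_reads is not None:
        pairs = zip(reads, index_reads)
        items = ((r[1], i[1]) for r, i in pairs)
    else:
        items = ((seq, title.rsplit(":", 1)[-1]) for title, seq, _ in reads)

    for seq, index in items:
        index = index.upper()
        if len(index) != bc_len:
            raise MatchingError(
                f"index length {len(index)} != sheet barcode length {bc_len}"
            )
        sample = by_barcode.get(index)
        if sample is None and max_mismatches > 0:
            hits = [
                sid for bc, sid in by_barcode.items()
                if _hamming(index, bc) <= max_mismatches
            ]
            sample = hits[0] if len(hits) == 1 else None
        out[sample if sample is not None else UNDETERMINED].append(seq)
    return out


# ---------------------------------------------------------------------------
# Prefix assignment and counting
# ---------------------------------------------------------------------------

def build_prefix_index(design: Design, k: int = PREFIX_LEN) -> dict[str, str]:
    """Map each countable strand's k-mer prefix to its strand_id.

    A prefix shared by several strands maps to :data:`AMBIGUOUS`, so collided
    reads are tallied rather than mis-assigned.
    """
    index: dict[str, str] = {}
    for s in design.countable_strands():
        p = s.prefix(k)
        index[p] = AMBIGUOUS if p in index else s.strand_id
    return index


def assign_read(read_seq: str, prefix_index: dict[str, str],
                k: int = PREFIX_LEN) -> str:
    """Assign one read to a strand by anchored exact prefix match.

    Offsets 4, 5, 6, 7 are scanned in increasing order; the first offset whose
    k-mer is in the index decides.  Returns a strand_id, :data:`AMBIGUOUS`
    (k-mer shared by several strands) or :data:`UNASSIGNED`.  Reads shorter
    than 24 nt are unassignable; `N` never matches (the index contains only
    ACGT k-mers).
    """
    seq = read_seq.upper()
    n = len(seq)
    if n < MIN_READ_LEN:
        return UNASSIGNED
    for off in LEADER_OFFSETS:
        if off + k > n:
            break
        hit = prefix_index.get(seq[off:off + k])
        if hit is not None:
            return hit
    return UNASSIGNED


def count_reads(reads: Iterable[str], design: Design,
                sample_id: str = "sample",
                prefix_index: dict[str, str] | None = None) -> CountTable:
    """Count reads per strand for one sample.

    The result is independent of read order; an empty stream yields an empty
    table (n_total == 0).
    """
    if prefix_index is None:
        prefix_index = build_prefix_index(design)
    counts: dict[str, int] = {}
    n_unassigned = 0
    n_ambiguous = 0
    for seq in reads:
        hit = assign_read(seq, prefix_index)
        if hit == UNASSIGNED:
            n_unassigned += 1
        elif hit == AMBIGUOUS:
            n_ambiguous += 1
        else:
            counts[hit] = counts.get(hit, 0) + 1
    table = CountTable(
        sample_id=sample_id,
        counts=counts,
        n_unassigned=n_unassigned,
        n_ambiguous=n_ambiguous,
    )
    table.validate()
    return table
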