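"""Synthetic designs, assembly outcomes and FASTQ files.

The simulator emulates the statistics of the wet-lab pipeline so that every
downstream stage can be exercised without a real sequencing run:

* each strand incorporates into a structure independently with probability
  ``true_p`` (product band) or stays a monomer with ``1 - true_p``;
* input stoichiometry varies mildly between strands (default cv 10%, the
  scale expected from spectrophotometric oligo quantification);
* ligation/amplification bias is one multiplicative lognormal factor per
  strand, shared between the product and monomer samples of an assembly
  (sequencing bias is consistent across samples, which is what lets the SRI
  ratio cancel it);
* reads are multinomial draws at a configurable depth, formatted as a 4–7 nt
  random leader followed by the strand sequence, padded with random bases to
  the read length, with a per-sample index barcode.

Sequencing errors, quality-score realism and chimeric reads are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .design import Design, Segment, Strand
from .matching import CountTable, SampleSheetEntry, write_sample_sheet
from .mixing import MixDesign

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)

#: sub-seed offsets so each band/sample of one config gets its own stream
_BAND_OFFSET = {"product": 1, "monomer": 2, "canvas_input": 3}


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

def _random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    mat = _LETTERS[rng.integers(0, 4, size=(n, length))]
    return [bytes(row).decode() for row in mat]


def random_canvas(n_strands: int, strand_length: int = 42,
                  seed: int = 0, name: str = "canvas") -> Design:
    """A molecular canvas of random bricks on a rectangular square-lattice grid.

    Sequences are uniform random ACGT with pairwise-distinct 20-nt prefixes
    (colliding sequences are redrawn); strand i sits at grid position
    (row, col) = (i // ncols, i % ncols) with one segment spanning its length.
    """
    if strand_length < 20:
        raise SimulationError("strand_length must be >= 20")
    if n_strands < 1:
        raise SimulationError("n_strands must be >= 1")
    if n_strands > 4 ** 10:
        raise SimulationError("prefix uniqueness infeasible at this scale")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    prefixes: set[str] = set()
    while len(seqs) < n_strands:
        for s in _random_seqs(rng, n_strands - len(seqs), strand_length):
            if s[:20] not in prefixes:
                prefixes.add(s[:20])
                seqs.append(s)
    ncols = int(np.ceil(np.sqrt(n_strands)))
    strands = {}
    for i, seq in enumerate(seqs):
        sid = f"b{i:04d}"
        strands[sid] = Strand(
            strand_id=sid,
            sequence=seq,
            role="brick",
            segments=(Segment(i // ncols, i % ncols, 0, strand_length),),
        )
    return Design(name=name, strands=strands)


def tag_rows(design: Design, shape_id: str, rows: range) -> Design:
    """Return a copy of ``design`` with strands whose first segment lies in
    ``rows`` additionally tagged as members of ``shape_id``."""
    strands = {}
    for s in design:
        shapes = set(s.shapes)
        if s.segments and s.segments[0].helix_row in rows:
            shapes.add(shape_id)
        strands[s.strand_id] = Strand(
            s.strand_id, s.sequence, s.role, s.segments, frozenset(shapes)
        )
    return Design(design.name, strands, design.lattice, design.geometry)


def spatial_incorporation_field(design: Design, base_p: float,
                                edge_penalty: float = 0.0,
                                noise_sd: float = 0.0,
                                seed: int = 0) -> dict[str, float]:
    """Incorporation probabilities with poorer incorporation at lattice edges.

    Strands on the boundary of the design's (row, col) grid get
    ``clamp(base_p - edge_penalty + noise, 0, 1)``; interior strands get
    ``clamp(base_p + noise, 0, 1)`` with iid Normal(0, noise_sd) noise.
    """
    if not 0 <= base_p <= 1 or not 0 <= edge_penalty <= 1:
        raise SimulationError("base_p and edge_penalty must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cells = [(s.segments[0].helix_row, s.segments[0].helix_col)
             for s in design if s.segments]
    rows = [r for r, _ in cells]
    cols = [c for _, c in cells]
    r_lo, r_hi, c_lo, c_hi = min(rows), max(rows), min(cols), max(cols)

    field_: dict[str, float] = {}
    for s in design:
        if not s.segments:
            continue
        r, c = s.segments[0].helix_row, s.segments[0].helix_col
        on_edge = r in (r_lo, r_hi) or c in (c_lo, c_hi)
        p = base_p - (edge_penalty if on_edge else 0.0)
        p += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        field_[s.strand_id] = float(np.clip(p, 0.0, 1.0))
    return field_


# ---------------------------------------------------------------------------
# Assembly + sequencing simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of one simulated assembly + sequencing experiment."""

    design: Design
    true_p: dict[str, float]
    seed: int
    depth: int = 500_000
    stoichiometry: dict[str, float] = field(default_factory=dict)
    ligation_bias: dict[str, float] = field(default_factory=dict)
    per_sample_bias_sd: float = 0.0
    read_length: int = 50
    leader_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise SimulationError("depth must be positive")
        for sid, p in self.true_p.items():
            if not 0 <= p <= 1:
                raise SimulationError(f"true_p[{sid!r}] = {p} outside [0, 1]")
        if any(b <= 0 for b in self.ligation_bias.values()):
            raise SimulationError("ligation biases must be positive")


def make_config(design: Design, true_p: dict[str, float], seed: int,
                depth: int = 500_000, stoich_cv: float = 0.10,
                bias_sd_log: float = 1.0,
                per_sample_bias_sd: float = 0.0) -> SimulationConfig:
    """Draw per-strand stoichiometry (lognormal, given cv) and shared
    ligation/amplification bias (lognormal, given sd of the log) and bundle
    them into a :class:`SimulationConfig`."""
    rng = np.random.default_rng([seed, 0])
    sids = [s.strand_id for s in design.countable_strands()]
    sd_st = np.sqrt(np.log(1 + stoich_cv ** 2)) if stoich_cv > 0 else 0.0
    stoich = dict(zip(sids, np.exp(rng.normal(0.0, sd_st, len(sids)))))
    bias = dict(zip(sids, np.exp(rng.normal(0.0, bias_sd_log, len(sids)))))
    return SimulationConfig(
        design=design, true_p=true_p, seed=seed, depth=depth,
        stoichiometry=stoich, ligation_bias=bias,
        per_sample_bias_sd=per_sample_bias_sd,
    )


def band_weights(config: SimulationConfig, band: str) -> dict[str, float]:
    """Analytic (unnormalized) sampling weights of each strand in a band."""
    weights = {}
    for s in config.design.countable_strands():
        sid = s.strand_id
        st = config.stoichiometry.get(sid, 1.0)
        b = config.ligation_bias.get(sid, 1.0)
        if band == "product":
            w = st * b * config.true_p[sid]
        elif band == "monomer":
            w = st * b * (1.0 - config.true_p[sid])
        elif band == "canvas_input":
            w = st * b
        else:
            raise SimulationError(f"unknown band {band!r}")
        weights[sid] = w
    return weights


def simulate_band_counts(config: SimulationConfig, band: str) -> CountTable:
    """Multinomial read counts for one gel band at the configured depth."""
    weights = band_weights(config, band)
    sids = list(weights)
    w = np.array([weights[sid] for sid in sids], dtype=float)
    rng = np.random.default_rng([config.seed, _BAND_OFFSET[band]])
    if config.per_sample_bias_sd > 0:
        w = w * np.exp(rng.normal(0.0, config.per_sample_bias_sd, len(w)))
    total = w.sum()
    if total == 0:
        # a band with no molecules yields no reads (e.g. the monomer band
        # when every strand incorporates fully)
        return CountTable(sample_id=band, counts={})
    counts = rng.multinomial(config.depth, w / total)
    return CountTable(
        sample_id=band,
        counts={sid: int(c) for sid, c in zip(sids, counts) if c > 0},
    )


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------

def emit_fastq(counts: CountTable, design: Design, entry: SampleSheetEntry,
               path, seed: int, index_path=None, read_length: int = 50,
               leader_weights=(0.25, 0.25, 0.25, 0.25)) -> int:
    """Write one sample's reads as FASTQ; returns the number of records.

    Each counted read is a random 4–7 nt leader, the strand sequence, then
    random filler up to ``read_length``.  Reads are emitted in shuffled order.
    The read title ends in ``:<barcode>`` so header-based demultiplexing
    works; if ``index_path`` is given, a paired index FASTQ is written too.
    Re-counting the emitted file reproduces the input counts exactly.
    """
    if read_length < 7 + 20:
        raise SimulationError(
            f"read_length {read_length} < 27: reads would be unassignable"
        )
    rng = np.random.default_rng(seed)
    sids = sorted(counts.counts)
    seqs = [design[sid].sequence for sid in sids]
    order = np.repeat(np.arange(len(sids)), [counts.counts[s] for s in sids])
    rng.shuffle(order)
    n = len(order)
    leader_len = rng.choice([4, 5, 6, 7], size=n, p=leader_weights)
    rand_mat = _LETTERS[rng.integers(0, 4, size=(n, read_length))]

    qual = "I" * read_length
    barcode = entry.index_barcode
    with open(path, "w") as fh, _maybe_open(index_path) as ifh:
        for i in range(n):
            k = int(leader_len[i])
            core = seqs[order[i]]
            rand = bytes(rand_mat[i]).decode()
            read = (rand[:k] + core + rand[k:])[:read_length]
            title = f"{entry.sample_id}.{i} 1:N:0:{barcode}"
            fh.write(f"@{title}\n{read}\n+\n{qual[:len(read)]}\n")
            if ifh is not None:
                ifh.write(f"@{title}\n{barcode}\n+\n{'I' * len(barcode)}\n")
    return n


class _Null:
    def __enter__(self):
        return None

    def __exit__(self, *exc):
        return False


def _maybe_open(path):
    return open(path, "w") if path is not None else _Null()


def barcode_for(i: int, length: int = 8) -> str:
    """Deterministic distinct index barcode for sample number ``i``."""
    digits = []
    for _ in range(length):
        digits.append("ACGT"[i % 4])
        i //= 4
    return "".join(digits)


# ---------------------------------------------------------------------------
# Mixing-experiment simulation
# ---------------------------------------------------------------------------

def simulate_mixing(mix_design: MixDesign, bias_sd_log: float = 1.0,
                    extra_noise_sd_log: float = 0.0, depth: int = 1_000_000,
                    seed: int = 0) -> dict[str, CountTable]:
    """Multinomial read counts for every mix of a mixing experiment.

    Per-oligo weights are pool_ratio × bias × exp(noise) with the lognormal
    bias shared across mixes (amplification/sequencing preference of that
    oligo) and the optional noise drawn independently per (oligo, mix)
    (ligation-step variability, which the reference normalization cannot
    cancel).
    """
    rng = np.random.default_rng([seed, 17])
    oligos = mix_design.oligo_ids
    bias = np.exp(rng.normal(0.0, bias_sd_log, len(oligos)))
    pool_idx = {pid: j for j, pid in enumerate(mix_design.pool_ids)}

    out: dict[str, CountTable] = {}
    for mid, ratios in mix_design.mixes.items():
        w = np.array(
            [ratios[pool_idx[mix_design.pool_of(o)]] for o in oligos]
        ) * bias
        if extra_noise_sd_log > 0:
            w = w * np.exp(rng.normal(0.0, extra_noise_sd_log, len(oligos)))
        total = w.sum()
        counts = rng.multinomial(depth, w / total)
        out[mid] = CountTable(
            sample_id=mid,
            counts={o: int(c) for o, c in zip(oligos, counts) if c > 0},
        )
    return out


# ---------------------------------------------------------------------------
# End-to-end structure run
# ---------------------------------------------------------------------------

def simulate_structure_run(
    canvas: Design,
    shape_id: str,
    true_p: dict[str, float],
    outdir,
    seed: int,
    depth: int = 500_000,
    stoich_cv: float = 0.10,
    bias_sd_log: float = 1.0,
    read_length: int = 50,
) -> dict[str, Path]:
    """Simulate product/monomer/canvas samples of one shape and write FASTQ.

    The product and monomer bands are assemblies of the shape's strands only;
    the canvas-input sample sequences the full canvas mix.  Ligation bias is
    drawn once per canvas strand and shared by all three samples.  Writes a
    pooled R1 FASTQ, a paired index FASTQ, the sample sheet, the design table
    and a ground-truth TSV; returns the paths.
    """
    from .design import subset_shape, write_design_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    shape = subset_shape(canvas, shape_id)
    missing = [sid for sid in shape.strands if sid not in true_p]
    if missing:
        raise SimulationError(f"true_p missing for shape strands: {missing[:5]}")

    canvas_cfg = make_config(
        canvas, {s.strand_id: 1.0 for s in canvas}, seed=seed,
        depth=depth, stoich_cv=stoich_cv, bias_sd_log=bias_sd_log,
    )
    shape_cfg = SimulationConfig(
        design=shape,
        true_p={sid: true_p[sid] for sid in shape.strands},
        seed=seed,
        depth=depth,
        stoichiometry={sid: canvas_cfg.stoichiometry[sid] for sid in shape.strands},
        ligation_bias={sid: canvas_cfg.ligation_bias[sid] for sid in shape.strands},
        read_length=read_length,
    )

    entries = []
    band_tables = {}
    for i, (band, cfg) in enumerate(
        [("product", shape_cfg), ("monomer", shape_cfg),
         ("canvas_input", canvas_cfg)]
    ):
        entry = SampleSheetEntry(
            sample_id=f"{shape_id}_{band}",
            band=band,
            index_barcode=barcode_for(i + 1),
            design_ref=canvas.name,
            shape_id=shape_id,
        )
        entries.append(entry)
        band_tables[band] = (simulate_band_counts(cfg, band), entry)

    r1 = outdir / "reads_R1.fastq"
    idx = outdir / "reads_I1.fastq"
    with open(r1, "w"), open(idx, "w"):
        pass
    # append each sample's reads into the pooled files
    with open(r1, "a") as rfh, open(idx, "a") as ifh:
        for j, (band, (tbl, entry)) in enumerate(band_tables.items()):
            tmp_r = outdir / f".{band}_r1.fastq"
            tmp_i = outdir / f".{band}_i1.fastq"
            emit_fastq(tbl, canvas, entry, tmp_r, seed=seed * 8 + 4 + j,
                       index_path=tmp_i, read_length=read_length)
            rfh.write(tmp_r.read_text())
            ifh.write(tmp_i.read_text())
            tmp_r.unlink()
            tmp_i.unlink()

    sheet = outdir / "sample_sheet.tsv"
    write_sample_sheet(entries, sheet)
    design_path = outdir / "design.tsv"
    write_design_table(canvas, design_path)

    truth = outdir / "ground_truth.tsv"
    with open(truth, "w") as fh:
        fh.write("strand_id\tin_shape\ttrue_p\tbias\n")
        for s in canvas:
            sid = s.strand_id
            in_shape = shape_id in s.shapes
            p = true_p.get(sid, 0.0) if in_shape else 0.0
            fh.write(f"{sid}\t{int(in_shape)}\t{p:.6g}\t"
                     f"{canvas_cfg.ligation_bias.get(sid, 1.0):.6g}\n")

    return {
        "reads": r1, "index": idx, "sample_sheet": sheet,
        "design": design_path, "ground_truth": truth,
    }
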