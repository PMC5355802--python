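"""Core incorporation statistics: read fractions, presence thresholding, SRI.

The per-strand statistic is the structure-wide relative incorporability (SRI):

    SRI_i = (P_i / P_tot) / (P_i / P_tot  +  M_i / M_tot)

where ``P_i`` and ``M_i`` are strand *i*'s read counts in the product and
monomer gel bands and ``P_tot``, ``M_tot`` the total assigned counts of each
band.  Because any strand-specific ligation/amplification/sequencing bias
multiplies ``P_i`` and ``M_i`` equally, it cancels from the ratio: SRI is a
relative (not absolute) measure of how well a strand incorporates, 0 meaning
all reads in the monomer band and 1 meaning all reads in the product band.

Before computing SRI, strands actually present in a structure are separated
from the rest of the canvas by thresholding the log2 ratio of product to
canvas read fractions: the ratio distribution is unimodal when all strands
incorporate and bimodal when the design uses a subset of the canvas, and the
threshold is placed at the minimum of a two-Gaussian fit to its 20-bin
histogram, rounded up to the next bin edge.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .design import EXCLUDED_ROLES, Design
from .matching import CountTable

logger = logging.getLogger(__name__)

N_BINS = 20
DEFAULT_MIN_PRODUCT_READS = 25
DEFAULT_PSEUDOCOUNT = 1.0

FLAG_OK = "ok"
FLAG_LOW_READS = "low_reads"
FLAG_BELOW_THRESHOLD = "below_threshold"
FLAG_EXCLUDED_ROLE = "excluded_role"


class IncorporationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Read fractions
# ---------------------------------------------------------------------------

@dataclass
class ReadFractionTable:
    sample_id: str
    fractions: dict[str, float]


def read_fractions(counts: CountTable, design: Design | None = None
                   ) -> ReadFractionTable:
    """Per-strand read fraction: count divided by total assigned reads.

    Strands of ``design`` absent from the count table get fraction 0.
    """
    total = counts.n_assigned
    if total == 0:
        raise IncorporationError(
            f"sample {counts.sample_id!r}: zero assigned reads"
        )
    fractions = {sid: c / total for sid, c in counts.counts.items()}
    if design is not None:
        for s in design.countable_strands():
            fractions.setdefault(s.strand_id, 0.0)
    return ReadFractionTable(sample_id=counts.sample_id, fractions=fractions)


# ---------------------------------------------------------------------------
# Presence thresholding
# ---------------------------------------------------------------------------

@dataclass
class GaussianComponent:
    weight: float  # area under the component, in histogram-count units
    mean: float
    sd: float


@dataclass
class ThresholdFit:
    """Two-Gaussian histogram fit of the product/canvas log2 ratio."""

    values: dict[str, float]          # per-strand log2(RF_product / RF_canvas)
    bin_edges: np.ndarray             # 21 edges (20 evenly spaced bins)
    components: list[GaussianComponent]
    threshold: float | None           # None: unimodal, all strands present
    present: frozenset[str]

    def write_values(self, path) -> None:
        rows = sorted(self.values.items())
        df = pd.DataFrame(rows, columns=["strand_id", "log2_ratio"])
        df["present"] = df["strand_id"].isin(self.present)
        df.to_csv(path, sep="\t", index=False)

    def write_summary(self, path) -> None:
        doc = {
            "n_strands": len(self.values),
            "n_components": len(self.components),
            "components": [
                {"weight": c.weight, "mean": c.mean, "sd": c.sd}
                for c in self.components
            ],
            "bin_width": float(self.bin_edges[1] - self.bin_edges[0]),
            "threshold": self.threshold,
            "n_present": len(self.present),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")


def _gauss(x, a, m, s):
    return a * np.exp(-0.5 * ((x - m) / s) ** 2)


def _gauss2(x, a1, m1, s1, a2, m2, s2):
    return _gauss(x, a1, m1, s1) + _gauss(x, a2, m2, s2)


def _aic(rss: float, n: int, k: int) -> float:
    return n * math.log(max(rss, 1e-300) / n) + 2 * k


def presence_threshold(
    product_counts: CountTable,
    canvas_counts: CountTable,
    design: Design,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ThresholdFit:
    """Classify canvas strands as present/absent in the assembled product.

    Computes v_i = log2(RF_product,i / RF_canvas,i) with a pseudocount added
    to the raw counts of this step (so absent strands give finite values),
    bins the values into a 20-bin histogram, and fits one- and two-component
    Gaussian models to the binned counts by least squares.  The two-component
    model is adopted only when it wins on AIC *and* its fitted means are at
    least one bin width apart; the threshold is then the minimum of the fitted
    two-component density between the means, rounded up to the next bin edge.
    A unimodal fit means all strands are well incorporated: threshold None,
    everything present.
    """
    if pseudocount <= 0:
        raise IncorporationError("pseudocount must be > 0")
    strand_ids = [s.strand_id for s in design.countable_strands()]

    p = np.array([product_counts.counts.get(sid, 0) for sid in strand_ids],
                 dtype=float) + pseudocount
    c = np.array([canvas_counts.counts.get(sid, 0) for sid in strand_ids],
                 dtype=float) + pseudocount
    v = np.log2((p / p.sum()) / (c / c.sum()))
    values = dict(zip(strand_ids, v.tolist()))

    hist, edges = np.histogram(v, bins=N_BINS)

    if len(strand_ids) < N_BINS:
        logger.warning(
            "only %d strands (< %d): too few for a histogram fit; "
            "treating all strands as present", len(strand_ids), N_BINS
        )
        return ThresholdFit(values, edges, [], None, frozenset(strand_ids))

    centers = (edges[:-1] + edges[1:]) / 2
    bin_width = edges[1] - edges[0]
    histf = hist.astype(float)

    # 1-component fit
    m0, s0 = float(v.mean()), max(float(v.std()), bin_width / 4)
    bounds1 = ([0, edges[0], bin_width / 10], [np.inf, edges[-1], np.inf])
    fit1 = _safe_fit(_gauss, centers, histf, p0=[histf.max(), m0, s0],
                     bounds=bounds1)

    # 2-component fit, several deterministic starts: the stated quartile
    # initialization (means at the 25th/75th percentiles, sds half the IQR)
    # plus histogram-mode starts, which rescue spiky single-bin modes.
    q25, q75 = np.percentile(v, [25, 75])
    iqr_sd = max((q75 - q25) / 2, bin_width / 4)
    starts = [
        [histf.max() / 2, q25, iqr_sd, histf.max() / 2, q75, iqr_sd],
    ]
    order = np.argsort(histf)[::-1]
    mode1 = int(order[0])
    far = [i for i in order[1:] if abs(centers[i] - centers[mode1]) >= 2 * bin_width]
    if far:
        mode2 = far[0]
        starts.append([
            histf[mode1], centers[mode1], bin_width,
            histf[mode2], centers[mode2], bin_width,
        ])
        starts.append([
            histf[mode1], centers[mode1], 2 * bin_width,
            histf[mode2], centers[mode2], 2 * bin_width,
        ])
    bounds2 = ([0, edges[0], bin_width / 10, 0, edges[0], bin_width / 10],
               [np.inf, edges[-1], np.inf, np.inf, edges[-1], np.inf])
    fit2 = None
    best_rss = np.inf
    for p0 in starts:
        cand = _safe_fit(_gauss2, centers, histf, p0=p0, bounds=bounds2)
        if cand is None:
            continue
        rss = float(((histf - _gauss2(centers, *cand)) ** 2).sum())
        if rss < best_rss:
            best_rss = rss
            fit2 = cand

    if fit1 is None and fit2 is None:
        # least-squares failed outright; fall back to the midpoint of the two
        # most populated local maxima of the histogram
        logger.warning("Gaussian fits did not converge; falling back to the "
                       "midpoint of the two histogram modes")
        threshold = _mode_midpoint(histf, centers)
        present = frozenset(sid for sid, x in values.items() if x >= threshold)
        return ThresholdFit(values, edges, [], threshold, present)

    use_two = False
    if fit2 is not None:
        a1, m1, s1, a2, m2, s2 = fit2
        rss2 = float(((histf - _gauss2(centers, *fit2)) ** 2).sum())
        if fit1 is not None:
            rss1 = float(((histf - _gauss(centers, *fit1)) ** 2).sum())
            use_two = (_aic(rss2, N_BINS, 6) < _aic(rss1, N_BINS, 3)
                       and abs(m2 - m1) >= bin_width)
        else:
            use_two = abs(m2 - m1) >= bin_width
        if use_two:
            # demand genuine bimodality: the fitted density must dip between
            # the two means to below half the smaller peak, otherwise the
            # second component is only absorbing histogram jitter
            between = np.linspace(min(m1, m2), max(m1, m2), 501)
            valley = float(_gauss2(between, *fit2).min())
            peaks = (float(_gauss2(np.array([m1]), *fit2)[0]),
                     float(_gauss2(np.array([m2]), *fit2)[0]))
            use_two = valley <= 0.5 * min(peaks)

    if not use_two:
        a, m, s = fit1 if fit1 is not None else fit2[:3]
        comp = [GaussianComponent(a * s * math.sqrt(2 * math.pi), m, s)]
        return ThresholdFit(values, edges, comp, None, frozenset(strand_ids))

    lo_m, hi_m = sorted([m1, m2])
    comps = sorted(
        [GaussianComponent(a1 * s1 * math.sqrt(2 * math.pi), m1, s1),
         GaussianComponent(a2 * s2 * math.sqrt(2 * math.pi), m2, s2)],
        key=lambda cpt: cpt.mean,
    )
    grid = np.linspace(lo_m, hi_m, 2001)[1:-1]  # open interval between means
    argmin = float(grid[np.argmin(_gauss2(grid, *fit2))])
    # round up to the next bin edge, staying strictly below the upper mean
    above = edges[(edges > argmin) & (edges < hi_m)]
    threshold = float(above[0]) if len(above) else argmin

    present = frozenset(sid for sid, x in values.items() if x >= threshold)
    return ThresholdFit(values, edges, comps, threshold, present)


def _safe_fit(fn, x, y, p0, bounds):
    try:
        popt, _ = curve_fit(fn, x, y, p0=p0, bounds=bounds, maxfev=20000)
        return popt
    except (RuntimeError, ValueError):
        return None


def _mode_midpoint(hist: np.ndarray, centers: np.ndarray) -> float:
    """Midpoint of the two most populated local maxima of a histogram."""
    maxima = [
        i for i in range(len(hist))
        if (i == 0 or hist[i] >= hist[i - 1])
        and (i == len(hist) - 1 or hist[i] >= hist[i + 1])
        and hist[i] > 0
    ]
    maxima.sort(key=lambda i: -hist[i])
    if len(maxima) < 2:
        return float(centers[0])
    i, j = sorted(maxima[:2])
    return float((centers[i] + centers[j]) / 2)


# ---------------------------------------------------------------------------
# SRI
# ---------------------------------------------------------------------------

def compute_sri(P_i: int, M_i: int, P_tot: int, M_tot: int) -> float | None:
    """SRI for one strand; None when the strand has no reads in either band."""
    if min(P_i, M_i, P_tot, M_tot) < 0:
        raise IncorporationError("read counts must be non-negative")
    if P_tot <= 0 or M_tot <= 0:
        raise IncorporationError("band totals must be positive")
    if P_i > P_tot or M_i > M_tot:
        raise IncorporationError("per-strand count exceeds band total")
    if P_i + M_i == 0:
        return None
    rf_p = P_i / P_tot
    rf_m = M_i / M_tot
    return rf_p / (rf_p + rf_m)


@dataclass
class SRITable:
    """Per-strand SRI with the raw band counts and filter flags.

    ``data`` columns: strand_id, P_i, M_i, sri (NaN when undefined), flag.
    """

    data: pd.DataFrame
    P_tot: int
    M_tot: int

    def defined(self) -> pd.DataFrame:
        return self.data[self.data["flag"] == FLAG_OK]

    def sri_of(self, strand_id: str) -> float:
        row = self.data.loc[self.data["strand_id"] == strand_id]
        if row.empty:
            raise KeyError(strand_id)
        return float(row["sri"].iloc[0])

    def write(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read(cls, path) -> "SRITable":
        df = pd.read_csv(path, sep="\t", dtype={"strand_id": str})
        P_tot = int(df["P_i"].sum())
        M_tot = int(df["M_i"].sum())
        return cls(data=df, P_tot=P_tot, M_tot=M_tot)


def build_sri_table(
    product: CountTable,
    monomer: CountTable,
    design: Design,
    present: frozenset[str] | None = None,
) -> SRITable:
    """Compute raw SRI for every countable design strand.

    Strands with an excluded role (half-brick, edge protector, scaffold) and
    strands outside the ``present`` set never receive an SRI.  Totals are the
    assigned read counts of each band.  The 25-read product filter is applied
    separately by :func:`apply_min_reads_filter`.
    """
    P_tot = product.n_assigned
    M_tot = monomer.n_assigned
    if P_tot <= 0 or M_tot <= 0:
        raise IncorporationError("product and monomer bands need assigned reads")

    rows = []
    for s in design.countable_strands():
        sid = s.strand_id
        P_i = product.counts.get(sid, 0)
        M_i = monomer.counts.get(sid, 0)
        if s.role in EXCLUDED_ROLES:
            flag, sri = FLAG_EXCLUDED_ROLE, float("nan")
        elif present is not None and sid not in present:
            flag, sri = FLAG_BELOW_THRESHOLD, float("nan")
        else:
            val = compute_sri(P_i, M_i, P_tot, M_tot)
            if val is None:
                flag, sri = FLAG_LOW_READS, float("nan")
            else:
                flag, sri = FLAG_OK, val
        rows.append((sid, P_i, M_i, sri, flag))

    df = pd.DataFrame(rows, columns=["strand_id", "P_i", "M_i", "sri", "flag"])
    return SRITable(data=df, P_tot=P_tot, M_tot=M_tot)


def apply_min_reads_filter(
    table: SRITable, min_product_reads: int = DEFAULT_MIN_PRODUCT_READS
) -> SRITable:
    """Disregard strands with fewer than ``min_product_reads`` product reads.

    Such strands carry too little information to quantify incorporation; they
    are flagged ``low_reads`` and their SRI set undefined.  Strands at or
    above the cutoff are untouched.
    """
    df = table.data.copy()
    low = (df["flag"] == FLAG_OK) & (df["P_i"] < min_product_reads)
    df.loc[low, "flag"] = FLAG_LOW_READS
    df.loc[low, "sri"] = float("nan")
    return SRITable(data=df, P_tot=table.P_tot, M_tot=table.M_tot)


# ---------------------------------------------------------------------------
# Sequence-composition QC
# ---------------------------------------------------------------------------

def qc_sequence_correlates(table: SRITable, design: Design
                           ) -> tuple[float, int]:
    """Pearson correlation of SRI against strand GC fraction.

    A well-behaved library shows no correlation: sequence-composition bias is
    shared between the product and monomer bands and cancels from the SRI.
    Returns (r, n) over strands with a defined SRI.
    """
    ok = table.defined()
    sri = []
    gc = []
    for _, row in ok.iterrows():
        sid = row["strand_id"]
        if sid in design:
            sri.append(row["sri"])
            gc.append(design[sid].gc_fraction)
    if len(sri) < 3:
        raise IncorporationError(
            f"need >= 3 strands with defined SRI, got {len(sri)}"
        )
    if np.std(sri) == 0 or np.std(gc) == 0:
        raise IncorporationError(
            "degenerate input: SRI or GC fraction is constant"
        )
    r, _ = pearsonr(sri, gc)
    return float(r), len(sri)
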