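"""Oligonucleotide mixing experiments: NRF computation and agreement summary.

The quantitative performance of amplicon sequencing is validated by mixing
pools of oligonucleotides at known stoichiometries (e.g. six mixes of five
pools, each pool present at 0/10/20/30/40% of a mix) and comparing observed
pool read fractions against the pipetted expectations.  Sequence-specific
amplification bias is cancelled by dividing each pool's read fraction by the
fraction measured in a uniform (1:1:1:1:1) reference mix; the resulting
normalized read fractions (NRF), renormalized to sum to 1 per mix, are
directly comparable to the expected fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .matching import CountTable


class MixingError(ValueError):
    pass


@dataclass
class MixDesign:
    """Pools of oligos and the ratio in which pools enter each mix."""

    pools: dict[str, list[str]]          # pool_id -> member oligo ids
    mixes: dict[str, list[float]]        # mix_id -> ratio vector over pools
    reference_mix: str

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for pid, members in self.pools.items():
            for oligo in members:
                if oligo in seen:
                    raise MixingError(
                        f"oligo {oligo!r} in pools {seen[oligo]!r} and {pid!r}"
                    )
                seen[oligo] = pid
        k = len(self.pools)
        for mid, ratios in self.mixes.items():
            if len(ratios) != k:
                raise MixingError(
                    f"mix {mid!r}: {len(ratios)} ratios for {k} pools"
                )
            if any(r < 0 for r in ratios):
                raise MixingError(f"mix {mid!r}: negative ratio")
        if self.reference_mix not in self.mixes:
            raise MixingError(f"reference mix {self.reference_mix!r} not defined")
        if any(r <= 0 for r in self.mixes[self.reference_mix]):
            raise MixingError("reference mix must have strictly positive ratios")

    @property
    def pool_ids(self) -> list[str]:
        return list(self.pools)

    def pool_of(self, oligo_id: str) -> str:
        for pid, members in self.pools.items():
            if oligo_id in members:
                return pid
        raise KeyError(oligo_id)

    @property
    def oligo_ids(self) -> list[str]:
        return [o for members in self.pools.values() for o in members]


def standard_mix_design(n_pools: int = 5, oligos_per_pool: int = 6) -> MixDesign:
    """The printed 6-mix design: a uniform reference plus five cyclic
    permutations of the ratio vector 1:2:3:4:0 over five pools."""
    pools = {
        f"pool{j + 1}": [f"oligo_{j + 1}_{i + 1}" for i in range(oligos_per_pool)]
        for j in range(n_pools)
    }
    if n_pools != 5:
        raise MixingError("the standard design uses exactly 5 pools")
    mixes: dict[str, list[float]] = {
        "A": [1.0, 1.0, 1.0, 1.0, 1.0],
        "B": [1.0, 2.0, 3.0, 4.0, 0.0],
        "C": [0.0, 1.0, 2.0, 3.0, 4.0],
        "D": [4.0, 0.0, 1.0, 2.0, 3.0],
        "E": [3.0, 4.0, 0.0, 1.0, 2.0],
        "F": [2.0, 3.0, 4.0, 0.0, 1.0],
    }
    return MixDesign(pools=pools, mixes=mixes, reference_mix="A")


def load_mix_design(path) -> MixDesign:
    """Read a mix design TSV with two sections.

    Rows ``pool<TAB>pool_id<TAB>oligo_id`` assign oligos to pools; rows
    ``mix<TAB>mix_id<TAB>r1;r2;...<TAB>is_reference`` give ratio vectors.
    """
    pools: dict[str, list[str]] = {}
    mixes: dict[str, list[float]] = {}
    reference = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "pool":
                pools.setdefault(fields[1], []).append(fields[2])
            elif fields[0] == "mix":
                mixes[fields[1]] = [float(x) for x in fields[2].split(";")]
                if len(fields) > 3 and fields[3].lower() in ("1", "true", "yes"):
                    reference = fields[1]
            else:
                raise MixingError(f"unknown mix-design row type {fields[0]!r}")
    if reference is None:
        raise MixingError("no mix flagged as reference")
    return MixDesign(pools=pools, mixes=mixes, reference_mix=reference)


def write_mix_design(design: MixDesign, path) -> None:
    with open(path, "w") as fh:
        for pid, members in design.pools.items():
            for oligo in members:
                fh.write(f"pool\t{pid}\t{oligo}\n")
        for mid, ratios in design.mixes.items():
            flag = "1" if mid == design.reference_mix else "0"
            fh.write(f"mix\t{mid}\t{';'.join(str(r) for r in ratios)}\t{flag}\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def expected_fractions(ratios: list[float]) -> np.ndarray:
    """Normalize a pool ratio vector to fractions summing to 1."""
    r = np.asarray(ratios, dtype=float)
    if (r < 0).any():
        raise MixingError("ratios must be non-negative")
    total = r.sum()
    if total == 0:
        raise MixingError("ratio vector is all zero")
    return r / total


def pool_read_fractions(counts: CountTable, design: MixDesign
                        ) -> dict[str, float]:
    """Per-pool read fraction: mean reads per member oligo, normalized across
    pools.  A pool with no reads gets fraction 0."""
    means = {}
    for pid, members in design.pools.items():
        means[pid] = np.mean([counts.counts.get(o, 0) for o in members])
    total = sum(means.values())
    if total == 0:
        raise MixingError(f"sample {counts.sample_id!r}: no reads in any pool")
    return {pid: m / total for pid, m in means.items()}


def normalize_to_reference(
    pool_rf_by_mix: dict[str, dict[str, float]], reference: str
) -> dict[str, dict[str, float]]:
    """Observed NRF per (mix, pool): reference-ratio then per-mix renormalization.

    raw_j = RF_j,mix / RF_j,reference; NRF_j = raw_j / Σ_j raw_j, so NRF sums
    to 1 per mix and equals the expected pool fraction in expectation when
    per-oligo bias is shared between each mix and the reference.
    """
    if reference not in pool_rf_by_mix:
        raise MixingError(f"reference mix {reference!r} missing from data")
    ref = pool_rf_by_mix[reference]
    if any(v <= 0 for v in ref.values()):
        raise MixingError("reference mix has a zero pool read fraction")
    nrf: dict[str, dict[str, float]] = {}
    for mid, rf in pool_rf_by_mix.items():
        raw = {pid: rf[pid] / ref[pid] for pid in ref}
        total = sum(raw.values())
        nrf[mid] = {pid: v / total for pid, v in raw.items()}
    return nrf


@dataclass
class MixResult:
    observed_nrf: dict[tuple[str, str], float]   # (mix_id, pool_id) -> NRF
    expected: dict[tuple[str, str], float]
    level_means: dict[float, float] = field(default_factory=dict)
    level_sds: dict[float, float] = field(default_factory=dict)
    r_squared: float = float("nan")

    def write(self, prefix) -> None:
        """Write per-point, per-level and summary TSVs under ``prefix``."""
        rows = [
            (mid, pid, self.expected[(mid, pid)], nrf)
            for (mid, pid), nrf in sorted(self.observed_nrf.items())
        ]
        pd.DataFrame(
            rows, columns=["mix_id", "pool_id", "expected", "observed_nrf"]
        ).to_csv(f"{prefix}_points.tsv", sep="\t", index=False)
        lev = [
            (level, self.level_means[level], self.level_sds[level])
            for level in sorted(self.level_means)
        ]
        pd.DataFrame(lev, columns=["level", "mean", "sd"]).to_csv(
            f"{prefix}_levels.tsv", sep="\t", index=False
        )
        with open(f"{prefix}_report.tsv", "w") as fh:
            fh.write(f"r_squared\t{self.r_squared:.6g}\n")


def summarize_mixing(
    mix_design: MixDesign,
    counts_by_mix: dict[str, CountTable],
) -> MixResult:
    """Full mixing analysis: pool fractions → NRF → level means/sds and R².

    Observed NRF values are grouped by their expected level across the
    non-reference mixes; the s.d. at each level is taken over the pools
    sharing that expected fraction.  R² is the squared Pearson correlation of
    (expected, observed) over all non-reference points.
    """
    pool_rf = {
        mid: pool_read_fractions(tbl, mix_design)
        for mid, tbl in counts_by_mix.items()
    }
    nrf = normalize_to_reference(pool_rf, mix_design.reference_mix)

    observed: dict[tuple[str, str], float] = {}
    expected: dict[tuple[str, str], float] = {}
    pool_ids = mix_design.pool_ids
    for mid, ratios in mix_design.mixes.items():
        if mid not in nrf:
            continue
        exp = expected_fractions(ratios)
        for pid, e in zip(pool_ids, exp):
            observed[(mid, pid)] = nrf[mid][pid]
            expected[(mid, pid)] = float(e)

    ref = mix_design.reference_mix
    pairs = [
        (expected[key], observed[key])
        for key in observed if key[0] != ref
    ]
    levels = sorted({round(e, 12) for e, _ in pairs})
    if len(levels) < 2:
        raise MixingError("need >= 2 distinct expected levels")

    level_means = {}
    level_sds = {}
    for level in levels:
        vals = [o for e, o in pairs if round(e, 12) == level]
        level_means[level] = float(np.mean(vals))
        level_sds[level] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    e_arr = np.array([e for e, _ in pairs])
    o_arr = np.array([o for _, o in pairs])
    if np.std(o_arr) == 0:
        r2 = float("nan")
    else:
        r, _ = pearsonr(e_arr, o_arr)
        r2 = float(r ** 2)

    return MixResult(
        observed_nrf=observed,
        expected=expected,
        level_means=level_means,
        level_sds=level_sds,
        r_squared=r2,
    )
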