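"""Methylation-correlated block (MCB) calling from CpG beta-value matrices.

An MCB is a genomic run of at least ``min_cpgs`` consecutive CpG sites in
which every adjacent pair of sites is (a) closer than ``max_gap`` bp and
(b) has a Pearson correlation of beta values above ``min_r`` across the
tissue samples used for segmentation.  Blocks are the atomic marker unit
for all downstream fragment-level quantification and modeling: averaging
over tightly co-methylated CpGs suppresses per-site technical noise.

Coordinates are 0-based half-open throughout; a CpG site is identified by
the forward-strand cytosine of the dinucleotide, so an MCB spanning member
CpGs ``p1 .. pk`` covers ``[p1, pk + 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "BetaMatrix",
    "MCB",
    "adjacent_correlations",
    "call_mcbs",
    "read_beta_tsv",
    "write_mcb_bed",
    "read_mcb_bed",
]

#: minimum pairwise-complete observations for a usable Pearson r
_MIN_COMPLETE_PAIRS = 3


@dataclass(frozen=True)
class MCB:
    """A methylation-correlated block: >=3 co-methylated CpGs."""

    mcb_id: str
    chrom: str
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = self.cpg_positions
        if len(pos) < 2:
            raise InvalidInputError("an MCB needs at least two CpG positions")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise InvalidInputError("MCB CpG positions must be strictly increasing")

    @property
    def start(self) -> int:
        return self.cpg_positions[0]

    @property
    def end(self) -> int:
        # +2 covers the CpG dinucleotide of the last member site
        return self.cpg_positions[-1] + 2

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


@dataclass
class BetaMatrix:
    """CpG-site x sample matrix of methylation fractions (beta values).

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom`` and ``pos`` (0-based CpG cytosine
        coordinate), sorted by (chrom, pos) and unique.
    values
        float array of shape ``(n_sites, n_samples)`` with entries in
        [0, 1]; ``NaN`` marks missing calls.
    samples
        sample identifiers, one per value column.
    """

    sites: pd.DataFrame
    values: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("beta values must be 2-D (sites x samples)")
        if len(self.sites) != self.values.shape[0]:
            raise InvalidInputError("site table and value rows disagree")
        if len(self.samples) != self.values.shape[1]:
            raise InvalidInputError("sample list and value columns disagree")
        if not {"chrom", "pos"} <= set(self.sites.columns):
            raise InvalidInputError("site table needs 'chrom' and 'pos' columns")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise InvalidInputError("beta values must lie in [0, 1]")
        if self.sites.duplicated(["chrom", "pos"]).any():
            raise InvalidInputError("duplicate (chrom, pos) in site table")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def is_sorted(self) -> bool:
        s = self.sites
        key = list(zip(s["chrom"], s["pos"]))
        return key == sorted(key)


def _pairwise_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r over pairwise-complete observations, NaN if unusable."""
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < _MIN_COMPLETE_PAIRS:
        return np.nan
    x, y = a[mask], b[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def adjacent_correlations(matrix: BetaMatrix) -> dict[str, np.ndarray]:
    """Pearson r between each consecutive same-chromosome CpG pair.

    Returns a mapping ``chrom -> array of length n_sites(chrom) - 1``.
    Pairs with fewer than three pairwise-complete observations or zero
    variance get ``NaN`` (treated downstream as failing the correlation
    criterion).
    """
    if matrix.n_samples < 2:
        raise InvalidInputError("need at least 2 samples to correlate CpG pairs")
    if not matrix.is_sorted():
        raise InvalidInputError("beta matrix sites must be sorted by (chrom, pos)")
    out: dict[str, np.ndarray] = {}
    chroms = matrix.sites["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        rs = np.array(
            [
                _pairwise_pearson(matrix.values[i], matrix.values[j])
                for i, j in zip(idx, idx[1:])
            ]
        )
        out[str(chrom)] = rs
    return out


def call_mcbs(
    matrix: BetaMatrix,
    max_gap: int = 100,
    min_r: float = 0.95,
    min_cpgs: int = 3,
) -> list[MCB]:
    """Segment CpG sites into maximal correlated runs.

    A run extends left to right while the next adjacent pair satisfies
    ``gap < max_gap`` (strict) and ``r > min_r`` (strict); a missing r
    breaks the run.  Runs shorter than ``min_cpgs`` are discarded.
    """
    if max_gap <= 0 or min_cpgs < 2:
        raise InvalidInputError("max_gap must be positive and min_cpgs >= 2")
    if not matrix.is_sorted():
        raise InvalidInputError("beta matrix sites must be sorted by (chrom, pos)")
    correlations = adjacent_correlations(matrix)
    chroms = matrix.sites["chrom"].to_numpy()
    positions = matrix.sites["pos"].to_numpy()
    mcbs: list[MCB] = []
    counter = 1
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        rs = correlations[str(chrom)]
        gaps = np.diff(pos)
        ok = np.zeros(len(pos) - 1, dtype=bool) if len(pos) else np.array([], bool)
        if len(pos) > 1:
            with np.errstate(invalid="ignore"):
                ok = (gaps < max_gap) & (rs > min_r) & np.isfinite(rs)
        run_start = 0
        for i in range(len(pos)):
            last = i == len(pos) - 1
            if last or not ok[i]:
                run = pos[run_start : i + 1]
                if len(run) >= min_cpgs:
                    mcbs.append(
                        MCB(
                            mcb_id=f"mcb_{counter:05d}",
                            chrom=str(chrom),
                            cpg_positions=tuple(int(p) for p in run),
                        )
                    )
                    counter += 1
                run_start = i + 1
    return mcbs


# ---------------------------------------------------------------------------
# I/O

def read_beta_tsv(path: str | Path) -> BetaMatrix:
    """Read a beta-value TSV: columns chrom, pos, then one per sample."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if list(df.columns[:2]) != ["chrom", "pos"]:
        raise InvalidInputError("beta TSV must start with 'chrom' and 'pos' columns")
    samples = [str(c) for c in df.columns[2:]]
    return BetaMatrix(
        sites=df[["chrom", "pos"]].reset_index(drop=True),
        values=df[df.columns[2:]].to_numpy(dtype=float),
        samples=samples,
    )


def write_beta_tsv(matrix: BetaMatrix, path: str | Path) -> None:
    values = pd.DataFrame(matrix.values, columns=matrix.samples)
    df = pd.concat([matrix.sites.reset_index(drop=True), values], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_mcb_bed(mcbs: Iterable[MCB], path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write MCBs as BED6-compatible TSV plus an optional CpG-position sidecar."""
    mcbs = list(mcbs)
    with open(path, "w") as fh:
        for m in mcbs:
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.mcb_id}\t{m.n_cpgs}\t.\n")
    if sidecar is not None:
        with open(sidecar, "w") as fh:
            fh.write("mcb_id\tcpg_positions\n")
            for m in mcbs:
                fh.write(f"{m.mcb_id}\t{','.join(map(str, m.cpg_positions))}\n")


def read_mcb_bed(path: str | Path, sidecar: str | Path | None = None) -> list[MCB]:
    """Read MCBs from BED(+sidecar).  Without a sidecar, member CpGs are
    approximated by the block boundaries (start, end-2)."""
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "mcb_id", "n_cpgs", "strand"],
    )
    positions: Mapping[str, tuple[int, ...]] = {}
    if sidecar is not None:
        side = pd.read_csv(sidecar, sep="\t")
        positions = {
            row.mcb_id: tuple(int(p) for p in str(row.cpg_positions).split(","))
            for row in side.itertuples()
        }
    out = []
    for row in bed.itertuples():
        pos = positions.get(row.mcb_id, (int(row.start), int(row.end) - 2))
        out.append(MCB(mcb_id=str(row.mcb_id), chrom=str(row.chrom), cpg_positions=pos))
    return out
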