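"""Fragment-level methylation quantification over MCB markers.

Paired sequencing reads are merged into cfDNA fragments carrying per-CpG
methylation calls.  Per sample and per MCB the module computes:

* ``coverage``   -- fragments whose span overlaps the block,
* ``n_informative`` -- fragments covering at least ``min_marker_cpgs``
  member CpGs of the block,
* ``mfc``        -- informative fragments whose covered member CpGs are
  all methylated (methylated fragment count),
* ``mfr``        -- ``mfc / n_informative`` (methylated fragment ratio,
  missing when there are no informative fragments).

Fragments, not reads, are the unit of evidence: a single molecule either
derives from tumor (typically fully methylated across a hypermethylated
block) or from normal cfDNA background.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .mcb import MCB

__all__ = [
    "ReadMethylation",
    "Fragment",
    "MarkerQuantification",
    "merge_read_pair",
    "filter_fragments",
    "quantify_sample",
    "quantify_cohort",
    "read_reads_tsv",
    "reads_to_fragments",
]

MIN_FRAGMENT_CPGS = 3


@dataclass(frozen=True)
class ReadMethylation:
    """CpG methylation calls of a single read (one mate of a pair)."""

    read_id: str
    mate: int
    chrom: str
    calls: tuple[tuple[int, bool], ...]  # (0-based CpG pos, methylated?)

    def __post_init__(self) -> None:
        pos = [p for p, _ in self.calls]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise InvalidInputError("read CpG positions must be strictly increasing")


@dataclass(frozen=True)
class Fragment:
    """A merged read pair: span plus the union of CpG calls."""

    sample_id: str
    chrom: str
    start: int
    end: int
    calls: tuple[tuple[int, bool], ...]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidInputError("fragment end must exceed start")

    @property
    def n_cpgs(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class MarkerQuantification:
    sample_id: str
    mcb_id: str
    mfc: int
    n_informative: int
    coverage: int

    @property
    def mfr(self) -> float:
        if self.n_informative == 0:
            return float("nan")
        return self.mfc / self.n_informative


def merge_read_pair(r1: ReadMethylation, r2: ReadMethylation, sample_id: str = "") -> Fragment:
    """Merge mates into a fragment.

    Calls are the position-union of both mates; where the mates disagree
    at a shared CpG the position is dropped (treated as missing) rather
    than called either way.  The fragment span is the union span of all
    called positions (each CpG occupying 2 bp).
    """
    if r1.chrom != r2.chrom:
        raise InvalidInputError(f"mate chromosomes differ: {r1.chrom} vs {r2.chrom}")
    if r1.read_id != r2.read_id:
        raise InvalidInputError("mates must share a read_id")
    merged: dict[int, bool | None] = {}
    for read in (r1, r2):
        for pos, call in read.calls:
            if pos in merged and merged[pos] is not None and merged[pos] != call:
                merged[pos] = None  # mate conflict -> missing
            elif pos not in merged:
                merged[pos] = call
    all_pos = sorted(merged)
    if not all_pos:
        raise InvalidInputError("read pair carries no CpG calls")
    calls = tuple((p, merged[p]) for p in all_pos if merged[p] is not None)
    return Fragment(
        sample_id=sample_id,
        chrom=r1.chrom,
        start=all_pos[0],
        end=all_pos[-1] + 2,
        calls=calls,
    )


def filter_fragments(
    fragments: Iterable[Fragment], min_cpgs: int = MIN_FRAGMENT_CPGS
) -> list[Fragment]:
    """Keep fragments carrying at least ``min_cpgs`` CpG calls."""
    return [f for f in fragments if f.n_cpgs >= min_cpgs]


class _MCBIndex:
    """Per-chromosome interval index for fragment -> MCB overlap lookup."""

    def __init__(self, mcbs: Sequence[MCB]):
        self.by_chrom: dict[str, list[MCB]] = {}
        for m in mcbs:
            self.by_chrom.setdefault(m.chrom, []).append(m)
        self.starts: dict[str, list[int]] = {}
        for chrom, blocks in self.by_chrom.items():
            blocks.sort(key=lambda m: m.start)
            self.starts[chrom] = [m.start for m in blocks]
        self.max_len = {
            chrom: max(m.end - m.start for m in blocks)
            for chrom, blocks in self.by_chrom.items()
        }

    def overlapping(self, chrom: str, start: int, end: int) -> list[MCB]:
        blocks = self.by_chrom.get(chrom)
        if not blocks:
            return []
        starts = self.starts[chrom]
        lo = bisect.bisect_left(starts, start - self.max_len[chrom])
        hi = bisect.bisect_left(starts, end)
        return [m for m in blocks[lo:hi] if m.end > start and m.start < end]


def quantify_sample(
    fragments: Sequence[Fragment],
    mcbs: Sequence[MCB],
    min_marker_cpgs: int = 3,
    sample_id: str | None = None,
) -> list[MarkerQuantification]:
    """Quantify MFC / n_informative / coverage for every MCB of one sample.

    ``fragments`` are assumed pair-merged and globally filtered.  A
    fragment is *informative* for a block when it calls at least
    ``min_marker_cpgs`` of the block's member CpGs; it counts toward the
    MFC when every member CpG it calls is methylated.
    """
    if not mcbs:
        raise InvalidInputError("empty MCB list")
    if sample_id is None:
        sample_id = fragments[0].sample_id if fragments else ""
    index = _MCBIndex(mcbs)
    stats = {m.mcb_id: [0, 0, 0] for m in mcbs}  # mfc, n_informative, coverage
    members = {m.mcb_id: frozenset(m.cpg_positions) for m in mcbs}
    for frag in fragments:
        for m in index.overlapping(frag.chrom, frag.start, frag.end):
            rec = stats[m.mcb_id]
            rec[2] += 1
            mem = members[m.mcb_id]
            covered = [(p, c) for p, c in frag.calls if p in mem]
            if len(covered) >= min_marker_cpgs:
                rec[1] += 1
                if all(c for _, c in covered):
                    rec[0] += 1
    return [
        MarkerQuantification(sample_id, m.mcb_id, *stats[m.mcb_id]) for m in mcbs
    ]


def quantify_cohort(
    fragments_by_sample: dict[str, Sequence[Fragment]],
    mcbs: Sequence[MCB],
    min_marker_cpgs: int = 3,
) -> pd.DataFrame:
    """Long-form marker matrix over samples: one row per (sample, MCB)."""
    rows = []
    for sample_id, frags in fragments_by_sample.items():
        for q in quantify_sample(frags, mcbs, min_marker_cpgs, sample_id=sample_id):
            rows.append(
                (q.sample_id, q.mcb_id, q.mfc, q.n_informative, q.mfr, q.coverage)
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "mcb_id", "mfc", "n_informative", "mfr", "coverage"],
    )


# ---------------------------------------------------------------------------
# I/O

def read_reads_tsv(path: str | Path) -> pd.DataFrame:
    """Read the per-read call table.

    Columns: sample_id, read_id, mate, chrom, cpg_pos_csv, call_string;
    ``call_string`` is an {M,U} string aligned with ``cpg_pos_csv``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"call_string": str, "cpg_pos_csv": str})
    required = {"sample_id", "read_id", "mate", "chrom", "cpg_pos_csv", "call_string"}
    if not required <= set(df.columns):
        raise InvalidInputError(f"reads TSV missing columns {required - set(df.columns)}")
    return df


def reads_to_fragments(
    reads: pd.DataFrame, min_cpgs: int = MIN_FRAGMENT_CPGS
) -> dict[str, list[Fragment]]:
    """Merge the read table into filtered fragments, grouped by sample."""
    out: dict[str, list[Fragment]] = {}
    for (sample_id, read_id), group in reads.groupby(["sample_id", "read_id"], sort=True):
        mates = []
        for row in group.itertuples():
            positions = [int(p) for p in str(row.cpg_pos_csv).split(",")]
            calls = tuple(
                (p, c == "M") for p, c in zip(positions, str(row.call_string))
            )
            mates.append(
                ReadMethylation(str(read_id), int(row.mate), str(row.chrom), calls)
            )
        if len(mates) == 1:
            frag = merge_read_pair(mates[0], mates[0], sample_id=str(sample_id))
        else:
            frag = merge_read_pair(mates[0], mates[1], sample_id=str(sample_id))
        out.setdefault(str(sample_id), [])
        if frag.n_cpgs >= min_cpgs:
            out[str(sample_id)].append(frag)
    return out
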