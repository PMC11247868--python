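"""Synthetic cfDNA methylation cohorts for end-to-end pipeline testing.

The generator emulates the statistical structure the pipeline assumes:

* healthy plasma background: per-sample, per-marker baseline methylated
  fragment rates drawn from a Beta distribution concentrated near zero
  (most cfDNA fragments at a hypermethylation marker are unmethylated in
  healthy donors);
* cancer-type-specific signatures: each class hypermethylates a fixed
  marker subset; signatures of different classes partially overlap;
* tumor-fraction dilution: a cancer sample's methylated fragment rate at
  a signature marker is the ctDNA mixture ``(1 - theta) * r0 + theta *
  r_tumor`` with the tumor fraction ``theta`` growing with stage;
* fragment counting noise: the informative fragment count is negative
  binomial, the methylated fragment count binomial given the rate.

Everything is seeded; the ground-truth signature map and per-sample
theta are recorded so recovery tests can check selection and scoring
against the planted truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .matrix import CANCER_CLASSES, HEALTHY_LABEL, MarkerMatrix, STAGES
from .mcb import MCB, BetaMatrix
from .fragments import Fragment

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_beta_matrix",
    "simulate_marker_matrix",
    "simulate_fragments",
    "mcb_scaffold",
    "stratified_split",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale analogue of a multi-cancer plasma
    study: 200 healthy controls plus 40 patients for each of the seven
    cancer classes, with a stage mix matching the roughly one-third
    early-stage fraction seen in clinical multi-cancer cohorts.
    """

    n_markers: int = 150
    n_healthy: int = 200
    n_per_class: int = 40
    #: fraction of each class at stages I-IV
    stage_weights: tuple[float, ...] = (0.18, 0.18, 0.32, 0.32)
    #: healthy baseline methylated-fragment rate ~ Beta(a0, b0)
    baseline_beta: tuple[float, float] = (1.0, 60.0)
    #: methylated-fragment rate of pure tumor DNA at a signature marker
    tumor_methylation: float = 0.6
    signature_size: int = 12
    #: pairwise Jaccard overlap between class signatures
    signature_jaccard: float = 0.1
    #: ctDNA tumor fraction by stage I-IV
    theta_by_stage: tuple[float, ...] = (0.004, 0.01, 0.03, 0.08)
    #: informative fragments per marker: NegBin(mean, dispersion=size)
    frag_mean: float = 40.0
    frag_dispersion: float = 5.0
    coverage_inflation: float = 1.2
    # beta-matrix mode (MCB-calling fixtures)
    n_blocks: int = 10
    block_size: int = 4
    within_block_corr: float = 0.99
    intra_spacing: int = 30
    inter_spacing: int = 500
    n_beta_samples: int = 130
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.stage_weights), 1.0, abs_tol=1e-9):
            raise InvalidInputError("stage weights must sum to 1")
        if any(t2 < t1 for t1, t2 in zip(self.theta_by_stage, self.theta_by_stage[1:])):
            raise InvalidInputError("theta must be non-decreasing across stages")
        if not all(0 <= t <= 1 for t in self.theta_by_stage):
            raise InvalidInputError("theta values must be rates in [0, 1]")
        if not 0 <= self.tumor_methylation <= 1:
            raise InvalidInputError("tumor methylation must be a rate in [0, 1]")
        if self.coverage_inflation < 1:
            raise InvalidInputError("coverage inflation must be >= 1")
        if min(self.n_markers, self.n_healthy, self.n_per_class,
               self.signature_size) <= 0:
            raise InvalidInputError("counts must be positive")


@dataclass
class SimulatedCohort:
    sheet: pd.DataFrame
    matrix: MarkerMatrix
    signatures: dict[str, list[str]]
    theta: pd.Series  # per-sample tumor fraction
    config: SimulationConfig

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        self.matrix.to_tsv(outdir / "marker_matrix.tsv")
        truth = {
            "signatures": self.signatures,
            "theta": {k: float(v) for k, v in self.theta.items()},
            "config": asdict(self.config),
        }
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def _signatures(config: SimulationConfig, rng: np.random.Generator) -> dict[str, list[str]]:
    """Plant per-class marker signatures with the configured pairwise Jaccard.

    Each class signature = a common shared core (identical across
    classes) plus class-private markers; for sets of size s sharing c
    markers the Jaccard index is c / (2s - c).
    """
    s = config.signature_size
    j = config.signature_jaccard
    shared = int(round(2 * s * j / (1 + j)))
    n_private = s - shared
    needed = shared + n_private * len(CANCER_CLASSES)
    if needed > config.n_markers:
        raise InvalidInputError("n_markers too small for the requested signatures")
    marker_ids = [f"mcb_{i+1:05d}" for i in range(config.n_markers)]
    chosen = rng.choice(config.n_markers, size=needed, replace=False)
    core = [marker_ids[i] for i in chosen[:shared]]
    out = {}
    for c, cls in enumerate(CANCER_CLASSES):
        lo = shared + c * n_private
        private = [marker_ids[i] for i in chosen[lo : lo + n_private]]
        out[cls] = sorted(core + private)
    return out


def _stage_counts(n: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n samples over the stages."""
    raw = [w * n for w in weights]
    counts = [int(math.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def simulate_marker_matrix(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Generate a marker matrix + sample sheet with planted class signal."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    signatures = _signatures(config, rng)
    marker_ids = [f"mcb_{i+1:05d}" for i in range(config.n_markers)]
    marker_pos = {m: i for i, m in enumerate(marker_ids)}

    rows: list[tuple[str, str, str]] = []  # sample, label, stage
    for i in range(config.n_healthy):
        rows.append((f"H{i+1:04d}", HEALTHY_LABEL, ""))
    for cls in CANCER_CLASSES:
        counts = _stage_counts(config.n_per_class, config.stage_weights)
        i = 0
        for stage, k in zip(STAGES, counts):
            for _ in range(k):
                i += 1
                rows.append((f"{cls}{i:04d}", cls, stage))
    sheet = pd.DataFrame(rows, columns=["sample_id", "label", "stage"])

    theta_map = dict(zip(STAGES, config.theta_by_stage))
    theta = sheet.apply(
        lambda r: theta_map.get(r["stage"], 0.0) if r["label"] != HEALTHY_LABEL else 0.0,
        axis=1,
    )
    theta.index = sheet["sample_id"]

    a0, b0 = config.baseline_beta
    n = len(sheet)
    p = config.n_markers
    r0 = rng.beta(a0, b0, size=(n, p))
    r = r0.copy()
    for i, (sample, label) in enumerate(zip(sheet["sample_id"], sheet["label"])):
        th = theta[sample]
        if label != HEALTHY_LABEL and th > 0:
            cols = [marker_pos[m] for m in signatures[label]]
            r[i, cols] = (1 - th) * r0[i, cols] + th * config.tumor_methylation
    size = config.frag_dispersion
    prob = size / (size + config.frag_mean)
    n_inf = rng.negative_binomial(size, prob, size=(n, p))
    n_inf = np.maximum(n_inf, 1)
    mfc = rng.binomial(n_inf, r)
    coverage = np.ceil(config.coverage_inflation * n_inf).astype(int)

    matrix = MarkerMatrix(
        mfc=pd.DataFrame(mfc, index=sheet["sample_id"], columns=marker_ids),
        n_informative=pd.DataFrame(n_inf, index=sheet["sample_id"], columns=marker_ids),
        coverage=pd.DataFrame(coverage, index=sheet["sample_id"], columns=marker_ids),
    )
    sheet = stratified_split(sheet, ratio=config.train_fraction, seed=config.seed + 1)
    return SimulatedCohort(
        sheet=sheet, matrix=matrix, signatures=signatures, theta=theta, config=config
    )


def stratified_split(
    sheet: pd.DataFrame, ratio: float = 0.7, seed: int = 0
) -> pd.DataFrame:
    """Assign train/test splits stratified by (label, stage).

    Per stratum ``round(ratio * n)`` samples go to train (a singleton
    stratum goes to train); deterministic given the seed.
    """
    if sheet.empty:
        raise InvalidInputError("empty sample sheet")
    rng = np.random.default_rng(seed)
    sheet = sheet.copy()
    sheet["split"] = ""
    stage = sheet.get("stage", pd.Series("", index=sheet.index)).fillna("")
    for _, idx in sheet.groupby([sheet["label"], stage], sort=True).groups.items():
        idx = np.array(sorted(idx))
        n_train = int(math.floor(ratio * len(idx) + 0.5))
        perm = rng.permutation(len(idx))
        sheet.loc[idx[perm[:n_train]], "split"] = "train"
        sheet.loc[idx[perm[n_train:]], "split"] = "test"
    return sheet


# ---------------------------------------------------------------------------
# beta-matrix mode: planted correlated blocks for MCB-calling fixtures

def simulate_beta_matrix(config: SimulationConfig | None = None) -> BetaMatrix:
    """Beta matrix with planted co-methylated CpG blocks.

    Within a block every CpG shares a latent per-sample methylation level
    plus small independent noise, so adjacent correlations approach 1;
    blocks are separated by more than the calling gap so they cannot
    chain together.
    """
    config = config or SimulationConfig()
    if config.block_size < 3:
        raise InvalidInputError("block size must be >= 3")
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_beta_samples
    rho = config.within_block_corr
    if not 0 <= rho <= 1:
        raise InvalidInputError("within-block correlation must be in [0, 1]")
    chroms, positions, values = [], [], []
    pos = 1000
    noise_sd = math.sqrt(1 - rho**2)
    for b in range(config.n_blocks):
        latent = rng.normal(size=n_samples)
        for k in range(config.block_size):
            site = rho * latent + noise_sd * rng.normal(size=n_samples)
            beta = 1 / (1 + np.exp(-site))  # squash to (0, 1)
            chroms.append("chr1")
            positions.append(pos)
            values.append(beta)
            pos += config.intra_spacing
        pos += config.inter_spacing
    sites = pd.DataFrame({"chrom": chroms, "pos": positions})
    return BetaMatrix(
        sites=sites,
        values=np.array(values),
        samples=[f"T{i+1:03d}" for i in range(n_samples)],
    )


def mcb_scaffold(
    marker_ids: Sequence[str], n_cpgs: int = 3, spacing: int = 30, gap: int = 1000
) -> list[MCB]:
    """Genomic scaffold giving each marker an MCB with ``n_cpgs`` members."""
    out, pos = [], 1000
    for m in marker_ids:
        members = tuple(pos + k * spacing for k in range(n_cpgs))
        out.append(MCB(mcb_id=str(m), chrom="chr1", cpg_positions=members))
        pos = members[-1] + gap
    return out


def simulate_fragments(
    cohort: SimulatedCohort,
    mcbs: Sequence[MCB] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emit a per-read call table that reproduces the marker matrix.

    For each (sample, marker) cell the function writes ``mfc`` fully
    methylated informative fragments, ``n_informative - mfc`` fragments
    with one random member CpG unmethylated, and ``coverage -
    n_informative`` overlapping-but-uninformative fragments (two member
    CpGs plus one filler CpG just outside the block, so they survive the
    global >= 3-call filter without informing the marker).  Quantifying
    the emitted reads recovers mfc / n_informative / coverage exactly.
    """
    matrix = cohort.matrix
    if mcbs is None:
        mcbs = mcb_scaffold(list(matrix.markers))
    by_id = {m.mcb_id: m for m in mcbs}
    missing = [m for m in matrix.markers if m not in by_id]
    if missing:
        raise InvalidInputError(f"no MCB for markers {missing[:5]}")
    rng = np.random.default_rng(cohort.config.seed + 7 if seed is None else seed)
    records = []
    read_no = 0
    for sample in matrix.samples:
        for marker in matrix.markers:
            block = by_id[marker]
            members = block.cpg_positions
            if len(members) < 3:
                raise InvalidInputError("scaffold MCBs need >= 3 member CpGs")
            mfc = int(matrix.mfc.loc[sample, marker])
            n_inf = int(matrix.n_informative.loc[sample, marker])
            cov = int(matrix.coverage.loc[sample, marker])
            unmeth_at = rng.integers(0, len(members), size=n_inf - mfc)
            for i in range(n_inf):
                read_no += 1
                calls = ["M"] * len(members)
                if i >= mfc:
                    calls[unmeth_at[i - mfc]] = "U"
                half = max(1, len(members) // 2)
                records.append(
                    (sample, f"r{read_no:08d}", 1, block.chrom,
                     ",".join(map(str, members[:half])), "".join(calls[:half]))
                )
                records.append(
                    (sample, f"r{read_no:08d}", 2, block.chrom,
                     ",".join(map(str, members[half:])), "".join(calls[half:]))
                )
            filler = block.end + 10  # outside the block, inside the scaffold gap
            for _ in range(cov - n_inf):
                read_no += 1
                records.append(
                    (sample, f"r{read_no:08d}", 1, block.chrom,
                     ",".join(map(str, members[:2])), "MM")
                )
                records.append(
                    (sample, f"r{read_no:08d}", 2, block.chrom, str(filler), "U")
                )
    return pd.DataFrame(
        records,
        columns=["sample_id", "read_id", "mate", "chrom", "cpg_pos_csv", "call_string"],
    )
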