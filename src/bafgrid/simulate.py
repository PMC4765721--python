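"""Synthetic locus observations and SAM fixtures from a known truth.

The generator draws, per candidate heterozygous locus, a total read depth
(Poisson around the mixture-model prediction, or fixed) and a count of
reads carrying one *phased* allele, Binomial(depth, p) with

    p = (C * n2 + (1 - C)) / (C * (n1 + n2) + 2 * (1 - C))

— the phased-allele fraction implied by the mixture model (algebraically
the unfolded minor-fraction prediction).  The recorded minor fraction is
``min(b, depth - b) / depth``, so the fold at 0.5 arises naturally from
the per-locus choice of minor allele rather than being injected.

:func:`write_sam_fixture` turns the same draws into a small, valid,
coordinate-sorted SAM file plus its candidate-loci table, so the scanner
can be tested end-to-end: scanning the fixture reproduces the simulated
per-locus counts exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import CopyState, GridSolution, predicted_depth

logger = logging.getLogger(__name__)

MAX_FIXTURE_READS = 100_000
_REF_BASE = "A"
_ALT_BASE = "C"


@dataclass(frozen=True)
class Segment:
    """A genomic segment with one clonal copy-number state."""

    chrom: str
    start: int
    end: int
    state: CopyState
    n_loci: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad segment bounds {self.start}-{self.end}")
        if self.n_loci < 0:
            raise ValueError("n_loci must be >= 0")
        if self.n_loci > (self.end - self.start + 1):
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end} too short "
                f"for {self.n_loci} loci"
            )


@dataclass(frozen=True)
class SegmentProfile:
    """Non-overlapping segments describing a clonal copy-number profile."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping segments on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.segments],
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "n1": [s.state.n1 for s in self.segments],
                "n2": [s.state.n2 for s in self.segments],
                "n_loci": [s.n_loci for s in self.segments],
            }
        )


def read_profile(path: str) -> SegmentProfile:
    """Load a profile TSV (chrom, start, end, n1, n2, n_loci)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "n1", "n2", "n_loci"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile missing columns: {sorted(missing)}")
    segs = tuple(
        Segment(
            str(r.chrom), int(r.start), int(r.end),
            CopyState(int(r.n1), int(r.n2)), int(r.n_loci),
        )
        for r in df.itertuples()
    )
    return SegmentProfile(segs)


def write_profile(profile: SegmentProfile, path: str) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SimTruth:
    """A generating model: profile + (C, D) solution + noise + seed."""

    profile: SegmentProfile
    solution: GridSolution
    seed: int = 0
    depth_noise: str = "poisson"  # "poisson" | "fixed"
    spacing: int = field(default=0)  # 0 -> spread loci evenly over the segment

    def __post_init__(self) -> None:
        if self.depth_noise not in ("poisson", "fixed"):
            raise ValueError(f"unknown depth_noise {self.depth_noise!r}")


def phased_allele_fraction(solution: GridSolution, state: CopyState) -> float:
    """Fraction of reads from one fixed (phased) parental allele.

    Equals the unfolded minor-fraction prediction; exposed separately
    because simulation tracks a *fixed* allele, whose mean fraction in a
    balanced region is exactly 0.5.
    """
    c = solution.cellularity
    denom = c * state.total + 2.0 * (1.0 - c)
    if denom <= 0.0:
        raise ValueError(
            f"degenerate pure-tumour state ({state.n1},{state.n2}) has no reads"
        )
    return (c * state.n2 + (1.0 - c)) / denom


def _segment_positions(seg: Segment, spacing: int) -> np.ndarray:
    if seg.n_loci == 0:
        return np.array([], dtype=int)
    if spacing > 0:
        pos = seg.start + spacing * np.arange(seg.n_loci)
        if pos[-1] > seg.end:
            raise ValueError(
                f"segment {seg.chrom}:{seg.start}-{seg.end} too short for "
                f"{seg.n_loci} loci at spacing {spacing}"
            )
        return pos
    return np.unique(
        np.linspace(seg.start, seg.end, seg.n_loci).round().astype(int)
    )


def simulate_observations(truth: SimTruth) -> pd.DataFrame:
    """Draw per-locus observations from `truth`.

    Returns a frame with the observation columns (chrom, pos, depth,
    minor_fraction) plus per-locus truth bookkeeping: n1, n2, the phased
    allele count ``alt_count`` and its fraction ``phased_fraction``, and
    the model-expected depth.  Zero-depth draws are dropped (logged).
    Deterministic for a given truth (seed included).
    """
    rng = np.random.default_rng(truth.seed)
    frames = []
    n_zero = 0
    for seg in truth.profile.segments:
        if seg.n_loci == 0:
            continue
        p = phased_allele_fraction(truth.solution, seg.state)  # rejects (0,0) @ C=1
        mean_depth = predicted_depth(truth.solution, seg.state)
        pos = _segment_positions(seg, truth.spacing)
        n = len(pos)
        if truth.depth_noise == "poisson":
            depth = rng.poisson(mean_depth, size=n)
        else:
            depth = np.full(n, max(int(round(mean_depth)), 0))
        keep = depth > 0
        n_zero += int((~keep).sum())
        depth = depth[keep]
        pos = pos[keep]
        alt = rng.binomial(depth, p)
        minor = np.minimum(alt, depth - alt) / depth
        frames.append(
            pd.DataFrame(
                {
                    "chrom": seg.chrom,
                    "pos": pos,
                    "depth": depth,
                    "minor_fraction": minor,
                    "alt_count": alt,
                    "phased_fraction": alt / depth,
                    "n1": seg.state.n1,
                    "n2": seg.state.n2,
                    "expected_depth": mean_depth,
                }
            )
        )
    if not frames:
        raise ValueError("profile produced no loci")
    if n_zero:
        logger.info("dropped %d zero-depth loci", n_zero)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def example_tetraploid_truth(
    loci_per_segment: int = 300,
    cellularity: float = 0.68,
    single_copy_depth: float = 15.0,
    seed: int = 0,
    spacing: int = 0,
) -> SimTruth:
    """A broadly tetraploid genome at 68% cellularity.

    Five clonal states — (2,0), (2,1), (2,2), (3,1), (4,2) — that a
    "diploid impostor" solution at higher cellularity can only partially
    explain: the odd-total states fall between its grid rows, mimicking
    the classic purity/ploidy ambiguity between a tetraploid solution and
    a hypo-diploid one with apparent sub-clonal mass.
    """
    states = [(2, 0), (2, 1), (2, 2), (3, 1), (4, 2)]
    span = max(loci_per_segment * max(spacing, 1) + 1, 10 * loci_per_segment)
    segs = tuple(
        Segment("1", 1 + i * (span + 10), (1 + i * (span + 10)) + span - 1,
                CopyState(n1, n2), loci_per_segment)
        for i, (n1, n2) in enumerate(states)
    )
    return SimTruth(
        SegmentProfile(segs),
        GridSolution(cellularity, single_copy_depth),
        seed=seed,
        spacing=spacing,
    )


def _sam_header_lines(chrom_lengths: dict[str, int]) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    return lines


def write_sam_fixture(
    truth: SimTruth,
    sam_path: str,
    loci_path: str,
    read_length: int = 50,
    base_quality: int = 40,
    mapping_quality: int = 60,
    extra_low_mapq_reads: int = 0,
    low_mapq: int = 5,
) -> pd.DataFrame:
    """Write a SAM file realising `truth`'s draws, plus its loci TSV.

    Every simulated locus gets exactly ``depth`` reads (``alt_count`` of
    them carrying the alternate base), all above the default quality
    filters, so a scan of the fixture reproduces the simulated counts
    read-for-read.  Adjacent loci must be at least one read length apart
    (each read then covers exactly one candidate locus).
    ``extra_low_mapq_reads`` adds per-locus reference reads below the
    default mapping-quality filter, for filter testing.

    Returns the simulated observation frame the fixture encodes.
    """
    if truth.spacing and truth.spacing < read_length:
        raise ValueError("locus spacing must be >= read_length for SAM fixtures")
    obs = simulate_observations(truth)
    for chrom, grp in obs.groupby("chrom"):
        gaps = np.diff(np.sort(grp["pos"].to_numpy()))
        if len(gaps) and gaps.min() < read_length:
            raise ValueError(
                f"loci on {chrom} closer than read_length={read_length}; "
                "use a wider segment or explicit spacing"
            )
    n_reads = int(obs["depth"].sum()) + extra_low_mapq_reads * len(obs)
    if n_reads > MAX_FIXTURE_READS:
        raise ValueError(f"fixture would hold {n_reads} reads (max {MAX_FIXTURE_READS})")

    chrom_lengths = {
        str(chrom): int(grp["pos"].max()) + read_length + 10
        for chrom, grp in obs.groupby("chrom")
    }
    qual = chr(33 + base_quality) * read_length
    cigar = f"{read_length}M"
    records: list[tuple[str, int, str]] = []
    for row in obs.itertuples():
        pos, depth, alt = int(row.pos), int(row.depth), int(row.alt_count)
        for j in range(depth + extra_low_mapq_reads):
            start = max(1, pos - (j % read_length))
            seq = list(_REF_BASE * read_length)
            if j < alt:
                seq[pos - start] = _ALT_BASE
            mq = mapping_quality if j < depth else low_mapq
            name = f"sim_{row.chrom}_{pos}_{j}"
            records.append(
                (
                    str(row.chrom),
                    start,
                    f"{name}\t0\t{row.chrom}\t{start}\t{mq}\t{cigar}\t*\t0\t0\t"
                    f"{''.join(seq)}\t{qual}",
                )
            )
    chrom_order = {c: i for i, c in enumerate(chrom_lengths)}
    records.sort(key=lambda r: (chrom_order[r[0]], r[1]))
    with open(sam_path, "w") as fh:
        for line in _sam_header_lines(chrom_lengths):
            fh.write(line + "\n")
        for _, _, line in records:
            fh.write(line + "\n")

    loci = obs[["chrom", "pos"]].copy()
    loci["ref"] = _REF_BASE
    loci["alt"] = _ALT_BASE
    loci.to_csv(loci_path, sep="\t", index=False)
    return obs


def write_pair_fixtures(
    truth: SimTruth,
    tumour_sam: str,
    normal_sam: str,
    loci_path: str,
    read_length: int = 50,
    **fixture_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched tumour/normal SAM fixtures sharing one loci table.

    The normal is pure diploid at every locus (cellularity 0, so depth
    2 D and balanced alleles) — definitionally what germline-heterozygous
    means — simulated with an offset seed.
    """
    normal_truth = SimTruth(
        truth.profile,
        GridSolution(0.0, truth.solution.single_copy_depth),
        seed=truth.seed + 1,
        depth_noise=truth.depth_noise,
        spacing=truth.spacing,
    )
    tum_obs = write_sam_fixture(truth, tumour_sam, loci_path,
                                read_length=read_length, **fixture_kwargs)
    norm_obs = write_sam_fixture(normal_truth, normal_sam, loci_path,
                                 read_length=read_length, **fixture_kwargs)
    return tum_obs, norm_obs
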