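"""Per-locus depth and minor-allele-fraction extraction from alignments.

Candidate germline-heterozygous sites (a TSV of chrom/pos, e.g. derived
from a common-SNP catalogue) are interrogated in tumour and, optionally,
matched-normal alignment files.  At each site, reads passing mapping- and
base-quality filters are counted per nucleotide; the observed minor
fraction is computed over the two most frequent bases (the model is
biallelic).  Two workflows are provided:

* :func:`tumour_normal_scan` — sites are first called heterozygous in the
  normal, then the normal's two alleles are counted in the tumour.
* :func:`cellline_scan` — without a normal, sites that have lost
  heterozygosity are indistinguishable from germline-homozygous ones and
  would drown out the informative loci; sites below an allele-fraction
  threshold are therefore down-sampled at a configurable rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

OBSERVATION_COLUMNS = ["chrom", "pos", "depth", "minor_fraction"]
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class CandidateLocus:
    """A candidate heterozygous site (1-based, VCF-style coordinates)."""

    chrom: str
    pos: int
    ref: Optional[str] = None
    alt: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass
class PileupCounts:
    """Filtered per-base read counts at one locus."""

    locus: CandidateLocus
    base_counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())

    def top_two(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """The two most frequent bases (count desc, base name as tie-break)."""
        ranked = sorted(self.base_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[0], ranked[1]


@dataclass(frozen=True)
class ScanFilters:
    """Read/base quality filters applied during pileup."""

    min_mapq: int = 30
    min_baseq: int = 20
    min_depth: int = 15


@dataclass(frozen=True)
class HetThresholds:
    """Heterozygous-call window on the second-allele fraction."""

    min_depth: int = 15
    lo_fraction: float = 0.3
    hi_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 < self.lo_fraction < self.hi_fraction < 1.0:
            raise ValueError(
                f"need 0 < lo < hi < 1, got [{self.lo_fraction}, {self.hi_fraction}]"
            )


def load_candidate_loci(path: str) -> list[CandidateLocus]:
    """Read a loci TSV with columns chrom, pos[, ref, alt].

    A header line is detected by a non-numeric pos field.  Loci are
    returned sorted by (chrom, pos); duplicates are dropped with a
    warning.  Malformed rows raise with their line number.
    """
    loci: list[CandidateLocus] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated fields")
            try:
                pos = int(fields[1])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(
                    f"{path}:{lineno}: non-integer position {fields[1]!r}"
                ) from None
            ref = fields[2].strip().upper() if len(fields) > 2 and fields[2].strip() else None
            alt = fields[3].strip().upper() if len(fields) > 3 and fields[3].strip() else None
            try:
                loci.append(CandidateLocus(fields[0].strip(), pos, ref, alt))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not loci:
        raise ValueError(f"no loci found in {path}")
    seen: set[tuple[str, int]] = set()
    unique: list[CandidateLocus] = []
    dups = 0
    for loc in sorted(loci, key=lambda l: (l.chrom, l.pos)):
        key = (loc.chrom, loc.pos)
        if key in seen:
            dups += 1
            continue
        seen.add(key)
        unique.append(loc)
    if dups:
        logger.warning("dropped %d duplicate loci from %s", dups, path)
    return unique


def _check_chrom_dialects(loci_chroms: set[str], references: set[str], path: str) -> set[str]:
    """Return loci chroms present in the file; raise on chr/no-chr mismatch."""
    missing = loci_chroms - references
    for chrom in sorted(missing):
        alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
        if alt in references:
            raise ValueError(
                f"chromosome-name dialect mismatch: loci use {chrom!r} but "
                f"{path} names it {alt!r}; rename one side (no automatic "
                "translation is applied)"
            )
    if missing:
        logger.warning(
            "omitting loci on %d contig(s) absent from %s: %s",
            len(missing), path, ", ".join(sorted(missing)),
        )
    return loci_chroms & references


def _count_read(
    read: pysam.AlignedSegment,
    pos_index: dict[int, int],
    counts: list[dict[str, int]],
    filters: ScanFilters,
) -> None:
    if (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.is_qcfail
    ):
        return
    if read.mapping_quality < filters.min_mapq:
        return
    seq = read.query_sequence
    if seq is None:
        return
    quals = read.query_qualities
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        idx = pos_index.get(rpos + 1)
        if idx is None:
            continue
        if quals is not None and quals[qpos] < filters.min_baseq:
            continue
        base = seq[qpos].upper()
        if base in _BASES:
            counts[idx][base] += 1


def pileup_at_loci(
    alignment_path: str,
    loci: Sequence[CandidateLocus],
    filters: ScanFilters = ScanFilters(),
) -> list[PileupCounts]:
    """Filtered A/C/G/T counts at each candidate locus.

    Accepts an indexed BAM (random access per chromosome) or a SAM text
    file (single streaming pass).  Reads flagged duplicate/secondary/
    supplementary/QC-fail, reads below ``min_mapq`` and bases below
    ``min_baseq`` are excluded.  Loci on contigs absent from the header
    are omitted with a warning; a chr-prefix dialect mismatch raises.
    """
    is_bam = str(alignment_path).endswith((".bam", ".cram"))
    mode = "rb" if is_bam else "r"
    with pysam.AlignmentFile(alignment_path, mode) as af:
        if is_bam and not af.has_index():
            raise FileNotFoundError(
                f"{alignment_path} has no index; create one with "
                f"'samtools index {alignment_path}' (pysam.index also works)"
            )
        references = set(af.references)
        present = _check_chrom_dialects({l.chrom for l in loci}, references,
                                        str(alignment_path))
        kept = [l for l in loci if l.chrom in present]
        counts: list[dict[str, int]] = [dict.fromkeys(_BASES, 0) for _ in kept]
        index_by_chrom: dict[str, dict[int, int]] = {}
        for i, loc in enumerate(kept):
            index_by_chrom.setdefault(loc.chrom, {})[loc.pos] = i
        if is_bam:
            for chrom, pos_index in index_by_chrom.items():
                for read in af.fetch(chrom):
                    _count_read(read, pos_index, counts, filters)
        else:
            for read in af.fetch(until_eof=True):
                if read.reference_name in index_by_chrom:
                    _count_read(read, index_by_chrom[read.reference_name],
                                counts, filters)
    return [PileupCounts(loc, c) for loc, c in zip(kept, counts)]


def call_heterozygous(
    counts: PileupCounts, thresholds: HetThresholds = HetThresholds()
) -> bool:
    """True iff the site looks germline heterozygous.

    Requires total filtered depth >= min_depth and the second-most-
    frequent base's share of total depth inside [lo, hi].
    """
    depth = counts.depth
    if depth < thresholds.min_depth:
        return False
    (_, c1), (_, c2) = counts.top_two()
    frac = c2 / depth
    return thresholds.lo_fraction <= frac <= thresholds.hi_fraction


def minor_fraction_biallelic(counts: PileupCounts,
                             alleles: Optional[tuple[str, str]] = None
                             ) -> tuple[int, float]:
    """(two-allele depth, minor fraction) over the given or top-two bases.

    Third-allele reads are ignored in the denominator: the model is
    biallelic, which keeps observed fractions on the same scale as the
    predictions.
    """
    if alleles is None:
        (b1, c1), (b2, c2) = counts.top_two()
    else:
        b1, b2 = alleles
        c1 = counts.base_counts.get(b1, 0)
        c2 = counts.base_counts.get(b2, 0)
    total = c1 + c2
    if total == 0:
        return 0, float("nan")
    return total, min(c1, c2) / total


def _observation_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def tumour_normal_scan(
    tumour_path: str,
    normal_path: str,
    loci: Sequence[CandidateLocus],
    filters: ScanFilters = ScanFilters(),
    het: HetThresholds = HetThresholds(),
) -> pd.DataFrame:
    """Observations at loci called heterozygous in the matched normal.

    The normal defines the two alleles at each het site; the tumour's
    minor fraction is computed over those two alleles only.  Tumour loci
    below the depth filter are dropped.
    """
    normal_counts = pileup_at_loci(normal_path, loci, filters)
    het_sites = [pc for pc in normal_counts if call_heterozygous(pc, het)]
    logger.info("%d/%d loci called heterozygous in %s",
                len(het_sites), len(normal_counts), normal_path)
    if not het_sites:
        return _observation_frame([])
    alleles = {
        (pc.locus.chrom, pc.locus.pos): (pc.top_two()[0][0], pc.top_two()[1][0])
        for pc in het_sites
    }
    tumour_counts = pileup_at_loci(tumour_path, [pc.locus for pc in het_sites],
                                   filters)
    rows = []
    for pc in tumour_counts:
        if pc.depth < filters.min_depth:
            continue
        pair = alleles[(pc.locus.chrom, pc.locus.pos)]
        total, frac = minor_fraction_biallelic(pc, pair)
        if total == 0:
            continue
        rows.append(
            {"chrom": pc.locus.chrom, "pos": pc.locus.pos,
             "depth": pc.depth, "minor_fraction": frac}
        )
    return _observation_frame(rows)


def cellline_scan(
    tumour_path: str,
    loci: Sequence[CandidateLocus],
    filters: ScanFilters = ScanFilters(),
    loh_threshold: float = 0.1,
    loh_keep_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Standalone (no matched normal) scan with LOH down-sampling.

    All sufficiently covered loci are observed; those with minor fraction
    below ``loh_threshold`` — indistinguishable from germline-homozygous
    sites in a pure cell line — are randomly retained at rate
    ``loh_keep_fraction`` (seeded, reproducible).
    """
    if not 0.0 < loh_threshold < 0.5:
        raise ValueError(f"loh_threshold must be in (0, 0.5), got {loh_threshold}")
    if not 0.0 < loh_keep_fraction <= 1.0:
        raise ValueError(
            f"loh_keep_fraction must be in (0, 1], got {loh_keep_fraction}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    n_loh = n_kept = 0
    for pc in pileup_at_loci(tumour_path, loci, filters):
        if pc.depth < filters.min_depth:
            continue
        total, frac = minor_fraction_biallelic(pc)
        if total == 0:
            continue
        if frac < loh_threshold:
            n_loh += 1
            if loh_keep_fraction < 1.0 and rng.random() >= loh_keep_fraction:
                continue
            n_kept += 1
        rows.append(
            {"chrom": pc.locus.chrom, "pos": pc.locus.pos,
             "depth": pc.depth, "minor_fraction": frac}
        )
    if n_loh:
        logger.info("retained %d of %d LOH-like loci (threshold %g, rate %g)",
                    n_kept, n_loh, loh_threshold, loh_keep_fraction)
    return _observation_frame(rows)


def write_observations(df: pd.DataFrame, path: str) -> None:
    """Write an observation table (chrom, pos, depth, minor_fraction) as TSV."""
    df[OBSERVATION_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_observations(path: str) -> pd.DataFrame:
    """Read an observation TSV produced by :func:`write_observations`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path} missing columns: {sorted(missing)}")
    return df
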