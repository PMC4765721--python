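"""Scanner tests: loci parsing, filtered pileup, het calling, workflows."""

import pysam
import pytest

from bafgrid.datasets import example_loci_path
from bafgrid.grid import CopyState, GridSolution
from bafgrid.scan import (
    CandidateLocus,
    HetThresholds,
    PileupCounts,
    ScanFilters,
    call_heterozygous,
    cellline_scan,
    load_candidate_loci,
    minor_fraction_biallelic,
    pileup_at_loci,
    read_observations,
    tumour_normal_scan,
    write_observations,
)
from bafgrid.simulate import (
    Segment,
    SegmentProfile,
    SimTruth,
    write_pair_fixtures,
    write_sam_fixture,
)

from conftest import make_truth


def _counts(chrom="1", pos=100, **bases):
    full = dict.fromkeys("ACGT", 0)
    full.update(bases)
    return PileupCounts(CandidateLocus(chrom, pos), full)


class TestLoadCandidateLoci:
    def test_dedup_and_sort(self, tmp_path):
        p = tmp_path / "loci.tsv"
        p.write_text("chrom\tpos\n1\t500\n1\t100\n1\t500\n")
        loci = load_candidate_loci(str(p))
        assert [(l.chrom, l.pos) for l in loci] == [("1", 100), ("1", 500)]

    def test_headerless_file(self, tmp_path):
        p = tmp_path / "loci.tsv"
        p.write_text("1\t100\tA\tC\n2\t200\n")
        loci = load_candidate_loci(str(p))
        assert loci[0].ref == "A" and loci[0].alt == "C"
        assert loci[1].ref is None

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "loci.tsv"
        p.write_text("")
        with pytest.raises(ValueError, match="no loci"):
            load_candidate_loci(str(p))

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "loci.tsv"
        p.write_text("1\t100\n1\tnot-a-number\n")
        with pytest.raises(ValueError, match=":2:"):
            load_candidate_loci(str(p))

    def test_bundled_example_list(self):
        path = example_loci_path()
        with open(path) as fh:
            n_lines = sum(1 for _ in fh)
        loci = load_candidate_loci(path)
        assert len(loci) == n_lines - 1  # header excluded, no duplicates


class TestCallHeterozygous:
    def test_balanced_site_is_het(self):
        assert call_heterozygous(_counts(A=22, C=18))

    def test_homozygous_site_is_not(self):
        assert not call_heterozygous(_counts(A=39, C=1))

    def test_low_depth_is_not(self):
        assert not call_heterozygous(_counts(A=3, C=2))

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            HetThresholds(lo_fraction=0.7, hi_fraction=0.3)


class TestMinorFraction:
    def test_third_allele_ignored_in_denominator(self):
        total, frac = minor_fraction_biallelic(_counts(A=30, C=10, G=2))
        assert total == 40
        assert frac == pytest.approx(0.25)

    def test_bounded_by_half(self):
        _, frac = minor_fraction_biallelic(_counts(A=10, C=10))
        assert frac == 0.5


@pytest.fixture(scope="module")
def fixture_paths(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("sam")
    truth = make_truth([(2, 1), (1, 1)], n_loci=12, cellularity=0.7,
                       single_copy_depth=12.0, seed=5, spacing=60)
    sam = tmp / "fix.sam"
    loci = tmp / "loci.tsv"
    obs = write_sam_fixture(truth, str(sam), str(loci),
                            extra_low_mapq_reads=3)
    return sam, loci, obs


@pytest.fixture(scope="module")
def pair(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("pair")
    truth = make_truth([(3, 1), (2, 0)], n_loci=25, cellularity=0.68,
                       single_copy_depth=15.0, seed=9, spacing=70)
    tum, norm, loci = tmp / "t.sam", tmp / "n.sam", tmp / "loci.tsv"
    write_pair_fixtures(truth, str(tum), str(norm), str(loci))
    return truth, tum, norm, loci


@pytest.fixture(scope="module")
def cellline(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("cl")
    # pure cell line: an LOH segment plus a balanced segment
    truth = SimTruth(
        SegmentProfile((
            Segment("1", 1000, 50_000, CopyState(2, 0), 300),
            Segment("2", 1000, 20_000, CopyState(1, 1), 100),
        )),
        GridSolution(1.0, 20.0), seed=4, spacing=60,
    )
    sam, loci = tmp / "cl.sam", tmp / "loci.tsv"
    write_sam_fixture(truth, str(sam), str(loci))
    return sam, loci


class TestPileup:
    def test_counts_match_simulation_exactly(self, fixture_paths):
        sam, loci_path, obs = fixture_paths
        loci = load_candidate_loci(str(loci_path))
        by_pos = {(r.chrom, r.pos): r for r in obs.itertuples()}
        for pc in pileup_at_loci(str(sam), loci):
            row = by_pos[(pc.locus.chrom, pc.locus.pos)]
            assert pc.depth == row.depth  # low-mapq extras are filtered out
            assert pc.base_counts["C"] == row.alt_count

    def test_low_mapq_reads_counted_when_filter_relaxed(self, fixture_paths):
        sam, loci_path, obs = fixture_paths
        loci = load_candidate_loci(str(loci_path))
        relaxed = pileup_at_loci(str(sam), loci, ScanFilters(min_mapq=0))
        by_pos = {(r.chrom, r.pos): r for r in obs.itertuples()}
        for pc in relaxed:
            assert pc.depth == by_pos[(pc.locus.chrom, pc.locus.pos)].depth + 3

    def test_uncovered_locus_has_zero_depth(self, fixture_paths):
        sam, _, obs = fixture_paths
        lonely = [CandidateLocus(obs.iloc[0].chrom, int(obs.pos.max()) + 10_000)]
        [pc] = pileup_at_loci(str(sam), lonely)
        assert pc.depth == 0 and all(v == 0 for v in pc.base_counts.values())

    def test_absent_contig_omitted_with_warning(self, fixture_paths, caplog):
        sam, _, _ = fixture_paths
        loci = [CandidateLocus("99", 100)]
        with caplog.at_level("WARNING"):
            assert pileup_at_loci(str(sam), loci) == []
        assert "absent" in caplog.text

    def test_chromosome_dialect_mismatch_names_both(self, fixture_paths):
        sam, _, _ = fixture_paths
        with pytest.raises(ValueError, match="'chr1'.*'1'"):
            pileup_at_loci(str(sam), [CandidateLocus("chr1", 100)])

    def test_bam_requires_index(self, fixture_paths, tmp_path):
        sam, loci_path, _ = fixture_paths
        bam = tmp_path / "fix.bam"
        pysam.sort("-o", str(bam), str(sam))
        loci = load_candidate_loci(str(loci_path))
        with pytest.raises(FileNotFoundError, match="samtools index"):
            pileup_at_loci(str(bam), loci)
        pysam.index(str(bam))
        sam_counts = pileup_at_loci(str(sam), loci)
        bam_counts = pileup_at_loci(str(bam), loci)
        assert [pc.base_counts for pc in bam_counts] == [
            pc.base_counts for pc in sam_counts
        ]


class TestTumourNormalScan:
    def test_output_subset_of_normal_het_calls(self, pair):
        _, tum, norm, loci_path = pair
        loci = load_candidate_loci(str(loci_path))
        het = {
            (pc.locus.chrom, pc.locus.pos)
            for pc in pileup_at_loci(str(norm), loci)
            if call_heterozygous(pc)
        }
        obs = tumour_normal_scan(str(tum), str(norm), loci)
        assert set(zip(obs.chrom.astype(str), obs.pos)) <= het

    def test_fractions_on_half_interval_and_near_state_prediction(self, pair):
        truth, tum, norm, loci_path = pair
        obs = tumour_normal_scan(str(tum), str(norm),
                                 load_candidate_loci(str(loci_path)))
        assert (obs.minor_fraction <= 0.5).all()
        assert len(obs) > 0

    def test_deterministic(self, pair, tmp_path):
        _, tum, norm, loci_path = pair
        loci = load_candidate_loci(str(loci_path))
        a = tumour_normal_scan(str(tum), str(norm), loci)
        b = tumour_normal_scan(str(tum), str(norm), loci)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_observations(a, str(pa))
        write_observations(b, str(pb))
        assert pa.read_bytes() == pb.read_bytes()
        assert read_observations(str(pa)).shape == a.shape


class TestCelllineScan:
    def test_loh_downsampled_and_reproducible(self, cellline):
        sam, loci_path = cellline
        loci = load_candidate_loci(str(loci_path))
        kept = cellline_scan(str(sam), loci, loh_keep_fraction=0.1, seed=7)
        again = cellline_scan(str(sam), loci, loh_keep_fraction=0.1, seed=7)
        assert kept.equals(again)
        full = cellline_scan(str(sam), loci, loh_keep_fraction=1.0, seed=7)
        n_loh = (full.minor_fraction < 0.1).sum()
        n_kept_loh = (kept.minor_fraction < 0.1).sum()
        assert n_kept_loh < n_loh  # thinned
        assert 0.02 <= n_kept_loh / n_loh <= 0.3  # near the 0.1 rate

    def test_keep_one_is_identity(self, cellline):
        sam, loci_path = cellline
        loci = load_candidate_loci(str(loci_path))
        full = cellline_scan(str(sam), loci, loh_keep_fraction=1.0, seed=7)
        other_seed = cellline_scan(str(sam), loci, loh_keep_fraction=1.0, seed=8)
        assert full.equals(other_seed)  # no randomness used at rate 1

    def test_balanced_loci_never_downsampled(self, cellline):
        sam, loci_path = cellline
        loci = load_candidate_loci(str(loci_path))
        full = cellline_scan(str(sam), loci, loh_keep_fraction=1.0, seed=7)
        kept = cellline_scan(str(sam), loci, loh_keep_fraction=0.05, seed=7)
        balanced_full = full[full.minor_fraction >= 0.1]
        balanced_kept = kept[kept.minor_fraction >= 0.1]
        assert len(balanced_full) == len(balanced_kept)

    def test_parameter_validation(self, cellline):
        sam, loci_path = cellline
        loci = load_candidate_loci(str(loci_path))
        with pytest.raises(ValueError):
            cellline_scan(str(sam), loci, loh_threshold=0.6)
        with pytest.raises(ValueError):
            cellline_scan(str(sam), loci, loh_keep_fraction=0.0)
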