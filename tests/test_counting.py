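import gzip

import numpy as np
import pytest

from screenhit.counting import (
    AMBIGUOUS,
    ASSIGNED,
    DEFAULT_ANCHOR,
    NO_ANCHOR,
    NO_MATCH,
    SHORT_TAIL,
    ExtractionParams,
    GuideIndex,
    assign_read,
    count_reads,
    extract_protospacer,
)
from screenhit.errors import FastqParseError, InputError
from screenhit.library import GuideLibrary, GuideRecord

PARAMS = ExtractionParams()


class TestExtractProtospacer:
    def test_takes_20nt_after_first_anchor_occurrence(self):
        proto = "ACGTACGTACGTACGTACGT"
        status, got = extract_protospacer(
            "TT" + DEFAULT_ANCHOR + proto + "GTTTTAGAGC", PARAMS
        )
        assert (status, got) == (ASSIGNED, proto)

    def test_read_without_anchor(self):
        assert extract_protospacer("A" * 80, PARAMS)[0] == NO_ANCHOR

    def test_short_tail_boundary(self):
        status, _ = extract_protospacer(DEFAULT_ANCHOR + "ACGTACGTAC", PARAMS)
        assert status == SHORT_TAIL
        # exactly 20 bases after the anchor is enough
        status, got = extract_protospacer(DEFAULT_ANCHOR + "A" * 20, PARAMS)
        assert status == ASSIGNED and got == "A" * 20

    def test_first_occurrence_used(self):
        # anchor twice; the protospacer follows the first one
        read = DEFAULT_ANCHOR + "C" * 20 + DEFAULT_ANCHOR + "G" * 20
        assert extract_protospacer(read, PARAMS)[1] == "C" * 20


class TestAssignRead:
    def test_exact_match(self, toy_library):
        proto = toy_library.records[0].protospacer
        asg = assign_read(proto, toy_library)
        assert (asg.status, asg.guide_id, asg.mismatches) == (ASSIGNED, "g0", 0)

    def test_single_best_within_budget(self, toy_library, mutate):
        proto = mutate(toy_library.records[2].protospacer, [5])
        asg = assign_read(proto, toy_library, max_mismatches=3)
        assert asg.status == ASSIGNED
        assert asg.guide_id == "g2"
        assert asg.mismatches == 1

    def test_tie_at_minimum_distance_is_ambiguous(self, mutate):
        s1 = "AAAAAAAAAACCCCCCCCCC"
        s2 = "AAAAAAAAAAGGGGGGGGGG"
        lib = GuideLibrary.from_records(
            [GuideRecord("g1", "A", s1), GuideRecord("g2", "B", s2)]
        )
        # equidistant query: 5 C's and 5 G's in the variable half
        q = "AAAAAAAAAA" + "CCCCC" + "GGGGG"
        asg = assign_read(q, lib, max_mismatches=3)  # d=5 from both: no match
        assert asg.status == NO_MATCH
        lib2 = GuideLibrary.from_records(
            [
                GuideRecord("g1", "A", "A" * 20),
                GuideRecord("g2", "B", "A" * 18 + "CC"),
            ]
        )
        tie = "A" * 18 + "AC"  # distance 1 from both
        assert assign_read(tie, lib2, max_mismatches=3).status == AMBIGUOUS

    def test_beyond_budget_is_no_match(self, toy_library, mutate):
        proto = mutate(toy_library.records[0].protospacer, [0, 5, 9, 13])
        assert assign_read(proto, toy_library, max_mismatches=3).status == NO_MATCH

    def test_duplicate_protospacer_exact_hit_is_ambiguous(self):
        seq = "ACGTACGTACGTACGTACGT"
        lib = GuideLibrary.from_records(
            [GuideRecord("g1", "A", seq), GuideRecord("g2", "B", seq)]
        )
        assert assign_read(seq, lib).status == AMBIGUOUS

    def test_n_counts_as_mismatch(self):
        lib = GuideLibrary.from_records([GuideRecord("g1", "A", "A" * 20)])
        asg = assign_read("N" + "A" * 19, lib, max_mismatches=3)
        assert (asg.status, asg.mismatches) == (ASSIGNED, 1)
        assert assign_read("N" * 4 + "A" * 16, lib, max_mismatches=3).status == NO_MATCH

    def test_length_mismatch_errors(self, toy_library):
        with pytest.raises(InputError):
            assign_read("ACGT", toy_library)

    def test_matches_brute_force_hamming_scan(self, toy_library, mutate):
        """Chunk-indexed search equals an exhaustive Hamming scan."""
        rng = np.random.default_rng(11)
        index = GuideIndex(toy_library, max_mismatches=3)
        seqs = [r.protospacer for r in toy_library.records]
        ids = toy_library.guide_ids
        for _ in range(300):
            base = seqs[rng.integers(len(seqs))]
            nmut = int(rng.integers(0, 6))
            q = mutate(base, rng.choice(20, size=nmut, replace=False))
            got = index.assign(q)
            dists = [sum(a != b for a, b in zip(q, s)) for s in seqs]
            dmin = min(dists)
            if dmin > 3:
                assert got.status == NO_MATCH
            elif dists.count(dmin) > 1:
                assert got.status == AMBIGUOUS
            else:
                assert got.status == ASSIGNED
                assert got.guide_id == ids[int(np.argmin(dists))]
                assert got.mismatches == dmin


class TestCountReads:
    def _reads(self, lib, per_guide=10):
        reads = []
        for rec in lib.records:
            reads += ["TT" + DEFAULT_ANCHOR + rec.protospacer + "GTTTTAGAGC"] * per_guide
        return reads

    def test_even_counts(self, tmp_path, toy_library, fastq_writer):
        path = fastq_writer(tmp_path / "s.fastq", self._reads(toy_library))
        table = count_reads({"s": path}, toy_library)
        assert (table.column("s") == 10).all()
        assert table.totals["s"] == 100
        assert table.stats["s"].assigned == 100

    def test_junk_reads_counted_as_no_anchor(self, tmp_path, toy_library, fastq_writer):
        reads = self._reads(toy_library) + ["T" * 70] * 5
        path = fastq_writer(tmp_path / "s.fastq", reads)
        table = count_reads({"s": path}, toy_library)
        assert (table.column("s") == 10).all()
        assert table.stats["s"].no_anchor == 5

    def test_status_conservation(self, tmp_path, toy_library, fastq_writer):
        """Every read lands in exactly one status tally."""
        rng = np.random.default_rng(3)
        reads = self._reads(toy_library, per_guide=3)
        reads += ["G" * 70] * 4  # no anchor
        reads += [DEFAULT_ANCHOR + "ACGTA"] * 2  # short tail
        reads += ["TT" + DEFAULT_ANCHOR + "ACGT" * 5 + "GTTT"]  # likely no_match
        rng.shuffle(reads)
        path = fastq_writer(tmp_path / "s.fastq", reads)
        st = count_reads({"s": path}, toy_library).stats["s"]
        assert st.reads_total == len(reads)
        assert (
            st.assigned + st.no_anchor + st.short_tail + st.no_match + st.ambiguous
            == st.reads_total
        )

    def test_quality_strings_ignored(self, tmp_path, toy_library):
        rec = toy_library.records[0]
        read = "TT" + DEFAULT_ANCHOR + rec.protospacer + "GTTTTAGAGC"
        for i, qual in enumerate(["I" * len(read), "!" * len(read)]):
            p = tmp_path / f"q{i}.fastq"
            p.write_text(f"@r\n{read}\n+\n{qual}\n")
        t0 = count_reads({"s": tmp_path / "q0.fastq"}, toy_library)
        t1 = count_reads({"s": tmp_path / "q1.fastq"}, toy_library)
        assert (t0.counts == t1.counts).all()

    def test_gzip_transparent(self, tmp_path, toy_library):
        reads = self._reads(toy_library, per_guide=2)
        path = tmp_path / "s.fastq.gz"
        with gzip.open(path, "wt") as fh:
            for i, r in enumerate(reads):
                fh.write(f"@r{i}\n{r}\n+\n{'I' * len(r)}\n")
        table = count_reads({"s": path}, toy_library)
        assert (table.column("s") == 2).all()

    def test_every_guide_present_zero_filled(self, tmp_path, toy_library, fastq_writer):
        rec = toy_library.records[0]
        path = fastq_writer(
            tmp_path / "s.fastq", ["TT" + DEFAULT_ANCHOR + rec.protospacer + "GT" * 10]
        )
        table = count_reads({"s": path}, toy_library)
        assert table.guides == toy_library.guide_ids
        assert table.column("s").sum() == 1

    def test_malformed_fastq_names_file_and_record(self, tmp_path, toy_library):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\nIIII\n")
        with pytest.raises(FastqParseError, match="bad.fastq"):
            count_reads({"s": path}, toy_library)

    def test_missing_sample_mapping_errors(self, toy_library):
        with pytest.raises(InputError):
            count_reads({}, toy_library)
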