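"""Discovery cascade: ORF scanning, filter stages, ledger accounting, features."""

import numpy as np
import pytest

from linctools.lincrna_discovery import (
    STOP_CODONS,
    DiscoveryConfig,
    EvidenceTable,
    FilterLedger,
    compute_features,
    extract_intergenic,
    filter_cpc,
    filter_evidence,
    filter_flanking,
    filter_length,
    filter_orf,
    find_longest_orf,
    run_discovery,
)
from linctools.transcript_io import (
    GeneLocus,
    TranscriptModel,
    read_fasta,
    read_genes,
    read_transcripts,
)

_COMP = str.maketrans("ACGTN", "TGCAN")


def brute_force_longest_orf(seq: str, both: bool) -> int:
    """Independent O(n^2) enumeration of every ATG..stop stretch."""
    best = 0
    strands = [seq, seq.translate(_COMP)[::-1]] if both else [seq]
    for s in strands:
        for i in range(len(s) - 2):
            if s[i:i + 3] != "ATG":
                continue
            j = i
            while j + 3 <= len(s):
                codon = s[j:j + 3]
                if codon in STOP_CODONS and "N" not in codon:
                    best = max(best, j + 3 - i)
                    break
                j += 3
    return best


class TestFindLongestOrf:
    def test_no_start_codon_yields_zero(self):
        assert find_longest_orf("CCCCCC").orf_length_nt == 0

    def test_minimal_orf_includes_stop(self):
        r = find_longest_orf("ATGAAATAG")
        assert (r.orf_length_nt, r.frame, r.orf_interval) == (9, 1, (0, 9))

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError, match="empty"):
            find_longest_orf("")

    def test_ambiguous_base_never_forms_start_or_stop(self):
        # ATG..TNA: the would-be stop contains N, and no other stop follows
        assert find_longest_orf("ATGTNA").orf_length_nt == 0

    def test_antisense_orf_found_only_in_both_mode(self):
        sense = "ATGAAATAG"
        anti = sense.translate(_COMP)[::-1]
        assert find_longest_orf(anti, "sense_only").orf_length_nt == 0
        r = find_longest_orf(anti, "both")
        assert r.orf_length_nt == 9 and r.frame < 0

    @pytest.mark.parametrize("mode", ["sense_only", "both"])
    def test_matches_brute_force_on_random_sequences(self, mode):
        rng = np.random.default_rng(7)
        for _ in range(120):
            seq = "".join(rng.choice(list("ACGTN"), size=600,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            expected = brute_force_longest_orf(seq, both=(mode == "both"))
            assert find_longest_orf(seq, mode).orf_length_nt == expected


def _mk(tid, length=300, code="u", chrom="chr1", start=10_000, strand="+"):
    return TranscriptModel(tid, chrom, strand, [(start, start + length)], code)


class TestStages:
    def test_extract_intergenic_keeps_only_u(self):
        ts = [_mk("a", code="u"), _mk("b", code="="), _mk("c", code="j"),
              _mk("d", code="u")]
        kept, removed = extract_intergenic(ts)
        assert [t.transcript_id for t in kept] == ["a", "d"]
        assert set(removed) == {"b", "c"}
        assert extract_intergenic([_mk("x", code="=")])[0] == []

    def test_length_boundary_200_removed_201_retained(self):
        kept, removed = filter_length([_mk("a", 200), _mk("b", 201)])
        assert [t.transcript_id for t in kept] == ["b"]
        assert "a" in removed

    def test_orf_boundary_300_retained_301_removed(self):
        from linctools.lincrna_discovery import OrfResult

        ts = [_mk("a"), _mk("b"), _mk("c")]
        orfs = {"a": OrfResult("a", 300), "b": OrfResult("b", 303),
                "c": OrfResult("c", 0)}
        kept, removed = filter_orf(ts, orfs)
        assert [t.transcript_id for t in kept] == ["a", "c"]
        assert "b" in removed
        with pytest.raises(ValueError, match="no ORF result"):
            filter_orf([_mk("zzz")], {})

    def test_evidence_filter_is_sequential_and_disjoint(self):
        ts = [_mk(t) for t in ("p", "d", "clean")]
        ev = EvidenceTable(protein_evalue={"p": 1e-5, "d": 0.01},
                           domain_evalue={"d": 1e-4, "p": 1e-9})
        kept, rp, rd = filter_evidence(ts, ev)
        assert set(rp) == {"p"}          # protein stage wins even with a domain hit
        assert set(rd) == {"d"}          # weak protein hit falls through to domain
        assert [t.transcript_id for t in kept] == ["clean"]
        assert not (set(rp) & set(rd))

    def test_negative_evalue_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            EvidenceTable(protein_evalue={"x": -1.0})

    def test_cpc_boundary_zero_retained(self):
        ts = [_mk("a"), _mk("b"), _mk("c")]
        ev = EvidenceTable(cpc_score={"a": 0.01, "b": 0.0, "c": -1.3})
        kept, removed = filter_cpc(ts, ev)
        assert [t.transcript_id for t in kept] == ["b", "c"]
        assert "a" in removed
        with pytest.raises(ValueError, match="missing"):
            filter_cpc([_mk("nope")], EvidenceTable())

    def test_flanking_gap_boundary(self):
        genes = [GeneLocus("g", "chr1", "+", (100, 600))]
        near = _mk("near", length=500, start=1000)       # gap 400
        far = _mk("far", length=500, start=1101)         # gap 501
        overlap = _mk("ov", length=500, start=400)       # gap 0
        other_chrom = _mk("oc", length=500, start=700, chrom="chr2")
        kept, removed = filter_flanking([near, far, overlap, other_chrom], genes)
        assert set(removed) == {"near", "ov"}
        assert [t.transcript_id for t in kept] == ["far", "oc"]


class TestLedger:
    def test_stage_conservation_enforced(self):
        ledger = FilterLedger()
        ledger.add_stage("s1", ["a", "b", "c"], {"a": "r"})
        ledger.add_stage("s2", ["b", "c"], {})
        assert ledger.final_retained_count == 2
        with pytest.raises(ValueError, match="ledger break"):
            ledger.add_stage("s3", ["b"], {})

    def test_counts_only_replay(self):
        ledger = FilterLedger.from_counts(100, [("x", 40), ("y", 10)])
        assert ledger.final_retained_count == 50
        ledger.validate()


class TestRunDiscovery:
    def test_empty_input_gives_empty_records_and_zero_ledger(self):
        records, ledger = run_discovery([], {}, EvidenceTable(), [])
        assert records == []
        assert all(s.input_count == 0 for s in ledger.stages)

    def test_recovers_exactly_the_planted_linc_set(self, fixture_dir, manifest):
        records, ledger = self._run(fixture_dir)
        assert {r.transcript_id for r in records} == set(
            manifest["discovery"]["true_lincs"])
        # per-stage removals match the planted category counts
        counts = manifest["discovery"]["counts"]
        by_stage = {s.stage_name: s.removed_count for s in ledger.stages}
        assert by_stage["class_code_u"] == counts["non_u"]
        assert by_stage["length_gt_200"] == counts["short"]
        assert by_stage["orf_le_300"] == counts["long_orf"]
        assert by_stage["protein_similarity"] == counts["protein_hit"]
        assert by_stage["protein_domain"] == counts["domain_hit"]
        assert by_stage["coding_potential"] == counts["cpc_positive"]
        assert by_stage["gene_flanking"] == counts["flanking"]

    def test_linc_ids_consecutive_and_coordinate_ordered(self, fixture_dir):
        records, _ = self._run(fixture_dir)
        assert [r.linc_id for r in records] == [
            f"Ca_linc_{i:04d}" for i in range(1, len(records) + 1)]
        keys = [(r.chrom, r.start) for r in records]
        assert keys == sorted(keys)
        assert all(r.length_nt > 200 for r in records)

    def test_post_hoc_orf_invariant(self, fixture_dir):
        records, _ = self._run(fixture_dir)
        seqs = read_fasta(fixture_dir / "transcripts.fa")
        for r in records:
            assert find_longest_orf(seqs[r.transcript_id], "both").orf_length_nt <= 300

    def test_final_set_invariant_under_cpc_flanking_swap(self, fixture_dir):
        transcripts = read_transcripts(fixture_dir / "transcripts.gtf")
        seqs = read_fasta(fixture_dir / "transcripts.fa")
        genes = read_genes(fixture_dir / "genes.gff3")
        ev = EvidenceTable.from_files(fixture_dir / "protein_hits.tsv",
                                      fixture_dir / "domain_hits.tsv",
                                      fixture_dir / "cpc_scores.tsv")
        records, _ = run_discovery(transcripts, seqs, ev, genes)
        # swap the last two independent predicates by hand
        kept, _ = extract_intergenic(transcripts)
        kept, _ = filter_length(kept)
        orfs = {t.transcript_id: find_longest_orf(
            seqs[t.transcript_id],
            "sense_only" if t.strand in "+-" else "both") for t in kept}
        kept, _ = filter_orf(kept, orfs)
        kept, _, _ = filter_evidence(kept, ev)
        kept, _ = filter_flanking(kept, genes)   # flanking before CPC
        kept, _ = filter_cpc(kept, ev)
        assert {t.transcript_id for t in kept} == {r.transcript_id for r in records}

    @staticmethod
    def _run(fixture_dir):
        return run_discovery(
            read_transcripts(fixture_dir / "transcripts.gtf"),
            read_fasta(fixture_dir / "transcripts.fa"),
            EvidenceTable.from_files(fixture_dir / "protein_hits.tsv",
                                     fixture_dir / "domain_hits.tsv",
                                     fixture_dir / "cpc_scores.tsv"),
            read_genes(fixture_dir / "genes.gff3"),
        )


class TestFeatures:
    def test_gc_fraction_and_exon_arithmetic(self, fixture_dir):
        records, _ = TestRunDiscovery._run(fixture_dir)
        seqs = read_fasta(fixture_dir / "transcripts.fa")
        df, summary = compute_features(records, seqs)
        # independent recomputation from the raw inputs
        lengths = [len(seqs[r.transcript_id]) for r in records]
        assert summary["mean_length"] == pytest.approx(np.mean(lengths))
        assert summary["fraction_single_exon"] == pytest.approx(
            np.mean([r.exon_count == 1 for r in records]))
        assert summary["mean_exon_count"] == pytest.approx(
            np.mean([r.exon_count for r in records]))
        assert sum(summary["per_chromosome"].values()) == len(records)
        for r in records[:5]:
            seq = seqs[r.transcript_id]
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            assert r.gc_fraction == pytest.approx(gc)
        # lincRNAs are AU-rich by construction
        assert df["au_fraction"].mean() > 0.6

    def test_summary_arithmetic_on_tiny_set(self):
        from linctools.lincrna_discovery import LincRNARecord

        recs = [LincRNARecord(f"L{i}", f"t{i}", "chr1", 0, 100, "+", 100, e, 0.0)
                for i, e in enumerate([1, 1, 1, 2])]
        _, summary = compute_features(recs)
        assert summary["fraction_single_exon"] == 0.75
        assert summary["mean_exon_count"] == 1.25

    def test_gc_zero_for_at_only(self):
        from linctools.lincrna_discovery import LincRNARecord, _gc_fraction

        assert _gc_fraction("ATAT") == 0.0
        assert _gc_fraction("") == 0.0
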