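"""Intron extraction, phase rules, projection, events and tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famscape.gene_structure import (
    GeneModel,
    IntronRecord,
    chromosome_summary,
    detect_events,
    extract_introns,
    intron_count_share,
    intron_count_table,
    intron_phase,
    parse_gene_models,
    project_intron,
)
from famscape.phylogeny import MSA


def two_exon_gene(len1, len2, strand="+", intron_len=100):
    """Plus-strand segments laid left to right; minus-strand mirrored."""
    if strand == "+":
        segs = [(1, len1), (len1 + intron_len + 1, len1 + intron_len + len2)]
    else:
        segs = [(len2 + intron_len + 1, len2 + intron_len + len1), (1, len2)]
    return GeneModel("g", "chr01", strand, segs)


class TestExtractIntrons:
    @pytest.mark.parametrize(
        "len1,len2,phase",
        [(99, 300, 0), (100, 299, 1), (101, 298, 2)],
        ids=["between-codons", "after-first-base", "after-second-base"],
    )
    def test_phase_follows_cumulative_cds_length(self, len1, len2, phase):
        recs = extract_introns(two_exon_gene(len1, len2))
        assert len(recs) == 1
        assert recs[0].cds_offset == len1
        assert recs[0].phase == phase

    def test_minus_strand_same_phase_and_offset(self):
        plus = extract_introns(two_exon_gene(100, 299, "+"))[0]
        minus = extract_introns(two_exon_gene(100, 299, "-"))[0]
        assert (minus.cds_offset, minus.phase, minus.residue_index) == (
            plus.cds_offset, plus.phase, plus.residue_index
        )

    def test_partial_gene_rejected(self):
        gene = two_exon_gene(100, 300)  # 400 nt, not divisible by 3
        assert gene.partial
        with pytest.raises(ValueError, match="partial"):
            extract_introns(gene)

    def test_round_trip_against_generator_truth(self, small_bundle,
                                                small_bundle_dir):
        """Every planted intron is recovered with its truth offset, phase
        and residue, from the serialized GFF3, on both strands."""
        models = parse_gene_models(
            small_bundle_dir["models"], genome=small_bundle_dir["genome"]
        )
        got = sorted(
            (r.gene_id, r.cds_offset, r.phase, r.residue_index)
            for m in models for r in extract_introns(m)
        )
        truth = small_bundle.truth.intron_frame()
        want = sorted(
            zip(truth.gene_id, truth.cds_offset, truth.phase,
                truth.residue_index)
        )
        assert got == want

    def test_strand_flip_leaves_offsets_phases_residues_unchanged(
        self, small_bundle
    ):
        """Reverse-complementing a chromosome and flipping every gene's
        strand and coordinates must not change (L, phase, residue)."""
        for model in small_bundle.models:
            length = len(small_bundle.genome[model.chromosome])
            flipped = GeneModel(
                model.gene_id, model.chromosome,
                "-" if model.strand == "+" else "+",
                [(length - hi + 1, length - lo + 1)
                 for lo, hi in model.cds_segments],
            )
            before = [(r.cds_offset, r.phase, r.residue_index)
                      for r in extract_introns(model)]
            after = [(r.cds_offset, r.phase, r.residue_index)
                     for r in extract_introns(flipped)]
            assert before == after

    @given(st.integers(min_value=1, max_value=3000))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_phase_equals_remainder_of_cds_prefix(self, L):
        assert intron_phase(L) == L - 3 * (L // 3)

    def test_phase_rule_full_range(self):
        for L in range(1, 3001):
            assert intron_phase(L) == L % 3


class TestParseGeneModels:
    def test_single_cds_gene_has_no_introns(self, small_bundle,
                                            small_bundle_dir):
        models = parse_gene_models(small_bundle_dir["models"])
        singles = [m for m in models if len(m.cds_segments) == 1]
        assert singles  # the bundle plants an intronless fraction
        assert all(extract_introns(m) == [] for m in singles)

    def test_minus_strand_segments_in_transcription_order(
        self, small_bundle_dir
    ):
        models = parse_gene_models(small_bundle_dir["models"])
        minus = [m for m in models if m.strand == "-"
                 and len(m.cds_segments) > 1]
        assert minus
        for m in minus:
            starts = [lo for lo, _ in m.cds_segments]
            assert starts == sorted(starts, reverse=True)

    def test_overlapping_cds_rejected(self):
        gff = (
            "##gff-version 3\n"
            "chr1\t.\tgene\t1\t60\t.\t+\t.\tID=bad\n"
            "chr1\t.\tmRNA\t1\t60\t.\t+\t.\tID=bad.1;Parent=bad\n"
            "chr1\t.\tCDS\t1\t30\t.\t+\t0\tID=c1;Parent=bad.1\n"
            "chr1\t.\tCDS\t25\t60\t.\t+\t0\tID=c2;Parent=bad.1\n"
        )
        with pytest.raises(ValueError, match="overlap"):
            parse_gene_models(gff)


class TestProjection:
    def test_hand_counted_column_with_gap(self):
        msa = MSA(["g"], ["M-KV"])
        rec = IntronRecord("g", 1, 0, 0, cds_offset=3, phase=0,
                           residue_index=2)
        assert project_intron(rec, msa) == 3

    def test_gap_free_row_projects_to_residue_index(self):
        msa = MSA(["g"], ["MKVLW"])
        rec = IntronRecord("g", 1, 0, 0, cds_offset=10, phase=1,
                           residue_index=4)
        assert project_intron(rec, msa) == 4

    def test_residue_beyond_row_is_error(self):
        msa = MSA(["g"], ["MKV"])
        rec = IntronRecord("g", 1, 0, 0, cds_offset=30, phase=0,
                           residue_index=10)
        with pytest.raises(ValueError, match="beyond"):
            project_intron(rec, msa)

    def test_indel_mode_carriers_coproject(self):
        """Under planted group-specific gaps, carriers of one event still
        project to a single shared column."""
        from famscape.simulate import FamilySimSpec, PlantedEvent, simulate_family

        spec = FamilySimSpec(
            n_family_genes=16, n_decoy_proteins=4, group_labels=tuple("ABCD"),
            planted_events=(PlantedEvent(column=120, phase=1),),
            indel_mode=True,
        )
        bundle = simulate_family(spec, seed=21)
        cols = set()
        for model in bundle.models:
            for rec in extract_introns(model):
                cols.add(project_intron(rec, bundle.msa))
        assert len(cols) == 1


class TestDetectEvents:
    def rec(self, gene, col, phase=1):
        return IntronRecord(gene, 1, 0, 0, cds_offset=3, phase=phase,
                            residue_index=2, alignment_column=col)

    def test_shared_column_is_one_event(self):
        events = detect_events([self.rec("a", 50), self.rec("b", 50)])
        assert len(events) == 1
        assert events[0].n_members == 2
        assert events[0].event_id == "I-1"

    @pytest.mark.parametrize("window,n_events", [(0, 2), (1, 1)])
    def test_window_controls_merging(self, window, n_events):
        events = detect_events(
            [self.rec("a", 50), self.rec("b", 51)], window=window
        )
        assert len(events) == n_events

    def test_input_order_never_changes_membership_or_numbering(self):
        recs = [self.rec(f"g{k}", col) for k, col in
                enumerate([300, 50, 50, 120, 300, 120, 120])]
        base = detect_events(recs)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = [recs[k] for k in rng.permutation(len(recs))]
            events = detect_events(perm)
            assert [(e.event_id, sorted(m.gene_id for m in e.members))
                    for e in events] == \
                   [(e.event_id, sorted(m.gene_id for m in e.members))
                    for e in base]

    def test_small_events_reported_but_flagged(self):
        events = detect_events([self.rec("a", 10)], min_members=2)
        assert events[0].flagged

    def test_planted_events_recovered_with_truth_membership(
        self, small_bundle, small_bundle_dir
    ):
        models = parse_gene_models(small_bundle_dir["models"])
        recs = []
        for m in models:
            for r in extract_introns(m):
                project_intron(r, small_bundle.msa)
                recs.append(r)
        events = detect_events(recs, window=0)
        truth = small_bundle.truth.events
        truth_present = {k: v for k, v in truth.items() if v["carriers"]}
        assert len(events) == len(truth_present)
        got = {e.column_lo: sorted({m.gene_id for m in e.members})
               for e in events}
        want = {v["column"]: sorted(v["carriers"])
                for v in truth_present.values()}
        assert got == want

    def test_member_counts_conserve_total_introns(self, small_bundle):
        truth = small_bundle.truth.intron_frame()
        recs = [
            IntronRecord(r.gene_id, 1, 0, 0, r.cds_offset, r.phase,
                         r.residue_index, alignment_column=r.column)
            for r in truth.itertuples()
        ]
        events = detect_events(recs)
        assert sum(e.n_members for e in events) == len(recs)


class TestTables:
    # the published family's group × intron-count layout
    PRINTED = {
        "A": [7, 1, 1, 0, 1], "B": [2, 0, 0, 0, 0], "C": [2, 0, 2, 0, 0],
        "D": [16, 1, 1, 1, 0], "E": [23, 4, 1, 1, 0], "F": [1, 2, 1, 0, 0],
        "G": [1, 31, 1, 1, 0], "H": [0, 8, 0, 1, 0], "I": [0, 5, 0, 0, 0],
        "J": [0, 5, 2, 0, 0], "K": [0, 7, 0, 0, 0], "L": [6, 12, 0, 0, 0],
        "M": [13, 1, 0, 0, 0], "N": [0, 1, 0, 0, 0], "O": [1, 0, 0, 0, 0],
        "P": [0, 4, 0, 0, 0],
    }
    N_INTRONS = [0, 1, 2, 3, 5]

    def printed_counts(self):
        counts, groups = {}, {}
        k = 0
        for grp, row in self.PRINTED.items():
            for n, cell in zip(self.N_INTRONS, row):
                for _ in range(cell):
                    gid = f"gene{k:03d}"
                    counts[gid] = n
                    groups[gid] = grp
                    k += 1
        return counts, groups

    def test_published_family_shares(self):
        counts, groups = self.printed_counts()
        table = intron_count_table(counts, groups)
        assert table.loc["Total", "Total"] == 168
        assert list(table.loc["Total", self.N_INTRONS]) == [72, 82, 9, 4, 1]
        assert intron_count_share(table, 0) == 43
        assert intron_count_share(table, 1, "G") == 91

    def test_row_and_column_totals_conserve_family_size(self, small_bundle):
        counts = {g: len(t.introns) for g, t in small_bundle.truth.genes.items()}
        groups = {g: t.group for g, t in small_bundle.truth.genes.items()}
        table = intron_count_table(counts, groups)
        n = len(small_bundle.truth.genes)
        assert table.loc["Total", "Total"] == n
        assert table.drop("Total")["Total"].sum() == n

    def test_gene_without_group_is_error(self):
        with pytest.raises(ValueError, match="without a group"):
            intron_count_table({"g1": 0}, {})

    def test_chromosome_summary_matches_generator_truth(self, small_bundle):
        groups = {g: t.group for g, t in small_bundle.truth.genes.items()}
        table = chromosome_summary(small_bundle.models, groups)
        truth = small_bundle.truth.gene_frame()
        for chrom, n in truth["chromosome"].value_counts().items():
            assert table.loc[chrom, "Total"] == n
        assert table.loc["Total", "Total"] == len(truth)

    def test_scaffold_genes_counted_unplaced_total_preserved(self):
        genes = [
            GeneModel("g1", "chr01", "+", [(1, 300)]),
            GeneModel("g2", "scaffold_7", "+", [(1, 300)]),
        ]
        table = chromosome_summary(genes, known_chromosomes=["chr01"])
        assert table.loc["unplaced", "Total"] == 1
        assert table.loc["Total", "Total"] == 2
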