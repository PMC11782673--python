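import itertools

import numpy as np
import pytest

from cas12akit import (DEFAULT_DR, GenomeModel, GuideConstruct, LibraryTable,
                       PairConstraints, assemble_cassette, build_dual_pairs,
                       build_quad_arrays, design_dual_library, generate_ntcs,
                       rank_candidates, read_library, write_library)
from cas12akit.genome import GeneModel, TranscriptModel
from cas12akit.library import FULLY_DESIGNED, NON_DESIGNABLE, PARTIAL
from cas12akit.spacers import SpacerCandidate
from cas12akit._seq import revcomp

from conftest import make_bare_genome


def cand(pos, *, strand="+", off=0, pfam=False, frac=0.5, score=0.5, exon=0,
         spacer="GCAGCAGCAGCAGCAGCAGCAGC"):
    return SpacerCandidate(
        gene_id="g", transcript_id="g_T1", contig="c", strand=strand,
        pam_start=pos - 4 if strand == "+" else pos + 23,
        pam_seq="TTTC", spacer_seq=spacer, proto_start=pos, proto_end=pos + 23,
        cut_pos=pos + 18 if strand == "+" else pos + 4, gc_percent=65.0,
        offtarget_count=off, on_target_score=score, cds_frac=frac,
        exon_index=exon, in_pfam=pfam)


def fake_gene(gene_id="g"):
    t = TranscriptModel(f"{gene_id}_T1", "+", [(0, 10_000)], [(0, 10_000)])
    return GeneModel(gene_id, "c", "+", [t],
                     canonical_transcript_id=f"{gene_id}_T1")


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

class TestRanking:
    def test_fewer_offtargets_first(self):
        a, b = cand(100, off=2), cand(200, off=0)
        assert rank_candidates([a, b]) == [b, a]

    def test_pfam_priority(self):
        a, b = cand(100, pfam=False), cand(200, pfam=True)
        assert rank_candidates([a, b]) == [b, a]

    def test_cds_85_priority(self):
        a, b = cand(100, frac=0.95), cand(200, frac=0.60)
        assert rank_candidates([a, b]) == [b, a]

    def test_score_priority(self):
        a, b = cand(100, score=0.2), cand(200, score=0.9)
        assert rank_candidates([a, b]) == [b, a]

    def test_position_tiebreak(self):
        a, b = cand(200), cand(100)
        assert rank_candidates([a, b]) == [b, a]

    def test_flagged_candidates_dropped(self):
        a = cand(100)
        a.filter_flags = {"POLY_T"}
        assert rank_candidates([a, cand(200)]) == [cand(200)]


# ---------------------------------------------------------------------------
# dual pairing
# ---------------------------------------------------------------------------

def oracle_dual(cands, constraints, ncrna):
    """Full enumeration over all 4-subsets x 3 pairings with linear-scan
    feasibility; returns (best_cost, set of optimal frozen assignments)."""
    def gap(a, b):
        if a.proto_start <= b.proto_start:
            return b.proto_start - a.proto_end
        return a.proto_start - b.proto_end

    def span(group):
        return (min(c.proto_start for c in group),
                max(c.proto_end for c in group))

    def span_clear(group):
        s, e = span(group)
        return not any(s < ne and e > ns for ns, ne in ncrna)

    best, opt = None, set()
    n = len(cands)
    for combo in itertools.combinations(range(n), 4):
        for split in ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2)):
            i, j, k, l = (combo[x] for x in split)
            p1, p2 = (cands[i], cands[j]), (cands[k], cands[l])
            if gap(*p1) < constraints.min_intra_pair_gap:
                continue
            if gap(*p2) < constraints.min_intra_pair_gap:
                continue
            if not (span_clear(p1) and span_clear(p2)):
                continue
            (s1, e1), (s2, e2) = sorted([span(p1), span(p2)])
            if s2 - e1 < constraints.min_inter_pair_gap:
                continue
            cost = sum(combo)
            key = frozenset([frozenset([i, j]), frozenset([k, l])])
            if best is None or cost < best:
                best, opt = cost, {key}
            elif cost == best:
                opt.add(key)
    return best, opt


class TestDualPairs:
    constraints = PairConstraints()

    def _genome(self, ncrna=()):
        return make_bare_genome("A" * 20_000, ncrna=ncrna)

    def test_unique_feasible_assignment_found(self):
        cands = [cand(0), cand(48), cand(150), cand(198)]
        genome = self._genome()
        best, opt = oracle_dual(cands, self.constraints, [])
        assert len(opt) == 1  # fixture admits exactly one assignment
        design = build_dual_pairs(fake_gene(), cands, self.constraints, genome)
        assert design.status == FULLY_DESIGNED
        got = frozenset(
            frozenset(cands.index(c) for c in pair) for pair in design.pairs)
        assert got in opt

    def test_close_spacers_never_paired(self):
        # gap 33 - 23 = 10 nt < 25
        cands = [cand(0), cand(33)]
        design = build_dual_pairs(fake_gene(), cands, self.constraints,
                                  self._genome())
        assert design.status == NON_DESIGNABLE

    def test_ncrna_overlap_excluded_next_best_chosen(self):
        cands = [cand(p) for p in (0, 48, 150, 198, 400, 448)]
        ncrna = [(60, 70)]  # inside the span of the (0, 48) pair
        genome = self._genome(ncrna=ncrna)
        design = build_dual_pairs(fake_gene(), cands, self.constraints, genome)
        assert design.status == FULLY_DESIGNED
        best, opt = oracle_dual(cands, self.constraints, ncrna)
        got = frozenset(
            frozenset(cands.index(c) for c in pair) for pair in design.pairs)
        assert got in opt
        cost = sum(cands.index(c) for pair in design.pairs for c in pair)
        assert cost == best
        for pair in design.pairs:  # linear-scan validator
            s = min(c.proto_start for c in pair)
            e = max(c.proto_end for c in pair)
            assert not (s < 70 and e > 60)

    @pytest.mark.parametrize("seed", range(8))
    def test_optimality_vs_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        cands = [cand(int(p)) for p in
                 np.sort(rng.choice(2000, size=n, replace=False))]
        rng.shuffle(cands)  # rank order decoupled from position
        ncrna = [(int(s), int(s) + 40)
                 for s in rng.integers(0, 2000, size=2)]
        genome = self._genome(ncrna=ncrna)
        best, opt = oracle_dual(cands, self.constraints, ncrna)
        design = build_dual_pairs(fake_gene(), cands, self.constraints, genome)
        if best is None:
            assert design.status in (PARTIAL, NON_DESIGNABLE)
        else:
            assert design.status == FULLY_DESIGNED
            cost = sum(cands.index(c) for pair in design.pairs for c in pair)
            assert cost == best

    def test_partial_when_single_pair_only(self):
        cands = [cand(0), cand(48), cand(60)]  # only (0, 48) is feasible
        design = build_dual_pairs(fake_gene(), cands, self.constraints,
                                  self._genome())
        assert design.status == PARTIAL
        assert len(design.pairs) == 1

    def test_constraints_hold_on_designed_library(self, dual_lib20, sim20):
        model, _ = sim20
        ncrna = [(s, e) for c, s, e in model.ncrna_intervals]
        spans = {}
        for c in dual_lib20.constructs:
            if c.is_ntc:
                continue
            a, b = sorted(c.candidates, key=lambda x: x.proto_start)
            assert b.proto_start - a.proto_end >= 25
            s, e = a.proto_start, b.proto_end
            assert not any(s < ne and e > ns for ns, ne in ncrna)
            spans.setdefault(c.gene_id, []).append((s, e))
        for gene_id, sp in spans.items():
            if len(sp) == 2:
                (s1, e1), (s2, e2) = sorted(sp)
                assert s2 - e1 >= 50, gene_id


# ---------------------------------------------------------------------------
# quad arrays
# ---------------------------------------------------------------------------

class TestQuadArrays:
    constraints = PairConstraints()

    def test_single_isoform_one_quad(self):
        cands = [cand(p) for p in (0, 48, 96, 144, 192)]
        genome = make_bare_genome("A" * 20_000)
        design = build_quad_arrays(fake_gene(), cands, self.constraints, genome)
        assert design.status == FULLY_DESIGNED
        assert len(design.quads) == 1
        quad = design.quads[0]
        ordered = sorted(quad, key=lambda c: c.proto_start)
        for a, b in zip(ordered, ordered[1:]):
            assert b.proto_start - a.proto_end >= 25

    def test_three_spacers_partial_no_quad(self):
        cands = [cand(p) for p in (0, 48, 96)]
        genome = make_bare_genome("A" * 20_000)
        design = build_quad_arrays(fake_gene(), cands, self.constraints, genome)
        assert design.status == PARTIAL
        assert design.quads == []

    def test_disjoint_isoforms_need_two_quads(self):
        # T1 coding over [0, 400); T2 coding over [600, 1000): no single
        # candidate covers both, and mixing regions would span the planted
        # non-coding element at (450, 460)
        t1 = TranscriptModel("g_T1", "+", [(0, 1000)], [(0, 400)])
        t2 = TranscriptModel("g_T2", "+", [(0, 1000)], [(600, 1000)])
        gene = GeneModel("g", "c", "+", [t1, t2],
                         canonical_transcript_id="g_T1")
        genome = make_bare_genome("A" * 20_000, ncrna=[(450, 460)])
        left = [cand(p) for p in (0, 50, 100, 150)]      # cuts 18..168 in T1
        right = [cand(p) for p in (600, 650, 700, 750)]  # cuts in T2
        design = build_quad_arrays(gene, left + right, self.constraints, genome)
        assert len(design.quads) == 2
        union = set().union(*design.covered)
        assert union == {"g_T1", "g_T2"}
        assert design.status == FULLY_DESIGNED
        # brute-force check: no feasible quad covers both isoforms
        allc = left + right
        for combo in itertools.combinations(allc, 4):
            cov_t1 = any(c.cut_pos < 400 for c in combo)
            cov_t2 = any(c.cut_pos >= 600 for c in combo)
            if cov_t1 and cov_t2:
                s = min(c.proto_start for c in combo)
                e = max(c.proto_end for c in combo)
                assert s < 460 and e > 450  # would overlap the ncRNA

    def test_quad_spacing_violation_rejected(self):
        cands = [cand(p) for p in (0, 48, 96, 120)]  # 96->120 gap is -1
        genome = make_bare_genome("A" * 20_000)
        design = build_quad_arrays(fake_gene(), cands, self.constraints, genome)
        assert design.quads == []


# ---------------------------------------------------------------------------
# cassette assembly
# ---------------------------------------------------------------------------

class TestAssembly:
    def test_printed_dr_and_overhangs(self):
        s = "GCAGCAGCAGCAGCAGCAGCAGC"
        c = GuideConstruct("x", "DUAL", "g", spacers=[s])
        assemble_cassette(c)
        assert c.sense_oligo == "TCCC" + "TAATTTCTACTCTTGTAGAT" + s
        assert c.antisense_oligo == "AAAC" + revcomp(DEFAULT_DR + s)
        assert c.antisense_oligo.startswith("AAAC")

    def test_dual_cassette_length(self):
        c = GuideConstruct("x", "DUAL", "g",
                           spacers=["GCAGCAGCAGCAGCAGCAGCAGC",
                                    "CAGCAGCAGCAGCAGCAGCAGCA"])
        assemble_cassette(c)
        assert len(c.cassette_seq) == 2 * (20 + 23) == 86
        assert c.cassette_seq == (DEFAULT_DR + c.spacers[0]
                                  + DEFAULT_DR + c.spacers[1])

    def test_empty_spacers_error(self):
        with pytest.raises(ValueError):
            assemble_cassette(GuideConstruct("x", "DUAL", "g", spacers=[]))

    def test_restriction_site_flags_and_deselects(self):
        c = GuideConstruct("x", "DUAL", "g",
                           spacers=["GAATTCGCAGCAGCAGCAGCAGC"])
        assemble_cassette(c)
        assert "RESTRICTION_SITE" in c.flags
        assert not c.selected

    def test_custom_dr_set(self):
        drs = ["AAATTTCTACTCTTGTAGAT", "CAATTTCTACTCTTGTAGAT"]
        c = GuideConstruct("x", "DUAL", "g",
                           spacers=["GCAGCAGCAGCAGCAGCAGCAGC"] * 2)
        assemble_cassette(c, dr_seqs=drs)
        assert c.cassette_seq.startswith(drs[0])
        assert drs[1] in c.cassette_seq

    def test_too_few_drs_error(self):
        c = GuideConstruct("x", "DUAL", "g",
                           spacers=["GCAGCAGCAGCAGCAGCAGCAGC"] * 2)
        with pytest.raises(ValueError, match="DR"):
            assemble_cassette(c, dr_seqs=["TAATTTCTACTCTTGTAGAT"])


# ---------------------------------------------------------------------------
# NTCs
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_genome():
    rng = np.random.default_rng(21)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30_000)])
    return make_bare_genome(seq)


class TestNtcs:
    def test_count_and_distinct_spacers(self, small_genome):
        ntcs = generate_ntcs(25, small_genome, "DUAL", seed=42)
        assert len(ntcs) == 25
        spacers = [s for c in ntcs for s in c.spacers]
        assert len(spacers) == len(set(spacers)) == 50

    def test_quad_mode(self, small_genome):
        ntcs = generate_ntcs(10, small_genome, "QUAD", seed=42)
        assert len(ntcs) == 10
        assert all(len(c.spacers) == 4 for c in ntcs)
        assert all(c.kind == "NTC_QUAD" for c in ntcs)

    def test_deterministic_per_seed(self, small_genome, tmp_path):
        a = generate_ntcs(10, small_genome, "DUAL", seed=7)
        b = generate_ntcs(10, small_genome, "DUAL", seed=7)
        write_library(LibraryTable(a), tmp_path / "a.tsv")
        write_library(LibraryTable(b), tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        other = generate_ntcs(10, small_genome, "DUAL", seed=8)
        assert [c.spacers for c in a] != [c.spacers for c in other]

    def test_zero_matches_by_exhaustive_scan(self, small_genome):
        from numpy.lib.stride_tricks import sliding_window_view
        from cas12akit.spacers import encode_seq
        ntcs = generate_ntcs(10, small_genome, "DUAL", seed=3)
        enc = encode_seq(small_genome.contigs["c"])
        windows = sliding_window_view(enc, 23)
        for c in ntcs:
            for sp in c.spacers:
                for q in (sp, revcomp(sp)):
                    qe = encode_seq(q)
                    assert ((windows != qe).sum(axis=1) <= 3).sum() == 0

    def test_invalid_mode(self, small_genome):
        with pytest.raises(ValueError):
            generate_ntcs(1, small_genome, "TRIPLE", seed=0)


# ---------------------------------------------------------------------------
# library I/O and drivers
# ---------------------------------------------------------------------------

class TestLibraryIO:
    def test_round_trip(self, dual_lib20, tmp_path):
        p = tmp_path / "lib.tsv"
        write_library(dual_lib20, p)
        back = read_library(p)
        assert len(back.constructs) == len(dual_lib20.constructs)
        for a, b in zip(dual_lib20.constructs, back.constructs):
            assert a.construct_id == b.construct_id
            assert a.kind == b.kind
            assert a.gene_id == b.gene_id
            assert a.spacers == b.spacers
            assert a.dr_seqs == b.dr_seqs
            assert a.cassette_seq == b.cassette_seq
            assert a.sense_oligo == b.sense_oligo
            assert a.antisense_oligo == b.antisense_oligo

    def test_duplicate_ids_fatal(self):
        c = GuideConstruct("dup", "DUAL", "g",
                           spacers=["GCAGCAGCAGCAGCAGCAGCAGC"] * 2)
        with pytest.raises(ValueError, match="dup"):
            LibraryTable([c, c])

    def test_empty_table_round_trip(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_library(LibraryTable([]), p)
        assert read_library(p).constructs == []
        assert p.read_text().startswith("construct_id\t")

    def test_design_deterministic(self, sim20, tmp_path):
        model, _ = sim20
        a = design_dual_library(model, n_ntc=5, seed=9)
        b = design_dual_library(model, n_ntc=5, seed=9)
        write_library(a, tmp_path / "a.tsv")
        write_library(b, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_dual_library_shape(self, dual_lib20):
        targeting = [c for c in dual_lib20.constructs if not c.is_ntc]
        assert all(len(c.spacers) == 2 for c in targeting)
        assert all(c.cassette_seq for c in dual_lib20.constructs)
        genes = {c.gene_id for c in targeting}
        full = {g for g, r in dual_lib20.design_report.items()
                if r["status"] == FULLY_DESIGNED}
        assert full <= genes
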