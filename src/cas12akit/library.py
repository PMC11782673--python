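"""Arrange filtered spacer candidates into dual pairs or quad pre-crRNA
arrays under spacing / non-coding / prioritisation constraints, generate
non-targeting controls, and assemble DR-interleaved cassettes and cloning
oligos.

Selection is an exhaustive search over the top-ranked candidates, so at desk
scale the emitted design provably attains the optimal summed rank priority
subject to the hard constraints:

* >= 25 nt gap between the protospacer intervals of spacers within a pair
  (or between adjacent spacers of a quad), so nucleases do not compete for
  occupancy;
* >= 50 nt gap between the spanned regions of a gene's two pairs;
* the region spanned by a pair's (or quad's) outermost protospacers must not
  overlap any annotated non-coding element, to avoid deleting it;
* spreading spacers over distinct exons is preferred when possible (soft).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import gc_percent, revcomp
from .genome import GenomeModel, cds_fraction
from .spacers import (DEFAULT_DR, CdsOfftargetScanner, FilterConfig,
                      GenomeMismatchScanner, SpacerCandidate,
                      candidate_context, default_scorer, enumerate_spacers,
                      score_on_target)

SENSE_OVERHANG = "TCCC"
ANTISENSE_OVERHANG = "AAAC"

FULLY_DESIGNED = "fully_designed"
PARTIAL = "partial"
NON_DESIGNABLE = "non_designable"


@dataclass
class PairConstraints:
    min_intra_pair_gap: int = 25
    min_inter_pair_gap: int = 50
    require_exon_diversity: bool = True  # soft preference
    avoid_ncrna_overlap: bool = True  # hard constraint
    max_candidates_considered: int = 50

    def __post_init__(self):
        if self.min_intra_pair_gap < 0 or self.min_inter_pair_gap < 0:
            raise ValueError("gaps must be >= 0")


@dataclass
class GuideConstruct:
    construct_id: str
    kind: str  # DUAL | QUAD | NTC_DUAL | NTC_QUAD
    gene_id: str  # gene id, or "NTC"
    spacers: list
    candidates: list = field(default_factory=list, compare=False)
    dr_seqs: list = field(default_factory=list)
    cassette_seq: str = ""
    sense_oligo: str = ""
    antisense_oligo: str = ""
    flags: set = field(default_factory=set)
    selected: bool = True

    @property
    def is_ntc(self) -> bool:
        return self.kind.startswith("NTC")


@dataclass
class LibraryTable:
    constructs: list
    design_report: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [c.construct_id for c in self.constructs]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate construct ids: {dup[:5]}")

    def construct(self, construct_id: str) -> GuideConstruct:
        for c in self.constructs:
            if c.construct_id == construct_id:
                return c
        raise KeyError(construct_id)

    def gene_map(self) -> dict:
        return {c.construct_id: c.gene_id for c in self.constructs}


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def rank_candidates(candidates):
    """Total priority order over filter-passing candidates.

    Keys, in order: fewer CDS off-targets; located in a Pfam domain; within
    the first 85% of the CDS; higher on-target score; then genomic position
    ascending with + before - as the final deterministic tie-break.
    """
    passing = [c for c in candidates if c.passes_filters]
    return sorted(
        passing,
        key=lambda c: (
            c.offtarget_count,
            not c.in_pfam,
            not (c.cds_frac is not None and c.cds_frac <= 0.85),
            -c.on_target_score,
            c.proto_start,
            c.strand != "+",
        ),
    )


# ---------------------------------------------------------------------------
# Dual-pair selection
# ---------------------------------------------------------------------------

@dataclass
class DualDesign:
    gene_id: str
    status: str
    pairs: list  # [(cand, cand)] in genomic order, leftmost pair first
    notes: list = field(default_factory=list)


def _interval_gap(a: SpacerCandidate, b: SpacerCandidate) -> int:
    """End-to-start gap between two protospacer intervals (< 0 if they
    overlap or touch out of order)."""
    if a.proto_start <= b.proto_start:
        return b.proto_start - a.proto_end
    return a.proto_start - b.proto_end


def _span(cands):
    return (min(c.proto_start for c in cands), max(c.proto_end for c in cands))


def _span_ok(cands, genome: GenomeModel, constraints: PairConstraints) -> bool:
    if not constraints.avoid_ncrna_overlap:
        return True
    s, e = _span(cands)
    return not genome.ncrna_index(cands[0].contig).overlaps(s, e)


def _pair_ok(a, b, genome, constraints) -> bool:
    return (_interval_gap(a, b) >= constraints.min_intra_pair_gap
            and _span_ok((a, b), genome, constraints))


def _exon_diversity(cands) -> int:
    return len({c.exon_index for c in cands})


def build_dual_pairs(gene, ranked_candidates, constraints: PairConstraints,
                     genome: GenomeModel) -> DualDesign:
    """Pick 2 constraint-satisfying pairs (4 spacers) of maximal priority.

    Minimises the summed rank index over all feasible 4-spacer/2-pair
    assignments within the top ``max_candidates_considered`` candidates
    (exhaustive, hence optimal at that scale); equal-priority assignments
    prefer more distinct exons.  Genes admitting only a single feasible pair
    get a partial design; genes with none are non-designable.
    """
    cands = ranked_candidates[:constraints.max_candidates_considered]
    n = len(cands)

    feasible_pairs = []  # (cost, i, j)
    for i in range(n):
        for j in range(i + 1, n):
            if _pair_ok(cands[i], cands[j], genome, constraints):
                feasible_pairs.append((i + j, i, j))
    feasible_pairs.sort()

    best_cost = None
    ties = []
    for a in range(len(feasible_pairs)):
        ca, ia, ja = feasible_pairs[a]
        if best_cost is not None and 2 * ca > best_cost:
            break
        for b in range(a + 1, len(feasible_pairs)):
            cb, ib, jb = feasible_pairs[b]
            if best_cost is not None and ca + cb > best_cost:
                break
            if len({ia, ja, ib, jb}) < 4:
                continue
            span_a = _span((cands[ia], cands[ja]))
            span_b = _span((cands[ib], cands[jb]))
            left, right = sorted([span_a, span_b])
            if right[0] - left[1] < constraints.min_inter_pair_gap:
                continue
            cost = ca + cb
            if best_cost is None or cost < best_cost:
                best_cost = cost
                ties = [(ia, ja, ib, jb)]
            elif cost == best_cost:
                ties.append((ia, ja, ib, jb))

    if best_cost is not None:
        pick = _break_ties(ties, cands, constraints)
        pair_a = tuple(sorted((cands[pick[0]], cands[pick[1]]),
                              key=lambda c: c.proto_start))
        pair_b = tuple(sorted((cands[pick[2]], cands[pick[3]]),
                              key=lambda c: c.proto_start))
        pairs = sorted([pair_a, pair_b], key=lambda p: p[0].proto_start)
        return DualDesign(gene.gene_id, FULLY_DESIGNED, pairs)

    if feasible_pairs:
        cost0 = feasible_pairs[0][0]
        tied = [(i, j) for c, i, j in feasible_pairs if c == cost0]
        pick = _break_ties(tied, cands, constraints)
        pair = tuple(sorted((cands[pick[0]], cands[pick[1]]),
                            key=lambda c: c.proto_start))
        return DualDesign(gene.gene_id, PARTIAL, [pair],
                          notes=["only one feasible pair"])

    note = ("fewer than 2 feasible spacers" if n < 2
            else "no constraint-satisfying pair")
    return DualDesign(gene.gene_id, NON_DESIGNABLE, [], notes=[note])


def _break_ties(assignments, cands, constraints):
    """Among equal-cost assignments prefer exon diversity, then the
    deterministically smallest index tuple."""
    def key(t):
        div = _exon_diversity([cands[i] for i in t])
        bonus = -div if constraints.require_exon_diversity else 0
        return (bonus, tuple(sorted(t)), t)
    return min(assignments, key=key)


# ---------------------------------------------------------------------------
# Quad-array selection
# ---------------------------------------------------------------------------

@dataclass
class QuadDesign:
    gene_id: str
    status: str
    quads: list  # [tuple of 4 candidates in genomic order]
    covered: list  # [set of transcript ids] parallel to quads
    notes: list = field(default_factory=list)


def _quad_ok(combo, genome, constraints) -> bool:
    ordered = sorted(combo, key=lambda c: c.proto_start)
    for a, b in zip(ordered, ordered[1:]):
        if b.proto_start - a.proto_end < constraints.min_intra_pair_gap:
            return False
    return _span_ok(ordered, genome, constraints)


def _coverage(cand, coding_transcripts):
    return {
        t.transcript_id for t in coding_transcripts
        if cds_fraction(t, cand.cut_pos) is not None
    }


def _best_quad(cands, genome, constraints, pool_idx):
    """Minimum-cost feasible quad within *pool_idx* (rank indices).

    Enumerates 4-subsets over a growing prefix; a solution whose cost rules
    out any subset touching the unexplored tail certifies global optimality,
    so the typical case stays far below full enumeration.
    """
    pool = sorted(pool_idx)
    if len(pool) < 4:
        return None
    best_cost, ties = None, []
    m = 8
    while True:
        m = min(m, len(pool))
        prefix = pool[:m]
        best_cost, ties = None, []
        for combo in itertools.combinations(range(m), 4):
            cost = sum(prefix[i] for i in combo)
            if best_cost is not None and cost > best_cost:
                continue
            group = [cands[prefix[i]] for i in combo]
            if not _quad_ok(group, genome, constraints):
                continue
            if best_cost is None or cost < best_cost:
                best_cost, ties = cost, [tuple(prefix[i] for i in combo)]
            elif cost == best_cost:
                ties.append(tuple(prefix[i] for i in combo))
        if m == len(pool):
            break
        # any subset using pool[m:] costs >= pool[m] + pool[0..2]
        tail_floor = pool[m] + pool[0] + pool[1] + pool[2]
        if best_cost is not None and best_cost < tail_floor:
            break
        m *= 2
    if best_cost is None:
        return None
    return _break_ties(ties, cands, constraints)


def build_quad_arrays(gene, ranked_candidates, constraints: PairConstraints,
                      genome: GenomeModel) -> QuadDesign:
    """Quad arrays covering all CDS-bearing isoforms of *gene*.

    The primary quad is drawn from candidates hitting every isoform when any
    feasible such quad exists; otherwise the quad covering the maximal
    isoform set is emitted and additional quads are designed for the
    remaining isoforms until all are covered or candidates run out.
    """
    cands = ranked_candidates[:constraints.max_candidates_considered]
    coding = [t for t in gene.transcripts if t.cds_length > 0]
    all_ids = {t.transcript_id for t in coding}
    cover = [_coverage(c, coding) for c in cands]

    if len(cands) < 4:
        return QuadDesign(gene.gene_id, NON_DESIGNABLE if not cands else PARTIAL,
                          [], [], notes=["fewer than 4 feasible spacers"])

    quads, covered_sets, notes = [], [], []
    remaining = set(all_ids)
    while remaining:
        pick = None
        # fast path: quad from candidates that each cover everything remaining
        full_pool = [i for i, cv in enumerate(cover) if remaining <= cv]
        if len(full_pool) >= 4:
            pick = _best_quad(cands, genome, constraints, full_pool)
            gain = set(remaining) if pick else None
        if pick is None:
            pick, gain = _max_coverage_quad(cands, cover, remaining, genome,
                                            constraints)
        if pick is None or not gain:
            notes.append(f"isoforms not coverable: {sorted(remaining)}")
            break
        group = tuple(sorted((cands[i] for i in pick),
                             key=lambda c: c.proto_start))
        quads.append(group)
        covered_sets.append(set().union(*(cover[i] for i in pick)))
        remaining -= gain
        if len(quads) > len(all_ids):  # safety: no infinite loop
            break

    if not quads:
        return QuadDesign(gene.gene_id, NON_DESIGNABLE, [], [],
                          notes=notes or ["no constraint-satisfying quad"])
    status = FULLY_DESIGNED if not remaining else PARTIAL
    if len(quads) > 1:
        notes.append("additional quad(s) emitted for remaining isoforms")
    return QuadDesign(gene.gene_id, status, quads, covered_sets, notes=notes)


def _max_coverage_quad(cands, cover, remaining, genome, constraints,
                       hard_cap: int = 30):
    """Feasible quad maximising newly covered isoforms, then priority."""
    pool = list(range(min(len(cands), hard_cap)))
    best = None  # (-gain, cost, combo)
    for combo in itertools.combinations(pool, 4):
        gain_set = set().union(*(cover[i] for i in combo)) & remaining
        gain = len(gain_set)
        if gain == 0:
            continue
        cost = sum(combo)
        key = (-gain, cost, combo)
        if best is not None and key >= best[0]:
            continue
        if not _quad_ok([cands[i] for i in combo], genome, constraints):
            continue
        best = (key, combo, gain_set)
    if best is None:
        return None, None
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Cassette assembly
# ---------------------------------------------------------------------------

def assemble_cassette(construct: GuideConstruct, dr_seqs=None,
                      overhangs=(SENSE_OVERHANG, ANTISENSE_OVERHANG),
                      restriction_sites=("GAATTC", "GGTACC")) -> GuideConstruct:
    """Assemble DR-interleaved cassette and cloning oligos in place.

    cassette = DR1 + spacer1 + DR2 + spacer2 + ...; the sense oligo prepends
    the TCCC overhang, the antisense oligo is AAAC + reverse complement of
    the cassette.  Oligos containing a forbidden restriction site on either
    strand are flagged and deselected rather than raising.
    """
    if not construct.spacers:
        raise ValueError(f"{construct.construct_id}: no spacers to assemble")
    if dr_seqs is None:
        dr_seqs = construct.dr_seqs or [DEFAULT_DR] * len(construct.spacers)
    if len(dr_seqs) < len(construct.spacers):
        raise ValueError(
            f"{construct.construct_id}: need {len(construct.spacers)} DRs, "
            f"got {len(dr_seqs)}"
        )
    drs = list(dr_seqs[:len(construct.spacers)])
    cassette = "".join(dr + sp for dr, sp in zip(drs, construct.spacers))
    construct.dr_seqs = drs
    construct.cassette_seq = cassette
    construct.sense_oligo = overhangs[0] + cassette
    construct.antisense_oligo = overhangs[1] + revcomp(cassette)
    for oligo in (construct.sense_oligo, construct.antisense_oligo):
        scan = oligo + "/" + revcomp(oligo)
        if any(site in scan for site in restriction_sites):
            construct.flags.add("RESTRICTION_SITE")
            construct.selected = False
    return construct


# ---------------------------------------------------------------------------
# Non-targeting controls
# ---------------------------------------------------------------------------

def generate_ntcs(n: int, genome: GenomeModel, mode: str = "DUAL",
                  filter_config: FilterConfig | None = None, seed: int = 0,
                  dr_seqs=None, max_mismatches: int = 3,
                  scanner: GenomeMismatchScanner | None = None):
    """Generate *n* non-targeting control constructs (reproducible per seed).

    Every NTC spacer passes the hard filters and has zero genomic matches at
    <= *max_mismatches* on either strand, PAM-agnostic.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    config = filter_config or FilterConfig()
    per = 2 if mode.upper() == "DUAL" else 4
    kind = f"NTC_{mode.upper()}"
    if mode.upper() not in ("DUAL", "QUAD"):
        raise ValueError(f"unknown NTC mode {mode!r}")
    needed = n * per
    if scanner is None:
        scanner = GenomeMismatchScanner(genome)
    # key the stream so a seed shared with the genome simulator does not
    # replay the very draws that produced the genome sequence
    rng = np.random.default_rng((seed, 0x4E5443))
    bases = np.array(list("ACGT"))

    spacers, seen = [], set()
    budget = max(1000, 200 * needed)
    attempts = 0
    while len(spacers) < needed and attempts < budget:
        attempts += 1
        sp = "".join(bases[rng.integers(0, 4, size=config.spacer_len)])
        if sp in seen:
            continue
        if "T" * config.poly_t_min_run in sp:
            continue
        gc = gc_percent(sp)
        if gc < config.gc_min_pct or gc > config.gc_max_pct:
            continue
        ctx = DEFAULT_DR + sp + DEFAULT_DR
        scan = ctx + "/" + revcomp(ctx)
        if any(site in scan for site in config.restriction_sites):
            continue
        if scanner.count_hits(sp, max_mismatches) != 0:
            continue
        seen.add(sp)
        spacers.append(sp)
    if len(spacers) < needed:
        raise RuntimeError(
            f"NTC generation exhausted attempt budget: found "
            f"{len(spacers)}/{needed} valid spacers"
        )

    out = []
    for i in range(n):
        c = GuideConstruct(
            construct_id=f"NTC_{mode.upper()}_{i + 1:04d}",
            kind=kind,
            gene_id="NTC",
            spacers=spacers[i * per:(i + 1) * per],
        )
        assemble_cassette(c, dr_seqs=dr_seqs)
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Whole-library drivers
# ---------------------------------------------------------------------------

def _prepare_candidates(genome, gene, config, scanner, scorer):
    cands = enumerate_spacers(genome, gene, config)
    for c in cands:
        if not c.passes_filters:
            continue
        c.offtarget_count = scanner.count(c, config.max_mismatches)
        c.on_target_score = score_on_target(
            c, candidate_context(genome, c), scorer=scorer, config=config)
    return rank_candidates(cands)


def design_dual_library(genome: GenomeModel,
                        filter_config: FilterConfig | None = None,
                        constraints: PairConstraints | None = None,
                        n_ntc: int = 500, seed: int = 0,
                        scorer=default_scorer, dr_seqs=None) -> LibraryTable:
    """Design a dual library: 2 pairs (2 constructs) per designable gene
    plus *n_ntc* NTC pairs."""
    config = filter_config or FilterConfig()
    constraints = constraints or PairConstraints()
    scanner = CdsOfftargetScanner(genome, config)
    constructs, report = [], {}
    for gene in genome.genes:
        if not gene.designable:
            report[gene.gene_id] = {"status": NON_DESIGNABLE,
                                    "notes": ["no CDS-bearing transcript"]}
            continue
        ranked = _prepare_candidates(genome, gene, config, scanner, scorer)
        design = build_dual_pairs(gene, ranked, constraints, genome)
        report[gene.gene_id] = {"status": design.status, "notes": design.notes}
        for k, pair in enumerate(design.pairs):
            c = GuideConstruct(
                construct_id=f"{gene.gene_id}_{'AB'[k]}",
                kind="DUAL",
                gene_id=gene.gene_id,
                spacers=[cand.spacer_seq for cand in pair],
                candidates=list(pair),
            )
            assemble_cassette(c, dr_seqs=dr_seqs)
            constructs.append(c)
    if n_ntc:
        constructs.extend(
            generate_ntcs(n_ntc, genome, "DUAL", config, seed, dr_seqs=dr_seqs)
        )
    return LibraryTable(constructs, report)


def design_quad_library(genome: GenomeModel,
                        filter_config: FilterConfig | None = None,
                        constraints: PairConstraints | None = None,
                        n_ntc: int = 500, seed: int = 0,
                        scorer=default_scorer, dr_seqs=None) -> LibraryTable:
    """Design a quad library: >= 1 four-spacer array per designable gene
    (extra arrays cover isoforms missed by the primary one) plus NTC quads."""
    config = filter_config or FilterConfig()
    constraints = constraints or PairConstraints()
    scanner = CdsOfftargetScanner(genome, config)
    constructs, report = [], {}
    for gene in genome.genes:
        if not gene.designable:
            report[gene.gene_id] = {"status": NON_DESIGNABLE,
                                    "notes": ["no CDS-bearing transcript"]}
            continue
        ranked = _prepare_candidates(genome, gene, config, scanner, scorer)
        design = build_quad_arrays(gene, ranked, constraints, genome)
        report[gene.gene_id] = {"status": design.status, "notes": design.notes}
        for k, quad in enumerate(design.quads):
            c = GuideConstruct(
                construct_id=f"{gene.gene_id}_Q{k + 1}",
                kind="QUAD",
                gene_id=gene.gene_id,
                spacers=[cand.spacer_seq for cand in quad],
                candidates=list(quad),
            )
            assemble_cassette(c, dr_seqs=dr_seqs)
            constructs.append(c)
    if n_ntc:
        constructs.extend(
            generate_ntcs(n_ntc, genome, "QUAD", config, seed, dr_seqs=dr_seqs)
        )
    return LibraryTable(constructs, report)


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

_LIB_COLUMNS = (
    ["construct_id", "kind", "gene_id"]
    + [f"spacer{i}" for i in range(1, 5)]
    + [f"dr{i}" for i in range(1, 5)]
    + ["cassette_seq", "sense_oligo", "antisense_oligo"]
)


def write_library(table: LibraryTable, path) -> None:
    """One row per construct; empty strings pad unused spacer/DR slots."""
    ids = [c.construct_id for c in table.constructs]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate construct ids in library")
    rows = []
    for c in table.constructs:
        row = {"construct_id": c.construct_id, "kind": c.kind,
               "gene_id": c.gene_id}
        for i in range(4):
            row[f"spacer{i + 1}"] = c.spacers[i] if i < len(c.spacers) else ""
            row[f"dr{i + 1}"] = c.dr_seqs[i] if i < len(c.dr_seqs) else ""
        row["cassette_seq"] = c.cassette_seq
        row["sense_oligo"] = c.sense_oligo
        row["antisense_oligo"] = c.antisense_oligo
        rows.append(row)
    df = pd.DataFrame(rows, columns=_LIB_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_library(path) -> LibraryTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    constructs = []
    for _, row in df.iterrows():
        spacers = [row[f"spacer{i}"] for i in range(1, 5) if row[f"spacer{i}"]]
        drs = [row[f"dr{i}"] for i in range(1, 5) if row[f"dr{i}"]]
        constructs.append(GuideConstruct(
            construct_id=row["construct_id"],
            kind=row["kind"],
            gene_id=row["gene_id"],
            spacers=spacers,
            dr_seqs=drs,
            cassette_seq=row["cassette_seq"],
            sense_oligo=row["sense_oligo"],
            antisense_oligo=row["antisense_oligo"],
        ))
    return LibraryTable(constructs)
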