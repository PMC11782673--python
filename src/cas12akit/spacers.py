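"""Cas12a spacer candidate enumeration, hard filters, off-target counting
and a pluggable on-target activity surrogate.

Candidates are 23-mer protospacers adjacent to a T-rich PAM (default TTTV)
whose predicted cut position falls inside the canonical transcript's CDS.
Hard filters follow pooled-library cloning practice: poly-T stretches,
extreme GC, restriction sites in the cloning context, ambiguous bases.
"""

from __future__ import annotations

import math
import re
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from ._seq import (compile_motifs, gc_percent, iupac_regex, max_homopolymer,
                   revcomp)
from .genome import GeneModel, GenomeModel, cds_fraction

# Direct repeat recognized by Cas12a during pre-crRNA maturation; each spacer
# is cloned 3' of one of these, so filter checks use it as sequence context.
DEFAULT_DR = "TAATTTCTACTCTTGTAGAT"

_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_revcomp(pattern: str) -> str:
    return pattern.upper().translate(_IUPAC_COMP)[::-1]


@dataclass
class FilterConfig:
    """Hard-filter and enumeration parameters."""

    gc_min_pct: float = 20.0
    gc_max_pct: float = 80.0
    poly_t_min_run: int = 4
    restriction_sites: tuple = ("GAATTC", "GGTACC")  # EcoRI, KpnI
    spacer_len: int = 23
    pam_patterns: tuple = ("TTTV",)
    pam_len: int = 4
    max_mismatches: int = 3  # off-target search budget

    def __post_init__(self):
        if not (0 <= self.gc_min_pct < self.gc_max_pct <= 100):
            raise ValueError("invalid GC bounds")
        for p in self.pam_patterns:
            if len(p) != self.pam_len:
                raise ValueError(f"PAM pattern {p!r} length != {self.pam_len}")


@dataclass
class SpacerCandidate:
    """One protospacer candidate with its annotation-derived metadata."""

    gene_id: str
    transcript_id: str
    contig: str
    strand: str  # strand of the protospacer
    pam_start: int  # genomic start of the 4-nt PAM
    pam_seq: str
    spacer_seq: str  # read on the protospacer strand, PAM-proximal first
    proto_start: int  # genomic interval of the protospacer
    proto_end: int
    cut_pos: int
    gc_percent: float = 0.0
    filter_flags: set = field(default_factory=set)
    offtarget_count: int = 0
    on_target_score: float = 0.0
    cds_frac: float | None = None
    exon_index: int = -1
    in_pfam: bool = False

    @property
    def passes_filters(self) -> bool:
        return not self.filter_flags


def apply_filters(candidate: SpacerCandidate, config: FilterConfig,
                  dr_seq: str = DEFAULT_DR) -> SpacerCandidate:
    """Set hard-filter flags on *candidate* (idempotent, order-independent).

    The restriction-site check runs on the spacer embedded in its cloning
    context (flanking DRs), on both strands, because cloning compatibility is
    a property of the synthesized oligo rather than the bare spacer.
    """
    seq = candidate.spacer_seq
    flags = set()
    if set(seq) - set("ACGT"):
        flags.add("AMBIGUOUS_BASE")
    if "T" * config.poly_t_min_run in seq:
        flags.add("POLY_T")
    gc = gc_percent(seq)
    candidate.gc_percent = gc
    if gc < config.gc_min_pct:
        flags.add("GC_LOW")
    if gc > config.gc_max_pct:
        flags.add("GC_HIGH")
    context = dr_seq + seq + dr_seq
    both = context + "/" + revcomp(context)
    if any(site in both for site in config.restriction_sites):
        flags.add("RESTRICTION_SITE")
    candidate.filter_flags = flags
    return candidate


def _cut_offset(config: FilterConfig) -> int:
    # Cas12a cuts ~18 nt distal to the PAM on the protospacer strand;
    # used as the nominal target position for CDS bookkeeping.
    return min(18, config.spacer_len - 1)


def enumerate_spacers(genome: GenomeModel, gene: GeneModel,
                      config: FilterConfig | None = None,
                      dr_seq: str = DEFAULT_DR):
    """All PAM-adjacent spacer candidates whose cut lies in the canonical CDS.

    Scans both strands of the gene's neighbourhood; candidates are returned
    ordered by genomic protospacer start, then strand (+ before -), with
    filter flags, ``cds_frac``, ``exon_index`` and ``in_pfam`` populated.
    Off-target counts and scores are filled in by the caller.
    """
    config = config or FilterConfig()
    if not gene.designable:
        return []
    canonical = gene.canonical
    contig_seq = genome.contigs[gene.contig]
    L = config.spacer_len
    P = config.pam_len
    cut_off = _cut_offset(config)

    gs, ge = gene.genomic_span()
    lo = max(0, gs - (L + P))
    hi = min(len(contig_seq), ge + (L + P))
    window = contig_seq[lo:hi]

    fwd_re = compile_motifs(config.pam_patterns)
    rev_re = compile_motifs([iupac_revcomp(p) for p in config.pam_patterns])
    pfam_idx = genome.pfam_index(gene.contig)

    out = []
    for m in fwd_re.finditer(window):
        p = lo + m.start()
        if p + P + L > len(contig_seq):
            continue
        cut = p + P + cut_off
        frac = cds_fraction(canonical, cut)
        if frac is None:
            continue
        spacer = contig_seq[p + P:p + P + L]
        out.append(_make_candidate(
            gene, canonical, contig_seq, "+", p, spacer,
            p + P, p + P + L, cut, frac, pfam_idx, config, dr_seq))
    for m in rev_re.finditer(window):
        p = lo + m.start()
        if p - L < 0:
            continue
        cut = p - 1 - cut_off
        frac = cds_fraction(canonical, cut)
        if frac is None:
            continue
        spacer = revcomp(contig_seq[p - L:p])
        out.append(_make_candidate(
            gene, canonical, contig_seq, "-", p, spacer,
            p - L, p, cut, frac, pfam_idx, config, dr_seq))
    out.sort(key=lambda c: (c.proto_start, c.strand != "+"))
    return out


def _make_candidate(gene, transcript, contig_seq, strand, pam_start, spacer,
                    proto_start, proto_end, cut, frac, pfam_idx, config,
                    dr_seq):
    pam = contig_seq[pam_start:pam_start + config.pam_len]
    if strand == "-":
        pam = revcomp(pam)
    exon_index = -1
    for i, (s, e) in enumerate(transcript.exons):
        if s <= cut < e:
            exon_index = i
            break
    cand = SpacerCandidate(
        gene_id=gene.gene_id,
        transcript_id=transcript.transcript_id,
        contig=gene.contig,
        strand=strand,
        pam_start=pam_start,
        pam_seq=pam,
        spacer_seq=spacer,
        proto_start=proto_start,
        proto_end=proto_end,
        cut_pos=cut,
        cds_frac=frac,
        exon_index=exon_index,
        in_pfam=pfam_idx.overlaps_point(cut),
    )
    return apply_filters(cand, config, dr_seq)


# ---------------------------------------------------------------------------
# Off-target counting over CDS
# ---------------------------------------------------------------------------

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _merged_intervals(intervals):
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


class CdsOfftargetScanner:
    """Pre-indexed scan of every PAM-adjacent window overlapping any CDS.

    Collects, once per genome, the protospacer window behind every PAM match
    (both strands) whose window intersects a CDS segment of any transcript of
    any gene, then answers per-candidate Hamming queries vectorised.
    """

    def __init__(self, genome: GenomeModel, config: FilterConfig | None = None):
        self.config = config or FilterConfig()
        cfg = self.config
        L, P = cfg.spacer_len, cfg.pam_len
        fwd_re = compile_motifs(cfg.pam_patterns)
        rev_re = compile_motifs([iupac_revcomp(p) for p in cfg.pam_patterns])

        windows, keys = [], []
        for contig, seq in genome.contigs.items():
            cds = [
                seg
                for g in genome.genes if g.contig == contig
                for t in g.transcripts
                for seg in t.cds_segments
            ]
            if not cds:
                continue
            merged = _merged_intervals(cds)
            starts = [iv[0] for iv in merged]
            ends = [iv[1] for iv in merged]
            enc = encode_seq(seq)

            def in_cds(ws, we):
                # merged intervals are disjoint and sorted, so only the last
                # interval starting before the window end can overlap it
                i = bisect_right(starts, we - 1) - 1
                return i >= 0 and ends[i] > ws

            for m in fwd_re.finditer(seq):
                p = m.start()
                if p + P + L <= len(seq) and in_cds(p + P, p + P + L):
                    windows.append(enc[p + P:p + P + L])
                    keys.append((contig, p, "+"))
            for m in rev_re.finditer(seq):
                p = m.start()
                if p - L >= 0 and in_cds(p - L, p):
                    windows.append(_COMP_CODE[enc[p - L:p]][::-1])
                    keys.append((contig, p, "-"))

        self._windows = (
            np.vstack(windows) if windows else np.empty((0, L), dtype=np.uint8)
        )
        self._keys = keys
        self._key_pos = {}
        for i, k in enumerate(keys):
            self._key_pos.setdefault(k, []).append(i)

    def count(self, candidate: SpacerCandidate, max_mismatches: int) -> int:
        if max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not self._keys:
            return 0
        sp = encode_seq(candidate.spacer_seq)
        diffs = (self._windows != sp).sum(axis=1)
        hits = int((diffs <= max_mismatches).sum())
        own = (candidate.contig, candidate.pam_start, candidate.strand)
        for i in self._key_pos.get(own, ()):
            if diffs[i] <= max_mismatches:
                hits -= 1
        return hits


def count_cds_offtargets(candidate: SpacerCandidate, genome: GenomeModel,
                         max_mismatches: int = 3,
                         scanner: CdsOfftargetScanner | None = None) -> int:
    """Number of PAM-adjacent, CDS-overlapping sites within *max_mismatches*
    of the candidate spacer, excluding the intended on-target site."""
    if scanner is None:
        scanner = CdsOfftargetScanner(genome)
    return scanner.count(candidate, max_mismatches)


# ---------------------------------------------------------------------------
# PAM-agnostic genome-wide mismatch scan (NTC validation)
# ---------------------------------------------------------------------------

class GenomeMismatchScanner:
    """Counts genome-wide matches of a spacer at <= max_mm mismatches on
    either strand, with no PAM requirement.

    Uses the pigeonhole principle: with ``max_mm`` mismatches, at least one
    of ``max_mm + 1`` disjoint 5-mer chunks of the spacer is exact, so exact
    5-mer index hits seed full-window verification.  Supports max_mm <= 3
    for 23-mers.
    """

    K = 5

    def __init__(self, genome_or_contigs):
        contigs = (
            genome_or_contigs.contigs
            if isinstance(genome_or_contigs, GenomeModel) else genome_or_contigs
        )
        self._enc = {}
        self._index = {}
        for name, seq in contigs.items():
            enc = encode_seq(seq)
            self._enc[name] = enc
            n = len(enc) - self.K + 1
            if n <= 0:
                continue
            valid = np.ones(n, dtype=bool)
            kid = np.zeros(n, dtype=np.int64)
            for i in range(self.K):
                chunk = enc[i:i + n]
                valid &= chunk < 4
                kid = kid * 4 + chunk
            kid[~valid] = -1
            order = np.argsort(kid, kind="stable")
            self._index[name] = (kid[order], order.astype(np.int64))

    def _chunk_positions(self, name, kmer_code, offset):
        sorted_kid, order = self._index[name]
        lo = np.searchsorted(sorted_kid, kmer_code, side="left")
        hi = np.searchsorted(sorted_kid, kmer_code, side="right")
        return order[lo:hi] - offset

    def count_hits(self, spacer: str, max_mm: int = 3) -> int:
        if max_mm > 3:
            raise ValueError("pigeonhole index supports max_mm <= 3")
        L = len(spacer)
        total = 0
        for query in (spacer, revcomp(spacer)):
            q = encode_seq(query)
            if (q > 3).any():
                continue
            offsets = [i * self.K for i in range(max_mm + 1)]
            for name, enc in self._enc.items():
                if name not in self._index or len(enc) < L:
                    continue
                pos_parts = []
                for off in offsets:
                    code = 0
                    for b in q[off:off + self.K]:
                        code = code * 4 + int(b)
                    pos_parts.append(self._chunk_positions(name, code, off))
                pos = np.unique(np.concatenate(pos_parts)) if pos_parts else []
                if len(pos) == 0:
                    continue
                pos = pos[(pos >= 0) & (pos <= len(enc) - L)]
                if len(pos) == 0:
                    continue
                win = enc[pos[:, None] + np.arange(L)]
                total += int(((win != q).sum(axis=1) <= max_mm).sum())
        return total


# ---------------------------------------------------------------------------
# On-target activity surrogate
# ---------------------------------------------------------------------------

_SURROGATE_WEIGHTS = (-1.0, 1.5, 1.0, 0.5)  # bias, PAM, GC, homopolymer


def default_scorer(spacer_seq: str, pam_seq: str) -> float:
    """Fixed logistic surrogate for on-target activity.

    Combines PAM canonicalness (TTTV), distance of spacer GC from 50%, and
    absence of >= 4-nt homopolymer runs.  Deterministic, bounded in (0, 1).
    This stands in for gradient-boosting activity models whose weights are
    not redistributable; swap in any callable with the same signature.
    """
    b0, b_pam, b_gc, b_run = _SURROGATE_WEIGHTS
    canonical = 1.0 if re.fullmatch(iupac_regex("TTTV"), pam_seq) else 0.0
    gc_term = 1.0 - abs(gc_percent(spacer_seq) - 50.0) / 50.0
    run_term = 1.0 if max_homopolymer(spacer_seq) < 4 else 0.0
    z = b0 + b_pam * canonical + b_gc * gc_term + b_run * run_term
    return 1.0 / (1.0 + math.exp(-z))


def score_on_target(candidate: SpacerCandidate, context_seq: str,
                    scorer=default_scorer,
                    config: FilterConfig | None = None) -> float:
    """Score a candidate from its PAM + protospacer + flank context.

    *context_seq* is read on the protospacer strand and must span at least
    PAM + spacer + 4 nt of flank on each side.
    """
    config = config or FilterConfig()
    needed = config.pam_len + config.spacer_len + 8
    if len(context_seq) < needed:
        raise ValueError(
            f"context too short: need >= {needed} nt, got {len(context_seq)}"
        )
    score = float(scorer(candidate.spacer_seq, candidate.pam_seq))
    if not (0.0 <= score <= 1.0):
        raise ValueError("scorer returned a value outside [0, 1]")
    return score


def candidate_context(genome: GenomeModel, candidate: SpacerCandidate,
                      flank: int = 10) -> str:
    """Genomic context around a candidate on the protospacer strand."""
    seq = genome.contigs[candidate.contig]
    if candidate.strand == "+":
        lo = max(0, candidate.pam_start - flank)
        hi = min(len(seq), candidate.proto_end + flank)
        return seq[lo:hi]
    lo = max(0, candidate.proto_start - flank)
    hi = min(len(seq), candidate.pam_start + 4 + flank)
    return revcomp(seq[lo:hi])
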