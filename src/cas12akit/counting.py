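"""Screen read counting and log-CPM normalisation.

Reads are assigned to library constructs by DR-anchored spacer extraction:
find the first direct-repeat anchor in the read, take the following 23 nt,
and look them up in the (validated-unique) position-1 spacer dictionary.
Short single-end reads rarely cover a whole 250-350 bp array, hence
position-1 identity is the default; a verify-all-positions mode exists for
long reads.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import hamming
from .spacers import DEFAULT_DR


@dataclass
class AnchorConfig:
    anchor_seq: str = DEFAULT_DR
    anchor_max_mismatches: int = 0  # 0 = exact anchor only
    spacer_max_mismatches: int = 0  # 0 = exact spacer match
    spacer_len: int = 23
    verify_all_positions: bool = False


@dataclass
class CountMatrix:
    """Constructs x samples non-negative integer counts plus metadata."""

    construct_ids: list
    sample_ids: list
    counts: np.ndarray  # shape (n_constructs, n_samples), int
    sample_meta: pd.DataFrame = None  # index sample_id: condition/replicate/timepoint
    unassigned: dict = field(default_factory=dict)  # sample_id -> int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.construct_ids), len(self.sample_ids)):
            raise ValueError("count matrix dimensions inconsistent with ids")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.construct_ids,
                            columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "construct_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, sample_meta=None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns),
                   df.to_numpy(dtype=np.int64), sample_meta=sample_meta)


@dataclass
class LogCpmMatrix:
    values: np.ndarray  # log2 CPM, constructs x samples
    construct_ids: list
    sample_ids: list
    pseudocount: float
    library_sizes: np.ndarray  # per-sample assigned totals
    counts: np.ndarray = None  # raw counts retained for variance-trend fits


def _open_maybe_gz(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(path):
    """Yield (read_id, sequence) from a plain or gzipped FASTQ."""
    with _open_maybe_gz(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper()


def _find_anchor(read: str, anchor: str, max_mm: int) -> int:
    """Position of the first anchor occurrence, or -1.

    Exact search first (fast path); the mismatch-tolerant sliding scan only
    runs when the exact search fails and mismatches are allowed.
    """
    pos = read.find(anchor)
    if pos >= 0 or max_mm == 0:
        return pos
    la = len(anchor)
    for i in range(len(read) - la + 1):
        if hamming(read[i:i + la], anchor, limit=max_mm) <= max_mm:
            return i
    return -1


class _SpacerLookup:
    def __init__(self, spacers, construct_ids, max_mm):
        self.exact = dict(zip(spacers, construct_ids))
        self.max_mm = max_mm
        if max_mm > 0:
            self._mat = np.array(
                [list(s.encode()) for s in spacers], dtype=np.uint8)
            self._ids = list(construct_ids)

    def __call__(self, seq: str):
        hit = self.exact.get(seq)
        if hit is not None or self.max_mm == 0:
            return hit
        q = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(q) != self._mat.shape[1]:
            return None
        d = (self._mat != q).sum(axis=1)
        best = d.min()
        if best > self.max_mm or (d == best).sum() != 1:
            return None  # ambiguous or too distant
        return self._ids[int(d.argmin())]


def count_reads(fastq_by_sample: dict, library, config: AnchorConfig | None = None,
                sample_meta: pd.DataFrame = None) -> CountMatrix:
    """Count reads per construct for each sample.

    *fastq_by_sample* maps sample_id -> FASTQ path (plain or gzip).
    Position-1 spacers must be unique across the library (collisions are
    fatal).  Reads failing anchor detection, spacer lookup, or (in
    verify-all-positions mode) downstream array verification increment the
    per-sample unassigned tally, so assigned + unassigned always equals the
    total number of reads processed.
    """
    config = config or AnchorConfig()
    constructs = library.constructs
    pos1 = [c.spacers[0] for c in constructs]
    if len(set(pos1)) != len(pos1):
        dup = sorted({s for s in pos1 if pos1.count(s) > 1})
        raise ValueError(
            f"position-1 spacer collisions across constructs: {dup[:3]}"
        )
    ids = [c.construct_id for c in constructs]
    lookup = _SpacerLookup(pos1, ids, config.spacer_max_mismatches)
    row = {cid: i for i, cid in enumerate(ids)}
    by_id = {c.construct_id: c for c in constructs}
    anchor = config.anchor_seq
    la = len(anchor)
    L = config.spacer_len

    sample_ids = list(fastq_by_sample)
    counts = np.zeros((len(ids), len(sample_ids)), dtype=np.int64)
    unassigned = {}
    for si, sid in enumerate(sample_ids):
        total = assigned = miss_anchor = 0
        for _, seq in _iter_fastq(fastq_by_sample[sid]):
            total += 1
            pos = _find_anchor(seq, anchor, config.anchor_max_mismatches)
            if pos < 0:
                miss_anchor += 1
                continue
            start = pos + la
            spacer = seq[start:start + L]
            if len(spacer) < L:
                continue
            cid = lookup(spacer)
            if cid is None:
                continue
            if config.verify_all_positions:
                if not _verify_array(seq, start + L, by_id[cid], config):
                    continue
            counts[row[cid], si] += 1
            assigned += 1
            if total == 10_000 and miss_anchor > 0.95 * total:
                warnings.warn(
                    f"sample {sid}: anchor {anchor!r} absent from >95% of the "
                    f"first 10,000 reads; check the DR/anchor dialect",
                    stacklevel=2,
                )
        unassigned[sid] = total - assigned
    return CountMatrix(ids, sample_ids, counts, sample_meta=sample_meta,
                       unassigned=unassigned)


def _verify_array(seq, offset, construct, config: AnchorConfig) -> bool:
    """Require every downstream DR + spacer of the array to match exactly."""
    pos = offset
    for dr, spacer in zip(construct.dr_seqs[1:], construct.spacers[1:]):
        expected = dr + spacer
        chunk = seq[pos:pos + len(expected)]
        if chunk != expected:
            return False
        pos += len(expected)
    return True


def normalize_log_cpm(counts: CountMatrix, pseudocount: float = 0.5) -> LogCpmMatrix:
    """log2 counts-per-million with a continuity pseudocount.

    value = log2((count + pc) / (library_size + 2 * pc) * 1e6), library size
    being the per-sample column sum.  Zero-depth samples are an error.
    """
    mat = counts.counts.astype(float)
    lib = mat.sum(axis=0)
    zero = [sid for sid, s in zip(counts.sample_ids, lib) if s <= 0]
    if zero:
        raise ValueError(f"zero-depth sample(s): {zero}")
    values = np.log2((mat + pseudocount) / (lib + 2 * pseudocount) * 1e6)
    return LogCpmMatrix(
        values=values,
        construct_ids=list(counts.construct_ids),
        sample_ids=list(counts.sample_ids),
        pseudocount=pseudocount,
        library_sizes=lib,
        counts=counts.counts.copy(),
    )
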