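"""Genome + annotation object model.

Ingests FASTA/GFF3 (Ensembl-style gene/mRNA/exon/CDS features with ``Parent``
attributes) plus optional BED tracks of Pfam domains and non-coding elements
into a validated, coordinate-safe :class:`GenomeModel`.  All internal
coordinates are 0-based half-open; GFF3 (1-based closed) is converted on
ingest and on write, BED is taken as-is.

Non-coding RNA features found directly in the GFF3 (types miRNA, tRNA,
lncRNA, rRNA, snRNA, snoRNA) are merged with the optional BED track into a
single interval set used by the library designer to avoid deleting
functional non-coding elements.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

from ._seq import revcomp
from .intervals import IntervalIndex

NCRNA_FEATURE_TYPES = frozenset(
    {"miRNA", "tRNA", "lncRNA", "rRNA", "snRNA", "snoRNA"}
)


class GenomeError(ValueError):
    """Raised on unresolvable or inconsistent annotation."""


@dataclass
class TranscriptModel:
    """One transcript: exons and CDS segments in transcription order."""

    transcript_id: str
    strand: str
    exons: list  # [(start, end)] genomic, transcription order
    cds_segments: list  # [(start, end)] genomic, transcription order

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    def genomic_span(self):
        coords = [c for s, e in self.exons for c in (s, e)]
        return min(coords), max(coords)


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    transcripts: list
    canonical_transcript_id: str | None = None

    @property
    def designable(self) -> bool:
        """A gene is designable when a CDS-bearing canonical transcript exists."""
        return self.canonical_transcript_id is not None

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)

    @property
    def canonical(self) -> TranscriptModel:
        if self.canonical_transcript_id is None:
            raise GenomeError(f"gene {self.gene_id} has no CDS-bearing transcript")
        return self.transcript(self.canonical_transcript_id)

    def genomic_span(self):
        coords = [c for t in self.transcripts for s, e in t.exons for c in (s, e)]
        return min(coords), max(coords)


@dataclass
class GenomeModel:
    """Contig sequences plus gene structures and auxiliary interval tracks."""

    contigs: dict  # name -> uppercase DNA string
    genes: list  # [GeneModel], sorted by (contig, gene_id)
    ncrna_intervals: set = field(default_factory=set)  # {(contig, start, end)}
    pfam_intervals: set = field(default_factory=set)  # {(contig, start, end, dom)}
    _ncrna_index: dict = field(default_factory=dict, repr=False, compare=False)
    _pfam_index: dict = field(default_factory=dict, repr=False, compare=False)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def ncrna_index(self, contig: str) -> IntervalIndex:
        if contig not in self._ncrna_index:
            self._ncrna_index[contig] = IntervalIndex(
                [(s, e) for c, s, e in self.ncrna_intervals if c == contig]
            )
        return self._ncrna_index[contig]

    def pfam_index(self, contig: str) -> IntervalIndex:
        if contig not in self._pfam_index:
            self._pfam_index[contig] = IntervalIndex(
                [(s, e, d) for c, s, e, d in self.pfam_intervals if c == contig]
            )
        return self._pfam_index[contig]

    def validate(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise GenomeError(f"contig {name}: invalid characters {sorted(bad)}")
        for g in self.genes:
            if g.contig not in self.contigs:
                raise GenomeError(f"gene {g.gene_id}: unknown contig {g.contig!r}")
            clen = len(self.contigs[g.contig])
            for t in g.transcripts:
                if t.strand != g.strand:
                    raise GenomeError(
                        f"transcript {t.transcript_id}: strand differs from gene"
                    )
                for s, e in t.exons + t.cds_segments:
                    if not (0 <= s < e <= clen):
                        raise GenomeError(
                            f"transcript {t.transcript_id}: interval ({s},{e}) "
                            f"out of bounds on {g.contig}"
                        )
                exons_sorted = sorted(t.exons)
                for (s1, e1), (s2, e2) in zip(exons_sorted, exons_sorted[1:]):
                    if s2 < e1:
                        raise GenomeError(
                            f"transcript {t.transcript_id}: overlapping exons"
                        )
                for cs, ce in t.cds_segments:
                    if not any(s <= cs and ce <= e for s, e in t.exons):
                        raise GenomeError(
                            f"transcript {t.transcript_id}: CDS ({cs},{ce}) "
                            f"not contained in an exon"
                        )
            if g.canonical_transcript_id is not None:
                g.transcript(g.canonical_transcript_id)
        for c, s, e in self.ncrna_intervals:
            self._check_interval(c, s, e, "ncRNA")
        for c, s, e, _ in self.pfam_intervals:
            self._check_interval(c, s, e, "Pfam")

    def _check_interval(self, contig, start, end, what):
        if contig not in self.contigs:
            raise GenomeError(f"{what} interval: unknown contig {contig!r}")
        if not (0 <= start < end <= len(self.contigs[contig])):
            raise GenomeError(
                f"{what} interval ({start},{end}) out of bounds on {contig}"
            )


def spliced_cds_seq(genome: GenomeModel, gene: GeneModel,
                    transcript: TranscriptModel) -> str:
    """Spliced CDS sequence in transcription (5'->3' mRNA) order."""
    contig = genome.contigs[gene.contig]
    parts = [contig[s:e] for s, e in transcript.cds_segments]
    if gene.strand == "-":
        return "".join(revcomp(p) for p in parts)
    return "".join(parts)


def cds_fraction(transcript: TranscriptModel, genomic_pos: int) -> float | None:
    """Fractional position of *genomic_pos* along the spliced CDS.

    Returns ``(1 + spliced offset) / cds_length`` when the position falls in a
    CDS segment, else None ("undefined").  The offset respects strand: base 0
    is the first coding base in transcription order.
    """
    clen = transcript.cds_length
    if clen == 0:
        return None
    offset = 0
    for s, e in transcript.cds_segments:
        if s <= genomic_pos < e:
            if transcript.strand == "+":
                return (1 + offset + (genomic_pos - s)) / clen
            return (1 + offset + (e - 1 - genomic_pos)) / clen
        offset += e - s
    return None


def select_canonical_transcript(gene: GeneModel, gff_tags: dict) -> str | None:
    """Resolve the canonical transcript of *gene*.

    Preference: a transcript whose annotation tags contain "canonical"
    (case-insensitive); otherwise the longest-CDS transcript; ties broken by
    lexicographically smallest transcript id.  Genes without any CDS-bearing
    transcript yield None (non-designable, not an error).
    """
    tagged = [
        t for t in gene.transcripts
        if any("canonical" in tag.lower()
               for tag in gff_tags.get(t.transcript_id, ()))
    ]
    if tagged:
        return min(tagged, key=lambda t: t.transcript_id).transcript_id
    coding = [t for t in gene.transcripts if t.cds_length > 0]
    if not coding:
        return None
    return min(coding, key=lambda t: (-t.cds_length, t.transcript_id)).transcript_id


def _order_by_transcription(intervals, strand):
    return sorted(intervals, reverse=(strand == "-"))


def _read_bed(path):
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else "."
            rows.append((f[0], int(f[1]), int(f[2]), name))
    return rows


def read_genome(fasta_path, gff_path, pfam_bed_path=None,
                ncrna_bed_path=None) -> GenomeModel:
    """Parse FASTA + GFF3 (+ optional BED tracks) into a GenomeModel."""
    contigs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not contigs:
        raise GenomeError(f"no sequences in {fasta_path}")

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )

    ncrna = set()
    for ftype in NCRNA_FEATURE_TYPES:
        for feat in db.features_of_type(ftype):
            if feat.seqid not in contigs:
                raise GenomeError(
                    f"feature {feat.id}: unknown contig {feat.seqid!r}"
                )
            ncrna.add((feat.seqid, feat.start - 1, feat.end))

    genes = []
    for gfeat in db.features_of_type("gene"):
        if gfeat.seqid not in contigs:
            raise GenomeError(f"gene {gfeat.id}: unknown contig {gfeat.seqid!r}")
        transcripts = []
        tags = {}
        for tfeat in db.children(gfeat, featuretype="mRNA", level=1):
            exons = [
                (c.start - 1, c.end)
                for c in db.children(tfeat, featuretype="exon", level=1)
            ]
            cds = [
                (c.start - 1, c.end)
                for c in db.children(tfeat, featuretype="CDS", level=1)
            ]
            strand = tfeat.strand
            transcripts.append(
                TranscriptModel(
                    transcript_id=tfeat.id,
                    strand=strand,
                    exons=_order_by_transcription(exons, strand),
                    cds_segments=_order_by_transcription(cds, strand),
                )
            )
            tvals = []
            for key, vals in tfeat.attributes.items():
                tvals.extend([key] + list(vals))
            tags[tfeat.id] = tvals
        if not transcripts:
            continue
        transcripts.sort(key=lambda t: t.transcript_id)
        gene = GeneModel(
            gene_id=gfeat.id,
            contig=gfeat.seqid,
            strand=gfeat.strand,
            transcripts=transcripts,
        )
        gene.canonical_transcript_id = select_canonical_transcript(gene, tags)
        genes.append(gene)
    genes.sort(key=lambda g: (g.contig, g.gene_id))

    pfam = set()
    if pfam_bed_path is not None:
        for contig, s, e, name in _read_bed(pfam_bed_path):
            pfam.add((contig, s, e, name))
    if ncrna_bed_path is not None:
        for contig, s, e, _ in _read_bed(ncrna_bed_path):
            ncrna.add((contig, s, e))

    model = GenomeModel(
        contigs=contigs, genes=genes,
        ncrna_intervals=ncrna, pfam_intervals=pfam,
    )
    model.validate()
    return model


def write_genome(model: GenomeModel, fasta_path, gff_path,
                 pfam_bed_path=None, ncrna_bed_path=None) -> None:
    """Serialize a GenomeModel back to FASTA + GFF3 (+ BED tracks).

    Written files round-trip through :func:`read_genome` to an equal model.
    """
    with open(fasta_path, "w") as fh:
        for name in sorted(model.contigs):
            fh.write(f">{name}\n")
            seq = model.contigs[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")

    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name in sorted(model.contigs):
            fh.write(f"##sequence-region {name} 1 {len(model.contigs[name])}\n")
        for g in model.genes:
            gs, ge = g.genomic_span()
            fh.write(
                f"{g.contig}\tcas12akit\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for t in g.transcripts:
                ts, te = t.genomic_span()
                attrs = f"ID={t.transcript_id};Parent={g.gene_id}"
                if t.transcript_id == g.canonical_transcript_id:
                    attrs += ";tag=Ensembl_canonical"
                fh.write(
                    f"{g.contig}\tcas12akit\tmRNA\t{ts + 1}\t{te}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
                for s, e in sorted(t.exons):
                    fh.write(
                        f"{g.contig}\tcas12akit\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\tParent={t.transcript_id}\n"
                    )
                for s, e in sorted(t.cds_segments):
                    fh.write(
                        f"{g.contig}\tcas12akit\tCDS\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t0\tParent={t.transcript_id}\n"
                    )

    if ncrna_bed_path is not None:
        with open(ncrna_bed_path, "w") as fh:
            for contig, s, e in sorted(model.ncrna_intervals):
                fh.write(f"{contig}\t{s}\t{e}\tncRNA\t0\t+\n")
    if pfam_bed_path is not None:
        with open(pfam_bed_path, "w") as fh:
            for contig, s, e, dom in sorted(model.pfam_intervals):
                fh.write(f"{contig}\t{s}\t{e}\t{dom}\t0\t+\n")
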