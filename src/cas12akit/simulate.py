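"""Synthetic inputs: designable mini-genomes, negative-binomial screen
counts with planted effects, and array-amplicon FASTQ reads.

Everything is a pure function of (config, seed): rerunning with the same
seed yields byte-identical files, which the test suite relies on.

The mini-genome is designable by construction: each gene's CDS is built
from "site blocks" (a TTTC PAM followed by a filter-clean 23-mer spacer and
a spacer of filler), so every gene carries a known number of valid,
well-separated candidate sites, with multi-isoform genes, intronic
non-coding elements and Pfam-like intervals planted at configurable rates
and recorded in a truth file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._seq import gc_percent, revcomp
from .genome import (GeneModel, GenomeModel, TranscriptModel, write_genome)
from .spacers import DEFAULT_DR
from .counting import CountMatrix

import pandas as pd

_BASES = np.array(list("ACGT"))

# fixed amplicon context 5' of the first DR (hU6-style vector tail)
VECTOR_PREFIX = "CTTGTGGAAAGGACGAAACACCG"


def _rand_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _clean_spacer(rng, length: int = 23) -> str:
    """Random spacer passing the hard design filters with moderate GC."""
    while True:
        s = _rand_seq(rng, length)
        gc = gc_percent(s)
        if not (40.0 <= gc <= 60.0):
            continue
        if "TTTT" in s:
            continue
        ctx = DEFAULT_DR + s + DEFAULT_DR
        if "GAATTC" in ctx or "GGTACC" in ctx:
            continue
        if "GAATTC" in revcomp(ctx) or "GGTACC" in revcomp(ctx):
            continue
        return s


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

@dataclass
class SimGenomeConfig:
    n_genes: int = 20
    exons_per_gene: tuple = (2, 4)  # inclusive range
    cds_length: tuple = (450, 700)  # target range, nt
    frac_multi_isoform: float = 0.2
    n_ncrna: int = 4  # genes with an intronic non-coding element planted
    n_pfam: int = 6  # genes with a Pfam-like interval planted
    site_spacing: int = 30  # filler nt between seeded PAM sites
    contig_length: int | None = None  # pad with random sequence if larger
    min_sites_per_gene: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0 or self.n_ncrna < 0 or self.n_pfam < 0:
            raise ValueError("counts must be >= 0")
        block = 4 + 23 + self.site_spacing
        if self.cds_length[0] // block < self.min_sites_per_gene:
            raise ValueError(
                "infeasible config: CDS too short for the PAM site density"
            )


def simulate_genome(config: SimGenomeConfig, outdir=None):
    """Build a designable mini-genome; returns ``(GenomeModel, truth)``.

    When *outdir* is given, writes genome.fa, genome.gff3, pfam.bed,
    ncrna.bed and truth.json there (byte-identical for a fixed config).
    """
    rng = np.random.default_rng(config.seed)
    block_len = 4 + 23 + config.site_spacing

    multi = rng.random(config.n_genes) < config.frac_multi_isoform
    ncrna_genes = set(
        rng.choice(config.n_genes, size=min(config.n_ncrna, config.n_genes),
                   replace=False).tolist()) if config.n_ncrna else set()
    pfam_genes = set(
        rng.choice(config.n_genes, size=min(config.n_pfam, config.n_genes),
                   replace=False).tolist()) if config.n_pfam else set()

    contig_parts = []
    pos = 0
    genes, ncrna, pfam = [], set(), set()
    truth_genes = {}
    contig = "chrS"

    for gi in range(config.n_genes):
        gid = f"G{gi + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        cds_target = int(rng.integers(config.cds_length[0],
                                      config.cds_length[1] + 1))
        n_sites = max(config.min_sites_per_gene, cds_target // block_len)
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        n_exons = min(n_exons, n_sites)

        spacers = [_clean_spacer(rng) for _ in range(n_sites)]
        blocks = [
            "TTTC" + sp + _rand_seq(rng, config.site_spacing) for sp in spacers
        ]
        # distribute blocks over exons as evenly as possible
        per_exon = [n_sites // n_exons] * n_exons
        for k in range(n_sites % n_exons):
            per_exon[k] += 1
        exon_seqs = []
        b = 0
        for cnt in per_exon:
            exon_seqs.append("".join(blocks[b:b + cnt]))
            b += cnt

        # forward (sense) layout of the gene region
        rel_exons = []
        parts = []
        cursor = 0
        intron_intervals = []
        for k, eseq in enumerate(exon_seqs):
            rel_exons.append((cursor, cursor + len(eseq)))
            parts.append(eseq)
            cursor += len(eseq)
            if k < len(exon_seqs) - 1:
                ilen = int(rng.integers(80, 151))
                intron_intervals.append((cursor, cursor + ilen))
                parts.append(_rand_seq(rng, ilen))
                cursor += ilen
        region = "".join(parts)
        rlen = len(region)

        # per-gene planted features, in sense-relative coordinates
        nc_rel = None
        if gi in ncrna_genes and intron_intervals:
            s, e = intron_intervals[len(intron_intervals) // 2]
            mid = (s + e) // 2
            nc_rel = (max(s + 5, mid - 20), min(e - 5, mid + 20))
        pf_rel = None
        if gi in pfam_genes:
            pf_rel = (rel_exons[0][0], rel_exons[0][1])

        intergenic = int(rng.integers(100, 301))
        gene_start = pos

        def to_genomic(iv):
            s, e = iv
            if strand == "+":
                return (gene_start + s, gene_start + e)
            return (gene_start + rlen - e, gene_start + rlen - s)

        genomic_exons = [to_genomic(iv) for iv in rel_exons]
        exons_tx = sorted(genomic_exons, reverse=(strand == "-"))

        cds_total = sum(e - s for s, e in rel_exons)
        transcripts = [TranscriptModel(
            transcript_id=f"{gid}_T1", strand=strand,
            exons=exons_tx, cds_segments=list(exons_tx))]
        if multi[gi]:
            # second isoform: same exons, CDS truncated to ~60% in
            # transcription order
            keep = int(cds_total * 0.6)
            cds2 = []
            acc = 0
            for s, e in exons_tx:
                seg = e - s
                if acc + seg <= keep:
                    cds2.append((s, e))
                    acc += seg
                else:
                    take = keep - acc
                    if take > 0:
                        if strand == "+":
                            cds2.append((s, s + take))
                        else:
                            cds2.append((e - take, e))
                    break
            transcripts.append(TranscriptModel(
                transcript_id=f"{gid}_T2", strand=strand,
                exons=list(exons_tx), cds_segments=cds2))

        genes.append(GeneModel(
            gene_id=gid, contig=contig, strand=strand,
            transcripts=transcripts, canonical_transcript_id=f"{gid}_T1"))

        if nc_rel is not None:
            s, e = to_genomic(nc_rel)
            ncrna.add((contig, s, e))
        if pf_rel is not None:
            s, e = to_genomic(pf_rel)
            pfam.add((contig, s, e, f"PF_{gid}"))

        seq = region if strand == "+" else revcomp(region)
        contig_parts.append(seq)
        contig_parts.append(_rand_seq(rng, intergenic))
        pos += rlen + intergenic

        truth_genes[gid] = {
            "strand": strand,
            "n_seeded_sites": n_sites,
            "seeded_spacers": spacers,
            "n_exons": n_exons,
            "multi_isoform": bool(multi[gi]),
            "ncrna_planted": nc_rel is not None,
            "pfam_planted": pf_rel is not None,
        }

    if config.contig_length is not None and config.contig_length > pos:
        contig_parts.append(_rand_seq(rng, config.contig_length - pos))

    model = GenomeModel(
        contigs={contig: "".join(contig_parts)},
        genes=sorted(genes, key=lambda g: (g.contig, g.gene_id)),
        ncrna_intervals=ncrna,
        pfam_intervals=pfam,
    )
    model.validate()
    truth = {"genes": truth_genes,
             "ncrna": sorted(list(ncrna)),
             "pfam": sorted(list(pfam))}

    if outdir is not None:
        import os
        os.makedirs(outdir, exist_ok=True)
        write_genome(
            model,
            fasta_path=os.path.join(outdir, "genome.fa"),
            gff_path=os.path.join(outdir, "genome.gff3"),
            pfam_bed_path=os.path.join(outdir, "pfam.bed"),
            ncrna_bed_path=os.path.join(outdir, "ncrna.bed"),
        )
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return model, truth


# ---------------------------------------------------------------------------
# Screen count simulation
# ---------------------------------------------------------------------------

@dataclass
class SimScreenConfig:
    coverage: float = 300.0  # mean reads per construct
    n_replicates: int = 6
    dispersion: float = 0.05  # NB: var = mu + dispersion * mu^2
    conditions: tuple = ("input", "treated")
    effects: dict = field(default_factory=dict)  # condition -> {gene: logFC}
    abundance_sigma: float = 0.25  # lognormal spread of baseline abundance
    seed: int = 0

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def simulate_screen_counts(library, config: SimScreenConfig):
    """Negative-binomial construct counts across conditions and replicates.

    Counts are NB(mean = depth * relative abundance) where abundance evolves
    per condition by 2^(planted gene logFC); NTCs carry logFC 0.  Returns
    ``(CountMatrix, truth)`` with truth holding each construct's planted
    logFC per condition.
    """
    constructs = _construct_records(library)
    ids = [c[0] for c in constructs]
    genes = [c[1] for c in constructs]
    n = len(ids)
    rng = np.random.default_rng(config.seed)

    base = np.exp(rng.normal(0.0, config.abundance_sigma, size=n))
    base /= base.sum()
    depth = config.coverage * n

    cols, sample_ids, meta_rows = [], [], []
    truth = {"logFC": {}}
    for cond in config.conditions:
        eff = config.effects.get(cond, {})
        lfc = np.array([float(eff.get(g, 0.0)) for g in genes])
        truth["logFC"][cond] = dict(zip(ids, lfc.tolist()))
        ab = base * np.exp2(lfc)
        ab /= ab.sum()
        mu = depth * ab
        for rep in range(1, config.n_replicates + 1):
            if config.dispersion > 0:
                r = 1.0 / config.dispersion
                p = r / (r + mu)
                col = rng.negative_binomial(r, p)
            else:
                col = rng.poisson(mu)
            cols.append(col)
            sid = f"{cond}_rep{rep}"
            sample_ids.append(sid)
            meta_rows.append({"sample_id": sid, "condition": cond,
                              "replicate": rep, "timepoint": cond})

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    counts = CountMatrix(ids, sample_ids, np.column_stack(cols),
                         sample_meta=meta)
    return counts, truth


def _construct_records(library):
    """Accept a LibraryTable or a DataFrame with construct_id/gene_id."""
    if hasattr(library, "constructs"):
        return [(c.construct_id, c.gene_id) for c in library.constructs]
    return list(zip(library["construct_id"], library["gene_id"]))


# ---------------------------------------------------------------------------
# Amplicon read simulation
# ---------------------------------------------------------------------------

def simulate_array_reads(library, abundances, n_reads: int,
                         error_rate: float = 0.0, read_length: int = 75,
                         seed: int = 0, amplicon_len_range=(250, 350),
                         out_fastq=None):
    """Simulate single-end reads over pre-crRNA array amplicons.

    Each read is the fixed vector prefix + the construct's cassette, padded
    with random sequence to an amplicon length drawn uniformly from
    *amplicon_len_range*, truncated to *read_length*, with iid substitution
    errors at *error_rate*.  Returns ``(reads, truth)`` where reads is a
    list of (read_id, sequence) and truth maps read_id -> construct_id;
    writes FASTQ when *out_fastq* is given.
    """
    constructs = library.constructs
    ids = [c.construct_id for c in constructs]
    ab = np.array([abundances[i] if isinstance(abundances, dict) else
                   abundances[k]
                   for k, i in enumerate(ids)], dtype=float)
    if abs(ab.sum() - 1.0) > 1e-6:
        raise ValueError(f"abundances sum to {ab.sum():.8f}, expected 1")
    if read_length < len(DEFAULT_DR) + 23:
        raise ValueError("read_length must cover anchor + spacer")
    rng = np.random.default_rng(seed)

    cassettes = [VECTOR_PREFIX + c.cassette_seq for c in constructs]
    choice = rng.choice(len(ids), size=n_reads, p=ab)
    amp_lens = rng.integers(amplicon_len_range[0], amplicon_len_range[1] + 1,
                            size=n_reads)
    reads, truth = [], {}
    for r in range(n_reads):
        ci = int(choice[r])
        body = cassettes[ci]
        target = max(int(amp_lens[r]), len(body))
        pad = target - len(body)
        seq = body + (_rand_seq(rng, pad) if pad else "")
        seq = seq[:read_length]
        if error_rate > 0:
            arr = np.array(list(seq))
            hit = rng.random(len(arr)) < error_rate
            if hit.any():
                # shift each hit base into one of the three other bases
                base_idx = np.searchsorted(_BASES, arr[hit])
                shift = rng.integers(1, 4, size=int(hit.sum()))
                arr[hit] = _BASES[(base_idx + shift) % 4]
            seq = "".join(arr)
        rid = f"read_{r + 1}"
        reads.append((rid, seq))
        truth[rid] = ids[ci]

    if out_fastq is not None:
        with open(out_fastq, "w") as fh:
            for rid, seq in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return reads, truth
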