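"""Synthetic single-transcript fixtures for annotation checks.

These are hand-buildable toy gene models: a transcript with a chosen codon
layout embedded in a random-background chromosome.  They are synthetic
stand-ins constructed from printed protein/cDNA coordinates (protein
length, codon identity at a position), not real gene sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import Gene, GeneSet, TranscriptModel, revcomp
from .simulate import SENSE_CODONS
from .variants import VariantCall


@dataclass
class CodingFixture:
    reference: dict[str, str]
    genes: GeneSet
    tx: TranscriptModel
    cds_positions: list[int]  # genomic position of each spliced-CDS base

    def codon_start(self, protein_pos: int) -> int:
        """Genomic position of the first base of a codon (transcript order)."""
        return self.cds_positions[3 * (protein_pos - 1)]


def make_coding_fixture(
    n_codons: int,
    codon_overrides: dict[int, str] | None = None,
    strand: str = "+",
    intron_after: dict[int, int] | None = None,
    chrom: str = "chrT",
    pad: int = 500,
    gene_pad: int = 300,
    seed: int = 11,
) -> CodingFixture:
    """Build a one-transcript gene with ``n_codons`` translated codons.

    ``codon_overrides`` maps 1-based protein positions to codon strings
    (transcript orientation).  ``intron_after`` maps a 0-based coding
    offset (bp into the spliced CDS) to an intron length inserted there.
    A stop codon is appended, so the CDS feature is 3*(n_codons+1) bp.
    """
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [
        SENSE_CODONS[int(i)] for i in rng.integers(0, len(SENSE_CODONS), n_codons - 1)
    ]
    for ppos, codon in (codon_overrides or {}).items():
        if not 1 <= ppos <= n_codons:
            raise ValueError(f"protein position {ppos} outside 1..{n_codons}")
        codons[ppos - 1] = codon
    codons.append("TAA")
    coding = "".join(codons)

    # split into exon chunks at the requested coding offsets
    breaks = sorted((intron_after or {}).items())
    chunks: list[str] = []
    introns: list[int] = []
    prev = 0
    for off, ilen in breaks:
        if not 0 < off < len(coding):
            raise ValueError("intron offset outside the coding sequence")
        chunks.append(coding[prev:off])
        introns.append(ilen)
        prev = off
    chunks.append(coding[prev:])

    if strand == "-":
        g_chunks = [revcomp(c) for c in chunks[::-1]]
        g_introns = introns[::-1]
    else:
        g_chunks = chunks
        g_introns = introns

    total = sum(len(c) for c in g_chunks) + sum(g_introns)
    length = total + 2 * pad
    seq = bytearray(
        np.frombuffer(b"ACGT", dtype=np.uint8)[
            rng.integers(0, 4, size=length, dtype=np.uint8)
        ].tobytes()
    )
    exons: list[tuple[int, int]] = []
    p = pad  # 0-based
    for j, chunk in enumerate(g_chunks):
        exons.append((p + 1, p + len(chunk)))
        seq[p : p + len(chunk)] = chunk.encode()
        if j < len(g_introns):
            ilen = g_introns[j]
            left = b"GT" if strand == "+" else b"CT"
            right = b"AG" if strand == "+" else b"AC"
            seq[p + len(chunk) : p + len(chunk) + 2] = left
            seq[p + len(chunk) + ilen - 2 : p + len(chunk) + ilen] = right
            p += len(chunk) + ilen
        else:
            p += len(chunk)
    reference = {chrom: seq.decode("ascii")}
    tx = TranscriptModel(
        transcript_id="FIX1.t1",
        gene_id="FIX1",
        gene_name="FIX1",
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_start=exons[0][0],
        cds_end=exons[-1][1],
        canonical=True,
    )
    gene = Gene(
        gene_id="FIX1",
        gene_name="FIX1",
        chrom=chrom,
        start=max(1, exons[0][0] - gene_pad),
        end=min(length, exons[-1][1] + gene_pad),
        transcripts=[tx],
    )
    segs = tx.cds_segments
    if strand == "+":
        positions = [q for s, e in segs for q in range(s, e + 1)]
    else:
        positions = [q for s, e in reversed(segs) for q in range(e, s - 1, -1)]
    return CodingFixture(
        reference=reference, genes=GeneSet([gene]), tx=tx, cds_positions=positions
    )


def top1_like_fixture() -> tuple[CodingFixture, VariantCall]:
    """A 765-residue topoisomerase-I-like transcript with His (CAT) at codon
    81, plus the 2-bp deletion that reduces that codon's 'CAT' to 'C'.

    The transcript is a synthetic stand-in built from the printed protein
    coordinates (765 residues, His81 in exon 4); the deletion is the
    sweep-to-fixation frameshift observed in all dependent clones of the
    resistant lineage.
    """
    fx = make_coding_fixture(
        n_codons=765,
        codon_overrides={81: "CAT"},
        intron_after={60: 800, 120: 650, 200: 700},  # codon 81 sits in exon 4
        seed=5,
    )
    pos = fx.codon_start(81)
    seq = fx.reference[fx.tx.chrom]
    ref = seq[pos - 1 : pos + 2]
    assert ref == "CAT"
    call = VariantCall(
        chrom=fx.tx.chrom,
        pos=pos,
        ref=ref,
        alt=ref[0],
        alt_depth=48,
        total_depth=48,
        clone_id="TPT-R4a",
    )
    return fx, call
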