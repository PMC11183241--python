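"""Sequence-ontology consequence annotation from gene models.

Assigns each somatic call a consequence term on the canonical transcript of
the gene it falls in, an impact tier (HIGH / MODERATE / LOW / MODIFIER), a
consolidated reporting class, and a protein-change label (Pro803Thr,
Asn80fs, Arg408*).  This is a minimal annotator covering the consequence
subset needed for haploid resistance-driver filtering: it handles
protein-coding canonical transcripts only (no regulatory features, no NMD
prediction).

Conventions
-----------
* Canonical transcript = longest spliced CDS; ties broken by
  lexicographically smallest transcript_id.
* CDS features include the stop codon; protein length is cds_len/3 - 1.
* Splice acceptor/donor = the 2 intronic bases at each intron edge (HIGH);
  splice region = intronic bases 3-8 from an edge (reported together with
  the intron term, LOW).
* "Intragenic" = inside the annotated gene span but outside every
  transcript of the gene (models promoter/UTR territory kept in the gene
  record).
* Frameshift position = the first codon whose composition changes.
* Standard nuclear genetic code.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .variants import VariantCall, compute_af

HIGH, MODERATE, LOW, MODIFIER = "HIGH", "MODERATE", "LOW", "MODIFIER"

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _TABLE.stop_codons})

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    return CODON_TO_AA[codon.upper()]


class DataIntegrityError(ValueError):
    """Reference sequence does not match a call's REF allele."""


class ClassificationError(KeyError):
    """Unknown sequence-ontology term (fail loud, never default-pass)."""


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript on a chromosome.

    ``exons`` are 1-based inclusive genomic intervals, sorted and
    non-overlapping.  ``cds_start``/``cds_end`` are genomic bounds of the
    CDS (stop codon included).
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    canonical: bool = False
    _cds_cache: str | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = tuple(sorted(tuple(e) for e in self.exons))
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            if e < s:
                raise ValueError(f"{self.transcript_id}: empty exon {s}-{e}")
            prev_end = e
        if not any(s <= self.cds_start <= e for s, e in self.exons) or not any(
            s <= self.cds_end <= e for s, e in self.exons
        ):
            raise ValueError(f"{self.transcript_id}: CDS bounds outside exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_segments(self) -> list[tuple[int, int]]:
        """Exon pieces clipped to the CDS, genomic ascending order."""
        segs = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 <= e2:
                segs.append((s2, e2))
        return segs

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def protein_length(self) -> int:
        """Residues encoded, the terminal stop codon excluded."""
        return self.cds_length // 3 - 1

    def cds_index(self, pos: int) -> int | None:
        """0-based index of a genomic position in the spliced CDS (5'->3'
        in transcript orientation), or None when pos is not coding."""
        segs = self.cds_segments
        offset = 0
        if self.strand == "+":
            for s, e in segs:
                if s <= pos <= e:
                    return offset + (pos - s)
                offset += e - s + 1
        else:
            for s, e in reversed(segs):
                if s <= pos <= e:
                    return offset + (e - pos)
                offset += e - s + 1
        return None

    def spliced_cds(self, reference: Mapping[str, str]) -> str:
        if self._cds_cache is None:
            seq = reference[self.chrom]
            parts = [seq[s - 1 : e] for s, e in self.cds_segments]
            cds = "".join(parts).upper()
            if self.strand == "-":
                cds = revcomp(cds)
            self._cds_cache = cds
        return self._cds_cache


@dataclass
class Gene:
    gene_id: str
    gene_name: str
    chrom: str
    start: int  # 1-based inclusive gene span; may exceed transcript span
    end: int
    transcripts: list[TranscriptModel]

    @property
    def canonical_transcript(self) -> TranscriptModel:
        marked = [t for t in self.transcripts if t.canonical]
        pool = marked or self.transcripts
        return min(pool, key=lambda t: (-t.cds_length, t.transcript_id))


class GeneSet:
    """Gene models indexed for fast point/interval lookup."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts = {c: [g.start for g in gs] for c, gs in self._by_chrom.items()}
        self._cummax_end: dict[str, list[int]] = {}
        for c, gs in self._by_chrom.items():
            acc, m = [], 0
            for g in gs:
                m = max(m, g.end)
                acc.append(m)
            self._cummax_end[c] = acc

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def by_name(self, gene_name: str) -> Gene:
        for g in self.genes:
            if g.gene_name == gene_name:
                return g
        raise KeyError(gene_name)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        """Genes whose span intersects [start, end] (1-based inclusive)."""
        gs = self._by_chrom.get(chrom)
        if not gs:
            return []
        out = []
        i = bisect_right(self._starts[chrom], end) - 1
        cummax = self._cummax_end[chrom]
        while i >= 0 and cummax[i] >= start:
            if gs[i].end >= start and gs[i].start <= end:
                out.append(gs[i])
            i -= 1
        out.reverse()
        return out

    def gene_at(self, chrom: str, start: int, end: int | None = None) -> Gene | None:
        hits = self.genes_overlapping(chrom, start, end if end is not None else start)
        return hits[0] if hits else None

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GeneSet":
        """Load gene/mRNA/exon/CDS features from a GFF3 file."""
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        genes = []
        for gf in db.features_of_type("gene"):
            name = gf.attributes.get("Name", [gf.id])[0]
            transcripts = []
            for mrna in db.children(gf, featuretype="mRNA"):
                exons = tuple(
                    (f.start, f.end) for f in db.children(mrna, featuretype="exon")
                )
                cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
                if not exons or not cds:
                    continue
                canonical = mrna.attributes.get("canonical", ["0"])[0] == "1"
                transcripts.append(
                    TranscriptModel(
                        transcript_id=mrna.id,
                        gene_id=gf.id,
                        gene_name=name,
                        chrom=gf.seqid,
                        strand=mrna.strand,
                        exons=exons,
                        cds_start=min(s for s, _ in cds),
                        cds_end=max(e for _, e in cds),
                        canonical=canonical,
                    )
                )
            if transcripts:
                genes.append(
                    Gene(
                        gene_id=gf.id,
                        gene_name=name,
                        chrom=gf.seqid,
                        start=gf.start,
                        end=gf.end,
                        transcripts=transcripts,
                    )
                )
        return cls(genes)


def load_fasta(path: str | Path) -> dict[str, str]:
    """Reference FASTA as a dict of upper-case sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# impact tiers and consolidated classes

IMPACT_TABLE: dict[str, str] = {
    "frameshift_variant": HIGH,
    "frameshift_variant&stop_gained": HIGH,
    "stop_gained": HIGH,
    "stop_lost": HIGH,
    "start_lost": HIGH,
    "splice_acceptor_variant": HIGH,
    "splice_donor_variant": HIGH,
    "missense_variant": MODERATE,
    "inframe_insertion": MODERATE,
    "inframe_deletion": MODERATE,
    "disruptive_inframe_deletion": MODERATE,
    "disruptive_inframe_insertion": MODERATE,
    "synonymous_variant": LOW,
    "stop_retained_variant": LOW,
    "splice_region_variant&intron_variant": LOW,
    "intron_variant": MODIFIER,
    "intragenic_variant": MODIFIER,
    "intergenic_variant": MODIFIER,
    "5_prime_UTR_variant": MODIFIER,
    "3_prime_UTR_variant": MODIFIER,
}

CONSOLIDATED_TABLE: dict[str, str] = {
    "missense_variant": "Missense",
    "frameshift_variant": "Frameshift",
    "frameshift_variant&stop_gained": "Frameshift plus stop-gained",
    "splice_region_variant&intron_variant": "Splice region plus intron",
    "intergenic_variant": "Intergenic",
    "intragenic_variant": "Intragenic",
    "intron_variant": "Intron",
    "stop_gained": "Stop gained",
    "stop_lost": "Stop lost",
    "start_lost": "Start lost",
    "synonymous_variant": "Synonymous",
    "inframe_insertion": "Inframe insertion",
    "inframe_deletion": "Inframe deletion",
    "disruptive_inframe_deletion": "Disruptive inframe del",
    "disruptive_inframe_insertion": "Disruptive inframe ins",
}

PROTEIN_AFFECTING_TERMS = {
    "missense_variant",
    "frameshift_variant",
    "frameshift_variant&stop_gained",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "synonymous_variant",
    "stop_retained_variant",
    "inframe_insertion",
    "inframe_deletion",
    "disruptive_inframe_deletion",
    "disruptive_inframe_insertion",
}


def impact_tier(so_term: str) -> str:
    try:
        return IMPACT_TABLE[so_term]
    except KeyError:
        raise ClassificationError(f"unknown sequence-ontology term {so_term!r}")


def consolidate_class(so_term: str, variant_kind: str = "SNV") -> str:
    """Map a consequence term to its consolidated reporting class.

    Total partition: unmapped terms fall into "Others".  ``variant_kind``
    (SNV/indel) only matters for the reporting layout, not the label.
    """
    return CONSOLIDATED_TABLE.get(so_term, "Others")


@dataclass
class AnnotatedVariant:
    call: VariantCall
    gene_id: str | None
    gene_name: str | None
    transcript_id: str | None
    so_term: str
    impact: str
    consolidated_class: str
    protein_change: str | None = None
    protein_pos: int | None = None


def protein_change_label(annotated: AnnotatedVariant) -> str | None:
    """Short protein-change label (Pro803Thr / Asn80fs / Arg408*); None for
    non-CDS consequences."""
    return annotated.protein_change


# ---------------------------------------------------------------------------
# annotation engine


def _intron_term(tx: TranscriptModel, pos: int) -> str:
    for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
        if e1 < pos < s2:
            d_left = pos - e1  # 1 = first intronic base from the left exon
            d_right = s2 - pos
            donor_d = d_left if tx.strand == "+" else d_right
            acceptor_d = d_right if tx.strand == "+" else d_left
            if donor_d <= 2:
                return "splice_donor_variant"
            if acceptor_d <= 2:
                return "splice_acceptor_variant"
            if min(d_left, d_right) <= 8:
                return "splice_region_variant&intron_variant"
            return "intron_variant"
    raise ValueError(f"position {pos} is not intronic in {tx.transcript_id}")


def _in_exon(tx: TranscriptModel, pos: int) -> bool:
    return any(s <= pos <= e for s, e in tx.exons)


def _utr_term(tx: TranscriptModel, pos: int) -> str:
    before_cds = pos < tx.cds_start
    five_prime = before_cds if tx.strand == "+" else not before_cds
    return "5_prime_UTR_variant" if five_prime else "3_prime_UTR_variant"


def _edit_cds(
    cds: str, deleted_idx: list[int], ins_at: int | None, ins_seq: str
) -> str:
    """Apply a CDS-coordinate edit: remove indices, insert ins_seq before
    position ins_at (transcript orientation)."""
    removed = set(deleted_idx)
    out = []
    for i, base in enumerate(cds):
        if ins_at is not None and i == ins_at:
            out.append(ins_seq)
        if i not in removed:
            out.append(base)
    if ins_at is not None and ins_at == len(cds):
        out.append(ins_seq)
    return "".join(out)


def _annotate_coding_snv(
    tx: TranscriptModel, pos: int, alt: str, reference: Mapping[str, str]
) -> tuple[str, str | None, int]:
    cds = tx.spliced_cds(reference)
    idx = tx.cds_index(pos)
    codon_i, off = divmod(idx, 3)
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    alt_base = alt if tx.strand == "+" else revcomp(alt)
    alt_codon = codon[:off] + alt_base.upper() + codon[off + 1 :]
    aa_ref = translate_codon(codon)
    aa_alt = translate_codon(alt_codon)
    ppos = codon_i + 1
    if codon_i == 0:
        return "start_lost", "Met1?", ppos
    if aa_ref == "*":
        if aa_alt == "*":
            return "stop_retained_variant", f"Ter{ppos}=", ppos
        return "stop_lost", f"Ter{ppos}{seq3(aa_alt)}", ppos
    if aa_alt == "*":
        return "stop_gained", f"{seq3(aa_ref)}{ppos}*", ppos
    if aa_alt == aa_ref:
        return "synonymous_variant", f"{seq3(aa_ref)}{ppos}=", ppos
    return "missense_variant", f"{seq3(aa_ref)}{ppos}{seq3(aa_alt)}", ppos


def _annotate_coding_indel(
    tx: TranscriptModel,
    deleted_pos: list[int],
    ins_point: int | None,
    ins_seq: str,
    reference: Mapping[str, str],
) -> tuple[str, str | None, int]:
    """Classify an indel touching the CDS.

    ``deleted_pos``: genomic positions removed; ``ins_point``: genomic
    position of the anchor base the insertion follows (None if no inserted
    bases); ``ins_seq``: inserted bases in genomic (+) orientation.
    """
    cds = tx.spliced_cds(reference)
    deleted_idx = sorted(
        i for i in (tx.cds_index(p) for p in deleted_pos) if i is not None
    )
    ins_at = None
    ins_tx_seq = ""
    if ins_point is not None and ins_seq:
        anchor_idx = tx.cds_index(ins_point)
        if tx.strand == "+":
            nxt = tx.cds_index(ins_point + 1)
            inside = anchor_idx is not None and nxt == anchor_idx + 1
            if inside:
                ins_at = anchor_idx + 1
                ins_tx_seq = ins_seq.upper()
        else:
            nxt = tx.cds_index(ins_point + 1)
            # transcript order on - strand: base at ins_point+1 precedes anchor
            inside = anchor_idx is not None and nxt == anchor_idx - 1
            if inside:
                ins_at = anchor_idx
                ins_tx_seq = revcomp(ins_seq.upper())
    n_ins = len(ins_tx_seq)
    n_del = len(deleted_idx)
    if n_del == 0 and n_ins == 0:
        raise ValueError("indel does not touch the CDS")
    first_idx_candidates = list(deleted_idx)
    if ins_at is not None:
        first_idx_candidates.append(ins_at)
    first_idx = min(first_idx_candidates)
    codon_i = first_idx // 3
    ppos = codon_i + 1
    aa_ref = translate_codon(cds[3 * codon_i : 3 * codon_i + 3])
    net = n_ins - n_del
    if net % 3 != 0:
        mutated = _edit_cds(cds, deleted_idx, ins_at, ins_tx_seq)
        first_codon = mutated[3 * codon_i : 3 * codon_i + 3]
        label = f"{seq3(aa_ref)}{ppos}fs"
        if len(first_codon) == 3 and translate_codon(first_codon) == "*":
            return "frameshift_variant&stop_gained", label, ppos
        return "frameshift_variant", label, ppos
    if n_del and not n_ins:
        term = (
            "inframe_deletion"
            if first_idx % 3 == 0 and n_del % 3 == 0
            else "disruptive_inframe_deletion"
        )
        return term, f"{seq3(aa_ref)}{ppos}del", ppos
    if n_ins and not n_del:
        term = (
            "inframe_insertion"
            if ins_at is not None and ins_at % 3 == 0
            else "disruptive_inframe_insertion"
        )
        return term, f"{seq3(aa_ref)}{ppos}ins", ppos
    # balanced replacement crossing codons
    term = "disruptive_inframe_deletion" if n_del >= n_ins else "disruptive_inframe_insertion"
    return term, f"{seq3(aa_ref)}{ppos}delins", ppos


def annotate_variant(
    call: VariantCall, gene_models: GeneSet, reference: Mapping[str, str]
) -> AnnotatedVariant:
    """Annotate one call on the canonical transcript of its gene."""
    seq = reference.get(call.chrom)
    if seq is None:
        raise DataIntegrityError(f"unknown chromosome {call.chrom!r}")
    window = seq[call.pos - 1 : call.pos - 1 + len(call.ref)].upper()
    if window != call.ref.upper():
        raise DataIntegrityError(
            f"reference mismatch at {call.chrom}:{call.pos}: "
            f"expected {call.ref!r}, reference has {window!r}"
        )

    # changed-base bookkeeping (VCF anchor convention)
    ref, alt = call.ref.upper(), call.alt.upper()
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    deleted_pos = [call.pos + i for i in range(k, len(ref))]
    ins_seq = alt[k:]
    ins_point = call.pos + k - 1 if ins_seq else None
    span_start = call.pos
    span_end = call.pos + len(ref) - 1

    gene = gene_models.gene_at(call.chrom, span_start, span_end)

    def build(term, gene=None, tx=None, label=None, ppos=None):
        return AnnotatedVariant(
            call=call,
            gene_id=gene.gene_id if gene else None,
            gene_name=gene.gene_name if gene else None,
            transcript_id=tx.transcript_id if tx else None,
            so_term=term,
            impact=impact_tier(term),
            consolidated_class=consolidate_class(term, call.kind),
            protein_change=label,
            protein_pos=ppos,
        )

    if gene is None:
        return build("intergenic_variant")
    tx = gene.canonical_transcript
    if span_end < tx.start or span_start > tx.end:
        return build("intragenic_variant", gene)

    if call.is_snv:
        if tx.cds_index(call.pos) is not None:
            term, label, ppos = _annotate_coding_snv(tx, call.pos, alt, reference)
            return build(term, gene, tx, label, ppos)
        if _in_exon(tx, call.pos):
            return build(_utr_term(tx, call.pos), gene, tx)
        return build(_intron_term(tx, call.pos), gene, tx)

    # indel: does any changed base (or the insertion point) touch the CDS?
    touches_cds = any(tx.cds_index(p) is not None for p in deleted_pos)
    if not touches_cds and ins_point is not None:
        a = tx.cds_index(ins_point)
        b = tx.cds_index(ins_point + 1)
        touches_cds = a is not None and b is not None and abs(b - a) == 1
    if touches_cds:
        term, label, ppos = _annotate_coding_indel(
            tx, deleted_pos, ins_point, ins_seq, reference
        )
        return build(term, gene, tx, label, ppos)

    probe = deleted_pos[0] if deleted_pos else call.pos
    if _in_exon(tx, probe):
        return build(_utr_term(tx, probe), gene, tx)
    # deletion overlapping a splice site outranks plain intron
    terms = set()
    for p in deleted_pos or [probe]:
        if _in_exon(tx, p):
            continue
        if tx.start <= p <= tx.end:
            terms.add(_intron_term(tx, p))
        else:
            terms.add("intragenic_variant")
    for strong in ("splice_acceptor_variant", "splice_donor_variant"):
        if strong in terms:
            return build(strong, gene, tx)
    for t in ("splice_region_variant&intron_variant", "intron_variant", "intragenic_variant"):
        if t in terms:
            return build(t, gene, tx)
    return build("intragenic_variant", gene)


ANNOTATION_COLUMNS = [
    "clone_id", "chrom", "pos", "ref", "alt", "kind", "filter_status",
    "gene_id", "gene_name", "transcript_id", "so_term", "impact",
    "consolidated_class", "protein_change", "protein_pos", "af", "dp",
]


def annotate_table(
    calls: Sequence[VariantCall],
    gene_models: GeneSet,
    reference: Mapping[str, str],
) -> pd.DataFrame:
    """Annotate calls into the standard per-variant table used downstream."""
    rows = []
    for call in calls:
        ann = annotate_variant(call, gene_models, reference)
        rows.append(
            {
                "clone_id": call.clone_id,
                "chrom": call.chrom,
                "pos": call.pos,
                "ref": call.ref,
                "alt": call.alt,
                "kind": call.kind,
                "filter_status": call.filter_status,
                "gene_id": ann.gene_id,
                "gene_name": ann.gene_name,
                "transcript_id": ann.transcript_id,
                "so_term": ann.so_term,
                "impact": ann.impact,
                "consolidated_class": ann.consolidated_class,
                "protein_change": ann.protein_change,
                "protein_pos": ann.protein_pos,
                "af": compute_af(call) if call.total_depth else float("nan"),
                "dp": call.total_depth,
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
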