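"""Hand-built annotation truth table: one variant per consolidated class.

Shared by the unit suite and the acceptance checks.  Expected values were
hand-derived from the codon layout below (standard genetic code).
"""

from __future__ import annotations

from hapdrive.fixtures import make_coding_fixture
from hapdrive.variants import VariantCall


def build_fixture():
    return make_coding_fixture(
        n_codons=30,
        codon_overrides={5: "CCA", 6: "CTT", 7: "TAC", 8: "TAC", 9: "AAA",
                         10: "CAT"},
        intron_after={45: 600, 75: 700},
        seed=3,
    )


def _snv(fx, pos, alt):
    seq = fx.reference[fx.tx.chrom]
    ref = seq[pos - 1]
    if alt == ref:  # only noncoding cases pass a don't-care alt base
        alt = "C" if ref != "C" else "G"
    return VariantCall(fx.tx.chrom, pos, ref, alt, 30, 30)


def _deletion(fx, anchor_pos, n_deleted):
    seq = fx.reference[fx.tx.chrom]
    ref = seq[anchor_pos - 1 : anchor_pos + n_deleted]
    return VariantCall(fx.tx.chrom, anchor_pos, ref, ref[0], 30, 30)


def _insertion(fx, anchor_pos, bases):
    seq = fx.reference[fx.tx.chrom]
    ref = seq[anchor_pos - 1]
    return VariantCall(fx.tx.chrom, anchor_pos, ref, ref + bases, 30, 30)


def codon_base(fx, protein_pos, offset):
    return fx.cds_positions[3 * (protein_pos - 1) + offset]


def cases(fx):
    """(name, call, so_term, impact, consolidated class, protein label)."""
    exon1_end = fx.tx.exons[0][1]
    gene = fx.genes.genes[0]
    return [
        ("missense", _snv(fx, codon_base(fx, 5, 0), "A"),
         "missense_variant", "MODERATE", "Missense", "Pro5Thr"),
        ("synonymous", _snv(fx, codon_base(fx, 6, 2), "C"),
         "synonymous_variant", "LOW", "Synonymous", "Leu6="),
        ("stop_gained", _snv(fx, codon_base(fx, 7, 2), "A"),
         "stop_gained", "HIGH", "Stop gained", "Tyr7*"),
        ("stop_lost", _snv(fx, codon_base(fx, 31, 1), "C"),
         "stop_lost", "HIGH", "Stop lost", "Ter31Ser"),
        ("start_lost", _snv(fx, codon_base(fx, 1, 0), "G"),
         "start_lost", "HIGH", "Start lost", "Met1?"),
        ("frameshift", _deletion(fx, codon_base(fx, 10, 0), 2),
         "frameshift_variant", "HIGH", "Frameshift", "His10fs"),
        ("frameshift_stop", _deletion(fx, codon_base(fx, 8, 1), 1),
         "frameshift_variant&stop_gained", "HIGH",
         "Frameshift plus stop-gained", "Tyr8fs"),
        ("inframe_del", _deletion(fx, codon_base(fx, 11, 2), 3),
         "inframe_deletion", "MODERATE", "Inframe deletion", None),
        ("disruptive_del", _deletion(fx, codon_base(fx, 13, 0), 3),
         "disruptive_inframe_deletion", "MODERATE",
         "Disruptive inframe del", None),
        ("inframe_ins", _insertion(fx, codon_base(fx, 16, 2), "AAA"),
         "inframe_insertion", "MODERATE", "Inframe insertion", None),
        ("disruptive_ins", _insertion(fx, codon_base(fx, 17, 0), "AAA"),
         "disruptive_inframe_insertion", "MODERATE",
         "Disruptive inframe ins", None),
        ("splice_region_intron", _snv(fx, exon1_end + 5, "A"),
         "splice_region_variant&intron_variant", "LOW",
         "Splice region plus intron", None),
        ("intron", _snv(fx, exon1_end + 50, "A"),
         "intron_variant", "MODIFIER", "Intron", None),
        ("intragenic", _snv(fx, gene.start + 5, "A"),
         "intragenic_variant", "MODIFIER", "Intragenic", None),
        ("intergenic", _snv(fx, 50, "A"),
         "intergenic_variant", "MODIFIER", "Intergenic", None),
    ]
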