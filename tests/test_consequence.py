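"""Consequence assignment against a hand-built toy transcript.

The toy + strand transcript lives on a 100-base chromosome:

    exons  [10,30) [40,60) [70,90)
    CDS    [20,30) [40,60) [70,82)   (42 bases = 14 codons)
    CDS sequence = ATG + 12x GAA + TAA

so every coding, UTR, intronic and splice-site rule can be probed at known
coordinates, and the whole construction can be mirrored to check strand
symmetry.
"""

import pytest

from rsvr.codec import NormalizedVariant, normalize_variant
from rsvr.consequence import (
    SPLICE_WINDOW,
    TranscriptModel,
    assign_consequences,
)

CDS_SEQ = "ATG" + "GAA" * 12 + "TAA"
COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMPLEMENT)[::-1]


def build_genome():
    base = ("ACGT" * 25)[:100]
    g = list(base)
    g[20:30] = CDS_SEQ[0:10]
    g[40:60] = CDS_SEQ[10:30]
    g[70:82] = CDS_SEQ[30:42]
    return {"1": "".join(g)}


@pytest.fixture(scope="module")
def genome():
    return build_genome()


@pytest.fixture(scope="module")
def tx():
    return TranscriptModel(
        transcript_id="TX1",
        gene_id="G1",
        chrom="1",
        strand="+",
        exons=((10, 30), (40, 60), (70, 90)),
        cds=((20, 30), (40, 60), (70, 82)),
    )


def snv(genome, pos0, alt):
    ref = genome["1"][pos0]
    return NormalizedVariant(1, pos0 + 1, ref, alt)


class TestCodingSnvs:
    def test_stop_gained(self, genome, tx):
        # codon 2 (GAA), first base G>T makes TAA
        assert assign_consequences(snv(genome, 23, "T"), tx, genome) == {"stop_gained"}

    def test_synonymous(self, genome, tx):
        # GAA -> GAG, still Glu
        assert assign_consequences(snv(genome, 25, "G"), tx, genome) == {
            "synonymous_variant"
        }

    def test_missense(self, genome, tx):
        # GAA -> GCA, Glu -> Ala
        assert assign_consequences(snv(genome, 24, "C"), tx, genome) == {
            "missense_variant"
        }

    def test_stop_lost(self, genome, tx):
        # TAA -> CAA
        assert assign_consequences(snv(genome, 79, "C"), tx, genome) == {"stop_lost"}

    def test_stop_to_stop_is_synonymous(self, genome, tx):
        # TAA -> TGA, still a stop
        assert assign_consequences(snv(genome, 80, "G"), tx, genome) == {
            "synonymous_variant"
        }

    def test_start_lost(self, genome, tx):
        assert assign_consequences(snv(genome, 20, "G"), tx, genome) == {"start_lost"}

    def test_every_cds_snv_gets_exactly_one_coding_term(self, genome, tx):
        coding = {
            "synonymous_variant",
            "missense_variant",
            "stop_gained",
            "stop_lost",
            "start_lost",
        }
        for s, e in tx.cds:
            for pos0 in range(s, e):
                ref = genome["1"][pos0]
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    terms = assign_consequences(
                        NormalizedVariant(1, pos0 + 1, ref, alt), tx, genome
                    )
                    assert len(terms & coding) == 1, (pos0, alt, terms)


class TestNonCoding:
    def test_outside_span(self, genome, tx):
        assert assign_consequences(snv(genome, 5, "A" if genome["1"][5] != "A" else "C"), tx, genome) == set()

    def test_five_prime_utr(self, genome, tx):
        v = snv(genome, 14, "A" if genome["1"][14] != "A" else "C")
        assert assign_consequences(v, tx, genome) == {"5_prime_UTR_variant"}

    def test_three_prime_utr(self, genome, tx):
        v = snv(genome, 85, "A" if genome["1"][85] != "A" else "C")
        assert assign_consequences(v, tx, genome) == {"3_prime_UTR_variant"}

    def test_intron(self, genome, tx):
        v = snv(genome, 34, "A" if genome["1"][34] != "A" else "C")
        assert assign_consequences(v, tx, genome) == {"intron_variant"}

    def test_splice_donor_plus(self, genome, tx):
        for pos0 in (30, 31):
            v = snv(genome, pos0, "A" if genome["1"][pos0] != "A" else "C")
            assert assign_consequences(v, tx, genome) == {"splice_donor_variant"}

    def test_splice_acceptor_plus(self, genome, tx):
        for pos0 in (38, 39):
            v = snv(genome, pos0, "A" if genome["1"][pos0] != "A" else "C")
            assert assign_consequences(v, tx, genome) == {"splice_acceptor_variant"}

    def test_noncoding_transcript_emits_no_coding_terms(self, genome):
        nc = TranscriptModel("NC1", "G2", "1", "+", exons=((10, 30), (40, 60)))
        v = snv(genome, 25, "T" if genome["1"][25] != "T" else "C")
        assert assign_consequences(v, nc, genome) == set()
        v_intron = snv(genome, 34, "A" if genome["1"][34] != "A" else "C")
        assert assign_consequences(v_intron, nc, genome) == {"intron_variant"}


class TestIndels:
    def test_one_base_cds_deletion_frameshift(self, genome, tx):
        ref = genome["1"][45]
        v = NormalizedVariant(1, 46, ref, "")
        assert assign_consequences(v, tx, genome) == {"frameshift_variant"}

    def test_three_base_cds_deletion_inframe(self, genome, tx):
        ref = genome["1"][45:48]
        v = NormalizedVariant(1, 46, ref, "")
        assert assign_consequences(v, tx, genome) == {"inframe_deletion"}

    def test_insertions(self, genome, tx):
        assert assign_consequences(
            NormalizedVariant(1, 46, "", "GGG"), tx, genome
        ) == {"inframe_insertion"}
        assert assign_consequences(NormalizedVariant(1, 46, "", "G"), tx, genome) == {
            "frameshift_variant"
        }

    def test_boundary_spanning_deletion_takes_splice_term(self, genome, tx):
        # deletes the last CDS base of exon 1 and the first donor base
        ref = genome["1"][29:31]
        v = NormalizedVariant(1, 30, ref, "")
        terms = assign_consequences(v, tx, genome)
        assert "splice_donor_variant" in terms
        assert "frameshift_variant" not in terms
        assert "inframe_deletion" not in terms

    def test_frameshift_and_inframe_mutually_exclusive(self, genome, tx):
        for alt_len in range(0, 7):
            alt = "T" * alt_len
            if alt == genome["1"][45]:
                continue
            v = NormalizedVariant(1, 46, genome["1"][45], alt)
            terms = assign_consequences(v, tx, genome)
            assert not (
                {"frameshift_variant"} <= terms
                and terms & {"inframe_deletion", "inframe_insertion"}
            )


class TestErrors:
    def test_reference_mismatch(self, genome, tx):
        wrong_ref = "A" if genome["1"][45] != "A" else "C"
        alt = "G" if wrong_ref != "G" else "T"
        with pytest.raises(ValueError, match="reference mismatch"):
            assign_consequences(NormalizedVariant(1, 46, wrong_ref, alt), tx, genome)


def mirror_setup(genome, tx):
    seq = genome["1"]
    length = len(seq)
    genome_m = {"1": revcomp(seq)}
    tx_m = TranscriptModel(
        transcript_id=tx.transcript_id,
        gene_id=tx.gene_id,
        chrom="1",
        strand="-" if tx.strand == "+" else "+",
        exons=tuple(sorted((length - e, length - s) for s, e in tx.exons)),
        cds=tuple(sorted((length - e, length - s) for s, e in tx.cds)),
    )
    return genome_m, tx_m, length


def mirror_variant(v: NormalizedVariant, length: int) -> NormalizedVariant:
    vs = v.pos - 1
    ve = vs + len(v.ref)
    return NormalizedVariant(v.chrom_code, length - ve + 1, revcomp(v.ref), revcomp(v.alt))


class TestStrandSymmetry:
    def test_minus_strand_donor(self, genome, tx):
        genome_m, tx_m, length = mirror_setup(genome, tx)
        # donor bases 30,31 on + mirror to the last intron bases on -
        for pos0 in (30, 31):
            v = snv(genome, pos0, "A" if genome["1"][pos0] != "A" else "C")
            vm = mirror_variant(v, length)
            assert assign_consequences(vm, tx_m, genome_m) == {"splice_donor_variant"}

    def test_mirror_preserves_terms_for_all_snvs(self, genome, tx):
        genome_m, tx_m, length = mirror_setup(genome, tx)
        for pos0 in range(8, 95):
            ref = genome["1"][pos0]
            alt = "A" if ref != "A" else "C"
            v = NormalizedVariant(1, pos0 + 1, ref, alt)
            vm = mirror_variant(v, length)
            assert assign_consequences(v, tx, genome) == assign_consequences(
                vm, tx_m, genome_m
            ), pos0

    def test_mirror_preserves_terms_for_interior_indels(self, genome, tx):
        genome_m, tx_m, length = mirror_setup(genome, tx)
        for pos0, ln in [(44, 1), (44, 3), (33, 2), (14, 1), (84, 2)]:
            ref = genome["1"][pos0 : pos0 + ln]
            v = NormalizedVariant(1, pos0 + 1, ref, "")
            vm = mirror_variant(v, length)
            assert assign_consequences(v, tx, genome) == assign_consequences(
                vm, tx_m, genome_m
            ), (pos0, ln)


class TestGtfLoading:
    def test_load_transcripts(self, tmp_path, genome, tx):
        gtf = tmp_path / "toy.gtf"
        lines = []
        attrs = 'gene_id "G1"; transcript_id "TX1"; transcript_biotype "protein_coding";'
        for s, e in tx.exons:
            lines.append(f'1\ttoy\texon\t{s + 1}\t{e}\t.\t+\t.\t{attrs}')
        for s, e in tx.cds:
            lines.append(f'1\ttoy\tCDS\t{s + 1}\t{e}\t.\t+\t.\t{attrs}')
        gtf.write_text("\n".join(lines) + "\n")
        from rsvr.consequence import load_transcripts

        (loaded,) = load_transcripts(str(gtf))
        assert loaded.exons == tx.exons
        assert loaded.cds == tx.cds
        assert loaded.strand == "+"
        assert loaded.gene_id == "G1"
        # identical behaviour to the hand-built model
        v = snv(genome, 23, "T")
        assert assign_consequences(v, loaded, genome) == {"stop_gained"}
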