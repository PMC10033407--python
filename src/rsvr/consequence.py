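"""Sequence Ontology consequence assignment for variant/transcript pairs.

Terms are assigned against transcript models (exon and CDS intervals read
from a GTF) and a reference-sequence accessor.  Positional rules:

* exonic positions outside the CDS are 5' or 3' UTR, strand-aware;
* intronic positions are ``intron_variant``, except the first two intronic
  bases after an exon in transcript orientation (``splice_donor_variant``)
  and the last two before the next exon (``splice_acceptor_variant``);
* CDS substitutions are translated through the standard genetic code into
  synonymous / missense / stop_gained / stop_lost / start_lost;
* CDS indels are ``frameshift_variant`` when the net length change is not a
  multiple of three, otherwise ``inframe_deletion`` / ``inframe_insertion``.

The splice window is fixed at two intronic bases per side.  Indels that
span an exon-intron boundary take the splice term (the most severe
applicable rule) and are not additionally classified against the CDS.
Variants that change one stop codon into another are synonymous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from rsvr.codec import NormalizedVariant, chrom_code

__all__ = [
    "TranscriptModel",
    "ConsequenceCall",
    "SPLICE_WINDOW",
    "assign_consequences",
    "load_transcripts",
]

SPLICE_WINDOW = 2

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# standard genetic code
_STOPS = {"TAA", "TAG", "TGA"}
_CODON_TABLE = {}
_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODON_TABLE[_b1 + _b2 + _b3] = _AMINO[16 * _i + 4 * _j + _k]


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate(seq: str) -> str:
    return "".join(
        _CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Slice ``genome[chrom][start:end]`` from a dict of strings or a
    pyfaidx.Fasta-like object (0-based, half-open)."""
    piece = genome[chrom][start:end]
    seq = piece.seq if hasattr(piece, "seq") else piece
    return str(seq).upper()


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript on one chromosome.

    Intervals are 0-based half-open, sorted, non-overlapping; CDS intervals
    are contained in exons.  ``strand`` is ``+`` or ``-``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    biotype: str = "protein_coding"
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        cds = tuple(sorted(tuple(c) for c in self.cds))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds", cds)
        for (a, b), (c, d) in zip(exons, exons[1:]):
            if c < b:
                raise ValueError("exons overlap or are unsorted")
        for c_start, c_end in cds:
            if not any(s <= c_start and c_end <= e for s, e in exons):
                raise ValueError("CDS interval not contained in any exon")

    @property
    def chrom_code(self) -> int:
        return chrom_code(self.chrom)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)


@dataclass(frozen=True)
class ConsequenceCall:
    rsvr_id: int
    transcript_id: str
    csq: int
    loftee_flag: str | None = None


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def assign_consequences(v: NormalizedVariant, t: TranscriptModel, genome) -> set[str]:
    """Set of SO terms describing the effect of ``v`` on transcript ``t``.

    Returns the empty set when the variant does not interact with the
    transcript span.  Raises ``ValueError`` when the variant's reference
    allele disagrees with the genome sequence.
    """
    if v.chrom_code != t.chrom_code:
        return set()
    vs = v.pos - 1
    ve = vs + len(v.ref)
    # an insertion (empty ref) is attributed to the base before which it
    # falls, giving every variant a non-empty effective interval
    eff = (vs, max(ve, vs + 1))
    if not _overlap(eff, t.span):
        return set()
    if v.ref:
        observed = _fetch(genome, t.chrom, vs, ve)
        if observed != v.ref:
            raise ValueError(
                f"reference mismatch at {t.chrom}:{v.pos}: "
                f"variant has {v.ref!r}, genome has {observed!r}"
            )

    terms: set[str] = set()
    exons = t.exons
    introns = [(a[1], b[0]) for a, b in zip(exons, exons[1:])]

    for a, b in introns:
        if not _overlap(eff, (a, b)):
            continue
        w = min(SPLICE_WINDOW, b - a)
        if t.strand == "+":
            donor, acceptor = (a, a + w), (max(b - w, a), b)
        else:
            donor, acceptor = (max(b - w, a), b), (a, a + w)
        in_donor = _overlap(eff, donor)
        in_acceptor = _overlap(eff, acceptor)
        if in_donor:
            terms.add("splice_donor_variant")
        if in_acceptor:
            terms.add("splice_acceptor_variant")
        # any intronic overlap outside the two windows
        core = (a + w, b - w)
        if core[0] < core[1] and _overlap(eff, core):
            terms.add("intron_variant")

    splice_hit = bool(terms & {"splice_donor_variant", "splice_acceptor_variant"})

    if t.is_coding:
        cds_span = (t.cds[0][0], t.cds[-1][1])
        for s, e in exons:
            if not _overlap(eff, (s, e)):
                continue
            # UTR portions of this exon
            for u_start, u_end in _subtract((s, e), t.cds):
                if _overlap(eff, (u_start, u_end)):
                    before_cds = u_end <= cds_span[0]
                    if (t.strand == "+") == before_cds:
                        terms.add("5_prime_UTR_variant")
                    else:
                        terms.add("3_prime_UTR_variant")
        cds_overlap = any(_overlap(eff, c) for c in t.cds)
        if cds_overlap and not (splice_hit and len(v.ref) != len(v.alt)):
            terms |= _coding_terms(v, t, genome, vs, ve)
    return terms


def _subtract(interval: tuple[int, int], holes: Sequence[tuple[int, int]]):
    """Yield the parts of ``interval`` not covered by ``holes`` (sorted)."""
    start, end = interval
    for h_start, h_end in holes:
        if h_end <= start or h_start >= end:
            continue
        if start < h_start:
            yield (start, h_start)
        start = max(start, h_end)
    if start < end:
        yield (start, end)


def _coding_terms(
    v: NormalizedVariant, t: TranscriptModel, genome, vs: int, ve: int
) -> set[str]:
    net = len(v.alt) - len(v.ref)
    if net != 0:
        if net % 3 != 0:
            return {"frameshift_variant"}
        return {"inframe_deletion"} if net < 0 else {"inframe_insertion"}

    # equal-length substitution: splice the alt into the forward-strand CDS,
    # orient, translate, and compare proteins
    contained = next((c for c in t.cds if c[0] <= vs and ve <= c[1]), None)
    if contained is None:
        # substitution straddling a CDS boundary within an exon: at least
        # one coding base changes, so report the generic coding term
        return {"missense_variant"}
    forward = []
    mutated = []
    for s, e in t.cds:
        piece = _fetch(genome, t.chrom, s, e)
        forward.append(piece)
        if (s, e) == contained:
            piece = piece[: vs - s] + v.alt + piece[ve - s :]
        mutated.append(piece)
    cds_seq = "".join(forward)
    mut_seq = "".join(mutated)
    if t.strand == "-":
        cds_seq, mut_seq = _revcomp(cds_seq), _revcomp(mut_seq)
    ref_protein = _translate(cds_seq)
    alt_protein = _translate(mut_seq)
    diffs = [i for i, (x, y) in enumerate(zip(ref_protein, alt_protein)) if x != y]
    if not diffs:
        return {"synonymous_variant"}
    i = diffs[0]
    if i == 0 and mut_seq[:3] != "ATG":
        return {"start_lost"}
    if ref_protein[i] == "*":
        return {"stop_lost"}
    if alt_protein[i] == "*":
        return {"stop_gained"}
    return {"missense_variant"}


def load_transcripts(gtf_path: str) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    Groups exon and CDS features by ``transcript_id``.  An optional
    ``canonical`` attribute (or Ensembl's ``tag "canonical"``) marks the
    canonical transcript; it is taken as given, never computed.
    """
    import gffutils

    db = gffutils.create_db(
        gtf_path,
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS", "transcript"}:
            continue
        tx_id = feat.attributes.get("transcript_id", [None])[0]
        if tx_id is None:
            continue
        attrs = feat.attributes
        info = meta.setdefault(tx_id, {})
        info.setdefault("gene_id", attrs.get("gene_id", [tx_id])[0])
        info.setdefault("chrom", feat.seqid)
        info.setdefault("strand", feat.strand)
        biotype = attrs.get("transcript_biotype", attrs.get("gene_biotype", [None]))[0]
        if biotype:
            info["biotype"] = biotype
        tags = attrs.get("tag", [])
        if "canonical" in tags or attrs.get("canonical", ["0"])[0] in {"1", "true"}:
            info["canonical"] = True
        interval = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
        if feat.featuretype == "exon":
            exons.setdefault(tx_id, []).append(interval)
        elif feat.featuretype == "CDS":
            cds.setdefault(tx_id, []).append(interval)
    models = []
    for tx_id, ex in exons.items():
        info = meta[tx_id]
        models.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=tuple(sorted(ex)),
                cds=tuple(sorted(cds.get(tx_id, []))),
                biotype=info.get("biotype", "protein_coding"),
                canonical=info.get("canonical", True),
            )
        )
    return models


def annotate_variants(
    variants: Iterable[tuple[int, NormalizedVariant]],
    transcripts: Sequence[TranscriptModel],
    genome,
) -> list[ConsequenceCall]:
    """Assign CSQ bitmasks for every interacting variant/transcript pair."""
    from rsvr.codec import encode_csq

    calls = []
    for rsvr_id, v in variants:
        for t in transcripts:
            terms = assign_consequences(v, t, genome)
            if terms:
                calls.append(ConsequenceCall(rsvr_id, t.transcript_id, encode_csq(terms)))
    return calls
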