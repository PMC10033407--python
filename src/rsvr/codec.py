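"""64-bit variant identifiers (RSVR IDs) and consequence bitmasks (CSQ IDs).

A small variant (SNV or short indel) is packed into 63 bits as

    c * 2**58 + p * 2**30 + |r| * 2**24 + |a| * 2**18 + sum_i A_i * 4**(i-1)

where ``c`` is the chromosome code (1-22, 23=X, 24=Y, 25=MT), ``p`` the
1-based position after trimming, ``|r|`` and ``|a|`` the reference and
alternate allele lengths, and ``A`` the alternate allele with bases valued
A=0, C=1, G=2, T=3.  The five fields occupy 5, 28, 6, 6 and 18 bits.  IDs
therefore sort numerically by genomic position.  Simple structural variants
use the 64th (most significant) bit as a discriminator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

__all__ = [
    "SEVERITY_ORDER",
    "HIGH_IMPACT_TERMS",
    "MODERATE_IMPACT_TERMS",
    "NormalizedVariant",
    "DecodedVariant",
    "DecodedSv",
    "CHROM_CODES",
    "chrom_code",
    "normalize_variant",
    "is_lossless",
    "encode_rsvr",
    "decode_rsvr",
    "encode_sv",
    "decode_sv",
    "encode_csq",
    "decode_csq",
    "worst_consequence",
    "meets_impact",
]

_POS_BITS = 28
_LEN_BITS = 6
_ALT_BITS = 18
_MAX_POS = 1 << _POS_BITS
_MAX_LEN = (1 << _LEN_BITS) - 1  # stored length saturates here
_BASE_VAL = {"A": 0, "C": 1, "G": 2, "T": 3}
_VAL_BASE = "ACGT"

#: Chromosome name -> integer code. X, Y and MT map to 23, 24 and 25.
CHROM_CODES = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}

# Fixed consequence severity table, least to most severe.  Bit index in the
# CSQ mask equals list index, so larger masks (after isolating the top bit)
# are more severe.  This ordering is a package constant: the source of truth
# for every severity comparison.
SEVERITY_ORDER: tuple[str, ...] = (
    "intergenic_variant",
    "downstream_gene_variant",
    "upstream_gene_variant",
    "intron_variant",
    "3_prime_UTR_variant",
    "5_prime_UTR_variant",
    "synonymous_variant",
    "splice_region_variant",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
)

_TERM_BIT = {term: i for i, term in enumerate(SEVERITY_ORDER)}

HIGH_IMPACT_TERMS = frozenset(
    {
        "start_lost",
        "stop_lost",
        "frameshift_variant",
        "stop_gained",
        "splice_donor_variant",
        "splice_acceptor_variant",
    }
)
# High-impact variants are deliberately embedded in the moderate class:
# both are capable of inducing a loss of function.
MODERATE_IMPACT_TERMS = HIGH_IMPACT_TERMS | {"missense_variant", "inframe_deletion"}

_HIGH_MASK = sum(1 << _TERM_BIT[t] for t in HIGH_IMPACT_TERMS)
_MODERATE_MASK = sum(1 << _TERM_BIT[t] for t in MODERATE_IMPACT_TERMS)
_UTR5_MASK = 1 << _TERM_BIT["5_prime_UTR_variant"]
_CLASS_MASKS = {"high": _HIGH_MASK, "moderate": _MODERATE_MASK, "utr5": _UTR5_MASK}


class SymbolicAlleleError(ValueError):
    """Raised for alleles containing characters outside {A, C, G, T}."""


@dataclass(frozen=True)
class NormalizedVariant:
    """A variant after prefix-then-suffix trimming of shared sequence.

    ``ref`` and ``alt`` may be empty (pure insertion / deletion) but never
    share a first or last character, and are never both empty.
    """

    chrom_code: int
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not 1 <= self.chrom_code <= 25:
            raise ValueError(f"chromosome code {self.chrom_code} outside 1-25")
        if self.pos < 1:
            raise ValueError(f"position {self.pos} is not 1-based")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.ref and self.alt:
            if self.ref[0] == self.alt[0] or self.ref[-1] == self.alt[-1]:
                raise ValueError("alleles are not fully trimmed")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


class DecodedVariant(NamedTuple):
    chrom_code: int
    pos: int
    ref_len: int
    alt_len: int
    alt: str
    partial: bool  # True when only the first-five + last-four alt bases are stored


class DecodedSv(NamedTuple):
    sv_type: int
    chrom_code: int
    start: int
    length: int


def chrom_code(name: str) -> int:
    """Map a chromosome name (with or without a ``chr`` prefix) to its code."""
    key = name[3:] if name.lower().startswith("chr") else name
    try:
        return CHROM_CODES[key.upper()]
    except KeyError:
        raise ValueError(f"unsupported chromosome {name!r}") from None


def _check_allele(allele: str, label: str) -> str:
    allele = allele.upper()
    if any(b not in _BASE_VAL for b in allele):
        raise SymbolicAlleleError(
            f"{label} allele {allele!r} contains non-ACGT characters"
        )
    return allele


def normalize_variant(chrom_code: int, pos: int, ref: str, alt: str) -> NormalizedVariant:
    """Trim shared sequence from the starts, then the ends, of ref/alt.

    The prefix trim advances ``pos`` by the trimmed length.  Input alleles
    are case-folded; symbolic alleles (``<DEL>``, breakends, ``N``) are
    rejected.
    """
    ref = _check_allele(ref, "reference")
    alt = _check_allele(alt, "alternate")
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref!r}); not a variant")
    # shared prefix first
    i = 0
    while i < len(ref) and i < len(alt) and ref[i] == alt[i]:
        i += 1
    ref, alt, pos = ref[i:], alt[i:], pos + i
    # then shared suffix
    j = 0
    while j < len(ref) and j < len(alt) and ref[len(ref) - 1 - j] == alt[len(alt) - 1 - j]:
        j += 1
    if j:
        ref, alt = ref[:-j], alt[:-j]
    return NormalizedVariant(chrom_code, pos, ref, alt)


def is_lossless(v: NormalizedVariant) -> bool:
    """Whether ``decode_rsvr(encode_rsvr(v))`` recovers the variant exactly.

    Encoding is ambiguous when either allele length exceeds 63 (the stored
    length saturates) or the alternate allele is 10 bases or longer (only
    the first five and last four bases are stored).  Ambiguous variants
    should be persisted in full in an overflow table keyed by RSVR ID.
    """
    return len(v.ref) <= _MAX_LEN and len(v.alt) < 10


def encode_rsvr(v: NormalizedVariant) -> int:
    """Pack a normalized variant into its 63-bit RSVR ID."""
    if v.pos >= _MAX_POS:
        raise OverflowError(f"position {v.pos} needs more than {_POS_BITS} bits")
    ref_len = min(len(v.ref), _MAX_LEN)
    alt_len = min(len(v.alt), _MAX_LEN)
    a = v.alt if len(v.alt) < 10 else v.alt[:5] + v.alt[-4:]
    alt_code = 0
    for i, base in enumerate(a):
        alt_code += _BASE_VAL[base] * 4**i
    return (
        (v.chrom_code << 58)
        | (v.pos << 30)
        | (ref_len << 24)
        | (alt_len << 18)
        | alt_code
    )


def decode_rsvr(value: int) -> DecodedVariant:
    """Unpack an RSVR ID.  The reference sequence is not stored and is
    reported only by length; alternate alleles of 10+ bases come back as a
    9-base fragment with ``partial=True``."""
    if not 0 <= value < (1 << 63):
        raise ValueError("RSVR IDs for small variants occupy 63 bits")
    alt_code = value & ((1 << _ALT_BITS) - 1)
    alt_len = (value >> _ALT_BITS) & _MAX_LEN
    ref_len = (value >> 24) & _MAX_LEN
    pos = (value >> 30) & (_MAX_POS - 1)
    chrom = value >> 58
    partial = alt_len >= 10
    n_bases = 9 if partial else alt_len
    bases = []
    for _ in range(n_bases):
        bases.append(_VAL_BASE[alt_code & 3])
        alt_code >>= 2
    return DecodedVariant(chrom, pos, ref_len, alt_len, "".join(bases), partial)


def encode_sv(sv_type: int, chrom_code: int, start: int, length: int) -> int:
    """Pack a simple structural variant (deletion 0, duplication 1,
    inversion 2, insertion 3) with the most significant bit set."""
    if not 0 <= sv_type <= 3:
        raise ValueError(f"SV type {sv_type} outside 0-3")
    if not 1 <= chrom_code <= 25:
        raise ValueError(f"chromosome code {chrom_code} outside 1-25")
    if not 0 <= start < _MAX_POS:
        raise ValueError(f"start {start} needs more than {_POS_BITS} bits")
    if not 0 <= length < _MAX_POS:
        raise ValueError(f"length {length} needs more than {_POS_BITS} bits")
    return (1 << 63) | (sv_type << 61) | (chrom_code << 56) | (start << 28) | length


def decode_sv(value: int) -> DecodedSv:
    if not value >> 63:
        raise ValueError("not a structural-variant RSVR ID (MSB is 0)")
    return DecodedSv(
        sv_type=(value >> 61) & 3,
        chrom_code=(value >> 56) & 31,
        start=(value >> 28) & (_MAX_POS - 1),
        length=value & (_MAX_POS - 1),
    )


def encode_csq(terms: Iterable[str]) -> int:
    """OR together the severity bits of a set of SO consequence terms."""
    mask = 0
    for term in terms:
        try:
            mask |= 1 << _TERM_BIT[term]
        except KeyError:
            raise ValueError(f"unknown consequence term {term!r}") from None
    return mask


def decode_csq(mask: int) -> set[str]:
    return {term for term, bit in _TERM_BIT.items() if mask >> bit & 1}


def worst_consequence(mask: int) -> str | None:
    """The term of the highest set bit, or ``None`` for an empty mask."""
    if mask == 0:
        return None
    return SEVERITY_ORDER[mask.bit_length() - 1]


def meets_impact(mask: int, impact_class: str) -> bool:
    """Whether a consequence mask qualifies for an impact class.

    ``high`` requires one of the six loss-of-function terms; ``moderate``
    additionally admits missense_variant and inframe_deletion; ``utr5``
    requires the 5_prime_UTR_variant bit.
    """
    try:
        return bool(mask & _CLASS_MASKS[impact_class])
    except KeyError:
        raise ValueError(f"unknown impact class {impact_class!r}") from None
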