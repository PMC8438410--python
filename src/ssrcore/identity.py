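"""Molecular identity cards: genotype coding and minimal discriminating markers.

Each genotype at a locus is written as one character:

* homozygotes ``A/A``, ``B/B``, ``C/C``, ``D/D`` (and onward) become the
  digits ``'1'``, ``'2'``, ``'3'``, ``'4'``, ... (k-th homozygote -> digit k,
  which caps the alphabet at nine alleles per locus);
* the heterozygotes among the first four alleles, in the order
  ``A/B, A/C, A/D, B/C, B/D, C/D``, become the letters ``'A'``-``'F'``;
* heterozygote pairs involving a fifth or later allele are appended after
  ``'F'`` in lexicographic pair order (``'G'``, ``'H'``, ..., continuing
  into lowercase after ``'Z'``), so the printed 4-allele assignments are
  never disturbed;
* a missing (no-band) genotype is ``'0'``.

An accession's *molecular identity* is the string of these characters over
an ordered marker panel.  The panel is chosen greedily: markers are ranked
by PIC (most informative first) and the prefix is grown one marker at a
time until every accession's identity string is unique.  Missing-data
``'0'`` characters count as distinguishing characters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .diversity import allele_freqs, pic
from .errors import ValidationError
from .genotypes import ALLELE_LETTERS, MISSING, GenotypeMatrix

__all__ = [
    "MISSING_CHAR",
    "IdentityScheme",
    "IdentityString",
    "encode_genotype",
    "decode_char",
    "select_discriminating_markers",
    "build_identities",
    "verify_uniqueness",
]

MISSING_CHAR = "0"

# The first six heterozygote codes are fixed by the published card format;
# everything beyond is a lexicographic extension.
_FIXED_HET = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]


def _build_tables() -> tuple[dict[tuple[str, str], str], dict[str, tuple[str, str] | None]]:
    enc: dict[tuple[str, str], str] = {}
    for k, letter in enumerate(ALLELE_LETTERS, start=1):
        enc[(letter, letter)] = str(k)
    for pair, ch in zip(_FIXED_HET, "ABCDEF"):
        enc[pair] = ch
    all_het = [
        (a, b) for a, b in itertools.combinations(ALLELE_LETTERS, 2)
    ]
    extra = sorted(p for p in all_het if p not in _FIXED_HET)
    codes = [chr(c) for c in range(ord("G"), ord("Z") + 1)]
    codes += [chr(c) for c in range(ord("a"), ord("z") + 1)]
    if len(extra) > len(codes):
        raise AssertionError("code alphabet exhausted")  # unreachable for <= 9 alleles
    for pair, ch in zip(extra, codes):
        enc[pair] = ch
    dec: dict[str, tuple[str, str] | None] = {v: k for k, v in enc.items()}
    dec[MISSING_CHAR] = MISSING
    return enc, dec

_ENCODE, _DECODE = _build_tables()


def encode_genotype(g: tuple[str, str] | None) -> str:
    """One-character code for a canonical genotype pair (or missing)."""
    if g is MISSING:
        return MISSING_CHAR
    pair = tuple(sorted(g))
    try:
        return _ENCODE[pair]
    except KeyError:
        raise ValidationError(f"genotype {g!r} outside the representable alphabet") from None


def decode_char(c: str) -> tuple[str, str] | None:
    """Invert :func:`encode_genotype`; ``'0'`` decodes to missing."""
    try:
        return _DECODE[c]
    except KeyError:
        raise ValidationError(f"unknown identity character {c!r}") from None


@dataclass
class IdentityScheme:
    """An ordered discriminating marker panel."""

    ordered_markers: list[str]
    missing_char: str = MISSING_CHAR

    def __len__(self) -> int:
        return len(self.ordered_markers)


@dataclass
class IdentityString:
    """One accession's identity card: one character per scheme marker."""

    accession_id: str
    characters: str


def build_identities(
    matrix: GenotypeMatrix, scheme: IdentityScheme
) -> list[IdentityString]:
    """Encode every accession over the scheme's markers, in scheme order."""
    unknown = [m for m in scheme.ordered_markers if m not in matrix.marker_ids]
    if unknown:
        raise ValidationError(f"scheme markers absent from matrix: {unknown}")
    out = []
    for acc in matrix.accession_ids:
        chars = "".join(
            encode_genotype(matrix.genotype(acc, m)) for m in scheme.ordered_markers
        )
        out.append(IdentityString(acc, chars))
    return out


def verify_uniqueness(
    identities: list[IdentityString],
) -> tuple[bool, list[list[str]]]:
    """True iff all identity strings are distinct; else the colliding groups."""
    groups: dict[str, list[str]] = {}
    for ident in identities:
        groups.setdefault(ident.characters, []).append(ident.accession_id)
    dupes = [ids for ids in groups.values() if len(ids) > 1]
    return (not dupes, dupes)


def select_discriminating_markers(
    matrix: GenotypeMatrix,
) -> tuple[IdentityScheme, list[list[str]]]:
    """Greedy PIC-ordered minimal discriminating marker panel.

    Markers are sorted by PIC descending (ties keep input order) and the
    panel is the shortest prefix whose identity strings are pairwise
    distinct.  If even the full marker set leaves collisions, the full set
    is returned together with the indistinguishable accession groups.
    """
    if matrix.n_accessions < 2:
        raise ValidationError("need at least two accessions to discriminate")
    scored = [(-pic(allele_freqs(matrix, m).p), k, m) for k, m in enumerate(matrix.marker_ids)]
    order = [m for _, _, m in sorted(scored)]
    prefix_codes = ["" for _ in matrix.accession_ids]
    for depth, marker in enumerate(order, start=1):
        col = [encode_genotype(matrix.genotype(a, marker)) for a in matrix.accession_ids]
        prefix_codes = [p + c for p, c in zip(prefix_codes, col)]
        if len(set(prefix_codes)) == matrix.n_accessions:
            return IdentityScheme(order[:depth]), []
    idents = [
        IdentityString(a, s) for a, s in zip(matrix.accession_ids, prefix_codes)
    ]
    _, dupes = verify_uniqueness(idents)
    return IdentityScheme(order), dupes
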