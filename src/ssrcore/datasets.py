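"""Bundled datasets.

The package ships the one genotype table the Akebia trifoliata survey
prints in full: the 164-accession core collection with its 11-character
molecular identity cards over the discriminating panel
(s28, s25, s74, s89, s68, s30, s13, s100, s72, s77, s3).  Decoding those
strings recovers a real 164 x 11 codominant genotype matrix that exercises
every stage of the pipeline.
"""

from __future__ import annotations

from importlib import resources

from .genotypes import GenotypeMatrix
from .identity import IdentityScheme, decode_char

__all__ = ["CORE164_MARKERS", "load_core164", "load_core164_identities"]

#: Discriminating marker panel, in PIC-descending selection order.
CORE164_MARKERS = (
    "s28", "s25", "s74", "s89", "s68", "s30", "s13", "s100", "s72", "s77", "s3",
)


def load_core164_identities() -> list[tuple[str, str]]:
    """The printed (accession, 11-character identity) pairs."""
    text = (
        resources.files("ssrcore.data").joinpath("core164_identities.tsv").read_text("utf-8")
    )
    lines = text.strip().splitlines()[1:]  # header
    return [tuple(ln.split("\t")) for ln in lines]


def load_core164() -> GenotypeMatrix:
    """Decode the identity cards into a 164 x 11 genotype matrix."""
    pairs = load_core164_identities()
    cells = []
    for _, ident in pairs:
        row = []
        for ch in ident:
            g = decode_char(ch)
            row.append(None if g is None else g[0] + g[1])
        cells.append(row)
    return GenotypeMatrix.from_cells(
        [acc for acc, _ in pairs], list(CORE164_MARKERS), cells
    )


def core164_scheme() -> IdentityScheme:
    """The survey's 11-marker identity scheme."""
    return IdentityScheme(list(CORE164_MARKERS))
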