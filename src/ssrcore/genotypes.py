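"""Domain model and I/O for codominant SSR genotype matrices.

An SSR (microsatellite) locus is scored from gel bands: the allele with the
largest molecular weight is labelled ``A``, the next ``B``, and so on.  A
diploid accession shows at most two bands per locus; a single band is scored
as a homozygote and no band at all as missing.  The data structure for a
study is therefore a rectangular accessions x loci table of unordered allele
pairs with missing cells, which :class:`GenotypeMatrix` represents.

Internally genotypes are stored as two integer allele indices per cell
(``a1 <= a2``, ``-1`` for missing), which keeps downstream statistics
vectorisable; the letter-pair view (``"AB"``, ``"--"``) is the interchange
format.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: Sentinel for a missing (no-band) genotype.
MISSING = None

#: Allele labels in rank order; at most nine alleles per locus so that the
#: single-character identity coding (see :mod:`ssrcore.identity`) stays total.
ALLELE_LETTERS = string.ascii_uppercase[:9]

MISSING_TOKEN = "--"


def genotype(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographically sorted) unordered allele pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Marker:
    """An SSR locus with its ordered allele labels.

    ``allele_labels`` run from ``'A'`` (largest band molecular weight)
    downward and must be contiguous; the cap of nine alleles is imposed by
    the single-character genotype coding used for molecular identities.
    """

    id: str
    allele_labels: tuple[str, ...]

    def __post_init__(self):
        labels = tuple(self.allele_labels)
        if not labels:
            raise ValidationError(f"marker {self.id!r}: empty allele label set")
        if len(labels) > len(ALLELE_LETTERS):
            raise ValidationError(
                f"marker {self.id!r}: {len(labels)} alleles exceed the "
                f"{len(ALLELE_LETTERS)}-allele coding bound"
            )
        expected = tuple(ALLELE_LETTERS[: len(labels)])
        if labels != expected:
            raise ValidationError(
                f"marker {self.id!r}: allele labels {labels} are not contiguous "
                f"from 'A' (expected {expected})"
            )
        object.__setattr__(self, "allele_labels", labels)

    @property
    def n_alleles(self) -> int:
        return len(self.allele_labels)


class GenotypeMatrix:
    """Accessions x loci matrix of unordered diploid allele pairs.

    Parameters
    ----------
    accession_ids
        Unique row labels.
    markers
        Column loci; each knows its allele alphabet.
    a1, a2
        Integer allele-index arrays of shape ``(n_accessions, n_loci)`` with
        ``a1 <= a2`` cell-wise and ``-1`` in both where the cell is missing.
    """

    def __init__(
        self,
        accession_ids: Sequence[str],
        markers: Sequence[Marker],
        a1: np.ndarray,
        a2: np.ndarray,
    ):
        accession_ids = list(accession_ids)
        if len(set(accession_ids)) != len(accession_ids):
            dupes = sorted({x for x in accession_ids if accession_ids.count(x) > 1})
            raise ValidationError(f"duplicate accession ids: {dupes}")
        markers = list(markers)
        a1 = np.asarray(a1, dtype=np.int16)
        a2 = np.asarray(a2, dtype=np.int16)
        shape = (len(accession_ids), len(markers))
        if a1.shape != shape or a2.shape != shape:
            raise ValidationError(f"allele arrays must have shape {shape}")
        missing = a1 < 0
        if not np.array_equal(missing, a2 < 0):
            raise ValidationError("missing state must apply to both alleles of a cell")
        if np.any(a1[~missing] > a2[~missing]):
            raise ValidationError("allele pairs must be stored canonically (a1 <= a2)")
        for j, m in enumerate(markers):
            hi = max(a1[:, j].max(initial=-1), a2[:, j].max(initial=-1))
            if hi >= m.n_alleles:
                raise ValidationError(
                    f"marker {m.id!r}: allele index {hi} out of range "
                    f"for {m.n_alleles} declared alleles"
                )
        self.accession_ids = accession_ids
        self.markers = markers
        self.a1 = a1
        self.a2 = a2
        self._acc_index = {a: i for i, a in enumerate(accession_ids)}
        self._marker_index = {m.id: j for j, m in enumerate(markers)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def marker(self, marker_id: str) -> Marker:
        return self.markers[self.locus_index(marker_id)]

    def locus_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_accessions, n_loci) array, True where the cell is missing."""
        return self.a1 < 0

    def genotype(self, accession_id: str, marker_id: str):
        """Return the canonical letter pair at a cell, or :data:`MISSING`."""
        i = self._acc_index[accession_id]
        j = self.locus_index(marker_id)
        if self.a1[i, j] < 0:
            return MISSING
        return (ALLELE_LETTERS[self.a1[i, j]], ALLELE_LETTERS[self.a2[i, j]])

    def cell_strings(self) -> np.ndarray:
        """Object array of two-letter genotype strings ('AB') with '--' for missing."""
        out = np.empty((self.n_accessions, self.n_loci), dtype=object)
        for i in range(self.n_accessions):
            for j in range(self.n_loci):
                if self.a1[i, j] < 0:
                    out[i, j] = MISSING_TOKEN
                else:
                    out[i, j] = ALLELE_LETTERS[self.a1[i, j]] + ALLELE_LETTERS[self.a2[i, j]]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Letter-pair view as a DataFrame (index = accessions, columns = markers)."""
        return pd.DataFrame(
            self.cell_strings(), index=self.accession_ids, columns=self.marker_ids
        )

    def subset(self, accession_ids: Iterable[str]) -> "GenotypeMatrix":
        """Row subset in the given order; marker alphabets are preserved."""
        ids = list(accession_ids)
        rows = [self._acc_index[a] for a in ids]
        return GenotypeMatrix(ids, self.markers, self.a1[rows], self.a2[rows])

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.markers == other.markers
            and np.array_equal(self.a1, other.a1)
            and np.array_equal(self.a2, other.a2)
        )

    def __repr__(self) -> str:
        return (
            f"<GenotypeMatrix {self.n_accessions} accessions x {self.n_loci} loci, "
            f"{int(self.missing_mask().sum())} missing cells>"
        )

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_cells(
        cls,
        accession_ids: Sequence[str],
        marker_ids: Sequence[str],
        cells: Sequence[Sequence[str | None]],
    ) -> "GenotypeMatrix":
        """Build a matrix from letter-pair cells, deriving allele alphabets.

        Each cell is a two-letter string (order irrelevant), ``"--"`` or
        ``None`` for missing.  A marker's alphabet is ``'A'`` up to the
        highest letter observed at that locus.
        """
        n, L = len(accession_ids), len(marker_ids)
        a1 = np.full((n, L), -1, dtype=np.int16)
        a2 = np.full((n, L), -1, dtype=np.int16)
        max_idx = np.full(L, -1, dtype=int)
        for i, row in enumerate(cells):
            if len(row) != L:
                raise ValidationError(
                    f"accession {accession_ids[i]!r}: expected {L} genotype "
                    f"cells, got {len(row)}"
                )
            for j, cell in enumerate(row):
                if cell is None or cell == MISSING_TOKEN:
                    continue
                if len(cell) != 2:
                    raise ValidationError(
                        f"accession {accession_ids[i]!r}, marker "
                        f"{marker_ids[j]!r}: malformed genotype {cell!r}"
                    )
                x, y = sorted(cell.upper())
                for letter in (x, y):
                    if letter not in string.ascii_uppercase[: len(ALLELE_LETTERS)]:
                        raise ValidationError(
                            f"accession {accession_ids[i]!r}, marker "
                            f"{marker_ids[j]!r}: allele {letter!r} outside the "
                            f"supported alphabet A-{ALLELE_LETTERS[-1]}"
                        )
                a1[i, j] = ord(x) - ord("A")
                a2[i, j] = ord(y) - ord("A")
                max_idx[j] = max(max_idx[j], a2[i, j])
        markers = [
            Marker(mid, tuple(ALLELE_LETTERS[: max(k + 1, 1)]))
            for mid, k in zip(marker_ids, max_idx)
        ]
        return cls(list(accession_ids), markers, a1, a2)


def recode_bands(
    accession_ids: Sequence[str],
    marker_ids: Sequence[str],
    bands: Sequence[Sequence[Sequence[float]]] | Mapping[str, Mapping[str, Sequence[float]]],
) -> GenotypeMatrix:
    """Recode raw band molecular weights into letter genotypes.

    Distinct band weights observed anywhere at a locus are ranked in
    decreasing order and lettered ``A``, ``B``, ...; an accession showing one
    band is a homozygote, none is missing, and more than two violates the
    diploid assumption.

    ``bands`` is either a nested list aligned with ``accession_ids`` x
    ``marker_ids`` or a mapping ``{accession: {marker: [weights]}}``.
    """
    if isinstance(bands, Mapping):
        table = [
            [list(bands.get(acc, {}).get(mid, [])) for mid in marker_ids]
            for acc in accession_ids
        ]
    else:
        table = [[list(cell) for cell in row] for row in bands]

    # locus-wide weight ranking is independent of accession order
    letters_for: list[dict[float, str]] = []
    for j, mid in enumerate(marker_ids):
        weights = sorted({w for row in table for w in row[j]}, reverse=True)
        if any(w <= 0 for w in weights):
            raise ValidationError(f"marker {mid!r}: band weights must be positive")
        if len(weights) > len(ALLELE_LETTERS):
            raise ValidationError(
                f"marker {mid!r}: {len(weights)} distinct bands exceed the "
                f"{len(ALLELE_LETTERS)}-allele coding bound"
            )
        letters_for.append({w: ALLELE_LETTERS[r] for r, w in enumerate(weights)})

    cells: list[list[str | None]] = []
    for acc, row in zip(accession_ids, table):
        out_row: list[str | None] = []
        for mid, cell, lut in zip(marker_ids, row, letters_for):
            if len(cell) > 2:
                raise ValidationError(
                    f"accession {acc!r}, marker {mid!r}: {len(cell)} bands "
                    "observed; a diploid shows at most two"
                )
            if not cell:
                out_row.append(MISSING)
            elif len(cell) == 1:
                out_row.append(lut[cell[0]] * 2)
            else:
                out_row.append("".join(sorted(lut[w] for w in cell)))
        cells.append(out_row)
    return GenotypeMatrix.from_cells(accession_ids, marker_ids, cells)


# ---------------------------------------------------------------------------
# File I/O: native CSV/TSV dialect and GenePop
# ---------------------------------------------------------------------------

NATIVE_DIALECTS = {"csv": ",", "tsv": "\t"}


def _native_sep(path: str, dialect: str | None) -> tuple[str, str]:
    if dialect in ("csv", "tsv"):
        return dialect, NATIVE_DIALECTS[dialect]
    if dialect is None:
        name = str(path).lower()
        if name.endswith(".tsv") or name.endswith(".txt"):
            return "tsv", "\t"
        return "csv", ","
    raise ValueError(f"unknown dialect {dialect!r}")


def read_genotypes(path, dialect: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix.

    ``dialect`` is ``"csv"``/``"tsv"`` (native: header ``id,<marker>,...``,
    cells ``"AB"`` / ``"--"``) or ``"genepop"``; ``None`` infers native
    csv/tsv from the file extension.
    """
    if dialect == "genepop":
        return _read_genepop(path)
    _, sep = _native_sep(path, dialect)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty genotype file")
    header = lines[0].split(sep)
    if len(header) < 2:
        raise ParseError("header must name an id column and at least one marker", line=1)
    marker_ids = [h.strip() for h in header[1:]]
    accession_ids: list[str] = []
    cells: list[list[str | None]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in ln.split(sep)]
        if len(fields) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, got {len(fields)}", line=lineno
            )
        accession_ids.append(fields[0])
        row: list[str | None] = []
        for mid, tok in zip(marker_ids, fields[1:]):
            if tok == MISSING_TOKEN:
                row.append(MISSING)
            elif len(tok) == 2 and tok.isalpha():
                row.append(tok)
            else:
                raise ParseError(
                    f"marker {mid!r}: genotype token {tok!r} is neither two "
                    f"letters nor {MISSING_TOKEN!r}",
                    line=lineno,
                )
        cells.append(row)
    return GenotypeMatrix.from_cells(accession_ids, marker_ids, cells)


def write_genotypes(matrix: GenotypeMatrix, path, dialect: str | None = None) -> None:
    """Write ``matrix`` in the native CSV/TSV dialect or GenePop format."""
    if dialect == "genepop":
        _write_genepop(matrix, path)
        return
    _, sep = _native_sep(path, dialect)
    strings = matrix.cell_strings()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["id"] + matrix.marker_ids) + "\n")
        for i, acc in enumerate(matrix.accession_ids):
            fh.write(sep.join([acc] + list(strings[i])) + "\n")


def _allele_code(idx: int) -> str:
    return f"{idx + 1:02d}"


def _write_genepop(matrix: GenotypeMatrix, path) -> None:
    """GenePop export: 4-digit diploid codes (A->01, B->02, ...), one POP block."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ssrcore genotype export\n")
        for mid in matrix.marker_ids:
            fh.write(mid + "\n")
        fh.write("POP\n")
        for i, acc in enumerate(matrix.accession_ids):
            codes = []
            for j in range(matrix.n_loci):
                if matrix.a1[i, j] < 0:
                    codes.append("0000")
                else:
                    codes.append(_allele_code(matrix.a1[i, j]) + _allele_code(matrix.a2[i, j]))
            fh.write(f"{acc} , " + " ".join(codes) + "\n")


def _read_genepop(path) -> GenotypeMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated GenePop file")
    body = lines[1:]
    marker_ids: list[str] = []
    pop_at = None
    for k, ln in enumerate(body):
        if ln.strip().upper() == "POP":
            pop_at = k
            break
        marker_ids.extend(m.strip() for m in ln.split(",") if m.strip())
    if pop_at is None:
        raise ParseError("no POP line found", line=len(lines))
    accession_ids: list[str] = []
    cells: list[list[str | None]] = []
    for off, ln in enumerate(body[pop_at + 1 :]):
        lineno = off + pop_at + 3
        if ln.strip().upper() == "POP":
            continue  # extra POP blocks are concatenated
        if not ln.strip():
            continue
        if "," not in ln:
            raise ParseError("expected '<id> , <genotypes>'", line=lineno)
        acc, _, rest = ln.partition(",")
        codes = rest.split()
        if len(codes) != len(marker_ids):
            raise ParseError(
                f"expected {len(marker_ids)} loci, got {len(codes)}", line=lineno
            )
        row: list[str | None] = []
        for mid, code in zip(marker_ids, codes):
            if len(code) != 4 or not code.isdigit():
                raise ParseError(f"marker {mid!r}: bad 4-digit code {code!r}", line=lineno)
            u, v = int(code[:2]), int(code[2:])
            if u == 0 and v == 0:
                row.append(MISSING)
            elif u == 0 or v == 0:
                raise ParseError(
                    f"marker {mid!r}: half-missing genotype {code!r} is not "
                    "representable",
                    line=lineno,
                )
            elif max(u, v) > len(ALLELE_LETTERS):
                raise ParseError(
                    f"marker {mid!r}: allele code {max(u, v)} exceeds the "
                    f"{len(ALLELE_LETTERS)}-allele bound",
                    line=lineno,
                )
            else:
                row.append(ALLELE_LETTERS[u - 1] + ALLELE_LETTERS[v - 1])
        accession_ids.append(acc.strip())
        cells.append(row)
    return GenotypeMatrix.from_cells(accession_ids, marker_ids, cells)
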