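"""Data model and TSV I/O for 2x3 case-control genotype count tables.

A diallelic marker with major allele ``a`` and minor allele ``A`` yields
three genotypes ordered by minor-allele count: ``aa`` (G0), ``Aa`` (G1),
``AA`` (G2).  A case-control study summarises into a 2x3 table of case
counts ``r = (r0, r1, r2)`` and control counts ``s = (s0, s1, s2)``, with
column margins ``n_i = r_i + s_i``, row margins ``R``/``S`` and total
``N = R + S``.  Every test in this package consumes this object.

Counts are usually integers, but fractional cell values are a first-class
mode: the theoretical-comparison workflow evaluates both trend statistics
on tables of *expected* cell values, which are non-integer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "GenotypeTable",
    "ScoreVector",
    "TestResult",
    "GenotypeTableError",
    "read_table",
    "write_table",
    "minor_allele_frequency",
    "GENOTYPE_LABELS",
]

GENOTYPE_LABELS = ("aa", "Aa", "AA")

_INT_TOL = 1e-9


class GenotypeTableError(ValueError):
    """Raised for malformed, negative or empty genotype tables."""


def _validate_triple(name: str, values: Iterable[float]) -> tuple[float, float, float]:
    vals = tuple(float(v) for v in values)
    if len(vals) != 3:
        raise GenotypeTableError(f"{name} must have exactly 3 entries, got {len(vals)}")
    for i, v in enumerate(vals):
        if not math.isfinite(v):
            raise GenotypeTableError(f"{name}[{i}] is not finite: {v}")
        if v < 0:
            raise GenotypeTableError(f"{name}[{i}] is negative: {v}")
    return vals


@dataclass(frozen=True)
class GenotypeTable:
    """2x3 case/control genotype counts with derived margins.

    Parameters
    ----------
    r : tuple of float
        Case counts for genotypes (aa, Aa, AA).
    s : tuple of float
        Control counts for genotypes (aa, Aa, AA).
    label : str
        Free-text identifier, e.g. a variant ID.

    Margins (``n``, ``R``, ``S``, ``N``) are always derived from the cells,
    never stored independently, so the margin invariants cannot be violated.
    """

    r: tuple[float, float, float]
    s: tuple[float, float, float]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", _validate_triple("cases", self.r))
        object.__setattr__(self, "s", _validate_triple("controls", self.s))
        if self.N <= 0:
            raise GenotypeTableError("table is empty: N must be > 0")

    # -- derived margins ---------------------------------------------------
    @property
    def n(self) -> tuple[float, float, float]:
        """Column margins n_i = r_i + s_i."""
        return tuple(ri + si for ri, si in zip(self.r, self.s))

    @property
    def R(self) -> float:
        return sum(self.r)

    @property
    def S(self) -> float:
        return sum(self.s)

    @property
    def N(self) -> float:
        return self.R + self.S

    @property
    def fractional(self) -> bool:
        """True when any cell is non-integer (expected-table mode)."""
        return any(
            abs(v - round(v)) > _INT_TOL for v in (*self.r, *self.s)
        )

    def as_integer(self) -> "GenotypeTable":
        """Return a copy with cells cast to int; error if fractional."""
        if self.fractional:
            raise GenotypeTableError(
                f"table {self.label!r} has fractional cells; integer counts required"
            )
        return GenotypeTable(
            tuple(int(round(v)) for v in self.r),
            tuple(int(round(v)) for v in self.s),
            self.label,
        )

    def swapped_rows(self) -> "GenotypeTable":
        return GenotypeTable(self.s, self.r, self.label)

    def reversed_columns(self) -> "GenotypeTable":
        return GenotypeTable(self.r[::-1], self.s[::-1], self.label)


@dataclass(frozen=True)
class ScoreVector:
    """Ordered genotype scores (x0, x1, x2) encoding a genetic-model assumption.

    Must satisfy x0 <= x1 <= x2 and x0 < x2.  The additive convention
    (0, 0.5, 1) is the usual default; (0, 1, 1) encodes dominant and
    (0, 0, 1) recessive effects of the minor allele.
    """

    x: tuple[float, float, float]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.x)
        if len(vals) != 3:
            raise ValueError("scores must have exactly 3 entries")
        x0, x1, x2 = vals
        if not (x0 <= x1 <= x2):
            raise ValueError(f"scores must be non-decreasing, got {vals}")
        if not x0 < x2:
            raise ValueError(f"scores must satisfy x0 < x2, got {vals}")
        object.__setattr__(self, "x", vals)


# Standard score presets, keyed by model name.
SCORE_PRESETS = {
    "additive": ScoreVector((0.0, 0.5, 1.0)),
    "dominant": ScoreVector((0.0, 1.0, 1.0)),
    "recessive": ScoreVector((0.0, 0.0, 1.0)),
}


@dataclass(frozen=True)
class TestResult:
    """Outcome of a 1-df association test.

    ``p_value`` is the upper-tail chi-square(df) probability at ``statistic``
    for all asymptotic tests in this package.
    """

    statistic: float
    df: int
    p_value: float
    test_name: str
    notes: str = ""
    extra: dict = field(default_factory=dict, compare=False)

    __test__ = False  # not a pytest collectible despite the name

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError(f"statistic must be >= 0, got {self.statistic}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


# -- I/O -------------------------------------------------------------------

_HEADER = ("genotype", *GENOTYPE_LABELS)


def read_table(path: str | Path, dialect: str = "tsv") -> GenotypeTable:
    """Read a genotype table from a TSV file.

    Expected layout (UTF-8, tab-separated)::

        genotype  aa   Aa   AA
        cases     r0   r1   r2
        controls  s0   s1   s2

    Raises
    ------
    GenotypeTableError
        On a malformed header, missing rows, non-numeric or negative
        counts, naming the offending row/column.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect: {dialect!r}")
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if len(lines) != 3:
        raise GenotypeTableError(
            f"{path}: expected header + 2 data rows, found {len(lines)} non-empty lines"
        )
    header = tuple(c.strip() for c in lines[0].split("\t"))
    if header != _HEADER:
        raise GenotypeTableError(
            f"{path}: bad header {header!r}, expected {_HEADER!r}"
        )
    rows: dict[str, tuple[float, float, float]] = {}
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split("\t")]
        if len(cells) != 4:
            raise GenotypeTableError(f"{path}: row {cells[0]!r} has {len(cells) - 1} cells, expected 3")
        name = cells[0].lower()
        if name not in ("cases", "controls"):
            raise GenotypeTableError(f"{path}: unknown row label {cells[0]!r}")
        try:
            vals = tuple(float(c) for c in cells[1:])
        except ValueError as exc:
            raise GenotypeTableError(f"{path}: non-numeric count in row {cells[0]!r}: {exc}") from exc
        rows[name] = vals
    if set(rows) != {"cases", "controls"}:
        raise GenotypeTableError(f"{path}: need one 'cases' and one 'controls' row")
    return GenotypeTable(rows["cases"], rows["controls"], label=path.stem)


def _fmt(v: float) -> str:
    if abs(v - round(v)) <= _INT_TOL:
        return str(int(round(v)))
    return repr(v)


def write_table(table: GenotypeTable, path: str | Path) -> None:
    """Write a genotype table in the TSV dialect of :func:`read_table`.

    The round trip ``read_table(write_table(t))`` reproduces cell values
    bit-exactly (integers as integers, fractional values via ``repr``).
    """
    path = Path(path)
    lines = [
        "\t".join(_HEADER),
        "\t".join(["cases", *(_fmt(v) for v in table.r)]),
        "\t".join(["controls", *(_fmt(v) for v in table.s)]),
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def minor_allele_frequency(table: GenotypeTable) -> float:
    """Pooled frequency of the minor allele A: (n1 + 2*n2) / (2N).

    Emits a ``UserWarning`` when the value exceeds 0.5, which usually means
    the genotype columns are not ordered by minor-allele count.
    """
    n0, n1, n2 = table.n
    maf = (n1 + 2.0 * n2) / (2.0 * table.N)
    if maf > 0.5:
        warnings.warn(
            f"pooled allele-A frequency {maf:.3f} > 0.5; genotype columns may be "
            "mis-ordered (expected ascending minor-allele count: aa, Aa, AA)",
            UserWarning,
            stacklevel=2,
        )
    return maf
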