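"""Exact linear algebra over the rationals or a large prime field.

Homology ranks must be exact — floating-point rank estimation can silently
mis-count cycles — so elimination is done either with
:class:`fractions.Fraction` arithmetic (default; the boundary matrices have
tiny integer entries, so this stays fast at pathway scale) or in
GF(2^31 − 1) for speed on larger problems.  Over a random large prime the
rank of a small-integer matrix equals its rational rank except on a
vanishing set of inputs; the rational backend remains the reference.

Matrices are plain lists of rows (ints or Fractions); columns are the
generators being reduced.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

_PRIME = 2**31 - 1

Matrix = list[list]


class QField:
    """Rational arithmetic."""

    @staticmethod
    def convert(x) -> Fraction:
        return Fraction(x)

    @staticmethod
    def inv(x: Fraction) -> Fraction:
        return 1 / x

    zero = Fraction(0)
    one = Fraction(1)


class GFPrimeField:
    """Arithmetic modulo a fixed 31-bit prime."""

    p = _PRIME

    @classmethod
    def convert(cls, x) -> int:
        return int(x) % cls.p

    @classmethod
    def inv(cls, x: int) -> int:
        return pow(x, cls.p - 2, cls.p)

    zero = 0
    one = 1


def get_field(backend: str):
    if backend == "fraction":
        return QField
    if backend == "gf":
        return GFPrimeField
    raise ValueError(f"unknown linear-algebra backend {backend!r}")


def _rref(rows: Matrix, field) -> tuple[Matrix, list[int]]:
    """Reduced row-echelon form; returns (reduced rows, pivot column indices)."""
    if not rows:
        return [], []
    p = getattr(field, "p", None)
    m, n = len(rows), len(rows[0])
    mat = [[field.convert(x) for x in row] for row in rows]
    pivots: list[int] = []
    r = 0
    for c in range(n):
        pivot_row = None
        for i in range(r, m):
            if mat[i][c] != field.zero:
                pivot_row = i
                break
        if pivot_row is None:
            continue
        mat[r], mat[pivot_row] = mat[pivot_row], mat[r]
        inv = field.inv(mat[r][c])
        if inv != field.one:
            if p is None:
                mat[r] = [x * inv for x in mat[r]]
            else:
                mat[r] = [(x * inv) % p for x in mat[r]]
        for i in range(m):
            if i != r and mat[i][c] != field.zero:
                f = mat[i][c]
                if p is None:
                    mat[i] = [a - f * b for a, b in zip(mat[i], mat[r])]
                else:
                    mat[i] = [(a - f * b) % p for a, b in zip(mat[i], mat[r])]
        pivots.append(c)
        r += 1
        if r == m:
            break
    return mat, pivots


def rank(rows: Matrix, backend: str = "fraction") -> int:
    """Exact rank of a matrix given as a list of rows."""
    if not rows or not rows[0]:
        return 0
    _, pivots = _rref(rows, get_field(backend))
    return len(pivots)


def nullspace(rows: Matrix, n_cols: int, backend: str = "fraction") -> Matrix:
    """Basis of the right null space; vectors returned as rows of length ``n_cols``.

    ``n_cols`` must be passed explicitly so an empty matrix (no constraints)
    still yields the full standard basis.
    """
    field = get_field(backend)
    if not rows:
        basis = []
        for j in range(n_cols):
            v = [field.zero] * n_cols
            v[j] = field.one
            basis.append(v)
        return basis
    mat, pivots = _rref(rows, field)
    pivot_set = set(pivots)
    free = [c for c in range(n_cols) if c not in pivot_set]
    basis = []
    for f in free:
        v = [field.zero] * n_cols
        v[f] = field.one
        for i, c in enumerate(pivots):
            # x_c = -mat[i][f] * x_f
            val = mat[i][f]
            if val != field.zero:
                v[c] = (-val) % field.p if hasattr(field, "p") else -val
        basis.append(v)
    return basis


def rank_of_columns(columns: Sequence[Sequence], backend: str = "fraction") -> int:
    """Rank of the matrix whose columns are the given vectors."""
    cols = [c for c in columns if any(x != 0 for x in c)]
    if not cols:
        return 0
    return rank([list(c) for c in cols], backend)  # row rank == column rank
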