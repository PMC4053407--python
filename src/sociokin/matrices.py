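"""Labelled symmetric dyadic matrices (association, relatedness, overlap).

All pairwise quantities in the package travel as :class:`DyadicMatrix`: a
square symmetric matrix with an ordered list of individual labels.  The
diagonal carries no information (an individual's association with itself is
undefined) and is stored as NaN.  Association and overlap indices live in
[0, 1]; relatedness may be negative and may be NaN for dyads sharing no
typed loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MATRIX_KINDS = ("association", "relatedness", "overlap")

# values must be symmetric to within this tolerance on construction / read
SYMMETRY_TOL = 1e-9
RANGE_TOL = 1e-9


class MatrixFormatError(ValueError):
    """Raised when a dyadic matrix violates its structural contract."""


@dataclass
class DyadicMatrix:
    ids: list[str]
    values: np.ndarray
    kind: str = "association"
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        v = np.asarray(self.values, dtype=float).copy()
        n = len(self.ids)
        if v.shape != (n, n):
            raise MatrixFormatError(
                f"matrix shape {v.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise MatrixFormatError("ids are not unique")
        np.fill_diagonal(v, np.nan)
        off = ~np.eye(n, dtype=bool)
        finite = off & np.isfinite(v)
        if not np.allclose(
            np.where(finite & finite.T, v, 0.0),
            np.where(finite & finite.T, v.T, 0.0),
            atol=SYMMETRY_TOL,
            rtol=0.0,
        ) or not (finite == finite.T).all():
            raise MatrixFormatError(
                f"matrix is asymmetric beyond {SYMMETRY_TOL:g}"
            )
        if self.kind not in MATRIX_KINDS:
            raise MatrixFormatError(
                f"unknown matrix kind {self.kind!r}; expected one of {MATRIX_KINDS}"
            )
        if self.kind in ("association", "overlap"):
            bad = finite & ((v < -RANGE_TOL) | (v > 1.0 + RANGE_TOL))
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise MatrixFormatError(
                    f"{self.kind} value {v[i, j]} at ({self.ids[i]}, "
                    f"{self.ids[j]}) outside [0, 1]"
                )
            v[finite] = np.clip(v[finite], 0.0, 1.0)
        # store the exact symmetrisation so downstream arithmetic is symmetric
        v = np.where(off, (np.where(finite, v, 0) + np.where(finite.T, v.T, 0))
                     / np.maximum(finite.astype(int) + finite.T.astype(int), 1),
                     np.nan)
        v[off & ~(finite | finite.T)] = np.nan
        self.values = v

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, id_: str) -> int:
        return self.ids.index(str(id_))

    def dyad_vector(self, ids: list[str] | None = None) -> np.ndarray:
        """Upper-triangle (i < j) values as a flat vector."""
        m = self if ids is None else self.subset(ids)
        iu = np.triu_indices(m.n, k=1)
        return m.values[iu]

    def subset(self, ids: list[str]) -> "DyadicMatrix":
        ids = [str(i) for i in ids]
        missing = [i for i in ids if i not in set(self.ids)]
        if missing:
            raise KeyError(f"ids not in matrix: {missing}")
        idx = [self.ids.index(i) for i in ids]
        return DyadicMatrix(ids, self.values[np.ix_(idx, idx)], self.kind)

    def reorder_like(self, other: "DyadicMatrix") -> "DyadicMatrix":
        return self.subset(other.ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DyadicMatrix):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.kind == other.kind
            and np.allclose(self.values, other.values, atol=1e-9, equal_nan=True)
        )


def align(*matrices: DyadicMatrix, subset: list[str] | None = None) -> list[DyadicMatrix]:
    """Restrict matrices to a common id set (optionally intersected with
    ``subset``) in a common order."""
    common = [i for i in matrices[0].ids if all(i in m.ids for m in matrices[1:])]
    if subset is not None:
        wanted = {str(s) for s in subset}
        common = [i for i in common if i in wanted]
    if len(common) < 2:
        raise ValueError("fewer than two shared ids after alignment")
    return [m.subset(common) for m in matrices]
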