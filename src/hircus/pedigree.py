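"""Pedigree handling and the additive genetic relationship matrix.

The additive relationship matrix A underlies every animal model in this
package: the vector of additive genetic effects is assumed a ~ N(0, A sigma2_a),
where A carries twice the kinship coefficient between each pair of animals and
1 + F_i (F_i the inbreeding coefficient) on the diagonal.

A is built dense by the tabular (recursive) method.  This is a deliberate
choice for herd-book scales of a few thousand animals: memory is quadratic in
pedigree size, and no sparse inverse is ever formed (the samplers invert A
densely once).  Identifiers are compared as exact strings after whitespace
trimming; ear-tag codes are case sensitive.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "PedigreeRecord",
    "Pedigree",
    "RelationshipMatrix",
    "read_pedigree",
    "write_pedigree",
    "sort_pedigree",
    "relationship_matrix",
    "inbreeding",
]

#: strings accepted as "parent unknown" in pedigree files
MISSING_PARENT_CODES = {"", "0", "NA", "na", "nan", "NaN", ".", "none", "None"}


class PedigreeError(ValueError):
    """Raised for structural pedigree problems (duplicates, cycles, unknowns)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal: its identifier, parents (None if unknown) and birth year."""

    animal_id: str
    sire_id: str | None = None
    dam_id: str | None = None
    birth_year: int | None = None


@dataclass
class Pedigree:
    """An ordered collection of :class:`PedigreeRecord` with an id index.

    After :func:`sort_pedigree` every parent precedes all of its offspring,
    which is what the recursive relationship-matrix construction requires.
    """

    records: list[PedigreeRecord]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {}
        for pos, rec in enumerate(self.records):
            if rec.animal_id in self.index:
                raise PedigreeError(f"duplicate animal id {rec.animal_id!r}")
            self.index[rec.animal_id] = pos

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.animal_id for r in self.records]

    def is_sorted(self) -> bool:
        """True when every parent's position precedes all its offspring."""
        for pos, rec in enumerate(self.records):
            for par in (rec.sire_id, rec.dam_id):
                if par is not None and self.index[par] >= pos:
                    return False
        return True

    def parent_indices(self) -> np.ndarray:
        """(n, 2) int array of sire/dam positions, -1 for unknown."""
        out = np.full((len(self.records), 2), -1, dtype=np.int64)
        for pos, rec in enumerate(self.records):
            if rec.sire_id is not None:
                out[pos, 0] = self.index[rec.sire_id]
            if rec.dam_id is not None:
                out[pos, 1] = self.index[rec.dam_id]
        return out


@dataclass
class RelationshipMatrix:
    """Dense symmetric additive relationship matrix in pedigree order."""

    values: np.ndarray
    order: list[str]

    def __post_init__(self) -> None:
        self._index = {a: i for i, a in enumerate(self.order)}

    def loc(self, a: str, b: str) -> float:
        """Relationship between two animals by identifier."""
        return float(self.values[self._index[a], self._index[b]])

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.values) - 1.0

    def inverse(self) -> np.ndarray:
        """Dense inverse of A (used by the Gibbs samplers)."""
        return np.linalg.inv(self.values)


def _clean_id(raw: object) -> str | None:
    s = str(raw).strip()
    if s in MISSING_PARENT_CODES:
        return None
    return s


def _validate(records: list[PedigreeRecord], *, strict: bool) -> list[PedigreeRecord]:
    declared = set()
    for rec in records:
        if rec.animal_id in declared:
            raise PedigreeError(f"duplicate animal id {rec.animal_id!r}")
        declared.add(rec.animal_id)

    sires = {r.sire_id for r in records if r.sire_id is not None}
    dams = {r.dam_id for r in records if r.dam_id is not None}
    both = sires & dams
    if both:
        raise PedigreeError(
            f"identifiers used as both sire and dam: {sorted(both)[:5]}"
        )

    undeclared = [p for p in (sires | dams) if p not in declared]
    if undeclared:
        if strict:
            raise PedigreeError(
                f"parent ids referenced but never declared: {sorted(undeclared)[:5]}"
            )
        warnings.warn(
            f"{len(undeclared)} parent id(s) not declared; added as founders",
            stacklevel=3,
        )
        founders = [PedigreeRecord(p) for p in sorted(undeclared)]
        records = founders + records
    return records


def read_pedigree(
    path: str | Path | _io.IOBase,
    *,
    sep: str | None = None,
    strict: bool = False,
) -> Pedigree:
    """Read a delimited pedigree file and return a sorted, validated Pedigree.

    The file must have columns ``animal``, ``sire``, ``dam`` and optionally
    ``birth_year`` (header required; comma or tab autodetected unless *sep*
    is given).  Unknown parents may be coded "0", empty or "NA".  In strict
    mode an undeclared parent is an error; otherwise it is auto-added as a
    founder with a warning.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    for needed in ("animal", "sire", "dam"):
        if needed not in cols:
            raise PedigreeError(f"pedigree file lacks a {needed!r} column")
    records = []
    for _, row in df.iterrows():
        aid = _clean_id(row[cols["animal"]])
        if aid is None:
            raise PedigreeError("blank/missing animal id in pedigree file")
        year = None
        if "birth_year" in cols and pd.notna(row[cols["birth_year"]]):
            year = int(float(row[cols["birth_year"]]))
        records.append(
            PedigreeRecord(
                aid,
                _clean_id(row[cols["sire"]]),
                _clean_id(row[cols["dam"]]),
                year,
            )
        )
    records = _validate(records, strict=strict)
    return sort_pedigree(Pedigree(records))


def write_pedigree(ped: Pedigree, path: str | Path, *, sep: str = ",") -> None:
    """Write the pedigree (in its current order) in the canonical format."""
    df = pd.DataFrame(
        {
            "animal": [r.animal_id for r in ped],
            "sire": [r.sire_id if r.sire_id is not None else "0" for r in ped],
            "dam": [r.dam_id if r.dam_id is not None else "0" for r in ped],
            "birth_year": [r.birth_year if r.birth_year is not None else "" for r in ped],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def sort_pedigree(ped: Pedigree) -> Pedigree:
    """Topologically sort so parents precede offspring; stable for ties.

    Kahn's algorithm with a queue keyed on original file position, so animals
    that are free to be emitted keep their original relative order.  A cycle
    (an animal its own ancestor) raises :class:`PedigreeError` listing the
    animals involved.
    """
    import heapq

    n = len(ped)
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    indeg = [0] * n
    for pos, rec in enumerate(ped.records):
        for par in (rec.sire_id, rec.dam_id):
            if par is not None:
                children[ped.index[par]].append(pos)
                indeg[pos] += 1
    ready = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(ready)
    out: list[PedigreeRecord] = []
    while ready:
        i = heapq.heappop(ready)
        out.append(ped.records[i])
        for ch in children[i]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                heapq.heappush(ready, ch)
    if len(out) != n:
        stuck = [ped.records[i].animal_id for i in range(n) if indeg[i] > 0]
        raise PedigreeError(f"pedigree contains a cycle involving: {stuck[:10]}")
    return Pedigree(out)


def relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix A by the tabular method.

    For animal j (parents s, d, processed in pedigree order):

        a_ij = 0.5 * (a_is + a_id)          for every earlier animal i
        a_jj = 1 + 0.5 * a_sd

    with an unknown parent contributing zero.  Requires a sorted pedigree.
    """
    if not ped.is_sorted():
        raise PedigreeError("pedigree must be sorted (parents before offspring)")
    n = len(ped)
    par = ped.parent_indices()
    A = np.zeros((n, n))
    for j in range(n):
        s, d = par[j]
        row = np.zeros(j)
        if s >= 0:
            row += 0.5 * A[:j, s]
        if d >= 0:
            row += 0.5 * A[:j, d]
        A[:j, j] = row
        A[j, :j] = row
        A[j, j] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(A, ped.ids)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F_i = 0.5 * a_{s(i),d(i)}; founders get 0."""
    return relationship_matrix(ped).inbreeding()
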