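"""Pedigrees and the additive (numerator) relationship matrix.

A pedigree is an ordered collection of individuals, each with an optional
sire and dam and a recorded sex.  The additive relationship matrix ``A``
holds twice the kinship coefficient between every pair of individuals; its
diagonal is ``1 + F`` where ``F`` is the inbreeding coefficient.  ``A`` is
the covariance structure of additive genetic effects in the animal model,
so everything downstream (REML heritability, genetic correlations,
pedigree-based kinship for association) consumes this module's output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "numerator_relationship_matrix",
]

UNKNOWN = "0"

MALE = "M"
FEMALE = "F"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, sex conflicts...)."""


@dataclasses.dataclass(frozen=True)
class Pedigree:
    """A validated, topologically sorted pedigree.

    Attributes
    ----------
    ids
        Individual identifiers, parents always before offspring.
    sire, dam
        Integer index of each individual's parent within ``ids``
        (``-1`` = unknown).
    sex
        ``"M"`` or ``"F"`` per individual.
    generation
        Generation number when known (founders = 0); ``-1`` if not recorded.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("sire", "dam", "sex", "generation"):
            if len(getattr(self, name)) != n:
                raise PedigreeError(f"field {name!r} has wrong length")
        order = np.arange(n)
        for par in (self.sire, self.dam):
            known = par >= 0
            if np.any(par[known] >= order[known]):
                raise PedigreeError("parents must precede offspring")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {i: k for k, i in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise KeyError(f"id {exc.args[0]!r} not in pedigree") from None

    def to_frame(self) -> pd.DataFrame:
        def name(idx: np.ndarray) -> np.ndarray:
            out = np.where(idx >= 0, self.ids[np.clip(idx, 0, None)], UNKNOWN)
            return out

        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": name(self.sire),
                "dam": name(self.dam),
                "sex": self.sex,
                "generation": self.generation,
            }
        )

    @classmethod
    def from_records(
        cls,
        records: Sequence[tuple[str, str, str, str]] | pd.DataFrame,
        generation: Mapping[str, int] | None = None,
    ) -> "Pedigree":
        """Build a pedigree from (id, sire, dam, sex) rows in any order.

        Rows are topologically sorted; ``"0"``, ``""`` and NA mean unknown
        parent.  Raises :class:`PedigreeError` on duplicated ids, cycles,
        unknown parent references, or an id used both as sire and dam.
        """
        if isinstance(records, pd.DataFrame):
            rows = [
                (str(r.id), str(r.sire), str(r.dam), str(r.sex))
                for r in records.itertuples()
            ]
        else:
            rows = [tuple(str(x) for x in row) for row in records]

        def clean(parent: str) -> str:
            return UNKNOWN if parent in ("0", "", "nan", "None", "NA") else parent

        ids = [r[0] for r in rows]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise PedigreeError(f"duplicate id(s): {dup[dup > 1].index.tolist()}")
        parent_of = {r[0]: (clean(r[1]), clean(r[2])) for r in rows}
        sex_of = {r[0]: r[3].upper()[:1] for r in rows}

        sires = {s for s, _ in parent_of.values() if s != UNKNOWN}
        dams = {d for _, d in parent_of.values() if d != UNKNOWN}
        both = sires & dams
        if both:
            raise PedigreeError(f"id(s) used as both sire and dam: {sorted(both)}")
        for pid, (s, d) in parent_of.items():
            for parent, role, want in ((s, "sire", MALE), (d, "dam", FEMALE)):
                if parent == UNKNOWN:
                    continue
                if parent not in parent_of:
                    raise PedigreeError(
                        f"individual {pid!r} references unknown {role} {parent!r}"
                    )
                if sex_of[parent] != want:
                    raise PedigreeError(
                        f"{role} {parent!r} of {pid!r} is recorded as sex "
                        f"{sex_of[parent]!r}"
                    )

        # Kahn topological sort; leftover nodes mean a parentage cycle.
        order: list[str] = []
        remaining = dict(parent_of)
        placed: set[str] = set()
        while remaining:
            ready = [
                i
                for i, (s, d) in remaining.items()
                if (s == UNKNOWN or s in placed) and (d == UNKNOWN or d in placed)
            ]
            if not ready:
                raise PedigreeError(
                    f"parentage cycle involving: {sorted(remaining)[:5]}"
                )
            for i in ready:
                order.append(i)
                placed.add(i)
                del remaining[i]

        pos = {i: k for k, i in enumerate(order)}

        def idx(parent: str) -> int:
            return -1 if parent == UNKNOWN else pos[parent]

        gen = generation or {}
        return cls(
            ids=np.array(order, dtype=object),
            sire=np.array([idx(parent_of[i][0]) for i in order], dtype=int),
            dam=np.array([idx(parent_of[i][1]) for i in order], dtype=int),
            sex=np.array([sex_of[i] for i in order], dtype=object),
            generation=np.array([gen.get(i, -1) for i in order], dtype=int),
        )


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree TSV with columns id, sire, dam, sex (0 = unknown).

    Rows may be in any order; the result is topologically sorted.  An
    optional ``generation`` column is carried through if present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"id", "sire", "dam", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree file missing column(s) {sorted(missing)}")
    df = df.fillna(UNKNOWN)
    gen = None
    if "generation" in df.columns:
        gen = {str(r.id): int(r.generation) for r in df.itertuples()}
    return Pedigree.from_records(df[["id", "sire", "dam", "sex"]], generation=gen)


def write_pedigree(pedigree: Pedigree, path: str | Path, header: str | None = None) -> None:
    """Write the pedigree as TSV (id, sire, dam, sex, generation)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        pedigree.to_frame().to_csv(fh, sep="\t", index=False)


def numerator_relationship_matrix(pedigree: Pedigree) -> np.ndarray:
    """Additive relationship matrix A by the tabular (recursive) method.

    Founders are taken as unrelated and non-inbred; an unknown single
    parent is treated as a phantom unrelated founder.  For individual
    ``i`` with parents ``s``, ``d`` (processed in topological order)::

        A[i, j] = (A[j, s] + A[j, d]) / 2      for j before i
        A[i, i] = 1 + A[s, d] / 2

    with terms for unknown parents dropped.  The result is symmetric and
    positive semi-definite, with diagonal ``1 + F_i``.
    """
    n = pedigree.n
    A = np.zeros((n, n))
    sire, dam = pedigree.sire, pedigree.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += A[s, :i]
        if d >= 0:
            row += A[d, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A
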