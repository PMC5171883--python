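"""Pedigree handling and exact inbreeding coefficients.

The drift test needs a colony-level inbreeding coefficient F.  For simulated
or user-supplied pedigrees this module computes per-individual F exactly from
the pedigree: F(x) is half the additive relationship between x's parents,
obtained with the Meuwissen–Luo algorithm (O(n * ancestors) without forming
the full relationship matrix).  The quadratic tabular method that builds the
whole numerator relationship matrix A is also provided; it serves as an
independent cross-check and is convenient on small pedigrees.

Unknown parents (coded 0 or blank in CSV) are treated as unrelated,
non-inbred founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import (
    DanglingParentError,
    DuplicateIdError,
    NoIndividualsError,
    PedigreeCycleError,
)

__all__ = [
    "Pedigree",
    "read_pedigree",
    "write_pedigree",
    "inbreeding_coefficients",
    "additive_relationship_matrix",
    "mean_line_F",
    "PEDIGREE_COLUMNS",
]

PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "generation", "family", "line"]


@dataclass
class Pedigree:
    """A validated, topologically ordered pedigree.

    ``frame`` keeps the original records (ids as strings, unknown parents as
    None); internal integer codes (``_sire_idx``/``_dam_idx``, -1 = unknown)
    index into the topological order used by the algorithms.
    """

    frame: pd.DataFrame
    _order: list[str] = field(default_factory=list, repr=False)
    _sire_idx: np.ndarray = field(default=None, repr=False)
    _dam_idx: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._validate_and_sort()

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> list[str]:
        """Individual ids in topological (parents-first) order."""
        return list(self._order)

    def _validate_and_sort(self) -> None:
        frame = self.frame.copy()
        frame["id"] = frame["id"].astype(str)
        for col in ("sire", "dam"):
            frame[col] = frame[col].map(_normalize_parent)

        ids = frame["id"].tolist()
        dupes = frame["id"][frame["id"].duplicated()].tolist()
        if dupes:
            raise DuplicateIdError(f"duplicate individual ids: {sorted(set(dupes))}")
        known = set(ids)
        for col in ("sire", "dam"):
            for parent in frame[col]:
                if parent is not None and parent not in known:
                    raise DanglingParentError(
                        f"{col} {parent!r} never appears as an individual"
                    )

        # Kahn topological sort; a leftover means a parentage cycle.
        parents = {
            row["id"]: [p for p in (row["sire"], row["dam"]) if p is not None]
            for _, row in frame.iterrows()
        }
        children: dict[str, list[str]] = {i: [] for i in ids}
        indeg = {i: 0 for i in ids}
        for child, ps in parents.items():
            for p in ps:
                children[p].append(child)
                indeg[child] += 1
        queue = [i for i in ids if indeg[i] == 0]
        order: list[str] = []
        while queue:
            node = queue.pop()
            order.append(node)
            for ch in children[node]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(order) != len(ids):
            cyclic = sorted(set(ids) - set(order))
            raise PedigreeCycleError(
                f"pedigree contains a parentage cycle involving: {cyclic}"
            )

        pos = {ident: k for k, ident in enumerate(order)}
        frame = frame.set_index("id", drop=False).loc[order].reset_index(drop=True)
        self.frame = frame
        self._order = order
        self._sire_idx = np.array(
            [pos[p] if p is not None else -1 for p in frame["sire"]], dtype=np.int64
        )
        self._dam_idx = np.array(
            [pos[p] if p is not None else -1 for p in frame["dam"]], dtype=np.int64
        )


def _normalize_parent(value) -> Optional[str]:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    text = str(value).strip()
    if text in ("", "0", "0.0", "nan", "NA"):
        return None
    return text


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV (id,sire,dam,sex,generation,family,line).

    Unknown parents may be coded as 0 or left blank.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in PEDIGREE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"pedigree file missing columns: {missing}")
    frame["generation"] = frame["generation"].astype(int)
    return Pedigree(frame[PEDIGREE_COLUMNS])


def write_pedigree(pedigree: Pedigree, path) -> None:
    """Write the pedigree in the same CSV dialect (unknown parents as 0)."""
    out = pedigree.frame.copy()
    for col in ("sire", "dam"):
        out[col] = out[col].map(lambda p: "0" if p is None else p)
    out[PEDIGREE_COLUMNS].to_csv(path, index=False)


def inbreeding_coefficients(pedigree: Pedigree) -> dict[str, float]:
    """Per-individual inbreeding coefficient F by the Meuwissen–Luo algorithm.

    For each individual the L-vector (fractional genome contributions of its
    ancestors) is accumulated parents-first; F then falls out of the
    Cholesky diagonal identity F_i = sum_j L_ij^2 D_jj - 1 with the
    within-family segregation variance D_jj = 0.5 - 0.25 (F_s + F_d).
    Founders (both parents unknown) have F = 0.
    """
    n = len(pedigree)
    sire = pedigree._sire_idx
    dam = pedigree._dam_idx
    F = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        fs = F[sire[i]] if sire[i] >= 0 else 0.0
        fd = F[dam[i]] if dam[i] >= 0 else 0.0
        # D_ii = 0.5 - 0.25 (F_s + F_d); unknown parent contributes 0.25 more
        d = 0.5 - 0.25 * (fs + fd)
        if sire[i] < 0:
            d += 0.25
        if dam[i] < 0:
            d += 0.25
        D[i] = d
        if sire[i] < 0 or dam[i] < 0:
            F[i] = 0.0
            continue
        # accumulate L-row sparsely over the ancestor set of i
        L: dict[int, float] = {i: 1.0}
        stack = [i]
        # process in decreasing index order so parents receive full weight
        pending = {i}
        acc = 0.0
        while pending:
            j = max(pending)
            pending.discard(j)
            lj = L.pop(j)
            acc += lj * lj * D[j]
            if sire[j] >= 0:
                L[sire[j]] = L.get(sire[j], 0.0) + 0.5 * lj
                pending.add(sire[j])
            if dam[j] >= 0:
                L[dam[j]] = L.get(dam[j], 0.0) + 0.5 * lj
                pending.add(dam[j])
        F[i] = acc - 1.0
    return {ident: float(F[k]) for k, ident in enumerate(pedigree.ids)}


def additive_relationship_matrix(pedigree: Pedigree) -> pd.DataFrame:
    """Numerator relationship matrix A by the recursive tabular method.

    Quadratic in pedigree size; intended for small pedigrees and as an
    independent check of :func:`inbreeding_coefficients`
    (F_i = A_ii - 1 = 0.5 * A[sire, dam]).
    """
    n = len(pedigree)
    sire = pedigree._sire_idx
    dam = pedigree._dam_idx
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
    return pd.DataFrame(A, index=pedigree.ids, columns=pedigree.ids)


def mean_line_F(
    pedigree: Pedigree,
    generation: int,
    line: str,
    coefficients: Optional[dict[str, float]] = None,
) -> float:
    """Mean inbreeding coefficient over one generation of one line.

    ``coefficients`` may be passed to reuse a previous
    :func:`inbreeding_coefficients` result.
    """
    frame = pedigree.frame
    mask = (frame["generation"] == generation) & (frame["line"] == line)
    members = frame.loc[mask, "id"].tolist()
    if not members:
        raise NoIndividualsError(
            f"no individuals in generation {generation} of line {line!r}"
        )
    if coefficients is None:
        coefficients = inbreeding_coefficients(pedigree)
    return float(np.mean([coefficients[m] for m in members]))
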