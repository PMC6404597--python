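"""Pedigree reading, validation, ordering and line composition.

A pedigree is a directed acyclic parent structure.  Founders are the
individuals with no recorded parents; each belongs to exactly one founder
line.  All recursions in this package run over a topological order with
founders first, never over generation labels (generation numbers are kept
as metadata only).

The *line composition* of an individual is the expected line-of-origin
fraction of a gamete it transmits.  On autosomes a transmitted gamete mixes
the two parental gametes equally, so f_k = ½(f_sire + f_dam).  On the X
chromosome a male carries (and transmits to daughters) the single X he
received from his dam, so f_male = f_dam, while females again average.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdError,
    HalfKnownParentError,
    InvalidLineLabelError,
    MissingLineLabelError,
    PedigreeCycleError,
    SelfingError,
    SexInconsistencyError,
    UnknownParentError,
    UnknownSexError,
)

AUTOSOMAL = "autosomal"
X = "x"
PARTITIONS = (AUTOSOMAL, X)


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"


_SEX_CODES = {
    "1": Sex.MALE,
    "m": Sex.MALE,
    "male": Sex.MALE,
    "2": Sex.FEMALE,
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
}

_UNKNOWN = {"", "0", "na", "none", "unknown"}


def parse_sex(code: object) -> Sex:
    """Parse a sex code (PLINK 1/2 convention, or M/F, case-insensitive)."""
    key = str(code).strip().lower()
    if key not in _SEX_CODES:
        raise UnknownSexError(f"unrecognized sex code {code!r} (use 1/2 or M/F)")
    return _SEX_CODES[key]


@dataclass(frozen=True)
class PedigreeRecord:
    """One pedigree row; ``sire``/``dam`` are None only for founders."""

    id: str
    sire: str | None
    dam: str | None
    sex: Sex
    line: str | None = None
    generation: int | None = None

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


class Pedigree:
    """Validated pedigree in founder-first topological order.

    Attributes
    ----------
    records : list[PedigreeRecord]
        Founders first (input order), then non-founders topologically.
    ids, founder_ids : list[str]
    line_labels : list[str]
        Ordered set of founder lines (first-appearance order).
    sire_idx, dam_idx : np.ndarray
        Parent positions in ``records``; -1 for founders.
    sexes : list[Sex]
    generations : np.ndarray
        Given labels, or inferred as 1 + max(parent generation), founders 0.
    """

    def __init__(self, records: list[PedigreeRecord]):
        self.records = _validate_and_order(records)
        self.ids = [r.id for r in self.records]
        self.index = {r.id: i for i, r in enumerate(self.records)}
        self.founder_ids = [r.id for r in self.records if r.is_founder]
        self.n_founders = len(self.founder_ids)
        seen: dict[str, None] = {}
        for r in self.records:
            if r.line is not None:
                seen.setdefault(r.line, None)
        self.line_labels = list(seen)
        self.sexes = [r.sex for r in self.records]
        n = len(self.records)
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        for i, r in enumerate(self.records):
            if not r.is_founder:
                self.sire_idx[i] = self.index[r.sire]
                self.dam_idx[i] = self.index[r.dam]
        self.generations = self._infer_generations()

    def __len__(self) -> int:
        return len(self.records)

    def _infer_generations(self) -> np.ndarray:
        gens = np.zeros(len(self.records), dtype=np.int64)
        for i, r in enumerate(self.records):
            if r.generation is not None:
                gens[i] = r.generation
            elif not r.is_founder:
                gens[i] = 1 + max(gens[self.sire_idx[i]], gens[self.dam_idx[i]])
        return gens

    @property
    def is_founder(self) -> np.ndarray:
        return self.sire_idx < 0

    def founder_lines(self) -> list[str]:
        """Line label of each founder, in founder order."""
        return [r.line for r in self.records if r.is_founder]  # type: ignore[misc]

    def founder_sexes(self) -> list[Sex]:
        return [r.sex for r in self.records if r.is_founder]


def _validate_and_order(records: list[PedigreeRecord]) -> list[PedigreeRecord]:
    ids = {}
    for r in records:
        if r.id in ids:
            raise DuplicateIdError(f"duplicate individual id {r.id!r}")
        ids[r.id] = r
    for r in records:
        if (r.sire is None) != (r.dam is None):
            raise HalfKnownParentError(
                f"individual {r.id!r} has exactly one recorded parent; "
                "unknown parents are allowed only for founders"
            )
        if r.is_founder:
            if r.line is None:
                raise MissingLineLabelError(f"founder {r.id!r} has no line label")
            continue
        if r.line is not None:
            raise InvalidLineLabelError(
                f"non-founder {r.id!r} carries line label {r.line!r}"
            )
        if r.sire == r.dam:
            raise SelfingError(f"individual {r.id!r} has sire == dam ({r.sire!r})")
        for parent, role in ((r.sire, "sire"), (r.dam, "dam")):
            if parent not in ids:
                raise UnknownParentError(
                    f"{role} {parent!r} of individual {r.id!r} is not in the pedigree"
                )
        if ids[r.sire].sex is not Sex.MALE:
            raise SexInconsistencyError(
                f"sex inconsistency: sire {r.sire!r} of {r.id!r} is not male"
            )
        if ids[r.dam].sex is not Sex.FEMALE:
            raise SexInconsistencyError(
                f"sex inconsistency: dam {r.dam!r} of {r.id!r} is not female"
            )
    # Kahn's algorithm, founders first, then input order among ready nodes.
    children: dict[str, list[str]] = {r.id: [] for r in records}
    missing = {}
    for r in records:
        if not r.is_founder:
            children[r.sire].append(r.id)
            children[r.dam].append(r.id)
            missing[r.id] = 2
    founders = [r for r in records if r.is_founder]
    ordered = list(founders)
    queue = deque(r.id for r in founders)
    placed = {r.id for r in founders}
    while queue:
        cur = queue.popleft()
        for child in children[cur]:
            missing[child] -= 1
            if missing[child] == 0:
                queue.append(child)
                placed.add(child)
                ordered.append(ids[child])
    if len(ordered) != len(records):
        stuck = [r.id for r in records if r.id not in placed]
        raise PedigreeCycleError(
            f"pedigree contains a cycle involving individuals {stuck[:5]}"
        )
    return ordered


def read_pedigree(path, format: str = "csv") -> Pedigree:
    """Read and validate a pedigree CSV.

    Expected header ``id,sire,dam,sex,line[,generation]``; unknown parents
    encoded as ``0`` or an empty field; sex as 1/2 (PLINK) or M/F.
    """
    if format != "csv":
        raise ValueError(f"unsupported pedigree format {format!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam", "sex", "line"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"pedigree file missing columns {sorted(missing_cols)}")
    records = []
    for row in df.itertuples(index=False):
        sire = None if row.sire.strip().lower() in _UNKNOWN else row.sire.strip()
        dam = None if row.dam.strip().lower() in _UNKNOWN else row.dam.strip()
        line = None if row.line.strip().lower() in _UNKNOWN else row.line.strip()
        gen = None
        if "generation" in df.columns:
            raw = getattr(row, "generation", "").strip()
            gen = int(raw) if raw else None
        records.append(
            PedigreeRecord(
                id=row.id.strip(),
                sire=sire,
                dam=dam,
                sex=parse_sex(row.sex),
                line=line,
                generation=gen,
            )
        )
    return Pedigree(records)


def write_pedigree_csv(ped: Pedigree, path) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in ped.records],
            "sire": [r.sire or "0" for r in ped.records],
            "dam": [r.dam or "0" for r in ped.records],
            "sex": ["1" if r.sex is Sex.MALE else "2" for r in ped.records],
            "line": [r.line or "0" for r in ped.records],
            "generation": ped.generations,
        }
    )
    df.to_csv(path, index=False)


@dataclass
class LineComposition:
    """Per-individual expected line-origin fractions of a transmitted gamete.

    ``autosomal`` and ``x`` are (n_individuals × n_lines) arrays whose rows
    sum to one; ``lines`` fixes the column order.
    """

    ids: list[str] = field(repr=False)
    lines: list[str]
    autosomal: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)

    def context(self, partition: str) -> np.ndarray:
        if partition == AUTOSOMAL:
            return self.autosomal
        if partition == X:
            return self.x
        raise ValueError(f"unknown partition {partition!r}")


def line_composition(ped: Pedigree) -> LineComposition:
    """Compute line compositions for every individual, both contexts.

    Founders get indicator vectors.  Autosomal: f = ½(f_sire + f_dam).
    X: females average as on autosomes; a male transmits the X he received
    from his dam, so f_male = f_dam.
    """
    n, L = len(ped), len(ped.line_labels)
    line_pos = {lab: j for j, lab in enumerate(ped.line_labels)}
    aut = np.zeros((n, L))
    xc = np.zeros((n, L))
    for i, r in enumerate(ped.records):
        if r.is_founder:
            aut[i, line_pos[r.line]] = 1.0
            xc[i, line_pos[r.line]] = 1.0
        else:
            s, d = ped.sire_idx[i], ped.dam_idx[i]
            aut[i] = 0.5 * (aut[s] + aut[d])
            if r.sex is Sex.FEMALE:
                xc[i] = 0.5 * (xc[s] + xc[d])
            else:
                xc[i] = xc[d]
    return LineComposition(ids=list(ped.ids), lines=list(ped.line_labels), autosomal=aut, x=xc)
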