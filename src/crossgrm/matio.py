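"""Text serialization of relationship matrices.

Two interchangeable formats, both with 17 significant digits so round trips
are bit-exact for doubles:

* dense: one header row of ids, then whitespace-delimited rows;
* triplets: lower triangle (including the diagonal) as
  ``id_i<TAB>id_j<TAB>value`` lines.
"""

from __future__ import annotations

import numpy as np

from .errors import LabelMismatchError
from .observed_grm import RelationshipMatrix

_FMT = "%.17g"


def write_dense(m: RelationshipMatrix, path) -> None:
    v = m.dense()
    with open(path, "w") as fh:
        fh.write("\t".join(m.ids) + "\n")
        for row in v:
            fh.write("\t".join(_FMT % x for x in row) + "\n")


def read_dense(path, partition: str, kind: str) -> RelationshipMatrix:
    with open(path) as fh:
        ids = fh.readline().split()
        vals = np.loadtxt(fh, ndmin=2)
    return RelationshipMatrix(values=vals, ids=ids, partition=partition, kind=kind)


def write_triplets(m: RelationshipMatrix, path) -> None:
    v = m.dense()
    with open(path, "w") as fh:
        for i, idi in enumerate(m.ids):
            for j in range(i + 1):
                fh.write(f"{idi}\t{m.ids[j]}\t{_FMT % v[i, j]}\n")


def read_triplets(path, partition: str, kind: str) -> RelationshipMatrix:
    ids: list[str] = []
    pos: dict[str, int] = {}
    entries = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            a, b, val = line.split("\t")
            for lab in (a, b):
                if lab not in pos:
                    pos[lab] = len(ids)
                    ids.append(lab)
            entries.append((pos[a], pos[b], float(val)))
    n = len(ids)
    vals = np.full((n, n), np.nan)
    for i, j, val in entries:
        vals[i, j] = val
        vals[j, i] = val
    if np.isnan(vals).any():
        raise LabelMismatchError("triplet file does not cover the full lower triangle")
    return RelationshipMatrix(values=vals, ids=ids, partition=partition, kind=kind)
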