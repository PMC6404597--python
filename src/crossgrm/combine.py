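"""Single-step combination H⁻¹ and the founder-relatedness correction Dk.

The combined matrix corrects the pedigree-propagated expectation Ã for the
founder relationships actually observed:

    H⁻¹ = Ã⁻¹ + [ G0_BLD⁻¹ − E(G0)⁻¹   0 ]
                [ 0                     0 ]

with the correction block on the founder indices (founders come first in
the ordering).  When G0_BLD = E(G0) the correction vanishes and H⁻¹ = Ã⁻¹.

Genetic variance components estimated against founder-related matrices are
re-expressed relative to unrelated base individuals by multiplying with

    Dk = mean(diag(g0)) − mean(g0)

over the f×f founder block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import LabelMismatchError, SingularMatrixError
from .observed_grm import KIND_COMBINED_INVERSE, RelationshipMatrix


@dataclass
class CombinedInverse:
    """H⁻¹ with founder-first ordering and construction provenance."""

    values: np.ndarray = field(repr=False)
    ids: list[str]
    partition: str
    provenance: dict = field(default_factory=dict)
    kind: str = KIND_COMBINED_INVERSE

    @property
    def n(self) -> int:
        return len(self.ids)

    def as_relationship_matrix(self) -> RelationshipMatrix:
        return RelationshipMatrix(
            values=self.values, ids=list(self.ids),
            partition=self.partition, kind=self.kind,
        )


def _inv_sym(values: np.ndarray, name: str, cond_threshold: float) -> np.ndarray:
    """Invert a symmetric matrix with a condition-number guard."""
    w = np.linalg.eigvalsh(values)
    wmax = float(np.abs(w).max()) if w.size else 0.0
    wmin = float(np.abs(w).min()) if w.size else 0.0
    if wmin == 0.0 or wmax / wmin > cond_threshold:
        raise SingularMatrixError(
            f"{name} is numerically singular (condition number above "
            f"{cond_threshold:g}); blend the observed matrix with its "
            "expectation (alpha < 1) to restore invertibility"
        )
    inv = scipy.linalg.inv(values, check_finite=False)
    return 0.5 * (inv + inv.T)


def build_h_inverse(
    atilde: RelationshipMatrix,
    g0_blended: RelationshipMatrix,
    e0: RelationshipMatrix,
    cond_threshold: float = 1e12,
) -> CombinedInverse:
    """Assemble H⁻¹ from Ã, the (blended) observed G0 and E(G0).

    ``atilde`` must carry the founders in its leading block (the ordering
    produced by the tabular extension); the founder correction is embedded
    there and all non-founder entries of H⁻¹ − Ã⁻¹ are exactly zero.
    """
    fids = list(e0.ids)
    if set(g0_blended.ids) != set(fids):
        raise LabelMismatchError("G0 and E(G0) founder ids differ")
    if atilde.ids[: len(fids)] != fids:
        if set(atilde.ids[: len(fids)]) != set(fids):
            raise LabelMismatchError(
                "Ã must carry the founders in its leading block"
            )
        fids = atilde.ids[: len(fids)]
    if len({atilde.partition, g0_blended.partition, e0.partition}) != 1:
        raise LabelMismatchError("partition tags differ between inputs")

    a_inv = _inv_sym(atilde.dense(), "Ã", cond_threshold)
    g_inv = _inv_sym(g0_blended.submatrix(fids).values, "G0 (blended)", cond_threshold)
    e_inv = _inv_sym(e0.submatrix(fids).values, "E(G0)", cond_threshold)

    h_inv = a_inv.copy()
    F = len(fids)
    h_inv[:F, :F] += g_inv - e_inv
    return CombinedInverse(
        values=h_inv,
        ids=list(atilde.ids),
        partition=atilde.partition,
        provenance={
            "founders": fids,
            "g0_kind": g0_blended.kind,
            "e0_kind": e0.kind,
            "cond_threshold": cond_threshold,
        },
    )


def dk_correction(founder_block) -> float:
    """Dk = mean founder self-relationship − mean of all f² founder entries."""
    if isinstance(founder_block, RelationshipMatrix):
        values = founder_block.dense()
    else:
        values = np.asarray(founder_block, dtype=float)
    f = values.shape[0]
    if values.shape != (f, f) or f < 2:
        raise ValueError("Dk requires a square founder block with f >= 2")
    return float(np.mean(np.diag(values)) - values.sum() / f**2)
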