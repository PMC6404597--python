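"""Observed genomic founder relationships G0 and blending.

Founder genotypes are centered with the composite frequency p̄: autosomal
entries of Z0 are c − 2p̄; on the X chromosome females are centered like
autosomes while hemizygous males (single allele, c ∈ {0,1}) use c − p̄.
Then

    G0 = Z0 Z0' / S,     S = 2·Σ_i p̄_i(1 − p̄_i).

G0 is frequently singular with few founders (e.g. duplicated or near-
identical genotypes); `blend` restores invertibility by the convex
combination α·G0 + (1−α)·E(G0) with the default α = 0.98.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LabelMismatchError
from .founder_genotypes import FounderGenotypes
from .moments import LineFrequencies, gametic_moments
from .pedigree import AUTOSOMAL, X, Sex

KIND_OBSERVED = "observed"
KIND_EXPECTED_FOUNDER = "expected-founder"
KIND_EXPECTED_PEDIGREE = "expected-pedigree"
KIND_BLENDED = "blended"
KIND_COMBINED_INVERSE = "combined-inverse"


@dataclass
class RelationshipMatrix:
    """Symmetric labelled relationship matrix.

    ``values`` may be an ndarray or an h5py dataset (chunked storage); all
    in-package consumers use row/block indexing that works for both.
    """

    values: np.ndarray = field(repr=False)
    ids: list[str]
    partition: str
    kind: str

    def __post_init__(self):
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise LabelMismatchError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise LabelMismatchError("relationship matrix ids must be unique")

    @property
    def n(self) -> int:
        return len(self.ids)

    def dense(self) -> np.ndarray:
        return np.asarray(self.values[...])

    def copy(self, kind: str | None = None) -> "RelationshipMatrix":
        return RelationshipMatrix(
            values=self.dense().copy(),
            ids=list(self.ids),
            partition=self.partition,
            kind=kind or self.kind,
        )

    def submatrix(self, ids: list[str]) -> "RelationshipMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        try:
            idx = [pos[i] for i in ids]
        except KeyError as exc:
            raise LabelMismatchError(f"id {exc.args[0]!r} not in matrix") from exc
        vals = self.dense()[np.ix_(idx, idx)]
        return RelationshipMatrix(
            values=vals, ids=list(ids), partition=self.partition, kind=self.kind
        )

    def require_symmetric(self, tol: float = 1e-12) -> None:
        v = self.dense()
        scale = max(1.0, float(np.abs(v).max())) if v.size else 1.0
        if v.size and np.abs(v - v.T).max() > tol * scale:
            raise LabelMismatchError("matrix is not symmetric")

    def min_relative_eigenvalue(self) -> float:
        """Smallest eigenvalue over the largest (PSD check helper)."""
        w = np.linalg.eigvalsh(self.dense())
        top = max(abs(w[0]), abs(w[-1]), 1e-300)
        return float(w[0] / top)


@dataclass
class CenteredGenotypes:
    """Centered founder genotype matrix Z0 (founders × markers).

    Each entry equals the gene count minus its centering constant: 2p̄ for
    autosomal entries and X females, p̄ for hemizygous X males.
    """

    values: np.ndarray = field(repr=False)
    founder_ids: list[str]
    marker_ids: list[str]
    partition: str


def centered_genotypes(
    g: FounderGenotypes, freqs: LineFrequencies, partition: str
) -> CenteredGenotypes:
    block = g.block(partition)
    pbar = freqs.block(partition).pbar
    if block.n_markers != len(pbar):
        raise LabelMismatchError(
            "genotype and frequency marker sets differ for partition "
            f"{partition!r} ({block.n_markers} vs {len(pbar)})"
        )
    center = 2.0 * pbar[None, :] * np.ones((len(g.founder_ids), 1))
    if partition == X:
        male = np.array([s is Sex.MALE for s in g.sexes])
        center[male] = pbar[None, :]
    return CenteredGenotypes(
        values=block.counts - center,
        founder_ids=list(g.founder_ids),
        marker_ids=list(block.marker_ids),
        partition=partition,
    )


def observed_founder_grm(
    g: FounderGenotypes, freqs: LineFrequencies, partition: str
) -> RelationshipMatrix:
    """G0 = Z0 Z0' / S for the requested partition."""
    S = gametic_moments(freqs, partition).S  # validates S > 0
    z = centered_genotypes(g, freqs, partition).values
    vals = (z @ z.T) / S
    vals = 0.5 * (vals + vals.T)
    return RelationshipMatrix(
        values=vals, ids=list(g.founder_ids), partition=partition, kind=KIND_OBSERVED
    )


def blend(
    g0: RelationshipMatrix, e0: RelationshipMatrix, alpha: float = 0.98
) -> RelationshipMatrix:
    """Convex combination α·G0 + (1−α)·E(G0); endpoints are returned bitwise."""
    if g0.ids != e0.ids or g0.partition != e0.partition:
        raise LabelMismatchError("blend requires matching ids and partition")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if alpha == 1.0:
        vals = g0.dense().copy()
    elif alpha == 0.0:
        vals = e0.dense().copy()
    else:
        vals = alpha * g0.dense() + (1.0 - alpha) * e0.dense()
    return RelationshipMatrix(
        values=vals, ids=list(g0.ids), partition=g0.partition, kind=KIND_BLENDED
    )


def rank_report(m: RelationshipMatrix, tol: float = 1e-8) -> int:
    """Number of eigenvalues above tol × (largest eigenvalue)."""
    w = np.linalg.eigvalsh(m.dense())
    top = float(w[-1])
    if top <= 0:
        return 0
    return int(np.sum(w > tol * top))
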