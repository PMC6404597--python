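"""Tabular extension of founder relationships through the pedigree.

Starting from a founder seed matrix (E(G0) for Ã, or observed/blended G0
for a conditional extension), pairwise expected genomic relationships are
propagated to every descendant in founder-first topological order.

Autosomes — for individual k with parents (sire, dam):

    g_kk   = s_sire + s_dam + ½·g(sire, dam)
    g_k,j  = ½·( g(sire, j) + g(dam, j) )          j processed earlier

X chromosome — females:

    g_kk   = s_sire + s_dam + g(sire, dam)
    g_k,j  = g(sire, j) + ½·g(dam, j)

and males (who carry only the maternal X):

    g_kk   = s_dam
    g_k,j  = ½·g(dam, j)

s_parent is the expected self-relationship of the gamete the parent
transmits.  When the seed is an HWE expectation it is s = Σ_ℓ f_ℓ d_ℓ with
f the parent's line composition.  When the seed is the observed G0 the
founder base values come from the actual genotypes (observed heterozygosity
replaces its HWE expectation) and the same recursion
s_k = ½(s_sire + s_dam) (X males: s_k = s_dam) applies; both forms satisfy
it, they differ only in the founder base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LabelMismatchError, NotTwoLinesError
from .founder_genotypes import FounderGenotypes
from .moments import GameticMoments, LineFrequencies
from .observed_grm import KIND_EXPECTED_PEDIGREE, RelationshipMatrix
from .pedigree import AUTOSOMAL, X, LineComposition, Pedigree, Sex


@dataclass
class GameteSelf:
    """Expected self-relationship of each individual's transmitted gamete."""

    ids: list[str]
    partition: str
    values: np.ndarray = field(repr=False)


def gamete_self(
    ped: Pedigree, mom: GameticMoments, lc: LineComposition
) -> GameteSelf:
    """s = Σ_ℓ f_ℓ d_ℓ from line composition (HWE-expectation form)."""
    f = lc.context(mom.partition)
    # align composition columns with the moments' line order
    order = [lc.lines.index(lab) for lab in mom.lines]
    vals = f[:, order] @ mom.d
    return GameteSelf(ids=list(ped.ids), partition=mom.partition, values=vals)


def gamete_self_observed(
    ped: Pedigree,
    g: FounderGenotypes,
    freqs: LineFrequencies,
    mom: GameticMoments,
) -> GameteSelf:
    """Gamete self-relationships conditional on the observed founder genotypes.

    A founder with gene count c at locus i transmits the counted allele with
    probability c/ploidy, so the transmitted-gamete moment per locus is
    (c/2)·(1−p̄)² + (1−c/2)·p̄² for diploid carriers and (c−p̄)² for
    hemizygous males.  Descendants follow s_k = ½(s_sire + s_dam); X males
    pass on their maternal X, s_k = s_dam.
    """
    partition = mom.partition
    block = g.block(partition)
    pbar = freqs.block(partition).pbar
    n = len(ped)
    s = np.zeros(n)
    founder_pos = {fid: k for k, fid in enumerate(g.founder_ids)}
    for i, rec in enumerate(ped.records):
        if rec.is_founder:
            c = block.counts[founder_pos[rec.id]]
            if partition == X and rec.sex is Sex.MALE:
                per_locus = (c - pbar) ** 2
            else:
                half = c / 2.0
                per_locus = half * (1.0 - pbar) ** 2 + (1.0 - half) * pbar**2
            s[i] = per_locus.sum() / mom.S
        else:
            si, di = ped.sire_idx[i], ped.dam_idx[i]
            if partition == X and rec.sex is Sex.MALE:
                s[i] = s[di]
            else:
                s[i] = 0.5 * (s[si] + s[di])
    return GameteSelf(ids=list(ped.ids), partition=partition, values=s)


def _allocate(n: int, store):
    if store is None:
        return np.zeros((n, n)), None
    import h5py

    fh = h5py.File(store, "w")
    chunk = min(n, 512)
    dset = fh.create_dataset(
        "matrix", shape=(n, n), dtype="f8", chunks=(chunk, n), fillvalue=0.0
    )
    return dset, fh


def _seed_founder_block(
    G, ped: Pedigree, seed: RelationshipMatrix, partition: str
) -> None:
    if set(seed.ids) != set(ped.founder_ids):
        raise LabelMismatchError(
            "seed matrix ids do not match the pedigree founders"
        )
    if seed.partition != partition:
        raise LabelMismatchError(
            f"seed matrix is for partition {seed.partition!r}, requested {partition!r}"
        )
    block = seed.submatrix(ped.founder_ids).values
    F = len(ped.founder_ids)
    G[:F, :F] = block


def _extend(
    ped: Pedigree,
    seed: RelationshipMatrix,
    s: np.ndarray,
    partition: str,
    store,
) -> RelationshipMatrix:
    n = len(ped)
    G, fh = _allocate(n, store)
    _seed_founder_block(G, ped, seed, partition)
    F = ped.n_founders
    for k in range(F, n):
        a, b = int(ped.sire_idx[k]), int(ped.dam_idx[k])
        row_a = np.asarray(G[a, :k])
        row_b = np.asarray(G[b, :k])
        if partition == AUTOSOMAL:
            row = 0.5 * (row_a + row_b)
            diag = s[a] + s[b] + 0.5 * row_a[b]
        elif ped.records[k].sex is Sex.FEMALE:
            row = row_a + 0.5 * row_b
            diag = s[a] + s[b] + row_a[b]
        else:
            row = 0.5 * row_b
            diag = s[b]
        G[k, :k] = row
        G[:k, k] = row
        G[k, k] = diag
    m = RelationshipMatrix(
        values=G, ids=list(ped.ids), partition=partition, kind=KIND_EXPECTED_PEDIGREE
    )
    if fh is not None:
        m._h5file = fh  # keep the handle alive with the matrix
    return m


def extend_autosomal(
    ped: Pedigree,
    seed: RelationshipMatrix,
    mom: GameticMoments,
    lc: LineComposition,
    gamete_self_values: GameteSelf | None = None,
    store=None,
) -> RelationshipMatrix:
    """Extend a founder seed matrix over the full pedigree (autosomes).

    ``store`` may name an HDF5 path for on-disk chunked output (full-size
    pedigrees); by default the matrix is dense in memory.
    """
    if mom.partition != AUTOSOMAL:
        raise LabelMismatchError("extend_autosomal requires autosomal moments")
    s = (gamete_self_values or gamete_self(ped, mom, lc)).values
    return _extend(ped, seed, s, AUTOSOMAL, store)


def extend_x(
    ped: Pedigree,
    seed: RelationshipMatrix,
    mom: GameticMoments,
    lc: LineComposition,
    gamete_self_values: GameteSelf | None = None,
    store=None,
) -> RelationshipMatrix:
    """Extend a founder seed matrix over the full pedigree (X chromosome)."""
    if mom.partition != X:
        raise LabelMismatchError("extend_x requires X moments")
    s = (gamete_self_values or gamete_self(ped, mom, lc)).values
    return _extend(ped, seed, s, X, store)


@dataclass
class F2ReferenceSummary:
    """Expected relationship structure of an infinitely large F2."""

    mean_self: float
    mean_pairwise: float
    segregation_proportion: float


def f2_reference_summary(mom: GameticMoments) -> F2ReferenceSummary:
    """Population moments of an infinite two-line F2.

    An F2 individual carries two A gametes with probability ¼, two B with ¼
    and one of each with ½.  The mean self-relationship enumerates to
    d_A + d_B (= 1 under uniform weights); the mean pairwise covariance is
    the (1,2,1)/4 × (1,2,1)/4 weighted average over the nine composition
    pairs and vanishes because r_AA = r_BB = −r_AB.  The proportion of
    genetic variance arising as segregation variance is
    1 − (d_A + d_B + 2r_AB) = −2r_AB.
    """
    if len(mom.lines) != 2:
        raise NotTwoLinesError(
            "the F2 reference summary is defined for a two-line cross only"
        )
    dA, dB = float(mom.d[0]), float(mom.d[1])
    rAA, rBB = float(mom.r[0, 0]), float(mom.r[1, 1])
    rAB = float(mom.r[0, 1])
    mean_self = (
        0.25 * (2 * dA + 2 * rAA)
        + 0.25 * (2 * dB + 2 * rBB)
        + 0.5 * (dA + dB + 2 * rAB)
    )
    # HWE-weighted nine-case average: compositions AA/AB/BB with weights
    # (1,2,1)/4 per individual; a pair's covariance sums r over gamete pairs.
    r = {("A", "A"): rAA, ("B", "B"): rBB, ("A", "B"): rAB, ("B", "A"): rAB}
    comps = [(("A", "A"), 0.25), (("A", "B"), 0.5), (("B", "B"), 0.25)]
    mean_pairwise = 0.0
    for (c1, w1) in comps:
        for (c2, w2) in comps:
            cov = sum(r[(x, y)] for x in c1 for y in c2)
            mean_pairwise += w1 * w2 * cov
    return F2ReferenceSummary(
        mean_self=mean_self,
        mean_pairwise=mean_pairwise,
        segregation_proportion=-2.0 * rAB,
    )
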