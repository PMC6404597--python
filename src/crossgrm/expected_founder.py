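"""Expected founder relationship matrix E(G0) from gametic moments.

Under line-specific Hardy–Weinberg sampling of founder alleles, the
expectation of every G0 entry is a simple function of the gamete moments.
Autosomes (ℓ, m line indices):

    self:          ω_ℓ  = 2d_ℓ + 2r_ℓℓ
    same line:     ω_ℓℓ = 4r_ℓℓ
    different:     ω_ℓm = 4r_ℓm

X chromosome: an individual carries n independent gametes from its own
line (n = 2 for females, 1 for hemizygous males), so between individuals
the expectation sums the gamete relationship over all gamete pairs,

    ω_ij = n_i · n_j · r_ℓm      (male–male r_ℓm, male–female 2r_ℓm,
                                  female–female 4r_ℓm)

and the self-relationship is n·d_ℓ + n(n−1)·r_ℓℓ (male d_ℓ, female
2d_ℓ + 2r_ℓℓ).  The two-line case enumerates to the classical eight X
relationship types; the (ℓ, m)-indexed forms extend them to any number of
lines.
"""

from __future__ import annotations

import numpy as np

from .errors import LabelMismatchError
from .moments import GameticMoments
from .observed_grm import KIND_EXPECTED_FOUNDER, RelationshipMatrix
from .pedigree import AUTOSOMAL, X, Pedigree, Sex


def expected_founder_matrix(
    ped: Pedigree, mom: GameticMoments, partition: str
) -> RelationshipMatrix:
    """E(G0) over the pedigree founders, ordered as ``ped.founder_ids``."""
    if mom.partition != partition:
        raise LabelMismatchError(
            f"moments are for partition {mom.partition!r}, requested {partition!r}"
        )
    line_pos = {lab: i for i, lab in enumerate(mom.lines)}
    lines = np.array([line_pos[lab] for lab in ped.founder_lines()])
    male = np.array([s is Sex.MALE for s in ped.founder_sexes()])
    d, r = mom.d, mom.r

    rij = r[np.ix_(lines, lines)]
    if partition == AUTOSOMAL:
        vals = 4.0 * rij
        np.fill_diagonal(vals, 2.0 * d[lines] + 2.0 * r[lines, lines])
    elif partition == X:
        rii = r[lines, lines]
        ncopies = np.where(male, 1.0, 2.0)
        vals = np.outer(ncopies, ncopies) * rij
        diag = ncopies * d[lines] + ncopies * (ncopies - 1.0) * rii
        np.fill_diagonal(vals, diag)
    else:
        raise ValueError(f"unknown partition {partition!r}")

    vals = 0.5 * (vals + vals.T)
    return RelationshipMatrix(
        values=vals,
        ids=list(ped.founder_ids),
        partition=partition,
        kind=KIND_EXPECTED_FOUNDER,
    )
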