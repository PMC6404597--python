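"""Line allele frequencies, composite frequencies and gametic moments.

For L founder lines with weights w (default uniform), the composite
frequency of marker i is p̄_i = Σ_ℓ w_ℓ p_iℓ — the frequency expected in
the intercross at equilibrium under the assumed line contributions.  The
relationship scale is S = 2·Σ_i p̄_i(1 − p̄_i), twice the expected
heterozygosity of the equilibrium population.

The *gametic moments* are, per partition,

    d_ℓ  = (1/S)·Σ_i [ p_iℓ(1 − p_iℓ) + (p_iℓ − p̄_i)² ]
    r_ℓm = (1/S)·Σ_i (p_iℓ − p̄_i)(p_im − p̄_i)

d_ℓ is the expected self-relationship of a gamete sampled from line ℓ at
its line frequencies; r_ℓm the expected relationship between two gametes
from lines ℓ and m.  For two lines with uniform weights, d_A + d_B = 1 and
r_AA = r_BB = −r_AB hold identically, and generally Σ_ℓ w_ℓ r_ℓm = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import WeightError, ZeroHeterozygosityError
from .founder_genotypes import FounderGenotypes
from .pedigree import AUTOSOMAL, X, Sex


@dataclass
class FreqBlock:
    """Line allele frequencies of one partition."""

    marker_ids: list[str]
    p: np.ndarray = field(repr=False)  # lines × markers
    pbar: np.ndarray = field(repr=False)  # markers

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class LineFrequencies:
    lines: list[str]
    weights: np.ndarray
    x_weights: np.ndarray
    autosomal: FreqBlock
    x: FreqBlock

    def block(self, partition: str) -> FreqBlock:
        if partition == AUTOSOMAL:
            return self.autosomal
        if partition == X:
            return self.x
        raise ValueError(f"unknown partition {partition!r}")

    def weights_for(self, partition: str) -> np.ndarray:
        return self.weights if partition == AUTOSOMAL else self.x_weights


@dataclass
class GameticMoments:
    """Scaling factor S and gamete moments d, r of one partition."""

    partition: str
    lines: list[str]
    S: float
    d: np.ndarray
    r: np.ndarray = field(repr=False)


def _check_weights(w: np.ndarray, L: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (L,):
        raise WeightError(f"expected {L} line weights, got shape {w.shape}")
    if (w < 0).any():
        raise WeightError("line weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-12:
        raise WeightError(f"line weights must sum to 1 (got {w.sum()!r})")
    return w


def compute_line_frequencies(
    g: FounderGenotypes,
    weights=None,
    x_weights=None,
) -> LineFrequencies:
    """Counted-allele frequencies per line and composite frequencies p̄.

    On the X chromosome males contribute one allele and females two.  The
    X composite frequency uses the same line weights as the autosomes by
    default (equal line contributions through both sexes); pass
    ``x_weights`` to reflect realized contributions instead.
    """
    lines = list(dict.fromkeys(g.lines))
    L = len(lines)
    w = np.full(L, 1.0 / L) if weights is None else _check_weights(weights, L)
    wx = w if x_weights is None else _check_weights(x_weights, L)

    blocks = {}
    for part in (AUTOSOMAL, X):
        block = g.block(part)
        ploidy = g.ploidy(part)
        M = block.n_markers
        p = np.zeros((L, M))
        for li, lab in enumerate(lines):
            sel = np.array([l == lab for l in g.lines])
            if not sel.any():
                raise WeightError(f"line {lab!r} has no founders")
            denom = ploidy[sel].sum()
            if M:
                p[li] = block.counts[sel].sum(axis=0) / denom
        weights_part = w if part == AUTOSOMAL else wx
        pbar = weights_part @ p if M else np.zeros(0)
        blocks[part] = FreqBlock(marker_ids=list(block.marker_ids), p=p, pbar=pbar)
    return LineFrequencies(
        lines=lines, weights=w, x_weights=wx,
        autosomal=blocks[AUTOSOMAL], x=blocks[X],
    )


def scaling_factor(freqs: LineFrequencies, partition: str) -> float:
    """S = 2·Σ_i p̄_i(1 − p̄_i) for the partition's loaded marker set."""
    pbar = freqs.block(partition).pbar
    return float(2.0 * np.sum(pbar * (1.0 - pbar)))


def gametic_moments(freqs: LineFrequencies, partition: str) -> GameticMoments:
    """Compute S and the d/r gamete moments over the partition's loci.

    Raises
    ------
    ZeroHeterozygosityError
        If the partition has no loci or S = 0 (all composite frequencies at
        0 or 1); no relationship scale exists then.
    """
    block = freqs.block(partition)
    if block.n_markers == 0:
        raise ZeroHeterozygosityError(f"partition {partition!r} has no loci")
    S = scaling_factor(freqs, partition)
    if S <= 0.0:
        raise ZeroHeterozygosityError(
            f"scaling factor S = 0 for partition {partition!r}: every composite "
            "frequency is 0 or 1"
        )
    p = block.p
    dev = p - block.pbar[None, :]
    d = (np.sum(p * (1.0 - p), axis=1) + np.sum(dev * dev, axis=1)) / S
    r = (dev @ dev.T) / S
    r = 0.5 * (r + r.T)
    return GameticMoments(partition=partition, lines=list(freqs.lines), S=S, d=d, r=r)
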