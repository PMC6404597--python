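"""Gene-drop Monte Carlo: the simulation oracle for expected relationships.

Founder alleles are transmitted through the pedigree by Mendelian sampling
at independent loci (no linkage, matching the analytic expectations): each
autosomal offspring allele is drawn uniformly from the parent's two;
daughters receive the sire's single X plus one maternal X allele; sons
receive a maternal X allele only.

Per replicate the realized genomic relationship matrix of all individuals
is computed with the composite-frequency centering (2p̄, or p̄ for
hemizygous males) and averaged.  Founders either keep their observed
genotypes (conditional oracle for the G0-seeded extension) or are resampled
from line-specific Hardy–Weinberg proportions each replicate (oracle for
E(G0) and Ã).

Each replicate draws from its own `numpy` SeedSequence stream
(seed, replicate-index), so results are bitwise reproducible and replicate
subsets are stable under re-partitioning of the batch loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LabelMismatchError
from .founder_genotypes import FounderGenotypes
from .moments import LineFrequencies, gametic_moments
from .pedigree import AUTOSOMAL, X, Pedigree, Sex

OBSERVED = "observed"
HWE_SAMPLED = "hwe-sampled"


@dataclass
class GeneDropConfig:
    replicates: int = 2000
    seed: int = 0
    founder_source: str = OBSERVED
    partition: str = AUTOSOMAL
    loci: np.ndarray | None = None  # optional subset of marker indices
    batch_size: int = 100

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.founder_source not in (OBSERVED, HWE_SAMPLED):
            raise ValueError(f"unknown founder_source {self.founder_source!r}")
        if self.partition not in (AUTOSOMAL, X):
            raise ValueError(f"unknown partition {self.partition!r}")


@dataclass
class GeneDropResult:
    """Replicate mean relationship matrix with elementwise Monte-Carlo SEs."""

    mean: np.ndarray = field(repr=False)
    se: np.ndarray = field(repr=False)
    replicates: int
    ids: list[str]
    partition: str
    founder_source: str


def _founder_setup(ped: Pedigree, g: FounderGenotypes, freqs: LineFrequencies,
                   partition: str, loci):
    """Founder count matrix in pedigree-founder order plus sampling frequencies."""
    if g.founder_ids != ped.founder_ids:
        pos = {fid: i for i, fid in enumerate(g.founder_ids)}
        try:
            order = [pos[fid] for fid in ped.founder_ids]
        except KeyError as exc:
            raise LabelMismatchError(
                f"founder {exc.args[0]!r} missing from genotypes"
            ) from exc
    else:
        order = list(range(len(g.founder_ids)))
    counts = g.block(partition).counts[order]
    fblock = freqs.block(partition)
    line_pos = {lab: i for i, lab in enumerate(freqs.lines)}
    p_founder = fblock.p[[line_pos[lab] for lab in ped.founder_lines()]]
    pbar = fblock.pbar
    if loci is not None:
        counts = counts[:, loci]
        p_founder = p_founder[:, loci]
        pbar = pbar[loci]
    return counts, p_founder, pbar


def _sample_founders(rng, p_founder, male, partition):
    """HWE draw of founder gene counts at line frequencies."""
    u = rng.random((2,) + p_founder.shape)
    counts = (u[0] < p_founder).astype(np.float64) + (u[1] < p_founder)
    if partition == X:
        counts[male] = (u[0][male] < p_founder[male]).astype(np.float64)
    return counts


def drop_once(ped: Pedigree, g: FounderGenotypes, partition: str, rng,
              freqs: LineFrequencies | None = None,
              founder_source: str = OBSERVED,
              loci=None) -> np.ndarray:
    """One gene-drop realization: gene counts for every individual.

    Returns an (n_individuals × n_loci) array in pedigree order.
    """
    if freqs is None and founder_source == HWE_SAMPLED:
        raise ValueError("HWE sampling requires line frequencies")
    counts0, p_founder, _ = _founder_setup(
        ped, g, freqs or _freqs_placeholder(g), partition, loci
    )
    male = np.array([s is Sex.MALE for s in ped.founder_sexes()])
    if founder_source == HWE_SAMPLED:
        founder_counts = _sample_founders(rng, p_founder, male, partition)
    else:
        founder_counts = counts0
    n, M = len(ped), founder_counts.shape[1]
    counts = np.zeros((n, M))
    counts[: ped.n_founders] = founder_counts
    for k in range(ped.n_founders, n):
        a, b = int(ped.sire_idx[k]), int(ped.dam_idx[k])
        if partition == AUTOSOMAL:
            t_s = rng.random(M) < counts[a] / 2.0
            t_d = rng.random(M) < counts[b] / 2.0
            counts[k] = t_s.astype(np.float64) + t_d
        elif ped.records[k].sex is Sex.FEMALE:
            t_d = rng.random(M) < counts[b] / 2.0
            counts[k] = counts[a] + t_d  # sire's single X passes unchanged
        else:
            counts[k] = rng.random(M) < counts[b] / 2.0
    return counts


def _freqs_placeholder(g):
    from .moments import compute_line_frequencies

    return compute_line_frequencies(g)


def expected_grm_by_genedrop(
    ped: Pedigree,
    g: FounderGenotypes,
    freqs: LineFrequencies,
    cfg: GeneDropConfig,
) -> GeneDropResult:
    """Mean realized GRM over replicates, with elementwise standard errors.

    The centering (2p̄; p̄ for X males) and the scale S come from ``freqs``
    so oracle comparisons use exactly the analytic marker set and scale.
    """
    partition = cfg.partition
    counts0, p_founder, pbar = _founder_setup(ped, g, freqs, partition, cfg.loci)
    S = gametic_moments(freqs, partition).S
    n, M = len(ped), counts0.shape[1]
    F = ped.n_founders
    male_f = np.array([s is Sex.MALE for s in ped.founder_sexes()])
    male_all = np.array([s is Sex.MALE for s in ped.sexes])
    female_child = np.array(
        [ped.records[k].sex is Sex.FEMALE for k in range(F, n)]
    )
    sire = ped.sire_idx[F:]
    dam = ped.dam_idx[F:]

    # centering multiplier of pbar per individual: 2 everywhere, 1 on male X
    mult = np.full(n, 2.0)
    if partition == X:
        mult[male_all] = 1.0

    # accumulate around the first replicate's matrix: the shift cancels in
    # the variance and avoids catastrophic cancellation (constant entries,
    # e.g. a fixed founder block, get exactly zero SE)
    shift = None
    acc = np.zeros((n, n))
    acc2 = np.zeros((n, n))
    done = 0
    while done < cfg.replicates:
        B = min(cfg.batch_size, cfg.replicates - done)
        counts = np.zeros((B, n, M))
        U = np.empty((B, n - F, 2, M))
        for r in range(B):
            # one independent stream per replicate: (seed, replicate index)
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, done + r]))
            if cfg.founder_source == HWE_SAMPLED:
                counts[r, :F] = _sample_founders(rng, p_founder, male_f, partition)
            else:
                counts[r, :F] = counts0
            U[r] = rng.random((n - F, 2, M))
        for j in range(n - F):
            k = F + j
            a, b = int(sire[j]), int(dam[j])
            if partition == AUTOSOMAL:
                t_s = U[:, j, 0, :] < counts[:, a, :] / 2.0
                t_d = U[:, j, 1, :] < counts[:, b, :] / 2.0
                counts[:, k, :] = t_s.astype(np.float64) + t_d
            elif female_child[j]:
                t_d = U[:, j, 1, :] < counts[:, b, :] / 2.0
                counts[:, k, :] = counts[:, a, :] + t_d
            else:
                counts[:, k, :] = U[:, j, 1, :] < counts[:, b, :] / 2.0
        Z = counts - mult[None, :, None] * pbar[None, None, :]
        Gb = Z @ Z.transpose(0, 2, 1) / S
        if shift is None:
            shift = Gb[0].copy()
        Gb -= shift[None, :, :]
        acc += Gb.sum(axis=0)
        acc2 += (Gb * Gb).sum(axis=0)
        done += B

    R = cfg.replicates
    mean_c = acc / R
    mean = mean_c + shift
    if R > 1:
        var = (acc2 - R * mean_c * mean_c) / (R - 1)
        var = np.maximum(var, 0.0)
        se = np.sqrt(var / R)
    else:
        se = np.zeros_like(mean)
    return GeneDropResult(
        mean=0.5 * (mean + mean.T),
        se=0.5 * (se + se.T),
        replicates=R,
        ids=list(ped.ids),
        partition=partition,
        founder_source=cfg.founder_source,
    )
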