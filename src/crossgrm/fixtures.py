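"""Deterministic synthetic founder lines and intercross pedigrees.

The generator emulates the structure of a laboratory line cross: L founder
lines with line-specific allele-frequency spectra (including fully inbred
lines fixed for opposite alleles), founder genotypes drawn in line-specific
Hardy–Weinberg proportions (hemizygous single-allele males on X), and
multi-generation intercross pedigrees — F1 from crossing the lines,
followed by full-sib rotation or random inter-mating (an advanced
intercross line).

``make_fixture`` returns the pedigree, the founder genotypes and the
*generating* line frequencies, so tests can separate sampling error from
code error.  All randomness flows through a single seeded generator;
identical specs reproduce identical fixtures bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FixtureError
from .founder_genotypes import FounderGenotypes, MarkerBlock
from .moments import FreqBlock, LineFrequencies
from .pedigree import AUTOSOMAL, X, LineComposition, Pedigree, PedigreeRecord, Sex

FIXED_OPPOSITE = "fixed-opposite"


@dataclass
class LineSpec:
    """One founder line: label, founder counts by sex and a frequency model.

    ``freq`` is ``"fixed-opposite"`` (two lines fixed for alternative
    alleles), ``("uniform",)``, ``("beta", a, b)`` or
    ``("vector", {"autosomal": array, "x": array})``.
    """

    label: str
    n_males: int
    n_females: int
    freq: object = ("uniform",)


@dataclass
class FixtureSpec:
    lines: list[LineSpec]
    n_autosomal: int = 100
    n_x: int = 20
    template: str = "f2"  # {"trio", "f2", "ail"}
    generations: int = 2
    litter_size: int = 8
    mating: str = "full-sib"  # {"full-sib", "random"}
    seed: int = 0


def two_inbred_lines(
    n_males_a: int = 4,
    n_females_b: int = 4,
    n_autosomal: int = 100,
    n_x: int = 20,
    **kwargs,
) -> FixtureSpec:
    """Canonical cross of two fully inbred lines fixed for opposite alleles:
    line-A males mated to line-B females (the classic inbred × selected
    design with hemizygous-male X asymmetry)."""
    return FixtureSpec(
        lines=[
            LineSpec("A", n_males_a, 0, FIXED_OPPOSITE),
            LineSpec("B", 0, n_females_b, FIXED_OPPOSITE),
        ],
        n_autosomal=n_autosomal,
        n_x=n_x,
        **kwargs,
    )


def _line_frequencies(spec: FixtureSpec, rng) -> dict[str, np.ndarray]:
    sizes = {AUTOSOMAL: spec.n_autosomal, X: spec.n_x}
    fixed = [ls for ls in spec.lines if ls.freq == FIXED_OPPOSITE]
    if fixed and len(spec.lines) != 2:
        raise FixtureError("fixed-opposite frequencies require exactly two lines")
    p: dict[str, np.ndarray] = {}
    for part, M in sizes.items():
        rows = []
        for li, ls in enumerate(spec.lines):
            if ls.freq == FIXED_OPPOSITE:
                rows.append(np.full(M, 1.0 if li == 0 else 0.0))
            elif isinstance(ls.freq, tuple) and ls.freq[0] == "uniform":
                rows.append(rng.uniform(size=M))
            elif isinstance(ls.freq, tuple) and ls.freq[0] == "beta":
                rows.append(rng.beta(ls.freq[1], ls.freq[2], size=M))
            elif isinstance(ls.freq, tuple) and ls.freq[0] == "vector":
                vec = np.asarray(ls.freq[1][part], dtype=float)
                if vec.shape != (M,):
                    raise FixtureError(
                        f"supplied {part} frequency vector for line {ls.label!r} "
                        f"has shape {vec.shape}, expected ({M},)"
                    )
                rows.append(vec)
            else:
                raise FixtureError(f"unknown frequency model {ls.freq!r}")
        p[part] = np.stack(rows) if rows else np.zeros((0, M))
    return p


def _founder_records(spec: FixtureSpec) -> list[PedigreeRecord]:
    recs = []
    for ls in spec.lines:
        for i in range(ls.n_males):
            recs.append(PedigreeRecord(f"{ls.label}M{i+1}", None, None, Sex.MALE, ls.label, 0))
        for i in range(ls.n_females):
            recs.append(PedigreeRecord(f"{ls.label}F{i+1}", None, None, Sex.FEMALE, ls.label, 0))
    return recs


def _cross_pairs(founders: list[PedigreeRecord]) -> list[tuple[str, str]]:
    """Pair founder males with founder females, preferring cross-line pairs."""
    males = [r for r in founders if r.sex is Sex.MALE]
    females = [r for r in founders if r.sex is Sex.FEMALE]
    if not males or not females:
        raise FixtureError("the cross template needs founder males and females")
    pairs: list[tuple[str, str]] = []
    used_f: set[str] = set()
    for m in males:
        other = [f for f in females if f.line != m.line and f.id not in used_f]
        same = [f for f in females if f.line == m.line and f.id not in used_f]
        pick = (other or same)
        if not pick:
            break
        pairs.append((m.id, pick[0].id))
        used_f.add(pick[0].id)
    if not any(
        next(r for r in founders if r.id == s).line
        != next(r for r in founders if r.id == d).line
        for s, d in pairs
    ):
        raise FixtureError("no cross-line founder pair could be formed")
    return pairs


def _litter_sexes(n: int) -> list[Sex]:
    # alternate so every litter of >= 2 contains both sexes
    return [Sex.MALE if i % 2 == 0 else Sex.FEMALE for i in range(n)]


def _build_pedigree(spec: FixtureSpec, rng) -> Pedigree:
    founders = _founder_records(spec)
    if spec.template == "trio":
        pairs = _cross_pairs(founders)
        sire, dam = pairs[0]
        child = PedigreeRecord("C1", sire, dam, Sex.FEMALE, None, 1)
        return Pedigree(founders + [child])
    if spec.template not in ("f2", "ail"):
        raise FixtureError(f"unknown pedigree template {spec.template!r}")
    generations = 2 if spec.template == "f2" else spec.generations
    if generations < 1:
        raise FixtureError("need at least one crossbred generation")
    if spec.litter_size < 2 and generations > 1:
        raise FixtureError("litters must contain both sexes (litter_size >= 2)")
    recs = list(founders)
    # F1: one family per founder pair
    families: list[list[PedigreeRecord]] = []
    for fam, (sire, dam) in enumerate(_cross_pairs(founders), start=1):
        litter = [
            PedigreeRecord(f"G1P{fam}I{i+1}", sire, dam, sex, None, 1)
            for i, sex in enumerate(_litter_sexes(spec.litter_size))
        ]
        families.append(litter)
        recs.extend(litter)
    for g in range(2, generations + 1):
        new_families = []
        if spec.mating == "full-sib":
            for fam, litter in enumerate(families, start=1):
                males = [r for r in litter if r.sex is Sex.MALE]
                females = [r for r in litter if r.sex is Sex.FEMALE]
                sire = males[(g - 2) % len(males)]
                dam = females[(g - 1) % len(females)]
                new_families.append((fam, sire.id, dam.id))
        elif spec.mating == "random":
            prev = [r for fam in families for r in fam]
            males = [r for r in prev if r.sex is Sex.MALE]
            females = [r for r in prev if r.sex is Sex.FEMALE]
            for fam in range(1, len(families) + 1):
                sire = males[rng.integers(len(males))]
                dam = females[rng.integers(len(females))]
                new_families.append((fam, sire.id, dam.id))
        else:
            raise FixtureError(f"unknown mating scheme {spec.mating!r}")
        families = []
        for fam, sire_id, dam_id in new_families:
            litter = [
                PedigreeRecord(f"G{g}P{fam}I{i+1}", sire_id, dam_id, sex, None, g)
                for i, sex in enumerate(_litter_sexes(spec.litter_size))
            ]
            families.append(litter)
            recs.extend(litter)
    return Pedigree(recs)


def _sample_founder_genotypes(
    ped: Pedigree, spec: FixtureSpec, p: dict[str, np.ndarray], rng
) -> FounderGenotypes:
    line_pos = {ls.label: i for i, ls in enumerate(spec.lines)}
    sexes = ped.founder_sexes()
    lines = ped.founder_lines()
    blocks = {}
    for part, chrom in ((AUTOSOMAL, "1"), (X, "X")):
        M = p[part].shape[1]
        counts = np.zeros((len(ped.founder_ids), M))
        for fi in range(len(ped.founder_ids)):
            pf = p[part][line_pos[lines[fi]]]
            if part == X and sexes[fi] is Sex.MALE:
                counts[fi] = rng.random(M) < pf
            else:
                counts[fi] = (rng.random(M) < pf).astype(float) + (rng.random(M) < pf)
        prefix = "AUT" if part == AUTOSOMAL else "XMK"
        blocks[part] = MarkerBlock(
            marker_ids=[f"{prefix}{i+1:04d}" for i in range(M)],
            chroms=[chrom] * M,
            counts=counts,
        )
    g = FounderGenotypes(
        founder_ids=list(ped.founder_ids),
        sexes=sexes,
        lines=lines,
        autosomal=blocks[AUTOSOMAL],
        x=blocks[X],
    )
    g.validate()
    return g


def make_fixture(
    spec: FixtureSpec,
) -> tuple[Pedigree, FounderGenotypes, LineFrequencies]:
    """Generate a self-consistent pedigree, founder genotypes and the
    generating line frequencies (uniform line weights)."""
    rng = np.random.default_rng(spec.seed)
    p = _line_frequencies(spec, rng)
    ped = _build_pedigree(spec, rng)
    g = _sample_founder_genotypes(ped, spec, p, rng)
    L = len(spec.lines)
    w = np.full(L, 1.0 / L)
    truth = LineFrequencies(
        lines=[ls.label for ls in spec.lines],
        weights=w,
        x_weights=w,
        autosomal=FreqBlock(
            marker_ids=list(g.autosomal.marker_ids),
            p=p[AUTOSOMAL],
            pbar=w @ p[AUTOSOMAL] if p[AUTOSOMAL].size else np.zeros(0),
        ),
        x=FreqBlock(
            marker_ids=list(g.x.marker_ids),
            p=p[X],
            pbar=w @ p[X] if p[X].size else np.zeros(0),
        ),
    )
    return ped, g, truth
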