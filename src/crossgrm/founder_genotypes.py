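"""Founder genotypes: loading, gene-count encoding and marker classification.

Genotypes of the founders are reduced to counts of a *counted allele* per
marker.  Autosomal counts are 0/1/2; on the X chromosome females are diploid
(0/1/2) while hemizygous males carry a single allele (0/1) — a homozygous
diploid call for a male X marker (e.g. ``A/A``) collapses to its single-copy
count.  Markers labelled ``X`` form the X partition; pseudoautosomal markers
(labels ``XY`` or ``PAR``) behave like autosomes and are placed in the
autosomal partition.

Loci monomorphic across *all* founders carry no relationship information
(their composite frequency is 0 or 1, contributing nothing to any sum) and
are dropped at load time with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    GenotypeError,
    MaleHeterozygousXError,
    MissingFounderGenotypeError,
    MissingGenotypeError,
)
from .pedigree import AUTOSOMAL, X, Pedigree, Sex

logger = logging.getLogger(__name__)

_MISSING_ALLELES = {"0", ".", "", "N"}

# pseudoautosomal labels treated as autosomal; everything else non-"X" too
_X_LABELS = {"x"}


def _partition_of(chrom: str) -> str:
    return X if chrom.strip().lower() in _X_LABELS else AUTOSOMAL


@dataclass
class MarkerBlock:
    """Markers of one partition: ids, chromosome labels and the count matrix.

    ``counts`` is founders × markers, float64 (fractional values can occur
    only after line-mean imputation).
    """

    marker_ids: list[str]
    chroms: list[str]
    counts: np.ndarray = field(repr=False)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class FounderGenotypes:
    """Gene-count matrix of all pedigree founders, split by partition."""

    founder_ids: list[str]
    sexes: list[Sex]
    lines: list[str]
    autosomal: MarkerBlock
    x: MarkerBlock
    n_dropped_monomorphic: dict[str, int] = field(default_factory=dict)

    def block(self, partition: str) -> MarkerBlock:
        if partition == AUTOSOMAL:
            return self.autosomal
        if partition == X:
            return self.x
        raise ValueError(f"unknown partition {partition!r}")

    def ploidy(self, partition: str) -> np.ndarray:
        """Allele copies per founder: 2 everywhere except male X (1)."""
        if partition == AUTOSOMAL:
            return np.full(len(self.founder_ids), 2.0)
        return np.where([s is Sex.MALE for s in self.sexes], 1.0, 2.0)

    def validate(self) -> None:
        male = np.array([s is Sex.MALE for s in self.sexes])
        cx = self.x.counts
        if cx.size and male.any():
            bad = (cx[male] < 0) | (cx[male] > 1)
            if bad.any():
                raise GenotypeError("male X gene counts must lie in [0, 1]")
        for block in (self.autosomal, self.x):
            if block.counts.size and (
                (block.counts < 0).any() or (block.counts > 2).any()
            ):
                raise GenotypeError("gene counts must lie in [0, 2]")
            if np.isnan(block.counts).any():
                raise MissingGenotypeError("gene-count matrix contains missing values")


@dataclass
class ClassCounts:
    """Marker classification counts for one partition."""

    all_founders: int
    within_line: dict[str, int]
    line_specific: int


@dataclass
class MarkerClassification:
    autosomal: ClassCounts
    x: ClassCounts

    def block(self, partition: str) -> ClassCounts:
        return self.autosomal if partition == AUTOSOMAL else self.x


def _call_to_count(
    call: str, counted: str, marker: str, founder: str, is_male_x: bool
) -> float:
    """Translate one diploid/hemizygous call into a counted-allele count."""
    alleles = call.replace("|", "/").split("/") if call else []
    alleles = [a.strip() for a in alleles if a.strip()]
    if not alleles or all(a in _MISSING_ALLELES for a in alleles):
        return np.nan
    if is_male_x:
        uniq = set(alleles)
        if len(uniq) > 1:
            raise MaleHeterozygousXError(
                f"male founder {founder!r} has heterozygous X call {call!r} "
                f"at locus {marker!r}"
            )
        return float(alleles[0] == counted)
    if len(alleles) == 1:
        alleles = alleles * 2  # single-letter shorthand for a homozygote
    return float(sum(a == counted for a in alleles))


def _finalize(
    ped: Pedigree,
    marker_ids: list[str],
    chroms: list[str],
    counts: np.ndarray,
    counted_alleles: list[str],
    male_het_x: str,
    impute_missing: str | None,
    het_x_drop: np.ndarray,
) -> FounderGenotypes:
    """Missing-data policy, monomorphic dropping and partition split."""
    founders = ped.founder_ids
    sexes = ped.founder_sexes()
    lines = ped.founder_lines()
    male = np.array([s is Sex.MALE for s in sexes])
    parts = np.array([_partition_of(c) for c in chroms])

    if male_het_x == "drop" and het_x_drop.any():
        keep = ~het_x_drop
        marker_ids = [m for m, k in zip(marker_ids, keep) if k]
        chroms = [c for c, k in zip(chroms, keep) if k]
        counts = counts[:, keep]
        parts = parts[keep]
        logger.info("dropped %d X loci with heterozygous male calls", int(het_x_drop.sum()))

    missing = np.isnan(counts)
    if missing.any():
        if impute_missing is None:
            f_idx, m_idx = np.argwhere(missing)[0]
            raise MissingGenotypeError(
                f"missing genotype for founder {founders[f_idx]!r} at locus "
                f"{marker_ids[m_idx]!r} (pass impute_missing='line-freq' to impute)"
            )
        if impute_missing != "line-freq":
            raise ValueError(f"unknown imputation mode {impute_missing!r}")
        for lab in dict.fromkeys(lines):
            in_line = np.array([l == lab for l in lines])
            sub = counts[in_line]
            with np.errstate(invalid="ignore"):
                line_mean = np.nanmean(sub, axis=0)
            sub = np.where(np.isnan(sub), line_mean[None, :], sub)
            counts[in_line] = sub
        if np.isnan(counts).any():
            raise MissingGenotypeError(
                "imputation failed: some locus is missing in an entire line"
            )

    # drop loci monomorphic across ALL founders (overall frequency 0 or 1)
    ploidy = np.where(male, 1.0, 2.0)
    denom = np.where(parts == X, ploidy[:, None], 2.0).sum(axis=0)
    total = counts.sum(axis=0)
    mono = (total == 0) | (total == denom)
    dropped = {
        AUTOSOMAL: int((mono & (parts == AUTOSOMAL)).sum()),
        X: int((mono & (parts == X)).sum()),
    }
    if mono.any():
        logger.info(
            "dropped %d loci monomorphic across all founders (%d autosomal, %d X)",
            int(mono.sum()), dropped[AUTOSOMAL], dropped[X],
        )
    keep = ~mono
    marker_ids = [m for m, k in zip(marker_ids, keep) if k]
    chroms = [c for c, k in zip(chroms, keep) if k]
    counts = counts[:, keep]
    parts = parts[keep]

    blocks = {}
    for part in (AUTOSOMAL, X):
        sel = parts == part
        blocks[part] = MarkerBlock(
            marker_ids=[m for m, k in zip(marker_ids, sel) if k],
            chroms=[c for c, k in zip(chroms, sel) if k],
            counts=np.ascontiguousarray(counts[:, sel]),
        )
    g = FounderGenotypes(
        founder_ids=list(founders),
        sexes=sexes,
        lines=lines,
        autosomal=blocks[AUTOSOMAL],
        x=blocks[X],
        n_dropped_monomorphic=dropped,
    )
    g.validate()
    return g


def read_founder_genotypes(
    geno_path,
    format: str,
    ped: Pedigree,
    map_path=None,
    male_het_x: str = "error",
    impute_missing: str | None = None,
) -> FounderGenotypes:
    """Read founder genotypes as counted-allele gene counts.

    Parameters
    ----------
    format : {"csv", "ped_map"}
        ``csv``: marker-major dialect with header
        ``marker,chrom,allele1,allele2,<founder ids...>`` and calls like
        ``A/a`` (single letters accepted for hemizygous males).
        ``ped_map``: whitespace PLINK pair; ``map_path`` defaults to the
        ``.map`` next to the ``.ped``.
    male_het_x : {"error", "drop"}
        Heterozygous male X calls abort by default; ``drop`` removes the locus.
    impute_missing : {None, "line-freq"}
        Missing calls abort by default; ``line-freq`` substitutes the line
        mean count.

    The counted allele is the first allele column (CSV) or, for a 4-column
    ``.map``, the first non-missing allele encountered among founders; a
    6-column ``.map`` may list the two alleles explicitly.
    """
    if format == "csv":
        return _read_csv(geno_path, ped, male_het_x, impute_missing)
    if format == "ped_map":
        return _read_ped_map(geno_path, map_path, ped, male_het_x, impute_missing)
    raise ValueError(f"unsupported genotype format {format!r}")


def _count_calls(
    ped: Pedigree,
    marker_ids: list[str],
    chroms: list[str],
    counted: list[str],
    calls: dict[str, list[str]],
    male_het_x: str,
) -> tuple[np.ndarray, np.ndarray]:
    founders = ped.founder_ids
    sexes = ped.founder_sexes()
    for fid in founders:
        if fid not in calls:
            raise MissingFounderGenotypeError(
                f"founder {fid!r} has no row in the genotype file"
            )
    M = len(marker_ids)
    counts = np.empty((len(founders), M))
    het_x_drop = np.zeros(M, dtype=bool)
    for fi, fid in enumerate(founders):
        is_male = sexes[fi] is Sex.MALE
        row = calls[fid]
        for mi in range(M):
            male_x = is_male and _partition_of(chroms[mi]) == X
            try:
                counts[fi, mi] = _call_to_count(
                    row[mi], counted[mi], marker_ids[mi], fid, male_x
                )
            except MaleHeterozygousXError:
                if male_het_x != "drop":
                    raise
                het_x_drop[mi] = True
                counts[fi, mi] = np.nan
    return counts, het_x_drop


def _read_csv(path, ped, male_het_x, impute_missing) -> FounderGenotypes:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    fixed = ["marker", "chrom", "allele1", "allele2"]
    if list(df.columns[:4]) != fixed:
        raise ValueError(f"genotype CSV must start with columns {fixed}")
    marker_ids = df["marker"].tolist()
    chroms = df["chrom"].tolist()
    counted = df["allele1"].tolist()
    calls = {fid: df[fid].tolist() for fid in df.columns[4:]}
    counts, het_x_drop = _count_calls(
        ped, marker_ids, chroms, counted, calls, male_het_x
    )
    return _finalize(
        ped, marker_ids, chroms, counts, counted, male_het_x, impute_missing, het_x_drop
    )


def _read_ped_map(ped_path, map_path, ped, male_het_x, impute_missing) -> FounderGenotypes:
    ped_path = str(ped_path)
    if map_path is None:
        if not ped_path.endswith(".ped"):
            raise ValueError("map_path is required when geno_path has no .ped suffix")
        map_path = ped_path[:-4] + ".map"
    marker_ids, chroms, counted = [], [], []
    explicit_alleles = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chroms.append(parts[0])
            marker_ids.append(parts[1])
            explicit_alleles.append(parts[4] if len(parts) >= 6 else None)
    M = len(marker_ids)
    calls: dict[str, list[str]] = {}
    first_seen: list[str | None] = [None] * M
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * M:
                raise GenotypeError(
                    f".ped row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts)} fields, expected {6 + 2 * M}"
                )
            iid = parts[1]
            geno = parts[6:]
            row = []
            for mi in range(M):
                a1, a2 = geno[2 * mi], geno[2 * mi + 1]
                if a1 in _MISSING_ALLELES or a2 in _MISSING_ALLELES:
                    row.append("")
                else:
                    row.append(f"{a1}/{a2}")
                    if first_seen[mi] is None:
                        first_seen[mi] = a1
            calls[iid] = row
    for mi in range(M):
        counted.append(explicit_alleles[mi] or first_seen[mi] or "?")
    counts, het_x_drop = _count_calls(
        ped, marker_ids, chroms, counted, calls, male_het_x
    )
    return _finalize(
        ped, marker_ids, chroms, counts, counted, male_het_x, impute_missing, het_x_drop
    )


def classify_markers(g: FounderGenotypes) -> MarkerClassification:
    """Classify markers per partition as in a segregation inventory.

    A marker is *polymorphic across all founders* if both alleles occur among
    the founder gene counts (after loading, every retained marker qualifies);
    *polymorphic within a line* if both alleles occur among that line's
    founders; and *line-specific* if every line is fixed (frequency 0 or 1)
    with at least two lines fixed for opposite alleles.
    """
    if len(set(g.lines)) < 2:
        raise ValueError("marker classification requires at least two lines")
    out = {}
    for part in (AUTOSOMAL, X):
        block = g.block(part)
        ploidy = g.ploidy(part)
        c = block.counts
        if c.size == 0:
            out[part] = ClassCounts(0, {lab: 0 for lab in dict.fromkeys(g.lines)}, 0)
            continue
        total = c.sum(axis=0)
        denom = ploidy.sum()
        poly_all = (total > 0) & (total < denom)
        within = {}
        line_freq = {}
        for lab in dict.fromkeys(g.lines):
            sel = np.array([l == lab for l in g.lines])
            tot = c[sel].sum(axis=0)
            den = ploidy[sel].sum()
            within[lab] = int(((tot > 0) & (tot < den)).sum())
            line_freq[lab] = tot / den
        freqs = np.stack(list(line_freq.values()))
        fixed = (freqs == 0) | (freqs == 1)
        line_specific = int(
            (fixed.all(axis=0) & (freqs == 1).any(axis=0) & (freqs == 0).any(axis=0)).sum()
        )
        out[part] = ClassCounts(int(poly_all.sum()), within, line_specific)
    return MarkerClassification(autosomal=out[AUTOSOMAL], x=out[X])


def write_founder_csv(g: FounderGenotypes, path) -> None:
    """Write the marker-major CSV dialect (integer counts only)."""
    rows = []
    for part in (AUTOSOMAL, X):
        block = g.block(part)
        for mi, (mid, chrom) in enumerate(zip(block.marker_ids, block.chroms)):
            row = {"marker": mid, "chrom": chrom, "allele1": "A", "allele2": "a"}
            for fi, fid in enumerate(g.founder_ids):
                c = block.counts[fi, mi]
                if c != int(c):
                    raise ValueError("cannot serialize fractional (imputed) counts")
                if part == X and g.sexes[fi] is Sex.MALE:
                    row[fid] = "A" if c == 1 else "a"
                else:
                    row[fid] = {2: "A/A", 1: "A/a", 0: "a/a"}[int(c)]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ped_map(g: FounderGenotypes, prefix) -> None:
    """Write a PLINK-style .ped/.map pair (6-column .map with alleles)."""
    prefix = str(prefix)
    with open(prefix + ".map", "w") as fh:
        pos = 0
        for part in (AUTOSOMAL, X):
            block = g.block(part)
            for mid, chrom in zip(block.marker_ids, block.chroms):
                pos += 1
                fh.write(f"{chrom}\t{mid}\t0\t{pos}\tA\ta\n")
    with open(prefix + ".ped", "w") as fh:
        for fi, fid in enumerate(g.founder_ids):
            sex = "1" if g.sexes[fi] is Sex.MALE else "2"
            fields = [fid, fid, "0", "0", sex, "-9"]
            for part in (AUTOSOMAL, X):
                block = g.block(part)
                for mi in range(block.n_markers):
                    c = block.counts[fi, mi]
                    if c != int(c):
                        raise ValueError("cannot serialize fractional (imputed) counts")
                    c = int(c)
                    if part == X and g.sexes[fi] is Sex.MALE:
                        a = "A" if c == 1 else "a"
                        fields += [a, a]
                    else:
                        fields += {2: ["A", "A"], 1: ["A", "a"], 0: ["a", "a"]}[c]
            fh.write(" ".join(fields) + "\n")
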