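"""End-to-end pipeline: read → moments → G0/E(G0) → Ã → H⁻¹ → reports.

Every stage writes re-loadable text artifacts into the output directory and
the run finishes with a machine-readable manifest (sha256 checksums) plus a
serialized copy of the configuration, so a run is reproducible from its
output directory alone.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import matio
from .combine import build_h_inverse, dk_correction
from .errors import CrossGRMError
from .expected_founder import expected_founder_matrix
from .founder_genotypes import classify_markers, read_founder_genotypes
from .genedrop import GeneDropConfig, expected_grm_by_genedrop
from .moments import compute_line_frequencies, gametic_moments
from .observed_grm import blend, observed_founder_grm, rank_report
from .pedigree import AUTOSOMAL, X, line_composition, read_pedigree
from .tabular import extend_autosomal, extend_x, f2_reference_summary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    pedigree: str = ""
    genotypes: str = ""
    genotype_format: str = "csv"
    map_path: str | None = None
    outdir: str = "crossgrm-out"
    partitions: str = "autosomal,x"
    alpha: float = 0.98
    line_weights: str = ""  # comma-separated, empty = uniform
    x_line_weights: str = ""
    male_het_x: str = "error"
    impute_missing: str = ""
    genedrop_replicates: int = 0
    genedrop_seed: int = 0
    rank_tol: float = 1e-8
    cond_threshold: float = 1e12

    @classmethod
    def from_file(cls, path, overrides: dict | None = None) -> "RunConfig":
        """Flat key=value (INI) config; every key overridable by CLI flag."""
        parser = configparser.ConfigParser()
        with open(path) as fh:
            text = fh.read()
        if not text.lstrip().startswith("["):
            text = "[crossgrm]\n" + text
        parser.read_string(text)
        section = parser[parser.sections()[0]] if parser.sections() else {}
        cfg = cls()
        for key, raw in section.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                value: object = raw.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                value = int(raw)
            elif isinstance(current, float):
                value = float(raw)
            else:
                value = raw
            setattr(cfg, key, value)
        for key, value in (overrides or {}).items():
            if value is not None:
                setattr(cfg, key, value)
        return cfg

    def parsed_weights(self, attr: str):
        raw = getattr(self, attr)
        if not raw:
            return None
        return np.array([float(tok) for tok in raw.split(",")])

    def partition_list(self) -> list[str]:
        parts = [tok.strip() for tok in self.partitions.split(",") if tok.strip()]
        bad = set(parts) - {AUTOSOMAL, X}
        if bad:
            raise ValueError(f"unknown partitions {sorted(bad)}")
        return parts


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    """Context manager tagging errors with the pipeline stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, CrossGRMError):
            raise type(exc)(f"[stage {self.name}] {exc}") from exc
        return False


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the manifest that is also written to disk."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    report: dict[str, object] = {}

    def save_matrix(m, name, fmt="dense"):
        path = outdir / f"{name}.txt"
        (matio.write_dense if fmt == "dense" else matio.write_triplets)(m, path)
        artifacts[name] = str(path)
        return m

    with _Stage("read"):
        ped = read_pedigree(cfg.pedigree)
        g = read_founder_genotypes(
            cfg.genotypes,
            format=cfg.genotype_format,
            ped=ped,
            map_path=cfg.map_path or None,
            male_het_x=cfg.male_het_x,
            impute_missing=cfg.impute_missing or None,
        )

    with _Stage("classify"):
        cls = classify_markers(g)
        lines = list(dict.fromkeys(g.lines))
        path = outdir / "marker_classification.tsv"
        with open(path, "w") as fh:
            fh.write("partition\tall_founders\t" + "\t".join(lines) + "\tline_specific\n")
            for part in (AUTOSOMAL, X):
                c = cls.block(part)
                fh.write(
                    f"{part}\t{c.all_founders}\t"
                    + "\t".join(str(c.within_line[l]) for l in lines)
                    + f"\t{c.line_specific}\n"
                )
        artifacts["marker_classification"] = str(path)

    with _Stage("moments"):
        freqs = compute_line_frequencies(
            g, weights=cfg.parsed_weights("line_weights"),
            x_weights=cfg.parsed_weights("x_line_weights"),
        )
        moms = {}
        for part in cfg.partition_list():
            moms[part] = gametic_moments(freqs, part)
            path = outdir / f"moments_{part}.tsv"
            write_moments_tsv(moms[part], path)
            artifacts[f"moments_{part}"] = str(path)

    lc = line_composition(ped)
    hinv_targets = []
    for part in cfg.partition_list():
        mom = moms[part]
        with _Stage(f"grm-observed[{part}]"):
            g0 = save_matrix(observed_founder_grm(g, freqs, part), f"G0_{part}")
            report[f"rank_G0_{part}"] = rank_report(g0, cfg.rank_tol)
        with _Stage(f"grm-expected[{part}]"):
            e0 = save_matrix(expected_founder_matrix(ped, mom, part), f"E0_{part}")
        with _Stage(f"blend[{part}]"):
            g0bld = save_matrix(blend(g0, e0, cfg.alpha), f"G0BLD_{part}")
        with _Stage(f"extend[{part}]"):
            extend = extend_autosomal if part == AUTOSOMAL else extend_x
            atilde = save_matrix(extend(ped, e0, mom, lc), f"Atilde_{part}")
        with _Stage(f"build-h[{part}]"):
            hinv = build_h_inverse(atilde, g0bld, e0, cfg.cond_threshold)
            path = outdir / f"Hinv_{part}.txt"
            matio.write_triplets(hinv.as_relationship_matrix(), path)
            artifacts[f"Hinv_{part}"] = str(path)
            report[f"Dk_{part}"] = dk_correction(g0bld)
        if cfg.genedrop_replicates > 0:
            with _Stage(f"genedrop[{part}]"):
                res = expected_grm_by_genedrop(
                    ped, g, freqs,
                    GeneDropConfig(
                        replicates=cfg.genedrop_replicates,
                        seed=cfg.genedrop_seed,
                        partition=part,
                    ),
                )
                from .observed_grm import RelationshipMatrix

                save_matrix(
                    RelationshipMatrix(res.mean, res.ids, part, "genedrop-mean"),
                    f"genedrop_mean_{part}",
                )
                save_matrix(
                    RelationshipMatrix(res.se, res.ids, part, "genedrop-se"),
                    f"genedrop_se_{part}",
                )

    with _Stage("report"):
        if len(freqs.lines) == 2 and AUTOSOMAL in moms:
            summary = f2_reference_summary(moms[AUTOSOMAL])
            report["f2_mean_self"] = summary.mean_self
            report["f2_mean_pairwise"] = summary.mean_pairwise
            report["segregation_proportion"] = summary.segregation_proportion
        # generation means of Ã diagonals: the diagnostic behind the
        # oscillating X / stable autosome contrast
        diag_path = outdir / "generation_means.tsv"
        with open(diag_path, "w") as fh:
            fh.write("partition\tgeneration\tmean_self\n")
            for part in cfg.partition_list():
                m = matio.read_dense(outdir / f"Atilde_{part}.txt", part, "expected-pedigree")
                diag = np.diag(m.dense())
                for gen in np.unique(ped.generations):
                    sel = ped.generations == gen
                    fh.write(f"{part}\t{gen}\t{diag[sel].mean():.17g}\n")
        artifacts["generation_means"] = str(diag_path)
        rep_path = outdir / "report.tsv"
        with open(rep_path, "w") as fh:
            for key, value in report.items():
                fh.write(f"{key}\t{value}\n")
        artifacts["report"] = str(rep_path)

    cfg_path = outdir / "config.ini"
    with open(cfg_path, "w") as fh:
        fh.write("[crossgrm]\n")
        for key, value in asdict(cfg).items():
            fh.write(f"{key} = {'' if value is None else value}\n")
    artifacts["config"] = str(cfg_path)

    manifest = {
        "artifacts": {
            name: {"path": path, "sha256": _sha256(Path(path))}
            for name, path in artifacts.items()
        },
        "report": {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                   for k, v in report.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_moments_tsv(mom, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"S\t{mom.S:.17g}\n")
        for lab, d in zip(mom.lines, mom.d):
            fh.write(f"d_{lab}\t{d:.17g}\n")
        for i, li in enumerate(mom.lines):
            for j, lj in enumerate(mom.lines):
                if j <= i:
                    fh.write(f"r_{li}{lj}\t{mom.r[i, j]:.17g}\n")
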