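"""Reproducible end-to-end run: config, validation, logging, report tables.

``run_report`` ties the genotype and phenotype stages together: for each
configured locus it tallies genotypes, writes a population-genetics summary
(genotype/allele frequencies, Ho/He/Ne/PIC, HWE test) and — when phenotype
records are supplied — fits the litter-size association model and writes the
ANOVA and per-genotype summary tables.  Outputs are deterministic for fixed
inputs; only the run log carries timestamps.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from . import association, popgen

__all__ = ["LocusDef", "RunConfig", "PipelineError", "run_report"]


class PipelineError(RuntimeError):
    """Stage failure; the message names the stage and the offending record."""


@dataclass(frozen=True)
class LocusDef:
    name: str
    alleles: tuple[str, ...] | None = None


@dataclass(frozen=True)
class RunConfig:
    genotypes: str
    phenotypes: str | None = None
    loci: tuple[LocusDef, ...] = ()
    alpha: float = 0.05
    digits: int = 2
    out_dir: str = "ovigene_report"
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.digits < 0:
            raise ValueError("digits must be >= 0")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        loci = tuple(
            LocusDef(name=entry["name"],
                     alleles=tuple(entry["alleles"]) if entry.get("alleles") else None)
            for entry in raw.pop("loci", [])
        )
        return cls(loci=loci, **raw)


def run_report(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute popgen (and, with phenotypes, association) per locus.

    Returns the result tables keyed by output name and writes them as CSV
    under ``cfg.out_dir`` together with ``run_log.txt``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"ovigene {__version__}",
        f"started {datetime.datetime.now().isoformat(timespec='seconds')}",
        f"seed {cfg.seed}",
    ]

    genotype_path = Path(cfg.genotypes)
    if not genotype_path.exists():
        raise PipelineError(f"[config] genotype file not found: {genotype_path}")
    try:
        genotype_frame = popgen.read_genotype_csv(str(genotype_path))
    except ValueError as err:
        raise PipelineError(f"[popgen] {err}") from err
    log_lines.append(f"genotype rows: {len(genotype_frame)}")

    loci = cfg.loci or tuple(
        LocusDef(name=str(name)) for name in genotype_frame["locus"].unique())

    phenotype_frame = None
    if cfg.phenotypes is not None:
        phenotype_path = Path(cfg.phenotypes)
        if not phenotype_path.exists():
            raise PipelineError(f"[config] phenotype file not found: {phenotype_path}")
        phenotype_frame = pd.read_csv(phenotype_path)
        log_lines.append(f"phenotype rows: {len(phenotype_frame)}")

    tables: dict[str, pd.DataFrame] = {}
    popgen_rows = []
    for locus in loci:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                gc = popgen.tabulate_genotypes(genotype_frame, locus=locus.name,
                                               alleles=locus.alleles)
                summary = popgen.locus_summary(gc, digits=cfg.digits)
            except ValueError as err:
                raise PipelineError(f"[popgen] locus {locus.name}: {err}") from err
        for warning in caught:
            log_lines.append(f"warning [popgen] {warning.message}")
        if gc.n_missing:
            log_lines.append(
                f"locus {locus.name}: {gc.n_missing} missing genotype(s) excluded")
        popgen_rows.append(summary)

        if phenotype_frame is not None:
            merged = phenotype_frame.merge(
                genotype_frame.loc[genotype_frame["locus"] == locus.name,
                                   ["animal_id", "genotype"]],
                on="animal_id", how="inner")
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                try:
                    result = association.fit_association(
                        merged, locus_id=locus.name, alpha=cfg.alpha)
                except ValueError as err:
                    raise PipelineError(
                        f"[association] locus {locus.name}: {err}") from err
            for warning in caught:
                log_lines.append(f"warning [association] {warning.message}")
            anova = result.anova.round(4)
            anova.insert(0, "locus", locus.name)
            summary4 = result.genotype_summaries.copy()
            summary4[["mean", "sd"]] = summary4[["mean", "sd"]].round(cfg.digits)
            summary4.insert(0, "locus", locus.name)
            tables[f"association_anova_{_slug(locus.name)}"] = anova
            tables[f"association_summary_{_slug(locus.name)}"] = summary4
            log_lines.append(
                f"locus {locus.name}: genotype term "
                f"{'significant' if result.significant else 'not significant'} "
                f"at alpha={cfg.alpha}")

    tables["popgen_summary"] = pd.concat(popgen_rows, ignore_index=True)

    for name, frame in tables.items():
        frame.to_csv(out_dir / f"{name}.csv", index=False)
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return tables


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name)
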