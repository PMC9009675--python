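"""End-to-end orchestration: trial in, full table set out.

``run_pipeline`` ingests a trial CSV (or simulates one), fits every trait's
mixed model, runs the likelihood-ratio tests, computes genetic parameters,
applies the genotype-ideotype index and writes the whole table set as CSV,
plus a JSON manifest recording the configuration hash and seed.  With a
fixed configuration the outputs are byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd

from . import __version__
from .explore import pca, pearson_matrix
from .genpar import parameter_table
from .index import run_mgidi, rescale, fit_factor_model, strengths_weaknesses
from .reml import (
    blup_means,
    fit_all_traits,
    genotype_blup_matrix,
    genotype_environment_blup_matrix,
    lrt_random,
    test_fixed_effects,
)
from .simulate import SimulationConfig, simulate_met
from .trial import TraitSpec, TrialData, load_trial_table

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("mgidi")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and trait."""


@dataclass
class PipelineConfig:
    trait_specs: list[TraitSpec]
    input_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    output_dir: str | Path = "mgidi_out"
    selection_proportion: float = 0.25
    heritability: Literal["mean", "broad"] = "mean"
    rge_variant: Literal["genotypic", "interaction"] = "genotypic"
    rotate: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0.0 < self.selection_proportion <= 1.0:
            raise PipelineError(
                f"config: selection proportion must be in (0, 1], got {self.selection_proportion}"
            )
        if (self.input_path is None) == (self.simulation is None):
            raise PipelineError("config: set exactly one of input_path / simulation")
        if not self.trait_specs:
            raise PipelineError("config: no trait specs declared")

    def digest(self) -> str:
        doc = {
            "input": None if self.input_path is None else str(self.input_path),
            "simulated": self.simulation is not None,
            "traits": [(s.name, s.direction) for s in self.trait_specs],
            "proportion": self.selection_proportion,
            "heritability": self.heritability,
            "rge": self.rge_variant,
            "rotate": self.rotate,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def _load(config: PipelineConfig) -> TrialData:
    if config.simulation is not None:
        config.simulation.seed = config.seed
        data, _ = simulate_met(config.simulation)
        return data
    return load_trial_table(config.input_path, config.trait_specs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the run manifest.

    Emits, under ``config.output_dir``: ``lrt_tests.csv``,
    ``genetic_parameters.csv``, ``blup_genotype.csv``, ``blup_cell.csv``,
    ``rescaled_matrix.csv``, ``factor_loadings.csv``, ``mgidi_ranking.csv``,
    ``factor_contributions.csv``, ``selection_gains.csv``,
    ``correlations.csv``, ``pca_explained.csv`` and ``manifest.json``.  Any
    stage failure removes partially written outputs and raises
    :class:`PipelineError` naming the stage (and trait, where relevant).
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> Path:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
        return path

    stage = "load"
    trait = None
    t0 = time.perf_counter()
    try:
        data = _load(config)
        log.info("stage=%s n=%d wall=%.2fs", stage, len(data.table), time.perf_counter() - t0)

        stage = "mixed-model"
        fits = {}
        lrt_rows = []
        for spec in config.trait_specs:
            trait = spec.name
            ts = time.perf_counter()
            from .reml import fit_reml

            fits[trait] = fit_reml(data, trait)
            for term in ("genotype", "genotype-environment"):
                res = lrt_random(data, trait, term)
                lrt_rows.append(
                    {"trait": trait, "term": term, "statistic": res.statistic,
                     "df": res.df, "p_value": res.p_value}
                )
            if fits[trait].design.e > 1:
                res = test_fixed_effects(data, trait)
                lrt_rows.append(
                    {"trait": trait, "term": "environment (fixed, ML)",
                     "statistic": res.statistic, "df": res.df, "p_value": res.p_value}
                )
            log.info("stage=%s trait=%s wall=%.2fs", stage, trait, time.perf_counter() - ts)
        trait = None
        emit("lrt_tests.csv", pd.DataFrame(lrt_rows))

        stage = "genetic-parameters"
        emit(
            "genetic_parameters.csv",
            parameter_table(fits, heritability=config.heritability, rge_variant=config.rge_variant),
        )

        stage = "blup"
        gmat = genotype_blup_matrix(fits)
        emit("blup_genotype.csv", gmat.rename_axis("genotype").reset_index())
        cell = genotype_environment_blup_matrix(fits)
        emit("blup_cell.csv", cell.reset_index())

        stage = "mgidi"
        # a trait whose genotypic variance hit the zero boundary has a
        # constant BLUP column: it carries no selection signal and cannot be
        # rescaled, so it is excluded from the index (but stays in every
        # upstream table)
        usable = [s for s in config.trait_specs if gmat[s.name].nunique() > 1]
        dropped = [s.name for s in config.trait_specs if s.name not in {u.name for u in usable}]
        if dropped:
            log.warning("traits with zero genotypic variance excluded from index: %s", dropped)
        rx = rescale(gmat, usable)
        model = fit_factor_model(rx, rotate=config.rotate)
        result, selected, gains = run_mgidi(
            gmat, usable,
            proportion=config.selection_proportion, rotate=config.rotate,
        )
        emit("rescaled_matrix.csv", rx.values.rename_axis("genotype").reset_index())
        loadings = model.loadings.copy()
        loadings["communality"] = model.communalities
        emit("factor_loadings.csv", loadings.rename_axis("trait").reset_index())
        emit("mgidi_ranking.csv", result.rank_table())
        emit("factor_contributions.csv", strengths_weaknesses(result))
        emit("selection_gains.csv", gains)

        stage = "exploration"
        corr = pearson_matrix(cell)
        emit("correlations.csv", corr.r.rename_axis("trait").reset_index())
        pca_res = pca(cell)
        emit("pca_explained.csv", pca_res.explained_pct.rename_axis("component").reset_index())
        emit(
            "pca_contributions.csv",
            pca_res.leading_contribution.rename_axis("trait").reset_index(),
        )

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config_hash": config.digest(),
            "seed": config.seed,
            "selected": [str(s) for s in selected],
            "n_genotypes": int(fits[config.trait_specs[0].name].design.g),
            "tables": {p.stem: str(p) for p in written},
        }
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(mpath)
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        where = f"stage '{stage}'" + (f", trait '{trait}'" if trait else "")
        raise PipelineError(f"pipeline failed at {where}: {exc}") from exc
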