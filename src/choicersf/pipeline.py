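"""Config-driven batch pipeline: track -> choice sets -> screen -> all-subsets
WAIC selection -> full-budget refit with PPC -> predicted-use map, per
individual; then the hierarchical population model and the individual-vs-
population map comparison.

Each individual receives a deterministic sub-seed derived from the master
seed and its ID, so results are independent of processing order, and every
bundle carries a JSON manifest sufficient to reproduce it.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .choices import ChoiceData, build_choice_sets, movement_stats, availability_radius, write_choice_csv
from .design import DesignCoding
from .errors import ChoicersfError, InvalidConfigError
from .hierarchy import HyperPosterior, fit_population, shrinkage_report, summarize_hyperparameters
from .inference import FitResult, McmcConfig, fit_individual, posterior_predictive_check
from .landscape import CovariateGrids
from .mapping import PredictionMap, compare_maps, correlation_table, predict_map
from .screen import ScreenResult, screen_collinearity
from .selection import CandidateModel, fit_candidates, inclusion_rates, rank_models
from .track import TelemetryTrack

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings shared by every pipeline stage."""

    n_available: int = 5
    nominal_interval: float = 5.0
    screen_threshold: float = 0.6
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    candidate_cap: int = 16
    candidates: list[list[str]] | None = None   # explicit override of the enumeration
    top_fraction: float = 0.05
    run_selection: bool = True
    run_ppc: bool = True
    ppc_reps: int = 500
    seed: int = 0

    def validate(self):
        if not 0 < self.top_fraction <= 1:
            raise InvalidConfigError("top_fraction must be in (0, 1]")
        if self.n_available < 1:
            raise InvalidConfigError("n_available must be >= 1")
        self.mcmc.validate()

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["mcmc"] = dict(self.mcmc.__dict__)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "mcmc" in d and isinstance(d["mcmc"], dict):
            d["mcmc"] = McmcConfig(**d["mcmc"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def individual_seed(master_seed: int, individual_id: str) -> int:
    """Stable sub-seed below 2^31, independent of processing order."""
    return (master_seed * 1_000_003 + zlib.crc32(individual_id.encode())) % (2**31 - 1)


@dataclass
class IndividualBundle:
    """Everything the pipeline produced for one individual."""

    individual_id: str
    choice_data: ChoiceData
    screen: ScreenResult
    ranked: pd.DataFrame | None
    inclusion: pd.DataFrame | None
    best_model: list[str]
    fit: FitResult
    p_b: float | None
    use_map: PredictionMap
    n_dropped_fixes: int
    radius: float
    seed: int


def run_individual(
    track: TelemetryTrack,
    grids: CovariateGrids,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> IndividualBundle:
    """Run the full per-animal workflow and optionally write its bundle."""
    config.validate()
    t0 = time.perf_counter()
    sub_seed = individual_seed(config.seed, track.individual_id)
    stats = movement_stats(track, nominal_interval=config.nominal_interval)
    radius = availability_radius(stats)

    coding = DesignCoding.from_grids(grids)
    data = build_choice_sets(
        track,
        grids,
        n_available=config.n_available,
        nominal_interval=config.nominal_interval,
        coding=coding,
        seed=sub_seed,
        stats=stats,
    )
    n_dropped = track.n_fixes - data.n_sets

    screen = screen_collinearity(data, threshold=config.screen_threshold)
    retained_vars = screen.retained + (["habitat"] if coding.habitat_labels else [])
    screened_coding = DesignCoding(
        continuous=tuple(screen.retained),
        habitat_labels=coding.habitat_labels,
        reference=coding.reference,
    )
    sdata = data.subset_columns(screened_coding.column_names)
    sdata.coding = screened_coding

    mcmc = config.mcmc.replace(seed=sub_seed)
    ranked = inclusion = None
    best_vars = retained_vars
    if config.run_selection:
        cands = (
            [CandidateModel(tuple(c)) for c in config.candidates]
            if config.candidates is not None
            else None
        )
        fits = fit_candidates(sdata, candidates=cands, config=mcmc, cap=config.candidate_cap)
        ranked = rank_models([(c, w) for c, w, _ in fits], coding=screened_coding)
        inclusion = inclusion_rates(ranked, config.top_fraction)
        best_vars = ranked.iloc[0]["variables"].split(",")

    best_data = sdata.subset_variables(best_vars)
    fit = fit_individual(best_data, mcmc)
    p_b = (
        posterior_predictive_check(fit, best_data, n_reps=config.ppc_reps, seed=sub_seed)
        if config.run_ppc
        else None
    )
    fit.p_b = p_b

    best_coding = DesignCoding(
        continuous=tuple(v for v in best_vars if v != "habitat"),
        habitat_labels=coding.habitat_labels if "habitat" in best_vars else (),
        reference=coding.reference if "habitat" in best_vars else None,
    )
    use_map = predict_map(
        fit.posterior_mean, grids, best_coding, provenance=f"individual:{track.individual_id}"
    )

    bundle = IndividualBundle(
        individual_id=track.individual_id,
        choice_data=data,
        screen=screen,
        ranked=ranked,
        inclusion=inclusion,
        best_model=list(best_vars),
        fit=fit,
        p_b=p_b,
        use_map=use_map,
        n_dropped_fixes=n_dropped,
        radius=radius,
        seed=sub_seed,
    )
    if out_dir is not None:
        _write_individual_bundle(bundle, Path(out_dir), config, time.perf_counter() - t0)
    return bundle


def _write_individual_bundle(
    b: IndividualBundle, out_dir: Path, config: PipelineConfig, elapsed: float
) -> None:
    d = out_dir / b.individual_id
    d.mkdir(parents=True, exist_ok=True)
    write_choice_csv(b.choice_data, d / "choice_sets.csv", d / "coding.json")
    b.screen.to_frame().to_csv(d / "screen.csv", index=False)
    if b.ranked is not None:
        b.ranked.to_csv(d / "model_ranking.csv", index=False)
    if b.inclusion is not None:
        b.inclusion.to_csv(d / "inclusion_rates.csv", index=False)
    b.fit.save(d / "fit")
    b.use_map.write(d / "use_map.asc")
    manifest = {
        "individual_id": b.individual_id,
        "seed": b.seed,
        "availability_radius_m": b.radius,
        "n_choice_sets": b.choice_data.n_sets,
        "n_dropped_fixes": b.n_dropped_fixes,
        "best_model": b.best_model,
        "p_b": b.p_b,
        "elapsed_s": round(elapsed, 3),
        "config": config.to_dict(),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


@dataclass
class PopulationBundle:
    hyper: HyperPosterior
    summary: pd.DataFrame
    shrinkage: pd.DataFrame
    use_map: PredictionMap
    rho_table: pd.DataFrame
    binned: pd.DataFrame


def run_population(
    bundles: list[IndividualBundle],
    grids: CovariateGrids,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> PopulationBundle:
    """Hierarchical fit over all successful individuals plus map comparison.

    The population model is fit on the shared global (screened) design so
    every individual contributes the same columns.
    """
    config.validate()
    if len(bundles) < 2:
        raise InvalidConfigError("population stage needs >= 2 successful individuals")

    # shared screened columns: intersection across individuals, stable order
    common = [
        c
        for c in bundles[0].choice_data.column_names
        if all(c in b.choice_data.column_names for b in bundles)
    ]
    ref_coding = bundles[0].choice_data.coding
    retained = [
        c for c in common if b_is_continuous(c, ref_coding)
    ]
    for b in bundles:
        sub = screen_collinearity(b.choice_data, threshold=config.screen_threshold)
        retained = [c for c in retained if c in sub.retained]
    hab_labels = ref_coding.habitat_labels if ref_coding else ()
    coding = DesignCoding(
        continuous=tuple(retained),
        habitat_labels=hab_labels,
        reference=ref_coding.reference if ref_coding else None,
    )
    all_data = []
    for b in bundles:
        d = b.choice_data.subset_columns(coding.column_names)
        d.coding = coding
        all_data.append(d)

    hyper = fit_population(all_data, config.mcmc.replace(seed=config.seed))
    summary = summarize_hyperparameters(hyper)

    # refit independent global models on the same columns for the shrinkage report
    indep = [
        fit_individual(d, config.mcmc.replace(seed=individual_seed(config.seed, d.individual_id)))
        for d in all_data
    ]
    shrink = shrinkage_report(hyper, indep)

    pop_map = predict_map(hyper.population_mean(), grids, coding, provenance="population")
    rhos = []
    for b in bundles:
        rhos.append(
            {"individual_id": b.individual_id, "rho": compare_maps(b.use_map, pop_map)}
        )
    rho_table = pd.DataFrame(rhos)
    binned = correlation_table(rho_table["rho"].to_numpy())

    out = PopulationBundle(
        hyper=hyper,
        summary=summary,
        shrinkage=shrink,
        use_map=pop_map,
        rho_table=rho_table,
        binned=binned,
    )
    if out_dir is not None:
        d = Path(out_dir) / "population"
        d.mkdir(parents=True, exist_ok=True)
        summary.to_csv(d / "hyperparameters.csv", index=False)
        shrink.to_csv(d / "shrinkage.csv", index=False)
        pop_map.write(d / "use_map.asc")
        rho_table.to_csv(d / "rho_by_individual.csv", index=False)
        binned.to_csv(d / "rho_binned.csv", index=False)
    return out


def b_is_continuous(column: str, coding: DesignCoding | None) -> bool:
    if coding is None:
        return not column.startswith("habitat:")
    return column in coding.continuous


def run_all(
    tracks: list[TelemetryTrack],
    grids: CovariateGrids,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> tuple[list[IndividualBundle], PopulationBundle | None, pd.DataFrame]:
    """Batch the per-individual workflow; failures are logged, not fatal.

    Returns the successful bundles, the population bundle (None if fewer
    than two individuals succeeded), and a per-individual status frame.
    """
    bundles, status = [], []
    for track in tracks:
        try:
            t0 = time.perf_counter()
            b = run_individual(track, grids, config, out_dir=out_dir)
            bundles.append(b)
            status.append(
                {
                    "individual_id": track.individual_id,
                    "status": "ok",
                    "reason": "",
                    "n_sets": b.choice_data.n_sets,
                    "elapsed_s": round(time.perf_counter() - t0, 3),
                }
            )
        except ChoicersfError as err:
            logger.warning("individual %s failed: %s", track.individual_id, err)
            status.append(
                {
                    "individual_id": track.individual_id,
                    "status": "failed",
                    "reason": str(err),
                    "n_sets": 0,
                    "elapsed_s": 0.0,
                }
            )
    pop = None
    if len(bundles) >= 2:
        pop = run_population(bundles, grids, config, out_dir=out_dir)
    status_df = pd.DataFrame(status)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        status_df.to_csv(Path(out_dir) / "batch_summary.csv", index=False)
    return bundles, pop, status_df
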