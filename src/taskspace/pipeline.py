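"""Configuration-driven orchestration of the full analysis.

The flow mirrors the analysis end to end: generate (or load) inputs ->
project maps into the state space -> fit the mixed model per dimension ->
derive per-condition trait slopes -> flag trait-by-condition interactions
at the Bonferroni threshold -> for each flag, locate the strongest
diverging condition pair, compute divergence scores and run the bootstrap
sign-stability ladder. All randomness flows from one root seed expanded
into per-stage streams; a rerun with the same config is byte-identical for
TSV/JSON payloads.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .conditions import CONDITIONS, TRAITS, check_conditions, UnknownConditionError
from .mixed_model import (
    ModelSpec,
    bonferroni_alpha,
    fit_state_space_model,
    flag_significant_interactions,
    strongest_divergent_pair,
    trait_slopes_by_condition,
)
from .stability import (
    DEFAULT_N_BOOT,
    DEFAULT_SIZES,
    SINGLETON_SIZES,
    bootstrap_stability,
    divergence_scores,
    log_spaced_sizes,
)
from .state_space import condition_centroids, project_cohort
from .synthetic import (
    DEFAULT_N_SUBJECTS,
    DEFAULT_SIBLING_FRACTION,
    EffectSpec,
    generate_cohort,
    generate_coordinates,
    generate_gradients,
    generate_maps,
)

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial artifacts are preserved on disk."""


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # or "real"
    seed: int = 0
    out_dir: str = "taskspace_out"
    # synthetic-mode generator parameters
    n_subjects: int = DEFAULT_N_SUBJECTS
    sibling_fraction: float = DEFAULT_SIBLING_FRACTION
    n_vertices: int = 1000
    use_maps: bool = True
    conditions: tuple[str, ...] = CONDITIONS
    effects: dict | None = None  # EffectSpec dict; None = null effects
    # real-mode input paths
    gradients_path: str | None = None
    cohort_path: str | None = None
    maps_dir: str | None = None
    state_space_path: str | None = None
    # model options
    fwer: float = 0.05
    # stability options
    stability_min_n: int = DEFAULT_SIZES[0]
    stability_max_n: int = DEFAULT_SIZES[1]
    stability_steps: int = DEFAULT_SIZES[2]
    n_boot: int = DEFAULT_N_BOOT
    singleton: bool = False
    singleton_sizes: tuple[int, int, int] = SINGLETON_SIZES

    def __post_init__(self):
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if not 0 < self.fwer < 1:
            raise ValueError("fwer must be in (0, 1)")
        self.conditions = tuple(self.conditions)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["singleton_sizes"] = list(self.singleton_sizes)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        if "singleton_sizes" in d:
            d["singleton_sizes"] = tuple(d["singleton_sizes"])
        return cls(**d)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # artifact location is not part of the analysis identity
        payload = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def effect_spec(self) -> EffectSpec:
        if self.effects is None:
            return EffectSpec.null(conditions=self.conditions)
        return EffectSpec.from_dict(self.effects)


@dataclass
class ValidationReport:
    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Check input consistency without mutating anything.

    Problems are reported, never raised: vertex-grid mismatches, unknown
    condition labels, missing traits, absent family ids.
    """
    rep = ValidationReport()
    try:
        check_conditions(config.conditions)
    except UnknownConditionError as e:
        rep.problems.append(str(e))
    if config.mode == "synthetic":
        if config.n_subjects < 1:
            rep.problems.append("n_subjects must be >= 1")
        return rep

    for name in ("gradients_path", "cohort_path"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            rep.problems.append(f"{name} missing or does not exist: {p}")
    if config.maps_dir is None and config.state_space_path is None:
        rep.problems.append("real mode needs maps_dir or state_space_path")
    if rep.problems:
        return rep

    try:
        cohort = tio.read_cohort(config.cohort_path)
    except ValueError as e:
        rep.problems.append(f"cohort_path unreadable: {e}")
        return rep
    missing_traits = [t for t in TRAITS if t not in cohort.columns]
    if missing_traits:
        rep.problems.append(f"cohort lacks trait columns {missing_traits}")
    else:
        bad = cohort[list(TRAITS)].isna().any(axis=1).sum()
        if bad:
            rep.problems.append(f"{bad} subjects have missing trait scores")
    if cohort["family_id"].isna().any():
        rep.problems.append("cohort has subjects without family_id")
    if cohort["subject_id"].duplicated().any():
        rep.problems.append("duplicate subject_id values in cohort")

    try:
        basis = tio.read_gradients(config.gradients_path)
    except ValueError as e:
        rep.problems.append(f"gradients_path unreadable: {e}")
        return rep
    if config.maps_dir is not None:
        maps = tio.read_mapset(config.maps_dir)
        if maps.n_vertices != basis.n_vertices:
            rep.problems.append(
                f"vertex grid mismatch: maps have {maps.n_vertices} vertices, "
                f"gradients have {basis.n_vertices}"
            )
        try:
            check_conditions(maps.conditions)
        except UnknownConditionError as e:
            rep.problems.append(str(e))
        unknown = set(maps.subjects) - set(cohort["subject_id"])
        if unknown:
            rep.problems.append(f"map subjects missing from cohort: {sorted(unknown)[:10]}")
    if config.state_space_path is not None:
        try:
            table = tio.read_state_space(config.state_space_path)
        except ValueError as e:
            rep.problems.append(f"state_space_path unreadable: {e}")
            return rep
        try:
            check_conditions(table["condition"].unique())
        except UnknownConditionError as e:
            rep.problems.append(str(e))
    return rep


@dataclass
class RunReport:
    config: dict
    provenance: dict
    n_comparisons: int
    alpha: float
    fits: dict  # dimension -> ModelFit.to_dict()
    flags: pd.DataFrame
    slopes: pd.DataFrame
    stability: dict  # "dim:trait" -> {pair, result dict, singleton variant}

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "provenance": self.provenance,
            "n_comparisons": self.n_comparisons,
            "alpha": self.alpha,
            "fits": self.fits,
            "flags": self.flags.to_dict(orient="records"),
            "stability": self.stability,
        }


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as e:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage '{name}' failed: {e}") from e
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full flow and write all artifacts under config.out_dir."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(4)]

    # --- acquire inputs -------------------------------------------------
    if config.mode == "synthetic":
        cohort = _stage("generate_cohort")(generate_cohort)(
            n_subjects=config.n_subjects,
            sibling_fraction=config.sibling_fraction,
            seed=stage_seeds[0],
        )
        effects = config.effect_spec()
        if config.use_maps:
            basis = _stage("generate_gradients")(generate_gradients)(
                n_vertices=config.n_vertices, n_dims=len(effects.dims), seed=stage_seeds[1]
            )
            maps = _stage("generate_maps")(generate_maps)(
                cohort, basis, effects, conditions=config.conditions, seed=stage_seeds[2]
            )
            table = _stage("project")(project_cohort)(maps, basis, cohort)
        else:
            table = _stage("generate_coordinates")(generate_coordinates)(
                cohort, effects, conditions=config.conditions, seed=stage_seeds[2]
            )
    else:
        rep = validate_inputs(config)
        if not rep.ok:
            raise PipelineError(f"stage 'validate' failed: {rep.problems}")
        cohort = tio.read_cohort(config.cohort_path)
        if config.state_space_path is not None:
            table = tio.read_state_space(config.state_space_path)
        else:
            basis = tio.read_gradients(config.gradients_path)
            maps = tio.read_mapset(config.maps_dir)
            table = _stage("project")(project_cohort)(maps, basis, cohort)

    tio.write_cohort(cohort, out / "cohort.tsv")
    tio.write_state_space(table, out / "state_space.tsv")
    condition_centroids(table).to_csv(out / "centroids.tsv", sep="\t", index=False)

    # --- model fits per dimension ---------------------------------------
    dims = sorted(table["dimension"].unique())
    spec = ModelSpec()
    fits = {}
    for d in dims:
        fits[d] = _stage(f"fit[{d}]")(fit_state_space_model)(table, d, spec)
        tio.write_json(fits[d].to_dict(), out / f"model_{d}.json")

    slopes = pd.concat(
        [_stage(f"slopes[{d}]")(trait_slopes_by_condition)(fits[d]) for d in dims],
        ignore_index=True,
    )
    slopes.to_csv(out / "slopes.tsv", sep="\t", index=False)

    n_cond = table["condition"].nunique()
    n_comp, alpha = bonferroni_alpha(n_cond, len(TRAITS), len(dims), config.fwer)
    flags = flag_significant_interactions(fits, alpha)
    flags.to_csv(out / "flags.tsv", sep="\t", index=False)

    # --- stability follow-up for each flagged interaction ----------------
    stability_out = {}
    flagged = flags[flags["significant"]]
    for _, row in flagged.iterrows():
        dim, trait = row["dimension"], row["trait"]
        cmax, cmin = strongest_divergent_pair(slopes, trait, dim)
        scores = _stage("divergence_scores")(divergence_scores)(
            table, cmax, cmin, dim, trait
        )
        sizes = log_spaced_sizes(
            config.stability_min_n, config.stability_max_n, config.stability_steps
        )
        res = _stage("bootstrap_stability")(bootstrap_stability)(
            scores, sizes=sizes, n_boot=config.n_boot, seed=stage_seeds[3]
        )
        entry = {
            "pair": [cmax, cmin],
            "n_scores": len(scores),
            "result": res.to_dict(),
        }
        if config.singleton:
            s_sizes = log_spaced_sizes(*config.singleton_sizes)
            res_s = _stage("bootstrap_stability[singleton]")(bootstrap_stability)(
                scores, sizes=s_sizes, n_boot=config.n_boot,
                seed=stage_seeds[3], singleton=True,
            )
            entry["singleton_result"] = res_s.to_dict()
        key = f"{dim}:{trait}"
        stability_out[key] = entry
        tio.write_json(entry, out / f"stability_{dim}_{trait}.json")

    report = RunReport(
        config=config.to_dict(),
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage_seeds": stage_seeds,
            "version": __version__,
        },
        n_comparisons=n_comp,
        alpha=alpha,
        fits={d: f.to_dict() for d, f in fits.items()},
        flags=flags,
        slopes=slopes,
        stability=stability_out,
    )
    tio.write_json(report.to_dict(), out / "report.json")
    return report
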