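"""Synthetic cohorts, gradient bases and activation maps with known truth.

Everything downstream (projection, mixed models, bootstrap stability) is
testable without any neuroimaging download because this module generates

* smooth, mutually decorrelated gradient basis maps over a generic vertex
  grid (stand-ins for the resting-state functional-connectivity gradients),
* a family-structured cohort (sibling pairs plus singletons) with five
  standardized personality trait scores, age, gender and per-task head
  motion (mean framewise displacement, mm), and
* per-subject per-condition activation maps (or state-space coordinates
  directly) whose gradient-space locations follow a known linear mixed
  model:

      location = condition mean
               + sum_t slope[trait t, condition] * trait_t
               + covariate effects (age, gender, meanFD; centered)
               + subject intercept + family intercept + noise

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .conditions import (
    CONDITIONS,
    DIMENSIONS,
    TASKS,
    TRAITS,
    check_conditions,
    task_of,
)

__all__ = [
    "GradientBasis",
    "EffectSpec",
    "MapSet",
    "generate_gradients",
    "generate_cohort",
    "generate_coordinates",
    "generate_maps",
]

# Default variance scale, in units of Spearman rho. Chosen so that the
# between-subject spread of a condition's location is ~0.1, the scale seen
# in individual-difference scatter of projected task maps.
DEFAULT_SD_SUBJECT = 0.05
DEFAULT_SD_FAMILY = 0.03
DEFAULT_SD_NOISE = 0.08
DEFAULT_VERTEX_NOISE = 0.1

# Default cohort emulates the full release sample: ~950 usable subjects of
# which ~442 are singletons (hence sibling_fraction such that the remainder
# pairs up).
DEFAULT_N_SUBJECTS = 950
DEFAULT_SIBLING_FRACTION = 0.535


@dataclass(frozen=True)
class GradientBasis:
    """Vertex-by-dimension loading matrix defining the state space."""

    values: np.ndarray
    dim_names: tuple[str, ...] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("gradient basis must be a 2-D vertex x dimension matrix")
        if v.shape[1] < 1:
            raise ValueError("need at least one gradient dimension")
        if not np.all(np.isfinite(v)):
            raise ValueError("gradient basis contains non-finite values")
        if np.any(v.std(axis=0) == 0):
            raise ValueError("gradient basis has a constant column")
        if self.dim_names is None:
            object.__setattr__(
                self, "dim_names", tuple(f"D{i + 1}" for i in range(v.shape[1]))
            )
        if len(self.dim_names) != v.shape[1]:
            raise ValueError("dim_names length must match number of columns")
        object.__setattr__(self, "dim_names", tuple(self.dim_names))

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]


@dataclass
class EffectSpec:
    """Ground-truth fixed effects and variance components for the generator.

    Arrays are indexed by the supplied ``conditions``/``dims`` label lists:
    ``condition_means[c, d]``, ``trait_slopes[t, c, d]`` (per unit trait),
    ``covariate_betas[k, d]`` for k in (age, gender, mean_fd).
    """

    conditions: tuple[str, ...] = CONDITIONS
    dims: tuple[str, ...] = DIMENSIONS
    traits: tuple[str, ...] = TRAITS
    condition_means: np.ndarray | None = None
    trait_slopes: np.ndarray | None = None
    covariate_betas: np.ndarray | None = None
    sd_subject: float = DEFAULT_SD_SUBJECT
    sd_family: float = DEFAULT_SD_FAMILY
    sd_noise: float = DEFAULT_SD_NOISE

    def __post_init__(self):
        self.conditions = tuple(self.conditions)
        self.dims = tuple(self.dims)
        self.traits = tuple(self.traits)
        nc, nd, nt = len(self.conditions), len(self.dims), len(self.traits)
        if self.condition_means is None:
            self.condition_means = np.zeros((nc, nd))
        if self.trait_slopes is None:
            self.trait_slopes = np.zeros((nt, nc, nd))
        if self.covariate_betas is None:
            self.covariate_betas = np.zeros((3, nd))
        self.condition_means = np.asarray(self.condition_means, dtype=float)
        self.trait_slopes = np.asarray(self.trait_slopes, dtype=float)
        self.covariate_betas = np.asarray(self.covariate_betas, dtype=float)
        if self.condition_means.shape != (nc, nd):
            raise ValueError("condition_means must be (n_conditions, n_dims)")
        if self.trait_slopes.shape != (nt, nc, nd):
            raise ValueError("trait_slopes must be (n_traits, n_conditions, n_dims)")
        if self.covariate_betas.shape != (3, nd):
            raise ValueError("covariate_betas must be (3, n_dims) for age/gender/mean_fd")
        for name in ("sd_subject", "sd_family", "sd_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def null(cls, conditions=CONDITIONS, dims=DIMENSIONS, traits=TRAITS, **kw) -> "EffectSpec":
        """All fixed effects zero; variance components at their defaults."""
        return cls(conditions=conditions, dims=dims, traits=traits, **kw)

    def with_slope(self, trait: str, condition: str, dim: str, value: float) -> "EffectSpec":
        """Return a copy with one trait-by-condition slope planted."""
        slopes = self.trait_slopes.copy()
        slopes[self.traits.index(trait), self.conditions.index(condition), self.dims.index(dim)] = value
        return dataclasses.replace(self, trait_slopes=slopes)

    # -- structured-text round trip -------------------------------------
    def to_dict(self) -> dict:
        return {
            "conditions": list(self.conditions),
            "dims": list(self.dims),
            "traits": list(self.traits),
            "condition_means": self.condition_means.tolist(),
            "trait_slopes": self.trait_slopes.tolist(),
            "covariate_betas": self.covariate_betas.tolist(),
            "sd_subject": float(self.sd_subject),
            "sd_family": float(self.sd_family),
            "sd_noise": float(self.sd_noise),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EffectSpec":
        return cls(
            conditions=tuple(d["conditions"]),
            dims=tuple(d["dims"]),
            traits=tuple(d["traits"]),
            condition_means=np.asarray(d["condition_means"], dtype=float),
            trait_slopes=np.asarray(d["trait_slopes"], dtype=float),
            covariate_betas=np.asarray(d["covariate_betas"], dtype=float),
            sd_subject=d.get("sd_subject", DEFAULT_SD_SUBJECT),
            sd_family=d.get("sd_family", DEFAULT_SD_FAMILY),
            sd_noise=d.get("sd_noise", DEFAULT_SD_NOISE),
        )


@dataclass
class MapSet:
    """Per-(subject, condition) synthetic z-maps on a common vertex grid.

    ``data[condition]`` is an (n_vertices, n_subjects) matrix whose columns
    follow ``subjects``. ``targets`` holds the generator's ground-truth
    state-space locations (long table) when produced by :func:`generate_maps`.
    """

    subjects: tuple[str, ...]
    conditions: tuple[str, ...]
    data: dict[str, np.ndarray]
    n_vertices: int
    targets: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.subjects = tuple(self.subjects)
        self.conditions = tuple(self.conditions)
        for c, m in self.data.items():
            if m.shape != (self.n_vertices, len(self.subjects)):
                raise ValueError(
                    f"map matrix for {c!r} has shape {m.shape}, expected "
                    f"({self.n_vertices}, {len(self.subjects)})"
                )

    def get(self, subject: str, condition: str) -> np.ndarray:
        return self.data[condition][:, self.subjects.index(subject)]

    def items(self):
        for c in self.conditions:
            mat = self.data[c]
            for j, s in enumerate(self.subjects):
                yield (s, c), mat[:, j]


# ---------------------------------------------------------------------------
# gradient basis
# ---------------------------------------------------------------------------

def generate_gradients(
    n_vertices: int,
    n_dims: int = 3,
    smoothness: float = 0.1,
    seed: int = 0,
) -> GradientBasis:
    """Generate smooth, mutually decorrelated gradient maps.

    Each column starts as a sum of low-frequency sinusoids over the vertex
    index (max spatial frequency ~ 1/smoothness cycles over the grid), then
    columns are centered and orthogonalized (QR) so pairwise Pearson
    correlations are ~0, and standardized to unit variance.
    """
    if n_vertices < 10:
        raise ValueError("n_vertices must be >= 10")
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    if n_vertices < n_dims:
        raise ValueError("n_vertices must be >= n_dims")
    if not 0 < smoothness <= 1:
        raise ValueError("smoothness must be in (0, 1]")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, n_vertices)
    max_freq = max(2, int(round(1.0 / smoothness)))
    cols = []
    for _ in range(n_dims):
        freqs = rng.uniform(0.5, max_freq, size=6)
        phases = rng.uniform(0, 2 * np.pi, size=6)
        amps = rng.normal(1.0, 0.3, size=6)
        g = np.sum(amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * x + phases[:, None]), axis=0)
        cols.append(g)
    G = np.column_stack(cols)
    G = G - G.mean(axis=0)
    Q, R = np.linalg.qr(G)
    Q = Q * np.sign(np.diag(R))  # keep orientation of the raw fields
    G = Q / Q.std(axis=0)
    names = tuple(f"D{i + 1}" for i in range(n_dims))
    return GradientBasis(values=G, dim_names=names)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    n_subjects: int = DEFAULT_N_SUBJECTS,
    sibling_fraction: float = DEFAULT_SIBLING_FRACTION,
    trait_means: np.ndarray | None = None,
    trait_sds: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a family-structured cohort table.

    ~``sibling_fraction`` of subjects are paired into two-member families
    (emulating sibling pairs); the rest are singletons. Trait scores are
    independent normals (standardized by default), ages uniform on [22, 37]
    years, gender a balanced 0/1 indicator, and per-task mean framewise
    displacement log-normal (median ~0.15 mm).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0 <= sibling_fraction <= 1:
        raise ValueError("sibling_fraction must be in [0, 1]")
    trait_means = np.zeros(5) if trait_means is None else np.asarray(trait_means, dtype=float)
    trait_sds = np.ones(5) if trait_sds is None else np.asarray(trait_sds, dtype=float)
    if trait_means.shape != (5,) or trait_sds.shape != (5,):
        raise ValueError("trait_means and trait_sds must each have 5 entries")
    if np.any(trait_sds <= 0):
        raise ValueError("trait_sds must be positive")

    rng = np.random.default_rng(seed)
    n_pairs = int(round(n_subjects * sibling_fraction / 2.0))
    n_pairs = min(n_pairs, n_subjects // 2)
    # family ids: pairs first, then singletons
    family = np.empty(n_subjects, dtype=object)
    fam_idx = 0
    i = 0
    for _ in range(n_pairs):
        fid = f"F{fam_idx:05d}"
        family[i] = fid
        family[i + 1] = fid
        fam_idx += 1
        i += 2
    while i < n_subjects:
        family[i] = f"F{fam_idx:05d}"
        fam_idx += 1
        i += 1

    df = pd.DataFrame(
        {
            "subject_id": [f"S{j:05d}" for j in range(n_subjects)],
            "family_id": family,
            "age": rng.uniform(22.0, 37.0, size=n_subjects),
            "gender": rng.integers(0, 2, size=n_subjects),
        }
    )
    for k, trait in enumerate(TRAITS):
        df[trait] = rng.normal(trait_means[k], trait_sds[k], size=n_subjects)
    # head motion: log-normal, median 0.15 mm, right-skewed like real data
    for task in TASKS:
        df[f"mean_fd_{task}"] = np.exp(rng.normal(np.log(0.15), 0.35, size=n_subjects))
    return df


# ---------------------------------------------------------------------------
# ground-truth locations (shared by both generators)
# ---------------------------------------------------------------------------

def _target_locations(
    cohort: pd.DataFrame,
    effects: EffectSpec,
    conditions,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Long table of model-equation locations, one row per (subject, condition, dim)."""
    conditions = list(conditions)
    if not conditions:
        raise ValueError("conditions must be nonempty")
    check_conditions(conditions)
    missing = [c for c in conditions if c not in effects.conditions]
    if missing:
        raise ValueError(f"effects spec lacks conditions {missing}")

    n = len(cohort)
    dims = effects.dims
    nd = len(dims)
    traits_mat = cohort[list(effects.traits)].to_numpy()  # n x 5
    cov = np.column_stack(
        [
            cohort["age"].to_numpy(dtype=float),
            cohort["gender"].to_numpy(dtype=float),
            np.zeros(n),  # mean_fd handled per condition below
        ]
    )
    cov[:, 0] -= cov[:, 0].mean()
    cov[:, 1] -= cov[:, 1].mean()

    # random intercepts, per dimension
    fam_ids = cohort["family_id"].to_numpy()
    uniq_fams = pd.unique(fam_ids)
    u_fam = rng.normal(0.0, effects.sd_family, size=(len(uniq_fams), nd))
    fam_index = pd.Series(np.arange(len(uniq_fams)), index=uniq_fams)
    u_fam_rows = u_fam[fam_index[fam_ids].to_numpy()]
    u_sub = rng.normal(0.0, effects.sd_subject, size=(n, nd))

    frames = []
    for c in conditions:
        ci = effects.conditions.index(c)
        fd = cohort[f"mean_fd_{task_of(c)}"].to_numpy(dtype=float)
        cov_c = cov.copy()
        cov_c[:, 2] = fd - fd.mean()
        fixed = (
            effects.condition_means[ci][None, :]
            + traits_mat @ effects.trait_slopes[:, ci, :]
            + cov_c @ effects.covariate_betas
        )
        eps = rng.normal(0.0, effects.sd_noise, size=(n, nd))
        loc = fixed + u_sub + u_fam_rows + eps
        block = pd.DataFrame(
            {
                "subject_id": np.repeat(cohort["subject_id"].to_numpy(), nd),
                "family_id": np.repeat(fam_ids, nd),
                "condition": c,
                "dimension": np.tile(list(dims), n),
                "location": loc.ravel(),
                "age": np.repeat(cohort["age"].to_numpy(), nd),
                "gender": np.repeat(cohort["gender"].to_numpy(), nd),
                "mean_fd": np.repeat(fd, nd),
            }
        )
        for t in effects.traits:
            block[t] = np.repeat(cohort[t].to_numpy(), nd)
        frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    return out


def generate_coordinates(
    cohort: pd.DataFrame,
    effects: EffectSpec,
    conditions=CONDITIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw state-space coordinates directly from the linear mixed model.

    Bypasses map synthesis and projection entirely; used to calibrate the
    modelling stage free of projection error.
    """
    rng = np.random.default_rng(seed)
    return _target_locations(cohort, effects, conditions, rng)


# ---------------------------------------------------------------------------
# map synthesis
# ---------------------------------------------------------------------------

def rank_standardized(basis: GradientBasis) -> np.ndarray:
    """Rank-transform each gradient, z-score, and re-orthonormalize.

    The Spearman correlation of a map with gradient d is the Pearson
    correlation of their ranks, so maps built as linear combinations of
    these rank-standardized columns have projections approximately equal to
    their coefficients.
    """
    R = np.column_stack([rankdata(basis.values[:, j]) for j in range(basis.n_dims)])
    R = (R - R.mean(axis=0)) / R.std(axis=0)
    Q, Rm = np.linalg.qr(R)
    Q = Q * np.sign(np.diag(Rm))
    return Q / Q.std(axis=0)


def generate_maps(
    cohort: pd.DataFrame,
    basis: GradientBasis,
    effects: EffectSpec,
    conditions=CONDITIONS,
    seed: int = 0,
    vertex_noise: float = DEFAULT_VERTEX_NOISE,
) -> MapSet:
    """Synthesize per-subject per-condition maps realizing target locations.

    Each map is ``sum_d rho_d * G_d + a * eta + vertex_noise * eps`` where
    ``G`` is the rank-standardized basis, ``rho`` the model-equation target
    location, ``eta`` a subject/condition-specific smooth-free noise field
    orthogonalized against the basis and scaled so the map has ~unit
    variance (``a = sqrt(max(1 - |rho|^2, 0.01))``). With that calibration
    the Pearson (hence approximately Spearman) projection of the map onto
    gradient d equals rho_d up to rank-transform attenuation.
    """
    if len(effects.dims) != basis.n_dims:
        raise ValueError("effects dims and basis dims disagree")
    rng = np.random.default_rng(seed)
    targets = _target_locations(cohort, effects, conditions, rng)
    G = rank_standardized(basis)
    nv = basis.n_vertices
    subjects = tuple(cohort["subject_id"])
    n = len(subjects)
    dims = list(effects.dims)

    wide = targets.pivot_table(
        index=["subject_id", "condition"], columns="dimension", values="location", sort=False
    )[dims]
    data: dict[str, np.ndarray] = {}
    for c in conditions:
        rho = wide.xs(c, level="condition").loc[list(subjects)].to_numpy()  # n x nd
        eta = rng.standard_normal((nv, n))
        eta -= G @ (G.T @ eta) / nv  # orthogonalize against basis
        eta = (eta - eta.mean(axis=0)) / eta.std(axis=0)
        amp = np.sqrt(np.maximum(1.0 - np.sum(rho**2, axis=1), 0.01))
        m = G @ rho.T + eta * amp[None, :]
        if vertex_noise > 0:
            m = m + vertex_noise * rng.standard_normal((nv, n))
        data[c] = m
    return MapSet(
        subjects=subjects,
        conditions=tuple(conditions),
        data=data,
        n_vertices=nv,
        targets=targets,
    )
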