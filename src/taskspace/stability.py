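"""Bootstrap sign-stability analysis of context-specific associations.

For a flagged trait-by-condition interaction, the follow-up statistic is
the bivariate Pearson correlation between trait scores and a per-subject
divergence score: the difference of state-space locations of the two
conditions with the most strongly diverging associations along the flagged
dimension. Subjects are resampled with replacement 1000 times at each of a
ladder of log-spaced sample sizes (default 25..950 in 16 steps; 25..442 in
13 steps for the family-singleton variant), and the sample size at which
more than 95/99/100% of bootstrap estimates share the direction of the
full-sample estimate is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditions import EmptyResultError

__all__ = [
    "divergence_scores",
    "log_spaced_sizes",
    "bootstrap_stability",
    "stabilization_n",
    "StabilityResult",
]

logger = logging.getLogger(__name__)

DEFAULT_SIZES = (25, 950, 16)
SINGLETON_SIZES = (25, 442, 13)
DEFAULT_N_BOOT = 1000
COVERAGE_LEVELS = (0.95, 0.99, 1.0)


def divergence_scores(
    table: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    dimension: str,
    trait: str,
) -> pd.DataFrame:
    """Per-subject location difference cond_a - cond_b paired with a trait.

    Complete cases only: subjects observed in both conditions on the given
    dimension. Returns columns (subject_id, family_id, value, trait_value);
    swapping cond_a and cond_b negates value.
    """
    if cond_a == cond_b:
        raise ValueError("cond_a and cond_b must differ")
    sub = table[table["dimension"] == dimension]
    cols = ["subject_id", "family_id", "location", trait]
    a = sub[sub["condition"] == cond_a][cols].set_index("subject_id")
    b = sub[sub["condition"] == cond_b][["subject_id", "location"]].set_index("subject_id")
    both = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    if len(both) == 0:
        raise EmptyResultError(
            f"no subject observed in both {cond_a!r} and {cond_b!r} on {dimension}"
        )
    out = pd.DataFrame(
        {
            "subject_id": both.index,
            "family_id": both["family_id"].to_numpy(),
            "value": (both["location_a"] - both["location_b"]).to_numpy(),
            "trait_value": both[trait].to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def log_spaced_sizes(min_n: int, max_n: int, steps: int) -> list[int]:
    """Integer ladder: exp-linspace between the endpoints, deduplicated."""
    if steps < 2:
        raise ValueError("steps must be >= 2")
    if not 0 < min_n < max_n:
        raise ValueError("need 0 < min_n < max_n")
    raw = np.rint(np.exp(np.linspace(np.log(min_n), np.log(max_n), steps))).astype(int)
    raw[0], raw[-1] = min_n, max_n
    out: list[int] = []
    for s in raw:
        if s not in out:
            out.append(int(s))
    return out


@dataclass
class StabilityResult:
    """Bootstrap correlation distributions across the sample-size ladder."""

    sizes: tuple[int, ...]
    estimates: np.ndarray  # (n_sizes, n_boot)
    reference_r: float
    reference_sign: int
    bands: dict[float, np.ndarray] = field(default_factory=dict)  # level -> (n_sizes, 2)
    stabilization: dict[float, int | None] = field(default_factory=dict)
    n_redrawn: int = 0
    singleton: bool = False

    def to_dict(self) -> dict:
        return {
            "sizes": list(self.sizes),
            "reference_r": self.reference_r,
            "reference_sign": self.reference_sign,
            "bands": {
                str(level): [[float(lo), float(hi)] for lo, hi in band]
                for level, band in self.bands.items()
            },
            "same_sign_fraction": [
                float(np.mean(np.sign(row) == self.reference_sign))
                for row in self.estimates
            ],
            "stabilization": {str(k): v for k, v in self.stabilization.items()},
            "n_redrawn": self.n_redrawn,
            "singleton": self.singleton,
        }

    def estimates_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.sizes):
            rows.append(
                pd.DataFrame(
                    {"size": s, "iteration": np.arange(self.estimates.shape[1]),
                     "r": self.estimates[i]}
                )
            )
        return pd.concat(rows, ignore_index=True)


class _SingletonSampler:
    """Family-respecting bootstrap draws: at most one member per family.

    For every iteration one representative member is chosen uniformly per
    family, then families are drawn with replacement and contribute their
    representative. A family drawn twice contributes the same subject twice
    (ordinary bootstrap duplication); two *different* members of one family
    can never co-occur within an iteration.
    """

    def __init__(self, family_ids: np.ndarray):
        uniq, fam_code = np.unique(family_ids, return_inverse=True)
        members = [np.flatnonzero(fam_code == i) for i in range(len(uniq))]
        self.family_code = fam_code
        self.n_families = len(uniq)
        self.msize = np.array([len(m) for m in members])
        self.mpad = np.full((len(uniq), self.msize.max()), -1)
        for i, m in enumerate(members):
            self.mpad[i, : len(m)] = m

    def draw(self, rng: np.random.Generator, m: int, s: int) -> np.ndarray:
        rep = rng.integers(0, self.msize, size=(m, self.n_families))
        f = rng.integers(0, self.n_families, size=(m, s))
        pick = np.take_along_axis(rep, f, axis=1)
        return self.mpad[f, pick]


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r for matched (n_boot, s) matrices."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = np.sum(xc * yc, axis=1)
    den = np.sqrt(np.sum(xc**2, axis=1) * np.sum(yc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bootstrap_stability(
    scores: pd.DataFrame,
    sizes=None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    singleton: bool = False,
) -> StabilityResult:
    """Bootstrap the trait-divergence Pearson correlation across sample sizes.

    At each ladder size s and iteration, s subjects are drawn with
    replacement (singleton mode: s families with replacement, then one
    member of each drawn family uniformly at random, so no iteration ever
    contains two members of one family). Iterations with undefined r
    (degenerate draws) are redrawn and counted. Deterministic given seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if sizes is None:
        sizes = log_spaced_sizes(*(SINGLETON_SIZES if singleton else DEFAULT_SIZES))
    sizes = [int(s) for s in sizes]
    if sorted(sizes) != sizes or len(set(sizes)) != len(sizes):
        raise ValueError("sizes must be strictly increasing")
    vals = scores["value"].to_numpy(dtype=float)
    trait = scores["trait_value"].to_numpy(dtype=float)
    n = len(vals)
    if n < 3:
        raise EmptyResultError("need at least 3 subjects to bootstrap a correlation")

    ref_r = float(np.corrcoef(trait, vals)[0, 1])
    ref_sign = 1 if ref_r >= 0 else -1
    if ref_r == 0:
        logger.warning("full-sample correlation is exactly 0; reference sign set to +1")

    rng = np.random.default_rng(seed)
    if singleton:
        sampler = _SingletonSampler(scores["family_id"].to_numpy())
        draw_fn = lambda m, s: sampler.draw(rng, m, s)
    else:
        draw_fn = lambda m, s: rng.integers(0, n, size=(m, s))

    est = np.empty((len(sizes), n_boot))
    n_redrawn = 0
    for i, s in enumerate(sizes):
        draw = lambda m: draw_fn(m, s)
        idx = draw(n_boot)
        r = _pearson_rows(trait[idx], vals[idx])
        bad = ~np.isfinite(r)
        guard = 0
        while bad.any():
            n_redrawn += int(bad.sum())
            idx_new = draw(int(bad.sum()))
            r[bad] = _pearson_rows(trait[idx_new], vals[idx_new])
            bad = ~np.isfinite(r)
            guard += 1
            if guard > 100:
                raise EmptyResultError("bootstrap correlation undefined in all redraws")
        est[i] = r
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap iterations", n_redrawn)

    bands = {}
    for level in COVERAGE_LEVELS:
        tail = (1.0 - level) / 2.0 * 100.0
        lo = np.percentile(est, tail, axis=1)
        hi = np.percentile(est, 100.0 - tail, axis=1)
        bands[level] = np.column_stack([lo, hi])

    result = StabilityResult(
        sizes=tuple(sizes),
        estimates=est,
        reference_r=ref_r,
        reference_sign=ref_sign,
        bands=bands,
        n_redrawn=n_redrawn,
        singleton=singleton,
    )
    result.stabilization = {
        level: stabilization_n(result, level) for level in COVERAGE_LEVELS
    }
    return result


def stabilization_n(result: StabilityResult, coverage: float) -> int | None:
    """Smallest ladder size with sustained same-sign bootstrap fraction.

    Returns the smallest size s such that at s and every larger ladder size
    the fraction of bootstrap estimates sharing the full-sample sign is
    strictly greater than ``coverage``; None if no size qualifies.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    frac = np.mean(np.sign(result.estimates) == result.reference_sign, axis=1)
    ok = frac > coverage if coverage < 1 else frac >= 1.0
    ans = None
    for i in range(len(result.sizes) - 1, -1, -1):
        if ok[i]:
            ans = result.sizes[i]
        else:
            break
    return ans
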