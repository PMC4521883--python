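"""Cross-species developmental-rate scaling and dynamics conservation.

Two related species developing at different rates (heterochrony, e.g.
driven by different growth temperatures) are compared by (i) estimating
the constant rate ratio rho as the zero-intercept regression slope of
matched gene initiation times, (ii) rescaling one species' time axis by
rho and interpolating its profiles onto the reference species' measured
time points, (iii) normalizing each profile to percent-of-maximum within
the shared window, and (iv) scoring conservation of relative dynamics as
the per-gene Pearson correlation of the aligned, normalized profiles —
benchmarked against the same score for non-orthologous (random) gene
pairs.
"""

from __future__ import annotations

import itertools
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from .errors import AlignmentError, InsufficientDataError
from .types import ExpressionProfile
from .variability import zero_intercept_slope

__all__ = [
    "ScalingEstimate",
    "AlignedProfilePair",
    "estimate_rate_ratio",
    "rescale_and_align",
    "normalize_to_max",
    "align_pair",
    "dynamics_correlation",
    "random_pair_baseline",
]


@dataclass
class ScalingEstimate:
    """Zero-intercept slope of species-B initiation times on species-A ones.

    ``ratio`` is species-B time per species-A time (> 1 means A develops
    faster). ``r2`` is computed about the mean of the B times, so a plain
    proportional relation with scatter scores below 1.
    """

    ratio: float
    r2: float
    pearson: float
    n_genes: int
    excluded_genes: list[str] = field(default_factory=list)


@dataclass
class AlignedProfilePair:
    """One orthologue pair on the common (reference-species) grid,
    percent-of-maximum normalized, with its Pearson correlation."""

    gene_id: str
    times_common: np.ndarray
    norm_levels_a: np.ndarray
    norm_levels_b: np.ndarray
    pearson: float


def estimate_rate_ratio(
    t0_a: Mapping[str, float],
    t0_b: Mapping[str, float],
    exclude: Sequence[str] = (),
) -> ScalingEstimate:
    """Estimate the developmental rate ratio from matched initiation times.

    Parameters
    ----------
    t0_a, t0_b
        Per-gene initiation times (hours) for species A and B, keyed by
        gene. Only genes present in both with finite positive t0 are used.
    exclude
        Genes left out of the regression (e.g. genes whose temporal
        profiles indicate changed regulation); always an explicit list,
        never automatic.
    """
    exclude = set(exclude)
    genes = sorted(
        g
        for g in set(t0_a) & set(t0_b)
        if g not in exclude
        and np.isfinite(t0_a[g])
        and np.isfinite(t0_b[g])
    )
    if len(genes) < 3:
        raise InsufficientDataError(
            f"estimate_rate_ratio needs >= 3 matched genes, got {len(genes)}"
        )
    x = np.array([t0_a[g] for g in genes])
    y = np.array([t0_b[g] for g in genes])
    if np.any(x <= 0) or np.any(y <= 0):
        raise InsufficientDataError("initiation times must be positive")
    slope = zero_intercept_slope(x, y)
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return ScalingEstimate(
        ratio=slope,
        r2=r2,
        pearson=float(pearsonr(x, y)[0]),
        n_genes=len(genes),
        excluded_genes=sorted(exclude & (set(t0_a) & set(t0_b))),
    )


def rescale_and_align(
    profile_a: ExpressionProfile,
    profile_b: ExpressionProfile,
    ratio: float,
    floor: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map species-A onto species-B time and interpolate onto B's grid.

    Species-A times are multiplied by ``ratio``; A levels are linearly
    interpolated on the log10(level + floor) scale (dynamics span orders
    of magnitude) onto the species-B measured time points inside the
    overlap of the two windows, then back-transformed. Returns
    ``(times_common, levels_a_interp, levels_b)`` with raw (unnormalized)
    levels.
    """
    if not ratio > 0:
        raise AlignmentError(f"ratio must be positive, got {ratio}")
    scaled = profile_a.times * ratio
    lo = max(scaled.min(), profile_b.times.min())
    hi = min(scaled.max(), profile_b.times.max())
    mask = (profile_b.times >= lo) & (profile_b.times <= hi)
    if not mask.any():
        raise AlignmentError(
            f"{profile_a.gene_id}: no overlap between scaled A window "
            f"[{scaled.min():g}, {scaled.max():g}] and B window "
            f"[{profile_b.times.min():g}, {profile_b.times.max():g}]"
        )
    if floor is None:
        floor = profile_a.default_floor()
    log_a = np.log10(profile_a.levels + floor)
    interp = np.interp(profile_b.times[mask], scaled, log_a)
    levels_a = np.clip(10.0 ** interp - floor, 0.0, None)
    return profile_b.times[mask], levels_a, profile_b.levels[mask]


def normalize_to_max(levels) -> np.ndarray:
    """Percent-of-maximum normalization: 100 * level / max(level).

    Idempotent; raises on an all-zero vector.
    """
    v = np.asarray(levels, dtype=float)
    m = v.max() if v.size else 0.0
    if not m > 0:
        raise ValueError("normalize_to_max: maximum level must be positive")
    return 100.0 * v / m


def align_pair(
    profile_a: ExpressionProfile,
    profile_b: ExpressionProfile,
    ratio: float,
    gene_id: str | None = None,
) -> AlignedProfilePair:
    """Rescale, align and normalize one cross-species profile pair."""
    times, lev_a, lev_b = rescale_and_align(profile_a, profile_b, ratio)
    norm_a = normalize_to_max(lev_a)
    norm_b = normalize_to_max(lev_b)
    if len(times) < 3 or np.std(norm_a) == 0 or np.std(norm_b) == 0:
        r = float("nan")
    else:
        r = float(pearsonr(norm_a, norm_b)[0])
    return AlignedProfilePair(
        gene_id=gene_id or profile_a.gene_id,
        times_common=times,
        norm_levels_a=norm_a,
        norm_levels_b=norm_b,
        pearson=r,
    )


def dynamics_correlation(pairs: Sequence[AlignedProfilePair]) -> tuple[dict[str, float], float]:
    """Per-gene Pearson correlations and their unweighted mean.

    Pairs with a degenerate (flat) vector are flagged with a warning and
    excluded from the mean.
    """
    per_gene: dict[str, float] = {}
    valid = []
    for p in pairs:
        per_gene[p.gene_id] = p.pearson
        if np.isfinite(p.pearson):
            valid.append(p.pearson)
        else:
            warnings.warn(f"{p.gene_id}: degenerate aligned profile, excluded from mean")
    if not valid:
        raise InsufficientDataError("no valid aligned pairs")
    return per_gene, float(np.mean(valid))


def random_pair_baseline(
    profiles_a: Mapping[str, ExpressionProfile],
    profiles_b: Mapping[str, ExpressionProfile],
    ratio: float,
    mode: str = "exhaustive",
    n_pairs: int = 200,
    seed: int | None = None,
) -> float:
    """Mean correlation of non-orthologous cross-species pairs.

    The null level of dynamics similarity: every ordered pair (gene g in
    species A, gene h in species B) with g != h is aligned and scored
    exactly like the matched pairs. ``mode="exhaustive"`` (default) is
    deterministic; ``mode="sampled"`` draws ``n_pairs`` pairs with a
    seeded generator.
    """
    genes_a = sorted(profiles_a)
    genes_b = sorted(profiles_b)
    if len(genes_a) < 2 or len(genes_b) < 2:
        raise InsufficientDataError("random_pair_baseline needs >= 2 genes per species")
    all_pairs = [(g, h) for g, h in itertools.product(genes_a, genes_b) if g != h]
    if mode == "sampled":
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(all_pairs), size=min(n_pairs, len(all_pairs)), replace=False)
        chosen = [all_pairs[i] for i in idx]
    elif mode == "exhaustive":
        chosen = all_pairs
    else:
        raise ValueError(f"unknown mode {mode!r}")
    vals = []
    for g, h in chosen:
        try:
            pair = align_pair(profiles_a[g], profiles_b[h], ratio, gene_id=f"{g}~{h}")
        except AlignmentError:
            continue
        if np.isfinite(pair.pearson):
            vals.append(pair.pearson)
    if not vals:
        raise InsufficientDataError("no valid random pairs")
    return float(np.mean(vals))
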