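"""Core domain containers.

A :class:`CtRecord` is a single qPCR well measurement; an
:class:`ExpressionProfile` is one gene's absolute mRNA time course for one
biological repeat (or a per-species reference/average series). Times are
real-valued hours post fertilization (hpf).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Reserved gene_id carried by spike-in rows (known-quantity exogenous template).
SPIKE_ID = "SPIKE"


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: gene (or spike-in), time point, repeat, technical replicate, Ct."""

    gene_id: str
    time: float
    repeat_id: str
    tech_rep: int
    ct: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not np.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(f"ct must be finite and positive, got {self.ct!r}")
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"time must be finite and >= 0, got {self.time!r}")

    @property
    def is_spike(self) -> bool:
        return self.gene_id == SPIKE_ID


@dataclass
class ExpressionProfile:
    """Absolute mRNA copies per embryo sampled on a strictly increasing time grid.

    Parameters
    ----------
    gene_id, repeat_id
        Labels. ``repeat_id`` identifies the biological repeat, or a
        conventional label such as ``"mean"`` for an averaged series.
    times
        Hours post fertilization, strictly increasing.
    levels
        Non-negative mRNA copies per embryo, one per time point.
    tech_errors
        Optional propagated technical errors on the level scale.
    """

    gene_id: str
    repeat_id: str
    times: np.ndarray
    levels: np.ndarray
    tech_errors: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.times.ndim != 1 or self.levels.ndim != 1:
            raise ValueError("times and levels must be 1-D")
        if len(self.times) != len(self.levels):
            raise ValueError("times and levels must have equal length")
        if len(self.times) and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"times must be strictly increasing for {self.gene_id}")
        if np.any(self.levels < 0):
            raise ValueError(f"levels must be >= 0 for {self.gene_id}")
        if self.tech_errors is not None:
            self.tech_errors = np.asarray(self.tech_errors, dtype=float)
            if len(self.tech_errors) != len(self.times):
                raise ValueError("tech_errors length mismatch")

    def __len__(self) -> int:
        return len(self.times)

    def default_floor(self) -> float:
        """Pseudo-level added before log10: half the smallest positive level.

        Falls back to 1.0 for profiles without any positive level (callers
        normally reject those first).
        """
        pos = self.levels[self.levels > 0]
        return float(pos.min() / 2.0) if len(pos) else 1.0


def average_profiles(profiles: list[ExpressionProfile], repeat_id: str = "mean") -> ExpressionProfile:
    """Average biological repeats of one gene on their shared time points.

    Time points present in every repeat are kept; levels are averaged
    arithmetically (the convention used when plotting species-average
    time courses).
    """
    if not profiles:
        raise ValueError("no profiles to average")
    gene = profiles[0].gene_id
    if any(p.gene_id != gene for p in profiles):
        raise ValueError("average_profiles requires a single gene")
    common = profiles[0].times
    for p in profiles[1:]:
        common = np.intersect1d(common, p.times)
    if len(common) == 0:
        raise ValueError(f"no shared time points across repeats of {gene}")
    stacked = np.vstack([
        p.levels[np.isin(p.times, common)] for p in profiles
    ])
    return ExpressionProfile(gene, repeat_id, common, stacked.mean(axis=0))
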