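"""Sliding-window functional-group enrichment.

For a functional group *f*, let ``P_f`` be the fraction of valid
molecules inside a sliding window of the generation stream that contain
*f*, and ``P_tf`` the corresponding fraction in the (unlabelled)
training set. The monitored quantity is their ratio

    P_E(f) = P_f / P_tf

A high ``P_E`` means the generator produces the group far more often
than the training distribution would — i.e. it has learned to exploit
that group to raise its reward. Tracking ``P_E`` per window over the
whole stream exposes strategy changes (e.g. a late shift from diketones
and anilines toward quinones).

Conventions: fractions are computed over *valid* molecules only;
duplicate SMILES count each time they occur; windows are the half-open
index ranges ``(window_end - window_length, window_end]`` on the
0-based stream, advanced by ``stride``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import FunctionalGroupCatalog, MoleculeRecord

__all__ = [
    "TrainingProfile",
    "WindowEnrichment",
    "EnrichmentTrajectory",
    "training_profile",
    "window_fractions",
    "odds_ratio",
    "enrichment_trajectory",
    "whole_run_enrichment",
]


@dataclass(frozen=True)
class TrainingProfile:
    """Baseline per-group fractions ``P_tf`` over the training set."""

    n_training: int
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_training < 1:
            raise ValueError("training profile needs at least one valid molecule")
        for name, frac in self.fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction for {name!r} outside [0, 1]: {frac}")


@dataclass(frozen=True)
class WindowEnrichment:
    """Enrichment of every catalog group in one window."""

    window_end: int
    p_f: dict[str, float]
    p_e: dict[str, float]


@dataclass
class EnrichmentTrajectory:
    """Ordered windowed enrichment over a stream."""

    window_length: int
    stride: int
    points: list[WindowEnrichment]

    def to_frame(self, profile: TrainingProfile | None = None) -> pd.DataFrame:
        """Tidy export: one row per (window_end, group)."""
        rows = []
        for pt in self.points:
            for group, p_f in pt.p_f.items():
                rows.append(
                    {
                        "window_end": pt.window_end,
                        "group": group,
                        "p_f": p_f,
                        "p_tf": profile.fractions.get(group, np.nan) if profile else np.nan,
                        "p_e": pt.p_e[group],
                    }
                )
        return pd.DataFrame(rows, columns=["window_end", "group", "p_f", "p_tf", "p_e"])


def _flags_matrix(
    stream: Sequence[MoleculeRecord], names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(valid mask, n x G boolean presence matrix with False rows for invalid)."""
    n = len(stream)
    valid = np.zeros(n, dtype=bool)
    flags = np.zeros((n, len(names)), dtype=bool)
    for i, rec in enumerate(stream):
        if rec.valid:
            if rec.group_flags is None:
                raise ValueError(
                    f"record {rec.index} is not annotated; run annotate_stream first"
                )
            valid[i] = True
            flags[i] = [rec.group_flags[name] for name in names]
    return valid, flags


def training_profile(
    training: Sequence[MoleculeRecord], catalog: FunctionalGroupCatalog
) -> TrainingProfile:
    """Per-group baseline fractions over the valid training molecules."""
    valid, flags = _flags_matrix(training, catalog.names)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("training set contains no valid molecules")
    fractions = dict(zip(catalog.names, (flags.sum(axis=0) / n_valid).tolist()))
    return TrainingProfile(n_training=n_valid, fractions=fractions)


def window_fractions(
    stream: Sequence[MoleculeRecord],
    window_length: int,
    window_end: int,
) -> dict[str, float]:
    """Per-group fraction ``P_f`` over the window ``(window_end - L, window_end]``."""
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    start = window_end - window_length + 1
    if start < 0 or window_end >= len(stream):
        raise ValueError(
            f"window ({start}, {window_end}] not fully inside stream of "
            f"length {len(stream)}"
        )
    window = stream[start : window_end + 1]
    if not any(rec.valid for rec in window):
        raise ValueError(f"window ending at {window_end} has no valid molecules")
    names = _annotated_names(window)
    valid, flags = _flags_matrix(window, names)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError(f"window ending at {window_end} has no valid molecules")
    return dict(zip(names, (flags.sum(axis=0) / n_valid).tolist()))


def _annotated_names(stream: Sequence[MoleculeRecord]) -> list[str]:
    for rec in stream:
        if rec.valid and rec.group_flags is not None:
            return list(rec.group_flags)
    raise ValueError("no annotated valid record in window")


def odds_ratio(p_f: float, p_tf: float, pseudocount: float = 0.0) -> float:
    """The enrichment ratio ``P_E = P_f / P_tf``.

    With ``pseudocount`` ε > 0 returns ``(P_f + ε) / (P_tf + ε)`` (useful
    for plotting groups absent from the training set). With ε = 0 the
    plain ratio is returned; ``P_tf = 0`` with ``P_f > 0`` yields ``inf``
    with a warning, and 0/0 is defined as 1 (no enrichment signal).
    """
    if p_f < 0 or p_tf < 0 or pseudocount < 0:
        raise ValueError("fractions and pseudocount must be non-negative")
    if p_f > 1 or p_tf > 1:
        raise ValueError("fractions must lie in [0, 1]")
    if pseudocount > 0:
        return (p_f + pseudocount) / (p_tf + pseudocount)
    if p_tf == 0:
        if p_f == 0:
            return 1.0
        warnings.warn(
            "group absent from training set: P_E is infinite; "
            "consider a pseudocount for plotting",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf
    return p_f / p_tf


def enrichment_trajectory(
    stream: Sequence[MoleculeRecord],
    profile: TrainingProfile,
    catalog: FunctionalGroupCatalog,
    window_length: int = 100,
    stride: int = 1,
    pseudocount: float = 0.0,
) -> EnrichmentTrajectory:
    """Windowed ``P_E`` trajectories for every catalog group.

    Windows end at ``window_length - 1``, ``window_length - 1 + stride``,
    ... up to the last index that fits. Computed with cumulative counts,
    so cost is O(n · G) regardless of stride.
    """
    if window_length < 1 or stride < 1:
        raise ValueError("window_length and stride must be >= 1")
    n = len(stream)
    if n < window_length:
        raise ValueError(
            f"stream of length {n} shorter than window of {window_length}"
        )
    names = catalog.names
    valid, flags = _flags_matrix(stream, names)
    cum_valid = np.concatenate([[0], np.cumsum(valid)])
    cum_flags = np.vstack([np.zeros(len(names), dtype=np.int64), np.cumsum(flags, axis=0)])

    points: list[WindowEnrichment] = []
    for end in range(window_length - 1, n, stride):
        start = end - window_length + 1
        n_valid = int(cum_valid[end + 1] - cum_valid[start])
        if n_valid == 0:
            raise ValueError(f"window ending at {end} has no valid molecules")
        counts = cum_flags[end + 1] - cum_flags[start]
        p_f = dict(zip(names, (counts / n_valid).tolist()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p_e = {
                g: odds_ratio(p_f[g], profile.fractions[g], pseudocount) for g in names
            }
        points.append(WindowEnrichment(window_end=end, p_f=p_f, p_e=p_e))
    return EnrichmentTrajectory(window_length=window_length, stride=stride, points=points)


def whole_run_enrichment(
    stream: Sequence[MoleculeRecord],
    profile: TrainingProfile,
    catalog: FunctionalGroupCatalog,
    pseudocount: float = 0.0,
) -> dict[str, float]:
    """``P_E`` per group with the entire stream as a single window."""
    if not stream:
        raise ValueError("empty stream")
    p_f = window_fractions(stream, len(stream), len(stream) - 1)
    return {
        g: odds_ratio(p_f[g], profile.fractions[g], pseudocount)
        for g in catalog.names
    }


def whole_run_summary(
    stream: Sequence[MoleculeRecord],
    profile: TrainingProfile,
    catalog: FunctionalGroupCatalog,
) -> pd.DataFrame:
    """Run-level summary table: group, P_E, generated %, training %."""
    p_f = window_fractions(stream, len(stream), len(stream) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rows = [
            {
                "group": g,
                "p_e": odds_ratio(p_f[g], profile.fractions[g]),
                "generated_pct": 100.0 * p_f[g],
                "training_pct": 100.0 * profile.fractions[g],
            }
            for g in catalog.names
        ]
    return pd.DataFrame(rows, columns=["group", "p_e", "generated_pct", "training_pct"])
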