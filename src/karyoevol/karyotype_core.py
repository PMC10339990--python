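"""Karyotype morphometrics: relative length, centromeric index, Levan classes.

A karyogram here is the ordered haploid complement of one taxon, one record
per chromosome pair, each carrying the relative length (RL, percent of total
haploid karyotype length) and, for biarmed pairs, the centromeric index
(CI = short-arm length / total chromosome length x 100, range 0-50).

Chromosome morphology follows the Levan scheme: metacentric (m),
submetacentric (sm), subtelocentric (st) and telocentric (t), with class
boundaries at CI 37.5, 25.0 and 12.5. A CI sitting exactly on a boundary is
reported as a two-class token (e.g. ``st/sm``) rather than silently rounded
into one class, matching how boundary chromosomes are reported in the
cytogenetic literature.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MorphClass",
    "ChromosomePairRecord",
    "Karyogram",
    "KaryotypeState",
    "classify_ci",
    "arm_count",
    "diploid_number",
    "fundamental_number",
    "relative_lengths",
    "summarize",
    "BIARMED_CLASSES",
]

# Levan CI boundaries (percent of total chromosome length taken by the
# short arm): t < 12.5 < st < 25.0 < sm < 37.5 < m <= 50.
CI_BOUNDARY_T_ST = 12.5
CI_BOUNDARY_ST_SM = 25.0
CI_BOUNDARY_SM_M = 37.5

#: comparisons against the boundaries use this absolute tolerance so that a
#: CI arriving as 24.999999999999996 from float arithmetic still counts as
#: sitting on the 25.0 transition.
_BOUNDARY_ATOL = 1e-9


class MorphClass(str, enum.Enum):
    """Chromosome morphology classes plus boundary and unknown tokens."""

    M = "m"
    SM = "sm"
    ST = "st"
    T = "t"
    T_ST_BOUNDARY = "t/st"
    ST_SM_BOUNDARY = "st/sm"
    SM_M_BOUNDARY = "sm/m"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_boundary(self) -> bool:
        return self in (
            MorphClass.T_ST_BOUNDARY,
            MorphClass.ST_SM_BOUNDARY,
            MorphClass.SM_M_BOUNDARY,
        )

    @classmethod
    def parse(cls, token: str) -> "MorphClass":
        token = token.strip().lower()
        aliases = {
            "st_sm_boundary": cls.ST_SM_BOUNDARY,
            "t_st_boundary": cls.T_ST_BOUNDARY,
            "sm_m_boundary": cls.SM_M_BOUNDARY,
            "sm/st": cls.ST_SM_BOUNDARY,
            "m/sm": cls.SM_M_BOUNDARY,
            "st/t": cls.T_ST_BOUNDARY,
        }
        if token in aliases:
            return aliases[token]
        try:
            return cls(token)
        except ValueError:
            raise ValueError(f"unknown morphology token: {token!r}") from None


#: pure (non-boundary, non-unknown) classes, largest CI first
PURE_CLASSES = (MorphClass.M, MorphClass.SM, MorphClass.ST, MorphClass.T)
BIARMED_CLASSES = (MorphClass.M, MorphClass.SM, MorphClass.ST)


def classify_ci(ci: float) -> MorphClass:
    """Assign a Levan morphology class from a centromeric index.

    Parameters
    ----------
    ci
        Centromeric index in percent, short-arm / total length x 100.
        Must lie in [0, 50]; 50 is a perfectly median centromere.

    Returns
    -------
    MorphClass
        ``t``, ``st``, ``sm`` or ``m``; a CI exactly on one of the class
        boundaries (12.5, 25.0, 37.5) returns the corresponding two-class
        boundary token.
    """
    if not math.isfinite(ci) or ci < -_BOUNDARY_ATOL or ci > 50 + _BOUNDARY_ATOL:
        raise ValueError(
            f"centromeric index {ci!r} outside [0, 50]; "
            "CI is defined on the short arm"
        )
    for bound, token in (
        (CI_BOUNDARY_T_ST, MorphClass.T_ST_BOUNDARY),
        (CI_BOUNDARY_ST_SM, MorphClass.ST_SM_BOUNDARY),
        (CI_BOUNDARY_SM_M, MorphClass.SM_M_BOUNDARY),
    ):
        if abs(ci - bound) <= _BOUNDARY_ATOL:
            return token
    if ci < CI_BOUNDARY_T_ST:
        return MorphClass.T
    if ci < CI_BOUNDARY_ST_SM:
        return MorphClass.ST
    if ci < CI_BOUNDARY_SM_M:
        return MorphClass.SM
    return MorphClass.M


def arm_count(morph: MorphClass) -> int:
    """Arms contributed by one chromosome: telocentric 1, everything else 2.

    Boundary tokens involve at least one biarmed flanking class and the
    convention here (used for all printed fundamental numbers) is that they
    count as biarmed.
    """
    if morph is MorphClass.UNKNOWN:
        raise ValueError("cannot count arms of an unknown morphology")
    return 1 if morph is MorphClass.T else 2


@dataclass(frozen=True)
class ChromosomePairRecord:
    """One measured chromosome pair of a karyogram.

    rank 1 is the largest pair; ``rl_mean``/``rl_sd`` are percent of total
    haploid karyotype length, ``ci_mean``/``ci_sd`` percent short-arm share
    (absent for pairs whose CI was not measured, typically telocentrics).
    """

    rank: int
    rl_mean: float
    rl_sd: float = 0.0
    ci_mean: float | None = None
    ci_sd: float | None = None
    morph: MorphClass = MorphClass.UNKNOWN

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")
        if not self.rl_mean > 0:
            raise ValueError(f"rl_mean must be positive, got {self.rl_mean}")
        if self.rl_sd < 0:
            raise ValueError(f"rl_sd must be non-negative, got {self.rl_sd}")
        if (self.ci_mean is None) != (self.ci_sd is None):
            raise ValueError("ci_mean and ci_sd must be given together")
        if self.ci_mean is not None and not 0 <= self.ci_mean <= 50:
            raise ValueError(f"ci_mean {self.ci_mean} outside [0, 50]")

    def resolved_morph(self) -> MorphClass:
        """Morphology class, derived from ci_mean when not stated."""
        if self.morph is not MorphClass.UNKNOWN:
            return self.morph
        if self.ci_mean is not None:
            return classify_ci(self.ci_mean)
        return MorphClass.UNKNOWN


# printed RL columns are rounded to one decimal, so adjacent pairs may tie
# or cross by a rounding step; this is the allowed inversion per rank step
RL_MONOTONE_TOL = 0.35
# and the column sum may drift off 100 by accumulated rounding
RL_SUM_RANGE = (98.0, 102.0)


@dataclass
class Karyogram:
    """An ordered measured haploid complement for one taxon."""

    taxon: str
    pairs: list[ChromosomePairRecord]
    annotations: dict[str, str] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.pairs:
            raise ValueError(f"karyogram {self.taxon!r} has no chromosome pairs")
        ranks = [p.rank for p in self.pairs]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(
                f"karyogram {self.taxon!r}: ranks must be contiguous 1..n, got {ranks}"
            )
        rl = [p.rl_mean for p in self.pairs]
        for a, b in zip(rl, rl[1:]):
            if b > a + RL_MONOTONE_TOL:
                raise ValueError(
                    f"karyogram {self.taxon!r}: rl_mean increases by more than "
                    f"{RL_MONOTONE_TOL} between adjacent ranks ({a} -> {b})"
                )
        total = self.rl_sum()
        if not RL_SUM_RANGE[0] <= total <= RL_SUM_RANGE[1]:
            raise ValueError(
                f"karyogram {self.taxon!r}: rl_mean sum {total:.2f} outside "
                f"{RL_SUM_RANGE}"
            )

    def rl_sum(self) -> float:
        return float(sum(p.rl_mean for p in self.pairs))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def diploid_number(k: Karyogram) -> int:
    """2n: twice the number of haploid chromosome pairs."""
    if not k.pairs:
        raise ValueError("empty karyogram has no diploid number")
    return 2 * len(k.pairs)


@dataclass(frozen=True)
class KaryotypeState:
    """Abstract haploid karyotype: chromosome counts per morphology class.

    This is the unit the rearrangement engine evolves: sizes and ranks are
    deliberately discarded, only the (m, sm, st, t) composition remains.
    """

    m: int = 0
    sm: int = 0
    st: int = 0
    t: int = 0

    def __post_init__(self) -> None:
        for name in ("m", "sm", "st", "t"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name}={v!r} must be a non-negative integer")
        if self.n < 1:
            raise ValueError("karyotype state must contain at least one chromosome")

    @classmethod
    def from_counts(cls, counts: Mapping[MorphClass | str, int]) -> "KaryotypeState":
        kw = {"m": 0, "sm": 0, "st": 0, "t": 0}
        for key, v in counts.items():
            name = key.value if isinstance(key, MorphClass) else str(key)
            if name not in kw:
                raise ValueError(f"not a pure morphology class: {key!r}")
            kw[name] += int(v)
        return cls(**kw)

    @property
    def counts(self) -> dict[MorphClass, int]:
        return {
            MorphClass.M: self.m,
            MorphClass.SM: self.sm,
            MorphClass.ST: self.st,
            MorphClass.T: self.t,
        }

    @property
    def n(self) -> int:
        """Haploid chromosome number."""
        return self.m + self.sm + self.st + self.t

    @property
    def diploid_number(self) -> int:
        return 2 * self.n

    @property
    def n_biarmed(self) -> int:
        return self.m + self.sm + self.st

    @property
    def fundamental_number(self) -> int:
        """Diploid arm count: biarmed pairs contribute 4 arms, telocentric 2."""
        return 2 * (2 * self.n_biarmed + self.t)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.m, self.sm, self.st, self.t)

    def __str__(self) -> str:
        parts = [
            f"{name}:{v}"
            for name, v in zip(("m", "sm", "st", "t"), self.as_tuple())
            if v
        ]
        return "{" + ", ".join(parts) + "}"


def fundamental_number(k: Karyogram | KaryotypeState) -> int:
    """FN: total diploid arm count (2 x haploid arm sum).

    Telocentrics carry one arm; m/sm/st and the boundary tokens carry two.
    """
    if isinstance(k, KaryotypeState):
        return k.fundamental_number
    unknown = [p.rank for p in k.pairs if p.resolved_morph() is MorphClass.UNKNOWN]
    if unknown:
        raise ValueError(
            f"karyogram {k.taxon!r}: unresolved morphology at ranks {unknown}"
        )
    return 2 * sum(arm_count(p.resolved_morph()) for p in k.pairs)


def summarize(
    k: Karyogram, boundary_as: MorphClass = MorphClass.ST
) -> KaryotypeState:
    """Collapse a measured karyogram to abstract morphology-class counts.

    Boundary pairs (e.g. the ``st/sm`` first pair of B. antongilensis) are
    biarmed either way; by default they are tallied as subtelocentric, the
    lower flanking class. ``boundary_as`` overrides that choice.
    """
    if boundary_as not in PURE_CLASSES:
        raise ValueError("boundary_as must be a pure morphology class")
    counts = {c: 0 for c in PURE_CLASSES}
    unknown = [p.rank for p in k.pairs if p.resolved_morph() is MorphClass.UNKNOWN]
    if unknown:
        raise ValueError(
            f"karyogram {k.taxon!r}: unresolved morphology at ranks {unknown}"
        )
    for p in k.pairs:
        morph = p.resolved_morph()
        counts[boundary_as if morph.is_boundary else morph] += 1
    return KaryotypeState.from_counts(counts)


def relative_lengths(measurements: pd.DataFrame, taxon: str = "sample") -> Karyogram:
    """Build a karyogram from per-cell chromosome length measurements.

    Parameters
    ----------
    measurements
        Long table with columns ``cell_id``, ``rank``, ``length`` and
        optionally ``short_arm_length``; one row per chromosome per cell,
        lengths in arbitrary (per-cell) units.
    taxon
        Label for the resulting karyogram.

    Notes
    -----
    Per cell, RL = 100 x length / total cell length, so each cell's RL
    vector sums to exactly 100. Means and standard deviations are taken
    across cells per chromosome; output ranks are reassigned by descending
    mean RL (stable for ties). CI is computed as 100 x short-arm / length
    where short-arm lengths are provided; a CI below the measurement floor
    (identically zero across cells) is treated as telocentric with no CI
    column, matching how such pairs are reported.
    """
    required = {"cell_id", "rank", "length"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    if measurements.empty:
        raise ValueError("measurement table is empty")
    if (measurements["length"] <= 0).any():
        raise ValueError("chromosome lengths must be positive")

    df = measurements.copy()
    rank_sets = df.groupby("cell_id")["rank"].apply(frozenset)
    if rank_sets.nunique() != 1:
        raise ValueError(
            "cells report differing chromosome complements; refusing to impute"
        )
    counts = df.groupby("cell_id")["rank"].count()
    if counts.nunique() != 1 or len(rank_sets.iloc[0]) != counts.iloc[0]:
        raise ValueError("duplicate ranks within a cell")

    df["rl"] = 100.0 * df["length"] / df.groupby("cell_id")["length"].transform("sum")
    has_ci = "short_arm_length" in df.columns and df["short_arm_length"].notna().any()
    if has_ci:
        if df["short_arm_length"].isna().any():
            raise ValueError("short_arm_length must be given for all rows or none")
        df["ci"] = 100.0 * df["short_arm_length"] / df["length"]
        if (df["ci"] < 0).any() or (df["ci"] > 50 + 1e-9).any():
            raise ValueError("short arm longer than half the chromosome")

    n_cells = df["cell_id"].nunique()

    def _sd(x: pd.Series) -> float:
        return 0.0 if n_cells == 1 else float(x.std(ddof=1))

    stats = df.groupby("rank").agg(
        rl_mean=("rl", "mean"), rl_sd=("rl", _sd)
    )
    if has_ci:
        ci_stats = df.groupby("rank").agg(ci_mean=("ci", "mean"), ci_sd=("ci", _sd))
        stats = stats.join(ci_stats)
    # reassign ranks by descending mean RL, stable under ties
    order = np.argsort(-stats["rl_mean"].to_numpy(), kind="stable")
    stats = stats.iloc[order]

    pairs = []
    for new_rank, (_, row) in enumerate(stats.iterrows(), start=1):
        ci_mean = ci_sd = None
        if has_ci and row.get("ci_mean", 0.0) > 0.0:
            ci_mean = float(row["ci_mean"])
            ci_sd = float(row["ci_sd"])
        morph = classify_ci(ci_mean) if ci_mean is not None else (
            MorphClass.T if has_ci else MorphClass.UNKNOWN
        )
        pairs.append(
            ChromosomePairRecord(
                rank=new_rank,
                rl_mean=float(row["rl_mean"]),
                rl_sd=float(row["rl_sd"]),
                ci_mean=ci_mean,
                ci_sd=ci_sd,
                morph=morph,
            )
        )
    return Karyogram(taxon=taxon, pairs=pairs)
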