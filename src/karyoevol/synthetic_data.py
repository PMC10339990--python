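"""Seeded generators emulating the study's two data-generating processes.

``simulate_history`` evolves an abstract karyotype along a rooted tree under
independent per-branch Poisson event processes (one rate per event kind),
returning the full truth — tip states, internal-node states and per-branch
event lists — so recovery tests can compare reconstructions against what
actually happened.

``simulate_measurements`` emulates scoring metaphase plates: per cell and
chromosome it draws a length with multiplicative Gaussian noise around a
base proportional to the true relative length, and, for biarmed pairs, a
short-arm fraction with additive Gaussian noise around the true centromeric
index. Only ratios carry information, so the absolute length unit is
arbitrary; with both noise scales at zero the measured table round-trips the
(renormalised) truth exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .karyotype_core import BIARMED_CLASSES, PURE_CLASSES, Karyogram, KaryotypeState, MorphClass
from .rearrangement_engine import (
    Event,
    EventKind,
    EventModel,
    apply_event,
    node_labels,
)

__all__ = [
    "EvolutionSimConfig",
    "MeasurementSimConfig",
    "SimulatedHistory",
    "simulate_history",
    "simulate_measurements",
]

logger = logging.getLogger(__name__)


@dataclass
class EvolutionSimConfig:
    """Karyotype evolution along a tree: per-branch Poisson event counts.

    ``rates`` maps event kinds to the expected number of events per branch
    (branch lengths are not used; every branch draws from the same Poisson).
    Fusion products take ``fusion_target``; fission sources and the
    source/target classes of reclassification events are drawn uniformly
    among the applicable choices.
    """

    tree: object  # dendropy.Tree
    root_state: KaryotypeState
    rates: Mapping[EventKind | str, float] = field(default_factory=dict)
    seed: int = 0
    fusion_target: MorphClass = MorphClass.M

    def normalized_rates(self) -> dict[EventKind, float]:
        out = {k: 0.0 for k in EventKind}
        for key, v in self.rates.items():
            kind = key if isinstance(key, EventKind) else EventKind(str(key))
            if v < 0:
                raise ValueError(f"rate for {kind} must be non-negative")
            out[kind] += float(v)
        return out


@dataclass
class SimulatedHistory:
    """Full truth of one simulated history."""

    tip_states: dict[str, KaryotypeState]
    node_states: dict[str, KaryotypeState]
    branch_events: dict[tuple[str, str], tuple[Event, ...]]

    @property
    def total_events(self) -> int:
        return sum(len(evs) for evs in self.branch_events.values())

    def to_json_dict(self) -> dict:
        def state_d(s: KaryotypeState) -> dict:
            return {"m": s.m, "sm": s.sm, "st": s.st, "t": s.t}

        return {
            "tip_states": {k: state_d(v) for k, v in self.tip_states.items()},
            "node_states": {k: state_d(v) for k, v in self.node_states.items()},
            "branch_events": [
                {
                    "parent": p,
                    "child": c,
                    "events": [
                        {
                            "kind": ev.kind.value,
                            "source": ev.source.value if ev.source else None,
                            "target": ev.target.value if ev.target else None,
                        }
                        for ev in evs
                    ],
                }
                for (p, c), evs in self.branch_events.items()
            ],
            "total_events": self.total_events,
        }


def _applicable_kinds(s: KaryotypeState, kinds: list[EventKind]) -> list[EventKind]:
    out = []
    for k in kinds:
        if k is EventKind.CENTRIC_FUSION and s.t >= 2:
            out.append(k)
        elif k is EventKind.CENTRIC_FISSION and s.n_biarmed >= 1:
            out.append(k)
        elif k in (
            EventKind.PERICENTRIC_INVERSION,
            EventKind.CENTROMERE_REPOSITIONING,
        ):
            out.append(k)  # some chromosome always exists to reclassify
    return out


def _sample_event(
    s: KaryotypeState, kind: EventKind, cfg: EvolutionSimConfig, rng: np.random.Generator
) -> Event:
    if kind is EventKind.CENTRIC_FUSION:
        return Event(kind, target=cfg.fusion_target)
    if kind is EventKind.CENTRIC_FISSION:
        present = [c for c in BIARMED_CLASSES if s.counts[c] >= 1]
        return Event(kind, source=present[rng.integers(len(present))])
    present = [c for c in PURE_CLASSES if s.counts[c] >= 1]
    source = present[rng.integers(len(present))]
    targets = [c for c in PURE_CLASSES if c is not source]
    return Event(kind, source=source, target=targets[rng.integers(len(targets))])


def simulate_history(cfg: EvolutionSimConfig) -> SimulatedHistory:
    """Evolve karyotype states down the tree; pure function of the config.

    Per branch the event count is Poisson with mean equal to the summed
    rates, and event kinds are multinomial by rate. A sampled kind that is
    inapplicable in the current state (e.g. a fission with no biarmed
    element) is resampled among the applicable kinds, rate-weighted; if no
    sampled kind is applicable the event is dropped and logged, keeping
    per-branch counts near-Poisson without biasing the reachable space.
    """
    if cfg.root_state.n < 1:
        raise ValueError("root state must contain at least one chromosome")
    rates = cfg.normalized_rates()
    total_rate = sum(rates.values())
    kinds = [k for k, r in rates.items() if r > 0]
    rng = np.random.default_rng(cfg.seed)
    labels = node_labels(cfg.tree)

    node_states: dict[str, KaryotypeState] = {}
    tip_states: dict[str, KaryotypeState] = {}
    branch_events: dict[tuple[str, str], tuple[Event, ...]] = {}

    root = cfg.tree.seed_node
    node_states[labels[id(root)]] = cfg.root_state
    states_by_id = {id(root): cfg.root_state}
    for nd in cfg.tree.preorder_node_iter():
        if nd is root:
            if nd.is_leaf():
                tip_states[labels[id(nd)]] = cfg.root_state
            continue
        parent_state = states_by_id[id(nd.parent_node)]
        s = parent_state
        events: list[Event] = []
        n_events = int(rng.poisson(total_rate)) if total_rate > 0 else 0
        for _ in range(n_events):
            applicable = _applicable_kinds(s, kinds)
            if not applicable:
                logger.info(
                    "dropped an event on branch to %s: no applicable kind in %s",
                    labels[id(nd)],
                    s,
                )
                continue
            weights = np.array([rates[k] for k in applicable])
            kind = applicable[rng.choice(len(applicable), p=weights / weights.sum())]
            ev = _sample_event(s, kind, cfg, rng)
            s = apply_event(s, ev)
            events.append(ev)
        states_by_id[id(nd)] = s
        label = labels[id(nd)]
        node_states[label] = s
        branch_events[(labels[id(nd.parent_node)], label)] = tuple(events)
        if nd.is_leaf():
            tip_states[label] = s
    return SimulatedHistory(
        tip_states=tip_states, node_states=node_states, branch_events=branch_events
    )


@dataclass
class MeasurementSimConfig:
    """Noisy per-cell chromosome measurements around a true karyogram.

    ``length_cv`` is the coefficient of variation of per-chromosome lengths
    (multiplicative Gaussian noise, truncated positive); ``ci_sd`` the
    additive Gaussian sd, in CI percentage points, of the short-arm
    fraction of biarmed pairs. Zero noise reproduces the truth exactly.
    """

    truth: Karyogram
    n_cells: int = 10
    length_cv: float = 0.0
    ci_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.length_cv < 0 or self.ci_sd < 0:
            raise ValueError("noise scales must be non-negative")

    def normalized_truth_rl(self) -> np.ndarray:
        """True RL vector rescaled to sum exactly 100.

        Printed RL columns carry rounding, so their sum can drift off 100;
        any relative-length vector computed from measured lengths sums to
        100 exactly, and this is the scale recovery is judged on.
        """
        rl = np.array([p.rl_mean for p in self.truth.pairs], dtype=float)
        return 100.0 * rl / rl.sum()


def simulate_measurements(cfg: MeasurementSimConfig) -> pd.DataFrame:
    """Generate a per-cell measurement table from a true karyogram.

    Returns the long-format table with columns ``cell_id``, ``rank``,
    ``length`` and ``short_arm_length`` consumed by
    :func:`karyoevol.karyotype_core.relative_lengths`. Telocentric pairs
    (no recorded CI) get short arm 0.
    """
    rng = np.random.default_rng(cfg.seed)
    base = np.array([p.rl_mean for p in cfg.truth.pairs], dtype=float)
    ranks = np.array([p.rank for p in cfg.truth.pairs])
    ci = np.array(
        [p.ci_mean if p.ci_mean is not None else 0.0 for p in cfg.truth.pairs]
    )
    has_ci = np.array([p.ci_mean is not None for p in cfg.truth.pairs])
    rows = []
    for cell in range(1, cfg.n_cells + 1):
        factors = 1.0 + rng.normal(0.0, cfg.length_cv, size=base.size)
        # truncate at zero: redraw non-positive multipliers (rare unless the
        # cv is extreme), falling back to a small floor
        for _ in range(100):
            bad = factors <= 0
            if not bad.any():
                break
            factors[bad] = 1.0 + rng.normal(0.0, cfg.length_cv, size=int(bad.sum()))
        factors = np.clip(factors, 1e-6, None)
        lengths = base * factors
        frac = np.clip((ci + rng.normal(0.0, cfg.ci_sd, size=ci.size)) / 100.0, 0.0, 0.5)
        short = np.where(has_ci, frac * lengths, 0.0)
        for r, ln, sa in zip(ranks, lengths, short):
            rows.append((f"cell{cell:03d}", int(r), float(ln), float(sa)))
    return pd.DataFrame(
        rows, columns=["cell_id", "rank", "length", "short_arm_length"]
    )
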