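"""Behavioral skill scoring for the sequential visual isometric pinch task.

Each training block is summarized by the average movement time (*duration*,
seconds) and the fraction of target gates over- or undershot (*error rate*).
The block-level skill measure trades speed against accuracy on a log scale:

    skill = ln[ (1 - error_rate) / (error_rate * (ln duration)^b) ]

with b = 5.424 taken from the original parameterization of the task
(Reis-style speed-accuracy function). Skill learning is the difference in
the skill measure between the last and the first training block.

Two parameterizations of the duration term are in circulation,
``(ln duration)^b`` and ``(ln duration)/b``; the exponent reading is the
default and the divisor reading is selectable via
:class:`SkillParams.parameterization`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "BlockSummary",
    "BehavioralRecord",
    "SkillParams",
    "SkillDomainError",
    "error_rate_from_gates",
    "skill_measure",
    "skill_learning",
    "record_from_tables",
]


class SkillDomainError(ValueError):
    """Inputs outside the domain of the skill formula (duration <= 1 s, or an
    error rate pinned at 0/1 with boundary clamping disabled)."""


@dataclass(frozen=True)
class BlockSummary:
    """Per-block behavioral summary.

    mean_duration
        Average movement time across the trials of the block, in seconds.
    error_rate
        Fraction of gate events over- or undershot, in [0, 1].
    n_trials, n_gates_per_trial
        Used to form the gate-event denominator for boundary clamping.
    """

    mean_duration: float
    error_rate: float
    n_trials: int = 35
    n_gates_per_trial: int = 5

    def __post_init__(self) -> None:
        if self.mean_duration <= 0:
            raise ValueError(f"mean_duration must be positive, got {self.mean_duration}")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError(f"error_rate must lie in [0, 1], got {self.error_rate}")
        if self.n_trials < 1 or self.n_gates_per_trial < 1:
            raise ValueError("n_trials and n_gates_per_trial must be >= 1")

    @property
    def n_gate_events(self) -> int:
        return self.n_trials * self.n_gates_per_trial


@dataclass(frozen=True)
class BehavioralRecord:
    """Ordered training blocks for one subject."""

    blocks: tuple[BlockSummary, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if len(self.blocks) < 1:
            raise ValueError("a BehavioralRecord needs at least one block")


@dataclass(frozen=True)
class SkillParams:
    """Parameters of the skill formula.

    b_constant
        The constant 5.424 of the speed-accuracy trade-off.
    parameterization
        "exponent": error_rate * (ln duration)^b  (default);
        "divisor":  error_rate * (ln duration)/b.
    clamp_boundary_rates
        Replace error rates of exactly 0 or 1 by the half-count values
        1/(2G) and 1 - 1/(2G), G = total gate events of the block.
    """

    b_constant: float = 5.424
    parameterization: str = "exponent"
    clamp_boundary_rates: bool = True

    def __post_init__(self) -> None:
        if self.b_constant <= 0:
            raise ValueError("b_constant must be positive")
        if self.parameterization not in ("exponent", "divisor"):
            raise ValueError(
                f"parameterization must be 'exponent' or 'divisor', got {self.parameterization!r}"
            )


def error_rate_from_gates(outcomes: Iterable[int]) -> float:
    """Fraction of missed gates. ``outcomes`` holds one hit(0)/miss(1) flag
    per gate event of the block."""
    flags = [int(bool(o)) for o in outcomes]
    if not flags:
        raise ValueError("no gate events supplied")
    return sum(flags) / len(flags)


def _clamped_error_rate(block: BlockSummary, params: SkillParams) -> float:
    er = block.error_rate
    if er in (0.0, 1.0):
        if not params.clamp_boundary_rates:
            raise SkillDomainError(
                f"error_rate={er} makes the skill measure infinite; "
                "enable clamp_boundary_rates or supply an interior rate"
            )
        half = 1.0 / (2.0 * block.n_gate_events)
        er = half if er == 0.0 else 1.0 - half
    return er


def skill_measure(block: BlockSummary, params: SkillParams | None = None) -> float:
    """Block-level skill measure (dimensionless; higher = more skilled)."""
    params = params or SkillParams()
    if block.mean_duration <= 1.0:
        raise SkillDomainError(
            f"mean_duration must exceed 1 s so that ln(duration) > 0, got {block.mean_duration}"
        )
    er = _clamped_error_rate(block, params)
    log_dur = math.log(block.mean_duration)
    if params.parameterization == "exponent":
        denom = er * log_dur**params.b_constant
    else:
        denom = er * log_dur / params.b_constant
    return math.log((1.0 - er) / denom)


def skill_learning(record: BehavioralRecord, params: SkillParams | None = None) -> float:
    """Skill learning: skill measure of the last block minus the first."""
    if len(record.blocks) < 2:
        raise ValueError("skill learning needs at least two blocks")
    return skill_measure(record.blocks[-1], params) - skill_measure(record.blocks[0], params)


def record_from_tables(trials: pd.DataFrame, gates: pd.DataFrame) -> BehavioralRecord:
    """Build a :class:`BehavioralRecord` from trial- and gate-level tables.

    ``trials`` needs columns (block, trial, duration_s); ``gates`` needs
    (block, gate_index, miss). Block labels must match between tables.
    """
    blocks: list[BlockSummary] = []
    trial_groups = trials.groupby("block", sort=True)
    gate_groups = dict(iter(gates.groupby("block", sort=True)))
    for block_id, tgrp in trial_groups:
        if block_id not in gate_groups:
            raise ValueError(f"block {block_id!r} present in trials but not in gates")
        ggrp = gate_groups[block_id]
        n_trials = tgrp["trial"].nunique()
        n_gates = len(ggrp) // n_trials if n_trials else 0
        blocks.append(
            BlockSummary(
                mean_duration=float(tgrp["duration_s"].mean()),
                error_rate=error_rate_from_gates(ggrp["miss"].tolist()),
                n_trials=int(n_trials),
                n_gates_per_trial=max(int(n_gates), 1),
            )
        )
    return BehavioralRecord(blocks=tuple(blocks))
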