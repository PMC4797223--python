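"""Eligibility, stratified permuted-block randomization, and power analysis.

The trial enrolls adults (18–70 y) with chronic (≥ 3 months) tonal tinnitus
between 1 and 12 kHz and at most 70 dB HL hearing loss in the half-octave
band around the tinnitus frequency. Allocation is stratified by age
(< 51 vs ≥ 51 years) and hearing loss (< 40 vs ≥ 40 dB) — four strata —
with 1:1 permuted-block randomization (block size 4) within each stratum.

Sample size follows the repeated-measures within-between-interaction
convention of G*Power 3: for k groups and m measurements with
repeated-measures correlation ρ and nonsphericity ε, the interaction F test
has df1 = (k−1)(m−1)·ε, df2 = (N−k)(m−1)·ε, and noncentrality
λ = N·f²·m/(1−ρ)·ε. With f = 0.25, α = .05, power .90, k = m = 2, ρ = 0
this yields a total N of 88, which the trial inflated to 100 for dropouts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Participant",
    "Stratum",
    "Allocation",
    "PowerConfig",
    "ARMS",
    "screen",
    "stratify",
    "randomize",
    "power_at",
    "sample_size_rm_interaction",
]

ARMS = ("treatment", "placebo")

AGE_RANGE = (18, 70)
AGE_STRATUM_CUT = 51
HL_STRATUM_CUT_DB = 40.0
MAX_HL_DB = 70.0
TINNITUS_RANGE_HZ = (1000.0, 12000.0)
MIN_CHRONICITY_MONTHS = 3.0

#: Exclusion-criterion flags; True means the criterion applies (excluded).
EXCLUSION_FLAGS = (
    "mental_or_neurological_disorder",
    "otological_disease",
    "substance_use",
    "concurrent_therapy",
)


@dataclass(frozen=True)
class Participant:
    id: str
    age: float
    hearing_loss_db: float  # max HL in the ±½-octave band around the tinnitus pitch
    tinnitus_hz: float
    chronicity_months: float
    mental_or_neurological_disorder: bool = False
    otological_disease: bool = False
    substance_use: bool = False
    concurrent_therapy: bool = False
    consent: bool = True

    def __post_init__(self):
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.hearing_loss_db < 0:
            raise ValueError("hearing_loss_db must be non-negative")


@dataclass(frozen=True)
class Stratum:
    age_class: str  # "under51" | "at_least_51"
    hl_class: str   # "under40" | "at_least_40"

    def __post_init__(self):
        if self.age_class not in ("under51", "at_least_51"):
            raise ValueError("invalid age_class")
        if self.hl_class not in ("under40", "at_least_40"):
            raise ValueError("invalid hl_class")

    @property
    def label(self) -> str:
        return f"{self.age_class}/{self.hl_class}"


ALL_STRATA = tuple(
    Stratum(a, h)
    for a in ("under51", "at_least_51")
    for h in ("under40", "at_least_40")
)


@dataclass(frozen=True)
class Allocation:
    participant_id: str
    stratum: Stratum
    arm: str
    block_index: int
    position_in_block: int


@dataclass(frozen=True)
class PowerConfig:
    effect_f: float = 0.25
    alpha: float = 0.05
    target_power: float = 0.90
    groups: int = 2
    measurements: int = 2
    rm_correlation: float = 0.0
    nonsphericity: float = 1.0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.target_power < 1):
            raise ValueError("target_power must be in (0, 1)")
        if self.effect_f <= 0:
            raise ValueError("effect_f must be positive")
        if not (0 <= self.rm_correlation < 1):
            raise ValueError("rm_correlation must be in [0, 1)")
        if self.groups < 2 or self.measurements < 2:
            raise ValueError("need at least 2 groups and 2 measurements")
        if not (0 < self.nonsphericity <= 1):
            raise ValueError("nonsphericity must be in (0, 1]")


def screen(p: Participant) -> tuple[bool, list[str]]:
    """Apply the inclusion/exclusion criteria; returns (eligible, reasons).

    ``reasons`` lists every failed criterion (empty when eligible).
    """
    reasons = []
    if p.chronicity_months < MIN_CHRONICITY_MONTHS:
        reasons.append("chronicity")
    lo, hi = TINNITUS_RANGE_HZ
    if not (lo <= p.tinnitus_hz <= hi):
        reasons.append("pitch")
    if p.hearing_loss_db > MAX_HL_DB:
        reasons.append("hearing_loss")
    if not (AGE_RANGE[0] <= p.age <= AGE_RANGE[1]):
        reasons.append("age")
    for flag in EXCLUSION_FLAGS:
        if getattr(p, flag):
            reasons.append(flag)
    if not p.consent:
        reasons.append("consent")
    return (not reasons, reasons)


def stratify(p: Participant) -> Stratum:
    """Stratum from age and hearing loss; 51 y and 40 dB go to the upper classes."""
    return Stratum(
        age_class="at_least_51" if p.age >= AGE_STRATUM_CUT else "under51",
        hl_class="at_least_40" if p.hearing_loss_db >= HL_STRATUM_CUT_DB else "under40",
    )


def permuted_block(block_size: int, rng: np.random.Generator) -> list[str]:
    """One random balanced block: equal counts of each arm, random order."""
    if block_size % 2 != 0:
        raise ValueError("block_size must be even for 1:1 allocation")
    block = list(ARMS) * (block_size // 2)
    rng.shuffle(block)
    return block


def randomize(roster: list[Participant], block_size: int = 4,
              seed: int | np.random.Generator = 0) -> list[Allocation]:
    """Stratified permuted-block randomization over an eligible roster.

    Each stratum gets an independent block sequence; within a stratum,
    participants are assigned in roster order. Every completed block
    contains exactly half of each arm.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if block_size % 2 != 0:
        raise ValueError("block_size must be even for 1:1 allocation")
    # one independent generator per stratum so sequences do not interleave
    stratum_rng = {s: np.random.default_rng(rng.integers(2 ** 31)) for s in ALL_STRATA}
    counters: dict[Stratum, int] = {s: 0 for s in ALL_STRATA}
    blocks: dict[Stratum, list[str]] = {s: [] for s in ALL_STRATA}
    out = []
    for p in roster:
        s = stratify(p)
        pos = counters[s]
        if pos % block_size == 0:
            blocks[s] = permuted_block(block_size, stratum_rng[s])
        out.append(Allocation(
            participant_id=p.id,
            stratum=s,
            arm=blocks[s][pos % block_size],
            block_index=pos // block_size,
            position_in_block=pos % block_size,
        ))
        counters[s] = pos + 1
    return out


def power_at(cfg: PowerConfig, n_total: int) -> float:
    """Power of the Session×Group interaction F test at total sample size N."""
    k, m = cfg.groups, cfg.measurements
    if n_total < 2 * k:
        raise ValueError("need at least 2 participants per group")
    eps = cfg.nonsphericity
    df1 = (k - 1) * (m - 1) * eps
    df2 = (n_total - k) * (m - 1) * eps
    lam = n_total * cfg.effect_f ** 2 * m / (1.0 - cfg.rm_correlation) * eps
    f_crit = stats.f.isf(cfg.alpha, df1, df2)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def sample_size_rm_interaction(cfg: PowerConfig, n_max: int = 10000) -> int:
    """Smallest balanced total N (multiple of k) reaching the target power."""
    k = cfg.groups
    for n in range(2 * k, n_max + 1, k):
        if power_at(cfg, n) >= cfg.target_power:
            return n
    raise ValueError(
        f"target power {cfg.target_power} not reached by N = {n_max}; "
        "the effect size may be too small"
    )


def balanced_block_arrangements(block_size: int = 4) -> list[tuple[str, ...]]:
    """All distinct balanced arm orderings of one block (6 for size 4)."""
    base = list(ARMS) * (block_size // 2)
    return sorted(set(itertools.permutations(base)))
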