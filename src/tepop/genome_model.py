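"""Simulated genome layout, parameterization, rescaling and scenario presets.

The simulated system is a 4 Mb fragment of a large (1.78 Gb) genome evolving in a
Wright-Fisher population of one million diploids.  The fragment is split 1:2:1 into
high / low / high recombination regions; high-recombination regions carry twice the
coding density.  Because a population of 10^6 diploids cannot be iterated forward
directly, all parameters are rescaled by a factor ``lambda`` that preserves the
population-scaled compound parameters (theta = 4*N*mu, the map length, and 2*N*s for
every selection class) while shrinking the population and the run length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "SelectionClass",
    "SelectionClassTable",
    "TEParams",
    "RawParams",
    "SimParams",
    "Region",
    "GenomeLayout",
    "build_layout",
    "rescale_parameters",
    "unrescale_parameters",
    "fragment_insertion_rate",
    "scenario_preset",
    "SCENARIO_NAMES",
]

Context = Literal["coding", "noncoding"]


@dataclass(frozen=True)
class SelectionClass:
    """One fitness class for new point mutations.

    ``fraction`` is the probability that a new mutation arising in ``context``
    belongs to this class; the per-context remainder is neutral.  ``two_N_s`` is the
    population-scaled selection coefficient 2*N_e*s (invariant under rescaling).
    """

    context: Context
    fraction: float
    two_N_s: float
    dominance: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must be a probability, got {self.fraction}")
        if not math.isfinite(self.two_N_s):
            raise ValueError("two_N_s must be finite")


@dataclass(frozen=True)
class SelectionClassTable:
    classes: tuple[SelectionClass, ...]

    def __post_init__(self) -> None:
        for ctx in ("coding", "noncoding"):
            tot = sum(c.fraction for c in self.for_context(ctx))
            if tot > 1.0 + 1e-12:
                raise ValueError(f"selected fractions for {ctx} sum to {tot} > 1")

    def for_context(self, context: Context) -> tuple[SelectionClass, ...]:
        return tuple(c for c in self.classes if c.context == context)

    def neutral_fraction(self, context: Context) -> float:
        return 1.0 - sum(c.fraction for c in self.for_context(context))


def default_selection_table() -> SelectionClassTable:
    """Reference fitness classes: 70% of coding mutations at 2Ns=-100, 10% of
    non-coding mutations at 2Ns=-10, the remainder neutral."""
    return SelectionClassTable(
        (
            SelectionClass("coding", 0.70, -100.0),
            SelectionClass("noncoding", 0.10, -10.0),
        )
    )


@dataclass(frozen=True)
class TEParams:
    """Transposition process parameters.

    ``P`` is the TOTAL genome-wide insertion rate per diploid individual per
    generation summed over the ``n_progenitors`` source elements.  ``Q`` is the
    probability that a new insertion lands in the high-recombination region class
    (0.5 reproduces per-bp uniformity because both classes total the same length).
    Burst mode multiplies ``P`` by ``burst_multiplier`` inside a bounded window and
    sets it to zero outside; constant mode applies ``P`` throughout.
    """

    n_progenitors: int = 10
    P: float = 1.0e-3
    burst_multiplier: float = 100.0
    burst_start_years_ago: float = 1_000_000.0
    burst_duration_years: float = 100_000.0
    constant_mode: bool = True
    Q: float = 0.5
    two_N_s_short: float = -0.1
    two_N_s_long_high: float = -10.0
    two_N_s_long_low: float = -1.0
    two_N_s_coding: float = -2000.0
    p_long: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.Q <= 1.0:
            raise ValueError(f"Q must be in [0,1], got {self.Q}")
        if not 0.0 <= self.p_long <= 1.0:
            raise ValueError("p_long must be a probability")
        if self.P < 0:
            raise ValueError("P must be >= 0")


@dataclass(frozen=True)
class RawParams:
    """Unscaled parameterization (generation time = 1 year)."""

    N_e: int = 1_000_000
    mu: float = 2.1e-10
    rec_high: float = 2.0e-10
    rec_low: float = 2.0e-11
    coding_density_high: float = 20_000.0  # coding bp per Mb
    coding_density_low: float = 10_000.0
    exon_length: int = 160
    fragment_length: int = 4_000_000
    genome_length: float = 1.78e9
    selection_classes: SelectionClassTable = field(default_factory=default_selection_table)
    te_params: TEParams = field(default_factory=TEParams)
    generations_unscaled: float = 2.0e7
    sample_diploids: int = 8
    replicates: int = 100

    def __post_init__(self) -> None:
        for name in ("mu", "rec_high", "rec_low"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("coding_density_high", "coding_density_low"):
            if not 0 <= getattr(self, name) <= 1e6:
                raise ValueError(f"{name} must be in [0, 1e6] bp/Mb")
        if self.fragment_length % 4 != 0:
            raise ValueError("fragment_length must divide into 1:2:1 regions")
        if self.fragment_length > self.genome_length:
            raise ValueError("fragment_length exceeds genome_length")


@dataclass(frozen=True)
class SimParams:
    """Fully rescaled parameterization ready to run.

    All per-bp rates carry the rescaling factor; N and the generation count are
    divided by it.  Per-class selection coefficients ``s`` satisfy
    2 * N_scaled * s == two_N_s exactly.
    """

    raw: RawParams
    lam: float
    N_scaled: int
    mu_scaled: float
    rec_high_scaled: float
    rec_low_scaled: float
    generations_scaled: int
    P_scaled: float
    burst_start_gen: int  # scaled generation at which the burst opens
    burst_end_gen: int    # half-open [start, end)
    tracked_neutral_fraction: float = 1.0
    seed: int | None = None

    @property
    def fragment_length(self) -> int:
        return self.raw.fragment_length

    @property
    def te_params(self) -> TEParams:
        return self.raw.te_params

    @property
    def selection_classes(self) -> SelectionClassTable:
        return self.raw.selection_classes

    def s_of(self, two_N_s: float) -> float:
        """Selection coefficient at the scaled population size."""
        return two_N_s / (2.0 * self.N_scaled)


def rescale_parameters(
    raw: RawParams,
    lam: float = 1000.0,
    *,
    tracked_neutral_fraction: float = 1.0,
    seed: int | None = None,
) -> SimParams:
    """Rescale by ``lam``: multiply mu, recombination and transposition rates by
    ``lam``; divide N and generation counts by ``lam``.  This preserves theta=4*N*mu,
    the population map length and every 2*N*s product.

    Burst timing: the burst opens ``burst_start_years_ago`` years (== unscaled
    generations; annual breeder) before the end of the run and lasts
    ``burst_duration_years``; both convert to scaled generations by dividing by lam.
    """
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    N_scaled = raw.N_e / lam
    if abs(N_scaled - round(N_scaled)) > 1e-9:
        raise ValueError(f"N_e={raw.N_e} not divisible by lambda={lam}")
    N_scaled = int(round(N_scaled))
    gens = raw.generations_unscaled / lam
    if abs(gens - round(gens)) > 1e-6:
        raise ValueError("generations_unscaled not divisible by lambda")
    gens = int(round(gens))

    te = raw.te_params
    g_end = gens
    b_start = g_end - te.burst_start_years_ago / lam
    b_end = b_start + te.burst_duration_years / lam
    if not te.constant_mode and b_start < 0:
        raise ValueError("burst window does not fit within the run")

    return SimParams(
        raw=raw,
        lam=lam,
        N_scaled=N_scaled,
        mu_scaled=raw.mu * lam,
        rec_high_scaled=raw.rec_high * lam,
        rec_low_scaled=raw.rec_low * lam,
        generations_scaled=gens,
        P_scaled=te.P * lam,
        burst_start_gen=int(round(b_start)),
        burst_end_gen=int(round(b_end)),
        tracked_neutral_fraction=tracked_neutral_fraction,
        seed=seed,
    )


def unrescale_parameters(params: SimParams) -> RawParams:
    """Invert :func:`rescale_parameters` (round-trip identity on RawParams)."""
    return params.raw


def fragment_insertion_rate(
    te: TEParams, fragment_length: float, genome_length: float
) -> float:
    """Per-diploid per-generation insertion rate into the fragment (before any burst
    multiplier): P * fragment_length / genome_length."""
    if fragment_length > genome_length:
        raise ValueError("fragment_length exceeds genome_length")
    return te.P * fragment_length / genome_length


@dataclass(frozen=True)
class Region:
    start: int
    end: int  # half-open
    rec_rate: float  # per bp per generation, already scaled
    klass: Literal["high", "low"]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeLayout:
    """Region tiling and exon intervals of the simulated fragment.

    ``exon_starts``/``exon_ends`` are sorted, non-overlapping, half-open, and each
    exon lies fully within one region.
    """

    fragment_length: int
    regions: tuple[Region, ...]
    exon_starts: np.ndarray
    exon_ends: np.ndarray

    def region_class_of(self, pos: np.ndarray) -> np.ndarray:
        """Vectorized region class lookup: True where ``pos`` is in a high region."""
        bounds = np.array([r.end for r in self.regions[:-1]])
        idx = np.searchsorted(bounds, pos, side="right")
        is_high = np.array([r.klass == "high" for r in self.regions])
        return is_high[idx]

    def in_exon(self, pos: np.ndarray) -> np.ndarray:
        """Vectorized exon-membership test for integer positions."""
        pos = np.asarray(pos)
        if self.exon_starts.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(self.exon_starts, pos, side="right") - 1
        idx_clip = np.clip(idx, 0, None)
        return (idx >= 0) & (pos < self.exon_ends[idx_clip])

    def high_length(self) -> int:
        return sum(r.length for r in self.regions if r.klass == "high")

    def low_length(self) -> int:
        return sum(r.length for r in self.regions if r.klass == "low")

    def class_intervals(self, klass: str) -> list[tuple[int, int]]:
        return [(r.start, r.end) for r in self.regions if r.klass == klass]

    def exon_bp_in(self, start: int, end: int) -> int:
        if self.exon_starts.size == 0:
            return 0
        s = np.maximum(self.exon_starts, start)
        e = np.minimum(self.exon_ends, end)
        return int(np.maximum(e - s, 0).sum())


def _place_exons(
    rng: np.random.Generator,
    region_start: int,
    region_end: int,
    target_bp: float,
    exon_length: int,
) -> list[tuple[int, int]]:
    """Place non-overlapping exons uniformly at random until cumulative exon bp
    reaches ``target_bp`` (accepting an overshoot of < one exon)."""
    if target_bp <= 0:
        return []
    region_len = region_end - region_start
    n_needed = math.ceil(target_bp / exon_length)
    # random sequential placement jams near ~75% packing (Renyi's constant);
    # refuse targets anywhere close, where the rejection loop would not finish
    if n_needed * exon_length > 0.65 * region_len:
        raise ValueError(
            f"coding density infeasible: {n_needed} exons of {exon_length} bp "
            f"cannot be placed at random without overlap in a "
            f"{region_len} bp region"
        )
    placed: list[tuple[int, int]] = []
    starts = np.empty(0, dtype=np.int64)
    total = 0
    attempts = 0
    max_attempts = 1000 * n_needed + 1000
    while total < target_bp:
        cand = int(rng.integers(region_start, region_end - exon_length + 1))
        # reject overlap with any placed exon
        i = np.searchsorted(starts, cand)
        ok = True
        if i > 0 and starts[i - 1] + exon_length > cand:
            ok = False
        if i < starts.size and cand + exon_length > starts[i]:
            ok = False
        if ok:
            starts = np.insert(starts, i, cand)
            placed.append((cand, cand + exon_length))
            total += exon_length
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("exon placement failed: density infeasible")
    placed.sort()
    return placed


def build_layout(params: SimParams, rng: np.random.Generator) -> GenomeLayout:
    """Construct the 1:2:1 high/low/high region tiling and randomly place exons to
    the per-region coding-density targets."""
    raw = params.raw
    L = raw.fragment_length
    q = L // 4
    regions = (
        Region(0, q, params.rec_high_scaled, "high"),
        Region(q, 3 * q, params.rec_low_scaled, "low"),
        Region(3 * q, L, params.rec_high_scaled, "high"),
    )
    exons: list[tuple[int, int]] = []
    for r in regions:
        density = raw.coding_density_high if r.klass == "high" else raw.coding_density_low
        target = density * r.length / 1e6
        exons.extend(_place_exons(rng, r.start, r.end, target, raw.exon_length))
    exons.sort()
    starts = np.array([s for s, _ in exons], dtype=np.int64)
    ends = np.array([e for _, e in exons], dtype=np.int64)
    return GenomeLayout(L, regions, starts, ends)


def _preset_fig9(q: float, burst: bool) -> RawParams:
    return RawParams(
        te_params=TEParams(Q=q, constant_mode=not burst),
        selection_classes=default_selection_table(),
    )


_PRESETS = {
    "fig9A": lambda: _preset_fig9(0.5, burst=False),
    "fig9B": lambda: _preset_fig9(0.5, burst=True),
    "fig9C": lambda: _preset_fig9(0.7, burst=False),
    "fig9D": lambda: _preset_fig9(0.7, burst=True),
    # Selection-strength variants (constant transposition, no insertion bias)
    "s8": lambda: replace(
        _preset_fig9(0.5, burst=False),
        selection_classes=SelectionClassTable(
            (
                SelectionClass("coding", 0.70, -400.0),
                SelectionClass("noncoding", 0.10, -40.0),
            )
        ),
    ),
    "s9": lambda: replace(
        _preset_fig9(0.5, burst=False),
        selection_classes=SelectionClassTable(
            (
                SelectionClass("coding", 0.70, -10.0),
                SelectionClass("noncoding", 0.10, -1.0),
            )
        ),
    ),
    "s10": lambda: replace(
        _preset_fig9(0.5, burst=False),
        selection_classes=SelectionClassTable(
            (
                SelectionClass("coding", 0.70, -10.0),
                SelectionClass("noncoding", 0.01, -1.0),
            )
        ),
    ),
    "s11": lambda: replace(
        _preset_fig9(0.5, burst=False),
        selection_classes=SelectionClassTable(
            (
                SelectionClass("coding", 0.70, -10.0),
                SelectionClass("noncoding", 0.01, -1.0),
                SelectionClass("coding", 0.01, 10.0),
                SelectionClass("noncoding", 0.001, 10.0),
            )
        ),
    ),
    "s12": lambda: replace(
        _preset_fig9(0.5, burst=False),
        selection_classes=SelectionClassTable(
            (
                SelectionClass("coding", 0.70, -10.0),
                SelectionClass("noncoding", 0.01, -1.0),
                SelectionClass("coding", 0.05, 10.0),
                SelectionClass("noncoding", 0.005, 10.0),
            )
        ),
    ),
}

SCENARIO_NAMES = tuple(_PRESETS)


def scenario_preset(name: str) -> RawParams:
    """Return the exact parameterization of a published simulation scenario.

    ``fig9A``: constant transposition, no insertion bias (Q=0.5).
    ``fig9B``: ancient transposition burst, no bias.
    ``fig9C``/``fig9D``: as A/B with preferential insertion Q=0.7.
    ``s8``-``s12``: point-mutation selection variants of fig9A.
    """
    key = name if name in _PRESETS else name.lower()
    if key not in _PRESETS:
        # case-insensitive lookup for the fig9 panels
        for k in _PRESETS:
            if k.lower() == name.lower():
                key = k
                break
    if key not in _PRESETS:
        raise KeyError(
            f"unknown scenario {name!r}; valid presets: {', '.join(_PRESETS)}"
        )
    return _PRESETS[key]()


def reduced_scale(
    raw: RawParams,
    *,
    N_scaled: int,
    fragment_length: int,
    generations_scaled: int,
    tracked_neutral_fraction: float = 1.0,
    seed: int | None = None,
) -> SimParams:
    """Convenience: shrink the fragment (1:2:1 region proportions and per-Mb coding
    densities preserved) and rescale to the requested population size and run
    length.  Used for desk-scale validation runs."""
    lam = raw.N_e / N_scaled
    raw2 = replace(
        raw,
        fragment_length=fragment_length,
        generations_unscaled=float(generations_scaled) * lam,
    )
    return rescale_parameters(
        raw2, lam, tracked_neutral_fraction=tracked_neutral_fraction, seed=seed
    )
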