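"""Sampling and summary statistics of simulated TE / SNP diversity.

Mirrors the empirical analysis on simulator output: a small diploid sample is
drawn from the final population, three TE summary statistics (mean frequency of
polymorphic insertions, density of polymorphic insertions, density of fixed
insertions) are computed per recombination-region class, replicates are
aggregated, and the qualitative high-vs-low-recombination sign pattern is mapped
to a dominant-process interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import stats as sps

from . import forward_sim as fs
from .forward_sim import SimResult
from .genome_model import GenomeLayout

__all__ = [
    "SampleGenotypes",
    "RegionStats",
    "ReplicateAggregate",
    "SignPattern",
    "sample_population",
    "region_statistics",
    "aggregate_replicates",
    "sign_pattern",
    "interpret_pattern",
    "allele_frequency_spectrum",
    "INTERPRETATION_TABLE",
]

TE_CLASSES = ("short", "long", "all")
STATS = ("mean_freq", "poly_density", "fixed_density")
REGIONS = ("high", "low")


@dataclass
class SampleGenotypes:
    """Genotype dosages of n sampled diploids over all variants.

    Rows of ``G`` are variants (segregating in the population, possibly at sample
    count 0 or 2n, plus population-fixed substitutions at dosage 2 everywhere);
    columns are the sampled diploids.
    """

    n_diploids: int
    position: np.ndarray     # (V,) int64
    is_te: np.ndarray        # (V,) int8
    len_class: np.ndarray    # (V,) int8 (fs.NOT_TE / fs.SHORT / fs.LONG)
    sel_code: np.ndarray     # (V,) int8
    from_substitution: np.ndarray  # (V,) bool
    G: np.ndarray            # (V, n) int8 dosage 0/1/2

    @property
    def counts(self) -> np.ndarray:
        return self.G.sum(axis=1, dtype=np.int64)

    @property
    def n_variants(self) -> int:
        return self.position.size


def sample_population(
    result: SimResult, n_diploids: int, rng: np.random.Generator
) -> SampleGenotypes:
    """Draw ``n_diploids`` without replacement and record their genotypes;
    population-fixed substitutions are appended at dosage 2 in every individual."""
    state = result.state
    if n_diploids > state.N:
        raise ValueError(f"cannot sample {n_diploids} diploids from N={state.N}")
    dips = rng.choice(state.N, size=n_diploids, replace=False)
    H = state.H
    S = state.n_segregating
    G = np.zeros((S, n_diploids), dtype=np.int8)
    for j, d in enumerate(dips):
        G[:, j] = H[2 * d] + H[2 * d + 1]
    nsub = state.n_substitutions
    Gsub = np.full((nsub, n_diploids), 2, dtype=np.int8)
    return SampleGenotypes(
        n_diploids=n_diploids,
        position=np.concatenate([state.pos, np.array(state.sub_pos, np.int64)]),
        is_te=np.concatenate([state.is_te, np.array(state.sub_is_te, np.int8)]),
        len_class=np.concatenate(
            [state.len_class, np.array(state.sub_len_class, np.int8)]
        ),
        sel_code=np.concatenate(
            [state.sel_code, np.array(state.sub_sel_code, np.int8)]
        ),
        from_substitution=np.concatenate(
            [np.zeros(S, bool), np.ones(nsub, bool)]
        ),
        G=np.concatenate([G, Gsub], axis=0),
    )


@dataclass
class RegionStats:
    """The three TE summary statistics (by TE length class, plus the SNP
    baseline) in one recombination-region class.  ``mean_freq`` entries are NaN
    when undefined (no polymorphic variant of that class in the region)."""

    region_class: Literal["high", "low"]
    length_mb: float
    mean_freq: dict = field(default_factory=dict)      # class -> float (NaN ok)
    poly_density: dict = field(default_factory=dict)   # class -> per Mb
    fixed_density: dict = field(default_factory=dict)  # class -> per Mb
    n_poly: dict = field(default_factory=dict)
    mean_derived_snp_freq: float = float("nan")


def region_statistics(
    sample: SampleGenotypes, layout: GenomeLayout
) -> list[RegionStats]:
    """Bin variants into high vs low recombination regions and compute, per TE
    length class and for SNPs: mean frequency over polymorphic variants (sample
    count strictly between 0 and 2n), polymorphic density and fixed density
    (sample count == 2n) per Mb."""
    twon = 2 * sample.n_diploids
    c = sample.counts
    freqs = c / twon
    in_high = layout.region_class_of(sample.position)
    out = []
    for region, rmask in (("high", in_high), ("low", ~in_high)):
        mb = (
            layout.high_length() if region == "high" else layout.low_length()
        ) / 1e6
        rs = RegionStats(region_class=region, length_mb=mb)
        subsets = {
            "short": rmask & (sample.is_te == fs.TE) & (sample.len_class == fs.SHORT),
            "long": rmask & (sample.is_te == fs.TE) & (sample.len_class == fs.LONG),
            "all": rmask & (sample.is_te == fs.TE),
            "snp": rmask & (sample.is_te == fs.SNP),
        }
        for cls, m in subsets.items():
            poly = m & (c > 0) & (c < twon)
            fixed = m & (c == twon)
            npoly = int(poly.sum())
            rs.n_poly[cls] = npoly
            rs.poly_density[cls] = npoly / mb
            rs.fixed_density[cls] = int(fixed.sum()) / mb
            rs.mean_freq[cls] = float(freqs[poly].mean()) if npoly else float("nan")
        rs.mean_derived_snp_freq = rs.mean_freq["snp"]
        out.append(rs)
    return out


@dataclass
class ReplicateAggregate:
    """Full replicate vectors of each statistic by (statistic, TE class, region);
    NaN marks replicates where the statistic was undefined."""

    n_replicates: int
    vectors: dict  # vectors[stat][cls][region] -> np.ndarray (n_replicates,)
    snp_freq: dict  # region -> np.ndarray

    def median(self, stat: str, cls: str, region: str) -> float:
        return float(np.nanmedian(self.vectors[stat][cls][region]))

    def n_defined(self, stat: str, cls: str, region: str) -> int:
        return int(np.isfinite(self.vectors[stat][cls][region]).sum())


def aggregate_replicates(stats_lists: list[list[RegionStats]]) -> ReplicateAggregate:
    """Stack per-replicate RegionStats into per-statistic replicate vectors."""
    if len(stats_lists) < 2:
        raise ValueError("need at least 2 replicates to aggregate")
    n = len(stats_lists)
    vectors = {
        stat: {cls: {r: np.full(n, np.nan) for r in REGIONS} for cls in TE_CLASSES}
        for stat in STATS
    }
    snp_freq = {r: np.full(n, np.nan) for r in REGIONS}
    for i, rep in enumerate(stats_lists):
        for rs in rep:
            r = rs.region_class
            for cls in TE_CLASSES:
                vectors["mean_freq"][cls][r][i] = rs.mean_freq[cls]
                vectors["poly_density"][cls][r][i] = rs.poly_density[cls]
                vectors["fixed_density"][cls][r][i] = rs.fixed_density[cls]
            snp_freq[r][i] = rs.mean_derived_snp_freq
    return ReplicateAggregate(n_replicates=n, vectors=vectors, snp_freq=snp_freq)


@dataclass(frozen=True)
class SignPattern:
    """Direction of the high-minus-low contrast for the three TE statistics,
    with the TE frequency level relative to derived SNPs (the Fig-9-style dotted
    line) used to disambiguate burst scenarios."""

    freq_sign: str   # '+', '-', '0'
    poly_sign: str
    fixed_sign: str
    freq_level: Literal["high", "low"]

    @property
    def signs(self) -> tuple[str, str, str]:
        return (self.freq_sign, self.poly_sign, self.fixed_sign)


def _contrast_sign(high: np.ndarray, low: np.ndarray, alpha: float) -> str:
    ok = np.isfinite(high) & np.isfinite(low)
    d = high[ok] - low[ok]
    if d.size < 2 or np.all(d == 0):
        return "0"
    try:
        _, p = sps.wilcoxon(d, alternative="two-sided")
    except ValueError:
        return "0"
    if p >= alpha:
        return "0"
    # direction from the signed-rank mass itself (robust to a zero median on
    # heavily tied, discrete differences)
    nz = d[d != 0]
    ranks = sps.rankdata(np.abs(nz))
    w_signed = np.sum(np.sign(nz) * ranks)
    return "+" if w_signed > 0 else "-"


def sign_pattern(
    agg: ReplicateAggregate, length_class: str = "short", alpha: float = 0.05
) -> SignPattern:
    """Qualitative pattern of a scenario: per statistic, the sign of the
    high-minus-low median across replicates if a paired Wilcoxon signed-rank
    test rejects at ``alpha``, else '0'."""
    if agg.n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    signs = {}
    for stat in STATS:
        v = agg.vectors[stat][length_class]
        signs[stat] = _contrast_sign(v["high"], v["low"], alpha)
    te_med = np.nanmedian(
        np.concatenate(
            [agg.vectors["mean_freq"][length_class][r] for r in REGIONS]
        )
    )
    snp_med = np.nanmedian(np.concatenate([agg.snp_freq[r] for r in REGIONS]))
    level = "high" if te_med > snp_med else "low"
    return SignPattern(
        freq_sign=signs["mean_freq"],
        poly_sign=signs["poly_density"],
        fixed_sign=signs["fixed_density"],
        freq_level=level,
    )


# decision table: (freq, poly, fixed, freq_level or None for 'any') -> label
INTERPRETATION_TABLE: dict = {
    ("+", "+", "+", None): "Linked Sel. + Pref. Ins.",
    ("+", "+", "-", None): "Linked Sel.",
    ("-", "+", "+", "high"): "Linked Sel. + Anc. Burst + Strong Pref. Ins.",
    ("-", "+", "-", "high"): "Linked Sel. + Anc. Burst",
    ("-", "+", "-", "low"): "Pur. Selec. Ect. Rec. + (Anc. Burst) + Pref. Ins.",
    ("-", "-", "-", None): "Pur. Selec. Ect. Rec. + (Anc. Burst)",
}


def interpret_pattern(pattern: SignPattern) -> str:
    """Map a sign pattern to its dominant-process label; patterns outside the
    decision table return 'unclassified'."""
    key_level = (*pattern.signs, pattern.freq_level)
    key_any = (*pattern.signs, None)
    if key_level in INTERPRETATION_TABLE:
        return INTERPRETATION_TABLE[key_level]
    if key_any in INTERPRETATION_TABLE:
        return INTERPRETATION_TABLE[key_any]
    return "unclassified"


def allele_frequency_spectrum(
    sample: SampleGenotypes,
    variant_filter: Callable[[SampleGenotypes], np.ndarray] | None = None,
) -> np.ndarray:
    """Histogram of sample allele counts, indexed 0..2n (0 = absent from the
    sample, 2n = fixed in the sample); sums to the number of variants passing
    the filter."""
    mask = (
        variant_filter(sample)
        if variant_filter is not None
        else np.ones(sample.n_variants, bool)
    )
    twon = 2 * sample.n_diploids
    return np.bincount(sample.counts[mask], minlength=twon + 1)


def sample_to_te_callset(
    sample: SampleGenotypes,
    layout: GenomeLayout,
    chrom: str = "sim",
    lengths: dict | None = None,
):
    """Convert the TE loci of a simulated sample into the empirical call-set
    container plus a window table of the layout's region intervals, so the
    windowed empirical pipeline can be run on simulator output.

    Length classes are encoded as clades ('short'/'long'); representative
    insertion lengths are nominal (the simulator does not model sequence)."""
    import pandas as pd

    from .popgen_windows import TECallSet

    if lengths is None:
        lengths = {"short": 400, "long": 4000}
    m = sample.is_te == fs.TE
    clade = np.where(sample.len_class[m] == fs.LONG, "long", "short")
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": sample.position[m] + 1,  # VCF 1-based
            "clade": clade,
            "category": "simulated",
            "length": [lengths[c] for c in clade],
            "divergence": 0.0,
            "call_rate": 1.0,
            "consensus_start": np.nan,
            "consensus_end": np.nan,
        }
    )
    samples = [f"dip{j}" for j in range(sample.n_diploids)]
    calls = TECallSet(meta, sample.G[m], samples).sort()
    windows = pd.DataFrame(
        [
            {"chrom": chrom, "start": r.start, "end": r.end, "name": r.klass}
            for r in layout.regions
        ]
    )
    return calls, windows


def te_filter(sample: SampleGenotypes) -> np.ndarray:
    return sample.is_te == fs.TE


def snp_filter(sample: SampleGenotypes) -> np.ndarray:
    return sample.is_te == fs.SNP
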