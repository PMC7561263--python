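"""Synthetic TE call sets, SNP sets and selection-scan score tracks.

These generators emulate the statistical structure the empirical analyses
assume — per-cluster allele-frequency spectra shaped by demography (spectra
skewed toward singletons in large stable clusters, flattened in recently
bottlenecked ones), per-window TE densities correlated with a recombination
map at a configurable Spearman strength, planted duplicate calls and planted
high-differentiation candidate loci — so the windowed analyses are fully
testable without any external data.  Every generator returns an exact truth
table: planted features are constructed, not sampled, wherever a downstream
operation is scored against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .popgen_windows import MISSING, PopulationMap, SNPSet, TECallSet

__all__ = [
    "SynthConfig",
    "default_population_map",
    "generate_te_callset",
    "generate_snp_set",
    "generate_score_tracks",
]

# demographic regimes -> Beta(a, b) shape of the per-cluster frequency model
REGIME_SHAPES = {
    "stable-large": (0.35, 1.6),   # skewed toward singletons
    "bottlenecked": (0.7, 0.9),    # flattened spectrum, more common alleles
}

DEFAULT_CLUSTERS = {
    # cluster -> (n_individuals, regime)
    "SF": (5, "stable-large"),
    "NWF": (4, "stable-large"),
    "NEF": (6, "stable-large"),
    "GA": (6, "bottlenecked"),
    "CA": (5, "bottlenecked"),
}

DEFAULT_CLADES = {
    # clade -> (category, consensus length bp)
    "L1": ("nLTR-RT", 6000),
    "CR1": ("nLTR-RT", 4500),
    "L2": ("nLTR-RT", 4800),
    "SINE2": ("SINE", 400),
    "Gypsy": ("LTR-RT", 9000),
    "hAT": ("DNA", 3000),
}


@dataclass(frozen=True)
class SynthConfig:
    clusters: dict = field(default_factory=lambda: dict(DEFAULT_CLUSTERS))
    outgroups: tuple = ("outgroup_allisoni", "outgroup_porcatus")
    clades: dict = field(default_factory=lambda: dict(DEFAULT_CLADES))
    chrom: str = "chr1"
    n_windows: int = 100
    window_size: int = 1_000_000
    # recombination map: log10(rho) uniform in [lo, hi] with AR(1) smoothness
    log10_rho_range: tuple = (-3.5, -1.5)
    rho_autocorr: float = 0.3
    # TE density model: expected insertions per window, Spearman-coupled to rho
    te_per_window: float = 30.0
    target_spearman: float = 0.5
    # frequency model
    outgroup_carrier_rate: float = 0.05
    # planted features
    n_planted_duplicates: int = 5
    n_planted_candidates: int = 3
    n_planted_missing: int = 4
    candidate_freq_north: float = 0.9
    candidate_freq_south: float = 0.05
    # SNP model
    snps_per_window: float = 120.0
    outgroup_concordance: float = 0.99
    frac_ancestral_alt: float = 0.2
    # score model
    track_names: tuple = ("lsd", "baypass", "diploshic")
    track_quantile: float = 0.90

    def __post_init__(self) -> None:
        if not -1 <= self.target_spearman <= 1:
            raise ValueError("target_spearman must be in [-1, 1]")
        for n, _ in self.clusters.values():
            if n < 0:
                raise ValueError("cluster sizes must be >= 0")
        if self.n_planted_candidates > self.te_per_window * self.n_windows:
            raise ValueError("more planted candidates than loci")

    @property
    def sample_names(self) -> list[str]:
        out = []
        for cl, (n, _) in self.clusters.items():
            out.extend(f"{cl}_{i + 1}" for i in range(n))
        out.extend(self.outgroups)
        return out

    def windows(self, rho: np.ndarray | None = None) -> pd.DataFrame:
        starts = np.arange(self.n_windows) * self.window_size
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": starts,
                "end": starts + self.window_size,
            }
        )
        if rho is not None:
            df["rho"] = rho
        return df


def default_population_map(config: SynthConfig) -> PopulationMap:
    assignments = {}
    for cl, (n, _) in config.clusters.items():
        for i in range(n):
            assignments[f"{cl}_{i + 1}"] = cl
    for og in config.outgroups:
        assignments[og] = og
    return PopulationMap(assignments, outgroups=config.outgroups)


def _rho_map(config: SynthConfig, rng: np.random.Generator):
    """AR(1) latent Gaussian mapped to a log-uniform rho range; returns
    (rho, latent z)."""
    a = config.rho_autocorr
    z = np.empty(config.n_windows)
    z[0] = rng.standard_normal()
    for i in range(1, config.n_windows):
        z[i] = a * z[i - 1] + np.sqrt(1 - a * a) * rng.standard_normal()
    u = sps.norm.cdf(z)
    lo, hi = config.log10_rho_range
    return 10.0 ** (lo + (hi - lo) * u), z


def _te_counts(config: SynthConfig, z_rho: np.ndarray, rng: np.random.Generator):
    """Per-window TE counts whose ranks are coupled to the rho map through a
    Gaussian copula at the configured Spearman strength."""
    rs = config.target_spearman
    # Spearman -> Pearson correlation of the latent Gaussians
    g = 2.0 * np.sin(np.pi * rs / 6.0)
    # enforce the latent correlation exactly IN SAMPLE (not just in expectation)
    # so the realized rank correlation tracks the target tightly
    z1 = (z_rho - z_rho.mean()) / z_rho.std()
    eps = rng.standard_normal(config.n_windows)
    eps = eps - eps.mean() - np.dot(eps - eps.mean(), z1) / np.dot(z1, z1) * z1
    eps /= eps.std()
    zc = g * z1 + np.sqrt(max(0.0, 1 - g * g)) * eps
    u = sps.norm.cdf(zc)
    return sps.poisson.ppf(np.clip(u, 1e-9, 1 - 1e-9), config.te_per_window).astype(int)


def _respace_same_clade(
    meta: pd.DataFrame,
    window_size: int,
    min_gap: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Re-draw positions (within each locus's window, so per-window counts and
    the planted density-rho coupling are untouched) until same-clade calls are
    pairwise at least ``min_gap`` apart; guarantees the only sub-threshold
    duplicate pairs in the final call set are the planted twins."""
    meta = meta.copy()
    for clade in meta["clade"].unique():
        m = np.nonzero((meta["clade"] == clade).to_numpy())[0]
        for _ in range(500):
            pos = meta.loc[meta.index[m], "pos"].to_numpy()
            order = np.argsort(pos)
            bad_local = np.nonzero(np.diff(pos[order]) < min_gap)[0] + 1
            if bad_local.size == 0:
                break
            rows = meta.index[m[order[bad_local]]]
            w = (meta.loc[rows, "pos"].to_numpy() - 1) // window_size
            meta.loc[rows, "pos"] = (
                w * window_size + rng.integers(1, window_size + 1, size=len(rows))
            )
        else:
            raise RuntimeError("could not honour same-clade spacing")
    return meta


def generate_te_callset(
    config: SynthConfig, seed: int
) -> tuple[TECallSet, dict]:
    """Generate a genotyped TE call set plus its exact truth table.

    Truth keys: ``windows`` (with the rho map), ``planted_duplicates`` (the
    (chrom, pos, clade) of every twin call that duplicate resolution must
    remove), ``planted_candidates``, ``planted_missing`` (loci carrying a
    missing genotype), ``target_spearman``, and per-locus per-cluster allele
    frequencies used for genotype draws.
    """
    rng = np.random.default_rng(seed)
    rho, z = _rho_map(config, rng)
    counts = _te_counts(config, z, rng)
    samples = config.sample_names
    popmap = default_population_map(config)

    clade_names = list(config.clades)
    rows = []
    for w in range(config.n_windows):
        lo = w * config.window_size
        hi = lo + config.window_size
        k = counts[w]
        pos = rng.integers(lo + 1, hi + 1, size=k)  # VCF 1-based
        for p in np.sort(pos):
            clade = clade_names[rng.integers(len(clade_names))]
            cat, cons_len = config.clades[clade]
            frac = rng.uniform(0.05, 1.0)
            length = max(int(frac * cons_len), 30)
            rows.append(
                {
                    "chrom": config.chrom,
                    "pos": int(p),
                    "clade": clade,
                    "category": cat,
                    "length": length,
                    "divergence": round(float(rng.uniform(0.0, 0.15)), 4),
                    "call_rate": round(float(rng.uniform(0.85, 1.0)), 3),
                    "consensus_start": float(cons_len - length),
                    "consensus_end": float(cons_len),
                }
            )
    meta = pd.DataFrame(rows)

    # same-clade spacing >= 4000 bp: a planted twin (< 1500 bp from its base)
    # then cannot chain with any third call under the 2000 bp rule
    meta = _respace_same_clade(meta, config.window_size, 4000, rng)
    meta = meta.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    # per-cluster frequencies and genotypes
    n_loci = len(meta)
    geno = np.zeros((n_loci, len(samples)), dtype=np.int8)
    freq_truth = {}
    col = 0
    for cl, (n, regime) in config.clusters.items():
        a, b = REGIME_SHAPES[regime]
        p = rng.beta(a, b, size=n_loci)
        freq_truth[cl] = p
        geno[:, col: col + n] = rng.binomial(2, p[:, None], size=(n_loci, n))
        col += n
    for _og in config.outgroups:
        present = rng.random(n_loci) < config.outgroup_carrier_rate
        geno[:, col] = present.astype(np.int8)
        col += 1

    # planted candidates: deterministic genotypes guaranteeing the frequency
    # shift between the northern pool and the Floridian pool
    north = [cl for cl, (_, r) in config.clusters.items() if r == "bottlenecked"]
    south = [cl for cl, (_, r) in config.clusters.items() if r == "stable-large"]
    cand_idx = rng.choice(n_loci, size=config.n_planted_candidates, replace=False)
    scol = {s: i for i, s in enumerate(samples)}
    for i in cand_idx:
        # deterministic dosages: one het in each pool, the rest homozygous,
        # guaranteeing the frequency shift regardless of sampling noise
        north_samples = popmap.samples_of_clusters(north)
        south_samples = popmap.samples_of_clusters(south)
        for s in north_samples:
            geno[i, scol[s]] = 2
        geno[i, scol[north_samples[0]]] = 1
        for s in south_samples:
            geno[i, scol[s]] = 0
        geno[i, scol[south_samples[0]]] = 1

    # planted duplicate twins: nearby same-clade call with strictly higher
    # divergence (the resolution rule must drop exactly these)
    dup_rows = []
    dup_geno = []
    base_idx = rng.choice(
        np.setdiff1d(np.arange(n_loci), cand_idx),
        size=config.n_planted_duplicates,
        replace=False,
    )
    for i in base_idx:
        r = meta.iloc[i].to_dict()
        r["pos"] = int(r["pos"]) + int(rng.integers(200, 1500))
        r["divergence"] = round(min(r["divergence"] + 0.03, 0.5), 4)
        dup_rows.append(r)
        dup_geno.append(geno[i])
    planted_dups = [(r["chrom"], r["pos"], r["clade"]) for r in dup_rows]

    meta_all = pd.concat([meta, pd.DataFrame(dup_rows)], ignore_index=True)
    geno_all = np.concatenate([geno, np.array(dup_geno, dtype=np.int8)], axis=0)
    order = np.lexsort((meta_all["pos"].to_numpy(), meta_all["chrom"].to_numpy()))
    meta_all = meta_all.iloc[order].reset_index(drop=True)
    geno_all = geno_all[order]

    # planted missing genotypes (loci that complete-data filtering must drop)
    dup_pos = {(c, p) for c, p, _ in planted_dups}
    eligible = [
        i for i in range(len(meta_all))
        if (meta_all.loc[i, "chrom"], meta_all.loc[i, "pos"]) not in dup_pos
        and i not in set(
            np.nonzero(meta_all["pos"].isin(meta.loc[cand_idx, "pos"]))[0]
        )
    ]
    miss_idx = rng.choice(
        eligible, size=config.n_planted_missing, replace=False
    )
    for i in miss_idx:
        geno_all[i, rng.integers(len(samples))] = MISSING

    calls = TECallSet(meta_all, geno_all, list(samples))
    truth = {
        "windows": config.windows(rho),
        "rho": rho,
        "target_spearman": config.target_spearman,
        "planted_duplicates": planted_dups,
        "planted_candidates": [
            (config.chrom, int(meta.loc[i, "pos"])) for i in cand_idx
        ],
        "planted_missing": [
            (meta_all.loc[i, "chrom"], int(meta_all.loc[i, "pos"]))
            for i in miss_idx
        ],
        "cluster_freqs": freq_truth,
        "north_clusters": north,
        "south_clusters": south,
    }
    return calls, truth


def generate_snp_set(config: SynthConfig, seed: int) -> tuple[SNPSet, dict]:
    """Generate a SNP set with two outgroup columns for polarization.

    Outgroups are homozygous for the ancestral allele at a configurable
    concordance rate; discordant loci (flipped or heterozygous outgroup) are the
    ones polarization must drop.  Truth records the ancestral state and the
    realized derived-allele frequency per cluster at every locus.
    """
    rng = np.random.default_rng(seed)
    samples = config.sample_names
    n_windows = config.n_windows
    counts = rng.poisson(config.snps_per_window, size=n_windows)
    rows = []
    for w in range(n_windows):
        lo = w * config.window_size
        pos = np.unique(rng.integers(0, config.window_size, size=counts[w]))
        for p in pos:
            rows.append({"chrom": config.chrom, "pos": int(lo + p + 1)})
    meta = pd.DataFrame(rows)
    n_loci = len(meta)

    ancestral_is_alt = rng.random(n_loci) < config.frac_ancestral_alt
    geno = np.zeros((n_loci, len(samples)), dtype=np.int8)
    col = 0
    daf_truth = {}
    for cl, (n, regime) in config.clusters.items():
        a, b = REGIME_SHAPES[regime]
        p = rng.beta(a, b, size=n_loci)  # derived-allele frequency
        derived_dosage = rng.binomial(2, p[:, None], size=(n_loci, n))
        alt_dosage = np.where(
            ancestral_is_alt[:, None], 2 - derived_dosage, derived_dosage
        )
        geno[:, col: col + n] = alt_dosage
        daf_truth[cl] = p
        col += 1 * n
    discordant = np.zeros(n_loci, dtype=bool)
    for k, _og in enumerate(config.outgroups):
        anc = np.where(ancestral_is_alt, 2, 0).astype(np.int8)
        flip = rng.random(n_loci) >= config.outgroup_concordance
        vals = np.where(flip, 2 - anc, anc)
        discordant |= flip
        geno[:, col] = vals
        col += 1

    snps = SNPSet(meta, geno, list(samples))
    truth = {
        "ancestral_is_alt": ancestral_is_alt,
        "derived_freq": daf_truth,
        "discordant": discordant,
        "windows": config.windows(),
    }
    return snps, truth


def generate_score_tracks(
    config: SynthConfig,
    calls: TECallSet,
    callset_truth: dict,
    seed: int,
    tracks_supporting: dict | None = None,
) -> tuple[pd.DataFrame, dict, dict]:
    """Per-locus differentiation scores plus three candidate-window tracks.

    Planted candidate loci receive top-tail values of both per-locus statistics;
    among non-planted loci the two score backgrounds are constructed so that no
    locus falls in the joint upper 1% tail (the top X^T X background loci are
    assigned the bottom eBPis background values), making the planted set the
    exact ground truth for the candidate filter.  Each track's candidate
    windows are its windows above the ``track_quantile`` score percentile;
    windows holding a planted candidate are pushed into that top tail for the
    tracks listed in ``tracks_supporting`` (default: all three).
    """
    rng = np.random.default_rng(seed)
    n_loci = calls.n_loci
    keys = list(
        zip(calls.meta["chrom"].to_numpy(), calls.meta["pos"].to_numpy())
    )
    planted = callset_truth["planted_candidates"]
    planted_rows = [keys.index(k) for k in planted]

    xtx = rng.gamma(4.0, 1.5, size=n_loci)
    ebp = rng.gamma(3.0, 1.0, size=n_loci)
    # decouple the joint background tail: the top ~2% background XtX loci get
    # the lowest background eBPis values
    bg = np.setdiff1d(np.arange(n_loci), planted_rows)
    k_tail = max(int(np.ceil(0.02 * n_loci)), len(planted_rows) + 1)
    top_x = bg[np.argsort(xtx[bg])[-k_tail:]]
    low_e_vals = np.sort(ebp[bg])[:k_tail]
    ebp[top_x] = low_e_vals[rng.permutation(k_tail)]
    xtx[planted_rows] = xtx.max() + 1.0 + rng.random(len(planted_rows))
    ebp[planted_rows] = ebp.max() + 1.0 + rng.random(len(planted_rows))

    scores = calls.meta[["chrom", "pos"]].copy()
    scores["XtX"] = xtx
    scores["eBPis"] = ebp

    if tracks_supporting is None:
        tracks_supporting = {t: list(planted) for t in config.track_names}
    windows = callset_truth["windows"][["chrom", "start", "end"]].copy()
    n_w = len(windows)
    tracks = {}
    track_truth = {}
    for t in config.track_names:
        wscore = rng.normal(0.0, 1.0, size=n_w)
        thr = np.quantile(wscore, config.track_quantile)
        top = wscore > thr
        supported = tracks_supporting.get(t, [])
        for chrom, pos in supported:
            wi = np.nonzero(
                (windows["chrom"] == chrom)
                & (windows["start"] <= pos - 1)
                & (pos - 1 < windows["end"])
            )[0]
            if wi.size:
                wscore[wi[0]] = wscore.max() + 1.0
        # windows holding an unsupported planted locus must stay below threshold
        for chrom, pos in planted:
            if (chrom, pos) in supported:
                continue
            wi = np.nonzero(
                (windows["chrom"] == chrom)
                & (windows["start"] <= pos - 1)
                & (pos - 1 < windows["end"])
            )[0]
            if wi.size:
                wscore[wi[0]] = min(wscore.min(), thr) - 1.0
        thr = np.quantile(wscore, config.track_quantile)
        cand = windows.loc[wscore >= thr].copy()
        cand["score"] = wscore[wscore >= thr]
        tracks[t] = cand.reset_index(drop=True)
        track_truth[t] = {
            "threshold": float(thr),
            "supported_candidates": list(supported),
        }
    truth = {"tracks": track_truth, "planted_rows": planted_rows}
    return scores, tracks, truth
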