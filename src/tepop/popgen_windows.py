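"""Windowed population-genomic analysis of TE insertion calls and SNPs.

Operates on genotyped TE insertion calls (a MELT-style call set), SNP genotypes
with two outgroup individuals for derived-allele polarization, a window table
carrying an externally estimated population recombination rate rho = 4*N_e*r,
and per-locus differentiation scores (X^T X / eBPis style) consumed as inputs.

Conventions: window coordinates are BED-style half-open 0-based; variant
positions are VCF-style 1-based.  'Fixed' in a population means the derived
allele count equals twice the number of genotyped individuals of that
population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TECallSet",
    "PopulationMap",
    "resolve_duplicates",
    "drop_missing",
    "window_te_stats",
    "polarize",
    "window_snp_stats",
    "r_over_mu",
    "correlate",
    "correlogram",
    "stratify_lines",
    "sharing_counts",
    "compare_frequencies",
    "filter_candidates",
    "truncation_summary",
    "hudson_fst",
]

MISSING = -1

META_COLUMNS = [
    "chrom", "pos", "clade", "category", "length",
    "divergence", "call_rate", "consensus_start", "consensus_end",
]


@dataclass
class TECallSet:
    """TE insertion calls: per-locus metadata plus a (loci x samples) genotype
    dosage matrix (0/1/2, -1 missing)."""

    meta: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.meta = self.meta.reset_index(drop=True)
        if self.genotypes.shape != (len(self.meta), len(self.samples)):
            raise ValueError("genotype matrix shape does not match meta/samples")
        if self.genotypes.size and (
            self.genotypes.max() > 2 or self.genotypes.min() < MISSING
        ):
            raise ValueError("genotype dosages must be in {-1, 0, 1, 2}")
        if (self.meta["length"] <= 0).any():
            raise ValueError("TE lengths must be positive")

    @property
    def n_loci(self) -> int:
        return len(self.meta)

    def subset(self, mask: np.ndarray) -> "TECallSet":
        return TECallSet(
            self.meta.loc[np.asarray(mask)].copy(),
            self.genotypes[np.asarray(mask)],
            list(self.samples),
        )

    def sort(self) -> "TECallSet":
        order = np.lexsort(
            (self.meta["pos"].to_numpy(), self.meta["chrom"].to_numpy())
        )
        return TECallSet(
            self.meta.iloc[order].copy(), self.genotypes[order], list(self.samples)
        )

    def allele_counts(self, samples: Iterable[str]) -> np.ndarray:
        idx = [self.samples.index(s) for s in samples]
        G = self.genotypes[:, idx]
        if (G == MISSING).any():
            raise ValueError("missing genotypes present; run drop_missing first")
        return G.sum(axis=1, dtype=np.int64)


# SNP sets share the container; clade/length columns are simply absent
@dataclass
class SNPSet:
    meta: pd.DataFrame  # chrom, pos (1-based)
    genotypes: np.ndarray  # (loci, samples) dosage of the ALT allele, -1 missing
    samples: list[str]

    @property
    def n_loci(self) -> int:
        return len(self.meta)

    def subset(self, mask: np.ndarray) -> "SNPSet":
        return SNPSet(
            self.meta.loc[np.asarray(mask)].reset_index(drop=True).copy(),
            self.genotypes[np.asarray(mask)],
            list(self.samples),
        )


@dataclass
class PopulationMap:
    """Sample -> genetic-cluster assignment, with designated outgroup clusters."""

    assignments: dict
    outgroups: tuple = ("outgroup_allisoni", "outgroup_porcatus")

    def cluster_of(self, sample: str) -> str:
        return self.assignments[sample]

    def samples_of(self, cluster: str) -> list[str]:
        return [s for s, c in self.assignments.items() if c == cluster]

    def samples_of_clusters(self, clusters: Iterable[str]) -> list[str]:
        cs = set(clusters)
        return [s for s, c in self.assignments.items() if c in cs]

    @property
    def ingroup_clusters(self) -> list[str]:
        seen = []
        for c in self.assignments.values():
            if c not in seen and c not in self.outgroups:
                seen.append(c)
        return seen

    @property
    def outgroup_samples(self) -> list[str]:
        return [s for s, c in self.assignments.items() if c in self.outgroups]

    def validate(self, samples: Iterable[str]) -> None:
        missing = [s for s in samples if s not in self.assignments]
        if missing:
            raise ValueError(f"individuals without cluster assignment: {missing}")


def resolve_duplicates(calls: TECallSet, max_dist: int = 2000) -> TECallSet:
    """Collapse putative duplicate calls: within each chain of same-chromosome,
    same-clade calls lying pairwise closer than ``max_dist`` bp, keep only the
    call with the lowest divergence to consensus; at equal divergence keep the
    highest calling rate (first occurrence on further ties)."""
    meta = calls.meta
    order = np.lexsort((meta["pos"].to_numpy(), meta["clade"].to_numpy(),
                        meta["chrom"].to_numpy()))
    keep = np.ones(calls.n_loci, dtype=bool)
    chrom = meta["chrom"].to_numpy()[order]
    clade = meta["clade"].to_numpy()[order]
    pos = meta["pos"].to_numpy()[order]
    div = meta["divergence"].to_numpy()[order]
    cr = meta["call_rate"].to_numpy()[order]

    i = 0
    n = len(order)
    while i < n:
        j = i + 1
        while (
            j < n
            and chrom[j] == chrom[i]
            and clade[j] == clade[i]
            and pos[j] - pos[j - 1] < max_dist
        ):
            j += 1
        if j - i > 1:
            chain = np.arange(i, j)
            # lowest divergence, then highest call rate, then first position
            best = chain[
                np.lexsort((chain, -cr[chain], div[chain]))[0]
            ]
            for k in chain:
                if k != best:
                    keep[order[k]] = False
        i = j
    return calls.subset(keep)


def drop_missing(calls):
    """Remove every locus with at least one missing genotype."""
    complete = ~(calls.genotypes == MISSING).any(axis=1)
    return calls.subset(complete)


def _validate_windows(windows: pd.DataFrame) -> None:
    for chrom, grp in windows.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (np.diff(starts) < 0).any():
            raise ValueError(f"windows unsorted on {chrom}")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping windows on {chrom}")
        if (ends <= starts).any():
            raise ValueError(f"empty/negative window on {chrom}")


def assign_windows(
    chrom: np.ndarray, pos_1based: np.ndarray, windows: pd.DataFrame
) -> np.ndarray:
    """Index of the window containing each locus (-1 when outside all windows).
    Window coordinates are half-open 0-based; positions are 1-based."""
    _validate_windows(windows)
    out = np.full(chrom.size, -1, dtype=np.int64)
    p0 = np.asarray(pos_1based) - 1
    for c, grp in windows.groupby("chrom", sort=False):
        m = chrom == c
        if not m.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = np.searchsorted(starts, p0[m], side="right") - 1
        ok = (idx >= 0) & (p0[m] < ends[np.clip(idx, 0, None)])
        res = np.where(ok, grp.index.to_numpy()[np.clip(idx, 0, None)], -1)
        out[m] = res
    return out


def window_te_stats(
    calls: TECallSet,
    windows: pd.DataFrame,
    population: list[str],
    min_poly: int = 3,
    by_clade: bool = False,
) -> pd.DataFrame:
    """Per-window TE statistics in one population: polymorphic and fixed counts,
    mean frequency over polymorphic loci (undefined — NaN — below ``min_poly``
    polymorphic insertions), mean insertion length, and an ``excluded`` flag for
    windows containing no TEs at all."""
    ac = calls.allele_counts(population)
    twon = 2 * len(population)
    widx = assign_windows(
        calls.meta["chrom"].to_numpy(), calls.meta["pos"].to_numpy(), windows
    )
    freqs = ac / twon
    poly = (ac > 0) & (ac < twon)
    fixed = ac == twon

    groups = (
        [("all",)]
        if not by_clade
        else [(c,) for c in sorted(calls.meta["clade"].unique())]
    )
    rows = []
    for (g,) in groups:
        gm = (
            np.ones(calls.n_loci, bool)
            if g == "all" and not by_clade
            else (calls.meta["clade"].to_numpy() == g)
        )
        for wi in windows.index:
            m = gm & (widx == wi)
            npoly = int((m & poly).sum())
            nfix = int((m & fixed).sum())
            ntot = int(m.sum())
            mb = (windows.loc[wi, "end"] - windows.loc[wi, "start"]) / 1e6
            rows.append(
                {
                    "chrom": windows.loc[wi, "chrom"],
                    "start": windows.loc[wi, "start"],
                    "end": windows.loc[wi, "end"],
                    "clade": g,
                    "n_total": ntot,
                    "n_poly": npoly,
                    "n_fixed": nfix,
                    "poly_density_mb": npoly / mb,
                    "fixed_density_mb": nfix / mb,
                    "mean_freq": float(freqs[m & poly].mean())
                    if npoly >= min_poly
                    else np.nan,
                    "mean_length": float(
                        calls.meta["length"].to_numpy()[m].mean()
                    )
                    if ntot
                    else np.nan,
                    "excluded": ntot == 0,
                }
            )
    return pd.DataFrame(rows)


class PolarizeResult(NamedTuple):
    daf: np.ndarray        # derived allele frequency per kept locus
    kept: np.ndarray       # boolean mask over input loci
    derived_is_alt: np.ndarray  # per kept locus
    n_dropped: int


def polarize(snps: SNPSet, popmap: PopulationMap) -> PolarizeResult:
    """Derived-allele polarization with two outgroup individuals: a locus is kept
    when both outgroups are genotyped, homozygous, and agree; the derived allele
    is the one they do not carry.  Frequencies are over the ingroup samples."""
    out_idx = [snps.samples.index(s) for s in popmap.outgroup_samples]
    if len(out_idx) < 2:
        raise ValueError("need two outgroup individuals for polarization")
    in_idx = [
        i for i, s in enumerate(snps.samples)
        if popmap.assignments.get(s) not in popmap.outgroups
    ]
    O = snps.genotypes[:, out_idx]
    homo = (O == 0) | (O == 2)
    keep = homo.all(axis=1) & (O.max(axis=1) == O.min(axis=1))
    derived_is_alt = O[:, 0] == 0  # outgroups carry REF -> ALT is derived
    Gin = snps.genotypes[:, in_idx].astype(np.float64)
    Gin[Gin == MISSING] = np.nan
    alt_freq = np.nanmean(Gin, axis=1) / 2.0
    daf = np.where(derived_is_alt, alt_freq, 1.0 - alt_freq)
    return PolarizeResult(
        daf=daf[keep],
        kept=keep,
        derived_is_alt=derived_is_alt[keep],
        n_dropped=int((~keep).sum()),
    )


def _pop_freqs(snps: SNPSet, samples: list[str]):
    idx = [snps.samples.index(s) for s in samples]
    G = snps.genotypes[:, idx].astype(np.float64)
    G[G == MISSING] = np.nan
    n_called = 2 * np.sum(~np.isnan(G), axis=1)
    with np.errstate(invalid="ignore"):
        p = np.nansum(G, axis=1) / n_called
    return p, n_called


def hudson_fst(p1, p2, n1, n2):
    """Hudson's FST estimator components per SNP (numerator, denominator);
    window values are the ratio of sums (ratio of means)."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
        - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def window_snp_stats(
    snps: SNPSet,
    windows: pd.DataFrame,
    populations: dict,
    popmap: PopulationMap | None = None,
) -> pd.DataFrame:
    """Per-window SNP statistics: theta_pi per population (mean pairwise
    difference per bp), pairwise dXY per bp and Hudson FST (ratio of sums over
    SNPs in the window), and, when a population map with outgroups is supplied,
    the mean derived allele frequency per population over its polymorphic loci."""
    widx = assign_windows(
        snps.meta["chrom"].to_numpy(), snps.meta["pos"].to_numpy(), windows
    )
    names = list(populations)
    freqs = {}
    ncalled = {}
    for name in names:
        freqs[name], ncalled[name] = _pop_freqs(snps, populations[name])

    pol = polarize(snps, popmap) if popmap is not None else None
    der_full = {}
    if pol is not None:
        dia = np.zeros(snps.n_loci, bool)
        dia[pol.kept] = pol.derived_is_alt
        for name in names:
            d = np.where(dia, freqs[name], 1.0 - freqs[name])
            d[~pol.kept] = np.nan
            der_full[name] = d
    rows = []
    for wi in windows.index:
        m = widx == wi
        L = windows.loc[wi, "end"] - windows.loc[wi, "start"]
        row = {
            "chrom": windows.loc[wi, "chrom"],
            "start": windows.loc[wi, "start"],
            "end": windows.loc[wi, "end"],
            "n_snps": int(m.sum()),
        }
        for name in names:
            p = freqs[name][m]
            n = ncalled[name][m]
            ok = n > 1
            # unbiased per-site heterozygosity 2p(1-p) * n/(n-1)
            pi = np.sum(2 * p[ok] * (1 - p[ok]) * n[ok] / (n[ok] - 1))
            row[f"theta_pi_{name}"] = pi / L
            if pol is not None:
                der = der_full[name][m]
                seg = (der > 0) & (der < 1)
                row[f"daf_{name}"] = float(der[seg].mean()) if seg.any() else np.nan
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                pa, pb = freqs[a][m], freqs[b][m]
                na, nb = ncalled[a][m], ncalled[b][m]
                ok = (na > 1) & (nb > 1)
                dxy = np.sum(pa[ok] * (1 - pb[ok]) + pb[ok] * (1 - pa[ok])) / L
                num, den = hudson_fst(pa[ok], pb[ok], na[ok], nb[ok])
                row[f"dxy_{a}_{b}"] = dxy
                row[f"fst_{a}_{b}"] = (
                    float(num.sum() / den.sum()) if den.sum() > 0 else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


def r_over_mu(rho: np.ndarray, theta_pi: np.ndarray) -> np.ndarray:
    """Effective-population-size-free recombination measure rho / theta_pi
    (both 4*N_e-scaled); NaN where theta_pi is zero or undefined."""
    rho = np.asarray(rho, float)
    theta_pi = np.asarray(theta_pi, float)
    out = np.full(rho.shape, np.nan)
    ok = theta_pi > 0
    out[ok] = rho[ok] / theta_pi[ok]
    return out


def correlate(x, y, method: str = "spearman"):
    """Spearman rank correlation with pairwise deletion of undefined cells."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    if method != "spearman":
        raise ValueError("only Spearman correlation is supported")
    r = sps.spearmanr(x[ok], y[ok])
    return float(r.statistic), float(r.pvalue)


def correlogram(df: pd.DataFrame, alpha: float = 0.05):
    """Full Spearman correlation matrix of the numeric columns of ``df`` with a
    significance mask (True where P > alpha, i.e. not significant)."""
    cols = df.columns
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            r, p = correlate(df[cols[i]], df[cols[j]])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    mask = pval > alpha
    np.fill_diagonal(mask.values, False)
    return rho, pval, mask


def stratify_lines(
    calls: TECallSet,
    clade_maxima: dict | None = None,
    short_frac: float = 0.20,
    long_frac: float = 0.30,
):
    """Split calls into short (< short_frac of the clade maximum length) and
    long (> long_frac of the clade maximum) sets; mid-range elements excluded."""
    lengths = calls.meta["length"].to_numpy(float)
    clades = calls.meta["clade"].to_numpy()
    if clade_maxima is None:
        clade_maxima = (
            calls.meta.groupby("clade")["length"].max().to_dict()
        )
    maxima = np.array([clade_maxima[c] for c in clades], float)
    short = lengths < short_frac * maxima
    long = lengths > long_frac * maxima
    return calls.subset(short), calls.subset(long)


SHARING_CATEGORIES = ("shared_outgroup", "shared_other_cluster",
                      "shared_within_cluster", "private")


def sharing_counts(calls: TECallSet, popmap: PopulationMap) -> pd.DataFrame:
    """Classify each individual's heterozygous loci by where else the insertion
    allele is found.  Categories are mutually exclusive with precedence
    outgroup > other cluster > within cluster > private."""
    G = calls.genotypes
    if (G == MISSING).any():
        raise ValueError("missing genotypes present; run drop_missing first")
    popmap.validate(calls.samples)
    clusters = np.array([popmap.cluster_of(s) for s in calls.samples])
    is_out = np.isin(clusters, popmap.outgroups)
    carrier = G >= 1
    out = []
    for i, samp in enumerate(calls.samples):
        het = G[:, i] == 1
        others = np.ones(len(calls.samples), bool)
        others[i] = False
        og = carrier[:, others & is_out].any(axis=1)
        other_cl = carrier[:, others & ~is_out & (clusters != clusters[i])].any(axis=1)
        within = carrier[:, others & ~is_out & (clusters == clusters[i])].any(axis=1)
        cats = {
            "shared_outgroup": int((het & og).sum()),
            "shared_other_cluster": int((het & ~og & other_cl).sum()),
            "shared_within_cluster": int(
                (het & ~og & ~other_cl & within).sum()
            ),
            "private": int((het & ~og & ~other_cl & ~within).sum()),
        }
        cats["individual"] = samp
        cats["cluster"] = clusters[i]
        cats["n_het"] = int(het.sum())
        out.append(cats)
    return pd.DataFrame(out).set_index("individual")


class ComparisonResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool


def compare_frequencies(a, b, paired: bool = False) -> ComparisonResult:
    """Two-sided Wilcoxon comparison of two groups of frequencies: signed-rank
    when paired, rank-sum (Mann-Whitney, exact where available) otherwise.
    All-tie inputs are flagged degenerate."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal lengths")
        d = a - b
        if np.all(d == 0):
            return ComparisonResult(0.0, 1.0, True)
        stat, p = sps.wilcoxon(d, alternative="two-sided")
        return ComparisonResult(float(stat), float(p), False)
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return ComparisonResult(np.nan, 1.0, True)
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult(float(stat), float(p), False)


def filter_candidates(
    records: pd.DataFrame,
    tracks: dict,
    q: float = 0.99,
    delta: float = 0.5,
) -> pd.DataFrame:
    """Select TE loci that are candidate targets of recent positive selection:
    in the top (1-q) tail for BOTH differentiation statistics (empirical
    quantile, linear interpolation, threshold ties included) AND showing an
    absolute frequency shift >= ``delta`` between the northern and the
    South-Florida pools.  Survivors are annotated with half-open interval
    overlap flags against each candidate-window track and the count of
    supporting tests.

    ``records`` needs columns: chrom, pos, XtX, eBPis, freq_north, freq_south.
    ``tracks`` maps track name -> DataFrame(chrom, start, end) of candidate
    windows.
    """
    for name, track in tracks.items():
        if len(track) == 0:
            raise ValueError(f"candidate-window track {name!r} is empty")
    if len(records) == 0:
        raise ValueError("empty records table")
    thr_x = np.quantile(records["XtX"], q)
    thr_e = np.quantile(records["eBPis"], q)
    shift = (records["freq_north"] - records["freq_south"]).abs()
    sel = (
        (records["XtX"] >= thr_x)
        & (records["eBPis"] >= thr_e)
        & (shift >= delta)
    )
    out = records.loc[sel].copy()
    out["delta_freq"] = shift[sel]
    n_support = np.zeros(len(out), dtype=int)
    for name, track in tracks.items():
        flag = (
            assign_windows(
                out["chrom"].to_numpy(), out["pos"].to_numpy(),
                track.reset_index(drop=True),
            )
            >= 0
        )
        out[f"in_{name}"] = flag
        n_support += flag.astype(int)
    out["n_tests_supporting"] = n_support
    return out.reset_index(drop=True)


def truncation_summary(
    calls: TECallSet, n_bins: int = 20
) -> dict:
    """Distributions of element start/end coordinates on their consensus, as
    fractions of the clade consensus length (taken as the maximum observed
    consensus end per clade).  Start mass away from 0 indicates 5' truncation;
    end mass away from 1 indicates 3' truncation."""
    out = {}
    meta = calls.meta.dropna(subset=["consensus_start", "consensus_end"])
    edges = np.linspace(0, 1, n_bins + 1)
    for clade, grp in meta.groupby("clade"):
        cons_len = grp["consensus_end"].max()
        if len(grp) == 0 or cons_len <= 0:
            out[clade] = {
                "start_hist": np.zeros(n_bins, int),
                "end_hist": np.zeros(n_bins, int),
                "bin_edges": edges,
                "mean_start_frac": np.nan,
                "mean_end_frac": np.nan,
            }
            continue
        sf = np.clip(grp["consensus_start"].to_numpy() / cons_len, 0, 1)
        ef = np.clip(grp["consensus_end"].to_numpy() / cons_len, 0, 1)
        out[clade] = {
            "start_hist": np.histogram(sf, bins=edges)[0],
            "end_hist": np.histogram(ef, bins=edges)[0],
            "bin_edges": edges,
            "mean_start_frac": float(sf.mean()),
            "mean_end_frac": float(ef.mean()),
        }
    return out
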