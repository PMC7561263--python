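"""Forward Wright-Fisher simulation of point mutations and TE insertions.

The population is N diploids (2N haplotypes).  Each generation: parents are sampled
with probability proportional to multiplicative diploid fitness; gametes are formed
with crossovers drawn as a Poisson process whose intensity is the per-region
recombination rate; new point mutations and TE insertions enter on random offspring
haplotypes; variants reaching count 2N are moved to a substitution log, variants at
count 0 are dropped.

Segregating variants live in a position-sorted registry (parallel metadata
arrays).  Haplotypes are stored sparsely as ragged, sorted lists of registry
column indices — per-generation work is then O(total derived alleles carried)
rather than O(2N x S).  A dense (2N x S) presence-matrix backend implements the
identical generation step from the identical random-draw sequence and is used to
cross-validate the sparse kernels bit-for-bit in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .genome_model import (
    GenomeLayout,
    SimParams,
    build_layout,
    fragment_insertion_rate,
)

__all__ = [
    "Mutation",
    "TEInsertion",
    "PopulationState",
    "SimResult",
    "initialize_population",
    "transposition_rate_at",
    "draw_te_insertion",
    "draw_point_mutation",
    "diploid_fitness",
    "step_generation",
    "run_simulation",
    "introduce_variant",
]

# variant type codes
SNP, TE = 0, 1
# selection-class codes for SNPs
NEUTRAL, DEL_NONCODING, DEL_CODING, BENEFICIAL = 0, 1, 2, 3
# length-class codes for TEs (-1 for SNPs)
NOT_TE, SHORT, LONG = -1, 0, 1

_SEL_NAMES = {NEUTRAL: "neutral", DEL_NONCODING: "del_noncoding",
              DEL_CODING: "del_coding", BENEFICIAL: "beneficial"}


@dataclass(frozen=True)
class Mutation:
    position: int
    sel_class: Literal["neutral", "del_noncoding", "del_coding", "beneficial"]
    s: float
    h: float
    origin_gen: int


@dataclass(frozen=True)
class TEInsertion:
    position: int
    length_class: Literal["short", "long"]
    in_exon: bool
    in_high: bool
    s_effective: float
    origin_gen: int


@dataclass
class PopulationState:
    """Variant registry plus haplotype contents.

    The registry arrays (pos, s, h, ...) are parallel over the S segregating
    variants and sorted by position.  In the sparse backend ``hap_data`` holds,
    haplotype by haplotype, the sorted registry indices each haplotype carries,
    delimited by ``hap_off`` (length 2N+1).  In the dense backend ``Hd`` is the
    (2N, S) uint8 presence matrix.  Substitutions (variants fixed population-wide)
    move to the ``sub_*`` log; dropping them leaves relative fitness unchanged
    because a fixed multiplicative factor is shared by everyone.
    """

    N: int
    generation: int
    pos: np.ndarray          # (S,) int64, sorted
    s: np.ndarray            # (S,) float64 scaled selection coefficient
    h: np.ndarray            # (S,) float64 dominance
    is_te: np.ndarray        # (S,) int8, SNP or TE
    len_class: np.ndarray    # (S,) int8, NOT_TE / SHORT / LONG
    sel_code: np.ndarray     # (S,) int8 (SNP selection class; NEUTRAL for TEs)
    origin: np.ndarray       # (S,) int32 origin generation
    # sparse backend
    hap_data: np.ndarray | None = None   # int32 flat, sorted within haplotype
    hap_off: np.ndarray | None = None    # (2N+1,) int64
    # sparse backend: selected-variant (s != 0) sublists, same layout; lets
    # fitness walk only selected alleles
    sel_data: np.ndarray | None = None
    sel_off: np.ndarray | None = None
    # dense backend
    Hd: np.ndarray | None = None         # (2N, S) uint8
    # substitution log
    sub_pos: list = field(default_factory=list)
    sub_is_te: list = field(default_factory=list)
    sub_len_class: list = field(default_factory=list)
    sub_sel_code: list = field(default_factory=list)
    sub_s: list = field(default_factory=list)
    sub_origin: list = field(default_factory=list)
    sub_fixed_gen: list = field(default_factory=list)
    # conservation accounting
    n_created: int = 0
    n_lost: int = 0
    # TE draw-time event counters by region class
    te_draws_high: int = 0
    te_draws_low: int = 0

    @property
    def sparse(self) -> bool:
        return self.hap_data is not None

    @property
    def n_segregating(self) -> int:
        return self.pos.size

    @property
    def H(self) -> np.ndarray:
        """(2N, S) uint8 presence matrix (materialized when sparse)."""
        if not self.sparse:
            return self.Hd
        twoN = 2 * self.N
        H = np.zeros((twoN, self.pos.size), dtype=np.uint8)
        if self.hap_data.size:
            rows = np.repeat(np.arange(twoN), np.diff(self.hap_off))
            H[rows, self.hap_data] = 1
        return H

    def haplotype(self, i: int) -> np.ndarray:
        """Sorted registry indices carried by haplotype ``i``."""
        if self.sparse:
            return self.hap_data[self.hap_off[i]: self.hap_off[i + 1]]
        return np.nonzero(self.Hd[i])[0]

    def counts(self) -> np.ndarray:
        """Population allele counts of segregating variants, in [1, 2N-1]."""
        if self.sparse:
            return np.bincount(self.hap_data, minlength=self.pos.size).astype(np.int64)
        return self.Hd.sum(axis=0, dtype=np.int64)

    @property
    def n_substitutions(self) -> int:
        return len(self.sub_pos)


def initialize_population(
    params: SimParams, layout: GenomeLayout, backend: str = "sparse"
) -> PopulationState:
    N = params.N_scaled
    st = PopulationState(
        N=N,
        generation=0,
        pos=np.empty(0, dtype=np.int64),
        s=np.empty(0, dtype=np.float64),
        h=np.empty(0, dtype=np.float64),
        is_te=np.empty(0, dtype=np.int8),
        len_class=np.full(0, NOT_TE, dtype=np.int8),
        sel_code=np.empty(0, dtype=np.int8),
        origin=np.empty(0, dtype=np.int32),
    )
    if backend == "sparse":
        st.hap_data = np.empty(0, dtype=np.int32)
        st.hap_off = np.zeros(2 * N + 1, dtype=np.int64)
        st.sel_data = np.empty(0, dtype=np.int32)
        st.sel_off = np.zeros(2 * N + 1, dtype=np.int64)
    elif backend == "dense":
        st.Hd = np.zeros((2 * N, 0), dtype=np.uint8)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return st


def transposition_rate_at(gen: int, params: SimParams) -> float:
    """Per-diploid fragment insertion rate at scaled generation ``gen``.

    Constant mode: the rescaled fragment rate at every generation.  Burst mode:
    ``burst_multiplier`` times the fragment rate inside the burst window
    [burst_start_gen, burst_end_gen) and zero outside.
    """
    te = params.te_params
    base = fragment_insertion_rate(
        te, params.raw.fragment_length, params.raw.genome_length
    ) * params.lam
    if te.constant_mode:
        return base
    if params.burst_start_gen <= gen < params.burst_end_gen:
        return te.burst_multiplier * base
    return 0.0


def _draw_te_batch(
    n: int,
    params: SimParams,
    layout: GenomeLayout,
    gen: int,
    rng: np.random.Generator,
):
    """Vectorized draw of ``n`` TE insertions; returns metadata arrays."""
    te = params.te_params
    in_high = rng.random(n) < te.Q
    pos = np.empty(n, dtype=np.int64)
    for klass, mask in (("high", in_high), ("low", ~in_high)):
        k = int(mask.sum())
        if k == 0:
            continue
        intervals = layout.class_intervals(klass)
        lens = np.array([e - s for s, e in intervals], dtype=np.float64)
        which = rng.choice(len(intervals), size=k, p=lens / lens.sum())
        starts = np.array([s for s, _ in intervals])
        widths = np.array([e - s for s, e in intervals])
        pos[mask] = starts[which] + (rng.random(k) * widths[which]).astype(np.int64)
    long = (rng.random(n) < te.p_long).astype(np.int8)
    in_exon = layout.in_exon(pos)
    s_eff = np.where(
        in_exon,
        params.s_of(te.two_N_s_coding),
        np.where(
            long == LONG,
            np.where(
                in_high,
                params.s_of(te.two_N_s_long_high),
                params.s_of(te.two_N_s_long_low),
            ),
            params.s_of(te.two_N_s_short),
        ),
    )
    return pos, long, in_exon, in_high, s_eff


def draw_te_insertion(
    params: SimParams, layout: GenomeLayout, gen: int, rng: np.random.Generator
) -> TEInsertion:
    """Draw one new TE insertion: region class ~ Bernoulli(Q) for high, position
    uniform within the class, length class long with probability p_long, fitness
    effect resolved from exon membership / region class at insertion time."""
    if transposition_rate_at(gen, params) <= 0:
        raise ValueError("transposition rate is zero at this generation")
    pos, long, in_exon, in_high, s_eff = _draw_te_batch(1, params, layout, gen, rng)
    return TEInsertion(
        position=int(pos[0]),
        length_class="long" if long[0] == LONG else "short",
        in_exon=bool(in_exon[0]),
        in_high=bool(in_high[0]),
        s_effective=float(s_eff[0]),
        origin_gen=gen,
    )


def _draw_mutation_batch(
    n: int,
    params: SimParams,
    layout: GenomeLayout,
    gen: int,
    rng: np.random.Generator,
    avoid_pos: np.ndarray,
):
    """Vectorized draw of ``n`` point mutations with finite-sites collision
    re-draw against ``avoid_pos`` (sorted) and within the batch."""
    L = params.raw.fragment_length
    pos = rng.integers(0, L, size=n)
    for _ in range(100):
        bad = np.zeros(n, dtype=bool)
        if avoid_pos.size:
            idx = np.searchsorted(avoid_pos, pos)
            idx_c = np.clip(idx, 0, avoid_pos.size - 1)
            bad |= avoid_pos[idx_c] == pos
        # collisions within the batch: keep first occurrence
        order = np.argsort(pos, kind="stable")
        sp = pos[order]
        dup = np.zeros(n, dtype=bool)
        dup[order[1:]] = sp[1:] == sp[:-1]
        bad |= dup
        if not bad.any():
            break
        pos[bad] = rng.integers(0, L, size=int(bad.sum()))
    else:
        raise RuntimeError(
            "finite-sites collision re-draw did not converge; "
            "segregating sites saturate the fragment"
        )
    in_exon = layout.in_exon(pos)
    table = params.selection_classes
    sel_code = np.zeros(n, dtype=np.int8)
    s = np.zeros(n, dtype=np.float64)
    h = np.full(n, 0.5, dtype=np.float64)
    u = rng.random(n)
    for ctx, mask in (("coding", in_exon), ("noncoding", ~in_exon)):
        rows = table.for_context(ctx)
        cum = 0.0
        assigned = np.zeros(n, dtype=bool)
        for row in rows:
            take = mask & ~assigned & (u >= cum) & (u < cum + row.fraction)
            cum += row.fraction
            if not take.any():
                continue
            assigned |= take
            s[take] = params.s_of(row.two_N_s)
            h[take] = row.dominance
            if row.two_N_s > 0:
                sel_code[take] = BENEFICIAL
            else:
                sel_code[take] = DEL_CODING if ctx == "coding" else DEL_NONCODING
    return pos, s, h, sel_code, in_exon


def draw_point_mutation(
    params: SimParams, layout: GenomeLayout, gen: int, rng: np.random.Generator
) -> Mutation:
    """Draw one point mutation: position uniform on the fragment, fitness class
    from the selection-class table row matching exon membership (neutral with the
    residual probability)."""
    pos, s, h, sel_code, _ = _draw_mutation_batch(
        1, params, layout, gen, rng, np.empty(0, dtype=np.int64)
    )
    return Mutation(
        position=int(pos[0]),
        sel_class=_SEL_NAMES[int(sel_code[0])],
        s=float(s[0]),
        h=float(h[0]),
        origin_gen=gen,
    )


def diploid_fitness(
    hapA: np.ndarray, hapB: np.ndarray, s: np.ndarray, h: np.ndarray
) -> float:
    """Multiplicative fitness of a diploid given two presence vectors over the same
    variant registry: heterozygote factor (1 + h*s), homozygote (1 + s), each
    factor floored at zero."""
    if hapA.shape != hapB.shape or hapA.shape != s.shape:
        raise ValueError("haplotype/registry shape mismatch")
    g = hapA.astype(np.int64) + hapB.astype(np.int64)
    factor = 1.0 + s * h * (g == 1) + s * (g == 2)
    return float(np.prod(np.clip(factor, 0.0, None)))


# ---------------------------------------------------------------------------
# backend kernels.  Sparse kernels are numba-compiled; numpy implementations
# double as the dense backend and the no-numba fallback.

def _fitness_dense(H, s, h):
    sel = np.nonzero(s != 0.0)[0]
    N = H.shape[0] // 2
    if sel.size == 0:
        return np.ones(N)
    Hs = H[:, sel].astype(np.int8)
    G = Hs[0::2] + Hs[1::2]
    factor = 1.0 + s[sel] * h[sel] * (G == 1) + s[sel] * (G == 2)
    return np.prod(np.clip(factor, 0.0, None), axis=1)


def _meiosis_dense(H, src, other, kvec, splits_flat, boffs):
    out = H[src]
    S = out.shape[1]
    for g in np.nonzero(kvec)[0]:
        sp = splits_flat[boffs[g]: boffs[g] + kvec[g]]
        parity = np.zeros(S, dtype=np.int64)
        for x in sp:
            parity[x:] += 1
        m = (parity & 1) == 1
        out[g, m] = H[other[g], m]
    return out


def _rebuild_dense(H_child, keep_idx, dest_old, dest_new, new_rows, S_next):
    out = np.zeros((H_child.shape[0], S_next), dtype=np.uint8)
    out[:, dest_old] = H_child[:, keep_idx]
    if dest_new.size:
        out[new_rows, dest_new] = 1
    return out


try:
    from numba import njit

    @njit(cache=True)
    def _fitness_sparse(hap_data, hap_off, s, h, N):  # pragma: no cover
        w = np.ones(N)
        for i in range(N):
            a = hap_off[2 * i]
            a1 = hap_off[2 * i + 1]
            b = a1
            b1 = hap_off[2 * i + 2]
            acc = 1.0
            while a < a1 or b < b1:
                if a < a1 and (b >= b1 or hap_data[a] < hap_data[b]):
                    e = hap_data[a]
                    a += 1
                    g = 1
                elif b < b1 and (a >= a1 or hap_data[b] < hap_data[a]):
                    e = hap_data[b]
                    b += 1
                    g = 1
                else:  # equal: homozygote
                    e = hap_data[a]
                    a += 1
                    b += 1
                    g = 2
                se = s[e]
                if se != 0.0:
                    f = 1.0 + (h[e] * se if g == 1 else se)
                    if f < 0.0:
                        f = 0.0
                    acc *= f
            w[i] = acc
        return w

    @njit(cache=True)
    def _meiosis_sparse(hap_data, hap_off, src, other, kvec, splits_flat, boffs, S):  # pragma: no cover
        twoN = src.size
        cap = 0
        for g in range(twoN):
            cap += (hap_off[src[g] + 1] - hap_off[src[g]]) + (
                hap_off[other[g] + 1] - hap_off[other[g]]
            )
        out = np.empty(cap, dtype=np.int32)
        out_off = np.zeros(twoN + 1, dtype=np.int64)
        cur = 0
        for g in range(twoN):
            k = kvec[g]
            a = src[g]
            if k == 0:
                lo = hap_off[a]
                hi = hap_off[a + 1]
                for t in range(lo, hi):
                    out[cur] = hap_data[t]
                    cur += 1
            else:
                b = other[g]
                o = boffs[g]
                use_a = True
                c0 = 0
                for i in range(k + 1):
                    c1 = splits_flat[o + i] if i < k else S
                    hap = a if use_a else b
                    lo = hap_off[hap]
                    hi = hap_off[hap + 1]
                    # binary search range [c0, c1) within sorted list
                    s0 = np.searchsorted(hap_data[lo:hi], c0)
                    s1 = np.searchsorted(hap_data[lo:hi], c1)
                    for t in range(lo + s0, lo + s1):
                        out[cur] = hap_data[t]
                        cur += 1
                    use_a = not use_a
                    c0 = c1
            out_off[g + 1] = cur
        return out[:cur], out_off

    @njit(cache=True)
    def _rebuild_sparse(child_data, child_off, colmap, new_sorted_rows,
                        new_sorted_ids, twoN):  # pragma: no cover
        n_new = new_sorted_ids.size
        out = np.empty(child_data.size + n_new, dtype=np.int32)
        out_off = np.zeros(twoN + 1, dtype=np.int64)
        cur = 0
        p_new = 0
        for g in range(twoN):
            lo = child_off[g]
            hi = child_off[g + 1]
            # new ids destined for this row (sorted by id)
            nlo = p_new
            while p_new < n_new and new_sorted_rows[p_new] == g:
                p_new += 1
            nhi = p_new
            i = lo
            j = nlo
            while i < hi or j < nhi:
                if i < hi:
                    m = colmap[child_data[i]]
                    if m < 0:
                        i += 1
                        continue
                    if j < nhi and new_sorted_ids[j] < m:
                        out[cur] = new_sorted_ids[j]
                        j += 1
                    else:
                        out[cur] = m
                        i += 1
                else:
                    out[cur] = new_sorted_ids[j]
                    j += 1
                cur += 1
            out_off[g + 1] = cur
        return out[:cur], out_off

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _fitness_sparse_py(hap_data, hap_off, s, h, N):  # numpy fallback
    H = np.zeros((2 * N, s.size), dtype=np.uint8)
    if hap_data.size:
        rows = np.repeat(np.arange(2 * N), np.diff(hap_off))
        H[rows, hap_data] = 1
    return _fitness_dense(H, s, h)


def _meiosis_sparse_py(hap_data, hap_off, src, other, kvec, splits_flat, boffs, S):
    parts = []
    out_off = np.zeros(src.size + 1, dtype=np.int64)
    for g in range(src.size):
        k = kvec[g]
        A = hap_data[hap_off[src[g]]: hap_off[src[g] + 1]]
        if k == 0:
            seg = A
        else:
            B = hap_data[hap_off[other[g]]: hap_off[other[g] + 1]]
            bounds = np.concatenate([[0], splits_flat[boffs[g]: boffs[g] + k], [S]])
            chunks = []
            for i in range(k + 1):
                lst = A if i % 2 == 0 else B
                c0, c1 = bounds[i], bounds[i + 1]
                chunks.append(lst[np.searchsorted(lst, c0): np.searchsorted(lst, c1)])
            seg = np.concatenate(chunks) if chunks else A[:0]
        parts.append(seg)
        out_off[g + 1] = out_off[g] + seg.size
    data = np.concatenate(parts) if parts else np.empty(0, np.int32)
    return data.astype(np.int32), out_off


def _rebuild_sparse_py(child_data, child_off, colmap, new_rows_sorted,
                       new_ids_sorted, twoN):
    parts = []
    out_off = np.zeros(twoN + 1, dtype=np.int64)
    for g in range(twoN):
        old = colmap[child_data[child_off[g]: child_off[g + 1]]]
        old = old[old >= 0]
        new = new_ids_sorted[new_rows_sorted == g]
        merged = np.sort(np.concatenate([old, new]))
        parts.append(merged)
        out_off[g + 1] = out_off[g] + merged.size
    data = np.concatenate(parts) if parts else np.empty(0, np.int32)
    return data.astype(np.int32), out_off


if not _HAVE_NUMBA:  # pragma: no cover
    _fitness_sparse = _fitness_sparse_py
    _meiosis_sparse = _meiosis_sparse_py
    _rebuild_sparse = _rebuild_sparse_py


def _fitness_vector(state: PopulationState) -> np.ndarray:
    if state.sparse:
        return _fitness_sparse(
            state.sel_data, state.sel_off, state.s, state.h, state.N
        )
    return _fitness_dense(state.Hd, state.s, state.h)


def _crossover_plan(
    state: PopulationState,
    layout: GenomeLayout,
    parents: np.ndarray,
    rng: np.random.Generator,
):
    """Draw coin starts and Poisson crossovers per gamete; crossover positions map
    to registry column split indices (columns are position-sorted)."""
    twoN = 2 * state.N
    par_hap = parents.reshape(-1)
    coin = rng.integers(0, 2, size=twoN)
    src = (2 * par_hap + coin).astype(np.int64)
    other = (2 * par_hap + (1 - coin)).astype(np.int64)

    regions = layout.regions
    map_lens = np.array([r.rec_rate * r.length for r in regions])
    kreg = rng.poisson(map_lens, size=(twoN, len(regions)))
    kvec = kreg.sum(axis=1).astype(np.int64)
    total = int(kvec.sum())
    if total:
        gidx = []
        bpos = []
        for ri, r in enumerate(regions):
            cnt = kreg[:, ri]
            t = int(cnt.sum())
            if t == 0:
                continue
            gidx.append(np.repeat(np.arange(twoN), cnt))
            bpos.append(rng.uniform(r.start, r.end, size=t))
        gidx = np.concatenate(gidx)
        bpos = np.concatenate(bpos)
        order = np.lexsort((bpos, gidx))
        breaks_flat = bpos[order]
    else:
        breaks_flat = np.empty(0)
    boffs = np.zeros(twoN, dtype=np.int64)
    np.cumsum(kvec[:-1], out=boffs[1:])
    splits_flat = np.searchsorted(state.pos, breaks_flat).astype(np.int64)
    return src, other, kvec, splits_flat, boffs


def step_generation(
    state: PopulationState,
    params: SimParams,
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> PopulationState:
    """Advance one Wright-Fisher generation in place (state is also returned)."""
    N = state.N
    twoN = 2 * N
    L = params.raw.fragment_length
    S = state.pos.size

    # 1) fitness-proportional parent sampling (inverse-CDF)
    if (state.s != 0.0).any():
        w = _fitness_vector(state)
        cdf = np.cumsum(w)
        if cdf[-1] <= 0:
            raise RuntimeError("population fitness collapsed to zero")
        parents = np.searchsorted(cdf, rng.random((N, 2)) * cdf[-1], side="right")
    else:
        parents = rng.integers(0, N, size=(N, 2))

    # 2) meiosis
    src, other, kvec, splits_flat, boffs = _crossover_plan(
        state, layout, parents, rng
    )
    if state.sparse:
        child_data, child_off = _meiosis_sparse(
            state.hap_data, state.hap_off, src, other, kvec, splits_flat, boffs, S
        )
        child_sel, child_sel_off = _meiosis_sparse(
            state.sel_data, state.sel_off, src, other, kvec, splits_flat, boffs, S
        )
        counts = np.bincount(child_data, minlength=S).astype(np.int64)
    else:
        H_child = _meiosis_dense(state.Hd, src, other, kvec, splits_flat, boffs)
        counts = H_child.sum(axis=0, dtype=np.int64)

    # 3) new point mutations (thinned neutral tracking is a measurement choice:
    #    neutral sites do not affect the dynamics)
    n_mut = rng.poisson(twoN * L * params.mu_scaled)
    if n_mut:
        mpos, ms, mh, mcode, _ = _draw_mutation_batch(
            n_mut, params, layout, state.generation, rng, state.pos
        )
        if params.tracked_neutral_fraction < 1.0:
            keep_m = (mcode != NEUTRAL) | (
                rng.random(n_mut) < params.tracked_neutral_fraction
            )
            mpos, ms, mh, mcode = mpos[keep_m], ms[keep_m], mh[keep_m], mcode[keep_m]
            n_mut = int(keep_m.sum())
    else:
        mpos = np.empty(0, dtype=np.int64)
        ms = mh = np.empty(0)
        mcode = np.empty(0, dtype=np.int8)

    # 4) new TE insertions
    rate = transposition_rate_at(state.generation, params)
    n_te = rng.poisson(N * rate) if rate > 0 else 0
    if n_te:
        tpos, tlong, _texon, thigh, ts = _draw_te_batch(
            n_te, params, layout, state.generation, rng
        )
        state.te_draws_high += int(thigh.sum())
        state.te_draws_low += int(n_te - thigh.sum())
    else:
        tpos = np.empty(0, dtype=np.int64)
        tlong = np.empty(0, dtype=np.int8)
        ts = np.empty(0)

    n_new = n_mut + n_te
    state.n_created += n_new

    # 5) bookkeeping: fixed -> substitution log; lost -> dropped
    fixed = counts == twoN
    lost = counts == 0
    keep = ~(fixed | lost)
    state.n_lost += int(lost.sum())
    if fixed.any():
        for j in np.nonzero(fixed)[0]:
            state.sub_pos.append(int(state.pos[j]))
            state.sub_is_te.append(int(state.is_te[j]))
            state.sub_len_class.append(int(state.len_class[j]))
            state.sub_sel_code.append(int(state.sel_code[j]))
            state.sub_s.append(float(state.s[j]))
            state.sub_origin.append(int(state.origin[j]))
            state.sub_fixed_gen.append(state.generation + 1)

    # stable two-way merge of kept old columns and sorted new columns keeps the
    # registry position-sorted
    gen = np.int32(state.generation)
    keep_idx = np.nonzero(keep)[0]
    npos = np.concatenate([mpos, tpos])
    ns = np.concatenate([ms, ts])
    nh = np.concatenate([mh, np.full(n_te, 0.5)])
    nis_te = np.concatenate([np.zeros(n_mut, np.int8), np.ones(n_te, np.int8)])
    nlen = np.concatenate([np.full(n_mut, NOT_TE, np.int8), tlong])
    ncode = np.concatenate([mcode, np.zeros(n_te, np.int8)])
    order = np.argsort(npos, kind="stable")
    npos, ns, nh = npos[order], ns[order], nh[order]
    nis_te, nlen, ncode = nis_te[order], nlen[order], ncode[order]

    new_rows = rng.integers(0, twoN, size=n_new)  # one carrier haplotype each

    pos_keep = state.pos[keep_idx]
    dest_new = np.searchsorted(pos_keep, npos, side="right") + np.arange(n_new)
    dest_old = np.arange(keep_idx.size) + np.searchsorted(
        npos, pos_keep, side="left"
    )
    S_next = keep_idx.size + n_new

    if state.sparse:
        colmap = np.full(S, -1, dtype=np.int64)
        colmap[keep_idx] = dest_old
        ro = np.argsort(new_rows, kind="stable")
        # within a row, ids must be ascending; dest_new is ascending in the
        # position-sorted new order, and stable argsort preserves that
        state.hap_data, state.hap_off = _rebuild_sparse(
            child_data, child_off, colmap,
            new_rows[ro].astype(np.int64), dest_new[ro].astype(np.int32), twoN,
        )
        selm = ns != 0.0
        ros = np.argsort(new_rows[selm], kind="stable")
        state.sel_data, state.sel_off = _rebuild_sparse(
            child_sel, child_sel_off, colmap,
            new_rows[selm][ros].astype(np.int64),
            dest_new[selm][ros].astype(np.int32), twoN,
        )
    else:
        state.Hd = _rebuild_dense(
            H_child, keep_idx, dest_old, dest_new, new_rows, S_next
        )

    def _merged(old, new):
        res = np.empty(S_next, dtype=old.dtype)
        res[dest_old] = old[keep_idx]
        res[dest_new] = new
        return res

    state.pos = _merged(state.pos, npos)
    state.s = _merged(state.s, ns)
    state.h = _merged(state.h, nh)
    state.is_te = _merged(state.is_te, nis_te)
    state.len_class = _merged(state.len_class, nlen)
    state.sel_code = _merged(state.sel_code, ncode)
    state.origin = _merged(state.origin, np.full(n_new, gen, np.int32))
    state.generation += 1
    return state


def introduce_variant(
    state: PopulationState,
    rng: np.random.Generator,
    *,
    s: float = 0.0,
    h: float = 0.5,
    count: int = 1,
    position: int = 0,
    is_te: int = SNP,
    length_class: int = NOT_TE,
) -> PopulationState:
    """Add a single variant at the given initial copy count on randomly chosen
    haplotypes (used for fixation-probability validation)."""
    twoN = 2 * state.N
    rows = rng.choice(twoN, size=count, replace=False)
    j = int(np.searchsorted(state.pos, position))  # keep registry sorted
    if state.sparse and state.n_segregating == 0:
        # fast path for seeding an empty population (fixation trials)
        carriers = np.sort(rows)
        for attr_d, attr_o, carry in (
            ("hap_data", "hap_off", True),
            ("sel_data", "sel_off", s != 0.0),
        ):
            if carry:
                setattr(state, attr_d, np.zeros(count, np.int32))
                off = np.zeros(2 * state.N + 1, np.int64)
                off[carriers + 1] = 1
                setattr(state, attr_o, np.cumsum(off))
    elif state.sparse:
        for attr_d, attr_o, carry in (
            ("hap_data", "hap_off", True),
            ("sel_data", "sel_off", s != 0.0),
        ):
            data = getattr(state, attr_d)
            off = getattr(state, attr_o)
            data = data + (data >= j).astype(np.int32)
            parts = []
            for g in range(twoN):
                lst = data[off[g]: off[g + 1]]
                if carry and g in rows:
                    lst = np.sort(np.append(lst, np.int32(j)))
                parts.append(lst)
            setattr(state, attr_d,
                    np.concatenate(parts).astype(np.int32) if parts else data)
            setattr(state, attr_o, np.concatenate(
                [[0], np.cumsum([p.size for p in parts])]).astype(np.int64))
    else:
        col = np.zeros((twoN, 1), dtype=np.uint8)
        col[rows, 0] = 1
        state.Hd = np.concatenate(
            [state.Hd[:, :j], col, state.Hd[:, j:]], axis=1
        )
    state.pos = np.insert(state.pos, j, position)
    state.s = np.insert(state.s, j, s)
    state.h = np.insert(state.h, j, h)
    state.is_te = np.insert(state.is_te, j, np.int8(is_te))
    state.len_class = np.insert(state.len_class, j, np.int8(length_class))
    state.sel_code = np.insert(state.sel_code, j, np.int8(NEUTRAL))
    state.origin = np.insert(state.origin, j, np.int32(state.generation))
    state.n_created += 1
    return state


@dataclass
class SimResult:
    params: SimParams
    layout: GenomeLayout
    seed: int | None
    state: PopulationState
    trajectory: list  # optional (gen, n_seg_snp, n_seg_te) tuples

    @property
    def te_draws_high(self) -> int:
        return self.state.te_draws_high

    @property
    def te_draws_low(self) -> int:
        return self.state.te_draws_low


def run_simulation(
    params: SimParams,
    seed: int | None = None,
    *,
    layout: GenomeLayout | None = None,
    trajectory_every: int = 0,
    stop_when_absorbed: bool = False,
    backend: str = "sparse",
) -> SimResult:
    """Run the full forward simulation; deterministic given (params, seed).

    ``stop_when_absorbed`` short-circuits generations once no variant segregates
    and no further input is possible (mu = 0 and no future transposition), which
    makes repeated single-variant fixation trials cheap.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    if layout is None:
        layout = build_layout(params, rng)
    state = initialize_population(params, layout, backend=backend)
    trajectory = []
    for gen in range(params.generations_scaled):
        if stop_when_absorbed and state.n_segregating == 0:
            no_mut = params.mu_scaled == 0
            te = params.te_params
            no_te = (te.P == 0) or (
                not te.constant_mode and gen >= params.burst_end_gen
            )
            if no_mut and no_te:
                state.generation = params.generations_scaled
                break
        step_generation(state, params, layout, rng)
        if trajectory_every and state.generation % trajectory_every == 0:
            n_te = int((state.is_te == TE).sum())
            trajectory.append(
                (state.generation, state.n_segregating - n_te, n_te)
            )
    return SimResult(params, layout, seed, state, trajectory)
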