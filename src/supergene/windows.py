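"""Sliding-window population-genetic statistics on haploid genotypes.

Windows are defined over *accessible* (non-N) reference positions: a window
always spans exactly ``size`` non-N bases, stretching further in physical
coordinates when it crosses an assembly gap, and successive windows start
``step`` accessible bases apart. Per window the module computes:

* multilocus FST between the SB and Sb groups — a two-level
  (Weir–Cockerham-style) variance-components estimator on haploid allele
  indicators, combined across sites as a ratio of sums. Negative values are
  meaningful (between-group variance smaller than within-group, as happens
  when the groups are composed of cross-group sibling pairs) and a window
  with no allelic variance has *undefined* FST (returned as NaN, never 0).
* nucleotide diversity π per accessible bp within a group (Nei's unbiased
  per-site heterozygosity, equal to the mean pairwise difference rate).
* counts of sites with fixed differences between the groups (all SB samples
  share one allele, all Sb samples share a different one), SNPs and indels
  tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io import MISSING, STRTable, SampleSet, VariantTable

__all__ = [
    "Window",
    "WindowStats",
    "make_windows",
    "multilocus_fst",
    "fst_components",
    "nucleotide_diversity",
    "fixed_differences",
    "str_fixed_differences",
    "genotype_distance_matrix",
    "compute_window_stats",
]


@dataclass(frozen=True)
class Window:
    """A window over one scaffold/pseudo-chromosome.

    ``start``/``end`` are 0-based half-open physical coordinates;
    ``accessible`` counts the non-N reference positions spanned (equal to the
    nominal window size except for flagged terminal partial windows).
    """

    chrom: str
    start: int
    end: int
    accessible: int
    partial: bool = False


@dataclass
class WindowStats:
    window: Window
    fst: float  # NaN when undefined
    pi_SB: float
    pi_Sb: float
    fixed_snps: int
    fixed_indels: int
    n_variants_SB: int = 0
    n_variants_Sb: int = 0


def make_windows(sequence: str, chrom: str, size: int, step: int) -> list[Window]:
    """Tile ``sequence`` with windows of ``size`` accessible (non-N) bases
    every ``step`` accessible bases. All-N sequence yields no windows."""
    if not (1 <= step <= size):
        raise ValueError("require size >= step >= 1")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    non_n = np.flatnonzero(arr != ord("N"))
    if non_n.size == 0:
        return []
    out = []
    k = 0
    while k < non_n.size:
        stop = k + size
        partial = stop > non_n.size
        last = non_n.size - 1 if partial else stop - 1
        out.append(Window(
            chrom=chrom,
            start=int(non_n[k]),
            end=int(non_n[last]) + 1,
            accessible=int(last - k + 1),
            partial=partial,
        ))
        if partial:
            break
        k += step
    return out


def _group_matrices(vt: VariantTable, ss: SampleSet):
    g1 = vt.sample_indices(ss.group_members("SB"))
    g2 = vt.sample_indices(ss.group_members("Sb"))
    return vt.genotypes[:, g1], vt.genotypes[:, g2]


def fst_components(geno_a: np.ndarray, geno_b: np.ndarray):
    """Per-site variance components (a, b) of the haploid two-group ANOVA.

    For each site and each allele observed there, the allele-presence
    indicator is decomposed into among-group (a) and within-group (b)
    components; components are summed over alleles per site. Sites with any
    missing call are excluded (returned components are NaN there).

    Returns (a, b): arrays of length n_sites.
    """
    n1, n2 = geno_a.shape[1], geno_b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples for variance components")
    N = n1 + n2
    r = 2
    n_c = (N - (n1**2 + n2**2) / N) / (r - 1)
    n_sites = geno_a.shape[0]
    a_out = np.zeros(n_sites)
    b_out = np.zeros(n_sites)
    complete = (geno_a != MISSING).all(axis=1) & (geno_b != MISSING).all(axis=1)
    max_allele = int(max(geno_a.max(initial=0), geno_b.max(initial=0)))
    for al in range(max_allele + 1):
        xa = geno_a == al
        xb = geno_b == al
        p1 = xa.mean(axis=1)
        p2 = xb.mean(axis=1)
        pbar = (n1 * p1 + n2 * p2) / N
        msb = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # df = r-1 = 1
        ssw = n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)
        msw = ssw / (N - r)
        a_out += (msb - msw) / n_c
        b_out += msw
    a_out[~complete] = np.nan
    b_out[~complete] = np.nan
    return a_out, b_out


def multilocus_fst(vt: VariantTable, ss: SampleSet, window: Window | None = None) -> float:
    """Multilocus FST between SB and Sb over the sites in ``window``
    (or all sites when window is None), as a ratio of summed variance
    components. NaN when no site contributes allelic variance."""
    sub = _restrict(vt, window)
    snp = sub.take_sites(sub.is_snp())
    ga, gb = _group_matrices(snp, ss)
    if ga.shape[0] == 0:
        return float("nan")
    a, b = fst_components(ga, gb)
    ok = ~np.isnan(a)
    denom = (a[ok] + b[ok]).sum()
    if denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def _restrict(vt: VariantTable, window: Window | None) -> VariantTable:
    if window is None:
        return vt
    mask = (vt.scaffold == window.chrom) & (vt.pos - 1 >= window.start) & (vt.pos - 1 < window.end)
    return vt.take_sites(mask)


def nucleotide_diversity(vt: VariantTable, ss: SampleSet, group: str,
                         window: Window | None = None,
                         accessible: int | None = None) -> float:
    """Nei's nucleotide diversity π per accessible bp within one group.

    π = Σ_sites (n/(n-1)) (1 - Σ_i p_i²) / accessible, with p_i the allele
    frequencies among the group's called samples at the site — the mean
    pairwise difference rate. Sites with fewer than two calls are skipped.
    """
    if accessible is None:
        if window is None:
            raise ValueError("need a window or an explicit accessible-base count")
        accessible = window.accessible
    if accessible <= 0:
        raise ValueError("accessible bases must be positive")
    sub = _restrict(vt, window)
    idx = sub.sample_indices(ss.group_members(group))
    geno = sub.genotypes[:, idx]
    return float(_pi_sum(geno) / accessible)


def _pi_sum(geno: np.ndarray) -> float:
    """Sum over sites of the unbiased per-site heterozygosity."""
    if geno.shape[0] == 0:
        return 0.0
    called = geno != MISSING
    n = called.sum(axis=1).astype(float)
    total = 0.0
    usable = n >= 2
    if not usable.any():
        return 0.0
    g = geno[usable]
    nn = n[usable]
    max_allele = int(g.max(initial=0))
    sum_p2 = np.zeros(g.shape[0])
    for al in range(max_allele + 1):
        cnt = (g == al).sum(axis=1)
        sum_p2 += (cnt / nn) ** 2
    het = nn / (nn - 1) * (1.0 - sum_p2)
    return float(het.sum())


def fixed_differences(vt: VariantTable, ss: SampleSet, window: Window | None = None):
    """Sites where all SB calls share one allele and all Sb calls share a
    different allele. Returns (snp_count, indel_count, site_index_array)
    with indices into the (window-restricted) table."""
    sub = _restrict(vt, window)
    ga, gb = _group_matrices(sub, ss)
    if ga.shape[0] == 0:
        return 0, 0, np.array([], dtype=int)
    complete = (ga != MISSING).all(axis=1) & (gb != MISSING).all(axis=1)
    mono_a = (ga == ga[:, :1]).all(axis=1)
    mono_b = (gb == gb[:, :1]).all(axis=1)
    fixed = complete & mono_a & mono_b & (ga[:, 0] != gb[:, 0])
    idx = np.flatnonzero(fixed)
    snp = int((sub.vclass[idx] == "SNP").sum())
    indel = len(idx) - snp
    return snp, indel, idx


def str_fixed_differences(st: STRTable, ss: SampleSet) -> pd.DataFrame:
    """STR loci fixed for alternative repeat-unit alleles in SB vs Sb.

    Returns a DataFrame (locus_id, scaffold, pos, units_SB, units_Sb,
    unit_difference) for loci where each group is internally invariant and
    the two groups differ; |units_SB - units_Sb| is the quantity plotted in
    strata inspection.
    """
    ia = st.sample_indices([s for s in st.samples if ss.groups.get(s) == "SB"])
    ib = st.sample_indices([s for s in st.samples if ss.groups.get(s) == "Sb"])
    ua, ub = st.units[:, ia], st.units[:, ib]
    complete = (ua != MISSING).all(axis=1) & (ub != MISSING).all(axis=1)
    mono_a = (ua == ua[:, :1]).all(axis=1)
    mono_b = (ub == ub[:, :1]).all(axis=1)
    fixed = complete & mono_a & mono_b & (ua[:, 0] != ub[:, 0])
    idx = np.flatnonzero(fixed)
    df = st.loci.iloc[idx][["locus_id", "scaffold", "pos"]].copy().reset_index(drop=True)
    df["units_SB"] = ua[idx, 0]
    df["units_Sb"] = ub[idx, 0]
    df["unit_difference"] = np.abs(ua[idx, 0] - ub[idx, 0])
    return df


def genotype_distance_matrix(vt: VariantTable, samples: list[str] | None = None):
    """Pairwise genotype distances and an average-linkage dendrogram.

    The distance between two haploid samples is the Euclidean norm of the
    difference of their (scaled) allele-indicator vectors, which equals
    sqrt(k) for samples differing at k sites. Sites with a missing call in
    either sample of a pair are skipped for that pair.

    Returns (distance_matrix, linkage_matrix, samples).
    """
    if samples is None:
        samples = list(vt.samples)
    idx = vt.sample_indices(samples)
    g = vt.genotypes[:, idx]
    m = len(samples)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ok = (g[:, i] != MISSING) & (g[:, j] != MISSING)
            k = int((g[ok, i] != g[ok, j]).sum())
            d[i, j] = d[j, i] = np.sqrt(k)
    z = linkage(squareform(d, checks=False), method="average") if m > 1 else None
    return d, z, samples


def compute_window_stats(vt_all: VariantTable, vt_sb: VariantTable,
                         vt_sbm: VariantTable, ss: SampleSet,
                         windows: list[Window]) -> list[WindowStats]:
    """Per-window statistics for a scan.

    ``vt_all`` is the whole-set-filtered table (FST, fixed differences);
    ``vt_sb``/``vt_sbm`` are the per-group-filtered tables for SB and Sb
    (diversity). Sites are assigned to windows by physical position; since
    sliding windows may overlap, a site can contribute to several windows.
    """
    out = []
    for w in windows:
        fst = multilocus_fst(vt_all, ss, w)
        snp, indel, _ = fixed_differences(vt_all, ss, w)
        pi_a = nucleotide_diversity(vt_sb, ss, "SB", w)
        pi_b = nucleotide_diversity(vt_sbm, ss, "Sb", w)
        na = _restrict(vt_sb, w).n_sites
        nb = _restrict(vt_sbm, w).n_sites
        out.append(WindowStats(w, fst, pi_a, pi_b, snp, indel, na, nb))
    return out


def window_stats_frame(stats: list[WindowStats]) -> pd.DataFrame:
    """BED-like table of per-window statistics."""
    return pd.DataFrame([
        {
            "chrom": s.window.chrom,
            "start": s.window.start,
            "end": s.window.end,
            "accessible": s.window.accessible,
            "partial": s.window.partial,
            "fst": s.fst,
            "pi_SB": s.pi_SB,
            "pi_Sb": s.pi_Sb,
            "fixed_snps": s.fixed_snps,
            "fixed_indels": s.fixed_indels,
            "n_variants_SB": s.n_variants_SB,
            "n_variants_Sb": s.n_variants_Sb,
        }
        for s in stats
    ])
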