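"""Builders for compact in-memory test objects."""

from __future__ import annotations

import numpy as np
import pandas as pd

from supergene.io import STRTable, SampleSet, VariantTable


def build_sampleset(n_per_group: int = 8, high=("SB1", "Sb1")) -> SampleSet:
    sb = [f"SB{i + 1}" for i in range(n_per_group)]
    sbm = [f"Sb{i + 1}" for i in range(n_per_group)]
    samples = sb + sbm
    return SampleSet(
        samples=samples,
        groups={s: "SB" for s in sb} | {s: "Sb" for s in sbm},
        coverage_class={s: ("high" if s in high else "low") for s in samples},
        sibling_pair={s: i + 1 for i, s in enumerate(sb)}
        | {s: i + 1 for i, s in enumerate(sbm)},
    )


def build_vt(geno, samples=None, scaffold="scf_1", start=100, step=10,
             vclass="SNP", ref="A", alt="T", site_conf=99.0, gt_conf=50.0,
             cov=5) -> VariantTable:
    """VariantTable from a (n_sites, n_samples) genotype matrix of allele
    indices, with uniformly passing annotations unless overridden.

    ``site_conf``/``gt_conf``/``cov`` may be scalars or full arrays.
    """
    geno = np.atleast_2d(np.asarray(geno, dtype=np.int16))
    n_sites, n_samples = geno.shape
    if samples is None:
        half = n_samples // 2
        samples = [f"SB{i + 1}" for i in range(half)] + \
                  [f"Sb{i + 1}" for i in range(n_samples - half)]
    pos = np.arange(start, start + step * n_sites, step, dtype=np.int64)
    alts = np.empty(n_sites, dtype=object)
    for i in range(n_sites):
        alts[i] = (alt,) if isinstance(alt, str) else tuple(alt)
    return VariantTable(
        scaffold=np.array([scaffold] * n_sites, dtype=object),
        pos=pos,
        ref=np.array([ref] * n_sites, dtype=object),
        alts=alts,
        vclass=np.array([vclass] * n_sites, dtype=object),
        site_conf=np.broadcast_to(np.asarray(site_conf, dtype=float),
                                  (n_sites,)).copy(),
        genotypes=geno,
        gt_conf=np.broadcast_to(np.asarray(gt_conf, dtype=float),
                                (n_sites, n_samples)).copy(),
        cov=np.broadcast_to(np.asarray(cov, dtype=np.int32),
                            (n_sites, n_samples)).copy(),
        samples=list(samples),
    )


def build_str(units, samples=None, period=2, ref_units=8, q=0.9, support=5,
              coverage=12) -> STRTable:
    units = np.atleast_2d(np.asarray(units, dtype=np.int32))
    m, n_samples = units.shape
    if samples is None:
        half = n_samples // 2
        samples = [f"SB{i + 1}" for i in range(half)] + \
                  [f"Sb{i + 1}" for i in range(n_samples - half)]
    loci = pd.DataFrame({
        "locus_id": [f"str_{i}" for i in range(m)],
        "scaffold": ["scf_1"] * m,
        "pos": np.arange(500, 500 + 50 * m, 50),
        "period": np.broadcast_to(np.asarray(period), (m,)).copy(),
        "ref_units": np.broadcast_to(np.asarray(ref_units), (m,)).copy(),
        "score": [50] * m,
    })
    return STRTable(
        loci=loci,
        units=units,
        q=np.broadcast_to(np.asarray(q, dtype=float), (m, n_samples)).copy(),
        support=np.broadcast_to(np.asarray(support, dtype=np.int32),
                                (m, n_samples)).copy(),
        coverage=np.broadcast_to(np.asarray(coverage, dtype=np.int32),
                                 (m, n_samples)).copy(),
        samples=list(samples),
    )


def brute_force_fst(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Independent multilocus FST oracle: explicit two-level ANOVA on allele
    indicators, looping over sites, alleles and samples with no shared code
    with the implementation."""
    num = 0.0
    den = 0.0
    n1, n2 = geno_a.shape[1], geno_b.shape[1]
    N = n1 + n2
    n_c = (N - (n1 * n1 + n2 * n2) / N) / 1.0
    for s in range(geno_a.shape[0]):
        alleles = sorted(set(geno_a[s]) | set(geno_b[s]))
        for al in alleles:
            xs_a = [1.0 if g == al else 0.0 for g in geno_a[s]]
            xs_b = [1.0 if g == al else 0.0 for g in geno_b[s]]
            p1 = sum(xs_a) / n1
            p2 = sum(xs_b) / n2
            pbar = (sum(xs_a) + sum(xs_b)) / N
            ss_between = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
            ss_within = sum((x - p1) ** 2 for x in xs_a) + \
                sum((x - p2) ** 2 for x in xs_b)
            msb = ss_between / 1.0
            msw = ss_within / (N - 2)
            a = (msb - msw) / n_c
            b = msw
            num += a
            den += a + b
    if den == 0:
        return float("nan")
    return num / den
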