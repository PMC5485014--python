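"""Synthetic-data generator emulating the supergene study design.

The generator produces a small genome (a few scaffolds with contiguous
assembly gaps), haploid genotypes for two groups of brothers (default 8 SB
+ 8 Sb, one pair per colony), protein-coding gene models, STR loci, and a
linkage-marker table, together with a ground-truth record of everything it
planted. A contiguous region of one scaffold is planted as a non-recombining
supergene: inside it, SB-vs-Sb fixed differences occur at a configurable
per-bp density and each group has its own (asymmetric) diversity level;
outside it, both groups share a single polymorphism pool.

Variant sites are placed by independent per-site draws — the downstream
statistics consume only marginal site patterns (densities, within-group
frequencies), so no coalescent machinery is needed. Within-group allele
frequencies follow a neutral-like 1/i weighting over minor counts, which
keeps the mapping from a target per-bp diversity to a per-bp site density
analytic: density = pi / E[h], with E[h] the 1/i-weighted mean of the
unbiased per-site heterozygosity.

Identical parameters and seed give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    GeneModel,
    STRTable,
    SampleSet,
    VariantTable,
    write_fasta,
    write_gff3,
    write_marker_table,
    write_sample_manifest,
    write_str_table,
    write_vcf,
)

__all__ = [
    "SimParams",
    "SyntheticTruth",
    "SimResult",
    "expected_site_het",
    "simulate_tables",
    "simulate_dataset",
    "plant_stratum",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N = ord("N")

# standard nuclear codon table, built lazily from biopython
_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data import CodonTable

        std = CodonTable.unambiguous_dna_by_id[1]
        _CODON_TABLE.update(std.forward_table)
        for stop in std.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic study.

    Defaults follow the magnitudes of the real system: 8 haploid males per
    group, SB–Sb fixed differences at 1.4 per kb inside the supergene
    region, background diversity 8.2e-4 per bp shared by both groups,
    in-region diversity 6.7e-4 (SB) and 1.3e-6 (Sb) per bp.
    """

    seed: int = 0
    n_per_group: int = 8
    scaffold_lengths: tuple[int, ...] = (3_000_000, 2_000_000, 1_500_000)
    n_gap_fraction: float = 0.01
    region_span: tuple[str, int, int] | None = ("scf_1", 1_000_000, 2_000_000)
    fixed_diff_density: float = 1.4e-3
    pi_background: float = 8.2e-4
    pi_SB_region: float = 6.7e-4
    pi_Sb_region: float = 1.3e-6
    paired_siblings: bool = False
    # full-sib pairing makes roughly half the shared pool's doubletons
    # pair-private; ~3e-4/bp at the default background diversity
    pair_private_density: float = 3e-4
    indel_fraction: float = 0.08
    gene_count: int = 320  # ~49 genes/Mb, the annotation's genome-wide density
    gene_length: int = 900
    frac_nonsyn_fixed: float = 0.47
    genes_with_planted_indel: int = 2
    str_locus_count: int = 200
    str_period_range: tuple[int, int] = (1, 6)
    str_region_fixed_fraction: float = 0.10
    str_background_poly_fraction: float = 0.27
    site_conf_fail: float = 0.005
    gt_conf_fail: float = 0.0005
    zero_cov_fail: float = 0.0002
    str_q_fail: float = 0.01
    str_high_cov_fail: float = 0.01
    n_linkage_groups: int = 4
    markers_per_scaffold: int = 6

    def validate(self):
        for name in ("fixed_diff_density", "pi_background", "pi_SB_region",
                     "pi_Sb_region", "pair_private_density", "n_gap_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.gene_length % 3 != 0:
            raise ValueError("gene_length must be a multiple of 3")
        if self.region_span is not None:
            scaf, start, end = self.region_span
            names = self.scaffold_names()
            if scaf not in names:
                raise ValueError(f"region scaffold {scaf!r} not among scaffolds")
            length = self.scaffold_lengths[names.index(scaf)]
            if not (0 <= start < end <= length):
                raise ValueError("region_span must lie within its scaffold")
        dens = (self.fixed_diff_density
                + max(self.pi_SB_region, self.pi_background) / expected_site_het(self.n_per_group)
                + self.pi_Sb_region / expected_site_het(self.n_per_group)
                + self.pair_private_density)
        if dens >= 1.0:
            raise ValueError("requested densities imply more than one variant per bp")

    def scaffold_names(self) -> list[str]:
        return [f"scf_{i + 1}" for i in range(len(self.scaffold_lengths))]


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset.

    ``site_class`` maps each emitted variant (scaffold, pos — 1-based) to
    exactly one of: ``fixed_diff``, ``SB_poly``, ``Sb_poly``,
    ``shared_poly``, ``pair_private``. ``gene_substitutions`` holds the
    planted (synonymous, nonsynonymous) fixed-difference counts per gene;
    ``str_genotypes`` the planted per-group repeat-unit counts.
    """

    region_span: tuple[str, int, int] | None
    site_class: dict[tuple[str, int], str] = field(default_factory=dict)
    gene_substitutions: dict[str, tuple[int, int]] = field(default_factory=dict)
    str_genotypes: dict[str, tuple[int, int]] = field(default_factory=dict)
    accessible: dict[str, int] = field(default_factory=dict)
    region_accessible: int = 0

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.site_class.values():
            out[c] = out.get(c, 0) + 1
        return out

    def to_json(self) -> str:
        return json.dumps({
            "region_span": self.region_span,
            "site_class": [[s, int(p), c] for (s, p), c in sorted(self.site_class.items())],
            "gene_substitutions": {g: list(v) for g, v in self.gene_substitutions.items()},
            "str_genotypes": {k: list(v) for k, v in self.str_genotypes.items()},
            "accessible": self.accessible,
            "region_accessible": self.region_accessible,
        }, indent=0)

    @staticmethod
    def from_json(text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return SyntheticTruth(
            region_span=tuple(d["region_span"]) if d["region_span"] else None,
            site_class={(s, int(p)): c for s, p, c in d["site_class"]},
            gene_substitutions={g: tuple(v) for g, v in d["gene_substitutions"].items()},
            str_genotypes={k: tuple(v) for k, v in d["str_genotypes"].items()},
            accessible=d["accessible"],
            region_accessible=d["region_accessible"],
        )


@dataclass
class SimResult:
    sequences: dict[str, str]
    variants: VariantTable
    genes: list[GeneModel]
    markers: pd.DataFrame
    strs: STRTable
    samples: SampleSet
    truth: SyntheticTruth


def expected_site_het(n: int) -> float:
    """Expected unbiased per-site heterozygosity under the 1/i minor-count
    weighting among n haploid samples: E[(n/(n-1)) * 2 p (1-p)]."""
    i = np.arange(1, n // 2 + 1, dtype=float)
    w = 1.0 / i
    h = n / (n - 1) * 2 * (i / n) * (1 - i / n)
    return float((w * h).sum() / w.sum())


def _draw_minor_counts(rng, n: int, size: int) -> np.ndarray:
    i = np.arange(1, n // 2 + 1)
    w = 1.0 / i
    return rng.choice(i, size=size, p=w / w.sum())


def _place_gaps(rng, seq: np.ndarray, fraction: float):
    """Blank contiguous blocks (2–10 kb) to N until `fraction` is reached."""
    target = int(len(seq) * fraction)
    placed = 0
    attempts = 0
    while placed < target and attempts < 1000:
        attempts += 1
        block = int(rng.integers(2_000, 10_000))
        start = int(rng.integers(0, max(1, len(seq) - block)))
        span = seq[start:start + block]
        fresh = int((span != _N).sum())
        span[:] = _N
        placed += fresh


def _sample_names(p: SimParams) -> tuple[list[str], SampleSet]:
    sb = [f"SB{i + 1}" for i in range(p.n_per_group)]
    sbm = [f"Sb{i + 1}" for i in range(p.n_per_group)]
    samples = sb + sbm
    groups = {s: "SB" for s in sb} | {s: "Sb" for s in sbm}
    # one high-coverage individual per group, mirroring the study design
    cov = {s: "low" for s in samples}
    cov[sb[0]] = cov[sbm[0]] = "high"
    pairs = {s: i + 1 for i, s in enumerate(sb)} | {s: i + 1 for i, s in enumerate(sbm)}
    return samples, SampleSet(samples, groups, cov, pairs)


def _place_genes(rng, p: SimParams, seqs: dict[str, np.ndarray]) -> list[GeneModel]:
    """Distribute genes across scaffolds proportional to length, in non-N
    stretches, and rewrite their CDS with random stop-free codons."""
    table = _codon_table()
    codons = [c for c, aa in table.items() if aa != "*"]
    codon_arr = np.array([[ord(ch) for ch in c] for c in codons], dtype=np.uint8)
    lengths = np.array([len(s) for s in seqs.values()], dtype=float)
    names = list(seqs)
    per_scaf = np.maximum(1, np.round(p.gene_count * lengths / lengths.sum()).astype(int))
    genes = []
    gi = 0
    for name, count in zip(names, per_scaf):
        seq = seqs[name]
        spacing = len(seq) // (count + 1)
        for k in range(count):
            if gi >= p.gene_count:
                break
            start = spacing * (k + 1) + int(rng.integers(0, max(1, spacing // 4)))
            # slide right until the CDS fits in a non-N stretch
            while start + p.gene_length < len(seq) and \
                    (seq[start:start + p.gene_length] == _N).any():
                start += 1000
            if start + p.gene_length >= len(seq):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            n_codons = p.gene_length // 3
            pick = rng.integers(0, len(codons), size=n_codons)
            coding = codon_arr[pick].reshape(-1)
            if strand == "-":
                coding = _revcomp_u8(coding)
            seq[start:start + p.gene_length] = coding
            gi += 1
            genes.append(GeneModel(
                gene_id=f"gene_{gi:04d}",
                scaffold=name,
                strand=strand,
                cds=[(start + 1, start + p.gene_length)],  # 1-based inclusive
                attributes={"transl_table": "1"},
            ))
    return genes


_RC = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _RC[_a] = _b


def _revcomp_u8(arr: np.ndarray) -> np.ndarray:
    return _RC[arr][::-1]


def _codon_context(gene: GeneModel, pos0: int, seq: np.ndarray):
    """Return (codon string in coding orientation, offset within codon,
    function mapping a ref-orientation base to coding orientation)."""
    s, e = gene.cds[0][0] - 1, gene.cds[0][1] - 1  # 0-based inclusive
    if gene.strand == "+":
        cpos = pos0 - s
        to_coding = lambda b: b  # noqa: E731
    else:
        cpos = e - pos0
        to_coding = lambda b: _COMPLEMENT[b]  # noqa: E731
    ci, within = divmod(cpos, 3)
    if gene.strand == "+":
        codon = bytes(seq[s + 3 * ci:s + 3 * ci + 3]).decode()
    else:
        codon = bytes(_revcomp_u8(seq[e - 3 * ci - 2:e - 3 * ci + 1])).decode()
    return codon, within, to_coding


def _choose_fixed_alt(rng, gene: GeneModel | None, pos0: int, seq: np.ndarray,
                      frac_nonsyn: float):
    """Pick the alternate base for a fixed difference; codon-aware inside a
    CDS. Returns (alt_base, effect) where effect is 'synonymous',
    'nonsynonymous' or 'noncoding'."""
    ref = chr(seq[pos0])
    others = [b for b in "ACGT" if b != ref]
    if gene is None:
        return others[int(rng.integers(0, 3))], "noncoding"
    table = _codon_table()
    codon, within, to_coding = _codon_context(gene, pos0, seq)
    aa0 = table[codon]
    syn, nonsyn = [], []
    for b in others:
        mut = list(codon)
        mut[within] = to_coding(b)
        aa1 = table["".join(mut)]
        (syn if aa1 == aa0 else nonsyn).append(b)
    want_nonsyn = rng.random() < frac_nonsyn
    pool = nonsyn if (want_nonsyn and nonsyn) or not syn else syn
    effect = "nonsynonymous" if pool is nonsyn else "synonymous"
    return pool[int(rng.integers(0, len(pool)))], effect


def simulate_tables(params: SimParams) -> SimResult:
    """Generate the full synthetic dataset in memory."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    names = params.scaffold_names()
    n = params.n_per_group

    # --- reference sequences with contiguous N gaps
    seqs: dict[str, np.ndarray] = {}
    for name, length in zip(names, params.scaffold_lengths):
        seq = _BASES[rng.integers(0, 4, size=length)]
        _place_gaps(rng, seq, params.n_gap_fraction)
        seqs[name] = seq

    # --- genes (rewrites CDS stretches in place, so before variants)
    genes = _place_genes(rng, params, seqs)
    gene_lookup: dict[str, list[GeneModel]] = {}
    for g in genes:
        gene_lookup.setdefault(g.scaffold, []).append(g)

    def gene_at(scaf: str, pos0: int) -> GeneModel | None:
        for g in gene_lookup.get(scaf, ()):
            s, e = g.cds[0]
            if s - 1 <= pos0 <= e - 1:
                return g
        return None

    samples, ss = _sample_names(params)
    truth = SyntheticTruth(region_span=params.region_span)

    # --- variant site placement: disjoint position pools per class
    h_group = expected_site_het(n)
    h_all = expected_site_het(2 * n)
    region = params.region_span
    site_rows = []  # (scaffold, pos0, class)
    for name in names:
        seq = seqs[name]
        non_n = np.flatnonzero(seq != _N)
        truth.accessible[name] = int(non_n.size)
        if region is not None and name == region[0]:
            in_region = (non_n >= region[1]) & (non_n < region[2])
            region_pos = non_n[in_region]
            bg_pos = non_n[~in_region]
            truth.region_accessible = int(region_pos.size)
        else:
            region_pos = np.array([], dtype=int)
            bg_pos = non_n
        # region classes
        pools = []
        if region_pos.size:
            pools.append((region_pos, [
                ("fixed_diff", params.fixed_diff_density),
                ("SB_poly", params.pi_SB_region / h_group),
                ("Sb_poly", params.pi_Sb_region / h_group),
            ]))
        bg_classes = [("shared_poly", params.pi_background / h_all)]
        if params.paired_siblings:
            bg_classes.append(("pair_private", params.pair_private_density))
        pools.append((bg_pos, bg_classes))
        for positions, classes in pools:
            if positions.size == 0:
                continue
            avail = rng.permutation(positions)
            offset = 0
            for cls, density in classes:
                k = int(rng.binomial(positions.size, density)) if density > 0 else 0
                k = min(k, avail.size - offset)
                for pos0 in avail[offset:offset + k]:
                    site_rows.append((name, int(pos0), cls))
                offset += k

    site_rows.sort(key=lambda r: (names.index(r[0]), r[1]))

    # --- alleles and genotypes
    n_sites = len(site_rows)
    scaffold_col = np.empty(n_sites, dtype=object)
    pos_col = np.empty(n_sites, dtype=np.int64)
    ref_col = np.empty(n_sites, dtype=object)
    alts_col = np.empty(n_sites, dtype=object)
    vclass_col = np.empty(n_sites, dtype=object)
    geno = np.zeros((n_sites, 2 * n), dtype=np.int16)
    gene_sub: dict[str, list[int]] = {g.gene_id: [0, 0] for g in genes}

    # genes that receive one deliberate in-CDS indel (exercises gene filter)
    indel_genes = set()
    if params.genes_with_planted_indel > 0 and genes:
        pick = rng.choice(len(genes), size=min(params.genes_with_planted_indel, len(genes)),
                          replace=False)
        indel_genes = {genes[i].gene_id for i in pick}

    for i, (scaf, pos0, cls) in enumerate(site_rows):
        seq = seqs[scaf]
        ref = chr(seq[pos0])
        g = gene_at(scaf, pos0)
        is_indel = False
        if cls == "fixed_diff":
            alt, effect = _choose_fixed_alt(rng, g, pos0, seq, params.frac_nonsyn_fixed)
            if effect == "synonymous":
                gene_sub[g.gene_id][0] += 1
            elif effect == "nonsynonymous":
                gene_sub[g.gene_id][1] += 1
            geno[i, :n] = 0
            geno[i, n:] = 1
        else:
            # polymorphic site: maybe an indel (kept out of CDS)
            if g is None and rng.random() < params.indel_fraction and pos0 + 1 < len(seq) \
                    and seq[pos0 + 1] != _N:
                is_indel = True
                if rng.random() < 0.5:
                    alt = ref + chr(_BASES[rng.integers(0, 4)])  # insertion
                else:
                    ref = ref + chr(seq[pos0 + 1])  # deletion
                    alt = ref[0]
            else:
                others = [b for b in "ACGT" if b != ref]
                alt = others[int(rng.integers(0, 3))]
            carriers = _poly_carriers(rng, cls, n, ss, samples)
            geno[i, carriers] = 1
        scaffold_col[i] = scaf
        pos_col[i] = pos0 + 1
        ref_col[i] = ref
        alts_col[i] = (alt,)
        vclass_col[i] = "indel" if is_indel else "SNP"
        truth.site_class[(scaf, pos0 + 1)] = cls

    # planted in-CDS indels (appended as extra sites)
    extra = []
    for gid in sorted(indel_genes):
        g = next(x for x in genes if x.gene_id == gid)
        s, e = g.cds[0]
        pos0 = int(rng.integers(s - 1, e - 1))
        if (str(g.scaffold), pos0 + 1) in truth.site_class:
            continue
        seq = seqs[g.scaffold]
        ref = chr(seq[pos0]) + chr(seq[pos0 + 1])
        row_geno = np.zeros(2 * n, dtype=np.int16)
        carriers = rng.choice(2 * n, size=max(1, n // 4), replace=False)
        row_geno[carriers] = 1
        extra.append((g.scaffold, pos0 + 1, ref, (ref[0],), "indel", row_geno))
        truth.site_class[(g.scaffold, pos0 + 1)] = "shared_poly"
    if extra:
        extra_alts = np.empty(len(extra), dtype=object)
        for k, r in enumerate(extra):
            extra_alts[k] = r[3]
        scaffold_col = np.concatenate([scaffold_col, np.array([r[0] for r in extra], dtype=object)])
        pos_col = np.concatenate([pos_col, np.array([r[1] for r in extra], dtype=np.int64)])
        ref_col = np.concatenate([ref_col, np.array([r[2] for r in extra], dtype=object)])
        alts_col = np.concatenate([alts_col, extra_alts])
        vclass_col = np.concatenate([vclass_col, np.array([r[4] for r in extra], dtype=object)])
        geno = np.vstack([geno, np.stack([r[5] for r in extra])])
        order = np.lexsort((pos_col, np.array([names.index(s) for s in scaffold_col])))
        scaffold_col, pos_col, ref_col = scaffold_col[order], pos_col[order], ref_col[order]
        alts_col, vclass_col, geno = alts_col[order], vclass_col[order], geno[order]

    n_sites = len(pos_col)
    truth.gene_substitutions = {gid: (v[0], v[1]) for gid, v in gene_sub.items()}

    # --- confidence annotations
    site_conf = np.where(
        rng.random(n_sites) < params.site_conf_fail,
        rng.uniform(1.0, 15.0, size=n_sites),
        rng.uniform(16.0, 200.0, size=n_sites),
    ).round(2)
    is_high = np.array([ss.coverage_class[s] == "high" for s in samples])
    thr = np.where(is_high, 2.0, 10.0)
    fail_gt = rng.random((n_sites, 2 * n)) < params.gt_conf_fail
    gt_conf = np.where(
        fail_gt,
        rng.uniform(0.0, 1.0, size=(n_sites, 2 * n)) * thr[None, :],
        thr[None, :] + rng.uniform(0.5, 50.0, size=(n_sites, 2 * n)),
    ).round(2)
    lam = np.where(is_high, 25.0, 7.0)
    cov = np.maximum(1, rng.poisson(lam[None, :], size=(n_sites, 2 * n))).astype(np.int32)
    cov[rng.random((n_sites, 2 * n)) < params.zero_cov_fail] = 0

    vt = VariantTable(
        scaffold=scaffold_col, pos=pos_col, ref=ref_col, alts=alts_col,
        vclass=vclass_col, site_conf=site_conf, genotypes=geno,
        gt_conf=gt_conf, cov=cov, samples=samples,
    )

    markers = _make_markers(params, names)
    strs = _make_strs(rng, params, seqs, names, samples, ss, truth)
    sequences = {name: bytes(seq).decode() for name, seq in seqs.items()}
    return SimResult(sequences, vt, genes, markers, strs, ss, truth)


def _poly_carriers(rng, cls: str, n: int, ss: SampleSet, samples) -> np.ndarray:
    """Indices (into the sample list: SB block then Sb block) of alt-allele
    carriers for a polymorphic site of the given truth class."""
    if cls == "SB_poly":
        i = int(_draw_minor_counts(rng, n, 1)[0])
        return rng.choice(n, size=i, replace=False)
    if cls == "Sb_poly":
        i = int(_draw_minor_counts(rng, n, 1)[0])
        return n + rng.choice(n, size=i, replace=False)
    if cls == "shared_poly":
        i = int(_draw_minor_counts(rng, 2 * n, 1)[0])
        return rng.choice(2 * n, size=i, replace=False)
    if cls == "pair_private":
        pair = int(rng.integers(0, n))
        return np.array([pair, n + pair])
    raise ValueError(cls)


def _make_markers(params: SimParams, names: list[str]) -> pd.DataFrame:
    """Linkage-marker table: each scaffold on one linkage group, markers in
    at least two family maps so the low-confidence filter keeps them; the
    supergene scaffold's in-region markers cosegregate with Gp-9."""
    region = params.region_span
    families = ([("fam_sq1", "single-queen"), ("fam_sq2", "single-queen"),
                 ("fam_sq3", "single-queen")]
                + [(f"fam_mq{i}", "multiple-queen") for i in range(1, 5)])
    rows = []
    mid = 0
    lg_offset: dict[str, float] = {}
    for si, name in enumerate(names):
        length = params.scaffold_lengths[si]
        if region is not None and name == region[0]:
            lg = "LG16"
        else:
            lg = f"LG{(si % params.n_linkage_groups) + 1}"
        base_cm = lg_offset.get(lg, 0.0)
        step = length // (params.markers_per_scaffold + 1)
        for k in range(params.markers_per_scaffold):
            pos = step * (k + 1)
            cm = base_cm + k * 1.7
            coseg = bool(region is not None and name == region[0]
                         and region[1] <= pos < region[2])
            # two family maps per marker (one single-queen, one multiple-queen)
            for fam, ftype in (families[si % 3], families[3 + si % 4]):
                mid += 1
                rows.append({
                    "marker_id": f"m{mid:05d}",
                    "scaffold": name,
                    "pos": int(pos),
                    "linkage_group": lg,
                    "cM": round(cm, 2),
                    "family_id": fam,
                    "family_type": ftype,
                    "cosegregates_gp9": coseg,
                })
        lg_offset[lg] = base_cm + params.markers_per_scaffold * 1.7 + 5.0
    return pd.DataFrame(rows)


def _make_strs(rng, params: SimParams, seqs, names, samples, ss,
               truth: SyntheticTruth) -> STRTable:
    n = params.n_per_group
    lengths = np.array([len(seqs[s]) for s in names], dtype=float)
    per_scaf = np.maximum(1, np.round(params.str_locus_count * lengths / lengths.sum()).astype(int))
    region = params.region_span
    rows, units_rows = [], []
    truth_geno = {}
    li = 0
    for name, count in zip(names, per_scaf):
        seq = seqs[name]
        non_n = np.flatnonzero(seq != _N)
        pos_pick = np.sort(rng.choice(non_n, size=min(count, non_n.size), replace=False))
        for pos0 in pos_pick:
            li += 1
            period = int(rng.integers(params.str_period_range[0],
                                      params.str_period_range[1] + 1))
            lo = {1: 10, 2: 6}.get(period, 5)
            ref_units = int(rng.integers(lo, lo + 10))
            in_region = bool(region is not None and name == region[0]
                             and region[1] <= pos0 < region[2])
            u = np.full(2 * n, ref_units, dtype=np.int32)
            if in_region:
                if rng.random() < params.str_region_fixed_fraction:
                    delta = int(rng.choice([-3, -2, -1, 1, 2, 3]))
                    u[n:] = max(1, ref_units + delta)
            else:
                if rng.random() < params.str_background_poly_fraction:
                    carriers = _poly_carriers(rng, "shared_poly", n, ss, samples)
                    u[carriers] = max(1, ref_units + int(rng.choice([-1, 1])))
            locus_id = f"str_{li:05d}"
            rows.append({
                "locus_id": locus_id, "scaffold": name, "pos": int(pos0) + 1,
                "period": period, "ref_units": ref_units,
                "score": int(rng.integers(20, 200)),
            })
            units_rows.append(u)
            truth_geno[locus_id] = (int(u[:n][0]), int(u[n:][0]))
    truth.str_genotypes = truth_geno
    m = len(rows)
    q = np.where(rng.random((m, 2 * n)) < params.str_q_fail,
                 rng.uniform(0.0, 0.25, size=(m, 2 * n)),
                 rng.uniform(0.25, 1.0, size=(m, 2 * n))).round(3)
    support = np.maximum(2, rng.poisson(8.0, size=(m, 2 * n))).astype(np.int32)
    coverage = np.minimum(25, np.maximum(support, rng.poisson(12.0, size=(m, 2 * n)))).astype(np.int32)
    high = rng.random((m, 2 * n)) < params.str_high_cov_fail
    coverage[high] = 26 + (rng.integers(0, 15, size=(m, 2 * n)))[high]
    return STRTable(pd.DataFrame(rows), np.stack(units_rows) if m else
                    np.zeros((0, 2 * n), dtype=np.int32), q, support, coverage, samples)


def simulate_dataset(params: SimParams, outdir: str) -> dict[str, str]:
    """Generate the dataset and write the standard files into ``outdir``.

    Writes reference.fasta, variants.vcf, genes.gff3, markers.tsv, strs.tsv,
    samples.tsv and truth.json; returns a name -> path mapping.
    """
    res = simulate_tables(params)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "reference.fasta"),
        "vcf": os.path.join(outdir, "variants.vcf"),
        "gff": os.path.join(outdir, "genes.gff3"),
        "markers": os.path.join(outdir, "markers.tsv"),
        "strs": os.path.join(outdir, "strs.tsv"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
        "params": os.path.join(outdir, "params.json"),
    }
    write_fasta(res.sequences, paths["fasta"])
    contig_lengths = {k: len(v) for k, v in res.sequences.items()}
    write_vcf(res.variants, paths["vcf"], contig_lengths)
    write_gff3(res.genes, paths["gff"])
    write_marker_table(res.markers, paths["markers"])
    write_str_table(res.strs, paths["strs"])
    write_sample_manifest(res.samples, paths["samples"])
    with open(paths["truth"], "w") as fh:
        fh.write(res.truth.to_json())
    with open(paths["params"], "w") as fh:
        json.dump(dataclasses.asdict(params), fh, indent=1, default=list)
    return paths


def plant_stratum(gene_lengths, span: tuple[int, int], rate_global: float,
                  rate_low: float, seed: int):
    """Poisson substitution counts per gene with a planted low-rate span.

    Genes with index in ``span`` = [start, stop) receive counts at
    ``rate_low`` per coding bp, all others at ``rate_global``. Returns
    (counts, truth_dict); the truth marks "no stratum" when the two rates
    are equal.
    """
    lengths = np.asarray(gene_lengths, dtype=float)
    if rate_low < 0 or rate_global < 0:
        raise ValueError("substitution rates must be non-negative")
    start, stop = span
    if not (0 <= start <= stop <= lengths.size):
        raise ValueError("span outside gene list")
    rng = np.random.default_rng(seed)
    rates = np.full(lengths.size, rate_global)
    rates[start:stop] = rate_low
    counts = rng.poisson(rates * lengths)
    truth = {
        "span": (int(start), int(stop)),
        "rate_global": rate_global,
        "rate_low": rate_low,
        "stratum": rate_low != rate_global and stop > start,
    }
    return counts, truth
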