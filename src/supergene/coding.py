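"""Protein-coding divergence between the SB and Sb haplotype groups.

Genes passing the annotation filters get one consensus coding sequence per
group, built from the reference CDS by substituting each group's allele at
SNP sites fixed for alternative alleles between the groups (the reference
individual is an SB male, so the SB consensus is usually the reference
itself). Synonymous and nonsynonymous divergence per site (dS, dN) between
the two consensus sequences is then estimated by Nei–Gojobori (1986)
counting with the Jukes–Cantor correction:

* per codon, each position contributes the fraction of its three possible
  changes that are synonymous to the synonymous site count S (changes to a
  stop codon count as nonsynonymous); site counts are averaged over the two
  sequences, so N + S equals the CDS length;
* observed differences in codons differing at >1 position are resolved by
  equal weighting of all minimal mutation paths, excluding paths through
  stop codons;
* dN = -3/4 ln(1 - 4 pN / 3), likewise dS; dN/dS is undefined (NaN) when
  dS = 0, and the correction is undefined when p >= 3/4 (flagged).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GeneModel, SampleSet, VariantTable
from .stats import wilcoxon_rank_sum, wilcoxon_signed_rank
from .windows import fixed_differences

__all__ = [
    "GeneModel",
    "ConsensusPair",
    "DivergenceRecord",
    "filter_genes",
    "classify_snp_effect",
    "build_consensus_pair",
    "ng86_divergence",
    "divergence_table",
    "count_coding_snps",
    "dnds_background_comparison",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_CODON_TABLE: dict[str, str] = {}


def codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data import CodonTable

        std = CodonTable.unambiguous_dna_by_id[1]
        _CODON_TABLE.update(std.forward_table)
        for stop in std.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


@dataclass
class ConsensusPair:
    """Equal-length in-frame CDS consensus sequences for the two groups."""

    gene_id: str
    seq_SB: str
    seq_Sb: str
    applied: list[tuple[int, str, str]] = field(default_factory=list)
    # applied: (0-based CDS position, SB base, Sb base)

    def __post_init__(self):
        if len(self.seq_SB) != len(self.seq_Sb):
            raise ValueError(f"{self.gene_id}: consensus lengths differ")
        if len(self.seq_SB) % 3 != 0:
            raise ValueError(f"{self.gene_id}: consensus length not a multiple of 3")


@dataclass
class DivergenceRecord:
    gene_id: str
    n_sites: float  # nonsynonymous sites (N)
    s_sites: float  # synonymous sites (S)
    nd: float       # nonsynonymous differences
    sd: float       # synonymous differences
    dn: float
    ds: float
    flags: list[str] = field(default_factory=list)

    @property
    def dnds(self) -> float:
        if self.ds == 0 or math.isnan(self.ds) or math.isnan(self.dn):
            return float("nan")
        return self.dn / self.ds


# ---------------------------------------------------------------------------
# gene filtering and SNP classification

def cds_sequence(gene: GeneModel, sequences: dict[str, str]) -> str:
    """Concatenated CDS in coding orientation (reverse-complemented for -)."""
    scaf = sequences[gene.scaffold]
    parts = [scaf[s - 1:e] for s, e in gene.cds]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq.upper()


def _truthy_tag(value: str | None) -> bool:
    return str(value).lower() in {"true", "1", "yes"}


def filter_genes(genes: list[GeneModel], vt: VariantTable,
                 sequences: dict[str, str]) -> list[GeneModel]:
    """Apply the annotation quality filters.

    A gene survives iff it is not tagged partial or modified-RefSeq, its CDS
    contains no N and has length divisible by 3, it does not use the
    mitochondrial code (transl_table=5), and no retained indel variant
    overlaps its CDS in any sample.
    """
    # collect retained indel footprints per scaffold
    indel_spans: dict[str, list[tuple[int, int]]] = {}
    is_indel = vt.vclass == "indel"
    for i in np.flatnonzero(is_indel):
        start = int(vt.pos[i])                      # 1-based
        end = start + len(vt.ref[i]) - 1
        indel_spans.setdefault(str(vt.scaffold[i]), []).append((start, end))
    out = []
    for g in genes:
        if _truthy_tag(g.attributes.get("partial")):
            continue
        if _truthy_tag(g.attributes.get("modified_refseq")):
            continue
        if str(g.attributes.get("transl_table", "1")) == "5":
            continue
        scaf_len = len(sequences[g.scaffold])
        if any(e > scaf_len or s < 1 for s, e in g.cds):
            raise ValueError(f"gene {g.gene_id}: CDS outside scaffold bounds")
        seq = cds_sequence(g, sequences)
        if len(seq) % 3 != 0 or "N" in seq:
            continue
        overlaps = False
        for s0, e0 in indel_spans.get(g.scaffold, ()):
            for cs, ce in g.cds:
                if s0 <= ce and e0 >= cs:
                    overlaps = True
                    break
            if overlaps:
                break
        if overlaps:
            continue
        out.append(g)
    return out


def _cds_offset(gene: GeneModel, pos1: int) -> int | None:
    """0-based position within the coding sequence of genomic position
    ``pos1`` (1-based), or None when outside the CDS."""
    acc = 0
    total = gene.cds_length
    for s, e in gene.cds:
        if s <= pos1 <= e:
            fwd = acc + (pos1 - s)
            return fwd if gene.strand == "+" else total - 1 - fwd
        acc += e - s + 1
    return None


def classify_snp_effect(gene: GeneModel, pos1: int, ref: str, alt: str,
                        sequences: dict[str, str]) -> str:
    """Classify a SNP as synonymous / nonsynonymous / noncoding for a gene.

    Strand-aware: on minus-strand genes the alleles are complemented into
    coding orientation before codon lookup (standard nuclear code).
    """
    for allele in (ref, alt):
        if allele not in "ACGT" or len(allele) != 1:
            raise ValueError(f"allele {allele!r} is not a single A/C/G/T base")
    off = _cds_offset(gene, pos1)
    if off is None:
        return "noncoding"
    cds = cds_sequence(gene, sequences)
    ci, within = divmod(off, 3)
    codon = cds[3 * ci:3 * ci + 3]
    if gene.strand == "-":
        ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
    if codon[within] != ref:
        raise ValueError(
            f"gene {gene.gene_id} position {pos1}: reference allele {ref!r} "
            f"does not match CDS base {codon[within]!r}")
    table = codon_table()
    mutated = codon[:within] + alt + codon[within + 1:]
    return "synonymous" if table[mutated] == table[codon] else "nonsynonymous"


# ---------------------------------------------------------------------------
# consensus building

def build_consensus_pair(gene: GeneModel, vt: VariantTable, ss: SampleSet,
                         sequences: dict[str, str]) -> ConsensusPair:
    """Consensus CDS per group from SNP fixed differences within the gene.

    The SB consensus substitutes the SB-fixed allele at each fixed-difference
    site (an identity operation when the reference genome is the SB
    consensus), the Sb consensus the Sb-fixed allele. Indel fixed
    differences are excluded by the gene filter's contract.
    """
    cds = list(cds_sequence(gene, sequences))
    seq_a, seq_b = cds[:], cds[:]
    mask = vt.scaffold == gene.scaffold
    sub = vt.take_sites(mask & vt.is_snp())
    _, _, idx = fixed_differences(sub, ss)
    ia = sub.sample_indices(ss.group_members("SB"))
    ib = sub.sample_indices(ss.group_members("Sb"))
    applied = []
    for i in idx:
        pos1 = int(sub.pos[i])
        off = _cds_offset(gene, pos1)
        if off is None:
            continue
        alleles = sub.alleles(i)
        base_a = alleles[int(sub.genotypes[i, ia[0]])]
        base_b = alleles[int(sub.genotypes[i, ib[0]])]
        if gene.strand == "-":
            base_a = base_a.translate(_COMPLEMENT)
            base_b = base_b.translate(_COMPLEMENT)
        seq_a[off] = base_a
        seq_b[off] = base_b
        applied.append((off, base_a, base_b))
    return ConsensusPair(gene.gene_id, "".join(seq_a), "".join(seq_b),
                         sorted(applied))


# ---------------------------------------------------------------------------
# NG86

def _codon_sites(codon: str, table: dict[str, str]) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; their sum is 3.
    Changes to stop codons count as nonsynonymous."""
    aa = table[codon]
    syn = 0.0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            mutated = codon[:i] + b + codon[i + 1:]
            if table[mutated] == aa and table[mutated] != "*":
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _codon_differences(c1: str, c2: str, table: dict[str, str]) -> tuple[float, float]:
    """(synonymous, nonsynonymous) observed differences between two codons,
    averaging equally over all minimal mutation paths that avoid stop
    codons (all paths used if every one passes through a stop)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if table[nxt] == "*" and nxt != c2:
                through_stop = True
            if table[nxt] == table[cur] and table[nxt] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, through_stop))
    usable = [p for p in paths if not p[2]] or paths
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_divergence(pair: ConsensusPair) -> DivergenceRecord:
    """Nei–Gojobori divergence between the two consensus sequences."""
    table = codon_table()
    s1, s2 = pair.seq_SB, pair.seq_Sb
    S = N = SD = ND = 0.0
    for k in range(0, len(s1), 3):
        c1, c2 = s1[k:k + 3], s2[k:k + 3]
        sa, na = _codon_sites(c1, table)
        sb, nb = _codon_sites(c2, table)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _codon_differences(c1, c2, table)
        SD += sd
        ND += nd
    flags = []
    ps = SD / S if S > 0 else 0.0
    pn = ND / N if N > 0 else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    if math.isnan(ds) or math.isnan(dn):
        flags.append("jc_correction_undefined")
    return DivergenceRecord(pair.gene_id, N, S, ND, SD, dn, ds, flags)


def divergence_table(genes: list[GeneModel], vt: VariantTable, ss: SampleSet,
                     sequences: dict[str, str]) -> list[DivergenceRecord]:
    """Consensus + NG86 divergence for every gene."""
    out = []
    for g in genes:
        pair = build_consensus_pair(g, vt, ss, sequences)
        out.append(ng86_divergence(pair))
    return out


def count_coding_snps(genes: list[GeneModel], vt: VariantTable, ss: SampleSet,
                      sequences: dict[str, str]) -> dict[str, int]:
    """Counts for the McDonald–Kreitman contrast over a gene set.

    Returns fixed_n / fixed_s (SNPs fixed for alternative alleles between the
    groups, by effect) and poly_n / poly_s (SNPs polymorphic among the SB
    samples within the same genes).
    """
    counts = {"fixed_n": 0, "fixed_s": 0, "poly_n": 0, "poly_s": 0}
    ia = vt.sample_indices(ss.group_members("SB"))
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    snp = vt.take_sites(vt.is_snp())
    _, _, fixed_idx = fixed_differences(snp, ss)
    fixed_set = set(fixed_idx.tolist())
    geno_a = snp.genotypes[:, ia]
    poly_a = ((geno_a != MISSING).sum(axis=1) >= 2) & \
        ~np.all(geno_a == geno_a[:, :1], axis=1)
    for i in range(snp.n_sites):
        is_fixed = i in fixed_set
        if not is_fixed and not poly_a[i]:
            continue
        scaf = str(snp.scaffold[i])
        pos1 = int(snp.pos[i])
        for g in by_scaffold.get(scaf, ()):
            off = _cds_offset(g, pos1)
            if off is None:
                continue
            effect = classify_snp_effect(g, pos1, str(snp.ref[i]),
                                         str(snp.alts[i][0]), sequences)
            key = "n" if effect == "nonsynonymous" else "s"
            if is_fixed:
                counts[f"fixed_{key}"] += 1
            else:
                counts[f"poly_{key}"] += 1
            break
    return counts


def dnds_background_comparison(records: list[DivergenceRecord], background,
                               side: str = "two-sided") -> dict:
    """Compare gene dN/dS values against a background dN/dS distribution.

    The primary test is a Wilcoxon signed-rank of the genes' dN/dS against
    the background median (the paired test the study names, with the
    background reduced to its median since no gene pairing exists); a
    Wilcoxon rank-sum of the two samples is reported alongside. Genes with
    undefined dN/dS (dS = 0) are excluded.
    """
    values = np.array([r.dnds for r in records], dtype=float)
    values = values[~np.isnan(values)]
    background = np.asarray(background, dtype=float)
    background = background[~np.isnan(background)]
    if values.size == 0 or background.size == 0:
        raise ValueError("need non-empty dN/dS sets on both sides")
    med = float(np.median(background))
    v, p_signed = wilcoxon_signed_rank(values, med, side=side)
    w, p_ranksum = wilcoxon_rank_sum(values, background, side=side)
    return {
        "n_genes": int(values.size),
        "background_median": med,
        "signed_rank_V": v,
        "signed_rank_p": p_signed,
        "rank_sum_W": w,
        "rank_sum_p": p_ranksum,
    }
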