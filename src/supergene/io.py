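"""Containers and file I/O for variant, sample, STR and marker data.

The central container is :class:`VariantTable`, a column-oriented table of
biallelic/multiallelic sites with one haploid call per sample per site plus
the caller confidence annotations the filtering rules operate on
(site confidence ``SITE_CONF``, per-sample genotype confidence ``GT_CONF``
and called-allele coverage ``COV``). VCF v4.2 is the on-disk format,
read and written through pysam; FASTA through pyfaidx; the marker and STR
tables are plain TSV read through pandas.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

__all__ = [
    "VariantTable",
    "SampleSet",
    "STRTable",
    "GeneModel",
    "read_vcf",
    "write_vcf",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_marker_table",
    "write_marker_table",
    "read_str_table",
    "write_str_table",
    "read_sample_manifest",
    "write_sample_manifest",
]

MISSING = -1  # sentinel for a missing haploid call


@dataclass
class VariantTable:
    """Per-site variant calls for a set of haploid samples.

    Attributes
    ----------
    scaffold, pos, ref, alts, vclass, site_conf : arrays of length n_sites
        Site-level columns. ``pos`` is 1-based (VCF convention); ``alts`` is
        an object array of tuples of alternate alleles; ``vclass`` is
        ``"SNP"`` or ``"indel"``.
    genotypes : (n_sites, n_samples) int16
        Haploid allele index per sample (0 = ref), ``MISSING`` if uncalled.
    gt_conf : (n_sites, n_samples) float
    cov : (n_sites, n_samples) int32
        Read coverage of the called allele.
    samples : list of sample ids (column order of the matrices).
    """

    scaffold: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alts: np.ndarray
    vclass: np.ndarray
    site_conf: np.ndarray
    genotypes: np.ndarray
    gt_conf: np.ndarray
    cov: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self):
        n = self.n_sites
        for name in ("scaffold", "ref", "alts", "vclass", "site_conf"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has wrong length")
        for name in ("genotypes", "gt_conf", "cov"):
            m = getattr(self, name)
            if m.shape != (n, len(self.samples)):
                raise ValueError(f"matrix {name!r} has wrong shape {m.shape}")
        # positions strictly increasing within each scaffold
        for scaf in pd.unique(self.scaffold):
            p = self.pos[self.scaffold == scaf]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {scaf}")

    def alleles(self, i: int) -> tuple[str, ...]:
        return (self.ref[i],) + tuple(self.alts[i])

    def take_sites(self, index) -> "VariantTable":
        """Subset by site index/boolean mask (order preserved)."""
        return VariantTable(
            scaffold=self.scaffold[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alts=self.alts[index],
            vclass=self.vclass[index],
            site_conf=self.site_conf[index],
            genotypes=self.genotypes[index],
            gt_conf=self.gt_conf[index],
            cov=self.cov[index],
            samples=list(self.samples),
        )

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in names], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in VariantTable") from None

    def is_snp(self) -> np.ndarray:
        return self.vclass == "SNP"

    @staticmethod
    def empty(samples) -> "VariantTable":
        samples = list(samples)
        z = np.zeros(0)
        return VariantTable(
            scaffold=np.array([], dtype=object),
            pos=np.array([], dtype=np.int64),
            ref=np.array([], dtype=object),
            alts=np.array([], dtype=object),
            vclass=np.array([], dtype=object),
            site_conf=z,
            genotypes=np.zeros((0, len(samples)), dtype=np.int16),
            gt_conf=np.zeros((0, len(samples))),
            cov=np.zeros((0, len(samples)), dtype=np.int32),
            samples=samples,
        )


@dataclass
class SampleSet:
    """Sample ids with group label (SB or Sb), coverage class and sibling pair.

    ``groups`` maps sample id -> "SB" | "Sb"; ``coverage_class`` maps
    sample id -> "high" | "low"; ``sibling_pair`` (optional) maps sample id
    to a pair id shared by one SB and one Sb brother.
    """

    samples: list[str]
    groups: dict[str, str]
    coverage_class: dict[str, str]
    sibling_pair: dict[str, int] | None = None

    def __post_init__(self):
        labels = set(self.groups.values())
        if not labels <= {"SB", "Sb"}:
            raise ValueError(f"unknown group labels: {labels - {'SB', 'Sb'}}")
        if not self.group_members("SB") or not self.group_members("Sb"):
            raise ValueError("both groups must be non-empty")

    def group_members(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups.get(s) == group]

    def group_of(self, sample: str) -> str:
        return self.groups[sample]

    def relabelled(self, new_groups: dict[str, str]) -> "SampleSet":
        return SampleSet(list(self.samples), dict(new_groups), dict(self.coverage_class), self.sibling_pair)


@dataclass
class STRTable:
    """Short-tandem-repeat loci with per-sample repeat-unit genotypes.

    ``loci`` is a DataFrame with columns locus_id, scaffold, pos, period,
    ref_units, score. The per-sample matrices are aligned to ``loci`` rows
    and the ``samples`` column order: ``units`` (called repeat units,
    MISSING if uncalled), ``q`` (lobSTR-style quality in [0,1]),
    ``support`` (reads supporting the call), ``coverage`` (total reads).
    """

    loci: pd.DataFrame
    units: np.ndarray
    q: np.ndarray
    support: np.ndarray
    coverage: np.ndarray
    samples: list[str]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def take_loci(self, index) -> "STRTable":
        idx = np.asarray(index)
        return STRTable(
            loci=self.loci.iloc[idx].reset_index(drop=True) if idx.dtype != bool
            else self.loci.loc[idx].reset_index(drop=True),
            units=self.units[idx],
            q=self.q[idx],
            support=self.support[idx],
            coverage=self.coverage[idx],
            samples=list(self.samples),
        )

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in names], dtype=int)


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER_ITEMS = [
    ('INFO', {'ID': 'SITE_CONF', 'Number': '1', 'Type': 'Float',
              'Description': 'Site confidence (variant vs error/repeat)'}),
    ('INFO', {'ID': 'VCLASS', 'Number': '1', 'Type': 'String',
              'Description': 'Variant class (SNP or indel)'}),
    ('FORMAT', {'ID': 'GT', 'Number': '1', 'Type': 'String',
                'Description': 'Haploid genotype'}),
    ('FORMAT', {'ID': 'GT_CONF', 'Number': '1', 'Type': 'Float',
                'Description': 'Genotype confidence'}),
    ('FORMAT', {'ID': 'COV', 'Number': '1', 'Type': 'Integer',
                'Description': 'Read coverage of the called allele'}),
]


def _classify_variant(ref: str, alts) -> str:
    if len(ref) == 1 and all(len(a) == 1 for a in alts):
        return "SNP"
    return "indel"


def write_vcf(vt: VariantTable, path: str, contig_lengths: dict[str, int] | None = None):
    """Write a VariantTable as an uncompressed VCF v4.2 file."""
    header = pysam.VariantHeader()
    if contig_lengths is None:
        contig_lengths = {}
        for scaf in pd.unique(vt.scaffold):
            p = vt.pos[vt.scaffold == scaf]
            contig_lengths[str(scaf)] = int(p.max()) + 1000 if len(p) else 1000
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    for kind, items in _VCF_HEADER_ITEMS:
        header.add_meta(kind, items=list(items.items()))
    for s in vt.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for i in range(vt.n_sites):
            rec = out.new_record(
                contig=str(vt.scaffold[i]),
                start=int(vt.pos[i]) - 1,
                alleles=vt.alleles(i),
            )
            rec.info["SITE_CONF"] = float(vt.site_conf[i])
            rec.info["VCLASS"] = str(vt.vclass[i])
            for j, s in enumerate(vt.samples):
                g = int(vt.genotypes[i, j])
                rec.samples[s]["GT"] = (None,) if g == MISSING else (g,)
                rec.samples[s]["GT_CONF"] = float(vt.gt_conf[i, j])
                rec.samples[s]["COV"] = int(vt.cov[i, j])
            out.write(rec)


def read_vcf(path: str) -> VariantTable:
    """Read a VCF with haploid GT calls into a VariantTable.

    Diploid (or higher-ploidy) genotype entries are rejected: the analysis is
    defined on haploid males only.
    """
    scaffold, pos, ref, alts, vclass, site_conf = [], [], [], [], [], []
    gts, confs, covs = [], [], []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for ln, rec in enumerate(vf):
            scaffold.append(rec.contig)
            pos.append(rec.pos)
            ref.append(rec.ref)
            alt = tuple(rec.alts) if rec.alts else ()
            alts.append(alt)
            if "VCLASS" in rec.info:
                vclass.append(str(rec.info["VCLASS"]))
            else:
                vclass.append(_classify_variant(rec.ref, alt))
            if "SITE_CONF" not in rec.info:
                raise ValueError(
                    f"record {rec.contig}:{rec.pos}: missing INFO field SITE_CONF")
            site_conf.append(float(rec.info["SITE_CONF"]))
            row_gt, row_conf, row_cov = [], [], []
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or len(gt) != 1:
                    raise ValueError(
                        f"record {rec.contig}:{rec.pos} sample {s}: "
                        "haploid required")
                row_gt.append(MISSING if gt[0] is None else int(gt[0]))
                gc = call.get("GT_CONF")
                cv = call.get("COV")
                if gc is None or cv is None:
                    raise ValueError(
                        f"record {rec.contig}:{rec.pos} sample {s}: missing "
                        f"{'GT_CONF' if gc is None else 'COV'}")
                row_conf.append(float(gc))
                row_cov.append(int(cv))
            gts.append(row_gt)
            confs.append(row_conf)
            covs.append(row_cov)
    n = len(pos)
    return VariantTable(
        scaffold=np.array(scaffold, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alts=np.array(alts, dtype=object),
        vclass=np.array(vclass, dtype=object),
        site_conf=np.array(site_conf),
        genotypes=np.array(gts, dtype=np.int16).reshape(n, len(samples)),
        gt_conf=np.array(confs).reshape(n, len(samples)),
        cov=np.array(covs, dtype=np.int32).reshape(n, len(samples)),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: dict[str, str], path: str, width: int = 80):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    """Read all sequences from a FASTA file (uppercased)."""
    with Fasta(path, rebuild=True) as fa:
        out = {name: str(fa[name][:]).upper() for name in fa.keys()}
    # pyfaidx leaves an index file behind; keep the directory clean
    for ext in (".fai",):
        try:
            os.remove(path + ext)
        except OSError:
            pass
    return out


# ---------------------------------------------------------------------------
# GFF3 gene models


@dataclass
class GeneModel:
    """A protein-coding gene: ordered CDS segments on one scaffold.

    ``cds`` is a list of (start, end) 1-based inclusive intervals in genomic
    order; on the minus strand the coding sequence is the reverse complement
    of their concatenation. ``attributes`` carries the annotation tags the
    gene filters act on (``partial``, ``modified_refseq``, ``transl_table``).
    """

    gene_id: str
    scaffold: str
    strand: str
    cds: list[tuple[int, int]]
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.cds:
            raise ValueError(f"gene {self.gene_id}: empty CDS")
        self.cds = sorted(self.cds)


def write_gff3(genes: list[GeneModel], path: str):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start = min(s for s, _ in g.cds)
            end = max(e for _, e in g.cds)
            attrs = [f"ID={g.gene_id}"]
            for k, v in g.attributes.items():
                attrs.append(f"{k}={v}")
            fh.write("\t".join([g.scaffold, "supergene", "gene", str(start),
                                str(end), ".", g.strand, ".",
                                ";".join(attrs)]) + "\n")
            for i, (s, e) in enumerate(g.cds):
                fh.write("\t".join([g.scaffold, "supergene", "CDS", str(s),
                                    str(e), ".", g.strand, "0",
                                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}"])
                         + "\n")


def read_gff3(path: str) -> list[GeneModel]:
    """Read gene models (gene + CDS features) from a GFF3 file via gffutils."""
    import gffutils

    db = gffutils.create_db(path, ":memory:", force=True,
                            merge_strategy="create_unique",
                            keep_order=True)
    out = []
    for g in db.features_of_type("gene"):
        attrs = {k: v[0] for k, v in g.attributes.items() if k != "ID"}
        cds = [(c.start, c.end) for c in db.children(g, featuretype="CDS")]
        if not cds:
            cds = [(g.start, g.end)]
        out.append(GeneModel(g.id, g.seqid, g.strand, sorted(cds), attrs))
    return out


# ---------------------------------------------------------------------------
# TSV tables

MARKER_COLUMNS = ["marker_id", "scaffold", "pos", "linkage_group", "cM",
                  "family_id", "family_type", "cosegregates_gp9"]


def write_marker_table(df: pd.DataFrame, path: str):
    df.to_csv(path, sep="\t", index=False)


def read_marker_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MARKER_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"marker table missing columns: {missing}")
    if "cosegregates_gp9" not in df.columns:
        df["cosegregates_gp9"] = False
    return df


def write_str_table(st: STRTable, path: str):
    """Write an STRTable as a wide TSV (four columns per sample)."""
    df = st.loci.copy()
    for j, s in enumerate(st.samples):
        df[f"{s}.units"] = st.units[:, j]
        df[f"{s}.Q"] = st.q[:, j]
        df[f"{s}.support"] = st.support[:, j]
        df[f"{s}.coverage"] = st.coverage[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.4g")


def read_str_table(path: str) -> STRTable:
    df = pd.read_csv(path, sep="\t")
    locus_cols = ["locus_id", "scaffold", "pos", "period", "ref_units", "score"]
    missing = [c for c in locus_cols if c not in df.columns]
    if missing:
        raise ValueError(f"STR table missing columns: {missing}")
    samples = []
    for c in df.columns:
        if c.endswith(".units"):
            samples.append(c[: -len(".units")])
    units = np.stack([df[f"{s}.units"].to_numpy(dtype=np.int32) for s in samples], axis=1) \
        if samples else np.zeros((len(df), 0), dtype=np.int32)
    q = np.stack([df[f"{s}.Q"].to_numpy(dtype=float) for s in samples], axis=1) \
        if samples else np.zeros((len(df), 0))
    support = np.stack([df[f"{s}.support"].to_numpy(dtype=np.int32) for s in samples], axis=1) \
        if samples else np.zeros((len(df), 0), dtype=np.int32)
    coverage = np.stack([df[f"{s}.coverage"].to_numpy(dtype=np.int32) for s in samples], axis=1) \
        if samples else np.zeros((len(df), 0), dtype=np.int32)
    return STRTable(df[locus_cols].copy(), units, q, support, coverage, samples)


def write_sample_manifest(ss: SampleSet, path: str):
    rows = []
    for s in ss.samples:
        rows.append({
            "sample": s,
            "group": ss.groups[s],
            "coverage_class": ss.coverage_class[s],
            "sibling_pair": (ss.sibling_pair or {}).get(s, ""),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_manifest(path: str) -> SampleSet:
    df = pd.read_csv(path, sep="\t")
    pairs = None
    if "sibling_pair" in df.columns and df["sibling_pair"].notna().any():
        pairs = {r["sample"]: int(r["sibling_pair"]) for _, r in df.iterrows()
                 if pd.notna(r["sibling_pair"]) and r["sibling_pair"] != ""}
    return SampleSet(
        samples=list(df["sample"]),
        groups=dict(zip(df["sample"], df["group"])),
        coverage_class=dict(zip(df["sample"], df["coverage_class"])),
        sibling_pair=pairs,
    )
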