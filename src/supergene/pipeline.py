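"""End-to-end orchestration: files in, differentiation report out.

``run_all`` wires the stages together the way the study design dictates:

1. read the VCF/FASTA/GFF/marker/STR inputs and the sample manifest;
2. apply the variant filters once over the whole sample set (used for
   FST and fixed differences) and once per group (used for within-group
   diversity);
3. place scaffolds on linkage groups from the marker table;
4. compute sliding-window and tiling-window statistics over mapped
   scaffolds;
5. call the supergene region as consecutive high-FST windows and summarise
   differentiation/diversity inside vs outside it;
6. filter gene models, compute NG86 consensus divergence for genes in the
   called region, run the McDonald–Kreitman contrast, and scan for strata
   against the Poisson null;
7. filter STR loci/calls and count group-fixed STR differences;
8. run a label permutation test of the fixed-difference count.

Everything is deterministic given the config seeds.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import yaml

from . import coding, filters, genome_map, regions, strata, windows
from .io import (
    read_fasta,
    read_gff3,
    read_marker_table,
    read_sample_manifest,
    read_str_table,
    read_vcf,
)
from .stats import density_enrichment_chi2, mk_test

__all__ = ["PipelineConfig", "run_all", "load_config"]


@dataclass
class PipelineConfig:
    vcf: str
    fasta: str
    gff: str
    markers: str
    strs: str
    samples: str
    outdir: str = "supergene_out"
    window_size: int = 30_000
    window_step: int = 10_000
    tile_size: int = 10_000
    region_call_window: int = 30_000
    fst_threshold: float = 0.25
    min_run: int = 2
    unmapped_fst_min: float = 0.75
    unmapped_fixed_min: int = 25
    strata_min_span: int = 30
    strata_rate: float = strata.DEFAULT_RATE
    strata_sims: int = 10_000
    n_perm: int = 200
    seed: int = 0
    genome_bp_low: float | None = None
    genome_bp_high: float | None = None
    dnds_background: str | None = None

    def validate(self):
        for name in ("vcf", "fasta", "gff", "markers", "strs", "samples"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"config input {name!r}: no such file {path}")


def load_config(path: str) -> PipelineConfig:
    """Read a flat key-value (YAML mapping) config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
        return inner
    return wrap


def _mapped_windows(gmap, sequences, size, step):
    """Windows over mapped scaffold segments, ordered along each linkage
    group; window coordinates remain scaffold-physical."""
    out = []
    for lg, segs in sorted(gmap.by_group().items()):
        for seg in segs:
            seq = sequences[seg.scaffold][seg.start:seg.end]
            for w in windows.make_windows(seq, seg.scaffold, size, step):
                out.append(windows.Window(
                    chrom=w.chrom, start=w.start + seg.start,
                    end=w.end + seg.start, accessible=w.accessible,
                    partial=w.partial))
    return out


def run_all(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report dict (also written to
    ``outdir/report.json`` alongside the per-window tables)."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config)}

    # --- inputs
    load = _stage("load_inputs")(_load_inputs)
    sequences, vt_raw, genes, markers, strs_raw, ss = load(config)

    # --- filters
    vt_all = _stage("variant_filters")(filters.apply_variant_filters)(vt_raw, ss, "all")
    vt_sb = filters.apply_variant_filters(vt_raw, ss, "SB")
    vt_sbm = filters.apply_variant_filters(vt_raw, ss, "Sb")
    report["n_sites_raw"] = vt_raw.n_sites
    report["n_sites_whole_set"] = vt_all.n_sites
    report["n_sites_SB"] = vt_sb.n_sites
    report["n_sites_Sb"] = vt_sbm.n_sites

    # --- genome map
    def make_map():
        mt = genome_map.filter_low_confidence_scaffolds(markers)
        mt, split_report = genome_map.split_chimeric_scaffolds(mt)
        lengths = {name: len(seq) for name, seq in sequences.items()}
        return genome_map.build_map(mt, lengths), split_report

    gmap, split_report = _stage("genome_map")(make_map)()
    report["mapped_bp"] = gmap.total_placed

    # --- windows
    comp = _stage("window_stats")(windows.compute_window_stats)
    tile = _mapped_windows(gmap, sequences, config.tile_size, config.tile_size)
    tile_stats = comp(vt_all, vt_sb, vt_sbm, ss, tile)
    call_win = _mapped_windows(gmap, sequences, config.region_call_window,
                               config.region_call_window)
    call_stats = comp(vt_all, vt_sb, vt_sbm, ss, call_win)
    windows.window_stats_frame(tile_stats).to_csv(
        os.path.join(config.outdir, "windows_tile.tsv"), sep="\t", index=False)
    windows.window_stats_frame(call_stats).to_csv(
        os.path.join(config.outdir, "windows_call.tsv"), sep="\t", index=False)

    # --- region call
    calls = _stage("call_region")(regions.call_region)(
        call_stats, config.fst_threshold, config.min_run)
    if calls:
        region = calls[0]
        report["region"] = {
            "scaffold": region.chrom, "start": region.start,
            "end": region.end, "length": region.length,
            "mean_fst": region.mean_fst, "fixed_snps": region.fixed_snps,
            "n_windows": len(region.window_indices),
        }
    else:
        region = None
        report["region"] = None

    def in_region(w: windows.Window) -> bool:
        return (region is not None and w.chrom == region.chrom
                and w.start >= region.start and w.end <= region.end)

    # --- Table-1-style summary over non-overlapping tiles (full tiles only)
    full = [s for s in tile_stats if not s.window.partial]
    reg = [s for s in full if in_region(s.window)]
    rest = [s for s in full if not in_region(s.window)]

    def summarise(subset):
        fst = np.array([s.fst for s in subset])
        fst = fst[~np.isnan(fst)]
        return {
            "n_windows": len(subset),
            "fst_mean": float(fst.mean()) if fst.size else float("nan"),
            "fst_sd": float(fst.std(ddof=1)) if fst.size > 1 else float("nan"),
            "pi_SB_mean": float(np.mean([s.pi_SB for s in subset])) if subset else float("nan"),
            "pi_Sb_mean": float(np.mean([s.pi_Sb for s in subset])) if subset else float("nan"),
            "fixed_snps": int(sum(s.fixed_snps for s in subset)),
            "fixed_indels": int(sum(s.fixed_indels for s in subset)),
            "accessible_bp": int(sum(s.window.accessible for s in subset)),
        }

    report["supergene_region"] = summarise(reg)
    report["background"] = summarise(rest)
    if reg and rest:
        enrich = density_enrichment_chi2(
            report["supergene_region"]["fixed_snps"],
            report["background"]["fixed_snps"],
            report["supergene_region"]["accessible_bp"],
            report["background"]["accessible_bp"])
        report["fixed_enrichment_chi2"] = enrich.statistic
        report["fixed_enrichment_p"] = enrich.p_value
    if reg and rest:
        report["pi_ratio_SB_pct"] = 100.0 * report["supergene_region"]["pi_SB_mean"] / \
            report["background"]["pi_SB_mean"]
        report["pi_ratio_Sb_pct"] = 100.0 * report["supergene_region"]["pi_Sb_mean"] / \
            report["background"]["pi_Sb_mean"]

    # --- coding divergence + MK + strata (genes inside the called region)
    genes_kept = _stage("gene_filters")(coding.filter_genes)(genes, vt_all, sequences)
    report["n_genes"] = len(genes)
    report["n_genes_kept"] = len(genes_kept)
    if region is not None:
        region_genes = [g for g in genes_kept if g.scaffold == region.chrom
                        and g.cds[0][0] - 1 >= region.start
                        and g.cds[-1][1] <= region.end]
        region_genes.sort(key=lambda g: g.cds[0][0])
        records = _stage("divergence")(coding.divergence_table)(
            region_genes, vt_all, ss, sequences)
        ds_vals = [r.ds for r in records]
        dn_vals = [r.dn for r in records]
        report["n_region_genes"] = len(region_genes)
        report["ds_mean"] = float(np.mean(ds_vals)) if ds_vals else float("nan")
        report["dn_mean"] = float(np.mean(dn_vals)) if dn_vals else float("nan")
        total_sd = sum(r.sd for r in records)
        total_nd = sum(r.nd for r in records)
        total_s = sum(r.s_sites for r in records)
        total_n = sum(r.n_sites for r in records)
        report["dnds_pooled"] = (total_nd / total_n) / (total_sd / total_s) \
            if total_sd > 0 and total_s > 0 and total_n > 0 else float("nan")

        mk_counts = coding.count_coding_snps(region_genes, vt_all, ss, sequences)
        report["mk_counts"] = mk_counts
        mk = mk_test(mk_counts["fixed_n"], mk_counts["fixed_s"],
                     mk_counts["poly_n"], mk_counts["poly_s"])
        report["mk_chi2"] = mk.statistic
        report["mk_p"] = mk.p_value
        report["mk_neutrality_index"] = mk.extra["neutrality_index"]

        # strata scan on fixed differences per coding bp, in map order
        if len(region_genes) >= config.strata_min_span + 2:
            lengths = [g.cds_length for g in region_genes]
            fixed_per_bp = []
            snp = vt_all.take_sites(vt_all.is_snp())
            _, _, fixed_idx = windows.fixed_differences(snp, ss)
            fixed_pos = {(str(snp.scaffold[i]), int(snp.pos[i])) for i in fixed_idx}
            for g in region_genes:
                k = sum(1 for s, e in g.cds
                        for p in range(s, e + 1) if (g.scaffold, p) in fixed_pos)
                fixed_per_bp.append(k / g.cds_length)
            res = _stage("strata_scan")(strata.strata_test)(
                fixed_per_bp, lengths, rate=config.strata_rate,
                n_sims=config.strata_sims, seed=config.seed,
                min_span=config.strata_min_span)
            report["strata"] = {
                "found": res.found, "best_start": res.best_start,
                "best_length": res.best_length, "p_observed": res.p_observed,
                "empirical_p": res.empirical_p, "n_sims": res.n_sims,
            }
        else:
            report["strata"] = None

    # --- STRs
    def str_stage():
        st = filters.filter_str_loci(strs_raw)
        st = filters.filter_str_calls(st, ss, "all")
        fixed = windows.str_fixed_differences(st, ss)
        return st, fixed

    st_kept, str_fixed = _stage("str_filters")(str_stage)()
    report["n_str_loci_kept"] = st_kept.n_loci
    report["n_str_fixed"] = int(len(str_fixed))

    # --- permutation robustness
    perm = _stage("permutation")(regions.permutation_test)(
        vt_all, ss, "fixed_differences", config.n_perm, config.seed)
    report["permutation"] = {
        "observed": perm["observed"], "p_value": perm["p_value"],
        "n_perm": perm["n_perm"], "null_max": float(perm["null"].max()),
        "seed": config.seed,
    }

    # --- extrapolation
    if region is not None and config.genome_bp_low and config.genome_bp_high:
        analysed = gmap.total_placed
        lo, hi = regions.extrapolate_region_size(
            region.length, analysed, config.genome_bp_low, config.genome_bp_high)
        report["region_size_extrapolated_bp"] = [lo, hi]

    # --- dN/dS background comparison (optional input)
    if config.dnds_background and region is not None:
        bg = np.loadtxt(config.dnds_background)
        report["dnds_background"] = coding.dnds_background_comparison(records, bg)

    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o).__name__)


def _load_inputs(config: PipelineConfig):
    sequences = read_fasta(config.fasta)
    vt = read_vcf(config.vcf)
    genes = read_gff3(config.gff)
    markers = read_marker_table(config.markers)
    strs = read_str_table(config.strs)
    ss = read_sample_manifest(config.samples)
    return sequences, vt, genes, markers, strs, ss
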