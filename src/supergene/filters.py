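"""Quality filters for variant and STR calls.

The variant filters mirror the recommended post-processing of a de Bruijn
graph bubble caller on haploid samples: a site-level confidence threshold
(SITE_CONF > 15), per-sample genotype confidence thresholds that depend on
each sample's sequencing depth class (GT_CONF > 10 for low-coverage samples,
> 2 for high-coverage ones), and the requirement that the called allele has
at least one supporting read in every sample considered.

Both variant and STR filters run in either *whole-set* mode (every sample
must pass — used for between-group differentiation) or *per-group* mode
(thresholds evaluated only over the named group — used for within-group
diversity, so that genotype quality in one group cannot censor sites from
the other group's diversity estimate).
"""

from __future__ import annotations

import numpy as np

from .io import MISSING, STRTable, SampleSet, VariantTable

__all__ = [
    "apply_variant_filters",
    "filter_str_loci",
    "filter_str_calls",
    "SITE_CONF_MIN",
    "GT_CONF_MIN_LOW",
    "GT_CONF_MIN_HIGH",
]

SITE_CONF_MIN = 15.0
GT_CONF_MIN_LOW = 10.0
GT_CONF_MIN_HIGH = 2.0

# reference repeat-unit thresholds by period: mono > 9, di > 5, >=3 bp > 4
_STR_UNIT_THRESHOLDS = {1: 9, 2: 5}
_STR_UNIT_DEFAULT = 4

STR_Q_MIN = 0.25
STR_SUPPORT_MIN = 2
STR_COVERAGE_MAX = 25


def _scope_indices(samples, ss: SampleSet, mode: str) -> np.ndarray:
    if mode == "all":
        names = [s for s in samples if s in ss.groups]
    elif mode in ("SB", "Sb"):
        names = [s for s in samples if ss.groups.get(s) == mode]
    else:
        raise ValueError(f"mode must be 'all', 'SB' or 'Sb', got {mode!r}")
    if not names:
        raise ValueError(f"no samples in scope for mode {mode!r}")
    lookup = {s: i for i, s in enumerate(samples)}
    return np.array([lookup[s] for s in names], dtype=int)


def apply_variant_filters(vt: VariantTable, ss: SampleSet, mode: str = "all") -> VariantTable:
    """Retain sites passing SITE_CONF, GT_CONF and called-allele coverage filters.

    Parameters
    ----------
    mode : "all" | "SB" | "Sb"
        "all" evaluates the per-sample thresholds over every sample;
        "SB"/"Sb" evaluates them only over that group's samples (the
        per-group filtering used for within-group diversity).

    A retained site has, for every sample in scope, a non-missing call with
    GT_CONF above the sample's depth-class threshold and coverage >= 1,
    and SITE_CONF > 15. The filter is idempotent.
    """
    idx = _scope_indices(vt.samples, ss, mode)
    names = [vt.samples[i] for i in idx]
    thresholds = np.array(
        [GT_CONF_MIN_LOW if ss.coverage_class[s] == "low" else GT_CONF_MIN_HIGH
         for s in names])
    if np.isnan(vt.site_conf).any():
        i = int(np.flatnonzero(np.isnan(vt.site_conf))[0])
        raise ValueError(
            f"site {vt.scaffold[i]}:{vt.pos[i]}: missing annotation SITE_CONF")
    gt = vt.genotypes[:, idx]
    conf = vt.gt_conf[:, idx]
    cov = vt.cov[:, idx]
    if np.isnan(conf).any():
        i = int(np.flatnonzero(np.isnan(conf).any(axis=1))[0])
        raise ValueError(
            f"site {vt.scaffold[i]}:{vt.pos[i]}: missing annotation GT_CONF")
    keep = (
        (vt.site_conf > SITE_CONF_MIN)
        & (gt != MISSING).all(axis=1)
        & (conf > thresholds[None, :]).all(axis=1)
        & (cov >= 1).all(axis=1)
    )
    return vt.take_sites(keep)


def filter_str_loci(st: STRTable, inclusive: bool = False) -> STRTable:
    """Retain STR loci whose reference repeat-unit count clears the
    period-dependent threshold (9 / 5 / 4 for mono- / di- / longer units).

    ``inclusive=False`` (default) reads "larger than" strictly; with
    ``inclusive=True`` a count equal to the threshold is kept. Loci with a
    period outside 1-6 are dropped with a warning.
    """
    period = st.loci["period"].to_numpy()
    ref_units = st.loci["ref_units"].to_numpy()
    bad_period = (period < 1) | (period > 6)
    if bad_period.any():
        import warnings

        warnings.warn(
            f"dropping {int(bad_period.sum())} STR loci with period outside 1-6",
            stacklevel=2)
    thr = np.array([_STR_UNIT_THRESHOLDS.get(int(p), _STR_UNIT_DEFAULT)
                    for p in period])
    keep = (ref_units >= thr) if inclusive else (ref_units > thr)
    keep &= ~bad_period
    return st.take_loci(keep)


def filter_str_calls(st: STRTable, ss: SampleSet, mode: str = "all") -> STRTable:
    """Retain STR loci where every in-scope sample's call passes
    Q >= 0.25, supporting reads >= 2 and total coverage <= 25."""
    idx = _scope_indices(st.samples, ss, mode)
    keep = (
        (st.units[:, idx] != MISSING).all(axis=1)
        & (st.q[:, idx] >= STR_Q_MIN).all(axis=1)
        & (st.support[:, idx] >= STR_SUPPORT_MIN).all(axis=1)
        & (st.coverage[:, idx] <= STR_COVERAGE_MAX).all(axis=1)
    )
    return st.take_loci(keep)
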