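"""Parent-informative marker selection and per-bulk SNP-index.

The SNP-index of a bulk at a marker is the fraction of its reads carrying
the dwarf-parent (AYP1) allele, computed from allele depths, never from
called genotypes: 0 means the bulk looks entirely like the tall reference
parent (XYP1), 1 entirely like the dwarf parent.  Markers are usable only
where both inbred parents are homozygous for different alleles.  The
study's marker filters are applied afterwards: a locus is dropped when its
index is below ``index_min`` in BOTH pools (no signal in either), when
depth is below ``depth_min`` (by default in EITHER pool, because one
shallow pool already makes its index unreliable), or when the index is
missing (zero depth) in any pool.  Boundary values are retained.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ORIENTATION_NOTE",
    "call_parent_informative_markers",
    "compute_snp_index",
    "filter_markers",
]

#: recorded in output metadata; reorienting maps index -> 1 - index.
ORIENTATION_NOTE = (
    "snp_index = frequency of the dwarf-parent (AYP1) allele; "
    "delta = index(high bulk) - index(low bulk)"
)

_HOM_REF = {"0/0", "0|0"}
_HOM_ALT = {"1/1", "1|1"}

TRACK_COLUMNS = [
    "chrom", "pos", "dwarf_high", "depth_high", "dwarf_low", "depth_low",
    "index_high", "index_low", "delta",
]


def _gt_class(gt: pd.Series) -> pd.Series:
    out = pd.Series("other", index=gt.index, dtype=object)
    out[gt.isin(_HOM_REF)] = "hom_ref"
    out[gt.isin(_HOM_ALT)] = "hom_alt"
    return out


def call_parent_informative_markers(records: pd.DataFrame) -> pd.DataFrame:
    """Keep loci where both parents are homozygous for different alleles.

    Heterozygous or missing parent genotypes drop the locus.  Never mutates
    the input; the returned frame is a filtered copy.
    """
    g1 = _gt_class(records["p1_gt"])
    g2 = _gt_class(records["p2_gt"])
    keep = (
        ((g1 == "hom_ref") & (g2 == "hom_alt"))
        | ((g1 == "hom_alt") & (g2 == "hom_ref"))
    )
    return records.loc[keep].reset_index(drop=True)


def compute_snp_index(records: pd.DataFrame) -> pd.DataFrame:
    """Per-bulk SNP-index track from allele depths at informative loci.

    The dwarf-allele read count per bulk is the alt column where the dwarf
    parent is hom-alt, the ref column where it is hom-ref.  Zero-depth
    indices are missing (NaN), not 0; delta is present only where both
    indices are.
    """
    dwarf_is_alt = records["p2_gt"].isin(_HOM_ALT).to_numpy()
    hb_alt = records["hb_alt"].to_numpy(float)
    hb_ref = records["hb_ref"].to_numpy(float)
    lb_alt = records["lb_alt"].to_numpy(float)
    lb_ref = records["lb_ref"].to_numpy(float)
    dwarf_h = np.where(dwarf_is_alt, hb_alt, hb_ref)
    dwarf_l = np.where(dwarf_is_alt, lb_alt, lb_ref)
    depth_h = hb_alt + hb_ref
    depth_l = lb_alt + lb_ref
    with np.errstate(invalid="ignore", divide="ignore"):
        idx_h = np.where(depth_h > 0, dwarf_h / depth_h, np.nan)
        idx_l = np.where(depth_l > 0, dwarf_l / depth_l, np.nan)
    track = pd.DataFrame(
        {
            "chrom": records["chrom"].to_numpy(),
            "pos": records["pos"].to_numpy(np.int64),
            "dwarf_high": dwarf_h.astype(np.int64),
            "depth_high": depth_h.astype(np.int64),
            "dwarf_low": dwarf_l.astype(np.int64),
            "depth_low": depth_l.astype(np.int64),
            "index_high": idx_h,
            "index_low": idx_l,
            "delta": idx_h - idx_l,
        }
    )
    return track


def filter_markers(
    track: pd.DataFrame,
    index_min: float = 0.3,
    depth_min: int = 7,
    depth_rule: str = "either",
) -> pd.DataFrame:
    """Apply the study's marker filters; idempotent.

    Drop a locus when (a) its index is < ``index_min`` in both pools,
    (b) depth is < ``depth_min`` in either pool (set ``depth_rule='both'``
    for the stricter-reading alternative: drop only when both pools are
    shallow), or (c) the index is missing in any pool.  Exactly-boundary
    loci are retained ("less than" is strict).
    """
    if depth_rule not in {"either", "both"}:
        raise ValueError("depth_rule must be 'either' or 'both'")
    idx_h = track["index_high"].to_numpy(float)
    idx_l = track["index_low"].to_numpy(float)
    dep_h = track["depth_high"].to_numpy(float)
    dep_l = track["depth_low"].to_numpy(float)
    low_index_both = (idx_h < index_min) & (idx_l < index_min)
    if depth_rule == "either":
        shallow = (dep_h < depth_min) | (dep_l < depth_min)
    else:
        shallow = (dep_h < depth_min) & (dep_l < depth_min)
    missing = np.isnan(idx_h) | np.isnan(idx_l)
    drop = low_index_both | shallow | missing
    return track.loc[~drop].reset_index(drop=True)
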