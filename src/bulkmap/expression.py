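"""Count-based differential expression and companion statistics.

A deliberately minimal negative-binomial pipeline at desk scale: FPKM
expression flagging, median-of-ratios library-size normalization, a
per-gene NB Wald test with pooled method-of-moments dispersion,
Benjamini-Hochberg FDR, the study's DEG rule (|log2FC| > 1 and q < 0.05,
both strict, with the tall line XYP1 as control), upper-tail
hypergeometric term enrichment, Pearson sample-correlation QC, and the
2^-ddCt relative-expression transform for qPCR validation.

This is not a DESeq2 clone: there is no dispersion trend, Cook's filtering
or independent filtering.  The dispersion is a single method-of-moments
value pooled across genes (and groups), which keeps the Wald z statistic
approximately standard normal even at 3-vs-3 designs, where per-gene
variance estimates are far too noisy to plug into a Wald denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_fpkm",
    "size_factors",
    "nb_test",
    "bh_adjust",
    "call_degs",
    "hypergeometric_enrichment",
    "sample_correlation",
    "ddct",
]

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = counts * 1e9 / (gene length in bp * library size).

    ``library_sizes`` defaults to the per-sample column sums.  Scale
    invariant: doubling all counts and library sizes leaves FPKM unchanged.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:5].tolist()
        raise ValueError(f"missing gene lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts * 1e9 / np.outer(lengths.to_numpy(), library_sizes.to_numpy())


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    Per gene with all-positive counts, the ratio of each sample's count to
    the gene's geometric mean across samples; the factor is the per-sample
    median of those ratios.
    """
    mat = counts.to_numpy(float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has nonzero counts in every sample")
    sub = mat[positive]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def _group_matrices(
    counts: pd.DataFrame, groups, sf: pd.Series, control: str
) -> tuple[np.ndarray, np.ndarray, str]:
    groups = pd.Series(list(groups), index=counts.columns)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    if control not in set(levels):
        raise ValueError(f"control {control!r} not among groups {list(levels)}")
    case = [lv for lv in levels if lv != control][0]
    norm = counts.to_numpy(float) / sf.reindex(counts.columns).to_numpy()[None, :]
    c0 = norm[:, (groups == control).to_numpy()]
    c1 = norm[:, (groups == case).to_numpy()]
    if c0.shape[1] < 2 or c1.shape[1] < 2:
        raise ValueError("each group needs >= 2 replicates")
    return c0, c1, case


def nb_test(
    counts: pd.DataFrame,
    groups,
    sf: pd.Series | None = None,
    control: str = "XYP1",
) -> pd.DataFrame:
    """Per-gene NB Wald test of the case group against ``control``.

    Counts are normalized by the size factors.  The NB dispersion
    (var = mu + alpha mu^2) is one method-of-moments value pooled across
    genes and groups: the mean over genes of (s2 - m)/m^2 with s2 the
    within-group pooled sample variance, floored at 1e-8.  log2FC is the
    log2 case/control ratio of group means with a 0.5 pseudo-count; the
    Wald z uses the delta-method variance of the log2 means and a standard
    normal reference, two-sided.
    """
    if sf is None:
        sf = size_factors(counts)
    c0, c1, case = _group_matrices(counts, groups, sf, control)
    n0, n1 = c0.shape[1], c1.shape[1]
    m0, m1 = c0.mean(axis=1), c1.mean(axis=1)
    base_mean = np.concatenate([c0, c1], axis=1).mean(axis=1)
    s2 = ((n0 - 1) * c0.var(axis=1, ddof=1) + (n1 - 1) * c1.var(axis=1, ddof=1)) / (
        n0 + n1 - 2
    )
    mean_for_disp = np.maximum(base_mean, PSEUDOCOUNT)
    per_gene = (s2 - mean_for_disp) / mean_for_disp**2
    alpha = max(float(np.mean(per_gene)) if per_gene.size else 0.0, DISPERSION_FLOOR)
    m0p, m1p = m0 + PSEUDOCOUNT, m1 + PSEUDOCOUNT
    log2fc = np.log2(m1p / m0p)
    v0 = (m0p + alpha * m0p**2) / n0
    v1 = (m1p + alpha * m1p**2) / n1
    se = np.sqrt(v0 / m0p**2 + v1 / m1p**2) / np.log(2.0)
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "dispersion": np.full(len(base_mean), alpha),
            "stat": z,
            "p": p,
        },
        index=counts.index,
    )
    out.attrs["case"] = case
    out.attrs["control"] = control
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_degs(
    results: pd.DataFrame,
    fpkm: pd.DataFrame | None = None,
    lfc_min: float = 1.0,
    q_max: float = 0.05,
    fpkm_min: float = 1.0,
) -> pd.DataFrame:
    """Apply the DEG rule: |log2FC| > lfc_min (strict) and q < q_max (strict).

    Adds q (BH over all tested genes), deg_flag, direction (up/down relative
    to the control, none otherwise) and, when FPKM is supplied, an
    expressed_flag (FPKM > fpkm_min in >= 1 sample; reported, not used as a
    prefilter).
    """
    out = results.copy()
    out.attrs.update(results.attrs)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["deg_flag"] = (out["log2fc"].abs() > lfc_min) & (out["q"] < q_max)
    direction = np.where(
        out["deg_flag"], np.where(out["log2fc"] > 0, "up", "down"), "none"
    )
    out["direction"] = direction
    if fpkm is not None:
        expressed = (fpkm > fpkm_min).any(axis=1)
        out["expressed_flag"] = expressed.reindex(out.index).fillna(False)
    return out


def hypergeometric_enrichment(
    degs: set, universe: set, term_map: dict[str, set]
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term's gene set.

    p = P(overlap >= observed) drawing |degs| genes from |universe| with
    term genes as successes; q = BH across terms; significant at q <= 0.05.
    """
    degs, universe = set(degs), set(universe)
    if not degs:
        raise ValueError("empty DEG set")
    if not degs <= universe:
        raise ValueError("DEG set must be a subset of the universe")
    rows = []
    n_draw = len(degs)
    n_uni = len(universe)
    for term in sorted(term_map):
        term_genes = set(term_map[term]) & universe
        k = len(term_genes & degs)
        big_k = len(term_genes)
        p = float(stats.hypergeom.sf(k - 1, n_uni, big_k, n_draw))
        rows.append((term, k, big_k, p))
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["q"] <= 0.05
    return out


def sample_correlation(
    counts: pd.DataFrame, sf: pd.Series | None = None
) -> pd.DataFrame:
    """Pearson correlation between samples on log2(normalized count + 1)."""
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if sf is None:
        sf = size_factors(counts)
    logn = np.log2(counts.to_numpy(float) / sf.to_numpy()[None, :] + 1.0)
    if np.any(logn.std(axis=0) == 0):
        raise ValueError("zero-variance sample")
    r = np.corrcoef(logn, rowvar=False)
    return pd.DataFrame(r, index=counts.columns, columns=counts.columns)


def ddct(
    ct_target: float, ct_ref: float, ct_target_control: float, ct_ref_control: float
) -> float:
    """Relative expression 2^-ddCt, double-normalized to a reference gene
    and a control condition (which returns 1 by construction)."""
    vals = (ct_target, ct_ref, ct_target_control, ct_ref_control)
    if not all(np.isfinite(vals)):
        raise ValueError("Ct values must be finite")
    ddct_val = (ct_target - ct_ref) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct_val))
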