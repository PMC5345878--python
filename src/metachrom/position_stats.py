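"""Positional statistics relating chromatin signal to expression and splicing.

These are the bespoke analyses of the pipeline:

* :func:`slope_profile` — at every base-pair offset from the boundary,
  OLS slope of the ChIP/input ratio (20-bp sliding window means, with a
  pseudocount) against log2(TPM + 1) across anchors.  A positive slope at
  exonic offsets larger than at intronic offsets means exons gain the
  variant faster than introns upon activation.
* :func:`positional_correlation` — Pearson correlation of log window-mean
  coverage between two tracks, in 50-bp windows tiling the flank.
* :func:`matched_subsample` — draw from a large exon pool a subset whose
  host-gene log-expression distribution matches a target set (confound
  control before comparing chromatin signal between exon classes).
* :func:`window_mean_compare` — mean per-region coverage of two region
  sets with a two-sided Welch t-test (Wilcoxon rank-sum optional).
* :func:`positional_gsea` — rank genes by mean coverage in 50-bp windows
  stepped across the flank and test each gene set by one-sided Wilcoxon
  rank-sum, BH-corrected across (window x set).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotations import ExonRecord
from .coverage import CoverageTrack
from .profiles import ProfileMatrix

__all__ = [
    "slope_profile",
    "positional_correlation",
    "matched_subsample",
    "window_mean_compare",
    "positional_gsea",
    "read_gene_sets",
    "sliding_window_means",
    "DEFAULT_PSEUDOCOUNT",
]

#: pseudocount (RPM) guarding ratios and log transforms against zeros
DEFAULT_PSEUDOCOUNT = 0.1


def sliding_window_means(values: np.ndarray, window: int) -> np.ndarray:
    """Centred sliding mean along columns, truncated (not padded) at edges.

    The window for column d covers columns [d - window//2, d + window//2);
    NaNs are excluded, and a window with no finite entry stays NaN.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    filled = np.where(finite, v, 0.0)
    zeros = np.zeros((v.shape[0], 1))
    cs = np.concatenate([zeros, np.cumsum(filled, axis=1)], axis=1)
    cn = np.concatenate([zeros, np.cumsum(finite, axis=1)], axis=1)
    half = window // 2
    cols = np.arange(v.shape[1])
    lo = np.clip(cols - half, 0, v.shape[1])
    hi = np.clip(cols + (window - half), 0, v.shape[1])
    s = cs[:, hi] - cs[:, lo]
    n = cn[:, hi] - cn[:, lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = s / n
    out[n == 0] = np.nan
    return out


def _expression_vector(expression, anchors) -> np.ndarray:
    if isinstance(expression, Mapping):
        return np.array([float(expression[a.gene_id]) for a in anchors])
    x = np.asarray(expression, dtype=float)
    if x.size != len(anchors):
        raise ValueError("expression vector must align with matrix anchors")
    return x


def slope_profile(
    chip: ProfileMatrix,
    input_: ProfileMatrix,
    expression,
    window: int = 20,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-offset OLS slope of the ChIP/input ratio versus log2 expression.

    For every anchor and offset d the ratio is

        r(d) = (mean ChIP in the ``window``-bp window centred at d + eps)
             / (mean input in the same window + eps)

    and at each offset the model ``r = a + b * log2(TPM + 1)`` is fit by
    ordinary least squares across anchors.  Returns a frame with columns
    offset, slope, stderr, n.  The slope is invariant to rescaling all
    TPM by a constant (absorbed by the intercept under log).

    ``expression`` is a gene_id -> TPM mapping or a vector aligned with
    the matrix rows.  Requires >= 3 anchors and non-constant expression.
    """
    if chip.values.shape != input_.values.shape or not np.array_equal(
        chip.offsets, input_.offsets
    ):
        raise ValueError("chip and input matrices must share anchors and offsets")
    if chip.n_anchors < 3:
        raise ValueError("slope_profile needs at least 3 anchors")
    x = np.log2(_expression_vector(expression, chip.anchors) + 1.0)
    if np.ptp(x) == 0:
        raise ValueError("expression has zero variance; slope is undefined")

    cw = sliding_window_means(chip.values, window)
    iw = sliding_window_means(input_.values, window)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (cw + pseudocount) / (iw + pseudocount)

    valid = np.isfinite(r)
    n = valid.sum(axis=0).astype(float)
    rv = np.where(valid, r, 0.0)
    sx = x @ valid
    sxx = (x**2) @ valid
    sy = rv.sum(axis=0)
    sxy = x @ rv
    syy = (rv**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sxx_c = sxx - sx**2 / n
        sxy_c = sxy - sx * sy / n
        syy_c = syy - sy**2 / n
        slope = sxy_c / sxx_c
        rss = np.maximum(syy_c - slope * sxy_c, 0.0)
        dof = n - 2
        stderr = np.sqrt(rss / np.where(dof > 0, dof, np.nan) / sxx_c)
    bad = (n < 3) | ~np.isfinite(sxx_c) | (sxx_c <= 0)
    slope[bad] = np.nan
    stderr[bad] = np.nan
    return pd.DataFrame(
        {"offset": chip.offsets, "slope": slope, "stderr": stderr, "n": n.astype(int)}
    )


def positional_correlation(
    track_a: ProfileMatrix,
    track_b: ProfileMatrix,
    window: int = 50,
    step: int | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Pearson correlation of log2 window-mean coverage between two tracks.

    Windows of ``window`` bp tile the shared offset range every ``step``
    bp (default: non-overlapping, step = window).  Within each window the
    per-anchor mean coverage of each track is log2(x + eps) transformed
    and correlated across anchors.  Constant vectors yield a missing r.
    Columns: offset (window centre), r, n.
    """
    if track_a.values.shape != track_b.values.shape or not np.array_equal(
        track_a.offsets, track_b.offsets
    ):
        raise ValueError("matrices must share anchors and offsets")
    if step is None:
        step = window
    offsets = track_a.offsets
    width = offsets.size
    rows = []
    for start_col in range(0, width - window + 1, step):
        cols = slice(start_col, start_col + window)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ma = np.nanmean(track_a.values[:, cols], axis=1)
            mb = np.nanmean(track_b.values[:, cols], axis=1)
        pair = np.isfinite(ma) & np.isfinite(mb)
        centre = int(offsets[start_col]) + window // 2
        n = int(pair.sum())
        if n < 3:
            rows.append((centre, np.nan, n))
            continue
        la = np.log2(ma[pair] + pseudocount)
        lb = np.log2(mb[pair] + pseudocount)
        if np.ptp(la) == 0 or np.ptp(lb) == 0:
            rows.append((centre, np.nan, n))
            continue
        r = float(stats.pearsonr(la, lb).statistic)
        rows.append((centre, r, n))
    return pd.DataFrame(rows, columns=["offset", "r", "n"])


def matched_subsample(
    pool: Sequence[ExonRecord],
    target: Sequence[ExonRecord],
    expression: Mapping[str, float] | None = None,
    nbins: int = 20,
    seed: int | np.random.Generator = 0,
) -> list[ExonRecord]:
    """Subsample ``pool`` to match ``target``'s log-expression distribution.

    The target's log2(TPM + 1) values define ``nbins`` quantile bins; the
    same number of pool records as target records is drawn without
    replacement per bin.  A bin whose pool is too small borrows its
    shortfall from the nearest bins (with a warning).  The subset size
    always equals ``len(target)`` and the draw is reproducible via
    ``seed``.
    """
    if len(pool) < len(target):
        raise ValueError(f"pool ({len(pool)}) smaller than target ({len(target)})")
    if not target:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def logexpr(records) -> np.ndarray:
        vals = []
        for r in records:
            tpm = r.expression
            if tpm is None and expression is not None:
                tpm = expression[r.gene_id]
            if tpm is None:
                raise ValueError(f"no expression for exon of gene {r.gene_id}")
            vals.append(float(tpm))
        return np.log2(np.asarray(vals) + 1.0)

    tv = logexpr(target)
    pv = logexpr(pool)
    edges = np.quantile(tv, np.linspace(0, 1, nbins + 1))
    inner = edges[1:-1]
    # right-closed bins, matching quantile edges; extremes swallow tails
    t_bins = np.searchsorted(inner, tv, side="left")
    p_bins = np.searchsorted(inner, pv, side="left")

    need = np.bincount(t_bins, minlength=nbins)
    pool_by_bin = [np.flatnonzero(p_bins == b) for b in range(nbins)]
    avail = np.array([idx.size for idx in pool_by_bin])

    take = np.minimum(need, avail)
    deficit = need - take
    if deficit.sum():
        warnings.warn(
            f"{int(deficit.sum())} matched draws borrowed from neighbouring "
            "expression bins (pool too sparse in some bins)"
        )
        for b in np.flatnonzero(deficit):
            for dist in range(1, nbins):
                for j in (b - dist, b + dist):
                    if 0 <= j < nbins and deficit[b] > 0:
                        spare = avail[j] - take[j]
                        grab = min(spare, deficit[b])
                        take[j] += grab
                        deficit[b] -= grab
                if deficit[b] == 0:
                    break
        if deficit.sum():
            raise ValueError("pool exhausted while matching expression bins")

    chosen: list[int] = []
    for b in range(nbins):
        if take[b]:
            chosen.extend(rng.choice(pool_by_bin[b], size=int(take[b]), replace=False))
    return [pool[i] for i in sorted(chosen)]


def window_mean_compare(
    track: CoverageTrack,
    regions_a: Sequence[tuple[str, int, int]],
    regions_b: Sequence[tuple[str, int, int]],
    test: str = "welch",
) -> tuple[float, float, float]:
    """Compare mean per-base coverage between two region sets.

    Each region contributes its mean coverage per base (clipped to the
    chromosome; regions empty after clipping are dropped).  Returns
    ``(mean_a, mean_b, p)`` with a two-sided Welch t-test on the
    per-region means, or a Wilcoxon rank-sum when ``test='wilcoxon'``.
    """

    def region_means(regions) -> np.ndarray:
        if not regions:
            raise ValueError("region set is empty")
        means = []
        for chrom, start, end in regions:
            arr = track.data.get(chrom)
            if arr is None:
                continue
            s, e = max(start, 0), min(end, arr.size)
            if e > s:
                means.append(arr[s:e].mean())
        return np.asarray(means)

    a = region_means(regions_a)
    b = region_means(regions_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 usable regions per group for a variance estimate")
    if test == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    p = float(res.pvalue)
    if np.isnan(p):  # identical constant groups: no evidence of difference
        p = 1.0
    return float(a.mean()), float(b.mean()), p


def positional_gsea(
    matrix: ProfileMatrix,
    gene_sets: Mapping[str, Sequence[str]],
    window: int = 50,
    step: int = 50,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """Positional gene-set enrichment along the anchor flank.

    In each ``window``-bp window stepped every ``step`` bp, genes are
    scored by their mean coverage and each gene set is tested by a
    one-sided Wilcoxon rank-sum (are in-set genes ranked higher than the
    rest?).  P-values are Benjamini-Hochberg corrected across every
    (window, set) pair.  Sets with fewer than ``min_set_size`` genes
    joined to the matrix are skipped with a warning.

    Columns: offset (window centre), term, statistic (rank-biserial
    enrichment in [-1, 1]), p, q.
    """
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    genes = np.array(matrix.gene_ids())
    memberships: dict[str, np.ndarray] = {}
    for term, members in gene_sets.items():
        mask = np.isin(genes, list(members))
        if mask.sum() < min_set_size:
            warnings.warn(f"gene set {term!r}: only {int(mask.sum())} genes joined; skipped")
            continue
        if mask.all():
            warnings.warn(f"gene set {term!r} covers every gene; skipped")
            continue
        memberships[term] = mask
    if not memberships:
        raise ValueError("no gene set had enough joined genes")

    offsets = matrix.offsets
    rows = []
    for start_col in range(0, offsets.size - window + 1, step):
        cols = slice(start_col, start_col + window)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            scores = np.nanmean(matrix.values[:, cols], axis=1)
        ok = np.isfinite(scores)
        centre = int(offsets[start_col]) + window // 2
        for term, mask in memberships.items():
            inside = scores[mask & ok]
            outside = scores[~mask & ok]
            if inside.size < min_set_size or outside.size < min_set_size:
                continue
            res = stats.mannwhitneyu(inside, outside, alternative="greater")
            # rank-biserial effect size: P(in > out) - P(out > in)
            effect = 2.0 * res.statistic / (inside.size * outside.size) - 1.0
            rows.append((centre, term, float(effect), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["offset", "term", "statistic", "p"])
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def read_gene_sets(path) -> dict[str, list[str]]:
    """Read gene sets from two-column TSV (term, gene) or GMT."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        gmt = len(first.rstrip("\n").split("\t")) > 2
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or not fields[0]:
                continue
            if gmt:
                term, members = fields[0], [g for g in fields[2:] if g]
                sets.setdefault(term, []).extend(members)
            else:
                if len(fields) < 2:
                    continue
                sets.setdefault(fields[0], []).append(fields[1])
    if not sets:
        raise ValueError(f"{path}: no gene sets parsed")
    return sets
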