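"""Anchored profile matrices, meta-profiles, stratification, metagenes, heatmaps.

The central object is the :class:`ProfileMatrix`: one row per anchor, one
column per relative offset, strand-corrected so that positive offsets
always point 5'->3' along the transcript.  Offsets run from ``-upstream``
to ``downstream - 1``; positions falling off the chromosome are missing
(NaN) rather than zero, so edge genes do not bias means.

Aggregations built on it:

* :func:`mean_profile` — per-offset mean with pointwise 95% normal
  confidence bands (the grey bands of a meta-profile plot);
* :func:`stratify` — expression classes (repressed + rank tertiles),
  signal-level quartiles scored in a window, or inclusion (PSI) classes;
* :func:`metagene_scale` — length-normalised 0..1 profiles with
  fractional-base bin weighting;
* :func:`heatmap` — 100 rank-group mean rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import Anchor, INCLUSION_CLASSES, inclusion_class
from .coverage import CoverageTrack

__all__ = [
    "ProfileMatrix",
    "anchored_matrix",
    "mean_profile",
    "stratify",
    "metagene_scale",
    "heatmap",
    "HeatmapMatrix",
    "EXPRESSION_CLASSES",
    "LEVEL_CLASSES",
    "REPRESSED_TPM",
    "TSS_SCORE_WINDOW",
    "EXON_SCORE_WINDOW",
]

EXPRESSION_CLASSES = ("repressed", "low", "medium", "high")
LEVEL_CLASSES = ("very_low", "low", "medium", "high")

#: genes below this TPM are called repressed
REPRESSED_TPM = 0.1
#: offsets scored for "signal level at the TSS" stratification
TSS_SCORE_WINDOW = (-75, -25)
#: offsets scored for "signal level over the exon" stratification
EXON_SCORE_WINDOW = (0, 150)


@dataclass
class ProfileMatrix:
    """Anchors x relative-offset signal matrix, strand-oriented.

    ``values[i, j]`` is the track value at ``pos_i + offsets[j]`` for a
    + strand anchor and ``pos_i - offsets[j]`` for a - strand anchor;
    NaN marks off-chromosome padding.
    """

    values: np.ndarray
    offsets: np.ndarray
    anchors: list[Anchor]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=int)
        if self.values.shape != (len(self.anchors), self.offsets.size):
            raise ValueError("ProfileMatrix shape disagrees with anchors/offsets")

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def gene_ids(self) -> list[str]:
        return [a.gene_id for a in self.anchors]

    def subset(self, indices: Sequence[int]) -> "ProfileMatrix":
        idx = np.asarray(indices, dtype=int)
        return ProfileMatrix(self.values[idx], self.offsets,
                             [self.anchors[i] for i in idx])

    def window_means(self, start: int, stop: int) -> np.ndarray:
        """Per-anchor mean over offsets in [start, stop), ignoring NaN."""
        cols = (self.offsets >= start) & (self.offsets < stop)
        if not cols.any():
            raise ValueError(f"window [{start},{stop}) outside matrix offsets")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values[:, cols], axis=1)


def anchored_matrix(
    track: CoverageTrack,
    anchors: Sequence[Anchor],
    upstream: int,
    downstream: int,
    allow_raw: bool = False,
) -> ProfileMatrix:
    """Extract the strand-oriented signal window around every anchor.

    Requires an RPM track unless ``allow_raw`` is set (raw tracks are
    only comparable within one library).  Offsets outside the chromosome
    are NaN.
    """
    if not anchors:
        raise ValueError("anchored_matrix needs at least one anchor")
    if not track.normalized and not allow_raw:
        raise ValueError("track is not RPM-normalized; pass allow_raw=True to override")
    offsets = np.arange(-upstream, downstream)
    values = np.full((len(anchors), offsets.size), np.nan)
    for i, a in enumerate(anchors):
        arr = track.data.get(a.chrom)
        if arr is None:
            continue
        if a.strand == "+":
            idx = a.pos + offsets
        else:
            idx = a.pos - offsets
        valid = (idx >= 0) & (idx < arr.size)
        values[i, valid] = arr[idx[valid]]
    return ProfileMatrix(values, offsets, list(anchors))


def mean_profile(matrix: ProfileMatrix) -> pd.DataFrame:
    """Per-offset mean with pointwise 95% confidence band.

    Missing entries are excluded from the mean; the band is the normal
    approximation mean +/- 1.96 * sd / sqrt(n).  Offsets with no data are
    NaN throughout; offsets with a single observation get a zero-width
    band.
    """
    v = matrix.values
    n = np.sum(np.isfinite(v), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(np.isfinite(v), v, np.nan), axis=0)
        sd = np.nanstd(v, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    mean = np.where(n > 0, mean, np.nan)
    return pd.DataFrame(
        {
            "offset": matrix.offsets,
            "mean": mean,
            "lower95": mean - 1.96 * sem,
            "upper95": mean + 1.96 * sem,
            "n": n,
        }
    )


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


def _rank_order(values: np.ndarray, anchors: Sequence[Anchor]) -> np.ndarray:
    # ascending by value; ties broken deterministically by gene_id then input order
    gene_ids = np.array([a.gene_id for a in anchors])
    return np.lexsort((np.arange(len(anchors)), gene_ids, values))


def stratify(
    anchors: Sequence[Anchor],
    key: str,
    *,
    expression: Mapping[str, float] | None = None,
    signal_matrix: ProfileMatrix | None = None,
    signal_window: tuple[int, int] | None = None,
    inclusion: Mapping[tuple[str, int], float] | None = None,
) -> dict[str, list[int]]:
    """Partition anchors into ranked classes; returns class -> row indices.

    ``key='expression'``
        Genes with TPM < 0.1 are *repressed*; the remainder are split by
        expression rank into equal-size tertiles (low/medium/high).
    ``key='signal'``
        Anchors are scored by their mean signal in ``signal_window`` of
        ``signal_matrix`` (defaults: the TSS window -75..-25) and split
        into rank quartiles very_low/low/medium/high.
    ``key='inclusion'``
        Anchors are assigned the fixed PSI classes via their
        ``(gene_id, exon_index)`` inclusion fraction.

    Ties are broken by gene_id, then input order, so the partition is
    deterministic.  Returned indices refer to the ``anchors`` sequence
    (and hence to rows of any matrix built from it).
    """
    if key == "expression":
        if expression is None:
            raise ValueError("expression stratification needs an expression mapping")
        tpm = np.array([float(expression[a.gene_id]) for a in anchors])
        repressed = np.flatnonzero(tpm < REPRESSED_TPM)
        expressed = np.flatnonzero(tpm >= REPRESSED_TPM)
        out: dict[str, list[int]] = {}
        if repressed.size:
            out["repressed"] = list(repressed)
        if expressed.size == 0:
            warnings.warn("all genes repressed; expression stratification has one class")
            return out
        sub = [anchors[i] for i in expressed]
        order = expressed[_rank_order(tpm[expressed], sub)]
        for name, grp in zip(("low", "medium", "high"), np.array_split(order, 3)):
            if grp.size:
                out[name] = list(grp)
        return out

    if key == "signal":
        if signal_matrix is None:
            raise ValueError("signal stratification needs a signal_matrix")
        lo, hi = signal_window if signal_window is not None else TSS_SCORE_WINDOW
        scores = signal_matrix.window_means(lo, hi)
        if len(scores) != len(anchors):
            raise ValueError("signal_matrix rows must align with anchors")
        order = _rank_order(scores, anchors)
        return {
            name: list(grp)
            for name, grp in zip(LEVEL_CLASSES, np.array_split(order, 4))
            if grp.size
        }

    if key == "inclusion":
        if inclusion is None:
            raise ValueError("inclusion stratification needs an inclusion mapping")
        out = {}
        for i, a in enumerate(anchors):
            cls = inclusion_class(float(inclusion[(a.gene_id, a.exon_index)]))
            out.setdefault(cls, []).append(i)
        return {c: out[c] for c in INCLUSION_CLASSES if c in out}

    raise ValueError(f"unknown stratification key {key!r}")


# ---------------------------------------------------------------------------
# metagene
# ---------------------------------------------------------------------------


def metagene_scale(
    track: CoverageTrack,
    intervals: Sequence[tuple[str, int, int, str]],
    nbins: int,
    allow_raw: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Average the track over intervals rescaled to a common 0..1 axis.

    Each interval of length L is divided into ``nbins`` equal spans of
    L/nbins bases; bin j averages the track over [j*L/nbins,
    (j+1)*L/nbins) in transcript orientation, weighting partial bases by
    their fractional overlap (exact for per-base-constant tracks, via the
    interval's cumulative integral).  Every interval contributes equally
    per bin regardless of its length.

    Returns ``(bin_means, per_interval_matrix)``.
    """
    if not intervals:
        raise ValueError("metagene_scale needs at least one interval")
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    if not track.normalized and not allow_raw:
        raise ValueError("track is not RPM-normalized; pass allow_raw=True to override")
    rows = np.full((len(intervals), nbins), np.nan)
    for i, (chrom, start, end, strand) in enumerate(intervals):
        arr = track.data.get(chrom)
        if arr is None or end <= start:
            continue
        vals = arr[max(start, 0):min(end, arr.size)].astype(float)
        if vals.size != end - start:  # clipped at chromosome edge: pad missing with NaN-skip
            continue
        if strand == "-":
            vals = vals[::-1]
        L = vals.size
        cum = np.concatenate([[0.0], np.cumsum(vals)])
        edges = np.linspace(0.0, L, nbins + 1)
        base = np.floor(edges).astype(int)
        base = np.minimum(base, L)
        frac = edges - base
        # integral of the piecewise-constant track from 0 to each edge
        F = cum[base] + frac * np.where(base < L, vals[np.minimum(base, L - 1)], 0.0)
        rows[i] = np.diff(F) / (L / nbins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(rows, axis=0)
    return means, rows


# ---------------------------------------------------------------------------
# heatmap
# ---------------------------------------------------------------------------


@dataclass
class HeatmapMatrix:
    """Rank-group mean signal: ``values[g]`` is the mean row of group g."""

    values: np.ndarray
    offsets: np.ndarray
    group_sizes: np.ndarray


def heatmap(matrix: ProfileMatrix, key_values: Sequence[float],
            n_groups: int = 100) -> HeatmapMatrix:
    """Collapse ranked anchors into ``n_groups`` contiguous group-mean rows.

    Anchors are ranked by ``key_values`` in decreasing order (highest
    expression first, matching the usual heat-map layout); groups
    partition the ranked list with sizes differing by at most one, the
    earlier groups taking the remainder.  Fewer anchors than groups
    degenerate to one group per anchor.
    """
    key = np.asarray(key_values, dtype=float)
    if key.size != matrix.n_anchors:
        raise ValueError("key_values must align with matrix rows")
    n_groups = min(n_groups, matrix.n_anchors)
    order = _rank_order(key, matrix.anchors)[::-1]
    groups = np.array_split(order, n_groups)  # earlier groups take the extra anchor
    values = np.full((n_groups, matrix.offsets.size), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for g, idx in enumerate(groups):
            values[g] = np.nanmean(matrix.values[idx], axis=0)
    return HeatmapMatrix(values, matrix.offsets,
                         np.array([len(g) for g in groups]))
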