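"""RNA-IP / CLIP track processing.

A chromatin-associated-RNA library is cleaned by subtracting a matched
control library (per base, on the RPM scale, clipped at zero), profiled
around splice boundaries, and intersected with ChIP fragments to ask
what fraction of the chromatin signal lies under well-supported RNA.
The overlap threshold (default 30 reads per base) applies to *raw*
counts, since it is a read-support cutoff, not a rate.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import Anchor, GeneModel
from .coverage import CoverageTrack
from .profiles import ProfileMatrix, anchored_matrix, mean_profile, stratify

__all__ = [
    "subtract_control",
    "rnaip_boundary_profile",
    "overlap_fraction",
    "gene_regions",
    "profile_peak_offset",
]


def subtract_control(signal: CoverageTrack, control: CoverageTrack) -> CoverageTrack:
    """Per-base ``max(signal - control, 0)`` on RPM tracks.

    Both inputs must be RPM-normalized and share the same chromosome
    universe.  Negative differences are clipped to zero so the result
    remains a valid coverage track; it is everywhere <= the signal.
    """
    if not signal.normalized or not control.normalized:
        raise ValueError("subtract_control requires RPM-normalized tracks")
    if set(signal.data) != set(control.data):
        raise ValueError("signal and control tracks cover different chromosomes")
    data = {}
    for chrom, s in signal.data.items():
        c = control.data[chrom]
        if s.size != c.size:
            raise ValueError(f"chromosome {chrom}: size mismatch between signal and control")
        data[chrom] = np.maximum(s - c, 0.0)
    return CoverageTrack(data, signal.library_size, normalized=True)


def profile_peak_offset(meta: pd.DataFrame) -> int:
    """Offset of the maximum of a mean profile (NaN-safe)."""
    vals = meta["mean"].to_numpy()
    if not np.isfinite(vals).any():
        raise ValueError("profile is all-missing; no peak")
    return int(meta["offset"].to_numpy()[np.nanargmax(vals)])


def rnaip_boundary_profile(
    track: CoverageTrack,
    anchors: Sequence[Anchor],
    upstream: int = 200,
    downstream: int = 300,
    stratify_key: str | None = None,
    expression: Mapping[str, float] | None = None,
    inclusion: Mapping[tuple[str, int], float] | None = None,
):
    """Boundary-anchored mean profile of an RNA-IP track, with peak offset.

    Without stratification returns ``(meta_profile, peak_offset)`` where
    the peak offset is the profile maximum — for exon-restricted RNA this
    is the distance of the bound RNA from the boundary.  With
    ``stratify_key`` ('expression' or 'inclusion') returns a dict
    class -> (meta_profile, peak_offset).
    """
    matrix = anchored_matrix(track, anchors, upstream, downstream)
    if stratify_key is None:
        meta = mean_profile(matrix)
        return meta, profile_peak_offset(meta)
    classes = stratify(list(anchors), stratify_key,
                       expression=expression, inclusion=inclusion)
    out = {}
    for name, idx in classes.items():
        meta = mean_profile(matrix.subset(idx))
        out[name] = (meta, profile_peak_offset(meta))
    return out


def gene_regions(models: Sequence[GeneModel], promoter: int = 1000) -> list[tuple[str, int, int]]:
    """Union of gene bodies and promoters (``promoter`` bp upstream of the TSS).

    Overlapping regions are merged per chromosome.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    for m in models:
        if m.strand == "+":
            start, end = m.start - promoter, m.end
        else:
            start, end = m.start, m.end + promoter
        raw.setdefault(m.chrom, []).append((max(start, 0), end))
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted(raw):
        ivs = sorted(raw[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def overlap_fraction(
    rnaip_raw: CoverageTrack,
    chip_fragments,
    regions: Sequence[tuple[str, int, int]],
    min_cov: int = 30,
    mode: str = "base",
) -> float:
    """Fraction of ChIP signal lying under well-supported RNA-IP coverage.

    A base *qualifies* when it falls inside ``regions`` and its raw
    RNA-IP coverage is >= ``min_cov``.  In the default ``'base'`` mode
    the statistic is

        (sum over ChIP fragments of qualifying bases overlapped)
        / (sum over ChIP fragments of region bases overlapped),

    i.e. the base-level share of in-region ChIP signal covered by RNA.
    ``mode='midpoint'`` instead counts whole fragments by whether their
    midpoint base qualifies, among fragments whose midpoint is in a
    region.  Monotone non-increasing in ``min_cov`` in both modes.
    """
    if rnaip_raw.normalized:
        raise ValueError("min_cov applies to raw read counts; pass the unnormalized track")
    if not regions:
        raise ValueError("empty region set")
    from .coverage import _as_frame

    df = _as_frame(chip_fragments)
    region_mask: dict[str, np.ndarray] = {}
    for chrom, start, end in regions:
        arr = rnaip_raw.data.get(chrom)
        if arr is None:
            continue
        mask = region_mask.setdefault(chrom, np.zeros(arr.size, dtype=bool))
        mask[max(start, 0):min(end, arr.size)] = True
    if not region_mask:
        raise ValueError("no region overlaps the RNA-IP track chromosomes")

    numer = 0.0
    denom = 0.0
    for chrom, grp in df.groupby("chrom", sort=False):
        chrom = str(chrom)
        if chrom not in region_mask:
            continue
        reg = region_mask[chrom]
        qual = reg & (rnaip_raw.data[chrom] >= min_cov)
        size = reg.size
        starts = np.clip(grp["start"].to_numpy(dtype=np.int64), 0, size)
        ends = np.clip(grp["end"].to_numpy(dtype=np.int64), 0, size)
        if mode == "base":
            reg_cum = np.concatenate([[0], np.cumsum(reg)])
            qual_cum = np.concatenate([[0], np.cumsum(qual)])
            numer += float((qual_cum[ends] - qual_cum[starts]).sum())
            denom += float((reg_cum[ends] - reg_cum[starts]).sum())
        elif mode == "midpoint":
            mids = np.clip((starts + ends) // 2, 0, size - 1)
            in_region = reg[mids]
            numer += float(qual[mids][in_region].sum())
            denom += float(in_region.sum())
        else:
            raise ValueError(f"unknown overlap mode {mode!r}")
    if denom == 0:
        raise ValueError("no ChIP fragment overlaps the regions")
    return numer / denom
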