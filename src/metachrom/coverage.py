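"""Per-base fragment coverage tracks, RPM normalisation, and bedGraph I/O.

Paired-end reads are collapsed upstream into single spanning fragments
(one pair = one fragment = one library unit); here fragments are plain
half-open intervals.  Coverage at base *b* counts the fragments whose
interval contains *b*.  Tracks are dense per-chromosome float arrays —
the pipeline targets toy and simulated genomes where density is cheap —
and carry their library size so RPM normalisation (value * 1e6 /
library_size) is a recorded, one-shot state change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Fragment",
    "CoverageTrack",
    "fragments_from_pairs",
    "fragments_from_single",
    "compute_coverage",
    "normalize_rpm",
    "read_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_fragments_bed",
    "write_fragments_bed",
]

DEFAULT_MAX_FRAGMENT = 1000


@dataclass(frozen=True)
class Fragment:
    """A sequenced fragment as a half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment [{self.start},{self.end}) is empty or inverted")


class CoverageTrack:
    """Dense per-base coverage, one float array per chromosome.

    Attributes
    ----------
    data : dict[str, np.ndarray]
        Per-chromosome per-base values.
    library_size : int
        Number of fragments counted into the track.
    normalized : bool
        True once values are in RPM (reads per base per million mapped).
    """

    def __init__(self, data: Mapping[str, np.ndarray], library_size: int,
                 normalized: bool = False):
        self.data = {c: np.asarray(v, dtype=float) for c, v in data.items()}
        self.library_size = int(library_size)
        self.normalized = bool(normalized)

    @property
    def units(self) -> str:
        return "RPM" if self.normalized else "raw"

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: v.size for c, v in self.data.items()}

    def total(self) -> float:
        """Sum of all per-base values across chromosomes."""
        return float(sum(v.sum() for v in self.data.values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return (
            self.normalized == other.normalized
            and self.library_size == other.library_size
            and set(self.data) == set(other.data)
            and all(np.array_equal(self.data[c], other.data[c]) for c in self.data)
        )


def _as_frame(fragments) -> pd.DataFrame:
    """Accept a fragment DataFrame (chrom,start,end) or an iterable of Fragment."""
    if isinstance(fragments, pd.DataFrame):
        return fragments
    rows = [(f.chrom, f.start, f.end) for f in fragments]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def fragments_from_pairs(
    pairs: Iterable[tuple[tuple[str, int, int], tuple[str, int, int]]],
    max_length: int = DEFAULT_MAX_FRAGMENT,
) -> tuple[list[Fragment], int]:
    """Collapse mate-interval pairs into single spanning fragments.

    Each pair of (chrom, start, end) mate intervals yields one fragment
    from the leftmost mate start to the rightmost mate end.  Discordant
    pairs — mates on different chromosomes or spans exceeding
    ``max_length`` — are skipped and counted; returns ``(fragments,
    n_skipped)``.
    """
    fragments: list[Fragment] = []
    skipped = 0
    for (c1, s1, e1), (c2, s2, e2) in pairs:
        if c1 != c2:
            skipped += 1
            continue
        start, end = min(s1, s2), max(e1, e2)
        if end - start > max_length or end <= start:
            skipped += 1
            continue
        fragments.append(Fragment(c1, start, end))
    return fragments, skipped


def fragments_from_single(
    reads: Iterable[tuple[str, int, int, str]],
    extension: int = 150,
) -> list[Fragment]:
    """Extend single-end reads to a fixed fragment length in read orientation.

    Fallback for single-end libraries: a + strand read keeps its start
    and is extended to ``extension`` bases; a - strand read keeps its end.
    """
    fragments = []
    for chrom, start, end, strand in reads:
        if strand == "+":
            fragments.append(Fragment(chrom, start, start + extension))
        else:
            fragments.append(Fragment(chrom, max(0, end - extension), end))
    return fragments


def compute_coverage(fragments, chrom_sizes: Mapping[str, int]) -> CoverageTrack:
    """Count, at every base, the fragments whose interval contains it.

    Fragments overhanging chromosome ends are clipped (not dropped);
    fragments on chromosomes absent from ``chrom_sizes`` are skipped with
    a warning.  ``library_size`` is the number of fragments counted.
    """
    df = _as_frame(fragments)
    data = {c: np.zeros(int(n), dtype=float) for c, n in chrom_sizes.items()}
    library_size = 0
    unknown: set[str] = set()
    if len(df):
        for chrom, grp in df.groupby("chrom", sort=False):
            chrom = str(chrom)
            if chrom not in data:
                unknown.add(chrom)
                continue
            size = data[chrom].size
            starts = np.clip(grp["start"].to_numpy(dtype=np.int64), 0, size)
            ends = np.clip(grp["end"].to_numpy(dtype=np.int64), 0, size)
            keep = ends > starts
            starts, ends = starts[keep], ends[keep]
            diff = np.zeros(size + 1, dtype=float)
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, ends, -1.0)
            data[chrom] += np.cumsum(diff[:-1])
            library_size += int(keep.sum())
    if unknown:
        warnings.warn(f"skipped fragments on unknown chromosomes: {sorted(unknown)}")
    return CoverageTrack(data, library_size, normalized=False)


def normalize_rpm(track: CoverageTrack) -> CoverageTrack:
    """Rescale a raw track to RPM: value * 1e6 / library_size.

    Refuses to normalise twice and refuses an empty library, so a track's
    units are always unambiguous.
    """
    if track.normalized:
        raise ValueError("track is already RPM-normalized")
    if track.library_size <= 0:
        raise ValueError("cannot normalize a track with library_size == 0")
    data = {c: v * 1e6 / track.library_size for c, v in track.data.items()}
    return CoverageTrack(data, track.library_size, normalized=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return {str(r.chrom): int(r.size) for r in df.itertuples(index=False)}


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    """Read a fragment BED (chrom, start, end[, name]) into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_fragments_bed(fragments, path: str | Path) -> None:
    df = _as_frame(fragments)
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write maximal constant-value runs, omitting zero runs."""
    with open(path, "w") as fh:
        for chrom in track.data:
            values = track.data[chrom]
            if values.size == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [values.size]])
            for s, e in zip(starts, ends):
                v = values[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_bedgraph(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    library_size: int = 0,
    normalized: bool = False,
) -> CoverageTrack:
    """Read a sorted, non-overlapping bedGraph into a dense track.

    Bases not covered by any run are zero.  Unsorted or overlapping runs
    raise a ``ValueError`` naming the first offending line.  The library
    size and normalisation state are not recoverable from the format and
    must be supplied by the caller when they matter downstream.
    """
    data = {c: np.zeros(int(n), dtype=float) for c, n in chrom_sizes.items()}
    last: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in data:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end <= start or end > data[chrom].size:
                raise ValueError(f"{path}:{lineno}: bad interval [{start},{end})")
            if start < last.get(chrom, 0):
                raise ValueError(f"{path}:{lineno}: unsorted or overlapping interval")
            last[chrom] = end
            data[chrom][start:end] = value
    return CoverageTrack(data, library_size, normalized=normalized)
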