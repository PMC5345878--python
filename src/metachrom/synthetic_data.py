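"""Synthetic genomes, expression, ChIP/input/CLIP fragments with known truth.

The generator emulates the statistical structure the anchored analyses
assume, on a toy genome small enough to simulate in seconds:

* genes with lognormal exon lengths (median 140 bp — most mammalian
  internal exons fall between 50 and 200 bp) separated by longer introns;
* a positioned nucleosome on each exon whose amplitude is linearly
  coupled to log2(TPM + 1), with a configurable intercept and slope per
  track — positive for the activation-coupled variant track, negative
  for input and for the repression-associated control variant;
* the exonic nucleosome centred nearer the exon-intron (donor) edge, so
  the acceptor-side depleted region is the wider one, plus explicit
  multiplicative depletion dips at both splice sites;
* a promoter nucleosome at -50 bp from the TSS on the variant track and
  a +1-nucleosome exclusion dip ~225 bp downstream of the TSS;
* expression drawn from a repressed-at-zero / lognormal mixture;
* a 13.4% cassette-exon fraction with Beta-distributed inclusion,
  optionally coupled to the variant's exonic amplitude (strength kappa)
  so inclusion-stratified profiles order monotonically;
* exon-restricted chromatin-associated RNA (CLIP) reads peaking 65 bp
  inside the exon from the acceptor, with rate proportional to TPM, and
  a uniform low-rate control library.

Fragment counts are Poisson per base (centre intensity = occupancy x
depth / mean fragment length, so expected coverage ~ occupancy x depth),
centres jittered N(0, 20 bp) and lengths N(147, 15) for nucleosomal
libraries.  Everything is deterministic under the config seed, and the
:class:`SimulationTruth` record keeps enough to predict every expected
profile analytically.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .annotations import GeneModel

__all__ = [
    "TrackParams",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genome",
    "occupancy",
    "simulate_fragments",
    "simulate_clip",
    "default_tracks",
]


@dataclass(frozen=True)
class TrackParams:
    """Occupancy model of one library: amplitude = intercept + slope * log2(TPM+1).

    Exon parameters scale the positioned exonic nucleosome, intron
    parameters the flat intra-intron occupancy, TSS parameters an extra
    promoter nucleosome.  Amplitudes are clipped at zero.
    """

    exon_intercept: float
    exon_slope: float
    intron_intercept: float
    intron_slope: float
    tss_intercept: float = 0.0
    tss_slope: float = 0.0
    plus_one_exclusion: bool = False
    inclusion_coupled: bool = False


def default_tracks() -> dict[str, TrackParams]:
    """The three study libraries.

    ``variant`` gains occupancy with expression (exons faster than
    introns), sits at the TSS and is excluded from the +1 nucleosome;
    ``input`` and ``control_variant`` (the repression-associated variant)
    lose exonic occupancy as expression rises.
    """
    # negative slopes are sized so occupancy stays positive across the
    # realistic expression range (log2(TPM+1) up to ~9): nucleosomes are
    # depleted by transcription, not eliminated
    return {
        "variant": TrackParams(0.5, 0.4, 0.3, 0.1, tss_intercept=0.3, tss_slope=0.5,
                               plus_one_exclusion=True, inclusion_coupled=True),
        "input": TrackParams(2.5, -0.15, 1.2, -0.08),
        "control_variant": TrackParams(2.0, -0.18, 1.0, -0.08),
    }


@dataclass
class SimulationConfig:
    """Generator parameters; every rate and geometry knob in one place."""

    seed: int
    n_genes: int = 300
    min_exons: int = 3
    max_exons: int = 7
    exon_length_median: float = 140.0
    exon_length_sigma: float = 0.2
    exon_length_min: int = 60
    exon_length_max: int = 400
    intron_length_median: float = 650.0
    intron_length_sigma: float = 0.4
    intron_length_min: int = 300
    intron_length_max: int = 3000
    intergenic_gap: int = 2000
    chrom_margin: int = 1500
    chrom_name: str = "chrS1"
    chrom_size: int | None = None  # None: sized to fit; fixed size errors if too small

    repressed_fraction: float = 0.2
    log2_tpm_mean: float = 3.0
    log2_tpm_sd: float = 1.5

    background: float = 0.05          # intergenic occupancy floor
    nucleosome_sigma: float = 45.0    # Gaussian half-width of the exonic nucleosome
    nucleosome_center_frac: float = 0.6   # centre at this fraction of exon length from the acceptor
    ndr_depth_acceptor: float = 0.6
    ndr_depth_donor: float = 0.3
    ndr_sigma: float = 30.0
    tss_offset: int = -50             # promoter nucleosome centre relative to TSS
    tss_sigma: float = 40.0
    plus_one_offset: int = 225        # +1 exclusion dip centre downstream of TSS
    plus_one_sigma: float = 40.0
    plus_one_depth: float = 0.9

    depth: float = 60.0               # expected per-base coverage per unit occupancy
    fragment_length_mean: float = 147.0
    fragment_length_sd: float = 15.0
    fragment_length_min: int = 20
    max_fragment_length: int = 1000
    center_jitter_sd: float = 20.0

    cassette_fraction: float = 0.134
    inclusion_alpha: float = 2.0
    inclusion_beta: float = 2.0
    kappa: float = 0.0                # inclusion->variant-amplitude coupling strength

    clip_reads: int = 100_000
    clip_peak_offset: int = 65        # CLIP peak distance into the exon from the acceptor
    clip_peak_sd: float = 15.0
    clip_fragment_length_mean: float = 50.0
    clip_fragment_length_sd: float = 8.0
    clip_fragment_length_min: int = 25
    clip_control_fraction: float = 0.3

    tracks: dict[str, TrackParams] = field(default_factory=default_tracks)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name, value in (
            ("n_genes", self.n_genes),
            ("depth", self.depth),
            ("clip_reads", self.clip_reads),
            ("background", self.background),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tracks"] = {k: dataclasses.asdict(v) for k, v in self.tracks.items()}
        return d


@dataclass
class SimulationTruth:
    """Ground truth: gene models plus every parameter the analyses estimate."""

    config: SimulationConfig
    models: list[GeneModel]
    chrom_sizes: dict[str, int]
    tpm: dict[str, float]
    inclusion: dict[tuple[str, int], float]  # (gene_id, genomic exon index) -> PSI

    def expression_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tpm": [self.tpm[m.gene_id] for m in self.models]},
            index=pd.Index([m.gene_id for m in self.models], name="gene_id"),
        )

    def cassette_table(self) -> pd.DataFrame:
        rows = []
        by_id = {m.gene_id: m for m in self.models}
        for (gene_id, idx), psi in sorted(self.inclusion.items()):
            m = by_id[gene_id]
            start, end = m.exons[idx]
            rows.append((m.chrom, start, end, m.strand, gene_id, psi))
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "strand", "gene_id", "inclusion"]
        )

    def to_json(self, path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "chrom_sizes": self.chrom_sizes,
            "tpm": self.tpm,
            "inclusion": {f"{g}:{i}": v for (g, i), v in self.inclusion.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def recovery_config(
    seed: int,
    beta_exon: float = 0.4,
    beta_intron: float = 0.1,
    n_genes: int = 300,
    depth: float = 60.0,
) -> SimulationConfig:
    """Study conditions for slope-calibration (parameter-recovery) experiments.

    The occupancy gain per unit log2 expression is only identifiable from
    the ChIP/input ratio when (i) the input library is expression-flat,
    (ii) region occupancy is a plateau rather than a positioned kernel
    (so the ratio does not depend on position within the region), and
    (iii) exons and introns are long enough that coverage at interior
    offsets — fragment footprint included — comes from one region only.
    This config therefore uses plateau occupancy (nucleosome width >>
    exon length), long tight exons (median 500 bp) and introns (median
    900 bp), no TSS features, and a flat unit input.  At interior offsets
    the expected fitted slope then equals ``beta`` exactly.
    """
    tracks = {
        "chip": TrackParams(0.5, beta_exon, 0.3, beta_intron),
        "input": TrackParams(1.0, 0.0, 1.0, 0.0),
    }
    return SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        depth=depth,
        tracks=tracks,
        nucleosome_sigma=1e9,
        ndr_depth_acceptor=0.0,
        ndr_depth_donor=0.0,
        exon_length_median=500.0,
        exon_length_sigma=0.15,
        exon_length_min=420,
        exon_length_max=700,
        intron_length_median=900.0,
        intron_length_sigma=0.2,
        intron_length_min=600,
        intron_length_max=1500,
    )


#: offsets from the acceptor that are purely exonic under ``recovery_config``
#: geometry (window half-width + fragment reach + jitter stay inside the exon)
RECOVERY_EXON_OFFSETS = (180, 250)
#: offsets that are purely intronic under the same geometry
RECOVERY_INTRON_OFFSETS = (-350, -200)


# ---------------------------------------------------------------------------
# genome & expression
# ---------------------------------------------------------------------------


def _lengths(rng, n, median, sigma, lo, hi) -> np.ndarray:
    vals = rng.lognormal(mean=math.log(median), sigma=sigma, size=n)
    return np.clip(np.round(vals), lo, hi).astype(int)


def simulate_genome(config: SimulationConfig) -> SimulationTruth:
    """Lay out non-overlapping genes and draw expression and inclusion.

    Deterministic given ``config.seed``.  With a fixed ``chrom_size``
    that cannot hold the genes, raises an error stating the size needed.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng([config.seed, 0])
    models: list[GeneModel] = []
    tpm: dict[str, float] = {}
    inclusion: dict[tuple[str, int], float] = {}

    cursor = config.chrom_margin
    width = len(str(config.n_genes))
    for g in range(config.n_genes):
        gene_id = f"g{g:0{width}d}"
        n_ex = int(rng.integers(config.min_exons, config.max_exons + 1))
        ex_len = _lengths(rng, n_ex, config.exon_length_median, config.exon_length_sigma,
                          config.exon_length_min, config.exon_length_max)
        in_len = _lengths(rng, n_ex - 1, config.intron_length_median,
                          config.intron_length_sigma,
                          config.intron_length_min, config.intron_length_max)
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for i in range(n_ex):
            exons.append((pos, pos + int(ex_len[i])))
            pos += int(ex_len[i])
            if i < n_ex - 1:
                pos += int(in_len[i])
        models.append(GeneModel(gene_id, config.chrom_name, strand, tuple(exons)))
        cursor = pos + config.intergenic_gap

        if rng.random() < config.repressed_fraction:
            tpm[gene_id] = 0.0
        else:
            tpm[gene_id] = float(2.0 ** rng.normal(config.log2_tpm_mean, config.log2_tpm_sd))

        for i in range(1, n_ex - 1):  # internal exons only
            if rng.random() < config.cassette_fraction:
                inclusion[(gene_id, i)] = float(
                    rng.beta(config.inclusion_alpha, config.inclusion_beta)
                )

    needed = cursor - config.intergenic_gap + config.chrom_margin
    if config.chrom_size is not None:
        if config.chrom_size < needed:
            raise ValueError(
                f"chrom_size {config.chrom_size} too small for {config.n_genes} genes; "
                f"need at least {needed}"
            )
        size = config.chrom_size
    else:
        size = needed
    models = [m.with_expression(tpm[m.gene_id]) for m in models]
    return SimulationTruth(config, models, {config.chrom_name: int(size)}, tpm, inclusion)


# ---------------------------------------------------------------------------
# occupancy model
# ---------------------------------------------------------------------------


def _gauss(centre: float, sigma: float, lo: int, hi: int):
    """(slice, kernel) of a unit-peak Gaussian over centre +/- 3 sigma, clipped."""
    a = max(int(centre - 3 * sigma), lo)
    b = min(int(centre + 3 * sigma) + 1, hi)
    if b <= a:
        return slice(0, 0), np.empty(0)
    pos = np.arange(a, b)
    return slice(a, b), np.exp(-((pos - centre) ** 2) / (2 * sigma**2))


def occupancy(truth: SimulationTruth, track: str) -> dict[str, np.ndarray]:
    """Expected per-base occupancy lambda(b) for one track.

    Expected fragment coverage is ``depth * lambda``; this is the analytic
    reference every recovery test is checked against.  The additive
    background applies to intergenic bases only — within genes the intron
    plateau plays that role, keeping the exonic ChIP/input ratio an exact
    linear function of log2 expression.
    """
    cfg = truth.config
    try:
        p = cfg.tracks[track]
    except KeyError:
        raise KeyError(f"unknown track {track!r}; config defines {sorted(cfg.tracks)}")
    lam = {c: np.zeros(n) for c, n in truth.chrom_sizes.items()}
    genic = {c: np.zeros(n, dtype=bool) for c, n in truth.chrom_sizes.items()}

    for m in truth.models:
        arr = lam[m.chrom]
        size = arr.size
        x = math.log2(truth.tpm[m.gene_id] + 1.0)
        genic[m.chrom][m.start:m.end] = True

        exon_amp_base = max(p.exon_intercept + p.exon_slope * x, 0.0)
        intron_amp = max(p.intron_intercept + p.intron_slope * x, 0.0)
        frac = cfg.nucleosome_center_frac
        for i, (s, e) in enumerate(m.exons):
            amp = exon_amp_base
            if p.inclusion_coupled and (m.gene_id, i) in truth.inclusion:
                psi = truth.inclusion[(m.gene_id, i)]
                amp *= max(1.0 + cfg.kappa * (psi - 0.5), 0.0)
            L = e - s
            centre = s + frac * L if m.strand == "+" else e - frac * L
            if amp > 0:
                pos = np.arange(s, e)
                arr[s:e] += amp * np.exp(-((pos - centre) ** 2) / (2 * cfg.nucleosome_sigma**2))
            if i < m.n_exons - 1:
                nxt = m.exons[i + 1][0]
                arr[e:nxt] += intron_amp

        tss_amp = max(p.tss_intercept + p.tss_slope * x, 0.0)
        if tss_amp > 0:
            centre = m.tss + (cfg.tss_offset if m.strand == "+" else -cfg.tss_offset)
            sl, k = _gauss(centre, cfg.tss_sigma, 0, size)
            arr[sl] += tss_amp * k

        # multiplicative structure: splice-site depletion and +1 exclusion
        for i, (s, e) in enumerate(m.exons):
            acceptor = s if m.strand == "+" else e - 1
            donor = e - 1 if m.strand == "+" else s
            if (m.strand == "+" and i > 0) or (m.strand == "-" and i < m.n_exons - 1):
                sl, k = _gauss(acceptor, cfg.ndr_sigma, 0, size)
                arr[sl] *= 1.0 - cfg.ndr_depth_acceptor * k
            if (m.strand == "+" and i < m.n_exons - 1) or (m.strand == "-" and i > 0):
                sl, k = _gauss(donor, cfg.ndr_sigma, 0, size)
                arr[sl] *= 1.0 - cfg.ndr_depth_donor * k
        if p.plus_one_exclusion:
            centre = m.tss + (cfg.plus_one_offset if m.strand == "+" else -cfg.plus_one_offset)
            sl, k = _gauss(centre, cfg.plus_one_sigma, 0, size)
            arr[sl] *= 1.0 - cfg.plus_one_depth * k

    for chrom in lam:
        lam[chrom][~genic[chrom]] += cfg.background
    return lam


# ---------------------------------------------------------------------------
# fragment sampling
# ---------------------------------------------------------------------------

_TRACK_SEED = 10  # stage offsets keeping per-track streams independent
_CLIP_SEED = 1000


def _sample_fragments(rng, lam: Mapping[str, np.ndarray], depth: float,
                      len_mean: float, len_sd: float, len_min: int, len_max: int,
                      jitter_sd: float) -> pd.DataFrame:
    frames = []
    for chrom in sorted(lam):
        rate = lam[chrom] * depth / len_mean
        counts = rng.poisson(rate)
        n = int(counts.sum())
        if n == 0:
            continue
        centres = np.repeat(np.arange(lam[chrom].size), counts).astype(float)
        centres += rng.normal(0.0, jitter_sd, size=n)
        lengths = np.clip(np.round(rng.normal(len_mean, len_sd, size=n)), len_min, len_max)
        starts = np.round(centres - lengths / 2).astype(np.int64)
        ends = starts + lengths.astype(np.int64)
        starts = np.clip(starts, 0, lam[chrom].size)
        ends = np.clip(ends, 0, lam[chrom].size)
        keep = ends > starts
        frames.append(pd.DataFrame(
            {"chrom": chrom, "start": starts[keep], "end": ends[keep]}
        ))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def simulate_fragments(truth: SimulationTruth, track: str,
                       depth: float | None = None) -> pd.DataFrame:
    """Draw sequenced fragments for one track as a (chrom, start, end) frame.

    Per-base fragment-centre counts are Poisson with intensity
    ``occupancy * depth / mean_length`` so that expected coverage equals
    ``occupancy * depth``; centres are jittered and lengths normal.
    Deterministic given the config seed and track name.
    """
    cfg = truth.config
    lam = occupancy(truth, track)
    if all(a.max() == 0 for a in lam.values()):
        import warnings

        warnings.warn(f"track {track!r}: occupancy is zero everywhere; empty library")
    track_index = sorted(cfg.tracks).index(track)
    rng = np.random.default_rng([cfg.seed, _TRACK_SEED + track_index])
    return _sample_fragments(
        rng, lam, cfg.depth if depth is None else depth,
        cfg.fragment_length_mean, cfg.fragment_length_sd,
        cfg.fragment_length_min, cfg.max_fragment_length, cfg.center_jitter_sd,
    )


def simulate_clip(truth: SimulationTruth,
                  n_reads: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exon-restricted chromatin-RNA reads plus a uniform control library.

    Signal reads land on internal exons with per-exon rate proportional
    to host TPM; each read centre sits ``clip_peak_offset`` bp into the
    exon from the acceptor (Gaussian spread, clipped inside the exon) and
    the read interval is truncated at the exon edges — the captured RNA
    is spliced, so it maps exonically.  The control is a uniform
    low-rate background over the whole genome.
    """
    cfg = truth.config
    if n_reads is None:
        n_reads = cfg.clip_reads
    rng = np.random.default_rng([cfg.seed, _CLIP_SEED])

    exons = []  # (chrom, strand, start, end, tpm)
    for m in truth.models:
        for i in range(1, m.n_exons - 1):
            s, e = m.exons[i]
            exons.append((m.chrom, m.strand, s, e, truth.tpm[m.gene_id]))
    weights = np.array([t for *_, t in exons], dtype=float)
    total = weights.sum()
    rows = []
    if total > 0 and n_reads > 0:
        expected = n_reads * weights / total
        counts = rng.poisson(expected)
        for (chrom, strand, s, e, _), k in zip(exons, counts):
            if k == 0:
                continue
            L = e - s
            offs = np.clip(
                rng.normal(cfg.clip_peak_offset, cfg.clip_peak_sd, size=k), 1, L - 1
            )
            centres = s + offs if strand == "+" else e - offs
            lengths = np.clip(
                np.round(rng.normal(cfg.clip_fragment_length_mean,
                                    cfg.clip_fragment_length_sd, size=k)),
                cfg.clip_fragment_length_min, None,
            )
            starts = np.clip(np.round(centres - lengths / 2), s, e).astype(np.int64)
            ends = np.clip(starts + lengths.astype(np.int64), s, e)
            keep = ends > starts
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts[keep], "end": ends[keep]}))
    signal = (pd.concat(rows, ignore_index=True)
              if rows else pd.DataFrame(columns=["chrom", "start", "end"]))

    ctrl_rng = np.random.default_rng([cfg.seed, _CLIP_SEED + 1])
    frames = []
    n_ctrl = int(round(n_reads * cfg.clip_control_fraction))
    sizes = truth.chrom_sizes
    total_size = sum(sizes.values())
    for chrom in sorted(sizes):
        k = int(round(n_ctrl * sizes[chrom] / total_size))
        if k == 0:
            continue
        centres = ctrl_rng.uniform(0, sizes[chrom], size=k)
        lengths = np.clip(
            np.round(ctrl_rng.normal(cfg.clip_fragment_length_mean,
                                     cfg.clip_fragment_length_sd, size=k)),
            cfg.clip_fragment_length_min, None,
        )
        starts = np.clip(np.round(centres - lengths / 2), 0, sizes[chrom]).astype(np.int64)
        ends = np.clip(starts + lengths.astype(np.int64), 0, sizes[chrom])
        keep = ends > starts
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts[keep], "end": ends[keep]}))
    control = (pd.concat(frames, ignore_index=True)
               if frames else pd.DataFrame(columns=["chrom", "start", "end"]))
    return signal, control
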