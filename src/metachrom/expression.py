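"""Expression quantification utilities and the qChIP 2^-ddCt calculator.

TPM (transcripts per million) is the length-normalised expression unit
used for all stratifications; gene-family pool fractions summarise how
much of a histone family's transcript output a subtype accounts for;
expression ratios compare two tissues gene by gene; and the 2^-ddCt
formula converts quantitative-ChIP cycle thresholds into fold
enrichments relative to a reference amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

__all__ = [
    "tpm",
    "pool_fraction",
    "expression_ratio",
    "CtReplicate",
    "QchipMeasurement",
    "DdctResult",
    "ddct",
    "read_expression_table",
    "write_expression_table",
]

RATIO_PSEUDOCOUNT = 0.01


def tpm(counts: Mapping[str, float], lengths: Mapping[str, float]) -> pd.DataFrame:
    """Length-normalised expression: TPM_g = 1e6 * (c_g/l_g) / sum_h (c_h/l_h).

    Returns a frame indexed by gene_id with columns count, length, tpm;
    the tpm column sums to 1e6.  All-zero counts are an error, as are
    non-positive lengths.
    """
    genes = list(counts)
    c = np.array([float(counts[g]) for g in genes])
    l = np.array([float(lengths[g]) for g in genes])
    if (l <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    rate = c / l
    total = rate.sum()
    if total == 0:
        raise ValueError("all counts are zero; TPM undefined")
    return pd.DataFrame(
        {"count": c, "length": l, "tpm": 1e6 * rate / total},
        index=pd.Index(genes, name="gene_id"),
    )


def _tpm_series(table) -> pd.Series:
    if isinstance(table, pd.DataFrame):
        return table["tpm"]
    return pd.Series(dict(table), dtype=float)


def pool_fraction(table, family_map: Mapping[str, str]) -> pd.DataFrame:
    """Share of a gene family's TPM pool per subtype.

    ``family_map`` assigns family genes to subtypes; genes outside the
    map are ignored.  Returns per subtype the percent of the family TPM
    total (summing to 100) and the mean TPM over that subtype's genes.
    """
    if not family_map:
        raise ValueError("family_map is empty")
    tpms = _tpm_series(table)
    rows: dict[str, list[float]] = {}
    for gene, subtype in family_map.items():
        if gene not in tpms.index:
            raise KeyError(f"family gene {gene!r} missing from expression table")
        rows.setdefault(subtype, []).append(float(tpms[gene]))
    family_total = sum(sum(v) for v in rows.values())
    if family_total == 0:
        raise ValueError("family TPM total is zero")
    return pd.DataFrame(
        {
            "percent": {s: 100.0 * sum(v) / family_total for s, v in rows.items()},
            "mean_tpm": {s: float(np.mean(v)) for s, v in rows.items()},
            "n_genes": {s: len(v) for s, v in rows.items()},
        }
    ).rename_axis("subtype")


def expression_ratio(
    table_a,
    table_b,
    genes: Sequence[str],
    pseudocount: float = RATIO_PSEUDOCOUNT,
) -> dict[str, float]:
    """Per-gene expression ratio (TPM_A + eps) / (TPM_B + eps).

    The pseudocount keeps the ratio defined when a gene is silent in one
    tissue; two silent genes give exactly 1.0 by construction.  A gene
    missing from either table raises an error naming it.
    """
    a = _tpm_series(table_a)
    b = _tpm_series(table_b)
    out = {}
    for g in genes:
        if g not in a.index:
            raise KeyError(f"gene {g!r} missing from table A")
        if g not in b.index:
            raise KeyError(f"gene {g!r} missing from table B")
        out[g] = (float(a[g]) + pseudocount) / (float(b[g]) + pseudocount)
    return out


@dataclass(frozen=True)
class CtReplicate:
    """One qPCR replicate: IP and input Cts for target and reference amplicons."""

    ct_ip: float
    ct_input: float
    ct_ip_ref: float
    ct_input_ref: float

    def ddct(self) -> float:
        for v in (self.ct_ip, self.ct_input, self.ct_ip_ref, self.ct_input_ref):
            if not math.isfinite(v):
                raise ValueError("Ct values must be finite")
        return (self.ct_ip - self.ct_input) - (self.ct_ip_ref - self.ct_input_ref)


@dataclass(frozen=True)
class QchipMeasurement:
    target_id: str
    replicates: tuple[CtReplicate, ...]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError(f"{self.target_id}: at least one replicate required")


@dataclass(frozen=True)
class DdctResult:
    target_id: str
    enrichment: float          # mean of per-replicate 2^-ddCt
    sd: float | None           # across replicates, reported when >= 3
    per_replicate: tuple[float, ...]


def ddct(measurement: QchipMeasurement) -> DdctResult:
    """Relative qChIP enrichment 2^-ddCt, averaged over replicates.

    ddCt = (Ct_ip - Ct_input)_target - (Ct_ip - Ct_input)_reference;
    enrichment = 2^-ddCt per replicate, mean across replicates, with a
    standard deviation once three replicates are available.  Invariant
    under adding a constant to all four Cts of a replicate.
    """
    folds = tuple(2.0 ** (-r.ddct()) for r in measurement.replicates)
    sd = float(np.std(folds, ddof=1)) if len(folds) >= 3 else None
    return DdctResult(measurement.target_id, float(np.mean(folds)), sd, folds)


def read_expression_table(path) -> pd.DataFrame:
    """Read a gene expression TSV with at least gene_id and tpm columns."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "tpm" not in df.columns:
        raise ValueError(f"{path}: expression table needs gene_id and tpm columns")
    return df.set_index("gene_id")


def write_expression_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=True, float_format="%.8g")
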