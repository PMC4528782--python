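"""Molecule counting, normalization and technical-noise quantification.

Counting unique barcode clusters (molecules) instead of raw reads removes the
variation injected by stochastic PCR amplification; the residual noise of
barcode counts approaches the Poisson sampling limit CV = 1/sqrt(mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: MoleculeTable column order
MOLECULE_COLUMNS = ["amplicon_id", "replicate_id", "barcode_count", "read_count"]


def molecule_table(rows: Iterable[tuple[str, str, int, int]]) -> pd.DataFrame:
    """Build a molecule table from (amplicon_id, replicate_id, barcode_count,
    read_count) rows and validate its invariants."""
    df = pd.DataFrame(rows, columns=MOLECULE_COLUMNS)
    if (df["barcode_count"] > df["read_count"]).any():
        raise ValueError("barcode_count exceeds read_count")
    if (df[["barcode_count", "read_count"]] < 0).any().any():
        raise ValueError("counts must be non-negative")
    return df


def amplicons_in_all_replicates(table: pd.DataFrame, basis: str = "barcode") -> list[str]:
    """Amplicon ids with a positive count in every replicate (the restriction
    applied before normalization and correlation)."""
    col = f"{basis}_count"
    n_reps = table["replicate_id"].nunique()
    pos = table[table[col] > 0]
    counts = pos.groupby("amplicon_id")["replicate_id"].nunique()
    return sorted(counts[counts == n_reps].index)


def normalize_log2(counts: Sequence[float] | np.ndarray | pd.Series,
                   target_mean: float = 10_000.0) -> np.ndarray:
    """Scale counts to a mean of ``target_mean`` and log2-transform.

    Counts must be strictly positive (apply the all-replicates restriction
    first); the post-scaling mean equals ``target_mean`` exactly, so no
    pseudocount is needed.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        return x
    if (x <= 0).any():
        raise ValueError("normalize_log2 requires strictly positive counts")
    return np.log2(x * (target_mean / x.mean()))


@dataclass
class NoiseSummary:
    """Per-amplicon technical noise against the Poisson limit."""

    table: pd.DataFrame  # amplicon_id, basis, mean, cv, poisson_cv
    basis: str


def cv_by_amplicon(table: pd.DataFrame, basis: str = "barcode",
                   ddof: int = 1) -> NoiseSummary:
    """Coefficient of variation of raw (un-normalized) counts across
    replicates, per amplicon, with the theoretical Poisson CV attached.

    CV = sample standard deviation (``ddof=1``) / mean; replicates should be
    downsampled to equal read totals first (see :func:`downsample_reads`).
    Amplicons with mean 0 get CV = NaN and are flagged.
    """
    if basis not in ("barcode", "read"):
        raise ValueError("basis must be 'barcode' or 'read'")
    col = f"{basis}_count"
    n_reps = table.groupby("amplicon_id")["replicate_id"].nunique()
    if (n_reps < 2).any():
        raise ValueError("cv_by_amplicon requires >= 2 replicates per amplicon")
    g = table.groupby("amplicon_id")[col]
    mean = g.mean()
    sd = g.std(ddof=ddof)
    out = pd.DataFrame(
        {
            "amplicon_id": mean.index,
            "basis": basis,
            "mean": mean.values,
            "cv": np.where(mean.values > 0, sd.values / np.where(mean.values > 0, mean.values, 1), np.nan),
            "poisson_cv": np.where(mean.values > 0, 1.0 / np.sqrt(np.where(mean.values > 0, mean.values, 1)), np.nan),
        }
    ).reset_index(drop=True)
    return NoiseSummary(table=out, basis=basis)


def poisson_cv(mean: float) -> float:
    """Theoretical sampling-limit CV of a count with the given mean."""
    if mean <= 0:
        raise ValueError("poisson_cv defined only for mean > 0")
    return 1.0 / np.sqrt(mean)


def downsample_reads(reads: Sequence, target_total: int, seed: int) -> list:
    """Uniform sampling of reads without replacement, reproducible by seed.

    Used to equalize replicate totals (to the minimum across replicates)
    before CV calculation, removing sequencer-loading variability.  Input
    order is preserved.
    """
    n = len(reads)
    if target_total > n:
        raise ValueError(f"target_total {target_total} exceeds total {n}")
    if target_total == n:
        return list(reads)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=target_total, replace=False))
    return [reads[i] for i in keep]
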