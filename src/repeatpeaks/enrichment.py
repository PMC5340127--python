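"""The Monte-Carlo enrichment statistic and its tabular report.

For each repeat family (or element) the observed summit-window overlap count
is compared with the empirical null from matched random sets.  With null
mean m and sample standard deviation s the Z-score is computed on whichever
side the observation falls:

    observed <= m:  z = (observed - m) / s
    observed >  m:  z = (m - observed) / s

so z <= 0 always, and the one-tailed p-value is the standard normal CDF
Phi(z) (<= 0.5; never doubled).  The tail's sign is carried separately as a
direction flag: '+' for enrichment (observed above the null mean), '-' for
under-representation, 'none' at equality.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from repeatpeaks.genomic_io import Genome, Peak, RepeatFeature
from repeatpeaks.interval_engine import RepeatIndex, make_summit_windows, windows_to_arrays
from repeatpeaks.null_model import RandomSetConfig, generate_null_counts

__all__ = [
    "EnrichmentRecord",
    "summarize_null",
    "overlap_zscore",
    "enrichment_table",
    "write_enrichment_tsv",
]

#: below this, p-values render as "0" in reports (stored values keep the float)
P_DISPLAY_FLOOR = 1e-300


@dataclass(frozen=True)
class EnrichmentRecord:
    """One report row: a repeat key with its observed count, null and test."""

    key: str
    granularity: str
    observed: int
    null_mean: float
    null_sd: float
    z: float
    p: float
    direction: str
    bh_q: float | None = None


def summarize_null(null_vector: Sequence[int] | np.ndarray) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of a null count vector."""
    vec = np.asarray(null_vector, dtype=float)
    if vec.ndim != 1 or vec.size < 2:
        raise ValueError("null vector must be 1-D with length >= 2")
    return float(vec.mean()), float(vec.std(ddof=1))


def overlap_zscore(
    observed: float, null_mean: float, null_sd: float
) -> tuple[float, float, str]:
    """Asymmetric Z-score, one-tailed normal p, and direction flag.

    Degenerate null (sd = 0): equality gives (0, 0.5, 'none'); any deviation
    gives z = -inf, p = 0 with the appropriate direction and a warning,
    since the null carries no variance to scale the deviation.
    """
    if null_sd < 0:
        raise ValueError("null_sd must be nonnegative")
    delta = observed - null_mean
    if delta > 0:
        direction = "+"
    elif delta < 0:
        direction = "-"
    else:
        direction = "none"
    if null_sd == 0:
        if direction == "none":
            return 0.0, 0.5, direction
        warnings.warn(
            "null standard deviation is 0 with observed != null mean; "
            "z set to -inf",
            stacklevel=2,
        )
        return float("-inf"), 0.0, direction
    z = -abs(delta) / null_sd
    p = float(norm.cdf(z))
    return z, p, direction


def enrichment_table(
    peaks: Sequence[Peak],
    repeats: Sequence[RepeatFeature],
    genome: Genome,
    width: int = 100,
    n_sets: int = 500,
    seed: int = 0,
    by: str = "family",
    mode: str = "pairs",
    bh: bool = False,
) -> list[EnrichmentRecord]:
    """Run the full enrichment pipeline and return the report rows.

    Pipeline: summit windows (width bp) -> observed grouped overlap counts ->
    matched random sets (n_sets, same count and length multiset) -> per-key
    null mean/sd -> Z, p, direction.  Rows are sorted by p ascending (ties by
    key for stable output); keys with zero observed count and an all-zero
    null are dropped, but zero-observed keys with nonzero null are kept as
    depletion evidence.  Optional Benjamini-Hochberg q-values are appended
    when ``bh`` is set; the primary report is uncorrected one-tailed p.
    """
    windows = make_summit_windows(peaks, genome, width=width)
    index = RepeatIndex(repeats, by=by)
    observed = index.count(windows_to_arrays(windows), mode=mode)
    config = RandomSetConfig.from_windows(windows, genome, n_sets=n_sets, seed=seed)
    null = generate_null_counts(windows, repeats, config, by=by, mode=mode)

    records = []
    for key in index.keys:
        obs = observed[key]
        vec = null[key]
        if obs == 0 and not vec.any():
            continue
        mean, sd = summarize_null(vec)
        z, p, direction = overlap_zscore(obs, mean, sd)
        records.append(
            EnrichmentRecord(
                key=key,
                granularity=by,
                observed=int(obs),
                null_mean=mean,
                null_sd=sd,
                z=z,
                p=p,
                direction=direction,
            )
        )
    records.sort(key=lambda r: (r.p, r.key))
    if bh and records:
        q = multipletests([r.p for r in records], method="fdr_bh")[1]
        records = [
            EnrichmentRecord(
                key=r.key, granularity=r.granularity, observed=r.observed,
                null_mean=r.null_mean, null_sd=r.null_sd, z=r.z, p=r.p,
                direction=r.direction, bh_q=float(qi),
            )
            for r, qi in zip(records, q)
        ]
    return records


def _format_p(p: float) -> str:
    if p < P_DISPLAY_FLOOR:
        return "0"
    return format(p, ".6g")


def write_enrichment_tsv(records: Sequence[EnrichmentRecord], path: str | Path) -> None:
    """Write the report as TSV; p-values below 1e-300 render as "0"."""
    has_q = any(r.bh_q is not None for r in records)
    columns = ["key", "granularity", "observed", "null_mean", "null_sd",
               "z", "direction", "p"] + (["q"] if has_q else [])
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in records:
            z_str = "-inf" if math.isinf(r.z) else format(r.z, ".6g")
            row = [
                r.key, r.granularity, str(r.observed),
                format(r.null_mean, ".6g"), format(r.null_sd, ".6g"),
                z_str, r.direction, _format_p(r.p),
            ]
            if has_q:
                row.append(_format_p(r.bh_q) if r.bh_q is not None else ".")
            fh.write("\t".join(row) + "\n")
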