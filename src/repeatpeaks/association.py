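"""DEG filtering and peak-to-gene linkage.

Expression tables are plain pandas DataFrames with columns ``gene_id``,
``fold_change`` (treatment/control ratio), optional ``p_raw`` / ``p_adj``,
and any number of per-sample FPKM columns prefixed ``fpkm_``.

Two filter modes mirror the two knockdown designs they summarise:

* ``adj_p_fc`` — BH-adjusted p below a threshold AND fold change beyond a
  ratio threshold (used when replicate designs give a usable p-value).
* ``fpkm_fc`` — expressed at >= 1 FPKM in at least one sample AND fold
  change beyond the threshold (used when only a single design was
  effective and no adjusted p is trusted).

Fold change is a ratio; "beyond 1.5x" is tested on max(fc, 1/fc) so a
>1.5-fold drop qualifies symmetrically with a >1.5-fold rise, strictly
(fc == 1.5 exactly is excluded).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from repeatpeaks.genomic_io import Peak

__all__ = [
    "filter_degs",
    "bh_adjust",
    "link_peaks_to_degs",
    "read_expression_table",
    "direction_of",
]


def fpkm_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("fpkm_")]


def direction_of(fold_change: float) -> str:
    return "up" if fold_change > 1.0 else "down"


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def filter_degs(
    records: pd.DataFrame,
    mode: str = "adj_p_fc",
    p_thresh: float = 0.05,
    fc_thresh: float = 1.5,
    fpkm_min: float = 1.0,
) -> pd.DataFrame:
    """Apply a DEG filter; returns the surviving rows with a direction column.

    ``adj_p_fc``: p_adj < p_thresh AND max(fc, 1/fc) > fc_thresh.  When the
    table has no ``p_adj`` column, it is computed from ``p_raw`` by BH
    step-up; with neither, this mode errors.

    ``fpkm_fc``: max FPKM across samples >= fpkm_min AND max(fc, 1/fc) >
    fc_thresh.
    """
    if mode not in ("adj_p_fc", "fpkm_fc"):
        raise ValueError(f"unknown DEG filter mode {mode!r}")
    table = records.copy()
    ratio = np.maximum(table["fold_change"], 1.0 / table["fold_change"])
    fc_pass = ratio > fc_thresh

    if mode == "adj_p_fc":
        if "p_adj" not in table.columns:
            if "p_raw" not in table.columns:
                raise ValueError("adj_p_fc mode needs a p_adj or p_raw column")
            table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
        keep = (table["p_adj"] < p_thresh) & fc_pass
    else:
        cols = fpkm_columns(table)
        if not cols:
            raise ValueError("fpkm_fc mode needs at least one fpkm_* column")
        keep = (table[cols].max(axis=1) >= fpkm_min) & fc_pass

    out = table.loc[keep].copy()
    out["direction"] = [direction_of(fc) for fc in out["fold_change"]]
    return out


def link_peaks_to_degs(
    degs: pd.DataFrame,
    peaks: Sequence[Peak],
    tss: pd.DataFrame,
    threshold: int = 5000,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Link each DEG to its nearest peak by summit-TSS distance.

    ``tss`` maps gene_id -> (chrom, position); DEGs without a TSS entry are
    dropped with a warning.  Each DEG is classified within/beyond the
    threshold (default 5 kb) and tallied by expression direction.  With no
    peaks on a gene's chromosome the distance is NaN and the gene is beyond.

    Returns (per-gene link table, tally dict with keys up_within,
    down_within, up_beyond, down_beyond).
    """
    tss_map = {
        str(row.gene_id): (str(row.chrom), int(row.position))
        for row in tss.itertuples(index=False)
    }
    summits_by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    grouped: dict[str, list[tuple[int, str]]] = {}
    for i, p in enumerate(peaks):
        grouped.setdefault(p.chrom, []).append((p.summit, p.label or f"peak_{i}"))
    for chrom, items in grouped.items():
        items.sort()
        summits_by_chrom[chrom] = (
            np.asarray([s for s, _ in items], dtype=np.int64),
            [lab for _, lab in items],
        )

    rows = []
    tally = {"up_within": 0, "down_within": 0, "up_beyond": 0, "down_beyond": 0}
    missing = []
    for row in degs.itertuples(index=False):
        gene = str(row.gene_id)
        if gene not in tss_map:
            missing.append(gene)
            continue
        chrom, pos = tss_map[gene]
        direction = getattr(row, "direction", None) or direction_of(row.fold_change)
        entry = summits_by_chrom.get(chrom)
        if entry is None:
            dist, label, within = np.nan, "", False
        else:
            summits, labels = entry
            j = int(np.searchsorted(summits, pos))
            best, best_dist = None, None
            for k in (j - 1, j):
                if 0 <= k < len(summits):
                    d = abs(int(summits[k]) - pos)
                    if best_dist is None or d < best_dist:
                        best, best_dist = k, d
            dist, label = best_dist, labels[best]
            within = dist <= threshold
        rows.append(
            {
                "gene_id": gene,
                "nearest_peak": label,
                "distance": dist,
                "proximity": "within" if within else "beyond",
                "direction": direction,
            }
        )
        tally[f"{direction}_{'within' if within else 'beyond'}"] += 1
    if missing:
        warnings.warn(
            f"{len(missing)} DEG(s) without a TSS entry excluded: {missing[:5]}",
            stacklevel=2,
        )
    links = pd.DataFrame(
        rows, columns=["gene_id", "nearest_peak", "distance", "proximity", "direction"]
    )
    return links, tally


def read_expression_table(path) -> pd.DataFrame:
    """Read a TSV expression table (gene_id, fold_change, p columns, fpkm_*)."""
    table = pd.read_csv(path, sep="\t")
    if "gene_id" not in table.columns or "fold_change" not in table.columns:
        raise ValueError(f"{path}: expression table needs gene_id and fold_change columns")
    if (table["fold_change"] <= 0).any():
        raise ValueError(f"{path}: fold_change must be positive (a ratio)")
    return table
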