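"""Normalized delivery: input-corrected barcode proportions per sample.

For a sorted-cell sample with raw counts c_i over N barcodes, the
within-sample proportion is p_i = c_i / sum_j c_j. Because the injected pool
is not perfectly uniform, p_i is corrected by the barcode's proportion q_i
in the sequenced input pool: d_i = (p_i / q_i) / sum_j (p_j / q_j). Columns
are rescaled to sum to 1 so values are comparable across samples. A
configurable pseudocount (default 0.5, applied to both sample and input
counts) keeps zero-count barcodes finite; setting it to 0 demands strictly
positive input counts.

The normalization order (within-sample proportion, then input ratio, then
rescale) is isolated in :func:`normalized_delivery` so alternative readings
can be swapped in one place.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import CountsTable


def normalized_delivery(
    counts: CountsTable,
    input_counts: CountsTable,
    pseudocount: float = 0.5,
) -> pd.Series:
    """One sample column of the delivery matrix (sums to 1).

    Raises if a barcode present in the sample has zero input count and no
    pseudocount is in effect (the input ratio would be undefined).
    """
    c = counts.counts["raw_reads"].astype(float)
    c_in = input_counts.counts["raw_reads"].reindex(c.index)
    if c_in.isna().any():
        missing = list(c.index[c_in.isna()])
        raise ValueError(f"input sample lacks barcodes: {missing}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0:
        zero_in = list(c.index[(c_in == 0) & (c > 0)])
        if zero_in:
            raise ValueError(
                "zero input count with no pseudocount for barcodes: "
                f"{zero_in}"
            )
    c = c + pseudocount
    c_in = c_in.astype(float) + pseudocount
    p = c / c.sum()
    q = c_in / c_in.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p / q
    ratio = ratio.fillna(0.0)
    total = ratio.sum()
    if total == 0:
        raise ValueError(f"sample {counts.sample_id} has no usable counts")
    d = ratio / total
    d.name = counts.sample_id
    return d


@dataclass
class DeliveryMatrix:
    """Normalized delivery per barcode (rows) per sample (columns)."""

    values: pd.DataFrame
    input_proportions: pd.Series

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"sample columns must sum to 1, got {dict(sums)}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def write_tsv(self, path: str | Path) -> None:
        self.values.rename_axis("barcode_id").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path,
                 input_proportions: pd.Series | None = None) -> "DeliveryMatrix":
        values = pd.read_csv(path, sep="\t", comment="#", index_col="barcode_id")
        if input_proportions is None:
            input_proportions = pd.Series(np.nan, index=values.index)
        return cls(values=values, input_proportions=input_proportions)


def build_delivery_matrix(
    sample_tables: Sequence[CountsTable],
    input_table: CountsTable,
    pseudocount: float = 0.5,
) -> DeliveryMatrix:
    cols = [normalized_delivery(t, input_table, pseudocount) for t in sample_tables]
    values = pd.concat(cols, axis=1)
    c_in = input_table.counts["raw_reads"].astype(float) + pseudocount
    return DeliveryMatrix(values=values, input_proportions=c_in / c_in.sum())


def aggregate_and_rank(
    matrix: DeliveryMatrix | pd.DataFrame,
    grouping: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean normalized delivery per group and within-group ranks.

    ``grouping`` maps sample id -> group label; by default all samples form
    one ``all`` group (delivery "averaged across all samples"). Ranks are
    1 = highest delivery, a permutation of 1..N per group; ties break
    deterministically by barcode id.
    """
    values = matrix.values if isinstance(matrix, DeliveryMatrix) else matrix
    if grouping is None:
        grouping = {s: "all" for s in values.columns}
    unmapped = [s for s in values.columns if s not in grouping]
    if unmapped:
        raise ValueError(f"samples not mapped to a group: {unmapped}")
    groups: dict[str, list[str]] = {}
    for sample, group in grouping.items():
        if sample in values.columns:
            groups.setdefault(group, []).append(sample)
    empty = [g for g, ss in groups.items() if not ss]
    if not groups or empty:
        raise ValueError(f"empty groups: {empty or 'no groups at all'}")
    aggregates = pd.DataFrame(
        {g: values[ss].mean(axis=1) for g, ss in groups.items()}
    )
    ranks = pd.DataFrame(index=aggregates.index, columns=aggregates.columns,
                         dtype=int)
    for g in aggregates.columns:
        order = sorted(
            aggregates.index, key=lambda b: (-aggregates.at[b, g], b)
        )
        ranks[g] = pd.Series(
            {b: i + 1 for i, b in enumerate(order)}
        ).reindex(aggregates.index)
    return aggregates, ranks


def control_check(
    aggregates: pd.DataFrame,
    control_barcode_id: str,
) -> pd.DataFrame:
    """Negative-control sanity check per group.

    The naked, unencapsulated barcode should show the lowest normalized
    delivery (free DNA does not readily enter cells). Reports, per group,
    whether the control is strictly the minimum and the ratio of the
    next-lowest barcode's delivery to the control's (> 1 when the check
    holds, with margin).
    """
    if control_barcode_id not in aggregates.index:
        raise KeyError(f"control barcode {control_barcode_id!r} not in matrix")
    rows = []
    others = aggregates.drop(index=control_barcode_id)
    for g in aggregates.columns:
        ctrl = aggregates.at[control_barcode_id, g]
        next_lowest = others[g].min()
        rows.append(
            {
                "group": g,
                "control_delivery": ctrl,
                "next_lowest": next_lowest,
                "is_lowest": bool(ctrl < next_lowest),
                "margin_ratio": (next_lowest / ctrl) if ctrl > 0 else np.inf,
            }
        )
    return pd.DataFrame(rows)
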