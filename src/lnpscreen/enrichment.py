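"""Component-level fold enrichment over the best and worst LNP deciles.

The structure–function statistic of a pooled screen: rank the screened LNPs
by aggregate normalized delivery, take the top and bottom 10% (k =
round-half-up of 0.10·N, floor 1), and for each level of a component axis
(ionizable lipid, cholesterol variant, PEG-lipid, molar ratio) compare the
level's frequency inside the decile with its frequency in the whole screened
library:

    fold = observed_fraction_in_decile / expected_fraction_in_library

fold > 1 means the component is over-represented among the best (or worst)
particles relative to random chance. The default statistic is this ratio of
fractions; an odds-ratio variant (odds in decile vs odds in library) is also
exposed. Expected fractions always use the screened (QC-passing) library,
and the unencapsulated control barcode is excluded from ranking. Bootstrap
intervals come from resampling sample columns with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .library import COMPONENT_AXES, Formulation
from .quantify import aggregate_and_rank


def decile_size(n: int, fraction: float = 0.10) -> int:
    """Round-half-up decile size with a floor of one LNP (65 → 7)."""
    if not 0 < fraction <= 0.5:
        raise ValueError(f"fraction must be in (0, 0.5], got {fraction}")
    return max(1, int(np.floor(n * fraction + 0.5)))


def decile_members(
    ranks: pd.Series,
    fraction: float = 0.10,
    direction: str = "top",
) -> list[str]:
    """Ids of the best- (or worst-) ranked k LNPs; rank 1 is the best."""
    if direction not in ("top", "bottom"):
        raise ValueError(f"direction must be 'top' or 'bottom', got {direction!r}")
    k = decile_size(len(ranks), fraction)
    ordered = ranks.sort_values(ascending=(direction == "top")).index
    return list(ordered[:k])


@dataclass(frozen=True)
class EnrichmentResult:
    component_axis: str
    level: str
    direction: str
    k: int
    observed_fraction: float
    expected_fraction: float
    fold: float
    resample_interval: tuple[float, float] | None = None


def fold_enrichment(
    members: Iterable[str],
    library: Sequence[Formulation],
    axis: str,
    level: str,
    direction: str = "top",
    statistic: str = "ratio",
) -> EnrichmentResult:
    """Enrichment of one component level within a decile.

    ``members`` are lnp_ids (or barcode_ids) of the decile; ``library`` is the
    screened library defining expected fractions. ``statistic`` selects the
    ratio of fractions (default) or the odds ratio. An expected fraction of 0
    yields fold NaN (undefined); an observed fraction of 0 yields fold 0.
    """
    if statistic not in ("ratio", "odds"):
        raise ValueError(f"statistic must be 'ratio' or 'odds', got {statistic!r}")
    ids = {f.lnp_id for f in library} | {f.barcode_id for f in library}
    members = list(members)
    unknown = [m for m in members if m not in ids]
    if unknown:
        raise ValueError(f"decile members not in library: {unknown}")
    levels_by_id: dict[str, str] = {}
    for f in library:
        value = f.component(axis)  # raises on unknown axis
        levels_by_id[f.lnp_id] = value
        levels_by_id[f.barcode_id] = value
    k = len(members)
    observed = sum(levels_by_id[m] == level for m in members) / k
    expected = sum(f.component(axis) == level for f in library) / len(library)
    if statistic == "ratio":
        fold = observed / expected if expected > 0 else float("nan")
    else:
        if expected in (0.0, 1.0) or observed == 1.0:
            fold = float("nan")
        else:
            obs_odds = observed / (1.0 - observed)
            exp_odds = expected / (1.0 - expected)
            fold = obs_odds / exp_odds
    return EnrichmentResult(
        component_axis=axis, level=level, direction=direction, k=k,
        observed_fraction=observed, expected_fraction=expected, fold=fold,
    )


def enrichment_table(
    ranks: pd.Series,
    library: Sequence[Formulation],
    axes: Sequence[str] = COMPONENT_AXES,
    fraction: float = 0.10,
    statistic: str = "ratio",
) -> pd.DataFrame:
    """Tidy fold-enrichment table over all axes, levels, and both deciles.

    ``ranks`` must be indexed by the screened LNPs' barcode ids (or lnp_ids),
    control excluded.
    """
    rows = []
    for direction in ("top", "bottom"):
        members = decile_members(ranks, fraction, direction)
        for axis in axes:
            levels = sorted({f.component(axis) for f in library})
            for level in levels:
                r = fold_enrichment(members, library, axis, level,
                                    direction, statistic)
                rows.append(
                    {
                        "axis": r.component_axis,
                        "level": r.level,
                        "direction": r.direction,
                        "k": r.k,
                        "observed": r.observed_fraction,
                        "expected": r.expected_fraction,
                        "fold": r.fold,
                    }
                )
    return pd.DataFrame(rows)


def bootstrap_enrichment(
    values: pd.DataFrame,
    library: Sequence[Formulation],
    axis: str,
    n_boot: int = 1000,
    seed: int = 0,
    fraction: float = 0.10,
    statistic: str = "ratio",
) -> pd.DataFrame:
    """Percentile bootstrap intervals for per-level folds.

    Resamples sample columns of the normalized-delivery matrix with
    replacement, re-aggregates, re-ranks, and recomputes deciles and folds.
    ``values`` must contain only screened LNP barcodes (control excluded).
    Returns a table with point fold and the 2.5/97.5 percentile interval per
    (level, direction). Deterministic per seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if values.shape[1] < 2:
        raise ValueError("bootstrap requires at least 2 samples")
    rng = np.random.default_rng(seed)
    levels = sorted({f.component(axis) for f in library})
    point = _folds_from_values(values, library, axis, levels, fraction, statistic)
    draws: dict[tuple[str, str], list[float]] = {
        key: [] for key in point
    }
    cols = list(values.columns)
    for _ in range(n_boot):
        resampled = values.iloc[:, rng.integers(0, len(cols), size=len(cols))]
        resampled.columns = [f"b{i}" for i in range(len(cols))]
        folds = _folds_from_values(resampled, library, axis, levels,
                                   fraction, statistic)
        for key, fold in folds.items():
            draws[key].append(fold)
    rows = []
    for (level, direction), fold in point.items():
        arr = np.asarray(draws[(level, direction)], dtype=float)
        lo, hi = np.nanpercentile(arr, [2.5, 97.5])
        rows.append(
            {
                "axis": axis, "level": level, "direction": direction,
                "fold": fold, "ci_low": float(lo), "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def _folds_from_values(
    values: pd.DataFrame,
    library: Sequence[Formulation],
    axis: str,
    levels: Sequence[str],
    fraction: float,
    statistic: str,
) -> dict[tuple[str, str], float]:
    aggregates, ranks = aggregate_and_rank(values)
    out = {}
    for direction in ("top", "bottom"):
        members = decile_members(ranks["all"], fraction, direction)
        for level in levels:
            r = fold_enrichment(members, library, axis, level, direction, statistic)
            out[(level, direction)] = r.fold
    return out
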