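"""DEG filtering and GO fold-enrichment arithmetic.

Consumes a differential-expression results table (the negative-binomial
test itself is upstream and out of scope) and category count tables.
Direction calls use strict fold-change gates by default (> 2 up, < 0.5
down, adjusted p < 0.05; an ``inclusive`` switch relaxes the upper gate to
>= 2).  Enrichment uses the hypergeometric upper tail with Bonferroni
adjustment across terms, gated at fold enrichment >= 1.5 and adjusted
p < 0.05.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, DomainError


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"
    NONE = "none"


@dataclass
class DEGCounts:
    """DEG direction calls plus the headline counts and percentages."""

    records: pd.DataFrame  # gene_id, fold_change, adjusted_p, direction
    n_up: int
    n_down: int
    pct_up: float
    pct_down: float


def filter_degs(
    table: pd.DataFrame,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.05,
    inclusive: bool = False,
) -> DEGCounts:
    """Call DEG directions and compute up/down counts and percentages.

    ``table`` needs columns ``gene_id``, ``fold_change`` (expression ratio,
    positive), ``adjusted_p``.  Percentages are of the DEG total
    (up + down), rounded to one decimal.
    """
    required = {"gene_id", "fold_change", "adjusted_p"}
    if not required.issubset(table.columns):
        raise DomainError(f"DE table needs columns {sorted(required)}")
    fc = table["fold_change"].to_numpy(dtype=float)
    p = table["adjusted_p"].to_numpy(dtype=float)
    if np.any(fc <= 0):
        raise DomainError("fold changes must be positive ratios")
    if np.any((p < 0) | (p > 1)):
        raise DomainError("adjusted p-values must lie in [0, 1]")

    up_gate = fc >= fc_up if inclusive else fc > fc_up
    up = up_gate & (p < alpha)
    down = (fc < fc_down) & (p < alpha)
    direction = np.where(up, Direction.UP.value,
                         np.where(down, Direction.DOWN.value, Direction.NONE.value))
    records = table.copy()
    records["direction"] = direction

    n_up, n_down = int(up.sum()), int(down.sum())
    total = n_up + n_down
    pct_up = round(100.0 * n_up / total, 1) if total else float("nan")
    pct_down = round(100.0 * n_down / total, 1) if total else float("nan")
    return DEGCounts(records=records, n_up=n_up, n_down=n_down,
                     pct_up=pct_up, pct_down=pct_down)


def fold_enrichment(observed: int, expected: float) -> float:
    """Observed/expected ratio reported to two decimals (0 when nothing is
    expected and nothing observed)."""
    if expected < 0:
        raise DomainError("expected count must be >= 0")
    if expected == 0:
        return 0.0 if observed == 0 else float("inf")
    return round(observed / expected, 2)


def estimate_universe_size(
    category_size: int, deg_count: int, expected: float
) -> int:
    """Invert ``expected = category_size * deg_count / universe`` for the
    universe size implied by one reported row."""
    if expected <= 0:
        raise DomainError("expected count must be > 0 to invert")
    return int(round(category_size * deg_count / expected))


@dataclass(frozen=True)
class EnrichmentRow:
    """One category's enrichment statistics."""

    term: str
    category_size: int
    observed: int
    expected: float
    fold_enrichment: float
    raw_p: float
    adjusted_p: float
    passes_gate: bool
    universe_size: int
    deg_count: int


def _hypergeom(universe: int, size: int, deg: int):
    # X = number of DEGs landing in the category under proportional sampling
    return stats.hypergeom(M=universe, n=size, N=deg)


def fold_enrichment_table(
    categories: pd.DataFrame,
    deg_count: int,
    universe_size: int | None = None,
    fold_min: float = 1.5,
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Per-category fold enrichment with hypergeometric upper-tail p.

    ``categories`` needs columns ``term``, ``category_size``, ``observed``
    and may carry an ``expected`` column; when present that printed value is
    used for the fold-enrichment ratio (reproduction mode) and, if
    ``universe_size`` is omitted, each row's universe is back-computed from
    it.  Raw p-values are Bonferroni-adjusted across the table's terms and
    the gate requires fold enrichment >= ``fold_min`` with adjusted
    p < ``alpha``.
    """
    required = {"term", "category_size", "observed"}
    if not required.issubset(categories.columns):
        raise DomainError(f"category table needs columns {sorted(required)}")
    has_expected = "expected" in categories.columns
    if universe_size is None and not has_expected:
        raise DomainError(
            "universe_size is required unless an expected column is given"
        )
    n_terms = len(categories)
    rows: list[EnrichmentRow] = []
    for rec in categories.itertuples(index=False):
        size, observed = int(rec.category_size), int(rec.observed)
        if observed > min(size, deg_count):
            raise ConsistencyError(
                f"term {rec.term}: observed {observed} exceeds "
                f"min(category size {size}, DEG count {deg_count})"
            )
        if has_expected and not pd.isna(rec.expected):
            expected = float(rec.expected)
            universe = (
                universe_size
                if universe_size is not None
                else estimate_universe_size(size, deg_count, expected)
            )
        else:
            universe = universe_size
            expected = size * deg_count / universe
        if size > universe:
            raise ConsistencyError(
                f"term {rec.term}: category size {size} exceeds universe {universe}"
            )
        raw_p = float(_hypergeom(universe, size, deg_count).sf(observed - 1))
        adj_p = min(1.0, raw_p * n_terms)
        fold = fold_enrichment(observed, expected)
        rows.append(
            EnrichmentRow(
                term=str(rec.term),
                category_size=size,
                observed=observed,
                expected=expected,
                fold_enrichment=fold,
                raw_p=raw_p,
                adjusted_p=adj_p,
                passes_gate=bool(fold >= fold_min and adj_p < alpha),
                universe_size=int(universe),
                deg_count=int(deg_count),
            )
        )
    return rows


def depletion_support(row: EnrichmentRow) -> float:
    """Lower-tail p, ``P[X <= observed]``, for under-represented terms."""
    return float(
        _hypergeom(row.universe_size, row.category_size, row.deg_count).cdf(
            row.observed
        )
    )


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Tabular mirror of the enrichment results (one row per term)."""
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "total_genes": r.category_size,
                "n_degs": r.observed,
                "n_degs_expected": round(r.expected, 2),
                "fold_enrichment": r.fold_enrichment,
                "raw_p": r.raw_p,
                "bonferroni_p": r.adjusted_p,
                "passes_gate": r.passes_gate,
            }
            for r in rows
        ]
    )
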