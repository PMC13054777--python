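"""Fore/hind-limb AUI quadrant framework and contingency statistics.

Species are placed in one of four quadrants by whether forelimb (FL) and
hindlimb (HL) AUI% exceed 50%:

* Quadrant I:   FL > 50, HL > 50 — coordinated high utilization
* Quadrant II:  FL <= 50, HL > 50 — hindlimb-dominant
* Quadrant III: FL <= 50, HL <= 50 — low utilization in both limbs
* Quadrant IV:  FL > 50, HL <= 50 — forelimb-dominant

Association between quadrant membership and each biological factor is tested
with a Pearson chi-square of independence; per-cell enrichment uses Fisher's
exact test on the category-vs-rest x quadrant-vs-rest collapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MissingDataError, StanceKinError

log = logging.getLogger(__name__)

QUADRANTS = ("I", "II", "III", "IV")
AUI_THRESHOLD = 50.0


@dataclass
class QuadrantAssignment:
    species_id: str
    fl_aui: float
    hl_aui: float
    quadrant: str


@dataclass
class CellEnrichment:
    category: str
    quadrant: str
    count: int
    odds_ratio: float
    fisher_p: float
    direction: str  # "over" | "under" | "none"


@dataclass
class QuadrantTable:
    factor_name: str
    counts: pd.DataFrame  # categories x quadrants
    chi2: Optional[float]
    df: Optional[int]
    p: Optional[float]
    enrichments: list[CellEnrichment] = field(default_factory=list)


def classify_quadrant(fl_aui: float, hl_aui: float) -> str:
    """Quadrant label from FL/HL AUI%; values exactly at 50 fall in the <= branch."""
    if fl_aui is None or hl_aui is None:
        raise MissingDataError("both limb AUI values are required")
    if not (np.isfinite(fl_aui) and np.isfinite(hl_aui)) or fl_aui < 0 or hl_aui < 0:
        raise ValueError("AUI values must be finite and non-negative")
    fl_high = fl_aui > AUI_THRESHOLD
    hl_high = hl_aui > AUI_THRESHOLD
    if fl_high and hl_high:
        return "I"
    if not fl_high and hl_high:
        return "II"
    if not fl_high and not hl_high:
        return "III"
    return "IV"


def assign_quadrants(
    aui_by_species: Mapping[str, tuple[Optional[float], Optional[float]]],
) -> tuple[list[QuadrantAssignment], list[str]]:
    """Classify every species with both AUI values; return assignments and exclusions."""
    assignments, excluded = [], []
    for sp, (fl, hl) in aui_by_species.items():
        if fl is None or hl is None:
            excluded.append(sp)
            log.info("quadrants: excluding %s (missing limb AUI)", sp)
            continue
        assignments.append(QuadrantAssignment(sp, float(fl), float(hl), classify_quadrant(fl, hl)))
    return assignments, excluded


def chi_square_independence(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence without continuity correction.

    Rows/columns with zero margins are dropped (with a warning) before the
    test; an all-zero table is an error.
    """
    t = np.asarray(counts, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("counts must be a non-negative 2-D table")
    if t.sum() == 0:
        raise StanceKinError("all-zero contingency table")
    row_keep = t.sum(axis=1) > 0
    col_keep = t.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        log.warning(
            "chi-square: dropping %d zero-margin rows and %d columns",
            int((~row_keep).sum()),
            int((~col_keep).sum()),
        )
        t = t[row_keep][:, col_keep]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise StanceKinError("need >= 2 rows and >= 2 columns with positive margins")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def fisher_exact_2x2(table: np.ndarray, alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test for a 2x2 table.

    Two-sided p sums hypergeometric probabilities of tables no more likely
    than the observed one. The odds ratio is the sample (a*d)/(b*c); 0.5 is
    added to every cell for reporting the OR when a zero cell exists — never
    for the p-value.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    if t.sum() == 0:
        raise ValueError("empty table")
    a, b, c, d = t.ravel()
    _, p = stats.fisher_exact(t.astype(int), alternative=alternative)
    if min(a, b, c, d) == 0:
        orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orat = (a * d) / (b * c)
    return float(orat), float(p)


def quadrant_enrichment(
    assignments: Sequence[QuadrantAssignment],
    factor_levels: Mapping[str, str],
    factor_name: str,
    alternative: str = "two-sided",
    holm: bool = False,
) -> QuadrantTable:
    """Contingency table of factor categories x quadrants with tests.

    Computes the global chi-square of independence and, for each
    (category, quadrant) cell, a Fisher exact test on the collapsed 2x2
    (category vs rest) x (quadrant vs rest), reporting the odds ratio, p and
    over/under direction. With a single category the tests are skipped.
    """
    rows = []
    for a in assignments:
        if a.species_id not in factor_levels:
            raise MissingDataError(f"no {factor_name} level for {a.species_id}")
        rows.append((factor_levels[a.species_id], a.quadrant))
    df_long = pd.DataFrame(rows, columns=["category", "quadrant"])
    categories = sorted(df_long["category"].unique())
    counts = (
        df_long.groupby(["category", "quadrant"]).size().unstack(fill_value=0)
        .reindex(index=categories, columns=list(QUADRANTS), fill_value=0)
    )

    if len(categories) < 2:
        log.info("quadrants: single %s category; global test skipped", factor_name)
        return QuadrantTable(factor_name, counts, None, None, None, [])

    chi2, dof, p = chi_square_independence(counts.to_numpy())

    enrichments = []
    total = counts.to_numpy().sum()
    raw_ps = []
    for cat in categories:
        for q in QUADRANTS:
            a = int(counts.loc[cat, q])
            row_total = int(counts.loc[cat].sum())
            col_total = int(counts[q].sum())
            b = row_total - a
            c = col_total - a
            d = total - row_total - col_total + a
            orat, fp = fisher_exact_2x2(np.array([[a, b], [c, d]]), alternative=alternative)
            direction = "over" if orat > 1 else ("under" if orat < 1 else "none")
            enrichments.append(CellEnrichment(cat, q, a, orat, fp, direction))
            raw_ps.append(fp)
    if holm:
        from .stats import holm_adjust

        for e, pa in zip(enrichments, holm_adjust(raw_ps)):
            e.fisher_p = pa
    return QuadrantTable(factor_name, counts, chi2, dof, p, enrichments)
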