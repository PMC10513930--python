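"""Direction-split Fisher's exact enrichment of physicochemical annotations.

Model coefficients are split into a positive and a negative foreground
(signed coefficient with FDR below a cut-off, default 10%) against the
background of all tested species in scope.  Each annotation category yields a
2x2 table and a two-sided Fisher's exact test, run across all lipids and
within each subclass (TAG dominance would otherwise drive the global
result).  Infinite log2(odds) from empty cells are imputed for display with
0.5x the minimum (negative infinity) or 0.5x the maximum (positive infinity)
finite value; categories significant in both directions have their displayed
enrichment zeroed and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import parse_lipid_name

logger = logging.getLogger(__name__)

__all__ = [
    "split_by_direction",
    "fisher_enrichment",
    "impute_infinite_odds",
    "apply_dual_direction_rule",
    "directional_enrichment",
]


def split_by_direction(
    results: pd.DataFrame,
    fdr_cut: float = 0.10,
    species_col: str = "species",
) -> tuple[list[str], list[str], list[str]]:
    """Split model results into positive/negative foregrounds and background.

    The positive foreground is {beta > 0, FDR < cut}, the negative
    {beta < 0, FDR < cut}; the background is every tested species.
    """
    if results.empty:
        raise ValueError("empty background: no tested species")
    pos = results.loc[(results["beta"] > 0) & (results["fdr"] < fdr_cut),
                      species_col].tolist()
    neg = results.loc[(results["beta"] < 0) & (results["fdr"] < fdr_cut),
                      species_col].tolist()
    background = results[species_col].tolist()
    return pos, neg, background


def fisher_enrichment(
    foreground: list[str],
    background: list[str],
    catalog: pd.DataFrame,
    scope: str = "all",
    direction: str = "positive",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Fisher's exact enrichment of each annotation category.

    ``catalog`` is the tidy (species, category_family, category) table.  With
    ``scope == 'within-subclass:<CLS>'`` both sets are restricted to that
    subclass.  The 2x2 table per category is (in-category & foreground,
    out-category & foreground, in-category & background-minus-foreground,
    out-category & background-minus-foreground); BH correction is applied
    within this (scope x direction) family.
    """
    bg = set(background)
    fg = set(foreground) & bg
    if scope.startswith("within-subclass:"):
        cls = scope.split(":", 1)[1]
        bg = {sp for sp in bg if parse_lipid_name(sp).subclass == cls}
        fg = fg & bg
    if not bg:
        raise ValueError(f"empty background in scope {scope!r}")
    rest = bg - fg
    cat = catalog[catalog["species"].isin(bg)]
    rows = []
    for (family, category), grp in cat.groupby(["category_family", "category"]):
        members = set(grp["species"])
        a = len(fg & members)
        b = len(fg) - a
        c = len(rest & members)
        d = len(rest) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        num, den = a * d, b * c
        if num > 0 and den > 0:
            log2_odds = float(np.log2(num / den))
        elif num == 0 and den == 0:
            log2_odds = np.nan
        else:
            log2_odds = np.inf if den == 0 else -np.inf
        rows.append({"category_family": family, "category": category,
                     "scope": scope, "direction": direction,
                     "a": a, "b": b, "c": c, "d": d,
                     "log2_odds": log2_odds, "imputed": False, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def impute_infinite_odds(results: pd.DataFrame, variant: str = "minmax"
                         ) -> pd.DataFrame:
    """Replace infinite log2(odds) with finite display values.

    ``minmax``: negative infinity becomes 0.5x the minimum finite value and
    positive infinity 0.5x the maximum.  ``mean``: both signs use 0.5x the
    mean of the finite values of that sign.

    Raises
    ------
    ValueError
        If every log2(odds) is infinite.
    """
    out = results.copy()
    vals = out["log2_odds"]
    finite = vals[np.isfinite(vals)]
    has_inf = np.isinf(vals).any()
    if has_inf and finite.empty:
        raise ValueError("all log2(odds) infinite; nothing to anchor on")
    if not has_inf:
        return out
    if variant == "minmax":
        neg_fill = 0.5 * finite.min()
        pos_fill = 0.5 * finite.max()
    elif variant == "mean":
        pos_vals = finite[finite > 0]
        neg_vals = finite[finite < 0]
        pos_fill = 0.5 * pos_vals.mean() if len(pos_vals) else 0.0
        neg_fill = 0.5 * neg_vals.mean() if len(neg_vals) else 0.0
    else:
        raise ValueError(f"unknown variant {variant!r}")
    neg_mask = vals == -np.inf
    pos_mask = vals == np.inf
    out.loc[neg_mask, "log2_odds"] = neg_fill
    out.loc[pos_mask, "log2_odds"] = pos_fill
    out.loc[neg_mask | pos_mask, "imputed"] = True
    return out


def apply_dual_direction_rule(results: pd.DataFrame) -> pd.DataFrame:
    """Zero out categories significant in both directions.

    ``results`` must hold joined positive and negative rows; categories
    (per family and scope) significant in both directions get their displayed
    enrichment set to 0 with ``dual_flag`` true.
    """
    out = results.copy()
    out["dual_flag"] = False
    keys = ["category_family", "category", "scope"]
    sig = out[out["significant"]]
    counts = sig.groupby(keys)["direction"].nunique()
    dual = counts[counts >= 2].index
    if len(dual):
        mask = out.set_index(keys).index.isin(dual)
        out.loc[mask, "log2_odds"] = 0.0
        out.loc[mask, "dual_flag"] = True
    return out


def directional_enrichment(
    results: pd.DataFrame,
    catalog: pd.DataFrame,
    scopes: list[str] | None = None,
    fdr_cut: float = 0.10,
    fdr_threshold: float = 0.05,
    impute_variant: str = "minmax",
) -> pd.DataFrame:
    """Full direction-split enrichment over the requested scopes."""
    pos, neg, background = split_by_direction(results, fdr_cut=fdr_cut)
    if scopes is None:
        classes = sorted({parse_lipid_name(sp).subclass for sp in background})
        scopes = ["all"] + [f"within-subclass:{c}" for c in classes]
    frames = []
    for scope in scopes:
        for direction, fg in (("positive", pos), ("negative", neg)):
            try:
                res = fisher_enrichment(fg, background, catalog, scope=scope,
                                        direction=direction,
                                        fdr_threshold=fdr_threshold)
            except ValueError:
                continue
            if not res.empty:
                frames.append(res)
    joined = pd.concat(frames, ignore_index=True)
    if np.isinf(joined["log2_odds"]).any():
        joined = impute_infinite_odds(joined, variant=impute_variant)
    return apply_dual_direction_rule(joined)
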