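"""Mid-parent / high-parent heterosis, heterosis groups, and their correlates.

Heterosis is expressed in percent of the parental reference value, so the
traits are assumed positive-valued; F1 records whose mid-parent or
higher-parent BLUP is not strictly positive are flagged and excluded from
percent summaries with a logged count.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

GROUPS = ("non", "medium", "strong")


def mp_hp_heterosis(p_f1: float, p_p1: float, p_p2: float) -> tuple[float, float]:
    """Percent mid-parent and high-parent heterosis of one F1.

    MP = (P_F1 - P_mid) / P_mid * 100 with P_mid the parental mean;
    HP = (P_F1 - P_max) / P_max * 100 with P_max the higher parent.
    Returns (nan, nan) when a denominator is not strictly positive.
    """
    p_mid = (p_p1 + p_p2) / 2.0
    p_max = max(p_p1, p_p2)
    if p_mid <= 0 or p_max <= 0:
        return (float("nan"), float("nan"))
    mp = (p_f1 - p_mid) / p_mid * 100.0
    hp = (p_f1 - p_max) / p_max * 100.0
    return (mp, hp)


def additive_effect(p_p1: float, p_p2: float) -> float:
    """Half the absolute phenotypic difference between the two parents."""
    return abs(p_p1 - p_p2) / 2.0


def classify(mp: float, hp: float) -> str:
    """Heterosis group: non (MP < 0), medium (MP > 0 & HP < 0), strong (HP > 0).

    Boundary ties go to the less extreme group (MP = 0 -> non, HP = 0 ->
    medium); on continuous data exact ties have probability ~0.
    """
    if np.isnan(mp) or np.isnan(hp):
        return "invalid"
    if hp > 0:
        return "strong"
    if mp > 0:
        return "medium"
    return "non"


def build_heterosis_table(
    blups: pd.Series | pd.DataFrame,
    crosses,
    trait: str | None = None,
) -> pd.DataFrame:
    """Per-F1 heterosis statistics for one trait.

    ``blups`` is a Series of BLUP values indexed by accession (covering F1s and
    parents) — or a BLUP table DataFrame together with ``trait``. Returns a
    HeterosisTable with columns f1_id, trait, p_f1, p_mid, p_max,
    mp_heterosis, hp_heterosis, additive_effect, group, valid.
    """
    if isinstance(blups, pd.DataFrame):
        from .pheno_blup import blup_series

        if trait is None:
            raise ValueError("trait required when passing a BLUP table")
        blups = blup_series(blups, trait)
    label = trait if trait is not None else "trait"

    rows = []
    n_flagged = 0
    for _, rec in crosses.table.iterrows():
        p1 = float(blups[rec["mother_id"]])
        p2 = float(blups[rec["father_id"]])
        pf1 = float(blups[rec["f1_id"]])
        mp, hp = mp_hp_heterosis(pf1, p1, p2)
        group = classify(mp, hp)
        valid = group != "invalid"
        if not valid:
            n_flagged += 1
        rows.append(
            {
                "f1_id": rec["f1_id"],
                "trait": label,
                "p_f1": pf1,
                "p_mid": (p1 + p2) / 2.0,
                "p_max": max(p1, p2),
                "mp_heterosis": mp,
                "hp_heterosis": hp,
                "additive_effect": additive_effect(p1, p2),
                "group": group,
                "valid": valid,
            }
        )
    if n_flagged:
        log.warning(
            "%d F1s with non-positive parental reference excluded from percent heterosis (%s)",
            n_flagged, label,
        )
    return pd.DataFrame(rows)


def heterosis_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trait distribution summary of MP/HP heterosis and group proportions.

    Statistics use only records with valid (positive) parental references;
    group proportions are percentages of classifiable records and sum to 100.
    """
    if table.empty:
        raise ValueError("empty heterosis table")
    out = []
    for trait, sub in table.groupby("trait"):
        ok = sub[sub["valid"]]
        row: dict = {"trait": trait, "n": len(ok), "n_flagged": int((~sub["valid"]).sum())}
        for kind, col in (("mp", "mp_heterosis"), ("hp", "hp_heterosis")):
            v = ok[col].to_numpy(float)
            row[f"{kind}_mean"] = v.mean() if len(v) else np.nan
            row[f"{kind}_sd"] = v.std(ddof=1) if len(v) > 1 else 0.0
            row[f"{kind}_median"] = np.median(v) if len(v) else np.nan
            row[f"{kind}_min"] = v.min() if len(v) else np.nan
            row[f"{kind}_max"] = v.max() if len(v) else np.nan
        counts = ok["group"].value_counts()
        total = max(len(ok), 1)
        for grp in GROUPS:
            row[f"prop_{grp}"] = counts.get(grp, 0) / total * 100.0
        out.append(row)
    return pd.DataFrame(out)


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "N.S."


def pearson_with_stars(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Pearson r with the two-sided t-approximation p-value (df = n - 2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        return (float("nan"), float("nan"), "")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), _stars(p)


def heterosis_correlates(table: pd.DataFrame, distances: pd.DataFrame) -> pd.DataFrame:
    """Correlate MP/HP heterosis with the additive effect and parental distance.

    Returns one row per (trait, factor in {additive_effect, distance},
    heterosis type) with Pearson r, p-value, significance stars, and n.
    """
    merged = table.merge(distances[["f1_id", "distance"]], on="f1_id", how="left")
    out = []
    for trait, sub in merged.groupby("trait"):
        ok = sub[sub["valid"]]
        for factor in ("additive_effect", "distance"):
            for kind, col in (("mp", "mp_heterosis"), ("hp", "hp_heterosis")):
                try:
                    r, p, star = pearson_with_stars(ok[factor], ok[col])
                except ValueError:
                    r, p, star = float("nan"), float("nan"), ""
                out.append(
                    {
                        "trait": trait,
                        "factor": factor,
                        "heterosis": kind,
                        "r": r,
                        "p_value": p,
                        "signif": star,
                        "n": len(ok),
                    }
                )
    return pd.DataFrame(out)


def export_cross_matrix(
    table: pd.DataFrame,
    trait: str,
    crosses,
    parental_blups: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parents x parents matrix of HP heterosis with direction tags.

    The actually crossed direction (mother row, father column) is tagged "R";
    the mirrored cell carries the identical value tagged "F" (reciprocal
    differences are ignored by design). Cells with no cross are empty. If
    ``parental_blups`` is given, a "_parent_blup" margin row and column are
    attached. Returns (value matrix, tag matrix).
    """
    sub = table[table["trait"] == trait].merge(
        crosses.table[["f1_id", "mother_id", "father_id"]], on="f1_id"
    )
    if sub.empty:
        raise ValueError(f"no crosses for trait {trait!r}")
    parents = sorted(set(sub["mother_id"]) | set(sub["father_id"]))
    vals = pd.DataFrame(np.nan, index=parents, columns=parents)
    tags = pd.DataFrame("", index=parents, columns=parents)
    for _, rec in sub.iterrows():
        m, f, hp = rec["mother_id"], rec["father_id"], rec["hp_heterosis"]
        if tags.loc[m, f] != "" and not np.isclose(vals.loc[m, f], hp, equal_nan=True):
            raise ValueError(
                f"conflicting duplicate cross {m} x {f}; pre-average reciprocal values"
            )
        vals.loc[m, f] = hp
        vals.loc[f, m] = hp
        tags.loc[m, f] = "R"
        if tags.loc[f, m] == "":
            tags.loc[f, m] = "F"
    if parental_blups is not None:
        vals["_parent_blup"] = [parental_blups.get(p, np.nan) for p in parents]
        vals.loc["_parent_blup"] = [parental_blups.get(p, np.nan) for p in parents] + [np.nan]
    return vals, tags
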