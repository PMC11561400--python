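"""Differential functional-category abundance between seasonal and
non-seasonal chronotypes.

The unit of observation is the chronotype: for each functional category
(PHROG-style) the ratio = total gene count in the chronotype / number of
member vOTUs.  Seasonal and non-seasonal chronotype ratio distributions are
compared per category with a one-tailed Welch t-test and Bonferroni
correction over the number of categories tested.

The default alternative is "greater" (category enriched in seasonal
chronotypes), a pre-specified direction: selecting the smaller of the two
one-sided p-values post hoc would double the per-test type-I error and break
family-wise control.  ``alternative="best"`` provides that exploratory
reading, with the chosen direction reported.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

__all__ = ["category_ratios", "enrichment_test"]


def category_ratios(annotations: pd.DataFrame, memberships: dict[str, int],
                    seasonal_chronotypes: set[int]) -> pd.DataFrame:
    """Gene-count / member-count ratio per (category, chronotype).

    ``annotations`` columns: votu_id, category_id, count.  Every annotated
    vOTU must be present in ``memberships``; categories absent from a
    chronotype get ratio 0.  Returns a category x chronotype DataFrame with a
    ``seasonal`` flag row attribute (``df.attrs['seasonal']``).
    """
    ann = annotations.copy()
    ann["votu_id"] = ann["votu_id"].astype(str)
    unknown = set(ann["votu_id"]) - set(memberships)
    if unknown:
        raise ValueError(f"annotation references unknown vOTU(s): {sorted(unknown)[:5]}")
    ann["chronotype"] = ann["votu_id"].map(memberships)
    chronos = sorted(set(memberships.values()))
    sizes = pd.Series(list(memberships.values())).value_counts()
    totals = ann.pivot_table(index="category_id", columns="chronotype",
                             values="count", aggfunc="sum", fill_value=0)
    totals = totals.reindex(columns=chronos, fill_value=0)
    ratios = totals.div(pd.Series({c: sizes[c] for c in chronos}), axis=1)
    ratios.attrs["seasonal"] = {c: (c in seasonal_chronotypes) for c in chronos}
    return ratios


def enrichment_test(ratios: pd.DataFrame, alpha: float = 0.05,
                    alternative: str = "greater", equal_var: bool = False,
                    n_categories_tested: int | None = None) -> pd.DataFrame:
    """Per-category t-test of seasonal versus non-seasonal chronotype ratios
    with Bonferroni correction.

    ``alternative``: "greater" (seasonal-enriched, default), "less",
    "two-sided", or "best" (smaller one-sided p of both directions, reported
    with its direction).  Bonferroni multiplier = ``n_categories_tested``
    (defaults to the number of category rows).  A category with zero variance
    in both groups gets p = 1.
    """
    seasonal = ratios.attrs["seasonal"]
    s_cols = [c for c in ratios.columns if seasonal[c]]
    n_cols = [c for c in ratios.columns if not seasonal[c]]
    if len(s_cols) < 2 or len(n_cols) < 2:
        raise ValueError("need >= 2 seasonal and >= 2 non-seasonal chronotypes")
    m = n_categories_tested if n_categories_tested is not None else ratios.shape[0]
    rows = []
    for cat, row in ratios.iterrows():
        a = row[s_cols].to_numpy(dtype=float)
        b = row[n_cols].to_numpy(dtype=float)
        if a.std() == 0 and b.std() == 0:
            rows.append((cat, 0.0, 1.0, 1.0, "none", False))
            continue
        if alternative == "best":
            tg, pg = stats.ttest_ind(a, b, equal_var=equal_var, alternative="greater")
            tl, pl = stats.ttest_ind(a, b, equal_var=equal_var, alternative="less")
            t, p, direction = (tg, pg, "seasonal") if pg <= pl else (tl, pl, "non-seasonal")
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
            direction = {"greater": "seasonal", "less": "non-seasonal",
                         "two-sided": "two-sided"}[alternative]
        p_adj = min(1.0, float(p) * m)
        rows.append((cat, float(t), float(p), p_adj, direction, p_adj < alpha))
    return pd.DataFrame(rows, columns=["category", "t", "p_raw", "p_bonferroni",
                                       "direction", "significant"])
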