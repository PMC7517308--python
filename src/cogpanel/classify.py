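"""Operational classification of strains into cognitive-aging categories.

Each strain, on a given basis (one trait or a composite z-score across
traits), receives exactly one category:

* ``excluded`` — fewer than 2 animals at either age (within-strain spread
  cannot be assessed);
* ``reserve`` — baseline (6-month) performance in the top quartile AND
  14-month performance still at or above the panel median;
* ``resilience`` — baseline at or above the panel median AND decline
  slower than the panel-average decline (delta strictly greater than the
  mean delta; the 6-to-14-month interval is constant, so raw deltas order
  the same way annualized rates would);
* ``reserve_and_resilience`` — both of the above;
* ``impaired`` — baseline strictly below the first quartile;
* ``normal`` — everything else.

Two stringencies are provided. ``suggestive`` compares strain means to the
thresholds directly; ``strict`` additionally requires the strain mean plus
or minus its standard error to fit within each criterion (x >= T becomes
x - SE >= T, x < T becomes x + SE < T, and the decline comparison becomes
delta - SE(delta) > mean delta, with SE(delta) the two age SEs combined in
quadrature). Quartiles and medians use linear interpolation between order
statistics and are computed over the included strains; threshold equality
satisfies ">=" comparisons.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

CATEGORIES = ("reserve", "resilience", "reserve_and_resilience",
              "normal", "impaired", "excluded")
TRAIT_BASES = ("ymaze_alt", "cfa", "cfm")
COMPOSITE = "composite"
STRINGENCIES = ("suggestive", "strict")


def composite_scores(
    summaries: pd.DataFrame, traits: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-strain composite cognitive score: sum of per-trait z-scores.

    For each trait x age the z-score is taken over the distribution of
    strain means (sample SD, n-1). The composite at an age sums the z-scores
    of all configured traits; strains missing any trait at that age are
    flagged (``complete = False``) and get no composite. A trait whose
    strain means have zero spread cannot be standardized and raises.
    """
    if traits is None:
        traits = sorted(summaries["trait"].unique())
    rows = []
    for age, sub_age in summaries.groupby("age_months", sort=True):
        z_by_trait = {}
        se_by_trait = {}
        n_by_trait = {}
        for trait in traits:
            sub = sub_age[sub_age["trait"] == trait].set_index("strain")
            if len(sub) < 2:
                raise ValueError(
                    f"trait {trait!r} at {age} months: need >= 2 strains "
                    "for a z-score"
                )
            means = sub["mean"].astype(float)
            sigma = means.std(ddof=1)
            if sigma == 0:
                raise ValueError(
                    f"trait {trait!r} at {age} months has zero spread in "
                    "strain means; z-score undefined"
                )
            z_by_trait[trait] = (means - means.mean()) / sigma
            se_by_trait[trait] = sub["se"].astype(float) / sigma
            n_by_trait[trait] = sub["n"].astype(int)
        strains = sorted(set().union(*(z.index for z in z_by_trait.values())))
        for strain in strains:
            have = [t for t in traits if strain in z_by_trait[t].index]
            complete = len(have) == len(traits)
            score = float(sum(z_by_trait[t][strain] for t in have))
            se_sq = [se_by_trait[t][strain] ** 2 for t in have]
            se = float(np.sqrt(np.nansum(se_sq))) if complete else np.nan
            if complete and any(np.isnan(v) for v in se_sq):
                se = np.nan
            n_min = int(min(n_by_trait[t][strain] for t in have)) if have else 0
            rows.append({
                "strain": strain, "age_months": age,
                "score": score if complete else np.nan,
                "se": se, "n": n_min,
                "n_traits_used": len(have), "complete": complete,
            })
            if not complete:
                logger.info("strain %s missing traits at %sm; composite flagged",
                            strain, age)
    return pd.DataFrame.from_records(rows)


def _basis_table(
    summaries: pd.DataFrame, basis: str, traits: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-strain baseline/later/delta/SE table for one classification basis."""
    if basis == COMPOSITE:
        comp = composite_scores(summaries, traits=traits)
        wide = comp.pivot(index="strain", columns="age_months")
        out = pd.DataFrame({
            "baseline": wide[("score", 6)], "later": wide[("score", 14)],
            "se6": wide[("se", 6)], "se14": wide[("se", 14)],
            "n6": wide[("n", 6)], "n14": wide[("n", 14)],
        })
    else:
        sub = summaries[summaries["trait"] == basis]
        if sub.empty:
            raise ValueError(f"no summaries for basis {basis!r}")
        wide = sub.pivot(index="strain", columns="age_months")
        for age in (6, 14):
            if ("mean", age) not in wide.columns:
                raise ValueError(f"basis {basis!r}: no summaries at {age} months")
        out = pd.DataFrame({
            "baseline": wide[("mean", 6)], "later": wide[("mean", 14)],
            "se6": wide[("se", 6)], "se14": wide[("se", 14)],
            "n6": wide[("n", 6)], "n14": wide[("n", 14)],
        })
    out["n6"] = out["n6"].fillna(0).astype(int)
    out["n14"] = out["n14"].fillna(0).astype(int)
    # a strain without a usable baseline/later value cannot be categorized
    out.loc[out["baseline"].isna(), "n6"] = 0
    out.loc[out["later"].isna(), "n14"] = 0
    out["delta"] = out["later"] - out["baseline"]
    out["se_delta"] = np.sqrt(out["se6"] ** 2 + out["se14"] ** 2)
    return out.sort_index()


def classify_panel(
    summaries: pd.DataFrame,
    declines: pd.DataFrame | None = None,
    basis: str = COMPOSITE,
    stringency: str = "suggestive",
    traits: Sequence[str] | None = None,
    min_strains: int = 4,
) -> pd.DataFrame:
    """Assign each strain exactly one cognitive-aging category.

    ``declines``, when given, supplies the per-strain delta for trait bases
    (it must cover every included strain); otherwise deltas are taken as
    later minus baseline of the basis itself, which is identical for strain
    means and is the definition used for the composite.
    """
    if stringency not in STRINGENCIES:
        raise ValueError(f"unknown stringency {stringency!r}")
    table = _basis_table(summaries, basis, traits=traits)

    if declines is not None and basis != COMPOSITE:
        d = declines[declines["trait"] == basis].set_index("strain")["delta"]
        merged = table.join(d.rename("delta_ext"))
        included_mask = (merged["n6"] >= 2) & (merged["n14"] >= 2)
        missing = merged.index[included_mask & merged["delta_ext"].isna()]
        if len(missing):
            raise ValueError(
                f"declines table missing non-excluded strains: {list(missing)}"
            )
        table["delta"] = merged["delta_ext"].combine_first(merged["delta"])

    included = table[(table["n6"] >= 2) & (table["n14"] >= 2)].copy()
    if len(included) < min_strains:
        raise ValueError(
            f"only {len(included)} included strains; quartile thresholds "
            f"unreliable (need >= {min_strains})"
        )
    baseline = included["baseline"].to_numpy(dtype=float)
    q1, med6, q3 = np.quantile(baseline, [0.25, 0.5, 0.75])
    med14 = float(np.quantile(included["later"].to_numpy(dtype=float), 0.5))
    mean_delta = float(included["delta"].mean())

    strict = stringency == "strict"
    calls = []
    for strain, row in table.iterrows():
        evidence = {
            "q1_6m": float(q1), "median_6m": float(med6), "q3_6m": float(q3),
            "median_14m": med14, "mean_delta": mean_delta,
            "baseline": row["baseline"], "later": row["later"],
            "delta": row["delta"], "se_6m": row["se6"], "se_14m": row["se14"],
            "se_delta": row["se_delta"],
            "n_6m": int(row["n6"]), "n_14m": int(row["n14"]),
        }
        if row["n6"] < 2 or row["n14"] < 2:
            category = "excluded"
        else:
            b, l, d = row["baseline"], row["later"], row["delta"]
            se6, se14, sed = row["se6"], row["se14"], row["se_delta"]
            if strict:
                reserve = (b - se6 >= q3) and (l - se14 >= med14)
                resilience = (b - se6 >= med6) and (d - sed > mean_delta)
                impaired = b + se6 < q1
            else:
                reserve = (b >= q3) and (l >= med14)
                resilience = (b >= med6) and (d > mean_delta)
                impaired = b < q1
            if reserve and resilience:
                category = "reserve_and_resilience"
            elif reserve:
                category = "reserve"
            elif resilience:
                category = "resilience"
            elif impaired:
                category = "impaired"
            else:
                category = "normal"
        calls.append({"strain": strain, "basis": basis,
                      "stringency": stringency, "category": category,
                      **evidence})
    return pd.DataFrame.from_records(calls).sort_values("strain").reset_index(
        drop=True
    )


class ReserveResilienceClassifier(BaseEstimator):
    """Estimator-style interface over :func:`classify_panel`.

    ``fit(summaries, declines)`` stores per-strain calls in ``calls_`` and
    the category of each strain in ``categories_``.
    """

    def __init__(self, basis: str = COMPOSITE, stringency: str = "suggestive",
                 min_strains: int = 4):
        self.basis = basis
        self.stringency = stringency
        self.min_strains = min_strains

    def fit(self, summaries: pd.DataFrame, declines: pd.DataFrame | None = None):
        self.calls_ = classify_panel(
            summaries, declines, basis=self.basis, stringency=self.stringency,
            min_strains=self.min_strains,
        )
        self.categories_ = self.calls_.set_index("strain")["category"]
        return self

    def predict(self, summaries: pd.DataFrame,
                declines: pd.DataFrame | None = None) -> pd.Series:
        return classify_panel(
            summaries, declines, basis=self.basis, stringency=self.stringency,
            min_strains=self.min_strains,
        ).set_index("strain")["category"]


def classification_report(calls: pd.DataFrame) -> dict:
    """Category counts per basis x stringency, JSON-serializable."""
    if calls.empty:
        raise ValueError("no classification calls to report")
    report: dict = {"counts": {}, "n_strains": int(calls["strain"].nunique())}
    for (basis, stringency), sub in calls.groupby(["basis", "stringency"],
                                                  sort=True):
        counts = {cat: int((sub["category"] == cat).sum()) for cat in CATEGORIES}
        report["counts"][f"{basis}:{stringency}"] = counts
    return report
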