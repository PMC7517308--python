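"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written with explicit loops and elementary
arithmetic, without reusing any code path from the package under test.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# behavioral scoring
# ---------------------------------------------------------------------------

def brute_alternation_percent(seq) -> float:
    """Window-by-window triplet count, straight from the definition."""
    windows = 0
    hits = 0
    for i in range(len(seq) - 2):
        windows += 1
        a, b, c = seq[i], seq[i + 1], seq[i + 2]
        if a != b and b != c and a != c:
            hits += 1
    return 100.0 * hits / windows


def brute_anova_f(groups) -> float:
    """Textbook one-way ANOVA F from sums of squares."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ssb / df_b) / (ssw / df_w)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_stepup(pvals) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the step-up recursion."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        q = min(prev, pvals[i] * m / rank_from_top)
        adjusted[i] = q
        prev = q
    return adjusted


# ---------------------------------------------------------------------------
# reserve / resilience classification
# ---------------------------------------------------------------------------

def _interp_quantile(sorted_vals, q) -> float:
    """Linear interpolation between order statistics (the R-7 rule)."""
    n = len(sorted_vals)
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    frac = h - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def classify_oracle(strain_rows: dict[str, dict], stringency: str) -> dict[str, str]:
    """Rule-by-rule category assignment from per-strain evidence dicts.

    ``strain_rows`` maps strain -> dict with keys baseline, later, delta,
    se6, se14, n6, n14. Returns strain -> category.
    """
    included = {
        s: r for s, r in strain_rows.items() if r["n6"] >= 2 and r["n14"] >= 2
    }
    baselines = sorted(r["baseline"] for r in included.values())
    laters = sorted(r["later"] for r in included.values())
    q1 = _interp_quantile(baselines, 0.25)
    med6 = _interp_quantile(baselines, 0.50)
    q3 = _interp_quantile(baselines, 0.75)
    med14 = _interp_quantile(laters, 0.50)
    mean_delta = sum(r["delta"] for r in included.values()) / len(included)

    out = {}
    for s, r in strain_rows.items():
        if s not in included:
            out[s] = "excluded"
            continue
        se_delta = math.sqrt(r["se6"] ** 2 + r["se14"] ** 2)
        if stringency == "strict":
            reserve = (r["baseline"] - r["se6"] >= q3
                       and r["later"] - r["se14"] >= med14)
            resilience = (r["baseline"] - r["se6"] >= med6
                          and r["delta"] - se_delta > mean_delta)
            impaired = r["baseline"] + r["se6"] < q1
        else:
            reserve = r["baseline"] >= q3 and r["later"] >= med14
            resilience = r["baseline"] >= med6 and r["delta"] > mean_delta
            impaired = r["baseline"] < q1
        if reserve and resilience:
            out[s] = "reserve_and_resilience"
        elif reserve:
            out[s] = "reserve"
        elif resilience:
            out[s] = "resilience"
        elif impaired:
            out[s] = "impaired"
        else:
            out[s] = "normal"
    return out


def composite_rows_oracle(summaries: pd.DataFrame, traits) -> dict[str, dict]:
    """Loop-based composite z-score table (baseline/later/SEs per strain)."""
    per_age: dict[int, dict[str, dict]] = {}
    for age in (6, 14):
        z_sum: dict[str, float] = {}
        se_sq: dict[str, float] = {}
        n_min: dict[str, int] = {}
        count: dict[str, int] = {}
        for trait in traits:
            sub = summaries[(summaries["trait"] == trait)
                            & (summaries["age_months"] == age)]
            means = list(sub["mean"])
            mu = sum(means) / len(means)
            sigma = math.sqrt(sum((m - mu) ** 2 for m in means) / (len(means) - 1))
            for _, row in sub.iterrows():
                s = row["strain"]
                z_sum[s] = z_sum.get(s, 0.0) + (row["mean"] - mu) / sigma
                se_val = row["se"] / sigma
                se_sq[s] = se_sq.get(s, 0.0) + (
                    se_val ** 2 if np.isfinite(se_val) else float("nan"))
                n_min[s] = min(n_min.get(s, 10**9), int(row["n"]))
                count[s] = count.get(s, 0) + 1
        per_age[age] = {
            s: {"score": z_sum[s], "se": math.sqrt(se_sq[s]),
                "n": n_min[s] if count[s] == len(traits) else 0}
            for s in z_sum
        }
    rows = {}
    for s in set(per_age[6]) | set(per_age[14]):
        a6 = per_age[6].get(s, {"score": float("nan"), "se": float("nan"), "n": 0})
        a14 = per_age[14].get(s, {"score": float("nan"), "se": float("nan"), "n": 0})
        rows[s] = {
            "baseline": a6["score"], "later": a14["score"],
            "delta": a14["score"] - a6["score"],
            "se6": a6["se"], "se14": a14["se"],
            "n6": a6["n"], "n14": a14["n"],
        }
    return rows


def random_panel_summaries(
    rng: np.random.Generator, n_strains: int = 12,
    traits=("ymaze_alt", "cfa", "cfm"),
) -> pd.DataFrame:
    """Random strain-summary table with occasional n < 2 exclusions."""
    rows = []
    for i in range(n_strains):
        strain = f"S{i:02d}"
        for trait in traits:
            for age in (6, 14):
                # guarantee enough included strains for stable quartiles
                n = int(rng.integers(2, 6)) if i < 6 else int(rng.integers(1, 6))
                mean = float(rng.uniform(10, 90))
                sd = float(rng.uniform(1, 15)) if n >= 2 else float("nan")
                se = sd / math.sqrt(n) if n >= 2 else float("nan")
                rows.append({"strain": strain, "trait": trait,
                             "age_months": age, "n": n, "mean": mean,
                             "sd": sd, "se": se})
    return pd.DataFrame.from_records(rows)


def panel_to_rows(summaries: pd.DataFrame, basis: str, traits) -> dict[str, dict]:
    """Per-strain evidence rows for one basis, assembled by plain loops."""
    if basis == "composite":
        return composite_rows_oracle(summaries, traits)
    by_age: dict[tuple[str, int], tuple] = {}
    for row in summaries.itertuples():
        if row.trait == basis:
            by_age[(row.strain, int(row.age_months))] = (
                float(row.mean), float(row.se), int(row.n))
    rows: dict[str, dict] = {}
    nan = float("nan")
    for strain in sorted({s for s, _ in by_age}):
        b, se6, n6 = by_age.get((strain, 6), (nan, nan, 0))
        l, se14, n14 = by_age.get((strain, 14), (nan, nan, 0))
        rows[strain] = {"baseline": b, "later": l, "delta": l - b,
                        "se6": se6, "se14": se14, "n6": n6, "n14": n14}
    return rows
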