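"""Behavioral phenotype scoring and strain-level summaries.

Covers the three percent-scale cognitive traits of the panel design:

* spontaneous alternation in a three-arm y-maze (working memory; 50% is
  chance performance),
* contextual fear acquisition, CFA — freezing during the fourth postshock
  interval of training,
* contextual fear memory, CFM — freezing on context re-exposure 24 h later,

plus strain x trait x age summaries, per-strain decline scores
(14-month mean minus 6-month mean; negative = decline), a one-sample
above-chance test, and a one-way ANOVA for the main effect of age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ARMS = frozenset({"A", "B", "C"})


def validate_arm_entries(seq: Sequence[str]) -> None:
    """Raise if a y-maze entry sequence is malformed.

    An entry implies leaving the previous arm, so two consecutive identical
    labels cannot occur; labels must be drawn from {A, B, C}.
    """
    bad = set(seq) - VALID_ARMS
    if bad:
        raise ValueError(f"unknown arm labels: {sorted(bad)}")
    for i in range(1, len(seq)):
        if seq[i] == seq[i - 1]:
            raise ValueError(
                f"consecutive duplicate arm {seq[i]!r} at position {i}"
            )


def percent_spontaneous_alternation(seq: Sequence[str]) -> float:
    """Percent of overlapping entry triplets visiting all three arms.

    Scored over the (len - 2) windows of three consecutive entries; a window
    counts when its three labels are all distinct. Requires at least three
    entries.
    """
    validate_arm_entries(seq)
    if len(seq) < 3:
        raise ValueError("alternation score undefined for fewer than 3 entries")
    windows = len(seq) - 2
    hits = sum(len({seq[i], seq[i + 1], seq[i + 2]}) == 3 for i in range(windows))
    return 100.0 * hits / windows


def cfa_from_postshock(
    freezing_by_interval: Mapping[str, float] | Sequence[float],
) -> float:
    """Contextual fear acquisition: freezing during the fourth postshock
    interval (PS4) of training."""
    if isinstance(freezing_by_interval, Mapping):
        if "PS4" not in freezing_by_interval:
            raise ValueError("missing PS4 interval; CFA undefined")
        return float(freezing_by_interval["PS4"])
    vals = list(freezing_by_interval)
    if len(vals) < 4:
        raise ValueError("need four postshock intervals; PS4 missing")
    return float(vals[3])


@dataclass(frozen=True)
class ChanceTestResult:
    """One-sample t-test of strain performance against chance level."""

    classification: str           # above | not-distinguishable | below | untested
    t: float
    ci_low: float
    ci_high: float
    n: int
    chance_level: float
    confidence: float


def chance_test(
    values: Sequence[float],
    chance_level: float = 50.0,
    confidence: float = 0.99,
) -> ChanceTestResult:
    """Classify a strain as above / below / indistinguishable from chance.

    Uses the two-sided one-sample t confidence interval: "above" iff the
    whole interval lies above ``chance_level``, "below" iff entirely below.
    Strains with fewer than 3 animals are flagged untested (the design
    requires n > 2 for the within-strain test).
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if n < 3:
        return ChanceTestResult("untested", np.nan, np.nan, np.nan, n,
                                chance_level, confidence)
    mean = vals.mean()
    sd = vals.std(ddof=1)
    se = sd / np.sqrt(n)
    if se == 0:
        t_stat = 0.0 if mean == chance_level else np.inf * np.sign(mean - chance_level)
        lo = hi = mean
    else:
        t_stat = (mean - chance_level) / se
        t_crit = stats.t.ppf(0.5 + confidence / 2, df=n - 1)
        lo, hi = mean - t_crit * se, mean + t_crit * se
    if lo > chance_level:
        cls = "above"
    elif hi < chance_level:
        cls = "below"
    else:
        cls = "not-distinguishable"
    return ChanceTestResult(cls, float(t_stat), float(lo), float(hi), n,
                            chance_level, confidence)


REQUIRED_COLUMNS = ("animal_id", "strain", "age_months", "trait", "value")


def summarize_by_strain(records: pd.DataFrame) -> pd.DataFrame:
    """Per (strain, trait, age) n / mean / sample SD / SE.

    SD uses the n-1 denominator; SD and SE are NaN-flagged when n < 2.
    Duplicate (animal_id, age_months, trait) rows violate the unit of
    replication and raise.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"phenotype records missing columns: {missing}")
    if records.empty:
        return pd.DataFrame(
            columns=["strain", "trait", "age_months", "n", "mean", "sd", "se"]
        )
    dup = records.duplicated(subset=["animal_id", "age_months", "trait"])
    if dup.any():
        offending = records.loc[dup, ["animal_id", "age_months", "trait"]]
        raise ValueError(
            f"duplicate animal x age x trait rows:\n{offending.head()}"
        )
    grouped = records.groupby(["strain", "trait", "age_months"], sort=True)["value"]
    out = grouped.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
    out["sd"] = out["sd"].where(out["n"] >= 2)
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.reset_index()[
        ["strain", "trait", "age_months", "n", "mean", "sd", "se"]
    ]


def decline_scores(summaries: pd.DataFrame) -> pd.DataFrame:
    """Strain decline score per trait: mean at 14 months minus mean at 6.

    Strains lacking either age mean are omitted (and logged). The returned
    table keeps both age means alongside ``delta`` for downstream use.
    """
    wide = summaries.pivot_table(
        index=["strain", "trait"], columns="age_months", values="mean"
    )
    if 6 not in wide.columns or 14 not in wide.columns:
        raise ValueError("decline scores need summaries at both 6 and 14 months")
    incomplete = wide[wide[6].isna() | wide[14].isna()]
    if len(incomplete):
        logger.info("omitting %d strain x trait pairs missing an age mean",
                    len(incomplete))
    wide = wide.dropna(subset=[6, 14])
    out = wide.reset_index()
    out.columns.name = None
    out = out.rename(columns={6: "mean_6m", 14: "mean_14m"})
    out["delta"] = out["mean_14m"] - out["mean_6m"]
    return out.sort_values(["strain", "trait"]).reset_index(drop=True)


def age_effect_anova(records: pd.DataFrame, trait: str) -> tuple[float, float]:
    """One-way ANOVA of animal-level values on age group for one trait."""
    sub = records[records["trait"] == trait]
    groups = [g["value"].to_numpy(dtype=float)
              for _, g in sub.groupby("age_months", sort=True)]
    if len(groups) < 2:
        raise ValueError(f"trait {trait!r}: need both age groups for ANOVA")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0     # degenerate: no variance at all
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def chance_tests_by_strain(
    records: pd.DataFrame,
    trait: str = "ymaze_alt",
    chance_level: float = 50.0,
    confidence: float = 0.99,
) -> pd.DataFrame:
    """Run the above-chance test for every strain x age on one trait."""
    sub = records[records["trait"] == trait]
    rows = []
    for (strain, age), g in sub.groupby(["strain", "age_months"], sort=True):
        res = chance_test(g["value"].to_numpy(), chance_level, confidence)
        rows.append({
            "strain": strain, "trait": trait, "age_months": age,
            "classification": res.classification, "t": res.t,
            "ci_low": res.ci_low, "ci_high": res.ci_high, "n": res.n,
        })
    return pd.DataFrame.from_records(rows)
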