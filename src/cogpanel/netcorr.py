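"""Expression filtering, module eigengenes, module-trait screens, hub genes.

Module *construction* (co-expression clustering) is taken as given: the
inputs are a strain-averaged expression matrix and a gene -> module
assignment table. This module implements the downstream screen:

* abundance filtering (keep genes with >= 1 TPM in >= 50% of samples, both
  bounds inclusive, by default);
* the module eigengene — first principal component of the standardized
  member-gene submatrix, unit variance, sign-oriented to correlate
  positively with mean member expression;
* Pearson eigengene-trait correlations with Benjamini-Hochberg FDR control
  (family = modules within one trait x age);
* hub genes by intramodular connectivity k_i = sum_j |cor(x_i, x_j)|^beta.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def filter_expression(
    raw: pd.DataFrame, min_tpm: float = 1.0, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Keep genes with value >= ``min_tpm`` in >= ``min_fraction`` of samples."""
    if raw.empty:
        raise ValueError("expression matrix is empty")
    frac = (raw >= min_tpm).mean(axis=1)
    keep = frac >= min_fraction
    out = raw.loc[keep]
    logger.info("expression filter: retained %d / %d genes", keep.sum(), len(raw))
    if out.empty:
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return out


def module_eigengene(
    expr: pd.DataFrame, member_genes: list[str] | pd.Index
) -> pd.Series:
    """First principal component of a module's standardized expression.

    Returned over strains with unit variance (n-1 denominator), signed so
    that its correlation with the mean standardized member expression is
    non-negative. A single-gene module yields that gene's standardized
    profile.
    """
    member_genes = list(member_genes)
    if len(member_genes) == 0:
        raise ValueError("module has no member genes")
    missing = [g for g in member_genes if g not in expr.index]
    if missing:
        raise KeyError(f"member genes absent from expression matrix: {missing}")
    sub = expr.loc[member_genes].to_numpy(dtype=float)   # genes x strains
    sds = sub.std(axis=1, ddof=1)
    if np.any(sds == 0):
        flat = [g for g, sd in zip(member_genes, sds) if sd == 0]
        raise ValueError(f"member genes with zero variance: {flat}")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sds[:, None]
    # first right singular vector = PC1 scores across strains
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc1 = vt[0]
    pc1 = pc1 / pc1.std(ddof=1)
    if np.corrcoef(pc1, z.mean(axis=0))[0, 1] < 0:
        pc1 = -pc1
    return pd.Series(pc1, index=expr.columns, name="eigengene")


def module_eigengenes(
    expr: pd.DataFrame, assignments: pd.DataFrame,
    min_module_size: int = 1, skip_modules: tuple[str, ...] = ("background",),
) -> pd.DataFrame:
    """Eigengene per module (modules x strains) from an assignment table."""
    rows = {}
    for module, sub in assignments.groupby("module", sort=True):
        if module in skip_modules:
            continue
        genes = [g for g in sub["gene"] if g in expr.index]
        if len(genes) < min_module_size:
            logger.warning("module %s below minimum size after filtering "
                           "(%d genes); skipped", module, len(genes))
            continue
        if not genes:
            continue
        rows[str(module)] = module_eigengene(expr, genes)
    return pd.DataFrame(rows).T


def module_trait_correlations(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    fdr: float = 0.05,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Pearson eigengene-trait screen with BH adjustment per trait x age.

    ``eigengenes`` is modules x strains; ``traits`` a strain-summary table
    (strain, trait, age_months, mean). Strains lacking either value are
    dropped pairwise; fewer than ``min_shared`` shared strains raises.
    """
    records = []
    for (trait, age), sub in traits.groupby(["trait", "age_months"], sort=True):
        tvals = sub.set_index("strain")["mean"]
        fam = []
        for module in eigengenes.index:
            ev = eigengenes.loc[module].dropna()
            shared = [s for s in ev.index if s in tvals.index
                      and np.isfinite(tvals[s])]
            if len(shared) < min_shared:
                raise ValueError(
                    f"module {module} x {trait}@{age}m: only {len(shared)} "
                    f"shared strains (need >= {min_shared})"
                )
            if len(shared) < len(ev):
                logger.info("module %s x %s@%sm: dropped %d strains pairwise",
                            module, trait, age, len(ev) - len(shared))
            r, p = stats.pearsonr(ev.loc[shared], tvals.loc[shared])
            fam.append({"module": module, "trait": trait, "age_months": age,
                        "r": float(r), "p_raw": float(p), "n_strains": len(shared)})
        pvals = np.array([f["p_raw"] for f in fam])
        _, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        for f, q in zip(fam, qvals):
            f["q_fdr"] = float(q)
            f["significant"] = bool(q < fdr)
        records.extend(fam)
    out = pd.DataFrame.from_records(records)
    return out.sort_values(["trait", "age_months", "module"]).reset_index(drop=True)


class ModuleTraitCorrelator(BaseEstimator):
    """Estimator-style module-eigengene / trait correlation screen.

    ``fit(expr, traits, assignments=...)`` computes eigengenes (or accepts a
    precomputed modules x strains frame as ``expr``) and stores the screen
    in ``results_``.
    """

    def __init__(self, fdr: float = 0.05, min_shared: int = 3,
                 min_module_size: int = 1):
        self.fdr = fdr
        self.min_shared = min_shared
        self.min_module_size = min_module_size

    def fit(self, expr: pd.DataFrame, traits: pd.DataFrame,
            assignments: pd.DataFrame | None = None):
        if assignments is not None:
            eig = module_eigengenes(expr, assignments,
                                    min_module_size=self.min_module_size)
        else:
            eig = expr
        self.eigengenes_ = eig
        self.results_ = module_trait_correlations(
            eig, traits, fdr=self.fdr, min_shared=self.min_shared
        )
        self.significant_ = self.results_[self.results_["significant"]]
        return self


def hub_gene(
    expr: pd.DataFrame, member_genes: list[str] | pd.Index, soft_power: float = 6
) -> str:
    """Member gene with the highest intramodular connectivity.

    Connectivity of gene i is sum over j != i of |cor(x_i, x_j)|^soft_power.
    Ties (including the symmetric two-gene module) resolve to the
    lexicographically first gene id.
    """
    member_genes = sorted(str(g) for g in member_genes)
    if len(member_genes) == 0:
        raise ValueError("module has no member genes")
    missing = [g for g in member_genes if g not in expr.index]
    if missing:
        raise KeyError(f"member genes absent from expression matrix: {missing}")
    if len(member_genes) == 1:
        logger.warning("single-gene module: hub is degenerate")
        return member_genes[0]
    sub = expr.loc[member_genes].to_numpy(dtype=float)
    corr = np.corrcoef(sub)
    k = (np.abs(corr) ** soft_power).sum(axis=1) - 1.0   # drop self-term
    best = int(np.argmax(k))     # argmax returns the first (lexicographic) tie
    return member_genes[best]


def hub_genes(
    expr: pd.DataFrame, assignments: pd.DataFrame, soft_power: float = 6,
    skip_modules: tuple[str, ...] = ("background",),
) -> pd.DataFrame:
    rows = []
    for module, sub in assignments.groupby("module", sort=True):
        if module in skip_modules:
            continue
        genes = [g for g in sub["gene"] if g in expr.index]
        if not genes:
            continue
        rows.append({"module": module,
                     "hub_gene": hub_gene(expr, genes, soft_power)})
    return pd.DataFrame.from_records(rows)
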