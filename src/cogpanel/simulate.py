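"""Synthetic strain-panel generator with known ground truth.

Emulates the statistical structure of a recombinant-inbred backcross panel:

* strain-level genotypes on a marker map, two states per locus
  (0 = B6/B6 homozygote, 1 = B6/D2 heterozygote — an F1 backcross design
  never shows the D2 homozygote, so recessive D2 effects are invisible);
* strain genetic values for bounded percentage traits, with replicate
  animals drawn around them (between-strain variance Va, within-strain
  variance Ve), strain-specific decline between 6 and 14 months, and an
  optional planted QTL explaining a stated share of Va;
* strain-averaged expression with latent module eigengenes correlated to a
  trait at a stated r, plus background noise genes;
* raw y-maze arm-entry sequences with a controllable alternation rate.

Every draw descends from one global seed through named child streams
(genotypes / phenotypes / expression / arm_entries / permutations), so the
same seed reproduces each component bit-for-bit and adding a stream does
not perturb the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CROSS_SECTIONAL_TRAITS, LONGITUDINAL_TRAITS, SimulationConfig

logger = logging.getLogger(__name__)

AGES = (6, 14)

_STREAMS = ("genotypes", "phenotypes", "expression", "arm_entries", "permutations")


def stream_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Named, independent random streams derived from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


@dataclass
class GenotypeMatrix:
    """Strain-level genotypes plus a (chromosome, cM) marker map.

    ``calls`` is markers x strains with values in {0, 1}; genotype is a
    strain property, shared by every replicate animal of the strain.
    """

    map: pd.DataFrame            # columns: marker, chromosome, position_cM
    calls: pd.DataFrame          # index: marker ids; columns: strain ids

    def __post_init__(self) -> None:
        if list(self.map["marker"]) != list(self.calls.index):
            raise ValueError("marker map and call matrix are out of order")
        for _, chrom_map in self.map.groupby("chromosome", sort=False):
            pos = chrom_map["position_cM"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must strictly increase within chromosome")

    @property
    def strains(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def markers(self) -> list[str]:
        return list(self.calls.index)

    def marker_id(self, chromosome: int, marker_index: int) -> str:
        sub = self.map[self.map["chromosome"] == chromosome]
        if marker_index >= len(sub):
            raise IndexError(
                f"marker index {marker_index} outside chromosome {chromosome}"
            )
        return str(sub["marker"].iloc[marker_index])


@dataclass
class PanelTruth:
    """Generating values retained for parameter-recovery checks."""

    strain_values: pd.DataFrame      # strain, trait, age_months, genetic_value
    declines: pd.DataFrame           # strain, trait, decline
    qtl_marker: str | None = None
    qtl_beta: float = 0.0
    truncation_events: int = 0
    module_assignments: pd.DataFrame | None = None
    module_eigengenes: pd.DataFrame | None = None   # modules x strains (latent)


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw panel genotypes as a two-state Markov chain along each chromosome.

    The chain starts from the stationary allele frequency 0.5 and switches
    state between adjacent markers with probability equal to the configured
    recombination fraction; chromosomes and strains are independent.
    """
    if rng is None:
        rng = stream_rngs(config.seed)["genotypes"]
    r = config.adjacent_marker_recomb_fraction
    n_s = config.n_strains
    n_c, n_m = config.n_chromosomes, config.markers_per_chromosome

    markers, chroms, positions, blocks = [], [], [], []
    for c in range(n_c):
        start = rng.integers(0, 2, size=n_s)
        switches = rng.random(size=(n_m - 1, n_s)) < r
        states = np.empty((n_m, n_s), dtype=np.int8)
        states[0] = start
        for m in range(1, n_m):
            states[m] = np.where(switches[m - 1], 1 - states[m - 1], states[m - 1])
        blocks.append(states)
        markers.extend(f"c{c + 1:02d}m{m + 1:03d}" for m in range(n_m))
        chroms.extend([c] * n_m)
        positions.extend(config.marker_spacing_cm * (m + 1) for m in range(n_m))

    calls = pd.DataFrame(
        np.vstack(blocks), index=markers, columns=config.strain_ids(), dtype=np.int8
    )
    marker_map = pd.DataFrame(
        {"marker": markers, "chromosome": chroms, "position_cM": positions}
    )
    return GenotypeMatrix(map=marker_map, calls=calls)


def _strain_genetic_values(
    config: SimulationConfig,
    trait: str,
    geno: GenotypeMatrix,
    rng: np.random.Generator,
) -> tuple[np.ndarray, str | None, float]:
    """Baseline strain genetic values: QTL effect + polygenic remainder."""
    va = config.va_for(trait)
    base = config.baseline_for(trait)
    n = config.n_strains
    qtl_marker, beta = None, 0.0
    values = np.full(n, base, dtype=float)

    poly_va = va
    if config.qtl_spec is not None and config.qtl_spec.trait == trait and va > 0:
        q = config.qtl_spec
        qtl_marker = geno.marker_id(q.chromosome, q.marker_index)
        g = geno.calls.loc[qtl_marker].to_numpy(dtype=float)
        var_g = g.var(ddof=0)
        if var_g == 0:
            logger.warning("planted QTL marker %s is monomorphic; effect dropped",
                           qtl_marker)
        else:
            beta = np.sqrt(q.pve * va / var_g)
            values = values + beta * (g - g.mean())
            poly_va = (1.0 - q.pve) * va
    if poly_va > 0:
        values = values + rng.normal(0.0, np.sqrt(poly_va), size=n)
    return values, qtl_marker, beta


def simulate_phenotypes(
    config: SimulationConfig,
    geno: GenotypeMatrix,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, PanelTruth]:
    """Draw replicate animal records around strain genetic values.

    Longitudinal traits reuse the same animals at both ages; cross-sectional
    traits get distinct cohorts per age (mirroring a repeated y-maze versus a
    terminal fear-conditioning design). Values are truncated to [0, 100] and
    truncation events are counted in the returned truth object.
    """
    if geno.strains != config.strain_ids():
        raise ValueError("genotype strains do not match configuration")
    if rng is None:
        rng = stream_rngs(config.seed)["phenotypes"]

    reps = config.reps_for_all_strains()
    strains = config.strain_ids()
    records: list[dict] = []
    truth_rows: list[dict] = []
    decline_rows: list[dict] = []
    qtl_marker_out, qtl_beta_out = None, 0.0
    truncated = 0

    for trait in config.traits:
        ve = config.ve_for(trait)
        sd_e = np.sqrt(ve)
        values6, qtl_marker, beta = _strain_genetic_values(config, trait, geno, rng)
        declines = rng.normal(config.decline_mean, config.decline_sd,
                              size=config.n_strains)
        if config.decline_sd == 0:
            declines = np.full(config.n_strains, config.decline_mean)
        values14 = values6 + declines
        if qtl_marker is not None:
            qtl_marker_out, qtl_beta_out = qtl_marker, beta
        longitudinal = trait in LONGITUDINAL_TRAITS

        for s_idx, strain in enumerate(strains):
            n_rep = reps[s_idx]
            truth_rows.append({"strain": strain, "trait": trait, "age_months": 6,
                               "genetic_value": values6[s_idx]})
            truth_rows.append({"strain": strain, "trait": trait, "age_months": 14,
                               "genetic_value": values14[s_idx]})
            decline_rows.append({"strain": strain, "trait": trait,
                                 "decline": declines[s_idx]})
            for age, strain_value in zip(AGES, (values6[s_idx], values14[s_idx])):
                noise = rng.normal(0.0, sd_e, size=n_rep) if ve > 0 else np.zeros(n_rep)
                vals = strain_value + noise
                clipped = np.clip(vals, 0.0, 100.0)
                truncated += int(np.sum(clipped != vals))
                cohort = "L" if longitudinal else f"X{age}"
                for r_i in range(n_rep):
                    records.append({
                        "animal_id": f"{strain}_{trait}_{cohort}_{r_i + 1}",
                        "strain": strain,
                        "sex": "F",
                        "age_months": age,
                        "trait": trait,
                        "value": clipped[r_i],
                    })

    if truncated:
        logger.info("truncated %d simulated values to [0, 100]", truncated)
    pheno = pd.DataFrame.from_records(records)
    truth = PanelTruth(
        strain_values=pd.DataFrame.from_records(truth_rows),
        declines=pd.DataFrame.from_records(decline_rows),
        qtl_marker=qtl_marker_out,
        qtl_beta=qtl_beta_out,
        truncation_events=truncated,
    )
    return pheno, truth


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def simulate_expression(
    config: SimulationConfig,
    strain_trait_means: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Strain-averaged expression with module structure tied to a trait.

    Parameters
    ----------
    strain_trait_means
        Strain summaries with columns ``strain``, ``trait``, ``age_months``
        and ``mean``; one row per strain for the configured target trait/age.

    Returns
    -------
    expression : genes x strains TPM-like matrix
    assignments : gene -> module table (module "background" for noise genes)
    latents : modules x strains latent eigengene matrix (ground truth)

    Each module's latent eigengene is built by mixing the standardized trait
    vector with noise residualized against it, so the *sample* correlation
    with the trait equals the requested r exactly. Member genes are
    ``loading * eigengene + noise`` with noise variance 1 - loading^2, i.e.
    the loading is the gene-eigengene correlation in expectation.
    """
    if rng is None:
        rng = stream_rngs(config.seed)["expression"]
    sel = strain_trait_means[
        (strain_trait_means["trait"] == config.expression_target_trait)
        & (strain_trait_means["age_months"] == config.expression_target_age)
    ]
    sel = sel.set_index("strain").loc[config.strain_ids()]
    trait_z = _standardize(sel["mean"].to_numpy(dtype=float))
    n_s = len(trait_z)

    rows, gene_ids, assign = [], [], []
    latent_rows = {}
    lo, hi = config.module_loading_range
    for m, r in enumerate(config.module_trait_rs()):
        module = f"module{m + 1:02d}"
        noise = rng.normal(size=n_s)
        # residualize against the trait so the sample correlation is exact
        resid = noise - (noise @ trait_z) / (trait_z @ trait_z) * trait_z
        if np.allclose(resid, 0):
            resid = rng.normal(size=n_s)
        eig = r * trait_z + np.sqrt(max(0.0, 1 - r * r)) * _standardize(resid)
        latent_rows[module] = eig
        loadings = rng.uniform(lo, hi, size=config.genes_per_module)
        for g_i, lam in enumerate(loadings):
            gene = f"{module}_g{g_i + 1:03d}"
            noise_sd = np.sqrt(max(0.0, 1 - lam * lam))
            profile = lam * eig + rng.normal(0.0, noise_sd, size=n_s)
            rows.append(profile)
            gene_ids.append(gene)
            assign.append({"gene": gene, "module": module})
    for b in range(config.n_background_genes):
        gene = f"bg_g{b + 1:04d}"
        rows.append(rng.normal(size=n_s))
        gene_ids.append(gene)
        assign.append({"gene": gene, "module": "background"})

    # shift/scale standardized profiles to a nonnegative TPM-like range
    raw = np.vstack(rows)
    tpm = np.clip(20.0 + 5.0 * raw, 0.0, None)
    expression = pd.DataFrame(tpm, index=gene_ids, columns=config.strain_ids())
    assignments = pd.DataFrame.from_records(assign)
    latents = pd.DataFrame(latent_rows, index=config.strain_ids()).T
    return expression, assignments, latents


ARMS = ("A", "B", "C")


def simulate_arm_entries(
    p_alt: float,
    n_entries: int,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Y-maze arm-entry sequence with alternation probability ``p_alt``.

    Consecutive entries never repeat an arm (an entry implies leaving the
    previous arm). From the third entry on, the arm completing a distinct
    triplet is chosen with probability ``p_alt``; otherwise the sequence
    returns to the arm visited two steps back. The expected spontaneous
    alternation score is therefore ~100 * p_alt.
    """
    if n_entries < 3:
        raise ValueError("need at least 3 entries for an alternation sequence")
    if not 0.0 <= p_alt <= 1.0:
        raise ValueError("p_alt must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    first = rng.integers(0, 3)
    second = (first + rng.integers(1, 3)) % 3
    seq = [int(first), int(second)]
    alternate = rng.random(size=n_entries - 2) < p_alt
    for i in range(n_entries - 2):
        prev2, prev = seq[-2], seq[-1]
        novel = 3 - prev - prev2   # the arm distinct from the last two
        seq.append(novel if alternate[i] else prev2)
    return [ARMS[i] for i in seq]
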