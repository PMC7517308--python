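"""End-to-end orchestration: simulate -> score -> map -> correlate -> classify.

``run_pipeline`` executes every enabled stage in dependency order on a
simulated panel, writes each intermediate table as plain text, and finishes
with a machine-readable manifest (seed, configuration hash, SHA-256 of
every output). The same configuration and seed reproduce every output file
byte for byte. A stage failure leaves a ``FAILED`` marker naming the stage,
with earlier outputs retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior, classify, io, netcorr, quantgen
from .config import PipelineConfig
from .simulate import (
    simulate_expression,
    simulate_genotypes,
    simulate_phenotypes,
    stream_rngs,
)

logger = logging.getLogger(__name__)


def correlate_baseline_to_later(
    summaries: pd.DataFrame, declines: pd.DataFrame, min_strains: int = 3
) -> pd.DataFrame:
    """Pearson correlations of 6-month strain means with 14-month means and
    with decline scores, per trait.

    The 6m-vs-delta correlation carries a built-in regression-to-the-mean
    artifact: when delta = later - baseline, measurement noise in the
    baseline enters delta with a negative sign, pushing the correlation
    negative even for independent ages. Interpret it accordingly.
    """
    rows = []
    for trait, sub in declines.groupby("trait", sort=True):
        sub = sub.dropna(subset=["mean_6m", "mean_14m", "delta"])
        if len(sub) < min_strains:
            raise ValueError(
                f"trait {trait!r}: only {len(sub)} strains with both ages "
                f"(need >= {min_strains})"
            )
        r_ll, p_ll = stats.pearsonr(sub["mean_6m"], sub["mean_14m"])
        r_ld, p_ld = stats.pearsonr(sub["mean_6m"], sub["delta"])
        rows.append({
            "trait": trait, "n_strains": len(sub),
            "r_6m_vs_14m": float(r_ll), "p_6m_vs_14m": float(p_ll),
            "r_6m_vs_delta": float(r_ld), "p_6m_vs_delta": float(p_ld),
        })
    del summaries  # interface symmetry; declines already carry both means
    return pd.DataFrame.from_records(rows)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every enabled stage; return the manifest dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = stream_rngs(config.seed)
    sim = config.simulation
    stage = "start"
    counts: dict[str, int] = {}
    try:
        # ---------------- simulate ----------------
        stage = "simulate"
        geno = simulate_genotypes(sim, rngs["genotypes"])
        pheno, truth = simulate_phenotypes(sim, geno, rngs["phenotypes"])
        io.write_genotypes(geno, out / "genotypes.tsv")
        io.write_phenotypes(pheno, out / "phenotypes.csv")
        io.write_table(truth.strain_values, out / "truth_strain_values.csv")
        io.write_table(truth.declines, out / "truth_declines.csv")
        counts["animals"] = int(pheno["animal_id"].nunique())
        counts["truncation_events"] = truth.truncation_events
        counts["strains"] = sim.n_strains
        counts["markers"] = len(geno.markers)
        logger.info("simulated %d animals on %d strains, %d markers",
                    counts["animals"], counts["strains"], counts["markers"])

        # ---------------- behavior ----------------
        stage = "behavior"
        summaries = behavior.summarize_by_strain(pheno)
        declines = behavior.decline_scores(summaries)
        chance = behavior.chance_tests_by_strain(
            pheno, chance_level=config.chance_level,
            confidence=config.chance_confidence,
        )
        anova_rows = []
        for trait in sim.traits:
            f, p = behavior.age_effect_anova(pheno, trait)
            anova_rows.append({"trait": trait, "F": f, "p": p})
        io.write_table(summaries, out / "strain_summaries.csv")
        io.write_table(declines, out / "decline_scores.csv")
        io.write_table(chance, out / "chance_tests.csv")
        io.write_table(pd.DataFrame.from_records(anova_rows),
                       out / "age_anova.csv")

        # ---------------- heritability ----------------
        stage = "heritability"
        h2 = quantgen.heritability_table(pheno)
        io.write_table(h2, out / "heritability.csv")

        # ---------------- scan ----------------
        stage = "scan"
        scan_rows, thr_obj = [], {}
        scan_targets = [(t, a) for t in sim.traits for a in (6, 14)]
        for trait, age in scan_targets:
            means = summaries[(summaries["trait"] == trait)
                              & (summaries["age_months"] == age)]
            res = quantgen.marker_regression_scan(
                geno, means, lod_cap=config.lod_cap)
            thr = quantgen.permutation_threshold(
                geno, means, n_perm=config.n_perm, alphas=config.scan_alphas,
                seed=rngs["permutations"], lod_cap=config.lod_cap)
            frame = res.to_frame()
            frame.insert(0, "trait", trait)
            frame.insert(1, "age_months", age)
            scan_rows.append(frame)
            thr_obj[f"{trait}@{age}m"] = {
                "peak_marker": res.peak_marker, "peak_lod": res.peak_lod,
                "thresholds": {str(a): v for a, v in thr.items()},
            }
        if config.scan_declines:
            for trait in sim.traits:
                means = declines[declines["trait"] == trait].set_index(
                    "strain")["delta"].rename("mean")
                res = quantgen.marker_regression_scan(
                    geno, means, lod_cap=config.lod_cap)
                thr = quantgen.permutation_threshold(
                    geno, means, n_perm=config.n_perm,
                    alphas=config.scan_alphas, seed=rngs["permutations"],
                    lod_cap=config.lod_cap)
                frame = res.to_frame()
                frame.insert(0, "trait", f"{trait}_decline")
                frame.insert(1, "age_months", -1)
                scan_rows.append(frame)
                thr_obj[f"{trait}_decline"] = {
                    "peak_marker": res.peak_marker, "peak_lod": res.peak_lod,
                    "thresholds": {str(a): v for a, v in thr.items()},
                }
        io.write_table(pd.concat(scan_rows, ignore_index=True),
                       out / "scans.csv")
        io.write_json(thr_obj, out / "scan_thresholds.json")
        counts["permutations_per_scan"] = config.n_perm

        # ---------------- power ----------------
        stage = "power"
        thr05 = [v["thresholds"][str(config.scan_alphas[0])]
                 for v in thr_obj.values()]
        median_thr = float(np.median(thr05))
        power = quantgen.power_table(
            n_strains=sim.n_strains, threshold_lod=median_thr,
            pves=(0.1, 0.2, 0.3, 0.4, config.power_pve),
            power_target=config.power_target,
        )
        io.write_table(power, out / "power.csv")

        # ---------------- expression / netcorr ----------------
        if config.run_expression:
            stage = "netcorr"
            expr, assignments, latents = simulate_expression(
                sim, summaries, rngs["expression"])
            io.write_expression(expr, out / "expression.tsv")
            io.write_table(assignments, out / "module_assignments.csv")
            filtered = netcorr.filter_expression(expr)
            counts["genes_filtered_out"] = len(expr) - len(filtered)
            eig = netcorr.module_eigengenes(filtered, assignments)
            corr = netcorr.module_trait_correlations(
                eig, summaries, fdr=config.fdr)
            hubs = netcorr.hub_genes(filtered, assignments)
            eig_out = eig.sort_index()
            eig_out.insert(0, "module", eig_out.index)
            eig_out.to_csv(out / "eigengenes.csv", index=False)
            io.write_table(corr, out / "module_trait_correlations.csv")
            io.write_table(hubs, out / "hub_genes.csv")
            io.write_table(latents.reset_index(names="module"),
                           out / "truth_module_eigengenes.csv")
            counts["significant_module_trait_pairs"] = int(
                corr["significant"].sum())

        # ---------------- classify ----------------
        if config.run_classifier:
            stage = "classify"
            comp = classify.composite_scores(summaries)
            io.write_table(comp, out / "composite_scores.csv")
            calls = []
            for basis in (*sim.traits, classify.COMPOSITE):
                for stringency in classify.STRINGENCIES:
                    calls.append(classify.classify_panel(
                        summaries, declines, basis=basis,
                        stringency=stringency))
            calls_df = pd.concat(calls, ignore_index=True)
            io.write_table(calls_df, out / "classification_calls.csv")
            io.write_json(classify.classification_report(calls_df),
                          out / "classification_summary.json")

        # ---------------- baseline correlations ----------------
        stage = "baseline-corr"
        base_corr = correlate_baseline_to_later(summaries, declines)
        io.write_table(base_corr, out / "baseline_correlations.csv")

    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "manifest"
    outputs = sorted(p.name for p in out.iterdir()
                     if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "config": config.to_dict(),
        "counts": counts,
        "outputs": {name: io.sha256_of(out / name) for name in outputs},
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
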