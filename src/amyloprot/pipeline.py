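"""End-to-end orchestration: synthesis -> filtering -> batch adjustment ->
differential abundance (pairwise + full model) -> trajectory classification ->
cross-species concordance -> candidate funnel -> side analyses -> CSF
biomarker evaluation.

A run is fully determined by its :class:`RunConfig` (hashed into every
artifact header); re-running with the same config yields identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import simulate
from .aux_analyses import intersect_deg_dep, wt_median_split
from .batch import combat_adjust
from .biomarker import CSFBiomarkerEvaluator
from .correlation import classify_dep_trajectories
from .cross_species import (
    concordance,
    cross_correlation,
    make_signatures,
    overlap_report,
    resolve_orthologs,
)
from .diffexpr import estimate_consensus_correlation, fit_contrasts, pairwise_fit
from .filtering import filter_tissue, full_model_set
from .io_tables import IntensityMatrix, write_diff_table
from .simulate import preset_5xfad, preset_smoke


@dataclass
class RunConfig:
    """Everything a run depends on; serializable and hashed."""

    seed: int = 0
    preset: str = "5xfad"  # or "5xfad-smoke"
    n_proteins: int | None = None
    fdr: float = 0.05
    alpha: float = 0.05
    reading: str = "all-conditions"
    rho: object = "auto"
    concordance_rule: str = "any"
    funnel_top_k: int = 25
    funnel_rank_by: str = "moderated_stat"
    annotation_terms: tuple = ("lysosome", "endo-lysosomal")
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["annotation_terms"] = list(self.annotation_terms)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _mouse_dataset_tables(pairwise: pd.DataFrame, symbol_of: dict) -> dict:
    """H5 / H8 / C8 tables (gene_symbol, logfc, significant) from pairwise results."""
    keys = {"H5": "DE.hippo.Age5", "H8": "DE.hippo.Age8", "C8": "DE.cortex.Age8"}
    out = {}
    for name, cid in keys.items():
        sub = pairwise[pairwise["contrast_id"] == cid].copy()
        sub["gene_symbol"] = sub["protein_id"].map(symbol_of)
        out[name] = sub[["gene_symbol", "protein_id", "logfc", "significant"]]
    return out


def run_all(config: RunConfig) -> dict:
    """Execute every stage in dependency order; returns results + manifest."""
    if config.preset in ("5xfad", "default"):
        design, params = preset_5xfad(config.seed, config.n_proteins or 4000)
    elif config.preset in ("5xfad-smoke", "smoke"):
        design, params = preset_smoke(config.seed, config.n_proteins or 200)
    else:
        raise ValueError(f"unknown preset {config.preset!r}")

    # --- synthesis
    matrix, truth = simulate.simulate_lfq(design, params)
    trajectories = simulate.simulate_abeta_trajectories(design, params)
    human_tables, ortho_map = simulate.simulate_human_tables(params, truth)
    csf = simulate.simulate_csf(params)
    deg = simulate.simulate_deg_table(params, truth)
    annotations = simulate.simulate_annotations(params, truth)
    symbol_of = dict(truth.gene_symbols)

    # --- per-tissue filtering and batch adjustment
    filtered, reports, adjusted = {}, {}, {}
    for tissue in design.tissues:
        filt, rep = filter_tissue(matrix, tissue, reading=config.reading)
        filtered[tissue] = filt
        reports[tissue] = rep
        adjusted[tissue], _ = combat_adjust(filt, covariates=("age", "genotype"))

    rho = config.rho
    if rho == "auto":
        rho = estimate_consensus_correlation(adjusted["hippocampus"])

    # --- pairwise model
    pairwise_frames = []
    for tissue in design.tissues:
        for age in design.ages:
            pairwise_frames.append(
                pairwise_fit(adjusted[tissue], tissue, age, rho=rho, fdr=config.fdr)
            )
    pairwise = pd.concat(pairwise_frames, ignore_index=True)

    # --- full model on the cross-tissue reconciled universe
    pairs, full_report = full_model_set(adjusted["cortex"], adjusted["hippocampus"])
    common = sorted(set(pairs["cortex_id"]))
    meta = pd.concat(
        [adjusted[t].sample_meta for t in design.tissues], ignore_index=True
    )
    values = pd.concat(
        [adjusted[t].values.loc[common] for t in design.tissues], axis=1
    )
    combined = IntensityMatrix(values, meta, matrix.gene_symbols)
    full_results, moderation = fit_contrasts(combined, rho=rho, fdr=config.fdr)

    # --- trajectory classification (pairwise DEP universe)
    traj = {
        t: simulate.trajectories_by_tissue(trajectories, t) for t in design.tissues
    }
    families, classification = classify_dep_trajectories(
        pairwise, traj, alpha=config.alpha, ages=design.ages
    )

    # --- cross-species
    resolution = resolve_orthologs(ortho_map)
    mouse_diff = _mouse_dataset_tables(pairwise, symbol_of)
    mouse_sig_sets = {
        name: set(t.loc[t["significant"], "gene_symbol"]) for name, t in mouse_diff.items()
    }
    human_sig_sets = {
        name: set(t.loc[t["significant"], "gene_symbol"]) for name, t in human_tables.items()
    }
    overlaps = overlap_report(mouse_sig_sets, human_sig_sets, resolution)
    cset = concordance(mouse_diff, human_tables, resolution, rule=config.concordance_rule)
    signature = make_signatures(cset) if len(cset) else None
    xcorr = cross_correlation(mouse_diff, human_tables, resolution, mode="all")

    # --- candidate funnel (hippocampus)
    funnel_report = None
    from .funnel import run_funnel  # local import to avoid cycle in docs builds

    funnel_report = run_funnel(
        present_set=set(filtered["hippocampus"].protein_ids),
        dep_table=pairwise,
        human_significant=human_sig_sets,
        concordant=cset,
        corr_families=families,
        annotations=annotations,
        symbol_of=symbol_of,
        human_symbol_of=resolution.mouse_to_human(),
        tissue="hippocampus",
        top_k=config.funnel_top_k,
        rank_by=config.funnel_rank_by,
        annotation_terms=config.annotation_terms,
    )

    # --- side analyses
    corr_union = families["c_corr"] | families["c_acorr"] | families["h_corr"] | families["h_acorr"]
    corr_symbols = {symbol_of[p] for p in corr_union}
    deg_overlap, deg_fraction = (
        intersect_deg_dep(deg, corr_symbols) if corr_symbols else (set(), float("nan"))
    )
    h8 = pairwise[pairwise["contrast_id"] == "DE.hippo.Age8"]
    wt_cols = adjusted["hippocampus"].sample_meta.query("genotype == 'WT' and age == 8")["sample"]
    wt_means = adjusted["hippocampus"].values[list(wt_cols)].mean(axis=1)
    wt_means = wt_means.loc[wt_means.index.isin(h8["protein_id"])]
    dep_flags = h8.set_index("protein_id")["significant"]
    wt_split = wt_median_split(wt_means.dropna(), dep_flags) if len(wt_means) >= 4 else None

    # --- CSF biomarker
    evaluator = CSFBiomarkerEvaluator().fit(csf)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "counts": {
            "proteins_simulated": int(matrix.n_proteins),
            "present": {t: reports[t].proteins_out for t in design.tissues},
            "full_model_universe": len(common),
            "pairwise_significant": int(pairwise["significant"].sum()),
            "full_model_significant": int(full_results["significant"].sum()),
            "dep_families": {k: len(v) for k, v in families.items()},
            "overlap_union": overlaps["union_overlap"],
            "concordant": int(len(cset)),
            "funnel": funnel_report.counts(),
            "deg_dep_overlap": len(deg_overlap),
        },
        "consensus_rho": float(rho),
        "moderation": {
            "prior_df": float(moderation.prior_df),
            "prior_var": float(moderation.prior_var),
        },
        "csf_auc": evaluator.auc_,
    }

    results = {
        "design": design,
        "params": params,
        "truth": truth,
        "matrix": matrix,
        "filtered": filtered,
        "adjusted": adjusted,
        "pairwise": pairwise,
        "full_results": full_results,
        "full_pairs": pairs,
        "families": families,
        "classification": classification,
        "trajectories": trajectories,
        "resolution": resolution,
        "overlaps": overlaps,
        "concordance": cset,
        "signature": signature,
        "cross_correlation": xcorr,
        "funnel": funnel_report,
        "deg_overlap": deg_overlap,
        "deg_fraction": deg_fraction,
        "wt_split": wt_split,
        "csf": evaluator,
        "manifest": manifest,
    }

    if config.out_dir:
        _write_outputs(results, config)
    return results


def _write_outputs(results: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    write_diff_table(results["pairwise"], out / "pairwise_diff.csv", config_hash=h)
    write_diff_table(results["full_results"], out / "full_model_diff.csv", config_hash=h)
    results["classification"].to_csv(out / "abeta_classification.csv", index=False)
    results["concordance"].to_csv(out / "concordance.csv", index=False)
    if results["signature"] is not None:
        results["signature"].sig_plus.to_csv(out / "signature_plus.csv", index=False)
        results["signature"].sig_minus.to_csv(out / "signature_minus.csv", index=False)
    results["cross_correlation"].to_csv(out / "cross_correlation.csv", index=False)
    results["funnel"].to_json(out / "funnel.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(results["manifest"], fh, indent=1, sort_keys=True)
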