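"""Synthetic-data generator emulating the study design.

Generates every input the pipeline consumes with the statistical structure the
analysis assumes: log10-scale LFQ intensities with intensity-dependent (MNAR)
missingness, additive/multiplicative acquisition-batch effects, planted
differential proteins with age-trajectory structure, planted aggregate-
correlated proteins, a planted lysosomal biomarker candidate, human
differential-abundance tables with controllable overlap and sign concordance,
an ortholog map with one-to-one / one-to-many / many-to-many rows, transcript
tables and two-group CSF analyte distributions.

All randomness flows from a single integer seed through named substreams, so
any one table can be regenerated in isolation and, for a fixed seed, outputs
are byte-identical across runs.

The generative model for protein g in sample (tissue t, age a, genotype G,
animal i, technical replicate r, batch b) is, on the log10 scale::

    x = baseline_g + lfc_g(t, a) * [G == TG] + gamma_{g,b} + animal_{g,i(t)}
        + eps_{g,r},

and the value is masked missing with probability
``expit(missing_slope * (missing_midpoint - x))`` — the standard logistic
MNAR assumption for label-free proteomics, which the no-imputation
reliability-filtering strategy guards against.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import StudyDesign
from .io_tables import HUMAN_DATASETS, IntensityMatrix

ABETA_READOUTS = ("MFA", "plaque_load", "plaque_count_6E10", "plaque_count_ThioS")

# named substreams: one child seed-sequence per generated table
_STREAMS = ("lfq", "abeta", "human", "ortholog", "csf", "deg", "annotations")


def _rng(seed: int, stream: str) -> np.random.Generator:
    if seed is None:
        raise ValueError("rng_seed must be set (reproducibility contract)")
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(_STREAMS.index(stream),))
    )


# ---------------------------------------------------------------------------
# parameters and ground truth
# ---------------------------------------------------------------------------

def _default_abeta_means() -> dict:
    # per-tissue 3-point means (ages 2, 5, 8); hippocampus strictly increasing
    # and steeper than cortex, with a ~10x MFA jump between 5 and 8 months in
    # hippocampus, mirroring the biology the design emulates.
    return {
        ("hippocampus", "MFA"): (0.02, 0.10, 1.00),
        ("hippocampus", "plaque_load"): (0.10, 1.50, 6.00),
        ("hippocampus", "plaque_count_6E10"): (20.0, 250.0, 900.0),
        ("hippocampus", "plaque_count_ThioS"): (10.0, 180.0, 700.0),
        ("cortex", "MFA"): (0.01, 0.05, 0.25),
        ("cortex", "plaque_load"): (0.05, 0.50, 2.00),
        ("cortex", "plaque_count_6E10"): (10.0, 90.0, 300.0),
        ("cortex", "plaque_count_ThioS"): (5.0, 60.0, 220.0),
    }


@dataclass
class CandidateSpec:
    """A planted lysosomal biomarker candidate.

    Hippocampus-specific, monotone increasing transgene effect proportional to
    the hippocampal aggregate trajectory, annotated as lysosomal, and
    concordantly upregulated in every human dataset.
    """

    tissue: str = "hippocampus"
    lfc_peak: float = 0.45  # log10 units at the oldest age
    lfc_offset: float = 0.25  # baseline transgene effect at the youngest age
    annotation_terms: tuple = ("lysosome", "endo-lysosomal")


@dataclass
class GeneratorParams:
    """Knobs of the synthetic world (log10-intensity scale unless noted)."""

    n_proteins: int = 4000
    baseline_mean: float = 7.0
    baseline_sd: float = 0.8
    animal_sd: float = 0.08
    tech_sd: float = 0.05
    missing_midpoint: float = 5.6
    missing_slope: float = 2.0
    batch_shifts: dict = field(default_factory=dict)  # batch label -> mean additive shift
    batch_shift_sd: float = 0.05  # per-protein jitter around the batch mean shift
    batch_scale_sd: float = 0.05  # log-sd of per-protein multiplicative noise scaling
    planted_dep_fraction: float = 0.10
    planted_lfc_range: tuple = (0.15, 0.5)  # |log10 LFC| at the oldest age
    n_abeta_corr: int = 50
    n_abeta_acorr: int = 30
    abeta_means: dict = field(default_factory=_default_abeta_means)
    abeta_cv: float = 0.2  # between-animal coefficient of variation of readouts
    candidate: CandidateSpec = field(default_factory=CandidateSpec)
    # human tables
    overlap_fraction: float = 0.5
    concordance_fraction: float = 0.8
    n_human_background: int = 1500
    human_sig_background_rate: float = 0.3
    ortholog_one_to_many: int = 20
    ortholog_many_to_many: int = 10
    # CSF
    n_cases: int = 38
    n_controls: int = 44
    csf_log_mean_control: float = np.log(250.0)  # pg/ml
    csf_log_sd: float = 0.45
    csf_effect_d: float = 0.8666  # standardized mean difference -> AUC ~ 0.73
    csf_biomarker_rho: dict = field(
        default_factory=lambda: {
            "abeta42": -0.25,
            "abeta40": 0.0,
            "ratio42_40": -0.405,
            "t_tau": 0.20,
            "p_tau": 0.35,
        }
    )
    rng_seed: int = None

    def __post_init__(self) -> None:
        for name in ("baseline_sd", "animal_sd", "tech_sd", "batch_shift_sd", "batch_scale_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        for name in ("planted_dep_fraction", "overlap_fraction", "concordance_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """What was planted: per-protein trajectories, classes and batch effects."""

    planted_lfc: dict  # protein -> tissue -> (lfc at each age)
    classes: dict  # {"dep": [...], "abeta_corr": [...], "abeta_acorr": [...], "candidate": str}
    batch_shift_means: dict
    gene_symbols: dict  # protein -> mouse symbol
    missing_params: tuple

    def to_json(self, path) -> None:
        payload = {
            "planted_lfc": {
                p: {t: list(map(float, v)) for t, v in per.items()}
                for p, per in self.planted_lfc.items()
            },
            "classes": self.classes,
            "batch_shift_means": self.batch_shift_means,
            "gene_symbols": self.gene_symbols,
            "missing_params": list(self.missing_params),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    def symbols_of(self, proteins) -> list:
        return [self.gene_symbols[p] for p in proteins]


# ---------------------------------------------------------------------------
# LFQ matrix
# ---------------------------------------------------------------------------

def _mouse_symbol(i: int) -> str:
    return f"Gene{i + 1:05d}"  # mouse symbols stored capitalized-first


def _plant_trajectories(design: StudyDesign, params: GeneratorParams,
                        rng: np.random.Generator) -> tuple[dict, dict]:
    """Choose planted proteins and their per-tissue LFC-over-age trajectories."""
    ages = np.asarray(design.ages, float)
    ramp = (ages - ages[0]) / (ages[-1] - ages[0])  # 0 .. 1 monotone profile
    n = params.n_proteins
    proteins = [f"P{i + 1:05d}" for i in range(n)]

    n_dep = int(round(params.planted_dep_fraction * n))
    n_corr = min(params.n_abeta_corr, n_dep)
    n_acorr = min(params.n_abeta_acorr, max(n_dep - n_corr, 0))
    if n_dep == 0:
        return {}, {"dep": [], "abeta_corr": [], "abeta_acorr": [], "candidate": None}
    order = rng.permutation(n)[:n_dep]
    dep = [proteins[i] for i in order]
    corr, acorr = dep[:n_corr], dep[n_corr:n_corr + n_acorr]

    lo, hi = params.planted_lfc_range
    planted: dict = {}
    tissues = list(design.tissues)
    readout_traj = {
        t: np.asarray(params.abeta_means[(t, "MFA")], float) for t in tissues
        if (t, "MFA") in params.abeta_means
    }
    for j, p in enumerate(dep):
        tissue = tissues[j % len(tissues)]
        peak = rng.uniform(lo, hi)
        if p in corr or p in acorr:
            # exactly proportional to that tissue's aggregate trajectory, so the
            # true trajectory correlation is +/-1 by construction
            base = readout_traj.get(tissue)
            if base is None:
                base = ramp
            traj = peak * base / base.max()
            if p in acorr:
                traj = -traj
        else:
            sign = rng.choice([-1.0, 1.0])
            traj = sign * peak * ramp
        planted[p] = {tissue: tuple(traj)}

    # candidate: hippocampus-specific, monotone increasing, proportional to the
    # hippocampal aggregate trajectory, strongest effect in the simulation
    candidate = None
    if params.candidate is not None and params.candidate.tissue in tissues:
        spec = params.candidate
        candidate = dep[0] if dep else None
        base = readout_traj.get(spec.tissue, ramp)
        # affine in the aggregate trajectory: correlation stays +1 while the
        # effect is sizable at every age (so the candidate ranks top-k throughout)
        traj = spec.lfc_offset + (spec.lfc_peak - spec.lfc_offset) * base / base.max()
        planted[candidate] = {spec.tissue: tuple(traj)}
        if candidate not in corr:
            corr = [candidate] + [p for p in corr if p != candidate]
    classes = {
        "dep": sorted(dep),
        "abeta_corr": sorted(corr),
        "abeta_acorr": sorted(acorr),
        "candidate": candidate,
    }
    return planted, classes


def simulate_lfq(design: StudyDesign, params: GeneratorParams) -> tuple[IntensityMatrix, GroundTruth]:
    """Generate the proteins x samples log10 LFQ matrix plus ground truth."""
    if params.rng_seed is None:
        raise ValueError("rng_seed must be set (reproducibility contract)")
    rng = _rng(params.rng_seed, "lfq")
    meta = design.sample_table()
    n, m = params.n_proteins, len(meta)
    proteins = [f"P{i + 1:05d}" for i in range(n)]
    symbols = {p: _mouse_symbol(i) for i, p in enumerate(proteins)}

    planted, classes = _plant_trajectories(design, params, rng)

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, size=n)

    batches = list(dict.fromkeys(meta["batch"]))
    shift_means = {b: float(params.batch_shifts.get(b, 0.0)) for b in batches}
    gamma = {
        b: shift_means[b] + rng.normal(0.0, params.batch_shift_sd, size=n) for b in batches
    }
    scale = {
        b: np.exp(rng.normal(0.0, params.batch_scale_sd, size=n)) for b in batches
    }

    # animal-level noise per (animal, tissue) homogenate
    homogenates = list(dict.fromkeys(zip(meta["animal_id"], meta["tissue"])))
    animal_eff = {h: rng.normal(0.0, params.animal_sd, size=n) for h in homogenates}

    age_index = {a: k for k, a in enumerate(design.ages)}
    X = np.empty((n, m))
    for j, row in enumerate(meta.itertuples(index=False)):
        mu = baseline + gamma[row.batch]
        h = animal_eff[(row.animal_id, row.tissue)]
        eps = rng.normal(0.0, params.tech_sd, size=n) * scale[row.batch]
        X[:, j] = mu + h + eps
        if row.genotype == "TG":
            k = age_index[row.age]
            for p, per_tissue in planted.items():
                traj = per_tissue.get(row.tissue)
                if traj is not None:
                    X[int(p[1:]) - 1, j] += traj[k]

    p_miss = expit(params.missing_slope * (params.missing_midpoint - X))
    mask = rng.random(size=X.shape) < p_miss
    X = np.where(mask, np.nan, X)

    values = pd.DataFrame(X, index=pd.Index(proteins, name="protein_id"), columns=meta["sample"])
    matrix = IntensityMatrix(values, meta, pd.Series(symbols))
    truth = GroundTruth(
        planted_lfc=planted,
        classes=classes,
        batch_shift_means=shift_means,
        gene_symbols=symbols,
        missing_params=(params.missing_midpoint, params.missing_slope),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# aggregate trajectories
# ---------------------------------------------------------------------------

def simulate_abeta_trajectories(design: StudyDesign, params: GeneratorParams) -> pd.DataFrame:
    """Per-tissue 3-point mean aggregate trajectories for the four readouts.

    Returns a tidy frame with columns ``tissue, readout, age, value, n_per_point``.
    Values are means over ``n_animals_per_condition`` simulated animals whose
    individual measures scatter around the stated per-age means; hippocampal
    trajectories are strictly increasing and steeper than cortical ones by
    construction of the default means. A zero-variance (flat) requested
    trajectory raises, since correlation against it is undefined.
    """
    if len(design.ages) < 2:
        raise ValueError("need >= 2 ages for a trajectory")
    rng = _rng(params.rng_seed, "abeta")
    rows = []
    for (tissue, readout), means in sorted(params.abeta_means.items()):
        means = np.asarray(means, float)
        if len(means) != len(design.ages):
            raise ValueError(f"trajectory {(tissue, readout)} must have one value per age")
        if np.ptp(means) == 0:
            raise ValueError(
                f"trajectory {(tissue, readout)} has zero variance; correlation undefined"
            )
        n_rep = design.n_animals_per_condition
        for age, mu in zip(design.ages, means):
            draws = rng.normal(mu, params.abeta_cv * abs(mu), size=n_rep)
            rows.append(
                {"tissue": tissue, "readout": readout, "age": age,
                 "value": float(np.mean(draws)), "n_per_point": n_rep}
            )
    out = pd.DataFrame(rows)
    # enforce the stated strictly-increasing hippocampal trajectories despite
    # sampling noise in the per-age means
    for (tissue, readout), grp in out.groupby(["tissue", "readout"]):
        if tissue != "hippocampus":
            continue
        ordered = grp.sort_values("age")
        vals = ordered["value"].to_numpy().copy()
        for k in range(1, len(vals)):
            if vals[k] <= vals[k - 1]:
                vals[k] = vals[k - 1] * 1.05 + 1e-9
        out.loc[ordered.index, "value"] = vals
    return out


def trajectories_by_tissue(trajectories: pd.DataFrame, tissue: str) -> dict:
    """Readout -> age-ordered numpy trajectory for one tissue."""
    sub = trajectories[trajectories["tissue"] == tissue]
    return {
        readout: grp.sort_values("age")["value"].to_numpy()
        for readout, grp in sub.groupby("readout")
    }


# ---------------------------------------------------------------------------
# human tables and ortholog map
# ---------------------------------------------------------------------------

def _human_symbol(mouse_symbol: str) -> str:
    return mouse_symbol.upper()


def simulate_human_tables(params: GeneratorParams, truth: GroundTruth) -> tuple[dict, pd.DataFrame]:
    """Three human datasets plus an ortholog map.

    ``overlap_fraction`` of the planted mouse differential proteins appear as
    significant entries in each human table; each overlapping entry agrees in
    sign with the planted mouse effect with probability
    ``concordance_fraction``. Background human-only genes pad the tables. The
    ortholog map contains one-to-one rows in both translation directions plus
    the stated numbers of one-to-many and many-to-many rows.
    """
    rng = _rng(params.rng_seed, "human")
    dep = truth.classes["dep"]
    dep_symbols = truth.symbols_of(dep)
    mouse_sign = {}
    for p, sym in zip(dep, dep_symbols):
        traj = next(iter(truth.planted_lfc[p].values()))
        mouse_sign[sym] = float(np.sign(traj[-1]))

    tables = {}
    candidate_sym = (
        truth.gene_symbols[truth.classes["candidate"]] if truth.classes["candidate"] else None
    )
    for d, dataset in enumerate(HUMAN_DATASETS[:3]):
        n_overlap = int(round(params.overlap_fraction * len(dep_symbols)))
        chosen = list(rng.choice(dep_symbols, size=n_overlap, replace=False)) if n_overlap else []
        if candidate_sym is not None and candidate_sym not in chosen:
            chosen.append(candidate_sym)  # candidate is human-concordant by spec
        rows = []
        for sym in chosen:
            agree = True if sym == candidate_sym else rng.random() < params.concordance_fraction
            sign = mouse_sign[sym] if agree else -mouse_sign[sym]
            if sign == 0.0:
                sign = 1.0
            rows.append(
                {"gene_symbol": _human_symbol(sym),
                 "effect": float(sign * rng.uniform(0.2, 1.5)),
                 "significant": True}
            )
        for i in range(params.n_human_background):
            rows.append(
                {"gene_symbol": f"HBG{d}{i + 1:05d}",
                 "effect": float(rng.normal(0.0, 0.5)),
                 "significant": bool(rng.random() < params.human_sig_background_rate)}
            )
        t = pd.DataFrame(rows)
        t["dataset_id"] = dataset
        tables[dataset] = t

    ortho = _simulate_ortholog_map(params, truth)
    return tables, ortho


def _simulate_ortholog_map(params: GeneratorParams, truth: GroundTruth) -> pd.DataFrame:
    rng = _rng(params.rng_seed, "ortholog")
    symbols = sorted(truth.gene_symbols.values())
    rows = []
    for sym in symbols:
        h = _human_symbol(sym)
        rows.append({"mouse_symbol": sym, "human_symbol": h, "source_direction": "m2h"})
        rows.append({"mouse_symbol": sym, "human_symbol": h, "source_direction": "h2m"})
    # one-to-many: a mouse gene additionally maps to a paralog-like second symbol.
    # Planted differential proteins are kept strictly one-to-one so ambiguity
    # never silently removes the ground truth.
    protected = set(truth.symbols_of(truth.classes["dep"]))
    free = [s for s in symbols if s not in protected]
    pick = rng.choice(len(free), size=min(params.ortholog_one_to_many, len(free)), replace=False)
    for i in pick:
        rows.append({"mouse_symbol": free[i], "human_symbol": _human_symbol(free[i]) + "B",
                     "source_direction": "m2h"})
    # many-to-many clusters: two mouse x two human fully connected
    for k in range(params.ortholog_many_to_many):
        m1, m2 = f"Ambm{2 * k + 1:03d}", f"Ambm{2 * k + 2:03d}"
        h1, h2 = f"AMBH{2 * k + 1:03d}", f"AMBH{2 * k + 2:03d}"
        for mm in (m1, m2):
            for hh in (h1, h2):
                rows.append({"mouse_symbol": mm, "human_symbol": hh, "source_direction": "m2h"})
    return pd.DataFrame(rows).drop_duplicates(ignore_index=True)


# ---------------------------------------------------------------------------
# transcript (DEG) table
# ---------------------------------------------------------------------------

def simulate_deg_table(params: GeneratorParams, truth: GroundTruth,
                       protein_level_fraction: float = 0.03) -> pd.DataFrame:
    """Transcript-level results with a small planted protein-level overlap.

    Most planted protein changes have no transcript counterpart (post-
    transcriptional regulation); ``protein_level_fraction`` of the aggregate-
    correlated/anticorrelated proteins are also significant transcripts.
    """
    rng = _rng(params.rng_seed, "deg")
    corr_universe = sorted(set(truth.classes["abeta_corr"]) | set(truth.classes["abeta_acorr"]))
    syms = truth.symbols_of(corr_universe)
    n_hit = max(1, int(round(protein_level_fraction * len(syms)))) if syms else 0
    hits = set(rng.choice(syms, size=n_hit, replace=False)) if n_hit else set()
    rows = []
    for sym in sorted(truth.gene_symbols.values()):
        sig = sym in hits or rng.random() < 0.01
        rows.append(
            {"gene_symbol": sym,
             "log2fc": float(rng.normal(0.0, 0.3) + (0.8 if sym in hits else 0.0)),
             "adjusted_p": float(rng.uniform(0.0, 0.049) if sig else rng.uniform(0.05, 1.0)),
             "significant": bool(sig)}
        )
    return pd.DataFrame(rows)


def simulate_annotations(params: GeneratorParams, truth: GroundTruth) -> pd.DataFrame:
    """Symbol -> annotation-term table; the candidate carries lysosomal terms."""
    rng = _rng(params.rng_seed, "annotations")
    terms_pool = ("synapse", "mitochondrion", "cytoskeleton", "nucleus", "ER")
    rows = []
    candidate = truth.classes["candidate"]
    for p, sym in sorted(truth.gene_symbols.items()):
        if p == candidate:
            terms = ";".join(params.candidate.annotation_terms)
        else:
            terms = str(rng.choice(terms_pool))
        rows.append({"gene_symbol": sym, "terms": terms})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSF
# ---------------------------------------------------------------------------

def simulate_csf(params: GeneratorParams) -> pd.DataFrame:
    """Two-group log-normal CSF analyte with rank-correlated biomarker columns.

    The analyte is log-normal with a standardized mean difference
    ``csf_effect_d`` on the log scale between cases and controls (expected
    AUC = Phi(d / sqrt(2))). Auxiliary biomarker columns are generated through
    a Gaussian copula with the stated latent correlations against the analyte.
    """
    if params.n_cases < 2 or params.n_controls < 2:
        raise ValueError("need >= 2 subjects per group")
    if params.csf_log_sd <= 0 or params.csf_log_mean_control <= 0:
        raise ValueError("group means/sds must be > 0")
    rng = _rng(params.rng_seed, "csf")
    n = params.n_cases + params.n_controls
    groups = ["AD"] * params.n_cases + ["control"] * params.n_controls

    z_analyte = rng.normal(size=n)
    log_x = params.csf_log_mean_control + params.csf_log_sd * (
        z_analyte + np.where(np.array(groups) == "AD", params.csf_effect_d, 0.0)
    )
    table = pd.DataFrame({
        "subject_id": [f"S{i + 1:03d}" for i in range(n)],
        "group": groups,
        "analyte": np.exp(log_x),
    })
    # copula target: the analyte's latent normal including the group shift
    z_total = (log_x - np.mean(log_x)) / np.std(log_x)
    biomarker_scale = {
        "abeta42": (np.log(700.0), 0.4),
        "abeta40": (np.log(9000.0), 0.35),
        "ratio42_40": (np.log(0.07), 0.45),
        "t_tau": (np.log(350.0), 0.5),
        "p_tau": (np.log(55.0), 0.5),
    }
    for name, rho in params.csf_biomarker_rho.items():
        if not -1.0 < rho < 1.0:
            raise ValueError("biomarker correlations must be in (-1, 1)")
        z = rho * z_total + np.sqrt(1.0 - rho ** 2) * rng.normal(size=n)
        mu, sd = biomarker_scale.get(name, (0.0, 1.0))
        table[name] = np.exp(mu + sd * z)
    return table


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset_5xfad(seed: int, n_proteins: int = 4000) -> tuple[StudyDesign, GeneratorParams]:
    """The full stated-world preset: 2 tissues x 3 ages x 2 genotypes x 5
    animals x 2 technical replicates (3 for the 5-month hippocampus)."""
    design = StudyDesign()
    params = GeneratorParams(
        n_proteins=n_proteins,
        batch_shifts={f"{t[:3]}_b2": 0.15 for t in design.tissues},
        rng_seed=seed,
    )
    return design, params


def preset_smoke(seed: int, n_proteins: int = 200) -> tuple[StudyDesign, GeneratorParams]:
    """Small preset for fast end-to-end runs and tests."""
    design, params = preset_5xfad(seed, n_proteins=n_proteins)
    params = dataclasses.replace(
        params,
        n_abeta_corr=12,
        n_abeta_acorr=8,
        n_human_background=200,
        ortholog_one_to_many=5,
        ortholog_many_to_many=3,
    )
    return design, params


def preset_engineered_funnel(seed: int, n_proteins: int = 400) -> tuple[StudyDesign, GeneratorParams]:
    """Preset engineered so the planted candidate satisfies every funnel stage.

    Noise is reduced far below the realistic level so that the candidate's
    3-point trajectory correlation is recovered essentially without error
    (with three time points the critical |r| at alpha = 0.05 is ~0.9969, which
    realistic estimation noise can miss); this isolates the funnel logic from
    trajectory-estimation power.
    """
    design, params = preset_smoke(seed, n_proteins=n_proteins)
    params = dataclasses.replace(
        params,
        animal_sd=0.02,
        tech_sd=0.01,
        missing_midpoint=4.5,  # little missingness, so stages see full data
        concordance_fraction=1.0,
    )
    return design, params
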