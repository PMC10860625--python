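"""End-to-end pipeline over synthetic cohorts.

Stages: simulate a three-group cohort (intact-hand controls, amputees,
congenital one-handers) -> score chord trials (deviance) -> rank chord
difficulty -> first-level GLM on synthetic BOLD runs -> crossnobis RSA
(RDMs, homotopy, typicality) -> tract summaries -> group statistics.

Configuration is a plain nested dict (JSON/YAML round-trippable); all
randomness flows from one master seed through named per-stage child
seeds, so a re-run with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import aggregate_learning, score_trial
from .designs import (
    SCANNER_CONFIGS,
    TRAINING_CONFIGS,
    build_scanner_design,
    build_training_design,
)
from .difficulty import rank_and_split, score_table, synthetic_enslavement_matrix
from .firstlevel import build_design_matrix, fit_glm
from .forces import SkillParams, simulate_force_trial
from .patterns import PatternGroundTruth, PatternSet, mds_embed, simulate_patterns
from .rdm import RDM
from .rsa import control_template, crossnobis_rdm, estimate_noise_model, homotopy, select_pairs, typicality
from .stats import adjusted_contrasts, format_effect, freedman_lane_permutation, one_sample_vs_zero, rm_ancova
from .tracts import simulate_tract_summary, tract_table

# group sizes and ages follow the scanned cohort; skill and pattern
# parameters encode the qualitative group structure the analyses assume:
# one-handers learn difficult chords poorly; amputees show elevated
# ipsilateral signal and higher interhemispheric homotopy.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "groups": {
        "control": {
            "n": 14,
            "age_mean": 44.2,
            "age_sd": 12.2,
            "skill": {
                "easy": {"noise_sd": 0.12, "enslavement_gain": 0.02, "learning_rate": 0.90},
                "difficult": {"noise_sd": 0.16, "enslavement_gain": 0.03, "learning_rate": 0.90},
            },
            "homotopy_level": 0.25,
            "signal_scale": [1.0, 0.45],
            "rdm_scale": 1.0,
        },
        "amputee": {
            "n": 16,
            "age_mean": 48.4,
            "age_sd": 12.6,
            "skill": {
                "easy": {"noise_sd": 0.15, "enslavement_gain": 0.025, "learning_rate": 0.90},
                "difficult": {"noise_sd": 0.20, "enslavement_gain": 0.035, "learning_rate": 0.90},
            },
            "homotopy_level": 0.65,
            "signal_scale": [1.0, 0.75],
            "rdm_scale": 1.1,
        },
        "one_hander": {
            "n": 13,
            "age_mean": 45.8,
            "age_sd": 11.3,
            "skill": {
                "easy": {"noise_sd": 0.15, "enslavement_gain": 0.025, "learning_rate": 0.92},
                "difficult": {"noise_sd": 0.22, "enslavement_gain": 0.04, "learning_rate": 0.99},
            },
            "homotopy_level": 0.25,
            "signal_scale": [0.9, 0.40],
            "rdm_scale": 0.9,
        },
    },
    "design": {
        "n_runs": 4,
        "blocks_per_config": 3,
        "trials_per_block": 3,
        "instruction_s": 1.3,
        "trial_s": 2.3,
        "tr_s": 1.5,
        "n_volumes": 141,
        "training_blocks": 6,
        "training_reps": 4,
    },
    "imaging": {
        "n_voxels": 60,
        "noise_sd": 1.0,
        "bold_noise_sd": 1.0,
        "base_rdm_scale": 0.8,
    },
    "tracts": {
        "n_lr": 420.0,
        "n_rl": 380.0,
        "fa": 0.45,
        "md": 0.80,
        "jitter": 0.10,
    },
    "stats": {"n_perm": 1000},
}


def default_config() -> dict:
    return json.loads(json.dumps(DEFAULT_CONFIG))


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not cfg.get("groups"):
        raise ValueError("config must define at least one group")
    for name, gspec in cfg["groups"].items():
        if int(gspec.get("n", 0)) < 1:
            raise ValueError(f"group {name!r} must have at least one subject")
        if not -1.0 <= float(gspec.get("homotopy_level", 0)) <= 1.0:
            raise ValueError(f"group {name!r}: homotopy_level must be in [-1, 1]")
    if int(cfg.get("seed", 0)) < 0:
        raise ValueError("seed must be nonnegative")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence([int(master_seed), int(hashlib.sha256(stage.encode()).hexdigest()[:8], 16)])
    return np.random.default_rng(ss)


def base_chord_rdm(labels=SCANNER_CONFIGS, scale: float = 1.0) -> RDM:
    """Plausible ground-truth chord geometry: dissimilarity grows with
    the number of fingers two chords do not share (set-overlap metric),
    scaled to per-voxel crossnobis units."""
    labs = [str(c) for c in labels]
    n = len(labs)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            overlap = len(set(labs[i]) & set(labs[j]))
            M[i, j] = scale * (3 - overlap) / 3.0 if i != j else 0.0
    return RDM.from_matrix(labs, M)


# ------------------------------------------------------------ stage: cohort

def simulate_cohort(cfg: dict, master_seed: int) -> pd.DataFrame:
    """Subject table: subject id, group, age."""
    rng = _stage_rng(master_seed, "cohort")
    rows = []
    for gname, gspec in cfg["groups"].items():
        for k in range(int(gspec["n"])):
            rows.append(
                {
                    "subject": f"{gname}_{k:02d}",
                    "group": gname,
                    "age": float(np.round(rng.normal(gspec["age_mean"], gspec["age_sd"]), 1)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------- stage: behavior

def simulate_behavior(cfg: dict, subjects: pd.DataFrame, master_seed: int):
    """Simulate and score both sessions for every subject.

    Returns (training_design, scanner_design, trial_records) where
    trial_records has one scored row per trial of both sessions.
    """
    rng = _stage_rng(master_seed, "behavior")
    d = cfg["design"]
    E = synthetic_enslavement_matrix()
    split = rank_and_split(E, TRAINING_CONFIGS + SCANNER_CONFIGS, n_easy=5)

    train = build_training_design(
        n_blocks=int(d["training_blocks"]),
        configs=TRAINING_CONFIGS,
        reps_per_config=int(d["training_reps"]),
        seed=int(rng.integers(2**31)),
    )
    scan = build_scanner_design(
        n_runs=int(d["n_runs"]),
        configs=SCANNER_CONFIGS,
        blocks_per_config=int(d["blocks_per_config"]),
        trials_per_block=int(d["trials_per_block"]),
        instruction_s=float(d["instruction_s"]),
        trial_s=float(d["trial_s"]),
        tr_s=float(d["tr_s"]),
        n_volumes=int(d["n_volumes"]),
        seed=int(rng.integers(2**31)),
    )

    records = []
    for _, subj in subjects.iterrows():
        gspec = cfg["groups"][subj["group"]]
        # stable between-subject heterogeneity in skill (lognormal factor)
        cv = float(gspec.get("between_subject_cv", 0.25))
        subj_factor = float(np.exp(rng.normal(0.0, cv)))
        skills = {
            lvl: SkillParams(
                press_gain=1.0,
                noise_sd=float(spec["noise_sd"]) * subj_factor,
                enslavement_gain=float(spec["enslavement_gain"]) * subj_factor,
                learning_rate=float(spec["learning_rate"]),
            )
            for lvl, spec in gspec["skill"].items()
        }
        for session, design, time_attr in (("training", train, "block"), ("scanner", scan, "run")):
            for tid, trial in enumerate(design.trials):
                lvl = split[trial.config.label]
                n_done = trial.block if session == "training" else trial.run
                skill = skills[lvl].after_blocks(n_done)
                ft = simulate_force_trial(
                    trial.config,
                    skill,
                    enslavement=E,
                    seed=rng,
                    run=trial.run,
                    block=trial.block,
                )
                rec = score_trial(ft, trial_id=tid)
                records.append(
                    {
                        "subject": subj["subject"],
                        "group": subj["group"],
                        "session": session,
                        "run": rec.run,
                        "block": rec.block,
                        "config": rec.config,
                        "difficulty": lvl,
                        "deviance": rec.deviance,
                        "valid": rec.valid,
                    }
                )
    return train, scan, pd.DataFrame(records)


def learning_tables(trials: pd.DataFrame, subjects: pd.DataFrame, split: dict[str, str]):
    """First/last-phase learning tables for both sessions, joined with age."""
    out = {}
    for session, time_col in (("training", "block"), ("scanner", "run")):
        sub = trials[trials["session"] == session]
        agg = aggregate_learning(sub, split, time_col=time_col)
        lo, hi = agg[time_col].min(), agg[time_col].max()
        phase = agg[agg[time_col].isin([lo, hi])].copy()
        phase["phase"] = np.where(phase[time_col] == lo, "first", "last")
        out[session] = phase.merge(subjects[["subject", "age"]], on="subject")
    return out["training"], out["scanner"]


# ----------------------------------------------------------- stage: imaging

def simulate_subject_patterns(
    cfg: dict,
    gspec: dict,
    scan_design,
    design_matrices: list,
    rng: np.random.Generator,
) -> tuple[PatternSet, PatternSet]:
    """BOLD route: noiseless condition means from the pattern model
    drive each run's time series through the design matrix; the GLM fit
    returns run-wise patterns and residuals per hemisphere."""
    img = cfg["imaging"]
    n_vox = int(img["n_voxels"])
    true = base_chord_rdm(scale=float(img["base_rdm_scale"]) * float(gspec.get("rdm_scale", 1.0)))
    gt = PatternGroundTruth(
        true_rdm_contra=true,
        homotopy_level=float(gspec["homotopy_level"]),
        signal_scale_by_hemisphere=tuple(gspec["signal_scale"]),
        noise_covariance=float(img["noise_sd"]) ** 2,
        n_voxels=n_vox,
        n_runs=int(cfg["design"]["n_runs"]),
    )
    # noiseless means per hemisphere from the latent geometry
    clean_c, clean_i = simulate_patterns(
        PatternGroundTruth(
            true_rdm_contra=true,
            homotopy_level=gt.homotopy_level,
            signal_scale_by_hemisphere=gt.signal_scale_by_hemisphere,
            noise_covariance=1e-12,
            n_voxels=n_vox,
            n_runs=2,
            n_residual_samples=2,
        ),
        seed=rng,
    )
    sigma = float(img["bold_noise_sd"])
    out = []
    for clean in (clean_c, clean_i):
        means = clean.patterns[0]  # (n_cond, n_vox), noiseless
        pats, resids = [], []
        for dm in design_matrices:
            cond_idx = [dm.labels.index(c) for c in dm.condition_labels]
            B_true = np.zeros((dm.values.shape[1], n_vox))
            B_true[cond_idx] = means
            Y = dm.values @ B_true + rng.normal(0.0, sigma, (dm.n_volumes, n_vox))
            fit = fit_glm(Y, dm)
            pats.append(fit.condition_patterns())
            resids.append(fit.residuals)
        out.append(
            PatternSet(
                patterns=np.stack(pats),
                residuals=np.stack(resids),
                condition_labels=tuple(dm.condition_labels),
                meta={"hemisphere": clean.meta["hemisphere"]},
            )
        )
    return out[0], out[1]


def run_imaging(cfg: dict, subjects: pd.DataFrame, scan_design, master_seed: int):
    """Per-subject RDMs for both hemispheres plus homotopy/typicality."""
    rng = _stage_rng(master_seed, "imaging")
    dms = [build_design_matrix(scan_design, run=r) for r in range(scan_design.n_runs)]

    rdm_rows, dist_rows = [], []
    rdms: dict[tuple[str, str], RDM] = {}
    for _, subj in subjects.iterrows():
        gspec = cfg["groups"][subj["group"]]
        ps_c, ps_i = simulate_subject_patterns(cfg, gspec, scan_design, dms, rng)
        for ps in (ps_c, ps_i):
            hemi = ps.meta["hemisphere"]
            nm = estimate_noise_model(ps.residuals)
            rdm = crossnobis_rdm(ps, nm, subject=subj["subject"], group=subj["group"])
            rdms[(subj["subject"], hemi)] = rdm
            long = rdm.to_long_frame()
            long["subject"], long["group"], long["hemisphere"] = subj["subject"], subj["group"], hemi
            rdm_rows.append(long)
            _, mean_all = select_pairs(rdm, "all")
            dist_rows.append(
                {
                    "subject": subj["subject"],
                    "group": subj["group"],
                    "age": subj["age"],
                    "hemisphere": hemi,
                    "mean_distance": mean_all,
                }
            )

    comp_rows = []
    controls = subjects[subjects["group"] == "control"]["subject"].tolist()
    control_contra = [rdms[(s, "contra")] for s in controls]
    for _, subj in subjects.iterrows():
        s = subj["subject"]
        h = homotopy(rdms[(s, "contra")], rdms[(s, "ipsi")])
        comp_rows.append(
            {
                "subject": s,
                "group": subj["group"],
                "age": subj["age"],
                "hemisphere": "pair",
                "kind": "homotopy",
                "r": h.r,
                "z": h.z,
            }
        )
        for hemi in ("contra", "ipsi"):
            if subj["group"] == "control":
                tpl = control_template(control_contra, exclude=controls.index(s))
            else:
                tpl = control_template(control_contra)
            ty = typicality(rdms[(s, hemi)], tpl)
            comp_rows.append(
                {
                    "subject": s,
                    "group": subj["group"],
                    "age": subj["age"],
                    "hemisphere": hemi,
                    "kind": "typicality",
                    "r": ty.r,
                    "z": ty.z,
                }
            )
    return pd.concat(rdm_rows, ignore_index=True), pd.DataFrame(dist_rows), pd.DataFrame(comp_rows)


# ------------------------------------------------------------ stage: tracts

def run_tracts(cfg: dict, subjects: pd.DataFrame, master_seed: int) -> pd.DataFrame:
    rng = _stage_rng(master_seed, "tracts")
    t = cfg["tracts"]
    summaries = []
    for _, subj in subjects.iterrows():
        summaries.append(
            simulate_tract_summary(
                n_lr=float(t["n_lr"]),
                n_rl=float(t["n_rl"]),
                fa_lr=float(t["fa"]),
                fa_rl=float(t["fa"]),
                md_lr=float(t["md"]),
                md_rl=float(t["md"]),
                jitter=float(t["jitter"]),
                seed=rng,
                subject=subj["subject"],
                tract="S1-S1",
            )
        )
    table = tract_table(summaries)
    return table.merge(subjects[["subject", "group", "age"]], on="subject")


# ------------------------------------------------------------- stage: stats

def run_stats(
    train_table: pd.DataFrame,
    scan_table: pd.DataFrame,
    distances: pd.DataFrame,
    comparisons: pd.DataFrame,
    tracts_df: pd.DataFrame,
    n_perm: int,
    master_seed: int,
):
    rng = _stage_rng(master_seed, "stats")
    effects, lines = [], []

    def note(title: str, fit, keep=None):
        for _, row in fit.effects.iterrows():
            if keep and row["effect"] not in keep:
                continue
            effects.append({"analysis": title, **row.to_dict()})
            lines.append(f"{title} | {row['effect']}: {format_effect(row)}")

    # behavioural learning, both sessions
    fit_tr = rm_ancova(train_table, "mean_deviance", within=["phase", "difficulty"], covariate="age")
    note("training deviance rmANCOVA", fit_tr)
    fit_sc = rm_ancova(scan_table, "mean_deviance", within=["phase", "difficulty"], covariate="age")
    note("scanner deviance rmANCOVA", fit_sc)

    # information content: mean crossnobis vs zero per group x hemisphere
    t_rows = []
    for (g, hemi), sub in distances.groupby(["group", "hemisphere"]):
        t, df, p = one_sample_vs_zero(sub["mean_distance"])
        t_rows.append({"analysis": "mean distance vs 0", "group": g, "hemisphere": hemi, "t": t, "df": df, "p": p})
    fit_d = rm_ancova(distances, "mean_distance", within=["hemisphere"], covariate="age")
    note("mean distance rmANCOVA", fit_d)

    # homotopy: vs zero per group, one-way ANCOVA across groups, FL permutation
    hom = comparisons[comparisons["kind"] == "homotopy"]
    for g, sub in hom.groupby("group"):
        t, df, p = one_sample_vs_zero(sub["z"])
        t_rows.append({"analysis": "homotopy z vs 0", "group": g, "hemisphere": "pair", "t": t, "df": df, "p": p})
    fit_h = rm_ancova(hom, "z", within=[], covariate="age")
    note("homotopy ANCOVA", fit_h)
    perm = freedman_lane_permutation(hom, "z", "group", ["age"], n_perm=n_perm, seed=rng)
    lines.append(
        f"homotopy Freedman-Lane | group: F({perm.df1}, {perm.df2}) = {perm.f_obs:.2f}; "
        f"permutation p = {perm.p:.4f} ({perm.n_perm} permutations)"
    )
    contr = adjusted_contrasts(fit_h)
    contr["analysis"] = "homotopy group contrasts"

    # typicality: experimental groups vs zero and group x hemisphere ANCOVA
    typ = comparisons[(comparisons["kind"] == "typicality") & (comparisons["group"] != "control")]
    for (g, hemi), sub in typ.groupby(["group", "hemisphere"]):
        t, df, p = one_sample_vs_zero(sub["z"])
        t_rows.append({"analysis": "typicality z vs 0", "group": g, "hemisphere": hemi, "t": t, "df": df, "p": p})
    fit_t = rm_ancova(typ, "z", within=["hemisphere"], covariate="age")
    note("typicality rmANCOVA", fit_t)

    # tracts: group ANCOVAs on the vertex-weighted metrics
    for metric in ("vw_FA", "vw_MD"):
        fit_w = rm_ancova(tracts_df, metric, within=[], covariate="age")
        note(f"{metric} ANCOVA", fit_w)

    perm_row = pd.DataFrame(
        [{"analysis": "homotopy Freedman-Lane", "effect": "group", "F": perm.f_obs, "df1": perm.df1, "df2": perm.df2, "p": perm.p, "pes": np.nan}]
    )
    effects_df = pd.concat([pd.DataFrame(effects), perm_row], ignore_index=True)
    return effects_df, pd.DataFrame(t_rows), contr, lines


# --------------------------------------------------------------- run-all

def run_pipeline(
    cfg: dict | None = None,
    out_dir: str | Path = "results/pipeline",
    seed: int | None = None,
    n_perm: int | None = None,
) -> dict:
    """Run every stage and write the report bundle; returns the tables.

    Outputs: per-stage CSVs, `manifest.json` (seed, config hash,
    package version, file list) and `report.txt` with the key
    statistics pretty-printed.
    """
    cfg = default_config() if cfg is None else json.loads(json.dumps(cfg))
    validate_config(cfg)
    if seed is not None:
        cfg["seed"] = int(seed)
    if n_perm is not None:
        cfg["stats"]["n_perm"] = int(n_perm)
    master_seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    subjects = simulate_cohort(cfg, master_seed)
    train, scan, trials = simulate_behavior(cfg, subjects, master_seed)

    E = synthetic_enslavement_matrix()
    scores = score_table(E, TRAINING_CONFIGS + SCANNER_CONFIGS)
    split = rank_and_split(E, TRAINING_CONFIGS + SCANNER_CONFIGS, n_easy=5)
    train_table, scan_table = learning_tables(trials, subjects, split)

    rdms_long, distances, comparisons = run_imaging(cfg, subjects, scan, master_seed)
    tracts_df = run_tracts(cfg, subjects, master_seed)
    effects, t_tests, contrasts, lines = run_stats(
        train_table, scan_table, distances, comparisons, tracts_df,
        n_perm=int(cfg["stats"]["n_perm"]), master_seed=master_seed,
    )

    tables = {
        "subjects": subjects,
        "design_scanner": scan.to_frame(),
        "design_training": train.to_frame(),
        "trials": trials,
        "difficulty_scores": scores,
        "learning_training": train_table,
        "learning_scanner": scan_table,
        "rdms": rdms_long,
        "distances": distances,
        "comparisons": comparisons,
        "tracts": tracts_df,
        "stats_effects": effects,
        "stats_t_tests": t_tests,
        "stats_contrasts": contrasts,
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "difficulty_split.json").write_text(json.dumps(split, indent=2))

    manifest = {
        "seed": master_seed,
        "config_hash": config_hash(cfg),
        "version": __version__,
        "n_perm": int(cfg["stats"]["n_perm"]),
        "tables": sorted(f"{n}.csv" for n in tables),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))
    (out / "report.txt").write_text("\n".join(lines) + "\n")

    return {**tables, "split": split, "manifest": manifest, "report_lines": lines, "config": cfg}
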