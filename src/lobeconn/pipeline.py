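"""End-to-end orchestration: simulate -> preprocess -> connectomes ->
resilience (analysis I) -> mixed-ANOVA reorganization (analysis II) ->
damage-score correlation.

Every stage is a pure function of its inputs plus the run configuration, so
a fixed :class:`RunConfig` reproduces all outputs bit-identically.  The
report keeps per-stage provenance (parameters, seed, wall time) alongside
the result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, LesionProfile, RoiTimeSeries, POST, PRE
from .connectome import WeightedConnectome, correlation_matrix, fisher_z, threshold_by_cost, to_weights
from .damage import compute_ds, ds_vs_sigma
from .metrics import CostProfile, metrics_over_costs, small_worldness, auc as curve_auc
from .preprocess import detrend_and_bandpass, flip_hemispheres, friston24, mean_fd, nuisance_regress
from .resilience import AttackConfig, compare_groups, random_failure, targeted_attack
from .stats import (
    chi_square_2x2,
    edge_keep_mask,
    edge_screen,
    exclude_damaged,
    false_positive_adjust,
    mixed_anova_2x2,
    two_sample_t,
)
from .synth import GeneratorConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_all", "write_report", "report_hash"]


@dataclass(frozen=True)
class RunConfig:
    """All analysis parameters; defaults mirror the emulated study where
    feasible at desk scale (cost 0.14, grid 0.10..0.35 step 0.01, one node
    removed per attack step, screen alpha 0.05, 1/n correction)."""

    cohort: GeneratorConfig = field(default_factory=GeneratorConfig)
    cost: float = 0.14
    cost_grid_start: float = 0.10
    cost_grid_stop: float = 0.35
    cost_grid_step: float = 0.01
    n_null: int = 10
    random_reps: int = 100
    nodes_per_step: int = 1
    screen_alpha: float = 0.05
    t_variant: str = "pooled"
    ds_mode: str = "sum"
    low_hz: float = 0.01
    high_hz: float = 0.08
    run_random_failure: bool = True
    rng_seed: int = 0

    def grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.cost_grid_start, self.cost_grid_stop + 1e-9, self.cost_grid_step),
            10,
        )


def validate_config(config: RunConfig) -> list[str]:
    """Return the complete list of configuration errors (empty if valid)."""
    errors = list(config.cohort.validate())
    if not 0 < config.cost <= 1:
        errors.append(f"cost must lie in (0, 1], got {config.cost}")
    grid = config.grid()
    if len(grid) == 0:
        errors.append("cost grid is empty")
    elif np.any(np.diff(grid) <= 0):
        errors.append("cost grid must be strictly increasing")
    if len(grid) and (grid[0] <= 0 or grid[-1] > 1):
        errors.append("cost grid values must lie in (0, 1]")
    if config.random_reps < 1:
        errors.append("random_reps must be >= 1")
    if config.n_null < 1:
        errors.append("n_null must be >= 1")
    if config.nodes_per_step < 1:
        errors.append("nodes_per_step must be >= 1")
    if not 0 < config.screen_alpha < 1:
        errors.append("screen_alpha must lie in (0, 1)")
    if config.t_variant not in ("pooled", "welch"):
        errors.append("t_variant must be 'pooled' or 'welch'")
    if config.ds_mode not in ("sum", "mean"):
        errors.append("ds_mode must be 'sum' or 'mean'")
    nyquist = 1.0 / (2.0 * config.cohort.tr_seconds)
    if not 0 < config.low_hz < config.high_hz < nyquist:
        errors.append("need 0 < low_hz < high_hz < Nyquist")
    return errors


# --------------------------------------------------------------------- stages


def preprocess_cohort(cohort: Cohort, config: RunConfig) -> tuple[dict, pd.DataFrame]:
    """Denoise every session and flip right-lateralised subjects to the
    canonical (left-focus) orientation. Returns processed series and an FD table."""
    parc = cohort.parcellation
    processed: dict[tuple[str, str], RoiTimeSeries] = {}
    fd_rows = []
    for (sid, ses), ts in sorted(cohort.timeseries.items()):
        filtered = detrend_and_bandpass(ts, config.low_hz, config.high_hz)
        regressors = [friston24(cohort.motion[(sid, ses)])]
        if (sid, ses) in cohort.nuisance:
            regressors.append(cohort.nuisance[(sid, ses)])
        regressors.append(filtered.data.mean(axis=1, keepdims=True))  # global signal
        cleaned = nuisance_regress(filtered, np.hstack(regressors))
        subject = cohort.subject(sid)
        data = cleaned.data
        if subject.laterality == "R":
            data = flip_hemispheres(data, parc)
        processed[(sid, ses)] = cleaned.with_data(data)
        fd_rows.append(
            {
                "subject_id": sid,
                "session": ses,
                "outcome": subject.outcome,
                "mean_fd_mm": mean_fd(cohort.motion[(sid, ses)]),
            }
        )
    return processed, pd.DataFrame(fd_rows)


def build_connectomes(processed: dict, parc) -> dict:
    """r -> Z -> w for every processed session (already in canonical orientation)."""
    out = {}
    for key, ts in sorted(processed.items()):
        r = correlation_matrix(ts, roi_names=parc.names)
        z = fisher_z(r)
        out[key] = {"z": z.matrix, "w": to_weights(z)}
    return out


def canonical_lesion_fractions(cohort: Cohort) -> dict[str, np.ndarray]:
    """Lesion fractions flipped into the canonical orientation per subject."""
    parc = cohort.parcellation
    out = {}
    for sid, prof in cohort.lesions.items():
        fr = np.asarray(prof.fractions)
        if cohort.subject(sid).laterality == "R":
            fr = fr[parc.partner]
        out[sid] = fr
    return out


def analysis_resilience(cohort: Cohort, connectomes: dict, config: RunConfig) -> dict:
    """Analysis I: pre-operative attack resilience, SF vs NSF."""
    attack_cfg = AttackConfig(
        cost=config.cost, mode="targeted", nodes_per_step=config.nodes_per_step
    )
    curves = {"targeted": {"SF": [], "NSF": []}, "random": {"SF": [], "NSF": []}}
    subject_ids = {"SF": [], "NSF": []}
    for subject in cohort.subjects:
        key = (subject.subject_id, PRE)
        if key not in connectomes:
            continue
        wt = threshold_by_cost(connectomes[key]["w"], config.cost)
        curves["targeted"][subject.outcome].append(targeted_attack(wt, attack_cfg))
        if config.run_random_failure:
            rf_cfg = AttackConfig(
                cost=config.cost,
                mode="random",
                n_random_reps=config.random_reps,
                nodes_per_step=config.nodes_per_step,
                rng_seed=config.rng_seed + len(subject_ids[subject.outcome]),
            )
            curves["random"][subject.outcome].append(random_failure(wt, rf_cfg))
        subject_ids[subject.outcome].append(subject.subject_id)

    result = {"subject_ids": subject_ids}
    result["targeted"] = compare_groups(
        curves["targeted"]["SF"], curves["targeted"]["NSF"], variant=config.t_variant
    )
    if config.run_random_failure:
        result["random"] = compare_groups(
            curves["random"]["SF"], curves["random"]["NSF"], variant=config.t_variant
        )
    result["curves"] = curves
    return result


def _paired_subjects(cohort: Cohort) -> dict[str, list[str]]:
    out = {"SF": [], "NSF": []}
    for s in cohort.subjects:
        if PRE in s.sessions and POST in s.sessions:
            out[s.outcome].append(s.subject_id)
    return out


def _upper_tri(matrix: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu, ju]


def analysis_reorganization(
    cohort: Cohort,
    connectomes: dict,
    profiles: dict,
    config: RunConfig,
) -> dict:
    """Analysis II: 2x2 mixed ANOVA on edges, nodal AUCs and global AUCs,
    with damaged regions excluded everywhere."""
    parc = cohort.parcellation
    paired = _paired_subjects(cohort)
    lesions = canonical_lesion_fractions(cohort)
    post_ids = paired["SF"] + paired["NSF"]
    node_keep = exclude_damaged([lesions[sid] for sid in post_ids if sid in lesions])
    e_keep = edge_keep_mask(node_keep)

    cells = {}
    for outcome in ("SF", "NSF"):
        for ses in (PRE, POST):
            cells[f"{outcome}_{ses}"] = np.array(
                [_upper_tri(connectomes[(sid, ses)]["z"])[e_keep] for sid in paired[outcome]]
            )
    screen = edge_screen(cells, alpha=config.screen_alpha)
    n_edges = int(screen.sum())
    edge_res = mixed_anova_2x2(
        cells["SF_pre"][:, screen],
        cells["SF_post"][:, screen],
        cells["NSF_pre"][:, screen],
        cells["NSF_post"][:, screen],
    )
    iu, ju = np.triu_indices(parc.n_rois, k=1)
    kept_pairs = np.column_stack([iu[e_keep], ju[e_keep]])[screen]

    any_profile = next(iter(profiles.values()))
    nodal_metrics = tuple(any_profile.nodal_auc)
    global_metrics = tuple(any_profile.global_curves)
    nodal = {}
    glob = {}
    for outcome in ("SF", "NSF"):
        for ses in (PRE, POST):
            n_auc = {m: [] for m in nodal_metrics}
            g_auc = {m: [] for m in global_metrics}
            for sid in paired[outcome]:
                prof: CostProfile = profiles[(sid, ses)]
                for m in n_auc:
                    n_auc[m].append(prof.nodal_auc[m][node_keep])
                for m in g_auc:
                    g_auc[m].append(prof.global_curves[m].auc)
            nodal[f"{outcome}_{ses}"] = {m: np.array(v) for m, v in n_auc.items()}
            glob[f"{outcome}_{ses}"] = {m: np.array(v) for m, v in g_auc.items()}

    nodal_res = {
        m: mixed_anova_2x2(
            nodal["SF_pre"][m], nodal["SF_post"][m], nodal["NSF_pre"][m], nodal["NSF_post"][m]
        )
        for m in nodal_metrics
    }
    global_res = {
        m: mixed_anova_2x2(
            glob["SF_pre"][m][:, None],
            glob["SF_post"][m][:, None],
            glob["NSF_pre"][m][:, None],
            glob["NSF_post"][m][:, None],
        )
        for m in global_metrics
    }
    return {
        "paired": paired,
        "node_keep": node_keep,
        "n_kept_nodes": int(node_keep.sum()),
        "edge_screen": screen,
        "kept_edge_pairs": kept_pairs,
        "n_screened_edges": n_edges,
        "edge_threshold": false_positive_adjust(max(n_edges, 1)),
        "node_threshold": false_positive_adjust(max(int(node_keep.sum()), 1)),
        "edges": edge_res,
        "nodal": nodal_res,
        "global": global_res,
    }


def analysis_damage(
    cohort: Cohort,
    connectomes: dict,
    profiles: dict,
    config: RunConfig,
) -> dict:
    """Damage scores from pre-operative nodal metrics, correlated with the
    post-operative small-worldness AUC."""
    lesions = canonical_lesion_fractions(cohort)
    paired = _paired_subjects(cohort)
    post_ids = [sid for g in ("SF", "NSF") for sid in paired[g]]
    grid = np.asarray(config.grid())
    rng = np.random.default_rng(config.rng_seed + 7_000_003)

    rows = []
    for sid in post_ids:
        prof_pre: CostProfile = profiles[(sid, PRE)]
        lesion = lesions[sid]
        subject = cohort.subject(sid)
        lp = LesionProfile(sid, lesion, subject.lacuna_volume_cm3 or 0.0)
        ds_ci = compute_ds(lp, prof_pre.nodal_auc["C_i"], mode=config.ds_mode)
        ds_ei = compute_ds(lp, prof_pre.nodal_auc["E_i"], mode=config.ds_mode)

        w_post = connectomes[(sid, POST)]["w"]
        sigmas = np.array(
            [
                small_worldness(
                    threshold_by_cost(w_post, float(c)), n_null=config.n_null, rng=rng
                )
                for c in grid
            ]
        )
        rows.append(
            {
                "subject_id": sid,
                "outcome": subject.outcome,
                "ds_ci": ds_ci,
                "ds_ei": ds_ei,
                "sigma_auc_post": curve_auc(grid, sigmas),
            }
        )
    table = pd.DataFrame(rows)
    corr = ds_vs_sigma(
        {"C_i": table["ds_ci"].to_numpy(), "E_i": table["ds_ei"].to_numpy()},
        table["sigma_auc_post"].to_numpy(),
    )
    sf = table[table["outcome"] == "SF"]
    nsf = table[table["outcome"] == "NSF"]
    group_t = {
        basis: two_sample_t(sf[col].to_numpy(), nsf[col].to_numpy(), variant=config.t_variant)
        for basis, col in (("C_i", "ds_ci"), ("E_i", "ds_ei"))
    }
    return {"table": table, "correlation": corr, "group_t": group_t}


def clinical_table(cohort: Cohort) -> pd.DataFrame:
    """Group comparison of demographics, as in a study's first table."""
    rows = []
    for ses in (PRE, POST):
        sf = cohort.by_group("SF", ses)
        nsf = cohort.by_group("NSF", ses)
        for label, attr in (
            ("age_years", "age_years"),
            ("onset_age_years", "onset_age_years"),
            ("duration_years", "duration_years"),
        ):
            x = np.array([getattr(s, attr) for s in sf])
            y = np.array([getattr(s, attr) for s in nsf])
            t, df, p = two_sample_t(x, y)
            rows.append(
                {
                    "session": ses,
                    "characteristic": label,
                    "SF": f"{x.mean():.2f} +/- {x.std(ddof=1):.2f}",
                    "NSF": f"{y.mean():.2f} +/- {y.std(ddof=1):.2f}",
                    "test": "t",
                    "statistic": t,
                    "p": p,
                }
            )
        table = [
            [sum(s.sex == "M" for s in sf), sum(s.sex == "F" for s in sf)],
            [sum(s.sex == "M" for s in nsf), sum(s.sex == "F" for s in nsf)],
        ]
        chi2, p = chi_square_2x2(table)
        rows.append(
            {
                "session": ses,
                "characteristic": "sex_mf",
                "SF": f"{table[0][0]}/{table[0][1]}",
                "NSF": f"{table[1][0]}/{table[1][1]}",
                "test": "chi2",
                "statistic": chi2,
                "p": p,
            }
        )
        if ses == POST:
            x = np.array([s.lacuna_volume_cm3 for s in sf])
            y = np.array([s.lacuna_volume_cm3 for s in nsf])
            t, df, p = two_sample_t(x, y, variant="welch")
            rows.append(
                {
                    "session": ses,
                    "characteristic": "lacuna_volume_cm3",
                    "SF": f"{x.mean():.2f} +/- {x.std(ddof=1):.2f}",
                    "NSF": f"{y.mean():.2f} +/- {y.std(ddof=1):.2f}",
                    "test": "t_welch",
                    "statistic": t,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- run all


def run_all(config: RunConfig) -> dict:
    """Execute the full study replica; fail fast naming the offending stage."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    report: dict = {
        "version": __version__,
        "config": dataclasses.asdict(dataclasses.replace(config, cohort=config.cohort.resolved())),
        "stages": {},
    }

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # annotate provenance, then re-raise
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        report["stages"][name] = {
            "status": "ok",
            "runtime_s": round(time.perf_counter() - t0, 3),
        }
        logger.info("stage %s done in %.2fs", name, report["stages"][name]["runtime_s"])
        return out

    cohort = stage("simulate", simulate_cohort, config.cohort)
    report["clinical"] = stage("clinical_table", clinical_table, cohort)
    processed, fd_table = stage("preprocess", preprocess_cohort, cohort, config)
    report["fd"] = fd_table
    connectomes = stage("connectomes", build_connectomes, processed, cohort.parcellation)

    def _profiles():
        paired = _paired_subjects(cohort)
        need = {(sid, ses) for g in paired.values() for sid in g for ses in (PRE, POST)}
        return {
            key: metrics_over_costs(connectomes[key]["w"], config.grid())
            for key in sorted(need)
        }

    profiles = stage("metric_profiles", _profiles)
    report["resilience"] = stage("analysis_resilience", analysis_resilience, cohort, connectomes, config)
    report["reorganization"] = stage(
        "analysis_reorganization", analysis_reorganization, cohort, connectomes, profiles, config
    )
    report["damage"] = stage("analysis_damage", analysis_damage, cohort, connectomes, profiles, config)
    return report


# --------------------------------------------------------------------- report IO


def _anova_frame(res, feature_labels) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": feature_labels,
            "F_interaction": res.f_interaction,
            "p_interaction": res.p_interaction,
            "F_outcome": res.f_outcome,
            "p_outcome": res.p_outcome,
            "F_treatment": res.f_treatment,
            "p_treatment": res.p_treatment,
        }
    )


def write_report(report: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["clinical"].to_csv(out / "clinical_table.tsv", sep="\t", index=False)
    report["fd"].to_csv(out / "mean_fd.tsv", sep="\t", index=False)
    res = report["resilience"]
    for mode in ("targeted", "random"):
        if mode in res:
            res[mode]["per_step"].to_csv(out / f"resilience_{mode}_steps.tsv", sep="\t", index=False)
            res[mode]["auc"].to_csv(out / f"resilience_{mode}_auc.tsv", sep="\t", index=False)
    reorg = report["reorganization"]
    pairs = reorg["kept_edge_pairs"]
    _anova_frame(reorg["edges"], [f"{i}-{j}" for i, j in pairs]).to_csv(
        out / "anova_edges.tsv", sep="\t", index=False
    )
    kept_nodes = np.flatnonzero(reorg["node_keep"])
    for m, r in reorg["nodal"].items():
        _anova_frame(r, kept_nodes).to_csv(out / f"anova_nodal_{m}.tsv", sep="\t", index=False)
    for m, r in reorg["global"].items():
        _anova_frame(r, [m]).to_csv(out / f"anova_global_{m}.tsv", sep="\t", index=False)
    report["damage"]["table"].to_csv(out / "damage_scores.tsv", sep="\t", index=False)

    summary = {
        "version": report["version"],
        "config": report["config"],
        "stages": report["stages"],
        "n_screened_edges": reorg["n_screened_edges"],
        "n_kept_nodes": reorg["n_kept_nodes"],
        "edge_threshold": reorg["edge_threshold"],
        "node_threshold": reorg["node_threshold"],
        "ds_sigma_correlation": {
            basis: {"r": r, "p": p} for basis, (r, p) in report["damage"]["correlation"].items()
        },
        "report_hash": report_hash(report),
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))


def report_hash(report: dict) -> str:
    """Stable digest of the numeric results (for rerun-identity checks)."""
    h = hashlib.sha256()
    reorg = report["reorganization"]
    for arr in (
        reorg["edges"].f_interaction,
        reorg["edges"].p_interaction,
        report["damage"]["table"][["ds_ci", "ds_ei", "sigma_auc_post"]].to_numpy(),
        report["resilience"]["targeted"]["auc"][["t", "p"]].to_numpy(),
    ):
        h.update(np.ascontiguousarray(np.asarray(arr, dtype=float)).tobytes())
    return h.hexdigest()
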