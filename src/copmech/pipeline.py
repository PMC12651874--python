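"""Recipe orchestration: ingest → features → selection → embed → cluster → explain.

Four analysis recipes mirror the study questions:

* ``intervention`` — PD subjects only, pre and post sessions, embedded at
  perplexity 2 and clustered at k = 3 and 5; reports which subjects
  change cluster membership between sessions.
* ``convergence`` — patients plus healthy controls, perplexity 3,
  k = 2, 3, 4; reports which TPEI post-intervention states land in the
  healthy-majority cluster.
* ``diagnosis`` — channel-SD feature block, one row per subject,
  perplexity 3, k = 2; reports agreement between clusters and the
  healthy/PD split.
* ``baseline`` — PD pre-intervention rows only, perplexity 1, k = 2
  (pre-exercise heterogeneity).

Every run is seed-deterministic and emits a manifest of the parameters
actually used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustering, embedding
from .features import (FeatureTable, build_feature_table, gait_features,
                       segment_gait_initiation, signal_sd_features,
                       standardize, standing_features)
from .preprocess import FilterSpec, ForcePlateTrial, preprocess_trial
from .selection import ClassifierSpec, forward_select, mcfadden_r2
from .shapley import exact_shapley, shap_summary
from .simulate import CohortConfig, CohortTruth, simulate_cohort
from .stats import cohens_d, kruskal_wallis, one_way_anova

__all__ = ["PipelineConfig", "RECIPES", "run_recipe", "report",
           "extract_features", "subject_plot_label", "adjusted_rand_index"]

RECIPES = {
    "intervention": {"perplexity": 2.0, "k_values": (3, 5)},
    "convergence": {"perplexity": 3.0, "k_values": (2, 3, 4)},
    "diagnosis": {"perplexity": 3.0, "k_values": (2,)},
    "baseline": {"perplexity": 1.0, "k_values": (2,)},
}


@dataclass(frozen=True)
class PipelineConfig:
    recipe: str = "diagnosis"
    cohort: CohortConfig = CohortConfig()
    seed: int = 0
    perplexity: float | None = None  # None -> recipe default
    k_values: tuple[int, ...] | None = None
    bootstrap_B: int = 200
    tsne_iters: int = 1000
    selection_size: int = 3
    filter_spec: FilterSpec = FilterSpec()

    def __post_init__(self) -> None:
        if self.recipe not in RECIPES:
            raise ValueError(f"unknown recipe {self.recipe!r}; "
                             f"choose from {sorted(RECIPES)}")
        if self.recipe == "intervention" and self.cohort.n_pd_tpei < 1:
            raise ValueError("intervention recipe needs TPEI subjects")

    @property
    def effective_perplexity(self) -> float:
        return self.perplexity if self.perplexity is not None \
            else RECIPES[self.recipe]["perplexity"]

    @property
    def effective_k(self) -> tuple[int, ...]:
        return self.k_values if self.k_values is not None \
            else RECIPES[self.recipe]["k_values"]


def subject_plot_label(subject_id: str, session: str, sex: str, age: float) -> str:
    """Render the compact plot label, e.g. ``E03-AM47`` for the post
    session of intervention subject 3 (male, 47). E/C/H mark the
    intervention, PD-control and healthy groups; ``-A`` marks an
    after-intervention (post) session."""
    post = "-A" if session == "post" else ""
    return f"{subject_id}{post}{sex}{int(round(age))}"


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two labelings (pair-counting form)."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    ua, ub = np.unique(a), np.unique(b)
    table = np.array([[np.sum((a == x) & (b == y)) for y in ub] for x in ua])

    def comb2(v):
        return v * (v - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# Feature extraction over a cohort

def extract_features(
    trials: list[ForcePlateTrial],
    filter_spec: FilterSpec = FilterSpec(),
) -> list[dict]:
    """Per subject-session records with standing, gait and SD blocks."""
    by_key: dict[tuple[str, str], dict] = {}
    for trial in trials:
        key = (trial.meta["subject_id"], trial.meta["session"])
        rec = by_key.setdefault(key, {"subject_id": key[0], "session": key[1],
                                      "group": trial.meta["group"]})
        if trial.meta["test_type"] == "standing":
            cop = preprocess_trial(trial, filter_spec=filter_spec)
            rec["standing"] = standing_features(cop)
            # channel SDs over the same trimmed window as the COP features
            n0 = int(round(2.0 * trial.fs))
            sl = slice(n0, trial.n_samples - n0)
            trimmed = ForcePlateTrial(
                fs=trial.fs, t=trial.t[sl] - trial.t[sl][0],
                **{k: v[sl] for k, v in trial.channels().items()},
                meta=trial.meta)
            rec["signal_sd"] = signal_sd_features(trimmed, cop)
        else:
            cop = preprocess_trial(trial, filter_spec=filter_spec)
            cue = float(trial.meta["events"]["cue_time"])
            phases = segment_gait_initiation(cop, cue_time=cue,
                                             baseline_window=1.0)
            rec["gait"] = gait_features(cop, phases)
    return list(by_key.values())


def _demographics_frame(truth: CohortTruth) -> pd.DataFrame:
    rows = []
    for sid, sessions in truth.profiles.items():
        p = next(iter(sessions.values()))
        rows.append({"subject_id": sid, "group": p.group, "age": p.age,
                     "sex": p.sex, "bmi": p.bmi})
    return pd.DataFrame(rows)


def _select_rows(table: FeatureTable, recipe: str, groups: dict[str, str]
                 ) -> FeatureTable:
    df = table.df
    keep = []
    for sid, session in df.index:
        g = groups[sid]
        if recipe == "intervention" and g != "healthy":
            keep.append((sid, session))
        elif recipe == "convergence":
            keep.append((sid, session))
        elif recipe == "diagnosis" and session in ("pre", "single"):
            keep.append((sid, session))
        elif recipe == "baseline" and g != "healthy" and session == "pre":
            keep.append((sid, session))
    sub = df.loc[keep]
    return FeatureTable(df=sub, provenance=dict(table.provenance),
                        standardized=table.standardized)


def run_recipe(config: PipelineConfig) -> dict:
    """Execute one analysis recipe end to end on a synthetic cohort.

    Returns a report bundle (plain dict of arrays/frames/scalars) that
    :func:`report` renders and tests interrogate.
    """
    trials, truth = simulate_cohort(config.cohort, seed=config.seed)
    groups = {sid: truth.group_of(sid) for sid in truth.profiles}
    records = extract_features(trials, config.filter_spec)
    demo = _demographics_frame(truth)

    if config.recipe == "diagnosis":
        blocks = ("signal_sd",)
    else:
        blocks = ("standing", "gait", "demographics")
    full = build_feature_table(records, blocks=blocks, demographics=demo)
    full_z = standardize(full)

    # Feature selection: PD vs healthy on the standardized full table
    # (skipped for the diagnosis recipe, which embeds the whole SD block).
    bundle: dict = {"config": config, "truth": truth}
    if config.recipe == "diagnosis":
        analysis = _select_rows(full_z, config.recipe, groups)
        feature_cols = list(analysis.df.columns)
        bundle["selection"] = None
    else:
        y = np.array([0 if groups[s] == "healthy" else 1
                      for s, _ in full_z.df.index])
        selections = {}
        if len(np.unique(y)) == 2:
            for spec in (ClassifierSpec("logistic_regression"),
                         ClassifierSpec("k_nearest_neighbors", k=5)):
                sel = forward_select(full_z, y, spec=spec,
                                     target_size=config.selection_size,
                                     seed=config.seed)
                selections[spec.kind] = sel
            union: list[str] = []
            for sel in selections.values():
                for f in sel.features:
                    if f not in union:
                        union.append(f)
            feature_cols = union[:max(config.selection_size,
                                      len(selections["logistic_regression"].features))]
            r2, sep = mcfadden_r2(full_z, y, selected=feature_cols)
            bundle["selection"] = {
                "per_estimator": {k: v.features for k, v in selections.items()},
                "union": union, "used": feature_cols,
                "mcfadden_r2": r2, "separable": sep,
            }
        else:
            feature_cols = list(full_z.df.columns)
            bundle["selection"] = None
        sub = FeatureTable(df=full_z.df[feature_cols],
                           provenance=dict(full_z.provenance),
                           standardized=True)
        analysis = _select_rows(sub, config.recipe, groups)

    X = analysis.df.to_numpy(float)
    index = list(analysis.df.index)
    labels_true = np.array([0 if groups[s] == "healthy" else 1
                            for s, _ in index])

    emb = embedding.tsne(X, perplexity=config.effective_perplexity,
                         seed=42, n_iter=config.tsne_iters, jitter=1e-8)
    elbow = clustering.elbow_curve(
        emb.Y, range(1, min(9, len(X))), seed=config.seed)

    cluster_results = {}
    for k in config.effective_k:
        km = clustering.kmeans(emb.Y, k, n_init=10, seed=config.seed)
        stats = clustering.cluster_descriptives(emb.Y, km.labels)
        indices = None
        if k >= 2:
            if config.bootstrap_B > 0:
                indices = clustering.bootstrap_indices(
                    emb.Y, k, B=config.bootstrap_B, seed=config.seed)
            else:
                indices = clustering.internal_indices(emb.Y, km.labels)
        cluster_results[k] = {"kmeans": km, "descriptives": stats,
                              "indices": indices}

    bundle.update({
        "feature_table": full_z,
        "analysis_table": analysis,
        "feature_cols": feature_cols,
        "index": index,
        "plot_labels": [
            subject_plot_label(sid, ses,
                               truth.profiles[sid][ses].sex,
                               truth.profiles[sid][ses].age)
            for sid, ses in index],
        "groups_true": labels_true,
        "embedding": emb,
        "elbow": elbow,
        "clusters": cluster_results,
    })

    # recipe-specific summaries
    k0 = config.effective_k[0]
    labels0 = cluster_results[k0]["kmeans"].labels
    if config.recipe == "diagnosis":
        bundle["ari"] = adjusted_rand_index(labels_true, labels0)
    if config.recipe == "intervention":
        bundle["transitions"] = {
            k: _session_transitions(index, cluster_results[k]["kmeans"].labels,
                                    groups)
            for k in config.effective_k
        }
    if config.recipe == "convergence":
        bundle["healthy_cluster_membership"] = _healthy_membership(
            index, labels0, groups)

    bundle["effects"] = _effect_report(full, groups)
    if config.recipe != "diagnosis" and bundle["selection"] is not None:
        bundle["shap"] = _shap_report(full_z, groups, feature_cols)
    bundle["manifest"] = _manifest(config)
    return bundle


def _session_transitions(index, labels, groups) -> dict[str, dict[str, bool]]:
    """Per group: which subjects changed cluster between pre and post."""
    by_subject: dict[str, dict[str, int]] = {}
    for (sid, ses), lab in zip(index, labels):
        by_subject.setdefault(sid, {})[ses] = int(lab)
    out: dict[str, dict[str, bool]] = {"pd_tpei": {}, "pd_control": {}}
    for sid, sess in by_subject.items():
        g = groups[sid]
        if g in out and "pre" in sess and "post" in sess:
            out[g][sid] = sess["pre"] != sess["post"]
    return out


def _healthy_membership(index, labels, groups) -> dict:
    healthy_labels = [lab for (sid, _), lab in zip(index, labels)
                      if groups[sid] == "healthy"]
    if not healthy_labels:
        return {}
    healthy_cluster = int(np.bincount(healthy_labels).argmax())
    tpei_post = {
        sid: int(lab) == healthy_cluster
        for (sid, ses), lab in zip(index, labels)
        if groups[sid] == "pd_tpei" and ses == "post"
    }
    return {"healthy_cluster": healthy_cluster, "tpei_post_in_healthy": tpei_post}


_EFFECT_FEATURES = ("stand_rms_ml", "stand_pl_ap", "gait_ldisp")


def _effect_report(table: FeatureTable, groups: dict[str, str]) -> dict:
    """Cohen's d contrasts and classical tests on the headline features."""
    df = table.df
    out: dict = {"cohens_d": {}, "anova": {}, "kruskal": {}}
    for feat in _EFFECT_FEATURES:
        if feat not in df.columns:
            continue

        def vals(group, session):
            sel = [(s, ses) for s, ses in df.index
                   if groups[s] == group and ses == session]
            return df.loc[sel, feat].to_numpy(float)

        contrasts = {
            "tpei_pre_vs_post": (vals("pd_tpei", "pre"), vals("pd_tpei", "post")),
            "control_pre_vs_post": (vals("pd_control", "pre"),
                                    vals("pd_control", "post")),
            "healthy_vs_tpei_post": (vals("healthy", "single"),
                                     vals("pd_tpei", "post")),
        }
        out["cohens_d"][feat] = {
            name: cohens_d(a, b) for name, (a, b) in contrasts.items()
            if len(a) >= 2 and len(b) >= 2
        }
        cells = [v for v in (vals("pd_tpei", "pre"), vals("pd_tpei", "post"),
                             vals("pd_control", "pre"), vals("pd_control", "post"))
                 if len(v) >= 2]
        if len(cells) >= 2:
            out["anova"][feat] = one_way_anova(*cells)
            out["kruskal"][feat] = kruskal_wallis(*cells)
    return out


def _shap_report(table: FeatureTable, groups: dict[str, str],
                 feature_cols: list[str]) -> dict:
    """Exact Shapley attribution of the PD-vs-healthy logistic model."""
    from sklearn.linear_model import LogisticRegression

    df = table.df[feature_cols]
    y = np.array([0 if groups[s] == "healthy" else 1 for s, _ in df.index])
    if len(np.unique(y)) < 2:
        return {}
    X = df.to_numpy(float)
    model = LogisticRegression(C=1.0, max_iter=1000).fit(X, y)
    predict = lambda A: model.predict_proba(A)[:, 1]  # noqa: E731
    reports = [exact_shapley(predict, X[i], X, feature_cols)
               for i in range(len(X))]
    ranking, dependence = shap_summary(reports)
    return {"reports": reports, "ranking": ranking, "dependence": dependence}


def _manifest(config: PipelineConfig) -> dict:
    cfg = dataclasses.asdict(config)
    blob = json.dumps(cfg, sort_keys=True, default=str)
    return {
        "config": cfg,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "seed": config.seed,
        "version": __import__("copmech").__version__,
    }


# ---------------------------------------------------------------------------
# Reporting

def _fmt_vec(v) -> str:
    return "[" + ", ".join(f"{x:.2f}" for x in np.atleast_1d(v)) + "]"


def report(bundle: dict) -> str:
    """Render a report bundle as a markdown summary."""
    lines = []
    cfg: PipelineConfig = bundle["config"]
    man = bundle.get("manifest", {})
    lines.append(f"# copmech report — recipe '{cfg.recipe}' "
                 f"(manifest {man.get('config_hash', 'n/a')})")
    lines.append(f"seed {cfg.seed}, perplexity {cfg.effective_perplexity}, "
                 f"k = {list(cfg.effective_k)}")
    sel = bundle.get("selection")
    if sel:
        lines.append("\n## Selected features")
        for kind, feats in sel["per_estimator"].items():
            lines.append(f"- {kind}: {', '.join(feats)}")
        lines.append(f"- used: {', '.join(sel['used'])} "
                     f"(McFadden R2 = {sel['mcfadden_r2']:.3f}"
                     + (", separable fit flagged" if sel["separable"] else "")
                     + ")")
    for k, res in bundle.get("clusters", {}).items():
        lines.append(f"\n## K-means, k = {k}")
        lines.append("| Cluster | Mean | Variance | SD | Size |")
        lines.append("|---|---|---|---|---|")
        st = res["descriptives"]
        for cid, m, v, s, n in zip(st.cluster_ids, st.means, st.variances,
                                   st.sds, st.sizes):
            lines.append(f"| {cid} | {_fmt_vec(m)} | {_fmt_vec(v)} | "
                         f"{_fmt_vec(s)} | {n} |")
        idx = res["indices"]
        if idx is None:
            lines.append("indices undefined (single cluster)")
        else:
            ci = (f" CI [{idx.silhouette_ci[0]:.3f}, {idx.silhouette_ci[1]:.3f}]"
                  if idx.silhouette_ci else "")
            lines.append(
                f"Silhouette {idx.silhouette:.3f}{ci}; "
                f"Davies-Bouldin {idx.davies_bouldin:.3f}; "
                f"Calinski-Harabasz {idx.calinski_harabasz:.1f}")
    if "ari" in bundle:
        lines.append(f"\nCluster/group agreement (ARI): {bundle['ari']:.3f}")
    if "transitions" in bundle:
        lines.append("\n## Pre/post cluster transitions")
        for k, tr in bundle["transitions"].items():
            for grp, moved in tr.items():
                n_moved = sum(moved.values())
                lines.append(f"- k={k} {grp}: {n_moved}/{len(moved)} subjects "
                             "changed cluster")
    eff = bundle.get("effects", {})
    if eff.get("cohens_d"):
        lines.append("\n## Effect sizes (Cohen's d)")
        lines.append("| Feature | TPEI pre vs post | Control pre vs post | "
                     "Healthy vs TPEI post |")
        lines.append("|---|---|---|---|")
        for feat, row in eff["cohens_d"].items():
            cells = []
            for key in ("tpei_pre_vs_post", "control_pre_vs_post",
                        "healthy_vs_tpei_post"):
                e = row.get(key)
                cells.append(f"{e.d:.2f} ({e.magnitude})" if e else "-")
            lines.append(f"| {feat} | " + " | ".join(cells) + " |")
    if eff.get("anova"):
        lines.append("\n## Classical tests (p-values across session cells)")
        lines.append("| Feature | ANOVA | Kruskal |")
        lines.append("|---|---|---|")
        for feat in eff["anova"]:
            lines.append(f"| {feat} | {eff['anova'][feat].p_value:.3f} | "
                         f"{eff['kruskal'][feat].p_value:.3f} |")
    shap = bundle.get("shap")
    if shap:
        lines.append("\n## Shapley feature importance (mean |phi|)")
        for _, r in shap["ranking"].iterrows():
            lines.append(f"- {r['feature']}: {r['mean_abs_phi']:.4f}")
    missing = [s for s in ("clusters", "effects") if s not in bundle]
    if missing:
        lines.append(f"\n(missing stages: {', '.join(missing)})")
    return "\n".join(lines) + "\n"


def write_bundle(bundle: dict, outdir: str | os.PathLike) -> None:
    """Write embedding, labels, indices, descriptives and report to disk."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    emb = bundle["embedding"]
    rows = pd.DataFrame(emb.Y, columns=["tsne_1", "tsne_2"])
    rows["label"] = bundle["plot_labels"]
    for k, res in bundle["clusters"].items():
        rows[f"cluster_k{k}"] = res["kmeans"].labels
    rows.to_csv(os.path.join(outdir, "embedding.csv"), index=False)
    summary = {}
    for k, res in bundle["clusters"].items():
        idx = res["indices"]
        summary[str(k)] = {
            "wcss": res["kmeans"].wcss,
            "silhouette": idx.silhouette if idx else None,
            "silhouette_ci": idx.silhouette_ci if idx else None,
            "davies_bouldin": idx.davies_bouldin if idx else None,
            "calinski_harabasz": idx.calinski_harabasz if idx else None,
        }
    with open(os.path.join(outdir, "indices.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    with open(os.path.join(outdir, "report.md"), "w") as fh:
        fh.write(report(bundle))
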