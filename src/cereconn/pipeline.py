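"""End-to-end orchestration: simulate -> QC -> connect -> metrics ->
contrasts -> ROC -> cluster -> report.

A single master seed is fanned out to per-stage seeds through a fixed
``SeedSequence`` derivation so stages rerun reproducibly in isolation.  A
manifest records the configuration hash and seed; downstream stages refuse
stale cached outputs whose manifest hash differs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, discrimination, io, metrics, simulate, stats
from .connectivity import connectome_from_timeseries, qc_exclude
from .types import CONDITIONS, ValidationError, default_atlas

logger = logging.getLogger(__name__)

_STAGE_NAMES = ("simulate", "qc", "metrics", "contrasts", "roc", "cluster", "report")


@dataclass
class PipelineConfig:
    """Validated configuration for a full synthetic-cohort run."""

    cohort: simulate.CohortConfig = field(default_factory=simulate.CohortConfig)
    subtype_preset: simulate.SubtypePreset = field(
        default_factory=simulate.default_subtype_preset
    )
    n_clinical: int = 98
    percentile: float = 85.0
    fd_threshold: float = 0.5
    fd_max_fraction: float = 0.20
    contrasts: tuple[tuple[str, str], ...] = stats.DEFAULT_CONTRASTS
    fdr_family: str = "class"
    q_threshold: float = 0.05
    roc_contrast: str = "SCZ:CON"
    roc_condition: str = "1-back"
    roc_bootstrap: int = 2000
    cluster_k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    cluster_iterations: int = 100
    cluster_subsample: float = 0.8
    permutation_B: int = 1000
    master_seed: int = 0

    def validate(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValidationError("percentile must lie in (0, 100)")
        if not 0 < self.q_threshold < 1:
            raise ValidationError("q_threshold must lie in (0, 1)")
        if min(self.cluster_k_range) < 2:
            raise ValidationError("cluster k range must start at 2 or above")
        if self.fdr_family not in ("class", "all"):
            raise ValidationError("fdr_family must be 'class' or 'all'")
        groups_in_contrasts = {g for c in self.contrasts for g in c}
        known = set(self.cohort.group_sizes)
        missing = groups_in_contrasts - known
        if missing:
            raise ValidationError(f"contrast groups absent from cohort: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = simulate.CohortConfig(**raw.pop("cohort", {}))
        preset_raw = raw.pop("subtype_preset", None)
        preset = (
            simulate.SubtypePreset(**preset_raw)
            if preset_raw
            else simulate.default_subtype_preset()
        )
        cfg = cls(cohort=cohort, subtype_preset=preset, **raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, pd.DataFrame):
                return obj.to_dict()
            if isinstance(obj, dict):
                return {str(k): encode(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        blob = json.dumps(encode(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seeds(master_seed: int, n: int = len(_STAGE_NAMES)) -> dict[str, int]:
    """Fixed fan-out of the master seed into independent per-stage seeds."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return {
        name: int(c.generate_state(1)[0] % (2**31))
        for name, c in zip(_STAGE_NAMES, children)
    }


def _write_json(path: Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=default))


@dataclass
class PipelineOutputs:
    out_dir: Path
    features: metrics.FeatureTable
    contrasts: pd.DataFrame
    qc: pd.DataFrame
    roc_summary: dict
    cluster_summary: dict
    report: dict


def run_all(config: PipelineConfig, out_dir: str | Path) -> PipelineOutputs:
    """Execute every stage on a synthetic cohort and write the report bundle."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.master_seed)
    chash = config.config_hash()
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") != chash:
            logger.info("config hash changed; ignoring cached outputs in %s", out)
    _write_json(manifest_path, {"config_hash": chash, "master_seed": config.master_seed,
                                "stage_seeds": seeds})

    # --- simulate ------------------------------------------------------
    cohort = dataclasses.replace(config.cohort, seed=seeds["simulate"])
    atlas = (
        default_atlas() if cohort.R == 165 else simulate._uniform_atlas(cohort.R)
    )
    try:
        series, traces = simulate.generate_roi_timeseries(cohort, atlas)
        clinical, truth = simulate.generate_clinical_table(
            config.subtype_preset, n=config.n_clinical, seed=seeds["simulate"]
        )
    except Exception as exc:  # pragma: no cover - defensive context wrapper
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    io.write_clinical_table(clinical, out / "clinical.csv")
    truth.to_frame().to_csv(out / "truth.csv")

    # --- QC ------------------------------------------------------------
    decisions = [
        qc_exclude(t, config.fd_threshold, config.fd_max_fraction) for t in traces
    ]
    qc_df = pd.DataFrame(
        {
            "subject_id": [d.subject_id for d in decisions],
            "proportion_high_fd": [d.proportion_high_fd for d in decisions],
            "decision": ["exclude" if d.exclude else "keep" for d in decisions],
        }
    )
    qc_df["config_hash"] = chash
    qc_df.to_csv(out / "qc.csv", index=False)
    excluded = {d.subject_id for d in decisions if d.exclude}

    # --- connect + metrics --------------------------------------------
    graphs = [
        connectome_from_timeseries(ts, config.percentile)
        for ts in series
        if ts.subject_id not in excluded
    ]
    table = metrics.build_feature_table(graphs, atlas, nodal=True)
    table.network.assign(config_hash=chash).to_csv(out / "features.csv", index=False)
    table.nodal_strength.assign(config_hash=chash).to_csv(
        out / "nodal_strength.csv", index=False
    )
    table.nodal_clustering.assign(config_hash=chash).to_csv(
        out / "nodal_clustering.csv", index=False
    )

    # --- contrasts -----------------------------------------------------
    contrast_df = stats.run_contrasts(
        table.network,
        table.feature_columns,
        contrasts=list(config.contrasts),
        family=config.fdr_family,
    )
    contrast_df.assign(config_hash=chash).to_csv(out / "contrasts.csv", index=False)

    # --- ROC -----------------------------------------------------------
    roc_summary: dict = {"status": "ok"}
    try:
        model = discrimination.fit_composite(
            contrast_df,
            contrast=config.roc_contrast,
            condition=config.roc_condition,
            q_threshold=config.q_threshold,
        )
        g1, g2 = config.roc_contrast.split(":")
        sub = table.network[
            (table.network["condition"] == config.roc_condition)
            & (table.network["group"].isin([g1, g2]))
        ]
        scores = discrimination.score(model, sub)
        labels = (sub["group"] == g1).astype(int).to_numpy()
        roc_res = discrimination.roc(
            scores.to_numpy(), labels, n_boot=config.roc_bootstrap, seed=seeds["roc"]
        )
        roc_summary.update(
            {
                "features": model.features,
                "weights": model.weights.tolist(),
                "auc": roc_res.auc,
                "auc_ci": roc_res.auc_ci,
                "youden_threshold": roc_res.youden_threshold,
                "sensitivity": roc_res.sensitivity,
                "specificity": roc_res.specificity,
                "flipped": roc_res.flipped,
                "scores": {str(k): float(v) for k, v in scores.items()},
            }
        )
    except discrimination.NoModelError as exc:
        roc_summary = {"status": f"no model: {exc}"}
    roc_summary["config_hash"] = chash
    _write_json(out / "roc.json", roc_summary)

    # --- cluster -------------------------------------------------------
    normalized = clustering.minmax_normalize(clinical)
    points = normalized.data.to_numpy(dtype=float)
    sel = clustering.select_k(
        points,
        k_range=list(config.cluster_k_range),
        iterations=config.cluster_iterations,
        subsample=config.cluster_subsample,
        seed=seeds["cluster"],
    )
    solution = sel.solutions[sel.chosen_k]
    solution.metrics.update(clustering.stability_metrics(solution, points))
    solution.permutation_p = clustering.permutation_test(
        points, sel.chosen_k, B=config.permutation_B, seed=seeds["cluster"]
    )
    profile, comp = clustering.profile_subtypes(solution.labels, normalized)
    labels_df = pd.DataFrame(
        {"subject_id": normalized.data.index, "subtype": solution.labels,
         "config_hash": chash}
    )
    labels_df.to_csv(out / "labels.csv", index=False)
    np.savetxt(out / "consensus.tsv", solution.consensus, delimiter="\t", fmt="%.6f")
    profile.to_csv(out / "profiles.csv")
    comp.to_csv(out / "composition.csv")
    cluster_summary = {
        "chosen_k": sel.chosen_k,
        "stable": sel.stable,
        "metrics_per_k": {str(k): row.to_dict() for k, row in sel.table.iterrows()},
        "metrics": solution.metrics,
        "permutation_p": solution.permutation_p,
        "dropped_rows": normalized.dropped,
        "config_hash": chash,
    }
    _write_json(out / "cluster_metrics.json", cluster_summary)

    report = make_report(
        out, contrasts=contrast_df, roc_summary=roc_summary,
        cluster_summary=cluster_summary, q_threshold=config.q_threshold,
        config_hash=chash,
    )
    return PipelineOutputs(
        out_dir=out,
        features=table,
        contrasts=contrast_df,
        qc=qc_df,
        roc_summary=roc_summary,
        cluster_summary=cluster_summary,
        report=report,
    )


def make_report(
    out_dir: str | Path,
    contrasts: pd.DataFrame | None = None,
    roc_summary: dict | None = None,
    cluster_summary: dict | None = None,
    q_threshold: float = 0.05,
    config_hash: str = "",
) -> dict:
    """Assemble machine- and human-readable summaries of a run's outputs."""
    out = Path(out_dir)
    report: dict = {"config_hash": config_hash}
    if contrasts is not None:
        sig = contrasts[contrasts["q"] < q_threshold]
        report["significant_features"] = [
            {
                "condition": r["condition"],
                "contrast": r["contrast"],
                "feature": r["feature"],
                "d": float(r["d"]),
                "q": float(r["q"]),
            }
            for _, r in sig.iterrows()
        ]
    else:
        report["significant_features"] = "not run"
    report["roc"] = (
        {k: v for k, v in roc_summary.items() if k != "scores"}
        if roc_summary is not None
        else "not run"
    )
    report["clustering"] = cluster_summary if cluster_summary is not None else "not run"
    _write_json(out / "report.json", report)

    lines = ["# Pipeline report", "", f"Config hash: `{config_hash}`", ""]
    lines.append("## Significant features (q < %.3g)" % q_threshold)
    if isinstance(report["significant_features"], list):
        if report["significant_features"]:
            for item in report["significant_features"]:
                lines.append(
                    f"- {item['condition']} {item['contrast']} {item['feature']}: "
                    f"d = {item['d']:.3f}, q = {item['q']:.4f}"
                )
        else:
            lines.append("- none")
    lines.append("")
    if isinstance(report["roc"], dict) and report["roc"].get("status") == "ok":
        r = report["roc"]
        lines.append(
            f"## ROC\n- AUC = {r['auc']:.3f} (95% CI {r['auc_ci'][0]:.3f}-{r['auc_ci'][1]:.3f}), "
            f"sensitivity {r['sensitivity']:.2f}, specificity {r['specificity']:.2f}"
        )
    if isinstance(report["clustering"], dict):
        c = report["clustering"]
        lines.append(
            f"## Clustering\n- chosen k = {c['chosen_k']}, "
            f"PAC = {c['metrics'].get('PAC', float('nan')):.3f}, "
            f"permutation p = {c.get('permutation_p')}"
        )
    (out / "report.md").write_text("\n".join(lines) + "\n")
    return report
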