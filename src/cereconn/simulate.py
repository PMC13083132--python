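"""Synthetic cohort generator for the dysconnectivity pipeline.

Two generation modes cover complementary needs:

* **time-series mode** draws ROI x time BOLD matrices from multivariate
  normals with a network-block correlation structure (plus FD motion
  traces), exercising the full connectivity pipeline end to end;
* **direct-feature mode** draws the 33 network-feature vectors from a
  multivariate normal in which contrasted groups differ by exactly the
  planted standardized amounts, giving precise control for effect-size
  recovery studies.

The generator's defaults emulate the reference study conditions: four
diagnostic groups (SCZ 23, SCZ-SIB 34, CON 20, CON-SIB 21), three N-back
load levels, 165 ROIs in six networks, cerebellar-cortical hypoconnectivity
that is maximal at 1-back (CER-SM d = -1.547, CER-CO d = -1.155 for
SCZ vs CON; CER-SM d = -1.086 for SCZ vs SCZ-SIB), and a three-subtype
clinical-cognitive structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import META_COLUMNS, network_feature_columns
from .types import (
    AtlasMap,
    CLINICAL_FEATURES,
    COGNITIVE_COLUMNS,
    CONDITIONS,
    ClinicalTable,
    DEFAULT_GROUP_SIZES,
    FdTrace,
    GROUPS,
    NETWORKS,
    RoiTimeSeries,
    SYMPTOM_COLUMNS,
    SYMPTOM_SCALE,
    ValidationError,
    default_atlas,
)


@dataclass(frozen=True)
class FeatureEffect:
    """A planted standardized group difference on one named feature.

    ``d`` is the standardized mean difference (first group minus second) for
    ``contrast`` at ``condition``.
    """

    contrast: tuple[str, str]
    condition: str
    feature: str
    d: float


#: Planted effects reproducing the dysconnectivity pattern the pipeline is
#: designed to detect: cerebellum-sensorimotor and cerebellum-cingulo-
#: opercular hypoconnectivity in patients, maximal at the 1-back load, with
#: a state (SCZ vs SCZ-SIB) but no trait (SCZ-SIB vs CON-SIB) component.
REFERENCE_EFFECTS: tuple[FeatureEffect, ...] = (
    FeatureEffect(("SCZ", "CON"), "0-back", "CER-SM", -1.078),
    FeatureEffect(("SCZ", "CON"), "0-back", "CER-DMN", 0.726),
    FeatureEffect(("SCZ", "CON"), "1-back", "CER-SM", -1.547),
    FeatureEffect(("SCZ", "CON"), "1-back", "CER-CO", -1.155),
    FeatureEffect(("SCZ", "CON"), "2-back", "CER-SM", -0.914),
    FeatureEffect(("SCZ", "SCZ-SIB"), "1-back", "CER-SM", -1.086),
)

#: Correlation-scale deficits for time-series mode, mirroring the ordering
#: of the planted feature-scale effects (largest CER-SM deficit at 1-back).
REFERENCE_BLOCK_DELTAS: dict[tuple[str, str], dict[str, float]] = {
    ("SCZ", "0-back"): {"CER-SM": -0.10, "CER-DMN": 0.07},
    ("SCZ", "1-back"): {"CER-SM": -0.15, "CER-CO": -0.11},
    ("SCZ", "2-back"): {"CER-SM": -0.09},
}


@dataclass
class CohortConfig:
    """Study-condition parameters for both generation modes."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    conditions: tuple[str, ...] = CONDITIONS
    R: int = 165
    T: int = 137
    sampling_interval: float = 2.5
    within_network_corr: float = 0.3
    between_network_corr: float = 0.1
    group_block_deltas: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in REFERENCE_BLOCK_DELTAS.items()}
    )
    effect_map: tuple[FeatureEffect, ...] = REFERENCE_EFFECTS
    feature_rho: float = 0.25
    noise_sd: float = 0.0
    high_motion_fraction: float = 0.12
    fd_low_median: float = 0.12
    fd_low_sigma: float = 0.4
    fd_high_median: float = 0.6
    fd_high_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValidationError(f"group {g!r} size must be >= 2, got {n}")
        if not -1 < self.between_network_corr < 1:
            raise ValidationError("between_network_corr must lie in (-1, 1)")
        if not 0 < self.within_network_corr < 1:
            raise ValidationError("within_network_corr must lie in (0, 1)")
        for eff in self.effect_map:
            if not np.isfinite(eff.d):
                raise ValidationError("planted differences must be finite")


# ---------------------------------------------------------------------------
# Covariance construction (time-series mode)
# ---------------------------------------------------------------------------


def build_target_covariance(
    block_corr: np.ndarray | pd.DataFrame,
    atlas: AtlasMap,
    within_network_corr: float,
) -> np.ndarray:
    """Expand a network-block correlation matrix to the full R x R target.

    Within-block off-diagonals get ``within_network_corr``; between-block
    cells get the corresponding ``block_corr`` entry; the diagonal is 1.
    A non-positive-definite result is projected to the nearest valid
    correlation matrix by eigenvalue clipping (floor 1e-6) followed by
    diagonal renormalization.
    """
    if isinstance(block_corr, pd.DataFrame):
        block = block_corr.loc[list(atlas.networks), list(atlas.networks)].to_numpy(float)
    else:
        block = np.asarray(block_corr, dtype=float)
    if block.shape != (len(atlas.networks),) * 2:
        raise ValidationError("block_corr must be K x K for the atlas's K networks")
    if not np.allclose(block, block.T):
        raise ValidationError("block_corr must be symmetric")
    if not 0 < within_network_corr < 1:
        raise ValidationError("within_network_corr must lie in (0, 1)")

    membership = np.array(
        [atlas.networks.index(atlas.network_of[r]) for r in atlas.roi_labels]
    )
    c = block[np.ix_(membership, membership)].copy()
    same = membership[:, None] == membership[None, :]
    c[same] = within_network_corr
    np.fill_diagonal(c, 1.0)

    for _ in range(20):
        eigvals = np.linalg.eigvalsh(c)
        if eigvals[0] >= 1e-6:
            return c
        vals, vecs = np.linalg.eigh(c)
        vals = np.clip(vals, 1e-6, None)
        c = (vecs * vals) @ vecs.T
        dsqrt = np.sqrt(np.diag(c))
        c = c / np.outer(dsqrt, dsqrt)
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
    raise ValidationError("block structure remains non-positive-definite after projection")


def _block_matrix_for(config: CohortConfig, group: str, condition: str) -> pd.DataFrame:
    from .metrics import pair_name

    k = len(NETWORKS)
    block = np.full((k, k), config.between_network_corr)
    np.fill_diagonal(block, config.within_network_corr)
    df = pd.DataFrame(block, index=list(NETWORKS), columns=list(NETWORKS))
    deltas = config.group_block_deltas.get((group, condition), {})
    for pair, delta in deltas.items():
        a, b = pair.split("-")
        name_check = pair_name(a, b)
        if name_check != pair:
            raise ValidationError(f"block delta pair {pair!r} not in canonical order")
        df.loc[a, b] += delta
        df.loc[b, a] = df.loc[a, b]
    return df


def generate_roi_timeseries(
    config: CohortConfig, atlas: AtlasMap | None = None
) -> tuple[list[RoiTimeSeries], list[FdTrace]]:
    """Draw per-subject x condition BOLD matrices and FD motion traces.

    Each series is zero-mean multivariate normal with the group x condition
    target covariance plus isotropic observation noise (``noise_sd``).  FD
    traces are log-normal, with a ``high_motion_fraction`` of subjects drawn
    from a high-motion regime that trips the exclusion rule.  Fully
    deterministic given ``config.seed``.
    """
    import warnings

    atlas = atlas if atlas is not None else (
        default_atlas() if config.R == 165 else _uniform_atlas(config.R)
    )
    if atlas.n_rois != config.R:
        raise ValidationError("atlas size does not match config.R")
    if config.T < config.R:
        warnings.warn(
            "T < R: sample covariance is rank-deficient (thresholding still applies)",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    chol_cache: dict[tuple[str, str], np.ndarray] = {}
    series: list[RoiTimeSeries] = []
    traces: list[FdTrace] = []
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        for i in range(n):
            sid = f"{group}{i + 1:03d}"
            high_motion = rng.random() < config.high_motion_fraction
            median, sigma = (
                (config.fd_high_median, config.fd_high_sigma)
                if high_motion
                else (config.fd_low_median, config.fd_low_sigma)
            )
            traces.append(
                FdTrace(sid, rng.lognormal(np.log(median), sigma, size=config.T))
            )
            for cond in config.conditions:
                key = (group, cond)
                if key not in chol_cache:
                    cov = build_target_covariance(
                        _block_matrix_for(config, group, cond),
                        atlas,
                        config.within_network_corr,
                    )
                    cov = cov + config.noise_sd**2 * np.eye(config.R)
                    chol_cache[key] = np.linalg.cholesky(cov)
                data = chol_cache[key] @ rng.standard_normal((config.R, config.T))
                series.append(
                    RoiTimeSeries(
                        subject_id=sid,
                        group=group,
                        condition=cond,
                        data=data,
                        sampling_interval=config.sampling_interval,
                        roi_labels=atlas.roi_labels,
                    )
                )
    return series, traces


def _uniform_atlas(R: int) -> AtlasMap:
    from .types import make_atlas

    base, extra = divmod(R, len(NETWORKS))
    sizes = {k: base + (1 if i < extra else 0) for i, k in enumerate(NETWORKS)}
    return make_atlas(sizes)


# ---------------------------------------------------------------------------
# Direct-feature mode
# ---------------------------------------------------------------------------


def resolve_group_means(
    effects: tuple[FeatureEffect, ...] | list[FeatureEffect],
    feature_columns: list[str],
) -> dict[tuple[str, str], dict[str, float]]:
    """Turn pairwise planted differences into per-group mean vectors.

    Group means start at 0 (unit SD scale).  Effects are applied in order:
    for contrast (A, B) with difference d, the undetermined side is set so
    that mean_A - mean_B = d.  Conflicting constraints raise.
    """
    means: dict[tuple[str, str], dict[str, float]] = {}
    determined: set[tuple[str, str, str]] = set()
    for eff in effects:
        if eff.feature not in feature_columns:
            raise ValidationError(f"unknown feature {eff.feature!r} in effect map")
        a, b = eff.contrast
        key_a, key_b = (a, eff.condition, eff.feature), (b, eff.condition, eff.feature)
        cond_means_a = means.setdefault((a, eff.condition), {})
        cond_means_b = means.setdefault((b, eff.condition), {})
        ma = cond_means_a.get(eff.feature, 0.0)
        mb = cond_means_b.get(eff.feature, 0.0)
        if key_a in determined and key_b in determined:
            if not np.isclose(ma - mb, eff.d):
                raise ValidationError(f"conflicting planted effects for {eff}")
        elif key_a in determined:
            cond_means_b[eff.feature] = ma - eff.d
            determined.add(key_b)
        else:
            cond_means_a[eff.feature] = mb + eff.d
            determined.add(key_a)
            determined.add(key_b)
    return means


def generate_feature_tables(
    config: CohortConfig,
    groups: list[str] | None = None,
    conditions: list[str] | None = None,
    n_per_group: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw 33-feature vectors with exactly the planted group differences.

    Features are unit-variance with equicorrelation ``config.feature_rho``;
    contrasted groups differ by the planted standardized amounts of
    ``config.effect_map``.  Returns a long table with subject_id /
    condition / group metadata plus the 33 feature columns.
    """
    feature_cols = network_feature_columns(NETWORKS)
    means = resolve_group_means(config.effect_map, feature_cols)
    groups = list(groups) if groups is not None else list(GROUPS)
    conditions = list(conditions) if conditions is not None else list(config.conditions)
    rho = config.feature_rho
    p = len(feature_cols)
    cov = np.full((p, p), rho)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    frames = []
    for group in groups:
        n = n_per_group if n_per_group is not None else config.group_sizes.get(group, 0)
        if n < 2:
            raise ValidationError(f"group {group!r} needs n >= 2")
        sids = [f"{group}{i + 1:04d}" for i in range(n)]
        for cond in conditions:
            mu = np.zeros(p)
            for feat, val in means.get((group, cond), {}).items():
                mu[feature_cols.index(feat)] = val
            draws = rng.standard_normal((n, p)) @ chol.T + mu
            frame = pd.DataFrame(draws, columns=feature_cols)
            frame.insert(0, "group", group)
            frame.insert(0, "condition", cond)
            frame.insert(0, "subject_id", sids)
            frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out[META_COLUMNS + feature_cols]


# ---------------------------------------------------------------------------
# Clinical-cognitive subtype structure
# ---------------------------------------------------------------------------


def _default_centroids() -> pd.DataFrame:
    """Normalized [0, 1] subtype centroids for the default three-subtype preset."""
    c1 = {col: 0.05 for col in SYMPTOM_COLUMNS}
    c1.update({col: 0.625 for col in COGNITIVE_COLUMNS})

    c2 = {
        "saps_global": 0.35,
        "sans_global": 0.55,
        "saps_hallucinations": 0.45,
        "saps_delusions": 0.35,
        "saps_bizarre_behavior": 0.25,
        "saps_formal_thought_disorder": 0.35,
        "sans_affective_flattening": 0.65,
        "sans_alogia": 0.50,
        "sans_avolition_apathy": 0.55,
        "sans_anhedonia_asociality": 0.45,
        "sans_attention": 0.50,
        "cog_vocabulary": 0.375,
        "cog_symbol_search": 0.40,
        "cog_trail_making_a": 0.40,
        "cog_logical_memory_i": 0.425,
        "cog_logical_memory_ii": 0.425,
        "cog_family_pictures_i": 0.40,
        "cog_family_pictures_ii": 0.40,
        "cog_letter_number_sequencing": 0.475,
        "cog_digit_span": 0.475,
    }
    c3 = {col: 0.20 for col in SYMPTOM_COLUMNS}
    c3.update({col: 0.45 for col in COGNITIVE_COLUMNS})
    c3["cog_letter_number_sequencing"] = 0.525
    c3["cog_digit_span"] = 0.525
    return pd.DataFrame([c1, c2, c3], index=[1, 2, 3])[list(CLINICAL_FEATURES)]


@dataclass
class SubtypePreset:
    """Generative parameters for the clinical-cognitive subtype structure."""

    k: int = 3
    centroids: pd.DataFrame = field(default_factory=_default_centroids)
    within_subtype_sd: float = 0.05
    mixing: tuple[float, ...] = (36 / 98, 29 / 98, 33 / 98)
    group_composition: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            1: {"CON": 0.56, "CON-SIB": 0.44},
            2: {"SCZ": 0.79, "SCZ-SIB": 0.21},
            3: {"SCZ": 0.29, "SCZ-SIB": 0.29, "CON": 0.21, "CON-SIB": 0.21},
        }
    )

    def __post_init__(self) -> None:
        if self.centroids.shape[0] != self.k:
            raise ValidationError("centroids must have one row per subtype")
        vals = self.centroids.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValidationError("centroids must lie in [0, 1]")
        if not np.isclose(sum(self.mixing), 1.0):
            raise ValidationError("mixing proportions must sum to 1")


def default_subtype_preset() -> SubtypePreset:
    return SubtypePreset()


def generate_clinical_table(
    preset: SubtypePreset, n: int = 98, seed: int = 0
) -> tuple[ClinicalTable, pd.Series]:
    """Draw a clinical-cognitive table with planted subtype structure.

    Each subject's subtype is multinomial with the preset mixing; features
    are the subtype centroid plus Gaussian noise clipped to [0, 1]; the
    diagnostic group label follows the subtype's composition.  Symptom
    columns are emitted on the raw 0-5 scale with declared bounds so
    normalization recovers the [0, 1] values exactly.  Returns the table
    and the hidden true-subtype assignment (evaluation only).
    """
    if n < preset.k:
        raise ValidationError("n must be at least the number of subtypes")
    rng = np.random.default_rng(seed)
    subtypes = rng.choice(
        np.arange(1, preset.k + 1), size=n, p=np.asarray(preset.mixing)
    )
    feats = list(preset.centroids.columns)
    centro = preset.centroids.loc[subtypes].to_numpy(dtype=float)
    noise = rng.standard_normal((n, len(feats))) * preset.within_subtype_sd
    values = np.clip(centro + noise, 0.0, 1.0)

    lo, hi = SYMPTOM_SCALE
    data = pd.DataFrame(values, columns=feats)
    bounds: dict[str, tuple[float, float]] = {}
    for col in feats:
        if col in SYMPTOM_COLUMNS:
            data[col] = data[col] * (hi - lo) + lo
            bounds[col] = (lo, hi)
        else:
            bounds[col] = (0.0, 1.0)

    group_labels = []
    for s in subtypes:
        comp = preset.group_composition.get(int(s), {})
        gs = list(comp) or list(GROUPS)
        ps = np.array([comp.get(g, 0.0) for g in gs], dtype=float)
        ps = ps / ps.sum() if ps.sum() > 0 else np.full(len(gs), 1 / len(gs))
        group_labels.append(rng.choice(gs, p=ps))
    data.insert(0, "group", group_labels)
    data.index = pd.Index([f"sub{i + 1:03d}" for i in range(n)], name="subject_id")
    truth = pd.Series(subtypes, index=data.index, name="true_subtype")
    return ClinicalTable(data=data, column_bounds=bounds), truth
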