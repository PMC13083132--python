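"""Shared domain types for the task-fMRI network-dysconnectivity pipeline.

The analysis operates on a cohort of four diagnostic groups (schizophrenia
patients, their unaffected siblings, healthy controls, and control siblings)
scanned during an N-back working-memory task at three load levels.  Regional
BOLD signals are summarised per atlas region of interest (ROI); ROIs belong
to one of six canonical large-scale networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Diagnostic groups, in the fixed order used throughout.
GROUPS: tuple[str, ...] = ("SCZ", "SCZ-SIB", "CON", "CON-SIB")

#: N-back load conditions.
CONDITIONS: tuple[str, ...] = ("0-back", "1-back", "2-back")

#: Canonical networks in fixed order so feature indices are stable.
NETWORKS: tuple[str, ...] = ("DMN", "FP", "CO", "SM", "OCC", "CER")

#: Default cohort sizes per group.
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "SCZ": 23,
    "SCZ-SIB": 34,
    "CON": 20,
    "CON-SIB": 21,
}

# ---------------------------------------------------------------------------
# Clinical-cognitive feature space (20 variables)
# ---------------------------------------------------------------------------

SAPS_DOMAIN_COLUMNS: tuple[str, ...] = (
    "saps_hallucinations",
    "saps_delusions",
    "saps_bizarre_behavior",
    "saps_formal_thought_disorder",
)
SANS_DOMAIN_COLUMNS: tuple[str, ...] = (
    "sans_affective_flattening",
    "sans_alogia",
    "sans_avolition_apathy",
    "sans_anhedonia_asociality",
    "sans_attention",
)
#: Symptom columns share the 0-5 rating scale of the SAPS/SANS instruments.
SYMPTOM_COLUMNS: tuple[str, ...] = (
    ("saps_global", "sans_global") + SAPS_DOMAIN_COLUMNS + SANS_DOMAIN_COLUMNS
)
COGNITIVE_COLUMNS: tuple[str, ...] = (
    "cog_vocabulary",
    "cog_symbol_search",
    "cog_trail_making_a",
    "cog_logical_memory_i",
    "cog_logical_memory_ii",
    "cog_family_pictures_i",
    "cog_family_pictures_ii",
    "cog_letter_number_sequencing",
    "cog_digit_span",
)
#: Full clinical-cognitive feature vector used for subtyping.
CLINICAL_FEATURES: tuple[str, ...] = SYMPTOM_COLUMNS + COGNITIVE_COLUMNS

#: Theoretical range of the SAPS/SANS rating scale.
SYMPTOM_SCALE: tuple[float, float] = (0.0, 5.0)


class FormatError(ValueError):
    """Raised when an on-disk table violates its declared format."""


class ValidationError(ValueError):
    """Raised when in-memory data violates a domain invariant."""


@dataclass(frozen=True)
class AtlasMap:
    """Assignment of ROI labels to canonical networks.

    ``roi_labels`` fixes the row order of every downstream matrix;
    ``networks`` fixes the order of network-level features.
    """

    roi_labels: tuple[str, ...]
    network_of: dict[str, str]
    networks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValidationError("duplicate ROI labels in atlas")
        if len(set(self.networks)) != len(self.networks):
            raise ValidationError("duplicate network names in atlas")
        missing = [r for r in self.roi_labels if r not in self.network_of]
        if missing:
            raise ValidationError(f"ROIs without network assignment: {missing[:5]}")
        unknown = set(self.network_of.values()) - set(self.networks)
        if unknown:
            raise ValidationError(f"network_of refers to unknown networks: {sorted(unknown)}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def indices(self, network: str) -> np.ndarray:
        """Row indices of the ROIs belonging to ``network``."""
        if network not in self.networks:
            raise ValidationError(f"unknown network {network!r}")
        return np.array(
            [i for i, r in enumerate(self.roi_labels) if self.network_of[r] == network],
            dtype=int,
        )

    def network_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {k: 0 for k in self.networks}
        for r in self.roi_labels:
            sizes[self.network_of[r]] += 1
        return sizes

    def require_min_sizes(self, minimum: int = 2) -> None:
        """Downstream network metrics need at least ``minimum`` ROIs per network."""
        small = {k: n for k, n in self.network_sizes().items() if n < minimum}
        if small:
            raise ValidationError(f"networks with fewer than {minimum} ROIs: {small}")


#: Approximate relative sizes of the six networks in a 160-region
#: Dosenbach-style parcellation, rescaled here to 165 ROIs.
_DEFAULT_NETWORK_SIZES: dict[str, int] = {
    "DMN": 34,
    "FP": 21,
    "CO": 32,
    "SM": 33,
    "OCC": 22,
    "CER": 23,
}


def make_atlas(sizes: dict[str, int] | None = None) -> AtlasMap:
    """Build a label-only atlas with the given ROIs-per-network counts.

    Labels are synthetic (``DMN_001`` ...); real anatomical coordinates are
    out of scope for this package.
    """
    sizes = dict(sizes) if sizes is not None else dict(_DEFAULT_NETWORK_SIZES)
    labels: list[str] = []
    network_of: dict[str, str] = {}
    for net, n in sizes.items():
        for i in range(n):
            lab = f"{net}_{i + 1:03d}"
            labels.append(lab)
            network_of[lab] = net
    return AtlasMap(tuple(labels), network_of, tuple(sizes))


def default_atlas() -> AtlasMap:
    """The default 165-ROI, six-network atlas."""
    return make_atlas()


@dataclass
class RoiTimeSeries:
    """One subject x condition matrix of ROI BOLD signals (R x T)."""

    subject_id: str
    group: str
    condition: str
    data: np.ndarray
    sampling_interval: float = 2.5
    roi_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("time-series data must be a 2-D (R x T) array")
        if self.data.shape[1] < 3:
            raise ValidationError(f"need at least 3 time points, got {self.data.shape[1]}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("time-series data contains non-finite values")
        if self.roi_labels is not None and len(self.roi_labels) != self.data.shape[0]:
            raise ValidationError("roi_labels length does not match data rows")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class FdTrace:
    """Per-volume framewise displacement (mm) for one subject."""

    subject_id: str
    fd: np.ndarray

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        if self.fd.ndim != 1 or self.fd.size == 0:
            raise ValidationError("FD trace must be a non-empty 1-D array")
        if np.any(self.fd < 0) or not np.all(np.isfinite(self.fd)):
            raise ValidationError("FD values must be finite and non-negative")


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics (n, mean, sd) for one feature in one group."""

    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")


@dataclass
class ClinicalTable:
    """Clinical-cognitive table keyed by subject_id.

    ``data`` holds one row per subject with a ``group`` column plus the 20
    clinical-cognitive features; missing values are NaN.  ``column_bounds``
    optionally declares the theoretical (min, max) of a column; columns
    without declared bounds are normalized to their observed range.
    """

    data: pd.DataFrame
    column_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.name != "subject_id":
            raise ValidationError("clinical table index must be subject_id")
        if len(set(self.data.columns)) != len(self.data.columns):
            raise ValidationError("duplicate column names in clinical table")
        lo, hi = SYMPTOM_SCALE
        for col in self.data.columns:
            if col in SYMPTOM_COLUMNS:
                vals = self.data[col]
                bad = vals[(vals < lo) | (vals > hi)].dropna()
                if len(bad):
                    row = bad.index[0]
                    raise ValidationError(
                        f"symptom score out of [{lo}, {hi}] range: "
                        f"row {row!r}, column {col!r}, value {bad.iloc[0]}"
                    )

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c in CLINICAL_FEATURES]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask of missing cells over the feature columns."""
        return self.data[self.feature_columns].isna()
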