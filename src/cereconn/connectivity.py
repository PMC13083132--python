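"""Functional-connectivity graph construction and motion QC.

A subject x condition graph is built as: pairwise Pearson correlation of
ROI time series -> Fisher r-to-z variance stabilisation -> sparsification at
the 85th percentile of the absolute off-diagonal values.  Surviving edges
keep their signed z value; everything else is zeroed.  Subjects whose
framewise displacement exceeds 0.5 mm in at least 20% of volumes are
excluded before graph construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import FdTrace, RoiTimeSeries, ValidationError

#: |r| is clipped here before arctanh so duplicated series stay finite.
_R_CLIP = 1.0 - 1e-7


@dataclass
class QcDecision:
    """Motion-exclusion decision for one subject."""

    subject_id: str
    proportion_high_fd: float
    exclude: bool


@dataclass
class ConnectomeGraph:
    """Sparse symmetric weighted connectivity matrix for one subject x condition.

    ``weights`` holds the retained signed Fisher-z values; zeros are removed
    edges; the diagonal is zero.
    """

    subject_id: str
    group: str
    condition: str
    weights: np.ndarray
    retained_fraction: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError("graph weights must be square")
        if not np.all(np.isfinite(w)):
            raise ValidationError("graph weights must be finite")
        if not np.allclose(w, w.T):
            raise ValidationError("graph weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValidationError("graph diagonal must be zero")
        self.weights = w

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


def qc_exclude(
    trace: FdTrace, fd_threshold: float = 0.5, max_fraction: float = 0.20
) -> QcDecision:
    """Apply the motion-exclusion rule.

    A subject is excluded when the fraction of volumes with FD above
    ``fd_threshold`` (mm) reaches ``max_fraction`` (boundary inclusive).
    """
    if trace.fd.size == 0:
        raise ValidationError("empty FD trace")
    proportion = float(np.mean(trace.fd > fd_threshold))
    return QcDecision(trace.subject_id, proportion, exclude=proportion >= max_fraction)


def pearson_matrix(ts: RoiTimeSeries) -> np.ndarray:
    """Pairwise Pearson correlations between ROI time series (R x R)."""
    data = ts.data
    sd = data.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        i = int(flat[0])
        name = ts.roi_labels[i] if ts.roi_labels is not None else f"row {i}"
        raise ValidationError(f"constant time series for ROI {name}")
    r = np.corrcoef(data)
    # BLAS products are not exactly symmetric; enforce it so downstream
    # percentile thresholding sees exactly duplicated off-diagonal pairs
    r = (r + r.T) / 2.0
    # guard against tiny numerical excursions outside [-1, 1]
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher r-to-z transform, elementwise arctanh with |r| clipped.

    The diagonal is zeroed: self-correlations carry no information and the
    later percentile is taken over off-diagonal values only.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValidationError("correlation matrix contains non-finite values")
    if np.any(np.abs(r) > 1):
        raise ValidationError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    if z.ndim == 2 and z.shape[0] == z.shape[1]:
        np.fill_diagonal(z, 0.0)
    return z


def threshold_sparsify(
    z: np.ndarray,
    percentile: float = 85.0,
    *,
    subject_id: str = "",
    group: str = "",
    condition: str = "",
) -> ConnectomeGraph:
    """Sparsify a symmetric z matrix at a percentile of |off-diagonal| values.

    The cutoff is the linear-interpolation ``percentile`` of the absolute
    off-diagonal entries (both triangles, matching the off-diagonal wording
    of the convention); entries with |z| >= cutoff keep their signed value,
    all others are zeroed.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValidationError("z matrix must be square")
    r = z.shape[0]
    if r < 3:
        raise ValidationError("need at least 3 ROIs to sparsify")
    if not np.allclose(z, z.T):
        raise ValidationError("z matrix must be symmetric")
    off = ~np.eye(r, dtype=bool)
    cutoff = float(np.percentile(np.abs(z[off]), percentile))
    weights = np.where(np.abs(z) >= cutoff, z, 0.0)
    np.fill_diagonal(weights, 0.0)
    weights = (weights + weights.T) / 2.0  # symmetrize (no-op for exact input)
    iu = np.triu_indices(r, k=1)
    retained = float(np.count_nonzero(weights[iu]) / iu[0].size)
    return ConnectomeGraph(
        subject_id=subject_id,
        group=group,
        condition=condition,
        weights=weights,
        retained_fraction=retained,
    )


def connectome_from_timeseries(
    ts: RoiTimeSeries, percentile: float = 85.0
) -> ConnectomeGraph:
    """Full pipeline: Pearson -> Fisher z -> percentile sparsification."""
    z = fisher_z(pearson_matrix(ts))
    return threshold_sparsify(
        z,
        percentile,
        subject_id=ts.subject_id,
        group=ts.group,
        condition=ts.condition,
    )
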