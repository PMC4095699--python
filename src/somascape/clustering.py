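"""Unsupervised discovery of genomic subsets.

Probe-level state vectors are encoded on an ordinal scale (LOSS -1,
NEUTRAL 0, GAIN +1, AMP +2) and clustered agglomeratively with Ward linkage
on Euclidean distances.  The linkage tree is returned alongside the labels
so callers can cut at a different k or at a height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, fcluster, linkage

from .calling import State
from .errors import ValidationError
from .recurrence import (
    RegionContrast,
    StatusMatrix,
    compare_group_frequencies,
    frequency_profile,
)

DEFAULT_ENCODING: dict[State, float] = {
    State.LOSS: -1.0,
    State.NEUTRAL: 0.0,
    State.GAIN: 1.0,
    State.AMP: 2.0,
}


@dataclass
class SubsetResult:
    """Clustering outcome: flat labels plus the full merge tree."""

    sample_ids: list[str]
    labels: np.ndarray  # int, 0-based cluster labels
    linkage: np.ndarray  # scipy linkage matrix, (n-1, 4)
    k: int

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, lab in zip(self.sample_ids, self.labels):
            out.setdefault(int(lab), []).append(sid)
        return out


def encode_states(
    matrix: StatusMatrix, encoding: dict[State, float] | None = None
) -> np.ndarray:
    """Samples x probes float matrix under the ordinal state encoding."""
    encoding = encoding or DEFAULT_ENCODING
    lut = np.zeros(max(int(s) for s in State) + 1, dtype=float)
    for state, value in encoding.items():
        lut[int(state)] = value
    return lut[matrix.states]


def ward_cluster(
    matrix: StatusMatrix,
    k: int = 2,
    encoding: dict[State, float] | None = None,
) -> SubsetResult:
    """Ward/Euclidean agglomerative clustering of encoded state vectors."""
    n = matrix.n_samples
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n:
        raise ValidationError(f"k={k} exceeds sample count {n}")
    encoded = encode_states(matrix, encoding)
    if n == 1:
        return SubsetResult(list(matrix.sample_ids), np.zeros(1, dtype=int),
                            np.empty((0, 4)), k)
    tree = linkage(encoded, method="ward", metric="euclidean")
    labels = np.asarray(cut_tree(tree, n_clusters=k)).ravel().astype(int)
    return SubsetResult(list(matrix.sample_ids), labels, tree, k)


def cut_at_height(result: SubsetResult, height: float) -> np.ndarray:
    """Alternative flat labels from cutting the stored tree at a merge height."""
    if result.linkage.size == 0:
        return np.zeros(len(result.sample_ids), dtype=int)
    raw = fcluster(result.linkage, t=height, criterion="distance")
    return (raw - raw.min()).astype(int)


def characterize_subsets(
    matrix: StatusMatrix,
    labels: np.ndarray,
    min_diff: float = 0.2,
    min_snps: int = 25,
) -> tuple[dict[int, dict[str, np.ndarray]], dict[tuple[int, int], list[RegionContrast]]]:
    """Per-subset event frequency profiles and pairwise region contrasts.

    Returns ``(profiles, contrasts)`` where ``profiles[label][event]`` is a
    per-probe frequency array (events: loss, gain, amp) and
    ``contrasts[(a, b)]`` lists regions separating subsets a and b.
    """
    labels = np.asarray(labels)
    if labels.shape != (matrix.n_samples,):
        raise ValidationError("labels length must equal sample count")
    uniq = sorted(int(v) for v in np.unique(labels))
    submatrices = {}
    for lab in uniq:
        idx = np.flatnonzero(labels == lab)
        if idx.size == 0:
            raise ValidationError(f"subset {lab} has no samples")
        submatrices[lab] = matrix.subset(idx)

    events = {
        "loss": State.LOSS,
        "gain": {State.GAIN, State.AMP},
        "amp": State.AMP,
    }
    profiles = {
        lab: {name: frequency_profile(sub, ev) for name, ev in events.items()}
        for lab, sub in submatrices.items()
    }
    contrasts: dict[tuple[int, int], list[RegionContrast]] = {}
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            found: list[RegionContrast] = []
            for ev in events.values():
                found.extend(
                    compare_group_frequencies(
                        submatrices[a], submatrices[b], ev,
                        min_diff=min_diff, min_snps=min_snps,
                    )
                )
            contrasts[(a, b)] = found
    return profiles, contrasts
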