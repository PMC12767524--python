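"""Average stranded footprint profiles, contact-midpoint detection and
PCA-based grouping of factor binding profiles.

A crosslinked protein leaves a pair of exonuclease stop-base peaks: one on
the positive strand upstream of the contact and one on the negative strand
downstream.  The DNA contact point is the midpoint between the paired
peaks.  Profiles of many factors are min-max normalized, decomposed by PCA
(centered, not variance-scaled) and grouped into modules by k-means on the
leading principal components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .coverage import ProfileMatrix

__all__ = [
    "AverageProfile",
    "FootprintContact",
    "ModuleAssignment",
    "average_profile",
    "detect_footprint_midpoints",
    "minmax_normalize",
    "pca_modules",
]


@dataclass
class AverageProfile:
    """Promoter-averaged stranded stop-base profile for one factor."""

    factor: str
    offsets: np.ndarray
    positive_strand: np.ndarray
    negative_strand: np.ndarray

    def __post_init__(self) -> None:
        if not (
            len(self.offsets)
            == len(self.positive_strand)
            == len(self.negative_strand)
        ):
            raise ValueError("offset/strand vectors differ in length")


@dataclass
class FootprintContact:
    """A paired positive/negative strand peak and its midpoint."""

    factor: str
    pos_peak_offset: int | None
    neg_peak_offset: int | None
    midpoint: float | None
    pos_height: float
    neg_height: float

    @property
    def paired(self) -> bool:
        return self.pos_peak_offset is not None and self.neg_peak_offset is not None


@dataclass
class ModuleAssignment:
    factor: str
    pc_coordinates: np.ndarray
    module_id: int


def average_profile(matrix: ProfileMatrix, factor: str = "") -> AverageProfile:
    """Arithmetic mean over promoters, per offset and strand plane."""
    if len(matrix.promoter_ids) == 0:
        raise ValueError("empty profile matrix")
    return AverageProfile(
        factor=factor,
        offsets=matrix.offsets,
        positive_strand=matrix.sense_positive.mean(axis=0),
        negative_strand=matrix.sense_negative.mean(axis=0),
    )


def _strand_peaks(
    values: np.ndarray, offsets: np.ndarray, min_height_frac: float, min_separation: int
) -> list[tuple[int, float]]:
    peak_idx, _ = find_peaks(
        values, height=min_height_frac * values.max(), distance=min_separation
    )
    return [(int(offsets[i]), float(values[i])) for i in peak_idx]


def detect_footprint_midpoints(
    profile: AverageProfile,
    min_height_frac: float = 0.2,
    min_separation: int = 3,
    max_pair_distance: int = 40,
) -> list[FootprintContact]:
    """Pair strand peaks into DNA contacts and compute their midpoints.

    Candidate peaks are local maxima at least ``min_height_frac`` of the
    strand maximum and at least ``min_separation`` bp apart.  Each
    positive-strand peak pairs with the nearest unused negative-strand
    peak strictly downstream within ``max_pair_distance`` bp (ties go to
    the higher negative peak); unpaired peaks on either strand are also
    reported.  Paired contacts come first, sorted by midpoint.
    """
    if profile.positive_strand.max() <= 0 and profile.negative_strand.max() <= 0:
        raise ValueError("all-zero profile")
    pos_peaks = _strand_peaks(
        profile.positive_strand, profile.offsets, min_height_frac, min_separation
    )
    neg_peaks = _strand_peaks(
        profile.negative_strand, profile.offsets, min_height_frac, min_separation
    )
    used_neg: set[int] = set()
    contacts: list[FootprintContact] = []
    for p_off, p_h in sorted(pos_peaks):
        candidates = [
            (n_off, n_h)
            for n_off, n_h in neg_peaks
            if n_off > p_off
            and n_off - p_off <= max_pair_distance
            and n_off not in used_neg
        ]
        if candidates:
            # nearest downstream; ties by higher negative-strand peak
            n_off, n_h = min(candidates, key=lambda c: (c[0] - p_off, -c[1]))
            used_neg.add(n_off)
            contacts.append(
                FootprintContact(
                    profile.factor, p_off, n_off, (p_off + n_off) / 2.0, p_h, n_h
                )
            )
        else:
            contacts.append(
                FootprintContact(profile.factor, p_off, None, None, p_h, 0.0)
            )
    for n_off, n_h in sorted(neg_peaks):
        if n_off not in used_neg:
            contacts.append(
                FootprintContact(profile.factor, None, n_off, None, 0.0, n_h)
            )
    contacts.sort(
        key=lambda c: (not c.paired, c.midpoint if c.paired else 0.0)
    )
    return contacts


def minmax_normalize(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale a vector to [0, 1] via (x - min) / (max - min).

    Returns the scaled vector and a flag that is True when the input was
    constant, in which case the output is all zeros.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant vector in min-max normalization", stacklevel=2)
        return np.zeros_like(x), True
    return (x - lo) / (hi - lo), False


def pca_modules(
    profiles: dict[str, AverageProfile],
    n_modules: int = 4,
    n_components: int = 2,
    seed: int = 0,
) -> list[ModuleAssignment]:
    """Group factor profiles into modules by PCA + k-means.

    Each factor's concatenated (positive, negative) strand vector is
    min-max normalized, the factor x feature matrix is decomposed by PCA
    (centered, unscaled), and module labels come from seeded k-means on
    the first ``n_components`` PC coordinates.
    """
    factors = list(profiles)
    if len(factors) < n_modules:
        raise ValueError("fewer factors than requested modules")
    rows = []
    for f in factors:
        p = profiles[f]
        vec = np.concatenate([p.positive_strand, p.negative_strand])
        rows.append(minmax_normalize(vec)[0])
    X = np.vstack(rows)
    n_components = min(n_components, len(factors) - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    km = KMeans(n_clusters=n_modules, n_init=10, random_state=seed)
    labels = km.fit_predict(coords)
    return [
        ModuleAssignment(factor=f, pc_coordinates=coords[i], module_id=int(labels[i]) + 1)
        for i, f in enumerate(factors)
    ]


def contacts_to_frame(contacts: list[FootprintContact]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "factor": [c.factor for c in contacts],
            "pos_peak": [c.pos_peak_offset for c in contacts],
            "neg_peak": [c.neg_peak_offset for c in contacts],
            "midpoint": [c.midpoint for c in contacts],
            "pos_height": [c.pos_height for c in contacts],
            "neg_height": [c.neg_height for c in contacts],
        }
    )
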