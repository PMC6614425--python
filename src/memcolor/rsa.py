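"""Cone-opponent representational-similarity analysis of skin matches.

Matches to skin regions are projected onto the two cone-opponent dimensions —
L−M (reddish–greenish, recently evolved) and S (bluish–yellowish, ancient) —
by converting match XYZ to LMS cone excitations and forming the luminance-
invariant ratios lm = L/(L+M) and s = S/(L+M).  Per-condition, per-participant
mean components form a condition × participant matrix; pairwise distances
between condition rows give a representational dissimilarity matrix (RDM),
summarized by classical (Torgerson) MDS and average-linkage (UPGMA)
hierarchical clustering.

The question the geometry answers: does face skin (cheek, forehead) separate
from non-face skin (masked forehead, neck, hand) along L−M but not S, and
only under LPS light?
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "HPE_XYZ_TO_LMS",
    "SKIN_CONDITIONS",
    "xyz_to_cone_opponent",
    "condition_matrix",
    "compute_rdm",
    "classical_mds",
    "average_linkage_tree",
    "cut_two_clusters",
]

# Hunt–Pointer–Estévez cone fundamentals (D65-normalized), XYZ → LMS.
# Any standard fundamentals preserve the L−M vs S dichotomy under test;
# override by passing your own matrix.
HPE_XYZ_TO_LMS = np.array([
    [0.4002, 0.7076, -0.0808],
    [-0.2263, 1.1653, 0.0457],
    [0.0000, 0.0000, 0.9182],
])

# skin-region conditions entering the RSA; face conditions pool actors,
# non-face conditions are split by actor race (lightness-matched body skin
# differs by race, and the analysis asks whether that structure is preserved)
_FACE_REGIONS = ("cheek", "forehead")
_NONFACE_REGIONS = ("masked_forehead", "neck", "hand")
SKIN_CONDITIONS = tuple(_FACE_REGIONS) + tuple(
    f"{r}_{race[0]}" for r in _NONFACE_REGIONS
    for race in ("Caucasian", "AfricanAmerican")
)


class RSAError(ValueError):
    pass


def xyz_to_cone_opponent(xyz, cone_matrix: np.ndarray = HPE_XYZ_TO_LMS) -> np.ndarray:
    """XYZ → (lm, s) = (L/(L+M), S/(L+M)); invariant to luminance scaling."""
    xyz = np.asarray(xyz, dtype=float)
    lms = xyz @ cone_matrix.T
    denom = lms[..., 0] + lms[..., 1]
    if np.any(denom <= 0):
        raise RSAError("non-positive L+M cone excitation")
    return np.stack([lms[..., 0] / denom, lms[..., 2] / denom], axis=-1)


def _condition_label(row: pd.Series) -> str | None:
    region = row["region"]
    if region in _FACE_REGIONS:
        return region
    if region in _NONFACE_REGIONS:
        return f"{region}_{row['race'][0]}"
    return None


def condition_matrix(matches: pd.DataFrame, catalog: pd.DataFrame,
                     illuminant: str, component: str,
                     cone_matrix: np.ndarray = HPE_XYZ_TO_LMS,
                     calib=None) -> pd.DataFrame:
    """Condition × participant matrix of mean cone-opponent components.

    ``component`` is ``"lm"`` or ``"s"``.  Cells average over actors (and
    stimuli) within a condition; a missing (condition, participant) cell is an
    error naming both.
    """
    from . import colorimetry as cm

    if component not in ("lm", "s"):
        raise RSAError(f"component must be 'lm' or 's', got {component!r}")
    calib = calib or cm.default_calibration()
    sub = matches[matches["illuminant"] == illuminant].merge(
        catalog, left_on="stimulus_id", right_on="id")
    labels = sub.apply(_condition_label, axis=1)
    sub = sub.assign(condition=labels).dropna(subset=["condition"])

    xyz = cm.rgb_to_xyz(sub[["R", "G", "B"]].to_numpy(dtype=float), calib)
    comp = xyz_to_cone_opponent(xyz, cone_matrix)
    sub[component] = comp[:, 0] if component == "lm" else comp[:, 1]

    table = sub.pivot_table(index="condition", columns="participant_id",
                            values=component, aggfunc="mean")
    table = table.reindex([c for c in SKIN_CONDITIONS if c in table.index])
    if table.isna().any().any():
        cond = table.index[table.isna().any(axis=1)][0]
        part = table.columns[table.isna().any(axis=0)][0]
        raise RSAError(f"missing cell: condition {cond!r}, participant {part!r}")
    return table


def compute_rdm(matrix: pd.DataFrame, metric: str = "euclidean") -> pd.DataFrame:
    """Pairwise distances between condition rows; symmetric, zero diagonal."""
    if len(matrix) < 2:
        raise RSAError("need >= 2 conditions")
    d = squareform(pdist(matrix.to_numpy(dtype=float), metric=metric))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def classical_mds(rdm: pd.DataFrame, dims: int = 1) -> pd.DataFrame:
    """Torgerson classical MDS of an RDM.

    Double-centers the squared distances and takes the top eigenvectors;
    the sign of each dimension is fixed so the condition with the largest
    absolute coordinate is positive.  Small negative eigenvalues (non-
    Euclidean residual) are tolerated; their dimensions are zeroed.
    """
    D = rdm.to_numpy(dtype=float)
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, dims))
    for k in range(min(dims, n)):
        if vals[k] > 1e-12:
            col = vecs[:, k] * np.sqrt(vals[k])
            if col[np.argmax(np.abs(col))] < 0:
                col = -col
            coords[:, k] = col
    return pd.DataFrame(coords, index=rdm.index,
                        columns=[f"dim{k + 1}" for k in range(dims)])


def average_linkage_tree(rdm: pd.DataFrame) -> list[dict]:
    """UPGMA dendrogram as a merge list [{pair: (i, j), height: h}, ...].

    Indices < n refer to the RDM's conditions in order; indices >= n refer to
    previously formed merges (scipy linkage convention).  Heights are
    non-decreasing; scipy breaks ties by candidate order, i.e. lowest index.
    """
    if len(rdm) < 2:
        raise RSAError("need >= 2 conditions")
    Z = hierarchy.linkage(squareform(rdm.to_numpy(dtype=float), checks=False),
                          method="average")
    return [
        {"pair": (int(i), int(j)), "height": float(h), "size": int(s)}
        for i, j, h, s in Z
    ]


def cut_two_clusters(rdm: pd.DataFrame) -> dict[str, int]:
    """Condition → cluster label (0/1) from cutting the UPGMA tree at k=2."""
    Z = hierarchy.linkage(squareform(rdm.to_numpy(dtype=float), checks=False),
                          method="average")
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust") - 1
    return dict(zip(rdm.index, (int(x) for x in labels)))
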