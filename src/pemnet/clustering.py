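"""K-means partitioning of conformers into metastable patterns.

A metastable pattern is an ensemble of structurally similar conformations
— one basin of attraction on the excited-state potential energy surface —
identified as one K-means cluster of the dihedral descriptors.

Because dihedrals are periodic, the default "circular" embedding maps each
angle theta to (cos theta, sin theta) before clustering, so conformers at
+175 and -175 degrees are close (chord metric).  The "raw" mode clusters
the plain angle values, as one would with non-periodic internal
coordinates; both are provided because the treatment of periodicity is a
modelling choice, not a given.

Molecules whose conformational motion is mirror-symmetric (clockwise vs
anti-clockwise rotation of the same dihedrals) produce clusters in pairs
(i, i') with centroids related by elementwise angular negation;
:func:`merge_symmetric_pairs` detects and fuses them for a simplified
pattern set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .descriptors import wrap_angle, wrap_difference

logger = logging.getLogger(__name__)

__all__ = [
    "PatternModel",
    "ClusterDiagnostics",
    "embed",
    "centroid_angles",
    "fit_patterns",
    "assign_pattern",
    "select_k",
    "superpose",
    "merge_symmetric_pairs",
    "circular_std",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

def embed(angles: np.ndarray, embedding: str) -> np.ndarray:
    """Map (n, p) angles in degrees to cluster space.

    "circular": each angle becomes (cos, sin) -> (n, 2p); "raw": unchanged.
    """
    a = np.atleast_2d(np.asarray(angles, dtype=float))
    if embedding == "raw":
        return a
    if embedding == "circular":
        rad = np.radians(a)
        return np.concatenate([np.cos(rad), np.sin(rad)], axis=1)
    raise ValueError(f"unknown embedding {embedding!r}")


def centroid_angles(model: "PatternModel") -> np.ndarray:
    """Back-map centroids to angles in degrees, shape (k, p).

    In circular embedding this is atan2 of the (sin, cos) halves of each
    centroid; in raw embedding the centroids are wrapped.
    """
    c = model.centroids
    if model.embedding == "raw":
        return wrap_angle(c)
    p = c.shape[1] // 2
    return wrap_angle(np.degrees(np.arctan2(c[:, p:], c[:, :p])))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PatternModel:
    """Fitted pattern classifier: centroids + training labels."""

    k: int
    centroids: np.ndarray          # (k, 2p) circular or (k, p) raw
    labels: np.ndarray             # per training frame, 0..k-1
    embedding: str                 # "circular" | "raw"
    seed: int
    inertia: float = float("nan")
    p: int = 0                     # descriptor count

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("non-finite centroid")
        if self.labels.size and self.labels.max() >= self.k:
            raise ValueError("label out of range")
        if self.p == 0:
            self.p = (
                self.centroids.shape[1] // 2
                if self.embedding == "circular"
                else self.centroids.shape[1]
            )


@dataclass
class ClusterDiagnostics:
    """Per-cluster quality summary for one fitted k."""

    k: int
    sizes: np.ndarray                      # member counts
    spread_deg: np.ndarray                 # circular std of descriptors, deg
    inertia: float
    coord_rmsd: np.ndarray | None = None   # heavy-atom spread after fit, A

    @property
    def max_spread(self) -> float:
        return float(np.max(self.spread_deg))

    @property
    def mean_spread(self) -> float:
        return float(np.mean(self.spread_deg))


# ---------------------------------------------------------------------------
# Fitting and assignment
# ---------------------------------------------------------------------------

def fit_patterns(
    descriptors: np.ndarray,
    k: int,
    embedding: str = "circular",
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> PatternModel:
    """Lloyd K-means with k-means++ seeding on the embedded descriptors.

    Deterministic given ``seed``.  Raises if the data contain fewer than
    ``k`` distinct embedded points.
    """
    x = np.atleast_2d(np.asarray(descriptors, dtype=float))
    if x.size == 0:
        raise ValueError("empty descriptor array")
    if k < 1:
        raise ValueError("k must be >= 1")
    emb = embed(x, embedding)
    n_distinct = np.unique(emb, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct points")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(emb)
    return PatternModel(
        k=k,
        centroids=km.cluster_centers_,
        labels=km.labels_,
        embedding=embedding,
        seed=seed,
        inertia=float(km.inertia_),
        p=x.shape[1],
    )


def assign_pattern(model: PatternModel, x) -> int | np.ndarray:
    """Pattern id(s) of the nearest centroid; ties broken by lowest index.

    Accepts a single descriptor vector (returns int) or an (n, p) array.
    """
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != model.p:
        raise ValueError(
            f"descriptor length {arr.shape[1]} != model p={model.p}"
        )
    emb = embed(arr, model.embedding)
    d2 = (
        np.sum(emb**2, axis=1)[:, None]
        - 2.0 * emb @ model.centroids.T
        + np.sum(model.centroids**2, axis=1)[None, :]
    )
    # round-off guard so exact ties resolve to the lowest index via argmin
    ids = np.argmin(np.round(d2, 12), axis=1)
    return int(ids[0]) if single else ids


def circular_std(angles_deg: np.ndarray) -> float:
    """Circular standard deviation in degrees (sqrt(-2 ln R))."""
    rad = np.radians(np.asarray(angles_deg, dtype=float))
    r = np.abs(np.mean(np.exp(1j * rad)))
    r = min(r, 1.0)
    return float(np.degrees(np.sqrt(max(0.0, -2.0 * np.log(r)))))


def _spread(descriptors: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Per-cluster descriptor spread: RMS over dihedrals of circular std."""
    out = np.zeros(k)
    for c in range(k):
        mem = descriptors[labels == c]
        if mem.size == 0:
            continue
        per_dim = [circular_std(mem[:, j]) for j in range(mem.shape[1])]
        out[c] = float(np.sqrt(np.mean(np.square(per_dim))))
    return out


def select_k(
    descriptors: np.ndarray,
    k_values: Sequence[int],
    embedding: str = "circular",
    seed: int = 0,
    **fit_kwargs,
) -> dict[int, ClusterDiagnostics]:
    """Fit each candidate k (fixed seed) and report per-cluster spreads.

    The caller picks the smallest k at which the maximum spread drops
    below a geometric tolerance; failures for individual k are logged and
    skipped.
    """
    if not k_values:
        raise ValueError("k_values is empty")
    out: dict[int, ClusterDiagnostics] = {}
    x = np.atleast_2d(np.asarray(descriptors, dtype=float))
    for k in k_values:
        try:
            m = fit_patterns(x, k, embedding=embedding, seed=seed, **fit_kwargs)
        except ValueError as exc:
            logger.warning("select_k: k=%d failed (%s)", k, exc)
            continue
        sizes = np.bincount(m.labels, minlength=k)
        out[k] = ClusterDiagnostics(
            k=k, sizes=sizes, spread_deg=_spread(x, m.labels, k),
            inertia=m.inertia,
        )
    return out


# ---------------------------------------------------------------------------
# Rigid-body superposition (Kabsch)
# ---------------------------------------------------------------------------

def superpose(
    ref_coords: np.ndarray,
    mov_coords: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of mov onto ref (Kabsch/SVD).

    ``mask`` optionally selects the atoms used for the fit (e.g. heavy
    atoms); the RMSD is computed over the same selection.  Returns
    (rotation 3x3, translation 3, rmsd) such that
    ``mov @ R.T + t`` approximates ref.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n_atoms, 3)")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        ref_fit, mov_fit = ref[mask], mov[mask]
    else:
        ref_fit, mov_fit = ref, mov
    if ref_fit.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    rc = ref_fit.mean(axis=0)
    mc = mov_fit.mean(axis=0)
    a = ref_fit - rc
    b = mov_fit - mc
    # collinearity check: rank of the centred coordinates
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValueError("collinear atom set: rotation underdetermined")
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    fitted = mov_fit @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref_fit) ** 2, axis=1))))
    return rot, trans, rmsd


# ---------------------------------------------------------------------------
# Mirror-pair merging
# ---------------------------------------------------------------------------

def merge_symmetric_pairs(
    model: PatternModel, tolerance_deg: float = 10.0
) -> tuple[dict[int, int], np.ndarray]:
    """Pair clusters whose centroid angles satisfy c' ~ -c elementwise.

    Clockwise / anti-clockwise rotation of the same dihedrals yields
    mirror clusters; each is mapped to min(i, i').  Unpaired clusters map
    to themselves.  Returns (mapping, merged per-frame labels).  If a
    centroid has several mirror candidates within tolerance the nearest is
    taken greedily, with a warning.
    """
    ang = centroid_angles(model)
    k = model.k
    # mirror distance between centroid i and negated centroid j
    mdist = np.full((k, k), np.inf)
    for i in range(k):
        for j in range(k):
            d = wrap_difference(ang[i], -ang[j])
            mdist[i, j] = float(np.max(np.abs(d)))
    mapping: dict[int, int] = {}
    used: set[int] = set()
    # greedy: smallest mirror distance first
    order = sorted(
        ((mdist[i, j], i, j) for i in range(k) for j in range(i, k)),
        key=lambda t: t[0],
    )
    for d, i, j in order:
        if d > tolerance_deg:
            break
        if i in used or j in used:
            continue
        n_cand_i = int(np.sum(mdist[i] <= tolerance_deg))
        if n_cand_i > 1 and i != j:
            logger.warning(
                "cluster %d has %d mirror candidates; pairing with %d",
                i, n_cand_i, j,
            )
        mapping[i] = mapping[j] = min(i, j)
        used.update((i, j))
    for i in range(k):
        mapping.setdefault(i, i)
    merged_labels = np.array([mapping[int(l)] for l in model.labels])
    return mapping, merged_labels


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: PatternModel, path) -> None:
    """Persist a fitted model as JSON (embedded + back-mapped centroids)."""
    doc = {
        "k": model.k,
        "embedding": model.embedding,
        "seed": model.seed,
        "p": model.p,
        "inertia": model.inertia,
        "centroids": model.centroids.tolist(),
        "centroid_angles_deg": centroid_angles(model).tolist(),
        "labels": model.labels.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> PatternModel:
    doc = json.loads(Path(path).read_text())
    return PatternModel(
        k=doc["k"],
        centroids=np.array(doc["centroids"]),
        labels=np.array(doc["labels"], dtype=int),
        embedding=doc["embedding"],
        seed=doc["seed"],
        inertia=doc.get("inertia", float("nan")),
        p=doc["p"],
    )
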