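"""Prediction with Ensemble Models (PEM): kernel interpolation over patterns.

A molecular property V of an arbitrary conformer X is estimated as a
weighted sum over reference conformers drawn from every metastable
pattern,

    V(X) = sum_i sum_j  w_ij(X) T_ij,            (ensemble sum)

where i runs over the M patterns, j over the n reference conformers kept
per pattern, T_ij is the stored property of reference (i, j) and the
weights are an inverse-distance (Shepard) kernel of the general distance

    u_ij(X) = || X - X'_ij ||                    (Euclidean over the p
                                                  dihedral descriptors),

computed on wrapped angular differences by default so that 179 and -179
degrees are 2 degrees apart.  Two kernel modes are provided:

* ``"shepard"`` (default): w_ij = u_ij^-pw / sum_kl u_kl^-pw, a
  normalised inverse-distance kernel with exponent pw (default 4).  The
  weights form a convex combination, so predictions interpolate the
  references exactly and stay within [min T, max T].
* ``"as-printed"``: w_ij = (1/u_ij) / sum_kl (1/u_kl)^4 — exponent 1 in
  the numerator against 4 in the denominator, an unnormalised variant
  retained for literal reproduction; its predictions are not convex
  combinations.

If a query coincides with one or more references (u = 0), all the weight
collapses onto the zero-distance references, split equally — the
continuous limit of the kernel, preserving interpolation consistency.

Reference selection per pattern: "batch" keeps every member, "stochastic"
a single seeded draw, "mini-batch" a seeded sample of n (default 10)
without replacement — the trade-off between the cost of batch and the
variance of stochastic.  One prediction costs O(M * n) distance
evaluations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .descriptors import wrap_difference
from .clustering import PatternModel
from .pattern_stats import GaussianFit, fit_gaussian

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceEntry",
    "ReferenceSet",
    "WeightVector",
    "PredictionReport",
    "select_references",
    "general_distance",
    "pem_weights",
    "pem_predict",
    "pem_predict_charges",
    "validate",
    "predict_timeseries",
    "save_references",
    "load_references",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ReferenceEntry:
    """One reference conformer: descriptors X', named properties, provenance."""

    descriptors: np.ndarray                 # (p,) degrees
    properties: dict[str, float]
    charges: np.ndarray | None = None       # (n_atoms,), e
    pattern: int = -1
    trajectory_id: str = ""
    frame: int = -1


@dataclass
class ReferenceSet:
    """The PEM parameter set: reference conformers grouped by pattern."""

    entries: list[ReferenceEntry]
    selection_mode: str = "mini-batch"      # batch | stochastic | mini-batch
    seed: int = 0
    circular: bool = True                   # wrapped angular differences

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty reference set")
        p = len(self.entries[0].descriptors)
        names = set(self.entries[0].properties)
        for e in self.entries:
            e.descriptors = np.asarray(e.descriptors, dtype=float)
            if len(e.descriptors) != p:
                raise ValueError("inconsistent descriptor lengths")
            if set(e.properties) != names:
                raise ValueError("inconsistent property names across entries")

    @property
    def p(self) -> int:
        return len(self.entries[0].descriptors)

    @property
    def M(self) -> int:
        return len({e.pattern for e in self.entries})

    @property
    def descriptor_matrix(self) -> np.ndarray:
        return np.stack([e.descriptors for e in self.entries])

    def property_vector(self, name: str) -> np.ndarray:
        try:
            return np.array([e.properties[name] for e in self.entries])
        except KeyError:
            raise KeyError(
                f"unknown property {name!r}; available: "
                f"{sorted(self.entries[0].properties)}"
            )

    def charge_matrix(self) -> np.ndarray:
        if any(e.charges is None for e in self.entries):
            raise ValueError("some references carry no charge vector")
        lengths = {len(e.charges) for e in self.entries}
        if len(lengths) != 1:
            raise ValueError(f"inconsistent charge vector lengths: {lengths}")
        return np.stack([e.charges for e in self.entries])


@dataclass
class WeightVector:
    """Kernel weights aligned with a ReferenceSet's entries."""

    weights: np.ndarray
    mode: str            # "shepard" | "as-printed"
    p_w: float

    def __post_init__(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("negative weight")


@dataclass
class PredictionReport:
    """Predicted-vs-reference comparison over a validation set."""

    predicted: np.ndarray
    reference: np.ndarray
    mode: str                               # "ratio" | "deviation"
    series: np.ndarray                      # ratios or deviations
    fit: GaussianFit | None = None
    excluded: int = 0                       # frames dropped (zero reference)
    per_atom: "np.ndarray | None" = None    # (n_atoms,) RMS dev for charges


# ---------------------------------------------------------------------------
# Reference selection
# ---------------------------------------------------------------------------

def select_references(
    model: PatternModel,
    descriptors: np.ndarray,
    properties: Sequence[Mapping[str, float]],
    charges: Sequence[np.ndarray | None] | None = None,
    mode: str = "mini-batch",
    n: int = 10,
    seed: int = 0,
    trajectory_ids: Sequence[str] | None = None,
    frames: Sequence[int] | None = None,
    circular: bool = True,
) -> ReferenceSet:
    """Sample reference conformers from each pattern of a fitted model.

    ``descriptors`` is the (N, p) training matrix aligned with
    ``model.labels``; ``properties`` a per-frame mapping of named scalar
    properties (frames with an empty mapping carry no properties and are
    never selected).  Modes: "batch" keeps all property-bearing members,
    "stochastic" one seeded uniform draw per pattern, "mini-batch"
    min(n, members) seeded draws without replacement.
    """
    if mode not in ("batch", "stochastic", "mini-batch"):
        raise ValueError(f"unknown selection mode {mode!r}")
    x = np.atleast_2d(np.asarray(descriptors, dtype=float))
    labels = model.labels
    if x.shape[0] != len(labels):
        raise ValueError("descriptors and model labels misaligned")
    rng = np.random.default_rng(seed)
    entries: list[ReferenceEntry] = []
    dropped = 0
    for pat in range(model.k):
        members = np.flatnonzero(labels == pat)
        members = np.array(
            [i for i in members if properties[i]], dtype=int
        )
        if members.size == 0:
            logger.warning("pattern %d has no property-bearing members; dropped", pat)
            dropped += 1
            continue
        if mode == "batch":
            chosen = members
        elif mode == "stochastic":
            chosen = rng.choice(members, size=1, replace=False)
        else:
            take = min(n, members.size)
            chosen = rng.choice(members, size=take, replace=False)
        for i in sorted(int(j) for j in chosen):
            entries.append(ReferenceEntry(
                descriptors=x[i].copy(),
                properties=dict(properties[i]),
                charges=None if charges is None or charges[i] is None
                else np.asarray(charges[i], dtype=float).copy(),
                pattern=pat,
                trajectory_id=trajectory_ids[i] if trajectory_ids else "",
                frame=int(frames[i]) if frames is not None else i,
            ))
    if not entries:
        raise ValueError("all patterns dropped: no property-bearing members")
    return ReferenceSet(entries=entries, selection_mode=mode, seed=seed,
                        circular=circular)


# ---------------------------------------------------------------------------
# Distance, weights, prediction
# ---------------------------------------------------------------------------

def general_distance(x, x_ref, circular: bool = True) -> float:
    """Euclidean norm of descriptor differences (wrapped if circular)."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(x_ref, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"descriptor length mismatch: {a.shape} vs {b.shape}")
    d = wrap_difference(a, b) if circular else a - b
    return float(np.sqrt(np.sum(d * d)))


def _distances(x: np.ndarray, refs: ReferenceSet) -> np.ndarray:
    xm = refs.descriptor_matrix
    a = np.asarray(x, dtype=float)
    if a.shape != (refs.p,):
        raise ValueError(f"query length {a.shape} != p={refs.p}")
    d = wrap_difference(a[None, :], xm) if refs.circular else a[None, :] - xm
    return np.sqrt(np.sum(d * d, axis=1))


def pem_weights(
    x, refs: ReferenceSet, mode: str = "shepard", p_w: float = 4.0
) -> WeightVector:
    """Kernel weights of a query against every reference entry.

    Shepard mode normalises u^-p_w over all (i, j) entries and sums to 1;
    as-printed mode evaluates (1/u) / sum (1/u)^4 literally.  Exact
    matches (u = 0) take all the weight, split equally among ties.
    """
    u = _distances(np.asarray(x, dtype=float), refs)
    n = len(u)
    w = np.zeros(n)
    exact = u == 0.0
    if np.any(exact):
        w[exact] = 1.0 / exact.sum()
        return WeightVector(weights=w, mode=mode, p_w=p_w)
    if mode == "shepard":
        inv = u ** (-p_w)
        w = inv / inv.sum()
    elif mode == "as-printed":
        w = (1.0 / u) / np.sum((1.0 / u) ** 4)
    else:
        raise ValueError(f"unknown kernel mode {mode!r}")
    return WeightVector(weights=w, mode=mode, p_w=p_w)


def pem_predict(
    x, refs: ReferenceSet, property_name: str,
    mode: str = "shepard", p_w: float = 4.0,
) -> float:
    """Ensemble prediction V(X) = sum_ij w_ij T_ij for a scalar property."""
    t = refs.property_vector(property_name)
    w = pem_weights(x, refs, mode=mode, p_w=p_w)
    return float(np.dot(w.weights, t))


def pem_predict_charges(
    x, refs: ReferenceSet,
    renormalize: bool = False, net_charge: float = 0.0,
    mode: str = "shepard", p_w: float = 4.0,
) -> np.ndarray:
    """Per-atom charge prediction: elementwise ensemble sum, shared weights.

    With ``renormalize`` the residual (net_charge - sum q) is distributed
    uniformly over atoms so the returned vector sums exactly to the
    configured total.
    """
    q = refs.charge_matrix()
    w = pem_weights(x, refs, mode=mode, p_w=p_w)
    pred = w.weights @ q
    if renormalize:
        pred = pred + (net_charge - pred.sum()) / len(pred)
    return pred


def predict_timeseries(
    descriptors: np.ndarray, refs: ReferenceSet, property_name: str,
    mode: str = "shepard", p_w: float = 4.0,
) -> np.ndarray:
    """Framewise PEM prediction along a trajectory's descriptor series."""
    x = np.atleast_2d(np.asarray(descriptors, dtype=float))
    return np.array([
        pem_predict(row, refs, property_name, mode=mode, p_w=p_w) for row in x
    ])


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(
    predictions: np.ndarray,
    references: np.ndarray,
    mode: str = "ratio",
) -> PredictionReport:
    """Compare predictions against reference values.

    ``mode="ratio"``: predicted/reference series with a Gaussian fit
    (frames with zero reference are excluded with a warning).
    ``mode="deviation"``: predicted - reference; for 2-D charge arrays a
    per-atom RMS deviation summary is included.
    """
    pred = np.asarray(predictions, dtype=float)
    ref = np.asarray(references, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    if pred.size == 0:
        raise ValueError("empty validation series")
    if mode == "ratio":
        if pred.ndim != 1:
            raise ValueError("ratio mode expects scalar series")
        nz = ref != 0
        excluded = int(np.sum(~nz))
        if excluded:
            logger.warning("%d frames with zero reference excluded", excluded)
        if not np.any(nz):
            raise ValueError("all reference values are zero")
        ratios = pred[nz] / ref[nz]
        return PredictionReport(
            predicted=pred, reference=ref, mode="ratio", series=ratios,
            fit=fit_gaussian(ratios), excluded=excluded,
        )
    if mode == "deviation":
        dev = pred - ref
        per_atom = None
        if dev.ndim == 2:
            per_atom = np.sqrt(np.mean(dev**2, axis=0))
        return PredictionReport(
            predicted=pred, reference=ref, mode="deviation",
            series=dev, fit=fit_gaussian(dev.ravel()), per_atom=per_atom,
        )
    raise ValueError(f"unknown validation mode {mode!r}")


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_references(refs: ReferenceSet, path) -> None:
    doc = {
        "selection_mode": refs.selection_mode,
        "seed": refs.seed,
        "circular": refs.circular,
        "entries": [
            {
                "descriptors": e.descriptors.tolist(),
                "properties": e.properties,
                "charges": None if e.charges is None else e.charges.tolist(),
                "pattern": e.pattern,
                "trajectory_id": e.trajectory_id,
                "frame": e.frame,
            }
            for e in refs.entries
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_references(path) -> ReferenceSet:
    doc = json.loads(Path(path).read_text())
    entries = [
        ReferenceEntry(
            descriptors=np.array(d["descriptors"]),
            properties=dict(d["properties"]),
            charges=None if d["charges"] is None else np.array(d["charges"]),
            pattern=d["pattern"],
            trajectory_id=d["trajectory_id"],
            frame=d["frame"],
        )
        for d in doc["entries"]
    ]
    return ReferenceSet(
        entries=entries, selection_mode=doc["selection_mode"],
        seed=doc["seed"], circular=doc["circular"],
    )
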