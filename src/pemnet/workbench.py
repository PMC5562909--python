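"""End-to-end pipeline orchestration and run manifests.

One call runs the full analysis chain — descriptors -> clustering ->
kinetic network -> per-pattern statistics -> reference selection ->
prediction -> validation — persisting every intermediate artifact under
an output directory together with a manifest recording the seed, a hash
of the configuration and a SHA-256 of each artifact, so reruns are
verifiable and interrupted runs can resume from the surviving artifacts.

Inputs are either real data (XYZ trajectories + property tables +
dihedral config) or a named synthetic preset.  Configuration precedence
is CLI > config file > defaults.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from . import descriptors as dsc
from . import clustering as clu
from . import tsf_network as net
from . import pattern_stats as pst
from . import pem
from . import synthetic_data as syn

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

STAGES = ("model", "labels", "counts", "stats", "references",
          "predictions", "report")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults follow the standard protocol
    (k = 12 patterns, mini-batch n = 10 references, lag 1)."""

    out_dir: str = "pemnet_run"
    # data source: either a synthetic preset ...
    preset: str | None = "two_state_easy"
    n_traj: int = 20
    n_frames: int = 400
    # ... or real inputs
    xyz_paths: list[str] = field(default_factory=list)
    property_table: str | None = None
    dihedral_config: str | None = None
    timestep_fs: float = 0.5
    # analysis parameters
    k: int = 12
    embedding: str = "circular"
    seed: int = 0
    lag: int = 1
    edge_threshold: float = 0.0
    selection_mode: str = "mini-batch"
    n_refs: int = 10
    kernel_mode: str = "shepard"
    p_w: float = 4.0
    property_name: str = "excitation_energy"
    merge_tolerance_deg: float = 10.0
    validation_fraction: float = 0.2
    resume: bool = False

    def config_hash(self) -> str:
        # hash the analysis parameters only, not where results land
        doc = {k: v for k, v in asdict(self).items()
               if k not in ("resume", "out_dir")}
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path, **overrides) -> RunConfig:
    """Read a YAML/JSON config file and apply keyword overrides."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(doc) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    doc.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**doc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stamp(cfg: RunConfig) -> str:
    return f"# seed={cfg.seed} config={cfg.config_hash()}\n"


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(cfg))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


class _StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_inputs(cfg: RunConfig):
    """Per-trajectory (ids, descriptor arrays, property dicts, charges)."""
    if cfg.preset:
        ds, _ = syn.make_benchmark(
            cfg.preset, n_traj=cfg.n_traj, n_frames=cfg.n_frames, seed=cfg.seed
        )
        ids = [f"synth_{i:03d}" for i in range(ds.n_traj)]
        descs = ds.descriptors
        props = [
            [{cfg.property_name: float(v)} for v in ds.properties[i]]
            for i in range(ds.n_traj)
        ]
        charges = (
            [list(ds.charges[i]) for i in range(ds.n_traj)]
            if ds.charges is not None else None
        )
        return ids, descs, props, charges
    if not cfg.xyz_paths or not cfg.dihedral_config:
        raise ValueError("need xyz_paths + dihedral_config, or a preset")
    specs = dsc.read_dihedral_specs(cfg.dihedral_config)
    table = (
        dsc.read_property_table(cfg.property_table)
        if cfg.property_table else None
    )
    ids, descs, props, charges = [], [], [], []
    any_charges = False
    for path in cfg.xyz_paths:
        traj = dsc.read_xyz_trajectory(path, timestep_fs=cfg.timestep_fs)
        if table is not None:
            dsc.join_properties(traj, table)
        ids.append(traj.trajectory_id)
        descs.append(dsc.compute_descriptors(traj, specs))
        props.append([dict(fr.properties) for fr in traj.frames])
        qs = [fr.charges for fr in traj.frames]
        charges.append(qs)
        any_charges = any_charges or any(q is not None for q in qs)
    return ids, descs, props, (charges if any_charges else None)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order; returns the run manifest.

    Any stage failure aborts with the stage name; artifacts persisted by
    earlier stages are left in place.  With ``cfg.resume`` stages whose
    artifact files already exist are loaded rather than recomputed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}

    def done(stage: str, *paths: Path) -> None:
        for p in paths:
            artifacts.setdefault(stage, p.name)
        timings[stage] = round(time.time() - t0, 3)
        logger.info("stage %-12s done (%.2fs)", stage, timings[stage])

    ids, descs, props, charges = _load_inputs(cfg)
    all_desc = np.concatenate(descs)
    lengths = [len(d) for d in descs]

    # --- model ------------------------------------------------------------
    model_path = out / "model.json"
    stage = "model"
    try:
        if cfg.resume and model_path.exists():
            model = clu.load_model(model_path)
        else:
            k = min(cfg.k, np.unique(
                clu.embed(all_desc, cfg.embedding), axis=0).shape[0])
            model = clu.fit_patterns(
                all_desc, k, embedding=cfg.embedding, seed=cfg.seed
            )
            clu.save_model(model, model_path)
    except Exception as exc:
        raise _StageError(stage, exc)
    done(stage, model_path)

    # --- labels -----------------------------------------------------------
    stage = "labels"
    labels_path = out / "labels.tsv"
    try:
        if cfg.resume and labels_path.exists():
            lab_df = _read_table(labels_path)
        else:
            rows = []
            pos = 0
            for tid, nlen in zip(ids, lengths):
                for f in range(nlen):
                    rows.append((tid, f, int(model.labels[pos + f])))
                pos += nlen
            lab_df = pd.DataFrame(rows, columns=["trajectory_id", "frame", "pattern"])
            _write_table(lab_df, labels_path, cfg)
        label_series = [
            lab_df[lab_df["trajectory_id"] == tid]["pattern"].to_numpy()
            for tid in ids
        ]
    except Exception as exc:
        raise _StageError(stage, exc)
    done(stage, labels_path)

    # --- counts / network ---------------------------------------------------
    stage = "counts"
    counts_path = out / "counts.tsv"
    try:
        tm = net.count_transitions(label_series, k=model.k, lag=cfg.lag)
        _write_table(net.matrix_to_frame(tm.counts), counts_path, cfg)
        _write_table(
            net.matrix_to_frame(tm.probabilities), out / "probabilities.tsv", cfg
        )
        pops = net.population_timeseries(label_series, k=model.k)
        _write_table(net.populations_to_frame(pops), out / "populations.tsv", cfg)
        g, comps, cuts = net.build_graph(tm.probabilities, cfg.edge_threshold)
        nx.write_graphml(g, out / "network.graphml")
        _write_dot(g, out / "network.dot")
        (out / "graph_summary.json").write_text(json.dumps({
            "seed": cfg.seed, "config": cfg.config_hash(),
            "components": [sorted(c) for c in comps],
            "articulation_vertices": cuts,
        }, indent=1))
    except Exception as exc:
        raise _StageError(stage, exc)
    done(stage, counts_path)

    # --- stats --------------------------------------------------------------
    stage = "stats"
    stats_path = out / "stats.tsv"
    try:
        flat_props: dict[str, np.ndarray] = {}
        names = sorted({k for tp in props for fp in tp for k in fp})
        for name in names:
            flat_props[name] = np.array([
                fp.get(name, np.nan) for tp in props for fp in tp
            ])
        fits = pst.per_pattern_stats(model.labels, flat_props)
        _write_table(pst.stats_to_frame(fits), stats_path, cfg)
    except Exception as exc:
        raise _StageError(stage, exc)
    done(stage, stats_path)

    # --- references ---------------------------------------------------------
    stage = "references"
    refs_path = out / "references.json"
    try:
        flat_prop_dicts = [fp for tp in props for fp in tp]
        flat_charges = (
            [q for tq in charges for q in tq] if charges is not None else None
        )
        flat_tids = [tid for tid, nlen in zip(ids, lengths) for _ in range(nlen)]
        flat_frames = [f for nlen in lengths for f in range(nlen)]
        if cfg.resume and refs_path.exists():
            refs = pem.load_references(refs_path)
        else:
            refs = pem.select_references(
                model, all_desc, flat_prop_dicts, charges=flat_charges,
                mode=cfg.selection_mode, n=cfg.n_refs, seed=cfg.seed,
                trajectory_ids=flat_tids, frames=flat_frames,
                circular=cfg.embedding == "circular",
            )
            pem.save_references(refs, refs_path)
    except Exception as exc:
        raise _StageError(stage, exc)
    done(stage, refs_path)

    # --- predictions --------------------------------------------------------
    stage = "predictions"
    pred_path = out / "predictions.tsv"
    try:
        rng = np.random.default_rng(cfg.seed + 1)
        has_prop = np.array([
            cfg.property_name in fp for fp in flat_prop_dicts
        ])
        candidates = np.flatnonzero(has_prop)
        n_val = max(1, int(round(cfg.validation_fraction * len(candidates))))
        val_idx = np.sort(rng.choice(candidates, size=min(n_val, len(candidates)),
                                     replace=False))
        preds = np.array([
            pem.pem_predict(all_desc[i], refs, cfg.property_name,
                            mode=cfg.kernel_mode, p_w=cfg.p_w)
            for i in val_idx
        ])
        truth = np.array([
            flat_prop_dicts[i][cfg.property_name] for i in val_idx
        ])
        pred_df = pd.DataFrame({
            "trajectory_id": [flat_tids[i] for i in val_idx],
            "frame": [flat_frames[i] for i in val_idx],
            "predicted": preds,
            "reference": truth,
        })
        _write_table(pred_df, pred_path, cfg)
    except Exception as exc:
        raise _StageError(stage, exc)
    done(stage, pred_path)

    # --- report -------------------------------------------------------------
    stage = "report"
    report_path = out / "report.json"
    try:
        rep = pem.validate(preds, truth, mode="ratio")
        report = {
            "seed": cfg.seed,
            "config": cfg.config_hash(),
            "n_validation": int(len(preds)),
            "excluded": rep.excluded,
            "ratio_mu": rep.fit.mu,
            "ratio_sigma": rep.fit.sigma,
            "rmse": float(np.sqrt(np.mean((preds - truth) ** 2))),
        }
        report_path.write_text(json.dumps(report, indent=1))
    except Exception as exc:
        raise _StageError(stage, exc)
    done(stage, report_path)

    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": {k: v for k, v in asdict(cfg).items()},
        "artifacts": {
            s: {"file": artifacts[s], "sha256": _sha256(out / artifacts[s])}
            for s in STAGES
        },
        "timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _write_dot(g: nx.Graph, path: Path) -> None:
    lines = ["graph patterns {"]
    for u in g.nodes:
        lines.append(f'  {u} [label="pattern {u}"];')
    for u, v, data in g.edges(data=True):
        lines.append(f'  {u} -- {v} [weight={data.get("weight", 1.0):.4f}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
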