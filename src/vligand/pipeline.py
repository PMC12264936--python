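"""End-to-end screening pipeline: build-db -> project -> optimize -> predict -> rank.

Given a run configuration the pipeline

1. instantiates the energy backend,
2. obtains the ligand database — packaged, loaded from file, or generated
   synthetically (dissociation table -> PCA -> descriptors -> projection),
3. optimizes the VL parameters against the objective (unless a reference
   point ``p_star`` is supplied directly),
4. builds the requested surrogate and predicts every database ligand,
5. applies the reliability filters and ranks the survivors,

writing each stage's artifact (CSV/JSON/text) under the output directory.
With ``mode: filter_only`` and an explicit ``p_star`` only the reliability
filtering is performed — no backend, surrogate or derivatives are needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .backends import SyntheticLigandSpec, SyntheticSurfaceSpec, make_synthetic_ligand
from .config import RunConfig
from .descriptors import (
    FRAGMENTS,
    LigandRecord,
    build_dissociation_table,
    builtin_ligand_db,
    fit_pca,
    load_param_db,
    save_param_db,
)
from .projection import project
from .ranking import RankingReport, apply_filter, rank
from .surrogates import TaylorSurrogate, TrajectorySurrogate, predict_direct
from .vl_model import VLParams
from .vlao import BarrierSpec, ObjectiveSpec, optimize, save_trajectory

__all__ = ["PipelineResult", "PCAScoreBackend", "run_pipeline", "synthetic_database"]

log = logging.getLogger("vligand")


class PCAScoreBackend:
    """Descriptor backend composed with a frozen PCA transform.

    Maps ``p`` to principal-component scores ``Q (G_virt(p) - mean)`` so that
    projection operates in the same space as the database descriptors.  The
    transform is orthonormal, so distances (and hence ``l_min``) coincide
    with raw dissociation-energy space.
    """

    def __init__(self, spec, pca):
        self.spec = spec
        self.pca = pca

    def eval_descriptors(self, p):
        x, jac = self.spec.eval_descriptors(p)
        return self.pca.loadings @ (x - self.pca.mean), self.pca.loadings @ jac

    def eval_objective(self, p):
        return self.spec.eval_objective(p)


def synthetic_database(
    spec: SyntheticSurfaceSpec,
    n_ligands: int,
    bounds,
    delta_scale: float = 1.0,
    seed: int = 0,
    projection_options: Optional[dict] = None,
):
    """Generate a ligand database the way the real one is built.

    Ground-truth parameters are drawn uniformly inside ``bounds`` and each
    ligand's raw energies are placed off the surface by an orthogonal offset
    (half-normal, scale ``delta_scale``).  The energies then flow through the
    real machinery: dissociation table -> PCA -> descriptors -> projection.

    Returns ``(records, pca, score_backend, truth)`` where ``truth`` maps
    ligand id to its (p_true, delta).
    """
    rng = np.random.default_rng(seed)
    ids = [f"S{i + 1}" for i in range(n_ligands)]
    truth = {}
    energies = {}
    for i, ident in enumerate(ids):
        p_true = bounds.lower + rng.uniform(0, 1, bounds.lower.size) * bounds.width
        delta = float(np.abs(rng.normal(0, delta_scale)))
        lig = make_synthetic_ligand(
            spec, SyntheticLigandSpec(p_true, delta, seed=int(rng.integers(2**31)))
        )
        truth[ident] = (p_true, delta)
        energies[ident] = lig.x  # raw dissociation energies for this ligand

    table = build_dissociation_table(
        ids, FRAGMENTS[: spec.m], lambda lig, fg: energies[lig][
            FRAGMENTS.index(fg)
        ],
    )
    pca = fit_pca(table)
    score_backend = PCAScoreBackend(spec, pca)

    options = dict(projection_options or {})
    records = []
    for ident in ids:
        x = pca.to_descriptor(energies[ident])
        res = project(x, score_backend, **options)
        records.append(
            LigandRecord(
                id=ident,
                name=f"synthetic-{ident}",
                p=VLParams.from_array(res.p),
                l_min=res.l_min,
                x=x,
            )
        )
    return records, pca, score_backend, truth


@dataclass
class PipelineResult:
    report: Optional[RankingReport]
    counts: dict
    artifacts: dict
    p_star: np.ndarray
    summary: str


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the configured pipeline; see the module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    log.info(
        "pipeline start: version=%s mode=%s seed=%d", __version__,
        config.mode, config.seed,
    )

    # stage: database ------------------------------------------------------
    if config.database_source == "builtin":
        db = builtin_ligand_db()
    elif config.database_source == "synthetic":
        backend_kwargs = dict(config.backend)
        backend_kwargs.setdefault("seed", config.seed)
        spec = SyntheticSurfaceSpec(**backend_kwargs)
        proj_opts = dict(config.projection_options)
        proj_opts.setdefault("seed", config.seed)
        db, _, _, _ = synthetic_database(
            spec,
            config.database_n_ligands,
            config.bounds,
            delta_scale=config.database_delta_scale,
            seed=config.seed,
            projection_options=proj_opts,
        )
    else:
        db = load_param_db(config.database_source)
    db_path = outdir / "param_db.csv"
    save_param_db(db, db_path)
    artifacts["database"] = db_path
    log.info("stage database: %d ligands", len(db))

    # stage: reference point ----------------------------------------------
    if config.mode == "filter_only":
        p_star = np.asarray(config.p_star, dtype=float)
        counts = {
            f.name: len(apply_filter(db, p_star, config.bounds, f))
            for f in config.filters
        }
        summary_lines = [f"ligands: {len(db)}", f"p_star: {list(p_star)}"]
        for f in config.filters:
            summary_lines.append(
                f"filter {f.name} (l_min < {f.l_min_max}, "
                f"||dp'|| < {f.dp_norm_max}): {counts[f.name]} ligands"
            )
        summary = "\n".join(summary_lines)
        (outdir / "summary.txt").write_text(summary + "\n")
        artifacts["summary"] = outdir / "summary.txt"
        return PipelineResult(None, counts, artifacts, p_star, summary)

    backend_kwargs = dict(config.backend)
    backend_kwargs.setdefault("seed", config.seed)
    spec = SyntheticSurfaceSpec(**backend_kwargs)
    obj = ObjectiveSpec(spec, sense=config.sense)
    bar = BarrierSpec(config.bounds)

    if config.p_star is not None:
        p_star = np.asarray(config.p_star, dtype=float)
        traj = None
    else:
        vlao_opts = dict(config.vlao_options)
        traj = optimize(obj, bar, **vlao_opts)
        p_star = traj.p_star
        traj_path = outdir / "trajectory.json"
        save_trajectory(traj, traj_path)
        artifacts["trajectory"] = traj_path
        log.info(
            "stage vlao: %d iterations, objective %.6g", traj.n_iter, traj.f_star
        )

    # stage: surrogate + prediction ---------------------------------------
    if config.surrogate_mode == "direct":
        predict = lambda p: predict_direct(spec, p)  # noqa: E731
    elif config.surrogate_mode == "taylor":
        if traj is None:
            raise ValueError("taylor surrogate requires a VLAO run with Hessian")
        predict = TaylorSurrogate.from_trajectory(traj, clip=config.surrogate_clip)
    else:  # weighted
        if traj is None:
            raise ValueError("weighted surrogate requires a VLAO trajectory")
        predict = TrajectorySurrogate.from_trajectory(
            traj, obj, config.bounds, clip=config.surrogate_clip,
            subsample=config.surrogate_subsample,
        )

    # stage: ranking -------------------------------------------------------
    report = rank(
        db, predict, sense=config.sense, p_star=p_star,
        bounds=config.bounds, filters=config.filters,
    )
    report_path = outdir / "ranking.csv"
    report.to_csv(report_path)
    artifacts["report"] = report_path
    summary = report.summary()
    (outdir / "summary.txt").write_text(summary + "\n")
    artifacts["summary"] = outdir / "summary.txt"
    log.info("stage rank: counts %s", report.counts())
    return PipelineResult(report, report.counts(), artifacts, p_star, summary)
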