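"""Groupwise template construction and the two-level subgroup scheme.

``build_template`` is the align-then-average loop: every scan is
registered to the current target, resampled, and the target is replaced
by the voxelwise mean of the aligned scans (log-Euclidean for tensors,
arithmetic for scalars); the stage sequence is rigid -> affine ->
deformable, each stage initialized from the previous one.

``istg_run`` stacks two such levels: scans are first aligned within
homogeneous subgroups to intermediate subgroup templates, the subgroup
templates are then aligned to the sample-specific common space, and each
native scan is carried into the final space through its composed
subgroup-level and across-subgroup transform chain with a single
interpolation.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np

from .clustering import Partition
from .registration import (
    RegistrationSettings,
    register_affine,
    register_deformable,
    register_rigid,
    registration_cost,
)
from .similarity import DistanceMatrix, pairwise_scalar_distance
from .transforms import (
    AffineTransform,
    Grid,
    TransformChain,
    apply_transform,
    resample_log_tensors,
)
from .volumes import (
    ScalarVolume,
    TensorVolume,
    compute_fa,
    compute_md,
    exp_tensor_field,
    log_tensor_field,
)

__all__ = [
    "DEFAULT_ITERATIONS",
    "TemplateResult",
    "select_initial_target",
    "build_template",
    "istg_run",
]

#: Per-stage iteration counts; improvements beyond 2 are negligible.
DEFAULT_ITERATIONS = {"rigid": 2, "affine": 2, "deform": 2}


@dataclasses.dataclass
class TemplateResult:
    """Output of one groupwise construction (one level, or the full run)."""

    template: TensorVolume | ScalarVolume
    per_scan_chains: dict
    stage_history: list
    level: str
    aligned: dict = dataclasses.field(default_factory=dict)

    @property
    def grid(self) -> Grid:
        return Grid.of(self.template)


def _intensity(vol) -> np.ndarray:
    if isinstance(vol, TensorVolume):
        return compute_md(vol).values
    return np.maximum(vol.values, 0.0)


def select_initial_target(
    scans: Sequence, d: DistanceMatrix | None = None, ids: Sequence | None = None
) -> tuple[int, AffineTransform]:
    """Choose the medoid scan and a transform centering its mass.

    The medoid minimizes the summed distance to all other scans (ties go
    to the lowest index); the returned pull-back translation places the
    scan's intensity (MD) center of mass at the center of its own grid.
    With a single scan the medoid is trivially that scan.
    """
    if len(scans) == 0:
        raise ValueError("need at least one scan")
    if len(scans) == 1:
        medoid = 0
    elif d is not None:
        sums = d.values.sum(axis=1)
        medoid = int(np.argmin(sums))
    else:
        fa_maps = [
            compute_fa(s) if isinstance(s, TensorVolume) else s for s in scans
        ]
        dm = pairwise_scalar_distance(fa_maps, ids=ids)
        medoid = int(np.argmin(dm.values.sum(axis=1)))
    scan = scans[medoid]
    w = _intensity(scan)
    total = w.sum()
    idx = np.indices(w.shape, dtype=float)
    com_vox = np.array([(idx[a] * w).sum() / total for a in range(3)])
    com_world = scan.affine[:3, :3] @ com_vox + scan.affine[:3, 3]
    gc_vox = (np.array(w.shape) - 1) / 2.0
    gc_world = scan.affine[:3, :3] @ gc_vox + scan.affine[:3, 3]
    m = np.eye(4)
    m[:3, 3] = com_world - gc_world  # pull-back: grid center looks up the COM
    return medoid, AffineTransform(m, dof=6)


class _Resampler:
    """Caches per-scan log-tensor fields so each warp is one interpolation."""

    def __init__(self, scans: Sequence, ids: Sequence):
        self.scans = dict(zip(ids, scans))
        self.tensor = isinstance(scans[0], TensorVolume)
        self._logs: dict = {}

    def log_field(self, sid):
        if sid not in self._logs:
            self._logs[sid] = log_tensor_field(self.scans[sid].tensors)
        return self._logs[sid]

    def warp_log(self, sid, chain, grid: Grid) -> np.ndarray:
        return resample_log_tensors(
            self.log_field(sid), self.scans[sid].affine, chain, grid
        )

    def warp(self, sid, chain, grid: Grid):
        if self.tensor:
            return TensorVolume(
                exp_tensor_field(self.warp_log(sid, chain, grid)), grid.affine.copy()
            )
        return apply_transform(self.scans[sid], chain, grid)


def _average(warped: list, grid: Grid, tensor: bool, log_inputs: bool = False):
    if tensor:
        logs = warped if log_inputs else [log_tensor_field(w.tensors) for w in warped]
        mean_log = np.mean(logs, axis=0)
        return TensorVolume(exp_tensor_field(mean_log), grid.affine.copy())
    vals = np.mean([w.values for w in warped], axis=0)
    return ScalarVolume(vals, grid.affine.copy(), unit=warped[0].unit)


def build_template(
    scans: Sequence,
    target,
    iters: Mapping[str, int] | None = None,
    settings: RegistrationSettings | None = None,
    ids: Sequence | None = None,
    level: str = "final",
) -> TemplateResult:
    """Iterative align-then-average groupwise template construction.

    Stage order is rigid -> affine -> deformable; within each stage every
    iteration registers each native scan to the current target, resamples
    it (once, through its full current chain) and replaces the target by
    the voxelwise mean of the aligned scans.  The affine stage starts from
    the rigid transforms, the deformable stage from the affine ones.
    """
    iters = {**DEFAULT_ITERATIONS, **(iters or {})}
    settings = settings or RegistrationSettings()
    ids = list(ids) if ids is not None else [str(i) for i in range(len(scans))]
    if len(scans) == 0:
        raise ValueError("need at least one scan")
    tensor = isinstance(scans[0], TensorVolume)
    if settings.metric == "fa" and tensor:
        scans = [compute_fa(s) for s in scans]
        tensor = False
    rs = _Resampler(scans, ids)
    grid = Grid.of(target)
    history: list[tuple] = []

    rigid: dict = {sid: None for sid in ids}
    for it in range(iters.get("rigid", 0)):
        warped = []
        costs = []
        for sid in ids:
            t = register_rigid(rs.scans[sid], target, settings=settings, init=rigid[sid])
            rigid[sid] = t
            costs.append(registration_cost(rs.scans[sid], target, t, settings))
            warped.append(rs.warp_log(sid, [t], grid) if tensor else rs.warp(sid, [t], grid))
        target = _average(warped, grid, tensor, log_inputs=tensor)
        history.append(("rigid", it, float(np.mean(costs))))

    affine: dict = {sid: rigid[sid] for sid in ids}
    for it in range(iters.get("affine", 0)):
        warped = []
        costs = []
        for sid in ids:
            t = register_affine(rs.scans[sid], target, init=affine[sid], settings=settings)
            affine[sid] = t
            costs.append(registration_cost(rs.scans[sid], target, t, settings))
            warped.append(rs.warp_log(sid, [t], grid) if tensor else rs.warp(sid, [t], grid))
        target = _average(warped, grid, tensor, log_inputs=tensor)
        history.append(("affine", it, float(np.mean(costs))))

    # deformable iterations refine incrementally: each iteration registers
    # the scan warped through its current chain to the updated target and
    # appends the new field, so later iterations correct the residual
    chains = {
        sid: TransformChain([affine[sid]] if affine[sid] is not None else [])
        for sid in ids
    }
    for it in range(iters.get("deform", 0)):
        warped = []
        costs = []
        for sid in ids:
            moving_aligned = rs.warp(sid, chains[sid], grid)
            field = register_deformable(moving_aligned, target, settings=settings)
            costs.append(field.provenance[-1][2])
            chains[sid] = TransformChain(list(chains[sid].elements) + [field])
            warped.append(
                rs.warp_log(sid, chains[sid], grid)
                if tensor
                else rs.warp(sid, chains[sid], grid)
            )
        target = _average(warped, grid, tensor, log_inputs=tensor)
        history.append(("deform", it, float(np.mean(costs))))

    aligned = {sid: rs.warp(sid, chains[sid], grid) for sid in ids}
    return TemplateResult(target, chains, history, level, aligned=aligned)


def istg_run(
    scans: Sequence,
    partition: Partition,
    iters: Mapping[str, int] | None = None,
    settings: RegistrationSettings | None = None,
    distances: DistanceMatrix | None = None,
) -> TemplateResult:
    """Two-level groupwise registration through intermediate subgroup templates.

    Level 1 builds a template per subgroup (target: centered subgroup
    medoid); level 2 builds the sample-specific common space from the
    subgroup templates (target: centered medoid template).  Each scan's
    final chain is its subgroup-level chain followed by its subgroup's
    across-level chain, and each native scan is interpolated exactly once
    through the composed chain.
    """
    settings = settings or RegistrationSettings()
    ids = partition.ids
    if len(scans) != len(ids):
        raise ValueError("scans and partition ids differ in length")
    by_id = dict(zip(ids, scans))
    groups = partition.groups()
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty subgroup")

    sub_templates = []
    sub_results = []
    for g, members in enumerate(groups):
        g_scans = [by_id[sid] for sid in members]
        if len(members) == 1:
            warnings.warn(f"subgroup {g} has a single scan; used as its own template")
            res = TemplateResult(
                g_scans[0],
                {members[0]: TransformChain([AffineTransform.identity(dof=6)])},
                [],
                "subgroup",
                aligned={members[0]: g_scans[0]},
            )
        else:
            if distances is not None:
                rows = [ids.index(sid) for sid in members]
                sub_d = DistanceMatrix(
                    members, distances.values[np.ix_(rows, rows)], normalized=False
                )
            else:
                sub_d = None
            mi, center = select_initial_target(g_scans, d=sub_d, ids=members)
            target = apply_transform(g_scans[mi], [center])
            res = build_template(
                g_scans, target, iters=iters, settings=settings, ids=members,
                level="subgroup",
            )
        sub_templates.append(res.template)
        sub_results.append(res)

    if len(groups) == 1:
        res = sub_results[0]
        return TemplateResult(
            res.template, res.per_scan_chains, res.stage_history, "final",
            aligned=res.aligned,
        )

    group_ids = [f"group{g}" for g in range(len(groups))]
    mi, center = select_initial_target(sub_templates, ids=group_ids)
    target2 = apply_transform(sub_templates[mi], [center])
    level2 = build_template(
        sub_templates, target2, iters=iters, settings=settings, ids=group_ids,
        level="final",
    )

    grid = level2.grid
    chains = {}
    history = []
    for g, members in enumerate(groups):
        history.extend(
            [(f"subgroup{g}/{s}", i, c) for (s, i, c) in sub_results[g].stage_history]
        )
        l2_chain = level2.per_scan_chains[group_ids[g]]
        for sid in members:
            chains[sid] = TransformChain(
                list(sub_results[g].per_scan_chains[sid].elements) + list(l2_chain.elements)
            )
    history.extend([(f"level2/{s}", i, c) for (s, i, c) in level2.stage_history])

    rs = _Resampler([by_id[sid] for sid in ids], ids)
    aligned = {sid: rs.warp(sid, chains[sid], grid) for sid in ids}
    return TemplateResult(level2.template, chains, history, "final", aligned=aligned)
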