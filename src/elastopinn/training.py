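"""Training loop binding networks, mechanics and losses.

Three problem modes share one loop:

* forward — elasticity known, both displacement components predicted by
  a displacement network; residual loss plus boundary-displacement and
  boundary-traction MAEs.
* inverse — displacement measured (per loading), Young's modulus and/or
  Poisson's ratio predicted by an elasticity network; residual loss plus
  the mean-elasticity constraint.
* mixed — one displacement component measured, the other predicted,
  together with an elasticity unknown; residual loss plus mean-elasticity
  and mean-displacement constraints.

Each loading case owns its displacement network (when displacements are
predicted); all loadings share one elasticity network.  Training is
full-batch over all q^2 material points with the Adam optimizer, and
every run is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .fields import DisplacementField, ElasticityField, StressField
from .grid import GridSpec
from .losses import (
    BoundaryData,
    ConstraintTargets,
    LossWeights,
    loss_boundary_displacement_with_grad,
    loss_boundary_traction_with_grad,
    loss_mean_displacement_with_grad,
    loss_mean_elasticity_with_grad,
    loss_residual_with_grad,
)
from .mechanics import (
    compute_strain,
    constitutive_stress,
    constitutive_vjp,
    residual_forces,
    residual_forces_adjoint,
    strain_adjoint,
)
from .networks import FieldNetwork, NetworkConfig
from .phantoms import LoadingCase

__all__ = [
    "Loading",
    "ProblemSpec",
    "TrainingConfig",
    "RunResult",
    "TrainingDiverged",
    "Adam",
    "train_single",
    "train_ensemble",
    "train_duo_loading",
]

_DISP_COMPONENTS = ("u_x", "u_y")


class TrainingDiverged(RuntimeError):
    """Loss became non-finite; carries the epoch index."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged at epoch {epoch}")
        self.epoch = epoch


@dataclass
class Loading:
    """One loading case: its measured displacement data and, in forward
    mode, the boundary conditions defining the problem."""

    measured: dict[str, np.ndarray] = dc_field(default_factory=dict)
    case: LoadingCase | None = None
    boundary: BoundaryData | None = None

    def unknown_components(self, mode: str) -> tuple[str, ...]:
        if mode == "forward":
            return _DISP_COMPONENTS
        return tuple(c for c in _DISP_COMPONENTS if c not in self.measured)


@dataclass
class ProblemSpec:
    """Declares what is measured and what is to be learned.

    ``elasticity`` holds the measured subset of {"E", "nu"} as grids;
    the complementary subset is predicted by the elasticity network.
    Every loading shares that one elasticity field; each loading with
    unknown displacement components gets its own displacement network.
    At most two physical quantities may be unknown overall — there are
    only two equilibrium conditions to constrain them.
    """

    mode: str
    grid: GridSpec
    loadings: list[Loading]
    elasticity: dict[str, np.ndarray] = dc_field(default_factory=dict)
    targets: ConstraintTargets = dc_field(default_factory=ConstraintTargets)
    truth: dict[str, np.ndarray] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("forward", "inverse", "mixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.loadings:
            raise ValueError("at least one loading case is required")
        q = self.grid.q
        for name, arr in {**self.elasticity, **self.truth}.items():
            if np.shape(arr) != (q, q):
                raise ValueError(f"{name} grid does not match GridSpec (stage: spec)")
        for k, ld in enumerate(self.loadings):
            for name, arr in ld.measured.items():
                if np.shape(arr) != (q, q):
                    raise ValueError(
                        f"loading {k}: measured {name} does not match GridSpec"
                    )
        if self.mode == "forward":
            if set(self.elasticity) != {"E", "nu"}:
                raise ValueError("forward mode requires the full elasticity field")
            for k, ld in enumerate(self.loadings):
                if ld.boundary is None or ld.boundary.n_u == 0:
                    raise ValueError(
                        f"loading {k}: forward mode needs geometric boundary data"
                    )
        elif self.mode == "inverse":
            for k, ld in enumerate(self.loadings):
                if set(ld.measured) != set(_DISP_COMPONENTS):
                    raise ValueError(
                        f"loading {k}: inverse mode requires measured u_x and u_y"
                    )
            if not self.unknown_elasticity:
                raise ValueError("inverse mode has nothing to recover")
        else:  # mixed
            for k, ld in enumerate(self.loadings):
                if len(ld.measured) != 1:
                    raise ValueError(
                        f"loading {k}: mixed mode measures exactly one displacement "
                        "component"
                    )
        n_unknown = len(self.unknown_elasticity) + max(
            (len(ld.unknown_components(self.mode)) for ld in self.loadings), default=0
        )
        if self.mode != "forward" and n_unknown > 2:
            raise ValueError(
                "more than two unknown quantities: only two equilibrium conditions "
                "are available"
            )

    @property
    def unknown_elasticity(self) -> tuple[str, ...]:
        if self.mode == "forward":
            return ()
        return tuple(n for n in ("E", "nu") if n not in self.elasticity)


@dataclass
class TrainingConfig:
    """Optimizer and protocol settings.

    Defaults follow the full-scale training protocol: Adam with learning rate
    0.005, 10 random restarts with the best 5 (by final loss) averaged.
    ``epochs`` must be set by the caller — sensible budgets scale with
    the grid and network size.
    """

    epochs: int
    learning_rate: float = 0.005
    restarts: int = 10
    ensemble_size: int = 5
    seed: int = 0
    weights: LossWeights | None = None  # None = auto-balance at epoch 0
    disp_net: NetworkConfig | None = None
    elast_net: NetworkConfig | None = None
    warm_start: dict[str, FieldNetwork] | None = None
    log_every: int = 100

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.ensemble_size > self.restarts:
            raise ValueError("ensemble_size cannot exceed restarts")


@dataclass
class RunResult:
    """Predicted fields with the loss history and optional truth metrics."""

    fields: dict[str, np.ndarray]
    final_loss: float
    history: pd.DataFrame
    seed: int
    weights: LossWeights
    metrics: dict[str, float] = dc_field(default_factory=dict)
    members: list["RunResult"] | None = None  # populated by train_ensemble
    networks: dict = dc_field(default_factory=dict)  # trained nets, for warm starts


class Adam:
    """Adaptive-moment estimation over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# network construction

def _derive_seed(base: int, salt: int) -> int:
    return int((base * 1_000_003 + salt * 7919 + 17) % (2**31 - 1))


def _default_disp_config() -> NetworkConfig:
    from .networks import displacement_config

    return displacement_config()


def _default_elast_config(spec: ProblemSpec) -> NetworkConfig:
    from .networks import elasticity_config

    return elasticity_config(
        mean_E=spec.targets.mean_E_target, with_nu="nu" in spec.unknown_elasticity
    )


def _displacement_scale(spec: ProblemSpec, ld: Loading) -> float:
    vals = [np.std(arr) for arr in ld.measured.values()]
    if ld.boundary is not None and ld.boundary.n_u > 0:
        vals.append(float(np.std(ld.boundary.disp_value)))
    scale = max(vals) if vals else 0.0
    if scale <= 0:
        scale = 0.01 * spec.grid.extent
    return float(scale)


def _build_networks(
    spec: ProblemSpec, cfg: TrainingConfig, seed: int
) -> tuple[FieldNetwork | None, list[FieldNetwork | None]]:
    elast_net = None
    if spec.unknown_elasticity:
        template = cfg.elast_net or _default_elast_config(spec)
        template = replace(
            template,
            outputs=spec.unknown_elasticity,
            init_seed=_derive_seed(seed, 0),
        )
        elast_net = FieldNetwork(template)
    disp_nets: list[FieldNetwork | None] = []
    for k, ld in enumerate(spec.loadings):
        comps = ld.unknown_components(spec.mode)
        if comps:
            template = cfg.disp_net or _default_disp_config()
            # de-normalization scale: a fresh network outputs O(1), so the
            # head scale should be the physical displacement magnitude —
            # taken from the measured component when one exists, else the
            # prescribed boundary values, else 1% of the extent
            scales = dict(template.output_scale)
            for comp in comps:
                if comp not in scales:
                    scales[comp] = _displacement_scale(spec, ld)
            template = replace(
                template,
                outputs=comps,
                output_scale=scales,
                init_seed=_derive_seed(seed, 1 + k),
            )
            disp_nets.append(FieldNetwork(template))
        else:
            disp_nets.append(None)
    if cfg.warm_start:
        if elast_net is not None and "elasticity" in cfg.warm_start:
            elast_net.set_parameters(cfg.warm_start["elasticity"].parameters)
        for k, net in enumerate(disp_nets):
            key = f"displacement_{k}"
            if net is not None and key in cfg.warm_start:
                net.set_parameters(cfg.warm_start[key].parameters)
    return elast_net, disp_nets


# ---------------------------------------------------------------------------
# one full-batch epoch: loss + gradients w.r.t. every predicted grid

def _epoch(
    spec: ProblemSpec,
    weights: LossWeights,
    E_grid: np.ndarray,
    nu_grid: np.ndarray,
    disp_grids: list[dict[str, np.ndarray]],
) -> tuple[dict[str, float], np.ndarray, np.ndarray, list[dict[str, np.ndarray]]]:
    """Evaluate the mode's total loss and its grid cotangents.

    Returns (terms, dL/dE, dL/dnu, per-loading dL/du dicts).  Terms
    holds the unweighted components plus the weighted total "L".
    """
    grid = spec.grid
    field = ElasticityField(E=E_grid, nu=nu_grid)
    dE = np.zeros_like(E_grid)
    dnu = np.zeros_like(nu_grid)
    d_disp: list[dict[str, np.ndarray]] = []
    L_r_total = 0.0
    L_u_total, L_f_total, L_d_total = 0.0, 0.0, 0.0
    n_u_terms = n_f_terms = 0

    for ld, grids in zip(spec.loadings, disp_grids):
        disp = DisplacementField(u_x=grids["u_x"], u_y=grids["u_y"])
        strain = compute_strain(disp, grid)
        stress = constitutive_stress(strain, field)
        res = residual_forces(stress, grid)

        L_r, bar_e, dE_norm = loss_residual_with_grad(res, E_grid)
        L_r_total += L_r
        bar_e.e_x *= weights.w_r
        bar_e.e_y *= weights.w_r
        bar_stress = residual_forces_adjoint(bar_e, grid)
        dE += weights.w_r * dE_norm

        if spec.mode == "forward" and ld.boundary is not None and ld.boundary.n_t > 0:
            L_f, bar_stress_f = loss_boundary_traction_with_grad(stress, ld.boundary)
            L_f_total += L_f
            n_f_terms += 1
            bar_stress = StressField(
                sigma_xx=bar_stress.sigma_xx + weights.w_f * bar_stress_f.sigma_xx,
                sigma_yy=bar_stress.sigma_yy + weights.w_f * bar_stress_f.sigma_yy,
                tau_xy=bar_stress.tau_xy + weights.w_f * bar_stress_f.tau_xy,
            )

        bar_eps, dE_c, dnu_c = constitutive_vjp(strain, field, bar_stress)
        bar_disp = strain_adjoint(bar_eps, grid)
        dE += dE_c
        dnu += dnu_c

        grads = {"u_x": bar_disp.u_x, "u_y": bar_disp.u_y}

        if spec.mode == "forward" and ld.boundary is not None and ld.boundary.n_u > 0:
            L_u, bar_u = loss_boundary_displacement_with_grad(disp, ld.boundary)
            L_u_total += L_u
            n_u_terms += 1
            grads["u_x"] = grads["u_x"] + weights.w_u * bar_u.u_x
            grads["u_y"] = grads["u_y"] + weights.w_u * bar_u.u_y

        if spec.mode == "mixed":
            for comp in ld.unknown_components(spec.mode):
                L_d, bar_d = loss_mean_displacement_with_grad(
                    grids[comp], spec.targets
                )
                L_d_total += L_d
                grads[comp] = grads[comp] + weights.w_d * bar_d
        d_disp.append(grads)

    terms: dict[str, float] = {"L_r": L_r_total}
    total = weights.w_r * L_r_total
    if spec.mode == "forward":
        terms["L_u"] = L_u_total
        terms["L_f"] = L_f_total if n_f_terms else 0.0
        total += weights.w_u * L_u_total + weights.w_f * terms["L_f"]
    if spec.mode in ("inverse", "mixed"):
        L_e, dE_e = loss_mean_elasticity_with_grad(E_grid, spec.targets)
        terms["L_e"] = L_e
        total += weights.w_e * L_e
        dE += weights.w_e * dE_e
    if spec.mode == "mixed":
        terms["L_d"] = L_d_total
        total += weights.w_d * L_d_total
    terms["L"] = total
    return terms, dE, dnu, d_disp


def _predict_grids(
    spec: ProblemSpec,
    positions: np.ndarray,
    elast_net: FieldNetwork | None,
    disp_nets: list[FieldNetwork | None],
    caches: dict,
) -> tuple[np.ndarray, np.ndarray, list[dict[str, np.ndarray]]]:
    q = spec.grid.q
    if elast_net is not None:
        caches["elast"] = {}
        out = elast_net.forward(positions, caches["elast"])
    else:
        out = {}
    E_grid = out["E"].reshape(q, q) if "E" in out else np.asarray(spec.elasticity["E"])
    nu_grid = (
        out["nu"].reshape(q, q) if "nu" in out else np.asarray(spec.elasticity["nu"])
    )
    disp_grids = []
    for k, (ld, net) in enumerate(zip(spec.loadings, disp_nets)):
        grids = {c: np.asarray(v) for c, v in ld.measured.items()}
        if net is not None:
            caches[f"disp_{k}"] = {}
            pred = net.forward(positions, caches[f"disp_{k}"])
            for c, v in pred.items():
                grids[c] = v.reshape(q, q)
        disp_grids.append(grids)
    return E_grid, nu_grid, disp_grids


def _auto_weights(
    spec: ProblemSpec,
    dE_res: np.ndarray,
    d_disp_res: list[dict[str, np.ndarray]],
) -> LossWeights:
    """Balance the constraint weights once, from epoch-0 gradient scales.

    The mean constraints are absolute deviations, so their per-point
    gradient has the constant magnitude w/q^2 and never decays; if it
    exceeds the per-point gradient of the residual term it dominates the
    adaptive optimizer's step normalization and recovery stalls.  Each
    constraint weight is therefore set so its per-point gradient matches
    the rms per-point gradient that the residual term produces at
    initialization, then frozen.
    """
    n = spec.grid.q**2

    def rms(a: np.ndarray) -> float:
        return float(np.sqrt((a**2).mean()))

    w_e = 1.0 / spec.targets.mean_E_target
    if spec.unknown_elasticity:
        scale = rms(dE_res)
        if scale > 0:
            w_e = scale * n
    disp_scales = [
        rms(d[c])
        for ld, d in zip(spec.loadings, d_disp_res)
        for c in ld.unknown_components(spec.mode)
    ]
    w_d = 1.0 / max(0.01 * spec.grid.extent, 1e-12)
    if disp_scales and max(disp_scales) > 0:
        w_d = float(np.mean(disp_scales)) * n
    return LossWeights(w_r=1.0, w_u=1.0, w_f=1.0, w_e=w_e, w_d=w_d)


def _truth_metrics(spec: ProblemSpec, fields: dict[str, np.ndarray]) -> dict[str, float]:
    from .metrics import mae, mre

    out: dict[str, float] = {}
    for name, pred in fields.items():
        if name in spec.truth:
            truth = np.asarray(spec.truth[name])
            if name.startswith("u"):
                # only derivatives of a predicted displacement are
                # identified; compare after matching the means
                pred = pred - pred.mean() + truth.mean()
                out[f"mae_{name}"] = mae(pred, truth)
            else:
                out[f"mae_{name}"] = mae(pred, truth)
                out[f"mre_{name}"] = mre(pred, truth)
    return out


def train_single(spec: ProblemSpec, cfg: TrainingConfig, seed: int | None = None) -> RunResult:
    """One optimization run from a single random initialization."""
    seed = cfg.seed if seed is None else seed
    positions = spec.grid.normalized_positions()
    elast_net, disp_nets = _build_networks(spec, cfg, seed)
    nets = [n for n in [elast_net, *disp_nets] if n is not None]
    if not nets:
        raise ValueError("nothing to train: every quantity is measured")
    optimizers = [Adam(net.parameters, cfg.learning_rate) for net in nets]

    weights = cfg.weights
    rows = []
    terms: dict[str, float] = {}
    for epoch in range(cfg.epochs):
        caches: dict = {}
        E_grid, nu_grid, disp_grids = _predict_grids(
            spec, positions, elast_net, disp_nets, caches
        )
        if not (
            np.all(np.isfinite(E_grid))
            and np.all(np.isfinite(nu_grid))
            and all(np.all(np.isfinite(g)) for d in disp_grids for g in d.values())
        ):
            raise TrainingDiverged(epoch)
        if weights is None:
            probe = LossWeights(w_r=1.0, w_u=1.0, w_f=1.0, w_e=0.0, w_d=0.0)
            _, dE0, _, d_disp0 = _epoch(spec, probe, E_grid, nu_grid, disp_grids)
            weights = _auto_weights(spec, dE0, d_disp0)
        try:
            terms, dE, dnu, d_disp = _epoch(spec, weights, E_grid, nu_grid, disp_grids)
        except ValueError:
            if epoch == 0:
                raise  # a genuine specification problem, not divergence
            # optimizer blow-up drove a field out of its admissible range
            raise TrainingDiverged(epoch) from None
        if not np.isfinite(terms["L"]):
            raise TrainingDiverged(epoch)

        grad_lists = []
        if elast_net is not None:
            go = {}
            if "E" in elast_net.config.outputs:
                go["E"] = dE.ravel()
            if "nu" in elast_net.config.outputs:
                go["nu"] = dnu.ravel()
            grad_lists.append(elast_net.backward(caches["elast"], go))
        for k, net in enumerate(disp_nets):
            if net is not None:
                go = {c: d_disp[k][c].ravel() for c in net.config.outputs}
                grad_lists.append(net.backward(caches[f"disp_{k}"], go))

        for net, opt, grads in zip(nets, optimizers, grad_lists):
            opt.step(net.parameters, grads)  # in-place on the live arrays

        if epoch % cfg.log_every == 0 or epoch == cfg.epochs - 1:
            row = {"epoch": epoch, **terms}
            if spec.truth:
                fields_now = _collect_fields(spec, E_grid, nu_grid, disp_grids)
                row.update(_truth_metrics(spec, fields_now))
            rows.append(row)

    caches = {}
    E_grid, nu_grid, disp_grids = _predict_grids(
        spec, positions, elast_net, disp_nets, caches
    )
    final_terms, _, _, _ = _epoch(spec, weights, E_grid, nu_grid, disp_grids)
    fields = _collect_fields(spec, E_grid, nu_grid, disp_grids)
    result = RunResult(
        fields=fields,
        final_loss=final_terms["L"],
        history=pd.DataFrame(rows),
        seed=seed,
        weights=weights,
        metrics=_truth_metrics(spec, fields),
    )
    result.networks = {"elasticity": elast_net}
    for k, net in enumerate(disp_nets):
        result.networks[f"displacement_{k}"] = net
    return result


def _collect_fields(spec, E_grid, nu_grid, disp_grids) -> dict[str, np.ndarray]:
    fields: dict[str, np.ndarray] = {}
    if "E" in spec.unknown_elasticity:
        fields["E"] = E_grid.copy()
    if "nu" in spec.unknown_elasticity:
        fields["nu"] = nu_grid.copy()
    for k, ld in enumerate(spec.loadings):
        for comp in ld.unknown_components(spec.mode):
            key = comp if len(spec.loadings) == 1 else f"{comp}_{k}"
            fields[key] = disp_grids[k][comp].copy()
    return fields


def train_ensemble(spec: ProblemSpec, cfg: TrainingConfig) -> RunResult:
    """Multi-restart training: average the best runs' predicted fields.

    Runs :func:`train_single` ``cfg.restarts`` times with distinct
    initialization seeds, ranks the surviving runs by final loss and
    averages the predicted fields of the best ``cfg.ensemble_size``
    pointwise.  Predicted displacement components are mean-centered to
    the constraint target before averaging, removing each run's
    undetermined constant.
    """
    members: list[RunResult] = []
    for k in range(cfg.restarts):
        try:
            members.append(train_single(spec, cfg, seed=_derive_seed(cfg.seed, 97 + k)))
        except TrainingDiverged:
            continue
    if len(members) < cfg.ensemble_size:
        raise RuntimeError(
            f"only {len(members)} of {cfg.restarts} restarts converged; "
            f"cannot average {cfg.ensemble_size}"
        )
    members.sort(key=lambda r: r.final_loss)
    best = members[: cfg.ensemble_size]

    fields: dict[str, np.ndarray] = {}
    for name in best[0].fields:
        stack = []
        for r in best:
            f = r.fields[name]
            if name.startswith("u") and spec.mode == "mixed":
                f = f - f.mean() + spec.targets.mean_disp_target
            stack.append(f)
        fields[name] = np.mean(stack, axis=0)

    result = RunResult(
        fields=fields,
        final_loss=best[0].final_loss,
        history=best[0].history,
        seed=cfg.seed,
        weights=best[0].weights,
        metrics=_truth_metrics(spec, fields),
        members=members,
        networks=best[0].networks,
    )
    return result


def train_duo_loading(spec: ProblemSpec, cfg: TrainingConfig) -> RunResult:
    """Train with two loading cases sharing one elasticity field."""
    if len(spec.loadings) != 2:
        raise ValueError("duo-loading training requires exactly two loadings")
    return train_ensemble(spec, cfg)
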