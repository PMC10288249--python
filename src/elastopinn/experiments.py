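"""End-to-end experiment orchestration.

Composes the pipeline phantom -> FEM ground truth -> training ->
evaluation into reproducible, fully configured runs, including the
packaged reduced-scale replication presets and the activation-function
sweep harness.  Every artifact written to disk embeds the configuration
that produced it, so a run directory can be regenerated from its own
metadata.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .fem import assemble_and_solve
from .fields import DisplacementField, ElasticityField
from .grid import GridSpec
from .losses import ConstraintTargets
from .metrics import error_report
from .networks import NetworkConfig, displacement_config, elasticity_config
from .phantoms import (
    InclusionShape,
    LoadingCase,
    RosePhantomSpec,
    boundary_displacements,
    forward_boundary_data,
    inclusion_field,
    rose_modulus_field,
)
from .training import (
    Loading,
    ProblemSpec,
    RunResult,
    TrainingConfig,
    train_ensemble,
)

__all__ = [
    "ExperimentConfig",
    "DatasetBundle",
    "make_dataset",
    "run_experiment",
    "activation_sweep",
    "PRESETS",
    "preset_config",
]


# ---------------------------------------------------------------------------
# dataset bundles

@dataclass
class DatasetBundle:
    """Self-describing synthetic dataset: truth fields + FEM displacements.

    Units are embedded in the metadata (E in MPa, displacements in mm,
    grid spacing in mm); ``save``/``load`` round-trip losslessly through
    an .npz of named arrays plus a JSON metadata sidecar.
    """

    grid: GridSpec
    elasticity: ElasticityField
    displacements: list[DisplacementField]
    cases: list[LoadingCase]
    metadata: dict = dc_field(default_factory=dict)

    def save(self, path) -> None:
        path = Path(path)
        arrays = {"E": self.elasticity.E, "nu": self.elasticity.nu}
        for k, d in enumerate(self.displacements):
            arrays[f"u_x_{k}"] = d.u_x
            arrays[f"u_y_{k}"] = d.u_y
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "grid": {"q": self.grid.q, "h": self.grid.h, "t": self.grid.t},
            "cases": [{"mode": c.mode, "magnitude": c.magnitude} for c in self.cases],
            "units": {"E": "MPa", "displacement": "mm", "h": "mm"},
            "layout": "arrays indexed [i, j]; x = j*h, y = i*h",
            **self.metadata,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "DatasetBundle":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        grid = GridSpec(**meta["grid"])
        with np.load(path.with_suffix(".npz")) as data:
            elast = ElasticityField(E=data["E"], nu=data["nu"])
            disps = []
            k = 0
            while f"u_x_{k}" in data:
                disps.append(
                    DisplacementField(u_x=data[f"u_x_{k}"], u_y=data[f"u_y_{k}"])
                )
                k += 1
        cases = [LoadingCase(**c) for c in meta.get("cases", [])]
        extra = {
            k: v
            for k, v in meta.items()
            if k not in ("grid", "cases", "units", "layout")
        }
        return cls(grid=grid, elasticity=elast, displacements=disps, cases=cases,
                   metadata=extra)


def _build_phantom(cfg: "ExperimentConfig", grid: GridSpec) -> ElasticityField:
    if cfg.phantom == "rose":
        return rose_modulus_field(cfg.rose or RosePhantomSpec(), grid)
    if cfg.phantom == "discs":
        return inclusion_field(
            grid, cfg.background_E, cfg.background_nu, cfg.shapes
        )
    raise ValueError(f"unknown phantom {cfg.phantom!r} (stage: phantom)")


def make_dataset(cfg: "ExperimentConfig") -> DatasetBundle:
    """Generate the phantom and solve the FEM for every loading case."""
    grid = cfg.grid
    field = _build_phantom(cfg, grid)
    disps = []
    for case in cfg.cases:
        try:
            sol = assemble_and_solve(field, boundary_displacements(case, grid), grid)
        except ValueError as exc:
            raise ValueError(f"FEM solve failed for {case.mode} (stage: fem): {exc}")
        disps.append(sol.displacement)
    return DatasetBundle(
        grid=grid,
        elasticity=field,
        displacements=disps,
        cases=list(cfg.cases),
        metadata={"phantom": cfg.phantom, "seed": cfg.seed},
    )


# ---------------------------------------------------------------------------
# experiment configuration

@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one end-to-end run."""

    mode: str  # forward | inverse | mixed
    grid: GridSpec
    phantom: str = "discs"  # rose | discs
    rose: RosePhantomSpec | None = None
    shapes: list[InclusionShape] = dc_field(default_factory=list)
    background_E: float = 0.1
    background_nu: float = 0.5
    cases: list[LoadingCase] = dc_field(default_factory=lambda: [LoadingCase("uniaxial-x", 0.01)])
    measured_axial: str = "u_x"  # mixed mode: which component is measured
    known_elasticity: tuple[str, ...] = ()  # inverse/mixed: measured elastic constants
    training: TrainingConfig | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        d = {k: enc(v) for k, v in dataclasses.asdict(self).items()}
        # FieldNetwork warm starts are not JSON-serializable; record presence only
        if self.training is not None and self.training.warm_start:
            d["training"]["warm_start"] = sorted(self.training.warm_start)
        return d


def _problem_spec(cfg: ExperimentConfig, data: DatasetBundle) -> ProblemSpec:
    grid = cfg.grid
    truth: dict[str, np.ndarray] = {
        "E": data.elasticity.E,
        "nu": data.elasticity.nu,
    }
    known = {k: getattr(data.elasticity, k) for k in cfg.known_elasticity}
    targets = ConstraintTargets(mean_E_target=float(data.elasticity.E.mean()))
    loadings = []
    for case, disp in zip(data.cases, data.displacements):
        if cfg.mode == "forward":
            loadings.append(
                Loading(case=case, boundary=forward_boundary_data(case, grid))
            )
        elif cfg.mode == "inverse":
            loadings.append(
                Loading(case=case, measured={"u_x": disp.u_x, "u_y": disp.u_y})
            )
        else:  # mixed
            comp = cfg.measured_axial
            loadings.append(
                Loading(case=case, measured={comp: getattr(disp, comp)})
            )
    if len(data.displacements) == 1:
        truth["u_x"] = data.displacements[0].u_x
        truth["u_y"] = data.displacements[0].u_y
    if cfg.mode == "forward":
        known = {"E": data.elasticity.E, "nu": data.elasticity.nu}
    return ProblemSpec(
        mode=cfg.mode, grid=grid, loadings=loadings, elasticity=known,
        targets=targets, truth=truth,
    )


def _default_training(cfg: ExperimentConfig, data: DatasetBundle) -> TrainingConfig:
    mean_E = float(data.elasticity.E.mean())
    with_nu = "nu" not in cfg.known_elasticity and cfg.mode != "forward"
    return TrainingConfig(
        epochs=20_000,
        learning_rate=0.005 if cfg.mode == "mixed" else 0.002,
        restarts=3,
        ensemble_size=3,
        seed=cfg.seed,
        disp_net=displacement_config(depth=4, width=48),
        elast_net=elasticity_config(mean_E=mean_E, with_nu=with_nu, depth=4, width=48),
    )


def run_experiment(cfg: ExperimentConfig, out_dir=None) -> tuple[RunResult, dict]:
    """Full pipeline: phantom -> FEM -> train -> evaluate (-> disk).

    Returns the training result and an evaluation report with an error
    summary per recovered field.  When ``out_dir`` is given, writes the
    predicted fields (.npz), loss history (.csv), the evaluation report
    and the config snapshot (.json).
    """
    data = make_dataset(cfg)
    spec = _problem_spec(cfg, data)
    tcfg = cfg.training or _default_training(cfg, data)
    result = train_ensemble(spec, tcfg)

    report: dict = {"mode": cfg.mode, "final_loss": result.final_loss}
    for name, pred in result.fields.items():
        base = name.split("_")[0] if name.startswith("u") else name
        if name in spec.truth or base in ("E", "nu"):
            truth = spec.truth.get(name)
            if truth is None and base in spec.truth:
                truth = spec.truth[base]
            if truth is None:
                continue
            if name.startswith("u"):
                # mean-matched: only the derivatives of a predicted
                # displacement are identified
                pred_c = pred - pred.mean() + np.asarray(truth).mean()
                report[f"mae_{name}"] = float(np.abs(pred_c - truth).mean())
            else:
                rep = error_report(pred, truth)
                report[f"mae_{name}"] = rep.mae
                report[f"mre_{name}"] = rep.mre

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "fields.npz", **result.fields)
        result.history.to_csv(out / "history.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        (out / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2))
        data.save(out / "dataset")
    return result, report


# ---------------------------------------------------------------------------
# activation sweep

def activation_sweep(
    cfg: ExperimentConfig,
    sigma_d: list[str],
    sigma_e: list[str],
) -> pd.DataFrame:
    """Grid of runs varying the two networks' activation functions.

    For every (elasticity activation, displacement activation) pair the
    same experiment is run with shared seeds; the result is a
    long-format table with the final modulus MAE and the MAE-vs-epoch
    curve for each combination.
    """
    if not sigma_d or not sigma_e:
        raise ValueError("need at least one activation per network")
    data = make_dataset(cfg)
    spec = _problem_spec(cfg, data)
    rows = []
    for act_e in sigma_e:
        for act_d in sigma_d:
            tcfg = cfg.training or _default_training(cfg, data)
            tcfg = dataclasses.replace(
                tcfg,
                disp_net=dataclasses.replace(
                    tcfg.disp_net or displacement_config(), activation=act_d
                ),
                elast_net=dataclasses.replace(
                    tcfg.elast_net
                    or elasticity_config(mean_E=float(data.elasticity.E.mean())),
                    activation=act_e,
                ),
            )
            result = train_ensemble(spec, tcfg)
            hist = result.history
            mae_curve = (
                hist[["epoch", "mae_E"]].values.tolist() if "mae_E" in hist else []
            )
            rows.append(
                {
                    "sigma_e": act_e,
                    "sigma_d": act_d,
                    "final_mae_E": result.metrics.get("mae_E", np.nan),
                    "final_mre_E": result.metrics.get("mre_E", np.nan),
                    "final_loss": result.final_loss,
                    "mae_curve": mae_curve,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# packaged reduced-scale replication presets

def _desk_grid(q: int = 32) -> GridSpec:
    return GridSpec(q=q, h=10.0 / (q - 1), t=1.0)


def _disc_inverse_preset(seed: int) -> ExperimentConfig:
    grid = _desk_grid(32)
    return ExperimentConfig(
        mode="inverse",
        grid=grid,
        phantom="discs",
        shapes=[InclusionShape(cx=5.0, cy=5.0, rx=2.5, E=1.0, smooth=0.6)],
        background_E=0.1,
        background_nu=0.5,
        cases=[LoadingCase("uniaxial-x", 0.01)],
        known_elasticity=("nu",),
        seed=seed,
    )


def _rose_mixed_preset(seed: int) -> ExperimentConfig:
    grid = _desk_grid(32)
    return ExperimentConfig(
        mode="mixed",
        grid=grid,
        phantom="rose",
        rose=RosePhantomSpec(),
        cases=[LoadingCase("sinusoidal-top", None)],
        measured_axial="u_y",
        known_elasticity=("nu",),
        seed=seed,
    )


def _duo_loading_preset(seed: int) -> ExperimentConfig:
    grid = _desk_grid(32)
    # modulus pattern: centered stiff disc; Poisson pattern: offset disc
    shapes = [
        InclusionShape(cx=5.0, cy=5.0, rx=2.5, E=1.0, smooth=0.6),
        InclusionShape(cx=3.5, cy=6.5, rx=2.0, nu=0.1, smooth=0.6),
    ]
    return ExperimentConfig(
        mode="inverse",
        grid=grid,
        phantom="discs",
        shapes=shapes,
        background_E=0.1,
        background_nu=0.5,
        cases=[LoadingCase("uniaxial-x", 0.01), LoadingCase("uniaxial-y", 0.01)],
        known_elasticity=(),
        seed=seed,
    )


PRESETS = {
    "disc-inverse": _disc_inverse_preset,
    "rose-mixed": _rose_mixed_preset,
    "duo-loading": _duo_loading_preset,
}


def preset_config(name: str, seed: int = 0) -> ExperimentConfig:
    """A packaged reduced-scale replication experiment by name."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return factory(seed)
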