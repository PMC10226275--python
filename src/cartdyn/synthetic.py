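"""Synthetic impedance killing-assay generator.

Emulates the xCELLigence-style experiment the pipeline is built for: cancer
cells seeded on a microelectrode plate grow alone for 24 h, CAR T-cells are
added at an effector-to-target (E:T) ratio of 1:4, 1:8 or 1:20, and the
adherent cancer population is read out as Cell Index (CI, 1 CI ~ 10,000
cells) every 15 minutes for 6-8 days, in duplicate wells.  The non-adherent
CAR T-cells are only measured at treatment and at assay termination (flow
cytometry), so the generator keeps the full CAR T trajectory as hidden truth
for validating latent-variable reconstruction.

Observation noise is multiplicative Gaussian (impedance noise scales with
signal), independent per time point and replicate, floored at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import CoefficientMatrix, GrowthParameters, assemble_effective_rhs

__all__ = [
    "CI_CELLS",
    "AssayDesign",
    "AssayDataset",
    "IntegrationError",
    "ci_cells",
    "simulate_trajectories",
    "generate_assay",
    "control_well",
    "write_assay_csv",
    "read_assay_csv",
]

#: Cells per unit Cell Index.
CI_CELLS = 10_000.0

ET_RATIOS = {"1:4": 4.0, "1:8": 8.0, "1:20": 20.0}


def ci_cells(value: float, direction: Literal["to_cells", "to_ci"] = "to_cells"):
    """Convert between Cell Index and cell counts (1 CI = 10,000 cells)."""
    if direction == "to_cells":
        return value * CI_CELLS
    return value / CI_CELLS


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last time reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time {last_time:g} h)")
        self.last_time = last_time


@dataclass(frozen=True)
class AssayDesign:
    """Design of one simulated killing-assay condition.

    Defaults mirror the assay protocol: seeding at 10-20k cells (1-2 CI),
    treatment 24 h after seeding, a 7-day horizon sampled every 15 min, and
    duplicate wells.
    """

    seed_density: float = 1.0          # CI at seeding
    treatment_time: float = 24.0       # h
    horizon: float = 168.0             # h (6-8 days)
    dt: float = 0.25                   # h (15-min sampling)
    et_ratio: str = "1:4"
    n_replicates: int = 2
    noise_sd: float = 0.02             # relative multiplicative noise
    rng_seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.horizon <= self.treatment_time:
            raise ValueError("horizon must exceed treatment_time")
        if self.et_ratio not in ET_RATIOS:
            raise ValueError(f"unknown E:T ratio {self.et_ratio!r}")
        if not (1.0 <= self.seed_density <= 2.0):
            raise ValueError("seed_density outside the assay range [1, 2] CI")

    @property
    def et_divisor(self) -> float:
        return ET_RATIOS[self.et_ratio]

    def time_grid(self) -> np.ndarray:
        n = int(round(self.horizon / self.dt))
        return np.arange(n + 1) * self.dt


@dataclass
class AssayDataset:
    """One condition's simulated (or loaded) assay data.

    ``cancer`` holds the observed CI series per replicate; ``cancer_truth``
    and ``cart_truth`` the noise-free trajectories (synthetic data only —
    hidden from the discovery pipeline, used for validation).  CAR T-cells
    are observed only through ``cart_endpoints`` = (CI at treatment, CI at
    horizon) per replicate.
    """

    times: np.ndarray
    cancer: list[np.ndarray]
    cart_endpoints: list[tuple[float, float]]
    condition: str
    design: AssayDesign | None = None
    cancer_truth: np.ndarray | None = None
    cart_truth: np.ndarray | None = None
    treatment_index: int = 0

    @property
    def n_replicates(self) -> int:
        return len(self.cancer)

    def post_treatment(self) -> "AssayDataset":
        """View restricted to the treated part of the assay."""
        i = self.treatment_index
        return AssayDataset(
            times=self.times[i:],
            cancer=[c[i:] for c in self.cancer],
            cart_endpoints=self.cart_endpoints,
            condition=self.condition,
            design=self.design,
            cancer_truth=None if self.cancer_truth is None else self.cancer_truth[i:],
            cart_truth=None if self.cart_truth is None else self.cart_truth[i:],
            treatment_index=0,
        )


def _rhs(t, state, xi):
    x, y = state
    mono = np.array([x, y, x * x, x * y, y * y, x**3, x * x * y, x * y * y, y**3])
    return xi @ mono


def simulate_trajectories(
    xi: CoefficientMatrix | np.ndarray,
    x0: float,
    y0: float,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    blowup: float = 1e3,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the polynomial two-species ODE on ``t_grid``.

    States are not clipped: negative excursions are physical evidence
    against a candidate model and must survive to the stability report.
    Divergence beyond ``blowup`` CI or integrator failure raises
    :class:`IntegrationError` carrying the last valid time.
    """
    m = xi.xi if isinstance(xi, CoefficientMatrix) else np.asarray(xi, float)
    t_grid = np.asarray(t_grid, dtype=float)

    def too_big(t, s, _m):
        return np.max(np.abs(s)) - blowup

    too_big.terminal = True

    sol = solve_ivp(
        _rhs,
        (t_grid[0], t_grid[-1]),
        [float(x0), float(y0)],
        t_eval=t_grid,
        args=(m,),
        rtol=rtol,
        atol=atol,
        events=too_big,
        dense_output=False,
    )
    if not sol.success or sol.y.shape[1] != t_grid.size:
        last = sol.t[-1] if sol.t.size else t_grid[0]
        raise IntegrationError("trajectory integration failed or diverged", last)
    return sol.y[0], sol.y[1]


def generate_assay(
    design: AssayDesign, xi: CoefficientMatrix | np.ndarray
) -> AssayDataset:
    """Simulate one condition of the killing assay under model ``xi``.

    The cancer population grows alone from seeding until
    ``design.treatment_time`` (the CAR T state is zero, so interaction terms
    vanish), CAR T-cells are then added at ``x(t_treat) / E:T`` and the
    coupled system runs to the horizon.  Observations multiply the truth by
    ``1 + eps`` with ``eps ~ N(0, noise_sd)``, independently per point and
    replicate (distinct substreams of the master seed), floored at 0.
    """
    t = design.time_grid()
    i_treat = int(round(design.treatment_time / design.dt))

    x_pre, _ = simulate_trajectories(xi, design.seed_density, 0.0, t[: i_treat + 1])
    y0 = x_pre[-1] / design.et_divisor
    x_post, y_post = simulate_trajectories(
        xi, x_pre[-1], y0, t[i_treat:] - t[i_treat]
    )
    cancer_truth = np.concatenate([x_pre[:-1], x_post])
    cart_truth = np.concatenate([np.zeros(i_treat), y_post])

    rng = np.random.default_rng(design.rng_seed)
    substreams = rng.spawn(design.n_replicates)
    cancer_obs = []
    for sub in substreams:
        eps = sub.normal(0.0, design.noise_sd, size=cancer_truth.size)
        cancer_obs.append(np.maximum(cancer_truth * (1.0 + eps), 0.0))

    endpoints = [(float(y0), float(y_post[-1]))] * design.n_replicates
    return AssayDataset(
        times=t,
        cancer=cancer_obs,
        cart_endpoints=endpoints,
        condition=design.et_ratio,
        design=design,
        cancer_truth=cancer_truth,
        cart_truth=cart_truth,
        treatment_index=i_treat,
    )


def control_well(design: AssayDesign, gx: GrowthParameters) -> AssayDataset:
    """Simulate an untreated control well (cancer growth only)."""
    xi = assemble_effective_rhs(gx, GrowthParameters("none"))
    t = design.time_grid()
    x, _ = simulate_trajectories(xi, design.seed_density, 0.0, t)
    rng = np.random.default_rng(design.rng_seed)
    obs = []
    for sub in rng.spawn(design.n_replicates):
        eps = sub.normal(0.0, design.noise_sd, size=x.size)
        obs.append(np.maximum(x * (1.0 + eps), 0.0))
    return AssayDataset(
        times=t,
        cancer=obs,
        cart_endpoints=[],
        condition=f"control-{design.et_ratio}",
        design=design,
        cancer_truth=x,
        cart_truth=None,
        treatment_index=int(round(design.treatment_time / design.dt)),
    )


# --- file I/O ----------------------------------------------------------


def write_assay_csv(dataset: AssayDataset, csv_path: str | Path) -> None:
    """Write long-format well data plus a sidecar JSON of endpoints/design.

    Columns: condition, replicate, time_h, cancer_ci.  The sidecar
    ``<stem>.json`` stores CAR T endpoints, the treatment index and, when
    available, the generating design.
    """
    csv_path = Path(csv_path)
    frames = []
    for r, series in enumerate(dataset.cancer):
        frames.append(
            pd.DataFrame(
                {
                    "condition": dataset.condition,
                    "replicate": r,
                    "time_h": dataset.times,
                    "cancer_ci": series,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    sidecar = {
        "condition": dataset.condition,
        "treatment_index": dataset.treatment_index,
        "cart_endpoints": [list(e) for e in dataset.cart_endpoints],
        "design": None if dataset.design is None else asdict(dataset.design),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_assay_csv(
    csv_path: str | Path, endpoints_path: str | Path | None = None
) -> AssayDataset:
    """Read a long-format well CSV (and sidecar JSON) back into a dataset."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    required = {"condition", "replicate", "time_h", "cancer_ci"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    condition = str(df["condition"].iloc[0])
    reps = sorted(df["replicate"].unique())
    times = np.sort(df[df["replicate"] == reps[0]]["time_h"].to_numpy())
    cancer = [
        df[df["replicate"] == r].sort_values("time_h")["cancer_ci"].to_numpy()
        for r in reps
    ]
    sidecar_path = (
        Path(endpoints_path) if endpoints_path else csv_path.with_suffix(".json")
    )
    endpoints: list[tuple[float, float]] = []
    treatment_index = 0
    design = None
    if sidecar_path.exists():
        doc = json.loads(sidecar_path.read_text())
        endpoints = [tuple(e) for e in doc.get("cart_endpoints", [])]
        treatment_index = int(doc.get("treatment_index", 0))
        if doc.get("design"):
            design = AssayDesign(**doc["design"])
    return AssayDataset(
        times=times,
        cancer=cancer,
        cart_endpoints=endpoints,
        condition=condition,
        design=design,
        treatment_index=treatment_index,
    )
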