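"""Forward simulation of coupled nucleation, growth and solution depletion.

A sealed (micro-batch) container starts at concentration C0.  Three
processes are integrated on a fixed time grid Δt:

* nucleation: the expected number of new crystals per unit time is
  I(C)·V, with I the classical-nucleation-theory rate law
  I(C) = A2·C·exp(−A3/ln(C/C_e)²);
* growth: every crystal's longest side grows at dL/dt = A1·(C − C_e),
  independent of its size;
* depletion: protein deposited into crystals leaves the solution,
  ΔC = −C_s · a·b·c · Σ_k ΔL_k³ / V, with (a, b, c) the fixed aspect
  ratios of the crystal habit and C_s the protein density of the lattice.

Depletion feeds back on both rates, which is what limits the final crystal
count and links the first crystal's head start to its final size.  In
deterministic mode the expected-nuclei integral ∫I·V dt spawns one crystal
each time it crosses the next integer — this reproduces whole-number
crystal counts.  In stochastic mode each step draws Poisson(I·V·Δt) nuclei,
reflecting that nucleation is genuinely a random process.

Because the growth law has no size dependence, all crystals share the same
growth increment each step; a crystal born when the cumulative growth was
G_b has length G(t) − G_b.  :func:`simulate` exploits this to run in O(1)
work per step regardless of crystal count, while :func:`step` is the plain
state-to-state transition on an explicit crystal list (useful for tests and
for custom loops); the two are algebraically identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import MG_PER_G, ML_PER_UM3, UL_PER_ML, UM_PER_MM
from .errors import CapExceededError, StepSizeError, ValidationError
from .estimate import KineticParameters

__all__ = [
    "CrystalHabit",
    "SimulationConfig",
    "SimulationState",
    "SimulationResult",
    "growth_rate",
    "nucleation_rate",
    "step",
    "simulate",
    "nucleation_curve",
]


@dataclass(frozen=True)
class CrystalHabit:
    """Fixed aspect ratios (a, b, c) of the crystal, longest side first.

    By convention a = 1 and the reported size L is the longest dimension,
    so the crystal volume is a·b·c·L³.
    """

    a: float = 1.0
    b: float = 0.84
    c: float = 0.77

    def __post_init__(self) -> None:
        if not (self.a == 1.0 and self.a >= self.b >= self.c > 0):
            raise ValidationError(
                f"habit must satisfy 1 = a >= b >= c > 0, got {(self.a, self.b, self.c)}"
            )

    @property
    def volume_factor(self) -> float:
        return self.a * self.b * self.c


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions and numerical settings for one container simulation.

    Parameters
    ----------
    conc0_mg_ml : float
        Initial protein concentration.
    volume_ml : float
        Container (solution) volume in ml; held constant during depletion.
    c_s_g_ml : float
        Protein density inside the crystal (from the Matthews coefficient;
        0.901 g/ml for the lysozyme reference form).
    dt_h : float
        Euler step, default 0.1 h.
    t_max_h : float
        Horizon; default 4380 h (six months, a typical observation span).
        The run stops early once the solution is depleted to solubility.
    mode : str
        "deterministic" (integer crossings of the expected-nuclei integral)
        or "stochastic" (Poisson draws per step).
    seed : int, optional
        Required in stochastic mode.
    habit : CrystalHabit
        Aspect ratios used in the mass balance.
    max_crystals : int
        Safety cap; exceeding it raises :class:`CapExceededError`.
    equil_rel_tol : float
        Relative supersaturation (C − C_e)/(C0 − C_e) below which the run
        terminates as equilibrated.
    record_every : int, optional
        Trajectory sampling stride in steps; default keeps ≤ about 2000 rows.
    """

    conc0_mg_ml: float
    volume_ml: float
    c_s_g_ml: float = 0.901
    dt_h: float = 0.1
    t_max_h: float = 4380.0
    mode: str = "deterministic"
    seed: int | None = None
    habit: CrystalHabit = field(default_factory=CrystalHabit)
    max_crystals: int = 100_000
    equil_rel_tol: float = 1e-6
    record_every: int | None = None

    def __post_init__(self) -> None:
        if not self.dt_h > 0:
            raise ValidationError(f"dt_h must be > 0, got {self.dt_h}")
        if not self.t_max_h > 0:
            raise ValidationError(f"t_max_h must be > 0, got {self.t_max_h}")
        if not self.volume_ml > 0:
            raise ValidationError(f"volume_ml must be > 0, got {self.volume_ml}")
        if self.conc0_mg_ml < 0:
            raise ValidationError(f"conc0_mg_ml must be >= 0, got {self.conc0_mg_ml}")
        if not self.c_s_g_ml > 0:
            raise ValidationError(f"c_s_g_ml must be > 0, got {self.c_s_g_ml}")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValidationError(f"mode must be deterministic|stochastic, got {self.mode}")
        if self.mode == "stochastic" and self.seed is None:
            raise ValidationError("stochastic mode requires an explicit seed")

    @classmethod
    def from_microliters(cls, conc0_mg_ml: float, volume_ul: float, **kwargs):
        return cls(conc0_mg_ml=conc0_mg_ml, volume_ml=volume_ul / UL_PER_ML, **kwargs)

    @property
    def depletion_coeff(self) -> float:
        """mg/ml of concentration removed per µm³ of longest-side cube volume."""
        return self.c_s_g_ml * MG_PER_G * self.habit.volume_factor * ML_PER_UM3 / self.volume_ml

    def to_dict(self) -> dict:
        return {
            "conc0_mg_ml": self.conc0_mg_ml,
            "volume_ml": self.volume_ml,
            "c_s_g_ml": self.c_s_g_ml,
            "dt_h": self.dt_h,
            "t_max_h": self.t_max_h,
            "mode": self.mode,
            "seed": self.seed,
            "habit_abc": [self.habit.a, self.habit.b, self.habit.c],
            "max_crystals": self.max_crystals,
        }


@dataclass
class SimulationState:
    """Instantaneous state: time, concentration and the crystal population."""

    t_h: float
    conc_mg_ml: float
    birth_times_h: list[float] = field(default_factory=list)
    lengths_um: list[float] = field(default_factory=list)
    expected_nuclei: float = 0.0

    @property
    def n_crystals(self) -> int:
        return len(self.birth_times_h)


@dataclass(frozen=True)
class SimulationResult:
    """Outcome of one container simulation."""

    birth_times_h: np.ndarray
    final_lengths_um: np.ndarray
    final_conc_mg_ml: float
    expected_nuclei: float
    trajectory: pd.DataFrame
    termination_reason: str
    config: SimulationConfig
    params: KineticParameters

    @property
    def n_crystals(self) -> int:
        return int(self.birth_times_h.size)

    @property
    def initiation_time_h(self) -> float | None:
        """Birth time of the first crystal, or None if none nucleated."""
        return float(self.birth_times_h[0]) if self.n_crystals else None

    @property
    def first_crystal_length_um(self) -> float | None:
        return float(self.final_lengths_um[0]) if self.n_crystals else None

    @property
    def first_crystal_length_mm(self) -> float | None:
        L = self.first_crystal_length_um
        return L / UM_PER_MM if L is not None else None

    def to_dict(self) -> dict:
        return {
            "n_crystals": self.n_crystals,
            "initiation_time_h": self.initiation_time_h,
            "first_crystal_length_um": self.first_crystal_length_um,
            "final_conc_mg_ml": self.final_conc_mg_ml,
            "expected_nuclei": self.expected_nuclei,
            "termination_reason": self.termination_reason,
            "crystals": [
                {"birth_time_h": float(b), "final_length_um": float(L)}
                for b, L in zip(self.birth_times_h, self.final_lengths_um)
            ],
            "config": self.config.to_dict(),
            "params": self.params.to_dict(),
        }


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------


def growth_rate(conc_mg_ml: float, params: KineticParameters) -> float:
    """Linear growth law dL/dt = A1·(C − C_e) in µm/h, clamped at zero.

    The model has no dissolution branch: below solubility the rate is zero.
    """
    return params.a1 * max(0.0, conc_mg_ml - params.c_e)


def nucleation_rate(conc_mg_ml: float, params: KineticParameters) -> float:
    """Nucleation rate I(C) = A2·C·exp(−A3/ln(C/C_e)²) in ml⁻¹ h⁻¹.

    Defined as 0 for C ≤ C_e (also the limit from above: the exponential
    barrier diverges as C → C_e⁺).
    """
    if conc_mg_ml <= params.c_e:
        return 0.0
    lg = math.log(conc_mg_ml / params.c_e)
    if params.a3 == 0.0:
        return params.a2 * conc_mg_ml
    return params.a2 * conc_mg_ml * math.exp(-params.a3 / (lg * lg))


def nucleation_curve(
    params: KineticParameters, conc_grid: np.ndarray
) -> pd.DataFrame:
    """Tabulate the nucleation rate law over a concentration grid.

    Returns a DataFrame with columns ``conc_mg_ml`` and
    ``nucleation_rate_per_ml_h``; useful for locating the effective border
    between the metastable and nucleation zones of the phase diagram.
    """
    grid = np.asarray(conc_grid, dtype=float)
    if np.any(grid <= 0):
        raise ValidationError("concentration grid values must be > 0")
    rates = np.array([nucleation_rate(c, params) for c in grid])
    return pd.DataFrame(
        {"conc_mg_ml": grid, "nucleation_rate_per_ml_h": rates}
    )


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------


def step(
    state: SimulationState,
    config: SimulationConfig,
    params: KineticParameters,
    rng: np.random.Generator | None = None,
) -> SimulationState:
    """Advance the state by one Δt (reference implementation).

    Order within a step follows the model's update sequence: (i) accumulate
    expected nuclei I(C)·V·Δt and spawn crystals at length 0 (integer
    crossing in deterministic mode, Poisson draw in stochastic mode);
    (ii) grow every crystal by A1·(C − C_e)·Δt; (iii) remove the deposited
    protein from the solution.
    """
    dt = config.dt_h
    C = state.conc_mg_ml
    births = list(state.birth_times_h)
    lengths = list(state.lengths_um)
    acc = state.expected_nuclei

    inc = nucleation_rate(C, params) * config.volume_ml * dt
    if config.mode == "deterministic":
        new_acc = acc + inc
        while len(births) + 1 <= new_acc:
            # linear interpolation of the crossing time inside the step
            frac = (len(births) + 1 - acc) / inc if inc > 0 else 1.0
            births.append(state.t_h + frac * dt)
            lengths.append(0.0)
        acc = new_acc
    else:
        if rng is None:
            raise ValidationError("stochastic step requires an rng")
        n_new = int(rng.poisson(inc))
        acc += inc
        for _ in range(n_new):
            births.append(state.t_h + dt)
            lengths.append(0.0)
    if len(births) > config.max_crystals:
        raise CapExceededError(
            f"crystal count exceeded cap {config.max_crystals}; "
            "check parameters or raise max_crystals"
        )

    g = growth_rate(C, params) * dt
    dep_vol = 0.0  # µm³ of longest-side cube volume added this step
    for k in range(len(lengths)):
        new_L = lengths[k] + g
        dep_vol += new_L**3 - lengths[k] ** 3
        lengths[k] = new_L

    new_C = C - config.depletion_coeff * dep_vol
    if new_C < -1e-9 * max(config.conc0_mg_ml, 1.0):
        raise StepSizeError(
            f"concentration went negative ({new_C:.3g} mg/ml) at t={state.t_h:.3g} h; "
            "reduce dt_h"
        )
    return SimulationState(
        t_h=state.t_h + dt,
        conc_mg_ml=max(new_C, 0.0),
        birth_times_h=births,
        lengths_um=lengths,
        expected_nuclei=acc,
    )


def simulate(config: SimulationConfig, params: KineticParameters) -> SimulationResult:
    """Integrate one container from t = 0 to depletion or the horizon.

    Runs the same update as :func:`step` but with O(1) work per step: all
    crystals share the growth increment, so the population is carried as
    power sums of the cumulative growth at birth, from which ΣL and ΣL²
    (and hence the exact depletion increment 3gΣL² + 3g²ΣL + Zg³) follow.

    Terminates when the horizon is reached, when the supersaturation has
    collapsed below ``equil_rel_tol`` of its initial value ("equilibrated"),
    or immediately if C0 ≤ C_e ("subsaturated").
    """
    dt = config.dt_h
    V = config.volume_ml
    kdep = config.depletion_coeff
    c_e = params.c_e
    C0 = config.conc0_mg_ml
    rng = (
        np.random.default_rng(config.seed) if config.mode == "stochastic" else None
    )
    n_steps = int(math.ceil(config.t_max_h / dt))
    stride = config.record_every or max(1, n_steps // 2000)

    # population bookkeeping: G = cumulative growth since t=0;
    # per crystal only G at birth is stored (lengths are G - G_birth).
    G = 0.0
    Z = 0
    sum_gb = 0.0
    sum_gb2 = 0.0
    births: list[float] = []
    g_births: list[float] = []
    acc = 0.0
    C = C0
    t = 0.0
    supersat0 = max(C0 - c_e, 0.0)

    rows = [(0.0, C, 0)]
    reason = "horizon"
    if supersat0 == 0.0:
        reason = "subsaturated"
        n_steps = 0

    for i in range(n_steps):
        inc = nucleation_rate(C, params) * V * dt
        if config.mode == "deterministic":
            new_acc = acc + inc
            while Z + 1 <= new_acc:
                frac = (Z + 1 - acc) / inc if inc > 0 else 1.0
                births.append(t + frac * dt)
                g_births.append(G)
                Z += 1
                sum_gb += G
                sum_gb2 += G * G
            acc = new_acc
        else:
            n_new = int(rng.poisson(inc))
            acc += inc
            for _ in range(n_new):
                births.append(t + dt)
                g_births.append(G)
            Z += n_new
            sum_gb += n_new * G
            sum_gb2 += n_new * G * G
        if Z > config.max_crystals:
            raise CapExceededError(
                f"crystal count exceeded cap {config.max_crystals}"
            )

        g = growth_rate(C, params) * dt
        if Z and g:
            s1 = Z * G - sum_gb  # Σ L_k
            s2 = Z * G * G - 2.0 * G * sum_gb + sum_gb2  # Σ L_k²
            dep_vol = 3.0 * g * s2 + 3.0 * g * g * s1 + Z * g**3
            G += g
            new_C = C - kdep * dep_vol
            if new_C < -1e-9 * max(C0, 1.0):
                raise StepSizeError(
                    f"concentration went negative ({new_C:.3g} mg/ml) at "
                    f"t={t:.3g} h; reduce dt_h"
                )
            C = max(new_C, 0.0)
        t += dt

        if (i + 1) % stride == 0:
            rows.append((t, C, Z))
        if Z and (C - c_e) <= config.equil_rel_tol * supersat0:
            reason = "equilibrated"
            break

    if rows[-1][0] != t:
        rows.append((t, C, Z))

    lengths = np.array([G - gb for gb in g_births])
    traj = pd.DataFrame(rows, columns=["t_h", "conc_mg_ml", "n_crystals"])
    return SimulationResult(
        birth_times_h=np.array(births),
        final_lengths_um=lengths,
        final_conc_mg_ml=C,
        expected_nuclei=acc,
        trajectory=traj,
        termination_reason=reason,
        config=config,
        params=params,
    )
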