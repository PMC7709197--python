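"""Synthetic micro-batch observations with the structure the estimators assume.

The generator emulates the capillary experiment the fitting workflow was
designed for: several protein concentrations, a few small sealed containers
per concentration, periodic size measurements under a microscope.  Two
statistical assumptions of the estimators are baked in deliberately:

* nucleation in each container is a homogeneous Poisson process at rate
  I(C0)·V — concentration depletion is ignored at generation time, just as
  the straight-line cumulative-count fit ignores it;
* once a crystal nucleates its length grows linearly at A1·(C0 − C_e),
  and only the length measurement carries (Gaussian) noise.

Because the generating process matches the estimators' model exactly,
noiseless data must be recovered to machine precision and noisy data with
correctly calibrated standard errors; the test suite checks both.  A
depletion-aware stress mode can be built by feeding :func:`xtalplan.simulate.simulate`
trajectories instead — that is intentionally not the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .estimate import GrowthSeries, KineticParameters, NucleationEvents
from .simulate import growth_rate, nucleation_rate

__all__ = ["GeneratorSpec", "generate_growth_series", "generate_nucleation_events"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Design of a synthetic micro-batch campaign.

    Defaults mirror the benchmark capillary experiment: concentrations
    9/12/15 mg/ml (the linear growth region), 2 µl containers, two per
    concentration, observed every 24 h for six months, with 2 µm
    measurement noise on crystal length.
    """

    true_params: KineticParameters
    conc_levels_mg_ml: tuple[float, ...] = (9.0, 12.0, 15.0)
    container_volume_ml: float = 0.002
    n_containers: int = 2
    obs_interval_h: float = 24.0
    noise_sd_length_um: float = 2.0
    horizon_h: float = 4380.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_length_um < 0:
            raise ValidationError("noise_sd_length_um must be >= 0")
        if not self.container_volume_ml > 0:
            raise ValidationError("container_volume_ml must be > 0")
        if any(c <= self.true_params.c_e for c in self.conc_levels_mg_ml):
            raise ValidationError(
                "all concentration levels must exceed the solubility c_e"
            )
        if self.n_containers < 1 or self.obs_interval_h <= 0 or self.horizon_h <= 0:
            raise ValidationError("invalid design: containers/interval/horizon")


def generate_growth_series(spec: GeneratorSpec) -> list[GrowthSeries]:
    """Simulate growth time courses, one per container per concentration.

    Each container draws a nucleation onset from the exponential waiting
    time of the Poisson process with rate I(C0)·V, then reports noisy
    lengths L(t) = rate·(t − onset) + ε at every scheduled observation time
    after the onset (clipped at zero — a microscope cannot measure a
    negative length).  Containers whose onset falls beyond the horizon
    yield an empty series, as in a real six-month campaign.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[GrowthSeries] = []
    obs_times = np.arange(
        spec.obs_interval_h, spec.horizon_h + 1e-9, spec.obs_interval_h
    )
    for conc in spec.conc_levels_mg_ml:
        lam = nucleation_rate(conc, spec.true_params) * spec.container_volume_ml
        rate = growth_rate(conc, spec.true_params)
        for j in range(spec.n_containers):
            onset = rng.exponential(1.0 / lam) if lam > 0 else np.inf
            t_obs = obs_times[obs_times >= onset]
            lengths = rate * (t_obs - onset)
            if spec.noise_sd_length_um > 0 and t_obs.size:
                lengths = lengths + rng.normal(
                    0.0, spec.noise_sd_length_um, size=t_obs.size
                )
            lengths = np.clip(lengths, 0.0, None)
            out.append(
                GrowthSeries(
                    container_id=f"c{conc:g}_{j}",
                    conc0_mg_ml=conc,
                    times_h=t_obs,
                    lengths_um=lengths,
                )
            )
    return out


def generate_nucleation_events(spec: GeneratorSpec) -> list[NucleationEvents]:
    """Simulate nucleation onset tables, one per container per concentration.

    Events follow a homogeneous Poisson process at rate I(C0)·V over the
    horizon: the count is Poisson(I·V·T) and the times are sorted uniforms.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[NucleationEvents] = []
    for conc in spec.conc_levels_mg_ml:
        lam = nucleation_rate(conc, spec.true_params) * spec.container_volume_ml
        for _ in range(spec.n_containers):
            n = int(rng.poisson(lam * spec.horizon_h)) if lam > 0 else 0
            times = np.sort(rng.uniform(0.0, spec.horizon_h, size=n))
            out.append(
                NucleationEvents(
                    conc0_mg_ml=conc,
                    container_volume_ml=spec.container_volume_ml,
                    onset_times_h=times,
                )
            )
    return out
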