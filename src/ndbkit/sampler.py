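"""Langevin-dynamics sampling of chromosome structural ensembles.

Replaces the external MD engine at desk scale (chains of roughly 100-2,000
beads, i.e. 5-100 Mb at 50-kb resolution): whole-genome production runs
should go through the exported MD-engine inputs instead.

The integrator is the BAOAB splitting of underdamped Langevin dynamics in
reduced units (mass = 1, kT = temperature).  Equilibration is NOT detected
automatically; a fixed number of equilibration steps is discarded and a
simple autocorrelation diagnostic of the radius of gyration is reported so
the user can judge whether it was enough.

Randomness is one documented generator (numpy PCG64); replicas are seeded
by (seed, replica_index) stream splitting, so every replica is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .michrom_model import ChromosomeSystem, make_force_field
from .ndb_io import LoopEntry, StructureEnsemble, ensemble_from_arrays

__all__ = [
    "SamplerConfig",
    "SamplerDivergence",
    "run_langevin",
    "run_replicas",
    "concatenate_ensembles",
]


class SamplerDivergence(RuntimeError):
    """Energy blow-up (overstretch/overlap) during integration."""

    def __init__(self, step: int, message: str):
        self.step = step
        super().__init__(f"divergence at step {step}: {message}")


@dataclass
class SamplerConfig:
    n_steps: int = 100_000
    save_every: int = 200
    timestep: float = 0.01  # reduced time units
    friction: float = 0.1   # reduced inverse time
    temperature: float = 1.0
    seed: int = 0
    n_replicas: int = 1
    equilibration_steps: int = 0

    def validate(self) -> None:
        for name in ("n_steps", "save_every", "timestep", "friction",
                     "temperature", "n_replicas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.equilibration_steps < 0:
            raise ValueError("equilibration_steps must be >= 0")
        if self.save_every > self.n_steps:
            raise ValueError("save_every must not exceed n_steps")


def _autocorrelation_time(series: np.ndarray) -> float:
    """Integrated autocorrelation time (in samples) of a scalar series."""
    s = np.asarray(series, dtype=float)
    if len(s) < 4 or np.ptp(s) == 0:
        return float("nan")
    s = s - s.mean()
    acf = np.correlate(s, s, mode="full")[len(s) - 1 :]
    acf /= acf[0]
    tau = 1.0
    for rho in acf[1:]:
        if rho < 0.05:
            break
        tau += 2.0 * rho
    return float(tau)


def run_langevin(
    system: ChromosomeSystem,
    initial_positions: np.ndarray,
    config: SamplerConfig,
    rng: np.random.Generator | None = None,
    diagnostics: dict | None = None,
    progress: Callable[[int, dict], None] | None = None,
) -> StructureEnsemble:
    """Integrate Langevin dynamics and return the saved-frame ensemble.

    Frames are saved every ``save_every`` steps after
    ``equilibration_steps``, giving exactly
    floor((n_steps - equilibration_steps) / save_every) frames.  The run
    is deterministic given the seed.  A dict passed as ``diagnostics`` is
    filled with the radius-of-gyration series, its autocorrelation time
    (in saved frames) and the final per-step acceptance-free energy check.

    Raises :class:`SamplerDivergence` (with the step number) on FENE
    overstretch or non-finite forces.
    """
    config.validate()
    x = np.array(initial_positions, dtype=float)
    if x.shape != (system.n_beads, 3):
        raise ValueError(
            f"initial positions shape {x.shape} != ({system.n_beads}, 3)"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    field = make_force_field(system)
    dt = config.timestep
    kT = config.temperature
    c1 = float(np.exp(-config.friction * dt))
    c2 = float(np.sqrt((1.0 - c1 * c1) * kT))

    v = rng.normal(scale=np.sqrt(kT), size=x.shape)
    try:
        F = field(x)
    except ValueError as exc:
        raise SamplerDivergence(0, str(exc)) from exc

    frames: list[np.ndarray] = []
    rg_series: list[float] = []
    eq = config.equilibration_steps
    for step in range(1, config.n_steps + 1):
        v += 0.5 * dt * F
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.normal(size=x.shape)
        x += 0.5 * dt * v
        try:
            F = field(x)
        except ValueError as exc:
            raise SamplerDivergence(step, str(exc)) from exc
        if not np.all(np.isfinite(F)):
            raise SamplerDivergence(step, "non-finite forces")
        v += 0.5 * dt * F
        if step > eq and (step - eq) % config.save_every == 0:
            frames.append(x.copy())
            com = x.mean(axis=0)
            rg_series.append(float(np.sqrt(np.mean(np.sum((x - com) ** 2, axis=1)))))
            if progress is not None:
                progress(step, {"rg": rg_series[-1]})

    if not frames:
        raise ValueError(
            "no frames saved: n_steps - equilibration_steps < save_every"
        )
    ens = ensemble_from_arrays(
        frames,
        annotations=system.type_labels(),
        resolution=system.resolution,
        loops=[LoopEntry(lp.anchor_a, lp.anchor_b, lp.loop_class)
               for lp in system.dedup_loops()],
        title="ndbkit Langevin trajectory",
        is_time_series=True,
    )
    if diagnostics is not None:
        diagnostics["rg_series"] = np.asarray(rg_series)
        diagnostics["rg_autocorr_time_frames"] = _autocorrelation_time(
            np.asarray(rg_series)
        )
        diagnostics["n_frames"] = len(frames)
    return ens


def run_replicas(
    system: ChromosomeSystem,
    config: SamplerConfig,
    initial_positions: np.ndarray | None = None,
) -> list[StructureEnsemble]:
    """Run ``config.n_replicas`` independent trajectories.

    Replica k uses the generator seeded with (seed, k); starting
    coordinates default to a fresh confined random walk per replica.
    """
    from .michrom_model import confinement_radius_for, initial_conformation

    config.validate()
    out: list[StructureEnsemble] = []
    R = system.parameters.confinement_radius
    for k in range(config.n_replicas):
        rng = np.random.default_rng([config.seed, k])
        if initial_positions is None:
            x0 = initial_conformation(
                system.n_beads, R, seed=int(rng.integers(2**31))
            )
        else:
            x0 = np.array(initial_positions, dtype=float)
        out.append(run_langevin(system, x0, config, rng=rng))
    return out


def concatenate_ensembles(ensembles: list[StructureEnsemble]) -> StructureEnsemble:
    """Pool replica ensembles into one (frame counts add; not a time series)."""
    if not ensembles:
        raise ValueError("nothing to concatenate")
    base = ensembles[0]
    pooled = StructureEnsemble(
        header=base.header,
        records=base.records,
        models=[m for e in ensembles for m in e.models],
        loops=base.loops,
        is_time_series=False,
    )
    pooled.header.model_count = pooled.n_models
    pooled.sync()
    return pooled
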