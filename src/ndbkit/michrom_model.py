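"""MiChroM-style coarse-grained energy model for interphase chromosomes.

A chromosome is a bead-spring polymer at 50-kb resolution.  The potential
energy is a sum of five term classes:

1. **Connectivity** — FENE bonds (or a harmonic/Gaussian variant) plus a
   bounded soft-core repulsion between nearest neighbors.
2. **Confinement** — a half-harmonic repulsive spherical wall mimicking the
   nuclear envelope.
3. **Ideal chromosome** — a translationally invariant, data-driven term
   gamma(d) * f(r) depending only on the genomic separation d = |i - j|,
   modeling motor-driven activity along the fiber.
4. **Type-to-type** — couplings alpha(t_i, t_j) * f(r) between chromatin
   subcompartment types (A1, A2, B1, B2, B3, B4, plus a neutral NA type
   for centromeres), the driver of microphase separation, together with
   the non-nearest-neighbor excluded-volume core.
5. **Loops** — an attractive contact chi * f(r) between listed anchor
   pairs (CTCF/cohesin loops).

f(r) = (1 + tanh(mu (rc - r))) / 2 is the sigmoidal contact kernel: ~1 in
contact, 1/2 at r = rc, ~0 far away.  All quantities are in reduced units
(bead diameter sigma = 1, thermal energy kT = 1); default coefficients form
a generic profile and every one is overridable via config, so a published
calibrated parameter set can be dropped in verbatim.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .ndb_io import LoopEntry, to_gro

__all__ = [
    "TYPE_LABELS",
    "MiChroMParameters",
    "ChromosomeSystem",
    "contact_kernel",
    "contact_kernel_derivative",
    "ideal_gamma_value",
    "fene_energy",
    "steric_energy",
    "energy_bonded",
    "energy_confinement",
    "energy_ideal_chromosome",
    "energy_type_to_type",
    "energy_loops",
    "energy_breakdown",
    "total_energy",
    "forces",
    "make_force_field",
    "pair_coupling_matrix",
    "export_md_inputs",
    "parse_top",
    "initial_conformation",
    "confinement_radius_for",
]

#: canonical chromatin type alphabet; index 6 is the neutral (centromere/NA)
#: type with zero type-to-type coupling
TYPE_LABELS = ("A1", "A2", "B1", "B2", "B3", "B4", "NA")

# Generic default type-to-type couplings (reduced energy units, negative =
# attractive).  Homotypic couplings are slightly stronger than heterotypic,
# which is the qualitative structure that produces compartmentalization;
# magnitudes are placeholders for a user-supplied calibrated set.
_DEFAULT_ALPHA = np.array(
    [
        # A1      A2      B1      B2      B3      B4     NA
        [-0.268, -0.274, -0.228, -0.230, -0.225, -0.230, 0.0],  # A1
        [-0.274, -0.299, -0.244, -0.245, -0.240, -0.245, 0.0],  # A2
        [-0.228, -0.244, -0.282, -0.250, -0.245, -0.250, 0.0],  # B1
        [-0.230, -0.245, -0.250, -0.310, -0.255, -0.255, 0.0],  # B2
        [-0.225, -0.240, -0.245, -0.255, -0.266, -0.250, 0.0],  # B3
        [-0.230, -0.245, -0.250, -0.255, -0.250, -0.300, 0.0],  # B4
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],                    # NA
    ]
)


@dataclass
class MiChroMParameters:
    """All coefficients of the energy function, in reduced units."""

    # connectivity
    bond_style: str = "fene"  # "fene" | "harmonic"
    fene_k: float = 30.0       # energy / length^2
    fene_r0: float = 1.5       # maximum bond extension
    harmonic_k: float = 3.0    # Gaussian-chain variant; b^2 = 3 T / k
    # excluded volume (soft-capped WCA)
    steric_epsilon: float = 1.0
    steric_sigma: float = 1.0
    steric_ecut: float = 4.0   # energy at which the core switches to linear
    # nuclear confinement
    confinement_radius: float = 10.0
    confinement_k: float = 30.0  # energy / length^2, half-harmonic wall
    # type-to-type couplings (7x7 incl. neutral type, symmetric)
    type_matrix: np.ndarray = field(default_factory=lambda: _DEFAULT_ALPHA.copy())
    # ideal chromosome: gamma(d) = g1/log(d) + g2/d + g3/d^2
    ideal_gamma: tuple[float, float, float] = (-0.030, -0.351, -3.727)
    ideal_d_min: int = 3
    ideal_d_max: int = 500
    # loops
    loop_chi: float = -1.613
    # contact kernel
    contact_mu: float = 3.22   # inverse length, steepness
    contact_rc: float = 1.78   # kernel midpoint, f(rc) = 1/2

    def validate(self) -> None:
        a = np.asarray(self.type_matrix, dtype=float)
        if a.shape != (7, 7) or not np.allclose(a, a.T):
            raise ValueError("type_matrix must be a symmetric 7x7 array")
        if not np.all(np.isfinite(a)):
            raise ValueError("type_matrix must be finite")
        if self.fene_r0 <= self.steric_sigma:
            raise ValueError("fene_r0 must exceed steric_sigma")
        if self.ideal_d_min < 3:
            raise ValueError(
                "ideal_d_min must be >= 3; nearest and next-nearest "
                "neighbors are handled by connectivity/steric terms"
            )
        for name in (
            "fene_k", "fene_r0", "harmonic_k", "steric_sigma",
            "confinement_radius", "confinement_k", "contact_mu", "contact_rc",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- config I/O (key-value YAML) ----------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["type_matrix"] = np.asarray(self.type_matrix).tolist()
        d["ideal_gamma"] = list(self.ideal_gamma)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MiChroMParameters":
        d = dict(d)
        if "type_matrix" in d:
            d["type_matrix"] = np.asarray(d["type_matrix"], dtype=float)
        if "ideal_gamma" in d:
            d["ideal_gamma"] = tuple(d["ideal_gamma"])
        p = cls(**d)
        p.validate()
        return p

    def save(self, path: str | Path) -> Path:
        import yaml

        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "MiChroMParameters":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ChromosomeSystem:
    """A single chromatin chain: per-bead types, loop list, parameters."""

    bead_types: np.ndarray  # int indices into TYPE_LABELS
    loops: list[LoopEntry] = field(default_factory=list)
    resolution: int = 50_000
    parameters: MiChroMParameters = field(default_factory=MiChroMParameters)

    def __post_init__(self):
        self.bead_types = np.asarray(self.bead_types, dtype=int)
        self.parameters.validate()
        n = self.n_beads
        if np.any(self.bead_types < 0) or np.any(self.bead_types >= 7):
            raise ValueError("bead_types must index the 7-letter type alphabet")
        for lp in self.loops:
            for a in (lp.anchor_a, lp.anchor_b):
                if not (1 <= a <= n):
                    raise ValueError(f"loop anchor {a} outside 1..{n}")

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)

    def type_labels(self) -> list[str]:
        return [TYPE_LABELS[t] for t in self.bead_types]

    def dedup_loops(self) -> list[LoopEntry]:
        """Unique anchor pairs (order-insensitive); warns on duplicates."""
        seen: dict[tuple[int, int], LoopEntry] = {}
        for lp in self.loops:
            key = (min(lp.anchor_a, lp.anchor_b), max(lp.anchor_a, lp.anchor_b))
            if key in seen:
                warnings.warn(
                    f"duplicate loop entry {key} collapsed to one",
                    stacklevel=2,
                )
            else:
                seen[key] = lp
        return list(seen.values())


# ---------------------------------------------------------------------------
# elementary functional forms
# ---------------------------------------------------------------------------

def contact_kernel(r, mu: float, rc: float):
    """Sigmoidal contact weight f(r) = (1 + tanh(mu (rc - r))) / 2.

    Monotone non-increasing, ~1 at contact, exactly 1/2 at r = rc, ~0 at
    large r.  Negative distances are rejected.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    return 0.5 * (1.0 + np.tanh(mu * (rc - r)))


def contact_kernel_derivative(r, mu: float, rc: float):
    """df/dr of the contact kernel (non-positive everywhere)."""
    r = np.asarray(r, dtype=float)
    return -0.5 * mu / np.cosh(mu * (rc - r)) ** 2


def ideal_gamma_value(d, coeffs: Sequence[float]):
    """gamma(d) = g1/log(d) + g2/d + g3/d^2 for genomic separation d >= 3."""
    d = np.asarray(d, dtype=float)
    g1, g2, g3 = coeffs
    return g1 / np.log(d) + g2 / d + g3 / d**2


def fene_energy(r, k: float, r0: float):
    """FENE bond energy -k r0^2/2 * ln(1 - (r/r0)^2); diverges at r -> r0."""
    r = np.asarray(r, dtype=float)
    if np.any(r >= r0):
        raise ValueError(f"bond length {float(np.max(r)):.4f} >= r0={r0}")
    return -0.5 * k * r0**2 * np.log1p(-((r / r0) ** 2))


def _steric_rs(eps: float, sigma: float, ecut: float) -> float:
    # inner radius where the WCA energy reaches ecut
    q = (ecut - eps) / (4.0 * eps)
    x = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * q))
    return sigma * x ** (-1.0 / 6.0)


def steric_energy(r, eps: float, sigma: float, ecut: float = 4.0):
    """Soft-capped WCA repulsion.

    Standard WCA (purely repulsive 12-6, shifted, cut at 2^(1/6) sigma) for
    r above the inner radius r_s where it reaches ``ecut``; below r_s it
    continues linearly with the slope at r_s, so energy and force stay
    finite down to r = 0 and the chain cannot blow up numerically.
    """
    r = np.asarray(r, dtype=float)
    if eps == 0.0:
        return np.zeros_like(r)
    rcut = 2.0 ** (1.0 / 6.0) * sigma
    rs = _steric_rs(eps, sigma, ecut)
    r_safe = np.maximum(r, rs)
    x = (sigma / r_safe) ** 6
    wca = 4.0 * eps * (x * x - x) + eps
    slope = _steric_slope(eps, sigma, ecut)  # dU/dr at r_s, negative
    linear = ecut + slope * (r - rs)
    out = np.where(r < rs, linear, np.where(r < rcut, wca, 0.0))
    return out


def _steric_slope(eps: float, sigma: float, ecut: float) -> float:
    rs = _steric_rs(eps, sigma, ecut)
    x = (sigma / rs) ** 6
    return 24.0 * eps * (x - 2.0 * x * x) / rs  # dU/dr at r_s (negative)


def steric_force_mag(r, eps: float, sigma: float, ecut: float = 4.0):
    """-dU/dr of :func:`steric_energy` (non-negative, repulsive)."""
    r = np.asarray(r, dtype=float)
    if eps == 0.0:
        return np.zeros_like(r)
    rcut = 2.0 ** (1.0 / 6.0) * sigma
    rs = _steric_rs(eps, sigma, ecut)
    r_safe = np.maximum(r, rs)
    x = (sigma / r_safe) ** 6
    dwca = 24.0 * eps * (x - 2.0 * x * x) / r_safe  # dU/dr
    slope = _steric_slope(eps, sigma, ecut)
    du = np.where(r < rs, slope, np.where(r < rcut, dwca, 0.0))
    return -du


# ---------------------------------------------------------------------------
# energy terms
# ---------------------------------------------------------------------------

def _bond_lengths(x: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(x, axis=0), axis=1)


def energy_bonded(positions: np.ndarray, params: MiChroMParameters) -> float:
    """Chain connectivity: FENE (or harmonic) bonds + nearest-neighbor core.

    Raises on an overstretched FENE bond, naming the bond.
    """
    x = np.asarray(positions, dtype=float)
    if len(x) < 2:
        return 0.0
    r = _bond_lengths(x)
    if params.bond_style == "fene":
        over = np.nonzero(r >= params.fene_r0)[0]
        if over.size:
            i = int(over[0])
            raise ValueError(
                f"bond {i}-{i + 1} overstretched: r={r[i]:.4f} >= "
                f"r0={params.fene_r0}"
            )
        e_bond = float(np.sum(fene_energy(r, params.fene_k, params.fene_r0)))
    elif params.bond_style == "harmonic":
        e_bond = float(np.sum(0.5 * params.harmonic_k * r**2))
    else:
        raise ValueError(f"unknown bond_style {params.bond_style!r}")
    e_steric = float(
        np.sum(
            steric_energy(
                r, params.steric_epsilon, params.steric_sigma, params.steric_ecut
            )
        )
    )
    return e_bond + e_steric


def energy_confinement(positions: np.ndarray, params: MiChroMParameters) -> float:
    """Half-harmonic spherical wall: k (|r| - R)^2 outside radius R, 0 inside."""
    x = np.asarray(positions, dtype=float)
    d = np.linalg.norm(x, axis=1)
    over = np.maximum(d - params.confinement_radius, 0.0)
    return float(params.confinement_k * np.sum(over**2))


def _pair_distances(x: np.ndarray):
    n = len(x)
    iu, ju = np.triu_indices(n, k=2)
    d = x[ju] - x[iu]
    return iu, ju, np.linalg.norm(d, axis=1)


def energy_ideal_chromosome(
    positions: np.ndarray, params: MiChroMParameters
) -> float:
    """Translationally invariant term: sum gamma(|i-j|) f(r_ij).

    Runs over pairs with ideal_d_min <= |i-j| <= ideal_d_max; depends only
    on genomic separation, never on bead identity.
    """
    x = np.asarray(positions, dtype=float)
    iu, ju, r = _pair_distances(x)
    sep = ju - iu
    mask = (sep >= params.ideal_d_min) & (sep <= params.ideal_d_max)
    if not np.any(mask):
        return 0.0
    g = ideal_gamma_value(sep[mask], params.ideal_gamma)
    f = contact_kernel(r[mask], params.contact_mu, params.contact_rc)
    return float(np.sum(g * f))


def energy_type_to_type(
    positions: np.ndarray,
    bead_types: np.ndarray,
    params: MiChroMParameters,
) -> float:
    """Type couplings alpha(t_i, t_j) f(r) plus the non-bonded steric core.

    Runs over all pairs with |i-j| >= 2 (nearest neighbors belong to the
    connectivity term).
    """
    x = np.asarray(positions, dtype=float)
    t = np.asarray(bead_types, dtype=int)
    if np.any(t < 0) or np.any(t >= 7):
        raise ValueError("unknown bead type index")
    iu, ju, r = _pair_distances(x)
    alpha = np.asarray(params.type_matrix, dtype=float)[t[iu], t[ju]]
    f = contact_kernel(r, params.contact_mu, params.contact_rc)
    e_type = float(np.sum(alpha * f))
    e_steric = float(
        np.sum(
            steric_energy(
                r, params.steric_epsilon, params.steric_sigma, params.steric_ecut
            )
        )
    )
    return e_type + e_steric


def energy_loops(
    positions: np.ndarray,
    loops: Sequence[LoopEntry],
    params: MiChroMParameters,
) -> float:
    """Loop term: chi * f(r) over unique anchor pairs (1-based indices)."""
    x = np.asarray(positions, dtype=float)
    seen: set[tuple[int, int]] = set()
    total = 0.0
    for lp in loops:
        key = (min(lp.anchor_a, lp.anchor_b), max(lp.anchor_a, lp.anchor_b))
        if key in seen:
            warnings.warn(
                f"duplicate loop entry {key} collapsed to one", stacklevel=2
            )
            continue
        seen.add(key)
        r = float(np.linalg.norm(x[lp.anchor_a - 1] - x[lp.anchor_b - 1]))
        total += params.loop_chi * float(
            contact_kernel(r, params.contact_mu, params.contact_rc)
        )
    return total


def energy_breakdown(
    system: ChromosomeSystem, positions: np.ndarray
) -> dict[str, float]:
    p = system.parameters
    return {
        "bonded": energy_bonded(positions, p),
        "confinement": energy_confinement(positions, p),
        "ideal_chromosome": energy_ideal_chromosome(positions, p),
        "type_to_type": energy_type_to_type(positions, system.bead_types, p),
        "loops": energy_loops(positions, system.loops, p),
    }


def total_energy(system: ChromosomeSystem, positions: np.ndarray) -> float:
    return float(sum(energy_breakdown(system, positions).values()))


# ---------------------------------------------------------------------------
# forces (analytic gradient, used by the sampler)
# ---------------------------------------------------------------------------

def pair_coupling_matrix(system: ChromosomeSystem) -> np.ndarray:
    """(n, n) matrix of summed contact-kernel couplings for |i-j| >= 2.

    Entry (i, j) = alpha(t_i, t_j) + gamma(|i-j|) [if within the ideal
    window] + chi [if (i, j) is a loop anchor pair].  Zero on and near the
    diagonal.  All f(r)-coupled terms share this single matrix, which is
    what makes per-step force evaluation one kernel pass.
    """
    p = system.parameters
    t = system.bead_types
    n = len(t)
    alpha = np.asarray(p.type_matrix, dtype=float)
    C = alpha[t[:, None], t[None, :]].astype(float)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        g = ideal_gamma_value(np.maximum(sep, 3), p.ideal_gamma)
    C += np.where((sep >= p.ideal_d_min) & (sep <= p.ideal_d_max), g, 0.0)
    for lp in system.dedup_loops():
        a, b = lp.anchor_a - 1, lp.anchor_b - 1
        C[a, b] += p.loop_chi
        C[b, a] += p.loop_chi
    C[sep < 2] = 0.0
    return C


def make_force_field(system: ChromosomeSystem):
    """Build F(x) = -grad U(x) with all pair structure precomputed.

    Returns a closure suitable for calling once per integrator step; the
    coupling matrix (type + ideal + loop coefficients) and the
    non-bonded mask are computed once.
    """
    p = system.parameters
    n = system.n_beads
    coupling = pair_coupling_matrix(system)
    idx = np.arange(n)
    nb = (np.abs(idx[:, None] - idx[None, :]) >= 2).astype(float)

    def field_fn(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        F = np.zeros_like(x)

        # pairwise (|i-j| >= 2): coupling * f(r) + steric core
        if n >= 3:
            sq = np.sum(x * x, axis=1)
            r2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
            np.fill_diagonal(r2, 1.0)
            r = np.sqrt(np.maximum(r2, 1e-24))
            du = coupling * contact_kernel_derivative(
                r, p.contact_mu, p.contact_rc
            )
            du -= steric_force_mag(
                r, p.steric_epsilon, p.steric_sigma, p.steric_ecut
            )
            du *= nb
            # force on i = -sum_j dU/dr (x_i - x_j)/r; contract via matmul
            w = du / r
            F -= w.sum(axis=1)[:, None] * x - w @ x

        # bonds (FENE or harmonic) + nearest-neighbor steric
        if n >= 2:
            b = x[1:] - x[:-1]
            r = np.linalg.norm(b, axis=1)
            r_safe = np.maximum(r, 1e-12)
            if p.bond_style == "fene":
                over = np.nonzero(r >= p.fene_r0)[0]
                if over.size:
                    i = int(over[0])
                    raise ValueError(
                        f"bond {i}-{i + 1} overstretched: r={r[i]:.4f}"
                    )
                du = p.fene_k * r / (1.0 - (r / p.fene_r0) ** 2)
            else:
                du = p.harmonic_k * r
            du -= steric_force_mag(
                r, p.steric_epsilon, p.steric_sigma, p.steric_ecut
            )
            fb = (du / r_safe)[:, None] * b  # dU/dr along bond direction
            F[:-1] += fb
            F[1:] -= fb

        # confinement wall
        d = np.linalg.norm(x, axis=1)
        outside = d > p.confinement_radius
        if np.any(outside):
            d_safe = np.where(outside, d, 1.0)
            mag = 2.0 * p.confinement_k * (d - p.confinement_radius)
            F -= np.where(outside, mag / d_safe, 0.0)[:, None] * x
        return F

    return field_fn


def forces(system: ChromosomeSystem, positions: np.ndarray) -> np.ndarray:
    """-grad of the total energy (one-shot convenience wrapper)."""
    return make_force_field(system)(np.asarray(positions, dtype=float))


# ---------------------------------------------------------------------------
# initial conformations
# ---------------------------------------------------------------------------

def confinement_radius_for(
    n_beads: int, volume_fraction: float = 0.1, sigma: float = 1.0
) -> float:
    """Sphere radius giving the requested bead volume fraction."""
    return 0.5 * sigma * (n_beads / volume_fraction) ** (1.0 / 3.0)


def initial_conformation(
    n_beads: int,
    confinement_radius: float,
    seed: int,
    bond_length: float = 1.0,
) -> np.ndarray:
    """Confined random walk with fixed bond length, deterministic in seed.

    Steps are uniform on the sphere; a step that would leave the safe
    radius (R - bond_length) is resampled, falling back to a step toward
    the origin.  Raises if the chain cannot plausibly fit.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    phi = n_beads * (bond_length / 2.0) ** 3 / confinement_radius**3
    if phi > 0.5:
        raise ValueError(
            f"cannot fit {n_beads} beads in sphere R={confinement_radius}: "
            f"volume fraction {phi:.2f} > 0.5"
        )
    rng = np.random.default_rng(seed)
    x = np.zeros((n_beads, 3))
    # preferred limit keeps a wall margin; the relaxed one only requires
    # staying strictly inside the sphere (tiny confinement spheres)
    limits = (
        max(confinement_radius - bond_length, 0.7 * confinement_radius),
        0.98 * confinement_radius,
    )
    clearance = 0.8 * bond_length  # keep starts off the steep steric core
    for i in range(1, n_beads):
        best, best_sep = None, -1.0
        for limit in limits:
            for _ in range(60):
                step = rng.normal(size=3)
                step *= bond_length / np.linalg.norm(step)
                cand = x[i - 1] + step
                if np.linalg.norm(cand) >= limit:
                    cand = x[i - 1] - step
                    if np.linalg.norm(cand) >= limit:
                        continue
                sep = (
                    float(np.min(np.linalg.norm(x[: i - 1] - cand, axis=1)))
                    if i > 1 else np.inf
                )
                if sep > clearance:
                    best = cand
                    break
                if sep > best_sep:
                    best, best_sep = cand, sep
            if best is not None:
                break
        if best is None:  # sphere smaller than one bond: shrink the step
            step = rng.normal(size=3)
            step *= 0.45 * confinement_radius / np.linalg.norm(step)
            best = step
        x[i] = best
    return x


# ---------------------------------------------------------------------------
# MD-engine input export (tabulated potentials + coordinates + topology)
# ---------------------------------------------------------------------------

_TABLE_SPACING = 1e-3


def _write_xvg(path: Path, header: str, cols: Sequence[np.ndarray]) -> None:
    arr = np.column_stack(cols)
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        np.savetxt(fh, arr, fmt="%.10e")


def export_md_inputs(
    system: ChromosomeSystem,
    positions: np.ndarray,
    out_dir: str | Path,
    name: str = "chromosome",
) -> dict[str, Path]:
    """Write the five tabulated-potential files plus .gro/.top to a directory.

    Files and their columns (documented in each file's header):

    * ``table_b0.xvg`` — (r, U) chain connectivity: FENE + nearest-neighbor
      steric core; the grid stops just short of the FENE divergence.
    * ``table_b1.xvg`` — (d, U) spherical confinement vs distance from the
      nuclear center.
    * ``table_b2.xvg`` — (r, f) the contact kernel; per-separation gamma(d)
      coefficients live in the .top.
    * ``table.xvg`` — (r, U_steric, f) type-to-type interactions together
      with the non-nearest-neighbor steric core; per-pair alpha
      coefficients live in the .top's type matrix.
    * ``tablep.xvg`` — (r, f) stable loops; chi and anchors in the .top.

    The .gro carries the initial coordinates with compartment annotations
    encoded in the bead names; the .top carries topology (bonds), the type
    sequence, the full parameter set, the gamma coefficients and the loop
    list.  Beads outside the confinement radius trigger a warning.
    """
    p = system.parameters
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    x = np.asarray(positions, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("positions must be finite")
    if np.any(np.linalg.norm(x, axis=1) > p.confinement_radius):
        warnings.warn("some beads start outside the confinement sphere")

    files: dict[str, Path] = {}
    dr = _TABLE_SPACING

    # b0: bonded
    if p.bond_style == "fene":
        r = np.arange(0.0, p.fene_r0 * (1.0 - 1e-3), dr)
        u = fene_energy(r, p.fene_k, p.fene_r0)
    else:
        r = np.arange(0.0, 3.0 * p.fene_r0, dr)
        u = 0.5 * p.harmonic_k * r**2
    u = u + steric_energy(r, p.steric_epsilon, p.steric_sigma, p.steric_ecut)
    files["table_b0"] = out_dir / "table_b0.xvg"
    _write_xvg(
        files["table_b0"],
        "ndbkit table_b0: chain connectivity (FENE + nearest-neighbor steric)\n"
        f"columns: r  U(r); spacing {dr}",
        (r, u),
    )

    # b1: confinement
    d = np.arange(0.0, p.confinement_radius + 3.0, dr)
    u = p.confinement_k * np.maximum(d - p.confinement_radius, 0.0) ** 2
    files["table_b1"] = out_dir / "table_b1.xvg"
    _write_xvg(
        files["table_b1"],
        "ndbkit table_b1: spherical confinement\n"
        f"columns: d  U(d); wall radius {p.confinement_radius}; spacing {dr}",
        (d, u),
    )

    rmax = 3.0 * p.contact_rc
    r = np.arange(0.0, rmax, dr)
    f = contact_kernel(r, p.contact_mu, p.contact_rc)

    # b2: ideal chromosome basis
    files["table_b2"] = out_dir / "table_b2.xvg"
    _write_xvg(
        files["table_b2"],
        "ndbkit table_b2: ideal chromosome contact basis\n"
        "columns: r  f(r); multiply by gamma(d) from the .top; "
        f"spacing {dr}",
        (r, f),
    )

    # table: type-to-type + non-nearest steric
    u_st = steric_energy(r, p.steric_epsilon, p.steric_sigma, p.steric_ecut)
    files["table"] = out_dir / "table.xvg"
    _write_xvg(
        files["table"],
        "ndbkit table: type-to-type + non-nearest-neighbor steric\n"
        "columns: r  U_steric(r)  f(r); multiply f by alpha(t_i, t_j) "
        f"from the .top type matrix; spacing {dr}",
        (r, u_st, f),
    )

    # tablep: loops
    files["tablep"] = out_dir / "tablep.xvg"
    _write_xvg(
        files["tablep"],
        "ndbkit tablep: stable loop contact basis\n"
        f"columns: r  f(r); multiply by chi from the .top; spacing {dr}",
        (r, f),
    )

    # .gro
    from .ndb_io import ensemble_from_arrays

    labels = system.type_labels()
    ens = ensemble_from_arrays(
        [x], annotations=labels, resolution=system.resolution, title=name
    )
    files["gro"] = out_dir / f"{name}.gro"
    to_gro(ens, files["gro"], annotations=labels)

    # .top
    files["top"] = out_dir / f"{name}.top"
    lines = [
        "; ndbkit topology v1",
        "[ system ]",
        f"name {name}",
        f"n_beads {system.n_beads}",
        f"resolution {system.resolution}",
        "",
        "[ parameters ]",
    ]
    for key, val in p.to_dict().items():
        if key == "type_matrix":
            continue
        if key == "ideal_gamma":
            val = " ".join(str(v) for v in val)
        lines.append(f"{key} {val}")
    lines += ["", "[ type_labels ]", " ".join(TYPE_LABELS), "", "[ type_matrix ]"]
    for row in np.asarray(p.type_matrix, dtype=float):
        lines.append(" ".join(f"{v:.6f}" for v in row))
    lines += ["", "[ atoms ]"]
    for i, lab in enumerate(labels, start=1):
        lines.append(f"{i} {lab}")
    lines += ["", "[ bonds ]"]
    for i in range(1, system.n_beads):
        lines.append(f"{i} {i + 1} b0")
    lines += ["", "[ loops ]"]
    for lp in system.dedup_loops():
        lines.append(
            f"{lp.anchor_a} {lp.anchor_b} {p.loop_chi} {lp.loop_class}"
        )
    files["top"].write_text("\n".join(lines) + "\n")
    return files


def parse_top(path: str | Path) -> dict:
    """Parse the exported .top back into its components.

    Returns a dict with keys ``loops`` (list of LoopEntry), ``bead_types``
    (int array), ``parameters`` (dict of scalars), ``n_beads``.
    """
    section = None
    loops: list[LoopEntry] = []
    labels: list[str] = []
    params: dict[str, object] = {}
    matrix_rows: list[list[float]] = []
    meta: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").strip()
            continue
        toks = line.split()
        if section == "system":
            meta[toks[0]] = toks[1]
        elif section == "parameters":
            key, vals = toks[0], toks[1:]

            def _scalar(tok: str):
                try:
                    return int(tok)
                except ValueError:
                    try:
                        return float(tok)
                    except ValueError:
                        return tok

            params[key] = (
                _scalar(vals[0]) if len(vals) == 1
                else tuple(_scalar(v) for v in vals)
            )
        elif section == "type_matrix":
            matrix_rows.append([float(v) for v in toks])
        elif section == "atoms":
            labels.append(toks[1])
        elif section == "loops":
            loops.append(LoopEntry(int(toks[0]), int(toks[1]), toks[3]))
    label_to_idx = {lab: i for i, lab in enumerate(TYPE_LABELS)}
    return {
        "n_beads": int(meta.get("n_beads", len(labels))),
        "resolution": int(meta.get("resolution", 50_000)),
        "bead_types": np.array([label_to_idx[lab] for lab in labels], dtype=int),
        "type_matrix": np.asarray(matrix_rows, dtype=float) if matrix_rows else None,
        "parameters": params,
        "loops": loops,
    }
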