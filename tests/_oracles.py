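"""Independent brute-force / closed-form oracles used across the test suite.

Everything here is written as plain scalar loops and textbook formulas,
deliberately sharing no code with the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def kernel(r, mu, rc):
    return 0.5 * (1.0 + math.tanh(mu * (rc - r)))


def gamma_of(d, g):
    return g[0] / math.log(d) + g[1] / d + g[2] / d**2


def fene(r, k, r0):
    return -0.5 * k * r0 * r0 * math.log(1.0 - (r / r0) ** 2)


def steric(r, eps, sigma, ecut):
    """Scalar soft-capped WCA, rebuilt from its definition."""
    if eps == 0.0:
        return 0.0
    rcut = 2.0 ** (1.0 / 6.0) * sigma
    if r >= rcut:
        return 0.0
    q = (ecut - eps) / (4.0 * eps)
    xs = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * q))
    rs = sigma * xs ** (-1.0 / 6.0)
    if r >= rs:
        x = (sigma / r) ** 6
        return 4.0 * eps * (x * x - x) + eps
    x = (sigma / rs) ** 6
    slope = 24.0 * eps * (x - 2.0 * x * x) / rs
    return ecut + slope * (r - rs)


def dist(x, i, j):
    return math.sqrt(sum((x[i][k] - x[j][k]) ** 2 for k in range(3)))


def energy_bonded_bf(x, p):
    total = 0.0
    for i in range(len(x) - 1):
        r = dist(x, i, i + 1)
        if p.bond_style == "fene":
            total += fene(r, p.fene_k, p.fene_r0)
        else:
            total += 0.5 * p.harmonic_k * r * r
        total += steric(r, p.steric_epsilon, p.steric_sigma, p.steric_ecut)
    return total


def energy_confinement_bf(x, p):
    total = 0.0
    for row in x:
        d = math.sqrt(sum(v * v for v in row))
        if d > p.confinement_radius:
            total += p.confinement_k * (d - p.confinement_radius) ** 2
    return total


def energy_ideal_bf(x, p):
    total = 0.0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            d = j - i
            if p.ideal_d_min <= d <= p.ideal_d_max:
                total += gamma_of(d, p.ideal_gamma) * kernel(
                    dist(x, i, j), p.contact_mu, p.contact_rc
                )
    return total


def energy_type_bf(x, types, p):
    total = 0.0
    n = len(x)
    alpha = np.asarray(p.type_matrix, dtype=float)
    for i in range(n):
        for j in range(i + 2, n):
            r = dist(x, i, j)
            total += alpha[types[i], types[j]] * kernel(
                r, p.contact_mu, p.contact_rc
            )
            total += steric(
                r, p.steric_epsilon, p.steric_sigma, p.steric_ecut
            )
    return total


def energy_loops_bf(x, loops, p):
    seen = set()
    total = 0.0
    for lp in loops:
        key = (min(lp.anchor_a, lp.anchor_b), max(lp.anchor_a, lp.anchor_b))
        if key in seen:
            continue
        seen.add(key)
        r = dist(x, lp.anchor_a - 1, lp.anchor_b - 1)
        total += p.loop_chi * kernel(r, p.contact_mu, p.contact_rc)
    return total


def contact_map_bf(frames, rc):
    """O(F n^2) triple loop over frames and pairs (hard cutoff)."""
    n = len(frames[0])
    m = [[0.0] * n for _ in range(n)]
    for x in frames:
        for i in range(n):
            for j in range(n):
                if i != j and dist(x, i, j) <= rc:
                    m[i][j] += 1.0
    out = np.array(m) / len(frames)
    np.fill_diagonal(out, 1.0)
    return out


def pearson_bf(a, b):
    """Textbook Pearson correlation."""
    a, b = list(a), list(b)
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((ai - ma) * (bi - mb) for ai, bi in zip(a, b))
    va = sum((ai - ma) ** 2 for ai in a)
    vb = sum((bi - mb) ** 2 for bi in b)
    return cov / math.sqrt(va * vb)


def fene_dimer_bond_cdf(p, temperature=1.0, n_grid=20_000):
    """Boltzmann bond-length CDF for a FENE+steric dimer by quadrature.

    P(r) dr proportional to r^2 exp(-U(r)/T) on (0, r0).
    """
    r0 = p.fene_r0
    rs = np.linspace(1e-6, r0 * (1 - 1e-9), n_grid)
    u = np.array(
        [
            fene(r, p.fene_k, p.fene_r0)
            + steric(r, p.steric_epsilon, p.steric_sigma, p.steric_ecut)
            for r in rs
        ]
    )
    w = rs**2 * np.exp(-(u - u.min()) / temperature)
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(rs))])
    cdf /= cdf[-1]

    def cdf_fn(x):
        return np.interp(x, rs, cdf)

    return cdf_fn
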