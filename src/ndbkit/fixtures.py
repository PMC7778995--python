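"""Deterministic generators for every synthetic input the toolkit needs.

The headline numbers of chromosome-scale studies require experimental Hi-C
maps and ensembles of hundreds of thousands of structures; at desk scale
every pipeline stage is instead validated against planted-truth synthetic
inputs whose expected outputs are known in closed form or by brute force:

* toy chromosomes and block copolymers (microphase-separation mechanism),
* ideal-chain ensembles (Gaussian-statistics oracle),
* planted-block contact maps (compartment-eigenvector recovery oracle),
* constructed .bed tracks (exact bin-integral arithmetic),
* randomized valid ensembles (format round-trip property testing).

Every generator is a pure function of its arguments including the
mandatory seed, and bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .epigenome import AnnotationSequence, annotations_to_bead_types
from .hic_analysis import ContactMap
from .michrom_model import (
    TYPE_LABELS,
    ChromosomeSystem,
    MiChroMParameters,
    confinement_radius_for,
)
from .ndb_io import (
    COMPARTMENT_CODES,
    LoopEntry,
    NdbHeader,
    NdbRecord,
    StructureEnsemble,
    ensemble_from_arrays,
)

__all__ = [
    "make_homopolymer",
    "make_block_copolymer",
    "make_ideal_chain_ensemble",
    "make_block_contact_map",
    "make_bed_track",
    "make_annotated_chromosome",
    "make_random_ensemble",
]


def make_homopolymer(
    n_beads: int,
    seed: int,
    type_label: str = "NA",
    volume_fraction: float = 0.1,
) -> ChromosomeSystem:
    """Single-type chain with default parameters and density-set confinement."""
    params = MiChroMParameters()
    params.confinement_radius = confinement_radius_for(n_beads, volume_fraction)
    t = TYPE_LABELS.index(type_label)
    return ChromosomeSystem(
        bead_types=np.full(n_beads, t, dtype=int), parameters=params
    )


def make_block_copolymer(
    n_beads: int,
    block_length: int,
    types: Sequence[str] = ("A1", "B1"),
    seed: int = 0,
    homotypic: float = -0.4,
    heterotypic: float = -0.1,
    loops: Sequence[tuple[int, int]] = (),
    volume_fraction: float = 0.1,
) -> ChromosomeSystem:
    """Alternating-block two-type chain for the microphase-separation test.

    Blocks of ``block_length`` beads cycle through ``types``; if
    ``block_length`` does not divide ``n_beads`` the final block is simply
    shorter (remainder rule).  The type matrix restricted to the used
    types has homotypic coupling ``homotypic`` and heterotypic coupling
    ``heterotypic`` (reduced energy units; defaults give the 0.3 kT
    demixing contrast of the standard block-copolymer setup), and the
    ideal-chromosome term is switched off so the type term is the only
    sequence-dependent interaction.  Loop anchor pairs are 1-based bead
    indices.
    """
    for t in types:
        if t not in TYPE_LABELS:
            raise ValueError(f"unknown type label {t!r}")
    idx = [TYPE_LABELS.index(t) for t in types]
    bead_types = np.empty(n_beads, dtype=int)
    for i in range(n_beads):
        bead_types[i] = idx[(i // block_length) % len(idx)]
    alpha = np.zeros((7, 7))
    for a in idx:
        for b in idx:
            alpha[a, b] = homotypic if a == b else heterotypic
    params = MiChroMParameters(
        type_matrix=alpha,
        ideal_gamma=(0.0, 0.0, 0.0),
        confinement_radius=confinement_radius_for(n_beads, volume_fraction),
    )
    return ChromosomeSystem(
        bead_types=bead_types,
        loops=[LoopEntry(a, b, "COHESIN") for a, b in loops],
        parameters=params,
    )


def make_ideal_chain_ensemble(
    n_beads: int,
    n_frames: int,
    bond_b: float = 1.0,
    seed: int = 0,
) -> StructureEnsemble:
    """Gaussian-chain ensemble: frames of cumulative Gaussian steps.

    Step components are N(0, b^2/3) so each bond has mean-squared length
    b^2 and internal distances satisfy <R^2(s)> = s b^2 exactly in
    expectation — the closed-form oracle for ensemble statistics.
    """
    if n_beads < 1 or n_frames < 1 or bond_b <= 0:
        raise ValueError("n_beads, n_frames, bond_b must be positive")
    rng = np.random.default_rng(seed)
    steps = rng.normal(
        scale=bond_b / np.sqrt(3.0), size=(n_frames, n_beads - 1, 3)
    )
    frames = np.zeros((n_frames, n_beads, 3))
    frames[:, 1:, :] = np.cumsum(steps, axis=1)
    return ensemble_from_arrays(list(frames), title="ideal chain fixture")


def make_block_contact_map(
    n_loci: int,
    blocks: int,
    p_within: float = 0.9,
    p_between: float = 0.3,
    noise: float = 0.3,
    seed: int = 0,
    decay_exponent: float = 1.0,
) -> tuple[ContactMap, np.ndarray]:
    """Planted checkerboard (plaid) contact map + labels for scoring.

    Base entry (i, j) = p(block_i, block_j) * (1 + |i-j|)^(-decay), with
    multiplicative log-normal noise exp(noise * N(0,1)) applied
    symmetrically and values clipped to [0, 1]; the diagonal is the
    self-contact frequency 1.  Returns (map, labels) with labels +1/-1 for
    the alternating A/B block membership.
    """
    if not (0.0 <= p_between <= p_within <= 1.0):
        raise ValueError("need 0 <= p_between <= p_within <= 1")
    rng = np.random.default_rng(seed)
    block_of = (np.arange(n_loci) * blocks // n_loci) % 2
    labels = np.where(block_of == 0, 1, -1)
    same = labels[:, None] == labels[None, :]
    p = np.where(same, p_within, p_between)
    s = np.abs(np.subtract.outer(np.arange(n_loci), np.arange(n_loci)))
    base = p * (1.0 + s) ** (-decay_exponent)
    if noise > 0:
        z = rng.normal(size=(n_loci, n_loci))
        z = (z + z.T) / np.sqrt(2.0)
        base = base * np.exp(noise * z)
    m = np.clip(base, 0.0, 1.0)
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    cm = ContactMap(matrix=m, n_frames_used=0, chrom_label="synthetic")
    return cm, labels


def make_bed_track(
    intervals_spec: Sequence[tuple[int, int, float]],
    seed: int = 0,
    chrom: str = "chr1",
    mark_name: str = "synthetic",
) -> str:
    """Standards-conformant .bed content from (start, end, score) triples.

    Coordinates are 0-based half-open.  Overlapping intervals are allowed;
    their bin contributions add (the binning integral is linear).  The
    analytic bin integral of each interval is score * overlap / resolution,
    which consumer tests assert exactly.
    """
    lines = []
    for k, (start, end, score) in enumerate(intervals_spec):
        if end <= start or start < 0:
            raise ValueError(f"invalid interval [{start}, {end})")
        lines.append(f"{chrom}\t{start}\t{end}\t{mark_name}_{k}\t{score}")
    return "\n".join(lines) + ("\n" if lines else "")


def make_annotated_chromosome(
    n_beads: int,
    seed: int,
    mean_block: int = 10,
    na_fraction: float = 0.05,
) -> tuple[AnnotationSequence, ChromosomeSystem]:
    """Random blocky annotation sequence + matching chromosome system.

    Labels are drawn per block (geometric block lengths, mean
    ``mean_block``) from the six subcompartment codes, with a centromere-like
    NA stretch of ``na_fraction * n_beads`` in the middle.
    """
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    while len(labels) < n_beads:
        blk = 1 + rng.geometric(1.0 / mean_block)
        labels += [str(rng.choice(COMPARTMENT_CODES))] * blk
    labels = labels[:n_beads]
    n_na = int(na_fraction * n_beads)
    if n_na:
        mid = n_beads // 2
        for i in range(mid, min(mid + n_na, n_beads)):
            labels[i] = "NA"
    ann = AnnotationSequence(chrom_label="chrS", labels=labels)
    params = MiChroMParameters(
        confinement_radius=confinement_radius_for(n_beads)
    )
    system = ChromosomeSystem(
        bead_types=annotations_to_bead_types(ann), parameters=params
    )
    return ann, system


def make_random_ensemble(
    seed: int,
    n_beads: int | None = None,
    n_models: int | None = None,
    with_dnaele: bool | None = None,
    with_loops: bool | None = None,
    two_chains: bool | None = None,
) -> StructureEnsemble:
    """Randomized *valid* ensemble for format round-trip property tests.

    Randomizes sizes, maternal/paternal chain split, an optional unbound
    DNAELE element, loops, spreads and header metadata; coordinates are
    quantized to the text format's milli-unit grid so text round trips
    are exact.  Every choice is drawn from the seeded generator.
    """
    rng = np.random.default_rng(seed)
    if n_beads is None:
        n_beads = int(rng.integers(3, 25))
    if n_models is None:
        n_models = int(rng.integers(1, 5))
    if with_dnaele is None:
        with_dnaele = bool(rng.integers(0, 2))
    if with_loops is None:
        with_loops = bool(rng.integers(0, 2)) and n_beads >= 4
    if two_chains is None:
        two_chains = bool(rng.integers(0, 2)) and n_beads >= 6

    res = 50_000
    records: list[NdbRecord] = []
    seq: dict[str, list[str]] = {}
    if two_chains:
        split = n_beads // 2
        chains = [("1M", range(0, split)), ("1P", range(split, n_beads))]
    else:
        chains = [("1M", range(0, n_beads))]
    idx = 0
    for cid, beads in chains:
        seq[cid] = []
        for w, i in enumerate(beads, start=1):
            idx += 1
            code = str(rng.choice(COMPARTMENT_CODES))
            seq[cid].append(code)
            records.append(
                NdbRecord(
                    element_type="CHROM",
                    element_index=idx,
                    epigenetic_code=code,
                    genetic_info="CTCF+" if rng.random() < 0.2 else "",
                    chain_id=cid,
                    within_chain_index=w,
                    genomic_start=(i % max(n_beads, 1)) * res + 1,
                    genomic_end=(i % max(n_beads, 1) + 1) * res,
                    spatial_spread=(
                        round(float(rng.uniform(0, 2)), 3)
                        if rng.random() < 0.3 else None
                    ),
                )
            )
    n_chrom = idx
    if with_dnaele:
        idx += 1
        bound = bool(rng.integers(0, 2))
        records.append(
            NdbRecord(
                element_type="DNAELE",
                element_index=idx,
                epigenetic_code=str(rng.choice(["TF", "CH"])),
                chain_id="E1",
                within_chain_index=1,
                genomic_start=100_001 if bound else None,
                genomic_end=100_200 if bound else None,
            )
        )
    n_total = len(records)
    models = [
        np.round(rng.uniform(-99, 99, size=(n_total, 3)), 3)
        for _ in range(n_models)
    ]
    loops: list[LoopEntry] = []
    if with_loops:
        n_loops = int(rng.integers(1, 3))
        for _ in range(n_loops):
            a, b = rng.choice(np.arange(1, n_chrom + 1), size=2, replace=False)
            loops.append(
                LoopEntry(int(a), int(b), str(rng.choice(["COHESIN", "POLYCOMB"])))
            )
    header = NdbHeader(
        title=f"random fixture {seed}",
        authors=["ndbkit fixture generator"],
        assembly="toy1",
        length_unit="sigma",
        compartment_sequence=seq,
        model_count=n_models,
    )
    ens = StructureEnsemble(
        header=header, records=records, models=models, loops=loops
    )
    ens.sync()
    return ens
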