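"""In-silico Hi-C validation stack for structural ensembles.

From an ensemble of 3D structures this module computes the observables
used to validate chromosome simulations against proximity-ligation
experiments: the locus x locus contact-frequency map, the contact
probability decay P(s) with genomic distance, the A/B compartment profile
(leading eigenvector of the Pearson correlation matrix of the
observed/expected map), distance-stratified map correlations, and
FISH-style pairwise distance distributions.

Contacts default to a hard distance cutoff (the in-silico analogue of a
ligation radius); a smooth kernel mode using the model's contact function
is available since the appropriate criterion is a modeling choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ndb_io import StructureEnsemble

__all__ = [
    "ContactMap",
    "CompartmentProfile",
    "contact_map",
    "ps_curve",
    "observed_over_expected",
    "pearson_correlation_matrix",
    "compartment_eigenvector",
    "compare_eigenvectors",
    "map_correlation_by_distance",
    "distance_distribution",
]


@dataclass
class ContactMap:
    """Symmetric locus x locus contact-frequency matrix."""

    matrix: np.ndarray
    resolution: int = 50_000
    chrom_label: str = ""
    n_frames_used: int = 0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact map must be square")
        if not np.all(np.isfinite(m)):
            raise ValueError("contact map entries must be finite")
        if not np.allclose(m, m.T):
            raise ValueError("contact map must be symmetric")
        if np.any(m < 0):
            raise ValueError("contact map entries must be non-negative")
        self.matrix = m

    @property
    def n_loci(self) -> int:
        return self.matrix.shape[0]


@dataclass
class CompartmentProfile:
    """Leading eigenvector of the Pearson matrix; NaN at masked loci."""

    eigenvector: np.ndarray
    sign_convention: str
    explained_share: float

    def __post_init__(self):
        self.eigenvector = np.asarray(self.eigenvector, dtype=float)

    def __len__(self) -> int:
        return len(self.eigenvector)


# ---------------------------------------------------------------------------

def contact_map(
    ensemble: StructureEnsemble,
    cutoff_rc: float = 1.78,
    mode: str = "hard",
    mu: float = 3.22,
) -> ContactMap:
    """Contact frequencies over the ensemble's frames.

    ``hard`` mode: entry (i, j) is the fraction of frames with
    r_ij <= cutoff_rc.  ``kernel`` mode: the mean of the sigmoidal contact
    weight (1 + tanh(mu (rc - r)))/2.  The diagonal is the self-contact
    frequency 1.
    """
    if ensemble.n_models < 1:
        raise ValueError("ensemble has no frames")
    if cutoff_rc <= 0:
        raise ValueError("cutoff_rc must be positive")
    n = ensemble.n_records
    acc = np.zeros((n, n))
    for xyz in ensemble.models:
        x = np.asarray(xyz, dtype=float)
        d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
        if mode == "hard":
            acc += d <= cutoff_rc
        elif mode == "kernel":
            acc += 0.5 * (1.0 + np.tanh(mu * (cutoff_rc - d)))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    m = acc / ensemble.n_models
    np.fill_diagonal(m, 1.0)
    m = 0.5 * (m + m.T)  # kill float asymmetry
    res = 50_000
    chrom = ""
    if ensemble.records:
        r0 = ensemble.records[0]
        chrom = r0.chain_id
        if r0.genomic_start is not None and r0.genomic_end is not None:
            res = r0.genomic_end - r0.genomic_start + 1
    return ContactMap(matrix=m, resolution=res, chrom_label=chrom,
                      n_frames_used=ensemble.n_models)


def ps_curve(cm: ContactMap | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean contact probability P(s) per genomic separation s = 1..n-1."""
    m = cm.matrix if isinstance(cm, ContactMap) else np.asarray(cm, dtype=float)
    n = m.shape[0]
    s = np.arange(1, n)
    p = np.array([np.mean(np.diagonal(m, offset=k)) for k in s])
    return s, p


def observed_over_expected(matrix: np.ndarray) -> np.ndarray:
    """Divide each diagonal by its mean (expected-at-distance normalization)."""
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    out = np.zeros_like(m)
    for k in range(n):
        diag = np.diagonal(m, offset=k)
        mean = diag.mean()
        vals = diag / mean if mean > 0 else np.zeros_like(diag)
        idx = np.arange(n - k)
        out[idx, idx + k] = vals
        out[idx + k, idx] = vals
    return out


def pearson_correlation_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pearson correlation of the observed/expected map's columns."""
    oe = observed_over_expected(matrix)
    sd = oe.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(
            "degenerate map: constant column(s) after observed/expected "
            "normalization"
        )
    return np.corrcoef(oe, rowvar=False)


def compartment_eigenvector(
    cm: ContactMap | np.ndarray,
    annotations: Sequence[str] | None = None,
) -> CompartmentProfile:
    """A/B compartment profile from a contact map.

    Pipeline: mask all-zero (centromeric) loci, observed/expected
    normalization by the per-diagonal mean, Pearson correlation matrix of
    the columns, leading eigenvector.  The eigenvector is unit-norm over
    unmasked loci and re-inserted with NaN at masked positions.

    The sign of an eigenvector is arbitrary; it is oriented so that (a)
    loci annotated A-class have positive mean when ``annotations`` are
    given, else (b) the largest-magnitude entry is positive.  The rule
    used is reported in ``sign_convention``.
    """
    m = cm.matrix if isinstance(cm, ContactMap) else np.asarray(cm, dtype=float)
    n = m.shape[0]
    off = m - np.diag(np.diagonal(m))
    keep = np.flatnonzero(off.sum(axis=0) > 0)
    if len(keep) < 3:
        raise ValueError("need >= 3 loci with nonzero off-diagonal rows")
    corr = pearson_correlation_matrix(m[np.ix_(keep, keep)])
    evals, evecs = np.linalg.eigh(corr)
    lead = evecs[:, -1]
    share = float(evals[-1] / np.sum(np.abs(evals)))

    if annotations is not None:
        ann = [annotations[i] for i in keep]
        a_mask = np.array([a.startswith("A") for a in ann])
        if a_mask.any() and float(lead[a_mask].mean()) < 0:
            lead = -lead
        convention = "A-class mean positive"
    else:
        if lead[np.argmax(np.abs(lead))] < 0:
            lead = -lead
        convention = "largest-magnitude entry positive"

    full = np.full(n, np.nan)
    full[keep] = lead / np.linalg.norm(lead)
    return CompartmentProfile(
        eigenvector=full, sign_convention=convention, explained_share=share
    )


def compare_eigenvectors(
    profile_a: CompartmentProfile | np.ndarray,
    profile_b: CompartmentProfile | np.ndarray,
) -> tuple[float, int]:
    """Pearson r between two compartment profiles over shared loci.

    Computed after optimal global sign alignment (signs are arbitrary);
    returns (r, sign) with sign in {+1, -1} the factor applied to the
    second profile.  Loci masked (NaN) in either profile are dropped;
    fewer than 3 shared loci is an error.
    """
    a = profile_a.eigenvector if isinstance(profile_a, CompartmentProfile) else np.asarray(profile_a, float)
    b = profile_b.eigenvector if isinstance(profile_b, CompartmentProfile) else np.asarray(profile_b, float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 shared unmasked loci")
    r = float(np.corrcoef(a[ok], b[ok])[0, 1])
    sign = 1 if r >= 0 else -1
    return abs(r) if sign < 0 else r, sign


def map_correlation_by_distance(
    map_a: ContactMap | np.ndarray,
    map_b: ContactMap | np.ndarray,
    max_s: int | None = None,
    transform: str = "raw",
    truncate: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between the s-th diagonals of two maps, for each s.

    ``transform`` applies to both maps first: ``raw``, ``log`` (log1p) or
    ``oe`` (observed/expected).  Maps of different size are an error
    unless ``truncate=True``, which crops both to the common upper-left
    block (the cross-chromosome null comparison).  A constant diagonal in
    either map makes r undefined at that s, reported as NaN.
    """
    a = map_a.matrix if isinstance(map_a, ContactMap) else np.asarray(map_a, float)
    b = map_b.matrix if isinstance(map_b, ContactMap) else np.asarray(map_b, float)
    if a.shape != b.shape:
        if not truncate:
            raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
        n = min(a.shape[0], b.shape[0])
        a, b = a[:n, :n], b[:n, :n]
    if transform == "log":
        a, b = np.log1p(a), np.log1p(b)
    elif transform == "oe":
        a, b = observed_over_expected(a), observed_over_expected(b)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    n = a.shape[0]
    smax = min(max_s if max_s is not None else n - 1, n - 1)
    s = np.arange(1, smax + 1)
    r = np.full(len(s), np.nan)
    for k, sk in enumerate(s):
        da, db = np.diagonal(a, offset=sk), np.diagonal(b, offset=sk)
        if len(da) < 2 or np.ptp(da) == 0 or np.ptp(db) == 0:
            continue  # undefined, stays NaN
        r[k] = float(np.corrcoef(da, db)[0, 1])
    return s, r


def distance_distribution(
    ensemble: StructureEnsemble,
    locus_i: int,
    locus_j: int,
    n_bins: int = 50,
) -> dict:
    """FISH-style distribution of the locus_i - locus_j distance.

    Loci are 0-based bead indices.  Returns the per-frame samples, a
    histogram, and summary statistics (mean, median, quartiles).
    """
    n = ensemble.n_records
    for k in (locus_i, locus_j):
        if not (0 <= k < n):
            raise ValueError(f"locus {k} outside 0..{n - 1}")
    if locus_i == locus_j:
        warnings.warn("identical loci: distance distribution is degenerate at 0")
    samples = np.array(
        [
            float(np.linalg.norm(np.asarray(m)[locus_i] - np.asarray(m)[locus_j]))
            for m in ensemble.models
        ]
    )
    counts, edges = np.histogram(samples, bins=n_bins)
    q25, q50, q75 = np.percentile(samples, [25, 50, 75])
    return {
        "samples": samples,
        "histogram": (counts, edges),
        "mean": float(samples.mean()),
        "median": float(q50),
        "q25": float(q25),
        "q75": float(q75),
        "n_frames": len(samples),
    }
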