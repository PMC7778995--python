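"""ChIP-seq track binning, subcompartment annotations and structure overlays.

Experimental ChIP-seq signal arrives as .bed intervals (0-based, half-open,
the genomics convention); physical simulations live on a 50-kb bead grid.
This module integrates interval signal onto that grid with proportional
length weighting — an interval contributes score x overlap_bp / resolution
to each bin it touches, so the genome-wide integral is conserved exactly
and the result is independent of how intervals happen to be split.

Subcompartment annotations use the six-letter alphabet A1, A2, B1, B2, B3,
B4 plus NA for centromeric/unannotatable loci.  The mapping from ChIP-seq
features to annotations is a pluggable predictor contract
(bins x marks -> labels); the shipped :class:`BaselineContrastPredictor`
is a transparent active-vs-repressive heuristic so the pipeline runs end
to end, NOT a reimplementation of any trained network, and user-supplied
annotation files bypass prediction entirely.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from .ndb_io import COMPARTMENT_CODES, NEUTRAL_CODE, StructureEnsemble

__all__ = [
    "CANONICAL_MARKS",
    "ACTIVE_MARKS",
    "REPRESSIVE_MARKS",
    "BinnedTrack",
    "AnnotationSequence",
    "read_bed",
    "bin_bed_signal",
    "collect_marks",
    "BaselineContrastPredictor",
    "predict_annotations",
    "annotations_to_bead_types",
    "bead_types_to_annotations",
    "TYPE_INDEX",
    "load_annotation_file",
    "write_annotation_file",
    "overlay_track",
]

#: the canonical 11 histone-modification tracks, in canonical column order
CANONICAL_MARKS = (
    "H2AFZ", "H3K27ac", "H3K27me3", "H3K36me3", "H3K4me1", "H3K4me2",
    "H3K4me3", "H3K79me2", "H3K9ac", "H3K9me3", "H4K20me1",
)

# partition used by the baseline predictor
ACTIVE_MARKS = frozenset(
    {"H2AFZ", "H3K27ac", "H3K36me3", "H3K4me1", "H3K4me2", "H3K4me3",
     "H3K79me2", "H3K9ac", "H4K20me1"}
)
REPRESSIVE_MARKS = frozenset({"H3K27me3", "H3K9me3"})

ANNOTATION_ALPHABET = COMPARTMENT_CODES + (NEUTRAL_CODE,)

#: bijective A1..B4 -> 0..5 mapping; NA is the dedicated neutral type 6
TYPE_INDEX = {label: i for i, label in enumerate(ANNOTATION_ALPHABET)}


@dataclass
class BinnedTrack:
    """Per-50-kb-locus scalar signal integrated from a .bed track."""

    mark_name: str
    chrom_label: str
    values: np.ndarray
    resolution: int = 50_000

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("binned values must be finite")
        if np.any(self.values < 0):
            raise ValueError("binned values must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass
class AnnotationSequence:
    """Ordered subcompartment labels, one per 50-kb locus."""

    chrom_label: str
    labels: list[str]
    resolution: int = 50_000

    def __post_init__(self):
        bad = [l for l in self.labels if l not in ANNOTATION_ALPHABET]
        if bad:
            raise ValueError(
                f"labels outside the annotation alphabet: {sorted(set(bad))}"
            )

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# .bed ingest and 50-kb binning
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a .bed signal file into (chrom, start, end, name, score).

    Coordinates stay 0-based half-open (the .bed standard); the binning
    step performs the coordinate arithmetic.  Files with only 4 columns
    are read as (chrom, start, end, score).
    """
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        toks = line.split("\t") if "\t" in line else line.split()
        if len(toks) < 4:
            raise ValueError(f"{path}:{lineno}: need >= 4 .bed columns")
        if len(toks) == 4:
            chrom, start, end, score = toks[0], toks[1], toks[2], toks[3]
            name = "."
        else:
            chrom, start, end, name, score = toks[:5]
        rows.append((chrom, int(start), int(end), name, float(score)))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score"]
    )


def bin_bed_signal(
    bed_intervals: Iterable[tuple[int, int, float]] | pd.DataFrame,
    chrom_length: int,
    resolution: int = 50_000,
    mark_name: str = "",
    chrom_label: str = "",
) -> BinnedTrack:
    """Integrate interval signal onto a fixed bin grid.

    Each interval (0-based half-open) contributes
    ``score * overlap_bp / resolution`` to every bin it overlaps, so the
    sum over bins equals the total length-weighted signal divided by the
    resolution.  Intervals extending beyond ``chrom_length`` are clipped
    with a warning; negative scores are an error.
    """
    if isinstance(bed_intervals, pd.DataFrame):
        it = bed_intervals[["start", "end", "score"]].itertuples(index=False)
    else:
        it = bed_intervals
    n_bins = math.ceil(chrom_length / resolution)
    values = np.zeros(n_bins)
    for start, end, score in it:
        if score < 0:
            raise ValueError(f"negative score {score} in interval [{start}, {end})")
        if end <= start:
            continue
        if end > chrom_length or start < 0:
            warnings.warn(
                f"interval [{start}, {end}) clipped to [0, {chrom_length})",
                stacklevel=2,
            )
            start, end = max(start, 0), min(end, chrom_length)
            if end <= start:
                continue
        b0 = start // resolution
        b1 = (end - 1) // resolution
        for b in range(b0, b1 + 1):
            lo = max(start, b * resolution)
            hi = min(end, (b + 1) * resolution)
            values[b] += score * (hi - lo) / resolution
    return BinnedTrack(
        mark_name=mark_name, chrom_label=chrom_label,
        values=values, resolution=resolution,
    )


def collect_marks(tracks: Sequence[BinnedTrack]) -> pd.DataFrame:
    """Assemble binned tracks into a bins x marks feature matrix.

    Columns follow the canonical 11-mark order (user-defined marks append
    alphabetically after them) regardless of input order.  Missing
    canonical marks are allowed and listed in ``df.attrs["missing_marks"]``
    so a subset of the data can still drive prediction.
    """
    if not tracks:
        raise ValueError("no tracks given")
    chrom = tracks[0].chrom_label
    res = tracks[0].resolution
    n = tracks[0].n_bins
    for t in tracks:
        if t.chrom_label != chrom:
            raise ValueError(f"mixed chromosomes: {t.chrom_label!r} vs {chrom!r}")
        if t.resolution != res:
            raise ValueError(f"mixed resolutions: {t.resolution} vs {res}")
        if t.n_bins != n:
            raise ValueError("tracks disagree in bin count")
    by_name = {t.mark_name: t for t in tracks}
    if len(by_name) != len(tracks):
        raise ValueError("duplicate mark names")
    ordered = [m for m in CANONICAL_MARKS if m in by_name]
    ordered += sorted(set(by_name) - set(CANONICAL_MARKS))
    df = pd.DataFrame({m: by_name[m].values for m in ordered})
    df.attrs["missing_marks"] = [m for m in CANONICAL_MARKS if m not in by_name]
    df.attrs["chrom_label"] = chrom
    df.attrs["resolution"] = res
    return df


# ---------------------------------------------------------------------------
# annotation prediction (pluggable contract)
# ---------------------------------------------------------------------------

class AnnotationPredictor(Protocol):
    def __call__(self, features: pd.DataFrame) -> Sequence[str]: ...


@dataclass
class BaselineContrastPredictor:
    """Transparent active-vs-repressive heuristic baseline.

    Per bin: let ``a`` be the summed signal of active marks present and
    ``r`` the summed signal of repressive marks present.  Bins with no
    signal at all get the default label (B3, the most common quiescent
    class); otherwise a > r maps to A1 and a <= r maps to B1.  This is a
    documented placeholder establishing the predictor contract, with no
    claim to the accuracy of a trained model.
    """

    default_label: str = "B3"
    active: frozenset = field(default_factory=lambda: ACTIVE_MARKS)
    repressive: frozenset = field(default_factory=lambda: REPRESSIVE_MARKS)

    def __call__(self, features: pd.DataFrame) -> list[str]:
        act_cols = [c for c in features.columns if c in self.active]
        rep_cols = [c for c in features.columns if c in self.repressive]
        a = features[act_cols].sum(axis=1).to_numpy() if act_cols else np.zeros(len(features))
        r = features[rep_cols].sum(axis=1).to_numpy() if rep_cols else np.zeros(len(features))
        total = features.sum(axis=1).to_numpy()
        out = np.where(a > r, "A1", "B1")
        out[total == 0] = self.default_label
        return list(out)


def predict_annotations(
    features: pd.DataFrame,
    predictor: AnnotationPredictor | None = None,
) -> AnnotationSequence:
    """Run a predictor over the feature matrix and validate its output.

    The predictor must return one label per bin, drawn from the annotation
    alphabet; anything else is an error.  Defaults to the baseline
    heuristic.
    """
    if predictor is None:
        predictor = BaselineContrastPredictor()
    labels = list(predictor(features))
    if len(labels) != len(features):
        raise ValueError(
            f"predictor returned {len(labels)} labels for {len(features)} bins"
        )
    return AnnotationSequence(
        chrom_label=features.attrs.get("chrom_label", ""),
        labels=labels,
        resolution=int(features.attrs.get("resolution", 50_000)),
    )


def annotations_to_bead_types(annotations: AnnotationSequence | Sequence[str]) -> np.ndarray:
    """Map labels to integer bead types: A1..B4 -> 0..5, NA -> 6."""
    labels = annotations.labels if isinstance(annotations, AnnotationSequence) else annotations
    try:
        return np.array([TYPE_INDEX[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown annotation label {exc.args[0]!r}") from None


def bead_types_to_annotations(types: Sequence[int]) -> list[str]:
    return [ANNOTATION_ALPHABET[t] for t in types]


def load_annotation_file(path: str | Path, chrom_label: str = "",
                         resolution: int = 50_000) -> AnnotationSequence:
    """Read one label per 50-kb line (the per-chromosome text layout)."""
    labels = [
        line.split()[-1]
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return AnnotationSequence(chrom_label=chrom_label, labels=labels,
                              resolution=resolution)


def write_annotation_file(ann: AnnotationSequence, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(ann.labels) + "\n")
    return path


# ---------------------------------------------------------------------------
# structure coloring overlays
# ---------------------------------------------------------------------------

_COMPARTMENT_COLORS = {
    # case-study convention: A orange, B green, centromere pink
    "A": (1.0, 0.55, 0.0),
    "B": (0.0, 0.6, 0.0),
    NEUTRAL_CODE: (1.0, 0.6, 0.75),
}


def overlay_track(
    ensemble: StructureEnsemble,
    binned_track: BinnedTrack | None = None,
    color_spec: str = "by-track",
    annotations: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bead scalar and RGB color for one of the three coloring modes.

    * ``by-index`` — monotone genomic-position gradient, head red to tail
      blue;
    * ``by-compartment`` — categorical: A-class orange, B-class green,
      NA pink (annotations default to the records' epigenetic codes);
    * ``by-track`` — continuous, intensity proportional to the integrated
      signal of ``binned_track`` (white at the track minimum to full blue
      at the maximum).

    Returns ``(scalars, colors)`` with shapes (n,) and (n, 3).
    """
    n = ensemble.n_records
    if color_spec == "by-index":
        s = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)
        red, blue = np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])
        colors = (1 - s)[:, None] * red + s[:, None] * blue
        return s, colors
    if color_spec == "by-compartment":
        if annotations is None:
            annotations = [r.epigenetic_code for r in ensemble.records]
        if len(annotations) != n:
            raise ValueError("annotation length != bead count")
        colors = np.empty((n, 3))
        s = np.empty(n)
        for i, lab in enumerate(annotations):
            key = lab[0] if lab and lab[0] in ("A", "B") else NEUTRAL_CODE
            colors[i] = _COMPARTMENT_COLORS[key]
            s[i] = {"A": 1.0, "B": -1.0}.get(key, 0.0)
        return s, colors
    if color_spec == "by-track":
        if binned_track is None:
            raise ValueError("by-track coloring needs a binned_track")
        if binned_track.n_bins != n:
            raise ValueError(
                f"track has {binned_track.n_bins} bins but ensemble has "
                f"{n} beads"
            )
        v = binned_track.values
        lo, hi = float(v.min()), float(v.max())
        s = np.zeros(n) if hi == lo else (v - lo) / (hi - lo)
        white, hue = np.array([1.0, 1.0, 1.0]), np.array([0.0, 0.0, 1.0])
        colors = (1 - s)[:, None] * white + s[:, None] * hue
        return s, colors
    raise ValueError(f"unknown color_spec {color_spec!r}")
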