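"""Reading, writing and interconversion of 3D genome structure formats.

The central text format (.ndb) is a PDB-inspired, human-readable layout for
chromatin structural ensembles: one twelve-field record per nuclear element
(a 50-kb chromatin bead, ``CHROM``, or any DNA-associated element,
``DNAELE``), a header carrying provenance and the per-chain compartment
sequence, ``MODEL``/``ENDMDL`` blocks for multi-frame ensembles, and a
trailing loop section listing stable loop anchors (cohesin- or
polycomb-mediated).

Sibling formats handled here:

* ``.spw`` — the spacewalk-style 6-column projection (element type, genomic
  start/end, x, y, z) of an .ndb file;
* ``.cndb`` — a lossless binary (HDF5) container, one coordinate array per
  frame plus one metadata table;
* ``.pdb`` — fixed-column export for molecular viewers, with an optional
  scalar track written into the B-factor column for coloring;
* ``.gro`` — MD-engine coordinate file whose residue/atom names encode the
  compartment annotation of each bead.

The exact column layout is documented in ``docs/ndb_format.md``; the parser
accepts both the fixed-width layout and a whitespace-delimited fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NdbHeader",
    "NdbRecord",
    "LoopEntry",
    "StructureEnsemble",
    "NdbParseError",
    "NdbValidationError",
    "read_ndb",
    "write_ndb",
    "to_spw",
    "from_spw",
    "to_cndb",
    "from_cndb",
    "to_pdb",
    "to_gro",
    "read_gro",
]

COMPARTMENT_CODES = ("A1", "A2", "B1", "B2", "B3", "B4")
NEUTRAL_CODE = "NA"  # centromere / unannotated

LOOP_CLASSES = ("COHESIN", "POLYCOMB", "UNKNOWN")

_COORD_DECIMALS = 3  # text formats quantize coordinates to milli-units


class NdbParseError(ValueError):
    """Malformed line in a structure file; carries the 1-based line number."""

    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


class NdbValidationError(ValueError):
    """An ensemble violates a structural invariant."""


@dataclass
class NdbHeader:
    title: str = ""
    authors: list[str] = field(default_factory=list)
    assembly: str = ""
    length_unit: str = "sigma"
    #: chain id -> ordered two-letter annotation codes, one per CHROM bead
    compartment_sequence: dict[str, list[str]] = field(default_factory=dict)
    model_count: int = 0


@dataclass
class NdbRecord:
    """One twelve-field row of an .ndb body.

    ``genomic_start``/``genomic_end`` are 1-based inclusive base-pair
    coordinates; ``None`` (a dash on disk) marks an unbound element.
    ``spatial_spread`` stores field 12 verbatim (the reported width of the
    locus' spatial distribution in optical experiments).
    """

    element_type: str  # CHROM | DNAELE (extensible)
    element_index: int
    epigenetic_code: str  # A1..B4 for CHROM; e.g. TF/CH for DNAELE
    genetic_info: str = ""  # e.g. CTCF motif + orientation
    chain_id: str = "1"
    within_chain_index: int = 1
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    genomic_start: int | None = None
    genomic_end: int | None = None
    spatial_spread: float | None = None


@dataclass(frozen=True)
class LoopEntry:
    anchor_a: int  # element_index of first anchor
    anchor_b: int
    loop_class: str = "UNKNOWN"


@dataclass
class StructureEnsemble:
    """Ordered set of coordinate frames over one static set of records.

    ``records`` carries the per-element metadata shared by every frame; its
    x/y/z mirror ``models[0]``.  ``models`` is a list of (n_records, 3)
    float arrays.  ``is_time_series`` distinguishes an MD trajectory from a
    bag of independently determined models.
    """

    header: NdbHeader
    records: list[NdbRecord]
    models: list[np.ndarray]
    loops: list[LoopEntry] = field(default_factory=list)
    is_time_series: bool = False

    # -- basic API -----------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def coordinates(self, model: int = 0) -> np.ndarray:
        return self.models[model]

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def chrom_records(self) -> list[NdbRecord]:
        return [r for r in self.records if r.element_type == "CHROM"]

    def sync(self) -> "StructureEnsemble":
        """Mirror models[0] into the record x/y/z and refresh model_count."""
        if self.models:
            xyz = np.asarray(self.models[0], dtype=float)
            for r, row in zip(self.records, xyz):
                r.x, r.y, r.z = float(row[0]), float(row[1]), float(row[2])
        self.header.model_count = len(self.models)
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureEnsemble):
            return NotImplemented
        if self.header != other.header or self.loops != other.loops:
            return False
        if self.is_time_series != other.is_time_series:
            return False
        if len(self.records) != len(other.records):
            return False
        if any(a != b for a, b in zip(self.records, other.records)):
            return False
        if len(self.models) != len(other.models):
            return False
        return all(
            a.shape == b.shape and np.array_equal(a, b)
            for a, b in zip(self.models, other.models)
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_ensemble(ens: StructureEnsemble) -> None:
    """Raise :class:`NdbValidationError` on any invariant violation."""
    if not ens.models:
        raise NdbValidationError("ensemble has no models")
    if not ens.records:
        raise NdbValidationError("ensemble has no records")
    if not ens.header.length_unit:
        raise NdbValidationError("header length_unit must be non-empty")
    n = len(ens.records)
    for k, m in enumerate(ens.models):
        arr = np.asarray(m)
        if arr.shape != (n, 3):
            raise NdbValidationError(
                f"model {k} has shape {arr.shape}, expected ({n}, 3)"
            )
        if not np.all(np.isfinite(arr)):
            raise NdbValidationError(f"model {k} contains non-finite coordinates")
    if ens.header.model_count != len(ens.models):
        raise NdbValidationError(
            f"header model_count={ens.header.model_count} but "
            f"{len(ens.models)} models stored"
        )

    by_chain: dict[str, list[NdbRecord]] = {}
    for r in ens.records:
        for fld in (r.element_type, r.epigenetic_code, r.chain_id):
            if not fld or any(c.isspace() for c in fld):
                raise NdbValidationError(
                    f"element {r.element_index}: empty or space-containing "
                    f"text field {fld!r}"
                )
        by_chain.setdefault(r.chain_id, []).append(r)
        if r.genomic_start is not None and r.genomic_end is not None:
            if r.genomic_end < r.genomic_start:
                raise NdbValidationError(
                    f"element {r.element_index}: genomic_end < genomic_start"
                )
        if r.spatial_spread is not None and r.spatial_spread < 0:
            raise NdbValidationError(
                f"element {r.element_index}: negative spatial_spread"
            )

    for cid, recs in by_chain.items():
        idx = [r.within_chain_index for r in recs]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise NdbValidationError(
                f"chain {cid}: within_chain_index not strictly increasing"
            )
        kinds = {r.element_type for r in recs}
        if "DNAELE" in kinds and len(recs) != 1:
            raise NdbValidationError(
                f"chain {cid}: a DNAELE chain must hold exactly one record"
            )

    for cid, seq in ens.header.compartment_sequence.items():
        n_chrom = sum(
            1 for r in by_chain.get(cid, []) if r.element_type == "CHROM"
        )
        if len(seq) != n_chrom:
            raise NdbValidationError(
                f"chain {cid}: compartment sequence length {len(seq)} != "
                f"{n_chrom} CHROM records"
            )

    chrom_idx = {r.element_index for r in ens.records if r.element_type == "CHROM"}
    for lp in ens.loops:
        if lp.anchor_a == lp.anchor_b:
            raise NdbValidationError(f"loop with identical anchors {lp.anchor_a}")
        for a in (lp.anchor_a, lp.anchor_b):
            if a not in chrom_idx:
                raise NdbValidationError(
                    f"loop anchor {a} does not reference a CHROM record"
                )


# ---------------------------------------------------------------------------
# .ndb text format
# ---------------------------------------------------------------------------
# Fixed-width record layout (0-based, end-exclusive slices); every field is
# separated from its neighbor by one space so the whitespace fallback sees
# exactly twelve tokens.
_SLICES = [
    (0, 6),     # element_type, left
    (7, 15),    # element_index, right
    (16, 18),   # epigenetic_code
    (19, 31),   # genetic_info, left ('-' if empty)
    (32, 38),   # chain_id, left
    (39, 47),   # within_chain_index, right
    (48, 56),   # x %8.3f
    (57, 65),   # y
    (66, 74),   # z
    (75, 85),   # genomic_start, right ('-' if absent)
    (86, 96),   # genomic_end
    (97, 105),  # spatial_spread %8.3f ('-' if absent)
]

_RECORD_KEYWORDS = ("CHROM", "DNAELE")


def _fmt_opt_int(v: int | None, width: int) -> str:
    return f"{'-' if v is None else v:>{width}}"


def _fmt_record(r: NdbRecord, xyz: Sequence[float]) -> str:
    spread = "-" if r.spatial_spread is None else f"{r.spatial_spread:.3f}"
    genetic = r.genetic_info if r.genetic_info else "-"
    fields = [
        f"{r.element_type:<6}",
        f"{r.element_index:>8}",
        f"{r.epigenetic_code:>2}",
        f"{genetic:<12}",
        f"{r.chain_id:<6}",
        f"{r.within_chain_index:>8}",
        f"{xyz[0]:8.3f}",
        f"{xyz[1]:8.3f}",
        f"{xyz[2]:8.3f}",
        _fmt_opt_int(r.genomic_start, 10),
        _fmt_opt_int(r.genomic_end, 10),
        f"{spread:>8}",
    ]
    return " ".join(fields)


def _parse_opt_int(tok: str, lineno: int, what: str) -> int | None:
    if tok == "-" or tok == "":
        return None
    try:
        return int(tok)
    except ValueError:
        raise NdbParseError(f"bad {what} {tok!r}", lineno) from None


def _parse_record(line: str, lineno: int) -> NdbRecord:
    raw = line.rstrip("\n")
    toks = raw.split()
    if len(toks) != 12 and len(raw) >= _SLICES[-1][0]:
        # fixed-width fallback: genetic_info containing spaces, etc.
        toks = [raw[a:b].strip() for a, b in _SLICES]
    if len(toks) != 12:
        raise NdbParseError(
            f"expected 12 fields, found {len(toks)}", lineno
        )
    try:
        return NdbRecord(
            element_type=toks[0],
            element_index=int(toks[1]),
            epigenetic_code=toks[2],
            genetic_info="" if toks[3] == "-" else toks[3],
            chain_id=toks[4],
            within_chain_index=int(toks[5]),
            x=float(toks[6]),
            y=float(toks[7]),
            z=float(toks[8]),
            genomic_start=_parse_opt_int(toks[9], lineno, "genomic_start"),
            genomic_end=_parse_opt_int(toks[10], lineno, "genomic_end"),
            spatial_spread=None if toks[11] == "-" else float(toks[11]),
        )
    except NdbParseError:
        raise
    except ValueError as exc:
        raise NdbParseError(str(exc), lineno) from None


def write_ndb(ens: StructureEnsemble, path: str | Path) -> Path:
    """Write an ensemble as .ndb text; validates first and refuses on error."""
    validate_ensemble(ens)
    path = Path(path)
    lines: list[str] = []
    h = ens.header
    if h.title:
        lines.append(f"TITLE     {h.title}")
    for a in h.authors:
        lines.append(f"AUTHOR    {a}")
    if h.assembly:
        lines.append(f"ASSEMBLY  {h.assembly}")
    lines.append(f"UNIT      {h.length_unit}")
    lines.append(f"NMODELS   {len(ens.models)}")
    if ens.is_time_series:
        lines.append("TIMESERIES yes")
    for cid, seq in h.compartment_sequence.items():
        for i in range(0, len(seq), 16):
            chunk = " ".join(seq[i : i + 16])
            lines.append(f"SEQCHR    {cid:<6} {i + 1:>6} {chunk}")
    for k, xyz in enumerate(ens.models, start=1):
        lines.append(f"MODEL  {k:>8}")
        for r, row in zip(ens.records, np.asarray(xyz, dtype=float)):
            lines.append(_fmt_record(r, row))
        lines.append("ENDMDL")
    for lp in ens.loops:
        lines.append(f"LOOP   {lp.anchor_a:>8} {lp.anchor_b:>8} {lp.loop_class}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_ndb(path: str | Path) -> StructureEnsemble:
    """Parse an .ndb file into a :class:`StructureEnsemble`.

    Raises :class:`NdbParseError` with the offending line number on
    malformed input, :class:`NdbValidationError` when models disagree in
    record count.
    """
    path = Path(path)
    header = NdbHeader()
    loops: list[LoopEntry] = []
    records: list[NdbRecord] = []
    models: list[list[list[float]]] = []
    current: list[list[float]] | None = None
    current_records: list[NdbRecord] = []
    first_model_done = False
    is_time_series = False
    seq_acc: dict[str, list[tuple[int, list[str]]]] = {}

    def close_model(lineno: int) -> None:
        nonlocal first_model_done, current, current_records
        if current is None:
            return
        if not first_model_done:
            records.extend(current_records)
            first_model_done = True
        elif len(current) != len(records):
            raise NdbValidationError(
                f"model {len(models) + 1} has {len(current)} records, "
                f"expected {len(records)}"
            )
        models.append(current)
        current = None
        current_records = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            key = line.split(None, 1)[0]
            rest = line[len(key):].strip() if len(line) > len(key) else ""
            if key == "TITLE":
                header.title = line[10:].rstrip() if len(line) > 10 else rest
            elif key == "AUTHOR":
                header.authors.append(rest)
            elif key == "ASSEMBLY":
                header.assembly = rest
            elif key == "UNIT":
                header.length_unit = rest
            elif key == "NMODELS":
                header.model_count = int(rest)
            elif key == "TIMESERIES":
                is_time_series = rest.lower() in ("yes", "true", "1")
            elif key == "SEQCHR":
                toks = rest.split()
                if len(toks) < 3:
                    raise NdbParseError("SEQCHR needs chain, offset, codes", lineno)
                seq_acc.setdefault(toks[0], []).append((int(toks[1]), toks[2:]))
            elif key == "MODEL":
                close_model(lineno)
                current = []
            elif key == "ENDMDL":
                close_model(lineno)
            elif key == "LOOP":
                toks = rest.split()
                if len(toks) < 2:
                    raise NdbParseError("LOOP needs two anchor indices", lineno)
                cls = toks[2] if len(toks) > 2 else "UNKNOWN"
                loops.append(LoopEntry(int(toks[0]), int(toks[1]), cls))
            elif key == "END":
                close_model(lineno)
            elif key in _RECORD_KEYWORDS or (
                line[:1] not in "#;" and len(line.split()) == 12
            ):
                rec = _parse_record(line, lineno)
                if current is None:  # headerless single-model file
                    current = []
                current.append([rec.x, rec.y, rec.z])
                if not first_model_done:
                    current_records.append(rec)
            else:
                raise NdbParseError(f"unrecognized line {line[:40]!r}", lineno)
    close_model(-1)

    for cid, chunks in seq_acc.items():
        chunks.sort(key=lambda c: c[0])
        header.compartment_sequence[cid] = [c for _, codes in chunks for c in codes]

    if not models:
        raise NdbParseError("file contains no coordinate models", None)
    ens = StructureEnsemble(
        header=header,
        records=records,
        models=[np.asarray(m, dtype=float) for m in models],
        loops=loops,
        is_time_series=is_time_series,
    )
    ens.header.model_count = len(ens.models)
    ens.sync()
    validate_ensemble(ens)
    return ens


# ---------------------------------------------------------------------------
# .spw — 6-column projection (fields 1, 10, 11, 7, 8, 9)
# ---------------------------------------------------------------------------

SPW_COLUMNS = ("element_type", "genomic_start", "genomic_end", "x", "y", "z")

# defaults used when re-inflating a .spw projection into a full ensemble
SPW_INFLATE_DEFAULTS = dict(
    epigenetic_code="UN", genetic_info="", chain_id="1", spatial_spread=None
)


def to_spw(ens: StructureEnsemble, path: str | Path) -> Path:
    """Project an ensemble onto the spacewalk-style 6-column text format.

    Each output row is exactly (element_type, genomic_start, genomic_end,
    x, y, z) of the corresponding .ndb record; one ``# model k`` block per
    frame.  CHROM records lacking genomic coordinates are an error.
    """
    validate_ensemble(ens)
    for r in ens.records:
        if r.element_type == "CHROM" and (
            r.genomic_start is None or r.genomic_end is None
        ):
            raise NdbValidationError(
                f"CHROM element {r.element_index} lacks genomic coordinates"
            )
    path = Path(path)
    lines = ["# spw v1", "# columns: " + "\t".join(SPW_COLUMNS)]
    for k, xyz in enumerate(ens.models, start=1):
        lines.append(f"# model {k}")
        for r, row in zip(ens.records, np.asarray(xyz, dtype=float)):
            gs = "-" if r.genomic_start is None else str(r.genomic_start)
            ge = "-" if r.genomic_end is None else str(r.genomic_end)
            lines.append(
                f"{r.element_type}\t{gs}\t{ge}\t"
                f"{row[0]:.3f}\t{row[1]:.3f}\t{row[2]:.3f}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def from_spw(path: str | Path) -> StructureEnsemble:
    """Re-inflate a .spw projection into a full ensemble.

    Fields absent from the projection take documented defaults: sequential
    element/within-chain indices, chain "1", epigenetic code "UN", empty
    genetic info, absent spread.
    """
    path = Path(path)
    models: list[list[list[float]]] = []
    records: list[NdbRecord] = []
    current: list[list[float]] | None = None
    first = True
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("# model"):
                if current is not None:
                    models.append(current)
                    first = False
                current = []
            continue
        toks = line.split("\t") if "\t" in line else line.split()
        if len(toks) != 6:
            raise NdbParseError(f"expected 6 columns, found {len(toks)}", lineno)
        if current is None:
            current = []
        x, y, z = (float(t) for t in toks[3:6])
        current.append([x, y, z])
        if first:
            i = len(records) + 1
            records.append(
                NdbRecord(
                    element_type=toks[0],
                    element_index=i,
                    within_chain_index=i,
                    x=x, y=y, z=z,
                    genomic_start=_parse_opt_int(toks[1], lineno, "genomic_start"),
                    genomic_end=_parse_opt_int(toks[2], lineno, "genomic_end"),
                    **SPW_INFLATE_DEFAULTS,
                )
            )
    if current is not None:
        models.append(current)
    if not models:
        raise NdbParseError("empty .spw file", None)
    ens = StructureEnsemble(
        header=NdbHeader(model_count=len(models)),
        records=records,
        models=[np.asarray(m, dtype=float) for m in models],
    )
    ens.sync()
    validate_ensemble(ens)
    return ens


# ---------------------------------------------------------------------------
# .cndb — binary (HDF5) container
# ---------------------------------------------------------------------------

def to_cndb(ens: StructureEnsemble, path: str | Path) -> Path:
    """Store an ensemble losslessly in the binary container.

    Layout: one float64 ``coordinates/<frame>`` dataset per frame, one
    ``records`` metadata group, loop table, header attributes.
    """
    import h5py

    validate_ensemble(ens)
    path = Path(path)
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "cndb"
        f.attrs["version"] = 1
        f.attrs["title"] = ens.header.title
        f.attrs["authors"] = json.dumps(ens.header.authors)
        f.attrs["assembly"] = ens.header.assembly
        f.attrs["length_unit"] = ens.header.length_unit
        f.attrs["is_time_series"] = bool(ens.is_time_series)
        f.attrs["compartment_sequence"] = json.dumps(
            ens.header.compartment_sequence
        )
        g = f.create_group("records")
        rs = ens.records
        g.create_dataset("element_type", data=[r.element_type for r in rs], dtype=str_dt)
        g.create_dataset("element_index", data=[r.element_index for r in rs], dtype="i8")
        g.create_dataset("epigenetic_code", data=[r.epigenetic_code for r in rs], dtype=str_dt)
        g.create_dataset("genetic_info", data=[r.genetic_info for r in rs], dtype=str_dt)
        g.create_dataset("chain_id", data=[r.chain_id for r in rs], dtype=str_dt)
        g.create_dataset("within_chain_index", data=[r.within_chain_index for r in rs], dtype="i8")
        g.create_dataset(
            "genomic_start",
            data=[-1 if r.genomic_start is None else r.genomic_start for r in rs],
            dtype="i8",
        )
        g.create_dataset(
            "genomic_end",
            data=[-1 if r.genomic_end is None else r.genomic_end for r in rs],
            dtype="i8",
        )
        g.create_dataset(
            "spatial_spread",
            data=[np.nan if r.spatial_spread is None else r.spatial_spread for r in rs],
            dtype="f8",
        )
        if ens.loops:
            f.create_dataset(
                "loops/anchors",
                data=[[lp.anchor_a, lp.anchor_b] for lp in ens.loops],
                dtype="i8",
            )
            f.create_dataset(
                "loops/classes",
                data=[lp.loop_class for lp in ens.loops],
                dtype=str_dt,
            )
        c = f.create_group("coordinates")
        for k, xyz in enumerate(ens.models):
            c.create_dataset(str(k), data=np.asarray(xyz, dtype=np.float64))
    return path


def from_cndb(path: str | Path) -> StructureEnsemble:
    import h5py

    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "cndb":
                raise NdbParseError(f"{path} is not a cndb container", None)
            header = NdbHeader(
                title=str(f.attrs["title"]),
                authors=json.loads(str(f.attrs["authors"])),
                assembly=str(f.attrs["assembly"]),
                length_unit=str(f.attrs["length_unit"]),
                compartment_sequence=json.loads(
                    str(f.attrs["compartment_sequence"])
                ),
            )
            g = f["records"]

            def s(name):
                return [v.decode() if isinstance(v, bytes) else str(v) for v in g[name][()]]

            et = s("element_type")
            n = len(et)
            gi = g["genomic_start"][()]
            ge = g["genomic_end"][()]
            sp = g["spatial_spread"][()]
            records = [
                NdbRecord(
                    element_type=et[i],
                    element_index=int(g["element_index"][i]),
                    epigenetic_code=s("epigenetic_code")[i],
                    genetic_info=s("genetic_info")[i],
                    chain_id=s("chain_id")[i],
                    within_chain_index=int(g["within_chain_index"][i]),
                    genomic_start=None if gi[i] < 0 else int(gi[i]),
                    genomic_end=None if ge[i] < 0 else int(ge[i]),
                    spatial_spread=None if np.isnan(sp[i]) else float(sp[i]),
                )
                for i in range(n)
            ]
            loops = []
            if "loops" in f:
                anchors = f["loops/anchors"][()]
                classes = [
                    v.decode() if isinstance(v, bytes) else str(v)
                    for v in f["loops/classes"][()]
                ]
                loops = [
                    LoopEntry(int(a), int(b), c)
                    for (a, b), c in zip(anchors, classes)
                ]
            c = f["coordinates"]
            models = [np.array(c[str(k)][()]) for k in range(len(c))]
            is_ts = bool(f.attrs.get("is_time_series", False))
    except OSError as exc:
        raise NdbParseError(f"corrupted or unreadable container: {exc}", None)
    ens = StructureEnsemble(
        header=header, records=records, models=models,
        loops=loops, is_time_series=is_ts,
    )
    ens.header.model_count = len(models)
    ens.sync()
    validate_ensemble(ens)
    return ens


# ---------------------------------------------------------------------------
# .pdb export (viewer compatibility)
# ---------------------------------------------------------------------------

def to_pdb(
    ens: StructureEnsemble,
    path: str | Path,
    scalar_track: Sequence[float] | None = None,
) -> Path:
    """Export as fixed-column PDB, one MODEL block per frame.

    ``scalar_track`` (one value per record) is rescaled linearly onto the
    B-factor column's printable range [0, 99.99] so viewers can color the
    polymer proportionally to an integrated signal.  Serial numbers wrap
    modulo 99999 (the PDB column limit), which is documented behavior.
    """
    validate_ensemble(ens)
    path = Path(path)
    beta = np.zeros(len(ens.records))
    if scalar_track is not None:
        track = np.asarray(scalar_track, dtype=float)
        if track.shape != (len(ens.records),):
            raise NdbValidationError(
                f"scalar_track length {track.shape} != record count"
            )
        lo, hi = float(track.min()), float(track.max())
        beta = (
            np.zeros_like(track)
            if hi == lo
            else (track - lo) / (hi - lo) * 99.99
        )
    chain_letters = {
        cid: "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"[i % 36]
        for i, cid in enumerate(ens.chain_ids())
    }
    lines: list[str] = []
    if ens.header.title:
        lines.append(f"TITLE     {ens.header.title}")
    for k, xyz in enumerate(ens.models, start=1):
        lines.append(f"MODEL     {k:>4}")
        for i, (r, row) in enumerate(zip(ens.records, np.asarray(xyz, dtype=float))):
            serial = i % 99999 + 1
            kind = "ATOM  " if r.element_type == "CHROM" else "HETATM"
            resname = (r.epigenetic_code or "UNK")[:3]
            resseq = r.within_chain_index % 10000
            lines.append(
                f"{kind}{serial:>5} {'CA':^4}{'':1}{resname:>3} "
                f"{chain_letters[r.chain_id]}{resseq:>4}{'':4}"
                f"{row[0]:8.3f}{row[1]:8.3f}{row[2]:8.3f}"
                f"{1.00:6.2f}{beta[i]:6.2f}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# .gro export (MD-engine coordinates + compartment annotations)
# ---------------------------------------------------------------------------

def to_gro(
    ens: StructureEnsemble,
    path: str | Path,
    annotations: Sequence[str] | None = None,
    box: float | None = None,
) -> Path:
    """Write the first model as a .gro coordinate file.

    Residue and atom names carry the compartment annotation (A1..B4 / NA)
    of each bead so the type sequence survives a round trip through the
    MD-engine input.  ``annotations`` defaults to each record's epigenetic
    code.
    """
    validate_ensemble(ens)
    path = Path(path)
    xyz = np.asarray(ens.models[0], dtype=float)
    if annotations is None:
        annotations = [r.epigenetic_code for r in ens.records]
    if len(annotations) != len(ens.records):
        raise NdbValidationError("annotations length != record count")
    if box is None:
        box = float(np.abs(xyz).max() * 2 + 2)
    lines = [ens.header.title or "ndbkit structure", f"{len(ens.records):>5}"]
    for i, (label, row) in enumerate(zip(annotations, xyz), start=1):
        resid = i % 100000
        lines.append(
            f"{resid:>5}{label:<5}{label:>5}{resid:>5}"
            f"{row[0]:8.3f}{row[1]:8.3f}{row[2]:8.3f}"
        )
    lines.append(f"{box:10.5f}{box:10.5f}{box:10.5f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gro(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Parse a .gro file back into (coordinates, per-bead annotation labels)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[1])
    xyz = np.empty((n, 3))
    labels: list[str] = []
    for i in range(n):
        line = lines[2 + i]
        labels.append(line[5:10].strip())
        xyz[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
    return xyz, labels


# ---------------------------------------------------------------------------
# convenience constructors
# ---------------------------------------------------------------------------

def ensemble_from_arrays(
    models: Iterable[np.ndarray],
    annotations: Sequence[str] | None = None,
    chain_id: str = "1",
    resolution: int = 50_000,
    loops: Iterable[LoopEntry] = (),
    title: str = "",
    length_unit: str = "sigma",
    is_time_series: bool = False,
) -> StructureEnsemble:
    """Build a single-chain CHROM ensemble from raw coordinate frames.

    Genomic coordinates are assigned contiguously at ``resolution`` bp per
    bead, 1-based inclusive.  Coordinates are quantized to the text
    format's milli-unit precision so the .ndb round trip is exact.
    """
    models = [
        np.round(np.asarray(m, dtype=float), _COORD_DECIMALS) for m in models
    ]
    if not models:
        raise NdbValidationError("need at least one model")
    n = models[0].shape[0]
    if annotations is None:
        annotations = [NEUTRAL_CODE] * n
    records = [
        NdbRecord(
            element_type="CHROM",
            element_index=i + 1,
            epigenetic_code=annotations[i],
            chain_id=chain_id,
            within_chain_index=i + 1,
            genomic_start=i * resolution + 1,
            genomic_end=(i + 1) * resolution,
        )
        for i in range(n)
    ]
    header = NdbHeader(
        title=title,
        length_unit=length_unit,
        compartment_sequence={chain_id: list(annotations)},
        model_count=len(models),
    )
    ens = StructureEnsemble(
        header=header,
        records=records,
        models=models,
        loops=list(loops),
        is_time_series=is_time_series,
    )
    ens.sync()
    return ens
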