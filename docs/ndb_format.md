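# Structure file formats (dialect v1)

This document is the normative reference for the text and binary layouts
written and read by `ndbkit.ndb_io`. The .ndb format follows the
structural-biology tradition of the PDB: fixed-width, human-readable,
header + body + connectivity records. Column positions below are this
package's dialect, versioned here; the parser additionally accepts any
whitespace-delimited file with the right token count per record.

## .ndb

### Header keywords

```
TITLE     <free text>
AUTHOR    <one author per line>
ASSEMBLY  <genome assembly label, e.g. hg38 or toy1>
UNIT      <length unit of the coordinates, e.g. sigma or um>   (required)
NMODELS   <number of coordinate models>
TIMESERIES yes|no          (present only for MD trajectories)
SEQCHR    <chain> <start-index> <up to 16 two-letter codes>
```

`SEQCHR` lines carry the per-chain compartment annotation sequence, one
code per CHROM bead, wrapped over multiple lines (like SEQRES).

### Body records — twelve fields

Each record is one line; fields are fixed-width, separated by single
spaces. 0-based column slices:

| # | cols | field | format | notes |
|---|------|-------|--------|-------|
| 1 | 0–6   | element type | left | `CHROM` (chromatin bead) or `DNAELE` (any other DNA-associated element); the vocabulary is extensible and unknown values are preserved verbatim |
| 2 | 7–15  | element index | right int | global, 1-based |
| 3 | 16–18 | epigenetic code | 2 chars | A1/A2/B1/B2/B3/B4 (or NA) for CHROM; e.g. TF, CH for DNAELE |
| 4 | 19–31 | genetic info | left | e.g. CTCF motif + orientation; `-` if empty |
| 5 | 32–38 | chain id | left | e.g. `1M` maternal / `1P` paternal copy of chromosome 1 |
| 6 | 39–47 | within-chain index | right int | strictly increasing along a chain |
| 7 | 48–56 | x | %8.3f | in header UNIT |
| 8 | 57–65 | y | %8.3f | |
| 9 | 66–74 | z | %8.3f | |
| 10 | 75–85 | genomic start | right int | base pairs, 1-based inclusive; `-` if unbound |
| 11 | 86–96 | genomic end | right int | `-` if unbound |
| 12 | 97–105 | spatial spread | %8.3f | width of the locus' spatial distribution in optical experiments; `-` if absent |

Missing values are a single dash. A DNAELE element forms its own chain
with exactly one record; a dash in fields 10–11 marks it unbound.
Coordinates are quantized to 3 decimals; a write→read→write cycle is
byte-identical.

Note on field 12: the source descriptions call this quantity both a
"width" and a "variance"; the value is stored and re-emitted verbatim
without interpretation.

### Models and loops

Each coordinate frame sits between `MODEL <k>` and `ENDMDL`. Record
metadata (fields 1–6, 10–12) is defined by the first model and must
repeat identically in count and order. After the last model:

```
LOOP   <anchor-a> <anchor-b> <class>
END
```

Anchors are element indices (field 2) of CHROM records; class is
`COHESIN`, `POLYCOMB` or `UNKNOWN`.

## .spw (spacewalk-style projection)

Tab-separated, exactly the .ndb fields 1, 10, 11, 7, 8, 9 in that order,
one `# model k` comment line per frame:

```
# spw v1
# columns: element_type	genomic_start	genomic_end	x	y	z
# model 1
CHROM	1	50000	0.000	0.000	0.000
```

Re-inflating a .spw into a full ensemble fills the non-projected fields
with documented defaults: sequential element and within-chain indices,
chain `1`, epigenetic code `UN`, empty genetic info, absent spread.

## .cndb (binary container)

An HDF5 file:

```
/            attrs: format="cndb", version=1, title, authors (JSON),
             assembly, length_unit, is_time_series,
             compartment_sequence (JSON)
/records/    one dataset per metadata field; genomic coords use -1,
             spread uses NaN for "absent"
/loops/      anchors (k,2) int64 + classes
/coordinates/<frame>   float64 (n,3), one dataset per frame
```

Storage is float64, hence lossless for arbitrary in-memory coordinates,
and individual frames can be read without loading the whole trajectory.

## .pdb export

Standard fixed-column ATOM/HETATM records, one MODEL/ENDMDL block per
frame, residue name = epigenetic code, chain id mapped to single
letters. An optional per-bead scalar track is rescaled linearly to
[0, 99.99] and written into the B-factor column for coloring. Serial
numbers wrap modulo 99999 (the PDB column limit).

## .gro / .top (MD-engine inputs)

`.gro`: title, atom count, then `resid resname atomname atomid x y z`
with both residue and atom names set to the bead's compartment label, so
the annotation sequence survives a round trip. `.top` is a sectioned
key-value file (`[ system ]`, `[ parameters ]`, `[ type_labels ]`,
`[ type_matrix ]`, `[ atoms ]`, `[ bonds ]`, `[ loops ]`) carrying the
topology, the full parameter set, and the loop list; `parse_top`
recovers all of it. The five tabulated potentials are `.xvg` files with
a comment header naming their columns (see `docs/methods.md`).
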