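"""Format fidelity: .ndb / .spw / .cndb / .pdb / .gro round trips and validation."""

import numpy as np
import pytest

from ndbkit import fixtures as fx
from ndbkit.ndb_io import (
    LoopEntry,
    NdbHeader,
    NdbParseError,
    NdbRecord,
    NdbValidationError,
    StructureEnsemble,
    ensemble_from_arrays,
    from_cndb,
    from_spw,
    read_gro,
    read_ndb,
    to_cndb,
    to_gro,
    to_pdb,
    to_spw,
    validate_ensemble,
    write_ndb,
)


@pytest.mark.parametrize("seed", range(20))
def test_ndb_round_trip_identity(seed, tmp_path):
    """read(write(e)) reproduces the in-memory ensemble exactly."""
    ens = fx.make_random_ensemble(seed)
    path = write_ndb(ens, tmp_path / "e.ndb")
    assert read_ndb(path) == ens


@pytest.mark.parametrize("seed", range(20))
def test_cndb_round_trip_identity(seed, tmp_path):
    ens = fx.make_random_ensemble(seed)
    path = to_cndb(ens, tmp_path / "e.cndb")
    assert from_cndb(path) == ens


def test_ndb_write_is_byte_stable(tmp_path):
    ens = fx.make_random_ensemble(7)
    p1 = write_ndb(ens, tmp_path / "a.ndb")
    p2 = write_ndb(read_ndb(p1), tmp_path / "b.ndb")
    assert p1.read_bytes() == p2.read_bytes()


def test_two_models_three_beads(tiny_ensemble, tmp_path):
    path = write_ndb(tiny_ensemble, tmp_path / "t.ndb")
    out = read_ndb(path)
    assert out.n_models == 2
    assert out.n_records == 3
    assert np.array_equal(out.models[1], tiny_ensemble.models[1])


def test_maternal_paternal_chains_are_distinct(tmp_path):
    ens = fx.make_random_ensemble(5, n_beads=10, two_chains=True,
                                  with_dnaele=False)
    out = read_ndb(write_ndb(ens, tmp_path / "mp.ndb"))
    assert out.chain_ids() == ["1M", "1P"]
    assert len(out.header.compartment_sequence["1M"]) == 5
    assert len(out.header.compartment_sequence["1P"]) == 5


def test_unbound_dnaele_serializes_as_dash(tmp_path):
    ens = ensemble_from_arrays([np.zeros((2, 3))], annotations=["A1", "A2"])
    ens.records.append(
        NdbRecord(element_type="DNAELE", element_index=3,
                  epigenetic_code="TF", chain_id="E1", within_chain_index=1)
    )
    ens.models = [np.zeros((3, 3))]
    ens.sync()
    path = write_ndb(ens, tmp_path / "d.ndb")
    body = [l for l in path.read_text().splitlines() if l.startswith("DNAELE")]
    assert len(body) == 1
    toks = body[0].split()
    assert toks[9] == "-" and toks[10] == "-"
    rec = read_ndb(path).records[-1]
    assert rec.genomic_start is None and rec.genomic_end is None


def test_whitespace_delimited_fallback(tmp_path):
    loose = "\n".join([
        "UNIT sigma",
        "NMODELS 1",
        "CHROM 1 A1 - 1M 1 0.0 0.0 0.0 1 50000 -",
        "CHROM 2 B2 CTCF+ 1M 2 1.0 0.0 0.0 50001 100000 0.5",
        "END",
    ])
    path = tmp_path / "loose.ndb"
    path.write_text(loose + "\n")
    ens = read_ndb(path)
    assert ens.n_records == 2
    assert ens.records[1].genetic_info == "CTCF+"
    assert ens.records[1].spatial_spread == 0.5


def test_parse_error_reports_line_number(tmp_path):
    path = tmp_path / "bad.ndb"
    path.write_text("UNIT sigma\nCHROM 1 A1 oops\nEND\n")
    with pytest.raises(NdbParseError, match="line 2"):
        read_ndb(path)


def test_inconsistent_model_sizes_rejected(tmp_path):
    good = fx.make_random_ensemble(3, n_beads=4, n_models=2,
                                   with_dnaele=False, with_loops=False,
                                   two_chains=False)
    text = write_ndb(good, tmp_path / "g.ndb").read_text()
    lines = text.splitlines()
    # drop one record line from the second MODEL block
    second_model = [i for i, l in enumerate(lines) if l.startswith("MODEL")][1]
    del lines[second_model + 1]
    bad = tmp_path / "bad.ndb"
    bad.write_text("\n".join(lines) + "\n")
    with pytest.raises(NdbValidationError, match="model 2"):
        read_ndb(bad)


def test_loops_round_trip_with_classes(tmp_path):
    ens = fx.make_random_ensemble(11, n_beads=8, with_loops=False,
                                  with_dnaele=False, two_chains=False)
    ens.loops = [LoopEntry(1, 5, "COHESIN"), LoopEntry(2, 7, "POLYCOMB")]
    path = write_ndb(ens, tmp_path / "l.ndb")
    text = path.read_text()
    assert "COHESIN" in text and "POLYCOMB" in text
    assert read_ndb(path).loops == ens.loops


def test_write_refuses_empty_model_list(tmp_path):
    ens = ensemble_from_arrays([np.zeros((2, 3))])
    ens.models = []
    ens.header.model_count = 0
    with pytest.raises(NdbValidationError, match="no models"):
        write_ndb(ens, tmp_path / "x.ndb")


class TestValidation:
    def _base(self):
        return fx.make_random_ensemble(2, n_beads=6, with_dnaele=False,
                                       with_loops=False, two_chains=False)

    def test_non_monotone_within_chain_index(self):
        ens = self._base()
        ens.records[2].within_chain_index = 1
        with pytest.raises(NdbValidationError, match="strictly increasing"):
            validate_ensemble(ens)

    def test_genomic_end_before_start(self):
        ens = self._base()
        ens.records[0].genomic_end = ens.records[0].genomic_start - 10
        with pytest.raises(NdbValidationError, match="genomic_end"):
            validate_ensemble(ens)

    def test_multi_record_dnaele_chain(self):
        ens = self._base()
        for i, r in enumerate(ens.records[:2]):
            r.element_type = "DNAELE"
            r.chain_id = "E1"
            r.within_chain_index = i + 1
        ens.header.compartment_sequence = {}
        with pytest.raises(NdbValidationError, match="DNAELE"):
            validate_ensemble(ens)

    def test_loop_anchor_must_exist(self):
        ens = self._base()
        ens.loops = [LoopEntry(1, 99)]
        with pytest.raises(NdbValidationError, match="anchor 99"):
            validate_ensemble(ens)

    def test_compartment_sequence_length_mismatch(self):
        ens = self._base()
        cid = ens.records[0].chain_id
        ens.header.compartment_sequence[cid] = ["A1"]
        with pytest.raises(NdbValidationError, match="sequence length"):
            validate_ensemble(ens)


# ---------------------------------------------------------------------------
# .spw
# ---------------------------------------------------------------------------

def test_spw_rows_are_exact_projection(tiny_ensemble, tmp_path):
    """Each .spw row is the (type, g_start, g_end, x, y, z) field subset."""
    path = to_spw(tiny_ensemble, tmp_path / "t.spw")
    rows = [l.split("\t") for l in path.read_text().splitlines()
            if not l.startswith("#")]
    assert len(rows) == 6  # 3 beads x 2 models
    for k, row in enumerate(rows):
        model, bead = divmod(k, 3)
        rec = tiny_ensemble.records[bead]
        xyz = tiny_ensemble.models[model][bead]
        assert row[0] == rec.element_type
        assert int(row[1]) == rec.genomic_start
        assert int(row[2]) == rec.genomic_end
        assert [float(v) for v in row[3:]] == pytest.approx(list(xyz))


def test_spw_reinflation_recovers_projected_fields(tmp_path):
    ens = fx.make_random_ensemble(9, with_dnaele=False, two_chains=False,
                                  with_loops=False)
    back = from_spw(to_spw(ens, tmp_path / "p.spw"))
    assert back.n_models == ens.n_models
    for m_in, m_out in zip(ens.models, back.models):
        assert np.array_equal(m_in, m_out)
    for a, b in zip(ens.records, back.records):
        assert (b.element_type, b.genomic_start, b.genomic_end) == (
            a.element_type, a.genomic_start, a.genomic_end)
        # non-projected fields take the documented defaults
        assert b.epigenetic_code == "UN" and b.chain_id == "1"


def test_spw_requires_genomic_coordinates(tmp_path):
    ens = fx.make_random_ensemble(4, with_dnaele=False, two_chains=False)
    ens.records[0].genomic_start = None
    with pytest.raises(NdbValidationError, match="genomic"):
        to_spw(ens, tmp_path / "x.spw")


def test_spw_preserves_frame_blocks(tmp_path):
    ens = fx.make_random_ensemble(6, n_models=2, with_dnaele=False,
                                  two_chains=False)
    text = to_spw(ens, tmp_path / "f.spw").read_text()
    assert text.count("# model") == 2


# ---------------------------------------------------------------------------
# .cndb
# ---------------------------------------------------------------------------

def test_cndb_full_precision(tmp_path):
    ens = fx.make_random_ensemble(13)
    ens.models = [m + 1e-9 for m in ens.models]  # off the milli-unit grid
    ens.sync()
    back = from_cndb(to_cndb(ens, tmp_path / "p.cndb"))
    for a, b in zip(ens.models, back.models):
        assert np.max(np.abs(a - b)) == 0.0


def test_cndb_smaller_than_text_for_many_frames(tmp_path):
    rng = np.random.default_rng(0)
    frames = [np.round(rng.uniform(-50, 50, (20, 3)), 3) for _ in range(150)]
    ens = ensemble_from_arrays(frames)
    ndb = write_ndb(ens, tmp_path / "big.ndb")
    cndb = to_cndb(ens, tmp_path / "big.cndb")
    assert ndb.stat().st_size / cndb.stat().st_size > 1.0


def test_cndb_rejects_corrupted_container(tmp_path):
    path = tmp_path / "junk.cndb"
    path.write_bytes(b"not an hdf5 container")
    with pytest.raises(NdbParseError):
        from_cndb(path)


# ---------------------------------------------------------------------------
# .pdb / .gro
# ---------------------------------------------------------------------------

def test_pdb_block_structure(tmp_path):
    ens = ensemble_from_arrays([np.arange(15, dtype=float).reshape(5, 3)],
                               annotations=["A1"] * 5)
    text = to_pdb(ens, tmp_path / "s.pdb").read_text()
    assert text.count("ATOM  ") == 5
    assert text.count("MODEL") == 1 and text.count("ENDMDL") == 1


def test_pdb_scalar_track_rescaled_to_bfactor_range(tmp_path):
    ens = ensemble_from_arrays([np.zeros((4, 3))], annotations=["A1"] * 4)
    track = [0.0, 1.0, 2.0, 4.0]
    text = to_pdb(ens, tmp_path / "b.pdb", scalar_track=track).read_text()
    betas = [float(l[60:66]) for l in text.splitlines() if l.startswith("ATOM")]
    assert betas[0] == 0.0 and betas[-1] == pytest.approx(99.99)
    # linear: 2.0 is halfway to 4.0
    assert betas[2] == pytest.approx(99.99 / 2, abs=0.01)


def test_gro_bead_names_encode_types(tmp_path):
    labels = ["A1", "A2", "B1", "B2", "B3", "B4", "NA"]
    ens = ensemble_from_arrays([np.random.default_rng(3).uniform(-5, 5, (7, 3)).round(3)],
                               annotations=labels)
    path = to_gro(ens, tmp_path / "s.gro")
    xyz, parsed = read_gro(path)
    assert parsed == labels
    assert np.allclose(xyz, ens.models[0], atol=5e-4)
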