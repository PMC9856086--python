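"""Structure, parameter and run-configuration I/O."""

import warnings

import numpy as np
import pytest

from ringfree.charmm_io import (
    RunConfig,
    parse_parameter_text,
    parse_run_config,
    read_parameters,
    read_pdb_coords,
    read_psf,
    write_pdb,
    write_psf,
    write_run_config,
)
from ringfree.errors import ConfigError, ParameterError, PDBError, PSFParseError


class TestPSF:
    @pytest.mark.parametrize("ext", [False, True], ids=["standard", "ext"])
    def test_round_trip_preserves_topology_and_metadata(self, benzene_bundle,
                                                        tmp_path, ext):
        path = tmp_path / "sys.psf"
        write_psf(benzene_bundle.system, path, ext=ext)
        back = read_psf(path)
        src = benzene_bundle.system
        assert back.n_atoms == src.n_atoms == 20
        assert back.bonds == src.bonds
        assert back.angles == src.angles
        assert back.dihedrals == src.dihedrals
        assert back.types == src.types
        assert np.allclose(back.charges, src.charges)
        assert np.allclose(back.masses, src.masses)

    def test_ext_dialect_parses_identically_to_standard(self, polymer_bundle,
                                                        tmp_path):
        std, ext = tmp_path / "a.psf", tmp_path / "b.psf"
        write_psf(polymer_bundle.system, std, ext=False)
        write_psf(polymer_bundle.system, ext, ext=True)
        a, b = read_psf(std), read_psf(ext)
        assert a.bonds == b.bonds and a.types == b.types
        assert [at.name for at in a.atoms] == [at.name for at in b.atoms]

    def test_declared_count_mismatch_is_an_error(self, benzene_bundle, tmp_path):
        path = tmp_path / "bad.psf"
        write_psf(benzene_bundle.system, path)
        text = path.read_text().replace(
            f"{len(benzene_bundle.system.bonds):>8d} !NBOND",
            f"{len(benzene_bundle.system.bonds) + 1:>8d} !NBOND",
        )
        path.write_text(text)
        with pytest.raises(PSFParseError, match="NBOND"):
            read_psf(path)

    def test_missing_section_is_an_error(self, tmp_path):
        path = tmp_path / "trunc.psf"
        path.write_text("PSF\n\n       1 !NATOM\n"
                        "       1 A    1    RES  X    CT     0.0  12.011  0\n")
        with pytest.raises(PSFParseError, match="NBOND"):
            read_psf(path)

    def test_unparseable_line_names_its_number(self, benzene_bundle, tmp_path):
        path = tmp_path / "garbled.psf"
        write_psf(benzene_bundle.system, path)
        lines = path.read_text().splitlines()
        atom_ln = next(i for i, l in enumerate(lines) if "!NATOM" in l) + 1
        lines[atom_ln] = "not an atom line"
        path.write_text("\n".join(lines))
        with pytest.raises(PSFParseError, match=str(atom_ln + 1)):
            read_psf(path)


class TestParameters:
    def test_bond_entry_echo(self, tmp_path):
        prm = tmp_path / "x.prm"
        prm.write_text("BONDS\nCA CA 305.000 1.3750\nNONBONDED\nCA 0.0 -0.07 1.99\nEND\n")
        params = read_parameters([prm])
        kb, b0 = params.bond_param("CA", "CA")
        assert b0 == pytest.approx(1.375)
        assert kb == pytest.approx(305.0)

    def test_lookup_symmetric_under_pair_reversal(self, tmp_path):
        prm = tmp_path / "x.prm"
        prm.write_text("BONDS\nY X 100.0 1.50\nEND\n")
        params = read_parameters([prm])
        assert params.bond_param("X", "Y") == params.bond_param("Y", "X")

    def test_later_file_overrides_earlier(self, tmp_path):
        a, b = tmp_path / "a.prm", tmp_path / "b.prm"
        a.write_text("BONDS\nCT CT 222.5 1.53\nEND\n")
        b.write_text("BONDS\nCT CT 222.5 1.60\nEND\n")
        params = read_parameters([a, b])
        assert params.bond_param("CT", "CT")[1] == pytest.approx(1.60)

    def test_no_bonds_block_anywhere_is_an_error(self, tmp_path):
        prm = tmp_path / "x.prm"
        prm.write_text("NONBONDED\nCA 0.0 -0.07 1.99\nEND\n")
        with pytest.raises(ParameterError, match="BONDS"):
            read_parameters([prm])

    def test_malformed_numeric_field_is_an_error(self, tmp_path):
        prm = tmp_path / "x.prm"
        prm.write_text("BONDS\nCA CA threehundred 1.375\nEND\n")
        with pytest.raises(ParameterError):
            read_parameters([prm])

    def test_comment_lines_ignored(self):
        params = parse_parameter_text(
            "BONDS\n! a comment\nCA CA 305.0 1.375 ! trailing\nEND\n"
        )
        assert params.bond_param("CA", "CA")[1] == pytest.approx(1.375)

    def test_wildcard_dihedral_lookup(self):
        params = parse_parameter_text(
            "BONDS\nA B 1.0 1.0\nDIHEDRALS\nX A B X 0.2 3 0.0\nEND\n"
        )
        assert params.dihedral_param("Q", "A", "B", "Z") == [(0.2, 3, 0.0)]

    def test_unresolvable_lookup_names_the_pair(self, benzene_bundle):
        with pytest.raises(ParameterError, match=r"\(ZZ, CT\)|\(CT, ZZ\)"):
            benzene_bundle.params.bond_param("ZZ", "CT")


class TestPDB:
    def test_round_trip_to_column_precision(self, benzene_bundle, tmp_path):
        path = tmp_path / "sys.pdb"
        system = benzene_bundle.system.copy()
        write_pdb(system, path)
        moved = system.copy()
        moved.coords = None
        read_pdb_coords(path, moved)
        assert np.abs(moved.coords - system.coords).max() < 1e-3

    def test_atom_count_mismatch_is_an_error(self, benzene_bundle, tmp_path):
        path = tmp_path / "short.pdb"
        write_pdb(benzene_bundle.system, path)
        lines = [l for l in path.read_text().splitlines() if l.startswith("ATOM")]
        path.write_text("\n".join(lines[:-1]) + "\nEND\n")
        with pytest.raises(PDBError, match="19"):
            read_pdb_coords(path, benzene_bundle.system.copy())

    def test_absent_occupancy_beta_columns_still_parse(self, tmp_path,
                                                       benzene_bundle):
        path = tmp_path / "bare.pdb"
        write_pdb(benzene_bundle.system, path)
        bare = "\n".join(l[:54] for l in path.read_text().splitlines()
                         if l.startswith("ATOM"))
        path.write_text(bare + "\n")
        system = benzene_bundle.system.copy()
        system.coords = None
        read_pdb_coords(path, system)
        assert np.abs(system.coords - benzene_bundle.system.coords).max() < 1e-3

    def test_coordinate_overflow_advises_alternative(self, benzene_bundle,
                                                     tmp_path):
        system = benzene_bundle.system.copy()
        system.coords = system.coords + 99999.0
        with pytest.raises(PDBError, match="overflow"):
            write_pdb(system, tmp_path / "far.pdb")


class TestRunConfig:
    def _write(self, tmp_path, body):
        for name in ("s.psf", "c.pdb", "p.prm"):
            (tmp_path / name).write_text("placeholder\n")
        cfg = tmp_path / "run.yaml"
        cfg.write_text(body)
        return cfg

    def test_defaults_when_only_paths_given(self, tmp_path):
        cfg = self._write(
            tmp_path,
            "structure: s.psf\ncoordinates: c.pdb\nparameters: [p.prm]\n",
        )
        rc = parse_run_config(cfg)
        assert rc.cutoff == 0.4
        assert rc.max_stages == 100
        assert rc.steps_per_stage == 500
        assert rc.dielectric == 80.0
        assert rc.nonbonded_cutoff == 12.0
        assert rc.window == 0.1
        assert rc.chirality is True

    def test_explicit_override(self, tmp_path):
        cfg = self._write(
            tmp_path,
            "structure: s.psf\ncoordinates: c.pdb\nparameters: [p.prm]\ncutoff: 0.2\n",
        )
        assert parse_run_config(cfg).cutoff == 0.2

    def test_missing_parameters_key_is_named(self, tmp_path):
        cfg = self._write(tmp_path, "structure: s.psf\ncoordinates: c.pdb\n")
        with pytest.raises(ConfigError, match="parameters"):
            parse_run_config(cfg)

    def test_unknown_key_warns_but_parses(self, tmp_path):
        cfg = self._write(
            tmp_path,
            "structure: s.psf\ncoordinates: c.pdb\nparameters: [p.prm]\nbogus: 1\n",
        )
        with pytest.warns(UserWarning, match="bogus"):
            rc = parse_run_config(cfg)
        assert rc.cutoff == 0.4

    def test_reserialization_is_idempotent(self, tmp_path):
        cfg = self._write(
            tmp_path,
            "structure: s.psf\ncoordinates: c.pdb\nparameters: [p.prm]\n"
            "cutoff: 0.3\nseed: 9\n",
        )
        rc = parse_run_config(cfg)
        out = tmp_path / "again.yaml"
        write_run_config(rc, out)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rc2 = parse_run_config(out)
        assert rc2 == rc

    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigError):
            RunConfig(cutoff=-1.0)
        with pytest.raises(ConfigError):
            RunConfig(max_stages=0)
        with pytest.raises(ConfigError):
            RunConfig(dielectric=0.5)


class TestExternalReader:
    """Our writers must be legible to an independent PSF/PDB reader."""

    def test_mdanalysis_reads_back_identical_structure(self, benzene_bundle,
                                                       tmp_path):
        mda = pytest.importorskip("MDAnalysis")
        psf, pdb = tmp_path / "s.psf", tmp_path / "c.pdb"
        write_psf(benzene_bundle.system, psf)
        write_pdb(benzene_bundle.system, pdb)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(psf), str(pdb))
        assert len(u.atoms) == benzene_bundle.system.n_atoms
        assert len(u.bonds) == len(benzene_bundle.system.bonds)
        assert list(u.atoms.types) == benzene_bundle.system.types
        assert np.abs(
            u.atoms.positions - benzene_bundle.system.coords
        ).max() < 1e-2
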