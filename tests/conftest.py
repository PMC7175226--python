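import numpy as np
import pytest

from structkit.core_model import Structure, iter_atoms
from structkit.fixtures import FixtureSpec, build_backbone, make_protein_structure, write_raw_pdb


def assert_structures_equal(a: Structure, b: Structure, atol: float = 0.0):
    """Field-by-field comparison ignoring the structure id/model number."""
    assert len(a.chains) == len(b.chains)
    for ca_, cb in zip(a.chains, b.chains):
        assert ca_.chain_id == cb.chain_id
        assert len(ca_.residues) == len(cb.residues)
        for ra, rb in zip(ca_.residues, cb.residues):
            assert (ra.res_name, ra.res_seq, ra.i_code) == (rb.res_name, rb.res_seq, rb.i_code)
            assert len(ra.atoms) == len(rb.atoms)
            for aa, ab in zip(ra.atoms, rb.atoms):
                assert aa.serial == ab.serial
                assert aa.name == ab.name
                assert aa.alt_loc == ab.alt_loc
                assert aa.element == ab.element
                assert aa.is_hetero == ab.is_hetero
                if atol == 0.0:
                    assert (aa.pos.x, aa.pos.y, aa.pos.z) == (ab.pos.x, ab.pos.y, ab.pos.z)
                    assert aa.occupancy == ab.occupancy
                    assert aa.b_factor == ab.b_factor
                else:
                    np.testing.assert_allclose(
                        aa.pos.to_array(), ab.pos.to_array(), atol=atol
                    )
                    assert abs(aa.occupancy - ab.occupancy) <= atol
                    assert abs(aa.b_factor - ab.b_factor) <= atol


@pytest.fixture
def helix():
    return build_backbone([(-57.0, -47.0)] * 10)


@pytest.fixture
def helix_file(tmp_path, helix):
    path = tmp_path / "helix.pdb"
    write_raw_pdb(helix, path)
    return path


@pytest.fixture
def protein_file(tmp_path):
    """Mixed fixture: 2 protein chains, ligand, calcium ion, alt-locs."""
    spec = FixtureSpec(
        seed=11, n_residues=5, n_chains=2,
        with_ligand=True, with_calcium=True, with_alt_locs=True,
    )
    structure, truth = make_protein_structure(spec)
    path = tmp_path / "protein.pdb"
    write_raw_pdb(structure, path)
    return path, structure, truth
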