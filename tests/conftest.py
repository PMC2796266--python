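"""Shared fixtures: synthetic families, toy structures, extracted signatures.

Everything is generated programmatically; module scope keeps the heavier
pipeline objects (signature sets, Gram matrices) computed once per session.
"""

from __future__ import annotations

import pytest

import ascsite as asc


@pytest.fixture(scope="session")
def default_spec() -> asc.FamilySpec:
    return asc.FamilySpec()  # 3 classes x 20, 8-position site, 2 SDPs


@pytest.fixture(scope="session")
def fixture_bundle(default_spec):
    """(family, truth, structure, selector) for the default planted family."""
    return asc.make_fixture(default_spec)


@pytest.fixture(scope="session")
def signature_bundle(fixture_bundle):
    """(family, truth, definition, signature_set) after extraction."""
    family, truth, structure, selector = fixture_bundle
    definition = asc.extract_signature_positions(
        structure, selector, family, cutoff=6.0, core_min=5.0
    )
    sigset = asc.map_signatures(family, definition)
    return family, truth, definition, sigset


@pytest.fixture(scope="session")
def clean_spec() -> asc.FamilySpec:
    """Noise-free, gap-free variant: labels fully determined by the SDPs."""
    return asc.FamilySpec(noise=0.0, gap_rate=0.0, n_per_class=8, seed=3)


@pytest.fixture(scope="session")
def clean_bundle(clean_spec):
    family, truth = asc.make_family(clean_spec)
    structure, selector = asc.make_toy_structure(clean_spec)
    definition = asc.extract_signature_positions(
        structure, selector, family, cutoff=6.0, core_min=5.0
    )
    sigset = asc.map_signatures(family, definition)
    return family, truth, definition, sigset


THREE_RES_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  N   ALA A   2       2.000   1.300   0.000  1.00  0.00           N
ATOM      4  CA  ALA A   2       3.450   1.300   0.000  1.00  0.00           C
ATOM      5  CB  ALA A   2       4.000   2.600   0.500  1.00  0.00           C
ATOM      6  N   SER A   3       4.000   0.000   1.200  1.00  0.00           N
ATOM      7  CA  SER A   3       5.450   0.000   1.200  1.00  0.00           C
END
"""

IPM_HET = """\
HETATM    8  C1  IPM A 101      10.000  10.000  10.000  1.00  0.00           C
HETATM    9  C2  IPM A 101      11.200  10.000  10.000  1.00  0.00           C
HETATM   10  O1  IPM A 101      10.000  11.200  10.000  1.00  0.00           O
HETATM   11  O2  IPM A 101      10.000  10.000  11.200  1.00  0.00           O
"""


@pytest.fixture()
def three_res_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(THREE_RES_PDB)
    return path


@pytest.fixture()
def three_res_het_pdb(tmp_path):
    path = tmp_path / "tiny_het.pdb"
    path.write_text(THREE_RES_PDB.replace("END\n", "") + IPM_HET + "END\n")
    return path
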