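"""Shared fixtures: toy alignments and a programmatic PDB builder.

All fixtures are generated at test time; nothing binary is stored.
"""

from __future__ import annotations

import pytest

from phyloconsensus.family_io import AlignedFamily


@pytest.fixture
def toy_family() -> AlignedFamily:
    """Three aligned 10-column sequences, query first."""
    return AlignedFamily(
        (
            ("query", "ACDEFGHIKL"),
            ("homolog1", "ACDEFGHIKV"),
            ("homolog2", "ACDEFGGIKV"),
        ),
        "query",
    )


@pytest.fixture
def toy_fasta(tmp_path, toy_family):
    path = tmp_path / "toy.fasta"
    with open(path, "w") as fh:
        for sid, seq in toy_family:
            fh.write(f">{sid}\n{seq}\n")
    return path


def format_pdb_atom(serial, name, resname, chain, resnum, x, y, z,
                    element, occupancy=1.0, altloc=" "):
    atom_field = name if len(name) == 4 else f" {name:<3}"
    return (
        f"ATOM  {serial:>5} {atom_field}{altloc}{resname:>3} {chain}"
        f"{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}  0.00"
        f"          {element:>2}\n"
    )


def write_pdb(path, residues):
    """Write a minimal PDB.

    ``residues``: list of ``(chain, resnum, resname, atoms)`` where each
    atom is ``(name, element, x, y, z)`` or
    ``(name, element, x, y, z, occupancy, altloc)``.
    """
    serial = 1
    with open(path, "w") as fh:
        for chain, resnum, resname, atoms in residues:
            for atom in atoms:
                name, element, x, y, z = atom[:5]
                occ = atom[5] if len(atom) > 5 else 1.0
                altloc = atom[6] if len(atom) > 6 else " "
                fh.write(
                    format_pdb_atom(
                        serial, name, resname, chain, resnum, x, y, z,
                        element, occ, altloc,
                    )
                )
                serial += 1
        fh.write("END\n")
    return path


GLY_BACKBONE = [
    ("N", "N", 0.0, 0.0, 0.0),
    ("CA", "C", 1.5, 0.0, 0.0),
    ("C", "C", 2.2, 1.3, 0.0),
    ("O", "O", 3.4, 1.4, 0.0),
]


def shifted(atoms, dx=0.0, dy=0.0, dz=0.0):
    return [(n, e, x + dx, y + dy, z + dz) for n, e, x, y, z in atoms]
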