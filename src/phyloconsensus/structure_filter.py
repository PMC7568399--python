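"""Structural screening of candidate substitutions.

Two geometric exclusion criteria are applied to each proposed substitution,
using a structure (crystal or homology model) of the query protein:

1. **Active-site proximity** — the candidate residue must lie farther than a
   minimum distance (default 6 Å) from a user-declared active-site set,
   measured as the minimum heavy-atom-to-heavy-atom Euclidean distance.
   Mutations close to the catalytic machinery risk destroying activity even
   if they stabilize the fold.
2. **Side-chain bonding** — residues whose side chain forms hydrogen bonds
   or salt bridges with other residues are excluded, since replacing them
   would delete stabilizing interactions.

Hydrogen bonds are detected by distance only (side-chain N/O of the
candidate to any N/O of another residue at ≤ 3.5 Å; backbone partners
count, because the criterion concerns the candidate's own side chain).
Salt bridges pair a basic side-chain nitrogen (Lys NZ; Arg NE/NH1/NH2;
His ND1/NE2) with an acidic side-chain carboxylate oxygen (Asp OD1/OD2;
Glu OE1/OE2) at ≤ 4.0 Å.  Hydrogens are ignored throughout: homology
models rarely carry them, and the thresholds are calibrated for
heavy-atom geometry.

Sites are never deleted by filtering — each receives a ``filter_status``
(``passed`` / ``rejected_distance`` / ``rejected_bonded``) so the full
audit trail survives into the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .consensus import CandidateSite
from .errors import ConfigError, MappingError
from .family_io import ungapped

#: Default exclusion radius around the active site, Å.
MIN_ACTIVE_SITE_DISTANCE = 6.0
#: Donor–acceptor heavy-atom cutoff for hydrogen bonds, Å.
HBOND_CUTOFF = 3.5
#: Nitrogen–oxygen cutoff for salt bridges, Å.
SALT_BRIDGE_CUTOFF = 4.0

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
_BASIC_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}
_ACIDIC_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


@dataclass(frozen=True)
class Residue:
    chain: str
    number: int
    name: str  # 3-letter code
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3)

    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    def sidechain_mask(self) -> np.ndarray:
        return np.array(
            [e != "H" and a not in _BACKBONE_ATOMS
             for a, e in zip(self.atom_names, self.elements)]
        )


@dataclass(frozen=True)
class BondContact:
    partner_position: int | None  # query position of partner if mapped
    partner_chain: str
    partner_number: int
    kind: str  # "hbond" | "salt_bridge"
    distance: float


@dataclass
class StructureModel:
    """A parsed structure plus the query-position → residue mapping."""

    residues: dict[tuple[str, int], Residue]
    mapping: dict[int, tuple[str, int]]  # query 1-based position → (chain, resnum)

    def residue_at(self, position: int) -> Residue:
        try:
            key = self.mapping[position]
        except KeyError:
            raise MappingError(f"query position {position} is not mapped") from None
        return self.residues[key]

    def position_of(self, chain: str, number: int) -> int | None:
        for pos, key in self.mapping.items():
            if key == (chain, number):
                return pos
        return None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body transform of every atom (used to test invariances)."""
        new = {
            key: Residue(
                r.chain, r.number, r.name, r.atom_names, r.elements,
                r.coords @ np.asarray(rotation).T + np.asarray(translation),
            )
            for key, r in self.residues.items()
        }
        return StructureModel(new, dict(self.mapping))


def _pick_altloc(residue) -> list:
    """Highest-occupancy conformer for disordered atoms, all others as-is."""
    atoms = []
    for atom in residue:
        if atom.is_disordered():
            best = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy() or 0.0)
            atoms.append(best)
        else:
            atoms.append(atom)
    return atoms


def load_structure(
    path,
    query_sequence: str | None = None,
    chain: str = "A",
    offset: int = 0,
) -> StructureModel:
    """Parse a PDB file and build the query-position mapping.

    Query position ``p`` (1-based along the ungapped query) maps to residue
    ``p + offset`` of the given chain.  When ``query_sequence`` is supplied
    (aligned or ungapped; gaps are stripped), every mapped residue's
    identity is checked against the corresponding query letter, and the
    first disagreement raises :class:`~phyloconsensus.errors.MappingError`
    — a mismatch almost always signals a numbering offset, which would
    silently corrupt every downstream distance.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate nonstandard toy PDBs
        structure = PDBParser(QUIET=True).get_structure("query", str(path))
    model = next(structure.get_models())
    residues: dict[tuple[str, int], Residue] = {}
    for ch in model:
        for res in ch:
            het, resnum, icode = res.get_id()
            if het.strip():  # skip waters / heteroatoms
                continue
            atoms = _pick_altloc(res)
            residues[(ch.id, resnum)] = Residue(
                chain=ch.id,
                number=resnum,
                name=res.get_resname().strip().upper(),
                atom_names=tuple(a.get_name() for a in atoms),
                elements=tuple((a.element or "?").strip().upper() for a in atoms),
                coords=np.array([a.get_coord() for a in atoms], dtype=float),
            )
    if not residues:
        raise MappingError(f"no polymer residues found in '{path}'")

    mapping = {}
    if query_sequence is not None:
        bare = ungapped(query_sequence)
        for pos, letter in enumerate(bare, start=1):
            key = (chain, pos + offset)
            if key not in residues:
                continue  # structure may be partial
            mapping[pos] = key
            resname = residues[key].name
            observed = protein_letters_3to1.get(resname, "X")
            if observed != letter and letter != "X":
                raise MappingError(
                    f"query position {pos} is '{letter}' but structure residue "
                    f"{chain}{pos + offset} is {resname} ('{observed}'); "
                    "check the numbering offset"
                )
        if not mapping:
            raise MappingError("no query position maps into the structure")
    else:
        for (ch_id, resnum) in residues:
            if ch_id == chain and resnum - offset >= 1:
                mapping[resnum - offset] = (ch_id, resnum)
    return StructureModel(residues, mapping)


def _min_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def distance_to_active_site(
    model: StructureModel,
    position: int,
    active_site: list[int],
) -> float:
    """Minimum heavy-atom distance (Å) from a residue to the active-site set.

    ``active_site`` lists query positions (catalytic residues, or residues
    lining a docked ligand).  A residue in the set has distance 0.
    """
    if not active_site:
        raise ConfigError("active-site set is empty")
    res = model.residue_at(position)
    if position in active_site:
        return 0.0
    a = res.coords[res.heavy_mask()]
    best = np.inf
    for site_pos in active_site:
        site = model.residue_at(site_pos)
        b = site.coords[site.heavy_mask()]
        best = min(best, _min_distance(a, b))
    return float(best)


def detect_sidechain_bonds(model: StructureModel, position: int) -> list[BondContact]:
    """Hydrogen bonds and salt bridges made by one residue's side chain.

    Returns one :class:`BondContact` per partner-residue contact; a pair
    that satisfies the salt-bridge geometry is reported as ``salt_bridge``
    (not doubly as an hbond).  Glycine yields an empty report.
    """
    res = model.residue_at(position)
    sc = res.sidechain_mask()
    contacts: list[BondContact] = []
    if not sc.any():
        return contacts

    sc_names = [a for a, keep in zip(res.atom_names, sc) if keep]
    sc_coords = res.coords[sc]
    basic_self = _BASIC_ATOMS.get(res.name, set())
    acidic_self = _ACIDIC_ATOMS.get(res.name, set())

    for key, other in model.residues.items():
        if key == (res.chain, res.number):
            continue
        heavy = other.heavy_mask()
        names_o = [a for a, keep in zip(other.atom_names, heavy) if keep]
        elems_o = [e for e, keep in zip(other.elements, heavy) if keep]
        coords_o = other.coords[heavy]
        if coords_o.size == 0:
            continue
        found_kind = None
        found_dist = np.inf
        for i, (an, el) in enumerate(
            zip(sc_names, (e for e, keep in zip(res.elements, sc) if keep))
        ):
            if el not in ("N", "O"):
                continue
            d = np.sqrt(((coords_o - sc_coords[i]) ** 2).sum(axis=1))
            for j, (bn, bel) in enumerate(zip(names_o, elems_o)):
                if bel not in ("N", "O"):
                    continue
                dij = float(d[j])
                is_salt = (
                    an in basic_self
                    and bn in _ACIDIC_ATOMS.get(other.name, set())
                    or an in acidic_self
                    and bn in _BASIC_ATOMS.get(other.name, set())
                ) and dij <= SALT_BRIDGE_CUTOFF
                is_hbond = dij <= HBOND_CUTOFF
                if is_salt and (found_kind != "salt_bridge" or dij < found_dist):
                    found_kind, found_dist = "salt_bridge", dij
                elif is_hbond and found_kind is None:
                    found_kind, found_dist = "hbond", dij
                elif is_hbond and found_kind == "hbond" and dij < found_dist:
                    found_dist = dij
        if found_kind is not None:
            contacts.append(
                BondContact(
                    partner_position=model.position_of(other.chain, other.number),
                    partner_chain=other.chain,
                    partner_number=other.number,
                    kind=found_kind,
                    distance=round(found_dist, 3),
                )
            )
    return contacts


def apply_structural_filters(
    candidates: list[CandidateSite],
    model: StructureModel,
    active_site: list[int],
    min_distance: float = MIN_ACTIVE_SITE_DISTANCE,
) -> list[CandidateSite]:
    """Set each candidate's filter status from the two geometric criteria.

    ``rejected_distance`` if the residue is ≤ ``min_distance`` Å from the
    active site (strict inequality required to pass); else
    ``rejected_bonded`` if its side chain makes any hydrogen bond or salt
    bridge; else ``passed``.  Input order is preserved and no site is
    dropped.
    """
    if min_distance <= 0:
        raise ConfigError("min_distance must be positive")
    out = []
    for site in candidates:
        dist = distance_to_active_site(model, site.position, active_site)
        if dist <= min_distance:
            out.append(
                site.with_status("rejected_distance", distance_to_active_site=dist)
            )
            continue
        bonds = detect_sidechain_bonds(model, site.position)
        if bonds:
            out.append(
                site.with_status(
                    "rejected_bonded",
                    distance_to_active_site=dist,
                    bonds=tuple(bonds),
                )
            )
        else:
            out.append(
                site.with_status("passed", distance_to_active_site=dist)
            )
    return out


def filter_audit_frame(sites: list[CandidateSite]):
    """Audit table: label, distance, bond counts, status."""
    import pandas as pd

    return pd.DataFrame(
        {
            "label": [s.label for s in sites],
            "distance_A": [
                None if s.distance_to_active_site is None
                else round(s.distance_to_active_site, 2)
                for s in sites
            ],
            "n_hbonds": [
                sum(1 for b in s.bonds if b.kind == "hbond") for s in sites
            ],
            "n_salt_bridges": [
                sum(1 for b in s.bonds if b.kind == "salt_bridge") for s in sites
            ],
            "status": [s.filter_status for s in sites],
        }
    )
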