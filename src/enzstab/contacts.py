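"""Structural statistics on protein crystal structures.

Implements the distance-based contact conventions common in structural
enzymology: polar contacts (N/O donor/acceptor atoms) within a 3.5 A
cutoff, salt bridges as polar contacts between oppositely charged
side-chain groups, normalized side-chain B-factors (group mean divided
by the all-atom mean of the same chain), and Kabsch superposition with
iterative outlier rejection.

Contact detection is purely distance-based (no donor-acceptor angle
term), matching the behaviour of interactive viewers' polar-contact
mode.  Histidine is treated as a neutral donor/acceptor by default:
whether its imidazole is protonated is structure- and pH-dependent, and
the default keeps His-carboxylate pairs classified as hydrogen bonds
rather than salt bridges (``his_charged=True`` flips this).

PDB input is parsed with gemmi (fixed-width ATOM/HETATM records, first
model); alternate locations are resolved by highest occupancy (ties:
first in file) and waters are retained but flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ContactEdge",
    "BFactorReport",
    "SuperpositionResult",
    "read_structure",
    "write_pdb",
    "polar_partner_atoms",
    "residue_network",
    "ligand_polar_contacts",
    "normalized_bfactor",
    "kabsch_superpose",
    "align_rmsd",
    "survey_salt_bridges",
    "map_equivalent_residue",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
BACKBONE_POLAR = {"N", "O", "OXT"}

# hydrogen-bond-capable side-chain N/O atoms per standard residue
SIDECHAIN_POLAR: dict[str, frozenset[str]] = {
    "ALA": frozenset(), "GLY": frozenset(), "VAL": frozenset(),
    "LEU": frozenset(), "ILE": frozenset(), "PRO": frozenset(),
    "PHE": frozenset(), "MET": frozenset(), "CYS": frozenset(),
    "SER": frozenset({"OG"}), "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}), "TRP": frozenset({"NE1"}),
    "ASN": frozenset({"OD1", "ND2"}), "GLN": frozenset({"OE1", "NE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}

# charged-group membership: +1 guanidinium/ammonium, -1 carboxylate
POSITIVE_GROUP = {"ARG": frozenset({"NE", "NH1", "NH2"}),
                  "LYS": frozenset({"NZ"})}
NEGATIVE_GROUP = {"ASP": frozenset({"OD1", "OD2"}),
                  "GLU": frozenset({"OE1", "OE2"})}
HIS_GROUP = frozenset({"ND1", "NE2"})

WATER_NAMES = {"HOH", "WAT", "DOD"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    pos: np.ndarray          # (3,) Angstrom
    b: float                 # B-factor, A^2
    occ: float
    altloc: str = ""


@dataclass
class Residue:
    chain: str
    name: str
    seqid: int
    icode: str = ""
    het: bool = False
    is_water: bool = False
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> str:
        ic = self.icode.strip()
        return f"{self.chain}/{self.name} {self.seqid}{ic}"


@dataclass
class Structure:
    """Chains -> residues -> atoms, author numbering preserved."""

    id: str = ""
    residues: list[Residue] = field(default_factory=list)

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def chain_residues(self, chain: str) -> list[Residue]:
        return [r for r in self.residues if r.chain == chain]

    def polymer_residues(self, chain: str | None = None) -> list[Residue]:
        return [r for r in self.residues
                if not r.het and not r.is_water
                and (chain is None or r.chain == chain)]

    def find_residue(self, chain: str, seqid: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.chain == chain and r.seqid == seqid and r.icode.strip() == icode.strip():
                return r
        raise KeyError(f"residue {chain}:{seqid}{icode} not found")

    def chain_sequence(self, chain: str) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X")
                       for r in self.polymer_residues(chain))


@dataclass(frozen=True)
class ContactEdge:
    atom_a: str              # "chain/RES num/ATOM"
    atom_b: str
    distance: float
    kind: str                # salt_bridge | hydrogen_bond | polar_contact


@dataclass
class BFactorReport:
    chain_mean_b: dict[str, float]
    per_chain_residue: dict[str, dict[int, float]]    # chain -> seqid -> ratio
    per_chain_combined: dict[str, float]
    cross_chain_residue: dict[int, float]
    cross_chain_combined: float


@dataclass
class SuperpositionResult:
    rotation: np.ndarray     # (3,3)
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms_used: int
    n_atoms_start: int
    cycles_run: int = 0


# ---------------------------------------------------------------------------
# PDB I/O

def _validate_pdb_lines(text: str) -> None:
    bad: list[int] = []
    for i, line in enumerate(text.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                bad.append(i)
                continue
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except ValueError:
                bad.append(i)
    if bad:
        shown = ", ".join(map(str, bad[:10]))
        raise ValueError(f"malformed fixed-width ATOM/HETATM records at line(s) {shown}")


def read_structure(source: str | Path) -> Structure:
    """Parse a PDB file or PDB-format text (first model only).

    Alternate locations are resolved by highest occupancy (ties: first
    in file); waters are kept and flagged via ``Residue.is_water``.
    """
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
        sid = Path(source).stem
    else:
        text = str(source)
        sid = ""
    if "ATOM" not in text and "HETATM" not in text:
        raise ValueError("no ATOM/HETATM records in input")
    _validate_pdb_lines(text)
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    out = Structure(id=sid or st.name)
    if len(st) == 0:
        raise ValueError("no models in input")
    model = st[0]
    for ch in model:
        for res in ch:
            rr = Residue(
                chain=ch.name, name=res.name, seqid=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                het=(res.het_flag == "H"),
                is_water=res.is_water() or res.name in WATER_NAMES,
            )
            # altloc resolution: highest occupancy per atom name
            chosen: dict[str, gemmi.Atom] = {}
            for a in res:
                prev = chosen.get(a.name)
                if prev is None or a.occ > prev.occ:
                    chosen[a.name] = a
            order: list[str] = []
            for a in res:
                if a.name not in order:
                    order.append(a.name)
            for name in order:
                a = chosen[name]
                rr.atoms.append(Atom(
                    name=a.name, element=a.element.name,
                    pos=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    b=a.b_iso, occ=a.occ,
                    altloc=(a.altloc or "").strip()))
            out.residues.append(rr)
    if not out.residues:
        raise ValueError("no residues parsed from input")
    return out


def write_pdb(structure: Structure) -> str:
    """Serialize to fixed-width PDB ATOM/HETATM/TER/END records."""
    lines: list[str] = []
    serial = 0
    last_chain = None
    for r in structure.residues:
        if last_chain is not None and r.chain != last_chain:
            lines.append("TER")
        last_chain = r.chain
        rec = "HETATM" if (r.het or r.is_water) else "ATOM  "
        for a in r.atoms:
            serial += 1
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"{rec}{serial:5d} {name}{'':1s}{r.name:>3s} {r.chain[:1]}"
                f"{r.seqid:4d}{(r.icode or ' ')[:1]}   "
                f"{a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
                f"{a.occ:6.2f}{a.b:6.2f}          {a.element:>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# polar contacts

def _charge_tag(resname: str, atom_name: str, his_charged: bool) -> int:
    """+1 / -1 when the atom belongs to a charged side-chain group, else 0."""
    if atom_name in POSITIVE_GROUP.get(resname, ()):
        return +1
    if atom_name in NEGATIVE_GROUP.get(resname, ()):
        return -1
    if his_charged and resname == "HIS" and atom_name in HIS_GROUP:
        return +1
    if atom_name == "OXT":
        return -1
    return 0


def polar_partner_atoms(residue: Residue, his_charged: bool = False,
                        include_backbone: bool = True) -> list[tuple[Atom, int]]:
    """Hydrogen-bond-capable N/O atoms of a residue with their charge tags.

    Standard residues use a fixed per-residue table (side-chain N/O plus
    backbone N and O); hetero ligands contribute every N/O atom.  Unknown
    polymer residue names raise.
    """
    out: list[tuple[Atom, int]] = []
    if residue.het or residue.is_water:
        for a in residue.atoms:
            if a.element in ("N", "O"):
                out.append((a, 0))
        return out
    if residue.name not in SIDECHAIN_POLAR:
        raise ValueError(f"unknown residue type {residue.name!r} at {residue.key}")
    allowed = set(SIDECHAIN_POLAR[residue.name])
    if include_backbone:
        allowed |= BACKBONE_POLAR
    for a in residue.atoms:
        if a.name in allowed:
            out.append((a, _charge_tag(residue.name, a.name, his_charged)))
    return out


def _sidechain_polar(residue: Residue, his_charged: bool) -> list[tuple[Atom, int]]:
    return [(a, t) for a, t in polar_partner_atoms(residue, his_charged)
            if a.name not in BACKBONE_ATOMS or (residue.het and not residue.is_water)]


def _qualify(res: Residue, atom: Atom) -> str:
    return f"{res.key}/{atom.name}"


def _classify(tag_a: int, tag_b: int) -> str:
    if tag_a * tag_b < 0:
        return "salt_bridge"
    return "hydrogen_bond"


def residue_network(s: Structure, chain: str, resnum: int, cutoff: float = 3.5,
                    his_charged: bool = False,
                    include_waters: bool = False) -> list[ContactEdge]:
    """Polar contacts emanating from the side chain of one residue.

    Every pair (side-chain polar atom of the target, polar atom of any
    other residue) within ``cutoff`` A yields one edge, classified as
    ``salt_bridge`` when the two atoms sit in oppositely charged groups
    and ``hydrogen_bond`` otherwise.  Sorted by distance.
    """
    target = s.find_residue(chain, resnum)
    sources = _sidechain_polar(target, his_charged)
    edges: list[ContactEdge] = []
    for other in s.residues:
        if other is target:
            continue
        if other.is_water and not include_waters:
            continue
        partners = polar_partner_atoms(other, his_charged)
        for a, ta in sources:
            for b, tb in partners:
                d = float(np.linalg.norm(a.pos - b.pos))
                if d <= cutoff:
                    edges.append(ContactEdge(_qualify(target, a),
                                             _qualify(other, b), d,
                                             _classify(ta, tb)))
    edges.sort(key=lambda e: e.distance)
    return edges


def ligand_polar_contacts(s: Structure, ligand_resname: str,
                          cutoff: float = 3.5,
                          his_charged: bool = False) -> dict[str, list[ContactEdge]]:
    """Per-residue polar contacts between a bound ligand and the protein.

    Returns a mapping residue key -> edges (ligand N/O atom vs protein
    polar atom within ``cutoff``).
    """
    ligands = [r for r in s.residues if r.name == ligand_resname]
    if not ligands:
        raise ValueError(f"ligand {ligand_resname!r} not present in structure")
    out: dict[str, list[ContactEdge]] = {}
    for lig in ligands:
        lig_atoms = [a for a in lig.atoms if a.element in ("N", "O")]
        for other in s.residues:
            if other is lig or other.is_water or other.het:
                continue
            for b, tb in polar_partner_atoms(other, his_charged):
                for a in lig_atoms:
                    d = float(np.linalg.norm(a.pos - b.pos))
                    if d <= cutoff:
                        out.setdefault(other.key, []).append(
                            ContactEdge(_qualify(lig, a), _qualify(other, b),
                                        d, "polar_contact"))
    for edges in out.values():
        edges.sort(key=lambda e: e.distance)
    return out


# ---------------------------------------------------------------------------
# B-factors

def normalized_bfactor(s: Structure, targets: list[tuple[int, str]],
                       chains: list[str] | None = None,
                       side_chain_only: bool = True) -> BFactorReport:
    """Normalized B-factors of target residues, per chain and averaged.

    For each chain the mean B of the targets' (side-chain) atoms is
    divided by the mean B over *all* atoms of that chain (polymer,
    ligand and water records sharing the chain id).  ``targets`` is a
    list of (residue number, residue name); every target must exist in
    every requested chain.  The combined value pools the atoms of all
    targets before normalizing; cross-chain values are arithmetic means
    over chains.
    """
    if chains is None:
        chains = [c for c in s.chains() if s.polymer_residues(c)]
    if not chains:
        raise ValueError("no polymer chains in structure")

    chain_mean: dict[str, float] = {}
    per_res: dict[str, dict[int, float]] = {}
    per_comb: dict[str, float] = {}
    for c in chains:
        residues = s.chain_residues(c)
        all_b = [a.b for r in residues for a in r.atoms]
        if not all_b:
            raise ValueError(f"chain {c!r} has no atoms")
        mean_b = float(np.mean(all_b))
        chain_mean[c] = mean_b
        per_res[c] = {}
        pooled: list[float] = []
        for num, name in targets:
            try:
                r = s.find_residue(c, num)
            except KeyError:
                raise ValueError(f"target residue {c}:{name}{num} missing") from None
            if name and r.name != name:
                raise ValueError(
                    f"target residue {c}:{num} is {r.name}, expected {name}")
            atoms = [a for a in r.atoms
                     if not side_chain_only or a.name not in BACKBONE_ATOMS]
            if not atoms:
                raise ValueError(f"no {'side-chain ' if side_chain_only else ''}"
                                 f"atoms for {c}:{name}{num}")
            bs = [a.b for a in atoms]
            pooled.extend(bs)
            per_res[c][num] = float(np.mean(bs)) / mean_b
        per_comb[c] = float(np.mean(pooled)) / mean_b

    cross_res = {num: float(np.mean([per_res[c][num] for c in chains]))
                 for num, _ in targets}
    cross_comb = float(np.mean([per_comb[c] for c in chains]))
    return BFactorReport(chain_mean_b=chain_mean, per_chain_residue=per_res,
                         per_chain_combined=per_comb,
                         cross_chain_residue=cross_res,
                         cross_chain_combined=cross_comb)


# ---------------------------------------------------------------------------
# superposition

def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Optimal rigid-body superposition of a onto b (Kabsch, SVD).

    Returns the proper rotation R and translation t minimizing
    ||R a_i + t - b_i|| in the least-squares sense, and the RMSD of the
    transformed coordinates.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need >= 3 point pairs")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cb - rot @ ca
    moved = (rot @ a.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=t, rmsd=rmsd,
                               n_atoms_used=n, n_atoms_start=n, cycles_run=0)


def _paired_coords(s_a: Structure, s_b: Structure, selection: str,
                   pairing: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    pa, pb, labels = [], [], []
    chains_b = set(s_b.chains())
    for c in s_a.chains():
        if c not in chains_b:
            continue
        res_a = s_a.polymer_residues(c)
        res_b = s_b.polymer_residues(c)
        if pairing == "label":
            index_b = {(r.seqid, r.icode, r.name): r for r in res_b}
            pairs = [(ra, index_b.get((ra.seqid, ra.icode, ra.name)))
                     for ra in res_a]
            pairs = [(ra, rb) for ra, rb in pairs if rb is not None]
        elif pairing == "sequence":
            from .seqtools import global_align
            sa = "".join(THREE_TO_ONE.get(r.name, "X") for r in res_a)
            sb = "".join(THREE_TO_ONE.get(r.name, "X") for r in res_b)
            row_a, row_b = global_align(sa, sb)
            ia = ib = 0
            pairs = []
            for xa, xb in zip(row_a, row_b):
                if xa != "-" and xb != "-":
                    pairs.append((res_a[ia], res_b[ib]))
                if xa != "-":
                    ia += 1
                if xb != "-":
                    ib += 1
        else:
            raise ValueError(f"unknown pairing mode {pairing!r}")
        for ra, rb in pairs:
            aa, ab = ra.atom(selection), rb.atom(selection)
            if aa is not None and ab is not None:
                pa.append(aa.pos)
                pb.append(ab.pos)
                labels.append(ra.key)
    if len(pa) < 3:
        raise ValueError(f"only {len(pa)} matchable {selection} pairs; need >= 3")
    return np.array(pa), np.array(pb), labels


def align_rmsd(s_a: Structure, s_b: Structure, selection: str = "CA",
               cycles: int = 5, reject_sigma: float = 2.0,
               pairing: str = "label") -> SuperpositionResult:
    """Superpose two structures with iterative outlier rejection.

    Residues are paired per shared chain (by residue number, insertion
    code and name, or by sequence alignment with ``pairing="sequence"``);
    the ``selection`` atom (Calpha by default) of each pair enters the
    fit.  Each cycle superposes, computes per-pair deviations and
    discards pairs deviating more than ``reject_sigma`` standard
    deviations above the mean deviation, until no pair is rejected or
    ``cycles`` is reached.  RMSD never increases across cycles.
    """
    a, b, _ = _paired_coords(s_a, s_b, selection, pairing)
    keep = np.ones(len(a), dtype=bool)
    res = kabsch_superpose(a, b)
    n_start = len(a)
    cycles_run = 0
    for _ in range(cycles):
        res = kabsch_superpose(a[keep], b[keep])
        moved = (res.rotation @ a[keep].T).T + res.translation
        dev = np.sqrt(np.sum((moved - b[keep]) ** 2, axis=1))
        thr = dev.mean() + reject_sigma * dev.std()
        # floor keeps numerically exact overlays from shedding pairs
        out = (dev > thr) & (dev > 1e-6)
        cycles_run += 1
        if not out.any():
            break
        if keep.sum() - out.sum() < 3:
            raise ValueError("outlier rejection left fewer than 3 pairs")
        idx = np.flatnonzero(keep)
        keep[idx[out]] = False
    res.n_atoms_start = n_start
    res.n_atoms_used = int(keep.sum())
    res.cycles_run = cycles_run
    return res


# ---------------------------------------------------------------------------
# homolog survey

def _group_atoms(res: Residue, his_charged: bool) -> list[Atom]:
    """Charged-group atoms of a residue, falling back to side-chain polar."""
    grp = POSITIVE_GROUP.get(res.name) or NEGATIVE_GROUP.get(res.name)
    if grp is None and his_charged and res.name == "HIS":
        grp = HIS_GROUP
    if grp is None:
        grp = SIDECHAIN_POLAR.get(res.name, frozenset())
    return [a for a in res.atoms if a.name in grp]


def survey_salt_bridges(entries, cutoff: float = 3.5, alt_cutoff: float = 4.0,
                        his_charged: bool = False) -> pd.DataFrame:
    """Salt-bridge survey across homologous structures.

    ``entries`` is an iterable of (label, Structure, chain, pos_a, pos_b)
    where pos_a/pos_b are the residue numbers equivalent to the two
    salt-bridge partners (``None`` marks an unmappable position: the row
    is flagged, not dropped).  For each structure the minimum distance
    between the charged-group atoms of the two residues is reported with
    a verdict at ``cutoff`` and at ``alt_cutoff`` (sensitivity check).
    A bridge requires the two residues to be of opposite formal charge.
    """
    rows = []
    for label, s, chain, pos_a, pos_b in entries:
        row = {"structure": label, "chain": chain, "pos_a": pos_a,
               "pos_b": pos_b, "res_a": None, "res_b": None,
               "min_distance": math.nan,
               f"salt_bridge_{cutoff:g}A": False,
               f"salt_bridge_{alt_cutoff:g}A": False,
               "mapped": pos_a is not None and pos_b is not None}
        if row["mapped"]:
            try:
                ra = s.find_residue(chain, pos_a)
                rb = s.find_residue(chain, pos_b)
            except KeyError:
                row["mapped"] = False
                rows.append(row)
                continue
            row["res_a"], row["res_b"] = ra.name, rb.name
            atoms_a = _group_atoms(ra, his_charged)
            atoms_b = _group_atoms(rb, his_charged)
            if atoms_a and atoms_b:
                dmin = min(float(np.linalg.norm(a.pos - b.pos))
                           for a in atoms_a for b in atoms_b)
                row["min_distance"] = dmin
                ca = _charge_tag(ra.name, next(iter(_group_atoms(ra, his_charged))).name,
                                 his_charged) if atoms_a else 0
                cb = _charge_tag(rb.name, next(iter(_group_atoms(rb, his_charged))).name,
                                 his_charged) if atoms_b else 0
                opposite = ca * cb < 0
                row[f"salt_bridge_{cutoff:g}A"] = bool(opposite and dmin <= cutoff)
                row[f"salt_bridge_{alt_cutoff:g}A"] = bool(opposite and dmin <= alt_cutoff)
        rows.append(row)
    return pd.DataFrame(rows)


def map_equivalent_residue(reference_seq: str, reference_pos: int,
                           homolog: Structure,
                           chain: str | None = None) -> tuple[str, int] | None:
    """Map a 1-based reference-sequence position onto a homolog structure.

    Globally aligns the reference sequence with the homolog chain's
    polymer sequence; returns (chain, residue number) of the residue in
    the column holding ``reference_pos``, or None when that column is a
    gap in the homolog.
    """
    from .seqtools import global_align
    if chain is None:
        chains = [c for c in homolog.chains() if homolog.polymer_residues(c)]
        if not chains:
            raise ValueError("homolog has no polymer chain")
        chain = chains[0]
    res = homolog.polymer_residues(chain)
    if len(res) < 30:
        raise ValueError(f"chain {chain!r} has fewer than 30 residues")
    if not 1 <= reference_pos <= len(reference_seq):
        raise ValueError("reference_pos outside reference sequence")
    row_ref, row_hom = global_align(reference_seq, homolog.chain_sequence(chain))
    i_ref = i_hom = 0
    for x_ref, x_hom in zip(row_ref, row_hom):
        if x_ref != "-":
            i_ref += 1
        if x_hom != "-":
            i_hom += 1
        if x_ref != "-" and i_ref == reference_pos:
            if x_hom == "-":
                return None
            return chain, res[i_hom - 1].seqid
    return None
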