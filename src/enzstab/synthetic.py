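"""Synthetic inputs with known ground truth for every pipeline stage.

Defaults emulate the study conditions this package was written around:
a mesophilic GH1 beta-glucosidase melting near 324.6 K monitored by CD
at 222 nm over 10-80 degC, and initial-rate assays at 8 substrate
levels spanning 0.5-5x Km in triplicate.  Noise models are additive
Gaussian for ellipticity (instrument-like) and multiplicative Gaussian
for velocities (rate-assay-like).

Toy structures use idealized geometry: side-chain polar atoms are
placed directly at requested offsets, which is sufficient to exercise
distance and B-factor logic but is not stereochemically valid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .contacts import SIDECHAIN_POLAR, Structure, Residue, Atom, write_pdb
from .kinetics import KineticsDataset
from .seqtools import AlignmentSet
from .thermal import (ANCHOR_T_FOLDED, ANCHOR_T_UNFOLDED, MeltingCurve,
                      UnfoldingParams, predicted_ellipticity)

__all__ = [
    "MeltSimSpec",
    "KineticsSimSpec",
    "ToyAtomSpec",
    "ToyResidueSpec",
    "ToyStructureSpec",
    "simulate_melting_curve",
    "simulate_kinetics_dataset",
    "build_toy_structure",
    "build_toy_alignment",
]

#: residue names accepted by the toy-structure builder
SUPPORTED_RESIDUES = set(SIDECHAIN_POLAR) | {"DNJ", "HOH"}


@dataclass(frozen=True)
class MeltSimSpec:
    """Ground truth for one simulated CD melt (defaults: wild-type-like)."""

    tm_true: float = 324.6            # K
    dH_true: float = 300.0            # kJ/mol
    dCp_true: float = 0.0             # kJ/mol/K
    eps_folded: float = -580.7        # at 25 degC anchor
    eps_unfolded: float = -348.0      # at 80 degC anchor
    slope_folded: float = 0.0
    slope_unfolded: float = 0.0
    t_min: float = 283.15
    t_max: float = 353.15
    t_step: float = 0.5
    noise_sd: float = 4.0
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        if self.t_min >= self.t_max:
            raise ValueError("degenerate temperature grid: t_min >= t_max")
        if not (self.t_min < self.tm_true < self.t_max):
            raise ValueError("tm_true must lie inside the temperature grid")
        if self.dH_true <= 0:
            raise ValueError("dH_true must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.t_step <= 0:
            raise ValueError("t_step must be positive")

    def params(self) -> UnfoldingParams:
        return UnfoldingParams(
            tm=self.tm_true, dH=self.dH_true, dCp=self.dCp_true,
            eps_folded=self.eps_folded, eps_unfolded=self.eps_unfolded,
            slope_folded=self.slope_folded, slope_unfolded=self.slope_unfolded,
            anchor_T_folded=ANCHOR_T_FOLDED, anchor_T_unfolded=ANCHOR_T_UNFOLDED)


def simulate_melting_curve(spec: MeltSimSpec) -> MeltingCurve:
    """Two-state melt evaluated at ground truth plus i.i.d. Gaussian noise."""
    n = int(round((spec.t_max - spec.t_min) / spec.t_step)) + 1
    t = spec.t_min + spec.t_step * np.arange(n)
    t = t[t <= spec.t_max + 1e-9]
    y = predicted_ellipticity(spec.params(), t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=t.size)
    return MeltingCurve(t, np.asarray(y), label=spec.label or f"sim_tm{spec.tm_true:g}")


@dataclass(frozen=True)
class KineticsSimSpec:
    """Ground truth for one simulated initial-rate dataset."""

    kcat_true: float = 55.6           # 1/s
    km_true: float = 135.0            # uM
    enzyme_conc: float = 0.002        # uM
    substrate_levels: tuple[float, ...] | None = None   # uM; default 0.5-5x Km
    replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0
    substrate: str = "pNPGlu"
    label: str = ""

    def __post_init__(self):
        if self.kcat_true <= 0 or self.km_true <= 0 or self.enzyme_conc <= 0:
            raise ValueError("kinetic ground-truth values must be positive")
        if self.substrate_levels is not None:
            if len(self.substrate_levels) == 0:
                raise ValueError("substrate_levels must not be empty")
            if any(s <= 0 for s in self.substrate_levels):
                raise ValueError("substrate concentrations must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")

    def levels(self) -> np.ndarray:
        if self.substrate_levels is not None:
            return np.asarray(self.substrate_levels, dtype=float)
        return np.linspace(0.5, 5.0, 8) * self.km_true


def simulate_kinetics_dataset(spec: KineticsSimSpec) -> KineticsDataset:
    """v = kcat*E0*S/(Km+S) * (1 + eps), eps ~ N(0, cv^2), per replicate."""
    levels = spec.levels()
    s = np.repeat(levels, spec.replicates)
    v = spec.kcat_true * spec.enzyme_conc * s / (spec.km_true + s)
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        v = v * (1.0 + rng.normal(0.0, spec.noise_cv, size=s.size))
    return KineticsDataset(substrate_um=s, velocities=v,
                           enzyme_um=spec.enzyme_conc,
                           substrate=spec.substrate,
                           label=spec.label or "sim_kinetics")


@dataclass(frozen=True)
class ToyAtomSpec:
    name: str
    position: tuple[float, float, float]
    b: float = 20.0
    occ: float = 1.0


@dataclass(frozen=True)
class ToyResidueSpec:
    name: str
    seqid: int
    atoms: tuple[ToyAtomSpec, ...]
    het: bool = False


@dataclass(frozen=True)
class ToyStructureSpec:
    """Plan for a small multi-chain coordinate file.

    ``chains`` identical copies of ``residues`` are emitted, each chain
    offset by ``chain_offset`` along x so chains do not overlap.  The
    optional ligand (default residue name DNJ, a 1-deoxynojirimycin
    stand-in) is attached to the first chain.
    """

    residues: tuple[ToyResidueSpec, ...]
    chains: int = 1
    chain_offset: float = 100.0
    ligand: ToyResidueSpec | None = None
    id: str = "toy"

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("need at least one chain")
        for r in list(self.residues) + ([self.ligand] if self.ligand else []):
            if r.name not in SUPPORTED_RESIDUES:
                raise ValueError(f"unsupported residue name {r.name!r}")
            for a in r.atoms:
                if not all(np.isfinite(a.position)):
                    raise ValueError(f"non-finite coordinates for {r.name} {a.name}")
                if a.b <= 0:
                    raise ValueError("B-factors must be positive")


_ELEMENT_FROM_NAME = {"N": "N", "O": "O", "C": "C", "S": "S", "H": "H"}


def _element(atom_name: str) -> str:
    return _ELEMENT_FROM_NAME.get(atom_name[0], atom_name[0])


def build_toy_structure(spec: ToyStructureSpec) -> tuple[Structure, str]:
    """Materialize the plan as a Structure plus serialized PDB text."""
    chain_names = [chr(ord("A") + i) for i in range(spec.chains)]
    st = Structure(id=spec.id)
    for i, cname in enumerate(chain_names):
        shift = np.array([spec.chain_offset * i, 0.0, 0.0])
        for rspec in spec.residues:
            res = Residue(chain=cname, name=rspec.name, seqid=rspec.seqid,
                          het=rspec.het or rspec.name in ("DNJ", "HOH"),
                          is_water=rspec.name == "HOH")
            for aspec in rspec.atoms:
                res.atoms.append(Atom(
                    name=aspec.name, element=_element(aspec.name),
                    pos=np.asarray(aspec.position, dtype=float) + shift,
                    b=aspec.b, occ=aspec.occ))
            st.residues.append(res)
    if spec.ligand is not None:
        res = Residue(chain=chain_names[0], name=spec.ligand.name,
                      seqid=spec.ligand.seqid, het=True,
                      is_water=spec.ligand.name == "HOH")
        for aspec in spec.ligand.atoms:
            res.atoms.append(Atom(
                name=aspec.name, element=_element(aspec.name),
                pos=np.asarray(aspec.position, dtype=float),
                b=aspec.b, occ=aspec.occ))
        st.residues.append(res)
    return st, write_pdb(st)


def build_toy_alignment(n_seqs: int,
                        column_plan: Mapping[int, str | Sequence[str]],
                        seed: int = 0, length: int = 30,
                        reference: str = "seq1") -> AlignmentSet:
    """Toy FASTA-serializable alignment with controlled column composition.

    ``column_plan`` maps 1-based column positions to either a single
    residue letter (placed in every row) or a sequence of ``n_seqs``
    letters (one per row, may include '-').  Unplanned columns hold the
    same randomly drawn residue in every row.
    """
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    rng = np.random.default_rng(seed)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    base = rng.choice(aa, size=length)
    rows = [list(base) for _ in range(n_seqs)]
    for pos, plan in column_plan.items():
        if not 1 <= pos <= length:
            raise ValueError(f"column {pos} outside alignment length {length}")
        if isinstance(plan, str) and len(plan) == 1:
            for row in rows:
                row[pos - 1] = plan
        else:
            if len(plan) != n_seqs:
                raise ValueError(f"column {pos}: plan must have {n_seqs} letters")
            for row, ch in zip(rows, plan):
                row[pos - 1] = ch
    return AlignmentSet(
        rows=[(f"seq{i + 1}", "".join(row)) for i, row in enumerate(rows)],
        reference=reference)
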