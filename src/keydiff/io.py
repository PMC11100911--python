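"""Structure I/O: pockets from PDB, ligands as SDF V2000.

Pockets are extracted around a reference ligand with residue-complete
inclusion: a residue enters the pocket if any of its atoms lies within the
extraction radius of any ligand atom.  Two representations are supported —
all heavy atoms (element one-hot features) or one node per residue at the
Cα position (residue-type one-hot features).

Generated ligands are geometric point clouds, so SDF output carries 3D
coordinates and elements but no bond block; bond perception is deliberately
left to downstream tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem  # noqa: F401  (registers conformer support)
from scipy.spatial.distance import cdist

from .core import AtomCloud, ElementVocabulary, PROTEIN_VOCAB

__all__ = [
    "PocketExtractionConfig",
    "EmptyPocketError",
    "AMINO_VOCAB",
    "read_pocket",
    "read_ligand_sdf",
    "write_ligand_sdf",
    "write_pocket_pdb",
]

AMINO_ACIDS = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL UNK"
).split()
AMINO_VOCAB = ElementVocabulary(tuple(AMINO_ACIDS))


class EmptyPocketError(ValueError):
    """No residue has an atom within the extraction radius of the ligand."""


@dataclass(frozen=True)
class PocketExtractionConfig:
    radius: float = 8.0  # Å
    representation: str = "all-atom"  # or "calpha"
    include_hydrogens: bool = False

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.representation not in ("all-atom", "calpha"):
            raise ValueError(f"unknown representation {self.representation!r}")


def _read_structure(source) -> gemmi.Structure:
    if isinstance(source, gemmi.Structure):
        return source
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    return st


def read_pocket(
    pdb_source,
    reference_ligand: AtomCloud,
    cfg: PocketExtractionConfig | None = None,
    vocab: ElementVocabulary = PROTEIN_VOCAB,
) -> AtomCloud:
    """Extract the binding pocket around a reference ligand.

    ``pdb_source`` may be a path, PDB text, a file object, or a parsed gemmi
    Structure.  Only the first model is used; for alternate locations the
    first conformer is kept.  Raises :class:`EmptyPocketError` when no
    residue is in range.
    """
    cfg = cfg or PocketExtractionConfig()
    if reference_ligand.n_atoms < 1:
        raise ValueError("reference ligand is empty")
    st = _read_structure(pdb_source)
    if len(st) == 0:
        raise ValueError("PDB contains no models")
    model = st[0]
    lig_pos = reference_ligand.positions

    positions: list[np.ndarray] = []
    symbols: list[str] = []
    for chain in model:
        for residue in chain:
            if residue.name == "HOH":
                continue
            atoms = [a for a in residue if a.altloc in ("\x00", "", " ", "A")]
            heavy = [a for a in atoms if a.element.name != "H"]
            candidates = atoms if cfg.include_hydrogens else heavy
            if not candidates:
                continue
            coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in candidates])
            if cdist(coords, lig_pos).min() >= cfg.radius:
                continue
            if cfg.representation == "calpha":
                ca = next((a for a in atoms if a.name == "CA"), None)
                if ca is None:
                    warnings.warn(f"residue {residue.name} {residue.seqid}: no Cα, skipped")
                    continue
                positions.append(np.array([ca.pos.x, ca.pos.y, ca.pos.z]))
                symbols.append(residue.name if residue.name in AMINO_ACIDS else "UNK")
            else:
                for a in candidates:
                    elem = a.element.name
                    if elem not in vocab.symbols:
                        warnings.warn(f"element {elem} outside vocabulary, atom skipped")
                        continue
                    positions.append(np.array([a.pos.x, a.pos.y, a.pos.z]))
                    symbols.append(elem)
    if not positions:
        raise EmptyPocketError(f"no residue within {cfg.radius} Å of the ligand")
    feat_vocab = AMINO_VOCAB if cfg.representation == "calpha" else vocab
    return AtomCloud(np.asarray(positions), feat_vocab.one_hot(symbols), kind="pocket")


def _sdf_text(source) -> str:
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        return Path(source).read_text()
    if isinstance(source, str):
        return source
    return source.read()


def read_ligand_sdf(sdf_source, vocab: ElementVocabulary) -> AtomCloud:
    """Read the first V2000 record into an AtomCloud with one-hot features."""
    text = _sdf_text(sdf_source)
    mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    if mol is None:
        raise ValueError("malformed SDF record")
    if mol.GetNumConformers() == 0:
        raise ValueError("SDF record has no coordinates")
    conf = mol.GetConformer()
    symbols = [atom.GetSymbol() for atom in mol.GetAtoms()]
    for s in symbols:
        if s not in vocab.symbols:
            raise KeyError(f"element {s!r} not in vocabulary {vocab.symbols}")
    pos = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
                    for i in range(mol.GetNumAtoms())])
    return AtomCloud(pos, vocab.one_hot(symbols), kind="ligand")


def write_ligand_sdf(ligand: AtomCloud, vocab: ElementVocabulary, sink) -> None:
    """Write a decoded ligand as one V2000 record (no bond block).

    The features must be exact one-hot — noisy intermediate states have to
    be decoded before serialisation.
    """
    if not ligand.is_one_hot():
        raise ValueError("features are not one-hot; decode the sample first")
    mol = Chem.RWMol()
    for symbol in vocab.decode(ligand.features):
        atom = Chem.Atom(symbol)
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    conf = Chem.Conformer(ligand.n_atoms)
    for i, p in enumerate(ligand.positions):
        conf.SetAtomPosition(i, tuple(float(v) for v in p))
    mol.AddConformer(conf)
    block = Chem.MolToMolBlock(mol.GetMol(), kekulize=False) + "$$$$\n"
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(block)
    else:
        sink.write(block)


def write_pocket_pdb(pocket: AtomCloud, vocab: ElementVocabulary, sink) -> None:
    """Write a pocket cloud as a PDB file, one single-atom residue per node
    (used to emit synthetic fixtures for the CLI round trip)."""
    st = gemmi.Structure()
    st.name = "pocket"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    symbols = vocab.decode(pocket.features)
    for i, (pos, sym) in enumerate(zip(pocket.positions, symbols), start=1):
        res = gemmi.Residue()
        res.name = "UNK"
        res.seqid = gemmi.SeqId(i, " ")
        res.het_flag = "A"
        atom = gemmi.Atom()
        atom.name = sym
        atom.element = gemmi.Element(sym)
        atom.pos = gemmi.Position(*pos)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    text = st.make_pdb_string()
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)
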