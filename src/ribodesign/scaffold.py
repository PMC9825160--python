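"""Fixed structural context for design campaigns.

A design problem is posed against a rigid crystal scaffold: the residues to
be redesigned plus every residue with a heavy atom inside a distance sphere
around them (RNA, protein and ions alike).  From that neighborhood two
models are derived — a *native* model containing designed and neighbor
residues, and a *starting* model with the designed residues omitted — plus
a numbered FASTA record set and the list of primary-sequence neighbors that
should stay minimizable next to the flexible designed region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ResidueSelection",
    "ScaffoldContext",
    "FastaSegment",
    "load_structure",
    "select_sphere_neighborhood",
    "adjacent_min_res",
    "split_native_starting",
    "context_to_fasta",
    "write_pdb",
    "write_fasta",
]

PolymerClass = Literal["rna", "protein", "other"]

# one-letter codes; RNA lowercase by convention, protein uppercase
_RNA_ONE = {"A": "a", "C": "c", "G": "g", "U": "u"}
_PROTEIN_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass(frozen=True)
class Residue:
    chain: str
    number: int
    name: str
    polymer_class: PolymerClass
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.number)


class Structure:
    """An ordered collection of residues with unique (chain, number) keys."""

    def __init__(self, residues: Iterable[Residue], name: str = ""):
        self.residues: list[Residue] = list(residues)
        self.name = name
        self._index: dict[tuple[str, int], Residue] = {}
        for res in self.residues:
            if not res.atoms:
                raise ValueError(f"residue {res.chain}:{res.number} has no atoms")
            if res.key in self._index:
                raise ValueError(
                    f"duplicate residue number {res.number} in chain {res.chain}"
                )
            for atom in res.atoms:
                if not all(math.isfinite(v) for v in atom.xyz):
                    raise ValueError(
                        f"non-finite coordinate in residue {res.chain}:{res.number}"
                    )
            self._index[res.key] = res
        if not self.residues:
            raise ValueError("structure contains no residues")

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._index

    def __getitem__(self, key: tuple[str, int]) -> Residue:
        return self._index[key]

    def subset(self, keys: Iterable[tuple[str, int]], name: str = "") -> "Structure":
        keyset = set(keys)
        return Structure(
            (r for r in self.residues if r.key in keyset),
            name=name or self.name,
        )

    def keys(self) -> list[tuple[str, int]]:
        return [r.key for r in self.residues]


@dataclass(frozen=True)
class ResidueSelection:
    """A labelled, ordered set of (chain, residue-number) identifiers."""

    ids: tuple[tuple[str, int], ...]
    label: str = ""

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError(f"selection {self.label!r} contains duplicate ids")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __contains__(self, key) -> bool:
        return key in set(self.ids)

    def resolve(self, s: Structure) -> list[Residue]:
        missing = [key for key in self.ids if key not in s]
        if missing:
            raise KeyError(
                f"selection {self.label!r}: residues not in structure: "
                + ", ".join(f"{c}:{n}" for c, n in missing)
            )
        return [s[key] for key in self.ids]

    @classmethod
    def from_spec(cls, text: str, label: str = "") -> "ResidueSelection":
        """Parse ``chain:start-end[,chain:n,...]`` selection syntax."""
        ids: list[tuple[str, int]] = []
        for part in text.split(","):
            part = part.strip()
            chain, _, rng = part.partition(":")
            if not rng:
                raise ValueError(f"bad selection token {part!r}: expected chain:range")
            lo, dash, hi = rng.partition("-")
            if dash and lo and hi:
                ids.extend((chain, n) for n in range(int(lo), int(hi) + 1))
            else:
                ids.append((chain, int(rng)))
        return cls(tuple(ids), label=label or text)


@dataclass(frozen=True)
class ScaffoldContext:
    """Designed residues plus their distance-sphere neighborhood."""

    structure: Structure
    designed: ResidueSelection
    neighbors: ResidueSelection
    radius: float
    min_res: ResidueSelection = field(default_factory=lambda: ResidueSelection((), "min_res"))

    def __post_init__(self):
        overlap = set(self.designed.ids) & set(self.neighbors.ids)
        if overlap:
            raise ValueError(f"designed and neighbor selections overlap: {sorted(overlap)}")
        if set(self.min_res.ids) & set(self.designed.ids):
            raise ValueError("min_res must exclude designed residues")


def _classify(name: str) -> PolymerClass:
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        if info.is_nucleic_acid():
            return "rna"
        if info.is_amino_acid():
            return "protein"
        return "other"
    if name in _RNA_ONE:
        return "rna"
    if name in _PROTEIN_ONE:
        return "protein"
    return "other"


def load_structure(path: str | Path, format: str | None = None) -> Structure:
    """Load a PDB or mmCIF file into a :class:`Structure`.

    Author residue numbering is preserved as deposited; heteroatoms and ions
    are retained with polymer class ``other``.  Only the first model of
    multi-model files is read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt_map = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}
    try:
        if format is None:
            st = gemmi.read_structure(str(path))
        else:
            if format not in fmt_map:
                raise ValueError(f"unknown format {format!r}; expected pdb or mmcif")
            st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise ValueError(f"cannot parse {path.name} as {format or 'auto'}: {exc}") from exc
    if len(st) == 0 or all(len(chain) == 0 for chain in st[0]):
        raise ValueError(f"{path.name}: file contains no residues (empty model)")
    st.setup_entities()
    residues: list[Residue] = []
    model = st[0]
    for chain in model:
        for res in chain:
            atoms = tuple(
                Atom(a.name, a.element.name or "C", a.pos.x, a.pos.y, a.pos.z)
                for a in res
            )
            residues.append(
                Residue(
                    chain=chain.name,
                    number=res.seqid.num,
                    name=res.name.strip(),
                    polymer_class=_classify(res.name.strip()),
                    atoms=atoms,
                )
            )
    return Structure(residues, name=path.stem)


def _heavy_coords(res: Residue) -> np.ndarray:
    pts = [a.xyz for a in res.atoms if a.is_heavy]
    return np.asarray(pts, dtype=float).reshape(-1, 3)


def select_sphere_neighborhood(
    s: Structure, designed: ResidueSelection, radius: float
) -> ScaffoldContext:
    """Expand a designed-residue selection to a distance-sphere neighborhood.

    A residue (any chain, any polymer class, ions included) is a neighbor if
    at least one of its heavy atoms lies within ``radius`` (Euclidean, <=)
    of any heavy atom of any designed residue.  Designed residues are never
    their own neighbors.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    designed_res = designed.resolve(s)
    designed_keys = set(designed.ids)
    dpts = np.vstack([_heavy_coords(r) for r in designed_res])
    neighbor_keys: list[tuple[str, int]] = []
    for res in s.residues:
        if res.key in designed_keys:
            continue
        pts = _heavy_coords(res)
        if pts.size == 0:
            continue
        d2 = np.sum((pts[:, None, :] - dpts[None, :, :]) ** 2, axis=-1)
        if radius > 0 and d2.min() <= radius * radius:
            neighbor_keys.append(res.key)
    neighbors = ResidueSelection(tuple(neighbor_keys), label=f"sphere@{radius:g}A")
    min_res = adjacent_min_res(s, designed)
    return ScaffoldContext(
        structure=s,
        designed=designed,
        neighbors=neighbors,
        radius=radius,
        min_res=min_res,
    )


def adjacent_min_res(s: Structure, designed: ResidueSelection) -> ResidueSelection:
    """Primary-sequence neighbors (n-1, n+1) of the designed residues.

    These flank the flexible designed region and should stay minimizable
    while the rest of the scaffold is held rigid.  Designed residues and
    positions absent from the structure are excluded; result deduplicated
    and sorted by (chain, number).
    """
    designed.resolve(s)
    designed_keys = set(designed.ids)
    out = set()
    for chain, num in designed.ids:
        for adj in (num - 1, num + 1):
            key = (chain, adj)
            if key in s and key not in designed_keys:
                out.add(key)
    return ResidueSelection(tuple(sorted(out)), label="min_res")


def split_native_starting(ctx: ScaffoldContext) -> tuple[Structure, Structure]:
    """Split a context into native (designed + neighbors) and starting
    (neighbors only) models, both keeping original coordinates/numbering."""
    native_keys = list(ctx.designed.ids) + list(ctx.neighbors.ids)
    native = ctx.structure.subset(native_keys, name="native")
    starting = ctx.structure.subset(ctx.neighbors.ids, name="starting")
    return native, starting


@dataclass(frozen=True)
class FastaSegment:
    """One contiguously numbered chain segment of a model's sequence."""

    chain: str
    start: int
    end: int
    sequence: str

    @property
    def header(self) -> str:
        return f"{self.chain}:{self.start}-{self.end}"

    def position_of(self, i: int) -> int:
        """Residue number of the i-th (0-based) letter."""
        return self.start + i


def _one_letter(res: Residue) -> str:
    if res.polymer_class == "rna":
        letter = _RNA_ONE.get(res.name)
        if letter is None and len(res.name) == 1:
            letter = res.name.lower() if res.name.upper() in _RNA_ONE else None
        if letter is None:
            raise ValueError(f"unknown RNA residue name {res.name!r} at {res.chain}:{res.number}")
        return letter
    if res.polymer_class == "protein":
        letter = _PROTEIN_ONE.get(res.name)
        if letter is None:
            raise ValueError(
                f"unknown protein residue name {res.name!r} at {res.chain}:{res.number}"
            )
        return letter
    raise ValueError(f"residue {res.name!r} at {res.chain}:{res.number} is not a polymer")


def context_to_fasta(model: Structure) -> list[FastaSegment]:
    """Numbered sequence records for a model: RNA lowercase, protein
    uppercase, one segment per contiguous numbering run within a chain.

    Non-polymer residues (ions, ligands) are skipped — they have no
    sequence representation.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    segments: list[FastaSegment] = []
    cur_chain, cur_start, cur_end, letters = None, None, None, []

    def flush():
        if letters:
            segments.append(FastaSegment(cur_chain, cur_start, cur_end, "".join(letters)))

    for res in model.residues:
        if res.polymer_class == "other":
            continue
        letter = _one_letter(res)
        if res.chain != cur_chain or cur_end is None or res.number != cur_end + 1:
            flush()
            cur_chain, cur_start, letters = res.chain, res.number, []
        letters.append(letter)
        cur_end = res.number
    flush()
    return segments


def write_fasta(segments: Sequence[FastaSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f">{seg.header}\n{seg.sequence}\n")


def write_pdb(s: Structure, path: str | Path) -> None:
    """Serialize as fixed-width PDB v3.3 ATOM/HETATM records."""
    serial = 0
    with open(path, "w") as fh:
        for res in s.residues:
            record = "ATOM  " if res.polymer_class in ("rna", "protein") else "HETATM"
            for atom in res.atoms:
                serial += 1
                name = atom.name
                # v3.3 alignment: element-left-justified names start col 14
                padded = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"{record}{serial:5d} {padded:<4s} {res.name:>3s} "
                    f"{res.chain[:1]}{res.number:4d}    "
                    f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          "
                    f"{atom.element.upper():>2s}\n"
                )
        fh.write("END\n")


def write_min_res(selection: ResidueSelection, path: str | Path) -> None:
    """Minimize-adjacent residue list as whitespace-separated chain:number tokens."""
    with open(path, "w") as fh:
        fh.write(" ".join(f"{c}:{n}" for c, n in selection.ids) + "\n")
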