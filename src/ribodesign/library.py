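"""Anything-but-wildtype design libraries over nucleotide identity.

A library region names a set of structure positions and, per position, the
wild-type base and the set of replacement bases allowed there.  The default
library style excludes the wild-type base at every designed position,
written compactly with the IUPAC ambiguity letters b/d/h/v ("not a/c/g/u").
Variants from several regions combine into combinatorial constructs by
Cartesian product, each region contributing either its wild-type sequence
or one of its variants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RNA_BASES",
    "AMBIGUITY",
    "LibraryPosition",
    "LibraryDefinition",
    "SequenceVariant",
    "CombinatorialConstruct",
    "encode_anything_but_wt",
    "expand_ambiguity",
    "enumerate_library",
    "build_combinations",
    "apply_to_reference",
]

RNA_BASES = ("a", "c", "g", "u")

# IUPAC: b/d/h/v exclude a/c/g/u respectively; n is fully ambiguous
AMBIGUITY = {
    "a": frozenset("a"),
    "c": frozenset("c"),
    "g": frozenset("g"),
    "u": frozenset("u"),
    "b": frozenset("cgu"),
    "d": frozenset("agu"),
    "h": frozenset("acu"),
    "v": frozenset("acg"),
    "n": frozenset("acgu"),
}
_NOT_WT = {"a": "b", "c": "d", "g": "h", "u": "v"}


def encode_anything_but_wt(seq: str, designed_mask: Iterable[int]) -> str:
    """Replace masked positions of a lowercase RNA string with the
    anything-but-that-base ambiguity code (a->b, c->d, g->h, u->v)."""
    mask = set(designed_mask)
    bad = [i for i in mask if not 0 <= i < len(seq)]
    if bad:
        raise IndexError(f"mask positions out of range: {sorted(bad)}")
    out = []
    for i, base in enumerate(seq):
        if base not in RNA_BASES:
            raise ValueError(f"non-RNA character {base!r} at position {i}")
        out.append(_NOT_WT[base] if i in mask else base)
    return "".join(out)


def expand_ambiguity(code: str) -> frozenset[str]:
    """Base set denoted by a single (lowercase) IUPAC RNA letter."""
    try:
        return AMBIGUITY[code]
    except KeyError:
        raise ValueError(f"unknown ambiguity code {code!r}") from None


@dataclass(frozen=True)
class LibraryPosition:
    chain: str
    number: int
    wild_type: str
    allowed: frozenset[str]

    def __post_init__(self):
        if self.wild_type not in RNA_BASES:
            raise ValueError(f"wild-type base must be one of acgu, got {self.wild_type!r}")
        if not self.allowed:
            raise ValueError(f"empty allowed set at {self.chain}:{self.number}")
        if not self.allowed <= set(RNA_BASES):
            raise ValueError(f"allowed set {set(self.allowed)} not a subset of acgu")


@dataclass(frozen=True)
class LibraryDefinition:
    """One design region: ordered positions with wild type and allowed bases."""

    region: str
    positions: tuple[LibraryPosition, ...]
    strand_lengths: tuple[int, ...] = ()

    def __post_init__(self):
        if not self.positions:
            raise ValueError("library has no positions")
        if self.strand_lengths and sum(self.strand_lengths) != len(self.positions):
            raise ValueError("strand lengths do not sum to position count")

    @classmethod
    def anything_but_wt(
        cls,
        region: str,
        positions: Sequence[tuple[str, int, str]],
        strand_lengths: Sequence[int] = (),
    ) -> "LibraryDefinition":
        """Build the standard library style: every position may take any
        base except its wild-type identity (|allowed| = 3)."""
        pos = tuple(
            LibraryPosition(c, n, wt, AMBIGUITY[_NOT_WT[wt]])
            for c, n, wt in positions
        )
        return cls(region, pos, tuple(strand_lengths))

    @property
    def wild_type(self) -> str:
        return "".join(p.wild_type for p in self.positions)

    @property
    def size(self) -> int:
        out = 1
        for p in self.positions:
            out *= len(p.allowed)
        return out

    def ambiguity_string(self) -> str:
        """Library written as IUPAC letters, one per position."""
        inv = {v: k for k, v in AMBIGUITY.items()}
        return "".join(inv[p.allowed] for p in self.positions)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SequenceVariant:
    """A concrete base assignment for one library region."""

    region: str
    variant_id: str
    bases: str
    strand_lengths: tuple[int, ...] = ()

    def __post_init__(self):
        if self.strand_lengths and sum(self.strand_lengths) != len(self.bases):
            raise ValueError("strand lengths do not sum to sequence length")

    def strands(self) -> tuple[str, ...]:
        if not self.strand_lengths:
            return (self.bases,)
        out, i = [], 0
        for ln in self.strand_lengths:
            out.append(self.bases[i : i + ln])
            i += ln
        return tuple(out)

    def display(self) -> str:
        """Strand-grouped display notation, e.g. ``(cggu,gcgc)``."""
        return "(" + ",".join(self.strands()) + ")"

    def mutations_vs(self, lib: LibraryDefinition) -> int:
        return sum(b != p.wild_type for b, p in zip(self.bases, lib.positions))


def _validate_variant(bases: str, lib: LibraryDefinition) -> None:
    if len(bases) != len(lib):
        raise ValueError(f"variant length {len(bases)} != library length {len(lib)}")
    for i, (b, p) in enumerate(zip(bases, lib.positions)):
        if b not in p.allowed and b != p.wild_type:
            raise ValueError(
                f"base {b!r} at position {i} not allowed at {p.chain}:{p.number}"
            )


def _index_to_bases(idx: int, alphabets: Sequence[Sequence[str]]) -> str:
    # mixed-radix decode, most significant digit first => lexicographic order
    out = []
    for alpha in reversed(alphabets):
        idx, digit = divmod(idx, len(alpha))
        out.append(alpha[digit])
    return "".join(reversed(out))


def enumerate_library(
    lib: LibraryDefinition, cap: int = 10_000, seed: int = 0
) -> list[SequenceVariant]:
    """Enumerate or sample the variant space of a library.

    Exhaustive in lexicographic order (a<c<g<u) when the space fits under
    ``cap``; otherwise a seeded uniform sample without replacement of size
    ``cap``.  Variant ids are ``REGION.k`` in emission order.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    alphabets = [sorted(p.allowed) for p in lib.positions]
    total = lib.size
    if total <= cap:
        indices: Iterable[int] = range(total)
    else:
        rng = np.random.default_rng(seed)
        if total <= 50_000_000:
            indices = sorted(rng.choice(total, size=cap, replace=False).tolist())
        else:
            chosen: set[int] = set()
            while len(chosen) < cap:
                chosen.add(int(rng.integers(total)))
            indices = sorted(chosen)
    return [
        SequenceVariant(
            region=lib.region,
            variant_id=f"{lib.region}.{k}",
            bases=_index_to_bases(idx, alphabets),
            strand_lengths=lib.strand_lengths,
        )
        for k, idx in enumerate(indices, start=1)
    ]


@dataclass(frozen=True)
class CombinatorialConstruct:
    """A multi-region construct: per region either WT (None) or a variant."""

    construct_id: str
    choices: tuple[tuple[str, SequenceVariant | None], ...]
    mutated_positions: int

    @property
    def regions_mutated(self) -> tuple[str, ...]:
        return tuple(r for r, v in self.choices if v is not None)

    def label(self) -> str:
        parts = [v.variant_id for _, v in self.choices if v is not None]
        return "+".join(parts) if parts else "WT"


def build_combinations(
    regions: Sequence[tuple[LibraryDefinition, Sequence[SequenceVariant]]],
    id_prefix: str = "C",
) -> list[CombinatorialConstruct]:
    """Cartesian product over per-region option sets {WT} U variants.

    Includes the all-WT construct; count = prod(1 + v_i).  Ids are assigned
    in product order (later regions vary fastest), starting at 1.
    """
    for lib, variants in regions:
        ids = [v.variant_id for v in variants]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate variant ids in region {lib.region}")
        for v in variants:
            _validate_variant(v.bases, lib)
    option_sets = [
        [(lib, None)] + [(lib, v) for v in variants] for lib, variants in regions
    ]
    constructs = []
    for k, combo in enumerate(itertools.product(*option_sets), start=1):
        mutated = sum(
            v.mutations_vs(lib) for lib, v in combo if v is not None
        )
        constructs.append(
            CombinatorialConstruct(
                construct_id=f"{id_prefix}{k}",
                choices=tuple((lib.region, v) for lib, v in combo),
                mutated_positions=mutated,
            )
        )
    return constructs


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference gene sequence with explicit residue numbering."""

    sequence: str
    first_number: int = 1
    chain: str = "A"

    def base_at(self, number: int) -> str:
        i = number - self.first_number
        if not 0 <= i < len(self.sequence):
            raise KeyError(f"position {number} outside reference numbering")
        return self.sequence[i]


def apply_to_reference(
    ref: ReferenceSequence,
    construct: CombinatorialConstruct,
    libraries: Sequence[LibraryDefinition],
) -> tuple[str, int]:
    """Apply a construct's substitutions to a reference sequence.

    The reference base at every library position must equal the library's
    recorded wild type — a guard against numbering drift.  Returns the
    mutant sequence and the realized mutated-position count.
    """
    lib_by_region = {lib.region: lib for lib in libraries}
    seq = list(ref.sequence)
    n_mut = 0
    for region, variant in construct.choices:
        lib = lib_by_region.get(region)
        if lib is None:
            raise KeyError(f"no library definition supplied for region {region}")
        for i, pos in enumerate(lib.positions):
            ref_base = ref.base_at(pos.number)
            if ref_base != pos.wild_type:
                raise ValueError(
                    f"wild-type mismatch at {pos.chain}:{pos.number}: "
                    f"reference has {ref_base!r}, library records {pos.wild_type!r}"
                )
            if variant is not None and variant.bases[i] != pos.wild_type:
                seq[pos.number - ref.first_number] = variant.bases[i]
                n_mut += 1
    return "".join(seq), n_mut
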