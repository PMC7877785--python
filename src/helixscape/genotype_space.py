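"""Encoding and combinatorics of the 4^8 intron genotype space.

The mutagenized region of the group I intron consists of two 4-base
sub-regions, sites 2-5 and sites 18-21 (1-based intron numbering).  A
genotype is written ``"LLLL-RRRR"`` where ``LLLL`` are the bases at sites
2-5 and ``RRRR`` the bases at sites 18-21; the hyphen is optional on
input.  The two sub-regions come together to form the P1 extension
(P1ex) helix, pairing site 2 with 21, 3 with 20, 4 with 19 and 5 with 18.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

ALPHABET = "ACGT"
SITES: tuple[int, ...] = (2, 3, 4, 5, 18, 19, 20, 21)
#: index of each 1-based site label in the 8-character genotype string
SITE_INDEX: dict[int, int] = {s: i for i, s in enumerate(SITES)}

#: the high-activity reference all fitness values are relative to
MASTER = "AGGT-ACAT"

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}
_STRONG = {("G", "C"), ("C", "G")}
_WEAK = {("A", "T"), ("T", "A")}


class ResourceLimitError(ValueError):
    """Raised when an enumeration would exceed the configured size guard."""


@dataclass(frozen=True)
class PairingScheme:
    """Which sites pair with which in a forced helix.

    ``wobble_policy`` controls how a G·T apposition is classified by
    :func:`pair_profile`: ``"separate_class"`` (default) counts it in its
    own ``wobble`` slot, ``"count_as_weak"`` lumps it with A·T pairs and
    ``"exclude"`` counts it as unpaired.
    """

    pairs: tuple[tuple[int, int], ...]
    wobble_policy: str = "separate_class"

    def __post_init__(self) -> None:
        flat = [s for p in self.pairs for s in p]
        if len(set(flat)) != len(flat):
            raise ValueError("each site may appear at most once in a scheme")
        if self.wobble_policy not in ("separate_class", "count_as_weak", "exclude"):
            raise ValueError(f"unknown wobble_policy {self.wobble_policy!r}")


#: P1ex pairing: site 2 with 21, 3 with 20, 4 with 19, 5 with 18
P1EX_SCHEME = PairingScheme(pairs=((2, 21), (3, 20), (4, 19), (5, 18)))


@dataclass(frozen=True)
class PairProfile:
    strong: int
    weak: int
    wobble: int
    unpaired: int

    @property
    def paired(self) -> int:
        return self.strong + self.weak + self.wobble

    def total(self) -> int:
        return self.strong + self.weak + self.wobble + self.unpaired


@dataclass(frozen=True)
class Genotype:
    """An 8-site genotype: 4 bases at sites 2-5 and 4 at sites 18-21."""

    left: str
    right: str

    def __post_init__(self) -> None:
        if len(self.left) != 4 or len(self.right) != 4:
            raise ValueError("genotype sub-regions must each have 4 bases")
        for b in self.left + self.right:
            if b not in ALPHABET:
                raise ValueError(f"invalid base {b!r}; alphabet is {ALPHABET}")

    @property
    def seq(self) -> str:
        """The 8 bases without the hyphen, sites 2-5 then 18-21."""
        return self.left + self.right

    def __str__(self) -> str:
        return f"{self.left}-{self.right}"

    def base(self, site: int) -> str:
        return self.seq[SITE_INDEX[site]]

    def d(self, reference: "Genotype | str" = MASTER) -> int:
        """Hamming distance to ``reference`` (default: the master)."""
        return hamming(self, reference)


def parse_genotype(text: str | Genotype) -> Genotype:
    """Parse ``"LLLL-RRRR"`` or ``"LLLLRRRR"`` into a :class:`Genotype`."""
    if isinstance(text, Genotype):
        return text
    s = text.replace("-", "").strip().upper()
    if len(s) != 8:
        raise ValueError(f"expected 8 variable bases, got {text!r}")
    return Genotype(s[:4], s[4:])


def _seq(g: Genotype | str) -> str:
    if isinstance(g, Genotype):
        return g.seq
    return parse_genotype(g).seq


def enumerate_genotypes(
    n_sites: int = 8, alphabet_size: int = 4, max_sites: int = 12
) -> list[str]:
    """All ``alphabet_size**n_sites`` sequences in lexicographic order.

    For the default 8-site case the strings are full genotypes (sites
    2-5 followed by 18-21).  ``n_sites`` above ``max_sites`` raises
    :class:`ResourceLimitError` rather than exhausting memory.
    """
    if n_sites <= 0 or alphabet_size <= 0:
        raise ValueError("n_sites and alphabet_size must be positive")
    if alphabet_size > len(ALPHABET):
        raise ValueError(f"alphabet_size must be <= {len(ALPHABET)}")
    if n_sites > max_sites:
        raise ResourceLimitError(
            f"n_sites={n_sites} exceeds the guard of {max_sites} "
            f"({alphabet_size ** n_sites:,} sequences)"
        )
    letters = ALPHABET[:alphabet_size]
    return ["".join(p) for p in itertools.product(letters, repeat=n_sites)]


def hamming(g1: Genotype | str, g2: Genotype | str) -> int:
    """Number of sites at which two equal-length sequences differ."""
    s1 = g1.seq if isinstance(g1, Genotype) else g1.replace("-", "").upper()
    s2 = g2.seq if isinstance(g2, Genotype) else g2.replace("-", "").upper()
    if len(s1) != len(s2):
        raise ValueError(f"length mismatch: {len(s1)} vs {len(s2)}")
    return sum(a != b for a, b in zip(s1, s2))


def mirror(g: Genotype | str) -> Genotype:
    """Reflect a genotype across the P1ex helix axis.

    The helix pairs site 2 with 21, 3 with 20, 4 with 19 and 5 with 18,
    so the reflection carries the bases at sites 18-21 (reversed) onto
    sites 2-5 and vice versa.  The operation is an involution and
    preserves Hamming distances.
    """
    gt = parse_genotype(g) if not isinstance(g, Genotype) else g
    return Genotype(left=gt.right[::-1], right=gt.left[::-1])


def pair_profile(g: Genotype | str, scheme: PairingScheme = P1EX_SCHEME) -> PairProfile:
    """Classify each scheme pair of ``g`` as strong (G·C), weak (A·T),
    wobble (G·T, per the scheme's policy) or unpaired."""
    gt = parse_genotype(g)
    strong = weak = wobble = unpaired = 0
    for a_site, b_site in scheme.pairs:
        duo = (gt.base(a_site), gt.base(b_site))
        if duo in _STRONG:
            strong += 1
        elif duo in _WEAK:
            weak += 1
        elif duo in _WOBBLE:
            if scheme.wobble_policy == "count_as_weak":
                weak += 1
            elif scheme.wobble_policy == "exclude":
                unpaired += 1
            else:
                wobble += 1
        else:
            unpaired += 1
    return PairProfile(strong, weak, wobble, unpaired)


def single_mutants(g: Genotype | str) -> Iterator[tuple[int, str, Genotype]]:
    """Yield ``(site, new_base, mutant)`` for all 24 single substitutions."""
    gt = parse_genotype(g)
    seq = gt.seq
    for i, site in enumerate(SITES):
        for b in ALPHABET:
            if b != seq[i]:
                new = seq[:i] + b + seq[i + 1 :]
                yield site, b, Genotype(new[:4], new[4:])


def full_pairing_mutants(
    g: Genotype | str, scheme: PairingScheme = P1EX_SCHEME
) -> tuple[list[tuple[int, str, Genotype]], bool]:
    """Single substitutions whose product is a fully Watson-Crick helix.

    Returns ``(mutants, already_full)`` where ``mutants`` lists every
    single-site substitution after which the scheme has no unpaired and
    no wobble position, and ``already_full`` flags an input that is
    itself fully paired.  For the master genotype the only two such
    mutations are G3T and A20C.
    """
    def _full(x: Genotype) -> bool:
        p = pair_profile(x, PairingScheme(scheme.pairs, "separate_class"))
        return p.unpaired == 0 and p.wobble == 0

    gt = parse_genotype(g)
    hits = [(site, b, m) for site, b, m in single_mutants(gt) if _full(m)]
    return hits, _full(gt)


def genotype_index(g: Genotype | str) -> int:
    """Position of ``g`` in the lexicographic enumeration of the 4^8 space."""
    idx = 0
    for b in _seq(g):
        idx = idx * 4 + ALPHABET.index(b)
    return idx


def gc_count(g: Genotype | str) -> int:
    """Number of G or C bases among the 8 variable sites."""
    return sum(b in "GC" for b in _seq(g))
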