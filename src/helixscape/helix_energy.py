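"""Nearest-neighbor free energies of the forced P1ex and P10 helices.

The two conformational states of the mutagenized region are scored as
*forced* hairpin helices: every position of the helix is treated as
paired regardless of whether the apposed bases can actually pair, which
mirrors how structures are evaluated when the pairing pattern of the
reference is imposed on every genotype.  Canonical pairs (Watson-Crick
and G·U wobble) contribute Turner 2004 stacking terms; a forced
non-canonical apposition has no defined nearest-neighbor term, so each
table lookup that touches one (the pair itself, plus each adjacent
stack) contributes a fixed, strongly destabilizing
``noncanonical_penalty`` instead.

All energies are held internally as integers in units of 0.01 kcal/mol,
so counting unique values across a genotype space is exact and
platform-independent.

Two parameter presets are provided:

* :func:`turner2004` - the strict forced-bracket convention (default
  penalty 50 kcal/mol) used for energy spectra and rank binning; across
  all 4^8 P1ex genotypes it yields 211 unique energies, and 21 across
  the 4^4 genotypes of the P10 helix.
* :func:`turner2004_soft` - the same stacking parameters with a mild
  penalty (default 6 kcal/mol, roughly the cost of losing one strong
  stack) used by the synthetic two-state fitness model, where a broken
  rung should destabilize, not annihilate, the conformation.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_space import ALPHABET, SITE_INDEX, Genotype, parse_genotype

# pair-type codes: canonical types 0..5, non-canonical 6
PAIR_TYPES = ("CG", "GC", "GU", "UG", "AU", "UA")
NC = 6
_DNA2RNA = str.maketrans("T", "U")


def _pair_type(a: str, b: str) -> int:
    duo = (a + b).translate(_DNA2RNA)
    try:
        return PAIR_TYPES.index(duo)
    except ValueError:
        return NC


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor parameters, all in integer 0.01 kcal/mol.

    ``stack[p, q]`` is the stacking term for consecutive pairs ``p`` then
    ``q`` reading 5'->3' along the top strand.  ``terminal_applies``
    lists the pair types charged the helix-end penalty (A·U/U·A here;
    forced G·U ends carry no extra charge in this parameterization).
    """

    stack: np.ndarray  # (6, 6) int
    hairpin_init: Mapping[int, int]
    terminal_penalty: int = 50
    terminal_applies: frozenset = frozenset({"AU", "UA"})
    noncanonical_penalty: int = 5000
    temperature: float = 37.0

    def with_noncanonical_penalty(self, kcal: float) -> "EnergyModel":
        return replace(self, noncanonical_penalty=int(round(kcal * 100)))


@dataclass(frozen=True)
class HelixSpec:
    """A forced helix: ordered pairs from the open end to the loop.

    Each pair is ``(five, three)`` where an ``int`` refers to a variable
    genotype site (1-based intron numbering) and a ``str`` is a fixed
    base.  The loop of ``loop_len`` undefined nucleotides contributes
    only its hairpin-initiation term.
    """

    name: str
    pairs: tuple[tuple[int | str, int | str], ...]
    loop_len: int = 6

    @property
    def bracket(self) -> str:
        n = len(self.pairs)
        return "(" * n + "." * self.loop_len + ")" * n

    def variable_sites(self) -> list[int]:
        return [s for p in self.pairs for s in p if isinstance(s, int)]


#: P1ex: sites 2-5 pair sites 21-18; all eight positions variable.
P1EX_HELIX = HelixSpec("P1ex", pairs=((2, 21), (3, 20), (4, 19), (5, 18)))

#: P10: the 5' half is intron sites 15-17 (fixed A,C,G after construct
#: redesign) followed by sites 18-20; the 3' half is the engineered exon
#: partner strand, complementary to the redesigned 15-20 sequence.  Site
#: 21 lies outside the forced bracket.
P10_HELIX = HelixSpec(
    "P10",
    pairs=(("A", "T"), ("C", "G"), ("G", "C"), (18, "T"), (19, "G"), (20, "G")),
)


@functools.lru_cache(maxsize=None)
def _load_tables() -> tuple[np.ndarray, dict[int, int]]:
    pkg = resources.files("helixscape") / "data"
    stacks = pd.read_csv(pkg / "turner2004_stacks.tsv", sep="\t")
    S = np.zeros((6, 6), dtype=np.int64)
    for row in stacks.itertuples():
        S[PAIR_TYPES.index(row.pair5), PAIR_TYPES.index(row.pair3)] = row.dg_centikcal
    hp = pd.read_csv(pkg / "turner2004_hairpin.tsv", sep="\t")
    return S, dict(zip(hp.loop_len, hp.dg_centikcal))


def turner2004(noncanonical_penalty: float = 50.0, temperature: float = 37.0) -> EnergyModel:
    """Turner 2004 parameters with the strict forced-bracket convention."""
    S, hp = _load_tables()
    return EnergyModel(
        stack=S,
        hairpin_init=hp,
        noncanonical_penalty=int(round(noncanonical_penalty * 100)),
        temperature=temperature,
    )


def turner2004_soft(noncanonical_penalty: float = 6.0, temperature: float = 37.0) -> EnergyModel:
    """Turner 2004 parameters with a mild non-canonical penalty."""
    return turner2004(noncanonical_penalty, temperature)


def _bases_for_spec(
    bases: Genotype | str | Mapping[int, str], spec: HelixSpec
) -> dict[int, str]:
    if isinstance(bases, Mapping):
        out = {s: bases[s] for s in spec.variable_sites()}
    else:
        g = parse_genotype(bases)
        out = {s: g.base(s) for s in spec.variable_sites()}
    for b in out.values():
        if b not in ALPHABET:
            raise ValueError(f"unknown base {b!r}")
    return out


def forced_helix_energy(
    bases: Genotype | str | Mapping[int, str],
    spec: HelixSpec,
    model: EnergyModel | None = None,
) -> float:
    """Free energy (kcal/mol) of one genotype's forced helix."""
    model = model or turner2004()
    site_bases = _bases_for_spec(bases, spec)

    def _base(x: int | str) -> str:
        return site_bases[x] if isinstance(x, int) else x

    types = [_pair_type(_base(a), _base(b)) for a, b in spec.pairs]
    return _energy_from_types(np.array([types]), spec, model)[0] / 100.0


def _energy_from_types(types: np.ndarray, spec: HelixSpec, model: EnergyModel) -> np.ndarray:
    """Integer energies for an (n, L) array of pair-type codes."""
    n, L = types.shape
    e = np.full(n, model.hairpin_init[spec.loop_len], dtype=np.int64)
    pen = model.noncanonical_penalty
    for i in range(L - 1):
        p, q = types[:, i], types[:, i + 1]
        nc = (p == NC) | (q == NC)
        stacked = model.stack[np.minimum(p, 5), np.minimum(q, 5)]
        e += np.where(nc, pen, stacked)
    term_codes = [PAIR_TYPES.index(t) for t in model.terminal_applies]
    for idx in (0, L - 1):
        e += np.where(np.isin(types[:, idx], term_codes), model.terminal_penalty, 0)
    e += pen * (types == NC).sum(axis=1)
    return e


def energies_for_space(
    genotypes: Sequence[str | Genotype],
    spec: HelixSpec,
    model: EnergyModel | None = None,
    as_kcal: bool = False,
) -> np.ndarray:
    """Vectorized forced-helix energies for many genotypes.

    Returns integer 0.01-kcal/mol values by default (exact for
    uniqueness counting); set ``as_kcal`` for floats in kcal/mol.
    """
    model = model or turner2004()
    if len(genotypes) == 0:
        raise ValueError("empty genotype space")
    seqs = np.array(
        [list(g.seq if isinstance(g, Genotype) else g.replace("-", "")) for g in genotypes]
    )
    base_code = np.zeros(128, dtype=np.int8)
    for i, b in enumerate(ALPHABET):
        base_code[ord(b)] = i
    codes = base_code[seqs.view(np.uint32).reshape(seqs.shape) & 0x7F]

    # 4x4 base-pair -> type-code lookup
    pt = np.full((4, 4), NC, dtype=np.int8)
    for a in range(4):
        for b in range(4):
            pt[a, b] = _pair_type(ALPHABET[a], ALPHABET[b])

    cols = []
    for a, b in spec.pairs:
        ca = codes[:, SITE_INDEX[a]] if isinstance(a, int) else np.full(len(seqs), ALPHABET.index(a))
        cb = codes[:, SITE_INDEX[b]] if isinstance(b, int) else np.full(len(seqs), ALPHABET.index(b))
        cols.append(pt[ca, cb])
    types = np.stack(cols, axis=1)
    e = _energy_from_types(types, spec, model)
    return e / 100.0 if as_kcal else e


def unique_energy_spectrum(
    genotypes: Sequence[str | Genotype],
    spec: HelixSpec,
    model: EnergyModel | None = None,
) -> pd.DataFrame:
    """Distinct forced-helix energies and their multiplicities.

    Rows are sorted by increasing free energy (most stable first);
    multiplicities sum to the size of the space.
    """
    e = energies_for_space(genotypes, spec, model)
    values, counts = np.unique(e, return_counts=True)
    return pd.DataFrame({"dg_kcal": values / 100.0, "multiplicity": counts})


def stability_rank_bins(energies: np.ndarray, n_bins: int) -> tuple[np.ndarray, int]:
    """Bin genotypes by the rank of their helix stability.

    Unique energy values are ordered from least stable (highest free
    energy) to most stable and partitioned into ``n_bins`` near-equal
    groups of *unique values*, so equal energies always share a bin.
    Returns ``(bin_index_per_genotype, n_bins_used)``; bin 0 is the
    least stable.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    energies = np.asarray(energies)
    uniq = np.unique(energies)[::-1]  # descending dG = increasing stability
    n_bins = min(n_bins, len(uniq))
    bin_of_value = {}
    for b, chunk in enumerate(np.array_split(uniq, n_bins)):
        for v in chunk:
            bin_of_value[v] = b
    bins = np.array([bin_of_value[v] for v in energies])
    return bins, n_bins


def landscape_surface(
    fitness: np.ndarray, p1ex_bins: np.ndarray, p10_bins: np.ndarray
) -> pd.DataFrame:
    """Median fitness in each (P1ex stability bin, P10 stability bin).

    Index is the P1ex bin, columns the P10 bin; combinations with no
    member genotypes are NaN, never zero-filled.
    """
    df = pd.DataFrame({"f": fitness, "p1ex": p1ex_bins, "p10": p10_bins})
    surface = df.pivot_table(index="p1ex", columns="p10", values="f", aggfunc="median")
    full_index = range(int(p1ex_bins.max()) + 1)
    full_cols = range(int(p10_bins.max()) + 1)
    return surface.reindex(index=full_index, columns=full_cols)
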