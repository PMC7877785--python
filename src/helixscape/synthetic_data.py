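"""Ground-truth two-state landscapes and simulation of the selection assay.

The generator emulates the pooled selection experiment end to end:

1. a *true* relative fitness ``w(g)`` for every genotype, driven by the
   two conformational states -- a band-pass constraint on P1ex stability
   (the helix must form, but must not be too stable to dissociate), a
   logistic benefit of P10 stability, a multiplicative geometry defect
   for cytosines at both sites 2 and 21, and optional lognormal
   genotype-level noise;
2. a mutagenesis library whose composition decays geometrically with
   Hamming distance from the master (weight ``lambda**d``), as produced
   by overlap-extension PCR seeded from the master template;
3. one fitness-weighted multinomial resampling step per replicate for
   growth under selection, with optional gamma (negative-binomial style)
   overdispersion;
4. optional amplicon FASTQ output so the read-counting stage can be
   exercised on synthetic reads.

All randomness derives from ``SimConfig.seed``; a fixed seed gives
byte-identical count tables and FASTQ files.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .genotype_space import ALPHABET, MASTER, enumerate_genotypes, parse_genotype
from .helix_energy import (
    P10_HELIX,
    P1EX_HELIX,
    EnergyModel,
    energies_for_space,
    turner2004_soft,
)

logger = logging.getLogger(__name__)

#: 5' constant region of the forward amplicon read (38 nt)
ANCHOR5 = "GGGGATGATGTTAAGGCTATTGGTGTTTATGGCTCTCT"
#: the 12 fixed loop bases separating the two variable sub-regions
LOOP12 = "AGCAATATTACG"
#: arbitrary constant context downstream of site 21, padding reads to 100 nt
_DOWN = "GGAGGGAAAAGTTATCAGGCATGCACTGGTAGCTAGTCTTTA"[:42]


@dataclass(frozen=True)
class TwoStateParams:
    """Parameters of the generative fitness model (energies in kcal/mol).

    ``theta_lo``/``theta_hi`` are the edges of the admissible band of
    P1ex stability, expressed on the ``-dG`` scale (higher = more
    stable); ``theta10`` is the midpoint of the logistic P10 benefit.
    ``delta`` multiplies fitness when cytosines occupy both site 2 and
    site 21 (the splice-site geometry defect), and ``sigma`` scales
    lognormal genotype-specific noise.  At 37 degC the stability ceiling
    ``theta_hi`` is raised by ``theta_hi_offset_37``: kinetic traps from
    excess stability are easier to escape at the higher temperature.
    """

    w0: float = 1.0
    theta_lo: float = -26.0
    theta_hi: float = 0.0
    tau: float = 4.0
    theta10: float = -12.0
    tau10: float = 4.0
    delta: float = 0.1
    sigma: float = 0.2
    theta_hi_offset_37: float = 2.0


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_replicates: int = 6
    depth: int = 2_000_000
    library_skew: float = 0.1  # lambda: library weight lambda**d
    overdispersion: float = 0.0  # phi: gamma-multinomial excess variance
    params: TwoStateParams = field(default_factory=TwoStateParams)
    temperature_mode: str = "30C"
    noncanonical_penalty: float = 6.0  # soft energy preset for the truth model

    def __post_init__(self) -> None:
        if not (0 < self.library_skew <= 1):
            raise ValueError("library_skew must be in (0, 1]")
        if not (0 < self.params.delta <= 1):
            raise ValueError("delta must be in (0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.temperature_mode not in ("30C", "37C"):
            raise ValueError("temperature_mode must be '30C' or '37C'")

    def param_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class TrueLandscape:
    """Per-genotype true relative fitness and its component factors."""

    genotypes: list[str]
    w: np.ndarray
    band_factor: np.ndarray
    p10_factor: np.ndarray
    geometry_factor: np.ndarray
    neg_dg_p1ex: np.ndarray
    neg_dg_p10: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "w": self.w,
                "band_factor": self.band_factor,
                "p10_factor": self.p10_factor,
                "geometry_factor": self.geometry_factor,
                "neg_dg_p1ex": self.neg_dg_p1ex,
                "neg_dg_p10": self.neg_dg_p10,
            },
            index=pd.Index(self.genotypes, name="genotype"),
        )


def _stability_band(x: np.ndarray, lo: float, hi: float, tau: float) -> np.ndarray:
    return expit((x - lo) / tau) * (1.0 - expit((x - hi) / tau))


def two_state_fitness(
    genotypes: list[str] | None = None,
    energies: tuple[np.ndarray, np.ndarray] | None = None,
    params: TwoStateParams | None = None,
    temperature_mode: str = "30C",
    sigma_rng: np.random.Generator | None = None,
    model: EnergyModel | None = None,
) -> TrueLandscape:
    """Evaluate the two-state fitness model over a genotype list.

    ``energies`` may supply precomputed ``(dG_P1ex, dG_P10)`` in
    kcal/mol; otherwise they are computed with the soft energy preset.
    Fitness is rescaled so the master genotype has ``w = 1``.
    """
    params = params or TwoStateParams()
    if genotypes is None:
        genotypes = canonical_space()
    if energies is None:
        model = model or turner2004_soft()
        dg1 = energies_for_space(genotypes, P1EX_HELIX, model, as_kcal=True)
        dg10 = energies_for_space(genotypes, P10_HELIX, model, as_kcal=True)
    else:
        dg1, dg10 = (np.asarray(e, dtype=float) for e in energies)
    x1, x10 = -dg1, -dg10

    theta_hi = params.theta_hi
    if temperature_mode == "37C":
        theta_hi += params.theta_hi_offset_37
    band = _stability_band(x1, params.theta_lo, theta_hi, params.tau)
    p10f = expit((x10 - params.theta10) / params.tau10)
    seqs = np.array([list(parse_genotype(g).seq) for g in genotypes])
    cc = (seqs[:, 0] == "C") & (seqs[:, 7] == "C")
    geom = np.where(cc, params.delta, 1.0)

    w = params.w0 * band * p10f * geom
    if params.sigma > 0 and sigma_rng is not None:
        w = w * np.exp(params.sigma * sigma_rng.standard_normal(len(w)))

    midx = genotypes.index(MASTER) if MASTER in genotypes else None
    if midx is None:
        midx = genotypes.index(MASTER.replace("-", ""))
    if w[midx] <= 0:
        raise ValueError("master fitness must be positive")
    w = w / w[midx]
    return TrueLandscape(list(genotypes), w, band, p10f, geom, x1, x10)


_SPACE_CACHE: list[str] | None = None


def canonical_space() -> list[str]:
    """The 65,536 genotypes in canonical ``LLLL-RRRR`` text form."""
    global _SPACE_CACHE
    if _SPACE_CACHE is None:
        _SPACE_CACHE = [s[:4] + "-" + s[4:] for s in enumerate_genotypes(8)]
    return _SPACE_CACHE


def hamming_to_master(genotypes: list[str]) -> np.ndarray:
    m = np.array(list(MASTER.replace("-", "")))
    seqs = np.array([list(g.replace("-", "")) for g in genotypes])
    return (seqs != m).sum(axis=1)


def library_weights(genotypes: list[str], skew: float) -> np.ndarray:
    """Sampling weights ``skew**d`` normalized to 1."""
    d = hamming_to_master(genotypes)
    logw = d * np.log(skew)
    w = np.exp(logw - logw.max())
    return w / w.sum()


def _draw_counts(
    rng: np.random.Generator, p: np.ndarray, depth: int, phi: float
) -> np.ndarray:
    if phi > 0:
        jitter = rng.gamma(shape=1.0 / phi, scale=phi, size=len(p))
        p = p * jitter
        p = p / p.sum()
    return rng.multinomial(depth, p)


def simulate_library(
    config: SimConfig, genotypes: list[str] | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Pre-selection counts: one multinomial draw per replicate."""
    genotypes = genotypes or canonical_space()
    rng = rng or np.random.default_rng(config.seed)
    p = library_weights(genotypes, config.library_skew)
    cols = {
        f"pre_rep{r + 1}": _draw_counts(rng, p, config.depth, config.overdispersion)
        for r in range(config.n_replicates)
    }
    return pd.DataFrame(cols, index=pd.Index(genotypes, name="genotype"))


def simulate_selection(
    pre: pd.DataFrame,
    truth: TrueLandscape,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    prefix: str = "post",
) -> pd.DataFrame:
    """Post-selection counts: fitness-weighted multinomial resampling."""
    if list(pre.index) != truth.genotypes:
        raise ValueError("pre-selection table and truth cover different genotypes")
    rng = rng or np.random.default_rng(config.seed + 1)
    cols = {}
    for i, col in enumerate(pre.columns):
        q = pre[col].to_numpy() * truth.w
        total = q.sum()
        if total <= 0:
            raise ValueError(f"no surviving genotypes in replicate column {col!r}")
        cols[f"{prefix}_rep{i + 1}"] = _draw_counts(
            rng, q / total, config.depth, config.overdispersion
        )
    return pd.DataFrame(cols, index=pre.index)


@dataclass
class Experiment:
    """A simulated pre/post selection experiment at one or two temperatures."""

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    truth: dict[str, TrueLandscape]
    config: SimConfig


def simulate_experiment(
    config: SimConfig, temperatures: tuple[str, ...] = ("30C",)
) -> Experiment:
    """Full experiment: shared library, then selection per temperature.

    Sample ids follow ``{temp}_{pre|post}_rep{r}``; the sample sheet
    records replicate index, selection flag and temperature.
    """
    genotypes = canonical_space()
    rng = np.random.default_rng(config.seed)
    sigma_rng = np.random.default_rng(rng.integers(2**31)) if config.params.sigma > 0 else None
    model = turner2004_soft(config.noncanonical_penalty)
    dg1 = energies_for_space(genotypes, P1EX_HELIX, model, as_kcal=True)
    dg10 = energies_for_space(genotypes, P10_HELIX, model, as_kcal=True)

    frames, rows, truths = [], [], {}
    for temp in temperatures:
        pre = simulate_library(config, genotypes, rng=rng)
        pre.columns = [f"{temp}_{c}" for c in pre.columns]
        truth = two_state_fitness(
            genotypes, (dg1, dg10), config.params, temp, sigma_rng=sigma_rng
        )
        post = simulate_selection(pre, truth, config, rng=rng, prefix="post")
        post.columns = [f"{temp}_{c}" for c in post.columns]
        frames += [pre, post]
        truths[temp] = truth
        for r in range(config.n_replicates):
            rows.append((f"{temp}_pre_rep{r + 1}", r + 1, False, temp))
            rows.append((f"{temp}_post_rep{r + 1}", r + 1, True, temp))
    counts = pd.concat(frames, axis=1)
    sheet = pd.DataFrame(rows, columns=["sample", "replicate", "selected", "temperature"])
    logger.info(
        "simulated experiment seed=%d params=%s samples=%d",
        config.seed,
        config.param_hash(),
        len(sheet),
    )
    return Experiment(counts, sheet, truths, config)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def write_amplicon_fastq(
    counts: pd.Series,
    path: str | Path,
    error_rate: float = 0.0,
    quality: int = 37,
    rng: np.random.Generator | None = None,
) -> Path:
    """Write one gzip FASTQ of forward reads for a sample's counts.

    Read layout: 38-nt 5' constant region, sites 2-5, the 12-nt loop,
    sites 18-21, then constant context to 100 nt -- all eight variable
    sites therefore sit within 58 bases of the 5' anchor.  Substitution
    errors are applied uniformly at ``error_rate`` per base; every base
    is given the same Phred quality.
    """
    rng = rng or np.random.default_rng(0)
    path = Path(path)
    qline = chr(quality + 33) * 100
    base_arr = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    with gzip.open(path, "wt") as fh:
        n = 0
        for genotype, count in counts.items():
            if count <= 0:
                continue
            g = parse_genotype(genotype)
            read = ANCHOR5 + g.left + LOOP12 + g.right + _DOWN
            if error_rate > 0:
                arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
                for _ in range(int(count)):
                    r = arr.copy()
                    hit = rng.random(len(r)) < error_rate
                    if hit.any():
                        r[hit] = base_arr[rng.integers(0, 4, size=hit.sum())]
                    n += 1
                    fh.write(f"@read{n}\n{r.tobytes().decode()}\n+\n{qline}\n")
            else:
                for _ in range(int(count)):
                    n += 1
                    fh.write(f"@read{n}\n{read}\n+\n{qline}\n")
    return path


def write_count_table(counts: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    counts.to_csv(path, sep="\t")
    return path


def read_count_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="genotype")
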