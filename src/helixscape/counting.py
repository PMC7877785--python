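"""Amplicon reads -> genotype count table.

Reads are anchored by the 38-nt 5' constant region (exact or one
mismatch); the eight variable bases are then read at fixed offsets
(38-41 and 54-57), so no alignment is needed -- the library contains
substitutions only.  A read is discarded when any targeted base is an N
or has Phred quality below ``qmin`` (default 30); non-targeted backbone
bases are not quality-filtered.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genotype_space import ALPHABET
from .synthetic_data import ANCHOR5

logger = logging.getLogger(__name__)

LEFT_OFFSET = len(ANCHOR5)  # 38
RIGHT_OFFSET = LEFT_OFFSET + 4 + 12  # 54
MIN_READ_LEN = RIGHT_OFFSET + 4  # 58


@dataclass
class CountingQC:
    """Per-sample accounting of the read filter."""

    reads_seen: int = 0
    reads_anchored: int = 0
    reads_passed: int = 0

    @property
    def anchor_rate(self) -> float:
        return self.reads_anchored / self.reads_seen if self.reads_seen else 0.0


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check sample-sheet invariants (unique ids, positive replicates)."""
    required = {"sample", "replicate", "selected", "temperature"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    if sheet["sample"].duplicated().any():
        dupes = sheet.loc[sheet["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    if (sheet["replicate"] <= 0).any():
        raise ValueError("replicate indices must be positive")
    return sheet


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _anchored(read: str, anchor: str, max_mismatch: int = 1) -> bool:
    if len(read) < len(anchor):
        return False
    mm = 0
    for a, b in zip(read, anchor):
        if a != b:
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def parse_amplicons(
    fastq: str | Path,
    anchor: str = ANCHOR5,
    qmin: int = 30,
    anchor_rate_floor: float = 0.5,
) -> tuple[Counter, CountingQC]:
    """Count genotypes in one FASTQ(.gz) of forward reads.

    Returns ``(counts, qc)`` where ``counts`` maps canonical
    ``"LLLL-RRRR"`` genotype strings to read counts.  An anchor-match
    rate below ``anchor_rate_floor`` is logged as a warning.
    """
    counts: Counter = Counter()
    qc = CountingQC()
    qthr = qmin + 33
    with _open_maybe_gz(Path(fastq)) as fh:
        for _title, seq, qual in FastqGeneralIterator(fh):
            qc.reads_seen += 1
            if len(seq) < MIN_READ_LEN or not _anchored(seq, anchor):
                continue
            qc.reads_anchored += 1
            left = seq[LEFT_OFFSET : LEFT_OFFSET + 4]
            right = seq[RIGHT_OFFSET : RIGHT_OFFSET + 4]
            targeted_q = qual[LEFT_OFFSET : LEFT_OFFSET + 4] + qual[RIGHT_OFFSET : RIGHT_OFFSET + 4]
            if any(ord(q) < qthr for q in targeted_q):
                continue
            bases = left + right
            if any(b not in ALPHABET for b in bases):
                continue
            qc.reads_passed += 1
            counts[f"{left}-{right}"] += 1
    if qc.reads_seen and qc.anchor_rate < anchor_rate_floor:
        logger.warning(
            "%s: anchor match rate %.2f below floor %.2f",
            fastq,
            qc.anchor_rate,
            anchor_rate_floor,
        )
    return counts, qc


def assemble_count_table(
    columns: dict[str, Counter],
    sheet: pd.DataFrame | None = None,
    genotypes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Merge per-sample counters into a genotype x sample matrix.

    Missing genotypes are zero-filled.  When ``genotypes`` is given it
    fixes the row universe (e.g. all 65,536); otherwise rows are the
    union of observed genotypes, sorted.
    """
    if sheet is not None:
        validate_sample_sheet(sheet)
        unknown = set(columns) - set(sheet["sample"])
        if unknown:
            raise ValueError(f"columns not in sample sheet: {sorted(unknown)}")
    if genotypes is None:
        universe = sorted(set().union(*[set(c) for c in columns.values()]))
    else:
        universe = list(genotypes)
    table = pd.DataFrame(
        {name: pd.Series(col, dtype="int64") for name, col in columns.items()},
        index=pd.Index(universe, name="genotype"),
    ).fillna(0).astype("int64")
    for name in table.columns:
        if table[name].sum() == 0:
            logger.warning("sample %s has zero reads", name)
    return table
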