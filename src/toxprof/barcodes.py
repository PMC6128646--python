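"""Barcode-to-mutant assignment for pooled deletion-library sequencing.

Each deletion strain carries a unique DNA barcode; sequencing the amplified
barcodes before and after selective growth and counting reads per strain
yields the abundance data behind growth-inhibition scores. This module
extracts the barcode window from each read and assigns it to the library
strain within a configurable Hamming (substitution-only) distance.

Assignment is deliberately conservative: a read whose barcode window is
equidistant from two library barcodes at the minimal distance is left
unassigned rather than broken arbitrarily, so miscounts do not leak into
fitness scores.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "BarcodeLibrary",
    "CountTable",
    "MatchResult",
    "match_barcode",
    "count_barcodes",
    "iter_fastq",
    "hamming",
]

_ALPHABET = set("ACGTN")

#: reason codes attached to every match decision
REASONS = ("matched", "too_short", "no_match", "ambiguous")


def hamming(a: str, b: str) -> int:
    """Substitution-only distance between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeLibrary:
    """Maps barcode sequences to mutant and gene identities.

    ``frame`` has columns mutant_id, barcode, gene. Barcodes must be unique,
    of a single fixed length, over the {A,C,G,T,N} alphabet.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"mutant_id", "barcode", "gene"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"library table missing columns: {sorted(missing)}")
        self.frame = self.frame.reset_index(drop=True)
        barcodes = self.frame["barcode"].astype(str).str.upper()
        self.frame["barcode"] = barcodes
        lengths = barcodes.str.len().unique()
        if len(lengths) != 1:
            raise ValueError(f"barcodes must share one length, found {sorted(lengths)}")
        bad = set("".join(barcodes)) - _ALPHABET
        if bad:
            raise ValueError(f"barcode alphabet must be A/C/G/T/N, found {sorted(bad)}")
        if self.frame["mutant_id"].duplicated().any():
            raise ValueError("mutant ids must be unique")
        if barcodes.duplicated().any():
            dups = barcodes[barcodes.duplicated()].unique()
            raise ValueError(f"barcodes must be unique; duplicated: {list(dups)[:3]}")
        self._exact = dict(zip(barcodes, self.frame["mutant_id"]))
        self._encoded = _encode(barcodes.tolist())

    @property
    def barcode_length(self) -> int:
        return len(self.frame["barcode"].iloc[0])

    @property
    def mutant_ids(self) -> list[str]:
        return self.frame["mutant_id"].tolist()

    def min_pairwise_distance(self) -> int:
        """Smallest Hamming distance between any two library barcodes."""
        enc = self._encoded
        best = self.barcode_length
        # chunked so the (n x n x L) comparison never materializes at once
        step = 256
        for start in range(0, len(enc), step):
            block = enc[start : start + step]
            d = (block[:, None, :] != enc[None, :, :]).sum(axis=2)
            for i in range(block.shape[0]):
                d[i, start + i] = best + 1  # mask self
            best = min(best, int(d.min()))
        return best

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeLibrary":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _encode(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


@dataclass(frozen=True)
class MatchResult:
    mutant_id: str | None
    reason: str  # one of REASONS


def match_barcode(
    read_sequence: str,
    library: BarcodeLibrary,
    max_mismatch: int = 1,
    offset: int = 0,
) -> MatchResult:
    """Assign a read to the unique library barcode within ``max_mismatch``.

    The barcode window is taken at a fixed ``offset`` from the read start
    (the declared layout position). Ties at the minimal distance, or no
    barcode within tolerance, leave the read unassigned.
    """
    L = library.barcode_length
    read_sequence = read_sequence.upper()
    if len(read_sequence) < offset + L:
        return MatchResult(None, "too_short")
    window = read_sequence[offset : offset + L]
    hit = library._exact.get(window)
    if hit is not None:
        return MatchResult(hit, "matched")
    if max_mismatch == 0:
        return MatchResult(None, "no_match")
    w = np.frombuffer(window.encode(), dtype=np.uint8)
    d = (library._encoded != w).sum(axis=1)
    dmin = int(d.min())
    if dmin > max_mismatch:
        return MatchResult(None, "no_match")
    hits = np.flatnonzero(d == dmin)
    if len(hits) > 1:
        return MatchResult(None, "ambiguous")
    return MatchResult(library.frame["mutant_id"].iloc[hits[0]], "matched")


@dataclass
class CountTable:
    """Per-mutant read counts for one sequenced sample.

    Invariant: ``counts.sum() + unassigned`` equals the number of reads
    processed, exactly.
    """

    sample_id: str
    condition: str  # "control" | "treatment"
    counts: pd.Series  # indexed by mutant_id, int64, >= 0
    unassigned: int = 0
    reasons: dict | None = None

    def __post_init__(self):
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype("int64")

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + int(self.unassigned)

    def to_tsv(self, path: str | Path, library: BarcodeLibrary | None = None) -> None:
        df = self.counts.rename("count").rename_axis("mutant_id").reset_index()
        if library is not None:
            df = df.merge(
                library.frame[["mutant_id", "gene"]], on="mutant_id", how="left"
            )[["mutant_id", "gene", "count"]]
        else:
            df.insert(1, "gene", "")
        df = pd.concat(
            [df, pd.DataFrame([{"mutant_id": "__unassigned__", "gene": "", "count": self.unassigned}])],
            ignore_index=True,
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str = "", condition: str = "") -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        un = df[df["mutant_id"] == "__unassigned__"]
        unassigned = int(un["count"].iloc[0]) if len(un) else 0
        df = df[df["mutant_id"] != "__unassigned__"]
        counts = pd.Series(df["count"].values, index=df["mutant_id"].values, dtype="int64")
        return cls(sample_id=sample_id, condition=condition, counts=counts, unassigned=unassigned)


def count_barcodes(
    reads: Iterable[str],
    library: BarcodeLibrary,
    max_mismatch: int = 1,
    offset: int = 0,
    sample_id: str = "sample",
    condition: str = "control",
) -> CountTable:
    """Tally reads per mutant in one pass over the read stream.

    Order-independent by construction: each read is matched in isolation.
    """
    tallies = dict.fromkeys(library.mutant_ids, 0)
    reasons = {"too_short": 0, "no_match": 0, "ambiguous": 0}
    n = 0
    for read in reads:
        n += 1
        res = match_barcode(str(read), library, max_mismatch=max_mismatch, offset=offset)
        if res.mutant_id is None:
            reasons[res.reason] += 1
        else:
            tallies[res.mutant_id] += 1
    if n == 0:
        warnings.warn("empty read stream; returning an all-zero count table", stacklevel=2)
    counts = pd.Series(tallies, dtype="int64")
    unassigned = sum(reasons.values())
    return CountTable(
        sample_id=sample_id,
        condition=condition,
        counts=counts,
        unassigned=unassigned,
        reasons=reasons,
    )


def iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (gzipped or plain)."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq)
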