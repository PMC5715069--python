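"""TCR CDR3 clonotype-table statistics.

Works on VDJtools-style clonotype tables (one row per clonotype: read
count, frequency, CDR3 nucleotide and amino-acid sequence, V/D/J segment
labels). Provides the standard repertoire-comparison chain: frame
filtering, depth-equalizing read downsampling (libraries are reduced to a
common read number before any cross-library comparison), CDR3 motif
abundance by regular expression, V/J segment usage, and inverse Simpson
diversity (the effective number of equally abundant clones).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("count", "freq", "cdr3nt", "cdr3aa", "v", "j")
#: characters marking a non-functional CDR3: '*' stop codon, '_' frameshift
_NONFUNCTIONAL = ("*", "_")


@dataclass
class ClonotypeTable:
    """One library's clonotype records plus locus/population metadata."""

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"clonotype table lacks column(s): {missing}")
        rec = self.records
        if len(rec) and (rec["count"] < 1).any():
            raise ValueError("clonotype counts must be >= 1")
        if rec.duplicated(subset=["cdr3nt", "v", "j"]).any():
            raise ValueError("duplicate (cdr3nt, v, j) clonotype rows")
        if len(rec):
            expected = rec["count"] / rec["count"].sum()
            if not np.allclose(rec["freq"], expected, atol=1e-6):
                warnings.warn("freq column inconsistent with counts; recomputed")
            self.records = rec.assign(freq=expected)

    @property
    def total_reads(self) -> int:
        return int(self.records["count"].sum())

    @property
    def n_clones(self) -> int:
        return len(self.records)


def read_clonotype_table(path: str | Path, **metadata) -> ClonotypeTable:
    """Read a tab-separated clonotype table; freq is recomputed from counts."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    numeric = pd.to_numeric(df["count"], errors="coerce")
    if numeric.isna().any():
        line = int(np.flatnonzero(numeric.isna())[0]) + 2  # header is line 1
        raise ValueError(f"{path}: malformed count at line {line}")
    df["count"] = numeric.astype(int)
    df["freq"] = df["freq"].astype(float)
    if "d" not in df.columns:
        df["d"] = "."
    return ClonotypeTable(df, metadata)


def write_clonotype_table(table: ClonotypeTable, path: str | Path) -> None:
    cols = ["count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j"]
    present = [c for c in cols if c in table.records.columns]
    table.records[present].to_csv(path, sep="\t", index=False)


def filter_in_frame(table: ClonotypeTable) -> ClonotypeTable:
    """Keep functionally recombined clonotypes only.

    In-frame means the CDR3 nucleotide length is divisible by 3 and the
    amino-acid sequence carries neither a stop ('*') nor a frameshift
    ('_') character. Frequencies are renormalized over the survivors.
    """
    rec = table.records
    in_frame = (rec["cdr3nt"].str.len() % 3 == 0) & ~rec["cdr3aa"].str.contains(
        "[*_]", regex=True
    )
    kept = rec[in_frame].reset_index(drop=True)
    if len(kept) == 0:
        warnings.warn("no in-frame clonotypes remain")
        return ClonotypeTable(kept, dict(table.metadata))
    kept = kept.assign(freq=kept["count"] / kept["count"].sum())
    return ClonotypeTable(kept, dict(table.metadata))


def downsample_reads(table: ClonotypeTable, n_target: int, seed: int) -> ClonotypeTable:
    """Downsample to exactly ``n_target`` reads, hypergeometrically.

    Reads are drawn without replacement across clones (multivariate
    hypergeometric), matching the depth-equalization used before
    cross-library motif and diversity comparisons. Clones sampled to zero
    are dropped. A library below the target depth raises (such a library
    must be excluded, not upsampled).
    """
    total = table.total_reads
    if total < n_target:
        raise ValueError(
            f"library has {total} reads, fewer than target {n_target}; exclude it"
        )
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    if total == n_target:
        return ClonotypeTable(table.records.copy(), dict(table.metadata))
    rng = np.random.default_rng(seed)
    counts = table.records["count"].to_numpy()
    new_counts = rng.multivariate_hypergeometric(counts, n_target)
    rec = table.records.assign(count=new_counts)
    rec = rec[rec["count"] > 0].reset_index(drop=True)
    rec = rec.assign(freq=rec["count"] / rec["count"].sum())
    return ClonotypeTable(rec, dict(table.metadata))


def motif_fraction(table: ClonotypeTable, motif_pattern: str) -> float:
    """Fraction of reads whose CDR3 amino-acid sequence matches a regex.

    Case-insensitive; the denominator is every read in the (already
    frame-filtered, depth-equalized) table.
    """
    try:
        pattern = re.compile(motif_pattern, flags=re.IGNORECASE)
    except re.error as exc:
        raise ValueError(f"invalid motif pattern {motif_pattern!r}: {exc}") from exc
    rec = table.records
    total = rec["count"].sum()
    if total == 0:
        return 0.0
    hits = rec["cdr3aa"].str.contains(pattern)
    return float(rec.loc[hits, "count"].sum() / total)


def segment_usage(table: ClonotypeTable, level: str = "v") -> dict[str, float]:
    """Read-weighted V (or J) segment usage; fractions sum to one."""
    if level not in {"v", "j"}:
        raise ValueError("level must be 'v' or 'j'")
    rec = table.records
    total = rec["count"].sum()
    usage = rec.groupby(level)["count"].sum() / total
    return {str(k): float(v) for k, v in usage.sort_index().items()}


def inverse_simpson(table: ClonotypeTable, unbiased: bool = False) -> float:
    """Inverse Simpson diversity D = 1 / sum(p_i^2).

    D lies between 1 (monoclonal) and the clone count (perfectly even).
    ``unbiased=True`` uses the finite-sample estimator
    1 / sum(n_i (n_i - 1) / (N (N - 1))).
    """
    counts = table.records["count"].to_numpy(dtype=float)
    if len(counts) == 0:
        raise ValueError("cannot compute diversity of an empty table")
    n = counts.sum()
    if unbiased:
        if n < 2:
            raise ValueError("unbiased estimator needs at least 2 reads")
        denom = (counts * (counts - 1)).sum() / (n * (n - 1))
        if denom == 0:
            raise ValueError("unbiased Simpson undefined: all clones are singletons")
        return float(1.0 / denom)
    p = counts / n
    return float(1.0 / np.sum(p**2))
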