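"""Marker-based staging of gamma-delta thymocytes.

Adult mouse gamma-delta thymocytes can be partitioned into seven
developmental populations (stages A-G) from the surface expression of six
markers: CD24, CD25, CD73, CD117, CD200 and CD371.  This module reads
cytometry event tables (CSV or FCS), applies the standard arcsinh
transform, fits per-marker positivity thresholds, and assigns every event
to exactly one stage via a deterministic decision-tree gate:

1. CD24 low                  -> G   (mature, export-ready)
2. CD73+  (CD117+ -> E, else -> F)
3. CD200+                    -> D
4. CD371+ (CD25+  -> A, else -> B)
5. otherwise                 -> C

The gate mirrors conventional bi-axial gating and resolves every
positivity pattern to a single stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import argrelmax, argrelmin
from scipy.stats import gaussian_kde

STAGES: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G")

REQUIRED_MARKERS: tuple[str, ...] = (
    "CD24", "CD25", "CD73", "CD117", "CD200", "CD371",
)

#: marker -> state for each stage; states: '+', '-', 'hi', 'lo', 'any'.
#: CD117 is informative only for the E/F split and is 'any' elsewhere.
DEFAULT_SIGNATURES: dict[str, dict[str, str]] = {
    "A": {"CD24": "hi", "CD25": "+", "CD371": "+", "CD73": "-", "CD200": "-", "CD117": "any"},
    "B": {"CD24": "hi", "CD25": "-", "CD371": "+", "CD73": "-", "CD200": "-", "CD117": "any"},
    "C": {"CD24": "hi", "CD25": "-", "CD371": "-", "CD73": "-", "CD200": "-", "CD117": "any"},
    "D": {"CD24": "hi", "CD200": "+", "CD73": "-", "CD25": "any", "CD371": "any", "CD117": "any"},
    "E": {"CD24": "hi", "CD73": "+", "CD117": "+", "CD25": "any", "CD200": "any", "CD371": "any"},
    "F": {"CD24": "hi", "CD73": "+", "CD117": "-", "CD25": "any", "CD200": "any", "CD371": "any"},
    "G": {"CD24": "lo", "CD25": "any", "CD73": "any", "CD117": "any", "CD200": "any", "CD371": "any"},
}

#: Decision-tree gating order: first matching rule wins; the final rule is
#: the catch-all.  Each rule is (stage, {marker: state}) where state is one
#: of '+', '-', 'hi', 'lo' (interpreted against a single threshold).
DEFAULT_GATING_ORDER: tuple[tuple[str, dict[str, str]], ...] = (
    ("G", {"CD24": "lo"}),
    ("E", {"CD73": "+", "CD117": "+"}),
    ("F", {"CD73": "+"}),
    ("D", {"CD200": "+"}),
    ("A", {"CD371": "+", "CD25": "+"}),
    ("B", {"CD371": "+"}),
    ("C", {}),
)

_POSITIVE_STATES = frozenset({"+", "hi"})
_NEGATIVE_STATES = frozenset({"-", "lo"})


class MissingMarkerError(KeyError):
    """A required marker channel is absent from the input."""


@dataclass
class EventMatrix:
    """Per-event fluorescence intensities plus categorical annotations.

    ``intensities`` holds one row per event and one column per marker;
    ``annotations`` is row-aligned and may carry ``subset`` (Vg1.1 / Vg2),
    ``group`` (treatment condition) and ``true_stage`` (simulation truth).
    """

    intensities: pd.DataFrame
    annotations: pd.DataFrame = None  # type: ignore[assignment]
    transformed: bool = False

    def __post_init__(self) -> None:
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=self.intensities.index)
        if len(self.annotations) != len(self.intensities):
            raise ValueError("annotations must be row-aligned with intensities")
        if self.intensities.isna().any().any():
            raise ValueError("missing intensity values are not allowed")
        if self.intensities.columns.duplicated().any():
            raise ValueError("marker names must be unique")

    @property
    def marker_names(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_events(self) -> int:
        return len(self.intensities)

    def require_markers(self, markers: Sequence[str] = REQUIRED_MARKERS) -> None:
        missing = [m for m in markers if m not in self.intensities.columns]
        if missing:
            raise MissingMarkerError(f"missing marker channel(s): {', '.join(missing)}")

    def subset_rows(self, index: np.ndarray) -> "EventMatrix":
        return EventMatrix(
            self.intensities.iloc[index].reset_index(drop=True),
            self.annotations.iloc[index].reset_index(drop=True),
            transformed=self.transformed,
        )


@dataclass(frozen=True)
class PositivityThresholds:
    """One positivity cut per marker, on the transformed scale."""

    thresholds: Mapping[str, float]
    method: str = "manual"

    def __post_init__(self) -> None:
        for marker, value in self.thresholds.items():
            if not np.isfinite(value):
                raise ValueError(f"threshold for {marker} is not finite")

    def __getitem__(self, marker: str) -> float:
        return float(self.thresholds[marker])


@dataclass(frozen=True)
class StageSignatureTable:
    """Marker-state signature for each of the seven stages A-G."""

    signatures: Mapping[str, Mapping[str, str]] = field(
        default_factory=lambda: DEFAULT_SIGNATURES
    )
    gating_order: tuple[tuple[str, dict[str, str]], ...] = DEFAULT_GATING_ORDER

    def __post_init__(self) -> None:
        missing = set(STAGES) - set(self.signatures)
        if missing:
            raise ValueError(f"signature table lacks stages: {sorted(missing)}")
        for stage, sig in self.signatures.items():
            for marker, state in sig.items():
                if state not in {"+", "-", "hi", "lo", "any"}:
                    raise ValueError(f"invalid state {state!r} for {stage}/{marker}")
        self._check_unambiguous()

    def _check_unambiguous(self) -> None:
        # Each stage's own signature pattern must gate back to that stage.
        for stage, sig in self.signatures.items():
            pattern = {
                m: (s in _POSITIVE_STATES) for m, s in sig.items() if s != "any"
            }
            routed = _route_pattern(pattern, self.gating_order)
            if routed != stage:
                raise ValueError(
                    f"ambiguous signature table: pattern of stage {stage} "
                    f"gates to {routed} under the gating order"
                )

    def satisfied_by(self, pattern: Mapping[str, bool], stage: str) -> bool:
        """True if a boolean positivity pattern meets the stage signature."""
        for marker, state in self.signatures[stage].items():
            if state == "any" or marker not in pattern:
                continue
            want_positive = state in _POSITIVE_STATES
            if pattern[marker] != want_positive:
                return False
        return True


def _route_pattern(
    pattern: Mapping[str, bool],
    gating_order: Sequence[tuple[str, Mapping[str, str]]],
) -> str:
    for stage, conditions in gating_order:
        ok = True
        for marker, state in conditions.items():
            want_positive = state in _POSITIVE_STATES
            if pattern.get(marker, False) != want_positive:
                ok = False
                break
        if ok:
            return stage
    raise RuntimeError("gating order has no catch-all rule")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_META_PREFIX = "meta_"


def write_events(events: EventMatrix, path: str | Path, format: str = "csv") -> None:
    """Write an event table to CSV (markers + ``meta_`` columns) or FCS 3.0.

    FCS holds numeric channels only, so annotations are dropped when
    writing FCS; CSV round-trips annotations losslessly.
    """
    path = Path(path)
    if format == "csv":
        df = events.intensities.copy()
        for col in events.annotations.columns:
            df[_META_PREFIX + col] = events.annotations[col].values
        df.to_csv(path, index=False)
    elif format == "fcs":
        _write_fcs(path, events.intensities)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_events(path: str | Path, format: str = "csv") -> EventMatrix:
    """Read an event table from CSV or FCS; marker channels mapped by name."""
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path)
        meta_cols = [c for c in df.columns if c.startswith(_META_PREFIX)]
        marker_cols = [c for c in df.columns if c not in meta_cols]
        annotations = df[meta_cols].rename(
            columns={c: c[len(_META_PREFIX):] for c in meta_cols}
        )
        events = EventMatrix(df[marker_cols].astype(float), annotations)
    elif format == "fcs":
        events = EventMatrix(_read_fcs(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    events.require_markers()
    return events


def _write_fcs(path: Path, intensities: pd.DataFrame) -> None:
    """Minimal FCS 3.0 writer: float32 data, one channel per marker."""
    data = intensities.to_numpy(dtype="<f4")
    n_events, n_par = data.shape
    keywords = {
        "$DATATYPE": "F", "$BYTEORD": "1,2,3,4", "$MODE": "L",
        "$PAR": str(n_par), "$TOT": str(n_events), "$NEXTDATA": "0",
    }
    for i, name in enumerate(intensities.columns, start=1):
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(1.0, float(np.nanmax(data)) + 1)))
    # Two-pass layout: TEXT length depends on the offsets written inside it.
    for _ in range(3):
        text = "|" + "|".join(f"{k}|{v}" for k, v in keywords.items()) + "|"
        text_start = 58
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + data.nbytes - 1
        keywords["$BEGINDATA"] = str(data_start)
        keywords["$ENDDATA"] = str(data_end)
    header = (
        f"FCS3.0    {text_start:>8d}{text_end:>8d}"
        f"{data_start:>8d}{data_end:>8d}{0:>8d}{0:>8d}"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(text.encode("ascii"))
        fh.write(data.tobytes())


def _read_fcs(path: Path) -> pd.DataFrame:
    """Minimal FCS 3.0/3.1 reader (list mode, float32/float64/int data)."""
    raw = path.read_bytes()
    if not raw[:6].startswith(b"FCS"):
        raise ValueError(f"{path} is not an FCS file")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    parts = text[1:].split(delim)
    kw = {parts[i].strip(): parts[i + 1] for i in range(0, len(parts) - 1, 2)}
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    data_start = int(kw.get("$BEGINDATA") or raw[26:34])
    dtype_char = kw["$DATATYPE"].strip().upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    if dtype_char == "F":
        dtype = np.dtype(f"{endian}f4")
    elif dtype_char == "D":
        dtype = np.dtype(f"{endian}f8")
    elif dtype_char == "I":
        bits = int(kw["$P1B"])
        dtype = np.dtype(f"{endian}u{bits // 8}")
    else:
        raise ValueError(f"unsupported FCS $DATATYPE {dtype_char!r}")
    count = n_par * n_tot
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=data_start)
    names = [kw.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)]
    return pd.DataFrame(data.reshape(n_tot, n_par).astype(float), columns=names)


# ---------------------------------------------------------------------------
# Transform and thresholds
# ---------------------------------------------------------------------------

def arcsinh_transform(events: EventMatrix, cofactor: float = 150.0) -> EventMatrix:
    """Elementwise x -> asinh(x / cofactor); standard cytometry variance
    stabilization. Monotone, so gating is unaffected as long as thresholds
    live on the same scale. Refuses to transform twice."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if events.transformed:
        raise ValueError("events are already transformed")
    out = np.arcsinh(events.intensities / cofactor)
    return EventMatrix(out, events.annotations.copy(), transformed=True)


def fit_positivity_thresholds(
    events: EventMatrix,
    method: str = "valley",
    manual: Mapping[str, float] | None = None,
    negative_mask: np.ndarray | None = None,
    quantile: float = 0.999,
    markers: Sequence[str] = REQUIRED_MARKERS,
) -> PositivityThresholds:
    """Fit one positivity threshold per marker on the transformed scale.

    ``valley`` places the cut at the kernel-density minimum between the two
    largest modes of each marker (errors on unimodal markers); ``quantile``
    takes the given quantile of a labelled negative-control subset;
    ``manual`` passes user thresholds through unchanged.
    """
    if method == "manual":
        if manual is None:
            raise ValueError("manual method requires explicit thresholds")
        return PositivityThresholds(dict(manual), method="manual")
    if events.n_events < 100:
        raise ValueError("need at least 100 events to fit thresholds")
    thresholds: dict[str, float] = {}
    if method == "valley":
        for marker in markers:
            thresholds[marker] = _valley_threshold(
                events.intensities[marker].to_numpy(), marker
            )
    elif method == "quantile":
        if negative_mask is None:
            raise ValueError("quantile method requires a negative-control mask")
        for marker in markers:
            neg = events.intensities[marker].to_numpy()[negative_mask]
            thresholds[marker] = float(np.quantile(neg, quantile))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return PositivityThresholds(thresholds, method=method)


def _valley_threshold(values: np.ndarray, marker: str, gridsize: int = 512) -> float:
    kde = gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), gridsize)
    density = kde(grid)
    peaks = argrelmax(density)[0]
    if len(peaks) < 2:
        raise ValueError(
            f"marker {marker} appears unimodal; set a manual threshold"
        )
    # two largest modes by density
    top2 = sorted(sorted(peaks, key=lambda i: density[i], reverse=True)[:2])
    lo, hi = top2
    valleys = argrelmin(density[lo : hi + 1])[0]
    if len(valleys) == 0:
        segment = density[lo : hi + 1]
        return float(grid[lo + int(np.argmin(segment))])
    inner = min(valleys, key=lambda i: density[lo + i])
    return float(grid[lo + inner])


# ---------------------------------------------------------------------------
# Stage assignment
# ---------------------------------------------------------------------------

def assign_stages(
    events: EventMatrix,
    thresholds: PositivityThresholds,
    signatures: StageSignatureTable | None = None,
) -> pd.Series:
    """Assign every event to exactly one stage A-G (a total partition).

    Uses the decision-tree gating order of the signature table; every event
    matches exactly one rule because the final rule is a catch-all.
    """
    if not events.transformed:
        raise ValueError("assign_stages expects transformed intensities")
    events.require_markers()
    signatures = signatures or StageSignatureTable()
    n = events.n_events
    labels = np.empty(n, dtype=object)
    assigned = np.zeros(n, dtype=bool)
    positive = {
        m: events.intensities[m].to_numpy() > thresholds[m]
        for m in REQUIRED_MARKERS
    }
    for stage, conditions in signatures.gating_order:
        mask = ~assigned
        for marker, state in conditions.items():
            want = state in _POSITIVE_STATES
            mask &= positive[marker] == want
        labels[mask] = stage
        assigned |= mask
    if not assigned.all():  # pragma: no cover - catch-all guarantees this
        raise RuntimeError("gating order failed to assign every event")
    return pd.Series(labels, name="stage")


def stage_composition(
    labels: pd.Series,
    annotations: pd.DataFrame | None = None,
    as_: str = "fraction",
) -> pd.DataFrame:
    """Stage x (group x subset) composition table.

    Fractions are normalized within each group x subset column and sum to
    one; counts are raw integers. Empty groups yield zero columns and a
    warning.
    """
    if as_ not in {"fraction", "count"}:
        raise ValueError("as_ must be 'fraction' or 'count'")
    frame = pd.DataFrame({"stage": labels.to_numpy()})
    group_cols = []
    if annotations is not None:
        for col in ("group", "subset"):
            if col in annotations.columns:
                frame[col] = annotations[col].to_numpy()
                group_cols.append(col)
    if group_cols:
        counts = frame.pivot_table(
            index="stage", columns=group_cols, aggfunc="size", fill_value=0
        )
    else:
        counts = frame.value_counts("stage").to_frame("all").sort_index()
    counts = counts.reindex(sorted(set(labels)), fill_value=0)
    if (counts.sum(axis=0) == 0).any():
        warnings.warn("empty group/subset combination in composition table")
    if as_ == "count":
        return counts.astype(int)
    totals = counts.sum(axis=0)
    return counts.div(totals.replace(0, np.nan), axis=1).fillna(0.0)
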