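"""Ground-truth synthetic data for every stage of the pipeline.

Four generators emulate the data classes the analysis consumes, with the
planted truth returned alongside so recovery can be asserted exactly:

* ``gen_cytometry_events`` — six-marker fluorescence events drawn from a
  per-stage two-component log-normal mixture (negative/positive modes,
  high/low for CD24), with Vg1.1/Vg2 subset labels and per-stage
  multiplicative count-accumulation factors for treatment groups
  (emigration blockade). Counts are allocated by largest-remainder
  rounding, so per-stage event numbers are deterministic.
* ``gen_expression_matrix`` — negative-binomial counts -> log2(CPM+1) for
  7 stages x 2 subsets x replicates, with stage means displaced along a
  designed lineage tree (one disjoint signature-gene block per tree edge),
  so adjacent stages are transcriptionally closer than non-adjacent ones.
* ``gen_clonotype_table`` — power-law clone sizes, planted CDR3
  amino-acid motifs at target read fractions, V-segment usage targets and
  an out-of-frame read fraction.
* ``gen_go_annotation`` — a gene -> GO-term map with a chosen fraction of
  genes carrying a cell-surface term.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cytometry_staging import REQUIRED_MARKERS, STAGES, EventMatrix
from .transcriptome_screen import ExpressionMatrix
from .repertoire import ClonotypeTable

_FRACTION_TOL = 1e-9


def _largest_remainder(expected: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative expecteds to integers summing exactly to total."""
    floors = np.floor(expected).astype(int)
    short = total - floors.sum()
    if short < 0:
        raise ValueError("total smaller than the sum of floors")
    remainders = expected - floors
    # ties broken by position for determinism
    order = np.argsort(-remainders, kind="stable")
    floors[order[:short]] += 1
    return floors


# ---------------------------------------------------------------------------
# Cytometry events
# ---------------------------------------------------------------------------

#: Raw-scale log-normal components per marker state: (log-location, log-spread).
#: Chosen so that states separate by >4 sigma after asinh(x / 150).
DEFAULT_STATE_MODEL: dict[str, tuple[float, float]] = {
    "neg": (np.log(20.0), 0.35),
    "pos": (np.log(2000.0), 0.35),
    "hi": (np.log(3000.0), 0.35),
    "lo": (np.log(80.0), 0.35),
}

#: Marker state per stage. CD117 is informative only for E vs F; stages
#: where gating treats it as "any" are generated negative.
DEFAULT_STAGE_PHENOTYPES: dict[str, dict[str, str]] = {
    "A": {"CD24": "hi", "CD25": "pos", "CD73": "neg", "CD117": "neg", "CD200": "neg", "CD371": "pos"},
    "B": {"CD24": "hi", "CD25": "neg", "CD73": "neg", "CD117": "neg", "CD200": "neg", "CD371": "pos"},
    "C": {"CD24": "hi", "CD25": "neg", "CD73": "neg", "CD117": "neg", "CD200": "neg", "CD371": "neg"},
    "D": {"CD24": "hi", "CD25": "neg", "CD73": "neg", "CD117": "neg", "CD200": "pos", "CD371": "neg"},
    "E": {"CD24": "hi", "CD25": "neg", "CD73": "pos", "CD117": "pos", "CD200": "neg", "CD371": "neg"},
    "F": {"CD24": "hi", "CD25": "neg", "CD73": "pos", "CD117": "neg", "CD200": "neg", "CD371": "neg"},
    "G": {"CD24": "lo", "CD25": "neg", "CD73": "pos", "CD117": "neg", "CD200": "neg", "CD371": "neg"},
}

#: Emigration-blockade accumulation: terminal stages C, E, G keep growing
#: (to 10x, 5x and 10x of untreated by day 10), transit stages D and F
#: saturate after a slight early increase.
DEFAULT_TREATMENT_EFFECTS: dict[str, dict[str, float]] = {
    "untreated": {s: 1.0 for s in STAGES},
    "FTY720_5d": {"A": 1.0, "B": 1.0, "C": 4.0, "D": 1.4, "E": 2.5, "F": 1.5, "G": 4.0},
    "FTY720_10d": {"A": 1.0, "B": 1.0, "C": 10.0, "D": 1.6, "E": 5.0, "F": 1.8, "G": 10.0},
}


def _default_marker_model() -> dict[str, dict[str, tuple[str, float, float]]]:
    model: dict[str, dict[str, tuple[str, float, float]]] = {}
    for stage, phenotype in DEFAULT_STAGE_PHENOTYPES.items():
        model[stage] = {}
        for marker, state in phenotype.items():
            loc, spread = DEFAULT_STATE_MODEL[state]
            model[stage][marker] = (state, loc, spread)
    return model


@dataclass
class CytometrySimConfig:
    """Study conditions for the cytometry-event generator."""

    n_events: int = 10_000
    stage_fractions: Mapping[str, float] = field(
        default_factory=lambda: {s: 1.0 / 7.0 for s in STAGES}
    )
    marker_model: Mapping[str, Mapping[str, tuple[str, float, float]]] = field(
        default_factory=_default_marker_model
    )
    subset_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"Vg1.1": 0.5, "Vg2": 0.5}
    )
    treatment_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"untreated": {s: 1.0 for s in STAGES}}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        for name, fractions in (
            ("stage_fractions", self.stage_fractions),
            ("subset_fractions", self.subset_fractions),
        ):
            vals = np.array(list(fractions.values()), dtype=float)
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"{name} must lie in [0, 1]")
            if abs(vals.sum() - 1.0) > _FRACTION_TOL:
                raise ValueError(f"{name} must sum to 1 (got {vals.sum()!r})")
        for stage, markers in self.marker_model.items():
            for marker, (_state, _loc, spread) in markers.items():
                if spread <= 0:
                    raise ValueError(f"spread must be positive ({stage}/{marker})")
        for group, factors in self.treatment_effects.items():
            for stage, f in factors.items():
                if f <= 0:
                    raise ValueError(f"accumulation factor must be > 0 ({group}/{stage})")


def gen_cytometry_events(config: CytometrySimConfig) -> EventMatrix:
    """Draw raw-scale fluorescence events with truth labels attached.

    Per group, the expected count of a stage is
    ``n_events * stage_fraction * accumulation_factor``, rounded by
    largest remainder, so the untreated group holds exactly ``n_events``
    rows. Annotations carry ``true_stage``, ``subset`` and ``group``.
    """
    rng = np.random.default_rng(config.seed)
    stages = sorted(config.stage_fractions)
    subsets = sorted(config.subset_fractions)
    blocks: list[pd.DataFrame] = []
    ann_blocks: list[pd.DataFrame] = []
    for group in config.treatment_effects:
        factors = config.treatment_effects[group]
        expected = np.array(
            [config.n_events * config.stage_fractions[s] * factors.get(s, 1.0) for s in stages]
        )
        group_total = int(round(expected.sum()))
        counts = _largest_remainder(expected, group_total)
        for stage, count in zip(stages, counts):
            if count == 0:
                continue
            model = config.marker_model[stage]
            data = {}
            for marker in REQUIRED_MARKERS:
                _state, loc, spread = model[marker]
                data[marker] = rng.lognormal(mean=loc, sigma=spread, size=count)
            blocks.append(pd.DataFrame(data))
            subset_counts = _largest_remainder(
                np.array([count * config.subset_fractions[s] for s in subsets]), count
            )
            subset_labels = np.repeat(subsets, subset_counts)
            ann_blocks.append(
                pd.DataFrame(
                    {
                        "true_stage": stage,
                        "subset": subset_labels,
                        "group": group,
                    }
                )
            )
    intensities = pd.concat(blocks, ignore_index=True)
    annotations = pd.concat(ann_blocks, ignore_index=True)
    return EventMatrix(intensities, annotations, transformed=False)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

#: Designed lineage: A-B-C-D backbone, D branching to E and to F-G.
DEFAULT_TOPOLOGY: tuple[tuple[str, str], ...] = (
    ("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("D", "F"), ("F", "G"),
)


@dataclass
class ExpressionSimConfig:
    """Study conditions for the population expression-profile generator."""

    topology: Sequence[tuple[str, str]] = DEFAULT_TOPOLOGY
    n_genes: int = 500
    signature_panels: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=dict
    )  # panel -> gene name -> stage -> log2 shift
    baseline: float = 6.0
    dispersion: float = 0.05
    n_replicates: int = 2
    subsets: Sequence[str] = ("Vg1.1", "Vg2")
    genes_per_edge: int = 40
    edge_effect: float = 1.5
    gene_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        nodes = {n for e in self.topology for n in e}
        if nodes != set(STAGES):
            raise ValueError("topology must cover exactly the 7 stages A-G")
        if len(self.topology) != len(STAGES) - 1:
            raise ValueError("topology must be a tree (6 edges over 7 stages)")
        # connectivity check by union-find
        parent = {n: n for n in nodes}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in self.topology:
            ru, rv = find(u), find(v)
            if ru == rv:
                raise ValueError("topology contains a cycle")
            parent[ru] = rv
        if len({find(n) for n in nodes}) != 1:
            raise ValueError("topology is disconnected")
        needed = len(self.topology) * self.genes_per_edge
        n_panel = len({g for p in self.signature_panels.values() for g in p})
        if needed + n_panel > self.n_genes:
            raise ValueError("n_genes too small for edge blocks plus panel genes")


@dataclass
class ExpressionTruth:
    """Planted ground truth accompanying a simulated expression matrix."""

    designed_means: pd.DataFrame  # genes x stages, log2(CPM + 1) scale
    topology: tuple[tuple[str, str], ...]
    edge_genes: dict[tuple[str, str], list[str]]


def _subtree_below(topology: Sequence[tuple[str, str]], edge: tuple[str, str],
                   root: str = "A") -> set[str]:
    """Stages on the far side of ``edge`` when the tree is rooted at root."""
    adj: dict[str, set[str]] = {}
    for u, v in topology:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    u, v = edge
    # orient: child = endpoint farther from the root
    def depth(node: str) -> int:
        seen, frontier, d = {root}, {root}, 0
        while frontier:
            if node in frontier:
                return d
            frontier = {n for f in frontier for n in adj[f] if n not in seen}
            seen |= frontier
            d += 1
        raise ValueError("node unreachable")

    child = v if depth(v) > depth(u) else u
    other = u if child == v else v
    members, frontier = {child}, {child}
    while frontier:
        frontier = {
            n for f in frontier for n in adj[f] if n not in members and n != other
        }
        members |= frontier
    return members


def gen_expression_matrix(
    config: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Simulate log2(CPM+1) profiles along the designed lineage tree.

    Stage mean log2 levels start from a per-gene baseline; each tree edge
    owns a disjoint block of signature genes shifted by ``edge_effect`` in
    every stage of the subtree beyond that edge, making squared distances
    between stage means additive along the tree (adjacent < non-adjacent).
    Counts are gamma-Poisson (negative binomial) with the configured
    dispersion; ``dispersion = 0`` returns the noiseless expectation.
    """
    rng = np.random.default_rng(config.seed)
    panel_genes = sorted({g for p in config.signature_panels.values() for g in p})
    n_auto = config.n_genes - len(panel_genes)
    genes = panel_genes + [f"gene_{i + 1:04d}" for i in range(n_auto)]
    stages = list(STAGES)
    base = config.baseline + rng.normal(0.0, config.gene_sd, size=config.n_genes)
    M = pd.DataFrame(
        np.tile(base[:, None], (1, len(stages))), index=genes, columns=stages
    )
    edge_genes: dict[tuple[str, str], list[str]] = {}
    cursor = len(panel_genes)
    for edge in config.topology:
        block = genes[cursor : cursor + config.genes_per_edge]
        cursor += config.genes_per_edge
        edge_genes[tuple(edge)] = block
        below = _subtree_below(config.topology, tuple(edge))
        M.loc[block, sorted(below)] += config.edge_effect
    for panel in config.signature_panels.values():
        for gene, effects in panel.items():
            for stage, shift in effects.items():
                M.loc[gene, stage] += shift
    lam = np.maximum(2.0**M.to_numpy() - 1.0, 0.0)  # expected counts per stage
    lib = lam.sum(axis=0)
    designed = pd.DataFrame(
        np.log2(1e6 * lam / lib + 1.0), index=genes, columns=stages
    )
    columns, values, meta_rows = [], [], []
    for subset in config.subsets:
        for stage_idx, stage in enumerate(stages):
            for rep in range(1, config.n_replicates + 1):
                mu = lam[:, stage_idx]
                if config.dispersion == 0:
                    counts = mu.copy()
                else:
                    shape = 1.0 / config.dispersion
                    rate = rng.gamma(shape, scale=mu * config.dispersion)
                    counts = rng.poisson(rate).astype(float)
                total = counts.sum()
                if total == 0:
                    raise RuntimeError("degenerate simulation: empty library")
                values.append(np.log2(1e6 * counts / total + 1.0))
                name = f"{subset}_{stage}_{rep}"
                columns.append(name)
                meta_rows.append(
                    {"sample": name, "subset": subset, "stage": stage, "replicate": rep}
                )
    frame = pd.DataFrame(np.column_stack(values), index=genes, columns=columns)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    truth = ExpressionTruth(designed, tuple(tuple(e) for e in config.topology), edge_genes)
    return ExpressionMatrix(frame, meta), truth


# ---------------------------------------------------------------------------
# Clonotype tables
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODON = {  # one representative codon per amino acid
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


@dataclass
class RepertoireSimConfig:
    """Study conditions for the clonotype-table generator."""

    n_clones: int = 200
    clone_size_law: float = 1.0  # power-law exponent on clone rank
    planted_motifs: Sequence[tuple[str, float]] = ()  # (aa motif, read fraction)
    v_usage: Mapping[str, float] = field(
        default_factory=lambda: {"TRDV4": 0.4, "TRDV6-3": 0.6}
    )
    out_of_frame_fraction: float = 0.0
    total_reads: int = 10_000
    locus: str = "TRD"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1 or self.total_reads < 1:
            raise ValueError("n_clones and total_reads must be positive")
        if not 0.0 <= self.out_of_frame_fraction <= 1.0:
            raise ValueError("out_of_frame_fraction must lie in [0, 1]")
        v_total = sum(self.v_usage.values())
        if abs(v_total - 1.0) > _FRACTION_TOL:
            raise ValueError(f"v_usage must sum to 1 (got {v_total!r})")
        motif_total = sum(f for _, f in self.planted_motifs)
        if motif_total > 1.0 + _FRACTION_TOL:
            raise ValueError("planted motif fractions must sum to <= 1")


@dataclass
class RepertoireTruth:
    motif_fractions: dict[str, float]
    v_usage: dict[str, float]
    out_of_frame_fraction: float


def _random_cdr3(rng: np.random.Generator, motif: str | None = None) -> tuple[str, str]:
    length = int(rng.integers(9, 17))
    aa = "C" + "".join(rng.choice(list(_AA), size=length - 2)) + "F"
    if motif:
        pos = int(rng.integers(1, max(2, len(aa) - len(motif))))
        aa = aa[:pos] + motif + aa[pos + len(motif):]
    nt = "".join(_CODON[c] for c in aa)
    return aa, nt


def gen_clonotype_table(
    config: RepertoireSimConfig,
) -> tuple[ClonotypeTable, RepertoireTruth]:
    """Simulate one library's clonotype table with planted structure.

    Read mass splits into an out-of-frame compartment and, within the
    in-frame mass, one compartment per planted motif at its target
    fraction; the remainder follows a rank^(-a) power law. Counts are a
    single multinomial draw of ``total_reads`` reads, so realized motif
    fractions deviate from targets only by multinomial sampling error.
    V labels are assigned to clones by a largest-deficit rule on expected
    read mass so read-level V usage tracks ``v_usage`` tightly.
    """
    rng = np.random.default_rng(config.seed)
    in_frame_mass = 1.0 - config.out_of_frame_fraction
    motif_mass = sum(f for _, f in config.planted_motifs) * in_frame_mass
    bulk_mass = in_frame_mass - motif_mass
    if bulk_mass < -_FRACTION_TOL:
        raise ValueError("motif fractions exceed the in-frame mass")
    rows: list[dict] = []
    probs: list[float] = []
    seen_cdr3: set[str] = set()

    def fresh_cdr3(motif: str | None = None) -> tuple[str, str]:
        for _ in range(1000):
            aa, nt = _random_cdr3(rng, motif)
            if nt not in seen_cdr3:
                seen_cdr3.add(nt)
                return aa, nt
        raise RuntimeError("could not generate a unique CDR3")

    # planted-motif clones: a handful per motif, sharing its target mass
    for motif, target in config.planted_motifs:
        n_m = max(1, config.n_clones // 20)
        weights = (np.arange(1, n_m + 1)) ** (-config.clone_size_law)
        weights = weights / weights.sum() * target * in_frame_mass
        for w in weights:
            aa, nt = fresh_cdr3(motif.upper())
            rows.append({"cdr3aa": aa, "cdr3nt": nt, "kind": "motif"})
            probs.append(w)
    # bulk in-frame clones
    n_bulk = max(1, config.n_clones - len(rows))
    weights = (np.arange(1, n_bulk + 1)) ** (-config.clone_size_law)
    weights = weights / weights.sum() * bulk_mass
    for w in weights:
        aa, nt = fresh_cdr3()
        rows.append({"cdr3aa": aa, "cdr3nt": nt, "kind": "bulk"})
        probs.append(w)
    # out-of-frame clones: frameshifted nt length, '_' marks the aa field
    if config.out_of_frame_fraction > 0:
        n_oof = max(1, config.n_clones // 10)
        weights = (np.arange(1, n_oof + 1)) ** (-config.clone_size_law)
        weights = weights / weights.sum() * config.out_of_frame_fraction
        for w in weights:
            aa, nt = fresh_cdr3()
            rows.append({"cdr3aa": aa + "_", "cdr3nt": nt + "A", "kind": "oof"})
            probs.append(w)
    probs_arr = np.asarray(probs)
    probs_arr = probs_arr / probs_arr.sum()
    counts = rng.multinomial(config.total_reads, probs_arr)
    # V assignment: clones go to the V label with the largest remaining deficit
    v_labels = sorted(config.v_usage)
    deficits = {v: config.v_usage[v] for v in v_labels}
    order = np.argsort(-probs_arr, kind="stable")
    assigned_v = [""] * len(rows)
    for i in order:
        v = max(v_labels, key=lambda lbl: deficits[lbl])
        assigned_v[i] = v
        deficits[v] -= probs_arr[i]
    df = pd.DataFrame(rows)
    df["count"] = counts
    df["v"] = assigned_v
    df["d"] = "TRDD1"
    df["j"] = "TRDJ1"
    df = df[df["count"] > 0].reset_index(drop=True)
    df["freq"] = df["count"] / df["count"].sum()
    table = ClonotypeTable(
        df[["count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j", "kind"]],
        {"locus": config.locus},
    )
    truth = RepertoireTruth(
        {m: f for m, f in config.planted_motifs},
        dict(config.v_usage),
        config.out_of_frame_fraction,
    )
    return table, truth


# ---------------------------------------------------------------------------
# GO annotation map
# ---------------------------------------------------------------------------

def gen_go_annotation(
    genes: Sequence[str],
    surface_terms: Sequence[str] = ("GO:0009986", "GO:0005886"),
    member_fraction: float = 0.3,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Assign each gene a term list; a fraction carry a surface term."""
    if not 0.0 <= member_fraction <= 1.0:
        raise ValueError("member_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for gene in genes:
        terms = ["GO:0008150"]  # generic biological-process placeholder
        if rng.random() < member_fraction:
            terms.append(str(rng.choice(list(surface_terms))))
        out[gene] = terms
    return out


def write_go_annotation(go_map: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for gene, terms in go_map.items():
            fh.write(f"{gene}\t{'; '.join(terms)}\n")


def read_go_annotation(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            gene, _, terms = line.rstrip("\n").partition("\t")
            out[gene] = [t.strip() for t in terms.split(";") if t.strip()]
    return out
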