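"""Lipid traffic analysis: presence calling, A/B/U/N2 typing, switch analysis.

Traffic analysis classifies each lipid variable by where it is found across
the compartments (tissues, sample types or colony member classes) of a
biological network, separately for each phenotype group:

* **A-type** — present in every compartment of the network.
* **B-type** — present in both compartments of an adjacent (edge-connected)
  pair; a lipid spanning several edges is B-type on each of them.  A-type
  lipids are excluded from B-sets by default, preserving the contrast
  between the ubiquitous set and the per-edge sets.
* **U-type** — present in exactly one compartment.
* **N2-type** — present in exactly two *non-adjacent* compartments; flags
  variables that exist independently or imply unexpected connections.

Lipids present in three or more (but not all) compartments that cover no
edge fall into a residual "other" set and are reported, not dropped.

A *switch analysis* compares the per-category variable sets of two
phenotypes with the Jaccard-Tanimoto coefficient J = |intersection|/|union|
and a permutation p-value: random variable sets of the observed sizes are
drawn from the class-level detected universe, and the observed J is ranked
two-sidedly against the null draws relative to the null mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .signal_sheet import SignalSheet

__all__ = [
    "CompartmentNetwork",
    "PresenceMatrix",
    "TrafficClassification",
    "SwitchComparison",
    "TrafficError",
    "call_presence",
    "classify_traffic",
    "jaccard",
    "jaccard_p",
    "switch_analysis",
]


class TrafficError(ValueError):
    pass


@dataclass(frozen=True)
class CompartmentNetwork:
    """Named compartments plus undirected adjacency edges (no self-loops)."""

    compartments: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.compartments) < 2:
            raise TrafficError("a network needs at least 2 compartments")
        if len(set(self.compartments)) != len(self.compartments):
            raise TrafficError("duplicate compartment names")
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise TrafficError(f"self-loop on compartment {a!r}")
            if a not in self.compartments or b not in self.compartments:
                raise TrafficError(f"edge ({a!r}, {b!r}) references unknown compartment")
            key = frozenset((a, b))
            if key in seen:
                raise TrafficError(f"duplicate edge ({a!r}, {b!r})")
            seen.add(key)

    @classmethod
    def from_edges(
        cls, compartments: Iterable[str], edges: Iterable[Sequence[str]]
    ) -> "CompartmentNetwork":
        return cls(tuple(compartments), tuple((a, b) for a, b in edges))

    def is_adjacent(self, a: str, b: str) -> bool:
        return any({a, b} == {x, y} for x, y in self.edges)

    def edge_key(self, a: str, b: str) -> tuple[str, str]:
        """Canonical (network-ordered) form of an edge or pair."""
        i, j = self.compartments.index(a), self.compartments.index(b)
        return (a, b) if i < j else (b, a)

    def nonadjacent_pairs(self) -> list[tuple[str, str]]:
        out = []
        comps = self.compartments
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                if not self.is_adjacent(comps[i], comps[j]):
                    out.append((comps[i], comps[j]))
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.compartments)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_json(cls, path: str | Path) -> "CompartmentNetwork":
        data = json.loads(Path(path).read_text())
        return cls.from_edges(data["compartments"], data["edges"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "compartments": list(self.compartments),
                    "edges": [list(e) for e in self.edges],
                },
                indent=2,
            )
            + "\n"
        )


@dataclass
class PresenceMatrix:
    """Per-phenotype presence calls: lipid id -> set of compartments."""

    phenotype: str
    presence: dict[str, set[str]]
    call_threshold: float = 0.66

    def lipids(self) -> set[str]:
        return {k for k, v in self.presence.items() if v}


def call_presence(
    sheet: SignalSheet,
    phenotype: str,
    min_frac: float = 0.66,
    lipid_class: str | None = None,
    use_annotation: bool = True,
) -> PresenceMatrix:
    """Call lipid presence per compartment for one phenotype group.

    A lipid is present in a compartment iff the fraction of that
    (phenotype, compartment) group's samples with intensity > 0 is >=
    ``min_frac`` (inclusive, 0.66 by default).  Features are identified by
    their annotation where available (falling back to feature_id), so DG
    in-source fragments annotated with their parent TG are pooled with it:
    a merged variable counts as detected in a sample if any of its features
    has signal there.  ``lipid_class`` restricts the call to one class.
    """
    if not 0 < min_frac <= 1:
        raise TrafficError("min_frac must be in (0, 1]")
    samples = [
        s
        for s in sheet.samples
        if s.role == "analytical" and s.phenotype == phenotype
    ]
    if not samples:
        raise TrafficError(f"no analytical samples with phenotype {phenotype!r}")
    by_comp: dict[str, list[int]] = {}
    for s in samples:
        by_comp.setdefault(s.compartment, []).append(sheet.sample_index(s.sample_id))

    # group features by variable identity (annotation merges DG fragments)
    variables: dict[str, list[int]] = {}
    for i, f in enumerate(sheet.features):
        if lipid_class is not None and f.lipid_class != lipid_class:
            continue
        name = f.annotation if (use_annotation and f.annotation) else f.feature_id
        variables.setdefault(name, []).append(i)

    presence: dict[str, set[str]] = {}
    for name, rows in variables.items():
        comps = set()
        for comp, cols in by_comp.items():
            detected = (sheet.intensities[np.ix_(rows, cols)] > 0).any(axis=0)
            if detected.mean() >= min_frac:
                comps.add(comp)
        presence[name] = comps
    return PresenceMatrix(phenotype=phenotype, presence=presence, call_threshold=min_frac)


@dataclass
class TrafficClassification:
    """A/B/U/N2 assignment of one phenotype's lipids over a network."""

    phenotype: str
    lipid_class: str
    network: CompartmentNetwork
    a_set: set[str] = field(default_factory=set)
    b_sets: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    u_sets: dict[str, set[str]] = field(default_factory=dict)
    n2_sets: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    other_set: set[str] = field(default_factory=set)

    def detected(self) -> set[str]:
        out = set(self.a_set) | set(self.other_set)
        for s in self.b_sets.values():
            out |= s
        for s in self.u_sets.values():
            out |= s
        for s in self.n2_sets.values():
            out |= s
        return out

    def category_sets(self) -> dict[str, set[str]]:
        """Flat mapping of category labels to lipid sets."""
        out = {"A": set(self.a_set)}
        for e, s in self.b_sets.items():
            out[f"B@{e[0]}-{e[1]}"] = set(s)
        for c, s in self.u_sets.items():
            out[f"U@{c}"] = set(s)
        for p, s in self.n2_sets.items():
            out[f"N2@{p[0]}|{p[1]}"] = set(s)
        return out


def classify_traffic(
    presence: PresenceMatrix,
    network: CompartmentNetwork,
    lipid_class: str = "",
    b_excludes_a: bool = True,
) -> TrafficClassification:
    """Classify each present lipid by its compartment pattern.

    A-type iff present in every network compartment; U-type iff present in
    exactly one; N2-type iff present in exactly two non-adjacent
    compartments; B-type on every edge both of whose endpoints contain it
    (excluding A-type lipids unless ``b_excludes_a`` is False).  Lipids in
    more than two but not all compartments covering no edge go to
    ``other_set``.
    """
    unknown = {
        c for comps in presence.presence.values() for c in comps
    } - set(network.compartments)
    if unknown:
        raise TrafficError(f"presence references unknown compartments {sorted(unknown)}")
    cls = TrafficClassification(
        phenotype=presence.phenotype,
        lipid_class=lipid_class,
        network=network,
        b_sets={network.edge_key(*e): set() for e in network.edges},
        u_sets={c: set() for c in network.compartments},
        n2_sets={network.edge_key(*p): set() for p in network.nonadjacent_pairs()},
    )
    all_comps = set(network.compartments)
    for lipid, comps in sorted(presence.presence.items()):
        if not comps:
            continue
        is_a = comps == all_comps
        if is_a:
            cls.a_set.add(lipid)
        elif len(comps) == 1:
            cls.u_sets[next(iter(comps))].add(lipid)
            continue
        elif len(comps) == 2:
            a, b = sorted(comps, key=network.compartments.index)
            if not network.is_adjacent(a, b):
                cls.n2_sets[(a, b)].add(lipid)
                continue
        if is_a and b_excludes_a:
            continue
        covered = False
        for x, y in network.edges:
            if x in comps and y in comps:
                cls.b_sets[network.edge_key(x, y)].add(lipid)
                covered = True
        if not is_a and not covered and len(comps) >= 3:
            cls.other_set.add(lipid)
    return cls


# -- Jaccard-Tanimoto statistics ------------------------------------------


def jaccard(set_1: Iterable, set_2: Iterable) -> float:
    """Jaccard-Tanimoto coefficient |intersection| / |union|; 1.0 if both empty."""
    s1, s2 = set(set_1), set(set_2)
    union = s1 | s2
    if not union:
        return 1.0
    return len(s1 & s2) / len(union)


def _null_jaccards(
    n_universe: int, n1: int, n2: int, rng: np.random.Generator, n_perm: int
) -> np.ndarray:
    # |intersection| of two uniform random subsets of fixed sizes is
    # hypergeometric; sampling it directly is equivalent to drawing the
    # subsets and far faster.
    if n1 == 0 or n2 == 0:
        k = np.zeros(n_perm)
    else:
        k = rng.hypergeometric(n1, n_universe - n1, n2, size=n_perm).astype(float)
    return k / (n1 + n2 - k) if (n1 + n2) else np.ones(n_perm)


def jaccard_p(
    set_1: Iterable,
    set_2: Iterable,
    universe: Iterable,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    method: str = "auto",
    ties: str = "conservative",
) -> float:
    """Permutation p-value for the overlap of two sets within a universe.

    Null model: variable sets of the observed sizes drawn uniformly from the
    universe, making the intersection size hypergeometric.  The p-value is
    two-sided relative to the null mean of J:
    ``p = (1 + #{null J at least as extreme}) / (n_perm + 1)``.

    ``method="exact"`` sums the hypergeometric pmf instead of sampling
    (used automatically for universes of <= 200 variables).
    ``ties="randomized"`` splits ties in the ranking uniformly, yielding a
    p-value that is exactly uniform under the null — the variant to use for
    calibration studies; the default tie-inclusive rule is conservative
    (super-uniform) because J is discrete.
    """
    s1, s2 = set(set_1), set(set_2)
    uni = set(universe)
    if not s1 <= uni or not s2 <= uni:
        raise TrafficError("both sets must be subsets of the universe")
    n, n1, n2 = len(uni), len(s1), len(s2)
    if n == 0:
        return 1.0
    j_obs = jaccard(s1, s2)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    if method == "exact" or (method == "auto" and n <= 200):
        if n1 == 0 or n2 == 0:
            return 1.0
        k = np.arange(max(0, n1 + n2 - n), min(n1, n2) + 1)
        pmf = stats.hypergeom.pmf(k, n, n1, n2)
        j_null = k / (n1 + n2 - k)
        mean = float(np.sum(pmf * j_null))
        extreme = np.abs(j_null - mean) >= abs(j_obs - mean) - 1e-12
        return float(min(1.0, np.sum(pmf[extreme])))

    j_null = _null_jaccards(n, n1, n2, rng, n_perm)
    mean = float(j_null.mean())
    d_obs = abs(j_obs - mean)
    d_null = np.abs(j_null - mean)
    if ties == "randomized":
        greater = int((d_null > d_obs + 1e-12).sum())
        tied = int((np.abs(d_null - d_obs) <= 1e-12).sum())
        u = rng.uniform()
        return float((greater + u * (tied + 1)) / (n_perm + 1))
    extreme = int((d_null >= d_obs - 1e-12).sum())
    return float((1 + extreme) / (n_perm + 1))


@dataclass
class SwitchComparison:
    """One category's two-phenotype comparison in a switch analysis."""

    category: str
    set_1: set[str]
    set_2: set[str]
    shared: set[str]
    jtc: float
    p_value: float | None
    n_permutations: int
    seed: int
    empty: bool = False

    @property
    def counts(self) -> tuple[int, int, int]:
        """(unique to phenotype 1, shared, unique to phenotype 2)."""
        return (
            len(self.set_1 - self.shared),
            len(self.shared),
            len(self.set_2 - self.shared),
        )

    def to_dict(self) -> dict:
        u1, sh, u2 = self.counts
        return {
            "category": self.category,
            "n_1": len(self.set_1),
            "n_2": len(self.set_2),
            "unique_1": u1,
            "shared": sh,
            "unique_2": u2,
            "jaccard": self.jtc,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "empty": self.empty,
        }


def switch_analysis(
    class_1: TrafficClassification,
    class_2: TrafficClassification,
    n_perm: int = 10_000,
    seed: int = 0,
    universe: set[str] | None = None,
) -> list[SwitchComparison]:
    """Compare the per-category lipid sets of two phenotypes.

    Produces one comparison per category (A; each edge's B; each
    compartment's U; each non-adjacent pair's N2) plus an ``"all"``
    comparison over every detected variable of the lipid class.  The
    permutation universe defaults to the union of variables detected in
    either phenotype.  Categories empty in both phenotypes are flagged and
    carry no p-value.
    """
    if class_1.network != class_2.network:
        raise TrafficError("switch analysis requires identical networks")
    if class_1.lipid_class != class_2.lipid_class:
        raise TrafficError("switch analysis requires the same lipid class")
    uni = universe if universe is not None else class_1.detected() | class_2.detected()
    cats_1 = class_1.category_sets()
    cats_2 = class_2.category_sets()
    labels = ["all"] + list(cats_1)
    cats_1["all"] = class_1.detected()
    cats_2["all"] = class_2.detected()

    out = []
    rng = np.random.default_rng(seed)
    for label in labels:
        s1, s2 = cats_1[label], cats_2[label]
        empty = not s1 and not s2
        p = None
        if not empty:
            p = jaccard_p(s1, s2, uni, n_perm=n_perm, seed=rng)
        out.append(
            SwitchComparison(
                category=label,
                set_1=s1,
                set_2=s2,
                shared=s1 & s2,
                jtc=jaccard(s1, s2),
                p_value=p,
                n_permutations=n_perm,
                seed=seed,
                empty=empty,
            )
        )
    return out
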