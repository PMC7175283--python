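"""Body-bar rigidity analysis: pebble game, dilution, labels, flexibility index.

Every atom is treated as a rigid body with six degrees of freedom, and every
interaction contributes a fixed number of distance bars between its two
bodies: five for a rotatable covalent bond (one dihedral left free), six for
a locked bond, five for a hydrogen bond or salt bridge, and two for a
hydrophobic tether.  Generic rigidity of such a multigraph is decided
combinatorially by the (6,6) pebble game: an edge set is independent exactly
when every sub-multigraph on ``n`` bodies spans at most ``6 n - 6`` bars.

Hydrogen-bond dilution removes the energy-dependent bonds one at a time from
weakest to strongest, recomputing the rigid-cluster decomposition after each
removal — a combinatorial analogue of slowly heating the protein.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .interactions import Interaction, Kind
from .structure import ProteinStructure, ResidueRef

logger = logging.getLogger(__name__)

DOF_PER_BODY = 6

#: Bars contributed by each interaction kind.
BAR_POLICY: dict[Kind, int] = {
    Kind.COVALENT_ROTATABLE: 5,
    Kind.COVALENT_LOCKED: 6,
    Kind.HBOND: 5,
    Kind.SALT_BRIDGE: 5,
    Kind.HYDROPHOBIC: 2,
}


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full flexibility-signature pipeline."""

    theta_rigid: float = 0.70          # rigid-fraction threshold for the cutoff
    min_cluster_residues: int = 2      # a rigid region must span >= this many residues
    k_neighbors: int = 3               # KNN neighbourhood size (odd)
    delta_prevalence: float = 0.25     # sensitive-feature prevalence gap
    bootstrap_iters: int = 10_000
    max_subset_size: int = 8           # exhaustive-search subset ceiling
    sfs_target_size: int = 8           # sequential-selection target size
    efs_guard: int = 5_000_000         # max subsets the exhaustive search will accept
    rng_seed: int = 0
    #: "strongest_above": most negative energy still holding >= theta_rigid
    #: rigid; "first_below": the first step past that level.
    cutoff_rule: Literal["strongest_above", "first_below"] = "strongest_above"

    def __post_init__(self) -> None:
        if not 0 < self.theta_rigid < 1:
            raise ValueError("theta_rigid must lie in (0, 1)")
        if self.k_neighbors % 2 == 0 or self.k_neighbors < 1:
            raise ValueError("k_neighbors must be a positive odd integer")
        for name in ("min_cluster_residues", "bootstrap_iters",
                     "max_subset_size", "sfs_target_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class ConstraintNetwork:
    """Multigraph of 6-DOF bodies joined by integer bar counts."""

    bodies: tuple[int, ...]                      # atom serials, sorted
    edges: dict[tuple[int, int], int]            # (u, v) u < v -> bar count
    kinds: dict[tuple[int, int], Kind] = field(default_factory=dict)

    def __post_init__(self) -> None:
        body_set = set(self.bodies)
        for (u, v), bars in self.edges.items():
            if u == v:
                raise ValueError("self-edges are not allowed")
            if u not in body_set or v not in body_set:
                raise ValueError(f"edge ({u}, {v}) references unknown body")
            if bars not in (2, 5, 6):
                raise ValueError(f"bar count {bars} outside policy {{2, 5, 6}}")

    @property
    def total_bars(self) -> int:
        return sum(self.edges.values())


def build_constraint_network(interactions: Sequence[Interaction],
                             energy_cutoff: float = 0.0) -> ConstraintNetwork:
    """Assemble the body-bar network at one energy cutoff.

    Covalent bonds and hydrophobic tethers are always present; hydrogen
    bonds and salt bridges enter only if their energy is at least as strong
    (as negative) as ``energy_cutoff``.
    """
    if not interactions:
        raise ValueError("empty interaction list")
    edges: dict[tuple[int, int], int] = {}
    kinds: dict[tuple[int, int], Kind] = {}
    for it in interactions:
        if it.kind in (Kind.HBOND, Kind.SALT_BRIDGE) and it.energy > energy_cutoff:
            continue
        bars = BAR_POLICY[it.kind]
        prev = edges.get(it.pair)
        if prev is None or bars > prev:
            edges[it.pair] = bars
            kinds[it.pair] = it.kind
    bodies = tuple(sorted({s for pair in edges for s in pair}
                          | {s for it in interactions for s in it.pair}))
    return ConstraintNetwork(bodies=bodies, edges=edges, kinds=kinds)


class _PebbleGame:
    """The (6,6) pebble game on a body-bar multigraph.

    Vertices start with six pebbles.  A bar between ``u`` and ``v`` is
    accepted (independent) when seven pebbles can be gathered onto the pair;
    acceptance consumes one pebble and orients the bar.  Pebble searches are
    depth-first with neighbours visited in ascending index order, which makes
    the whole procedure deterministic.
    """

    def __init__(self, n: int):
        self.n = n
        self.pebbles = [DOF_PER_BODY] * n
        # directed multigraph: out[u][v] = number of bars oriented u -> v
        self.out: list[dict[int, int]] = [dict() for _ in range(n)]

    def _find_pebble(self, root: int, blocked: tuple[int, ...]) -> bool:
        """DFS from ``root``; on success move one pebble to ``root``."""
        seen = [False] * self.n
        for b in blocked:
            seen[b] = True
        seen[root] = True
        parent: dict[int, int] = {}
        stack = [root]
        found = -1
        while stack:
            u = stack.pop()
            for v in sorted(self.out[u]):
                if seen[v]:
                    continue
                seen[v] = True
                parent[v] = u
                if self.pebbles[v] > 0:
                    found = v
                    stack.clear()
                    break
                stack.append(v)
        if found < 0:
            return False
        # reverse the path: move the pebble back to the root
        self.pebbles[found] -= 1
        self.pebbles[root] += 1
        v = found
        while v != root:
            u = parent[v]
            self.out[u][v] -= 1
            if self.out[u][v] == 0:
                del self.out[u][v]
            self.out[v][u] = self.out[v].get(u, 0) + 1
            v = u
        return True

    def collect(self, u: int, v: int, target: int = DOF_PER_BODY + 1) -> bool:
        """Try to gather ``target`` pebbles onto the pair ``(u, v)``."""
        while self.pebbles[u] + self.pebbles[v] < target:
            if self._find_pebble(u, (u, v)):
                continue
            if self._find_pebble(v, (u, v)):
                continue
            return False
        return True

    def insert_bar(self, u: int, v: int) -> bool:
        """Insert one bar; returns True when independent."""
        if not self.collect(u, v):
            return False
        self.pebbles[u] -= 1
        self.out[u][v] = self.out[u].get(v, 0) + 1
        return True

    def pair_rigid(self, u: int, v: int) -> bool:
        """A pair is mutually rigid when a seventh pebble cannot be freed."""
        return not self.collect(u, v)


@dataclass
class RigidDecomposition:
    """Partition of bodies into rigid clusters plus the floppy-mode count."""

    bodies: tuple[int, ...]
    cluster_of: dict[int, int]          # body serial -> cluster id
    clusters: dict[int, tuple[int, ...]]  # cluster id -> sorted body serials
    floppy_modes: int
    independent_bars: int

    @property
    def cluster_sizes(self) -> list[int]:
        return sorted((len(m) for m in self.clusters.values()), reverse=True)

    @property
    def largest_cluster_id(self) -> int:
        # largest body count; ties broken by the lowest minimum serial
        return min(self.clusters, key=lambda c: (-len(self.clusters[c]),
                                                 self.clusters[c][0]))

    def same_cluster(self, u: int, v: int) -> bool:
        return self.cluster_of[u] == self.cluster_of[v]


class _UnionFind:
    def __init__(self, items: Iterable[int]):
        self.parent = {i: i for i in items}

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def run_pebble_game(net: ConstraintNetwork) -> RigidDecomposition:
    """Play the (6,6) pebble game and extract rigid clusters and floppy modes.

    Floppy modes are internal degrees of freedom: free pebbles summed per
    connected component, minus the six trivial rigid-body motions of each
    component.  Mutual rigidity of bodies is transitive in the body-bar
    picture (two clusters sharing a full 6-DOF body cannot move relative to
    it), so clusters are the connected components of the pairwise-rigid
    relation restricted to network edges.
    """
    bodies = net.bodies
    index = {s: i for i, s in enumerate(bodies)}
    game = _PebbleGame(len(bodies))
    accepted = 0
    ordered = sorted(net.edges.items())
    for (u, v), bars in ordered:
        iu, iv = index[u], index[v]
        for _ in range(bars):
            if game.insert_bar(iu, iv):
                accepted += 1
    # connected components over all edges (including redundant bars)
    uf_conn = _UnionFind(range(len(bodies)))
    for (u, v), _ in ordered:
        uf_conn.union(index[u], index[v])
    comp_pebbles: dict[int, int] = {}
    for i in range(len(bodies)):
        root = uf_conn.find(i)
        comp_pebbles[root] = comp_pebbles.get(root, 0) + game.pebbles[i]
    floppy = sum(p - DOF_PER_BODY for p in comp_pebbles.values())
    # rigid clusters: union over edges whose endpoints are mutually rigid
    uf = _UnionFind(range(len(bodies)))
    for (u, v), _ in ordered:
        iu, iv = index[u], index[v]
        if uf.find(iu) != uf.find(iv) and game.pair_rigid(iu, iv):
            uf.union(iu, iv)
    members: dict[int, list[int]] = {}
    for i, s in enumerate(bodies):
        members.setdefault(uf.find(i), []).append(s)
    # deterministic ids: descending size, then ascending minimum serial
    ordered_clusters = sorted(members.values(), key=lambda m: (-len(m), m[0]))
    clusters = {cid: tuple(m) for cid, m in enumerate(ordered_clusters)}
    cluster_of = {s: cid for cid, m in clusters.items() for s in m}
    return RigidDecomposition(bodies=bodies, cluster_of=cluster_of,
                              clusters=clusters, floppy_modes=floppy,
                              independent_bars=accepted)


# ---------------------------------------------------------------------------
# Residue labels
# ---------------------------------------------------------------------------

LABEL_LARGEST = "largest"
LABEL_SEPARATE = "separate"
LABEL_FLEXIBLE = "flexible"

_LABEL_CHAR = {LABEL_LARGEST: "l", LABEL_SEPARATE: "s", LABEL_FLEXIBLE: "f"}


def _residue_cluster(res: ResidueRef, decomp: RigidDecomposition) -> int | None:
    """Cluster assignment of a residue: its CA body, else the majority
    cluster over its heavy atoms (ties to the cluster with the lowest
    minimum serial)."""
    if not res.heavy_atoms:
        raise ValueError(f"residue {res.key} has no heavy atoms")
    ca = res.atom("CA")
    if ca is not None and ca.serial in decomp.cluster_of:
        return decomp.cluster_of[ca.serial]
    counts: dict[int, int] = {}
    for a in res.heavy_atoms:
        cid = decomp.cluster_of.get(a.serial)
        if cid is not None:
            counts[cid] = counts.get(cid, 0) + 1
    if not counts:
        return None
    return min(counts, key=lambda c: (-counts[c], decomp.clusters[c][0]))


def label_residues(decomp: RigidDecomposition, s: ProteinStructure,
                   config: AnalysisConfig | None = None) -> list[str]:
    """Per-residue labels: part of the largest rigid region, separately
    rigid, or flexible.

    A cluster counts as a rigid region only when it spans at least
    ``min_cluster_residues`` residues; the largest rigid region is the one
    spanning the most residues (ties to the lowest minimum atom serial).
    """
    config = config or AnalysisConfig()
    assignment = [_residue_cluster(res, decomp) for res in s.residues]
    span: dict[int, int] = {}
    for cid in assignment:
        if cid is not None:
            span[cid] = span.get(cid, 0) + 1
    rigid_clusters = {cid for cid, n in span.items()
                      if n >= config.min_cluster_residues}
    if rigid_clusters:
        largest = min(rigid_clusters,
                      key=lambda c: (-span[c], decomp.clusters[c][0]))
    else:
        largest = None
    labels: list[str] = []
    for cid in assignment:
        if cid is None or cid not in rigid_clusters:
            labels.append(LABEL_FLEXIBLE)
        elif cid == largest:
            labels.append(LABEL_LARGEST)
        else:
            labels.append(LABEL_SEPARATE)
    return labels


def label_string(labels: Sequence[str]) -> str:
    return "".join(_LABEL_CHAR[l] for l in labels)


def rigid_fraction(labels: Sequence[str]) -> float:
    if not labels:
        return 0.0
    return sum(1 for l in labels if l != LABEL_FLEXIBLE) / len(labels)


# ---------------------------------------------------------------------------
# Hydrogen-bond dilution
# ---------------------------------------------------------------------------


@dataclass
class DilutionStep:
    energy: float                    # kcal/mol; all remaining bonds at least this strong
    removed_donor: int | None        # donor serial of the bond just broken
    removed_acceptor: int | None
    labels: tuple[str, ...]          # per-residue {largest, separate, flexible}
    fraction_rigid: float
    floppy_modes: int
    largest_cluster_residues: int

    @property
    def label_string(self) -> str:
        return label_string(self.labels)


@dataclass
class DilutionProfile:
    steps: list[DilutionStep]

    def __post_init__(self) -> None:
        energies = [s.energy for s in self.steps]
        if any(b > a + 1e-9 for a, b in zip(energies, energies[1:])):
            raise ValueError("dilution energies must be non-increasing")

    def energies(self) -> list[float]:
        return [s.energy for s in self.steps]


def removal_order(interactions: Sequence[Interaction]) -> list[Interaction]:
    """Breakable bonds (hydrogen bonds and salt bridges) from weakest (least
    negative) to strongest; ties by ascending donor then acceptor serial."""
    breakable = [it for it in interactions
                 if it.kind in (Kind.HBOND, Kind.SALT_BRIDGE)]
    return sorted(breakable,
                  key=lambda b: (-b.energy, b.donor or b.atom_i,
                                 b.acceptor or b.atom_j))


def hydrogen_bond_dilution(s: ProteinStructure,
                           interactions: Sequence[Interaction],
                           config: AnalysisConfig | None = None) -> DilutionProfile:
    """Break energy-dependent bonds one at a time, weakest first, recording a
    profile step whenever any residue label changes.

    The structure is required alongside the interaction list because the
    per-step labels and rigid fractions are residue-level quantities.
    """
    config = config or AnalysisConfig()
    order = removal_order(interactions)
    if not order:
        raise ValueError("dilution requires at least one hydrogen bond or salt bridge")
    fixed = [it for it in interactions
             if it.kind not in (Kind.HBOND, Kind.SALT_BRIDGE)]

    def snapshot(current: list[Interaction], energy: float,
                 removed: Interaction | None) -> DilutionStep:
        net = build_constraint_network(current, energy_cutoff=0.0)
        decomp = run_pebble_game(net)
        labels = tuple(label_residues(decomp, s, config))
        largest = sum(1 for l in labels if l == LABEL_LARGEST)
        return DilutionStep(
            energy=energy,
            removed_donor=None if removed is None else removed.donor,
            removed_acceptor=None if removed is None else removed.acceptor,
            labels=labels,
            fraction_rigid=rigid_fraction(labels),
            floppy_modes=decomp.floppy_modes,
            largest_cluster_residues=largest,
        )

    current = fixed + order
    steps = [snapshot(current, order[0].energy, None)]
    for bond in order:
        current = [it for it in current if it is not bond]
        step = snapshot(current, bond.energy, bond)
        if step.labels != steps[-1].labels:
            steps.append(step)
    return DilutionProfile(steps=steps)


def select_energy_cutoff(profile: DilutionProfile,
                         config: AnalysisConfig | None = None) -> float:
    """Pick the analysis energy from a dilution profile.

    Default rule: the most negative step energy at which the rigid-residue
    fraction is still at least ``theta_rigid``.  The alternative
    ``first_below`` rule returns the first step past that level.  If no step
    reaches the threshold, the first (weakest-energy) step is returned with
    a warning.
    """
    config = config or AnalysisConfig()
    if not profile.steps:
        raise ValueError("empty dilution profile")
    above = [i for i, st in enumerate(profile.steps)
             if st.fraction_rigid >= config.theta_rigid]
    if not above:
        warnings.warn(
            f"no dilution step reaches a rigid fraction of {config.theta_rigid:.0%};"
            " falling back to the weakest-energy step", stacklevel=2)
        return profile.steps[0].energy
    last = above[-1]
    if config.cutoff_rule == "first_below" and last + 1 < len(profile.steps):
        return profile.steps[last + 1].energy
    return profile.steps[last].energy


# ---------------------------------------------------------------------------
# Flexibility index
# ---------------------------------------------------------------------------


def compute_flexibility_index(decomp: RigidDecomposition,
                              net: ConstraintNetwork,
                              s: ProteinStructure) -> np.ndarray:
    """Per-residue flexibility index on a 0-100 scale.

    Bonds interior to a rigid cluster score 0.  The remaining bonds form
    underconstrained linkage regions (connected components after contracting
    each rigid cluster to a single body); each region scores
    ``100 * floppy_modes / rotatable_bonds`` — the fraction of its dihedral
    freedoms that remain independent.  A residue's index is the mean over
    the rotatable (5-bar) bonds incident to its atoms; locked bonds carry no
    dihedral and never enter the average.  A residue with no rotatable bond
    (fully locked) scores 0.
    """
    interior = {pair for pair in net.edges
                if decomp.cluster_of[pair[0]] == decomp.cluster_of[pair[1]]}
    contracted: dict[tuple[int, int], list[int]] = {}
    for pair, bars in net.edges.items():
        if pair in interior:
            continue
        cu, cv = decomp.cluster_of[pair[0]], decomp.cluster_of[pair[1]]
        key = (min(cu, cv), max(cu, cv))
        contracted.setdefault(key, []).append(bars)
    # connected components of the contracted linkage graph
    uf = _UnionFind({c for key in contracted for c in key})
    for cu, cv in contracted:
        uf.union(cu, cv)
    comp_of = {c: uf.find(c) for c in uf.parent}
    # per-region pebble game on the contracted multigraph
    region_index: dict[int, float] = {}
    for root in set(comp_of.values()):
        nodes = sorted(c for c, r in comp_of.items() if r == root)
        nindex = {c: i for i, c in enumerate(nodes)}
        game = _PebbleGame(len(nodes))
        for (cu, cv), bar_list in sorted(contracted.items()):
            if comp_of.get(cu) != root:
                continue
            for bars in bar_list:
                for _ in range(bars):
                    game.insert_bar(nindex[cu], nindex[cv])
        floppy = sum(game.pebbles) - DOF_PER_BODY
        rotatable = sum(
            1 for (cu, cv), bar_list in contracted.items()
            if comp_of.get(cu) == root for bars in bar_list if bars == 5)
        if rotatable == 0:
            value = 100.0 if floppy > 0 else 0.0
        else:
            value = 100.0 * min(1.0, max(0.0, floppy / rotatable))
        region_index[root] = value

    def edge_value(pair: tuple[int, int]) -> float:
        if pair in interior:
            return 0.0
        cu = decomp.cluster_of[pair[0]]
        return region_index[comp_of[cu]]

    # rotatable bonds incident to each residue
    res_of = {a.serial: res.seq_index for res in s.residues for a in res.atoms}
    sums = np.zeros(len(s.residues))
    counts = np.zeros(len(s.residues))
    for pair, bars in net.edges.items():
        if bars != 5:
            continue
        val = edge_value(pair)
        for serial in pair:
            ridx = res_of.get(serial)
            if ridx is not None:
                sums[ridx] += val
                counts[ridx] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return out
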