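"""Self-contained validation experiments.

Each function here sets up its own synthetic inputs, runs one part of the
pipeline, and measures an outcome with a known expectation: pebble-game
results against a numerical rigidity-matrix rank oracle, monotonicity of
hydrogen-bond dilution, hydrogen-bond counts on the ideal helix, the
worked nearest-neighbour example, and recovery of planted flexibility
signatures.  They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .interactions import find_hbonds
from .ml import knn_predict
from .rigidity import AnalysisConfig, ConstraintNetwork, run_pebble_game
from .synthetic import (FeatureGenSpec, make_bodybar_network,
                        make_feature_dataset, make_helix_peptide)
from . import ml
from .rigidity import hydrogen_bond_dilution
from .interactions import find_all_interactions

_SEED_CAP = 2**31 - 1


class RankOracle:
    """Generic rigidity-matrix oracle for body-bar networks.

    Each body gets a random reference point; each bar a random attachment
    pair.  A bar's constraint row couples the translational velocity along
    the bar with the angular velocity through the attachment lever arms.
    Floppy modes and pairwise rigidity follow from matrix ranks — a route
    entirely independent of the combinatorial pebble game.
    """

    def __init__(self, net: ConstraintNetwork, seed: int = 0):
        self.net = net
        self.rng = np.random.default_rng(seed)
        self.index = {b: i for i, b in enumerate(net.bodies)}
        self.n = len(net.bodies)
        self.positions = self.rng.normal(scale=2.0, size=(self.n, 3))
        rows = []
        for (u, v), bars in sorted(net.edges.items()):
            for _ in range(bars):
                rows.append(self._bar_row(self.index[u], self.index[v]))
        self.matrix = np.array(rows) if rows else np.zeros((0, 6 * self.n))
        self.rank = int(np.linalg.matrix_rank(self.matrix)) if rows else 0

    def _bar_row(self, iu: int, iv: int) -> np.ndarray:
        a_u = self.rng.normal(size=3)
        a_v = self.rng.normal(size=3)
        # the constraint direction is the bar itself: attachment to attachment
        d = (self.positions[iv] + a_v) - (self.positions[iu] + a_u)
        row = np.zeros(6 * self.n)
        row[6 * iu:6 * iu + 3] = d
        row[6 * iu + 3:6 * iu + 6] = np.cross(a_u, d)
        row[6 * iv:6 * iv + 3] = -d
        row[6 * iv + 3:6 * iv + 6] = -np.cross(a_v, d)
        return row

    def _n_components(self) -> int:
        parent = list(range(self.n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (u, v) in self.net.edges:
            ru, rv = find(self.index[u]), find(self.index[v])
            if ru != rv:
                parent[ru] = rv
        return len({find(i) for i in range(self.n)})

    def floppy_modes(self) -> int:
        return 6 * self.n - 6 * self._n_components() - self.rank

    def pair_rigid(self, u: int, v: int) -> bool:
        """True when six generic extra bars between u and v are all
        redundant, i.e. the pair admits no relative motion."""
        iu, iv = self.index[u], self.index[v]
        extra = np.array([self._bar_row(iu, iv) for _ in range(6)])
        stacked = np.vstack([self.matrix, extra])
        return int(np.linalg.matrix_rank(stacked)) == self.rank


@dataclass
class OracleComparison:
    n_networks: int
    n_floppy_agreements: int
    n_pair_comparisons: int
    n_pair_agreements: int

    @property
    def all_agree(self) -> bool:
        return (self.n_floppy_agreements == self.n_networks
                and self.n_pair_agreements == self.n_pair_comparisons)

    @property
    def agreement_percent(self) -> float:
        total = self.n_networks + self.n_pair_comparisons
        agree = self.n_floppy_agreements + self.n_pair_agreements
        return 100.0 * agree / total


def pebble_vs_rank_experiment(n_networks: int = 200, max_bodies: int = 12,
                              seed: int = 0) -> OracleComparison:
    """Compare pebble-game floppy modes and the rigid-pair relation against
    the rank oracle on random body-bar networks."""
    rng = np.random.default_rng(seed)
    floppy_ok = 0
    pair_total = pair_ok = 0
    for _ in range(n_networks):
        n = int(rng.integers(2, max_bodies + 1))
        net = make_bodybar_network("random", n,
                                   seed=int(rng.integers(0, _SEED_CAP)))
        decomp = run_pebble_game(net)
        oracle = RankOracle(net, seed=int(rng.integers(0, _SEED_CAP)))
        floppy_ok += decomp.floppy_modes == oracle.floppy_modes()
        for u, v in itertools.combinations(net.bodies, 2):
            pair_total += 1
            pair_ok += decomp.same_cluster(u, v) == oracle.pair_rigid(u, v)
    return OracleComparison(n_networks=n_networks,
                            n_floppy_agreements=floppy_ok,
                            n_pair_comparisons=pair_total,
                            n_pair_agreements=pair_ok)


@dataclass
class DilutionCheck:
    n_fixtures: int
    n_monotone: int

    @property
    def monotone_percent(self) -> float:
        return 100.0 * self.n_monotone / self.n_fixtures


def dilution_monotonicity_experiment(n_fixtures: int = 50, n_res: int = 12,
                                     seed: int = 0,
                                     jitter: float = 0.05) -> DilutionCheck:
    """Along each helix dilution, floppy modes must never decrease and the
    largest rigid region must never grow."""
    rng = np.random.default_rng(seed)
    config = AnalysisConfig()
    ok = 0
    for _ in range(n_fixtures):
        helix = make_helix_peptide(n_res, with_hbonds=True,
                                   seed=int(rng.integers(0, _SEED_CAP)),
                                   jitter=jitter)
        interactions = find_all_interactions(helix)
        profile = hydrogen_bond_dilution(helix, interactions, config)
        floppy = [st.floppy_modes for st in profile.steps]
        largest = [st.largest_cluster_residues for st in profile.steps]
        monotone = (all(b >= a for a, b in zip(floppy, floppy[1:]))
                    and all(b <= a for a, b in zip(largest, largest[1:])))
        ok += monotone
    return DilutionCheck(n_fixtures=n_fixtures, n_monotone=ok)


@dataclass
class HelixCheck:
    n_backbone_hbonds: int
    n_i_to_i4: int
    floppy_initial: int
    floppy_final: int
    largest_initial: int
    largest_final: int


def helix_hbond_experiment(n_res: int = 12) -> HelixCheck:
    """Hydrogen-bond count on the ideal helix and the rigidity loss after
    full dilution."""
    helix = make_helix_peptide(n_res, with_hbonds=True)
    hbonds = find_hbonds(helix)
    resnum = {a.serial: res.resnum for res in helix.residues for a in res.atoms}
    n_i4 = sum(1 for b in hbonds
               if resnum[b.donor] - resnum[b.acceptor] == 4)
    interactions = find_all_interactions(helix)
    profile = hydrogen_bond_dilution(helix, interactions, AnalysisConfig())
    first, last = profile.steps[0], profile.steps[-1]
    return HelixCheck(n_backbone_hbonds=len(hbonds), n_i_to_i4=n_i4,
                      floppy_initial=first.floppy_modes,
                      floppy_final=last.floppy_modes,
                      largest_initial=first.largest_cluster_residues,
                      largest_final=last.largest_cluster_residues)


#: The worked three-feature training set (H5.1l, H2.2s, H3.1f): three
#: inactive receptors at (1,0,0), two active at (1,0,1), one active at
#: (0,1,1).
WORKED_TRAINING_ROWS = np.array([
    [1, 0, 0], [1, 0, 0], [1, 0, 0],   # inactive
    [1, 0, 1], [1, 0, 1],              # active
    [0, 1, 1],                         # active
])
WORKED_TRAINING_LABELS = np.array([0, 0, 0, 1, 1, 1])


def worked_knn_example(test_row=(1, 0, 1), k: int = 3) -> int:
    """Classify the worked example's query against the six printed training
    points; 1 means active."""
    return knn_predict(WORKED_TRAINING_ROWS, WORKED_TRAINING_LABELS,
                       np.asarray(test_row), k)


@dataclass
class RecoveryResult:
    n_runs: int
    n_recovered: int

    @property
    def recovery_percent(self) -> float:
        return 100.0 * self.n_recovered / self.n_runs


def planted_recovery_experiment(n_runs: int = 100, seed: int = 0,
                                spec: FeatureGenSpec | None = None,
                                ) -> RecoveryResult:
    """Fraction of seeded generator runs in which the full
    sensitive + sequential + exhaustive pipeline ranks the planted
    signature first."""
    rng = np.random.default_rng(seed)
    base = spec or FeatureGenSpec()
    planted_names = {name for name, _, _ in base.planted}
    recovered = 0
    for _ in range(n_runs):
        run_spec = FeatureGenSpec(
            n_active=base.n_active, n_inactive=base.n_inactive,
            planted=base.planted, background=dict(base.background),
            seed=int(rng.integers(0, _SEED_CAP)))
        m = make_feature_dataset(run_spec)
        config = AnalysisConfig(rng_seed=int(rng.integers(0, _SEED_CAP)))
        result = ml.run_signature_discovery(m, config, with_bootstrap=False)
        recovered += set(result.chosen_signature) == planted_names
    return RecoveryResult(n_runs=n_runs, n_recovered=recovered)
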