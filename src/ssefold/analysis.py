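"""Ensemble analysis: RMSD clustering, scoring, interaction annotation,
and evaluation metrics.

Clustering is k-means on the pairwise RMSD matrix with the medoid rule:
the representative s_i of cluster i is the member with the smallest sum
of distances to all other members,

    s_i = argmin_k sum_{j != k, j in cluster i} d_{k,j}

Cluster representatives are ranked by a knowledge-based scoring variant
(distance-binned atom-pair pseudo-energies plus a backbone
pseudo-torsion term, trained by log-ratio to a reference state over a
configurable structure set; the shipped default is trained on synthetic
fixtures and is a stand-in for published RNA scoring potentials).
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .conformation import Conformation
from .geometry import CoordSet, kabsch, rmsd as _rmsd
from . import nucgeom

__all__ = [
    "InteractionSet",
    "ClusterSet",
    "ScoringTables",
    "pairwise_rmsd_matrix",
    "kmeans_rmsd",
    "score_structure",
    "rank_centroids",
    "annotate_interactions",
    "inf",
    "default_potential",
]

log = logging.getLogger(__name__)

# geometric annotation thresholds (documented, configurable per call)
WC_N1N3_RANGE = (2.3, 3.5)
WC_C1C1_RANGE = (9.0, 11.5)
WC_PLANE_ANGLE_MAX = 30.0  # degrees
STACK_CENTROID_MAX = 5.5  # Å between base-pair step centroids
STACK_ANGLE_MAX = 30.0


@dataclass
class InteractionSet:
    """Annotated canonical interactions of one conformation.

    ``wc_pairs`` holds unordered residue pairs in canonical Watson-Crick
    (or wobble) geometry.  ``stacks`` holds helical steps: one entry per
    stacked pair of canonical base pairs, keyed by the unordered pair of
    their 5'-most residues.
    """

    wc_pairs: set[tuple[int, int]] = field(default_factory=set)
    stacks: set[tuple[int, int]] = field(default_factory=set)


@dataclass
class ClusterSet:
    assignment: np.ndarray  # conformation index -> cluster id
    centroids: list[int]  # one conformation index per cluster
    distances: np.ndarray  # pairwise RMSD matrix
    sizes: list[int]

    @property
    def k(self) -> int:
        return len(self.centroids)


# ---------------------------------------------------------------------------
# RMSD matrix + clustering


def pairwise_rmsd_matrix(
    confs: list[Conformation], atom_subset: set[str] | None = None
) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs between all conformations."""
    if not confs:
        raise ValueError("need at least one conformation")
    seqs = {c.sequence for c in confs}
    if len(seqs) > 1:
        raise ValueError("conformations must share one sequence")
    sets = [c.coords(atom_subset) for c in confs]
    n = len(sets)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _rmsd(sets[i], sets[j], superpose=True)
    return out


def _medoid(dmat: np.ndarray, members: np.ndarray) -> int:
    """Member with the smallest distance sum to all other members.

    Ties break on the smallest conformation index.
    """
    sub = dmat[np.ix_(members, members)]
    sums = sub.sum(axis=1)
    best = members[int(np.argmin(sums))]  # argmin returns first (smallest index)
    return int(best)


def kmeans_rmsd(
    confs: list[Conformation] | None,
    k: int,
    seed: int = 0,
    dmat: np.ndarray | None = None,
    atom_subset: set[str] | None = None,
) -> ClusterSet:
    """Medoid-style k-means on the pairwise RMSD matrix.

    Initialization is farthest-point seeding from a seeded random start;
    iteration alternates nearest-medoid assignment with the argmin-sum
    medoid update until the assignment is stable.  The total
    within-cluster distance to medoids never increases across iterations.
    """
    if dmat is None:
        if confs is None:
            raise ValueError("need conformations or a distance matrix")
        dmat = pairwise_rmsd_matrix(confs, atom_subset)
    n = len(dmat)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")
    rng = np.random.default_rng(seed)

    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        dist_to_near = np.min(dmat[:, medoids], axis=1)
        dist_to_near[medoids] = -1.0
        medoids.append(int(np.argmax(dist_to_near)))

    assignment = None
    last_cost = math.inf
    for _ in range(200):
        d = dmat[:, medoids]
        new_assign = np.argmin(d, axis=1)
        # keep clusters non-empty: medoid always belongs to its own cluster
        for ci, m in enumerate(medoids):
            new_assign[m] = ci
        cost = float(
            sum(dmat[i, medoids[new_assign[i]]] for i in range(n))
        )
        if assignment is not None and np.array_equal(new_assign, assignment):
            break
        assert cost <= last_cost + 1e-9, "k-means cost increased"
        last_cost = cost
        assignment = new_assign
        medoids = [
            _medoid(dmat, np.where(assignment == ci)[0]) for ci in range(k)
        ]
    sizes = [int(np.sum(assignment == ci)) for ci in range(k)]
    return ClusterSet(assignment, medoids, dmat, sizes)


# ---------------------------------------------------------------------------
# knowledge-based scoring


@dataclass
class ScoringTables:
    """Distance- and torsion-binned pseudo-energy tables.

    ``pair_energy[(t1, t2)]`` is indexed by distance bin; ``torsion_energy``
    by backbone pseudo-torsion bin (P-C1'-P-C1').  Lower totals mean more
    native-like geometry.  Empty tables score every structure 0.
    """

    r_max: float = 20.0
    n_bins: int = 40
    n_torsion_bins: int = 24
    pair_energy: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    torsion_energy: np.ndarray | None = None

    @property
    def bin_width(self) -> float:
        return self.r_max / self.n_bins

    # -- feature extraction ----------------------------------------

    @staticmethod
    def _typed_atoms(conf: Conformation) -> list[tuple[int, str, np.ndarray]]:
        out = []
        for i in range(conf.n_residues):
            atoms = conf.residue_atoms(i)
            ngly = nucgeom.GLYCOSIDIC_N[conf.sequence[i]]
            for nm, t in (("P", "P"), ("C1'", "C1"), (ngly, "N")):
                if nm in atoms:
                    out.append((i, t, atoms[nm]))
        return out

    def _pair_counts(self, conf: Conformation) -> dict[tuple[str, str], np.ndarray]:
        typed = self._typed_atoms(conf)
        counts: dict[tuple[str, str], np.ndarray] = {}
        for a in range(len(typed)):
            ia, ta, pa = typed[a]
            for b in range(a + 1, len(typed)):
                ib, tb, pb = typed[b]
                if abs(ia - ib) < 2:
                    continue  # bonded context excluded
                d = float(np.linalg.norm(pa - pb))
                if d >= self.r_max:
                    continue
                key = tuple(sorted((ta, tb)))
                arr = counts.setdefault(key, np.zeros(self.n_bins))
                arr[int(d / self.bin_width)] += 1
        return counts

    def _torsions(self, conf: Conformation) -> list[float]:
        out = []
        for i in range(conf.n_residues - 1):
            need = [(i, "P"), (i, "C1'"), (i + 1, "P"), (i + 1, "C1'")]
            if not all(conf.has_atom(r, nm) for r, nm in need):
                continue
            p = [conf.atom(r, nm) for r, nm in need]
            out.append(_dihedral(*p))
        return out

    # -- training / scoring ----------------------------------------

    @classmethod
    def train(
        cls,
        structures: list[Conformation],
        r_max: float = 20.0,
        n_bins: int = 40,
        n_torsion_bins: int = 24,
        pseudocount: float = 1.0,
    ) -> "ScoringTables":
        """Log-ratio training against a uniform-density reference.

        Observed distance counts per atom-type pair are compared with a
        reference distribution proportional to r^2 (uniform spatial
        density); torsion counts are compared with a flat reference.
        """
        self = cls(r_max=r_max, n_bins=n_bins, n_torsion_bins=n_torsion_bins)
        totals: dict[tuple[str, str], np.ndarray] = {}
        torsion_counts = np.zeros(n_torsion_bins)
        for conf in structures:
            for key, arr in self._pair_counts(conf).items():
                totals[key] = totals.get(key, 0) + arr
            for t in self._torsions(conf):
                torsion_counts[_torsion_bin(t, n_torsion_bins)] += 1
        edges = np.linspace(0, r_max, n_bins + 1)
        ref = (edges[1:] ** 3 - edges[:-1] ** 3)  # shell volume ~ r^2 dr
        ref = ref / ref.sum()
        for key, arr in totals.items():
            obs = (arr + pseudocount) / (arr.sum() + pseudocount * n_bins)
            table = -np.log(obs / (ref + 1e-12))
            # distances never seen in the training set (clash range and
            # beyond-envelope bins) are penalized above every observed bin
            never = arr == 0
            if never.any() and (~never).any():
                table[never] = table[~never].max() + 2.0
            self.pair_energy[key] = table
        tobs = (torsion_counts + pseudocount) / (
            torsion_counts.sum() + pseudocount * n_torsion_bins
        )
        self.torsion_energy = -np.log(tobs * n_torsion_bins)
        return self

    def score(self, conf: Conformation) -> float:
        total = 0.0
        skipped = 0
        for key, arr in self._pair_counts(conf).items():
            table = self.pair_energy.get(key)
            if table is None:
                skipped += 1
                continue
            total += float(np.dot(arr, table))
        if self.torsion_energy is not None:
            for t in self._torsions(conf):
                total += float(self.torsion_energy[_torsion_bin(t, self.n_torsion_bins)])
        if skipped:
            log.warning("%d atom-type pairs had no table and were skipped", skipped)
        return total


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def _torsion_bin(t: float, n: int) -> int:
    return min(int((t + np.pi) / (2 * np.pi / n)), n - 1)


@functools.lru_cache(maxsize=1)
def default_potential() -> ScoringTables:
    """Default tables trained on the synthetic fixture set.

    A deterministic collection of ideal helices and generated
    hairpin/internal-loop structures; a stand-in for potentials trained
    on experimental structures.
    """
    from .synthetic import build_structure, random_sequence_for
    from .templates import build_ideal_helix, _template_as_conformation

    structures = []
    for seq in ("GCGCGC", "AUGCAUGC", "GGGGCCCC", "AGCUAGCUAG"):
        structures.append(_template_as_conformation(build_ideal_helix(seq)))
    fixtures = [
        "((((....))))",
        "(((((...)))))",
        "((((((....))))))",
        "(((..((((...))))..))).",
    ]
    for k, db in enumerate(fixtures):
        conf, _ = build_structure(random_sequence_for(db, seed=k), db, seed=1)
        structures.append(conf)
    return ScoringTables.train(structures)


def score_structure(
    conf: Conformation, potential: ScoringTables | None = None
) -> float:
    """Knowledge-based pseudo-energy of one conformation (lower = better)."""
    potential = potential if potential is not None else default_potential()
    return potential.score(conf)


def rank_centroids(
    clusters: ClusterSet,
    confs: list[Conformation],
    potential: ScoringTables | None = None,
) -> list[Conformation]:
    """Cluster representatives sorted by ascending score (best first)."""
    scored = []
    for ci, m in enumerate(clusters.centroids):
        scored.append((score_structure(confs[m], potential), m, ci))
    scored.sort()
    out = []
    for s, m, ci in scored:
        c = confs[m].copy()
        c.provenance["cluster"] = {
            "index": ci,
            "size": clusters.sizes[ci],
            "score": s,
            "member": m,
        }
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# geometric interaction annotation


def _base_plane(conf: Conformation, i: int):
    ring = nucgeom.BASE_RING[conf.sequence[i]]
    pts = []
    for nm in ring:
        if conf.has_atom(i, nm):
            pts.append(conf.atom(i, nm))
    if len(pts) < 3:
        return None
    pts = np.array(pts)
    com = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - com)
    return com, vt[2]


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    c = abs(float(np.dot(n1, n2)))
    return math.degrees(math.acos(min(1.0, c)))


def annotate_interactions(
    conf: Conformation,
    n1n3_range: tuple[float, float] = WC_N1N3_RANGE,
    c1c1_range: tuple[float, float] = WC_C1C1_RANGE,
    plane_angle_max: float = WC_PLANE_ANGLE_MAX,
    stack_centroid_max: float = STACK_CENTROID_MAX,
    stack_angle_max: float = STACK_ANGLE_MAX,
) -> InteractionSet:
    """Geometric detection of canonical pairs and helical stacking.

    Watson-Crick (incl. wobble) pairs require complementary bases, the
    purine N1 to pyrimidine N3 distance and the C1'-C1' distance inside
    their canonical windows, and near-parallel base planes.  Stacking is
    annotated at the helical-step level: two canonical pairs stack when
    their pair centroids are close and their planes near-parallel; the
    step is recorded under the two 5'-most residues.
    """
    n = conf.n_residues
    planes = [_base_plane(conf, i) for i in range(n)]
    wc: set[tuple[int, int]] = set()
    for i in range(n):
        if planes[i] is None:
            continue
        for j in range(i + 1, n):
            if planes[j] is None:
                continue
            bi, bj = conf.sequence[i], conf.sequence[j]
            if not nucgeom.is_complementary(bi, bj):
                continue
            pur, pyr = (i, j) if bi in "AG" else (j, i)
            # wobble G-U: G is the 'purine reference' even against U
            if bi in "AG" and bj in "AG":
                continue
            if not (conf.has_atom(pur, "N1") and conf.has_atom(pyr, "N3")):
                continue
            d_hb = float(np.linalg.norm(conf.atom(pur, "N1") - conf.atom(pyr, "N3")))
            if not (n1n3_range[0] <= d_hb <= n1n3_range[1]):
                continue
            if conf.has_atom(i, "C1'") and conf.has_atom(j, "C1'"):
                d_c1 = float(np.linalg.norm(conf.atom(i, "C1'") - conf.atom(j, "C1'")))
                if not (c1c1_range[0] <= d_c1 <= c1c1_range[1]):
                    continue
            if _plane_angle(planes[i][1], planes[j][1]) > plane_angle_max:
                continue
            wc.add((i, j))

    stacks: set[tuple[int, int]] = set()
    pairs = sorted(wc)
    for a in range(len(pairs)):
        ia, ja = pairs[a]
        ca = 0.5 * (planes[ia][0] + planes[ja][0])
        na = planes[ia][1]
        for b in range(a + 1, len(pairs)):
            ib, jb = pairs[b]
            if {ia, ja} & {ib, jb}:
                continue
            cb = 0.5 * (planes[ib][0] + planes[jb][0])
            if float(np.linalg.norm(ca - cb)) > stack_centroid_max:
                continue
            if _plane_angle(na, planes[ib][1]) > stack_angle_max:
                continue
            stacks.add((min(ia, ib), max(ia, ib)))
    return InteractionSet(wc, stacks)


# ---------------------------------------------------------------------------
# INF


def inf(pred: InteractionSet | set, native: InteractionSet | set, which: str = "wc") -> float:
    """Interaction network fidelity: sqrt(PPV x STY).

    PPV = |pred ∩ native| / |pred|, STY = |pred ∩ native| / |native|.
    Both sets empty -> 1 (nothing to find, nothing found wrongly);
    exactly one empty -> 0.
    """
    if isinstance(pred, InteractionSet):
        pred = pred.wc_pairs if which == "wc" else pred.stacks
    if isinstance(native, InteractionSet):
        native = native.wc_pairs if which == "wc" else native.stacks
    pred = set(pred)
    native = set(native)
    if not pred and not native:
        return 1.0
    if not pred or not native:
        return 0.0
    tp = len(pred & native)
    ppv = tp / len(pred)
    sty = tp / len(native)
    return math.sqrt(ppv * sty)
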