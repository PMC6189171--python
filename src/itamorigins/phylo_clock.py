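"""Distance-based protein phylogenetics with molecular-clock calibration.

The dating workflow is: compute corrected amino-acid distances from a
pre-aligned matrix, build a neighbor-joining tree (branch lengths in
substitutions/site), attach bootstrap supports by column resampling, root by
outgroup, and convert branch lengths to absolute ages with species-divergence
calibrations (Mya) under a per-clade strict clock.  For a pair of paralogous
clades (e.g. Syk vs ZAP70) each clade yields its own rate and hence its own
estimate of the duplication (root) age; the pair of estimates is reported as
a two-sided interval rather than averaged.

Trees are :class:`dendropy.Tree` objects so Newick I/O, bipartitions,
rerooting and patristic distances come from a standard toolkit; the NJ
agglomeration, clock fit and rate profile are implemented here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

log = logging.getLogger(__name__)

GAP_SYMBOLS = set("-.?X*")


class SaturationError(ValueError):
    """Corrected distance undefined because observed divergence p >= 1."""


@dataclass(frozen=True)
class DistanceSpec:
    """Distance correction model: raw p, Poisson, or gamma-rates."""

    model: str = "poisson"
    alpha: float = 1.0

    def __post_init__(self):
        if self.model not in {"p", "poisson", "gamma"}:
            raise ValueError(f"unknown distance model {self.model!r}")
        if self.model == "gamma" and not self.alpha > 0:
            raise ValueError("gamma shape alpha must be > 0")

    def correct(self, p: float) -> float:
        if self.model == "p":
            return p
        if p >= 1.0:
            raise SaturationError(f"p-distance {p} saturated under {self.model} model")
        if self.model == "poisson":
            return -math.log1p(-p)
        return self.alpha * ((1.0 - p) ** (-1.0 / self.alpha) - 1.0)


@dataclass
class ProteinAlignment:
    """Equal-length aligned residue rows keyed by taxon label."""

    taxa: list[str]
    rows: dict[str, str]

    def __post_init__(self):
        lengths = {len(self.rows[t]) for t in self.taxa}
        if len(lengths) > 1:
            raise ValueError(f"aligned rows differ in length: {sorted(lengths)}")

    @property
    def n_sites(self) -> int:
        return len(self.rows[self.taxa[0]])

    @classmethod
    def from_fasta(cls, path) -> "ProteinAlignment":
        from Bio import SeqIO

        taxa, rows = [], {}
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows[rec.id] = str(rec.seq).upper()
        if not taxa:
            raise IOError(f"no records in alignment {path}")
        return cls(taxa=taxa, rows=rows)

    def subset_columns(self, cols: Sequence[int]) -> "ProteinAlignment":
        rows = {t: "".join(self.rows[t][c] for c in cols) for t in self.taxa}
        return ProteinAlignment(taxa=list(self.taxa), rows=rows)


def pairwise_distance(row_a: str, row_b: str, spec: DistanceSpec | None = None) -> float:
    """Corrected distance between two aligned rows, substitutions/site.

    Columns where either row carries a gap or unknown symbol are excluded
    (pairwise deletion).  p = mismatches / usable columns, then the model
    correction of ``spec`` is applied.
    """
    spec = spec or DistanceSpec()
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    usable = mismatch = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a in GAP_SYMBOLS or b in GAP_SYMBOLS:
            continue
        usable += 1
        if a != b:
            mismatch += 1
    if usable == 0:
        raise ValueError("zero usable columns between rows")
    return spec.correct(mismatch / usable)


def distance_matrix(aln: ProteinAlignment, spec: DistanceSpec | None = None) -> np.ndarray:
    n = len(aln.taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pairwise_distance(
                aln.rows[aln.taxa[i]], aln.rows[aln.taxa[j]], spec
            )
    return D


def neighbor_joining(
    D: np.ndarray, labels: Sequence[str], taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Ties in the Q criterion break deterministically on the lowest (i, j)
    index pair; negative branch-length estimates are clamped to zero with a
    log warning.  Returns an unrooted tree (trifurcating seed node).
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")

    tns = taxon_namespace or dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(nd)
    active = list(range(n))
    D = D.copy()

    def clamp(x: float) -> float:
        if x < 0:
            log.warning("clamping negative NJ branch length %.4g to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index deterministic tie-break
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or Q[a, b] < Q[best] - 1e-15:
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        d_ij = sub[a, b]
        li = clamp(0.5 * d_ij + (r[a] - r[b]) / (2.0 * (m - 2)))
        lj = clamp(d_ij - (0.5 * d_ij + (r[a] - r[b]) / (2.0 * (m - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances from the new node to all remaining
        new_row = np.zeros(D.shape[0] + 1)
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # resolve the final three nodes around the seed with three-point formulas
    i, j, k = active
    d_ij, d_ik, d_jk = D[i, j], D[i, k], D[j, k]
    seed = tree.seed_node
    for nd, length in (
        (nodes[i], 0.5 * (d_ij + d_ik - d_jk)),
        (nodes[j], 0.5 * (d_ij + d_jk - d_ik)),
        (nodes[k], 0.5 * (d_ik + d_jk - d_ij)),
    ):
        seed.add_child(nd)
        nd.edge.length = clamp(length)
    tree.is_rooted = False
    return tree


def _internal_bipartitions(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    out = set()
    n_taxa = len(tree.taxon_namespace)
    for edge in tree.preorder_edge_iter():
        bp = edge.bipartition
        if bp is None:
            continue
        ones = bin(bp.split_bitmask).count("1")
        if 1 < ones < n_taxa - 1:  # skip trivial splits
            out.add(bp.split_bitmask)
    return out


def bootstrap_support(
    aln: ProteinAlignment,
    spec: DistanceSpec | None = None,
    n_replicates: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ point-estimate tree with bipartition supports from column bootstrap.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of each internal bipartition of the point-estimate tree is the
    percentage of replicate trees containing it.  Replicates that produce a
    saturated distance are skipped and logged; more than 20% skipped is an
    error.
    """
    spec = spec or DistanceSpec()
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    tns = dendropy.TaxonNamespace(list(aln.taxa))
    point = neighbor_joining(distance_matrix(aln, spec), aln.taxa, taxon_namespace=tns)
    target = _internal_bipartitions(point)
    counts = {bp: 0 for bp in target}

    rng = np.random.default_rng(seed)
    L = aln.n_sites
    skipped = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = aln.subset_columns(cols)
        try:
            rep_tree = neighbor_joining(distance_matrix(rep, spec), aln.taxa, taxon_namespace=tns)
        except SaturationError:
            skipped += 1
            log.warning("bootstrap replicate skipped: saturated distance")
            continue
        rep_bps = _internal_bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    if skipped > 0.2 * n_replicates:
        raise SaturationError(f"{skipped}/{n_replicates} bootstrap replicates saturated")
    used = n_replicates - skipped
    point.encode_bipartitions()
    for node in point.preorder_internal_node_iter():
        edge = node.edge
        if edge.bipartition is None:
            continue
        mask = edge.bipartition.split_bitmask
        if mask in counts:
            node.label = str(round(100.0 * counts[mask] / used))
    return point


def root_by_outgroup(tree: dendropy.Tree, outgroup: Sequence[str]) -> dendropy.Tree:
    """Root at the midpoint of the branch separating ``outgroup`` from the rest.

    The outgroup tips must form one side of a bipartition of the unrooted
    tree; otherwise an error names the offending split.
    """
    tree = tree.clone(depth=1)
    taxa = {t.label for t in tree.taxon_namespace}
    og = set(outgroup)
    if not og <= taxa:
        raise ValueError(f"outgroup tips not in tree: {sorted(og - taxa)}")
    if len(og) == len(taxa):
        raise ValueError("outgroup cannot be the whole taxon set")
    tree.encode_bipartitions()
    og_mask = 0
    for t in tree.taxon_namespace:
        if t.label in og:
            og_mask |= tree.taxon_namespace.taxon_bitmask(t)
    all_mask = tree.taxon_namespace.all_taxa_bitmask()
    edge = None
    for e in tree.preorder_edge_iter():
        if e.bipartition is None:
            continue
        leafset = e.bipartition.leafset_bitmask
        if leafset == og_mask or leafset == (all_mask ^ og_mask):
            if e.head_node is not tree.seed_node:
                edge = e
                break
    if edge is None:
        raise ValueError(
            f"outgroup {sorted(og)} is not monophyletic in the unrooted tree"
        )
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half)
    tree.is_rooted = True
    return tree


def _root_to_tip(tree: dendropy.Tree) -> dict[str, float]:
    out = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        nd = leaf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        out[leaf.taxon.label] = d
    return out


def patristic_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            if t1.label < t2.label:
                d = pdm.patristic_distance(t1, t2)
                out[(t1.label, t2.label)] = d
                out[(t2.label, t1.label)] = d
    return out


@dataclass
class ClockFit:
    """Per-clade strict-clock rates and root-age estimates."""

    rates: dict[str, float] = field(default_factory=dict)  # subs/site/Mya
    root_ages: dict[str, float] = field(default_factory=dict)  # Mya
    interval: tuple[float, float] = (0.0, 0.0)  # [min, max] over clades


def fit_clock(
    tree: dendropy.Tree,
    calibrations: Mapping[tuple[str, str], float],
    clades: Mapping[str, Sequence[str]],
) -> ClockFit:
    """Date the root of a rooted tree by per-clade molecular clocks.

    Each clade's rate is the mean over calibrated tip pairs inside the clade
    of patristic(i, j) / (2 t_ij); its root-age estimate is the mean
    root-to-tip distance of the clade's tips divided by that rate.  The
    reported interval is [min, max] over the clade estimates.
    """
    if not tree.is_rooted:
        raise ValueError("fit_clock requires a rooted tree")
    pat = patristic_distances(tree)
    rtt = _root_to_tip(tree)
    fit = ClockFit()
    for name, tips in clades.items():
        tipset = set(tips)
        missing = tipset - set(rtt)
        if missing:
            raise ValueError(f"clade {name!r} tips not in tree: {sorted(missing)}")
        pair_rates = []
        for (a, b), t in calibrations.items():
            if a in tipset and b in tipset:
                if t <= 0:
                    raise ValueError(f"nonpositive calibration time for ({a}, {b})")
                pair_rates.append(pat[(a, b)] / (2.0 * t))
        if not pair_rates:
            raise ValueError(f"clade {name!r} has no calibrated tip pair")
        rate = float(np.mean(pair_rates))
        if rate <= 0:
            raise ValueError(f"clade {name!r} has zero substitution rate")
        fit.rates[name] = rate
        fit.root_ages[name] = float(np.mean([rtt[t] for t in tipset])) / rate
    ages = sorted(fit.root_ages.values())
    fit.interval = (ages[0], ages[-1])
    return fit


def rate_profile(
    tree: dendropy.Tree,
    focal: str,
    calibrations: Mapping[str, float],
    distances: Mapping[str, float] | None = None,
) -> list[tuple[str, float, float, float]]:
    """Divergence-time vs distance-to-focal series with per-segment slopes.

    ``calibrations`` maps each non-focal tip to its divergence time from the
    focal taxon (Mya).  ``distances`` optionally supplies per-tip distances
    to the focal taxon (e.g. direct corrected pairwise distances from the
    alignment); when omitted, patristic distances from the tree are used.
    Returns rows (tip, time_mya, distance, segment_slope) sorted by time;
    the first segment's slope is measured from the origin (0, 0).
    """
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    if focal not in tips:
        raise ValueError(f"focal tip {focal!r} not in tree")
    others = [t for t in tips if t != focal]
    missing = [t for t in others if t not in calibrations]
    if missing:
        raise ValueError(f"missing calibration to focal for tips: {sorted(missing)}")
    if distances is None:
        pat = patristic_distances(tree)
        distances = {t: pat[(focal, t)] for t in others}
    series = sorted(((calibrations[t], t) for t in others))
    rows = []
    prev_t, prev_d = 0.0, 0.0
    for t_mya, tip in series:
        d = distances[tip]
        dt = t_mya - prev_t
        slope = (d - prev_d) / dt if dt > 0 else math.nan
        rows.append((tip, t_mya, d, slope))
        prev_t, prev_d = t_mya, d
    return rows
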