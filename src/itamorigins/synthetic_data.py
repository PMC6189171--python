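"""Ground-truth generators for every pipeline input class.

Each generator is a pure function of (parameters, seed): repeated calls are
byte-identical, and each returns a :class:`TruthRecord` alongside its data
so downstream expectations can be computed without rerunning the generator.

The generators emulate the study's input classes:

* proteomes with planted two-half-site motifs among rejection-sampled
  motif-free decoys (the proteome screen's sensitivity/specificity oracle);
* log-normal RNA-seq-style abundance tables with a tunable cross-dataset
  rank concordance (a Gaussian copula over a shared latent rank);
* protein alignments evolved along a time-calibrated tree under a 20-state
  symmetric substitution model with optional gamma rate variation across
  sites (closed-form expected p-distance, so clock recovery is checkable);
* membrane-ring time-lapse stacks with a contact arc enriched by a known
  fold after a known onset frame, Gaussian PSF and Poisson shot noise;
* Hertz force–indentation curves with multiplicative noise and an optional
  planted contact-point offset;
* stiffness/phagocytosis-efficiency group tables with a monotone link.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage

from .mechanics_stats import ForceCurve, HertzParams, hertz_force
from .motif_screen import AMINO_ACIDS, MotifPattern, scan_sequence


@dataclass
class TruthRecord:
    """Provenance + planted parameters of one generator call."""

    generator: str
    seed: int
    parameters: dict = field(default_factory=dict)
    manifest: list = field(default_factory=list)

    def to_json(self, **kwargs) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON-serializable: {type(o)}")

        return json.dumps(
            {
                "generator": self.generator,
                "seed": self.seed,
                "parameters": self.parameters,
                "manifest": self.manifest,
            },
            default=default,
            sort_keys=True,
            **kwargs,
        )


# ---------------------------------------------------------------------------
# proteomes with planted motifs


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def gen_proteome(
    n_decoys: int = 500,
    n_planted: int = 50,
    length: int = 300,
    pattern: MotifPattern | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], TruthRecord]:
    """Proteome of motif-free decoys plus proteins with exactly one plant.

    Decoys are uniform random sequences rejection-sampled until they contain
    no probe match.  Each planted protein carries exactly one match, at a
    position and spacer drawn uniformly (rejection-sampled so no incidental
    second match appears).  The truth record stores per-protein (start,
    spacer) for every plant.
    """
    pattern = pattern or MotifPattern()
    if length < pattern.max_length:
        raise ValueError(
            f"length {length} too short to plant a match (needs >= {pattern.max_length})"
        )
    rng = np.random.default_rng(seed)
    proteome: dict[str, str] = {}
    plants: dict[str, dict] = {}

    for i in range(n_decoys):
        while True:
            seq = _random_protein(rng, length)
            if not scan_sequence(seq, pattern):
                break
        proteome[f"DECOY_{i:04d}"] = seq

    tails1 = sorted(pattern.tail1)
    tails2 = sorted(pattern.tail2)
    for i in range(n_planted):
        while True:
            seq = list(_random_protein(rng, length))
            s = int(rng.integers(pattern.spacer_min, pattern.spacer_max + 1))
            start0 = int(rng.integers(0, length - (8 + s) + 1))  # 0-based
            seq[start0] = pattern.anchor1
            seq[start0 + 3] = tails1[rng.integers(len(tails1))]
            seq[start0 + 4 + s] = pattern.anchor2
            seq[start0 + 7 + s] = tails2[rng.integers(len(tails2))]
            planted = "".join(seq)
            hits = scan_sequence(planted, pattern)
            if len(hits) == 1 and hits[0].start == start0 + 1 and hits[0].spacer == s:
                break
        pid = f"PLANT_{i:04d}"
        proteome[pid] = planted
        plants[pid] = {"start": start0 + 1, "spacer": s}

    truth = TruthRecord(
        generator="gen_proteome",
        seed=seed,
        parameters={
            "n_decoys": n_decoys,
            "n_planted": n_planted,
            "length": length,
            "pattern": pattern.to_string(),
            "plants": plants,
        },
    )
    return proteome, truth


# ---------------------------------------------------------------------------
# expression tables


def gen_expression(
    genes: Sequence[str],
    n_datasets: int = 3,
    mu: float = 3.0,
    sigma: float = 1.5,
    concordance: float = 0.9,
    seed: int = 0,
) -> tuple[list[pd.Series], TruthRecord]:
    """Log-normal abundance tables with tunable cross-dataset concordance.

    A shared latent standard-normal score per gene is mixed with per-dataset
    noise (Gaussian copula): dataset score = c*z + sqrt(1-c^2)*eps with
    c = ``concordance``.  c = 1 gives identical rank orders, c = 0 gives
    independent ones.  Abundances are exp(mu + sigma * score), so they are
    nonnegative and heavy-tailed like RNA-seq expression values.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not (0.0 <= concordance <= 1.0):
        raise ValueError("concordance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    z = rng.standard_normal(len(genes))
    tables = []
    for _ in range(n_datasets):
        eps = rng.standard_normal(len(genes))
        score = concordance * z + math.sqrt(1.0 - concordance**2) * eps
        tables.append(pd.Series(np.exp(mu + sigma * score), index=genes))
    truth = TruthRecord(
        generator="gen_expression",
        seed=seed,
        parameters={
            "genes": genes,
            "n_datasets": n_datasets,
            "mu": mu,
            "sigma": sigma,
            "concordance": concordance,
            "latent_rank_order": [genes[i] for i in np.argsort(-z)],
        },
    )
    return tables, truth


# ---------------------------------------------------------------------------
# sequence evolution on time trees


def gen_two_clade_tree(
    n_tips_per_clade: int = 4,
    root_age: float = 800.0,
    clade_age_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[dendropy.Tree, TruthRecord]:
    """Ultrametric two-clade time tree (edge lengths in Mya) with known ages.

    Two sister clades ("A", "B") coalesce at ``root_age``; each clade's own
    root sits at ``clade_age_fraction`` x root_age, with the remaining
    within-clade node ages drawn uniformly and nested consistently.  The
    truth record stores every tip pair's divergence time, which downstream
    clock fitting uses as its calibration table.
    """
    if n_tips_per_clade < 2:
        raise ValueError("need >= 2 tips per clade")
    rng = np.random.default_rng(seed)
    labels = [f"A{i+1}" for i in range(n_tips_per_clade)] + [
        f"B{i+1}" for i in range(n_tips_per_clade)
    ]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    clade_age = clade_age_fraction * root_age

    def build_clade(prefix: str) -> dendropy.Node:
        # sequential random coalescent: ages sorted ascending then joined
        tips = [dendropy.Node(taxon=tns.get_taxon(f"{prefix}{i+1}")) for i in range(n_tips_per_clade)]
        for t in tips:
            t.age_mya = 0.0
        nodes = list(tips)
        inner_ages = np.sort(rng.uniform(0.05, 0.95, size=n_tips_per_clade - 2)) * clade_age if n_tips_per_clade > 2 else np.array([])
        ages = list(inner_ages) + [clade_age]
        for age in ages:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            parent = dendropy.Node()
            parent.age_mya = float(age)
            a, b = nodes[i], nodes[j]
            parent.add_child(a)
            parent.add_child(b)
            a.edge.length = parent.age_mya - a.age_mya
            b.edge.length = parent.age_mya - b.age_mya
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
        return nodes[0]

    root = tree.seed_node
    root.age_mya = root_age
    for prefix in ("A", "B"):
        clade_root = build_clade(prefix)
        root.add_child(clade_root)
        clade_root.edge.length = root_age - clade_root.age_mya
    tree.is_rooted = True

    # true divergence time of every tip pair = age of their MRCA
    pair_times: dict[str, float] = {}
    pdm_leaves = list(tree.leaf_node_iter())
    for i, la in enumerate(pdm_leaves):
        for lb in pdm_leaves[i + 1 :]:
            mrca = tree.mrca(taxa=[la.taxon, lb.taxon])
            key = "|".join(sorted([la.taxon.label, lb.taxon.label]))
            pair_times[key] = float(mrca.age_mya)

    truth = TruthRecord(
        generator="gen_two_clade_tree",
        seed=seed,
        parameters={
            "n_tips_per_clade": n_tips_per_clade,
            "root_age_mya": root_age,
            "clade_age_mya": clade_age,
            "pair_divergence_mya": pair_times,
            "clades": {
                "A": [f"A{i+1}" for i in range(n_tips_per_clade)],
                "B": [f"B{i+1}" for i in range(n_tips_per_clade)],
            },
        },
    )
    return tree, truth


def expected_p_distance(rate: float, time_mya: float) -> float:
    """Expected p-distance between two tips diverged for ``time_mya``.

    Under the 20-state symmetric model at rate r subs/site/Mya the
    divergence along the two-lineage path of length 2rt saturates at 19/20:
    E[p] = (19/20) (1 - exp(-(20/19) * 2 r t)).
    """
    return (19.0 / 20.0) * (1.0 - math.exp(-(20.0 / 19.0) * 2.0 * rate * time_mya))


def evolve_alignment(
    tree: dendropy.Tree,
    rate: float,
    n_sites: int = 2000,
    gamma_alpha: float | None = None,
    seed: int = 0,
):
    """Evolve a protein alignment along a time tree (edge lengths in Mya).

    The root sequence is uniform over the 20 residues.  On each branch every
    site accrues Poisson(rate x branch_time x site_factor) substitution
    events, each replacing the residue with one of the other 19 uniformly.
    Site factors are iid gamma(alpha) with mean one when ``gamma_alpha`` is
    given, else one.  Returns (ProteinAlignment, TruthRecord).
    """
    from .phylo_clock import ProteinAlignment

    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    if gamma_alpha is not None:
        if gamma_alpha <= 0:
            raise ValueError("gamma shape must be positive")
        site_factor = rng.gamma(gamma_alpha, 1.0 / gamma_alpha, size=n_sites)
    else:
        site_factor = np.ones(n_sites)

    root_seq = rng.integers(0, 20, size=n_sites)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        parent_seq = seqs[id(node.parent_node)]
        child = parent_seq.copy()
        n_events = rng.poisson(rate * t * site_factor)
        for site in np.flatnonzero(n_events):
            for _ in range(n_events[site]):
                child[site] = (child[site] + 1 + rng.integers(0, 19)) % 20
        seqs[id(node)] = child

    taxa, rows = [], {}
    for leaf in tree.leaf_node_iter():
        lab = leaf.taxon.label
        taxa.append(lab)
        rows[lab] = "".join(aa[seqs[id(leaf)]])
    truth = TruthRecord(
        generator="evolve_alignment",
        seed=seed,
        parameters={
            "rate_subs_per_site_per_mya": rate,
            "n_sites": n_sites,
            "gamma_alpha": gamma_alpha,
            "taxa": taxa,
        },
    )
    return ProteinAlignment(taxa=taxa, rows=rows), truth


# ---------------------------------------------------------------------------
# membrane-ring image stacks


def gen_cell_stack(
    shape: tuple[int, int] = (96, 96),
    ring_radius: float = 30.0,
    ring_thickness: float = 6.0,
    contact_halfwidth_deg: float = 35.0,
    enrichment: float = 3.0,
    onset_frame: int = 10,
    n_frames: int = 50,
    base_intensity: float = 100.0,
    psf_sigma: float = 0.0,
    poisson_noise: bool = False,
    frame_interval_s: float = 6.0,
    seed: int = 0,
):
    """Membrane ring with a contact arc enriched ``enrichment``-fold.

    The noiseless intensity is ``base_intensity`` on an annulus and
    ``enrichment`` x base on the contact arc from ``onset_frame`` onward,
    optionally blurred with a Gaussian PSF and Poisson-sampled.  Returns
    (stack T x H x W, masks dict, TruthRecord); masks contain boolean
    ``contact``, ``reference`` and ``background`` ground-truth regions.
    """
    if enrichment < 1.0:
        raise ValueError("enrichment fold must be >= 1")
    if ring_thickness <= 0:
        raise ValueError("degenerate ring: thickness must be positive")
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(yy - cy, xx - cx)
    theta = np.degrees(np.arctan2(yy - cy, xx - cx))
    ring = np.abs(rr - ring_radius) <= ring_thickness / 2.0
    arc = ring & (np.abs(theta) <= contact_halfwidth_deg)
    if not arc.any():
        raise ValueError("contact arc is empty; widen it or thicken the ring")
    # keep an angular guard band between contact and reference regions
    guard = ring & (np.abs(theta) <= contact_halfwidth_deg + 15.0)
    reference = ring & ~guard
    background = rr > ring_radius + 4.0 * ring_thickness

    rng = np.random.default_rng(seed)
    stack = np.empty((n_frames, h, w))
    for t in range(n_frames):
        frame = np.zeros((h, w))
        frame[ring] = base_intensity
        if t >= onset_frame:
            frame[arc] = enrichment * base_intensity
        if psf_sigma > 0:
            frame = ndimage.gaussian_filter(frame, psf_sigma)
        if poisson_noise:
            frame = rng.poisson(frame).astype(float)
        stack[t] = frame

    masks = {"contact": arc, "reference": reference, "background": background}
    truth = TruthRecord(
        generator="gen_cell_stack",
        seed=seed,
        parameters={
            "shape": list(shape),
            "ring_radius": ring_radius,
            "ring_thickness": ring_thickness,
            "contact_halfwidth_deg": contact_halfwidth_deg,
            "enrichment": enrichment,
            "onset_frame": onset_frame,
            "n_frames": n_frames,
            "base_intensity": base_intensity,
            "psf_sigma": psf_sigma,
            "poisson_noise": poisson_noise,
            "frame_interval_s": frame_interval_s,
        },
    )
    return stack, masks, truth


# ---------------------------------------------------------------------------
# force curves and stiffness/uptake tables


def gen_force_curves(
    E: float = 3e9,
    R: float = 1.5e-6,
    nu: float = 0.33,
    delta_max: float = 10e-9,
    n_samples: int = 100,
    noise_frac: float = 0.0,
    delta0: float = 0.0,
    n_curves: int = 20,
    seed: int = 0,
):
    """Hertz force curves with multiplicative Gaussian noise.

    Indentation runs on a uniform grid up to ``delta_max`` (m); forces are
    hertz_force(max(delta - delta0, 0)) x (1 + noise_frac * eps).  An
    optional planted contact offset ``delta0`` shifts the contact point.
    """
    if E <= 0 or R <= 0:
        raise ValueError("E and R must be positive")
    rng = np.random.default_rng(seed)
    params = HertzParams(E=E, nu=nu, R=R)
    delta = np.linspace(0.0, delta_max, n_samples)
    clean = hertz_force(np.clip(delta - delta0, 0.0, None), params)
    curves = []
    for _ in range(n_curves):
        noise = 1.0 + noise_frac * rng.standard_normal(n_samples) if noise_frac > 0 else 1.0
        curves.append(ForceCurve(delta=delta, force=clean * noise, R=R, nu=nu))
    truth = TruthRecord(
        generator="gen_force_curves",
        seed=seed,
        parameters={
            "E_pa": E,
            "R_m": R,
            "nu": nu,
            "delta_max_m": delta_max,
            "n_samples": n_samples,
            "noise_frac": noise_frac,
            "delta0_m": delta0,
            "n_curves": n_curves,
        },
    )
    return curves, truth


def gen_stiffness_phago(
    n_groups: int = 5,
    stiffness_gpa: Sequence[float] | None = None,
    link: Callable[[np.ndarray], np.ndarray] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Stiffness/phagocytosis-efficiency group table with a monotone link.

    Stiffness values are strictly increasing across groups (default: evenly
    spaced on a log scale over roughly the soft-to-stiff polystyrene range);
    efficiency = link(stiffness) + Gaussian noise.  With zero noise and an
    increasing link the table is perfectly concordant.
    """
    if n_groups < 3:
        raise ValueError("need >= 3 groups for a rank correlation")
    rng = np.random.default_rng(seed)
    if stiffness_gpa is None:
        stiffness = np.logspace(-1, 0.5, n_groups)  # ~0.1 to ~3.2 GPa
    else:
        stiffness = np.asarray(stiffness_gpa, dtype=float)
        if not (np.diff(stiffness) > 0).all():
            raise ValueError("stiffness values must be strictly increasing")
    if link is None:
        link = lambda s: 20.0 + 60.0 * (np.log10(s) - np.log10(stiffness[0])) / (
            np.log10(stiffness[-1]) - np.log10(stiffness[0])
        )
    efficiency = link(stiffness) + noise_sd * rng.standard_normal(len(stiffness))
    table = pd.DataFrame(
        {
            "group": [f"G{i+1}" for i in range(len(stiffness))],
            "stiffness_gpa": stiffness,
            "phago_efficiency": efficiency,
        }
    )
    truth = TruthRecord(
        generator="gen_stiffness_phago",
        seed=seed,
        parameters={
            "n_groups": len(stiffness),
            "stiffness_gpa": list(stiffness),
            "noise_sd": noise_sd,
        },
    )
    return table, truth


def gen_phago_counts(
    n_cells: int = 50,
    mean_internalized: float = 1.5,
    mean_surface: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Per-cell internalized/surface-bound bead counts (Poisson)."""
    if n_cells < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed)
    internal = rng.poisson(mean_internalized, size=n_cells)
    surface = rng.poisson(mean_surface, size=n_cells)
    table = pd.DataFrame(
        {"cell": np.arange(n_cells), "internalized": internal, "surface_bound": surface}
    )
    truth = TruthRecord(
        generator="gen_phago_counts",
        seed=seed,
        parameters={
            "n_cells": n_cells,
            "mean_internalized": mean_internalized,
            "mean_surface": mean_surface,
            "true_fraction_positive": float((internal >= 1).mean()),
            "true_mean_internalized": float(internal.mean()),
        },
    )
    return table, truth
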