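"""Concrete pipeline stages wired over the library modules.

Each ``stage_*`` function takes (params, seed, out_dir), reads its inputs
either from explicit paths in ``params`` or from the artifacts earlier
stages left in ``out_dir``, writes its outputs there and returns the list
of files written.  Stages are deliberately thin: all computation lives in
the library modules.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging_quant, ioutils, mechanics_stats, motif_screen, phylo_clock, synthetic_data


def stage_simulate(params: dict, seed: int, out_dir: Path) -> list[Path]:
    written = []
    proteome, truth_p = synthetic_data.gen_proteome(
        n_decoys=params.get("n_decoys", 500),
        n_planted=params.get("n_planted", 50),
        length=params.get("length", 300),
        seed=seed,
    )
    fasta = out_dir / "proteome.fasta"
    ioutils.write_fasta(proteome, fasta)
    written.append(fasta)

    genes = [pid.split("|")[-1] for pid in proteome]
    tables, truth_e = synthetic_data.gen_expression(
        genes,
        n_datasets=params.get("n_datasets", 3),
        concordance=params.get("concordance", 0.9),
        seed=seed + 1,
    )
    for k, tab in enumerate(tables):
        p = out_dir / f"expression_{k}.tsv"
        ioutils.write_table(
            pd.DataFrame({"gene": tab.index, "abundance": tab.values}), p
        )
        written.append(p)

    tree, truth_t = synthetic_data.gen_two_clade_tree(
        n_tips_per_clade=params.get("n_tips_per_clade", 4),
        root_age=params.get("root_age_mya", 800.0),
        seed=seed + 2,
    )
    aln, truth_a = synthetic_data.evolve_alignment(
        tree,
        rate=params.get("rate", 5e-4),
        n_sites=params.get("n_sites", 2000),
        seed=seed + 3,
    )
    aln_path = out_dir / "alignment.fasta"
    ioutils.write_fasta({t: aln.rows[t] for t in aln.taxa}, aln_path)
    written.append(aln_path)
    calib_rows = []
    for key, t in truth_t.parameters["pair_divergence_mya"].items():
        a, b = key.split("|")
        calib_rows.append({"taxonA": a, "taxonB": b, "time_mya": t})
    calib_path = out_dir / "calibrations.tsv"
    ioutils.write_table(pd.DataFrame(calib_rows), calib_path)
    written.append(calib_path)
    clades_path = out_dir / "clades.json"
    clades_path.write_text(json.dumps(truth_t.parameters["clades"], sort_keys=True))
    written.append(clades_path)

    stack, masks, truth_s = synthetic_data.gen_cell_stack(
        enrichment=params.get("enrichment", 3.0),
        poisson_noise=params.get("poisson_noise", True),
        seed=seed + 4,
    )
    stack_path = out_dir / "stack.tif"
    ioutils.write_stack(stack, stack_path)
    written.append(stack_path)
    for role, mask in masks.items():
        p = out_dir / f"mask_{role}.tsv"
        ioutils.write_mask_rle(mask, p)
        written.append(p)

    curves, truth_f = synthetic_data.gen_force_curves(
        E=params.get("E_pa", 3e9),
        noise_frac=params.get("noise_frac", 0.01),
        n_curves=params.get("n_curves", 20),
        seed=seed + 5,
    )
    for k, curve in enumerate(curves):
        p = out_dir / f"force_curve_{k:02d}.tsv"
        ioutils.write_table(
            pd.DataFrame(
                {"delta_nm": curve.delta * 1e9, "force_nN": curve.force * 1e9}
            ),
            p,
        )
        written.append(p)
    meta = out_dir / "force_meta.json"
    meta.write_text(json.dumps({"R_nm": curves[0].R * 1e9, "nu": curves[0].nu}))
    written.append(meta)

    pairs, truth_sp = synthetic_data.gen_stiffness_phago(seed=seed + 6)
    pairs_path = out_dir / "stiffness_phago.tsv"
    ioutils.write_table(pairs, pairs_path)
    written.append(pairs_path)

    truth_path = out_dir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                t.generator: json.loads(t.to_json())
                for t in (truth_p, truth_e, truth_t, truth_a, truth_s, truth_f, truth_sp)
            },
            sort_keys=True,
            indent=1,
        )
    )
    written.append(truth_path)
    return written


def stage_scan(params: dict, seed: int, out_dir: Path) -> list[Path]:
    pattern = motif_screen.MotifPattern.from_string(
        params.get("pattern", "Y-X-X-[LI]-X(6,12)-Y-X-X-[LI]")
    )
    fasta = Path(params.get("proteome", out_dir / "proteome.fasta"))
    proteome = ioutils.read_fasta(fasta)
    hits = motif_screen.scan_proteome(proteome, pattern)
    out = out_dir / "hits.tsv"
    ioutils.write_table(hits, out)
    return [out]


def stage_rank(params: dict, seed: int, out_dir: Path) -> list[Path]:
    hits = ioutils.read_table(out_dir / "hits.tsv")
    expr_paths = params.get("expression") or sorted(out_dir.glob("expression_*.tsv"))
    tables = []
    for p in expr_paths:
        tab = ioutils.read_table(p)
        tables.append(pd.Series(tab["abundance"].values, index=tab["gene"]))
    ranked = motif_screen.rank_candidates(hits, tables, top_n=params.get("top_n", 25))
    out = out_dir / "ranked.tsv"
    ioutils.write_table(ranked, out)
    return [out]


def stage_exclude(params: dict, seed: int, out_dir: Path) -> list[Path]:
    ranked = ioutils.read_table(out_dir / "ranked.tsv")
    top = ranked.loc[ranked["is_top"]].reset_index(drop=True)
    if "annotations" in params:
        ann = ioutils.read_table(params["annotations"]).set_index("gene")
    else:
        ann = pd.DataFrame(index=pd.Index([], name="gene"))
    flagged = motif_screen.apply_exclusions(top, ann)
    short = motif_screen.shortlist(flagged)
    out1, out2 = out_dir / "candidates.tsv", out_dir / "shortlist.tsv"
    ioutils.write_table(flagged, out1)
    ioutils.write_table(short, out2)
    return [out1, out2]


def _read_alignment(params: dict, out_dir: Path) -> phylo_clock.ProteinAlignment:
    path = Path(params.get("alignment", out_dir / "alignment.fasta"))
    return phylo_clock.ProteinAlignment.from_fasta(path)


def _distance_spec(params: dict) -> phylo_clock.DistanceSpec:
    return phylo_clock.DistanceSpec(
        model=params.get("model", "poisson"), alpha=params.get("alpha", 1.0)
    )


def stage_tree(params: dict, seed: int, out_dir: Path) -> list[Path]:
    aln = _read_alignment(params, out_dir)
    spec = _distance_spec(params)
    tree = phylo_clock.bootstrap_support(
        aln, spec, n_replicates=params.get("bootstrap", 100), seed=seed
    )
    out = out_dir / "tree.nwk"
    ioutils.write_newick(tree, out)
    return [out]


def _clades(params: dict, out_dir: Path) -> dict:
    path = Path(params.get("clades", out_dir / "clades.json"))
    return json.loads(path.read_text())


def stage_clock(params: dict, seed: int, out_dir: Path) -> list[Path]:
    tree = ioutils.read_newick(out_dir / "tree.nwk")
    calib = ioutils.read_calibrations(
        Path(params.get("calibrations", out_dir / "calibrations.tsv"))
    )
    clades = _clades(params, out_dir)
    outgroup = params.get("outgroup") or clades[sorted(clades)[-1]]
    rooted = phylo_clock.root_by_outgroup(tree, outgroup)
    fit = phylo_clock.fit_clock(rooted, calib, clades)
    out = out_dir / "clock.json"
    out.write_text(
        json.dumps(
            {
                "rates_subs_per_site_per_mya": fit.rates,
                "root_ages_mya": fit.root_ages,
                "interval_mya": list(fit.interval),
            },
            sort_keys=True,
            indent=1,
        )
    )
    rooted_path = out_dir / "tree.rooted.nwk"
    ioutils.write_newick(rooted, rooted_path)
    return [out, rooted_path]


def stage_rates(params: dict, seed: int, out_dir: Path) -> list[Path]:
    tree = ioutils.read_newick(out_dir / "tree.rooted.nwk")
    calib = ioutils.read_calibrations(
        Path(params.get("calibrations", out_dir / "calibrations.tsv"))
    )
    focal = params.get("focal") or sorted(
        l.taxon.label for l in tree.leaf_node_iter()
    )[0]
    times = {b: t for (a, b), t in calib.items() if a == focal}
    rows = phylo_clock.rate_profile(tree, focal, times)
    out = out_dir / "rate_profile.tsv"
    ioutils.write_table(
        pd.DataFrame(rows, columns=["tip", "time_mya", "distance", "segment_slope"]), out
    )
    return [out]


def stage_quantify(params: dict, seed: int, out_dir: Path) -> list[Path]:
    stack = ioutils.read_stack(Path(params.get("stack", out_dir / "stack.tif")))
    masks = {
        role: ioutils.read_mask_rle(out_dir / f"mask_{role}.tsv")
        for role in ("contact", "reference", "background")
    }
    nf = imaging_quant.normalized_fluorescence(
        stack, masks["contact"], masks["reference"],
        masks["background"] if params.get("subtract_background", False) else None,
    )
    out = out_dir / "normalized_fluorescence.tsv"
    ioutils.write_table(pd.DataFrame({"frame": np.arange(len(nf)), "nf": nf}), out)
    written = [out]
    if "line" in params:
        x0, y0, x1, y1, width = params["line"]
        kymo = imaging_quant.kymograph(
            stack, imaging_quant.ProfileLine(x0, y0, x1, y1, int(width))
        )
        kymo_path = out_dir / "kymograph.tsv"
        ioutils.write_table(pd.DataFrame(kymo), kymo_path)
        written.append(kymo_path)
    return written


def stage_hertz(params: dict, seed: int, out_dir: Path) -> list[Path]:
    meta = json.loads((out_dir / "force_meta.json").read_text())
    rows = []
    for p in sorted(out_dir.glob("force_curve_*.tsv")):
        tab = ioutils.read_table(p)
        curve = mechanics_stats.ForceCurve.from_nm_nN(
            tab["delta_nm"], tab["force_nN"], R_nm=meta["R_nm"], nu=meta["nu"]
        )
        fit = mechanics_stats.fit_hertz(curve)
        rows.append(
            {
                "curve": p.name,
                "E_gpa": fit.params.E / 1e9,
                "delta0_nm": fit.params.delta0 * 1e9,
                "residual_rms_nN": fit.residual_rms * 1e9,
            }
        )
    out = out_dir / "hertz_fits.tsv"
    ioutils.write_table(pd.DataFrame(rows), out)
    return [out]


def stage_spearman(params: dict, seed: int, out_dir: Path) -> list[Path]:
    tab = ioutils.read_table(
        Path(params.get("table", out_dir / "stiffness_phago.tsv"))
    )
    res = mechanics_stats.spearman_exact(
        tab["stiffness_gpa"].values, tab["phago_efficiency"].values
    )
    out = out_dir / "spearman.json"
    out.write_text(
        json.dumps(
            {
                "r": res.r,
                "p_one_sided": res.p_one_sided,
                "p_two_sided": res.p_two_sided,
                "n": res.n,
                "exact": res.exact,
            },
            sort_keys=True,
            indent=1,
        )
    )
    return [out]
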