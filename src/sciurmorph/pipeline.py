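"""End-to-end analysis: superimposition through classification and lever arms.

Stages run in the study's order: GPA -> taxon means -> allometry (and
size-corrected residuals) -> PCA on the residual covariance -> ancestral
shapes and tree projection -> phylogenetic-signal tests (whole tree and
per-clade) -> SCI/SRI homoplasy indices for small clades -> CVA per
grouping with leave-one-out cross-validation and classification of
ungrouped specimens -> between-group distance tests -> mechanical-advantage
tables for taxon means, dietary group means, and shapes reconstructed at
chosen ordination scores and centroid sizes.

The report is a plain nested dict (JSON-serializable), a pure function of
(bundle, config): every seed and permutation count is explicit in the
echoed provenance block, together with SHA-256 hashes of the inputs.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .allometry import fit_allometry, residual_shapes, test_common_allometry
from .biomechanics import MuscleMap, advantage_table
from .cva import classify_specimens, fit_cva, group_distance_tests
from .datatypes import vector_to_shape
from .io import read_groups, read_tps, read_tree
from .ordination import fit_pca, map_tree_to_ordination, shape_at_score
from .phylo import homoplasy_indices, permutation_signal_test, reconstruct_ancestral_shapes
from .superimposition import gpa_align, taxon_mean_shapes

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "predictor": "cs",
    "n_perm_allometry": 999,
    "n_perm_ancova": 199,
    "n_perm_signal": 999,
    "n_perm_distance": 499,
    "max_taxa_exhaustive": 8,
    "clades": {},  # name -> list of taxa
    "muscle_map": MuscleMap(),
    "pc_scores": [-0.2, 0.15],
    "cv_scores": [-6.0, 6.0],
    "cs_values": [100.0, 800.0],
}


def default_clades(tree) -> dict[str, list[str]]:
    """Two disjoint clades off a tree: a small one (5-8 tips, within reach
    of the exact Steiner search) and a larger one for per-clade signal
    tests. Falls back to slicing the sorted tip list on shallow trees."""
    clades: list[list[str]] = []
    for node in tree.dtree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clades.append([l.taxon.label for l in node.leaf_iter()])
    small = next((c for c in clades if 5 <= len(c) <= 8), None)
    if small is None:
        small = sorted(tree.tip_labels)[:7]
    rest = [t for t in sorted(tree.tip_labels) if t not in small]
    large = next(
        (c for c in clades if len(c) >= 10 and not set(c) & set(small)), None
    )
    if large is None:
        large = rest[: max(10, len(rest) // 2)]
    return {"clade_small": sorted(small), "clade_large": sorted(large)}


def parse_config(path) -> dict:
    """Parse a flat key = value config file (INI sections) into a config dict."""
    cp = configparser.ConfigParser()
    cp.read(path)
    cfg = dict(DEFAULT_CONFIG)
    if cp.has_section("analysis"):
        a = cp["analysis"]
        for key in ("seed", "n_perm_allometry", "n_perm_ancova", "n_perm_signal",
                    "n_perm_distance", "max_taxa_exhaustive"):
            if key in a:
                cfg[key] = a.getint(key)
        if "predictor" in a:
            cfg["predictor"] = a["predictor"]
        for key in ("pc_scores", "cv_scores", "cs_values"):
            if key in a:
                cfg[key] = [float(v) for v in a[key].split(",")]
    if cp.has_section("clades"):
        cfg["clades"] = {
            name: [t.strip() for t in taxa.split(",")]
            for name, taxa in cp["clades"].items()
        }
    if cp.has_section("muscle_map"):
        mm = cp["muscle_map"]
        insertions = dict(MuscleMap().insertions)
        for name in insertions:
            if name.lower() in mm:
                insertions[name] = mm.getint(name.lower())
        condyle = MuscleMap().condyle_pair
        if "condyle_pair" in mm:
            condyle = tuple(int(v) for v in mm["condyle_pair"].split(","))
        incisor = mm.getint("incisor", MuscleMap().incisor)
        cfg["muscle_map"] = MuscleMap(
            condyle_pair=condyle, incisor=incisor, insertions=insertions
        )
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _round_floats(obj, nd=12):
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), nd)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def run_full_analysis(
    bundle, config: Optional[dict] = None, out_dir=None
) -> dict:
    """Run the whole analysis on a fixture bundle directory.

    The bundle must contain ``landmarks.tps``, ``tree.nwk`` (or ``tree.nex``)
    and optionally ``groups.tsv``. Returns the report dict; when ``out_dir``
    is given, also writes ``report.json`` plus delimited tables and TPS
    shape exports. Any stage failure aborts with the stage name attached.
    """
    bundle = Path(bundle)
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    seed = int(cfg["seed"])
    report: dict = {}
    tables: dict[str, pd.DataFrame] = {}
    shapes_out: dict[str, np.ndarray] = {}

    stage = "io"
    try:
        dataset = read_tps(bundle / "landmarks.tps")
        groups_path = bundle / "groups.tsv"
        have_groups = groups_path.exists()
        if have_groups:
            dataset = read_groups(groups_path, dataset)
        else:
            # no specimen table: infer taxon from a replicate suffix in the
            # specimen id (taxon_spN), else treat each specimen as its taxon
            import re

            from .io import attach_taxa

            dataset = attach_taxa(
                dataset,
                {
                    s.specimen_id: re.sub(r"_sp\d+$", "", s.specimen_id)
                    for s in dataset.specimens
                },
            )
        tree_path = bundle / "tree.nwk"
        if not tree_path.exists():
            tree_path = bundle / "tree.nex"
        taxa = sorted({s.taxon for s in dataset.specimens if s.taxon})
        tree = read_tree(tree_path, taxa)
        report["inputs"] = {
            "n_specimens": dataset.n,
            "n_taxa": len(taxa),
            "k": dataset.k,
            "has_groups": have_groups,
        }

        stage = "gpa"
        aligned = gpa_align(dataset)
        means = taxon_mean_shapes(aligned)
        report["gpa"] = {
            "converged": aligned.gpa_converged,
            "consensus_centroid_size": float(
                np.sqrt(np.sum(np.asarray(aligned.consensus) ** 2))
            ),
        }
        shapes_out["consensus"] = np.asarray(aligned.consensus)

        stage = "allometry"
        model = fit_allometry(
            means,
            predictor=cfg["predictor"],
            n_perm=int(cfg["n_perm_allometry"]),
            seed=seed + 1,
        )
        report["allometry"] = {
            "predictor": model.predictor,
            "percent_predicted": model.percent_predicted,
            "goodall_F": model.goodall_F,
            "df": [1, model.n - 2],
            "p_permutation": model.p_permutation,
            "n_taxa": model.n,
        }
        if cfg["clades"]:
            grouping = {
                taxon: name for name, members in cfg["clades"].items()
                for taxon in members
            }
            try:
                hom = test_common_allometry(
                    means, grouping, predictor=cfg["predictor"],
                    n_perm=int(cfg["n_perm_ancova"]), seed=seed + 2,
                )
                report["allometry"]["homogeneity"] = {
                    "groups": hom.groups,
                    "excluded": hom.excluded,
                    "slope_F": hom.slope_F,
                    "slope_df": list(hom.slope_df),
                    "slope_p": hom.slope_p,
                    "slope_p_perm": hom.slope_p_perm,
                    "intercept_F": hom.intercept_F,
                    "intercept_df": list(hom.intercept_df),
                    "intercept_p": hom.intercept_p,
                    "intercept_p_perm": hom.intercept_p_perm,
                }
            except ValueError as exc:
                report["allometry"]["homogeneity"] = {"skipped": str(exc)}
        residuals = residual_shapes(model, means)

        stage = "pca"
        pca_raw = fit_pca(means, basis="raw")
        pca = fit_pca(residuals, basis="size_corrected")
        report["pca"] = {
            "raw_percent_variance": pca_raw.percent_variance[:6].tolist(),
            "size_corrected_percent_variance": pca.percent_variance[:6].tolist(),
            "n_axes": pca.n_axes,
        }
        tables["pca_scores"] = pd.DataFrame(
            pca.scores,
            index=pca.taxa,
            columns=[f"PC{i + 1}" for i in range(pca.n_axes)],
        )

        stage = "ancestral_shapes"
        tip_shapes = {
            taxon: residuals.tangent_coords[i]
            for i, taxon in enumerate(residuals.taxa)
        }
        ancestors = reconstruct_ancestral_shapes(tree, tip_shapes)
        node_scores, edge_list = map_tree_to_ordination(pca, tree, ancestors)
        report["ancestral_shapes"] = {
            "tree_length": ancestors.tree_length,
            "n_internal_nodes": ancestors.states.shape[0] - ancestors.n_tips,
        }
        tables["tree_projection"] = node_scores
        tables["tree_edges"] = pd.DataFrame(edge_list, columns=["from", "to"])
        for label, vec in ancestors.internal_shapes().items():
            shapes_out[label] = vector_to_shape(vec)

        stage = "phylogenetic_signal"
        sig = permutation_signal_test(
            tree, tip_shapes, n_perm=int(cfg["n_perm_signal"]), seed=seed + 3
        )
        report["phylogenetic_signal"] = {
            "full_tree": {
                "tree_length": sig.observed_length,
                "p_value": sig.p_value,
                "n_perm": sig.n_perm,
            }
        }
        for name, members in cfg["clades"].items():
            members = [t for t in members if t in tip_shapes]
            if len(members) < 4:
                report["phylogenetic_signal"][name] = {
                    "skipped": "fewer than 4 tips"
                }
                continue
            sub = tree.extract_clade(members)
            sub_shapes = {t: tip_shapes[t] for t in members}
            s = permutation_signal_test(
                sub, sub_shapes, n_perm=int(cfg["n_perm_signal"]), seed=seed + 4
            )
            entry = {
                "n_tips": len(members),
                "tree_length": s.observed_length,
                "p_value": s.p_value,
            }
            if len(members) <= int(cfg["max_taxa_exhaustive"]):
                hom_idx = homoplasy_indices(
                    sub, sub_shapes,
                    max_taxa_exhaustive=int(cfg["max_taxa_exhaustive"]),
                )
                entry["homoplasy"] = {
                    "min_length": hom_idx.min_length,
                    "max_length": hom_idx.max_length,
                    "SCI": hom_idx.sci,
                    "SRI": hom_idx.sri,
                    "exact": hom_idx.exact,
                }
            report["phylogenetic_signal"][name] = entry

        stage = "cva"
        report["cva"] = {}
        cva_models = {}
        for grouping in ("diet", "locomotion"):
            labels = (
                dataset.diets if grouping == "diet" else dataset.locomotions
            )
            if not have_groups or all(l == "ungrouped" for l in labels):
                report["cva"][grouping] = {"skipped": "no group labels in bundle"}
                continue
            cmodel = fit_cva(aligned, grouping)
            cva_models[grouping] = cmodel
            ctable = classify_specimens(
                cmodel, aligned, grouping, cross_validate=True
            )
            ungrouped_rows = ctable.table[
                ~ctable.table["true_group"].isin(cmodel.groups)
            ]
            report["cva"][grouping] = {
                "groups": cmodel.groups,
                "percent_variance": cmodel.percent_variance.tolist(),
                "percent_correct": ctable.percent_correct,
                "percent_correct_cv": ctable.percent_correct_cv,
                "ungrouped_assignments": {
                    row["specimen_id"]: {
                        "predicted": row["predicted"],
                        "posterior": float(row[f"p_{row['predicted']}"]),
                    }
                    for _, row in ungrouped_rows.iterrows()
                },
            }
            tables[f"cva_{grouping}_confusion"] = ctable.confusion
            if ctable.confusion_cv is not None:
                tables[f"cva_{grouping}_confusion_cv"] = ctable.confusion_cv
            tables[f"cva_{grouping}_posteriors"] = ctable.table

            dist, pvals = group_distance_tests(
                aligned, grouping,
                n_perm=int(cfg["n_perm_distance"]), seed=seed + 5,
            )
            tables[f"cva_{grouping}_distances"] = dist
            tables[f"cva_{grouping}_distance_p"] = pvals

        stage = "lever_arms"
        mm: MuscleMap = cfg["muscle_map"]
        taxon_shapes = {
            taxon: vector_to_shape(means.tangent_coords[i])
            for i, taxon in enumerate(means.taxa)
        }
        tables["lever_arms_taxa"] = advantage_table(taxon_shapes, mm)
        named: dict[str, np.ndarray] = {}
        if have_groups:
            Y = aligned.require_aligned()
            diets = np.array(dataset.diets)
            for grp in sorted(set(diets) - {"ungrouped"}):
                named[f"{grp}_mean"] = vector_to_shape(
                    Y[diets == grp].mean(axis=0)
                )
        for cs in cfg["cs_values"]:
            named[f"CS_{cs:g}mm"] = model.predict(cs)
        for s in cfg["pc_scores"]:
            for ax in (1, 2):
                if ax <= pca.n_axes:
                    named[f"PC{ax}_{s:+g}"] = shape_at_score(pca, ax, s)
        if "diet" in cva_models:
            cmodel = cva_models["diet"]
            for s in cfg["cv_scores"]:
                for ax in (1, 2):
                    if ax <= cmodel.axes_reduced.shape[0]:
                        named[f"CV{ax}_{s:+g}"] = cmodel.shape_at_score(ax, s)
        tables["lever_arms_reconstructed"] = advantage_table(named, mm)
        report["lever_arms"] = {
            "taxa": tables["lever_arms_taxa"].round(4).to_dict(orient="index"),
            "reconstructed": tables["lever_arms_reconstructed"]
            .round(4)
            .to_dict(orient="index"),
        }

        stage = "provenance"
        report["provenance"] = {
            "sciurmorph_version": __version__,
            "numpy_version": np.__version__,
            "seed": seed,
            "config": {
                k: (v if not isinstance(v, MuscleMap) else {
                    "condyle_pair": list(v.condyle_pair),
                    "incisor": v.incisor,
                    "insertions": dict(v.insertions),
                })
                for k, v in cfg.items()
            },
            "input_hashes": {
                p.name: _sha256(p)
                for p in sorted(bundle.iterdir())
                if p.is_file()
            },
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = _round_floats(report)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        tdir = out_dir / "tables"
        tdir.mkdir(exist_ok=True)
        for name, table in tables.items():
            table.to_csv(tdir / f"{name}.csv", float_format="%.10g")
        from .io import write_shapes_tps

        write_shapes_tps(shapes_out, out_dir / "shapes.tps")
    return report
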