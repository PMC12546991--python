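"""End-to-end pipeline: simulate -> preprocess -> integrate -> cluster ->
trajectory -> differential expression -> reference transfer.

Each stage writes its artifacts under the configured output directory and
logs one structured line with parameters, seed and shapes.  The run is
fully determined by the config: a fixed seed reproduces byte-identical
artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexp, integrate, mapping, preprocess, simulate, trajectory
from .config import PipelineConfig
from .containers import ClusterLabels, Embedding
from .io import (
    write_cell_meta,
    write_count_matrix,
    write_embedding_csv,
    write_results,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log_stage(stage: str, seed: int, params: dict, shapes: dict) -> None:
    logger.info(
        "stage=%s seed=%d params=%s shapes=%s",
        stage,
        seed,
        json.dumps(params, sort_keys=True, default=str),
        json.dumps(shapes, sort_keys=True),
    )


def select_root(dc: Embedding, mode: str = "min-dc1") -> str:
    """Deterministic root cell: extreme of the first diffusion component."""
    if mode == "min-dc1":
        return dc.cell_ids[int(np.argmin(dc.coordinates[:, 0]))]
    if mode == "max-dc1":
        return dc.cell_ids[int(np.argmax(dc.coordinates[:, 0]))]
    return mode  # treat as an explicit cell id


def run_pipeline(config: PipelineConfig) -> dict[str, list[str]]:
    """Execute all stages in order; returns {stage: [artifact paths]}."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}

    def record(stage: str, *paths) -> None:
        # paths stored relative to outdir so runs are comparable byte-for-byte
        manifest[stage] = [str(Path(p).relative_to(out)) for p in paths]

    # ---- stage 1: simulate -------------------------------------------------
    stage = "simulate"
    try:
        sim = config.simulate
        pops = simulate.default_query_populations(
            n_genes=sim.n_genes,
            n_cells=sim.n_cells_per_population,
            n_markers=sim.n_markers,
            marker_log2fc=sim.marker_log2fc,
            baseline_mean=sim.baseline_mean,
            dispersion=sim.dispersion,
            names=tuple(f"population_{i + 1}" for i in range(sim.n_populations)),
        )
        contaminant = (
            simulate.default_contaminant(
                n_genes=sim.n_genes,
                n_cells=sim.contaminant_cells,
                marker_offset=sim.n_populations * sim.n_markers,
                baseline_mean=sim.baseline_mean,
                dispersion=sim.dispersion,
            )
            if sim.contaminant_cells > 0
            else None
        )
        query, truth = simulate.generate_query_batches(
            pops,
            n_genes=sim.n_genes,
            n_replicates=sim.n_replicates,
            batch_sd=sim.batch_sd,
            cycle_fraction=sim.cycle_fraction,
            cycle_gene_count=sim.cycle_gene_count,
            contaminant=contaminant,
            seed=config.stage_seed(1),
        )
        ref_pops = [
            simulate.PopulationSpec(
                name=p.name,
                n_cells=sim.reference_cells_per_population,
                baseline_mean=p.baseline_mean,
                marker_genes=p.marker_genes,
                marker_log2fc=p.marker_log2fc,
                dispersion=p.dispersion,
            )
            for p in pops[: sim.reference_populations]
        ]
        atlas, ref_truth = simulate.generate_reference_atlas(
            ref_pops, n_genes=sim.n_genes, seed=config.stage_seed(2)
        )
        paths = [out / p for p in (
            "query.mtx", "query_genes.tsv", "query_cells.tsv", "query_meta.csv",
            "query_truth_cells.csv", "query_truth_genes.csv",
            "reference.mtx", "reference_genes.tsv", "reference_cells.tsv",
            "reference_labels.csv",
        )]
        write_count_matrix(query, paths[0], paths[1], paths[2])
        write_cell_meta(query, paths[3])
        write_results(truth.cells, paths[4])
        write_results(truth.genes, paths[5])
        write_count_matrix(atlas.matrix, paths[6], paths[7], paths[8])
        write_results(
            pd.DataFrame({"cell_id": atlas.matrix.cell_ids, "cell_type": atlas.cell_types}),
            paths[9],
        )
        record(stage, *paths)
        _log_stage(stage, config.stage_seed(1), sim.model_dump(),
                   {"query": list(query.counts.shape), "reference": list(atlas.matrix.counts.shape)})
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- stage 2: preprocess ----------------------------------------------
    stage = "preprocess"
    try:
        pp = config.preprocess
        filtered = preprocess.filter_genes(preprocess.filter_cells(query, pp.min_genes))
        sf = preprocess.compute_size_factors(filtered, method=pp.size_factor_method)
        nm = preprocess.normalize_log(filtered, sf)
        # cycle-score marker pairs from the generator's ground truth
        cycle_genes = truth.genes.loc[truth.genes["is_cycle_gene"], "gene_id"]
        present = set(nm.gene_ids)
        pairs = [
            (hi, lo)
            for hi, lo in simulate.cycle_marker_pairs(truth)
            if hi in present and lo in present
        ]
        cc = preprocess.score_cell_cycle(nm, pairs, threshold=pp.g2m_threshold)
        nm = preprocess.regress_out_covariate(
            nm, np.array([1.0 if p == "G2/M" else 0.0 for p in cc.phase])
        ) if len(set(cc.phase)) > 1 else nm
        exclude = {"cycle": set(cycle_genes)}
        hvgs = preprocess.select_hvgs(nm, fraction=pp.hvg_fraction, exclude=exclude)
        p1, p2, p3 = out / "size_factors.csv", out / "cell_cycle.csv", out / "hvgs.csv"
        write_results(pd.DataFrame({"cell_id": nm.cell_ids, "size_factor": sf}), p1)
        write_results(cc.to_frame(), p2)
        write_results(hvgs.to_frame(), p3)
        record(stage, p1, p2, p3)
        _log_stage(stage, config.seed, pp.model_dump(),
                   {"cells": nm.n_cells, "genes": nm.n_genes, "hvgs": len(hvgs)})
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- stage 3: integrate ------------------------------------------------
    stage = "integrate"
    try:
        ig = config.integrate
        reps = sorted(nm.replicates.unique())
        nm_hvg = nm.subset_genes(hvgs.gene_ids)
        batches = [
            nm_hvg.subset_cells((nm_hvg.replicates == r).to_numpy()) for r in reps
        ]
        d_use = min(ig.d, len(hvgs.gene_ids), nm.n_cells)
        emb = integrate.mnn_correct(batches, d=d_use, k=ig.k)
        # restore original cell order
        order = {c: i for i, c in enumerate(emb.cell_ids)}
        perm = [order[c] for c in nm.cell_ids]
        emb = Embedding(
            coordinates=emb.coordinates[perm], cell_ids=list(nm.cell_ids),
            space="mnn-corrected",
        )
        p1 = write_embedding_csv(emb.coordinates, emb.cell_ids, out / "embedding.csv")
        record(stage, p1)
        _log_stage(stage, config.seed, ig.model_dump(), {"cells": emb.coordinates.shape[0], "d": emb.d})
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- stage 4: cluster ---------------------------------------------------
    stage = "cluster"
    try:
        cl = config.cluster
        g = integrate.build_snn_graph(emb, k=cl.snn_k, d=cl.snn_d)
        labels = integrate.louvain_cluster(g, resolution=cl.resolution, seed=config.stage_seed(4))
        pluripotency = truth.genes.loc[
            truth.genes["is_marker_of"].str.contains("contaminant"), "gene_id"
        ]
        pluri = [g_ for g_ in pluripotency if g_ in set(nm.gene_ids)]
        if pluri:
            labels = integrate.apply_cluster_exclusion(
                labels, nm, pluripotency_genes=pluri,
                min_cells=cl.min_cells, imbalance_threshold=cl.imbalance_threshold,
            )
        p1 = write_results(labels.to_frame(), out / "clusters.csv")
        record(stage, p1)
        _log_stage(stage, config.stage_seed(4), cl.model_dump(), {"clusters": labels.n_clusters})
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- stage 5: trajectory -------------------------------------------------
    stage = "trajectory"
    try:
        tj = config.trajectory
        dc = trajectory.diffusion_components(emb, n_comps=tj.n_comps, k=tj.k)
        root = select_root(dc)
        pt = trajectory.diffusion_pseudotime(dc, root)
        conn = trajectory.paga_connectivity(g, labels)
        p1 = write_embedding_csv(dc.coordinates, dc.cell_ids, out / "diffusion.csv")
        p2 = write_results(pt.to_frame(), out / "pseudotime.csv")
        p3 = write_results(pd.DataFrame(conn), out / "connectivity.csv")
        record(stage, p1, p2, p3)
        _log_stage(stage, config.seed, tj.model_dump(), {"root": root, "n_comps": tj.n_comps})
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- stage 6: differential expression -------------------------------------
    stage = "de"
    try:
        de = config.de
        keep = np.array([
            labels.exclusion_flags.get(int(l), "none") == "none" for l in labels.labels
        ])
        sub = filtered.subset_cells(keep)
        sub_labels = labels.labels[keep]
        design = diffexp.design_from_matrix(sub, [f"c{l}" for l in sub_labels])
        sizes = pd.Series(design.cluster).value_counts()
        targets = list(sizes.index[: de.max_clusters])
        marker_paths, marker_sets = [], {}
        for t in targets:
            mt = diffexp.derive_markers(sub, design, t)
            pth = write_results(mt, out / f"markers_{t}.csv")
            marker_paths.append(pth)
            marker_sets[t] = mapping.top_marker_set(mt, p_cut=de.p_cut, top_n=de.top_n, name=t)
        jac = pd.DataFrame(
            [
                {"set_a": a, "set_b": b,
                 "jaccard": mapping.jaccard_similarity(marker_sets[a], marker_sets[b])}
                for a in targets for b in targets
            ]
        )
        pj = write_results(jac, out / "jaccard.csv")
        record(stage, *marker_paths, pj)
        _log_stage(stage, config.seed, de.model_dump(), {"targets": targets})
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- stage 7: transfer -----------------------------------------------------
    stage = "transfer"
    try:
        tr = config.transfer
        ref_nm = mapping.normalize_reference(atlas)
        query_batches = [
            nm.subset_cells((nm.replicates == r).to_numpy()) for r in reps
        ]
        joint, is_ref = mapping.map_to_reference(
            query_batches, ref_nm, hvg_fraction_ref=tr.hvg_fraction_ref,
            d=tr.d, k=min(tr.k, atlas.matrix.n_cells),
        )
        qcl = ClusterLabels(
            cell_ids=list(nm.cell_ids), labels=labels.labels, resolution=labels.resolution
        )
        res = mapping.knn_assign_types(
            joint, is_ref, atlas.cell_types, query_cluster_labels=qcl,
            k=min(tr.k, atlas.matrix.n_cells),
            confidence_threshold=tr.confidence_threshold,
            distance_threshold=tr.distance_threshold, min_cluster=tr.min_cluster,
        )
        p1 = write_results(res, out / "assignments.csv")
        # combined PCA: per-replicate pseudobulks plus reference per-type bulks
        samples = {}
        for r in reps:
            cells = [c for c, rr in zip(filtered.cell_ids, filtered.replicates) if rr == r]
            samples[f"query_{r}"] = mapping.pseudobulk_profile(filtered, cells)
        for t in sorted(set(atlas.cell_types)):
            cells = [c for c, tt in zip(atlas.matrix.cell_ids, atlas.cell_types) if tt == t]
            samples[f"reference_{t}"] = mapping.pseudobulk_profile(atlas.matrix, cells)
        table = pd.DataFrame(samples).reindex(filtered.gene_ids).fillna(0)
        first_target = targets[0]
        coords = mapping.combined_pca(table, marker_sets[first_target])
        p2 = write_results(coords.reset_index(names="sample"), out / "combined_pca.csv")
        record(stage, p1, p2)
        _log_stage(stage, config.seed, tr.model_dump(),
                   {"assigned": int(res.assigned_mask.sum()), "query_cells": len(res)})
    except Exception as e:
        raise StageError(stage, e) from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
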