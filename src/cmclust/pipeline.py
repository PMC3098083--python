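"""Workflow composition: similarity front-ends -> CMC + UPGMA -> artifacts.

``run_matrix_workflow`` is the common back half shared by the three
front-ends (potential grids, sequences, precomputed matrices): given a
similarity and/or distance matrix it runs chaotic map clustering and
the UPGMA baseline and writes a reproducible artifact set — matrices,
a TSV cluster-assignment table, the full theta hierarchy as JSON, the
entropy curve as CSV, a Newick tree, a C_SIM report and a manifest
recording seed, parameters and input checksums.  Re-running with the
same manifest inputs reproduces every file byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .cmc import CMCParams, CMCResult, cmc_cluster
from .matrices import (
    LabeledSquareMatrix,
    distance_to_similarity,
    global_similarity,
    similarity_to_distance,
    write_matrix,
)
from .upgma import upgma_tree, write_newick

logger = logging.getLogger(__name__)

__all__ = ["run_matrix_workflow", "csim_report", "sha256_of"]


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def csim_report(
    sim: LabeledSquareMatrix, class_labels: dict[str, str] | None = None
) -> dict:
    """Global similarity overall and per class, plus the inter-class level.

    ``class_labels`` maps item label -> class name; classes with fewer
    than two members are skipped (a single item has no pairs).  The
    inter-class value is the mean similarity over pairs whose members
    belong to different classes — reporting both exposes the
    intra-class versus inter-class contrast.
    """
    report: dict = {"overall": global_similarity(sim), "n": sim.n}
    if class_labels:
        classes: dict[str, list[int]] = {}
        for idx, label in enumerate(sim.labels):
            cls = class_labels.get(label)
            if cls is not None:
                classes.setdefault(cls, []).append(idx)
        per_class = {}
        for cls, idxs in sorted(classes.items()):
            if len(idxs) < 2:
                continue
            sub = sim.values[np.ix_(idxs, idxs)]
            iu = np.triu_indices(len(idxs), k=1)
            per_class[cls] = {"csim": float(sub[iu].mean()), "n": len(idxs)}
        report["per_class"] = per_class
        member = np.array([class_labels.get(l) for l in sim.labels], dtype=object)
        inter_mask = (member[:, None] != member[None, :]) & np.triu(
            np.ones((sim.n, sim.n), dtype=bool), k=1
        )
        if inter_mask.any():
            report["inter_class"] = float(sim.values[inter_mask].mean())
    return report


def _partition_to_json(partition) -> list[list[str]]:
    return [sorted(cluster) for cluster in partition]


def run_matrix_workflow(
    outdir,
    params: CMCParams,
    sim: LabeledSquareMatrix | None = None,
    dist: LabeledSquareMatrix | None = None,
    class_labels: dict[str, str] | None = None,
    spy_threshold: float | None = None,
    plot: bool = False,
    manifest_extra: dict | None = None,
) -> CMCResult:
    """Cluster one similarity/distance matrix and write the artifact set.

    Exactly one of ``sim``/``dist`` may be omitted; the other is derived
    through D = sqrt(2(1-SI)) (or its inverse SI = 1 - D^2/2).
    """
    if sim is None and dist is None:
        raise ValueError("need a similarity or a distance matrix")
    if dist is None:
        dist = similarity_to_distance(sim)
    if sim is None:
        sim = distance_to_similarity(dist)
    if sim.labels != dist.labels:
        raise ValueError("similarity and distance matrices have different labels")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    result = cmc_cluster(dist, params)
    logger.info(
        "CMC: N=%d K=%d a=%.6g selected theta=%.4f -> %d clusters",
        dist.n, params.K, result.coupling.a, result.selected_theta,
        len(result.selected_partition),
    )

    write_matrix(sim, outdir / "similarity.csv", "csv")
    write_matrix(dist, outdir / "distance.csv", "csv")

    assignments = result.assignments()
    with open(outdir / "assignments.tsv", "w") as fh:
        fh.write("label\tcluster\n")
        for label in dist.labels:
            fh.write(f"{label}\t{assignments[label]}\n")

    hierarchy_json = [
        {"theta": theta, "entropy": entropy, "partition": _partition_to_json(part)}
        for theta, part, entropy in result.hierarchy
    ]
    with open(outdir / "hierarchy.json", "w") as fh:
        json.dump(
            {
                "selected_theta": result.selected_theta,
                "selected_partition": _partition_to_json(result.selected_partition),
                "levels": hierarchy_json,
            },
            fh,
            indent=1,
        )

    with open(outdir / "entropy.csv", "w") as fh:
        fh.write("theta,entropy,n_clusters\n")
        for theta, part, entropy in result.hierarchy:
            fh.write(f"{theta:.6f},{entropy:.12g},{len(part)}\n")

    tree = upgma_tree(dist)
    write_newick(tree, outdir / "upgma.nwk")

    with open(outdir / "csim.json", "w") as fh:
        json.dump(csim_report(sim, class_labels), fh, indent=1)

    if plot:
        from . import viz

        viz.plot_heatmap(sim, outdir / "heatmap.png")
        if spy_threshold is not None:
            viz.plot_spy(sim, spy_threshold, outdir / "spy.png")
        viz.plot_entropy_curve(
            result.hierarchy, dist.n, result.selected_theta, outdir / "entropy.png"
        )

    manifest = {
        "params": asdict(params),
        "n_items": dist.n,
        "local_scale_a": result.coupling.a,
        "selected_theta": result.selected_theta,
        "n_clusters": len(result.selected_partition),
        "outputs": {
            name: sha256_of(outdir / name)
            for name in (
                "similarity.csv",
                "distance.csv",
                "assignments.tsv",
                "hierarchy.json",
                "entropy.csv",
                "upgma.nwk",
                "csim.json",
            )
        },
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return result
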