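"""End-to-end stage orchestration: plate -> phenotypes -> fermentation groups.

Thin glue over the per-stage modules, shared by the CLI, the examples and the
test-suite so the "simulate, calibrate, phenotype, cluster" path is exercised
through one code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ferm_cluster, ph, phenotype

__all__ = ["phenotype_plate", "cluster_fermentation"]


def phenotype_plate(plate: pd.DataFrame, calibration: ph.PhCalibrationModel,
                    window: int = 9, degree: int = 2):
    """Twelve-descriptor profiles for every (glycan, replicate) well.

    Converts the two BCECF channels to pH through the calibration model, then
    extracts descriptors from the paired OD/pH curves.  Returns
    ``(per_replicate, per_glycan)`` descriptor tables; the per-glycan table
    is the replicate mean.
    """
    wide = plate.pivot_table(index=["glycan_id", "replicate", "time"],
                             columns="channel", values="value").reset_index()
    rows = []
    for (glycan, rep), grp in wide.groupby(["glycan_id", "replicate"]):
        grp = grp.sort_values("time")
        t = grp["time"].to_numpy()
        ratio = ph.compute_bcecf_ratio(grp["F_sens"].to_numpy(),
                                       grp["F_iso"].to_numpy())
        ph_series, _ = ph.ratio_to_ph(calibration, ratio)
        prof = phenotype.extract_descriptors(t, grp["OD600"].to_numpy(),
                                             ph_series, window, degree)
        rows.append({"glycan_id": glycan, "replicate": rep,
                     **{n: getattr(prof, n) for n in phenotype.DESCRIPTOR_NAMES}})
    per_rep = pd.DataFrame(rows)
    per_glycan = (per_rep.drop(columns="replicate")
                  .groupby("glycan_id").mean())
    return per_rep, per_glycan


def cluster_fermentation(descriptors: pd.DataFrame, k: int | str = "elbow",
                         kmax: int = 12):
    """Z-score -> Manhattan/complete tree -> elbow cut.

    ``descriptors`` is glycans x 12 (replicate means).  Returns
    ``(assignment, tree, wcss_curve)``; ``k`` may be fixed or "elbow".
    """
    z = ferm_cluster.zscore(descriptors)
    tree = ferm_cluster.hcluster(z, metric="manhattan", linkage="complete")
    curve = ferm_cluster.wcss_for_cuts(z, tree, kmax=kmax)
    if k == "elbow":
        k = ferm_cluster.select_k_elbow(curve)
    assignment = ferm_cluster.cut_tree(tree, int(k), ids=descriptors.index)
    return assignment, tree, curve
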