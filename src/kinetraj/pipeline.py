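"""End-to-end orchestration of the comparative analysis workflow.

A :class:`RunConfig` names the input trajectory (or replicas), the region
selections (loop, hinge, ligand, fit region), and every stage parameter —
each defaulting to the standard analysis settings (100 K-means centers, 100
iterations, 4.5 Å contact cutoff at 75% occupancy, 0.3 correlation display
mask, 1 kcal/mol significance threshold, 300 K).  :func:`run_pipeline`
executes the stages in order (stability → correlation → collective motions →
MSM → energetics → network), writes per-stage TSV/JSON artifacts plus a log
of effective parameters, and returns a machine-readable report.
:func:`compare_systems` puts two reports side by side — the apo-vs-bound /
isoform-vs-isoform comparisons that motivate the whole workflow.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import collective, correlation, energetics, msm, network, stability
from .constants import DEFAULT_TEMPERATURE
from .traj import Selection, Trajectory, select

__all__ = ["RunConfig", "run_pipeline", "compare_systems"]

ALL_STAGES = ("stability", "correlation", "collective", "msm", "energetics", "network")


@dataclass
class RunConfig:
    """Declarative configuration of one system's analysis run."""

    trajectory: Trajectory
    selections: dict = field(default_factory=dict)  # name -> expression
    seed: int = 0
    stages: tuple = ALL_STAGES
    output_dir: str | None = None
    # stage parameters (defaults follow the standard protocol)
    mask_threshold: float = 0.3
    fel_bins: int = 100
    temperature: float = DEFAULT_TEMPERATURE
    kmeans_k: int = 100
    kmeans_max_iter: int = 100
    msm_lag: int = 1
    msm_n_metastates: int = 2
    contact_cutoff: float = 4.5
    contact_occupancy: float = 0.75
    energy_threshold: float = 1.0
    pca_n_modes: int = 2
    # optional energy inputs: (complex, receptor, ligand) EnergyTable triple
    energy_tables: tuple | None = None
    pairwise_energy_table: pd.DataFrame | None = None

    def effective_parameters(self) -> dict:
        return {
            "seed": self.seed,
            "stages": list(self.stages),
            "mask_threshold": self.mask_threshold,
            "fel_bins": self.fel_bins,
            "temperature_K": self.temperature,
            "kmeans_k": self.kmeans_k,
            "kmeans_max_iter": self.kmeans_max_iter,
            "msm_lag_frames": self.msm_lag,
            "msm_n_metastates": self.msm_n_metastates,
            "contact_cutoff_A": self.contact_cutoff,
            "contact_occupancy": self.contact_occupancy,
            "energy_threshold_kcal_mol": self.energy_threshold,
            "pca_n_modes": self.pca_n_modes,
            "selections": dict(self.selections),
        }


def _resolve(config: RunConfig, name: str, default_expr: str | None = None) -> Selection | None:
    expr = config.selections.get(name, default_expr)
    if expr is None:
        return None
    return select(config.trajectory.topology, expr)


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages over one system and return the report bundle.

    Any stage failure aborts with the stage name and cause; artifacts from
    stages already completed remain on disk when ``output_dir`` is set.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": config.effective_parameters()}
    traj = config.trajectory
    fit_sel = _resolve(config, "fit", "calpha")
    report_sel = _resolve(config, "report", "calpha")
    loop_sel = _resolve(config, "loop")
    hinge_sel = _resolve(config, "hinge")
    ligand_sel = _resolve(config, "ligand", "ligand")

    stage = None
    try:
        if "stability" in config.stages:
            stage = "stability"
            series = stability.rmsd_series(traj, 0, fit_sel, report_sel)
            mean, sd = stability.equilibrated_stats(series)
            res_ids, fluct = stability.rmsf(traj, report_sel, fit_sel)
            report["stability"] = {
                "rmsd_series": series,
                "rmsd_equilibrated_mean": mean,
                "rmsd_equilibrated_sd": sd,
                "rmsf_residue_ids": res_ids,
                "rmsf": fluct,
            }
            if out_dir:
                pd.DataFrame({"frame": np.arange(len(series)), "rmsd": series}).to_csv(
                    out_dir / "rmsd.tsv", sep="\t", index=False
                )
                pd.DataFrame({"residue_id": res_ids, "rmsf": fluct}).to_csv(
                    out_dir / "rmsf.tsv", sep="\t", index=False
                )

        if "correlation" in config.stages:
            stage = "correlation"
            C = correlation.dccm(traj, report_sel, fit_sel)
            masked = correlation.mask_correlations(C, config.mask_threshold)
            report["correlation"] = {"matrix": C, "masked": masked}
            if loop_sel is not None and hinge_sel is not None:
                loop_res = sorted(
                    {traj.topology.residue_of_atom(i) for i in loop_sel}
                )
                hinge_res = sorted(
                    {traj.topology.residue_of_atom(i) for i in hinge_sel}
                )
                report["correlation"]["loop_hinge_summary"] = (
                    correlation.region_correlation_summary(C, loop_res, hinge_res)
                )
            if out_dir:
                correlation.write_correlation_tsv(C, out_dir / "dccm.tsv")

        if "collective" in config.stages:
            stage = "collective"
            pca = collective.fit_pca(
                traj, report_sel, n_modes=min(config.pca_n_modes, traj.n_frames - 1)
            )
            fel = collective.free_energy_landscape(
                pca.projections[:, 0],
                pca.projections[:, min(1, pca.n_modes - 1)],
                n_bins=config.fel_bins,
                temperature=config.temperature,
            )
            report["collective"] = {"pca": pca, "fel": fel}
            if loop_sel is not None and ligand_sel is not None and len(ligand_sel):
                dist = collective.loop_distance_series(traj, loop_sel, ligand_sel)
                report["collective"]["loop_ligand_distance"] = dist
                report["collective"]["loop_ligand_distance_mean"] = float(dist.mean())
            if out_dir:
                pd.DataFrame(
                    pca.projections,
                    columns=[f"PC{i+1}" for i in range(pca.n_modes)],
                ).to_csv(out_dir / "pca_projections.tsv", sep="\t", index=False)

        if "msm" in config.stages:
            stage = "msm"
            pca = report.get("collective", {}).get("pca")
            if pca is None:
                pca = collective.fit_pca(traj, report_sel, n_modes=2)
            k = min(config.kmeans_k, max(2, traj.n_frames // 10))
            labels = msm.cluster_microstates(
                pca.projections, k, config.kmeans_max_iter, config.seed
            )
            model = msm.estimate_transition_matrix(
                labels, config.msm_lag, frame_interval=traj.frame_interval
            )
            partition = msm.pcca_metastates(model, config.msm_n_metastates)
            reps = msm.representative_frames(partition, labels, pca.projections)
            report["msm"] = {
                "labels": labels,
                "model": model,
                "partition": partition,
                "representative_frames": reps,
            }
            if out_dir:
                np.savetxt(out_dir / "msm_labels.tsv", labels, fmt="%d")
                with open(out_dir / "msm_model.json", "w") as fh:
                    json.dump(
                        {
                            "lag": model.lag,
                            "transition_matrix": model.transition_matrix.tolist(),
                            "stationary_distribution": model.stationary_distribution.tolist(),
                            "memberships": partition.memberships.tolist(),
                        },
                        fh,
                        indent=1,
                    )

        if "energetics" in config.stages and config.energy_tables is not None:
            stage = "energetics"
            cpx, rec, lig = config.energy_tables
            result = energetics.mmgbsa_combine(cpx, rec, lig)
            report["energetics"] = {"binding": result}
            if config.pairwise_energy_table is not None:
                contributions = energetics.per_residue_decompose(
                    config.pairwise_energy_table, config.energy_threshold
                )
                report["energetics"]["per_residue"] = contributions
            if out_dir:
                with open(out_dir / "mmgbsa.json", "w") as fh:
                    json.dump(
                        {
                            "component_means": result.component_means,
                            "component_sds": result.component_sds,
                            "total_mean": result.total_mean,
                            "total_sd": result.total_sd,
                        },
                        fh,
                        indent=1,
                    )

        if "network" in config.stages:
            stage = "network"
            C = report.get("correlation", {}).get("matrix")
            if C is None:
                C = correlation.dccm(traj, report_sel, fit_sel)
            edges = network.contact_edges(
                traj,
                cutoff=config.contact_cutoff,
                occupancy=config.contact_occupancy,
            )
            # edges may touch the ligand residue, which the DCCM (protein CA
            # selection) does not cover; keep protein-protein edges for weighting
            known = set(int(r) for r in C.residue_ids)
            protein_edges = [e for e in edges if e[0] in known and e[1] in known]
            graph = network.weight_edges(protein_edges, C)
            partition = network.girvan_newman_communities(graph)
            summary = network.network_summary(partition)
            report["network"] = {
                "edges": edges,
                "graph": graph,
                "partition": partition,
                "summary": summary,
            }
            if loop_sel is not None and hinge_sel is not None:
                loop_res = {traj.topology.residue_of_atom(i) for i in loop_sel}
                hinge_res = {traj.topology.residue_of_atom(i) for i in hinge_sel}
                lh_edges = [
                    e
                    for e in edges
                    if (e[0] in loop_res and e[1] in hinge_res)
                    or (e[1] in loop_res and e[0] in hinge_res)
                ]
                link = None
                cl = {partition.community_of.get(r) for r in loop_res} - {None}
                ch = {partition.community_of.get(r) for r in hinge_res} - {None}
                for (a, b), s in partition.intercommunity_links.items():
                    if (a in cl and b in ch) or (b in cl and a in ch):
                        link = (a, b, s)
                report["network"]["loop_hinge_contact_edges"] = lh_edges
                report["network"]["loop_hinge_link"] = link
            if out_dir:
                network.export_graph_json(graph, partition, out_dir / "network.json")

        if out_dir:
            with open(out_dir / "run_log.json", "w") as fh:
                json.dump(report["parameters"], fh, indent=1)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report


def compare_systems(report_a: dict, report_b: dict) -> dict:
    """Side-by-side deltas between two report bundles (B − A).

    Covers the quantities the comparative study reads off: equilibrated RMSD
    means, per-residue RMSF, loop–hinge correlation blocks, loop–ligand
    distance, binding energy, and community counts.  Stages absent from
    either report are skipped.
    """
    out: dict = {}
    if "stability" in report_a and "stability" in report_b:
        sa, sb = report_a["stability"], report_b["stability"]
        out["delta_rmsd_mean"] = (
            sb["rmsd_equilibrated_mean"] - sa["rmsd_equilibrated_mean"]
        )
        ids_a = np.asarray(sa["rmsf_residue_ids"])
        ids_b = np.asarray(sb["rmsf_residue_ids"])
        if not np.array_equal(ids_a, ids_b):
            unmatched = sorted(set(ids_a.tolist()) ^ set(ids_b.tolist()))
            raise ValueError(f"residue maps differ between systems: {unmatched}")
        out["delta_rmsf"] = sb["rmsf"] - sa["rmsf"]
        out["delta_rmsf_mean"] = float(out["delta_rmsf"].mean())
        out["rmsf_residue_ids"] = ids_a
    if "correlation" in report_a and "correlation" in report_b:
        la = report_a["correlation"].get("loop_hinge_summary")
        lb = report_b["correlation"].get("loop_hinge_summary")
        if la and lb:
            out["delta_loop_hinge_correlation"] = lb["mean"] - la["mean"]
    if "collective" in report_a and "collective" in report_b:
        da = report_a["collective"].get("loop_ligand_distance_mean")
        db = report_b["collective"].get("loop_ligand_distance_mean")
        if da is not None and db is not None:
            out["delta_loop_ligand_distance"] = db - da
    if "energetics" in report_a and "energetics" in report_b:
        ba = report_a["energetics"]["binding"]
        bb = report_b["energetics"]["binding"]
        out["delta_binding_energy"] = bb.total_mean - ba.total_mean
    if "network" in report_a and "network" in report_b:
        na = report_a["network"]["summary"]
        nb = report_b["network"]["summary"]
        out["delta_n_communities"] = nb["n_communities"] - na["n_communities"]
        out["delta_n_pathways"] = nb["n_pathways"] - na["n_pathways"]
        out["loop_hinge_link_a"] = report_a["network"].get("loop_hinge_link")
        out["loop_hinge_link_b"] = report_b["network"].get("loop_hinge_link")
    return out
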