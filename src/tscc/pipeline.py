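"""Two-stage combinatorial clustering (TSCC) orchestration.

Stage one clusters docked poses by their protein-ligand interaction
profiles (correlation distance, UPGMA, cut at the stage-1 reference
threshold). Stage two re-clusters the compounds of each stage-1 cluster by
2D atom-pair descriptors (Tanimoto distance, UPGMA, cut at the stage-2
reference threshold) and selects the lowest-docked-energy member of every
sub-cluster as its final representative. All intermediates are persisted
as TSV/Newick/JSON artifacts so a run is fully auditable and reproducible.
"""
from __future__ import annotations

import json
import logging
import re
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import interaction, structio
from .atompair import MolGraph, descriptor_matrix
from .cluster import (
    ClusterAssignment,
    ClusterTree,
    cut_tree,
    pairwise_distances,
    to_newick,
    upgma,
)
from .interaction import (
    DEFAULT_EPSILON,
    DEFAULT_ES_CUTOFF,
    DEFAULT_PLP,
    PLPParams,
    ProfileMatrix,
    atom_profile,
    build_profile_matrix,
)
from .structio import LigandPose, ReceptorSite, extract_binding_site, read_poses, read_receptor

logger = logging.getLogger("tscc")

#: reference thresholds calibrated on docked verification sets: 0.39 on the
#: correlation distance of interaction profiles, 0.55 on the Tanimoto
#: distance of atom-pair descriptors.
DEFAULT_STAGE1_THRESHOLD = 0.39
DEFAULT_STAGE2_THRESHOLD = 0.55


@dataclass
class TSCCConfig:
    """Run configuration; defaults reproduce the standard protocol."""

    stage1_threshold: float = DEFAULT_STAGE1_THRESHOLD
    stage2_threshold: float = DEFAULT_STAGE2_THRESHOLD
    site_radius: float = 10.0
    plp: Mapping[str, PLPParams] = field(default_factory=lambda: dict(DEFAULT_PLP))
    es_cutoff: float = DEFAULT_ES_CUTOFF
    include_electrostatics: bool = True
    epsilon: float = DEFAULT_EPSILON
    energy_field: str = "docked_energy"
    default_energy: float | None = None
    reference_ligand: str | None = None  # path; None -> union of all poses
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.stage1_threshold <= 2):
            raise ValueError("stage1 threshold must lie in [0, 2]")
        if not (0 <= self.stage2_threshold <= 1):
            raise ValueError("stage2 threshold must lie in [0, 1]")
        if self.site_radius <= 0:
            raise ValueError("site_radius must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "TSCCConfig":
        """Load a YAML or JSON config; the ``plp`` section maps class name
        to {V1..V6}."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        plp_raw = raw.pop("plp", None)
        cfg = cls(**raw)
        if plp_raw:
            params = dict(DEFAULT_PLP)
            for cls_name, vals in plp_raw.items():
                params[cls_name] = PLPParams(
                    *(float(vals[f"V{k}"]) for k in range(1, 7))
                )
            cfg.plp = params
        return cfg

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["plp"] = {
            name: {f"V{k}": getattr(p, f"v{k}") for k in range(1, 7)}
            for name, p in self.plp.items()
        }
        return d


@dataclass
class Representative:
    """Final selected compound: one per stage-2 sub-cluster."""

    stage1_cluster: str
    stage2_cluster: str
    pose_id: str
    docked_energy: float


@dataclass
class TSCCReport:
    """Everything a TSCC run produced."""

    stage1_assignment: ClusterAssignment
    stage2_assignments: dict[str, ClusterAssignment]
    representatives: list[Representative]
    artifact_paths: dict[str, str] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "stage1_clusters": self.stage1_assignment.clusters(),
            "stage1_cut_height": self.stage1_assignment.cut_height,
            "stage2_clusters": {
                lab: asg.clusters() for lab, asg in sorted(self.stage2_assignments.items())
            },
            "representatives": [asdict(r) for r in self.representatives],
            "artifacts": dict(sorted(self.artifact_paths.items())),
        }


def dedupe_poses(poses: Sequence[LigandPose]) -> list[LigandPose]:
    """Keep the minimum-energy pose per compound id (ties: first in file).

    One pose per compound is assumed downstream; duplicates of the same
    pose_id are collapsed here.
    """
    best: dict[str, LigandPose] = {}
    order: list[str] = []
    for p in poses:
        if p.pose_id not in best:
            best[p.pose_id] = p
            order.append(p.pose_id)
        elif p.docked_energy < best[p.pose_id].docked_energy:
            best[p.pose_id] = p
    return [best[pid] for pid in order]


def run_stage1(
    site: ReceptorSite, poses: Sequence[LigandPose], cfg: TSCCConfig
) -> tuple[ProfileMatrix, ClusterTree, ClusterAssignment]:
    """Interaction profiles -> correlation distances -> UPGMA -> cut."""
    if len(poses) < 2:
        raise ValueError("stage 1 needs at least 2 poses")
    profiles = [
        atom_profile(
            site,
            pose,
            params=cfg.plp,
            es_cutoff=cfg.es_cutoff,
            include_electrostatics=cfg.include_electrostatics,
        )
        for pose in poses
    ]
    matrix = build_profile_matrix(profiles, epsilon=cfg.epsilon, site=site)
    dm = pairwise_distances(matrix.values, "correlation", ids=matrix.pose_ids)
    tree = upgma(dm)
    assignment = cut_tree(tree, cfg.stage1_threshold)
    return matrix, tree, assignment


def _select_representative(
    members: Sequence[LigandPose],
) -> LigandPose:
    # minimum docked energy; ties broken by lexicographically smallest id
    return min(members, key=lambda p: (p.docked_energy, p.pose_id))


def run_stage2(
    members: Sequence[LigandPose], cfg: TSCCConfig
) -> tuple[ClusterTree | None, ClusterAssignment, list[tuple[str, LigandPose]]]:
    """Atom-pair descriptors -> Tanimoto distances -> UPGMA -> cut -> reps.

    A single-member cluster yields one sub-cluster with that member as its
    representative (no tree).
    """
    if not members:
        raise ValueError("stage 2 needs at least 1 member")
    by_id = {p.pose_id: p for p in members}
    if len(members) == 1:
        only = members[0]
        assignment = ClusterAssignment(
            labels={only.pose_id: only.pose_id}, cut_height=cfg.stage2_threshold
        )
        return None, assignment, [(only.pose_id, only)]
    graphs = [MolGraph.from_pose(p) for p in members]
    mat, _ = descriptor_matrix(graphs)
    dm = pairwise_distances(mat, "tanimoto", ids=[p.pose_id for p in members])
    tree = upgma(dm)
    assignment = cut_tree(tree, cfg.stage2_threshold)
    reps = [
        (label, _select_representative([by_id[pid] for pid in group]))
        for label, group in assignment.clusters().items()
    ]
    return tree, assignment, reps


def _safe(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", label)


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", index_label=index_label)


def run_tscc(
    receptor_path: str | Path,
    poses_path: str | Path,
    cfg: TSCCConfig,
    out_dir: str | Path,
    restrict_clusters: Sequence[str] | None = None,
) -> TSCCReport:
    """Full two-stage run from files to artifacts.

    The binding site is cut at ``cfg.site_radius`` around the reference
    ligand (``cfg.reference_ligand`` if given, else the union of all docked
    pose atoms). ``restrict_clusters`` limits stage 2 to the named stage-1
    clusters; by default every cluster is processed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    t0 = time.perf_counter()
    receptor = read_receptor(receptor_path)
    poses = dedupe_poses(
        read_poses(poses_path, cfg.energy_field, cfg.default_energy)
    )
    if cfg.reference_ligand:
        ref = read_poses(cfg.reference_ligand, cfg.energy_field, 0.0)[0].coords
    else:
        ref = np.vstack([p.coords for p in poses])
    site = extract_binding_site(receptor, ref, cfg.site_radius)
    logger.info(
        "loaded %d poses, site of %d/%d atoms (%.2fs)",
        len(poses), len(site), len(receptor), time.perf_counter() - t0,
    )

    t1 = time.perf_counter()
    matrix, tree1, stage1 = run_stage1(site, poses, cfg)
    path = out / "stage1_profiles.tsv"
    _write_tsv(matrix.to_dataframe(), path, "pose_id")
    artifacts["stage1_profiles"] = str(path)
    path = out / "stage1_tree.nwk"
    path.write_text(to_newick(tree1) + "\n")
    artifacts["stage1_tree"] = str(path)
    path = out / "stage1_clusters.tsv"
    _write_tsv(
        pd.DataFrame(
            {"cluster": [stage1.labels[p.pose_id] for p in poses]},
            index=[p.pose_id for p in poses],
        ),
        path,
        "pose_id",
    )
    artifacts["stage1_clusters"] = str(path)
    logger.info(
        "stage 1: %d clusters from %d involved atoms (%.2fs)",
        stage1.n_clusters, matrix.n_involved_atoms, time.perf_counter() - t1,
    )

    t2 = time.perf_counter()
    by_id = {p.pose_id: p for p in poses}
    stage2_assignments: dict[str, ClusterAssignment] = {}
    representatives: list[Representative] = []
    for label, member_ids in stage1.clusters().items():
        if restrict_clusters is not None and label not in restrict_clusters:
            continue
        members = [by_id[pid] for pid in member_ids]
        tree2, asg, reps = run_stage2(members, cfg)
        stage2_assignments[label] = asg
        safe = _safe(label)
        if tree2 is not None:
            path = out / f"stage2_{safe}_tree.nwk"
            path.write_text(to_newick(tree2) + "\n")
            artifacts[f"stage2_{safe}_tree"] = str(path)
        path = out / f"stage2_{safe}_clusters.tsv"
        _write_tsv(
            pd.DataFrame(
                {"cluster": [asg.labels[pid] for pid in member_ids]},
                index=member_ids,
            ),
            path,
            "pose_id",
        )
        artifacts[f"stage2_{safe}_clusters"] = str(path)
        for sub_label, rep in reps:
            representatives.append(
                Representative(
                    stage1_cluster=label,
                    stage2_cluster=sub_label,
                    pose_id=rep.pose_id,
                    docked_energy=rep.docked_energy,
                )
            )
    representatives.sort(key=lambda r: (r.stage1_cluster, r.stage2_cluster))
    rep_df = pd.DataFrame(
        [asdict(r) for r in representatives],
        columns=["stage1_cluster", "stage2_cluster", "pose_id", "docked_energy"],
    )
    path = out / "representatives.tsv"
    rep_df.to_csv(path, sep="\t", float_format="%.10g", index=False)
    artifacts["representatives"] = str(path)
    logger.info(
        "stage 2: %d sub-clusters -> %d representatives (%.2fs)",
        sum(a.n_clusters for a in stage2_assignments.values()),
        len(representatives), time.perf_counter() - t2,
    )

    report = TSCCReport(
        stage1_assignment=stage1,
        stage2_assignments=stage2_assignments,
        representatives=representatives,
        artifact_paths=artifacts,
    )
    # report stores artifact file names relative to the output directory so
    # reruns into different directories produce byte-identical reports
    rel = TSCCReport(
        stage1_assignment=stage1,
        stage2_assignments=stage2_assignments,
        representatives=representatives,
        artifact_paths={k: Path(v).name for k, v in artifacts.items()},
    )
    payload = {"config": cfg.to_jsonable(), **rel.to_jsonable()}
    path = out / "report.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    report.artifact_paths["report"] = str(path)
    return report
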