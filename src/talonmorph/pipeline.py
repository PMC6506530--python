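"""The full study workflow, from synthetic radiation to comparative tables.

Stages: simulate a diet-structured talon radiation on a phylogeny; build
each species' surface/volume mesh and ground-truth landmarks; scale every
model to the reference species' surface area; solve the grip load case;
sample von Mises stress at the selected landmarks; run GPA + PCA; the
shape and stress diet ANOVAs with pairwise tests; the four-model allometry
battery; and the phylogenetic battery (K_mult for shape and stress, PGLS
for diet and size). Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .fea import BONE, ElasticMaterial, grip_load_case, solve_grip
from .gmm import (AlignedShapes, PCAResult, StatResult, allometric_regression,
                  gpa, pairwise_group_tests, pca, procrustes_anova)
from .landmarks import LandmarkSet
from .pcm import kmult, pgls
from .phylo import Phylo
from .semilandmarks import project_semilandmarks
from .stress import StressProfile, default_selection, sample_vm_at_landmarks
from .talon import RadiationSpec, make_talon, simulate_radiation

log = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """One end-to-end study run."""

    radiation: RadiationSpec = field(default_factory=RadiationSpec)
    resolution: tuple[int, int, int] = (32, 16, 4)
    reference_species: str = "Accipiter_fasciatus"
    material: ElasticMaterial = BONE
    total_grip_force: float = 9.77   # N, in vivo hawk grip force
    n_digits: int = 4
    perms: int = 499
    seed: int = 1
    landmark_selection: list[str] | None = None   # default: 26-landmark scheme
    use_template_projection: bool = False
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        rad = RadiationSpec(**raw.pop("radiation", {}))
        mat = ElasticMaterial(**raw.pop("material", {})) if "material" in raw else BONE
        if "resolution" in raw:
            raw["resolution"] = tuple(raw["resolution"])
        return cls(radiation=rad, material=mat, **raw)

    def digest(self) -> str:
        blob = json.dumps({
            "radiation": {k: (v if not isinstance(v, (dict, tuple)) else str(v))
                          for k, v in vars(self.radiation).items() if k != "tree"},
            "resolution": self.resolution, "reference": self.reference_species,
            "material": [self.material.youngs_modulus, self.material.poisson_ratio],
            "force": self.total_grip_force, "digits": self.n_digits,
            "perms": self.perms, "seed": self.seed,
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    shape_anova: StatResult
    shape_pairwise: tuple[list[str], np.ndarray]
    stress_anova: StatResult
    stress_pairwise: tuple[list[str], np.ndarray]
    allometry: dict[str, StatResult]        # the four-model battery
    kmult_shape: "object"
    kmult_stress: "object"
    pgls_tests: dict[str, StatResult]
    pca: PCAResult
    aligned: AlignedShapes
    profiles: list[StressProfile]
    species_table: pd.DataFrame
    tree: Phylo
    mean_vm: dict[str, float]
    timings: dict[str, float]
    provenance: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        """Report tables in the study's layout (pairwise p above the
        diagonal; allometry battery of exactly four models)."""
        def pw_frame(levels, pmat):
            return pd.DataFrame(pmat, index=levels, columns=levels)

        def stat_rows(d: dict[str, StatResult]) -> pd.DataFrame:
            return pd.DataFrame([{"model": k, **v.as_dict()} for k, v in d.items()])

        return {
            "shape_anova": stat_rows({"shape~diet": self.shape_anova}),
            "shape_pairwise": pw_frame(*self.shape_pairwise),
            "stress_anova": stat_rows({"mean_vm~diet": self.stress_anova}),
            "stress_pairwise": pw_frame(*self.stress_pairwise),
            "allometry": stat_rows(self.allometry),
            "pcm": pd.concat([
                pd.DataFrame([
                    {"model": "kmult_shape", "K": self.kmult_shape.k,
                     "p": self.kmult_shape.p},
                    {"model": "kmult_stress", "K": self.kmult_stress.k,
                     "p": self.kmult_stress.p}]),
                stat_rows(self.pgls_tests)], ignore_index=True),
            "pc_variance": pd.DataFrame(
                {"component": np.arange(1, len(self.pca.pct_variance) + 1),
                 "pct_variance": self.pca.pct_variance}),
            "mean_vm": pd.DataFrame(
                {"species": list(self.mean_vm), "mean_vm": list(self.mean_vm.values())}),
        }

    def to_json(self) -> str:
        out = {name: df.to_dict(orient="records")
               for name, df in self.tables().items()}
        out["provenance"] = self.provenance
        return json.dumps(out, indent=2, default=float)


def run_study(config: StudyConfig) -> StudyReport:
    """Execute every stage of the study under one seed; see module docs."""
    timings: dict[str, float] = {}
    t_all = time.time()

    def tick(name, t0):
        timings[name] = time.time() - t0
        log.info("stage %s: %.2fs", name, timings[name])

    # --- radiation
    t0 = time.time()
    rad = config.radiation
    rad.seed = rad.seed if rad.seed is not None else config.seed
    params, table, tree = simulate_radiation(rad)
    species = list(table["species"])
    diet = dict(zip(table["species"], table["diet"]))
    if config.reference_species not in species:
        raise ValueError(f"reference species {config.reference_species!r} "
                         "absent from the radiation")
    tick("radiation", t0)

    # --- geometry
    t0 = time.time()
    meshes, tris, lms = {}, {}, {}
    for sp in species:
        tri, tet, lm = make_talon(params[sp], config.resolution)
        lm.specimen_id = sp
        meshes[sp], tris[sp], lms[sp] = tet, tri, lm
    tick("geometry", t0)

    # --- template projection of semilandmarks (optional; ground-truth
    # landmarks are homologous by construction and are the default)
    if config.use_template_projection:
        t0 = time.time()
        ref = config.reference_species
        fixed_labels = [lb for lb, k in zip(lms[ref].labels, lms[ref].kind)
                        if k == "fixed"]
        for sp in species:
            if sp == ref:
                continue
            lms[sp] = project_semilandmarks(
                lms[ref], tris[ref], lms[sp].subset(fixed_labels), tris[sp])
            lms[sp].specimen_id = sp
        tick("projection", t0)

    # --- scale-free FEA + stress sampling
    t0 = time.time()
    ref_area = meshes[config.reference_species].surface_area()
    case = grip_load_case(config.total_grip_force, config.n_digits)
    profiles = []
    selection = config.landmark_selection
    for sp in species:
        field_, scaled_mesh = solve_grip(meshes[sp], case, config.material,
                                         reference_area=ref_area)
        sfac = float(np.sqrt(ref_area / meshes[sp].surface_area()))
        lm_scaled = LandmarkSet(sp, lms[sp].points * sfac, list(lms[sp].labels),
                                list(lms[sp].kind), list(lms[sp].curve_id))
        sel = selection or default_selection(lm_scaled)
        profiles.append(sample_vm_at_landmarks(field_, scaled_mesh, lm_scaled, sel))
    tick("fea", t0)

    # --- GPA / PCA
    t0 = time.time()
    aligned = gpa([lms[sp] for sp in species])
    pca_res = pca(aligned)
    tick("gpa", t0)

    # --- diet ANOVAs
    t0 = time.time()
    groups = [diet[sp] for sp in species]
    seed = config.seed
    shape_anova = procrustes_anova(aligned, groups=groups,
                                   n_perm=config.perms, seed=seed)
    shape_pw = pairwise_group_tests(aligned, groups,
                                    n_perm=config.perms, seed=seed + 1)
    vm = np.array([p.mean_vm for p in profiles])
    stress_anova = procrustes_anova(vm, groups=groups,
                                    n_perm=config.perms, seed=seed + 2)
    stress_pw = pairwise_group_tests(vm, groups,
                                     n_perm=config.perms, seed=seed + 3)
    tick("anova", t0)

    # --- allometry battery (four models)
    t0 = time.time()
    cs = aligned.centroid_sizes
    allom = {
        "shape~size": allometric_regression(
            aligned, cs, n_perm=config.perms, seed=seed + 4),
        "shape~size_noNP": allometric_regression(
            aligned, cs, groups=groups, exclude_group="NP",
            n_perm=config.perms, seed=seed + 5),
        "vm~size": allometric_regression(
            vm, cs, n_perm=config.perms, seed=seed + 6),
        "vm~size_noNP": allometric_regression(
            vm, cs, groups=groups, exclude_group="NP",
            n_perm=config.perms, seed=seed + 7),
    }
    tick("allometry", t0)

    # --- phylogenetic battery
    t0 = time.time()
    Y = aligned.flat()
    km_shape = kmult(Y, tree, tip_order=species, n_perm=config.perms, seed=seed + 8)
    km_vm = kmult(vm, tree, tip_order=species, n_perm=config.perms, seed=seed + 9)
    keep = [sp for sp in species if diet[sp] != "NP"]
    kidx = [species.index(sp) for sp in keep]
    sub = tree.subset(keep)
    pgls_tests = {
        "pgls_shape~diet": pgls(Y, tree, groups=groups, tip_order=species,
                                n_perm=config.perms, seed=seed + 10),
        "pgls_shape~size": pgls(Y, tree, covariate=cs, tip_order=species,
                                n_perm=config.perms, seed=seed + 11),
        "pgls_shape~size_noNP": pgls(Y[kidx], sub, covariate=cs[kidx],
                                     tip_order=keep, n_perm=config.perms,
                                     seed=seed + 12),
        "pgls_vm~diet": pgls(vm, tree, groups=groups, tip_order=species,
                             n_perm=config.perms, seed=seed + 13),
        "pgls_vm~size": pgls(vm, tree, covariate=cs, tip_order=species,
                             n_perm=config.perms, seed=seed + 14),
        "pgls_vm~size_noNP": pgls(vm[kidx], sub, covariate=cs[kidx],
                                  tip_order=keep, n_perm=config.perms,
                                  seed=seed + 15),
    }
    tick("pcm", t0)
    timings["total"] = time.time() - t_all

    report = StudyReport(
        shape_anova=shape_anova, shape_pairwise=shape_pw,
        stress_anova=stress_anova, stress_pairwise=stress_pw,
        allometry=allom, kmult_shape=km_shape, kmult_stress=km_vm,
        pgls_tests=pgls_tests, pca=pca_res, aligned=aligned,
        profiles=profiles, species_table=table, tree=tree,
        mean_vm=dict(zip(species, vm)), timings=timings,
        provenance={"seed": config.seed, "perms": config.perms,
                    "config_hash": config.digest(),
                    "n_species": len(species),
                    "resolution": list(config.resolution)})

    if config.output_dir:
        _write_outputs(report, config, meshes, lms)
    return report


def _write_outputs(report: StudyReport, config: StudyConfig,
                   meshes, lms) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.tables().items():
        df.to_csv(out / f"{name}.csv", index=bool(name.endswith("pairwise")))
    (out / "report.json").write_text(report.to_json())
    report.tree.write(out / "tree.nwk")
    report.species_table.to_csv(out / "species.csv", index=False)
    tio.write_landmarks_csv(list(lms.values()), out / "landmarks.csv")
    mesh_dir = out / "meshes"
    mesh_dir.mkdir(exist_ok=True)
    for sp, mesh in meshes.items():
        tio.write_mesh(mesh, mesh_dir / f"{sp}.node")
    pd.concat([p.to_frame() for p in report.profiles]).to_csv(
        out / "stress_profiles.csv", index=False)
    log.info("wrote study outputs to %s", out)
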